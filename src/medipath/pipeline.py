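"""End-to-end orchestration of the microbiome-mediated genome scan.

Stages (thresholds configurable via :class:`PipelineSettings`):

1.  OTU preprocessing: sparsity filter -> zero replacement -> CLR.
2.  Trait standardization (mean 0, SD 1, recorded once at ingest so
    variance-absorbed proportions stay well defined).
3.  Design-effect collapsing: one standardized (CGb, Sr) pair per response
    (each trait and each CLR feature).
4.  MWAS (Mod2) and mediator selection: a microbial feature is kept for a
    factor's trait triplet iff it is Bonferroni-significant on all three
    traits, absorbs > 1% of variance on all three, and its sampling stage
    does not postdate any trait in the triplet (causal-timing constraint).
5.  GWAS (Mod1) totals per trait; candidates with gamma p < 0.01 go to
    bootstrap-only empirical testing.
6.  Mediation path model (Mod4) per (marker, mediator, trait); triples with
    mediated/direct ratio > 1 are empirical-test candidates, prioritized by
    Sobel p and capped at ``max_candidates``.
7.  Latent models (Mod1L / Mod4L) for each factor, run on the marker set
    surfaced by the measured analysis.
8.  Bootstrap + permutation on mediation candidates; a triple is a
    discovery only if it passes both. Discovered markers are grouped into
    contiguous 10-SNP windows per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import scan
from .compositions import OtuTable, clr_transform, filter_otus, replace_zeros
from .design_effects import collapse_all
from .empirical_tests import bootstrap_test, joint_decision, permutation_test
from .latent_sem import LatentSpec, fit_sem, indirect_effect_latent
from .mediation import _fit_arrays, fit_mediation, sobel_test
from .simulate import CohortData

__all__ = [
    "PipelineSettings",
    "MediatorSelection",
    "DiscoveryTable",
    "select_mediators",
    "screen_candidates",
    "group_windows",
    "count_annotation_overlaps",
    "run_pipeline",
]

_STAGE_ORDER = {"S1": 1, "S2": 2, "S3": 3}


@dataclass
class PipelineSettings:
    """Thresholds and sizes for one pipeline run."""

    min_total: int = 1200
    max_zero_fraction: float = 0.80
    delta_fraction: float = 0.65
    mediator_p: float = 0.05  # Bonferroni-adjusted MWAS threshold
    min_var_absorbed: float = 0.01
    ratio_threshold: float = 1.0
    gamma_p_threshold: float = 0.01
    n_rounds: int = 1000
    level: float = 0.95
    max_candidates: int = 100
    include_latent: bool = True
    max_latent_candidates: int = 10
    window_size: int = 10
    trait_stages: dict[str, str] = field(default_factory=dict)
    seed: int = 0


@dataclass
class MediatorSelection:
    """Per-mediator decision record for one factor's trait triplet."""

    mediator: str
    factor: str
    traits: tuple[str, str, str]
    p_bonferroni: dict[str, float]
    var_absorbed: dict[str, float]
    stage_compatible: bool
    selected: bool


@dataclass
class DiscoveryTable:
    """Row-level results plus windows; all summaries derive from the rows."""

    records: pd.DataFrame
    windows: pd.DataFrame
    mediator_selection: list[MediatorSelection]
    stage_counts: dict[str, int]

    def summary(self) -> pd.DataFrame:
        """Discovery counts per response x mediator, recomputed from rows."""
        disc = self.records[self.records["joint_sig"] == True]  # noqa: E712
        if disc.empty:
            return pd.DataFrame(columns=["response", "mediator", "n_markers"])
        return (
            disc.groupby(["response", "mediator"])["marker"]
            .nunique()
            .reset_index(name="n_markers")
        )

    def venn_partition(self) -> dict[str, set]:
        """Partition discovered markers into latent-only / measured-only /
        shared sets (exhaustive and disjoint)."""
        disc = self.records[self.records["joint_sig"] == True]  # noqa: E712
        latent = set(disc.loc[disc["response_kind"] == "latent", "marker"])
        measured = set(disc.loc[disc["response_kind"] == "measured", "marker"])
        return {
            "latent_only": latent - measured,
            "measured_only": measured - latent,
            "shared": latent & measured,
        }


def select_mediators(
    mwas: pd.DataFrame,
    factor: str,
    traits: tuple[str, str, str],
    mediator_stages: dict[str, str],
    trait_stages: dict[str, str],
    p_threshold: float = 0.05,
    min_var_absorbed: float = 0.01,
) -> list[MediatorSelection]:
    """Apply the three-part mediator-selection rule for one trait triplet.

    ``mwas`` is the tidy Mod2 scan table. A mediator is selected iff its
    Bonferroni-adjusted p is below ``p_threshold`` AND its variance absorbed
    exceeds ``min_var_absorbed`` on every trait of the triplet, AND it was
    sampled no later than the earliest-recorded trait in the triplet.
    """
    if len(traits) != 3:
        raise ValueError("a factor's trait triplet must have exactly 3 traits")
    missing = [t for t in traits if t not in set(mwas["response"])]
    if missing:
        raise ValueError(f"MWAS results missing traits: {missing}")
    earliest = min(_STAGE_ORDER[trait_stages.get(t, "S3")] for t in traits)
    out = []
    for mediator, sub in mwas[mwas["response"].isin(traits)].groupby("feature"):
        sub = sub.set_index("response")
        p = {t: float(sub.loc[t, "p_bonferroni"]) for t in traits}
        va = {t: float(sub.loc[t, "var_absorbed"]) for t in traits}
        stage_ok = _STAGE_ORDER[mediator_stages.get(mediator, "S3")] <= earliest
        selected = (
            stage_ok
            and all(p[t] < p_threshold for t in traits)
            and all(va[t] > min_var_absorbed for t in traits)
        )
        out.append(
            MediatorSelection(mediator, factor, tuple(traits), p, va, stage_ok, selected)
        )
    return out


def screen_candidates(
    fits: pd.DataFrame,
    total_fits: pd.DataFrame,
    ratio_threshold: float = 1.0,
    gamma_p_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split fitted results into empirical-test candidate lists.

    Mediation candidates: path fits with mediated/direct ratio strictly
    above ``ratio_threshold``. Total-effect candidates: Mod1 rows with
    gamma p-value strictly below ``gamma_p_threshold`` (bootstrap only).
    Empty lists are legitimate outcomes.
    """
    med = fits[fits["ratio"] > ratio_threshold].copy()
    tot = total_fits[total_fits["p"] < gamma_p_threshold].copy()
    return med, tot


def group_windows(markers: pd.DataFrame, window_size: int = 10) -> pd.DataFrame:
    """Greedy left-to-right grouping of markers into contiguous SNP windows.

    ``markers`` needs columns ``marker``, ``chrom``, ``index`` (ordinal
    position on the genotyping panel). Within a chromosome, a marker joins
    the current window while its panel index is within ``window_size`` of
    the window's seed (first member); otherwise it opens a new window.
    """
    required = {"marker", "chrom", "index"}
    if not required.issubset(markers.columns):
        raise ValueError(f"markers frame needs columns {sorted(required)}")
    if markers[["chrom", "index"]].isna().any().any():
        raise ValueError("marker without chromosome/position")
    rows = []
    wid = 0
    for chrom, sub in markers.sort_values(["chrom", "index"]).groupby("chrom"):
        seed = None
        members: list[str] = []
        start = end = None
        for _, row in sub.iterrows():
            if seed is not None and row["index"] - seed <= window_size:
                members.append(row["marker"])
                end = row["index"]
            else:
                if members:
                    rows.append((wid, chrom, start, end, len(members), members))
                    wid += 1
                seed, start, end = row["index"], row["index"], row["index"]
                members = [row["marker"]]
        if members:
            rows.append((wid, chrom, start, end, len(members), members))
            wid += 1
    return pd.DataFrame(
        rows, columns=["window", "chrom", "start_index", "end_index", "n_markers", "markers"]
    )


def count_annotation_overlaps(
    windows: pd.DataFrame, annotation: pd.DataFrame,
    marker_info: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Count annotation intervals (BED-like: chrom, start, end, category)
    overlapping each discovery window; returns counts per category.

    Window bounds are panel indices unless ``marker_info`` (with ``chrom``,
    ``index``, ``pos``) is supplied to translate them to positions.
    """
    need = {"chrom", "start", "end", "category"}
    if not need.issubset(annotation.columns):
        raise ValueError(f"annotation needs columns {sorted(need)}")
    win = windows.copy()
    if marker_info is not None:
        pos_map = marker_info.set_index(["chrom", "index"])["pos"]
        win["start_pos"] = [pos_map[(c, i)] for c, i in zip(win["chrom"], win["start_index"])]
        win["end_pos"] = [pos_map[(c, i)] for c, i in zip(win["chrom"], win["end_index"])]
    else:
        win["start_pos"] = win["start_index"]
        win["end_pos"] = win["end_index"]
    counts: dict[str, int] = {}
    for _, w in win.iterrows():
        hits = annotation[
            (annotation["chrom"] == w["chrom"])
            & (annotation["start"] <= w["end_pos"])
            & (annotation["end"] >= w["start_pos"])
        ]
        for cat in hits["category"]:
            counts[cat] = counts.get(cat, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["category", "n_windows"]
    )


# ---------------------------------------------------------------------------

def _standardize_frame(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=0)


def run_pipeline(cohort: CohortData, settings: PipelineSettings | None = None) -> DiscoveryTable:
    """Run the full framework on one cohort; deterministic given settings."""
    s = settings or PipelineSettings()
    stage_counts: dict[str, int] = {}

    # 1-2: preprocessing -------------------------------------------------
    counts = filter_otus(cohort.otus, s.min_total, s.max_zero_fraction)
    clr = clr_transform(replace_zeros(counts, s.delta_fraction))
    stage_counts["otus_kept"] = len(clr.feature_ids)
    traits = _standardize_frame(cohort.phenotypes)
    dosages = cohort.genotypes.dosages
    damline = cohort.design["damline"].to_numpy(float)
    mediator_stages = {f: clr.stage for f in clr.feature_ids}

    # 3: collapsed covariates per response --------------------------------
    clr_std = _standardize_frame(clr.data)
    covs = collapse_all(pd.concat([traits, clr_std], axis=1), cohort.design)

    # 4: MWAS + mediator selection ---------------------------------------
    mwas = scan(traits, clr.data, covs, damline, model="mod2")
    stage_counts["mwas_tests"] = len(mwas)
    factors = {
        f: tuple(t for t, _, _ in entries)
        for f, entries in cohort.config.loadings.items()
    }
    selection: list[MediatorSelection] = []
    for factor, triplet in factors.items():
        selection += select_mediators(
            mwas, factor, triplet, mediator_stages, s.trait_stages,
            s.mediator_p, s.min_var_absorbed,
        )
    selected = sorted({sel.mediator for sel in selection if sel.selected})
    stage_counts["mediators_selected"] = len(selected)

    # 5: GWAS totals ------------------------------------------------------
    gwas = scan(traits, dosages, covs, damline, model="mod1")
    stage_counts["gwas_tests"] = len(gwas)

    # 6: mediation fits + screening --------------------------------------
    med_rows = []
    cov_arrays = {
        name: np.column_stack([c["CGb"], damline, c["Sr"]]) for name, c in covs.items()
    }
    G_all = dosages.to_numpy(float)
    marker_cols = list(dosages.columns)
    for mediator in selected:
        M = clr.data[mediator].to_numpy(float)
        cm = cov_arrays[mediator]
        med_traits = [
            t for f, triplet in factors.items() for t in triplet
            if any(sel.selected and sel.mediator == mediator and sel.factor == f
                   for sel in selection)
        ]
        for trait in med_traits:
            P = traits[trait].to_numpy(float)
            cp = cov_arrays[trait]
            for j, marker in enumerate(marker_cols):
                fit = fit_mediation(P, M, G_all[:, j], cm, cp)
                if fit.untestable:
                    continue
                z, p_sobel = sobel_test(fit)
                med_rows.append(
                    (marker, mediator, trait, fit.alpha, fit.beta,
                     fit.gamma_direct, fit.indirect, fit.ratio, z, p_sobel)
                )
    med_fits = pd.DataFrame(
        med_rows,
        columns=["marker", "mediator", "response", "alpha", "beta",
                 "gamma_direct", "indirect", "ratio", "sobel_z", "sobel_p"],
    )
    med_cand, tot_cand = screen_candidates(
        med_fits, gwas.rename(columns={"feature": "marker"}),
        s.ratio_threshold, s.gamma_p_threshold,
    )
    med_cand = med_cand.sort_values("sobel_p").head(s.max_candidates)
    stage_counts["mediation_candidates"] = len(med_cand)
    stage_counts["total_effect_candidates"] = len(tot_cand)

    # 7: latent models on the surfaced marker set -------------------------
    latent_rows = []
    if s.include_latent and selected:
        latent_markers = list(
            med_cand.sort_values("sobel_p")["marker"].unique()[: s.max_latent_candidates]
        )
        for factor, triplet in factors.items():
            spec = LatentSpec(
                factor, list(triplet),
                cg_adjusters=[f"CGb_{t}" for t in triplet],
                sr_adjusters=[f"Sr_{t}" for t in triplet],
            )
            base = pd.DataFrame(
                {t: traits[t].to_numpy(float) for t in triplet}
                | {f"CGb_{t}": covs[t]["CGb"].to_numpy(float) for t in triplet}
                | {f"Sr_{t}": covs[t]["Sr"].to_numpy(float) for t in triplet}
                | {"damline": damline},
            )
            factor_mediators = [
                sel.mediator for sel in selection
                if sel.selected and sel.factor == factor
            ]
            for mediator in factor_mediators:
                for marker in latent_markers:
                    df = base.copy()
                    df["M"] = clr.data[mediator].to_numpy(float)
                    df["G"] = dosages[marker].to_numpy(float)
                    df["CGbm"] = covs[mediator]["CGb"].to_numpy(float)
                    df["Srm"] = covs[mediator]["Sr"].to_numpy(float)
                    try:
                        fit = fit_sem(
                            df, spec, "mod4l", g_col="G", m_col="M",
                            damline_col="damline", m_cov_cols=("CGbm", "Srm"),
                            compute_se=False,
                        )
                    except (RuntimeError, ValueError):
                        continue
                    alpha = fit.structural["alpha"][0]
                    beta = fit.structural["beta_m"][0]
                    gamma_d = fit.structural["gamma_g"][0]
                    indirect = indirect_effect_latent(fit)
                    ratio = (
                        np.inf if gamma_d == 0 and indirect != 0
                        else abs(indirect) / abs(gamma_d) if gamma_d != 0 else 0.0
                    )
                    latent_rows.append(
                        (marker, mediator, factor, alpha, beta, gamma_d,
                         indirect, ratio, np.nan, np.nan)
                    )
    latent_fits = pd.DataFrame(latent_rows, columns=med_fits.columns)
    stage_counts["latent_fits"] = len(latent_fits)

    # 8: empirical tests --------------------------------------------------
    rng = np.random.default_rng(s.seed)
    records = []
    latent_cand = (
        latent_fits[latent_fits["ratio"] > s.ratio_threshold]
        .assign(_mag=lambda d: d["indirect"].abs())
        .sort_values("_mag", ascending=False)
        .head(s.max_latent_candidates)
        .drop(columns="_mag")
    )
    for kind, cand in (("measured", med_cand), ("latent", latent_cand)):
        for _, row in cand.iterrows():
            marker, mediator, response = row["marker"], row["mediator"], row["response"]
            if kind == "measured":
                data = pd.DataFrame({
                    "P": traits[response].to_numpy(float),
                    "M": clr.data[mediator].to_numpy(float),
                    "G": dosages[marker].to_numpy(float),
                    "CGbm": covs[mediator]["CGb"].to_numpy(float),
                    "Srm": covs[mediator]["Sr"].to_numpy(float),
                    "CGbp": covs[response]["CGb"].to_numpy(float),
                    "Srp": covs[response]["Sr"].to_numpy(float),
                    "damline": damline,
                })
                fitter = _measured_fitter
            else:
                triplet = factors[response]
                data = pd.DataFrame(
                    {t: traits[t].to_numpy(float) for t in triplet}
                    | {f"CGb_{t}": covs[t]["CGb"].to_numpy(float) for t in triplet}
                    | {f"Sr_{t}": covs[t]["Sr"].to_numpy(float) for t in triplet}
                    | {
                        "damline": damline,
                        "M": clr.data[mediator].to_numpy(float),
                        "G": dosages[marker].to_numpy(float),
                        "CGbm": covs[mediator]["CGb"].to_numpy(float),
                        "Srm": covs[mediator]["Sr"].to_numpy(float),
                    },
                )
                fitter = _latent_fitter_factory(response, list(triplet))
            boot_seed = int(rng.integers(0, 2**31 - 1))
            perm_seed = int(rng.integers(0, 2**31 - 1))
            try:
                boot = bootstrap_test(fitter, data, "indirect", s.n_rounds,
                                      s.level, boot_seed)
                perm = permutation_test(fitter, data, "M", "indirect",
                                        s.n_rounds, s.level, perm_seed)
            except RuntimeError:
                continue
            joint = joint_decision({"bootstrap": boot, "permutation": perm})
            records.append({
                "marker": marker, "mediator": mediator, "response": response,
                "response_kind": kind,
                "alpha": row["alpha"], "beta": row["beta"],
                "gamma_direct": row["gamma_direct"],
                "indirect": row["indirect"], "ratio": row["ratio"],
                "sobel_p": row["sobel_p"],
                "boot_lower": boot.lower, "boot_upper": boot.upper,
                "boot_sig": boot.significant,
                "perm_lower": perm.lower, "perm_upper": perm.upper,
                "perm_sig": perm.significant, "joint_sig": joint,
            })
    # bootstrap-only totals
    for _, row in tot_cand.iterrows():
        marker, response = row["marker"], row["response"]
        data = pd.DataFrame({
            "P": traits[response].to_numpy(float),
            "G": dosages[marker].to_numpy(float),
            "CGbp": covs[response]["CGb"].to_numpy(float),
            "Srp": covs[response]["Sr"].to_numpy(float),
            "damline": damline,
        })
        boot_seed = int(rng.integers(0, 2**31 - 1))
        try:
            boot = bootstrap_test(_total_fitter, data, "gamma", s.n_rounds,
                                  s.level, boot_seed)
        except RuntimeError:
            continue
        records.append({
            "marker": marker, "mediator": None, "response": response,
            "response_kind": "total",
            "alpha": np.nan, "beta": np.nan, "gamma_direct": np.nan,
            "indirect": np.nan, "ratio": np.nan, "sobel_p": np.nan,
            "boot_lower": boot.lower, "boot_upper": boot.upper,
            "boot_sig": boot.significant,
            "perm_lower": np.nan, "perm_upper": np.nan,
            "perm_sig": np.nan, "joint_sig": boot.significant,
        })
    records_df = pd.DataFrame(records)
    stage_counts["empirical_records"] = len(records_df)

    # windows over jointly significant mediation markers ------------------
    if len(records_df):
        disc = records_df[
            (records_df["joint_sig"] == True)  # noqa: E712
            & (records_df["response_kind"] != "total")
        ]
        sig_markers = sorted(set(disc["marker"]))
    else:
        sig_markers = []
    info = cohort.genotypes.marker_info
    windows = group_windows(
        info[info["marker"].isin(sig_markers)], s.window_size
    ) if sig_markers else pd.DataFrame(
        columns=["window", "chrom", "start_index", "end_index", "n_markers", "markers"]
    )
    stage_counts["discovery_windows"] = len(windows)

    return DiscoveryTable(records_df, windows, selection, stage_counts)


def _measured_fitter(data: pd.DataFrame) -> dict:
    G = data["G"].to_numpy(float)
    M = data["M"].to_numpy(float)
    if np.ptp(G) == 0 or np.ptp(M) == 0:
        raise RuntimeError("untestable resample (constant G or M)")
    covs_m = data[["CGbm", "damline", "Srm"]].to_numpy(float)
    covs_p = data[["CGbp", "damline", "Srp"]].to_numpy(float)
    alpha, beta, _ = _fit_arrays(
        data["P"].to_numpy(float), M, G, covs_m, covs_p, np.ones(len(data))
    )
    return {"indirect": alpha * beta, "alpha": alpha, "beta": beta}


def _total_fitter(data: pd.DataFrame) -> dict:
    X = np.column_stack([
        np.ones(len(data)), data["G"], data["CGbp"], data["damline"], data["Srp"],
    ])
    coef = np.linalg.lstsq(X, data["P"].to_numpy(), rcond=None)[0]
    return {"gamma": coef[1]}


def _latent_fitter_factory(factor: str, triplet: list[str]):
    spec = LatentSpec(
        factor, triplet,
        cg_adjusters=[f"CGb_{t}" for t in triplet],
        sr_adjusters=[f"Sr_{t}" for t in triplet],
    )
    state = {"theta": None}

    def fitter(data: pd.DataFrame) -> dict:
        fit = fit_sem(
            data, spec, "mod4l", g_col="G", m_col="M", damline_col="damline",
            m_cov_cols=("CGbm", "Srm"), compute_se=False, theta0=state["theta"],
        )
        if state["theta"] is None:
            state["theta"] = fit.theta
        return {
            "indirect": indirect_effect_latent(fit),
            "alpha": fit.structural["alpha"][0],
            "beta": fit.structural["beta_m"][0],
        }

    return fitter
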