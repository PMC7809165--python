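"""Plain-text readers and writers for the framework's tabular formats.

Genotypes travel as PLINK ``.raw``-style whitespace tables (header
``FID IID PAT MAT SEX PHENOTYPE`` followed by one dosage column per
marker), OTU counts as samples x features TSV, phenotypes and design
factors as CSV, and simulation / run configuration as YAML.
"""

from __future__ import annotations

import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compositions import OtuTable
from .simulate import GenotypeMatrix, N_CHROMOSOMES, SimConfig

__all__ = [
    "write_plink_raw", "read_plink_raw",
    "write_otu_tsv", "read_otu_tsv",
    "write_csv", "read_csv",
    "write_sim_config", "read_sim_config",
]

_ALLELE_SUFFIX = re.compile(r"_[ACGT]$")


def write_plink_raw(genotypes: GenotypeMatrix, path: str | Path) -> None:
    d = genotypes.dosages
    out = pd.DataFrame({
        "FID": d.index, "IID": d.index,
        "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9,
    })
    out = pd.concat([out.reset_index(drop=True),
                     d.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=" ", index=False)


def read_plink_raw(path: str | Path) -> GenotypeMatrix:
    """Read a .raw dosage table; trailing allele suffixes (snp_A) are
    stripped from marker names. Marker metadata (chromosome, panel index)
    is reconstructed by even assignment over the autosomes, matching the
    generator's layout."""
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    markers = [c for c in df.columns if c not in meta_cols]
    dosages = df[markers].copy()
    dosages.columns = [_ALLELE_SUFFIX.sub("", c) for c in markers]
    dosages.index = df["IID"].astype(str)
    m = len(dosages.columns)
    chrom = 1 + (np.arange(m) * N_CHROMOSOMES) // m
    within = np.concatenate(
        [np.arange((chrom == c).sum()) for c in range(1, N_CHROMOSOMES + 1)]
    )
    info = pd.DataFrame({
        "marker": list(dosages.columns), "chrom": chrom,
        "index": within, "pos": (within + 1) * 50_000,
    })
    return GenotypeMatrix(dosages=dosages, marker_info=info)


def write_otu_tsv(table: OtuTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample")


def read_otu_tsv(path: str | Path, stage: str = "S2", kind: str = "counts") -> OtuTable:
    data = pd.read_csv(path, sep="\t", index_col="sample")
    data.index.name = None
    return OtuTable(data=data, stage=stage, kind=kind)


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="id")


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")


def write_sim_config(config: SimConfig, path: str | Path) -> None:
    payload = asdict(config)
    payload["maf_range"] = list(payload["maf_range"])
    payload["genetic_effects"] = [list(e) for e in payload["genetic_effects"]]
    payload["mediator_effects"] = [list(e) for e in payload["mediator_effects"]]
    payload["direct_effects"] = [list(e) for e in payload["direct_effects"]]
    payload["loadings"] = {
        k: [list(e) for e in v] for k, v in payload["loadings"].items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_sim_config(path: str | Path) -> SimConfig:
    payload = yaml.safe_load(Path(path).read_text())
    payload["maf_range"] = tuple(payload["maf_range"])
    for key in ("genetic_effects", "mediator_effects", "direct_effects"):
        payload[key] = [tuple(e) for e in payload.get(key, [])]
    if "loadings" in payload:
        payload["loadings"] = {
            k: [tuple(e) for e in v] for k, v in payload["loadings"].items()
        }
    return SimConfig(**payload)
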