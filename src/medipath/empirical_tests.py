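"""Empirical significance for mediated paths: bootstrap and permutation.

The Sobel test assumes normality of the product alpha'*beta', which is
doubtful in finite samples, so two resampling tests back it up:

* **Percentile bootstrap** — resample complete records with replacement,
  refit, and build a percentile confidence interval around the point
  estimate; significant iff 0 falls outside the interval.
* **Path-breaking permutation** — shuffle the mediator column only, which
  severs both the G->M and M->P arms of the mediated path while leaving the
  direct path intact; the permuted indirect estimates form the null
  distribution, and significance is declared iff the observed (unshuffled)
  indirect effect falls outside the null percentile interval.

Both operate on any deterministic fitter that maps a data table to a scalar
target (the indirect product by default; per-coefficient nulls are stored
for audit). A triple is declared a discovery only when it passes both tests
(:func:`joint_decision`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TestResult",
    "bootstrap_test",
    "permutation_test",
    "joint_decision",
]


@dataclass
class TestResult:
    """Outcome of one empirical significance test."""

    __test__ = False  # not a pytest collectable despite the name

    method: str  # sobel | bootstrap | permutation
    target: str
    estimate: float
    lower: float
    upper: float
    n_rounds: int
    n_failed: int
    seed: int | None
    significant: bool
    round_estimates: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isnan(self.lower) and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def _percentile_interval(values: np.ndarray, level: float) -> tuple[float, float]:
    tail = (1.0 - level) / 2.0
    return (
        float(np.quantile(values, tail)),
        float(np.quantile(values, 1.0 - tail)),
    )


def bootstrap_test(
    fitter,
    data: pd.DataFrame,
    target: str = "indirect",
    n_rounds: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    keep_rounds: bool = False,
) -> TestResult:
    """Percentile-bootstrap interval for a fitted quantity.

    ``fitter(data) -> dict`` must return at least ``{target: value}`` and be
    deterministic given the data. Rows are resampled with replacement
    ``n_rounds`` times; significance means 0 lies outside the percentile
    interval. Rounds where the fitter raises are excluded and counted; more
    than 10% failures aborts.
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    observed = fitter(data)
    estimates, failed = [], 0
    for _ in range(n_rounds):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            estimates.append(fitter(sample)[target])
        except Exception:
            failed += 1
    if failed > 0.10 * n_rounds:
        raise RuntimeError(
            f"bootstrap unstable: {failed}/{n_rounds} rounds failed"
        )
    values = np.asarray(estimates, float)
    lower, upper = _percentile_interval(values, level)
    return TestResult(
        method="bootstrap",
        target=target,
        estimate=float(observed[target]),
        lower=lower,
        upper=upper,
        n_rounds=n_rounds,
        n_failed=failed,
        seed=seed,
        significant=not (lower <= 0.0 <= upper),
        round_estimates=values if keep_rounds else None,
    )


def permutation_test(
    fitter,
    data: pd.DataFrame,
    mediator_col: str,
    target: str = "indirect",
    n_rounds: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    keep_rounds: bool = False,
) -> TestResult:
    """Path-breaking permutation test for the mediated effect.

    Each round shuffles only the mediator column (jointly breaking the
    G->M and M->P links), refits, and records the target estimate; the
    percentile interval of the permuted estimates is the null interval.
    Significant iff the observed estimate falls outside it. Per-coefficient
    null intervals for alpha' and beta' are stored in ``extra`` when the
    fitter reports them.
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    observed = fitter(data)
    estimates, failed = [], 0
    aux = {k: [] for k in ("alpha", "beta") if k in observed}
    for _ in range(n_rounds):
        shuffled = data.copy()
        shuffled[mediator_col] = data[mediator_col].to_numpy()[rng.permutation(n)]
        try:
            res = fitter(shuffled)
        except Exception:
            failed += 1
            continue
        estimates.append(res[target])
        for k in aux:
            aux[k].append(res[k])
    if failed > 0.10 * n_rounds:
        raise RuntimeError(
            f"permutation unstable: {failed}/{n_rounds} rounds failed"
        )
    values = np.asarray(estimates, float)
    lower, upper = _percentile_interval(values, level)
    est = float(observed[target])
    extra = {
        f"null_interval_{k}": _percentile_interval(np.asarray(v, float), level)
        for k, v in aux.items()
    }
    return TestResult(
        method="permutation",
        target=target,
        estimate=est,
        lower=lower,
        upper=upper,
        n_rounds=n_rounds,
        n_failed=failed,
        seed=seed,
        significant=not (lower <= est <= upper),
        round_estimates=values if keep_rounds else None,
        extra=extra,
    )


def joint_decision(results: dict[str, TestResult],
                   rule: tuple[str, ...] = ("bootstrap", "permutation")) -> bool:
    """A triple is a discovery iff every required method is significant."""
    if not rule:
        raise ValueError("empty requirement set")
    missing = [m for m in rule if m not in results]
    if missing:
        raise ValueError(f"missing test results for: {missing}")
    return all(results[m].significant for m in rule)
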