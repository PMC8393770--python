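"""PCA-based spectral outlier screening.

Samples are flagged on two criteria, mirroring common chemometric
practice: (1) a standardized orthogonal residual (S-distance) more than
``residual_z_threshold`` standard deviations above the calibration-set
mean S-distance, and (2) leverage above ``leverage_multiplier`` times
the average leverage.  Two average-leverage formulas are available: the
standard hat-matrix average (1 + A)/n, and the literal published form
1/(n + A/n), kept selectable for reproducibility of the source
protocol.  Screening refits the PCA and repeats until no sample is
flagged or ``max_rounds`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ibernir.latent_core import fit_pca, pca_project


@dataclass
class OutlierPolicy:
    residual_z_threshold: float = 2.0
    leverage_multiplier: float = 3.0
    leverage_formula: str = "standard"  # or "as_printed"
    A: int | None = None  # default: PCs for 95% variance, capped at 10
    max_rounds: int = 5

    def __post_init__(self) -> None:
        if self.residual_z_threshold <= 0 or self.leverage_multiplier <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.leverage_formula not in ("standard", "as_printed"):
            raise ValueError("leverage_formula must be 'standard' or 'as_printed'")


@dataclass
class OutlierReport:
    """Flagged sample ids per screening round, with reasons."""

    rounds: list[dict[str, str]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for rnd in self.rounds:
            out.update(rnd)
        return out

    def to_frame(self):
        import pandas as pd

        rows = [
            {"sample_id": sid, "round": i + 1, "reason": reason}
            for i, rnd in enumerate(self.rounds)
            for sid, reason in rnd.items()
        ]
        return pd.DataFrame(rows, columns=["sample_id", "round", "reason"])


def average_leverage(n: int, A: int, formula: str = "standard") -> float:
    """Average leverage of an A-component model fitted on n samples.

    "standard" gives the hat-matrix trace average (1 + A)/n;
    "as_printed" reproduces the published expression 1/(n + A/n).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if A < 1:
        raise ValueError("need A >= 1")
    if formula == "standard":
        return (1.0 + A) / n
    if formula == "as_printed":
        return 1.0 / (n + A / n)
    raise ValueError(f"unknown formula {formula!r}")


def _screen_A(X: np.ndarray, policy: OutlierPolicy) -> int:
    if policy.A is not None:
        return policy.A
    n, p = X.shape
    cap = min(10, n - 1, p)
    model = fit_pca(X, cap)
    cum = np.cumsum(model.explained_variance_ratio)
    hits = np.nonzero(cum >= 0.95)[0]
    return int(hits[0]) + 1 if hits.size else model.A


def flag_outliers(model, X: np.ndarray, policy: OutlierPolicy) -> dict[int, str]:
    """Single screening round against a fitted PCA model.

    Returns {row index: reason} with reason in {residual, leverage, both}.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to screen")
    _, s_dist, lev = pca_project(model, X)
    sd = np.std(s_dist, ddof=1)
    if sd <= 0:
        z = np.zeros(n)
    else:
        z = (s_dist - s_dist.mean()) / sd
    h_bar = average_leverage(model.n_train, model.A, policy.leverage_formula)
    res_flag = z > policy.residual_z_threshold
    lev_flag = lev > policy.leverage_multiplier * h_bar
    out: dict[int, str] = {}
    for i in range(n):
        if res_flag[i] and lev_flag[i]:
            out[i] = "both"
        elif res_flag[i]:
            out[i] = "residual"
        elif lev_flag[i]:
            out[i] = "leverage"
    return out


def iterative_outlier_removal(
    X: np.ndarray,
    policy: OutlierPolicy | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[np.ndarray, OutlierReport]:
    """Screen-and-refit loop: remove flagged samples, refit PCA, repeat.

    Stops when a round flags nothing, ``max_rounds`` is reached, or a
    further removal would leave fewer than 10 samples (those flags are
    not applied).  Returns the retained row indices and the report.
    """
    policy = policy or OutlierPolicy()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for outlier screening")
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    keep = np.arange(n)
    report = OutlierReport()
    for _ in range(policy.max_rounds):
        A = _screen_A(X[keep], policy)
        model = fit_pca(X[keep], A)
        flags = flag_outliers(model, X[keep], policy)
        if not flags:
            break
        if len(keep) - len(flags) < 10:
            break
        report.rounds.append({ids[keep[i]]: reason for i, reason in flags.items()})
        keep = np.delete(keep, sorted(flags))
    report.retained = [ids[i] for i in keep]
    return keep, report
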