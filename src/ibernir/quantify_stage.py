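"""Per-trait PLSR pipelines with cross-validation and external validation.

For each quality trait (dry matter, NaCl, α-/γ-tocopherol, four major
fatty acids plus linolenic acid, lipid and protein oxidation indices)
the pipeline applies a pre-treatment preset, screens spectral outliers
per trait model, runs leave-one-out cross-validation over 1..A_max
latent variables, selects the LV count from the SECV curve, refits at
that count, and validates externally with R²v, RMSEV and the RPD/RER
practical-utility indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ibernir.latent_core import PLSModel, fit_pls, loo_cv, pls_predict, select_components
from ibernir.metrics_report import r_squared, rpd_rer
from ibernir.outlier_screen import OutlierPolicy, OutlierReport, iterative_outlier_removal
from ibernir.preprocess import apply_pipeline
from ibernir.spectra_io import SpectraSet, SpectraError

#: The eleven modelled quality traits and their units.
TRAITS: dict[str, str] = {
    "DM": "g/100 g",
    "NaCl": "g/100 g",
    "alpha_tocopherol": "ug/g",
    "gamma_tocopherol": "ug/g",
    "C16:0": "g/100 g FAME",
    "C18:0": "g/100 g FAME",
    "C18:1 n-9": "g/100 g FAME",
    "C18:2 n-6": "g/100 g FAME",
    "C18:3 n-3": "g/100 g FAME",
    "MDA": "mg MDA/kg",
    "carbonyls": "nmol carbonyls/mg protein",
}


@dataclass
class TraitModelResult:
    """Everything reported for one trait model (one table row)."""

    trait: str
    pretreatment: str
    A: int
    n: int
    one_minus_vr: float
    rmsecv: float
    secv: float
    r2v: float | None = None
    rmsev: float | None = None
    rpdv: float | None = None
    rerv: float | None = None
    outliers: OutlierReport | None = None

    def as_row(self) -> dict:
        return {
            "trait": self.trait,
            "pretreatment": self.pretreatment,
            "LVs": self.A,
            "n": self.n,
            "one_minus_VR": self.one_minus_vr,
            "RMSECV": self.rmsecv,
            "R2v": self.r2v,
            "RMSEV": self.rmsev,
            "RPDv": self.rpdv,
            "RERv": self.rerv,
        }


def fit_trait_model(
    cal: SpectraSet,
    trait: str,
    preset: str = "SNV-DE SG 1,4,4,1",
    A_max: int = 10,
    policy: OutlierPolicy | None = None,
    tol: float = 0.02,
) -> tuple[TraitModelResult, PLSModel, SpectraSet]:
    """Full calibration pipeline for one trait.

    Returns the result record, the final PLS model (fit at the selected
    LV count on the outlier-screened samples) and the pre-treated,
    screened calibration set the model was fit on.
    """
    if cal.traits is None or trait not in cal.traits.columns:
        raise SpectraError(f"calibration set has no trait {trait!r}")
    y_all = cal.traits[trait].to_numpy(dtype=float)
    if np.any(np.isnan(y_all)):
        raise SpectraError(f"missing values in trait {trait!r}")
    if np.std(y_all) <= 1e-12 * (1 + abs(np.mean(y_all))):
        raise SpectraError(f"trait {trait!r} has (near-)zero variance")
    pre = apply_pipeline(cal, preset)
    keep, report = iterative_outlier_removal(
        pre.X, policy or OutlierPolicy(), sample_ids=list(pre.sample_ids)
    )
    screened = pre.subset([pre.sample_ids[i] for i in keep])
    y = y_all[keep]
    n = screened.n_samples
    A_max = min(A_max, n - 2, screened.n_wavelengths)
    cv = loo_cv(screened.X, y, A_max)
    A_star = select_components(cv, tol=tol)
    model = fit_pls(screened.X, y, A_star)
    result = TraitModelResult(
        trait=trait,
        pretreatment=preset,
        A=A_star,
        n=n,
        one_minus_vr=float(cv.one_minus_vr[A_star - 1, 0]),
        rmsecv=float(cv.rmsecv[A_star - 1, 0]),
        secv=float(cv.secv[A_star - 1, 0]),
        outliers=report,
    )
    return result, model, screened


def external_validate(
    model: PLSModel,
    cal_provenance: list[str],
    val: SpectraSet,
    trait: str,
    a: int | None = None,
    r2_kind: str = "corr",
) -> dict[str, float]:
    """External-validation statistics of a fitted trait model.

    ``val`` must have been pre-treated with the same pipeline as the
    calibration set (checked via provenance).  RPDv and RERv use the
    validation set's own SD (n-1) and range.
    """
    if list(val.provenance) != list(cal_provenance):
        raise SpectraError(
            "validation set pre-treatment differs from calibration: "
            f"{val.provenance} vs {cal_provenance}"
        )
    if val.traits is None or trait not in val.traits.columns:
        raise SpectraError(f"validation set has no trait {trait!r}")
    y = val.traits[trait].to_numpy(dtype=float)
    y_hat = pls_predict(model, val.X, a)[:, 0]
    rmsev = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    sd = float(np.std(y, ddof=1))
    rpdv, rerv = rpd_rer(sd, float(np.min(y)), float(np.max(y)), rmsev)
    return {
        "R2v": r_squared(y, y_hat, kind=r2_kind),
        "RMSEV": rmsev,
        "RPDv": rpdv,
        "RERv": rerv,
        "SD": sd,
        "Y_min": float(np.min(y)),
        "Y_max": float(np.max(y)),
        "n": int(y.size),
    }


def run_trait_pipeline(
    cal: SpectraSet,
    val: SpectraSet,
    trait: str,
    preset: str = "SNV-DE SG 1,4,4,1",
    A_max: int = 10,
    policy: OutlierPolicy | None = None,
    tol: float = 0.02,
    r2_kind: str = "corr",
) -> TraitModelResult:
    """Calibrate on ``cal``, validate on ``val``; one table row out."""
    result, model, screened = fit_trait_model(cal, trait, preset, A_max, policy, tol)
    val_pre = apply_pipeline(val, preset)
    stats = external_validate(
        model, screened.provenance, val_pre, trait, result.A, r2_kind
    )
    result.r2v = stats["R2v"]
    result.rmsev = stats["RMSEV"]
    result.rpdv = stats["RPDv"]
    result.rerv = stats["RERv"]
    return result
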