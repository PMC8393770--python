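"""Spectral pre-treatments and their ordered composition.

Implements the four pre-treatments evaluated in the study — the
absorbance transform log10(1/R), the Standard Normal Variate (SNV),
second-order polynomial detrending (DT), and Savitzky-Golay derivatives
parameterised as (derivative order d, left points l, right points r,
polynomial order q) — plus named presets for the combinations that won
each model comparison ("SNV-DE", "SNV-DE SG 1,4,4,1", "SNV-DE SG
2,5,5,2", "SG 1,4,4,1").

Conventions:

* SNV scales by the n-1 (sample) standard deviation.
* "SNV-DE" applies SNV first, detrending second.
* Savitzky-Golay output is trimmed to interior points so every value
  uses the full symmetric kernel; derivatives are per nm (scaled by the
  grid spacing), making them invariant to the grid step.
* Named presets operate on absorbance: applying one to a reflectance
  set converts it with log10(1/R) first ("none" leaves reflectance
  untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from ibernir.spectra_io import SpectraSet, SpectraError


class DegenerateSpectrumError(ValueError):
    """A spectrum is (near-)constant and cannot be SNV-scaled."""


@dataclass(frozen=True)
class PretreatmentStep:
    """One pre-treatment: kind in {absorbance, snv, detrend, savgol}.

    ``params`` holds ``degree`` for detrend (default 2) and
    ``(d, l, r, q)`` for savgol, e.g. the study's (1, 4, 4, 1) and
    (2, 5, 5, 2) settings.
    """

    kind: str
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("absorbance", "snv", "detrend", "savgol"):
            raise ValueError(f"unknown pre-treatment kind {self.kind!r}")
        if self.kind == "savgol":
            if len(self.params) != 4:
                raise ValueError("savgol needs params (d, l, r, q)")
            d, l, r, q = self.params
            if l != r:
                raise ValueError("savgol kernel must be symmetric (l == r)")
            if q < d:
                raise ValueError("polynomial order q must be >= derivative d")
            if l + r + 1 <= q:
                raise ValueError("window must exceed polynomial order")
        if self.kind == "detrend" and self.params and self.params[0] < 0:
            raise ValueError("detrend degree must be >= 0")

    def describe(self) -> str:
        if self.kind == "savgol":
            return "savgol({},{},{},{})".format(*self.params)
        if self.kind == "detrend":
            return f"detrend({self.params[0] if self.params else 2})"
        return self.kind


def to_absorbance(sset: SpectraSet) -> SpectraSet:
    """Convert reflectance R to absorbance log10(1/R)."""
    if sset.mode != "reflectance":
        raise SpectraError(f"to_absorbance expects reflectance, got {sset.mode}")
    bad = np.argwhere(sset.X <= 0)
    if bad.size:
        i, j = bad[0]
        raise SpectraError(
            f"non-positive reflectance at sample {sset.sample_ids[i]}, "
            f"{sset.wavelengths[j]:g} nm"
        )
    out = sset.replace(X=-np.log10(sset.X), mode="absorbance")
    out.provenance.append("absorbance")
    return out


def snv(sset: SpectraSet, eps: float = 1e-12) -> SpectraSet:
    """Standard Normal Variate: centre each spectrum and scale by its own
    (n-1) standard deviation, correcting per-sample multiplicative and
    additive scatter."""
    mu = sset.X.mean(axis=1, keepdims=True)
    sd = sset.X.std(axis=1, ddof=1, keepdims=True)
    low = np.nonzero(sd.ravel() <= eps)[0]
    if low.size:
        raise DegenerateSpectrumError(
            f"near-constant spectrum for sample {sset.sample_ids[low[0]]}"
        )
    out = sset.replace(X=(sset.X - mu) / sd)
    out.provenance.append("snv")
    return out


def detrend(sset: SpectraSet, degree: int = 2) -> SpectraSet:
    """Subtract each spectrum's own least-squares polynomial in wavelength.

    The study used a second-order polynomial; degree 0 reduces to
    per-spectrum mean centering.
    """
    p = sset.n_wavelengths
    if degree >= p:
        raise SpectraError(f"detrend degree {degree} >= grid length {p}")
    # Legendre-style scaled Vandermonde keeps the solve well conditioned
    # for raw-nm wavelengths; residuals equal the raw-basis fit.
    wl = sset.wavelengths
    t = 2 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1
    V = np.vander(t, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, sset.X.T, rcond=None)
    out = sset.replace(X=sset.X - (V @ coef).T)
    out.provenance.append(f"detrend({degree})")
    return out


def savgol_derivative(sset: SpectraSet, step: PretreatmentStep) -> SpectraSet:
    """Savitzky-Golay derivative with a symmetric (l, r) kernel.

    Each interior point gets the d-th derivative (per nm) of the local
    polynomial of order q fitted over its w = l + r + 1 point window;
    the grid is trimmed to interior points so no asymmetric edge fits
    are produced.  Output mode is "derivative".
    """
    if step.kind != "savgol":
        raise SpectraError("savgol_derivative expects a savgol step")
    d, l, r, q = step.params
    w = l + r + 1
    wl = sset.wavelengths
    spacing = np.diff(wl)
    h = spacing.mean()
    if np.max(np.abs(spacing - h)) > 1e-6 * h:
        raise SpectraError("savgol requires a uniformly spaced grid")
    if sset.n_wavelengths < w:
        raise SpectraError(f"grid length {sset.n_wavelengths} < window {w}")
    Y = savgol_filter(sset.X, window_length=w, polyorder=q, deriv=d, delta=h, axis=1)
    out = sset.replace(
        wavelengths=wl[l: len(wl) - r],
        X=Y[:, l: Y.shape[1] - r],
        mode="derivative" if d > 0 else sset.mode,
    )
    out.provenance.append(step.describe())
    return out


def apply_step(sset: SpectraSet, step: PretreatmentStep) -> SpectraSet:
    if step.kind == "absorbance":
        return to_absorbance(sset)
    if step.kind == "snv":
        return snv(sset)
    if step.kind == "detrend":
        return detrend(sset, step.params[0] if step.params else 2)
    return savgol_derivative(sset, step)


@dataclass
class PretreatmentPipeline:
    """Ordered pre-treatment steps with a name for provenance."""

    steps: list[PretreatmentStep] = field(default_factory=list)
    name: str = "custom"

    def __post_init__(self) -> None:
        kinds = [s.kind for s in self.steps]
        if kinds.count("absorbance") > 1:
            raise ValueError("at most one absorbance step")
        if "absorbance" in kinds and kinds[0] != "absorbance":
            raise ValueError("absorbance must come first")
        if "savgol" in kinds and kinds[-1] != "savgol":
            raise ValueError("savgol must come last")


#: Presets named as in the study's model tables.  Each maps to the step
#: sequence applied to absorbance spectra; "none" is the identity on
#: reflectance and "abs" is the bare log10(1/R) transform.
PRESETS: dict[str, list[PretreatmentStep]] = {
    "none": [],
    "abs": [],
    "SNV-DE": [PretreatmentStep("snv"), PretreatmentStep("detrend", (2,))],
    "SNV-DE SG 1,4,4,1": [
        PretreatmentStep("snv"),
        PretreatmentStep("detrend", (2,)),
        PretreatmentStep("savgol", (1, 4, 4, 1)),
    ],
    "SNV-DE SG 2,5,5,2": [
        PretreatmentStep("snv"),
        PretreatmentStep("detrend", (2,)),
        PretreatmentStep("savgol", (2, 5, 5, 2)),
    ],
    "SG 1,4,4,1": [PretreatmentStep("savgol", (1, 4, 4, 1))],
}


def get_preset(name: str) -> PretreatmentPipeline:
    if name not in PRESETS:
        raise KeyError(
            f"unknown pre-treatment preset {name!r}; choose from {sorted(PRESETS)}"
        )
    return PretreatmentPipeline(steps=list(PRESETS[name]), name=name)


def apply_pipeline(sset: SpectraSet, pipe: PretreatmentPipeline | str) -> SpectraSet:
    """Apply a pipeline (or preset name) in order.

    Named presets other than "none" operate on absorbance: a
    reflectance input is converted with log10(1/R) before the first
    step.  An empty pipeline is the identity.
    """
    if isinstance(pipe, str):
        pipe = get_preset(pipe)
    out = sset
    if pipe.name != "none" and pipe.name != "custom" and out.mode == "reflectance":
        out = to_absorbance(out)
    for step in pipe.steps:
        out = apply_step(out, step)
    return out
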