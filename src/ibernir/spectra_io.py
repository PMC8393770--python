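"""Spectra containers, CSV input/output and the calibration/validation split.

The canonical on-disk format is a wide CSV: one row per sample package,
wavelength (nm) column headers, plus a sibling metadata CSV keyed by
``sample_id`` with columns ``category`` (Black/Red/White), ``storage_time``
(T0/T4/T8/T12) and ``set`` (cal/val/unassigned), and an optional traits CSV
with one column per quality trait.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("Black", "Red", "White")
STORAGE_TIMES = ("T0", "T4", "T8", "T12")
SET_LABELS = ("cal", "val", "unassigned")
MODES = ("reflectance", "absorbance", "derivative")

#: Per-stratum calibration counts of the study's sample distribution
#: (rows: storage time, columns: category).  Totals: 138 calibration,
#: 47 validation, 185 overall.
STUDY_CAL_MANIFEST: Mapping[tuple[str, str], int] = {
    ("Black", "T0"): 13, ("Red", "T0"): 15, ("White", "T0"): 15,
    ("Black", "T4"): 13, ("Red", "T4"): 12, ("White", "T4"): 15,
    ("Black", "T8"): 14, ("Red", "T8"): 15, ("White", "T8"): 15,
    ("Black", "T12"): 3, ("Red", "T12"): 5, ("White", "T12"): 3,
}

#: Per-stratum total counts (calibration + validation) of the study design.
STUDY_STRATUM_SIZES: Mapping[tuple[str, str], int] = {
    ("Black", "T0"): 18, ("Red", "T0"): 20, ("White", "T0"): 20,
    ("Black", "T4"): 18, ("Red", "T4"): 17, ("White", "T4"): 19,
    ("Black", "T8"): 18, ("Red", "T8"): 19, ("White", "T8"): 19,
    ("Black", "T12"): 5, ("Red", "T12"): 7, ("White", "T12"): 5,
}


class SpectraError(ValueError):
    """Raised on malformed spectra collections or file contents."""


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise SpectraError("wavelength grid must be 1-D with length >= 2")
    if not np.all(np.isfinite(wl)):
        raise SpectraError("wavelength grid contains non-finite values")
    if not np.all(np.diff(wl) > 0):
        raise SpectraError("grid not increasing")
    return wl


@dataclass
class SpectraSet:
    """A sample x wavelength spectra matrix with aligned metadata.

    Parameters
    ----------
    wavelengths : array of float
        Strictly increasing wavelengths in nm.
    X : array, shape (n_samples, n_wavelengths)
        Spectral values; interpretation set by ``mode``.
    mode : {"reflectance", "absorbance", "derivative"}
        Reflectance values must lie in (0, 1].
    sample_ids : sequence of str
        Unique sample identifiers, aligned to rows of ``X``.
    meta : DataFrame
        Indexed by sample id with columns ``category``, ``storage_time``
        and ``set``.
    traits : DataFrame, optional
        Reference quality-trait values keyed by sample id.
    provenance : list of str
        Ordered descriptors of every pre-treatment applied so far.
    """

    wavelengths: np.ndarray
    X: np.ndarray
    mode: str = "reflectance"
    sample_ids: Sequence[str] = ()
    meta: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = _check_grid(self.wavelengths)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise SpectraError("X must be 2-D (samples x wavelengths)")
        if self.X.shape[1] != self.wavelengths.size:
            raise SpectraError(
                f"X has {self.X.shape[1]} columns but grid has "
                f"{self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.X)):
            raise SpectraError("spectra contain missing or non-finite values")
        if self.mode not in MODES:
            raise SpectraError(f"unknown mode {self.mode!r}")
        if self.mode == "reflectance" and (np.any(self.X <= 0) or np.any(self.X > 1)):
            raise SpectraError("reflectance values must lie in (0, 1]")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(self.X.shape[0])]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.X.shape[0]:
            raise SpectraError("sample_ids length does not match X rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraError("duplicate sample ids")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"category": "Black", "storage_time": "T0", "set": "unassigned"},
                index=pd.Index(self.sample_ids, name="sample_id"),
            )
        else:
            self.meta = self.meta.copy()
            self.meta.index = self.meta.index.astype(str)
            self.meta.index.name = "sample_id"
            missing = [s for s in self.sample_ids if s not in self.meta.index]
            if missing:
                raise SpectraError(f"sample ids absent from metadata: {missing}")
            self.meta = self.meta.loc[list(self.sample_ids)]
            for col, allowed in (
                ("category", CATEGORIES),
                ("storage_time", STORAGE_TIMES),
                ("set", SET_LABELS),
            ):
                if col not in self.meta.columns:
                    raise SpectraError(f"metadata missing column {col!r}")
                bad = set(self.meta[col]) - set(allowed)
                if bad:
                    raise SpectraError(f"invalid {col} values: {sorted(bad)}")
        if self.traits is not None:
            self.traits = self.traits.copy()
            self.traits.index = self.traits.index.astype(str)
            self.traits.index.name = "sample_id"
            missing = [s for s in self.sample_ids if s not in self.traits.index]
            if missing:
                raise SpectraError(f"sample ids absent from traits: {missing}")
            self.traits = self.traits.loc[list(self.sample_ids)]

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def replace(self, **changes) -> "SpectraSet":
        """Return a copy with the given fields replaced (re-validated)."""
        kwargs = dict(
            wavelengths=self.wavelengths.copy(),
            X=self.X.copy(),
            mode=self.mode,
            sample_ids=list(self.sample_ids),
            meta=self.meta,
            traits=self.traits,
            provenance=list(self.provenance),
        )
        kwargs.update(changes)
        return SpectraSet(**kwargs)

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        """Row subset (by sample id), preserving order of ``ids``."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in idx]
        if missing:
            raise SpectraError(f"unknown sample ids: {missing}")
        rows = [idx[s] for s in ids]
        return self.replace(
            X=self.X[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
        )

    def split_sets(self) -> tuple["SpectraSet", "SpectraSet"]:
        """Return the (calibration, validation) subsets per ``meta['set']``."""
        cal_ids = [s for s in self.sample_ids if self.meta.loc[s, "set"] == "cal"]
        val_ids = [s for s in self.sample_ids if self.meta.loc[s, "set"] == "val"]
        return self.subset(cal_ids), self.subset(val_ids)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["category"].to_numpy()


# ----------------------------------------------------------------------
# CSV input / output
# ----------------------------------------------------------------------

def write_spectra_csv(sset: SpectraSet, path: str | Path) -> tuple[Path, Path]:
    """Write a SpectraSet to ``<stem>.csv`` plus ``<stem>_meta.csv``.

    The spectra file begins with a ``# mode=<mode>`` directive and, when
    present, provenance directives; traits go to ``<stem>_traits.csv``.
    Values round-trip exactly through :func:`read_spectra_csv`.
    """
    if sset.n_samples == 0:
        raise SpectraError("empty set")
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    path.parent.mkdir(parents=True, exist_ok=True)
    meta_path = path.with_name(path.stem + "_meta.csv")
    header = ",".join(["sample_id"] + [f"{w:.12g}" for w in sset.wavelengths])
    lines = [f"# mode={sset.mode}"]
    for step in sset.provenance:
        lines.append(f"# provenance={step}")
    lines.append(header)
    for sid, row in zip(sset.sample_ids, sset.X):
        lines.append(sid + "," + ",".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    sset.meta.to_csv(meta_path)
    if sset.traits is not None:
        sset.traits.to_csv(path.with_name(path.stem + "_traits.csv"), float_format="%.17g")
    return path, meta_path


def read_spectra_csv(
    path: str | Path,
    meta_path: str | Path,
    traits_path: str | Path | None = None,
    mode: str | None = None,
) -> SpectraSet:
    """Read the wide spectra CSV / metadata CSV pair written by
    :func:`write_spectra_csv` (or prepared externally in that layout).

    ``mode`` overrides the file's ``# mode=`` directive; the default is
    reflectance when neither is given.
    """
    path = Path(path)
    file_mode = None
    provenance: list[str] = []
    n_directives = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_directives += 1
            body = line[1:].strip()
            if body.startswith("mode="):
                file_mode = body[5:]
            elif body.startswith("provenance="):
                provenance.append(body[11:])
    df = pd.read_csv(
        path, skiprows=n_directives, index_col=0, float_precision="round_trip"
    )
    try:
        wavelengths = np.asarray([float(c) for c in df.columns])
    except ValueError as exc:
        raise SpectraError(f"non-numeric wavelength header: {exc}") from exc
    if df.isna().any().any() or not all(
        np.issubdtype(dt, np.number) for dt in df.dtypes
    ):
        raise SpectraError("non-numeric or missing cells in spectra table")
    meta = pd.read_csv(meta_path, index_col=0)
    traits = None
    if traits_path is not None:
        traits = pd.read_csv(traits_path, index_col=0, float_precision="round_trip")
    return SpectraSet(
        wavelengths=wavelengths,
        X=df.to_numpy(dtype=float),
        mode=mode or file_mode or "reflectance",
        sample_ids=[str(s) for s in df.index],
        meta=meta,
        traits=traits,
        provenance=provenance,
    )


def select_wavelength_range(sset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep columns with ``lo <= wavelength <= hi`` (closed interval).

    The study retains 1000-1800 nm, discarding the low signal-to-noise
    region above 1800 nm.
    """
    if lo >= hi:
        raise SpectraError("lo must be < hi")
    keep = (sset.wavelengths >= lo) & (sset.wavelengths <= hi)
    if not np.any(keep):
        raise SpectraError(f"no wavelengths in [{lo}, {hi}]")
    out = sset.replace(wavelengths=sset.wavelengths[keep], X=sset.X[:, keep])
    out.provenance.append(f"range[{lo:g},{hi:g}]")
    return out


# ----------------------------------------------------------------------
# Calibration / validation split
# ----------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Stratified calibration/validation split specification.

    Strata are (category x storage_time) cells.  Per-stratum calibration
    counts are either apportioned from ``fraction_cal`` by the largest-
    remainder rule or taken verbatim from ``manifest`` (e.g. the study's
    published per-stratum calibration counts).
    """

    fraction_cal: float = 0.75
    seed: int = 0
    manifest: Mapping[tuple[str, str], int] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fraction_cal <= 1:
            raise SpectraError("fraction_cal must be in (0, 1]")


def _largest_remainder(sizes: Sequence[int], fraction: float) -> list[int]:
    quotas = [fraction * s for s in sizes]
    base = [int(np.floor(q)) for q in quotas]
    target = int(round(fraction * sum(sizes)))
    remainders = [q - b for q, b in zip(quotas, base)]
    order = np.argsort(remainders)[::-1]
    extra = max(0, min(target - sum(base), len(sizes)))
    counts = list(base)
    for i in order[:extra]:
        if counts[i] < sizes[i]:
            counts[i] += 1
    return counts


def stratified_split(
    sset: SpectraSet, plan: SplitPlan, allow_reassign: bool = False
) -> SpectraSet:
    """Assign every sample to the calibration or validation set.

    Within each (category, storage_time) stratum the calibration count is
    the manifest value when given, otherwise the largest-remainder
    apportionment of ``fraction_cal``; membership within a stratum is
    uniformly random under ``plan.seed``.
    """
    meta = sset.meta
    if not allow_reassign and not (meta["set"] == "unassigned").all():
        raise SpectraError("samples already assigned; pass allow_reassign=True")
    rng = np.random.default_rng(plan.seed)
    strata: dict[tuple[str, str], list[str]] = {}
    for sid in sset.sample_ids:
        key = (meta.loc[sid, "category"], meta.loc[sid, "storage_time"])
        strata.setdefault(key, []).append(sid)
    keys = sorted(strata)
    sizes = [len(strata[k]) for k in keys]
    if plan.manifest is not None:
        counts = []
        for k, size in zip(keys, sizes):
            c = int(plan.manifest.get(k, round(plan.fraction_cal * size)))
            if c > size:
                raise SpectraError(
                    f"manifest requests {c} calibration samples from stratum "
                    f"{k} of size {size}"
                )
            counts.append(c)
    else:
        counts = _largest_remainder(sizes, plan.fraction_cal)
    new_meta = meta.copy()
    for k, n_cal in zip(keys, counts):
        ids = strata[k]
        chosen = rng.choice(len(ids), size=n_cal, replace=False)
        cal_ids = {ids[i] for i in chosen}
        for sid in ids:
            new_meta.loc[sid, "set"] = "cal" if sid in cal_ids else "val"
    return sset.replace(meta=new_meta)
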