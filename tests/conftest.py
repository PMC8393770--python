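import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ibernir.spectra_io import (
    STUDY_CAL_MANIFEST,
    SpectraSet,
    SplitPlan,
    select_wavelength_range,
    stratified_split,
)
from ibernir.synthetic_data import calibration_preset, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_small_set(n=6, p=9, seed=0, mode="absorbance", with_traits=False):
    """A tiny valid SpectraSet for interface tests."""
    rng = np.random.default_rng(seed)
    wl = 1000.0 + 10.0 * np.arange(p)
    X = 0.4 + 0.05 * rng.standard_normal((n, p))
    ids = [f"P{i:02d}" for i in range(n)]
    cats = ["Black", "Red", "White"] * (n // 3 + 1)
    times = ["T0", "T4", "T8", "T12"] * (n // 4 + 1)
    meta = pd.DataFrame(
        {"category": cats[:n], "storage_time": times[:n], "set": "unassigned"},
        index=pd.Index(ids, name="sample_id"),
    )
    traits = None
    if with_traits:
        traits = pd.DataFrame(
            {"DM": 73 + rng.standard_normal(n), "C18:3 n-3": 0.6 + 0.1 * rng.standard_normal(n)},
            index=meta.index,
        )
    return SpectraSet(
        wavelengths=wl, X=X, mode=mode, sample_ids=ids, meta=meta, traits=traits
    )


@pytest.fixture
def small_set():
    return make_small_set()


@pytest.fixture(scope="session")
def paper_like_study():
    """One synthetic study under the default conditions, range-selected
    to 1000-1800 nm and split with the published per-stratum manifest."""
    sset, truth = generate(calibration_preset("paper_like", seed=1))
    sel = select_wavelength_range(sset, 1000, 1800)
    split = stratified_split(sel, SplitPlan(seed=1, manifest=STUDY_CAL_MANIFEST))
    cal, val = split.split_sets()
    return {"full": split, "cal": cal, "val": val, "truth": truth}


@pytest.fixture(scope="session")
def separable_study():
    sset, _ = generate(calibration_preset("separable", seed=1))
    sel = select_wavelength_range(sset, 1000, 1800)
    split = stratified_split(sel, SplitPlan(seed=1, manifest=STUDY_CAL_MANIFEST))
    cal, val = split.split_sets()
    return {"full": split, "cal": cal, "val": val}
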