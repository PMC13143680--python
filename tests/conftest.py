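import numpy as np
import pandas as pd
import pytest

from fluxpro import fluxomics as fx
from fluxpro import phantom as ph
from fluxpro import synthdata as sd


@pytest.fixture(scope="session")
def small_cohort():
    cfg = sd.default_cohort_config(seed=101, n_per_group=(30, 40, 40))
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """2000 per group: used for location/correlation convergence checks."""
    cfg = sd.default_cohort_config(seed=7, n_per_group=(2000, 2000, 2000))
    return sd.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def default_panel(small_cohort):
    return sd.generate_metabolite_panel(small_cohort, sd.default_flux_effects(seed=5))


@pytest.fixture(scope="session")
def rendered_series():
    """One rendered phantom with bubbles (reused across extraction tests)."""
    rng = np.random.default_rng(3)
    spec = ph.ImageSpec(
        foam_half_life_s=45.8,
        bubble_diameters_mm=ph.sample_bubble_diameters(40, 0.6, rng),
        seed=11,
    )
    return ph.render_urine_series(spec)


def make_panel(serum, urine, lod=None, serum_creat=None, urine_creat=None,
               serum_cens=None, urine_cens=None):
    """Hand-build a small PairedPanel from dicts of columns."""
    serum = pd.DataFrame(serum, dtype=float)
    urine = pd.DataFrame(urine, dtype=float)
    n = len(serum)
    idx = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
    serum.index = urine.index = idx
    if serum_cens is None:
        serum_cens = pd.DataFrame(False, index=idx, columns=serum.columns)
    else:
        serum_cens = pd.DataFrame(serum_cens, index=idx, columns=serum.columns)
    if urine_cens is None:
        urine_cens = pd.DataFrame(False, index=idx, columns=urine.columns)
    else:
        urine_cens = pd.DataFrame(urine_cens, index=idx, columns=urine.columns)
    if lod is None:
        lod = pd.DataFrame({"serum": 1e-6, "urine": 1e-6}, index=serum.columns)
    else:
        lod = pd.DataFrame(lod).T.rename(columns={0: "serum", 1: "urine"})
        lod.columns = ["serum", "urine"]
    return fx.PairedPanel(
        serum=serum,
        urine=urine,
        serum_censored=serum_cens,
        urine_censored=urine_cens,
        serum_creatinine=pd.Series(serum_creat if serum_creat is not None else 80.0, index=idx, dtype=float),
        urine_creatinine=pd.Series(urine_creat if urine_creat is not None else 8000.0, index=idx, dtype=float),
        lod=lod,
    )
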