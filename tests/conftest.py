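import numpy as np
import pytest

from pkpgx import nca, synth


def make_profile(times, concs, bloq=None, **kwargs):
    """Build a ConcentrationProfile from plain lists; BLOQ inferred from None."""
    times = np.asarray(times, float)
    vals = np.array([np.nan if c is None else float(c) for c in concs])
    if bloq is None:
        bloq = np.isnan(vals)
    defaults = dict(
        subject_id="S001", drug="valsartan", period=1, formulation="R",
        dose_mg=160.0, weight_kg=70.0, lloq=20.02,
    )
    defaults.update(kwargs)
    return nca.ConcentrationProfile(
        times=times, concentrations=vals, bloq=np.asarray(bloq, bool), **defaults
    )


@pytest.fixture(scope="session")
def valsartan_params():
    return synth.PKTrueParameters("valsartan", **synth.DRUG_PARAMS["valsartan"])


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 24-subject cohort with default effects."""
    cfg = synth.CohortConfig(n_subjects=24, master_seed=11)
    return synth.generate_cohort(cfg)
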