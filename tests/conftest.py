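import warnings

import pytest

from renalpk.compounds import CompoundModel, EnzymePathway, load_compound
from renalpk.population import make_standard_populations, sample_population


@pytest.fixture(autouse=True)
def _quiet_halflife_warnings():
    # many fixtures deliberately simulate slow scenarios on short grids;
    # the coverage warning is exercised explicitly in test_engine
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="t_end=.*half-lives")
        yield


@pytest.fixture(scope="session")
def nifedipine():
    return load_compound("nifedipine")


@pytest.fixture(scope="session")
def single_pathway_low_extraction():
    """Hand-built single-pathway compound in the linear, low-extraction regime.

    At mean physiology: CLint_u ≈ 34 L/h, fu_b·CLint ≈ 1.4 L/h ≪ Q_h ≈ 90 L/h
    (extraction ratio ≈ 1.5 %), so oral AUC follows fa·fg·D/(fu·CLint_u).
    """
    return CompoundModel(
        name="probe",
        mw=400.0,
        fu=0.04,
        bp_ratio=1.0,
        ka=1.5,
        f_abs=0.9,
        f_gut=0.9,
        vss_per_kg=1.0,
        pathways=(EnzymePathway("CYP3A4", vmax=0.5, km=20.0),),
        renal_filtration_fraction=0.0,
    )


@pytest.fixture(scope="session")
def healthy_subject():
    spec = make_standard_populations()["healthy"]
    return sample_population(spec, 1, 1, seed=42)[0][0]
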