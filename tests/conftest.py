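import warnings

import pytest

from memkin import (KineticParams, LabellingSchedule, SamplerConfig,
                    StudyDesign, default_truth, fit_model,
                    generate_labelling_dataset, with_equilibrium_influx)
from memkin.priors import LogNormal

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def young_truth():
    return default_truth("young")


@pytest.fixture()
def schedule():
    return LabellingSchedule()


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


def recovery_truth() -> KineticParams:
    """Branched ground truth used for recovery checks: fast cells dividing
    at 0.2/d and lost at 0.25/d, slow at 0.007/0.012, influx split equally,
    labelling efficiency 0.5, Ki67 lifetime 3.1 d, pool of 5e4 cells."""
    p = KineticParams(alpha_A=0.007, delta_A=0.012, alpha_B=0.2,
                      delta_B=0.25, psi=0.5, beta=1.0 / 3.1, epsilon=0.5,
                      N0=5e4)
    return with_equilibrium_influx("branched", p)


QUICK = SamplerConfig(n_walkers=32, n_steps=600, burn=300, n_store=300)


@pytest.fixture(scope="session")
def quick_fit():
    """One small branched fit with an informative influx prior, shared by
    tests that only need a plausible posterior object."""
    p = recovery_truth()
    ds = generate_labelling_dataset("branched", {"TCM": {"donor": p}},
                                    StudyDesign(), seed=11)
    tc = ds.select(lineage="donor")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model("branched", tc,
                         priors={"Phi": LogNormal(median=p.Phi, sdlog=0.15)},
                         sampler_config=QUICK, seed=7)
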