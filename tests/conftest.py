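import numpy as np
import pytest

from pedpk.model import Covariates, DoseEvent, IndividualParameters, PopulationParameters


def make_ind(cl=3.0, v=30.0, tvka=0.5, eta_cl=0.0, eta_v=0.0) -> IndividualParameters:
    """Individual parameters assembled directly (flip-flop: ka = tvka + ke)."""
    ke = cl / v
    return IndividualParameters(
        cl=cl, v=v, ka=tvka + ke, ke=ke, t_half=np.log(2) / ke,
        eta_cl=eta_cl, eta_v=eta_v,
    )


@pytest.fixture(scope="session")
def default_pop():
    from pedpk.reference import default_parameters

    return default_parameters()


@pytest.fixture
def plain_pop():
    """Covariate-free population for oracle fixtures: CL 3 L/h, V 30 L."""
    return PopulationParameters(
        tvcl=3.0, cl_age=0.0, cl_sex=0.0, tvv=30.0, v_age=0.0, tvka=0.5,
        omega2_cl=0.09, omega2_v=0.09, sigma2_prop=0.04,
    )


@pytest.fixture
def child():
    return Covariates(age=5.0, sex="male", weight=18.0, height=105.0)


def bid_history(dose=5.0, tau=12.0, n=13):
    return [DoseEvent(i * tau, dose) for i in range(n)]
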