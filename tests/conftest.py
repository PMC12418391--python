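import numpy as np
import pytest

from mirpulse import FAST_SOLVER, ParamsM1, ParamsM2, SolverSettings
from mirpulse.sampling import ParameterRanges


@pytest.fixture(scope="session")
def median_params_m1() -> ParamsM1:
    """Geometric medians of the default sampling ranges (the 'typical' system)."""
    return ParameterRanges.m1().median_params()


@pytest.fixture(scope="session")
def median_params_m2() -> ParamsM2:
    return ParameterRanges.m2_full().median_params()


@pytest.fixture(scope="session")
def fast_solver() -> SolverSettings:
    return FAST_SOLVER


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_params_m1(rng: np.random.Generator, moderate: bool = False) -> ParamsM1:
    """Log-uniform draw of M1 parameters over the default ranges.

    ``moderate`` restricts every rate to [0.1, 10] so that explicit
    fixed-step integration stays stable (used by brute-force oracles).
    """
    if moderate:
        lo, hi = 0.1, 10.0
        draw = lambda: float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        return ParamsM1(
            sigma=draw(), kappa_on=draw(), kappa_off=draw(),
            alpha=draw(), beta=draw(), gamma=draw(),
        )
    ranges = ParameterRanges.m1().ranges
    vals = {
        k: float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        for k, (lo, hi) in ranges.items()
    }
    return ParamsM1(**vals)
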