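import numpy as np
import pytest

from lipiddose.dose_response import STUDY_DOSES
from lipiddose.mz_targets import load_standards
from lipiddose.synthetic_data import fixture_table1


@pytest.fixture(scope="session")
def table1():
    """Packaged per-lipid group-summary fixture (472 rows)."""
    return fixture_table1()


@pytest.fixture(scope="session")
def standards():
    """Packaged internal-standard configuration."""
    return load_standards()


@pytest.fixture(scope="session")
def doses():
    return np.asarray(STUDY_DOSES)


def t_tail_two_sided(t_value: float, df: int, n_grid: int = 200_001) -> float:
    """Independent two-sided Student-t tail by trapezoid quadrature.

    Maps x in [|t|, inf) to s in [0, 1) via x = |t| + s/(1-s) and integrates the
    density written directly from gamma functions.
    """
    import math

    t_abs = abs(float(t_value))
    norm = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    s = np.linspace(0.0, 1.0, n_grid)
    x = t_abs + s[:-1] / (1.0 - s[:-1])
    jac = 1.0 / (1.0 - s[:-1]) ** 2
    dens = norm * (1.0 + x**2 / df) ** (-(df + 1) / 2)
    # limiting value of the transformed integrand at s = 1 (finite for df = 1)
    endpoint = norm * df ** ((df + 1) / 2) if df == 1 else 0.0
    integrand = np.append(dens * jac, endpoint)
    return float(2.0 * np.trapezoid(integrand, s))
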