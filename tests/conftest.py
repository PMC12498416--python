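import warnings

import numpy as np
import pytest

from rdkit import RDLogger

import seedkin as sk

RDLogger.DisableLog("rdApp.*")
warnings.filterwarnings("ignore", message="aggregation incomplete")


@pytest.fixture(scope="session")
def frag_params() -> sk.RateParameters:
    """Fragmentation-dominated seeded condition at 5 uM."""
    return sk.default_rate_parameters(5.0, model="fragmentation")


@pytest.fixture(scope="session")
def sat_params() -> sk.RateParameters:
    """Saturating secondary-nucleation seeded condition at 5 uM."""
    return sk.default_rate_parameters(5.0, model="saturating")


@pytest.fixture(scope="session")
def time_grid_150h() -> np.ndarray:
    return np.arange(0, 150 * 3600 + 1, 900.0)


@pytest.fixture(scope="session")
def small_library():
    """A 300-molecule synthetic library with its oracle (session-cached)."""
    cfg = sk.GeneratorConfig(rng_seed=11)
    spec = sk.LibrarySpec(size=300, n_actives=4)
    return sk.gen_library(cfg, spec)


def rk4_oracle(params: sk.RateParameters, t_end: float, n_steps: int = 10_000):
    """Brute-force fixed-step RK4 integration of the three-variable system
    (P, M, m) -- independent of the adaptive integrator under test.

    Returns (time, P, M, m) arrays.
    """
    import math

    p = params

    def rhs(y):
        P, M, m = y
        mm = max(m, 0.0)
        sec = 0.0
        if p.k_2 > 0 and mm > 0:
            mn = mm ** p.n_2
            if math.isfinite(p.K_M):
                sec = p.k_2 * mn / (1.0 + (mm / p.K_M) ** p.n_2)
            else:
                sec = p.k_2 * mn
        dP = p.k_n * (mm ** p.n_c) + (sec + p.k_minus) * M
        dM = 2.0 * p.k_plus * mm * P
        return np.array([dP, dM, -dM])

    h = t_end / n_steps
    y = np.array([p.P_0, p.M_0, p.m_tot - p.M_0])
    ts = [0.0]
    ys = [y.copy()]
    for i in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        ts.append((i + 1) * h)
        ys.append(y.copy())
    ys = np.array(ys)
    return np.array(ts), ys[:, 0], ys[:, 1], ys[:, 2]


def crossing_half_time(time, signal):
    """Linear-interpolated first crossing of (baseline+plateau)/2."""
    base = float(np.median(signal[:5]))
    plat = float(np.median(signal[-5:]))
    mid = 0.5 * (base + plat)
    above = np.nonzero(signal >= mid)[0]
    i = above[0]
    if i == 0:
        return float(time[0])
    t0, t1 = time[i - 1], time[i]
    y0, y1 = signal[i - 1], signal[i]
    return float(t0 + (mid - y0) * (t1 - t0) / (y1 - y0))
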