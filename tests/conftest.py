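import numpy as np
import pytest

import shelfkin as sk


@pytest.fixture
def tvc_pad_params():
    """Baranyi parameters of the TVC in pad-augmented MAP at 0 degC."""
    return sk.BaranyiParams(y0=5.41, ymax=8.09, mu=0.224, lag=8.44)


@pytest.fixture
def tvc_pad_rates():
    """TVC growth rates in pad-augmented MAP at 0/2.5/5/10 degC."""
    return [(273.15, 0.224), (275.65, 0.294), (278.15, 0.51), (283.15, 1.07)]


@pytest.fixture
def m_type_global():
    return sk.datasets.tti_global_models()["M"]


@pytest.fixture
def lp_type_global():
    return sk.datasets.tti_global_models()["LP"]


def rk4_baranyi(params, t_grid, mu_of_t=None):
    """Independent fixed-step RK4 integration of the differential Baranyi
    system (natural-log state), used as the oracle for the explicit
    solution and for dynamic-temperature predictions."""
    ln10 = np.log(10.0)
    lag = 0.0 if params.lag is None else params.lag
    mu_ref = params.mu * ln10
    h0 = mu_ref * lag
    q0 = np.inf if h0 <= 0 else 1.0 / np.expm1(h0)
    ymax = params.ymax * ln10

    state = np.array([np.inf if np.isinf(q0) else np.log(q0),
                      params.y0 * ln10])
    out = [params.y0]
    substeps = 40
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        # mu is piecewise-constant and the grid aligns with profile
        # boundaries, so the midpoint value is exact on the interval
        mu = mu_ref if mu_of_t is None else mu_of_t((t0 + t1) / 2) * ln10

        def rhs(t, state):
            lnq, y = state
            alpha = 1.0 if np.isinf(q0) else 1.0 / (1.0 + np.exp(-lnq))
            return np.array([mu, mu * alpha * -np.expm1(min(y - ymax, 0.0))])

        h = (t1 - t0) / substeps
        t = t0
        for _ in range(substeps):
            if np.isinf(state[0]):
                # lag-free: advance only y
                def rhs_y(tt, y):
                    return mu * -np.expm1(min(y - ymax, 0.0))
                y = state[1]
                k1 = rhs_y(t, y)
                k2 = rhs_y(t + h / 2, y + h / 2 * k1)
                k3 = rhs_y(t + h / 2, y + h / 2 * k2)
                k4 = rhs_y(t + h, y + h * k3)
                state[1] = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            else:
                k1 = rhs(t, state)
                k2 = rhs(t + h / 2, state + h / 2 * k1)
                k3 = rhs(t + h / 2, state + h / 2 * k2)
                k4 = rhs(t + h, state + h * k3)
                state = state + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out.append(state[1] / ln10)
    return np.array(out)
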