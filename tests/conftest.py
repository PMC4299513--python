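import numpy as np
import pytest

from growthlaws import GrowthParams, get_preset, standard_control


@pytest.fixture(scope="session")
def fig2():
    """Narrow-plateau illustration preset (K_nu = 5 K_gamma)."""
    return get_preset("fig2")


@pytest.fixture(scope="session")
def fig3():
    """Wide-plateau illustration preset (K_nu = 50 K_gamma)."""
    return get_preset("fig3")


@pytest.fixture(scope="session")
def wide():
    """Plateau-limit preset (thresholds separated by 1e5)."""
    return get_preset("wide")


@pytest.fixture(scope="session")
def chi_fig3(fig3):
    """Generic supply-driven-activation rule for the fig3 preset."""
    return standard_control(fig3)


def bisect_flux_balance(phiR, p: GrowthParams, iters=120):
    """Independent oracle: plain bisection on the flux residual.

    Shares nothing with the production solver beyond the residual itself.
    """
    from growthlaws import flux_residual

    lo, hi = p.K_gamma * 1e-8, p.K_nu * 1e8
    assert flux_residual(lo, phiR, p) > 0 > flux_residual(hi, phiR, p)
    for _ in range(iters):
        mid = np.sqrt(lo * hi) if hi / lo > 10 else 0.5 * (lo + hi)
        if flux_residual(mid, phiR, p) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
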