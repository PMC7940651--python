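import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epiherit import load_neuropsych_five

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def five_disorders():
    return load_neuropsych_five()


def grid_search_tetrachoric(n11, n10, n01, n00, step=1e-4):
    """Brute-force tetrachoric oracle: exhaustive likelihood grid over r.

    Independent of the package's Owen's-T bivariate CDF: cell
    probabilities on the grid come from Plackett's identity, integrating
    the bivariate normal density over the correlation from 0 (where the
    CDF factorizes) by cumulative trapezoid on the same 1e-4 grid.
    """
    from scipy.integrate import cumulative_trapezoid
    from scipy.stats import norm

    counts = np.array([n11, n10, n01, n00], float)
    if np.any(counts == 0):
        counts = counts + 0.5
    n = counts.sum()
    p1 = (counts[0] + counts[1]) / n
    p2 = (counts[0] + counts[2]) / n
    h, k = norm.ppf(1 - p1), norm.ppf(1 - p2)

    m = int(round(0.9999 / step))
    grid = np.arange(-m, m + 1) * step          # contains 0.0 exactly
    dens = np.exp(-(h * h - 2 * grid * h * k + k * k) / (2 * (1 - grid ** 2)))
    dens /= 2 * np.pi * np.sqrt(1 - grid ** 2)
    F = cumulative_trapezoid(dens, grid, initial=0.0)
    F = F - F[m] + norm.cdf(h) * norm.cdf(k)    # anchor at rho = 0
    P1, P2 = norm.cdf(h), norm.cdf(k)
    probs = np.clip(np.stack([1 - P1 - P2 + F, P2 - F, P1 - F, F]), 1e-300, None)
    nll = -(counts[:, None] * np.log(probs)).sum(axis=0)
    return float(grid[np.argmin(nll)])


def random_concordance_table(rng, n_pairs=2000):
    """Counts from a dichotomized bivariate normal with random r and margins."""
    rho = rng.uniform(-0.8, 0.8)
    k1, k2 = rng.uniform(0.1, 0.5, size=2)
    from scipy.stats import norm
    z1 = rng.standard_normal(n_pairs)
    z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_pairs)
    a = z1 > norm.ppf(1 - k1)
    b = z2 > norm.ppf(1 - k2)
    return (int((a & b).sum()), int((a & ~b).sum()),
            int((~a & b).sum()), int((~a & ~b).sum())), rho
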