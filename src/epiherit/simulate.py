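"""Nuclear-family liability-threshold simulator with environmental transmission.

Each family has two parents and ``n_offspring`` children.  Binary disease
status arises from a standardized Gaussian liability thresholded at the
population prevalence ``K``.  Liabilities are composed of:

parents
    additive genetic value ``G_p ~ N(0, G_A)``, a couple-shared
    environmental deviate ``C ~ N(0, E_P)`` carried by both spouses, and
    unique environment filling the variance budget to 1.

offspring
    mid-parent genetic value plus Mendelian segregation noise
    ``N(0, G_A/2)`` (infinitesimal model); a transmitted environmental
    component ``x*C`` topped up with independent noise ``N(0, x(1-x)E_P)``
    so its variance is ``x*E_P`` while its covariance with each parent's
    environment is also ``x*E_P`` (the covariance-x convention); a
    sibling-shared deviate ``N(0, E_S)``; and unique environment filling
    to 1.

The implied latent (liability-scale) correlations are

    r_spouse           = E_P
    r_parent_offspring = G_A/2 + x*E_P
    r_sibling          = G_A/2 + x^2*E_P + E_S

so the naive parent–offspring heritability estimator
``2*r_parent_offspring = G_A + 2x*E_P`` strictly exceeds ``G_A`` whenever
``x*E_P > 0`` — transmitted environment masquerading as inheritance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimulationParams",
    "FamilyTable",
    "FamilialCorrelations",
    "simulate_families",
    "expected_latent_correlations",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings for the family simulator.

    ``x = 0`` is allowed here (no transmission), unlike in the closed-form
    solver where the hybrid model requires ``0 < x < 1``.
    """

    G_A: float
    E_P: float
    E_S: float
    x: float
    K: float = 0.1
    n_families: int = 10_000
    n_offspring: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("G_A", "E_P", "E_S"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if not 0.0 <= self.x < 1.0:
            raise ValueError(f"x={self.x!r} outside [0, 1)")
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K={self.K!r} outside (0, 1)")
        if self.G_A + self.E_P > 1.0 + 1e-12:
            raise ValueError(
                f"parental variance budget violated: G_A + E_P = "
                f"{self.G_A + self.E_P:.6g} > 1"
            )
        if self.G_A + self.x * self.E_P + self.E_S > 1.0 + 1e-12:
            raise ValueError(
                f"offspring variance budget violated: G_A + x*E_P + E_S = "
                f"{self.G_A + self.x * self.E_P + self.E_S:.6g} > 1"
            )
        if self.n_families < 1 or self.n_offspring < 1:
            raise ValueError("n_families and n_offspring must be >= 1")


@dataclass(frozen=True)
class FamilialCorrelations:
    """Latent-scale spouse / parent–offspring / sibling correlations."""

    r_spouse: float
    r_parent_offspring: float
    r_sibling: float | None = None
    se_spouse: float | None = None
    se_parent_offspring: float | None = None
    se_sibling: float | None = None
    n_spouse: int | None = None
    n_parent_offspring: int | None = None
    n_sibling: int | None = None
    flags: tuple[str, ...] = field(default=())


@dataclass
class FamilyTable:
    """Realized families: latent liabilities, components and affection status.

    Arrays are indexed by family; offspring arrays have shape
    ``(n_families, n_offspring)``.  ``tau`` is the liability threshold
    (upper-``K`` standard-normal quantile).
    """

    params: SimulationParams
    tau: float
    father_latent: np.ndarray
    mother_latent: np.ndarray
    offspring_latent: np.ndarray
    father_genetic: np.ndarray
    mother_genetic: np.ndarray
    offspring_genetic: np.ndarray
    couple_env: np.ndarray           # C, shared by both parents
    offspring_trans_env: np.ndarray  # x*C + top-up, per offspring
    sibling_env: np.ndarray          # one draw per family
    father_unique: np.ndarray
    mother_unique: np.ndarray
    offspring_unique: np.ndarray

    @property
    def n_families(self) -> int:
        return self.father_latent.shape[0]

    @property
    def n_offspring(self) -> int:
        return self.offspring_latent.shape[1]

    @property
    def father_affected(self) -> np.ndarray:
        return self.father_latent > self.tau

    @property
    def mother_affected(self) -> np.ndarray:
        return self.mother_latent > self.tau

    @property
    def offspring_affected(self) -> np.ndarray:
        return self.offspring_latent > self.tau

    def latent_correlations(self) -> FamilialCorrelations:
        """Empirical Pearson correlations of the latent liabilities.

        Parent–offspring pools all (parent, child) pairs; siblings pool all
        unordered offspring pairs.  Standard errors use the number of
        independent families, conservative for pooled within-family pairs.
        """
        n = self.n_families
        k = self.n_offspring
        r_sp = _corr(self.father_latent, self.mother_latent)
        parents = np.concatenate([np.repeat(self.father_latent, k),
                                  np.repeat(self.mother_latent, k)])
        children = np.concatenate([self.offspring_latent.ravel()] * 2)
        r_po = _corr(parents, children)
        r_sib = None
        n_sib = 0
        if k >= 2:
            i, j = np.triu_indices(k, 1)
            r_sib = _corr(self.offspring_latent[:, i].ravel(),
                          self.offspring_latent[:, j].ravel())
            n_sib = n * len(i)
        se = lambda r: (1.0 - r ** 2) / np.sqrt(n) if r is not None else None
        return FamilialCorrelations(
            r_spouse=r_sp, r_parent_offspring=r_po, r_sibling=r_sib,
            se_spouse=se(r_sp), se_parent_offspring=se(r_po), se_sibling=se(r_sib),
            n_spouse=n, n_parent_offspring=2 * n * k, n_sibling=n_sib)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per family member."""
        n, k = self.n_families, self.n_offspring
        rows = []
        fam = np.arange(n)
        for role, latent, genetic, env, unique in (
            ("father", self.father_latent, self.father_genetic,
             self.couple_env, self.father_unique),
            ("mother", self.mother_latent, self.mother_genetic,
             self.couple_env, self.mother_unique),
        ):
            rows.append(pd.DataFrame({
                "family_id": fam, "role": role, "latent": latent,
                "affected": (latent > self.tau).astype(int),
                "genetic": genetic, "parental_env": env,
                "sibling_env": 0.0, "unique_env": unique}))
        for j in range(k):
            latent = self.offspring_latent[:, j]
            rows.append(pd.DataFrame({
                "family_id": fam, "role": f"offspring_{j + 1}", "latent": latent,
                "affected": (latent > self.tau).astype(int),
                "genetic": self.offspring_genetic[:, j],
                "parental_env": self.offspring_trans_env[:, j],
                "sibling_env": self.sibling_env, "unique_env": self.offspring_unique[:, j]}))
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["family_id", "role"], kind="stable").reset_index(drop=True)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def simulate_families(params: SimulationParams) -> FamilyTable:
    """Draw families under the transmission model; identical seeds give identical tables."""
    p = params
    rng = np.random.default_rng(p.seed)
    n, k = p.n_families, p.n_offspring
    sd = np.sqrt

    C = rng.normal(0.0, sd(p.E_P), n)
    G_f = rng.normal(0.0, sd(p.G_A), n)
    G_m = rng.normal(0.0, sd(p.G_A), n)
    u_par = 1.0 - p.G_A - p.E_P
    U_f = rng.normal(0.0, sd(u_par), n)
    U_m = rng.normal(0.0, sd(u_par), n)

    M = rng.normal(0.0, sd(p.G_A / 2.0), (n, k))
    G_o = 0.5 * (G_f + G_m)[:, None] + M
    delta = rng.normal(0.0, sd(p.x * (1.0 - p.x) * p.E_P), (n, k))
    T_o = p.x * C[:, None] + delta
    S = rng.normal(0.0, sd(p.E_S), n)
    u_off = 1.0 - p.G_A - p.x * p.E_P - p.E_S
    U_o = rng.normal(0.0, sd(u_off), (n, k))

    tau = float(norm.ppf(1.0 - p.K))
    return FamilyTable(
        params=p, tau=tau,
        father_latent=G_f + C + U_f, mother_latent=G_m + C + U_m,
        offspring_latent=G_o + T_o + S[:, None] + U_o,
        father_genetic=G_f, mother_genetic=G_m, offspring_genetic=G_o,
        couple_env=C, offspring_trans_env=T_o, sibling_env=S,
        father_unique=U_f, mother_unique=U_m, offspring_unique=U_o)


def expected_latent_correlations(params: SimulationParams) -> FamilialCorrelations:
    """Closed-form latent correlations implied by the generative model."""
    p = params
    return FamilialCorrelations(
        r_spouse=p.E_P,
        r_parent_offspring=0.5 * p.G_A + p.x * p.E_P,
        r_sibling=0.5 * p.G_A + p.x ** 2 * p.E_P + p.E_S)
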