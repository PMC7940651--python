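"""Closed-form arithmetic of the hybrid heritability model.

The model treats a fraction ``x`` of the couple-shared environmental
variance ``E_P`` as transmitted to offspring alongside additive genetic
variance ``G_A``, so that on the liability scale the broad-sense
heritability satisfies

    H^2 = (G_A + x * E_P) / (G_A + E),        0 < x < 1,

with ``E = E_P + E_F + E_S + E_U`` the total environmental variance
(couple-shared, familial, sibling-shared and unique components).  The
total "genetic" variance under this hybrid model is ``G = G_A + x*E_P``;
the residual heritability is ``H^2 - G``.

Given ``(H^2, E, E_P, x)`` the unique algebraic inversion for the
additive genetic variance is

    G_A = (H^2 * E - x * E_P) / (1 - H^2),

which is feasible (non-negative) iff ``H^2 * E >= x * E_P``.  Infeasible
inputs raise :class:`InfeasibleModelError` rather than being clamped: a
negative variance signals inconsistent inputs.

Two modes are supported.  ``solve`` mode requires the total environmental
variance ``E`` and solves for ``G_A``; ``reproduce`` mode assembles the
decomposition from an externally supplied ``G_A`` without needing ``E``
(useful when only published per-disorder decompositions are available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Collection, Iterable, Sequence

__all__ = [
    "DisorderSummary",
    "TransmissionModel",
    "HybridDecomposition",
    "ExplainedRange",
    "InfeasibleModelError",
    "InsufficientDataError",
    "DEFAULT_X_GRID",
    "total_environment",
    "solve_hybrid",
    "reproduce_hybrid",
    "measured_genetics",
    "residual_share",
    "explained_range",
    "round_half_away",
]

#: Transmission fractions evaluated by default; 0.5 is the headline model.
DEFAULT_X_GRID = (0.25, 0.5, 0.6, 0.667)


class InfeasibleModelError(ValueError):
    """Raised when the requested decomposition implies a negative variance."""


class InsufficientDataError(ValueError):
    """Raised when a disorder summary lacks the fields an operation needs."""


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (report convention).

    Python's builtin ``round`` uses banker's rounding; published summary
    tables round half away from zero (e.g. 39.35 -> 39.4).
    """
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def _check_fraction(name: str, value: float | None, *, upper_open: bool = False) -> None:
    if value is None:
        return
    if value < 0 or value > 1 or (upper_open and value >= 1):
        bound = "[0, 1)" if upper_open else "[0, 1]"
        raise ValueError(f"{name}={value!r} outside {bound}")


@dataclass(frozen=True)
class TransmissionModel:
    """Fraction ``x`` of couple-shared environmental variance transmitted."""

    x: float

    def __post_init__(self) -> None:
        if not 0.0 < self.x < 1.0:
            raise ValueError(f"transmission fraction must satisfy 0 < x < 1, got {self.x!r}")

    def __float__(self) -> float:
        return self.x


def _as_x(x: "TransmissionModel | float") -> float:
    xv = float(x)
    if not 0.0 < xv < 1.0:
        raise ValueError(f"transmission fraction must satisfy 0 < x < 1, got {xv!r}")
    return xv


@dataclass(frozen=True)
class DisorderSummary:
    """Liability-scale summary statistics for one disorder.

    All variance components are fractions of the (standardized) liability
    variance.  ``E_total`` may be supplied directly when the individual
    environmental components are unknown; ``G_A_reported`` enables
    ``reproduce`` mode when ``E_total`` is unknown.
    """

    name: str
    H2: float
    E_P: float | None = None
    E_S: float | None = None
    E_F: float | None = None
    E_U: float | None = None
    E_total: float | None = None
    G_SNP: float | None = None
    G_CNV: float | None = None
    G_A_reported: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.H2 < 1.0:
            raise ValueError(f"{self.name}: H2={self.H2!r} outside [0, 1)")
        for fname in ("E_P", "E_S", "E_F", "E_U", "E_total"):
            v = getattr(self, fname)
            if v is not None and v < 0:
                raise ValueError(f"{self.name}: {fname}={v!r} is negative")
        for fname in ("G_SNP", "G_CNV", "G_A_reported"):
            _check_fraction(f"{self.name}: {fname}", getattr(self, fname))
        comps = [self.E_P, self.E_F, self.E_S, self.E_U]
        if self.E_total is not None and all(c is not None for c in comps):
            total = sum(c for c in comps if c is not None)
            if abs(self.E_total - total) > 1e-9:
                raise ValueError(
                    f"{self.name}: E_total={self.E_total!r} inconsistent with "
                    f"component sum {total!r}"
                )


@dataclass(frozen=True)
class HybridDecomposition:
    """One disorder's heritability split into genetic, transmitted and residual parts."""

    G_A: float
    xEP: float
    G: float
    residual: float
    pct_G_of_H2: float
    pct_residual_of_H2: float
    mode: str  # "solved" | "reproduced"
    flags: tuple[str, ...] = field(default=())


def _decomposition(H2: float, G_A: float, xEP: float, mode: str,
                   flags: tuple[str, ...] = ()) -> HybridDecomposition:
    G = G_A + xEP
    residual = H2 - G
    if H2 > 0:
        pct_G = 100.0 * G / H2
        pct_res = 100.0 * residual / H2
    else:
        pct_G = math.nan
        pct_res = math.nan
    if residual < 0 and "negative_residual" not in flags:
        flags = flags + ("negative_residual",)
    return HybridDecomposition(G_A=G_A, xEP=xEP, G=G, residual=residual,
                               pct_G_of_H2=pct_G, pct_residual_of_H2=pct_res,
                               mode=mode, flags=flags)


def total_environment(d: DisorderSummary) -> float:
    """Total environmental variance ``E`` for one disorder.

    Returns ``E_total`` when supplied, otherwise the component sum
    ``E_P + E_F + E_S + E_U`` (``E_F`` defaults to 0 when absent, since
    some source decompositions name only couple, sibling and unique
    components).
    """
    if d.E_total is not None:
        return d.E_total
    if d.E_P is None or d.E_U is None:
        raise InsufficientDataError(
            f"{d.name}: insufficient environmental data "
            "(need E_total, or E_P and E_U with optional E_F, E_S)"
        )
    return d.E_P + (d.E_F or 0.0) + (d.E_S or 0.0) + d.E_U


def solve_hybrid(H2: float, E: float, E_P: float,
                 x: TransmissionModel | float) -> HybridDecomposition:
    """Solve the hybrid model for ``G_A`` given ``(H^2, E, E_P, x)``.

    The returned ``G_A`` back-substitutes into
    ``(G_A + x*E_P) / (G_A + E) = H^2`` exactly (to numerical precision).

    Raises
    ------
    InfeasibleModelError
        When ``H^2 * E < x * E_P``, i.e. the transmitted environment alone
        exceeds the heritability budget and ``G_A`` would be negative.
    ValueError
        When ``H^2 >= 1`` (the solution has a pole at 1) or the
        environmental inputs are inconsistent (``E < E_P``).
    """
    xv = _as_x(x)
    if H2 >= 1.0:
        raise ValueError("heritability must be below 1 for solving")
    if H2 < 0.0:
        raise ValueError(f"H2={H2!r} is negative")
    if E_P < 0.0 or E < E_P:
        raise ValueError(f"need E >= E_P >= 0, got E={E!r}, E_P={E_P!r}")
    xEP = xv * E_P
    if H2 * E < xEP:
        raise InfeasibleModelError(
            "infeasible: transmitted environment exceeds heritability budget "
            f"(H2*E = {H2 * E:.6g} < x*E_P = {xEP:.6g})"
        )
    G_A = (H2 * E - xEP) / (1.0 - H2)
    return _decomposition(H2, G_A, xEP, mode="solved")


def reproduce_hybrid(H2: float, G_A_reported: float, E_P: float,
                     x: TransmissionModel | float) -> HybridDecomposition:
    """Assemble the hybrid decomposition from an externally supplied ``G_A``.

    Used when the total environmental variance is unknown but a published
    additive genetic variance is available.  A total ``G`` exceeding
    ``H^2`` is flagged (``negative_residual``) rather than raised, since
    printed rounding can produce tiny negatives.
    """
    xv = _as_x(x)
    for name, v in (("H2", H2), ("G_A_reported", G_A_reported), ("E_P", E_P)):
        if not 0.0 <= v < 1.0:
            raise ValueError(f"{name}={v!r} outside [0, 1)")
    return _decomposition(H2, G_A_reported, xv * E_P, mode="reproduced")


def measured_genetics(G_SNP: float, G_CNV: float | None = None) -> float:
    """Measured additive genetic variance: SNP-based estimate plus CNV share."""
    if G_SNP is None:
        raise InsufficientDataError("G_SNP is required for measured genetics")
    cnv = 0.0 if G_CNV is None else G_CNV
    if G_SNP < 0 or cnv < 0:
        raise ValueError("genetic variance components must be non-negative")
    return G_SNP + cnv


def residual_share(H2: float, G: float) -> tuple[float, float]:
    """Residual heritability ``H^2 - G`` and its percentage of ``H^2``.

    Raw (unrounded) values are returned; report formatting applies the
    rounding convention separately.
    """
    if H2 <= 0:
        raise ValueError("undefined share: H2 must be positive")
    residual = H2 - G
    return residual, 100.0 * residual / H2


@dataclass(frozen=True)
class ExplainedRange:
    """Extremes of explained percentage and residual variance across disorders."""

    pct_min: float
    pct_max: float
    residual_min: float
    residual_max: float
    included: tuple[str, ...]

    @property
    def pct_min_int(self) -> int:
        return int(round_half_away(self.pct_min))

    @property
    def pct_max_int(self) -> int:
        return int(round_half_away(self.pct_max))


def explained_range(items: Iterable[tuple[str, float, float]],
                    exclude: Collection[str] = ()) -> ExplainedRange:
    """Range of ``100*G/H^2`` and of ``H^2 - G`` over disorders.

    Parameters
    ----------
    items : iterable of (name, H2, G)
        Per-disorder heritability and modeled genetic variance.
    exclude : collection of names
        Disorders dropped before taking extremes (e.g. outliers with no
        shared parental environment).
    """
    kept = [(n, h2, g) for n, h2, g in items if n not in set(exclude)]
    if not kept:
        raise ValueError("no disorders left after exclusions")
    pcts = [100.0 * g / h2 for _, h2, g in kept]
    residuals = [h2 - g for _, h2, g in kept]
    return ExplainedRange(pct_min=min(pcts), pct_max=max(pcts),
                          residual_min=min(residuals), residual_max=max(residuals),
                          included=tuple(n for n, _, _ in kept))
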