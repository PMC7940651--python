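"""Decomposition reports across disorders.

Builds, from a table of per-disorder summary statistics, the side-by-side
comparison of the measured-genetics model (``G = G_SNP + CNVs``) and the
hybrid transmission model (``G = G_A + x*E_P``), the stacked series of
``(G_A, x*E_P)`` ordered by heritability, and the aggregate
explained/residual ranges.

Rounding convention for formatted output: variances to 3 decimals,
percentages to 1 decimal, range endpoints additionally to integer
percent; ties round half away from zero.  Raw values are retained in the
machine-readable tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Sequence

import math

import pandas as pd

from .model import (DisorderSummary, ExplainedRange, InsufficientDataError,
                    TransmissionModel, explained_range, measured_genetics,
                    reproduce_hybrid, residual_share, round_half_away,
                    solve_hybrid, total_environment)

__all__ = [
    "AggregateRanges",
    "build_decomposition_table",
    "format_decomposition_table",
    "build_transmission_series",
    "plot_transmission_series",
    "aggregate_ranges",
    "outlier_names",
]

_TABLE_COLUMNS = [
    "disorder", "H2",
    "G_measured", "pct_measured", "residual_measured", "pct_residual_measured",
    "G_A_hybrid", "xEP", "G_hybrid", "pct_hybrid",
    "residual_hybrid", "pct_residual_hybrid", "note",
]


def _hybrid_for(d: DisorderSummary, x: TransmissionModel | float, mode: str):
    if mode == "reproduced":
        if d.G_A_reported is None or d.E_P is None:
            missing = [f for f, v in (("G_A_reported", d.G_A_reported),
                                      ("E_P", d.E_P)) if v is None]
            raise InsufficientDataError(f"{d.name}: missing {', '.join(missing)}")
        return reproduce_hybrid(d.H2, d.G_A_reported, d.E_P, x)
    if mode == "solved":
        if d.E_P is None:
            raise InsufficientDataError(f"{d.name}: missing E_P")
        return solve_hybrid(d.H2, total_environment(d), d.E_P, x)
    raise ValueError(f"mode must be 'solved' or 'reproduced', got {mode!r}")


def build_decomposition_table(disorders: Sequence[DisorderSummary],
                              x: TransmissionModel | float = 0.5,
                              mode: str = "reproduced",
                              on_error: str = "raise") -> pd.DataFrame:
    """Per-disorder measured and hybrid decompositions (raw values).

    ``on_error="collect"`` records per-disorder failures in an ``error``
    column and keeps going, so one infeasible or incomplete disorder does
    not sink the whole report.
    """
    rows = []
    for d in disorders:
        row = {c: math.nan for c in _TABLE_COLUMNS}
        row.update(disorder=d.name, H2=d.H2, note=d.note or "")
        try:
            if d.G_SNP is not None:
                g_meas = measured_genetics(d.G_SNP, d.G_CNV)
                res_m, pct_res_m = residual_share(d.H2, g_meas)
                row.update(G_measured=g_meas, pct_measured=100.0 * g_meas / d.H2,
                           residual_measured=res_m, pct_residual_measured=pct_res_m)
            dec = _hybrid_for(d, x, mode)
            row.update(G_A_hybrid=dec.G_A, xEP=dec.xEP, G_hybrid=dec.G,
                       pct_hybrid=dec.pct_G_of_H2, residual_hybrid=dec.residual,
                       pct_residual_hybrid=dec.pct_residual_of_H2)
        except (ValueError, InsufficientDataError) as exc:
            if on_error != "collect":
                raise
            row["error"] = str(exc)
        rows.append(row)
    cols = _TABLE_COLUMNS + (["error"] if on_error == "collect" else [])
    df = pd.DataFrame(rows)
    if "error" in df.columns and "error" not in cols:
        cols = cols + ["error"]
    return df.reindex(columns=cols)


def format_decomposition_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the report rounding convention; output is deterministic."""
    out = table.copy()
    for col in out.columns:
        if col.startswith("pct_"):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{round_half_away(v, 1):.1f}")
        elif col not in ("disorder", "note", "error"):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{round_half_away(v, 3):.3f}")
    return out


def build_transmission_series(disorders: Sequence[DisorderSummary],
                              x: TransmissionModel | float = 0.5,
                              mode: str = "reproduced") -> pd.DataFrame:
    """Stacked ``(G_A, x*E_P)`` pairs with ``H^2``, sorted by descending
    heritability (ties broken by disorder name for determinism)."""
    rows = []
    for d in disorders:
        dec = _hybrid_for(d, x, mode)
        rows.append({"disorder": d.name, "H2": d.H2, "G_A": dec.G_A,
                     "xEP": dec.xEP, "G": dec.G, "residual": dec.residual})
    df = pd.DataFrame(rows, columns=["disorder", "H2", "G_A", "xEP", "G", "residual"])
    if df.empty:
        return df
    return (df.sort_values(["H2", "disorder"], ascending=[False, True], kind="stable")
              .reset_index(drop=True))


def plot_transmission_series(series: pd.DataFrame, path: str) -> None:
    """Stacked bar chart of G_A and x*E_P with the heritability marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(series)), 4.5))
    idx = range(len(series))
    ax.bar(idx, series["G_A"], color="#e08214", label="$G_A$")
    ax.bar(idx, series["xEP"], bottom=series["G_A"], color="#4393c3",
           label="$x\\,E_P$ (transmitted)")
    ax.scatter(idx, series["H2"], color="black", zorder=3, marker="_",
               s=220, label="$H^2$")
    ax.set_xticks(list(idx))
    ax.set_xticklabels(series["disorder"], rotation=45, ha="right")
    ax.set_ylabel("liability variance fraction")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def outlier_names(disorders: Sequence[DisorderSummary]) -> tuple[str, ...]:
    """Disorders with no couple-shared environment (``E_P == 0``).

    These explain heritability trivially under the hybrid model and are
    excluded from the hybrid aggregate ranges.
    """
    return tuple(d.name for d in disorders if d.E_P is not None and d.E_P == 0.0)


@dataclass(frozen=True)
class AggregateRanges:
    """Explained-percentage and residual ranges under both models."""

    measured: ExplainedRange
    hybrid: ExplainedRange
    excluded_from_hybrid: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "measured_pct_range": [self.measured.pct_min_int, self.measured.pct_max_int],
            "measured_pct_range_raw": [self.measured.pct_min, self.measured.pct_max],
            "hybrid_pct_range": [self.hybrid.pct_min_int, self.hybrid.pct_max_int],
            "hybrid_pct_range_raw": [self.hybrid.pct_min, self.hybrid.pct_max],
            "hybrid_residual_range": [round_half_away(self.hybrid.residual_min, 3),
                                      round_half_away(self.hybrid.residual_max, 3)],
            "excluded_from_hybrid": list(self.excluded_from_hybrid),
        }


def aggregate_ranges(disorders: Sequence[DisorderSummary],
                     x: TransmissionModel | float = 0.5,
                     mode: str = "reproduced",
                     exclude: Collection[str] | None = None) -> AggregateRanges:
    """Aggregate explained/residual ranges over disorders.

    The measured-model range covers all disorders with a ``G_SNP`` entry.
    The hybrid range excludes ``exclude`` (default: the ``E_P == 0``
    outliers, for which the hybrid model is degenerate).
    """
    if len(disorders) < 2:
        raise ValueError("need at least two disorders to aggregate")
    table = build_decomposition_table(disorders, x=x, mode=mode)
    measured_items = [(r.disorder, r.H2, r.G_measured)
                      for r in table.itertuples() if not pd.isna(r.G_measured)]
    hybrid_items = [(r.disorder, r.H2, r.G_hybrid)
                    for r in table.itertuples() if not pd.isna(r.G_hybrid)]
    excl = tuple(exclude) if exclude is not None else outlier_names(disorders)
    return AggregateRanges(
        measured=explained_range(measured_items),
        hybrid=explained_range(hybrid_items, exclude=excl),
        excluded_from_hybrid=excl)
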