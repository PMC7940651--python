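"""Reading and writing the package's tabular formats.

Canonical format is TSV with a mandatory header row, UTF-8, '.' decimal;
comma-separated files are accepted by sniffing the header line.  Family
tables are gzip-transparent (by file extension, via pandas).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DisorderSummary
from .simulate import FamilyTable, SimulationParams

__all__ = [
    "read_summary_table",
    "write_summary_table",
    "write_family_table",
    "read_family_table",
]

_SUMMARY_FIELDS = ["name", "H2", "E_P", "E_S", "E_F", "E_U", "E_total",
                   "G_SNP", "G_CNV", "G_A_reported", "note"]
_FAMILY_COLUMNS = ["family_id", "role", "latent", "affected",
                   "genetic", "parental_env", "sibling_env", "unique_env"]


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_table(path: str | Path) -> list[DisorderSummary]:
    """Parse a disorder summary table into validated records.

    Requires ``name`` and ``H2`` columns; all other known columns are
    optional.  Unknown columns are ignored.  Parse and validation errors
    carry the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"name": str, "note": str})
    missing = [c for c in ("name", "H2") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for i, row in df.iterrows():
        kwargs = {}
        for f in _SUMMARY_FIELDS:
            if f not in df.columns:
                continue
            v = row[f]
            if f in ("name", "note"):
                kwargs[f] = None if pd.isna(v) else str(v).strip() or None
            else:
                kwargs[f] = None if pd.isna(v) else float(v)
        try:
            out.append(DisorderSummary(**kwargs))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return out


def write_summary_table(disorders: Sequence[DisorderSummary],
                        path: str | Path) -> None:
    rows = []
    for d in disorders:
        rows.append({f: getattr(d, f) for f in _SUMMARY_FIELDS})
    pd.DataFrame(rows, columns=_SUMMARY_FIELDS).to_csv(path, sep="\t", index=False)


def write_family_table(fam: FamilyTable, path: str | Path,
                       sidecar: bool = True) -> None:
    """Write the long-format family table as TSV (gzip by extension).

    A sidecar ``<path>.meta.json`` records the generative parameters,
    seed and threshold so runs are self-describing.
    """
    path = Path(path)
    fam.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    if sidecar:
        p = fam.params
        meta = {"params": {"G_A": p.G_A, "E_P": p.E_P, "E_S": p.E_S, "x": p.x,
                           "K": p.K, "n_families": p.n_families,
                           "n_offspring": p.n_offspring, "seed": p.seed},
                "tau": fam.tau}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_family_table(path: str | Path) -> FamilyTable:
    """Reconstruct a :class:`FamilyTable` from its TSV serialization.

    Requires a constant family composition (two parents, same offspring
    count everywhere); schema violations raise with column-level detail.
    The threshold and parameters are taken from the sidecar when present,
    otherwise inferred (threshold from the affected fraction; parameters
    are left as a permissive placeholder).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _FAMILY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")

    wide = df.pivot_table(index="family_id", columns="role", values="latent")
    for role in ("father", "mother"):
        if role not in wide.columns or wide[role].isna().any():
            raise ValueError(f"{path}: column 'role' must include a '{role}' "
                             "row for every family")
    off_cols = sorted(c for c in wide.columns if c.startswith("offspring_"))
    if not off_cols or wide[off_cols].isna().any().any():
        raise ValueError(f"{path}: families must share a constant offspring count")

    comp = {}
    for col in ("genetic", "parental_env", "sibling_env", "unique_env"):
        comp[col] = df.pivot_table(index="family_id", columns="role", values=col)

    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        params = SimulationParams(**meta["params"])
        tau = float(meta["tau"])
    else:
        k_hat = float(df["affected"].mean())
        from scipy.stats import norm
        tau = float(norm.ppf(1.0 - min(max(k_hat, 1e-6), 1 - 1e-6)))
        params = SimulationParams(G_A=0.0, E_P=0.0, E_S=0.0, x=0.0,
                                  K=min(max(k_hat, 1e-6), 1 - 1e-6),
                                  n_families=wide.shape[0],
                                  n_offspring=len(off_cols), seed=0)

    off = wide[off_cols].to_numpy(float)
    return FamilyTable(
        params=params, tau=tau,
        father_latent=wide["father"].to_numpy(float),
        mother_latent=wide["mother"].to_numpy(float),
        offspring_latent=off,
        father_genetic=comp["genetic"]["father"].to_numpy(float),
        mother_genetic=comp["genetic"]["mother"].to_numpy(float),
        offspring_genetic=comp["genetic"][off_cols].to_numpy(float),
        couple_env=comp["parental_env"]["father"].to_numpy(float),
        offspring_trans_env=comp["parental_env"][off_cols].to_numpy(float),
        sibling_env=comp["sibling_env"][off_cols[0]].to_numpy(float),
        father_unique=comp["unique_env"]["father"].to_numpy(float),
        mother_unique=comp["unique_env"]["mother"].to_numpy(float),
        offspring_unique=comp["unique_env"][off_cols].to_numpy(float))
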