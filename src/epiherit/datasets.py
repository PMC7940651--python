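"""Bundled example data.

``load_neuropsych_five`` returns published liability-scale summary
statistics for five high-heritability neuropsychiatric disorders (ASD,
ADHD, bipolar disorder, depression, schizophrenia): broad-sense
heritability, couple-shared environmental variance, SNP- and CNV-based
measured genetic variance, and the additive genetic variance implied by
the hybrid transmission model at x = 0.5.  Depression carries a note
documenting a rounding discrepancy in its source decomposition.
"""

from __future__ import annotations

from importlib import resources

from .io import read_summary_table
from .model import DisorderSummary

__all__ = ["load_neuropsych_five"]


def load_neuropsych_five() -> list[DisorderSummary]:
    """The five-disorder neuropsychiatric summary table bundled with the package."""
    path = resources.files("epiherit") / "data" / "neuropsych_five.tsv"
    with resources.as_file(path) as p:
        return read_summary_table(p)
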