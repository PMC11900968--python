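"""Threshold classification of differential-expression result tables.

Consumes a precomputed table of genes with log2 fold changes and
multiple-testing-adjusted p-values (q-values) and applies the standard
significance rule: a gene is differentially expressed when q < 0.05 (strict)
and |log2FC| >= 1 (inclusive), split into up- and down-regulated by the sign
of the fold change. Differential testing itself is never performed here —
q-values are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DEGCounts", "deg_classify"]

UP, DOWN, NS = "up", "down", "ns"


@dataclass(frozen=True)
class DEGCounts:
    n_up: int
    n_down: int
    n_ns: int

    @property
    def n_total_de(self) -> int:
        return self.n_up + self.n_down

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down + self.n_ns


def deg_classify(
    table: pd.DataFrame, lfc_threshold: float = 1.0, q_threshold: float = 0.05
) -> tuple[pd.DataFrame, DEGCounts]:
    """Classify each gene as up / down / ns and tally the classes.

    ``table`` needs columns ``gene_id``, ``log2fc`` and ``q``. Rows with a
    missing log2fc or q are classified ``ns`` and flagged in a ``missing``
    column; a q outside [0, 1] is a validation error naming the offending gene.
    Returns a copy of the table with ``class`` and ``missing`` columns plus the
    class counts.
    """
    required = {"gene_id", "log2fc", "q"}
    if missing_cols := required - set(table.columns):
        raise ValueError(f"missing required columns: {sorted(missing_cols)}")
    out = table.copy()
    lfc = pd.to_numeric(out["log2fc"], errors="coerce")
    q = pd.to_numeric(out["q"], errors="coerce")

    bad_q = q.notna() & ((q < 0) | (q > 1))
    if bad_q.any():
        genes = out.loc[bad_q, "gene_id"].astype(str).tolist()
        raise ValueError(f"q-values outside [0, 1] for: {', '.join(genes[:5])}")
    if np.isinf(lfc).any():
        genes = out.loc[np.isinf(lfc), "gene_id"].astype(str).tolist()
        raise ValueError(f"non-finite log2fc for: {', '.join(genes[:5])}")

    missing = lfc.isna() | q.isna()
    sig = q < q_threshold
    cls = np.select(
        [missing, sig & (lfc >= lfc_threshold), sig & (lfc <= -lfc_threshold)],
        [NS, UP, DOWN],
        default=NS,
    )
    out["class"] = cls
    out["missing"] = missing.to_numpy()
    counts = DEGCounts(
        n_up=int((cls == UP).sum()),
        n_down=int((cls == DOWN).sum()),
        n_ns=int((cls == NS).sum()),
    )
    return out, counts
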