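"""Differential-expression gene sets and overlap enrichment.

Consumes per-gene differential-expression results (gene id, log2 fold
change, adjusted p) as produced by count-based DE tools, applies the
threshold rule FDR < q and linear fold change > F, and tests overlaps
between gene sets with Fisher's exact (hypergeometric) test. The DE
model fit itself is upstream and out of scope here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "DEGSets",
    "OverlapResult",
    "read_deg_table",
    "filter_degs",
    "overlap_enrichment",
    "venn_counts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGSets:
    """Up- and down-regulated gene sets with the thresholds that made them."""

    up: frozenset[str]
    down: frozenset[str]
    q: float
    min_fold: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


@dataclass(frozen=True)
class OverlapResult:
    """2x2 contingency result of a gene-set overlap test.

    ``table`` is ((k, |A|-k), (|B|-k, N-|A|-|B|+k)); ``odds_ratio`` is the
    sample odds ratio (inf when a zero cell forces it, NaN for 0/0).
    """

    k: int
    size_a: int
    size_b: int
    universe: int
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    alternative: str


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a DEG TSV with header columns gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def filter_degs(table: pd.DataFrame, q: float = 0.01, min_fold: float = 3.0) -> DEGSets:
    """Split a DEG table into up/down sets by FDR and fold-change cutoffs.

    A gene is *up* if ``padj < q`` and ``log2fc >= log2(min_fold)``, and
    *down* if ``padj < q`` and ``log2fc <= -log2(min_fold)``. Boundary
    equality passes on the fold change but fails on padj (the FDR rule is
    a strict "smaller than"). Rows with missing padj never pass.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    if min_fold <= 1:
        raise ValueError(f"min_fold must exceed 1, got {min_fold}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    for col in ("log2fc", "padj"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric {col} at row {row} (gene {table['gene_id'].iloc[row]!r})"
            )
    log2fc = pd.to_numeric(table["log2fc"])
    padj = pd.to_numeric(table["padj"])
    lf = math.log2(min_fold)
    sig = padj.notna() & (padj < q)
    up = frozenset(table.loc[sig & (log2fc >= lf), "gene_id"])
    down = frozenset(table.loc[sig & (log2fc <= -lf), "gene_id"])
    return DEGSets(up=up, down=down, q=q, min_fold=min_fold)


def overlap_enrichment(
    set_a,
    set_b,
    universe_size: int,
    alternative: str = "greater",
    universe=None,
) -> OverlapResult:
    """Fisher's exact test of the overlap between two gene sets.

    Builds the 2x2 table from ``k = |A ∩ B|``, |A|, |B| and the universe
    size N. ``alternative='greater'`` asks the enrichment question: the
    p-value is the hypergeometric upper tail
    ``sum_{i>=k} C(|A|, i) C(N-|A|, |B|-i) / C(N, |B|)``. Gene ids absent
    from an explicit universe are dropped with a logged count (id
    mismatches between annotation versions are common).
    """
    if alternative not in {"greater", "less", "two-sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    set_a, set_b = set(set_a), set(set_b)
    if universe is not None:
        uni = set(universe)
        dropped = len(set_a - uni) + len(set_b - uni)
        if dropped:
            logger.warning("dropping %d gene ids absent from the universe", dropped)
        set_a &= uni
        set_b &= uni
        if universe_size != len(uni):
            raise ValueError("universe_size disagrees with the universe list")
    na, nb = len(set_a), len(set_b)
    k = len(set_a & set_b)
    if universe_size < len(set_a | set_b):
        raise ValueError(
            f"universe size {universe_size} smaller than |A ∪ B| = {len(set_a | set_b)}"
        )
    table = ((k, na - k), (nb - k, universe_size - na - nb + k))
    if min(min(row) for row in table) < 0:
        raise ValueError("inconsistent overlap inputs (negative 2x2 cell)")
    a, b = table[0]
    c, d = table[1]
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if alternative == "greater":
        # hypergeometric upper tail; scipy computes it in log space
        p = float(scipy.stats.hypergeom.sf(k - 1, universe_size, na, nb))
    elif alternative == "less":
        p = float(scipy.stats.hypergeom.cdf(k, universe_size, na, nb))
    else:
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p = float(p)
    p = min(max(p, 0.0), 1.0)
    return OverlapResult(k, na, nb, universe_size, table, odds, p, alternative)


def venn_counts(*sets) -> dict[str, int]:
    """Region cardinalities of a 2- or 3-set Venn diagram.

    Keys are binary membership signatures, e.g. ``"110"`` for elements in
    the first two sets but not the third. Counts sum to |union|.
    """
    if len(sets) not in (2, 3):
        raise ValueError(f"venn_counts takes 2 or 3 sets, got {len(sets)}")
    sets = [set(s) for s in sets]
    union = set().union(*sets)
    out: dict[str, int] = {}
    n = len(sets)
    for code in range(1, 2**n):
        sig = format(code, f"0{n}b")
        region = union.copy()
        for bit, s in zip(sig, sets):
            region = region & s if bit == "1" else region - s
        out[sig] = len(region)
    return out
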