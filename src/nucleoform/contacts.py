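"""Sparse binned contact matrices: I/O, masking, and ICE balancing.

A :class:`ContactMatrix` stores the upper triangle (``i <= j``) of a
symmetric genome-wide contact map on a :class:`~nucleoform.binning.GenomeBinning`
grid, together with the set of masked bins. Raw matrices hold integer
counts; balancing produces real values and a per-bin bias vector ``b``
such that ``balanced(i, j) = raw(i, j) / (b_i * b_j)``.

The interchange format is a 5-column triplet TSV
``chrom1  start1  chrom2  start2  count`` where the start coordinates are
bin starts, plus a standard two-column chrom.sizes file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .binning import GenomeBinning, bin_genome, read_chrom_sizes

__all__ = [
    "ContactMatrix",
    "read_contacts",
    "write_contacts",
    "read_bed3",
    "mask_bins",
    "balance_ice",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric binned contact map stored as its upper triangle.

    Attributes
    ----------
    binning : GenomeBinning
        The bin grid.
    upper : scipy.sparse.csr_matrix
        Upper-triangular (``i <= j``) matrix of contact values.
    masked : frozenset of int
        Global indices of masked bins; no stored entry touches a masked bin.
    normalized : bool
        True after ICE balancing.
    biases : numpy.ndarray or None
        Per-bin biases (NaN on masked bins); present iff ``normalized``.
    """

    binning: GenomeBinning
    upper: sp.csr_matrix
    masked: frozenset[int]
    normalized: bool = False
    biases: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.binning.n_bins
        if self.upper.shape != (n, n):
            raise ValueError("matrix shape does not match binning")
        coo = self.upper.tocoo()
        if np.any(coo.row > coo.col):
            raise ValueError("entries must be upper-triangular (i <= j)")
        if self.normalized != (self.biases is not None):
            raise ValueError("biases must be present exactly when normalized")

    # -- views ------------------------------------------------------------

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal counted once)."""
        u = self.upper.tocsr()
        diag = u.diagonal()
        d = sp.diags(diag, dtype=diag.dtype)
        return (u + u.T - d).tocsr()

    def dense(self) -> np.ndarray:
        return self.symmetric().toarray()

    def marginals(self) -> np.ndarray:
        """Genome-wide per-bin marginal sums (diagonal weight 1)."""
        return np.asarray(self.symmetric().sum(axis=1)).ravel()

    def unmasked_index(self) -> np.ndarray:
        mask = np.ones(self.binning.n_bins, dtype=bool)
        if self.masked:
            mask[list(self.masked)] = False
        return np.flatnonzero(mask)

    def triplets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Canonical (i, j, value) arrays sorted by (i, j), i <= j."""
        coo = self.upper.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return coo.row[order], coo.col[order], coo.data[order]

    def total(self) -> float:
        """Grand total of the upper triangle (read-pair count for raw maps)."""
        return float(self.upper.sum())


def _build_upper(
    n: int, rows: Iterable[int], cols: Iterable[int], vals: Iterable[float],
    dtype=np.int64,
) -> sp.csr_matrix:
    rows = np.asarray(list(rows), dtype=np.int64)
    cols = np.asarray(list(cols), dtype=np.int64)
    vals = np.asarray(list(vals), dtype=dtype)
    # fold lower-triangle presentations into the upper triangle
    swap = rows > cols
    rows2 = np.where(swap, cols, rows)
    cols2 = np.where(swap, rows, cols)
    m = sp.coo_matrix((vals, (rows2, cols2)), shape=(n, n))
    m.sum_duplicates()
    return m.tocsr()


def matrix_from_triplets(
    binning: GenomeBinning,
    rows: Sequence[int],
    cols: Sequence[int],
    vals: Sequence[float],
    masked: Iterable[int] = (),
    normalized: bool = False,
    biases: np.ndarray | None = None,
) -> ContactMatrix:
    """Build a ContactMatrix from (i, j, value) triplets in any orientation."""
    dtype = np.float64 if normalized else np.int64
    upper = _build_upper(binning.n_bins, rows, cols, vals, dtype=dtype)
    return ContactMatrix(binning, upper, frozenset(int(i) for i in masked),
                         normalized, biases)


# -- triplet text I/O -----------------------------------------------------


def read_contacts(
    triplet_path: str | Path,
    chrom_sizes_path: str | Path,
    bin_size: int,
) -> ContactMatrix:
    """Read a raw contact matrix from 5-column triplet text.

    Rows are ``chrom1 start1 chrom2 start2 count``; starts are bin start
    coordinates. Lower-triangle presentations are folded and duplicate
    pairs summed, so the result is invariant to row order and orientation.
    """
    sizes = read_chrom_sizes(chrom_sizes_path)
    binning = bin_genome(sizes, bin_size)
    rows, cols, vals = [], [], []
    with open(triplet_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{triplet_path}:{lineno}: expected 5 tab-separated "
                    f"fields, got {len(fields)}"
                )
            c1, s1, c2, s2, cnt = fields
            try:
                s1, s2 = int(s1), int(s2)
            except ValueError:
                raise ValueError(
                    f"{triplet_path}:{lineno}: non-integer bin start"
                ) from None
            try:
                count = int(cnt)
            except ValueError:
                raise ValueError(
                    f"{triplet_path}:{lineno}: non-integer count {cnt!r}"
                ) from None
            try:
                i = binning.bin_index(c1, s1)
                j = binning.bin_index(c2, s2)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{triplet_path}:{lineno}: {exc}") from None
            rows.append(i)
            cols.append(j)
            vals.append(count)
    return matrix_from_triplets(binning, rows, cols, vals)


def write_contacts(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the canonical upper-triangle triplets as 5-column TSV."""
    b = matrix.binning
    rows, cols, vals = matrix.triplets()
    with open(path, "w") as fh:
        for i, j, v in zip(rows, cols, vals):
            c1 = b.chroms[b.bin_chrom_idx[i]]
            c2 = b.chroms[b.bin_chrom_idx[j]]
            val = int(v) if not matrix.normalized else repr(float(v))
            fh.write(f"{c1}\t{b.bin_start[i]}\t{c2}\t{b.bin_start[j]}\t{val}\n")


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (chrom, start, end), 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


# -- masking --------------------------------------------------------------


def _drop_masked_entries(upper: sp.csr_matrix, masked: frozenset[int]) -> sp.csr_matrix:
    if not masked:
        return upper
    coo = upper.tocoo()
    bad = np.zeros(upper.shape[0], dtype=bool)
    bad[list(masked)] = True
    keep = ~(bad[coo.row] | bad[coo.col])
    return sp.coo_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=upper.shape
    ).tocsr()


def mask_bins(
    matrix: ContactMatrix,
    regions: Sequence[tuple[str, int, int]] | None = None,
    min_coverage_fraction: float | None = None,
) -> ContactMatrix:
    """Mask bins by BED regions and/or a low-coverage rule.

    ``regions`` are 0-based half-open (chrom, start, end) intervals; every
    bin overlapping a region is masked. ``min_coverage_fraction`` masks
    bins whose raw marginal is below ``fraction`` times the median
    marginal of nonzero bins. Newly masked bins are unioned with the
    existing masked set and all entries touching them are removed.
    """
    if regions is None and min_coverage_fraction is None:
        raise ValueError("provide regions and/or min_coverage_fraction")
    new_masked = set(matrix.masked)
    if regions is not None:
        for chrom, start, end in regions:
            new_masked.update(matrix.binning.bins_overlapping(chrom, start, end).tolist())
    if min_coverage_fraction is not None:
        if not 0 < min_coverage_fraction < 1:
            raise ValueError("min_coverage_fraction must be in (0, 1)")
        marg = matrix.marginals()
        nonzero = marg[marg > 0]
        cutoff = (min_coverage_fraction * float(np.median(nonzero))
                  if nonzero.size else 0.0)
        new_masked.update(np.flatnonzero(marg < cutoff).tolist())
        # all-zero bins are always unusable
        new_masked.update(np.flatnonzero(marg == 0).tolist())
    masked = frozenset(new_masked)
    upper = _drop_masked_entries(matrix.upper, masked)
    biases = None
    if matrix.normalized and matrix.biases is not None:
        biases = matrix.biases.copy()
        biases[list(masked)] = np.nan
    return replace(matrix, upper=upper, masked=masked, biases=biases)


# -- ICE balancing --------------------------------------------------------


def balance_ice(
    matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative correction: equalize unmasked marginals.

    Finds per-bin biases ``b_i > 0`` (geometric mean 1 over unmasked bins)
    such that the balanced matrix ``raw(i,j) / (b_i b_j)`` has equal
    genome-wide marginals on all unmasked bins, to relative tolerance
    ``tol`` measured as max |marginal/mean - 1|.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    n = matrix.binning.n_bins
    active = matrix.unmasked_index()
    if active.size == 0:
        raise ValueError("all bins are masked")

    sym = matrix.symmetric().astype(np.float64)
    marg = np.asarray(sym.sum(axis=1)).ravel()
    zero_active = active[marg[active] == 0]
    if zero_active.size:
        raise ValueError(
            f"{zero_active.size} unmasked bin(s) have zero marginal "
            f"(e.g. global bin {int(zero_active[0])}); mask them first "
            f"(mask_bins with min_coverage_fraction or explicit regions)"
        )

    bias = np.ones(n)
    work = sym.tocsr(copy=True)

    def residual(m: sp.csr_matrix) -> float:
        cur = np.asarray(m.sum(axis=1)).ravel()[active]
        return float(np.max(np.abs(cur / cur.mean() - 1.0)))

    converged = False
    res = residual(work)
    for _ in range(max_iter):
        if res < tol:
            converged = True
            break
        cur = np.asarray(work.sum(axis=1)).ravel()
        delta = np.ones(n)
        delta[active] = cur[active] / cur[active].mean()
        inv = 1.0 / delta
        d = sp.diags(inv)
        work = (d @ work @ d).tocsr()
        bias *= delta
        res = residual(work)
    if not converged and res < tol:
        converged = True
    if not converged:
        raise RuntimeError(
            f"ICE did not converge in {max_iter} iterations "
            f"(final marginal residual {res:.3e} >= tol {tol:g})"
        )

    # rescale so the geometric mean of unmasked biases is 1
    g = np.exp(np.mean(np.log(bias[active])))
    bias /= g
    inv = np.zeros(n)
    inv[active] = 1.0 / bias[active]
    d = sp.diags(inv)
    balanced_sym = (d @ sym @ d).tocsr()
    # keep upper triangle only
    balanced_upper = sp.triu(balanced_sym).tocsr()
    out_bias = np.full(n, np.nan)
    out_bias[active] = bias[active]
    logger.info("ICE converged: residual %.2e on %d unmasked bins", res, active.size)
    return replace(
        matrix, upper=balanced_upper, normalized=True, biases=out_bias
    )
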