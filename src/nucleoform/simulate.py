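"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* :func:`simulate_contact_map` — binned Hi-C maps with power-law cis
  decay (expected contact at separation s bins proportional to
  ``s**-alpha``), a uniform chromosome-territory trans background,
  Poisson sampling noise scaled to a target sequencing depth, and
  optional masked regions.
* :func:`simulate_gene_sets` — a gene universe carrying two labelled
  sets with an exactly specified overlap.
* :func:`simulate_nucleus_image` — grayscale images of non-overlapping
  ellipses with analytic ground-truth area and circularity (Ramanujan's
  perimeter approximation).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .binning import GenomeBinning, bin_genome
from .contacts import ContactMatrix
from .morphology import MorphologyRecord

__all__ = [
    "HiCSimParams",
    "GeneSetSimParams",
    "NucleusSimParams",
    "simulate_contact_map",
    "simulate_gene_sets",
    "simulate_nucleus_image",
    "ellipse_truth",
    "write_image",
]

S_REF_BINS = 10  # trans expectation is anchored to the cis expectation here


@dataclass(frozen=True)
class HiCSimParams:
    """Knobs of the Hi-C map generator.

    alpha is the cis contact-decay exponent (expected contact at
    separation s bins proportional to ``s**-alpha``); territory_strength
    is the ratio of the expected per-pair trans contact to the expected
    cis contact at the reference separation of 10 bins (0 = perfectly
    separated territories); depth is the expected total read-pair count.
    """

    chrom_lengths: dict[str, int]
    bin_size: int = 10_000
    alpha: float = 1.0
    territory_strength: float = 0.05
    depth: float = 2e6
    masked_regions: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if self.territory_strength < 0:
            raise ValueError("territory_strength must be >= 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")


@dataclass(frozen=True)
class GeneSetSimParams:
    """Two labelled gene sets of exact sizes and overlap in a universe."""

    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.universe_size, self.size_a, self.size_b, self.overlap) < 0:
            raise ValueError("sizes must be nonnegative")
        if self.overlap > min(self.size_a, self.size_b):
            raise ValueError("overlap exceeds a set size")
        if max(self.size_a, self.size_b) > self.universe_size:
            raise ValueError("set larger than universe")
        if self.size_a + self.size_b - self.overlap > self.universe_size:
            raise ValueError("sets cannot fit in the universe with this overlap")


@dataclass(frozen=True)
class NucleusSimParams:
    """Ellipse layout and imaging noise for the nucleus-image generator.

    Each ellipse is (center_row, center_col, semi_axis_a, semi_axis_b,
    rotation_rad); intensities are gray levels on a 16-bit scale.
    """

    image_shape: tuple[int, int]
    ellipses: tuple[tuple[float, float, float, float, float], ...]
    foreground: float = 20_000.0
    background: float = 2_000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for e in self.ellipses:
            _, _, a, b, _ = e
            if a <= 0 or b <= 0:
                raise ValueError("semi-axes must be positive")


# ---------------------------------------------------------------------------
# Hi-C maps


def expected_contact_matrix(
    params: HiCSimParams, binning: GenomeBinning
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expectation of the generator, scaled to ``depth``.

    Returns the dense upper-triangular expectation matrix and the boolean
    mask of masked bins. Expectations on short terminal bins are scaled
    by (bin length / bin_size) on each axis; the diagonal carries no
    mass (downstream statistics exclude it regardless).
    """
    n = binning.n_bins
    w = binning.bin_widths() / binning.bin_size
    cidx = binning.bin_chrom_idx
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    same = cidx[:, None] == cidx[None, :]
    expect = np.zeros((n, n))
    cis = same & (sep >= 1)
    with np.errstate(divide="ignore"):
        expect[cis] = sep[cis] ** (-params.alpha)
    trans_level = params.territory_strength * S_REF_BINS ** (-params.alpha)
    expect[~same] = trans_level
    expect *= w[:, None] * w[None, :]

    masked = np.zeros(n, dtype=bool)
    for chrom, start, end in params.masked_regions:
        masked[binning.bins_overlapping(chrom, start, end)] = True
    expect[masked, :] = 0.0
    expect[:, masked] = 0.0

    expect = np.triu(expect)
    total = expect.sum()
    if total <= 0:
        raise ValueError("expectation has no mass (everything masked?)")
    if round(params.depth) == 0:
        raise ValueError(f"depth {params.depth} rounds to zero read pairs")
    expect *= params.depth / total
    return expect, masked


def simulate_contact_map(
    params: HiCSimParams, binning: GenomeBinning | None = None
) -> ContactMatrix:
    """Draw a raw contact map: independent Poisson counts around the
    power-law/territory expectation, scaled so the expected grand total
    equals ``params.depth``.
    """
    if binning is None:
        binning = bin_genome(params.chrom_lengths, params.bin_size)
    elif (
        binning.chrom_lengths != params.chrom_lengths
        or binning.bin_size != params.bin_size
    ):
        raise ValueError("binning does not match the simulation parameters")
    expect, masked = expected_contact_matrix(params, binning)
    rng = np.random.default_rng(params.seed)
    counts = rng.poisson(expect)
    upper = sp.csr_matrix(sp.triu(sp.coo_matrix(counts)))
    upper.eliminate_zeros()
    return ContactMatrix(
        binning=binning,
        upper=upper.astype(np.int64),
        masked=frozenset(np.flatnonzero(masked).tolist()),
    )


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(
    params: GeneSetSimParams,
) -> tuple[frozenset[str], frozenset[str], list[str]]:
    """Draw two gene sets with exact sizes and overlap from a universe.

    Returns (set_a, set_b, universe). Membership is uniform given the
    seed: the shared, A-only and B-only genes are disjoint uniform draws.
    """
    rng = np.random.default_rng(params.seed)
    width = max(6, len(str(max(params.universe_size - 1, 1))))
    universe = [f"g{idx:0{width}d}" for idx in range(params.universe_size)]
    n_needed = params.size_a + params.size_b - params.overlap
    chosen = rng.choice(params.universe_size, size=n_needed, replace=False)
    shared = chosen[: params.overlap]
    only_a = chosen[params.overlap : params.size_a]
    only_b = chosen[params.size_a :]
    set_a = frozenset(universe[i] for i in np.concatenate([shared, only_a]))
    set_b = frozenset(universe[i] for i in np.concatenate([shared, only_b]))
    assert len(set_a) == params.size_a and len(set_b) == params.size_b
    return set_a, set_b, universe


# ---------------------------------------------------------------------------
# nucleus images


def ellipse_truth(a: float, b: float) -> tuple[float, float, float]:
    """Analytic (area, perimeter, circularity) of an ellipse.

    Perimeter uses Ramanujan's approximation
    ``pi (a+b) (1 + 3h / (10 + sqrt(4 - 3h)))`` with
    ``h = ((a-b)/(a+b))**2``; circularity is ``4 pi A / P**2``.
    """
    area = math.pi * a * b
    h = ((a - b) / (a + b)) ** 2
    perimeter = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    circularity = 4 * math.pi * area / perimeter**2
    return area, perimeter, circularity


def _ellipse_mask(
    shape: tuple[int, int], cr: float, cc: float, a: float, b: float, theta: float
) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rows - cr
    dc = cols - cc
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def simulate_nucleus_image(
    params: NucleusSimParams,
) -> tuple[np.ndarray, list[MorphologyRecord]]:
    """Render non-overlapping ellipses with Gaussian noise.

    Returns the image (float64, gray levels clipped to [0, 65535]) and
    ground-truth records carrying the analytic area, perimeter and
    circularity of each ellipse. Ellipses extending beyond the image or
    overlapping each other are errors (overlap would make the truth
    ambiguous).
    """
    nr, nc = params.image_shape
    image = np.full((nr, nc), float(params.background))
    masks = []
    truth = []
    for lab, (cr, cc, a, b, theta) in enumerate(params.ellipses, start=1):
        # analytic bounding box of the rotated ellipse
        dr = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
        dc = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
        if cr - dr < 0 or cr + dr > nr - 1 or cc - dc < 0 or cc + dc > nc - 1:
            raise ValueError(f"ellipse {lab} extends beyond the image")
        mask = _ellipse_mask((nr, nc), cr, cc, a, b, theta)
        for prev_lab, prev in enumerate(masks, start=1):
            if np.any(mask & prev):
                raise ValueError(f"ellipses {prev_lab} and {lab} overlap")
        masks.append(mask)
        image[mask] = float(params.foreground)
        area, perim, circ = ellipse_truth(a, b)
        truth.append(
            MorphologyRecord(
                label=lab,
                area=area,
                perimeter=perim,
                circularity=circ,
                equivalent_diameter=2.0 * math.sqrt(area / math.pi),
                centroid=(cr, cc),
            )
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 65535.0)
    return image, truth


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a grayscale image as 16-bit TIFF (or PGM by extension)."""
    path = Path(path)
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".pgm":
        with open(path, "wb") as fh:
            fh.write(f"P5\n{arr.shape[1]} {arr.shape[0]}\n65535\n".encode())
            fh.write(arr.astype(">u2").tobytes())
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
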