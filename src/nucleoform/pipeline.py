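"""Config-driven orchestration of the analysis stages.

A YAML config describes up to three stage blocks — ``hic``, ``deg``,
``morphology`` — each either consuming files or simulating its own
inputs. :func:`run_pipeline` executes the requested stages in order,
writes per-stage TSV/JSON outputs under ``output_dir`` and a
machine-readable ``report.json`` recording the fully resolved
configuration (every applied default), the seed, and per-stage
summaries. Reruns with the same config and seed reproduce identical
numeric outputs.

Defaults follow the study conventions this pipeline models: 10-kb bins
for per-chromosome maps, a 200-kb compactness window, decay-exponent
fits up to 2.5 Mb, and DEG thresholds FDR < 0.01 with linear fold
change > 3.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import __version__
from .binning import bin_genome, read_chrom_sizes, write_chrom_sizes
from .contacts import balance_ice, mask_bins, read_bed3, read_contacts, write_contacts
from .degs import filter_degs, overlap_enrichment, read_deg_table, venn_counts
from .morphology import (
    compare_morphology,
    max_project,
    measure_all,
    read_image_stack,
    records_table,
    segment_nuclei,
)
from .simulate import (
    GeneSetSimParams,
    HiCSimParams,
    NucleusSimParams,
    simulate_contact_map,
    simulate_gene_sets,
    simulate_nucleus_image,
    write_image,
)
from .stats import (
    compactness_profile,
    compare_genotypes,
    expected_contact_curve,
    fit_decay_exponent,
    trans_contact_profile,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenotypeSim(_Model):
    alpha: float
    territory_strength: Optional[float] = None  # falls back to the block value


class HicSimulateBlock(_Model):
    # the first genotype listed is the reference (A side of comparisons)
    genotypes: dict[str, GenotypeSim]
    chrom_lengths: dict[str, int]
    bin_size: int = 10_000
    depth: float = 2e6
    territory_strength: float = 0.05
    masked_regions: list[tuple[str, int, int]] = []


class HicStage(_Model):
    simulate: Optional[HicSimulateBlock] = None
    matrices: Optional[dict[str, str]] = None  # genotype -> triplet TSV
    chrom_sizes: Optional[str] = None
    bin_size: int = 10_000
    mask_bed: Optional[str] = None
    min_coverage_fraction: Optional[float] = None
    window: int = 200_000
    s_max: int = 2_500_000
    s_min: Optional[int] = None
    balance_tol: float = 1e-5
    balance_max_iter: int = 200

    @model_validator(mode="after")
    def _one_input(self) -> "HicStage":
        if (self.simulate is None) == (self.matrices is None):
            raise ValueError("hic stage needs exactly one of 'simulate' or 'matrices'")
        if self.matrices is not None and self.chrom_sizes is None:
            raise ValueError("'matrices' input requires 'chrom_sizes'")
        return self


class GeneSetSimBlock(_Model):
    universe_size: int
    size_a: int
    size_b: int
    overlap: int


class DegStage(_Model):
    simulate: Optional[GeneSetSimBlock] = None
    deg_table: Optional[str] = None
    reference_sets: Optional[dict[str, str]] = None  # name -> one-id-per-line file
    universe_size: Optional[int] = None
    q: float = 0.01
    min_fold: float = 3.0
    alternative: Literal["greater", "less", "two-sided"] = "greater"

    @model_validator(mode="after")
    def _one_input(self) -> "DegStage":
        file_mode = self.deg_table is not None
        if (self.simulate is None) == (not file_mode):
            raise ValueError("deg stage needs exactly one of 'simulate' or 'deg_table'")
        if file_mode and (self.reference_sets is None or self.universe_size is None):
            raise ValueError("'deg_table' input requires 'reference_sets' and 'universe_size'")
        return self


class NucleusGroupSim(_Model):
    ellipses: list[tuple[float, float, float, float, float]]


class MorphSimulateBlock(_Model):
    image_shape: tuple[int, int]
    groups: dict[str, NucleusGroupSim]
    foreground: float = 20_000.0
    background: float = 2_000.0
    noise_sd: float = 0.0


class MorphologyStage(_Model):
    simulate: Optional[MorphSimulateBlock] = None
    images: Optional[dict[str, list[str]]] = None  # group -> image files
    pixel_size: float = 1.0
    min_area: float = 100.0
    threshold: float | Literal["otsu"] = "otsu"

    @model_validator(mode="after")
    def _one_input(self) -> "MorphologyStage":
        if (self.simulate is None) == (self.images is None):
            raise ValueError("morphology stage needs exactly one of 'simulate' or 'images'")
        return self


class PipelineConfig(_Model):
    run_name: str = "run"
    seed: int = 0
    output_dir: str
    hic: Optional[HicStage] = None
    deg: Optional[DegStage] = None
    morphology: Optional[MorphologyStage] = None


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config, applying all defaults.

    Unknown keys and type errors are rejected with a message listing
    every problem pydantic found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ValueError(f"{path}: invalid config: {problems}") from None


def _stage_seed(base: int, stage: str, item: int = 0) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    h = np.random.SeedSequence([base & 0x7FFFFFFF, tag, item])
    return int(h.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# stages


def _run_hic(cfg: HicStage, seed: int, outdir: Path) -> dict:
    summary: dict = {"genotypes": {}}
    matrices = {}
    if cfg.simulate is not None:
        sim = cfg.simulate
        binning = bin_genome(sim.chrom_lengths, sim.bin_size)
        write_chrom_sizes(sim.chrom_lengths, outdir / "chrom.sizes")
        for i, (name, geno) in enumerate(sim.genotypes.items()):
            params = HiCSimParams(
                chrom_lengths=sim.chrom_lengths,
                bin_size=sim.bin_size,
                alpha=geno.alpha,
                territory_strength=(
                    geno.territory_strength
                    if geno.territory_strength is not None
                    else sim.territory_strength
                ),
                depth=sim.depth,
                masked_regions=tuple(sim.masked_regions),
                seed=_stage_seed(seed, "hic", i),
            )
            mat = simulate_contact_map(params, binning)
            write_contacts(mat, outdir / f"{name}.contacts.tsv")
            matrices[name] = mat
    else:
        for name, p in cfg.matrices.items():
            matrices[name] = read_contacts(p, cfg.chrom_sizes, cfg.bin_size)

    if cfg.mask_bed is not None:
        regions = read_bed3(cfg.mask_bed)
        matrices = {k: mask_bins(m, regions=regions) for k, m in matrices.items()}
    if cfg.min_coverage_fraction is not None:
        matrices = {
            k: mask_bins(m, min_coverage_fraction=cfg.min_coverage_fraction)
            for k, m in matrices.items()
        }

    compactness = {}
    trans = {}
    for name, mat in matrices.items():
        # ICE refuses all-zero unmasked bins; mask them automatically here
        marg = mat.marginals()
        zero = set(np.flatnonzero(marg == 0).tolist()) - set(mat.masked)
        if zero:
            mat = mask_bins(mat, min_coverage_fraction=1e-12)
        balanced = balance_ice(mat, tol=cfg.balance_tol, max_iter=cfg.balance_max_iter)
        prof = compactness_profile(balanced, window=cfg.window)
        prof.table().to_csv(outdir / f"{name}.compactness.tsv", sep="\t", index=False)
        compactness[name] = prof
        curve = expected_contact_curve(balanced, s_max=cfg.s_max)
        curve.table().to_csv(outdir / f"{name}.decay.tsv", sep="\t", index=False)
        exponent = fit_decay_exponent(curve, s_min=cfg.s_min, s_max=cfg.s_max)
        geno_summary = {
            "n_bins": mat.binning.n_bins,
            "n_masked": len(mat.masked),
            "total_contacts": mat.total() if not mat.normalized else None,
            "decay_exponent": exponent,
        }
        if len(mat.binning.chroms) >= 2:
            tp = trans_contact_profile(balanced)
            tp.table().to_csv(outdir / f"{name}.trans.tsv", sep="\t", index=False)
            trans[name] = tp
            geno_summary["mean_trans_fraction"] = float(
                np.nanmean(tp.fraction)
            )
        summary["genotypes"][name] = geno_summary

    names = list(matrices)
    if len(names) >= 2:
        ref = names[0]
        comparisons = []
        for other in names[1:]:
            comp = compare_genotypes(compactness[ref], compactness[other])
            t = comp.table.copy()
            t.insert(0, "genotype_b", other)
            t.insert(0, "genotype_a", ref)
            comparisons.append(t)
        comp_table = pd.concat(comparisons, ignore_index=True)
        comp_table.to_csv(outdir / "compactness_comparison.tsv", sep="\t", index=False)
        summary["compactness_comparison"] = comp_table.to_dict(orient="records")
    return summary


def _run_deg(cfg: DegStage, seed: int, outdir: Path) -> dict:
    summary: dict = {}
    if cfg.simulate is not None:
        params = GeneSetSimParams(
            universe_size=cfg.simulate.universe_size,
            size_a=cfg.simulate.size_a,
            size_b=cfg.simulate.size_b,
            overlap=cfg.simulate.overlap,
            seed=_stage_seed(seed, "deg"),
        )
        set_a, set_b, universe = simulate_gene_sets(params)
        res = overlap_enrichment(
            set_a, set_b, len(universe), alternative=cfg.alternative
        )
        results = {"set_a_vs_set_b": res}
        venn = venn_counts(set_a, set_b)
    else:
        table = read_deg_table(cfg.deg_table)
        sets = filter_degs(table, q=cfg.q, min_fold=cfg.min_fold)
        degs = sets.up | sets.down
        summary["n_up"] = len(sets.up)
        summary["n_down"] = len(sets.down)
        results = {}
        refs = {}
        for name, p in cfg.reference_sets.items():
            with open(p) as fh:
                refs[name] = {line.strip() for line in fh if line.strip()}
            results[f"degs_vs_{name}"] = overlap_enrichment(
                degs, refs[name], cfg.universe_size, alternative=cfg.alternative
            )
        ref_sets = list(refs.values())
        if len(ref_sets) == 1:
            venn = venn_counts(degs, ref_sets[0])
        elif len(ref_sets) >= 2:
            venn = venn_counts(degs, ref_sets[0], ref_sets[1])
        else:
            venn = None

    summary["overlaps"] = {
        key: {
            "k": r.k,
            "size_a": r.size_a,
            "size_b": r.size_b,
            "universe": r.universe,
            "table": r.table,
            "odds_ratio": r.odds_ratio,
            "p": r.p,
            "alternative": r.alternative,
        }
        for key, r in results.items()
    }
    if venn is not None:
        summary["venn"] = venn
    with open(outdir / "deg_overlap.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _run_morphology(cfg: MorphologyStage, seed: int, outdir: Path) -> dict:
    groups: dict[str, list] = {}
    if cfg.simulate is not None:
        sim = cfg.simulate
        for i, (name, grp) in enumerate(sim.groups.items()):
            params = NucleusSimParams(
                image_shape=tuple(sim.image_shape),
                ellipses=tuple(tuple(e) for e in grp.ellipses),
                foreground=sim.foreground,
                background=sim.background,
                noise_sd=sim.noise_sd,
                seed=_stage_seed(seed, "morphology", i),
            )
            image, _truth = simulate_nucleus_image(params)
            write_image(image, outdir / f"{name}.nuclei.tiff")
            labels = segment_nuclei(
                image, min_area=cfg.min_area, threshold=cfg.threshold
            )
            groups[name] = measure_all(labels, pixel_size=cfg.pixel_size)
    else:
        for name, paths in cfg.images.items():
            records = []
            for p in paths:
                stack = read_image_stack(p)
                proj = max_project(stack)
                labels = segment_nuclei(
                    proj, min_area=cfg.min_area, threshold=cfg.threshold
                )
                records.extend(measure_all(labels, pixel_size=cfg.pixel_size))
            groups[name] = records

    summary: dict = {"groups": {}}
    for name, records in groups.items():
        records_table(records).to_csv(
            outdir / f"{name}.morphology.tsv", sep="\t", index=False
        )
        summary["groups"][name] = {
            "n": len(records),
            "median_area": float(np.median([r.area for r in records])) if records else None,
            "median_circularity": (
                float(np.median([r.circularity for r in records])) if records else None
            ),
        }
    names = list(groups)
    if len(names) >= 2:
        comps = []
        for other in names[1:]:
            for metric in ("area", "circularity"):
                c = compare_morphology(groups[names[0]], groups[other], metric=metric)
                c["group_a"] = names[0]
                c["group_b"] = other
                comps.append(c)
        pd.DataFrame(comps).to_csv(
            outdir / "morphology_comparison.tsv", sep="\t", index=False
        )
        summary["comparisons"] = comps
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write a run report.

    Returns the report dict (also written to ``output_dir/report.json``).
    Stage failures raise :class:`PipelineError` naming the stage, after
    writing a report marking it failed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "run_name": config.run_name,
        "seed": config.seed,
        "nucleoform_version": __version__,
        "config": config.model_dump(),
        "stages": {},
    }
    stage_fns = [
        ("hic", config.hic, _run_hic),
        ("deg", config.deg, _run_deg),
        ("morphology", config.morphology, _run_morphology),
    ]
    for name, cfg, fn in stage_fns:
        if cfg is None:
            continue
        stage_dir = outdir / name
        stage_dir.mkdir(exist_ok=True)
        logger.info("running stage %s", name)
        try:
            report["stages"][name] = fn(cfg, config.seed, stage_dir)
        except Exception as exc:
            report["stages"][name] = {"error": str(exc)}
            with open(outdir / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, default=_json_default)
            raise PipelineError(name, str(exc)) from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report
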