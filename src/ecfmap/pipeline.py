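"""End-to-end orchestration: peaks -> flanks -> motif -> candidates ->
PWM build -> genome scan -> classification -> conservation.

The pipeline is a plain library call sequence (single process); each stage
writes its outputs before the next starts, any stage failure aborts with the
stage name while preserving completed outputs, and stages are skipped when
their inputs are not configured (e.g. a precomputed candidate table can
replace the peak/motif stages).  All randomness flows from one root seed,
split deterministically per stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_io import (Contig, GeneModel, PromoterEntry, extract_upstream,
                        load_validated_promoters, read_fasta, read_gff,
                        read_promoter_table, write_promoter_table)
from .peak_caller import (CoverageTrack, PeakParams, call_peaks,
                          oriented_flanks, read_coverage, summit_flank,
                          write_peaks)
from .motif_discovery import GibbsParams, gibbs_two_block, motif_to_frame
from .promoter_model import (CandidateRule, ScanParams, build_validated_pwms,
                             candidate_promoters, scan_region, write_pwm)
from .expression_class import (ClassThresholds, classify_matrix,
                               dependence_report, read_expression_matrix,
                               read_promoter_counts)
from .conservation import (ConservationParams, SpeciesData,
                           conservation_matrix, conserved_targets)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths plus every stage's parameter block.

    In-memory objects (contigs, tracks, frames, panel) may be supplied
    directly instead of paths; paths win when both are given.
    """

    output_dir: str | Path = "ecfmap_out"
    seed: int = 0
    # inputs (paths or objects)
    genome: Any = None            # path or list[Contig]
    annotation: Any = None        # path or list[GeneModel]
    chip: Any = None              # path or CoverageTrack
    control: Any = None
    expression: Any = None        # path or DataFrame
    promoter_counts: Any = None   # path or dict
    validated_promoters: Any = None  # path or list[PromoterEntry]; None -> packaged
    candidates: Any = None        # precomputed candidate table (skips peaks/motif)
    panel: Any = None             # list[SpeciesData] (conservation stage)
    skip: tuple[str, ...] = ()
    # parameter blocks
    peak_params: PeakParams = field(default_factory=PeakParams)
    gibbs_params: GibbsParams = field(default_factory=GibbsParams)
    scan_params: ScanParams = field(default_factory=ScanParams)
    candidate_rule: CandidateRule = field(default_factory=CandidateRule)
    class_thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    conservation_params: ConservationParams = field(
        default_factory=ConservationParams)
    flank_bp: int = 100


@dataclass
class ReportBundle:
    output_dir: Path
    peaks: list = field(default_factory=list)
    motif: Any = None
    candidates: list = field(default_factory=list)
    pwms: tuple = ()
    scan_hits: pd.DataFrame | None = None
    classification: pd.DataFrame | None = None
    conservation: Any = None
    conserved: list = field(default_factory=list)
    log: dict = field(default_factory=dict)


def _load_genome(cfg: PipelineConfig) -> list[Contig]:
    if isinstance(cfg.genome, (str, Path)):
        return read_fasta(cfg.genome)
    return cfg.genome or []


def _load_genes(cfg: PipelineConfig, contigs) -> list[GeneModel]:
    if isinstance(cfg.annotation, (str, Path)):
        return read_gff(cfg.annotation, contigs=contigs)
    return cfg.annotation or []


def _load_track(obj) -> CoverageTrack | None:
    if obj is None:
        return None
    if isinstance(obj, (str, Path)):
        return read_coverage(obj)
    return obj


def hits_to_frame(hits) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": h.gene_id, "pwm": h.pwm_name,
        "genomic_start": h.genomic_start, "gap": h.gap,
        "raw_score": h.raw_score, "normalized_score": h.normalized_score,
        "distance_bp": h.distance_bp,
    } for h in hits], columns=["gene_id", "pwm", "genomic_start", "gap",
                               "raw_score", "normalized_score", "distance_bp"])


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the configured stages in order and bundle the outputs."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(cfg.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(
                       ("peaks", "motif", "scan", "classify", "conserve"),
                       rng_root.spawn(5))}
    bundle = ReportBundle(output_dir=out)
    log: dict[str, Any] = {
        "version": __version__, "seed": cfg.seed, "stage_seeds": stage_seeds,
        "stages": [],
    }
    bundle.log = log

    contigs = _load_genome(cfg)
    genes = _load_genes(cfg, contigs)
    contig_len = {c.id: len(c) for c in contigs}

    def record(stage: str, params: Any) -> None:
        log["stages"].append({
            "stage": stage,
            "params": dataclasses.asdict(params) if dataclasses.is_dataclass(params)
            else params})

    # ---- stage: peaks -----------------------------------------------------
    flanks: list[tuple[str, str]] = []
    chip = _load_track(cfg.chip)
    control = _load_track(cfg.control)
    if "peaks" not in cfg.skip and chip is not None and control is not None:
        try:
            bundle.peaks = call_peaks(chip, control, cfg.peak_params)
            write_peaks(bundle.peaks, out / "peaks.tsv")
            flanks = oriented_flanks(
                bundle.peaks, contigs, genes, cfg.flank_bp,
                cfg.candidate_rule.max_distance_bp)
            with open(out / "flanks.fa", "w") as fh:
                for name, seq in flanks:
                    fh.write(f">{name}\n{seq}\n")
            record("peaks", cfg.peak_params)
        except Exception as exc:
            raise StageError("peaks", exc) from exc

    # ---- stage: motif -----------------------------------------------------
    if "motif" not in cfg.skip and len(flanks) >= 2:
        try:
            gp = dataclasses.replace(cfg.gibbs_params, seed=stage_seeds["motif"])
            bundle.motif, assignment = gibbs_two_block(
                [seq for _, seq in flanks], gp)
            motif_to_frame(bundle.motif).to_csv(out / "motif_counts.tsv",
                                                sep="\t", index=False)
            record("motif", gp)
        except Exception as exc:
            raise StageError("motif", exc) from exc

    # ---- stage: candidates ------------------------------------------------
    if cfg.candidates is not None:
        bundle.candidates = (read_promoter_table(cfg.candidates)
                             if isinstance(cfg.candidates, (str, Path))
                             else list(cfg.candidates))
    elif bundle.peaks and genes:
        try:
            cands, orphans = candidate_promoters(
                bundle.peaks, contigs, genes, cfg.candidate_rule, bundle.motif)
            bundle.candidates = cands
            write_promoter_table(cands, out / "candidates.tsv")
            pd.DataFrame([{"contig": p.contig_id, "start": p.interval[0],
                           "end": p.interval[1]} for p in orphans]
                         ).to_csv(out / "orphan_peaks.tsv", sep="\t", index=False)
            record("candidates", cfg.candidate_rule)
        except Exception as exc:
            raise StageError("candidates", exc) from exc

    # ---- stage: PWM build (validated subset) ------------------------------
    try:
        if cfg.validated_promoters is None:
            validated = load_validated_promoters()
        elif isinstance(cfg.validated_promoters, (str, Path)):
            validated = read_promoter_table(cfg.validated_promoters)
        else:
            validated = list(cfg.validated_promoters)
        bundle.pwms = build_validated_pwms(validated)
        for pwm in bundle.pwms:
            write_pwm(pwm, out / f"{pwm.name}.tsv")
        record("pwm_build", {"n_promoters": len(validated)})
    except Exception as exc:
        raise StageError("pwm_build", exc) from exc

    # ---- stage: genome scan -----------------------------------------------
    if "scan" not in cfg.skip and contigs and genes:
        try:
            all_hits = []
            for gene in genes:
                region = extract_upstream(contigs, gene,
                                          cfg.scan_params.near_bp,
                                          cfg.scan_params.far_bp)
                all_hits.extend(scan_region(bundle.pwms, region,
                                            cfg.scan_params))
            bundle.scan_hits = hits_to_frame(all_hits)
            bundle.scan_hits.to_csv(out / "scan_hits.tsv", sep="\t", index=False)
            record("scan", cfg.scan_params)
        except Exception as exc:
            raise StageError("scan", exc) from exc

    # ---- stage: classification --------------------------------------------
    if "classify" not in cfg.skip and cfg.expression is not None:
        try:
            matrix = (read_expression_matrix(cfg.expression)
                      if isinstance(cfg.expression, (str, Path))
                      else cfg.expression)
            if isinstance(cfg.promoter_counts, (str, Path)):
                n_prom = read_promoter_counts(cfg.promoter_counts)
            else:
                n_prom = cfg.promoter_counts or {}
            classifications = classify_matrix(matrix, n_prom,
                                              cfg.class_thresholds)
            bundle.classification = dependence_report(
                classifications, out / "classification.tsv")
            record("classify", cfg.class_thresholds)
        except Exception as exc:
            raise StageError("classify", exc) from exc

    # ---- stage: conservation ----------------------------------------------
    if "conserve" not in cfg.skip and cfg.panel:
        try:
            # cfg.panel is (reference: SpeciesData, panel: list[SpeciesData])
            reference, panel = cfg.panel
            targets = sorted({c.target_id for c in bundle.candidates}) or \
                [g.gene_id for g in genes]
            bundle.conservation = conservation_matrix(
                targets, reference, panel, bundle.pwms,
                cfg.conservation_params)
            bundle.conservation.write(out / "conservation.tsv")
            bundle.conserved = conserved_targets(
                bundle.conservation, cfg.conservation_params.min_genomes)
            (out / "conserved_targets.txt").write_text(
                "\n".join(bundle.conserved) + "\n")
            record("conserve", cfg.conservation_params)
        except Exception as exc:
            raise StageError("conserve", exc) from exc

    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return bundle
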