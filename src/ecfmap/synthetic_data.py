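"""Seeded generators for genomes, ChIP tracks, expression courses and species
families with the statistical structure the pipeline assumes.

The generators emulate the data shapes of a Streptomyces-style regulon study:
a ~72% GC chromosome with two-block promoter sites planted 10-400 bp
upstream of start codons, ChIP coverage with localised enrichment over an
input control, WT vs deletion-mutant vancomycin-induction time courses with
full/partial/no dependence, and a family of related genomes in which
orthologous genes retain or lose the promoter site.  Every generator is
deterministic under a fixed seed, and each emits a truth table sufficient to
score the corresponding pipeline stage.

Site emission draws each block column independently from the emission PWM's
count frequencies and rejects draws that would not be detectable at default
scan settings: a planted site is by definition a consensus site (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_io import (Contig, GeneModel, reverse_complement,
                        write_fasta, write_gff)
from .motif_discovery import BASE_ORDER
from .peak_caller import CoverageTrack
from .promoter_model import (BLOCK10_LEN, BLOCK35_LEN, ScanParams, TwoBlockPWM,
                             build_validated_pwms)
from .conservation import Proteome, SpeciesData

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# stage tags decorrelate the random streams of the four generators
_TAG_GENOME, _TAG_CHIP, _TAG_EXPR, _TAG_FAMILY = 11, 23, 37, 53


@dataclass
class SimConfig:
    """Study-shaped simulation settings; ``seed`` is mandatory.

    Class mix fractions are the planted proportions of Class I / II / III
    target genes; the remainder are non-targets without sites.
    """

    seed: int
    gc_content: float = 0.72
    n_genes: int = 40
    gene_len: int = 300                      # multiple of 3
    intergenic_range: tuple[int, int] = (900, 1300)
    distance_range: tuple[int, int] = (10, 400)   # -10 3' end to start codon
    class_mix: dict = field(default_factory=lambda: {
        "I": 0.20, "II": 0.20, "III": 0.10})
    # ChIP
    chip_depth: float = 5.0
    chip_enrichment: float = 10.0
    chip_halfwidth: int = 150
    # expression
    expression_sigma: float = 0.3
    n_replicates: int = 2                    # replicate arrays combined per value
    wt_delta_range: tuple[float, float] = (2.0, 4.0)
    partial_factor_range: tuple[float, float] = (0.3, 0.7)
    class3_factor_range: tuple[float, float] = (0.4, 0.7)
    # species family
    n_species: int = 10
    substitution_rate: float = 0.05          # per site (aa for proteins)
    site_loss_prob: float = 0.2
    gene_loss_prob: float = 0.1
    # site emission / detection
    emission_pwm: TwoBlockPWM | None = None
    gap_probs: dict = field(default_factory=lambda: {16: 17 / 19, 17: 2 / 19})

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.gene_len % 3:
            raise ValueError("gene_len must be a multiple of 3")
        if sum(self.class_mix.values()) > 1 + 1e-9:
            raise ValueError("class mix fractions exceed 1")

    def resolve_pwms(self) -> tuple[TwoBlockPWM, TwoBlockPWM]:
        """Emission/detection PWM pair (defaults to the validated set)."""
        if self.emission_pwm is not None:
            return self.emission_pwm, self.emission_pwm
        from .genome_io import load_validated_promoters
        return build_validated_pwms(load_validated_promoters())


@dataclass
class GenomeTruth:
    contigs: list[Contig]
    genes: list[GeneModel]
    proteome: Proteome
    sites: pd.DataFrame    # one row per planted site
    classes: pd.DataFrame  # gene_id, class_label, n_promoters

    @property
    def species(self) -> SpeciesData:
        return SpeciesData("ref", self.contigs, self.genes, self.proteome)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
                      p=[at, gc / 2, gc / 2, at])


def _translate(dna: str) -> str:
    return str(Seq(dna).translate()).replace("*", "X")


def simulate_genome_with_sites(cfg: SimConfig,
                               rng: np.random.Generator | None = None
                               ) -> GenomeTruth:
    """One contig with alternating-strand genes and planted promoter sites.

    The background is i.i.d. mononucleotide at ``gc_content``; genes carry a
    start codon (ATG) and translate to the proteome.  For each target gene a
    site is drawn from the emission PWM, assigned a 16/17-bp gap, and written
    on the gene's sense strand at a drawn distance (-10 3' end to the first
    start-codon base).  With the default gene spacing, neighbouring upstream
    windows cannot collide; a drawn site that would not fit is resampled.
    """
    rng = rng or np.random.default_rng([_TAG_GENOME, cfg.seed])
    pwm16, pwm17 = cfg.resolve_pwms()
    gaps = sorted(cfg.gap_probs)
    gap_p = np.array([cfg.gap_probs[g] for g in gaps], dtype=float)
    gap_p = gap_p / gap_p.sum()

    # gene layout
    spans: list[tuple[int, int, str]] = []
    cursor = 0
    for i in range(cfg.n_genes):
        cursor += int(rng.integers(*cfg.intergenic_range))
        spans.append((cursor, cursor + cfg.gene_len, "+" if i % 2 == 0 else "-"))
        cursor += cfg.gene_len
    genome_len = cursor + int(rng.integers(*cfg.intergenic_range))
    seq = _random_dna(rng, genome_len, cfg.gc_content)

    classes = assign_classes(cfg, [f"g{i:03d}" for i in range(cfg.n_genes)], rng)
    label_of = dict(zip(classes.gene_id, classes.class_label))
    genes: list[GeneModel] = []
    site_rows = []
    for i, (lo, hi, strand) in enumerate(spans):
        gene_id = f"g{i:03d}"
        gene = GeneModel(gene_id, "chr", strand, (lo, hi))
        genes.append(gene)
        # start codon
        s = gene.start_codon_pos
        if strand == "+":
            seq[s:s + 3] = np.frombuffer(b"ATG", dtype=np.uint8)
        else:
            seq[s - 2:s + 1] = np.frombuffer(b"CAT", dtype=np.uint8)
        label = label_of[gene_id]
        if label == "none":
            continue
        m35, m10 = pwm16.sample_site(rng, detectable=True)
        gap = int(gaps[rng.choice(len(gaps), p=gap_p)])
        span = BLOCK35_LEN + gap + BLOCK10_LEN
        d = int(rng.integers(cfg.distance_range[0], cfg.distance_range[1] + 1))
        site_sense = m35 + _decode(_random_dna(rng, gap, cfg.gc_content)) + m10
        if strand == "+":
            g_lo, g_hi = s - d - span, s - d
            planted = site_sense
        else:
            g_lo, g_hi = s + d, s + d + span
            planted = reverse_complement(site_sense)
        if g_lo < 0 or g_hi > genome_len:
            raise RuntimeError("site does not fit; enlarge intergenic_range")
        seq[g_lo:g_hi] = np.frombuffer(planted.encode(), dtype=np.uint8)
        site_rows.append({
            "gene_id": gene_id, "contig": "chr", "strand": strand,
            "site_start": g_lo, "site_end": g_hi, "minus35": m35,
            "spacer_len": gap, "minus10": m10, "distance_bp": d,
            "class_label": label,
        })
    # guarantee the truth table: no chance consensus matches in any
    # gene's upstream screen window beyond the planted sites
    detection_pwms = (pwm16, pwm17)
    site_span = {r["gene_id"]: (r["site_start"], r["site_end"])
                 for r in site_rows}
    for gene in genes:
        _scrub_spurious_sites(seq, gene, site_span.get(gene.gene_id),
                              detection_pwms, rng, cfg.gc_content)
    contig = Contig("chr", seq.tobytes().decode())
    proteins, link = {}, {}
    for gene in genes:
        dna = contig.sequence[gene.span[0]:gene.span[1]]
        if gene.strand == "-":
            dna = reverse_complement(dna)
        pid = f"{gene.gene_id}_p"
        proteins[pid] = _translate(dna)
        link[pid] = gene.gene_id
    site_cols = ["gene_id", "contig", "strand", "site_start", "site_end",
                 "minus35", "spacer_len", "minus10", "distance_bp", "class_label"]
    return GenomeTruth(
        [contig], genes, Proteome("ref", proteins, link),
        pd.DataFrame(site_rows, columns=site_cols), classes)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _scrub_spurious_sites(seq: np.ndarray, gene: GeneModel,
                          protected: tuple[int, int] | None,
                          pwms, rng: np.random.Generator, gc: float,
                          far: int = 435, max_rounds: int = 10) -> None:
    """Re-randomise chance consensus matches in a gene's upstream window.

    The generators guarantee that a scanned upstream window contains a
    detectable site exactly where the truth table says so; frames of
    spurious scan hits (outside the ``protected`` planted span) have their
    scored positions redrawn from the background until the window is clean.
    """
    from .promoter_model import scan_sequence
    s = gene.start_codon_pos
    if gene.strand == "+":
        lo, hi = max(0, s - far), s
    else:
        lo, hi = s + 1, min(len(seq), s + 1 + far)
    if hi - lo < 26:
        return
    scan = ScanParams()
    for _ in range(max_rounds):
        sense = _decode(seq[lo:hi])
        if gene.strand == "-":
            sense = reverse_complement(sense)
        dirty: set[int] = set()
        for hit in scan_sequence(pwms, sense, scan):
            span = BLOCK35_LEN + hit.gap + BLOCK10_LEN
            offsets = list(range(hit.region_start, hit.region_start + BLOCK35_LEN)) \
                + list(range(hit.region_start + span - BLOCK10_LEN,
                             hit.region_start + span))
            for j in offsets:
                g = lo + j if gene.strand == "+" else hi - 1 - j
                if protected and protected[0] <= g < protected[1]:
                    continue
                dirty.add(g)
        if not dirty:
            return
        idx = np.fromiter(dirty, dtype=np.int64)
        seq[idx] = _random_dna(rng, len(idx), gc)


def simulate_chip(cfg: SimConfig, truth: GenomeTruth,
                  rng: np.random.Generator | None = None
                  ) -> tuple[CoverageTrack, CoverageTrack]:
    """ChIP and input-control tracks.

    The control is Poisson at ``chip_depth`` per base.  The ChIP rate rises
    over a triangular profile of half-width ``chip_halfwidth`` centred on
    each planted site, peaking at ``chip_depth * chip_enrichment`` — the
    unimodal pile-up of fragments around a bound site, which localises the
    summit window at the site.  Profiles of nearby sites merge additively
    into one coverage bump.
    """
    rng = rng or np.random.default_rng([_TAG_CHIP, cfg.seed])
    n = len(truth.contigs[0])
    rate = np.full(n, cfg.chip_depth)
    for _, row in truth.sites.iterrows():
        center = (int(row.site_start) + int(row.site_end)) // 2
        lo = max(0, center - cfg.chip_halfwidth)
        hi = min(n, center + cfg.chip_halfwidth)
        x = np.arange(lo, hi)
        bump = (cfg.chip_enrichment - 1.0) * (
            1.0 - np.abs(x - center) / cfg.chip_halfwidth)
        rate[lo:hi] += cfg.chip_depth * bump
    chip = CoverageTrack("chr", rng.poisson(rate))
    control = CoverageTrack("chr", rng.poisson(np.full(n, cfg.chip_depth)))
    return chip, control


def assign_classes(cfg: SimConfig, gene_ids: Sequence[str],
                   rng: np.random.Generator) -> pd.DataFrame:
    """Draw a class label (I/II/III/none) and promoter count per gene."""
    labels = list(cfg.class_mix) + ["none"]
    probs = list(cfg.class_mix.values())
    probs.append(1.0 - sum(probs))
    rows = []
    for gene_id in gene_ids:
        label = labels[rng.choice(len(labels), p=probs)]
        n_prom = int(rng.integers(2, 5)) if label == "III" else 1
        rows.append({"gene_id": gene_id, "class_label": label,
                     "n_promoters": n_prom})
    return pd.DataFrame(rows, columns=["gene_id", "class_label", "n_promoters"])


def simulate_expression(cfg: SimConfig, truth: GenomeTruth | pd.DataFrame,
                        rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Replicate-combined log2 expression matrix for WT and mutant strains.

    Each gene gets a Normal(0,1) baseline.  Induced genes rise by a step
    delta after t = 0: Class I in WT only; Class II/III in both strains with
    the mutant delta scaled by a partial-dependence factor.  Per-replicate
    Gaussian noise (sd ``expression_sigma``) is averaged over
    ``n_replicates`` arrays per reported value, mirroring the replicate-
    combination step of microarray processing.
    """
    rng = rng or np.random.default_rng([_TAG_EXPR, cfg.seed])
    classes = truth.classes if isinstance(truth, GenomeTruth) else truth
    times = (0, 30, 60, 90)
    cols = [f"WT_{t}" for t in times] + [f"dsigE_{t}" for t in times]
    rows = {}
    for _, g in classes.iterrows():
        baseline = rng.normal(0.0, 1.0)
        wt_delta = mut_delta = 0.0
        if g.class_label in ("I", "II", "III"):
            wt_delta = rng.uniform(*cfg.wt_delta_range)
            if g.class_label == "II":
                mut_delta = wt_delta * rng.uniform(*cfg.partial_factor_range)
            elif g.class_label == "III":
                mut_delta = wt_delta * rng.uniform(*cfg.class3_factor_range)
        values = []
        for delta in (wt_delta, mut_delta):
            for t in times:
                signal = baseline + (delta if t > 0 else 0.0)
                noise = rng.normal(0.0, cfg.expression_sigma,
                                   size=cfg.n_replicates).mean() \
                    if cfg.expression_sigma > 0 else 0.0
                values.append(signal + noise)
        rows[g.gene_id] = values
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    idx = np.flatnonzero(mask)
    aa = np.frombuffer(AA20.encode(), dtype=np.uint8)
    arr[idx] = aa[rng.integers(0, 20, size=len(idx))]
    return arr.tobytes().decode()


def simulate_species_family(cfg: SimConfig, truth: GenomeTruth,
                            rng: np.random.Generator | None = None
                            ) -> tuple[list[SpeciesData], pd.DataFrame]:
    """Derive a panel of related genomes from the reference.

    Per species and target gene: with ``gene_loss_prob`` the gene is deleted
    (dropped from annotation and proteome, its span and site randomised);
    otherwise with ``site_loss_prob`` the planted site is randomised to
    background (resampled until it no longer scores as a site in its own
    frame).  Retained sites are preserved exactly; all other positions
    mutate at ``substitution_rate`` (DNA), and proteins mutate independently
    at the same rate per residue, keeping orthology detectable.
    """
    rng = rng or np.random.default_rng([_TAG_FAMILY, cfg.seed])
    pwm16, pwm17 = cfg.resolve_pwms()
    scan = ScanParams()
    ref_seq = np.frombuffer(truth.contigs[0].sequence.encode(),
                            dtype=np.uint8).copy()
    site_by_gene = {r.gene_id: r for _, r in truth.sites.iterrows()}
    target_genes = list(truth.sites["gene_id"])
    panel: list[SpeciesData] = []
    truth_rows = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for k in range(cfg.n_species):
        sid = f"sp{k + 1:02d}"
        seq = ref_seq.copy()
        gene_lost = {g: rng.random() < cfg.gene_loss_prob for g in target_genes}
        site_lost = {g: (not gene_lost[g]) and rng.random() < cfg.site_loss_prob
                     for g in target_genes}
        protected = np.zeros(len(seq), dtype=bool)
        for g in target_genes:
            row = site_by_gene[g]
            if not gene_lost[g] and not site_lost[g]:
                protected[int(row.site_start):int(row.site_end)] = True
        # background substitution outside retained sites
        mut_mask = (np.asarray(rng.random(len(seq)) < cfg.substitution_rate)
                    & ~protected)
        idx = np.flatnonzero(mut_mask)
        seq[idx] = bases[rng.integers(0, 4, size=len(idx))]
        # destroy lost sites / lost genes
        for g in target_genes:
            row = site_by_gene[g]
            lo, hi = int(row.site_start), int(row.site_end)
            if gene_lost[g]:
                gene = next(x for x in truth.genes if x.gene_id == g)
                glo, ghi = gene.span
                seq[glo:ghi] = _random_dna(rng, ghi - glo, cfg.gc_content)
                seq[lo:hi] = _random_dna(rng, hi - lo, cfg.gc_content)
            elif site_lost[g]:
                seq[lo:hi] = _scrubbed_site(rng, hi - lo, cfg, (pwm16, pwm17),
                                            scan, row.strand)
        # keep grey cells honest: substitutions (or site loss) must not leave
        # a chance consensus match in a surviving target's scan window
        gene_models = {g.gene_id: g for g in truth.genes}
        for g in target_genes:
            if gene_lost[g]:
                continue
            row = site_by_gene[g]
            prot = (None if site_lost[g]
                    else (int(row.site_start), int(row.site_end)))
            _scrub_spurious_sites(seq, gene_models[g], prot,
                                  (pwm16, pwm17), rng, cfg.gc_content, far=235)
        genes = [g for g in truth.genes
                 if not gene_lost.get(g.gene_id, False)]
        proteins, link = {}, {}
        for pid, pseq in truth.proteome.proteins.items():
            gid = truth.proteome.gene_link[pid]
            if gene_lost.get(gid, False):
                continue
            proteins[pid] = _mutate_protein(pseq, cfg.substitution_rate, rng)
            link[pid] = gid
        panel.append(SpeciesData(
            sid, [Contig("chr", seq.tobytes().decode())], list(genes),
            Proteome(sid, proteins, link)))
        for g in target_genes:
            truth_rows.append({
                "species": sid, "gene_id": g,
                "ortholog_retained": not gene_lost[g],
                "site_retained": not gene_lost[g] and not site_lost[g],
            })
    return panel, pd.DataFrame(
        truth_rows, columns=["species", "gene_id",
                             "ortholog_retained", "site_retained"])


def _scrubbed_site(rng: np.random.Generator, length: int, cfg: SimConfig,
                   pwms, scan: ScanParams, strand: str,
                   max_tries: int = 50) -> np.ndarray:
    """Random replacement for a lost site that does not itself score as one."""
    for _ in range(max_tries):
        repl = _random_dna(rng, length, cfg.gc_content)
        sense = _decode(repl)
        if strand == "-":
            sense = reverse_complement(sense)
        m35 = sense[:BLOCK35_LEN]
        m10 = sense[-BLOCK10_LEN:]
        hit = False
        for pwm in pwms:
            full_thr, core_thr = pwm.thresholds(scan)
            _, norm, core = pwm.score_blocks(m35, m10)
            if norm >= full_thr and core >= core_thr:
                hit = True
                break
        if not hit:
            return repl
    return repl  # vanishingly unlikely; keep the last draw


# ---------------------------------------------------------------------------
# file emission (CLI convenience)

def write_dataset(truth: GenomeTruth, outdir: str | Path,
                  chip: tuple[CoverageTrack, CoverageTrack] | None = None,
                  expression: pd.DataFrame | None = None) -> None:
    from .peak_caller import write_coverage
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.contigs, outdir / "genome.fa")
    write_gff(truth.genes, outdir / "genes.gff3")
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.classes.to_csv(outdir / "truth_classes.tsv", sep="\t", index=False)
    with open(outdir / "proteome.faa", "w") as fh:
        for pid, seq in truth.proteome.proteins.items():
            fh.write(f">{pid} gene={truth.proteome.gene_link[pid]}\n{seq}\n")
    if chip is not None:
        write_coverage(chip[0], outdir / "chip.bedgraph")
        write_coverage(chip[1], outdir / "control.bedgraph")
    if expression is not None:
        expression.to_csv(outdir / "expression.tsv", sep="\t",
                          index_label="gene_id")
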