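"""Cross-genome conservation of target promoters.

For each reference target gene and each genome of a species panel: find the
ortholog by reciprocal best hit (RBH) of protein sequences under an
affine-gap local alignment with BLOSUM62 scoring (the desk-scale stand-in
for a BlastP search); then scan the ortholog's 10-200 bp upstream window
with the promoter PWMs.  The result is a targets x species matrix whose
cells are "absent" (no ortholog), "no_site" (ortholog without a detectable
site) or the best hit's normalised score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Contig, GeneModel, extract_upstream
from .promoter_model import ScanParams, TwoBlockPWM, scan_region

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

ABSENT = "absent"
NO_SITE = "no_site"
SITE = "site"


@dataclass
class Proteome:
    species_id: str
    proteins: dict[str, str]                    # protein id -> aa sequence
    gene_link: dict[str, str] = field(default_factory=dict)  # protein id -> gene id

    def __post_init__(self) -> None:
        for pid, seq in self.proteins.items():
            if not seq:
                raise ValueError(f"{self.species_id}/{pid}: empty protein")
            bad = set(seq) - AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"{self.species_id}/{pid}: non-amino-acid characters {sorted(bad)}")


@dataclass
class SpeciesData:
    """One panel genome: sequence, annotation and proteome."""

    species_id: str
    contigs: list[Contig]
    genes: list[GeneModel]
    proteome: Proteome

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"{self.species_id}: unknown gene {gene_id!r}")


@dataclass(frozen=True)
class ConservationParams:
    min_identity: float = 30.0     # percent
    min_coverage: float = 50.0     # percent
    near_bp: int = 10
    far_bp: int = 200
    min_genomes: int = 9
    panel_size: int = 19

    def __post_init__(self) -> None:
        if not 0 < self.min_genomes <= self.panel_size:
            raise ValueError("need 0 < min_genomes <= panel_size")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_protein(a: str, b: str,
                  aligner: Align.PairwiseAligner | None = None
                  ) -> tuple[float, float, float]:
    """Local affine-gap alignment of two proteins.

    Returns (identity %, coverage %, score) where identity is matches over
    aligned columns (gap columns included) and coverage is the aligned span
    of the shorter sequence over its length.
    """
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"sequence {name}: non-amino-acid characters {sorted(bad)}")
    aligner = aligner or _aligner()
    alignments = aligner.align(a, b)
    if len(alignments) == 0:
        return 0.0, 0.0, 0.0
    aln = alignments[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    aligned_res = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_res += a1 - a0
        matches += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    # columns = matched residues plus internal gap columns
    columns = aligned_res + (span_a - aligned_res) + (span_b - aligned_res)
    identity = 100.0 * matches / columns if columns else 0.0
    short_len = min(len(a), len(b))
    coverage = 100.0 * min(span_a, span_b) / short_len
    return identity, coverage, float(aln.score)


@dataclass
class OrthologPair:
    ref_protein: str
    other_protein: str
    identity: float
    coverage: float
    score: float


def _best_hits(queries: Mapping[str, str], subjects: Mapping[str, str],
               aligner: Align.PairwiseAligner) -> dict[str, str]:
    """Best-scoring subject per query; ties by higher identity then id."""
    best: dict[str, str] = {}
    for qid, qseq in queries.items():
        scores = {sid: aligner.score(qseq, sseq) for sid, sseq in subjects.items()}
        top = max(scores.values())
        tied = sorted(sid for sid, sc in scores.items() if sc == top)
        if len(tied) > 1:
            tied.sort(key=lambda sid: (-align_protein(qseq, subjects[sid],
                                                      aligner)[0], sid))
        best[qid] = tied[0]
    return best


def rbh_orthologs(reference: Proteome, other: Proteome,
                  params: ConservationParams = ConservationParams()
                  ) -> dict[str, OrthologPair]:
    """Reciprocal-best-hit ortholog pairs passing identity/coverage thresholds.

    Keyed by reference protein id; absence from the mapping is a value
    (the gene has no ortholog in ``other``).
    """
    if not reference.proteins or not other.proteins:
        raise ValueError("both proteomes must be non-empty")
    aligner = _aligner()
    fwd = _best_hits(reference.proteins, other.proteins, aligner)
    rev = _best_hits(other.proteins, reference.proteins, aligner)
    pairs: dict[str, OrthologPair] = {}
    for rid, oid in fwd.items():
        if rev.get(oid) != rid:
            continue
        identity, coverage, score = align_protein(
            reference.proteins[rid], other.proteins[oid], aligner)
        if identity >= params.min_identity and coverage >= params.min_coverage:
            pairs[rid] = OrthologPair(rid, oid, identity, coverage, score)
    return pairs


@dataclass
class ConservationMatrix:
    """Targets x species grid of {absent, no_site, site(score)} cells."""

    states: pd.DataFrame   # str cells
    scores: pd.DataFrame   # float cells, NaN where no site

    def site_counts(self) -> pd.Series:
        return (self.states == SITE).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Cell codes: 'absent', 'no_site' or the score as a decimal string."""
        out = self.states.copy().astype(object)
        for t in out.index:
            for s in out.columns:
                if out.loc[t, s] == SITE:
                    out.loc[t, s] = f"{self.scores.loc[t, s]:.4f}"
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.states.index:
            for s in self.states.columns:
                rows.append({"target": t, "species": s,
                             "state": self.states.loc[t, s],
                             "score": self.scores.loc[t, s]})
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="target")


def conservation_matrix(targets: Sequence[str], reference: SpeciesData,
                        panel: Sequence[SpeciesData],
                        pwms: Sequence[TwoBlockPWM],
                        params: ConservationParams = ConservationParams(),
                        orthologs: Mapping[str, Mapping[str, str]] | None = None,
                        ) -> ConservationMatrix:
    """Assemble the conservation grid for reference ``targets`` over a panel.

    ``orthologs`` may supply a precomputed {species_id: {ref gene -> ortholog
    gene}} mapping (e.g. from an external BlastP run), bypassing the internal
    RBH search.
    """
    scan = ScanParams(near_bp=params.near_bp, far_bp=params.far_bp)
    ref_gene_to_protein = {g: p for p, g in reference.proteome.gene_link.items()}
    species_ids = [sp.species_id for sp in panel]
    states = pd.DataFrame(ABSENT, index=list(targets), columns=species_ids)
    scores = pd.DataFrame(np.nan, index=list(targets), columns=species_ids)
    for sp in panel:
        contig_ids = {c.id for c in sp.contigs}
        if any(g.contig_id not in contig_ids for g in sp.genes):
            raise ValueError(
                f"species {sp.species_id}: annotation refers to unknown contigs")
        if orthologs is not None:
            gene_map = dict(orthologs.get(sp.species_id, {}))
        else:
            pairs = rbh_orthologs(reference.proteome, sp.proteome, params)
            gene_map = {
                reference.proteome.gene_link.get(rid, rid):
                    sp.proteome.gene_link.get(pair.other_protein, pair.other_protein)
                for rid, pair in pairs.items()}
        for target in targets:
            ortho_gene = gene_map.get(target)
            if ortho_gene is None:
                continue
            region = extract_upstream(sp.contigs, sp.gene_by_id(ortho_gene),
                                      params.near_bp, params.far_bp)
            hits = scan_region(pwms, region, scan)
            if hits:
                states.loc[target, sp.species_id] = SITE
                scores.loc[target, sp.species_id] = hits[0].normalized_score
            else:
                states.loc[target, sp.species_id] = NO_SITE
    return ConservationMatrix(states, scores)


def conserved_targets(matrix: ConservationMatrix, min_genomes: int) -> list[str]:
    """Targets with a detected site in at least ``min_genomes`` genomes,
    sorted by site count (descending) then target id."""
    counts = matrix.site_counts()
    keep = counts[counts >= min_genomes]
    return sorted(keep.index, key=lambda t: (-int(counts[t]), t))
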