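"""Readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  GFF3 files are read
and written in their native 1-based inclusive dialect; BED-like tables stay
0-based half-open.  Upstream regions are always reported on the gene's sense
strand, 5'->3' toward the start codon, so downstream motif scanning is a
forward-strand operation regardless of genomic strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
#: IUPAC ambiguity codes other than N (may be mapped to N on request)
IUPAC_AMBIGUOUS = set("RYSWKMBDHV")

PROMOTER_COLUMNS = [
    "target_id", "minus35", "spacer", "minus10",
    "distance_bp", "validated", "promoter_class",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Contig:
    """A chromosome/contig: uppercase DNA over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"contig {self.id!r} has empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.id!r} contains non-DNA characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene/CDS with its start-codon coordinate.

    ``span`` is 0-based half-open.  On the + strand the start codon is the
    first base of the span; on the - strand it is the last base.
    """

    gene_id: str
    contig_id: str
    strand: str
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.span[1] <= self.span[0] or self.span[0] < 0:
            raise ValueError(f"gene {self.gene_id!r}: invalid span {self.span}")

    @property
    def start_codon_pos(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1] - 1


@dataclass(frozen=True)
class PromoterEntry:
    """A two-block promoter instance: -35 tetramer, 16/17-bp spacer, -10 pentamer.

    ``distance_bp`` counts the bases between the 3' end of the -10 element and
    the first base of the start codon of the target gene.
    """

    target_id: str
    minus35: str
    spacer: str
    minus10: str
    distance_bp: int
    validated: bool = False
    promoter_class: str = "unassigned"

    def __post_init__(self) -> None:
        if len(self.minus35) != 4:
            raise FormatError(f"{self.target_id}: -35 element must be 4 bp")
        if len(self.minus10) != 5:
            raise FormatError(f"{self.target_id}: -10 element must be 5 bp")
        if len(self.spacer) not in (16, 17):
            raise FormatError(
                f"{self.target_id}: spacer length {len(self.spacer)} not in {{16,17}}")
        if self.distance_bp < 0:
            raise FormatError(f"{self.target_id}: negative distance_bp")
        for block in (self.minus35, self.spacer, self.minus10):
            bad = set(block) - DNA_ALPHABET
            if bad:
                raise FormatError(f"{self.target_id}: non-DNA characters {sorted(bad)}")
        if self.promoter_class not in ("I", "II", "III", "unassigned"):
            raise FormatError(
                f"{self.target_id}: unknown promoter class {self.promoter_class!r}")

    @property
    def sequence(self) -> str:
        """-35 + spacer + -10 as a single string (gene sense strand)."""
        return self.minus35 + self.spacer + self.minus10

    @property
    def spacer_len(self) -> int:
        return len(self.spacer)


@dataclass
class UpstreamRegion:
    """An upstream window on the gene's sense strand, 5'->3' toward the start codon.

    ``near_bp``/``far_bp`` record the requested window (bp upstream of the
    start codon); clipping at contig ends shortens the far side.  The region
    index ``j`` maps to the genomic coordinate ``genomic(j)``.
    """

    gene_id: str
    contig_id: str
    strand: str
    sequence: str
    near_bp: int
    far_bp: int
    genomic_interval: tuple[int, int]  # 0-based half-open, reference strand

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_empty(self) -> bool:
        return len(self.sequence) == 0

    def genomic(self, pos: int) -> int:
        """Genomic (reference-strand) coordinate of region position ``pos``."""
        if not 0 <= pos < len(self.sequence):
            raise IndexError(pos)
        lo, hi = self.genomic_interval
        return lo + pos if self.strand == "+" else hi - 1 - pos

    def distance_to_start(self, pos: int) -> int:
        """bp between region position ``pos`` and the first start-codon base."""
        return self.near_bp + (len(self.sequence) - 1 - pos)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, ambiguous: str = "error") -> list[Contig]:
    """Read a DNA FASTA into a list of :class:`Contig` (file order).

    Parameters
    ----------
    ambiguous:
        ``"error"`` rejects IUPAC ambiguity codes other than N;
        ``"n"`` maps them to N.
    """
    if ambiguous not in ("error", "n"):
        raise ValueError("ambiguous must be 'error' or 'n'")
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        extra = set(seq) - DNA_ALPHABET
        if extra:
            if ambiguous == "n" and extra <= IUPAC_AMBIGUOUS:
                seq = "".join("N" if c in IUPAC_AMBIGUOUS else c for c in seq)
            else:
                raise FormatError(
                    f"record {rec.id!r}: unexpected characters {sorted(extra)}")
        contigs.append(Contig(rec.id, seq))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff(path: str | Path,
             feature_types: Sequence[str] = ("gene", "CDS"),
             contigs: Sequence[Contig] | None = None) -> list[GeneModel]:
    """Read gene/CDS features from a GFF3 file.

    1-based inclusive GFF coordinates become 0-based half-open spans.  When
    ``contigs`` is given, features beyond contig bounds raise an error.
    """
    lengths = {c.id: len(c) for c in contigs} if contigs else {}
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in feature_types:
                continue
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if "ID" not in attributes:
                raise FormatError(f"{path}:{lineno}: feature lacks an ID attribute")
            span = (int(start) - 1, int(end))
            if seqid in lengths and span[1] > lengths[seqid]:
                raise FormatError(
                    f"{path}:{lineno}: feature {attributes['ID']!r} beyond "
                    f"contig {seqid!r} bounds")
            genes.append(GeneModel(attributes["ID"], seqid, strand, span))
    return genes


def write_gff(genes: Iterable[GeneModel], path: str | Path,
              feature_type: str = "gene", source: str = "ecfmap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                g.contig_id, source, feature_type,
                str(g.span[0] + 1), str(g.span[1]),
                ".", g.strand, ".", f"ID={g.gene_id}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Upstream windows

def extract_upstream(contigs: Sequence[Contig], gene: GeneModel,
                     near: int, far: int) -> UpstreamRegion:
    """Extract the [near, far) bp upstream window of a gene, sense strand.

    For a + strand gene with start codon at ``s`` this is the genomic interval
    ``[s - far, s - near)``; for a - strand gene the mirror interval
    ``[s + near, s + far)`` reverse-complemented.  Windows running off the
    contig are clipped (with a logged warning); a window entirely off-contig
    yields an empty region rather than an exception.
    """
    if near >= far:
        raise ValueError("need near < far")
    by_id = {c.id: c for c in contigs}
    if gene.contig_id not in by_id:
        raise KeyError(f"unknown contig {gene.contig_id!r} for gene {gene.gene_id!r}")
    contig = by_id[gene.contig_id]
    s = gene.start_codon_pos
    if gene.strand == "+":
        lo, hi = s - far, s - near
    else:
        lo, hi = s + near, s + far
    clipped_lo, clipped_hi = max(lo, 0), min(hi, len(contig))
    far_eff = far
    if clipped_lo >= clipped_hi:
        logger.warning("upstream window of %s entirely off contig %s",
                       gene.gene_id, contig.id)
        return UpstreamRegion(gene.gene_id, contig.id, gene.strand, "",
                              near, near, (max(clipped_lo, 0), max(clipped_lo, 0)))
    if (clipped_lo, clipped_hi) != (lo, hi):
        far_eff = near + (clipped_hi - clipped_lo)
        logger.warning("upstream window of %s clipped to %d bp at contig edge",
                       gene.gene_id, clipped_hi - clipped_lo)
    seq = contig.sequence[clipped_lo:clipped_hi]
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return UpstreamRegion(gene.gene_id, contig.id, gene.strand, seq,
                          near, far_eff, (clipped_lo, clipped_hi))


# ---------------------------------------------------------------------------
# Promoter tables

def _entries_from_frame(df: pd.DataFrame, origin: str) -> list[PromoterEntry]:
    missing = set(PROMOTER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{origin}: missing columns {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(PromoterEntry(
                target_id=str(row["target_id"]),
                minus35=str(row["minus35"]).upper(),
                spacer=str(row["spacer"]).upper(),
                minus10=str(row["minus10"]).upper(),
                distance_bp=int(row["distance_bp"]),
                validated=str(row["validated"]).strip().lower() in ("true", "1", "yes"),
                promoter_class=str(row["promoter_class"]),
            ))
        except FormatError as exc:
            raise FormatError(f"{origin}: row {i} ({row['target_id']}): {exc}") from exc
    return entries


def read_promoter_table(path: str | Path) -> list[PromoterEntry]:
    """Read a TSV promoter table; every row is validated against the invariants."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _entries_from_frame(df, str(path))


def write_promoter_table(entries: Iterable[PromoterEntry], path: str | Path) -> None:
    rows = [{
        "target_id": e.target_id, "minus35": e.minus35, "spacer": e.spacer,
        "minus10": e.minus10, "distance_bp": e.distance_bp,
        "validated": "true" if e.validated else "false",
        "promoter_class": e.promoter_class,
    } for e in entries]
    pd.DataFrame(rows, columns=PROMOTER_COLUMNS).to_csv(path, sep="\t", index=False)


def _packaged(name: str) -> list[PromoterEntry]:
    with resources.as_file(resources.files("ecfmap.data").joinpath(name)) as p:
        return read_promoter_table(p)


def load_table1() -> list[PromoterEntry]:
    """The packaged table of 91 predicted sigma-E target promoters."""
    return _packaged("table1_promoters.tsv")


def load_validated_promoters() -> list[PromoterEntry]:
    """The 19 experimentally validated sigma-E promoters (with class labels)."""
    return _packaged("validated_promoters.tsv")
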