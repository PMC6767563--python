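"""Two-block promoter PWMs: construction, scoring, scanning and candidate calls.

A :class:`TwoBlockPWM` holds probability matrices for the -35 tetramer and
-10 pentamer only; spacer columns are score-neutral.  That makes the spacer
normalisation exact: a promoter with a 17-bp spacer contributes the same
block counts to the 16-spacer matrix as to the 17-spacer one, so the two
matrices differ only in the gap they are scanned with.

Scoring is summed log2 odds against a mononucleotide background, reported
both raw and min-max normalised to [0, 1].  Scan thresholds are calibrated
on the PWM's own training sites: a sensitivity of ``s`` sets the threshold
to the score quantile at which a fraction ``s`` of the training promoters is
still detected, so at the default sensitivity of 1 every training promoter
is recovered by construction.  The "core" is the six most informative
columns; the core threshold is calibrated the same way at core sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, Contig, PromoterEntry, UpstreamRegion, extract_upstream
from .motif_discovery import (BASE_ORDER, TwoBlockMotif, encode, gc_background)

STREPTOMYCES_BACKGROUND = gc_background(0.72)
BLOCK35_LEN = 4
BLOCK10_LEN = 5
N_COLUMNS = BLOCK35_LEN + BLOCK10_LEN


@dataclass(frozen=True)
class ScanParams:
    """Scan dials.  Sensitivity values are fractions of training sites detected."""

    sensitivity: float = 1.0
    core_sensitivity: float = 1.0
    core_size: int = 6
    near_bp: int = 10
    far_bp: int = 200

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.core_sensitivity <= 1):
            raise ValueError("sensitivities must lie in [0, 1]")


@dataclass
class SiteHit:
    gene_id: str
    pwm_name: str
    region_start: int          # offset of the -35 block within the region
    genomic_start: int | None  # reference-strand coordinate, None for bare sequences
    gap: int
    raw_score: float
    normalized_score: float
    core_score: float
    distance_bp: int | None


@dataclass(frozen=True)
class CandidateRule:
    """Regex-style prefilter formalising conservation of "AAC" (-35) and "TC" (-10).

    ``minus35_core`` must match at ``minus35_offset`` with at most
    ``minus35_max_mismatch`` mismatches; ``minus10_core`` must match at one of
    ``minus10_offsets`` with at most ``minus10_max_mismatch`` mismatches.
    """

    minus35_core: str = "AAC"
    minus35_offset: int = 0
    minus35_max_mismatch: int = 1
    minus10_core: str = "TC"
    minus10_offsets: tuple[int, ...] = (2, 3)
    minus10_max_mismatch: int = 1
    max_distance_bp: int = 400

    def matches(self, minus35: str, minus10: str) -> bool:
        o = self.minus35_offset
        m35 = sum(a != b for a, b in
                  zip(minus35[o:o + len(self.minus35_core)], self.minus35_core))
        if m35 > self.minus35_max_mismatch:
            return False
        for off in self.minus10_offsets:
            mm = sum(a != b for a, b in
                     zip(minus10[off:off + len(self.minus10_core)], self.minus10_core))
            if mm <= self.minus10_max_mismatch:
                return True
        return False


@dataclass
class TwoBlockPWM:
    """Paired -35/-10 probability matrices with a fixed scan spacer length."""

    name: str
    counts35: np.ndarray          # 4 x 4 raw counts (no pseudocount)
    counts10: np.ndarray          # 4 x 5
    spacer_len: int
    pseudocount: float
    background: np.ndarray
    core_positions: tuple[int, ...]       # indices into the 9 scored columns
    training_scores: np.ndarray           # normalised full score per training site
    training_core_scores: np.ndarray      # normalised core score per training site

    # --- derived tables -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return int(round(self.counts35[:, 0].sum()))

    @property
    def probs(self) -> np.ndarray:
        """4 x 9 probability matrix over the scored columns."""
        counts = np.hstack([self.counts35, self.counts10])
        n = counts.sum(axis=0)
        return (counts + self.pseudocount) / (n + 4 * self.pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        """5 x 9 log2-odds table; 5th row scores N at background (zero)."""
        with np.errstate(divide="ignore"):
            lod = np.log2(self.probs / self.background[:, None])
        return np.vstack([lod, np.zeros(N_COLUMNS)])

    @property
    def span(self) -> int:
        return BLOCK35_LEN + self.spacer_len + BLOCK10_LEN

    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in self.probs.argmax(axis=0))

    def max_scoring_blocks(self) -> tuple[str, str]:
        """The block pair attaining normalised score 1 (per-column best odds)."""
        best = self.log_odds[:4].argmax(axis=0)
        return ("".join(BASE_ORDER[i] for i in best[:BLOCK35_LEN]),
                "".join(BASE_ORDER[i] for i in best[BLOCK35_LEN:]))

    def min_scoring_blocks(self) -> tuple[str, str]:
        """The anti-consensus block pair attaining normalised score 0."""
        worst = self.log_odds[:4].argmin(axis=0)
        return ("".join(BASE_ORDER[i] for i in worst[:BLOCK35_LEN]),
                "".join(BASE_ORDER[i] for i in worst[BLOCK35_LEN:]))

    def information_content(self) -> np.ndarray:
        """Per-column KL divergence from background, bits."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / self.background[:, None]), 0.0)
        return terms.sum(axis=0)

    # --- scoring ------------------------------------------------------------
    def _column_scores(self, seq9: np.ndarray) -> np.ndarray:
        return self.log_odds[seq9, np.arange(N_COLUMNS)]

    def score_blocks(self, minus35: str, minus10: str) -> tuple[float, float, float]:
        """(raw, normalised, normalised core) score of a block pair."""
        if len(minus35) != BLOCK35_LEN or len(minus10) != BLOCK10_LEN:
            raise ValueError("block lengths must match the PWM widths (4 and 5)")
        seq9 = np.concatenate([encode(minus35), encode(minus10)])
        cols = self._column_scores(seq9)
        raw = float(cols.sum())
        return raw, self._normalize(raw), self._normalize_core(
            float(cols[list(self.core_positions)].sum()))

    def _bounds(self, positions: Sequence[int]) -> tuple[float, float]:
        lod = self.log_odds[:4]
        return (float(lod.min(axis=0)[list(positions)].sum()),
                float(lod.max(axis=0)[list(positions)].sum()))

    def _normalize(self, raw: float) -> float:
        lo, hi = self._bounds(range(N_COLUMNS))
        return (raw - lo) / (hi - lo)

    def _normalize_core(self, raw_core: float) -> float:
        lo, hi = self._bounds(self.core_positions)
        return (raw_core - lo) / (hi - lo)

    # --- calibrated thresholds ----------------------------------------------
    @staticmethod
    def _quantile_threshold(scores: np.ndarray, sensitivity: float) -> float:
        """Largest threshold keeping at least ``sensitivity`` of training sites."""
        if sensitivity <= 0:
            return -np.inf
        k = int(np.ceil(sensitivity * len(scores)))
        return float(np.sort(scores)[::-1][k - 1])

    def thresholds(self, params: ScanParams) -> tuple[float, float]:
        return (self._quantile_threshold(self.training_scores, params.sensitivity),
                self._quantile_threshold(self.training_core_scores,
                                         params.core_sensitivity))

    # --- site emission (synthetic data) --------------------------------------
    def sample_site(self, rng: np.random.Generator,
                    detectable: bool = True, max_tries: int = 200) -> tuple[str, str]:
        """Draw a (-35, -10) block pair column-wise from the count frequencies.

        With ``detectable`` the draw is rejection-sampled until it would be
        detected at default scan settings (scores at least those of the
        weakest training promoter) — a planted site is by definition a
        consensus site.
        """
        freqs = np.hstack([self.counts35, self.counts10])
        freqs = freqs / freqs.sum(axis=0)
        full_thr = float(self.training_scores.min())
        core_thr = float(self.training_core_scores.min())
        for _ in range(max_tries):
            cols = [rng.choice(4, p=freqs[:, j]) for j in range(N_COLUMNS)]
            m35 = "".join(BASE_ORDER[i] for i in cols[:BLOCK35_LEN])
            m10 = "".join(BASE_ORDER[i] for i in cols[BLOCK35_LEN:])
            if not detectable:
                return m35, m10
            _, norm, core = self.score_blocks(m35, m10)
            if norm >= full_thr and core >= core_thr:
                return m35, m10
        raise RuntimeError("failed to sample a detectable site")


def build_pwm(promoters: Sequence[PromoterEntry], spacer_len: int,
              pseudocount: float = 0.5,
              background: np.ndarray = STREPTOMYCES_BACKGROUND,
              core_size: int = 6, name: str | None = None) -> TwoBlockPWM:
    """Build a spacer-normalised two-block PWM from validated promoters.

    Every promoter contributes its -35 and -10 blocks regardless of its own
    spacer length (spacer columns carry no probabilities, so moving a
    promoter between the 16- and 17-spacer matrices is exact).  Core
    positions are the ``core_size`` highest-information columns, ties broken
    5'-first.
    """
    if not promoters:
        raise ValueError("empty promoter list")
    if spacer_len not in (16, 17):
        raise ValueError("spacer_len must be 16 or 17")
    for p in promoters:
        if p.spacer_len not in (16, 17):
            raise ValueError(f"{p.target_id}: spacer length {p.spacer_len}")
    counts35 = np.zeros((4, BLOCK35_LEN))
    counts10 = np.zeros((4, BLOCK10_LEN))
    for p in promoters:
        for j, b in enumerate(encode(p.minus35)):
            if b >= 4:
                raise ValueError(f"{p.target_id}: ambiguous base in -35 block")
            counts35[b, j] += 1
        for j, b in enumerate(encode(p.minus10)):
            if b >= 4:
                raise ValueError(f"{p.target_id}: ambiguous base in -10 block")
            counts10[b, j] += 1
    pwm = TwoBlockPWM(
        name=name or f"PWM_{len(promoters)}_{spacer_len}",
        counts35=counts35, counts10=counts10, spacer_len=spacer_len,
        pseudocount=pseudocount, background=np.asarray(background, float),
        core_positions=(), training_scores=np.empty(0),
        training_core_scores=np.empty(0))
    info = pwm.information_content()
    # ties broken 5'-first: stable sort on (-info, position)
    order = np.lexsort((np.arange(N_COLUMNS), -info))
    core = tuple(sorted(int(i) for i in order[:core_size]))
    pwm = replace(pwm, core_positions=core)
    full, cores = [], []
    for p in promoters:
        _, norm, core_norm = pwm.score_blocks(p.minus35, p.minus10)
        full.append(norm)
        cores.append(core_norm)
    return replace(pwm, training_scores=np.array(full),
                   training_core_scores=np.array(cores))


def build_validated_pwms(promoters: Sequence[PromoterEntry],
                         pseudocount: float = 0.5,
                         background: np.ndarray = STREPTOMYCES_BACKGROUND
                         ) -> tuple[TwoBlockPWM, TwoBlockPWM]:
    """The 16- and 17-spacer PWM pair from one validated promoter set."""
    return (build_pwm(promoters, 16, pseudocount, background),
            build_pwm(promoters, 17, pseudocount, background))


def score_site(pwm: TwoBlockPWM, minus35: str, minus10: str) -> tuple[float, float]:
    """(raw, normalised) log-odds score of a block pair under ``pwm``."""
    raw, norm, _ = pwm.score_blocks(minus35, minus10)
    return raw, norm


# ---------------------------------------------------------------------------
# scanning

def scan_sequence(pwms: Sequence[TwoBlockPWM], seq: str,
                  params: ScanParams = ScanParams(),
                  gene_id: str = "") -> list[SiteHit]:
    """Scan a bare sense-strand sequence with a set of PWMs.

    Every start offset of every PWM (hence both spacer lengths) is evaluated;
    a hit needs both the calibrated full-score and core-score thresholds.
    """
    hits: list[SiteHit] = []
    enc = encode(seq)
    for pwm in pwms:
        full_thr, core_thr = pwm.thresholds(params)
        span = pwm.span
        n_starts = len(seq) - span + 1
        if n_starts < 1:
            continue
        lod = pwm.log_odds
        core35 = [j for j in pwm.core_positions if j < BLOCK35_LEN]
        core10 = [j - BLOCK35_LEN for j in pwm.core_positions if j >= BLOCK35_LEN]
        w35 = np.lib.stride_tricks.sliding_window_view(enc, BLOCK35_LEN)
        w10 = np.lib.stride_tricks.sliding_window_view(enc, BLOCK10_LEN)
        s35 = lod[w35, np.arange(BLOCK35_LEN)].sum(axis=1)
        s10 = lod[w10, np.arange(BLOCK10_LEN) + BLOCK35_LEN].sum(axis=1)
        c35 = lod[w35[:, core35], core35].sum(axis=1)
        c10 = lod[w10[:, core10], np.array(core10) + BLOCK35_LEN].sum(axis=1)
        off = BLOCK35_LEN + pwm.spacer_len
        raw = s35[:n_starts] + s10[off:off + n_starts]
        core_raw = c35[:n_starts] + c10[off:off + n_starts]
        flo, fhi = pwm._bounds(range(N_COLUMNS))
        clo, chi = pwm._bounds(pwm.core_positions)
        norm = (raw - flo) / (fhi - flo)
        core_norm = (core_raw - clo) / (chi - clo)
        # small epsilon so a training site never misses its own calibrated
        # threshold through summation-order rounding
        eps = 1e-9
        for start in np.flatnonzero((core_norm >= core_thr - eps)
                                    & (norm >= full_thr - eps)):
            hits.append(SiteHit(gene_id, pwm.name, int(start), None,
                                pwm.spacer_len, float(raw[start]),
                                float(norm[start]), float(core_norm[start]), None))
    hits.sort(key=lambda h: -h.normalized_score)
    return hits


def scan_region(pwms: Sequence[TwoBlockPWM], region: UpstreamRegion,
                params: ScanParams = ScanParams()) -> list[SiteHit]:
    """Scan an upstream region; hits annotated with genomic position and distance.

    Returns hits sorted by normalised score (descending), ties broken by
    smaller distance to the start codon.  Regions shorter than the PWM span
    yield an empty list.
    """
    hits: list[SiteHit] = []
    if region.is_empty:
        return hits
    for hit in scan_sequence(pwms, region.sequence, params, region.gene_id):
        span = BLOCK35_LEN + hit.gap + BLOCK10_LEN
        end = hit.region_start + span - 1   # 3' base of the -10 element
        dist = region.distance_to_start(end)
        if not params.near_bp <= dist <= params.far_bp:
            continue
        hit.genomic_start = region.genomic(hit.region_start)
        hit.distance_bp = dist
        hits.append(hit)
    hits.sort(key=lambda h: (-h.normalized_score, h.distance_bp))
    return hits


def best_hit(pwms: Sequence[TwoBlockPWM], region: UpstreamRegion,
             params: ScanParams = ScanParams()) -> SiteHit | None:
    hits = scan_region(pwms, region, params)
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# candidate promoters from peaks

def _motif_log_odds(motif: TwoBlockMotif, pseudocount: float = 0.5
                    ) -> tuple[np.ndarray, np.ndarray]:
    return motif.log_odds(pseudocount)


def candidate_promoters(peaks, contigs: Sequence[Contig],
                        genes: Sequence[GeneModel],
                        rule: CandidateRule = CandidateRule(),
                        motif: TwoBlockMotif | None = None,
                        ) -> tuple[list[PromoterEntry], list]:
    """Candidate two-block promoters for each peak-gene pair.

    Stage 1 screens the gene-sense upstream window (within
    ``rule.max_distance_bp`` of the start codon) of every gene whose window
    overlaps a peak, keeping block pairs matching the conservation rule with
    a 16- or 17-bp spacer.  Stage 2 (when a discovered ``motif`` is given)
    rescores candidates with the motif's log-odds tables and keeps the best
    per peak-gene pair.  Peaks with no gene in range are returned as orphans.
    """
    span_max = BLOCK35_LEN + 17 + BLOCK10_LEN
    far = rule.max_distance_bp + span_max
    candidates: list[PromoterEntry] = []
    orphans = []
    lod = motif.log_odds() if motif is not None else None
    for peak in peaks:
        peak_genes = []
        for gene in genes:
            if gene.contig_id != peak.contig_id:
                continue
            s = gene.start_codon_pos
            if gene.strand == "+":
                window = (s - far, s)
            else:
                window = (s + 1, s + far)
            if window[0] < peak.interval[1] and peak.interval[0] < window[1]:
                peak_genes.append(gene)
        if not peak_genes:
            orphans.append(peak)
            continue
        for gene in peak_genes:
            region = extract_upstream(contigs, gene, 0, far)
            matches = []
            for gap in (16, 17):
                span = BLOCK35_LEN + gap + BLOCK10_LEN
                for start in range(0, len(region.sequence) - span + 1):
                    m35 = region.sequence[start:start + BLOCK35_LEN]
                    spacer = region.sequence[start + BLOCK35_LEN:
                                             start + BLOCK35_LEN + gap]
                    m10 = region.sequence[start + BLOCK35_LEN + gap:start + span]
                    if not rule.matches(m35, m10):
                        continue
                    dist = region.distance_to_start(start + span - 1)
                    if dist > rule.max_distance_bp:
                        continue
                    score = 0.0
                    if lod is not None:
                        s35 = sum(lod[0][b, j] for j, b in enumerate(encode(m35)))
                        s10 = sum(lod[1][b, j] for j, b in enumerate(encode(m10)))
                        score = float(s35 + s10)
                    matches.append((score, dist, start,
                                    PromoterEntry(gene.gene_id, m35, spacer, m10, dist)))
            if not matches:
                continue
            if motif is not None:
                # best per peak-gene pair: score, then proximity, then leftmost
                matches.sort(key=lambda m: (-m[0], m[1], m[2]))
                matches = matches[:1]
            candidates.extend(m[3] for m in matches)
    return candidates, orphans


# ---------------------------------------------------------------------------
# logo export and PWM I/O

def export_logo_counts(pwm: TwoBlockPWM) -> pd.DataFrame:
    """Lossless position x base count table; spacer rows are marked gap columns."""
    rows = []
    for j in range(BLOCK35_LEN):
        rows.append({"position": j, "block": "minus35",
                     **{b: pwm.counts35[i, j] for i, b in enumerate(BASE_ORDER)}})
    for j in range(pwm.spacer_len):
        rows.append({"position": BLOCK35_LEN + j, "block": "spacer",
                     **{b: 0.0 for b in BASE_ORDER}})
    for j in range(BLOCK10_LEN):
        rows.append({"position": BLOCK35_LEN + pwm.spacer_len + j, "block": "minus10",
                     **{b: pwm.counts10[i, j] for i, b in enumerate(BASE_ORDER)}})
    return pd.DataFrame(rows)


def write_pwm(pwm: TwoBlockPWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name\t{pwm.name}\n")
        fh.write(f"#spacer_len\t{pwm.spacer_len}\n")
        fh.write(f"#pseudocount\t{pwm.pseudocount}\n")
        fh.write("#background\t" + ",".join(f"{x:.6g}" for x in pwm.background) + "\n")
        fh.write("#core_positions\t" + ",".join(map(str, pwm.core_positions)) + "\n")
        fh.write("#training_scores\t"
                 + ",".join(f"{x:.10g}" for x in pwm.training_scores) + "\n")
        fh.write("#training_core_scores\t"
                 + ",".join(f"{x:.10g}" for x in pwm.training_core_scores) + "\n")
        fh.write("block\tposition\t" + "\t".join(BASE_ORDER) + "\n")
        for j in range(BLOCK35_LEN):
            fh.write("minus35\t%d\t%s\n"
                     % (j, "\t".join(f"{pwm.counts35[i, j]:.10g}" for i in range(4))))
        for j in range(BLOCK10_LEN):
            fh.write("minus10\t%d\t%s\n"
                     % (j, "\t".join(f"{pwm.counts10[i, j]:.10g}" for i in range(4))))


def read_pwm(path: str | Path) -> TwoBlockPWM:
    meta: dict[str, str] = {}
    counts35 = np.zeros((4, BLOCK35_LEN))
    counts10 = np.zeros((4, BLOCK10_LEN))
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key] = value
            elif line.startswith(("minus35", "minus10")):
                block, pos, *vals = line.split("\t")
                target = counts35 if block == "minus35" else counts10
                target[:, int(pos)] = [float(v) for v in vals]
    return TwoBlockPWM(
        name=meta["name"], counts35=counts35, counts10=counts10,
        spacer_len=int(meta["spacer_len"]), pseudocount=float(meta["pseudocount"]),
        background=np.array([float(x) for x in meta["background"].split(",")]),
        core_positions=tuple(int(x) for x in meta["core_positions"].split(",")),
        training_scores=np.array([float(x) for x in meta["training_scores"].split(",")]),
        training_core_scores=np.array(
            [float(x) for x in meta["training_core_scores"].split(",")]),
    )
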