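"""Windowed enrichment peak calling of ChIP coverage against an input control.

The chromosome is tiled in fixed windows (25 bp by default, the resolution at
which summit windows are reported).  Each window's ChIP count is compared with
the input-control count by the exact conditional test for a ratio of two
Poisson counts: given the window total ``n = chip + control``, the ChIP count
is Binomial(n, rho) under the null, where ``rho`` is the ChIP share of the
combined library size.  This test is exactly calibrated, which a plug-in
Poisson test with the scaled control treated as a known mean is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CoverageTrack:
    """Per-base read counts for one contig."""

    contig_id: str
    counts: np.ndarray
    library_size: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.library_size <= 0:
            self.library_size = int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class PeakParams:
    window_bp: int = 25
    p_threshold: float = 1e-4
    min_enrichment: float = 2.0
    merge_gap_bp: int = 25
    bh_correction: bool = False  # Benjamini-Hochberg on window p-values

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class PeakCall:
    contig_id: str
    interval: tuple[int, int]
    summit_window: tuple[int, int]
    enrichment: float
    p_value: float

    def __post_init__(self) -> None:
        lo, hi = self.interval
        slo, shi = self.summit_window
        if not (lo <= slo and shi <= hi):
            raise ValueError("summit window must lie inside the peak interval")


def _window_counts(counts: np.ndarray, window: int) -> np.ndarray:
    n_win = len(counts) // window
    return counts[: n_win * window].reshape(n_win, window).sum(axis=1)


def window_p_values(chip: CoverageTrack, control: CoverageTrack,
                    params: PeakParams) -> pd.DataFrame:
    """Per-window one-sided p-values and enrichment ratios.

    Returns a frame with columns start, end, chip, control, enrichment, p_value.
    A trailing partial window is dropped.
    """
    if chip.contig_id != control.contig_id or len(chip) != len(control):
        raise ValueError("chip and control must cover the same contig")
    if control.counts.sum() == 0:
        raise ValueError(
            "control track is all zero; supply a pseudo-flat control "
            "(uniform counts at the expected background depth) instead")
    w = params.window_bp
    cw = _window_counts(chip.counts, w)
    xw = _window_counts(control.counts, w)
    n = cw + xw
    rho = chip.library_size / (chip.library_size + control.library_size)
    # one-sided exact test for ChIP excess given the window total
    p = stats.binom.sf(cw - 1, n, rho)
    p[n == 0] = 1.0
    ratio = control.library_size / chip.library_size
    enr = (cw + 0.5) / (xw + 0.5) * ratio
    starts = np.arange(len(cw)) * w
    return pd.DataFrame({
        "start": starts, "end": starts + w,
        "chip": cw, "control": xw,
        "enrichment": enr, "p_value": p,
    })


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_peaks(chip: CoverageTrack, control: CoverageTrack,
               params: PeakParams = PeakParams()) -> list[PeakCall]:
    """Call enriched peaks: significant windows merged when close together.

    A window is significant when its p-value passes ``p_threshold`` (raw by
    default, after Benjamini-Hochberg when ``bh_correction``) and its
    library-size-normalised enrichment passes ``min_enrichment``.  Runs of
    significant windows separated by at most ``merge_gap_bp`` are merged; the
    best window of each merged peak (lowest p, then highest enrichment, then
    leftmost) is its summit.
    """
    wins = window_p_values(chip, control, params)
    pvals = wins["p_value"].to_numpy()
    if params.bh_correction:
        pvals = _benjamini_hochberg(pvals)
    sig = (pvals <= params.p_threshold) & \
          (wins["enrichment"].to_numpy() >= params.min_enrichment)
    idx = np.flatnonzero(sig)
    peaks: list[PeakCall] = []
    if len(idx) == 0:
        return peaks
    w = params.window_bp
    max_gap_windows = params.merge_gap_bp // w
    group_start = idx[0]
    prev = idx[0]
    groups: list[tuple[int, int]] = []
    for i in idx[1:]:
        if i - prev - 1 > max_gap_windows:
            groups.append((group_start, prev))
            group_start = i
        prev = i
    groups.append((group_start, prev))
    for lo_w, hi_w in groups:
        members = [i for i in idx if lo_w <= i <= hi_w]
        # summit: lowest p, then highest enrichment, then leftmost
        best = min(members, key=lambda i: (pvals[i], -wins["enrichment"][i], i))
        peaks.append(PeakCall(
            contig_id=chip.contig_id,
            interval=(int(wins["start"][lo_w]), int(wins["end"][hi_w])),
            summit_window=(int(wins["start"][best]), int(wins["end"][best])),
            enrichment=float(wins["enrichment"][best]),
            p_value=float(pvals[best]),
        ))
    return peaks


def summit_flank(peak: PeakCall, flank_bp: int = 100,
                 contig_length: int | None = None) -> tuple[int, int]:
    """Summit window extended ``flank_bp`` each side, clipped at contig ends."""
    lo = peak.summit_window[0] - flank_bp
    hi = peak.summit_window[1] + flank_bp
    if lo < 0:
        lo = 0
    if contig_length is not None and hi > contig_length:
        hi = contig_length
    return lo, hi


def oriented_flanks(peaks: Sequence[PeakCall], contigs, genes,
                    flank_bp: int = 100, max_distance_bp: int = 400
                    ) -> list[tuple[str, str]]:
    """Summit-flank sequences oriented to the nearest downstream gene.

    A forward-strand motif search needs every promoter in the same
    orientation; each flank is therefore reverse-complemented when its
    nearest in-range gene (start codon within ``max_distance_bp`` of the
    summit, looking downstream on either strand) lies on the minus strand.
    Peaks with no gene in range keep the reference orientation.
    """
    from .genome_io import reverse_complement
    by_id = {c.id: c for c in contigs}
    out: list[tuple[str, str]] = []
    for i, p in enumerate(peaks):
        contig = by_id[p.contig_id]
        lo, hi = summit_flank(p, flank_bp, len(contig))
        seq = contig.sequence[lo:hi]
        center = (p.summit_window[0] + p.summit_window[1]) // 2
        best: tuple[int, str] | None = None
        for g in genes:
            if g.contig_id != p.contig_id:
                continue
            s = g.start_codon_pos
            d = s - center if g.strand == "+" else center - s
            if 0 <= d <= max_distance_bp and (best is None or d < best[0]):
                best = (d, g.strand)
        if best is not None and best[1] == "-":
            seq = reverse_complement(seq)
        out.append((f"peak_{i + 1}", seq))
    return out


# ---------------------------------------------------------------------------
# I/O: bedgraph-style coverage and BED6+ peaks

def read_coverage(path: str | Path, contig_length: int | None = None) -> CoverageTrack:
    """Read a 4-column (contig, start, end, count) TSV/bedGraph into a track."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["contig", "start", "end", "count"])
    if df.empty:
        raise ValueError(f"empty coverage file {path}")
    contig = df["contig"].iloc[0]
    if (df["contig"] != contig).any():
        raise ValueError("coverage file spans multiple contigs; split it first")
    length = contig_length or int(df["end"].max())
    counts = np.zeros(length, dtype=np.int64)
    for start, end, cnt in df[["start", "end", "count"]].itertuples(index=False):
        counts[int(start):int(end)] = int(cnt)
    return CoverageTrack(str(contig), counts)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as run-length-encoded bedGraph."""
    counts = track.counts
    change = np.flatnonzero(np.diff(counts)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(counts)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.contig_id}\t{s}\t{e}\t{counts[s]}\n")


def peaks_to_frame(peaks: Sequence[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig": p.contig_id, "start": p.interval[0], "end": p.interval[1],
        "name": f"peak_{i + 1}", "score": min(1000, int(-10 * np.log10(max(p.p_value, 1e-300)))),
        "strand": ".",
        "summit_start": p.summit_window[0], "summit_end": p.summit_window[1],
        "enrichment": p.enrichment, "p_value": p.p_value,
    } for i, p in enumerate(peaks)])


def write_peaks(peaks: Sequence[PeakCall], path: str | Path) -> None:
    peaks_to_frame(peaks).to_csv(path, sep="\t", index=False)
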