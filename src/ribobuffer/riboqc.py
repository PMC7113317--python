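"""Ribosome-profiling quality control in transcript coordinates.

Three checks that a footprint library behaves like ribosome-protected
fragments rather than RNA background:

* the distance from footprint 5' ends to annotated translation initiation
  sites (TIS) has a sharp mode — the P-site offset, −12 nt in a well-behaved
  library (negative = upstream of the TIS, position 0 = first nt of AUG);
* metagene coverage in 10-nt bins is concentrated in the CDS and depleted in
  the flanking UTRs;
* union-mode counting assigns each read to the single gene whose CDS it
  overlaps, discarding ambiguous and non-CDS reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .synthdata import FootprintAlignment, TranscriptModel

__all__ = [
    "OffsetHistogram",
    "MetageneProfile",
    "estimate_psite_offset",
    "metagene_profile",
    "count_cds_reads",
]


@dataclass(frozen=True)
class OffsetHistogram:
    """Histogram of (read 5' end − TIS) distances within a window.

    ``offsets`` is dense over the window: every offset in [lo, hi] has an
    entry, zero where no read landed.  ``modes`` lists all offsets with the
    maximal count, ascending — ties are reported, never silently broken.
    """

    offsets: dict[int, int]
    window: tuple[int, int]

    @property
    def total(self) -> int:
        return sum(self.offsets.values())

    @property
    def modes(self) -> list[int]:
        peak = max(self.offsets.values())
        if peak == 0:
            return []
        return sorted(o for o, c in self.offsets.items() if c == peak)


@dataclass(frozen=True)
class MetageneProfile:
    """Per-bin mean coverage (read 5' ends per nt, averaged over qualifying
    transcripts) for one region."""

    region: str  # "utr5_flank" | "cds" | "utr3_flank"
    bin_width: int
    values: np.ndarray


def _transcript_index(
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
) -> dict[str, TranscriptModel]:
    if isinstance(transcripts, Mapping):
        return dict(transcripts)
    return {t.gene_id: t for t in transcripts}


def estimate_psite_offset(
    reads: Sequence[FootprintAlignment],
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    window: tuple[int, int] = (-30, 30),
) -> OffsetHistogram:
    """Histogram of 5'-end-to-TIS distances, restricted to ``window``.

    Raises
    ------
    ValueError
        On an empty read set ("no reads") or a read whose transcript is not
        in ``transcripts`` (named in the message).
    """
    if not reads:
        raise ValueError("no reads")
    lo, hi = window
    if lo > hi:
        raise ValueError("invalid window")
    index = _transcript_index(transcripts)
    counts: Counter[int] = Counter()
    for read in reads:
        t = index.get(read.transcript_id)
        if t is None:
            raise ValueError(f"unknown transcript id {read.transcript_id!r}")
        offset = read.start - t.tis
        if lo <= offset <= hi:
            counts[offset] += 1
    dense = {o: counts.get(o, 0) for o in range(lo, hi + 1)}
    return OffsetHistogram(dense, (lo, hi))


def _bin_means(per_pos: np.ndarray, bin_width: int) -> np.ndarray:
    """Mean coverage per bin; a final partial bin is normalized by its true
    width."""
    n = per_pos.size
    n_bins = (n + bin_width - 1) // bin_width
    out = np.empty(n_bins)
    for b in range(n_bins):
        chunk = per_pos[b * bin_width : (b + 1) * bin_width]
        out[b] = chunk.mean()
    return out


def metagene_profile(
    reads: Sequence[FootprintAlignment],
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    bin_width: int = 10,
    flank5: int = 50,
    flank3: int = 200,
    min_cds_len: int = 1000,
) -> list[MetageneProfile]:
    """Metagene coverage around the TIS and stop codon.

    Only transcripts with CDS length > ``min_cds_len`` contribute.  Three
    regions are profiled: the ``flank5`` nt upstream of the TIS (bins anchored
    at the TIS, leftmost bin first), the CDS (bins anchored at the TIS), and
    the ``flank3`` nt downstream of the stop codon (bins anchored at the
    stop).  Coverage is the count of read 5' ends per position, averaged
    within bins, then across the transcripts that have the bin.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    index = _transcript_index(transcripts)
    qualifying = {g: t for g, t in index.items() if len(t.cds) > min_cds_len}
    if not qualifying:
        raise ValueError("no transcript passes min_cds_len")

    ends: dict[str, Counter[int]] = {g: Counter() for g in qualifying}
    for read in reads:
        if read.transcript_id in ends:
            ends[read.transcript_id][read.start] += 1

    region_bins: dict[str, list[np.ndarray]] = {
        "utr5_flank": [],
        "cds": [],
        "utr3_flank": [],
    }
    for g, t in sorted(qualifying.items()):
        cov = np.zeros(t.length)
        for pos, c in ends[g].items():
            if 0 <= pos < t.length:
                cov[pos] = c
        lo5 = max(0, t.tis - flank5)
        region_bins["utr5_flank"].append(_bin_means(cov[lo5 : t.tis], bin_width))
        region_bins["cds"].append(_bin_means(cov[t.tis : t.cds_end], bin_width))
        hi3 = min(t.length, t.cds_end + flank3)
        region_bins["utr3_flank"].append(_bin_means(cov[t.cds_end : hi3], bin_width))

    profiles = []
    for region, per_tx in region_bins.items():
        n_bins = max((v.size for v in per_tx), default=0)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for v in per_tx:
            if region == "utr5_flank":
                # anchor at the TIS: right-align shorter flanks
                sums[n_bins - v.size :] += v
                counts[n_bins - v.size :] += 1
            else:
                sums[: v.size] += v
                counts[: v.size] += 1
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        profiles.append(MetageneProfile(region, bin_width, values))
    return profiles


def count_cds_reads(
    reads: Sequence[FootprintAlignment],
    transcripts: Sequence[TranscriptModel]
    | Mapping[str, TranscriptModel]
    | Mapping[str, Sequence[tuple[str, int, int]]],
) -> dict[str, int]:
    """Union-mode CDS counting.

    A read is assigned to a gene iff its [start, start+length) interval
    overlaps that gene's CDS on the read's transcript; reads overlapping the
    CDS of more than one gene, or of none, are discarded.

    ``transcripts`` may be transcript models (one CDS per transcript) or a
    mapping transcript_id -> [(gene_id, cds_start, cds_end), ...] allowing
    several genes' CDS intervals on one transcript.
    """
    cds: dict[str, list[tuple[str, int, int]]] = {}
    if isinstance(transcripts, Mapping) and transcripts and not isinstance(
        next(iter(transcripts.values())), TranscriptModel
    ):
        for tid, intervals in transcripts.items():
            cds[tid] = [(g, int(a), int(b)) for g, a, b in intervals]
    else:
        for t in _transcript_index(transcripts).values():
            cds[t.gene_id] = [(t.gene_id, t.tis, t.cds_end)]

    counts: Counter[str] = Counter()
    for read in reads:
        intervals = cds.get(read.transcript_id, [])
        hits = {
            g
            for g, a, b in intervals
            if read.start < b and read.end > a  # half-open overlap
        }
        if len(hits) == 1:
            counts[hits.pop()] += 1
    return dict(counts)
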