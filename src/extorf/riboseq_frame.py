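"""Frame-resolved ribosome-footprint analysis on single transcripts.

Works from ribosome-protected-fragment 5'-end positions in transcript
coordinates (read trimming and genome alignment are upstream of this
package). Reads of 28-31 nt are accepted by default; a fixed 15-nt offset
from the 5' end estimates the ribosomal A site, and 12 nt (A site minus
one codon) estimates the P site that an initiating ribosome holds over
the start codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._defs import InvalidRegionError
from .feature_scan import Transcript

DEFAULT_ACCEPTED_LENGTHS = (28, 31)
DEFAULT_A_SITE_OFFSET = 15
DEFAULT_P_SITE_OFFSET = 12


@dataclass
class FootprintProfile:
    transcript_id: str
    counts: np.ndarray  # per-position 5'-end tallies
    length_histogram: dict[int, int]
    accepted_lengths: tuple[int, int] = DEFAULT_ACCEPTED_LENGTHS
    n_accepted: int = 0
    n_rejected_length: int = 0
    n_out_of_bounds: int = 0


@dataclass
class FrameHistogram:
    region: tuple[int, int]
    label: str
    n_reads: int
    proportions: Optional[tuple[float, float, float]]  # frames 1/2/3 or None


@dataclass
class RegionRatio:
    region_a: str
    region_b: str
    count_a: int
    count_b: int
    ratio: Optional[float]
    density_ratio: Optional[float]
    status: str  # ok | undefined


@dataclass
class PeakAssignment:
    pos: int  # 5'-end position of the peak
    count: int
    threshold: float
    candidate_pos: Optional[int]  # codon start the peak maps to, or None


def build_profile(
    reads: Iterable[tuple[str, int, int]],
    t: Transcript,
    accepted_lengths: tuple[int, int] = DEFAULT_ACCEPTED_LENGTHS,
) -> FootprintProfile:
    """Tally read 5' ends per position.

    `reads` yields (transcript_id, five_prime_pos, length); records for
    other transcripts are ignored, out-of-range lengths and out-of-bounds
    positions are dropped and counted.
    """
    lo, hi = accepted_lengths
    counts = np.zeros(len(t.seq), dtype=np.int64)
    hist: dict[int, int] = {}
    prof = FootprintProfile(
        transcript_id=t.id, counts=counts, length_histogram=hist,
        accepted_lengths=accepted_lengths,
    )
    for tid, pos, length in reads:
        if tid != t.id:
            continue
        if not (lo <= length <= hi):
            prof.n_rejected_length += 1
            continue
        if not (0 <= pos < len(t.seq)):
            prof.n_out_of_bounds += 1
            continue
        counts[pos] += 1
        hist[length] = hist.get(length, 0) + 1
        prof.n_accepted += 1
    return prof


def frame_histogram(
    p: FootprintProfile,
    t: Transcript,
    region: tuple[int, int],
    a_site_offset: int = DEFAULT_A_SITE_OFFSET,
    label: str = "",
) -> FrameHistogram:
    """Frame proportions of A-site landings inside a region.

    Each counted 5' end x contributes to the frame
    ((x + offset - main_start) mod 3), labelled 1/2/3 (frame 1 = main-ORF
    frame), provided x + offset falls inside the half-open region.
    """
    start, end = region
    if not (0 <= start < end <= len(t.seq)):
        raise InvalidRegionError(f"region {region} outside transcript")
    if a_site_offset < 0:
        raise InvalidRegionError("offset must be >= 0")
    frames = np.zeros(3, dtype=np.int64)
    positions = np.nonzero(p.counts)[0]
    for x in positions:
        a = x + a_site_offset
        if start <= a < end:
            frames[(a - t.main_start) % 3] += p.counts[x]
    n = int(frames.sum())
    props = tuple(float(v) / n for v in frames) if n > 0 else None
    return FrameHistogram(region=region, label=label, n_reads=n, proportions=props)


def _region_count(
    p: FootprintProfile, region: tuple[int, int], a_site_offset: int
) -> int:
    start, end = region
    lo = max(0, start - a_site_offset)
    hi = max(0, end - a_site_offset)
    return int(p.counts[lo:hi].sum())


def region_ratio(
    p_a: FootprintProfile,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    p_b: Optional[FootprintProfile] = None,
    a_site_offset: int = DEFAULT_A_SITE_OFFSET,
    label_a: str = "a",
    label_b: str = "b",
) -> RegionRatio:
    """Ratio of A-site-assigned footprint counts between two regions.

    The denominator region may come from the same profile or (p_b) from a
    second condition. Raw counts by default; a per-nucleotide density
    ratio is reported alongside.
    """
    pb = p_b if p_b is not None else p_a
    ca = _region_count(p_a, region_a, a_site_offset)
    cb = _region_count(pb, region_b, a_site_offset)
    if cb == 0:
        return RegionRatio(
            region_a=label_a, region_b=label_b, count_a=ca, count_b=cb,
            ratio=None, density_ratio=None, status="undefined",
        )
    la = region_a[1] - region_a[0]
    lb = region_b[1] - region_b[0]
    return RegionRatio(
        region_a=label_a, region_b=label_b, count_a=ca, count_b=cb,
        ratio=ca / cb,
        density_ratio=(ca / la) / (cb / lb) if la and lb else None,
        status="ok",
    )


def detect_start_peaks(
    p: FootprintProfile,
    t: Transcript,
    candidates: Sequence[int],
    p_site_offset: int = DEFAULT_P_SITE_OFFSET,
    k: float = 5.0,
    min_count: int = 10,
    background_window: int = 50,
) -> list[PeakAssignment]:
    """Call initiation peaks and assign them to candidate start codons.

    A position x is a peak when counts[x] >= max(min_count, k x median of
    counts within +/- background_window nt, excluding x). A peak is
    assigned to a candidate codon start exactly when
    x + p_site_offset == candidate (1-nt resolution), else reported
    unassigned.
    """
    cands = set(int(c) for c in candidates)
    counts = p.counts
    n = len(counts)
    out: list[PeakAssignment] = []
    for x in np.nonzero(counts)[0]:
        lo, hi = max(0, x - background_window), min(n, x + background_window + 1)
        neigh = np.concatenate([counts[lo:x], counts[x + 1 : hi]])
        med = float(np.median(neigh)) if neigh.size else 0.0
        thr = max(float(min_count), k * med)
        if counts[x] >= thr:
            target = int(x) + p_site_offset
            out.append(
                PeakAssignment(
                    pos=int(x), count=int(counts[x]), threshold=thr,
                    candidate_pos=target if target in cands else None,
                )
            )
    return out
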