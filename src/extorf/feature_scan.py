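"""5'-leader architecture scanning.

Annotates the translational landscape upstream of an annotated main start
codon: AUG-initiated ORFs/uORFs in all three frames, in-frame near-cognate
start codons (NCCs) upstream of a configurable inhibitory boundary, and the
maximal in-frame N-terminal extension of the main ORF.

Coordinates are 0-based, half-open, transcript space, forward strand only.
RNA input (U) is normalized to DNA (T) at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._defs import (
    DEFAULT_NCC_SET,
    STOP_CODONS,
    InvalidInputError,
    InvalidRegionError,
)

NT_ALPHABET = set("ACGTN")


def normalize_seq(seq: str) -> str:
    """Uppercase, U->T. Raises on empty or non-nucleotide input."""
    if not seq:
        raise InvalidInputError("empty sequence")
    s = seq.upper().replace("U", "T")
    bad = set(s) - NT_ALPHABET
    if bad:
        raise InvalidInputError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def _frame_label(pos: int, main_start: int) -> int:
    """Frame 1 = in frame with the main ORF; 2/3 = shifted by +1/+2 nt."""
    return ((pos - main_start) % 3) + 1


@dataclass
class Transcript:
    """An mRNA with an annotated main-ORF start.

    main_start indexes the first nucleotide of the annotated start codon;
    main_end (optional) is the exclusive end of the main ORF including its
    stop codon.
    """

    id: str
    seq: str
    main_start: int
    main_end: Optional[int] = None
    non_aug_annotated: bool = False

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        if not (0 <= self.main_start <= len(self.seq) - 3):
            raise InvalidInputError(
                f"{self.id}: main_start {self.main_start} outside sequence"
            )
        start = self.seq[self.main_start : self.main_start + 3]
        if start != "ATG" and not self.non_aug_annotated:
            raise InvalidInputError(
                f"{self.id}: codon at main_start is {start}, not ATG"
            )
        if self.main_end is not None and (self.main_end - self.main_start) % 3:
            raise InvalidInputError(f"{self.id}: main ORF length not a multiple of 3")

    @property
    def leader(self) -> str:
        return self.seq[: self.main_start]


@dataclass
class OrfFeature:
    transcript_id: str
    start: int
    end: int  # half-open; includes the stop codon when stop-terminated
    frame_label: int
    start_codon: str
    n_codons: int  # includes the stop codon when present
    kind: str  # uORF | mORF | overlapping_uORF | ORF
    stop_terminated: bool = True


@dataclass
class NccCandidate:
    transcript_id: str
    pos: int
    codon: str
    dist_to_main: int
    upstream_of_boundary: bool
    context_window: str
    no_inframe_stop: bool = True
    context_score: Optional[float] = None
    number: Optional[int] = None  # 5'->3' numbering starting at 1


@dataclass
class ExtensionReport:
    transcript_id: str
    ext_start: int
    ext_codons: int
    reaches_5prime: bool
    upstream_stop_pos: Optional[int] = None


def context_window(seq: str, pos: int) -> str:
    """11-mer covering -6..+5 around the codon starting at pos, N-padded."""
    lo, hi = pos - 6, pos + 5
    left = "N" * max(0, -lo)
    right = "N" * max(0, hi - len(seq))
    return left + seq[max(0, lo) : min(len(seq), hi)] + right


def find_orfs(seq: str, min_codons: int = 2) -> list[OrfFeature]:
    """Every ATG in every frame, extended to the first in-frame stop
    (inclusive) or, open-ended, to the sequence end.

    Codons containing N are never called as start or stop. Features sorted
    by start.
    """
    s = normalize_seq(seq)
    if len(s) < 3:
        raise InvalidInputError("sequence shorter than one codon")
    orfs: list[OrfFeature] = []
    for start in range(len(s) - 2):
        if s[start : start + 3] != "ATG":
            continue
        end = None
        p = start + 3
        while p + 3 <= len(s):
            c = s[p : p + 3]
            if c in STOP_CODONS:
                end = p + 3
                break
            p += 3
        if end is None:
            # open-ended: truncate to the last complete codon
            n_complete = (len(s) - start) // 3
            feat = OrfFeature(
                transcript_id="",
                start=start,
                end=start + 3 * n_complete,
                frame_label=(start % 3) + 1,
                start_codon="ATG",
                n_codons=n_complete,
                kind="ORF",
                stop_terminated=False,
            )
        else:
            feat = OrfFeature(
                transcript_id="",
                start=start,
                end=end,
                frame_label=(start % 3) + 1,
                start_codon="ATG",
                n_codons=(end - start) // 3,
                kind="ORF",
                stop_terminated=True,
            )
        if feat.n_codons >= min_codons:
            orfs.append(feat)
    orfs.sort(key=lambda f: f.start)
    return orfs


def has_inframe_stop(seq: str, start: int, end: int) -> bool:
    """Any stop codon at positions start, start+3, ... < end."""
    for p in range(start, end - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            return True
    return False


def scan_nccs(
    t: Transcript,
    ncc_set: Optional[Sequence[str]] = None,
    boundary: Optional[int] = None,
) -> list[NccCandidate]:
    """In-frame near-cognate candidates upstream of `boundary`.

    A candidate is a codon c at p < boundary with p = main_start (mod 3),
    c in the NCC set, and no stop codon in the main frame between p and
    main_start. Candidates are numbered 5'->3' from 1. Codons containing N
    are skipped.
    """
    ncc = set(ncc_set) if ncc_set is not None else set(DEFAULT_NCC_SET)
    if boundary is None:
        boundary = t.main_start
    if boundary > t.main_start:
        raise InvalidRegionError(
            f"boundary {boundary} downstream of main_start {t.main_start}"
        )
    if t.main_start < 3:
        return []
    out: list[NccCandidate] = []
    first = t.main_start % 3
    for p in range(first, min(boundary, t.main_start), 3):
        c = t.seq[p : p + 3]
        if "N" in c or c not in ncc:
            continue
        if has_inframe_stop(t.seq, p, t.main_start):
            continue
        out.append(
            NccCandidate(
                transcript_id=t.id,
                pos=p,
                codon=c,
                dist_to_main=t.main_start - p,
                upstream_of_boundary=True,
                context_window=context_window(t.seq, p),
            )
        )
    for i, cand in enumerate(out, start=1):
        cand.number = i
    return out


def max_extension(t: Transcript) -> ExtensionReport:
    """Maximal in-frame N-terminal extension of the main ORF.

    Scans upstream from main_start in the main frame for the 3'-most stop;
    the extension runs from the codon after it (or from the 5'-most in-frame
    position) up to main_start.
    """
    stop_pos: Optional[int] = None
    first = t.main_start % 3
    for p in range(t.main_start - 3, first - 1, -3):
        if t.seq[p : p + 3] in STOP_CODONS:
            stop_pos = p
            break
    ext_start = first if stop_pos is None else stop_pos + 3
    return ExtensionReport(
        transcript_id=t.id,
        ext_start=ext_start,
        ext_codons=(t.main_start - ext_start) // 3,
        reaches_5prime=stop_pos is None,
        upstream_stop_pos=stop_pos,
    )


def default_ncc_boundary(t: Transcript, uorfs: Sequence[OrfFeature]) -> int:
    """uAUG2 when >= 2 uORFs exist; else the single uORF's start; else
    main_start."""
    starts = sorted(f.start for f in uorfs)
    if len(starts) >= 2:
        return starts[1]
    if len(starts) == 1:
        return starts[0]
    return t.main_start


@dataclass
class ArchitectureReport:
    transcript_id: str
    uorfs: list[OrfFeature] = field(default_factory=list)
    ncc_candidates: list[NccCandidate] = field(default_factory=list)
    extension: Optional[ExtensionReport] = None
    boundary: Optional[int] = None


def annotate_architecture(
    t: Transcript,
    ncc_set: Optional[Sequence[str]] = None,
    boundary: Optional[int] = None,
    min_uorf_codons: int = 2,
) -> ArchitectureReport:
    """Composite of find_orfs (restricted to uORFs), scan_nccs and
    max_extension.

    uORFs are AUG-initiated ORFs starting upstream of main_start, any frame;
    a uORF whose end extends past main_start is flagged overlapping_uORF.
    The default NCC boundary follows default_ncc_boundary.
    """
    uorfs = []
    for f in find_orfs(t.seq, min_codons=min_uorf_codons):
        if f.start >= t.main_start:
            continue
        f.transcript_id = t.id
        f.frame_label = _frame_label(f.start, t.main_start)
        f.kind = "overlapping_uORF" if f.end > t.main_start else "uORF"
        uorfs.append(f)
    if boundary is None:
        boundary = default_ncc_boundary(t, uorfs)
    cands = scan_nccs(t, ncc_set=ncc_set, boundary=boundary)
    ext = max_extension(t)
    return ArchitectureReport(
        transcript_id=t.id,
        uorfs=uorfs,
        ncc_candidates=cands,
        extension=ext,
        boundary=boundary,
    )
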