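"""Initiation-context (Kozak-style) frequency matrices and scoring.

The context window is an 11-mer: six nucleotides upstream of the start
codon (positions -6..-1), the codon itself (+1..+3) and two downstream
nucleotides (+4, +5). Log-odds scores are computed over the seven non-codon
positions -6..-1 and +4 — the codon identity is judged by the NCC set, not
by the context — with +4 and -3 carrying the optimal/near-optimal calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._defs import NUCLEOTIDES, InvalidInputError

POSITION_LABELS = ("-6", "-5", "-4", "-3", "-2", "-1", "+1", "+2", "+3", "+4", "+5")
#: window indices entering the log-odds sum (flanks; the codon and +5 excluded)
SCORED_INDICES = (0, 1, 2, 3, 4, 5, 9)
IDX_MINUS3 = 3
IDX_PLUS4 = 9

UNIFORM_BACKGROUND = {nt: 0.25 for nt in NUCLEOTIDES}


@dataclass
class ContextMatrix:
    """Column-stochastic position x nucleotide frequency table."""

    freqs: np.ndarray  # shape (11, 4), rows = POSITION_LABELS, cols = ACGT
    n_sites: int

    def freq(self, pos_index: int, nt: str) -> float:
        return float(self.freqs[pos_index, NUCLEOTIDES.index(nt)])

    def consensus(self, pos_index: int) -> str:
        """Modal nucleotide at a window position (ties: alphabetical)."""
        return NUCLEOTIDES[int(np.argmax(self.freqs[pos_index]))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freqs, index=list(POSITION_LABELS), columns=list(NUCLEOTIDES)
        )


@dataclass
class ContextScore:
    candidate_id: str
    log_odds: float
    optimal_minus3: Optional[bool]
    optimal_plus4: Optional[bool]
    label: str  # optimal | near-optimal | poor | unknown


def build_context_matrix(
    windows: Iterable[str], pseudocount: float = 0.5
) -> ContextMatrix:
    """Per-position nucleotide frequencies over 11-mer windows.

    N is excluded per position from the counts; pseudocount alpha is added
    to every cell before normalization (Jeffreys alpha=0.5 by default keeps
    log-odds finite for unseen letters).
    """
    wins = list(windows)
    if not wins:
        raise InvalidInputError("no context windows supplied")
    counts = np.zeros((len(POSITION_LABELS), 4))
    for w in wins:
        w = w.upper().replace("U", "T")
        if len(w) != len(POSITION_LABELS):
            raise InvalidInputError(f"window {w!r} is not {len(POSITION_LABELS)} nt")
        for i, nt in enumerate(w):
            if nt in NUCLEOTIDES:
                counts[i, NUCLEOTIDES.index(nt)] += 1
    counts += pseudocount
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise InvalidInputError("a window position has no counts and no pseudocount")
    return ContextMatrix(freqs=counts / totals, n_sites=len(wins))


def score_context(
    window: str,
    m: ContextMatrix,
    background: Optional[Mapping[str, float]] = None,
    candidate_id: str = "",
) -> ContextScore:
    """Log2-odds of a window against a context matrix.

    log_odds = sum over the non-codon positions (-6..-1, +4) of
    log2(freq[pos][nt] / background[nt]). The -3/+4 flags compare the
    window to the matrix consensus at those positions; an N there leaves
    the flag unknown and the position out of the score.
    """
    bg = dict(background) if background is not None else UNIFORM_BACKGROUND
    w = window.upper().replace("U", "T")
    if len(w) != len(POSITION_LABELS):
        raise InvalidInputError(f"window {w!r} is not {len(POSITION_LABELS)} nt")
    score = 0.0
    for i in SCORED_INDICES:
        nt = w[i]
        if nt not in NUCLEOTIDES:
            continue
        score += np.log2(m.freq(i, nt) / bg[nt])

    def flag(i: int) -> Optional[bool]:
        nt = w[i]
        if nt not in NUCLEOTIDES:
            return None
        return nt == m.consensus(i)

    f3, f4 = flag(IDX_MINUS3), flag(IDX_PLUS4)
    if f3 is None or f4 is None:
        label = "unknown"
    elif f3 and f4:
        label = "optimal"
    elif f3 or f4:
        label = "near-optimal"
    else:
        label = "poor"
    return ContextScore(
        candidate_id=candidate_id,
        log_odds=float(score),
        optimal_minus3=f3,
        optimal_plus4=f4,
        label=label,
    )


def ncc_context_table(
    candidates: Sequence,
    m: ContextMatrix,
    background: Optional[Mapping[str, float]] = None,
) -> tuple[pd.DataFrame, Optional[ContextMatrix]]:
    """Score a set of NCC candidates and build their own frequency matrix.

    Returns (per-candidate table, matrix over the candidates' windows).
    Candidates must expose .context_window (NccCandidate does); the scores
    are written back onto the candidates. An empty candidate list yields an
    empty table and no matrix.
    """
    rows = []
    for c in candidates:
        sc = score_context(
            c.context_window, m, background=background,
            candidate_id=f"{c.transcript_id}:{c.pos}",
        )
        c.context_score = sc.log_odds
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "number": c.number,
                "pos": c.pos,
                "codon": c.codon,
                "dist_to_main": c.dist_to_main,
                "context_window": c.context_window,
                "log_odds": sc.log_odds,
                "optimal_minus3": sc.optimal_minus3,
                "optimal_plus4": sc.optimal_plus4,
                "label": sc.label,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "number", "pos", "codon", "dist_to_main",
            "context_window", "log_odds", "optimal_minus3", "optimal_plus4",
            "label",
        ],
    )
    cand_matrix = None
    if rows:
        cand_matrix = build_context_matrix([c.context_window for c in candidates])
    return table, cand_matrix
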