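"""Comparative codon-evolution statistics on reference-anchored alignments.

The pipeline here mirrors how overlapping/uncertain coding regions are
interrogated comparatively: a peptide-guided codon alignment is mapped to
reference coordinates, then interrogated with

* consensus-codon substitution tallies in three frames,
* per-residue amino-acid conservation,
* NG86 (Nei–Gojobori counting) dN/dS with a codon-column bootstrap,
* synonymous-site conservation in short sliding windows (observed/expected
  synonymous substitutions against a neutral null), and
* a simplified star-topology coding-vs-noncoding log-likelihood-ratio in
  20-codon sliding windows (an MLOGD-style statistic).

All statistics are pairwise reference-vs-other over a star topology; no
tree is inferred or used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps
from Bio import Align
from Bio.Align import substitution_matrices

from ._defs import (
    ALL_CODONS,
    GAP_CODON,
    GENETIC_CODE,
    NUCLEOTIDES,
    STOP_CODONS,
    FrameError,
    InvalidInputError,
    InvalidRegionError,
)

CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}


def translate_codon(codon: str) -> str:
    """One-letter amino acid; 'X' for codons containing N or other ambiguity."""
    return GENETIC_CODE.get(codon, "X")


# ---------------------------------------------------------------------------
# Alignment container and construction
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Reference-anchored codon-columnar alignment.

    rows maps id -> list of codons ('---' for a gap); after
    reference-mapping the reference row contains no gaps and `length`
    equals the reference codon count.
    """

    ids: list[str]
    ref_id: str
    rows: dict[str, list[str]]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) != 1:
            raise InvalidInputError("rows span different numbers of columns")
        if self.ref_id not in self.rows:
            raise InvalidInputError(f"reference {self.ref_id!r} missing from rows")

    @property
    def length(self) -> int:
        return len(self.rows[self.ref_id])

    @property
    def ref_codons(self) -> list[str]:
        return self.rows[self.ref_id]

    @property
    def other_ids(self) -> list[str]:
        return [i for i in self.ids if i != self.ref_id]

    def nt_row(self, seq_id: str) -> str:
        return "".join(self.rows[seq_id])

    def column(self, j: int) -> dict[str, str]:
        return {i: self.rows[i][j] for i in self.ids}

    def slice(self, start: int, end: int) -> "CodonAlignment":
        return CodonAlignment(
            ids=list(self.ids),
            ref_id=self.ref_id,
            rows={i: r[start:end] for i, r in self.rows.items()},
        )

    def take_columns(self, indices: Sequence[int]) -> "CodonAlignment":
        return CodonAlignment(
            ids=list(self.ids),
            ref_id=self.ref_id,
            rows={i: [r[j] for j in indices] for i, r in self.rows.items()},
        )


def translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise FrameError(f"sequence length {len(cds)} not divisible by 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def back_translate(aligned_pep: str, cds: str) -> list[str]:
    """Thread the codons of `cds` through an aligned peptide string."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    out: list[str] = []
    k = 0
    for aa in aligned_pep:
        if aa == "-":
            out.append(GAP_CODON)
        else:
            if k >= len(codons):
                raise InvalidInputError("aligned peptide longer than CDS")
            out.append(codons[k])
            k += 1
    if k != len(codons):
        raise InvalidInputError(
            f"aligned peptide consumed {k} codons, CDS has {len(codons)}"
        )
    return out


def _peptide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def map_to_reference(a: CodonAlignment) -> CodonAlignment:
    """Drop every column holding a gap in the reference row."""
    keep = [j for j, c in enumerate(a.ref_codons) if c != GAP_CODON]
    return a.take_columns(keep)


def align_codons(
    cds_set: Mapping[str, str],
    ref_id: str,
    aligned_peptides: Optional[Mapping[str, str]] = None,
) -> CodonAlignment:
    """Peptide-guided codon alignment anchored on a reference.

    Each CDS is conceptually translated; peptides are aligned globally
    against the reference (star topology, BLOSUM62, affine gaps) unless a
    pre-computed peptide alignment is supplied, in which case only
    back-translation is performed. Columns gapped in the reference are then
    removed, mapping the alignment to reference codon coordinates.
    Internal stop codons are permitted (leader regions) and translate to
    '*', which BLOSUM62's '*' row scores.
    """
    if ref_id not in cds_set:
        raise InvalidInputError(f"reference {ref_id!r} not among sequences")
    for sid, s in cds_set.items():
        if len(s) % 3:
            raise FrameError(f"{sid}: length {len(s)} not divisible by 3")

    ids = list(cds_set)
    if aligned_peptides is not None:
        rows = {sid: back_translate(aligned_peptides[sid], cds_set[sid]) for sid in ids}
        return map_to_reference(CodonAlignment(ids=ids, ref_id=ref_id, rows=rows))

    aligner = _peptide_aligner()
    peps = {sid: translate_cds(s) for sid, s in cds_set.items()}
    ref_pep = peps[ref_id]
    ref_codons = [cds_set[ref_id][i : i + 3] for i in range(0, len(cds_set[ref_id]), 3)]
    rows: dict[str, list[str]] = {ref_id: ref_codons}
    for sid in ids:
        if sid == ref_id:
            continue
        aln = aligner.align(ref_pep, peps[sid])[0]
        ref_aln, other_aln = str(aln[0]), str(aln[1])
        other_row = back_translate(other_aln, cds_set[sid])
        # keep only columns where the reference contributes a residue
        row = [
            other_row[k] for k, aa in enumerate(ref_aln) if aa != "-"
        ]
        rows[sid] = row
    return CodonAlignment(ids=ids, ref_id=ref_id, rows=rows)


# ---------------------------------------------------------------------------
# Consensus, tallies, residue conservation (three-frame re-chunking)
# ---------------------------------------------------------------------------

def _modal(values: Sequence[str], ref_value: Optional[str]) -> str:
    """Mode with reference-first then lexicographic tie-breaking."""
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    modes = sorted(v for v, n in counts.items() if n == best)
    if ref_value is not None and ref_value in modes:
        return ref_value
    return modes[0]


def rechunk_frame(a: CodonAlignment, frame_label: int) -> CodonAlignment:
    """Re-derive codon columns by shifting the reference chunking.

    Frame 1 is the alignment as given; frames 2/3 shift the start of the
    codon grid by 1/2 nt on the underlying nucleotide alignment. Codons
    spanning a gap character become gap codons.
    """
    if frame_label not in (1, 2, 3):
        raise InvalidInputError(f"frame_label must be 1, 2 or 3, got {frame_label}")
    if frame_label == 1:
        return a
    offset = frame_label - 1
    n_nt = 3 * a.length
    ncols = (n_nt - offset) // 3
    rows: dict[str, list[str]] = {}
    for sid in a.ids:
        nts = a.nt_row(sid)
        row = []
        for j in range(ncols):
            c = nts[offset + 3 * j : offset + 3 * j + 3]
            row.append(GAP_CODON if "-" in c else c)
        rows[sid] = row
    return CodonAlignment(ids=list(a.ids), ref_id=a.ref_id, rows=rows)


def consensus_codons(a: CodonAlignment) -> list[str]:
    """Per-column modal codon over non-gap entries (ref-first tie-break)."""
    if a.length == 0:
        raise InvalidInputError("empty alignment")
    out = []
    for j in range(a.length):
        col = a.column(j)
        non_gap = [c for c in col.values() if c != GAP_CODON]
        if not non_gap:
            raise InvalidInputError(f"all-gap column {j}")
        ref_c = col[a.ref_id]
        out.append(_modal(non_gap, ref_c if ref_c != GAP_CODON else None))
    return out


@dataclass
class SubstitutionTally:
    syn: int = 0
    nonsyn: int = 0
    stops: int = 0
    masked: int = 0
    per_column: Optional[list[dict[str, int]]] = None


def tally_substitutions(
    a: CodonAlignment, frame_label: int = 1, per_column: bool = False
) -> SubstitutionTally:
    """Classify every non-consensus codon against the column consensus.

    A deviant codon counts once (codon-level, not per-nucleotide):
    synonymous when it encodes the consensus amino acid, stop when it is a
    stop while the consensus is not, otherwise nonsynonymous. Gap cells and
    codons containing N are masked.
    """
    fa = rechunk_frame(a, frame_label)
    cons = consensus_codons(fa)
    tally = SubstitutionTally(per_column=[] if per_column else None)
    for j in range(fa.length):
        col = fa.column(j)
        cj = cons[j]
        aa_cons = translate_codon(cj)
        counts = {"syn": 0, "nonsyn": 0, "stops": 0, "masked": 0}
        for sid in fa.ids:
            c = col[sid]
            if c == GAP_CODON or "N" in c:
                counts["masked"] += 1
                continue
            if c == cj:
                continue
            aa = translate_codon(c)
            if aa == "*" and aa_cons != "*":
                counts["stops"] += 1
            elif aa == aa_cons:
                counts["syn"] += 1
            else:
                counts["nonsyn"] += 1
        tally.syn += counts["syn"]
        tally.nonsyn += counts["nonsyn"]
        tally.stops += counts["stops"]
        tally.masked += counts["masked"]
        if per_column:
            tally.per_column.append(counts)
    return tally


def residue_conservation(a: CodonAlignment) -> list[float]:
    """Per reference column: fraction of non-gap rows matching the modal
    amino acid (ref-first tie-break)."""
    if a.length == 0:
        raise InvalidInputError("empty alignment")
    out = []
    for j in range(a.length):
        col = a.column(j)
        aas = {sid: translate_codon(c) for sid, c in col.items() if c != GAP_CODON}
        if not aas:
            out.append(float("nan"))
            continue
        modal = _modal(list(aas.values()), aas.get(a.ref_id))
        out.append(sum(1 for v in aas.values() if v == modal) / len(aas))
    return out


# ---------------------------------------------------------------------------
# NG86 machinery: per-codon site fractions and pathway-averaged differences
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(S, N) site fractions of a sense codon.

    Changes to stop codons are excluded from the mutational opportunity
    and each position renormalized (s_j = syn / (3 - stops)), so S + N = 3
    exactly while stop-creating changes count as neither class.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for j in range(3):
        syn = stops = 0
        for nt in NUCLEOTIDES:
            if nt == codon[j]:
                continue
            mut_aa = GENETIC_CODE[codon[:j] + nt + codon[j + 1 :]]
            if mut_aa == "*":
                stops += 1
            elif mut_aa == aa:
                syn += 1
        if stops < 3:
            s += syn / (3 - stops)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two sense codons.

    Multi-nucleotide differences are resolved by equal-weight averaging
    over all orderings of the single-nucleotide steps; pathways passing
    through a stop codon are excluded (all-pathway average if every
    pathway is blocked).
    """
    diff = [j for j in range(3) if c1[j] != c2[j]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for j in order:
            nxt = cur[:j] + c2[j] + cur[j + 1 :]
            if GENETIC_CODE[nxt] == "*":
                blocked = True
            steps.append((GENETIC_CODE[cur] == GENETIC_CODE[nxt], blocked))
            cur = nxt
        syn = sum(1 for is_syn, _ in steps if is_syn)
        paths.append((syn, len(diff) - syn, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    use = open_paths if open_paths else [(s, n) for s, n, _ in paths]
    syn = sum(s for s, _ in use) / len(use)
    return syn, len(diff) - syn


def _usable(codon: str) -> bool:
    return (
        codon != GAP_CODON
        and "N" not in codon
        and "-" not in codon
        and GENETIC_CODE.get(codon, "*") != "*"
    )


def _pair_column_stats(a: CodonAlignment, start: int, end: int):
    """Per (pair, column) NG86 quantities for reuse by the estimators.

    Returns arrays of shape (n_pairs, n_cols): sd, nd (pathway-averaged
    differences), ss, ns (pair-averaged site fractions), cmp (1 where the
    codon pair was comparable). Pairs are reference vs each other row.
    """
    others = a.other_ids
    if not others:
        raise InvalidInputError("alignment has no non-reference rows")
    if end <= start:
        raise InvalidRegionError(f"empty region [{start}, {end})")
    if start < 0 or end > a.length:
        raise InvalidRegionError(
            f"region [{start}, {end}) outside alignment of {a.length} codons"
        )
    ncol = end - start
    sd = np.zeros((len(others), ncol))
    nd = np.zeros_like(sd)
    ss = np.zeros_like(sd)
    ns = np.zeros_like(sd)
    cmp_ = np.zeros_like(sd)
    ref = a.ref_codons
    for p, sid in enumerate(others):
        row = a.rows[sid]
        for k, j in enumerate(range(start, end)):
            c1, c2 = ref[j], row[j]
            if not (_usable(c1) and _usable(c2)):
                continue
            s1, n1 = ng86_site_counts(c1)
            s2, n2 = ng86_site_counts(c2)
            dsyn, dnon = ng86_path_counts(c1, c2)
            sd[p, k] = dsyn
            nd[p, k] = dnon
            ss[p, k] = (s1 + s2) / 2
            ns[p, k] = (n1 + n2) / 2
            cmp_[p, k] = 1.0
    return others, sd, nd, ss, ns, cmp_


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); requires p < 3/4."""
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass
class DnDsEstimate:
    dN: Optional[float]
    dS: Optional[float]
    omega: Optional[float]
    S_sites: float
    N_sites: float
    n_codons: float
    n_pairs: int
    n_saturated: int
    status: str  # ok | undefined | all_saturated
    per_pair: list[dict] = field(default_factory=list)


def _estimate_from_sums(sd, nd, ss, ns, cmp_) -> DnDsEstimate:
    """Pool per-pair NG86 estimates, weighting by compared codons."""
    n_pairs = sd.shape[0]
    per_pair = []
    w_sum = 0.0
    dn_sum = ds_sum = 0.0
    s_sites = n_sites = ncod = 0.0
    n_sat = 0
    for p in range(n_pairs):
        n_cmp = float(cmp_[p].sum())
        if n_cmp == 0:
            continue
        S = float(ss[p].sum())
        N = float(ns[p].sum())
        pS = float(sd[p].sum()) / S if S > 0 else 0.0
        pN = float(nd[p].sum()) / N if N > 0 else 0.0
        if pS >= 0.75 or pN >= 0.75:
            n_sat += 1
            per_pair.append({"pair": p, "saturated": True, "pS": pS, "pN": pN})
            continue
        dS = float(jukes_cantor(pS))
        dN = float(jukes_cantor(pN))
        per_pair.append(
            {"pair": p, "saturated": False, "pS": pS, "pN": pN, "dS": dS, "dN": dN,
             "n_codons": n_cmp}
        )
        w_sum += n_cmp
        dn_sum += n_cmp * dN
        ds_sum += n_cmp * dS
        s_sites += S
        n_sites += N
        ncod += n_cmp
    if w_sum == 0:
        status = "all_saturated" if n_sat else "undefined"
        return DnDsEstimate(
            dN=None, dS=None, omega=None, S_sites=0.0, N_sites=0.0, n_codons=0.0,
            n_pairs=n_pairs, n_saturated=n_sat, status=status, per_pair=per_pair,
        )
    used = n_pairs - n_sat if n_pairs > n_sat else 1
    dN = dn_sum / w_sum
    dS = ds_sum / w_sum
    omega = dN / dS if dS > 0 else None
    return DnDsEstimate(
        dN=dN, dS=dS, omega=omega,
        S_sites=s_sites / used, N_sites=n_sites / used, n_codons=ncod / used,
        n_pairs=n_pairs, n_saturated=n_sat,
        status="ok" if omega is not None else "undefined",
        per_pair=per_pair,
    )


def ng86_dnds(
    a: CodonAlignment, region: Optional[tuple[int, int]] = None
) -> DnDsEstimate:
    """Counting-method dN/dS, pooled over reference-vs-other pairs.

    Site fractions are averaged over each pair, multi-nucleotide codon
    differences are pathway-averaged (stop-transiting pathways excluded),
    proportions are Jukes–Cantor corrected, and pairwise estimates are
    pooled with weights proportional to compared codons. A pair with
    p >= 3/4 is flagged saturated and excluded. omega is undefined when
    pooled dS = 0 (e.g. identical sequences or purely nonsynonymous
    divergence).
    """
    start, end = region if region is not None else (0, a.length)
    _, sd, nd, ss, ns, cmp_ = _pair_column_stats(a, start, end)
    return _estimate_from_sums(sd, nd, ss, ns, cmp_)


@dataclass
class BootstrapResult:
    boot_sd: Optional[float]
    ci99: Optional[tuple[float, float]]
    B: int
    n_defined: int
    n_undefined: int
    status: str  # ok | all_undefined


def bootstrap_dnds(
    a: CodonAlignment,
    region: Optional[tuple[int, int]] = None,
    B: int = 100,
    seed: int = 1729,
) -> BootstrapResult:
    """Codon-column bootstrap of the pooled omega.

    Columns of the region are resampled with replacement B times; omega is
    recomputed per replicate; replicates with undefined omega are dropped
    and counted. Reports the SD and the 0.5/99.5 percentile interval.
    """
    if B < 1:
        raise InvalidInputError("B must be >= 1")
    start, end = region if region is not None else (0, a.length)
    _, sd, nd, ss, ns, cmp_ = _pair_column_stats(a, start, end)
    rng = np.random.default_rng(seed)
    ncol = end - start
    omegas = []
    n_undef = 0
    for _ in range(B):
        idx = rng.integers(0, ncol, size=ncol)
        est = _estimate_from_sums(
            sd[:, idx], nd[:, idx], ss[:, idx], ns[:, idx], cmp_[:, idx]
        )
        if est.omega is None:
            n_undef += 1
        else:
            omegas.append(est.omega)
    if not omegas:
        return BootstrapResult(
            boot_sd=None, ci99=None, B=B, n_defined=0, n_undefined=n_undef,
            status="all_undefined",
        )
    arr = np.asarray(omegas)
    sd_val = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    lo, hi = np.percentile(arr, [0.5, 99.5])
    return BootstrapResult(
        boot_sd=sd_val, ci99=(float(lo), float(hi)), B=B,
        n_defined=len(arr), n_undefined=n_undef, status="ok",
    )


# ---------------------------------------------------------------------------
# Synonymous-site conservation (o/e in short windows)
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    ref_codon_start: int
    frame_label: int
    score: Optional[float]  # o/e ratio, or LRT score for coding windows
    p_value: Optional[float] = None
    n_contributing: float = 0.0
    omitted: bool = False


def syn_site_conservation(
    a: CodonAlignment,
    window: int = 5,
    region: Optional[tuple[int, int]] = None,
) -> list[WindowStat]:
    """Observed/expected synonymous substitutions in sliding windows.

    Per pair, the neutral synonymous rate r = (total synonymous
    differences) / (total synonymous sites) is estimated from the whole
    alignment (or region). Per window, O sums observed synonymous
    differences over pairs and E sums r_pair x synonymous sites; o/e < 1
    flags excess synonymous conservation, i.e. overlapping functional
    elements constraining silent sites. Significance is a one-sided
    Poisson mid-p value for observing as few as O events given E.
    """
    if window < 1:
        raise InvalidInputError("window must be >= 1")
    start, end = region if region is not None else (0, a.length)
    _, sd, nd, ss, ns, cmp_ = _pair_column_stats(a, start, end)
    ncol = end - start
    tot_sd = sd.sum(axis=1)
    tot_ss = ss.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(tot_ss > 0, tot_sd / np.maximum(tot_ss, 1e-300), 0.0)
    out: list[WindowStat] = []
    n_win = max(1, ncol - window + 1)
    for w0 in range(n_win):
        w1 = min(w0 + window, ncol)
        O = float(sd[:, w0:w1].sum())
        E = float((r * ss[:, w0:w1].sum(axis=1)).sum())
        masked_frac = 1.0 - float(cmp_[:, w0:w1].mean())
        stat = WindowStat(
            ref_codon_start=start + w0,
            frame_label=1,
            score=None,
            n_contributing=float(cmp_[:, w0:w1].sum()),
            omitted=masked_frac > 0.5,
        )
        if E > 0:
            stat.score = O / E
            # mid-p: P(X < O) + 0.5 P(X = O) under Poisson(E)
            k = int(round(O * 2)) / 2  # O may be half-integral (path averages)
            kf = int(np.floor(k))
            cdf_below = float(sps.poisson.cdf(kf - 1, E)) if kf >= 1 else 0.0
            pmf_at = float(sps.poisson.pmf(kf, E)) if abs(k - kf) < 1e-9 else 0.0
            extra = float(sps.poisson.pmf(kf, E)) if k > kf else 0.0
            stat.p_value = min(1.0, max(cdf_below + 0.5 * pmf_at + extra, 1e-300))
        else:
            stat.omitted = True
        out.append(stat)
    return out


# ---------------------------------------------------------------------------
# Coding-vs-noncoding likelihood ratio (simplified MLOGD, star topology)
# ---------------------------------------------------------------------------

_HAMMING = np.zeros((64, 64), dtype=int)
for _i, _c1 in enumerate(ALL_CODONS):
    for _j, _c2 in enumerate(ALL_CODONS):
        _HAMMING[_i, _j] = sum(1 for x, y in zip(_c1, _c2) if x != y)


@lru_cache(maxsize=8)
def _coding_weights(lam: float, eps: float) -> np.ndarray:
    """W[i, j] = amino-acid acceptability weight for codon i -> codon j.

    exp(lam * BLOSUM62[aa_i, aa_j]) with the matrix's '*' row covering
    stop codons on the reference side; substitutions INTO a stop from a
    sense codon receive the small weight eps before normalization.
    """
    B = substitution_matrices.load("BLOSUM62")
    W = np.zeros((64, 64))
    for i, ci in enumerate(ALL_CODONS):
        aai = GENETIC_CODE[ci]
        for j, cj in enumerate(ALL_CODONS):
            aaj = GENETIC_CODE[cj]
            if aaj == "*" and aai != "*":
                W[i, j] = eps
            else:
                W[i, j] = np.exp(lam * float(B[aai, aaj]))
    return W


def pairwise_nt_divergence(a: CodonAlignment) -> dict[str, float]:
    """Mismatch fraction per reference-vs-other pair over non-gap, non-N
    codon columns of the whole alignment."""
    ref = a.ref_codons
    out = {}
    for sid in a.other_ids:
        row = a.rows[sid]
        mm = n = 0
        for c1, c2 in zip(ref, row):
            if c1 == GAP_CODON or c2 == GAP_CODON or "N" in c1 or "N" in c2:
                continue
            n += 3
            mm += sum(1 for x, y in zip(c1, c2) if x != y)
        out[sid] = mm / n if n else 0.0
    return out


def coding_lrt_windows(
    a: CodonAlignment,
    window: int = 20,
    frame_label: int = 1,
    lam: float = 0.3,
    eps: float = 1e-3,
) -> list[WindowStat]:
    """Sliding-window coding-vs-noncoding log-likelihood ratio.

    For each non-reference row and gap-free codon site, the noncoding
    model treats the three nucleotides independently (match prob 1-p,
    each mismatch p/3, p the pair's global divergence); the coding model
    multiplies the same nucleotide term by an amino-acid acceptability
    weight and renormalizes over all target codons. The per-site
    contribution therefore reduces to log w(obs) - log Z(ref, pair).
    Positive window sums indicate coding-like constraint in the chosen
    frame. Windows with more than half of their cells masked by gaps are
    flagged omitted; sliding step is one codon.
    """
    fa = rechunk_frame(a, frame_label)
    pdiv = pairwise_nt_divergence(a)  # divergence measured once, frame-free
    W = _coding_weights(lam, eps)
    logW = np.log(W)
    others = fa.other_ids
    ncol = fa.length
    contrib = np.zeros((len(others), ncol))
    mask = np.zeros((len(others), ncol), dtype=bool)
    ref_idx = np.array(
        [CODON_INDEX.get(c, -1) for c in fa.ref_codons], dtype=int
    )
    # log Z per (pair, ref codon index): Z = sum_t ntterm(dist) * W[ref, t]
    for p, sid in enumerate(others):
        phat = min(max(pdiv[sid], 0.0), 0.999)
        dist_term = np.array([(1 - phat) ** (3 - d) * (phat / 3) ** d for d in range(4)])
        Zrow = (W * dist_term[_HAMMING]).sum(axis=1)  # per ref codon index
        logZ = np.log(Zrow)
        row = fa.rows[sid]
        for j in range(ncol):
            ri = ref_idx[j]
            ci = CODON_INDEX.get(row[j], -1)
            if ri < 0 or ci < 0:
                mask[p, j] = True
                continue
            contrib[p, j] = logW[ri, ci] - logZ[ri]
    out: list[WindowStat] = []
    truncated = window > ncol
    win = min(window, ncol)
    for w0 in range(max(1, ncol - win + 1)):
        w1 = w0 + win
        m = mask[:, w0:w1]
        c = contrib[:, w0:w1]
        masked_frac = float(m.mean()) if m.size else 1.0
        out.append(
            WindowStat(
                ref_codon_start=w0,
                frame_label=frame_label,
                score=float(np.where(m, 0.0, c).sum()),
                n_contributing=float((~m).sum()),
                omitted=masked_frac > 0.5 or truncated,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Homologous NCC conservation
# ---------------------------------------------------------------------------

@dataclass
class AnchorConservation:
    anchor: int  # reference codon index
    ref_codon: str
    n_species: int
    n_match_ref: int
    n_match_ncc: int
    n_absent: int
    codons: dict[str, str]
    windows: dict[str, str]


def ncc_conservation(
    a: CodonAlignment,
    anchors: Sequence[int],
    ncc_set: Sequence[str],
) -> list[AnchorConservation]:
    """Tabulate the codon at each homologous anchor across species.

    Anchors are reference codon indices (from align_codons coordinates).
    Counts exact matches to the reference codon and matches to any codon
    of the NCC set; species gapped at the anchor are counted absent.
    Alignment-space 11-mer context windows (gaps as N) are emitted for
    init_context.
    """
    ncc = set(ncc_set)
    out = []
    nt = {sid: a.nt_row(sid) for sid in a.ids}
    for anc in anchors:
        if not (0 <= anc < a.length):
            raise InvalidRegionError(f"anchor {anc} outside alignment")
        ref_c = a.ref_codons[anc]
        if ref_c == GAP_CODON:
            raise InvalidRegionError(f"anchor {anc} falls in a reference gap")
        codons: dict[str, str] = {}
        windows: dict[str, str] = {}
        n_ref = n_ncc = n_abs = 0
        for sid in a.other_ids:
            c = a.rows[sid][anc]
            if c == GAP_CODON:
                n_abs += 1
                continue
            codons[sid] = c
            if c == ref_c:
                n_ref += 1
            if c in ncc:
                n_ncc += 1
            p = 3 * anc
            raw = nt[sid][max(0, p - 6) : p + 5]
            raw = "N" * max(0, 6 - p) + raw.replace("-", "N")
            windows[sid] = raw + "N" * (11 - len(raw))
        out.append(
            AnchorConservation(
                anchor=anc, ref_codon=ref_c,
                n_species=len(a.other_ids), n_match_ref=n_ref,
                n_match_ncc=n_ncc, n_absent=n_abs,
                codons=codons, windows=windows,
            )
        )
    return out
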