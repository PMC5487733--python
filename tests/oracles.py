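"""Independent oracles for cross-checking the package's estimators.

Everything here is deliberately self-contained: its own genetic-code
table, its own pathway enumeration, its own scanning logic. Nothing is
imported from extorf.
"""

from itertools import permutations
from math import log

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)

CODE = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
STOPS = {c for c, a in CODE.items() if a == "*"}


def classify(consensus: str, codon: str) -> str:
    """Codon-level substitution class against a consensus codon."""
    if codon == consensus:
        return "identical"
    if CODE[codon] == "*" and CODE[consensus] != "*":
        return "stop"
    if CODE[codon] == CODE[consensus]:
        return "syn"
    return "nonsyn"


def site_counts(codon: str):
    """(S, N): stop-excluded renormalized synonymous site fractions."""
    s_total = 0.0
    for pos in range(3):
        syn = stops = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if CODE[mut] == "*":
                stops += 1
            elif CODE[mut] == CODE[codon]:
                syn += 1
        if stops < 3:
            s_total += syn / (3 - stops)
    return s_total, 3.0 - s_total


def path_counts(c1: str, c2: str):
    """(syn, nonsyn) differences by explicit pathway enumeration."""
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    if not diffs:
        return 0.0, 0.0
    tallies = []
    for order in permutations(diffs):
        cur = c1
        syn = non = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if CODE[nxt] == "*":
                blocked = True
            if CODE[nxt] == CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        tallies.append((syn, non, blocked))
    unblocked = [(s, n) for s, n, b in tallies if not b]
    use = unblocked if unblocked else [(s, n) for s, n, _ in tallies]
    return (
        sum(s for s, _ in use) / len(use),
        sum(n for _, n in use) / len(use),
    )


def pairwise_dnds(seq1: str, seq2: str):
    """Brute-force NG86 (dN, dS) for one codon-sequence pair.

    Returns (dN, dS) or None where a proportion is saturated (>= 3/4).
    Codons containing stops in either sequence are skipped.
    """
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if CODE[c1] == "*" or CODE[c2] == "*":
            continue
        s1, n1 = site_counts(c1)
        s2, n2 = site_counts(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = path_counts(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    if pS >= 0.75 or pN >= 0.75:
        return None
    jc = lambda p: -0.75 * log(1 - 4 * p / 3)
    return jc(pN), jc(pS)


def scan_ncc_bruteforce(seq: str, main_start: int, ncc_set, boundary: int):
    """Position-by-position NCC scan, independently of the package."""
    hits = []
    for p in range(0, boundary - 2):
        if (main_start - p) % 3 != 0:
            continue
        codon = seq[p : p + 3]
        if codon not in ncc_set:
            continue
        blocked = any(
            seq[q : q + 3] in STOPS for q in range(p, main_start - 2, 3)
        )
        if not blocked:
            hits.append((p, codon))
    return hits


def thread_codons(aligned_pep: str, cds: str):
    """Back-translation oracle: walk the peptide, consuming codons."""
    out = []
    i = 0
    for aa in aligned_pep:
        if aa == "-":
            out.append("---")
        else:
            out.append(cds[3 * i : 3 * i + 3])
            i += 1
    assert 3 * i == len(cds)
    return out
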