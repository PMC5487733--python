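"""Architecture-true synthetic data for every pipeline stage.

Three generators, each emitting a machine-readable truth record alongside
its output:

* make_transcript — a transcript whose 5' leader contains exactly the
  planted uORFs and in-frame NCCs (and nothing else that the scanners
  would call), built by constrained per-position sampling with a
  rejection cap and verified by re-scanning.
* evolve_alignment — a star-topology codon alignment evolved at a known
  dN/dS (omega), with optional synonymous-suppression blocks emulating
  overlapping functional elements.
* simulate_footprints — ribosome-footprint 5'-end reads with per-region
  densities and frame mixes, planted initiation peaks, and Poisson
  background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from ._defs import (
    DEFAULT_NCC_SET,
    GENETIC_CODE,
    NUCLEOTIDES,
    STOP_CODONS,
    GenerationError,
    InvalidInputError,
)
from .feature_scan import Transcript, annotate_architecture
from .riboseq_frame import (
    DEFAULT_A_SITE_OFFSET,
    DEFAULT_P_SITE_OFFSET,
)

SENSE_NON_STOP = tuple(c for c, aa in GENETIC_CODE.items() if aa != "*")


# ---------------------------------------------------------------------------
# Transcript architecture
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Planted 5'-leader architecture.

    uorf_specs: (start, n_codons) pairs, n_codons counting the stop codon,
    uORFs fully inside the leader. ncc_specs: (position, codon) pairs in
    the main frame. Positions are 0-based; main_start equals leader_len.
    """

    leader_len: int
    uorf_specs: list[tuple[int, int]] = field(default_factory=list)
    ncc_specs: list[tuple[int, str]] = field(default_factory=list)
    main_orf_codons: int = 50
    forbid_inframe_aug: bool = True
    forbid_inframe_stop: bool = True
    ncc_set: tuple[str, ...] = DEFAULT_NCC_SET
    max_attempts: int = 10_000

    def validate(self) -> None:
        L = self.leader_len
        if L < 0 or self.main_orf_codons < 2:
            raise InvalidInputError("leader_len >= 0 and main_orf_codons >= 2 required")
        fixed: set[int] = set()
        for start, n in self.uorf_specs:
            if n < 2:
                raise InvalidInputError("uORFs need at least start + stop codons")
            if start < 0 or start + 3 * n > L:
                raise InvalidInputError(f"uORF at {start} not inside leader")
            if start % 3 == L % 3:
                # a main-frame uORF carries a main-frame AUG and stop,
                # contradicting the scan semantics and stop constraints
                raise InvalidInputError(
                    f"uORF at {start} lies in the main frame; plant it in a "
                    "shifted frame or drop it"
                )
            span = set(range(start, start + 3 * n))
            if span & fixed:
                raise InvalidInputError("overlapping planted uORFs")
            fixed |= span
        boundary = _planted_boundary(self)
        for pos, codon in self.ncc_specs:
            if pos >= boundary:
                raise InvalidInputError(
                    f"NCC at {pos} lies at/after the scan boundary {boundary} "
                    "and could never be recovered"
                )
            if codon not in self.ncc_set:
                raise InvalidInputError(f"{codon} not in the configured NCC set")
            if pos % 3 != L % 3:
                raise InvalidInputError(f"NCC at {pos} not in frame with main_start {L}")
            if pos < 0 or pos + 3 > L:
                raise InvalidInputError(f"NCC at {pos} not inside leader")
            span = set(range(pos, pos + 3))
            if span & fixed:
                raise InvalidInputError("planted NCC overlaps another planted feature")
            fixed |= span


def _planted_boundary(spec: ArchitectureSpec) -> int:
    starts = sorted(s for s, _ in spec.uorf_specs)
    if len(starts) >= 2:
        return starts[1]
    if len(starts) == 1:
        return starts[0]
    return spec.leader_len


def _build_fixed_map(spec: ArchitectureSpec, rng: np.random.Generator):
    """Fixed nucleotides (planted starts/stops/NCC codons) and the uORF
    body frames that must stay stop-free."""
    fixed: dict[int, str] = {}
    body_frames: list[tuple[int, int]] = []  # (body_start, stop_codon_start)
    for start, n in spec.uorf_specs:
        stop_start = start + 3 * (n - 1)
        for k, nt in enumerate("ATG"):
            fixed[start + k] = nt
        stop = "TAA" if rng.random() < 0.5 else "TGA"
        for k, nt in enumerate(stop):
            fixed[stop_start + k] = nt
        body_frames.append((start + 3, stop_start))
    for pos, codon in spec.ncc_specs:
        for k, nt in enumerate(codon):
            fixed[pos + k] = nt
    return fixed, body_frames


def _trigram_ok(
    tri: str,
    j: int,
    spec: ArchitectureSpec,
    planted_atg: set[int],
    planted_ncc: set[int],
    boundary: int,
    min_ncc_pos: Optional[int],
    body_frames: list[tuple[int, int]],
) -> bool:
    L = spec.leader_len
    if tri == "ATG" and j not in planted_atg:
        return False
    if j % 3 == L % 3:  # main frame
        if tri in STOP_CODONS:
            if spec.forbid_inframe_stop:
                return False
            if min_ncc_pos is not None and j >= min_ncc_pos:
                return False  # would disqualify a planted NCC
        if tri in spec.ncc_set and j not in planted_ncc and j < boundary:
            return False
    if tri in STOP_CODONS:
        for body_start, stop_start in body_frames:
            if body_start <= j < stop_start and (j - body_start) % 3 == 0:
                return False  # premature uORF termination
    return True


def make_transcript(
    spec: ArchitectureSpec, seed: int = 1729, transcript_id: str = "synthetic"
) -> tuple[Transcript, dict]:
    """Sample a transcript realizing exactly the planted architecture.

    The leader is sampled position by position under trigram constraints
    (no unplanned AUG in any frame, no unplanned in-frame NCC upstream of
    the boundary, no forbidden in-frame stop, no premature uORF stop),
    then verified by re-running the scanners; failed attempts restart up
    to spec.max_attempts before a GenerationError with diagnostics.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    planted_atg = {s for s, _ in spec.uorf_specs}
    planted_ncc = {p for p, _ in spec.ncc_specs}
    boundary = _planted_boundary(spec)
    min_ncc = min(planted_ncc) if planted_ncc else None
    L = spec.leader_len
    last_reason = "no attempts made"
    fixed_conflicts = 0
    for _attempt in range(spec.max_attempts):
        fixed, body_frames = _build_fixed_map(spec, rng)
        # fully-fixed trigrams that violate a constraint can never be
        # repaired by sampling; bail out fast instead of exhausting the DFS
        conflict = None
        for j in range(L - 2):
            if j in fixed and j + 1 in fixed and j + 2 in fixed:
                tri = fixed[j] + fixed[j + 1] + fixed[j + 2]
                if not _trigram_ok(
                    tri, j, spec, planted_atg, planted_ncc, boundary,
                    min_ncc, body_frames,
                ):
                    conflict = f"planted trigram {tri} at {j} violates constraints"
                    break
        if conflict:
            last_reason = conflict
            fixed_conflicts += 1
            if fixed_conflicts >= 8:  # only the stop-codon draw varies
                break
            continue

        def options(i: int) -> list[str]:
            if i in fixed:
                return [fixed[i]]
            return list(rng.permutation(list(NUCLEOTIDES)))

        # depth-first with backtracking: a legal trigram ending at i can
        # still leave position i+2 without any legal completion (e.g. an
        # 'AT' prefix at a main-frame position), so dead ends step back.
        leader: list[str] = []
        stacks: list[list[str]] = [options(0)] if L else []
        steps = 0
        ok = L == 0
        while stacks:
            steps += 1
            if steps > 200 * L:
                last_reason = "backtracking budget exhausted"
                break
            i = len(leader)
            if not stacks[-1]:
                stacks.pop()
                if leader:
                    leader.pop()
                continue
            nt = stacks[-1].pop()
            good = True
            if i >= 2:
                tri = leader[i - 2] + leader[i - 1] + nt
                good = _trigram_ok(
                    tri, i - 2, spec, planted_atg, planted_ncc, boundary,
                    min_ncc, body_frames,
                )
            if not good:
                continue
            leader.append(nt)
            if len(leader) == L:
                ok = True
                break
            stacks.append(options(len(leader)))
        if not ok:
            if stacks == []:
                last_reason = "constraint set unsatisfiable for this attempt"
            continue
        body = rng.choice(SENSE_NON_STOP, size=spec.main_orf_codons - 2)
        seq = "".join(leader) + "ATG" + "".join(body) + "TAA"
        t = Transcript(
            id=transcript_id, seq=seq, main_start=L,
            main_end=L + 3 * spec.main_orf_codons,
        )
        rep = annotate_architecture(t, ncc_set=spec.ncc_set)
        got_uorfs = sorted((f.start, f.n_codons) for f in rep.uorfs)
        want_uorfs = sorted(spec.uorf_specs)
        got_nccs = sorted((c.pos, c.codon) for c in rep.ncc_candidates)
        want_nccs = sorted(spec.ncc_specs)
        if got_uorfs != want_uorfs:
            last_reason = f"uORF mismatch: got {got_uorfs}, want {want_uorfs}"
            continue
        if rep.boundary != boundary or got_nccs != want_nccs:
            last_reason = f"NCC mismatch: got {got_nccs}, want {want_nccs}"
            continue
        if spec.forbid_inframe_stop and not rep.extension.reaches_5prime:
            last_reason = "unexpected in-frame stop in leader"
            continue
        truth = {
            "transcript_id": transcript_id,
            "leader_len": L,
            "main_start": L,
            "main_end": L + 3 * spec.main_orf_codons,
            "uorfs": [list(u) for u in sorted(spec.uorf_specs)],
            "nccs": [[p, c] for p, c in sorted(spec.ncc_specs)],
            "boundary": boundary,
            "reaches_5prime": bool(rep.extension.reaches_5prime),
            "ext_codons": rep.extension.ext_codons,
            "seed": seed,
        }
        return t, truth
    raise GenerationError(
        f"spec unsatisfiable within {spec.max_attempts} attempts; last failure: "
        f"{last_reason}"
    )


def cpc1_like_spec() -> ArchitectureSpec:
    """Synthetic stand-in for the N. crassa cpc-1 5' leader architecture.

    The real leader sequence is not redistributed here; this spec plants
    the published architecture — a 703-nt leader with two AUG-initiated
    uORFs (uORF1 short, uORF2 tens of codons, both outside the main
    frame), eight in-frame NCCs upstream of the uORF2 AUG with composition
    3x AUC, 2x ACG, 2x AUU, 1x CUG (5'->3': AUC, ACG, AUC, AUC, AUU, CUG,
    AUU, ACG), and no in-frame stop anywhere in the leader, so the
    N-terminal extension reaches the transcript 5' end. Coordinates are
    invented; the architecture is the published one.
    """
    return ArchitectureSpec(
        leader_len=703,
        uorf_specs=[(98, 4), (381, 42)],
        ncc_specs=[
            (40, "ATC"), (76, "ACG"), (130, "ATC"), (175, "ATC"),
            (220, "ATT"), (262, "CTG"), (301, "ATT"), (340, "ACG"),
        ],
        main_orf_codons=60,
    )


def make_cpc1_like(seed: int = 1729) -> tuple[Transcript, dict]:
    """The synthetic cpc-1-like worked-example transcript."""
    return make_transcript(cpc1_like_spec(), seed=seed, transcript_id="cpc1_like")


# ---------------------------------------------------------------------------
# Codon-alignment evolution at known omega
# ---------------------------------------------------------------------------

@dataclass
class EvolutionSpec:
    """Star-topology evolution parameters.

    mu is the expected number of nucleotide change proposals per site per
    branch; synonymous proposals are accepted with the block multiplier
    (1.0 outside suppression blocks) and nonsynonymous proposals with
    probability omega (for omega > 1 the acceptance pair is rescaled so
    the nonsyn/syn ratio still equals omega). Proposals creating stop
    codons are rejected.
    """

    n_species: int = 20
    n_codons: int = 300
    omega: float = 0.35
    mu: float = 0.08
    syn_suppression_blocks: list[tuple[int, int, float]] = field(default_factory=list)
    #: include the unevolved ancestor as the reference row; reference-vs-
    #: other pairs are then independent, which the pairwise statistics
    #: assume (an extant reference shares its branch across all pairs)
    root_as_ref: bool = True
    #: conservative amino-acid substitutions are more probable than radical
    #: ones in real coding sequences; nonsynonymous acceptance is graded by
    #: exp(lambda * (B[a1,a2] - B[a1,a1])), normalized to mean 1 over the
    #: one-step nonsynonymous neighbourhood so the average acceptance stays
    #: omega. Set to 0 for ungraded (uniform) acceptance.
    conservative_lambda: float = 0.3

    def validate(self) -> None:
        if self.omega <= 0 or not (0 <= self.mu < 0.75):
            raise InvalidInputError("need omega > 0 and 0 <= mu < 0.75")
        if self.n_species < 2 or self.n_codons < 1:
            raise InvalidInputError("need >= 2 species and >= 1 codon")
        for s, e, m in self.syn_suppression_blocks:
            if not (0 <= s < e <= self.n_codons) or m < 0:
                raise InvalidInputError(f"bad suppression block ({s}, {e}, {m})")


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free coding sequence."""
    return "".join(rng.choice(SENSE_NON_STOP, size=n_codons))


@lru_cache(maxsize=4)
def _acceptability(lam: float) -> tuple[dict[tuple[str, str], float], float]:
    """Mean-1 acceptability grading over one-step nonsynonymous changes.

    Returns ({(codon, mutated_codon): gamma}, gamma_max) where gamma is
    exp(lam * (B[a1, a2] - B[a1, a1])) divided by its mean over all
    ordered sense-codon single-nucleotide nonsynonymous neighbours.
    """
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    raw: dict[tuple[str, str], float] = {}
    for c1, aa1 in GENETIC_CODE.items():
        if aa1 == "*":
            continue
        for j in range(3):
            for nt in NUCLEOTIDES:
                if nt == c1[j]:
                    continue
                c2 = c1[:j] + nt + c1[j + 1 :]
                aa2 = GENETIC_CODE[c2]
                if aa2 == "*" or aa2 == aa1:
                    continue
                raw[(c1, c2)] = float(np.exp(lam * (B[aa1, aa2] - B[aa1, aa1])))
    mean = sum(raw.values()) / len(raw)
    gamma = {k: v / mean for k, v in raw.items()}
    return gamma, max(gamma.values())


def evolve_alignment(
    spec: EvolutionSpec,
    seed: int = 1729,
    root_cds: Optional[str] = None,
):
    """Evolve a star-topology codon alignment from a common root.

    Returns (CodonAlignment, truth dict). The reference is the first
    species (itself evolved). No indels are simulated, so the alignment is
    already reference-mapped.
    """
    from .codon_evo import CodonAlignment  # local import avoids cycles

    spec.validate()
    rng = np.random.default_rng(seed)
    if root_cds is None:
        root_cds = random_cds(spec.n_codons, rng)
    if len(root_cds) % 3:
        raise InvalidInputError("root CDS length not divisible by 3")
    n_codons = len(root_cds) // 3
    for i in range(0, len(root_cds), 3):
        if GENETIC_CODE[root_cds[i : i + 3]] == "*":
            raise InvalidInputError("root CDS contains an internal stop codon")

    s_mult = np.ones(n_codons)
    for s, e, m in spec.syn_suppression_blocks:
        s_mult[s:e] = m
    omega = spec.omega
    if spec.conservative_lambda > 0:
        gamma, gamma_max = _acceptability(spec.conservative_lambda)
    else:
        gamma, gamma_max = {}, 1.0
    # global scale keeps every acceptance probability <= 1 while preserving
    # the nonsyn/syn rate ratio (= omega) exactly
    scale = 1.0 / max(1.0, omega * gamma_max, float(s_mult.max()))

    ids = [f"sp{i:03d}" for i in range(spec.n_species)]
    rows: dict[str, list[str]] = {}
    L = len(root_cds)
    if spec.root_as_ref:
        rows["root"] = [root_cds[j : j + 3] for j in range(0, L, 3)]
    for sid in ids:
        seq = list(root_cds)
        sites = np.nonzero(rng.random(L) < spec.mu)[0]
        for i in sites:
            cod_i = i // 3
            off = i % 3
            cur = "".join(seq[3 * cod_i : 3 * cod_i + 3])
            alts = [n for n in NUCLEOTIDES if n != seq[i]]
            new_nt = alts[rng.integers(0, 3)]
            new = cur[:off] + new_nt + cur[off + 1 :]
            if GENETIC_CODE[new] == "*":
                continue
            if GENETIC_CODE[new] == GENETIC_CODE[cur]:
                p_acc = s_mult[cod_i] * scale
            else:
                p_acc = omega * gamma.get((cur, new), 1.0) * scale
            if rng.random() < p_acc:
                seq[i] = new_nt
        rows[sid] = ["".join(seq[j : j + 3]) for j in range(0, L, 3)]
    all_ids = (["root"] if spec.root_as_ref else []) + ids
    aln = CodonAlignment(ids=all_ids, ref_id=all_ids[0], rows=rows)
    truth = {
        "omega": omega,
        "mu": spec.mu,
        "n_species": spec.n_species,
        "n_codons": n_codons,
        "syn_suppression_blocks": [list(b) for b in spec.syn_suppression_blocks],
        "seed": seed,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# Ribosome-footprint simulation
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    label: str
    start: int
    end: int
    density: float  # expected reads per nt
    frame_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)


@dataclass
class FootprintSpec:
    regions: list[RegionSpec] = field(default_factory=list)
    peaks: list[tuple[int, int]] = field(default_factory=list)  # (codon pos, reads)
    length_probs: dict[int, float] = field(
        default_factory=lambda: {28: 0.25, 29: 0.25, 30: 0.25, 31: 0.25}
    )
    n_reads: Optional[int] = None  # fixed total for region reads; else Poisson
    background_rate: float = 0.05  # reads per nt, Poisson
    a_site_offset: int = DEFAULT_A_SITE_OFFSET
    p_site_offset: int = DEFAULT_P_SITE_OFFSET

    def validate(self, transcript_len: int) -> None:
        for r in self.regions:
            if not (0 <= r.start < r.end <= transcript_len):
                raise InvalidInputError(f"region {r.label} outside transcript")
            if r.density < 0:
                raise InvalidInputError("densities must be >= 0")
            if abs(sum(r.frame_mix) - 1.0) > 1e-9:
                raise InvalidInputError(f"frame mix of {r.label} does not sum to 1")


def simulate_footprints(
    t: Transcript, spec: FootprintSpec, seed: int = 1729
) -> tuple[list[tuple[str, int, int]], dict]:
    """Sample footprint reads as (transcript_id, 5'-end, length) triples.

    A-site positions are drawn per region by density and frame mix and
    converted to 5' ends by subtracting the A-site offset (reads whose
    5' end would fall off the transcript are dropped); planted peak reads
    place their P site exactly on the planted codon start; Poisson
    background is added per position.
    """
    spec.validate(len(t.seq))
    rng = np.random.default_rng(seed)
    lengths = sorted(spec.length_probs)
    lprobs = np.array([spec.length_probs[l] for l in lengths], dtype=float)
    lprobs = lprobs / lprobs.sum()

    def draw_len(n: int) -> np.ndarray:
        return rng.choice(lengths, size=n, p=lprobs)

    reads: list[tuple[str, int, int]] = []
    region_counts: dict[str, int] = {}
    weights = np.array([r.density * (r.end - r.start) for r in spec.regions])
    if spec.n_reads is not None and len(spec.regions):
        totals = rng.multinomial(spec.n_reads, weights / weights.sum())
    else:
        totals = rng.poisson(weights) if len(weights) else np.array([], dtype=int)
    for r, n in zip(spec.regions, totals):
        frame_pos = []
        for f in range(3):
            first = r.start + ((t.main_start + f - r.start) % 3)
            frame_pos.append(np.arange(first, r.end, 3))
        frames = rng.choice(3, size=int(n), p=np.asarray(r.frame_mix))
        lens = draw_len(int(n))
        kept = 0
        for f, ln in zip(frames, lens):
            pool = frame_pos[f]
            if pool.size == 0:
                continue
            a_pos = int(pool[rng.integers(0, pool.size)])
            x = a_pos - spec.a_site_offset
            if x < 0:
                continue
            reads.append((t.id, x, int(ln)))
            kept += 1
        region_counts[r.label] = kept
    for codon_pos, n in spec.peaks:
        x = codon_pos - spec.p_site_offset
        if x < 0:
            raise InvalidInputError(f"peak codon {codon_pos} too close to 5' end")
        for ln in draw_len(int(n)):
            reads.append((t.id, x, int(ln)))
    if spec.background_rate > 0:
        bg = rng.poisson(spec.background_rate, size=len(t.seq))
        for x in np.nonzero(bg)[0]:
            for ln in draw_len(int(bg[x])):
                reads.append((t.id, int(x), int(ln)))
    truth = {
        "transcript_id": t.id,
        "regions": [
            {
                "label": r.label, "start": r.start, "end": r.end,
                "density": r.density, "frame_mix": list(r.frame_mix),
                "n_sampled": region_counts.get(r.label, 0),
            }
            for r in spec.regions
        ],
        "peaks": [[p, n] for p, n in spec.peaks],
        "a_site_offset": spec.a_site_offset,
        "p_site_offset": spec.p_site_offset,
        "n_reads": len(reads),
        "seed": seed,
    }
    return reads, truth
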