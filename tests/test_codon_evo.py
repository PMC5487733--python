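import numpy as np
import pytest

from extorf import (
    CodonAlignment,
    FrameError,
    InvalidInputError,
    InvalidRegionError,
    align_codons,
    bootstrap_dnds,
    coding_lrt_windows,
    consensus_codons,
    ncc_conservation,
    ng86_dnds,
    residue_conservation,
    syn_site_conservation,
    tally_substitutions,
)
from extorf.codon_evo import back_translate, ng86_path_counts, ng86_site_counts
from extorf.synthetic_data import EvolutionSpec, evolve_alignment, random_cds

import oracles


def _aln(rows, ref_id=None):
    ids = list(rows)
    return CodonAlignment(ids=ids, ref_id=ref_id or ids[0], rows=rows)


class TestAlignCodons:
    def test_identical_sequences_align_without_gaps(self):
        a = align_codons({"r": "ATGAAACCC", "o": "ATGAAACCC"}, "r")
        assert a.length == 3 and a.rows["o"] == ["ATG", "AAA", "CCC"]

    def test_reference_gap_columns_removed(self):
        a = align_codons({"r": "ATGAAA", "o": "ATGGGGAAA"}, "r")
        assert a.length == 2
        assert a.rows["o"] == ["ATG", "AAA"]

    def test_frame_error(self):
        with pytest.raises(FrameError):
            align_codons({"r": "ATGA", "o": "ATG"}, "r")

    def test_back_translation_matches_threading_oracle(self):
        rng = np.random.default_rng(11)
        for i in range(20):
            ref = random_cds(50, rng)
            ins_at = int(rng.integers(1, 49))
            other = ref[: 3 * ins_at] + random_cds(3, rng) + ref[3 * ins_at :]
            a = align_codons({"ref": ref, "oth": other}, "ref")
            # independently thread the other CDS through the aligned peptide
            pep = "".join(
                "-" if c == "---" else "X" for c in a.rows["oth"]
            )
            kept = [c for c in a.rows["oth"] if c != "---"]
            threaded = oracles.thread_codons(
                pep.replace("X", "A"), "".join(kept)
            )
            assert [c for c in threaded if c != "---"] == kept
            # the reference coordinates must be preserved exactly
            assert a.ref_codons == [ref[j : j + 3] for j in range(0, len(ref), 3)]

    def test_back_translate_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            back_translate("MK", "ATGAAACCC")


class TestConsensus:
    def test_modal_codon(self):
        a = _aln({"a": ["AAA"], "b": ["AAA"], "c": ["AAG"]})
        assert consensus_codons(a) == ["AAA"]

    def test_reference_tie_break(self):
        a = _aln({"a": ["GAA"], "b": ["AAA"]}, ref_id="a")
        assert consensus_codons(a) == ["GAA"]

    def test_lexicographic_tie_break_without_reference_mode(self):
        a = _aln({"a": ["CCC"], "b": ["AAA"], "c": ["GGG"], "d": ["AAA"], "e": ["GGG"]})
        # modes {AAA, GGG}; ref CCC not among them -> smallest mode
        assert consensus_codons(a) == ["AAA"]

    def test_identical_rows(self):
        a = _aln({"a": ["ATG", "AAA"], "b": ["ATG", "AAA"]})
        assert consensus_codons(a) == ["ATG", "AAA"]


class TestTally:
    def test_identical_rows_zero(self):
        a = _aln({"a": ["ATG"], "b": ["ATG"], "c": ["ATG"]})
        t = tally_substitutions(a)
        assert (t.syn, t.nonsyn, t.stops) == (0, 0, 0)

    @pytest.mark.parametrize(
        "col,expect",
        [
            (["AAA", "AAA", "AAG"], (1, 0, 0)),  # Lys/Lys
            (["AAA", "AAA", "GAA"], (0, 1, 0)),  # Lys->Glu
            (["TGG", "TGA", "TGG"], (0, 0, 1)),  # Trp consensus, TGA stop
        ],
    )
    def test_classification_examples(self, col, expect):
        a = _aln({f"s{i}": [c] for i, c in enumerate(col)})
        t = tally_substitutions(a)
        assert (t.syn, t.nonsyn, t.stops) == expect

    def test_invalid_frame(self):
        a = _aln({"a": ["ATG"], "b": ["ATG"]})
        with pytest.raises(InvalidInputError):
            tally_substitutions(a, frame_label=4)

    def test_frame_rechunking_shifts_grid(self):
        rows = {"a": ["ATG", "AAA", "CCC"], "b": ["ATG", "AAA", "CCC"]}
        a = _aln(rows)
        t2 = tally_substitutions(a, frame_label=2)
        assert (t2.syn, t2.nonsyn, t2.stops) == (0, 0, 0)

    def test_agrees_with_code_oracle_for_all_sense_pairs(self):
        """Codon-level classification matches an independent genetic-code
        lookup for every ordered sense-codon pair."""
        sense = [c for c, aa in oracles.CODE.items() if aa != "*"]
        for cons in sense:
            for obs in sense:
                a = _aln({"r": [cons], "s": [cons], "o": [obs]}, ref_id="r")
                t = tally_substitutions(a)
                want = oracles.classify(cons, obs)
                got = {
                    (1, 0, 0): "syn",
                    (0, 1, 0): "nonsyn",
                    (0, 0, 1): "stop",
                    (0, 0, 0): "identical",
                }[(t.syn, t.nonsyn, t.stops)]
                assert got == want, (cons, obs)


class TestResidueConservation:
    def test_identical_rows(self):
        a = _aln({"a": ["ATG", "AAA"], "b": ["ATG", "AAA"]})
        assert residue_conservation(a) == [1.0, 1.0]

    def test_split_column(self):
        a = _aln({i: [c] for i, c in zip("abcd", ["AAA", "AAG", "GAA", "GAG"])})
        # K,K,E,E -> tie; reference (AAA -> K) wins the tie-break
        assert residue_conservation(a) == [0.5]

    def test_planted_conserved_block_is_track_maximum(self):
        spec = EvolutionSpec(n_codons=100, omega=1.0, mu=0.15)
        rng = np.random.default_rng(3)
        root = random_cds(100, rng)
        aln, _ = evolve_alignment(spec, seed=8, root_cds=root)
        # freeze a block: copy reference codons into all rows
        for sid in aln.ids:
            for j in range(40, 50):
                aln.rows[sid][j] = aln.rows[aln.ref_id][j]
        cons = residue_conservation(aln)
        assert min(cons[40:50]) == 1.0
        assert np.mean(cons[40:50]) >= max(np.mean(cons[:40]), np.mean(cons[50:]))


class TestNg86:
    def test_identical_pair_undefined_omega(self):
        a = _aln({"r": ["ATG", "AAA"], "o": ["ATG", "AAA"]})
        est = ng86_dnds(a)
        assert est.dN == 0 and est.dS == 0 and est.omega is None

    def test_pure_nonsyn_and_pure_syn(self):
        a = _aln({"r": ["AAA"], "o": ["GAA"]})
        est = ng86_dnds(a)
        assert est.dS == 0 and est.omega is None and est.dN > 0
        a2 = _aln(
            {"r": ["AAA", "CCC", "GGG", "TTT"], "o": ["AAG", "CCC", "GGG", "TTT"]}
        )
        est2 = ng86_dnds(a2)
        assert est2.dN == 0 and est2.omega == 0

    def test_sites_sum_to_three_per_codon(self):
        for codon in ("AAA", "TGG", "TAT", "CTG", "ATG"):
            s, n = ng86_site_counts(codon)
            assert s + n == pytest.approx(3.0)

    def test_fixed_ten_codon_pair_matches_oracle(self):
        seq1 = "ATGAAACCCGGGTTTCTGCATGAGTGGATC"
        seq2 = "ATGAAGCCCGGATTTCTGCATGAGTGGGTA"
        a = _aln({"r": seq_to_codons(seq1), "o": seq_to_codons(seq2)})
        est = ng86_dnds(a)
        dn, ds = oracles.pairwise_dnds(seq1, seq2)
        assert est.dN == pytest.approx(dn, rel=1e-9)
        assert est.dS == pytest.approx(ds, rel=1e-9)

    def test_random_pairs_match_bruteforce_oracle(self):
        """200 random codon-sequence pairs agree with the independent
        pathway-enumeration oracle."""
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 200:
            n = int(rng.integers(5, 30))
            s1 = random_cds(n, rng)
            s2 = mutate(s1, rng, p=float(rng.uniform(0.02, 0.25)))
            want = oracles.pairwise_dnds(s1, s2)
            a = _aln({"r": seq_to_codons(s1), "o": seq_to_codons(s2)})
            est = ng86_dnds(a)
            if want is None:
                assert est.n_saturated == 1
            else:
                assert est.dN == pytest.approx(want[0], rel=1e-9, abs=1e-12)
                assert est.dS == pytest.approx(want[1], rel=1e-9, abs=1e-12)
            checked += 1

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        s1 = random_cds(30, rng)
        s2 = mutate(s1, rng, p=0.1)
        e1 = ng86_dnds(_aln({"a": seq_to_codons(s1), "b": seq_to_codons(s2)}))
        e2 = ng86_dnds(_aln({"b": seq_to_codons(s2), "a": seq_to_codons(s1)}))
        assert e1.dN == pytest.approx(e2.dN) and e1.dS == pytest.approx(e2.dS)

    def test_empty_region_rejected(self):
        a = _aln({"r": ["AAA"], "o": ["AAA"]})
        with pytest.raises(InvalidRegionError):
            ng86_dnds(a, region=(1, 1))


class TestBootstrap:
    def test_identical_rows_all_undefined(self):
        a = _aln({"r": ["ATG", "AAA"], "o": ["ATG", "AAA"]})
        res = bootstrap_dnds(a, B=10, seed=1)
        assert res.status == "all_undefined" and res.boot_sd is None

    def test_single_replicate_degenerate(self):
        aln, _ = evolve_alignment(EvolutionSpec(n_species=4, n_codons=60), seed=2)
        res = bootstrap_dnds(aln, B=1, seed=3)
        assert res.boot_sd == 0.0
        assert res.ci99[0] == pytest.approx(res.ci99[1])

    def test_deterministic_under_fixed_seed(self):
        aln, _ = evolve_alignment(EvolutionSpec(n_species=6, n_codons=80), seed=4)
        r1 = bootstrap_dnds(aln, B=25, seed=77)
        r2 = bootstrap_dnds(aln, B=25, seed=77)
        assert r1 == r2


class TestSynSiteConservation:
    def test_zero_substitutions_all_flagged(self):
        a = _aln({"r": ["ATG"] * 10, "o": ["ATG"] * 10})
        stats = syn_site_conservation(a, window=5)
        assert all(w.score is None and w.omitted for w in stats)

    def test_suppression_monotone_in_multiplier(self):
        """Stronger synonymous suppression in a planted block strictly
        lowers the block's mean o/e."""
        means = []
        for mult in (1.0, 0.5, 0.1):
            spec = EvolutionSpec(
                n_codons=200, syn_suppression_blocks=[(80, 100, mult)]
            )
            aln, _ = evolve_alignment(spec, seed=21)
            stats = syn_site_conservation(aln, window=5)
            blk = [w.score for w in stats if 80 <= w.ref_codon_start < 96]
            means.append(np.mean(blk))
        assert means[0] > means[1] > means[2]

    def test_window_must_be_positive(self):
        a = _aln({"r": ["ATG"], "o": ["ATG"]})
        with pytest.raises(InvalidInputError):
            syn_site_conservation(a, window=0)


class TestCodingLrt:
    def test_identical_rows_score_zero(self):
        a = _aln({"r": ["ATG", "AAA", "CCC"] * 10, "o": ["ATG", "AAA", "CCC"] * 10})
        for f in (1, 2, 3):
            ws = coding_lrt_windows(a, window=5, frame_label=f)
            assert all(w.score == pytest.approx(0.0, abs=1e-9) for w in ws)

    def test_window_larger_than_alignment_flagged(self):
        a = _aln({"r": ["ATG", "AAA"], "o": ["ATG", "AAG"]})
        ws = coding_lrt_windows(a, window=20)
        assert len(ws) == 1 and ws[0].omitted

    def test_coding_signal_positive_in_frame_one_only(self):
        aln, _ = evolve_alignment(EvolutionSpec(omega=0.2), seed=11)
        means = {}
        for f in (1, 2, 3):
            ws = coding_lrt_windows(aln, frame_label=f)
            means[f] = np.mean([w.score for w in ws if not w.omitted])
        assert means[1] > 0
        assert means[2] < 0 and means[3] < 0


class TestNccConservation:
    def test_all_identical(self):
        rows = {f"s{i}": ["ACG", "AAA"] for i in range(5)}
        a = _aln(rows, ref_id="s0")
        (rep,) = ncc_conservation(a, [0], ["ACG", "ATT"])
        assert rep.n_match_ref == 4 and rep.n_match_ncc == 4

    def test_planted_conservation_level(self):
        rng = np.random.default_rng(13)
        n = 200
        rows = {"ref": ["ACG", "GGG"]}
        hits = 0
        for i in range(n):
            conserved = rng.random() < 0.8
            hits += conserved
            rows[f"s{i}"] = [("ACG" if conserved else "CCT"), "GGG"]
        a = CodonAlignment(ids=list(rows), ref_id="ref", rows=rows)
        (rep,) = ncc_conservation(a, [0], ["ACG"])
        assert rep.n_match_ref == hits
        # binomial sanity: within 4 SE of 0.8 * n
        assert abs(rep.n_match_ref - 0.8 * n) < 4 * np.sqrt(n * 0.8 * 0.2)

    def test_invalid_anchor(self):
        a = _aln({"r": ["ATG"], "o": ["ATG"]})
        with pytest.raises(InvalidRegionError):
            ncc_conservation(a, [5], ["ACG"])


def seq_to_codons(seq):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def mutate(seq, rng, p):
    """Random point mutations avoiding stop codons, for oracle tests."""
    s = list(seq)
    for i in range(len(s)):
        if rng.random() < p:
            s[i] = "ACGT"[rng.integers(0, 4)]
    # repair stops so both sequences stay sense-codon only
    for j in range(0, len(s), 3):
        while oracles.CODE["".join(s[j : j + 3])] == "*":
            s[j + int(rng.integers(0, 3))] = "ACGT"[rng.integers(0, 4)]
    return "".join(s)
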