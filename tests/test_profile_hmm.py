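"""Profile-HMM estimation, Viterbi alignment, trimming, consensus and
iterative refinement."""

import math

import numpy as np
import pytest

from ph4h3 import profile_hmm as ph
from ph4h3.errors import DegenerateModelError, InputError
from ph4h3.msa_phylo import Alignment

BASES = "ACGT"


def _l2(p):
    return math.log2(p) if p > 0 else -1e30


def random_hmm(rng, M):
    """A random, fully normalised model (no zero transitions except the
    structurally impossible ones)."""
    em = np.zeros((M + 1, 4))
    em[1:] = rng.dirichlet(np.ones(4) * 2, size=M)
    ins = rng.dirichlet(np.ones(4) * 2, size=M + 1)
    def rows(last_two):
        t = rng.dirichlet(np.ones(3), size=M + 1)
        t[M, 2] = 0
        t[M] /= t[M].sum()
        return t
    tm, ti, td = rows(True), rows(True), rows(True)
    td[0] = 0
    return ph.ProfileHMM(em, ins, tm, ti, td)


def oracle_viterbi_score(hmm, seq):
    """Exhaustive enumeration of all glocal state paths with free flanks."""
    M = hmm.M
    bg = 0.25
    lm = lambda k, c: _l2(hmm.match_emissions[k][c]) - _l2(bg)
    li = lambda k, c: _l2(hmm.insert_emissions[k][c]) - _l2(bg)
    codes = [BASES.index(c) for c in seq]

    def best_core(core):
        def rec(pos, node, kind):
            t = {"M": hmm.tm, "I": hmm.ti, "D": hmm.td}[kind][node]
            options = []
            if node == M:
                if pos == len(core):
                    options.append(_l2(t[0]))  # exit
            else:
                if pos < len(core):
                    options.append(_l2(t[0]) + lm(node + 1, core[pos]) + rec(pos + 1, node + 1, "M"))
                options.append(_l2(t[2]) + rec(pos, node + 1, "D"))
            if pos < len(core):
                options.append(_l2(t[1]) + li(node, core[pos]) + rec(pos + 1, node, "I"))
            return max(options) if options else -1e30
        return rec(0, 0, "M")

    best = -1e30
    L = len(codes)
    for npre in range(L + 1):
        for nsuf in range(L + 1 - npre):
            best = max(best, best_core(codes[npre : L - nsuf]))
    return best


class TestAssignMatchColumns:
    def test_gapless_alignment_all_match(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        assert ph.assign_match_columns(aln).all()

    def test_half_gapped_column_is_insert_at_default_threshold(self):
        aln = Alignment(["a", "b"], ["A-", "AC"])
        mask = ph.assign_match_columns(aln, 0.5)
        assert mask.tolist() == [True, False]

    def test_matches_direct_gap_counting(self, rng):
        rows = []
        for _ in range(7):
            row = ["ACGT-"[i] for i in rng.integers(0, 5, 30)]
            rows.append("".join(row))
        aln = Alignment([f"s{i}" for i in range(7)], rows)
        mask = ph.assign_match_columns(aln, 0.5)
        for c in range(30):
            frac = sum(r[c] == "-" for r in rows) / 7
            assert mask[c] == (frac < 0.5)


class TestEstimate:
    def test_identical_sequences_zero_pseudocount_point_masses(self):
        aln = Alignment(["a", "b", "c"], ["ACGT"] * 3)
        hmm = ph.estimate_hmm(aln, pseudocount=0.0)
        for k, base in enumerate("ACGT", start=1):
            assert hmm.match_emissions[k, BASES.index(base)] == 1.0
        hmm.validate()

    def test_single_column_laplace_arithmetic(self):
        aln = Alignment(list("wxyz"), ["A", "A", "C", "G"])
        hmm = ph.estimate_hmm(aln, pseudocount=1.0)
        assert hmm.match_emissions[1, 0] == pytest.approx((2 + 1) / (4 + 4))

    def test_normalisation_on_random_alignments(self, rng):
        for _ in range(3):
            rows = ["".join("ACGT-"[i] for i in rng.integers(0, 5, 25)) for _ in range(6)]
            aln = Alignment([f"s{i}" for i in range(6)], rows)
            mask = ph.assign_match_columns(aln)
            if not mask.any():
                continue
            ph.estimate_hmm(aln, mask).validate()

    def test_no_match_columns_is_degenerate(self):
        aln = Alignment(["a", "b"], ["A-", "-C"])
        with pytest.raises(DegenerateModelError):
            ph.estimate_hmm(aln, np.array([False, False]))

    def test_emissions_recovered_from_large_sample(self, rng):
        # sample gapless sequences from a match-only model and re-estimate
        M = 10
        hmm = random_hmm(rng, M)
        hmm.tm[:, :] = [1.0, 0.0, 0.0]
        hmm.ti[:, :] = [1.0, 0.0, 0.0]
        rows = ["".join(BASES[rng.choice(4, p=hmm.match_emissions[k])] for k in range(1, M + 1))
                for _ in range(500)]
        est = ph.estimate_hmm(Alignment([f"s{i}" for i in range(500)], rows), pseudocount=1.0)
        tv = 0.5 * np.abs(est.match_emissions[1:] - hmm.match_emissions[1:]).sum(axis=1)
        assert tv.mean() < 0.05


class TestViterbi:
    def test_consensus_sequence_takes_all_match_path(self, rng):
        M = 8
        hmm = random_hmm(rng, M)
        hmm.match_emissions[1:] = 0.01
        cons = rng.integers(0, 4, M + 1)
        for k in range(1, M + 1):
            hmm.match_emissions[k, cons[k]] = 0.97
        hmm.tm[:, :] = [0.9, 0.05, 0.05]
        hmm.tm[M] = [0.95, 0.05, 0]
        seq = "".join(BASES[cons[k]] for k in range(1, M + 1))
        path = ph.viterbi_align(hmm, seq)
        assert [s for s in path.states] == [("M", k) for k in range(1, M + 1)]

    def test_score_equals_exhaustive_path_enumeration(self, rng):
        for trial in range(25):
            M = int(rng.integers(1, 5))
            L = int(rng.integers(1, 7))
            hmm = random_hmm(rng, M)
            seq = "".join(BASES[i] for i in rng.integers(0, 4, L))
            got = ph.viterbi_align(hmm, seq).score
            want = oracle_viterbi_score(hmm, seq)
            assert got == pytest.approx(want, abs=1e-9), (M, seq)

    def test_emitted_count_matches_sequence_length(self, rng):
        hmm = random_hmm(rng, 6)
        for L in (1, 4, 9):
            seq = "".join(BASES[i] for i in rng.integers(0, 4, L))
            assert ph.viterbi_align(hmm, seq).emitted_count() == L

    def test_appending_flanks_never_decreases_score(self, rng):
        hmm = random_hmm(rng, 5)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, 8))
        base = ph.viterbi_align(hmm, seq).score
        assert ph.viterbi_align(hmm, "ACGT" + seq + "GGTA").score >= base - 1e-9

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(InputError):
            ph.viterbi_align(random_hmm(rng, 3), "")


class TestTrim:
    def test_all_match_path_keeps_sequence(self, rng):
        seq = "ACGTAC"
        path = ph.AlignedPath("s", [("M", k) for k in range(1, 7)], 0.0)
        assert ph.trim_flanks(path, seq) == seq

    def test_n_flank_residues_removed(self):
        seq = "ACGTACGTAA"
        states = [("N", 0)] * 5 + [("M", 1), ("M", 2), ("M", 3)] + [("C", 0)] * 2
        path = ph.AlignedPath("s", states, 0.0)
        assert ph.trim_flanks(path, seq) == seq[5:8]

    def test_trimming_never_lengthens(self, rng):
        hmm = random_hmm(rng, 6)
        for _ in range(10):
            seq = "".join(BASES[i] for i in rng.integers(0, 4, int(rng.integers(3, 15))))
            path = ph.viterbi_align(hmm, seq)
            assert len(ph.trim_flanks(path, seq)) <= len(seq)


class TestConsensus:
    def test_point_mass_uppercase(self):
        hmm = _single_state_hmm([1.0, 0, 0, 0])
        assert ph.emit_consensus(hmm) == "A"

    def test_mid_confidence_lowercase(self):
        hmm = _single_state_hmm([0.4, 0.3, 0.2, 0.1])
        assert ph.emit_consensus(hmm, 0.25, 0.5) == "a"

    def test_uniform_boundary_is_lowercase_argmax(self):
        hmm = _single_state_hmm([0.25, 0.25, 0.25, 0.25])
        assert ph.emit_consensus(hmm, 0.25, 0.5) == "a"  # >= convention, A first

    def test_low_probability_is_n(self):
        hmm = _single_state_hmm([0.26, 0.26, 0.24, 0.24])
        assert ph.emit_consensus(hmm, 0.3, 0.5) == "n"

    def test_bad_thresholds_rejected(self):
        hmm = _single_state_hmm([1.0, 0, 0, 0])
        with pytest.raises(InputError):
            ph.emit_consensus(hmm, 0.6, 0.5)

    def test_random_tables_match_hand_rule(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(4))
            minl, minu = sorted(rng.uniform(0, 1, 2))
            got = ph.emit_consensus(_single_state_hmm(p), minl, minu)
            r = int(np.argmax(p))
            if p[r] >= minu:
                want = BASES[r]
            elif p[r] >= minl:
                want = BASES[r].lower()
            else:
                want = "n"
            assert got == want


def _single_state_hmm(p):
    em = np.zeros((2, 4))
    em[1] = p
    ins = np.full((2, 4), 0.25)
    tm = np.array([[0.9, 0.05, 0.05], [1.0, 0.0, 0.0]])
    return ph.ProfileHMM(em, ins, tm, tm.copy(), np.array([[0, 0, 0], [1.0, 0, 0]]))


class TestInformationContent:
    @pytest.mark.parametrize(
        "p,ic",
        [([1, 0, 0, 0], 2.0), ([0.25] * 4, 0.0), ([0.5, 0.5, 0, 0], 1.0)],
    )
    def test_entropy_arithmetic(self, p, ic):
        assert ph.information_content(_single_state_hmm(p))[0] == pytest.approx(ic)

    def test_range_bounds(self, rng):
        hmm = random_hmm(rng, 20)
        icp = ph.information_content(hmm)
        assert np.all((icp >= 0) & (icp <= 2))


class TestRefine:
    def test_identical_sequences_converge_immediately(self):
        seq = "ACGTACGTGGCCAATTACGT"
        res = ph.refine({f"s{i}": seq for i in range(4)})
        assert res.converged
        assert res.iterations <= 2
        assert res.hmm.M == len(seq)
        assert res.consensus.upper() == seq
        assert res.consensus == seq  # all uppercase: every column is unanimous

    def test_consensus_matches_model_and_length(self, small_bundle):
        res = ph.refine(small_bundle.promoters, max_iter=30)
        assert len(res.consensus) == res.hmm.M
        assert ph.emit_consensus(res.hmm) == res.consensus
        res.hmm.validate()

    def test_refine_deterministic(self, small_bundle):
        r1 = ph.refine(small_bundle.promoters, max_iter=30)
        r2 = ph.refine(small_bundle.promoters, max_iter=30)
        assert r1.consensus == r2.consensus
        assert r1.iterations == r2.iterations

    def test_match_length_recovery_small(self, rng):
        M = 60
        hmm = _blocky_hmm(rng, M)
        seqs = {f"s{i:02d}": ph.sample_sequence(hmm, rng) for i in range(40)}
        res = ph.refine(seqs, max_iter=30)
        assert abs(res.hmm.M - M) <= 2

    def test_single_sequence_rejected(self):
        with pytest.raises(InputError):
            ph.refine({"only": "ACGT"})


def _blocky_hmm(rng, M, match_p=0.9, tmm=0.98):
    em = np.full((M + 1, 4), (1 - 0.9) / 3)
    cons = rng.integers(0, 4, M + 1)
    for k in range(1, M + 1):
        em[k] = (1 - match_p) / 3
        em[k, cons[k]] = match_p
    em[0] = 0
    ins = np.full((M + 1, 4), 0.25)
    rest = (1 - tmm) / 2
    tm = np.tile([tmm, rest, rest], (M + 1, 1))
    tm[M] = [1 - rest, rest, 0]
    ti = np.tile([0.5, 0.48, 0.02], (M + 1, 1))
    ti[M] = [0.52, 0.48, 0]
    td = np.tile([0.7, 0.02, 0.28], (M + 1, 1))
    td[0] = 0
    td[M] = [0.98, 0.02, 0]
    return ph.ProfileHMM(em, ins, tm, ti, td)


class TestModelIO:
    def test_text_roundtrip(self, tmp_path, rng):
        hmm = random_hmm(rng, 7)
        ph.write_model(hmm, tmp_path / "m.txt")
        back = ph.read_model(tmp_path / "m.txt")
        assert back.M == hmm.M
        assert np.allclose(back.match_emissions, hmm.match_emissions, atol=1e-6)
        assert np.allclose(back.tm, hmm.tm, atol=1e-6)
        back.validate()

    def test_ic_tsv_layout(self, tmp_path, rng):
        import pandas as pd

        hmm = random_hmm(rng, 5)
        ph.write_ic_tsv(hmm, tmp_path / "ic.tsv")
        df = pd.read_csv(tmp_path / "ic.tsv", sep="\t")
        assert list(df.columns) == ["position", "A", "C", "G", "T", "ic_bits"]
        assert len(df) == 5
        assert np.allclose(df[list("ACGT")].sum(axis=1), 1.0, atol=1e-4)
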