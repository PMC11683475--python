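import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from ovis.chromstate import (BernoulliHMM, BinaryMarks, Segmentation,
                             _forward_backward, _frame_prob, binarize_track,
                             call_tissue_specific, label_states,
                             merge_nonredundant, state_coverage, tss_profile,
                             variability_curve)
from ovis.intervals import GenomicInterval, IntervalSet
from ovis.io import GeneModel, SignalTrack


def poisson_tail_oracle(count, lam):
    """P(X >= count) by explicit pmf summation of the complement."""
    acc = 0.0
    for k in range(count):
        acc += math.exp(-lam) * lam ** k / math.factorial(k)
    return 1.0 - acc


def simulate_hmm(E, T, n, seed):
    rng = np.random.default_rng(seed)
    K = len(E)
    Tn = np.asarray(T) / np.asarray(T).sum(axis=1, keepdims=True)
    states = np.empty(n, dtype=int)
    states[0] = rng.integers(K)
    for t in range(1, n):
        states[t] = rng.choice(K, p=Tn[states[t - 1]])
    x = (rng.uniform(size=(n, np.asarray(E).shape[1])) < np.asarray(E)[states]).astype(np.int8)
    return states, x


class TestBinarize:
    def test_threshold_against_tail_sum_oracle(self):
        # 100 bins with mean exactly 1: one 7, six 0s, ninety-three 1s
        vals = np.array([7.0] + [0.0] * 6 + [1.0] * 93)
        track = SignalTrack({"chr1": vals}, bin_size=200)
        out = binarize_track(track, p_threshold=1e-4)["chr1"]
        assert poisson_tail_oracle(7, 1.0) < 1e-4 < poisson_tail_oracle(6, 1.0)
        assert out[0] == 1
        assert out[1:].sum() == 0

    def test_zero_count_never_on(self, rng):
        vals = rng.poisson(3.0, size=200).astype(float)
        vals[:20] = 0.0
        out = binarize_track(SignalTrack({"chr1": vals}, 200))["chr1"]
        assert out[:20].sum() == 0

    def test_all_zero_track_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = binarize_track(SignalTrack({"chr1": np.zeros(50)}, 200))
        assert out["chr1"].sum() == 0


class TestForwardBackward:
    def test_likelihood_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(7)
        K, M, T_len = 3, 3, 3
        E = rng.uniform(0.1, 0.9, size=(K, M))
        A = rng.uniform(0.1, 1.0, size=(K, K))
        A /= A.sum(axis=1, keepdims=True)
        pi0 = np.array([0.5, 0.3, 0.2])
        x = np.array([[1, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        fp = _frame_prob(x, E)
        ll, gamma, _ = _forward_backward(pi0, A, fp)
        brute = 0.0
        for path in itertools.product(range(K), repeat=T_len):
            p = pi0[path[0]] * fp[0, path[0]]
            for t in range(1, T_len):
                p *= A[path[t - 1], path[t]] * fp[t, path[t]]
            brute += p
        assert math.exp(ll) == pytest.approx(brute, rel=1e-12)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_agrees_with_hmmlearn_on_pattern_encoding(self):
        """Cross-check the forward likelihood against an independent HMM library."""
        from hmmlearn.hmm import CategoricalHMM

        rng = np.random.default_rng(3)
        K, M = 4, 3
        E = rng.uniform(0.05, 0.95, size=(K, M))
        A = rng.uniform(size=(K, K)) + 0.5
        A /= A.sum(axis=1, keepdims=True)
        pi0 = np.full(K, 0.25)
        _, x = simulate_hmm(E, A, 500, seed=9)
        fp = _frame_prob(x.astype(float), E)
        ll, _, _ = _forward_backward(pi0, A, fp)
        # encode the 8 joint mark patterns as one categorical symbol
        pat = ((np.arange(8)[:, None] >> np.arange(M)) & 1)
        emission = np.exp(pat @ np.log(E).T + (1 - pat) @ np.log1p(-E).T).T
        ref = CategoricalHMM(n_components=K)
        ref.startprob_, ref.transmat_, ref.emissionprob_ = pi0, A, emission
        codes = (x @ (1 << np.arange(M))).astype(int).reshape(-1, 1)
        assert ll == pytest.approx(ref.score(codes), abs=1e-8)


class TestTraining:
    def test_two_state_parameter_recovery_and_decoding(self):
        E = np.array([[0.9, 0.9, 0.9], [0.05, 0.05, 0.05]])
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        states, x = simulate_hmm(E, A, 30_000, seed=21)
        bm = BinaryMarks({"chr1": x}, 200)
        res = BernoulliHMM(n_states=2, n_restarts=3, seed=0).fit([bm])
        cost = ((res.emissions[:, None, :] - E[None]) ** 2).sum(-1)
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(2, dtype=int)
        perm[cols] = rows
        assert np.abs(res.emissions[perm] - E).max() <= 0.05
        seg = res.decode(bm)
        mapping = np.empty(2, dtype=int)
        mapping[rows] = cols
        acc = np.mean(mapping[seg.states["chr1"]] == states)
        assert acc >= 0.95

    def test_monotone_ll_and_determinism(self):
        _, x = simulate_hmm(np.array([[0.8, 0.2, 0.5], [0.1, 0.7, 0.3]]),
                            np.array([[0.9, 0.1], [0.2, 0.8]]), 3_000, seed=5)
        bm = BinaryMarks({"chr1": x}, 200)
        r1 = BernoulliHMM(2, n_restarts=2, seed=42).fit([bm])
        r2 = BernoulliHMM(2, n_restarts=2, seed=42).fit([bm])
        diffs = np.diff(r1.ll_history)
        assert (diffs >= -1e-6).all()
        np.testing.assert_array_equal(r1.emissions, r2.emissions)
        np.testing.assert_array_equal(r1.transmat, r2.transmat)

    def test_pattern_deficit_warns(self):
        x = np.zeros((500, 3), dtype=np.int8)
        bm = BinaryMarks({"chr1": x}, 200)
        with pytest.warns(UserWarning, match="distinct"):
            BernoulliHMM(2, n_restarts=1, max_iter=5, seed=0).fit([bm])


class TestLabels:
    @pytest.mark.parametrize("row,expected", [
        ((0.9, 0.9, 0.9), "TssA"),
        ((0.05, 0.05, 0.05), "Quies"),
        ((0.9, 0.05, 0.9), "EnhA"),
        ((0.6, 0.9, 0.1), "TssW"),
        ((0.4, 0.05, 0.35), "EnhAW"),
        ((0.9, 0.05, 0.05), "ATAC_Is"),
    ])
    def test_rule_table(self, row, expected):
        assert label_states(np.array([row]))[0] == expected

    def test_six_state_duplicates_resolved_uniquely(self):
        E = np.array([(0.9, 0.9, 0.9), (0.05, 0.05, 0.05), (0.9, 0.05, 0.9),
                      (0.5, 0.9, 0.1), (0.04, 0.03, 0.06), (0.9, 0.05, 0.05)])
        with pytest.warns(UserWarning, match="duplicate"):
            labels = label_states(E)
        assert sorted(labels) == sorted(
            ["TssA", "TssW", "EnhA", "EnhAW", "ATAC_Is", "Quies"])


class TestSegmentationSummaries:
    def seg(self, arrs, labels=None):
        return Segmentation({c: np.asarray(a) for c, a in arrs.items()}, 200,
                            labels=labels)

    def test_state_coverage_partition(self):
        seg = self.seg({"chr1": [0, 0, 1, 1], "chr2": [1, 1, 1, 1]},
                       labels=["a", "b"])
        cov = state_coverage(seg)
        assert cov.sum() == pytest.approx(1.0, abs=1e-12)
        assert cov["a"] == pytest.approx(0.25)

    def test_state_intervals_merge_adjacent_bins(self):
        seg = self.seg({"chr1": [1, 1, 0, 1]})
        ivs = list(seg.state_intervals(1))
        assert [(i.start, i.end) for i in ivs] == [(0, 400), (600, 800)]

    def test_tss_profile_peak_at_tss_and_strand_mirror(self):
        nb = 100
        v = np.zeros(nb)
        genes = [GeneModel("g+", "chr1", "+", 50 * 200 + 1, 50 * 200 + 1000, 1000),
                 GeneModel("g-", "chr1", "-", 70 * 200 + 1, 70 * 200 - 1000, 1000)]
        v[50] = 1.0  # promoter state at the + gene's TSS
        v[70 + 2] = 1.0  # two bins downstream of the - gene's TSS (upstream genomically)
        prof = tss_profile({"chr1": v}, 200, genes, flank=1000)
        mid = len(prof) // 2
        assert prof.loc[mid, "offset"] == 0
        assert prof.loc[mid, "mean"] == pytest.approx(0.5)  # only the + gene peaks at 0
        # the - gene's signal lands at offset -2 bins after mirroring
        assert prof.loc[mid - 2, "mean"] == pytest.approx(0.5)


class TestNonredundantAndSpecificity:
    def test_merge_idempotent_and_book_ended(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 100, 200)])
        merged = merge_nonredundant({"t1": a, "t2": b})
        assert [(iv.start, iv.end) for iv in merged] == [(0, 200)]
        same = merge_nonredundant({"t1": a, "t2": a})
        assert [(iv.start, iv.end) for iv in same] == [(0, 100)]

    def test_presence_one_bp_counts(self):
        nr = IntervalSet([GenomicInterval("chr1", 100, 200)])
        per_tissue = {
            "t1": IntervalSet([GenomicInterval("chr1", 199, 300)]),  # 1 bp overlap
            "t2": IntervalSet([GenomicInterval("chr1", 300, 400)]),
            "t3": IntervalSet([GenomicInterval("chr1", 100, 200)]),
        }
        df = call_tissue_specific(nr, per_tissue)
        row = df.iloc[0]
        assert row["t1"] == 1 and row["t2"] == 0 and row["t3"] == 1
        assert row["category"] == "shared"

    def test_specific_and_common_categories(self):
        nr = IntervalSet([GenomicInterval("chr1", 0, 100),
                          GenomicInterval("chr1", 200, 300)])
        only_first = IntervalSet([GenomicInterval("chr1", 0, 100)])
        both = IntervalSet([GenomicInterval("chr1", 0, 100),
                            GenomicInterval("chr1", 200, 300)])
        df = call_tissue_specific(nr, {"t1": both, "t2": only_first})
        assert df.iloc[0]["category"] == "common"
        assert df.iloc[1]["category"] == "specific" and df.iloc[1]["tissue"] == "t1"

    def test_variability_curve_hand_case(self):
        # half the bp specific to one tissue, half common to all 9
        presence = pd.DataFrame({"length": [500, 500], "n_tissues": [1, 9]})
        f, summary = variability_curve(presence, n_tissues=9)
        assert f.loc[1] == pytest.approx(0.5)
        assert f.loc[8] == pytest.approx(0.5)
        assert f.loc[9] == pytest.approx(1.0)
        assert summary == 9

    def test_variability_all_specific(self):
        presence = pd.DataFrame({"length": [100, 300], "n_tissues": [1, 1]})
        f, summary = variability_curve(presence, n_tissues=9)
        assert f.loc[1] == 1.0 and summary == 1
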