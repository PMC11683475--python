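import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ovis.io import GenotypeMatrix, VariantRecord
from ovis.sweep import (fst_windowed, intersect_top_quantile, make_windows,
                        pi_ratio, pi_windowed, standardize_xpehh,
                        weir_cockerham_components, window_xpehh, xpehh)


def gm_from(dosages, positions=None, populations=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = positions if positions is not None else range(1, m + 1)
    variants = [VariantRecord(chrom, int(p), "A", "C", f"v{j}")
                for j, p in enumerate(positions)]
    return GenotypeMatrix(dosages, [f"i{k}" for k in range(n)], variants,
                          populations=np.asarray(populations) if populations is not None else None)


def one_window(end=1000):
    return pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [end]})


class TestMakeWindows:
    def test_1mb_has_12_full_windows(self):
        w = make_windows({"chr1": 1_000_000})
        assert len(w) == 12
        assert (w.iloc[-1].start, w.iloc[-1].end) == (825_000, 975_000)

    @pytest.mark.parametrize("L,n", [(150_000, 1), (149_999, 0), (225_000, 2)])
    def test_full_window_rule(self, L, n):
        assert len(make_windows({"chr1": L})) == n


def wc_oracle(dos_a, dos_b):
    """Scalar Weir-Cockerham two-population variance components, one site."""
    r = 2
    stats = []
    for d in (dos_a, dos_b):
        d = [x for x in d if not math.isnan(x)]
        n = len(d)
        p = sum(d) / (2 * n)
        h = sum(1 for x in d if x == 1) / n
        stats.append((n, p, h))
    nbar = sum(s[0] for s in stats) / r
    nc = (r * nbar - sum(s[0] ** 2 for s in stats) / (r * nbar)) / (r - 1)
    pbar = sum(s[0] * s[1] for s in stats) / (r * nbar)
    s2 = sum(s[0] * (s[1] - pbar) ** 2 for s in stats) / ((r - 1) * nbar)
    hbar = sum(s[0] * s[2] for s in stats) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, a + b + c


class TestFst:
    def test_single_site_matches_scalar_oracle(self):
        # nA = nB = 4 diploids, pA = 0.75 (two hom-alt, two het), pB = 0.25
        dos_a = [2, 2, 1, 1]
        dos_b = [0, 0, 1, 1]
        a, total = weir_cockerham_components(
            np.array(dos_a, float)[:, None], np.array(dos_b, float)[:, None])
        oa, ot = wc_oracle(dos_a, dos_b)
        assert a[0] == pytest.approx(oa, abs=1e-12)
        assert total[0] == pytest.approx(ot, abs=1e-12)

    def test_multi_site_window_vs_oracle_ratio_of_sums(self, rng):
        dos = rng.integers(0, 3, size=(12, 8)).astype(float)
        dos[0, 2] = np.nan
        gm = gm_from(dos, populations=["A"] * 6 + ["B"] * 6)
        res = fst_windowed(gm, "A", "B", one_window())
        num = den = 0.0
        for j in range(8):
            oa, ot = wc_oracle(dos[:6, j], dos[6:, j])
            p_all = np.nansum(dos[:, j]) / (2 * np.sum(~np.isnan(dos[:, j])))
            if p_all in (0.0, 1.0):
                continue
            num += oa
            den += ot
        assert res["fst"].iloc[0] == pytest.approx(num / den, abs=1e-12)

    def test_fixed_difference_is_one(self):
        gm = gm_from([[0] * 5] * 4 + [[2] * 5] * 4, populations=["A"] * 4 + ["B"] * 4)
        res = fst_windowed(gm, "A", "B", one_window())
        assert res["fst"].iloc[0] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        block = rng.integers(0, 3, size=(50, 40)).astype(float)
        gm = gm_from(np.vstack([block, block]),
                     populations=["A"] * 50 + ["B"] * 50)
        res = fst_windowed(gm, "A", "B", one_window())
        assert res["fst"].iloc[0] <= 0.0 + 1e-12  # duplicated samples: no among-pop variance

    def test_empty_window_missing(self):
        gm = gm_from([[1, 0], [0, 1], [1, 1], [2, 0]],
                     positions=[5000, 6000], populations=["A", "A", "B", "B"])
        res = fst_windowed(gm, "A", "B", one_window(1000))
        assert np.isnan(res["fst"].iloc[0]) and res["n_variants"].iloc[0] == 0


def pi_oracle(dosages, length):
    """All-pairs allele comparison per site, summed / window length."""
    total = 0.0
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        alleles = []
        for d in col:
            if not math.isnan(d):
                alleles += [1] * int(d) + [0] * (2 - int(d))
        diffs = sum(1 for x, y in itertools.combinations(alleles, 2) if x != y)
        pairs = len(alleles) * (len(alleles) - 1) / 2
        if pairs:
            total += diffs / pairs
    return total / length


class TestPi:
    def test_hand_case(self):
        gm = gm_from([[1], [1]], positions=[50], populations=["A", "A"])
        res = pi_windowed(gm, "A", one_window(100))
        assert res["pi"].iloc[0] == pytest.approx((2 * 2 * 2) / (4 * 3) / 100)

    def test_matches_all_pairs_oracle(self, rng):
        dos = rng.integers(0, 3, size=(6, 9)).astype(float)
        dos[2, 4] = np.nan
        gm = gm_from(dos, populations=["A"] * 6)
        res = pi_windowed(gm, "A", one_window(500))
        assert res["pi"].iloc[0] == pytest.approx(pi_oracle(dos, 500), abs=1e-12)

    def test_monomorphic_window_zero(self):
        gm = gm_from([[0, 2], [0, 2]], populations=["A", "A"])
        assert pi_windowed(gm, "A", one_window())["pi"].iloc[0] == 0.0

    def test_ref_alt_swap_invariant(self, rng):
        dos = rng.integers(0, 3, size=(8, 6)).astype(float)
        gm1 = gm_from(dos, populations=["A"] * 8)
        gm2 = gm_from(2 - dos, populations=["A"] * 8)
        assert (pi_windowed(gm1, "A", one_window())["pi"].iloc[0]
                == pytest.approx(pi_windowed(gm2, "A", one_window())["pi"].iloc[0]))

    def test_ratio(self):
        w = one_window()
        pa = w.assign(n_variants=1, pi=[0.002])
        pb = w.assign(n_variants=1, pi=[0.001])
        assert pi_ratio(pa, pb)["pi_ratio"].iloc[0] == pytest.approx(2.0)
        pz = w.assign(n_variants=1, pi=[0.0])
        assert np.isnan(pi_ratio(pa, pz)["pi_ratio"].iloc[0])


# ---------------------------------------------------------------------------
# XP-EHH

def ehh_bf(haps, core, x):
    """Fraction of haplotype pairs identical over the inclusive span core..x."""
    lo, hi = min(core, x), max(core, x)
    segs = [tuple(h[lo:hi + 1]) for h in haps]
    same = sum(1 for a, b in itertools.combinations(segs, 2) if a == b)
    n = len(haps)
    return same / (n * (n - 1) / 2)


def ihh_bf(haps, core, gpos, cutoff):
    """Trapezoid integral of brute-force EHH, truncated below cutoff."""
    total = 0.0
    for direction in (1, -1):
        prev_e, prev_d = ehh_bf(haps, core, core), 0.0
        x = core + direction
        while 0 <= x < haps.shape[1]:
            e = ehh_bf(haps, core, x)
            d = abs(gpos[x] - gpos[core])
            if e < cutoff:
                break
            total += 0.5 * (e + prev_e) * (d - prev_d)
            if e == 0.0:
                break
            prev_e, prev_d = e, d
            x += direction
    return total


class TestXpehh:
    def test_identical_sets_score_zero(self, rng):
        haps = rng.integers(0, 2, size=(6, 10)).astype(np.int8)
        gpos = np.arange(10) * 0.01
        raw = xpehh(haps, haps.copy(), gpos)
        ok = ~np.isnan(raw)
        assert ok.any()
        np.testing.assert_allclose(raw[ok], 0.0, atol=1e-12)

    def test_antisymmetric_under_population_swap(self, rng):
        a = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        b = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        gpos = np.cumsum(rng.uniform(0.005, 0.02, 12))
        fwd, rev = xpehh(a, b, gpos), xpehh(b, a, gpos)
        mask = ~np.isnan(fwd)
        np.testing.assert_allclose(fwd[mask], -rev[mask], atol=1e-12)

    def test_matches_bruteforce_pairwise_oracle(self, rng):
        a = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        b = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        # plant a shared run so EHH stays high for a while in pop a
        a[:5, 4:9] = 1
        gpos = np.cumsum(rng.uniform(0.005, 0.02, 12))
        raw = xpehh(a, b, gpos, ehh_cutoff=0.05)
        for core in range(12):
            ia = ihh_bf(a, core, gpos, 0.05)
            ib = ihh_bf(b, core, gpos, 0.05)
            if ia > 0 and ib > 0:
                assert raw[core] == pytest.approx(math.log(ia / ib), abs=1e-12)
            else:
                assert np.isnan(raw[core])

    def test_standardization_moments(self, rng):
        raw = rng.normal(2.0, 3.0, size=500)
        raw[::50] = np.nan
        z = standardize_xpehh(raw)
        assert np.nanmean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(z) == pytest.approx(1.0, abs=1e-9)

    def test_window_mean(self):
        w = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 200]})
        z = np.array([1.0, 3.0, np.nan, 5.0])
        res = window_xpehh(z, np.array(["chr1"] * 4, dtype=object),
                           np.array([10, 20, 110, 150]), w)
        assert res["xpehh_mean"].tolist() == [2.0, 5.0]
        assert res["n_variants"].tolist() == [2, 1]


class TestTopQuantileIntersection:
    def _stats(self, values_by_name, n=1000):
        w = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 100,
                          "end": np.arange(n) * 100 + 100})
        return {k: w.assign(**{k: v}) for k, v in values_by_name.items()}

    def test_identical_rankings_select_exactly_five_per_mille(self):
        vals = np.arange(1000, dtype=float)
        stats = self._stats({"a": vals, "b": vals * 2, "c": vals + 7})
        hits, regions = intersect_top_quantile(stats, q=0.005)
        assert len(hits) == 5
        # the five top windows are contiguous -> one merged region
        assert len(list(regions)) == 1

    def test_disjoint_top_sets_give_nothing(self):
        a = np.arange(1000, dtype=float)
        stats = self._stats({"a": a, "b": a[::-1].copy()})
        hits, regions = intersect_top_quantile(stats, q=0.005)
        assert len(hits) == 0 and len(list(regions)) == 0

    def test_count_bounded_by_quantile(self, rng):
        stats = self._stats({k: rng.normal(size=1000) for k in "abc"})
        hits, _ = intersect_top_quantile(stats, q=0.01)
        assert len(hits) <= int(np.ceil(0.01 * 1000))
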