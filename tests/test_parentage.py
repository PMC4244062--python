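"""Trio/pair likelihoods, LOD scores, exclusion and ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_genotype_matrix
from snpquant.intensity import (
    GenotypeStore,
    build_genotype_store,
    missing_parent_matrix,
)
from snpquant.parentage import (
    TrioScore,
    classify_assignment,
    count_mismatches,
    null_marker_likelihood,
    rank_parent_pairs,
    rank_parent_pairs_exclusion,
    resolve_trio,
    resolved_scores,
    score_trios,
    transmission_vector,
    trio_lod,
    trio_marker_likelihood,
)

AA = np.array([[1.0, 0.0], [0.0, 0.0]])
BB = np.array([[0.0, 0.0], [0.0, 1.0]])
HET = np.array([[0.0, 0.5], [0.5, 0.0]])
F_HALF = np.array([0.5, 0.5])


def brute_force_trio_likelihood(g_s, g_d, g_o):
    """Independent oracle: enumerate transmitted-allele combinations.

    P(offspring ordered genotype (a, b)) = P(sire transmits a) P(dam
    transmits b), each transmission marginalising the parent's ordered
    genotype with a half chance per allele.
    """
    total = 0.0
    for a in (0, 1):  # allele from sire
        p_a = sum(
            g_s[i, j] * ((i == a) + (j == a)) / 2.0 for i in (0, 1) for j in (0, 1)
        )
        for b in (0, 1):  # allele from dam
            p_b = sum(
                g_d[i, j] * ((i == b) + (j == b)) / 2.0
                for i in (0, 1)
                for j in (0, 1)
            )
            total += p_a * p_b * g_o[a, b]
    return total


class TestTransmission:
    def test_homozygote(self):
        np.testing.assert_allclose(transmission_vector(AA), [1.0, 0.0])

    def test_heterozygote(self):
        np.testing.assert_allclose(transmission_vector(HET), [0.5, 0.5])

    def test_asymmetric_matrix(self):
        g = np.array([[0.5, 0.25], [0.25, 0.0]])
        np.testing.assert_allclose(transmission_vector(g), [0.75, 0.25])


class TestMarkerLikelihood:
    def test_mendelian_certainties(self):
        t_aa = transmission_vector(AA)
        assert trio_marker_likelihood(t_aa, t_aa, AA) == 1.0
        assert trio_marker_likelihood(t_aa, t_aa, BB) == 0.0
        # AB x AB -> het: the ordered transmission products are 0.25 per
        # cell and the het mass is split 0.5/0.5, so the marker likelihood
        # is 0.25; the same half-mass convention applies in the null, so
        # likelihood *ratios* are unaffected by the ordered representation.
        t_het = transmission_vector(HET)
        assert trio_marker_likelihood(t_het, t_het, HET) == pytest.approx(0.25)

    def test_null_likelihood(self):
        assert null_marker_likelihood(AA, F_HALF) == pytest.approx(0.25)
        assert null_marker_likelihood(HET, F_HALF) == pytest.approx(0.25)
        assert null_marker_likelihood(AA, np.array([0.3, 0.7])) == pytest.approx(0.09)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(300):
            g_s = random_genotype_matrix(rng)
            g_d = random_genotype_matrix(rng)
            g_o = random_genotype_matrix(rng, symmetric=False)
            fast = trio_marker_likelihood(
                transmission_vector(g_s), transmission_vector(g_d), g_o
            )
            assert fast == pytest.approx(
                brute_force_trio_likelihood(g_s, g_d, g_o), abs=1e-12
            )


def _store_from_matrices(matrices: dict[str, list[np.ndarray | None]], snps=None):
    """Build a GenotypeStore directly from per-sample matrix lists."""
    samples = list(matrices)
    n_snps = len(next(iter(matrices.values())))
    snps = snps or [f"m{j}" for j in range(n_snps)]
    G = np.full((len(samples), n_snps, 2, 2), np.nan)
    for i, s in enumerate(samples):
        for j, g in enumerate(matrices[s]):
            if g is not None:
                G[i, j] = g
    return GenotypeStore(samples, snps, G, "quantitative")


class TestTrioLod:
    def test_single_snp_closed_form(self):
        store = _store_from_matrices({"o": [AA], "s": [AA], "d": [AA]})
        freqs = {"m0": F_HALF}
        score = trio_lod("o", "s", "d", store, freqs, min_snps=1)
        assert score.lod == pytest.approx(math.log(4))
        assert score.n_snps == 1

    def test_both_parents_missing_lod_zero(self):
        store = _store_from_matrices({"o": [AA, HET, BB]})
        freqs = {f"m{j}": np.array([0.4, 0.6]) for j in range(3)}
        score = trio_lod("o", None, None, store, freqs, min_snps=1)
        assert score.lod == pytest.approx(0.0)
        assert score.n_snps == 3

    def test_min_snps_rule(self):
        mats = {"o": [AA] * 9, "s": [AA] * 9, "d": [AA] * 9}
        store = _store_from_matrices(mats)
        freqs = {f"m{j}": F_HALF for j in range(9)}
        assert trio_lod("o", "s", "d", store, freqs, min_snps=10) is None
        assert trio_lod("o", "s", "d", store, freqs, min_snps=9) is not None

    def test_offspring_missing_snp_skipped(self):
        mats = {"o": [AA, None], "s": [AA, AA], "d": [AA, AA]}
        store = _store_from_matrices(mats)
        freqs = {"m0": F_HALF, "m1": F_HALF}
        score = trio_lod("o", "s", "d", store, freqs, min_snps=1)
        assert score.n_snps == 1

    def test_uninformative_snp_leaves_lod_unchanged(self):
        # a SNP where likelihood ratio is 1 contributes nothing
        mats1 = {"o": [AA], "s": [AA], "d": [AA]}
        freqs1 = {"m0": F_HALF}
        base = trio_lod("o", "s", "d", _store_from_matrices(mats1), freqs1, min_snps=1)
        ff = missing_parent_matrix(F_HALF)
        mats2 = {"o": [AA, ff], "s": [AA, ff], "d": [AA, ff]}
        freqs2 = {"m0": F_HALF, "m1": F_HALF}
        both = trio_lod("o", "s", "d", _store_from_matrices(mats2), freqs2, min_snps=1)
        assert both.lod == pytest.approx(base.lod)

    def test_impossible_trio_negative_infinity(self):
        store = _store_from_matrices({"o": [BB], "s": [AA], "d": [AA]})
        score = trio_lod("o", "s", "d", store, {"m0": F_HALF}, min_snps=1)
        assert score.lod == -np.inf


class TestResolveAndClassify:
    def s(self, lod, sire="s", dam="d"):
        return TrioScore("o", sire, dam, lod, 20)

    def test_trio_kept_when_best(self):
        out = resolve_trio(self.s(8), self.s(3, dam=None), self.s(2, sire=None))
        assert (out.sire_id, out.dam_id, out.lod) == ("s", "d", 8)

    def test_sire_pair_fallback(self):
        out = resolve_trio(self.s(2), self.s(5, dam=None), self.s(1, sire=None))
        assert (out.sire_id, out.dam_id, out.lod) == ("s", None, 5)

    def test_only_dam_pair_defined(self):
        out = resolve_trio(None, None, self.s(4, sire=None))
        assert (out.sire_id, out.dam_id, out.lod) == (None, "d", 4)
        assert resolve_trio(None, None, None) is None

    @pytest.mark.parametrize(
        "trio,sire,dam,expected",
        [
            (5, 3, 2, "sire+dam"),
            (3, 4, -1, "sire+missing"),
            (3, -1, 4, "dam+missing"),
            (1, 4, 2, "either+missing"),
            (-2, -1, -3, "both_missing"),
            (None, 4, -1, "sire+missing"),
        ],
    )
    def test_classification(self, trio, sire, dam, expected):
        assert classify_assignment(trio, sire, dam) == expected


class TestExclusion:
    @pytest.mark.parametrize(
        "ds,dd,do,expected",
        [(AA, AA, BB, 1), (AA, BB, HET, 0), (AA, AA, HET, 1)],
    )
    def test_single_marker(self, ds, dd, do, expected):
        assert count_mismatches([ds], [dd], [do]) == expected

    def test_missing_member_skipped(self):
        assert count_mismatches([AA, None], [AA, AA], [BB, BB]) == 1


class TestVectorisedScoring:
    def test_matches_scalar_path(self, rng):
        """Dense scoring equals per-trio trio_lod on random sparse data."""
        snps = [f"m{j}" for j in range(12)]
        samples = ["o1", "o2", "s1", "s2", "d1", "d2"]
        G = np.full((6, 12, 2, 2), np.nan)
        for i in range(6):
            for j in range(12):
                if rng.random() > 0.2:
                    G[i, j] = random_genotype_matrix(rng)
        store = GenotypeStore(samples, snps, G, "quantitative")
        freqs = {s: np.array([0.6, 0.4]) for s in snps}
        sets = score_trios(store, ["o1", "o2"], ["s1", "s2"], ["d1", "d2"],
                           freqs, min_snps=1)
        for ss in sets:
            for i, s in enumerate(ss.sires):
                for j, d in enumerate(ss.dams):
                    ref = trio_lod(ss.offspring_id, s, d, store, freqs, min_snps=1)
                    assert ss.trio_lod[i, j] == pytest.approx(ref.lod, abs=1e-10)
                    assert ss.trio_n[i, j] == ref.n_snps
                ref_s = trio_lod(ss.offspring_id, s, None, store, freqs, min_snps=1)
                assert ss.sire_lod[i] == pytest.approx(ref_s.lod, abs=1e-10)

    def test_min_snps_masks_scores(self, rng):
        snps = [f"m{j}" for j in range(5)]
        G = np.stack([np.stack([random_genotype_matrix(rng) for _ in snps])] * 3)
        store = GenotypeStore(["o", "s", "d"], snps, G, "quantitative")
        freqs = {s: F_HALF for s in snps}
        ss = score_trios(store, ["o"], ["s"], ["d"], freqs, min_snps=6)[0]
        assert np.isnan(ss.trio_lod).all()


class TestRanking:
    def _score_set(self, rng, n_snps=20):
        """Clean one-family setup: o's true parents are s1 x d1."""
        snps = [f"m{j}" for j in range(n_snps)]
        freqs = {s: F_HALF for s in snps}
        mats = {
            "o": [HET] * n_snps,
            "s1": [AA] * n_snps,
            "d1": [BB] * n_snps,
            "s2": [AA] * (n_snps // 2) + [BB] * (n_snps - n_snps // 2),
            "d2": [HET] * n_snps,
        }
        store = _store_from_matrices(mats, snps)
        return score_trios(store, ["o"], ["s1", "s2"], ["d1", "d2"], freqs,
                           min_snps=10)[0]

    def test_true_pair_ranked_first(self, rng):
        ranked = rank_parent_pairs(self._score_set(rng))
        assert ranked.best[0] == "s1" and ranked.best[1] == "d1"
        assert ranked.delta >= 0
        assert ranked.category == "sire+dam"

    def test_delta_threshold_blocks_assignment(self):
        ss = self._score_set(np.random.default_rng(0))
        tight = rank_parent_pairs(ss, lod_threshold=3.0, delta_threshold=1e9)
        assert not tight.assigned

    def test_exclusion_ranking(self, rng):
        n = 15
        snps = [f"m{j}" for j in range(n)]
        freqs = {s: F_HALF for s in snps}
        # offspring mixes het and AA markers; only s1 x d1 (AA x AB) is
        # consistent everywhere — any BB parent clashes with the AA markers
        mats = {
            "o": [HET] * 8 + [AA] * (n - 8),
            "s1": [AA] * n,
            "d1": [HET] * n,
            "s2": [BB] * n,
            "d2": [BB] * n,
        }
        store = _store_from_matrices(mats, snps)
        store.kind = "discrete"
        ss = score_trios(store, ["o"], ["s1", "s2"], ["d1", "d2"], freqs,
                         min_snps=10, count_exclusion_mismatches=True)[0]
        ranked = rank_parent_pairs_exclusion(ss, max_mismatches=0)
        assert ranked.best[:2] == ("s1", "d1")
        assert ranked.best[2] == 0
        assert ranked.assigned

    def test_exclusion_three_mismatch_rule(self, rng):
        n = 15
        snps = [f"m{j}" for j in range(n)]
        freqs = {s: F_HALF for s in snps}
        # true pair with 2 discordant markers, competitor with many
        mats = {
            "o": [HET] * (n - 2) + [AA, AA],
            "s1": [AA] * n,
            "d1": [BB] * n,
            "d2": [AA] * n,
        }
        store = _store_from_matrices(mats, snps)
        ss = score_trios(store, ["o"], ["s1"], ["d1", "d2"], freqs,
                         min_snps=10, count_exclusion_mismatches=True)[0]
        strict = rank_parent_pairs_exclusion(ss, max_mismatches=0)
        lenient = rank_parent_pairs_exclusion(ss, max_mismatches=3)
        assert not strict.assigned
        assert lenient.assigned and lenient.best[:2] == ("s1", "d1")
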