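import numpy as np
import pytest

from sigconnect import (
    ExtremeGeneSet,
    ScreenConfig,
    Signature,
    cosine_score,
    css,
    enrichment_score,
    pearson_score,
    score_pair,
    select_extreme_genes,
    spearman_score,
    wtcs,
    xsum,
)
from sigconnect.scoring import METHODS

from .oracles import naive_css, naive_enrichment_score, naive_xsum


class TestFullVectorScores:
    @pytest.mark.parametrize(
        "fn,q,r,expected",
        [
            (pearson_score, [1, 2, 3], [1, 2, 3], 1.0),
            (pearson_score, [1, 2, 3], [-1, -2, -3], -1.0),
            (pearson_score, [1, 2, 3], [1, 2, 4], 9 / (2 * np.sqrt(21))),
            (spearman_score, [1, 2, 3], [10, 200, 3000], 1.0),  # monotone map
            (spearman_score, [1, 2, 3], [5, 0, -5], -1.0),
            (spearman_score, [1, 2, 3, 4], [1, 3, 2, 4], 0.8),
            (cosine_score, [1, 2], [3, 6], 1.0),  # positive scaling
            (cosine_score, [1, 0], [0, 1], 0.0),
            (cosine_score, [1, 0], [1, 1], 1 / np.sqrt(2)),
        ],
    )
    def test_worked_examples(self, fn, q, r, expected):
        assert fn(q, r) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_score([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            spearman_score([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])

    def test_zero_norm_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_score([0.0, 0.0], [1.0, 2.0])


class TestEnrichmentScore:
    def test_top_gene_set_peaks_at_one(self, ref4):
        assert enrichment_score(["g1"], ref4) == pytest.approx(1.0)

    def test_bottom_gene_set_reaches_minus_one(self, ref4):
        assert enrichment_score(["g4"], ref4) == pytest.approx(-1.0)

    def test_whole_universe_set_disallowed(self, ref4):
        with pytest.raises(ValueError, match="proper subset"):
            enrichment_score(["g1", "g2", "g3", "g4"], ref4)

    def test_missing_gene_raises(self, ref4):
        with pytest.raises(KeyError, match="absent"):
            enrichment_score(["nope"], ref4)

    def test_matches_running_sum_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = rng.integers(5, 12)
            genes = tuple(f"g{i}" for i in range(n))
            z = rng.normal(size=n)
            m = rng.integers(1, n // 2 + 1)
            gene_set = list(rng.choice(genes, size=m, replace=False))
            ref = Signature("r", genes, z)
            assert enrichment_score(gene_set, ref) == pytest.approx(
                naive_enrichment_score(gene_set, genes, z), abs=1e-12
            )


class TestWtcs:
    def test_perfect_mimic_scores_one(self, ref4):
        ex = ExtremeGeneSet(("g1",), ("g4",), 1, [2.0], [-2.0])
        s = wtcs(ex, ref4)
        assert s.value == pytest.approx(1.0)
        assert s.es_up == pytest.approx(1.0)
        assert s.es_down == pytest.approx(-1.0)

    def test_swapping_sets_negates(self, ref4):
        ex = ExtremeGeneSet(("g1",), ("g4",), 1, [2.0], [-2.0])
        assert wtcs(ex.swapped(), ref4).value == pytest.approx(-wtcs(ex, ref4).value)

    def test_same_sign_components_force_zero(self):
        # both sets at the top of a 6-gene ranking: both ES positive
        genes = tuple(f"g{i}" for i in range(6))
        ref = Signature("r", genes, [3.0, 2.5, 2.0, -1.0, -1.5, -2.0])
        ex = ExtremeGeneSet(("g0",), ("g1",), 1, [5.0], [-4.0])
        s = wtcs(ex, ref)
        assert s.es_up > 0 and s.es_down > 0
        assert s.value == 0.0


class TestCss:
    def test_hand_example(self, ref6):
        ex = ExtremeGeneSet(("g1",), ("g6",), 1, [2.0], [-1.0])
        assert css(ex, ref6).value == pytest.approx(16 / 17, abs=1e-12)

    def test_attains_max_on_matching_extremes(self, ref6):
        # query extremes = reference's strongest genes, matching signs/order
        ex = ExtremeGeneSet(("g6",), ("g1",), 1, [9.0], [-8.0])
        # g6 has ref z < 0, so a query calling it "up" cannot reach +1;
        # the +1 pairing is up=g1 (ref +), down=g6 (ref -), |q| order matching
        ex = ExtremeGeneSet(("g1",), ("g6",), 1, [8.0], [-9.0])
        assert css(ex, ref6).value == pytest.approx(1.0)

    def test_flipped_query_signs_give_minus_one(self, ref6):
        ex = ExtremeGeneSet(("g6",), ("g1",), 1, [9.0], [-8.0])
        assert css(ex, ref6).value == pytest.approx(-1.0)


class TestXsum:
    def test_hand_enumeration(self):
        genes = tuple(f"g{i}" for i in range(1, 7))
        ref = Signature("r", genes, [3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ex = ExtremeGeneSet(("g1", "g3"), ("g6", "g4"), 2, [5.0, 4.0], [-5.0, -4.0])
        assert xsum(ex, ref, ref_extreme_n=2).value == pytest.approx(6.0)

    def test_zero_when_query_extremes_outside_reference_extremes(self):
        genes = tuple(f"g{i}" for i in range(1, 7))
        ref = Signature("r", genes, [3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ex = ExtremeGeneSet(("g3",), ("g4",), 1, [5.0], [-5.0])
        assert xsum(ex, ref, ref_extreme_n=1).value == 0.0

    def test_swapping_sets_negates(self):
        genes = tuple(f"g{i}" for i in range(1, 7))
        ref = Signature("r", genes, [3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ex = ExtremeGeneSet(("g1", "g3"), ("g6", "g4"), 2, [5.0, 4.0], [-5.0, -4.0])
        assert xsum(ex.swapped(), ref, 2).value == -xsum(ex, ref, 2).value


def _random_pair(rng, n):
    genes = tuple(f"g{i:03d}" for i in range(n))
    q = Signature("q", genes, rng.normal(size=n))
    r = Signature("r", genes, rng.normal(size=n))
    return q, r


class TestSmallInstanceOracles:
    """css and xsum against the independent naive evaluators on random
    small instances (N <= 12, K <= 3)."""

    def test_css_and_xsum_match_naive_evaluators(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            n = int(rng.integers(6, 13))
            k = int(rng.integers(1, 4))
            if 2 * k > n:
                continue
            q, r = _random_pair(rng, n)
            ex = select_extreme_genes(q, k)
            got_css = css(ex, r).value
            want_css = naive_css(ex.up, ex.down, ex.up_z, ex.down_z, r.gene_ids, r.z)
            assert got_css == pytest.approx(want_css, abs=1e-12)
            ref_n = int(rng.integers(1, n // 2 + 1))
            got_x = xsum(ex, r, ref_n).value
            want_x = naive_xsum(ex.up, ex.down, r.gene_ids, r.z, ref_n)
            assert got_x == pytest.approx(want_x, abs=1e-12)


class TestMethodProperties:
    def test_antisymmetry_in_the_query(self):
        """m(-q, r) == -m(q, r) for all six methods (up/down swap for the
        extreme methods) on 100 random tie-free instances."""
        rng = np.random.default_rng(31)
        cfg = ScreenConfig(K=3, min_overlap_frac=0.0)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            q, r = _random_pair(rng, n)
            fwd = {s.method: s.value for s in score_pair(q, r, cfg)}
            rev = {s.method: s.value for s in score_pair(q.negated(), r, cfg)}
            for m in METHODS:
                assert rev[m] == pytest.approx(-fwd[m], abs=1e-12), m

    def test_bounded_methods_stay_in_unit_interval(self):
        rng = np.random.default_rng(77)
        cfg = ScreenConfig(K=5)
        for _ in range(1000):
            q, r = _random_pair(rng, 20)
            for s in score_pair(q, r, cfg):
                if s.method != "xsum":
                    assert -1.0 - 1e-12 <= s.value <= 1.0 + 1e-12, s.method

    def test_permutation_invariance_of_all_scores(self):
        rng = np.random.default_rng(5)
        q, r = _random_pair(rng, 24)
        cfg = ScreenConfig(K=4)
        base = {s.method: s.value for s in score_pair(q, r, cfg)}
        perm = rng.permutation(24)
        q2 = Signature("q", tuple(q.gene_ids[i] for i in perm), q.z[perm])
        perm_r = rng.permutation(24)
        r2 = Signature("r", tuple(r.gene_ids[i] for i in perm_r), r.z[perm_r])
        shuffled = {s.method: s.value for s in score_pair(q2, r2, cfg)}
        for m in METHODS:
            assert shuffled[m] == pytest.approx(base[m], abs=1e-12), m


class TestScorePair:
    def test_self_comparison_maxima(self):
        rng = np.random.default_rng(9)
        genes = tuple(f"g{i:02d}" for i in range(50))
        q = Signature("q", genes, rng.normal(size=50))
        cfg = ScreenConfig(K=5)
        vals = {s.method: s.value for s in score_pair(q, q, cfg)}
        for m in ("pearson", "spearman", "cosine"):
            assert vals[m] == pytest.approx(1.0, abs=1e-12)
        assert vals["wtcs"] > 0.9
        assert vals["css"] > 0.9
        assert vals["xsum"] > 0.0

    def test_single_method_dispatch(self):
        rng = np.random.default_rng(10)
        q, r = _random_pair(rng, 12)
        out = score_pair(q, r, methods=["pearson"])
        assert len(out) == 1 and out[0].method == "pearson"

    def test_matches_standalone_operations(self):
        rng = np.random.default_rng(11)
        q, r = _random_pair(rng, 50)
        cfg = ScreenConfig(K=6)
        vals = {s.method: s.value for s in score_pair(q, r, cfg)}
        ex = select_extreme_genes(q, 6)
        assert vals["pearson"] == pytest.approx(pearson_score(q.z, r.z), abs=1e-12)
        assert vals["spearman"] == pytest.approx(spearman_score(q.z, r.z), abs=1e-12)
        assert vals["cosine"] == pytest.approx(cosine_score(q.z, r.z), abs=1e-12)
        assert vals["wtcs"] == pytest.approx(wtcs(ex, r).value, abs=1e-12)
        assert vals["css"] == pytest.approx(css(ex, r).value, abs=1e-12)
        assert vals["xsum"] == pytest.approx(xsum(ex, r, 6).value, abs=1e-12)

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(12)
        q, r = _random_pair(rng, 10)
        with pytest.raises(ValueError, match="unknown methods"):
            score_pair(q, r, methods=["tau"])
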