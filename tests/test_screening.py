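import io

import numpy as np
import pytest

from sigconnect import (
    BackgroundStore,
    ScreenConfig,
    Signature,
    SignatureRepository,
    SimulationSpec,
    build_background,
    meta_score,
    method_votes,
    run_screen,
    simulate_query,
    simulate_repository,
    wtcs_gate,
)


class TestMetaScore:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            ((1, 1, 1, 1, 1, 1), 6),  # every method in its top fraction
            ((0, 0, 0, 0, 0, 0), 0),  # no method votes
            ((1, 1, 1, 0, 0, 0), 3),
        ],
    )
    def test_counts_votes(self, votes, expected):
        assert meta_score(votes) == expected

    def test_wrong_arity_raises(self):
        with pytest.raises(ValueError, match="six votes"):
            meta_score((1, 1, 1))

    def test_non_binary_votes_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            meta_score((2, 0, 0, 0, 0, 0))


class TestMethodVotes:
    def test_exact_cutoff_count_without_ties(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i:03d}" for i in range(100)]
        scores = rng.normal(size=100)
        votes = method_votes(ids, scores=scores, direction="positive", vote_quantile=0.05)
        assert votes.sum() == 5
        top5 = np.argsort(-scores)[:5]
        assert set(np.flatnonzero(votes)) == set(top5)

    def test_ceiling_rule_on_small_screens(self):
        ids = [f"s{i}" for i in range(10)]
        votes = method_votes(ids, scores=np.arange(10.0), direction="positive",
                             vote_quantile=0.05)
        assert votes.sum() == 1 and votes[9] == 1

    def test_negative_direction_flips_ranking(self):
        ids = ["a", "b", "c", "d"]
        scores = np.array([0.9, -0.8, 0.1, -0.2])
        votes = method_votes(ids, scores=scores, direction="negative", vote_quantile=0.25)
        assert votes.tolist() == [0, 1, 0, 0]

    def test_pvalue_ranking_prefers_small_p(self):
        ids = ["a", "b", "c", "d"]
        p = np.array([0.5, 0.01, 0.2, 0.9])
        votes = method_votes(ids, pvalues=p, vote_quantile=0.25)
        assert votes.tolist() == [0, 1, 0, 0]

    def test_ineligible_references_never_vote(self):
        ids = ["a", "b", "c", "d"]
        scores = np.array([4.0, 3.0, 2.0, 1.0])
        eligible = np.array([False, True, True, True])
        votes = method_votes(ids, scores=scores, direction="positive",
                             vote_quantile=0.25, eligible=eligible)
        assert votes.tolist() == [0, 1, 0, 0]


class TestWtcsGate:
    def test_union_rule(self):
        flags = np.array([[0, 0, 0, 1, 0], [0, 0, 0, 0, 0], [1, 1, 0, 0, 1]])
        np.testing.assert_array_equal(wtcs_gate(flags), [True, False, True])

    def test_all_significant_gate_is_identity(self):
        flags = np.ones((4, 5), dtype=int)
        assert wtcs_gate(flags).all()

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="S, 5"):
            wtcs_gate(np.ones((3, 6)))


@pytest.fixture(scope="module")
def copy_screen():
    """Positive screen over nulls plus an exact copy of the query."""
    query = simulate_query(500, seed=21)
    repo, _ = simulate_repository(SimulationSpec(n_genes=500, n_signatures=220, seed=22), query)
    matrix = np.column_stack([repo.matrix, query.z])
    repo2 = SignatureRepository(
        repo.gene_universe,
        list(repo.sig_ids) + ["COPY_OF_QUERY"],
        matrix,
        repo.metadata + [{"compound": "self"}],
    )
    cfg = ScreenConfig(K=50, direction="positive", vote_quantile=0.05)
    return run_screen(query, repo2, cfg)


class TestRunScreen:
    def test_exact_copy_ranks_first_with_full_meta_score(self, copy_screen):
        top = copy_screen.results[0]
        assert top.sig_id == "COPY_OF_QUERY"
        assert top.meta_score == 6
        assert all(v == 1 for v in top.votes.values())

    def test_null_reference_below_every_cutoff_scores_zero(self, copy_screen):
        median = copy_screen.results[len(copy_screen.results) // 2]
        assert median.meta_score == 0
        assert all(v == 0 for v in median.votes.values())

    def test_planted_reversal_tops_negative_screen(self, planted_screen_inputs):
        query, repo, truth = planted_screen_inputs
        planted = truth.loc[truth.kind == "reversal", "sig_id"].item()
        rep = run_screen(query, repo, ScreenConfig(K=50, direction="negative"))
        assert rep.results[0].sig_id == planted
        assert rep.results[0].meta_score >= 5

    def test_direction_flip_demotes_the_reversal(self, planted_screen_inputs):
        query, repo, truth = planted_screen_inputs
        planted = truth.loc[truth.kind == "reversal", "sig_id"].item()
        rep = run_screen(query, repo, ScreenConfig(K=50, direction="positive"))
        assert rep.results[0].sig_id != planted

    def test_gated_set_contains_every_non_wtcs_voter(self, planted_screen_inputs):
        query, repo, _ = planted_screen_inputs
        rep = run_screen(query, repo, ScreenConfig(K=50, direction="negative"))
        for r in rep.results:
            if any(r.votes[m] for m in ("pearson", "spearman", "cosine", "css", "xsum")):
                assert r.gated
            if not r.gated:
                assert r.votes["wtcs"] == 0
                assert "wtcs" not in r.scores

    def test_mean_meta_score_on_null_repository(self):
        """Each method votes ceil(q*S) of S references, so the null mean
        meta-score is ~ 6*q."""
        query = simulate_query(400, seed=31)
        repo, _ = simulate_repository(SimulationSpec(n_genes=400, n_signatures=400, seed=32), query)
        rep = run_screen(query, repo, ScreenConfig(K=40, direction="negative"))
        mean_meta = np.mean([r.meta_score for r in rep.results])
        assert mean_meta == pytest.approx(6 * 0.05, abs=0.05)

    def test_ranks_are_contiguous_from_one(self, copy_screen):
        ranks = [r.rank for r in copy_screen.results]
        assert ranks == list(range(1, len(ranks) + 1))

    def test_empty_overlap_raises(self):
        query = Signature("q", ("x1", "x2", "x3"), [1.0, 2.0, 3.0])
        repo, _ = simulate_repository(SimulationSpec(n_genes=100, n_signatures=5, seed=1))
        with pytest.raises(ValueError):
            run_screen(query, repo, ScreenConfig(K=2))


class TestDeterminism:
    def _tsv_bytes(self, report) -> bytes:
        buf = io.StringIO()
        report.to_tsv(buf)
        return buf.getvalue().encode()

    def test_repeat_runs_are_byte_identical(self, planted_screen_inputs):
        query, repo, _ = planted_screen_inputs
        cfg = ScreenConfig(K=50, direction="negative", seed=5)
        a = self._tsv_bytes(run_screen(query, repo, cfg))
        b = self._tsv_bytes(run_screen(query, repo, cfg))
        assert a == b

    def test_worker_count_does_not_change_output(self, planted_screen_inputs):
        query, repo, _ = planted_screen_inputs
        cfg = ScreenConfig(K=50, direction="negative", seed=5)
        serial = self._tsv_bytes(run_screen(query, repo, cfg, n_jobs=1))
        parallel = self._tsv_bytes(run_screen(query, repo, cfg, n_jobs=4))
        assert serial == parallel

    def test_reversal_duality(self, planted_screen_inputs):
        """Negating the query and swapping the screen direction yields the
        same ranking."""
        query, repo, _ = planted_screen_inputs
        neg = run_screen(query, repo, ScreenConfig(K=50, direction="negative"))
        dual = run_screen(query.negated(), repo, ScreenConfig(K=50, direction="positive"))
        assert [r.sig_id for r in neg.results] == [r.sig_id for r in dual.results]
        assert [r.meta_score for r in neg.results] == [r.meta_score for r in dual.results]


class TestScreenWithBackgrounds:
    def test_pvalues_reported_and_votes_consistent(self):
        query = simulate_query(300, seed=41)
        repo, _ = simulate_repository(SimulationSpec(n_genes=300, n_signatures=30, seed=42), query)
        cfg = ScreenConfig(K=20, direction="positive", n_perm=200, seed=7)
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            store = BackgroundStore(d)
            for sig in repo:
                store.put(
                    build_background(sig, "css", cfg.K, cfg.n_perm, cfg.seed),
                    build_background(sig, "xsum", cfg.K, cfg.n_perm, cfg.seed),
                )
            rep = run_screen(query, repo, cfg, backgrounds=store)
        for r in rep.results:
            for m in ("css", "xsum"):
                assert 1 / (cfg.n_perm + 1) <= r.pvalues[m] <= 1.0
        # votes still sum to the meta-score
        for r in rep.results:
            assert r.meta_score == sum(r.votes.values())

    def test_missing_background_coverage_raises(self):
        query = simulate_query(300, seed=41)
        repo, _ = simulate_repository(SimulationSpec(n_genes=300, n_signatures=5, seed=42), query)
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            store = BackgroundStore(d)  # empty
            with pytest.raises(KeyError):
                run_screen(query, repo, ScreenConfig(K=20, n_perm=100), backgrounds=store)
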