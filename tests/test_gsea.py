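import numpy as np
import pandas as pd
import pytest

from mirgenet import (
    enrichment_score,
    generate_cohort,
    goplot_zscore,
    gsea_phenotype_permutation,
    rank_by_trait_correlation,
)

from conftest import toy_matrix


def es_oracle(scores, hit, weight):
    """Exhaustive evaluation of the weighted KS deviation at every rank."""
    N = len(scores)
    nh = hit.sum()
    w = np.abs(scores) ** weight
    denom = w[hit].sum()
    if denom == 0:
        w = np.ones(N)
        denom = float(nh)
    running, best = 0.0, 0.0
    for i in range(N):
        running += w[i] / denom if hit[i] else -1.0 / (N - nh)
        if abs(running) > abs(best):
            best = running
    return best


class TestRanking:
    def test_matches_closed_form_pearson(self, rng):
        Z = rng.normal(size=(6, 5))
        trait = rng.normal(size=6)
        ranked = rank_by_trait_correlation(toy_matrix(Z, prefix="G"), trait)
        for _, row in ranked.iterrows():
            j = int(row["gene_id"][1:]) - 1
            x, t = Z[:, j], trait
            r = np.sum((x - x.mean()) * (t - t.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((t - t.mean()) ** 2)
            )
            assert abs(row["score"] - r) < 1e-12
        assert ranked["score"].is_monotonic_decreasing

    def test_trait_equal_to_gene_ranks_it_first(self, rng):
        Z = rng.normal(size=(8, 4))
        ranked = rank_by_trait_correlation(toy_matrix(Z, prefix="G"), Z[:, 2])
        assert ranked["gene_id"].iloc[0] == "G3"
        assert ranked["score"].iloc[0] == pytest.approx(1.0)

    def test_negated_trait_reverses_ranking(self, rng):
        Z = rng.normal(size=(7, 6))
        trait = rng.normal(size=7)
        m = toy_matrix(Z, prefix="G")
        fwd = rank_by_trait_correlation(m, trait)["gene_id"].tolist()
        rev = rank_by_trait_correlation(m, -trait)["gene_id"].tolist()
        assert fwd == rev[::-1]

    def test_constant_trait_rejected_constant_gene_warned(self, rng):
        Z = rng.normal(size=(5, 3))
        m = toy_matrix(Z, prefix="G")
        with pytest.raises(ValueError, match="constant"):
            rank_by_trait_correlation(m, np.ones(5))
        Zc = Z.copy()
        Zc[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant gene"):
            ranked = rank_by_trait_correlation(toy_matrix(Zc, prefix="G"), rng.normal(size=5))
        assert ranked.set_index("gene_id").loc["G2", "score"] == 0.0


class TestEnrichmentScore:
    def _ranked(self, scores):
        return pd.DataFrame(
            {"gene_id": [f"G{i + 1}" for i in range(len(scores))], "score": scores}
        )

    def test_top_gene_unweighted_walk(self):
        # N=4, set={top gene}, weight 0: hit at position 1 contributes the
        # full +1 before any of the 1/3 miss decrements
        ranked = self._ranked([0.9, 0.5, -0.2, -0.8])
        es, running = enrichment_score(ranked, {"G1"}, weight_exponent=0.0)
        assert es == pytest.approx(1.0)
        np.testing.assert_allclose(running, [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_bottom_gene_unweighted_walk(self):
        # hand-derived walk: three 1/3 misses then the hit
        ranked = self._ranked([0.9, 0.5, -0.2, -0.8])
        es, running = enrichment_score(ranked, {"G4"}, weight_exponent=0.0)
        np.testing.assert_allclose(running, [-1 / 3, -2 / 3, -1.0, 0.0])
        assert es == pytest.approx(-1.0)

    def test_reversed_list_negates_and_mirrors_running_sum(self, rng):
        # reversing the ranked list turns running'_j into -running_{N-2-j}
        # (the total walk sums to zero), so the ES flips sign and its
        # extremum moves to the mirrored position
        N = 12
        scores = np.sort(rng.normal(size=N))[::-1]
        ranked = self._ranked(scores)
        flipped = ranked.iloc[::-1].reset_index(drop=True)
        members = {"G2", "G5", "G11"}
        es_f, run_f = enrichment_score(ranked, members, 1.0)
        es_r, run_r = enrichment_score(flipped, members, 1.0)
        assert es_r == pytest.approx(-es_f, abs=1e-12)
        np.testing.assert_allclose(run_r[: N - 1], -run_f[: N - 1][::-1], atol=1e-12)
        pos_f = int(np.argmax(np.abs(run_f)))
        pos_r = int(np.argmax(np.abs(run_r)))
        assert pos_r == N - 2 - pos_f

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(500):
            N = int(rng.integers(5, 51))
            scores = np.sort(rng.normal(size=N))[::-1]
            k = int(rng.integers(1, N))
            hit_idx = rng.choice(N, size=k, replace=False)
            hit = np.zeros(N, bool)
            hit[hit_idx] = True
            ranked = self._ranked(scores)
            members = {f"G{i + 1}" for i in np.flatnonzero(hit)}
            weight = float(rng.choice([0.0, 1.0, 1.5]))
            es, _ = enrichment_score(ranked, members, weight)
            assert es == pytest.approx(es_oracle(scores, hit, weight), abs=1e-12)

    def test_degenerate_overlap_rejected(self):
        ranked = self._ranked([0.5, -0.5])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"G1", "G2"}, 1.0)
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"ABSENT"}, 1.0)


class TestZscore:
    @pytest.mark.parametrize(
        "n_up,n_down,expected", [(4, 0, 2.0), (3, 3, 0.0), (1, 0, 1.0)]
    )
    def test_values(self, n_up, n_down, expected):
        assert goplot_zscore(n_up, n_down) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            goplot_zscore(0, 0)


class TestPhenotypePermutation:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(p_mirna=60, q_gene=300, n_null_sets=10, seed=4)

    def _trait(self, cohort):
        # class-driven trait emulating a component-1 score
        return cohort.labels.y_index().astype(float) + np.random.default_rng(
            0
        ).normal(0, 0.3, cohort.labels.n_samples)

    def test_planted_target_set_enriched(self, cohort):
        table = gsea_phenotype_permutation(
            cohort.gene,
            self._trait(cohort),
            cohort.gene_sets,
            n_perm=200,
            min_size=5,
            seed=9,
        )
        row = table.set_index("set").loc["TARGET_BLOCK_C1"]
        assert row["q"] < 0.05
        assert row["direction"] == "negative"  # targets are repressed
        assert row["z_score"] < 0
        # NES sign matches ES sign, q in [0, 1] for every set
        assert np.all(np.sign(table["nes"]) == np.sign(table["es"]))
        assert table["q"].between(0, 1).all()
        assert table["p"].gt(0).all() and table["p"].le(1).all()

    def test_deterministic_in_seed(self, cohort):
        kwargs = dict(n_perm=100, min_size=5, seed=3)
        t1 = gsea_phenotype_permutation(
            cohort.gene, self._trait(cohort), cohort.gene_sets, **kwargs
        )
        t2 = gsea_phenotype_permutation(
            cohort.gene, self._trait(cohort), cohort.gene_sets, **kwargs
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_size_window_filters_sets(self, cohort):
        with pytest.warns(UserWarning, match="dropped"):
            table = gsea_phenotype_permutation(
                cohort.gene,
                self._trait(cohort),
                cohort.gene_sets,
                n_perm=100,
                min_size=6,  # planted block has 5 members
                seed=3,
            )
        assert "TARGET_BLOCK_C1" not in set(table["set"])

    def test_singleton_set_nominal_p_approaches_rank_probability(self, rng):
        # weight 0, set of size 1: under trait permutation the hit lands
        # uniformly; P(ES >= observed) has a closed form from the rank
        Z = rng.normal(size=(30, 20))
        m = toy_matrix(Z, prefix="G")
        trait = Z[:, 0] + rng.normal(0, 2.0, 30)  # moderate association
        from mirgenet.io import GeneSetCollection

        sets = GeneSetCollection(sets={"ONE": ["G1"]})
        table = gsea_phenotype_permutation(
            m, trait, sets, n_perm=2000, weight_exponent=0.0, min_size=1, seed=6
        )
        # with weight 0 and one member, ES is a deterministic, monotone
        # decreasing function of the member's rank; the permutation p of
        # the observed ES therefore converges to P(rank_perm <= rank_obs
        # | same sign), which we estimate directly from fresh permutations
        ranked = rank_by_trait_correlation(m, trait)
        obs_rank = ranked["gene_id"].tolist().index("G1")
        rng2 = np.random.default_rng(1)
        ranks, N = [], 2000
        for _ in range(N):
            rb = rank_by_trait_correlation(m, rng2.permutation(trait))
            ranks.append(rb["gene_id"].tolist().index("G1"))
        ranks = np.asarray(ranks)
        es_obs = table["es"].iloc[0]
        if es_obs >= 0:
            better = (ranks <= obs_rank) & (ranks < 10)  # same-sign side
            same = ranks < 10
        else:
            better = (ranks >= obs_rank) & (ranks >= 10)
            same = ranks >= 10
        analytic = (1 + better.sum()) / (1 + same.sum())
        assert table["p"].iloc[0] == pytest.approx(analytic, abs=0.05)
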