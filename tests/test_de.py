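"""Tests of filtering, normalization, the paired mixed model, moderation,
FDR adjustment and the DEG summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from plaquestrat import de
from plaquestrat import simulate as sim
from plaquestrat.errors import ParameterError
from conftest import two_group_paired_study


# ---------------------------------------------------------------------------
# filtering + normalization


class TestFilterProbes:
    @pytest.mark.parametrize(
        "values,kept",
        [
            ([2.9, 2.9, 2.9, 2.9], False),       # fails expression rule
            ([5.0, 5.0, 5.0, 5.0], False),       # passes expression, fails SD
            ([3.1, 2.8, 2.9, 3.05], True),       # one sample > 3 and SD > 0.1
        ],
    )
    def test_rules(self, values, kept):
        matrix = pd.DataFrame(
            [values, [8.0, 9.0, 7.5, 8.5]], index=["probe", "anchor"],
            columns=list("abcd"),
        )
        out, report = de.filter_probes(matrix)
        assert ("probe" in out.index) == kept
        assert report["n_input"] == 2

    def test_report_counts(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.uniform(4, 10, (50, 6)))
        out, report = de.filter_probes(matrix)
        assert report["n_kept"] == len(out) == 50


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        col = np.array([1.0, 5.0, 3.0])
        matrix = pd.DataFrame({"a": col, "b": col})
        out = de.quantile_normalize(matrix)
        np.testing.assert_allclose(out, matrix)

    def test_two_column_hand_example(self):
        matrix = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = de.quantile_normalize(matrix)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_equal_column_means_and_idempotence(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(rng.normal(8, 2, (40, 5)))
        once = de.quantile_normalize(matrix)
        means = once.mean(axis=0).to_numpy()
        np.testing.assert_allclose(means, means[0], atol=1e-12)
        twice = de.quantile_normalize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)


# ---------------------------------------------------------------------------
# paired mixed model


class TestGeneModels:
    def test_noise_free_interaction_identity(self):
        study = two_group_paired_study(
            n_per_group=4, n_genes=5, seed=0, delta_thin=1.0, delta_thick=2.5,
            subject_sd=0.5, noise_sd=0.0,
        )
        fits = de.fit_gene_models(study)
        table = de.apply_contrasts(fits)
        inter = table[table.contrast == "interaction"]["estimate"]
        np.testing.assert_allclose(inter, 1.5, atol=1e-10)

    def test_single_group_contrast_equals_paired_ttest(self):
        study = two_group_paired_study(n_per_group=9, n_genes=25, seed=3,
                                       delta_thin=0.4)
        # keep only the thin group → model reduces to expression ~ tissue + (1|subj)
        keep = study.samples[study.samples.group == "thin"]
        sub = sim.ExpressionStudy(
            matrix=study.matrix[keep["sample_id"]], samples=keep
        )
        fits = de.fit_gene_models(sub)
        assert fits.single_group
        table = de.apply_contrasts(fits)
        ls = sub.matrix[[c for c in sub.matrix.columns if c.endswith("_LS")]]
        nl = sub.matrix[[c for c in sub.matrix.columns if c.endswith("_NL")]]
        t_ref, p_ref = stats.ttest_rel(ls, nl, axis=1)
        np.testing.assert_allclose(table["t"], t_ref, atol=1e-8)
        np.testing.assert_allclose(table["p"], p_ref, atol=1e-8)

    def test_two_group_contrast_equals_pooled_paired_ttest(self):
        study = two_group_paired_study(n_per_group=7, n_genes=10, seed=4,
                                       delta_thin=0.5, delta_thick=0.9)
        fits = de.fit_gene_models(study)
        table = de.apply_contrasts(fits)
        d = (
            study.matrix[[c for c in study.matrix.columns if c.endswith("_LS")]]
            .to_numpy()
            - study.matrix[[c for c in study.matrix.columns if c.endswith("_NL")]]
            .to_numpy()
        )
        grp = study.samples[study.samples.tissue == "LS"]["group"].to_numpy()
        d1, d2 = d[:, grp == "thin"], d[:, grp == "thick"]
        n1, n2 = d1.shape[1], d2.shape[1]
        ss = ((d1 - d1.mean(1, keepdims=True)) ** 2).sum(1) + (
            (d2 - d2.mean(1, keepdims=True)) ** 2
        ).sum(1)
        s2 = ss / (n1 + n2 - 2)
        t_ref = d1.mean(1) / np.sqrt(s2 / n1)
        got = table[table.contrast == "LSvsNL_thin"]["t"].to_numpy()
        np.testing.assert_allclose(got, t_ref, atol=1e-8)

    def test_recovers_interaction_amplitude(self, small_study):
        fits = de.fit_gene_models(small_study)
        table = de.apply_contrasts(fits)
        inter = table[table.contrast == "interaction"].set_index("gene")
        up = small_study.truth.loc[small_study.truth.role == "up", "gene"]
        # E[interaction] = (amplitude − 1) · base_lfc = 0.6 · 1.5 = 0.9
        mean_est = inter.loc[up, "estimate"].mean()
        assert mean_est == pytest.approx(0.9, abs=0.15)

    def test_boundary_variance_flagged(self):
        # noise-only data with no subject effect → σ²_b often at the boundary
        study = two_group_paired_study(n_per_group=6, n_genes=40, seed=5,
                                       subject_sd=0.0, noise_sd=1.0)
        fits = de.fit_gene_models(study)
        assert fits.boundary.any()
        assert (fits.sigma2_b >= 0).all()


class TestContrasts:
    def test_zero_contrast_flagged(self):
        study = two_group_paired_study(n_per_group=4, n_genes=3, seed=6)
        fits = de.fit_gene_models(study)
        table = de.apply_contrasts(fits, {"null": np.zeros(4)})
        assert (table["estimate"] == 0).all()
        assert table["t"].isna().all()

    def test_contrast_linear_consistency(self, small_study):
        table = de.apply_contrasts(de.fit_gene_models(small_study))
        wide = table.pivot(index="gene", columns="contrast", values="estimate")
        np.testing.assert_allclose(
            wide["LSvsNL_thin"] + wide["interaction"], wide["LSvsNL_thick"],
            atol=1e-12,
        )

    def test_hand_computed_cell_means(self):
        # 1 gene, 2 subjects per group, hand-constructed values
        vals = {
            "t1_LS": 5.0, "t1_NL": 3.0, "t2_LS": 6.0, "t2_NL": 4.0,   # thin
            "k1_LS": 9.0, "k1_NL": 4.0, "k2_LS": 11.0, "k2_NL": 6.0,  # thick
        }
        meta = pd.DataFrame(
            [
                {"sample_id": s, "subject_id": s.split("_")[0],
                 "tissue": s.split("_")[1],
                 "group": "thin" if s.startswith("t") else "thick"}
                for s in vals
            ]
        )
        study = sim.ExpressionStudy(
            matrix=pd.DataFrame([list(vals.values())], index=["g"],
                                columns=list(vals)),
            samples=meta,
        )
        table = de.apply_contrasts(de.fit_gene_models(study)).set_index("contrast")
        assert table.loc["LSvsNL_thin", "estimate"] == pytest.approx(2.0)
        assert table.loc["LSvsNL_thick", "estimate"] == pytest.approx(5.0)
        assert table.loc["interaction", "estimate"] == pytest.approx(3.0)
        assert table.loc["ThickvsThin_NL", "estimate"] == pytest.approx(1.5)
        assert table.loc["ThickvsThin_LS", "estimate"] == pytest.approx(4.5)

    def test_bad_contrast_length_rejected(self):
        study = two_group_paired_study(n_per_group=4, n_genes=2, seed=7)
        fits = de.fit_gene_models(study)
        with pytest.raises(ParameterError):
            de.apply_contrasts(fits, {"bad": np.ones(3)})


class TestModeration:
    def test_identical_variances_are_left_alone(self):
        study = two_group_paired_study(n_per_group=5, n_genes=30, seed=8)
        fits = de.fit_gene_models(study)
        fits.sigma2_e = np.full_like(fits.sigma2_e, 0.25)
        table = de.apply_contrasts(fits)
        table["sigma2_e"] = 0.25
        out, params = de.moderate(table, fits)
        np.testing.assert_allclose(params.s2_post, 0.25, rtol=1e-6)

    def test_prior_recovery_from_scaled_inv_chisq(self):
        # s²_g ~ σ²_g χ²_d / d with σ²_g ~ d0·s0²/χ²_{d0}; d0=4, s0²=0.05
        d0_true, s0_true, df = 4.0, 0.05, 20
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sigma2 = d0_true * s0_true / rng.chisquare(d0_true, 1500)
            s2 = sigma2 * rng.chisquare(df, 1500) / df
            d0, s0_sq = de.estimate_prior(s2, df)
            if abs(d0 - d0_true) < 0.25 * d0_true and abs(s0_sq - s0_true) < 0.25 * s0_true:
                hits += 1
        assert hits >= 75

    def test_infinite_prior_df_pools_variances(self):
        study = two_group_paired_study(n_per_group=5, n_genes=50, seed=9)
        fits = de.fit_gene_models(study)
        # variances with *less* spread than χ² sampling noise → d0 = ∞
        fits.sigma2_e = np.full_like(fits.sigma2_e, 0.1)
        table = de.apply_contrasts(fits)
        out, params = de.moderate(table, fits)
        assert np.isinf(params.d0)
        assert np.isinf(params.df_total)


class TestBHAdjust:
    def test_step_up_hand_example(self):
        q = de.bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, 0.05)

    def test_all_equal_p(self):
        q = de.bh_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, 0.2)

    @staticmethod
    def brute_force(p):
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        for rank_i, i in enumerate(order):
            tail = [p[j] * m / (rank_j + 1)
                    for rank_j, j in enumerate(order) if rank_j >= rank_i]
            q[i] = min(1.0, min(tail))
        return q

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(de.bh_adjust(p), self.brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        q_ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(de.bh_adjust(p), q_ref, atol=1e-12)

    def test_permutation_invariance_and_q_ge_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        q = de.bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        np.testing.assert_allclose(de.bh_adjust(p[perm]), q[perm], atol=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            de.bh_adjust([0.5, 1.2])


class TestDegCalling:
    def test_conjunction_rule(self):
        table = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3"],
                "contrast": "LSvsNL_thin",
                "estimate": [np.log2(2.1), np.log2(2.1), np.log2(1.5)],
                "p": [0.01, 0.01, 0.001],
                "q": [0.06, 0.01, 0.001],
            }
        )
        degs = de.call_degs(table)["LSvsNL_thin"]
        # g1 fails FDR, g3 fails fold change, g2 passes all three
        assert list(degs["gene"]) == ["g2"]

    def test_empty_table_empty_sets(self):
        table = pd.DataFrame(
            {"gene": [], "contrast": pd.Series([], dtype=str),
             "estimate": [], "p": [], "q": []}
        )
        assert de.call_degs(table) == {}

    def test_strong_signature_recovered_exactly(self):
        cohort = sim.attach_groups(
            sim.simulate_thickness(sim.CohortSimParams(n_patients=30, seed=11))
        )
        params = sim.ExpressionSimParams(
            n_genes=300, n_signature=30, base_lfc=2.0, amplitude=1.5,
            subject_sd=0.1, noise_sd=0.05, seed=11,
        )
        study = sim.simulate_expression(cohort, params)
        fits = de.fit_gene_models(study)
        table, _ = de.moderate(de.apply_contrasts(fits), fits)
        degs = de.call_degs(de.add_fdr(table))
        sig = set(study.truth.loc[study.truth.role != "null", "gene"])
        assert set(degs["LSvsNL_thin"]["gene"]) == sig
        assert set(degs["LSvsNL_thick"]["gene"]) == sig


class TestOverlapAndCorrelation:
    def test_identical_sets_full_overlap(self):
        out = de.overlap_summary({"a", "b"}, {"a", "b"})
        assert out["overlap_pct"] == 100.0

    def test_hand_counts(self):
        out = de.overlap_summary({1, 2, 3}, {2, 3, 4}, reference={2, 3})
        assert out["n_intersection"] == 2
        assert out["n_union"] == 4
        assert out["overlap_pct"] == 50.0
        assert out["overlap_min_pct"] == pytest.approx(100 * 2 / 3)
        assert out["reference_in_both_pct"] == 100.0

    def test_fc_correlation_identical_vectors(self):
        table = pd.DataFrame(
            {
                "gene": ["a", "b", "c"] * 2,
                "contrast": ["LSvsNL_thin"] * 3 + ["LSvsNL_thick"] * 3,
                "estimate": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            }
        )
        assert de.fc_correlation(table) == pytest.approx(1.0)

    def test_fc_correlation_hand_example(self):
        table = pd.DataFrame(
            {
                "gene": ["a", "b", "c"] * 2,
                "contrast": ["LSvsNL_thin"] * 3 + ["LSvsNL_thick"] * 3,
                "estimate": [1.0, 2.0, 3.0, 1.0, 3.0, 2.0],
            }
        )
        assert de.fc_correlation(table) == pytest.approx(0.5)

    def test_shared_signature_gives_high_correlation(self, small_study):
        fits = de.fit_gene_models(small_study)
        table, _ = de.moderate(de.apply_contrasts(fits), fits)
        table = de.add_fdr(table)
        degs = de.call_degs(table)
        union = set(degs["LSvsNL_thin"]["gene"]) | set(degs["LSvsNL_thick"]["gene"])
        r = de.fc_correlation(table, genes=union)
        assert r > 0.9


# ---------------------------------------------------------------------------
# clustering


def wpgma_oracle(points):
    """Brute-force WPGMA: explicit distance-matrix updates."""
    d = squareform(pdist(points))
    n = len(points)
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((min(i, j), max(i, j), h, len(active[i]) + len(active[j])))
        newd = {}
        for k in active:
            if k in (i, j):
                continue
            a = dist[tuple(sorted((i, k)))]
            b = dist[tuple(sorted((j, k)))]
            newd[k] = 0.5 * (a + b)
        active[next_id] = active.pop(i) + active.pop(j)
        dist = {
            (a, b): v for (a, b), v in dist.items()
            if a not in (i, j) and b not in (i, j)
        }
        for k, v in newd.items():
            dist[tuple(sorted((k, next_id)))] = v
        next_id += 1
    return merges


class TestWPGMA:
    def test_three_point_hand_execution(self):
        # pairwise distances: d(a,b)=1, d(a,c)=2, d(b,c)=3 on a line won't
        # work in Euclidean 1-D, so use explicit coordinates giving 1, 2, ~3
        pts = np.array([[0.0], [1.0], [-2.0]])  # d(ab)=1, d(ac)=2, d(bc)=3
        Z, order = de.wpgma_cluster(pts)
        assert Z[0, 2] == pytest.approx(1.0)       # first merge at distance 1
        assert Z[1, 2] == pytest.approx(2.5)       # (2 + 3) / 2

    def test_duplicate_points_merge_first_at_zero(self):
        pts = np.array([[5.0, 1.0], [0.0, 0.0], [5.0, 1.0]])
        Z, _ = de.wpgma_cluster(pts)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        Z, _ = de.wpgma_cluster(pts)
        merges = wpgma_oracle(pts)
        np.testing.assert_allclose(Z[:, 2], [m[2] for m in merges], atol=1e-10)
        np.testing.assert_allclose(Z[:, 3], [m[3] for m in merges])
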