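"""Relationship matrices and animal-model REML."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from resilipig.genetics import (
    RelationshipMatrix,
    blend_H,
    build_design,
    pedigree_A,
    reml_bivariate_arrays,
    reml_loglik,
    reml_univariate_arrays,
    vanraden_G,
)
from resilipig.simulate import simulate_half_sib_trait

_LOG2PI = np.log(2 * np.pi)


def half_sib_K(n_sires, k):
    """Additive relationships for paternal half-sib families (unique dams)."""
    n = n_sires * k
    K = np.eye(n)
    for s in range(n_sires):
        sl = slice(s * k, (s + 1) * k)
        block = np.full((k, k), 0.25)
        np.fill_diagonal(block, 1.0)
        K[sl, sl] = block
    return K


def dense_reml_loglik_oracle(y, X, K, s2a, s2e):
    """Direct-formula restricted log-likelihood, independent implementation."""
    n, p = X.shape
    V = s2a * K + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = r @ Vi @ r
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * _LOG2PI + ldV + ldX + quad)


class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        ped = pd.DataFrame(
            {"animal_id": list("abcd"), "sire_id": [""] * 4, "dam_id": [""] * 4}
        )
        A = pedigree_A(ped)
        assert np.allclose(A.values, np.eye(4))

    def test_textbook_relationships(self):
        ped = pd.DataFrame(
            {
                "animal_id": ["s", "d1", "d2", "c1", "c2", "c3"],
                "sire_id": ["", "", "", "s", "s", "s"],
                "dam_id": ["", "", "", "d1", "d1", "d2"],
            }
        )
        A = pedigree_A(ped)
        pos = {a: i for i, a in enumerate(A.ids)}
        v = A.values
        assert v[pos["s"], pos["c1"]] == pytest.approx(0.5)  # parent-offspring
        assert v[pos["c1"], pos["c2"]] == pytest.approx(0.5)  # full sibs
        assert v[pos["c1"], pos["c3"]] == pytest.approx(0.25)  # half sibs
        assert v[pos["c1"], pos["c1"]] == pytest.approx(1.0)  # non-inbred

    def test_inbred_diagonal(self):
        # full-sib mating: offspring inbreeding 0.25
        ped = pd.DataFrame(
            {
                "animal_id": ["s", "d", "a", "b", "x"],
                "sire_id": ["", "", "s", "s", "a"],
                "dam_id": ["", "", "d", "d", "b"],
            }
        )
        A = pedigree_A(ped)
        pos = {a: i for i, a in enumerate(A.ids)}
        assert A.values[pos["x"], pos["x"]] == pytest.approx(1.25)

    def test_cycle_detected(self):
        ped = pd.DataFrame(
            {
                "animal_id": ["a", "b"],
                "sire_id": ["b", "a"],
                "dam_id": ["", ""],
            }
        )
        with pytest.raises(ValueError, match="cycle"):
            pedigree_A(ped)

    def test_missing_parents_added_as_founders(self):
        ped = pd.DataFrame(
            {"animal_id": ["x"], "sire_id": ["s9"], "dam_id": ["d9"]}
        )
        A = pedigree_A(ped)
        assert set(A.ids) == {"s9", "d9", "x"}

    def test_gene_drop_oracle_random_pedigree(self):
        # 8 founders + 12 descendants; expected allele sharing from 20,000
        # gene drops should match the tabular A within 0.02
        rng = np.random.default_rng(42)
        n_f, n_d = 8, 12
        ids = [f"f{i}" for i in range(n_f)] + [f"x{i}" for i in range(n_d)]
        sires, dams = [""] * n_f, [""] * n_f
        for i in range(n_d):
            pool = ids[: n_f + i]
            s, d = rng.choice(pool, size=2, replace=False)
            sires.append(s)
            dams.append(d)
        ped = pd.DataFrame({"animal_id": ids, "sire_id": sires, "dam_id": dams})
        A = pedigree_A(ped)

        reps = 20_000
        m = len(ids)
        pos = {a: i for i, a in enumerate(ids)}
        # allele ids per (rep, animal, 2)
        al = np.zeros((reps, m, 2), dtype=np.int32)
        next_allele = 0
        for i, a in enumerate(ids):
            s, d = sires[i], dams[i]
            if s == "":
                al[:, i, 0] = next_allele
                al[:, i, 1] = next_allele + 1
                next_allele += 2
            else:
                pick_s = rng.integers(0, 2, size=reps)
                pick_d = rng.integers(0, 2, size=reps)
                al[:, i, 0] = al[np.arange(reps), pos[s], pick_s]
                al[:, i, 1] = al[np.arange(reps), pos[d], pick_d]
        for i in range(m):
            for j in range(i, m):
                share = np.zeros(reps)
                for u in range(2):
                    for v in range(2):
                        share += al[:, i, u] == al[:, j, v]
                a_hat = share.mean() / 2.0  # 2 * kinship
                assert abs(a_hat - A.values[i, j]) < 0.02


class TestVanRadenG:
    def test_hw_unrelated_mean_diagonal_near_one(self, rng):
        n, m = 200, 5000
        p = rng.uniform(0.1, 0.5, m)
        M = rng.binomial(2, p, size=(n, m)).astype(float)
        G = vanraden_G(pd.DataFrame(M, index=[f"a{i}" for i in range(n)]))
        assert np.mean(np.diag(G.values)) == pytest.approx(1.0, abs=0.05)
        off = G.values[np.triu_indices(n, 1)]
        assert abs(off.mean()) < 0.01

    def test_duplicate_individuals(self, rng):
        m = 3000
        p = rng.uniform(0.2, 0.5, m)
        row = rng.binomial(2, p)
        M = np.vstack([row, row, rng.binomial(2, p)]).astype(float)
        G = vanraden_G(pd.DataFrame(M, index=["a", "a2", "b"]))
        assert G.values[0, 1] == pytest.approx(G.values[0, 0], abs=1e-9)

    def test_monomorphic_excluded_and_all_mono_error(self):
        M = pd.DataFrame([[2, 1], [2, 0]], index=["a", "b"]).astype(float)
        G = vanraden_G(M)  # first SNP monomorphic, dropped silently
        assert G.values.shape == (2, 2)
        with pytest.raises(ValueError):
            vanraden_G(pd.DataFrame([[2, 0], [2, 0]], index=["a", "b"]).astype(float))


class TestBlendH:
    def ped_cohort(self):
        ids = [f"f{i}" for i in range(4)] + [f"x{i}" for i in range(8)]
        sires = [""] * 4 + ["f0", "f0", "f1", "f1", "f2", "f2", "f3", "f3"]
        dams = [""] * 4 + ["f1", "f2", "f2", "f3", "f3", "f0", "f0", "f1"]
        return pd.DataFrame({"animal_id": ids, "sire_id": sires, "dam_id": dams})

    def test_g_equal_a_gives_h_equal_a(self):
        A = pedigree_A(self.ped_cohort())
        G = RelationshipMatrix("G", list(A.ids), A.values.copy())
        H = blend_H(A, G, weight=0.95)
        Ha = A.subset(H.ids).values
        assert np.allclose(H.values, Ha, atol=1e-9)

    def test_no_genotyped_returns_a(self):
        A = pedigree_A(self.ped_cohort())
        G = RelationshipMatrix("G", [], np.zeros((0, 0)))
        H = blend_H(A, G)
        assert np.allclose(H.values, A.values)

    def test_partial_genotyping_concentrates_on_genotyped_block(self, rng):
        ped = self.ped_cohort()
        A = pedigree_A(ped)
        geno_ids = [f"x{i}" for i in range(8)]
        A22 = A.subset(geno_ids).values
        noise = rng.normal(0, 0.03, A22.shape)
        G = RelationshipMatrix("G", geno_ids, A22 + (noise + noise.T) / 2)
        H = blend_H(A, G, weight=0.95)
        assert np.linalg.eigvalsh(H.values).min() > -1e-8
        diff = np.abs(H.values - A.subset(H.ids).values)
        n1 = len(A.ids) - len(geno_ids)
        assert diff[n1:, n1:].max() >= diff[:n1, :n1].max() - 1e-12


class TestUnivariateReml:
    def test_loglik_matches_independent_dense_formula(self, rng):
        n = 40
        K = half_sib_K(8, 5)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.multivariate_normal(np.zeros(n), 0.3 * K + 0.7 * np.eye(n))
        for s2a, s2e in [(0.3, 0.7), (0.1, 1.2), (1.0, 0.5)]:
            assert reml_loglik(y, X, K, s2a, s2e) == pytest.approx(
                dense_reml_loglik_oracle(y, X, K, s2a, s2e), abs=1e-8
            )

    def test_optimum_matches_grid_search_oracle(self, rng):
        n = 30
        K = half_sib_K(6, 5)
        X = np.ones((n, 1))
        L = np.linalg.cholesky(0.4 * K + 0.6 * np.eye(n))
        y = L @ rng.standard_normal(n)
        est = reml_univariate_arrays(y, X, K)
        # two-stage grid refine on (s2a, s2e)
        best = -np.inf
        center = (est.sigma2_a[0] + 0.05, est.sigma2_e[0])
        lo_a, hi_a = 1e-6, 4 * np.var(y)
        lo_e, hi_e = 1e-4, 4 * np.var(y)
        for _ in range(4):
            aa = np.linspace(lo_a, hi_a, 30)
            ee = np.linspace(lo_e, hi_e, 30)
            vals = np.array(
                [[dense_reml_loglik_oracle(y, X, K, a, e) for e in ee] for a in aa]
            )
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            best = vals[i, j]
            da, de = aa[1] - aa[0], ee[1] - ee[0]
            lo_a, hi_a = max(aa[i] - da, 1e-8), aa[i] + da
            lo_e, hi_e = max(ee[j] - de, 1e-8), ee[j] + de
        assert est.loglik == pytest.approx(best, abs=1e-4)
        assert est.loglik >= best - 1e-6  # optimizer at least as good as grid

    def test_null_heritability_recovered(self):
        hits = 0
        for seed in range(10):
            phen, sire = simulate_half_sib_trait(100, 20, h2=0.0, seed=seed)
            K = half_sib_K(100, 20)
            est = reml_univariate_arrays(phen[:, 0], np.ones((2000, 1)), K)
            if est.h2[0] <= 0.05:
                hits += 1
        assert hits >= 9

    def test_shift_and_reorder_invariance(self, rng):
        n = 60
        K = half_sib_K(12, 5)
        X = np.ones((n, 1))
        y = rng.multivariate_normal(np.zeros(n), 0.3 * K + 0.7 * np.eye(n))
        e1 = reml_univariate_arrays(y, X, K)
        e2 = reml_univariate_arrays(y + 100.0, X, K)
        assert e1.h2[0] == pytest.approx(e2.h2[0], abs=1e-6)
        perm = rng.permutation(n)
        e3 = reml_univariate_arrays(y[perm], X, K[np.ix_(perm, perm)])
        assert e1.h2[0] == pytest.approx(e3.h2[0], abs=1e-6)
        assert e1.loglik == pytest.approx(e3.loglik, abs=1e-6)

    def test_loglik_trace_monotone(self, rng):
        n = 50
        K = half_sib_K(10, 5)
        y = rng.multivariate_normal(np.zeros(n), 0.4 * K + 0.6 * np.eye(n))
        est = reml_univariate_arrays(y, np.ones((n, 1)), K)
        tr = np.array(est.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-12)


class TestBivariateReml:
    def test_same_trait_twice_rg_near_one(self):
        phen, sire = simulate_half_sib_trait(100, 20, h2=0.3, seed=1)
        y = phen[:, 0]
        K = half_sib_K(100, 20)
        Y = np.column_stack([y, y + 1e-6 * np.random.default_rng(0).standard_normal(len(y))])
        est = reml_bivariate_arrays(Y, np.ones((len(y), 1)), K)
        assert est.r_g >= 0.98

    def test_independent_traits_rg_near_zero(self):
        vals = []
        for seed in range(5):
            phen, _ = simulate_half_sib_trait(
                100, 20, h2=0.3, seed=seed, h2_2=0.3, r_g=0.0, r_e=0.0
            )
            K = half_sib_K(100, 20)
            est = reml_bivariate_arrays(phen, np.ones((2000, 1)), K)
            vals.append(est.r_g)
        assert abs(np.mean(vals)) <= 0.15

    def test_univariate_consistency_on_complete_data(self):
        phen, _ = simulate_half_sib_trait(
            80, 15, h2=0.3, seed=3, h2_2=0.3, r_g=0.5, r_e=0.2
        )
        K = half_sib_K(80, 15)
        X = np.ones((1200, 1))
        biv = reml_bivariate_arrays(phen, X, K)
        uni = reml_univariate_arrays(phen[:, 0], X, K)
        assert biv.h2[0] == pytest.approx(uni.h2[0], abs=0.06)

    def test_trace_monotone_and_bounds(self):
        phen, _ = simulate_half_sib_trait(
            50, 10, h2=0.4, seed=9, h2_2=0.2, r_g=0.4, r_e=0.1
        )
        K = half_sib_K(50, 10)
        est = reml_bivariate_arrays(phen, np.ones((500, 1)), K)
        tr = np.array(est.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-12)
        assert -1.0 <= est.r_g <= 1.0
        assert all(0.0 <= h <= 1.0 for h in est.h2)


class TestBuildDesign:
    def test_aliased_columns_dropped(self):
        df = pd.DataFrame(
            {
                "f": ["a", "a", "b", "b", "c", "c"],
                "x": [1.0, 2, 3, 4, 5, 6],
                "x2": [2.0, 4, 6, 8, 10, 12],  # aliased with x
            }
        )
        X = build_design(df, factors=("f",), covariates=("x", "x2"))
        assert np.linalg.matrix_rank(X) == X.shape[1]
        assert X.shape[1] == 4  # intercept + 2 dummies + one of x/x2
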