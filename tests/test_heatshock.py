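import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from rootatlas import heatshock as hs
from rootatlas._stats import bh_qvalues
from rootatlas.io import CountMatrix


def make_matrix(values, prefix="c"):
    values = np.asarray(values)
    return CountMatrix(sp.csr_matrix(values),
                       [f"g{i}" for i in range(values.shape[0])],
                       [f"{prefix}{i}" for i in range(values.shape[1])])


def nb_counts(rng, mu, alpha, size):
    size_param = 1.0 / alpha
    return rng.negative_binomial(size_param, size_param / (size_param + mu),
                                 size=size)


class TestMnnAlign:
    def test_constant_shift_removed(self, rng):
        a = rng.normal(0, 1, size=(120, 3))
        b = rng.normal(0, 1, size=(120, 3)) + np.array([6.0, -4.0, 2.0])
        ca, cb = hs.mnn_align(a, b, k_mnn=15)
        before = np.linalg.norm(a.mean(0) - b.mean(0))
        after = np.linalg.norm(ca.mean(0) - cb.mean(0))
        assert after < 0.05 * before
        np.testing.assert_array_equal(ca, a)  # control untouched

    def test_identity_when_conditions_match(self, rng):
        a = rng.normal(0, 1, size=(100, 2))
        ca, cb = hs.mnn_align(a, a.copy(), k_mnn=10)
        assert np.linalg.norm(cb.mean(0) - a.mean(0)) < 0.05
        assert np.linalg.norm(cb - a, axis=1).mean() < 0.2

    def test_deterministic(self, rng):
        a = rng.normal(0, 1, size=(60, 2))
        b = rng.normal(0, 1, size=(60, 2)) + 3
        r1 = hs.mnn_align(a, b, k_mnn=8)[1]
        r2 = hs.mnn_align(a, b, k_mnn=8)[1]
        np.testing.assert_array_equal(r1, r2)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            hs.mnn_align(np.zeros((0, 2)), np.ones((5, 2)))


class TestNbGlmLrt:
    def test_reduced_equal_full_gives_p_one(self, rng):
        y = rng.poisson(5.0, 50)
        X = np.ones((50, 1))
        p, _ = hs.nb_glm_lrt(y, X, X)
        assert p == 1.0

    def test_planted_fold_detected_with_accurate_lfc(self, rng):
        n = 200
        mu = np.concatenate([np.full(n, 2.0), np.full(n, 16.0)])
        y = nb_counts(rng, mu, alpha=0.3, size=2 * n)
        X_full = np.column_stack([np.ones(2 * n),
                                  np.repeat([0.0, 1.0], n)])
        p, _ = hs.nb_glm_lrt(y, X_full, np.ones((2 * n, 1)))
        assert p < 1e-6
        m = make_matrix(y[None, :])
        lfc = hs.log2_fold_change(m, np.repeat([False, True], n),
                                  np.ones(2 * n))
        assert abs(lfc[0] - 3.0) < 0.5

    def test_null_pvalues_calibrated(self, rng):
        """Type-I error of the NB LRT at alpha=0.05 over null genes."""
        n = 120
        n_genes = 300
        X_full = np.column_stack([np.ones(2 * n), np.repeat([0.0, 1.0], n)])
        X_red = np.ones((2 * n, 1))
        pvals = []
        for _ in range(n_genes):
            y = nb_counts(rng, np.full(2 * n, 3.0), alpha=0.4, size=2 * n)
            p, _ = hs.nb_glm_lrt(y, X_full, X_red)
            pvals.append(p)
        rate = np.nanmean(np.array(pvals) < 0.05)
        assert 0.02 <= rate <= 0.08

    def test_interaction_design_detects_type_restricted_effect(self, rng):
        # gene responds to treatment only in type A
        n = 80
        ttype = np.tile(np.repeat(["A", "B"], n), 2)
        treat = np.repeat(["ctl", "heat"], 2 * n)
        mu = np.where((ttype == "A") & (treat == "heat"), 12.0, 2.0)
        y = nb_counts(rng, mu, alpha=0.3, size=4 * n)
        m = make_matrix(y[None, :])
        cov = pd.DataFrame({"treatment": treat, "cluster": ttype})
        res = hs.de_test(m, cov, ["treatment*cluster"],
                         ["treatment", "cluster"],
                         size_fac=np.ones(4 * n))
        assert res.p.iloc[0] < 1e-6


class TestPerClusterDe:
    def _paired(self, rng, n_per_cluster=40, planted=None, n_genes=30):
        """Two clusters; ``planted`` maps gene index -> fold in both."""
        planted = planted or {}
        labels, ctl_cols, trt_cols = [], [], []
        for lab in ("c1", "c2"):
            mu = np.full((n_genes, n_per_cluster), 3.0)
            ctl_cols.append(nb_counts(rng, mu, 0.3, mu.shape))
            mu_t = mu.copy()
            for gi, fold in planted.items():
                mu_t[gi] = 3.0 * fold
            trt_cols.append(nb_counts(rng, mu_t, 0.3, mu_t.shape))
            labels += [lab] * n_per_cluster
        control = make_matrix(np.hstack(ctl_cols), prefix="ctl")
        treated = make_matrix(np.hstack(trt_cols), prefix="trt")
        return control, treated, np.array(labels + labels)

    def test_small_cluster_skipped(self, rng):
        control, treated, labels = self._paired(rng, n_per_cluster=40)
        labels[:26] = "tiny"  # leaves cluster c1 with 14 control cells
        result = hs.per_cluster_de(control, treated, labels, min_cells=15,
                                   fdr_max=0.05, lfc_min=0.5)
        assert "c1" in result.skipped_clusters or "tiny" in result.skipped_clusters

    def test_shared_planted_genes_intersect(self, rng):
        # keep the planted fraction small so size factors stay comparable
        # across conditions and null genes keep |lfc| ~ 0
        planted = {i: 8.0 for i in range(10)}
        control, treated, labels = self._paired(rng, planted=planted,
                                                n_genes=150)
        result = hs.per_cluster_de(control, treated, labels, min_cells=15,
                                   fdr_max=0.01, lfc_min=1.0)
        shared = result.intersections[
            result.intersections.clusters == ("c1", "c2")]
        assert shared["count"].iloc[0] == 10
        exclusive = result.intersections[
            result.intersections.clusters != ("c1", "c2")]
        assert exclusive["count"].sum() == 0

    def test_exclusive_counts_conserve_per_cluster_totals(self, rng):
        planted = {i: 8.0 for i in range(6)}
        control, treated, labels = self._paired(rng, planted=planted,
                                                n_genes=100)
        result = hs.per_cluster_de(control, treated, labels, min_cells=15,
                                   fdr_max=0.01, lfc_min=1.0)
        table, inter = result.table, result.intersections
        for lab in ("c1", "c2"):
            total = int(((table.cluster == lab) & table.significant).sum())
            from_intersections = int(
                inter[inter.clusters.map(lambda c: lab in c)]["count"].sum())
            assert total == from_intersections

    def test_no_eligible_cluster_rejected(self, rng):
        control, treated, labels = self._paired(rng, n_per_cluster=5)
        with pytest.raises(ValueError):
            hs.per_cluster_de(control, treated, labels, min_cells=15)


class TestSignatures:
    def test_two_programs_recovered_exactly(self, rng):
        n_cells = 60
        on = np.zeros(n_cells)
        on[:30] = 20.0
        prog_a = np.vstack([rng.poisson(on + 1) for _ in range(6)])
        prog_b = np.vstack([rng.poisson(20.0 - on + 1) for _ in range(6)])
        m = make_matrix(np.vstack([prog_a, prog_b]))
        sigs = hs.gene_cluster_signatures(m, list(m.gene_ids), k=2,
                                          size_fac=np.ones(n_cells))
        labels = sigs.gene_clusters.signature_cluster.to_numpy()
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]
        assert sigs.cell_signatures.shape == (n_cells, 2)

    def test_k_equal_genes_gives_singletons(self, rng):
        m = make_matrix(rng.poisson(5.0, size=(4, 20)))
        sigs = hs.gene_cluster_signatures(m, list(m.gene_ids), k=4,
                                          size_fac=np.ones(20))
        assert sorted(sigs.gene_clusters.signature_cluster) == [1, 2, 3, 4]

    def test_duplicated_profiles_co_cluster(self, rng):
        base = rng.poisson(5.0, size=20)
        other = rng.poisson(50.0, size=(3, 20))
        m = make_matrix(np.vstack([base, base, other]))
        sigs = hs.gene_cluster_signatures(m, list(m.gene_ids), k=2,
                                          size_fac=np.ones(20))
        labels = sigs.gene_clusters.signature_cluster
        assert labels.iloc[0] == labels.iloc[1]

    def test_absent_genes_dropped_with_warning(self, rng):
        m = make_matrix(rng.poisson(5.0, size=(5, 20)))
        with pytest.warns(UserWarning, match="absent"):
            sigs = hs.gene_cluster_signatures(
                m, list(m.gene_ids) + ["ghost"], k=2, size_fac=np.ones(20))
        assert "ghost" not in set(sigs.gene_clusters.gene)


class TestBhOracle:
    def test_matches_step_up_procedure(self, rng):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            np.testing.assert_allclose(bh_qvalues(p), oracle(p), atol=1e-12)
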