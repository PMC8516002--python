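import numpy as np
import pandas as pd
import pytest

from rootatlas import simulate as sim


def cfg(**kw):
    base = dict(n_types=3, n_stages=4, n_genes=300, markers_per_type=10,
                stage_genes_per_type=8, hs_program_size=20, n_cells=200,
                seed=11)
    base.update(kw)
    return sim.SimConfig(**base)


class TestReferenceMap:
    def test_no_signal_gives_identical_columns(self):
        rs = sim.simulate_reference_map(
            cfg(marker_fold=1.0, stage_gradient_fold=1.0))
        first = rs.reference.means[:, [0]]
        np.testing.assert_allclose(
            rs.reference.means, np.broadcast_to(first, rs.reference.means.shape))

    def test_marker_fold_ratio_is_exact(self):
        fold = 8.0
        rs = sim.simulate_reference_map(cfg(marker_fold=fold))
        ref, types = rs.reference, [t for t, _ in rs.reference.columns]
        gene_row = {g: i for i, g in enumerate(ref.genes)}
        for _, row in rs.markers.iterrows():
            own = np.array([t == row.type for t in types])
            means = ref.means[gene_row[row.gene]]
            ratio = means[own].mean() / means[~own].mean()
            assert ratio == pytest.approx(fold, rel=1e-12)

    def test_doubling_marker_fold_doubles_ratio(self):
        r4 = sim.simulate_reference_map(cfg(marker_fold=4.0))
        r8 = sim.simulate_reference_map(cfg(marker_fold=8.0))
        g = r4.markers.gene.iloc[0]
        i = r4.reference.genes.index(g)
        ratio = r8.reference.means[i].max() / r4.reference.means[i].max()
        assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_stage_gradient_monotone_within_type(self):
        rs = sim.simulate_reference_map(cfg(stage_gradient_fold=4.0))
        ref = rs.reference
        roles = rs.gene_roles
        stage_genes = roles[roles.role == "stage-gradient"]
        types = [t for t, _ in ref.columns]
        for _, row in stage_genes.iterrows():
            i = ref.genes.index(row.gene)
            own = [j for j, t in enumerate(types) if t == row.type]
            vals = ref.means[i, own]
            assert np.all(np.diff(vals) > 0)
            assert vals[-1] / vals[0] == pytest.approx(4.0, rel=1e-12)

    def test_determinism(self):
        a = sim.simulate_reference_map(cfg())
        b = sim.simulate_reference_map(cfg())
        np.testing.assert_array_equal(a.reference.means, b.reference.means)

    def test_too_many_planted_genes_rejected(self):
        with pytest.raises(sim.ConfigurationError):
            cfg(n_genes=50, markers_per_type=20)


class TestSimulateCells:
    def test_law_of_large_numbers_means(self):
        # Poisson limit, no library variation, no decay: sample means track
        # the reference column means
        config = cfg(n_types=1, n_stages=2, n_genes=100, markers_per_type=5,
                     stage_genes_per_type=5, hs_program_size=5, n_cells=1000,
                     nb_dispersion=np.inf, libsize_lognormal_sigma=0.0,
                     mrna_decay_fold=1.0, base_mean=2.0)
        rs = sim.simulate_reference_map(config)
        m, truth = sim.simulate_cells(config, rs)
        dense = m.dense()
        names = [f"{t}_{z}" for t, z in rs.reference.columns]
        for col, name in enumerate(names):
            ctype, zone = name.rsplit("_", 1)
            mask = ((truth.cells.true_type == ctype)
                    & (truth.cells.true_stage == int(zone))).to_numpy()
            assert mask.sum() > 300
            sample = dense[:, mask].mean(axis=1)
            expected = rs.reference.means[:, col]
            big = expected >= 1.0
            rel = np.abs(sample[big] - expected[big]) / expected[big]
            assert rel.mean() < 0.05

    def test_mrna_decay_ratio(self):
        config = cfg(n_cells=800, mrna_decay_fold=4.0,
                     stage_gradient_fold=1.0, libsize_lognormal_sigma=0.0)
        rs = sim.simulate_reference_map(config)
        m, truth = sim.simulate_cells(config, rs)
        totals = np.asarray(m.values.sum(axis=0)).ravel()
        hair = truth.cells.true_type == config.lineage
        early = (hair & (truth.cells.true_stage == 1)).to_numpy()
        late = (hair & (truth.cells.true_stage == 4)).to_numpy()
        ratio = totals[early].mean() / totals[late].mean()
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_decay_confined_to_designated_lineage(self):
        config = cfg(n_cells=800, mrna_decay_fold=4.0,
                     stage_gradient_fold=1.0, libsize_lognormal_sigma=0.0)
        rs = sim.simulate_reference_map(config)
        m, truth = sim.simulate_cells(config, rs)
        totals = np.asarray(m.values.sum(axis=0)).ravel()
        other = truth.cells.true_type == "cortex"
        early = (other & (truth.cells.true_stage == 1)).to_numpy()
        late = (other & (truth.cells.true_stage == 4)).to_numpy()
        assert totals[early].mean() / totals[late].mean() == pytest.approx(1.0, rel=0.15)

    def test_empty_matrix_for_zero_cells(self):
        config = cfg(n_cells=0)
        rs = sim.simulate_reference_map(config)
        m, truth = sim.simulate_cells(config, rs)
        assert m.n_cells == 0 and len(truth.cells) == 0

    def test_conservation_and_role_partition(self, atlas, small_config):
        m, truth = atlas
        assert len(truth.cells) == m.n_cells
        assert len(truth.genes) == m.n_genes
        counts = truth.genes.role.value_counts()
        assert counts["marker"] == small_config.markers_per_type * small_config.n_types
        assert counts["stage-gradient"] == \
            small_config.stage_genes_per_type * small_config.n_types
        assert counts["hs-program"] == small_config.hs_program_size

    def test_determinism(self):
        config = cfg(n_cells=50)
        rs = sim.simulate_reference_map(config)
        a, _ = sim.simulate_cells(config, rs)
        b, _ = sim.simulate_cells(config, rs)
        assert (a.values != b.values).nnz == 0


class TestHeatShock:
    def test_null_folds_leave_distribution_unchanged(self):
        config = cfg(hs_up_fold=1.0, marker_down_fold=1.0, n_cells=600)
        rs = sim.simulate_reference_map(config)
        base = sim.simulate_cells(config, rs)
        control, treated, _ = sim.simulate_heat_shock(config, rs, base)
        ratio = treated.values.sum() / control.values.sum()
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_program_upregulation_ratio(self):
        config = cfg(hs_up_fold=8.0, n_cells=600, libsize_lognormal_sigma=0.0)
        rs = sim.simulate_reference_map(config)
        base = sim.simulate_cells(config, rs)
        control, treated, truth = sim.simulate_heat_shock(config, rs, base)
        hs_genes = truth.genes_with_role("hs-program")
        idx = control.gene_index(hs_genes)
        ratio = (treated.values[idx].mean() / control.values[idx].mean())
        assert ratio == pytest.approx(8.0, rel=0.15)

    def test_type_restricted_perturbation(self):
        config = cfg(hs_up_fold=1.0, marker_down_fold=1.0, n_cells=900,
                     libsize_lognormal_sigma=0.0, base_mean=2.0)
        rs = sim.simulate_reference_map(config)
        base = sim.simulate_cells(config, rs)
        gene = rs.gene_roles[rs.gene_roles.role == "background"].gene.iloc[0]
        control, treated, truth = sim.simulate_heat_shock(
            config, rs, base, type_restricted={gene: ("cortex", 6.0)})
        gi = control.gene_index([gene])[0]
        cells = truth.cells
        for ctype, expected in [("cortex", 6.0), ("hair", 1.0)]:
            in_c = ((cells.treatment == "control")
                    & (cells.true_type == ctype)).to_numpy()
            in_t = ((cells.treatment == "heat")
                    & (cells.true_type == ctype)).to_numpy()
            ctl = control.dense()[gi, in_c[: control.n_cells]].mean()
            trt = treated.dense()[gi, in_t[control.n_cells:]].mean()
            assert trt / ctl == pytest.approx(expected, rel=0.35)


class TestPromoters:
    def _setup(self, rate, n_set=20):
        config = cfg(motif_plant_rate=rate, promoter_length=60)
        motif = sim.random_motifs(1, length=8, seed=5)[0]
        genes = [f"G{i:05d}" for i in range(40)]
        sets = {"target": genes[:n_set]}
        return config, genes, sets, {"target": motif}, motif

    def test_rate_zero_plants_nothing(self):
        config, genes, sets, motifs, _ = self._setup(0.0)
        _, plants = sim.simulate_promoters(config, genes, sets, motifs)
        assert len(plants) == 0

    def test_rate_one_plants_everywhere_at_recorded_offsets(self):
        config, genes, sets, motifs, motif = self._setup(1.0)
        promoters, plants = sim.simulate_promoters(config, genes, sets, motifs)
        assert len(plants) == len(sets["target"])
        for _, row in plants.iterrows():
            window = promoters[row.gene][row.offset:row.offset + len(motif)]
            expected = motif.consensus if row.strand == "+" \
                else sim.reverse_complement(motif.consensus)
            assert window == expected

    def test_determinism(self):
        config, genes, sets, motifs, _ = self._setup(0.5)
        a, _ = sim.simulate_promoters(config, genes, sets, motifs)
        b, _ = sim.simulate_promoters(config, genes, sets, motifs)
        assert a == b

    def test_motif_longer_than_promoter_rejected(self):
        config = cfg(promoter_length=5)
        motif = sim.random_motifs(1, length=8, seed=5)[0]
        with pytest.raises(sim.ConfigurationError, match="longer"):
            sim.simulate_promoters(config, ["G00000"], {"s": ["G00000"]},
                                   {"s": motif})
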