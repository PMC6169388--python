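"""Maintenance-cost hypothesis tests and the correlation sweep."""

import numpy as np
import pytest

import prfcub as pc
from prfcub.sequence_core import SequenceError
from prfcub.teh_analysis import associate, binned_trend


def _make_sites(rel_positions, gene_ids=None, L=1000):
    sites = []
    for i, rel in enumerate(rel_positions):
        gid = gene_ids[i] if gene_ids is not None else f"g{i}"
        l = max(3, int(rel * L))
        sites.append(pc.SlipperySite(gid, l, "AAAAAAT", rel, True, 30, True, ""))
    return sites


class TestAssociate:
    def test_perfect_monotone_gives_unit_spearman(self):
        x = np.arange(10.0)
        y = -(x**3) - x
        res = associate(x, y)
        assert res.spearman_r == pytest.approx(-1.0)
        assert res.slope < 0

    def test_zero_variance_flags_degenerate(self):
        res = associate(np.arange(5.0), np.ones(5))
        assert res.degenerate and np.isnan(res.pearson_r)

    def test_too_few_points_errors(self):
        with pytest.raises(SequenceError):
            associate(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestH1:
    def test_planted_negative_density_slope_recovered(self, default_dataset, default_sites):
        res = pc.h1_site_density(default_dataset.genes, default_sites, default_dataset.expression)
        assert res.association.spearman_r < 0
        assert res.association.corr_p < 0.01
        assert res.mean_sites_per_gene > 0

    def test_constant_density_is_null(self):
        rng = np.random.default_rng(3)
        lengths = rng.integers(100, 500, 500)
        genes = [pc.Gene(f"g{i}", "ACG" * int(n)) for i, n in enumerate(lengths)]
        # one site each; density varies only through length, independent of expression
        sites = _make_sites(rng.uniform(0.1, 0.8, 500), [g.id for g in genes], L=300)
        expr = [
            pc.ExpressionRecord(g.id, float(10 ** rng.uniform(1, 4)), float(10 ** rng.uniform(0, 2)))
            for g in genes
        ]
        res = pc.h1_site_density(genes, sites, expr)
        assert abs(res.association.spearman_r) < 0.1
        assert res.association.corr_p > 0.05

    def test_requires_mrna_levels(self):
        genes = [pc.Gene(f"g{i}", "ACG" * 10) for i in range(5)]
        expr = [pc.ExpressionRecord(g.id, 100.0, None) for g in genes]
        with pytest.raises(SequenceError):
            pc.h1_site_density(genes, [], expr)


class TestH2:
    def test_degenerate_point_mass(self):
        res = pc.h2_position_skew(_make_sites([0.25] * 10))
        assert res.mean_rel_pos == pytest.approx(0.25)
        assert res.sem == 0.0
        assert res.ci_excludes_half

    def test_uniform_null_contains_half(self):
        rng = np.random.default_rng(1)
        res = pc.h2_position_skew(_make_sites(rng.uniform(0, 1, 10_000)))
        assert res.ci_low < 0.5 < res.ci_high
        assert not res.ci_excludes_half

    def test_beta_2_4_mean_near_one_third(self):
        rng = np.random.default_rng(1)
        res = pc.h2_position_skew(_make_sites(rng.beta(2, 4, 2000)))
        assert res.mean_rel_pos == pytest.approx(1 / 3, abs=0.02)
        assert res.ci_excludes_half

    def test_histogram_covers_all_sites(self):
        rng = np.random.default_rng(2)
        res = pc.h2_position_skew(_make_sites(rng.beta(2, 4, 500)), n_bins=10)
        assert res.hist_counts.sum() == res.n == 500


class TestH3:
    def test_planted_negative_position_slope_recovered(self, default_dataset, default_sites):
        assoc, trend = pc.h3_position_vs_expression(default_sites, default_dataset.expression)
        assert assoc.slope < 0
        assert assoc.slope_p < 0.05
        assert trend.bin_n.sum() == assoc.n
        assert len(trend.bin_means) == 20

    def test_expression_independent_positions_are_null(self):
        rng = np.random.default_rng(9)
        n = 500
        sites = _make_sites(rng.beta(2, 2, n))
        expr = [pc.ExpressionRecord(f"g{i}", float(10 ** rng.uniform(0, 5))) for i in range(n)]
        assoc, _ = pc.h3_position_vs_expression(sites, expr)
        assert assoc.slope_p > 0.05

    def test_single_occupied_bin_flags_not_crashes(self):
        x = np.full(50, 2.0)
        x[0] = 0.0  # two distinct values so binning has width
        y = np.linspace(0, 1, 50)
        trend = binned_trend(x, y, n_bins=20)
        assert trend.bin_n.sum() == 50
        assert np.isnan(trend.bin_means[trend.bin_n == 0]).all()
        assert trend.low_n[trend.bin_n < 2].all()


class TestSweep:
    def test_p_zero_limit_reproduces_uncorrected(self, default_dataset, default_sites, default_table):
        ds = default_dataset
        sweep = pc.correlation_sweep(
            ds.genes, default_sites, default_table, ds.expression,
            p_grid=[1e-9], pi_grid=[0.0],
        )
        unc = pc.uncorrected_association(ds.genes, default_sites, default_table, ds.expression)
        for kind in ("i_c_hat", "i_a"):
            row = sweep[sweep.index_kind == kind].iloc[0]
            assert abs(row.pearson_r - unc.pearson_r) < 1e-6
            assert abs(row.spearman_r - unc.spearman_r) < 1e-6

    def test_ic_correlation_non_increasing_in_p(self, default_dataset, default_sites, default_table):
        ds = default_dataset
        sweep = pc.correlation_sweep(
            ds.genes, default_sites, default_table, ds.expression,
            p_grid=pc.DEFAULT_P_GRID, pi_grid=[0.0],
        )
        ic = sweep[sweep.index_kind == "i_c_hat"].sort_values("p_or_pb")
        rs = ic.pearson_r.to_numpy()
        assert np.all(np.diff(rs) <= 1e-9)

    def test_large_pi_depresses_ic_correlation(self, default_dataset, default_sites, default_table):
        ds = default_dataset
        sweep = pc.correlation_sweep(
            ds.genes, default_sites, default_table, ds.expression,
            p_grid=[0.5], pi_grid=[0.0, 10000.0],
        )
        ic = sweep[sweep.index_kind == "i_c_hat"].set_index("pi")
        assert ic.loc[10000.0, "pearson_r"] < ic.loc[0.0, "pearson_r"]

    def test_n_conserved_across_cells(self, default_dataset, default_sites, default_table):
        ds = default_dataset
        sweep = pc.correlation_sweep(
            ds.genes, default_sites, default_table, ds.expression,
            p_grid=[0.05, 0.3], pi_grid=[0.0, 100.0],
        )
        assert sweep.n.nunique() == 1

    def test_ia_grid_point_0p9_evaluated_at_unity(self, small_dataset):
        ds = small_dataset
        sites = pc.scan_and_frameshift(ds.genes)
        table = pc.reference_table(ds)
        sweep = pc.correlation_sweep(
            ds.genes, sites, table, ds.expression,
            p_grid=[0.9], pi_grid=[0.0],
        )
        ia = sweep[sweep.index_kind == "i_a"]
        assert list(ia.p_or_pb) == [1.0]

    def test_expression_dependent_mode_runs_and_reports(self, small_dataset):
        ds = small_dataset
        sites = pc.scan_and_frameshift(ds.genes)
        table = pc.reference_table(ds)
        sweep = pc.correlation_sweep(
            ds.genes, sites, table, ds.expression,
            p_grid=[0.1, 0.3], pi_grid=[0.0], mode="expression_dependent",
        )
        assert set(sweep["mode"]) == {"expression_dependent"}
        assert np.isfinite(sweep.pearson_r).all()

    def test_empty_gene_set_errors(self, default_table):
        with pytest.raises(SequenceError):
            pc.correlation_sweep([], [], default_table, [])
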