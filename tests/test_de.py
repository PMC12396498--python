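"""The NB-GLM pseudobulk differential-expression engine."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from lactolink.de import (
    DEDesign,
    DesignError,
    PseudobulkDE,
    _fit_nb,
    correlate_lfc_time,
    de_hmo_lrt,
    de_wald,
    estimate_dispersion,
    per_sample_log2fc,
)
from lactolink.pseudobulk import PseudobulkTable
from lactolink.simulate import (
    simulate_de_pseudobulk,
    simulate_hmo_linked_pseudobulk,
)


def _pb_from_counts(counts, cell_types=None):
    n = len(counts)
    cell_types = cell_types or ["LC1"] * n
    idx = pd.MultiIndex.from_tuples(
        [(f"S{i}", ct) for i, ct in enumerate(cell_types)],
        names=["sample_id", "cell_type"],
    )
    counts = pd.DataFrame(np.asarray(counts), index=idx)
    counts.columns = [f"G{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame(
        {
            "donor_id": [f"D{i}" for i in range(n)],
            "study_id": "ST",
            "time_postpartum_days": np.linspace(1, 100, n),
            "n_cells_aggregated": 10,
        },
        index=idx,
    )
    return PseudobulkTable(counts=counts, meta=meta)


class TestDispersion:
    def test_poisson_like_gene_floors(self, rng):
        counts = rng.poisson(20.0, size=(50, 30))
        pb = _pb_from_counts(counts).with_size_factors()
        disp = estimate_dispersion(pb)
        # equidispersed genes: moment estimate non-positive for most genes
        assert (disp["alpha"] <= 0.05).mean() > 0.8

    def test_moments_formula_on_constructed_values(self):
        # with unit size factors, alpha = (s^2 - mu) / mu^2 on the raw counts
        rng = np.random.default_rng(0)
        base = rng.permutation(np.repeat([3.0, 10.0, 17.0], 10))
        counts = np.column_stack([base, base]).astype(int)
        pb = _pb_from_counts(counts)
        pb = PseudobulkTable(pb.counts, pb.meta,
                             size_factors=pd.Series(1.0, index=pb.counts.index))
        disp = estimate_dispersion(pb)
        mu, s2 = base.mean(), base.var(ddof=1)
        expected = (s2 - mu) / mu**2
        assert expected > 0
        assert disp["alpha"].iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_recovery_of_simulated_alpha(self):
        pb = simulate_de_pseudobulk(seed=3, n_samples_per_study=13, n_studies=2,
                                    n_genes=200, dispersion_alpha=0.1).with_size_factors()
        disp = estimate_dispersion(pb)
        assert 0.05 <= disp["alpha"].median() <= 0.2

    def test_all_zero_gene_flagged_at_floor(self):
        counts = np.ones((6, 3), dtype=int) * 5
        counts[:, 2] = 0
        pb = _pb_from_counts(counts).with_size_factors()
        disp = estimate_dispersion(pb)
        assert disp["all_zero"].iloc[2]
        assert disp["alpha"].iloc[2] == pytest.approx(1e-8)


class TestWald:
    def test_flipping_cluster_labels_negates_lfc(self):
        pb = simulate_de_pseudobulk(seed=4, n_genes=30).with_size_factors()
        res = de_wald(pb)
        flipped_counts = pb.counts.rename(
            index={"LC1": "LC2", "LC2": "LC1"}, level="cell_type"
        ).sort_index()
        flipped = PseudobulkTable(
            counts=flipped_counts,
            meta=pb.meta.rename(index={"LC1": "LC2", "LC2": "LC1"},
                                level="cell_type").sort_index(),
        ).with_size_factors()
        res_f = de_wald(flipped, dispersions=res.set_index("gene")[["alpha", "base_mean"]]
                        .assign(all_zero=False))
        merged = res.set_index("gene").join(res_f.set_index("gene"), rsuffix="_f")
        np.testing.assert_allclose(merged["log2fc"], -merged["log2fc_f"], atol=1e-6)

    def test_rank_deficient_design_names_columns(self):
        pb = simulate_de_pseudobulk(seed=4, n_genes=5).with_size_factors()
        meta = pb.meta.copy()
        meta["dup"] = meta["study_id"]  # perfectly collinear with study
        pb2 = PseudobulkTable(counts=pb.counts, meta=meta, size_factors=pb.size_factors)
        with pytest.raises(DesignError, match="dup|study"):
            de_wald(pb2, design=DEDesign(full=["study_id", "dup", "cell_type"],
                                         tested="cell_type"))

    def test_null_lfc_centered_at_zero(self):
        pb = simulate_de_pseudobulk(seed=6, n_genes=300).with_size_factors()
        res = de_wald(pb)
        assert abs(res["log2fc"].mean()) < 0.05

    def test_adjusted_p_at_least_raw(self):
        pb = simulate_de_pseudobulk(seed=6, n_genes=50).with_size_factors()
        res = de_wald(pb)
        ok = res["p_adjusted"].notna()
        assert (res.loc[ok, "p_adjusted"] >= res.loc[ok, "pvalue"] - 1e-15).all()


class TestHMOLRT:
    def test_planted_link_found_with_positive_sign(self):
        pb, panel = simulate_hmo_linked_pseudobulk(
            seed=9, n_genes=60, linked_lfc={0: 1.0, 1: 1.0}
        )
        res = de_hmo_lrt(pb, panel, "LNT", cell_type="LC2")
        planted = res.iloc[:2]
        assert (planted["pvalue"] <= 0.05).all()
        assert (planted["log2fc"] > 0).all()

    def test_statistic_nonnegative_and_chi2_like(self):
        pb, panel = simulate_hmo_linked_pseudobulk(
            seed=13, n_donors=10, samples_per_donor=4, n_genes=200
        )
        res = de_hmo_lrt(pb, panel, "LNT", cell_type="LC2")
        assert (res["stat"] >= 0).all()
        ks = stats.kstest(res["stat"], stats.chi2(df=1).cdf).statistic
        assert ks < 0.12
        assert res["stat"].mean() == pytest.approx(1.0, abs=0.35)

    def test_unknown_hmo_raises(self):
        pb, panel = simulate_hmo_linked_pseudobulk(seed=9, n_genes=5)
        with pytest.raises(KeyError):
            de_hmo_lrt(pb, panel, "NOPE", cell_type="LC2")


class TestPoissonLimit:
    def test_nb_fit_matches_poisson_at_vanishing_alpha(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = rng.poisson(np.exp(1.2 + 0.7 * X[:, 1]))
        offset = np.zeros(40)
        nb, conv = _fit_nb(y, X, 1e-10, offset)
        assert conv
        pois = sm.GLM(y.astype(float), X, family=sm.families.Poisson(),
                      offset=offset).fit()
        np.testing.assert_allclose(nb.params, pois.params, atol=1e-6)


class TestPerSampleLFC:
    def _pb(self):
        idx = pd.MultiIndex.from_tuples(
            [("S1", "LC1"), ("S1", "LC2"), ("S2", "LC1"), ("S2", "LC2"),
             ("S3", "LC1")],
            names=["sample_id", "cell_type"],
        )
        counts = pd.DataFrame(
            [[8, 2], [2, 8], [5, 5], [5, 5], [9, 1]],
            index=idx, columns=["GA", "GB"],
        )
        meta = pd.DataFrame(
            {"donor_id": "D", "study_id": "ST", "time_postpartum_days": 1.0,
             "n_cells_aggregated": 2},
            index=idx,
        )
        return PseudobulkTable(counts=counts, meta=meta)

    def test_formula_with_pseudocount(self):
        # CPM of (8,2) is (8e5, 2e5); pseudocount 1 is negligible at CPM scale,
        # so verify against the exact formula instead of a rounded value
        lfc = per_sample_log2fc(self._pb())
        a, b = 8 / 10 * 1e6, 2 / 10 * 1e6
        assert lfc.loc["S1", "GA"] == pytest.approx(np.log2((a + 1) / (b + 1)))

    def test_equal_expression_gives_zero(self):
        lfc = per_sample_log2fc(self._pb())
        assert lfc.loc["S2", "GA"] == pytest.approx(0.0)

    def test_swapping_groups_negates(self):
        pb = self._pb()
        fwd = per_sample_log2fc(pb, "LC1", "LC2")
        rev = per_sample_log2fc(pb, "LC2", "LC1")
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)

    def test_sample_missing_a_type_excluded(self):
        lfc = per_sample_log2fc(self._pb())
        assert "S3" not in lfc.index


class TestLFCTimeCorrelation:
    def test_perfect_monotone_decrease_gives_minus_one(self):
        lfc = pd.DataFrame({"GA": [3.0, 2.0, 1.0, 0.0]},
                           index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"))
        times = pd.Series([1.0, 5.0, 10.0, 20.0], index=lfc.index)
        out = correlate_lfc_time(lfc, times, method="spearman")
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_spearman_invariant_to_monotone_time_transform(self, rng):
        lfc = pd.DataFrame({"GA": rng.normal(size=8)},
                           index=pd.Index([f"S{i}" for i in range(8)], name="sample_id"))
        times = pd.Series(rng.uniform(1, 100, 8), index=lfc.index)
        a = correlate_lfc_time(lfc, times, method="spearman")
        b = correlate_lfc_time(lfc, np.exp(times / 50.0), method="spearman")
        assert a.loc[0, "rho"] == pytest.approx(b.loc[0, "rho"])

    def test_constant_lfc_reported_missing(self):
        lfc = pd.DataFrame({"GA": [1.0, 1.0, 1.0]},
                           index=pd.Index(["S1", "S2", "S3"], name="sample_id"))
        times = pd.Series([1.0, 2.0, 3.0], index=lfc.index)
        out = correlate_lfc_time(lfc, times)
        assert np.isnan(out.loc[0, "rho"])


class TestEstimatorInterface:
    def test_get_params_round_trip(self):
        model = PseudobulkDE(design="hmo", hmo="LNT", cell_type="LC2")
        params = model.get_params()
        clone = PseudobulkDE(**params)
        assert clone.get_params() == params

    def test_cluster_fit_exposes_results_and_dispersions(self):
        pb = simulate_de_pseudobulk(seed=4, n_genes=20)
        model = PseudobulkDE(design="cluster").fit(pb)
        assert {"gene", "log2fc", "pvalue", "p_adjusted"} <= set(model.results_)
        assert len(model.dispersions_) == 20
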