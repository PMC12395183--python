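import numpy as np
import pandas as pd
import pytest

from ecostoich import (
    GenerationError, SimulationConfig, backsolve_senesced, fit_homeostasis,
    generate_dataset, validate_dataset,
)
from ecostoich.io_tables import POOLED_TOKEN
from ecostoich.resorption import nure, strategy_from_tables


class TestBacksolve:
    def test_inverse_of_nure_example(self):
        ltn_s, _ = backsolve_senesced(20.0, 2.0, 61.9, 10.0, mlcf=0.762)
        assert ltn_s == pytest.approx(10.0, rel=1e-10)

    @pytest.mark.parametrize("nre,rnp", [(50.0, 8.0), (78.0, 13.0), (90.0, 15.0)])
    def test_forward_recomputation_reproduces_targets(self, nre, rnp):
        ltn, ltp = 24.0, 1.85
        ltn_s, ltp_s = backsolve_senesced(ltn, ltp, nre, rnp, mlcf=0.762)
        assert nure(ltn, ltn_s, 0.762) == pytest.approx(nre, abs=1e-10)
        got = (ltn - ltn_s * 0.762) / (ltp - ltp_s * 0.762)
        assert got == pytest.approx(rnp, rel=1e-10)

    def test_infeasible_targets_raise(self):
        # tiny resorbed ratio forces senesced P above what green P allows
        with pytest.raises(GenerationError, match="senesced P"):
            backsolve_senesced(24.0, 1.85, 78.0, 2.0, mlcf=0.762)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            backsolve_senesced(24.0, 1.85, 120.0, 13.0)
        with pytest.raises(ValueError):
            backsolve_senesced(24.0, 1.85, 78.0, -1.0)


class TestGenerateDataset:
    def test_identical_seed_gives_identical_tables(self):
        a = generate_dataset(SimulationConfig(seed=7))
        b = generate_dataset(SimulationConfig(seed=7))
        pd.testing.assert_frame_equal(a.survey, b.survey)
        pd.testing.assert_frame_equal(a.litter, b.litter)
        pd.testing.assert_frame_equal(a.soil, b.soil)
        assert a.truth == b.truth

    def test_design_shape(self, default_dataset):
        soil = default_dataset.soil
        assert len(soil) == 24
        assert soil["elevation"].nunique() == 6
        assert soil["elevation"].min() == 1960.0
        assert soil["elevation"].max() == 3548.0

    def test_litter_protocols_mirror_growth_forms(self, default_dataset):
        litter = default_dataset.litter
        soil = default_dataset.soil
        elev = dict(zip(soil["plot_id"], soil["elevation"]))
        pooled = litter["species"] == POOLED_TOKEN
        shrub_elevs = {elev[p] for p in litter.loc[~pooled, "plot_id"]}
        herb_elevs = {elev[p] for p in litter.loc[pooled, "plot_id"]}
        assert max(shrub_elevs) < min(herb_elevs)

    def test_all_concentrations_positive_and_validation_clean(self):
        for seed in range(5):
            ds = generate_dataset(SimulationConfig(seed=seed))
            assert (ds.survey[["leaf_C", "leaf_N", "leaf_P"]] > 0).all().all()
            assert (ds.litter[["senesced_N", "senesced_P"]] > 0).all().all()
            assert validate_dataset(ds.survey, ds.litter, ds.soil).empty

    def test_nre_sample_mean_near_target(self, default_dataset):
        truth = pd.DataFrame(default_dataset.truth["plots"])
        cfg = default_dataset.truth["config"]
        n = len(truth)
        tol = 2 * cfg["nre_sd"] / np.sqrt(n)
        assert abs(truth["nre_target"].mean() - cfg["nre_mean"]) < 2 * tol

    def test_community_ratio_matches_latent_leaf_np(self, default_dataset):
        from ecostoich import aggregate_communities

        com = aggregate_communities(default_dataset.survey, default_dataset.soil)
        truth = pd.DataFrame(default_dataset.truth["plots"])
        merged = com.merge(truth[["plot_id", "leaf_NP"]], on="plot_id")
        np.testing.assert_allclose(merged["ratio_NP"], merged["leaf_NP"], rtol=1e-9)

    def test_infeasible_config_raises_generation_error(self):
        cfg = SimulationConfig(seed=0, lambda_true=0.5, omega_true=0.05)
        with pytest.raises(GenerationError):
            generate_dataset(cfg)


class TestEndToEndRecovery:
    def test_lambda_unbiased_and_strategy_classified(self):
        """Mean exponent over seeds is within 0.05 of truth; the configured
        strategy is recovered in >= 90% of replicates (n = 60 communities)."""
        lams, hits = [], 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = SimulationConfig(seed=seed, n_sites=6, plots_per_site=10,
                                   lambda_true=1.0)
            ds = generate_dataset(cfg)
            res = strategy_from_tables(ds.survey, ds.litter)
            lams.append(res.lambda_hat)
            hits += res.label == "stoichiometric control"
        assert abs(np.mean(lams) - 1.0) < 0.05
        assert hits / n_rep >= 0.9

    def test_homeostasis_recovery_from_dataset(self):
        cfg = SimulationConfig(seed=3, n_sites=6, plots_per_site=10, H_true=4.0)
        ds = generate_dataset(cfg)
        truth = pd.DataFrame(ds.truth["plots"])
        res = fit_homeostasis(ds.soil["TN"] / ds.soil["TP"], truth["leaf_NP"])
        assert res.p_value < 0.05
        assert abs(res.H - 4.0) / 4.0 < 0.25
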