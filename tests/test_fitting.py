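"""Differential-evolution fitting: objective, recovery, determinism."""

import numpy as np
import pytest

import sccosol as s
from sccosol.model import PENALTY, objective


class TestObjective:
    def test_exact_fit_is_zero(self, clean_dataset):
        # regenerate the dataset's own truth coefficients
        truth = s.load_reference_coefficients("busulfan")
        assert objective("modified_arrhenius", truth.a, clean_dataset) == \
            pytest.approx(0.0, abs=1e-10)

    def test_hand_value_constant_model(self):
        ds = s.SolubilityDataset("x", [310, 320], [15, 20], [700, 750],
                                 [1e-6, 2e-6])
        # constant prediction 1.1e-6: AARD = 100*(0.1 + 0.45)/2
        a = (0, 0, 0, 0, 0, 1.1e-6)
        assert objective("modified_arrhenius", a, ds) == pytest.approx(27.5)

    def test_penalty_dominance(self, clean_dataset):
        # negative a4 makes exp(+a4... ) overflow: every record penalized
        a = (0, 0, 1, -1e9, 0, 0)
        val = objective("modified_arrhenius", a, clean_dataset)
        assert val == pytest.approx(PENALTY)

    def test_partial_penalty(self):
        ds = s.SolubilityDataset("x", [310, 320], [15, 20], [700, 750],
                                 [1e-6, 2e-6])
        # constant -1 prediction is non-physical for both records
        a = (0, 0, 0, 0, 0, -1.0)
        assert objective("modified_arrhenius", a, ds) == pytest.approx(PENALTY)

    def test_totality_no_nan(self, clean_dataset):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = rng.uniform(-1, 1, 6) * 10.0 ** rng.integers(-8, 8, 6)
            val = objective("modified_arrhenius", a, clean_dataset)
            assert np.isfinite(val) and val >= 0

    def test_population_objective_matches_scalar(self, clean_dataset):
        m = s.SolubilityModel(clean_dataset)
        f = m._population_objective()
        rng = np.random.default_rng(5)
        A = rng.normal(scale=1e-4, size=(6, 8))
        np.testing.assert_allclose(
            f(A), [m.objective(A[:, j]) for j in range(8)], rtol=1e-12
        )


class TestFit:
    def test_noiseless_parameter_recovery(self, clean_dataset, bracket_bounds):
        res = s.SolubilityModel(clean_dataset).fit(
            bounds=bracket_bounds, seed=0, restarts=1
        )
        assert res.aard < 0.01
        assert res.rsquared > 0.999999

    def test_seed_reproducibility(self, clean_dataset, bracket_bounds,
                                  quick_config):
        m = s.SolubilityModel(clean_dataset)
        r1 = m.fit(config=quick_config, bounds=bracket_bounds)
        r2 = m.fit(config=quick_config, bounds=bracket_bounds)
        assert np.array_equal(r1.params, r2.params)
        assert r1.aard == r2.aard
        assert r1.trace == r2.trace

    def test_trace_is_monotone_nonincreasing(self, noisy_dataset_factory,
                                             bracket_bounds, quick_config):
        ds = noisy_dataset_factory(seed=11)
        res = s.SolubilityModel(ds).fit(config=quick_config,
                                        bounds=bracket_bounds)
        trace = np.asarray(res.trace)
        assert np.all(np.diff(trace) <= 0)
        assert res.aard <= trace[-1] + 1e-12

    def test_dataset_too_small_raises(self):
        ds = s.SolubilityDataset("x", [310, 320, 330], [15, 20, 25],
                                 [700, 750, 800], [1e-6, 2e-6, 3e-6])
        with pytest.raises(ValueError):
            s.SolubilityModel(ds, "modified_arrhenius")

    def test_all_penalty_population_is_diagnosed(self, clean_dataset):
        # bounds forcing a negative constant prediction everywhere
        bounds = [(-1e-12, 1e-12)] * 3 + [(0, 1e-12), (-1e-12, 1e-12),
                                          (-2e-4, -1e-4)]
        with pytest.raises(RuntimeError, match="bounds"):
            s.SolubilityModel(clean_dataset).fit(
                bounds=bounds, seed=1, restarts=1, generations=10, patience=5
            )

    def test_one_free_coefficient_matches_grid_oracle(
        self, busulfan_truth, noisy_dataset_factory
    ):
        """DE on a 1-D slice agrees with a dense grid search."""
        ds = noisy_dataset_factory(seed=21)
        t = np.asarray(busulfan_truth.a)
        eps = np.abs(t) * 1e-12 + 1e-18
        lo, hi = 0.5 * t[3], 1.5 * t[3]
        bounds = list(zip(t - eps, t + eps))
        bounds[3] = (lo, hi)
        m = s.SolubilityModel(ds)
        res = m.fit(bounds=bounds, seed=3, restarts=1, generations=600)

        # dense grid oracle over the free coefficient, vectorised in chunks
        grid = np.linspace(lo, hi, 1_000_001)
        f = m._population_objective()
        best_val, best_x = np.inf, None
        for chunk in np.array_split(grid, 20):
            A = np.tile(t[:, None], (1, chunk.size))
            A[3] = chunk
            vals = f(A)
            j = int(np.argmin(vals))
            if vals[j] < best_val:
                best_val, best_x = vals[j], chunk[j]
        step = grid[1] - grid[0]
        assert abs(res.params[3] - best_x) <= step
        assert res.aard <= best_val + 1e-9


class TestFitAll:
    def test_smoke_two_drugs_two_models(self, quick_config):
        datasets = {}
        for i, drug in enumerate(["busulfan", "tamoxifen"]):
            truth = s.load_reference_coefficients(drug)
            datasets[drug] = s.generate_dataset(
                "modified_arrhenius", truth,
                noise=s.NoiseSpec(sigma=0.05, seed=50 + i),
            )
        cfg = s.DEConfig(restarts=1, generations=200, patience=100, seed=1)
        out = s.fit_all(datasets, ["modified_arrhenius", "bartle"], config=cfg)
        assert len(out) == 4
        for res in out.values():
            assert isinstance(res, s.SolubilityResults)
            assert np.isfinite(res.aard)

    def test_single_cell_equals_direct_fit(self, clean_dataset, bracket_bounds,
                                           quick_config):
        out = s.fit_all({"busulfan": clean_dataset}, ["modified_arrhenius"],
                        config=quick_config, bounds=bracket_bounds)
        direct = s.SolubilityModel(clean_dataset).fit(
            config=quick_config, bounds=bracket_bounds
        )
        res = out[("busulfan", "modified_arrhenius")]
        assert np.array_equal(res.params, direct.params)

    def test_failure_is_isolated(self, clean_dataset, quick_config):
        # chrastil without a molar mass cannot be fitted to y2 data
        with pytest.warns(UserWarning, match="chrastil"):
            out = s.fit_all({"busulfan": clean_dataset},
                            ["modified_arrhenius", "chrastil"],
                            config=quick_config)
        assert isinstance(out[("busulfan", "chrastil")], s.FitFailure)
        assert isinstance(out[("busulfan", "modified_arrhenius")],
                          s.SolubilityResults)

    def test_empty_model_list_raises(self, clean_dataset):
        with pytest.raises(s.ConfigurationError):
            s.fit_all({"busulfan": clean_dataset}, [])


@pytest.fixture(scope="module")
def res():
    truth = s.load_reference_coefficients("busulfan")
    ds = s.generate_dataset("modified_arrhenius", truth,
                            noise=s.NoiseSpec(sigma=0.05, seed=9))
    t = np.asarray(truth.a)
    w = 0.5 * np.abs(t) + 1e-5
    return s.SolubilityModel(ds).fit(
        bounds=list(zip(t - w, t + w)), seed=5, restarts=1,
        generations=300, patience=100,
    )


class TestResultsObject:

    def test_summary_mentions_key_quantities(self, res):
        text = res.summary()
        assert "AARD" in text and "busulfan" in text
        assert "a6" in text and f"{res.nobs}" in text

    def test_json_round_trip(self, res, tmp_path):
        import json

        path = tmp_path / "fit.json"
        res.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["model"] == "modified_arrhenius"
        np.testing.assert_allclose(doc["coefficients"], res.params)
        assert doc["aard_pct"] == pytest.approx(res.aard)

    def test_metrics_consistent_with_module_functions(self, res):
        y_exp = res.model.dataset.y2
        assert res.aard == pytest.approx(s.aard(y_exp, res.fittedvalues),
                                         rel=1e-9)
        assert res.rsquared == pytest.approx(s.r2(y_exp, res.fittedvalues))

    def test_leverage_report_and_plots(self, res):
        import matplotlib

        matplotlib.use("Agg")
        rep = res.leverage_report()
        assert rep.hat.shape == (res.nobs,)
        assert rep.valid_fraction >= 90.0
        ax1 = res.plot_parity()
        ax2 = res.plot_williams()
        assert ax1.get_xlabel() and ax2.get_xlabel()
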