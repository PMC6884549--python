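import numpy as np
import pandas as pd
import pytest

import berquant as bq
from berquant.configs import GateConfig
from berquant.flow import EmptySampleError, PairingError, ReporterResult


def _events(intensities, threshold_cols=None):
    n = len(intensities)
    df = pd.DataFrame(
        {
            "fsc_a": np.full(n, 1e4),
            "fsc_h": np.full(n, 1e4),
            "ssc_a": np.full(n, 3e3),
            "viability": np.full(n, 1e2),
            "ch_egfp": np.full(n, 1e4),
            "ch_reporter": np.asarray(intensities, dtype=float),
        }
    )
    return df


class TestGating:
    def test_dead_cells_excluded(self):
        df = _events([1e4, 1e4])
        df.loc[0, "viability"] = 1e5
        gated = bq.gate_live_singlets(df)
        assert len(gated) == 1

    def test_doublets_excluded_by_ratio_band(self):
        df = _events([1e4, 1e4])
        df.loc[0, "fsc_h"] = df.loc[0, "fsc_a"] * 0.5
        assert len(bq.gate_live_singlets(df)) == 1

    def test_idempotent(self):
        samples, _ = bq.simulate_flow_experiment(bq.FlowSimConfig(seed=0))
        once = bq.gate_live_singlets(samples["damaged"])
        twice = bq.gate_live_singlets(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_gated_fraction_matches_planted_dead_and_doublet_rates(self):
        cfg = bq.FlowSimConfig(
            n_events=50_000, dead_fraction=0.10, doublet_fraction=0.05, seed=7
        )
        samples, _ = bq.simulate_flow_experiment(cfg)
        frac = len(bq.gate_live_singlets(samples["damaged"])) / cfg.n_events
        expected = 0.90 * 0.95
        # 4-sigma binomial bound plus slack for gate-tail leakage
        tol = 4 * np.sqrt(expected * (1 - expected) / cfg.n_events) + 0.01
        assert abs(frac - expected) < tol

    def test_relaxing_a_bound_never_shrinks_the_gate(self):
        samples, _ = bq.simulate_flow_experiment(bq.FlowSimConfig(seed=1))
        tight = GateConfig(viability_max=5e2)
        loose = GateConfig(viability_max=5e3)
        assert len(bq.gate_live_singlets(samples["damaged"], loose)) >= len(
            bq.gate_live_singlets(samples["damaged"], tight)
        )


class TestReporterSignal:
    def test_hand_computed_f(self):
        # 50 positive cells at MFI 1000 among 10000 live -> F = 5.0
        intens = np.full(10_000, 10.0)
        intens[:50] = 1000.0
        cfg = GateConfig(positivity_thresholds={"ch_egfp": 1e3, "ch_reporter": 500.0})
        res = bq.reporter_signal(_events(intens), "ch_reporter", cfg)
        assert res == ReporterResult(n_positive=50, mfi=1000.0, n_live=10_000, f_signal=5.0)

    def test_no_positive_events_gives_zero_f(self):
        res = bq.reporter_signal(_events([10.0] * 100), "ch_reporter")
        assert res.f_signal == 0.0 and res.mfi == 0.0

    def test_f_linear_in_positive_intensity(self):
        intens = np.full(1000, 10.0)
        intens[:20] = 5000.0
        base = bq.reporter_signal(_events(intens), "ch_reporter").f_signal
        doubled = bq.reporter_signal(_events(np.where(intens > 1e3, 2 * intens, intens)),
                                     "ch_reporter").f_signal
        assert doubled == pytest.approx(2 * base)

    def test_empty_sample_errors(self):
        with pytest.raises(EmptySampleError):
            bq.reporter_signal(_events([]).iloc[0:0], "ch_reporter")


class TestNormalisation:
    def test_self_normalisation(self):
        assert bq.normalize_to_transfection(2.5, 2.5) == 1.0
        assert bq.normalize_to_transfection(5.0, 2.0) == 2.5

    def test_zero_transfection_control_errors(self):
        with pytest.raises(EmptySampleError, match="transfection-control"):
            bq.normalize_to_transfection(5.0, 0.0)

    def test_percent_re_bounds(self):
        assert bq.percent_reporter_expression(1.0, 1.0) == 100.0
        assert bq.percent_reporter_expression(0.0, 1.0) == 0.0
        with pytest.raises(EmptySampleError):
            bq.percent_reporter_expression(1.0, 0.0)


class TestExperiment:
    @pytest.mark.parametrize("r", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_percent_re_recovers_planted_repair_probability(
        self, r, flow_sample_sheet
    ):
        samples, truth = bq.simulate_flow_experiment(
            bq.FlowSimConfig(n_events=10_000, repair_prob=r, seed=int(100 * r) + 11)
        )
        est = bq.RepairCapacityEstimator().fit(samples, flow_sample_sheet)
        got = est.capacities_["percent_re"].iloc[0]
        assert abs(got - truth.params["expected_percent_re"]) < 3.0

    def test_identical_event_tables_give_identical_percent_re(self):
        samples, _ = bq.simulate_flow_experiment(bq.FlowSimConfig(seed=5))
        events = {
            "d1": samples["damaged"], "u1": samples["undamaged"],
            "d2": samples["damaged"], "u2": samples["undamaged"],
        }
        sheet = pd.DataFrame(
            {
                "sample_id": ["d1", "u1", "d2", "u2"],
                "condition": ["A", "A", "B", "B"],
                "damaged": [True, False, True, False],
                "replicate": [1, 1, 1, 1],
            }
        )
        caps = bq.RepairCapacityEstimator().fit(events, sheet).capacities_
        vals = caps.set_index("condition")["percent_re"]
        assert vals["A"] == vals["B"]

    def test_sem_is_sd_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        events, rows = {}, []
        for rep in range(1, 4):
            s, _ = bq.simulate_flow_experiment(
                bq.FlowSimConfig(n_events=4000, repair_prob=0.5, seed=rep)
            )
            events[f"d{rep}"], events[f"u{rep}"] = s["damaged"], s["undamaged"]
            rows += [
                {"sample_id": f"d{rep}", "condition": "WT", "damaged": True, "replicate": rep},
                {"sample_id": f"u{rep}", "condition": "WT", "damaged": False, "replicate": rep},
            ]
        est = bq.RepairCapacityEstimator().fit(events, pd.DataFrame(rows))
        per_rep = est.per_replicate_["percent_re"].to_numpy()
        expected_sem = per_rep.std(ddof=1) / np.sqrt(len(per_rep))
        assert est.capacities_["sem"].iloc[0] == pytest.approx(expected_sem)

    def test_missing_undamaged_counterpart_raises(self, flow_sample_sheet):
        samples, _ = bq.simulate_flow_experiment(bq.FlowSimConfig(seed=2))
        sheet = flow_sample_sheet[flow_sample_sheet["damaged"]]
        with pytest.raises(PairingError):
            bq.RepairCapacityEstimator().fit(samples, sheet)

    def test_lower_repair_prob_gives_lower_percent_re(self, flow_sample_sheet):
        caps = {}
        for r in (0.2, 0.8):
            samples, _ = bq.simulate_flow_experiment(
                bq.FlowSimConfig(n_events=8000, repair_prob=r, seed=42)
            )
            est = bq.RepairCapacityEstimator().fit(samples, flow_sample_sheet)
            caps[r] = est.capacities_["percent_re"].iloc[0]
        assert caps[0.2] < caps[0.8]
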