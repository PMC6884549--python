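import math

import numpy as np
import pandas as pd
import pytest

import berquant as bq
from berquant.configs import InvalidParameterError, QpcrAssayConfig
from berquant.qpcr import MissingDataError


class TestScalarOps:
    def test_aggregate_ct_is_replicate_mean(self):
        wells = pd.DataFrame(
            {
                "sample_id": "S",
                "gene": "G",
                "region": "promoter",
                "treatment": "AAG+APE1",
                "replicate": [1, 2, 3],
                "ct": [25.0, 25.2, 24.8],
            }
        )
        out = bq.aggregate_ct(wells)
        assert out["ct"].iloc[0] == pytest.approx(25.0)
        assert out["n_replicates"].iloc[0] == 3

    def test_aggregate_ct_single_replicate_identity(self):
        wells = pd.DataFrame(
            {
                "sample_id": ["S"],
                "gene": ["G"],
                "region": ["end"],
                "treatment": ["IP"],
                "replicate": [1],
                "ct": [26.1],
            }
        )
        assert bq.aggregate_ct(wells)["ct"].iloc[0] == 26.1

    def test_aggregate_ct_rejects_empty_and_nonfinite(self):
        with pytest.raises(MissingDataError):
            bq.aggregate_ct(pd.DataFrame(columns=["sample_id", "ct"]))
        bad = pd.DataFrame(
            {"sample_id": ["S"], "gene": ["G"], "region": ["r"],
             "treatment": ["IP"], "replicate": [1], "ct": [np.nan]}
        )
        with pytest.raises(ValueError, match="non-finite"):
            bq.aggregate_ct(bad)

    @pytest.mark.parametrize(
        "plus,minus,expected", [(26.0, 25.0, 1.0), (25.0, 25.0, 0.0), (24.5, 25.0, -0.5)]
    )
    def test_lesion_delta_ct(self, plus, minus, expected):
        assert bq.lesion_delta_ct(plus, minus) == pytest.approx(expected)

    def test_lesion_delta_ct_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            bq.lesion_delta_ct(float("nan"), 25.0)

    @pytest.mark.parametrize(
        "dct,expected",
        [(0.0, 0.0), (1.0, math.log(2)), (-0.2, 0.0), (2.0, 2 * math.log(2))],
    )
    def test_lesion_frequency_poisson_inversion(self, dct, expected):
        assert bq.lesion_frequency(dct) == pytest.approx(expected)

    def test_lesion_frequency_rejects_bad_efficiency(self):
        with pytest.raises(InvalidParameterError):
            bq.lesion_frequency(1.0, QpcrAssayConfig(efficiency=0.9))

    def test_percent_input_identities(self):
        cfg = QpcrAssayConfig(input_fraction=0.01)
        # IP Ct equal to the 1% input aliquot Ct -> exactly 1% of input
        assert bq.percent_input(25.0, 25.0, cfg) == pytest.approx(1.0)
        # full recovery: IP amplifies log2(100) cycles earlier
        assert bq.percent_input(25.0 - math.log2(100), 25.0, cfg) == pytest.approx(100.0)
        # one extra IP cycle halves the signal at E=2
        assert bq.percent_input(26.0, 25.0, cfg) == pytest.approx(0.5)

    def test_relative_expression_ddct(self):
        assert bq.relative_expression(25, 20, 25, 20) == pytest.approx(1.0)
        assert bq.relative_expression(24, 20, 25, 20) == pytest.approx(2.0)


class TestLesionEstimator:
    def test_noiseless_gradient_recovered_to_high_precision(self, noiseless_lesion_wells):
        est = bq.LesionFrequencyEstimator().fit(noiseless_lesion_wells)
        rel = est.estimates_.set_index("region")["rel_to_promoter"]
        assert rel["promoter"] == 1.0
        assert rel["end"] == pytest.approx(5.0, rel=1e-9)
        assert rel["middle"] == pytest.approx(math.sqrt(5.0), rel=1e-9)

    def test_ddct_mode_reports_cycle_differences(self, noiseless_lesion_wells):
        est = bq.LesionFrequencyEstimator(mode="ddct").fit(noiseless_lesion_wells)
        rel = est.estimates_.set_index("region")["rel_to_promoter"]
        assert rel["promoter"] == 0.0
        # delta_ct(end) - delta_ct(promoter) = (0.5 - 0.1)/ln2 cycles
        assert rel["end"] == pytest.approx(0.4 / math.log(2), rel=1e-9)

    def test_zero_promoter_gets_pseudocount(self):
        landscapes = [
            bq.LesionLandscape(gene="G", region_lambdas={"promoter": 0.0, "end": 0.5})
        ]
        wells, _ = bq.simulate_damage_qpcr(landscapes, ct_noise_sd=0.0, seed=0)
        est = bq.LesionFrequencyEstimator(pseudocount=0.01).fit(wells)
        rel = est.estimates_.set_index("region")["rel_to_promoter"]
        assert rel["promoter"] == 1.0
        assert rel["end"] == pytest.approx(0.5 / 0.01)

    def test_missing_arm_raises(self, noiseless_lesion_wells):
        only_plus = noiseless_lesion_wells[
            noiseless_lesion_wells["treatment"] == "AAG+APE1"
        ]
        with pytest.raises(MissingDataError):
            bq.LesionFrequencyEstimator().fit(only_plus)

    def test_sklearn_params_roundtrip(self):
        est = bq.LesionFrequencyEstimator(efficiency=1.9)
        assert est.get_params()["efficiency"] == 1.9
        est.set_params(mode="ddct")
        assert est.mode == "ddct"


class TestChipEstimator:
    def test_noiseless_occupancy_recovered_exactly(self):
        wells, _ = bq.simulate_chip_qpcr(
            {"promoter": 1.0, "middle": 2.0, "end": 4.0}, ct_noise_sd=0.0, seed=0
        )
        est = bq.ChipOccupancyEstimator(input_fraction=0.01).fit(wells)
        rel = est.estimates_.set_index("region")["relative_occupancy"]
        assert rel["promoter"] == 1.0
        assert rel["end"] == pytest.approx(4.0, rel=1e-9)
        assert rel["middle"] == pytest.approx(2.0, rel=1e-9)

    def test_uniform_occupancy_is_flat(self):
        wells, _ = bq.simulate_chip_qpcr(
            {"promoter": 3.0, "middle": 3.0, "end": 3.0}, ct_noise_sd=0.0, seed=0
        )
        est = bq.ChipOccupancyEstimator().fit(wells)
        assert np.allclose(est.estimates_["relative_occupancy"], 1.0)

    def test_end_enrichment_recovered_under_noise(self):
        # 200 noisy simulations: mean recovered end/promoter ratio within 3 SE of 4
        vals = []
        for i in range(200):
            wells, _ = bq.simulate_chip_qpcr(
                {"promoter": 1.0, "end": 4.0}, ct_noise_sd=0.15, seed=10_000 + i
            )
            est = bq.ChipOccupancyEstimator().fit(wells)
            rel = est.estimates_.set_index("region")["relative_occupancy"]
            vals.append(rel["end"])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 4.0) < 3 * se + 1e-12


class TestExpressionEstimator:
    def test_planted_induction_recovered(self):
        rows = []
        # calibrator WT: target Ct 25, GAPDH 20; KO: target 2 cycles lower -> 4-fold
        for sample, tct in (("WT", 25.0), ("KO", 23.0)):
            for gene, ct in (("TARGET", tct), ("GAPDH", 20.0)):
                for rep in (1, 2, 3):
                    rows.append(
                        {"sample_id": sample, "gene": gene, "replicate": rep, "ct": ct}
                    )
        est = bq.RelativeExpressionEstimator(calibrator_sample="WT").fit(
            pd.DataFrame(rows)
        )
        fc = est.estimates_.set_index("sample_id")["fold_change"]
        assert fc["WT"] == pytest.approx(1.0)
        assert fc["KO"] == pytest.approx(4.0)

    def test_missing_reference_gene_raises(self):
        df = pd.DataFrame(
            {"sample_id": ["WT"], "gene": ["TARGET"], "replicate": [1], "ct": [25.0]}
        )
        with pytest.raises(MissingDataError, match="GAPDH"):
            bq.RelativeExpressionEstimator().fit(df)
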