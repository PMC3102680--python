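import numpy as np
import pandas as pd
import pytest

from phosphopath import quant
from phosphopath.io_formats import QuantTable
from phosphopath.quant import (
    SENTINEL_REF_ONLY,
    SENTINEL_TEST_ONLY,
    ComparisonSpec,
    QCConfig,
    RatioTable,
    RegulationCall,
)
from phosphopath.synthetic_data import SimulationConfig, simulate_dataset


def build_table(values, runs=("A.1", "A.2", "B.1", "B.2"), standard_row="std"):
    """QuantTable from a dict peptide_id → list of per-run abundances."""
    meta = pd.DataFrame(
        {
            "peptide_sequence": ["AAApSAAA"] * len(values),
            "protein_accession": [f"P{i}" for i in range(len(values))],
            "gene_symbol": [f"G{i}" for i in range(len(values))],
            "sites": ["S4"] * len(values),
            "is_standard": [pid == standard_row for pid in values],
        },
        index=list(values),
    )
    abundance = pd.DataFrame(values, index=list(runs)).T
    return QuantTable(meta=meta, abundance=abundance)


class TestNormalize:
    def test_peptides_equal_to_standard_become_one(self):
        t = build_table({"std": [5, 6, 7, 8], "pep": [5, 6, 7, 8]})
        norm = quant.normalize_to_standard(t)
        assert (norm.abundance.loc["pep"] == 1).all()
        assert (norm.abundance.loc["std"] == 1).all()

    def test_per_run_scale_invariance(self):
        t = build_table({"std": [5, 6, 7, 8], "pep": [10, 12, 3, 4]})
        scaled = build_table({"std": [10, 6, 7, 8], "pep": [20, 12, 3, 4]})
        a = quant.normalize_to_standard(t).abundance
        b = quant.normalize_to_standard(scaled).abundance
        pd.testing.assert_frame_equal(a, b)

    def test_standard_missing_in_run_names_the_run(self):
        t = build_table({"std": [5, 6, np.nan, 8], "pep": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="B.1"):
            quant.normalize_to_standard(t)


class TestReplicateCV:
    def test_constant_values(self):
        assert quant.replicate_cv([100, 100, 100]) == 0

    def test_sample_sd_over_mean(self):
        assert quant.replicate_cv([90, 100, 110]) == pytest.approx(0.10)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            quant.replicate_cv([1.0])


class TestSummarize:
    def test_full_triplicate_mean_and_cv_flag(self):
        t = build_table(
            {"std": [1, 1, 1, 1, 1, 1], "pep": [90, 100, 110, 5, 5, 5]},
            runs=("A.1", "A.2", "A.3", "B.1", "B.2", "B.3"),
        )
        s = quant.summarize_replicates(t, QCConfig(cv_threshold=0.20))
        assert s.mean.loc["pep", "A"] == pytest.approx(100)
        assert s.cv.loc["pep", "A"] == pytest.approx(0.10)
        assert bool(s.clean.loc["pep", "A"])

    def test_below_min_replicates_is_missing(self):
        t = build_table(
            {"std": [1, 1, 1, 1, 1, 1], "pep": [90, np.nan, np.nan, 5, 5, 5]},
            runs=("A.1", "A.2", "A.3", "B.1", "B.2", "B.3"),
        )
        s = quant.summarize_replicates(t, QCConfig(min_detected_replicates=2))
        assert np.isnan(s.mean.loc["pep", "A"])
        assert s.mean.loc["pep", "B"] == 5


class TestLog2Ratios:
    def summary(self, test, ref):
        return pd.DataFrame({"T": [test], "R": [ref]}, index=["pep"])

    def test_plain_ratio(self):
        rt = quant.log2_ratio_table(self.summary(4.0, 1.0), [ComparisonSpec("T", "R")])
        assert rt.ratios.loc["pep", "T/R"] == pytest.approx(2.0)

    def test_test_only_sentinel(self):
        rt = quant.log2_ratio_table(self.summary(4.0, np.nan), [ComparisonSpec("T", "R")])
        assert rt.ratios.loc["pep", "T/R"] == SENTINEL_TEST_ONLY

    def test_reference_only_sentinel(self):
        rt = quant.log2_ratio_table(self.summary(np.nan, 4.0), [ComparisonSpec("T", "R")])
        assert rt.ratios.loc["pep", "T/R"] == SENTINEL_REF_ONLY

    def test_neither_detected_is_nan(self):
        rt = quant.log2_ratio_table(self.summary(np.nan, np.nan), [ComparisonSpec("T", "R")])
        assert np.isnan(rt.ratios.loc["pep", "T/R"])

    def test_antisymmetry_with_sentinels(self, rng):
        n = 50
        means = pd.DataFrame(
            {
                "T": np.where(rng.random(n) < 0.2, np.nan, rng.lognormal(0, 1, n)),
                "R": np.where(rng.random(n) < 0.2, np.nan, rng.lognormal(0, 1, n)),
            },
            index=[f"p{i}" for i in range(n)],
        )
        fwd = quant.log2_ratio_table(means, [ComparisonSpec("T", "R")]).ratios["T/R"]
        rev = quant.log2_ratio_table(means, [ComparisonSpec("R", "T")]).ratios["R/T"]
        for f, r in zip(fwd, rev):
            if np.isnan(f):
                assert np.isnan(r)
            elif f == SENTINEL_TEST_ONLY:
                assert r == SENTINEL_REF_ONLY
            elif f == SENTINEL_REF_ONLY:
                assert r == SENTINEL_TEST_ONLY
            else:
                assert r == pytest.approx(-f)


class TestCentering:
    def table(self, values):
        return RatioTable(
            meta=pd.DataFrame(index=range(len(values))),
            ratios=pd.DataFrame({"T/R": values}),
        )

    def test_mean_centering(self):
        out = quant.center_ratios(self.table([1.0, 2.0, 3.0]))
        assert list(out.ratios["T/R"]) == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        once = quant.center_ratios(self.table([1.0, 2.0, 3.0]))
        twice = quant.center_ratios(once)
        pd.testing.assert_frame_equal(once.ratios, twice.ratios)

    def test_sentinels_preserved_single_ratio_zeroed(self):
        out = quant.center_ratios(self.table([2.5, SENTINEL_TEST_ONLY, SENTINEL_REF_ONLY]))
        assert list(out.ratios["T/R"]) == [0.0, SENTINEL_TEST_ONLY, SENTINEL_REF_ONLY]

    def test_all_sentinel_comparison_rejected(self):
        with pytest.raises(ValueError, match="center"):
            quant.center_ratios(self.table([SENTINEL_TEST_ONLY, np.nan]))


class TestRegulationCalls:
    spec = ComparisonSpec("T", "R")

    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.737, RegulationCall.UP),
            (0.977, RegulationCall.UNCHANGED),
            (1.0, RegulationCall.UP),          # closed bound
            (-1.0, RegulationCall.DOWN),
            (-0.999, RegulationCall.UNCHANGED),
            (SENTINEL_REF_ONLY, RegulationCall.REFERENCE_ONLY),
            (SENTINEL_TEST_ONLY, RegulationCall.TEST_ONLY),
            (float("nan"), RegulationCall.NOT_QUANTIFIED),
        ],
    )
    def test_threshold_and_sentinel_semantics(self, value, expected):
        assert quant.call_regulation(value, self.spec) is expected


class TestConcurrence:
    def table(self, rows):
        comps = ["W/Z", "X/Z", "Y/Z", "V/Z"]
        meta = pd.DataFrame({"gene_symbol": list(rows)}, index=list(rows))
        return RatioTable(meta=meta, ratios=pd.DataFrame(rows, index=comps).T)

    def test_direction_discordant_exclude_included(self):
        # regulated up everywhere required, down in the excluded comparison
        rt = self.table({"CTTN": [1.065, 1.052, 1.236, -1.680]})
        res = quant.concurrent_regulation(rt, require=["W/Z", "X/Z", "Y/Z"], exclude=["V/Z"])
        assert res["up"] == ["CTTN"]

    def test_sentinel_in_exclude_counts_as_non_concurrent(self):
        rt = self.table({"TMEM40": [-1.293, -5.644, -2.08, SENTINEL_REF_ONLY]})
        res = quant.concurrent_regulation(rt, require=["W/Z", "X/Z", "Y/Z"], exclude=["V/Z"])
        assert res["down"] == ["TMEM40"]

    def test_concurrent_in_excluded_comparison_drops_protein(self):
        rt = self.table({"G": [2.0, 2.0, 2.0, 2.0]})
        res = quant.concurrent_regulation(rt, require=["W/Z", "X/Z", "Y/Z"], exclude=["V/Z"])
        assert res == {"up": [], "down": []}

    def test_sentinel_never_supports_a_required_call(self):
        rt = self.table({"G": [SENTINEL_TEST_ONLY, 2.0, 2.0, 0.0]})
        res = quant.concurrent_regulation(rt, require=["W/Z", "X/Z", "Y/Z"], exclude=["V/Z"])
        assert res == {"up": [], "down": []}

    def test_unknown_comparison_label(self):
        rt = self.table({"G": [1.0, 1.0, 1.0, 0.0]})
        with pytest.raises(KeyError):
            quant.concurrent_regulation(rt, require=["nope"], exclude=[])


class TestPipelineInvariants:
    def test_run_scaling_cancelled_by_normalization_and_centering(self, rng):
        """Ratios are invariant to arbitrary per-run multiplicative biases."""
        base = SimulationConfig(n_proteins=40, seed=7, replicate_noise_sd=0.1)
        runs = base.runs
        scaled = SimulationConfig(
            n_proteins=40, seed=7, replicate_noise_sd=0.1,
            run_scale_factors=tuple(2.0 ** rng.uniform(-2, 2, len(runs))),
        )
        outputs = []
        for cfg in (base, scaled):
            ds = simulate_dataset(cfg)
            norm = quant.normalize_to_standard(ds.quant)
            s = quant.summarize_replicates(norm)
            rt = quant.log2_ratio_table(s.mean, [ComparisonSpec("3KTR", "3KT")])
            outputs.append(quant.center_ratios(rt).ratios)
        pd.testing.assert_frame_equal(outputs[0], outputs[1])

    def test_noise_free_calls_recover_planted_directions_exactly(self):
        cfg = SimulationConfig(
            n_proteins=60, n_regulated=25, effect_size_log2=2.0,
            replicate_noise_sd=0.0, seed=13,
        )
        ds = simulate_dataset(cfg)
        norm = quant.normalize_to_standard(ds.quant)
        s = quant.summarize_replicates(norm)
        rt = quant.log2_ratio_table(s.mean.drop(index=["STD_bcasein"]), [ComparisonSpec("3KTR", "3KT")])
        truth = ds.truth.regulated_peptides("3KTR")
        calls = quant.call_regulation_table(rt, [ComparisonSpec("3KTR", "3KT")])["3KTR/3KT"]
        for pid, call in calls.items():
            if pid in truth:
                assert call is (RegulationCall.UP if truth[pid] > 0 else RegulationCall.DOWN)
            else:
                assert call is RegulationCall.UNCHANGED

    def test_null_simulation_tail_fraction_below_one_percent(self):
        cfg = SimulationConfig(n_proteins=520, replicate_noise_sd=0.2, seed=21)
        ds = simulate_dataset(cfg)
        norm = quant.normalize_to_standard(ds.quant)
        s = quant.summarize_replicates(norm)
        rt = quant.log2_ratio_table(s.mean.drop(index=["STD_bcasein"]), [ComparisonSpec("3KTR", "3KT")])
        vals = rt.ratios["3KTR/3KT"]
        ordinary = vals[rt.ordinary_mask()["3KTR/3KT"]]
        assert len(ordinary) >= 1000
        assert (ordinary.abs() >= 1).mean() < 0.01
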