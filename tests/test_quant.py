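"""XIC integration, reference normalization and mass-balance quantification."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from myofilquant.lcms import SampleRun, default_ground_truth, simulate_design, simulate_run
from myofilquant.quant import (XICPeakArea, fraction_phosphorylated, integrate_xic,
                               normalize, normalized_abundance, quantify_study,
                               relative_abundance, run_areas, truncation_ratio,
                               two_sample_t)
from myofilquant.species import cterm_ids, reference_ids


class TestIntegrateXic:
    def test_all_zero_trace_gives_zero_area(self):
        rt = np.linspace(0, 10, 101)
        assert integrate_xic(rt, np.zeros_like(rt), (2.0, 4.0)).area == 0.0

    def test_rectangular_pulse_closed_form(self):
        rt = np.linspace(0, 10, 10001)
        y = np.where((rt >= 3.0) & (rt <= 5.0), 2.0, 0.0)
        area = integrate_xic(rt, y, (2.5, 5.5)).area
        assert area == pytest.approx(2.0 * 2.0, rel=1e-3)

    def test_gaussian_peak_matches_analytic_integral(self):
        rt = np.linspace(0, 10, 20001)
        amplitude, sigma, center = 7.0, 0.1, 5.0
        y = amplitude * np.exp(-0.5 * ((rt - center) / sigma) ** 2)
        area = integrate_xic(rt, y, (4.0, 6.0)).area
        assert area == pytest.approx(amplitude * sigma * np.sqrt(2 * np.pi), rel=1e-3)

    @pytest.mark.parametrize("window", [(11.0, 12.0), (-1.0, 2.0), (4.0, 4.0)])
    def test_bad_window_rejected(self, window):
        rt = np.linspace(0, 10, 101)
        with pytest.raises(ValueError):
            integrate_xic(rt, np.zeros_like(rt), window)


class TestNormalize:
    def make(self, sid, area):
        return XICPeakArea(sid, area, 0.0, 1.0)

    def test_ratio_per_reference(self):
        ratios = normalize(self.make("t", 10.0), [self.make("r1", 5.0), self.make("r2", 2.0)])
        assert ratios == {"r1": 2.0, "r2": 5.0}

    def test_zero_target_gives_zero_ratios(self):
        ratios = normalize(self.make("t", 0.0), [self.make("r1", 5.0)])
        assert ratios == {"r1": 0.0}

    def test_global_scaling_cancels(self):
        refs = [self.make("r1", 5.0), self.make("r2", 2.0)]
        scaled = [self.make("r1", 10.0), self.make("r2", 4.0)]
        assert normalize(self.make("t", 3.0), refs) == normalize(self.make("t", 6.0), scaled)

    def test_zero_reference_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero area"):
            ratios = normalize(self.make("t", 3.0), [self.make("r1", 0.0), self.make("r2", 2.0)])
        assert list(ratios) == ["r2"]

    def test_all_zero_references_error(self):
        with pytest.raises(ValueError, match="zero area"):
            normalize(self.make("t", 3.0), [self.make("r1", 0.0)])


class TestFractionPhosphorylated:
    def test_equal_ratios_mean_no_phosphorylation(self):
        r = fraction_phosphorylated([{"r1": 0.5, "r2": 0.8}], [{"r1": 0.5, "r2": 0.8}])
        assert r.estimate == 0.0 and r.n == 2

    def test_single_reference_arithmetic(self):
        r = fraction_phosphorylated([{"r1": 0.4}], [{"r1": 0.8}])
        assert r.estimate == pytest.approx(0.5)

    def test_negative_raw_values_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            r = fraction_phosphorylated([{"r1": 1.0}], [{"r1": 0.5}])
        assert r.estimate == 0.0 and r.clamped

    def test_zero_treated_ratio_drops_reference(self):
        with pytest.warns(UserWarning, match="dropped"):
            r = fraction_phosphorylated([{"r1": 0.4, "r2": 0.4}], [{"r1": 0.0, "r2": 0.8}])
        assert r.n == 1


class TestEndToEndMassBalance:
    def test_zero_noise_recovers_all_generating_fractions(self, noiseless_design,
                                                          noiseless_truth):
        table = quantify_study(noiseless_design).set_index(["group", "quantity"])["estimate"]
        g = noiseless_truth.groups
        for group in ("control", "IR2", "IDNR"):
            total = g[group].tni_mono_fraction + g[group].tni_bis_fraction
            assert table[group, "tni_fraction_phosphorylated"] == pytest.approx(total, abs=1e-9)
            assert table[group, "tm_fraction_phosphorylated"] == pytest.approx(
                g[group].tm_phospho_fraction, abs=1e-9)
        assert table["IDNR", "tni_mono_relative_abundance"] == pytest.approx(0.19, abs=1e-9)
        assert table["IDNR", "tni_bis_relative_abundance"] == pytest.approx(2.8, abs=1e-9)
        assert table["IR2", "tni_bis_relative_abundance"] == pytest.approx(4.2, abs=1e-9)
        assert table["IDNR", "tni_cterm_truncation_ratio"] == pytest.approx(1.0, abs=1e-9)

    def test_loading_invariance(self, noiseless_truth, fixture_table):
        """Scaling every trace of one run by c > 0 changes no normalized output."""
        runs = simulate_design(noiseless_truth, 7, n_replicates=1,
                               groups=("control", "IDNR"))
        base = quantify_study(runs)
        runs[0].traces = {sid: 3.7 * y for sid, y in runs[0].traces.items()}
        scaled = quantify_study(runs)
        for col in ("estimate", "sd"):
            np.testing.assert_allclose(scaled[col].astype(float),
                                       base[col].astype(float), rtol=1e-9, atol=1e-12)

    def test_recovered_fraction_monotone_in_occupancy(self, fixture_table):
        """Recovered TnI fraction phosphorylated is nondecreasing in the truth."""
        refs = reference_ids(fixture_table, "TnI")
        recovered = []
        for mono in (0.0, 0.1, 0.25, 0.4, 0.6):
            truth = replace(default_ground_truth(), noise_cv=0.0, loading_sigma=0.0)
            truth = replace(truth, groups={"control": replace(
                truth.groups["control"], tni_mono_fraction=mono, tni_bis_fraction=0.1)})
            u = run_areas(simulate_run(truth, SampleRun("control", False, 1, 1)), fixture_table)
            t = run_areas(simulate_run(truth, SampleRun("control", True, 1, 1)), fixture_table)
            r = fraction_phosphorylated(
                [normalized_abundance(u, ["tni_analog_SSANYR"], refs)],
                [normalized_abundance(t, ["tni_analog_SSANYR"], refs)])
            recovered.append(r.estimate)
        assert all(b > a for a, b in zip(recovered, recovered[1:]))


class TestRelativeAbundanceAndTruncation:
    def test_control_against_itself_is_one(self, noiseless_design):
        from myofilquant.species import load_fixture
        fixture = load_fixture()
        refs = reference_ids(fixture, "TnI")
        ctl = [run_areas(c, fixture) for c in noiseless_design
               if c.run.group == "control" and not c.run.treated]
        norm = [normalized_abundance(a, ["tni_mono_RSSpANYR"], refs) for a in ctl]
        r = relative_abundance(norm, norm)
        assert r.estimate == pytest.approx(1.0, abs=1e-12)

    def test_truncation_ratio_half(self, fixture_table):
        """50% truncation in the experimental group, none in control -> 0.5."""
        truth = replace(default_ground_truth(), noise_cv=0.0, loading_sigma=0.0)
        truth = replace(truth, groups={
            "control": truth.groups["control"],
            "IR2": replace(truth.groups["IR2"], tni_truncated_fraction=0.5)})
        refs = reference_ids(fixture_table, "TnI")
        cterm = cterm_ids(fixture_table)
        ctl = [run_areas(simulate_run(truth, SampleRun("control", False, 1, 1)), fixture_table)]
        exp = [run_areas(simulate_run(truth, SampleRun("IR2", False, 1, 2)), fixture_table)]
        assert truncation_ratio(exp, ctl, cterm, refs).estimate == pytest.approx(0.5, abs=1e-9)

    def test_oxidation_redistribution_leaves_summed_ratio_unchanged(self, fixture_table):
        """Shifting the C-terminal Met oxidation split at fixed truncation does
        not move the summed-form ratio."""
        base = replace(default_ground_truth(), noise_cv=0.0, loading_sigma=0.0)
        refs = reference_ids(fixture_table, "TnI")
        cterm = cterm_ids(fixture_table)
        ctl = [run_areas(simulate_run(base, SampleRun("control", False, 1, 1)), fixture_table)]
        results = []
        for ox in (0.0, 0.3, 0.9):
            truth = replace(base, groups={
                "control": base.groups["control"],
                "IR2": replace(base.groups["IR2"], tni_cterm_oxidation=ox)})
            exp = [run_areas(simulate_run(truth, SampleRun("IR2", False, 1, 2)), fixture_table)]
            results.append(truncation_ratio(exp, ctl, cterm, refs).estimate)
        np.testing.assert_allclose(results, results[0], rtol=1e-6)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_textbook_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1e-4, 4)
        b = 1.0 + rng.normal(0.0, 1e-4, 4)
        _, p = two_sample_t(a, b)
        assert p < 1e-6

    def test_zero_variance_conventions(self):
        assert two_sample_t([1, 1], [1, 1]) == (0.0, 1.0)
        t, p = two_sample_t([0, 0], [1, 1])
        assert p == 0.0 and t < 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])
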