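"""Cohort generator: structure, hidden-truth statistics, canonical CSV IO."""

import io

import numpy as np
import pytest
from scipy.stats import chisquare, norm

from glyctest.bias_sim import BiasParams
from glyctest.cases import CaseDataError
from glyctest.audiogram_data import error_samples, mtr_samples
from glyctest.hydrops_model import TemplateParams, build_template
from glyctest.synthetic_data import (
    CohortConfig,
    generate_cohort,
    load_cohort_config,
    read_cases,
    write_cases,
)

ALL_PATIENTS = TemplateParams(0.378, 3.89)


def _single_group(**kw):
    return CohortConfig(template_params_by_group={"all": ALL_PATIENTS}, **kw)


class TestConfigValidation:
    def test_ramp_must_start_at_zero_and_saturate(self):
        with pytest.raises(ValueError, match="ramp"):
            _single_group(effect_ramp={0: 0.1, 1: 0.5, 2: 0.8, 3: 1.0, 4: 1.0})
        with pytest.raises(ValueError, match="ramp"):
            _single_group(effect_ramp={0: 0.0, 1: 0.9, 2: 0.8, 3: 1.0, 4: 1.0})
        with pytest.raises(ValueError, match="hours"):
            _single_group(effect_ramp={0: 0.0, 4: 1.0})

    def test_frequency_lists_nonempty_and_increasing(self):
        with pytest.raises(ValueError, match="low_freqs"):
            _single_group(low_freqs=())
        with pytest.raises(ValueError, match="high_freqs"):
            _single_group(high_freqs=(8000, 4000))

    def test_group_mix_bounds(self):
        with pytest.raises(ValueError, match="group_mix"):
            CohortConfig(group_mix=1.2)


class TestGenerateCohort:
    def test_noise_free_cohort_shows_the_exact_effect(self):
        config = _single_group(n_cases=40, sigma_single=0.0, fixed_true_mtr=10, seed=3)
        cases = generate_cohort(config)
        pre = cases.threshold_pivot(0, config.low_freqs)
        post = cases.threshold_pivot(4, config.low_freqs)
        np.testing.assert_array_equal((pre - post).to_numpy(), 10)
        # high frequencies carry no glycerol effect
        pre_h = cases.threshold_pivot(0, config.high_freqs)
        post_h = cases.threshold_pivot(4, config.high_freqs)
        np.testing.assert_array_equal((pre_h - post_h).to_numpy(), 0)
        assert all(s.mtr == 10 for s in mtr_samples(cases))

    def test_same_seed_reproduces_the_cohort(self):
        config = _single_group(n_cases=60, seed=9, bias=BiasParams())
        a, b = generate_cohort(config), generate_cohort(config)
        assert a.equals(b)
        assert a.truth.equals(b.truth)

    def test_thresholds_are_quantized_and_in_range(self):
        cases = generate_cohort(_single_group(n_cases=200, seed=2))
        thr = cases.data["threshold_db"].to_numpy()
        assert np.all(thr % 5 == 0)
        assert thr.min() >= -10 and thr.max() <= 120

    def test_pure_no_effect_truth_stays_in_the_pooled_bins(self):
        config = CohortConfig(
            n_cases=100_000,
            template_params_by_group={"all": TemplateParams(1.0, 3.0)},
            seed=5,
        )
        truth = generate_cohort(config).truth
        assert np.isin(truth["true_mtr"], [-1, 0, 1]).all()

    def test_hidden_truth_follows_the_template(self):
        # chi-square goodness of fit of generated true MTRs at alpha = 0.01
        config = _single_group(n_cases=100_000, seed=17)
        truth = generate_cohort(config).truth
        template = build_template(ALL_PATIENTS)
        counts = np.array(
            [(truth["true_mtr"] == v).sum() for v in template.support], dtype=float
        )
        expected = template.probs * counts.sum()
        keep = expected >= 5.0
        counts = np.append(counts[keep], counts[~keep].sum())
        expected = np.append(expected[keep], expected[~keep].sum())
        stat, pvalue = chisquare(counts, expected)
        assert pvalue > 0.01

    def test_repeat_audiogram_noise_has_the_predicted_spread(self):
        # hours 3 and 4 share ramp = 1, so their MTR is pure estimation noise;
        # its SD must match the discretized-normal reference (5 dB rounding
        # inflates sqrt(2/5)*sigma by a few percent)
        config = _single_group(n_cases=50_000, seed=31)
        values = np.array([s.mtr for s in error_samples(generate_cohort(config))], float)
        sigma = config.sigma_single
        k = np.arange(-100, 101)
        var_rounded = np.sum((5 * k) ** 2 * (norm.cdf((5 * k + 2.5) / sigma) - norm.cdf((5 * k - 2.5) / sigma)))
        ref = np.sqrt(2 * var_rounded / 5)
        assert values.std(ddof=1) == pytest.approx(ref, rel=0.02)
        assert np.sqrt(2 / 5) * sigma == pytest.approx(2.45, abs=0.005)

    def test_biased_generation_reuses_previous_thresholds(self):
        config = _single_group(
            n_cases=4_000, sigma_single=4.43, bias=BiasParams(), seed=23
        )
        biased = np.array([s.mtr for s in error_samples(generate_cohort(config))], float)
        plain = np.array(
            [s.mtr for s in error_samples(generate_cohort(_single_group(
                n_cases=4_000, sigma_single=4.43, seed=23)))], float
        )
        # reuse/shrink rules concentrate retest differences at zero
        assert np.mean(biased == 0) > np.mean(plain == 0)


class TestCasesIO:
    def test_round_trip_preserves_the_case_set(self, tmp_path):
        cases = generate_cohort(_single_group(n_cases=3, seed=1))
        write_cases(cases, tmp_path / "cases.csv", tmp_path / "truth.csv")
        back = read_cases(tmp_path / "cases.csv", tmp_path / "truth.csv")
        assert cases.equals(back)
        assert list(back.truth["true_mtr"]) == list(cases.truth["true_mtr"])

    def test_unquantized_threshold_is_rejected_by_row(self):
        csv = "case_id,ear,hour,freq_hz,threshold_db\nC1,L,0,125,40\nC1,L,0,250,42\n"
        with pytest.raises(CaseDataError, match="row 1.*multiple of 5"):
            read_cases(io.StringIO(csv))

    def test_duplicate_key_is_rejected(self):
        csv = "case_id,ear,hour,freq_hz,threshold_db\nC1,L,0,125,40\nC1,L,0,125,45\n"
        with pytest.raises(CaseDataError, match="duplicate"):
            read_cases(io.StringIO(csv))

    def test_header_only_file_yields_empty_case_set(self):
        cases = read_cases(io.StringIO("case_id,ear,hour,freq_hz,threshold_db\n"))
        assert cases.n_cases == 0

    def test_invalid_ear_and_hour_are_rejected(self):
        with pytest.raises(CaseDataError, match="ear"):
            read_cases(io.StringIO("case_id,ear,hour,freq_hz,threshold_db\nC1,X,0,125,40\n"))
        with pytest.raises(CaseDataError, match="hour"):
            read_cases(io.StringIO("case_id,ear,hour,freq_hz,threshold_db\nC1,L,7,125,40\n"))


class TestConfigLoading:
    def test_yaml_config_round_trip(self, tmp_path):
        doc = """
n_cases: 25
group_mix: 0.4
template_params_by_group:
  good: {p0: 0.244, theta: 5.67}
  poor: {p0: 0.377, theta: 2.71}
sigma_single: 4.43
bias: {sigma_single: 4.43, p_ignore_5: 0.8, p_shrink_10: 0.3}
effect_ramp: {0: 0.0, 1: 0.5, 2: 0.8, 3: 1.0, 4: 1.0}
seed: 12
"""
        path = tmp_path / "cohort.yaml"
        path.write_text(doc)
        config = load_cohort_config(path)
        assert config.n_cases == 25
        assert config.template_params_by_group["good"] == TemplateParams(0.244, 5.67)
        assert config.bias == BiasParams(sigma_single=4.43, p_ignore_5=0.8, p_shrink_10=0.3)
        generate_cohort(config)  # must be a usable configuration
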