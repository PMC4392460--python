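"""Reference parameter values from the retrospective glycerol-test cohort.

These are the fitted template parameters and error characteristics for
the 354-case retrospective cohort of suspected Menière's disease that
motivates this package: per-group (p0, theta) fits of the true-MTR
template, the test-retest MTR error SD estimated from hour-3 vs hour-4
audiograms, the roughly halved SD used to explore methodological
improvements, and the two virtual gold-standard thresholds.  They make
desk-scale reproduction runs possible without the clinical data.
"""

from __future__ import annotations

from .bias_sim import BiasParams
from .hydrops_model import TemplateParams

#: Fitted (p0, theta) per patient group on the retrospective cohort.
REFERENCE_FITS: dict[str, TemplateParams] = {
    "all": TemplateParams(0.378, 3.89),
    "poor": TemplateParams(0.377, 2.71),
    "good": TemplateParams(0.244, 5.67),
}

#: Group sizes of the retrospective cohort.
REFERENCE_GROUP_SIZES: dict[str, int] = {"all": 354, "poor": 229, "good": 125}

#: Test-retest MTR error SD (dB) estimated from hour-3 vs hour-4 audiograms.
REFERENCE_SIGMA = 2.45

#: Hypothetical improved measurement error SD (dB), roughly half the current one.
IMPROVED_SIGMA = 1.2

#: Gold-standard thresholds on the true MTR (dB): default and strong-effect variant.
DEFAULT_TAU = 2.0
STRONG_EFFECT_TAU = 5.0

#: Biased-investigator parameters that reproduce the clinical error histogram.
REFERENCE_BIAS = BiasParams(sigma_single=4.43, p_ignore_5=0.80, p_shrink_10=0.30)
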