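"""From audiograms to analysis quantities.

The glycerol test is read off serial audiograms in three ways:

* the **MTR** (mean threshold reduction) between the pre-test audiogram
  and the hour-4 audiogram — the test statistic proper, positive when
  hearing improved;
* the hour-3 vs hour-4 MTR — since the glycerol effect has saturated by
  hour 3, this pair measures pure test-retest noise and is the
  fingerprint of the measurement error;
* the **good/poor candidate** rule of thumb on the pre-test audiogram: a
  positive test is more likely when the mean low-frequency loss is within
  30–70 dB and not smaller than the mean high-frequency loss.

Because each threshold is a multiple of 5 dB and the MTR averages five of
them, the MTR is always an integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .cases import Audiogram, CaseSet
from .synthetic_data import DEFAULT_HIGH_FREQS, DEFAULT_LOW_FREQS

__all__ = [
    "MtrSample",
    "EmpiricalDistribution",
    "MtrSummary",
    "CandidateRule",
    "compute_mtr",
    "error_samples",
    "mtr_samples",
    "summarize",
    "classify_candidate",
    "candidate_labels",
    "analysis_table",
]

logger = logging.getLogger(__name__)

PRE_VS_HOUR4 = "pre_vs_hour4"
HOUR3_VS_HOUR4 = "hour3_vs_hour4"


@dataclass(frozen=True)
class MtrSample:
    """One MTR value with its provenance (which audiogram pair)."""

    case_id: str
    ear: str
    mtr: int
    comparison: str


def compute_mtr(pre: Audiogram, post: Audiogram, freqs=DEFAULT_LOW_FREQS) -> int:
    """Mean threshold reduction over ``freqs``: mean(pre - post), in dB.

    Positive when hearing improved (post thresholds lower).  With five
    frequencies on the 5 dB grid the mean is exactly integral; a
    non-integral mean (other frequency counts) is rounded to nearest.
    """
    if len(freqs) == 0:
        raise ValueError("freqs must not be empty")
    total = 0
    for f in freqs:
        total += int(pre.threshold_at(f)) - int(post.threshold_at(f))
    mean = Fraction(total, len(freqs))
    return int(mean) if mean.denominator == 1 else int(round(float(mean)))


def _paired_mtr(cases: CaseSet, hour_a: int, hour_b: int, freqs) -> tuple[pd.DataFrame, int]:
    """Per-case MTR = mean(hour_a - hour_b thresholds); skips incomplete cases."""
    a = cases.threshold_pivot(hour_a, freqs)
    b = cases.threshold_pivot(hour_b, freqs)
    common = a.index.intersection(b.index)
    n_skipped = cases.n_cases - len(common)
    mtr = (a.loc[common] - b.loc[common]).mean(axis=1)
    out = mtr.round().astype(int).rename("mtr_db").reset_index()
    return out, n_skipped


def error_samples(cases: CaseSet, freqs=DEFAULT_LOW_FREQS) -> list[MtrSample]:
    """Test-retest MTR samples: hour-3 minus hour-4 thresholds, per case.

    Positive when the hour-4 threshold is lower.  Cases lacking either
    audiogram (or any requested frequency) are skipped with a logged count.
    """
    table, n_skipped = _paired_mtr(cases, 3, 4, freqs)
    if n_skipped:
        logger.info("error_samples: skipped %d case(s) lacking a complete hour-3/hour-4 pair", n_skipped)
    return [
        MtrSample(str(r.case_id), str(r.ear), int(r.mtr_db), HOUR3_VS_HOUR4)
        for r in table.itertuples()
    ]


def mtr_samples(cases: CaseSet, freqs=DEFAULT_LOW_FREQS) -> list[MtrSample]:
    """Clinical MTR samples: pre-test (hour 0) vs hour-4 audiograms."""
    table, n_skipped = _paired_mtr(cases, 0, 4, freqs)
    if n_skipped:
        logger.info("mtr_samples: skipped %d case(s) lacking a complete hour-0/hour-4 pair", n_skipped)
    return [
        MtrSample(str(r.case_id), str(r.ear), int(r.mtr_db), PRE_VS_HOUR4)
        for r in table.itertuples()
    ]


@dataclass(frozen=True)
class EmpiricalDistribution:
    """Empirical pmf/cdf of integer MTR values with summary moments."""

    support: np.ndarray
    pmf: np.ndarray
    cdf: np.ndarray
    n: int
    mean: float
    sd: float

    @classmethod
    def from_samples(cls, values) -> "EmpiricalDistribution":
        x = np.asarray(values, dtype=int)
        if x.size < 2:
            raise ValueError(f"need at least 2 samples, got {x.size}")
        support, counts = np.unique(x, return_counts=True)
        pmf = counts / x.size
        return cls(
            support=support,
            pmf=pmf,
            cdf=np.cumsum(pmf),
            n=int(x.size),
            mean=float(x.mean()),
            sd=float(x.std(ddof=1)),
        )


@dataclass(frozen=True)
class MtrSummary:
    """Descriptives plus a one-sample two-sided t-test of mean = 0.

    ``degenerate`` flags a zero-variance sample, for which the t statistic
    is undefined; the p-value is then reported as 1.
    """

    distribution: EmpiricalDistribution
    t_pvalue: float
    degenerate: bool = False

    @property
    def mean(self) -> float:
        return self.distribution.mean

    @property
    def sd(self) -> float:
        return self.distribution.sd

    @property
    def n(self) -> int:
        return self.distribution.n


def _sample_values(samples) -> np.ndarray:
    if len(samples) and isinstance(samples[0], MtrSample):
        return np.asarray([s.mtr for s in samples], dtype=int)
    return np.asarray(samples, dtype=int)


def summarize(samples) -> MtrSummary:
    """Empirical distribution and t-test for a set of MTR samples."""
    values = _sample_values(samples)
    dist = EmpiricalDistribution.from_samples(values)
    if dist.sd == 0.0:
        logger.warning("summarize: zero-variance sample, t-test degenerate; p reported as 1")
        return MtrSummary(dist, t_pvalue=1.0, degenerate=True)
    res = stats.ttest_1samp(values, popmean=0.0)
    return MtrSummary(dist, t_pvalue=float(res.pvalue), degenerate=False)


@dataclass(frozen=True)
class CandidateRule:
    """Good-candidate rule: mean low-frequency loss in ``low_range`` (both
    bounds inclusive) and not smaller than the mean high-frequency loss."""

    low_freqs: tuple[int, ...] = DEFAULT_LOW_FREQS
    high_freqs: tuple[int, ...] = DEFAULT_HIGH_FREQS
    low_range: tuple[float, float] = (30.0, 70.0)


def classify_candidate(pre: Audiogram, rule: CandidateRule = CandidateRule()) -> str:
    """Classify the pre-test audiogram as ``"good"`` or ``"poor"``."""
    low_mean = pre.mean_over(rule.low_freqs)
    high_mean = pre.mean_over(rule.high_freqs)
    lo, hi = rule.low_range
    good = (lo <= low_mean <= hi) and (low_mean >= high_mean)
    return "good" if good else "poor"


def candidate_labels(cases: CaseSet, rule: CandidateRule = CandidateRule()) -> pd.DataFrame:
    """Vectorized candidate classification of all hour-0 audiograms."""
    low = cases.threshold_pivot(0, rule.low_freqs).mean(axis=1)
    high = cases.threshold_pivot(0, rule.high_freqs).mean(axis=1)
    common = low.index.intersection(high.index)
    lo, hi = rule.low_range
    good = (low.loc[common] >= lo) & (low.loc[common] <= hi) & (low.loc[common] >= high.loc[common])
    out = good.map({True: "good", False: "poor"}).rename("candidate").reset_index()
    return out


def analysis_table(cases: CaseSet, rule: CandidateRule = CandidateRule()) -> pd.DataFrame:
    """Per-case table ``case_id, ear, comparison, mtr_db, candidate``.

    One row per (case, comparison) for the pre-vs-hour-4 and the
    hour-3-vs-hour-4 MTR of every case that has the needed audiograms.
    """
    frames = []
    for comparison, sampler in ((PRE_VS_HOUR4, mtr_samples), (HOUR3_VS_HOUR4, error_samples)):
        rows = sampler(cases, rule.low_freqs)
        if rows:
            frames.append(
                pd.DataFrame(
                    {
                        "case_id": [s.case_id for s in rows],
                        "ear": [s.ear for s in rows],
                        "comparison": comparison,
                        "mtr_db": [s.mtr for s in rows],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["case_id", "ear", "comparison", "mtr_db", "candidate"])
    table = pd.concat(frames, ignore_index=True)
    labels = candidate_labels(cases, rule)
    return table.merge(labels, on=["case_id", "ear"], how="left")
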