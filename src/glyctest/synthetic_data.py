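"""Synthetic glycerol-test cohorts with the statistical structure the
analysis assumes.

The generator emulates the study situation the analysis chain is built
for: each case is one tested ear with a pre-test audiogram and hourly
post-glycerol audiograms up to hour 4.  A latent group ("good" / "poor"
candidate) selects a true-MTR template; the drawn true MTR is applied to
the five low audiometric frequencies with a saturating time course (the
glycerol effect barely intensifies after the third hour), high frequencies
are unaffected, and every recorded threshold is the true value plus an
independent Gaussian estimation error, rounded to 5 dB and clamped to the
audiometer range.  Optionally the partially biased investigator of
:mod:`glyctest.bias_sim` reuses/shrinks small changes relative to the
immediately preceding audiogram.  The hidden truth (group, true MTR) is
retained so recovery tests need no re-inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .bias_sim import BiasParams
from .cases import CASE_COLUMNS, TRUTH_COLUMNS, CaseDataError, CaseSet
from .hydrops_model import TemplateParams, build_template
from .quantize import AUDIOMETER_MAX_DB, AUDIOMETER_MIN_DB, clamp_to_audiometer, round_to_step

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "write_cases",
    "read_cases",
    "load_cohort_config",
    "DEFAULT_LOW_FREQS",
    "DEFAULT_HIGH_FREQS",
]

DEFAULT_LOW_FREQS = (125, 250, 500, 1000, 1500)
DEFAULT_HIGH_FREQS = (2000, 3000, 4000, 6000, 8000)

# Study-scale defaults: 354 cases, of which 125 satisfied the good-candidate
# rule of thumb; per-group templates as fitted on that cohort; unbiased
# per-threshold SD chosen so the MTR-scale error SD is 2.45 dB.
_DEFAULT_GROUPS: Mapping[str, TemplateParams] = {
    "good": TemplateParams(0.244, 5.67),
    "poor": TemplateParams(0.377, 2.71),
}
_DEFAULT_RAMP: Mapping[int, float] = {0: 0.0, 1: 0.5, 2: 0.8, 3: 1.0, 4: 1.0}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``group_mix`` is the proportion of cases assigned to the "good"
    candidate group (latent template selector).  ``sigma_single`` is the
    SD in dB of one threshold estimation; 0 disables noise entirely.
    ``effect_ramp`` maps hour to the fraction of the true MTR realized at
    that hour; it must be non-decreasing with ramp(0)=0 and ramp(4)=1.
    ``fixed_true_mtr`` overrides the template draw with a constant
    (validation scenarios).
    """

    n_cases: int = 354
    group_mix: float = 125 / 354
    template_params_by_group: Mapping[str, TemplateParams] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )
    sigma_single: float = 2.45 * math.sqrt(2.5)
    bias: BiasParams | None = None
    low_freqs: tuple[int, ...] = DEFAULT_LOW_FREQS
    high_freqs: tuple[int, ...] = DEFAULT_HIGH_FREQS
    baseline_low_range: tuple[float, float] = (20.0, 80.0)
    baseline_high_range: tuple[float, float] = (10.0, 70.0)
    effect_ramp: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_RAMP))
    fixed_true_mtr: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be >= 1, got {self.n_cases}")
        if not 0.0 <= self.group_mix <= 1.0:
            raise ValueError(f"group_mix must be in [0, 1], got {self.group_mix}")
        if not self.template_params_by_group:
            raise ValueError("template_params_by_group must not be empty")
        if self.sigma_single < 0:
            raise ValueError(f"sigma_single must be >= 0, got {self.sigma_single}")
        for name in ("low_freqs", "high_freqs"):
            freqs = getattr(self, name)
            if len(freqs) == 0:
                raise ValueError(f"{name} must not be empty")
            if any(b <= a for a, b in zip(freqs, freqs[1:])):
                raise ValueError(f"{name} must be strictly increasing, got {freqs}")
        for name in ("baseline_low_range", "baseline_high_range"):
            lo, hi = getattr(self, name)
            if not (AUDIOMETER_MIN_DB <= lo <= hi <= AUDIOMETER_MAX_DB):
                raise ValueError(f"{name} must be an ordered dB interval within the audiometer range")
        hours = sorted(self.effect_ramp)
        if hours != [0, 1, 2, 3, 4]:
            raise ValueError(f"effect_ramp must cover hours 0..4, got {hours}")
        vals = [self.effect_ramp[h] for h in hours]
        if vals[0] != 0.0 or vals[-1] != 1.0:
            raise ValueError("effect_ramp must have ramp(0)=0 and ramp(4)=1")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"effect_ramp must be non-decreasing, got {vals}")


def _group_labels(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    groups = sorted(config.template_params_by_group)
    if len(groups) == 1:
        return np.full(config.n_cases, groups[0], dtype=object)
    if set(groups) != {"good", "poor"}:
        raise ValueError(
            "template_params_by_group must have a single group or exactly the groups "
            f"'good' and 'poor', got {groups}"
        )
    is_good = rng.random(config.n_cases) < config.group_mix
    return np.where(is_good, "good", "poor").astype(object)


def generate_cohort(config: CohortConfig) -> CaseSet:
    """Generate a cohort; deterministic given ``config`` (including its seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    hours = np.array(sorted(config.effect_ramp))
    ramp = np.array([config.effect_ramp[h] for h in hours])
    low = np.asarray(config.low_freqs)
    high = np.asarray(config.high_freqs)
    freqs = np.concatenate([low, high])
    is_low = np.concatenate([np.ones(low.size, bool), np.zeros(high.size, bool)])

    groups = _group_labels(config, rng)
    true_mtr = np.zeros(n, dtype=int)
    if config.fixed_true_mtr is not None:
        true_mtr[:] = int(config.fixed_true_mtr)
    else:
        for g, params in sorted(config.template_params_by_group.items()):
            mask = groups == g
            if mask.any():
                true_mtr[mask] = build_template(params).sample(int(mask.sum()), rng)

    lo, hi = config.baseline_low_range
    baseline = np.empty((n, freqs.size))
    baseline[:, is_low] = round_to_step(rng.uniform(lo, hi, (n, int(is_low.sum()))))
    lo, hi = config.baseline_high_range
    baseline[:, ~is_low] = round_to_step(rng.uniform(lo, hi, (n, int((~is_low).sum()))))

    # true threshold (case, hour, freq): baseline minus the ramped effect at low freqs
    effect = ramp[None, :, None] * true_mtr[:, None, None] * is_low[None, None, :]
    true_thr = baseline[:, None, :] - effect
    noise = (
        rng.normal(0.0, config.sigma_single, true_thr.shape)
        if config.sigma_single > 0
        else np.zeros_like(true_thr)
    )
    recorded = clamp_to_audiometer(round_to_step(true_thr + noise))

    if config.bias is not None:
        b = config.bias
        for t in range(1, hours.size):
            d = recorded[:, t, :] - recorded[:, t - 1, :]
            u = rng.random(d.shape)
            reuse = (np.abs(d) == b.step) & (u < b.p_ignore_5)
            shrink = (np.abs(d) == 2 * b.step) & (u < b.p_shrink_10)
            recorded[:, t, :] = np.where(
                reuse,
                recorded[:, t - 1, :],
                np.where(shrink, recorded[:, t - 1, :] + np.sign(d) * b.step, recorded[:, t, :]),
            )

    width = max(4, len(str(n)))
    ids = np.array([f"C{i:0{width}d}" for i in range(1, n + 1)], dtype=object)
    data = pd.DataFrame(
        {
            "case_id": np.repeat(ids, hours.size * freqs.size),
            "ear": "L",
            "hour": np.tile(np.repeat(hours, freqs.size), n).astype(np.int8),
            "freq_hz": np.tile(freqs, n * hours.size).astype(np.int32),
            "threshold_db": recorded.reshape(-1).astype(np.int16),
        }
    )
    truth = pd.DataFrame(
        {"case_id": ids, "ear": "L", "true_mtr": true_mtr, "group": groups}
    )
    truth["true_baseline_low_mean"] = baseline[:, is_low].mean(axis=1)
    return CaseSet(data, truth)


def write_cases(cases: CaseSet, destination, truth_destination=None) -> None:
    """Write the canonical case CSV (and, optionally, the truth sidecar CSV)."""
    cases.data.to_csv(destination, index=False, columns=CASE_COLUMNS)
    if truth_destination is not None:
        if cases.truth is None:
            raise ValueError("case set has no hidden truth to write")
        cases.truth.to_csv(truth_destination, index=False, columns=TRUTH_COLUMNS)


def read_cases(source, truth_source=None) -> CaseSet:
    """Read the canonical case CSV; validation errors name the offending row."""
    try:
        data = pd.read_csv(source, dtype={"case_id": str, "ear": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise CaseDataError(f"cannot parse case CSV {source}: {exc}") from exc
    truth = None
    if truth_source is not None:
        truth = pd.read_csv(truth_source, dtype={"case_id": str, "ear": str, "group": str})
    return CaseSet(data, truth)


def _coerce_config(doc: dict) -> CohortConfig:
    doc = dict(doc)
    if "template_params_by_group" in doc:
        doc["template_params_by_group"] = {
            g: p if isinstance(p, TemplateParams) else TemplateParams(**p)
            for g, p in doc["template_params_by_group"].items()
        }
    if doc.get("bias") is not None and not isinstance(doc["bias"], BiasParams):
        doc["bias"] = BiasParams(**doc["bias"])
    if "effect_ramp" in doc:
        doc["effect_ramp"] = {int(h): float(v) for h, v in doc["effect_ramp"].items()}
    for name in ("low_freqs", "high_freqs", "baseline_low_range", "baseline_high_range"):
        if name in doc:
            doc[name] = tuple(doc[name])
    return CohortConfig(**doc)


def load_cohort_config(path) -> CohortConfig:
    """Load a cohort configuration from a YAML or JSON document."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping of CohortConfig fields")
    return _coerce_config(doc)
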