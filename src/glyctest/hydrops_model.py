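"""Generative model for the glycerol-induced true mean threshold reduction.

The glycerol test probes whether a hydropic inner ear is partially
reversible: oral glycerol dehydrates the endolymphatic compartment and a
transient hearing improvement a few hours later counts as a positive
result.  The test statistic is the mean threshold reduction (MTR), the mean
improvement in dB across the five lowest audiometric frequencies between a
pre-test audiogram and one taken four hours after intake.  Because
thresholds are measured in 5 dB steps, the MTR is always an integer.

The population is modelled as a two-component mixture:

* a fraction ``p0`` of patients shows no glycerol-induced effect at all
  (a point mass at zero true MTR);
* the remaining ``1 - p0`` show a true MTR distributed as a *flattened*
  gamma distribution with shape 2 and scale ``theta``: the rising flank of
  the gamma density on ``[0, theta]`` is replaced by a constant plateau at
  the density's maximum, and the result is renormalized.  The plateau
  height is ``1/(3*theta)`` and exactly one third of the responder mass
  lies below ``theta``.

The continuous mixture is discretized to the integer MTR lattice by bin
integration, and all mass at MTR <= 1 dB (the point mass plus the first
two responder bins) is pooled and spread equally over {-1, 0, 1} dB: on
real data "no effect" and "almost no effect" are indistinguishable, and the
equal split visualizes the pooled group without a towering spike at zero.

What is actually observed is the true MTR plus an audiometric measurement
error, taken to be zero-mean Gaussian with standard deviation ``sigma`` on
the MTR scale.  The observed integer-MTR distribution is therefore the
discrete template convolved with the Gaussian kernel, evaluated by bin
integration so that the model lives on the same integer lattice as data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import ndtr
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "TemplateParams",
    "TrueMtrTemplate",
    "ErrorModel",
    "ObservedMtrDistribution",
    "gamma2_pdf",
    "flattened_pdf",
    "flattened_cdf",
    "build_template",
    "convolve_with_error",
    "model_cdf_on_grid",
]

_E = math.e
# CDF of the shape-2 gamma at its mode x = theta: 1 - 2/e, independent of theta.
_GAMMA2_CDF_AT_MODE = 1.0 - 2.0 / _E


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not theta > 0.0:
        raise ValueError(f"scale parameter theta must be > 0, got {theta}")
    return theta


@dataclass(frozen=True)
class TemplateParams:
    """Parameters of the true-MTR template.

    Parameters
    ----------
    p0 : float
        Proportion of patients without any glycerol-induced threshold
        reduction, in [0, 1].
    theta : float
        Scale parameter (dB) of the flattened shape-2 gamma distribution
        describing effect sizes among responders; strictly positive.
    """

    p0: float
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        _check_theta(self.theta)


@dataclass(frozen=True)
class ErrorModel:
    """Zero-mean Gaussian measurement error on the MTR scale, SD in dB."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def gamma2_pdf(x, theta: float):
    """Density of the gamma distribution with shape 2 and scale ``theta``.

    ``x * exp(-x/theta) / theta**2`` for ``x >= 0`` and 0 below; the mode
    sits at ``x = theta``.
    """
    theta = _check_theta(theta)
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0.0, x * np.exp(-np.minimum(x, 700 * theta) / theta) / theta**2, 0.0)
    return float(out) if out.ndim == 0 else out


def flattened_pdf(x, theta: float):
    """Flattened shape-2 gamma density: constant on [0, theta], gamma tail.

    The unnormalized plateau (at the gamma's maximum ``e**-1 / theta``)
    carries mass ``e**-1`` and the tail carries ``2 e**-1``; renormalizing
    by ``3 e**-1`` gives plateau height ``1/(3 theta)`` and tail
    ``x * exp(1 - x/theta) / (3 theta**2)``.
    """
    theta = _check_theta(theta)
    x = np.asarray(x, dtype=float)
    plateau = 1.0 / (3.0 * theta)
    tail = gamma2_pdf(x, theta) * (_E / 3.0)
    out = np.where(x < 0.0, 0.0, np.where(x <= theta, plateau, tail))
    return float(out) if out.ndim == 0 else out


def flattened_cdf(x, theta: float):
    """CDF of :func:`flattened_pdf`; ``P(X <= theta) = 1/3`` exactly."""
    theta = _check_theta(theta)
    x = np.asarray(x, dtype=float)
    tail_cdf = 1.0 / 3.0 + (_E / 3.0) * (
        _gamma_dist.cdf(np.maximum(x, theta), a=2.0, scale=theta) - _GAMMA2_CDF_AT_MODE
    )
    out = np.where(x < 0.0, 0.0, np.where(x <= theta, np.maximum(x, 0.0) / (3.0 * theta), tail_cdf))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TrueMtrTemplate:
    """Discrete probability mass function of the error-free ("true") MTR.

    ``support`` is an increasing integer array (minimum -1 for templates
    built from :class:`TemplateParams`), ``probs`` the matching masses.
    """

    support: np.ndarray
    probs: np.ndarray
    params: TemplateParams | None = None

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)
        if support.shape != probs.shape or support.ndim != 1:
            raise ValueError("support and probs must be matching 1-d arrays")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(probs < -1e-15):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {probs.sum()!r}")

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.probs)

    def mean(self) -> float:
        return float(np.sum(self.support * self.probs))

    def variance(self) -> float:
        m = self.mean()
        return float(np.sum((self.support - m) ** 2 * self.probs))

    def prob_at_most(self, value: float) -> float:
        """Total mass on support values <= ``value``."""
        return float(self.probs[self.support <= value].sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` true MTR values (integers)."""
        return rng.choice(self.support, size=int(n), p=self.probs)

    def to_dict(self) -> dict:
        d = {"support": self.support.tolist(), "probs": self.probs.tolist()}
        if self.params is not None:
            d["params"] = {"p0": self.params.p0, "theta": self.params.theta}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrueMtrTemplate":
        params = None
        if d.get("params") is not None:
            params = TemplateParams(**d["params"])
        return cls(np.asarray(d["support"]), np.asarray(d["probs"]), params)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "TrueMtrTemplate":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_template(params: TemplateParams, tail_tol: float = 1e-9) -> TrueMtrTemplate:
    """Discretize the two-component mixture onto the integer MTR lattice.

    Integer ``n >= 2`` receives ``(1 - p0)`` times the flattened-gamma mass
    of the bin ``[n - 1/2, n + 1/2)``; the point mass ``p0`` plus the
    responder mass below 1.5 dB is pooled and spread equally over
    {-1, 0, 1}.  The support is truncated where the cumulative mass reaches
    ``1 - tail_tol`` and the masses renormalized to sum exactly to 1.
    """
    p0, theta = params.p0, params.theta
    w = 1.0 - p0

    n_max = 1
    if w * (1.0 - flattened_cdf(1.5, theta)) > tail_tol:
        hi = max(4, int(math.ceil(2 * theta)))
        while w * (1.0 - flattened_cdf(hi + 0.5, theta)) > tail_tol:
            hi *= 2
        ns = np.arange(2, hi + 1)
        surv = w * (1.0 - flattened_cdf(ns + 0.5, theta))
        n_max = int(ns[np.argmax(surv <= tail_tol)])

    support = np.arange(-1, n_max + 1)
    probs = np.zeros(support.size)
    pooled = p0 + w * flattened_cdf(1.5, theta)
    probs[:3] = pooled / 3.0
    if n_max >= 2:
        edges = np.arange(2, n_max + 2) - 0.5  # 1.5, 2.5, ..., n_max + 0.5
        cdf_edges = flattened_cdf(edges, theta)
        probs[3:] = w * np.diff(cdf_edges)
    probs /= probs.sum()
    return TrueMtrTemplate(support, probs, params)


@dataclass(frozen=True)
class ObservedMtrDistribution:
    """Model distribution of the observed (error-contaminated) integer MTR."""

    support: np.ndarray
    pmf: np.ndarray
    cdf: np.ndarray

    def mean(self) -> float:
        return float(np.sum(self.support * self.pmf))

    def variance(self) -> float:
        m = self.mean()
        return float(np.sum((self.support - m) ** 2 * self.pmf))

    def cdf_at(self, values) -> np.ndarray:
        """CDF evaluated at arbitrary integer points (0 left of support, 1 right)."""
        idx = np.searchsorted(self.support, np.asarray(values), side="right")
        padded = np.concatenate([[0.0], self.cdf])
        return padded[idx]

    def to_dict(self) -> dict:
        return {"support": self.support.tolist(), "pmf": self.pmf.tolist()}


def convolve_with_error(
    template: TrueMtrTemplate, err: ErrorModel
) -> ObservedMtrDistribution:
    """Convolve the discrete template with the Gaussian error, bin-integrated.

    Observed integer ``m`` receives
    ``sum_n P(n) * [Phi((m + 1/2 - n)/sigma) - Phi((m - 1/2 - n)/sigma)]``.
    The support spans the template support padded by ``ceil(6 sigma) + 1``,
    which keeps the truncated mass below 1e-9 for any sigma.
    """
    sigma = err.sigma
    pad = int(math.ceil(6.0 * sigma)) + 1
    m = np.arange(int(template.support.min()) - pad, int(template.support.max()) + pad + 1)
    edges = np.concatenate([m - 0.5, [m[-1] + 0.5]])
    z = (edges[:, None] - template.support[None, :]) / sigma
    cdf_edges = ndtr(z) @ template.probs
    pmf = np.diff(cdf_edges)
    return ObservedMtrDistribution(m, pmf, np.cumsum(pmf))


def model_cdf_on_grid(template: TrueMtrTemplate, sigma: float, grid) -> np.ndarray:
    """Observed-model CDF at integer grid points, without support truncation.

    ``F(m) = sum_n P(n) * Phi((m + 1/2 - n)/sigma)`` — the probability that
    a noise-contaminated value rounds to at most ``m``.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] + 0.5 - template.support[None, :]) / sigma
    return ndtr(z) @ template.probs
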