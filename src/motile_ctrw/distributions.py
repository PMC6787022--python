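"""Jump-length and waiting-time distribution families.

Motile bacteria of the kind analysed here make runs whose lengths peak
around a few µm but extend to ~100 µm, and pause for waiting periods
whose tails exceed 200 s — both far heavier-tailed than Gaussian.  This
module provides the named families used by the synthetic generator
(lognormal, truncated Pareto, exponential, uniform, and a degenerate
point mass), all with an optional hard upper truncation, plus the
Gaussian-copula machinery that injects a controlled lag-1 Pearson
correlation between successive samples.

The copula correlation is *calibrated*: for a non-Gaussian marginal the
latent Gaussian correlation rho does not equal the Pearson correlation of
the transformed samples, so the requested correlation is mapped to the
latent rho by Gauss–Hermite quadrature and root finding.  The value a
user asks for is therefore the value a sample estimate converges to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

__all__ = ["DistributionSpec", "TruncatedDistribution", "CorrelatedSampler"]

_FAMILIES = ("lognormal", "truncpareto", "exponential", "uniform", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """A named positive-support distribution with optional hard maximum.

    Parameters by family (all lengths in µm or times in s):

    - ``lognormal``: ``mu``, ``sigma`` of log-values, or ``mode`` with
      ``sigma`` (mode = exp(mu - sigma^2));
    - ``truncpareto``: ``b`` (tail exponent), ``lower`` (scale x_m),
      ``upper`` (hard maximum, required);
    - ``exponential``: ``scale``;
    - ``uniform``: ``lo``, ``hi``;
    - ``fixed``: ``value`` (degenerate point mass).

    ``upper`` truncates any family from above (inverse-CDF truncation,
    so samples never exceed it).
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {_FAMILIES}"
            )

    def build(self) -> "TruncatedDistribution":
        return TruncatedDistribution(self)


def _frozen(spec: DistributionSpec):
    p = dict(spec.params)
    if spec.family == "lognormal":
        sigma = float(p["sigma"])
        if "mu" in p:
            mu = float(p["mu"])
        elif "mode" in p:
            mu = np.log(float(p["mode"])) + sigma**2
        else:
            raise ValueError("lognormal needs 'mu' or 'mode'")
        return stats.lognorm(s=sigma, scale=np.exp(mu))
    if spec.family == "truncpareto":
        lower = float(p["lower"])
        upper = float(p["upper"] if "upper" in p else spec.upper)
        if not upper > lower > 0:
            raise ValueError("truncpareto needs 0 < lower < upper")
        return stats.truncpareto(b=float(p["b"]), c=upper / lower, scale=lower)
    if spec.family == "exponential":
        return stats.expon(scale=float(p["scale"]))
    if spec.family == "uniform":
        lo, hi = float(p["lo"]), float(p["hi"])
        return stats.uniform(loc=lo, scale=hi - lo)
    raise AssertionError(spec.family)


class TruncatedDistribution:
    """A frozen distribution with inverse-CDF upper truncation.

    Exposes ``ppf`` on the truncated scale, moments computed under the
    truncation, and i.i.d. sampling.  ``fixed`` specs are degenerate
    point masses (zero variance).
    """

    def __init__(self, spec: DistributionSpec):
        self.spec = spec
        self.is_degenerate = spec.family == "fixed"
        if self.is_degenerate:
            self._value = float(spec.params["value"])
            if self._value <= 0:
                raise ValueError("fixed value must be positive")
            self._f_upper = 1.0
        else:
            self._dist = _frozen(spec)
            self._f_upper = (
                1.0 if spec.upper is None else float(self._dist.cdf(spec.upper))
            )
            if self._f_upper <= 0:
                raise ValueError("upper truncation leaves zero mass")

    # -- inverse CDF on the truncated distribution -------------------------
    def ppf(self, u):
        # clip away the exact endpoints so unbounded families stay finite
        u = np.clip(np.asarray(u, dtype=float), 1e-300, 1.0 - 1e-16)
        if self.is_degenerate:
            return np.full_like(u, self._value)
        return self._dist.ppf(u * self._f_upper)

    def rvs(self, size, rng: np.random.Generator):
        return self.ppf(rng.uniform(size=size))

    @property
    def upper(self) -> float | None:
        return self.spec.upper

    # -- truncated moments via Gauss–Legendre on the unit interval ---------
    def _quad_moments(self, n: int = 400) -> tuple[float, float]:
        if self.is_degenerate:
            return self._value, 0.0
        nodes, weights = np.polynomial.legendre.leggauss(n)
        u = 0.5 * (nodes + 1.0)
        w = 0.5 * weights
        x = self.ppf(u)
        mean = float(np.sum(w * x))
        var = float(np.sum(w * (x - mean) ** 2))
        return mean, max(var, 0.0)

    def mean(self) -> float:
        return self._quad_moments()[0]

    def std(self) -> float:
        return float(np.sqrt(self._quad_moments()[1]))


class CorrelatedSampler:
    """Lag-1 Gaussian-copula sampler for a truncated marginal.

    Successive latent normals follow an AR(1) chain ``z[n+1] = rho*z[n] +
    sqrt(1-rho^2)*eta`` and are pushed through ``F^{-1}(Phi(z))``.  The
    latent ``rho`` is calibrated so that the *Pearson* lag-1 correlation
    of the output chain equals ``target_corr``; with ``target_corr=0``
    samples are i.i.d.
    """

    def __init__(self, dist: TruncatedDistribution, target_corr: float = 0.0):
        if not -1.0 < target_corr < 1.0:
            raise ValueError("correlation must lie in (-1, 1)")
        self.dist = dist
        self.target_corr = float(target_corr)
        if dist.is_degenerate or target_corr == 0.0:
            self.rho = 0.0
        else:
            self.rho = _calibrate_rho(dist, self.target_corr)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.sample_chain(n, rng)[0]

    def sample_chain(
        self, n: int, rng: np.random.Generator, z0: float | None = None
    ) -> tuple[np.ndarray, float]:
        """Draw ``n`` chain values, optionally continuing from latent ``z0``.

        Returns the values and the final latent normal so a chain can be
        extended without breaking its correlation structure.
        """
        if self.rho == 0.0:
            return self.dist.rvs(n, rng), 0.0
        z = np.empty(n)
        prev = rng.standard_normal() if z0 is None else z0
        scale = np.sqrt(1.0 - self.rho**2)
        if z0 is None:
            z[0] = prev
            start = 1
        else:
            start = 0
        innov = rng.standard_normal(n) * scale
        for i in range(start, n):
            prev = self.rho * prev + innov[i]
            z[i] = prev
        return self.dist.ppf(ndtr(z)), float(z[-1])


def _calibrate_rho(
    dist: TruncatedDistribution, target: float, n_nodes: int = 80
) -> float:
    """Latent Gaussian rho achieving a given Pearson correlation.

    Uses probabilists' Gauss–Hermite quadrature for
    E[q(Z1) q(rho Z1 + sqrt(1-rho^2) Z2)] with q = F^{-1} o Phi, then
    solves corr(rho) = target by bisection (corr is increasing in rho).
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / np.sqrt(2.0 * np.pi)
    q = dist.ppf(ndtr(nodes))
    mu = float(np.sum(w * q))
    var = float(np.sum(w * (q - mu) ** 2))
    if var <= 0:
        raise ValueError("cannot correlate a zero-variance distribution")

    z1 = nodes[:, None]
    z2 = nodes[None, :]
    w2 = w[:, None] * w[None, :]

    def corr_of(rho: float) -> float:
        q2 = dist.ppf(ndtr(rho * z1 + np.sqrt(1.0 - rho**2) * z2))
        exy = float(np.sum(w2 * q[:, None] * q2))
        return (exy - mu**2) / var

    lo, hi = -0.9999, 0.9999
    c_lo, c_hi = corr_of(lo), corr_of(hi)
    if not c_lo <= target <= c_hi:
        raise ValueError(
            f"target correlation {target} outside achievable range "
            f"[{c_lo:.3f}, {c_hi:.3f}] for this marginal"
        )
    return float(optimize.brentq(lambda r: corr_of(r) - target, lo, hi, xtol=1e-6))
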