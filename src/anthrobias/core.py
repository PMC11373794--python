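"""Normal-distribution prevalence math.

Anthropometric prevalence indicators (stunting, wasting, underweight) are
defined as the proportion of children whose z-score falls below a threshold,
conventionally -2.0.  For a normal z-score distribution with mean ``mu`` and
standard deviation ``sigma`` that proportion has the closed form

    P[Z < T] = Phi((T - mu) / sigma)

where ``Phi`` is the standard normal CDF.  This module provides that closed
form, a seeded Monte Carlo sampler, and the empirical prevalence counter the
rest of the package builds on.

Conventions
-----------
* Prevalences are proportions in [0, 1]; percentages appear only in
  display/CLI layers.
* "Below threshold" is strict (``z < T``); ties at exactly the threshold
  count as not-below.  Ties are measure-zero for continuous draws, and the
  fixed convention keeps the empirical counter deterministic.
* All random draws come from :class:`numpy.random.Generator` seeded with
  PCG64; the generator name is recorded in Monte Carlo metadata so results
  can be reproduced across runs and machines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .exceptions import InvalidInputError, InvalidParameterError

#: default indicator threshold in z-score units
DEFAULT_THRESHOLD: float = -2.0

#: bit-generator recorded in Monte Carlo metadata
RNG_ALGORITHM: str = "PCG64"


@dataclass(frozen=True)
class NormalParams:
    """Mean and standard deviation of a z-score distribution.

    Parameters
    ----------
    mean : float
        Distribution mean in z-score units.
    sd : float
        Distribution standard deviation in z-score units; strictly positive.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and math.isfinite(self.sd)):
            raise InvalidParameterError(
                f"mean and sd must be finite, got mean={self.mean}, sd={self.sd}"
            )
        if self.sd <= 0:
            raise InvalidParameterError(f"sd must be strictly positive, got {self.sd}")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Proportion of a distribution below a threshold.

    ``mc_standard_error`` and ``n_samples`` are present exactly when the
    estimate came from Monte Carlo counting; the closed form is exact and
    carries neither.
    """

    value: float
    method: str  # "closed_form" | "monte_carlo"
    threshold: float
    n_samples: Optional[int] = None
    mc_standard_error: Optional[float] = None
    rng_algorithm: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise InvalidParameterError(f"prevalence must lie in [0,1], got {self.value}")
        if self.method not in ("closed_form", "monte_carlo"):
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if (self.method == "monte_carlo") != (self.mc_standard_error is not None):
            raise InvalidParameterError(
                "mc_standard_error must be present iff method='monte_carlo'"
            )


def prevalence_closed_form(
    params: NormalParams, threshold: float = DEFAULT_THRESHOLD
) -> PrevalenceEstimate:
    """Exact prevalence below ``threshold`` for a normal distribution.

    Returns ``Phi((threshold - mean) / sd)``.  Deterministic; used as the
    default engine everywhere a figure-level number is needed, with Monte
    Carlo retained as the simulation-faithful mode.
    """
    if not math.isfinite(threshold):
        raise InvalidParameterError(f"threshold must be finite, got {threshold}")
    value = float(norm.cdf((threshold - params.mean) / params.sd))
    return PrevalenceEstimate(value=value, method="closed_form", threshold=threshold)


def simulate_normal(params: NormalParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` observations from Normal(mean, sd^2).

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; the same
    seed always yields the identical sample (PCG64 stream).
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rng = np.random.Generator(np.random.PCG64(seed))
    return rng.normal(params.mean, params.sd, size=int(n))


def prevalence_empirical(
    samples: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> PrevalenceEstimate:
    """Fraction of samples strictly below ``threshold``.

    The Monte Carlo standard error is the binomial ``sqrt(p(1-p)/n)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise InvalidInputError("cannot compute prevalence of an empty sample")
    n = samples.size
    p = float(np.count_nonzero(samples < threshold)) / n
    se = math.sqrt(p * (1.0 - p) / n)
    return PrevalenceEstimate(
        value=p,
        method="monte_carlo",
        threshold=threshold,
        n_samples=n,
        mc_standard_error=se,
        rng_algorithm=RNG_ALGORITHM,
    )
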