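"""Log-scale Gaussian class components and their binormal superposition.

The model underlying the whole package: a continuous classifier variable
(e.g. serum PSA) is log-transformed, and its population distribution is
treated as the superposition of two Gaussian densities — one for the
negative (non-diseased) class with parameters ``(mu1, sigma1)`` and one for
the positive (diseased) class with ``(mu2, sigma2)`` — mixed with prior
probability ``pr`` of the positive class and an overall scale factor ``a``
that maps a probability density onto relative-frequency bin heights:

    y(x) = a*(1-pr)/sigma1 * phi((x-mu1)/sigma1)
         + a*pr/sigma2     * phi((x-mu2)/sigma2)

Everything in this module lives on the natural-log scale of the original
variable; conversion back to original units (exponentiation of quantiles)
happens only at the reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NormalComponent",
    "BinormalMixture",
    "normal_pdf",
    "normal_cdf",
    "mixture_density",
]


@dataclass(frozen=True)
class NormalComponent:
    """One class-conditional Gaussian on the log scale.

    Parameters
    ----------
    mu : float
        Mean of the log-transformed variable.
    sigma : float
        Standard deviation of the log-transformed variable; must be > 0.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be a positive finite number, got {self.sigma}")

    def pdf(self, x):
        return normal_pdf(x, self)

    def cdf(self, x):
        return normal_cdf(x, self)


@dataclass(frozen=True)
class BinormalMixture:
    """Two-component Gaussian mixture with prior ``pr`` and scale ``a``.

    ``neg`` is the negative-class (lower-mean) component, ``pos`` the
    positive-class component. The component weights ``1 - pr`` and ``pr``
    sum to one; ``a`` rescales the probability density to the units of a
    relative-frequency histogram (``a`` is the integral of the curve over
    the whole real line). The general n-component superposition
    ``F(x) = A * sum_i pr_i f_i(x)`` specializes to this type for n = 2;
    only the two-component case is fit and reported.
    """

    neg: NormalComponent
    pos: NormalComponent
    pr: float
    a: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pr <= 1.0:
            raise ValueError(f"pr must lie in [0, 1], got {self.pr}")
        if not (self.a >= 0 and math.isfinite(self.a)):
            raise ValueError(f"a must be finite and >= 0, got {self.a}")

    def density(self, x):
        return mixture_density(x, self)

    def ordered(self) -> "BinormalMixture":
        """Return the equivalent mixture with ``neg.mu <= pos.mu``.

        The superposition is invariant under swapping the components
        together with ``pr <-> 1 - pr``; the diseased component is the one
        sitting higher on the log scale, so fits are relabelled through
        this method.
        """
        if self.neg.mu <= self.pos.mu:
            return self
        return BinormalMixture(neg=self.pos, pos=self.neg, pr=1.0 - self.pr, a=self.a)


def _check_finite(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    return arr


def normal_pdf(x, comp: NormalComponent):
    """Gaussian density (1/sigma) * phi((x - mu)/sigma) at log-value(s) x."""
    arr = _check_finite(x)
    out = stats.norm.pdf(arr, loc=comp.mu, scale=comp.sigma)
    return float(out) if np.isscalar(x) else out


def normal_cdf(x, comp: NormalComponent):
    """Gaussian cumulative probability Phi((x - mu)/sigma), erf-based."""
    arr = _check_finite(x)
    out = stats.norm.cdf(arr, loc=comp.mu, scale=comp.sigma)
    return float(out) if np.isscalar(x) else out


def mixture_density(x, mix: BinormalMixture):
    """Binormal superposition a*[(1-pr) f_neg(x) + pr f_pos(x)].

    Integrates to ``a`` over the real line; with ``pr`` at 0 or 1 it
    collapses exactly to a single scaled component.
    """
    arr = _check_finite(x)
    out = mix.a * (
        (1.0 - mix.pr) * stats.norm.pdf(arr, mix.neg.mu, mix.neg.sigma)
        + mix.pr * stats.norm.pdf(arr, mix.pos.mu, mix.pos.sigma)
    )
    return float(out) if np.isscalar(x) else out
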