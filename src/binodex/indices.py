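"""Diagnostic-test performance indices derived analytically from the fit.

Once the class-conditional Gaussians are in hand, every standard index of a
continuous binary classifier follows in closed form. For a log-scale
cut-off t:

    Se(t) = 1 - Phi((t - mu2)/sigma2)      true-positive rate
    Sp(t) = Phi((t - mu1)/sigma1)          true-negative rate

The ROC curve is the locus of (1-Sp, Se) as t sweeps the value range; its
area has the binormal closed form Phi((mu2-mu1)/sqrt(sigma1^2+sigma2^2)).
Predictive values follow from Bayes' theorem with the fitted prevalence,
likelihood ratios from ratios of tail masses or densities, and the
reference range of the healthy class is exp(mu1 -/+ 1.96 sigma1).

The optimal cut-off comes from the density-crossing condition: Youden's
index Se + Sp - 1 is maximized where the two class densities are equal,
and the cost-weighted rule generalizes this to LR(t) = (1-pr)/(C*pr),
the first-order condition of minimizing the expected misclassification
cost C*pr*(1-Se) + (1-pr)*(1-Sp), where C = cost(FN)/cost(FP). Both reduce
to a quadratic in t from equating log-densities; the admissible root is
the one between the two means, with a bisection fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

from .distributions import BinormalMixture, NormalComponent

__all__ = [
    "IndexReport",
    "RocCurve",
    "sensitivity",
    "specificity",
    "roc_curve",
    "auc",
    "optimal_cutoff",
    "reference_range",
    "predictive_values",
    "likelihood_ratios",
    "interval_lr",
    "point_lr",
    "posterior_probability",
    "compute_report",
]

ROC_GRID_SIZE = 512
ROC_SPAN_SIGMAS = 6.0


@dataclass(frozen=True)
class RocCurve:
    """Discrete ROC: thresholds (log scale, increasing) with per-threshold
    false-positive rate 1-Sp and true-positive rate Se (both decreasing)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass(frozen=True)
class IndexReport:
    """Every index for one stratum at one cut-off, in reporting units.

    Proportions are carried at full precision; cut-off and reference
    limits are given both on the log scale and back-transformed to the
    original measurement units.
    """

    cutoff_log: float
    cutoff_raw: float
    se: float
    sp: float
    youden: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    auc: float
    prevalence: float
    ref_low: float
    ref_high: float
    p95: float
    cost_ratio: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def sensitivity(t, pos: NormalComponent):
    """Se(t) = 1 - Phi((t - mu2)/sigma2): positive-class mass above t."""
    return 1.0 - stats.norm.cdf(t, loc=pos.mu, scale=pos.sigma)


def specificity(t, neg: NormalComponent):
    """Sp(t) = Phi((t - mu1)/sigma1): negative-class mass below t."""
    return stats.norm.cdf(t, loc=neg.mu, scale=neg.sigma)


def roc_curve(mix: BinormalMixture, grid_size: int = ROC_GRID_SIZE) -> RocCurve:
    """ROC from a series of cut-offs spanning mu1-6*sigma1 .. mu2+6*sigma2."""
    if grid_size < 3:
        raise ValueError("grid_size must be at least 3")
    lo = mix.neg.mu - ROC_SPAN_SIGMAS * mix.neg.sigma
    hi = mix.pos.mu + ROC_SPAN_SIGMAS * mix.pos.sigma
    if hi <= lo:  # components in reverse order or collapsed span
        lo, hi = min(lo, hi) - 1.0, max(lo, hi) + 1.0
    t = np.linspace(lo, hi, grid_size)
    return RocCurve(
        thresholds=t,
        fpr=1.0 - specificity(t, mix.neg),
        tpr=sensitivity(t, mix.pos),
    )


def auc(mix: BinormalMixture, method: str = "closed_form", grid_size: int = ROC_GRID_SIZE) -> float:
    """Area under the binormal ROC.

    ``closed_form`` evaluates Phi((mu2-mu1)/sqrt(sigma1^2+sigma2^2)), which
    equals P(X_pos > X_neg) for independent class draws. ``trapezoid``
    integrates the discrete curve with exact (0,0)/(1,1) endpoints
    appended; the two agree to ~1e-3 at the default grid.
    """
    if method == "closed_form":
        delta = mix.pos.mu - mix.neg.mu
        return float(stats.norm.cdf(delta / math.hypot(mix.neg.sigma, mix.pos.sigma)))
    if method == "trapezoid":
        roc = roc_curve(mix, grid_size)
        fpr = np.concatenate([[0.0], roc.fpr[::-1], [1.0]])
        tpr = np.concatenate([[0.0], roc.tpr[::-1], [1.0]])
        return float(np.trapezoid(tpr, fpr))
    raise ValueError(f"unknown method {method!r}")


def _log_density_gap(t, mix: BinormalMixture) -> float:
    """log f_pos(t) - log f_neg(t) of the class densities (no pr weighting)."""
    return float(
        stats.norm.logpdf(t, mix.pos.mu, mix.pos.sigma)
        - stats.norm.logpdf(t, mix.neg.mu, mix.neg.sigma)
    )


def optimal_cutoff(
    mix: BinormalMixture,
    mode: str = "youden",
    cost_ratio: float | None = None,
) -> float:
    """Log-scale cut-off maximizing Youden's index or minimizing expected cost.

    ``youden`` solves f_pos(t) = f_neg(t) (the stationary point of
    Se + Sp - 1); ``cost`` solves LR(t) = (1-pr)/(C*pr) with
    C = cost(FN)/cost(FP). With C = (1-pr)/pr the two coincide. The
    quadratic from equating log-densities is solved analytically and the
    root inside (mu1, mu2) returned; if root selection is ambiguous a
    bracketed bisection on the log-density gap is used instead.
    """
    m1, s1 = mix.neg.mu, mix.neg.sigma
    m2, s2 = mix.pos.mu, mix.pos.sigma
    if m2 <= m1:
        raise ValueError("positive component must sit above the negative one")
    if mode == "youden":
        log_target = 0.0
    elif mode == "cost":
        if cost_ratio is None or not cost_ratio > 0:
            raise ValueError("mode 'cost' needs cost_ratio > 0")
        if not 0.0 < mix.pr < 1.0:
            raise ValueError("mode 'cost' needs prevalence strictly inside (0, 1)")
        log_target = math.log((1.0 - mix.pr) / (cost_ratio * mix.pr))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # log f2 - log f1 - log_target = A t^2 + B t + C
    A = 1.0 / (2 * s1**2) - 1.0 / (2 * s2**2)
    B = m2 / s2**2 - m1 / s1**2
    C = m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2) + math.log(s1 / s2) - log_target
    roots: list[float] = []
    if abs(A) < 1e-14:
        if abs(B) > 1e-14:
            roots = [-C / B]
    else:
        disc = B * B - 4 * A * C
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    admissible = [r for r in roots if m1 <= r <= m2]
    if len(admissible) == 1:
        return float(admissible[0])

    gap = lambda t: _log_density_gap(t, mix) - log_target
    g1, g2 = gap(m1), gap(m2)
    if g1 == 0.0:
        return float(m1)
    if g2 == 0.0:
        return float(m2)
    if g1 * g2 > 0:
        raise ValueError(
            "no admissible cut-off between the component means "
            f"(log-density gap {g1:.3g} .. {g2:.3g}); components overlap too strongly"
        )
    return float(optimize.brentq(gap, m1, m2, xtol=1e-12))


def reference_range(neg: NormalComponent) -> tuple[float, float, float]:
    """Central 95% interval and 95th percentile of the healthy class,
    back-transformed to original units:
    (exp(mu1-1.96 sigma1), exp(mu1+1.96 sigma1), exp(mu1+1.645 sigma1))."""
    low = math.exp(neg.mu - 1.96 * neg.sigma)
    high = math.exp(neg.mu + 1.96 * neg.sigma)
    p95 = math.exp(neg.mu + 1.645 * neg.sigma)
    return low, high, p95


def predictive_values(se: float, sp: float, pr: float) -> tuple[float, float]:
    """Post-test probabilities (PPV, NPV) at prevalence pr (Bayes)."""
    for name, v in (("se", se), ("sp", sp), ("pr", pr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    denom_p = pr * se + (1.0 - pr) * (1.0 - sp)
    denom_n = (1.0 - pr) * sp + pr * (1.0 - se)
    if denom_p == 0.0 or denom_n == 0.0:
        raise ValueError("predictive value undefined: zero probability of that test result")
    return pr * se / denom_p, (1.0 - pr) * sp / denom_n


def likelihood_ratios(se: float, sp: float) -> tuple[float, float]:
    """(LR+, LR-) = (Se/(1-Sp), (1-Se)/Sp)."""
    if sp >= 1.0:
        raise ValueError("LR+ undefined at sp = 1 (no false positives)")
    if sp <= 0.0:
        raise ValueError("LR- undefined at sp = 0")
    return se / (1.0 - sp), (1.0 - se) / sp


def interval_lr(t1: float, t2: float, mix: BinormalMixture) -> float:
    """Likelihood ratio of an observation falling in [t1, t2):
    -(Se(t1)-Se(t2))/(Sp(t1)-Sp(t2)), i.e. the ratio of the class
    probability masses in the interval."""
    if not t1 < t2:
        raise ValueError("need t1 < t2")
    se1, se2 = sensitivity(t1, mix.pos), sensitivity(t2, mix.pos)
    sp1, sp2 = specificity(t1, mix.neg), specificity(t2, mix.neg)
    denom = sp1 - sp2
    if denom == 0.0:
        raise ValueError("degenerate interval: negative class carries no mass in it")
    return -(se1 - se2) / denom


def point_lr(x, mix: BinormalMixture):
    """Density ratio f_pos(x)/f_neg(x) = (sigma1/sigma2) *
    phi((x-mu2)/sigma2)/phi((x-mu1)/sigma1) — the slope of the ROC tangent
    at the operating point of x. Computed in log space for tail stability."""
    log_ratio = stats.norm.logpdf(x, mix.pos.mu, mix.pos.sigma) - stats.norm.logpdf(
        x, mix.neg.mu, mix.neg.sigma
    )
    out = np.exp(log_ratio)
    return float(out) if np.isscalar(x) else out


def posterior_probability(p_evidence_given_disease: float, p_evidence: float, prior: float) -> float:
    """Bayes' theorem: P(D|E) = P(E|D)/P(E) * P(D)."""
    if not 0.0 < p_evidence <= 1.0:
        raise ValueError("p_evidence must lie in (0, 1]")
    if not 0.0 <= p_evidence_given_disease <= 1.0 or not 0.0 <= prior <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    post = p_evidence_given_disease / p_evidence * prior
    if post > 1.0 + 1e-12:
        raise ValueError(f"incoherent inputs: posterior {post:.4f} exceeds 1")
    return min(post, 1.0)


def compute_report(
    mix: BinormalMixture,
    mode: str = "youden",
    cost_ratio: float | None = None,
    cutoff_log: float | None = None,
) -> IndexReport:
    """Assemble the full index report for one fitted stratum.

    The cut-off is taken as given (``cutoff_log``) or located by
    :func:`optimal_cutoff`; all other indices are evaluated there.
    """
    t = optimal_cutoff(mix, mode=mode, cost_ratio=cost_ratio) if cutoff_log is None else cutoff_log
    se = float(sensitivity(t, mix.pos))
    sp = float(specificity(t, mix.neg))
    ppv, npv = predictive_values(se, sp, mix.pr)
    lr_pos, lr_neg = likelihood_ratios(se, sp)
    low, high, p95 = reference_range(mix.neg)
    return IndexReport(
        cutoff_log=float(t),
        cutoff_raw=float(math.exp(t)),
        se=se,
        sp=sp,
        youden=se + sp - 1.0,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        auc=auc(mix, "closed_form"),
        prevalence=mix.pr,
        ref_low=low,
        ref_high=high,
        p95=p95,
        cost_ratio=cost_ratio if mode == "cost" else None,
    )
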