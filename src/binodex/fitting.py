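"""Decompose a relative-frequency histogram into its two Gaussian components.

The six-parameter superposition ``a*[(1-pr) f1(x) + pr f2(x)]`` is fit to
the bin heights by bounded Levenberg–Marquardt least squares (lmfit, the
Python counterpart of R's ``nlsLM``). Constraints: ``a >= 0``, both sigmas
positive (a small floor converts non-negativity into numerically safe
positivity), ``pr`` in [0, 1]. Least squares is unweighted on bin heights.

Because the positive-class component is assumed age-invariant while the
negative-class mean drifts with age, identification improves with a
two-pass strategy: first a free six-parameter fit on an "anchor" stratum
where both classes carry comparable weight (age >= 65, where the prevalence
approaches one half), then four-parameter fits of every other stratum with
the positive component frozen to the anchor's estimate.

LM is a local optimizer and no canonical starting point exists, so a fixed
number of deterministically seeded jittered restarts is attempted whenever
the first fit fails or lands on a parameter bound; the restart with the
smallest residual sum of squares wins, ties going to the smaller pr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import lmfit
import numpy as np

from .distributions import BinormalMixture, NormalComponent, mixture_density
from .histogram import RelFreqHistogram

__all__ = ["FitResult", "FitError", "initial_guess", "fit_mixture", "r_squared", "two_pass_fit"]

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-6
N_RESTARTS = 5
MIN_BINS = 8
_BOUND_TOL = 1e-8


class FitError(RuntimeError):
    """Raised when the decomposition cannot be fit to a histogram."""


@dataclass(frozen=True)
class FitResult:
    """Outcome of one mixture decomposition.

    ``r_squared`` is 1 - SS_res/SS_tot with SS_tot taken about the mean of
    the observed bin heights (the convention of R's nonlinear-fitting
    ecosystem; no canonical r-squared exists for a nonlinear model).
    ``fixed_pos`` marks second-pass fits where the positive component was
    held constant (four free parameters instead of six). The fitted ``pr``
    is the prevalence estimate for the stratum.
    """

    mixture: BinormalMixture
    r_squared: float
    fixed_pos: bool
    n_params: int
    converged: bool
    residuals: np.ndarray
    ss_res: float

    @property
    def prevalence(self) -> float:
        return self.mixture.pr


def initial_guess(hist: RelFreqHistogram) -> BinormalMixture:
    """Feasible starting point from weighted quantiles of the bin centers.

    mu1 from the 25th rel-freq-weighted percentile, mu2 from the 90th
    (nudged above mu1 if needed), both sigmas from the weighted SD,
    pr = 0.3, a = h. All values respect the fit bounds.
    """
    w = hist.rel_freq / hist.rel_freq.sum()
    cum = np.cumsum(w)
    mu1 = float(np.interp(0.25, cum, hist.centers))
    mu2 = float(np.interp(0.90, cum, hist.centers))
    mean = float(np.sum(w * hist.centers))
    sd = float(np.sqrt(np.sum(w * (hist.centers - mean) ** 2)))
    sd = max(sd, hist.h)  # a histogram narrower than one bin is degenerate
    if mu2 <= mu1:
        mu2 = mu1 + 0.5 * sd
    return BinormalMixture(
        neg=NormalComponent(mu1, sd),
        pos=NormalComponent(mu2, sd),
        pr=0.3,
        a=hist.h,
    )


def r_squared(observed, fitted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValueError("observed and fitted must be equal-length vectors of size >= 2")
    if np.all(obs == obs[0]):
        raise ValueError("observed vector is constant; r-squared undefined")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((obs - fit) ** 2))
    return 1.0 - ss_res / ss_tot


def _make_params(start: BinormalMixture, fixed_pos: NormalComponent | None) -> lmfit.Parameters:
    p = lmfit.Parameters()
    p.add("a", value=max(start.a, SIGMA_FLOOR), min=0.0)
    p.add("pr", value=min(max(start.pr, 0.0), 1.0), min=0.0, max=1.0)
    p.add("mu1", value=start.neg.mu)
    p.add("sigma1", value=max(start.neg.sigma, SIGMA_FLOOR), min=SIGMA_FLOOR)
    if fixed_pos is None:
        p.add("mu2", value=start.pos.mu)
        p.add("sigma2", value=max(start.pos.sigma, SIGMA_FLOOR), min=SIGMA_FLOOR)
    else:
        p.add("mu2", value=fixed_pos.mu, vary=False)
        p.add("sigma2", value=fixed_pos.sigma, vary=False)
    return p


def _params_to_mixture(p: lmfit.Parameters) -> BinormalMixture:
    return BinormalMixture(
        neg=NormalComponent(p["mu1"].value, max(p["sigma1"].value, SIGMA_FLOOR)),
        pos=NormalComponent(p["mu2"].value, max(p["sigma2"].value, SIGMA_FLOOR)),
        pr=min(max(p["pr"].value, 0.0), 1.0),
        a=max(p["a"].value, 0.0),
    )


def _at_bound(p: lmfit.Parameters) -> bool:
    for par in p.values():
        if not par.vary:
            continue
        if par.min is not None and np.isfinite(par.min) and abs(par.value - par.min) < _BOUND_TOL:
            if par.name == "sigma1" or par.name == "sigma2" or par.name == "a":
                return True
            if par.name == "pr":
                return True
        if par.max is not None and np.isfinite(par.max) and abs(par.value - par.max) < _BOUND_TOL:
            return True
    return False


def fit_mixture(
    hist: RelFreqHistogram,
    fixed_pos: NormalComponent | None = None,
    n_restarts: int = N_RESTARTS,
    seed: int = 0,
) -> FitResult:
    """Bounded LM least-squares fit of the binormal curve to bin heights.

    With ``fixed_pos`` given, mu2/sigma2 are frozen to it (second-pass,
    four-parameter model). Components of a free fit are relabelled so the
    negative one has the smaller mean. Raises :class:`FitError` on
    non-convergence after the multistart schedule or on a histogram with
    fewer than 8 bins.
    """
    if hist.n_bin < MIN_BINS:
        raise FitError(f"insufficient resolution: {hist.n_bin} bins < {MIN_BINS}")
    start = initial_guess(hist)

    def residual(p):
        mix = _params_to_mixture(p)
        return hist.rel_freq - mixture_density(hist.centers, mix)

    attempts: list[tuple[float, float, lmfit.minimizer.MinimizerResult]] = []

    def run(start_mix: BinormalMixture) -> lmfit.minimizer.MinimizerResult | None:
        params = _make_params(start_mix, fixed_pos)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception as exc:  # lmfit surfaces MINPACK failures as exceptions
            logger.debug("fit attempt failed: %s", exc)
            return None
        if res.success:
            attempts.append((float(np.sum(res.residual**2)), res.params["pr"].value, res))
        return res

    first = run(start)
    need_restarts = first is None or not first.success or _at_bound(first.params)
    if need_restarts and n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            jitter = BinormalMixture(
                neg=NormalComponent(
                    start.neg.mu + rng.normal(0.0, 0.5 * start.neg.sigma),
                    start.neg.sigma * float(np.exp(rng.normal(0.0, 0.3))),
                ),
                pos=NormalComponent(
                    start.pos.mu + rng.normal(0.0, 0.5 * start.pos.sigma),
                    start.pos.sigma * float(np.exp(rng.normal(0.0, 0.3))),
                ),
                pr=float(rng.uniform(0.05, 0.95)),
                a=start.a * float(np.exp(rng.normal(0.0, 0.2))),
            )
            run(jitter)
    if not attempts:
        raise FitError("mixture fit did not converge after multistart schedule")

    attempts.sort(key=lambda t: (t[0], t[1]))  # best SS_res; ties -> smaller pr
    ss_res, _, best = attempts[0]
    mix = _params_to_mixture(best.params)
    if fixed_pos is None:
        mix = mix.ordered()
    fitted = mixture_density(hist.centers, mix)
    return FitResult(
        mixture=mix,
        r_squared=r_squared(hist.rel_freq, fitted),
        fixed_pos=fixed_pos is not None,
        n_params=4 if fixed_pos is not None else 6,
        converged=True,
        residuals=hist.rel_freq - fitted,
        ss_res=ss_res,
    )


def two_pass_fit(
    strata: dict[str, RelFreqHistogram],
    anchor: str,
    seed: int = 0,
) -> dict[str, FitResult]:
    """Anchor-first decomposition of age-stratified histograms.

    The anchor stratum is fit with all six parameters free; every other
    stratum is then fit with the positive component frozen to the anchor's
    estimate. Anchor failure aborts the whole analysis; a failure in any
    other stratum is logged and that stratum omitted from the result.
    """
    if anchor not in strata:
        raise KeyError(f"anchor stratum {anchor!r} not among {sorted(strata)}")
    results: dict[str, FitResult] = {}
    try:
        results[anchor] = fit_mixture(strata[anchor], seed=seed)
    except FitError as exc:
        raise FitError(f"anchor stratum {anchor!r} failed to fit: {exc}") from exc
    pos = results[anchor].mixture.pos
    for label, hist in strata.items():
        if label == anchor:
            continue
        try:
            results[label] = fit_mixture(hist, fixed_pos=pos, seed=seed)
        except FitError as exc:
            logger.warning("stratum %r failed to fit: %s", label, exc)
    return results
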