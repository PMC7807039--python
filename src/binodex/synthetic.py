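"""Labeled synthetic cohorts with the structure the decomposition assumes.

Each subject carries an age, a hidden disease label, and a biomarker value
whose natural log is drawn from the label's Gaussian component. The
negative-class mean rises with age (band-wise constant) while the positive
component is the same at every age — the generating assumption that makes
the anchor-stratum two-pass fit identifiable. Raw values are truncated to
the plausibility window by resampling, which keeps the per-cohort n exact
at the price of a slight tail perturbation relative to the untruncated
model.

Because labels are generated but hidden from the fitting pipeline, the
cohort doubles as a gold standard: :func:`empirical_indices` computes the
contingency-table Se = TP/(TP+FN) etc. against which the label-free
estimates can be validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .distributions import NormalComponent

__all__ = ["AGE_BANDS", "CohortSpec", "default_spec", "generate_cohort", "empirical_indices"]

#: (label, low age, high age) — six bands used throughout for stratified runs.
AGE_BANDS: tuple[tuple[str, int, int], ...] = (
    ("20-39", 20, 39),
    ("40-49", 40, 49),
    ("50-59", 50, 59),
    ("60-69", 60, 69),
    ("70-79", 70, 79),
    ("80+", 80, 94),
)

# Illustrative age profile: prevalence rising steeply through midlife and
# plateauing, negative-class log-mean drifting upward with age. The 50-59
# band matches the fitted PSA example (pr ~= 0.165-0.198, mu1 = -0.124,
# sigma1 = 0.643); the positive component (1.033, 0.766) is age-invariant.
_DEFAULT_PR = {"20-39": 0.03, "40-49": 0.08, "50-59": 0.165, "60-69": 0.406, "70-79": 0.545, "80+": 0.50}
_DEFAULT_NEG_MU = {"20-39": -0.55, "40-49": -0.35, "50-59": -0.124, "60-69": 0.02, "70-79": 0.15, "80+": 0.25}
_DEFAULT_AGE_WEIGHTS = {"20-39": 0.25, "40-49": 0.20, "50-59": 0.20, "60-69": 0.15, "70-79": 0.12, "80+": 0.08}


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for one synthetic cohort."""

    n: int
    pr: Mapping[str, float]
    neg_mu_by_age: Mapping[str, float]
    neg_sigma: float
    pos: NormalComponent
    age_distribution: Mapping[str, float]
    seed: int = 0
    vmin: float = 0.1
    vmax: float = 100.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not self.neg_sigma > 0:
            raise ValueError("neg_sigma must be positive")
        if not self.vmin > 0:
            raise ValueError("vmin must be positive")
        bands = set(self.age_distribution)
        if not bands <= {b[0] for b in AGE_BANDS}:
            raise ValueError(f"unknown age bands {bands - {b[0] for b in AGE_BANDS}}")
        for label in bands:
            p = self.pr[label]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pr[{label!r}] = {p} outside [0, 1]")
            if label not in self.neg_mu_by_age:
                raise ValueError(f"no negative-class mean for band {label!r}")

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            raw = json.load(fh)
        pos = raw.pop("pos")
        return cls(pos=NormalComponent(pos["mu"], pos["sigma"]), **raw)


def default_spec(n: int = 20_000, seed: int = 0) -> CohortSpec:
    """The default age-structured cohort (six bands, shared positive component)."""
    return CohortSpec(
        n=n,
        pr=dict(_DEFAULT_PR),
        neg_mu_by_age=dict(_DEFAULT_NEG_MU),
        neg_sigma=0.643,
        pos=NormalComponent(1.033, 0.766),
        age_distribution=dict(_DEFAULT_AGE_WEIGHTS),
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with columns ``age``, ``value``, ``label``.

    Ages come from the band weights (uniform integer within a band), the
    label is Bernoulli with the band's prevalence, and the log-value from
    the label's component. Values falling outside [vmin, vmax] are redrawn
    from the same component; a first-pass acceptance rate below 1% aborts
    (the spec contradicts its own truncation window). Identical specs give
    identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    labels_bands = list(spec.age_distribution)
    weights = np.array([spec.age_distribution[b] for b in labels_bands], dtype=float)
    weights = weights / weights.sum()
    band_idx = rng.choice(len(labels_bands), size=spec.n, p=weights)
    bounds = {b[0]: (b[1], b[2]) for b in AGE_BANDS}
    lows = np.array([bounds[labels_bands[i]][0] for i in band_idx])
    highs = np.array([bounds[labels_bands[i]][1] for i in band_idx])
    ages = rng.integers(lows, highs + 1)
    pr_arr = np.array([spec.pr[labels_bands[i]] for i in band_idx])
    diseased = rng.random(spec.n) < pr_arr
    mu = np.where(
        diseased,
        spec.pos.mu,
        np.array([spec.neg_mu_by_age[labels_bands[i]] for i in band_idx]),
    )
    sigma = np.where(diseased, spec.pos.sigma, spec.neg_sigma)
    logv = rng.normal(mu, sigma)

    lo, hi = np.log(spec.vmin), np.log(spec.vmax)
    outside = (logv < lo) | (logv > hi)
    if outside.mean() > 0.99:
        raise ValueError("spec inconsistent with bounds: truncation acceptance rate < 1%")
    while outside.any():
        logv[outside] = rng.normal(mu[outside], sigma[outside])
        outside = (logv < lo) | (logv > hi)

    return pd.DataFrame(
        {"age": ages.astype(int), "value": np.exp(logv), "label": diseased.astype(int)}
    )


def empirical_indices(table: pd.DataFrame, t: float) -> tuple[float, float, float, float]:
    """Gold-standard (Se, Sp, PPV, NPV) from the hidden labels at log cut-off t.

    Contingency counts of label against the call ``log(value) > t``:
    Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN).
    """
    label = table["label"].to_numpy().astype(bool)
    if label.all() or not label.any():
        raise ValueError("both classes must be present to form a contingency table")
    call = np.log(table["value"].to_numpy(dtype=float)) > t
    tp = int(np.sum(call & label))
    fn = int(np.sum(~call & label))
    fp = int(np.sum(call & ~label))
    tn = int(np.sum(~call & ~label))
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return se, sp, ppv, npv
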