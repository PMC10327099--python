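"""Contamination estimators from filtered hom-alt records.

At a truly homozygous-alternate site every well-mapped read should carry
the alternate allele; reference reads appear through contamination. If a
fraction c of reads comes from other individuals, a contaminating read is
a reference read with probability p (the population reference allele
frequency), so the reference allele balance at hom-alt sites has
expectation

    E[AB_ref] = c * p,      AB_ref = RR / (RR + AR).

The point estimator is the AF-adjusted sample mean over the m retained
hom-alt sites,

    CHARR = (1/m) * sum_j RR_j / (p_j * (AR_j + RR_j)),

and the per-sample likelihood of the read counts,

    L(c) = prod_j (1 - c p_j)^{AR_j} (c p_j)^{RR_j},

is maximized over the grid c = 0, 0.001, ..., 0.1. When 1 - c p_j ~ 1 the
likelihood maximizer has the closed form
sum_j RR_j / sum_j p_j (AR_j + RR_j), which the grid MLE and CHARR both
approximate closely at realistic contamination levels.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .io import SiteGenotype

RecordsWithP = Sequence[tuple[SiteGenotype, float]]


@dataclasses.dataclass
class CharrResult:
    """Per-sample contamination estimate.

    ``charr`` is nan when no sites survive filtering; ``insufficient``
    flags n_sites below the configured minimum (default 500), the count
    below which the estimate is considered unreliable.
    """

    sample_id: str
    charr: float
    n_sites: int
    mean_dp: float
    het_hom_ratio: float
    insufficient: bool


@dataclasses.dataclass
class MleResult:
    """Grid-search likelihood maximum and its closed-form approximation."""

    c_mle: float
    grid_start: float
    grid_stop: float
    grid_step: float
    loglik_at_max: float
    c_closed_form: float


def ab_ref(ad_ref: int, ad_alt: int) -> float:
    """Reference allele balance: AD_ref / (AD_ref + AD_alt).

    The denominator is the sum of the two allele depths, not DP -- DP may
    include uninformative reads.
    """
    if ad_ref < 0 or ad_alt < 0:
        raise ValueError(f"allele depths must be non-negative, got ({ad_ref}, {ad_alt})")
    denom = ad_ref + ad_alt
    if denom == 0:
        raise ValueError("ab_ref undefined at zero total allele depth")
    return ad_ref / denom


def _arrays(records_with_p: RecordsWithP) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rr = np.array([rec.ad_ref for rec, _ in records_with_p], dtype=float)
    ar = np.array([rec.ad_alt for rec, _ in records_with_p], dtype=float)
    p = np.array([p for _, p in records_with_p], dtype=float)
    return rr, ar, p


def charr(
    records_with_p: RecordsWithP,
    sample_id: str = "sample",
    min_sites: int = 500,
    het_hom: float = math.nan,
) -> CharrResult:
    """Compute CHARR over the retained (record, p) pairs of one sample.

    Every record must have positive total allele depth and p strictly in
    (0, 1) -- the filter guarantees both; violations here are internal
    errors, not data errors.
    """
    m = len(records_with_p)
    if m == 0:
        return CharrResult(sample_id, math.nan, 0, math.nan, het_hom, True)
    rr, ar, p = _arrays(records_with_p)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise RuntimeError("internal invariant violated: p outside (0, 1) reached the estimator")
    denom = p * (ar + rr)
    if np.any(denom <= 0.0):
        raise RuntimeError("internal invariant violated: zero allele depth reached the estimator")
    value = float(np.mean(rr / denom))
    mean_dp = float(np.mean([rec.dp for rec, _ in records_with_p]))
    return CharrResult(sample_id, value, m, mean_dp, het_hom, m < min_sites)


def loglik(c: float, records_with_p: RecordsWithP) -> float:
    """Log-likelihood sum_j [AR_j log(1 - c p_j) + RR_j log(c p_j)].

    Uses the 0*log(0) = 0 convention, so c=0 is finite (0.0) for a
    contamination-free sample and -inf as soon as any reference read is
    observed. c < 0 or c*p >= 1 is a domain error.
    """
    if c < 0:
        raise ValueError(f"contamination rate must be >= 0, got {c}")
    rr, ar, p = _arrays(records_with_p)
    cp = c * p
    if np.any(cp >= 1.0):
        raise ValueError(f"c * p >= 1 at c={c}; likelihood undefined")
    return float(np.sum(xlogy(ar, 1.0 - cp) + xlogy(rr, cp)))


def closed_form_mle(records_with_p: RecordsWithP) -> float:
    """sum_j RR_j / sum_j p_j (AR_j + RR_j): the small-c likelihood maximizer."""
    rr, ar, p = _arrays(records_with_p)
    return float(np.sum(rr) / np.sum(p * (ar + rr)))


def grid_mle(
    records_with_p: RecordsWithP,
    grid_start: float = 0.0,
    grid_stop: float = 0.1,
    grid_step: float = 0.001,
) -> MleResult:
    """Maximize the log-likelihood over an evenly spaced contamination grid.

    Grid points where any c*p_j >= 1 are skipped; ties break toward the
    smaller c (conservative). Raises on an empty record list.
    """
    if len(records_with_p) == 0:
        raise ValueError("grid_mle requires at least one record")
    if grid_step <= 0 or grid_stop < grid_start or grid_start < 0:
        raise ValueError(f"invalid grid ({grid_start}, {grid_stop}, {grid_step})")
    n_steps = int(round((grid_stop - grid_start) / grid_step))
    grid = grid_start + grid_step * np.arange(n_steps + 1)
    grid[-1] = grid_stop

    rr, ar, p = _arrays(records_with_p)
    cp = grid[:, None] * p[None, :]  # (G, m)
    valid = np.all(cp < 1.0, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.sum(xlogy(ar[None, :], 1.0 - cp) + xlogy(rr[None, :], cp), axis=1)
    ll[~valid] = -np.inf
    if not np.any(np.isfinite(ll)) and not np.any(valid):
        raise ValueError("no valid grid point (c * p >= 1 everywhere)")
    best = int(np.argmax(ll))  # first max == smallest c on ties
    return MleResult(
        c_mle=float(grid[best]),
        grid_start=grid_start,
        grid_stop=grid_stop,
        grid_step=grid_step,
        loglik_at_max=float(ll[best]),
        c_closed_form=closed_form_mle(records_with_p),
    )
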