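"""Relative-risk association records from stratified co-occurrence summaries.

The epidemiological input is one :class:`CooccurrenceSummary` per age-band x
gender stratum: the stratum population size ``N``, per-disease prevalence
counts ``N_i`` and pairwise Jaccard indices ``J_ij``.  Because the Jaccard
index is a deterministic function of the integer co-occurrence count
``C = |i and j|`` and the two prevalences, it can be inverted exactly::

    J = C / (N_i + N_j - C)   <=>   C = J * (N_i + N_j) / (1 + J)

and the comorbidity strength is then the observed-over-expected relative
risk::

    RR_ij = C * N / (N_i * N_j)

``RR > 1`` marks co-occurring (comorbid) disease pairs and ``RR < 1`` pairs
tending to mutual exclusivity.  Confidence intervals use the Katz
log-normal method on the reconstructed 2x2 table and P values follow the
Altman-Bland normal approximation on ``ln RR / SE``.

Note on estimands: the point estimate is the observed/expected ratio above,
while the Katz interval is built for the *conditional* risk ratio
``[a/(a+b)] / [c/(c+d)]`` of the same 2x2 table.  For the low-prevalence
diagnoses this pipeline handles, the two nearly coincide; the interval is
attached to the observed/expected estimate as is conventional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

__all__ = [
    "CooccurrenceSummary",
    "AssociationRecord",
    "cooccurrence_from_jaccard",
    "relative_risk",
    "katz_ci",
    "build_association_table",
    "vigintile_thresholds",
]

#: fixed fallback edge thresholds used when a stratum has too few records
#: to estimate percentiles (the vigintiles of the source cohort correspond
#: to RR < 0.8 / RR > 1.6).
FALLBACK_THRESHOLDS = (0.8, 1.6)


@dataclass
class CooccurrenceSummary:
    """One stratum's co-occurrence summary.

    Parameters
    ----------
    stratum
        ``(age_band, gender)`` label, e.g. ``("65-69", "women")``.
    n
        Population size N of the stratum.
    prevalence
        Mapping disease code -> prevalence count ``N_i``.
    jaccard
        Mapping sorted code pair ``(code_i, code_j)`` -> Jaccard index.
    """

    stratum: tuple[str, str]
    n: int
    prevalence: dict[str, int]
    jaccard: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("population size must be positive")
        for code, cnt in self.prevalence.items():
            if cnt < 0 or cnt > self.n:
                raise ValueError(f"prevalence count out of range for {code!r}")


@dataclass
class AssociationRecord:
    """A disease pair in one stratum with its relative-risk estimate."""

    stratum: tuple[str, str]
    pair: tuple[str, str]
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    c: int
    jaccard: float


def cooccurrence_from_jaccard(j: float, n_i: int, n_j: int, n: int | None = None) -> int:
    """Invert the Jaccard index to the integer co-occurrence count.

    ``C = J (N_i + N_j) / (1 + J)``, rounded to the nearest integer.  A
    consistency warning is emitted when the raw value is far from an
    integer, and an error is raised when the reconstructed count violates
    the 2x2 margins (requires ``n``).
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError("Jaccard index must lie in [0, 1]")
    if n_i < 1 or n_j < 1:
        raise ValueError("prevalence counts must be >= 1")
    raw = j * (n_i + n_j) / (1.0 + j)
    c = int(np.rint(raw))
    if abs(raw - c) > 1e-6 * (n_i + n_j):
        warnings.warn(
            f"Jaccard index {j!r} does not invert to an integer count "
            f"(raw {raw}); using {c}",
            stacklevel=2,
        )
    if n is not None:
        lo, hi = max(0, n_i + n_j - n), min(n_i, n_j)
        if not lo <= c <= hi:
            raise ValueError(
                f"reconstructed co-occurrence {c} outside feasible range [{lo}, {hi}]"
            )
    return c


def relative_risk(j: float, n_i: int, n_j: int, n: int) -> float:
    """Observed/expected relative risk ``RR = C N / (N_i N_j)`` from J."""
    if n < max(n_i, n_j):
        raise ValueError("population must be at least as large as each prevalence")
    c = cooccurrence_from_jaccard(j, n_i, n_j, n)
    return c * n / (n_i * n_j)


def katz_ci(
    c: int, n_i: int, n_j: int, n: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Katz confidence interval and Altman-Bland P for a reconstructed 2x2 table.

    The table is ``a = C``, ``b = N_j - C``, ``c' = N_i - C``,
    ``d = N - N_i - N_j + C``; the interval is on the conditional risk
    ratio ``[a/(a+b)] / [c'/(c'+d)]`` with
    ``SE(ln RR) = sqrt(1/a - 1/(a+b) + 1/c' - 1/(c'+d))``.

    Returns ``(ci_low, ci_high, p)``.  When ``a = 0`` or ``c' = 0`` the
    interval is undefined: ``(nan, nan, 1.0)`` is returned by convention.
    """
    a, b, cc, d = c, n_j - c, n_i - c, n - n_i - n_j + c
    if min(a, b, cc, d) < 0:
        raise ValueError("2x2 table margins not reconstructible (negative cell)")
    if a == 0 or cc == 0:
        return (float("nan"), float("nan"), 1.0)
    rr_cond = (a / (a + b)) / (cc / (cc + d))
    se = np.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / cc - 1.0 / (cc + d))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    log_rr = np.log(rr_cond)
    lo = float(np.exp(log_rr - zcrit * se))
    hi = float(np.exp(log_rr + zcrit * se))
    if se == 0.0:
        p = 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(log_rr) / se))
    return (lo, hi, p)


def build_association_table(
    summary: CooccurrenceSummary, min_prevalence: float = 0.01
) -> list[AssociationRecord]:
    """All pairwise association records of a stratum, prevalence-filtered.

    Only pairs where *both* diseases reach ``min_prevalence`` (as a
    proportion of N) are kept; one record per unordered pair present in the
    Jaccard map.  The whole table is computed vectorised; scalar helpers
    (:func:`relative_risk`, :func:`katz_ci`) define the per-pair semantics.
    """
    n = summary.n
    keep = {
        code for code, cnt in summary.prevalence.items() if cnt / n >= min_prevalence
    }
    pairs = [p for p in summary.jaccard if p[0] in keep and p[1] in keep]
    if not pairs:
        warnings.warn(
            f"no association records for stratum {summary.stratum}", stacklevel=2
        )
        return []

    n_i = np.array([summary.prevalence[p[0]] for p in pairs], dtype=np.int64)
    n_j = np.array([summary.prevalence[p[1]] for p in pairs], dtype=np.int64)
    jac = np.array([summary.jaccard[p] for p in pairs], dtype=np.float64)

    c = np.rint(jac * (n_i + n_j) / (1.0 + jac)).astype(np.int64)
    lo_b = np.maximum(0, n_i + n_j - n)
    hi_b = np.minimum(n_i, n_j)
    bad = (c < lo_b) | (c > hi_b)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"inconsistent Jaccard summary for pair {pairs[idx]} in "
            f"stratum {summary.stratum}"
        )
    rr = c * n / (n_i * n_j)

    # Katz CI / Altman-Bland P, vectorised over valid tables
    a, b = c.astype(float), (n_j - c).astype(float)
    cp, d = (n_i - c).astype(float), (n - n_i - n_j + c).astype(float)
    valid = (a > 0) & (cp > 0)
    ci_low = np.full(len(pairs), np.nan)
    ci_high = np.full(len(pairs), np.nan)
    pval = np.ones(len(pairs))
    if valid.any():
        av, bv, cv, dv = a[valid], b[valid], cp[valid], d[valid]
        rr_cond = (av / (av + bv)) / (cv / (cv + dv))
        se = np.sqrt(1.0 / av - 1.0 / (av + bv) + 1.0 / cv - 1.0 / (cv + dv))
        zcrit = stats.norm.ppf(0.975)
        log_rr = np.log(rr_cond)
        ci_low[valid] = np.exp(log_rr - zcrit * se)
        ci_high[valid] = np.exp(log_rr + zcrit * se)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, np.abs(log_rr) / se, 0.0)
        pval[valid] = np.where(se > 0, 2.0 * stats.norm.sf(z), 1.0)

    return [
        AssociationRecord(
            stratum=summary.stratum,
            pair=pairs[k],
            rr=float(rr[k]),
            ci_low=float(ci_low[k]),
            ci_high=float(ci_high[k]),
            p_value=float(pval[k]),
            c=int(c[k]),
            jaccard=float(jac[k]),
        )
        for k in range(len(pairs))
    ]


def vigintile_thresholds(
    records: Iterable[AssociationRecord],
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> tuple[float, float]:
    """5th/95th percentile RR cut-offs of one stratum's RR distribution.

    Edges are retained downstream iff ``RR <= lower`` or ``RR >= upper``.
    With fewer than 20 records percentiles are meaningless at the vigintile
    scale and the fixed fallback thresholds (0.8, 1.6) are returned with a
    warning.  Percentiles interpolate linearly between order statistics.
    """
    rrs = np.asarray([r.rr for r in records], dtype=float)
    if rrs.size < 20:
        warnings.warn(
            f"only {rrs.size} records; falling back to fixed thresholds "
            f"{FALLBACK_THRESHOLDS}",
            stacklevel=2,
        )
        return FALLBACK_THRESHOLDS
    lo, hi = np.percentile(rrs, [lower_pct, upper_pct], method="linear")
    if lo == hi:
        warnings.warn("degenerate RR distribution: lower == upper threshold",
                      stacklevel=2)
    return (float(lo), float(hi))
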