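"""Optimal dichotomization of a continuous marker against survival.

Implements the X-tile-style search: every midpoint between consecutive
observed marker values is a candidate threshold; for each admissible
candidate (both groups at least ``min_group_fraction`` of the cohort) the
two-group log-rank chi-square is computed, and the maximizing threshold is
selected. Because the maximum over many correlated tests inflates the naive
p-value, a corrected p-value is reported using the Miller-Siegmund
approximation for maximally selected statistics (or, optionally, a seeded
permutation null).

The "high" group includes values equal to the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CutpointResult",
    "StatisticUndefinedError",
    "NoAdmissibleCutError",
    "logrank_test",
    "find_optimal_cutpoint",
    "apply_cutpoint",
    "miller_siegmund_pvalue",
]


class StatisticUndefinedError(ValueError):
    """Raised when a survival statistic has no defined value (e.g. no events)."""


class NoAdmissibleCutError(ValueError):
    """Raised when no candidate threshold satisfies the group-size guard."""


@dataclass(frozen=True)
class CutpointResult:
    """Selected threshold with its log-rank statistic and corrected p-value."""

    threshold: float
    chi_square: float
    p_raw: float
    p_corrected: float
    n_low: int
    n_high: int
    scan: tuple[tuple[float, float], ...]  # (candidate, chi_square)


def _prepare_sorted(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be 1D arrays of equal length")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be positive and finite")
    order = np.argsort(t, kind="stable")
    return t[order], e[order], order


def _logrank_chi2_sorted(
    st: np.ndarray, se: np.ndarray, sg: np.ndarray
) -> float:
    """Log-rank chi-square given time-sorted arrays; sg marks group A."""
    n = len(st)
    starts = np.flatnonzero(np.r_[True, st[1:] != st[:-1]])
    counts = np.add.reduceat(np.ones(n), starts)
    counts_a = np.add.reduceat(sg.astype(float), starts)
    d = np.add.reduceat(se.astype(float), starts)
    d_a = np.add.reduceat((se & sg).astype(float), starts)
    # At-risk sets: everyone with time >= t (reverse cumulative sums).
    at_risk = counts[::-1].cumsum()[::-1]
    at_risk_a = counts_a[::-1].cumsum()[::-1]
    ev = d > 0
    nn, na, dd, da = at_risk[ev], at_risk_a[ev], d[ev], d_a[ev]
    exp_a = dd * na / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            nn > 1, dd * (na / nn) * (1.0 - na / nn) * (nn - dd) / (nn - 1.0), 0.0
        )
    v = var.sum()
    if v <= 0:
        return 0.0
    return float((da.sum() - exp_a.sum()) ** 2 / v)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk set; the
    statistic is ``(sum(O-E))^2 / sum(V)``, chi-square with 1 df under the
    null of equal hazards.

    Returns
    -------
    (chi_square, p_value)
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ea.sum() + eb.sum() == 0:
        raise StatisticUndefinedError("log-rank statistic undefined without events")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.r_[np.ones(len(ta), dtype=bool), np.zeros(len(tb), dtype=bool)]
    st, se, order = _prepare_sorted(times, events)
    chi2 = _logrank_chi2_sorted(st, se, group[order])
    return chi2, float(stats.chi2.sf(chi2, df=1))


def miller_siegmund_pvalue(
    chi_square: float, eps_low: float, eps_high: float
) -> float:
    """Approximate p-value for a maximally selected chi-square statistic.

    Improved-Bonferroni bound for the maximum of the standardized log-rank
    process scanned over sample quantiles in ``[eps_low, eps_high]``.
    """
    b = np.sqrt(max(chi_square, 0.0))
    if b < 1e-8:
        return 1.0
    phi = stats.norm.pdf(b)
    log_term = np.log((eps_high * (1.0 - eps_low)) / (eps_low * (1.0 - eps_high)))
    p = phi * (b - 1.0 / b) * log_term + 4.0 * phi / b
    return float(min(1.0, max(p, 0.0)))


def _scan_max(
    values: np.ndarray,
    st: np.ndarray,
    se: np.ndarray,
    order: np.ndarray,
    candidates: np.ndarray,
    min_group: int,
) -> tuple[list[tuple[float, float]], float, float]:
    """Chi-square for every admissible candidate; returns scan, best, threshold."""
    n = len(values)
    scan: list[tuple[float, float]] = []
    best_chi2 = -1.0
    best_thr = np.nan
    for c in candidates:
        high = values >= c
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_group:
            continue
        chi2 = _logrank_chi2_sorted(st, se, high[order])
        scan.append((float(c), chi2))
        if chi2 > best_chi2 + 1e-12:  # ties keep the smallest threshold
            best_chi2 = chi2
            best_thr = float(c)
    return scan, best_chi2, best_thr


def find_optimal_cutpoint(
    values,
    times,
    events,
    min_group_fraction: float = 0.1,
    correction: str = "miller-siegmund",
    n_permutations: int = 1000,
    seed: int = 0,
) -> CutpointResult:
    """Find the marker threshold maximizing the two-group log-rank statistic.

    Candidates are midpoints between consecutive sorted unique marker values;
    candidates leaving either group below ``min_group_fraction`` of the
    cohort are skipped. On ties the smallest threshold wins.

    ``correction`` selects the multiplicity adjustment for ``p_corrected``:
    ``"miller-siegmund"`` (analytic, default) or ``"permutation"`` (seeded
    relabeling null using ``n_permutations`` draws).
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n < 20:
        raise ValueError("cut-point search requires at least 20 subjects")
    if not 0 < min_group_fraction <= 0.5:
        raise ValueError("min_group_fraction must be in (0, 0.5]")
    ev = np.asarray(events, dtype=bool)
    if ev.sum() == 0:
        raise StatisticUndefinedError("no events; log-rank scan undefined")
    uniq = np.unique(vals)
    if len(uniq) < 2:
        raise NoAdmissibleCutError("all marker values identical; no cut exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    min_group = int(np.ceil(min_group_fraction * n))
    st, se, order = _prepare_sorted(times, ev)

    scan, best_chi2, best_thr = _scan_max(vals, st, se, order, candidates, min_group)
    if not scan:
        raise NoAdmissibleCutError(
            f"no candidate threshold leaves both groups >= {min_group} subjects"
        )
    p_raw = float(stats.chi2.sf(best_chi2, df=1))
    if correction == "miller-siegmund":
        p_corr = miller_siegmund_pvalue(
            best_chi2, min_group_fraction, 1.0 - min_group_fraction
        )
    elif correction == "permutation":
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(vals)
            _, chi2_p, _ = _scan_max(perm, st, se, order, candidates, min_group)
            if chi2_p >= best_chi2:
                exceed += 1
        p_corr = (exceed + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown correction: {correction!r}")
    p_corr = max(p_corr, p_raw)  # a multiplicity correction can only weaken
    n_high = int((vals >= best_thr).sum())
    return CutpointResult(
        threshold=best_thr,
        chi_square=best_chi2,
        p_raw=p_raw,
        p_corrected=float(p_corr),
        n_low=n - n_high,
        n_high=n_high,
        scan=tuple(scan),
    )


def apply_cutpoint(values, threshold: float) -> np.ndarray:
    """Dichotomize marker values: True ("high") where value >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(values, dtype=float) >= threshold
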