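"""Kaplan-Meier estimation and Cox proportional-hazards regression.

Both estimators are implemented directly on the partial-likelihood /
product-limit definitions so they can be verified against independent
survival packages:

* :func:`kaplan_meier` — product-limit survival estimate with Greenwood 95%
  confidence intervals under right censoring.
* :func:`cox_fit` — Cox proportional-hazards model maximized by Newton's
  method with Efron's tie correction (Breslow optional), Wald confidence
  intervals and p-values.
* :func:`run_table2_models` — the cohort analysis battery: univariate fits
  for each clinicopathological factor plus one multivariate model over age,
  pT, pN, pTNM stage, lymphovascular invasion and dichotomized eTILs, using
  the conventional reference levels (age < 70, pT1-2, pN0-1, Stage II, LVI
  absent, low eTILs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCohort",
    "KaplanMeierEstimate",
    "CoxResult",
    "ConvergenceError",
    "kaplan_meier",
    "cox_ph",
    "cox_fit",
    "run_table2_models",
]

PT_LEVELS = ("pT1", "pT2", "pT3", "pT4")
PN_LEVELS = ("pN0", "pN1", "pN2", "pN3")
PM_LEVELS = ("pM0", "pM1")
STAGE_LEVELS = ("Stage II", "Stage III", "Stage IV")


class ConvergenceError(RuntimeError):
    """Raised when the Newton iterations fail to converge."""


@dataclass(frozen=True)
class SurvivalCohort:
    """Per-patient survival table with clinical covariates and TILs scores.

    ``data`` must contain ``patient_id``, ``time_months`` (> 0) and ``event``
    (0/1); clinical columns (``age_years``, ``sex``, ``pT``, ``pN``, ``pM``,
    ``pTNM``, ``lymphovascular_invasion``) and the TILs variables are
    optional and validated when present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("patient_id", "time_months", "event"):
            if col not in df.columns:
                raise ValueError(f"cohort is missing required column {col!r}")
        if df["patient_id"].duplicated().any():
            raise ValueError("duplicated patient ids")
        t = df["time_months"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("time_months must be positive and finite")
        ev = df["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_months"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalCohort":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Step-function survival estimate with Greenwood 95% CIs."""

    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t):
        """Evaluate the step function at arbitrary times (S(0) = 1)."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(t), side="right")
        s = np.r_[1.0, self.survival]
        out = s[idx]
        return float(out[0]) if np.isscalar(t) else out


def kaplan_meier(times, events, alpha: float = 0.05) -> KaplanMeierEstimate:
    """Product-limit survival estimate under right censoring.

    The Greenwood variance ``S(t)^2 * sum d_i / (n_i (n_i - d_i))`` gives
    symmetric (linear-scale) confidence intervals clipped to [0, 1].
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("kaplan_meier requires at least one subject")
    order = np.argsort(t, kind="stable")
    st, se = t[order], e[order]
    n = len(st)
    starts = np.flatnonzero(np.r_[True, st[1:] != st[:-1]])
    counts = np.add.reduceat(np.ones(n), starts)
    d = np.add.reduceat(se.astype(float), starts)
    at_risk = counts[::-1].cumsum()[::-1]
    ev = d > 0
    tt, nn, dd = st[starts][ev], at_risk[ev], d[ev]
    surv = np.cumprod(1.0 - dd / nn)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(nn > dd, dd / (nn * (nn - dd)), np.inf)
        var = np.where(surv > 0, surv**2 * np.cumsum(gw_terms), 0.0)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se_s = np.sqrt(np.where(np.isfinite(var), var, 0.0))
    lower = np.clip(surv - z * se_s, 0.0, 1.0)
    upper = np.clip(surv + z * se_s, 0.0, 1.0)
    return KaplanMeierEstimate(
        event_times=tt,
        survival=surv,
        ci_lower=lower,
        ci_upper=upper,
        n_at_risk=nn.astype(int),
        n_events=dd.astype(int),
    )


@dataclass(frozen=True)
class CoxResult:
    """Cox model fit: one row per covariate plus fit diagnostics.

    ``summary`` columns: coef, hr, ci_lower, ci_upper, se, z, p.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    ties: str = "efron"

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _partial_likelihood(beta, st, se, sx, starts, ties):
    """Log partial likelihood, gradient and negative Hessian (information)."""
    n, p = sx.shape
    eta = sx @ beta
    w = np.exp(eta)
    wx = w[:, None] * sx
    wxx = wx[:, :, None] * sx[:, None, :]  # (n, p, p)

    W0 = np.add.reduceat(w, starts)
    W1 = np.add.reduceat(wx, starts, axis=0)
    W2 = np.add.reduceat(wxx.reshape(n, p * p), starts, axis=0)
    S0R = W0[::-1].cumsum()[::-1]
    S1R = W1[::-1].cumsum(axis=0)[::-1]
    S2R = W2[::-1].cumsum(axis=0)[::-1].reshape(-1, p, p)

    ef = se.astype(float)
    d = np.add.reduceat(ef, starts)
    S0D = np.add.reduceat(w * ef, starts)
    S1D = np.add.reduceat(wx * ef[:, None], starts, axis=0)
    S2D = np.add.reduceat(
        wxx.reshape(n, p * p) * ef[:, None], starts, axis=0
    ).reshape(-1, p, p)
    eta_D = np.add.reduceat(eta * ef, starts)
    x_D = np.add.reduceat(sx * ef[:, None], starts, axis=0)

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for g in np.flatnonzero(d > 0):
        dg = d[g]
        loglik += eta_D[g]
        grad += x_D[g]
        if ties == "efron" and dg > 1:
            fracs = np.arange(dg) / dg
            for f in fracs:
                denom = S0R[g] - f * S0D[g]
                zbar = (S1R[g] - f * S1D[g]) / denom
                loglik -= np.log(denom)
                grad -= zbar
                info += (S2R[g] - f * S2D[g]) / denom - np.outer(zbar, zbar)
        else:  # breslow, or a single event where both coincide
            denom = S0R[g]
            zbar = S1R[g] / denom
            loglik -= dg * np.log(denom)
            grad -= dg * zbar
            info += dg * (S2R[g] / denom - np.outer(zbar, zbar))
    return loglik, grad, info


def cox_ph(
    x: np.ndarray,
    times,
    events,
    ties: str = "efron",
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    covariate_names: list[str] | None = None,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    x : ndarray, shape (n, p)
        Covariate matrix (no intercept; the baseline hazard absorbs it).
    ties : {"efron", "breslow"}
        Tie-handling scheme for the partial likelihood.

    Raises
    ------
    ValueError
        For a zero-variance covariate (named) or too few events.
    ConvergenceError
        If the gradient norm does not fall below ``grad_tol`` in
        ``max_iter`` iterations.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and len(np.atleast_1d(times)) > 1:
        x = x.T
    n, p = x.shape
    names = covariate_names or [f"x{i}" for i in range(p)]
    variances = x.var(axis=0)
    dead = [names[i] for i in np.flatnonzero(variances == 0)]
    if dead:
        raise ValueError(f"zero-variance covariate(s): {', '.join(dead)}")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if e.sum() < 1:
        raise ValueError("Cox fit requires at least one event")

    order = np.argsort(t, kind="stable")
    st, se, sx = t[order], e[order], x[order]
    starts = np.flatnonzero(np.r_[True, st[1:] != st[:-1]])

    beta = np.zeros(p)
    loglik, grad, info = _partial_likelihood(beta, st, se, sx, starts, ties)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # Step-halving keeps the ascent monotone.
        for _h in range(30):
            new_beta = beta + step
            new_ll, new_grad, new_info = _partial_likelihood(
                new_beta, st, se, sx, starts, ties
            )
            if np.isfinite(new_ll) and new_ll >= loglik - 1e-12:
                break
            step = step / 2.0
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        # Near the optimum the log-likelihood plateaus below float precision;
        # a vanishing Newton step then certifies convergence.
        if np.linalg.norm(step) < 1e-10:
            converged = True
            break
    if not converged and np.linalg.norm(grad) >= grad_tol:
        raise ConvergenceError(
            f"Newton iterations did not converge in {max_iter} steps "
            f"(gradient norm {np.linalg.norm(grad):.3g})"
        )

    cond = np.linalg.cond(info)
    if cond > 1e8:
        logger.warning("ill-conditioned information matrix (cond %.3g)", cond)
    cov = np.linalg.inv(info)
    se_beta = np.sqrt(np.diag(cov))
    z = beta / se_beta
    zcrit = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "ci_lower": np.exp(beta - zcrit * se_beta),
            "ci_upper": np.exp(beta + zcrit * se_beta),
            "se": se_beta,
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(names, name="covariate"),
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(loglik),
        n=n,
        n_events=int(e.sum()),
        ties=ties,
    )


def _design_from_cohort(
    df: pd.DataFrame,
    covariates: list[str],
    dichotomize: tuple[str, float] | None,
) -> tuple[pd.DataFrame, list[str]]:
    """Expand cohort columns into a numeric design matrix.

    Categorical stage columns are collapsed to the conventional contrasts
    (pT3-4 vs pT1-2, pN2-3 vs pN0-1, pM1 vs pM0, Stage III-IV vs Stage II);
    "x" stage categories (pTx etc.) become missing and are dropped
    complete-case by the caller.
    """
    cols = {}
    for cov in covariates:
        if cov == "age_years":
            cols["age_ge70"] = (df["age_years"] >= 70).astype(float)
        elif cov == "sex":
            cols["male"] = df["sex"].map({"male": 1.0, "female": 0.0})
        elif cov == "pT":
            cols["pT3_4"] = df["pT"].map(
                {"pT1": 0.0, "pT2": 0.0, "pT3": 1.0, "pT4": 1.0}
            )
        elif cov == "pN":
            cols["pN2_3"] = df["pN"].map(
                {"pN0": 0.0, "pN1": 0.0, "pN2": 1.0, "pN3": 1.0}
            )
        elif cov == "pM":
            cols["pM1"] = df["pM"].map({"pM0": 0.0, "pM1": 1.0})
        elif cov == "pTNM":
            cols["stage_III_IV"] = df["pTNM"].map(
                {"Stage II": 0.0, "Stage III": 1.0, "Stage IV": 1.0}
            )
        elif cov == "lymphovascular_invasion":
            cols["lvi"] = pd.to_numeric(
                df["lymphovascular_invasion"], errors="coerce"
            )
        else:
            cols[cov] = pd.to_numeric(df[cov], errors="coerce")
    design = pd.DataFrame(cols, index=df.index)
    if dichotomize is not None:
        var, thr = dichotomize
        name = f"{var.replace('_pct', '')}_high"
        design[name] = (pd.to_numeric(df[var], errors="coerce") >= thr).astype(float)
        design.loc[df[var].isna(), name] = np.nan
    return design, list(design.columns)


def cox_fit(
    cohort: SurvivalCohort,
    covariates: list[str],
    dichotomize: tuple[str, float] | None = None,
    ties: str = "efron",
) -> CoxResult:
    """Fit a Cox model on cohort columns, expanding categoricals.

    ``covariates`` may name raw numeric columns or the clinical categoricals
    (``age_years``, ``sex``, ``pT``, ``pN``, ``pM``, ``pTNM``,
    ``lymphovascular_invasion``), which are expanded against their reference
    levels. ``dichotomize=(column, threshold)`` appends a binary
    at-or-above-threshold covariate. Rows with missing values in any model
    column are dropped (complete-case) with a logged count.
    """
    df = cohort.data
    design, names = _design_from_cohort(df, covariates, dichotomize)
    complete = design.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropping %d rows with missing covariate values", n_dropped)
    sub = df.loc[complete]
    if int(sub["event"].sum()) < 10:
        raise ValueError("Cox fit requires at least 10 events")
    return cox_ph(
        design.loc[complete].to_numpy(dtype=float),
        sub["time_months"].to_numpy(dtype=float),
        sub["event"].to_numpy(dtype=int),
        ties=ties,
        covariate_names=names,
    )


UNIVARIATE_FACTORS = (
    "age_years",
    "sex",
    "pT",
    "pN",
    "pM",
    "pTNM",
    "lymphovascular_invasion",
)
MULTIVARIATE_FACTORS = ("age_years", "pT", "pN", "pTNM", "lymphovascular_invasion")


def run_table2_models(
    cohort: SurvivalCohort,
    etils_variable: str = "eTILs_pct",
    etils_threshold: float = 13.2,
    ties: str = "efron",
) -> dict:
    """Univariate Cox fit per clinical factor plus one multivariate model.

    Univariate models cover age (>=70 vs <70), sex, pT (3-4 vs 1-2), pN (2-3
    vs 0-1), pM, pTNM stage (III-IV vs II), lymphovascular invasion and the
    dichotomized eTILs variable; the multivariate model jointly fits age, pT,
    pN, pTNM, LVI and eTILs. Returns
    ``{"univariate": {factor: CoxResult}, "multivariate": CoxResult}``.
    """
    univariate: dict[str, CoxResult] = {}
    for factor in UNIVARIATE_FACTORS:
        if factor not in cohort.data.columns:
            continue
        univariate[factor] = cox_fit(cohort, [factor], ties=ties)
    univariate["eTILs"] = cox_fit(
        cohort, [], dichotomize=(etils_variable, etils_threshold), ties=ties
    )
    multivariate = cox_fit(
        cohort,
        [f for f in MULTIVARIATE_FACTORS if f in cohort.data.columns],
        dichotomize=(etils_variable, etils_threshold),
        ties=ties,
    )
    return {"univariate": univariate, "multivariate": multivariate}
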