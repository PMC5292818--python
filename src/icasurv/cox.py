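"""Cox proportional-hazards fitting and the five-model chained suite.

The partial likelihood is maximised by Newton-Raphson with step-halving;
ties are handled by the Breslow approximation by default (Efron selectable).
Standard errors come from the inverse observed information at the optimum.

The model suite chains five fits: (1) structural-image features only,
(2) metabolic-image features only, (3) two-modality on the per-covariate
Wald-significant factors of (1)+(2), (4) clinical variables only,
(5) comprehensive on the significant factors of (3)+(4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "CoxModelResult",
    "SuiteResult",
    "fit_cox",
    "log_partial_likelihood",
    "hazard_ratio_ci",
    "wald_test",
    "significant_factors",
    "run_model_suite",
]

Z_95 = 1.959964  # 0.975 normal quantile used for 95% CIs


@dataclass
class CoxModelResult:
    """Per-covariate estimates plus fit diagnostics.

    ``summary`` columns: covariate, beta, se, z, p, hr, ci_low, ci_high.
    """

    summary: pd.DataFrame
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    n_subjects: int
    n_events: int
    tie_method: str
    message: str = ""

    @property
    def beta(self) -> pd.Series:
        return self.summary.set_index("covariate")["beta"]

    @property
    def se(self) -> pd.Series:
        return self.summary.set_index("covariate")["se"]

    @property
    def p(self) -> pd.Series:
        return self.summary.set_index("covariate")["p"]


def _prepare(covariates: pd.DataFrame, time, event):
    x = covariates.to_numpy(dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=bool)
    if x.shape[0] != t.size or t.size != d.size:
        raise ValueError("covariates, time and event lengths differ")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if d.sum() < 1:
        raise ValueError("at least one event is required to fit")
    sds = x.std(axis=0)
    constant = [c for c, s in zip(covariates.columns, sds) if s == 0]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if rank < x.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "collinear covariates: "
            f"{covariates.columns[i]!r} and {covariates.columns[j]!r} "
            f"(|r| = {abs(corr[i, j]):.3f})"
        )
    order = np.argsort(t, kind="stable")
    return x[order], t[order], d[order]


def _loglik_grad_hess(beta, x, t, d, tie_method):
    """Breslow/Efron log partial likelihood with gradient and Hessian.

    Inputs must be sorted by ascending time.  Risk sets are handled with
    suffix cumulative sums; event times are grouped for ties.
    """
    n, p = x.shape
    eta = x @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = np.einsum("i,ij,ik->ijk", w, x, x)
    # suffix sums: risk set of time t_i = subjects i..n-1 (ties included)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.flatnonzero(d[i:j]) + i
        m = ev.size
        if m:
            loglik += eta[ev].sum()
            grad += x[ev].sum(axis=0)
            if tie_method == "breslow" or m == 1:
                loglik -= m * np.log(s0[i])
                grad -= m * s1[i] / s0[i]
                hess -= m * (s2[i] / s0[i] - np.outer(s1[i], s1[i]) / s0[i] ** 2)
            else:  # efron
                wd = w[ev].sum()
                wd1 = wx[ev].sum(axis=0)
                wd2 = wxx[ev].sum(axis=0)
                for r in range(m):
                    f = r / m
                    a0 = s0[i] - f * wd
                    a1 = s1[i] - f * wd1
                    a2 = s2[i] - f * wd2
                    loglik -= np.log(a0)
                    grad -= a1 / a0
                    hess -= a2 / a0 - np.outer(a1, a1) / a0**2
        i = j
    return loglik, grad, hess


def log_partial_likelihood(
    beta, covariates: pd.DataFrame, time, event, tie_method: str = "breslow"
) -> float:
    """Evaluate the log partial likelihood at an arbitrary ``beta``."""
    x, t, d = _prepare(covariates, time, event)
    ll, _, _ = _loglik_grad_hess(np.asarray(beta, dtype=float), x, t, d, tie_method)
    return float(ll)


def fit_cox(
    covariates: pd.DataFrame,
    time,
    event,
    tie_method: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
    level: float = 0.95,
) -> CoxModelResult:
    """Maximum partial-likelihood Cox fit by Newton-Raphson with step-halving.

    ``covariates`` is a numeric DataFrame (one column per covariate), ``time``
    event/censoring times in months, ``event`` boolean event indicators.
    Raises named errors for constant or collinear covariates; monotone
    likelihood (risk separation) is flagged as non-convergence with a
    diagnostic message rather than raised.
    """
    if tie_method not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {tie_method!r}")
    x, t, d = _prepare(covariates, time, event)
    n, p = x.shape
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, x, t, d, tie_method)
    ll_null = ll
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving to guarantee monotone ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(cand, x, t, d, tie_method)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        if np.abs(beta * x.std(axis=0)).max() > 50:
            message = (
                "monotone partial likelihood (risk separation): "
                "coefficients diverging"
            )
            break
    if not converged and not message:
        message = f"no convergence in {max_iter} iterations (|score| = {np.linalg.norm(grad):.2e})"
    if message:
        warnings.warn(f"Cox fit: {message}", RuntimeWarning)

    cov_beta = np.linalg.pinv(-hess)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    rows = []
    for name, b, s in zip(covariates.columns, beta, se):
        z, pval = wald_test(b, s) if s > 0 else (np.nan, np.nan)
        hr, lo, hi = hazard_ratio_ci(b, s, level) if s > 0 else (np.exp(b), np.nan, np.nan)
        rows.append(
            {"covariate": name, "beta": b, "se": s, "z": z, "p": pval,
             "hr": hr, "ci_low": lo, "ci_high": hi}
        )
    return CoxModelResult(
        summary=pd.DataFrame(rows),
        loglik=float(ll),
        loglik_null=float(ll_null),
        n_iter=it,
        converged=converged,
        n_subjects=n,
        n_events=int(d.sum()),
        tie_method=tie_method,
        message=message,
    )


def hazard_ratio_ci(
    beta: float, se: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Hazard ratio ``exp(beta)`` with ``exp(beta -/+ z se)`` bounds."""
    if se <= 0:
        raise ValueError("se must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf((1 + level) / 2))
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def wald_test(beta: float, se: float) -> tuple[float, float]:
    """Wald statistic ``z = beta/se`` and two-sided normal p-value."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = beta / se
    p = float(special.erfc(abs(z) / np.sqrt(2.0)))
    return float(z), p


def significant_factors(result: CoxModelResult, alpha: float = 0.05) -> list[str]:
    """Covariate names with Wald ``p < alpha`` in a fitted model."""
    sig = result.summary[result.summary["p"] < alpha]
    return list(sig["covariate"])


@dataclass
class SuiteResult:
    """Five chained Cox models plus the covariates carried between stages."""

    models: dict[str, CoxModelResult | None] = field(default_factory=dict)
    carried_forward: dict[str, list[str]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    STAGES = ("structural", "metabolic", "two_modality", "clinical", "comprehensive")


def _align(tables: list[pd.DataFrame]) -> pd.DataFrame:
    joined = tables[0]
    for tab in tables[1:]:
        joined = joined.join(tab, how="inner")
    return joined


def run_model_suite(
    mri_features: pd.DataFrame,
    pet_features: pd.DataFrame,
    clinical: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
    tie_method: str = "breslow",
    carry_all_clinical: bool = False,
) -> SuiteResult:
    """Run the five-model chained Cox analysis.

    All feature tables are indexed (or indexable) by ``subject_id``;
    ``survival`` must carry ``time_months`` and ``event`` columns.  Stages
    with an empty covariate set are skipped with a logged reason.  With
    ``carry_all_clinical`` the comprehensive stage receives every clinical
    variable instead of only the stage-4-significant ones.
    """
    def keyed(df: pd.DataFrame) -> pd.DataFrame:
        if "subject_id" in df.columns:
            df = df.set_index("subject_id")
        return df

    mri = keyed(mri_features)
    pet = keyed(pet_features)
    clin = keyed(clinical).astype(float)
    surv = keyed(survival)
    all_cov = _align([mri, pet, clin])
    surv = surv.loc[all_cov.index]
    time, event = surv["time_months"], surv["event"].astype(bool)

    res = SuiteResult()

    def run_stage(name: str, cols: list[str]) -> CoxModelResult | None:
        if not cols:
            res.skipped[name] = "no covariates entered this stage"
            res.models[name] = None
            return None
        model = fit_cox(all_cov[cols], time, event, tie_method=tie_method)
        res.models[name] = model
        return model

    m1 = run_stage("structural", list(mri.columns))
    m2 = run_stage("metabolic", list(pet.columns))

    carried_img = []
    for m in (m1, m2):
        if m is not None:
            carried_img += significant_factors(m, alpha)
    res.carried_forward["two_modality"] = carried_img
    m3 = run_stage("two_modality", carried_img)

    m4 = run_stage("clinical", list(clin.columns))

    carried_comp = []
    if m3 is not None:
        carried_comp += significant_factors(m3, alpha)
    if carry_all_clinical:
        carried_comp += list(clin.columns)
    elif m4 is not None:
        carried_comp += significant_factors(m4, alpha)
    res.carried_forward["comprehensive"] = carried_comp
    run_stage("comprehensive", carried_comp)
    return res
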