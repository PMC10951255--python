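"""Survival association of subpopulations.

Cox partial likelihood is maximised by Newton iterations with Breslow tie
handling; robust sandwich variance clustered by patient supports the
count-process (multiple records per patient) pairwise comparisons. The
model-selection grid fits one joint Cox model of all admissible
cluster-presence indicators per (K, threshold) cell and ranks cells by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from msihetero.types import (
    RESPONSE_UNKNOWN,
    ClusterComposition,
    SurvivalRecord,
)

__all__ = [
    "CoxResult",
    "PresenceMatrix",
    "AICGrid",
    "cox_fit",
    "null_partial_loglik",
    "cox_score_test",
    "presence_matrix",
    "aic_grid",
    "km_estimate",
    "logrank_test",
    "pairwise_subpop_survival",
    "response_association",
    "heterogeneity_response_fisher",
]


class ConvergenceError(RuntimeError):
    """Raised when the partial likelihood has no finite maximiser."""


@dataclass
class CoxResult:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    aic: float
    converged: bool
    robust_se: np.ndarray | None = None
    n: int = 0
    n_events: int = 0

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def wald_p(self, robust: bool = False) -> np.ndarray:
        se = self.robust_se if robust else self.se
        z = self.beta / se
        return 2.0 * stats.norm.sf(np.abs(z))


def _risk_index(times_desc: np.ndarray) -> np.ndarray:
    """For descending-sorted times, index of the last row still in the risk
    set at each row's own time (ties share the full risk set)."""
    return np.searchsorted(-times_desc, -times_desc, side="right") - 1


def _breslow_loglik_grad_hess(X, times, events, beta):
    order = np.argsort(-times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w)
    S1 = np.cumsum(Xs * w[:, None], axis=0)
    S2 = np.cumsum(w[:, None, None] * Xs[:, :, None] * Xs[:, None, :], axis=0)
    r = _risk_index(ts)
    ev = es == 1
    re = r[ev]
    s0 = S0[re]
    m = S1[re] / s0[:, None]
    loglik = float(np.sum(eta[ev] - np.log(s0)))
    grad = (Xs[ev] - m).sum(axis=0)
    hess = -(S2[re] / s0[:, None, None] - m[:, :, None] * m[:, None, :]).sum(axis=0)
    return loglik, grad, hess


def null_partial_loglik(times: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood of the covariate-free model."""
    p0 = np.zeros(0)
    ll, _, _ = _breslow_loglik_grad_hess(
        np.zeros((len(times), 0)), np.asarray(times, float), np.asarray(events, int), p0
    )
    return ll


def _score_residuals(X, times, events, beta):
    """Per-record Breslow score residuals at ``beta`` (n x p)."""
    n, p = X.shape
    order = np.argsort(times, kind="stable")  # ascending
    Xs, ts, es = X[order], times[order], events[order]
    w = np.exp(np.clip(Xs @ beta, -500, 500))
    # risk-set sums: suffix sums over ascending order with tie grouping
    S0_suf = np.cumsum(w[::-1])[::-1]
    S1_suf = np.cumsum((Xs * w[:, None])[::-1], axis=0)[::-1]
    first_in_group = np.searchsorted(ts, ts, side="left")
    R0 = S0_suf[first_in_group]
    R1 = S1_suf[first_in_group]
    m = R1 / R0[:, None]
    # cumulative hazard-increment sums over event times <= t_i
    ev = es == 1
    a = np.zeros(n)
    a[ev] = 1.0 / R0[ev]
    b = np.zeros((n, p))
    b[ev] = m[ev] / R0[ev][:, None]
    # include all events with time <= own time (full tie group)
    last_in_group = np.searchsorted(ts, ts, side="right") - 1
    cumA = np.cumsum(a)[last_in_group]
    cumB = np.cumsum(b, axis=0)[last_in_group]
    U = np.where(ev[:, None], Xs - m, 0.0) - w[:, None] * (Xs * cumA[:, None] - cumB)
    out = np.empty_like(U)
    out[order] = U
    return out


def cox_fit(
    covariates: np.ndarray,
    surv: Sequence[SurvivalRecord] | None = None,
    *,
    times: np.ndarray | None = None,
    events: np.ndarray | None = None,
    cluster: Sequence | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxResult:
    """Maximum partial likelihood Cox fit (Breslow ties, Newton iterations).

    ``surv`` may be given instead of ``times``/``events``. A constant
    covariate column is inadmissible and raises ValueError. ``cluster``
    labels enable the robust sandwich variance grouped by patient.
    Monotone-likelihood divergence is reported via ``converged=False``.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if surv is not None:
        times = np.array([r.time for r in surv], dtype=float)
        events = np.array([r.event for r in surv], dtype=int)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    if n != times.size:
        raise ValueError("covariate rows must match number of patients")
    if p < 1:
        raise ValueError("at least one covariate required")
    if events.sum() < 1:
        raise ValueError("at least one event required")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate column is inadmissible")

    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _breslow_loglik_grad_hess(X, times, events, beta)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        new_beta = beta - step
        # step-halving to guarantee ascent
        for _ in range(30):
            ll_new, _, _ = _breslow_loglik_grad_hess(X, times, events, new_beta)
            if ll_new >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        beta = new_beta
        if np.max(np.abs(beta)) > 15:
            break  # monotone likelihood: no finite maximiser
        if abs(ll_new - ll_old) < tol and np.max(np.abs(grad)) < 1e-6:
            converged = True
            break
        ll_old = ll_new

    ll, grad, hess = _breslow_loglik_grad_hess(X, times, events, beta)
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information matrix") from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    aic = 2.0 * p - 2.0 * ll
    robust_se = None
    if cluster is not None:
        U = _score_residuals(X, times, events, beta)
        groups = pd.Series(range(n)).groupby(list(cluster)).indices
        B = np.zeros((p, p))
        for idx in groups.values():
            s = U[list(idx)].sum(axis=0)
            B += np.outer(s, s)
        V = cov @ B @ cov
        robust_se = np.sqrt(np.maximum(np.diag(V), 0.0))
    return CoxResult(
        beta=beta,
        se=se,
        loglik=float(ll),
        aic=float(aic),
        converged=converged,
        robust_se=robust_se,
        n=n,
        n_events=int(events.sum()),
    )


def cox_score_test(covariate: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Score (Rao) test of a single covariate at beta = 0.

    Returns ``(chi2, p)``; on untied data this equals the two-group log-rank
    test when the covariate is a group indicator.
    """
    X = np.asarray(covariate, dtype=float).reshape(-1, 1)
    _, grad, hess = _breslow_loglik_grad_hess(
        X, np.asarray(times, float), np.asarray(events, int), np.zeros(1)
    )
    info = -hess[0, 0]
    if info <= 0:
        return 0.0, 1.0
    chi2 = float(grad[0] ** 2 / info)
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# presence thresholding and the AIC model-selection grid


@dataclass
class PresenceMatrix:
    """Binary patients x K matrix: share strictly above ``threshold``."""

    threshold: float
    patient_ids: list[str]
    matrix: np.ndarray

    @property
    def admissible(self) -> np.ndarray:
        """Columns usable as Cox covariates (neither all 0 nor all 1)."""
        col = self.matrix
        return (col.sum(axis=0) > 0) & (col.sum(axis=0) < col.shape[0])

    def members(self, cluster: int) -> list[str]:
        """Patient ids assigned to 1-based ``cluster``."""
        mask = self.matrix[:, cluster - 1] == 1
        return [pid for pid, m in zip(self.patient_ids, mask) if m]


def presence_matrix(
    compositions: Sequence[ClusterComposition], threshold: float
) -> PresenceMatrix:
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    comps = sorted(compositions, key=lambda c: c.patient_id)
    mat = np.stack([(c.shares > threshold).astype(int) for c in comps])
    return PresenceMatrix(threshold, [c.patient_id for c in comps], mat)


@dataclass
class AICGrid:
    entries: pd.DataFrame  # columns: k, threshold, aic, n_admissible, converged
    optimum: tuple[int, float]  # (K*, threshold*)
    null_aic: float
    metadata: dict = field(default_factory=dict)

    def scaled(self) -> pd.DataFrame:
        """Grid with AIC min-max scaled to [0, 1] (heat-map analogue)."""
        df = self.entries.copy()
        ok = df["converged"]
        lo, hi = df.loc[ok, "aic"].min(), df.loc[ok, "aic"].max()
        span = hi - lo if hi > lo else 1.0
        df["aic_scaled"] = (df["aic"] - lo) / span
        return df


def aic_grid(
    compositions_by_k: dict[int, Sequence[ClusterComposition]],
    surv: Sequence[SurvivalRecord],
    thresholds: Iterable[float] | None = None,
) -> AICGrid:
    """Fit one joint Cox model per (K, threshold) cell and rank by AIC.

    Each model contains every admissible cluster-presence indicator of that
    segmentation; cells with no admissible indicator score the null model's
    AIC. Ties at the optimum break toward smaller K, then smaller threshold.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.04, 0.401, 0.02), 10)
    surv = sorted(surv, key=lambda r: r.patient_id)
    times = np.array([r.time for r in surv])
    events = np.array([r.event for r in surv])
    ll0 = null_partial_loglik(times, events)
    null_aic = -2.0 * ll0
    rows = []
    for k in sorted(compositions_by_k):
        comps = compositions_by_k[k]
        ids = sorted(c.patient_id for c in comps)
        if ids != [r.patient_id for r in surv]:
            raise ValueError("composition and survival patient sets differ")
        for t in thresholds:
            pm = presence_matrix(comps, float(t))
            adm = pm.admissible
            n_adm = int(adm.sum())
            if n_adm == 0:
                rows.append((k, float(t), null_aic, 0, True))
                continue
            X = pm.matrix[:, adm].astype(float)
            # drop duplicated columns (identical indicators are collinear)
            _, uniq = np.unique(X.T, axis=0, return_index=True)
            X = X[:, np.sort(uniq)]
            try:
                fit = cox_fit(X, times=times, events=events)
            except (ConvergenceError, ValueError):
                rows.append((k, float(t), np.nan, n_adm, False))
                continue
            rows.append((k, float(t), fit.aic, X.shape[1], fit.converged))
    df = pd.DataFrame(rows, columns=["k", "threshold", "aic", "n_admissible", "converged"])
    ok = df[df["converged"] & df["aic"].notna()]
    if ok.empty:
        raise ConvergenceError("no (K, threshold) cell converged")
    best = ok.sort_values(["aic", "k", "threshold"], kind="stable").iloc[0]
    grid = AICGrid(
        entries=df,
        optimum=(int(best["k"]), float(best["threshold"])),
        null_aic=float(null_aic),
        metadata={
            "best_aic": float(best["aic"]),
            "delta_vs_null": float(best["aic"] - null_aic),
            "selection_note": "optimum chosen over the full grid; AIC differences "
            "near 0 vs the null model indicate no real signal",
        },
    )
    return grid


# ---------------------------------------------------------------------------
# nonparametric survival comparisons


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a frame with one row per distinct event time: columns ``time``,
    ``n_risk``, ``n_events``, ``survival`` (right-continuous step values).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order]
    rows = []
    s = 1.0
    n = ts.size
    i = 0
    while i < n:
        t = ts[i]
        j = i
        d = 0
        while j < n and ts[j] == t:
            d += es[j]
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append((t, at_risk, d, s))
        i = j
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "survival"])


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    ea = np.asarray(events_a, int)
    eb = np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O = E = V = 0.0
    for t in event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n < 2 or n1 == 0 or n2 == 0:
            continue
        O += d1
        E += d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V <= 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def pairwise_subpop_survival(
    presence: PresenceMatrix,
    surv: Sequence[SurvivalRecord],
    min_members: int = 3,
) -> pd.DataFrame:
    """Wald p-value per cluster pair from the count-process comparison.

    One record is stacked per patient-membership (a patient present in both
    clusters contributes two records); the Cox fit of the group indicator
    uses the robust sandwich variance clustered by patient.
    """
    by_id = {r.patient_id: r for r in surv}
    k = presence.matrix.shape[1]
    rows = []
    for i in range(1, k + 1):
        for j in range(i, k + 1):
            mi = [p for p in presence.members(i) if p in by_id]
            mj = [p for p in presence.members(j) if p in by_id]
            if i == j:
                rows.append((i, j, np.nan, 1.0, len(mi), len(mj), "degenerate"))
                continue
            ev_i = sum(by_id[p].event for p in mi)
            ev_j = sum(by_id[p].event for p in mj)
            if len(mi) < min_members or len(mj) < min_members or ev_i < 1 or ev_j < 1:
                rows.append((i, j, np.nan, np.nan, len(mi), len(mj), "insufficient"))
                continue
            ids = mi + mj
            grp = np.array([0.0] * len(mi) + [1.0] * len(mj))
            times = np.array([by_id[p].time for p in ids])
            events = np.array([by_id[p].event for p in ids])
            try:
                fit = cox_fit(grp.reshape(-1, 1), times=times, events=events, cluster=ids)
            except (ConvergenceError, ValueError):
                rows.append((i, j, np.nan, np.nan, len(mi), len(mj), "non-convergent"))
                continue
            p_wald = float(fit.wald_p(robust=True)[0])
            rows.append((i, j, float(fit.beta[0]), p_wald, len(mi), len(mj), "ok"))
    return pd.DataFrame(
        rows, columns=["cluster_i", "cluster_j", "log_hr", "wald_p", "n_i", "n_j", "status"]
    )


def response_association(
    presence_column: np.ndarray, response: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation of binary cluster presence with binary response.

    Patients with unknown response are excluded by the caller or via the
    RESPONSE_UNKNOWN sentinel. For binary-binary data rho equals the phi
    coefficient.
    """
    pres = np.asarray(presence_column)
    resp = np.asarray(response)
    keep = resp != RESPONSE_UNKNOWN
    pres, resp = pres[keep], resp[keep]
    if np.unique(resp).size < 2:
        raise ValueError("need at least 2 patients in each response class")
    if np.unique(pres).size < 2:
        raise ValueError("degenerate presence column (all identical)")
    rho, p = stats.spearmanr(pres, resp)
    return float(rho), float(p)


def heterogeneity_response_fisher(
    groups: Sequence[str], response: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Fisher exact test of the high/low split against response.

    Returns (odds ratio, two-sided p, 2x2 table) where the table rows are
    high/low heterogeneity and columns sensitive/resistant.
    """
    groups = np.asarray(groups)
    resp = np.asarray(response)
    keep = resp != RESPONSE_UNKNOWN
    groups, resp = groups[keep], resp[keep]
    table = np.array(
        [
            [int(((groups == "high") & (resp == 1)).sum()), int(((groups == "high") & (resp == 0)).sum())],
            [int(((groups == "low") & (resp == 1)).sum()), int(((groups == "low") & (resp == 0)).sum())],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table
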