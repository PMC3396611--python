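"""Genome-wide univariate Cox screening with robust variance and FDR statistics.

For every feature, normalized expression is standardized to unit SD and a
single-covariate Cox proportional-hazards model is fit by Newton iteration on
the partial likelihood (Efron tie handling by default, Breslow switchable).
Reported per feature:

* ``beta`` — log hazard per 1-SD increase in expression, and ``shr`` =
  exp(beta), the standardized hazard ratio;
* ``robust_se`` — the Lin–Wei sandwich standard error, I^-1 (sum W_i^2) I^-1
  with W_i the per-subject score residuals, robust to non-proportional
  hazards and nonlinearity;
* ``p`` — two-sided Wald p from beta / robust_se. The reference distribution
  is Student t with (number of events - 1) degrees of freedom rather than
  the normal: the sandwich variance is informed by only as many independent
  contributions as there are events, and with few events (26 in the emulated
  cohort) a normal reference is anti-conservative in exactly the far tail a
  genome-wide screen reads, breaking FDR control on null data. A normal
  reference remains available (``wald_reference="normal"``);
* ``q`` — Storey q-value with tuning parameter lambda (default 0.5);
* ``tdrda_lower_bound`` — the maximum lower bound B such that the feature
  belongs to the set declared to have |SHR| > B while controlling FDR at 10%
  (true-discovery degree-of-association sets);
* ``shr_rtm`` — the standardized hazard ratio after empirical-Bayes
  normal–normal shrinkage correcting selection-induced regression to the mean.

The solver is vectorized across features (all features share one risk-set
ordering), which is what makes the 20k-feature screens and the replicated
simulation suites tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

DEFAULT_TDRDA_GRID = tuple(np.round(np.arange(1.00, 2.0001, 0.05), 2))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def standardize_expression(values: np.ndarray) -> np.ndarray:
    """Center and scale to unit SD (n-1 denominator). Constant input raises."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if not sd > 0:
        raise ValueError("constant feature: SD is zero, cannot standardize")
    return (values - values.mean()) / sd


# ---------------------------------------------------------------------------
# Cox partial likelihood, vectorized across features
# ---------------------------------------------------------------------------


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[:, ::-1], axis=1)[:, ::-1]


@dataclass
class _RiskSets:
    """Time-ordered layout shared by all features of one screen."""

    order: np.ndarray          # sample permutation: ascending time
    event_sorted: np.ndarray   # bool, in sorted order
    group_start: np.ndarray    # risk-set start index per unique event time
    group_members: list[np.ndarray]  # event positions per unique event time


def _risk_sets(time: np.ndarray, event: np.ndarray) -> _RiskSets:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if event.sum() == 0:
        raise ValueError("no events: Cox model is undefined")
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    starts: list[int] = []
    members: list[np.ndarray] = []
    ev_pos = np.flatnonzero(d)
    for et in np.unique(t[ev_pos]):
        starts.append(int(np.searchsorted(t, et, side="left")))
        members.append(ev_pos[t[ev_pos] == et])
    return _RiskSets(order, d, np.array(starts), members)


def _loglik_grad_hess(
    beta: np.ndarray, z: np.ndarray, rs: _RiskSets, ties: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partial log-likelihood, gradient and Hessian per feature (m-vectors).

    ``z`` is the (m features x n samples) covariate matrix already permuted to
    ascending-time order.
    """
    w = np.exp(beta[:, None] * z)
    wz = w * z
    r0 = _revcumsum(w)
    r1 = _revcumsum(wz)
    r2 = _revcumsum(wz * z)
    d = rs.event_sorted
    ll = (beta[:, None] * z)[:, d].sum(axis=1)
    grad = z[:, d].sum(axis=1)
    hess = np.zeros_like(beta)
    for start, members in zip(rs.group_start, rs.group_members):
        S0, S1, S2 = r0[:, start], r1[:, start], r2[:, start]
        k = len(members)
        if ties == "breslow" or k == 1:
            ll -= k * np.log(S0)
            grad -= k * S1 / S0
            hess -= k * (S2 / S0 - (S1 / S0) ** 2)
        else:  # efron
            s0d = w[:, members].sum(axis=1)
            s1d = wz[:, members].sum(axis=1)
            s2d = (wz * z)[:, members].sum(axis=1)
            for l in range(k):
                f = l / k
                D0 = S0 - f * s0d
                D1 = S1 - f * s1d
                D2 = S2 - f * s2d
                ll -= np.log(D0)
                grad -= D1 / D0
                hess -= D2 / D0 - (D1 / D0) ** 2
    return ll, grad, hess


def _wald_sf(z: np.ndarray, n_events: int, reference: str) -> np.ndarray:
    """One-sided upper tail of the Wald statistic under the chosen reference."""
    if reference == "t-events" and n_events > 1:
        return t_dist.sf(z, df=n_events - 1)
    if reference in ("normal", "t-events"):
        return norm.sf(z)
    raise ValueError("wald_reference must be 't-events' or 'normal'")


def cox_screen_matrix(
    z_matrix: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
    wald_reference: str = "t-events",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit every row of ``z_matrix`` as a univariate Cox covariate.

    Returns (beta, robust_se, p, converged) arrays of length m. Newton
    iteration from beta=0 with step halving, to relative tolerance ``tol``.
    The Wald p uses a t reference with df = events - 1 by default (see
    module docstring).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    z_matrix = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    rs = _risk_sets(time, event)
    z = z_matrix[:, rs.order]
    m = z.shape[0]
    beta = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    ll, grad, hess = _loglik_grad_hess(beta, z, rs, ties)
    for _ in range(max_iter):
        info = -hess
        step = np.where(info > 0, grad / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -2.0, 2.0)  # guard against overshoot on flat likelihoods
        newly = np.abs(step) < tol * (1.0 + np.abs(beta))
        converged |= newly
        if converged.all():
            break
        beta = beta + np.where(converged, 0.0, step)
        new_ll, new_grad, new_hess = _loglik_grad_hess(beta, z, rs, ties)
        # step halving where the likelihood worsened
        for _h in range(30):
            worse = (~converged) & (new_ll < ll - 1e-12)
            if not worse.any():
                break
            beta = np.where(worse, beta - step / 2, beta)
            step = np.where(worse, step / 2, step)
            new_ll, new_grad, new_hess = _loglik_grad_hess(beta, z, rs, ties)
        ll, grad, hess = new_ll, new_grad, new_hess
    robust_se = _lin_wei_se(beta, z, rs, hess)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(robust_se > 0, beta / robust_se, 0.0)
    n_events = int(np.asarray(event).astype(bool).sum())
    p = 2.0 * _wald_sf(np.abs(zstat), n_events, wald_reference)
    return beta, robust_se, p, converged


def _lin_wei_se(
    beta: np.ndarray, z: np.ndarray, rs: _RiskSets, hess: np.ndarray
) -> np.ndarray:
    """Lin–Wei sandwich SE: sqrt(I^-2 * sum_i W_i^2), W_i the score residuals.

    Score residuals use Breslow-style martingale increments at each event
    time; with continuous (untied) survival times this is exact.
    """
    m, n = z.shape
    w = np.exp(beta[:, None] * z)
    inc0 = np.zeros((m, n))
    inc1 = np.zeros((m, n))
    xbar_at = {}
    r0 = _revcumsum(w)
    r1 = _revcumsum(w * z)
    for start, members in zip(rs.group_start, rs.group_members):
        S0, S1 = r0[:, start], r1[:, start]
        xbar = S1 / S0
        k = len(members)
        inc0[:, start] += k / S0
        inc1[:, start] += k * xbar / S0
        for pos in members:
            xbar_at[int(pos)] = xbar
    H0 = np.cumsum(inc0, axis=1)
    H1 = np.cumsum(inc1, axis=1)
    U = -w * (z * H0 - H1)
    for pos, xbar in xbar_at.items():
        U[:, pos] += z[:, pos] - xbar
    bread = np.maximum(-hess, 1e-300)
    var = (U**2).sum(axis=1) / bread**2
    return np.sqrt(var)


def cox_univariate(
    z: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str = "efron"
) -> tuple[float, float, float]:
    """Single-feature convenience wrapper: returns (beta, robust_se, p)."""
    beta, se, p, conv = cox_screen_matrix(np.asarray(z)[None, :], time, event, ties=ties)
    if not conv[0]:
        raise RuntimeError("Cox Newton iteration did not converge")
    return float(beta[0]), float(se[0]), float(p[0])


# ---------------------------------------------------------------------------
# Storey FDR
# ---------------------------------------------------------------------------


def storey_qvalues(pvals: np.ndarray, lam: float = 0.5) -> tuple[np.ndarray, float]:
    """Storey q-values: pi0 = #{p > lam} / ((1-lam) m), clipped to (0, 1].

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j (monotone enforcement). Returns
    (q-values in input order, pi0 estimate).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0, 1)")
    m = p.size
    pi0 = (p > lam).sum() / ((1.0 - lam) * m)
    pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


# ---------------------------------------------------------------------------
# TDRDA sets
# ---------------------------------------------------------------------------


def tdrda_lower_bounds(
    beta: np.ndarray,
    robust_se: np.ndarray,
    fdr: float = 0.10,
    grid: tuple[float, ...] = DEFAULT_TDRDA_GRID,
    lam: float = 0.5,
    n_events: int | None = None,
    wald_reference: str = "t-events",
) -> np.ndarray:
    """Maximum SHR lower bound at which each feature stays FDR-significant.

    For each bound B >= 1 a shifted Wald test of H0: |beta| <= log B is run in
    each direction (p_B = 2 * (1 - Phi((|beta| - log B)/se)), capped at 1, the
    two-direction screen; at B = 1 this reduces exactly to the two-sided Wald
    p). Storey q-values are computed per bound; a feature is in the B-set iff
    q_B < fdr. Returns each feature's maximum qualifying B, NaN if it is not
    even in the B = 1 set. Membership is monotone: qualifying at B implies
    qualifying at every smaller bound. Supplying ``n_events`` applies the
    same small-sample t reference as the screen; without it the reference is
    normal.
    """
    grid = tuple(grid)
    if not grid or any(b < 1.0 for b in grid) or list(grid) != sorted(grid):
        raise ValueError("grid must be sorted ascending and start at >= 1.0")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(robust_se, dtype=float)
    bound = np.full(beta.shape, np.nan)
    reference = wald_reference if n_events is not None else "normal"
    df_events = n_events if n_events is not None else 2
    for b in grid:
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = np.where(se > 0, (np.abs(beta) - np.log(b)) / se, -np.inf)
        p_b = np.minimum(1.0, 2.0 * _wald_sf(zstat, df_events, reference))
        q_b, _ = storey_qvalues(p_b, lam=lam)
        member = q_b < fdr
        bound[member] = b
    return bound


# ---------------------------------------------------------------------------
# Regression-to-the-mean correction
# ---------------------------------------------------------------------------


def rtm_correct(beta: np.ndarray, robust_se: np.ndarray) -> np.ndarray:
    """Empirical-Bayes normal–normal shrinkage of the screen estimates.

    The between-feature effect variance is tau^2 = max(0, Var(beta) -
    mean(se^2)); each estimate is pulled toward the grand mean by the factor
    tau^2 / (tau^2 + se_i^2). With tau^2 = 0 (pure noise) everything collapses
    to the mean; with negligible SEs nothing moves. Corrects the upward bias
    of top-ranked effects selected from a genome-wide screen.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(robust_se, dtype=float)
    if beta.size < 10:
        raise ValueError("RTM correction needs >= 10 features to estimate tau^2")
    mu = beta.mean()
    tau2 = max(0.0, beta.var(ddof=1) - float(np.mean(se**2)))
    shrink = tau2 / (tau2 + se**2) if tau2 > 0 else np.zeros_like(se)
    return mu + (beta - mu) * shrink


# ---------------------------------------------------------------------------
# Full screen
# ---------------------------------------------------------------------------


def screen(
    values: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    fdr: float = 0.10,
    lam: float = 0.5,
    ties: str = "efron",
    tdrda_grid: tuple[float, ...] = DEFAULT_TDRDA_GRID,
) -> tuple[pd.DataFrame, float, list[str]]:
    """Screen every feature (row) of a normalized matrix against survival.

    Returns (result table, pi0 estimate, excluded feature IDs). Constant
    features are excluded with a reason rather than fit. The result table has
    columns feature_id, beta, robust_se, shr, p, q, tdrda_lower_bound,
    shr_rtm, converged.
    """
    arr = values.to_numpy(dtype=float)
    sds = arr.std(axis=1, ddof=1)
    keep = sds > 0
    excluded = [f"{fid}: constant expression" for fid in values.index[~keep]]
    arr = arr[keep]
    if arr.shape[0] == 0:
        raise ValueError("no non-constant features to screen")
    z = (arr - arr.mean(axis=1, keepdims=True)) / sds[keep][:, None]
    beta, robust_se, p, converged = cox_screen_matrix(z, time, event, ties=ties)
    q, pi0 = storey_qvalues(p, lam=lam)
    n_events = int(np.asarray(event).astype(bool).sum())
    bounds = tdrda_lower_bounds(
        beta, robust_se, fdr=fdr, grid=tdrda_grid, lam=lam, n_events=n_events
    )
    beta_rtm = rtm_correct(beta, robust_se) if beta.size >= 10 else beta.copy()
    table = pd.DataFrame(
        {
            "feature_id": values.index[keep],
            "beta": beta,
            "robust_se": robust_se,
            "shr": np.exp(beta),
            "p": p,
            "q": q,
            "tdrda_lower_bound": bounds,
            "shr_rtm": np.exp(beta_rtm),
            "converged": converged,
        }
    ).set_index("feature_id")
    return table, pi0, excluded
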