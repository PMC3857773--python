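"""Clinical layer: relative-expression group comparisons, Kaplan-Meier
estimation, log-rank testing, single-covariate Cox proportional hazards,
and the percentile-scan optimal-cutoff procedure.

The cutoff scan dichotomizes a cohort at every integer expression
percentile between the quartiles and keeps the best-separating split.
Because that selection step is itself a multiple test over ~51 correlated
cutoffs, the scan reports both the nominal minimum p (the conventional
"optimal cutoff" result) and a permutation-adjusted p that restores
calibration: the covariate is shuffled against the fixed survival data and
the observed minimum is referred to the distribution of permuted minima.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, SurvivalTable, ValidationError

logger = logging.getLogger("netmra")


# ------------------------------------------------------------ expression ops

def relative_expression(expr: ExpressionMatrix, gene: str) -> np.ndarray:
    """Per-sample expression divided by the gene's mean across all samples
    (so the output has mean exactly 1)."""
    values = expr.row(gene)
    mean = values.mean()
    if mean == 0:
        raise ValidationError(f"gene {gene!r} has zero mean expression")
    return values / mean


def pairwise_group_tests(values: np.ndarray, groups) -> pd.DataFrame:
    """All pairwise two-tailed Welch t-tests between labeled groups.

    Correction rule: Bonferroni when there are at most 4 groups, BH when
    there are more. Both raw and corrected p-values are reported.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    by_label = {g: values[groups == g] for g in labels}
    for g, v in by_label.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")

    rows = []
    for g1, g2 in combinations(labels, 2):
        t, p = stats.ttest_ind(by_label[g1], by_label[g2], equal_var=False)
        rows.append({"group1": g1, "group2": g2, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    if len(labels) <= 4:
        method = "bonferroni"
    else:
        method = "fdr_bh"
    df["p_corrected"] = multipletests(df["p"], method=method)[1]
    df["correction"] = method
    return df


# -------------------------------------------------------------- Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray


def km_estimate(table: SurvivalTable) -> KMCurve:
    """Kaplan-Meier estimator S(t) = prod(1 - d_i/n_i) over event times,
    with Greenwood variance. Records censored at an event time remain at
    risk for the events at that time."""
    order = np.argsort(table.time, kind="stable")
    t = table.time[order]
    e = table.event[order]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        logger.warning("no events: Kaplan-Meier curve is flat at 1")
        empty = np.array([])
        return KMCurve(empty, empty, empty, empty, empty)
    # at risk at u: all records with time >= u (ties: censored stay at risk)
    n_at_risk = t.size - np.searchsorted(t, event_times, side="left")
    d = np.array([np.sum((t == u) & (e == 1)) for u in event_times], dtype=float)
    survival = np.cumprod(1.0 - d / n_at_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf)
        var = survival**2 * np.cumsum(terms)
    var = np.where(survival == 0, 0.0, var)
    return KMCurve(event_times, n_at_risk.astype(float), d, survival, var)


# ------------------------------------------------------------------ log-rank

def _logrank_many(time: np.ndarray, event: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Log-rank chi-square (df=1) for each column of the 0/1 group-indicator
    matrix ``z`` (n x m), vectorized over columns."""
    n = time.size
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(float)
    zs = z[order].astype(float)
    starts = np.r_[0, 1 + np.nonzero(np.diff(t))[0]]  # first row of each unique time
    n_u = n - starts  # at risk per unique time
    d_u = np.add.reduceat(e, starts)  # events per unique time

    # group-1 at risk: suffix sums of zs evaluated at block starts
    csum = np.cumsum(zs, axis=0)
    total = csum[-1]
    before = np.vstack([np.zeros_like(total), csum[:-1]])
    n1_u = total[None, :] - before[starts]  # (n_times, m)
    d1_u = np.add.reduceat(e[:, None] * zs, starts, axis=0)

    frac = n1_u / n_u[:, None]
    o_minus_e = (d1_u - d_u[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = (
            d_u[:, None] * frac * (1.0 - frac)
            * ((n_u - d_u) / np.maximum(n_u - 1.0, 1.0))[:, None]
        )
    var = v_terms.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(var > 0, o_minus_e**2 / var, 0.0)
    return chi2


def logrank_test(table_a: SurvivalTable, table_b: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic df=1, p-value)."""
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValidationError("both groups must be non-empty")
    time = np.r_[table_a.time, table_b.time]
    event = np.r_[table_a.event, table_b.event]
    if event.sum() == 0:
        raise ValidationError("log-rank test needs at least one event")
    z = np.r_[np.zeros(len(table_a)), np.ones(len(table_b))][:, None]
    chi2 = float(_logrank_many(time, event, z)[0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ----------------------------------------------------------------------- Cox

@dataclass
class CoxFit:
    beta: float
    se: float
    hazard_ratio: float
    wald_z: float
    p: float
    log_partial_likelihood: float
    n_events: int
    converged: bool
    diverged: bool
    n_iter: int


def _cox_blocks(table: SurvivalTable):
    order = np.argsort(table.time, kind="stable")
    t = table.time[order]
    e = table.event[order].astype(bool)
    x = table.covariate[order]
    event_times = np.unique(t[e])
    starts = np.searchsorted(t, event_times, side="left")
    # per event-time block: which rows are tied events at that time
    blocks = [np.nonzero((t == u) & e)[0] for u in event_times]
    return t, e, x, starts, blocks


def _cox_ll_grad_hess(beta: float, x, starts, blocks):
    """Efron partial log-likelihood and derivatives for one covariate."""
    w = np.exp(beta * x)
    wx = w * x
    wxx = wx * x
    # suffix sums give risk-set aggregates at each block start
    sw = np.cumsum(w[::-1])[::-1]
    swx = np.cumsum(wx[::-1])[::-1]
    swxx = np.cumsum(wxx[::-1])[::-1]

    ll = grad = hess = 0.0
    for start, idx in zip(starts, blocks):
        d = idx.size
        xd = x[idx]
        wd, wxd, wxxd = w[idx].sum(), wx[idx].sum(), wxx[idx].sum()
        ll += beta * xd.sum()
        frac = np.arange(d) / d
        a = sw[start] - frac * wd
        ax = swx[start] - frac * wxd
        axx = swxx[start] - frac * wxxd
        ll -= np.log(a).sum()
        r = ax / a
        grad += xd.sum() - r.sum()
        hess -= (axx / a - r**2).sum()
    return ll, grad, hess


def cox_fit(table: SurvivalTable, tie_method: str = "efron") -> CoxFit:
    """Single-covariate Cox proportional hazards by damped Newton iteration
    on the Efron partial likelihood (Breslow available via ``tie_method``).

    Converges when the Newton step falls below 1e-9 (max 50 iterations);
    the Wald standard error comes from the observed information. A monotone
    partial likelihood (perfect separation) is reported as ``diverged``.
    """
    if tie_method not in ("efron", "breslow"):
        raise ValidationError("tie_method must be 'efron' or 'breslow'")
    n_events = int(table.event.sum())
    if n_events < 2:
        raise ValidationError("Cox fit needs at least 2 events")
    if np.all(table.covariate == table.covariate[0]):
        raise ValidationError("covariate is constant")
    _, _, x, starts, blocks = _cox_blocks(table)
    if tie_method == "breslow":
        blocks = [idx for idx in blocks]  # same blocks; Breslow sets frac = 0
        ll_fn = lambda b: _breslow_ll_grad_hess(b, x, starts, blocks)
    else:
        ll_fn = lambda b: _cox_ll_grad_hess(b, x, starts, blocks)

    beta = 0.0
    ll, grad, hess = ll_fn(beta)
    converged = diverged = False
    it = 0
    for it in range(1, 51):
        step = -grad / hess if hess < 0 else np.sign(grad)
        # dampen: halve until the partial likelihood does not decrease
        for _ in range(40):
            new_beta = beta + step
            new_ll, new_grad, new_hess = ll_fn(new_beta)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if abs(beta) > 50:
            diverged = True
            logger.warning("Cox fit diverging (|beta| > 50): monotone likelihood")
            break
        if abs(step) < 1e-9:
            converged = True
            break
    se = float(1.0 / np.sqrt(-hess)) if hess < 0 else float("inf")
    wald = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(wald)))
    return CoxFit(float(beta), se, float(np.exp(beta)), float(wald), max(p, 5e-324),
                  float(ll), n_events, converged, diverged, it)


def _breslow_ll_grad_hess(beta: float, x, starts, blocks):
    w = np.exp(beta * x)
    wx = w * x
    wxx = wx * x
    sw = np.cumsum(w[::-1])[::-1]
    swx = np.cumsum(wx[::-1])[::-1]
    swxx = np.cumsum(wxx[::-1])[::-1]
    ll = grad = hess = 0.0
    for start, idx in zip(starts, blocks):
        d = idx.size
        xd = x[idx]
        a, ax, axx = sw[start], swx[start], swxx[start]
        ll += beta * xd.sum() - d * np.log(a)
        r = ax / a
        grad += xd.sum() - d * r
        hess -= d * (axx / a - r**2)
    return ll, grad, hess


def cox_score_test(table: SurvivalTable) -> tuple[float, float]:
    """Efron score test of beta = 0 for the single covariate:
    chi-square = U(0)^2 / I(0). With untied event times and a binary
    covariate this equals the log-rank statistic exactly."""
    _, _, x, starts, blocks = _cox_blocks(table)
    _, grad, hess = _cox_ll_grad_hess(0.0, x, starts, blocks)
    if hess >= 0:
        raise ValidationError("degenerate information at beta = 0")
    chi2 = grad**2 / (-hess)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# --------------------------------------------------------------- cutoff scan

@dataclass
class CutoffScanResult:
    scan: pd.DataFrame  # percentile, cutoff, n_low, n_high, chi2, p
    selected_percentile: int
    selected_cutoff: float
    selected_p: float
    adjusted_p: float
    n_permutations: int
    seed: int


def optimal_cutoff_scan(
    table: SurvivalTable,
    n_permutations: int = 1000,
    seed: int = 0,
    percentiles: range = range(25, 76),
) -> CutoffScanResult:
    """Scan every integer covariate percentile between the quartiles as a
    dichotomization cutoff, select the split with the smallest log-rank p,
    and correct the selection by permutation.

    Percentile cutoffs use the nearest-rank method. The adjusted p is the
    (add-one smoothed) fraction of covariate permutations whose own minimum
    scanned p is at most the observed minimum; it is floored at the nominal
    selected p, which the selection makes a lower bound by construction.
    """
    n = len(table)
    if n < 20:
        raise ValidationError("cutoff scan needs at least 20 samples")
    x = table.covariate
    if np.all(x == x[0]):
        raise ValidationError("covariate is constant")
    if table.event.sum() == 0:
        raise ValidationError("cutoff scan needs at least one event")

    x_sorted = np.sort(x)
    records = []
    indicators = []
    for q in percentiles:
        cutoff = x_sorted[int(np.ceil(q / 100.0 * n)) - 1]  # nearest rank
        high = x > cutoff
        n_high = int(high.sum())
        if n_high == 0 or n_high == n:
            continue
        records.append((q, float(cutoff), n - n_high, n_high))
        indicators.append(high)
    if not records:
        raise ValidationError("every scanned cutoff produced an empty group")

    g = np.column_stack(indicators).astype(float)
    chi2 = _logrank_many(table.time, table.event, g)
    pvals = stats.chi2.sf(chi2, df=1)
    scan = pd.DataFrame(records, columns=["percentile", "cutoff", "n_low", "n_high"])
    scan["chi2"] = chi2
    scan["p"] = pvals
    best = int(np.argmax(chi2))
    obs_max_chi2 = float(chi2[best])
    selected_p = float(pvals[best])

    # permutation adjustment: shuffle the covariate (i.e. the rows of the
    # indicator matrix) against the fixed survival data, re-run the scan,
    # and compare minima (via the equivalent maximum chi-square)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_permutations, 4_000_000 // (n * g.shape[1]) or 1))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        cols = []
        for _ in range(m):
            cols.append(g[rng.permutation(n)])
        big = np.hstack(cols)
        perm_chi2 = _logrank_many(table.time, table.event, big).reshape(m, g.shape[1])
        count += int(np.sum(perm_chi2.max(axis=1) >= obs_max_chi2))
        done += m
    adjusted = (1.0 + count) / (1.0 + n_permutations)
    adjusted = max(adjusted, selected_p)
    return CutoffScanResult(
        scan=scan,
        selected_percentile=int(scan["percentile"].iloc[best]),
        selected_cutoff=float(scan["cutoff"].iloc[best]),
        selected_p=selected_p,
        adjusted_p=float(adjusted),
        n_permutations=n_permutations,
        seed=seed,
    )
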