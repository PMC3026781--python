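"""Biomarker and outcome analysis: ROC cut-off tables, Kaplan-Meier,
log-rank and Cox proportional-hazards regression.

These are implemented directly (product-limit estimator, O-E/V log-rank,
Newton-Raphson partial likelihood with Breslow ties and step halving) so
the numerical contracts are explicit; library implementations serve as
independent cross-checks in the test suite, not as the computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RocTable:
    table: pd.DataFrame  # per cut-off: sensitivity, 1-specificity, ppv, npv, lr+, lr-, accuracy
    auc: float
    higher_is_positive: bool


def roc(values, labels, higher_is_positive: bool = True) -> RocTable:
    """ROC curve and per-cut-off diagnostic table.

    ``labels`` are binary (1 = disease); a marker may be oriented either
    way (e.g., a liver-abundant miRNA that *drops* in tumors uses
    ``higher_is_positive=False``).  Thresholds run over all distinct
    values; a case is called positive when its oriented value >= threshold.
    AUC is the trapezoid over the full curve, which equals the
    Mann-Whitney U statistic divided by n1*n2.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y)) < 2:
        raise ValueError("both labels must be present")
    s = v if higher_is_positive else -v
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    rows = []
    pts = [(0.0, 0.0)]
    for t in sorted(np.unique(s), reverse=True):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = n1 - tp
        tn = n0 - fp
        sens = tp / n1
        spec = tn / n0
        ppv = tp / (tp + fp) if tp + fp else np.nan
        npv = tn / (tn + fn) if tn + fn else np.nan
        lr_pos = sens / (1 - spec) if spec < 1 else np.inf
        lr_neg = (1 - sens) / spec if spec > 0 else np.inf
        rows.append(dict(cutoff=t if higher_is_positive else -t, sensitivity=sens,
                         one_minus_specificity=1 - spec, ppv=ppv, npv=npv,
                         lr_positive=lr_pos, lr_negative=lr_neg,
                         accuracy=(tp + tn) / (n0 + n1)))
        pts.append((1 - spec, sens))
    pts.append((1.0, 1.0))
    xs, ys = zip(*pts)
    auc = float(np.trapezoid(ys, xs))
    return RocTable(pd.DataFrame(rows), auc, higher_is_positive)


def km(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with right censoring.

    Returns one row per distinct event time: (time, n_risk, n_events,
    n_censored, survival).  At tied times deaths are counted before
    censorings (the standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    n = len(t)
    rows = []
    surv = 1.0
    at_risk = n
    i = 0
    while i < n:
        ti = t[i]
        d = int(((t == ti) & (e == 1)).sum())
        c = int(((t == ti) & (e == 0)).sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append(dict(time=ti, n_risk=at_risk, n_events=d, n_censored=c, survival=surv))
        at_risk -= d + c
        i += d + c
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "n_censored", "survival"])


def km_by_group(times, events, groups) -> dict:
    g = np.asarray(groups)
    out = {}
    for lab in np.unique(g):
        m = g == lab
        out[lab] = km(np.asarray(times)[m], np.asarray(events)[m])
    return out


def survival_at(km_table: pd.DataFrame, t: float) -> float:
    s = km_table[km_table.time <= t]
    return float(s.survival.iloc[-1]) if len(s) else 1.0


@dataclass
class LogrankResult:
    chi2: float
    p: float
    observed: np.ndarray
    expected: np.ndarray
    flagged: bool = False


def logrank(times, events, groups) -> LogrankResult:
    """Two-group log-rank test (O-E / V chi-square with 1 df)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labs = np.unique(g)
    if labs.size != 2:
        raise ValueError("log-rank requires exactly two groups")
    if e.sum() < 1:
        raise ValueError("at least one event required")
    o1 = e1 = v = 0.0
    obs = np.zeros(2)
    exp = np.zeros(2)
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = at_risk.sum()
        n1 = (at_risk & (g == labs[0])).sum()
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & (g == labs[0])).sum())
        o1 += d1
        e1_t = d * n1 / n
        e1 += e1_t
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        obs += [d1, d - d1]
        exp += [e1_t, d - e1_t]
    if v == 0:
        return LogrankResult(np.nan, np.nan, obs, exp, flagged=True)
    chi2 = (o1 - e1) ** 2 / v
    return LogrankResult(float(chi2), float(sps.chi2.sf(chi2, 1)), obs, exp)


@dataclass
class CoxResult:
    summary: pd.DataFrame  # coef, hr, se, z, p per covariate
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def coef(self) -> pd.Series:
        return self.summary["coef"]


def cox_fit(
    X: pd.DataFrame,
    times,
    events,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional hazards by Newton-Raphson on the partial likelihood.

    Breslow tie handling by default (Efron available).  Step halving keeps
    the partial log-likelihood non-decreasing; standard errors come from
    the inverse observed information; p-values are Wald.  Raises on
    non-convergence or monotone likelihood (perfect separation).
    """
    Xm = X.to_numpy(dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n, p = Xm.shape
    with_events = e == 1
    for j, c in enumerate(X.columns):
        if np.ptp(Xm[with_events, j]) == 0 and np.ptp(Xm[:, j]) == 0:
            raise ValueError(f"covariate {c} is constant")
    order = np.argsort(-t, kind="mergesort")  # decreasing time for risk-set sums
    Xs, ts, es = Xm[order], t[order], e[order]

    def loglik_grad_hess(beta):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _loglik_impl(beta)

    def _loglik_impl(beta):
        eta = Xs @ beta
        w = np.exp(np.minimum(eta, 700.0))
        # cumulative risk-set sums (times sorted decreasing)
        S0 = np.cumsum(w)
        S1 = np.cumsum(w[:, None] * Xs, axis=0)
        S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
        # risk set for time ti = all with t >= ti -> last index with ts >= ti
        ll = 0.0
        g = np.zeros(p)
        H = np.zeros((p, p))
        # iterate distinct times; risk set = prefix up to last tied index
        i = 0
        while i < n:
            j = i
            while j < n and ts[j] == ts[i]:
                j += 1
            D = [k for k in range(i, j) if es[k] == 1]
            if D:
                d = len(D)
                s0 = S0[j - 1]
                s1 = S1[j - 1]
                s2 = S2[j - 1]
                if ties == "breslow":
                    ll += eta[D].sum() - d * np.log(s0)
                    g += Xs[D].sum(axis=0) - d * s1 / s0
                    H -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
                else:  # efron
                    wD = w[D]
                    xD = Xs[D]
                    s0d = wD.sum()
                    s1d = (wD[:, None] * xD).sum(axis=0)
                    s2d = (wD[:, None, None] * (xD[:, :, None] * xD[:, None, :])).sum(axis=0)
                    ll += eta[D].sum()
                    for r in range(d):
                        f = r / d
                        a0 = s0 - f * s0d
                        a1 = s1 - f * s1d
                        a2 = s2 - f * s2d
                        ll -= np.log(a0)
                        g -= a1 / a0
                        H -= a2 / a0 - np.outer(a1, a1) / a0**2
                    g += xD.sum(axis=0)
            i = j
        return ll, g, H

    beta = np.zeros(p)
    ll, g, H = loglik_grad_hess(beta)
    trace = [ll]
    for it in range(max_iter):
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as err:
            raise RuntimeError("singular information matrix") from err
        # step halving: partial likelihood must not decrease
        alpha = 1.0
        for _ in range(30):
            nb = beta + alpha * step
            nll, ng, nH = loglik_grad_hess(nb)
            if nll >= ll - 1e-12:
                break
            alpha /= 2
        else:
            raise RuntimeError("step halving failed to improve the likelihood")
        beta, ll, g, H = nb, nll, ng, nH
        trace.append(ll)
        if np.abs(beta).max() > 50:
            raise RuntimeError(
                f"monotone likelihood (perfect separation?) on covariate "
                f"{X.columns[int(np.argmax(np.abs(beta)))]}"
            )
        # converged when the gradient vanishes or the update stalls (the
        # risk-set cumsums floor the attainable gradient near n * eps)
        if np.abs(g).max() < tol or np.abs(alpha * step).max() < tol:
            break
    else:
        raise RuntimeError("Cox Newton-Raphson did not converge")
    cov = np.linalg.inv(-H)
    diag = np.diag(cov)
    if not np.all(np.isfinite(diag)) or np.any(diag <= 0):
        worst = X.columns[int(np.nanargmin(diag))]
        raise RuntimeError(
            f"monotone likelihood (perfect separation?) on covariate {worst}: "
            "observed information is not positive definite"
        )
    se = np.sqrt(diag)
    z = beta / se
    pvals = 2 * sps.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {"coef": beta, "hr": np.exp(beta), "se": se, "z": z, "p": pvals}, index=X.columns
    )
    return CoxResult(summary, float(ll), trace, it + 1)
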