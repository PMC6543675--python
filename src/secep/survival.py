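"""Two-group survival statistics: Kaplan-Meier, log-rank, binary-covariate Cox.

The combination screen evaluates survival splits for up to millions of
candidate gene sets, so these routines are lean array implementations
specialised to the two-group case rather than wrappers around a general
survival library.  :class:`SurvivalData` pre-sorts a cohort once and caches
the risk-set bookkeeping; each candidate split then only supplies a boolean
group mask, and both the log-rank statistic and the Efron-tie Cox fit reduce
to a handful of vectorised passes over the distinct event times.

Conventions
-----------
* Times are in months and must be positive; zero times are shifted to half
  the smallest positive time (with a warning) so the risk set at the first
  event is well defined.
* The Cox model has a single binary covariate (altered vs not altered).
  Ties are handled with the Efron approximation and the confidence interval
  is Wald on the log-hazard scale with z = 1.959964.
* Monotone partial likelihoods (e.g. every event in one group before any in
  the other) are reported via ``converged=False`` with the hazard ratio at
  the boundary direction, never as an exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

Z_95 = 1.959964  # two-sided 95% normal quantile

__all__ = [
    "KmCurve",
    "LogrankResult",
    "CoxResult",
    "km_estimate",
    "SurvivalData",
    "logrank_test",
    "cox_binary_hr",
]


@dataclass
class KmCurve:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int
    n_events_total: int

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass
class LogrankResult:
    chi_square: float
    p: float
    observed: np.ndarray  # events per group (group0, group1)
    expected: np.ndarray


@dataclass
class CoxResult:
    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    se: float
    p: float
    converged: bool
    n_iter: int = 0


def _clean_times(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("no samples")
    if not np.all(np.isfinite(time)) or np.any(time < 0):
        raise ValueError("survival times must be finite and non-negative")
    if np.any(time == 0):
        pos = time[time > 0]
        if pos.size == 0:
            raise ValueError("all survival times are zero")
        shift = pos.min() / 2.0
        warnings.warn(f"zero survival times shifted to {shift:g}")
        time = np.where(time == 0, shift, time)
    return time, event


def km_estimate(time, event) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations reduce the risk set without producing a drop in
    the survival curve.  With no censoring the estimate coincides with the
    empirical survivor function.
    """
    time, event = _clean_times(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size
    ut = np.unique(t[e]) if e.any() else np.empty(0)
    left = np.searchsorted(t, ut, side="left")
    right = np.searchsorted(t, ut, side="right")
    at_risk = n - left
    ce = np.concatenate(([0], np.cumsum(e)))
    d = ce[right] - ce[left]
    surv = np.cumprod(1.0 - d / at_risk)
    return KmCurve(
        event_times=ut,
        survival=surv,
        at_risk=at_risk,
        n_events=d,
        n=n,
        n_events_total=int(e.sum()),
    )


class SurvivalData:
    """Pre-sorted survival cohort supporting repeated two-group tests.

    Parameters
    ----------
    time, event
        Follow-up in months and event indicator, in the caller's patient
        order.  Group masks passed to :meth:`logrank` / :meth:`cox` use the
        same order; the internal sort is transparent.
    """

    def __init__(self, time, event):
        time, event = _clean_times(time, event)
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order]
        self.n_events = int(self.event.sum())
        # distinct event times and risk-set bookkeeping
        ut = np.unique(self.time[self.event]) if self.n_events else np.empty(0)
        self._ut = ut
        self._left = np.searchsorted(self.time, ut, side="left")
        self._right = np.searchsorted(self.time, ut, side="right")
        self._n_at = self.n - self._left
        ce = np.concatenate(([0], np.cumsum(self.event)))
        self._d = ce[self._right] - ce[self._left]
        # Efron expansion: one row per (event time, within-tie index l),
        # with coefficient a = l/d.  Depends only on the tie pattern, so it
        # is shared by every candidate split of this cohort.
        d = self._d.astype(int)
        self._efron_t = np.repeat(np.arange(ut.size), d)
        if ut.size:
            offs = np.concatenate(([0], np.cumsum(d)))[:-1]
            l = np.arange(d.sum()) - np.repeat(offs, d)
            self._efron_a = l / np.repeat(d, d)
        else:
            self._efron_a = np.empty(0)

    # -- per-mask risk-set counts -------------------------------------
    def _group_counts(self, mask):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n,):
            raise ValueError("mask length does not match cohort size")
        g = mask[self.order]
        cg = np.concatenate(([0], np.cumsum(g)))
        g_at = int(g.sum()) - cg[self._left]  # group members still at risk
        ce1 = np.concatenate(([0], np.cumsum(g & self.event)))
        d1 = ce1[self._right] - ce1[self._left]  # group events at each time
        return g, g_at, d1

    def logrank(self, mask) -> LogrankResult:
        """Unweighted two-group log-rank test (hypergeometric variance)."""
        g, g_at, d1 = self._group_counts(mask)
        n1 = int(g.sum())
        if n1 == 0 or n1 == self.n:
            raise ValueError("both groups must be non-empty")
        if self.n_events == 0:
            raise ValueError("no events")
        d, n_at = self._d, self._n_at
        o1 = d1.sum()
        e1 = (d * g_at / n_at).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(
                n_at > 1,
                d * (g_at / n_at) * ((n_at - g_at) / n_at) * (n_at - d) / np.maximum(n_at - 1, 1),
                0.0,
            )
        var = v.sum()
        if var <= 0:
            chi2, p = 0.0, 1.0
        else:
            chi2 = float((o1 - e1) ** 2 / var)
            p = float(stats.chi2.sf(chi2, df=1))
        obs = np.array([self.n_events - o1, o1], dtype=float)
        exp = np.array([self.n_events - e1, e1], dtype=float)
        return LogrankResult(chi_square=chi2, p=max(p, np.finfo(float).tiny), observed=obs, expected=exp)

    def cox(self, mask, max_iter: int = 60, tol: float = 1e-9) -> CoxResult:
        """Cox proportional hazards for the binary split, Efron ties.

        Newton-Raphson on the partial log-likelihood with step-halving;
        the Wald CI is exp(log HR +/- 1.959964 * se).
        """
        g, g_at, d1 = self._group_counts(mask)
        n1 = int(g.sum())
        if n1 == 0 or n1 == self.n:
            raise ValueError("no contrast: all samples in one group")
        if self.n_events < 1:
            raise ValueError("no events")
        ev1 = int(d1.sum())
        ev0 = self.n_events - ev1
        if ev1 == 0 or ev0 == 0:
            # infinite-HR boundary: all events on one side
            hr = 0.0 if ev1 == 0 else np.inf
            return CoxResult(
                log_hr=np.log(hr) if hr > 0 else -np.inf,
                hr=hr, ci_low=np.nan, ci_high=np.nan,
                se=np.nan, p=np.nan, converged=False,
            )
        t = self._efron_t
        a = self._efron_a
        d0 = self._d - d1
        n0_at = self._n_at - g_at
        # per Efron row: denom(b) = A + B * exp(b)
        A = (n0_at[t] - a * d0[t]).astype(float)
        B = (g_at[t] - a * d1[t]).astype(float)
        s1 = float(ev1)

        def loglik(b):
            return s1 * b - np.log(A + B * np.exp(b)).sum()

        b = 0.0
        ll = loglik(b)
        info = np.nan
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            eb = np.exp(b)
            denom = A + B * eb
            frac = (B * eb) / denom
            score = s1 - frac.sum()
            info = (frac * (A / denom)).sum()
            if info <= 0:
                break
            step = score / info
            # step-halving to guarantee likelihood ascent
            new_b = b + step
            new_ll = loglik(new_b)
            halvings = 0
            while new_ll < ll - 1e-12 and halvings < 30:
                step /= 2.0
                new_b = b + step
                new_ll = loglik(new_b)
                halvings += 1
            b, ll = new_b, new_ll
            if abs(score) < tol or abs(step) < 1e-12:
                converged = True
                break
            if abs(b) > 15:  # monotone likelihood drifting to the boundary
                break
        if not converged or not np.isfinite(b) or info <= 0:
            hr = np.inf if b > 0 else 0.0
            return CoxResult(
                log_hr=b, hr=hr, ci_low=np.nan, ci_high=np.nan,
                se=np.nan, p=np.nan, converged=False, n_iter=it,
            )
        se = float(1.0 / np.sqrt(info))
        z = b / se
        return CoxResult(
            log_hr=float(b),
            hr=float(np.exp(b)),
            ci_low=float(np.exp(b - Z_95 * se)),
            ci_high=float(np.exp(b + Z_95 * se)),
            se=se,
            p=float(2.0 * stats.norm.sf(abs(z))),
            converged=True,
            n_iter=it,
        )


def logrank_test(time, event, mask) -> LogrankResult:
    """One-shot log-rank test; see :meth:`SurvivalData.logrank`."""
    return SurvivalData(time, event).logrank(mask)


def cox_binary_hr(time, event, mask) -> CoxResult:
    """One-shot binary-covariate Cox fit; see :meth:`SurvivalData.cox`."""
    return SurvivalData(time, event).cox(mask)
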