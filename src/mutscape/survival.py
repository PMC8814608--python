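"""Kaplan-Meier estimation, log-rank tests and optimal score cutpoints.

The cutpoint selector implements the maximally selected rank statistic used
for survival dichotomisation (the ``surv_cutpoint`` procedure): every
observed score value whose split leaves at least a minimum proportion of
samples on each side is a candidate, the standardized two-group log-rank
statistic is computed for each, and the candidate maximising the absolute
statistic is returned. The p-value at the selected cutpoint is the
unadjusted log-rank p; because the cutpoint is chosen to maximise the
statistic this p is anti-conservative under the null, and an adjusted
p-value (Lausen-Schumacher approximation) is reported alongside as a
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.base import BaseEstimator


def _as_survival_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if len(time) == 0:
        raise ValueError("no survival records")
    if (time <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return time, event.astype(int)


@dataclass
class KMResult:
    """Product-limit estimate with its risk table."""

    timeline: np.ndarray
    survival: np.ndarray
    risk_table: pd.DataFrame = field(repr=False)

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMResult:
    """Kaplan-Meier product-limit estimator, S(0)=1, with a risk table."""
    time, event = _as_survival_arrays(time, event)
    kmf = KaplanMeierFitter().fit(time, event)
    sf = kmf.survival_function_
    risk = pd.DataFrame(
        {
            "n_at_risk": kmf.event_table["at_risk"],
            "n_events": kmf.event_table["observed"],
            "n_censored": kmf.event_table["censored"],
        }
    )
    return KMResult(
        timeline=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        risk_table=risk,
    )


def _two_group_oev(time, event, in_group):
    """Observed, expected and hypergeometric variance for group membership.

    Standard log-rank accounting with ties: at each distinct event time the
    events are treated as draws without replacement from the risk set.
    """
    event_times = np.unique(time[event == 1])
    t1 = np.sort(time[in_group])
    t_all = np.sort(time)
    n1 = len(t1) - np.searchsorted(t1, event_times, side="left")
    n = len(t_all) - np.searchsorted(t_all, event_times, side="left")
    te1 = np.sort(time[in_group & (event == 1)])
    te = np.sort(time[event == 1])
    d1 = np.searchsorted(te1, event_times, side="right") - np.searchsorted(te1, event_times, side="left")
    d = np.searchsorted(te, event_times, side="right") - np.searchsorted(te, event_times, side="left")
    frac = n1 / n
    O = d1.sum()
    E = (d * frac).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac * (1 - frac) * (n - d) / (n - 1)
    V = np.nansum(np.where(n > 1, v, 0.0))
    return float(O), float(E), float(V)


def logrank_test(time, event, groups) -> dict:
    """Log-rank comparison of two or more groups.

    Returns the chi-square statistic, degrees of freedom and p-value; for
    two groups the standardized statistic ``z = (O-E)/sqrt(V)`` of the
    first group (sorted label order) is included.
    """
    time, event = _as_survival_arrays(time, event)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("logrank_test needs at least two nonempty groups")
    if len(labels) == 2:
        O, E, V = _two_group_oev(time, event, groups == labels[0])
        if V <= 0:
            chi2, z = 0.0, 0.0
        else:
            z = (O - E) / np.sqrt(V)
            chi2 = z * z
        p = float(stats.chi2.sf(chi2, df=1))
        return {"statistic": float(chi2), "df": 1, "p": p, "z": float(z),
                "observed": O, "expected": E, "variance": V}
    # g groups: vector of O-E over the first g-1 groups with its covariance
    event_times = np.unique(time[event == 1])
    g = len(labels)
    n_gt = np.empty((g, len(event_times)))
    d_gt = np.empty((g, len(event_times)))
    t_all = np.sort(time)
    n_t = len(t_all) - np.searchsorted(t_all, event_times, side="left")
    te = np.sort(time[event == 1])
    d_t = (np.searchsorted(te, event_times, side="right")
           - np.searchsorted(te, event_times, side="left"))
    for i, lab in enumerate(labels):
        tg = np.sort(time[groups == lab])
        n_gt[i] = len(tg) - np.searchsorted(tg, event_times, side="left")
        teg = np.sort(time[(groups == lab) & (event == 1)])
        d_gt[i] = (np.searchsorted(teg, event_times, side="right")
                   - np.searchsorted(teg, event_times, side="left"))
    frac = n_gt / n_t
    x = (d_gt - d_t * frac).sum(axis=1)[: g - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tie = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
    V = np.zeros((g - 1, g - 1))
    for a in range(g - 1):
        for b in range(g - 1):
            delta = 1.0 if a == b else 0.0
            V[a, b] = np.sum(tie * frac[a] * (delta - frac[b]))
    chi2 = float(x @ np.linalg.pinv(V) @ x) if np.any(V) else 0.0
    p = float(stats.chi2.sf(chi2, df=g - 1))
    return {"statistic": chi2, "df": g - 1, "p": p}


def lausen_schumacher_p(z_max: float, minprop: float) -> float:
    """Approximate p-value of the maximally selected log-rank statistic."""
    b = abs(float(z_max))
    if b <= 1e-12:
        return 1.0
    q1, q2 = minprop, 1.0 - minprop
    phi = stats.norm.pdf(b)
    p = phi * (b - 1.0 / b) * np.log((q2 * (1 - q1)) / ((1 - q2) * q1)) + 4.0 * phi / b
    return float(min(max(p, 0.0), 1.0))


class SurvivalCutpoint(BaseEstimator):
    """Optimal survival cutpoint by maximally selected rank statistics.

    Parameters
    ----------
    minprop : float, default 0.1
        Minimum fraction of samples required on each side of a candidate
        split.

    Attributes
    ----------
    cutpoint_ : float
        Score value maximising the absolute standardized log-rank
        statistic; the high group is ``score > cutpoint_``. Ties favour the
        smaller candidate.
    statistic_ : float
        Standardized statistic at the selected cutpoint.
    p_ : float
        Unadjusted two-group log-rank p at the selected cutpoint.
    p_adjusted_ : float
        Lausen-Schumacher approximation accounting for the maximal
        selection (diagnostic).
    candidates_ : pandas.DataFrame
        Per-candidate table of the standardized statistic and group sizes.
    n_high_, n_low_ : int
    """

    def __init__(self, minprop: float = 0.1):
        self.minprop = minprop

    def fit(self, score, time, event):
        score = np.asarray(score, dtype=float)
        time, event = _as_survival_arrays(time, event)
        if len(score) != len(time):
            raise ValueError("score and survival arrays differ in length")
        if np.unique(score).size < 2:
            raise ValueError("score is constant: no admissible cutpoint")
        n = len(score)
        min_n = self.minprop * n
        rows = []
        for c in np.unique(score):
            high = score > c
            n_high = int(high.sum())
            n_low = n - n_high
            if n_high < min_n or n_low < min_n or n_high == 0 or n_low == 0:
                continue
            O, E, V = _two_group_oev(time, event, high)
            z = (O - E) / np.sqrt(V) if V > 0 else 0.0
            rows.append({"cutpoint": float(c), "statistic": float(z),
                         "n_high": n_high, "n_low": n_low})
        if not rows:
            raise ValueError("no candidate cutpoint satisfies the minprop constraint")
        table = pd.DataFrame(rows)
        best = int(np.argmax(np.abs(table["statistic"].to_numpy())))
        self.candidates_ = table
        self.cutpoint_ = float(table.loc[best, "cutpoint"])
        self.statistic_ = float(table.loc[best, "statistic"])
        self.n_high_ = int(table.loc[best, "n_high"])
        self.n_low_ = int(table.loc[best, "n_low"])
        self.p_ = float(stats.chi2.sf(self.statistic_**2, df=1))
        self.p_adjusted_ = lausen_schumacher_p(self.statistic_, self.minprop)
        return self

    def predict(self, score) -> np.ndarray:
        """Group labels ('high'/'low') for scores under the fitted cutpoint."""
        score = np.asarray(score, dtype=float)
        return np.where(score > self.cutpoint_, "high", "low")


def optimal_cutpoint(score, time, event, minprop: float = 0.1) -> SurvivalCutpoint:
    """Fit a :class:`SurvivalCutpoint` on the given score and survival data."""
    return SurvivalCutpoint(minprop=minprop).fit(score, time, event)


def dichotomize_and_compare(time, event, score, threshold: float) -> dict:
    """Split at a fixed threshold (high = score > threshold) and log-rank test."""
    score = np.asarray(score, dtype=float)
    time, event = _as_survival_arrays(time, event)
    high = score > threshold
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(
            f"threshold {threshold} leaves an empty arm (high={n_high}, low={n_low})"
        )
    res = logrank_test(time, event, np.where(high, "high", "low"))
    res.update({"n_high": n_high, "n_low": n_low, "threshold": float(threshold)})
    return res
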