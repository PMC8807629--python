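"""Censored-survival imputation and the two-level survival partition.

The imputation follows the piecewise rule

    survival = mean                                if t0 <= mean / 2
             = t0 + (1 / S(t0)) * int_{t0} S(t) dt  if t0 >  mean / 2

for a sample censored at ``t0``, where ``S`` is the product-limit estimate
of the survival function and ``mean`` is the restricted mean survival (area
under ``S`` up to the last observed time).  The second branch is the exact
conditional expectation of the remaining lifetime under the step-function
estimate, with the integral truncated at the last observed time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LEVEL1_LABELS = ("L", "S")
LEVEL2_LABELS = ("LL", "LS", "SL", "SS")


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``surv[i]`` is S(t) for ``event_times[i] <= t < event_times[i+1]``
    (right-continuous step convention); S(t) = 1 before the first event
    time.  ``tau`` is the largest observed time (event or censoring) and
    ``mean_survival`` the area under the curve on [0, tau].
    """

    event_times: np.ndarray
    surv: np.ndarray
    n_at_risk: np.ndarray
    tau: float
    mean_survival: float

    def survival_at(self, t: float) -> float:
        """S(t) with the right-continuous step convention."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.surv[idx - 1])

    def integral(self, t0: float) -> float:
        """Area under S on [t0, tau], summed exactly over the steps."""
        if t0 >= self.tau:
            return 0.0
        t0 = max(t0, 0.0)
        knots = np.concatenate(
            [[t0], self.event_times[self.event_times > t0], [self.tau]]
        )
        knots = np.unique(knots)
        knots = knots[knots <= self.tau]
        widths = np.diff(knots)
        heights = np.array([self.survival_at(t) for t in knots[:-1]])
        return float(np.sum(widths * heights))


def fit_km(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Ties between events and censorings at the same time are resolved with
    events first (the censored sample still counts as at risk).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be 1-D arrays of equal length")
    if len(times) == 0:
        raise ValueError("empty cohort")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if events.sum() == 0:
        raise ValueError(
            "no events observed: the product-limit curve never drops"
        )
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = len(t_sorted)
    distinct = np.unique(t_sorted[e_sorted == 1])
    surv_vals = []
    at_risk = []
    s = 1.0
    for t in distinct:
        n_risk = int(np.sum(t_sorted >= t))
        d = int(np.sum((t_sorted == t) & (e_sorted == 1)))
        s *= 1.0 - d / n_risk
        surv_vals.append(s)
        at_risk.append(n_risk)
    curve = KMCurve(
        event_times=distinct,
        surv=np.asarray(surv_vals),
        n_at_risk=np.asarray(at_risk, dtype=int),
        tau=float(t_sorted[-1]),
        mean_survival=0.0,
    )
    curve.mean_survival = curve.integral(0.0)
    return curve


def expected_residual_survival(curve: KMCurve, t0: float) -> float:
    """Conditional expected survival time for a sample censored at ``t0``.

    Returns ``t0 + integral(S, t0..tau) / S(t0)``.  For ``t0`` at (or
    beyond) the last observed time the restricted-mean convention returns
    ``t0`` itself.
    """
    if t0 >= curve.tau:
        return float(t0)
    s0 = curve.survival_at(t0)
    if s0 <= 0.0:
        raise ValueError(
            f"S({t0}) = 0; no survival mass remains -- fall back to the "
            f"last event time {curve.event_times[-1]}"
        )
    return float(t0 + curve.integral(t0) / s0)


def impute_survival(times, events, mean_rule: str = "km") -> pd.DataFrame:
    """Impute survival times for censored samples.

    Events keep their observed time.  A censored sample at ``t0`` receives
    the mean survival if ``t0 <= mean / 2`` and the conditional expectation
    otherwise.  ``mean_rule`` selects the restricted KM mean (default) or
    the arithmetic mean of observed times.

    Returns a DataFrame with columns ``time``, ``event``, ``imputed_time``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    curve = fit_km(times, events)
    if mean_rule == "km":
        mean = curve.mean_survival
    elif mean_rule == "arithmetic":
        mean = float(np.mean(times))
    else:
        raise ValueError("mean_rule must be 'km' or 'arithmetic'")
    imputed = times.astype(float).copy()
    for i in np.flatnonzero(events == 0):
        t0 = times[i]
        if t0 <= mean / 2.0:
            imputed[i] = mean
        else:
            imputed[i] = expected_residual_survival(curve, t0)
    return pd.DataFrame(
        {"time": times, "event": events, "imputed_time": imputed}
    )


def split_two_groups(values, rule: str = "variance") -> tuple[np.ndarray, float]:
    """Cut a 1-D sample into short/long at a threshold.

    Returns ``(is_long, threshold)`` where ``is_long[i]`` is True when
    ``values[i] >= threshold``.  The threshold is always the smallest value
    of the long group, so ties at the threshold go to "long".

    ``rule="variance"`` scans all n-1 cut points and minimises the total
    within-class sum of squares; ``rule="median"`` cuts at the sample
    median.  Both classes are guaranteed non-empty.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need at least two values to split")
    x = np.sort(values)
    if x[0] == x[-1]:
        raise ValueError("all values identical: no admissible split")
    n = len(x)
    if rule == "variance":
        csum = np.cumsum(x)
        csq = np.cumsum(x * x)
        k = np.arange(1, n)
        s1, q1 = csum[:-1], csq[:-1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        within = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
        # cuts between equal values are not admissible
        within[x[1:] == x[:-1]] = np.inf
        best = int(np.argmin(within)) + 1
        threshold = float(x[best])
    elif rule == "median":
        med = float(np.median(x))
        above = x[x > med]
        threshold = float(above[0]) if len(above) else float(x[-1])
    else:
        raise ValueError("rule must be 'variance' or 'median'")
    is_long = values >= threshold
    if is_long.all() or not is_long.any():  # pragma: no cover - guarded above
        raise ValueError("degenerate split")
    return is_long, threshold


@dataclass
class SurvivalTree:
    """Per-sample survival subgroup labels plus the imputed times used.

    ``labels`` has columns ``sample_id``, ``level1``, ``level2``,
    ``imputed_time`` (cohort-level imputation).  ``side_imputed`` maps
    "L"/"S" to the within-subset imputed times (pandas Series indexed by
    sample_id) that the level-2 splits were computed on.
    """

    labels: pd.DataFrame
    thresholds: dict
    side_imputed: dict


def build_survival_tree(
    times,
    events,
    sample_ids=None,
    split_rule: str = "median",
    mean_rule: str = "km",
    min_leaf: int = 10,
) -> SurvivalTree:
    """Two-level recursive partition into LL / LS / SL / SS.

    Level 1 splits the whole cohort on imputed survival; each side is then
    re-imputed on its own product-limit curve and split again.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(times)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n)]
    sample_ids = list(sample_ids)
    if len(sample_ids) != n:
        raise ValueError("sample_ids length mismatch")

    imp = impute_survival(times, events, mean_rule=mean_rule)
    y = imp["imputed_time"].to_numpy()
    is_long, thr1 = split_two_groups(y, rule=split_rule)

    level1 = np.where(is_long, "L", "S")
    level2 = np.empty(n, dtype=object)
    thresholds = {"root": thr1}
    side_imputed = {}
    for side, long_leaf, short_leaf in (("L", "LL", "LS"), ("S", "SL", "SS")):
        idx = np.flatnonzero(level1 == side)
        if len(idx) < 2 * min_leaf:
            raise ValueError(
                f"level-1 group {side!r} has {len(idx)} samples, fewer than "
                f"2 * min_leaf = {2 * min_leaf}; use the two-group model"
            )
        sub = impute_survival(times[idx], events[idx], mean_rule=mean_rule)
        y_sub = sub["imputed_time"].to_numpy()
        sub_long, thr2 = split_two_groups(y_sub, rule=split_rule)
        if sub_long.sum() < min_leaf or (~sub_long).sum() < min_leaf:
            raise ValueError(
                f"level-2 split of group {side!r} yields a leaf below "
                f"min_leaf = {min_leaf}; use the two-group model"
            )
        level2[idx] = np.where(sub_long, long_leaf, short_leaf)
        thresholds[side] = thr2
        side_imputed[side] = pd.Series(
            y_sub, index=[sample_ids[i] for i in idx]
        )

    labels = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "level1": level1,
            "level2": level2,
            "imputed_time": y,
        }
    )
    return SurvivalTree(
        labels=labels, thresholds=thresholds, side_imputed=side_imputed
    )
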