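"""Classifier and prognosis evaluation.

Confusion metrics treat HG3 as the positive class: sensitivity is the
fraction of pathological-grade-3 (pHG3) samples called HG3,
specificity the fraction of pHG1 samples called HG1, and the F-score
their harmonic mean. Prognostic separation between classifier groups
is quantified with Kaplan-Meier curves and the log-rank test, a
univariate Cox proportional-hazards fit (hazard ratio with Wald 95%
CI, Efron tie handling), and Harrell's concordance index. A
direction-concordance score compares two signed differential-gene
lists over their intersection, with a binomial test against chance
agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index

from .classifier import HG1, HG3, NOT_EVALUABLE, GradeCall
from .discovery import binomial_reo_pvalue, confusion_f_score

__all__ = [
    "ConfusionReport",
    "SurvivalComparison",
    "confusion_report",
    "km_logrank",
    "cox_hr",
    "c_index",
    "direction_concordance",
]


@dataclass(frozen=True)
class ConfusionReport:
    """2x2 agreement with pathological labels (HG3 positive)."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    f_score: float
    n_not_evaluable: int = 0


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-group survival contrast: log-rank, Cox HR + 95% CI, C-index."""

    curves: pd.DataFrame  # columns: group, time, at_risk, survival
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    c_index: float


def confusion_report(
    calls: Sequence[GradeCall], truth: Mapping[str, str] | pd.Series
) -> ConfusionReport:
    """Confusion metrics of grade calls against pHG1/pHG3 labels.

    ``not_evaluable`` calls are excluded from the 2x2 table and counted
    separately. A truth class with no evaluable member makes its metric
    undefined and raises.
    """
    truth = pd.Series(truth)
    tp = fn = tn = fp = n_ne = 0
    for call in calls:
        label = truth.get(call.sample_id)
        if label not in ("pHG1", "pHG3"):
            raise ValueError(
                f"sample {call.sample_id!r} has truth label {label!r}; expected pHG1/pHG3"
            )
        if call.call == NOT_EVALUABLE:
            n_ne += 1
            continue
        if label == "pHG3":
            tp += call.call == HG3
            fn += call.call == HG1
        else:
            tn += call.call == HG1
            fp += call.call == HG3
    if tp + fn == 0:
        raise ValueError("no evaluable pHG3 sample: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no evaluable pHG1 sample: specificity undefined")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ConfusionReport(tp, fn, tn, fp, sens, spec, confusion_f_score(sens, spec), n_ne)


def _align(groups: Mapping[str, object] | pd.Series, clinical: pd.DataFrame):
    groups = pd.Series(groups)
    missing = [s for s in groups.index if s not in clinical.index]
    if missing:
        raise KeyError(f"samples without clinical records: {missing[:10]}")
    clin = clinical.loc[groups.index]
    levels = sorted(pd.unique(groups.astype(str)))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    indicator = (groups.astype(str) == levels[1]).astype(int).to_numpy()
    return indicator, levels, clin["time"].to_numpy(float), clin["event"].to_numpy(int)


def km_logrank(
    groups: Mapping[str, object] | pd.Series, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, float, float]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns ``(curves, statistic, p_value)`` where curves has one row
    per (group, time) with the number at risk and the product-limit
    survival estimate. The statistic is the standard chi-square on 1 df
    built from observed-minus-expected event sums over the distinct
    event times.
    """
    indicator, levels, time, event = _align(groups, clinical)
    if event.sum() == 0:
        raise ValueError("no events in either group: log-rank statistic undefined")
    rows = []
    for lev, mask in zip(levels, (indicator == 0, indicator == 1)):
        if mask.sum() == 0:
            raise ValueError(f"group {lev!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(lev))
        at_risk = kmf.event_table["at_risk"]
        surv = kmf.survival_function_.iloc[:, 0]
        for t in kmf.event_table.index:
            rows.append(
                {
                    "group": str(lev),
                    "time": float(t),
                    "at_risk": int(at_risk.loc[t]),
                    "survival": float(surv.loc[t]),
                }
            )
    curves = pd.DataFrame(rows, columns=["group", "time", "at_risk", "survival"])
    res = logrank_test(
        time[indicator == 0], time[indicator == 1],
        event_observed_A=event[indicator == 0], event_observed_B=event[indicator == 1],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def cox_hr(
    groups: Mapping[str, object] | pd.Series, clinical: pd.DataFrame
) -> tuple[float, float, float]:
    """Univariate Cox PH fit of the group indicator.

    Returns ``(HR, ci_low, ci_high)`` for the lexicographically later
    group level versus the earlier one; the CI is the Wald 95% interval
    on the log-hazard scale. No events in one group (complete
    separation) produces a warning and an effectively unbounded CI
    rather than an error.
    """
    indicator, levels, time, event = _align(groups, clinical)
    if event.sum() == 0:
        raise ValueError("no events at all: hazard ratio undefined")
    for lev, mask in zip(levels, (indicator == 0, indicator == 1)):
        if event[mask].sum() == 0:
            warnings.warn(
                f"group {lev!r} has no events: HR is unstable and its CI unbounded",
                stacklevel=2,
            )
    df = pd.DataFrame({"time": time, "event": event, "group": indicator})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lifelines convergence chatter on degenerate input
        cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["group"]))
    ci = cph.confidence_intervals_
    with np.errstate(over="ignore"):  # a separated group yields an unbounded CI
        lo = float(np.exp(ci.loc["group"].iloc[0]))
        hi = float(np.exp(ci.loc["group"].iloc[1]))
    return hr, lo, hi


def c_index(
    risk_scores: Mapping[str, float] | pd.Series, clinical: pd.DataFrame
) -> float:
    """Harrell's concordance index of a risk score against survival.

    Fraction of usable pairs (per the standard censoring rules: a pair
    is usable when the shorter observed time belongs to an event) in
    which the higher-risk sample fails first; tied risks count 0.5.
    1.0 = perfect concordance, 0.5 = uninformative.
    """
    risk = pd.Series(risk_scores, dtype=float)
    missing = [s for s in risk.index if s not in clinical.index]
    if missing:
        raise KeyError(f"samples without clinical records: {missing[:10]}")
    clin = clinical.loc[risk.index]
    time = clin["time"].to_numpy(float)
    event = clin["event"].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no usable pairs: C-index undefined")
    # lifelines scores "higher prediction = longer survival"; risk is the opposite
    return float(concordance_index(time, -risk.to_numpy(), event))


def direction_concordance(
    list_a: Mapping[str, str], list_b: Mapping[str, str]
) -> tuple[int, float | None, float | None]:
    """Agreement of dysregulation directions between two signed gene lists.

    Over the gene-ID intersection, returns the overlap size, the
    fraction of genes with the same direction ("up"/"down"), and the
    one-sided binomial probability of at least that much agreement by
    chance (p0 = 0.5). An empty overlap leaves fraction and p-value
    undefined (None).
    """
    for name, lst in (("list_a", list_a), ("list_b", list_b)):
        bad = {d for d in lst.values() if d not in ("up", "down")}
        if bad:
            raise ValueError(f"{name} has directions outside up/down: {sorted(bad)}")
    overlap = sorted(set(list_a) & set(list_b))
    if not overlap:
        return 0, None, None
    concordant = sum(list_a[g] == list_b[g] for g in overlap)
    fraction = concordant / len(overlap)
    p = binomial_reo_pvalue(concordant, len(overlap), 0.5)
    return len(overlap), fraction, p
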