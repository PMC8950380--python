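"""Stratified synthetic-subset selection by integrated Brier score.

Partitions a cohort (and each candidate synthetic dataset) into age-group x
stage strata, scores every synthetic stratum against the cohort stratum with
the censoring-weighted integrated Brier score on the annual grid, takes the
row-wise argmin, and merges the winning subsets into one combined cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import AGE_GROUPS, STAGES, PatientRecord, cohort_to_frame

__all__ = [
    "SurvCurve",
    "ScoreMatrix",
    "km_estimate",
    "censoring_km",
    "brier_censored",
    "ibs",
    "partition",
    "score_matrix",
    "select_and_merge",
]

logger = logging.getLogger(__name__)

#: Follow-up horizon of the annual grid.
T_STAR = 10

#: Censoring-survival floor below which Graf weights are truncated.
G_FLOOR = 1e-8


@dataclass(frozen=True)
class SurvCurve:
    """Product-limit estimates on the grid t = 0..10.

    ``surv[t]`` is the probability of being event-free just after time t;
    ``at_risk[t]`` / ``events[t]`` are the interval bookkeeping counts
    (index 0 unused for events).
    """

    times: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray | None = None
    events: np.ndarray | None = None

    def at(self, t: float) -> float:
        """Step-function evaluation S(t) (right-continuous)."""
        t = min(int(np.floor(t)), len(self.surv) - 1)
        return float(self.surv[max(t, 0)])


def _followup_events(subset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(subset, pd.DataFrame):
        times = subset["followup"].to_numpy(dtype=int)
        died = (subset["exitus"] == "died").to_numpy()
    else:
        times = np.array([r.followup for r in subset], dtype=int)
        died = np.array([r.exitus == "died" for r in subset])
    return times, died


def _product_limit(times, flags, risk_adjust=None, horizon=T_STAR) -> SurvCurve:
    n = len(times)
    surv = np.ones(horizon + 1)
    at_risk = np.zeros(horizon + 1, dtype=int)
    events = np.zeros(horizon + 1, dtype=int)
    s = 1.0
    for t in range(1, horizon + 1):
        risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & flags))
        if risk_adjust is not None:
            risk -= int(np.sum((times == t) & risk_adjust))
        at_risk[t] = risk
        events[t] = d
        if risk > 0:
            s *= 1.0 - d / risk
        surv[t] = s
    at_risk[0] = n
    return SurvCurve(times=np.arange(horizon + 1), surv=surv, at_risk=at_risk, events=events)


def km_estimate(subset) -> SurvCurve:
    """Kaplan-Meier survival with deaths as events on the annual grid."""
    times, died = _followup_events(subset)
    if len(times) == 0:
        raise ValueError("cannot estimate survival on an empty subset")
    return _product_limit(times, died)


def censoring_km(subset) -> SurvCurve:
    """Kaplan-Meier of the censoring distribution G (events reversed).

    At tied times deaths precede censorings: the risk set for censoring
    events at time t excludes deaths occurring at t.
    """
    times, died = _followup_events(subset)
    if len(times) == 0:
        raise ValueError("cannot estimate censoring distribution on an empty subset")
    return _product_limit(times, ~died, risk_adjust=died)


def brier_censored(
    subset,
    predicted: SurvCurve,
    t: float,
    censor_curve: SurvCurve | None = None,
    printed_variant: bool = False,
) -> float:
    """Censoring-weighted Brier score of ``predicted`` at time ``t``.

    Subjects dead by t contribute ``(0 - S(t))^2 / G(t_i-)``; subjects still
    under follow-up past t contribute ``(1 - S(t))^2 / G(t)``; subjects
    censored at or before t contribute 0.  ``printed_variant=True`` divides
    both terms by G(t) instead (sensitivity check only).  Weights with
    G below ``G_FLOOR`` are truncated at the last grid time where G is at
    least the floor (logged).
    """
    times, died = _followup_events(subset)
    n = len(times)
    if n == 0:
        raise ValueError("empty subset")
    g = censor_curve if censor_curve is not None else censoring_km(subset)
    s_t = predicted.at(t)

    def g_weight(value_t: float) -> float:
        gv = g.at(value_t)
        if gv < G_FLOOR:
            grid = np.flatnonzero(g.surv >= G_FLOOR)
            fallback = float(g.surv[grid[-1]]) if grid.size else G_FLOOR
            logger.debug("G weight truncated at %.3g", fallback)
            return fallback
        return gv

    total = 0.0
    for time_i, died_i in zip(times, died):
        dead_by_t = died_i and time_i <= t
        past_t = time_i > t
        if dead_by_t:
            denom = g_weight(t if printed_variant else time_i - 1)
            total += s_t**2 / denom
        elif past_t:
            denom = g_weight(t)
            total += (1.0 - s_t) ** 2 / denom
        # censored at or before t: weight 0
    return total / n


def ibs(
    subset,
    predicted: SurvCurve,
    t_star: int = T_STAR,
    printed_variant: bool = False,
) -> float:
    """Integrated Brier score (1/t*) * int_0^t* BS(t) dt, trapezoid rule.

    BS is evaluated on the annual grid t = 0..t*; uniform time weighting
    W(t) = t/t* makes the integral a plain time average.
    """
    censor_curve = censoring_km(subset)
    grid = np.arange(0, t_star + 1)
    bs = np.array(
        [
            brier_censored(
                subset, predicted, t, censor_curve=censor_curve, printed_variant=printed_variant
            )
            for t in grid
        ]
    )
    return float(np.trapezoid(bs, grid) / t_star)


def partition(
    cohort,
    age_groups: Sequence[str] = AGE_GROUPS,
    stages: Sequence[str] = STAGES,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Split into L = A x S disjoint exhaustive strata (age outer, stage inner).

    Empty strata are kept (and flagged by callers); ordering is fixed.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for group in age_groups:
        for stage in stages:
            mask = (frame["age_group"] == group) & (frame["stage"] == stage)
            out[(group, stage)] = frame.loc[mask].reset_index(drop=True)
    return out


@dataclass
class ScoreMatrix:
    """L strata x M synthetic datasets of IBS values plus the argmin selection.

    ``values[l, m]`` is NaN when the entry is invalid (empty synthetic
    stratum); ``selection[l]`` is the winning model label, or None for
    strata skipped because the cohort stratum is empty.
    """

    strata: list[tuple[str, str]]
    labels: list[str]
    values: np.ndarray
    selection: list[str | None] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.labels)
        frame.insert(0, "age_group", [s[0] for s in self.strata])
        frame.insert(1, "stage", [s[1] for s in self.strata])
        frame["selected"] = self.selection
        return frame


def argmin_selection(
    values: np.ndarray, labels: Sequence[str]
) -> list[str | None]:
    """Row-wise argmin with ties broken by the fixed label order.

    Rows that are entirely NaN select None.
    """
    selection: list[str | None] = []
    for row in np.asarray(values, dtype=float):
        if np.all(np.isnan(row)):
            selection.append(None)
            continue
        best = np.nanmin(row)
        winner = next(
            label for label, v in zip(labels, row) if not np.isnan(v) and v == best
        )
        selection.append(winner)
    return selection


def score_matrix(
    cohort,
    synds: Mapping[str, pd.DataFrame],
    t_star: int = T_STAR,
    age_groups: Sequence[str] = AGE_GROUPS,
    stages: Sequence[str] = STAGES,
) -> ScoreMatrix:
    """IBS of every synthetic dataset's stratum curve against each cohort stratum.

    ``synds`` maps model label -> synthetic dataset; iteration order of the
    mapping fixes the column (and tie-break) order.  Cohort strata with no
    records are skipped (selection None); synthetic strata with no records
    yield NaN entries that are never selectable.
    """
    cohort_parts = partition(cohort, age_groups, stages)
    labels = list(synds)
    synd_parts = {label: partition(df, age_groups, stages) for label, df in synds.items()}
    strata = list(cohort_parts)
    values = np.full((len(strata), len(labels)), np.nan)
    for li, stratum in enumerate(strata):
        cohort_subset = cohort_parts[stratum]
        if len(cohort_subset) == 0:
            logger.warning("cohort stratum %s is empty; skipped", stratum)
            continue
        for mi, label in enumerate(labels):
            synd_subset = synd_parts[label][stratum]
            if len(synd_subset) == 0:
                logger.warning("synthetic stratum %s of %s is empty", stratum, label)
                continue
            predicted = km_estimate(synd_subset)
            values[li, mi] = ibs(cohort_subset, predicted, t_star=t_star)
    matrix = ScoreMatrix(strata=strata, labels=labels, values=values)
    matrix.selection = [
        None if len(cohort_parts[s]) == 0 else sel
        for s, sel in zip(strata, argmin_selection(values, labels))
    ]
    for stratum, sel in zip(strata, matrix.selection):
        if sel is None and len(cohort_parts[stratum]) > 0:
            raise ValueError(f"stratum {stratum} has no valid synthetic candidate")
    return matrix


def select_and_merge(
    matrix: ScoreMatrix, synds: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Concatenate the argmin synthetic subset of every selected stratum.

    Adds provenance columns ``source_model``, ``stratum_age_group`` and
    ``stratum_stage`` so every record traces to exactly one (stratum, model).
    """
    synd_parts = {label: partition(df) for label, df in synds.items()}
    pieces = []
    for stratum, label in zip(matrix.strata, matrix.selection):
        if label is None:
            continue
        part = synd_parts[label][stratum].copy()
        part["source_model"] = label
        part["stratum_age_group"] = stratum[0]
        part["stratum_stage"] = stratum[1]
        pieces.append(part)
    if not pieces:
        raise ValueError("no stratum was selected; nothing to merge")
    return pd.concat(pieces, ignore_index=True)
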