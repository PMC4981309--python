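"""ROC/AUC discrimination and MET-association evaluation of activity metrics.

Given a set of simulated (or annotated real) lab sessions and per-session
metric series, this module reproduces the comparison methodology used to
benchmark activity summary metrics against each other and against measured
energy expenditure:

* second-by-second ROC curves for discriminating pairs of activity types,
  pooling values across participants;
* ROC curves for classifying MET-defined intensity categories (sedentary
  MET < 1.5, light MET in [1.5, 3), moderate-to-vigorous MET >= 3) from
  per-participant-per-activity median metric values;
* Pearson correlation (and R^2) between median metric and median MET across
  participant-activity pairs.

AUC is computed as the Mann-Whitney statistic with ties counted 1/2, which
equals the trapezoidal area under the empirical ROC curve with midrank tie
handling, and equals the probability that a random positive scores above a
random negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_metrics import (
    Metric,
    MetricSeries,
    NoiseProfile,
    TriaxialRecording,
    ai_per_second,
    enmo_per_second,
)
from .synthetic_data import LabSession

__all__ = [
    "IntensityClass",
    "ROCResult",
    "met_from_vo2",
    "classify_intensity",
    "roc_auc",
    "session_metrics",
    "activity_pair_rocs",
    "intensity_rocs",
    "met_association",
    "DEFAULT_ACTIVITY_PAIRS",
    "rocs_to_frame",
]

#: Activity pairs used to illustrate type discrimination (sedentary-to-light
#: contrasts against DVD, plus one moderate-intensity contrast).
DEFAULT_ACTIVITY_PAIRS: tuple[tuple[str, str], ...] = (
    ("DVD", "DISH"),
    ("DVD", "LAUN"),
    ("DVD", "PUZZ"),
    ("WALK", "MOP"),
)


class IntensityClass(str, Enum):
    """MET-defined physical activity intensity category.

    The classes partition [0, inf) into left-closed/right-open intervals:
    sedentary [0, 1.5), light [1.5, 3), mvpa [3, inf).
    """

    SEDENTARY = "sedentary"
    LIGHT = "light"
    MVPA = "mvpa"

    @property
    def met_interval(self) -> tuple[float, float]:
        return {
            IntensityClass.SEDENTARY: (0.0, 1.5),
            IntensityClass.LIGHT: (1.5, 3.0),
            IntensityClass.MVPA: (3.0, float("inf")),
        }[self]


def met_from_vo2(vo2: float) -> float:
    """Convert oxygen uptake (mL per kg per minute) to METs: VO2 / 3.5."""
    if vo2 < 0:
        raise ValueError("VO2 must be non-negative")
    return vo2 / 3.5


def classify_intensity(met: float) -> IntensityClass:
    """Map a MET value to its intensity class (boundaries 1.5 and 3 inclusive
    on the left, so 1.5 is light and 3.0 is mvpa)."""
    if met < 0:
        raise ValueError("MET must be non-negative")
    if met < 1.5:
        return IntensityClass.SEDENTARY
    if met < 3.0:
        return IntensityClass.LIGHT
    return IntensityClass.MVPA


@dataclass(frozen=True)
class ROCResult:
    """AUC and operating points of one binary discrimination task."""

    auc: float
    curve: np.ndarray  # (k, 2) columns (fpr, tpr), from (0,0) to (1,1)
    n_pos: int
    n_neg: int
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.curve, dtype=float)
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("curve must be a (k, 2) array")
        object.__setattr__(self, "curve", c)


def roc_auc(
    scores_pos: Sequence[float], scores_neg: Sequence[float], label: str = ""
) -> ROCResult:
    """Empirical ROC and its area for scores of a positive and negative class.

    AUC is the Mann-Whitney statistic: the fraction of (positive, negative)
    pairs the positive wins, ties counting 1/2 (midranks).  The curve is
    enumerated at every distinct score threshold, descending, and always
    starts at (0, 0) and ends at (1, 1).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # midranks
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (
        pos.size * neg.size
    )

    # operating points at each distinct threshold, descending
    thresholds = np.unique(combined)[::-1]
    tpr = [(pos >= th).mean() for th in thresholds]
    fpr = [(neg >= th).mean() for th in thresholds]
    curve = np.vstack([[0.0, 0.0], np.column_stack([fpr, tpr]), [1.0, 1.0]])
    return ROCResult(float(auc), curve, int(pos.size), int(neg.size), label)


def session_metrics(
    session: LabSession,
    noise: NoiseProfile,
    metrics: Sequence[Metric] = (Metric.AI_REL, Metric.ENMO),
) -> dict[Metric, MetricSeries]:
    """Second-by-second metric series of one session's recording."""
    out: dict[Metric, MetricSeries] = {}
    for m in metrics:
        m = Metric(m)
        if m is Metric.AI_ABS:
            out[m] = ai_per_second(session.recording, noise, scale="abs")
        elif m is Metric.AI_REL:
            out[m] = ai_per_second(session.recording, noise, scale="rel")
        else:
            out[m] = enmo_per_second(session.recording)
    return out


def _bout_values(
    session: LabSession, series: MetricSeries, alias: str
) -> np.ndarray:
    """Metric values of the epochs fully inside one bout's sample interval."""
    sr = session.recording.sample_rate
    s, e = session.interval(alias)
    H = series.epoch_length_seconds * sr
    first = int(np.ceil(s / H))
    last = e // H
    return series.values[first:last]


def activity_pair_rocs(
    sessions: Sequence[LabSession],
    metrics: Sequence[Mapping[Metric, MetricSeries]],
    pairs: Sequence[tuple[str, str]] = DEFAULT_ACTIVITY_PAIRS,
    pooling: str = "pooled_seconds",
) -> list[ROCResult]:
    """ROC per activity pair per metric.

    The positive class of each pair is the activity with the higher median
    MET across sessions, so an informative metric yields AUC above 0.5.
    ``pooling="pooled_seconds"`` (default) pools all second-level values
    across participants within each alias; ``pooling="participant_median"``
    uses one median value per participant per alias instead.
    """
    if pooling not in ("pooled_seconds", "participant_median"):
        raise ValueError(f"unknown pooling {pooling!r}")
    if len(sessions) != len(metrics):
        raise ValueError("sessions and metrics must align")
    results: list[ROCResult] = []
    metric_names = list(metrics[0].keys())
    for alias_a, alias_b in pairs:
        for sess in sessions:
            for alias in (alias_a, alias_b):
                if alias not in sess.aliases:
                    raise ValueError(f"alias {alias!r} absent from a session")
        med_met = {
            alias: float(np.median([s.met_values[alias] for s in sessions]))
            for alias in (alias_a, alias_b)
        }
        pos_alias, neg_alias = (
            (alias_b, alias_a)
            if med_met[alias_b] >= med_met[alias_a]
            else (alias_a, alias_b)
        )
        for name in metric_names:
            pooled: dict[str, list[np.ndarray]] = {alias_a: [], alias_b: []}
            for sess, mm in zip(sessions, metrics):
                for alias in (alias_a, alias_b):
                    vals = _bout_values(sess, mm[name], alias)
                    if pooling == "participant_median":
                        vals = np.array([np.median(vals)])
                    pooled[alias].append(vals)
            results.append(
                roc_auc(
                    np.concatenate(pooled[pos_alias]),
                    np.concatenate(pooled[neg_alias]),
                    label=f"{alias_a}_vs_{alias_b}:{Metric(name).value}",
                )
            )
    return results


def _median_table(
    sessions: Sequence[LabSession],
    metrics: Sequence[Mapping[Metric, MetricSeries]],
) -> pd.DataFrame:
    """Tidy per-(participant, activity) medians of each metric plus MET."""
    rows = []
    for sess, mm in zip(sessions, metrics):
        for alias in sess.aliases:
            row = {
                "participant": sess.participant_id,
                "activity": alias,
                "met": sess.met_values[alias],
            }
            for name, series in mm.items():
                row[Metric(name).value] = float(
                    np.median(_bout_values(sess, series, alias))
                )
            rows.append(row)
    return pd.DataFrame(rows)


#: The three binary intensity tasks: (label, positive classes, negative classes).
_INTENSITY_TASKS: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("sedentary_vs_light", ("light",), ("sedentary",)),
    ("light_vs_mvpa", ("mvpa",), ("light",)),
    ("mvpa_vs_rest", ("mvpa",), ("sedentary", "light")),
)


def intensity_rocs(
    sessions: Sequence[LabSession],
    metrics: Sequence[Mapping[Metric, MetricSeries]],
) -> list[ROCResult]:
    """ROC per intensity task per metric.

    Each (participant, activity) contributes one point: its median metric
    value as the score and its MET-derived intensity class as the label.
    The three tasks are sedentary-vs-light, light-vs-MVPA and MVPA-vs-rest
    (rest = sedentary + light), the positive class being the higher-intensity
    one in each case.
    """
    table = _median_table(sessions, metrics)
    table["class"] = table["met"].map(lambda m: classify_intensity(m).value)
    results: list[ROCResult] = []
    metric_names = [Metric(m).value for m in metrics[0].keys()]
    for task, pos_classes, neg_classes in _INTENSITY_TASKS:
        pos_rows = table[table["class"].isin(pos_classes)]
        neg_rows = table[table["class"].isin(neg_classes)]
        for cls, rows in (
            ("+".join(pos_classes), pos_rows),
            ("+".join(neg_classes), neg_rows),
        ):
            if rows.empty:
                raise ValueError(f"intensity class {cls!r} has no members in {task}")
        for name in metric_names:
            results.append(
                roc_auc(
                    pos_rows[name].to_numpy(),
                    neg_rows[name].to_numpy(),
                    label=f"{task}:{name}",
                )
            )
    return results


def met_association(
    sessions: Sequence[LabSession],
    metrics: Sequence[Mapping[Metric, MetricSeries]],
) -> pd.DataFrame:
    """Pearson r and R^2 between median metric and median MET.

    One point per (participant, activity): the participant's median metric
    value during the activity against the activity's MET value.  Requires at
    least three points and non-degenerate variance in both variables.
    """
    table = _median_table(sessions, metrics)
    if len(table) < 3:
        raise ValueError("MET association needs at least 3 (participant, activity) points")
    rows = []
    for name in [Metric(m).value for m in metrics[0].keys()]:
        x, y = table["met"].to_numpy(), table[name].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance in MET or {name}; correlation undefined")
        r = float(stats.pearsonr(x, y).statistic)
        rows.append({"metric": name, "pearson_r": r, "r_squared": r * r})
    return pd.DataFrame(rows)


def rocs_to_frame(results: Sequence[ROCResult]) -> pd.DataFrame:
    """Tidy (task, metric, auc, n_pos, n_neg) table from ROC results."""
    rows = []
    for r in results:
        task, _, metric = r.label.rpartition(":")
        rows.append(
            {
                "task": task,
                "metric": metric,
                "auc": r.auc,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
            }
        )
    return pd.DataFrame(rows)
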