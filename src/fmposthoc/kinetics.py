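"""Unloading kinetics per ROI and group-stratified statistics.

The per-bouton efficiency measure is the *unloaded fraction*
``(F0 - plateau) / F0``: the share of baseline FM1-43 fluorescence lost by
the end of the recording, with F0 the baseline-frame mean of the ROI trace
and the plateau the mean over a tail window of late frames.

Group statistics mirror the stratified comparison this pipeline exists
for: the unloaded fractions of the whole population, of the high-IR group
(normalized marker IR > 2) and of the low-IR group (< 0.5) are compared by
one-way ANOVA followed by Bonferroni-corrected pairwise t tests.  Note the
three compared samples overlap (whole contains high and low); that design
is reproduced deliberately, and the statistically independent disjoint
variant (high vs mid vs low) is computed alongside it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import TimeLapseStack
from .segment import RoiSet, roi_traces

__all__ = [
    "KineticRecords",
    "GroupSummary",
    "compute_kinetics",
    "one_way_anova",
    "bonferroni_pairwise",
    "summarize_groups",
]


@dataclass
class KineticRecords:
    """Per-ROI traces, baseline F0 and unloaded fractions."""

    traces: np.ndarray  # (n_rois, n_frames) mean-intensity traces
    f0: np.ndarray
    normalized_traces: np.ndarray  # traces / f0, baseline mean exactly 1
    unloaded_fraction: np.ndarray  # fraction internally; percent in outputs
    tail_window_frames: int

    @property
    def n_rois(self) -> int:
        return len(self.f0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": np.arange(1, self.n_rois + 1),
                "f0": self.f0,
                "unloaded_fraction_pct": 100.0 * self.unloaded_fraction,
            }
        )


def compute_kinetics(
    stack: TimeLapseStack, rois: RoiSet, tail_window_frames: int = 10
) -> KineticRecords:
    """Compute per-ROI normalized traces and unloaded fractions."""
    if stack.n_frames < stack.timing.n_baseline_frames + tail_window_frames:
        raise ValueError("stack too short for baseline + tail windows")
    traces = roi_traces(stack, rois)
    nb = stack.timing.n_baseline_frames
    f0 = traces[:, :nb].mean(axis=1)
    if np.any(f0 <= 0):
        raise ValueError("ROI with non-positive baseline mean F0")
    tail = traces[:, stack.n_frames - tail_window_frames :].mean(axis=1)
    return KineticRecords(
        traces=traces,
        f0=f0,
        normalized_traces=traces / f0[:, None],
        unloaded_fraction=(f0 - tail) / f0,
        tail_window_frames=tail_window_frames,
    )


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Textbook one-way fixed-effects ANOVA on k samples.

    Degenerate conventions: if the between-group sum of squares is zero
    (all group means equal, e.g. all values identical) the statistic is
    F = 0 with p = 1; if within-group variance is zero but means differ,
    F = inf with p = 0.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if ss_between <= 0 or np.isclose(ss_between, 0.0, atol=1e-300):
        return 0.0, 1.0
    if ss_within == 0:
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


def bonferroni_pairwise(
    samples: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise two-sample t tests with Bonferroni multiplication.

    Raw p-values are multiplied by the number of pairs actually tested and
    capped at 1.
    """
    names = [k for k, v in samples.items() if len(v) >= 2]
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(samples[a], samples[b])
        p_adj = min(1.0, float(p) * len(pairs))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p_raw", "p_bonferroni", "significant"])


@dataclass
class GroupSummary:
    """Stratified unloading statistics in the overlapping-group design."""

    group_n: dict[str, int]
    unloaded_pct_mean: dict[str, float]
    unloaded_pct_sem: dict[str, float]
    trace_mean: dict[str, np.ndarray]
    trace_sem: dict[str, np.ndarray]
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame
    alpha: float
    anova_skipped: bool = False
    # statistically independent variant over disjoint groups high/mid/low
    disjoint_anova_f: float = float("nan")
    disjoint_anova_p: float = float("nan")
    disjoint_pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.group_n:
            rows.append(
                {
                    "group": g,
                    "n_rois": self.group_n[g],
                    "unloaded_pct_mean": self.unloaded_pct_mean[g],
                    "unloaded_pct_sem": self.unloaded_pct_sem[g],
                }
            )
        return pd.DataFrame(rows)


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def summarize_groups(
    records: KineticRecords, groups: np.ndarray, alpha: float = 0.05
) -> GroupSummary:
    """Stratify unloading by IR group and run the ANOVA/Bonferroni battery.

    ``groups`` holds the per-ROI labels ``high``/``mid``/``low``.  The
    compared samples are ``whole`` (all ROIs), ``high`` and ``low`` —
    the overlapping design — plus the disjoint high/mid/low variant.  If
    the high or low group has fewer than 2 members the ANOVA is skipped
    with a warning rather than failing the run.
    """
    groups = np.asarray(groups)
    if len(groups) != records.n_rois:
        raise ValueError("groups length must equal number of kinetic records")
    u = records.unloaded_fraction
    membership = {
        "whole": np.ones(len(groups), dtype=bool),
        "high": groups == "high",
        "low": groups == "low",
    }
    group_n = {g: int(m.sum()) for g, m in membership.items()}
    unloaded_pct_mean = {}
    unloaded_pct_sem = {}
    trace_mean = {}
    trace_sem = {}
    for g, m in membership.items():
        if m.any():
            unloaded_pct_mean[g] = float(100.0 * u[m].mean())
            unloaded_pct_sem[g] = 100.0 * _sem(u[m])
            tr = records.normalized_traces[m]
            trace_mean[g] = tr.mean(axis=0)
            trace_sem[g] = (
                tr.std(axis=0, ddof=1) / np.sqrt(m.sum()) if m.sum() > 1 else np.full(tr.shape[1], np.nan)
            )
        else:
            unloaded_pct_mean[g] = float("nan")
            unloaded_pct_sem[g] = float("nan")
            trace_mean[g] = np.full(records.traces.shape[1], np.nan)
            trace_sem[g] = np.full(records.traces.shape[1], np.nan)

    skipped = group_n["high"] < 2 or group_n["low"] < 2
    if skipped:
        warnings.warn(
            "high or low IR group has < 2 ROIs; ANOVA skipped", stacklevel=2
        )
        f = p = float("nan")
        pairwise = pd.DataFrame()
        dis_f = dis_p = float("nan")
        dis_pairwise = pd.DataFrame()
    else:
        samples = {g: u[m] for g, m in membership.items()}
        f, p = one_way_anova(list(samples.values()))
        pairwise = bonferroni_pairwise(samples, alpha)
        disjoint = {g: u[groups == g] for g in ("high", "mid", "low") if (groups == g).sum() >= 2}
        if len(disjoint) >= 2:
            dis_f, dis_p = one_way_anova(list(disjoint.values()))
            dis_pairwise = bonferroni_pairwise(disjoint, alpha)
        else:
            dis_f = dis_p = float("nan")
            dis_pairwise = pd.DataFrame()

    return GroupSummary(
        group_n=group_n,
        unloaded_pct_mean=unloaded_pct_mean,
        unloaded_pct_sem=unloaded_pct_sem,
        trace_mean=trace_mean,
        trace_sem=trace_sem,
        anova_f=f,
        anova_p=p,
        pairwise=pairwise,
        alpha=alpha,
        anova_skipped=skipped,
        disjoint_anova_f=dis_f,
        disjoint_anova_p=dis_p,
        disjoint_pairwise=dis_pairwise,
    )
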