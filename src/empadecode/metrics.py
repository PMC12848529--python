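"""Single-subject temporal decoding metrics and brain-behavior relations.

From each subject's significant decoding clusters three metrics are
extracted: onset latency (start of the first cluster), sustainability
(total duration of all clusters, counted as members x sample period with
inclusive endpoints) and peak latency (time of the maximum statistic
within the union of significant clusters; a global argmax is available by
flag).  Metrics exist only for "decoders" — subjects with at least one
significant cluster.  Group comparisons use independent-samples t-tests
(pooled variance by default, Welch by flag); brain-behavior relations are
Spearman correlations between each metric and a behavioral
positive-minus-negative difference score, pooling decodable subjects from
both groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BrainBehaviorResult, Cluster, SubjectMetrics, TimeCourse

__all__ = [
    "extract_metrics",
    "metrics_table",
    "compare_groups",
    "behavior_differences",
    "brain_behavior",
]


def extract_metrics(
    timecourse: TimeCourse,
    clusters: list[Cluster],
    peak_global: bool = False,
    group=None,
    task=None,
) -> SubjectMetrics:
    """Onset / sustainability / peak latency from significant clusters.

    ``clusters`` must be 1D clusters on the same time axis as
    ``timecourse``; an empty list marks the subject as a non-decoder with
    all metrics missing."""
    times = timecourse.times
    if not clusters:
        return SubjectMetrics(
            subject_id=timecourse.subject_id, decoder=False, group=group, task=task
        )
    member_idx = np.concatenate([np.asarray(c.indices).ravel() for c in clusters])
    if member_idx.min() < 0 or member_idx.max() >= len(times):
        raise ValueError("cluster indices out of range of the time axis")
    dt = float(times[1] - times[0])
    onset = float(times[member_idx.min()])
    sustainability = float(len(np.unique(member_idx)) * dt)
    if peak_global:
        peak = float(times[int(np.argmax(timecourse.values))])
    else:
        vals = timecourse.values[member_idx]
        peak = float(times[member_idx[int(np.argmax(vals))]])
    return SubjectMetrics(
        subject_id=timecourse.subject_id,
        decoder=True,
        onset_latency=onset,
        sustainability=sustainability,
        peak_latency=peak,
        group=group,
        task=task,
    )


def metrics_table(metrics: list[SubjectMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in metrics],
            "group": [m.group for m in metrics],
            "task": [m.task for m in metrics],
            "decoder": [m.decoder for m in metrics],
            "onset_ms": [m.onset_latency for m in metrics],
            "sustain_ms": [m.sustainability for m in metrics],
            "peak_ms": [m.peak_latency for m in metrics],
        }
    )


_METRIC_FIELDS = {
    "onset_latency": "onset_latency",
    "sustainability": "sustainability",
    "peak_latency": "peak_latency",
}


def compare_groups(
    metrics_a: list[SubjectMetrics],
    metrics_b: list[SubjectMetrics],
    welch: bool = False,
) -> dict[str, dict]:
    """Independent-samples t-test per metric over decodable subjects only.

    Groups with fewer than 2 decoders are flagged and the test skipped."""
    out: dict[str, dict] = {}
    dec_a = [m for m in metrics_a if m.decoder]
    dec_b = [m for m in metrics_b if m.decoder]
    for name, attr in _METRIC_FIELDS.items():
        x = np.array([getattr(m, attr) for m in dec_a], dtype=float)
        y = np.array([getattr(m, attr) for m in dec_b], dtype=float)
        if len(x) < 2 or len(y) < 2:
            out[name] = {"skipped": True, "reason": "fewer than 2 decoders in a group"}
            continue
        res = stats.ttest_ind(x, y, equal_var=not welch)
        df = res.df if hasattr(res, "df") else len(x) + len(y) - 2
        out[name] = {
            "t": float(res.statistic),
            "p": float(res.pvalue),
            "df": float(df),
            "n_a": len(x),
            "n_b": len(y),
            "skipped": False,
        }
    return out


def behavior_differences(behavior: pd.DataFrame, task: str) -> pd.DataFrame:
    """Per-subject positive-minus-negative difference scores for one task.

    Returns columns subject_id, rt_diff, acc_diff, rating_diff."""
    sub = behavior[behavior["task"] == task]
    wide = sub.pivot_table(
        index="subject_id", columns="emotion", values=["mean_rt", "mean_acc", "mean_rating"]
    )
    out = pd.DataFrame(index=wide.index)
    for dv, name in (("mean_rt", "rt_diff"), ("mean_acc", "acc_diff"), ("mean_rating", "rating_diff")):
        out[name] = wide[(dv, "positive")] - wide[(dv, "negative")]
    return out.reset_index()


def brain_behavior(
    metrics: list[SubjectMetrics],
    behavior_diffs: pd.DataFrame,
    min_n: int = 5,
) -> list[BrainBehaviorResult]:
    """Spearman correlations between each neural metric and each behavioral
    difference score, over decodable subjects that join the behavior table.
    Pairs with fewer than ``min_n`` subjects are skipped."""
    table = metrics_table(metrics)
    table = table[table["decoder"]]
    merged = table.merge(behavior_diffs, on="subject_id", how="inner")
    results: list[BrainBehaviorResult] = []
    metric_cols = {"onset_latency": "onset_ms", "sustainability": "sustain_ms", "peak_latency": "peak_ms"}
    diff_cols = [c for c in behavior_diffs.columns if c != "subject_id"]
    for mname, mcol in metric_cols.items():
        for bcol in diff_cols:
            sub = merged[[mcol, bcol]].dropna()
            n = len(sub)
            if n < min_n:
                continue
            if sub[mcol].nunique() < 2 or sub[bcol].nunique() < 2:
                continue  # constant input: correlation undefined
            rho, p = stats.spearmanr(sub[mcol], sub[bcol])
            results.append(
                BrainBehaviorResult(
                    metric=mname, behavior=bcol, spearman_rho=float(rho), p=float(p), n=n
                )
            )
    return results
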