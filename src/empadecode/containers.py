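"""Core in-memory containers shared by all analysis stages.

The containers are thin dataclasses around numpy arrays and pandas frames:
``EpochSet`` holds epoched multi-channel EEG with per-trial metadata,
``TimeCourse`` a per-subject statistic versus time (decoding AUC or an
RSA correlation), ``GeneralizationMatrix`` a train-time x test-time AUC
matrix, and ``RDMSeries`` a stack of per-timepoint representational
dissimilarity matrices.  Validation happens at construction so that
downstream code can assume consistent shapes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "TimeCourse",
    "GeneralizationMatrix",
    "RDMSeries",
    "RejectionReport",
    "Cluster",
    "ClusterTestResult",
    "SubjectMetrics",
    "BrainBehaviorResult",
]

#: metadata columns every EpochSet carries per trial
TRIAL_META_COLUMNS = ("subject_id", "group", "task", "stimulus_id", "category")


@dataclass
class EpochSet:
    """Epoched EEG: ``data`` is trials x channels x samples in signal units.

    ``times`` is the epoch time axis in milliseconds (uniformly spaced at
    1000/fs), ``trial_meta`` one row per trial with at least the columns in
    :data:`TRIAL_META_COLUMNS`.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    channel_names: list[str]
    trial_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.times) != n_samples:
            raise ValueError("times length must equal number of samples")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1000.0 / self.fs, rtol=1e-6)):
            raise ValueError("times must increase uniformly at 1000/fs ms")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length must equal number of channels")
        if len(self.trial_meta) != n_trials:
            raise ValueError("trial_meta must have one row per trial")
        missing = set(TRIAL_META_COLUMNS) - set(self.trial_meta.columns)
        if missing:
            raise ValueError(f"trial_meta missing columns: {sorted(missing)}")
        self.trial_meta = self.trial_meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        """Return a copy restricted to the trials where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype == bool and len(mask) != self.n_trials:
            raise ValueError("boolean mask length mismatch")
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            times=self.times,
            channel_names=list(self.channel_names),
            trial_meta=self.trial_meta.iloc[mask].reset_index(drop=True),
        )

    # -- serialization: raw array + JSON sidecar --------------------------
    def save(self, path: str | Path) -> None:
        """Write ``<path>.npy`` (the data array) and ``<path>.json`` (sidecar
        with fs, times, channel names and trial metadata records)."""
        path = Path(path)
        stem = path.with_suffix("")
        np.save(stem.with_suffix(".npy"), self.data)
        sidecar = {
            "fs": float(self.fs),
            "times_ms": self.times.tolist(),
            "channel_names": list(self.channel_names),
            "trial_meta": self.trial_meta.to_dict(orient="list"),
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        stem = Path(path).with_suffix("")
        data = np.load(stem.with_suffix(".npy"))
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        return cls(
            data=data,
            fs=sidecar["fs"],
            times=np.asarray(sidecar["times_ms"]),
            channel_names=sidecar["channel_names"],
            trial_meta=pd.DataFrame(sidecar["trial_meta"]),
        )


@dataclass
class TimeCourse:
    """A statistic sampled on the epoch time axis for one subject."""

    times: np.ndarray
    values: np.ndarray
    subject_id: object = None
    statistic_name: str = "auc"
    chance_level: float = 0.5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have identical shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times,
                self.statistic_name: self.values,
                "subject_id": self.subject_id,
            }
        )


@dataclass
class GeneralizationMatrix:
    """Train-time x test-time decoding performance (AUC)."""

    train_times: np.ndarray
    test_times: np.ndarray
    values: np.ndarray
    subject_id: object = None

    def __post_init__(self) -> None:
        self.train_times = np.asarray(self.train_times, dtype=float)
        self.test_times = np.asarray(self.test_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.train_times), len(self.test_times)):
            raise ValueError("values must be (n_train_times, n_test_times)")

    def diagonal(self) -> TimeCourse:
        if not np.array_equal(self.train_times, self.test_times):
            raise ValueError("diagonal undefined on mismatched axes")
        return TimeCourse(self.train_times, np.diag(self.values), self.subject_id)


@dataclass
class RDMSeries:
    """Per-timepoint symmetric stimulus dissimilarity matrices.

    ``matrices`` has shape (n_times, n_stim, n_stim); entries are pairwise
    decoding accuracies, so greater dissimilarity = higher decodability.
    The diagonal carries no information and is ignored.
    """

    times: np.ndarray
    matrices: np.ndarray
    stimulus_ids: np.ndarray
    subject_id: object = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        n_stim = len(self.stimulus_ids)
        if self.matrices.shape != (len(self.times), n_stim, n_stim):
            raise ValueError("matrices must be (n_times, n_stim, n_stim)")
        if not np.allclose(self.matrices, np.swapaxes(self.matrices, 1, 2), equal_nan=True):
            raise ValueError("RDMs must be symmetric")

    @property
    def n_stim(self) -> int:
        return len(self.stimulus_ids)

    def lower_triangles(self) -> np.ndarray:
        """Vectorized lower triangles, shape (n_times, n_pairs)."""
        i, j = np.tril_indices(self.n_stim, k=-1)
        return self.matrices[:, i, j]

    def to_long_frame(self) -> pd.DataFrame:
        i, j = np.tril_indices(self.n_stim, k=-1)
        rows = []
        for t_idx, t in enumerate(self.times):
            rows.append(
                pd.DataFrame(
                    {
                        "time_ms": t,
                        "stim_i": self.stimulus_ids[i],
                        "stim_j": self.stimulus_ids[j],
                        "dissimilarity": self.matrices[t_idx, i, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class RejectionReport:
    """Bookkeeping for amplitude-based trial rejection."""

    n_input_trials: int
    n_rejected: int
    rejected_indices: list[int]
    threshold: float

    def __post_init__(self) -> None:
        if self.n_rejected != len(self.rejected_indices):
            raise ValueError("n_rejected inconsistent with rejected_indices")
        if self.n_rejected > self.n_input_trials:
            raise ValueError("cannot reject more trials than supplied")

    @property
    def rejection_rate(self) -> float:
        return self.n_rejected / self.n_input_trials if self.n_input_trials else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input_trials": self.n_input_trials,
                "n_rejected": self.n_rejected,
                "rejected_indices": list(map(int, self.rejected_indices)),
                "threshold": self.threshold,
            }
        )


@dataclass
class Cluster:
    """A contiguous supra-threshold region of a statistic map.

    ``indices`` holds flat member indices for 1D maps or (row, col) pairs for
    2D maps; ``mass`` is the maxsum cluster statistic (sum of the point-level
    statistics over members).
    """

    indices: np.ndarray
    mass: float
    p_value: float = np.nan

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices)

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class ClusterTestResult:
    """Outcome of a cluster-based permutation test."""

    point_stats: np.ndarray
    point_p: np.ndarray
    clusters: list[Cluster]
    null_distribution: np.ndarray
    alpha_cluster: float = 0.05
    n_permutations: int = 1000
    times: np.ndarray | None = None

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= self.alpha_cluster]

    def significant_mask(self) -> np.ndarray:
        mask = np.zeros(self.point_stats.shape, dtype=bool)
        for c in self.significant_clusters():
            if mask.ndim == 1:
                mask[c.indices] = True
            else:
                mask[tuple(c.indices.T)] = True
        return mask

    def to_json(self) -> str:
        out = []
        for c in self.clusters:
            entry = {"mass": float(c.mass), "p": float(c.p_value), "size": int(c.size)}
            if self.times is not None and c.indices.ndim == 1:
                entry["start_ms"] = float(self.times[int(np.min(c.indices))])
                entry["end_ms"] = float(self.times[int(np.max(c.indices))])
            out.append(entry)
        return json.dumps({"clusters": out, "n_permutations": int(self.n_permutations)})


@dataclass
class SubjectMetrics:
    """Single-subject temporal decoding metrics extracted from significant
    clusters: onset latency (start of the first cluster), sustainability
    (summed duration of all clusters) and peak latency (time of maximum
    statistic inside the significant set)."""

    subject_id: object
    decoder: bool
    onset_latency: float = np.nan
    sustainability: float = np.nan
    peak_latency: float = np.nan
    group: object = None
    task: object = None


@dataclass
class BrainBehaviorResult:
    """Spearman association between a neural metric and a behavioral
    positive-minus-negative difference score."""

    metric: str
    behavior: str
    spearman_rho: float
    p: float
    n: int
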