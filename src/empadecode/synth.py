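"""Synthetic stimuli, trial designs, EEG epochs and behavioral tables.

The generator emulates the statistical structure that the downstream
analyses assume: a two-group (high-ALT / low-ALT), two-task (CE / AE)
design with 20 emotional-scene stimuli (10 positive, 10 negative) shown 16
times each per block, 64-channel epochs from -200 to 500 ms at 200 Hz, and
two additive multivariate signal components embedded in temporally
autocorrelated noise:

* a *category* component — a fixed random spatial pattern whose sign
  follows the stimulus' emotion category, active in a configurable
  time window, which makes the category decodable;
* a *low-level feature* component — two further spatial patterns
  (orthogonalized against the category pattern) driven by each stimulus'
  standardized luminance and contrast, which gives the neural RDM the
  geometry of the low-level feature model.

Noise is AR(1) Gaussian per trial and channel, a deliberately simple
stand-in for 1/f EEG background that still gives cluster-based inference a
temporally correlated null.  All generators are pure functions of their
seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .containers import EpochSet

__all__ = [
    "EffectSpec",
    "BehaviorEffects",
    "make_stimulus_set",
    "make_trial_design",
    "simulate_epochs",
    "simulate_behavior",
    "simulate_subject",
]

CATEGORIES = ("positive", "negative")


@dataclass
class EffectSpec:
    """Parameters of the injected signal components and the noise.

    Amplitudes are in the same (arbitrary) signal units as ``noise_sd``, so
    ``category_amplitude / noise_sd`` is the per-channel-pattern SNR.
    Onsets/durations are in ms relative to stimulus onset.
    """

    category_amplitude: float = 0.0
    category_onset: float = 100.0
    category_duration: float = 300.0
    feature_amplitude: float = 0.0
    feature_onset: float = 100.0
    feature_duration: float = 300.0
    #: idiosyncratic per-stimulus response patterns, drawn fresh per subject
    #: (from the epoch seed, not the shared pattern seed); they model the
    #: exemplar-specific component of real evoked responses, which makes
    #: representational geometry vary across subjects
    exemplar_amplitude: float = 0.0
    spatial_pattern_seed: int = 0
    noise_sd: float = 1.0
    noise_ar1: float = 0.5
    ramp_ms: float = 10.0

    def validate(self, window: tuple[float, float]) -> None:
        vals = [
            self.category_amplitude,
            self.category_onset,
            self.category_duration,
            self.feature_amplitude,
            self.feature_onset,
            self.feature_duration,
            self.exemplar_amplitude,
            self.noise_sd,
            self.noise_ar1,
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("EffectSpec parameters must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must be in [0, 1)")
        if self.category_duration <= 0 or self.feature_duration <= 0:
            raise ValueError("effect durations must be > 0")
        lo, hi = window
        for onset in (self.category_onset, self.feature_onset):
            if not lo <= onset <= hi:
                raise ValueError("effect onset must lie inside the epoch window")


def make_stimulus_set(
    n_per_category: int = 10,
    luminance_range: tuple[float, float] = (0.2, 0.8),
    contrast_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> pd.DataFrame:
    """Stimulus table: ``n_per_category`` positive + as many negative images
    with per-image mean luminance and contrast drawn uniformly from the
    given ranges (the real images' feature values are not published, so the
    ranges are configurable)."""
    if n_per_category < 2:
        raise ValueError("need at least 2 stimuli per category for pairwise decoding")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_category
    table = pd.DataFrame(
        {
            "stimulus_id": np.arange(1, n + 1),
            "category": np.repeat(CATEGORIES, n_per_category),
            "luminance": rng.uniform(*luminance_range, size=n),
            "contrast": rng.uniform(*contrast_range, size=n),
        }
    )
    return table


def make_trial_design(
    stimuli: pd.DataFrame,
    repetitions: int = 16,
    task: str = "CE",
    seed: int = 0,
    max_attempts: int = 200,
) -> pd.DataFrame:
    """Pseudorandomized trial order: each stimulus exactly ``repetitions``
    times, with no immediate stimulus repetition.

    Returns a frame with columns ``trial_index``, ``stimulus_id``, ``task``.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if task not in ("CE", "AE"):
        raise ValueError("task must be 'CE' or 'AE'")
    ids = np.asarray(stimuli["stimulus_id"])
    n_stim = len(ids)
    total = n_stim * repetitions
    # no-adjacent-repeat order exists iff the most frequent id fits into
    # every other slot
    if repetitions > (total + 1) // 2 and total > 1:
        raise ValueError("no-repeat constraint unsatisfiable for this design")
    rng = np.random.default_rng(seed)
    pool = np.repeat(ids, repetitions)
    for _ in range(max_attempts):
        order = rng.permutation(pool)
        if _repair_adjacent(order, rng):
            return pd.DataFrame(
                {"trial_index": np.arange(total), "stimulus_id": order, "task": task}
            )
    raise ValueError("failed to build a no-repeat pseudorandom order")


def _repair_adjacent(order: np.ndarray, rng: np.random.Generator) -> bool:
    """Fix adjacent duplicates in-place by swapping with a compatible slot."""
    for _ in range(10):
        dup = np.flatnonzero(order[1:] == order[:-1]) + 1
        if len(dup) == 0:
            return True
        for i in dup:
            candidates = np.flatnonzero(
                (order != order[i])
                & (np.roll(order, 1) != order[i])
                & (np.roll(order, -1) != order[i])
            )
            candidates = candidates[(candidates < i - 1) | (candidates > i + 1)]
            if len(candidates) == 0:
                break
            j = rng.choice(candidates)
            order[i], order[j] = order[j], order[i]
    return bool(np.all(order[1:] != order[:-1]))


def _edge_window(times: np.ndarray, onset: float, duration: float, ramp: float) -> np.ndarray:
    """Boxcar with raised-cosine edges (``ramp`` ms each side)."""
    t = np.asarray(times, dtype=float)
    w = np.zeros_like(t)
    end = onset + duration
    ramp = min(ramp, duration / 2.0)
    inside = (t >= onset) & (t <= end)
    w[inside] = 1.0
    if ramp > 0:
        up = inside & (t < onset + ramp)
        w[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - onset) / ramp))
        down = inside & (t > end - ramp)
        w[down] = 0.5 * (1 - np.cos(np.pi * (end - t[down]) / ramp))
    return w


def _spatial_patterns(n_channels: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-norm category pattern plus two feature patterns orthogonalized
    against it (and each other), so category and feature signals live in
    separable subspaces by construction."""
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((3, n_channels))
    q, _ = np.linalg.qr(vecs.T)
    p_cat, q_lum, q_con = q.T[:3]
    return p_cat, q_lum, q_con


def simulate_epochs(
    design: pd.DataFrame,
    stimuli: pd.DataFrame,
    effects: EffectSpec,
    n_channels: int = 64,
    fs: float = 200.0,
    window: tuple[float, float] = (-200.0, 500.0),
    seed: int = 0,
    subject_id: object = 0,
    group: str = "low-ALT",
) -> EpochSet:
    """Simulate one subject-block of epochs for a trial design.

    data = AR(1) Gaussian noise
         + category_amplitude * (+/-1 by category) * spatial pattern * window
         + feature_amplitude * (z-luminance, z-contrast) . feature patterns * window
         + exemplar_amplitude * per-stimulus random pattern * window

    The category/feature patterns are fixed by ``spatial_pattern_seed`` and
    shared across subjects; the exemplar patterns are drawn from ``seed``
    and therefore subject-specific.
    """
    lo, hi = window
    if not lo <= 0 <= hi:
        raise ValueError("epoch window must span stimulus onset (0 ms)")
    effects.validate(window)
    dt = 1000.0 / fs
    n_samples = int(round((hi - lo) / dt)) + 1
    times = lo + dt * np.arange(n_samples)

    stim = stimuli.set_index("stimulus_id")
    trial_stim = np.asarray(design["stimulus_id"])
    n_trials = len(trial_stim)

    rng = np.random.default_rng(seed)
    # AR(1) noise with stationary sd = noise_sd; burn-in trimmed
    a = effects.noise_ar1
    burn = 25
    innov = rng.standard_normal((n_trials, n_channels, n_samples + burn))
    innov *= effects.noise_sd * np.sqrt(1.0 - a**2)
    data = lfilter([1.0], [1.0, -a], innov, axis=-1)[..., burn:]

    p_cat, q_lum, q_con = _spatial_patterns(n_channels, effects.spatial_pattern_seed)

    if effects.category_amplitude != 0.0:
        w = _edge_window(times, effects.category_onset, effects.category_duration, effects.ramp_ms)
        sign = np.where(stim.loc[trial_stim, "category"].to_numpy() == "positive", 1.0, -1.0)
        data += (
            effects.category_amplitude
            * sign[:, None, None]
            * p_cat[None, :, None]
            * w[None, None, :]
        )
    if effects.exemplar_amplitude != 0.0:
        w = _edge_window(times, effects.category_onset, effects.category_duration, effects.ramp_ms)
        n_stim = len(stim)
        ex_patterns = rng.standard_normal((n_stim, n_channels)) / np.sqrt(n_channels)
        pos = stim.index.get_indexer(trial_stim)
        data += effects.exemplar_amplitude * ex_patterns[pos][:, :, None] * w[None, None, :]
    if effects.feature_amplitude != 0.0:
        feats = stim.loc[trial_stim, ["luminance", "contrast"]].to_numpy()
        all_feats = stim[["luminance", "contrast"]].to_numpy()
        z = (feats - all_feats.mean(0)) / all_feats.std(0)
        w = _edge_window(times, effects.feature_onset, effects.feature_duration, effects.ramp_ms)
        pattern = z[:, 0, None] * q_lum[None, :] + z[:, 1, None] * q_con[None, :]
        data += effects.feature_amplitude * pattern[:, :, None] * w[None, None, :]

    task = design["task"].iloc[0] if "task" in design else "CE"
    meta = pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": group,
            "task": task,
            "stimulus_id": trial_stim,
            "category": stim.loc[trial_stim, "category"].to_numpy(),
        }
    )
    channel_names = [f"EEG{i:03d}" for i in range(1, n_channels + 1)]
    return EpochSet(data=data, fs=fs, times=times, channel_names=channel_names, trial_meta=meta)


def simulate_subject(
    effects: EffectSpec,
    stimuli: pd.DataFrame | None = None,
    repetitions: int = 16,
    task: str = "CE",
    n_channels: int = 64,
    fs: float = 200.0,
    window: tuple[float, float] = (-200.0, 500.0),
    seed: int = 0,
    subject_id: object = 0,
    group: str = "low-ALT",
) -> EpochSet:
    """Convenience wrapper: stimulus set + design + epochs from one seed."""
    ss = np.random.SeedSequence(seed)
    s_stim, s_design, s_epochs = ss.generate_state(3) >> np.uint32(1)
    if stimuli is None:
        stimuli = make_stimulus_set(seed=int(s_stim))
    design = make_trial_design(stimuli, repetitions=repetitions, task=task, seed=int(s_design))
    return simulate_epochs(
        design,
        stimuli,
        effects,
        n_channels=n_channels,
        fs=fs,
        window=window,
        seed=int(s_epochs),
        subject_id=subject_id,
        group=group,
    )


@dataclass
class BehaviorEffects:
    """Cell-mean model for one behavioral dependent variable.

    ``emotion_effect`` is the positive-minus-negative difference,
    ``group_effect`` the high-minus-low-ALT difference, and ``interaction``
    the difference of those differences; ``subject_sd`` is the
    between-subject intercept SD and ``cell_sd`` the residual within-cell SD.
    """

    baseline: float
    emotion_effect: float = 0.0
    group_effect: float = 0.0
    interaction: float = 0.0
    subject_sd: float = 1.0
    cell_sd: float = 0.5

    def validate(self) -> None:
        if self.subject_sd < 0 or self.cell_sd < 0:
            raise ValueError("standard deviations must be non-negative")


#: defaults loosely shaped after the observed behavioral pattern: a positive-
#: emotion advantage in accuracy and rating, no group effects
DEFAULT_BEHAVIOR = {
    "rt": BehaviorEffects(baseline=900.0, subject_sd=150.0, cell_sd=50.0),
    "acc": BehaviorEffects(baseline=0.545, emotion_effect=0.07, subject_sd=0.10, cell_sd=0.03),
    "rating": BehaviorEffects(baseline=5.7, emotion_effect=0.7, subject_sd=1.2, cell_sd=0.4),
}

_BOUNDS = {"rt": (1.0, np.inf), "acc": (0.0, 1.0), "rating": (1.0, 9.0)}


def simulate_behavior(
    n_per_group: int = 20,
    group_effects: dict[str, BehaviorEffects] | None = None,
    seed: int = 0,
    tasks: tuple[str, ...] = ("CE", "AE"),
) -> pd.DataFrame:
    """Behavioral table: one row per subject x task x emotion with mean RT,
    accuracy and empathy rating, for a two-group design."""
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    eff = dict(DEFAULT_BEHAVIOR)
    if group_effects:
        eff.update(group_effects)
    for e in eff.values():
        e.validate()
    rng = np.random.default_rng(seed)

    rows = []
    subj = 0
    for group, s_g in (("high-ALT", 1.0), ("low-ALT", -1.0)):
        for _ in range(n_per_group):
            intercepts = {dv: rng.normal(0.0, eff[dv].subject_sd) for dv in eff}
            for task in tasks:
                for emotion, s_e in (("positive", 1.0), ("negative", -1.0)):
                    row = {"subject_id": subj, "group": group, "task": task, "emotion": emotion}
                    for dv, e in eff.items():
                        val = (
                            e.baseline
                            + 0.5 * s_e * e.emotion_effect
                            + 0.5 * s_g * e.group_effect
                            + 0.25 * s_e * s_g * e.interaction
                            + intercepts[dv]
                            + rng.normal(0.0, e.cell_sd)
                        )
                        lo, hi = _BOUNDS[dv]
                        row[f"mean_{dv}"] = float(np.clip(val, lo, hi))
                    rows.append(row)
            subj += 1
    return pd.DataFrame(rows)
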