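"""Presentation scheduling and click-stream matching.

A session presents every peripheral stimulus ``weight`` times in a random
order, one at a time, separated by randomised blank gaps during which only
the central disc is shown.  The observer signals each detection with a
mouse click; the recorded click times are later matched back to trials to
produce the per-stimulus miss counts that feed the disturbance index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import StimulusLayout, generate_layout, validate_config


@dataclass(frozen=True)
class PresentationSchedule:
    """Ordered, timed trials of one session.

    ``trials`` has columns ``trial_index, stimulus_id, onset_s, offset_s``.
    The first onset falls after the dark-adaptation and central-stimulus
    adaptation periods; each trial lasts exactly the exposure time and the
    offset-to-next-onset gap is a uniform draw from the configured refresh
    interval.
    """

    trials: pd.DataFrame
    seed: int
    layout: StimulusLayout

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def end_s(self) -> float:
        """End of the last response window."""
        return float(self.trials["offset_s"].iloc[-1] + self.layout.config.refresh_max_s)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


def build_schedule(layout: StimulusLayout, seed: int) -> PresentationSchedule:
    """Randomise trial order and inter-trial gaps for one session.

    The trial sequence is a uniform permutation of the multiset in which
    each stimulus id occurs ``weight`` times; both the permutation and the
    gap draws come from a single generator seeded with ``seed``, so the
    schedule is exactly reproducible.
    """
    cfg = validate_config(layout.config)
    rng = np.random.default_rng(seed)
    ids = np.repeat(layout.stimulus_ids, cfg.weight)
    order = rng.permutation(ids)
    n = len(order)
    gaps = rng.uniform(cfg.refresh_min_s, cfg.refresh_max_s, size=n - 1) if n > 1 else np.array([])
    onsets = np.empty(n)
    onsets[0] = cfg.darkness_s + cfg.main_adapt_s
    for i in range(1, n):
        onsets[i] = onsets[i - 1] + cfg.exposure_s + gaps[i - 1]
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "stimulus_id": order,
            "onset_s": onsets,
            "offset_s": onsets + cfg.exposure_s,
        }
    )
    return PresentationSchedule(trials=trials, seed=seed, layout=layout)


def read_schedule(path, layout: StimulusLayout, seed: int = -1) -> PresentationSchedule:
    """Load a schedule exported with :meth:`PresentationSchedule.to_csv`."""
    trials = pd.read_csv(path)
    required = {"trial_index", "stimulus_id", "onset_s", "offset_s"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    return PresentationSchedule(trials=trials, seed=seed, layout=layout)


@dataclass
class DetectionMatrix:
    """Per-stimulus presentation and miss counts, plus session false positives.

    ``misses[i]`` is p_i: how many of the ``presentations[i]`` showings of
    stimulus ``stimulus_ids[i]`` drew no click.  Clicks that land in no
    response window, or beyond the first click of a window, count as false
    positives for the whole session.
    """

    stimulus_ids: np.ndarray
    presentations: np.ndarray
    misses: np.ndarray
    false_positive_count: int = 0

    def __post_init__(self):
        self.stimulus_ids = np.asarray(self.stimulus_ids, dtype=int)
        self.presentations = np.asarray(self.presentations, dtype=int)
        self.misses = np.asarray(self.misses, dtype=int)
        if not (len(self.stimulus_ids) == len(self.presentations) == len(self.misses)):
            raise ValueError("stimulus_ids, presentations and misses must align")
        if np.any(self.misses < 0) or np.any(self.misses > self.presentations):
            raise ValueError("miss counts must satisfy 0 <= p_i <= presentations")
        if self.false_positive_count < 0:
            raise ValueError("false_positive_count must be >= 0")

    @property
    def detections(self) -> np.ndarray:
        return self.presentations - self.misses

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": self.stimulus_ids,
                "presentations": self.presentations,
                "misses": self.misses,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, false_positive_count: int = 0) -> "DetectionMatrix":
        return cls(
            stimulus_ids=frame["stimulus_id"].to_numpy(),
            presentations=frame["presentations"].to_numpy(),
            misses=frame["misses"].to_numpy(),
            false_positive_count=false_positive_count,
        )

    @classmethod
    def from_csv(cls, path) -> "DetectionMatrix":
        return cls.from_frame(pd.read_csv(path))


def match_responses(
    schedule: PresentationSchedule,
    click_times_s,
    *,
    end_time_s: float | None = None,
) -> DetectionMatrix:
    """Attribute clicks to trials and count per-stimulus misses.

    A trial's response window runs from its onset to the next trial's
    onset (for the last trial: offset plus the maximum refresh gap), so a
    click during the blank after a stimulus is credited to that stimulus —
    reaction times routinely outlast short gaps.  The first click in a
    window detects the trial; surplus clicks in a window and clicks in no
    window are false positives.  Clicks after the schedule end are counted
    as false positives with a warning.

    ``end_time_s`` optionally truncates the session: trials with onset
    after it are excluded entirely (an aborted run) instead of being
    scored as misses.
    """
    clicks = np.asarray(click_times_s, dtype=float)
    if clicks.ndim != 1:
        raise ValueError("click times must be a 1-D sequence")
    if np.any(np.diff(clicks) < 0):
        raise ValueError("click times must be sorted ascending")
    if clicks.size and clicks[0] < 0:
        raise ValueError("click times must be non-negative")

    trials = schedule.trials
    if end_time_s is not None:
        trials = trials[trials["onset_s"] <= end_time_s].reset_index(drop=True)
        if trials.empty:
            raise ValueError("end_time_s precedes every trial onset")
    onsets = trials["onset_s"].to_numpy()
    end = float(trials["offset_s"].iloc[-1] + schedule.layout.config.refresh_max_s)

    n_late = int(np.sum(clicks >= end))
    if n_late:
        warnings.warn(
            f"{n_late} click(s) after the schedule end counted as false positives",
            stacklevel=2,
        )

    # window of trial i is [onsets[i], onsets[i+1]); last window ends at `end`
    bounds = np.append(onsets, end)
    idx = np.searchsorted(bounds, clicks, side="right") - 1
    in_window = (idx >= 0) & (clicks < end)
    false_positives = int(np.sum(~in_window))

    detected_trials = np.zeros(len(trials), dtype=bool)
    for trial in idx[in_window]:
        if detected_trials[trial]:
            false_positives += 1
        else:
            detected_trials[trial] = True

    ids = schedule.layout.stimulus_ids
    trial_sid = trials["stimulus_id"].to_numpy()
    presentations = np.array([np.sum(trial_sid == sid) for sid in ids])
    detections = np.array(
        [np.sum(detected_trials[trial_sid == sid]) for sid in ids]
    )
    return DetectionMatrix(
        stimulus_ids=ids,
        presentations=presentations,
        misses=presentations - detections,
        false_positive_count=false_positives,
    )


def read_clicks(path) -> np.ndarray:
    """Load a click log: CSV with a single ``click_time_s`` column."""
    frame = pd.read_csv(path)
    if "click_time_s" not in frame.columns:
        raise ValueError("click log must have a click_time_s column")
    return frame["click_time_s"].to_numpy(dtype=float)


def write_clicks(click_times_s, path) -> None:
    pd.DataFrame({"click_time_s": np.asarray(click_times_s, dtype=float)}).to_csv(
        path, index=False
    )
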