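"""Trial-aligned session containers and HDF5 persistence.

A session couples a behavioral trial table with two-channel ROI fluorescence
traces sampled at a fixed frame rate (11.5 Hz by default): an activity channel
(GCaMP6s-like) and an activity-independent control channel (mRuby2-like).
Frames are 0-based; all time spans are half-open ``[start, end)`` in seconds
relative to trial start.  Frames not belonging to any trial carry the trial id
``-1`` and are treated as spontaneous-activity segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "revlearn-session-1"

STIMULI = ("P120", "P280")
OUTCOMES = ("hit", "miss", "FA", "CR")


@dataclass(frozen=True)
class TrialLayout:
    """Within-trial timing: baseline, auditory cue, delay, texture, post period.

    Defaults follow the Go/No-go task structure: a 1-s pre-stimulus baseline,
    a 200-ms auditory cue, a 500-ms delay, then a 2-s texture presentation.
    The default post period stretches the trial toward the task's ~6
    trials/min pacing so that slow indicator transients decay between
    consecutive texture windows.
    """

    baseline_s: float = 1.0
    cue_s: float = 0.2
    delay_s: float = 0.5
    texture_s: float = 2.0
    post_s: float = 3.3

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"trial layout duration {name} must be positive")

    @property
    def cue_onset_s(self) -> float:
        return self.baseline_s

    @property
    def texture_onset_s(self) -> float:
        return self.baseline_s + self.cue_s + self.delay_s

    @property
    def texture_offset_s(self) -> float:
        return self.texture_onset_s + self.texture_s

    @property
    def total_s(self) -> float:
        return self.texture_offset_s + self.post_s

    def n_frames(self, frame_rate: float) -> int:
        return int(round(self.total_s * frame_rate))


@dataclass
class TrialRecord:
    """One behavioral trial: stimulus, contingency, events and outcome.

    ``lick_times`` and ``whisk_times`` are seconds relative to trial start.
    ``reaction_time_s`` is the latency from texture onset to the first lick in
    the texture window and is NaN when no such lick occurred.
    """

    trial_id: int
    session_id: str
    stimulus: str
    rewarded_stimulus: str
    lick_times: np.ndarray
    whisk_times: np.ndarray
    outcome: str
    reaction_time_s: float = np.nan

    def __post_init__(self) -> None:
        if self.stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus!r}")
        if self.rewarded_stimulus not in STIMULI:
            raise ValueError(f"unknown rewarded stimulus {self.rewarded_stimulus!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        self.whisk_times = np.asarray(self.whisk_times, dtype=float)

    @property
    def is_go(self) -> bool:
        """Go trial = the currently rewarded texture was presented."""
        return self.stimulus == self.rewarded_stimulus

    @property
    def licked(self) -> bool:
        return self.outcome in ("hit", "FA")

    @property
    def correct(self) -> bool:
        return self.outcome in ("hit", "CR")


@dataclass
class SessionData:
    """Aligned container: trial table + per-neuron trace matrices.

    Traces are ``neurons x frames``; ``frame_trial`` maps every frame to a
    trial id (or -1 for spontaneous segments).  ``ground_truth`` is present
    only for synthetic sessions and records each neuron's programmed class.
    """

    subject_id: str
    session_id: str
    frame_rate: float
    layout: TrialLayout
    trials: list[TrialRecord]
    activity: np.ndarray
    control: np.ndarray
    neuropil: np.ndarray | None = None
    frame_trial: np.ndarray = field(default=None)  # type: ignore[assignment]
    phase_hint: str = ""
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.activity.shape != self.control.shape:
            raise ValueError(
                "traces/activity and traces/control must share shape; got "
                f"{self.activity.shape} vs {self.control.shape}"
            )
        if self.neuropil is not None:
            self.neuropil = np.asarray(self.neuropil, dtype=float)
            if self.neuropil.shape != self.activity.shape:
                raise ValueError(
                    "traces/neuropil shape inconsistent with traces/activity: "
                    f"{self.neuropil.shape} vs {self.activity.shape}"
                )
        if self.frame_trial is None:
            self.frame_trial = default_frame_trial(
                len(self.trials), self.layout, self.frame_rate, self.n_frames
            )
        self.frame_trial = np.asarray(self.frame_trial, dtype=int)
        if self.frame_trial.shape != (self.n_frames,):
            raise ValueError(
                f"frame_trial has {self.frame_trial.shape[0]} entries for "
                f"{self.n_frames} frames"
            )
        trial_ids = {t.trial_id for t in self.trials}
        mapped = set(np.unique(self.frame_trial)) - {-1}
        if not mapped <= trial_ids:
            raise ValueError(f"frame_trial refers to unknown trials {sorted(mapped - trial_ids)}")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_frames(self, trial_id: int) -> np.ndarray:
        """Frame indices belonging to one trial, in acquisition order."""
        return np.flatnonzero(self.frame_trial == trial_id)

    def window_frames(self, trial_id: int, start_s: float, end_s: float) -> np.ndarray:
        """Frames of a trial whose centers fall in ``[start_s, end_s)`` (trial-relative)."""
        frames = self.trial_frames(trial_id)
        if frames.size == 0:
            return frames
        t = (np.arange(frames.size) + 0.5) / self.frame_rate
        return frames[(t >= start_s) & (t < end_s)]

    def texture_frames(self, trial_id: int) -> np.ndarray:
        return self.window_frames(
            trial_id, self.layout.texture_onset_s, self.layout.texture_offset_s
        )

    def spontaneous_frames(self) -> np.ndarray:
        return np.flatnonzero(self.frame_trial == -1)

    def trial_table(self) -> pd.DataFrame:
        """Trial table with derived texture-window event summaries."""
        onset, offset = self.layout.texture_onset_s, self.layout.texture_offset_s
        rows = []
        for t in self.trials:
            in_win = (t.lick_times >= onset) & (t.lick_times < offset)
            whisk_in = (t.whisk_times >= onset) & (t.whisk_times < offset)
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "session_id": t.session_id,
                    "stimulus": t.stimulus,
                    "rewarded_stimulus": t.rewarded_stimulus,
                    "outcome": t.outcome,
                    "reaction_time_s": t.reaction_time_s,
                    "n_licks_texture": int(in_win.sum()),
                    "lick_rate_texture": in_win.sum() / self.layout.texture_s,
                    "whisk_rate_texture": whisk_in.sum() / self.layout.texture_s,
                }
            )
        return pd.DataFrame(rows)


def default_frame_trial(
    n_trials: int, layout: TrialLayout, frame_rate: float, n_frames: int
) -> np.ndarray:
    """Contiguous trial blocks followed by a trailing spontaneous segment."""
    fpt = layout.n_frames(frame_rate)
    if n_trials * fpt > n_frames:
        raise ValueError(
            f"{n_frames} frames cannot hold {n_trials} trials of {fpt} frames"
        )
    mapping = np.full(n_frames, -1, dtype=int)
    for i in range(n_trials):
        mapping[i * fpt : (i + 1) * fpt] = i
    return mapping


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _write_ragged(group: h5py.Group, name: str, arrays: Sequence[np.ndarray]) -> None:
    flat = np.concatenate([np.asarray(a, dtype=float) for a in arrays]) if arrays else np.empty(0)
    offsets = np.cumsum([0] + [len(a) for a in arrays])
    group.create_dataset(f"{name}_flat", data=flat)
    group.create_dataset(f"{name}_offsets", data=offsets)


def _read_ragged(group: h5py.Group, name: str, n: int) -> list[np.ndarray]:
    flat = group[f"{name}_flat"][()]
    offsets = group[f"{name}_offsets"][()]
    if len(offsets) != n + 1:
        raise ValueError(f"dataset trials/{name}_offsets has wrong length")
    return [flat[offsets[i] : offsets[i + 1]] for i in range(n)]


def write_session(session: SessionData, path: str) -> None:
    """Write a session container to HDF5 (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["subject_id"] = session.subject_id
        f.attrs["session_id"] = session.session_id
        f.attrs["phase_hint"] = session.phase_hint
        f.attrs["frame_rate"] = session.frame_rate
        for k, v in asdict(session.layout).items():
            f.attrs[f"layout_{k}"] = v

        traces = f.create_group("traces")
        traces.create_dataset("activity", data=session.activity)
        traces.create_dataset("control", data=session.control)
        if session.neuropil is not None:
            traces.create_dataset("neuropil", data=session.neuropil)
        f.create_dataset("frame_trial", data=session.frame_trial)

        tg = f.create_group("trials")
        tg.create_dataset("trial_id", data=[t.trial_id for t in session.trials])
        tg.create_dataset("session_id", data=[t.session_id for t in session.trials], dtype=_STR)
        tg.create_dataset("stimulus", data=[t.stimulus for t in session.trials], dtype=_STR)
        tg.create_dataset(
            "rewarded_stimulus", data=[t.rewarded_stimulus for t in session.trials], dtype=_STR
        )
        tg.create_dataset("outcome", data=[t.outcome for t in session.trials], dtype=_STR)
        tg.create_dataset(
            "reaction_time_s", data=[t.reaction_time_s for t in session.trials]
        )
        _write_ragged(tg, "lick_times", [t.lick_times for t in session.trials])
        _write_ragged(tg, "whisk_times", [t.whisk_times for t in session.trials])

        if session.ground_truth is not None:
            gg = f.create_group("ground_truth")
            for col in session.ground_truth.columns:
                values = session.ground_truth[col].to_numpy()
                if values.dtype.kind in "OU":
                    gg.create_dataset(col, data=[str(x) for x in values], dtype=_STR)
                else:
                    gg.create_dataset(col, data=values)
            gg.attrs["columns"] = list(session.ground_truth.columns)


def read_session(path: str) -> SessionData:
    """Read a session container; fails naming the offending dataset."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version", "<missing>")
        if version != SCHEMA_VERSION:
            raise ValueError(f"unknown schema version {version!r}, expected {SCHEMA_VERSION!r}")
        for name in ("traces/activity", "traces/control", "frame_trial", "trials/trial_id"):
            if name not in f:
                raise ValueError(f"missing dataset {name}")
        layout = TrialLayout(
            **{k: float(f.attrs[f"layout_{k}"]) for k in
               ("baseline_s", "cue_s", "delay_s", "texture_s", "post_s")}
        )
        tg = f["trials"]
        n = len(tg["trial_id"])
        licks = _read_ragged(tg, "lick_times", n)
        whisks = _read_ragged(tg, "whisk_times", n)

        def _s(name: str) -> list[str]:
            return [x.decode() if isinstance(x, bytes) else str(x) for x in tg[name][()]]

        trials = [
            TrialRecord(
                trial_id=int(tg["trial_id"][i]),
                session_id=_s("session_id")[i],
                stimulus=_s("stimulus")[i],
                rewarded_stimulus=_s("rewarded_stimulus")[i],
                lick_times=licks[i],
                whisk_times=whisks[i],
                outcome=_s("outcome")[i],
                reaction_time_s=float(tg["reaction_time_s"][i]),
            )
            for i in range(n)
        ]
        ground_truth = None
        if "ground_truth" in f:
            gg = f["ground_truth"]
            cols = list(gg.attrs["columns"])
            data = {}
            for col in cols:
                v = gg[col][()]
                if v.dtype.kind in "OS":
                    v = np.array([x.decode() if isinstance(x, bytes) else x for x in v])
                data[col] = v
            ground_truth = pd.DataFrame(data)
        return SessionData(
            subject_id=str(f.attrs["subject_id"]),
            session_id=str(f.attrs["session_id"]),
            phase_hint=str(f.attrs["phase_hint"]),
            frame_rate=float(f.attrs["frame_rate"]),
            layout=layout,
            trials=trials,
            activity=f["traces/activity"][()],
            control=f["traces/control"][()],
            neuropil=f["traces/neuropil"][()] if "traces/neuropil" in f else None,
            frame_trial=f["frame_trial"][()],
            ground_truth=ground_truth,
        )
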