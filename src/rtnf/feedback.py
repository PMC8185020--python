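"""Online feedback signal: per-TR percent-signal-change difference.

At every displayed frame the feedback signal is

    FS_t = 100*(target_t - target_bas)/target_bas
         - 100*(bg_t - bg_bas)/bg_bas

where the baseline means come from the most recent completed control
period: the last 10 volumes of the preceding "count" block in the
parallel paradigm, or the 5 volumes of the preceding "feedback count"
block in the serial paradigm.  For the first cycle (no completed
control period yet) the tail of the initial baseline block is used
with the same window length.  Subtracting the whole-brain background
PSC cancels global intensity fluctuations exactly.

FS is quantized onto a 21-level thermometer display: a linear map of
[-fs_max, +fs_max] onto levels 0..20 with FS = 0 at level 10, clamped
at the ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .paradigm import DISPLAY_CONDITIONS, ParadigmSchedule
from .synthetic import RunData

#: baseline window length (volumes) per paradigm
BASELINE_WINDOW = {"parallel": 10, "serial": 5}
#: the control condition whose preceding block provides the baseline
BASELINE_SOURCE = {"parallel": "count", "serial": "feedback_count"}

N_LEVELS = 21
DEFAULT_FS_MAX = 2.0


@dataclass(frozen=True)
class BaselineWindow:
    indices: tuple[int, ...]
    mean_target: float
    mean_background: float


@dataclass
class FeedbackTrace:
    fs: np.ndarray          # percent; NaN off display frames
    level: np.ndarray       # int 0..20; -1 off display frames
    display_frames: list[int]


def display_frames(schedule: ParadigmSchedule) -> list[int]:
    conds = DISPLAY_CONDITIONS[schedule.name]
    from .paradigm import schedule_to_frames

    return [i for i, c in enumerate(schedule_to_frames(schedule)) if c in conds]


def baseline_indices(schedule: ParadigmSchedule, frame: int) -> tuple[int, ...]:
    """Volume indices of the baseline window for a display frame."""
    name = schedule.name
    window = BASELINE_WINDOW[name]
    source = BASELINE_SOURCE[name]
    bi = schedule.block_index_of_frame(frame)
    block = schedule.blocks[bi]
    if block.condition not in DISPLAY_CONDITIONS[name]:
        raise ValueError(
            f"frame {frame} ({block.condition}) is not in a display period"
        )
    # most recent completed baseline-source block before the current block
    for j in range(bi - 1, -1, -1):
        if schedule.blocks[j].condition == source:
            frames = schedule.frames_of_block(j)
            return tuple(frames[-window:])
    # first cycle: tail of the initial baseline block
    frames = schedule.frames_of_block(0)
    return tuple(frames[-window:])


def baseline_for_frame(
    run: RunData, schedule: ParadigmSchedule, frame: int
) -> BaselineWindow:
    idx = baseline_indices(schedule, frame)
    sel = list(idx)
    return BaselineWindow(
        idx,
        float(np.mean(run.target_ts[sel])),
        float(np.mean(run.background_ts[sel])),
    )


def percent_signal_change(value: float, baseline_mean: float) -> float:
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (value - baseline_mean) / baseline_mean


def feedback_signal(psc_target: float, psc_background: float) -> float:
    return psc_target - psc_background


def quantize_thermometer(fs: float, fs_max: float = DEFAULT_FS_MAX) -> int:
    """Map FS in [-fs_max, fs_max] linearly onto levels 0..20 (FS=0 -> 10)."""
    if fs_max <= 0:
        raise ValueError("fs_max must be positive")
    level = int(round(10.0 + 10.0 * fs / fs_max))
    return max(0, min(N_LEVELS - 1, level))


def run_feedback_loop(
    run: RunData,
    schedule: ParadigmSchedule,
    fs_max: float = DEFAULT_FS_MAX,
    display_shift: int = 0,
) -> FeedbackTrace:
    """Compute FS and thermometer level at every display frame.

    ``display_shift`` optionally delays the recorded trace by a number
    of frames to mimic the presentation lag of an online system; the
    computation itself always uses the data available at each frame.
    """
    if run.n_volumes != schedule.n_volumes:
        raise ValueError(
            f"run has {run.n_volumes} volumes, schedule expects {schedule.n_volumes}"
        )
    n = schedule.n_volumes
    fs = np.full(n, np.nan)
    level = np.full(n, -1, dtype=int)
    frames = display_frames(schedule)
    for f in frames:
        bw = baseline_for_frame(run, schedule, f)
        psc_t = percent_signal_change(float(run.target_ts[f]), bw.mean_target)
        psc_b = percent_signal_change(float(run.background_ts[f]), bw.mean_background)
        out = min(f + display_shift, n - 1)
        fs[out] = feedback_signal(psc_t, psc_b)
        level[out] = quantize_thermometer(fs[out], fs_max)
    shown = [min(f + display_shift, n - 1) for f in frames]
    return FeedbackTrace(fs, level, shown)


def trace_to_tsv(trace: FeedbackTrace, schedule: ParadigmSchedule, path) -> None:
    from pathlib import Path

    from .paradigm import schedule_to_frames

    conds = schedule_to_frames(schedule)
    lines = ["frame\tcondition\tfs_percent\tlevel"]
    for i in range(schedule.n_volumes):
        fs = "" if np.isnan(trace.fs[i]) else f"{trace.fs[i]:.6g}"
        lev = "" if trace.level[i] < 0 else str(trace.level[i])
        lines.append(f"{i}\t{conds[i]}\t{fs}\t{lev}")
    Path(path).write_text("\n".join(lines) + "\n")
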