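"""Block schedules for the parallel and serial neurofeedback paradigms.

Both paradigms are block designs acquired at TR = 2 s, 185 volumes
(370 s of task schedule).  The *parallel* paradigm interleaves a 20-s
"think" regulation period with a 30-s "count" control period, with
continuous feedback shown during both; the *serial* paradigm separates
strategy execution from feedback processing into consecutive 10-s
blocks ("think", "feedback think", "count", "feedback count").

Times are seconds everywhere at API boundaries; volume indices are
0-based.  Volume ``i`` covers the half-open acquisition interval
``[i*tr, (i+1)*tr)`` and takes the condition of the block containing
its start time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

CONDITIONS = ("baseline", "think", "count", "feedback_think", "feedback_count")

#: Conditions during which feedback is displayed, per paradigm.
DISPLAY_CONDITIONS = {
    "parallel": ("think", "count"),
    "serial": ("feedback_think", "feedback_count"),
}


class ScheduleError(ValueError):
    """Raised when a schedule configuration is inconsistent."""


@dataclass(frozen=True)
class Block:
    """A contiguous condition block: half-open interval [onset, onset+duration)."""

    condition: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ScheduleError(f"unknown condition {self.condition!r}")
        if self.onset < 0:
            raise ScheduleError("block onset must be non-negative")
        if self.duration <= 0:
            raise ScheduleError("block duration must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class ParadigmSchedule:
    """An ordered, gap-free sequence of condition blocks."""

    name: str
    tr: float
    blocks: tuple[Block, ...]
    n_volumes: int = field(default=0)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ScheduleError("tr must be positive")
        t = 0.0
        for blk in self.blocks:
            if abs(blk.onset - t) > 1e-9:
                raise ScheduleError(
                    f"blocks not contiguous: expected onset {t}, got {blk.onset}"
                )
            t = blk.end
        total = t
        n = total / self.tr
        if abs(n - round(n)) > 1e-9:
            raise ScheduleError(
                f"total duration {total} s is not a multiple of tr={self.tr}"
            )
        if self.n_volumes == 0:
            object.__setattr__(self, "n_volumes", int(round(n)))
        elif self.n_volumes != int(round(n)):
            raise ScheduleError("n_volumes inconsistent with block durations")

    @property
    def total_duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def conditions(self) -> set[str]:
        return {b.condition for b in self.blocks}

    def block_at(self, time_s: float) -> Block:
        """Block containing ``time_s`` under the half-open convention."""
        for blk in self.blocks:
            if blk.onset - 1e-9 <= time_s < blk.end - 1e-9:
                return blk
        raise ScheduleError(f"time {time_s} s outside schedule")

    def block_index_of_frame(self, frame: int) -> int:
        t = frame * self.tr
        for i, blk in enumerate(self.blocks):
            if blk.onset - 1e-9 <= t < blk.end - 1e-9:
                return i
        raise ScheduleError(f"frame {frame} outside schedule")

    def frames_of_block(self, block_index: int) -> list[int]:
        """0-based volume indices whose start time lies within the block."""
        blk = self.blocks[block_index]
        first = int(round(blk.onset / self.tr))
        last = int(round(blk.end / self.tr))
        return list(range(first, last))

    def total_time(self, condition: str) -> float:
        return sum(b.duration for b in self.blocks if b.condition == condition)


def _check_divisible(durations: Sequence[float], tr: float) -> None:
    for d in durations:
        if abs(d / tr - round(d / tr)) > 1e-9:
            raise ScheduleError(f"tr={tr} does not divide block duration {d} s")


def build_parallel_schedule(tr: float = 2.0) -> ParadigmSchedule:
    """50 s baseline, six cycles of 20 s think / 30 s count, 20 s baseline."""
    _check_divisible([50.0, 20.0, 30.0], tr)
    blocks: list[Block] = [Block("baseline", 0.0, 50.0)]
    t = 50.0
    for _ in range(6):
        blocks.append(Block("think", t, 20.0))
        t += 20.0
        blocks.append(Block("count", t, 30.0))
        t += 30.0
    blocks.append(Block("baseline", t, 20.0))
    return ParadigmSchedule("parallel", tr, tuple(blocks))


def build_serial_schedule(tr: float = 2.0) -> ParadigmSchedule:
    """40 s baseline, eight cycles of 10-s think / feedback_think / count /
    feedback_count, 10 s baseline."""
    _check_divisible([40.0, 10.0], tr)
    blocks: list[Block] = [Block("baseline", 0.0, 40.0)]
    t = 40.0
    for _ in range(8):
        for cond in ("think", "feedback_think", "count", "feedback_count"):
            blocks.append(Block(cond, t, 10.0))
            t += 10.0
    blocks.append(Block("baseline", t, 10.0))
    return ParadigmSchedule("serial", tr, tuple(blocks))


BUILTIN_SCHEDULES = {
    "parallel": build_parallel_schedule,
    "serial": build_serial_schedule,
}


def get_schedule(name: str, tr: float = 2.0) -> ParadigmSchedule:
    try:
        return BUILTIN_SCHEDULES[name](tr)
    except KeyError:
        raise ScheduleError(f"unknown paradigm {name!r}") from None


def schedule_to_frames(schedule: ParadigmSchedule) -> list[str]:
    """Per-volume condition labels (length ``n_volumes``)."""
    return [
        schedule.block_at(i * schedule.tr).condition
        for i in range(schedule.n_volumes)
    ]


def condition_frames(schedule: ParadigmSchedule, condition: str) -> list[int]:
    frames = schedule_to_frames(schedule)
    return [i for i, c in enumerate(frames) if c == condition]


# ---------------------------------------------------------------------------
# serialization

def schedule_to_tsv(schedule: ParadigmSchedule, path: str | Path) -> None:
    lines = ["condition\tonset_s\tduration_s"]
    for b in schedule.blocks:
        lines.append(f"{b.condition}\t{b.onset:g}\t{b.duration:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def schedule_from_tsv(
    path: str | Path, name: str = "custom", tr: float = 2.0
) -> ParadigmSchedule:
    rows = Path(path).read_text().strip().splitlines()
    header = rows[0].split("\t")
    if header != ["condition", "onset_s", "duration_s"]:
        raise ScheduleError(f"unexpected TSV header {header}")
    blocks = []
    for row in rows[1:]:
        cond, onset, dur = row.split("\t")
        blocks.append(Block(cond, float(onset), float(dur)))
    return ParadigmSchedule(name, tr, tuple(blocks))


def schedule_to_json(schedule: ParadigmSchedule, path: str | Path) -> None:
    payload = {
        "name": schedule.name,
        "tr": schedule.tr,
        "n_volumes": schedule.n_volumes,
        "blocks": [
            {"condition": b.condition, "onset_s": b.onset, "duration_s": b.duration}
            for b in schedule.blocks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def schedule_from_json(path: str | Path) -> ParadigmSchedule:
    payload = json.loads(Path(path).read_text())
    blocks = tuple(
        Block(b["condition"], b["onset_s"], b["duration_s"])
        for b in payload["blocks"]
    )
    return ParadigmSchedule(payload["name"], payload["tr"], blocks)
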