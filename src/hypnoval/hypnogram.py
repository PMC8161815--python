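"""Epoch-indexed hypnogram container, file I/O, and clock-time synchronization.

A hypnogram is a sequence of sleep-stage labels, one per fixed-duration epoch
(30 s by convention in AASM scoring). Epochs are 0-based; epoch ``i`` spans the
half-open interval ``[start_time + i*epoch_duration, start_time +
(i+1)*epoch_duration)``.

Stage alphabets
---------------
``PSG5``
    Wake, N1, N2, N3, REM — the AASM stages scored from polysomnography.
``DEV4``
    Wake, Light, Deep, REM — "type I" wearables that report REM distinctly.
``DEV3``
    Wake, Light, Deep — "type II" wearables.
"""

from __future__ import annotations

import csv
import datetime as dt
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlignmentError, HypnogramError

ALPHABETS: dict[str, tuple[str, ...]] = {
    "PSG5": ("Wake", "N1", "N2", "N3", "REM"),
    "DEV4": ("Wake", "Light", "Deep", "REM"),
    "DEV3": ("Wake", "Light", "Deep"),
}

WAKE = "Wake"

#: reference date attached to clock times parsed without a date
_DEFAULT_DATE = dt.date(1900, 1, 1)


def parse_clock_time(text: str) -> tuple[dt.datetime, bool]:
    """Parse ``hh:mm:ss`` or ``YYYY-mm-dd hh:mm:ss``.

    Returns the datetime and whether a date was actually present. Dateless
    times are anchored to a fixed reference date; synchronization resolves
    midnight wrap-around for them.
    """
    text = text.strip()
    for fmt in ("%Y-%m-%d %H:%M:%S", "%Y-%m-%dT%H:%M:%S"):
        try:
            return dt.datetime.strptime(text, fmt), True
        except ValueError:
            pass
    try:
        t = dt.datetime.strptime(text, "%H:%M:%S").time()
    except ValueError as exc:
        raise HypnogramError(f"unparseable clock time: {text!r}") from exc
    return dt.datetime.combine(_DEFAULT_DATE, t), False


def format_clock_time(t: dt.datetime, dated: bool) -> str:
    return t.strftime("%Y-%m-%d %H:%M:%S") if dated else t.strftime("%H:%M:%S")


@dataclass(frozen=True)
class Hypnogram:
    """A validated stage sequence on a uniform epoch grid.

    Parameters
    ----------
    stages
        One label per epoch, all members of ``alphabet``.
    epoch_duration
        Epoch length in seconds (default 30).
    start_time
        Clock time of epoch 0, or None when unknown.
    source
        ``"PSG"`` or ``"device"``.
    alphabet
        Key into :data:`ALPHABETS`.
    dated
        Whether ``start_time`` carries a real date (False for bare hh:mm:ss).
    """

    stages: tuple[str, ...]
    epoch_duration: float = 30.0
    start_time: dt.datetime | None = None
    source: str = "PSG"
    alphabet: str = "PSG5"
    dated: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise HypnogramError(f"unknown alphabet {self.alphabet!r}")
        if len(self.stages) < 1:
            raise HypnogramError("hypnogram must contain at least one epoch")
        if not self.epoch_duration > 0:
            raise HypnogramError("epoch_duration must be positive")
        legal = set(ALPHABETS[self.alphabet])
        bad = [s for s in self.stages if s not in legal]
        if bad:
            raise HypnogramError(
                f"stage(s) {sorted(set(bad))} not in alphabet {self.alphabet}"
            )
        if self.source not in ("PSG", "device"):
            raise HypnogramError(f"source must be 'PSG' or 'device', got {self.source!r}")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_minutes(self) -> float:
        return self.n_epochs * self.epoch_duration / 60.0

    def time_of_epoch(self, i: int) -> dt.datetime:
        """Clock time of the start of epoch ``i`` (0-based)."""
        if self.start_time is None:
            raise HypnogramError("hypnogram has no start_time")
        return self.start_time + dt.timedelta(seconds=i * self.epoch_duration)

    @property
    def end_time(self) -> dt.datetime:
        return self.time_of_epoch(self.n_epochs)

    def is_sleep(self) -> np.ndarray:
        """Boolean array, True where the epoch is any non-Wake stage."""
        return np.array([s != WAKE for s in self.stages], dtype=bool)

    def stage_counts(self) -> Counter:
        return Counter(self.stages)

    def slice_epochs(self, start: int, stop: int) -> "Hypnogram":
        """Sub-hypnogram over epochs ``[start, stop)`` with shifted start_time."""
        if not 0 <= start < stop <= self.n_epochs:
            raise HypnogramError(f"bad epoch slice [{start}, {stop})")
        new_start = self.time_of_epoch(start) if self.start_time is not None else None
        return replace(self, stages=self.stages[start:stop], start_time=new_start)


@dataclass(frozen=True)
class AlignedPair:
    """A PSG and a device hypnogram on a common epoch grid.

    Construction enforces equal length and epoch duration; stage-alphabet
    agreement is checked by the metrics that need it (the PSG member is
    usually categorized to the device alphabet first).
    """

    psg: Hypnogram
    device: Hypnogram

    def __post_init__(self) -> None:
        if self.psg.n_epochs != self.device.n_epochs:
            raise AlignmentError(
                f"length mismatch: {self.psg.n_epochs} vs {self.device.n_epochs}"
            )
        if self.psg.epoch_duration != self.device.epoch_duration:
            raise AlignmentError("epoch_duration mismatch")

    @property
    def n_epochs(self) -> int:
        return self.psg.n_epochs


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: optional leading '# key: value' metadata lines, then a header row
# 'epoch,stage' or 'time,stage'. Timestamped rows may step by any whole
# multiple of the epoch duration; each row is expanded to cover its span.
# ---------------------------------------------------------------------------


def _map_label(raw: str, legal: set[str], label_map: Mapping[str, str] | None) -> str:
    raw = raw.strip()
    if raw in legal:
        return raw
    if label_map and raw in label_map:
        mapped = label_map[raw]
        if mapped in legal:
            return mapped
        raise HypnogramError(f"label map sends {raw!r} to {mapped!r}, not in alphabet")
    raise HypnogramError(f"stage label {raw!r} not in alphabet and not mapped")


def read_hypnogram(
    path: str | Path,
    format: str = "csv",
    alphabet: str | None = None,
    *,
    label_map: Mapping[str, str] | None = None,
    epoch_duration: float | None = None,
    start_time: str | None = None,
    source: str | None = None,
) -> Hypnogram:
    """Read a hypnogram from a CSV file or an EDF+ annotation track.

    Explicit keyword arguments override metadata found in the file. For
    ``format="edf_annotations"`` the file's annotation descriptions are mapped
    to stage labels via ``label_map`` (or used verbatim when already legal)
    and laid onto the epoch grid; partial final epochs are truncated.
    """
    path = Path(path)
    if not path.exists():
        raise HypnogramError(f"no such file: {path}")
    if format == "csv":
        return _read_csv(path, alphabet, label_map, epoch_duration, start_time, source)
    if format == "edf_annotations":
        return _read_edf_annotations(
            path, alphabet, label_map, epoch_duration, start_time, source
        )
    raise HypnogramError(f"unknown format {format!r}")


def _read_csv(path, alphabet, label_map, epoch_duration, start_time, source):
    meta: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    header: list[str] | None = None
    with open(path, newline="", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parsed = next(csv.reader([line]))
            if header is None:
                header = [c.strip().lower() for c in parsed]
                if header not in (["epoch", "stage"], ["time", "stage"]):
                    raise HypnogramError(
                        f"expected header 'epoch,stage' or 'time,stage', got {parsed}"
                    )
                continue
            if len(parsed) != 2:
                raise HypnogramError(f"malformed row: {line!r}")
            rows.append((parsed[0], parsed[1]))
    if header is None or not rows:
        raise HypnogramError(f"{path}: no hypnogram rows")

    alphabet = alphabet or meta.get("alphabet")
    if alphabet is None:
        raise HypnogramError("alphabet not given and not found in file metadata")
    legal = set(ALPHABETS.get(alphabet, ()))
    if not legal:
        raise HypnogramError(f"unknown alphabet {alphabet!r}")
    epoch_duration = float(
        epoch_duration if epoch_duration is not None else meta.get("epoch_duration", 30)
    )
    source = source or meta.get("source", "PSG")
    start_text = start_time or meta.get("start_time")

    if header == ["epoch", "stage"]:
        idx = [int(r[0]) for r in rows]
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise HypnogramError("epoch indices must be contiguous and increasing")
        stages = [_map_label(r[1], legal, label_map) for r in rows]
        start = None
        dated = False
        if start_text:
            start, dated = parse_clock_time(start_text)
    else:  # time,stage
        times = []
        dated = False
        for r in rows:
            t, d = parse_clock_time(r[0])
            dated = dated or d
            times.append(t)
        # dateless recordings may cross midnight: unwrap backward steps
        for j in range(1, len(times)):
            while times[j] <= times[j - 1]:
                times[j] += dt.timedelta(days=1)
        steps = {
            (times[j + 1] - times[j]).total_seconds() for j in range(len(times) - 1)
        }
        if len(times) == 1:
            step = epoch_duration
        elif len(steps) != 1:
            raise HypnogramError("non-uniform or non-monotonic timestamps")
        else:
            step = steps.pop()
        reps = step / epoch_duration
        if abs(reps - round(reps)) > 1e-9 or round(reps) < 1:
            raise HypnogramError(
                f"timestamp step {step}s is not a whole number of {epoch_duration}s epochs"
            )
        reps = int(round(reps))
        stages = []
        for _, raw in rows:
            stages.extend([_map_label(raw, legal, label_map)] * reps)
        start = times[0]

    return Hypnogram(
        stages=tuple(stages),
        epoch_duration=epoch_duration,
        start_time=start,
        source=source,
        alphabet=alphabet,
        dated=dated,
    )


def annotations_to_stages(
    onsets: Sequence[float],
    durations: Sequence[float],
    labels: Sequence[str],
    *,
    alphabet: str,
    epoch_duration: float = 30.0,
    label_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Lay stage annotations (onset/duration in seconds) onto the epoch grid.

    Annotations must tile the recording contiguously from onset 0 in order.
    Each annotation contributes ``floor(duration / epoch_duration)`` whole
    epochs at its position; a trailing partial epoch is truncated.
    """
    legal = set(ALPHABETS[alphabet])
    stages: list[str] = []
    cursor = 0.0
    for onset, dur, lab in sorted(zip(onsets, durations, labels)):
        if abs(onset - cursor) > 1e-6:
            raise HypnogramError(
                f"annotations do not tile the record: gap/overlap at {onset}s"
            )
        n = int(dur // epoch_duration)
        stages.extend([_map_label(lab, legal, label_map)] * n)
        cursor = onset + dur
    if not stages:
        raise HypnogramError("annotations cover less than one epoch")
    return stages


def _read_edf_annotations(path, alphabet, label_map, epoch_duration, start_time, source):
    import mne  # heavy import; only needed for EDF+ input

    if alphabet is None:
        raise HypnogramError("alphabet is required for edf_annotations input")
    ann = mne.read_annotations(str(path))
    stages = annotations_to_stages(
        ann.onset,
        ann.duration,
        list(ann.description),
        alphabet=alphabet,
        epoch_duration=float(epoch_duration or 30.0),
        label_map=label_map,
    )
    start = None
    dated = False
    if start_time:
        start, dated = parse_clock_time(start_time)
    elif ann.orig_time is not None:
        start = ann.orig_time.replace(tzinfo=None)
        dated = True
    return Hypnogram(
        stages=tuple(stages),
        epoch_duration=float(epoch_duration or 30.0),
        start_time=start,
        source=source or "PSG",
        alphabet=alphabet,
        dated=dated,
    )


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    """Write the CSV dialect with metadata comments; round-trips exactly."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# alphabet: {h.alphabet}\n")
        fh.write(f"# epoch_duration: {h.epoch_duration:g}\n")
        if h.start_time is not None:
            fh.write(f"# start_time: {format_clock_time(h.start_time, h.dated)}\n")
        fh.write(f"# source: {h.source}\n")
        fh.write("epoch,stage\n")
        for i, s in enumerate(h.stages):
            fh.write(f"{i},{s}\n")


# ---------------------------------------------------------------------------
# Synchronization
# ---------------------------------------------------------------------------


def resample_hypnogram(h: Hypnogram, new_duration: float) -> Hypnogram:
    """Change epoch duration by label repetition (finer) or majority vote (coarser).

    The new duration must be a whole multiple or divisor of the old one.
    Majority votes break ties toward the earlier label within the block,
    preserving stage dwell rather than inventing stages.
    """
    old = h.epoch_duration
    if new_duration == old:
        return h
    if new_duration < old:
        k = old / new_duration
        if abs(k - round(k)) > 1e-9:
            raise HypnogramError("durations are not whole multiples")
        k = int(round(k))
        stages = [s for s in h.stages for _ in range(k)]
    else:
        k = new_duration / old
        if abs(k - round(k)) > 1e-9:
            raise HypnogramError("durations are not whole multiples")
        k = int(round(k))
        stages = []
        for b in range(len(h.stages) // k):
            block = h.stages[b * k : (b + 1) * k]
            counts = Counter(block)
            best = max(counts.values())
            stages.append(next(s for s in block if counts[s] == best))
        if not stages:
            raise HypnogramError("hypnogram shorter than one coarse epoch")
    return replace(h, stages=tuple(stages), epoch_duration=float(new_duration))


def synchronize(psg: Hypnogram, device: Hypnogram) -> AlignedPair:
    """Align two hypnograms on the PSG epoch grid via their clock times.

    Both inputs must carry a start_time. Unequal epoch durations are first
    resampled to the coarser one. The device's clock offset relative to PSG
    is rounded to the nearest whole epoch; both sequences are truncated to
    the overlapping interval. Raises :class:`AlignmentError` when the
    recordings do not overlap.
    """
    if psg.start_time is None or device.start_time is None:
        raise AlignmentError("both hypnograms need a start_time to synchronize")
    if psg.epoch_duration != device.epoch_duration:
        coarse = max(psg.epoch_duration, device.epoch_duration)
        psg = resample_hypnogram(psg, coarse)
        device = resample_hypnogram(device, coarse)
    dur = psg.epoch_duration

    offset = (device.start_time - psg.start_time).total_seconds()
    if not (psg.dated and device.dated):
        # dateless clock times: resolve midnight wrap to the nearest night
        while offset > 43200:
            offset -= 86400
        while offset <= -43200:
            offset += 86400
    k = int(round(offset / dur))  # device epoch j sits at psg epoch j + k

    lo = max(0, k)
    hi = min(psg.n_epochs, k + device.n_epochs)
    if hi <= lo:
        raise AlignmentError("hypnograms have no temporal overlap")
    psg_cut = psg.slice_epochs(lo, hi)
    dev_cut = device.slice_epochs(lo - k, hi - k)
    # snap device start onto the PSG grid
    dev_cut = replace(
        dev_cut, start_time=psg_cut.start_time, dated=psg_cut.dated
    )
    return AlignedPair(psg=psg_cut, device=dev_cut)
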