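"""AASM-based categorization of PSG stages to device alphabets, and integer
stage encoding for the transition algebra.

Wearables report coarser stage sets than the five AASM stages. To compare a
PSG hypnogram with a device hypnogram epoch by epoch, the PSG stages are
collapsed onto the device's alphabet:

========  =======  ==========
PSG       type I   type II
========  =======  ==========
Wake      Wake     Wake
N1        Light    Light
N2        Light    Light
N3        Deep     Deep
REM       REM      Deep
========  =======  ==========

Type I devices (Wake-Light-Deep-REM) report REM distinctly; type II devices
(Wake-Light-Deep) fold REM into Deep.

The transition algebra assigns each stage an integer code — Wake=1, Light=2,
Deep=4 by convention, with REM=8 by default in 4-stage mode — so that stage
transitions become first differences and the localized mismatch index becomes
a product of differences. With these codes every transition pair has a
distinct delta magnitude (1, 2, 3 for three stages; 1, 2, 3, 4, 6, 7 with
REM=8), so a delta identifies its transition unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .errors import HypnogramError
from .hypnogram import ALPHABETS, WAKE, Hypnogram


class DeviceType(Enum):
    """Wearable stage-reporting convention."""

    TYPE_I = "I"  # Wake-Light-Deep-REM
    TYPE_II = "II"  # Wake-Light-Deep

    @property
    def alphabet(self) -> str:
        return "DEV4" if self is DeviceType.TYPE_I else "DEV3"

    @classmethod
    def from_string(cls, s: str) -> "DeviceType":
        s = s.strip().upper()
        if s in ("I", "1", "TYPE_I"):
            return cls.TYPE_I
        if s in ("II", "2", "TYPE_II"):
            return cls.TYPE_II
        raise ValueError(f"unknown device type {s!r}")


_PSG_TO_DEVICE = {
    DeviceType.TYPE_I: {"Wake": "Wake", "N1": "Light", "N2": "Light", "N3": "Deep", "REM": "REM"},
    DeviceType.TYPE_II: {"Wake": "Wake", "N1": "Light", "N2": "Light", "N3": "Deep", "REM": "Deep"},
}


def categorize_psg(psg: Hypnogram, device_type: DeviceType) -> Hypnogram:
    """Collapse a PSG5 hypnogram onto the device's stage alphabet.

    The wake/sleep partition is preserved exactly: Wake maps to Wake and
    every sleep stage maps to a sleep stage.
    """
    if psg.alphabet != "PSG5":
        raise HypnogramError(
            f"categorize_psg expects a PSG5 hypnogram, got {psg.alphabet}"
        )
    table = _PSG_TO_DEVICE[device_type]
    return replace(
        psg,
        stages=tuple(table[s] for s in psg.stages),
        alphabet=device_type.alphabet,
    )


@dataclass(frozen=True)
class StageEncoding:
    """Stage label → integer code map used by the transition algebra.

    Codes must be distinct positive integers with Wake the smallest, so a
    positive delta always means moving away from wake and deeper into the
    code scale. The default REM code of 8 keeps all transition delta
    magnitudes pairwise distinct in 4-stage mode.
    """

    codes: dict[str, int] = field(
        default_factory=lambda: {"Wake": 1, "Light": 2, "Deep": 4, "REM": 8}
    )

    def __post_init__(self) -> None:
        vals = list(self.codes.values())
        if len(set(vals)) != len(vals) or any(v <= 0 for v in vals):
            raise ValueError("stage codes must be distinct positive integers")
        if WAKE not in self.codes or self.codes[WAKE] != min(vals):
            raise ValueError("Wake must carry the smallest code")

    @classmethod
    def default(cls, rem_code: int = 8) -> "StageEncoding":
        return cls({"Wake": 1, "Light": 2, "Deep": 4, "REM": rem_code})

    def covers(self, alphabet: str) -> bool:
        return all(s in self.codes for s in ALPHABETS[alphabet])

    def wake_delta_magnitudes(self, alphabet: str) -> frozenset[int]:
        """|delta| values of transitions with Wake at one endpoint."""
        w = self.codes[WAKE]
        return frozenset(
            abs(self.codes[s] - w) for s in ALPHABETS[alphabet] if s != WAKE
        )


def encode(h: Hypnogram, enc: StageEncoding | None = None) -> np.ndarray:
    """Element-wise integer encoding of a hypnogram's stage sequence."""
    enc = enc or StageEncoding.default()
    try:
        return np.array([enc.codes[s] for s in h.stages], dtype=np.int64)
    except KeyError as exc:
        raise HypnogramError(f"stage {exc.args[0]!r} has no integer code") from exc
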