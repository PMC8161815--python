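"""Wake-sleep and sleep-architecture features of a single hypnogram.

All durations are reported in minutes. The features are the standard
sleep-medicine summary measures:

SO (sleep onset)
    First epoch scored as any sleep stage; reported as epoch index and,
    when a start time is known, clock time.
SPT (sleep period time)
    Elapsed time from sleep onset through the last sleep epoch, inclusive
    of that epoch's full duration.
TST (total sleep time)
    Minutes scored as sleep within the sleep period; decomposes into light
    (TLST), deep (TDST), and REM (TRST) components.
SE (sleep efficiency)
    100 * TST / SPT.
WASO (wakefulness after sleep onset)
    SPT - TST, plus wake time between the last sleep epoch and lights-on
    when a lights-on time is supplied (zero otherwise: hypnogram-only input
    carries no lights-on event).
PLS / PDS / PRS
    Percentage of TST spent in light / deep / REM sleep; PRS is absent for
    alphabets without REM.

Wake-sleep features (SO, SPT, TST, SE, WASO) depend only on the wake/sleep
partition and are therefore invariant under PSG→device stage categorization.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .errors import HypnogramError, NoSleepError
from .hypnogram import WAKE, Hypnogram, parse_clock_time

# stage → architecture category, across all alphabets
_CATEGORY = {
    "Wake": "wake",
    "N1": "light",
    "N2": "light",
    "Light": "light",
    "N3": "deep",
    "Deep": "deep",
    "REM": "rem",
}


@dataclass(frozen=True)
class FeatureSet:
    """One night's feature vector for one scorer."""

    tst: float  # min
    spt: float  # min
    se: float  # percent
    waso: float  # min
    so_epoch: int
    so_clock: dt.datetime | None
    so_minutes: float  # minutes from recording start; subtractable scale
    lsp_epoch: int
    lsp_clock: dt.datetime | None
    tlst: float  # min
    tdst: float  # min
    trst: float  # min
    pls: float  # percent of TST
    pds: float  # percent of TST
    prs: float | None  # percent of TST; None when alphabet lacks REM

    def as_dict(self) -> dict:
        d = {
            "TST": self.tst,
            "SPT": self.spt,
            "SE": self.se,
            "WASO": self.waso,
            "SO_epoch": self.so_epoch,
            "SO_minutes": self.so_minutes,
            "SO_clock": self.so_clock.strftime("%H:%M:%S") if self.so_clock else None,
            "TLST": self.tlst,
            "TDST": self.tdst,
            "TRST": self.trst,
            "PLS": self.pls,
            "PDS": self.pds,
        }
        if self.prs is not None:
            d["PRS"] = self.prs
        return d


def sleep_onset(h: Hypnogram) -> tuple[int, dt.datetime | None]:
    """Index (and clock time, if known) of the first sleep epoch."""
    sleep = h.is_sleep()
    if not sleep.any():
        raise NoSleepError("hypnogram contains no sleep epoch")
    idx = int(np.argmax(sleep))
    clock = h.time_of_epoch(idx) if h.start_time is not None else None
    return idx, clock


def _last_sleep_epoch(h: Hypnogram) -> int:
    sleep = h.is_sleep()
    if not sleep.any():
        raise NoSleepError("hypnogram contains no sleep epoch")
    return int(len(sleep) - 1 - np.argmax(sleep[::-1]))


def sleep_period_time(h: Hypnogram) -> float:
    """Minutes from sleep onset through the last sleep epoch, inclusive."""
    so = sleep_onset(h)[0]
    lsp = _last_sleep_epoch(h)
    return (lsp - so + 1) * h.epoch_duration / 60.0


def total_sleep_time(h: Hypnogram) -> tuple[float, float, float, float]:
    """(TST, TLST, TDST, TRST) in minutes, counted within the sleep period."""
    so = sleep_onset(h)[0]
    lsp = _last_sleep_epoch(h)
    mins = h.epoch_duration / 60.0
    comp = {"light": 0, "deep": 0, "rem": 0}
    for s in h.stages[so : lsp + 1]:
        cat = _CATEGORY[s]
        if cat != "wake":
            comp[cat] += 1
    tlst, tdst, trst = (comp[c] * mins for c in ("light", "deep", "rem"))
    return tlst + tdst + trst, tlst, tdst, trst


def sleep_efficiency(h: Hypnogram) -> float:
    """100 * TST / SPT (percent)."""
    spt = sleep_period_time(h)
    if spt <= 0:
        raise NoSleepError("sleep period time is zero")
    return 100.0 * total_sleep_time(h)[0] / spt


def waso(h: Hypnogram, lights_on: str | dt.datetime | None = None) -> float:
    """Wake minutes after sleep onset: SPT - TST + WAS.

    WAS — wake between the last sleep epoch and lights-on — is zero unless a
    lights-on time is supplied, in which case it counts wake epochs whose
    interval falls inside [end of last sleep epoch, lights_on).
    """
    spt = sleep_period_time(h)
    tst = total_sleep_time(h)[0]
    was = 0.0
    if lights_on is not None:
        if h.start_time is None:
            raise HypnogramError("lights_on given but hypnogram has no start_time")
        if isinstance(lights_on, str):
            lights_on, lo_dated = parse_clock_time(lights_on)
            if not lo_dated and not h.dated:
                while lights_on < h.start_time:
                    lights_on += dt.timedelta(days=1)
        lsp = _last_sleep_epoch(h)
        lsp_end = h.time_of_epoch(lsp + 1)
        if lights_on < lsp_end:
            raise HypnogramError("lights_on precedes the end of the last sleep epoch")
        for i in range(lsp + 1, h.n_epochs):
            if h.stages[i] != WAKE:
                continue
            if h.time_of_epoch(i + 1) <= lights_on:
                was += h.epoch_duration / 60.0
    return spt - tst + was


def stage_percentages(h: Hypnogram) -> tuple[float, float, float | None]:
    """(PLS, PDS, PRS) as percent of TST; PRS None when alphabet lacks REM."""
    tst, tlst, tdst, trst = total_sleep_time(h)
    if tst <= 0:
        raise NoSleepError("TST is zero; stage percentages undefined")
    pls = 100.0 * tlst / tst
    pds = 100.0 * tdst / tst
    prs = 100.0 * trst / tst if h.alphabet in ("PSG5", "DEV4") else None
    return pls, pds, prs


def extract_features(
    h: Hypnogram, lights_on: str | dt.datetime | None = None
) -> FeatureSet:
    """Full feature vector; raises :class:`NoSleepError` on an all-wake night."""
    so_idx, so_clock = sleep_onset(h)
    lsp = _last_sleep_epoch(h)
    spt = sleep_period_time(h)
    tst, tlst, tdst, trst = total_sleep_time(h)
    pls, pds, prs = stage_percentages(h)
    return FeatureSet(
        tst=tst,
        spt=spt,
        se=100.0 * tst / spt,
        waso=waso(h, lights_on),
        so_epoch=so_idx,
        so_clock=so_clock,
        so_minutes=so_idx * h.epoch_duration / 60.0,
        lsp_epoch=lsp,
        lsp_clock=h.time_of_epoch(lsp) if h.start_time is not None else None,
        tlst=tlst,
        tdst=tdst,
        trst=trst,
        pls=pls,
        pds=pds,
        prs=prs,
    )
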