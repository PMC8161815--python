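"""Synthetic paired hypnograms with known ground truth.

Real validation studies pair a physician-scored PSG hypnogram with a
device-scored one; no such recordings ship with this package, so every
metric is exercised against simulated nights whose error structure is known
exactly.

The PSG night is a first-order Markov chain over the five AASM stages at
30-s epochs. The default parameterization produces ~8-h nights whose stage
mix roughly matches adult norms (wake ~5% of the sleep period, light ~50%,
deep ~20%, REM ~25%) with plausible bout lengths; it is a plausible default,
not a fitted model of any population.

The device channel is generated *from* the PSG truth: the PSG night is
categorized to the device alphabet and then corrupted by

* a per-stage mislabel matrix (row = true device-alphabet stage, column =
  reported stage),
* a transition-lag distribution (each stage boundary slips by k epochs),
* a missing-epoch probability (dropped epochs carry the previous label
  forward).

Ground truth (the uncorrupted categorized sequence plus per-epoch
modification flags) is returned alongside, so expected values for accuracy
and transition rates can be computed exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import HypnogramError
from .hypnogram import ALPHABETS, Hypnogram, write_hypnogram
from .staging import DeviceType, categorize_psg

PSG_STAGES = ALPHABETS["PSG5"]

#: default per-epoch stage-transition matrix (rows/cols in PSG5 order
#: Wake, N1, N2, N3, REM). Self-transition probabilities encode mean bout
#: lengths of roughly 2, 1.5, 12.5, 11 and 9 minutes respectively.
DEFAULT_TRANSITIONS = np.array(
    [
        [0.750, 0.225, 0.025, 0.000, 0.000],  # Wake
        [0.067, 0.667, 0.233, 0.000, 0.033],  # N1
        [0.008, 0.010, 0.960, 0.014, 0.008],  # N2
        [0.005, 0.000, 0.035, 0.955, 0.005],  # N3
        [0.010, 0.020, 0.024, 0.002, 0.944],  # REM
    ]
)

#: nights start awake (sleep latency emerges from the Wake row's dwell)
DEFAULT_INITIAL = np.array([1.0, 0.0, 0.0, 0.0, 0.0])


def _check_stochastic(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if (m < -1e-12).any() or not np.allclose(m.sum(axis=-1), 1.0, atol=1e-9):
        raise ValueError(f"{name} rows must be non-negative and sum to 1")
    return m


@dataclass(frozen=True)
class DeviceErrorModel:
    """Stochastic corruption applied to the categorized PSG sequence.

    ``mislabel`` rows are indexed by the true device-alphabet stage in
    alphabet order; ``lag_probs`` maps boundary slip (epochs, may be
    negative) to probability; ``missing_prob`` is the per-epoch dropout
    probability (dropped epochs repeat the previous reported label).
    """

    mislabel: np.ndarray | None = None  # None = identity (no mislabeling)
    lag_probs: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    missing_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.mislabel is not None:
            _check_stochastic(np.asarray(self.mislabel), "mislabel matrix")
        if abs(sum(self.lag_probs.values()) - 1.0) > 1e-9 or any(
            p < 0 for p in self.lag_probs.values()
        ):
            raise ValueError("lag_probs must be a probability distribution")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob must be in [0, 1)")

    @classmethod
    def uniform_mislabel(cls, rate: float, n_stages: int) -> "DeviceErrorModel":
        """Each epoch keeps its stage w.p. 1-rate, else uniform over the others."""
        if not 0.0 <= rate < 1.0:
            raise ValueError("rate must be in [0, 1)")
        m = np.full((n_stages, n_stages), rate / (n_stages - 1))
        np.fill_diagonal(m, 1.0 - rate)
        return cls(mislabel=m)


@dataclass(frozen=True)
class SimScenario:
    """Everything needed to generate one (or many) paired synthetic nights."""

    n_epochs: int = 960  # ~8 h at 30-s epochs
    epoch_duration: float = 30.0
    start_time: str = "23:00:00"
    initial_probs: np.ndarray = field(
        default_factory=lambda: DEFAULT_INITIAL.copy()
    )
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )
    device_type: DeviceType = DeviceType.TYPE_II
    error_model: DeviceErrorModel = field(default_factory=DeviceErrorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        _check_stochastic(np.asarray(self.initial_probs), "initial_probs")
        t = _check_stochastic(np.asarray(self.transition_matrix), "transition_matrix")
        if t.shape != (5, 5):
            raise ValueError("transition_matrix must be 5x5 (PSG5 stages)")

    # -- YAML round trip (scenario files for the CLI) -----------------------

    def to_yaml(self, path: str | Path) -> None:
        em = self.error_model
        doc = {
            "n_epochs": self.n_epochs,
            "epoch_duration": self.epoch_duration,
            "start_time": self.start_time,
            "initial_probs": np.asarray(self.initial_probs).tolist(),
            "transition_matrix": np.asarray(self.transition_matrix).tolist(),
            "device_type": self.device_type.value,
            "seed": self.seed,
            "error_model": {
                "mislabel": None
                if em.mislabel is None
                else np.asarray(em.mislabel).tolist(),
                "lag_probs": {int(k): float(v) for k, v in em.lag_probs.items()},
                "missing_prob": em.missing_prob,
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        doc = yaml.safe_load(Path(path).read_text())
        em_doc = doc.get("error_model", {}) or {}
        em = DeviceErrorModel(
            mislabel=None
            if em_doc.get("mislabel") is None
            else np.asarray(em_doc["mislabel"], dtype=float),
            lag_probs={int(k): float(v) for k, v in (em_doc.get("lag_probs") or {0: 1.0}).items()},
            missing_prob=float(em_doc.get("missing_prob", 0.0)),
        )
        return cls(
            n_epochs=int(doc.get("n_epochs", 960)),
            epoch_duration=float(doc.get("epoch_duration", 30.0)),
            start_time=str(doc.get("start_time", "23:00:00")),
            initial_probs=np.asarray(doc.get("initial_probs", DEFAULT_INITIAL), float),
            transition_matrix=np.asarray(
                doc.get("transition_matrix", DEFAULT_TRANSITIONS), float
            ),
            device_type=DeviceType.from_string(str(doc.get("device_type", "II"))),
            error_model=em,
            seed=int(doc.get("seed", 0)),
        )


def _sample_chain(
    n: int, initial: np.ndarray, trans: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample a first-order Markov chain of stage indices."""
    cum_init = np.cumsum(initial)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    out[0] = np.searchsorted(cum_init, u[0], side="right")
    for i in range(1, n):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i], side="right")
    return np.minimum(out, len(initial) - 1)


def simulate_psg(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> Hypnogram:
    """One PSG5 Markov night; bit-reproducible given the scenario seed."""
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    idx = _sample_chain(
        scenario.n_epochs,
        np.asarray(scenario.initial_probs, float),
        np.asarray(scenario.transition_matrix, float),
        rng,
    )
    from .hypnogram import parse_clock_time

    start, dated = parse_clock_time(scenario.start_time)
    return Hypnogram(
        stages=tuple(PSG_STAGES[i] for i in idx),
        epoch_duration=scenario.epoch_duration,
        start_time=start,
        source="PSG",
        alphabet="PSG5",
        dated=dated,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Bookkeeping emitted with each simulated device night.

    ``true_stages`` is the categorized (error-free) device-alphabet
    sequence; ``modified`` flags epochs whose reported label differs from
    the truth for any reason (lag, mislabel, or dropout).
    """

    true_stages: tuple[str, ...]
    mislabeled: np.ndarray  # bool per epoch: mislabel channel fired
    missing: np.ndarray  # bool per epoch: dropout carried a label forward
    lagged: bool  # whether any boundary slipped

    @property
    def modified(self) -> np.ndarray:
        return np.array(
            [a != b for a, b in zip(self.true_stages, self._reported)], dtype=bool
        )

    _reported: tuple[str, ...] = ()


def _apply_lag(
    idx: np.ndarray, lag_probs: dict[int, float], rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Slip each stage boundary by a sampled number of epochs.

    The sequence is decomposed into runs; each internal boundary moves by a
    lag drawn from ``lag_probs`` (positive = device detects the change
    late). Boundaries are kept monotonic by clipping.
    """
    lags = sorted(lag_probs.items())
    ks = np.array([k for k, _ in lags])
    ps = np.array([p for _, p in lags])
    if ks.size == 1 and ks[0] == 0:
        return idx, False
    boundaries = np.flatnonzero(np.diff(idx) != 0) + 1  # run starts
    if boundaries.size == 0:
        return idx, False
    shifts = rng.choice(ks, size=boundaries.size, p=ps)
    new_bounds = boundaries + shifts
    starts = np.concatenate(([0], new_bounds))
    run_vals = np.concatenate(([idx[0]], idx[boundaries]))
    n = idx.size
    out = np.empty(n, dtype=idx.dtype)
    prev = 0
    for v, s in zip(run_vals, starts):
        s = int(np.clip(s, prev, n))
        out[s:] = v
        prev = s
    return out, bool((shifts != 0).any())


def simulate_device(
    psg: Hypnogram,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
) -> tuple[Hypnogram, GroundTruth]:
    """Corrupt the categorized PSG night through the device-error channel."""
    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 1)
    truth_h = categorize_psg(psg, scenario.device_type)
    alpha = ALPHABETS[truth_h.alphabet]
    stage_idx = {s: i for i, s in enumerate(alpha)}
    idx = np.array([stage_idx[s] for s in truth_h.stages], dtype=np.int64)
    em = scenario.error_model
    if em.mislabel is not None and np.asarray(em.mislabel).shape[0] != len(alpha):
        raise HypnogramError(
            f"mislabel matrix has {np.asarray(em.mislabel).shape[0]} rows for a "
            f"{len(alpha)}-stage alphabet"
        )

    reported, lagged = _apply_lag(idx, em.lag_probs, rng)
    reported = reported.copy()

    mislabeled = np.zeros(idx.size, dtype=bool)
    if em.mislabel is not None:
        m = np.asarray(em.mislabel, float)
        cum = np.cumsum(m, axis=1)
        u = rng.random(idx.size)
        drawn = np.array(
            [np.searchsorted(cum[reported[i]], u[i], side="right") for i in range(idx.size)],
            dtype=np.int64,
        )
        drawn = np.minimum(drawn, len(alpha) - 1)
        mislabeled = drawn != reported
        reported = drawn

    missing = np.zeros(idx.size, dtype=bool)
    if em.missing_prob > 0:
        drop = rng.random(idx.size) < em.missing_prob
        drop[0] = False  # first epoch always reported
        for i in np.flatnonzero(drop):
            reported[i] = reported[i - 1]
        missing = drop

    device = replace(
        truth_h,
        stages=tuple(alpha[i] for i in reported),
        source="device",
    )
    truth = GroundTruth(
        true_stages=truth_h.stages,
        mislabeled=mislabeled,
        missing=missing,
        lagged=lagged,
        _reported=device.stages,
    )
    return device, truth


def night_seeds(master_seed: int, n_nights: int) -> list[int]:
    """Deterministic per-night seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_nights)]


def generate_night(
    scenario: SimScenario, seed: int | None = None
) -> tuple[Hypnogram, Hypnogram, GroundTruth]:
    """(psg, device, truth) for one night; in-memory counterpart of the cohort."""
    s = scenario if seed is None else replace(scenario, seed=seed)
    rng = np.random.default_rng(s.seed)
    psg = simulate_psg(s, rng)
    device, truth = simulate_device(psg, s, rng)
    return psg, device, truth


def simulate_cohort(
    n_nights: int, scenario: SimScenario, out_dir: str | Path
) -> Path:
    """Write ``n_nights`` paired hypnogram CSVs plus a manifest; returns the
    manifest path. Per-night seeds derive deterministically from the
    scenario's master seed, so identical scenarios give byte-identical
    output trees."""
    if n_nights < 1:
        raise ValueError("n_nights must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    seeds = night_seeds(scenario.seed, n_nights)
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["night", "psg_path", "device_path", "device_type", "seed"])
        for i, seed in enumerate(seeds):
            psg, device, _ = generate_night(scenario, seed)
            psg_path = out / f"psg_{i:03d}.csv"
            dev_path = out / f"device_{i:03d}.csv"
            write_hypnogram(psg, psg_path)
            write_hypnogram(device, dev_path)
            w.writerow(
                [i, psg_path.name, dev_path.name, scenario.device_type.value, seed]
            )
    return manifest
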