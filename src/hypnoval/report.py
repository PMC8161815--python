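"""Per-night and cohort report assembly.

A per-night comparison runs synchronize → categorize → features (both
scorers) → LMI → confusion and collects everything into one JSON-ready
dictionary plus a per-epoch transition CSV. A cohort report aggregates
nights listed in a manifest: per-feature paired tests, mean transition
rates, a pooled confusion matrix, and — when the manifest covers several
devices — a ranking by the paired-test p-value (larger p = closer to PSG;
ties broken by smaller absolute effect size).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import confusion, paired_feature_test
from .errors import HypnovalError
from .features import extract_features
from .hypnogram import AlignedPair, Hypnogram, read_hypnogram, synchronize
from .lmi import lmi_sequence
from .staging import DeviceType, StageEncoding, categorize_psg

#: features compared across nights, in reporting order
COHORT_FEATURES = ("SPT", "SE", "WASO", "SO_minutes", "TST", "PLS", "PDS", "PRS")


@dataclass(frozen=True)
class RunConfig:
    """Validated knobs for one comparison run; echoed into every report."""

    device_type: DeviceType = DeviceType.TYPE_II
    epoch_duration: float = 30.0
    rem_code: int = 8
    kappa_threshold: float = 0.8
    alpha: float = 0.05
    lights_on: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.kappa_threshold <= 1:
            raise ValueError("kappa_threshold must be in [0, 1]")

    @property
    def encoding(self) -> StageEncoding:
        return StageEncoding.default(rem_code=self.rem_code)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["device_type"] = self.device_type.value
        return d


def compare_pair(
    psg: Hypnogram, device: Hypnogram, config: RunConfig
) -> tuple[dict, pd.DataFrame]:
    """Full per-night comparison; returns (summary dict, per-epoch LMI table)."""
    pair = synchronize(psg, device)
    psg_cat = categorize_psg(pair.psg, config.device_type)
    pair = AlignedPair(psg=psg_cat, device=pair.device)

    feats_psg = extract_features(psg_cat, config.lights_on)
    feats_dev = extract_features(pair.device, config.lights_on)
    lmi_res = lmi_sequence(pair, config.encoding)
    conf = confusion(pair)

    summary = {
        "config": config.as_dict(),
        "version": __version__,
        "n_epochs": pair.n_epochs,
        "features": {"psg": feats_psg.as_dict(), "device": feats_dev.as_dict()},
        "transition_rates": lmi_res.rates,
        "n_transitions": lmi_res.n_transitions,
        "confusion": {
            "counts": conf.counts.to_dict(),
            "sensitivity": conf.sensitivity,
            "specificity": conf.specificity,
            "accuracy": conf.accuracy,
            "undefined_stages": list(conf.undefined_stages),
        },
    }
    return summary, lmi_res.to_frame()


def write_night_report(summary: dict, lmi_table: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_default))
    lmi_table.to_csv(out / "lmi_epochs.csv", index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, dt.datetime):
        return o.isoformat()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _feature_value(fd: dict, name: str) -> float | None:
    return fd.get(name)


def cohort_report(manifest_path: str | Path, config: RunConfig) -> dict:
    """Aggregate a manifest of paired nights into cohort-level tables.

    With fewer than 3 nights the paired tests are reported as errors while
    transition rates and the pooled confusion matrix are still emitted.
    Manifests listing several device types produce one block per device
    plus a p-value ranking per feature.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except Exception as exc:  # noqa: BLE001 - surface as package error
        raise HypnovalError(f"unparseable manifest: {exc}") from exc
    required = {"night", "psg_path", "device_path", "device_type"}
    if not required <= set(manifest.columns):
        raise HypnovalError(f"manifest must have columns {sorted(required)}")
    base = manifest_path.parent

    blocks: dict[str, dict] = {}
    for dtype_str, grp in manifest.groupby("device_type", sort=False):
        dtype = DeviceType.from_string(str(dtype_str))
        cfg = RunConfig(
            device_type=dtype,
            epoch_duration=config.epoch_duration,
            rem_code=config.rem_code,
            kappa_threshold=config.kappa_threshold,
            alpha=config.alpha,
            lights_on=config.lights_on,
            seed=config.seed,
        )
        feats_psg: dict[str, list[float]] = {f: [] for f in COHORT_FEATURES}
        feats_dev: dict[str, list[float]] = {f: [] for f in COHORT_FEATURES}
        rates_acc: list[dict] = []
        pooled_counts = None
        n_epochs = 0
        for _, row in grp.iterrows():
            psg = read_hypnogram(base / row["psg_path"], alphabet="PSG5")
            device = read_hypnogram(base / row["device_path"], alphabet=dtype.alphabet)
            summary, _ = compare_pair(psg, device, cfg)
            for f in COHORT_FEATURES:
                feats_psg[f].append(_feature_value(summary["features"]["psg"], f))
                feats_dev[f].append(_feature_value(summary["features"]["device"], f))
            if summary["transition_rates"] is not None:
                rates_acc.append(summary["transition_rates"])
            counts = pd.DataFrame(summary["confusion"]["counts"])
            pooled_counts = counts if pooled_counts is None else pooled_counts + counts
            n_epochs += summary["n_epochs"]

        tests: dict[str, dict] = {}
        for f in COHORT_FEATURES:
            xs = [v for v in feats_psg[f] if v is not None]
            ys = [v for v in feats_dev[f] if v is not None]
            if not xs or len(xs) != len(ys):
                continue
            if len(xs) < 3:
                tests[f] = {"error": "fewer than 3 nights; paired test not run"}
                continue
            r = paired_feature_test(xs, ys, feature=f, alpha=cfg.alpha)
            tests[f] = {
                "test": r.test,
                "p_value": r.p_value,
                "effect": r.effect,
                "significant": r.significant,
                "marker": "(*)" if r.significant else "(**)",
                "n": r.n,
            }

        mean_rates = (
            {
                k: float(np.mean([r[k] for r in rates_acc]))
                for k in rates_acc[0]
            }
            if rates_acc
            else None
        )
        acc = None
        if pooled_counts is not None:
            total = pooled_counts.to_numpy().sum()
            acc = 100.0 * float(np.trace(pooled_counts.to_numpy())) / total
        blocks[str(dtype_str)] = {
            "n_nights": int(len(grp)),
            "n_epochs": n_epochs,
            "paired_tests": tests,
            "mean_transition_rates": mean_rates,
            "pooled_confusion_counts": pooled_counts.to_dict()
            if pooled_counts is not None
            else None,
            "pooled_accuracy": acc,
        }

    rankings: dict[str, list[str]] = {}
    if len(blocks) > 1:
        for f in COHORT_FEATURES:
            entries = [
                (name, b["paired_tests"][f])
                for name, b in blocks.items()
                if f in b["paired_tests"] and "p_value" in b["paired_tests"][f]
            ]
            if entries:
                entries.sort(key=lambda kv: (-kv[1]["p_value"], abs(kv[1]["effect"])))
                rankings[f] = [name for name, _ in entries]

    return {
        "config": config.as_dict(),
        "version": __version__,
        "devices": blocks,
        "ranking_by_p": rankings,
    }


def write_cohort_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "cohort.json").write_text(json.dumps(report, indent=2, default=_json_default))
    rows = []
    for device, block in report["devices"].items():
        for f, t in block["paired_tests"].items():
            if "p_value" in t:
                rows.append(
                    {
                        "device_type": device,
                        "feature": f,
                        "test": t["test"],
                        "p_value": t["p_value"],
                        "effect": t["effect"],
                        "marker": t["marker"],
                    }
                )
    if rows:
        pd.DataFrame(rows).to_csv(out / "paired_tests.csv", index=False)
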