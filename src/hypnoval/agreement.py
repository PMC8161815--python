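"""Interrater gating, epoch-by-epoch confusion metrics, and the paired
feature-comparison suite.

Fleiss' kappa gates the PSG ground truth: when several raters scored the
PSG hypnogram, kappa = (P_bar - Pe_bar) / (1 - Pe_bar) must reach the gate
threshold (0.8 by convention) or the hypnogram is flagged for concurrent
revision before any device comparison runs.

Per-night features from PSG and device are compared pairwise across nights:
the paired t-test when the paired differences look normal (Shapiro-Wilk at
alpha = 0.05), the Wilcoxon signed-rank test otherwise, with a signed paired
Cohen's d = mean(diff)/sd(diff) as the effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats import inter_rater

from .errors import HypnogramError, UndefinedKappaError
from .hypnogram import ALPHABETS, AlignedPair

# ---------------------------------------------------------------------------
# Fleiss' kappa gate
# ---------------------------------------------------------------------------


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa over an epochs x raters matrix of categorical labels.

    ``ratings`` may be a 2-D array-like or DataFrame; cells are stage labels
    (any hashable). Returns 1.0 on total agreement (including the degenerate
    single-category case, where the chance-agreement denominator vanishes).
    """
    arr = np.asarray(ratings, dtype=object)
    if arr.ndim != 2:
        raise ValueError("ratings must be 2-D (epochs x raters)")
    n_epochs, n_raters = arr.shape
    if n_raters < 2 or n_epochs < 1:
        raise ValueError("need at least 2 raters and 1 epoch")
    if all(len(set(row)) == 1 for row in arr):
        return 1.0
    table, _ = inter_rater.aggregate_raters(arr)
    kappa = inter_rater.fleiss_kappa(table, method="fleiss")
    if not np.isfinite(kappa):
        raise UndefinedKappaError("chance agreement is 1 without total agreement")
    return float(kappa)


@dataclass(frozen=True)
class GateDecision:
    kappa: float
    threshold: float
    passed: bool

    @property
    def action(self) -> str:
        return "pass" if self.passed else "revise"


def interrater_gate(kappa: float, threshold: float = 0.8) -> GateDecision:
    """Pass iff kappa >= threshold (boundary inclusive); otherwise revise."""
    return GateDecision(kappa=kappa, threshold=threshold, passed=kappa >= threshold)


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionSummary:
    """Stage-wise sensitivity/specificity and overall epoch accuracy.

    ``counts`` is the raw matrix with device stages as rows and PSG stages
    as columns. Sensitivity of stage s is the percent of PSG epochs of s the
    device also scored s; specificity is the percent of PSG epochs *not* of
    s the device scored not-s. Stages never scored by the PSG have undefined
    sensitivity (NaN, listed in ``undefined_stages``).
    """

    counts: pd.DataFrame
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    accuracy: float
    undefined_stages: tuple[str, ...]

    @property
    def n_epochs(self) -> int:
        return int(self.counts.to_numpy().sum())


def confusion(pair: AlignedPair) -> ConfusionSummary:
    """Epoch-by-epoch confusion summary for an aligned, common-alphabet pair."""
    if pair.psg.alphabet != pair.device.alphabet:
        raise HypnogramError(
            "confusion requires a common alphabet; categorize the PSG hypnogram first"
        )
    stages = list(ALPHABETS[pair.psg.alphabet])
    psg = pd.Categorical(pair.psg.stages, categories=stages)
    dev = pd.Categorical(pair.device.stages, categories=stages)
    counts = pd.crosstab(
        pd.Series(dev, name="device"), pd.Series(psg, name="psg"), dropna=False
    ).reindex(index=stages, columns=stages, fill_value=0)
    n = pair.n_epochs
    sens: dict[str, float] = {}
    spec: dict[str, float] = {}
    undefined = []
    for s in stages:
        pos = int(counts[s].sum())  # PSG epochs of stage s
        if pos == 0:
            sens[s] = float("nan")
            undefined.append(s)
        else:
            sens[s] = 100.0 * int(counts.loc[s, s]) / pos
        neg = n - pos
        if neg == 0:
            spec[s] = float("nan")
        else:
            tn = neg - (int(counts.loc[s].sum()) - int(counts.loc[s, s]))
            spec[s] = 100.0 * tn / neg
    accuracy = 100.0 * float(np.trace(counts.to_numpy())) / n
    return ConfusionSummary(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        accuracy=accuracy,
        undefined_stages=tuple(undefined),
    )


# ---------------------------------------------------------------------------
# Paired feature comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    """Outcome of one paired feature comparison across nights.

    ``effect`` is the signed paired Cohen's d, mean(device - PSG) / sd of
    the differences, reported under the eta-squared column label in tabular
    output for continuity with the field's reporting convention.
    """

    feature: str
    test: str  # "paired_t" | "wilcoxon" | "degenerate"
    p_value: float
    effect: float
    significant: bool
    n: int


def paired_feature_test(
    psg_values, dev_values, feature: str = "", alpha: float = 0.05
) -> TestResult:
    """Compare per-night feature values from PSG and a device.

    Normality of the paired differences is decided by Shapiro-Wilk at
    alpha = 0.05: normal differences get the paired t-test, otherwise the
    Wilcoxon signed-rank test. All-zero differences are reported as a
    degenerate no-difference outcome with p = 1.
    """
    x = np.asarray(psg_values, dtype=float)
    y = np.asarray(dev_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("psg_values and dev_values must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired nights")
    diff = y - x
    if np.allclose(diff, 0.0):
        return TestResult(feature, "degenerate", 1.0, 0.0, False, n)
    sd = diff.std(ddof=1)
    effect = float(diff.mean() / sd) if sd > 0 else float("inf") * np.sign(diff.mean())
    if sd > 0 and stats.shapiro(diff).pvalue >= 0.05:
        test = "paired_t"
        p = float(stats.ttest_rel(y, x).pvalue)
    else:
        test = "wilcoxon"
        p = float(stats.wilcoxon(diff).pvalue)
    return TestResult(feature, test, p, effect, p < alpha, n)
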