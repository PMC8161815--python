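"""Localized mismatch index (LMI): epoch-by-epoch scoring of sleep-stage
transition agreement between a PSG and a device hypnogram.

Both hypnograms are first encoded as integers (Wake=1, Light=2, Deep=4, and
REM=8 in 4-stage mode). Writing ``Y_P`` and ``Y_W`` for the encoded PSG and
wearable sequences, the transition deltas are the first differences

    dP_i = Y_P[i+1] - Y_P[i],    dW_i = Y_W[i+1] - Y_W[i],

the transition set is ``A = {i : dP_i != 0 or dW_i != 0}``, and the index at
each transition epoch is the product ``LMI_i = dW_i * dP_i``.

With the 3-stage codes the six legal transitions W-L, W-D, L-D, L-W, D-L,
D-W have deltas 1, 3, 2, -1, -2, -3, so the product table is symmetric with
diagonal {1, 4, 9}: 1 and 9 mark correctly detected wake transitions, 4 a
correctly detected light/deep transition, and every other value some form of
disagreement.

Classification
--------------
Each transition epoch receives one of four classes:

correct_wake / correct_sleep
    The two scorers registered the *same* transition (equal deltas); wake if
    the transition has Wake at an endpoint, sleep otherwise.
incorrect_wake / incorrect_sleep
    Any disagreement. The split asks whether the scorers agree on the
    wake-crossing component of the transition: each delta is reduced to its
    wake direction (sign of the delta when the transition involves Wake,
    else 0). Agreeing wake directions mean the error lies in sleep-stage
    depth (incorrect_sleep, e.g. products 3 and -4 in 3-stage mode);
    differing directions mean a missed or spurious wake transition
    (incorrect_wake — all remaining products, including the one-sided
    product-0 epochs where only one scorer transitioned).

In 3-stage mode this rule reproduces the canonical product grouping
correct wake {1, 9}, correct sleep {4}, incorrect sleep {3, -4}, incorrect
wake {2, 6, -1, -2, -3, -6, -9} exactly; because it operates on the delta
pair rather than the product alone, it extends unchanged to 4-stage (REM)
mode regardless of the REM code chosen.

Rates are denominated by |A|: the four class percentages sum to 100 over
the transition epochs, and overall correct = correct_wake + correct_sleep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import HypnogramError, UndefinedRateError
from .hypnogram import AlignedPair
from .staging import StageEncoding, encode

CLASSES = ("correct_wake", "correct_sleep", "incorrect_wake", "incorrect_sleep")


def transition_deltas(codes: np.ndarray) -> np.ndarray:
    """First differences of an encoded stage sequence (length n-1)."""
    codes = np.asarray(codes)
    if codes.size < 2:
        raise ValueError("need at least 2 epochs to form transition deltas")
    return np.diff(codes)


def _wake_direction(delta: int, wake_mags: frozenset[int]) -> int:
    """Sign of the delta if the transition involves Wake, else 0."""
    if delta != 0 and abs(delta) in wake_mags:
        return 1 if delta > 0 else -1
    return 0


def classify_lmi(
    delta_psg: int, delta_device: int, enc: StageEncoding, alphabet: str
) -> str:
    """Classify one transition epoch from its delta pair.

    Raises ``ValueError`` when both deltas are zero (not a transition epoch).
    """
    if delta_psg == 0 and delta_device == 0:
        raise ValueError("both deltas are zero: not a member of the transition set")
    wake_mags = enc.wake_delta_magnitudes(alphabet)
    if delta_psg == delta_device:
        return (
            "correct_wake"
            if abs(delta_psg) in wake_mags
            else "correct_sleep"
        )
    if _wake_direction(delta_psg, wake_mags) == _wake_direction(delta_device, wake_mags):
        return "incorrect_sleep"
    return "incorrect_wake"


@dataclass(frozen=True)
class LMIResult:
    """Per-night LMI decomposition.

    ``transition_set`` holds the sorted epoch indices i where at least one
    scorer changed stage between epochs i and i+1; ``lmi_values`` and
    ``classes`` are indexed parallel to it.
    """

    deltas_psg: np.ndarray
    deltas_device: np.ndarray
    transition_set: np.ndarray
    lmi_values: np.ndarray
    classes: tuple[str, ...]
    rates: dict[str, float] | None

    @property
    def n_transitions(self) -> int:
        return int(self.transition_set.size)

    def to_frame(self) -> pd.DataFrame:
        """Per-transition-epoch table (epoch, deltas, LMI, class)."""
        return pd.DataFrame(
            {
                "epoch": self.transition_set,
                "delta_psg": self.deltas_psg[self.transition_set],
                "delta_device": self.deltas_device[self.transition_set],
                "lmi": self.lmi_values,
                "class": list(self.classes),
            }
        )


def summarize_rates(
    transition_classes, n_transitions: int | None = None
) -> dict[str, float]:
    """Percent of transition epochs in each class, plus overall correct/incorrect.

    Accepts an :class:`LMIResult` or a sequence of class labels. Raises
    :class:`UndefinedRateError` on an empty transition set.
    """
    if isinstance(transition_classes, LMIResult):
        transition_classes = transition_classes.classes
    labels = list(transition_classes)
    total = len(labels) if n_transitions is None else n_transitions
    if total == 0:
        raise UndefinedRateError("no transition epochs: rates undefined")
    rates = {c: 100.0 * labels.count(c) / total for c in CLASSES}
    rates["overall_correct"] = rates["correct_wake"] + rates["correct_sleep"]
    rates["overall_incorrect"] = rates["incorrect_wake"] + rates["incorrect_sleep"]
    return rates


def lmi_sequence(pair: AlignedPair, enc: StageEncoding | None = None) -> LMIResult:
    """Compute deltas, the transition set A, LMI products, classes and rates.

    The pair's members must share a stage alphabet (categorize the PSG
    hypnogram to the device alphabet first) covered by the encoding. On a
    transition-free night ``rates`` is None.
    """
    if pair.psg.alphabet != pair.device.alphabet:
        raise HypnogramError(
            "PSG and device alphabets differ "
            f"({pair.psg.alphabet} vs {pair.device.alphabet}); "
            "categorize the PSG hypnogram first"
        )
    enc = enc or StageEncoding.default()
    if not enc.covers(pair.psg.alphabet):
        raise HypnogramError("encoding does not cover the pair's alphabet")
    yp = encode(pair.psg, enc)
    yw = encode(pair.device, enc)
    dp = transition_deltas(yp)
    dw = transition_deltas(yw)
    a = np.flatnonzero((dp != 0) | (dw != 0))
    values = dw[a] * dp[a]
    classes = tuple(
        classify_lmi(int(dp[i]), int(dw[i]), enc, pair.psg.alphabet) for i in a
    )
    rates = summarize_rates(classes) if a.size else None
    return LMIResult(
        deltas_psg=dp,
        deltas_device=dw,
        transition_set=a,
        lmi_values=values,
        classes=classes,
        rates=rates,
    )
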