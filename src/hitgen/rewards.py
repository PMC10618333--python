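"""Reward shaping and self-adaptive two-objective scalarization.

Each raw property (predicted pIC50, synthetic accessibility) is mapped
through a clipped monotone sigmoid onto [0, 1]: pIC50 rises from 0 to 1
across [4, 9]; SAS falls from 1 to 0 across [1, 6].  The two shaped
rewards are combined additively, f = w1*r1 + w2*r2 with w1 + w2 = 1.

The weights adapt online: when one weighted objective dominates the
other while the dominated objective's reward has plateaued (variation
ratio over the last five batch means below 0.05), the dominant weight
is decremented by a fixed step and the other incremented, rebalancing
the optimization pressure.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np


@dataclass
class RewardShape:
    """Clipped sigmoid from property units onto [0, 1].

    ``low`` and ``high`` are the saturation points; ``increasing``
    selects whether the reward rises (pIC50) or falls (SAS) with the
    property value.  The sigmoid spans ~[0.01, 0.99] between the
    saturation points and is hard-clipped outside.
    """

    low: float
    high: float
    increasing: bool = True

    def __call__(self, value: float | np.ndarray) -> float | np.ndarray:
        value = np.asarray(value, dtype=float)
        if np.any(np.isnan(value)):
            raise ValueError("NaN property value")
        mid = 0.5 * (self.low + self.high)
        # logistic scale chosen so the curve is ~0.01/0.99 at the saturation points
        scale = (self.high - self.low) / (2.0 * np.log(99.0))
        z = np.clip((value - mid) / scale, -60.0, 60.0)
        r = 1.0 / (1.0 + np.exp(-z))
        r = np.where(value <= self.low, 0.0, np.where(value >= self.high, 1.0, r))
        if not self.increasing:
            r = 1.0 - r
        return float(r) if r.ndim == 0 else r


PIC50_SHAPE = RewardShape(low=4.0, high=9.0, increasing=True)
SAS_SHAPE = RewardShape(low=1.0, high=6.0, increasing=False)


def shape_reward(value: float, shape: RewardShape) -> float:
    return shape(value)


def variation_ratio(history, method: str = "range") -> float:
    """Plateau detector over a reward window.

    ``method='range'`` (default): (max - min) / max.
    ``method='cv'``: coefficient of variation, std / mean.
    Both return 0 for a constant series.
    """
    h = np.asarray(list(history), dtype=float)
    if len(h) < 2:
        raise ValueError("variation ratio needs at least 2 entries")
    if method == "range":
        hi = h.max()
        if hi <= 0:
            return 0.0
        return float((hi - h.min()) / hi)
    if method == "cv":
        mean = h.mean()
        if mean <= 0:
            return 0.0
        return float(h.std() / mean)
    raise ValueError(f"unknown variation-ratio method {method!r}")


@dataclass
class ScalarizationState:
    """Weights, reward histories and update hyperparameters."""

    w1: float = 0.6
    w2: float = 0.4
    step: float = 0.05
    vr_threshold: float = 0.05
    vr_method: str = "range"
    window: int = 5
    history1: deque = field(default_factory=lambda: deque(maxlen=5))
    history2: deque = field(default_factory=lambda: deque(maxlen=5))

    def __post_init__(self):
        self._check()
        self.history1 = deque(self.history1, maxlen=self.window)
        self.history2 = deque(self.history2, maxlen=self.window)

    def _check(self):
        if not (0.0 <= self.w1 <= 1.0 and 0.0 <= self.w2 <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def record(self, f1: float, f2: float) -> None:
        """Append the batch-mean shaped rewards for both objectives."""
        self.history1.append(float(f1))
        self.history2.append(float(f2))

    def scalarize(self, r1, r2):
        """f = w1*r1 + w2*r2 (elementwise for arrays)."""
        self._check()
        r1 = np.asarray(r1, dtype=float)
        r2 = np.asarray(r2, dtype=float)
        if np.any((r1 < 0) | (r1 > 1) | (r2 < 0) | (r2 > 1)):
            raise ValueError("rewards must lie in [0, 1]")
        out = self.w1 * r1 + self.w2 * r2
        return float(out) if out.ndim == 0 else out

    def update_weights(self) -> bool:
        """One self-adaptive update from the latest batch-mean rewards.

        Fires only when one weighted objective dominates and the other
        objective's reward history has plateaued.  Returns True when the
        weights changed.
        """
        if not self.history1 or not self.history2:
            return False
        f1, f2 = self.history1[-1], self.history2[-1]
        can_vr1 = len(self.history1) >= 2
        can_vr2 = len(self.history2) >= 2
        changed = False
        # tie guard: exact equality of the weighted objectives must not
        # oscillate under floating-point round-off
        diff = self.w1 * f1 - self.w2 * f2
        tol = 1e-9
        if (diff > tol and can_vr2
                and variation_ratio(self.history2, self.vr_method)
                < self.vr_threshold):
            self.w1 -= self.step
            self.w2 += self.step
            changed = True
        elif (diff < -tol and can_vr1
                and variation_ratio(self.history1, self.vr_method)
                < self.vr_threshold):
            self.w1 += self.step
            self.w2 -= self.step
            changed = True
        if changed:
            self.w1 = float(np.clip(self.w1, 0.0, 1.0))
            self.w2 = float(np.clip(self.w2, 0.0, 1.0))
            # re-couple so the pair stays on the simplex after clipping
            self.w2 = 1.0 - self.w1
        return changed
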