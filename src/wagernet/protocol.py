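"""Per-pool external input time courses for one trial.

A trial unfolds as: spontaneous phase (background only), direction
targets on (strong transient to pools L and R), random-dot-motion
stimulus (rate lambda +/- delta_lambda to L/R), delay, optional sure
target to pool S (free-choice trials only), and a saccade-related
signal to all three selective pools at the end of the trial.

All rates are *extra* external input in Hz, added on top of the
aggregated background drive (N_ext sources at 3 Hz each); the spiking
network adds the background itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TargetInput",
    "StimulationProtocol",
    "motion_input",
    "target_transient",
    "assemble_protocol",
    "DIRECTION_TARGET",
    "SURE_TARGET",
]

POOLS = ("L", "R", "S", "ns", "I")


@dataclass(frozen=True)
class TargetInput:
    """Double-exponential target input: fast visual transient plus a
    slow component reflecting the continued visibility of the target,
    decaying toward ``asymptote``.

    rate(t) = asymptote + A_fast exp(-t/tau_fast) + A_slow exp(-t/tau_slow)
    """

    A_fast: float   # Hz
    tau_fast: float  # ms
    A_slow: float   # Hz
    tau_slow: float  # ms
    asymptote: float  # Hz

    def rate(self, t: float | np.ndarray) -> float | np.ndarray:
        """Input rate at time ``t`` (ms) since target onset."""
        t = np.asarray(t, dtype=float)
        out = (self.asymptote
               + self.A_fast * np.exp(-t / self.tau_fast)
               + self.A_slow * np.exp(-t / self.tau_slow))
        return float(out) if out.ndim == 0 else out


# The direction targets decay toward zero; the sure target sustains a
# 5 Hz asymptote and carries a weaker input overall (lower stakes).
# Amplitudes are calibrated so the network reproduces the canonical
# trial dynamics: a strong, adapting response of pools L/R to target
# onset, comparably elevated rates of both pools at motion onset, and
# a winner that can sustain decision-level activity (above the 28 Hz
# decision threshold) through the delay period.
DIRECTION_TARGET = TargetInput(A_fast=120.0, tau_fast=80.0,
                               A_slow=55.0, tau_slow=5000.0, asymptote=0.0)
SURE_TARGET = TargetInput(A_fast=185.0, tau_fast=80.0,
                          A_slow=68.0, tau_slow=5000.0, asymptote=5.0)


def target_transient(t_since_onset: float | np.ndarray,
                     asymptote: float = 0.0,
                     target: TargetInput = DIRECTION_TARGET) -> float | np.ndarray:
    """Target input rate at ``t_since_onset`` ms, decaying toward
    ``asymptote`` (0 Hz for direction targets, 5 Hz for the sure
    target)."""
    if np.any(np.asarray(t_since_onset) < 0):
        raise ValueError("t_since_onset must be nonnegative")
    return replace(target, asymptote=asymptote).rate(t_since_onset)


def motion_input(pool: str, lam: float, dlam: float) -> float:
    """Extra rate from the motion stimulus: lambda + delta_lambda to the
    pool voting for the correct direction (L), lambda - delta_lambda to
    the other (R), nothing to S."""
    if lam - dlam < 0:
        raise ValueError("lambda - delta_lambda must be nonnegative")
    if pool == "L":
        return lam + dlam
    if pool == "R":
        return lam - dlam
    if pool == "S":
        return 0.0
    raise ValueError(f"pool must be L, R or S, got {pool!r}")


@dataclass(frozen=True)
class StimulationProtocol:
    """Piecewise time course of extra external input for one trial.

    Phase intervals are half-open [onset, offset) at the integration
    grid resolution.  In forced-choice trials pool S receives only the
    background (plus the saccade signal)."""

    lambda_mean: float
    delta_lambda: float
    motion_duration: float
    free_choice: bool
    spontaneous_duration: float = 500.0
    target_duration: float = 500.0      # target-only phase before motion
    sure_delay: float = 500.0           # sure onset after motion offset
    post_sure_duration: float = 1000.0  # sure onset -> trial end
    saccade_rate: float = 80.0
    saccade_duration: float = 100.0
    direction_target: TargetInput = DIRECTION_TARGET
    sure_target: TargetInput = SURE_TARGET

    def __post_init__(self) -> None:
        if self.lambda_mean - self.delta_lambda < 0:
            raise ValueError("lambda - delta_lambda must be nonnegative")
        if self.delta_lambda < 0:
            raise ValueError("delta_lambda must be nonnegative")
        for name in ("motion_duration", "spontaneous_duration",
                     "target_duration", "sure_delay", "post_sure_duration",
                     "saccade_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.saccade_duration > self.post_sure_duration:
            raise ValueError("saccade signal does not fit before trial end")

    # -- timeline ----------------------------------------------------------
    @property
    def target_onset(self) -> float:
        return self.spontaneous_duration

    @property
    def motion_onset(self) -> float:
        return self.target_onset + self.target_duration

    @property
    def motion_offset(self) -> float:
        return self.motion_onset + self.motion_duration

    @property
    def sure_onset(self) -> float:
        """Time the sure target would appear (defined for forced-choice
        trials too, so rate snapshots stay comparable)."""
        return self.motion_offset + self.sure_delay

    @property
    def trial_end(self) -> float:
        return self.sure_onset + self.post_sure_duration

    @property
    def go_cue(self) -> float:
        """Onset of the saccade-related signal; decisions are assessed
        up to this time."""
        return self.trial_end - self.saccade_duration

    # -- rates -------------------------------------------------------------
    def extra_rates(self, t: np.ndarray) -> np.ndarray:
        """Extra external rate (Hz) per pool at times ``t`` (ms).

        Returns an array of shape (len(t), 5) ordered (L, R, S, ns, I);
        the nonspecific and inhibitory pools never receive extra input.
        """
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape + (5,))

        on_target = t >= self.target_onset
        tt = np.where(on_target, t - self.target_onset, 0.0)
        target = np.where(on_target, self.direction_target.rate(tt), 0.0)
        out[..., 0] += target
        out[..., 1] += target

        in_motion = (t >= self.motion_onset) & (t < self.motion_offset)
        out[..., 0] += np.where(in_motion, self.lambda_mean + self.delta_lambda, 0.0)
        out[..., 1] += np.where(in_motion, self.lambda_mean - self.delta_lambda, 0.0)

        if self.free_choice:
            on_sure = t >= self.sure_onset
            ts = np.where(on_sure, t - self.sure_onset, 0.0)
            out[..., 2] += np.where(on_sure, self.sure_target.rate(ts), 0.0)

        in_saccade = (t >= self.go_cue) & (t < self.trial_end)
        for p in range(3):
            out[..., p] += np.where(in_saccade, self.saccade_rate, 0.0)
        return out

    def rate_table(self, dt: float) -> np.ndarray:
        """Extra rates sampled on the integration grid (n_steps, 5)."""
        n = int(round(self.trial_end / dt))
        t = np.arange(n) * dt
        return self.extra_rates(t)

    def to_frame(self, dt: float = 5.0) -> pd.DataFrame:
        """Tabular export of the input time course for inspection."""
        n = int(round(self.trial_end / dt))
        t = np.arange(n) * dt
        rates = self.extra_rates(t)
        return pd.DataFrame({
            "time_ms": t,
            "rate_L": rates[:, 0],
            "rate_R": rates[:, 1],
            "rate_S": rates[:, 2],
            "rate_nonspecific": rates[:, 3],
            "rate_inhibitory": rates[:, 4],
        })


def assemble_protocol(
    duration: float,
    lam: float,
    dlam: float,
    free_choice: bool,
    **overrides,
) -> StimulationProtocol:
    """Build the full trial protocol for one stimulus condition.

    ``duration`` is the motion-stimulus duration in ms (the published
    conditions use 100, 200, 300 and 500 ms); timeline fields can be
    overridden by keyword.
    """
    return StimulationProtocol(
        lambda_mean=lam, delta_lambda=dlam,
        motion_duration=duration, free_choice=free_choice,
        **overrides,
    )
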