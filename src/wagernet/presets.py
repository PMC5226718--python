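"""Named run configurations: reduced-scale fixtures and full-scale
reproduction presets.

``smoke`` exercises every code path on a 200-neuron network in well
under a minute; ``bistable`` and ``multistable`` pin the two dynamical
regimes studied in the task (lambda = 15 Hz with a 24 Hz decision
threshold, lambda = 50 Hz with 28 Hz); the ``full-*`` presets carry
the full condition grids at publication scale (1000 trials per
condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import NetworkSpec
from .trials import DecisionParams

__all__ = ["RunConfig", "PRESETS", "get_preset", "list_presets"]

DURATIONS = (100.0, 200.0, 300.0, 500.0)
DLAMBDAS = (0.0, 4.0, 8.0, 16.0, 24.0, 30.0)


def _grid(lam: float, dlams, durations, free_choice) -> list[dict]:
    return [dict(lam=lam, dlam=d, duration=dur, free_choice=fc)
            for d in dlams for dur in durations for fc in free_choice]


@dataclass(frozen=True)
class RunConfig:
    """One reproducible simulation campaign."""

    name: str
    conditions: tuple[dict, ...]
    n_trials: int
    decision: DecisionParams = DecisionParams()
    network: NetworkSpec = NetworkSpec()
    base_seed: int = 0
    dt: float = 0.05
    description: str = ""

    def with_overrides(self, n_trials: int | None = None,
                       base_seed: int | None = None) -> "RunConfig":
        from dataclasses import replace
        kwargs = {}
        if n_trials is not None:
            kwargs["n_trials"] = n_trials
        if base_seed is not None:
            kwargs["base_seed"] = base_seed
        return replace(self, **kwargs) if kwargs else self


PRESETS: dict[str, RunConfig] = {
    "smoke": RunConfig(
        name="smoke",
        conditions=tuple(_grid(50.0, (0.0, 16.0), (100.0,), (False, True))),
        n_trials=5,
        network=NetworkSpec(N=200, scale_recurrent=True),
        description="200-neuron network, 4 conditions x 5 trials; "
                    "exercises all paths in well under a minute.",
    ),
    "bistable": RunConfig(
        name="bistable",
        conditions=tuple(_grid(15.0, (0.0, 7.0, 16.0), (300.0, 500.0),
                               (False, True))),
        n_trials=100,
        decision=DecisionParams(theta=24.0),
        description="lambda = 15 Hz (bistable regime), decision "
                    "threshold 24 Hz; unimodal decision times.",
    ),
    "multistable": RunConfig(
        name="multistable",
        conditions=tuple(_grid(50.0, (0.0, 4.0, 8.0, 16.0), (300.0, 500.0),
                               (False, True))),
        n_trials=100,
        decision=DecisionParams(theta=28.0),
        description="lambda = 50 Hz (multistable regime), decision "
                    "threshold 28 Hz; bimodal decision times.",
    ),
    "full-psychophysics": RunConfig(
        name="full-psychophysics",
        conditions=tuple(_grid(50.0, DLAMBDAS, DURATIONS, (False, True))),
        n_trials=1000,
        description="Full psychophysics grid at publication scale "
                    "(1000 trials per condition).",
    ),
    "full-dt": RunConfig(
        name="full-dt",
        conditions=tuple(_grid(50.0, (7.0,), (300.0, 500.0), (False, True))),
        n_trials=1000,
        description="Decision-time distributions, delta_lambda = 7 Hz.",
    ),
}


def get_preset(name: str) -> RunConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(sorted(PRESETS))}") from None


def list_presets() -> list[tuple[str, str]]:
    return [(cfg.name, cfg.description) for cfg in PRESETS.values()]
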