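"""Experiment presets for the standard mixing scenarios.

The mixing experiments compare 0% (baseline), 10%, 30%, 50% and 100%
SRAC agents on the two network types under otherwise identical default
settings; each preset differs from the defaults only in the documented
keys.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulation import SimulationConfig

__all__ = ["ExperimentPreset", "PRESETS", "get_preset", "SWEEP_FRACTIONS"]

#: SRAC fractions of the standard mixing sweep.
SWEEP_FRACTIONS = (0.0, 0.1, 0.3, 0.5, 1.0)


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    overrides: dict
    description: str

    def config(self, **extra) -> SimulationConfig:
        merged = {**self.overrides, **extra}
        return SimulationConfig(**merged).validate()


def _mixing_presets() -> dict[str, ExperimentPreset]:
    presets = {}
    for net, tag in (("cellular_automata", "ca"), ("small_world", "sw")):
        presets[f"baseline_{tag}"] = ExperimentPreset(
            name=f"baseline_{tag}",
            overrides={"net_type": net, "srac_fraction": 0.0},
            description=f"0% SRAC agents (baseline) on the {net} network",
        )
        for pct in (10, 30, 50, 100):
            name = f"srac{pct}_{tag}"
            presets[name] = ExperimentPreset(
                name=name,
                overrides={"net_type": net, "srac_fraction": pct / 100.0},
                description=f"{pct}% SRAC agents on the {net} network",
            )
    return presets


PRESETS: dict[str, ExperimentPreset] = _mixing_presets()


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
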