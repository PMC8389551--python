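"""Run configuration: defaults, YAML loading, strict validation.

Every default reproduces the model's reference parameters (membrane range
[-70, -54.4] mV, under-threshold decay 0.02 /ms, maximum spike latency
25 ms, plasticity amplitude 0.0005 with a 12.5 ms window, the anatomical
population sizes and in-degrees at 100 pA / 1 ms, the 300-trial detector
protocol and the 500-presentation / 37-orientation column protocol).
Unknown keys are rejected with the offending path named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cortex import ColumnSpec
from .engine import AdExParams
from .mnsd import MNSDSpec
from .neuron import NeuronParams
from .plasticity import PlasticityParams
from .retina import (
    DEFAULT_CONTRAST_THRESHOLD,
    DEFAULT_T0,
    DEFAULT_WINDOW,
    GaborParams,
)

__all__ = ["RunConfig", "load_config", "default_config_dict", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


DEFAULTS: dict = {
    "run": {
        "seed": 0,
        "outdir": "out",
        "dt": 0.1,            # ms simulation step
    },
    "neuron": {
        "v_rest": NeuronParams.v_rest,
        "v_th": NeuronParams.v_th,
        "decay_rate": NeuronParams.decay_rate,
        "sl_max": NeuronParams.sl_max,
        "syn_tau": NeuronParams.syn_tau,
        "refractory": NeuronParams.refractory,
        "latency_shape": NeuronParams.latency_shape,
        "c_m": NeuronParams.c_m,
    },
    "plasticity": {
        "lam": PlasticityParams.lam,          # 'lambda': max change per pulse
        "tau": PlasticityParams.tau,          # plasticity window, ms
        "enabled": True,                      # the stdp_mod switch
        "sign_convention": PlasticityParams.sign_convention,
    },
    "mnsd": {
        "n_branches": MNSDSpec.n_branches,
        "generator_times": list(MNSDSpec.generator_times),
        "input_weight": MNSDSpec.input_weight,
        "modulator_weight": MNSDSpec.modulator_weight,
        "target_weight": None,
        "sync_window": MNSDSpec.sync_window,
        "delay": MNSDSpec.delay,
        "wiring": MNSDSpec.wiring,
        "n_trials": 300,
    },
    "retina": {
        "t0": DEFAULT_T0,
        "window": DEFAULT_WINDOW,
        "contrast_threshold": DEFAULT_CONTRAST_THRESHOLD,
        "spatial_frequency": GaborParams.spatial_frequency,
        "phase": GaborParams.phase,
        "envelope_sigma": GaborParams.envelope_sigma,
        "contrast": GaborParams.contrast,
    },
    "column": {
        "weight": ColumnSpec.weight,
        "delay": ColumnSpec.delay,
        "input_weight": ColumnSpec.input_weight,
        "modulator_weight": ColumnSpec.modulator_weight,
        "target_weight": None,
        "sync_window": ColumnSpec.sync_window,
        "ss_noise_rate": ColumnSpec.ss_noise_rate,
        "ss_noise_weight": ColumnSpec.ss_noise_weight,
        "bg_noise_rate": ColumnSpec.bg_noise_rate,
        "bg_noise_weight": ColumnSpec.bg_noise_weight,
        "bg_bias": ColumnSpec.bg_bias,
        "deep_bias": ColumnSpec.deep_bias,
        "n_presentations": 500,
    },
    "analysis": {
        "rate_window": [50.0, 100.0],
        "sweep_step": 5.0,
        "sweep_trials": 30,
        "mua_window": [0.0, 110.0],
        "mua_bin": 10.0,
        "similarity_window": [25.0, 100.0],
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, value in defaults.items():
        if isinstance(value, dict):
            sub = override.get(key, {})
            if sub is None:
                sub = {}
            if not isinstance(sub, dict):
                raise ConfigError(f"section {path}{key} must be a mapping")
            out[key] = _merge(value, sub, f"{path}{key}.")
        else:
            out[key] = override.get(key, value)
    unknown = set(override) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(path + k for k in unknown)}")
    return out


@dataclass
class RunConfig:
    """Validated configuration with typed accessors for every module."""

    data: dict = field(default_factory=lambda: _merge(DEFAULTS, {}))

    @property
    def seed(self) -> int:
        return int(self.data["run"]["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.data["run"]["outdir"])

    def neuron_params(self) -> NeuronParams:
        return NeuronParams(**self.data["neuron"])

    def plasticity_params(self, stimulators=frozenset()) -> PlasticityParams:
        d = self.data["plasticity"]
        return PlasticityParams(
            lam=d["lam"],
            tau=d["tau"],
            stimulators=frozenset(stimulators),
            enabled=bool(d["enabled"]),
            sign_convention=d["sign_convention"],
        )

    def mnsd_spec(self) -> MNSDSpec:
        d = dict(self.data["mnsd"])
        d.pop("n_trials")
        d["generator_times"] = tuple(d["generator_times"])
        return MNSDSpec(**d)

    def gabor_params(self, orientation: float = 0.0) -> GaborParams:
        d = self.data["retina"]
        return GaborParams(
            orientation=orientation,
            spatial_frequency=d["spatial_frequency"],
            phase=d["phase"],
            envelope_sigma=d["envelope_sigma"],
            contrast=d["contrast"],
        )

    def column_spec(self, preferred_orientation: float = 0.0) -> ColumnSpec:
        d = dict(self.data["column"])
        d.pop("n_presentations")
        return ColumnSpec(preferred_orientation=preferred_orientation, **d)

    def adex_params(self) -> AdExParams:
        return AdExParams()


def default_config_dict() -> dict:
    return _merge(DEFAULTS, {})


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML configuration; None loads pure defaults."""
    data: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    if overrides:
        for key, value in overrides.items():
            section, _, leaf = key.partition(".")
            data.setdefault(section, {})[leaf] = value
    return RunConfig(_merge(DEFAULTS, data))
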