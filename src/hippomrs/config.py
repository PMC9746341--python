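"""Pipeline configuration: a single mapping with per-stage sections.

The configuration is deliberately flat and explicit — every stage reads its
parameters from here, CLI flags override file values, and unknown keys are
rejected by name so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


_SECTION_KEYS = {
    "acquisition": {
        "tr_ms", "te_ms", "spectral_width_hz", "n_points", "n_averages",
        "voxel_dims_mm", "larmor_mhz",
    },
    "phantom": {"grid_shape", "voxel_size_mm", "hippocampus_ellipsoids", "seed"},
    "spectrum": {"noise_sd", "linewidth_hz", "concentrations_mmol_kg"},
    "cohort": {"n_rd", "n_nrd", "n_hc", "age_onset_group_shift"},
    "quant": {"water_concentration", "tr_ms", "te_ms"},
    "qc": {"snr", "fwhm_hz", "crlb_pct"},
    "search": {"step_mm", "search_rotations", "rotation_step_deg", "rotation_range_deg"},
    "stats": {"week_pair", "label_week", "p_enter", "p_remove", "force_covariates"},
}
_TOP_KEYS = set(_SECTION_KEYS) | {"seed", "validation_seed"}


@dataclass
class PipelineConfig:
    seed: int = 0
    validation_seed: int | None = None  # derived from seed when unset
    acquisition: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    spectrum: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    quant: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    search: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, allowed in _SECTION_KEYS.items():
            values = getattr(self, section)
            if not isinstance(values, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            unknown = set(values) - allowed
            if unknown:
                raise ConfigError(
                    f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}"
                )
        if self.validation_seed is None:
            self.validation_seed = (int(self.seed) + 104729) % (2**31)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "validation_seed": self.validation_seed,
            **{s: dict(getattr(self, s)) for s in _SECTION_KEYS},
        }


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return PipelineConfig.from_dict(raw)
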