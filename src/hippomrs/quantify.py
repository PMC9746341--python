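"""Water-referenced absolute metabolite quantification with CSF correction.

The internal-water reference method converts a fitted metabolite amplitude
``S_M`` and water amplitude ``S_W`` into an absolute concentration::

    C_M = (S_M / S_W) * C_W * (n_W / n_M) * (f_W^T1 / f_M^T1) * (f_W^T2 / f_M^T2)

with ``C_W`` the molal water concentration (55.51 mol/kg), ``n`` the number
of chemically equivalent protons contributing to each signal, and the
relaxation attenuation factors

    f^T1 = 1 - exp(-TR / T1)        (saturation over the repetition time)
    f^T2 = exp(-TE / T2)            (decay over the echo time)

Cerebrospinal fluid carries essentially no metabolite signal, so the voxel's
CSF fraction dilutes the apparent concentration; the partial-volume
correction rescales it::

    C_cor = C_raw * V_total / (V_total - V_CSF)

Concentrations are reported in mmol/kg wet weight.  The left and right
hippocampal voxels are averaged when both pass quality control; a single
passing side is used alone and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "RelaxationEntry",
    "QuantConfig",
    "ConcentrationRecord",
    "BilateralResult",
    "InvalidReferenceError",
    "DegenerateVoxelError",
    "QuantConfigError",
    "absolute_concentration",
    "csf_correct",
    "bilateral_mean",
    "DEFAULT_RELAXATION_3T",
    "DEFAULT_PROTON_COUNTS",
]


class InvalidReferenceError(ValueError):
    pass


class DegenerateVoxelError(ValueError):
    pass


class QuantConfigError(KeyError):
    pass


@dataclass(frozen=True)
class RelaxationEntry:
    """Longitudinal / transverse relaxation times of one species (ms)."""

    species: str
    t1_ms: float
    t2_ms: float

    def __post_init__(self) -> None:
        if not (self.t1_ms >= self.t2_ms > 0):
            raise ValueError(f"{self.species}: require T1 >= T2 > 0")


#: 3 T relaxation constants (ms). Literature consensus values for brain
#: tissue; editable configuration, not code constants.
DEFAULT_RELAXATION_3T = {
    "water": RelaxationEntry("water", 1100.0, 80.0),
    "naa": RelaxationEntry("naa", 1400.0, 250.0),
    "tcho": RelaxationEntry("tcho", 1150.0, 220.0),
    "tcr": RelaxationEntry("tcr", 1240.0, 160.0),
    "glx": RelaxationEntry("glx", 1200.0, 180.0),
    "ins": RelaxationEntry("ins", 1100.0, 200.0),
}

#: Fit-display peak names -> canonical species keys.
_SPECIES_ALIASES = {"cho": "tcho", "cr": "tcr", "water": "water"}


def canonical_species(name: str) -> str:
    """Normalise a peak / species name ("Cho", "tCho", "naa", ...) to the
    canonical lower-case key used by the quantification tables."""
    key = name.strip().lower()
    return _SPECIES_ALIASES.get(key, key)


#: Protons contributing to the quantified resonance of each species.
DEFAULT_PROTON_COUNTS = {
    "water": 2,
    "naa": 3,   # CH3 singlet at 2.01 ppm
    "tcho": 9,  # N(CH3)3 at 3.20 ppm
    "tcr": 3,   # CH3 at 3.03 ppm
    "ins": 6,   # ring protons near 3.56 ppm
    "glx": 2,   # composite CH2 resonance near 2.35 ppm
}


@dataclass(frozen=True)
class QuantConfig:
    """Quantification settings: water molality, proton counts, relaxation
    table and sequence timings."""

    water_concentration: float = 55.51  # mol/kg
    proton_counts: dict = field(default_factory=lambda: dict(DEFAULT_PROTON_COUNTS))
    relaxation: dict = field(default_factory=lambda: dict(DEFAULT_RELAXATION_3T))
    tr_ms: float = 2000.0
    te_ms: float = 35.0

    def __post_init__(self) -> None:
        if self.water_concentration <= 0:
            raise ValueError("water_concentration must be positive")
        if any(n < 1 for n in self.proton_counts.values()):
            raise ValueError("proton counts must be >= 1")

    def relaxation_factors(self, species: str) -> tuple[float, float]:
        """(f^T1, f^T2) for one species at this TR/TE."""
        species = canonical_species(species)
        if species not in self.relaxation:
            raise QuantConfigError(f"no relaxation entry for species {species!r}")
        entry = self.relaxation[species]
        f_t1 = 1.0 - math.exp(-self.tr_ms / entry.t1_ms)
        f_t2 = math.exp(-self.te_ms / entry.t2_ms)
        return f_t1, f_t2


@dataclass
class ConcentrationRecord:
    """Quantified voxel: raw and CSF-corrected concentrations (mmol/kg)."""

    concentrations_raw: dict
    concentrations_corrected: dict
    v_total_mm3: float
    v_csf_mm3: float
    side: str
    week: int
    qc_pass: bool = True


@dataclass
class BilateralResult:
    """Per-metabolite bilateral mean with QC provenance."""

    concentrations: dict
    sides_used: tuple
    single_side: bool
    reason: str = ""

    @property
    def missing(self) -> bool:
        return len(self.sides_used) == 0


def absolute_concentration(
    s_metabolite: float, s_water: float, species: str, cfg: QuantConfig | None = None
) -> float:
    """Water-referenced absolute concentration of ``species`` in mmol/kg."""
    cfg = cfg if cfg is not None else QuantConfig()
    if s_water <= 0:
        raise InvalidReferenceError("water reference amplitude must be positive")
    species = canonical_species(species)
    if species not in cfg.proton_counts:
        raise QuantConfigError(f"no proton count for species {species!r}")
    f_t1_w, f_t2_w = cfg.relaxation_factors("water")
    f_t1_m, f_t2_m = cfg.relaxation_factors(species)
    n_w = cfg.proton_counts["water"]
    n_m = cfg.proton_counts[species]
    c_mol_kg = (
        (s_metabolite / s_water)
        * cfg.water_concentration
        * (n_w / n_m)
        * (f_t1_w / f_t1_m)
        * (f_t2_w / f_t2_m)
    )
    return 1000.0 * c_mol_kg


def csf_correct(c_raw: float, v_total: float, v_csf: float) -> float:
    """Rescale for the metabolite-free CSF fraction of the voxel."""
    if not 0 <= v_csf < v_total:
        raise DegenerateVoxelError(
            f"require 0 <= V_CSF < V_total, got V_CSF={v_csf}, V_total={v_total}"
        )
    # ratio first: keeps the V_CSF = 0 case an exact identity
    return c_raw * (v_total / (v_total - v_csf))


def bilateral_mean(
    left: ConcentrationRecord | None, right: ConcentrationRecord | None
) -> BilateralResult:
    """Arithmetic mean of the two hippocampal voxels' corrected
    concentrations; falls back to the single QC-passing side with a flag."""
    usable = {}
    if left is not None and left.qc_pass:
        usable["left"] = left
    if right is not None and right.qc_pass:
        usable["right"] = right
    if not usable:
        return BilateralResult(
            concentrations={},
            sides_used=(),
            single_side=False,
            reason="both sides failed QC",
        )
    if len(usable) == 1:
        side, rec = next(iter(usable.items()))
        return BilateralResult(
            concentrations=dict(rec.concentrations_corrected),
            sides_used=(side,),
            single_side=True,
            reason=f"only {side} side passed QC",
        )
    keys = set(usable["left"].concentrations_corrected) & set(
        usable["right"].concentrations_corrected
    )
    means = {
        k: 0.5
        * (
            usable["left"].concentrations_corrected[k]
            + usable["right"].concentrations_corrected[k]
        )
        for k in keys
    }
    return BilateralResult(concentrations=means, sides_used=("left", "right"), single_side=False)
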