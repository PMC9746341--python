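"""Synthetic inputs for the hippocampal MRS pipeline.

Three generators cover everything the downstream stages consume:

* :func:`generate_phantom_volume` — a brain-like integer label volume (CSF /
  GM / WM shells) with two ellipsoidal hippocampi, standing in for an FSL
  segmentation in subject space.
* :func:`generate_fid` — water-suppressed and water-reference free induction
  decays for the PRESS protocol (TE 35 ms, TR 2 s, 5 kHz spectral width,
  2048 points, 128 averages), built from Lorentzian components with circular
  complex Gaussian noise, so the fitting stage has exact ground truth.
* :func:`generate_cohort` — a two-group (RD / n-RD) plus healthy-control
  longitudinal table of weekly HDRS-17 scores and hippocampal metabolite
  concentrations over a 7-visit, 6-week follow-up.  The default trajectories
  emulate the qualitative treatment-response pattern: tCho rises from week 2
  in both patient groups, NAA rises earlier/stronger in the non-refractory
  group, Glx rises from week 3, while Ins and tCr stay flat.  A latent
  per-subject response propensity couples the HDRS decline to the metabolite
  rises, which is what makes short-term metabolite changes predictive of the
  week-6 response label.

All randomness flows through explicit integer seeds; there is no hidden
global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectral import FidSignal, lorentzian_fid
from .volumes import LABELS, LabelVolume

__all__ = [
    "AcquisitionParams",
    "PhantomSpec",
    "GroundTruthSpectrum",
    "MetaboliteTrajectory",
    "CohortSpec",
    "InvalidSpecError",
    "generate_phantom_volume",
    "jittered_phantom_spec",
    "generate_fid",
    "generate_cohort",
    "write_fid",
    "read_fid",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
    "METABOLITES",
]

METABOLITES = ("naa", "tcho", "tcr", "glx", "ins")

#: Cohort CSV schema (fixed column order).
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "week",
    "hdrs",
    "age",
    "gender",
    "age_onset",
    "duration",
    "naa",
    "tcho",
    "tcr",
    "glx",
    "ins",
]


class InvalidSpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# acquisition


@dataclass(frozen=True)
class AcquisitionParams:
    """PRESS single-voxel acquisition settings."""

    tr_ms: float = 2000.0
    te_ms: float = 35.0
    spectral_width_hz: float = 5000.0
    n_points: int = 2048
    n_averages: int = 128
    voxel_dims_mm: tuple = (10.0, 10.0, 15.0)
    larmor_mhz: float = 123.25

    def __post_init__(self) -> None:
        if not (self.tr_ms > self.te_ms > 0):
            raise InvalidSpecError("require tr_ms > te_ms > 0")
        if self.n_points < 2:
            raise InvalidSpecError("n_points must be >= 2")
        if self.spectral_width_hz <= 0:
            raise InvalidSpecError("spectral_width_hz must be positive")
        if any(d <= 0 for d in self.voxel_dims_mm):
            raise InvalidSpecError("voxel dimensions must be positive")
        if self.n_averages < 1:
            raise InvalidSpecError("n_averages must be >= 1")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def duration_s(self) -> float:
        return self.n_points * self.dwell_s

    def to_dict(self) -> dict:
        return {
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "spectral_width_hz": self.spectral_width_hz,
            "n_points": self.n_points,
            "n_averages": self.n_averages,
            "voxel_dims_mm": list(self.voxel_dims_mm),
            "larmor_mhz": self.larmor_mhz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        d = dict(d)
        d["voxel_dims_mm"] = tuple(d.get("voxel_dims_mm", (10.0, 10.0, 15.0)))
        return cls(**d)


# ---------------------------------------------------------------------------
# phantom label volume


@dataclass(frozen=True)
class PhantomSpec:
    """Brain-like phantom: concentric CSF/GM/WM shells inside an ellipsoidal
    head, plus two disjoint hippocampal ellipsoids given as
    ``(center_mm, semi_axes_mm)`` in world coordinates (grid centre = origin)."""

    grid_shape: tuple = (90, 110, 90)
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    hippocampus_ellipsoids: tuple = (
        ((-22.0, -5.0, -8.0), (8.0, 8.0, 10.0)),
        ((22.0, -5.0, -8.0), (8.0, 8.0, 10.0)),
    )
    tissue_rules: dict = field(default_factory=lambda: dict(LABELS))
    seed: int = 0

    def affine(self) -> np.ndarray:
        vs = np.asarray(self.voxel_size_mm, dtype=float)
        shape = np.asarray(self.grid_shape, dtype=float)
        aff = np.eye(4)
        aff[:3, :3] = np.diag(vs)
        aff[:3, 3] = -(shape - 1) / 2.0 * vs
        return aff

    def validate(self) -> None:
        if any(s < 1 for s in self.grid_shape):
            raise InvalidSpecError("grid_shape components must be >= 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidSpecError("voxel_size_mm components must be positive")
        if len(self.hippocampus_ellipsoids) != 2:
            raise InvalidSpecError("exactly two hippocampal ellipsoids required")
        half_extent = (
            np.asarray(self.grid_shape) * np.asarray(self.voxel_size_mm) / 2.0
        )
        for center, semi in self.hippocampus_ellipsoids:
            center = np.asarray(center, dtype=float)
            semi = np.asarray(semi, dtype=float)
            if np.any(semi < 0):
                raise InvalidSpecError("ellipsoid semi-axes must be non-negative")
            if np.any(np.abs(center) + semi > half_extent):
                raise InvalidSpecError("hippocampal ellipsoid extends outside the grid")
        (c1, s1), (c2, s2) = self.hippocampus_ellipsoids
        gap = np.linalg.norm(np.asarray(c1, float) - np.asarray(c2, float))
        if gap < min(np.max(np.asarray(s1, float)), np.max(np.asarray(s2, float))):
            raise InvalidSpecError("left and right hippocampal ellipsoids overlap")


def _inside_ellipsoid(coords: np.ndarray, center, semi_axes) -> np.ndarray:
    center = np.asarray(center, dtype=float)
    semi = np.asarray(semi_axes, dtype=float)
    if np.any(semi <= 0):
        return np.zeros(coords.shape[:-1], dtype=bool)
    q = (coords - center) / semi
    return (q**2).sum(axis=-1) <= 1.0


def generate_phantom_volume(spec: PhantomSpec) -> LabelVolume:
    """Deterministic label volume: WM core, GM shell, CSF rim, hippocampi."""
    spec.validate()
    aff = spec.affine()
    shape = spec.grid_shape
    idx = np.stack(
        np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1
    ).astype(float)
    coords = idx @ aff[:3, :3].T + aff[:3, 3]

    rules = spec.tissue_rules
    half_extent = np.asarray(shape) * np.asarray(spec.voxel_size_mm) / 2.0
    brain_semi = 0.92 * half_extent
    data = np.full(shape, rules["background"], dtype=np.int16)
    data[_inside_ellipsoid(coords, (0, 0, 0), brain_semi)] = rules["CSF"]
    data[_inside_ellipsoid(coords, (0, 0, 0), 0.90 * brain_semi)] = rules["GM"]
    data[_inside_ellipsoid(coords, (0, 0, 0), 0.72 * brain_semi)] = rules["WM"]
    (c_left, s_left), (c_right, s_right) = spec.hippocampus_ellipsoids
    data[_inside_ellipsoid(coords, c_left, s_left)] = rules["hippoL"]
    data[_inside_ellipsoid(coords, c_right, s_right)] = rules["hippoR"]
    return LabelVolume(data, aff)


def jittered_phantom_spec(
    spec: PhantomSpec, session_seed: int, jitter_mm: float = 0.6
) -> PhantomSpec:
    """Re-segmentation of the same anatomy at a follow-up session: the
    hippocampal ellipsoid centres are perturbed by isotropic Gaussian jitter
    (segmentation + repositioning variability)."""
    rng = np.random.default_rng(session_seed)
    jittered = tuple(
        (tuple(np.asarray(c, float) + rng.normal(0.0, jitter_mm, 3)), tuple(s))
        for c, s in spec.hippocampus_ellipsoids
    )
    return replace(spec, hippocampus_ellipsoids=jittered, seed=session_seed)


# ---------------------------------------------------------------------------
# ground-truth spectra and FIDs


@dataclass(frozen=True)
class GroundTruthSpectrum:
    """Known Lorentzian composition of a simulated voxel.

    Amplitudes are in arbitrary units, proportional to concentration x
    number of contributing protons x relaxation attenuation.  The default
    amplitudes correspond to typical hippocampal concentrations through
    :meth:`from_concentrations`.
    """

    amplitudes: dict = field(
        default_factory=lambda: {
            "naa": 25.0, "tcho": 13.5, "tcr": 20.0, "glx": 16.0, "ins": 30.0
        }
    )
    shifts_ppm: dict = field(
        default_factory=lambda: {
            "naa": 2.01, "tcho": 3.20, "tcr": 3.03, "glx": 2.35, "ins": 3.56
        }
    )
    linewidths_hz: dict = field(
        default_factory=lambda: {m: 5.0 for m in METABOLITES}
    )
    water_amplitude: float = 25000.0
    water_shift_ppm: float = 4.70
    water_linewidth_hz: float = 6.0
    water_phase_rad: float = 0.0
    noise_sd: float = 80.0
    transmitter_ppm: float = 4.70

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes.values()):
            raise InvalidSpecError("amplitudes must be non-negative")
        if any(lw <= 0 for lw in self.linewidths_hz.values()):
            raise InvalidSpecError("linewidths must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")

    @property
    def names(self) -> tuple:
        return tuple(self.amplitudes)

    @classmethod
    def from_concentrations(
        cls,
        concentrations_mmol_kg: dict,
        quant_config=None,
        scale: float = 1500.0,
        **kwargs,
    ) -> "GroundTruthSpectrum":
        """Build amplitudes that encode known concentrations through the
        water-referenced quantification formula, so the full pipeline
        (fit -> absolute quantification) can be checked for exact recovery.
        """
        from .quantify import QuantConfig

        cfg = quant_config if quant_config is not None else QuantConfig()
        amps = {}
        for name, conc in concentrations_mmol_kg.items():
            f1, f2 = cfg.relaxation_factors(name)
            amps[name] = scale * (conc / 1000.0) * cfg.proton_counts[name] * f1 * f2
        f1w, f2w = cfg.relaxation_factors("water")
        water_amp = scale * cfg.water_concentration * cfg.proton_counts["water"] * f1w * f2w
        return cls(amplitudes=amps, water_amplitude=water_amp, **kwargs)


def generate_fid(
    truth: GroundTruthSpectrum, acq: AcquisitionParams, seed: int = 0
) -> tuple[FidSignal, FidSignal]:
    """Simulate one (water-suppressed, water-reference) FID pair.

    The suppressed signal is the sum of the five metabolite Lorentzians; the
    reference contains a single water Lorentzian (with its own phase).  Both
    carry circular complex Gaussian noise of per-channel SD
    ``noise_sd / sqrt(n_averages)``, the effective noise after averaging.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(acq.n_points) * acq.dwell_s
    eff_sd = truth.noise_sd / np.sqrt(acq.n_averages)

    def _noise() -> np.ndarray:
        if eff_sd == 0:
            return np.zeros(acq.n_points, dtype=complex)
        return rng.normal(0.0, eff_sd, acq.n_points) + 1j * rng.normal(
            0.0, eff_sd, acq.n_points
        )

    names = truth.names
    amps = np.array([truth.amplitudes[m] for m in names])
    freqs = np.array(
        [(truth.shifts_ppm[m] - truth.transmitter_ppm) * acq.larmor_mhz for m in names]
    )
    # per-peak linewidths are allowed at generation time even though the
    # fitting model ties them; defaults keep them equal
    sig = np.zeros(acq.n_points, dtype=complex)
    for k, m in enumerate(names):
        sig += lorentzian_fid(t, amps[k], freqs[k], truth.linewidths_hz[m])
    suppressed = FidSignal(
        sig + _noise(),
        acq.spectral_width_hz,
        transmitter_ppm=truth.transmitter_ppm,
        larmor_mhz=acq.larmor_mhz,
        n_averages=acq.n_averages,
    )
    f_water = (truth.water_shift_ppm - truth.transmitter_ppm) * acq.larmor_mhz
    water_sig = lorentzian_fid(
        t, truth.water_amplitude, f_water, truth.water_linewidth_hz, truth.water_phase_rad
    )
    water = FidSignal(
        water_sig + _noise(),
        acq.spectral_width_hz,
        transmitter_ppm=truth.transmitter_ppm,
        larmor_mhz=acq.larmor_mhz,
        n_averages=acq.n_averages,
    )
    return suppressed, water


# ---------------------------------------------------------------------------
# longitudinal cohort


@dataclass(frozen=True)
class MetaboliteTrajectory:
    """Per-metabolite generative settings (concentrations in mmol/kg).

    ``deltas`` maps group -> per-week mean change from baseline;
    ``coupling`` scales the contribution of the latent response propensity
    (per SD) to the metabolite change, on the shared week ramp.
    """

    baseline: float
    sd_between: float
    sd_within: float
    deltas: dict
    coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_between < 0 or self.sd_within < 0:
            raise InvalidSpecError("SDs must be non-negative")


def _default_metabolites() -> dict:
    flat = [0.0] * 7
    return {
        "naa": MetaboliteTrajectory(
            8.2, 0.80, 0.35,
            {"RD": [0, 0, 0.05, 0.35, 0.55, 0.65, 0.70],
             "n-RD": [0, 0.10, 0.70, 1.20, 1.35, 1.45, 1.50],
             "HC": flat},
            coupling=0.30,
        ),
        "tcho": MetaboliteTrajectory(
            1.55, 0.15, 0.08,
            {"RD": [0, 0.02, 0.12, 0.20, 0.26, 0.30, 0.33],
             "n-RD": [0, 0.04, 0.22, 0.38, 0.48, 0.55, 0.60],
             "HC": flat},
            coupling=0.10,
        ),
        "tcr": MetaboliteTrajectory(
            6.9, 0.70, 0.35, {"RD": flat, "n-RD": flat, "HC": flat}
        ),
        "glx": MetaboliteTrajectory(
            8.8, 1.00, 0.80,
            {"RD": [0, 0, 0.10, 0.60, 0.90, 1.05, 1.10],
             "n-RD": [0, 0.05, 0.30, 1.50, 1.90, 2.10, 2.20],
             "HC": flat},
            coupling=0.30,
        ),
        "ins": MetaboliteTrajectory(
            5.4, 0.60, 0.30, {"RD": flat, "n-RD": flat, "HC": flat}
        ),
    }


def _default_hdrs() -> dict:
    return {
        "RD": [25.2, 24.6, 23.9, 22.8, 21.3, 19.8, 18.3],
        "n-RD": [24.6, 23.2, 21.2, 17.8, 14.0, 10.5, 7.6],
        "HC": [5.5] * 7,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for the longitudinal RD / n-RD / HC cohort."""

    n_rd: int = 26
    n_nrd: int = 41
    n_hc: int = 20
    weeks: tuple = (0, 1, 2, 3, 4, 5, 6)
    hdrs_means: dict = field(default_factory=_default_hdrs)
    hdrs_baseline_sd: float = 4.0
    hdrs_visit_sd: float = 2.0
    hdrs_delay_sd_weeks: float = 1.5
    reduction_sd: float = 0.12
    metabolites: dict = field(default_factory=_default_metabolites)
    ramp: tuple = (0.0, 0.15, 0.40, 0.70, 0.85, 0.95, 1.0)
    age_mean: float = 30.0
    age_sd: float = 8.0
    female_prob: float = 0.58
    age_onset_mean: float = 23.6
    age_onset_sd: float = 4.0
    duration_mean: float = 6.9
    duration_sd: float = 3.3
    age_onset_group_shift: float = 0.0  # added to RD onset age (knob, default off)
    seed: int = 0

    def validate(self) -> None:
        if len(self.weeks) == 0:
            raise InvalidSpecError("weeks list must not be empty")
        if self.n_rd < 2 or self.n_nrd < 2:
            raise InvalidSpecError("patient group sizes must be >= 2")
        if self.n_hc < 0:
            raise InvalidSpecError("n_hc must be >= 0")
        if not 0 <= self.female_prob <= 1:
            raise InvalidSpecError("female_prob must lie in [0, 1]")
        for m, traj in self.metabolites.items():
            for g, d in traj.deltas.items():
                if len(d) < len(self.weeks):
                    raise InvalidSpecError(f"deltas for {m}/{g} shorter than weeks")
        for g, means in self.hdrs_means.items():
            if len(means) < len(self.weeks):
                raise InvalidSpecError(f"hdrs means for {g} shorter than weeks")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject per week, per the cohort CSV schema.

    Patients carry a latent response propensity ``eta ~ N(0, 1)``; their
    realised week-6 HDRS reduction is ``group mean reduction +
    reduction_sd * eta`` and the metabolite rises share the same ``eta``
    through each metabolite's coupling.  The onset of the clinical decline
    is subject-specific (a Gaussian delay of SD ``hdrs_delay_sd_weeks``
    applied to the group decline shape, renormalised to reach the full
    reduction by the final week): clinical response latency varies between
    patients, which is what makes the early HDRS change a weaker predictor
    of the final outcome than the early metabolite change.  The ``group``
    column is the generative group; the analysis-side response label is
    recomputed from the realised HDRS values by
    ``stats.response_classification``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    weeks = list(spec.weeks)
    nw = len(weeks)
    rows = []
    subject_counter = 0
    for group, n_subj in (("HC", spec.n_hc), ("RD", spec.n_rd), ("n-RD", spec.n_nrd)):
        means = np.asarray(spec.hdrs_means[group], dtype=float)[:nw]
        if group == "HC":
            shape = np.zeros(nw)
            mean_reduction = 0.0
        else:
            total_drop = means[0] - means[-1]
            shape = (means[0] - means) / total_drop if total_drop > 0 else np.zeros(nw)
            mean_reduction = total_drop / means[0] if means[0] > 0 else 0.0
        for _ in range(n_subj):
            subject_counter += 1
            sid = f"S{subject_counter:03d}"
            eta = rng.normal()
            reduction = float(
                np.clip(mean_reduction + spec.reduction_sd * eta, 0.0, 0.95)
            )
            baseline = max(rng.normal(means[0], spec.hdrs_baseline_sd), 1.0)
            # subject-specific response latency: shift the decline shape,
            # then rescale so the final-week reduction is still attained
            if group == "HC":
                subj_shape = shape
            else:
                delay = rng.normal(0.0, spec.hdrs_delay_sd_weeks)
                weeks_arr = np.asarray(weeks, dtype=float)
                subj_shape = np.interp(
                    weeks_arr - delay, weeks_arr, shape, left=0.0, right=shape[-1]
                )
                if subj_shape[-1] > 0:
                    subj_shape = subj_shape / subj_shape[-1]
            hdrs = np.clip(
                baseline * (1.0 - reduction * subj_shape)
                + rng.normal(0.0, spec.hdrs_visit_sd, nw),
                0.0,
                None,
            )
            age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18, 60))
            gender = int(rng.random() < spec.female_prob)  # 1 = female
            if group == "HC":
                age_onset = np.nan
                duration = np.nan
            else:
                shift = spec.age_onset_group_shift if group == "RD" else 0.0
                age_onset = float(
                    rng.normal(spec.age_onset_mean + shift, spec.age_onset_sd)
                )
                duration = float(
                    max(rng.normal(spec.duration_mean, spec.duration_sd), 0.5)
                )
            conc = {}
            for m, traj in spec.metabolites.items():
                base_i = rng.normal(traj.baseline, traj.sd_between)
                deltas = np.asarray(traj.deltas[group], dtype=float)[:nw]
                ramp = np.asarray(spec.ramp, dtype=float)[:nw]
                coup = traj.coupling * eta * ramp if group != "HC" else 0.0
                conc[m] = np.clip(
                    base_i + deltas + coup + rng.normal(0.0, traj.sd_within, nw),
                    0.0,
                    None,
                )
            for j, w in enumerate(weeks):
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "week": w,
                        "hdrs": float(hdrs[j]),
                        "age": age,
                        "gender": gender,
                        "age_onset": age_onset,
                        "duration": duration,
                        **{m: float(conc[m][j]) for m in spec.metabolites},
                    }
                )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# file formats


def write_fid(fid: FidSignal, path, acq: AcquisitionParams | None = None) -> None:
    """Two-column (real, imaginary) text file plus a JSON metadata sidecar."""
    path = str(path)
    np.savetxt(
        path,
        np.column_stack([fid.samples.real, fid.samples.imag]),
        fmt="%.10e",
        header="real imaginary",
    )
    meta = {
        "spectral_width_hz": fid.spectral_width_hz,
        "transmitter_ppm": fid.transmitter_ppm,
        "larmor_mhz": fid.larmor_mhz,
        "n_averages": fid.n_averages,
        "n_points": fid.n_points,
        "processing": list(fid.processing),
    }
    if acq is not None:
        meta["acquisition"] = acq.to_dict()
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_fid(path) -> FidSignal:
    path = str(path)
    arr = np.loadtxt(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    return FidSignal(
        arr[:, 0] + 1j * arr[:, 1],
        spectral_width_hz=meta["spectral_width_hz"],
        transmitter_ppm=meta.get("transmitter_ppm", 4.70),
        larmor_mhz=meta.get("larmor_mhz", 123.25),
        n_averages=meta.get("n_averages", 1),
        processing=list(meta.get("processing", [])),
    )


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COHORT_COLUMNS, float_format="%.6f")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df[COHORT_COLUMNS]
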