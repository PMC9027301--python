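"""In-silico CoCl₂ dose-response experiments.

Generates complete synthetic datasets — multifrequency impedance
timecourses, Mito-Stress OCR traces and an LDH plate — with the statistical
structure the analysis pipeline assumes, plus the ground-truth barrier
parameter traces every fit can be checked against.

The emulated experiment: retinal endothelial cells are seeded on a 96-well
ECIS array, attach (alpha rises with a sub-hour time constant, established
by ~2 h), form junctions (Rb starts rising ~5 h after seeding and plateaus
at 10-12 h), and are treated at t = 0 (44.8 h post-seeding) with CoCl₂ at
0/10/100/1000 µM.  Treatment collapses Rb to exactly zero dose-dependently
(within 1 h at 1000 µM, 10-15 h at 100 µM, 20-25 h at 10 µM), raises the
membrane capacitance Cm only at ≥100 µM (immediately at 1000 µM, with an
8-12 h delay at 100 µM), and leaves alpha untouched.  Mitochondrial basal
respiration is reduced at every dose while ATP-linked and maximal
respiration fall only at ≥100 µM; LDH release is unchanged (no
cytotoxicity).

Kinetic forms (saturating exponential for alpha, clipped logistic for the
Rb rise, smoothstep for the Rb collapse, gated sigmoid for the Cm rise) are
modeling choices calibrated to those landmark times; the real curves are
only known empirically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioenergetics import OCRTrace
from .impedance import (
    DEFAULT_ELECTRODE,
    BarrierParameters,
    ElectrodeParameters,
    FrequencyGrid,
    well_impedance,
)

__all__ = [
    "DoseEffect",
    "SyntheticConfig",
    "LDHPlate",
    "SyntheticExperiment",
    "simulate_barrier_kinetics",
    "simulate_experiment",
    "simulate_ocr",
    "simulate_ldh",
]


@dataclass(frozen=True)
class DoseEffect:
    """Per-dose treatment effect parameters.

    ``rb_time_to_zero_h``: hours post-treatment at which Rb reaches exactly
    zero (None = never).  ``cm_rise_uf``: amplitude of the membrane
    capacitance increase (µF/cm²), with sigmoidal onset at
    ``cm_onset_h`` ± ``cm_width_h``.  Alpha is never affected.
    """

    rb_time_to_zero_h: float | None = None
    cm_rise_uf: float = 0.0
    cm_onset_h: float = 0.0
    cm_width_h: float = 1.0


#: Dose-effect defaults: Rb collapse windows (≤1 h at 1000 µM, 10-15 h at
#: 100 µM, 20-25 h at 10 µM), immediate Cm rise at 1000 µM, delayed
#: (8-12 h) Cm rise at 100 µM, no Cm effect at ≤10 µM.
DEFAULT_DOSE_EFFECTS: dict[float, DoseEffect] = {
    0.0: DoseEffect(),
    10.0: DoseEffect(rb_time_to_zero_h=22.5),
    100.0: DoseEffect(rb_time_to_zero_h=12.5, cm_rise_uf=0.8,
                      cm_onset_h=8.5, cm_width_h=1.0),
    1000.0: DoseEffect(rb_time_to_zero_h=0.8, cm_rise_uf=0.9,
                       cm_onset_h=0.2, cm_width_h=0.15),
}

#: OCR phase table, pmol O₂/min (corrected values; raw plateaus are derived).
#: Basal falls at every dose; ATP-linked and maximal only at ≥100 µM.
DEFAULT_OCR_TABLE: dict[float, dict[str, float]] = {
    0.0: {"basal": 90.0, "atp_linked": 60.0, "maximal": 140.0, "non_mito": 10.0},
    10.0: {"basal": 76.0, "atp_linked": 60.0, "maximal": 140.0, "non_mito": 10.0},
    100.0: {"basal": 55.0, "atp_linked": 40.0, "maximal": 90.0, "non_mito": 10.0},
    1000.0: {"basal": 30.0, "atp_linked": 25.0, "maximal": 50.0, "non_mito": 10.0},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one in-silico experiment."""

    doses_um: tuple[float, ...] = (0.0, 10.0, 100.0, 1000.0)
    wells_per_group: int = 6
    cellfree_wells: int = 6
    seeding_to_treatment_h: float = 44.8
    followup_h: float = 25.0
    sample_interval_h: float = 0.25
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    electrode: ElectrodeParameters = DEFAULT_ELECTRODE
    # attachment / barrier-formation kinetics (hours since seeding)
    alpha_plateau: float = 8.0
    alpha_tau_h: float = 0.7
    cm_baseline_uf: float = 1.8
    rb_plateau: float = 4.0
    rb_onset_h: float = 5.0
    rb_mid_h: float = 8.0
    rb_rise_width_h: float = 0.9
    dose_effects: dict[float, DoseEffect] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_EFFECTS))
    # noise / replicate variability
    noise_fraction: float = 0.01       # multiplicative complex impedance noise
    well_variability: float = 0.03     # per-well lognormal sd on plateaus
    drift_per_h: float = 0.001         # sd of per-well linear relative drift
    ocr_table: dict[float, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OCR_TABLE.items()})
    ocr_noise_sd: float = 3.0          # pmol/min per measurement
    ldh_sample_mean: float = 0.18      # absorbance units
    ldh_sample_sd: float = 0.012
    ldh_spontaneous_mean: float = 0.15
    ldh_spontaneous_sd: float = 0.008
    ldh_maximum_mean: float = 1.20
    ldh_maximum_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seeding_to_treatment_h", "followup_h",
                     "sample_interval_h", "alpha_tau_h", "rb_rise_width_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for dose in self.doses_um:
            if dose not in self.dose_effects:
                raise ValueError(f"no dose effect configured for {dose} µM")


@dataclass(frozen=True)
class LDHPlate:
    """Absorbance readings of an LDH release plate."""

    samples: dict[float, tuple[float, ...]]   # dose µM -> treated wells
    spontaneous: tuple[float, ...]
    maximum: tuple[float, ...]


@dataclass
class SyntheticExperiment:
    """A complete simulated experiment with its ground truth.

    ``impedance``: tidy frame (time_h, well, group, frequency_hz,
    z_real_ohm, z_imag_ohm), times in hours relative to treatment.
    ``ground_truth``: per (well, time) true Rb/alpha/Cm.
    """

    impedance: pd.DataFrame
    ground_truth: pd.DataFrame
    ocr: list[OCRTrace]
    ldh: LDHPlate
    config: SyntheticConfig
    seed: int

    @property
    def cell_wells(self) -> list[str]:
        return sorted(self.ground_truth["well"].unique())

    @property
    def cellfree_wells(self) -> list[str]:
        return sorted(
            self.impedance.loc[self.impedance["group"] == "cellfree", "well"]
            .unique()
        )

    def wells_for_dose(self, dose_um: float) -> list[str]:
        gt = self.ground_truth
        return sorted(gt.loc[gt["dose_um"] == dose_um, "well"].unique())


def _smoothstep_down(s: np.ndarray) -> np.ndarray:
    """C1 monotone decrease from 1 at s=0 to exactly 0 at s>=1."""
    s = np.clip(s, 0.0, 1.0)
    return 1.0 - s * s * (3.0 - 2.0 * s)


def _kinetic_traces(t_since_seeding_h: np.ndarray, dose_um: float,
                    config: SyntheticConfig,
                    scales: tuple[float, float, float] = (1.0, 1.0, 1.0)):
    """Vectorized ground-truth (rb, alpha, cm) at times since seeding."""
    t = np.asarray(t_since_seeding_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since seeding must be >= 0")
    effect = config.dose_effects[dose_um]
    rb_scale, alpha_scale, cm_scale = scales

    alpha = config.alpha_plateau * alpha_scale * (1.0 - np.exp(-t / config.alpha_tau_h))

    # junction formation: clipped logistic, exactly zero before onset
    logistic = 1.0 / (1.0 + np.exp(-(t - config.rb_mid_h) / config.rb_rise_width_h))
    l_onset = 1.0 / (1.0 + np.exp(-(config.rb_onset_h - config.rb_mid_h)
                                  / config.rb_rise_width_h))
    form = np.clip((logistic - l_onset) / (1.0 - l_onset), 0.0, None)
    form = np.where(t < config.rb_onset_h, 0.0, form)

    tt = t - config.seeding_to_treatment_h  # hours post-treatment
    if effect.rb_time_to_zero_h is not None:
        decay = np.where(tt > 0,
                         _smoothstep_down(tt / effect.rb_time_to_zero_h), 1.0)
    else:
        decay = np.ones_like(t)
    rb = config.rb_plateau * rb_scale * form * decay

    cm = np.full_like(t, config.cm_baseline_uf * cm_scale)
    if effect.cm_rise_uf > 0:
        sig = 1.0 / (1.0 + np.exp(-(tt - effect.cm_onset_h) / effect.cm_width_h))
        sig0 = 1.0 / (1.0 + np.exp(effect.cm_onset_h / effect.cm_width_h))
        rise = np.clip((sig - sig0) / (1.0 - sig0), 0.0, None)
        cm = cm + np.where(tt > 0, effect.cm_rise_uf * rise, 0.0)
    return rb, alpha, cm


def simulate_barrier_kinetics(t_since_seeding_h: float, dose_um: float,
                              config: SyntheticConfig = SyntheticConfig()
                              ) -> BarrierParameters:
    """Ground-truth barrier parameters at one time for one dose group.

    ``t_since_seeding_h`` is hours since seeding (treatment occurs at
    ``config.seeding_to_treatment_h``).  At t = 0 the well is bare:
    Rb = 0, alpha = 0, Cm at baseline.
    """
    rb, alpha, cm = _kinetic_traces(np.asarray([t_since_seeding_h]),
                                    dose_um, config)
    return BarrierParameters(rb=float(rb[0]), alpha=float(alpha[0]),
                             cm=float(cm[0]))


def _time_grid(config: SyntheticConfig) -> np.ndarray:
    """Times relative to treatment; t = 0 is always on the grid."""
    dt = config.sample_interval_h
    pre = -np.arange(dt, config.seeding_to_treatment_h + 1e-9, dt)[::-1]
    post = np.arange(0.0, config.followup_h + 1e-9, dt)
    return np.concatenate([pre, post])


def simulate_experiment(config: SyntheticConfig = SyntheticConfig(),
                        seed: int | None = None) -> SyntheticExperiment:
    """Simulate the full ECIS + OCR + LDH experiment.

    Each cell well carries mild lognormal variability on its plateau
    parameters (biological replicates); every complex impedance is
    multiplied by ``1 + ε`` with ε complex Gaussian of scale
    ``config.noise_fraction``.  Identical (config, seed) pairs reproduce
    identical outputs.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng_imp, rng_ocr, rng_ldh = (np.random.default_rng(s) for s in ss.spawn(3))

    times_rel = _time_grid(config)
    t_seed = times_rel + config.seeding_to_treatment_h
    freqs = config.grid.as_array()
    electrode = config.electrode

    imp_rows: list[pd.DataFrame] = []
    gt_rows: list[pd.DataFrame] = []
    widx = 0

    def noisy(z: np.ndarray) -> np.ndarray:
        eps = (config.noise_fraction / np.sqrt(2.0)
               * (rng_imp.standard_normal(z.shape)
                  + 1j * rng_imp.standard_normal(z.shape)))
        return z * (1.0 + eps)

    for dose in config.doses_um:
        for _ in range(config.wells_per_group):
            widx += 1
            well = f"w{widx:02d}"
            scales = tuple(np.exp(rng_imp.normal(0.0, config.well_variability, 3)))
            rb, alpha, cm = _kinetic_traces(t_seed, dose, config, scales)
            # slow per-well biological drift (relative, linear in time from
            # treatment); keeps replicate traces from being identical after
            # normalization
            slopes = rng_imp.normal(0.0, config.drift_per_h, 3)
            rb = np.clip(rb * (1.0 + slopes[0] * times_rel), 0.0, None)
            alpha = np.clip(alpha * (1.0 + slopes[1] * times_rel), 0.0, None)
            cm = np.clip(cm * (1.0 + slopes[2] * times_rel), 1e-3, None)
            z = np.empty((t_seed.size, freqs.size), dtype=complex)
            for i in range(t_seed.size):
                barrier = BarrierParameters(rb=rb[i], alpha=alpha[i],
                                            cm=cm[i])
                z[i] = well_impedance(freqs, electrode, barrier)
            z = noisy(z)
            imp_rows.append(pd.DataFrame({
                "time_h": np.repeat(times_rel, freqs.size),
                "well": well,
                "group": f"cocl2_{dose:g}uM",
                "frequency_hz": np.tile(freqs, t_seed.size),
                "z_real_ohm": z.real.ravel(),
                "z_imag_ohm": z.imag.ravel(),
            }))
            gt_rows.append(pd.DataFrame({
                "time_h": times_rel, "well": well, "dose_um": dose,
                "rb": rb, "alpha": alpha, "cm": cm,
            }))

    z_free = well_impedance(freqs, electrode, None)
    for _ in range(config.cellfree_wells):
        widx += 1
        well = f"w{widx:02d}"
        z = noisy(np.tile(z_free, (t_seed.size, 1)))
        imp_rows.append(pd.DataFrame({
            "time_h": np.repeat(times_rel, freqs.size),
            "well": well,
            "group": "cellfree",
            "frequency_hz": np.tile(freqs, t_seed.size),
            "z_real_ohm": z.real.ravel(),
            "z_imag_ohm": z.imag.ravel(),
        }))

    impedance = pd.concat(imp_rows, ignore_index=True)
    ground_truth = pd.concat(gt_rows, ignore_index=True)
    ocr = simulate_ocr(config, rng=rng_ocr)
    ldh = simulate_ldh(config, rng=rng_ldh)
    return SyntheticExperiment(impedance=impedance, ground_truth=ground_truth,
                               ocr=ocr, ldh=ldh, config=config, seed=seed)


#: Measurement times (min) and injection schedule of the simulated
#: Mito-Stress run: three cycles per phase.
OCR_MEASUREMENT_TIMES_MIN = (3.0, 9.5, 16.0, 21.0, 27.5, 34.0,
                             39.0, 45.5, 52.0, 57.0, 63.5, 70.0)
OCR_INJECTIONS_MIN = {"oligomycin": 18.0, "fccp": 36.0,
                      "rotenone_antimycin": 54.0}


def simulate_ocr(config: SyntheticConfig = SyntheticConfig(),
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> list[OCRTrace]:
    """Mito-Stress OCR traces: one per well, three cycles per phase.

    Phase plateau means come from ``config.ocr_table`` (corrected metrics;
    raw plateaus derived by adding back the non-mitochondrial floor), with
    i.i.d. Gaussian measurement noise of sd ``config.ocr_noise_sd``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    traces: list[OCRTrace] = []
    times = np.asarray(OCR_MEASUREMENT_TIMES_MIN)
    for dose in config.doses_um:
        tab = config.ocr_table[dose]
        basal_raw = tab["basal"] + tab["non_mito"]
        post_oligo = basal_raw - tab["atp_linked"]
        maximal_raw = tab["maximal"] + tab["non_mito"]
        plateau = np.repeat([basal_raw, post_oligo, maximal_raw,
                             tab["non_mito"]], 3)
        for w in range(config.wells_per_group):
            values = plateau + rng.normal(0.0, config.ocr_noise_sd,
                                          plateau.size)
            traces.append(OCRTrace(
                times_min=tuple(times), ocr_pmol_min=tuple(values),
                injections=dict(OCR_INJECTIONS_MIN),
                well=f"ocr_{dose:g}uM_{w + 1}", dose_um=dose,
            ))
    return traces


def simulate_ldh(config: SyntheticConfig = SyntheticConfig(),
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> LDHPlate:
    """LDH release plate: every dose shares the control release distribution
    (no cytotoxicity), plus spontaneous- and maximum-release control wells."""
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.wells_per_group
    samples = {
        dose: tuple(rng.normal(config.ldh_sample_mean, config.ldh_sample_sd, n))
        for dose in config.doses_um
    }
    spont = tuple(rng.normal(config.ldh_spontaneous_mean,
                             config.ldh_spontaneous_sd, n))
    maxi = tuple(rng.normal(config.ldh_maximum_mean, config.ldh_maximum_sd, n))
    return LDHPlate(samples=samples, spontaneous=spont, maximum=maxi)
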