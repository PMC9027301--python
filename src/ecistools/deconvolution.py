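"""Inverse problem: recover (Rb, alpha, Cm) from multifrequency spectra.

Per timepoint the measured cell-covered well spectrum is fitted with the
Giaever-Keese forward model by bounded nonlinear least squares on the
frequency-summed squared *relative* complex residuals

    Σ_f | (Z_model(f) - Z_cell(f)) / Z_cell(f) |²

Relative residuals equalize the influence of frequencies whose |Z| spans
orders of magnitude across 250 Hz - 64 kHz, and make the objective invariant
to an overall impedance rescaling.

The electrode (cell-free) parameters are fitted once per well from a
cell-free reference spectrum and frozen during the barrier fits, mirroring
how instrument software anchors the model on a cell-free baseline.

Degeneracy rule: when the paracellular path is a short (fitted Rb at or
below ``rb_zero_threshold``), Rb is reported as exactly 0 and alpha/Cm are
flagged non-modelable — a cell-free-looking spectrum carries no information
about them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .impedance import (
    BarrierParameters,
    ComplexSpectrum,
    ElectrodeParameters,
    cell_covered_impedance,
    cpe_interface_impedance,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "TimecourseFit",
    "extract_series_rc",
    "fit_electrode_parameters",
    "fit_barrier_parameters",
    "deconvolve_timecourse",
]


@dataclass(frozen=True)
class FitConfig:
    """Controls for the per-timepoint barrier fit.

    ``initial_guess`` is (Rb, alpha, Cm); with ``warm_start`` the previous
    timepoint's solution seeds the next fit (temporal smoothness).
    ``rb_zero_threshold`` (Ω·cm²) triggers the degeneracy rule.
    """

    rb_bounds: tuple[float, float] = (0.0, 1e4)
    alpha_bounds: tuple[float, float] = (0.0, 1e3)
    cm_bounds: tuple[float, float] = (1e-3, 100.0)
    initial_guess: tuple[float, float, float] = (2.0, 5.0, 1.0)
    warm_start: bool = True
    rb_zero_threshold: float = 0.4
    max_iterations: int = 200
    tolerance: float = 1e-12
    min_frequencies: int = 4

    def __post_init__(self) -> None:
        for name in ("rb_bounds", "alpha_bounds", "cm_bounds"):
            lo, hi = getattr(self, name)
            if not (lo < hi):
                raise ValueError(f"{name}: lower bound must be < upper bound")
            if lo < 0:
                raise ValueError(f"{name}: lower bound must be >= 0")
        if not self.rb_zero_threshold > 0:
            raise ValueError("rb_zero_threshold must be > 0")


@dataclass(frozen=True)
class FitResult:
    """One timepoint's fitted barrier with diagnostics."""

    barrier: BarrierParameters | None
    residual_norm: float
    converged: bool
    n_frequencies_used: int
    message: str = ""

    @property
    def failed(self) -> bool:
        return self.barrier is None


@dataclass
class TimecourseFit:
    """Per-timepoint fit results with aligned parameter traces.

    ``alpha_modelable`` / ``cm_modelable`` are the masks downstream plotting
    and statistics use to terminate alpha and Cm traces exactly where Rb
    hits zero.
    """

    times_h: np.ndarray
    results: list[FitResult]
    well: str | None = None
    dose_um: float | None = None

    def _trace(self, attr: str) -> np.ndarray:
        return np.array(
            [getattr(r.barrier, attr) if r.barrier is not None else np.nan
             for r in self.results]
        )

    @property
    def rb(self) -> np.ndarray:
        return self._trace("rb")

    @property
    def alpha(self) -> np.ndarray:
        return self._trace("alpha")

    @property
    def cm(self) -> np.ndarray:
        return self._trace("cm")

    @property
    def alpha_modelable(self) -> np.ndarray:
        return np.array([r.barrier is not None and r.barrier.alpha_modelable
                         for r in self.results])

    @property
    def cm_modelable(self) -> np.ndarray:
        return np.array([r.barrier is not None and r.barrier.cm_modelable
                         for r in self.results])

    def rb_zero_time(self, after_h: float = 0.0) -> float | None:
        """First time at or after ``after_h`` with reported Rb = 0.

        With ``after_h`` at the treatment time this is the barrier-collapse
        time; None when Rb never reaches zero in that window.
        """
        rb = self.rb
        for i in np.flatnonzero(self.times_h >= after_h):
            if rb[i] == 0.0:
                return float(self.times_h[i])
        return None

    def terminated_masks(self, after_h: float = 0.0
                         ) -> tuple[np.ndarray, np.ndarray]:
        """(alpha, cm) modelability masks, terminated at barrier collapse.

        Once Rb is reported zero at or after ``after_h`` the masks stay off
        for the rest of the trace: alpha and Cm stop being modelable when
        the paracellular short appears, and near-zero true Rb makes later
        refits flicker without carrying information.  This reproduces the
        abrupt ends of instrument alpha/Cm curves.
        """
        a, c = self.alpha_modelable.copy(), self.cm_modelable.copy()
        tz = self.rb_zero_time(after_h)
        if tz is not None:
            off = self.times_h >= tz
            a[off] = False
            c[off] = False
        return a, c

    def rb_terminated(self, after_h: float = 0.0) -> np.ndarray:
        """Rb trace with values clamped to 0 from the collapse time on.

        The same truncation rule as :meth:`terminated_masks`: after the
        first post-``after_h`` zero the barrier is gone, and later nonzero
        refits are identifiability noise, not recovery.
        """
        rb = self.rb.copy()
        tz = self.rb_zero_time(after_h)
        if tz is not None:
            rb[self.times_h >= tz] = 0.0
        return rb


def extract_series_rc(z, f):
    """Series-RC decomposition of a complex well impedance.

    ``R = Re(Z)``; ``C = -1 / (2πf·Im(Z))`` for capacitive records
    (Im(Z) < 0).  Non-capacitive records (Im(Z) ≥ 0) get ``C = nan`` —
    the flagged-invalid marker.  Scalar or array inputs.
    """
    z = np.asarray(z, dtype=complex)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0 Hz")
    r = z.real.copy()
    with np.errstate(divide="ignore"):
        c = np.where(z.imag < 0, -1.0 / (2.0 * np.pi * f * z.imag), np.nan)
    if r.ndim == 0:
        return float(r), float(c)
    return r, c


def _relative_residuals(z_model: np.ndarray, z_meas: np.ndarray) -> np.ndarray:
    rel = (z_model - z_meas) / z_meas
    return np.concatenate([rel.real, rel.imag])


def fit_electrode_parameters(
    reference: ComplexSpectrum,
    area_cm2: float | None = None,
    initial: ElectrodeParameters | None = None,
) -> ElectrodeParameters:
    """Fit (Q, n, Rsol) of the cell-free electrode model to a reference well.

    The effective area cannot be separated from Q by a single-well spectrum
    (only Q·A and Rsol are identifiable), so ``area_cm2`` is supplied and
    frozen; Q absorbs any area miscalibration.
    """
    from .impedance import DEFAULT_ELECTRODE

    if area_cm2 is None:
        area_cm2 = DEFAULT_ELECTRODE.area_cm2
    f = reference.grid.as_array()
    z = reference.as_array()
    if initial is None:
        init = (3e-6, 0.9, max(float(z.real.min()), 1.0))
    else:
        init = (initial.cpe_q, initial.cpe_n, initial.r_solution)

    def resid(p):
        q, n, rsol = p
        el = ElectrodeParameters(cpe_q=q, cpe_n=n, r_solution=rsol,
                                 area_cm2=area_cm2)
        zm = rsol + np.asarray(cpe_interface_impedance(f, el)) / area_cm2
        return _relative_residuals(zm, z)

    sol = least_squares(
        resid, init,
        bounds=([1e-12, 0.3, 0.0], [1.0, 1.0, 1e6]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
    )
    q, n, rsol = sol.x
    return ElectrodeParameters(cpe_q=float(q), cpe_n=float(n),
                               r_solution=float(rsol), area_cm2=area_cm2)


def fit_barrier_parameters(
    cell_spectrum: ComplexSpectrum,
    reference_spectrum: ComplexSpectrum | None,
    electrode: ElectrodeParameters | None = None,
    config: FitConfig = FitConfig(),
    x0: tuple[float, float, float] | None = None,
) -> FitResult:
    """Fit (Rb, alpha, Cm) of one cell-covered spectrum.

    ``electrode`` may be supplied pre-fitted (it is then frozen); otherwise
    it is fitted from ``reference_spectrum`` first.  ``x0`` overrides the
    configured initial guess (used for warm starts).

    Raises ``ValueError`` when fewer than ``config.min_frequencies`` usable
    (finite, nonzero) frequencies remain.
    """
    if electrode is None:
        if reference_spectrum is None:
            raise ValueError("need a reference spectrum or electrode parameters")
        electrode = fit_electrode_parameters(reference_spectrum)
    if (reference_spectrum is not None
            and reference_spectrum.grid != cell_spectrum.grid):
        raise ValueError("cell and reference spectra must share one grid")

    f = cell_spectrum.grid.as_array()
    z = cell_spectrum.as_array()
    usable = np.isfinite(z) & (z != 0)
    if usable.sum() < config.min_frequencies:
        raise ValueError(
            f"only {int(usable.sum())} usable frequencies; "
            f"need at least {config.min_frequencies}"
        )
    f, z = f[usable], z[usable]

    lo = [config.rb_bounds[0], config.alpha_bounds[0], config.cm_bounds[0]]
    hi = [config.rb_bounds[1], config.alpha_bounds[1], config.cm_bounds[1]]
    guess = np.clip(np.asarray(x0 if x0 is not None else config.initial_guess,
                               dtype=float), lo, hi)

    def resid(p):
        barrier = BarrierParameters(rb=p[0], alpha=p[1], cm=p[2])
        zc = np.asarray(cell_covered_impedance(f, electrode, barrier))
        zw = electrode.r_solution + zc / electrode.area_cm2
        return _relative_residuals(zw, z)

    sol = least_squares(
        resid, guess, bounds=(lo, hi),
        xtol=config.tolerance, ftol=config.tolerance, gtol=config.tolerance,
        max_nfev=config.max_iterations * 4,
    )
    rb, alpha, cm = (float(v) for v in sol.x)
    residual_norm = float(math.sqrt(2.0 * sol.cost))
    if rb <= config.rb_zero_threshold:
        barrier = BarrierParameters(rb=0.0, alpha=alpha, cm=cm)  # flags off
    else:
        barrier = BarrierParameters(rb=rb, alpha=alpha, cm=cm)
    return FitResult(
        barrier=barrier,
        residual_norm=residual_norm,
        converged=bool(sol.success),
        n_frequencies_used=int(f.size),
        message=str(sol.message),
    )


def deconvolve_timecourse(
    spectra: list[ComplexSpectrum],
    reference: list[ComplexSpectrum] | ComplexSpectrum | None,
    electrode: ElectrodeParameters | None = None,
    config: FitConfig = FitConfig(),
    times_h: np.ndarray | None = None,
    well: str | None = None,
    dose_um: float | None = None,
) -> TimecourseFit:
    """Fit every timepoint of one well, warm-starting from the previous fit.

    ``reference`` may be a single cell-free spectrum, one per timepoint
    (the first is used to fit the electrode), or None when ``electrode`` is
    given.  Failed timepoints are recorded (``FitResult.failed``) and never
    abort the trace.
    """
    if times_h is None:
        times_h = np.arange(len(spectra), dtype=float)
    times_h = np.asarray(times_h, dtype=float)
    if times_h.shape != (len(spectra),):
        raise ValueError("times_h must align with spectra")

    if electrode is None:
        ref0 = reference[0] if isinstance(reference, list) else reference
        if ref0 is None:
            raise ValueError("need a reference spectrum or electrode parameters")
        electrode = fit_electrode_parameters(ref0)

    results: list[FitResult] = []
    x0: tuple[float, float, float] | None = None
    for spec in spectra:
        try:
            res = fit_barrier_parameters(
                spec, None, electrode=electrode, config=config, x0=x0
            )
        except (ValueError, FloatingPointError) as exc:
            res = FitResult(barrier=None, residual_norm=np.inf,
                            converged=False, n_frequencies_used=0,
                            message=str(exc))
        results.append(res)
        if config.warm_start and res.barrier is not None:
            b = res.barrier
            # do not warm-start from a degenerate zero: keep alpha/Cm seeds
            rb_seed = b.rb if b.rb > 0 else config.initial_guess[0]
            x0 = (rb_seed, b.alpha, b.cm)
    return TimecourseFit(times_h=times_h, results=results, well=well,
                         dose_um=dose_um)
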