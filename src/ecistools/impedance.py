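"""Forward biophysical model of cell-covered microelectrode impedance.

Implements the Giaever-Keese description of current flow under an adherent
cell monolayer on a gold microelectrode.  The cell-free electrode-electrolyte
interface is modeled as a constant phase element (CPE), the cell membranes as
a pure series capacitance (apical + basal), and the monolayer by three
barrier parameters:

* ``Rb`` -- paracellular (cell-cell junction) resistance, Ω·cm²
* ``alpha`` -- cell-substrate constraint parameter, Ω·cm^1/2, reflecting the
  radial current path in the thin channel between the basal membrane and the
  substrate
* ``Cm`` -- combined membrane capacitance per unit area, µF/cm²

The current-spreading term uses the ratio of modified Bessel functions
I0/I1 of the complex argument γ = α·√(1/Zn + 1/Zm).

All specific impedances are in Ω·cm²; well-level impedances in Ω.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ive

__all__ = [
    "DEFAULT_FREQUENCIES_HZ",
    "FrequencyGrid",
    "ElectrodeParameters",
    "BarrierParameters",
    "ComplexSpectrum",
    "DEFAULT_ELECTRODE",
    "CONFLUENT_BARRIER",
    "cpe_interface_impedance",
    "membrane_impedance",
    "bessel_ratio",
    "cell_covered_impedance",
    "well_impedance",
]

#: Nine doubling frequencies, 250 Hz .. 64 kHz -- the standard multifrequency
#: acquisition grid of 96-well ECIS arrays.
DEFAULT_FREQUENCIES_HZ: tuple[float, ...] = (
    250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0, 16000.0, 32000.0, 64000.0,
)


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered measurement frequencies in Hz (strictly increasing, > 0)."""

    frequencies_hz: tuple[float, ...] = DEFAULT_FREQUENCIES_HZ

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D sequence")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies_hz", tuple(float(x) for x in f))

    def __len__(self) -> int:
        return len(self.frequencies_hz)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies_hz, dtype=float)


@dataclass(frozen=True)
class ElectrodeParameters:
    """Electrical model of one cell-free well.

    Parameters
    ----------
    cpe_q : float
        CPE admittance coefficient Q, S·s^n·cm⁻².  For ``cpe_n == 1`` this is
        an ideal interfacial capacitance in F/cm².
    cpe_n : float
        CPE exponent in (0, 1]; 1 = ideal capacitor, 0.9 is typical for gold.
    r_solution : float
        Series (spreading + lead) resistance of the well, Ω.
    area_cm2 : float
        Effective working-electrode area, cm².
    """

    cpe_q: float
    cpe_n: float
    r_solution: float
    area_cm2: float

    def __post_init__(self) -> None:
        if not self.cpe_q > 0:
            raise ValueError(f"cpe_q must be > 0, got {self.cpe_q}")
        if not 0 < self.cpe_n <= 1:
            raise ValueError(f"cpe_n must be in (0, 1], got {self.cpe_n}")
        if self.r_solution < 0:
            raise ValueError(f"r_solution must be >= 0, got {self.r_solution}")
        if not self.area_cm2 > 0:
            raise ValueError(f"area_cm2 must be > 0, got {self.area_cm2}")


@dataclass(frozen=True)
class BarrierParameters:
    """The Giaever-Keese barrier triplet with modelability flags.

    ``alpha_modelable`` / ``cm_modelable`` record whether alpha and Cm carry
    information: when Rb is zero the paracellular path is a short and the fit
    cannot constrain them, so both flags are forced off.
    """

    rb: float
    alpha: float
    cm: float
    alpha_modelable: bool = True
    cm_modelable: bool = True

    def __post_init__(self) -> None:
        if self.rb < 0:
            raise ValueError(f"rb must be >= 0, got {self.rb}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not self.cm > 0:
            raise ValueError(f"cm must be > 0, got {self.cm}")
        if self.rb == 0.0:
            object.__setattr__(self, "alpha_modelable", False)
            object.__setattr__(self, "cm_modelable", False)


@dataclass(frozen=True)
class ComplexSpectrum:
    """Complex impedance, one value per grid frequency.

    ``values`` are in Ω for well-level spectra and Ω·cm² for specific
    (area-normalized) spectra.
    """

    grid: FrequencyGrid
    values: tuple[complex, ...] = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"expected {len(self.grid)} values, got shape {v.shape}"
            )
        object.__setattr__(self, "values", tuple(complex(x) for x in v))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=complex)


# Default "96W20idf-like" electrode profile.  The constants are calibration
# choices, not vendor data: together with CONFLUENT_BARRIER they place the
# cell/cell-free impedance-ratio maximum at 16 kHz, the resistance-ratio
# maximum at 4 kHz, the capacitance minimum at 64 kHz, and put the confluent
# well below (and the cell-free well above) the 20 nF confluency gate.
DEFAULT_ELECTRODE = ElectrodeParameters(
    cpe_q=8e-6, cpe_n=0.9, r_solution=100.0, area_cm2=0.02
)

#: Mature confluent-monolayer barrier parameters used as the simulation
#: plateau and as the reference operating point for frequency selection.
CONFLUENT_BARRIER = BarrierParameters(rb=4.0, alpha=8.0, cm=1.8)


def _check_frequency(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0 Hz")
    return f


def cpe_interface_impedance(f, electrode: ElectrodeParameters):
    """Specific impedance Zn of the cell-free electrode interface, Ω·cm².

    ``Zn(f) = 1 / (Q · (i·2πf)^n)`` on the principal branch, so the phase is
    ``-n·π/2``: Re(Zn) ≥ 0, Im(Zn) ≤ 0.  Accepts scalar or array ``f``.
    """
    f = _check_frequency(f)
    w = 2.0 * np.pi * f
    z = np.asarray(1.0 / (electrode.cpe_q * (1j * w) ** electrode.cpe_n),
                   dtype=complex)
    return z if z.ndim else complex(z)


def membrane_impedance(f, cm: float):
    """Specific impedance Zm of the two cell membranes in series, Ω·cm².

    ``Zm(f) = 2 / (i·2πf·Cm)`` with ``cm`` in µF/cm² (the 1e-6 factor is
    applied here, at the formula boundary).  Purely imaginary (capacitive).
    """
    f = _check_frequency(f)
    if not cm > 0:
        raise ValueError(f"cm must be > 0 µF/cm², got {cm}")
    z = np.asarray(2.0 / (1j * 2.0 * np.pi * f * cm * 1e-6), dtype=complex)
    return z if z.ndim else complex(z)


def bessel_ratio(x):
    """Ratio of modified Bessel functions ``I0(x) / I1(x)`` for complex x.

    Uses exponentially scaled evaluations so the result is stable for |x|
    from ~1e-6 up to ~1e6 (the unscaled functions overflow near |x| ≈ 700).
    Diverges as 2/x for x → 0; x = 0 is a domain error.
    """
    x = np.asarray(x, dtype=complex)
    if np.any(x == 0):
        raise ValueError("bessel_ratio is singular at x = 0 (diverges as 2/x)")
    r = ive(0, x) / ive(1, x)
    return r if r.ndim else complex(r)


def _spreading_term(gamma):
    """(γ/2)·I0(γ)/I1(γ), extended continuously to 1 at γ = 0."""
    gamma = np.asarray(gamma, dtype=complex)
    out = np.ones_like(gamma)
    nz = gamma != 0
    if np.any(nz):
        g = gamma[nz]
        out[nz] = 0.5 * g * ive(0, g) / ive(1, g)
    return out


def cell_covered_impedance(f, electrode: ElectrodeParameters,
                           barrier: BarrierParameters):
    """Specific impedance Zc of a cell-covered electrode, Ω·cm².

    Giaever-Keese solution for radial current spreading beneath a confluent
    monolayer: with Zn the cell-free interface, Zm the transmembrane path,
    S = 1/Zn + 1/Zm and γ = α·√S (principal root),

        1/Zc = (1/Zn)·[ Zn/(Zn+Zm) + (Zm/(Zn+Zm)) / ((γ/2)·I0(γ)/I1(γ) + Rb·S) ]

    Limits: Zc → Zn when Rb = α = 0 (no barrier), Zc → Zn + Zm as Rb → ∞
    (all current transcellular).
    """
    f = _check_frequency(f)
    zn = np.asarray(cpe_interface_impedance(f, electrode), dtype=complex)
    zm = np.asarray(membrane_impedance(f, barrier.cm), dtype=complex)
    s = 1.0 / zn + 1.0 / zm
    gamma = barrier.alpha * np.sqrt(s)
    # principal branch: Re(S) > 0 for physical Zn, Zm, hence Re(γ) ≥ 0
    denom = _spreading_term(gamma) + barrier.rb * s
    inv_zc = (1.0 / zn) * (zn / (zn + zm) + (zm / (zn + zm)) / denom)
    zc = 1.0 / inv_zc
    return zc if zc.ndim else complex(zc)


def well_impedance(f, electrode: ElectrodeParameters,
                   barrier: BarrierParameters | None = None):
    """Measured well impedance, Ω: ``Rsol + Zspec(f) / A``.

    ``Zspec`` is the cell-free interface impedance when ``barrier`` is None,
    otherwise the cell-covered impedance.
    """
    if barrier is None:
        zspec = cpe_interface_impedance(f, electrode)
    else:
        zspec = cell_covered_impedance(f, electrode, barrier)
    z = electrode.r_solution + np.asarray(zspec, dtype=complex) / electrode.area_cm2
    return z if z.ndim else complex(z)


def well_spectrum(grid: FrequencyGrid, electrode: ElectrodeParameters,
                  barrier: BarrierParameters | None = None) -> ComplexSpectrum:
    """Evaluate :func:`well_impedance` on every grid frequency."""
    values = well_impedance(grid.as_array(), electrode, barrier)
    return ComplexSpectrum(grid=grid, values=tuple(np.atleast_1d(values)))
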