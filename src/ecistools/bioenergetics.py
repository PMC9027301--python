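"""Mito-Stress OCR metrics and LDH cytotoxicity.

A Mito-Stress run measures the oxygen consumption rate (OCR, pmol O₂/min)
of a well through four phases separated by sequential injections:

    baseline  →  oligomycin  →  FCCP  →  rotenone/antimycin A

Phase aggregation follows standard Mito-Stress conventions: basal is the
last pre-injection cycle, the post-oligomycin value is the phase minimum,
maximal is the post-FCCP maximum, and the non-mitochondrial OCR is the mean
of the rotenone/antimycin phase.  Derived metrics subtract non-mitochondrial
OCR (basal, maximal) or the post-oligomycin OCR (ATP-linked), so adding a
constant offset to every reading leaves all three metrics unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "INJECTION_ORDER",
    "OCRTrace",
    "PhaseSummary",
    "MitoMetrics",
    "segment_phases",
    "compute_mito_metrics",
    "ldh_cytotoxicity",
]

INJECTION_ORDER = ("oligomycin", "fccp", "rotenone_antimycin")


@dataclass(frozen=True)
class OCRTrace:
    """One well's OCR timecourse plus its injection schedule.

    ``injections`` maps event name -> injection time (min); events must
    follow :data:`INJECTION_ORDER` in time.
    """

    times_min: tuple[float, ...]
    ocr_pmol_min: tuple[float, ...]
    injections: dict[str, float]
    well: str | None = None
    dose_um: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.ocr_pmol_min, dtype=float)
        if t.shape != v.shape or t.size == 0:
            raise ValueError("times and OCR values must be non-empty and align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if set(self.injections) != set(INJECTION_ORDER):
            raise ValueError(
                f"injection schedule must contain exactly {INJECTION_ORDER}"
            )
        times = [self.injections[k] for k in INJECTION_ORDER]
        if not (times[0] < times[1] < times[2]):
            raise ValueError(
                "injections out of order: require oligomycin < fccp < "
                "rotenone_antimycin"
            )
        object.__setattr__(self, "times_min", tuple(float(x) for x in t))
        object.__setattr__(self, "ocr_pmol_min", tuple(float(x) for x in v))


@dataclass(frozen=True)
class PhaseSummary:
    """Raw per-phase OCR values (pmol/min) before corrections."""

    basal_raw: float
    post_oligo: float
    maximal_raw: float
    non_mito: float


@dataclass(frozen=True)
class MitoMetrics:
    """Corrected Mito-Stress metrics (pmol/min)."""

    non_mito_ocr: float
    basal_ocr: float
    atp_linked_ocr: float
    maximal_ocr: float

    def __post_init__(self) -> None:
        if self.non_mito_ocr < 0:
            raise ValueError("non-mitochondrial OCR must be >= 0")
        if self.atp_linked_ocr > self.basal_ocr + 1e-9:
            raise ValueError("ATP-linked OCR cannot exceed basal OCR")
        if self.maximal_ocr < 0:
            raise ValueError("maximal OCR must be >= 0")


def segment_phases(trace: OCRTrace) -> PhaseSummary:
    """Aggregate each Mito-Stress phase of one trace.

    basal_raw: last measurement before oligomycin; post_oligo: minimum
    between oligomycin and FCCP; maximal_raw: maximum between FCCP and
    rotenone/antimycin; non_mito: mean after rotenone/antimycin.
    Raises ``ValueError`` naming any phase without measurements.
    """
    t = np.asarray(trace.times_min)
    v = np.asarray(trace.ocr_pmol_min)
    t_olig = trace.injections["oligomycin"]
    t_fccp = trace.injections["fccp"]
    t_rot = trace.injections["rotenone_antimycin"]
    phases = {
        "baseline": t < t_olig,
        "post-oligomycin": (t >= t_olig) & (t < t_fccp),
        "post-FCCP": (t >= t_fccp) & (t < t_rot),
        "post-rotenone/antimycin": t >= t_rot,
    }
    for name, mask in phases.items():
        if not mask.any():
            raise ValueError(f"no measurements in phase {name!r}")
    return PhaseSummary(
        basal_raw=float(v[phases["baseline"]][-1]),
        post_oligo=float(v[phases["post-oligomycin"]].min()),
        maximal_raw=float(v[phases["post-FCCP"]].max()),
        non_mito=float(v[phases["post-rotenone/antimycin"]].mean()),
    )


def compute_mito_metrics(phases: PhaseSummary) -> MitoMetrics:
    """Derive basal, ATP-linked and maximal OCR from phase values.

    basal = basal_raw − non_mito; atp_linked = basal_raw − post_oligo;
    maximal = maximal_raw − non_mito.  Negative corrected values are
    clipped to 0 with a warning (they indicate readings below the
    non-mitochondrial floor, i.e. noise-dominated wells).
    """
    raw = {
        "basal_ocr": phases.basal_raw - phases.non_mito,
        "atp_linked_ocr": phases.basal_raw - phases.post_oligo,
        "maximal_ocr": phases.maximal_raw - phases.non_mito,
    }
    clipped = {}
    for name, value in raw.items():
        if value < 0:
            warnings.warn(f"{name} negative ({value:.3g} pmol/min); clipped to 0")
            value = 0.0
        clipped[name] = value
    if clipped["atp_linked_ocr"] > clipped["basal_ocr"]:
        # post-oligomycin OCR below the non-mitochondrial floor is noise;
        # ATP-linked respiration cannot exceed basal mitochondrial respiration
        warnings.warn("atp_linked_ocr exceeds basal_ocr; clipped to basal")
        clipped["atp_linked_ocr"] = clipped["basal_ocr"]
    return MitoMetrics(non_mito_ocr=phases.non_mito, **clipped)


def ldh_cytotoxicity(sample, spontaneous: float, maximum: float):
    """Percent cytotoxicity from LDH release absorbances.

    ``100 · (sample − spontaneous) / (maximum − spontaneous)`` where
    ``spontaneous`` is the untreated-release control and ``maximum`` the
    full-lysis control.  Vectorized over ``sample``.
    """
    if not maximum > spontaneous:
        raise ValueError("maximum release must exceed spontaneous release")
    sample = np.asarray(sample, dtype=float)
    pct = 100.0 * (sample - spontaneous) / (maximum - spontaneous)
    return pct if pct.ndim else float(pct)
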