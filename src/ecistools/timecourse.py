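"""Timecourse analysis: ratio spectra, frequency selection, normalization,
AUC, confluency gating and group statistics.

The analysis conventions follow standard ECIS practice: treatment time is
t = 0 h (seeding at negative time); traces are normalized to their value at
treatment so every trace starts at 1 (0 on the log10 scale); whole-experiment
effects are summarized by the trapezoidal area under the normalized curve;
group differences use one-way ANOVA with Tukey HSD post-hoc tests (the
Tukey-Kramer form when group sizes differ) or a two-tailed t-test for
two-group calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .deconvolution import extract_series_rc
from .impedance import FrequencyGrid

__all__ = [
    "RatioSpectrum",
    "NormalizedTrace",
    "AUCResult",
    "GroupComparison",
    "CONFLUENCY_THRESHOLD_F",
    "ratio_spectrum",
    "select_frequency",
    "normalize_trace",
    "area_under_curve",
    "confluency_gate",
    "star_annotation",
    "compare_groups",
]

#: Confluency gate: a mature monolayer is declared when the 64 kHz well
#: capacitance is strictly below 20 nF.
CONFLUENCY_THRESHOLD_F = 20e-9

QUANTITIES = ("impedance_magnitude", "resistance", "capacitance")


@dataclass(frozen=True)
class RatioSpectrum:
    """Per-frequency cell / cell-free ratio of a derived quantity."""

    grid: FrequencyGrid
    quantity: str
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        r = np.asarray(self.ratios, dtype=float)
        if r.shape != (len(self.grid),):
            raise ValueError("one ratio per grid frequency required")
        if np.any(r[np.isfinite(r)] <= 0):
            raise ValueError("ratios must be positive")
        object.__setattr__(self, "ratios", tuple(float(x) for x in r))


@dataclass(frozen=True)
class NormalizedTrace:
    """A timecourse normalized to its value at treatment time.

    ``times_h`` are hours relative to treatment (t = 0 at dose application).
    On the linear scale the value at t0 is exactly 1; on the log10 scale 0.
    """

    times_h: tuple[float, ...]
    values: tuple[float, ...]
    frequency_hz: float | None = None
    quantity: str | None = None
    well: str | None = None
    dose_um: float | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_h", tuple(float(x) for x in t))
        object.__setattr__(
            self, "values",
            tuple(float(x) for x in np.asarray(self.values, dtype=float)),
        )
        if len(self.values) != len(self.times_h):
            raise ValueError("times and values must align")

    def t_array(self) -> np.ndarray:
        return np.asarray(self.times_h)

    def v_array(self) -> np.ndarray:
        return np.asarray(self.values)


@dataclass(frozen=True)
class AUCResult:
    """Trapezoidal area under a trace over [t_start, t_end], (units)·h."""

    value: float
    t_start: float
    t_end: float
    method: str = "trapezoid"


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA + Tukey HSD summary (or two-group t-test)."""

    statistic: float
    p_value: float
    test: str                       # "anova" or "t-test"
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_stars: dict[tuple[str, str], str] = field(default_factory=dict)
    design: str = "endpoint"        # "endpoint" or "auc"
    degenerate: bool = False


def _derived_quantity(z: np.ndarray, f: np.ndarray, quantity: str) -> np.ndarray:
    if quantity == "impedance_magnitude":
        return np.abs(z)
    r, c = extract_series_rc(z, f)
    return r if quantity == "resistance" else c


def ratio_spectrum(
    records: pd.DataFrame,
    cell_wells: list[str],
    cellfree_wells: list[str],
    quantity: str,
    at_time_h: float,
    time_tol_h: float = 1e-6,
) -> RatioSpectrum:
    """Per-frequency ratio of group means, cell ÷ cell-free, at one time.

    ``records`` is a tidy frame with columns ``time_h, well, frequency_hz,
    z_real_ohm, z_imag_ohm``.  R and C are obtained by series-RC
    decomposition of each complex record before averaging.  A frequency
    missing from either group is omitted with a warning.
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}")
    if not cell_wells or not cellfree_wells:
        raise ValueError("need at least one well per group")
    snap = records[np.abs(records["time_h"] - at_time_h) <= time_tol_h]

    def group_mean(wells: list[str]) -> pd.Series:
        sub = snap[snap["well"].isin(wells)]
        z = sub["z_real_ohm"].to_numpy() + 1j * sub["z_imag_ohm"].to_numpy()
        q = _derived_quantity(z, sub["frequency_hz"].to_numpy(), quantity)
        return pd.Series(q, index=sub["frequency_hz"].to_numpy()).groupby(level=0).mean()

    mc, mf = group_mean(cell_wells), group_mean(cellfree_wells)
    common = mc.index.intersection(mf.index)
    missing = mc.index.symmetric_difference(mf.index)
    if len(missing):
        warnings.warn(f"frequencies missing from one group, omitted: "
                      f"{sorted(missing)}")
    if not len(common):
        raise ValueError("no common frequencies between groups")
    freqs = np.sort(common.to_numpy())
    ratios = (mc[freqs] / mf[freqs]).to_numpy()
    return RatioSpectrum(grid=FrequencyGrid(tuple(freqs)), quantity=quantity,
                         ratios=tuple(ratios))


def select_frequency(spec: RatioSpectrum, objective: str = "maximize") -> float:
    """Grid frequency attaining the ratio extremum.

    Ties break toward the lower frequency (first occurrence on the
    increasing grid).
    """
    r = np.asarray(spec.ratios)
    if objective == "maximize":
        idx = int(np.nanargmax(r))
    elif objective == "minimize":
        idx = int(np.nanargmin(r))
    else:
        raise ValueError("objective must be 'maximize' or 'minimize'")
    return spec.grid.frequencies_hz[idx]


def normalize_trace(
    times_h,
    values,
    t0: float = 0.0,
    log_scale: bool = False,
    time_tol_h: float = 1e-9,
    **meta,
) -> NormalizedTrace:
    """Divide a raw trace by its value at ``t0`` (optionally log10).

    ``t0`` must be present on the time grid and the baseline value nonzero.
    Normalizing an already-normalized trace is the identity.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    hits = np.flatnonzero(np.abs(t - t0) <= time_tol_h)
    if hits.size == 0:
        raise ValueError(f"t0={t0} h not present in the time grid")
    v0 = v[hits[0]]
    if v0 == 0 or not np.isfinite(v0):
        raise ValueError("baseline value at t0 is zero or non-finite")
    norm = v / v0
    if log_scale:
        norm = np.log10(norm)
    return NormalizedTrace(times_h=tuple(t), values=tuple(norm),
                           log_scale=log_scale, **meta)


def area_under_curve(trace: NormalizedTrace, t_start: float,
                     t_end: float) -> AUCResult:
    """Trapezoidal AUC on the (possibly non-uniform) time grid.

    Window endpoints may fall between samples; the trace is linearly
    interpolated there, which makes the AUC exactly additive over adjacent
    windows.  The window must lie within the trace support.
    """
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    t, v = trace.t_array(), trace.v_array()
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise ValueError(
            f"window [{t_start}, {t_end}] outside trace support "
            f"[{t[0]}, {t[-1]}]"
        )
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inside], [t_end]])
    vv = np.concatenate([[np.interp(t_start, t, v)], v[inside],
                         [np.interp(t_end, t, v)]])
    return AUCResult(value=float(np.trapezoid(vv, tt)),
                     t_start=float(t_start), t_end=float(t_end))


def confluency_gate(
    times_h,
    capacitance_f,
    threshold_f: float = CONFLUENCY_THRESHOLD_F,
    dwell_h: float = 1.0,
) -> float | None:
    """Earliest time a well qualifies as a mature confluent monolayer.

    The capacitance (typically at 64 kHz) must be *strictly* below the
    threshold and stay below for ``dwell_h`` hours (noise suppression);
    the trace must extend through the dwell window.  Returns None when the
    well never qualifies.  A reading exactly at the threshold does not count.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(capacitance_f, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    below = c < threshold_f
    for i in np.flatnonzero(below):
        if t[-1] < t[i] + dwell_h:
            return None
        window = (t >= t[i]) & (t <= t[i] + dwell_h)
        if np.all(below[window]):
            return float(t[i])
    return None


def star_annotation(p: float) -> str:
    """Significance stars: * p≤0.05, ** p≤0.01, *** p≤0.001, **** p≤0.0001."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_groups(groups: dict[str, np.ndarray],
                   design: str = "endpoint") -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` maps group label -> replicate values (≥2 groups with ≥2
    replicates each).  Two-group calls use the two-tailed t-test instead.
    All-equal (zero-variance) data is flagged degenerate with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 replicates")

    flat = np.concatenate(list(arrays.values()))
    if np.ptp(flat) == 0:  # no variance anywhere
        pairs = [(a, b) for i, a in enumerate(arrays) for b in list(arrays)[i + 1:]]
        return GroupComparison(
            statistic=0.0, p_value=1.0, test="anova",
            pairwise_p={p: 1.0 for p in pairs},
            pairwise_stars={p: "ns" for p in pairs},
            design=design, degenerate=True,
        )

    labels = list(arrays)
    if len(labels) == 2:
        a, b = arrays[labels[0]], arrays[labels[1]]
        tstat, p = sstats.ttest_ind(a, b)
        pair = (labels[0], labels[1])
        return GroupComparison(
            statistic=float(tstat), p_value=float(p), test="t-test",
            pairwise_p={pair: float(p)},
            pairwise_stars={pair: star_annotation(float(p))},
            design=design,
        )

    fstat, p = sstats.f_oneway(*arrays.values())
    values = np.concatenate([arrays[k] for k in labels])
    codes = np.concatenate([[k] * arrays[k].size for k in labels])
    tukey = pairwise_tukeyhsd(values, codes)
    pairwise_p: dict[tuple[str, str], float] = {}
    pairwise_stars: dict[tuple[str, str], str] = {}
    res = tukey.summary().data[1:]
    for row in res:
        g1, g2, _, padj = str(row[0]), str(row[1]), row[2], float(row[3])
        pairwise_p[(g1, g2)] = padj
        pairwise_stars[(g1, g2)] = star_annotation(padj)
    return GroupComparison(statistic=float(fstat), p_value=float(p),
                           test="anova", pairwise_p=pairwise_p,
                           pairwise_stars=pairwise_stars, design=design)
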