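"""End-to-end analysis pipeline: simulate → deconvolve → analyze.

Stages mirror the experimental workflow: frequency selection from the
pre-treatment ratio spectra, confluency gating on the 64 kHz capacitance,
normalization of each well's traces to treatment time, trapezoidal AUC and
endpoint statistics per dose group, per-timepoint deconvolution into
(Rb, alpha, Cm) with modelable-window statistics, and Mito-Stress / LDH
endpoints.  All artifacts are plain CSV/JSON; repeated runs with the same
(config, seed) are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .bioenergetics import compute_mito_metrics, ldh_cytotoxicity, segment_phases
from .deconvolution import (
    FitConfig,
    TimecourseFit,
    deconvolve_timecourse,
    extract_series_rc,
    fit_electrode_parameters,
)
from .impedance import ComplexSpectrum, ElectrodeParameters, FrequencyGrid
from .io import (
    RunConfig,
    read_impedance_csv,
    read_ldh_csv,
    read_ocr_csv,
    write_impedance_csv,
    write_ldh_csv,
    write_ocr_csv,
)
from .synthetic import OCR_INJECTIONS_MIN, SyntheticConfig, simulate_experiment
from .timecourse import (
    NormalizedTrace,
    area_under_curve,
    compare_groups,
    confluency_gate,
    normalize_trace,
    ratio_spectrum,
    select_frequency,
)

__all__ = [
    "PipelineError",
    "dose_groups",
    "spectra_for_well",
    "select_analysis_frequencies",
    "well_quantity_trace",
    "deconvolve_well",
    "run_pipeline",
]

logger = logging.getLogger("ecistools")

QUANTITY_OBJECTIVE = {
    "impedance_magnitude": "maximize",
    "resistance": "maximize",
    "capacitance": "minimize",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def dose_groups(records: pd.DataFrame) -> tuple[dict[float, list[str]], list[str]]:
    """Map dose (µM) -> cell wells, plus the list of cell-free wells.

    Cell groups are named ``cocl2_<dose>uM``; cell-free wells ``cellfree``.
    """
    doses: dict[float, list[str]] = {}
    cellfree: list[str] = []
    for group, sub in records.groupby("group"):
        wells = sorted(sub["well"].unique())
        if group == "cellfree":
            cellfree = wells
        elif str(group).startswith("cocl2_") and str(group).endswith("uM"):
            doses[float(str(group)[6:-2])] = wells
        else:
            raise PipelineError(f"unrecognized group name {group!r}")
    return dict(sorted(doses.items())), cellfree


def spectra_for_well(records: pd.DataFrame, well: str,
                     t_start: float | None = None,
                     t_end: float | None = None
                     ) -> tuple[np.ndarray, list[ComplexSpectrum]]:
    """One well's records as per-timepoint complex spectra."""
    sub = records[records["well"] == well]
    if sub.empty:
        raise PipelineError(f"no records for well {well!r}")
    if t_start is not None:
        sub = sub[sub["time_h"] >= t_start - 1e-9]
    if t_end is not None:
        sub = sub[sub["time_h"] <= t_end + 1e-9]
    wide = sub.pivot(index="time_h", columns="frequency_hz",
                     values=["z_real_ohm", "z_imag_ohm"]).sort_index()
    freqs = np.sort(sub["frequency_hz"].unique())
    grid = FrequencyGrid(tuple(freqs))
    z = (wide["z_real_ohm"][freqs].to_numpy()
         + 1j * wide["z_imag_ohm"][freqs].to_numpy())
    times = wide.index.to_numpy(dtype=float)
    spectra = [ComplexSpectrum(grid=grid, values=tuple(row)) for row in z]
    return times, spectra


def mean_cellfree_spectrum(records: pd.DataFrame, cellfree_wells: list[str],
                           at_time_h: float = 0.0) -> ComplexSpectrum:
    """Mean cell-free spectrum across wells at one timepoint."""
    sub = records[(records["well"].isin(cellfree_wells))
                  & (np.abs(records["time_h"] - at_time_h) <= 1e-6)]
    if sub.empty:
        raise PipelineError("no cell-free records at the reference time")
    z = sub["z_real_ohm"] + 1j * sub["z_imag_ohm"]
    mean = z.groupby(sub["frequency_hz"]).mean().sort_index()
    return ComplexSpectrum(grid=FrequencyGrid(tuple(mean.index)),
                           values=tuple(mean.to_numpy()))


def select_analysis_frequencies(records: pd.DataFrame,
                                cell_wells: list[str],
                                cellfree_wells: list[str],
                                at_time_h: float = 0.0) -> dict[str, float]:
    """Selected frequency per quantity from the cell/cell-free ratio spectra.

    Impedance magnitude and resistance take the ratio maximum; capacitance
    the frequency of the lowest cell-covered capacitance (equivalently the
    ratio minimum, as cells lower the apparent capacitance).
    """
    out = {}
    for quantity, objective in QUANTITY_OBJECTIVE.items():
        spec = ratio_spectrum(records, cell_wells, cellfree_wells, quantity,
                              at_time_h)
        out[quantity] = select_frequency(spec, objective)
    return out


def well_quantity_trace(records: pd.DataFrame, well: str, frequency_hz: float,
                        quantity: str) -> tuple[np.ndarray, np.ndarray]:
    """(times, values) of one derived quantity for one well at one frequency."""
    sub = records[(records["well"] == well)
                  & (np.abs(records["frequency_hz"] - frequency_hz) <= 1e-6)]
    sub = sub.sort_values("time_h")
    z = sub["z_real_ohm"].to_numpy() + 1j * sub["z_imag_ohm"].to_numpy()
    t = sub["time_h"].to_numpy(dtype=float)
    if quantity == "impedance_magnitude":
        return t, np.abs(z)
    r, c = extract_series_rc(z, sub["frequency_hz"].to_numpy())
    return (t, r) if quantity == "resistance" else (t, c)


def deconvolve_well(records: pd.DataFrame, well: str,
                    electrode: ElectrodeParameters,
                    config: FitConfig = FitConfig(),
                    t_start: float = 0.0,
                    t_end: float | None = None,
                    dose_um: float | None = None) -> TimecourseFit:
    """Deconvolve one well's spectra over a time window."""
    times, spectra = spectra_for_well(records, well, t_start, t_end)
    return deconvolve_timecourse(spectra, None, electrode=electrode,
                                 config=config, times_h=times, well=well,
                                 dose_um=dose_um)


def _group_stats_rows(quantity: str, measure: str,
                      values_by_dose: dict[float, np.ndarray],
                      control_dose: float = 0.0) -> list[dict]:
    """Tidy stats rows: one per group with its Tukey-adjusted p vs control."""
    comparison = compare_groups(
        {f"{d:g}" : v for d, v in values_by_dose.items()}, design=measure)
    rows = []
    control = f"{control_dose:g}"
    for dose, values in values_by_dose.items():
        key = tuple(sorted((control, f"{dose:g}")))
        lookup = {tuple(sorted(k)): k for k in comparison.pairwise_p}
        p_adj = stars = None
        if f"{dose:g}" != control and key in lookup:
            p_adj = comparison.pairwise_p[lookup[key]]
            stars = comparison.pairwise_stars[lookup[key]]
        rows.append({
            "quantity": quantity, "measure": measure, "dose_uM": dose,
            "n": int(np.size(values)), "estimate": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)),
            "anova_F": comparison.statistic, "anova_p": comparison.p_value,
            "p_adj_vs_control": p_adj, "stars": stars,
        })
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; writes artifacts under ``config.outdir``.

    Returns the JSON-serializable run summary.  Raises
    :class:`PipelineError` naming the failed stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {
            "version": _version,
            "seed": config.seed,
            "config_digest": config.digest(),
            "config": config.to_dict(),
        }
    }

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        if config.impedance_csv is None:
            syn = SyntheticConfig(
                wells_per_group=config.wells_per_group,
                sample_interval_h=config.sample_interval_h,
                noise_fraction=config.noise_fraction,
                seed=config.seed,
            )
            exp = simulate_experiment(syn, seed=config.seed)
            records = exp.impedance
            ocr_traces, ldh_plate = exp.ocr, exp.ldh
            write_impedance_csv(records, outdir / "impedance.csv")
            write_ocr_csv(ocr_traces, outdir / "ocr.csv")
            write_ldh_csv(ldh_plate, outdir / "ldh.csv")
        else:
            records = read_impedance_csv(config.impedance_csv)
            ocr_traces = (read_ocr_csv(config.ocr_csv, OCR_INJECTIONS_MIN)
                          if config.ocr_csv else [])
            ldh_plate = read_ldh_csv(config.ldh_csv) if config.ldh_csv else None
        if records.empty:
            raise PipelineError("impedance input is empty")
        doses, cellfree = dose_groups(records)
        if not doses or not cellfree:
            raise PipelineError("need both cell and cell-free groups")
        cell_wells = [w for wells in doses.values() for w in wells]
        followup_end = float(records["time_h"].max())
        auc_end = min(config.auc_end_h, followup_end)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: frequency selection ------------------------------------
    stage = "frequency-selection"
    try:
        if config.frequency == "auto":
            selected = select_analysis_frequencies(records, cell_wells,
                                                   cellfree, at_time_h=0.0)
        else:
            selected = {q: float(config.frequency) for q in QUANTITY_OBJECTIVE}
        summary["selected_frequencies_hz"] = selected
        logger.info("selected frequencies: %s", selected)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: confluency gate ----------------------------------------
    stage = "confluency-gate"
    try:
        gates = {}
        for well in cell_wells:
            t, c = well_quantity_trace(records, well, 64000.0, "capacitance")
            pre = t <= 0.0
            gates[well] = confluency_gate(t[pre], c[pre],
                                          dwell_h=config.dwell_h)
        summary["confluency_gate_h"] = gates
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: normalized traces + endpoint/AUC statistics ------------
    stage = "timecourse-statistics"
    try:
        trace_rows, stats_rows = [], []
        for quantity, freq in selected.items():
            endpoint_by_dose, auc_by_dose = {}, {}
            for dose, wells in doses.items():
                endpoints, aucs = [], []
                for well in wells:
                    t, v = well_quantity_trace(records, well, freq, quantity)
                    post = t >= config.auc_start_h - 1e-9
                    trace = normalize_trace(t[post], v[post], t0=0.0,
                                            frequency_hz=freq,
                                            quantity=quantity, well=well,
                                            dose_um=dose)
                    endpoints.append(trace.values[-1])
                    aucs.append(area_under_curve(trace, config.auc_start_h,
                                                 auc_end).value)
                    trace_rows.append(pd.DataFrame({
                        "quantity": quantity, "frequency_hz": freq,
                        "well": well, "dose_uM": dose,
                        "time_h": trace.times_h, "value": trace.values,
                    }))
                endpoint_by_dose[dose] = np.asarray(endpoints)
                auc_by_dose[dose] = np.asarray(aucs)
            stats_rows += _group_stats_rows(quantity, "endpoint",
                                            endpoint_by_dose)
            stats_rows += _group_stats_rows(quantity, "auc", auc_by_dose)
        normalized = pd.concat(trace_rows, ignore_index=True)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: deconvolution ------------------------------------------
    # Parameter traces are normalized to each well's mean over the hour
    # preceding treatment (5 samples): pre-treatment kinetics are at plateau
    # and unaffected by any dose, and averaging halves the per-well scale
    # noise a single t = 0 fit would inject into every normalized AUC.
    stage = "deconvolution"
    baseline_h = 1.0
    try:
        reference = mean_cellfree_spectrum(records, cellfree, at_time_h=0.0)
        electrode = fit_electrode_parameters(reference)
        fit_config = FitConfig(rb_zero_threshold=config.rb_zero_threshold)
        param_rows = []
        fits: dict[float, list[TimecourseFit]] = {}
        for dose, wells in doses.items():
            fits[dose] = []
            for well in wells:
                tc = deconvolve_well(records, well, electrode, fit_config,
                                     t_start=-baseline_h, t_end=auc_end,
                                     dose_um=dose)
                fits[dose].append(tc)
                a_mask, c_mask = tc.terminated_masks(after_h=0.0)
                param_rows.append(pd.DataFrame({
                    "well": well, "dose_uM": dose, "time_h": tc.times_h,
                    "rb_raw": tc.rb, "rb": tc.rb_terminated(0.0),
                    "alpha": tc.alpha, "cm": tc.cm,
                    "alpha_modelable": a_mask, "cm_modelable": c_mask,
                }))
        params = pd.concat(param_rows, ignore_index=True)

        def baseline_mean(tc: TimecourseFit, values: np.ndarray) -> float:
            pre = (tc.times_h >= -baseline_h - 1e-9) & (tc.times_h <= 1e-9)
            ok = pre & np.isfinite(values) & (values > 0)
            return float(values[ok].mean()) if ok.any() else np.nan

        # normalized Rb AUC over the full window (terminated trace)
        rb_auc_by_dose = {}
        collapse_by_dose = {}
        for dose, tcs in fits.items():
            aucs, collapses = [], []
            for tc in tcs:
                rb = tc.rb_terminated(0.0)
                rb0 = baseline_mean(tc, rb)
                if not np.isfinite(rb0) or rb0 <= 0:
                    continue  # no barrier at treatment: cannot normalize
                post = tc.times_h >= -1e-9
                trace = NormalizedTrace(times_h=tuple(tc.times_h[post]),
                                        values=tuple(rb[post] / rb0))
                aucs.append(area_under_curve(trace, config.auc_start_h,
                                             auc_end).value)
                tz = tc.rb_zero_time(0.0)
                collapses.append(tz if tz is not None else np.inf)
            rb_auc_by_dose[dose] = np.asarray(aucs)
            collapse_by_dose[dose] = collapses
        stats_rows += _group_stats_rows("rb", "auc", rb_auc_by_dose)
        summary["rb_collapse_h"] = {
            f"{d:g}": [None if not np.isfinite(x) else float(x) for x in v]
            for d, v in collapse_by_dose.items()
        }

        # alpha / Cm AUC within each treated group's modelable window,
        # each group compared against control over its own window
        control = fits.get(0.0, [])
        for name in ("alpha", "cm"):
            for dose, tcs in fits.items():
                if dose == 0.0 or not control:
                    continue
                window = [c for c in collapse_by_dose[dose] if np.isfinite(c)]
                w_end = float(np.median(window)) if window else auc_end
                w_end = max(w_end, config.auc_start_h + 2 * config.sample_interval_h)

                def window_auc(tc: TimecourseFit) -> float | None:
                    values = getattr(tc, name)
                    v0 = baseline_mean(tc, values)
                    if not np.isfinite(v0) or v0 <= 0:
                        return None
                    post = (tc.times_h >= -1e-9) & np.isfinite(values)
                    trace = NormalizedTrace(
                        times_h=tuple(tc.times_h[post]),
                        values=tuple(values[post] / v0))
                    end = min(w_end, trace.times_h[-1])
                    if end <= config.auc_start_h:
                        return None
                    return area_under_curve(trace, config.auc_start_h,
                                            end).value
                treated = [a for a in map(window_auc, tcs) if a is not None]
                ctrl = [a for a in map(window_auc, control) if a is not None]
                if len(treated) >= 2 and len(ctrl) >= 2:
                    rows = _group_stats_rows(
                        name, f"auc_window_{w_end:g}h",
                        {0.0: np.asarray(ctrl), dose: np.asarray(treated)})
                    stats_rows += rows
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: bioenergetics ------------------------------------------
    stage = "bioenergetics"
    try:
        mito_rows = []
        if ocr_traces:
            metric_names = ("basal_ocr", "atp_linked_ocr", "maximal_ocr")
            by_dose: dict[float, dict[str, list[float]]] = {}
            for trace in ocr_traces:
                metrics = compute_mito_metrics(segment_phases(trace))
                dose = trace.dose_um
                store = by_dose.setdefault(dose, {m: [] for m in metric_names})
                for m in metric_names:
                    store[m].append(getattr(metrics, m))
                mito_rows.append({"well": trace.well, "dose_uM": dose,
                                  **{m: getattr(metrics, m)
                                     for m in ("non_mito_ocr",) + metric_names}})
            for m in metric_names:
                control_mean = float(np.mean(by_dose[0.0][m]))
                values = {d: np.asarray(v[m]) / control_mean
                          for d, v in sorted(by_dose.items())}
                stats_rows += _group_stats_rows(m, "normalized", values)
        if ldh_plate is not None:
            spont = float(np.mean(ldh_plate.spontaneous))
            maxi = float(np.mean(ldh_plate.maximum))
            cyto = {dose: ldh_cytotoxicity(np.asarray(v), spont, maxi)
                    for dose, v in sorted(ldh_plate.samples.items())}
            stats_rows += _group_stats_rows("ldh_cytotoxicity_pct",
                                            "endpoint", cyto)
            summary["ldh_cytotoxicity_pct_mean"] = {
                f"{d:g}": float(np.mean(v)) for d, v in cyto.items()}
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: outputs -------------------------------------------------
    stage = "outputs"
    try:
        stats = pd.DataFrame(stats_rows)
        normalized.to_csv(outdir / "normalized_traces.csv", index=False,
                          float_format="%.10g")
        params.to_csv(outdir / "parameter_traces.csv", index=False,
                      float_format="%.10g")
        stats.to_csv(outdir / "stats.csv", index=False, float_format="%.10g")
        if mito_rows:
            pd.DataFrame(mito_rows).to_csv(outdir / "mito_metrics.csv",
                                           index=False, float_format="%.10g")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float)
            + "\n")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    summary["stats"] = stats
    return summary
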