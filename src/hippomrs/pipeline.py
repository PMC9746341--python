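"""End-to-end pipeline stages tying the modules together.

Each stage is a plain function taking a :class:`~hippomrs.config.PipelineConfig`
and an output directory; it reads the upstream stage's files, writes its own
outputs plus a JSON log with full parameter provenance, and returns a small
summary dict.  The stage order mirrors the acquisition-to-prediction flow:

    simulate -> place -> fit -> quantify -> analyze -> predict

Every stage is idempotent and fully reproducible from config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .predict import ResponsePredictionModel, build_diff_table, roc_analysis
from .quantify import (
    ConcentrationRecord,
    QuantConfig,
    absolute_concentration,
    bilateral_mean,
    canonical_species,
    csf_correct,
)
from .spectral import (
    AmaresModel,
    preprocess,
    qc_gate,
    water_reference_model,
)
from .stats import (
    chi_square_2x2,
    icc_test_retest,
    pearson_diff_correlation,
    t_test_from_summary,
    trend_anova,
)
from .synthdata import (
    AcquisitionParams,
    CohortSpec,
    GroundTruthSpectrum,
    PhantomSpec,
    generate_cohort,
    generate_fid,
    generate_phantom_volume,
    read_cohort,
    read_fid,
    write_cohort,
    write_fid,
)
from .volumes import LABELS, LabelVolume
from .voxelplace import (
    SearchConfig,
    optimize_placement,
    read_voxel_location,
    tissue_fractions,
    write_voxel_location,
)

logger = logging.getLogger("hippomrs")

__all__ = [
    "stage_simulate",
    "stage_place",
    "stage_fit",
    "stage_quantify",
    "stage_analyze",
    "stage_predict",
    "run_all",
]

#: Default true concentrations (mmol/kg) encoded into the simulated FIDs.
DEFAULT_TRUE_CONCENTRATIONS = {
    "naa": 8.2, "tcho": 1.55, "tcr": 6.9, "glx": 8.8, "ins": 5.4
}


def _write_log(outdir: Path, stage: str, params: dict, inputs: list, outputs: list) -> None:
    log = {
        "stage": stage,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": params,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
    }
    with open(outdir / f"{stage}_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)


def _acq(cfg: PipelineConfig) -> AcquisitionParams:
    d = dict(cfg.acquisition)
    if "voxel_dims_mm" in d:
        d["voxel_dims_mm"] = tuple(d["voxel_dims_mm"])
    return AcquisitionParams(**d)


def _quant_cfg(cfg: PipelineConfig) -> QuantConfig:
    return QuantConfig(**cfg.quant)


def stage_simulate(cfg: PipelineConfig, outdir) -> dict:
    """Generate every pipeline input: phantom label volume, one FID pair and
    the test + validation cohort tables, plus a manifest with the seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    acq = _acq(cfg)

    phantom_kwargs = dict(cfg.phantom)
    phantom_kwargs.setdefault("seed", cfg.seed)
    if "grid_shape" in phantom_kwargs:
        phantom_kwargs["grid_shape"] = tuple(phantom_kwargs["grid_shape"])
    if "voxel_size_mm" in phantom_kwargs:
        phantom_kwargs["voxel_size_mm"] = tuple(phantom_kwargs["voxel_size_mm"])
    if "hippocampus_ellipsoids" in phantom_kwargs:
        phantom_kwargs["hippocampus_ellipsoids"] = tuple(
            (tuple(c), tuple(s)) for c, s in phantom_kwargs["hippocampus_ellipsoids"]
        )
    phantom_spec = PhantomSpec(**phantom_kwargs)
    phantom = generate_phantom_volume(phantom_spec)
    phantom_path = outdir / "phantom.nii.gz"
    phantom.save(phantom_path)

    spec_kwargs = dict(cfg.spectrum)
    conc = spec_kwargs.pop("concentrations_mmol_kg", DEFAULT_TRUE_CONCENTRATIONS)
    lw = spec_kwargs.pop("linewidth_hz", 5.0)
    truth = GroundTruthSpectrum.from_concentrations(
        dict(conc),
        quant_config=_quant_cfg(cfg),
        linewidths_hz={m: float(lw) for m in conc},
        **spec_kwargs,
    )
    suppressed, water = generate_fid(truth, acq, seed=cfg.seed)
    fid_s_path = outdir / "fid_suppressed.txt"
    fid_w_path = outdir / "fid_water.txt"
    write_fid(suppressed, fid_s_path, acq)
    write_fid(water, fid_w_path, acq)
    with open(outdir / "true_concentrations.json", "w") as fh:
        json.dump(dict(conc), fh, indent=2)

    cohort_spec = CohortSpec(seed=cfg.seed, **cfg.cohort)
    cohort = generate_cohort(cohort_spec)
    cohort_path = outdir / "cohort.csv"
    write_cohort(cohort, cohort_path)
    validation_spec = CohortSpec(
        seed=cfg.validation_seed,
        n_rd=22,
        n_nrd=35,
        n_hc=0,
        **{k: v for k, v in cfg.cohort.items() if k not in ("n_rd", "n_nrd", "n_hc")},
    )
    validation = generate_cohort(validation_spec)
    validation_path = outdir / "cohort_validation.csv"
    write_cohort(validation, validation_path)

    manifest = {
        "artifact_classes": ["label_volume", "fid", "cohort"],
        "seed": cfg.seed,
        "validation_seed": cfg.validation_seed,
        "version": __version__,
        "files": {
            "label_volume": [phantom_path.name],
            "fid": [fid_s_path.name, fid_w_path.name],
            "cohort": [cohort_path.name, validation_path.name],
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    outputs = [phantom_path, fid_s_path, fid_w_path, cohort_path, validation_path]
    _write_log(outdir, "simulate", cfg.to_dict(), [], outputs)
    logger.info("simulate: wrote %d artifacts to %s", len(outputs), outdir)
    return manifest


def stage_place(cfg: PipelineConfig, outdir) -> dict:
    """Optimise the left and right hippocampal voxel boxes on the phantom."""
    outdir = Path(outdir)
    phantom_path = outdir / "phantom.nii.gz"
    if not phantom_path.exists():
        raise FileNotFoundError(
            f"{phantom_path} not found — run the simulate stage first"
        )
    phantom = LabelVolume.load(phantom_path)
    acq = _acq(cfg)
    search = SearchConfig(**cfg.search)
    placements, reports = [], {}
    for side, label in (("left", LABELS["hippoL"]), ("right", LABELS["hippoR"])):
        placement, report = optimize_placement(
            phantom,
            size_mm=acq.voxel_dims_mm,
            search=search,
            label_value=label,
            side=side,
            subject_id="phantom",
        )
        placements.append(placement)
        reports[side] = {
            "overlap_volume_mm3": report.overlap_volume_mm3,
            "overlap_fraction_pct": report.overlap_fraction_pct,
            "n_candidates_evaluated": report.n_candidates_evaluated,
            "center_mm": list(placement.center_mm),
        }
    loc_path = outdir / "Voxel_Location.txt"
    write_voxel_location(placements, loc_path)
    report_path = outdir / "placement_report.json"
    with open(report_path, "w") as fh:
        json.dump(reports, fh, indent=2)
    _write_log(outdir, "place", cfg.to_dict(), [phantom_path], [loc_path, report_path])
    logger.info("place: optimised %d placements", len(placements))
    return reports


def stage_fit(cfg: PipelineConfig, outdir) -> dict:
    """Preprocess and fit the simulated FID pair; apply the QC gates."""
    outdir = Path(outdir)
    fid_s_path = outdir / "fid_suppressed.txt"
    fid_w_path = outdir / "fid_water.txt"
    for p in (fid_s_path, fid_w_path):
        if not p.exists():
            raise FileNotFoundError(f"{p} not found — run the simulate stage first")
    suppressed = preprocess(read_fid(fid_s_path))
    fit = AmaresModel(suppressed).fit()
    qc = qc_gate(fit, thresholds=cfg.qc or None)
    water_fit = AmaresModel(read_fid(fid_w_path), prior=water_reference_model()).fit()

    frame = fit.to_frame()
    frame["snr"] = fit.snr
    frame["fwhm_hz"] = fit.linewidth_hz
    frame["qc_pass"] = qc.overall_pass
    csv_path = outdir / "fit_results.csv"
    frame.to_csv(csv_path, index=False)
    result = {
        "metabolites": {
            name: {
                "amplitude": float(fit.amplitudes[i]),
                "freq_ppm": float(fit.freqs_ppm[i]),
                "crlb_pct": float(fit.crlb_pct[i]),
            }
            for i, name in enumerate(fit.peak_names)
        },
        "linewidth_hz": fit.linewidth_hz,
        "snr": fit.snr,
        "noise_sd": fit.noise_sd,
        "converged": fit.converged,
        "qc": {
            "overall_pass": qc.overall_pass,
            "snr_pass": qc.snr_pass,
            "fwhm_pass": qc.fwhm_pass,
            "crlb_pass": qc.crlb_pass,
            "reasons": qc.reasons,
        },
        "water_amplitude": float(water_fit.amplitudes[0]),
        "water_converged": water_fit.converged,
    }
    json_path = outdir / "fit_results.json"
    with open(json_path, "w") as fh:
        json.dump(result, fh, indent=2)
    _write_log(outdir, "fit", cfg.to_dict(), [fid_s_path, fid_w_path], [csv_path, json_path])
    logger.info("fit: SNR=%.1f FWHM=%.1f Hz QC pass=%s", fit.snr, fit.linewidth_hz, qc.overall_pass)
    return result


def stage_quantify(cfg: PipelineConfig, outdir) -> dict:
    """Convert fitted amplitudes to CSF-corrected absolute concentrations
    using the placements' tissue fractions."""
    outdir = Path(outdir)
    fit_path = outdir / "fit_results.json"
    loc_path = outdir / "Voxel_Location.txt"
    phantom_path = outdir / "phantom.nii.gz"
    for p in (fit_path, loc_path, phantom_path):
        if not p.exists():
            raise FileNotFoundError(f"{p} not found — run upstream stages first")
    with open(fit_path) as fh:
        fit = json.load(fh)
    if not fit["qc"]["overall_pass"]:
        raise RuntimeError(
            "QC-failing spectrum cannot be quantified: " + "; ".join(fit["qc"]["reasons"])
        )
    placements = read_voxel_location(loc_path)
    if not isinstance(placements, list):
        placements = [placements]
    phantom = LabelVolume.load(phantom_path)
    qcfg = _quant_cfg(cfg)
    s_water = fit["water_amplitude"]
    records = {}
    for placement in placements:
        vols = tissue_fractions(placement, phantom)
        raw = {
            canonical_species(name): absolute_concentration(
                info["amplitude"], s_water, name, qcfg
            )
            for name, info in fit["metabolites"].items()
        }
        corrected = {
            name: csf_correct(c, vols["V_total"], vols["V_CSF"])
            for name, c in raw.items()
        }
        records[placement.label] = ConcentrationRecord(
            concentrations_raw=raw,
            concentrations_corrected=corrected,
            v_total_mm3=vols["V_total"],
            v_csf_mm3=vols["V_CSF"],
            side=placement.label,
            week=0,
            qc_pass=True,
        )
    bilateral = bilateral_mean(records.get("left"), records.get("right"))
    out = {
        "per_side": {
            side: {
                "raw": rec.concentrations_raw,
                "corrected": rec.concentrations_corrected,
                "v_total_mm3": rec.v_total_mm3,
                "v_csf_mm3": rec.v_csf_mm3,
            }
            for side, rec in records.items()
        },
        "bilateral_mean": bilateral.concentrations,
        "single_side": bilateral.single_side,
    }
    json_path = outdir / "concentrations.json"
    with open(json_path, "w") as fh:
        json.dump(out, fh, indent=2)
    rows = [
        {"metabolite": m, "concentration_mmol_kg": c}
        for m, c in bilateral.concentrations.items()
    ]
    csv_path = outdir / "concentrations.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    _write_log(
        outdir, "quantify", cfg.to_dict(), [fit_path, loc_path, phantom_path],
        [json_path, csv_path],
    )
    return out


def stage_analyze(cfg: PipelineConfig, outdir) -> dict:
    """Group comparisons, trends, reliability and correlations on the cohort."""
    outdir = Path(outdir)
    cohort_path = outdir / "cohort.csv"
    if not cohort_path.exists():
        raise FileNotFoundError(f"{cohort_path} not found — run the simulate stage first")
    cohort = read_cohort(cohort_path)
    stats_cfg = dict(cfg.stats)
    week_pair = tuple(stats_cfg.get("week_pair", (0, 3)))

    # Table-1-style group comparison of clinical characteristics
    rd = cohort[(cohort["group"] == "RD") & (cohort["week"] == 0)]
    nrd = cohort[(cohort["group"] == "n-RD") & (cohort["week"] == 0)]
    table1_rows = []
    for col in ("age", "age_onset", "duration", "hdrs"):
        res = t_test_from_summary(
            rd[col].mean(), rd[col].std(ddof=1), len(rd),
            nrd[col].mean(), nrd[col].std(ddof=1), len(nrd),
        )
        table1_rows.append(
            {
                "characteristic": col,
                "rd_mean": rd[col].mean(), "rd_sd": rd[col].std(ddof=1),
                "nrd_mean": nrd[col].mean(), "nrd_sd": nrd[col].std(ddof=1),
                "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
                "test": res.test_name,
            }
        )
    chi = chi_square_2x2(
        int((rd["gender"] == 0).sum()), int((rd["gender"] == 1).sum()),
        int((nrd["gender"] == 0).sum()), int((nrd["gender"] == 1).sum()),
    )
    table1_rows.append(
        {
            "characteristic": "gender(m/f)",
            "rd_mean": float((rd["gender"] == 0).sum()), "rd_sd": float((rd["gender"] == 1).sum()),
            "nrd_mean": float((nrd["gender"] == 0).sum()), "nrd_sd": float((nrd["gender"] == 1).sum()),
            "statistic": chi.statistic, "df": chi.df, "p_value": chi.p_value,
            "test": chi.test_name,
        }
    )
    table1 = pd.DataFrame(table1_rows)
    table1_path = outdir / "group_characteristics.csv"
    table1.to_csv(table1_path, index=False)

    # trend ANOVA per group and metabolite
    trend_rows = []
    for group in ("RD", "n-RD"):
        sub = cohort[cohort["group"] == group]
        for m in ("naa", "tcho", "tcr", "glx", "ins"):
            res = trend_anova(sub, m)
            trend_rows.append(
                {"group": group, "metabolite": m, "t": res.statistic,
                 "df": res.df, "p_for_trend": res.p_value}
            )
    trends = pd.DataFrame(trend_rows)
    trend_path = outdir / "trend_results.csv"
    trends.to_csv(trend_path, index=False)

    # test-retest ICC in healthy controls (week 0 vs week 1)
    hc = cohort[cohort["group"] == "HC"]
    icc_rows = []
    if len(hc) and {0, 1} <= set(hc["week"]):
        w0 = hc[hc["week"] == 0].set_index("subject_id")
        w1 = hc[hc["week"] == 1].set_index("subject_id")
        shared = w0.index.intersection(w1.index)
        for m in ("naa", "tcho", "tcr", "glx", "ins"):
            icc = icc_test_retest(w0.loc[shared, m], w1.loc[shared, m])
            icc_rows.append({"metabolite": m, "icc": icc, "good_reliability": icc > 0.7})
    icc_table = pd.DataFrame(icc_rows)
    icc_path = outdir / "icc_results.csv"
    icc_table.to_csv(icc_path, index=False)

    # correlations of differentiated scores over the analysis week pair
    diffs = build_diff_table(cohort, week_pair)
    corr_rows = []
    for m in ("d_tcho", "d_naa", "d_glx"):
        r, p = pearson_diff_correlation(diffs["d_hdrs"], diffs[m])
        corr_rows.append({"pair": f"d_hdrs~{m}", "r": r, "p_value": p})
    corr = pd.DataFrame(corr_rows)
    corr_path = outdir / "correlation_results.csv"
    corr.to_csv(corr_path, index=False)

    outputs = [table1_path, trend_path, icc_path, corr_path]
    _write_log(outdir, "analyze", cfg.to_dict(), [cohort_path], outputs)
    return {
        "n_table1_rows": len(table1),
        "n_trend_rows": len(trends),
        "n_icc_rows": len(icc_table),
        "n_correlations": len(corr),
    }


def stage_predict(cfg: PipelineConfig, outdir) -> dict:
    """Stepwise logistic prediction with ROC and validation confusion table."""
    outdir = Path(outdir)
    cohort_path = outdir / "cohort.csv"
    validation_path = outdir / "cohort_validation.csv"
    for p in (cohort_path, validation_path):
        if not p.exists():
            raise FileNotFoundError(f"{p} not found — run the simulate stage first")
    cohort = read_cohort(cohort_path)
    validation = read_cohort(validation_path)
    stats_cfg = dict(cfg.stats)
    week_pair = tuple(stats_cfg.get("week_pair", (0, 3)))
    model = ResponsePredictionModel.from_cohort(
        cohort,
        week_pair=week_pair,
        p_enter=stats_cfg.get("p_enter", 0.05),
        p_remove=stats_cfg.get("p_remove", 0.10),
        force_covariates=stats_cfg.get("force_covariates", False),
    )
    results = model.fit()
    if not results.terms:
        raise RuntimeError("stepwise selection retained no predictors")
    table2 = results.coefficient_table()
    table2_path = outdir / "logistic_model.csv"
    table2.to_csv(table2_path, index=False)

    roc = results.roc()
    scores, labels = results.training_scores()
    order = np.argsort(scores)
    roc_coords = pd.DataFrame(
        {
            "threshold": scores[order],
            "sensitivity": [
                float((scores[labels == "RD"] >= t).mean()) for t in scores[order]
            ],
            "specificity": [
                float((scores[labels == "n-RD"] < t).mean()) for t in scores[order]
            ],
        }
    )
    roc_path = outdir / "roc_coordinates.csv"
    roc_coords.to_csv(roc_path, index=False)

    diffs_val = build_diff_table(validation, week_pair)
    cm = results.validate(diffs_val)
    val_roc = roc_analysis(
        results.selection.linear_predictor(diffs_val), diffs_val["label"].to_numpy()
    )
    table3 = pd.DataFrame(
        {
            "predicted_rd": [cm.tp, cm.fp],
            "predicted_nrd": [cm.fn, cm.tn],
        },
        index=["actual_rd", "actual_nrd"],
    )
    table3_path = outdir / "validation_confusion.csv"
    table3.to_csv(table3_path)
    summary = {
        "selected_terms": results.terms,
        "training_auc": roc.auc,
        "training_auc_ci": [roc.ci_low, roc.ci_high],
        "threshold": roc.threshold,
        "validation_accuracy_pct": cm.accuracy_pct,
        "validation_auc": val_roc.auc,
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
    }
    summary_path = outdir / "prediction_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    _write_log(
        outdir, "predict", cfg.to_dict(), [cohort_path, validation_path],
        [table2_path, roc_path, table3_path, summary_path],
    )
    logger.info(
        "predict: terms=%s AUC=%.3f validation accuracy=%.2f%%",
        results.terms, roc.auc, cm.accuracy_pct,
    )
    return summary


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage in order; returns the prediction summary."""
    stage_simulate(cfg, outdir)
    stage_place(cfg, outdir)
    stage_fit(cfg, outdir)
    stage_quantify(cfg, outdir)
    stage_analyze(cfg, outdir)
    return stage_predict(cfg, outdir)
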