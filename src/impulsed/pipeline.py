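"""End-to-end runs: simulate -> fit -> stats, with manifests and logging."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import build_reports, icc_reliability, summarize_cohort, ALL_PARAMS
from .fitting import FitOptions, fit_adc, fit_impulsed, fit_maps, normalize_per_sequence
from .io import write_manifest, write_nifti, write_table
from .protocol import adc_name, default_protocol, load_protocol
from .signal_model import TwoCompartmentModel
from .synthetic_cohort import (CohortSpec, apply_exclusions, cohort_table,
                               check_subtype_feasibility, generate_lesion_image,
                               generate_roster, roster_table,
                               simulate_observer_pair)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("impulsed")

STAGES = ("simulate", "fit", "stats")


class PipelineError(RuntimeError):
    """A pipeline stage failed or the stage toggles are inconsistent."""


@dataclass
class RunConfig:
    out_dir: str
    protocol_path: str | None = None
    spec_path: str | None = None
    seed: int = 0
    snr: float = 50.0
    stages: tuple[str, ...] = STAGES
    n_map_lesions: int = 2  # lesions rendered as voxel phantoms + maps
    phantom_shape: tuple[int, int, int] = (12, 12, 3)
    jitter_cv: float = 0.05

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        if "stats" in self.stages and "fit" not in self.stages:
            raise PipelineError(
                "stage dependency violated: 'stats' consumes fitted lesion "
                "summaries, enable 'fit' as well")
        if "fit" in self.stages and "simulate" not in self.stages:
            raise PipelineError(
                "stage dependency violated: 'fit' needs the simulated cohort, "
                "enable 'simulate' as well")


def _fit_lesion_summaries(cohort: pd.DataFrame, model: TwoCompartmentModel,
                          snr: float, seed: int) -> pd.DataFrame:
    """ROI-level noisy forward signals refit per lesion.

    Returns a table in which the canonical parameter columns hold FITTED
    values; the generating truths are kept under ``truth_*``.
    """
    rng = np.random.default_rng(seed)
    shells = model.protocol.shells()
    rows = []
    opts = FitOptions()
    for _, lesion in cohort.iterrows():
        clean = model.predict(lesion["d_mean"], lesion["f_in"],
                              lesion["D_ex"], shells)
        if np.isfinite(snr):
            sigma = 1.0 / snr
            noisy = np.hypot(clean + rng.normal(0, sigma, clean.size),
                             rng.normal(0, sigma, clean.size))
        else:
            noisy = clean
        fit_shells, norm_sig, _ = normalize_per_sequence(noisy, shells)
        fr = fit_impulsed(fit_shells, norm_sig, model, opts)
        row = {c: lesion[c] for c in cohort.columns
               if not (c in ("d_mean", "f_in", "D_ex", "cellularity")
                       or c.startswith("ADC_"))}
        row.update({f"truth_{c}": lesion[c]
                    for c in ("d_mean", "f_in", "D_ex", "cellularity")})
        row.update({
            "d_mean": fr.params.d_mean, "f_in": fr.params.f_in,
            "D_ex": fr.params.D_ex, "cellularity": fr.cellularity,
            "fit_converged": fr.converged, "fit_rms": fr.residual_rms,
        })
        for seq in model.protocol.sequences:
            bs = [b for l, b in fit_shells if l == seq.label]
            ss = [s for (l, _), s in zip(fit_shells, norm_sig)
                  if l == seq.label]
            row[adc_name(seq.label)] = fit_adc([0.0] + bs, [1.0] + ss,
                                               seq.label).adc
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Outputs: roster.csv, cohort.csv (truth), cohort_fitted.csv, parameter-map
    NIfTIs + roi_summary.csv for the first ``n_map_lesions`` lesions, the
    report tables, and a manifest recording versions/seed/config hash.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(out, asdict(config), config.seed)
    protocol = (default_protocol() if config.protocol_path is None
                else load_protocol(config.protocol_path))
    spec = CohortSpec.from_yaml(config.spec_path)
    model = TwoCompartmentModel(protocol)
    cohort = None

    try:
        if "simulate" in config.stages:
            t0 = time.time()
            roster = generate_roster(spec, seed=config.seed)
            enrolled, report = apply_exclusions(roster)
            cohort = cohort_table(enrolled, model)
            write_table(roster_table(roster), out / "roster.csv", config.seed)
            write_table(cohort, out / "cohort.csv", config.seed)
            (out / "exclusion_report.json").write_text(
                json.dumps(report, indent=2) + "\n")
            comp = summarize_cohort(cohort)
            comp["subtype_feasibility"] = check_subtype_feasibility(spec)
            (out / "composition.json").write_text(
                json.dumps(comp, indent=2) + "\n")
            log.info("stage=simulate n_collected=%d n_enrolled=%d "
                     "elapsed=%.1fs", len(roster), len(enrolled),
                     time.time() - t0)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    try:
        if "fit" in config.stages:
            t0 = time.time()
            fitted = _fit_lesion_summaries(cohort, model, config.snr,
                                           config.seed + 1)
            write_table(fitted, out / "cohort_fitted.csv", config.seed)
            summaries = []
            for i in range(min(config.n_map_lesions, len(cohort))):
                lesion = cohort.iloc[i]
                from .signal_model import TissueParams
                truth = TissueParams(lesion["d_mean"], lesion["f_in"],
                                     lesion["D_ex"])
                ph = generate_lesion_image(truth, model,
                                           shape=config.phantom_shape,
                                           snr=config.snr,
                                           seed=config.seed + 100 + i,
                                           jitter_cv=config.jitter_cv)
                maps = fit_maps(ph.volume4d, ph.mask, model,
                                lesion_id=str(lesion["patient_id"]))
                pdir = out / "phantoms" / str(lesion["patient_id"])
                write_nifti(ph.volume4d, None, pdir / "dwi.nii.gz")
                write_nifti(ph.mask.astype(np.uint8), None, pdir / "mask.nii.gz")
                for name, arr in maps.maps.items():
                    write_nifti(arr, None, pdir / f"{name}.nii.gz")
                summaries.append(maps.roi_summary)
                log.info("stage=fit lesion=%s n_voxels=%d n_flagged=%d",
                         lesion["patient_id"],
                         int(maps.roi_summary["n_voxels"].iloc[0]),
                         maps.n_flagged)
            if summaries:
                write_table(pd.concat(summaries, ignore_index=True),
                            out / "roi_summary.csv", config.seed)
            log.info("stage=fit n_lesions=%d elapsed=%.1fs", len(fitted),
                     time.time() - t0)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'fit' failed: {exc}") from exc

    try:
        if "stats" in config.stages:
            t0 = time.time()
            fitted = pd.read_csv(out / "cohort_fitted.csv", comment="#")
            table4, table5 = build_reports(fitted)
            write_table(table4, out / "table4_report.csv", config.seed)
            write_table(table5, out / "table5_report.csv", config.seed)
            icc_rows = []
            for param in ALL_PARAMS:
                if param not in fitted.columns:
                    continue
                r1, r2 = simulate_observer_pair(fitted[param].to_numpy(),
                                                seed=config.seed + 7)
                icc = icc_reliability(r1, r2, param)
                icc_rows.append({"parameter": param, "icc": icc.icc,
                                 "ci_low": icc.ci_low, "ci_high": icc.ci_high})
            write_table(pd.DataFrame(icc_rows), out / "table3_report.csv",
                        config.seed)
            log.info("stage=stats n_comparisons=%d n_roc=%d elapsed=%.1fs",
                     len(table4), len(table5), time.time() - t0)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'stats' failed: {exc}") from exc
    return out
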