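"""End-to-end orchestration from a single YAML/dict study config.

A config names, for each of the three inputs (LC volume + masks, one
night of sleep EEG, cohort table), either file paths or a synthetic
generator spec, plus analysis options and a mandatory global seed when
any generator is used.  :func:`run_pipeline` executes the stages in
order — LC contrast, sleep metrics, cohort assembly, statistics — and
writes CSV/JSON outputs plus a run manifest carrying the config hash and
seed, so reruns with an identical config are byte-identical.

Config schema (all sections optional except ``output_dir``)::

    seed: 1                     # mandatory when any 'generate' is used
    output_dir: out
    lc_volume:
      generate: {...LCVolumeSpec fields...}       # or:
      volume_path: vol.nii.gz
      left_mask_path: left.nii.gz
      right_mask_path: right.nii.gz
      ref_centers: {10: [30, 24], ...}            # slice -> [row, col]
      ref_size: 15
    sleep:
      generate:
        hypnogram: {...HypnogramSpec fields...}
        spectrum: {...StageSpectrumSpec fields...}
      # or: eeg_path / channel / hypnogram_path / annotations_path
      swe_stages: [N3]
    cohort:
      generate: {...CohortSpec fields...}         # or: path: cohort.csv
    analysis:
      family: gaussian
      fdr_q: 0.05
      n_boot: 500
      mediation:
        outcome: psqi
        exposure: lc_activity
        mediator: rem_theta_energy
        transform: sqrt
        covariates: [age_group, sex, bmi]
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrast as _contrast
from . import sleep as _sleep
from . import stats as _stats
from . import synthetic as _synthetic

__all__ = ["StudyConfig", "ValidationReport", "validate_inputs", "run_pipeline", "demo_config"]

log = logging.getLogger("lcsleep")

_FLOAT_FMT = "%.10g"  # fixed CSV float format => byte-identical reruns


@dataclass
class StudyConfig:
    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(raw=yaml.safe_load(fh) or {})

    @property
    def seed(self) -> int | None:
        return self.raw.get("seed")

    @property
    def output_dir(self) -> Path | None:
        out = self.raw.get("output_dir")
        return Path(out) if out else None

    def hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_one_source(section: dict, name: str, path_keys: tuple[str, ...], report: ValidationReport) -> None:
    has_gen = "generate" in section
    has_path = any(k in section for k in path_keys)
    if has_gen and has_path:
        report.errors.append(
            f"{name}: specify either 'generate' or file paths, not both"
        )
    if not has_gen and not has_path:
        report.errors.append(f"{name}: needs a 'generate' spec or file paths")


def validate_inputs(config: StudyConfig) -> ValidationReport:
    """Schema, file-existence and cross-input consistency checks.

    Errors abort a run; warnings do not.  All offending keys are listed,
    not just the first.
    """
    report = ValidationReport()
    raw = config.raw
    if config.output_dir is None:
        report.errors.append("missing required key: output_dir")

    uses_generator = False
    for name in ("lc_volume", "sleep", "cohort"):
        if name in raw and isinstance(raw[name], dict) and "generate" in raw[name]:
            uses_generator = True
    if uses_generator and config.seed is None:
        report.errors.append("seed is mandatory when any synthetic generator is used")
    if config.seed is not None and not isinstance(config.seed, int):
        report.errors.append(f"seed must be an integer, got {config.seed!r}")

    if "lc_volume" in raw:
        sec = raw["lc_volume"]
        _check_one_source(sec, "lc_volume", ("volume_path",), report)
        if "volume_path" in sec:
            for key in ("volume_path", "left_mask_path", "right_mask_path"):
                if key not in sec:
                    report.errors.append(f"lc_volume: missing {key}")
                elif not Path(sec[key]).exists():
                    report.errors.append(f"lc_volume: unreadable file {sec[key]}")
            if "ref_centers" not in sec:
                report.errors.append("lc_volume: file inputs need 'ref_centers'")
            if report.ok:
                vol = _contrast.load_volume(sec["volume_path"])
                for key in ("left_mask_path", "right_mask_path"):
                    mask = _contrast.load_mask(sec[key])
                    if mask.shape != vol.data.shape:
                        report.errors.append(
                            f"lc_volume: mask grid {mask.shape} ({key}) does not "
                            f"match volume grid {vol.data.shape}"
                        )

    if "sleep" in raw:
        sec = raw["sleep"]
        _check_one_source(sec, "sleep", ("eeg_path", "hypnogram_path"), report)
        if "eeg_path" in sec or "hypnogram_path" in sec:
            for key in ("eeg_path", "hypnogram_path", "annotations_path"):
                if key not in sec:
                    report.errors.append(f"sleep: missing {key}")
                elif not Path(sec[key]).exists():
                    report.errors.append(f"sleep: unreadable file {sec[key]}")
            if report.ok:
                signal, fs = _sleep.read_eeg(sec["eeg_path"], sec.get("channel"))
                hyp = _sleep.read_hypnogram_csv(sec["hypnogram_path"])
                span = int(round(hyp.duration_seconds * fs))
                if signal.size < span:
                    report.errors.append(
                        f"sleep: EEG length ({signal.size / fs:.0f} s) shorter than "
                        f"hypnogram span ({hyp.duration_seconds:.0f} s)"
                    )

    if "cohort" in raw:
        sec = raw["cohort"]
        _check_one_source(sec, "cohort", ("path",), report)
        if "path" in sec:
            if not Path(sec["path"]).exists():
                report.errors.append(f"cohort: unreadable file {sec['path']}")
            else:
                df = pd.read_csv(sec["path"])
                needed = {"lc_activity", "age_group", "sex", "bmi", *(_stats.PRIMARY_OUTCOMES)}
                missing = sorted(needed - set(df.columns))
                if missing:
                    report.errors.append(f"cohort: missing columns {missing}")

    return report


# ---------------------------------------------------------------------------
# Stage runners


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _run_contrast_stage(sec: dict, seed: int | None, outdir: Path) -> dict:
    if "generate" in sec:
        spec = _synthetic.LCVolumeSpec(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in sec["generate"].items()
        })
        vol, masks, truth = _synthetic.generate_lc_volume(spec, seed=seed + 1)
        centers = dict(spec.ref_center_per_slice)
        ref_size = spec.ref_size
    else:
        vol = _contrast.load_volume(sec["volume_path"])
        masks = {
            "left": _contrast.load_mask(sec["left_mask_path"]),
            "right": _contrast.load_mask(sec["right_mask_path"]),
        }
        centers = {int(k): tuple(v) for k, v in sec["ref_centers"].items()}
        ref_size = int(sec.get("ref_size", 15))
        truth = None

    ref = _contrast.ReferenceRegionSpec(center_per_slice=centers, size_voxels=ref_size)
    results = {}
    rows = []
    for side in ("left", "right"):
        skel = _contrast.skeletonize_lc(vol, masks[side], side)
        res = _contrast.lc_contrast(vol, skel, ref)
        results[side] = res
        for sl, c in zip(res.slice_indices, res.per_slice_contrast):
            rows.append({"side": side, "slice": sl, "contrast": c})
    bilateral = _contrast.bilateral_contrast(results["left"], results["right"])

    pd.DataFrame(rows).to_csv(outdir / "lc_contrast_per_slice.csv", index=False,
                              float_format=_FLOAT_FMT)
    summary = {
        "left": results["left"].side_contrast,
        "right": results["right"].side_contrast,
        "bilateral": bilateral,
    }
    if truth is not None:
        summary["ground_truth"] = truth
    _write_json(summary, outdir / "lc_contrast_summary.json")
    log.info("LC contrast: left=%.4f right=%.4f bilateral=%.4f",
             summary["left"], summary["right"], bilateral)
    return summary


def _run_sleep_stage(sec: dict, seed: int | None, outdir: Path) -> dict:
    if "generate" in sec:
        gen = sec["generate"]
        hspec = _synthetic.HypnogramSpec(**gen.get("hypnogram", {}))
        sspec_kwargs = dict(gen.get("spectrum", {}))
        sspec = _synthetic.StageSpectrumSpec(**sspec_kwargs)
        hyp, ann = _synthetic.generate_hypnogram(hspec, seed=seed + 2)
        signal, _truth = _synthetic.generate_sleep_eeg(hyp, sspec, seed=seed + 3, annotations=ann)
        fs = sspec.sampling_rate
    else:
        signal, fs = _sleep.read_eeg(sec["eeg_path"], sec.get("channel"))
        hyp = _sleep.read_hypnogram_csv(sec["hypnogram_path"])
        ann = _sleep.read_annotations_csv(sec["annotations_path"])

    swe_stages = tuple(sec.get("swe_stages", ("N3",)))
    metrics, bin_series = _sleep.compute_sleep_metrics(
        hyp, ann, signal=signal, sampling_rate=fs, swe_stages=swe_stages
    )
    _write_json(metrics.to_dict(), outdir / "sleep_metrics.json")
    for name, bins in bin_series.items():
        bins.to_csv(outdir / f"bins_{name}.csv", index=False, float_format=_FLOAT_FMT)
    log.info("sleep metrics: TST=%.1f min, SWE=%s, REM theta=%s (SWE stages %s)",
             metrics.tst_minutes, metrics.swe, metrics.rem_theta_energy, swe_stages)
    return metrics.to_dict()


def _run_stats_stage(
    cohort: pd.DataFrame, analysis: dict, seed: int | None, outdir: Path
) -> dict:
    family = analysis.get("family", "gaussian")
    fdr_q = float(analysis.get("fdr_q", 0.05))
    fdr_on = analysis.get("fdr_on", "interaction")
    report = _stats.run_primary_models(
        cohort, family=family, fdr_q=fdr_q, fdr_on=fdr_on
    )
    models = report.pop("_model_objects")
    log.info("primary models fitted (family=%s, FDR on %s at q=%g, critical p=%.4g)",
             family, fdr_on, fdr_q, report["fdr"]["critical_p"])

    slope_rows = []
    for outcome, entry in report["models"].items():
        for group, ss in entry["simple_slopes"].items():
            slope_rows.append({
                "outcome": outcome, "group": group, **ss,
                "interaction_p": entry["term_tests"]["interaction"]["p"],
                "interaction_partial_r2": entry["term_tests"]["interaction"]["partial_r2"],
            })
    pd.DataFrame(slope_rows).to_csv(
        outdir / "simple_slopes.csv", index=False, float_format=_FLOAT_FMT
    )

    med_cfg = analysis.get("mediation")
    if med_cfg:
        med = _stats.mediation_analysis(
            cohort,
            outcome=med_cfg["outcome"],
            exposure=med_cfg["exposure"],
            mediator=med_cfg["mediator"],
            covariates=tuple(med_cfg.get("covariates", ())),
            n_boot=int(analysis.get("n_boot", 1000)),
            seed=(seed or 0) + 5,
            transform=med_cfg.get("transform"),
        )
        report["mediation"] = med.to_dict()
        log.info("mediation: CDE%%=%.1f PIE%%=%.1f (unstable=%s)",
                 med.cde_percent, med.pie_percent, med.unstable)

    sens_cfg = analysis.get("sensitivity", {})
    sens = _stats.sensitivity_min_effect(
        n=int(sens_cfg.get("n", len(cohort))),
        alpha=float(sens_cfg.get("alpha", 0.05)),
        power=float(sens_cfg.get("power", 0.8)),
        sides=int(sens_cfg.get("sides", 1)),
        n_covariates=int(sens_cfg.get("n_covariates", 4)),
    )
    report["sensitivity"] = {
        "n": sens.n, "alpha": sens.alpha, "power": sens.power, "sides": sens.sides,
        "n_covariates": sens.n_covariates,
        "min_detectable_r": sens.min_detectable_r,
        "min_detectable_r2": sens.min_detectable_r2,
    }
    _write_json(report, outdir / "stats_report.json")
    return report


def run_pipeline(config: StudyConfig) -> dict:
    """Validate, run all configured stages in order, write a manifest.

    Raises ``ValueError`` listing every schema violation if validation
    fails; a failing stage aborts the downstream stages.  Returns the
    manifest dict (also written to ``manifest.json``).
    """
    report = validate_inputs(config)
    for w in report.warnings:
        log.warning(w)
    if not report.ok:
        raise ValueError("invalid study config:\n- " + "\n- ".join(report.errors))

    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    raw = config.raw
    manifest: dict = {
        "config_hash": config.hash(),
        "seed": seed,
        "options": {
            "family": raw.get("analysis", {}).get("family", "gaussian"),
            "fdr_q": raw.get("analysis", {}).get("fdr_q", 0.05),
            "fdr_on": raw.get("analysis", {}).get("fdr_on", "interaction"),
            "swe_stages": list(raw.get("sleep", {}).get("swe_stages", ["N3"])),
            "mediation_reference": "covariate-adjusted mediator mean",
        },
        "stages": {},
    }
    log.info("run %s (seed=%s): options %s", manifest["config_hash"], seed, manifest["options"])

    if "lc_volume" in raw:
        manifest["stages"]["lc_contrast"] = _run_contrast_stage(raw["lc_volume"], seed, outdir)
    if "sleep" in raw:
        manifest["stages"]["sleep_metrics"] = _run_sleep_stage(raw["sleep"], seed, outdir)

    if "cohort" in raw:
        sec = raw["cohort"]
        if "generate" in sec:
            spec = _synthetic.CohortSpec(**sec["generate"])
            cohort, truth = _synthetic.generate_cohort(spec, seed=seed + 4)
            manifest["stages"]["cohort"] = {"n": len(cohort), "ground_truth": truth}
        else:
            cohort = pd.read_csv(sec["path"])
            manifest["stages"]["cohort"] = {"n": len(cohort), "source": str(sec["path"])}
        cohort.to_csv(outdir / "cohort.csv", index=False, float_format=_FLOAT_FMT)

        stats_report = _run_stats_stage(cohort, raw.get("analysis", {}), seed, outdir)
        manifest["stages"]["statistics"] = {
            "fdr": stats_report["fdr"],
            "sensitivity": stats_report["sensitivity"],
        }

    _write_json(manifest, outdir / "manifest.json")
    return manifest


def demo_config(output_dir, seed: int = 7) -> dict:
    """A small self-contained synthetic study config (all three stages)."""
    return {
        "seed": seed,
        "output_dir": str(output_dir),
        "lc_volume": {
            "generate": {
                "lc_intensity": 120.0,
                "background_intensity": 100.0,
                "noise_sd": 0.5,
            }
        },
        "sleep": {
            "generate": {
                "hypnogram": {
                    "time_in_bed_minutes": 120.0,
                    "sleep_onset_epoch": 10,
                    "arousal_rate_per_hour": 5.0,
                    "artifact_fraction": 0.02,
                },
                "spectrum": {},
            },
            "swe_stages": ["N3"],
        },
        "cohort": {
            "generate": {
                "n_young": 33,
                "n_old": 19,
                "slope_young": 0.0,
                "slope_old": 1.0,
                "a": 0.5,
                "b": 0.4,
            }
        },
        "analysis": {
            "family": "gaussian",
            "fdr_q": 0.05,
            "n_boot": 500,
            "mediation": {
                "outcome": "psqi",
                "exposure": "lc_activity",
                "mediator": "rem_theta_energy",
                "transform": "sqrt",
                "covariates": ["sex", "bmi"],
            },
        },
    }
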