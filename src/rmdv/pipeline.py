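"""End-to-end orchestration: simulate -> measure -> classify -> evaluate.

A run writes, into its output directory: the cohort CSV, per-case NIfTI
images and masks with a JSON manifest, the measurement CSV, the
classification CSV, the diagnostic report JSON, the group-comparison table
CSV, the three-point ROC CSV, the resolved run config (YAML) and a log.
Re-running with the same config and seed reproduces byte-identical tabular
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, apply_enrollment_filter, sample_cohort
from .core import adjudicate_followup, classify_rmdv, compute_rmdv, measure_case
from .diagnostics import CE, HT, build_table, diagnostic_summary, roc_points
from .errors import ConfigurationError, RmdvError, SchemaError
from .io import read_csv, save_mask, save_slice, write_csv
from .phantom import PhantomSpec, render_case
from .tableone import table_one, table_one_frame

logger = logging.getLogger("rmdv")

__all__ = ["RunConfig", "run_pipeline", "evaluate_only"]


@dataclass
class MeasurementParams:
    """Tunable densitometry parameters (all in HU or pixels)."""

    min_excess: float = 5.0
    min_area: int = 5
    hu_tolerance: float = 5.0
    skull_hu_threshold: float = 200.0
    exclusion_dilation: float = 2.0
    elimination_excess: float = 5.0


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    measurement: MeasurementParams = field(default_factory=MeasurementParams)
    seed: int = 0
    exact_counts: bool = True
    save_images: bool = True

    def to_dict(self) -> dict:
        d = {
            "cohort": {
                k: v
                for k, v in dataclasses.asdict(self.cohort).items()
                if k != "covariate_freqs"
            },
            "phantom": dataclasses.asdict(self.phantom),
            "measurement": dataclasses.asdict(self.measurement),
            "seed": self.seed,
            "exact_counts": self.exact_counts,
            "save_images": self.save_images,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, payload):
            if payload is None:
                return klass()
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(payload) - names
            if bad:
                raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
            kwargs = {
                k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
            }
            return klass(**kwargs)

        known = {"cohort", "phantom", "measurement", "seed", "exact_counts", "save_images"}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(
            cohort=build(CohortConfig, d.get("cohort")),
            phantom=build(PhantomSpec, d.get("phantom")),
            measurement=build(MeasurementParams, d.get("measurement")),
            seed=int(d.get("seed", 0)),
            exact_counts=bool(d.get("exact_counts", True)),
            save_images=bool(d.get("save_images", True)),
        )

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _case_seed(seed: int, index: int) -> int:
    """Per-case substream seed, stable across runs."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0])


def _record_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "excluded_artifact": r.excluded_artifact,
            "excluded_no_immediate": r.excluded_no_immediate,
            "excluded_no_followup": r.excluded_no_followup,
            "enrolled": r.enrolled,
            "has_pchd": r.has_pchd,
            "true_outcome": r.true_outcome or "",
            "rmdv_positive": "" if r.rmdv_positive is None else bool(r.rmdv_positive),
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir: Path, force: bool = False) -> Path:
    """Execute the full pipeline into ``out_dir`` and return that path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "report.json"
    if report_path.exists() and not force:
        raise RmdvError(
            f"{report_path} already exists; pass force=True (--force) to overwrite"
        )
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        return _run(config, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> Path:
    seed, version = config.seed, __version__
    config.to_yaml(out_dir / "config.yaml")
    logger.info("seed=%d version=%s", seed, version)

    records = sample_cohort(config.cohort, seed=seed, exact_counts=config.exact_counts)
    write_csv(out_dir / "cohort.csv", _record_frame(records), seed, version)
    enrolled = apply_enrollment_filter(records, config.cohort)
    analysis = [r for r in enrolled if r.has_pchd]
    logger.info(
        "screened=%d enrolled=%d pchd=%d", len(records), len(enrolled), len(analysis)
    )
    if not analysis:
        logger.warning("empty PCHD analysis set; writing empty outputs")
        for name in ("measurements.csv", "classification.csv"):
            write_csv(out_dir / name, pd.DataFrame(), seed, version)
        report_payload = {
            "meta": {"seed": seed, "version": version},
            "n_cases": 0,
            "warning": "empty PCHD analysis set",
        }
        (out_dir / "report.json").write_text(json.dumps(report_payload, indent=2))
        return out_dir

    img_dir = out_dir / "images"
    if config.save_images:
        img_dir.mkdir(exist_ok=True)
    m = config.measurement
    manifest = {"midline": config.phantom.midline, "cases": []}
    meas_rows, class_rows = [], []
    predictions: dict[str, str] = {}
    outcomes: dict[str, str] = {}

    for i, rec in enumerate(analysis):
        case = render_case(rec, config.phantom, seed=_case_seed(seed, i))
        if config.save_images:
            stem = rec.patient_id
            save_slice(img_dir / f"{stem}_immediate.nii.gz", case.immediate)
            if case.followup is not None:
                save_slice(img_dir / f"{stem}_followup.nii.gz", case.followup)
            save_mask(img_dir / f"{stem}_sinus.nii.gz", case.sinus_mask,
                      case.immediate.spacing)
            save_mask(img_dir / f"{stem}_brain.nii.gz", case.immediate.brain_mask,
                      case.immediate.spacing)
            manifest["cases"].append(
                {"patient_id": stem, "has_followup": case.followup is not None}
            )
        result = measure_case(
            case,
            min_excess=m.min_excess,
            min_area=m.min_area,
            hu_tolerance=m.hu_tolerance,
            skull_hu_threshold=m.skull_hu_threshold,
            exclusion_dilation=m.exclusion_dilation,
        )
        if result is None:
            logger.warning("no hyperdensity detected for %s; skipped", rec.patient_id)
            continue
        measurement, region = result
        label = adjudicate_followup(case, region, elimination_excess=m.elimination_excess)
        rec.true_outcome = label.outcome  # follow-up adjudication defines the outcome
        predictions[rec.patient_id] = measurement.predicted
        outcomes[rec.patient_id] = label.outcome
        meas_rows.append(
            {
                "patient_id": rec.patient_id,
                "lesion_max_hu": measurement.lesion_max_hu,
                "sinus_max_hu": measurement.sinus_max_hu,
                "lesion_argmax_row": region.argmax[0],
                "lesion_argmax_col": region.argmax[1],
                "lesion_area_px": region.area,
                "contralateral_excess_hu": round(region.contralateral_excess, 2),
            }
        )
        class_rows.append(
            {
                "patient_id": rec.patient_id,
                "rmdv": round(measurement.rmdv, 4),
                "predicted": measurement.predicted,
                "outcome": label.outcome,
                "residual_excess_hu": label.residual_excess_hu,
            }
        )

    write_csv(out_dir / "measurements.csv", pd.DataFrame(meas_rows), seed, version)
    write_csv(out_dir / "classification.csv", pd.DataFrame(class_rows), seed, version)
    if config.save_images:
        (img_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    table = build_table(predictions, outcomes)
    report = diagnostic_summary(table)
    payload = report.to_dict()
    payload["meta"] = {"seed": seed, "version": version, "n_cases": table.n}
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    measured = [r for r in analysis if r.patient_id in outcomes]
    rows = table_one(measured, predictions=predictions)
    write_csv(out_dir / "table_one.csv", table_one_frame(rows), seed, version)
    roc = pd.DataFrame(roc_points(table), columns=["fpr", "tpr"])
    write_csv(out_dir / "roc.csv", roc, seed, version)
    logger.info("report: %s", report.to_json())
    return out_dir


def evaluate_only(measurements: Path, outcomes: Path):
    """Diagnostics from user-supplied CSVs, bypassing the imaging stages.

    ``measurements`` needs ``patient_id`` plus either ``lesion_max_hu`` and
    ``sinus_max_hu``, or ``rmdv``, or a ``predicted`` HT/CE label.
    ``outcomes`` needs ``patient_id`` and ``outcome``.  Returns the
    :class:`~rmdv.diagnostics.DiagnosticReport`.
    """
    meas = read_csv(measurements, required=("patient_id",))
    outc = read_csv(outcomes, required=("patient_id", "outcome"))

    predictions: dict[str, str] = {}
    for i, row in meas.iterrows():
        pid = str(row["patient_id"])
        try:
            if {"lesion_max_hu", "sinus_max_hu"} <= set(meas.columns):
                ratio = compute_rmdv(float(row["lesion_max_hu"]), float(row["sinus_max_hu"]))
            elif "rmdv" in meas.columns:
                ratio = float(row["rmdv"])
            elif "predicted" in meas.columns:
                label = str(row["predicted"])
                if label not in (HT, CE):
                    raise ValueError(f"bad label {label!r}")
                predictions[pid] = label
                continue
            else:
                raise SchemaError(
                    "measurements need lesion_max_hu+sinus_max_hu, rmdv, or predicted"
                )
        except SchemaError:
            raise
        except (ValueError, RmdvError) as exc:
            raise SchemaError(f"malformed measurement row {i} ({pid}): {exc}") from exc
        predictions[pid] = classify_rmdv(ratio)

    outcome_map: dict[str, str] = {}
    for i, row in outc.iterrows():
        pid, lab = str(row["patient_id"]), str(row["outcome"])
        if lab not in (HT, CE):
            raise SchemaError(f"malformed outcome row {i} ({pid}): {lab!r}")
        outcome_map[pid] = lab

    table = build_table(predictions, outcome_map)
    return diagnostic_summary(table)
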