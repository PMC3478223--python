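"""Pipeline orchestration: per-nucleus feature extraction and cohort stats.

These functions back the CLI but are importable on their own.  All outputs
are CSV, written with a fixed float format so reruns under the same inputs
are byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import NucleusImage, PatientRecord
from .errors import ValidationError
from .fractal import DEFAULT_EPS_MAX, fractal_dimension
from .glcm import compute_glcm, glcm_features
from .io import load_nucleus
from .morphometry import morphometry
from .stats import (
    DEFAULT_MIN_NUCLEI,
    aggregate_cohort,
    cohort_report,
    cox_stratified,
    cox_univariate,
)

log = logging.getLogger("karyotex")

FEATURE_COLUMNS = [
    "area_um2",
    "form_factor",
    "mean_gray",
    "sd_gray",
    "entropy",
    "contrast",
    "local_homogeneity",
    "cluster_prominence",
    "fd",
    "r2",
]

_FLOAT_FORMAT = "%.10g"


@dataclass
class FeatureOptions:
    calibration: float = 0.1
    glcm_log_base: float = 2.0
    eps_max: int = DEFAULT_EPS_MAX
    fd_normalization: str = "sausage"


@dataclass
class StatsOptions:
    grouping: str = "group"
    strata: str = "group"
    min_nuclei: int = DEFAULT_MIN_NUCLEI
    ci_level: float = 0.95


def nucleus_features(nucleus: NucleusImage, options: FeatureOptions | None = None) -> dict:
    """The ten per-nucleus features as a flat dict."""
    options = options or FeatureOptions()
    morph = morphometry(nucleus)
    texture = glcm_features(compute_glcm(nucleus), log_base=options.glcm_log_base)
    series = fractal_dimension(
        nucleus, eps_max=options.eps_max, normalization=options.fd_normalization
    )
    return {
        "area_um2": morph.area_um2,
        "form_factor": morph.form_factor,
        "mean_gray": morph.mean_gray,
        "sd_gray": morph.sd_gray,
        "entropy": texture.entropy,
        "contrast": texture.contrast,
        "local_homogeneity": texture.local_homogeneity,
        "cluster_prominence": texture.cluster_prominence,
        "fd": series.fd,
        "r2": series.r2,
    }


def run_features(
    manifest_path: str | Path,
    out_path: str | Path,
    options: FeatureOptions | None = None,
    resume: bool = False,
    keep_going: bool = False,
) -> pd.DataFrame:
    """Compute the feature CSV (one row per manifest nucleus).

    With ``resume`` rows already present in ``out_path`` are kept.  A
    failing image is logged and marked in the ``status`` column; unless
    ``keep_going`` is set the first failure raises at the end.
    """
    options = options or FeatureOptions()
    manifest = pd.read_csv(manifest_path)
    required = {"patient_id", "nucleus_id", "image_path", "mask_path"}
    if not required.issubset(manifest.columns):
        raise ValidationError(f"manifest must have columns {sorted(required)}")
    out_path = Path(out_path)
    done: dict[str, dict] = {}
    if resume and out_path.exists():
        for _, row in pd.read_csv(out_path).iterrows():
            done[str(row["nucleus_id"])] = row.to_dict()
    manifest_dir = Path(manifest_path).parent

    def _resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else manifest_dir / path

    rows = []
    failures = []
    for _, entry in manifest.iterrows():
        nid = str(entry["nucleus_id"])
        if nid in done:
            rows.append(done[nid])
            continue
        row = {"patient_id": entry["patient_id"], "nucleus_id": nid}
        try:
            nucleus = load_nucleus(
                _resolve(entry["image_path"]),
                _resolve(entry["mask_path"]),
                calibration=options.calibration,
                patient_id=str(entry["patient_id"]),
                nucleus_id=nid,
            )
            row.update(nucleus_features(nucleus, options))
            row["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - per-row error containment
            log.error("nucleus %s failed: %s", nid, exc)
            row.update({c: np.nan for c in FEATURE_COLUMNS})
            row["status"] = "failed"
            failures.append(nid)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["patient_id", "nucleus_id", *FEATURE_COLUMNS, "status"])
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False, float_format=_FLOAT_FORMAT)
    if failures and not keep_going:
        raise ValidationError(f"{len(failures)} nuclei failed: {failures[:5]}")
    return table


def _patient_records(
    patient_medians: pd.DataFrame, patients: pd.DataFrame
) -> list[PatientRecord]:
    records = []
    for pid, row in patients.set_index("patient_id").iterrows():
        medians = (
            patient_medians.loc[pid].to_dict() if pid in patient_medians.index else {}
        )
        covars = {
            k: float(v)
            for k, v in row.items()
            if k not in ("time", "event") and np.isreal(v) and not pd.isna(v)
        }
        records.append(
            PatientRecord(
                patient_id=str(pid),
                covariates=covars,
                time=float(row["time"]),
                event=int(row["event"]),
                feature_medians={k: float(v) for k, v in medians.items()},
            )
        )
    return records


def run_stats(
    features_path: str | Path,
    patients_path: str | Path,
    outdir: str | Path,
    options: StatsOptions | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Aggregate features and emit the report CSVs plus run metadata."""
    options = options or StatsOptions()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features = pd.read_csv(features_path)
    patients = pd.read_csv(patients_path)
    if patients.empty:
        raise ValidationError("patients table is empty")
    if "status" in features.columns:
        features = features[features["status"] == "ok"]
    feat_ids = set(features["patient_id"].astype(str))
    pat_ids = set(patients["patient_id"].astype(str))
    orphans = sorted(feat_ids ^ pat_ids)
    if orphans:
        raise ValidationError(f"feature/patient id mismatch: {orphans}")

    medians = aggregate_cohort(
        features.drop(columns=["status"], errors="ignore"),
        min_nuclei=options.min_nuclei,
    )
    comparison, correlations = cohort_report(
        medians, patients, grouping=options.grouping
    )
    records = _patient_records(medians, patients)
    cox_rows = []
    covariates = ["leukocyte_count", *FEATURE_COLUMNS]
    for cov in covariates:
        for stratified in (False, True):
            try:
                if stratified:
                    res = cox_stratified(records, cov, strata=options.strata)
                else:
                    res = cox_univariate(records, cov)
                cox_rows.append(
                    {
                        "covariate": cov,
                        "B": res.coefficient,
                        "p": res.p_value,
                        "stratified": stratified,
                        "converged": res.converged,
                    }
                )
            except ValidationError as exc:
                log.warning("cox %s (stratified=%s): %s", cov, stratified, exc)
    paths = {
        "comparison": outdir / "group_comparison.csv",
        "correlations": outdir / "correlations.csv",
        "cox": outdir / "cox.csv",
        "medians": outdir / "patient_medians.csv",
        "metadata": outdir / "run_metadata.json",
    }
    comparison.to_csv(paths["comparison"], index=False, float_format=_FLOAT_FORMAT)
    correlations.to_csv(paths["correlations"], index=False, float_format=_FLOAT_FORMAT)
    pd.DataFrame(cox_rows).to_csv(paths["cox"], index=False, float_format=_FLOAT_FORMAT)
    medians.to_csv(paths["medians"], float_format=_FLOAT_FORMAT)
    metadata = {
        "version": __version__,
        "seed": seed,
        "options": {
            "grouping": options.grouping,
            "strata": options.strata,
            "min_nuclei": options.min_nuclei,
            "ci_level": options.ci_level,
        },
        "inputs": {"features": str(features_path), "patients": str(patients_path)},
        "python": sys.version.split()[0],
    }
    paths["metadata"].write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    return paths
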