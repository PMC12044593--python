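"""Readers/writers for response tables, spectra, classifiers and run reports.

CSV is the interchange format throughout (UTF-8, '.' decimal, mandatory
header row). Two response-table layouts are supported:

* long — columns ``sensor_id,analyte,replicate,response``
* wide — columns ``analyte,replicate,<sensor id>,...``

Classifiers serialize to JSON, elimination traces to a per-iteration CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import VoronoiClassifier
from .core import (ACFSAConfig, EliminationTrace, PCAModel, ResponseTable,
                   StoppingCondition)
from .errors import ValidationError
from .spectra import Spectrum

__all__ = [
    "read_response_table",
    "write_response_table",
    "read_spectra_manifest",
    "write_spectrum",
    "write_trace_report",
    "classifier_to_dict",
    "classifier_from_dict",
    "write_classifier",
    "read_classifier",
]

LONG_COLUMNS = ["sensor_id", "analyte", "replicate", "response"]


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"cannot parse CSV {path}: {exc}") from exc


def read_response_table(path: str | Path, layout: str = "auto") -> ResponseTable:
    """Read and validate a ResponseTable CSV (long, wide, or auto-detected)."""
    df = _read_csv(path)
    if layout == "auto":
        layout = "long" if list(df.columns[:4]) == LONG_COLUMNS else "wide"
    if layout == "long":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"long layout lacks columns: {missing}")
        dup = df.duplicated(subset=["sensor_id", "analyte", "replicate"])
        if dup.any():
            rows = df.loc[dup, ["sensor_id", "analyte", "replicate"]]
            raise ValidationError(
                f"duplicate (sensor, analyte, replicate) keys: "
                f"{rows.values.tolist()[:5]}"
            )
        resp = pd.to_numeric(df["response"], errors="coerce")
        if resp.isna().any():
            bad = df.loc[resp.isna(), LONG_COLUMNS].values.tolist()
            raise ValidationError(f"non-numeric responses at: {bad[:5]}")
        wide = df.pivot(index=["analyte", "replicate"], columns="sensor_id",
                        values="response")
        if wide.isna().any().any():
            missing_cells = [
                (c, *i) for c in wide.columns for i in wide.index[wide[c].isna()]
            ]
            raise ValidationError(
                f"missing (sensor, analyte, replicate) cells: {missing_cells[:10]}"
            )
        wide.columns.name = None
        table = ResponseTable(wide)
    elif layout == "wide":
        if list(df.columns[:2]) != ["analyte", "replicate"]:
            raise ValidationError(
                "wide layout must start with columns 'analyte,replicate'"
            )
        sensors = list(df.columns[2:])
        if not sensors:
            raise ValidationError("wide layout has no sensor columns")
        for c in sensors:
            vals = pd.to_numeric(df[c], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna(), ["analyte", "replicate"]].values.tolist()
                raise ValidationError(
                    f"non-numeric responses in sensor {c!r} at: {bad[:5]}")
        table = ResponseTable(df.set_index(["analyte", "replicate"]))
    else:
        raise ValidationError(f"unknown layout {layout!r}")
    table.check_complete()
    return table


def write_response_table(table: ResponseTable, path: str | Path,
                         layout: str = "wide") -> None:
    path = Path(path)
    if layout == "wide":
        table.data.reset_index().to_csv(path, index=False)
    elif layout == "long":
        long = (table.data.stack().rename("response").reset_index())
        long.columns = ["analyte", "replicate", "sensor_id", "response"]
        long[LONG_COLUMNS].to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# Spectra


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column ``wavelength_nm,intensity`` CSV."""
    pd.DataFrame({"wavelength_nm": spectrum.wavelength_nm,
                  "intensity": spectrum.intensity}).to_csv(path, index=False)


def read_spectra_manifest(manifest_path: str | Path) -> list[Spectrum]:
    """Read a manifest CSV (columns ``file,sensor_id,analyte,replicate,
    excitation_nm``; paths relative to the manifest) and load every
    spectrum file."""
    manifest_path = Path(manifest_path)
    mdf = _read_csv(manifest_path)
    required = ["file", "sensor_id", "analyte", "replicate", "excitation_nm"]
    missing = [c for c in required if c not in mdf.columns]
    if missing:
        raise ValidationError(f"manifest lacks columns: {missing}")
    spectra = []
    for _, row in mdf.iterrows():
        sdf = _read_csv(manifest_path.parent / str(row["file"]))
        if list(sdf.columns[:2]) != ["wavelength_nm", "intensity"]:
            raise ValidationError(
                f"spectrum file {row['file']!r} must have columns "
                "'wavelength_nm,intensity'"
            )
        spectra.append(Spectrum(
            wavelength_nm=sdf["wavelength_nm"].to_numpy(float),
            intensity=sdf["intensity"].to_numpy(float),
            excitation_nm=float(row["excitation_nm"]),
            sensor_id=str(row["sensor_id"]),
            analyte=str(row["analyte"]),
            replicate=int(row["replicate"]),
        ))
    return spectra


# ---------------------------------------------------------------------------
# Classifier JSON


def classifier_to_dict(clf: VoronoiClassifier) -> dict:
    return {
        "sensor_ids": list(clf.sensor_ids),
        "labels": list(clf.labels),
        "centers": clf.centers.tolist(),
        "pca": {
            "mean": clf.pca.mean.tolist(),
            "scale": clf.pca.scale.tolist(),
            "loadings": clf.pca.loadings.tolist(),
            "explained_variance": clf.pca.explained_variance.tolist(),
            "explained_variance_ratio":
                clf.pca.explained_variance_ratio.tolist(),
            "degenerate": clf.pca.degenerate,
        },
        "gaussian_means": clf.gaussian_means.tolist(),
        "gaussian_covs": clf.gaussian_covs.tolist(),
        "distance_matrix": clf.distance_matrix.tolist(),
        "mean_intercluster_distance": clf.mean_intercluster_distance,
        "classification_error": clf.classification_error,
        "error_se": clf.error_se,
    }


def classifier_from_dict(d: dict) -> VoronoiClassifier:
    pca = PCAModel(
        mean=np.asarray(d["pca"]["mean"], float),
        scale=np.asarray(d["pca"]["scale"], float),
        loadings=np.asarray(d["pca"]["loadings"], float),
        explained_variance=np.asarray(d["pca"]["explained_variance"], float),
        explained_variance_ratio=np.asarray(
            d["pca"]["explained_variance_ratio"], float),
        degenerate=bool(d["pca"]["degenerate"]),
    )
    clf = VoronoiClassifier(
        centers=np.asarray(d["centers"], float),
        labels=tuple(d["labels"]),
        pca=pca,
        sensor_ids=tuple(d["sensor_ids"]),
        gaussian_means=np.asarray(d["gaussian_means"], float),
        gaussian_covs=np.asarray(d["gaussian_covs"], float),
    )
    clf.classification_error = d.get("classification_error")
    clf.error_se = d.get("error_se")
    return clf


def write_classifier(clf: VoronoiClassifier, path: str | Path) -> None:
    Path(path).write_text(json.dumps(classifier_to_dict(clf), indent=1),
                          encoding="utf-8")


def read_classifier(path: str | Path) -> VoronoiClassifier:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    return classifier_from_dict(json.loads(path.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Trace report


def trace_to_frame(trace: EliminationTrace) -> pd.DataFrame:
    """Per-iteration summary table of an elimination run."""
    rows = []
    for rec in trace.records:
        rows.append({
            "iteration": rec.iteration,
            "n_sensors": rec.n_sensors,
            "sensors": ";".join(rec.sensors),
            "chi2_scores": json.dumps(
                {s: rec.chi2_scores[s] for s in rec.sensors}),
            "eliminated": rec.eliminated if rec.eliminated is not None else "",
            "eliminated_score": (rec.chi2_scores[rec.eliminated]
                                 if rec.eliminated is not None else np.nan),
            "ari": rec.ari,
            "mean_intercluster_distance": rec.mean_intercluster_distance,
            "error": rec.error,
            "error_se": rec.error_se,
        })
    return pd.DataFrame(rows)


def write_trace_report(trace: EliminationTrace, outdir: str | Path,
                       plots: bool = False) -> dict[str, Path]:
    """Write ``trace.csv`` and ``classifier.json`` (the selected set's
    classifier) into ``outdir``; optionally a PC-scatter/Voronoi figure."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"trace": outdir / "trace.csv",
                 "classifier": outdir / "classifier.json"}
        trace_to_frame(trace).to_csv(paths["trace"], index=False)
        write_classifier(trace.final_classifier, paths["classifier"])
    except OSError as exc:
        raise ValidationError(f"cannot write report to {outdir}: {exc}") from exc
    if plots:
        paths["plot"] = outdir / "voronoi.png"
        _plot_classifier(trace, paths["plot"])
    return paths


def _plot_classifier(trace: EliminationTrace, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec = trace.selected if trace.selected is not None else trace.records[-1]
    clf = rec.classifier
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, lab in enumerate(clf.labels):
        ax.scatter(*clf.centers[i], marker="x", s=60, label=lab)
    ax.legend(fontsize=7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"Voronoi centers, {rec.n_sensors} sensors")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_config_from_json(path: str | Path) -> tuple[ACFSAConfig, StoppingCondition]:
    """Load an ACFSAConfig + StoppingCondition from a config JSON file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    d = json.loads(path.read_text(encoding="utf-8"))
    stop_d = d.pop("stopping", {})
    cfg_fields = {f for f in ACFSAConfig.__dataclass_fields__}
    unknown = set(d) - cfg_fields
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return ACFSAConfig(**d), StoppingCondition(**stop_d)
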