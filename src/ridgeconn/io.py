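"""Plain-text serialization: subject TSVs, phenotype CSV, matrices, JSON.

The pipeline starts from ROI time series, so every artifact is a TSV/CSV/
JSON file: one TSV per subject (timepoints x labelled ROI columns), a
phenotype CSV, ROI-labelled connectivity TSVs with a JSON sidecar, long
format metric curves, and wide AUC feature tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, TimeSeriesMatrix
from .graph_metrics import MetricCurve
from .synthetic_cohort import Cohort

__all__ = [
    "write_cohort",
    "read_timeseries_dir",
    "write_connectivity",
    "read_connectivity",
    "write_metric_curves",
    "read_metric_curves",
    "write_json",
]

_FLOAT_FMT = "%.10g"


def write_json(obj: dict, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_cohort(cohort: Cohort, out_dir: Path) -> None:
    """Write one TSV per subject, the phenotype CSV and ground-truth JSON."""
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for subj in cohort.subjects:
        df = pd.DataFrame(subj.values, columns=list(subj.node_labels))
        df.to_csv(ts_dir / f"{subj.subject_id}.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
    cohort.phenotypes.to_csv(out_dir / "phenotypes.csv", index=False,
                             float_format=_FLOAT_FMT)
    gt = cohort.ground_truth
    write_json(
        {
            "seed": gt.seed,
            "planted_edges": [
                {"i": e.i, "j": e.j, "delta": e.delta} for e in gt.planted_edges
            ],
            "n_nodes": cohort.config.n_nodes,
            "n_per_group": cohort.config.n_per_group,
            "n_timepoints": cohort.config.n_timepoints,
            "ar_coeff": cohort.config.ar_coeff,
        },
        out_dir / "ground_truth.json",
    )


def read_timeseries_dir(path: Path) -> list[TimeSeriesMatrix]:
    """Load all per-subject TSVs from a directory, sorted by subject id.

    All files must carry the same ROI labels; a file whose columns are in a
    different order is realigned by label against the first subject.
    Missing or non-numeric cells are an error, never imputed.
    """
    path = Path(path)
    files = sorted(path.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no subject TSVs under {path}")
    subjects = []
    reference: list[str] | None = None
    ref_name = ""
    for f in files:
        df = pd.read_csv(f, sep="\t")
        labels = list(df.columns)
        if reference is None:
            reference, ref_name = labels, f.name
        elif set(labels) != set(reference):
            raise ValueError(f"ROI header mismatch between {ref_name} and {f.name}")
        else:
            df = df[reference]
        if df.isna().any().any():
            row, col = next(
                (r, c) for c in df.columns for r in df.index[df[c].isna()]
            )
            raise ValueError(f"missing value in {f.name} at row {row}, column {col!r}")
        values = df.to_numpy(dtype=float)
        subjects.append(TimeSeriesMatrix(values, tuple(reference), f.stem))
    return subjects


def write_connectivity(cm: ConnectivityMatrix, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(cm.z_values, index=list(cm.node_labels), columns=list(cm.node_labels))
    df.to_csv(out_dir / f"{cm.subject_id}_connectivity.tsv", sep="\t",
              float_format="%.12g")
    write_json({"subject_id": cm.subject_id, "alpha": cm.alpha},
               out_dir / f"{cm.subject_id}_connectivity.json")


def read_connectivity(out_dir: Path, subject_id: str) -> ConnectivityMatrix:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / f"{subject_id}_connectivity.tsv", sep="\t", index_col=0)
    meta = json.loads((out_dir / f"{subject_id}_connectivity.json").read_text())
    return ConnectivityMatrix(
        z_values=df.to_numpy(dtype=float),
        alpha=meta["alpha"],
        node_labels=tuple(df.columns),
        subject_id=subject_id,
    )


def write_metric_curves(
    subject_curves: dict[str, dict[str, MetricCurve]], path: Path
) -> None:
    """Long-format TSV: subject, attribute, sparsity, value."""
    rows = []
    for sid, curves in subject_curves.items():
        for name, curve in curves.items():
            for s, v in zip(curve.sparsities, curve.values):
                rows.append((sid, name, s, v))
    df = pd.DataFrame(rows, columns=["subject_id", "attribute", "sparsity", "value"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_metric_curves(path: Path) -> dict[str, dict[str, MetricCurve]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, MetricCurve]] = {}
    for (sid, name), block in df.groupby(["subject_id", "attribute"], sort=False):
        block = block.sort_values("sparsity")
        out.setdefault(sid, {})[name] = MetricCurve(
            block["sparsity"].to_numpy(), block["value"].to_numpy(), name, sid
        )
    return out
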