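"""Plain-text, versioned readers and writers for every pipeline artifact.

All tables are tab-separated with one header row.  Parsing is strict:
duplicate labels, ragged rows, non-numeric or missing cells are errors
naming the offending label or line — never silently imputed.  The frozen
signature model is serialized as JSON whose floats round-trip binary64
exactly (Python's shortest-repr float formatting).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .bootstrap import BootstrapReport
from .datatypes import CohortDesign, normalize_group, validate_expression
from .signature import RocResult, SignatureModel
from .syndata import QpcrBatch

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the full analysis, as read from a YAML config."""

    variance_fraction: float = 0.10
    alpha_report: float = 0.05
    alpha_select: float = 0.01
    bootstrap_iterations: int = 30_000
    bootstrap_mode: str = "percentile"
    seed: int = 0
    refilter_in_bootstrap: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_fraction <= 1.0):
            raise ValueError(f"variance_fraction must be in (0, 1], got {self.variance_fraction!r}")
        if self.alpha_select > self.alpha_report:
            raise ValueError("alpha_select must be <= alpha_report")
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be >= 1")
        if self.bootstrap_mode not in ("percentile", "optimism"):
            raise ValueError(f"unknown bootstrap_mode {self.bootstrap_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def matrix_fingerprint(matrix: pd.DataFrame) -> str:
    """Stable sha256 fingerprint of labels plus values."""
    h = hashlib.sha256()
    h.update("\x1f".join(map(str, matrix.index)).encode())
    h.update("\x1e".encode())
    h.update("\x1f".join(map(str, matrix.columns)).encode())
    h.update(np.ascontiguousarray(matrix.to_numpy(dtype=float)).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# expression matrices

def _parse_table(path) -> tuple[list, list, list]:
    """Split a TSV into (header labels, row labels, row string-fields)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header row and at least one data row")
    header = lines[0].split("\t")
    n_fields = len(header)
    row_labels, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != n_fields:
            raise ValueError(
                f"{path}: line {lineno}: ragged row ({len(fields)} fields, "
                f"expected {n_fields})"
            )
        row_labels.append(fields[0])
        rows.append(fields[1:])
    return header[1:], row_labels, rows


def read_expression(path, orientation: str = "samples_by_genes") -> pd.DataFrame:
    """Read an expression TSV into samples x genes orientation.

    ``orientation`` names the on-disk layout; the returned matrix is
    always samples x genes with labels preserved verbatim.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    col_labels, row_labels, rows = _parse_table(path)
    for labels, what in ((col_labels, "column"), (row_labels, "row")):
        seen = set()
        for lab in labels:
            if lab in seen:
                raise ValueError(f"{path}: duplicate {what} label {lab!r}")
            seen.add(lab)
    values = np.empty((len(row_labels), len(col_labels)))
    for i, fields in enumerate(rows):
        for j, cell in enumerate(fields):
            if cell == "" or cell.upper() in ("NA", "NAN"):
                raise ValueError(
                    f"{path}: line {i + 2}: missing value for {col_labels[j]!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: line {i + 2}: non-numeric cell {cell!r} "
                    f"under {col_labels[j]!r}"
                ) from None
    matrix = pd.DataFrame(values, index=row_labels, columns=col_labels)
    if orientation == "genes_by_samples":
        matrix = matrix.T
    return validate_expression(matrix)


def write_expression(
    matrix: pd.DataFrame, path, orientation: str = "samples_by_genes"
) -> None:
    validate_expression(matrix)
    out = matrix if orientation == "samples_by_genes" else matrix.T
    label = "sample_id" if orientation == "samples_by_genes" else "gene_id"
    out.to_csv(path, sep="\t", index_label=label)


# ---------------------------------------------------------------------------
# cohort designs

def read_design(path) -> CohortDesign:
    """Read a design TSV (sample_id, group, pair_id); groups are accepted
    case-insensitively and normalized."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "group", "pair_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column {missing[0]!r}")
    df["group"] = df["group"].map(normalize_group)
    return CohortDesign(df.set_index("sample_id")[["group", "pair_id"]])


def write_design(design: CohortDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# signature models

def write_model(model: SignatureModel, path) -> None:
    """Serialize a frozen model; floats survive the round trip bit-exactly."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "intercept": model.intercept,
        "genes": model.gene_ids,
        "coefficients": {g: model.coefficients[g] for g in model.gene_ids},
        "converged": model.converged,
        "separation_flag": model.separation_flag,
        "collinearity_flag": model.collinearity_flag,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model(path) -> SignatureModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    genes = payload["genes"]
    coefs = payload["coefficients"]
    missing = [g for g in genes if g not in coefs]
    if missing:
        raise ValueError(f"{path}: coefficient missing for gene {missing[0]!r}")
    return SignatureModel(
        intercept=float(payload["intercept"]),
        coefficients={g: float(coefs[g]) for g in genes},
        metadata=payload.get("metadata", {}),
        converged=bool(payload.get("converged", True)),
        separation_flag=bool(payload.get("separation_flag", False)),
        collinearity_flag=bool(payload.get("collinearity_flag", False)),
    )


# ---------------------------------------------------------------------------
# derived tables

def write_screen_table(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)


def write_roc(roc: RocResult, path) -> None:
    """ROC curve TSV: threshold, sensitivity, 1-specificity."""
    out = roc.curve.rename(columns={"fpr": "fpr"})
    out.to_csv(path, sep="\t", index=False)


def write_bootstrap_report(report: BootstrapReport, path, summary_path=None) -> None:
    """Per-iteration TSV plus an optional JSON summary block."""
    if report.iterations is not None:
        report.iterations.to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        summary = {
            "B": report.B,
            "mode": report.mode,
            "seed": report.seed,
            "mean_auc": report.mean_auc,
            "ci95": list(report.ci95),
            "n_degenerate": report.n_degenerate,
            "apparent_auc": report.apparent_auc,
            "optimism_corrected_auc": report.optimism_corrected_auc,
        }
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# qPCR batches

def read_qpcr(path, efficiency_path=None, housekeeping=()) -> QpcrBatch:
    """Read a long-format Cq TSV (sample_id, gene_id, cq1, cq2, cq3).

    ``efficiency_path`` is an optional TSV (gene_id, efficiency); genes
    without an entry default to perfect doubling (E = 2).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    required = ["sample_id", "gene_id", "cq1", "cq2", "cq3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column {missing[0]!r}")
    samples = list(dict.fromkeys(df["sample_id"]))
    genes = list(dict.fromkeys(df["gene_id"]))
    cq = np.full((len(samples), len(genes), 3), np.nan)
    si = {s: i for i, s in enumerate(samples)}
    gi = {g: j for j, g in enumerate(genes)}
    for _, row in df.iterrows():
        cq[si[row["sample_id"]], gi[row["gene_id"]]] = (
            row["cq1"], row["cq2"], row["cq3"],
        )
    if np.isnan(cq).any():
        i, j = np.argwhere(np.isnan(cq).any(axis=2))[0]
        raise ValueError(f"{path}: no triplicate for sample {samples[i]!r}, gene {genes[j]!r}")
    efficiency = {g: 2.0 for g in genes}
    if efficiency_path is not None:
        eff = pd.read_csv(efficiency_path, sep="\t", dtype={"gene_id": str})
        for _, row in eff.iterrows():
            efficiency[row["gene_id"]] = float(row["efficiency"])
    return QpcrBatch(
        sample_ids=tuple(samples),
        gene_ids=tuple(genes),
        cq=cq,
        efficiency=efficiency,
        housekeeping=tuple(housekeeping),
    )


def write_qpcr(batch: QpcrBatch, path) -> None:
    rows = []
    for i, s in enumerate(batch.sample_ids):
        for j, g in enumerate(batch.gene_ids):
            rows.append((s, g, *batch.cq[i, j]))
    pd.DataFrame(rows, columns=["sample_id", "gene_id", "cq1", "cq2", "cq3"]).to_csv(
        path, sep="\t", index=False
    )
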