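"""Readers and writers for the pipeline's external representations.

Signal matrices are tab-separated UTF-8 text, probes as rows, samples as
columns, first column ``probe_id``, ``NA`` for missing cells.  Probe panels
and sample sheets are TSV, clinical tables are CSV.  Fitted index models are
versioned JSON documents so that the scientific deliverable — the formula —
stays auditable by eye.  A minimal GEO series-matrix reader ingests the
deposited form of such studies without any network client.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    COHORT_COLUMNS,
    DiscriminantModel,
    FormatError,
    ProbePanel,
    SampleRecord,
    SignalMatrix,
    Stage,
    TimePoint,
    ValidationError,
    samples_from_frame,
    samples_to_frame,
    validate_cohort,
)

MODEL_FORMAT = "mirecur-discriminant-model"
MODEL_VERSION = 1

#: Editable lookup from GEO sample-characteristic wording to time points.
#: GEO annotation vocabulary varies between submissions, so the mapping is a
#: module-level table users can extend rather than hard-coded matching.
GEO_TIMEPOINT_VOCABULARY: dict[str, TimePoint] = {
    "pre-operative": TimePoint.PRE,
    "preoperative": TimePoint.PRE,
    "pre operative": TimePoint.PRE,
    "before surgery": TimePoint.PRE,
    "before radical surgery": TimePoint.PRE,
    "post-operative": TimePoint.POST,
    "postoperative": TimePoint.POST,
    "post operative": TimePoint.POST,
    "after surgery": TimePoint.POST,
    "after radical surgery": TimePoint.POST,
    "recurrence": TimePoint.FINAL,
    "at recurrence": TimePoint.FINAL,
    "last observation": TimePoint.FINAL,
    "last-observation": TimePoint.FINAL,
}


# ---------------------------------------------------------------------------
# probe panel


def write_panel(panel: ProbePanel, path: str | Path) -> None:
    out = panel.table.copy()
    out["probe_class"] = out["probe_class"].map(lambda c: c.value)
    out.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> ProbePanel:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ProbePanel(table=table)


# ---------------------------------------------------------------------------
# signal matrix


def write_signal_matrix(matrix: SignalMatrix, path: str | Path) -> None:
    """Write probes x samples TSV; undetected cells still carry their value.

    The processing stage is recorded in a ``#stage=`` header comment so a
    round trip restores it.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#stage={matrix.stage.value}\n")
        out = matrix.values.copy()
        out.insert(0, "probe_id", matrix.values.index)
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_signal_matrix(
    path: str | Path, panel: ProbePanel | None = None
) -> SignalMatrix:
    """Read a TSV intensity matrix, validating probes against a panel.

    Missing cells (``NA``) are flagged in the detection mask rather than
    silently zeroed; their stored value is 0.
    """
    path = Path(path)
    stage = Stage.RAW
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#stage="):
            stage = Stage(first.strip().split("=", 1)[1])
            table = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        else:
            fh.seek(0)
            table = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if table.columns[0] != "probe_id":
        raise FormatError("first column of a signal matrix must be 'probe_id'")
    table = table.set_index("probe_id")
    table.index = table.index.astype(str)
    table.index.name = None
    if panel is not None:
        known = set(panel.ids())
        unknown = [p for p in table.index if p not in known]
        if unknown:
            raise FormatError(
                f"probe ids absent from panel: {unknown[:5]}"
                + ("..." if len(unknown) > 5 else "")
            )
    values = table.astype(float)
    missing = values.isna()
    if (values.fillna(0.0).to_numpy() < 0).any():
        raise ValidationError("negative intensity in signal matrix")
    detected = ~missing
    return SignalMatrix(values=values.fillna(0.0), detected=detected, stage=stage)


# ---------------------------------------------------------------------------
# sample sheet and cohort table


def write_samples(records: list[SampleRecord], path: str | Path) -> None:
    samples_to_frame(records).to_csv(path, index=False)


def read_samples(path: str | Path) -> list[SampleRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = samples_from_frame(frame)
    SampleRecord.validate(records)
    return records


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort)
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    cohort["patient_id"] = cohort["patient_id"].astype(str)
    for col in ("rfs_event", "os_event", "lymph_metastasis"):
        cohort[col] = cohort[col].astype(bool)
    validate_cohort(cohort)
    return cohort


# ---------------------------------------------------------------------------
# GEO series matrix


def map_geo_time_point(text: str) -> TimePoint | None:
    """Map a GEO characteristic string to a time point via the vocabulary."""
    low = text.lower()
    for phrase, tp in GEO_TIMEPOINT_VOCABULARY.items():
        if phrase in low:
            return tp
    return None


def read_geo_series_matrix(
    path: str | Path,
) -> tuple[SignalMatrix, list[SampleRecord]]:
    """Parse a GEO series-matrix text file into a raw matrix + sample sheet.

    Sample characteristics lines are scanned for time-point wording via
    :data:`GEO_TIMEPOINT_VOCABULARY`; samples without a recognized annotation
    get ``time_point=None`` with a warning.  Patient identifiers are taken
    from a ``patient:``/``patient id:`` characteristic when present, else the
    sample title, else the GSM accession.
    """
    path = Path(path)
    accessions: list[str] = []
    titles: list[str] = []
    characteristics: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    table_closed = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                table_closed = True
                continue
            if in_table:
                table_lines.append(line)
                continue
            if line.startswith("!Sample_geo_accession"):
                accessions = _geo_fields(line)
            elif line.startswith("!Sample_title"):
                titles = _geo_fields(line)
            elif line.startswith("!Sample_characteristics_ch1"):
                fields = _geo_fields(line)
                if not characteristics:
                    characteristics = [[] for _ in fields]
                for i, f in enumerate(fields):
                    characteristics[i].append(f)
    if in_table or not table_closed or not table_lines:
        raise FormatError(f"{path}: truncated or malformed series matrix table")
    if not accessions:
        raise FormatError(f"{path}: no !Sample_geo_accession line")

    header = [f.strip('"') for f in table_lines[0].split("\t")]
    rows = [ln.split("\t") for ln in table_lines[1:]]
    probe_ids = [r[0].strip('"') for r in rows]
    data = np.array(
        [[_geo_value(v) for v in r[1:]] for r in rows], dtype=float
    )
    if data.shape != (len(probe_ids), len(header) - 1):
        raise FormatError(f"{path}: ragged series matrix table")
    values = pd.DataFrame(data, index=probe_ids, columns=header[1:])
    detected = ~values.isna()
    matrix = SignalMatrix(
        values=values.fillna(0.0), detected=detected, stage=Stage.RAW
    )

    records: list[SampleRecord] = []
    unmapped = []
    for i, acc in enumerate(accessions):
        chars = characteristics[i] if i < len(characteristics) else []
        tp = None
        for c in chars:
            tp = map_geo_time_point(c)
            if tp is not None:
                break
        if tp is None:
            unmapped.append(acc)
        patient = acc
        for c in chars:
            low = c.lower()
            if low.startswith("patient:") or low.startswith("patient id:"):
                patient = c.split(":", 1)[1].strip()
                break
        else:
            if i < len(titles) and titles[i]:
                patient = titles[i]
        records.append(
            SampleRecord(sample_id=acc, patient_id=patient, time_point=tp)
        )
    if unmapped:
        warnings.warn(
            f"no time-point annotation recognized for {len(unmapped)} "
            f"sample(s) (e.g. {unmapped[0]}); extend GEO_TIMEPOINT_VOCABULARY",
            stacklevel=2,
        )
    return matrix, records


def _geo_fields(line: str) -> list[str]:
    return [f.strip().strip('"') for f in line.split("\t")[1:]]


def _geo_value(token: str) -> float:
    token = token.strip().strip('"')
    if token in ("", "null", "NA", "NaN"):
        return np.nan
    return float(token)


# ---------------------------------------------------------------------------
# model serialization


def write_model(model: DiscriminantModel, path: str | Path) -> None:
    """Serialize an index model as versioned JSON (lossless floats)."""
    if len(model.members) == 0:
        raise ValidationError("refusing to write a model with no members")
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "members": list(model.members),
        "coefficients": [float(c) for c in model.coefficients],
        "intercept": float(model.intercept),
        "cutoff": float(model.cutoff),
        "metrics": {k: float(v) for k, v in model.metrics.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_model(path: str | Path) -> DiscriminantModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: not a {MODEL_FORMAT} document")
    if doc.get("version") != MODEL_VERSION:
        raise FormatError(
            f"{path}: model file version {doc.get('version')!r} not supported "
            f"(expected {MODEL_VERSION})"
        )
    return DiscriminantModel(
        members=list(doc["members"]),
        coefficients=[float(c) for c in doc["coefficients"]],
        intercept=float(doc["intercept"]),
        cutoff=float(doc["cutoff"]),
        metrics=dict(doc.get("metrics", {})),
    )
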