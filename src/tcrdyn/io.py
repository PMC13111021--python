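"""Reading and writing clonotype tables, cohort manifests and metrics tables.

The rearrangement dialect is the AIRR community TSV: tab-separated, UTF-8,
with at least ``v_call``, ``j_call`` and ``junction`` columns;
``duplicate_count`` is optional and defaults to 1 per row. A ``junction_aa``
column, when present, is ignored and recomputed by translation so the
amino-acid level is always internally consistent.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .clonotype import RawRearrangementRecord, collapse_clonotypes
from .model import (
    TIMEPOINTS,
    CohortManifest,
    PatientRecord,
    RepertoireSample,
    SampleMetrics,
)

REQUIRED_REARRANGEMENT_COLUMNS = ("v_call", "j_call", "junction")

METRICS_COLUMNS = (
    "patient_id",
    "timepoint",
    "group",
    "depth",
    "unique_clones",
    "shannon",
    "evenness",
    "convergence",
)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates the expected schema."""


def read_repertoire(path: PathLike, format: str = "airr_tsv") -> RepertoireSample:
    """Read a rearrangement TSV and return a collapsed :class:`RepertoireSample`.

    Unproductive junctions (out of frame or stop-containing) are excluded;
    their read mass is recorded in ``discarded_reads`` so that
    ``depth + discarded_reads`` equals the summed input counts.
    """
    if format != "airr_tsv":
        raise ValueError(f"unsupported repertoire format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    for col in REQUIRED_REARRANGEMENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: no rearrangement rows")

    if "duplicate_count" in df.columns:
        counts = (
            pd.to_numeric(df["duplicate_count"], errors="coerce")
            .fillna(1)
            .astype(int)
        )
    else:
        counts = pd.Series(1, index=df.index)

    records = []
    bad_lines = []
    for i, (v, j, junction, n) in enumerate(
        zip(df["v_call"], df["j_call"], df["junction"], counts)
    ):
        junction = str(junction).upper().strip()
        if set(junction) - set("ACGT"):
            bad_lines.append(i + 2)  # 1-based, counting the header line
            continue
        records.append(
            RawRearrangementRecord(
                v_call=str(v),
                j_call=str(j),
                junction=junction,
                duplicate_count=max(int(n), 1),
            )
        )
    if bad_lines:
        raise FormatError(
            f"{path}: non-ACGT junction character on line(s) {bad_lines}"
        )
    clonotypes, discarded = collapse_clonotypes(records)
    return RepertoireSample(
        clonotypes=clonotypes, discarded_reads=discarded, source=str(path)
    )


def read_cohort_manifest(path: PathLike) -> CohortManifest:
    """Read a comma-delimited cohort manifest.

    Expected columns: ``patient_id``, ``response`` (PR/SD/PD/NE),
    ``os_days``, ``event`` (1 = death, 0 = censored) and one path column per
    time point (``T1``, ``T2``, ``T3``); an empty path marks the sample as
    unavailable at that time point. Relative paths resolve against the
    manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    required = ["patient_id", "response", "os_days", "event"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    tp_cols = [tp for tp in TIMEPOINTS if tp in df.columns]
    if not tp_cols:
        raise FormatError(f"{path}: no time-point path column among {TIMEPOINTS}")
    if df["patient_id"].duplicated().any():
        dup = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"])
        raise FormatError(f"{path}: duplicate patient_id rows: {dup}")

    base = path.parent
    patients = []
    for _, row in df.iterrows():
        os_days = float(row["os_days"])
        if os_days < 0:
            raise FormatError(
                f"{path}: negative os_days for patient {row['patient_id']}"
            )
        sample_paths = {}
        for tp in tp_cols:
            raw = row[tp]
            if isinstance(raw, str) and raw.strip():
                p = Path(raw.strip())
                sample_paths[tp] = p if p.is_absolute() else base / p
        patients.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                response=str(row["response"]).strip(),
                os_days=os_days,
                event=int(row["event"]),
                sample_paths=sample_paths,
            )
        )
    return CohortManifest(patients=patients)


def write_cohort_manifest(manifest: CohortManifest, path: PathLike) -> None:
    path = Path(path)
    rows = []
    for p in manifest:
        row = {
            "patient_id": p.patient_id,
            "response": p.response,
            "os_days": p.os_days,
            "event": p.event,
        }
        for tp in TIMEPOINTS:
            row[tp] = str(p.sample_paths[tp]) if tp in p.sample_paths else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_repertoire(sample: RepertoireSample, path: PathLike) -> None:
    """Write a collapsed sample back out as an AIRR-style rearrangement TSV."""
    rows = [
        {
            "v_call": c.v_gene,
            "j_call": c.j_gene,
            "junction": c.cdr3_nt,
            "junction_aa": c.cdr3_aa,
            "duplicate_count": c.count,
        }
        for c in sample.clonotypes
    ]
    pd.DataFrame(
        rows, columns=["v_call", "j_call", "junction", "junction_aa", "duplicate_count"]
    ).to_csv(path, sep="\t", index=False)


def metrics_to_frame(metrics: Iterable[SampleMetrics]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": m.patient_id,
            "timepoint": m.timepoint,
            "group": m.group if m.group is not None else "",
            "depth": m.depth,
            "unique_clones": m.unique_clones,
            "shannon": m.shannon,
            "evenness": m.evenness,
            "convergence": m.convergence,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=list(METRICS_COLUMNS))


def write_metrics_table(metrics: list[SampleMetrics], path: PathLike) -> None:
    """Write per-sample metrics as a TSV with a fixed column order.

    Floats are serialised with ``repr`` round-trip precision so re-reading
    reproduces every value exactly; a missing evenness is stored empty.
    """
    if not metrics:
        raise ValueError("metrics list is empty; nothing to write")
    df = metrics_to_frame(metrics)
    df.to_csv(path, sep="\t", index=False, float_format=None)


def read_metrics_table(path: PathLike) -> list[SampleMetrics]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "group": str})
    out = []
    for _, row in df.iterrows():
        group = row["group"] if isinstance(row["group"], str) and row["group"] else None
        evenness = float(row["evenness"]) if not pd.isna(row["evenness"]) else math.nan
        out.append(
            SampleMetrics(
                patient_id=str(row["patient_id"]),
                timepoint=str(row["timepoint"]),
                group=group,
                depth=int(row["depth"]),
                unique_clones=int(row["unique_clones"]),
                shannon=float(row["shannon"]),
                evenness=evenness,
                convergence=float(row["convergence"]),
            )
        )
    return out
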