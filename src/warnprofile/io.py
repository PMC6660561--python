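"""CSV ingestion and serialization for records and fiducial tables.

Three plain-text interfaces, all comma-separated UTF-8 with a mandatory
header and ``NA`` as the only missing-value token:

* samples CSV: ``record_id,time_min,hr,sbp,map`` (``map`` optional)
* manifest CSV: ``record_id,record_type,event_time_min,baseline_start_min,baseline_end_min``
* fiducial CSV: ``record_id,record_type,time_event_min,time_warning_min``
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import NA_TOKEN, FiducialRow, FormatError, RecordSeries, RecordType, ValidationError

SAMPLES_COLUMNS = ("record_id", "time_min", "hr", "sbp", "map")
MANIFEST_COLUMNS = (
    "record_id",
    "record_type",
    "event_time_min",
    "baseline_start_min",
    "baseline_end_min",
)
FIDUCIAL_COLUMNS = ("record_id", "record_type", "time_event_min", "time_warning_min")

_READ_KWARGS = dict(
    na_values=[NA_TOKEN],
    keep_default_na=False,
    dtype={"record_id": str},
    float_precision="round_trip",
)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def _optional_float(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_records(samples_path, manifest_path) -> list[RecordSeries]:
    """Read a cohort from a samples CSV plus its records manifest.

    Returns one :class:`RecordSeries` per manifest row, with samples grouped
    by ``record_id`` and sorted by time. All record invariants (uniform
    sampling, positive vitals, event time within span) are enforced.
    """
    samples = pd.read_csv(samples_path, **_READ_KWARGS)
    manifest = pd.read_csv(manifest_path, **_READ_KWARGS)
    _require_columns(samples, [c for c in SAMPLES_COLUMNS if c != "map"], samples_path)
    _require_columns(manifest, MANIFEST_COLUMNS, manifest_path)

    dup = manifest["record_id"][manifest["record_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"{manifest_path}: record {dup.iloc[0]!r} has multiple manifest rows "
            "(at most one event per record)"
        )

    has_map = "map" in samples.columns
    grouped = {rid: grp for rid, grp in samples.groupby("record_id", sort=False)}
    records: list[RecordSeries] = []
    for row in manifest.itertuples(index=False):
        rid = row.record_id
        try:
            rtype = RecordType(row.record_type)
        except ValueError:
            raise FormatError(
                f"{manifest_path}: record {rid!r} has unknown record_type "
                f"{row.record_type!r}"
            ) from None
        event_time = _optional_float(row.event_time_min)
        if rtype is RecordType.NONEVENT and event_time is not None:
            raise ValidationError(
                f"{manifest_path}: nonevent record {rid!r} has a defined event time"
            )
        if rtype is RecordType.EVENT and event_time is None:
            raise ValidationError(
                f"{manifest_path}: event record {rid!r} lacks an event time"
            )
        grp = grouped.pop(rid, None)
        if grp is None:
            raise ValidationError(f"{samples_path}: no samples for record {rid!r}")
        grp = grp.sort_values("time_min")
        records.append(
            RecordSeries(
                record_id=rid,
                times=grp["time_min"].to_numpy(float),
                hr=grp["hr"].to_numpy(float),
                sbp=grp["sbp"].to_numpy(float),
                map=grp["map"].to_numpy(float) if has_map else None,
                baseline_window=(float(row.baseline_start_min), float(row.baseline_end_min)),
                event_time=event_time,
            )
        )
    if grouped:
        orphan = next(iter(grouped))
        raise ValidationError(f"{manifest_path}: record {orphan!r} missing from manifest")
    return records


def write_records(records: Sequence[RecordSeries], samples_path, manifest_path) -> None:
    """Write a cohort in the samples + manifest format read by :func:`read_records`."""
    sample_frames = []
    manifest_rows = []
    for rec in records:
        n = rec.times.size
        sample_frames.append(
            pd.DataFrame(
                {
                    "record_id": np.repeat(rec.record_id, n),
                    "time_min": rec.times,
                    "hr": rec.hr,
                    "sbp": rec.sbp,
                    "map": rec.map if rec.map is not None else np.full(n, np.nan),
                }
            )
        )
        manifest_rows.append(
            {
                "record_id": rec.record_id,
                "record_type": rec.record_type.value,
                "event_time_min": rec.event_time,
                "baseline_start_min": rec.baseline_window[0],
                "baseline_end_min": rec.baseline_window[1],
            }
        )
    samples = (
        pd.concat(sample_frames, ignore_index=True)
        if sample_frames
        else pd.DataFrame(columns=list(SAMPLES_COLUMNS))
    )
    samples.to_csv(samples_path, index=False, na_rep=NA_TOKEN)
    pd.DataFrame(manifest_rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest_path, index=False, na_rep=NA_TOKEN
    )


def read_fiducials(path) -> list[FiducialRow]:
    """Read a fiducial table: one row per warning plus one NA-warning row
    per warningless record.

    Raises :class:`ValidationError` if a record id appears under both record
    types or a nonevent row carries an event time.
    """
    df = pd.read_csv(path, **_READ_KWARGS)
    _require_columns(df, FIDUCIAL_COLUMNS, path)

    types_per_record = df.groupby("record_id")["record_type"].nunique()
    mixed = types_per_record[types_per_record > 1]
    if not mixed.empty:
        raise ValidationError(
            f"{path}: record {mixed.index[0]!r} appears under both record types"
        )

    rows: list[FiducialRow] = []
    for row in df.itertuples(index=False):
        try:
            rtype = RecordType(row.record_type)
        except ValueError:
            raise FormatError(
                f"{path}: record {row.record_id!r} has unknown record_type "
                f"{row.record_type!r}"
            ) from None
        rows.append(
            FiducialRow(
                record_id=row.record_id,
                record_type=rtype,
                time_event=_optional_float(row.time_event_min),
                time_warning=_optional_float(row.time_warning_min),
            )
        )
    return rows


def write_fiducials(rows: Sequence[FiducialRow], path) -> None:
    """Write a fiducial CSV; ``read_fiducials(write_fiducials(x)) == x``."""
    df = pd.DataFrame(
        {
            "record_id": [r.record_id for r in rows],
            "record_type": [r.record_type.value for r in rows],
            "time_event_min": [r.time_event for r in rows],
            "time_warning_min": [r.time_warning for r in rows],
        },
        columns=list(FIDUCIAL_COLUMNS),
    )
    if os.path.isdir(path):
        raise IOError(f"{path} is a directory")
    df.to_csv(path, index=False, na_rep=NA_TOKEN)
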