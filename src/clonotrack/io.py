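"""Reading, validating and writing clonotype tables and study metadata.

Clonotype tables are AIRR-rearrangement-style TSVs: tab-separated, UTF-8,
header mandatory, one row per clonotype. The canonical column names are the
AIRR ones (``v_call``, ``junction``, ``junction_aa``, ``duplicate_count``,
``productive``); a column-mapping dict admits other dialects (e.g. MiTCR
exports). Rows whose clone key coincides are merged by summing counts, so a
table is always a valid clonotype *set* after reading.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import pandas as pd

from .errors import (
    InvalidSequenceError,
    MissingColumnError,
    NegativeCountError,
    SubsetFractionError,
)
from .models import (
    CloneKey,
    Clonotype,
    RepertoireSample,
    SubsetFractionTable,
    _DNA,
    is_functional,
    make_clone_key,
    translate_junction,
)

MANDATORY_COLUMNS = ("v_call", "junction", "duplicate_count")

#: Column mapping for MiTCR-style exports → AIRR canonical names.
MITCR_COLUMN_MAP: Mapping[str, str] = {
    "V segments": "v_call",
    "CDR3 nucleotide sequence": "junction",
    "CDR3 amino acid sequence": "junction_aa",
    "Read count": "duplicate_count",
}

_TRUE = {"T", "TRUE", "True", "true", "1"}
_FALSE = {"F", "FALSE", "False", "false", "0"}


def _parse_productive(value: object, junction: str) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return is_functional(junction)
    if isinstance(value, bool):
        return value
    text = str(value).strip()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    return is_functional(junction)


def read_repertoire(
    path: str | os.PathLike,
    sample_id: str,
    subject_id: str,
    tissue: str,
    subset: str,
    timepoint: str,
    platform: str,
    column_map: Optional[Mapping[str, str]] = None,
) -> RepertoireSample:
    """Read one clonotype TSV into a validated :class:`RepertoireSample`.

    Rows with an identical clone key are merged by summing counts.
    ``junction_aa`` is recomputed from ``junction`` when absent, and the
    ``productive`` flag is computed from the junction when absent.

    Raises
    ------
    MissingColumnError, InvalidSequenceError, NegativeCountError
        Distinct named failures for each class of malformed input.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing mandatory columns {missing}")

    merged: dict[CloneKey, Clonotype] = {}
    for row in df.itertuples(index=False):
        junction = str(getattr(row, "junction")).strip().upper()
        if not junction or set(junction) - _DNA:
            raise InvalidSequenceError(
                f"{path}: non-DNA junction {junction!r}"
            )
        raw_count = str(getattr(row, "duplicate_count")).strip()
        try:
            count = int(raw_count)
        except ValueError as exc:
            raise NegativeCountError(
                f"{path}: non-integer duplicate_count {raw_count!r}"
            ) from exc
        if count < 0:
            raise NegativeCountError(f"{path}: negative count {count}")
        v_call = str(getattr(row, "v_call")).strip()
        aa = str(getattr(row, "junction_aa", "")).strip()
        if not aa:
            aa = translate_junction(junction)
        productive = _parse_productive(
            getattr(row, "productive", None), junction
        )
        clono = Clonotype(
            v_call=v_call,
            cdr3_nt=junction,
            count=count,
            cdr3_aa=aa,
            productive=productive,
        )
        key = make_clone_key(clono)
        if key in merged:
            prev = merged[key]
            merged[key] = Clonotype(
                v_call=prev.v_call,
                cdr3_nt=prev.cdr3_nt,
                count=prev.count + count,
                cdr3_aa=prev.cdr3_aa,
                productive=prev.productive,
            )
        else:
            merged[key] = clono

    return RepertoireSample(
        sample_id=sample_id,
        subject_id=subject_id,
        tissue=tissue,
        subset=subset,
        timepoint=timepoint,
        platform=platform,
        clonotypes=list(merged.values()),
    )


def write_repertoire(sample: RepertoireSample, path: str | os.PathLike) -> None:
    """Write an AIRR-style rearrangement TSV (one row per clonotype)."""
    rows = [
        {
            "sequence_id": f"{sample.sample_id}-{i}",
            "v_call": c.v_call,
            "junction": c.cdr3_nt,
            "junction_aa": c.cdr3_aa,
            "duplicate_count": c.count,
            "productive": "T" if c.productive else "F",
        }
        for i, c in enumerate(sample.clonotypes)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "v_call",
            "junction",
            "junction_aa",
            "duplicate_count",
            "productive",
        ],
    ).to_csv(path, sep="\t", index=False)


def filter_functional(
    sample: RepertoireSample, require_anchors: bool = True
) -> RepertoireSample:
    """Keep only clonotypes with a functional CDR3.

    Functional = in-frame (length a multiple of 3), stop-free translation,
    and (by default) the conserved C...F/W junction anchors. Idempotent;
    never increases the total count. Downstream frequency denominators are
    always totals over this filtered set ("functional reads").
    """
    kept = [
        c
        for c in sample.clonotypes
        if c.productive and is_functional(c.cdr3_nt, require_anchors)
    ]
    provenance = None
    if sample.provenance is not None:
        kept_keys = {make_clone_key(c) for c in kept}
        provenance = {
            k: dict(v) for k, v in sample.provenance.items() if k in kept_keys
        }
    return RepertoireSample(
        sample_id=sample.sample_id,
        subject_id=sample.subject_id,
        tissue=sample.tissue,
        subset=sample.subset,
        timepoint=sample.timepoint,
        platform=sample.platform,
        clonotypes=kept,
        provenance=provenance,
    )


SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "subject_id",
    "tissue",
    "subset",
    "timepoint",
    "platform",
    "path",
)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: sample sheet missing {missing}")
    return df


def write_sample_sheet(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    rows.to_csv(path, sep="\t", index=False, columns=list(SAMPLE_SHEET_COLUMNS))


def read_subset_fractions(path: str | os.PathLike) -> SubsetFractionTable:
    """Read a FACS fraction TSV (subject_id, timepoint, subset, fraction_of_cd4)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["subject_id", "timepoint", "subset", "fraction_of_cd4"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: fraction table missing {missing}")
    rows = []
    for r in df.itertuples(index=False):
        try:
            frac = float(r.fraction_of_cd4)
        except ValueError as exc:
            raise SubsetFractionError(
                f"{path}: non-numeric fraction {r.fraction_of_cd4!r}"
            ) from exc
        rows.append((r.subject_id, r.timepoint, r.subset, frac))
    return SubsetFractionTable(rows=rows)


def write_subset_fractions(
    table: SubsetFractionTable, path: str | os.PathLike
) -> None:
    pd.DataFrame(
        table.rows,
        columns=["subject_id", "timepoint", "subset", "fraction_of_cd4"],
    ).to_csv(path, sep="\t", index=False)
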