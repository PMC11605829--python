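"""Read, validate, and write the delimited compound tables of the screen.

Input tables are one-row-per-identified-compound exports of an annotated
LC-MS/MS experiment (e.g. an MS-DIAL alignment export re-shaped to columns).
The only columns the pipeline requires are an annotation name and a peak
area; ion mode, m/z, retention time, adduct and chemical superclass are
carried through when present.  Column headers and the delimiter are supplied
by a :class:`Dialect` so arbitrary vendor layouts can be mapped without
editing code.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
import os
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .classify import StabilityResult

_WS = re.compile(r"\s+")

#: Reserved superclass label for compounds whose annotation carries none.
UNCLASSIFIED_SUPERCLASS = "unclassified_superclass"


class FeatureTableError(ValueError):
    """Hard error while reading or validating a feature table."""


class IonMode(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNSPECIFIED = "unspecified"


_ION_ALIASES = {
    "positive": IonMode.POSITIVE,
    "pos": IonMode.POSITIVE,
    "+": IonMode.POSITIVE,
    "esi+": IonMode.POSITIVE,
    "negative": IonMode.NEGATIVE,
    "neg": IonMode.NEGATIVE,
    "-": IonMode.NEGATIVE,
    "esi-": IonMode.NEGATIVE,
}


def normalize_key(name: str) -> str:
    """Normalize an annotation name into the matching key.

    Case-folds, trims, and collapses internal whitespace.  Annotation
    strings are the only key shared between the two independently processed
    treatment tables, so both tables must pass through the same
    normalization before matching.
    """
    return _WS.sub(" ", str(name).strip()).casefold()


@dataclass(frozen=True)
class CompoundRecord:
    """One identified compound in one treatment."""

    compound_key: str
    raw_name: str
    ion_mode: IonMode
    area: float
    mz: Optional[float] = None
    rt: Optional[float] = None
    adduct: Optional[str] = None
    superclass: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.compound_key:
            raise FeatureTableError("compound_key must be non-empty")
        if not (math.isfinite(self.area) and self.area > 0):
            raise FeatureTableError(
                f"area must be a positive finite number, got {self.area!r} "
                f"for {self.raw_name!r}"
            )


@dataclass(frozen=True)
class Dialect:
    """Column mapping and delimiter for a delimited compound table.

    ``name`` and ``area`` are required in the header; the remaining columns
    are read only when present.
    """

    delimiter: str = "\t"
    name: str = "name"
    area: str = "area"
    ion_mode: str = "ion_mode"
    mz: str = "mz"
    rt: str = "rt"
    adduct: str = "adduct"
    superclass: str = "superclass"
    dialect_name: str = "default_tsv"

    def __post_init__(self) -> None:
        if self.delimiter not in ("\t", ","):
            raise FeatureTableError(
                f"delimiter must be tab or comma, got {self.delimiter!r}"
            )


@dataclass(frozen=True)
class FeatureTable:
    """Validated, deduplicated compound collection for a single treatment."""

    treatment_label: str
    records: tuple[CompoundRecord, ...]
    source_path: str = ""
    dialect_name: str = ""

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise FeatureTableError(
                f"feature table {self.treatment_label!r} has no records"
            )
        keys = [r.compound_key for r in self.records]
        if len(set(keys)) != len(keys):
            raise FeatureTableError(
                f"duplicate compound_key values in table {self.treatment_label!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[str]:
        return {r.compound_key for r in self.records}

    def get(self, key: str) -> CompoundRecord:
        for r in self.records:
            if r.compound_key == key:
                return r
        raise KeyError(key)

    def areas(self) -> dict[str, float]:
        return {r.compound_key: r.area for r in self.records}


@dataclass
class ValidationReport:
    n_rows_read: int = 0
    n_rejected: int = 0
    n_deduplicated: int = 0
    messages: list[tuple[str, int, str]] = field(default_factory=list)

    def warn(self, row: int, text: str) -> None:
        self.messages.append(("warning", row, text))


def _parse_float(value: str) -> Optional[float]:
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return out if math.isfinite(out) else None


def read_feature_table(
    path: str | os.PathLike,
    dialect: Dialect | None = None,
    treatment_label: str = "",
) -> tuple[FeatureTable, ValidationReport]:
    """Read and validate one treatment's compound table.

    Rows with a missing/empty annotation name or a non-positive,
    non-numeric area are rejected and reported.  Duplicate normalized keys
    within the table (e.g. the same compound annotated in both ion modes or
    as several adducts) are collapsed to the record with the largest peak
    area, the conventional quantifier.

    Returns the deduplicated :class:`FeatureTable` and a
    :class:`ValidationReport`; raises :class:`FeatureTableError` if the
    file is missing, a required column is absent, or nothing survives
    validation.
    """
    dialect = dialect or Dialect()
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FeatureTableError(f"input file does not exist: {path}")
    frame = pd.read_csv(
        path, sep=dialect.delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    for required in (dialect.name, dialect.area):
        if required not in frame.columns:
            raise FeatureTableError(
                f"required column {required!r} absent from header of {path} "
                f"(found: {list(frame.columns)})"
            )

    report = ValidationReport(n_rows_read=len(frame))
    has = {c: c in frame.columns for c in (
        dialect.ion_mode, dialect.mz, dialect.rt, dialect.adduct, dialect.superclass)}

    candidates: list[CompoundRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        row = dict(zip(frame.columns, row))
        raw_name = str(row[dialect.name])
        key = normalize_key(raw_name)
        if not key:
            report.n_rejected += 1
            report.warn(i, "row rejected: empty annotation name")
            continue
        area = _parse_float(row[dialect.area])
        if area is None or area <= 0:
            report.n_rejected += 1
            report.warn(i, f"row rejected: invalid area {row[dialect.area]!r} for {raw_name!r}")
            continue
        mode = IonMode.UNSPECIFIED
        if has[dialect.ion_mode]:
            mode = _ION_ALIASES.get(str(row[dialect.ion_mode]).strip().casefold(), IonMode.UNSPECIFIED)
        mz = _parse_float(row[dialect.mz]) if has[dialect.mz] else None
        if mz is not None and mz <= 0:
            mz = None
        rt = _parse_float(row[dialect.rt]) if has[dialect.rt] else None
        if rt is not None and rt < 0:
            rt = None
        adduct = (str(row[dialect.adduct]).strip() or None) if has[dialect.adduct] else None
        superclass = (str(row[dialect.superclass]).strip() or None) if has[dialect.superclass] else None
        candidates.append(CompoundRecord(key, raw_name, mode, area, mz, rt, adduct, superclass))

    if not candidates:
        raise FeatureTableError(
            f"no valid compound rows in {path}: {report.n_rows_read} read, "
            f"{report.n_rejected} rejected"
        )

    # dedup: keep the largest-area record per key; first occurrence wins ties
    best: dict[str, CompoundRecord] = {}
    for rec in candidates:
        kept = best.get(rec.compound_key)
        if kept is None or rec.area > kept.area:
            best[rec.compound_key] = rec
    report.n_deduplicated = len(candidates) - len(best)

    order: list[str] = []
    seen: set[str] = set()
    for rec in candidates:
        if rec.compound_key not in seen:
            seen.add(rec.compound_key)
            order.append(rec.compound_key)
    table = FeatureTable(
        treatment_label=treatment_label or os.path.basename(path),
        records=tuple(best[k] for k in order),
        source_path=path,
        dialect_name=dialect.dialect_name,
    )
    return table, report


def write_feature_table(
    table: FeatureTable, path: str | os.PathLike, dialect: Dialect | None = None
) -> None:
    """Write a feature table in a dialect :func:`read_feature_table` accepts."""
    dialect = dialect or Dialect()
    rows = []
    for r in table.records:
        rows.append({
            dialect.name: r.raw_name,
            dialect.ion_mode: r.ion_mode.value,
            dialect.area: _fmt(r.area),
            dialect.mz: _fmt(r.mz) if r.mz is not None else "",
            dialect.rt: _fmt(r.rt) if r.rt is not None else "",
            dialect.adduct: r.adduct or "",
            dialect.superclass: r.superclass or "",
        })
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False, encoding="utf-8")


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips a double exactly."""
    return repr(float(x))


_RESULT_FILES = {
    "per_compound": "shared_compounds.tsv",
    "partition": "partition_counts.tsv",
    "superclass": "superclass_summary.tsv",
    "metadata": "run_metadata.json",
}


def write_results(result: "StabilityResult", out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the screen's outputs as delimited text plus a JSON summary.

    Emits the per-compound table (key, Rf, Ra, ratio, label, superclass),
    the partition-count summary, the superclass summary, and machine-
    readable run metadata recording thresholds and software version.
    Floats are written with round-trip precision so re-reading reproduces
    ratios exactly.
    """
    from . import __version__

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, v) for k, v in _RESULT_FILES.items()}

    per = pd.DataFrame(
        [
            {
                "compound_key": r.compound_key,
                "Rf": _fmt(r.Rf),
                "Ra": _fmt(r.Ra),
                "ratio": _fmt(r.ratio),
                "label": r.label.value,
                "superclass": r.superclass or "",
            }
            for r in result.records
        ],
        columns=["compound_key", "Rf", "Ra", "ratio", "label", "superclass"],
    )
    per.to_csv(paths["per_compound"], sep="\t", index=False, encoding="utf-8")

    c = result.counts
    part = pd.DataFrame(
        [
            ("n_filter_total", c.n_filter_total),
            ("n_autoclave_total", c.n_autoclave_total),
            ("n_shared", c.n_shared),
            ("n_filter_only", c.n_filter_only),
            ("n_autoclave_only", c.n_autoclave_only),
            ("n_anti_aging", result.n_anti_aging),
            ("n_inhibitor", result.n_inhibitor),
        ],
        columns=["metric", "count"],
    )
    part.to_csv(paths["partition"], sep="\t", index=False, encoding="utf-8")

    sc = pd.DataFrame(
        sorted(result.superclass_summary.items()), columns=["superclass", "count"]
    )
    sc.to_csv(paths["superclass"], sep="\t", index=False, encoding="utf-8")

    meta = {
        "software": "thermoscreen",
        "version": __version__,
        "thresholds": {
            "anti_aging_low": result.thresholds.low,
            "anti_aging_high": result.thresholds.high,
            "inhibitor_ratio": result.thresholds.inhibitor,
        },
        "counts": {
            "n_filter_total": c.n_filter_total,
            "n_autoclave_total": c.n_autoclave_total,
            "n_shared": c.n_shared,
            "n_filter_only": c.n_filter_only,
            "n_autoclave_only": c.n_autoclave_only,
            "n_anti_aging": result.n_anti_aging,
            "n_inhibitor": result.n_inhibitor,
        },
    }
    with open(paths["metadata"], "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_results(out_dir: str | os.PathLike) -> "StabilityResult":
    """Reconstruct a :class:`~thermoscreen.classify.StabilityResult` from a
    directory written by :func:`write_results`."""
    from .classify import StabilityLabel, StabilityRecord, StabilityResult, Thresholds
    from .matching import PartitionCounts

    out_dir = os.fspath(out_dir)
    per = pd.read_csv(
        os.path.join(out_dir, _RESULT_FILES["per_compound"]),
        sep="\t", dtype=str, keep_default_na=False, encoding="utf-8",
    )
    records = tuple(
        StabilityRecord(
            compound_key=row["compound_key"],
            Rf=float(row["Rf"]),
            Ra=float(row["Ra"]),
            ratio=float(row["ratio"]),
            label=StabilityLabel(row["label"]),
            superclass=row["superclass"] or None,
        )
        for _, row in per.iterrows()
    )
    with open(os.path.join(out_dir, _RESULT_FILES["metadata"]), encoding="utf-8") as fh:
        meta = json.load(fh)
    t = meta["thresholds"]
    counts = meta["counts"]
    sc = pd.read_csv(
        os.path.join(out_dir, _RESULT_FILES["superclass"]),
        sep="\t", dtype={"superclass": str, "count": int}, keep_default_na=False,
        encoding="utf-8",
    )
    return StabilityResult(
        records=records,
        counts=PartitionCounts(
            n_shared=counts["n_shared"],
            n_filter_only=counts["n_filter_only"],
            n_autoclave_only=counts["n_autoclave_only"],
            n_filter_total=counts["n_filter_total"],
            n_autoclave_total=counts["n_autoclave_total"],
        ),
        n_anti_aging=counts["n_anti_aging"],
        n_inhibitor=counts["n_inhibitor"],
        superclass_summary=dict(zip(sc["superclass"], sc["count"])) if len(sc) else {},
        thresholds=Thresholds(
            low=t["anti_aging_low"], high=t["anti_aging_high"], inhibitor=t["inhibitor_ratio"]
        ),
    )


def sha256_of(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
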