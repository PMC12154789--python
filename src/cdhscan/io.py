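"""On-disk formats for the CDH detection pipeline.

Every artifact the pipeline touches is plain text: tag count matrices
(TSV with a BED companion for tag locations), sample manifests, 1 Mb bin
definitions, and call tables.  Coordinates are 0-based half-open (BED
convention) throughout.  Readers validate eagerly and raise
:class:`FormatError` with the offending location; they never silently
coerce malformed cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "TagLocation",
    "TagMatrix",
    "ControlManifest",
    "BinDefinition",
    "CallTable",
    "read_tag_matrix",
    "write_tag_matrix",
    "read_manifest",
    "write_manifest",
    "read_bins",
    "write_bins",
    "read_call_table",
    "write_call_table",
]

SAMPLE_CLASSES = frozenset({"control", "experimental", "blank"})
CDH_STATUSES = frozenset({"positive", "negative", "unknown"})
COPY_CLASSES = frozenset({"high", "low", "unknown"})
AB10_TYPES = frozenset({"I", "II", "III", "unknown"})
CALLS = frozenset({"positive", "negative", "ambiguous"})

# manifest columns that are not CDH status columns
_MANIFEST_FIXED = ("sample_id", "sample_class", "copy_class", "ab10_type")


class FormatError(ValueError):
    """Malformed input file; the message names the file location."""


@dataclass(frozen=True)
class TagLocation:
    """Genomic location of one GBS tag (0-based half-open)."""

    tag_id: str
    chrom: str
    start: int
    end: int
    mapq: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"tag {self.tag_id!r}: start {self.start} must be < end {self.end}"
            )
        if self.mapq < 0:
            raise FormatError(f"tag {self.tag_id!r}: negative mapq {self.mapq}")


@dataclass
class TagMatrix:
    """Tags x samples read counts with per-tag locations.

    ``counts`` is indexed by tag_id with one column per sample.  Raw
    counts are non-negative integers; after RPM normalization the values
    are floats (``normalized`` is then True).
    """

    locations: pd.DataFrame  # index tag_id; columns chrom, start, end, mapq
    counts: pd.DataFrame  # index tag_id; columns sample ids
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.locations.index.equals(self.counts.index):
            raise ValueError("locations and counts must share an identical tag index")
        if self.locations.index.has_duplicates:
            dup = self.locations.index[self.locations.index.duplicated()][0]
            raise FormatError(f"duplicate tag_id {dup!r}")
        if not self.normalized:
            vals = self.counts.to_numpy()
            if not np.issubdtype(vals.dtype, np.integer):
                raise ValueError("raw counts must be integers")
            if (vals < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_tags(self) -> int:
        return len(self.counts)

    def tag_locations(self) -> list[TagLocation]:
        return [
            TagLocation(str(t), str(r.chrom), int(r.start), int(r.end), int(r.mapq))
            for t, r in self.locations.iterrows()
        ]

    def subset_samples(self, sample_ids: Sequence[str]) -> "TagMatrix":
        return TagMatrix(self.locations, self.counts[list(sample_ids)], self.normalized)

    def subset_tags(self, tag_ids: Sequence[str]) -> "TagMatrix":
        return TagMatrix(
            self.locations.loc[list(tag_ids)],
            self.counts.loc[list(tag_ids)],
            self.normalized,
        )

    def missingness(self) -> pd.Series:
        """Per-sample fraction of tags with zero count."""
        if self.n_tags == 0:
            return pd.Series(0.0, index=self.counts.columns)
        return (self.counts == 0).sum(axis=0) / self.n_tags


@dataclass
class ControlManifest:
    """Per-sample metadata: class, known CDH status, copy class, Ab10 type.

    ``table`` is indexed by sample_id with columns ``sample_class``,
    one status column per CDH name, ``copy_class`` and ``ab10_type``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        bad = set(t["sample_class"]) - SAMPLE_CLASSES
        if bad:
            raise FormatError(f"unrecognized sample_class token(s): {sorted(bad)}")
        for cdh in self.cdh_names:
            bad = set(t[cdh]) - CDH_STATUSES
            if bad:
                raise FormatError(f"unrecognized status in column {cdh!r}: {sorted(bad)}")
        if "copy_class" in t.columns:
            bad = set(t["copy_class"]) - COPY_CLASSES
            if bad:
                raise FormatError(f"unrecognized copy_class token(s): {sorted(bad)}")
        if "ab10_type" in t.columns:
            bad = set(t["ab10_type"]) - AB10_TYPES
            if bad:
                raise FormatError(f"unrecognized ab10_type token(s): {sorted(bad)}")
        # invariants: blanks all-unknown; controls have >=1 known status
        for sid, row in t.iterrows():
            statuses = [row[c] for c in self.cdh_names]
            if row["sample_class"] == "blank" and any(s != "unknown" for s in statuses):
                raise FormatError(f"blank sample {sid!r} has a known CDH status")
            if row["sample_class"] == "control" and all(s == "unknown" for s in statuses):
                raise FormatError(f"control sample {sid!r} has no known CDH status")

    @property
    def cdh_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in _MANIFEST_FIXED]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_of_class(self, sample_class: str) -> list[str]:
        return list(self.table.index[self.table["sample_class"] == sample_class])

    @property
    def blanks(self) -> list[str]:
        return self.samples_of_class("blank")

    @property
    def experimental(self) -> list[str]:
        return self.samples_of_class("experimental")

    def controls_for(
        self, cdh: str, status: str | None = None, copy_class: str | None = None
    ) -> list[str]:
        """Control samples with a known status for one CDH."""
        t = self.table
        mask = (t["sample_class"] == "control") & (t[cdh] != "unknown")
        if status is not None:
            mask &= t[cdh] == status
        if copy_class is not None:
            mask &= t["copy_class"] == copy_class
        return list(t.index[mask])

    def status(self, cdh: str) -> pd.Series:
        return self.table[cdh]

    def subset(self, sample_ids: Sequence[str]) -> "ControlManifest":
        return ControlManifest(self.table.loc[list(sample_ids)])


@dataclass(frozen=True)
class BinDefinition:
    """A tag-index bin: half-open genomic interval, optionally diagnostic
    for one CDH (carrier/non-carrier contrast lives there)."""

    chrom: str
    start: int
    end: int
    label: str
    diagnostic_for: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"bin {self.label!r}: start must be < end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def check_bins_disjoint(bins: Sequence[BinDefinition]) -> None:
    """Raise if any two bins on the same chromosome overlap."""
    by_chrom: dict[str, list[BinDefinition]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.start)
        for a, b in zip(bs, bs[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"overlapping bins on {chrom}: {a.label!r} and {b.label!r}"
                )


@dataclass
class CallTable:
    """Per-sample, per-CDH presence/absence calls with consensus support.

    ``table`` columns: sample_id, cdh, call, consensus_fraction, n_rounds.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "cdh", "call", "consensus_fraction", "n_rounds"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"call table missing columns: {sorted(missing)}")
        bad = set(self.table["call"]) - CALLS - {"unknown"}
        if bad:
            raise FormatError(f"unrecognized call token(s): {sorted(bad)}")
        cf = self.table["consensus_fraction"].to_numpy(dtype=float)
        if len(cf) and ((cf < 0) | (cf > 1)).any():
            raise ValueError("consensus_fraction must lie in [0, 1]")

    def call_for(self, sample_id: str, cdh: str) -> str:
        t = self.table
        row = t[(t["sample_id"] == sample_id) & (t["cdh"] == cdh)]
        if row.empty:
            return "unknown"
        return str(row["call"].iloc[0])

    def samples_with_call(self, cdh: str, call: str) -> list[str]:
        t = self.table
        return list(t.loc[(t["cdh"] == cdh) & (t["call"] == call), "sample_id"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc


def read_tag_matrix(counts_path: str | Path, bed_path: str | Path) -> TagMatrix:
    """Load a tag count matrix (TSV) and its BED companion.

    The counts file has a header row of sample ids and a first column
    ``tag_id``.  The BED file has >= 5 columns: chrom, start, end,
    tag_id, mapq.  Every tag in the counts file must have exactly one
    BED record; order of the counts file is preserved.
    """
    raw = _read_tsv(counts_path)
    if raw.empty and len(raw.columns) == 0:
        raise FormatError(f"{counts_path}: empty file")
    if raw.columns[0] != "tag_id":
        raise FormatError(f"{counts_path}: first column must be 'tag_id', got {raw.columns[0]!r}")
    sample_ids = list(raw.columns[1:])
    raw = raw.set_index("tag_id")

    counts = pd.DataFrame(index=raw.index, dtype=np.int64)
    parsed = {}
    for col in sample_ids:
        s = pd.to_numeric(raw[col], errors="coerce")
        bad = s.isna() | (s != s.round())
        if bad.any():
            tag = raw.index[bad.to_numpy()][0]
            raise FormatError(
                f"{counts_path}: non-integer count at tag {tag!r}, sample {col!r}"
            )
        if (s < 0).any():
            tag = raw.index[(s < 0).to_numpy()][0]
            raise FormatError(
                f"{counts_path}: negative count at tag {tag!r}, sample {col!r}"
            )
        parsed[col] = s.astype(np.int64)
    counts = pd.DataFrame(parsed, index=raw.index) if parsed else pd.DataFrame(
        index=raw.index
    )

    bed = _read_tsv(bed_path, header=None)
    if bed.shape[1] < 5:
        raise FormatError(f"{bed_path}: BED needs >= 5 columns (chrom, start, end, tag_id, mapq)")
    bed = bed.iloc[:, :5]
    bed.columns = ["chrom", "start", "end", "tag_id", "mapq"]
    for col in ("start", "end", "mapq"):
        s = pd.to_numeric(bed[col], errors="coerce")
        if s.isna().any():
            i = int(np.flatnonzero(s.isna())[0])
            raise FormatError(f"{bed_path}: non-numeric {col} at line {i + 1}")
        bed[col] = s.astype(np.int64)
    if bed["tag_id"].duplicated().any():
        dup = bed.loc[bed["tag_id"].duplicated(), "tag_id"].iloc[0]
        raise FormatError(f"{bed_path}: duplicate tag_id {dup!r}")
    bed = bed.set_index("tag_id")

    missing = counts.index.difference(bed.index)
    if len(missing):
        raise FormatError(
            f"{bed_path}: tag id(s) missing from BED: {sorted(map(str, missing))}"
        )
    locations = bed.loc[counts.index, ["chrom", "start", "end", "mapq"]]
    return TagMatrix(locations=locations, counts=counts)


def write_tag_matrix(tags: TagMatrix, counts_path: str | Path, bed_path: str | Path) -> None:
    out = tags.counts.copy()
    out.insert(0, "tag_id", out.index)
    out.to_csv(counts_path, sep="\t", index=False)
    bed = tags.locations.reset_index()
    # standard BED column order
    bed = bed[["chrom", "start", "end", "tag_id", "mapq"]]
    bed.to_csv(bed_path, sep="\t", index=False, header=False)


def read_manifest(path: str | Path) -> ControlManifest:
    """Load a sample manifest TSV.

    Required columns: sample_id, sample_class.  Any column not in the
    fixed set is treated as a CDH status column.  Absent copy_class /
    ab10_type columns are filled with 'unknown'.
    """
    t = _read_tsv(path)
    for col in ("sample_id", "sample_class"):
        if col not in t.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if t["sample_id"].duplicated().any():
        dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicated sample_id {dup!r}")
    t = t.set_index("sample_id")
    for col in ("copy_class", "ab10_type"):
        if col not in t.columns:
            t[col] = "unknown"
    cdh_cols = [c for c in t.columns if c not in _MANIFEST_FIXED]
    for c in cdh_cols:
        t[c] = t[c].replace("", "unknown")
    return ControlManifest(t)


def write_manifest(manifest: ControlManifest, path: str | Path) -> None:
    out = manifest.table.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_bins(path: str | Path) -> list[BinDefinition]:
    """Load bin definitions from TSV (chrom, start, end, label, diagnostic_for)."""
    t = _read_tsv(path)
    required = {"chrom", "start", "end", "label"}
    missing = required - set(t.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    bins = []
    for i, row in t.iterrows():
        diag = row.get("diagnostic_for", "")
        bins.append(
            BinDefinition(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                label=str(row["label"]),
                diagnostic_for=str(diag) if diag not in ("", "none") else None,
            )
        )
    check_bins_disjoint(bins)
    return bins


def write_bins(bins: Sequence[BinDefinition], path: str | Path) -> None:
    rows = [
        {
            "chrom": b.chrom,
            "start": b.start,
            "end": b.end,
            "label": b.label,
            "diagnostic_for": b.diagnostic_for or "",
        }
        for b in bins
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "diagnostic_for"]).to_csv(
        path, sep="\t", index=False
    )


def read_call_table(path: str | Path) -> CallTable:
    t = _read_tsv(path)
    if t.empty:
        t = pd.DataFrame(
            columns=["sample_id", "cdh", "call", "consensus_fraction", "n_rounds"]
        )
    t["consensus_fraction"] = pd.to_numeric(t["consensus_fraction"])
    t["n_rounds"] = pd.to_numeric(t["n_rounds"]).astype(int)
    return CallTable(t.reset_index(drop=True))


def write_call_table(calls: CallTable, path: str | Path) -> None:
    calls.table.to_csv(path, sep="\t", index=False)
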