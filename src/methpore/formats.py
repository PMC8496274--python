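"""Readers and writers for the external formats the pipeline touches.

Formats handled here:

* FASTA (read) — transcriptome or genome contigs for CpG counting.
* Per-read methylation call tables (read) — the tab-separated per-read ×
  CpG-group output dialect of signal-level 5mC callers, one row per read per
  CpG group with a log-likelihood ratio (positive = methylated).
* Site frequency tables (read/write) — per-CpG-group aggregates.
* BED6 (write) — differentially methylated regions.
* Sample sheets (read) — sample_id / call-file path / group label.

Coordinate convention: every internal position is 0-based with an inclusive
end. Only the BED writer converts to half-open.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import FormatError

logger = logging.getLogger("methpore")

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")

#: canonical column order of a site frequency table
SITE_TABLE_COLUMNS = [
    "chromosome",
    "start",
    "end",
    "num_motifs_in_group",
    "called_sites",
    "called_sites_methylated",
    "methylated_frequency",
    "group_sequence",
]

#: columns a per-read call table must provide (num_cpgs accepted for num_motifs)
CALL_TABLE_REQUIRED = [
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "num_motifs",
    "sequence",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (IUPAC alphabet, case preserved)."""

    id: str
    seq: str


@dataclass(frozen=True)
class PerReadCall:
    """One read's methylation evidence at one CpG group.

    ``start``/``end`` are the 0-based forward-strand positions of the first
    and last CpG cytosine in the group (inclusive); ``llr`` is the
    log-likelihood ratio of methylated over unmethylated, so positive values
    support 5mC. ``group_seq`` is the local sequence context containing the
    group's ``n_motifs`` CG dinucleotides.
    """

    contig: str
    strand: str
    start: int
    end: int
    read_id: str
    llr: float
    n_motifs: int
    group_seq: str


@dataclass(frozen=True)
class SiteMethylation:
    """Aggregate methylation at one CpG group (or one CpG after splitting).

    ``called_sites`` counts called reads times motifs in the group, matching
    the layout of the standard frequency-summarising helper scripts;
    ``frequency`` is called_methylated / called_sites.
    """

    contig: str
    start: int
    end: int
    n_motifs: int
    called_sites: int
    called_methylated: int
    frequency: float
    group_seq: str

    @property
    def called_reads(self) -> int:
        return self.called_sites // self.n_motifs


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    path: str
    group: str


@dataclass(frozen=True)
class SampleSheet:
    """Assignment of per-sample call files to experimental groups."""

    entries: tuple[SampleEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample ids in sample sheet: {dupes}")
        if not self.entries:
            raise FormatError("sample sheet is empty")

    @property
    def samples(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def groups(self) -> dict[str, str]:
        return {e.sample_id: e.group for e in self.entries}

    def by_group(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for e in self.entries:
            out.setdefault(e.group, []).append(e.sample_id)
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Wrapped sequence lines are concatenated; case is preserved (downstream
    counting is case-insensitive). Raises :class:`FormatError` naming the
    offending line for malformed headers, empty sequences, duplicate ids or
    non-IUPAC characters.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(
                f"{path}: empty sequence for record '{header}' (header at line {header_line})"
            )
        records.append(SequenceRecord(id=header, seq=seq))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: malformed FASTA header at line {line_no}")
                if name in seen:
                    raise FormatError(f"{path}: duplicate record id '{name}' at line {line_no}")
                seen.add(name)
                header, header_line = name, line_no
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence data before any header at line {line_no}"
                    )
                bad = set(line.upper()) - _IUPAC_DNA
                if bad:
                    raise FormatError(
                        f"{path}: non-IUPAC characters {sorted(bad)} at line {line_no}"
                    )
                chunks.append(line)
        flush(line_no=-1)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Per-read call tables


def _resolve_call_columns(fieldnames: Sequence[str]) -> dict[str, str]:
    """Map canonical column names to the file's actual header names."""
    names = list(fieldnames)
    mapping: dict[str, str] = {}
    missing: list[str] = []
    for col in CALL_TABLE_REQUIRED:
        if col in names:
            mapping[col] = col
        elif col == "num_motifs" and "num_cpgs" in names:
            # older caller versions name the motif count num_cpgs
            mapping[col] = "num_cpgs"
        else:
            missing.append(col)
    if missing:
        raise FormatError(f"call table missing mandatory columns: {missing}")
    return mapping


def _parse_call_row(row: Mapping[str, str], cols: Mapping[str, str], line_no: int) -> PerReadCall:
    try:
        contig = row[cols["chromosome"]]
        strand = row[cols["strand"]]
        start = int(row[cols["start"]])
        end = int(row[cols["end"]])
        read_id = row[cols["read_name"]]
        llr = float(row[cols["log_lik_ratio"]])
        n_motifs = int(row[cols["num_motifs"]])
        group_seq = row[cols["sequence"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"line {line_no}: cannot coerce row fields ({exc})") from exc
    if strand not in ("+", "-"):
        raise FormatError(f"line {line_no}: strand must be '+' or '-', got {strand!r}")
    if not math.isfinite(llr):
        raise FormatError(f"line {line_no}: non-finite log_lik_ratio {llr!r}")
    if start > end:
        raise FormatError(f"line {line_no}: start {start} > end {end}")
    if n_motifs < 1:
        raise FormatError(f"line {line_no}: num_motifs must be >= 1, got {n_motifs}")
    n_cg = group_seq.upper().count("CG")
    if n_cg != n_motifs:
        raise FormatError(
            f"line {line_no}: num_motifs={n_motifs} but sequence contains {n_cg} CG dinucleotides"
        )
    if n_motifs == 1 and start != end:
        raise FormatError(f"line {line_no}: single-motif group must have start == end")
    return PerReadCall(contig, strand, start, end, read_id, llr, n_motifs, group_seq)


def read_methylation_calls(
    path: str | Path, strict: bool = False
) -> Iterator[PerReadCall]:
    """Stream per-read methylation calls from a tab-separated call table.

    Rows that fail type coercion or the group invariants are skipped with a
    warning naming the line number (or raised, with ``strict=True``). Both
    ``num_motifs`` and ``num_cpgs`` header spellings are accepted.
    """
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header row")
        cols = _resolve_call_columns(reader.fieldnames)
        n_rejected = 0
        for line_no, row in enumerate(reader, start=2):
            try:
                yield _parse_call_row(row, cols, line_no)
            except FormatError as exc:
                if strict:
                    raise FormatError(f"{path}: {exc}") from exc
                n_rejected += 1
                logger.warning("%s: rejected row — %s", path, exc)
        if n_rejected:
            logger.info("%s: %d rows rejected during parsing", path, n_rejected)


def calls_to_frame(calls: Iterable[PerReadCall]) -> pd.DataFrame:
    """Materialize a call stream as a DataFrame with canonical column names."""
    return pd.DataFrame(
        [
            (c.contig, c.strand, c.start, c.end, c.read_id, c.llr, c.n_motifs, c.group_seq)
            for c in calls
        ],
        columns=[
            "chromosome",
            "strand",
            "start",
            "end",
            "read_name",
            "log_lik_ratio",
            "num_motifs",
            "sequence",
        ],
    )


def write_call_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a per-read call table in the consumed dialect (emits num_motifs)."""
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site frequency tables


def sites_to_frame(records: Sequence[SiteMethylation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.contig,
                r.start,
                r.end,
                r.n_motifs,
                r.called_sites,
                r.called_methylated,
                r.frequency,
                r.group_seq,
            )
            for r in records
        ],
        columns=SITE_TABLE_COLUMNS,
    )


def frame_to_sites(frame: pd.DataFrame) -> list[SiteMethylation]:
    return [
        SiteMethylation(
            contig=row.chromosome,
            start=int(row.start),
            end=int(row.end),
            n_motifs=int(row.num_motifs_in_group),
            called_sites=int(row.called_sites),
            called_methylated=int(row.called_sites_methylated),
            frequency=float(row.methylated_frequency),
            group_seq=row.group_sequence,
        )
        for row in frame.itertuples(index=False)
    ]


def _check_sorted(records: Sequence[SiteMethylation]) -> None:
    keys = [(r.contig, r.start) for r in records]
    if keys != sorted(keys):
        raise FormatError("site records must be sorted by (contig, start)")


def write_site_table(
    records: Sequence[SiteMethylation],
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write a site frequency table (TSV, ``#``-prefixed parameter header).

    Input must be sorted by (contig, start); downstream merging assumes it.
    """
    _check_sorted(records)
    with open(path, "w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        sites_to_frame(records).to_csv(fh, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[SiteMethylation]:
    """Read a site frequency table, verifying frequency == methylated/called."""
    frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in SITE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: site table missing columns: {missing}")
    if len(frame):
        if (frame["called_sites"] <= 0).any():
            raise FormatError(f"{path}: called_sites must be positive")
        expect = frame["called_sites_methylated"] / frame["called_sites"]
        bad = (frame["methylated_frequency"] - expect).abs() > 1e-9
        if bad.any():
            first = frame.index[bad][0]
            raise FormatError(
                f"{path}: methylated_frequency inconsistent with counts at data row {first}"
            )
    records = frame_to_sites(frame)
    _check_sorted(records)
    return records


# ---------------------------------------------------------------------------
# Sample sheets


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet TSV with columns sample_id, path, group."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in ("sample_id", "path", "group") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns: {missing}")
    entries = tuple(
        SampleEntry(row.sample_id, row.path, row.group)
        for row in frame.itertuples(index=False)
    )
    return SampleSheet(entries=entries)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        [(e.sample_id, e.path, e.group) for e in sheet.entries],
        columns=["sample_id", "path", "group"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED export


def write_bed(regions: Sequence["DMRegion"], path: str | Path) -> None:  # noqa: F821
    """Write regions as BED6.

    Internal coordinates are 0-based inclusive; BED is half-open, so
    ``bed_end = end + 1``. The score is the mean absolute between-group
    frequency difference scaled to 0–1000 and clipped.
    """
    with open(path, "w") as fh:
        for i, region in enumerate(regions, start=1):
            means = list(region.group_means.values())
            diff = abs(means[0] - means[1]) if len(means) == 2 else 0.0
            score = int(min(1000, max(0, round(diff * 1000))))
            name = f"dmr_{i}"
            fh.write(
                f"{region.contig}\t{region.start}\t{region.end + 1}\t{name}\t{score}\t.\n"
            )
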