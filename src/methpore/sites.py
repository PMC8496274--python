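"""Per-site methylation frequencies from per-read log-likelihood calls.

A read at a CpG group is called methylated when its log-likelihood ratio
exceeds ``+call_threshold``, unmethylated below ``-call_threshold``, and
ambiguous in between (ambiguous reads are excluded from both numerator and
denominator). Counts are reported per CpG group as called reads x motifs, so
they match the layout of the standard frequency-summarising helpers; groups
can optionally be split back into single-CpG records.
"""

from __future__ import annotations

import logging
import math
import re
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .formats import PerReadCall, SiteMethylation, calls_to_frame

logger = logging.getLogger("methpore")

DEFAULT_CALL_THRESHOLD = 2.0


class Call(Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    AMBIGUOUS = "ambiguous"


def call_read(llr: float, call_threshold: float = DEFAULT_CALL_THRESHOLD) -> Call:
    """Classify one read's LLR against a symmetric threshold."""
    if call_threshold <= 0:
        raise ParameterError(f"call_threshold must be positive, got {call_threshold}")
    if not math.isfinite(llr):
        raise DataError(f"non-finite log-likelihood ratio: {llr!r}")
    if llr > call_threshold:
        return Call.METHYLATED
    if llr < -call_threshold:
        return Call.UNMETHYLATED
    return Call.AMBIGUOUS


def summarize_llr_matrix(
    llrs: np.ndarray, call_threshold: float = DEFAULT_CALL_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized read calling over a (groups x reads) LLR array.

    Returns per-group (called reads, methylated reads); distributionally and
    numerically identical to applying :func:`call_read` read by read.
    """
    if call_threshold <= 0:
        raise ParameterError(f"call_threshold must be positive, got {call_threshold}")
    meth = llrs > call_threshold
    unmeth = llrs < -call_threshold
    return (meth | unmeth).sum(axis=-1), meth.sum(axis=-1)


def _cg_offsets(group_seq: str) -> list[int]:
    return [m.start() for m in re.finditer("CG", group_seq.upper())]


def _split_group(
    contig: str,
    start: int,
    n_motifs: int,
    group_seq: str,
    called_reads: int,
    meth_reads: int,
) -> list[SiteMethylation]:
    """Expand a multi-CpG group into per-CpG records at each CG's C offset.

    Each CpG inherits the group's read counts (the caller reports one shared
    call for the whole group). The per-record context is trimmed to the
    window around its CG so it contains exactly one CG.
    """
    offsets = _cg_offsets(group_seq)
    out = []
    for i, off in enumerate(offsets):
        pos = start + off - offsets[0]
        lo = offsets[i - 1] + 2 if i > 0 else 0
        hi = offsets[i + 1] if i + 1 < len(offsets) else len(group_seq)
        out.append(
            SiteMethylation(
                contig=contig,
                start=pos,
                end=pos,
                n_motifs=1,
                called_sites=called_reads,
                called_methylated=meth_reads,
                frequency=meth_reads / called_reads,
                group_seq=group_seq[lo:hi],
            )
        )
    return out


def aggregate_sites(
    calls: Iterable[PerReadCall] | pd.DataFrame,
    call_threshold: float = DEFAULT_CALL_THRESHOLD,
    split_groups: bool = False,
    collapse_strands: bool = True,
) -> list[SiteMethylation]:
    """Aggregate per-read calls into per-group methylation frequencies.

    Reads are grouped by (contig, start, end); called_sites = unambiguous
    reads x motifs, called_methylated = methylated reads x motifs. Groups
    with no unambiguous read are dropped. Duplicate (read, group) pairs keep
    the first occurrence. With ``collapse_strands`` (default), '-'-strand
    calls are shifted one base left onto the forward-strand C of the
    palindromic CpG; otherwise strands are kept as distinct groups.

    With ``split_groups``, every multi-CpG group is expanded into single-CpG
    records at the forward-strand C offset of each CG in its context.
    """
    frame = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    if frame.empty:
        return []
    frame = frame.copy()

    if collapse_strands:
        minus = frame["strand"] == "-"
        if minus.any():
            frame.loc[minus, ["start", "end"]] -= 1
            frame.loc[minus, "strand"] = "+"
        key = ["chromosome", "start", "end"]
    else:
        key = ["chromosome", "strand", "start", "end"]

    n_before = len(frame)
    frame = frame.drop_duplicates(subset=key + ["read_name"], keep="first")
    if len(frame) != n_before:
        logger.info(
            "collapsed %d duplicate (read, group) call rows", n_before - len(frame)
        )

    llr = frame["log_lik_ratio"].to_numpy()
    if not np.isfinite(llr).all():
        raise DataError("non-finite log-likelihood ratios in call table")
    frame["_meth"] = llr > call_threshold
    frame["_called"] = frame["_meth"] | (llr < -call_threshold)

    grouped = frame.groupby(key, sort=True)
    agg = grouped.agg(
        n_motifs=("num_motifs", "first"),
        n_motifs_nunique=("num_motifs", "nunique"),
        group_seq=("sequence", "first"),
        seq_nunique=("sequence", "nunique"),
        called_reads=("_called", "sum"),
        meth_reads=("_meth", "sum"),
    ).reset_index()

    bad = agg[(agg["n_motifs_nunique"] > 1) | (agg["seq_nunique"] > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise DataError(
            "conflicting num_motifs/sequence within group "
            f"{row['chromosome']}:{row['start']}-{row['end']}"
        )

    n_groups = len(agg)
    agg = agg[agg["called_reads"] > 0]
    logger.info(
        "aggregate_sites: %d groups observed, %d with >=1 called read "
        "(call_threshold=%g)",
        n_groups, len(agg), call_threshold,
    )

    records: list[SiteMethylation] = []
    for row in agg.itertuples(index=False):
        called = int(row.called_reads)
        meth = int(row.meth_reads)
        if split_groups and row.n_motifs > 1:
            records.extend(
                _split_group(
                    row.chromosome, int(row.start), int(row.n_motifs),
                    row.group_seq, called, meth,
                )
            )
        else:
            n_motifs = int(row.n_motifs)
            records.append(
                SiteMethylation(
                    contig=row.chromosome,
                    start=int(row.start),
                    end=int(row.end),
                    n_motifs=n_motifs,
                    called_sites=called * n_motifs,
                    called_methylated=meth * n_motifs,
                    frequency=meth / called,
                    group_seq=row.group_seq,
                )
            )
    records.sort(key=lambda r: (r.contig, r.start, r.end))
    return records


def filter_min_called(
    sites: Sequence[SiteMethylation], min_called: int
) -> list[SiteMethylation]:
    """Keep sites covered by at least ``min_called`` called reads.

    The threshold counts reads (called_sites / n_motifs), not read x motif
    products, so multi-CpG groups are not advantaged.
    """
    if min_called < 1:
        raise ParameterError(f"min_called must be >= 1, got {min_called}")
    kept = [s for s in sites if s.called_reads >= min_called]
    logger.info(
        "coverage filter (min %d called reads): %d -> %d sites",
        min_called, len(sites), len(kept),
    )
    return kept
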