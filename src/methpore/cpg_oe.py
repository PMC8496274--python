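"""CpG observed/expected (CpG O/E) depletion statistic.

Germline 5mC deaminates to thymine over evolutionary time, so historically
methylated sequence is depleted of CpG dinucleotides relative to the
expectation from its C and G composition. For a sequence of length ``l``:

    CpG O/E = n_CpG / (n_C * n_G) * l^2 / (l - 1)

Low values indicate historical methylation; values near 1 indicate none.
Records outside the strict bounds (0.001, 2) are treated as outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .errors import ParameterError, UndefinedStatisticError
from .formats import SequenceRecord

logger = logging.getLogger("methpore")

#: strict default outlier bounds on CpG O/E
OE_LO = 0.001
OE_HI = 2.0


class CpGCounts(NamedTuple):
    n_c: int
    n_g: int
    n_cpg: int
    length: int


@dataclass(frozen=True)
class CpGOERecord:
    """Per-sequence CpG depletion statistic with its raw counts.

    ``oe`` is NaN when the statistic is undefined (no C, no G, or length < 2);
    such records are flagged, not dropped, so filter funnels stay auditable.
    """

    seq_id: str
    length: int
    n_c: int
    n_g: int
    n_cpg: int
    oe: float
    defined: bool
    outlier: bool


def count_cpg_features(seq: str) -> CpGCounts:
    """Count C, G and forward-strand CpG dinucleotides, case-insensitively.

    Ambiguity codes (N etc.) count toward the length but not toward any base
    or dinucleotide count. CG cannot overlap itself, so a plain substring
    count enumerates every offset.
    """
    if not seq:
        raise ParameterError("cannot count features of an empty sequence")
    upper = seq.upper()
    return CpGCounts(
        n_c=upper.count("C"),
        n_g=upper.count("G"),
        n_cpg=upper.count("CG"),
        length=len(upper),
    )


def cpg_oe(counts: CpGCounts) -> float:
    """Evaluate CpG O/E = n_CpG/(n_C·n_G) · l²/(l−1) in exact rational
    arithmetic, converting to float only at the end."""
    n_c, n_g, n_cpg, length = counts
    if n_c == 0 or n_g == 0 or length < 2:
        raise UndefinedStatisticError(
            f"CpG O/E undefined for counts {counts} (needs C>0, G>0, length>=2)"
        )
    value = Fraction(n_cpg, n_c * n_g) * Fraction(length * length, length - 1)
    return float(value)


def compute_oe(
    records: Iterable[SequenceRecord], lo: float = OE_LO, hi: float = OE_HI
) -> list[CpGOERecord]:
    """Compute a :class:`CpGOERecord` for every sequence.

    Undefined statistics are flagged (``defined=False``, ``outlier=True``)
    rather than raised, so a single degenerate contig does not abort a run.
    """
    out: list[CpGOERecord] = []
    for rec in records:
        counts = count_cpg_features(rec.seq)
        try:
            oe = cpg_oe(counts)
            defined = True
        except UndefinedStatisticError:
            oe = float("nan")
            defined = False
        outlier = not (lo < oe < hi) if defined else True
        out.append(
            CpGOERecord(
                seq_id=rec.id,
                length=counts.length,
                n_c=counts.n_c,
                n_g=counts.n_g,
                n_cpg=counts.n_cpg,
                oe=oe,
                defined=defined,
                outlier=outlier,
            )
        )
    return out


def filter_oe_outliers(
    records: Sequence[CpGOERecord], lo: float = OE_LO, hi: float = OE_HI
) -> list[CpGOERecord]:
    """Keep records with lo < CpG O/E < hi (strict on both sides)."""
    kept = [r for r in records if r.defined and lo < r.oe < hi]
    logger.info(
        "CpG O/E outlier filter (%g, %g): %d -> %d sequences",
        lo, hi, len(records), len(kept),
    )
    return kept


def oe_frame(records: Sequence[CpGOERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.seq_id, r.length, r.n_c, r.n_g, r.n_cpg, r.oe, r.outlier)
            for r in records
        ],
        columns=["seq_id", "length", "n_C", "n_G", "n_CpG", "cpg_oe", "outlier"],
    )
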