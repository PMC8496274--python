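"""Transcript-level methylation and its validation against CpG depletion.

Invertebrate gene-body methylation leaves an evolutionary footprint: the more
a transcript is methylated in the germline, the more CpG-depleted its
sequence becomes. This module aggregates site frequencies to the transcript
level and provides the two validation statistics: the Pearson correlation of
transcript methylation against CpG O/E, and a two-sample t-test of CpG O/E
between fully unmethylated (frequency exactly 0) and fully methylated
(exactly 1) transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DataError, UndefinedStatisticError
from .formats import SiteMethylation

logger = logging.getLogger("methpore")

CLASS_UNMETHYLATED = "fully_unmethylated"
CLASS_METHYLATED = "fully_methylated"
CLASS_INTERMEDIATE = "intermediate"

DEFAULT_MIN_COVERAGE_FRACTION = 0.2


@dataclass(frozen=True)
class TranscriptMethylation:
    """Per-transcript methylation summary.

    ``mean_frequency`` pools read counts over the transcript's covered CpG
    groups (sum methylated / sum called), so deeply covered sites weigh more;
    ``coverage_fraction`` is the fraction of the transcript's CpGs with a
    methylation call.
    """

    seq_id: str
    n_cpgs_total: int
    n_cpgs_called: int
    coverage_fraction: float
    mean_frequency: float
    methylation_class: str


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ExtremesResult:
    """Two-sample t-test of CpG O/E between the fully un/methylated classes."""

    t_statistic: float
    p_value: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    perfect_separation: bool


def _classify(mean_frequency: float) -> str:
    if mean_frequency == 0.0:
        return CLASS_UNMETHYLATED
    if mean_frequency == 1.0:
        return CLASS_METHYLATED
    return CLASS_INTERMEDIATE


def transcript_methylation(
    sites: Sequence[SiteMethylation],
    cpg_totals: Mapping[str, int],
    weighted: bool = True,
) -> list[TranscriptMethylation]:
    """Aggregate site frequencies to per-transcript methylation levels.

    ``cpg_totals`` maps each transcript id to its total CpG count (from
    counting on the same FASTA the reads were mapped to). ``weighted=False``
    switches from pooled counts to the unweighted mean of site frequencies.
    """
    by_contig: dict[str, list[SiteMethylation]] = {}
    for site in sites:
        by_contig.setdefault(site.contig, []).append(site)

    out: list[TranscriptMethylation] = []
    for contig, contig_sites in sorted(by_contig.items()):
        if contig not in cpg_totals:
            raise DataError(
                f"contig '{contig}' has methylation calls but is absent from the "
                "sequence CpG totals (mapping/FASTA mismatch)"
            )
        n_total = cpg_totals[contig]
        n_called = sum(s.n_motifs for s in contig_sites)
        if weighted:
            called = sum(s.called_sites for s in contig_sites)
            meth = sum(s.called_methylated for s in contig_sites)
            mean_freq = meth / called
        else:
            mean_freq = float(np.mean([s.frequency for s in contig_sites]))
        out.append(
            TranscriptMethylation(
                seq_id=contig,
                n_cpgs_total=n_total,
                n_cpgs_called=n_called,
                coverage_fraction=n_called / n_total,
                mean_frequency=mean_freq,
                methylation_class=_classify(mean_freq),
            )
        )
    return out


def filter_transcript_coverage(
    records: Sequence[TranscriptMethylation],
    min_fraction: float = DEFAULT_MIN_COVERAGE_FRACTION,
) -> list[TranscriptMethylation]:
    """Keep transcripts with calls at >= ``min_fraction`` of their CpGs.

    The exclusion rule is "fewer than" the threshold, so a transcript at
    exactly the threshold survives.
    """
    kept = [r for r in records if r.coverage_fraction >= min_fraction]
    logger.info(
        "transcript coverage filter (>=%.0f%% of CpGs called): %d -> %d transcripts",
        min_fraction * 100, len(records), len(kept),
    )
    return kept


def correlate_oe_methylation(
    oe: Sequence[float], mean_frequency: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation of CpG O/E against transcript methylation.

    Two-sided p-value from the t distribution with n-2 degrees of freedom.
    Under genuine gene-body methylation the correlation is negative.
    """
    x = np.asarray(oe, dtype=float)
    y = np.asarray(mean_frequency, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError(f"need >= 3 paired observations, got {len(x)} and {len(y)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: a variable has zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def compare_extremes(
    records: Sequence[TranscriptMethylation],
    oe_by_id: Mapping[str, float],
    equal_var: bool = False,
) -> ExtremesResult:
    """t-test of CpG O/E between fully unmethylated and fully methylated
    transcripts (Welch by default; ``equal_var=True`` for the pooled form).

    When both classes have zero internal variance but different means the
    statistic is undefined and the result is flagged as perfect separation.
    """
    groups: dict[str, list[float]] = {CLASS_UNMETHYLATED: [], CLASS_METHYLATED: []}
    for rec in records:
        if rec.methylation_class in groups and rec.seq_id in oe_by_id:
            groups[rec.methylation_class].append(oe_by_id[rec.seq_id])
    for name, vals in groups.items():
        if not vals:
            raise DataError(f"no transcripts in class '{name}'")
    a = np.asarray(groups[CLASS_UNMETHYLATED], dtype=float)
    b = np.asarray(groups[CLASS_METHYLATED], dtype=float)
    means = {CLASS_UNMETHYLATED: float(a.mean()), CLASS_METHYLATED: float(b.mean())}
    ns = {CLASS_UNMETHYLATED: len(a), CLASS_METHYLATED: len(b)}

    var_a = a.var(ddof=1) if len(a) > 1 else 0.0
    var_b = b.var(ddof=1) if len(b) > 1 else 0.0
    if var_a == 0.0 and var_b == 0.0:
        if a.mean() != b.mean():
            return ExtremesResult(
                t_statistic=float("nan"), p_value=float("nan"),
                group_means=means, group_ns=ns, perfect_separation=True,
            )
        return ExtremesResult(0.0, 1.0, means, ns, perfect_separation=False)

    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return ExtremesResult(
        t_statistic=float(t), p_value=float(p),
        group_means=means, group_ns=ns, perfect_separation=False,
    )
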