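"""Two-group genome-wide differential methylation.

Builds the positions x samples frequency matrix from per-sample site tables
(strict intersection: a position is kept only if every sample covers it with
at least ``min_called`` called reads), then provides genome-wide summaries,
PCA of sample methylation patterns, per-position two-sample t-tests with
Benjamini-Hochberg FDR correction, detection of "perfect" differences
(positions with zero within-group variance and differing group means, where
the t statistic is undefined), and single-linkage merging of flagged
positions into differentially methylated regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError, UndefinedStatisticError
from .formats import SampleSheet, SiteMethylation, sites_to_frame

logger = logging.getLogger("methpore")

DEFAULT_MIN_CALLED = 3
DEFAULT_ALPHA = 0.05
DEFAULT_MAX_GAP = 2000
DEFAULT_EPSILON = 1e-12

POSITION_COLUMNS = ["contig", "start", "end", "n_motifs"]


@dataclass
class MethylationMatrix:
    """Positions x samples methylation frequencies with per-cell coverage.

    ``positions`` has columns contig, start, end, n_motifs (0-based inclusive
    coordinates); ``frequencies`` and ``coverages`` are (P, S) arrays aligned
    with ``samples``; ``groups`` maps sample id to group label.
    """

    positions: pd.DataFrame
    samples: list[str]
    groups: dict[str, str]
    frequencies: np.ndarray
    coverages: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def group_columns(self) -> dict[str, np.ndarray]:
        """Column indices of each group, in first-appearance order."""
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            out.setdefault(self.groups[s], []).append(j)
        return {g: np.asarray(idx) for g, idx in out.items()}


@dataclass(frozen=True)
class DMRegion:
    """A merged run of flagged positions with per-group mean frequencies."""

    contig: str
    start: int
    end: int
    n_positions: int
    group_means: dict[str, float]
    members: tuple[int, ...] = field(default=())  # row indices into the matrix


@dataclass(frozen=True)
class GenomewideResult:
    sample_means: dict[str, float]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    t_statistic: float
    p_value: float
    perfect_separation: bool


@dataclass(frozen=True)
class PCAResult:
    """Sample scores, loadings and variance-explained fractions.

    Samples are observations and positions variables; frequencies are
    centered per position but not scaled (they share the [0, 1] scale). Sign
    convention: the largest-magnitude loading of each component is positive.
    """

    scores: pd.DataFrame  # samples x components
    variance_ratio: np.ndarray
    loadings: np.ndarray  # positions x components


def _site_frame(table: Sequence[SiteMethylation] | pd.DataFrame) -> pd.DataFrame:
    frame = table if isinstance(table, pd.DataFrame) else sites_to_frame(table)
    frame = frame.rename(columns={"chromosome": "contig", "num_motifs_in_group": "n_motifs"})
    frame["called_reads"] = frame["called_sites"] // frame["n_motifs"]
    return frame[
        ["contig", "start", "end", "n_motifs", "called_reads", "methylated_frequency"]
    ]


def build_matrix(
    site_tables: Mapping[str, Sequence[SiteMethylation] | pd.DataFrame],
    sample_sheet: SampleSheet,
    min_called: int = DEFAULT_MIN_CALLED,
) -> MethylationMatrix:
    """Assemble the positions x samples matrix by strict intersection.

    A position survives only if it is present with >= ``min_called`` called
    reads in *every* sample (the literal per-k-mer per-sample threshold);
    the retained matrix therefore has no missing cells.
    """
    if min_called < 1:
        raise ParameterError(f"min_called must be >= 1, got {min_called}")
    missing = [s for s in sample_sheet.samples if s not in site_tables]
    if missing:
        raise DataError(f"sample sheet entries with no site table: {missing}")

    merged: pd.DataFrame | None = None
    for sample in sample_sheet.samples:
        frame = _site_frame(site_tables[sample])
        frame = frame[frame["called_reads"] >= min_called]
        frame = frame.rename(
            columns={
                "called_reads": f"cov_{sample}",
                "methylated_frequency": f"freq_{sample}",
            }
        )
        merged = frame if merged is None else merged.merge(
            frame, on=POSITION_COLUMNS, how="inner"
        )

    assert merged is not None
    merged = merged.sort_values(["contig", "start", "end"]).reset_index(drop=True)
    if merged.empty:
        logger.warning(
            "no position passed the min %d called-reads threshold in every sample",
            min_called,
        )
    samples = sample_sheet.samples
    freqs = merged[[f"freq_{s}" for s in samples]].to_numpy(dtype=float)
    covs = merged[[f"cov_{s}" for s in samples]].to_numpy(dtype=int)
    logger.info(
        "matrix: %d positions x %d samples retained (min %d called reads per sample)",
        len(merged), len(samples), min_called,
    )
    return MethylationMatrix(
        positions=merged[POSITION_COLUMNS].copy(),
        samples=list(samples),
        groups=sample_sheet.groups,
        frequencies=freqs,
        coverages=covs,
    )


def _two_group_indices(matrix: MethylationMatrix) -> tuple[str, str, np.ndarray, np.ndarray]:
    cols = matrix.group_columns()
    if len(cols) != 2:
        raise DataError(f"two-group comparison needs exactly 2 groups, got {list(cols)}")
    (ga, ia), (gb, ib) = cols.items()
    return ga, gb, ia, ib


def genomewide_means(
    matrix: MethylationMatrix, equal_var: bool = False
) -> GenomewideResult:
    """Per-sample mean frequency over all retained positions, and a
    two-sample t-test on the per-group sample means."""
    if matrix.n_positions == 0:
        raise DataError("empty matrix: no positions to summarize")
    sample_means = matrix.frequencies.mean(axis=0)
    means = {s: float(m) for s, m in zip(matrix.samples, sample_means)}
    ga, gb, ia, ib = _two_group_indices(matrix)
    a, b = sample_means[ia], sample_means[ib]
    group_means = {ga: float(a.mean()), gb: float(b.mean())}
    group_sds = {
        ga: float(a.std(ddof=1)) if len(a) > 1 else float("nan"),
        gb: float(b.std(ddof=1)) if len(b) > 1 else float("nan"),
    }
    if len(a) < 2 or len(b) < 2:
        return GenomewideResult(means, group_means, group_sds,
                                float("nan"), float("nan"), False)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() != b.mean():
            return GenomewideResult(means, group_means, group_sds,
                                    float("nan"), float("nan"), True)
        return GenomewideResult(means, group_means, group_sds, 0.0, 1.0, False)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GenomewideResult(means, group_means, group_sds, float(t), float(p), False)


def pca(matrix: MethylationMatrix) -> PCAResult:
    """PCA of samples in methylation-frequency space.

    Computed by SVD of the per-position-centered matrix. Variance-explained
    fractions sum to 1 over all computed components. Deterministic sign
    convention: each component is flipped so its largest-magnitude loading
    is positive.
    """
    if len(matrix.samples) < 3:
        raise DataError(f"PCA needs >= 3 samples, got {len(matrix.samples)}")
    x = matrix.frequencies.T  # samples x positions
    xc = x - x.mean(axis=0, keepdims=True)
    if not np.any(xc):
        raise UndefinedStatisticError("PCA undefined: matrix is constant across samples")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u * s
    loadings = vt.T
    # sign convention
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    variance_ratio = s**2 / np.sum(s**2)
    names = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.samples, columns=names),
        variance_ratio=variance_ratio,
        loadings=loadings,
    )


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test; a, b are (P, n) arrays."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def _pooled(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def per_site_tests(
    matrix: MethylationMatrix,
    flavor: str = "welch",
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Two-sample t-test at every position.

    Returns a DataFrame aligned with ``matrix.positions`` with columns
    ``mean_<groupA>``, ``mean_<groupB>``, ``t``, ``p``, ``perfect``.
    Positions where both group variances are < ``epsilon`` get t/p = NaN and
    ``perfect=True`` when the means differ, or t=0, p=1 when they are equal.
    """
    if flavor not in ("welch", "pooled"):
        raise ParameterError(f"unknown test flavor: {flavor!r}")
    ga, gb, ia, ib = _two_group_indices(matrix)
    a = matrix.frequencies[:, ia]
    b = matrix.frequencies[:, ib]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DataError("per-position tests need >= 2 samples per group")
    test = _welch if flavor == "welch" else _pooled
    t, p = test(a, b)

    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    degenerate = (va < epsilon) & (vb < epsilon)
    diff = np.abs(a.mean(axis=1) - b.mean(axis=1)) > epsilon
    perfect = degenerate & diff
    tied = degenerate & ~diff
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    t[tied] = 0.0
    p[tied] = 1.0

    out = matrix.positions.copy()
    out[f"mean_{ga}"] = a.mean(axis=1)
    out[f"mean_{gb}"] = b.mean(axis=1)
    out["t"] = t
    out["p"] = p
    out["perfect"] = perfect
    logger.info(
        "per-position %s t-tests: %d positions, %d perfect differences",
        flavor, len(out), int(perfect.sum()),
    )
    return out


def bh_adjust(
    p_values: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns (q_values, significant) where q_(i) = min_{j>=i} m * p_(j) / j
    capped at 1, and significant means q <= alpha. Undefined p-values
    (perfect-difference positions) must be excluded by the caller; they are
    not part of the tested family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any()):
        raise DataError("p-values must be finite and in (0, 1]")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


def find_perfect_differences(
    matrix: MethylationMatrix, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Row indices of positions where each group's within-group variance is
    below ``epsilon`` and the group means differ by more than ``epsilon``.

    At these positions the t statistic is undefined (zero pooled variance),
    so they form a separate evidence class from the tested positions.
    """
    _, _, ia, ib = _two_group_indices(matrix)
    a = matrix.frequencies[:, ia]
    b = matrix.frequencies[:, ib]
    mask = (
        (a.var(axis=1, ddof=1) < epsilon)
        & (b.var(axis=1, ddof=1) < epsilon)
        & (np.abs(a.mean(axis=1) - b.mean(axis=1)) > epsilon)
    )
    return np.flatnonzero(mask)


def merge_regions(
    matrix: MethylationMatrix,
    flagged: Sequence[int],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[DMRegion]:
    """Single-linkage merge of flagged positions into regions.

    Same-contig positions whose successive gaps (next start minus previous
    end) are <= ``max_gap`` join one region; each region reports per-group
    mean frequency over its member positions.
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be >= 0, got {max_gap}")
    flagged = list(flagged)
    if not flagged:
        return []
    pos = matrix.positions
    keys = [(pos.iloc[i]["contig"], int(pos.iloc[i]["start"])) for i in flagged]
    if keys != sorted(keys):
        raise DataError("flagged positions must be sorted by (contig, start)")

    cols = matrix.group_columns()
    regions: list[DMRegion] = []
    run: list[int] = []

    def close_run() -> None:
        rows = np.asarray(run)
        sub = pos.iloc[rows]
        group_means = {
            g: float(matrix.frequencies[np.ix_(rows, idx)].mean())
            for g, idx in cols.items()
        }
        regions.append(
            DMRegion(
                contig=sub.iloc[0]["contig"],
                start=int(sub.iloc[0]["start"]),
                end=int(sub.iloc[-1]["end"]),
                n_positions=len(rows),
                group_means=group_means,
                members=tuple(int(r) for r in rows),
            )
        )

    for i in flagged:
        if run:
            prev = pos.iloc[run[-1]]
            cur = pos.iloc[i]
            same = prev["contig"] == cur["contig"]
            gap = int(cur["start"]) - int(prev["end"])
            if same and gap <= max_gap:
                run.append(i)
                continue
            close_run()
            run = []
        run.append(i)
    close_run()
    logger.info(
        "merged %d flagged positions into %d regions (max_gap=%d)",
        len(flagged), len(regions), max_gap,
    )
    return regions


def regions_frame(regions: Sequence[DMRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {
            "contig": r.contig,
            "start": r.start,
            "end": r.end,
            "n_positions": r.n_positions,
            "span_bp": r.end - r.start + 1,
        }
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
        rows.append(row)
    return pd.DataFrame(rows)
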