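"""Synthetic data with known ground truth for every pipeline input.

Three layers, all deterministic under a fixed seed:

* **Sequences** — transcripts whose CpG content decays with their true
  methylation level (each CpG is replaced by TpG with probability
  decay_rate x level), emulating the evolutionary CpG depletion that makes
  CpG O/E an indicator of germline methylation.
* **Per-read calls** — reads drawn per CpG group; each read's methylation
  state is Bernoulli(true frequency) and its log-likelihood ratio is Normal
  (+llr_mu, llr_sigma) if methylated, Normal(-llr_mu, llr_sigma) otherwise,
  reproducing the bimodal LLR distribution of signal-level callers. CpGs
  within ``group_merge_distance`` bases share one group (callers cannot
  resolve CpGs closer than ~6 bases).
* **Experiments** — a multi-sample two-group design (default 4 aposymbiotic
  vs 4 symbiotic, genome-wide means 0.055 vs 0.059) with per-sample jitter
  and optional injected differentially methylated blocks.

The frequency-level fast path (:func:`simulate_frequency_matrix`,
:func:`simulate_transcript_sites`) draws per-read states and LLRs vectorized
and aggregates them with the same thresholding rule as the site aggregator,
skipping the per-read table materialization; it is the layer of choice for
large property simulations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import MethylationMatrix
from .errors import ParameterError
from .formats import (
    SampleEntry,
    SampleSheet,
    SequenceRecord,
    SITE_TABLE_COLUMNS,
    write_call_table,
    write_sample_sheet,
)

_BASES = np.frombuffer(b"ACGT", dtype="u1")


@dataclass(frozen=True)
class DMRSpecEntry:
    """An injected differentially methylated block.

    ``group_freqs`` maps group label to the true frequency inside the block;
    ``jitter_sd`` overrides the global per-sample jitter within the block
    (0 makes every block position a perfect difference).
    """

    contig: str
    start: int
    end: int
    group_freqs: Mapping[str, float]
    jitter_sd: float | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    Defaults encode the emulated study conditions: sparse invertebrate
    methylation (90% of sites near 0, 10% near 1), well-separated LLR modes
    at +/-5 (sd 1), 30 reads per site, a 4 vs 4 design with genome-wide
    baselines 0.055 and 0.059 and tiny between-sample jitter, and ~6 bp CpG
    grouping.
    """

    seed: int
    # transcriptome layer
    n_transcripts: int = 200
    sequence_length: int = 2000
    p_high: float = 0.1
    beta_low: tuple[float, float] = (1.0, 15.0)
    beta_high: tuple[float, float] = (15.0, 1.0)
    p_zero_within_low: float = 0.3
    p_one_within_high: float = 0.3
    decay_rate: float = 0.9
    # read layer
    llr_mu: float = 5.0
    llr_sigma: float = 1.0
    reads_per_site: int = 30
    group_merge_distance: int = 6
    # experiment layer
    n_positions: int = 5000
    position_spacing: int = 50
    contig: str = "tig1"
    group_design: tuple[tuple[str, int, float], ...] = (
        ("aposymbiotic", 4, 0.055),
        ("symbiotic", 4, 0.059),
    )
    jitter_sd: float = 0.002
    sample_offset_sd: float = 0.002
    dmr_spec: tuple[DMRSpecEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory (no silent nondeterminism)")
        if not 0.0 <= self.decay_rate <= 1.0:
            raise ParameterError(
                f"decay_rate x max methylation level must stay in [0, 1]; "
                f"got decay_rate={self.decay_rate}"
            )
        if not 0.0 <= self.p_high <= 1.0:
            raise ParameterError(f"p_high must be in [0, 1], got {self.p_high}")
        if self.llr_mu <= 0 or self.llr_sigma <= 0:
            raise ParameterError("llr_mu and llr_sigma must be positive")
        if self.reads_per_site < 1:
            raise ParameterError("reads_per_site must be >= 1")
        if self.jitter_sd < 0 or self.sample_offset_sd < 0:
            raise ParameterError("jitter_sd and sample_offset_sd must be >= 0")
        for grp, n, base in self.group_design:
            if n < 1 or not 0.0 <= base <= 1.0:
                raise ParameterError(f"bad group design entry {(grp, n, base)}")
        spans: dict[str, list[tuple[int, int]]] = {}
        for entry in self.dmr_spec:
            for s, e in spans.get(entry.contig, []):
                if entry.start <= e and s <= entry.end:
                    raise ParameterError(
                        f"overlapping dmr_spec entries on {entry.contig}"
                    )
            spans.setdefault(entry.contig, []).append((entry.start, entry.end))
            for f in entry.group_freqs.values():
                if not 0.0 <= f <= 1.0:
                    raise ParameterError("dmr_spec frequencies must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ExperimentData:
    """Everything a two-group run needs, plus its ground truth."""

    sheet: SampleSheet
    call_frames: dict[str, pd.DataFrame]
    truth: pd.DataFrame  # per position: group truths, sample truths, dmr flag
    positions: pd.DataFrame


# ---------------------------------------------------------------------------
# sequences


def _draw_levels(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal sparse-methylation prior: mostly near 0, a minority near 1.

    Both modes are point-mass inflated at their extreme (exactly 0 or
    exactly 1): many invertebrate genes carry no gene-body methylation at
    all and a few are uniformly methylated, which is what makes the
    fully-unmethylated vs fully-methylated contrast observable.
    """
    high = rng.random(n) < config.p_high
    levels = rng.beta(*config.beta_low, size=n)
    levels[rng.random(n) < config.p_zero_within_low] = 0.0
    high_levels = rng.beta(*config.beta_high, size=n)
    high_levels[rng.random(n) < config.p_one_within_high] = 1.0
    levels[high] = high_levels[high]
    return levels


def simulate_depleted_sequences(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Transcripts whose CpG content decays with true methylation level.

    Each sequence starts as iid equiprobable bases; every CpG is then
    replaced by TpG independently with probability decay_rate x level.
    Returns the records and a truth table (seq_id, methylation_level).
    """
    rng = config.rng() if rng is None else rng
    levels = _draw_levels(config, rng, config.n_transcripts)
    records: list[SequenceRecord] = []
    for i, level in enumerate(levels):
        arr = _BASES[rng.integers(0, 4, size=config.sequence_length)].copy()
        is_cpg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        offsets = np.flatnonzero(is_cpg)
        decayed = offsets[rng.random(offsets.size) < config.decay_rate * level]
        arr[decayed] = ord("T")
        records.append(
            SequenceRecord(id=f"transcript_{i + 1}", seq=arr.tobytes().decode())
        )
    truth = pd.DataFrame(
        {"seq_id": [r.id for r in records], "methylation_level": levels}
    )
    return records, truth


# ---------------------------------------------------------------------------
# CpG groups and read calls


def transcript_groups(
    records: Sequence[SequenceRecord], merge_distance: int = 6
) -> pd.DataFrame:
    """CpG groups per sequence: consecutive CpGs whose C positions are within
    ``merge_distance`` bases share one group, as the signal-level caller
    reports them. Returns contig, start, end, num_motifs, sequence context."""
    flank = max(0, min(5, merge_distance - 1))
    rows = []
    for rec in records:
        offsets = [m.start() for m in re.finditer("CG", rec.seq.upper())]
        if not offsets:
            continue
        run = [offsets[0]]
        for off in offsets[1:]:
            if off - run[-1] <= merge_distance:
                run.append(off)
            else:
                rows.append(_group_row(rec, run, flank))
                run = [off]
        rows.append(_group_row(rec, run, flank))
    return pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "num_motifs", "sequence"]
    )


def _group_row(rec: SequenceRecord, run: list[int], flank: int) -> tuple:
    lo = max(0, run[0] - flank)
    hi = min(len(rec.seq), run[-1] + 2 + flank)
    return (rec.id, run[0], run[-1], len(run), rec.seq[lo:hi])


def _draw_llrs(
    truth: np.ndarray, reads: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """(groups x reads) LLR draws: state ~ Bernoulli(truth), LLR ~ Normal
    around +/-llr_mu depending on state."""
    states = rng.random((truth.size, reads)) < truth[:, None]
    noise = rng.normal(0.0, config.llr_sigma, size=(truth.size, reads))
    return np.where(states, config.llr_mu, -config.llr_mu) + noise


def simulate_read_calls(
    groups: pd.DataFrame,
    truth: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    read_prefix: str = "read",
) -> pd.DataFrame:
    """Per-read call rows for the given CpG groups at the given true
    frequencies, in the consumed call-table dialect (one row per read x
    group, strand '+')."""
    rng = config.rng() if rng is None else rng
    truth = np.asarray(truth, dtype=float)
    if truth.size != len(groups):
        raise ParameterError("truth must have one frequency per group")
    if ((truth < 0) | (truth > 1)).any():
        raise ParameterError("true frequencies must lie in [0, 1]")
    reads = config.reads_per_site
    llrs = _draw_llrs(truth, reads, config, rng)
    g = len(groups)
    frame = pd.DataFrame(
        {
            "chromosome": np.repeat(groups["chromosome"].to_numpy(), reads),
            "strand": "+",
            "start": np.repeat(groups["start"].to_numpy(), reads),
            "end": np.repeat(groups["end"].to_numpy(), reads),
            "read_name": [
                f"{read_prefix}_{i}_{r}" for i in range(g) for r in range(reads)
            ],
            "log_lik_ratio": llrs.ravel().round(4),
            "num_motifs": np.repeat(groups["num_motifs"].to_numpy(), reads),
            "sequence": np.repeat(groups["sequence"].to_numpy(), reads),
        }
    )
    return frame


def simulate_transcript_sites(
    records: Sequence[SequenceRecord],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    call_threshold: float = 2.0,
) -> pd.DataFrame:
    """Fast path: per-read draws aggregated directly to a site table.

    Statistically identical to emitting per-read rows and running the site
    aggregator; returns a site-table frame (groups with no called read are
    dropped, as the aggregator drops them).
    """
    from .sites import summarize_llr_matrix

    rng = config.rng() if rng is None else rng
    groups = transcript_groups(records, config.group_merge_distance)
    level = truth.set_index("seq_id")["methylation_level"]
    group_truth = level.loc[groups["chromosome"]].to_numpy()
    llrs = _draw_llrs(group_truth, config.reads_per_site, config, rng)
    called, meth = summarize_llr_matrix(llrs, call_threshold)
    keep = called > 0
    n_motifs = groups["num_motifs"].to_numpy()
    frame = pd.DataFrame(
        {
            "chromosome": groups["chromosome"].to_numpy()[keep],
            "start": groups["start"].to_numpy()[keep],
            "end": groups["end"].to_numpy()[keep],
            "num_motifs_in_group": n_motifs[keep],
            "called_sites": (called * n_motifs)[keep],
            "called_sites_methylated": (meth * n_motifs)[keep],
            "methylated_frequency": (meth[keep] / called[keep]),
            "group_sequence": groups["sequence"].to_numpy()[keep],
        },
        columns=SITE_TABLE_COLUMNS,
    )
    return frame.sort_values(["chromosome", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# experiments


def _random_single_cpg_contexts(
    n: int, rng: np.random.Generator, flank: int = 5
) -> np.ndarray:
    """Random contexts containing exactly one CG: the left flank draws from
    {A,C,T} and the right from {A,G,T}, so no second CG can form."""
    left = np.frombuffer(b"ACT", dtype="u1")[rng.integers(0, 3, size=(n, flank))]
    right = np.frombuffer(b"AGT", dtype="u1")[rng.integers(0, 3, size=(n, flank))]
    cg = np.tile(np.frombuffer(b"CG", dtype="u1"), (n, 1))
    full = np.concatenate([left, cg, right], axis=1)
    return np.array([row.tobytes().decode() for row in full])


def _experiment_truth(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, SampleSheet, pd.DataFrame, np.ndarray]:
    """Positions, sample sheet, truth table and per-sample true frequencies."""
    starts = 100 + config.position_spacing * np.arange(config.n_positions)
    positions = pd.DataFrame(
        {
            "contig": config.contig,
            "start": starts,
            "end": starts,
            "n_motifs": 1,
        }
    )
    contexts = _random_single_cpg_contexts(config.n_positions, rng)

    samples: list[tuple[str, str]] = []
    for grp, n, _ in config.group_design:
        samples.extend((f"{grp}_{i + 1}", grp) for i in range(n))
    sheet = SampleSheet(
        entries=tuple(SampleEntry(s, "", g) for s, g in samples)
    )

    group_truth = {
        grp: np.full(config.n_positions, base)
        for grp, _, base in config.group_design
    }
    jitter_sd = np.full(config.n_positions, config.jitter_sd)
    in_dmr = np.zeros(config.n_positions, dtype=bool)
    for entry in config.dmr_spec:
        mask = (
            (positions["contig"] == entry.contig)
            & (positions["start"] >= entry.start)
            & (positions["start"] <= entry.end)
        ).to_numpy()
        in_dmr |= mask
        for grp, freq in entry.group_freqs.items():
            group_truth[grp][mask] = freq
        if entry.jitter_sd is not None:
            jitter_sd[mask] = entry.jitter_sd

    # a per-sample genome-wide offset (individual biology / run effects)
    # plus independent per-position jitter; zero-jitter blocks stay fully
    # deterministic, so offsets are suppressed there too
    offsets = rng.normal(0.0, config.sample_offset_sd, size=len(samples))
    stochastic = jitter_sd > 0
    sample_truth = np.empty((config.n_positions, len(samples)))
    for j, (_, grp) in enumerate(samples):
        jitter = rng.normal(0.0, 1.0, size=config.n_positions) * jitter_sd
        sample_truth[:, j] = np.clip(
            group_truth[grp] + offsets[j] * stochastic + jitter, 0.0, 1.0
        )

    truth = positions.copy()
    truth["group_sequence"] = contexts
    for grp, vals in group_truth.items():
        truth[f"truth_{grp}"] = vals
    for j, (sample, _) in enumerate(samples):
        truth[f"truth_{sample}"] = sample_truth[:, j]
    truth["in_dmr"] = in_dmr
    return positions, sheet, truth, sample_truth


def simulate_frequency_matrix(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Frequency-level experiment: the matrix holds each sample's true
    per-position frequency (group baseline + jitter, truncated to [0, 1])
    with coverage ``reads_per_site`` everywhere. No read sampling."""
    rng = config.rng() if rng is None else rng
    positions, sheet, truth, sample_truth = _experiment_truth(config, rng)
    matrix = MethylationMatrix(
        positions=positions,
        samples=sheet.samples,
        groups=sheet.groups,
        frequencies=sample_truth,
        coverages=np.full(sample_truth.shape, config.reads_per_site, dtype=int),
    )
    return matrix, truth


def simulate_null_signal_matrix(
    seed: int,
    n_null: int = 5000,
    n_signal: int = 50,
    shift: float = 0.4,
    jitter_sd: float = 0.05,
    baseline: float = 0.3,
    n_per_group: int = 4,
    reads_per_site: int = 30,
) -> tuple[MethylationMatrix, np.ndarray]:
    """A 4-vs-4 null-plus-signal design for FDR calibration: ``n_null``
    positions share the baseline in both groups; the last ``n_signal``
    positions shift the second group by ``shift``. Returns the matrix and
    the boolean signal mask."""
    n = n_null + n_signal
    config = SimulationConfig(
        seed=seed,
        n_positions=n,
        jitter_sd=jitter_sd,
        sample_offset_sd=0.0,
        reads_per_site=reads_per_site,
        group_design=(
            ("aposymbiotic", n_per_group, baseline),
            ("symbiotic", n_per_group, baseline),
        ),
    )
    rng = config.rng()
    positions, sheet, _, sample_truth = _experiment_truth(config, rng)
    signal = np.zeros(n, dtype=bool)
    signal[n_null:] = True
    for j, sample in enumerate(sheet.samples):
        if sheet.groups[sample] == "symbiotic":
            sample_truth[signal, j] = np.clip(sample_truth[signal, j] + shift, 0, 1)
    matrix = MethylationMatrix(
        positions=positions,
        samples=sheet.samples,
        groups=sheet.groups,
        frequencies=sample_truth,
        coverages=np.full(sample_truth.shape, reads_per_site, dtype=int),
    )
    return matrix, signal


def simulate_experiment(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> ExperimentData:
    """Full two-group experiment with per-read call tables.

    Per position, the group truth is the group baseline (or a dmr_spec
    override) plus per-sample Gaussian jitter truncated to [0, 1]; call
    rows are drawn per sample from those frequencies. With ``out_dir``,
    writes per-sample call TSVs, the sample sheet and the truth table, and
    the sheet's paths point at the written files.
    """
    rng = config.rng()
    positions, sheet, truth, sample_truth = _experiment_truth(config, rng)
    groups_frame = pd.DataFrame(
        {
            "chromosome": positions["contig"],
            "start": positions["start"],
            "end": positions["end"],
            "num_motifs": positions["n_motifs"],
            "sequence": truth["group_sequence"],
        }
    )
    call_frames: dict[str, pd.DataFrame] = {}
    for j, sample in enumerate(sheet.samples):
        call_frames[sample] = simulate_read_calls(
            groups_frame, sample_truth[:, j], config, rng, read_prefix=sample
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for sample in sheet.samples:
            path = out / f"{sample}.calls.tsv"
            write_call_table(call_frames[sample], path)
            entries.append(SampleEntry(sample, str(path), sheet.groups[sample]))
        sheet = SampleSheet(entries=tuple(entries))
        write_sample_sheet(sheet, out / "sample_sheet.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    return ExperimentData(
        sheet=sheet, call_frames=call_frames, truth=truth, positions=positions
    )
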