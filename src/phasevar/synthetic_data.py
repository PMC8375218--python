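"""Synthetic genomes, populations and reads with machine-readable truth.

This module emulates the data underlying phase-variation analysis of a
*Bacteroides*-like host: a genome carrying several invertible promoter
loci (a 183-186 bp spacer flanked by a perfect 10 bp inverted repeat,
default arm sequence GTTCGTTTAA), a cell population in which each locus
is independently ON or OFF per cell, 2x150 nt paired-end reads with
~350 bp inserts, heavy-tailed long reads (median 1882 nt, IQR 4697 nt),
and host/phage read mixtures at a chosen virus-to-microbe ratio (VMR).

Every generator is seed-deterministic and returns a truth table alongside
the sequence data, so each downstream stage can be tested against known
ground truth without external alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .io_align import SequenceRecord

_BASES = np.array(list("ACGT"))

TRUTH_COLUMNS = [
    "label",
    "left_start",
    "left_end",
    "spacer_start",
    "spacer_end",
    "right_start",
    "right_end",
    "repeat_seq",
    "state",
]


@dataclass
class GenomeSpec:
    """Parameters of a synthetic host genome with invertible loci.

    Defaults mirror the biological system being emulated: a ~5.8 Mb
    genome with five capsular-polysaccharide loci, each controlled by an
    invertible promoter of 183-186 bp flanked by the perfect 10 bp
    inverted repeat GTTCGTTTAA, at ~43% GC.
    """

    genome_length: int = 5_800_000
    n_loci: int = 5
    repeat_seq: str = "GTTCGTTTAA"
    spacer_length_range: tuple[int, int] = (183, 186)
    gc: float = 0.43
    seed: int = 0
    margin: int = 1500
    min_separation: int = 2500

    def __post_init__(self) -> None:
        if len(self.repeat_seq) < 6:
            raise ValueError("repeat_seq must be >= 6 nt")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        lo, hi = self.spacer_length_range
        if lo > hi or lo < 0:
            raise ValueError("bad spacer_length_range")
        locus_span = 2 * len(self.repeat_seq) + hi
        needed = 2 * self.margin + self.n_loci * max(locus_span, self.min_separation)
        if self.n_loci and needed > self.genome_length:
            raise ValueError(
                f"{self.n_loci} loci with margins do not fit in {self.genome_length} nt"
            )


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return rng.choice(_BASES, size=n, p=p)


def make_genome(spec: GenomeSpec) -> tuple[SequenceRecord, pd.DataFrame]:
    """Random genome with planted invertible loci and a truth table.

    Each planted locus is ``repeat_seq + spacer + revcomp(repeat_seq)``
    with the spacer length drawn from ``spec.spacer_length_range``.  The
    truth table gives 0-based half-open coordinates of both arms and the
    spacer; the planted state is declared ON (the reference orientation).
    """
    rng = np.random.default_rng(spec.seed)
    seq = _random_sequence(rng, spec.genome_length, spec.gc)
    arm = spec.repeat_seq.upper()
    arm_rc = revcomp(arm)
    lo, hi = spec.spacer_length_range

    rows = []
    placed: list[tuple[int, int]] = []
    max_locus_span = 2 * len(arm) + hi
    for i in range(spec.n_loci):
        for _attempt in range(1000):
            start = int(rng.integers(spec.margin, spec.genome_length - spec.margin - max_locus_span))
            if all(abs(start - s) >= spec.min_separation for s, _ in placed):
                break
        else:
            raise RuntimeError("could not place loci without overlap; genome too small")
        spacer_len = int(rng.integers(lo, hi + 1))
        spacer = _random_sequence(rng, spacer_len, spec.gc)
        left_end = start + len(arm)
        spacer_end = left_end + spacer_len
        right_end = spacer_end + len(arm)
        seq[start:left_end] = list(arm)
        seq[left_end:spacer_end] = spacer
        seq[spacer_end:right_end] = list(arm_rc)
        placed.append((start, right_end))
        rows.append(
            {
                "label": f"locus{i + 1}",
                "left_start": start,
                "left_end": left_end,
                "spacer_start": left_end,
                "spacer_end": spacer_end,
                "right_start": spacer_end,
                "right_end": right_end,
                "repeat_seq": arm,
                "state": "ON",
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values("left_start").reset_index(drop=True) if len(truth) else truth
    genome = SequenceRecord(id=f"synthetic_genome_seed{spec.seed}", seq="".join(seq))
    return genome, truth


# ---------------------------------------------------------------------------
# cell populations


@dataclass
class PopulationState:
    """Per-cell, per-locus promoter orientations for a simulated population."""

    on_fractions: np.ndarray  # one target ON fraction per locus
    n_cells: int
    assignment: np.ndarray  # (n_cells, n_loci) bool, True = ON
    seed: int

    def realized_on_fraction(self, locus_index: int) -> float:
        return float(self.assignment[:, locus_index].mean())


def assign_orientations(
    truth: pd.DataFrame,
    on_fractions: Sequence[float],
    n_cells: int,
    seed: int = 0,
) -> PopulationState:
    """Independent Bernoulli ON/OFF assignment per cell per locus."""
    fr = np.asarray(on_fractions, dtype=float)
    if len(fr) != len(truth):
        raise ValueError("need exactly one on_fraction per locus")
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("on_fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    assignment = rng.random((n_cells, len(fr))) < fr[None, :]
    return PopulationState(fr, n_cells, assignment, seed)


def haplotype_sequence(genome: SequenceRecord, truth: pd.DataFrame, states: Sequence[bool]) -> str:
    """Genome sequence of one cell: OFF loci have [left_start, right_end)
    reverse-complemented (the arms are invariant under this inversion;
    only the spacer flips)."""
    seq = genome.seq
    parts: list[str] = []
    pos = 0
    for (_, row), on in zip(truth.iterrows(), states):
        if on:
            continue
        s, e = int(row.left_start), int(row.right_end)
        parts.append(seq[pos:s])
        parts.append(revcomp(seq[s:e]))
        pos = e
    parts.append(seq[pos:])
    return "".join(parts)


class _HaplotypeCache:
    """Builds per-cell haplotypes lazily, cached by orientation pattern."""

    def __init__(self, genome: SequenceRecord, truth: pd.DataFrame, population: PopulationState):
        self.genome = genome
        self.truth = truth
        self.population = population
        self._cache: dict[tuple[bool, ...], str] = {}

    def for_cell(self, cell: int) -> str:
        key = tuple(bool(x) for x in self.population.assignment[cell])
        if key not in self._cache:
            self._cache[key] = haplotype_sequence(self.genome, self.truth, key)
        return self._cache[key]


# ---------------------------------------------------------------------------
# read simulation


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) whose median and inter-quartile range match.

    For X ~ LogNormal(mu, sigma): median = e^mu and
    IQR = e^mu (x - 1/x) with x = e^(z75 sigma), which gives the closed
    form x = (r + sqrt(r^2 + 4)) / 2 for r = IQR / median.
    """
    z75 = 0.6744897501960817
    r = iqr / median
    x = (r + math.sqrt(r * r + 4.0)) / 2.0
    return math.log(median), math.log(x) / z75


@dataclass
class ReadSimParams:
    """Sequencing-simulation parameters.

    Short-read defaults follow 2x150 nt chemistry on ~350 bp fragments;
    long-read lengths follow a log-normal matched to median 1882 nt and
    IQR 4697 nt; substitution-only errors at 0.1% (short) / 5% (long).
    """

    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    substitution_error: float = 0.001
    long_substitution_error: float = 0.05
    long_length_median: float = 1882.0
    long_length_iqr: float = 4697.0
    n_reads: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.read_length <= 0:
            raise ValueError("counts must be non-negative and read_length positive")
        for e in (self.substitution_error, self.long_substitution_error):
            if not (0.0 <= e < 1.0):
                raise ValueError("error rates must be in [0, 1)")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    arr = np.array(list(seq))
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def simulate_paired_reads(
    genome: SequenceRecord,
    truth: pd.DataFrame,
    population: PopulationState,
    params: ReadSimParams,
    n_pairs: Optional[int] = None,
    region: Optional[tuple[int, int]] = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Paired-end reads from random cells of the population.

    Fragment lengths are Normal(insert_mean, insert_sd) truncated at
    read_length; starts are uniform (optionally restricted to ``region``,
    emulating a targeted look at one locus).  Returns (R1, R2, truth);
    the truth table records the source cell, fragment interval, any locus
    whose spacer the fragment overlaps, that cell's state there, and the
    per-mate spacer overlap in nt.
    """
    n_pairs = params.n_reads if n_pairs is None else n_pairs
    rng = np.random.default_rng(params.seed)
    L = params.read_length
    g_len = len(genome.seq)
    lo, hi = region if region is not None else (0, g_len)
    cache = _HaplotypeCache(genome, truth, population)
    spacers = [
        (row.label, int(row.spacer_start), int(row.spacer_end)) for row in truth.itertuples()
    ]
    states = population.assignment

    r1: list[SequenceRecord] = []
    r2: list[SequenceRecord] = []
    rows = []
    for i in range(n_pairs):
        cell = int(rng.integers(population.n_cells))
        insert = max(L, int(round(rng.normal(params.insert_mean, params.insert_sd))))
        insert = min(insert, hi - lo)
        start = int(rng.integers(lo, max(lo + 1, hi - insert + 1)))
        end = start + insert
        hap = cache.for_cell(cell)
        frag = hap[start:end]
        fwd = _mutate(rng, frag[:L], params.substitution_error)
        rev = _mutate(rng, revcomp(frag[-L:]), params.substitution_error)
        pid = f"pair{i}"
        r1.append(SequenceRecord(pid, fwd, "I" * len(fwd)))
        r2.append(SequenceRecord(pid, rev, "I" * len(rev)))
        locus, state, ov1, ov2 = "", "", 0, 0
        for j, (label, s, e) in enumerate(spacers):
            if _overlap(start, end, s, e) > 0:
                locus = label
                state = "ON" if states[cell, j] else "OFF"
                ov1 = _overlap(start, start + L, s, e)
                ov2 = _overlap(end - L, end, s, e)
                break
        rows.append(
            {
                "pair_id": pid,
                "cell": cell,
                "start": start,
                "end": end,
                "locus": locus,
                "state": state,
                "mate1_spacer_overlap": ov1,
                "mate2_spacer_overlap": ov2,
            }
        )
    return r1, r2, pd.DataFrame(rows)


def simulate_long_reads(
    genome: SequenceRecord,
    truth: pd.DataFrame,
    population: PopulationState,
    params: ReadSimParams,
    n_reads: Optional[int] = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Long reads with log-normal lengths drawn from per-cell haplotypes.

    A read that spans a locus whose cell state is OFF contains a segment
    that is inverted relative to the (ON) reference genome; downstream
    split-alignment analysis should recover it.  Truth records the source
    cell, reference interval, read strand, and the states of any loci
    whose spacers the read covers.
    """
    n_reads = params.n_reads if n_reads is None else n_reads
    rng = np.random.default_rng(params.seed)
    mu, sigma = lognormal_from_median_iqr(params.long_length_median, params.long_length_iqr)
    g_len = len(genome.seq)
    cache = _HaplotypeCache(genome, truth, population)
    spacers = [
        (row.label, int(row.spacer_start), int(row.spacer_end)) for row in truth.itertuples()
    ]
    states = population.assignment

    reads: list[SequenceRecord] = []
    rows = []
    for i in range(n_reads):
        length = int(round(rng.lognormal(mu, sigma)))
        length = max(20, min(length, g_len))
        start = int(rng.integers(0, g_len - length + 1))
        end = start + length
        cell = int(rng.integers(population.n_cells))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = cache.for_cell(cell)[start:end]
        if strand == "-":
            seq = revcomp(seq)
        seq = _mutate(rng, seq, params.long_substitution_error)
        rid = f"longread{i}"
        reads.append(SequenceRecord(rid, seq, "I" * len(seq)))
        spanned = [
            (label, "ON" if states[cell, j] else "OFF")
            for j, (label, s, e) in enumerate(spacers)
            if start <= s and e <= end
        ]
        rows.append(
            {
                "read_id": rid,
                "cell": cell,
                "start": start,
                "end": end,
                "strand": strand,
                "length": length,
                "loci": ",".join(l for l, _ in spanned),
                "states": ",".join(s for _, s in spanned),
            }
        )
    return reads, pd.DataFrame(rows)


def simulate_metagenome(
    host_genome: SequenceRecord,
    phage_genome: SequenceRecord,
    vmr: float,
    n_reads: int,
    params: ReadSimParams,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Host/phage read mixture at a target virus-to-microbe ratio.

    The per-read source probability is chosen so that the *expected
    per-base coverage ratio* phage:host equals ``vmr`` (reads are
    equal-length, so P(phage)/P(host) = vmr * phage_len / host_len).
    """
    if vmr < 0:
        raise ValueError("vmr must be >= 0")
    rng = np.random.default_rng(params.seed)
    L = params.read_length
    hl, pl = len(host_genome.seq), len(phage_genome.seq)
    w_phage = vmr * pl
    p_phage = w_phage / (w_phage + hl) if (w_phage + hl) > 0 else 0.0

    reads: list[SequenceRecord] = []
    rows = []
    for i in range(n_reads):
        from_phage = rng.random() < p_phage
        src = phage_genome if from_phage else host_genome
        g_len = len(src.seq)
        rl = min(L, g_len)
        start = int(rng.integers(0, g_len - rl + 1))
        seq = _mutate(rng, src.seq[start : start + rl], params.substitution_error)
        rid = f"metaread{i}"
        reads.append(SequenceRecord(rid, seq, "I" * len(seq)))
        rows.append(
            {"read_id": rid, "source": "phage" if from_phage else "host", "start": start}
        )
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth-table output


def save_table(df: pd.DataFrame, path) -> None:
    """TSV with a single commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def load_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        return pd.read_csv(fh, sep="\t", names=header)


def write_locus_bed(truth: pd.DataFrame, path) -> None:
    """BED of planted loci: one line per left arm, spacer, and right arm."""
    with open(path, "w") as fh:
        for row in truth.itertuples():
            for part, s, e in (
                ("left_arm", row.left_start, row.left_end),
                ("spacer", row.spacer_start, row.spacer_end),
                ("right_arm", row.right_start, row.right_end),
            ):
                fh.write(f"genome\t{s}\t{e}\t{row.label}:{part}\n")
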