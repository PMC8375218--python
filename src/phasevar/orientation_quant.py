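"""Per-locus ON/OFF quantification from concordant read pairs.

For each invertible locus two haplotypes are built (the locus plus a
flank in each orientation); read pairs are aligned competitively to
both and a pair votes for the haplotype it aligns to concordantly with
enough bases inside the spacer — the only interval where the two
orientations differ, since the arms are reverse complements of each
other and hence invariant under inversion.  Counts per locus yield the
population ON fraction with a Wilson 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._seq import revcomp
from .io_align import (
    DEFAULT_MAX_INSERT,
    DEFAULT_MIN_INSERT,
    AlignmentBlock,
    ReferenceIndex,
    SequenceRecord,
    is_concordant,
)
from .repeat_finder import InvertibleLocus


class Orientation(str, Enum):
    ON = "ON"
    OFF = "OFF"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class DualReference:
    """The two orientations of one locus (plus flank) as sequences.

    ``spacer_local`` is the spacer interval in haplotype-local
    coordinates; it is identical for both haplotypes because inversion
    of the arm-to-arm segment preserves arm sequence and spacer span.
    """

    label: str
    on_haplotype: SequenceRecord
    off_haplotype: SequenceRecord
    flank: int
    spacer_local: tuple[int, int]
    span_local: tuple[int, int]  # arm-to-arm inverted segment, local coords
    offset: int  # genome coordinate of haplotype position 0


def build_dual_references(
    genome: Union[SequenceRecord, str],
    loci: Sequence[InvertibleLocus],
    flank: int = 1000,
) -> list[DualReference]:
    """ON and OFF haplotypes for each locus: the OFF haplotype has the
    [left arm start, right arm end) segment reverse-complemented."""
    seq = genome.seq if isinstance(genome, SequenceRecord) else genome
    out = []
    for locus in loci:
        s, e = locus.span
        w_lo = max(0, s - flank)
        w_hi = min(len(seq), e + flank)
        on = seq[w_lo:w_hi]
        off = on[: s - w_lo] + revcomp(on[s - w_lo : e - w_lo]) + on[e - w_lo :]
        label = locus.label or f"{locus.ref_name}:{s}-{e}"
        out.append(
            DualReference(
                label=label,
                on_haplotype=SequenceRecord(f"{label}|ON", on),
                off_haplotype=SequenceRecord(f"{label}|OFF", off),
                flank=flank,
                spacer_local=(locus.spacer[0] - w_lo, locus.spacer[1] - w_lo),
                span_local=(s - w_lo, e - w_lo),
                offset=w_lo,
            )
        )
    return out


def invert_segment(seq: str, start: int, end: int) -> str:
    """Reverse-complement [start, end) in place; applying it twice is the
    identity, which is the involution property of promoter inversion."""
    return seq[:start] + revcomp(seq[start:end]) + seq[end:]


@dataclass
class PairClassification:
    orientation: Orientation
    informative_overlap: int = 0


def _pair_features(
    b1: Optional[AlignmentBlock],
    b2: Optional[AlignmentBlock],
    spacer: tuple[int, int],
    min_insert: int,
    max_insert: int,
) -> tuple[bool, int, float]:
    """(concordant, spacer overlap in nt, summed match score) for one pair
    against one haplotype."""
    conc, _ = is_concordant(b1, b2, min_insert, max_insert)
    overlap = 0
    score = 0.0
    for b in (b1, b2):
        if b is None:
            continue
        overlap += max(0, min(b.ref_end, spacer[1]) - max(b.ref_start, spacer[0]))
        score += b.identity * (b.ref_end - b.ref_start)
    return conc, overlap, score


def classify_pair(
    on_blocks: tuple[Optional[AlignmentBlock], Optional[AlignmentBlock]],
    off_blocks: tuple[Optional[AlignmentBlock], Optional[AlignmentBlock]],
    spacer_local: tuple[int, int],
    min_informative_overlap: int = 10,
    min_insert: int = DEFAULT_MIN_INSERT,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> PairClassification:
    """Competitive classification of one read pair.

    ON requires a concordant alignment to the ON haplotype with at least
    ``min_informative_overlap`` bases inside the spacer, and either no
    concordant OFF alignment or a lower summed match score there;
    symmetric for OFF; everything else is AMBIGUOUS.
    """
    on_conc, on_ov, on_score = _pair_features(*on_blocks, spacer_local, min_insert, max_insert)
    off_conc, off_ov, off_score = _pair_features(*off_blocks, spacer_local, min_insert, max_insert)
    on_ok = on_conc and on_ov >= min_informative_overlap
    off_ok = off_conc and off_ov >= min_informative_overlap
    if on_ok and (not off_conc or on_score > off_score):
        return PairClassification(Orientation.ON, on_ov)
    if off_ok and (not on_conc or off_score > on_score):
        return PairClassification(Orientation.OFF, off_ov)
    return PairClassification(Orientation.AMBIGUOUS, max(on_ov, off_ov))


@dataclass
class OrientationCount:
    """Per-locus tally of read pairs supporting each orientation."""

    locus: str
    n_on: int
    n_off: int
    n_ambiguous: int
    fraction_on: float  # NaN when no informative pairs
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return (self.n_on + self.n_off) > 0


def wilson_interval(n_on: int, n_total: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = proportion_confint(n_on, n_total, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def count_to_orientation(locus: str, n_on: int, n_off: int, n_ambiguous: int = 0) -> OrientationCount:
    total = n_on + n_off
    if total == 0:
        return OrientationCount(locus, 0, 0, n_ambiguous, float("nan"), float("nan"), float("nan"))
    frac = n_on / total
    lo, hi = wilson_interval(n_on, total)
    return OrientationCount(locus, n_on, n_off, n_ambiguous, frac, lo, hi)


@dataclass
class QuantParams:
    k: int = 21
    max_mismatch_frac: float = 0.1
    min_informative_overlap: int = 10
    min_insert: int = DEFAULT_MIN_INSERT
    max_insert: int = DEFAULT_MAX_INSERT
    flank: int = 1000


def quantify_orientations(
    reads1: Sequence[SequenceRecord],
    reads2: Sequence[SequenceRecord],
    genome: Union[SequenceRecord, str],
    loci: Sequence[InvertibleLocus],
    params: Optional[QuantParams] = None,
) -> list[OrientationCount]:
    """ON fraction per locus from paired reads via competitive mapping.

    Each pair is mapped against both haplotypes of every locus with the
    internal mapper and classified; a pair informative for more than one
    locus (possible only for adjacent loci) is assigned to the locus with
    the larger spacer overlap, ties discarded as ambiguous.
    """
    params = params or QuantParams()
    duals = build_dual_references(genome, loci, flank=params.flank)
    indexes = [
        (d, ReferenceIndex(d.on_haplotype, k=params.k), ReferenceIndex(d.off_haplotype, k=params.k))
        for d in duals
    ]
    counts = {d.label: [0, 0, 0] for d in duals}  # on, off, ambiguous
    for r1, r2 in zip(reads1, reads2):
        votes: list[tuple[str, Orientation, int]] = []
        for d, ix_on, ix_off in indexes:
            on_b = (ix_on.map_read(r1, params.max_mismatch_frac), ix_on.map_read(r2, params.max_mismatch_frac))
            off_b = (ix_off.map_read(r1, params.max_mismatch_frac), ix_off.map_read(r2, params.max_mismatch_frac))
            if all(b is None for b in (*on_b, *off_b)):
                continue
            cls = classify_pair(
                on_b,
                off_b,
                d.spacer_local,
                params.min_informative_overlap,
                params.min_insert,
                params.max_insert,
            )
            if cls.orientation is not Orientation.AMBIGUOUS:
                votes.append((d.label, cls.orientation, cls.informative_overlap))
            else:
                counts[d.label][2] += 1
        if not votes:
            continue
        votes.sort(key=lambda v: -v[2])
        if len(votes) > 1 and votes[0][2] == votes[1][2] and votes[0][0] != votes[1][0]:
            counts[votes[0][0]][2] += 1  # tie between loci -> ambiguous
            continue
        label, orient, _ = votes[0]
        counts[label][0 if orient is Orientation.ON else 1] += 1
    return [
        count_to_orientation(label, c[0], c[1], c[2]) for label, c in counts.items()
    ]


def quantify_from_classified(
    labels: Iterable[str],
    orientations: Iterable[Orientation],
) -> list[OrientationCount]:
    """Aggregate pre-classified pair votes (e.g. from truth tables or an
    external aligner's SAM) into per-locus OrientationCounts."""
    tally: dict[str, list[int]] = {}
    for label, orient in zip(labels, orientations):
        c = tally.setdefault(label, [0, 0, 0])
        if orient is Orientation.ON or orient == "ON":
            c[0] += 1
        elif orient is Orientation.OFF or orient == "OFF":
            c[1] += 1
        else:
            c[2] += 1
    return [count_to_orientation(k, v[0], v[1], v[2]) for k, v in tally.items()]


def orientation_table(counts: Sequence[OrientationCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": c.locus,
                "n_on": c.n_on,
                "n_off": c.n_off,
                "n_ambiguous": c.n_ambiguous,
                "fraction_on": c.fraction_on,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
            }
            for c in counts
        ]
    )
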