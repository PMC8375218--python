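"""Within-read rearrangement detection from long-read split alignments.

A long read crossing a genomic segment that has inverted (or moved)
relative to the reference aligns as several blocks whose reference
layout disagrees with their read layout.  Reads are filtered (>1000 nt),
their alignment blocks are filtered (>200 nt, >90% identity, and an
e-value cut-off when the aligner reports one), blocks are chained along
the read axis, and adjacent-block discrepancies are emitted as events:
opposite strands -> an inversion; a same-strand reference shift of more
than 200 nt relative to the read spacing -> a displacement.  Event
positions binned into 1000-nt windows give a genome-wide recombination
histogram in which hotspot bins are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_align import AlignmentBlock

DEFAULT_MIN_READ_LEN = 1000
DEFAULT_MIN_BLOCK_LEN = 200
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MAX_EVALUE = 1e-20
DEFAULT_MIN_SHIFT = 200
DEFAULT_BIN_WIDTH = 1000


@dataclass
class ReadChain:
    """Filtered alignment blocks of one read, ordered along the read."""

    read_id: str
    read_length: int
    blocks: list[AlignmentBlock]


@dataclass
class InversionEvent:
    """One within-read rearrangement signal.

    ``kind`` is 'inverted' (adjacent blocks on opposite strands) or
    'displaced' (same-strand blocks whose reference gap disagrees with
    their read gap by more than the shift threshold).  ``ref_pos`` is the
    reference coordinate of the offending block boundary at the junction.
    """

    read_id: str
    kind: str
    ref_name: str
    ref_pos: int
    strands: tuple[str, str]
    shift: Optional[int] = None


@dataclass
class HotspotBin:
    bin_index: int
    start: int
    end: int
    event_count: int
    is_hotspot: bool


def chain_read_blocks(
    blocks: Iterable[AlignmentBlock],
    read_lengths: Optional[dict[str, int]] = None,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
    min_block_len: int = DEFAULT_MIN_BLOCK_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: Optional[float] = DEFAULT_MAX_EVALUE,
) -> list[ReadChain]:
    """Group alignment blocks per read and apply the retention filters.

    Reads of ``min_read_len`` or shorter are dropped; blocks are kept
    only if strictly longer than ``min_block_len`` with identity strictly
    above ``min_identity``, and (when the block carries an e-value)
    e-value <= ``max_evalue``.  Surviving blocks are ordered by read
    coordinate.
    """
    read_lengths = read_lengths or {}
    per_read: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        per_read.setdefault(b.read_id, []).append(b)
    chains = []
    for read_id, blks in per_read.items():
        length = read_lengths.get(read_id)
        if length is None:
            lens = [b.read_length for b in blks if b.read_length is not None]
            length = lens[0] if lens else max(b.read_end for b in blks)
        if length <= min_read_len:
            continue
        kept = [
            b
            for b in blks
            if min(b.read_span, b.ref_span) > min_block_len
            and b.identity > min_identity
            and (max_evalue is None or b.evalue is None or b.evalue <= max_evalue)
        ]
        if not kept:
            continue
        kept.sort(key=lambda b: b.read_start)
        chains.append(ReadChain(read_id, length, kept))
    chains.sort(key=lambda c: c.read_id)
    return chains


def _junction_ref_pos(block: AlignmentBlock, junction_at_read_start: bool) -> int:
    """Reference coordinate of the block end adjacent to a junction.

    For a '+' block the read-start side maps to ref_start; for a '-'
    block it maps to ref_end (alignment runs backwards on the
    reference), so a fully spanned inversion contributes one event at
    each arm of the inverted segment.
    """
    if block.strand == "+":
        return block.ref_start if junction_at_read_start else block.ref_end
    return block.ref_end if junction_at_read_start else block.ref_start


def detect_rearrangements(
    chain: ReadChain,
    min_shift: int = DEFAULT_MIN_SHIFT,
) -> list[InversionEvent]:
    """Adjacent-block discrepancies of one chain as events.

    Opposite-strand adjacent blocks emit an 'inverted' event anchored at
    the offending (minority-strand) block's boundary at that junction.
    Same-strand adjacent blocks whose reference gap differs from their
    read gap by more than ``min_shift`` emit a 'displaced' event at the
    second block's start with the observed shift.  Single-block chains
    emit nothing.
    """
    events: list[InversionEvent] = []
    blocks = chain.blocks
    if len(blocks) < 2:
        return events
    n_plus = sum(1 for b in blocks if b.strand == "+")
    minority = "-" if n_plus >= len(blocks) - n_plus else "+"
    for a, b in zip(blocks, blocks[1:]):
        if a.ref_name != b.ref_name:
            continue
        if a.strand != b.strand:
            if b.strand == minority:
                off, at_start = b, True
            else:
                off, at_start = a, False
            events.append(
                InversionEvent(
                    read_id=chain.read_id,
                    kind="inverted",
                    ref_name=off.ref_name,
                    ref_pos=_junction_ref_pos(off, at_start),
                    strands=(a.strand, b.strand),
                )
            )
        else:
            read_gap = b.read_start - a.read_end
            if a.strand == "+":
                ref_gap = b.ref_start - a.ref_end
            else:
                ref_gap = a.ref_start - b.ref_end
            shift = abs(ref_gap - read_gap)
            if shift > min_shift:
                events.append(
                    InversionEvent(
                        read_id=chain.read_id,
                        kind="displaced",
                        ref_name=b.ref_name,
                        ref_pos=b.ref_start,
                        strands=(a.strand, b.strand),
                        shift=shift,
                    )
                )
    return events


def detect_all_rearrangements(
    chains: Iterable[ReadChain], min_shift: int = DEFAULT_MIN_SHIFT
) -> list[InversionEvent]:
    out: list[InversionEvent] = []
    for c in chains:
        out.extend(detect_rearrangements(c, min_shift=min_shift))
    return out


def hotspot_histogram(
    events: Sequence[InversionEvent],
    genome_length: int,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_count: Optional[int] = None,
) -> list[HotspotBin]:
    """Bin event positions genome-wide and flag hotspot bins.

    ``min_count`` defaults to max(5, 99.9th percentile of a Poisson with
    the mean events-per-bin rate) — a configurable excess-over-uniform
    rule; the raw histogram is always returned so users can re-threshold.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n_bins = max(1, -(-genome_length // bin_width))
    counts = np.zeros(n_bins, dtype=int)
    for ev in events:
        idx = min(ev.ref_pos // bin_width, n_bins - 1)
        counts[idx] += 1
    if min_count is None:
        mean = len(events) / n_bins
        min_count = max(5, int(stats.poisson.ppf(0.999, mean)) if mean > 0 else 5)
    return [
        HotspotBin(
            bin_index=i,
            start=i * bin_width,
            end=(i + 1) * bin_width,
            event_count=int(c),
            is_hotspot=bool(c >= min_count),
        )
        for i, c in enumerate(counts)
    ]


def events_table(events: Sequence[InversionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": e.read_id,
                "kind": e.kind,
                "ref_name": e.ref_name,
                "ref_pos": e.ref_pos,
                "strands": "".join(e.strands),
                "shift": e.shift if e.shift is not None else "",
            }
            for e in events
        ],
        columns=["read_id", "kind", "ref_name", "ref_pos", "strands", "shift"],
    )


def bins_table(bins: Sequence[HotspotBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bin_index": b.bin_index,
                "start": b.start,
                "end": b.end,
                "event_count": b.event_count,
                "is_hotspot": b.is_hotspot,
            }
            for b in bins
        ]
    )


def hotspots_to_bed(bins: Sequence[HotspotBin], ref_name: str, path) -> None:
    with open(path, "w") as fh:
        for b in bins:
            if b.is_hotspot:
                fh.write(f"{ref_name}\t{b.start}\t{b.end}\thotspot\t{b.event_count}\n")
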