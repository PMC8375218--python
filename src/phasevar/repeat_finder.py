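"""Discovery of invertible-promoter candidate loci.

An invertible promoter locus is a spacer (the promoter proper) flanked by
a perfect inverted repeat: the left arm reads the same as the reverse
complement of the right arm.  Site-specific recombinases act at such
repeats, flipping the spacer between ON and OFF orientations.  This
module finds candidate loci either seeded by a known arm sequence
(e.g. GTTCGTTTAA) or de novo as maximal perfect inverted-repeat pairs,
matches degenerate IUPAC motifs (e.g. ARACGTTCGTN), and assigns an
ON-orientation convention relative to a downstream operon.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from ._seq import IUPAC_CODES, revcomp, revcomp_iupac
from .io_align import SequenceRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class InvertibleLocus:
    """An invertible promoter: two inverted-repeat arms and the spacer
    between them, with an ON-orientation convention.

    ``reference_is_on`` records whether the reference (as-deposited)
    orientation is the ON state under the current convention.
    """

    ref_name: str
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    spacer: tuple[int, int]
    repeat_seq: str
    on_definition: str = "as_reference"  # or "toward_operon"
    label: str = ""
    reference_is_on: bool = True
    resolved: bool = False  # True when an annotation resolved the convention

    def __post_init__(self) -> None:
        if not (self.left_arm[1] <= self.spacer[0] and self.spacer[1] <= self.right_arm[0]):
            raise ValueError("arm/spacer intervals out of order")
        if (self.left_arm[1] - self.left_arm[0]) != (self.right_arm[1] - self.right_arm[0]):
            raise ValueError("arm lengths differ")

    @property
    def arm_length(self) -> int:
        return self.left_arm[1] - self.left_arm[0]

    @property
    def spacer_length(self) -> int:
        return self.spacer[1] - self.spacer[0]

    @property
    def span(self) -> tuple[int, int]:
        return self.left_arm[0], self.right_arm[1]

    def check_against(self, seq: str) -> bool:
        """Literal complementarity check of the arms against the genome."""
        left = seq[self.left_arm[0] : self.left_arm[1]]
        right = seq[self.right_arm[0] : self.right_arm[1]]
        return left == revcomp(right)


@dataclass
class MotifHit:
    ref_name: str
    start: int
    end: int
    strand: str
    matched_seq: str


def _as_seq(genome: Union[SequenceRecord, str]) -> tuple[str, str]:
    if isinstance(genome, SequenceRecord):
        return genome.id, genome.seq.upper()
    return "seq", genome.upper()


# ---------------------------------------------------------------------------
# inverted-repeat search


def _antidiagonal_run(seq: str, p: int, q: int) -> tuple[int, int]:
    """Maximal contiguous run of complementary position pairs through
    (p, q) on the anti-diagonal p + q = const; returns (a, b) with the
    run covering left positions a..b pairing with right positions
    (d - b)..(d - a)."""
    d = p + q
    a = p
    while a - 1 >= 0 and d - (a - 1) < len(seq) and _COMP.get(seq[a - 1]) == seq[d - a + 1]:
        a -= 1
    b = p
    while b + 1 < len(seq) and d - (b + 1) >= 0 and _COMP.get(seq[b + 1]) == seq[d - b - 1]:
        b += 1
    return a, b


def _dedup_longest_arm(loci: list[InvertibleLocus]) -> list[InvertibleLocus]:
    """Among overlapping candidates keep the one with the longest arm
    (ties broken by leftmost position)."""
    loci = sorted(loci, key=lambda l: (-l.arm_length, l.left_arm[0], l.right_arm[0]))
    kept: list[InvertibleLocus] = []
    for cand in loci:
        s, e = cand.span
        if all(min(e, k.span[1]) - max(s, k.span[0]) <= 0 for k in kept):
            kept.append(cand)
    kept.sort(key=lambda l: l.left_arm[0])
    return kept


def find_inverted_repeat_loci(
    genome: Union[SequenceRecord, str],
    min_arm_len: int = 10,
    spacer_range: tuple[int, int] = (150, 250),
    seed_motif: Optional[str] = None,
) -> list[InvertibleLocus]:
    """Find candidate invertible loci as perfect inverted-repeat pairs.

    Seeded mode (``seed_motif`` given): every pairing of a motif
    occurrence with a downstream occurrence of its reverse complement at
    a spacer distance within ``spacer_range`` is reported, with arms equal
    to the motif occurrence itself.

    De novo mode: all maximal perfect inverted-repeat pairs with arm
    length >= ``min_arm_len`` and spacer length within ``spacer_range``;
    maximal means the complementary run cannot be extended in either
    direction.  Overlapping candidates are deduplicated keeping the
    longest arm.
    """
    if min_arm_len < 6:
        raise ValueError("min_arm_len must be >= 6")
    smin, smax = spacer_range
    if smin > smax or smin < 0:
        raise ValueError("bad spacer_range")
    ref_name, seq = _as_seq(genome)
    n = len(seq)
    if n < 2 * min_arm_len + smin:
        warnings.warn("genome shorter than the smallest possible locus", stacklevel=2)
        return []

    loci: list[InvertibleLocus] = []
    if seed_motif is not None:
        motif = seed_motif.upper()
        m = len(motif)
        rc = revcomp(motif)
        fwd = [i for i in range(n - m + 1) if seq[i : i + m] == motif]
        rev = [j for j in range(n - m + 1) if seq[j : j + m] == rc]
        for i in fwd:
            for j in rev:
                spacer = j - (i + m)
                if smin <= spacer <= smax:
                    loci.append(
                        InvertibleLocus(
                            ref_name=ref_name,
                            left_arm=(i, i + m),
                            right_arm=(j, j + m),
                            spacer=(i + m, j),
                            repeat_seq=motif,
                        )
                    )
        loci.sort(key=lambda l: l.left_arm[0])
    else:
        k = min_arm_len
        index: dict[str, list[int]] = {}
        for i in range(n - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        seen: set[tuple[int, int]] = set()
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            for j in index.get(revcomp(kmer), ()):
                if j <= i:
                    continue
                # left-arm prefix at i pairs with run cell (i, j + k - 1)
                a, b = _antidiagonal_run(seq, i, j + k - 1)
                d = i + j + k - 1
                key = (d, a)
                if key in seen:
                    continue
                seen.add(key)
                arm_len = b - a + 1
                right_start = d - b
                spacer = right_start - (b + 1)
                if arm_len >= min_arm_len and smin <= spacer <= smax:
                    loci.append(
                        InvertibleLocus(
                            ref_name=ref_name,
                            left_arm=(a, b + 1),
                            right_arm=(right_start, d - a + 1),
                            spacer=(b + 1, right_start),
                            repeat_seq=seq[a : b + 1],
                        )
                    )
        loci = _dedup_longest_arm(loci)

    for idx, locus in enumerate(loci):
        locus.label = locus.label or f"IR{idx + 1}"
    return loci


def group_repeat_families(loci: Sequence[InvertibleLocus]) -> pd.DataFrame:
    """Group loci by exact arm sequence; one row per family with member
    count and labels (supports 'which loci share an identical repeat')."""
    fam: dict[str, list[str]] = {}
    for l in loci:
        fam.setdefault(l.repeat_seq, []).append(l.label)
    rows = [
        {"repeat_seq": k, "n_members": len(v), "members": ",".join(v)}
        for k, v in sorted(fam.items(), key=lambda kv: -len(kv[1]))
    ]
    return pd.DataFrame(rows, columns=["repeat_seq", "n_members", "members"])


# ---------------------------------------------------------------------------
# IUPAC motif matching


def iupac_to_regex(motif: str) -> str:
    parts = []
    for c in motif.upper():
        if c not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {c!r} in motif {motif!r}")
        opts = IUPAC_CODES[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def match_iupac_motif(genome: Union[SequenceRecord, str], motif: str) -> list[MotifHit]:
    """All matches of a degenerate IUPAC motif on both strands.

    Minus-strand hits are reported on forward-strand coordinates with
    ``matched_seq`` being the motif-orientation (reverse-complemented)
    sequence.  Overlapping hits are all reported.
    """
    ref_name, seq = _as_seq(genome)
    m = len(motif)
    hits: list[MotifHit] = []
    fwd_re = re.compile(f"(?=({iupac_to_regex(motif)}))")
    for match in fwd_re.finditer(seq):
        s = match.start()
        hits.append(MotifHit(ref_name, s, s + m, "+", match.group(1)))
    rc_motif = revcomp_iupac(motif)
    rc_re = re.compile(f"(?=({iupac_to_regex(rc_motif)}))")
    for match in rc_re.finditer(seq):
        s = match.start()
        hits.append(MotifHit(ref_name, s, s + m, "-", revcomp(match.group(1))))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# ON-orientation convention

PROMOTER_MOTIF_DEFAULT = "ARACGTTCGTN"


def set_orientation_convention(
    loci: Sequence[InvertibleLocus],
    operons: Optional[Sequence[tuple[int, int, str]]] = None,
    genome: Optional[Union[SequenceRecord, str]] = None,
    promoter_motif: str = PROMOTER_MOTIF_DEFAULT,
    window: int = 5000,
) -> list[InvertibleLocus]:
    """Label which orientation of each locus is ON.

    Without an operon annotation the reference orientation is labelled ON
    (``on_definition='as_reference'``) and the locus flagged unresolved.
    With operons (``(start, end, strand)`` intervals), ON is the
    orientation in which the promoter points toward the nearest
    downstream operon within ``window`` nt.  The promoter's direction in
    the reference is inferred from a strand-specific promoter motif hit
    inside the locus; loci with no such hit stay as_reference, flagged.
    Loci are modified in place and returned.
    """
    out = list(loci)
    if operons is None:
        for l in out:
            l.on_definition = "as_reference"
            l.reference_is_on = True
            l.resolved = False
        return out
    if genome is None:
        raise ValueError("an operon annotation requires the genome sequence")
    _, seq = _as_seq(genome)
    for l in out:
        s, e = l.span
        local = seq[s:e]
        hits = match_iupac_motif(local, promoter_motif)
        strands = {h.strand for h in hits}
        if len(strands) != 1:
            l.on_definition = "as_reference"
            l.reference_is_on = True
            l.resolved = False
            continue
        direction = strands.pop()  # '+': promoter points right, '-': left
        if direction == "+":
            cands = [
                (op[0] - e)
                for op in operons
                if op[2] == "+" and 0 <= op[0] - e <= window
            ]
        else:
            cands = [
                (s - op[1])
                for op in operons
                if op[2] == "-" and 0 <= s - op[1] <= window
            ]
        if cands:
            l.on_definition = "toward_operon"
            l.reference_is_on = True
            l.resolved = True
            continue
        # is there an operon the promoter would face after inversion?
        if direction == "+":
            flipped = [
                (s - op[1]) for op in operons if op[2] == "-" and 0 <= s - op[1] <= window
            ]
        else:
            flipped = [
                (op[0] - e) for op in operons if op[2] == "+" and 0 <= op[0] - e <= window
            ]
        if flipped:
            l.on_definition = "toward_operon"
            l.reference_is_on = False
            l.resolved = True
        else:
            l.on_definition = "as_reference"
            l.reference_is_on = True
            l.resolved = False
    return out


def loci_to_bed(loci: Sequence[InvertibleLocus], path) -> None:
    """BED output: one line per arm and spacer of each locus."""
    with open(path, "w") as fh:
        for l in loci:
            for part, (s, e) in (
                ("left_arm", l.left_arm),
                ("spacer", l.spacer),
                ("right_arm", l.right_arm),
            ):
                fh.write(f"{l.ref_name}\t{s}\t{e}\t{l.label}:{part}\n")
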