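"""Sequence and alignment I/O, plus a minimal internal read mapper.

All coordinates are 0-based, half-open, on the forward strand of the
reference.  SAM and BLAST tabular conventions (1-based, strand encoded as
reversed coordinates) are converted at the parsing boundary.

The mapper here (:func:`minimal_map`, :func:`split_map`) is a deliberately
small exact-seed / ungapped-extension aligner intended for synthetic,
low-error reads against kilobase-to-megabase references; it exists so the
rest of the toolkit can be exercised end-to-end without an external
aligner.  It is not a general-purpose read mapper.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from ._seq import revcomp

# ---------------------------------------------------------------------------
# domain types


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentBlock:
    """One local ungapped/colinear alignment between a read segment and the
    reference.

    ``read_start``/``read_end`` are offsets on the read's stored orientation;
    ``ref_start``/``ref_end`` are always on the + strand of the reference
    (``ref_start < ref_end`` regardless of ``strand``).
    """

    read_id: str
    read_start: int
    read_end: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    evalue: Optional[float] = None
    read_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.read_start < self.read_end):
            raise ValueError("read_start must be < read_end")
        if not (self.ref_start < self.ref_end):
            raise ValueError("ref_start must be < ref_end")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


@dataclass
class ReadPairAlignment:
    """Joined alignments of the two mates of a read pair.

    ``mate1``/``mate2`` are ``None`` when the mate is unmapped or absent.
    """

    pair_id: str
    mate1: Optional[AlignmentBlock]
    mate2: Optional[AlignmentBlock]
    concordant: bool
    insert_size: Optional[int] = None


DEFAULT_MIN_INSERT = 100
DEFAULT_MAX_INSERT = 1000


def is_concordant(
    b1: Optional[AlignmentBlock],
    b2: Optional[AlignmentBlock],
    min_insert: int = DEFAULT_MIN_INSERT,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> tuple[bool, Optional[int]]:
    """Apply the concordance contract to two mate alignments.

    Concordant means: both mates mapped to the same reference on opposite
    strands, in FR orientation (the forward-strand mate starts before the
    reverse-strand mate ends), with the outer insert within
    ``[min_insert, max_insert]``.  Returns ``(concordant, insert_size)``;
    the insert is reported whenever both mates share a reference.
    """
    if b1 is None or b2 is None:
        return False, None
    if b1.ref_name != b2.ref_name:
        return False, None
    insert = max(b1.ref_end, b2.ref_end) - min(b1.ref_start, b2.ref_start)
    if b1.strand == b2.strand:
        return False, insert
    fwd, rev = (b1, b2) if b1.strand == "+" else (b2, b1)
    if fwd.ref_start > rev.ref_start:
        return False, insert
    return (min_insert <= insert <= max_insert), insert


# ---------------------------------------------------------------------------
# sequence file I/O


def _open_maybe_gzip(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _guess_format(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if ext in {".fa", ".fasta", ".fna"}:
        return "FASTA"
    if ext in {".fq", ".fastq"}:
        return "FASTQ"
    raise ValueError(f"cannot guess sequence format from {path!r}")


def read_sequences(path, format: Optional[str] = None) -> list[SequenceRecord]:
    """Read FASTA or FASTQ (optionally gzipped) into SequenceRecords.

    ``format`` is ``"FASTA"`` or ``"FASTQ"``; when omitted it is guessed
    from the file extension.  Records are returned in file order with FASTQ
    qualities preserved.
    """
    fmt = (format or _guess_format(path)).upper()
    if fmt not in {"FASTA", "FASTQ"}:
        raise ValueError(f"unknown sequence format {format!r}")
    out: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt.lower()):
                qual = None
                if fmt == "FASTQ":
                    qual = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                out.append(SequenceRecord(rec.id, str(rec.seq).upper(), qual))
        except ValueError as exc:  # Biopython raises ValueError on bad records
            raise ValueError(f"malformed {fmt} in {path}: {exc}") from exc
    return out


def write_sequences(records: Iterable[SequenceRecord], path, format: Optional[str] = None) -> None:
    """Write SequenceRecords as FASTA or FASTQ (gzipped if path ends .gz)."""
    fmt = (format or _guess_format(path)).upper()
    if fmt not in {"FASTA", "FASTQ"}:
        raise ValueError(f"unknown sequence format {format!r}")
    bio = []
    for r in records:
        rec = _BioRecord(Seq(r.seq), id=r.id, description="")
        if fmt == "FASTQ":
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        bio.append(rec)
    with _open_maybe_gzip(path, "wt") as fh:
        SeqIO.write(bio, fh, fmt.lower())


# ---------------------------------------------------------------------------
# tabular alignment parsing (PAF, BLAST outfmt 6)


def parse_alignment_table(path, dialect: str) -> list[AlignmentBlock]:
    """Parse a PAF or 12-column BLAST tabular (outfmt 6) file.

    Coordinates are normalised to 0-based half-open intervals on the +
    reference strand; BLAST percent identity becomes a fraction; BLAST rows
    with reversed subject coordinates get ``strand='-'``.
    """
    dialect = dialect.upper()
    if dialect not in {"PAF", "BLAST6"}:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    blocks: list[AlignmentBlock] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "PAF":
                    blocks.append(_parse_paf_row(fields))
                else:
                    blocks.append(_parse_blast6_row(fields))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad {dialect} row: {exc}") from exc
    return blocks


def _parse_paf_row(f: Sequence[str]) -> AlignmentBlock:
    if len(f) < 12:
        raise ValueError(f"expected >=12 columns, got {len(f)}")
    nmatch, alen = int(f[9]), int(f[10])
    return AlignmentBlock(
        read_id=f[0],
        read_length=int(f[1]),
        read_start=int(f[2]),
        read_end=int(f[3]),
        strand=f[4],
        ref_name=f[5],
        ref_start=int(f[7]),
        ref_end=int(f[8]),
        identity=nmatch / alen if alen else 0.0,
    )


def _parse_blast6_row(f: Sequence[str]) -> AlignmentBlock:
    if len(f) != 12:
        raise ValueError(f"expected 12 columns, got {len(f)}")
    sstart, send = int(f[8]), int(f[9])
    strand = "+" if sstart <= send else "-"
    lo, hi = (sstart, send) if strand == "+" else (send, sstart)
    return AlignmentBlock(
        read_id=f[0],
        ref_name=f[1],
        identity=float(f[2]) / 100.0,
        read_start=int(f[6]) - 1,
        read_end=int(f[7]),
        ref_start=lo - 1,
        ref_end=hi,
        strand=strand,
        evalue=float(f[10]),
    )


# ---------------------------------------------------------------------------
# SAM paired-end parsing


def _block_from_sam(aln: pysam.AlignedSegment) -> AlignmentBlock:
    nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
    alen = aln.query_alignment_length or 1
    return AlignmentBlock(
        read_id=aln.query_name,
        read_start=aln.query_alignment_start,
        read_end=aln.query_alignment_end,
        ref_name=aln.reference_name,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
        identity=max(0.0, 1.0 - nm / alen),
        read_length=aln.query_length or None,
    )


def parse_paired_alignments(
    path,
    min_insert: int = DEFAULT_MIN_INSERT,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> list[ReadPairAlignment]:
    """Join primary SAM alignments into read pairs.

    Concordance comes from the proper-pair flag when the aligner set it;
    otherwise it is recomputed from the contract in :func:`is_concordant`.
    Orphan mates produce a pair with an unmapped marker and are counted in
    a summary warning.
    """
    mates: dict[str, dict[int, Optional[pysam.AlignedSegment]]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            which = 2 if aln.is_read2 else 1
            mates.setdefault(aln.query_name, {})[which] = aln

    pairs: list[ReadPairAlignment] = []
    n_orphan = 0
    for name, d in mates.items():
        a1, a2 = d.get(1), d.get(2)
        if a1 is None or a2 is None:
            n_orphan += 1
        b1 = _block_from_sam(a1) if a1 is not None and not a1.is_unmapped else None
        b2 = _block_from_sam(a2) if a2 is not None and not a2.is_unmapped else None
        flagged = any(
            a is not None and a.is_paired and a.is_proper_pair for a in (a1, a2)
        )
        if flagged:
            concordant = True
            insert = None
            for a in (a1, a2):
                if a is not None and a.template_length:
                    insert = abs(a.template_length)
                    break
        else:
            concordant, insert = is_concordant(b1, b2, min_insert, max_insert)
        pairs.append(ReadPairAlignment(name, b1, b2, concordant, insert))
    if n_orphan:
        warnings.warn(f"{n_orphan} read pair(s) with an orphan mate", stacklevel=2)
    return pairs


# ---------------------------------------------------------------------------
# minimal internal mapper

_BASE_TO_U8 = np.zeros(256, dtype=np.uint8)
for i, b in enumerate(b"ACGTN"):
    _BASE_TO_U8[b] = i


def _encode(seq: str) -> np.ndarray:
    return _BASE_TO_U8[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ReferenceIndex:
    """Exact k-mer index over one or more reference sequences.

    Built once per reference set; reused across many reads.  Intended for
    synthetic references (kilobases to a few megabases).
    """

    def __init__(self, references: Union[SequenceRecord, Sequence[SequenceRecord]], k: int = 21):
        if isinstance(references, SequenceRecord):
            references = [references]
        if k < 11:
            raise ValueError("seed length k must be >= 11")
        for ref in references:
            if len(ref.seq) < k:
                raise ValueError(f"reference {ref.id!r} shorter than k={k}")
        self.k = k
        self.refs = {r.id: r.seq for r in references}
        self._enc = {r.id: _encode(r.seq) for r in references}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for r in references:
            seq = r.seq
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((r.id, i))

    # -- single best-hit mapping -------------------------------------------

    def _seed_positions(self, read_len: int, n_seeds: int = 8) -> list[int]:
        span = read_len - self.k
        if span < 0:
            return []
        if span == 0:
            return [0]
        n = min(n_seeds, span + 1)
        return sorted({round(i * span / (n - 1)) for i in range(n)}) if n > 1 else [0]

    def _candidates(self, oriented: str) -> set[tuple[str, int]]:
        cands: set[tuple[str, int]] = set()
        for pos in self._seed_positions(len(oriented)):
            for ref_id, ref_pos in self._index.get(oriented[pos : pos + self.k], ()):
                cands.add((ref_id, ref_pos - pos))
        return cands

    def map_read(self, read: SequenceRecord, max_mismatch_frac: float = 0.1) -> Optional[AlignmentBlock]:
        """Best unique ungapped placement of a read, or None.

        Ties between distinct placements (equal match count) are reported as
        unmapped so downstream orientation counts are never fed ambiguous
        placements.
        """
        n = len(read.seq)
        scored: list[tuple[int, int, str, str, int, int, int]] = []
        for strand, oriented in (("+", read.seq), ("-", revcomp(read.seq))):
            enc = _encode(oriented)
            for ref_id, diag in self._candidates(oriented):
                ref_enc = self._enc[ref_id]
                ref_s = max(diag, 0)
                ref_e = min(diag + n, len(ref_enc))
                if ref_e - ref_s < self.k:
                    continue
                q_s, q_e = ref_s - diag, ref_e - diag
                matches = int(np.count_nonzero(ref_enc[ref_s:ref_e] == enc[q_s:q_e]))
                scored.append((matches, ref_e - ref_s, strand, ref_id, ref_s, q_s, q_e))
        if not scored:
            return None
        scored.sort(key=lambda t: (-t[0], t[3], t[4]))
        best = scored[0]
        matches, alen, strand, ref_id, ref_s, q_s, q_e = best
        if len(scored) > 1 and scored[1][0] == matches:
            return None  # ambiguous best hit
        identity = matches / alen
        if 1.0 - identity > max_mismatch_frac:
            return None
        if strand == "+":
            read_start, read_end = q_s, q_e
        else:
            read_start, read_end = n - q_e, n - q_s
        return AlignmentBlock(
            read_id=read.id,
            read_start=read_start,
            read_end=read_end,
            ref_name=ref_id,
            ref_start=ref_s,
            ref_end=ref_s + alen,
            strand=strand,
            identity=identity,
            read_length=n,
        )

    # -- multi-block (split) mapping ---------------------------------------

    def split_map(
        self,
        read: SequenceRecord,
        min_block_len: int = 50,
        seed_stride: Optional[int] = None,
        max_seed_gap: int = 150,
        x_drop: int = 20,
        overlap_tol: int = 20,
    ) -> list[AlignmentBlock]:
        """Local multi-block mapping of a (long) read.

        Seeds are clustered per (reference, strand, diagonal), each cluster
        is extended without gaps under an X-drop rule (+1 match, -3
        mismatch), and blocks are greedily selected so that no two kept
        blocks overlap on the read by more than ``overlap_tol`` nt.  A read
        spanning an inverted segment therefore yields blocks of opposite
        strands; this is the raw material for split-read inversion calling.

        ``max_seed_gap`` breaks seed clusters on one diagonal at gaps
        larger than this, so that collinear flanks on either side of a
        short rearranged segment are not fused into one block; keep it
        below the smallest rearrangement of interest.
        """
        n = len(read.seq)
        stride = seed_stride or max(1, self.k // 2)
        raw: list[AlignmentBlock] = []
        for strand, oriented in (("+", read.seq), ("-", revcomp(read.seq))):
            enc = _encode(oriented)
            by_diag: dict[tuple[str, int], list[int]] = {}
            for pos in range(0, n - self.k + 1, stride):
                for ref_id, ref_pos in self._index.get(oriented[pos : pos + self.k], ()):
                    by_diag.setdefault((ref_id, ref_pos - pos), []).append(pos)
            for (ref_id, diag), seeds in by_diag.items():
                seeds.sort()
                cluster = [seeds[0]]
                for pos in seeds[1:]:
                    if pos - cluster[-1] <= max_seed_gap:
                        cluster.append(pos)
                    else:
                        blk = self._extend_cluster(read.id, enc, strand, ref_id, diag, cluster, n, x_drop)
                        if blk is not None:
                            raw.append(blk)
                        cluster = [pos]
                blk = self._extend_cluster(read.id, enc, strand, ref_id, diag, cluster, n, x_drop)
                if blk is not None:
                    raw.append(blk)
        raw = [b for b in raw if b.read_span >= min_block_len]
        # greedy selection by score (matches), limited read overlap
        raw.sort(key=lambda b: (-(b.identity * b.read_span), b.read_start))
        kept: list[AlignmentBlock] = []
        for b in raw:
            ok = True
            for kb in kept:
                ov = min(b.read_end, kb.read_end) - max(b.read_start, kb.read_start)
                if ov > overlap_tol:
                    ok = False
                    break
            if ok:
                kept.append(b)
        kept.sort(key=lambda b: b.read_start)
        return kept

    def _extend_cluster(
        self,
        read_id: str,
        enc: np.ndarray,
        strand: str,
        ref_id: str,
        diag: int,
        cluster: list[int],
        n: int,
        x_drop: int,
    ) -> Optional[AlignmentBlock]:
        ref_enc = self._enc[ref_id]
        q_lo, q_hi = cluster[0], cluster[-1] + self.k  # [q_lo, q_hi) seed-covered
        q_lo = max(q_lo, -diag if diag < 0 else 0)
        q_hi = min(q_hi, len(ref_enc) - diag, n)
        if q_hi <= q_lo:
            return None
        # X-drop extension right
        best, score, q_end = 0, 0, q_hi
        q = q_hi
        lim = min(n, len(ref_enc) - diag)
        while q < lim:
            score += 1 if enc[q] == ref_enc[q + diag] else -3
            q += 1
            if score > best:
                best, q_end = score, q
            elif best - score > x_drop:
                break
        # X-drop extension left
        best, score, q_start = 0, 0, q_lo
        q = q_lo
        low = max(0, -diag)
        while q > low:
            q -= 1
            score += 1 if enc[q] == ref_enc[q + diag] else -3
            if score > best:
                best, q_start = score, q
            elif best - score > x_drop:
                break
        seg = slice(q_start, q_end)
        matches = int(np.count_nonzero(enc[seg] == ref_enc[q_start + diag : q_end + diag]))
        alen = q_end - q_start
        if alen <= 0:
            return None
        identity = matches / alen
        if strand == "+":
            rs, re_ = q_start, q_end
        else:
            rs, re_ = n - q_end, n - q_start
        return AlignmentBlock(
            read_id=read_id,
            read_start=rs,
            read_end=re_,
            ref_name=ref_id,
            ref_start=q_start + diag,
            ref_end=q_end + diag,
            strand=strand,
            identity=identity,
            read_length=n,
        )


def minimal_map(
    reads: Iterable[SequenceRecord],
    reference: Union[SequenceRecord, Sequence[SequenceRecord]],
    k: int = 21,
    max_mismatch_frac: float = 0.1,
) -> list[AlignmentBlock]:
    """Map reads to the reference; unique best ungapped hits only.

    Reads with no seed hit or with tied best placements are omitted
    (unmapped).  See :class:`ReferenceIndex` for mapping details.
    """
    index = ReferenceIndex(reference, k=k)
    out = []
    for read in reads:
        blk = index.map_read(read, max_mismatch_frac=max_mismatch_frac)
        if blk is not None:
            out.append(blk)
    return out


def split_map(
    reads: Iterable[SequenceRecord],
    reference: Union[SequenceRecord, Sequence[SequenceRecord]],
    k: int = 21,
    **kwargs,
) -> list[AlignmentBlock]:
    """Multi-block local mapping of long reads (see ReferenceIndex.split_map)."""
    index = ReferenceIndex(reference, k=k)
    out: list[AlignmentBlock] = []
    for read in reads:
        out.extend(index.split_map(read, **kwargs))
    return out
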