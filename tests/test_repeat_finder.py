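"""Inverted-repeat discovery tests, including an exhaustive anti-diagonal
oracle, a regex-expansion oracle for IUPAC matching, and the orientation
convention's flip behaviour."""

from itertools import product

import numpy as np
import pytest

from phasevar._seq import IUPAC_CODES, revcomp
from phasevar.io_align import SequenceRecord
from phasevar.repeat_finder import (
    InvertibleLocus,
    find_inverted_repeat_loci,
    group_repeat_families,
    match_iupac_motif,
    set_orientation_convention,
)
from phasevar.synthetic_data import GenomeSpec, make_genome

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive scan of anti-diagonal complementary runs


def brute_force_loci(seq: str, min_arm: int = 10, spacer_range=(150, 250)):
    """Every maximal perfect inverted-repeat pair with arm >= min_arm and
    spacer in range, by direct scan of all anti-diagonal run inner-ends.

    A run cell (p, q) on anti-diagonal d = p + q matches when seq[p] is
    complementary to seq[q]; a locus is a maximal contiguous run, its
    left arm ending at the run's inner end b with spacer d - 2b - 1.
    """
    n = len(seq)
    smin, smax = spacer_range

    def match(p, q):
        return 0 <= p < q < n and _COMP[seq[p]] == seq[q]

    out = []
    for d in range(2 * min_arm + smin - 1, 2 * n - 1):
        b_lo = -((-(d - 1 - smax)) // 2)  # ceil((d-1-smax)/2)
        b_hi = (d - 1 - smin) // 2
        for b in range(max(b_lo, min_arm - 1), min(b_hi, n - 1) + 1):
            q = d - b
            if not (smin <= q - b - 1 <= smax):
                continue
            if match(b + 1, q - 1):
                continue  # not the inner end of its run
            if not all(match(b - t, q + t) for t in range(min_arm)):
                continue
            a = b - min_arm + 1
            while match(a - 1, d - a + 1):
                a -= 1
            out.append(((a, b + 1), (d - b, d - a + 1)))
    # deduplicate overlapping candidates keeping the longest arm
    out.sort(key=lambda c: (-(c[0][1] - c[0][0]), c[0][0], c[1][0]))
    kept = []
    for cand in out:
        s, e = cand[0][0], cand[1][1]
        if all(min(e, k[1][1]) - max(s, k[0][0]) <= 0 for k in kept):
            kept.append(cand)
    return sorted(kept)


class TestDeNovoSearch:
    def test_planted_loci_recovered(self):
        genome, truth = make_genome(GenomeSpec(genome_length=20_000, n_loci=2, seed=4))
        loci = find_inverted_repeat_loci(genome)
        for row in truth.itertuples():
            spans = [l.span for l in loci]
            # planted locus present, possibly with chance arm extension
            assert any(s <= row.left_start and e >= row.right_end for s, e in spans)

    def test_no_complementary_pair_in_range_gives_empty(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 1500))
        assert brute_force_loci(seq) == []  # verified negative case
        assert find_inverted_repeat_loci(seq) == []

    def test_too_short_genome_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert find_inverted_repeat_loci("ACGTACGTACGT" * 10) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq_arr = rng.choice(list("ACGT"), 4000)
        n_loci = seed % 4
        pos = 300
        for _ in range(n_loci):
            arm = "".join(rng.choice(list("ACGT"), rng.integers(10, 14)))
            spacer_len = int(rng.integers(160, 240))
            ins = list(arm) + list(rng.choice(list("ACGT"), spacer_len)) + list(revcomp(arm))
            seq_arr[pos : pos + len(ins)] = ins
            pos += len(ins) + 600
        seq = "".join(seq_arr)
        got = sorted((l.left_arm, l.right_arm) for l in find_inverted_repeat_loci(seq))
        assert got == brute_force_loci(seq)

    def test_strand_symmetry(self):
        genome, _ = make_genome(GenomeSpec(genome_length=15_000, n_loci=2, seed=5))
        n = len(genome.seq)
        fwd = find_inverted_repeat_loci(genome.seq)
        rev = find_inverted_repeat_loci(revcomp(genome.seq))
        mirrored = sorted(
            ((n - r_e, n - r_s), (n - l_e, n - l_s))
            for (l_s, l_e), (r_s, r_e) in ((l.left_arm, l.right_arm) for l in rev)
        )
        assert sorted((l.left_arm, l.right_arm) for l in fwd) == mirrored

    def test_every_reported_locus_satisfies_complementarity(self):
        genome, _ = make_genome(GenomeSpec(genome_length=30_000, n_loci=3, seed=6))
        for l in find_inverted_repeat_loci(genome):
            assert l.check_against(genome.seq)


class TestSeededSearch:
    def test_toy_motif_spacer_motif_rc(self):
        rng = np.random.default_rng(1)
        seq = "GTTCGTTTAA" + "".join(rng.choice(list("ACGT"), 183)) + "TTAAACGAAC"
        (locus,) = find_inverted_repeat_loci(seq, seed_motif="GTTCGTTTAA")
        assert locus.arm_length == 10
        assert locus.spacer_length == 183
        assert locus.repeat_seq == "GTTCGTTTAA"

    def test_seeded_hits_contained_in_de_novo_hits(self):
        genome, _ = make_genome(GenomeSpec(genome_length=40_000, n_loci=4, seed=7))
        seeded = find_inverted_repeat_loci(genome, seed_motif="GTTCGTTTAA")
        denovo = find_inverted_repeat_loci(genome)
        for s in seeded:
            assert any(
                d.left_arm[0] <= s.left_arm[0] and d.right_arm[1] >= s.right_arm[1]
                for d in denovo
            ), s

    def test_family_grouping_counts_shared_repeats(self):
        genome, truth = make_genome(GenomeSpec(genome_length=40_000, n_loci=4, seed=7))
        seeded = find_inverted_repeat_loci(genome, seed_motif="GTTCGTTTAA")
        fam = group_repeat_families(seeded)
        assert fam.iloc[0].repeat_seq == "GTTCGTTTAA"
        assert fam.iloc[0].n_members == len(truth)


class TestIupacMotif:
    def test_named_motif_matches_concrete_instance(self):
        seq = "TTTTAGACGTTCGTATTTT"
        hits = [h for h in match_iupac_motif(seq, "ARACGTTCGTN") if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].start == 4
        assert hits[0].matched_seq == "AGACGTTCGTA"

    def test_identity_motif(self):
        hits = match_iupac_motif("ACGT", "ACGT")
        plus = [h for h in hits if h.strand == "+"]
        assert plus[0].start == 0 and plus[0].end == 4

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            match_iupac_motif("ACGT", "AXGT")

    def test_against_regex_expansion_oracle(self):
        """Hit set equals exhaustive search over all concrete expansions."""
        motif = "ARYCGWN"
        expansions = ["".join(p) for p in product(*(IUPAC_CODES[c] for c in motif))]
        rng = np.random.default_rng(9)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), 250))
            expected = set()
            for m in expansions:
                for strand, hay in (("+", seq), ("-", revcomp(seq))):
                    start = hay.find(m)
                    while start != -1:
                        if strand == "+":
                            expected.add((start, "+"))
                        else:
                            expected.add((len(seq) - start - len(m), "-"))
                        start = hay.find(m, start + 1)
            got = {(h.start, h.strand) for h in match_iupac_motif(seq, motif)}
            assert got == expected


def _motif_locus_genome(seed=13):
    """Genome with one locus whose spacer carries a directional promoter
    motif, and 1 kb of flank on each side."""
    rng = np.random.default_rng(seed)
    arm = "GTTCGTTTAA"
    spacer = list("".join(rng.choice(list("ACGT"), 184)))
    spacer[80:91] = "AGACGTTCGTA"  # concrete ARACGTTCGTN instance, + strand
    left = "".join(rng.choice(list("ACGT"), 1000))
    right = "".join(rng.choice(list("ACGT"), 1000))
    seq = left + arm + "".join(spacer) + revcomp(arm) + right
    s = len(left)
    e = s + 10 + 184 + 10
    locus = InvertibleLocus(
        ref_name="g",
        left_arm=(s, s + 10),
        right_arm=(e - 10, e),
        spacer=(s + 10, e - 10),
        repeat_seq=arm,
        label="L1",
    )
    return seq, locus, s, e


class TestOrientationConvention:
    def test_no_annotation_falls_back_to_reference(self):
        seq, locus, *_ = _motif_locus_genome()
        (out,) = set_orientation_convention([locus])
        assert out.on_definition == "as_reference"
        assert out.reference_is_on and not out.resolved

    def test_operon_downstream_labels_reference_on(self):
        seq, locus, s, e = _motif_locus_genome()
        operons = [(e + 200, e + 900, "+")]
        (out,) = set_orientation_convention([locus], operons, genome=seq)
        assert out.on_definition == "toward_operon"
        assert out.reference_is_on and out.resolved

    def test_in_silico_inversion_flips_label(self):
        seq, locus, s, e = _motif_locus_genome()
        operons = [(e + 200, e + 900, "+")]
        flipped_seq = seq[:s] + revcomp(seq[s:e]) + seq[e:]
        (out,) = set_orientation_convention([locus], operons, genome=flipped_seq)
        assert out.on_definition == "toward_operon"
        assert not out.reference_is_on and out.resolved

    def test_unresolvable_locus_flagged(self):
        seq, locus, s, e = _motif_locus_genome()
        operons = [(e + 20_000, e + 21_000, "+")]  # beyond the window
        (out,) = set_orientation_convention([locus], operons, genome=seq)
        assert out.on_definition == "as_reference" and not out.resolved
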