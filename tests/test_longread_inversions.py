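"""Filter semantics, event calling on constructed chains, the hotspot
histogram, and end-to-end recovery of a planted inversion from simulated
long reads."""

import numpy as np
import pytest

from phasevar.io_align import AlignmentBlock, ReferenceIndex
from phasevar.longread_inversions import (
    InversionEvent,
    ReadChain,
    chain_read_blocks,
    detect_all_rearrangements,
    detect_rearrangements,
    hotspot_histogram,
)
from phasevar.synthetic_data import (
    GenomeSpec,
    ReadSimParams,
    assign_orientations,
    make_genome,
    simulate_long_reads,
)


def _blk(read_id, rs, re_, ts, te, strand="+", identity=0.99, evalue=1e-40, read_length=None):
    return AlignmentBlock(read_id, rs, re_, "ref", ts, te, strand, identity,
                          evalue=evalue, read_length=read_length)


class TestRetentionFilters:
    def test_short_read_excluded_long_read_kept(self):
        b900 = _blk("r900", 0, 800, 100, 900, read_length=900)
        b1100 = _blk("r1100", 0, 800, 100, 900, read_length=1100)
        chains = chain_read_blocks([b900, b1100])
        assert [c.read_id for c in chains] == ["r1100"]

    def test_exactly_1000nt_read_excluded(self):
        b = _blk("r", 0, 900, 100, 1000, read_length=1000)
        assert chain_read_blocks([b]) == []

    def test_block_length_threshold(self):
        short = _blk("r", 0, 150, 100, 250, read_length=2000)
        kept = _blk("r", 200, 450, 400, 650, read_length=2000)
        chains = chain_read_blocks([short, kept])
        assert len(chains) == 1
        assert chains[0].blocks == [kept]

    def test_exactly_200nt_block_excluded(self):
        b200 = _blk("r", 0, 200, 100, 300, read_length=2000)
        b201 = _blk("r", 300, 501, 400, 601, read_length=2000)
        chains = chain_read_blocks([b200, b201])
        assert chains[0].blocks == [b201]

    def test_identity_threshold(self):
        low = _blk("r", 0, 300, 100, 400, identity=0.85, read_length=2000)
        high = _blk("r", 400, 700, 500, 800, identity=0.95, read_length=2000)
        chains = chain_read_blocks([low, high])
        assert chains[0].blocks == [high]

    def test_exactly_090_identity_excluded(self):
        b = _blk("r", 0, 300, 100, 400, identity=0.90, read_length=2000)
        assert chain_read_blocks([b]) == []

    def test_evalue_cutoff_applies_when_present(self):
        weak = _blk("r", 0, 300, 100, 400, evalue=1e-10, read_length=2000)
        strong = _blk("r", 400, 700, 500, 800, evalue=1e-30, read_length=2000)
        chains = chain_read_blocks([weak, strong])
        assert chains[0].blocks == [strong]
        # blocks without an e-value (e.g. from the internal mapper) pass
        no_ev = _blk("r", 0, 300, 100, 400, evalue=None, read_length=2000)
        assert chain_read_blocks([no_ev])[0].blocks == [no_ev]

    def test_filter_monotonicity(self):
        rng = np.random.default_rng(8)
        blocks = []
        for i in range(90):
            rs = (i % 3) * 400
            span = int(rng.integers(150, 600))
            ts = int(rng.integers(0, 30_000))
            blocks.append(
                _blk(
                    f"r{i // 3}", rs, rs + span, ts, ts + span,
                    identity=float(rng.uniform(0.8, 1.0)),
                    read_length=int(rng.integers(800, 4000)),
                )
            )
        prev_chains = prev_events = None
        for ident in (0.85, 0.90, 0.95):
            chains = chain_read_blocks(blocks, min_identity=ident)
            events = detect_all_rearrangements(chains)
            if prev_chains is not None:
                assert len(chains) <= prev_chains
                assert len(events) <= prev_events
            prev_chains, prev_events = len(chains), len(events)


class TestEventCalling:
    def test_single_block_chain_emits_nothing(self):
        chain = ReadChain("r", 2000, [_blk("r", 0, 1800, 100, 1900)])
        assert detect_rearrangements(chain) == []

    def test_collinear_blocks_emit_nothing(self):
        chain = ReadChain(
            "r", 3000,
            [_blk("r", 0, 1000, 100, 1100), _blk("r", 1050, 2500, 1150, 2600)],
        )
        assert detect_rearrangements(chain) == []

    def test_inverted_middle_block_emits_both_boundaries(self):
        # read spans an inversion: + block, - block over [5000,5200), + block
        chain = ReadChain(
            "r", 3000,
            [
                _blk("r", 0, 900, 4100, 5000, "+"),
                _blk("r", 900, 1100, 5000, 5200, "-"),
                _blk("r", 1100, 2000, 5200, 6100, "+"),
            ],
        )
        events = detect_rearrangements(chain)
        assert [e.kind for e in events] == ["inverted", "inverted"]
        assert sorted(e.ref_pos for e in events) == [5000, 5200]

    def test_displacement_threshold_is_strict_200(self):
        def chain_with_shift(shift):
            return ReadChain(
                "r", 3000,
                [
                    _blk("r", 0, 1000, 100, 1100),
                    _blk("r", 1050, 2500, 1150 + shift, 2600 + shift),
                ],
            )
        assert detect_rearrangements(chain_with_shift(150)) == []
        events = detect_rearrangements(chain_with_shift(250))
        assert len(events) == 1
        assert events[0].kind == "displaced"
        assert events[0].shift == 250

    def test_exactly_200_shift_not_called(self):
        chain = ReadChain(
            "r", 3000,
            [_blk("r", 0, 1000, 100, 1100), _blk("r", 1050, 2500, 1350, 2800)],
        )
        assert detect_rearrangements(chain) == []


class TestHotspotHistogram:
    def test_zero_events_no_hotspots(self):
        bins = hotspot_histogram([], 10_000)
        assert all(b.event_count == 0 and not b.is_hotspot for b in bins)

    def test_clustered_events_flag_one_bin(self):
        rng = np.random.default_rng(1)
        events = [
            InversionEvent("r", "inverted", "ref", int(p), ("+", "-"))
            for p in rng.integers(5200, 5400, 30)
        ]
        bins = hotspot_histogram(events, 50_000, bin_width=1000)
        hot = [b for b in bins if b.is_hotspot]
        assert len(hot) == 1
        assert hot[0].bin_index == 5
        assert hot[0].event_count == 30

    def test_bin_counts_conserve_events(self):
        rng = np.random.default_rng(2)
        events = [
            InversionEvent("r", "inverted", "ref", int(p), ("+", "-"))
            for p in rng.integers(0, 49_999, 500)
        ]
        bins = hotspot_histogram(events, 50_000)
        assert sum(b.event_count for b in bins) == len(events)
        assert len(bins) == 50

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            hotspot_histogram([], 1000, bin_width=0)


class TestEndToEnd:
    def test_off_spanning_zero_error_read_splits_into_three_blocks(self, small_genome):
        """A zero-error long read across an OFF locus aligned to the ON
        reference yields exactly 3 blocks with an inverted middle."""
        genome, truth = small_genome
        pop = assign_orientations(truth, [0.0, 1.0, 1.0], 1, seed=1)  # locus 1 OFF
        row = truth.iloc[0]
        from phasevar.synthetic_data import haplotype_sequence
        from phasevar.io_align import SequenceRecord

        hap = haplotype_sequence(genome, truth, [False, True, True])
        s = int(row.left_start) - 700
        read = SequenceRecord("lr", hap[s : s + 1600])
        ix = ReferenceIndex(genome, k=21)
        blocks = ix.split_map(read)
        assert len(blocks) == 3
        assert [b.strand for b in blocks] == ["+", "-", "+"]
        mid = blocks[1]
        # the inverted block covers the locus (arms absorb a few bases)
        assert abs(mid.ref_start - row.left_start) <= len(row.repeat_seq)
        assert abs(mid.ref_end - row.right_end) <= len(row.repeat_seq)

    def test_planted_inversion_hotspot_recovery(self, small_genome):
        genome, truth = small_genome
        pop = assign_orientations(truth, [0.5, 0.5, 0.5], 100, seed=2)
        params = ReadSimParams(seed=3, long_substitution_error=0.0)
        reads, _ = simulate_long_reads(genome, truth, pop, params, n_reads=200)
        ix = ReferenceIndex(genome, k=21)
        blocks = []
        for r in reads:
            blocks.extend(ix.split_map(r))
        chains = chain_read_blocks(blocks)
        events = detect_all_rearrangements(chains)
        assert events, "mixed orientations must produce inversion signals"
        bins = hotspot_histogram(events, len(genome.seq))
        hot = {b.bin_index for b in bins if b.is_hotspot}
        locus_bins = set()
        for row in truth.itertuples():
            locus_bins.update(range(row.left_start // 1000, (row.right_end - 1) // 1000 + 1))
        assert hot <= locus_bins
        assert hot, "at least one locus bin must be called"
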