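"""liftIn / liftOut coordinate mapping and multi-mapper deduplication."""

import pandas as pd
import pytest

from replift import (
    Chain,
    ChainIndex,
    GenomeSource,
    LocusSpec,
    lift_interval,
    lift_out,
    lift_reads,
    make_repeat_genome,
    revcomp,
)
from replift.chain import Block
from replift.lift import LiftError

from conftest import random_consensus
from oracles import genome_to_consensus_map


def _chain(blocks, t_start=0, q_start=0, q_strand="+", q_size=600,
           t_name="chr1", q_name="L1toy", chain_id=1):
    t_span = sum(b.size + b.dt for b in blocks)
    q_span = sum(b.size + b.dq for b in blocks)
    ch = Chain(
        score=1, t_name=t_name, t_size=100000, t_start=t_start,
        t_end=t_start + t_span, q_name=q_name, q_size=q_size,
        q_strand=q_strand, q_start=q_start, q_end=q_start + q_span,
        chain_id=chain_id, blocks=tuple(blocks),
    )
    ch.validate()
    return ch


@pytest.fixture()
def gap_index():
    # blocks [(4, dt=1, dq=0), (5, 0, 0)] anchored at t=0, q=0
    return ChainIndex([_chain([Block(4, 1, 0), Block(5, 0, 0)])])


class TestLiftInterval:
    def test_block_pieces_map_linearly(self, gap_index):
        (seg,) = lift_interval(gap_index, "chr1", 0, 4)
        assert (seg.q_start, seg.q_end) == (0, 4)
        (seg,) = lift_interval(gap_index, "chr1", 5, 10)
        assert (seg.q_start, seg.q_end) == (4, 9)

    def test_dt_gap_base_dropped_and_pieces_merged(self, gap_index):
        (seg,) = lift_interval(gap_index, "chr1", 3, 6)
        assert (seg.q_start, seg.q_end) == (3, 5)  # inserted base maps nowhere

    def test_no_overlap_is_empty(self, gap_index):
        assert lift_interval(gap_index, "chr1", 500, 600) == []
        assert lift_interval(gap_index, "chr9", 0, 10) == []

    def test_agrees_with_column_walk_on_fixture(self, fixture, chain_index):
        for rec in fixture.align_records[:8]:
            for g, c in genome_to_consensus_map(rec).items():
                segs = [
                    s for s in lift_interval(chain_index, rec.chrom, g, g + 1)
                    if s.q_name == rec.repeat_id
                ]
                assert [(s.q_start, s.q_end) for s in segs] == [(c, c + 1)]

    def test_conservation_of_read_length(self, fixture, chain_index):
        """Lifted pieces of one read never exceed the read length."""
        chrom = next(iter(fixture.genome))
        glen = len(fixture.genome[chrom])
        for start in range(0, glen - 36, 997):
            segs = lift_interval(chain_index, chrom, start, start + 36)
            assert sum(s.length for s in segs) <= 36


def _dup_read_bed(fixture, k):
    """One read name mapped at k genomic copies of the same consensus span."""
    rows = []
    recs = [r for r in fixture.align_records if r.c_start == 0][:k]
    assert len(recs) == k
    for rec in recs:
        g = genome_to_consensus_map(rec)
        inv = {c: gp for gp, c in g.items()}
        span = sorted(inv[c] for c in range(50, 86) if c in inv)
        rows.append((rec.chrom, span[0], span[-1] + 1, "readA"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestDedup:
    def test_multimapper_counts_once(self, fixture, chain_index):
        bed = _dup_read_bed(fixture, 3)
        segs = lift_reads(bed, chain_index, dedup=True)
        assert len({(s.chrom, s.g_start) for s in segs}) == 1

    def test_dedup_off_keeps_all_copies(self, fixture, chain_index):
        bed = _dup_read_bed(fixture, 3)
        segs = lift_reads(bed, chain_index, dedup=False)
        assert len({(s.chrom, s.g_start) for s in segs}) == 3

    def test_unnamed_reads_rejected(self, chain_index):
        bed = pd.DataFrame([("chrsyn", 0, 36)], columns=["chrom", "start", "end"])
        with pytest.raises(LiftError, match="dedup"):
            lift_reads(bed, chain_index, dedup=True)
        bed["name"] = "."
        with pytest.raises(LiftError):
            lift_reads(bed, chain_index, dedup=True)

    def test_copy_number_neutral(self):
        """Duplicating every instance leaves deduplicated counts unchanged."""
        cons = {"L1toy": random_consensus(200, seed=9)}
        segs = {}
        for n in (4, 8):
            fx = make_repeat_genome(cons, n_instances=n, sub_rate=0.0,
                                    indel_rate=0.0, minus_fraction=0.0,
                                    spacer_len=100, seed=3)
            from replift import build_chains
            idx = ChainIndex(build_chains(fx.align_records,
                                          fx.consensus_sizes(),
                                          fx.chrom_sizes()))
            rows = []
            for rec in fx.align_records:
                rows.append((rec.chrom, rec.g_start + 10, rec.g_start + 46, "r1"))
            bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
            segs[n] = lift_reads(bed, idx, dedup=True)
        assert [(s.q_start, s.q_end) for s in segs[4]] == \
               [(s.q_start, s.q_end) for s in segs[8]] == [(10, 46)]


class TestLiftOut:
    def test_plus_strand_ungapped_slice(self):
        cons = {"L1toy": "AACCGGTTAA"}
        genome = GenomeSource({"chr1": "T" * 100 + "AACCGGTTAA" + "T" * 20})
        from replift import RepeatAlignment
        rec = RepeatAlignment(
            chrom="chr1", g_start=100, g_end=110, strand="+",
            repeat_id="L1toy", repeat_class="", c_start=0, c_end=10,
            sw_score=10, divergence_pct=0.0, aligned_genome="AACCGGTTAA",
            aligned_consensus="AACCGGTTAA", record_id="p1",
        )
        sites = lift_out([rec], LocusSpec("L1toy", 2, 8), genome, cons["L1toy"])
        (e,) = sites.entries
        assert (e.g_start, e.g_end) == (102, 108)
        assert e.sequence == "CCGGTT" and e.n_mismatch == 0

    def test_minus_strand_reverse_complement(self):
        cons = {"L1toy": "AACCGGTTAA"}
        inst = revcomp("AACCGGTTAA")
        genome = GenomeSource({"chr1": "T" * 100 + inst + "T" * 20})
        from replift import RepeatAlignment
        rec = RepeatAlignment(
            chrom="chr1", g_start=100, g_end=110, strand="-",
            repeat_id="L1toy", repeat_class="", c_start=0, c_end=10,
            sw_score=10, divergence_pct=0.0, aligned_genome="AACCGGTTAA",
            aligned_consensus="AACCGGTTAA", record_id="m1",
        )
        sites = lift_out([rec], LocusSpec("L1toy", 2, 8), genome, cons["L1toy"])
        (e,) = sites.entries
        assert e.sequence == "CCGGTT" and e.strand == "-"

    def test_roundtrip_through_chains(self, fixture, chain_index,
                                      genome_source, planted_locus):
        sites = lift_out(fixture.align_records, planted_locus, genome_source,
                         fixture.consensus["L1toy"])
        assert sites.entries, "no indel-free instances covering the locus"
        for e in sites.entries:
            segs = [
                s for s in lift_interval(chain_index, e.chrom, e.g_start, e.g_end)
                if s.q_name == "L1toy"
            ]
            covered = sorted((s.q_start, s.q_end) for s in segs)
            assert covered[0][0] == planted_locus.start
            assert covered[-1][1] == planted_locus.end

    def test_partial_and_indel_instances_counted(self, genome_source, fixture,
                                                 planted_locus):
        sites = lift_out(fixture.align_records, planted_locus, genome_source,
                         fixture.consensus["L1toy"])
        total = len(sites.entries) + sites.n_partial + sites.n_indel_skipped
        assert total == len(fixture.align_records)

    def test_allow_indel_projects_fixed_length(self, genome_source, fixture,
                                               planted_locus):
        sites = lift_out(fixture.align_records, planted_locus, genome_source,
                         fixture.consensus["L1toy"], allow_indel=True)
        assert len(sites.entries) + sites.n_partial == len(fixture.align_records)
        assert all(len(e.sequence) == planted_locus.length for e in sites.entries)

    def test_unknown_repeat_rejected(self, genome_source, fixture):
        with pytest.raises(LiftError, match="nosuch"):
            lift_out(fixture.align_records, LocusSpec("nosuch", 0, 5),
                     genome_source, "ACGTACGT")
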