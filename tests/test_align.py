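"""Three-letter alignment: conversion, index vs naive scan, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gametemeth as gm
from gametemeth import align as al
from gametemeth.genome import revcomp
from conftest import random_seq, toy_genome_from_seq


# ---------------------------------------------------------------- oracle

def naive_hits(sequences, read, protocol):
    """Independent O(n*m) oracle: scan both converted reference images for
    every searched conversion of the read."""
    searches = {"methylc": ["OT", "OB"], "wba": ["OT", "OB", "CTOT", "CTOB"],
                "pbat": ["CTOT", "CTOB"]}[protocol]
    queries = {
        "OT": ("ct", read.replace("C", "T")),
        "OB": ("ga", revcomp(read.replace("C", "T"))),
        "CTOB": ("ga", read.replace("G", "A")),
        "CTOT": ("ct", revcomp(read.replace("G", "A"))),
    }
    hits = []
    for bs in searches:
        space, q = queries[bs]
        for chrom, seq in sequences.items():
            text = (seq.replace("C", "T") if space == "ct"
                    else seq.replace("G", "A"))
            for p in range(len(text) - len(q) + 1):
                if text[p:p + len(q)] == q:
                    strand = "+" if bs in ("OT", "CTOB") else "-"
                    hits.append((chrom, p, strand, bs))
    return sorted(hits)


def index_hits(index, read, protocol):
    out = []
    for bs in al.PROTOCOL_SEARCHES[protocol]:
        space, make_query, strand = al._SEARCHES[bs]
        q = make_query(read)
        text = index.index_ct if space == "ct" else index.index_ga
        for gp in text.find(q):
            loc = index.locate(gp, len(read))
            if loc is not None:
                out.append((loc[0], loc[1], strand, bs))
    return sorted(out)


# ---------------------------------------------------------------- conversion

@pytest.mark.parametrize("seq,mode,expected", [
    ("ACGT", "c_to_t", "ATGT"),
    ("ACGT", "g_to_a", "ACAT"),
    ("TTTT", "c_to_t", "TTTT"),
    ("CCCC", "c_to_t", "TTTT"),
    ("NACG", "c_to_t", "NATG"),
])
def test_convert_sequence(seq, mode, expected):
    assert al.convert_sequence(seq, mode) == expected
    assert len(al.convert_sequence(seq, mode)) == len(seq)


def test_convert_sequence_rejects_non_iupac():
    with pytest.raises(ValueError, match="non-IUPAC"):
        al.convert_sequence("ACXT", "c_to_t")
    with pytest.raises(ValueError, match="conversion mode"):
        al.convert_sequence("ACGT", "x_to_y")


@given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
@settings(max_examples=100, deadline=None)
def test_converted_sequences_lack_replaced_base(seq):
    assert "C" not in al.convert_sequence(seq, "c_to_t")
    assert "G" not in al.convert_sequence(seq, "g_to_a")


# ---------------------------------------------------------------- index

def test_every_kmer_of_toy_genome_is_found():
    rng = np.random.default_rng(1)
    seq = random_seq(rng, 1000)
    index = al.build_reference_index({"chr1": seq})
    ct = seq.replace("C", "T")
    for p in range(0, len(ct) - 32 + 1, 7):
        q = ct[p:p + 32]
        hits = index.index_ct.find(q)
        assert p in hits
        # agreement with a direct scan
        expect = [i for i in range(len(ct) - 31) if ct[i:i + 32] == q]
        assert hits == expect


def test_all_a_genome_ct_reference_is_identity():
    seq = "A" * 200
    index = al.build_reference_index({"chr1": seq})
    assert index.index_ct.text.startswith(seq)


def test_empty_genome_rejected():
    with pytest.raises(ValueError, match="empty genome"):
        al.build_reference_index({"chr1": ""})


def test_duplicate_segment_reports_two_hits():
    rng = np.random.default_rng(2)
    flank1, seg, flank2 = random_seq(rng, 300), random_seq(rng, 100), \
        random_seq(rng, 300)
    seq = flank1 + seg + flank2 + seg + random_seq(rng, 100)
    index = al.build_reference_index({"chr1": seq})
    read = seg[10:60]
    df = al.align_reads([("r1", read)], index, "methylc")
    assert len(df) == 1
    assert df.n_hits.iloc[0] == 2


# ---------------------------------------------------------------- align

def test_alignment_matches_naive_scan_oracle():
    """Index-based alignment equals the naive scan on random genomes,
    for reads drawn from all four bisulfite strands, all protocols."""
    rng = np.random.default_rng(3)
    n_checked = 0
    for rep in range(12):
        seqs = {f"chr{i}": random_seq(rng, int(rng.integers(400, 2000)),
                                      gc=0.45) for i in range(2)}
        index = al.build_reference_index(seqs)
        for _ in range(8):
            chrom = f"chr{int(rng.integers(2))}"
            L = int(rng.integers(32, 60))
            p = int(rng.integers(0, len(seqs[chrom]) - L))
            frag = seqs[chrom][p:p + L]
            bs = ["OT", "OB", "CTOT", "CTOB"][int(rng.integers(4))]
            # partially converted read from that strand
            conv = "".join(
                ("T" if b == "C" and rng.random() < 0.5 else b)
                for b in frag)
            if bs == "OT":
                read = conv
            elif bs == "CTOT":
                read = revcomp(conv)
            else:
                conv = "".join(
                    ("A" if b == "G" and rng.random() < 0.5 else b)
                    for b in frag)
                read = conv if bs == "CTOB" else revcomp(conv)
            for protocol in ("methylc", "wba", "pbat"):
                assert index_hits(index, read, protocol) == \
                    naive_hits(seqs, read, protocol)
                n_checked += 1
    assert n_checked == 12 * 8 * 3


def test_fully_methylated_read_still_aligns():
    rng = np.random.default_rng(4)
    seq = random_seq(rng, 2000, gc=0.5)
    index = al.build_reference_index({"chr1": seq})
    p = 500
    read = seq[p:p + 50]          # no conversion at all (every C methylated)
    assert "C" in read
    df = al.align_reads([("r", read)], index, "methylc")
    assert len(df) == 1
    assert (df.chrom.iloc[0], df.start.iloc[0], df.strand.iloc[0]) == \
        ("chr1", p, "+")


def test_single_mismatch_kills_alignment():
    rng = np.random.default_rng(5)
    seq = random_seq(rng, 2000)
    index = al.build_reference_index({"chr1": seq})
    read = list(seq[700:750])
    # flip a base in the middle to something that can't be explained by
    # bisulfite conversion
    read[25] = {"A": "G", "C": "G", "G": "T", "T": "G"}[read[25]]
    read = "".join(read)
    df = al.align_reads([("r", read)], index, "methylc")
    assert len(df) == 0


def test_short_reads_skipped_with_counter():
    rng = np.random.default_rng(6)
    seq = random_seq(rng, 500)
    index = al.build_reference_index({"chr1": seq})
    df = al.align_reads([("short", seq[10:40]), ("ok", seq[100:140])],
                        index, "methylc")
    assert df.attrs["n_too_short"] == 1
    assert list(df.read_id) == ["ok"]


def test_pbat_trimming_path():
    """52-nt raw reads trimmed (4,1) align as 47-nt tags at shifted starts."""
    rng = np.random.default_rng(7)
    seq = random_seq(rng, 3000)
    g = toy_genome_from_seq(seq)
    m = gm.generate_true_methylome(g, "custom",
                                   gm.MethylomeParams(constant=0.7))
    lib = gm.simulate_bisulfite_reads(g, m, gm.ReadSimParams(
        protocol="pbat", depth=2, seed=1))
    assert all(len(s) == 52 for _, s in lib.reads)
    index = al.build_reference_index(g)
    df = al.align_reads(lib, index, "pbat", trim=(4, 1))
    assert (df.length == 47).all()
    u = df[df.n_hits == 1]
    truth = u.read_id.str.split("|", expand=True)
    shift = np.where(u.bisulfite_strand == "CTOB", 4, 1)
    assert ((truth[2].astype(int) + shift) == u.start).all()


def test_wba_searches_both_conversions(small_genome):
    m = gm.generate_true_methylome(small_genome, "custom",
                                   gm.MethylomeParams(constant=0.5))
    lib = gm.simulate_bisulfite_reads(small_genome, m, gm.ReadSimParams(
        protocol="wba", depth=1, seed=8))
    index = al.build_reference_index(small_genome)
    df = al.align_reads(lib, index, "wba")
    u = df[df.n_hits == 1]
    assert set(u.bisulfite_strand) == {"OT", "OB", "CTOT", "CTOB"}
    truth = u.read_id.str.split("|", expand=True)
    assert (truth[1] == u.chrom).all()
    assert (truth[2].astype(int) == u.start).all()
    assert (truth[3] == u.bisulfite_strand).all()


# ---------------------------------------------------------------- filters

def _toy_alignments():
    return pd.DataFrame({
        "read_id": [f"r{i}" for i in range(6)],
        "chrom": ["chr1", "chr1", "chrM", "chrY", "chr1", "chr1"],
        "start": [100, 200, 50, 60, 300, 400],
        "strand": ["+"] * 6,
        "bisulfite_strand": ["OT"] * 6,
        "length": [40] * 6,
        "n_hits": [1, 2, 1, 1, 1, 1],
        "seq": ["A" * 40] * 6,
    })


def test_filter_rules():
    repeats = pd.DataFrame([
        dict(chrom="chr1", start=430, end=500, family="satellite"),
        dict(chrom="chr1", start=0, end=50, family="LINE"),
    ])
    res = al.filter_alignments(_toy_alignments(), repeats=repeats)
    kept = set(res.main.read_id)
    assert kept == {"r0", "r4"}          # r1 multihit, r3 chrY, r5 satellite
    assert list(res.mito.read_id) == ["r2"]
    assert res.counters["multi_hit"] == 1
    assert res.counters["chrY"] == 1
    assert res.counters["repeat_overlap"] == 1


def test_filter_requires_repeat_annotation():
    with pytest.raises(ValueError, match="repeat annotation"):
        al.filter_alignments(_toy_alignments())


def test_line_overlap_is_kept():
    """Only simple repeat / low complexity / satellite classes are dropped."""
    repeats = pd.DataFrame([
        dict(chrom="chr1", start=90, end=150, family="LINE")])
    res = al.filter_alignments(_toy_alignments(), repeats=repeats)
    assert "r0" in set(res.main.read_id)


def test_filter_and_dedup_are_idempotent():
    repeats = pd.DataFrame([
        dict(chrom="chr1", start=430, end=500, family="satellite")])
    once = al.filter_alignments(_toy_alignments(), repeats=repeats)
    twice = al.filter_alignments(once.main, repeats=repeats)
    assert once.main.equals(twice.main)
    d1 = al.deduplicate_alignments(once.main)
    assert d1.equals(al.deduplicate_alignments(d1))


def test_deduplication_key_and_stability():
    df = pd.DataFrame({
        "read_id": ["a", "b", "c"],
        "chrom": ["chr1"] * 3, "start": [10, 10, 10],
        "strand": ["+", "+", "-"],
        "bisulfite_strand": ["OT", "OT", "OB"],
        "length": [40] * 3, "n_hits": [1] * 3, "seq": ["A" * 40] * 3})
    out = al.deduplicate_alignments(df)
    assert list(out.read_id) == ["a", "c"]   # first kept; OB key differs


def test_dedup_recovers_unique_fragment_depth(small_genome):
    m = gm.generate_true_methylome(small_genome, "custom",
                                   gm.MethylomeParams(constant=0.5))
    lib = gm.simulate_bisulfite_reads(small_genome, m, gm.ReadSimParams(
        depth=1.0, duplicate_rate=0.5, seed=11))
    index = al.build_reference_index(small_genome)
    aln = al.align_reads(lib, index, "methylc")
    uniq = al.deduplicate_alignments(aln[aln.n_hits == 1])
    # deduplicated alignments ~ unique fragments (collisions of independent
    # fragments at identical (start, strand) are possible but rare)
    n_unique = sum(lib.n_unique_fragments.values())
    assert len(uniq) <= n_unique
    assert len(uniq) > 0.93 * n_unique
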