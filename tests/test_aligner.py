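"""Seed-and-extend aligner: index, modes, SAM output, correctness classes."""

import numpy as np
import pytest

from rnaseqbench import aligner
from rnaseqbench.synthetic_data import (
    LibraryParams,
    baseline_profile,
    simulate_library,
)
from tests.conftest import make_annotation


def _random_seq(rng, n):
    return np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, n)].tobytes()


@pytest.fixture(scope="module")
def toy_index():
    rng = np.random.default_rng(10)
    seq_a = _random_seq(rng, 400)
    seq_b = _random_seq(rng, 400)
    ann = make_annotation(
        [
            dict(locus_id="LA", isoforms={"LA.1": [(100, 500)]}, sequence=seq_a),
            dict(locus_id="LB", isoforms={"LB.1": [(700, 1100)]}, sequence=seq_b),
            # identical paralog pair of LA at a different locus
            dict(locus_id="LP", isoforms={"LP.1": [(1300, 1700)]}, sequence=seq_a),
        ],
        chrom_len=2000,
    )
    return ann, aligner.build_index(ann, k=20)


def test_index_position_count():
    ann = make_annotation(
        [dict(locus_id="L1", isoforms={"L1.1": [(10, 310)]})], chrom_len=400
    )
    idx = aligner.build_index(ann, k=20)
    assert idx.n_positions("L1.1") == 300 - 20 + 1


def test_index_rejects_bad_k(toy_index):
    ann, _ = toy_index
    with pytest.raises(ValueError):
        aligner.build_index(ann, k=7)
    with pytest.raises(ValueError):
        aligner.build_index(ann, k=401)


def test_index_entries_verified_by_substring(toy_index):
    """Every indexed (isoform, offset) entry equals the sequence substring."""
    ann, idx = toy_index
    rng = np.random.default_rng(1)
    for iso in ann.isoforms:
        seq = ann.spliced_sequence(iso.isoform_id)
        for off in rng.integers(0, len(seq) - idx.k + 1, size=20):
            kmer = seq[off : off + idx.k]
            hits = idx.lookup(kmer)
            assert (iso.isoform_id, int(off)) in hits


def test_identical_paralogs_duplicate_entries(toy_index):
    ann, idx = toy_index
    seq = ann.spliced_sequence("LA.1")
    hits = idx.lookup(seq[50:70])
    names = {h[0] for h in hits}
    assert {"LA.1", "LP.1"} <= names


def test_exact_read_single_unique_alignment(toy_index):
    ann, idx = toy_index
    read = ann.spliced_sequence("LB.1")[100:201]
    recs = aligner.align_read(read, idx, aligner.AlignmentParams(mode="global"))
    assert len(recs) == 1
    assert recs[0].isoform_id == "LB.1"
    assert recs[0].mismatches == 0
    assert recs[0].t_start == 101 and recs[0].t_end == 201


def test_paralog_read_multiplicity_two(toy_index):
    ann, idx = toy_index
    read = ann.spliced_sequence("LA.1")[10:111]
    recs = aligner.align_read(read, idx, aligner.AlignmentParams(mode="global"))
    assert len(recs) == 2
    assert {r.isoform_id for r in recs} == {"LA.1", "LP.1"}
    assert all(r.multiplicity == 2 for r in recs)


def test_polya_tail_read_global_fails_local_clips(toy_index):
    ann, idx = toy_index
    core = ann.spliced_sequence("LB.1")[329:400]  # last 71 bases
    read = core + b"A" * 30
    assert aligner.align_read(read, idx, aligner.AlignmentParams(mode="global")) == []
    recs = aligner.align_read(read, idx, aligner.AlignmentParams(mode="local"))
    assert recs, "local mode should rescue the poly-A read"
    best = recs[0]
    assert best.isoform_id == "LB.1"
    assert best.clip_right == 30 and best.clip_left == 0
    assert best.mismatches == 0


def test_mismatch_limit_respected(toy_index):
    ann, idx = toy_index
    read = bytearray(ann.spliced_sequence("LB.1")[100:201])
    positions = [5, 20, 35, 50, 65, 80]  # 6 substitutions > max 5
    for p in positions:
        read[p] = ord("A") if read[p] != ord("A") else ord("C")
    assert aligner.align_read(bytes(read), idx, aligner.AlignmentParams()) == []
    read2 = bytearray(ann.spliced_sequence("LB.1")[100:201])
    for p in positions[:3]:
        read2[p] = ord("A") if read2[p] != ord("A") else ord("C")
    recs = aligner.align_read(bytes(read2), idx, aligner.AlignmentParams())
    assert recs and recs[0].mismatches == 3


def test_align_library_nh_consistency_and_sam(small_annotation, tmp_path):
    import pysam

    ann = small_annotation
    base = baseline_profile(ann)
    (rs,) = simulate_library([base], ann, LibraryParams(), 1500, seed=11)
    index = aligner.build_index(ann, 20)
    table = aligner.align_library(rs, index, aligner.AlignmentParams(mode="global"),
                                  sam_path=tmp_path / "out.sam")
    # NH equals the record count per read
    counts = np.bincount(table.read_idx, minlength=table.n_reads)
    assert np.array_equal(table.nh, counts[table.read_idx])
    # SAM parses with pysam and NH tags match
    seen = {}
    with pysam.AlignmentFile(str(tmp_path / "out.sam")) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            seen[rec.query_name] = seen.get(rec.query_name, 0) + 1
            assert rec.get_tag("NH") >= 1
    aligned_reads = int(table.aligned_mask().sum())
    assert len(seen) == aligned_reads
    # round trip back into a table
    back = aligner.AlignmentTable.from_sam(tmp_path / "out.sam", ann)
    assert back.read_idx.size == table.read_idx.size


def test_empty_fastq_yields_valid_sam(toy_index, tmp_path):
    import pysam

    ann, idx = toy_index
    fq = tmp_path / "empty.fastq"
    fq.write_text("")
    table = aligner.align_library(fq, idx, aligner.AlignmentParams(),
                                  sam_path=tmp_path / "empty.sam")
    assert table.read_idx.size == 0
    with pysam.AlignmentFile(str(tmp_path / "empty.sam")) as fh:
        assert len(list(fh)) == 0
        assert len(fh.header["SQ"]) == len(ann.isoforms)


def test_classification_true_alignments_all_correct(small_annotation):
    ann = small_annotation
    base = baseline_profile(ann)
    (rs,) = simulate_library(
        [base], ann, LibraryParams(error_rate=0.0), 2000, seed=12
    )
    index = aligner.build_index(ann, 20)
    table = aligner.align_batch(rs.seqs, index, aligner.AlignmentParams())
    correct, rates = aligner.classify_alignments(table, rs, ann)
    assert correct.mean() == 1.0
    covered = rates[rates["n_reads"] > 0]
    assert (covered["rate"] == 1.0).all()


def test_sibling_isoform_alignment_counts_as_correct():
    """A read aligned to a span-overlapping sibling of its source is correct."""
    rng = np.random.default_rng(13)
    seq = _random_seq(rng, 900)
    ann = make_annotation(
        [
            dict(
                locus_id="L1",
                isoforms={
                    "L1.1": [(0, 300), (500, 800)],
                    "L1.2": [(0, 300)],
                },
                sequence=seq,
            )
        ],
        chrom_len=1000,
    )
    idx = aligner.build_index(ann, 20)
    # read from the shared exon: aligns to both isoforms, same locus
    read = ann.spliced_sequence("L1.2")[50:151]
    table = aligner.align_batch(
        np.frombuffer(read, np.uint8)[None, :], idx, aligner.AlignmentParams()
    )
    assert len(set(table.iso_idx.tolist())) == 2

    class _Truth:
        iso_idx = np.array([0])  # generated by L1.1
        read_ids = ["r0"]

    table.read_ids = ["r0"]
    correct, _ = aligner.classify_alignments(table, _Truth(), ann)
    assert correct[0]


def test_diverged_paralog_misalignment_is_incorrect():
    """A read forced onto a paralog at another locus is classified wrong."""
    rng = np.random.default_rng(14)
    seq_a = _random_seq(rng, 400)
    ann = make_annotation(
        [
            dict(locus_id="LA", isoforms={"LA.1": [(0, 400)]}, sequence=seq_a),
            dict(locus_id="LP", isoforms={"LP.1": [(600, 1000)]}, sequence=seq_a),
        ],
        chrom_len=1200,
    )
    idx = aligner.build_index(ann, 20)
    read = ann.spliced_sequence("LA.1")[100:201]
    table = aligner.align_batch(
        np.frombuffer(read, np.uint8)[None, :], idx, aligner.AlignmentParams()
    )
    # keep only the alignment to the paralog locus
    keep = table.iso_idx == 1
    table.iso_idx = table.iso_idx[keep]
    table.read_idx = table.read_idx[keep]
    table.t_start = table.t_start[keep]
    table.mismatches = table.mismatches[keep]
    table.clip_left = table.clip_left[keep]
    table.clip_right = table.clip_right[keep]

    class _Truth:
        iso_idx = np.array([0])
        read_ids = ["r0"]

    table.read_ids = ["r0"]
    correct, _ = aligner.classify_alignments(table, _Truth(), ann)
    assert not correct[0]


def test_local_rate_at_least_global(small_annotation):
    """Clipping only adds alignments: local >= global per isoform."""
    ann = small_annotation
    base = baseline_profile(ann)
    (rs,) = simulate_library(
        [base], ann, LibraryParams(regime="tss_polya"), 4000, seed=15
    )
    index = aligner.build_index(ann, 20)
    t_g = aligner.align_batch(rs.seqs, index, aligner.AlignmentParams(mode="global"))
    t_l = aligner.align_batch(rs.seqs, index, aligner.AlignmentParams(mode="local"))
    _, r_g = aligner.classify_alignments(t_g, rs, ann)
    _, r_l = aligner.classify_alignments(t_l, rs, ann)
    covered = r_g["n_reads"] > 0
    assert np.all(
        r_l.loc[covered, "rate"].values >= r_g.loc[covered, "rate"].values - 1e-12
    )


def test_raising_multimap_cap_never_reduces_alignments(small_annotation):
    ann = small_annotation
    base = baseline_profile(ann)
    (rs,) = simulate_library([base], ann, LibraryParams(), 2000, seed=16)
    index = aligner.build_index(ann, 20)
    t10 = aligner.align_batch(
        rs.seqs, index, aligner.AlignmentParams(max_alignments=10)
    )
    t30 = aligner.align_batch(
        rs.seqs, index, aligner.AlignmentParams(max_alignments=30)
    )
    assert t30.read_idx.size >= t10.read_idx.size
    assert t30.aligned_mask().sum() >= t10.aligned_mask().sum()
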