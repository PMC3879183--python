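"""Exon-bin flattening, bin counting, and the two switch tests."""

import numpy as np
import pandas as pd
import pytest

from rnaseqbench import aligner, isoform_switch
from rnaseqbench.synthetic_data import (
    AnnotationConfig,
    build_annotation,
)
from tests.conftest import make_annotation


def test_flatten_single_exon_single_isoform():
    ann = make_annotation(
        [dict(locus_id="L1", isoforms={"L1.1": [(100, 300)]})], chrom_len=400
    )
    bins, excluded = isoform_switch.flatten_bins(ann)
    assert excluded == []
    assert len(bins) == 1
    assert bins[0].interval == (100, 300)
    assert bins[0].isoforms == {"L1.1"}


def test_flatten_shared_plus_private_exon():
    ann = make_annotation(
        [
            dict(
                locus_id="L1",
                isoforms={
                    "L1.1": [(100, 300)],
                    "L1.2": [(100, 300), (400, 500)],
                },
            )
        ],
        chrom_len=600,
    )
    bins, _ = isoform_switch.flatten_bins(ann)
    assert [(b.interval, set(b.isoforms)) for b in bins] == [
        ((100, 300), {"L1.1", "L1.2"}),
        ((400, 500), {"L1.2"}),
    ]


def test_flatten_staggered_exons():
    ann = make_annotation(
        [
            dict(
                locus_id="L1",
                isoforms={
                    "L1.1": [(100, 300), (350, 400)],
                    "L1.2": [(200, 400)],
                },
            )
        ],
        chrom_len=600,
    )
    bins, _ = isoform_switch.flatten_bins(ann)
    got = [(b.interval, set(b.isoforms)) for b in bins]
    assert ((100, 200), {"L1.1"}) in got
    assert ((200, 300), {"L1.1", "L1.2"}) in got
    assert ((300, 350), {"L1.2"}) in got


def test_flatten_invariants_on_random_annotations():
    """Disjointness, exon coverage, and membership constancy per locus."""
    for seed in range(8):
        cfg = AnnotationConfig(
            n_loci=25, n_paralog_pairs=2, n_identical_pairs=0,
            n_paralog_triples=0, n_retro_fragments=2,
            isoform_number_probs={2: 0.5, 3: 0.5},
        )
        ann = build_annotation(cfg, seed=100 + seed)
        bins, _ = isoform_switch.flatten_bins(ann)
        by_locus = {}
        for b in bins:
            by_locus.setdefault(b.locus_id, []).append(b)
        for locus in ann.loci:
            lb = sorted(by_locus[locus.locus_id], key=lambda b: b.interval)
            # pairwise disjoint
            for b1, b2 in zip(lb[:-1], lb[1:]):
                assert b1.interval[1] <= b2.interval[0]
            # union of bins equals union of exons
            exon_pos = set()
            for iso in ann.isoforms_of_locus(locus.locus_id):
                for s, e in iso.exons:
                    exon_pos.update(range(s, e))
            bin_pos = set()
            for b in lb:
                bin_pos.update(range(*b.interval))
            assert bin_pos == exon_pos
            # membership constant across each bin
            for b in lb:
                for iso in ann.isoforms_of_locus(locus.locus_id):
                    covers = [
                        s <= b.interval[0] and b.interval[1] <= e
                        for s, e in iso.exons
                    ]
                    partial = any(
                        s < b.interval[1] and b.interval[0] < e
                        for s, e in iso.exons
                    )
                    assert any(covers) == partial  # no partial overlap


def test_multi_locus_symbol_excluded_and_logged():
    ann = make_annotation(
        [
            dict(locus_id="L1", symbols=("GX",), isoforms={"L1.1": [(0, 300)]}),
            dict(locus_id="L2", symbols=("GX",), isoforms={"L2.1": [(500, 800)]}),
            dict(locus_id="L3", symbols=("GY",), isoforms={"L3.1": [(900, 1200)]}),
        ],
        chrom_len=1500,
    )
    bins, excluded = isoform_switch.flatten_bins(ann)
    assert set(excluded) == {"L1", "L2"}
    assert {b.locus_id for b in bins} == {"L3"}


def _aln_table(ann, rows, L=101):
    rows = sorted(rows)
    arr = np.array(rows, dtype=np.int64).reshape(-1, 3)
    return aligner.AlignmentTable(
        read_idx=arr[:, 0], iso_idx=arr[:, 1], t_start=arr[:, 2],
        mismatches=np.zeros(len(rows), np.int32),
        clip_left=np.zeros(len(rows), np.int32),
        clip_right=np.zeros(len(rows), np.int32),
        n_reads=int(arr[:, 0].max()) + 1, read_length=L, annotation=ann,
    )


@pytest.fixture()
def staggered_ann():
    return make_annotation(
        [
            dict(
                locus_id="L1",
                isoforms={
                    "L1.1": [(0, 300)],
                    "L1.2": [(0, 300), (400, 600)],
                },
            )
        ],
        chrom_len=800,
    )


def test_count_bins_read_inside_one_bin(staggered_ann):
    bins, _ = isoform_switch.flatten_bins(staggered_ann)
    table = _aln_table(staggered_ann, [(0, 0, 10)])
    counts = isoform_switch.count_bins(table, bins, staggered_ann)
    assert counts.tolist() == [1, 0]


def test_count_bins_boundary_spanning_read(staggered_ann):
    bins, _ = isoform_switch.flatten_bins(staggered_ann)
    # read on isoform 2 crossing the junction at transcript position 300
    table = _aln_table(staggered_ann, [(0, 1, 250)])
    counts = isoform_switch.count_bins(table, bins, staggered_ann)
    assert counts.tolist() == [1, 1]


def test_count_bins_excludes_multi_locus_reads():
    ann = make_annotation(
        [
            dict(locus_id="L1", isoforms={"L1.1": [(0, 300)]}),
            dict(locus_id="L2", isoforms={"L2.1": [(500, 800)]}),
        ],
        chrom_len=1000,
    )
    bins, _ = isoform_switch.flatten_bins(ann)
    table = _aln_table(ann, [(0, 0, 10), (0, 1, 10)])
    counts = isoform_switch.count_bins(table, bins, ann)
    assert counts.sum() == 0


def test_bin_usage_null_and_switch_signal(staggered_ann):
    """Isoform-specific bins separate single-isoform conditions; shared not."""
    bins, _ = isoform_switch.flatten_bins(staggered_ann)
    rng = np.random.default_rng(9)
    # condition A: only isoform 1 (shared bin only); B: only isoform 2
    def sample(shared, private):
        return pd.Series(
            [rng.poisson(shared), rng.poisson(private)],
            index=[b.bin_id for b in bins],
        )

    cols = {
        "a_r1": sample(200, 0), "a_r2": sample(200, 0), "a_r3": sample(200, 0),
        "b_r1": sample(200, 130), "b_r2": sample(200, 130), "b_r3": sample(200, 130),
    }
    frame = pd.DataFrame(cols)
    res = isoform_switch.bin_usage_test(
        frame, bins, ["a", "a", "a", "b", "b", "b"]
    )
    private_bin = [b.bin_id for b in bins if len(b.isoforms) == 1][0]
    assert res.loc[private_bin, "p"] < 0.01
    gene = isoform_switch.gene_switch_test(res)
    assert gene.loc["L1", "p"] < 0.02


def test_bin_usage_rescaling_removes_expression_change(staggered_ann):
    """A 2-fold DE gene with constant usage shows no usage signal."""
    bins, _ = isoform_switch.flatten_bins(staggered_ann)
    rng = np.random.default_rng(10)

    def sample(mu):
        return pd.Series(
            [rng.poisson(2 * mu), rng.poisson(mu)],
            index=[b.bin_id for b in bins],
        )

    cols = {f"a_r{i}": sample(150) for i in (1, 2, 3)}
    cols.update({f"b_r{i}": sample(300) for i in (1, 2, 3)})  # 2x expression
    res = isoform_switch.bin_usage_test(
        pd.DataFrame(cols), bins, ["a"] * 3 + ["b"] * 3
    )
    assert (res["p"] > 0.05).all()


def test_gene_switch_test_bonferroni_min_p():
    frame = pd.DataFrame(
        dict(
            locus_id=["L1", "L1", "L1", "L2", "L3"],
            p=[0.001, 0.5, 0.9, 0.2, 1.0],
            tested=[True, True, True, True, False],
        ),
        index=[f"b{i}" for i in range(5)],
    )
    res = isoform_switch.gene_switch_test(frame)
    assert res.loc["L1", "p"] == pytest.approx(0.003)
    assert res.loc["L2", "p"] == pytest.approx(0.2)
    assert res.loc["L3", "p"] == 1.0 and not res.loc["L3", "tested"]


def test_fraction_switch_identical_profiles_p_one(staggered_ann):
    tpm = pd.DataFrame(
        {f"a_r{i}": [500.0, 500.0] for i in (1, 2, 3)}
        | {f"b_r{i}": [500.0, 500.0] for i in (1, 2, 3)}
    )
    res = isoform_switch.fraction_switch_test(
        tpm, ["a"] * 3 + ["b"] * 3, staggered_ann, seed=1
    )
    assert res.loc["L1", "p"] == 1.0


def test_fraction_switch_perfect_separation_floor(staggered_ann):
    """(1,0) vs (0,1) with 3v3 replicates: p = 1/10, stat = sqrt(log 2)."""
    tpm = pd.DataFrame(
        {f"a_r{i}": [1000.0, 0.0] for i in (1, 2, 3)}
        | {f"b_r{i}": [0.0, 1000.0] for i in (1, 2, 3)}
    )
    res = isoform_switch.fraction_switch_test(
        tpm, ["a"] * 3 + ["b"] * 3, staggered_ann, seed=1
    )
    assert res.loc["L1", "p"] == pytest.approx(0.1)
    from rnaseqbench.isoform_switch import _js_stat

    assert _js_stat(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(
        np.sqrt(np.log(2)), rel=1e-9
    )


def test_fraction_switch_label_swap_symmetric(staggered_ann):
    rng = np.random.default_rng(11)
    tpm = pd.DataFrame(
        rng.uniform(10, 100, size=(2, 6)),
        columns=[f"{g}_r{i}" for g in "ab" for i in (1, 2, 3)],
    )
    p1 = isoform_switch.fraction_switch_test(
        tpm, ["a"] * 3 + ["b"] * 3, staggered_ann, seed=2
    ).loc["L1", "p"]
    p2 = isoform_switch.fraction_switch_test(
        tpm, ["b"] * 3 + ["a"] * 3, staggered_ann, seed=2
    ).loc["L1", "p"]
    assert p1 == p2


def test_fraction_switch_single_isoform_untested():
    ann = make_annotation(
        [dict(locus_id="L1", isoforms={"L1.1": [(0, 300)]})], chrom_len=400
    )
    tpm = pd.DataFrame({f"a_r{i}": [100.0] for i in (1, 2, 3)}
                       | {f"b_r{i}": [100.0] for i in (1, 2, 3)})
    res = isoform_switch.fraction_switch_test(
        tpm, ["a"] * 3 + ["b"] * 3, ann, seed=1
    )
    assert len(res) == 0  # single-isoform loci are not tested


def test_end_clipping_reduces_boundary_spanning_bin_increments(small_annotation):
    """Local (clip-tolerant) alignment of modified-transcript reads crosses
    fewer bin boundaries than global alignment of the same reads."""
    from rnaseqbench import aligner
    from rnaseqbench.synthetic_data import (
        LibraryParams, baseline_profile, simulate_library,
    )

    ann = small_annotation
    base = baseline_profile(ann)
    (rs,) = simulate_library(
        [base], ann, LibraryParams(regime="tss_polya"), 6000, seed=24
    )
    index = aligner.build_index(ann, 20)
    bins, _ = isoform_switch.flatten_bins(ann)
    t_g = aligner.align_batch(rs.seqs, index, aligner.AlignmentParams(mode="global"))
    t_l = aligner.align_batch(rs.seqs, index, aligner.AlignmentParams(mode="local"))
    # same reads for both modes: those aligned under global (subset of local)
    keep = t_g.aligned_mask()
    c_g = isoform_switch.count_bins(t_g, bins, ann).sum()
    # restrict local table to reads aligned in both modes
    sel = keep[t_l.read_idx]
    t_l_sub = aligner.AlignmentTable(
        read_idx=t_l.read_idx[sel], iso_idx=t_l.iso_idx[sel],
        t_start=t_l.t_start[sel], mismatches=t_l.mismatches[sel],
        clip_left=t_l.clip_left[sel], clip_right=t_l.clip_right[sel],
        n_reads=t_l.n_reads, read_length=t_l.read_length, annotation=ann,
    )
    c_l = isoform_switch.count_bins(t_l_sub, bins, ann).sum()
    assert c_l <= c_g


from hypothesis import given, settings, strategies as st


@st.composite
def _locus_isoforms(draw):
    """Random exon structures for one locus sharing the first exon."""
    n_exons = draw(st.integers(2, 6))
    exons = []
    pos = 10
    for _ in range(n_exons):
        length = draw(st.integers(30, 120))
        exons.append((pos, pos + length))
        pos += length + draw(st.integers(20, 80))
    n_iso = draw(st.integers(2, 4))
    isoforms = {}
    for k in range(n_iso):
        kept = [exons[0]]
        for s, e in exons[1:]:
            choice = draw(st.integers(0, 2))
            if choice == 0:
                continue
            if choice == 2 and e - s >= 60:
                e = s + draw(st.integers(30, e - s - 1))
            kept.append((s, e))
        isoforms[f"L1.{k + 1}"] = kept
    return isoforms


@settings(max_examples=60, deadline=None, derandomize=True)
@given(_locus_isoforms())
def test_flatten_invariants_property(isoforms):
    """Bins are disjoint, cover exactly the exons, with constant membership."""
    ann = make_annotation(
        [dict(locus_id="L1", isoforms=isoforms)], chrom_len=3000
    )
    bins, _ = isoform_switch.flatten_bins(ann)
    lb = sorted(bins, key=lambda b: b.interval)
    for b1, b2 in zip(lb[:-1], lb[1:]):
        assert b1.interval[1] <= b2.interval[0]
    exon_pos = {
        p for iso in ann.isoforms for s, e in iso.exons for p in range(s, e)
    }
    bin_pos = {p for b in lb for p in range(*b.interval)}
    assert bin_pos == exon_pos
    for b in lb:
        members = {
            iso.isoform_id
            for iso in ann.isoforms
            if any(s <= b.interval[0] and b.interval[1] <= e for s, e in iso.exons)
        }
        assert members == set(b.isoforms)
        for iso in ann.isoforms:
            partial = any(
                s < b.interval[1] and b.interval[0] < e for s, e in iso.exons
            )
            assert partial == (iso.isoform_id in members)
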