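"""Counting policies, effective lengths, EM and Gibbs abundance estimation."""

import numpy as np
import pytest

from rnaseqbench import aligner, quantify
from rnaseqbench.synthetic_data import LibraryParams
from tests.conftest import make_annotation


def _table(ann, rows, n_reads=None, L=101):
    """Build an AlignmentTable from (read_idx, iso_idx, t_start) rows."""
    rows = sorted(rows)
    arr = np.array(rows, dtype=np.int64).reshape(-1, 3)
    n = int(arr[:, 0].max()) + 1 if len(rows) else 0
    return aligner.AlignmentTable(
        read_idx=arr[:, 0],
        iso_idx=arr[:, 1],
        t_start=arr[:, 2],
        mismatches=np.zeros(len(rows), np.int32),
        clip_left=np.zeros(len(rows), np.int32),
        clip_right=np.zeros(len(rows), np.int32),
        n_reads=n_reads or n,
        read_length=L,
        annotation=ann,
    )


@pytest.fixture(scope="module")
def counting_ann():
    return make_annotation(
        [
            dict(locus_id="L1", symbols=("GA",), isoforms={"L1.1": [(0, 1000)]}),
            dict(locus_id="L2", symbols=("GB",), isoforms={"L2.1": [(1200, 2200)]}),
            dict(locus_id="L3", symbols=("GC",), isoforms={"L3.1": [(2400, 3400)]}),
            dict(
                locus_id="L4",
                symbols=("GD", "GE"),  # overlapping gene symbols
                isoforms={"L4.1": [(3600, 4600)]},
            ),
        ],
        chrom_len=5000,
    )


def test_count_modes_unique_read(counting_ann):
    table = _table(counting_ann, [(0, 0, 10)])
    for mode in quantify.COUNT_MODES:
        counts = quantify.count_genes(table, counting_ann, mode)
        assert counts["GA"] == 1.0, mode


def test_count_modes_paralog_ambiguity(counting_ann):
    # one read hitting two loci (GA and GB)
    table = _table(counting_ann, [(0, 0, 10), (0, 1, 10)])
    all_c = quantify.count_genes(table, counting_ann, "count_all")
    unq = quantify.count_genes(table, counting_ann, "count_unique")
    frac = quantify.count_genes(table, counting_ann, "fractional")
    assert all_c["GA"] == 1.0 and all_c["GB"] == 1.0
    assert unq["GA"] == 0.0 and unq["GB"] == 0.0
    assert frac["GA"] == 0.5 and frac["GB"] == 0.5


def test_overlapping_symbol_locus_discarded_by_unique(counting_ann):
    table = _table(counting_ann, [(0, 3, 10)])
    unq = quantify.count_genes(table, counting_ann, "count_unique")
    assert unq["GD"] == 0.0 and unq["GE"] == 0.0
    all_c = quantify.count_genes(table, counting_ann, "count_all")
    assert all_c["GD"] == 1.0 and all_c["GE"] == 1.0


def test_unknown_mode_rejected(counting_ann):
    with pytest.raises(ValueError):
        quantify.count_genes(_table(counting_ann, [(0, 0, 1)]), counting_ann, "x")


@pytest.mark.parametrize(
    "l,mu,expected", [(1000, 200, 801), (150, 200, 1), (200, 200, 1)]
)
def test_effective_length_formula(l, mu, expected):
    ann = make_annotation(
        [dict(locus_id="L1", isoforms={"L1.1": [(0, l)]})], chrom_len=l + 10
    )
    le = quantify.effective_lengths(ann, LibraryParams(mu_frag=mu))
    assert le[0] == expected


def test_em_unique_reads_recovered_exactly(counting_ann):
    rows = [(i, 0, 5) for i in range(7)] + [(i, 2, 5) for i in range(7, 10)]
    table = _table(counting_ann, rows)
    l_eff = quantify.effective_lengths(counting_ann, LibraryParams())
    ab = quantify.em_abundance(table, counting_ann, l_eff)
    assert ab.frame["expected_count"].iloc[0] == pytest.approx(7, abs=1e-9)
    assert ab.frame["expected_count"].iloc[2] == pytest.approx(3, abs=1e-9)
    assert ab.n_assigned == 10
    ab.validate()


def test_em_symmetric_split_for_identical_twins(counting_ann):
    # n fully ambiguous reads between two equal-length isoforms
    n = 40
    rows = [(i, 0, 5) for i in range(n)] + [(i, 1, 5) for i in range(n)]
    table = _table(counting_ann, rows)
    l_eff = quantify.effective_lengths(counting_ann, LibraryParams())
    ab = quantify.em_abundance(table, counting_ann, l_eff)
    assert ab.frame["expected_count"].iloc[0] == pytest.approx(n / 2, abs=1e-6)
    assert ab.frame["expected_count"].iloc[1] == pytest.approx(n / 2, abs=1e-6)


def _grid_search_mle(class_counts, class_members, l_eff, step=1e-3):
    """Brute-force likelihood maximization over the theta grid (3 isoforms)."""
    best, best_ll = None, -np.inf
    grid = np.arange(0, 1 + step / 2, step)
    for a in grid:
        for b in np.arange(0, 1 - a + step / 2, step):
            c = 1 - a - b
            alpha = np.array([a, b, max(c, 0.0)])
            ll = 0.0
            ok = True
            for members, count in zip(class_members, class_counts):
                s = sum(alpha[m] / l_eff[m] for m in members)
                if s <= 0:
                    ok = False
                    break
                ll += count * np.log(s)
            if ok and ll > best_ll:
                best_ll, best = ll, alpha
    return best


def test_em_matches_grid_search_oracle(counting_ann):
    """EM agrees with brute-force likelihood maximization on a 3-isoform toy."""
    members = [(0,), (0, 1), (1, 2), (2,), (0, 1, 2)]
    counts = [30, 22, 18, 12, 25]
    rows = []
    r = 0
    for mem, cnt in zip(members, counts):
        for _ in range(cnt):
            rows.extend((r, m, 5) for m in mem)
            r += 1
    table = _table(counting_ann, rows)
    l_eff = quantify.effective_lengths(counting_ann, LibraryParams())
    ab = quantify.em_abundance(table, counting_ann, l_eff, tol=1e-12)
    alpha_em = (ab.frame["expected_count"].values / ab.n_assigned)[:3]
    alpha_grid = _grid_search_mle(counts, members, l_eff[:3])
    np.testing.assert_allclose(alpha_em, alpha_grid, atol=2e-3)


def test_em_conservation_and_tpm_sum(small_annotation):
    from rnaseqbench.synthetic_data import baseline_profile, simulate_library

    base = baseline_profile(small_annotation)
    (rs,) = simulate_library([base], small_annotation, LibraryParams(), 3000, seed=20)
    index = aligner.build_index(small_annotation, 20)
    table = aligner.align_batch(rs.seqs, index, aligner.AlignmentParams())
    l_eff = quantify.effective_lengths(small_annotation, LibraryParams())
    ab = quantify.em_abundance(table, small_annotation, l_eff)
    assert ab.frame["expected_count"].sum() == pytest.approx(ab.n_assigned, rel=1e-9)
    assert ab.frame["tpm"].sum() == pytest.approx(1e6, abs=1e-3)
    ab.validate()


def test_gibbs_unique_reads_immovable(counting_ann):
    rows = [(i, 0, 5) for i in range(9)] + [(9, 2, 5)]
    table = _table(counting_ann, rows)
    l_eff = quantify.effective_lengths(counting_ann, LibraryParams())
    post = quantify.gibbs_posterior(table, counting_ann, l_eff, 30, 10, seed=1)
    assert post[0] == pytest.approx(9.0)
    assert post[2] == pytest.approx(1.0)


def test_gibbs_symmetric_posterior_for_identical_pair(counting_ann):
    n = 1000
    rows = []
    for i in range(n):
        rows.extend([(i, 0, 5), (i, 1, 5)])
    table = _table(counting_ann, rows)
    l_eff = quantify.effective_lengths(counting_ann, LibraryParams())
    post = quantify.gibbs_posterior(table, counting_ann, l_eff, 200, 50, seed=2)
    # the flat posterior over splits has sd ~ n/sqrt(12); 3 SDs is generous
    sd = n / np.sqrt(12)
    assert abs(post[0] - n / 2) < 3 * sd
    assert post[0] + post[1] == pytest.approx(n)


def test_gibbs_silent_sibling_gets_positive_posterior_count():
    """Posterior counts shrink toward the locus mean: no hard zeros."""
    ann = make_annotation(
        [
            dict(
                locus_id="L1",
                isoforms={"L1.1": [(0, 1000)], "L1.2": [(0, 1000)]},
            )
        ],
        chrom_len=1200,
    )
    rows = []
    for i in range(200):  # all reads ambiguous between the twin isoforms
        rows.extend([(i, 0, 5), (i, 1, 5)])
    table = _table(ann, rows)
    l_eff = quantify.effective_lengths(ann, LibraryParams())
    post = quantify.gibbs_posterior(table, ann, l_eff, 100, 30, seed=3)
    assert post[1] > 0  # the truly silent sibling is not reported as zero


def test_fragment_feasibility_filter_drops_ungeneratable_alignments(counting_ann):
    # alignment starting beyond l_eff cannot come from a full-size fragment
    l_eff = quantify.effective_lengths(counting_ann, LibraryParams())
    rows = [(0, 0, int(l_eff[0]) + 10), (0, 1, 5)]
    table = _table(counting_ann, rows)
    ab = quantify.em_abundance(table, counting_ann, l_eff)
    assert ab.frame["expected_count"].iloc[1] == pytest.approx(1.0)
    assert ab.frame["expected_count"].iloc[0] == pytest.approx(0.0)
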