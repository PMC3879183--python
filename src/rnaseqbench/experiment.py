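"""End-to-end experiment orchestration.

The default experiment reproduces the study design at desk scale: a
~500-locus annotation with duplicated loci and overlapping gene symbols,
equal baseline molar abundance per isoform, three library regimes for the
bias and alignment analyses, an 11-condition x 3-replicate two-fold
differential-expression design, and isoform-switch conditions that move each
multi-isoform locus's output onto a single isoform.  Every stage feeds the
evaluation module, producing bias summaries, alignment-rate summaries,
counting-accuracy fractions, DE ROC/AUC and per-gene detectability, and
switch-detection ROC/FPR analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aligner, diffexp, evaluate, isoform_switch, quantify
from .synthetic_data import (
    AnnotationConfig,
    LibraryParams,
    baseline_profile,
    build_annotation,
    make_condition_designs,
    make_switch_designs,
    nominal_fpkm,
    realize_replicate,
    simulate_library,
)
from .synthetic_data.designs import ConditionDesign, switch_truth


@dataclass
class ExperimentScale:
    """Problem sizes for the default experiment (desk scale)."""

    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    n_reads_bias: int = 100_000
    n_reads_counting: int = 200_000
    n_counting_samples: int = 3
    n_reads_de: int = 100_000
    n_reads_switch: int = 100_000
    n_chunks: int = 10
    n_replicates: int = 3
    sigma: float = 0.25
    k: int = 20
    gibbs_samples: int = 50
    gibbs_burn_in: int = 20

    @classmethod
    def smoke(cls) -> "ExperimentScale":
        cfg = AnnotationConfig(
            n_loci=60,
            n_paralog_pairs=4,
            n_paralog_triples=1,
            n_retro_fragments=3,
            overlapping_symbol_fraction=0.06,
        )
        return cls(
            annotation=cfg,
            n_reads_bias=20_000,
            n_reads_counting=30_000,
            n_counting_samples=2,
            n_reads_de=8_000,
            n_reads_switch=8_000,
            gibbs_samples=30,
            gibbs_burn_in=10,
        )


def _align_samples(read_sets, index, params):
    return [aligner.align_batch(rs.seqs, index, params) for rs in read_sets]


# ---------------------------------------------------------------------------
# stage 1: library bias
# ---------------------------------------------------------------------------

def library_bias_experiment(
    annotation, scale: ExperimentScale, seed: int
) -> dict:
    """Truth-count FPKM bias per regime (no alignment involved).

    Observed FPKM uses the effective length (the number of fragment start
    positions), the honest per-read normalizer for a fragment library;
    nominal FPKM is implied by molar fraction and annotated length.
    """
    base = baseline_profile(annotation)
    nominal = nominal_fpkm(base, annotation)
    lengths = annotation.sequence_arrays()["lengths"]
    out = {"per_regime": {}, "summary": {}}
    for i, regime in enumerate(("uniform", "coverage_bias", "tss_polya")):
        params = LibraryParams(regime=regime)
        (rs,) = simulate_library(
            [base], annotation, params, scale.n_reads_bias, seed + 11 * i + 1
        )
        counts = rs.truth_counts()
        l_eff = quantify.effective_lengths(annotation, params)
        observed = 1e9 * counts / (l_eff * scale.n_reads_bias)
        bias = evaluate.bias_factors(observed, nominal)
        bias["length"] = lengths
        bias["isoform_id"] = [iso.isoform_id for iso in annotation.isoforms]
        bias["truth_reads"] = counts
        out["per_regime"][regime] = bias
        mu = params.mu_frag
        near_peak = (lengths >= 0.9 * mu) & (lengths <= 1.1 * mu)
        long = lengths > 5000
        log2b = bias["log2B"].values
        out["summary"][regime] = dict(
            fraction_within2=evaluate.fraction_within_factor(observed, nominal),
            median_log2B_near_peak=float(np.nanmedian(log2b[near_peak]))
            if near_peak.any()
            else np.nan,
            median_log2B_long=float(np.nanmedian(log2b[long])) if long.any() else np.nan,
        )
    return out


# ---------------------------------------------------------------------------
# stage 2: alignment
# ---------------------------------------------------------------------------

def alignment_experiment(annotation, scale: ExperimentScale, seed: int) -> dict:
    """Per-isoform alignment rates: regimes x (global, local) modes."""
    base = baseline_profile(annotation)
    index = aligner.build_index(annotation, scale.k)
    out = {"rates": {}, "summary": {}}
    samples = {}
    for i, regime in enumerate(("uniform", "tss_polya")):
        params = LibraryParams(regime=regime)
        (rs,) = simulate_library(
            [base], annotation, params, scale.n_reads_bias, seed + 101 * i + 7
        )
        samples[regime] = rs
    for regime, modes in (("uniform", ("global",)), ("tss_polya", ("global", "local"))):
        rs = samples[regime]
        for mode in modes:
            ap = aligner.AlignmentParams(mode=mode)
            table = aligner.align_batch(rs.seqs, index, ap)
            _, rates = aligner.classify_alignments(table, rs, annotation)
            key = f"{regime}_{mode}"
            out["rates"][key] = rates
            covered = rates[rates["n_reads"] > 0]
            out["summary"][key] = dict(
                median_rate=float(covered["rate"].median()),
                overall_rate=float(covered["n_correct"].sum() / covered["n_reads"].sum()),
            )
    # length dependence under transcript modifications (global mode)
    rates = out["rates"]["tss_polya_global"]
    covered = rates[rates["n_reads"] > 0].sort_values("length")
    n = len(covered)
    q = n // 5
    out["summary"]["tss_polya_global"]["short_quintile_median_rate"] = float(
        covered["rate"].iloc[:q].median()
    )
    out["summary"]["tss_polya_global"]["long_quintile_median_rate"] = float(
        covered["rate"].iloc[-q:].median()
    )
    return out


# ---------------------------------------------------------------------------
# stage 3: counting accuracy
# ---------------------------------------------------------------------------

def _truth_gene_counts(read_set, annotation) -> pd.Series:
    """Reads sequenced per gene symbol (locus reads credited to each symbol)."""
    locus_counts = np.bincount(
        annotation.sequence_arrays()["locus_idx"][read_set.iso_idx],
        minlength=len(annotation.loci),
    )
    out = {}
    for i, locus in enumerate(annotation.loci):
        for sym in locus.gene_symbols:
            out[sym] = out.get(sym, 0) + int(locus_counts[i])
    return pd.Series(out)


def gene_estimates_for_sample(
    table, annotation, l_eff, gibbs_samples, gibbs_burn_in, seed
) -> dict[str, pd.Series]:
    """Gene-symbol counts for one sample under all five policies."""
    est = {
        mode: quantify.count_genes(table, annotation, mode)
        for mode in quantify.COUNT_MODES
    }
    ab = quantify.em_abundance(table, annotation, l_eff)
    est["em_expected"] = ab.gene_counts(annotation)
    post = quantify.gibbs_posterior(
        table, annotation, l_eff,
        n_samples=gibbs_samples, burn_in=gibbs_burn_in, seed=seed,
    )
    ab.frame["posterior_count"] = post
    est["gibbs_posterior"] = ab.gene_counts(annotation, column="posterior_count")
    est["_abundance"] = ab
    return est


def counting_experiment(annotation, scale: ExperimentScale, seed: int) -> dict:
    """Within-factor-two accuracy of gene expression counts per policy.

    Uses a few differential-condition samples (so paralog family members are
    expressed unequally), uniform regime, global transcriptome alignment.
    """
    designs = make_condition_designs(annotation, scale.n_chunks)
    base = baseline_profile(annotation)
    params = LibraryParams(regime="uniform")
    profiles = [
        realize_replicate(designs[i], base, scale.sigma, seed + 211 * i + 3, annotation)
        for i in range(scale.n_counting_samples)
    ]
    read_sets = simulate_library(
        profiles, annotation, params, scale.n_reads_counting, seed + 37
    )
    index = aligner.build_index(annotation, scale.k)
    tables = _align_samples(read_sets, index, aligner.AlignmentParams(mode="global"))
    l_eff = quantify.effective_lengths(annotation, params)
    modes = list(quantify.COUNT_MODES) + ["em_expected", "gibbs_posterior"]
    fractions = {m: [] for m in modes}
    per_gene_bias = []
    for si, (rs, table) in enumerate(zip(read_sets, tables)):
        truth = _truth_gene_counts(rs, annotation)
        est = gene_estimates_for_sample(
            table, annotation, l_eff, scale.gibbs_samples, scale.gibbs_burn_in,
            seed + 53 * si,
        )
        covered = truth[truth >= 1]
        for m in modes:
            e = est[m].reindex(covered.index).fillna(0.0)
            fractions[m].append(
                evaluate.fraction_within_factor(e.values, covered.values)
            )
            per_gene_bias.append(
                pd.DataFrame(
                    dict(
                        gene=covered.index,
                        sample=rs.sample_id,
                        mode=m,
                        observed=e.values,
                        truth=covered.values,
                    )
                )
            )
    return dict(
        fraction_within2={m: float(np.mean(v)) for m, v in fractions.items()},
        per_gene=pd.concat(per_gene_bias, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# stage 4: differential expression
# ---------------------------------------------------------------------------

def de_experiment(annotation, scale: ExperimentScale, seed: int) -> dict:
    """11-condition x 3-replicate DE experiment over all count policies."""
    designs = make_condition_designs(annotation, scale.n_chunks)
    base = baseline_profile(annotation)
    params = LibraryParams(regime="uniform")
    profiles = []
    for d_i, design in enumerate(designs):
        for rep in range(1, scale.n_replicates + 1):
            profiles.append(
                realize_replicate(
                    design, base, scale.sigma,
                    seed + 1009 * d_i + 17 * rep, annotation, replicate=rep,
                )
            )
    read_sets = simulate_library(
        profiles, annotation, params, scale.n_reads_de, seed + 101
    )
    index = aligner.build_index(annotation, scale.k)
    tables = _align_samples(read_sets, index, aligner.AlignmentParams(mode="global"))
    l_eff = quantify.effective_lengths(annotation, params)

    modes = list(quantify.COUNT_MODES) + ["em_expected", "gibbs_posterior"]
    columns: dict[str, dict[str, pd.Series]] = {m: {} for m in modes}
    for si, (rs, table) in enumerate(zip(read_sets, tables)):
        est = gene_estimates_for_sample(
            table, annotation, l_eff, scale.gibbs_samples, scale.gibbs_burn_in,
            seed + 79 * si + 5,
        )
        for m in modes:
            columns[m][rs.sample_id] = est[m]

    results = {}
    auc = {}
    undetectable = {}
    for m in modes:
        ct = quantify.CountTable.from_samples("gene", m, columns[m])
        res = diffexp.run_de(ct, designs, annotation)
        results[m] = res
        labels = res["truth"].values
        auc[m] = dict(
            exact=evaluate.roc(evaluate.score_from_pvalues(res["p_exact"]), labels).auc,
            logratio=evaluate.roc(np.abs(res["log2ratio"]), labels).auc,
            ttest=evaluate.roc(evaluate.score_from_pvalues(res["p_ttest"]), labels).auc,
        )
        res["score_exact"] = evaluate.score_from_pvalues(res["p_exact"])
        pg = evaluate.per_gene_auc(res, "score_exact")
        assessable = pg[pg["assessable"]]
        undetectable[m] = dict(
            n_undetectable=int((~assessable["detectable"]).sum()),
            undetectable_genes=list(assessable.index[~assessable["detectable"]]),
            per_gene=pg,
        )
    return dict(results=results, auc=auc, undetectable=undetectable, designs=designs)


# ---------------------------------------------------------------------------
# stage 5: isoform switching
# ---------------------------------------------------------------------------

def switch_experiment(annotation, scale: ExperimentScale, seed: int) -> dict:
    """Switch conditions vs matched no-switch null: FPR and detection ROC."""
    all_iso = ConditionDesign(condition_id="cond00", fold={})
    null_rep = ConditionDesign(condition_id="null00", fold={})
    switches = make_switch_designs(annotation, [1, 2, 3])
    designs = [all_iso, null_rep] + switches

    params = LibraryParams(regime="uniform")
    base = baseline_profile(annotation)
    profiles = []
    for d_i, design in enumerate(designs):
        for rep in range(1, scale.n_replicates + 1):
            profiles.append(
                realize_replicate(
                    design, base, scale.sigma,
                    seed + 2003 * d_i + 23 * rep, annotation, replicate=rep,
                )
            )
    read_sets = simulate_library(
        profiles, annotation, params, scale.n_reads_switch, seed + 397
    )
    index = aligner.build_index(annotation, scale.k)
    tables = _align_samples(read_sets, index, aligner.AlignmentParams(mode="global"))
    l_eff = quantify.effective_lengths(annotation, params)

    # gene-level counts and TPM pseudo-counts per sample
    count_cols: dict[str, pd.Series] = {}
    tpm_cols: dict[str, pd.Series] = {}
    iso_tpm_cols: dict[str, pd.Series] = {}
    assigned = {}
    for rs, table in zip(read_sets, tables):
        count_cols[rs.sample_id] = quantify.count_genes(table, annotation, "count_all")
        ab = quantify.em_abundance(table, annotation, l_eff)
        tpm_cols[rs.sample_id] = ab.gene_counts(annotation, column="tpm")
        iso_tpm_cols[rs.sample_id] = ab.frame["tpm"]
        assigned[rs.sample_id] = ab.n_assigned
    count_table = quantify.CountTable.from_samples("gene", "count_all", count_cols)
    gene_tpm = pd.DataFrame(tpm_cols)
    pseudo = diffexp.tpm_pseudocounts(gene_tpm, pd.Series(assigned))
    pseudo_table = quantify.CountTable(level="gene", mode="tpm_pseudo", frame=pseudo)

    comparisons = [("cond00", "null00")] + [
        ("cond00", s.condition_id) for s in switches
    ]
    de_counts = diffexp.run_de(count_table, designs, annotation, comparisons)
    de_tpm = diffexp.run_de(pseudo_table, designs, annotation, comparisons)

    thresholds = (0.001, 0.01, 0.05)

    def fprs(res: pd.DataFrame) -> dict:
        out = {}
        for ca, cb in comparisons:
            sub = res[(res["cond_a"] == ca) & (res["cond_b"] == cb)]
            tag = "noswitch" if cb == "null00" else cb
            out[tag] = evaluate.fpr_analysis(sub, thresholds)["fpr"].to_dict()
        switch_tags = [t for t in out if t.startswith("switch")]
        out["switch_mean"] = {
            thr: float(np.mean([out[t][thr] for t in switch_tags]))
            for thr in thresholds
        }
        return out

    fpr = dict(counts=fprs(de_counts), tpm=fprs(de_tpm))

    # --- switch detection: exon-bin and isoform-fraction methods ----------
    bins, excluded = isoform_switch.flatten_bins(annotation)
    sample_ids = [rs.sample_id for rs in read_sets]
    bin_cols = {
        sid: isoform_switch.count_bins(tbl, bins, annotation)
        for sid, tbl in zip(sample_ids, tables)
    }
    bin_counts = pd.DataFrame(bin_cols)
    iso_tpm = pd.DataFrame(iso_tpm_cols)

    def samples_of(cond):
        return [s for s in sample_ids if s.rsplit("_r", 1)[0] == cond]

    instances = []
    for ca, cb in comparisons:
        cols = samples_of(ca) + samples_of(cb)
        groups = [ca] * len(samples_of(ca)) + [cb] * len(samples_of(cb))
        bp = isoform_switch.bin_usage_test(bin_counts[cols], bins, groups)
        gene_bin = isoform_switch.gene_switch_test(bp)
        frac = isoform_switch.fraction_switch_test(
            iso_tpm[cols], groups, annotation, n_perm=99, seed=seed + 7
        )
        if cb == "null00":
            truth = set()
        else:
            design_b = next(d for d in designs if d.condition_id == cb)
            truth = switch_truth(all_iso, design_b, annotation)
        for locus in annotation.loci:
            if len(annotation.isoforms_of_locus(locus.locus_id)) < 2:
                continue
            if locus.locus_id in excluded:
                continue
            pb = gene_bin["p"].get(locus.locus_id, 1.0)
            pf = frac["p"].get(locus.locus_id, 1.0)
            instances.append(
                (locus.locus_id, cb, pb, pf, locus.locus_id in truth)
            )
    inst = pd.DataFrame(
        instances, columns=["locus_id", "comparison", "p_bin", "p_fraction", "truth"]
    )
    labels = inst["truth"].values
    auc_bin = evaluate.roc(evaluate.score_from_pvalues(inst["p_bin"]), labels).auc
    auc_frac = evaluate.roc(
        evaluate.score_from_pvalues(inst["p_fraction"]), labels
    ).auc
    return dict(
        fpr=fpr,
        auc=dict(bin=auc_bin, fraction=auc_frac),
        instances=inst,
        de_counts=de_counts,
        de_tpm=de_tpm,
        excluded_loci=excluded,
    )


# ---------------------------------------------------------------------------
# the default experiment
# ---------------------------------------------------------------------------

def run_default_experiment(
    seed: int = 1, scale: ExperimentScale | None = None
) -> dict:
    """Run every stage of the default synthetic experiment.

    Returns a nested dict of stage outputs plus a flat ``metrics`` dict with
    the headline quantities.
    """
    scale = scale or ExperimentScale()
    annotation = build_annotation(scale.annotation, seed)
    bias = library_bias_experiment(annotation, scale, seed + 10_000)
    align = alignment_experiment(annotation, scale, seed + 20_000)
    counting = counting_experiment(annotation, scale, seed + 30_000)
    de = de_experiment(annotation, scale, seed + 40_000)
    switch = switch_experiment(annotation, scale, seed + 50_000)

    m: dict[str, float] = {}
    m["library_fraction_within2_uniform"] = bias["summary"]["uniform"][
        "fraction_within2"
    ]
    m["library_fraction_within2_coverage_bias"] = bias["summary"]["coverage_bias"][
        "fraction_within2"
    ]
    m["library_peak_median_log2_bias"] = bias["summary"]["coverage_bias"][
        "median_log2B_near_peak"
    ]
    m["library_long_median_log2_bias"] = bias["summary"]["coverage_bias"][
        "median_log2B_long"
    ]
    m["alignment_median_rate_uniform_global"] = align["summary"]["uniform_global"][
        "median_rate"
    ]
    m["alignment_median_rate_tss_polya_global"] = align["summary"][
        "tss_polya_global"
    ]["median_rate"]
    m["alignment_median_rate_tss_polya_local"] = align["summary"][
        "tss_polya_local"
    ]["median_rate"]
    m["alignment_short_quintile_median_rate"] = align["summary"][
        "tss_polya_global"
    ]["short_quintile_median_rate"]
    m["alignment_long_quintile_median_rate"] = align["summary"][
        "tss_polya_global"
    ]["long_quintile_median_rate"]
    for mode, frac in counting["fraction_within2"].items():
        m[f"counting_within2_{mode}"] = frac
    for mode in ("count_all", "count_unique", "em_expected"):
        for score in ("exact", "logratio", "ttest"):
            m[f"de_auc_{score}_{mode}"] = de["auc"][mode][score]
    for mode, u in de["undetectable"].items():
        m[f"de_undetectable_{mode}"] = u["n_undetectable"]
    for thr in (0.001, 0.01, 0.05):
        m[f"fpr_counts_switch_{thr}"] = switch["fpr"]["counts"]["switch_mean"][thr]
        m[f"fpr_counts_noswitch_{thr}"] = switch["fpr"]["counts"]["noswitch"][thr]
        m[f"fpr_tpm_switch_{thr}"] = switch["fpr"]["tpm"]["switch_mean"][thr]
        m[f"fpr_tpm_noswitch_{thr}"] = switch["fpr"]["tpm"]["noswitch"][thr]
    m["switch_auc_bin"] = switch["auc"]["bin"]
    m["switch_auc_fraction"] = switch["auc"]["fraction"]
    return dict(
        annotation=annotation,
        bias=bias,
        alignment=align,
        counting=counting,
        de=de,
        switch=switch,
        metrics=m,
    )
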