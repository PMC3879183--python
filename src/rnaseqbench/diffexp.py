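"""Differential expression testing.

Counts are modelled as negative binomial with a single common dispersion phi
(variance = mu + phi * mu^2) estimated by maximizing the conditional
log-likelihood of the within-group counts given their group totals -- valid
here because all simulated samples have identical library sizes, so no depth
normalization is applied.  Differential expression between two conditions is
scored three ways: the exact conditional NB test on the group sums, the
log-ratio effect size, and a pooled-variance t-test on log2 expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy import stats

from .quantify import CountTable
from .synthetic_data.annotation import AnnotationSet
from .synthetic_data.designs import ConditionDesign, de_truth


@dataclass
class Dispersion:
    """Common NB dispersion phi >= 0; phi = 0 degenerates to Poisson."""

    phi: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi) or self.phi < 0:
            raise ValueError("phi must be finite and >= 0")


def _group_cond_loglik(y: np.ndarray, r: float) -> float:
    """Conditional NB log-likelihood of counts given their row totals.

    ``y`` is genes x replicates for one group; equal library sizes assumed.
    """
    n = y.shape[1]
    t = y.sum(axis=1)
    ll = (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        - gammaln(y + 1).sum(axis=1)
        - gammaln(t + n * r)
        + gammaln(n * r)
        + gammaln(t + 1)
    )
    return float(ll[t > 0].sum())


def estimate_common_dispersion(
    counts: pd.DataFrame | CountTable, groups
) -> Dispersion:
    """Maximize the summed conditional log-likelihood over log phi in [1e-6, 5].

    ``groups`` assigns each sample column to a condition; groups with fewer
    than two replicates carry no information and are skipped.
    """
    frame = counts.frame if isinstance(counts, CountTable) else counts
    groups = np.asarray(groups)
    y_groups = []
    for g in pd.unique(groups):
        cols = np.flatnonzero(groups == g)
        if cols.size >= 2:
            y_groups.append(np.rint(frame.values[:, cols]).astype(np.float64))
    if not y_groups:
        raise ValueError("conditional likelihood needs >= 2 replicates in a group")

    def neg_ll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        return -sum(_group_cond_loglik(y, r) for y in y_groups)

    res = minimize_scalar(
        neg_ll,
        bounds=(np.log(1e-6), np.log(5.0)),
        method="bounded",
        options=dict(xatol=1e-6),
    )
    return Dispersion(phi=float(np.exp(res.x)))


def nb_exact_test(y_a, y_b, phi: float) -> float:
    """Exact conditional NB test on the group sums.

    Under H0 the group sums are NB with sizes n_A/phi and n_B/phi; the
    p-value sums, over all splits (a, t-a) of the conditioned total t, the
    conditional probabilities no larger than the observed one.  phi -> 0
    reduces to the exact binomial test.  Symmetric in group swap; p in (0,1].
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    y_a = np.asarray(y_a, dtype=np.int64)
    y_b = np.asarray(y_b, dtype=np.int64)
    s_a = int(y_a.sum())
    t = s_a + int(y_b.sum())
    if t == 0:
        return 1.0
    n_a, n_b = y_a.size, y_b.size
    a = np.arange(t + 1)
    if phi < 1e-12:  # Poisson limit: conditional is binomial
        logp = stats.binom.logpmf(a, t, n_a / (n_a + n_b))
    else:
        r = 1.0 / phi
        logp = (
            gammaln(a + n_a * r)
            - gammaln(a + 1)
            + gammaln(t - a + n_b * r)
            - gammaln(t - a + 1)
        )
        logp = logp - logsumexp(logp)
    obs = logp[s_a]
    # include all splits with probability <= P(observed), with slack for ties
    p = np.exp(logsumexp(logp[logp <= obs + 1e-10]))
    return float(min(1.0, max(p, np.exp(obs))))


def log_ratio(mean_a: float, mean_b: float, pseudo: float = 0.5) -> float:
    """log2((mean_a + pseudo) / (mean_b + pseudo)); ranked by absolute value."""
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    return float(np.log2((mean_a + pseudo) / (mean_b + pseudo)))


def t_test_log(counts_a, counts_b) -> float:
    """Pooled-variance two-sample t-test on log2(count + 0.5), two-sided."""
    la = np.log2(np.asarray(counts_a, float) + 0.5)
    lb = np.log2(np.asarray(counts_b, float) + 0.5)
    if la.size < 2 or lb.size < 2:
        raise ValueError("need >= 2 replicates per group")
    va = la.var(ddof=1)
    vb = lb.var(ddof=1)
    if va + vb == 0:
        return 1.0
    res = stats.ttest_ind(la, lb, equal_var=True)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _condition_of_sample(sample_id: str) -> str:
    if "_r" not in sample_id:
        raise ValueError(f"sample id {sample_id!r} does not encode a condition")
    return sample_id.rsplit("_r", 1)[0]


def run_de(
    table: CountTable,
    designs: list[ConditionDesign],
    annotation: AnnotationSet,
    comparisons: list[tuple[str, str]] | None = None,
    dispersion: Dispersion | None = None,
) -> pd.DataFrame:
    """Score every gene in every pairwise condition comparison.

    Sample columns must be named ``<condition_id>_r<replicate>``.  Truth
    labels mark genes whose fold factor differs between the two conditions.
    Genes with zero counts in both groups carry p = 1 and effect 0.
    """
    frame = table.frame
    sample_cond = np.array([_condition_of_sample(c) for c in frame.columns])
    design_by_id = {d.condition_id: d for d in designs}
    if comparisons is None:
        conds = [d.condition_id for d in designs if d.condition_id in set(sample_cond)]
        comparisons = list(combinations(conds, 2))
    for ca, cb in comparisons:
        if ca == cb:
            raise ValueError(f"comparison of {ca!r} with itself: groups overlap")
    if dispersion is None:
        dispersion = estimate_common_dispersion(frame, sample_cond)

    symbol_loci = annotation.symbol_to_loci
    genes = list(frame.index)
    rows = []
    for ca, cb in comparisons:
        ya = np.rint(frame.values[:, sample_cond == ca]).astype(np.int64)
        yb = np.rint(frame.values[:, sample_cond == cb]).astype(np.int64)
        if ya.shape[1] == 0 or yb.shape[1] == 0:
            raise ValueError(f"comparison {ca} vs {cb}: missing samples")
        raw_a = frame.values[:, sample_cond == ca]
        raw_b = frame.values[:, sample_cond == cb]
        truth_loci = de_truth(design_by_id[ca], design_by_id[cb], annotation)
        mean_a = raw_a.mean(axis=1)
        mean_b = raw_b.mean(axis=1)
        # vectorized pooled t on log counts
        la = np.log2(raw_a + 0.5)
        lb = np.log2(raw_b + 0.5)
        with np.errstate(invalid="ignore", divide="ignore"):
            tt = stats.ttest_ind(la, lb, axis=1, equal_var=True)
        p_t = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
        zero_var = (la.var(axis=1, ddof=1) + lb.var(axis=1, ddof=1)) == 0
        p_t = np.where(zero_var, 1.0, p_t)
        for gi, gene in enumerate(genes):
            p_e = nb_exact_test(ya[gi], yb[gi], dispersion.phi)
            lr = log_ratio(mean_a[gi], mean_b[gi])
            truth = any(l in truth_loci for l in symbol_loci.get(gene, []))
            rows.append(
                (
                    gene, ca, cb, p_e, float(p_t[gi]), lr,
                    mean_a[gi], mean_b[gi], truth,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "cond_a", "cond_b", "p_exact", "p_ttest", "log2ratio",
            "mean_a", "mean_b", "truth",
        ],
    )


def tpm_pseudocounts(tpm: pd.DataFrame, assigned_reads: pd.Series) -> pd.DataFrame:
    """Convert TPM to pseudo-counts (TPM * assigned / 1e6) per sample.

    This re-expresses length-normalized abundance on the count scale so the
    exact test applies; isoform switching without abundance change leaves
    these invariant, unlike raw gene counts.
    """
    return tpm.mul(assigned_reads, axis=1) / 1e6
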