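"""Evaluation surfaces: bias factors, ROC/AUC, detectability, FPR analyses.

Scores are oriented so that larger means "more confidently positive":
p-values enter ROC analysis as 1 - p, effect sizes as their absolute value.
A gene is called "not detectable" by a method when its per-gene AUC -- built
over the condition comparisons the gene appears in -- falls below 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n: int
    n_pos: int


def roc(scores, labels) -> RocResult:
    """ROC curve and AUC over a threshold sweep (higher score = positive call).

    Ties contribute diagonal segments, so the trapezoid AUC equals the
    Mann-Whitney statistic with half credit for ties.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # threshold at each distinct score
    distinct = np.concatenate([s[1:] != s[:-1], [True]])
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, n=labels.size, n_pos=n_pos)


def score_from_pvalues(p) -> np.ndarray:
    """Rank orientation for p-values (1 - p, larger = more significant)."""
    return 1.0 - np.asarray(p, float)


def mann_whitney_auc(scores, labels, tie_credit: float = 0.5) -> float:
    """Pairwise-comparison AUC with configurable credit for tied pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = np.sort(scores[~labels])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    lo = np.searchsorted(neg, pos, "left").sum()
    hi = np.searchsorted(neg, pos, "right").sum()
    return float((lo + tie_credit * (hi - lo)) / (pos.size * neg.size))


def per_gene_auc(
    results: pd.DataFrame,
    score_col: str,
    gene_col: str = "gene",
    label_col: str = "truth",
    threshold: float = 0.1,
    tie_credit: float = 0.0,
) -> pd.DataFrame:
    """Per-gene AUC across comparisons and the detectability flag.

    For each gene, the instances are the comparisons it appears in; a gene
    lacking either a truly-positive or a truly-negative comparison is
    flagged not assessable.  Tied score pairs earn no credit by default: a
    method that cannot rank any of the gene's positive comparisons above its
    null ones (e.g. a gene with structurally zero counts, where every
    p-value is 1) scores AUC 0 and is flagged not detectable, rather than
    drifting to 0.5 on pure ties.
    """
    rows = []
    for gene, sub in results.groupby(gene_col, sort=False):
        labels = sub[label_col].values.astype(bool)
        if labels.all() or not labels.any():
            rows.append((gene, np.nan, False, False))
            continue
        auc = mann_whitney_auc(sub[score_col].values, labels, tie_credit)
        rows.append((gene, auc, auc >= threshold, True))
    return pd.DataFrame(
        rows, columns=["gene", "auc", "detectable", "assessable"]
    ).set_index("gene")


def bias_factors(observed, nominal) -> pd.DataFrame:
    """Bias factor B = observed / nominal per feature, with log2 B.

    log2 B is stored unclipped; clipping to [-2, 2] is applied only by
    :func:`clipped_log2` for density displays.
    """
    observed = np.asarray(observed, float)
    nominal = np.asarray(nominal, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = observed / nominal
        log2b = np.log2(b)
    return pd.DataFrame(dict(observed=observed, nominal=nominal, B=b, log2B=log2b))


def clipped_log2(log2b: np.ndarray, lo: float = -2.0, hi: float = 2.0) -> np.ndarray:
    return np.clip(np.asarray(log2b, float), lo, hi)


def fraction_within_factor(observed, nominal, window: float = 2.0) -> float:
    """Fraction of features whose bias factor lies within ``window``-fold."""
    b = bias_factors(observed, nominal)["log2B"].values
    ok = np.abs(b) <= np.log2(window)
    return float(np.mean(np.where(np.isfinite(b), ok, False)))


def length_binned_median(
    lengths, log2b, edges=(0, 300, 500, 1000, 2000, 5000, np.inf)
) -> pd.DataFrame:
    """Median log2 bias per isoform-length bin (bias-vs-length summaries)."""
    lengths = np.asarray(lengths, float)
    log2b = np.asarray(log2b, float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (lengths >= lo) & (lengths < hi) & np.isfinite(log2b)
        rows.append((lo, hi, m.sum(), np.median(log2b[m]) if m.any() else np.nan))
    return pd.DataFrame(rows, columns=["lo", "hi", "n", "median_log2B"])


def bias_summary(
    records: pd.DataFrame, window: float = 2.0
) -> pd.DataFrame:
    """Per-stage summary of bias records (columns: stage, observed, nominal)."""
    rows = []
    for stage, sub in records.groupby("stage", sort=False):
        frac = fraction_within_factor(sub["observed"], sub["nominal"], window)
        log2b = bias_factors(sub["observed"], sub["nominal"])["log2B"].values
        finite = log2b[np.isfinite(log2b)]
        rows.append(
            (
                stage,
                len(sub),
                frac,
                float(np.median(finite)) if finite.size else np.nan,
                float(np.std(clipped_log2(finite))) if finite.size else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["stage", "n", "fraction_within", "median_log2B", "sd_clipped_log2B"],
    ).set_index("stage")


def fpr_analysis(
    results: pd.DataFrame,
    thresholds=(0.001, 0.01, 0.05),
    p_col: str = "p_exact",
    null_col: str = "truth",
) -> pd.DataFrame:
    """False positive rate among true-null genes at each p-value threshold."""
    null = ~results[null_col].values.astype(bool)
    p = results[p_col].values
    rows = [
        (thr, int(null.sum()), float(np.mean(p[null] <= thr))) for thr in thresholds
    ]
    return pd.DataFrame(rows, columns=["threshold", "n_null", "fpr"]).set_index(
        "threshold"
    )


def plot_roc(results: dict[str, RocResult], path) -> None:
    """ROC curves for several methods on one axis (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in results.items():
        ax.plot(r.fpr, r.tpr, label=f"{name} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bias_density(records: pd.DataFrame, path) -> None:
    """Clipped-log2 bias densities per stage (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(-2.1, 2.1, 300)
    for stage, sub in records.groupby("stage", sort=False):
        log2b = bias_factors(sub["observed"], sub["nominal"])["log2B"].values
        vals = clipped_log2(log2b[np.isfinite(log2b)])
        if vals.size < 2:
            continue
        bw = 0.05
        dens = np.exp(
            -0.5 * ((grid[:, None] - vals[None, :]) / bw) ** 2
        ).sum(axis=1) / (vals.size * bw * np.sqrt(2 * np.pi))
        ax.plot(grid, dens, label=stage)
    ax.set_xlabel("log2 bias factor (clipped to [-2, 2])")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stage_report(
    per_isoform: dict[str, pd.Series | np.ndarray] | None = None,
    per_gene: dict[str, pd.Series | np.ndarray] | None = None,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-isoform and per-gene statistics tables.

    Missing upstream stages simply contribute no columns.  When ``out_dir``
    is given the tables are written as TSV.
    """
    iso_frame = pd.DataFrame(per_isoform or {})
    gene_frame = pd.DataFrame(per_gene or {})
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iso_frame.to_csv(out / "per_isoform.tsv", sep="\t", index_label="isoform_id")
        gene_frame.to_csv(out / "per_gene.tsv", sep="\t", index_label="gene")
    return iso_frame, gene_frame
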