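"""Gene- and isoform-level abundance estimation under competing paradigms.

Multi-reads (reads whose alignments are compatible with several loci) are the
central ambiguity.  Overlap counting resolves them by policy: ``count_all``
credits every hit locus, ``count_unique`` discards ambiguous reads (and reads
over loci carrying two overlapping gene symbols), ``fractional`` splits the
read reciprocally to its locus multiplicity.  The isoform-abundance model
resolves them statistically: an EM on the standard mixture (read given
isoform uniform over the effective length) yields expected read counts,
TPM and FPKM; a collapsed Gibbs sampler over read assignments with a flat
Dirichlet prior yields posterior mean counts.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .aligner import AlignmentTable
from .synthetic_data.annotation import AnnotationSet
from .synthetic_data.library import LibraryParams

COUNT_MODES = ("count_all", "count_unique", "fractional")
ABUNDANCE_MODES = ("em_expected", "gibbs_posterior")


@dataclass
class CountTable:
    """Feature x sample count matrix with its counting-mode tag."""

    level: str  # gene | isoform | exon_bin
    mode: str
    frame: pd.DataFrame  # features x samples

    def __post_init__(self) -> None:
        if (self.frame.values < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_samples(cls, level: str, mode: str, columns: dict[str, pd.Series]):
        return cls(level=level, mode=mode, frame=pd.DataFrame(columns))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# level={self.level} mode={self.mode}\n")
            self.frame.to_csv(fh, sep="\t", index_label="feature_id")


def effective_lengths(
    annotation: AnnotationSet, params: LibraryParams
) -> np.ndarray:
    """l_eff = max(1, l - mu_frag + 1): fragment start positions per isoform."""
    lengths = annotation.sequence_arrays()["lengths"]
    return np.maximum(1, lengths - params.mu_frag + 1).astype(np.float64)


def _read_locus_pairs(table: AlignmentTable):
    """Distinct (read, locus) pairs plus per-read locus multiplicity."""
    locus = table.annotation.sequence_arrays()["locus_idx"][table.iso_idx]
    n_loci = len(table.annotation.loci)
    key = table.read_idx * n_loci + locus
    uniq = np.unique(key)
    pr = uniq // n_loci
    pl = uniq % n_loci
    mult = np.bincount(pr, minlength=table.n_reads)
    return pr, pl, mult


def count_genes(
    table: AlignmentTable, annotation: AnnotationSet, mode: str
) -> pd.Series:
    """Per-gene-symbol counts for one sample under one multi-read policy."""
    if mode not in COUNT_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    pr, pl, mult = _read_locus_pairs(table)
    n_loci = len(annotation.loci)
    n_symbols_per_locus = np.array(
        [len(l.gene_symbols) for l in annotation.loci]
    )
    if mode == "count_all":
        locus_counts = np.bincount(pl, minlength=n_loci).astype(float)
    elif mode == "fractional":
        locus_counts = np.bincount(
            pl, weights=1.0 / mult[pr], minlength=n_loci
        )
    else:  # count_unique: single locus AND that locus has one gene symbol
        keep = (mult[pr] == 1) & (n_symbols_per_locus[pl] == 1)
        locus_counts = np.bincount(pl[keep], minlength=n_loci).astype(float)
    out = {}
    for i, locus in enumerate(annotation.loci):
        for sym in locus.gene_symbols:
            out[sym] = out.get(sym, 0.0) + locus_counts[i]
    return pd.Series(out, name="count")


@dataclass
class AbundanceEstimate:
    """Per-isoform abundance: transcript fractions, counts, TPM, FPKM."""

    frame: pd.DataFrame  # isoform_id-indexed: theta, l_eff, expected_count, tpm, fpkm
    n_assigned: int
    converged: bool = True
    n_iterations: int = 0

    def validate(self) -> None:
        th = self.frame["theta"].values
        if (th < -1e-12).any() or abs(th.sum() - 1.0) > 1e-8:
            raise ValueError("theta is not a distribution")
        if abs(self.frame["tpm"].sum() - 1e6) > 1e-3:
            raise ValueError("TPM does not sum to 1e6")
        if abs(self.frame["expected_count"].sum() - self.n_assigned) > 1e-6 * max(
            1, self.n_assigned
        ):
            raise ValueError("expected counts do not sum to assigned reads")

    def gene_counts(self, annotation: AnnotationSet, column: str = "expected_count"):
        """Sum the isoform values of each locus for every gene symbol."""
        locus_vals: dict[str, float] = {}
        for iso_id, val in self.frame[column].items():
            lid = annotation.isoform_by_id[iso_id].locus_id
            locus_vals[lid] = locus_vals.get(lid, 0.0) + float(val)
        out = {}
        for locus in annotation.loci:
            for sym in locus.gene_symbols:
                out[sym] = out.get(sym, 0.0) + locus_vals.get(locus.locus_id, 0.0)
        return pd.Series(out, name=column)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="isoform_id")


def _compatibility_classes(table: AlignmentTable, l_eff: np.ndarray | None = None):
    """Group reads by their compatible-isoform set.

    When ``l_eff`` is given, alignments starting beyond an isoform's last
    possible fragment start (t_start >= l_eff) are not generatively feasible
    under the fragment model and are dropped from the read's compatibility
    set -- without this, sequence windows that are alignable but not
    generatable (e.g. the tail of a truncated retrocopy) soak up reads they
    cannot have produced.

    Returns (class_iso, class_offsets, class_count): ragged membership arrays
    plus the number of reads per class.
    """
    n_iso = len(table.annotation.isoforms)
    read_idx, iso_idx = table.read_idx, table.iso_idx
    if l_eff is not None:
        feasible = table.t_start < l_eff[iso_idx]
        read_idx, iso_idx = read_idx[feasible], iso_idx[feasible]
    # distinct (read, iso) pairs, already lex-sorted by construction
    key = read_idx * n_iso + iso_idx
    uniq = np.unique(key)
    pr = (uniq // n_iso).astype(np.int64)
    pi = (uniq % n_iso).astype(np.int64)
    # split per read
    first = np.concatenate([[True], pr[1:] != pr[:-1]])
    starts = np.flatnonzero(first)
    ends = np.concatenate([starts[1:], [pr.size]])
    classes: dict[bytes, int] = {}
    class_iso_parts: list[np.ndarray] = []
    class_count: list[int] = []
    for s, e in zip(starts, ends):
        sig = pi[s:e].tobytes()
        ci = classes.get(sig)
        if ci is None:
            classes[sig] = len(class_count)
            class_iso_parts.append(pi[s:e])
            class_count.append(1)
        else:
            class_count[ci] += 1
    sizes = np.array([p.size for p in class_iso_parts], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    class_iso = (
        np.concatenate(class_iso_parts) if class_iso_parts else np.zeros(0, np.int64)
    )
    return class_iso, offsets, np.array(class_count, dtype=np.int64)


def em_abundance(
    table: AlignmentTable,
    annotation: AnnotationSet,
    l_eff: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> AbundanceEstimate:
    """EM on the standard isoform mixture model.

    The responsibility of isoform i for a read is proportional to
    alpha_i / l_eff,i over the read's compatible isoforms, where alpha is the
    per-isoform read fraction; the reported theta is the transcript fraction
    (alpha / l_eff, normalized), TPM = 1e6 * theta, and
    FPKM = 1e9 * c_i / (l_eff,i * assigned reads).
    """
    n_iso = len(annotation.isoforms)
    class_iso, offsets, class_count = _compatibility_classes(table, l_eff)
    n_assigned = int(class_count.sum())
    if n_assigned == 0:
        frame = _abundance_frame(annotation, np.zeros(n_iso), l_eff, np.zeros(n_iso), 0)
        return AbundanceEstimate(frame=frame, n_assigned=0)
    inv_leff = 1.0 / l_eff
    seg = np.repeat(np.arange(class_count.size), np.diff(offsets))
    alpha = np.full(n_iso, 1.0 / n_iso)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = alpha[class_iso] * inv_leff[class_iso]
        denom = np.bincount(seg, weights=w, minlength=class_count.size)
        resp = w * (class_count[seg] / denom[seg])
        c = np.bincount(class_iso, weights=resp, minlength=n_iso)
        alpha_new = c / n_assigned
        delta = np.abs(alpha_new - alpha).max()
        alpha = alpha_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations")
    c = alpha * n_assigned
    frame = _abundance_frame(annotation, alpha, l_eff, c, n_assigned)
    return AbundanceEstimate(
        frame=frame, n_assigned=n_assigned, converged=converged, n_iterations=it
    )


def _abundance_frame(annotation, alpha, l_eff, counts, n_assigned):
    dens = alpha / l_eff
    total = dens.sum()
    theta = dens / total if total > 0 else dens
    tpm = 1e6 * theta
    fpkm = (
        1e9 * counts / (l_eff * n_assigned) if n_assigned > 0 else np.zeros_like(counts)
    )
    return pd.DataFrame(
        dict(
            theta=theta,
            l_eff=l_eff,
            expected_count=counts,
            tpm=tpm,
            fpkm=fpkm,
        ),
        index=pd.Index(
            [iso.isoform_id for iso in annotation.isoforms], name="isoform_id"
        ),
    )


def gibbs_posterior(
    table: AlignmentTable,
    annotation: AnnotationSet,
    l_eff: np.ndarray,
    n_samples: int = 100,
    burn_in: int = 50,
    alpha: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Posterior mean read counts from collapsed Gibbs over read assignments.

    Each sweep resamples every ambiguous read's assignment z_r with
    probability proportional to (n_i,-r + alpha) / l_eff,i over its
    compatible isoforms; the posterior mean count is the average of the
    per-isoform assignment counts over the retained sweeps.
    """
    if not n_samples > burn_in >= 0:
        raise ValueError("need n_samples > burn_in >= 0")
    n_iso = len(annotation.isoforms)
    class_iso, offsets, class_count = _compatibility_classes(table, l_eff)
    if class_count.size == 0:
        return np.zeros(n_iso)
    rng = np.random.default_rng(seed)
    sizes = np.diff(offsets)
    # unique reads are immovable; expand ambiguous reads individually
    counts = np.zeros(n_iso)
    uniq_cls = sizes == 1
    for ci in np.flatnonzero(uniq_cls):
        counts[class_iso[offsets[ci]]] += class_count[ci]
    sup_parts: list[np.ndarray] = []
    amb_sizes: list[int] = []
    for ci in np.flatnonzero(~uniq_cls):
        sup = class_iso[offsets[ci] : offsets[ci + 1]]
        for _ in range(int(class_count[ci])):
            sup_parts.append(sup)
            amb_sizes.append(sup.size)
    n_amb = len(sup_parts)
    inv_leff = 1.0 / l_eff
    acc = np.zeros(n_iso)
    if n_amb == 0:
        return counts
    sup = np.concatenate(sup_parts)
    offs = np.concatenate([[0], np.cumsum(amb_sizes)]).astype(np.int64)
    z = np.zeros(n_amb, dtype=np.int64)
    for r in range(n_amb):  # initial assignment ~ prior weights
        s = sup[offs[r] : offs[r + 1]]
        w = inv_leff[s]
        z[r] = s[np.searchsorted(np.cumsum(w), rng.random() * w.sum())]
        counts[z[r]] += 1
    retained = 0
    for sweep in range(n_samples):
        _gibbs_sweep(sup, offs, z, counts, inv_leff, alpha, rng.random(n_amb))
        if sweep >= burn_in:
            acc += counts
            retained += 1
    return acc / retained


def _gibbs_sweep_py(sup, offs, z, counts, inv_leff, alpha, u):
    """One collapsed-Gibbs sweep over all ambiguous reads (in order)."""
    for r in range(z.size):
        s0, s1 = offs[r], offs[r + 1]
        counts[z[r]] -= 1
        tot = 0.0
        for j in range(s0, s1):
            tot += (counts[sup[j]] + alpha) * inv_leff[sup[j]]
        x = u[r] * tot
        acc = 0.0
        pick = sup[s1 - 1]
        for j in range(s0, s1):
            acc += (counts[sup[j]] + alpha) * inv_leff[sup[j]]
            if x <= acc:
                pick = sup[j]
                break
        z[r] = pick
        counts[pick] += 1


try:  # the jitted sweep is a pure speedup; results are identical
    from numba import njit

    _gibbs_sweep = njit(cache=True)(_gibbs_sweep_py)
except Exception:  # pragma: no cover - numba always present in practice
    _gibbs_sweep = _gibbs_sweep_py
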