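"""Condition designs and expression profiles.

The baseline expression state gives every isoform the same molar abundance.
Differential-expression designs divide the gene loci into ``n_chunks`` chunks
(round-robin over the locus order, so paralog-family members land in
different chunks) and each non-baseline condition up-regulates one chunk
two-fold and down-regulates the chunk half a rotation away.  Isoform-switch
designs move the entire output of every multi-isoform locus onto a single
annotated isoform while conserving the locus total.  Replicates add
log-normal noise to the per-isoform expression fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationSet


@dataclass
class ConditionDesign:
    """Per-locus fold factors plus (for switch designs) the active isoform."""

    condition_id: str
    fold: dict[str, float]  # locus_id -> fold factor in {0.5, 1, 2}
    active_isoform: dict[str, int] | None = None  # locus_id -> 1-based index
    log: list[str] = field(default_factory=list)

    def fold_of(self, locus_id: str) -> float:
        return self.fold.get(locus_id, 1.0)


@dataclass
class ExpressionProfile:
    """Per-isoform molar fractions for one sample (condition x replicate)."""

    sample_id: str
    condition_id: str
    replicate: int
    fractions: np.ndarray  # aligned with annotation.isoforms
    sdlog: float = 0.0

    def validate(self) -> None:
        if np.any(self.fractions < 0):
            raise ValueError("negative expression fraction")
        if abs(float(self.fractions.sum()) - 1.0) > 1e-9:
            raise ValueError("fractions do not sum to 1")


def baseline_profile(annotation: AnnotationSet) -> ExpressionProfile:
    """Equal molar abundance for every isoform."""
    n = len(annotation.isoforms)
    return ExpressionProfile(
        sample_id="baseline",
        condition_id="cond00",
        replicate=0,
        fractions=np.full(n, 1.0 / n),
    )


def _chunk_of_locus(annotation: AnnotationSet, n_chunks: int) -> dict[str, int]:
    """Round-robin chunk assignment over the locus order."""
    return {
        locus.locus_id: i % n_chunks for i, locus in enumerate(annotation.loci)
    }


def make_condition_designs(
    annotation: AnnotationSet, n_chunks: int = 10, fold: float = 2.0
) -> list[ConditionDesign]:
    """Baseline plus ``n_chunks`` differential conditions.

    Condition ``k`` (1-based) up-regulates chunk ``k - 1`` by ``fold`` and
    down-regulates chunk ``(k - 1 + n_chunks // 2) % n_chunks`` by
    ``1 / fold``, so each condition changes ``2 / n_chunks`` of the genes and
    every gene is differential in some pairwise comparison and null in others.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if n_chunks < 2:
        raise ValueError("n_chunks must be >= 2")
    if len(annotation.loci) < n_chunks:
        raise ValueError("fewer genes than chunks")
    chunk = _chunk_of_locus(annotation, n_chunks)
    designs = [ConditionDesign(condition_id="cond00", fold={})]
    for k in range(1, n_chunks + 1):
        up = k - 1
        down = (k - 1 + n_chunks // 2) % n_chunks
        fold_map = {}
        for locus_id, c in chunk.items():
            if c == up:
                fold_map[locus_id] = fold
            elif c == down:
                fold_map[locus_id] = 1.0 / fold
        designs.append(ConditionDesign(condition_id=f"cond{k:02d}", fold=fold_map))
    return designs


def de_truth(
    design_a: ConditionDesign, design_b: ConditionDesign, annotation: AnnotationSet
) -> set[str]:
    """Loci whose fold factor differs between the two designs."""
    return {
        locus.locus_id
        for locus in annotation.loci
        if design_a.fold_of(locus.locus_id) != design_b.fold_of(locus.locus_id)
    }


def make_switch_designs(
    annotation: AnnotationSet, k_values: list[int]
) -> list[ConditionDesign]:
    """One design per k: every multi-isoform locus expresses only isoform k.

    The locus total stays at its baseline value; a k exceeding a locus's
    isoform count falls back to the last isoform and is recorded in the
    design log.
    """
    designs = []
    for k in k_values:
        if k < 1:
            raise ValueError("isoform index k must be >= 1")
        active: dict[str, int] = {}
        log: list[str] = []
        for locus in annotation.loci:
            n_iso = len(annotation.isoforms_of_locus(locus.locus_id))
            if n_iso == 1:
                continue
            if k > n_iso:
                active[locus.locus_id] = n_iso
                log.append(
                    f"{locus.locus_id}: k={k} exceeds {n_iso} isoforms; using last"
                )
            else:
                active[locus.locus_id] = k
        designs.append(
            ConditionDesign(
                condition_id=f"switch_k{k}", fold={}, active_isoform=active, log=log
            )
        )
    return designs


def switch_truth(
    design_a: ConditionDesign, design_b: ConditionDesign, annotation: AnnotationSet
) -> set[str]:
    """Loci whose active isoform set differs between the two designs."""
    out = set()
    for locus in annotation.loci:
        isos = annotation.isoforms_of_locus(locus.locus_id)
        if len(isos) == 1:
            continue

        def active_set(design: ConditionDesign) -> frozenset[str]:
            if design.active_isoform is None or locus.locus_id not in design.active_isoform:
                return frozenset(i.isoform_id for i in isos)
            k = design.active_isoform[locus.locus_id]
            return frozenset({isos[k - 1].isoform_id})

        if active_set(design_a) != active_set(design_b):
            out.add(locus.locus_id)
    return out


def design_fractions(
    design: ConditionDesign,
    baseline: ExpressionProfile,
    annotation: AnnotationSet,
) -> np.ndarray:
    """Noise-free per-isoform fractions implied by a design (before renorm).

    Fold factors scale all isoforms of a locus; switch designs concentrate the
    locus's baseline total on the active isoform.  The result is NOT
    renormalized, so locus totals can be compared across designs directly.
    """
    fr = baseline.fractions.copy()
    iso_index = annotation.isoform_index
    for locus in annotation.loci:
        isos = annotation.isoforms_of_locus(locus.locus_id)
        idx = [iso_index[i.isoform_id] for i in isos]
        if (
            design.active_isoform is not None
            and locus.locus_id in design.active_isoform
        ):
            total = fr[idx].sum()
            fr[idx] = 0.0
            fr[idx[design.active_isoform[locus.locus_id] - 1]] = total
        f = design.fold_of(locus.locus_id)
        if f != 1.0:
            fr[idx] *= f
    return fr


def realize_replicate(
    design: ConditionDesign,
    baseline: ExpressionProfile,
    sigma: float,
    seed: int,
    annotation: AnnotationSet,
    replicate: int = 1,
) -> ExpressionProfile:
    """Apply the design's folds and log-normal replicate noise, renormalize."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    fr = design_fractions(design, baseline, annotation)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        fr = fr * np.exp(rng.normal(0.0, sigma, size=fr.size))
    fr = fr / fr.sum()
    return ExpressionProfile(
        sample_id=f"{design.condition_id}_r{replicate}",
        condition_id=design.condition_id,
        replicate=replicate,
        fractions=fr,
        sdlog=sigma,
    )


def nominal_fpkm(
    profile: ExpressionProfile, annotation: AnnotationSet, n_reads: int | None = None
) -> np.ndarray:
    """FPKM implied by molar fractions under unbiased length-proportional sampling.

    FPKM_nom,i = 1e9 * a_i / sum_j a_j * l_j; independent of sequencing depth
    and constant across isoforms when all fractions are equal.
    """
    a = profile.fractions
    if not np.any(a > 0):
        raise ValueError("all expression fractions are zero")
    lengths = np.array([iso.length for iso in annotation.isoforms], float)
    return 1e9 * a / float((a * lengths).sum())


def designs_to_json(
    designs: list[ConditionDesign], annotation: AnnotationSet, path
) -> None:
    payload = []
    for d in designs:
        payload.append(
            dict(
                condition_id=d.condition_id,
                fold=d.fold,
                active_isoform=d.active_isoform,
                log=d.log,
            )
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
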