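import numpy as np
import pytest

from rnaseqbench.synthetic_data import (
    AnnotationConfig,
    AnnotationSet,
    Isoform,
    Locus,
    build_annotation,
)


@pytest.fixture(scope="session")
def small_annotation() -> AnnotationSet:
    """A small but structurally complete annotation (paralogs, overlaps)."""
    cfg = AnnotationConfig(
        n_loci=60,
        n_paralog_pairs=4,
        n_identical_pairs=1,
        n_paralog_triples=1,
        n_retro_fragments=4,
        overlapping_symbol_fraction=0.06,
    )
    return build_annotation(cfg, seed=7)


def make_annotation(loci_spec, chrom_len=None, seed=0):
    """Hand-build an AnnotationSet.

    ``loci_spec`` is a list of dicts with keys: locus_id, symbols, strand,
    isoforms = {isoform_id: [(start, end), ...]}, and optionally ``sequence``
    (placed at the locus span on the chromosome).
    """
    rng = np.random.default_rng(seed)
    spans = []
    for spec in loci_spec:
        exons = [iv for ivs in spec["isoforms"].values() for iv in ivs]
        spans.append((min(s for s, _ in exons), max(e for _, e in exons)))
    total = max(e for _, e in spans) + 100 if chrom_len is None else chrom_len
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chrom = bases[rng.integers(0, 4, size=total)].tobytes()
    chrom = bytearray(chrom)
    loci, isoforms = [], []
    for spec, span in zip(loci_spec, spans):
        if "sequence" in spec:
            seq = spec["sequence"]
            chrom[span[0] : span[0] + len(seq)] = seq
        loci.append(
            Locus(
                locus_id=spec["locus_id"],
                gene_symbols=tuple(spec.get("symbols", (spec["locus_id"],))),
                chromosome="chr1",
                strand=spec.get("strand", "+"),
                span=span,
                family_id=spec.get("family_id"),
            )
        )
        for iso_id, exons in spec["isoforms"].items():
            isoforms.append(
                Isoform(
                    isoform_id=iso_id,
                    locus_id=spec["locus_id"],
                    exons=tuple(sorted(exons)),
                )
            )
    return AnnotationSet(chromosomes={"chr1": bytes(chrom)}, loci=loci, isoforms=isoforms)
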