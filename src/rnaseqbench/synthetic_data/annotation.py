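"""Synthetic genome and transcript annotation.

The generator emulates the structural features of a real vertebrate
annotation that drive read-mapping ambiguity: multiple overlapping isoforms
per locus, duplicated (paralogous) loci whose sequence is identical or nearly
identical to their source, processed-pseudogene-like truncated copies, and
loci carrying two overlapping gene symbols.  Genomic intervals are 0-based
half-open internally and 1-based inclusive in GTF output; transcript
coordinates are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: bytes) -> bytes:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Isoform:
    """One transcript: an ordered list of genomic exon intervals."""

    isoform_id: str
    locus_id: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, genomic order

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class Locus:
    locus_id: str
    gene_symbols: tuple[str, ...]  # two symbols = overlapping gene symbols
    chromosome: str
    strand: str
    span: tuple[int, int]
    family_id: str | None = None


@dataclass
class AnnotationSet:
    """Synthetic genome plus loci and isoforms; source of truth for coordinates."""

    chromosomes: dict[str, bytes]
    loci: list[Locus]
    isoforms: list[Isoform]
    _cache: dict = field(default_factory=dict, repr=False)

    # ---- lookups ---------------------------------------------------------
    @property
    def locus_by_id(self) -> dict[str, Locus]:
        if "locus_by_id" not in self._cache:
            self._cache["locus_by_id"] = {l.locus_id: l for l in self.loci}
        return self._cache["locus_by_id"]

    @property
    def isoform_by_id(self) -> dict[str, Isoform]:
        if "isoform_by_id" not in self._cache:
            self._cache["isoform_by_id"] = {i.isoform_id: i for i in self.isoforms}
        return self._cache["isoform_by_id"]

    @property
    def isoform_index(self) -> dict[str, int]:
        if "isoform_index" not in self._cache:
            self._cache["isoform_index"] = {
                iso.isoform_id: k for k, iso in enumerate(self.isoforms)
            }
        return self._cache["isoform_index"]

    def isoforms_of_locus(self, locus_id: str) -> list[Isoform]:
        if "by_locus" not in self._cache:
            by_locus: dict[str, list[Isoform]] = {}
            for iso in self.isoforms:
                by_locus.setdefault(iso.locus_id, []).append(iso)
            self._cache["by_locus"] = by_locus
        return self._cache["by_locus"][locus_id]

    @property
    def gene_symbols(self) -> list[str]:
        """All gene symbols, in locus order."""
        if "gene_symbols" not in self._cache:
            out: list[str] = []
            for locus in self.loci:
                out.extend(locus.gene_symbols)
            self._cache["gene_symbols"] = out
        return self._cache["gene_symbols"]

    @property
    def symbol_to_loci(self) -> dict[str, list[str]]:
        if "symbol_to_loci" not in self._cache:
            mapping: dict[str, list[str]] = {}
            for locus in self.loci:
                for sym in locus.gene_symbols:
                    mapping.setdefault(sym, []).append(locus.locus_id)
            self._cache["symbol_to_loci"] = mapping
        return self._cache["symbol_to_loci"]

    # ---- sequence access -------------------------------------------------
    def spliced_sequence(self, isoform_id: str) -> bytes:
        """Spliced transcript sequence, 5'->3'."""
        cache = self._cache.setdefault("spliced", {})
        if isoform_id not in cache:
            iso = self.isoform_by_id[isoform_id]
            locus = self.locus_by_id[iso.locus_id]
            chrom = self.chromosomes[locus.chromosome]
            seq = b"".join(chrom[s:e] for s, e in iso.exons)
            if locus.strand == "-":
                seq = revcomp(seq)
            cache[isoform_id] = seq
        return cache[isoform_id]

    def transcript_to_genomic(
        self, isoform_id: str, t_start: int, t_end: int
    ) -> list[tuple[int, int]]:
        """Project a 1-based inclusive transcript interval to genomic intervals.

        Returns 0-based half-open genomic intervals in genomic order.
        """
        iso = self.isoform_by_id[isoform_id]
        locus = self.locus_by_id[iso.locus_id]
        if not (1 <= t_start <= t_end <= iso.length):
            raise ValueError(
                f"transcript interval [{t_start},{t_end}] outside [1,{iso.length}]"
            )
        # walk exons in 5'->3' transcript order
        exons = iso.exons if locus.strand == "+" else iso.exons[::-1]
        out: list[tuple[int, int]] = []
        offset = 0  # transcript bases consumed
        for s, e in exons:
            elen = e - s
            lo = max(t_start - 1, offset)
            hi = min(t_end, offset + elen)
            if lo < hi:
                if locus.strand == "+":
                    out.append((s + (lo - offset), s + (hi - offset)))
                else:
                    out.append((e - (hi - offset), e - (lo - offset)))
            offset += elen
        if locus.strand == "-":
            out = out[::-1]
        return out

    def sequence_arrays(self) -> dict:
        """Cached numpy view of all spliced transcript sequences.

        Returns a dict with ``tx`` (uint8 concatenation of all spliced
        sequences), ``offsets`` (start of each isoform in ``tx``),
        ``lengths``, and ``locus_idx`` (index into ``self.loci``).
        """
        if "seq_arrays" not in self._cache:
            seqs = [
                np.frombuffer(self.spliced_sequence(iso.isoform_id), dtype=np.uint8)
                for iso in self.isoforms
            ]
            lengths = np.array([len(s) for s in seqs], dtype=np.int64)
            offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
            locus_pos = {l.locus_id: i for i, l in enumerate(self.loci)}
            locus_idx = np.array(
                [locus_pos[iso.locus_id] for iso in self.isoforms], dtype=np.int64
            )
            self._cache["seq_arrays"] = dict(
                tx=np.concatenate(seqs) if seqs else np.zeros(0, np.uint8),
                offsets=offsets,
                lengths=lengths,
                locus_idx=locus_idx,
            )
        return self._cache["seq_arrays"]

    # ---- validation ------------------------------------------------------
    def validate(self) -> None:
        for iso in self.isoforms:
            locus = self.locus_by_id[iso.locus_id]
            chrom_len = len(self.chromosomes[locus.chromosome])
            prev_end = -1
            for s, e in iso.exons:
                if not (0 <= s < e <= chrom_len):
                    raise ValueError(f"{iso.isoform_id}: exon ({s},{e}) out of range")
                if s < prev_end:
                    raise ValueError(f"{iso.isoform_id}: overlapping/unsorted exons")
                prev_end = e
            if iso.length < 200:
                raise ValueError(f"{iso.isoform_id}: spliced length {iso.length} < 200")
        for locus in self.loci:
            isos = self.isoforms_of_locus(locus.locus_id)
            lo = min(i.start for i in isos)
            hi = max(i.end for i in isos)
            if not (locus.span[0] <= lo and hi <= locus.span[1]):
                raise ValueError(f"{locus.locus_id}: span does not cover exons")
            if len(isos) > 1:
                shared = set(isos[0].exons)
                for other in isos[1:]:
                    if not shared.intersection(other.exons):
                        raise ValueError(
                            f"{locus.locus_id}: isoforms without a shared exon"
                        )

    # ---- export ----------------------------------------------------------
    def to_gtf(self, path) -> None:
        """Write exon features with gene_id / transcript_id, 1-based inclusive."""
        with open(path, "w") as fh:
            for iso in self.isoforms:
                locus = self.locus_by_id[iso.locus_id]
                gene_id = locus.gene_symbols[0]
                symbols = ",".join(locus.gene_symbols)
                for s, e in iso.exons:
                    attrs = (
                        f'gene_id "{gene_id}"; transcript_id "{iso.isoform_id}"; '
                        f'locus_id "{locus.locus_id}"; gene_symbols "{symbols}";'
                    )
                    fh.write(
                        f"{locus.chromosome}\trnaseqbench\texon\t{s + 1}\t{e}\t.\t"
                        f"{locus.strand}\t.\t{attrs}\n"
                    )

    def to_fasta(self, path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                text = seq.decode()
                for i in range(0, len(text), line_width):
                    fh.write(text[i : i + line_width] + "\n")

    def transcripts_to_fasta(self, path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for iso in self.isoforms:
                fh.write(f">{iso.isoform_id}\n")
                text = self.spliced_sequence(iso.isoform_id).decode()
                for i in range(0, len(text), line_width):
                    fh.write(text[i : i + line_width] + "\n")


@dataclass
class AnnotationConfig:
    """Generator settings for :func:`build_annotation`.

    Counts are totals: ``n_loci`` includes duplicated and retro-fragment
    copies.  ``paralog_divergence`` is the exact number of substitutions
    introduced into each duplicated locus (0 = identical copies).
    """

    n_loci: int = 500
    isoform_number_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.35, 3: 0.30}
    )
    min_length: int = 200
    max_length: int = 12000
    first_exon_range: tuple[int, int] = (200, 400)
    internal_exon_range: tuple[int, int] = (80, 350)
    intron_range: tuple[int, int] = (100, 600)
    intergenic_range: tuple[int, int] = (200, 800)
    exon_drop_prob: float = 0.4
    exon_truncate_prob: float = 0.15
    n_paralog_pairs: int = 18
    n_identical_pairs: int = 2
    n_paralog_triples: int = 5
    n_retro_fragments: int = 30
    paralog_divergence: int = 6
    retro_length_range: tuple[int, int] = (210, 400)
    overlapping_symbol_fraction: float = 0.04
    minus_strand_fraction: float = 0.3
    n_chromosomes: int = 5

    def validate(self) -> None:
        if self.min_length < 200:
            raise ValueError("isoform length < 200 is not supported (min_length)")
        if self.paralog_divergence < 0:
            raise ValueError("paralog divergence must be >= 0")
        if self.retro_length_range[0] < 200:
            raise ValueError("retro fragment length < 200 is not supported")
        n_copies = (
            self.n_paralog_pairs
            + self.n_identical_pairs
            + 2 * self.n_paralog_triples
            + self.n_retro_fragments
        )
        if self.n_loci <= n_copies:
            raise ValueError("n_loci must exceed the number of duplicated loci")
        if abs(sum(self.isoform_number_probs.values()) - 1.0) > 1e-9:
            raise ValueError("isoform_number_probs must sum to 1")


def _random_seq(rng: np.random.Generator, n: int) -> bytes:
    return _BASES[rng.integers(0, 4, size=n)].tobytes()


def _build_gene_model(cfg: AnnotationConfig, rng: np.random.Generator):
    """Exon lengths + intron lengths for one locus (local coordinates)."""
    target = math.exp(rng.uniform(math.log(cfg.min_length), math.log(cfg.max_length)))
    first = int(rng.integers(cfg.first_exon_range[0], cfg.first_exon_range[1] + 1))
    exon_lens = [first]
    remaining = target - first
    lo, hi = cfg.internal_exon_range
    while remaining > 0:
        e = int(rng.integers(lo, hi + 1))
        if remaining < lo:
            exon_lens[-1] += int(round(remaining))
            break
        e = min(e, int(round(remaining)))
        e = max(e, lo)
        exon_lens.append(e)
        remaining -= e
    introns = [
        int(rng.integers(cfg.intron_range[0], cfg.intron_range[1] + 1))
        for _ in range(len(exon_lens) - 1)
    ]
    return exon_lens, introns


def _isoform_exon_sets(
    cfg: AnnotationConfig,
    exon_lens: list[int],
    n_isoforms: int,
    rng: np.random.Generator,
):
    """Choose exon subsets (with optional 3'-side truncation of non-first exons).

    Returns a list of lists of (exon_index, used_length).  The first exon is
    present full-length in every isoform so that all isoforms of a locus share
    at least one identical exon interval.
    """
    full = [(j, exon_lens[j]) for j in range(len(exon_lens))]
    chosen = [full]
    seen = {tuple(full)}
    for _ in range(n_isoforms - 1):
        for _attempt in range(20):
            iso = [(0, exon_lens[0])]
            for j in range(1, len(exon_lens)):
                if rng.random() < cfg.exon_drop_prob:
                    continue
                length = exon_lens[j]
                if rng.random() < cfg.exon_truncate_prob and length >= 80:
                    length = max(40, int(round(length * rng.uniform(0.3, 0.7))))
                iso.append((j, length))
            key = tuple(iso)
            if key not in seen:
                seen.add(key)
                chosen.append(iso)
                break
    return chosen


def build_annotation(
    config: AnnotationConfig | None = None, seed: int = 0
) -> AnnotationSet:
    """Generate a synthetic annotation; deterministic for a fixed seed."""
    cfg = config or AnnotationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    n_copies = (
        cfg.n_paralog_pairs
        + cfg.n_identical_pairs
        + 2 * cfg.n_paralog_triples
        + cfg.n_retro_fragments
    )
    n_primary = cfg.n_loci - n_copies

    iso_counts = np.array(sorted(cfg.isoform_number_probs))
    iso_probs = np.array([cfg.isoform_number_probs[k] for k in iso_counts], float)

    # --- primary gene models ---------------------------------------------
    primaries = []  # dicts with exon/intron structure + strand + seq
    for i in range(n_primary):
        exon_lens, introns = _build_gene_model(cfg, rng)
        n_iso = 1 if len(exon_lens) == 1 else int(rng.choice(iso_counts, p=iso_probs))
        iso_sets = _isoform_exon_sets(cfg, exon_lens, n_iso, rng)
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        span = sum(exon_lens) + sum(introns)
        seq = _random_seq(rng, span)
        primaries.append(
            dict(
                exon_lens=exon_lens,
                introns=introns,
                iso_sets=iso_sets,
                strand=strand,
                seq=seq,
            )
        )

    # --- duplicate loci (identical up to configured divergence) -----------
    records = [dict(kind="primary", model=m, family=None) for m in primaries]
    family_counter = 0

    def _exonic_positions(model: dict) -> np.ndarray:
        """Region-local positions covered by the gene model's exons."""
        parts = []
        cursor = 0
        for j, elen in enumerate(model["exon_lens"]):
            parts.append(np.arange(cursor, cursor + elen))
            cursor += elen
            if j < len(model["introns"]):
                cursor += model["introns"][j]
        return np.concatenate(parts)

    def _diverge(model: dict, n_subs: int) -> bytes:
        """Introduce exactly n_subs substitutions at exonic positions."""
        seq = model["seq"]
        if n_subs == 0:
            return seq
        arr = np.frombuffer(seq, dtype=np.uint8).copy()
        exonic = _exonic_positions(model)
        pos = rng.choice(exonic, size=min(n_subs, exonic.size), replace=False)
        for p in pos:
            choices = [b for b in b"ACGT" if b != arr[p]]
            arr[p] = choices[rng.integers(0, 3)]
        return arr.tobytes()

    n_families = (
        cfg.n_paralog_pairs + cfg.n_identical_pairs + cfg.n_paralog_triples
    )
    family_sources = rng.choice(n_primary, size=n_families, replace=False)
    for fi, src_idx in enumerate(family_sources):
        family_counter += 1
        fam = f"FAM{family_counter:03d}"
        records[src_idx]["family"] = fam
        if fi < cfg.n_paralog_pairs:
            n_extra, divergence = 1, cfg.paralog_divergence
        elif fi < cfg.n_paralog_pairs + cfg.n_identical_pairs:
            n_extra, divergence = 1, 0
        else:
            n_extra, divergence = 2, cfg.paralog_divergence
        src = primaries[src_idx]
        for _ in range(n_extra):
            copy = dict(src)
            copy["seq"] = _diverge(src, divergence)
            records.append(dict(kind="duplicate", model=copy, family=fam))

    # --- retro fragments: single-exon copies of a 3' spliced window --------
    free = [i for i in range(n_primary) if records[i]["family"] is None]
    # retrocopies descend from long, well-expressed mRNAs; require the source
    # to be long enough that the copied window is interior to the transcript
    spliced_len = {i: sum(primaries[i]["exon_lens"]) for i in free}
    eligible = [i for i in free if spliced_len[i] >= 1400]
    if len(eligible) < cfg.n_retro_fragments:
        eligible = sorted(free, key=lambda i: -spliced_len[i])[
            : cfg.n_retro_fragments
        ]
    retro_sources = rng.choice(
        np.array(eligible), size=cfg.n_retro_fragments, replace=False
    )
    for src_idx in retro_sources:
        family_counter += 1
        fam = f"FAM{family_counter:03d}"
        records[src_idx]["family"] = fam
        src = primaries[src_idx]
        # spliced sequence of the full-exon isoform in transcript orientation
        spliced_parts = []
        cursor = 0
        starts = []
        for j, elen in enumerate(src["exon_lens"]):
            starts.append(cursor)
            cursor += elen
            if j < len(src["introns"]):
                cursor += src["introns"][j]
        plus_spliced = b"".join(
            src["seq"][starts[j] : starts[j] + src["exon_lens"][j]]
            for j in range(len(src["exon_lens"]))
        )
        spliced = plus_spliced if src["strand"] == "+" else revcomp(plus_spliced)
        w = int(rng.integers(cfg.retro_length_range[0], cfg.retro_length_range[1] + 1))
        w = min(w, len(spliced))
        # 3'-biased but truncated retrocopy: an interior window of the mRNA
        gap3 = int(rng.integers(300, 601))
        end = max(w, len(spliced) - gap3)
        window = spliced[end - w : end]
        strand = "-" if rng.random() < 0.5 else "+"
        region = window if strand == "+" else revcomp(window)
        model = dict(
            exon_lens=[w],
            introns=[],
            iso_sets=[[(0, w)]],
            strand=strand,
            seq=region,  # recent retrocopy: identical to the source window
        )
        records.append(dict(kind="retro", model=model, family=fam))

    # --- shuffle locus order so copies are scattered along the genome ------
    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    # --- overlapping-symbol loci ------------------------------------------
    n_overlap = int(round(cfg.overlapping_symbol_fraction * cfg.n_loci))
    overlap_set = set(
        rng.choice(len(records), size=n_overlap, replace=False).tolist()
    )

    # --- layout on chromosomes --------------------------------------------
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    chrom_parts: dict[str, list[bytes]] = {c: [] for c in chrom_names}
    cursors = {c: 0 for c in chrom_names}

    loci: list[Locus] = []
    isoforms: list[Isoform] = []
    for i, rec in enumerate(records):
        model = rec["model"]
        chrom = chrom_names[i * cfg.n_chromosomes // len(records)]
        gap = int(rng.integers(cfg.intergenic_range[0], cfg.intergenic_range[1] + 1))
        chrom_parts[chrom].append(_random_seq(rng, gap))
        cursors[chrom] += gap
        start = cursors[chrom]
        chrom_parts[chrom].append(model["seq"])
        cursors[chrom] += len(model["seq"])
        end = cursors[chrom]

        locus_id = f"LOC{i + 1:04d}"
        symbols = [f"G{i + 1:04d}"]
        if i in overlap_set:
            symbols.append(f"G{i + 1:04d}OV")
        loci.append(
            Locus(
                locus_id=locus_id,
                gene_symbols=tuple(symbols),
                chromosome=chrom,
                strand=model["strand"],
                span=(start, end),
                family_id=rec["family"],
            )
        )
        # exon genomic starts within the locus
        exon_starts = []
        cursor = start
        for j, elen in enumerate(model["exon_lens"]):
            exon_starts.append(cursor)
            cursor += elen
            if j < len(model["introns"]):
                cursor += model["introns"][j]
        for k, iso_set in enumerate(model["iso_sets"]):
            exons = []
            for j, used in iso_set:
                s = exon_starts[j]
                if model["strand"] == "+" or used == model["exon_lens"][j]:
                    exons.append((s, s + used))
                else:
                    # 3'-side truncation on the minus strand trims the genomic start
                    e = s + model["exon_lens"][j]
                    exons.append((e - used, e))
            isoforms.append(
                Isoform(
                    isoform_id=f"{locus_id}.{k + 1}",
                    locus_id=locus_id,
                    exons=tuple(exons),
                )
            )

    chromosomes = {c: b"".join(chrom_parts[c]) for c in chrom_names}
    ann = AnnotationSet(chromosomes=chromosomes, loci=loci, isoforms=isoforms)
    ann.validate()
    return ann
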