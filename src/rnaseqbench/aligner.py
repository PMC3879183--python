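"""Transcriptome k-mer seed-and-extend aligner.

Reads are aligned to the spliced transcript sequences (the transcriptome
paradigm).  Two modes realize the behaviours of the common genome aligners:
``global`` requires the full read to align end-to-end with a bounded number
of mismatches; ``local`` additionally permits soft-clipping at the read ends
(scored at 1 per 4 clipped bases), which rescues reads that run into poly-A
tails or off transcript ends.  Extension is ungapped -- the simulator emits
no indels.  All alignments tying the best score are reported, capped at
``max_alignments`` with a deterministic leftmost-isoform-id tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .synthetic_data.annotation import AnnotationSet

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class AlignmentParams:
    mode: str = "global"  # "global" or "local"
    max_mismatches: int = 5
    max_clip: int = 81  # per end; ignored (0) in global mode
    min_aligned: int = 20
    max_alignments: int = 30

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "global":
            self.max_clip = 0


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    isoform_id: str
    t_start: int  # 1-based transcript coordinate of the aligned core
    t_end: int
    mismatches: int
    clip_left: int
    clip_right: int
    multiplicity: int


class KmerIndex:
    """Exact k-mer lookup over all spliced transcript sequences."""

    def __init__(self, annotation: AnnotationSet, k: int):
        if not (8 <= k <= 32):
            raise ValueError("k must be in [8, 32]")
        arrays = annotation.sequence_arrays()
        if int(arrays["lengths"].min()) < k:
            raise ValueError("k exceeds the shortest isoform length")
        self.annotation = annotation
        self.k = k
        self.tx = arrays["tx"]
        self.tx_offsets = arrays["offsets"]
        self.lengths = arrays["lengths"]
        self.locus_idx = arrays["locus_idx"]

        codes = _CODE[self.tx].astype(np.uint64)
        pow4 = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
        n_iso = self.lengths.size
        kmers_parts, iso_parts, off_parts = [], [], []
        for i in range(n_iso):
            s = self.tx_offsets[i]
            c = codes[s : s + self.lengths[i]]
            if c.size < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(c, k)
            km = win @ pow4
            kmers_parts.append(km)
            iso_parts.append(np.full(km.size, i, dtype=np.int32))
            off_parts.append(np.arange(km.size, dtype=np.int32))
        kmers = np.concatenate(kmers_parts)
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.entry_iso = np.concatenate(iso_parts)[order]
        self.entry_off = np.concatenate(off_parts)[order]

    def n_positions(self, isoform_id: str) -> int:
        i = self.annotation.isoform_index[isoform_id]
        return max(0, int(self.lengths[i]) - self.k + 1)

    def lookup(self, kmer_seq: bytes) -> list[tuple[str, int]]:
        """All (isoform_id, offset) entries for one k-mer (for inspection)."""
        c = _CODE[np.frombuffer(kmer_seq, np.uint8)].astype(np.uint64)
        pow4 = (4 ** np.arange(self.k - 1, -1, -1)).astype(np.uint64)
        q = c @ pow4
        lo = np.searchsorted(self.sorted_kmers, q, "left")
        hi = np.searchsorted(self.sorted_kmers, q, "right")
        ids = [self.annotation.isoforms[i].isoform_id for i in self.entry_iso[lo:hi]]
        return list(zip(ids, self.entry_off[lo:hi].tolist()))


def build_index(annotation: AnnotationSet, k: int = 20) -> KmerIndex:
    return KmerIndex(annotation, k)


@dataclass
class AlignmentTable:
    """Flat alignment records for one read set (sorted by read, isoform)."""

    read_idx: np.ndarray
    iso_idx: np.ndarray
    t_start: np.ndarray  # 0-based transcript start of the aligned core
    mismatches: np.ndarray
    clip_left: np.ndarray
    clip_right: np.ndarray
    n_reads: int
    read_length: int
    annotation: AnnotationSet
    read_ids: list[str] | None = None

    @property
    def nh(self) -> np.ndarray:
        """Multiplicity (reported alignments) per record."""
        counts = np.bincount(self.read_idx, minlength=self.n_reads)
        return counts[self.read_idx]

    def aligned_mask(self) -> np.ndarray:
        m = np.zeros(self.n_reads, bool)
        m[self.read_idx] = True
        return m

    def _rid(self, i: int) -> str:
        return self.read_ids[i] if self.read_ids is not None else f"r{i:07d}"

    def to_records(self) -> list[AlignmentRecord]:
        nh = self.nh
        out = []
        for j in range(self.read_idx.size):
            iso = self.annotation.isoforms[self.iso_idx[j]]
            core = self.read_length - self.clip_left[j] - self.clip_right[j]
            out.append(
                AlignmentRecord(
                    read_id=self._rid(self.read_idx[j]),
                    isoform_id=iso.isoform_id,
                    t_start=int(self.t_start[j]) + 1,
                    t_end=int(self.t_start[j]) + int(core),
                    mismatches=int(self.mismatches[j]),
                    clip_left=int(self.clip_left[j]),
                    clip_right=int(self.clip_right[j]),
                    multiplicity=int(nh[j]),
                )
            )
        return out

    def to_sam(self, path, seqs: np.ndarray | None = None) -> None:
        """Write SAM with soft clips in CIGAR and NH / NM tags."""
        ann = self.annotation
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [
                    {"SN": iso.isoform_id, "LN": iso.length}
                    for iso in ann.isoforms
                ],
            }
        )
        nh = self.nh
        L = self.read_length
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            j = 0
            order = np.argsort(self.read_idx, kind="stable")
            by_read: dict[int, list[int]] = {}
            for jj in order:
                by_read.setdefault(int(self.read_idx[jj]), []).append(int(jj))
            for i in range(self.n_reads):
                recs = by_read.get(i)
                if recs is None:
                    a = pysam.AlignedSegment(header)
                    a.query_name = self._rid(i)
                    a.is_unmapped = True
                    if seqs is not None:
                        a.query_sequence = seqs[i].tobytes().decode()
                        a.query_qualities = pysam.qualitystring_to_array("I" * L)
                    out.write(a)
                    continue
                for rank, jj in enumerate(recs):
                    a = pysam.AlignedSegment(header)
                    a.query_name = self._rid(i)
                    a.reference_id = int(self.iso_idx[jj])
                    a.reference_start = int(self.t_start[jj])
                    a.is_secondary = rank > 0
                    lc, rc = int(self.clip_left[jj]), int(self.clip_right[jj])
                    core = L - lc - rc
                    cigar = []
                    if lc:
                        cigar.append((4, lc))
                    cigar.append((0, core))
                    if rc:
                        cigar.append((4, rc))
                    a.cigartuples = cigar
                    a.mapping_quality = 255
                    if seqs is not None:
                        a.query_sequence = seqs[i].tobytes().decode()
                        a.query_qualities = pysam.qualitystring_to_array("I" * L)
                    a.set_tag("NH", int(nh[jj]))
                    a.set_tag("NM", int(self.mismatches[jj]))
                    out.write(a)
                    j += 1

    @classmethod
    def from_sam(cls, path, annotation: AnnotationSet) -> "AlignmentTable":
        iso_index = annotation.isoform_index
        read_pos: dict[str, int] = {}
        rows = []
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            L = None
            for rec in fh:
                if rec.query_name not in read_pos:
                    read_pos[rec.query_name] = len(read_pos)
                if L is None and rec.query_length:
                    L = rec.query_length
                if rec.is_unmapped:
                    continue
                lc = rc = 0
                if rec.cigartuples:
                    if rec.cigartuples[0][0] == 4:
                        lc = rec.cigartuples[0][1]
                    if rec.cigartuples[-1][0] == 4:
                        rc = rec.cigartuples[-1][1]
                rows.append(
                    (
                        read_pos[rec.query_name],
                        iso_index[rec.reference_name],
                        rec.reference_start,
                        rec.get_tag("NM") if rec.has_tag("NM") else 0,
                        lc,
                        rc,
                    )
                )
        arr = np.array(rows, dtype=np.int64).reshape(-1, 6)
        ids = [None] * len(read_pos)
        for rid, i in read_pos.items():
            ids[i] = rid
        return cls(
            read_idx=arr[:, 0],
            iso_idx=arr[:, 1],
            t_start=arr[:, 2],
            mismatches=arr[:, 3],
            clip_left=arr[:, 4],
            clip_right=arr[:, 5],
            n_reads=len(read_pos),
            read_length=L or 0,
            annotation=annotation,
            read_ids=ids,
        )


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-row [lo, hi) ranges into flat entry indices + row ids."""
    cnt = hi - lo
    nz = cnt > 0
    lo, cnt = lo[nz], cnt[nz]
    rows = np.flatnonzero(nz)
    total = int(cnt.sum())
    if total == 0:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    rep_row = np.repeat(rows, cnt)
    cum = np.concatenate([[0], np.cumsum(cnt)[:-1]])
    inner = np.arange(total) - np.repeat(cum, cnt)
    return np.repeat(lo, cnt) + inner, rep_row


def align_batch(
    seqs: np.ndarray, index: KmerIndex, params: AlignmentParams
) -> AlignmentTable:
    """Align a (n_reads, L) uint8 matrix of read sequences."""
    n, L = seqs.shape
    k = index.k
    if L < k:
        raise ValueError("reads shorter than the index k-mer size")
    codes = _CODE[seqs].astype(np.uint64)
    pow4 = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    seed_pos = list(range(0, L - k + 1, k))
    if seed_pos[-1] != L - k:
        seed_pos.append(L - k)

    # --- seed lookup -> candidate (read, iso, diagonal) --------------------
    cand_read_parts, cand_iso_parts, cand_diag_parts = [], [], []
    for p in seed_pos:
        q = codes[:, p : p + k] @ pow4
        lo = np.searchsorted(index.sorted_kmers, q, "left")
        hi = np.searchsorted(index.sorted_kmers, q, "right")
        entries, rows = _expand_ranges(lo, hi)
        cand_read_parts.append(rows)
        cand_iso_parts.append(index.entry_iso[entries].astype(np.int64))
        cand_diag_parts.append(index.entry_off[entries].astype(np.int64) - p)
    read = np.concatenate(cand_read_parts)
    iso = np.concatenate(cand_iso_parts)
    diag = np.concatenate(cand_diag_parts)

    # dedupe candidates (same read/iso/diagonal hit by several seeds)
    key = (read << 40) | (iso << 20) | (diag + 256)
    _, first = np.unique(key, return_index=True)
    read, iso, diag = read[first], iso[first], diag[first]

    iso_len = index.lengths[iso]
    if params.mode == "global":
        ok = (diag >= 0) & (diag + L <= iso_len)
    else:
        ok = (diag + L > 0) & (diag < iso_len)
    read, iso, diag, iso_len = read[ok], iso[ok], diag[ok], iso_len[ok]
    if read.size == 0:
        return _empty_table(n, L, index)

    # verify candidates in chunks to bound the gather matrices
    parts = []
    chunk = 200_000
    for c0 in range(0, read.size, chunk):
        sl = slice(c0, c0 + chunk)
        if params.mode == "global":
            parts.append(
                _verify_global(seqs, index, params, read[sl], iso[sl], diag[sl])
            )
        else:
            parts.append(
                _verify_local(
                    seqs, index, params, read[sl], iso[sl], diag[sl], iso_len[sl]
                )
            )
    read, iso, t_start, mism, lclip, rclip, score = (
        np.concatenate([p[i] for p in parts]) for i in range(7)
    )
    return _finalize(n, L, index, params, read, iso, t_start, mism, lclip, rclip, score)


def _verify_global(seqs, index, params, read, iso, diag):
    L = seqs.shape[1]
    pos = (index.tx_offsets[iso] + diag)[:, None].astype(np.int64) + np.arange(L)
    eq = index.tx[pos] == seqs[read]
    mism = (L - eq.sum(axis=1)).astype(np.int32)
    keep = mism <= params.max_mismatches
    nkeep = int(keep.sum())
    return (
        read[keep], iso[keep], diag[keep].astype(np.int64), mism[keep],
        np.zeros(nkeep, np.int32), np.zeros(nkeep, np.int32),
        mism[keep].astype(np.float64),
    )


def _verify_local(seqs, index, params, read, iso, diag, iso_len):
    L = seqs.shape[1]
    pos_t = diag[:, None] + np.arange(L)[None, :]
    inb = (pos_t >= 0) & (pos_t < iso_len[:, None])
    g = index.tx_offsets[iso][:, None] + np.clip(pos_t, 0, (iso_len - 1)[:, None])
    eq = (index.tx[g] == seqs[read]) & inb
    # Kadane with match +1 / mismatch (or out-of-bounds) -3: the best-scoring
    # contiguous core; ends of the core are always matches.
    vals = np.where(eq, 1, -3).astype(np.int32)
    C = read.size
    run = np.zeros(C, np.int32)
    run_start = np.zeros(C, np.int64)
    best = np.full(C, -1, np.int32)
    b_s = np.zeros(C, np.int64)
    b_e = np.zeros(C, np.int64)
    for j in range(L):
        v = vals[:, j]
        restart = run <= 0
        run = np.where(restart, v, run + v)
        run_start = np.where(restart, j, run_start)
        better = run > best
        best = np.where(better, run, best)
        b_s = np.where(better, run_start, b_s)
        b_e = np.where(better, j, b_e)
    pref = np.concatenate(
        [np.zeros((C, 1), np.int32), np.cumsum(eq, axis=1, dtype=np.int32)], axis=1
    )
    core_len = (b_e - b_s + 1).astype(np.int32)
    matches = pref[np.arange(C), b_e + 1] - pref[np.arange(C), b_s]
    mism = core_len - matches
    lclip = b_s.astype(np.int32)
    rclip = (L - 1 - b_e).astype(np.int32)
    keep = (
        (best >= 1)
        & (core_len >= params.min_aligned)
        & (mism <= params.max_mismatches * core_len / L)
        & (lclip <= params.max_clip)
        & (rclip <= params.max_clip)
    )
    score = mism + 0.25 * (lclip + rclip)
    return (
        read[keep], iso[keep], (diag + b_s)[keep], mism[keep],
        lclip[keep], rclip[keep], score[keep].astype(np.float64),
    )


def _empty_table(n: int, L: int, index: KmerIndex) -> AlignmentTable:
    z = np.zeros(0, np.int64)
    return AlignmentTable(
        read_idx=z, iso_idx=z.copy(), t_start=z.copy(),
        mismatches=np.zeros(0, np.int32),
        clip_left=np.zeros(0, np.int32), clip_right=np.zeros(0, np.int32),
        n_reads=n, read_length=L, annotation=index.annotation,
    )


def _finalize(
    n, L, index, params, read, iso, t_start, mism, lclip, rclip, score
) -> AlignmentTable:
    """Keep only best-scoring alignments per read, cap at max_alignments."""
    if read.size == 0:
        return _empty_table(n, L, index)
    best = np.full(n, np.inf)
    np.minimum.at(best, read, score)
    keep = score <= best[read] + 1e-9
    read, iso, t_start = read[keep], iso[keep], t_start[keep]
    mism, lclip, rclip = mism[keep], lclip[keep], rclip[keep]
    # deterministic order: by read, then isoform index, then position
    order = np.lexsort((t_start, iso, read))
    read, iso, t_start = read[order], iso[order], t_start[order]
    mism, lclip, rclip = mism[order], lclip[order], rclip[order]
    # rank within read for the M-cap (leftmost-isoform-id tie-break)
    first = np.concatenate([[True], read[1:] != read[:-1]])
    idx_first = np.flatnonzero(first)
    group = np.cumsum(first) - 1
    rank = np.arange(read.size) - idx_first[group]
    keep = rank < params.max_alignments
    return AlignmentTable(
        read_idx=read[keep], iso_idx=iso[keep], t_start=t_start[keep],
        mismatches=mism[keep], clip_left=lclip[keep], clip_right=rclip[keep],
        n_reads=n, read_length=L, annotation=index.annotation,
    )


def align_read(
    sequence: bytes, index: KmerIndex, params: AlignmentParams
) -> list[AlignmentRecord]:
    """Align a single read; an empty list means unaligned."""
    seqs = np.frombuffer(sequence, np.uint8)[None, :]
    table = align_batch(seqs, index, params)
    return table.to_records()


def align_library(
    reads, index: KmerIndex, params: AlignmentParams, sam_path=None
) -> AlignmentTable:
    """Align a ReadSet or a FASTQ file; optionally write SAM.

    All reads must share one length; a length mismatch aborts.
    """
    if hasattr(reads, "seqs"):  # ReadSet
        seqs = reads.seqs
        ids = reads.read_ids
    else:
        records = []
        ids = []
        with pysam.FastxFile(str(reads)) as fh:
            for rec in fh:
                records.append(np.frombuffer(rec.sequence.encode(), np.uint8))
                ids.append(rec.name)
        if records:
            lens = {r.size for r in records}
            if len(lens) > 1:
                raise ValueError(f"inconsistent read lengths in FASTQ: {sorted(lens)}")
            seqs = np.vstack(records)
        else:
            seqs = np.zeros((0, index.k), np.uint8)
    table = align_batch(seqs, index, params) if seqs.shape[0] else _empty_table(
        0, seqs.shape[1] if seqs.ndim == 2 else index.k, index
    )
    table.read_ids = list(ids)
    if sam_path is not None:
        table.to_sam(sam_path, seqs=seqs)
    return table


def classify_alignments(
    table: AlignmentTable, truth, annotation: AnnotationSet
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-read correctness plus a per-isoform alignment-rate table.

    A read is correctly aligned when at least one of its alignments is to an
    isoform of the generating locus whose genomic projection overlaps the
    generating isoform's span; clipping never voids correctness.  ``truth``
    is a ReadSet or a truth DataFrame (read_id, isoform_id columns).
    """
    iso_index = annotation.isoform_index
    if hasattr(truth, "iso_idx"):
        src_iso = truth.iso_idx
        truth_ids = truth.read_ids
    else:
        src_iso = np.array([iso_index[i] for i in truth["isoform_id"]])
        truth_ids = list(truth["read_id"])
    if table.read_ids is not None:
        pos = {rid: i for i, rid in enumerate(truth_ids)}
        orphans = [rid for rid in table.read_ids if rid not in pos]
        if orphans:
            raise ValueError(f"reads absent from truth: {orphans[:5]} ...")
        remap = np.array([pos[rid] for rid in table.read_ids], dtype=np.int64)
        read_of_aln = remap[table.read_idx]
    else:
        read_of_aln = table.read_idx
    n_reads = len(truth_ids)

    arrays = annotation.sequence_arrays()
    locus_idx = arrays["locus_idx"]
    # genomic span of every isoform
    g_lo = np.array([iso.start for iso in annotation.isoforms])
    g_hi = np.array([iso.end for iso in annotation.isoforms])

    same_locus = locus_idx[table.iso_idx] == locus_idx[src_iso[read_of_aln]]
    correct = np.zeros(n_reads, bool)
    cand = np.flatnonzero(same_locus)
    L = table.read_length
    for j in cand:
        i = int(table.iso_idx[j])
        iso = annotation.isoforms[i]
        core = L - int(table.clip_left[j]) - int(table.clip_right[j])
        t1 = int(table.t_start[j]) + 1
        t2 = min(int(table.t_start[j]) + core, iso.length)
        if t1 > iso.length or t2 < 1:
            continue
        intervals = annotation.transcript_to_genomic(iso.isoform_id, max(t1, 1), t2)
        gmin = intervals[0][0]
        gmax = intervals[-1][1]
        src = int(src_iso[read_of_aln[j]])
        if gmin < g_hi[src] and gmax > g_lo[src]:
            correct[read_of_aln[j]] = True

    # per-isoform rates over reads generated
    n_gen = np.bincount(src_iso, minlength=len(annotation.isoforms))
    n_ok = np.bincount(
        src_iso[correct], minlength=len(annotation.isoforms)
    )
    lengths = np.array([iso.length for iso in annotation.isoforms])
    frame = pd.DataFrame(
        dict(
            isoform_id=[iso.isoform_id for iso in annotation.isoforms],
            locus_id=[iso.locus_id for iso in annotation.isoforms],
            n_reads=n_gen,
            n_correct=n_ok,
            rate=np.where(n_gen > 0, n_ok / np.maximum(n_gen, 1), np.nan),
            length=lengths,
        )
    )
    return correct, frame
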