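"""Single-end read simulation under three library-preparation regimes.

* ``uniform`` -- fragment starts are uniform over the transcript and the
  fragment count is proportional to the number of possible start positions,
  so coverage is homogeneous (the idealized library).
* ``coverage_bias`` -- molecules are broken iteratively (each piece larger
  than the size-selection upper bound is split at a uniform point) for a
  bounded number of rounds, then size selection retains pieces inside the
  window.  Molecules near the selected size convert whole; long molecules
  lose mass to pieces outside the window, which over-represents short and
  under-represents long transcripts.
* ``tss_polya`` -- before fragmentation each molecule's 5' end is truncated
  by a uniform offset and a poly-A tail of uniform length is appended,
  mimicking variable transcription starts and polyadenylation.

Reads are the first ``read_length`` bases of a retained fragment's 5' end,
with i.i.d. substitution errors.  Every read carries a truth record with its
generating isoform and its interval in unmodified transcript coordinates
(1-based); reads lying wholly in the poly-A tail have no interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .designs import ExpressionProfile

REGIMES = ("uniform", "coverage_bias", "tss_polya")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class LibraryParams:
    """Library-preparation settings.

    ``frags_per_site`` controls the expected number of fragments per molecule
    in the uniform regime (per possible fragment start position);
    ``breakage_rounds`` bounds the iterative breakage in the coverage-bias
    regime (finite shearing time; pieces still above ``size_window[1]``
    afterwards are removed by size selection).
    """

    regime: str = "uniform"
    read_length: int = 101
    mu_frag: int = 200
    size_window: tuple[int, int] = (150, 300)
    frags_per_site: float = 0.01
    breakage_rounds: int = 7
    delta_max: int = 100
    polya_range: tuple[int, int] = (0, 250)
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        s_lo, s_hi = self.size_window
        if not (s_lo < self.mu_frag < s_hi):
            raise ValueError("size window must satisfy s_lo < mu_frag < s_hi")
        if self.read_length > s_lo:
            raise ValueError("read_length must not exceed the size window lower bound")


def modify_molecule(
    sequence: bytes, params: LibraryParams, rng: np.random.Generator
) -> tuple[bytes, int, int]:
    """Apply 5' truncation and poly-A tailing (tss_polya regime only).

    Returns ``(modified_sequence, offset, polya_len)`` where ``offset`` maps
    positions on the modified molecule back to unmodified transcript
    coordinates (unmodified = modified + offset for the transcript part).
    """
    if params.regime != "tss_polya":
        return sequence, 0, 0
    l = len(sequence)
    offset = int(rng.integers(0, min(params.delta_max, l - 1) + 1))
    lo, hi = params.polya_range
    polya = int(rng.integers(lo, hi + 1))
    return sequence[offset:] + b"A" * polya, offset, polya


def fragment_molecule(
    molecule_length: int, params: LibraryParams, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Fragment one molecule; returns 0-based half-open intervals."""
    if molecule_length < 1:
        raise ValueError("molecule_length must be >= 1")
    if params.regime == "coverage_bias":
        starts, ends, _ = _break_pieces(
            np.zeros(1, np.int64),
            np.array([molecule_length], np.int64),
            np.zeros(1, np.int64),
            params,
            rng,
        )
        return list(zip(starts.tolist(), ends.tolist()))
    l = molecule_length
    n_sites = max(1, l - params.mu_frag + 1)
    count = int(rng.poisson(params.frags_per_site * n_sites))
    if count == 0:
        return []
    flen = _fragment_lengths(count, l, params, rng)
    start = rng.integers(0, l - flen + 1)
    return list(zip(start.tolist(), (start + flen).tolist()))


def _fragment_lengths(
    count: int, mol_len: int | np.ndarray, params: LibraryParams, rng
) -> np.ndarray:
    s_lo, s_hi = params.size_window
    flen = rng.normal(params.mu_frag, params.mu_frag / 5.0, size=count)
    flen = np.clip(np.rint(flen), s_lo, s_hi).astype(np.int64)
    return np.minimum(flen, mol_len)


def _break_pieces(starts, ends, owner, params: LibraryParams, rng):
    """Iterative uniform breakage of pieces above the window, bounded rounds.

    Returns retained (start, end, owner) arrays after size selection.
    """
    s_lo, s_hi = params.size_window
    for _ in range(params.breakage_rounds):
        lens = ends - starts
        big = lens > s_hi
        if not big.any():
            break
        bs, be, bo = starts[big], ends[big], owner[big]
        cut = bs + 1 + (rng.random(bs.size) * (be - bs - 1)).astype(np.int64)
        starts = np.concatenate([starts[~big], bs, cut])
        ends = np.concatenate([ends[~big], cut, be])
        owner = np.concatenate([owner[~big], bo, bo])
    lens = ends - starts
    keep = (lens >= s_lo) & (lens <= s_hi)
    return starts[keep], ends[keep], owner[keep]


@dataclass
class ReadSet:
    """Simulated reads for one sample plus their truth records."""

    sample_id: str
    seqs: np.ndarray  # (n_reads, read_length) uint8 of ACGT letters
    iso_idx: np.ndarray  # generating isoform index into annotation.isoforms
    tx_start: np.ndarray  # 1-based; 0 where the read lies wholly in poly-A
    tx_end: np.ndarray
    contains_polya: np.ndarray
    crosses_modified_start: np.ndarray
    annotation: AnnotationSet

    @property
    def n_reads(self) -> int:
        return self.seqs.shape[0]

    @property
    def read_ids(self) -> list[str]:
        return [f"{self.sample_id}:r{i:07d}" for i in range(self.n_reads)]

    def sequences(self) -> list[bytes]:
        return [row.tobytes() for row in self.seqs]

    def truth_frame(self) -> pd.DataFrame:
        isoforms = self.annotation.isoforms
        iso_ids = np.array([iso.isoform_id for iso in isoforms])
        loc_ids = np.array([iso.locus_id for iso in isoforms])
        return pd.DataFrame(
            dict(
                read_id=self.read_ids,
                isoform_id=iso_ids[self.iso_idx],
                locus_id=loc_ids[self.iso_idx],
                tx_start=self.tx_start,
                tx_end=self.tx_end,
                contains_polya=self.contains_polya,
                crosses_modified_start=self.crosses_modified_start,
            )
        )

    def truth_counts(self) -> np.ndarray:
        """Reads generated per isoform (length = number of isoforms)."""
        return np.bincount(self.iso_idx, minlength=len(self.annotation.isoforms))

    def to_fastq(self, path) -> None:
        qual = "I" * self.seqs.shape[1]
        with open(path, "w") as fh:
            for rid, row in zip(self.read_ids, self.seqs):
                fh.write(f"@{rid}\n{row.tobytes().decode()}\n+\n{qual}\n")

    def truth_to_tsv(self, path) -> None:
        self.truth_frame().to_csv(path, sep="\t", index=False)


def _simulate_sample(
    profile: ExpressionProfile,
    annotation: AnnotationSet,
    params: LibraryParams,
    n_reads: int,
    rng: np.random.Generator,
) -> ReadSet:
    arrays = annotation.sequence_arrays()
    lengths = arrays["lengths"]
    if profile.fractions.size != lengths.size:
        raise ValueError(
            "expression profile does not match annotation "
            f"({profile.fractions.size} fractions vs {lengths.size} isoforms)"
        )
    a = profile.fractions / profile.fractions.sum()
    L = params.read_length
    s_lo, s_hi = params.size_window

    if params.regime == "coverage_bias":
        # molecule-level pool: iterative breakage + size selection, then
        # fragments resampled with replacement to hit exactly n_reads
        pool_iso: list[np.ndarray] = []
        pool_rs: list[np.ndarray] = []
        pool_size = 0
        target_pool = max(3 * n_reads, n_reads + 100)
        fpm = max(0.2, float((a * lengths).sum()) / (2.0 * (s_hi - s_lo)))
        for _attempt in range(60):
            if pool_size >= target_pool:
                break
            n_mol = int(np.ceil((target_pool - pool_size) / fpm)) + 16
            n_mol = min(n_mol, 4_000_000)
            iso = rng.choice(lengths.size, size=n_mol, p=a)
            mol_len = lengths[iso].astype(np.int64)
            fs, fe, owner = _break_pieces(
                np.zeros(n_mol, np.int64), mol_len, np.arange(n_mol), params, rng
            )
            keep = (fe - fs) >= L
            fs, owner = fs[keep], owner[keep]
            pool_iso.append(iso[owner])
            pool_rs.append(fs)
            pool_size += fs.size
            fpm = max(pool_size / max(1, (_attempt + 1) * n_mol), 1e-3)
        if pool_size == 0:
            raise RuntimeError("fragmentation yielded no sequenceable fragments")
        iso_all = np.concatenate(pool_iso)
        rs_all = np.concatenate(pool_rs)
        pick = rng.integers(0, iso_all.size, size=n_reads)
        iso = iso_all[pick]
        rs = rs_all[pick]
        off = np.zeros(n_reads, np.int64)
    else:
        # homogeneous regimes model the deeply subsampled library: each
        # sequenced fragment comes from a distinct molecule, so fragments are
        # i.i.d. draws from the molecule -> fragment generative marginal
        # (fragment count per molecule proportional to max(1, l_mod - mu + 1))
        # and per-isoform read counts are exactly multinomial.
        if params.regime == "tss_polya":
            cap = (lengths + params.polya_range[1] - params.mu_frag + 1).astype(float)
            cap = np.maximum(cap, 1.0)
        else:
            cap = np.maximum(1, lengths - params.mu_frag + 1).astype(float)
        w = a * cap
        p = w / w.sum()
        iso_parts, rs_parts, off_parts = [], [], []
        have = 0
        for _attempt in range(200):
            if have >= n_reads:
                break
            m = int((n_reads - have) * 1.4) + 16
            cand = rng.choice(lengths.size, size=m, p=p)
            mol_len = lengths[cand].astype(np.int64)
            if params.regime == "tss_polya":
                off_c = rng.integers(
                    0, np.minimum(params.delta_max, mol_len - 1) + 1
                )
                polya = rng.integers(
                    params.polya_range[0], params.polya_range[1] + 1, size=m
                )
                mol_len = mol_len - off_c + polya
            else:
                off_c = np.zeros(m, np.int64)
            n_sites = np.maximum(1, mol_len - params.mu_frag + 1)
            accept = rng.random(m) < n_sites / cap[cand]
            flen = _fragment_lengths(m, mol_len, params, rng)
            start = (rng.random(m) * (mol_len - flen + 1)).astype(np.int64)
            keep = accept & (flen >= L)
            iso_parts.append(cand[keep])
            rs_parts.append(start[keep])
            off_parts.append(off_c[keep])
            have += int(keep.sum())
        if have < n_reads:
            raise RuntimeError("fragment sampling failed to reach n_reads")
        iso = np.concatenate(iso_parts)[:n_reads]
        rs = np.concatenate(rs_parts)[:n_reads]
        off = np.concatenate(off_parts)[:n_reads]

    # --- emit read sequences ----------------------------------------------
    tx = arrays["tx"]
    tx_off = arrays["offsets"]
    l_iso = lengths[iso]
    pos_unmod = (off + rs)[:, None] + np.arange(L)[None, :]  # unmodified coords
    in_tx = pos_unmod < l_iso[:, None]
    gather = tx_off[iso][:, None] + np.minimum(pos_unmod, (l_iso - 1)[:, None])
    seqs = np.where(in_tx, tx[gather], ord("A")).astype(np.uint8)

    if params.error_rate > 0:
        err = rng.random(seqs.shape) < params.error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            codes = _CODE[seqs[err]]
            seqs[err] = _BASES[(codes + shift) % 4]

    # --- truth -------------------------------------------------------------
    part_len = l_iso - off - rs  # transcript bases available from read start
    wholly_polya = part_len <= 0
    tx_start = np.where(wholly_polya, 0, off + rs + 1)
    tx_end = np.where(wholly_polya, 0, off + rs + np.minimum(L, np.maximum(part_len, 0)))
    return ReadSet(
        sample_id=profile.sample_id,
        seqs=seqs,
        iso_idx=iso,
        tx_start=tx_start.astype(np.int64),
        tx_end=tx_end.astype(np.int64),
        contains_polya=part_len < L,
        crosses_modified_start=(off > 0) & (rs == 0),
        annotation=annotation,
    )


def simulate_library(
    profiles: list[ExpressionProfile],
    annotation: AnnotationSet,
    params: LibraryParams,
    n_reads: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[ReadSet]:
    """Simulate one FASTQ-equivalent read set per expression profile.

    Each sample gets an independent substream derived from ``seed``; when
    ``out_dir`` is given, FASTQ files and truth sidecar TSVs are written
    there as ``<sample_id>.fastq`` / ``<sample_id>.truth.tsv``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(len(profiles))
    out = []
    for profile, ss in zip(profiles, streams):
        rs = _simulate_sample(
            profile, annotation, params, n_reads, np.random.default_rng(ss)
        )
        if out_dir is not None:
            out_path = Path(out_dir)
            out_path.mkdir(parents=True, exist_ok=True)
            rs.to_fastq(out_path / f"{profile.sample_id}.fastq")
            rs.truth_to_tsv(out_path / f"{profile.sample_id}.truth.tsv")
        out.append(rs)
    return out
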