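"""Canonical k-mer sets, multi-genome core intersection, repeat overlap.

k-mers (k <= 31) are 2-bit packed into uint64 and held as sorted unique
arrays, which keeps intersections deterministic and memory-bounded on
large genomes.  Windows containing N (or any non-ACGT character) are
skipped.  The canonical form of a k-mer is the lexicographic minimum of
itself and its reverse complement (in the 2-bit A<C<G<T order, which
coincides with lexicographic order on the strings).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .io_formats import Interval, SequenceRecord

_MAGIC = b"SYMK"

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_DECODE = "ACGT"


@dataclass(frozen=True)
class KmerConfig:
    k: int = 23
    canonical: bool = True
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError("k must be in [1, 31] for 2-bit packing")


@dataclass
class KmerSet:
    taxon: str
    k: int
    kmers: np.ndarray  # sorted unique uint64

    def __len__(self) -> int:
        return len(self.kmers)


def _encode_windows(seq: str, k: int) -> np.ndarray:
    """All valid k-mer codes of one sequence, in positional order.

    Invalid windows (containing non-ACGT) appear as the sentinel
    ``2**64 - 1`` so callers can keep positional alignment.
    """
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    ok = (
        np.convolve(valid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
    )
    codes64 = np.where(valid, codes, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | codes64[j : j + n]
    out = fwd.copy()
    out[~ok] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return out


def _revcomp_codes(vals: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mers."""
    comp = ~vals  # 2-bit complement: A<->T, C<->G
    out = np.zeros_like(vals)
    for _ in range(k):
        out = (out << np.uint64(2)) | (comp & np.uint64(3))
        comp = comp >> np.uint64(2)
    return out


def _canonicalize(vals: np.ndarray, k: int) -> np.ndarray:
    rc = _revcomp_codes(vals, k)
    return np.minimum(vals, rc)


def _positional_kmers(
    genome: Sequence[SequenceRecord], cfg: KmerConfig
) -> Dict[str, np.ndarray]:
    """Scaffold -> per-position canonical codes (sentinel for invalid)."""
    sentinel = np.uint64(0xFFFFFFFFFFFFFFFF)
    out: Dict[str, np.ndarray] = {}
    for rec in genome:
        vals = _encode_windows(rec.seq, cfg.k)
        if len(vals):
            ok = vals != sentinel
            if cfg.canonical and ok.any():
                vals = vals.copy()
                vals[ok] = _canonicalize(vals[ok], cfg.k)
        out[rec.id] = vals
    return out


def extract_kmers(
    genome: Sequence[SequenceRecord], cfg: Optional[KmerConfig] = None, taxon: str = ""
) -> KmerSet:
    """Distinct (canonical) k-mers over every scaffold of a genome."""
    cfg = cfg or KmerConfig()
    sentinel = np.uint64(0xFFFFFFFFFFFFFFFF)
    parts = []
    for vals in _positional_kmers(genome, cfg).values():
        vals = vals[vals != sentinel]
        if len(vals):
            parts.append(vals)
    if parts:
        kmers = np.unique(np.concatenate(parts))
    else:
        kmers = np.empty(0, dtype=np.uint64)
    return KmerSet(taxon=taxon, k=cfg.k, kmers=kmers)


def core_kmers(sets: Sequence[KmerSet]) -> KmerSet:
    """Intersection across ALL input sets (which must share k)."""
    if not sets:
        raise ValueError("core_kmers needs >= 1 set")
    ks = {s.k for s in sets}
    if len(ks) != 1:
        raise ValueError(f"mixed k values: {sorted(ks)}")
    core = sets[0].kmers
    for s in sets[1:]:
        core = np.intersect1d(core, s.kmers, assume_unique=True)
    return KmerSet(taxon="core", k=sets[0].k, kmers=core)


def repeat_overlap_fraction(
    core: KmerSet,
    genome: Sequence[SequenceRecord],
    repeats: Sequence[Interval],
    cfg: Optional[KmerConfig] = None,
) -> float:
    """Fraction of this genome's core k-mers with >= 1 occurrence in repeats.

    A core k-mer counts as "in repeats" when at least one of its
    occurrences in this genome overlaps a repeat interval by >= 1 bp;
    the denominator is the number of core k-mers present in this genome.
    """
    cfg = cfg or KmerConfig(k=core.k)
    if cfg.k != core.k:
        raise ValueError("KmerConfig.k must match the core set's k")
    sentinel = np.uint64(0xFFFFFFFFFFFFFFFF)
    cover: Dict[str, np.ndarray] = {}
    for rec in genome:
        mask = np.zeros(len(rec.seq), dtype=bool)
        cover[rec.id] = mask
    for iv in repeats:
        if iv.scaffold in cover:
            cover[iv.scaffold][iv.start : iv.end] = True

    present_parts: List[np.ndarray] = []
    inrep_parts: List[np.ndarray] = []
    positional = _positional_kmers(genome, cfg)
    for rec in genome:
        vals = positional[rec.id]
        if not len(vals):
            continue
        ok = vals != sentinel
        if not ok.any():
            continue
        # window [i, i+k) touches a repeat iff any covered base inside
        c = np.concatenate([[0], np.cumsum(cover[rec.id].astype(np.int64))])
        touches = (c[cfg.k :] - c[: -cfg.k]) > 0  # aligned with window starts
        is_core = np.isin(vals, core.kmers)
        sel = ok & is_core
        present_parts.append(vals[sel])
        inrep_parts.append(vals[sel & touches])
    present = (
        np.unique(np.concatenate(present_parts)) if present_parts else np.empty(0)
    )
    if len(present) == 0:
        return 0.0
    inrep = np.unique(np.concatenate(inrep_parts)) if inrep_parts else np.empty(0)
    return len(inrep) / len(present)


# ---------------------------------------------------------------------------
# string helpers and the on-disk set format


def kmer_to_string(val: int, k: int) -> str:
    chars = []
    for shift in range(2 * (k - 1), -2, -2):
        chars.append(_DECODE[(val >> shift) & 3])
    return "".join(chars)


def string_to_kmer(s: str) -> int:
    val = 0
    for ch in s:
        val = (val << 2) | int(_CODE[ord(ch)])
    return val


def write_kmer_set(kset: KmerSet, path) -> None:
    """Little-endian binary: magic 'SYMK', uint8 k, uint64 count, payload."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<BQ", kset.k, len(kset.kmers)))
        fh.write(kset.kmers.astype("<u8").tobytes())


def read_kmer_set(path, taxon: str = "") -> KmerSet:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a k-mer set file")
        k, count = struct.unpack("<BQ", fh.read(9))
        kmers = np.frombuffer(fh.read(8 * count), dtype="<u8").astype(np.uint64)
    return KmerSet(taxon=taxon, k=k, kmers=kmers)
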