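"""Canonical k-mer counting and read-vs-assembly copy-number spectra.

K-mers are counted strand-canonically: each window is represented by the
lexicographically smaller of itself and its reverse complement. With the
2-bit encoding A=0 < C=1 < G=2 < T=3 and the first base in the most
significant position, numeric order on packed codes equals lexicographic
order on strings, so canonicalization is ``min(code, rc_code)``.

``k`` is capped at 31 so every k-mer packs into one unsigned 64-bit
integer; counting, lookup and set operations are then plain sorted-array
operations in numpy. Windows containing ``N`` are skipped entirely.

The joint histogram of read multiplicity versus assembly copy number
(:class:`CopyNumberMatrix`) is the central diagnostic for haplotig
detection: content that occurs twice in the assembly but at single-copy
read depth indicates an assembled alternate haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Sequence, Tuple, Union

import numpy as np

from .io_formats import SeqRecord

__all__ = [
    "KmerCountTable",
    "KmerSpectrum",
    "CopyNumberMatrix",
    "count_kmers",
    "spectrum",
    "spectra_cn",
]

PathLike = Union[str, Path]

# base byte -> 2-bit code; 4 marks anything that is not A/C/G/T
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c

_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

# chunk size (in bases) for streaming large read sets through the counter
_CHUNK_BASES = 48_000_000


def _check_k(k: int) -> None:
    if not (1 <= k <= 31) or k % 2 == 0:
        raise ValueError(f"k must be odd and in [1, 31], got {k}")


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence string to 2-bit codes (4 for non-ACGT)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


try:  # single-pass rolling packer; the numpy fallback is ~10x slower
    from numba import njit as _njit

    @_njit(cache=True)
    def _pack_windows_numba(codes, k):  # pragma: no cover - jitted
        n = len(codes) - k + 1
        fwd = np.zeros(n, dtype=np.uint64)
        rev = np.zeros(n, dtype=np.uint64)
        ok = np.zeros(n, dtype=np.bool_)
        mask = np.uint64((1 << (2 * k)) - 1) if k < 32 else np.uint64(0xFFFFFFFFFFFFFFFF)
        hi_shift = np.uint64(2 * (k - 1))
        f = np.uint64(0)
        r = np.uint64(0)
        last_bad = -1
        for i in range(len(codes)):
            c = codes[i]
            if c == 4:
                last_bad = i
                c = 0
            f = ((f << np.uint64(2)) | np.uint64(c)) & mask
            r = (r >> np.uint64(2)) | (np.uint64(3 - c) << hi_shift)
            p = i - k + 1
            if p >= 0:
                fwd[p] = f
                rev[p] = r
                ok[p] = last_bad < p
        return fwd, rev, ok

except ImportError:  # pragma: no cover
    _pack_windows_numba = None


def _pack_windows_numpy(codes: np.ndarray, k: int):
    n = len(codes) - k + 1
    bad = (codes == 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    ok = (cs[k:] - cs[:-k]) == 0
    safe = np.where(codes == 4, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : j + n]
        rev |= (three - safe[j : j + n]) << np.uint64(2 * j)
    return fwd, rev, ok


def window_codes(codes: np.ndarray, k: int, canonical: bool = True):
    """Packed codes of all valid (N-free) k-mer windows of ``codes``.

    Returns canonical codes by default; with ``canonical=False`` returns a
    ``(fwd, rev, valid_positions)`` tuple used by the minimizer indexer.
    """
    n = len(codes) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty if canonical else (empty, empty, np.empty(0, dtype=np.int64))
    if _pack_windows_numba is not None:
        fwd, rev, ok = _pack_windows_numba(codes, k)
    else:
        fwd, rev, ok = _pack_windows_numpy(codes, k)
    if canonical:
        return np.minimum(fwd, rev)[ok]
    pos = np.flatnonzero(ok)
    return fwd[pos], rev[pos], pos


def decode_kmer(code: int, k: int) -> str:
    """Unpack a 2-bit k-mer code back to its string."""
    out = bytearray(k)
    c = int(code)
    for i in range(k - 1, -1, -1):
        out[i] = _CODE_BASE[c & 3]
        c >>= 2
    return out.decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def canonical(seq: str) -> str:
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


@dataclass
class KmerCountTable:
    """Counts of canonical k-mers for one sequence collection.

    Stored as a sorted ``uint64`` code array with parallel counts, which
    makes membership lookup a binary search and table intersection a
    single ``searchsorted`` pass.
    """

    k: int
    codes: np.ndarray  # sorted uint64 canonical k-mer codes
    counts: np.ndarray  # int64, parallel to codes

    @property
    def n_distinct(self) -> int:
        return int(len(self.codes))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum()) if len(self.counts) else 0

    def __len__(self) -> int:
        return self.n_distinct

    def get(self, kmer: str) -> int:
        """Count of one k-mer string (canonicalized before lookup)."""
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != table k {self.k}")
        codes = window_codes(encode_bases(kmer.upper()), self.k)
        if len(codes) == 0:  # contains N
            return 0
        return int(self.lookup_codes(codes)[0])

    def __getitem__(self, kmer: str) -> int:
        return self.get(kmer)

    def lookup_codes(self, query: np.ndarray) -> np.ndarray:
        """Counts for an array of canonical codes (0 where absent)."""
        idx = np.searchsorted(self.codes, query)
        idx_c = np.minimum(idx, len(self.codes) - 1) if len(self.codes) else idx
        if len(self.codes) == 0:
            return np.zeros(len(query), dtype=np.int64)
        hit = self.codes[idx_c] == query
        out = np.where(hit, self.counts[idx_c], 0)
        return out.astype(np.int64)

    def items(self) -> Iterator[Tuple[str, int]]:
        for code, count in zip(self.codes, self.counts):
            yield decode_kmer(int(code), self.k), int(count)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.items())

    def to_tsv(self, path: PathLike) -> None:
        """Write a sorted two-column (kmer, count) TSV."""
        with open(path, "w") as out:
            out.write(f"# k={self.k}\n")
            for kmer, count in self.items():
                out.write(f"{kmer}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: PathLike) -> "KmerCountTable":
        k = None
        kmers: List[str] = []
        counts: List[int] = []
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("k="):
                            k = int(tok[2:])
                    continue
                if not line:
                    continue
                kmer, count = line.split("\t")
                kmers.append(kmer)
                counts.append(int(count))
        if k is None:
            if not kmers:
                raise ValueError(f"{path}: empty table with no '# k=' header")
            k = len(kmers[0])
        codes = np.array(
            [int(np.uint64(c)) for c in (window_codes(encode_bases(s), k)[0] for s in kmers)],
            dtype=np.uint64,
        ) if kmers else np.empty(0, dtype=np.uint64)
        order = np.argsort(codes)
        return cls(k=k, codes=codes[order], counts=np.asarray(counts, dtype=np.int64)[order])

    def to_npz(self, path: PathLike) -> None:
        """Binary cache for large tables."""
        np.savez_compressed(path, k=self.k, codes=self.codes, counts=self.counts)

    @classmethod
    def from_npz(cls, path: PathLike) -> "KmerCountTable":
        data = np.load(path)
        return cls(k=int(data["k"]), codes=data["codes"], counts=data["counts"])


@dataclass
class KmerSpectrum:
    """Histogram of read multiplicity: distinct k-mers per count value."""

    k: int
    multiplicity: np.ndarray  # sorted, >= 1
    n_kmers: np.ndarray  # distinct k-mers at each multiplicity

    @property
    def hist(self) -> Dict[int, int]:
        return {int(m): int(n) for m, n in zip(self.multiplicity, self.n_kmers)}

    @property
    def n_distinct(self) -> int:
        return int(self.n_kmers.sum()) if len(self.n_kmers) else 0

    def dense(self, max_m: int | None = None) -> np.ndarray:
        """Counts on the dense grid 1..max_m (index 0 unused)."""
        if max_m is None:
            max_m = int(self.multiplicity.max()) if len(self.multiplicity) else 0
        out = np.zeros(max_m + 1, dtype=np.float64)
        keep = self.multiplicity <= max_m
        out[self.multiplicity[keep]] = self.n_kmers[keep]
        return out

    def to_tsv(self, path: PathLike) -> None:
        with open(path, "w") as out:
            out.write(f"# k={self.k}\n")
            out.write("multiplicity\tdistinct_kmers\n")
            for m, n in zip(self.multiplicity, self.n_kmers):
                out.write(f"{m}\t{n}\n")

    @classmethod
    def from_tsv(cls, path: PathLike) -> "KmerSpectrum":
        k = 0
        ms: List[int] = []
        ns: List[int] = []
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("k="):
                            k = int(tok[2:])
                    continue
                if not line or line.startswith("multiplicity"):
                    continue
                m, n = line.split("\t")
                ms.append(int(m))
                ns.append(int(n))
        return cls(k=k, multiplicity=np.asarray(ms, dtype=np.int64), n_kmers=np.asarray(ns, dtype=np.int64))


@dataclass
class CopyNumberMatrix:
    """Joint histogram of (assembly copy, read multiplicity) over read k-mers.

    Assembly copies above ``max_copy`` are accumulated in the ``max_copy``
    row. ``assembly_only`` counts k-mers present in the assembly but absent
    from the reads (typically assembly errors or collapsed repeats).
    """

    k: int
    max_copy: int
    copy: np.ndarray  # per-cell assembly copy (0..max_copy)
    mult: np.ndarray  # per-cell read multiplicity (>= 1)
    n_kmers: np.ndarray  # distinct read k-mers in the cell
    assembly_only: int

    @property
    def cells(self) -> Dict[Tuple[int, int], int]:
        return {
            (int(c), int(m)): int(n)
            for c, m, n in zip(self.copy, self.mult, self.n_kmers)
        }

    @property
    def total_mass(self) -> int:
        return int(self.n_kmers.sum()) if len(self.n_kmers) else 0

    def band_mass(self, copy_min: int, copy_max: int, m_lo: float, m_hi: float) -> int:
        """Distinct-k-mer mass with copy in [copy_min, copy_max] and mult in [m_lo, m_hi]."""
        sel = (
            (self.copy >= copy_min)
            & (self.copy <= copy_max)
            & (self.mult >= m_lo)
            & (self.mult <= m_hi)
        )
        return int(self.n_kmers[sel].sum())

    def to_tsv(self, path: PathLike) -> None:
        """Dense TSV: one row per assembly copy 0..max_copy, columns m=1..max."""
        max_m = int(self.mult.max()) if len(self.mult) else 1
        dense = np.zeros((self.max_copy + 1, max_m + 1), dtype=np.int64)
        dense[self.copy, self.mult] = self.n_kmers
        with open(path, "w") as out:
            out.write(f"# k={self.k} max_copy={self.max_copy} assembly_only={self.assembly_only}\n")
            out.write("copy\t" + "\t".join(str(m) for m in range(1, max_m + 1)) + "\n")
            for c in range(self.max_copy + 1):
                out.write(str(c) + "\t" + "\t".join(str(v) for v in dense[c, 1:]) + "\n")

    @classmethod
    def from_tsv(cls, path: PathLike) -> "CopyNumberMatrix":
        k = 0
        max_copy = 0
        assembly_only = 0
        rows: List[List[int]] = []
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line[1:].split():
                        key, _, val = tok.partition("=")
                        if key == "k":
                            k = int(val)
                        elif key == "max_copy":
                            max_copy = int(val)
                        elif key == "assembly_only":
                            assembly_only = int(val)
                    continue
                if not line or line.startswith("copy"):
                    continue
                rows.append([int(v) for v in line.split("\t")])
        cs: List[int] = []
        ms: List[int] = []
        ns: List[int] = []
        for row in rows:
            c = row[0]
            for m, n in enumerate(row[1:], start=1):
                if n:
                    cs.append(c)
                    ms.append(m)
                    ns.append(n)
        return cls(
            k=k,
            max_copy=max_copy,
            copy=np.asarray(cs, dtype=np.int64),
            mult=np.asarray(ms, dtype=np.int64),
            n_kmers=np.asarray(ns, dtype=np.int64),
            assembly_only=assembly_only,
        )


def _merge_counts(
    codes_a: np.ndarray, counts_a: np.ndarray, codes_b: np.ndarray, counts_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    codes = np.concatenate([codes_a, codes_b])
    counts = np.concatenate([counts_a, counts_b])
    uniq, inverse = np.unique(codes, return_inverse=True)
    merged = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(merged, inverse, counts)
    return uniq, merged


def count_kmers(records: Sequence[SeqRecord], k: int) -> KmerCountTable:
    """Count canonical k-mers over a sequence collection.

    Sequences are concatenated with ``N`` separators (so no window spans a
    record boundary) and processed in large chunks; per-chunk counts are
    merged into one sorted table. Deterministic for fixed input.
    """
    _check_k(k)
    codes_acc = np.empty(0, dtype=np.uint64)
    counts_acc = np.empty(0, dtype=np.int64)
    chunk: List[str] = []
    chunk_bases = 0

    def flush(chunk: List[str]) -> Tuple[np.ndarray, np.ndarray]:
        joined = "N".join(chunk)
        win = window_codes(encode_bases(joined), k)
        return np.unique(win, return_counts=True)

    for rec in records:
        chunk.append(rec.seq)
        chunk_bases += len(rec.seq)
        if chunk_bases >= _CHUNK_BASES:
            codes_acc, counts_acc = _merge_counts(codes_acc, counts_acc, *flush(chunk))
            chunk = []
            chunk_bases = 0
    if chunk:
        codes_acc, counts_acc = _merge_counts(codes_acc, counts_acc, *flush(chunk))
    return KmerCountTable(k=k, codes=codes_acc, counts=counts_acc)


def spectrum(table: KmerCountTable) -> KmerSpectrum:
    """Multiplicity histogram of a count table."""
    if table.n_distinct == 0:
        return KmerSpectrum(
            k=table.k,
            multiplicity=np.empty(0, dtype=np.int64),
            n_kmers=np.empty(0, dtype=np.int64),
        )
    mult, n = np.unique(table.counts, return_counts=True)
    return KmerSpectrum(k=table.k, multiplicity=mult.astype(np.int64), n_kmers=n.astype(np.int64))


def spectra_cn(
    read_table: KmerCountTable, asm_table: KmerCountTable, max_copy: int = 10
) -> CopyNumberMatrix:
    """Joint (assembly copy, read multiplicity) histogram over read k-mers.

    Every distinct read k-mer lands in exactly one cell: its assembly copy
    (0 if absent, clipped at ``max_copy``) crossed with its read
    multiplicity. Mass is therefore conserved: the matrix total equals the
    read table's distinct-k-mer count.
    """
    if read_table.k != asm_table.k:
        raise ValueError(f"k mismatch: reads k={read_table.k}, assembly k={asm_table.k}")
    if max_copy < 1:
        raise ValueError("max_copy must be >= 1")
    copies = np.minimum(asm_table.lookup_codes(read_table.codes), max_copy)
    mult = read_table.counts
    key = copies.astype(np.int64) * (np.int64(1) << 32) + mult
    uniq, counts = np.unique(key, return_counts=True)
    cell_copy = (uniq >> 32).astype(np.int64)
    cell_mult = (uniq & ((np.int64(1) << 32) - 1)).astype(np.int64)
    # assembly k-mers never seen in the reads
    shared = int(np.count_nonzero(copies)) if len(copies) else 0
    # number of distinct asm codes that matched a read code == number of
    # read codes with copy > 0 (codes are unique within each table)
    assembly_only = asm_table.n_distinct - shared
    return CopyNumberMatrix(
        k=read_table.k,
        max_copy=max_copy,
        copy=cell_copy,
        mult=cell_mult,
        n_kmers=counts.astype(np.int64),
        assembly_only=assembly_only,
    )
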