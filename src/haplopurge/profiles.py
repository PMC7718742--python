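"""Per-scaffold k-mer statistics and the GC/coverage screening table.

For each scaffold, the multiset of its valid k-mer windows is looked up in
the read table (multiplicity, 0 when absent) and in the assembly table
(copy number), and the median of each multiset is recorded. A scaffold
whose median assembly copy is 2 while its median read multiplicity sits in
the homozygous band is the haplotig signature the pipeline flags.

The screening table adds robust z-scores of coverage and GC against the
length-weighted assembly distribution — the analytics behind GC/coverage
("blobplot"-style) contamination screens, minus taxonomy annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import SeqRecord
from .kmer import KmerCountTable, encode_bases, window_codes

__all__ = ["ScaffoldProfile", "profile_scaffolds", "gc_coverage_table"]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ScaffoldProfile:
    """Length, GC and median k-mer statistics for one scaffold."""

    id: str
    length: int
    gc_fraction: float
    n_kmers: int
    median_read_mult: int
    median_asm_copy: int


def _lower_median(values: np.ndarray) -> int:
    """Median taken as the lower middle value for even-sized multisets.

    Keeps medians integral so predicates like ``median_asm_copy == 2``
    are exact.
    """
    n = len(values)
    if n == 0:
        return 0
    return int(np.partition(values, (n - 1) // 2)[(n - 1) // 2])


def _gc_fraction(codes: np.ndarray) -> float:
    acgt = codes != 4
    n_acgt = int(acgt.sum())
    if n_acgt == 0:
        return 0.0
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n_acgt


def profile_scaffolds(
    assembly: Sequence[SeqRecord],
    read_table: KmerCountTable,
    asm_table: KmerCountTable,
) -> List[ScaffoldProfile]:
    """Compute per-scaffold medians of read multiplicity and assembly copy.

    ``asm_table`` must have been counted from exactly this assembly, so
    every valid scaffold window occurs at least once there. Scaffolds
    shorter than k (or all-N) get ``n_kmers = 0`` and zero medians; they
    are reported but never flagged downstream.
    """
    if read_table.k != asm_table.k:
        raise ValueError(f"k mismatch: reads k={read_table.k}, assembly k={asm_table.k}")
    k = read_table.k
    profiles: List[ScaffoldProfile] = []
    for rec in assembly:
        codes = encode_bases(rec.seq)
        win = window_codes(codes, k)
        if len(win) == 0:
            profiles.append(
                ScaffoldProfile(
                    id=rec.id,
                    length=len(rec.seq),
                    gc_fraction=_gc_fraction(codes),
                    n_kmers=0,
                    median_read_mult=0,
                    median_asm_copy=0,
                )
            )
            continue
        read_mult = read_table.lookup_codes(win)
        asm_copy = asm_table.lookup_codes(win)
        profiles.append(
            ScaffoldProfile(
                id=rec.id,
                length=len(rec.seq),
                gc_fraction=_gc_fraction(codes),
                n_kmers=int(len(win)),
                median_read_mult=_lower_median(read_mult),
                median_asm_copy=_lower_median(asm_copy),
            )
        )
    return profiles


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order].astype(float)
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def _robust_z(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """z-scores against the length-weighted median/MAD of the assembly."""
    center = _weighted_median(values, weights)
    mad = _weighted_median(np.abs(values - center), weights)
    scale = 1.4826 * mad
    if scale <= 0:
        return np.zeros_like(values, dtype=float)
    return (values - center) / scale


def gc_coverage_table(profiles: Sequence[ScaffoldProfile]) -> pd.DataFrame:
    """Screening table: per-scaffold GC, coverage proxy and robust z-scores.

    Median read k-mer multiplicity serves as the coverage proxy (no read
    alignment involved). Scaffolds with aberrant ``coverage_z``/``gc_z``
    are candidates for manual contamination review.
    """
    df = pd.DataFrame(
        {
            "scaffold_id": [p.id for p in profiles],
            "length": [p.length for p in profiles],
            "gc_fraction": [p.gc_fraction for p in profiles],
            "median_read_mult": [p.median_read_mult for p in profiles],
        }
    )
    if len(df) == 0:
        df["coverage_z"] = []
        df["gc_z"] = []
        return df
    weights = df["length"].to_numpy()
    df["coverage_z"] = _robust_z(df["median_read_mult"].to_numpy(float), weights)
    df["gc_z"] = _robust_z(df["gc_fraction"].to_numpy(float), weights)
    return df


def profiles_to_tsv(
    profiles: Sequence[ScaffoldProfile], path: PathLike, k: int, note: str = ""
) -> None:
    with open(path, "w") as out:
        out.write(f"# k={k}{(' ' + note) if note else ''}\n")
        out.write("scaffold_id\tlength\tgc_fraction\tn_kmers\tmedian_read_mult\tmedian_asm_copy\n")
        for p in profiles:
            out.write(
                f"{p.id}\t{p.length}\t{p.gc_fraction:.4f}\t{p.n_kmers}\t"
                f"{p.median_read_mult}\t{p.median_asm_copy}\n"
            )
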