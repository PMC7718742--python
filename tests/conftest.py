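"""Shared fixtures and naive reference implementations.

The naive functions recompute k-mer quantities by direct per-window
enumeration on strings; they are deliberately independent of the packed
array implementation they are used to check.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from haplopurge import SeqRecord, SimulationSpec

_COMP = str.maketrans("ACGTN", "TGCAN")


def naive_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_canonical(kmer: str) -> str:
    rc = naive_revcomp(kmer)
    return kmer if kmer <= rc else rc


def naive_count(seqs: Sequence[str], k: int) -> Dict[str, int]:
    counts: Counter = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) <= set("ACGT"):
                counts[naive_canonical(window)] += 1
    return dict(counts)


def naive_spectrum(counts: Dict[str, int]) -> Dict[int, int]:
    hist: Counter = Counter()
    for c in counts.values():
        hist[c] += 1
    return dict(hist)


def naive_spectra_cn(
    read_counts: Dict[str, int], asm_counts: Dict[str, int], max_copy: int
) -> Tuple[Dict[Tuple[int, int], int], int]:
    cells: Counter = Counter()
    for kmer, m in read_counts.items():
        c = min(asm_counts.get(kmer, 0), max_copy)
        cells[(c, m)] += 1
    assembly_only = sum(1 for kmer in asm_counts if kmer not in read_counts)
    return dict(cells), assembly_only


def naive_lower_median(values: Sequence[int]) -> int:
    if not values:
        return 0
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def naive_scaffold_medians(
    scaffold: str, read_counts: Dict[str, int], asm_counts: Dict[str, int], k: int
) -> Tuple[int, int]:
    read_mult: List[int] = []
    asm_copy: List[int] = []
    for i in range(len(scaffold) - k + 1):
        window = scaffold[i : i + k]
        if set(window) <= set("ACGT"):
            canon = naive_canonical(window)
            read_mult.append(read_counts.get(canon, 0))
            asm_copy.append(asm_counts.get(canon, 0))
    return naive_lower_median(read_mult), naive_lower_median(asm_copy)


def random_seq(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A small but fully featured diploid dataset spec for integration tests."""
    return SimulationSpec(
        seed=11,
        genome_length=300_000,
        segment_length_mean=15_000,
        het_rate=0.01,
        haplotig_fraction=0.5,
        depth=40.0,
        read_length=100,
        error_rate=0.005,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """(assembly, truth, reads) generated once per session."""
    from haplopurge import build_mock_assembly, simulate_diploid, simulate_reads

    haps = simulate_diploid(small_spec)
    assembly, truth = build_mock_assembly(haps, small_spec)
    reads = simulate_reads(haps, small_spec)
    return assembly, truth, reads
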