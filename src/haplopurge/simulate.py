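"""Synthetic diploid genomes, mock assemblies with planted haplotigs, and
error-bearing short reads — with full truth labels.

The generator reproduces the specific assembly pathology the pipeline
targets: a diploid genome whose heterozygous regions were assembled twice
(once per haplotype), so that the duplicated copies carry assembly k-mer
copy 2 at homozygous read depth. Defaults model a moderately heterozygous
insect genome sequenced with PCR-free short reads:

- genome 5 Mb, GC 0.32 (AT-rich, typical of insect genomes)
- heterozygosity 1% (substitutions only)
- contig scale 50 kb (exponential segment lengths, truncated to
  [5 kb, 10x mean])
- 30% of variant-bearing segments also emit a trimmed alternate-haplotype
  copy (the planted haplotig)
- 40x total depth of 100 bp single-end reads at 0.5% substitution error

All outputs are pure functions of the spec (including its mandatory
seed); independent random streams are derived per stage so each operation
is reproducible regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .io_formats import SeqRecord, write_fasta, write_fastq

__all__ = [
    "SimulationSpec",
    "TruthRecord",
    "TruthSet",
    "simulate_diploid",
    "build_mock_assembly",
    "simulate_reads",
    "write_simulation",
]

PathLike = Union[str, Path]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic diploid dataset. ``seed`` is mandatory."""

    seed: int
    genome_length: int = 5_000_000
    gc: float = 0.32
    het_rate: float = 0.01
    segment_length_mean: int = 50_000
    haplotig_fraction: float = 0.3
    depth: float = 40.0
    read_length: int = 100
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0 <= self.het_rate <= 0.05:
            raise ValueError(f"het_rate must be in [0, 0.05], got {self.het_rate}")
        if not 0 <= self.haplotig_fraction <= 1:
            raise ValueError(
                f"haplotig_fraction must be in [0, 1], got {self.haplotig_fraction}"
            )
        if self.depth <= 0:
            raise ValueError(f"depth must be > 0, got {self.depth}")
        if not 0 < self.gc < 1:
            raise ValueError(f"gc must be in (0, 1), got {self.gc}")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of one assembly record. Coordinates are 0-based, half-open
    on the source haplotype."""

    record_id: str
    role: str  # "primary" | "haplotig"
    haplotype: str  # "A" | "B"
    start: int
    end: int
    partner_id: str  # primary partner for haplotigs, "" for primaries


@dataclass
class TruthSet:
    records: List[TruthRecord]

    def by_role(self, role: str) -> List[TruthRecord]:
        return [r for r in self.records if r.role == role]

    @property
    def haplotig_ids(self) -> List[str]:
        return [r.record_id for r in self.by_role("haplotig")]

    @property
    def primary_ids(self) -> List[str]:
        return [r.record_id for r in self.by_role("primary")]

    def to_tsv(self, path: PathLike) -> None:
        with open(path, "w") as out:
            out.write("record_id\trole\thaplotype\tstart\tend\tpartner_id\n")
            for r in self.records:
                out.write(
                    f"{r.record_id}\t{r.role}\t{r.haplotype}\t{r.start}\t{r.end}\t{r.partner_id}\n"
                )

    @classmethod
    def from_tsv(cls, path: PathLike) -> "TruthSet":
        records = []
        with open(path) as handle:
            header = handle.readline()
            for line in handle:
                rec_id, role, hap, start, end, partner = line.rstrip("\n").split("\t")
                records.append(TruthRecord(rec_id, role, hap, int(start), int(end), partner))
        return cls(records)


def _rng(spec: SimulationSpec, stage: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, stage)."""
    tag = sum(ord(c) * 131**i for i, c in enumerate(stage)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([spec.seed, tag]))


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_diploid(spec: SimulationSpec) -> Tuple[str, str, np.ndarray]:
    """Draw the two haplotypes of a diploid genome.

    Haplotype A is i.i.d. with P(G or C) = ``gc``; haplotype B equals A
    with Bernoulli(``het_rate``) substitutions to a uniformly chosen
    different base. Returns (hap_A, hap_B, variant_positions).
    """
    rng = _rng(spec, "diploid")
    at = (1.0 - spec.gc) / 2.0
    gc2 = spec.gc / 2.0
    hap_a = rng.choice(4, size=spec.genome_length, p=[at, gc2, gc2, at]).astype(np.uint8)
    variants = np.flatnonzero(rng.random(spec.genome_length) < spec.het_rate)
    hap_b = hap_a.copy()
    if len(variants):
        shift = rng.integers(1, 4, size=len(variants)).astype(np.uint8)
        hap_b[variants] = (hap_a[variants] + shift) % 4
    return _codes_to_str(hap_a), _codes_to_str(hap_b), variants


def _segment_bounds(spec: SimulationSpec, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Cut the genome into exponential-length segments, truncated to
    [5 kb, 10x mean]; a short final remainder is merged into the previous
    segment."""
    lo = min(5_000, spec.genome_length)
    hi = 10 * spec.segment_length_mean
    bounds: List[Tuple[int, int]] = []
    start = 0
    while start < spec.genome_length:
        length = int(np.clip(rng.exponential(spec.segment_length_mean), lo, hi))
        end = min(start + length, spec.genome_length)
        if spec.genome_length - end < lo and end < spec.genome_length:
            end = spec.genome_length
        bounds.append((start, end))
        start = end
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < lo:
        prev = bounds[-2]
        bounds[-2:] = [(prev[0], bounds[-1][1])]
    return bounds


def build_mock_assembly(
    haplotypes: Tuple[str, str, np.ndarray], spec: SimulationSpec
) -> Tuple[List[SeqRecord], TruthSet]:
    """Emit a mock assembly: every segment as a haplotype-A primary contig,
    plus (for a ``haplotig_fraction`` of variant-bearing segments) a trimmed
    haplotype-B copy spanning a random 30-90% sub-interval — the planted
    haplotig."""
    hap_a, hap_b, variants = haplotypes
    rng = _rng(spec, "assembly")
    records: List[SeqRecord] = []
    truth: List[TruthRecord] = []
    for i, (start, end) in enumerate(_segment_bounds(spec, rng)):
        pid = f"contig_{i:04d}"
        records.append(SeqRecord(pid, hap_a[start:end]))
        truth.append(TruthRecord(pid, "primary", "A", start, end, ""))
        n_var = int(np.searchsorted(variants, end) - np.searchsorted(variants, start))
        emit = rng.random() < spec.haplotig_fraction
        if n_var >= 1 and emit:
            seg_len = end - start
            hap_len = int(rng.uniform(0.3, 0.9) * seg_len)
            if hap_len < 1:
                continue
            off = int(rng.integers(0, seg_len - hap_len + 1))
            hid = f"haplotig_{i:04d}"
            records.append(SeqRecord(hid, hap_b[start + off : start + off + hap_len]))
            truth.append(TruthRecord(hid, "haplotig", "B", start + off, start + off + hap_len, pid))
    return records, TruthSet(truth)


def simulate_reads(
    haplotypes: Tuple[str, str, np.ndarray], spec: SimulationSpec
) -> List[SeqRecord]:
    """Sample single-end reads uniformly from both haplotypes (depth/2
    each) with uniform substitution errors at ``error_rate``. Read ids
    encode haplotype and start position for debugging."""
    hap_a, hap_b, _ = haplotypes
    if spec.read_length > spec.genome_length:
        raise ValueError(
            f"read_length {spec.read_length} exceeds genome_length {spec.genome_length}"
        )
    rng = _rng(spec, "reads")
    rl = spec.read_length
    n_per_hap = int(round(spec.depth / 2.0 * spec.genome_length / rl))
    reads: List[SeqRecord] = []
    for hap_name, hap_seq in (("A", hap_a), ("B", hap_b)):
        codes = np.frombuffer(hap_seq.encode("ascii"), dtype=np.uint8)
        codes = np.searchsorted(_BASES, codes)  # ACGT guaranteed by construction
        starts = rng.integers(0, spec.genome_length - rl + 1, size=n_per_hap)
        matrix = codes[starts[:, None] + np.arange(rl)[None, :]].astype(np.uint8)
        if spec.error_rate > 0:
            err = rng.random(matrix.shape) < spec.error_rate
            ri, ci = np.nonzero(err)
            if len(ri):
                shift = rng.integers(1, 4, size=len(ri)).astype(np.uint8)
                matrix[ri, ci] = (matrix[ri, ci] + shift) % 4
        flat = _BASES[matrix].tobytes()
        for j in range(n_per_hap):
            reads.append(
                SeqRecord(
                    f"r{hap_name}_{j:07d}_{starts[j]}",
                    flat[j * rl : (j + 1) * rl].decode("ascii"),
                )
            )
    return reads


def write_simulation(spec: SimulationSpec, prefix: PathLike) -> Dict[str, str]:
    """Generate a full dataset and write haplotypes, assembly, reads and
    truth labels under ``prefix``. Returns the output paths."""
    prefix = str(prefix)
    haps = simulate_diploid(spec)
    assembly, truth = build_mock_assembly(haps, spec)
    reads = simulate_reads(haps, spec)
    paths = {
        "haplotypes": f"{prefix}.haplotypes.fasta",
        "assembly": f"{prefix}.assembly.fasta",
        "reads": f"{prefix}.reads.fastq",
        "truth": f"{prefix}.truth.tsv",
    }
    write_fasta(
        [SeqRecord("haplotype_A", haps[0]), SeqRecord("haplotype_B", haps[1])],
        paths["haplotypes"],
    )
    write_fasta(assembly, paths["assembly"])
    write_fastq(reads, paths["reads"])
    truth.to_tsv(paths["truth"])
    return paths


def expected_kmer_depth(spec: SimulationSpec, k: int) -> float:
    """Expected homozygous k-mer multiplicity: C·(L−k+1)/L·(1−e)^k."""
    return (
        spec.depth
        * (spec.read_length - k + 1)
        / spec.read_length
        * (1.0 - spec.error_rate) ** k
    )
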