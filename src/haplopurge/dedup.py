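"""Haplotig flagging, removal and post-deduplication validation.

The pipeline mirrors a k-mer-based assembly deduplication workflow:

1. count canonical k-mers in the reads and in the assembly;
2. decompose the read spectrum to locate the homozygous-coverage band;
3. profile every scaffold (median read multiplicity, median assembly
   copy);
4. flag scaffolds whose median assembly copy equals 2 while their median
   read multiplicity lies inside the homozygous band — the signature of
   an assembled alternate haplotype;
5. remove a flagged scaffold iff it is contained in a strictly longer
   scaffold at ≥ 75% identity and ≥ 25% query coverage (both inclusive);
6. recompute the copy-number spectrum on the kept assembly and verify
   that duplicated homozygous content decreased while essentially no
   single-copy homozygous content was lost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .io_formats import SeqRecord, write_fasta
from .kmer import CopyNumberMatrix, KmerCountTable, count_kmers, spectra_cn, spectrum
from .containment import ContainmentHit, find_containments, index_minimizers
from .profiles import ScaffoldProfile, profile_scaffolds, profiles_to_tsv
from .spectrum_model import SpectrumFit, fit_spectrum

__all__ = [
    "DedupParams",
    "DedupDecision",
    "ValidationMetrics",
    "DedupReport",
    "flag_haplotigs",
    "hit_passes_thresholds",
    "deduplicate",
    "validate_dedup",
]

PathLike = Union[str, Path]


@dataclass
class DedupParams:
    """Tunable parameters of the deduplication pipeline.

    Defaults follow the published workflow: haplotig candidates have
    median assembly k-mer copy exactly ``target_copy`` (2), and removal
    requires containment at ≥ 75% identity and ≥ 25% query coverage.
    """

    k: int = 27
    target_copy: int = 2
    min_identity: float = 0.75
    min_query_coverage: float = 0.25
    max_copy: int = 10
    n_components: int = 3
    anchor_k: int = 15
    anchor_w: int = 10
    min_chain_anchors: int = 4
    copy_mode: str = "exact"  # "exact": copy == target_copy; "at_least": copy >= target_copy

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError(f"min_identity must be in (0, 1], got {self.min_identity}")
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError(
                f"min_query_coverage must be in (0, 1], got {self.min_query_coverage}"
            )
        if self.target_copy < 2:
            raise ValueError(f"target_copy must be >= 2, got {self.target_copy}")
        if self.copy_mode not in ("exact", "at_least"):
            raise ValueError(f"copy_mode must be 'exact' or 'at_least', got {self.copy_mode}")

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass
class DedupDecision:
    """Flag/removal outcome for one scaffold."""

    scaffold_id: str
    length: int
    gc_fraction: float
    median_read_mult: int
    median_asm_copy: int
    flagged: bool
    removed: bool
    reason: str  # not_flagged | flagged_no_hit | removed
    best_hit: Optional[ContainmentHit] = None


@dataclass
class ValidationMetrics:
    """Before/after accounting of homozygous k-mer content.

    ``duplicated_hom_*``: distinct k-mers at assembly copy >= 2 with read
    multiplicity inside the homozygous band — the artifact mass the
    pipeline exists to shrink. ``lost_single_copy``: increase in
    homozygous-band k-mers missing from the assembly — genuine content
    destroyed by removal, which must stay (near) zero.
    """

    duplicated_hom_before: int
    duplicated_hom_after: int
    lost_single_copy: int
    hom_band_mass: int
    lost_fraction: float
    passed: bool

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass
class DedupReport:
    """Full record of one deduplication run."""

    params: DedupParams
    bounds: Tuple[float, float]
    fit: SpectrumFit
    decisions: List[DedupDecision]
    spectra_before: CopyNumberMatrix
    spectra_after: CopyNumberMatrix
    validation: ValidationMetrics

    @property
    def n_removed(self) -> int:
        return sum(1 for d in self.decisions if d.removed)

    @property
    def bases_removed(self) -> int:
        return sum(d.length for d in self.decisions if d.removed)

    @property
    def n_flagged(self) -> int:
        return sum(1 for d in self.decisions if d.flagged)

    def summary(self) -> str:
        lines = [
            "Deduplication report",
            f"  scaffolds          : {len(self.decisions)}",
            f"  flagged haplotigs  : {self.n_flagged}",
            f"  removed            : {self.n_removed} ({self.bases_removed / 1e6:.2f} Mb)",
            f"  homozygous bounds  : [{self.bounds[0]:.1f}, {self.bounds[1]:.1f}]",
            f"  duplicated hom k-mers: {self.validation.duplicated_hom_before} -> "
            f"{self.validation.duplicated_hom_after}",
            f"  lost single-copy fraction: {self.validation.lost_fraction:.5f}",
            f"  validation         : {'PASS' if self.validation.passed else 'FAIL'}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: PathLike) -> None:
        with open(path, "w") as out:
            out.write(
                "scaffold_id\tlength\tgc\tmedian_read_mult\tmedian_asm_copy\t"
                "flagged\tremoved\treason\ttarget_id\tidentity\tquery_coverage\n"
            )
            for d in self.decisions:
                hit = d.best_hit
                tid = hit.target_id if hit else ""
                ident = f"{hit.identity:.4f}" if hit else ""
                qcov = f"{hit.query_coverage:.4f}" if hit else ""
                out.write(
                    f"{d.scaffold_id}\t{d.length}\t{d.gc_fraction:.4f}\t"
                    f"{d.median_read_mult}\t{d.median_asm_copy}\t"
                    f"{int(d.flagged)}\t{int(d.removed)}\t{d.reason}\t{tid}\t{ident}\t{qcov}\n"
                )

    def run_record(self) -> Dict:
        return {
            "params": self.params.to_dict(),
            "hom_lower": self.bounds[0],
            "hom_upper": self.bounds[1],
            "error_cutoff": self.fit.error_cutoff,
            "n_scaffolds": len(self.decisions),
            "n_flagged": self.n_flagged,
            "n_removed": self.n_removed,
            "bases_removed": self.bases_removed,
            "validation": self.validation.to_dict(),
        }

    def write_outputs(
        self,
        prefix: PathLike,
        kept: Sequence[SeqRecord],
        removed: Sequence[SeqRecord],
    ) -> None:
        """Write the five run outputs under ``prefix``."""
        prefix = str(prefix)
        write_fasta(kept, f"{prefix}.kept.fasta")
        write_fasta(removed, f"{prefix}.removed.fasta")
        self.to_tsv(f"{prefix}.report.tsv")
        self.spectra_before.to_tsv(f"{prefix}.spectra_cn_before.tsv")
        self.spectra_after.to_tsv(f"{prefix}.spectra_cn_after.tsv")
        with open(f"{prefix}.params.json", "w") as out:
            json.dump(self.run_record(), out, indent=2)
            out.write("\n")


def flag_haplotigs(
    profiles: Sequence[ScaffoldProfile],
    bounds: Tuple[float, float],
    params: DedupParams,
) -> List[str]:
    """Ids of scaffolds matching the haplotig signature.

    A scaffold is flagged iff its median assembly k-mer copy equals
    ``target_copy`` (or ``>=`` in at_least mode), its median read k-mer
    multiplicity lies inside the homozygous band (inclusive), and it has
    at least one valid k-mer window.
    """
    lower, upper = bounds
    flagged: List[str] = []
    for p in profiles:
        if p.n_kmers == 0:
            continue
        copy_ok = (
            p.median_asm_copy == params.target_copy
            if params.copy_mode == "exact"
            else p.median_asm_copy >= params.target_copy
        )
        if copy_ok and lower <= p.median_read_mult <= upper:
            flagged.append(p.id)
    return flagged


def hit_passes_thresholds(hit: ContainmentHit, params: DedupParams) -> bool:
    """Inclusive removal test: identity >= min_identity and coverage >= min_query_coverage."""
    return (
        hit.identity >= params.min_identity
        and hit.query_coverage >= params.min_query_coverage
    )


def deduplicate(
    assembly: Sequence[SeqRecord],
    reads: Sequence[SeqRecord],
    params: DedupParams | None = None,
    read_table: KmerCountTable | None = None,
) -> Tuple[List[SeqRecord], List[SeqRecord], DedupReport]:
    """Run the full deduplication pipeline.

    Returns ``(kept, removed, report)`` where kept and removed partition
    the input assembly (input order preserved within each part). A
    pre-computed ``read_table`` may be passed to avoid recounting.
    Deterministic for fixed inputs and parameters.
    """
    params = params or DedupParams()
    if not assembly:
        raise ValueError("assembly is empty")
    if read_table is None:
        if not reads:
            raise ValueError("read set is empty")
        read_table = count_kmers(reads, params.k)
    elif read_table.k != params.k:
        raise ValueError(f"read table k={read_table.k} != params.k={params.k}")
    asm_table = count_kmers(assembly, params.k)

    fit = fit_spectrum(spectrum(read_table), params.n_components)
    bounds = fit.bounds
    profiles = profile_scaffolds(assembly, read_table, asm_table)
    flagged = set(flag_haplotigs(profiles, bounds, params))

    by_id = {rec.id: rec for rec in assembly}
    seqs = {rec.id: rec.seq for rec in assembly}
    index = None
    if flagged:
        index = index_minimizers(assembly, params.anchor_k, params.anchor_w)

    # test flagged scaffolds in ascending length order (ties by id) against
    # all strictly longer scaffolds, regardless of their own status
    decisions_by_id: Dict[str, DedupDecision] = {}
    profile_by_id = {p.id: p for p in profiles}
    flagged_order = sorted(flagged, key=lambda i: (len(by_id[i].seq), i))
    removed_ids: set[str] = set()
    for qid in flagged_order:
        hits = find_containments(
            by_id[qid], index, seqs, min_chain_anchors=params.min_chain_anchors
        )
        qualifying = [h for h in hits if hit_passes_thresholds(h, params)]
        if qualifying:
            best = qualifying[0]
            removed_ids.add(qid)
            reason = "removed"
        else:
            best = hits[0] if hits else None
            reason = "flagged_no_hit"
        p = profile_by_id[qid]
        decisions_by_id[qid] = DedupDecision(
            scaffold_id=qid,
            length=p.length,
            gc_fraction=p.gc_fraction,
            median_read_mult=p.median_read_mult,
            median_asm_copy=p.median_asm_copy,
            flagged=True,
            removed=qid in removed_ids,
            reason=reason,
            best_hit=best,
        )
    for p in profiles:
        if p.id not in decisions_by_id:
            decisions_by_id[p.id] = DedupDecision(
                scaffold_id=p.id,
                length=p.length,
                gc_fraction=p.gc_fraction,
                median_read_mult=p.median_read_mult,
                median_asm_copy=p.median_asm_copy,
                flagged=False,
                removed=False,
                reason="not_flagged",
            )
    decisions = [decisions_by_id[rec.id] for rec in assembly]

    kept = [rec for rec in assembly if rec.id not in removed_ids]
    removed = [rec for rec in assembly if rec.id in removed_ids]

    before = spectra_cn(read_table, asm_table, params.max_copy)
    kept_table = count_kmers(kept, params.k) if removed else asm_table
    after = spectra_cn(read_table, kept_table, params.max_copy)
    validation = validate_dedup(before, after, bounds)

    report = DedupReport(
        params=params,
        bounds=bounds,
        fit=fit,
        decisions=decisions,
        spectra_before=before,
        spectra_after=after,
        validation=validation,
    )
    return kept, removed, report


def validate_dedup(
    before: CopyNumberMatrix,
    after: CopyNumberMatrix,
    bounds: Tuple[float, float],
) -> ValidationMetrics:
    """Check that deduplication removed duplicated homozygous content
    without destroying single-copy content.

    Passes iff duplicated homozygous mass did not increase and the newly
    missing homozygous-band mass is at most 0.5% of the band.
    """
    if before.k != after.k:
        raise ValueError(f"k mismatch: before k={before.k}, after k={after.k}")
    lower, upper = bounds
    dup_before = before.band_mass(2, before.max_copy, lower, upper)
    dup_after = after.band_mass(2, after.max_copy, lower, upper)
    missing_before = before.band_mass(0, 0, lower, upper)
    missing_after = after.band_mass(0, 0, lower, upper)
    lost = max(0, missing_after - missing_before)
    hom_band = before.band_mass(0, before.max_copy, lower, upper)
    lost_fraction = lost / hom_band if hom_band else 0.0
    passed = (dup_after <= dup_before) and lost_fraction <= 0.005
    return ValidationMetrics(
        duplicated_hom_before=dup_before,
        duplicated_hom_after=dup_after,
        lost_single_copy=lost,
        hom_band_mass=hom_band,
        lost_fraction=lost_fraction,
        passed=passed,
    )
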