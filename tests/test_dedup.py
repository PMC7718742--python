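"""Flagging predicate, removal thresholds, pipeline invariants, validation."""

import numpy as np
import pytest

from haplopurge import (
    ContainmentHit,
    CopyNumberMatrix,
    DedupParams,
    SeqRecord,
    count_kmers,
    deduplicate,
    flag_haplotigs,
    hit_passes_thresholds,
    spectra_cn,
    validate_dedup,
)
from haplopurge.profiles import ScaffoldProfile

from conftest import random_seq


def _profile(pid="s", copy=2, mult=30, n_kmers=1000, length=5000):
    return ScaffoldProfile(
        id=pid, length=length, gc_fraction=0.4, n_kmers=n_kmers,
        median_read_mult=mult, median_asm_copy=copy,
    )


BOUNDS = (21.0, 39.0)


class TestFlagging:
    @pytest.mark.parametrize(
        "copy, mult, n_kmers, expect_flag",
        [
            (2, 30, 1000, True),   # the haplotig signature
            (1, 30, 1000, False),  # single-copy scaffold
            (2, 55, 1000, False),  # coverage above homozygous band
            (2, 10, 1000, False),  # coverage below homozygous band
            (3, 30, 1000, False),  # copy 3 not flagged in exact mode
            (2, 21, 1000, True),   # bounds inclusive at lower edge
            (2, 39, 1000, True),   # bounds inclusive at upper edge
            (2, 30, 0, False),     # no valid windows -> never flagged
        ],
    )
    def test_flag_predicate(self, copy, mult, n_kmers, expect_flag):
        profiles = [_profile(copy=copy, mult=mult, n_kmers=n_kmers)]
        flagged = flag_haplotigs(profiles, BOUNDS, DedupParams())
        assert (flagged == ["s"]) is expect_flag

    def test_at_least_mode_flags_higher_copies(self):
        profiles = [_profile(copy=3)]
        assert flag_haplotigs(profiles, BOUNDS, DedupParams(copy_mode="at_least")) == ["s"]


class TestRemovalThresholds:
    @pytest.mark.parametrize(
        "identity, coverage, expect",
        [
            (0.75, 0.25, True),    # both exactly at threshold: inclusive
            (0.7499, 0.25, False),
            (0.75, 0.2499, False),
            (0.9, 0.9, True),
            (0.74, 0.90, False),   # high coverage cannot rescue low identity
        ],
    )
    def test_inclusive_thresholds(self, identity, coverage, expect):
        hit = ContainmentHit("q", "t", identity, coverage, 1)
        assert hit_passes_thresholds(hit, DedupParams()) is expect


def _toy_dataset(rng, n_primary=4, hap_fraction=1.0, length=12_000):
    """Tiny hand-built assembly: unique primaries + divergent copies of
    some primary intervals, with matching error-free reads covering both
    haplotype variants 15x/15x."""
    primaries = [SeqRecord(f"p{i}", random_seq(rng, length)) for i in range(n_primary)]
    haplotigs = []
    alt_seqs = []
    for i, p in enumerate(primaries):
        alt = list(p.seq)
        for j in np.flatnonzero(rng.random(len(alt)) < 0.01):
            alt[j] = "ACGT"[("ACGT".index(alt[j]) + 1) % 4]
        alt = "".join(alt)
        alt_seqs.append(alt)
        if rng.random() < hap_fraction:
            haplotigs.append(SeqRecord(f"h{i}", alt[1_000 : length - 2_000]))
    reads = []
    ridx = 0
    for source in [p.seq for p in primaries] + alt_seqs:
        n = 15 * len(source) // 100
        starts = rng.integers(0, len(source) - 100 + 1, n)
        for s in starts:
            reads.append(SeqRecord(f"r{ridx}", source[s : s + 100]))
            ridx += 1
    return primaries, haplotigs, reads


@pytest.fixture(scope="module")
def toy_run():
    rng = np.random.default_rng(60)
    primaries, haplotigs, reads = _toy_dataset(rng)
    assembly = primaries + haplotigs
    params = DedupParams(n_components=2)
    kept, removed, report = deduplicate(assembly, reads, params)
    return assembly, primaries, haplotigs, reads, kept, removed, report


class TestDeduplicate:
    def test_partition_invariant(self, toy_run):
        assembly, _, _, _, kept, removed, _ = toy_run
        kept_ids = [r.id for r in kept]
        removed_ids = [r.id for r in removed]
        assert set(kept_ids) | set(removed_ids) == {r.id for r in assembly}
        assert not set(kept_ids) & set(removed_ids)
        # order stability within each partition
        order = {r.id: i for i, r in enumerate(assembly)}
        assert kept_ids == sorted(kept_ids, key=order.get)
        assert removed_ids == sorted(removed_ids, key=order.get)

    def test_haplotigs_removed_primaries_kept(self, toy_run):
        _, primaries, haplotigs, _, kept, removed, _ = toy_run
        assert {r.id for r in removed} == {h.id for h in haplotigs}
        assert {p.id for p in primaries} <= {r.id for r in kept}

    def test_base_conservation(self, toy_run):
        assembly, _, _, _, kept, removed, report = toy_run
        total = sum(len(r.seq) for r in assembly)
        assert report.bases_removed == sum(len(r.seq) for r in removed)
        assert report.bases_removed == total - sum(len(r.seq) for r in kept)
        assert report.n_removed == len(removed)

    def test_removed_decisions_have_qualifying_hits(self, toy_run):
        *_, report = toy_run
        params = report.params
        for d in report.decisions:
            if d.removed:
                assert d.flagged
                assert d.best_hit is not None
                assert d.best_hit.identity >= params.min_identity
                assert d.best_hit.query_coverage >= params.min_query_coverage
            if not d.flagged:
                assert d.reason == "not_flagged"

    def test_validation_reports_duplication_decrease(self, toy_run):
        *_, report = toy_run
        v = report.validation
        assert v.duplicated_hom_after < v.duplicated_hom_before
        assert v.duplicated_hom_after <= v.duplicated_hom_before

    def test_deterministic(self, toy_run):
        assembly, _, _, reads, kept, removed, _ = toy_run
        kept2, removed2, _ = deduplicate(assembly, reads, DedupParams(n_components=2))
        assert [r.id for r in kept2] == [r.id for r in kept]
        assert [r.id for r in removed2] == [r.id for r in removed]

    def test_threshold_monotonicity(self, toy_run):
        """Loosening identity/coverage thresholds never shrinks the removed set."""
        assembly, _, _, reads, _, removed, _ = toy_run
        strict_ids = {r.id for r in removed}
        _, removed_loose, _ = deduplicate(
            assembly, reads,
            DedupParams(n_components=2, min_identity=0.5, min_query_coverage=0.1),
        )
        assert strict_ids <= {r.id for r in removed_loose}

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            deduplicate([], [SeqRecord("r", "ACGT")], DedupParams())
        with pytest.raises(ValueError):
            deduplicate([SeqRecord("s", "ACGT" * 100)], [], DedupParams())

    def test_output_files(self, toy_run, tmp_path):
        _, _, _, _, kept, removed, report = toy_run
        prefix = tmp_path / "run"
        report.write_outputs(prefix, kept, removed)
        for suffix in (
            ".kept.fasta", ".removed.fasta", ".report.tsv",
            ".spectra_cn_before.tsv", ".spectra_cn_after.tsv", ".params.json",
        ):
            assert (tmp_path / f"run{suffix}").exists()
        header = (tmp_path / "run.report.tsv").read_text().splitlines()[0]
        assert header.split("\t") == [
            "scaffold_id", "length", "gc", "median_read_mult", "median_asm_copy",
            "flagged", "removed", "reason", "target_id", "identity", "query_coverage",
        ]


class TestSyntheticIntegration:
    def test_no_genuine_homozygous_content_lost(self, small_dataset, small_spec):
        """Truth-aware content check: the k-mers that go missing from the
        assembly after deduplication are exclusively alternate-allele
        (haplotype-B-only) content from the removed haplotigs — no k-mer of
        the reference haplotype is lost, at any multiplicity."""
        import numpy as np

        from haplopurge.kmer import encode_bases, window_codes

        assembly, truth, reads = small_dataset
        params = DedupParams()
        kept, removed, report = deduplicate(assembly, reads, params)

        removed_ids = {r.id for r in removed}
        haplotigs = set(truth.haplotig_ids)
        primaries = set(truth.primary_ids)
        assert len(removed_ids & haplotigs) / len(haplotigs) >= 0.9
        assert not removed_ids & primaries

        read_table = count_kmers(reads, params.k)
        before = count_kmers(assembly, params.k)
        after = count_kmers(kept, params.k)
        gone = (after.lookup_codes(read_table.codes) == 0) & (
            before.lookup_codes(read_table.codes) > 0
        )
        gone_codes = read_table.codes[gone]
        # haplotype A = the collapsed reference representation
        hap_a = "".join(
            r.seq for r in assembly if r.id in primaries
        )
        hap_a_codes = np.unique(window_codes(encode_bases(hap_a), params.k))
        assert not np.isin(gone_codes, hap_a_codes).any()
        assert report.validation.duplicated_hom_after < report.validation.duplicated_hom_before


class TestValidateDedup:
    def _matrix(self, cells, k=21, max_copy=10, assembly_only=0):
        copy = np.array([c for c, _ in cells], dtype=np.int64)
        mult = np.array([m for _, m in cells], dtype=np.int64)
        n = np.array([cells[c] for c in cells], dtype=np.int64)
        return CopyNumberMatrix(
            k=k, max_copy=max_copy, copy=copy, mult=mult, n_kmers=n,
            assembly_only=assembly_only,
        )

    def test_identity_passes(self):
        m = self._matrix({(1, 30): 1000, (2, 30): 50, (0, 2): 500})
        v = validate_dedup(m, m, BOUNDS)
        assert v.duplicated_hom_before == v.duplicated_hom_after == 50
        assert v.lost_single_copy == 0
        assert v.passed

    def test_unit_bookkeeping(self):
        """Moving one duplicated in-band k-mer to copy 1 reduces the
        duplicated count by one with no loss."""
        before = self._matrix({(1, 30): 1000, (2, 30): 50})
        after = self._matrix({(1, 30): 1001, (2, 30): 49})
        v = validate_dedup(before, after, BOUNDS)
        assert v.duplicated_hom_before - v.duplicated_hom_after == 1
        assert v.lost_single_copy == 0
        assert v.passed

    def test_content_loss_detected(self):
        """In-band k-mers dropping to copy 0 count as lost content."""
        before = self._matrix({(1, 30): 1000, (2, 30): 100})
        after = self._matrix({(0, 30): 900, (1, 30): 100, (2, 30): 100})
        v = validate_dedup(before, after, BOUNDS)
        assert v.lost_single_copy == 900
        assert not v.passed

    def test_mismatched_k_rejected(self):
        a = self._matrix({(1, 30): 10}, k=21)
        b = self._matrix({(1, 30): 10}, k=27)
        with pytest.raises(ValueError, match="k mismatch"):
            validate_dedup(a, b, BOUNDS)
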