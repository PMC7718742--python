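"""Spectrum mixture decomposition and homozygous-coverage bounds."""

import numpy as np
import pytest

from haplopurge import (
    SeqRecord,
    SimulationSpec,
    SpectrumFitError,
    count_kmers,
    expected_kmer_depth,
    fit_spectrum,
    homozygous_bounds,
    simulate_diploid,
    simulate_reads,
    spectrum,
)
from haplopurge.kmer import KmerSpectrum
from haplopurge.spectrum_model import SpectrumComponent, SpectrumFit, error_cutoff_from_hist


def _gaussian_spectrum(mean, sd, weight, k=27, max_m=None, error_spike=False):
    """Synthetic histogram: a Gaussian signal peak, optionally with an
    exponential low-multiplicity error spike."""
    max_m = max_m or int(mean + 6 * sd)
    m = np.arange(1, max_m + 1)
    y = weight * np.exp(-0.5 * ((m - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    if error_spike:
        y = y + 5 * weight * np.exp(-m / 1.5)
    y = np.round(y).astype(np.int64)
    keep = y > 0
    return KmerSpectrum(k=k, multiplicity=m[keep], n_kmers=y[keep])


class TestFitSpectrum:
    def test_single_spike_recovery(self):
        """A lone Gaussian peak at 30 +/- 2 is recovered within 1 multiplicity unit."""
        spec = _gaussian_spectrum(30, 2, 1e6, error_spike=True)
        fit = fit_spectrum(spec, n_components=2)
        assert abs(fit.hom_mean - 30) <= 1
        assert fit.hom_lower < 30 < fit.hom_upper

    def test_two_peak_ratio(self):
        """Het + hom peaks at 15/30 fit with mean ratio ~2."""
        m = np.arange(1, 61)
        y = (
            4e5 * np.exp(-0.5 * ((m - 15) / 2.5) ** 2)
            + 8e5 * np.exp(-0.5 * ((m - 30) / 3.5) ** 2)
            + 5e6 * np.exp(-m / 1.5)
        ).astype(np.int64)
        spec = KmerSpectrum(k=27, multiplicity=m, n_kmers=y)
        fit = fit_spectrum(spec, n_components=2)
        means = sorted(c.mean for c in fit.components)
        assert 1.7 <= means[1] / means[0] <= 2.3
        assert fit.hom_index == len(fit.components) - 1 or abs(fit.hom_mean - 30) < 3

    def test_scale_equivariance(self):
        """Scaling all histogram counts scales weights, not means/sds."""
        spec1 = _gaussian_spectrum(28, 3, 1e5, error_spike=True)
        spec2 = KmerSpectrum(k=27, multiplicity=spec1.multiplicity, n_kmers=spec1.n_kmers * 10)
        f1 = fit_spectrum(spec1, 2)
        f2 = fit_spectrum(spec2, 2)
        assert len(f1.components) == len(f2.components)
        for c1, c2 in zip(f1.components, f2.components):
            assert c1.mean == pytest.approx(c2.mean, abs=1e-6)
            assert c1.sd == pytest.approx(c2.sd, abs=1e-6)
            assert c2.weight == pytest.approx(10 * c1.weight, rel=1e-6)

    def test_degenerate_spectrum_raises(self):
        """All mass below the error cutoff is a hard fit error."""
        spec = KmerSpectrum(
            k=27,
            multiplicity=np.array([1, 2, 3]),
            n_kmers=np.array([1000, 100, 10]),
        )
        with pytest.raises(SpectrumFitError, match="coverage"):
            fit_spectrum(spec, 2)

    def test_invalid_component_count(self):
        spec = _gaussian_spectrum(30, 2, 1e6)
        with pytest.raises(ValueError):
            fit_spectrum(spec, 1)
        with pytest.raises(ValueError):
            fit_spectrum(spec, 5)

    def test_deterministic(self):
        spec = _gaussian_spectrum(25, 4, 1e6, error_spike=True)
        f1 = fit_spectrum(spec, 3)
        f2 = fit_spectrum(spec, 3)
        assert [c.mean for c in f1.components] == [c.mean for c in f2.components]

    def test_component_means_increasing(self):
        spec = _gaussian_spectrum(25, 4, 1e6, error_spike=True)
        fit = fit_spectrum(spec, 3)
        means = [c.mean for c in fit.components]
        assert means == sorted(means)
        assert all(c.weight > 0 for c in fit.components)


class TestErrorCutoff:
    def test_local_minimum_found(self):
        # error spike decays to m=4, signal rises after
        y = np.array([0, 1000, 300, 80, 20, 30, 80, 150, 80, 30], dtype=float)
        assert error_cutoff_from_hist(y) == 4

    def test_monotone_fallback(self):
        y = np.array([0, 1000, 500, 200, 100, 50, 20], dtype=float)
        assert error_cutoff_from_hist(y) == 3


class TestHomozygousBounds:
    def _fit(self, comps, hom_index, cutoff=5):
        return SpectrumFit(
            k=27, error_cutoff=cutoff, components=comps, hom_index=hom_index,
            hom_lower=0.0, hom_upper=0.0,
        )

    def test_single_component_three_sigma(self):
        fit = self._fit([SpectrumComponent(30, 3, 1e6)], 0, cutoff=5)
        assert homozygous_bounds(fit) == (21, 39)

    def test_cutoff_clips_lower(self):
        fit = self._fit([SpectrumComponent(10, 3, 1e6)], 0, cutoff=5)
        lower, upper = homozygous_bounds(fit)
        assert lower == 5
        assert upper == 19

    def test_degenerate_sd_widened(self):
        fit = self._fit([SpectrumComponent(30, 0.0, 1e6)], 0)
        assert homozygous_bounds(fit) == (29, 31)

    def test_het_crossing_raises_lower_bound(self):
        """Lower bound sits at the point where hom density overtakes het density."""
        het = SpectrumComponent(15, 2, 5e5)
        hom = SpectrumComponent(30, 4, 1e6)
        fit = self._fit([het, hom], 1, cutoff=3)
        lower, upper = homozygous_bounds(fit)
        # independent numeric crossing of the two densities
        grid = np.linspace(15, 30, 2000)
        crossing = grid[np.flatnonzero(hom.density(grid) < het.density(grid))[-1]]
        assert lower == pytest.approx(crossing, abs=0.1)
        assert lower > 30 - 3 * 4  # strictly above the plain 3-sigma bound
        assert upper == 42

    def test_repeat_crossing_truncates_upper(self):
        hom = SpectrumComponent(30, 4, 1e6)
        rep = SpectrumComponent(45, 4, 5e5)
        fit = self._fit([hom, rep], 0, cutoff=3)
        lower, upper = homozygous_bounds(fit)
        grid = np.linspace(30, 45, 2000)
        crossing = grid[np.flatnonzero(rep.density(grid) < hom.density(grid))[-1]]
        assert upper == pytest.approx(crossing, abs=0.1)
        assert upper < 30 + 3 * 4
        assert lower < 30 < upper


class TestSimulatedRecovery:
    def test_haploid_kmer_depth_recovered(self):
        """Error-free haploid reads at depth 40: hom peak within 10% of
        the expected k-mer depth C*(L-k+1)/L = 29.6."""
        spec = SimulationSpec(
            seed=21, genome_length=150_000, het_rate=0.0, depth=40.0,
            read_length=100, error_rate=0.0,
        )
        haps = simulate_diploid(spec)
        reads = simulate_reads(haps, spec)
        fit = fit_spectrum(spectrum(count_kmers(reads, 27)), 2)
        expected = 40 * (100 - 27 + 1) / 100
        assert abs(fit.hom_mean - expected) / expected < 0.10
        assert fit.hom_lower < expected < fit.hom_upper

    def test_diploid_het_hom_ratio(self):
        """1% heterozygosity at depth 40: het and hom components separated
        by a factor ~2 in mean (het content is covered by one haplotype)."""
        spec = SimulationSpec(
            seed=22, genome_length=200_000, het_rate=0.01, depth=40.0,
            read_length=100, error_rate=0.005,
        )
        haps = simulate_diploid(spec)
        reads = simulate_reads(haps, spec)
        fit = fit_spectrum(spectrum(count_kmers(reads, 27)), 2)
        means = sorted(c.mean for c in fit.components)
        assert len(means) >= 2
        ratio = means[1] / means[0]
        assert 1.7 <= ratio <= 2.3
        truth = expected_kmer_depth(spec, 27)
        assert fit.hom_lower <= truth <= fit.hom_upper


def test_fit_tsv_round_trip(tmp_path):
    spec = _gaussian_spectrum(30, 3, 1e6, error_spike=True)
    fit = fit_spectrum(spec, 2)
    path = tmp_path / "fit.tsv"
    fit.to_tsv(path)
    loaded = SpectrumFit.from_tsv(path)
    assert loaded.error_cutoff == fit.error_cutoff
    assert loaded.hom_lower == pytest.approx(fit.hom_lower, abs=1e-3)
    assert [c.mean for c in loaded.components] == pytest.approx(
        [c.mean for c in fit.components], rel=1e-4
    )
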