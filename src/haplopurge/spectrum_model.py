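"""Mixture decomposition of the read k-mer spectrum.

The read k-mer multiplicity histogram of a diploid WGS data set has a
characteristic shape: a large error component at very low multiplicity, a
heterozygous peak near half the sequencing k-mer depth (content carried by
one haplotype only), a homozygous peak at the full k-mer depth, and
optional repeat peaks at integer multiples. This module fits that shape
with a sum of Gaussian components on the histogram and reports the
multiplicity interval attributable to homozygous single-copy content —
the interval the haplotig-flagging rule uses.

Fitting is bounded least squares on the histogram itself (not per-k-mer
EM): deterministic, fast at any spectrum size, and adequate because the
downstream consumer only needs the homozygous component's location and
spread, not per-k-mer responsibilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .kmer import KmerSpectrum

__all__ = [
    "SpectrumComponent",
    "SpectrumFit",
    "SpectrumFitError",
    "fit_spectrum",
    "homozygous_bounds",
]

PathLike = Union[str, Path]


class SpectrumFitError(RuntimeError):
    """Raised when the spectrum carries no usable signal above the error region."""


@dataclass(frozen=True)
class SpectrumComponent:
    """One Gaussian component: location and spread in multiplicity units,
    weight in distinct-k-mer mass."""

    mean: float
    sd: float
    weight: float

    def density(self, m: np.ndarray) -> np.ndarray:
        sd = max(self.sd, 1e-9)
        z = (np.asarray(m, dtype=float) - self.mean) / sd
        return self.weight * np.exp(-0.5 * z * z) / (sd * np.sqrt(2 * np.pi))


@dataclass
class SpectrumFit:
    """Result of the spectrum decomposition.

    ``components`` are ordered by increasing mean; ``hom_index`` marks the
    homozygous component (the one nearest the spectrum's main peak) and
    ``hom_lower``/``hom_upper`` delimit the homozygous-coverage interval.
    """

    k: int
    error_cutoff: int
    components: List[SpectrumComponent]
    hom_index: int
    hom_lower: float
    hom_upper: float

    @property
    def hom_mean(self) -> float:
        return self.components[self.hom_index].mean

    @property
    def bounds(self) -> Tuple[float, float]:
        return (self.hom_lower, self.hom_upper)

    def predict(self, m: np.ndarray) -> np.ndarray:
        """Model-predicted histogram counts at multiplicities ``m``."""
        m = np.asarray(m, dtype=float)
        out = np.zeros_like(m)
        for comp in self.components:
            out += comp.density(m)
        return out

    def summary(self) -> str:
        lines = [
            f"Spectrum decomposition (k={self.k})",
            f"  error cutoff     : {self.error_cutoff}",
            f"  homozygous peak  : {self.hom_mean:.2f}",
            f"  homozygous bounds: [{self.hom_lower:.2f}, {self.hom_upper:.2f}]",
            f"  {'component':<10} {'mean':>8} {'sd':>8} {'weight':>14}",
        ]
        for i, comp in enumerate(self.components):
            tag = "hom" if i == self.hom_index else ("het" if comp.mean < self.hom_mean else "rep")
            lines.append(
                f"  {i} ({tag})    {comp.mean:8.2f} {comp.sd:8.2f} {comp.weight:14.1f}"
            )
        return "\n".join(lines)

    def to_tsv(self, path: PathLike) -> None:
        with open(path, "w") as out:
            out.write(
                f"# k={self.k} error_cutoff={self.error_cutoff} "
                f"hom_index={self.hom_index} hom_lower={self.hom_lower:.4f} "
                f"hom_upper={self.hom_upper:.4f}\n"
            )
            out.write("component\tmean\tsd\tweight\n")
            for i, comp in enumerate(self.components):
                out.write(f"{i}\t{comp.mean:.6g}\t{comp.sd:.6g}\t{comp.weight:.6g}\n")

    @classmethod
    def from_tsv(cls, path: PathLike) -> "SpectrumFit":
        meta = {}
        comps: List[SpectrumComponent] = []
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line[1:].split():
                        key, _, val = tok.partition("=")
                        meta[key] = val
                    continue
                if not line or line.startswith("component"):
                    continue
                _, mean, sd, weight = line.split("\t")
                comps.append(SpectrumComponent(float(mean), float(sd), float(weight)))
        return cls(
            k=int(meta.get("k", 0)),
            error_cutoff=int(meta["error_cutoff"]),
            components=comps,
            hom_index=int(meta["hom_index"]),
            hom_lower=float(meta["hom_lower"]),
            hom_upper=float(meta["hom_upper"]),
        )


def error_cutoff_from_hist(y: np.ndarray) -> int:
    """First local minimum of the histogram scanning up from m=1.

    ``y`` is dense with index = multiplicity (index 0 unused). Sequencing
    errors produce a spike at m=1 that decays before the signal peaks
    rise; the first local minimum separates the two regimes. Falls back
    to m=3 when the histogram is monotone (no error spike).
    """
    max_m = len(y) - 1
    for m in range(2, max_m):
        if y[m] <= y[m - 1] and y[m] < y[m + 1]:
            return m
    return min(3, max(1, max_m))


def fit_spectrum(spec: KmerSpectrum, n_components: int = 3) -> SpectrumFit:
    """Decompose a k-mer spectrum into Gaussian components.

    Components are initialized at m̂/2, m̂, 2m̂, 3m̂ (m̂ = histogram mode
    above the error cutoff) — the expected locations of heterozygous,
    homozygous and repeat content — and fitted to the histogram counts on
    m ∈ [cutoff, 4m̂] by bounded least squares. The homozygous component
    is the fitted component whose mean is nearest m̂. Components whose
    weight collapses to (numerically) zero are dropped.
    """
    if not (2 <= n_components <= 4):
        raise ValueError(f"n_components must be in 2..4, got {n_components}")
    if spec.n_distinct == 0:
        raise SpectrumFitError("empty spectrum")
    y_full = spec.dense()
    cutoff = error_cutoff_from_hist(y_full)
    max_m = len(y_full) - 1
    signal = y_full[cutoff:]
    if max_m <= cutoff or signal.sum() <= 0:
        raise SpectrumFitError(
            "no k-mer mass above the error cutoff; the read set is too shallow "
            "for spectrum decomposition (deeper coverage needed)"
        )
    m_hat = cutoff + int(np.argmax(signal))
    if m_hat <= cutoff:
        # mode sits at the cutoff itself: no distinct signal peak
        raise SpectrumFitError(
            "spectrum mode coincides with the error cutoff; cannot separate "
            "signal from sequencing errors (deeper coverage needed)"
        )
    fit_hi = min(max_m, 4 * m_hat)
    m_grid = np.arange(cutoff, fit_hi + 1, dtype=float)
    y = y_full[cutoff : fit_hi + 1].astype(float)
    scale = y.max()
    y_n = y / scale  # normalized so the fit is exactly scale-equivariant

    init_means = [m_hat / 2.0, float(m_hat), 2.0 * m_hat, 3.0 * m_hat][:n_components]
    p0: List[float] = []
    lo: List[float] = []
    hi: List[float] = []
    for mu in init_means:
        sd0 = max(1.0, np.sqrt(mu))
        idx = int(np.clip(round(mu) - cutoff, 0, len(y_n) - 1))
        w0 = max(y_n[idx] * sd0 * np.sqrt(2 * np.pi), 1e-6)
        p0 += [mu, sd0, w0]
        lo += [max(cutoff * 0.5, 1.0), 0.1, 0.0]
        hi += [4.0 * m_hat + 1.0, 2.0 * m_hat + 1.0, np.inf]

    def model(params: np.ndarray) -> np.ndarray:
        out = np.zeros_like(m_grid)
        for i in range(0, len(params), 3):
            mu, sd, w = params[i : i + 3]
            z = (m_grid - mu) / max(sd, 1e-9)
            out += w * np.exp(-0.5 * z * z) / (max(sd, 1e-9) * np.sqrt(2 * np.pi))
        return out

    res = least_squares(
        lambda p: model(p) - y_n, x0=np.asarray(p0), bounds=(np.asarray(lo), np.asarray(hi)),
        xtol=1e-10, ftol=1e-10, max_nfev=20_000,
    )
    params = res.x
    comps = [
        SpectrumComponent(mean=float(params[i]), sd=float(params[i + 1]), weight=float(params[i + 2]) * scale)
        for i in range(0, len(params), 3)
    ]
    total_w = sum(c.weight for c in comps)
    comps = [c for c in comps if c.weight > 1e-9 * max(total_w, 1.0)]
    if not comps:
        raise SpectrumFitError("all mixture components collapsed to zero weight")
    comps.sort(key=lambda c: c.mean)
    hom_index = int(np.argmin([abs(c.mean - m_hat) for c in comps]))
    fit = SpectrumFit(
        k=spec.k,
        error_cutoff=cutoff,
        components=comps,
        hom_index=hom_index,
        hom_lower=0.0,
        hom_upper=0.0,
    )
    fit.hom_lower, fit.hom_upper = homozygous_bounds(fit)
    return fit


def _crossing(
    low: SpectrumComponent, high: SpectrumComponent, lo_m: float, hi_m: float
) -> float | None:
    """Largest m in (lo_m, hi_m) where the lower component still dominates.

    Returns the point where dominance flips to the higher component, or
    None if one component dominates throughout.
    """
    grid = np.linspace(lo_m, hi_m, 512)
    diff = high.density(grid) - low.density(grid)
    below = np.flatnonzero(diff < 0)
    if len(below) == 0 or len(below) == len(grid):
        return None
    return float(grid[below[-1]])


def homozygous_bounds(fit: SpectrumFit) -> Tuple[float, float]:
    """Multiplicity interval attributed to homozygous single-copy content.

    The interval is μ ± 3σ of the homozygous component, clipped below at
    the error cutoff and truncated at the density crossing with the
    adjacent component on either side, so that heterozygous (below) or
    repeat (above) mass does not leak into the homozygous band.
    """
    hom = fit.components[fit.hom_index]
    mu, sd = hom.mean, hom.sd
    if sd < 0.5:  # degenerate spike
        return (mu - 1.0, mu + 1.0)
    lower = max(float(fit.error_cutoff), mu - 3.0 * sd)
    upper = mu + 3.0 * sd
    if fit.hom_index > 0:
        below = fit.components[fit.hom_index - 1]
        cross = _crossing(below, hom, below.mean, mu)
        if cross is not None:
            lower = max(lower, cross)
    if fit.hom_index + 1 < len(fit.components):
        above = fit.components[fit.hom_index + 1]
        cross = _crossing(hom, above, mu, above.mean)
        if cross is not None:
            upper = min(upper, cross)
    if not lower < upper:
        return (mu - 1.0, mu + 1.0)
    return (lower, upper)


def plot_spectrum_fit(spec: KmerSpectrum, fit: SpectrumFit, path: PathLike) -> None:
    """Spectrum histogram with fitted component curves and homozygous band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    max_m = min(int(spec.multiplicity.max()), int(4 * fit.hom_mean) + 10)
    y = spec.dense(max_m)
    m = np.arange(1, max_m + 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(m, y[1:], width=1.0, color="0.8", label="spectrum")
    grid = np.linspace(1, max_m, 400)
    for i, comp in enumerate(fit.components):
        ax.plot(grid, comp.density(grid), label=f"component {i} (μ={comp.mean:.1f})")
    ax.plot(grid, fit.predict(grid), "k--", lw=1, label="mixture")
    ax.axvspan(fit.hom_lower, fit.hom_upper, color="tab:green", alpha=0.15, label="homozygous band")
    ax.axvline(fit.error_cutoff, color="tab:red", ls=":", label="error cutoff")
    ax.set_xlabel("k-mer multiplicity in reads")
    ax.set_ylabel("distinct k-mers")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
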