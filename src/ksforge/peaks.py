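"""Density estimation and peak detection on corrected dS distributions.

WGD events leave waves of similarly aged paralog pairs, visible as modes
in the corrected dS distribution. The density is a Gaussian kernel
estimate on a uniform grid over [0, 5] (the subfamily threshold caps the
usable range), with reflection at zero to remove the downward boundary
bias of a plain KDE — a genuine excess of near-zero values (unmerged
haplotypes, retained splice forms) still shows up as a peak. Peaks are
strict local maxima filtered by prominence and thinned to a minimum
separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal


@dataclass
class DsDistribution:
    values: np.ndarray  # in-range values used for fitting
    lo: float
    hi: float
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass(frozen=True)
class Peak:
    position: float
    height: float
    prominence: float


def silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread <= 0:
        spread = max(abs(float(np.mean(values))), 1.0) * 0.01
    return 0.9 * spread * n ** (-0.2)


def estimate_density(
    values: Sequence[float],
    bandwidth: float | str = "silverman",
    grid_points: int = 512,
    ds_range: tuple[float, float] = (0.0, 5.0),
) -> DsDistribution:
    """Gaussian KDE with reflection at the lower boundary.

    Values outside ``ds_range`` are excluded from fitting; fewer than two
    in-range values is an error. The density is renormalized to unit
    mass over the range (trapezoid rule).
    """
    lo, hi = ds_range
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    vals = vals[(vals >= lo) & (vals <= hi)]
    if len(vals) < 2:
        raise ValueError(f"need at least 2 dS values in [{lo}, {hi}], got {len(vals)}")
    if bandwidth == "silverman":
        h = silverman_bandwidth(vals)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    grid = np.linspace(lo, hi, grid_points)
    # reflection at lo: mirror the sample across the boundary
    z = (grid[:, None] - vals[None, :]) / h
    zr = (grid[:, None] - (2 * lo - vals)[None, :]) / h
    kern = np.exp(-0.5 * z**2) + np.exp(-0.5 * zr**2)
    density = kern.sum(axis=1) / (len(vals) * h * np.sqrt(2 * np.pi))
    mass = np.trapezoid(density, grid)
    if mass > 0:
        density = density / mass
    return DsDistribution(vals, lo, hi, grid, density, h)


def find_peaks(
    dist: DsDistribution,
    min_prominence_frac: float = 0.05,
    min_separation: float = 0.1,
) -> list[Peak]:
    """Strict local maxima of the density, prominence-filtered and thinned.

    Candidates need prominence >= ``min_prominence_frac`` times the
    maximum density; of any two candidates closer than
    ``min_separation`` in dS, the lower one is dropped (greedy, highest
    first). Peaks are returned sorted by position.
    """
    min_prom = min_prominence_frac * float(dist.density.max())
    idx, props = signal.find_peaks(dist.density, prominence=min_prom)
    candidates = [
        Peak(float(dist.grid[i]), float(dist.density[i]), float(p))
        for i, p in zip(idx, props["prominences"])
    ]
    candidates.sort(key=lambda p: -p.height)
    kept: list[Peak] = []
    for cand in candidates:
        if all(abs(cand.position - k.position) >= min_separation for k in kept):
            kept.append(cand)
    kept.sort(key=lambda p: p.position)
    return kept


def write_peak_table(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak\tds\tdensity\tprominence\n")
        for i, p in enumerate(peaks, start=1):
            fh.write(f"{i}\t{p.position:.4f}\t{p.height:.6f}\t{p.prominence:.6f}\n")


def render(
    dist: DsDistribution,
    peaks: Sequence[Peak],
    out_prefix: str | Path,
    bins: int = 50,
) -> list[Path]:
    """Write the density/histogram plot (SVG + PNG) and the peak/value tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(
        dist.values,
        bins=np.linspace(dist.lo, dist.hi, bins + 1),
        density=True,
        color="#9ecae1",
        alpha=0.6,
        label=f"corrected dS (n={len(dist.values)})",
    )
    ax.plot(dist.grid, dist.density, color="#08519c", lw=1.8, label="kernel density")
    for p in peaks:
        ax.axvline(p.position, color="#de2d26", ls="--", lw=1)
        ax.annotate(
            f"{p.position:.2f}",
            (p.position, p.height),
            textcoords="offset points",
            xytext=(4, 4),
            color="#de2d26",
            fontsize=9,
        )
    ax.set_xlabel("dS")
    ax.set_ylabel("density")
    ax.set_xlim(dist.lo, dist.hi)
    ax.legend(frameon=False)
    fig.tight_layout()
    written = []
    for ext in ("svg", "png"):
        path = out_prefix.with_suffix(f".{ext}")
        fig.savefig(path, dpi=150)
        written.append(path)
    plt.close(fig)
    table = out_prefix.parent / (out_prefix.name + "_peaks.tsv")
    write_peak_table(peaks, table)
    written.append(table)
    values_path = out_prefix.parent / (out_prefix.name + "_values.tsv")
    np.savetxt(values_path, dist.values, fmt="%.6f")
    written.append(values_path)
    return written
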