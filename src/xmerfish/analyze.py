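"""Quantitative analyses: density→efficiency benchmark, expression
statistics, two-condition count comparison, and a simple smFISH spot caller.

The central benchmark sweeps molecular density and measures how decoding
efficiency degrades as single-molecule signals start to overlap: spots of
σ ≈ 1.6 px on a 109-nm grid begin to merge once the density approaches a few
molecules per µm² per optical section, and the density at which efficiency
falls to half its low-density baseline quantifies the crowding limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from skimage import feature

from .codebook import Codebook
from .decode import DecodeConfig, decode_stack, match_to_truth
from .simulate import FieldGeometry, ImageStack, OpticsModel, place_molecules, render_stack

__all__ = [
    "EfficiencyCurve",
    "CountComparison",
    "Spot",
    "efficiency_sweep",
    "run_pipeline_once",
    "expression_stats",
    "compare_counts",
    "call_spots",
    "molecules_per_cell",
]


@dataclass
class EfficiencyCurve:
    """Detection efficiency as a function of molecular density."""

    densities: np.ndarray  # molecules/µm² per optical section
    efficiency_mean: np.ndarray
    efficiency_sd: np.ndarray  # Monte-Carlo sd over replicates
    precision_mean: np.ndarray
    n_replicates: int
    seeds: list[int]
    baseline_density: float
    baseline_efficiency: float

    @property
    def relative_efficiency(self) -> np.ndarray:
        return self.efficiency_mean / self.baseline_efficiency

    @property
    def density_at_half(self) -> float:
        """Density where efficiency crosses 50% of the low-density baseline,
        by linear interpolation between bracketing sweep points (NaN if the
        sweep never crosses)."""
        rel = self.relative_efficiency
        below = np.flatnonzero(rel < 0.5)
        if len(below) == 0:
            return float("nan")
        j = below[0]
        if j == 0:
            return float(self.densities[0])
        x0, x1 = self.densities[j - 1], self.densities[j]
        y0, y1 = rel[j - 1], rel[j]
        return float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0))

    def reduction_at(self, density: float) -> float:
        """Efficiency reduction (fraction of baseline lost) at a density,
        linearly interpolated on the sweep grid."""
        rel = float(np.interp(density, self.densities, self.relative_efficiency))
        return 1.0 - rel

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "density_per_um2": self.densities,
                "efficiency_mean": self.efficiency_mean,
                "efficiency_sd": self.efficiency_sd,
                "precision_mean": self.precision_mean,
                "relative_efficiency": self.relative_efficiency,
            }
        )


def run_pipeline_once(
    codebook: Codebook,
    density: float,
    geometry: FieldGeometry,
    optics: OpticsModel,
    config: DecodeConfig,
    seed: int,
    register: bool = False,
):
    """place → render → decode → match for one field; returns a MatchResult."""
    truth = place_molecules(codebook, density, geometry, seed=seed)
    stack = render_stack(truth, geometry, optics, seed=seed + 1)
    mols, _ = decode_stack(stack, codebook, config, register=register)
    return match_to_truth(mols, truth, radius_um=config.match_radius_um,
                          codebook=codebook)


def efficiency_sweep(
    densities,
    codebook: Codebook,
    geometry: FieldGeometry,
    optics: OpticsModel,
    config: DecodeConfig | None = None,
    n_reps: int = 5,
    seed: int = 0,
    register: bool = False,
) -> EfficiencyCurve:
    """Measure decoding efficiency across a density sweep.

    Each density × replicate runs the full simulate-decode-match pipeline
    with a seed derived from ``seed`` and the replicate index only, so the
    same replicate across densities shares its random stream ancestry
    (paired seeds).  No per-bit errors are injected: the benchmark isolates
    the effect of optical crowding.
    """
    densities = np.asarray(sorted(densities), dtype=float)
    if len(densities) < 2:
        raise ValueError("need at least two densities")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or DecodeConfig()
    eff = np.zeros((len(densities), n_reps))
    prec = np.zeros_like(eff)
    seeds = []
    for j in range(n_reps):
        rep_seed = int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2**31))
        seeds.append(rep_seed)
        for i, d in enumerate(densities):
            res = run_pipeline_once(codebook, d, geometry, optics, config,
                                    seed=rep_seed + 2 * i, register=register)
            eff[i, j] = res.efficiency
            prec[i, j] = res.precision
    mean = eff.mean(axis=1)
    return EfficiencyCurve(
        densities=densities,
        efficiency_mean=mean,
        efficiency_sd=eff.std(axis=1, ddof=1) if n_reps > 1 else np.zeros(len(densities)),
        precision_mean=prec.mean(axis=1),
        n_replicates=n_reps,
        seeds=seeds,
        baseline_density=float(densities[0]),
        baseline_efficiency=float(mean[0]),
    )


# --------------------------------------------------------------------------
# expression statistics

def expression_stats(count_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean, sample variance and Fano factor over cells.

    The Fano factor (variance / mean of per-cell copy numbers) is 1 for a
    Poisson-distributed species; species with zero mean get NaN and a flag.
    """
    if len(count_matrix) < 2:
        raise ValueError("expression statistics need at least two cells")
    mean = count_matrix.mean(axis=0)
    var = count_matrix.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean > 0, var / mean, np.nan)
    return pd.DataFrame(
        {"mean": mean, "variance": var, "fano": fano,
         "undefined": mean == 0}
    )


@dataclass
class CountComparison:
    """Per-species comparison of mean counts between two conditions."""

    species: list[str]
    mean_a: np.ndarray
    mean_b: np.ndarray
    ratio: np.ndarray  # B / A per species (NaN where A == 0)
    mean_ratio: float
    sem_ratio: float  # sd / sqrt(N species)
    median_ratio: float
    log10_pearson_r: float
    n_species_in_r: int
    excluded_species: list[str] = field(default_factory=list)


def compare_counts(
    counts_a: pd.Series | dict,
    counts_b: pd.Series | dict,
) -> CountComparison:
    """Compare per-species mean counts between conditions A and B.

    Ratios are B/A per species; the summary is mean ± s.e.m. across species
    (s.e.m. convention: sd/√N over the N species) and the median.  The
    Pearson r is computed on log10 means over species with both means > 0;
    excluded species are recorded, and no pseudocount is added.
    """
    a = pd.Series(counts_a, dtype=float)
    b = pd.Series(counts_b, dtype=float)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no overlapping species between conditions")
    a, b = a[common], b[common]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(a > 0, b / a, np.nan)
    finite = np.isfinite(ratio)
    pos = (a > 0) & (b > 0)
    excluded = list(common[~pos])
    if pos.sum() >= 2:
        la, lb = np.log10(a[pos]), np.log10(b[pos])
        r = float(np.corrcoef(la, lb)[0, 1]) if la.std() > 0 and lb.std() > 0 else 1.0
    else:
        r = float("nan")
    vals = ratio[finite]
    return CountComparison(
        species=list(common),
        mean_a=a.to_numpy(),
        mean_b=b.to_numpy(),
        ratio=ratio,
        mean_ratio=float(np.mean(vals)) if len(vals) else float("nan"),
        sem_ratio=float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0,
        median_ratio=float(np.median(vals)) if len(vals) else float("nan"),
        log10_pearson_r=r,
        n_species_in_r=int(pos.sum()),
        excluded_species=excluded,
    )


# --------------------------------------------------------------------------
# smFISH spot calling

@dataclass
class Spot:
    x: float  # px
    y: float
    z: int  # section index (of maximal amplitude for merged spots)
    amplitude: float
    sigma: float
    n_sections: int = 1


def _fit_gaussian_2d(patch: np.ndarray, y0: int, x0: int) -> tuple[float, float, float, float]:
    """Least-squares 2D symmetric Gaussian fit on a small patch.

    Returns (x, y, amplitude, sigma) in the patch's parent coordinates;
    falls back to the centre-of-mass on failure.
    """
    yy, xx = np.mgrid[0:patch.shape[0], 0:patch.shape[1]]
    bg = float(patch.min())
    amp0 = float(patch.max() - bg)
    cy0, cx0 = np.unravel_index(np.argmax(patch), patch.shape)

    def model(p):
        a, cx, cy, s, b = p
        return a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s**2)) + b

    def resid(p):
        return (model(p) - patch).ravel()

    try:
        fit = optimize.least_squares(
            resid, [amp0, cx0, cy0, 1.6, bg],
            bounds=([0, -1, -1, 0.3, -np.inf],
                    [np.inf, patch.shape[1], patch.shape[0], 10, np.inf]),
            max_nfev=200,
        )
        a, cx, cy, s, _ = fit.x
        return x0 + cx, y0 + cy, a, s
    except Exception:
        w = np.clip(patch - bg, 0, None)
        tot = w.sum() or 1.0
        return (x0 + (xx * w).sum() / tot, y0 + (yy * w).sum() / tot, amp0, 1.6)


def call_spots(
    stack: ImageStack,
    threshold_sd: float = 6.0,
    merge_radius_px: float = 2.0,
    fit: bool = True,
) -> list[Spot]:
    """Detect single-molecule spots in a 1-bit stack and merge across z.

    Per z section, local maxima above background + ``threshold_sd`` × noise
    (robust estimates) are refined by a 2D Gaussian fit.  Spots appearing in
    adjacent z sections within ``merge_radius_px`` in x,y are combined into
    one, keeping the coordinates of the brightest section.
    """
    if stack.data.shape[0] != 1 or stack.data.shape[1] != 1:
        raise ValueError("call_spots expects a single-round, single-channel stack")
    volume = stack.data[0, 0]
    per_z: list[list[Spot]] = []
    for z in range(volume.shape[0]):
        img = volume[z]
        med = float(np.median(img))
        noise = float(np.median(np.abs(img - med)) / 0.6745) + 1e-9
        peaks = feature.peak_local_max(
            img, min_distance=2, threshold_abs=med + threshold_sd * noise
        )
        spots = []
        r = 5
        for py, pxl in peaks:
            y0, y1 = max(py - r, 0), min(py + r + 1, img.shape[0])
            x0, x1 = max(pxl - r, 0), min(pxl + r + 1, img.shape[1])
            if fit:
                x, y, amp, sig = _fit_gaussian_2d(img[y0:y1, x0:x1], y0, x0)
            else:
                x, y, amp, sig = float(pxl), float(py), float(img[py, pxl] - med), 1.6
            spots.append(Spot(x=x, y=y, z=z, amplitude=amp, sigma=sig))
        per_z.append(spots)
    # merge across adjacent z: greedy chaining, keep brightest section's x,y
    merged: list[Spot] = []
    active: list[Spot] = []
    for z, spots in enumerate(per_z):
        nxt: list[Spot] = []
        unclaimed = list(spots)
        for a in active:
            best, best_d = None, merge_radius_px
            for s in unclaimed:
                d = math.hypot(s.x - a.x, s.y - a.y)
                if d <= best_d:
                    best, best_d = s, d
            if best is not None:
                unclaimed.remove(best)
                keep = best if best.amplitude > a.amplitude else a
                keep = Spot(keep.x, keep.y, keep.z, keep.amplitude, keep.sigma,
                            n_sections=a.n_sections + 1)
                nxt.append(keep)
            else:
                merged.append(a)
        nxt.extend(unclaimed)
        active = nxt
    merged.extend(active)
    return merged


def molecules_per_cell(
    density_per_um2: float,
    cytoplasm_volume_um3: float,
    section_depth_um: float = 1.0,
) -> float:
    """Copy-number extrapolation: total molecules a cytoplasm holds when each
    optical section of ``section_depth_um`` carries ``density_per_um2``.

    molecules = density × (volume / depth) × depth / depth simplifies to
    density × volume / depth: the cytoplasm is a stack of volume/depth·area
    sections each holding density·area molecules.
    """
    return density_per_um2 * cytoplasm_volume_um3 / section_depth_um
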