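"""Pixel-based MERFISH decoding.

The pipeline mirrors the standard pixel-vector decoding scheme:

1. align imaging rounds on fiducial beads (sub-pixel centroid matching, with
   a cross-correlation fallback);
2. per z-plane and bit: high-pass filter to remove background,
   Richardson–Lucy deconvolution to tighten spots, Gaussian low-pass to help
   connect signal across rounds;
3. equalize per-bit intensities (initial quantile scaling refined by
   iterative decoding trials);
4. treat each pixel's 16 normalized intensities as a vector, L2-normalize it
   and assign it to the nearest barcode if the Euclidean distance is below
   the single-bit-error threshold;
5. merge same-barcode pixels across z with 26-connectivity into molecules.

The decoding threshold: after unit normalization, a weight-4 barcode that
lost one on-bit sits at distance sqrt(2 - sqrt(3)) ≈ 0.5176 from its
barcode, and one that gained an extra on-bit at sqrt(2 - 4/sqrt(5)) ≈ 0.4595.
The default threshold is the larger of the two, so both single-bit error
modes remain decodable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, measure, restoration

from .codebook import Codebook
from .simulate import GroundTruth, ImageStack

__all__ = [
    "DecodeConfig",
    "RegistrationResult",
    "NormalizedPixelField",
    "DecodedMolecule",
    "MatchResult",
    "SINGLE_BIT_DROP_DISTANCE",
    "SINGLE_BIT_GAIN_DISTANCE",
    "register_rounds",
    "apply_registration",
    "preprocess",
    "preprocess_stack",
    "normalize_bits",
    "decode_pixels",
    "assemble_molecules",
    "decode_stack",
    "match_to_truth",
]

#: L2 distance between a unit-normalized weight-4 barcode and the same
#: barcode with one on-bit dropped (weight-3 support), also unit-normalized.
SINGLE_BIT_DROP_DISTANCE = math.sqrt(2 - math.sqrt(3))
#: Same with one spurious extra on-bit (weight-5 support).
SINGLE_BIT_GAIN_DISTANCE = math.sqrt(2 - 4 / math.sqrt(5))


@dataclass
class DecodeConfig:
    """Tunable parameters of the decoding pipeline (pixel/count units)."""

    highpass_sigma: float = 3.0
    decon_iterations: int = 3
    # The low-pass connects signal across rounds; its width sets the
    # effective spot scale the decoder sees, slightly above the best-focus
    # spot σ to account for defocus across the optical section.
    lowpass_sigma: float = 2.2
    psf_sigma: float = 1.6
    distance_threshold: float = SINGLE_BIT_DROP_DISTANCE
    norm_quantile: float = 0.99
    norm_tol: float = 1e-3
    norm_max_iters: int = 20
    min_size: int = 1
    # Pixel gate: decode only pixels whose max-bit raw intensity exceeds
    # background + k·noise.  The max over 16 bits inflates the noise tail
    # ~16-fold, so k = 5 keeps the expected number of pure-noise pixels
    # passing the gate below one per megapixel field.
    intensity_gate_sd: float = 5.0
    match_radius_um: float = 0.5


@dataclass
class RegistrationResult:
    """Per-round lateral offsets (dx, dy) in px; reference round is (0, 0)."""

    offsets: np.ndarray  # (n_rounds, 2)
    residual_px: float
    method: str = "beads"


@dataclass
class NormalizedPixelField:
    """Per-pixel 16-component vectors after filtering and bit equalization."""

    vectors: np.ndarray  # (16, nz, ny, nx), filtered / scale
    scale_factors: np.ndarray  # (16,)
    gate_mask: np.ndarray  # (nz, ny, nx) bool, pixels worth decoding
    n_iterations: int = 0


@dataclass
class DecodedMolecule:
    barcode_id: int
    label: str
    x_um: float
    y_um: float
    z_um: float
    n_pixels: int
    distance: float
    was_corrected: bool
    cell_id: int = 0


@dataclass
class MatchResult:
    efficiency: float
    precision: float
    misid_rate: float
    n_true: int
    n_called: int
    n_matched: int
    blank_counts: np.ndarray = field(default_factory=lambda: np.zeros(0))


# --------------------------------------------------------------------------
# registration

def _detect_beads(image: np.ndarray, min_distance: int = 5) -> np.ndarray:
    """Sub-pixel bead centroids in a 2D image, brightest first."""
    med = np.median(image)
    mad = np.median(np.abs(image - med)) + 1e-9
    if image.max() <= med + 10 * mad:
        return np.zeros((0, 2))
    # beads are several-fold brighter than molecule spots: threshold at a
    # fixed fraction of the brightest peak so only fiducials survive
    thr = med + 0.6 * (image.max() - med)
    peaks = feature.peak_local_max(image, min_distance=min_distance, threshold_abs=thr)
    out = []
    r = 3
    for py, pxl in peaks:
        y0, y1 = max(py - r, 0), min(py + r + 1, image.shape[0])
        x0, x1 = max(pxl - r, 0), min(pxl + r + 1, image.shape[1])
        patch = image[y0:y1, x0:x1] - med
        patch = np.clip(patch, 0, None)
        tot = patch.sum()
        if tot <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out.append(((xx * patch).sum() / tot, (yy * patch).sum() / tot))
    return np.array(out) if out else np.zeros((0, 2))


def register_rounds(stack: ImageStack, reference_round: int = 0) -> RegistrationResult:
    """Estimate per-round lateral offsets from fiducial bead positions.

    Uses channel 0 of the middle z section.  Needs at least 3 beads matched
    per round; otherwise falls back to phase cross-correlation on the images.
    """
    zmid = stack.data.shape[2] // 2
    ref_img = stack.data[reference_round, 0, zmid]
    ref_beads = _detect_beads(ref_img)
    offsets = np.zeros((stack.n_rounds, 2))
    residuals = []
    use_beads = len(ref_beads) >= 3
    for rd in range(stack.n_rounds):
        if rd == reference_round:
            continue
        img = stack.data[rd, 0, zmid]
        if use_beads:
            beads = _detect_beads(img)
            if len(beads) >= 3:
                # nearest-neighbour matching; drift assumed < half bead spacing
                d = np.linalg.norm(beads[:, None, :] - ref_beads[None, :, :], axis=2)
                j = np.argmin(d, axis=1)
                keep = d[np.arange(len(beads)), j] < 10.0
                if keep.sum() >= 3:
                    disp = beads[keep] - ref_beads[j[keep]]
                    offsets[rd] = disp.mean(axis=0)
                    residuals.append(float(np.sqrt(((disp - offsets[rd]) ** 2).sum(1).mean())))
                    continue
        # fallback: cross-correlation (dy, dx order from skimage)
        from skimage.registration import phase_cross_correlation

        if float(img.std()) == 0.0 and float(ref_img.std()) == 0.0:
            raise RuntimeError("registration failed: no beads and featureless images")
        shift, _, _ = phase_cross_correlation(ref_img, img, upsample_factor=20)
        offsets[rd] = [-shift[1], -shift[0]]
        residuals.append(0.0)
    return RegistrationResult(
        offsets=offsets,
        residual_px=float(np.mean(residuals)) if residuals else 0.0,
        method="beads" if use_beads else "xcorr",
    )


def apply_registration(stack: ImageStack, registration: RegistrationResult) -> np.ndarray:
    """Shift each round onto the reference frame (bilinear sub-pixel shift).

    Returns registered data with the stack's shape; the input is untouched.
    """
    out = np.empty_like(stack.data)
    for rd in range(stack.n_rounds):
        dx, dy = registration.offsets[rd]
        for ch in range(stack.n_channels):
            for z in range(stack.data.shape[2]):
                if dx == 0 and dy == 0:
                    out[rd, ch, z] = stack.data[rd, ch, z]
                else:
                    out[rd, ch, z] = ndimage.shift(
                        stack.data[rd, ch, z], (-dy, -dx), order=1, mode="nearest"
                    )
    return out


# --------------------------------------------------------------------------
# filtering

def _gaussian_psf(sigma: float) -> np.ndarray:
    r = int(math.ceil(4 * sigma))
    ax = np.arange(-r, r + 1)
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    return k / k.sum()


def preprocess(
    image: np.ndarray,
    highpass_sigma: float = 3.0,
    decon_iterations: int = 10,
    lowpass_sigma: float = 1.0,
    psf_sigma: float = 1.6,
) -> np.ndarray:
    """High-pass, Richardson–Lucy deconvolve, then Gaussian low-pass a 2D image.

    The high-pass is ``image − GaussianBlur(image)`` clipped at zero; the
    deconvolution uses a Gaussian PSF of the imaging σ.  Output is
    non-negative.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("preprocess requires finite input")
    hp = img - ndimage.gaussian_filter(img, highpass_sigma)
    np.clip(hp, 0, None, out=hp)
    if decon_iterations > 0 and hp.max() > 0:
        psf = _gaussian_psf(psf_sigma)
        hp = restoration.richardson_lucy(hp, psf, num_iter=decon_iterations, clip=False)
        np.clip(hp, 0, None, out=hp)
    if lowpass_sigma > 0:
        hp = ndimage.gaussian_filter(hp, lowpass_sigma)
    return hp


def preprocess_stack(
    stack: ImageStack,
    config: DecodeConfig,
    registration: RegistrationResult | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Register and filter a stack into per-bit images.

    Returns ``(filtered, registered_raw)``, both shaped (16, nz, ny, nx) in
    readout bit order.
    """
    data = stack.data if registration is None else None
    if registration is not None:
        data = apply_registration(stack, registration)
    n_bits = stack.n_bits
    nz, ny, nx = data.shape[2:]
    raw = np.empty((n_bits, nz, ny, nx))
    filt = np.empty_like(raw)
    for bit in range(n_bits):
        rd, ch = bit // stack.n_channels, bit % stack.n_channels
        for z in range(nz):
            raw[bit, z] = data[rd, ch, z]
            filt[bit, z] = preprocess(
                data[rd, ch, z],
                highpass_sigma=config.highpass_sigma,
                decon_iterations=config.decon_iterations,
                lowpass_sigma=config.lowpass_sigma,
                psf_sigma=config.psf_sigma,
            )
    return filt, raw


# --------------------------------------------------------------------------
# normalization and pixel decoding

def _decode_vectors(
    vectors: np.ndarray, barcode_matrix: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Assign unit-normalized pixel vectors to nearest normalized barcodes.

    ``vectors`` is (n_pixels, 16) of non-negative normalized intensities.
    Returns (assignment, distance); assignment −1 where unassigned.
    Exact distance ties leave the pixel unassigned.
    """
    norms = np.linalg.norm(vectors, axis=1)
    ok = norms > 0
    assign = np.full(len(vectors), -1, dtype=np.int64)
    dist = np.full(len(vectors), np.inf)
    if not np.any(ok):
        return assign, dist
    v = vectors[ok] / norms[ok, None]
    b = barcode_matrix / np.linalg.norm(barcode_matrix, axis=1, keepdims=True)
    dots = v @ b.T  # both unit: d^2 = 2 - 2 dot
    order = np.argsort(dots, axis=1)
    best, second = order[:, -1], order[:, -2]
    rows = np.arange(len(v))
    d2 = np.clip(2 - 2 * dots[rows, best], 0, None)
    d = np.sqrt(d2)
    # strict-tie pixels stay unassigned (deterministic; measure zero in floats)
    tied = dots[rows, best] == dots[rows, second]
    hit = (d <= threshold + 1e-12) & ~tied
    a = np.full(len(v), -1, dtype=np.int64)
    a[hit] = best[hit]
    assign[ok] = a
    dd = np.full(len(v), np.inf)
    dd[hit] = d[hit]
    dist[ok] = dd
    return assign, dist


def normalize_bits(
    filtered: np.ndarray,
    codebook: Codebook,
    config: DecodeConfig | None = None,
    gate_mask: np.ndarray | None = None,
) -> NormalizedPixelField:
    """Equalize per-bit intensity scales by iterative decoding trials.

    Initial scale for bit b is its ``norm_quantile`` intensity over gated
    pixels; each refinement decodes the field and resets the scale to the
    median intensity of bit b over pixels assigned to barcodes with bit b on,
    stopping when the largest relative change drops below ``norm_tol``.
    """
    config = config or DecodeConfig()
    n_bits = filtered.shape[0]
    if gate_mask is None:
        gate_mask = np.ones(filtered.shape[1:], dtype=bool)
    flat = filtered.reshape(n_bits, -1)
    gate_flat = gate_mask.ravel()
    for b in range(n_bits):
        if flat[b].max() == 0:
            raise ValueError(f"bit {b + 1} image is identically zero; cannot normalize")
    sel = flat[:, gate_flat]
    s = np.quantile(sel, config.norm_quantile, axis=1)
    s = np.where(s <= 0, np.quantile(sel, 1.0, axis=1), s)
    s = np.where(s <= 0, 1.0, s)
    bits_on = codebook.bit_matrix.astype(bool)
    n_iter = 0
    for n_iter in range(1, config.norm_max_iters + 1):
        vecs = (sel / s[:, None]).T
        assign, _ = _decode_vectors(vecs, codebook.bit_matrix.astype(float),
                                    config.distance_threshold)
        new_s = s.copy()
        for b in range(n_bits):
            hit = assign >= 0
            on = np.zeros(len(assign), dtype=bool)
            on[hit] = bits_on[assign[hit], b]
            if on.sum() >= 10:
                med = np.median(sel[b, on])
                if med > 0:
                    new_s[b] = med
        change = np.max(np.abs(new_s - s) / s)
        s = new_s
        if change < config.norm_tol:
            break
    vectors = filtered / s[:, None, None, None]
    return NormalizedPixelField(
        vectors=vectors, scale_factors=s, gate_mask=gate_mask, n_iterations=n_iter
    )


def compute_gate_mask(raw: np.ndarray, config: DecodeConfig,
                      background: float | None = None,
                      read_noise_sd: float | None = None) -> np.ndarray:
    """Pixels worth decoding: max-bit raw intensity above background + k·noise.

    Background and noise default to robust image estimates (median and MAD).
    """
    mx = raw.max(axis=0)
    if background is None:
        background = float(np.median(raw))
    if read_noise_sd is None:
        read_noise_sd = float(np.median(np.abs(raw - background)) / 0.6745)
    return mx > background + config.intensity_gate_sd * max(read_noise_sd, 1e-9)


def decode_pixels(
    pixel_field: NormalizedPixelField,
    codebook: Codebook,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign every gated pixel to a barcode (or −1).

    Returns ``(barcode_map, distance_map)`` of shape (nz, ny, nx).
    """
    cfg_thr = SINGLE_BIT_DROP_DISTANCE if threshold is None else threshold
    n_bits = pixel_field.vectors.shape[0]
    shape = pixel_field.vectors.shape[1:]
    flat = pixel_field.vectors.reshape(n_bits, -1).T
    gate = pixel_field.gate_mask.ravel()
    assign = np.full(flat.shape[0], -1, dtype=np.int64)
    dist = np.full(flat.shape[0], np.inf)
    if gate.any():
        a, d = _decode_vectors(flat[gate], codebook.bit_matrix.astype(float), cfg_thr)
        assign[gate] = a
        dist[gate] = d
    return assign.reshape(shape), dist.reshape(shape)


# --------------------------------------------------------------------------
# molecule assembly

def assemble_molecules(
    barcode_map: np.ndarray,
    codebook: Codebook,
    geometry,
    intensity: np.ndarray | None = None,
    distance_map: np.ndarray | None = None,
    vectors: np.ndarray | None = None,
    min_size: int = 1,
) -> list[DecodedMolecule]:
    """Group same-barcode pixels into molecules with 26-connectivity in 3D.

    ``barcode_map`` is (nz, ny, nx) with −1 for unassigned pixels.  Each
    connected component becomes one molecule with an intensity-weighted
    centroid (µm, image frame); components below ``min_size`` pixels are
    dropped.  ``was_corrected`` records whether the component's binarized
    mean vector differs from its barcode.
    """
    nz, ny, nx = barcode_map.shape
    if intensity is None:
        intensity = np.ones_like(barcode_map, dtype=float)
    px = geometry.pixel_um
    molecules: list[DecodedMolecule] = []
    present = np.unique(barcode_map)
    present = present[present >= 0]
    bits_on = codebook.bit_matrix.astype(bool)
    for bc in present:
        mask = barcode_map == bc
        labeled = measure.label(mask, connectivity=3)
        for comp in range(1, labeled.max() + 1):
            sel = labeled == comp
            n_pix = int(sel.sum())
            if n_pix < min_size:
                continue
            w = intensity[sel]
            if w.sum() <= 0:
                w = np.ones(n_pix)
            zz, yy, xx = np.nonzero(sel)
            cx = float((xx * w).sum() / w.sum())
            cy = float((yy * w).sum() / w.sum())
            cz = float((zz * w).sum() / w.sum())
            mean_dist = (
                float(np.mean(distance_map[sel])) if distance_map is not None else 0.0
            )
            corrected = False
            if vectors is not None:
                mean_vec = vectors[:, sel].mean(axis=1)
                on = mean_vec >= 0.5 * mean_vec.max() if mean_vec.max() > 0 else mean_vec > 0
                corrected = not np.array_equal(on, bits_on[bc])
            molecules.append(
                DecodedMolecule(
                    barcode_id=int(bc),
                    label=codebook.barcodes[bc].label,
                    x_um=cx * px,
                    y_um=cy * px,
                    z_um=(cz + 0.5) * geometry.z_step * geometry.expansion_factor,
                    n_pixels=n_pix,
                    distance=mean_dist,
                    was_corrected=bool(corrected),
                )
            )
    return molecules


def decode_stack(
    stack: ImageStack,
    codebook: Codebook,
    config: DecodeConfig | None = None,
    register: bool = True,
) -> tuple[list[DecodedMolecule], dict]:
    """Run the full pipeline on a stack; returns molecules and a report."""
    config = config or DecodeConfig()
    registration = None
    if register:
        registration = register_rounds(stack)
    filtered, raw = preprocess_stack(stack, config, registration)
    gate = compute_gate_mask(raw, config,
                             background=stack.optics.background,
                             read_noise_sd=max(stack.optics.read_noise_sd,
                                               math.sqrt(max(stack.optics.background, 1))))
    field_ = normalize_bits(filtered, codebook, config, gate_mask=gate)
    barcode_map, dist_map = decode_pixels(field_, codebook, config.distance_threshold)
    mols = assemble_molecules(
        barcode_map,
        codebook,
        stack.geometry,
        intensity=field_.vectors.sum(axis=0),
        distance_map=dist_map,
        vectors=field_.vectors,
        min_size=config.min_size,
    )
    counts = np.bincount([m.barcode_id for m in mols], minlength=len(codebook))
    report = {
        "scale_factors": field_.scale_factors.tolist(),
        "norm_iterations": field_.n_iterations,
        "n_molecules": len(mols),
        "per_barcode_counts": counts.tolist(),
        "registration_offsets": registration.offsets.tolist() if registration else None,
    }
    return mols, report


# --------------------------------------------------------------------------
# ground-truth matching

def match_to_truth(
    molecules: list[DecodedMolecule],
    truth: GroundTruth,
    radius_um: float = 0.5,
    codebook: Codebook | None = None,
) -> MatchResult:
    """Greedy nearest-neighbour matching of calls to true molecules.

    A call matches an unused true molecule if it carries the same barcode and
    lies within ``radius_um`` (image frame).  Efficiency = matched / true;
    precision = matched / called; the misidentification rate is the mean
    count per blank barcode divided by the mean count per gene barcode.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    from scipy.spatial import cKDTree

    n_true = len(truth)
    n_called = len(molecules)
    matched = 0
    # group by barcode
    called_by_bc: dict[int, list[DecodedMolecule]] = {}
    for m in molecules:
        called_by_bc.setdefault(m.barcode_id, []).append(m)
    truth_xy = np.column_stack([truth.x, truth.y])
    for bc, calls in called_by_bc.items():
        t_idx = np.flatnonzero(truth.barcode_idx == bc)
        if len(t_idx) == 0:
            continue
        tree = cKDTree(truth_xy[t_idx])
        used = np.zeros(len(t_idx), dtype=bool)
        # larger molecules first: they are the more confident calls
        for m in sorted(calls, key=lambda m: -m.n_pixels):
            hits = tree.query_ball_point([m.x_um, m.y_um], r=radius_um)
            hits = [h for h in hits if not used[h]]
            if hits:
                d = [math.hypot(truth_xy[t_idx[h], 0] - m.x_um,
                                truth_xy[t_idx[h], 1] - m.y_um) for h in hits]
                used[hits[int(np.argmin(d))]] = True
                matched += 1
    efficiency = matched / n_true if n_true else 0.0
    precision = matched / n_called if n_called else 0.0
    misid, blank_counts = _misid_rate(molecules, codebook)
    return MatchResult(
        efficiency=efficiency,
        precision=precision,
        misid_rate=misid,
        n_true=n_true,
        n_called=n_called,
        n_matched=matched,
        blank_counts=blank_counts,
    )


def _misid_rate(
    molecules: list[DecodedMolecule], codebook: Codebook | None
) -> tuple[float, np.ndarray]:
    """Mean count per blank barcode over mean count per gene barcode.

    With a codebook, the means run over *all* blank and gene barcodes so that
    undetected barcodes count as zero; without one, only observed barcodes
    contribute.
    """
    counts: dict[int, int] = {}
    is_blank: dict[int, bool] = {}
    for m in molecules:
        counts[m.barcode_id] = counts.get(m.barcode_id, 0) + 1
        is_blank[m.barcode_id] = m.label.startswith("Blank-")
    if codebook is not None:
        blank_ids = [b.index for b in codebook if b.label.startswith("Blank-")]
        gene_ids = [b.index for b in codebook
                    if b.label and not b.label.startswith("Blank-")]
    else:
        blank_ids = [i for i, bl in is_blank.items() if bl]
        gene_ids = [i for i, bl in is_blank.items() if not bl]
    blank_counts = np.array([counts.get(i, 0) for i in blank_ids], dtype=float)
    if not gene_ids:
        return 0.0, blank_counts
    mean_gene = float(np.mean([counts.get(i, 0) for i in gene_ids]))
    mean_blank = float(blank_counts.mean()) if len(blank_counts) else 0.0
    return (mean_blank / mean_gene if mean_gene > 0 else 0.0), blank_counts
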