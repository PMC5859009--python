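"""Synthetic multiplexed-FISH data: ground-truth molecules and image stacks.

The simulator emulates the imaging side of a MERFISH experiment: molecules
are scattered uniformly over a field of view at a controlled areal density
(molecules/µm² per optical section), each molecule carries a 16-bit barcode
whose four "on" bits produce diffraction-limited Gaussian spots (σ = 1.6 px
on a 109-nm pixel grid by default) across 8 two-color imaging rounds.
Physical expansion of the sample is modelled as a linear scaling of all
coordinates by ``expansion_factor`` before rasterization: the molecules keep
their identity and brightness but move apart, which is the mechanism by which
expansion recovers decoding efficiency at high density.

Noise model: per-molecule-per-bit lognormal amplitudes, constant background,
Poisson shot noise and Gaussian read noise.  Fiducial beads are rendered at
fixed positions in every round, and a per-round whole-frame drift can be
injected for registration testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .codebook import Codebook

__all__ = [
    "FieldGeometry",
    "OpticsModel",
    "GroundTruth",
    "ImageStack",
    "place_molecules",
    "corrupt_bits",
    "render_stack",
    "simulate_smfish",
    "simulate_cell_field",
    "CellField",
]

N_ROUNDS = 8
N_CHANNELS = 2


@dataclass(frozen=True)
class FieldGeometry:
    """Field-of-view geometry.  ``fov_x``/``fov_y`` are pre-expansion µm;
    image dimensions grow with the linear expansion factor."""

    fov_x: float = 40.0
    fov_y: float = 40.0
    n_z: int = 1
    z_step: float = 1.0  # µm
    pixel_size: float = 109.0  # nm
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")

    @property
    def pixel_um(self) -> float:
        return self.pixel_size / 1000.0

    @property
    def shape_yx(self) -> tuple[int, int]:
        ny = math.ceil(self.fov_y * self.expansion_factor / self.pixel_um)
        nx = math.ceil(self.fov_x * self.expansion_factor / self.pixel_um)
        return ny, nx

    @property
    def area_um2(self) -> float:
        """Pre-expansion FOV area (µm²)."""
        return self.fov_x * self.fov_y


@dataclass(frozen=True)
class OpticsModel:
    """Point-spread, brightness and noise parameters (pixel/count units)."""

    psf_sigma: float = 1.6  # px
    amplitude_mean: float = 1000.0  # peak counts per molecule-bit
    # Brightness varies mostly per molecule (how many of the ~92 encoding
    # probes bound), shared by its four on-bits, with a smaller independent
    # per-bit factor (readout hybridization efficiency).  Both lognormal.
    amplitude_cv: float = 0.5  # molecule-level coefficient of variation
    bit_cv: float = 0.2  # independent per-bit coefficient of variation
    # Relative brightness of the two color channels: the far-red readout dye
    # yields substantially fewer detected photons than the red one, so its
    # bits sit closer to the noise floor before equalization.
    channel_gain: tuple[float, float] = (1.0, 0.4)
    background: float = 100.0  # counts
    read_noise_sd: float = 2.0  # counts
    shot_noise: bool = True
    bead_count: int = 20
    bead_amplitude: float = 5000.0
    per_round_drift: tuple[tuple[float, float], ...] | None = None  # (dx, dy) px
    z_spread_sigma_um: float = 0.0  # optional axial extent of a spot

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        for name in ("amplitude_mean", "amplitude_cv", "background",
                     "read_noise_sd", "bead_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Simulated molecules: identity, realized bits and expanded coordinates.

    Coordinates are stored in the *expanded* (image) frame in µm, i.e.
    pre-expansion positions multiplied by the linear expansion factor, so the
    areal density seen by the camera is ``density / expansion_factor**2``.
    """

    species: np.ndarray  # (N,) labels
    barcode_idx: np.ndarray  # (N,) int
    bits_true: np.ndarray  # (N, 16) uint8
    bits_realized: np.ndarray  # (N, 16) uint8
    x: np.ndarray  # (N,) µm, expanded frame
    y: np.ndarray
    z: np.ndarray
    geometry: FieldGeometry
    amplitudes: np.ndarray | None = None  # (N, 16), filled by render_stack
    cell_id: np.ndarray | None = None  # for synthetic cell fields

    def __len__(self) -> int:
        return len(self.barcode_idx)


@dataclass
class ImageStack:
    """Rounds × channels × z × y × x intensities with calibration metadata.

    Bit ``b`` (0-based) maps to round ``b // 2``, channel ``b % 2``.
    """

    data: np.ndarray
    geometry: FieldGeometry
    optics: OpticsModel
    bead_xy: np.ndarray | None = None  # (K, 2) px, undrifted
    drift: np.ndarray | None = None  # (n_rounds, 2) px (dx, dy)

    @property
    def n_rounds(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_bits(self) -> int:
        return self.n_rounds * self.n_channels

    def bit_image(self, bit: int) -> np.ndarray:
        """The (z, y, x) image for one bit in readout order."""
        return self.data[bit // self.n_channels, bit % self.n_channels]


def place_molecules(
    codebook: Codebook,
    density: float,
    geometry: FieldGeometry,
    seed: int,
    abundance: np.ndarray | None = None,
    n_molecules: int | None = None,
) -> GroundTruth:
    """Scatter molecules uniformly over the field of view.

    Parameters
    ----------
    density : float
        Molecules per µm² per optical section, in pre-expansion units.  The
        molecule count per section is Poisson(density × FOV area) unless
        ``n_molecules`` fixes it exactly.
    abundance : array, optional
        Relative species weights (length = codebook size).  If omitted,
        weights are uniform over gene-assigned barcodes; blank barcodes are
        misidentification controls and receive no molecules.
    """
    if len(codebook) == 0:
        raise ValueError("codebook is empty")
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    per_section = density * geometry.area_um2
    if n_molecules is not None:
        counts = [n_molecules] if geometry.n_z == 1 else rng.multinomial(
            n_molecules, np.full(geometry.n_z, 1 / geometry.n_z))
    else:
        counts = rng.poisson(per_section, size=geometry.n_z)
    n = int(np.sum(counts))
    if abundance is None:
        blank = np.array([b.label.startswith("Blank-") for b in codebook])
        p = np.where(blank, 0.0, 1.0)
        p = p / p.sum()
    else:
        p = np.asarray(abundance, dtype=float)
        p = p / p.sum()
    idx = rng.choice(len(codebook), size=n, p=p)
    x = rng.uniform(0, geometry.fov_x, size=n)
    y = rng.uniform(0, geometry.fov_y, size=n)
    z_sec = np.repeat(np.arange(geometry.n_z), counts)
    z = (z_sec + rng.uniform(0, 1, size=n)) * geometry.z_step
    bits = codebook.bit_matrix[idx]
    labels = np.array(codebook.labels, dtype=object)
    f = geometry.expansion_factor
    return GroundTruth(
        species=labels[idx],
        barcode_idx=idx.astype(np.int64),
        bits_true=bits.copy(),
        bits_realized=bits.copy(),
        x=x * f,
        y=y * f,
        z=z * f,
        geometry=geometry,
    )


def corrupt_bits(
    truth: GroundTruth, p_drop: float, p_gain: float, seed: int
) -> GroundTruth:
    """Apply independent per-bit readout errors.

    Each on-bit is dropped (1→0) with probability ``p_drop`` and each off-bit
    gained (0→1) with probability ``p_gain``; true bits are preserved.
    """
    for p in (p_drop, p_gain):
        if not 0 <= p <= 1:
            raise ValueError("error probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=truth.bits_true.shape)
    on = truth.bits_true == 1
    realized = truth.bits_true.copy()
    realized[on & (u < p_drop)] = 0
    realized[~on & (u < p_gain)] = 1
    return replace(truth, bits_realized=realized)


def _stamp_spots(
    image: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    amps: np.ndarray,
    sigma: float,
) -> None:
    """Accumulate peak-normalized 2D Gaussians into ``image`` in place.

    Spots are truncated at a 6σ half-window; sub-pixel centers are honoured
    by evaluating the Gaussian at pixel centers.
    """
    if len(xs) == 0:
        return
    ny, nx = image.shape
    r = int(math.ceil(6 * sigma))
    w = 2 * r + 1
    off = np.arange(-r, r + 1)
    cx = np.round(xs).astype(int)
    cy = np.round(ys).astype(int)
    gx = cx[:, None] + off[None, :]  # (N, w)
    gy = cy[:, None] + off[None, :]
    ex = np.exp(-((gx - xs[:, None]) ** 2) / (2 * sigma**2))
    ey = np.exp(-((gy - ys[:, None]) ** 2) / (2 * sigma**2))
    patch = amps[:, None, None] * ey[:, :, None] * ex[:, None, :]  # (N, w, w)
    iy = np.clip(gy, 0, ny - 1)
    ix = np.clip(gx, 0, nx - 1)
    valid = ((gy >= 0) & (gy < ny))[:, :, None] & ((gx >= 0) & (gx < nx))[:, None, :]
    iyy = np.broadcast_to(iy[:, :, None], patch.shape)
    ixx = np.broadcast_to(ix[:, None, :], patch.shape)
    np.add.at(image, (iyy[valid], ixx[valid]), patch[valid])


def _lognormal(rng, mean, cv, shape):
    if cv <= 0:
        return np.full(shape, mean)
    s2 = math.log(1 + cv**2)
    return rng.lognormal(math.log(mean) - s2 / 2, math.sqrt(s2), size=shape)


def _draw_amplitudes(rng: np.random.Generator, optics: OpticsModel, shape) -> np.ndarray:
    """Per-(molecule, bit) peak amplitudes: shared molecule factor × per-bit factor."""
    n_mol, n_bits = shape
    mol = _lognormal(rng, optics.amplitude_mean, optics.amplitude_cv, (n_mol, 1))
    bit = _lognormal(rng, 1.0, optics.bit_cv, shape)
    gain = np.array([optics.channel_gain[b % N_CHANNELS] for b in range(n_bits)])
    return mol * bit * gain[None, :]


def _z_weights(z_um: float, geometry: FieldGeometry, sigma_z: float) -> list[tuple[int, float]]:
    """Sections a molecule contributes to and its relative weight in each."""
    centers = (np.arange(geometry.n_z) + 0.5) * geometry.z_step * geometry.expansion_factor
    if sigma_z <= 0:
        sec = int(np.argmin(np.abs(centers - z_um)))
        return [(sec, 1.0)]
    w = np.exp(-((centers - z_um) ** 2) / (2 * sigma_z**2))
    w = w / w.max()
    return [(int(i), float(v)) for i, v in enumerate(w) if v > 1e-3]


def render_stack(
    truth: GroundTruth,
    geometry: FieldGeometry,
    optics: OpticsModel,
    seed: int,
) -> ImageStack:
    """Rasterize ground truth into an 8-round × 2-channel image stack.

    Every realized on-bit contributes a Gaussian spot (σ = ``psf_sigma``) at
    the molecule's position in its z section; off-bits contribute nothing.
    Fiducial beads appear at the same positions in every round; the optional
    per-round drift translates the whole frame (molecules and beads alike).
    Background, Poisson shot noise and Gaussian read noise are then applied.
    """
    rng = np.random.default_rng(seed)
    ny, nx = geometry.shape_yx
    n_rounds, n_channels = N_ROUNDS, N_CHANNELS
    drift = optics.per_round_drift
    if drift is not None and len(drift) != n_rounds:
        raise ValueError(f"per_round_drift must have {n_rounds} entries")
    drift_arr = np.zeros((n_rounds, 2)) if drift is None else np.asarray(drift, float)

    amps = _draw_amplitudes(rng, optics, (len(truth), 16))
    truth.amplitudes = amps

    px = geometry.pixel_um
    mx = truth.x / px
    my = truth.y / px
    bead_xy = None
    if optics.bead_count > 0:
        bead_xy = np.column_stack(
            [rng.uniform(0, nx, optics.bead_count), rng.uniform(0, ny, optics.bead_count)]
        )

    data = np.zeros((n_rounds, n_channels, geometry.n_z, ny, nx), dtype=np.float64)
    sigma_z = optics.z_spread_sigma_um
    # per-molecule section memberships (shared across bits)
    zw = [_z_weights(zv, geometry, sigma_z) for zv in truth.z]
    for bit in range(16):
        rd, ch = bit // n_channels, bit % n_channels
        dx, dy = drift_arr[rd]
        on = np.flatnonzero(truth.bits_realized[:, bit] == 1)
        # group by z section
        for sec in range(geometry.n_z):
            sel, wts = [], []
            for i in on:
                for s, w in zw[i]:
                    if s == sec:
                        sel.append(i)
                        wts.append(w)
            if sel:
                sel = np.asarray(sel)
                wts = np.asarray(wts)
                _stamp_spots(
                    data[rd, ch, sec],
                    mx[sel] + dx,
                    my[sel] + dy,
                    amps[sel, bit] * wts,
                    optics.psf_sigma,
                )
    if bead_xy is not None:
        for rd in range(n_rounds):
            dx, dy = drift_arr[rd]
            for ch in range(n_channels):
                for sec in range(geometry.n_z):
                    _stamp_spots(
                        data[rd, ch, sec],
                        bead_xy[:, 0] + dx,
                        bead_xy[:, 1] + dy,
                        np.full(len(bead_xy), optics.bead_amplitude),
                        optics.psf_sigma,
                    )
    data += optics.background
    if optics.shot_noise:
        data = rng.poisson(data).astype(np.float64)
    if optics.read_noise_sd > 0:
        data += rng.normal(0, optics.read_noise_sd, size=data.shape)
    np.clip(data, 0, None, out=data)
    return ImageStack(
        data=data, geometry=geometry, optics=optics, bead_xy=bead_xy, drift=drift_arr
    )


def simulate_smfish(
    positions_um: np.ndarray,
    geometry: FieldGeometry,
    optics: OpticsModel,
    seed: int,
) -> ImageStack:
    """Render a single-round, single-channel (1-bit) stack for spot calling.

    ``positions_um`` is (N, 3) x, y, z in the image frame (µm); every
    molecule is "on" in the single bit, as in an smFISH measurement of one
    gene with one readout probe.
    """
    pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
    n = len(pos)
    truth = GroundTruth(
        species=np.array(["smFISH"] * n, dtype=object),
        barcode_idx=np.zeros(n, dtype=np.int64),
        bits_true=np.ones((n, 16), dtype=np.uint8),
        bits_realized=np.ones((n, 16), dtype=np.uint8),
        x=pos[:, 0],
        y=pos[:, 1],
        z=pos[:, 2],
        geometry=geometry,
    )
    stack = render_stack(truth, geometry, optics, seed)
    return ImageStack(
        data=stack.data[:1, :1],
        geometry=geometry,
        optics=optics,
        bead_xy=stack.bead_xy,
        drift=stack.drift[:1],
    )


@dataclass
class CellField:
    """Synthetic cell layout: molecule truth plus nucleus seeds for watershed."""

    truth: GroundTruth
    cell_centers_um: np.ndarray  # (n_cells, 2), image frame
    cell_radius_um: np.ndarray  # (n_cells,)
    seed_mask: np.ndarray  # (ny, nx) int labels, nucleus disks
    counts: np.ndarray  # (n_cells, n_species) true per-cell counts


def simulate_cell_field(
    codebook: Codebook,
    n_cells: int,
    geometry: FieldGeometry,
    seed: int,
    molecules_per_cell: float = 300.0,
    cell_radius_um: float | np.ndarray = 8.0,
    nucleus_radius_um: float = 3.0,
    counts_per_cell: np.ndarray | None = None,
) -> CellField:
    """Lay out non-overlapping round cells with clustered molecules.

    Cell centers are placed on a jittered grid so neighbouring clouds stay
    disjoint; molecules scatter uniformly inside each cell disk.  The seed
    mask contains one labelled nucleus disk per cell, emulating DAPI seeds.
    ``counts_per_cell`` ((n_cells, n_species), optional) fixes the exact
    per-cell composition; otherwise counts are Poisson around
    ``molecules_per_cell`` with uniform species.
    """
    rng = np.random.default_rng(seed)
    f = geometry.expansion_factor
    ny, nx = geometry.shape_yx
    px = geometry.pixel_um
    # jittered grid in expanded-frame µm
    n_side = math.ceil(math.sqrt(n_cells))
    pitch_x = geometry.fov_x * f / n_side
    pitch_y = geometry.fov_y * f / n_side
    r_um = np.broadcast_to(np.asarray(cell_radius_um, dtype=float), (n_cells,))
    centers = []
    for k in range(n_cells):
        gx, gy = k % n_side, k // n_side
        jit = rng.uniform(-0.2, 0.2, size=2)
        cxu = (gx + 0.5 + jit[0]) * pitch_x
        cyu = (gy + 0.5 + jit[1]) * pitch_y
        centers.append((cxu, cyu))
    centers = np.array(centers)

    n_species = len(codebook)
    if counts_per_cell is None:
        counts = rng.poisson(molecules_per_cell / n_species, size=(n_cells, n_species))
    else:
        counts = np.asarray(counts_per_cell, dtype=int)
        if counts.shape != (n_cells, n_species):
            raise ValueError("counts_per_cell must be (n_cells, n_species)")

    xs, ys, zs, species_idx, cell_ids = [], [], [], [], []
    for c in range(n_cells):
        n_c = int(counts[c].sum())
        theta = rng.uniform(0, 2 * math.pi, n_c)
        rad = r_um[c] * np.sqrt(rng.uniform(0, 1, n_c))
        xs.append(centers[c, 0] + rad * np.cos(theta))
        ys.append(centers[c, 1] + rad * np.sin(theta))
        zs.append(rng.uniform(0, geometry.n_z * geometry.z_step * f, n_c))
        species_idx.append(np.repeat(np.arange(n_species), counts[c]))
        cell_ids.append(np.full(n_c, c + 1))
    x = np.clip(np.concatenate(xs), 0, geometry.fov_x * f - 1e-9)
    y = np.clip(np.concatenate(ys), 0, geometry.fov_y * f - 1e-9)
    z = np.concatenate(zs)
    idx = np.concatenate(species_idx).astype(np.int64)
    labels = np.array(codebook.labels, dtype=object)
    bits = codebook.bit_matrix[idx]
    truth = GroundTruth(
        species=labels[idx],
        barcode_idx=idx,
        bits_true=bits.copy(),
        bits_realized=bits.copy(),
        x=x,
        y=y,
        z=z,
        geometry=geometry,
        cell_id=np.concatenate(cell_ids).astype(np.int64),
    )
    # nucleus seed disks
    seed_mask = np.zeros((ny, nx), dtype=np.int32)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for c, (cxu, cyu) in enumerate(centers):
        d2 = (xx - cxu / px) ** 2 + (yy - cyu / px) ** 2
        seed_mask[d2 <= (nucleus_radius_um / px) ** 2] = c + 1
    return CellField(
        truth=truth,
        cell_centers_um=centers,
        cell_radius_um=r_um,
        seed_mask=seed_mask,
        counts=counts,
    )
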