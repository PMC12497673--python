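"""Digital phantom, synthetic coil maps, and k-space synthesis.

The synthesizer implements the extended-readout signal model: the
magnetization state M_{q,v} evolves through the pulse train (Bloch
simulation) and accrues only the off-resonance phase
``exp(-i 2 pi Delta_v tau_p)`` during each readout — within-readout
relaxation is neglected.  Sampling follows the stack-of-spirals
trajectory and golden-ratio schedule, with i.i.d. complex Gaussian
noise added per sample and coil.

Synthesis uses an exact (vectorized) non-uniform DFT sum rather than
the gridding operator used for reconstruction, so the generated data is
an independent ground truth for the reconstruction chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .bloch import SlabEnsemble, simulate_mu_batch, simulate_si_batch
from .sampling import SamplingOperator
from .sequence import PulseTrain

__all__ = [
    "ParamMap",
    "CoilMaps",
    "KSpaceData",
    "make_phantom",
    "make_coilmaps",
    "synthesize_kspace",
    "save_kspace",
    "load_kspace_arrays",
]


@dataclass
class ParamMap:
    """Per-voxel tissue parameters over a 2D image grid plus validity mask."""

    t1: np.ndarray      # ms
    t2: np.ndarray      # ms
    delta: np.ndarray   # Hz
    b1: np.ndarray      # dimensionless
    i0: np.ndarray      # complex apparent proton density
    mask: np.ndarray    # bool, True = valid voxel

    def __post_init__(self) -> None:
        shp = self.mask.shape
        for name in ("t1", "t2", "delta", "b1", "i0"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"{name} shape does not match mask")
        if np.any(self.i0[~self.mask] != 0):
            raise ValueError("masked-out voxels must have I0 = 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def masked(self, name: str) -> np.ndarray:
        """Flat array of parameter ``name`` over valid voxels."""
        return getattr(self, name)[self.mask]


@dataclass
class CoilMaps:
    """Complex coil sensitivities, shape (n_coils, *grid_shape)."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        if self.maps.ndim < 2:
            raise ValueError("maps must be (n_coils, ...grid)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


@dataclass
class KSpaceData:
    """Acquired/synthesized samples, shape (n_contrasts, n_coils, P).

    Sample ordering per contrast is shot-major, matching
    ``SamplingOperator``: samples of the first scheduled interleave, then
    the second, and so on; within an interleave the within-readout offset
    tau runs from 0 to the readout length.
    """

    data: np.ndarray
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (n_contrasts, n_coils, P)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite k-space samples")

    @property
    def n_contrasts(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# digital phantom
# ---------------------------------------------------------------------------

#: nominal tube relaxation times, ms (synthetic defaults in the spirit of
#: Eurospin gel tubes; not calibrated against any physical phantom)
DEFAULT_TUBE_T1 = (300.0, 600.0, 1000.0, 1500.0)
DEFAULT_TUBE_T2 = (50.0, 80.0, 120.0, 200.0)

#: default smooth B0 polynomial (Hz): const, x, y, r^2 terms on [-1, 1] coords
DEFAULT_B0_POLY = (0.0, 20.0, 10.0, 30.0)

#: default radial B1 profile: center value and r^2 coefficient
DEFAULT_B1_RADIAL = (1.05, -0.2)


def _tube_geometry(grid_shape, n_tubes, tube_radius_frac):
    """Tube centers, radius, and per-voxel distances in unit coordinates."""
    nx, ny = grid_shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    u = (xx - nx / 2 + 0.5) / (nx / 2)
    v = (yy - ny / 2 + 0.5) / (ny / 2)
    ang = 2 * np.pi * np.arange(n_tubes) / n_tubes + np.pi / n_tubes
    centers = 0.5 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    radius = 2.0 * tube_radius_frac  # unit coords (FOV spans [-1, 1])
    dists = np.stack([np.hypot(u - c[0], v - c[1]) for c in centers])
    return u, v, centers, radius, dists


def make_phantom(grid_shape: tuple[int, int] = (32, 32),
                 tube_t1=DEFAULT_TUBE_T1,
                 tube_t2=DEFAULT_TUBE_T2,
                 tube_radius_frac: float = 0.16,
                 b0_poly=DEFAULT_B0_POLY,
                 b1_radial=DEFAULT_B1_RADIAL,
                 edge_smooth_px: float = 1.2,
                 background: tuple | None = (0.3, 2000.0, 250.0),
                 background_radius_frac: float = 0.45) -> ParamMap:
    """Four-tube (or n-tube) disk phantom with smooth B0 and B1 fields.

    Tubes are placed on a circle of half the FOV radius.  The proton
    density of each tube tapers to zero over ``edge_smooth_px`` pixels
    (raised cosine) so the phantom is nearly band-limited within the
    sampled k-space disk; relaxation parameters are constant across each
    tube.  ``b0_poly`` gives (const, cx, cy, cr2) coefficients of
    Delta(u, v) = const + cx u + cy v + cr2 (u^2 + v^2) on unit
    coordinates, and ``b1_radial = (center, cr2)`` gives
    B1(r) = center + cr2 (u^2 + v^2).

    ``background = (i0, t1_ms, t2_ms)`` adds a weak connected medium (a
    centered disk of ``background_radius_frac`` of the FOV) surrounding
    the tubes, as in a physical phantom where tubes sit in a filled
    holder; it makes the signal support simply connected, which spatial
    B0 unwrapping relies on.  ``background=None`` gives isolated tubes.
    """
    tube_t1 = np.asarray(tube_t1, dtype=float)
    tube_t2 = np.asarray(tube_t2, dtype=float)
    if tube_t1.size != tube_t2.size:
        raise ValueError("tube_t1 and tube_t2 must have equal length")
    n_tubes = tube_t1.size
    nx, ny = grid_shape
    u, v, centers, radius, dists = _tube_geometry(grid_shape, n_tubes,
                                                  tube_radius_frac)
    if n_tubes > 1:
        dmin = np.min([np.linalg.norm(centers[i] - centers[j])
                       for i in range(n_tubes) for j in range(i)])
        if dmin < 2 * radius:
            raise ValueError("tubes overlap; reduce tube_radius_frac")

    w = edge_smooth_px / (nx / 2)  # taper width in unit coords
    t1 = np.zeros(grid_shape)
    t2 = np.zeros(grid_shape)
    profile = np.zeros(grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    if background is not None:
        bg_i0, bg_t1, bg_t2 = background
        r_bg = 2.0 * background_radius_frac
        d_bg = np.hypot(u, v)
        p_bg = np.clip((r_bg - d_bg) / max(w, 1e-9), 0.0, 1.0)
        p_bg = 0.5 - 0.5 * np.cos(np.pi * p_bg)
        bg = p_bg > 0
        mask |= bg
        profile[bg] = bg_i0 * p_bg[bg]
        t1[bg] = bg_t1
        t2[bg] = bg_t2
    tube_mask = np.zeros(grid_shape, dtype=bool)
    for d, a1, a2 in zip(dists, tube_t1, tube_t2):
        p = np.clip((radius - d) / max(w, 1e-9), 0.0, 1.0)
        p = 0.5 - 0.5 * np.cos(np.pi * p)  # raised-cosine edge
        inside = p > 0
        if np.any(tube_mask & inside):
            raise ValueError("tubes overlap on the grid")
        tube_mask |= inside
        mask |= inside
        # tubes replace the background medium where they sit
        profile[inside] = np.maximum(profile[inside], p[inside])
        t1[inside] = a1
        t2[inside] = a2

    c0, cx, cy, cr2 = b0_poly
    delta = c0 + cx * u + cy * v + cr2 * (u ** 2 + v ** 2)
    bc, br2 = b1_radial
    b1 = bc + br2 * (u ** 2 + v ** 2)
    b1 = np.clip(b1, 0.8, 1.2)

    i0 = profile.astype(complex)
    t1[~mask] = 1000.0  # placeholder relaxation outside the mask
    t2[~mask] = 100.0
    return ParamMap(t1=t1, t2=t2, delta=delta * mask, b1=b1,
                    i0=i0, mask=mask)


def tube_rois(grid_shape: tuple[int, int] = (32, 32), n_tubes: int = 4,
              tube_radius_frac: float = 0.16,
              edge_smooth_px: float = 1.2) -> list[np.ndarray]:
    """Conservative per-tube ROI masks (the flat, full-density interior).

    Mirrors how phantom ROIs are drawn in practice: inside the tube,
    away from the edge-taper region.
    """
    nx, _ = grid_shape
    w = edge_smooth_px / (nx / 2)
    _, _, _, radius, dists = _tube_geometry(grid_shape, n_tubes,
                                            tube_radius_frac)
    return [d <= radius - w for d in dists]


def make_coilmaps(n_coils: int, grid_shape: tuple[int, int],
                  smoothness: float = 0.6,
                  phase_coeff: float = 0.5) -> CoilMaps:
    """Smooth synthetic coil sensitivities (Gaussian lobes on a ring).

    A single coil gives a uniform all-ones map.  ``smoothness`` is the
    Gaussian lobe standard deviation as a fraction of the FOV; each coil
    additionally carries a smooth linear phase along its look direction.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nx, ny = grid_shape
    if n_coils == 1:
        return CoilMaps(maps=np.ones((1, nx, ny), dtype=complex))
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    u = (xx - nx / 2 + 0.5) / (nx / 2)
    v = (yy - ny / 2 + 0.5) / (ny / 2)
    maps = np.empty((n_coils, nx, ny), dtype=complex)
    ang = 2 * np.pi * np.arange(n_coils) / n_coils
    for c, a in enumerate(ang):
        cxp, cyp = 1.1 * np.cos(a), 1.1 * np.sin(a)
        r2 = (u - cxp) ** 2 + (v - cyp) ** 2
        mag = np.exp(-r2 / (2 * smoothness ** 2))
        phase = phase_coeff * (u * np.cos(a) + v * np.sin(a))
        maps[c] = mag * np.exp(1j * np.pi * phase)
    return CoilMaps(maps=maps)


# ---------------------------------------------------------------------------
# k-space synthesis
# ---------------------------------------------------------------------------

def simulate_map_signals(pmap: ParamMap, train: PulseTrain,
                         mode: str = "si",
                         ensemble: SlabEnsemble | None = None,
                         slice_index: int | None = None) -> np.ndarray:
    """Echo-state series M_{q,v} for every valid voxel: (n_q, n_valid)."""
    t1 = pmap.masked("t1")
    t2 = pmap.masked("t2")
    delta = pmap.masked("delta")
    b1 = pmap.masked("b1")
    if mode == "si":
        sig = simulate_si_batch(train, t1, t2, delta, b1)
    elif mode == "mu":
        if ensemble is None:
            raise ValueError("mu mode requires an ensemble")
        sl = ensemble.central_slice if slice_index is None else slice_index
        sig = simulate_mu_batch(train, ensemble, t1, t2, delta, b1)[sl]
    else:
        raise ValueError("mode must be 'si' or 'mu'")
    return sig * pmap.masked("i0")[None, :]


def synthesize_kspace(pmap: ParamMap, train: PulseTrain,
                      operator: SamplingOperator, coils: CoilMaps,
                      noise_sd: float = 0.0, seed: int | None = None,
                      mode: str = "si",
                      ensemble: SlabEnsemble | None = None,
                      slice_index: int | None = None) -> KSpaceData:
    """Synthesize k-space data Y_{q,c,p} under the off-resonance model.

    Y_{q,c,p} = sum_v C_{c,v} M_{q,v} exp(-i 2 pi Delta_v tau_p)
                exp(-i 2 pi k_p . (r_v - N/2) / N) + noise,
    evaluated as an exact vectorized sum over valid voxels; noise is
    i.i.d. complex Gaussian with standard deviation ``noise_sd`` per
    real/imaginary component.
    """
    nx, ny = pmap.shape
    if operator.grid_shape != (nx, ny):
        raise ValueError("operator grid does not match the parameter map")
    if coils.maps.shape[1:] != (nx, ny):
        raise ValueError("coil maps do not match the parameter map")
    M = simulate_map_signals(pmap, train, mode, ensemble, slice_index)
    n_q = train.n_contrasts
    if operator.n_contrasts != n_q:
        raise ValueError("schedule contrast count does not match the train")

    vx, vy = np.nonzero(pmap.mask)
    rx = vx - nx // 2
    ry = vy - ny // 2
    delta = pmap.masked("delta")
    C = coils.maps[:, vx, vy]  # (n_c, n_valid)

    P = operator.n_samples_per_contrast
    out = np.empty((n_q, coils.n_coils, P), dtype=complex)
    for q in range(n_q):
        k = operator.coords(q)
        tau_s = operator.tau(q) * 1e-3  # seconds
        phase = (k[:, 0:1] * rx[None, :] / nx
                 + k[:, 1:2] * ry[None, :] / ny
                 + tau_s[:, None] * delta[None, :])
        A = np.exp(-2j * np.pi * phase)  # (P, n_valid)
        out[q] = (C * M[q][None, :]) @ A.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out += noise_sd * (rng.standard_normal(out.shape)
                           + 1j * rng.standard_normal(out.shape))
    return KSpaceData(data=out, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# hierarchical container I/O
# ---------------------------------------------------------------------------

def save_kspace(path, kdata: KSpaceData, operator: SamplingOperator,
                coils: CoilMaps | None = None) -> None:
    """Write k-space samples plus trajectory/schedule to an HDF5 container."""
    traj = operator.trajectory
    sched = operator.schedule
    with h5py.File(path, "w") as f:
        f.create_dataset("kdata", data=kdata.data.astype(np.complex64))
        if coils is not None:
            f.create_dataset("coilmaps",
                             data=coils.maps.astype(np.complex64))
        f.create_dataset("k_coords", data=traj.k_coords)
        f.create_dataset("tau_ms", data=traj.tau)
        f.create_dataset("schedule", data=sched.arm_index)
        f.attrs["n_arms_full"] = traj.n_arms_full
        f.attrs["readout_ms"] = traj.readout_ms
        f.attrs["fov_mm"] = traj.fov_mm
        f.attrs["acceleration"] = sched.acceleration
        f.attrs["noise_sd"] = kdata.noise_sd
        f.attrs["seed"] = -1 if kdata.seed is None else int(kdata.seed)
        f.attrs["grid_shape"] = operator.grid_shape


def load_kspace_arrays(path) -> dict:
    """Read back the container written by :func:`save_kspace`."""
    with h5py.File(path, "r") as f:
        return dict(
            kdata=f["kdata"][...].astype(complex),
            coilmaps=(f["coilmaps"][...].astype(complex)
                      if "coilmaps" in f else None),
            k_coords=f["k_coords"][...],
            tau_ms=f["tau_ms"][...],
            schedule=f["schedule"][...],
            n_arms_full=int(f.attrs["n_arms_full"]),
            readout_ms=float(f.attrs["readout_ms"]),
            fov_mm=float(f.attrs["fov_mm"]),
            acceleration=float(f.attrs["acceleration"]),
            noise_sd=float(f.attrs["noise_sd"]),
            seed=int(f.attrs["seed"]),
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
        )
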