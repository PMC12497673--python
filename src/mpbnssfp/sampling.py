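"""Stack-of-spirals trajectory design, golden-ratio undersampling schedule,
and the per-contrast non-uniform Fourier sampling operator F.

The slice-encoding direction is fully sampled, so after an inverse Fourier
transform along z each slice is handled by a 2D in-plane operator; this
module implements that in-plane part.  k-space coordinates are in
cycles/FOV; image indices are 0-based and FOV-centered; the forward
operator evaluates ``sum_r x(r) exp(-i 2 pi k . (r - N/2) / N)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nufft import GriddingNufft2D, nudft2_direct  # noqa: F401  (oracle re-export)

__all__ = [
    "SpiralTrajectory",
    "UndersamplingSchedule",
    "SamplingOperator",
    "design_spiral",
    "schedule_arms",
    "rotate_arm",
    "build_operator",
    "GOLDEN_RATIO",
]

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class SpiralTrajectory:
    """One spiral-out interleave plus the full-design arm count.

    ``k_coords`` holds the base (unrotated) arm; the other interleaves of
    the fully sampled design are rigid rotations by multiples of
    ``2 pi / n_arms_full``.  ``tau`` is the within-readout time offset of
    each sample from the magnetization state (tau_1 = 0), identical for
    every interleave.
    """

    k_coords: np.ndarray          # (n_samples, 2), cycles/FOV
    tau: np.ndarray               # (n_samples,), ms, strictly increasing
    readout_ms: float
    n_arms_full: int
    fov_mm: float = 240.0

    def __post_init__(self) -> None:
        if self.k_coords.ndim != 2 or self.k_coords.shape[1] != 2:
            raise ValueError("k_coords must be (n_samples, 2)")
        if self.tau.shape[0] != self.k_coords.shape[0]:
            raise ValueError("tau length must match k_coords")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing")
        if self.tau[0] != 0:
            raise ValueError("first sample must be at tau = 0")

    @property
    def n_samples(self) -> int:
        return self.k_coords.shape[0]

    def arm(self, index: int) -> np.ndarray:
        """k-coordinates of interleave ``index`` (rotated base arm)."""
        angle = 2.0 * np.pi * index / self.n_arms_full
        return _rotate_coords(self.k_coords, angle)


def _rotate_coords(coords: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return coords @ rot.T


def rotate_arm(traj: SpiralTrajectory, angle: float) -> SpiralTrajectory:
    """Rigidly rotate all k-coordinates by ``angle`` radians (tau unchanged)."""
    return SpiralTrajectory(
        k_coords=_rotate_coords(traj.k_coords, angle),
        tau=traj.tau, readout_ms=traj.readout_ms,
        n_arms_full=traj.n_arms_full, fov_mm=traj.fov_mm)


def design_spiral(matrix: int, fov: float = 240.0, n_arms: int = 16,
                  readout_ms: float = 22.0,
                  n_samples: int = 512) -> SpiralTrajectory:
    """Design a constant-density Archimedean spiral-out interleave.

    The arm starts at k = 0 and reaches k_max = matrix/2 cycles/FOV at
    ``tau = readout_ms``; the number of turns is chosen so that the radial
    spacing between turns of the complete ``n_arms`` design meets Nyquist
    (1 cycle/FOV) exactly.  Sampling is uniform in time.
    """
    if n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    if readout_ms <= 0:
        raise ValueError("readout_ms must be positive")
    if matrix < 2:
        raise ValueError("matrix must be >= 2")
    k_max = matrix / 2.0
    n_turns = matrix / (2.0 * n_arms)
    t = np.linspace(0.0, 1.0, n_samples)
    radius = k_max * t
    angle = 2.0 * np.pi * n_turns * t
    coords = np.stack([radius * np.cos(angle), radius * np.sin(angle)],
                      axis=1)
    # azimuthal sample spacing at the k-space edge
    edge_step = 2.0 * np.pi * n_turns * k_max / (n_samples - 1)
    if edge_step > 1.0:
        warnings.warn(
            f"azimuthal sample spacing {edge_step:.2f} cycles/FOV at the "
            "k-space edge exceeds Nyquist; increase n_samples",
            stacklevel=2)
    tau = np.linspace(0.0, readout_ms, n_samples)
    return SpiralTrajectory(k_coords=coords, tau=tau, readout_ms=readout_ms,
                            n_arms_full=n_arms, fov_mm=fov)


@dataclass(frozen=True)
class UndersamplingSchedule:
    """Which spiral interleaves each contrast acquires."""

    n_arms_full: int
    acceleration: float
    arm_index: np.ndarray  # (n_contrasts, arms_per_contrast) ints in [0, n_s)

    def __post_init__(self) -> None:
        if np.any(self.arm_index < 0) or \
           np.any(self.arm_index >= self.n_arms_full):
            raise ValueError("arm indices out of range")

    @property
    def n_contrasts(self) -> int:
        return self.arm_index.shape[0]

    @property
    def arms_per_contrast(self) -> int:
        return self.arm_index.shape[1]


def schedule_arms(n_contrasts: int, n_arms_full: int,
                  acceleration: float = 1.0) -> UndersamplingSchedule:
    """Golden-ratio interleave selection across contrasts.

    ``arms_per_contrast = round(n_arms_full / acceleration)``.  Each
    contrast ``q`` rotates the interleave set by the doubled-golden-ratio
    increment ``round(q * frac(2 phi) * n_s) mod n_s`` (``phi`` the golden
    ratio), and its shots are spread evenly over the full design
    (``round(j * n_s / shots)`` apart), so every contrast sees
    near-uniform angular coverage while consecutive contrasts sample
    complementary interleaves.  At acceleration 1 every contrast acquires
    all interleaves.
    """
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    shots = int(round(n_arms_full / acceleration))
    if shots < 1:
        raise ValueError("acceleration too high: no interleave per contrast")
    q = np.arange(n_contrasts)[:, None]
    j = np.arange(shots)[None, :]
    frac = 2.0 * GOLDEN_RATIO - np.floor(2.0 * GOLDEN_RATIO)
    base = np.rint(q * frac * n_arms_full).astype(int)
    spread = np.rint(j * n_arms_full / shots).astype(int)
    idx = (base + spread) % n_arms_full
    return UndersamplingSchedule(n_arms_full=n_arms_full,
                                 acceleration=acceleration, arm_index=idx)


@dataclass
class SamplingOperator:
    """Per-contrast non-uniform Fourier sampling operator F.

    For contrast ``q``, ``forward(image, q)`` evaluates the image's
    non-uniform DFT at the k-positions of the interleaves scheduled for
    that contrast (samples ordered shot-major); ``adjoint`` is the exact
    conjugate-transpose.
    """

    grid_shape: tuple[int, int]
    trajectory: SpiralTrajectory
    schedule: UndersamplingSchedule
    _plans: dict = field(default_factory=dict, repr=False)

    def _plan(self, q: int) -> GriddingNufft2D:
        arms = tuple(self.schedule.arm_index[q])
        if arms not in self._plans:
            coords = np.concatenate(
                [self.trajectory.arm(a) for a in arms], axis=0)
            self._plans[arms] = GriddingNufft2D(self.grid_shape, coords)
        return self._plans[arms]

    @property
    def n_contrasts(self) -> int:
        return self.schedule.n_contrasts

    @property
    def n_samples_per_contrast(self) -> int:
        return self.schedule.arms_per_contrast * self.trajectory.n_samples

    def coords(self, q: int) -> np.ndarray:
        """(P, 2) k-coordinates sampled by contrast q."""
        return np.concatenate(
            [self.trajectory.arm(a) for a in self.schedule.arm_index[q]],
            axis=0)

    def tau(self, q: int) -> np.ndarray:
        """(P,) within-readout time offsets (ms) for contrast q's samples."""
        return np.tile(self.trajectory.tau, self.schedule.arms_per_contrast)

    def forward(self, image: np.ndarray, q: int) -> np.ndarray:
        return self._plan(q).forward(image)

    def adjoint(self, samples: np.ndarray, q: int) -> np.ndarray:
        return self._plan(q).adjoint(samples)


def build_operator(traj: SpiralTrajectory, schedule: UndersamplingSchedule,
                   grid_shape: tuple[int, int]) -> SamplingOperator:
    """Bind a trajectory and schedule to an image grid."""
    return SamplingOperator(grid_shape=tuple(grid_shape), trajectory=traj,
                            schedule=schedule)
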