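"""Image reconstruction from undersampled multi-contrast spiral k-space.

Three least-squares reconstructions, all solved by conjugate gradient on
the normal equations (CGLS, which makes the data-residual norm
monotonically non-increasing):

* ``sense_b0`` — per-contrast SENSE, optionally with B0 compensation of
  the within-readout off-resonance phase;
* ``scr`` — subspace-constrained reconstruction: solve jointly for d1
  component images in the dictionary's truncated contrast basis U;
* ``scr_b0`` — SCR with the B0 phase term expressed in a second, low-rank
  (d2) subspace of the within-readout phase factors exp(-i 2 pi Delta tau).

No additional regularization is applied; redundancy across the contrast
dimension is the only prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dictionary import ContrastSubspace
from .sampling import SamplingOperator
from .synth import CoilMaps, KSpaceData

__all__ = [
    "PhaseSubspace",
    "ComponentImages",
    "ContrastImages",
    "CGInfo",
    "cgls",
    "phase_subspace",
    "sense_b0",
    "scr",
    "scr_b0",
    "compose_contrasts",
]


@dataclass
class PhaseSubspace:
    """Truncated SVD of the within-readout phase matrix exp(-i2pi Delta tau).

    ``u_tilde`` spans the temporal (within-readout) variation over the
    n_p samples of one readout; ``v_field`` holds the conjugated,
    singular-value-weighted spatial factors s_w * conj(V_w) reshaped to
    the image grid, so the rank-d2 model of the phase matrix is
    E[p, v] ~ sum_w u_tilde[p, w] * v_field[w, v].
    """

    u_tilde: np.ndarray          # (n_p, d2), orthonormal columns
    s_tilde: np.ndarray          # (d2,), non-increasing
    v_tilde: np.ndarray          # (n_v, d2)
    grid_shape: tuple[int, int]
    total_energy: float          # full Frobenius^2 of the phase matrix

    @property
    def d2(self) -> int:
        return self.u_tilde.shape[1]

    @property
    def v_field(self) -> np.ndarray:
        """(d2, nx, ny): s_w * conj(V_w) on the image grid."""
        f = (self.s_tilde[None, :] * np.conj(self.v_tilde)).T
        return f.reshape((self.d2,) + self.grid_shape)

    def energy_fraction(self, d: int | None = None) -> float:
        d = self.d2 if d is None else d
        return float((self.s_tilde[:d] ** 2).sum() / self.total_energy)


def phase_subspace(delta_map: np.ndarray, tau_ms: np.ndarray,
                   d2: int | None = None, energy: float = 0.999,
                   d2_cap: int = 16,
                   subsample: int = 4096) -> PhaseSubspace:
    """Low-rank model of the within-readout off-resonance phase factors.

    Parameters
    ----------
    delta_map:
        Off-resonance map in Hz, shape (nx, ny) (unwrapped).
    tau_ms:
        Within-readout sample time offsets of one interleave, ms.
    d2:
        Number of components; if None, the smallest d2 whose squared
        singular-value energy fraction reaches ``energy`` (capped at
        ``d2_cap``) is chosen.
    subsample:
        When the grid has more voxels than this, the SVD runs on an
        evenly strided voxel subset (memory bound); the spatial factors
        are then re-projected exactly on the full grid.
    """
    delta = np.asarray(delta_map, dtype=float)
    grid_shape = delta.shape
    dv = delta.ravel()
    tau_s = np.asarray(tau_ms, dtype=float) * 1e-3
    n_p, n_v = tau_s.size, dv.size

    stride = max(1, int(np.ceil(n_v / subsample)))
    dv_sub = dv[::stride]
    E_sub = np.exp(-2j * np.pi * tau_s[:, None] * dv_sub[None, :])
    U, s, _ = np.linalg.svd(E_sub, full_matrices=False)
    total_sub = float(n_p * dv_sub.size)  # |E| entries are unit modulus
    if d2 is None:
        frac = np.cumsum(s ** 2) / total_sub
        d2 = int(np.searchsorted(frac, energy) + 1)
        d2 = min(d2, d2_cap, s.size)
    if not 1 <= d2 <= s.size:
        raise ValueError("invalid d2")
    Ud = U[:, :d2]
    # exact projection of the full phase matrix onto the temporal basis
    E_full = np.exp(-2j * np.pi * tau_s[:, None] * dv[None, :])
    B = Ud.conj().T @ E_full  # (d2, n_v) = S V^H in the Ud basis
    Ub, sb, Vbh = np.linalg.svd(B, full_matrices=False)
    return PhaseSubspace(u_tilde=Ud @ Ub, s_tilde=sb,
                         v_tilde=Vbh.conj().T, grid_shape=grid_shape,
                         total_energy=float(n_p * n_v))


@dataclass
class ComponentImages:
    """Subspace component images sigma, shape (d1, nx, ny)."""

    coefficients: np.ndarray
    subspace: ContrastSubspace

    @property
    def d1(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class ContrastImages:
    """Per-contrast complex images, shape (n_q, nx, ny)."""

    images: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.images)):
            raise ValueError("non-finite contrast images")

    @property
    def n_contrasts(self) -> int:
        return self.images.shape[0]


def compose_contrasts(subspace: ContrastSubspace,
                      components: ComponentImages | np.ndarray
                      ) -> ContrastImages:
    """Contrast images I = U sigma from component images."""
    sigma = (components.coefficients
             if isinstance(components, ComponentImages) else components)
    imgs = np.einsum("qm,mxy->qxy", subspace.basis, sigma)
    return ContrastImages(images=imgs)


# ---------------------------------------------------------------------------
# CGLS
# ---------------------------------------------------------------------------

@dataclass
class CGInfo:
    """Solver diagnostics: per-iteration data-residual norms."""

    residual_norms: list
    converged: bool
    n_iter: int


def cgls(forward, adjoint, y: np.ndarray, x0: np.ndarray,
         max_iter: int = 40, tol: float = 1e-6):
    """Conjugate gradient on the normal equations (CGLS).

    Minimizes ||y - A x|| starting from ``x0``; ``forward``/``adjoint``
    map arrays of the shapes of ``x0``/``y``.  Stops when the relative
    data-residual improvement per iteration stalls below ``tol`` or after
    ``max_iter`` iterations (with a warning).  The residual-norm sequence
    is monotonically non-increasing by construction.
    """
    x = np.array(x0, dtype=complex)
    r = y - forward(x)
    s = adjoint(r)
    p = s.copy()
    gamma = np.vdot(s, s).real
    y_norm = float(np.linalg.norm(y)) or 1.0
    res = [float(np.linalg.norm(r))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = forward(p)
        qq = np.vdot(q, q).real
        if qq == 0 or gamma == 0:
            converged = True
            break
        alpha = gamma / qq
        x += alpha * p
        r -= alpha * q
        res.append(float(np.linalg.norm(r)))
        if res[-1] / y_norm < tol or \
           (res[-2] - res[-1]) / y_norm < tol * 1e-2:
            converged = True
            break
        s = adjoint(r)
        gamma_new = np.vdot(s, s).real
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    if not converged:
        warnings.warn(f"CGLS did not converge in {max_iter} iterations "
                      f"(relative residual {res[-1] / y_norm:.2e})",
                      stacklevel=2)
    return x, CGInfo(residual_norms=res, converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# encoding blocks
# ---------------------------------------------------------------------------

def _contrast_forward(x: np.ndarray, q: int, coils: CoilMaps,
                      operator: SamplingOperator,
                      phase: PhaseSubspace | None):
    """(nx, ny) contrast image -> (n_c, P) samples for contrast q."""
    C = coils.maps
    if phase is None:
        return operator.forward(C * x[None], q)
    n_shots = operator.schedule.arms_per_contrast
    vf = phase.v_field  # (d2, nx, ny)
    # stack (w, c) images and push through one batched NUFFT call
    imgs = vf[:, None] * (C * x[None])[None]        # (d2, n_c, nx, ny)
    samp = operator.forward(imgs, q)                # (d2, n_c, P)
    u_full = np.tile(phase.u_tilde.T[:, None, :], (1, 1, n_shots))
    return (samp * u_full).sum(axis=0)


def _contrast_adjoint(y: np.ndarray, q: int, coils: CoilMaps,
                      operator: SamplingOperator,
                      phase: PhaseSubspace | None):
    """(n_c, P) samples -> (nx, ny) adjoint contrast image for contrast q."""
    C = coils.maps
    if phase is None:
        imgs = operator.adjoint(y, q)               # (n_c, nx, ny)
        return (np.conj(C) * imgs).sum(axis=0)
    n_shots = operator.schedule.arms_per_contrast
    vf = phase.v_field
    u_full = np.tile(phase.u_tilde.T[:, None, :], (1, 1, n_shots))
    samp = np.conj(u_full) * y[None]                # (d2, n_c, P)
    imgs = operator.adjoint(samp, q)                # (d2, n_c, nx, ny)
    return (np.conj(vf)[:, None] * np.conj(C)[None] * imgs).sum(axis=(0, 1))


# ---------------------------------------------------------------------------
# reconstructions
# ---------------------------------------------------------------------------

def density_weights(operator: SamplingOperator, q: int) -> np.ndarray:
    """Radial density-compensation weights for contrast q's samples.

    Constant-density spiral-out readouts oversample the k-space center
    heavily; weighting the data term by the local sample sparsity (~|k|,
    floored at half the first nonzero radius) conditions the normal
    equations so CG converges in tens of iterations.  Weights are
    normalized to unit mean.
    """
    r = np.linalg.norm(operator.coords(q), axis=1)
    floor = 0.5 * (r[r > 0].min() if np.any(r > 0) else 1.0)
    w = np.maximum(r, floor)
    return w / w.mean()


def sense_b0(kdata: KSpaceData, coils: CoilMaps,
             operator: SamplingOperator,
             phase: PhaseSubspace | None = None,
             max_iter: int = 40, tol: float = 1e-6,
             use_weights: bool = True) -> ContrastImages:
    """Per-contrast (B0-compensated) SENSE reconstruction.

    Each contrast is an independent least-squares problem; with ``phase``
    given, the forward model includes the low-rank within-readout
    off-resonance phase, compensating blurring from extended readouts.
    With ``use_weights`` the least squares is density-weighted
    (identical solution for consistent data, far better conditioning).
    """
    n_q = kdata.n_contrasts
    nx, ny = operator.grid_shape
    out = np.empty((n_q, nx, ny), dtype=complex)
    for q in range(n_q):
        sw = (np.sqrt(density_weights(operator, q))
              if use_weights else None)
        def fwd(x, q=q, sw=sw):
            s = _contrast_forward(x, q, coils, operator, phase)
            return s if sw is None else s * sw[None, :]
        def adj(y, q=q, sw=sw):
            yw = y if sw is None else y * sw[None, :]
            return _contrast_adjoint(yw, q, coils, operator, phase)
        yq = kdata.data[q] if sw is None else kdata.data[q] * sw[None, :]
        out[q], _ = cgls(fwd, adj, yq,
                         np.zeros((nx, ny), dtype=complex),
                         max_iter=max_iter, tol=tol)
    return ContrastImages(images=out)


def _joint_forward(sigma, subspace, coils, operator, phase):
    n_q = subspace.basis.shape[0]
    P = operator.n_samples_per_contrast
    out = np.empty((n_q, coils.n_coils, P), dtype=complex)
    for q in range(n_q):
        x = np.tensordot(subspace.basis[q], sigma, axes=(0, 0))
        out[q] = _contrast_forward(x, q, coils, operator, phase)
    return out


def _joint_adjoint(y, subspace, coils, operator, phase, grid_shape):
    d1 = subspace.d1
    nx, ny = grid_shape
    sigma = np.zeros((d1, nx, ny), dtype=complex)
    n_q = subspace.basis.shape[0]
    for q in range(n_q):
        g = _contrast_adjoint(y[q], q, coils, operator, phase)
        sigma += np.conj(subspace.basis[q])[:, None, None] * g[None]
    return sigma


def scr(kdata: KSpaceData, coils: CoilMaps, operator: SamplingOperator,
        subspace: ContrastSubspace, max_iter: int = 40,
        tol: float = 1e-6, use_weights: bool = True) -> ComponentImages:
    """Subspace-constrained reconstruction (no B0 compensation)."""
    return scr_b0(kdata, coils, operator, subspace, phase=None,
                  max_iter=max_iter, tol=tol, use_weights=use_weights)


def scr_b0(kdata: KSpaceData, coils: CoilMaps, operator: SamplingOperator,
           subspace: ContrastSubspace,
           phase: PhaseSubspace | None,
           max_iter: int = 40, tol: float = 1e-6,
           use_weights: bool = True) -> ComponentImages:
    """Subspace-constrained reconstruction with B0 compensation.

    Solves jointly over all contrasts for the d1 component images sigma;
    the forward model applies, per contrast and readout sample, the
    rank-d2 off-resonance phase model (``phase=None`` collapses to plain
    SCR).
    """
    nx, ny = operator.grid_shape
    if kdata.n_contrasts != subspace.basis.shape[0]:
        raise ValueError("k-space contrast count does not match subspace")
    if use_weights:
        sw = np.stack([np.sqrt(density_weights(operator, q))
                       for q in range(kdata.n_contrasts)])[:, None, :]
    else:
        sw = None

    def fwd(s):
        y = _joint_forward(s, subspace, coils, operator, phase)
        return y if sw is None else y * sw

    def adj(y):
        yw = y if sw is None else y * sw
        return _joint_adjoint(yw, subspace, coils, operator, phase,
                              (nx, ny))

    y0 = kdata.data if sw is None else kdata.data * sw
    sigma0 = np.zeros((subspace.d1, nx, ny), dtype=complex)
    sigma, _ = cgls(fwd, adj, y0, sigma0, max_iter=max_iter, tol=tol)
    return ComponentImages(coefficients=sigma, subspace=subspace)
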