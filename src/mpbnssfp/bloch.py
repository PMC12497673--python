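"""Transient-state Bloch simulation of the MP-b-nSSFP pulse train.

Two fidelity levels are provided:

* **Si** (single spin): one isochromat per voxel, instantaneous RF
  rotations at the pulse centers.  This is the fast mode used for
  dictionary grids.
* **Mu** (multi spin): an ensemble of sub-spins distributed along the
  slice-encoding axis over an extent wider than the excited slab.  Each
  sub-spin is propagated through the time-discretized RF envelopes
  (hard-pulse approximation) with the position-dependent off-resonance
  of the slice-select gradient, so the slab excitation/inversion profile
  is encoded automatically.  The balanced z-encoding gradients are
  treated separately: one simulation yields all z-encodes by applying
  the encode phase to each sub-spin, and an inverse Fourier transform
  across z-encodes separates the per-slice signals.

Sign conventions: positive off-resonance Delta (Hz) accrues transverse
phase ``exp(-i 2 pi Delta t)`` (left-handed precession), matching the
``exp(-i Delta tau)`` factor of the within-readout signal model.
Equilibrium longitudinal magnetization is normalized to 1; complex
apparent proton density I0 scales the recorded transverse signal only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import PulseTrain, RFPulse

__all__ = [
    "TissueParams",
    "SlabEnsemble",
    "rotate",
    "relax_precess",
    "simulate_si",
    "simulate_si_batch",
    "simulate_mu",
    "simulate_mu_batch",
]


@dataclass(frozen=True)
class TissueParams:
    """The six-parameter tissue vector theta estimated per voxel."""

    i0_re: float = 1.0  # Re of apparent proton density (a.u.)
    i0_im: float = 0.0  # Im of apparent proton density (a.u.)
    t1: float = 1000.0  # longitudinal relaxation time, ms
    t2: float = 100.0   # transverse relaxation time, ms
    delta: float = 0.0  # off-resonance, Hz
    b1: float = 1.0     # transmit field scale (1 = nominal flip)

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive")
        if self.b1 <= 0:
            raise ValueError("b1 must be positive")

    @property
    def i0(self) -> complex:
        return complex(self.i0_re, self.i0_im)


@dataclass(frozen=True)
class SlabEnsemble:
    """Sub-spin ensemble for slab-resolved (Mu) simulation.

    ``n_subspins`` isochromats are placed on a uniform lattice spanning
    ``slab_factor`` times the slab width, centered on the slab;
    ``n_zencodes`` balanced z-encodes (and hence reconstructed slices)
    cover the same extent.
    """

    n_subspins: int = 64
    slab_factor: float = 1.8
    n_zencodes: int = 8
    slab_width_mm: float = 132.0  # 44 slices x 3 mm in the reference setting

    def __post_init__(self) -> None:
        if self.n_subspins < self.n_zencodes:
            raise ValueError("need at least as many sub-spins as z-encodes")
        if self.slab_factor <= 0 or self.slab_width_mm <= 0:
            raise ValueError("slab extent must be positive")

    @property
    def extent_mm(self) -> float:
        return self.slab_factor * self.slab_width_mm

    @property
    def positions(self) -> np.ndarray:
        """Sub-spin positions (mm) along the slice axis, slab-centered."""
        n, L = self.n_subspins, self.extent_mm
        return (np.arange(n) + 0.5 - n / 2) * (L / n)

    @property
    def slice_positions(self) -> np.ndarray:
        """Reconstructed slice positions (mm) across the encoded extent."""
        n, L = self.n_zencodes, self.extent_mm
        return (np.arange(n) - n // 2) * (L / n)

    @property
    def central_slice(self) -> int:
        return self.n_zencodes // 2


# ---------------------------------------------------------------------------
# elementary spin operations (scalar 3-vector interface)
# ---------------------------------------------------------------------------

def rotate(magnetization, flip: float, phase_axis: float) -> np.ndarray:
    """Rotate a magnetization 3-vector about a transverse axis.

    ``flip`` and ``phase_axis`` in degrees; the axis lies in the transverse
    plane at azimuth ``phase_axis`` (0 = x, 90 = y).  The convention is such
    that a 30deg pulse about x takes equilibrium (0,0,1) to
    (0, -sin30, cos30).
    """
    mx, my, mz = np.asarray(magnetization, dtype=float)
    a = np.deg2rad(flip)
    phi = np.deg2rad(phase_axis)
    m = (mx + 1j * my) * np.exp(-1j * phi)  # into the pulse frame
    xt, yt = m.real, m.imag
    ca, sa = np.cos(a), np.sin(a)
    yt2 = yt * ca - mz * sa
    mz2 = yt * sa + mz * ca
    m2 = (xt + 1j * yt2) * np.exp(1j * phi)
    return np.array([m2.real, m2.imag, mz2])


def relax_precess(magnetization, dt: float, t1: float, t2: float,
                  delta: float = 0.0) -> np.ndarray:
    """Free evolution over ``dt`` ms: T2 decay + precession, T1 recovery."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    mx, my, mz = np.asarray(magnetization, dtype=float)
    m = (mx + 1j * my) * np.exp(-dt / t2 - 2j * np.pi * delta * dt * 1e-3)
    e1 = np.exp(-dt / t1)
    mz2 = 1.0 + (mz - 1.0) * e1
    return np.array([m.real, m.imag, mz2])


# ---------------------------------------------------------------------------
# single-spin (Si) simulation, vectorized over a batch of parameter vectors
# ---------------------------------------------------------------------------

def _as_batch(t1, t2, delta, b1):
    t1, t2, delta, b1 = np.broadcast_arrays(
        np.atleast_1d(np.asarray(t1, float)),
        np.atleast_1d(np.asarray(t2, float)),
        np.atleast_1d(np.asarray(delta, float)),
        np.atleast_1d(np.asarray(b1, float)))
    if np.any(t1 <= 0) or np.any(t2 <= 0) or np.any(b1 <= 0):
        raise ValueError("t1, t2 and b1 must be positive")
    return t1, t2, delta, b1


def simulate_si_batch(train: PulseTrain, t1, t2, delta, b1) -> np.ndarray:
    """Simulate the echo-state signal series for a batch of spins.

    Instantaneous rotations at the pulse centers; the complex transverse
    signal (Mx + i My, unit proton density) is recorded
    ``readout_start_offset`` ms after each pulse.

    Returns
    -------
    numpy.ndarray, complex, shape (n_contrasts, n_batch)
    """
    t1, t2, delta, b1 = _as_batch(t1, t2, delta, b1)
    n = t1.size
    trp = train.block.trp
    off = train.readout_start_offset
    rest = trp - off

    def decay(dt):
        e2 = np.exp(-dt / t2 - 2j * np.pi * delta * dt * 1e-3)
        e1 = np.exp(-dt / t1)
        return e2, e1

    e2a, e1a = decay(off)
    e2b, e1b = decay(rest)

    mxy = np.zeros(n, dtype=complex)
    mz = np.ones(n, dtype=float)
    out = np.empty((train.n_contrasts, n), dtype=complex)

    pulses = train.block.pulses
    # per-pulse rotation terms at flip * b1
    rot = []
    for p in pulses:
        a = np.deg2rad(p.flip_angle) * b1
        phi = np.deg2rad(p.phase_axis)
        rot.append((np.cos(a), np.sin(a), np.exp(-1j * phi), np.exp(1j * phi)))

    q = 0
    for _ in range(train.n_blocks):
        for ca, sa, fwd, bwd in rot:
            m = mxy * fwd
            yt = m.imag
            y2 = yt * ca - mz * sa
            mz = yt * sa + mz * ca
            mxy = (m.real + 1j * y2) * bwd
            # to readout state
            mxy = mxy * e2a
            mz = 1.0 + (mz - 1.0) * e1a
            out[q] = mxy
            q += 1
            # to next pulse
            mxy = mxy * e2b
            mz = 1.0 + (mz - 1.0) * e1b
    return out


def simulate_si(theta: TissueParams, train: PulseTrain) -> np.ndarray:
    """Echo-state signal series (length n_contrasts) for one voxel."""
    s = simulate_si_batch(train, theta.t1, theta.t2, theta.delta, theta.b1)
    return s[:, 0] * theta.i0


# ---------------------------------------------------------------------------
# slab-resolved multi-spin (Mu) simulation
# ---------------------------------------------------------------------------

def _pulse_is_instant(p: RFPulse) -> bool:
    return p.duration == 0.0 or not p.selective


def simulate_mu_batch(train: PulseTrain, ensemble: SlabEnsemble,
                      t1, t2, delta, b1,
                      hard_pulse_max_deg: float = 2.0) -> np.ndarray:
    """Slab-resolved signal series for a batch of parameter vectors.

    Every sub-spin is propagated once through the full train (hard-pulse
    discretized selective pulses with slice-select gradient off-resonance,
    symmetric gradient rephasing lobes so the net gradient moment per TR
    is zero).  The balanced z-encode phases are applied afterwards and an
    inverse DFT across z-encodes yields one series per slice position.

    Returns
    -------
    numpy.ndarray, complex64, shape (n_slices, n_contrasts, n_batch)
    """
    t1, t2, delta, b1 = _as_batch(t1, t2, delta, b1)
    n_atoms = t1.size
    pulses = train.block.pulses
    if all(_pulse_is_instant(p) for p in pulses):
        # no slice-selection: every sub-spin sees an identical history, so
        # the per-slice series all equal the single-spin series exactly
        si = simulate_si_batch(train, t1, t2, delta, b1)
        return np.broadcast_to(
            si.astype(np.complex64), (ensemble.n_zencodes,) + si.shape).copy()
    for p in pulses:
        if p.selective and p.duration > 0 and p.envelope is None:
            raise ValueError("selective pulse lacks an envelope")

    z = ensemble.positions  # (n_sub,) mm
    n_sub = z.size
    L = ensemble.extent_mm
    trp = train.block.trp
    off = train.readout_start_offset

    c64 = np.complex64
    f32 = np.float32
    b1f = b1.astype(f32)[:, None]            # (n_atoms, 1)
    delta_f = delta.astype(f32)[:, None]     # (n_atoms, 1)

    # precompute per distinct pulse: increments, per-atom rotation tables,
    # per-(atom, subspin) dwell phase, gradient rephaser phase
    b1_max = float(b1.max())
    prep = []
    for p in pulses:
        if _pulse_is_instant(p):
            a = (np.deg2rad(p.flip_angle) * b1).astype(f32)[:, None]
            prep.append(dict(instant=True, ca=np.cos(a), sa=np.sin(a),
                             phi=p.phase_axis, dt_edge=0.0))
            continue
        inc = p.flip_increments(hard_pulse_max_deg, b1_max)  # degrees
        n_inc = inc.size
        dwell = p.duration / n_inc  # ms
        ang = np.deg2rad(inc)[:, None].astype(f32) * b1.astype(f32)[None, :]
        ca = np.cos(ang)  # (n_inc, n_atoms)
        sa = np.sin(ang)
        # slice-select gradient strength: pulse bandwidth maps to slab width
        g_hz_mm = (p.time_bandwidth / p.duration) * 1e3 / ensemble.slab_width_mm
        f_grad = g_hz_mm * z  # (n_sub,) Hz seen during the pulse
        f_tot = delta_f + f_grad[None, :].astype(f32)  # (n_atoms, n_sub)
        ph_half = np.exp(-2j * np.pi * f_tot * (dwell / 2) * 1e-3).astype(c64)
        ph_full = (ph_half * ph_half).astype(c64)
        # relaxation during one dwell
        e2d = np.exp(-dwell / t2).astype(f32)[:, None]
        e1d = np.exp(-dwell / t1).astype(f32)[:, None]
        # balanced rephaser lobes: -1/2 gradient area before and after
        reph = np.exp(2j * np.pi * f_grad * (p.duration / 2) * 1e-3)
        reph = np.broadcast_to(reph.astype(c64), (n_atoms, n_sub))
        prep.append(dict(instant=False, ca=ca, sa=sa, phi=p.phase_axis,
                         ph_half=ph_half * e2d, ph_full=ph_full * e2d,
                         e1d=e1d, reph=reph, dt_edge=p.duration / 2))

    def free(mxy, mz, dt):
        if dt <= 0:
            return mxy, mz
        e2 = np.exp(-dt / t2 - 2j * np.pi * delta * dt * 1e-3)
        e1 = np.exp(-dt / t1).astype(f32)[:, None]
        mxy *= e2.astype(c64)[:, None]
        mz = 1.0 + (mz - 1.0) * e1
        return mxy, mz

    mxy = np.zeros((n_atoms, n_sub), dtype=c64)
    mz = np.ones((n_atoms, n_sub), dtype=f32)

    n_z = ensemble.n_zencodes
    kz = np.arange(n_z) - n_z // 2  # cycles across the encoded extent
    enc = np.exp(-2j * np.pi * kz[:, None] * z[None, :] / L).astype(c64)
    zenc = np.empty((train.n_contrasts, n_z, n_atoms), dtype=c64)

    q = 0
    for _ in range(train.n_blocks):
        for p, pr in zip(pulses, prep):
            phi = np.deg2rad(pr["phi"])
            fwd = c64(np.exp(-1j * phi))
            bwd = c64(np.exp(1j * phi))
            if pr["instant"]:
                m = mxy * fwd
                yt = m.imag
                y2 = yt * pr["ca"] - mz * pr["sa"]
                mz = yt * pr["sa"] + mz * pr["ca"]
                mxy = (m.real + 1j * y2).astype(c64) * bwd
            else:
                mxy *= pr["reph"]          # pre-rephaser (-A/2)
                mxy = mxy * fwd
                ca, sa, e1d = pr["ca"], pr["sa"], pr["e1d"]
                n_inc = ca.shape[0]
                mxy *= pr["ph_half"]
                mz = 1.0 + (mz - 1.0) * e1d
                for k in range(n_inc):
                    yt = mxy.imag
                    y2 = yt * ca[k][:, None] - mz * sa[k][:, None]
                    mz = yt * sa[k][:, None] + mz * ca[k][:, None]
                    mxy = (mxy.real + 1j * y2).astype(c64)
                    if k < n_inc - 1:
                        mxy *= pr["ph_full"]
                        mz = 1.0 + (mz - 1.0) * e1d
                mxy *= pr["ph_half"]
                mz = 1.0 + (mz - 1.0) * e1d
                mxy = mxy * bwd
                mxy *= pr["reph"]          # post-rephaser (-A/2)
            # free evolution from pulse edge to the readout state
            mxy, mz = free(mxy, mz, off - pr["dt_edge"])
            zenc[q] = enc @ mxy.T
            q += 1
            # free evolution to the start of the next pulse
            mxy, mz = free(mxy, mz, trp - off - pr["dt_edge"])

    # inverse DFT across z-encodes -> per-slice series, unit-density scaling
    zs = ensemble.slice_positions
    dec = np.exp(2j * np.pi * kz[None, :] * zs[:, None] / L).astype(c64)
    out = np.einsum("sm,qma->sqa", dec, zenc) / n_sub
    return out.astype(c64)


def simulate_mu(theta: TissueParams, train: PulseTrain,
                ensemble: SlabEnsemble,
                hard_pulse_max_deg: float = 2.0) -> np.ndarray:
    """Per-slice echo-state series for one voxel: shape (n_slices, n_q)."""
    s = simulate_mu_batch(train, ensemble, theta.t1, theta.t2,
                          theta.delta, theta.b1, hard_pulse_max_deg)
    return s[:, :, 0] * theta.i0
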