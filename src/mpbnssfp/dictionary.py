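"""Signal dictionaries over a tissue-parameter grid, the truncated contrast
subspace, and dictionary-matching parameter estimation.

The dictionary holds one Bloch-simulated echo-signal series per grid
atom (proton density fixed at 1).  Matching maximizes the normalized
correlation |<d, y>| / ||d|| over atoms (which absorbs the complex
proton-density scale), then refines each nonlinear parameter off-grid by
fitting a parabola to the match metric at the winning node and its grid
neighbors along each axis; the complex I0 is re-estimated by
least-squares projection onto the re-simulated refined atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .bloch import SlabEnsemble, simulate_mu_batch, simulate_si_batch
from .sequence import PulseTrain
from .synth import ParamMap

__all__ = [
    "ParamGrid",
    "SignalDictionary",
    "ContrastSubspace",
    "make_param_grid",
    "build_dictionary",
    "compute_subspace",
    "match_dictionary",
    "interpolate_refine",
    "refine_descent",
    "save_dictionary",
    "load_dictionary_arrays",
]

#: default grid ranges: T1/T2 log-spaced, Delta/B1 linear
DEFAULT_RANGES = dict(t1=(100.0, 2500.0), t2=(20.0, 300.0),
                      delta=(-200.0, 200.0), b1=(0.8, 1.2))
#: default per-axis step counts for the fitting grid
DEFAULT_STEPS = dict(t1=40, t2=40, delta=41, b1=9)


@dataclass(frozen=True)
class ParamGrid:
    """Cartesian T1 x T2 x Delta x B1 grid with T2 > T1 atoms excluded.

    ``atom_index`` maps lattice coordinates to the dictionary column
    (-1 for excluded combinations); ``atom_coords`` is the inverse map.
    """

    t1_values: np.ndarray
    t2_values: np.ndarray
    delta_values: np.ndarray
    b1_values: np.ndarray
    atom_index: np.ndarray = field(repr=False)   # (n1, n2, nd, nb) int
    atom_coords: np.ndarray = field(repr=False)  # (n_atoms, 4) int

    @property
    def n_atoms(self) -> int:
        return self.atom_coords.shape[0]

    @property
    def axes(self) -> tuple[np.ndarray, ...]:
        return (self.t1_values, self.t2_values,
                self.delta_values, self.b1_values)

    def thetas(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-atom (t1, t2, delta, b1) arrays in column order."""
        i1, i2, idl, ib = self.atom_coords.T
        return (self.t1_values[i1], self.t2_values[i2],
                self.delta_values[idl], self.b1_values[ib])


def make_param_grid(t1_range=DEFAULT_RANGES["t1"],
                    t2_range=DEFAULT_RANGES["t2"],
                    delta_range=DEFAULT_RANGES["delta"],
                    b1_range=DEFAULT_RANGES["b1"],
                    t1_steps: int = DEFAULT_STEPS["t1"],
                    t2_steps: int = DEFAULT_STEPS["t2"],
                    delta_steps: int = DEFAULT_STEPS["delta"],
                    b1_steps: int = DEFAULT_STEPS["b1"]) -> ParamGrid:
    """Build the parameter grid: log spacing for T1/T2, linear for Delta/B1."""
    for name, (lo, hi) in (("t1", t1_range), ("t2", t2_range),
                           ("delta", delta_range), ("b1", b1_range)):
        if lo >= hi:
            raise ValueError(f"{name} range must be increasing")
    for name, s in (("t1", t1_steps), ("t2", t2_steps),
                    ("delta", delta_steps), ("b1", b1_steps)):
        if s < 2:
            raise ValueError(f"{name}_steps must be >= 2")
    if t1_range[0] <= 0 or t2_range[0] <= 0:
        raise ValueError("t1/t2 ranges must be positive for log spacing")
    t1v = np.geomspace(*t1_range, t1_steps)
    t2v = np.geomspace(*t2_range, t2_steps)
    dv = np.linspace(*delta_range, delta_steps)
    bv = np.linspace(*b1_range, b1_steps)

    idx = np.full((t1_steps, t2_steps, delta_steps, b1_steps), -1, dtype=int)
    valid = t2v[None, :] <= t1v[:, None]  # physical constraint T2 <= T1
    coords = []
    col = 0
    for i1 in range(t1_steps):
        for i2 in range(t2_steps):
            if not valid[i1, i2]:
                continue
            for idl in range(delta_steps):
                for ib in range(b1_steps):
                    idx[i1, i2, idl, ib] = col
                    coords.append((i1, i2, idl, ib))
                    col += 1
    return ParamGrid(t1_values=t1v, t2_values=t2v, delta_values=dv,
                     b1_values=bv, atom_index=idx,
                     atom_coords=np.asarray(coords, dtype=int))


@dataclass
class SignalDictionary:
    """Simulated echo signals over a grid: atom_signals (n_q, n_atoms)."""

    atom_signals: np.ndarray
    grid: ParamGrid
    train: PulseTrain
    mode: str = "si"                       # 'si' or 'mu'
    ensemble: SlabEnsemble | None = None
    slice_index: int | None = None
    atom_norms: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.atom_norms is None:
            self.atom_norms = np.linalg.norm(self.atom_signals, axis=0)
        if np.any(self.atom_norms == 0):
            raise ValueError("dictionary contains zero-norm atoms")

    @property
    def n_contrasts(self) -> int:
        return self.atom_signals.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atom_signals.shape[1]

    def simulate(self, t1, t2, delta, b1) -> np.ndarray:
        """Simulate atoms at arbitrary parameters in this dictionary's mode."""
        if self.mode == "si":
            return simulate_si_batch(self.train, t1, t2, delta, b1)
        sl = (self.ensemble.central_slice if self.slice_index is None
              else self.slice_index)
        return simulate_mu_batch(self.train, self.ensemble,
                                 t1, t2, delta, b1)[sl].astype(complex)


def build_dictionary(grid: ParamGrid, train: PulseTrain, mode: str = "si",
                     ensemble: SlabEnsemble | None = None,
                     slice_index: int | None = None,
                     chunk: int = 8192) -> SignalDictionary:
    """Simulate one dictionary column per atom (Si or per-slice Mu)."""
    if mode not in ("si", "mu"):
        raise ValueError("mode must be 'si' or 'mu'")
    if mode == "mu" and ensemble is None:
        raise ValueError("mu mode requires an ensemble")
    t1, t2, delta, b1 = grid.thetas()
    n = grid.n_atoms
    out = np.empty((train.n_contrasts, n), dtype=np.complex64)
    sl = None
    if mode == "mu":
        sl = ensemble.central_slice if slice_index is None else slice_index
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        if mode == "si":
            out[:, lo:hi] = simulate_si_batch(
                train, t1[lo:hi], t2[lo:hi], delta[lo:hi], b1[lo:hi])
        else:
            out[:, lo:hi] = simulate_mu_batch(
                train, ensemble, t1[lo:hi], t2[lo:hi],
                delta[lo:hi], b1[lo:hi])[sl]
    return SignalDictionary(atom_signals=out, grid=grid, train=train,
                            mode=mode, ensemble=ensemble, slice_index=sl)


@dataclass
class ContrastSubspace:
    """Truncated SVD of the dictionary's contrast dimension: M ~ U S V^H."""

    basis: np.ndarray             # U, (n_q, d1), orthonormal columns
    singular_values: np.ndarray   # S, (d1,), non-increasing
    v_factor: np.ndarray          # V, (n_atoms, d1)
    total_energy: float           # sum of *all* squared singular values

    @property
    def d1(self) -> int:
        return self.basis.shape[1]

    def energy_fraction(self, d: int | None = None) -> float:
        """Fraction of total squared singular-value energy in the first d."""
        d = self.d1 if d is None else d
        if d > self.d1:
            raise ValueError("d exceeds the retained number of components")
        return float((self.singular_values[:d] ** 2).sum()
                     / self.total_energy)

    def project(self, signals: np.ndarray) -> np.ndarray:
        """Compress series (..., n_q) to subspace coefficients (..., d1)."""
        return signals @ np.conj(self.basis)


def compute_subspace(dictionary: SignalDictionary,
                     d1: int = 12) -> ContrastSubspace:
    """Truncated contrast SVD via the (n_q x n_q) Gram eigendecomposition."""
    A = dictionary.atom_signals
    n_q = A.shape[0]
    if not 1 <= d1 <= n_q:
        raise ValueError("d1 must lie in [1, n_q]")
    G = (A @ A.conj().T).astype(complex)  # (n_q, n_q)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    s_all = np.sqrt(evals)
    U = evecs[:, order]
    total = float(evals.sum())
    keep = s_all[:d1]
    Ud = U[:, :d1]
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.where(keep[None, :] > 0,
                     (A.conj().T @ Ud) / keep[None, :], 0.0)
    return ContrastSubspace(basis=Ud, singular_values=keep, v_factor=V,
                            total_energy=total)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _axis_neighbors(grid: ParamGrid, coords: np.ndarray, axis: int):
    """Column indices of the -1/+1 lattice neighbors along ``axis`` (-1 if
    absent or excluded)."""
    lo = coords.copy()
    hi = coords.copy()
    lo[axis] -= 1
    hi[axis] += 1
    n_ax = grid.atom_index.shape[axis]
    left = grid.atom_index[tuple(lo)] if lo[axis] >= 0 else -1
    right = grid.atom_index[tuple(hi)] if hi[axis] < n_ax else -1
    return left, right


def _parabola_offset(sl: float, sc: float, sr: float) -> float:
    """Fractional vertex offset in [-0.5, 0.5] of a parabola through three
    equally spaced metric values (0 when degenerate/non-concave)."""
    denom = sl - 2.0 * sc + sr
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (sl - sr) / denom, -0.5, 0.5))


def _axis_value(values: np.ndarray, idx: int, frac: float,
                log_spaced: bool) -> float:
    """Off-grid parameter value at fractional lattice position idx + frac."""
    pos = np.clip(idx + frac, 0, values.size - 1)
    i0 = int(np.floor(pos))
    i1 = min(i0 + 1, values.size - 1)
    w = pos - i0
    if log_spaced:
        return float(np.exp((1 - w) * np.log(values[i0])
                            + w * np.log(values[i1])))
    return float((1 - w) * values[i0] + w * values[i1])


def interpolate_refine(atom: int, dictionary: SignalDictionary,
                       y: np.ndarray, resimulate: bool = True):
    """Refine the winning atom's parameters by per-axis parabola fitting.

    For each of T1, T2, Delta, B1 the normalized match metric
    |<d, y>| / ||d|| is evaluated at the winning node and its two lattice
    neighbors; the parabola vertex (clamped to the neighbor interval)
    gives the off-grid coordinate.  Returns ``(t1, t2, delta, b1, i0)``;
    ``i0`` is re-estimated by projecting y onto the re-simulated refined
    atom when ``resimulate`` is True (else None).
    """
    grid = dictionary.grid
    D = dictionary.atom_signals
    norms = dictionary.atom_norms
    coords = grid.atom_coords[atom]

    def metric(a: int) -> float:
        return float(np.abs(np.vdot(D[:, a], y)) / norms[a])

    sc = metric(atom)
    frac = np.zeros(4)
    for ax in range(4):
        left, right = _axis_neighbors(grid, coords, ax)
        if left < 0 or right < 0:
            continue  # edge-clamped or excluded neighbor: keep grid value
        frac[ax] = _parabola_offset(metric(left), sc, metric(right))
    log_spaced = (True, True, False, False)
    vals = tuple(_axis_value(grid.axes[ax], coords[ax], frac[ax],
                             log_spaced[ax]) for ax in range(4))
    if not resimulate:
        return (*vals, None)
    d_ref = dictionary.simulate(*[np.atleast_1d(v) for v in vals])[:, 0]
    i0 = np.vdot(d_ref, y) / np.vdot(d_ref, d_ref)
    return (*vals, complex(i0))


#: default refinement step-shrink schedule: full-grid-step walk sweeps to
#: traverse shallow degeneracy ridges (T2-B1, T1-B1 coupling), then
#: halving brackets for sub-grid precision
REFINE_SCHEDULE = (1.0, 1.0, 1.0, 1.0, 0.5, 0.25, 0.125)

#: search directions in (log t1, log t2, delta, b1) step units: the four
#: axes plus the diagonals of the known degenerate parameter pairs
REFINE_DIRECTIONS = (
    (1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1),
    (1, 0, 0, 1), (1, 0, 0, -1), (0, 1, 0, 1), (0, 1, 0, -1),
    (1, 1, 0, 0), (1, -1, 0, 0),
)


def refine_descent(dictionary: SignalDictionary, signals: np.ndarray,
                   init: np.ndarray,
                   schedule=REFINE_SCHEDULE,
                   directions=REFINE_DIRECTIONS) -> np.ndarray:
    """Iterated quadratic-interpolation refinement of matched parameters.

    Starting from the winning grid nodes, sweeps a set of search
    directions (axes and degenerate-pair diagonals); along each
    direction the match metric is evaluated at +/- one step (re-simulated
    atoms), a parabola vertex proposes an off-grid point, and the best of
    the four candidates is kept.  Early sweeps use full grid steps so the
    estimate can walk along shallow metric ridges; later sweeps shrink
    the bracket for sub-grid precision.  T1/T2 move multiplicatively
    (log-spaced axes), Delta/B1 additively.  All voxels are processed in
    vectorized batches.

    Parameters
    ----------
    signals:
        (n_vox, n_q) complex series (arbitrary complex scale).
    init:
        (n_vox, 4) initial (t1, t2, delta, b1), typically the winning
        grid nodes.

    Returns
    -------
    (n_vox, 4) refined parameters, clamped to the grid bounding box.
    """
    g = dictionary.grid
    Y = np.asarray(signals, dtype=complex)
    cur = np.asarray(init, dtype=float).copy()
    steps = np.array([
        np.log(g.t1_values[1] / g.t1_values[0]),
        np.log(g.t2_values[1] / g.t2_values[0]),
        g.delta_values[1] - g.delta_values[0],
        g.b1_values[1] - g.b1_values[0]])
    lims = [(g.t1_values[0], g.t1_values[-1]),
            (g.t2_values[0], g.t2_values[-1]),
            (g.delta_values[0], g.delta_values[-1]),
            (g.b1_values[0], g.b1_values[-1])]

    def move(P, dvec, t):
        # t may be scalar or per-voxel
        Q = P.copy()
        t = np.asarray(t, dtype=float)
        for ax in range(4):
            if dvec[ax] == 0:
                continue
            h = dvec[ax] * steps[ax] * t
            if ax < 2:
                Q[:, ax] = Q[:, ax] * np.exp(h)
            else:
                Q[:, ax] = Q[:, ax] + h
            Q[:, ax] = np.clip(Q[:, ax], *lims[ax])
        # keep T2 <= T1 (grid exclusion rule)
        Q[:, 1] = np.minimum(Q[:, 1], Q[:, 0])
        return Q

    def metrics(P):
        S = dictionary.simulate(P[:, 0], P[:, 1], P[:, 2], P[:, 3])
        return (np.abs(np.einsum("qv,vq->v", S.conj(), Y))
                / np.linalg.norm(S, axis=0))

    mc = metrics(cur)
    for shrink in schedule:
        for dvec in directions:
            L = move(cur, dvec, -shrink)
            R = move(cur, dvec, shrink)
            ml, mr = metrics(L), metrics(R)
            den = ml - 2.0 * mc + mr
            safe = np.where(den < 0, den, -1.0)
            off = np.where(den < 0,
                           np.clip(0.5 * (ml - mr) / safe, -1.0, 1.0),
                           np.where(mr > ml, 1.0, -1.0))
            V = move(cur, dvec, off * shrink)
            mv = metrics(V)
            stack_m = np.stack([mc, ml, mr, mv])
            best = np.argmax(stack_m, axis=0)
            for i, (P, m) in enumerate([(cur, mc), (L, ml), (R, mr),
                                        (V, mv)]):
                sel = best == i
                cur[sel] = P[sel]
                mc[sel] = m[sel]
    return cur


def match_dictionary(signals: np.ndarray, dictionary: SignalDictionary,
                     subspace: ContrastSubspace | None = None,
                     refine: bool = True,
                     chunk: int = 64) -> dict:
    """Match voxel series to the dictionary and estimate parameters.

    Parameters
    ----------
    signals:
        Complex series, shape (n_voxels, n_q).
    subspace:
        Optional contrast subspace; when given, the argmax search runs in
        the compressed d1-dimensional domain (exact for series lying in
        the subspace span, and a standard accurate approximation
        otherwise); refinement always uses the full-length metric.
    refine:
        Apply per-axis quadratic interpolation refinement.

    Returns
    -------
    dict with per-voxel arrays ``t1``, ``t2``, ``delta``, ``b1``
    (NaN for invalid voxels), complex ``i0``, int ``atom`` (-1 invalid)
    and boolean ``valid`` (all-zero series are flagged invalid).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=complex))
    n_vox, n_q = signals.shape
    if n_q != dictionary.n_contrasts:
        raise ValueError("signal length does not match the dictionary")
    valid = np.linalg.norm(signals, axis=1) > 0

    Dn = (dictionary.atom_signals
          / dictionary.atom_norms[None, :]).astype(np.complex64)
    if subspace is not None:
        Dn = subspace.basis.conj().T.astype(np.complex64) @ Dn  # (d1, n_atoms)
        Y = signals @ np.conj(subspace.basis)                   # (n_vox, d1)
    else:
        Y = signals
    best = np.full(n_vox, -1, dtype=int)
    for lo in range(0, n_vox, chunk):
        hi = min(lo + chunk, n_vox)
        scores = np.abs(Y[lo:hi].astype(np.complex64) @ np.conj(Dn))
        best[lo:hi] = np.argmax(scores, axis=1)
    best[~valid] = -1

    out = dict(
        t1=np.full(n_vox, np.nan), t2=np.full(n_vox, np.nan),
        delta=np.full(n_vox, np.nan), b1=np.full(n_vox, np.nan),
        i0=np.zeros(n_vox, dtype=complex), atom=best, valid=valid)

    t1g, t2g, dg, bg = dictionary.grid.thetas()
    idx = np.nonzero(valid)[0]
    if refine and idx.size:
        init = np.stack([t1g[best[idx]], t2g[best[idx]],
                         dg[best[idx]], bg[best[idx]]], axis=1)
        refined = refine_descent(dictionary, signals[idx], init)
        d_ref = dictionary.simulate(*refined.T)  # (n_q, n_valid)
        num = np.einsum("qv,vq->v", d_ref.conj(), signals[idx])
        den = (np.abs(d_ref) ** 2).sum(axis=0)
        out["i0"][idx] = num / den
        for name, col in zip(("t1", "t2", "delta", "b1"), range(4)):
            out[name][idx] = refined[:, col]
    else:
        out["t1"][idx] = t1g[best[idx]]
        out["t2"][idx] = t2g[best[idx]]
        out["delta"][idx] = dg[best[idx]]
        out["b1"][idx] = bg[best[idx]]
        D = dictionary.atom_signals
        for v in idx:
            d = D[:, best[v]]
            out["i0"][v] = np.vdot(d, signals[v]) / np.vdot(d, d)
    return out


def match_to_parammap(result: dict, shape: tuple[int, int],
                      mask: np.ndarray) -> ParamMap:
    """Assemble flat match results over ``mask`` into a ParamMap."""
    def full(name, fill=0.0):
        arr = np.full(shape, fill, dtype=float)
        arr[mask] = np.nan_to_num(result[name], nan=fill)
        return arr
    i0 = np.zeros(shape, dtype=complex)
    i0[mask] = result["i0"]
    m = np.zeros(shape, dtype=bool)
    m[mask] = result["valid"]
    i0[~m] = 0
    return ParamMap(t1=full("t1", 1000.0), t2=full("t2", 100.0),
                    delta=full("delta"), b1=full("b1", 1.0), i0=i0, mask=m)


# ---------------------------------------------------------------------------
# dictionary store
# ---------------------------------------------------------------------------

def save_dictionary(path, dictionary: SignalDictionary) -> None:
    """Write atom signals and grid axes to an HDF5 dictionary store."""
    g = dictionary.grid
    with h5py.File(path, "w") as f:
        f.create_dataset("atom_signals",
                         data=dictionary.atom_signals.astype(np.complex64))
        f.create_dataset("t1_values", data=g.t1_values)
        f.create_dataset("t2_values", data=g.t2_values)
        f.create_dataset("delta_values", data=g.delta_values)
        f.create_dataset("b1_values", data=g.b1_values)
        f.attrs["mode"] = dictionary.mode
        f.attrs["slice_index"] = (-1 if dictionary.slice_index is None
                                  else dictionary.slice_index)


def load_dictionary_arrays(path) -> dict:
    """Read back the store written by :func:`save_dictionary`."""
    with h5py.File(path, "r") as f:
        return dict(
            atom_signals=f["atom_signals"][...],
            t1_values=f["t1_values"][...],
            t2_values=f["t2_values"][...],
            delta_values=f["delta_values"][...],
            b1_values=f["b1_values"][...],
            mode=str(f.attrs["mode"]),
            slice_index=int(f.attrs["slice_index"]),
        )
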