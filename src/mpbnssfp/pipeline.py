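"""Two-pass B0-compensated mapping pipeline and map I/O.

The fitted off-resonance Delta is identifiable only modulo the wrap
period 1/TRp (the echo-state signal is periodic in Delta), so the
first-pass map is *wrapped* into the band (-1/(2 TRp), +1/(2 TRp)].
The pipeline therefore runs:

1. uncompensated reconstruction (SCR or SENSE) + dictionary fit
   -> wrapped Delta map;
2. quality-guided spatial unwrapping;
3. phase-subspace construction from the unwrapped map and
   B0-compensated reconstruction + final dictionary fit.

All randomness is seeded; identical config + seed give bit-identical
maps.
"""

from __future__ import annotations

import heapq
import json
import time
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .bloch import SlabEnsemble
from .config import PipelineConfig
from .dictionary import (ContrastSubspace, SignalDictionary,
                         build_dictionary, compute_subspace,
                         make_param_grid, match_dictionary)
from .recon import (ContrastImages, compose_contrasts, phase_subspace,
                    scr, scr_b0, sense_b0)
from .sampling import (SamplingOperator, build_operator, design_spiral,
                       schedule_arms)
from .sequence import PulseTrain, build_optimized_block, build_pulse_train
from .synth import (CoilMaps, KSpaceData, load_kspace_arrays,
                    make_coilmaps, make_phantom, synthesize_kspace)

__all__ = [
    "B0Map",
    "wrap_period_hz",
    "estimate_b0_initial",
    "unwrap_b0",
    "run_pipeline",
    "band_delta_range",
    "save_maps_nifti",
]


def wrap_period_hz(trp_ms: float) -> float:
    """Off-resonance aliasing period of the fitted Delta map, in Hz.

    |Delta * TRp| > pi (Delta in rad/s) wraps; in Hz the period is
    1000 / trp_ms (33.33 Hz at TRp 30 ms).  This is the single place
    where the angular-units statement is converted to Hz.
    """
    return 1000.0 / trp_ms


def band_delta_range(trp_ms: float, steps: int) -> tuple[float, float]:
    """Half-open single-band Delta axis endpoints (-w/2, w/2].

    Both band edges are exact signal aliases of each other, so a
    matching grid must not contain both; the returned range yields
    ``steps`` values with spacing w/steps ending exactly at +w/2.
    """
    w = wrap_period_hz(trp_ms)
    step = w / steps
    return (-w / 2 + step, w / 2)


@dataclass
class B0Map:
    """Off-resonance map in Hz with wrap state and validity mask."""

    delta: np.ndarray
    wrapped: bool
    mask: np.ndarray
    quality: np.ndarray | None = None  # e.g. |I0|, guides unwrapping

    def __post_init__(self) -> None:
        if self.delta.shape != self.mask.shape:
            raise ValueError("delta and mask shapes differ")


def estimate_b0_initial(kdata: KSpaceData, coils: CoilMaps,
                        operator: SamplingOperator,
                        dictionary: SignalDictionary,
                        subspace: ContrastSubspace,
                        mask: np.ndarray,
                        max_iter: int = 40, tol: float = 1e-6) -> B0Map:
    """First-pass wrapped Delta estimate: uncompensated SCR + fit."""
    comp = scr(kdata, coils, operator, subspace,
               max_iter=max_iter, tol=tol)
    images = compose_contrasts(subspace, comp).images
    res = match_dictionary(images[:, mask].T, dictionary,
                           subspace=subspace)
    delta = np.zeros(mask.shape)
    quality = np.zeros(mask.shape)
    delta[mask] = np.nan_to_num(res["delta"])
    quality[mask] = np.abs(res["i0"])
    return B0Map(delta=delta, wrapped=True, mask=mask.copy(),
                 quality=quality)


def unwrap_b0(wrapped: B0Map, trp_ms: float) -> B0Map:
    """Quality-guided region-growing unwrap of a wrapped Delta map.

    Starting from the highest-quality voxel of each connected mask
    component, voxels are visited in decreasing quality order; each gets
    the integer multiple of the wrap period that brings it closest to
    the mean of its already-unwrapped neighbors.  Each component is then
    re-centered by the integer number of periods that brings its median
    closest to zero (the absolute B0 reference is ambiguous modulo the
    wrap period; a field distribution centered in the base band is the
    conventional choice).  Offsets between disconnected components are
    otherwise not resolved.
    """
    if not wrapped.wrapped:
        raise ValueError("input map is not flagged wrapped")
    mask = wrapped.mask
    if not mask.any():
        raise ValueError("empty mask")
    period = wrap_period_hz(trp_ms)
    quality = (wrapped.quality if wrapped.quality is not None
               else np.ones(mask.shape))
    out = wrapped.delta.copy()
    labels, n_comp = ndimage.label(mask)
    done = np.zeros(mask.shape, dtype=bool)
    nbrs = ((1, 0), (-1, 0), (0, 1), (0, -1))
    counter = 0
    for comp in range(1, n_comp + 1):
        sel = labels == comp
        q_comp = np.where(sel, quality, -np.inf)
        seed = np.unravel_index(np.argmax(q_comp), mask.shape)
        done[seed] = True
        heap = []
        for dx, dy in nbrs:
            p = (seed[0] + dx, seed[1] + dy)
            if 0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1] \
                    and sel[p] and not done[p]:
                counter += 1
                heapq.heappush(heap, (-quality[p], counter, p))
        while heap:
            _, _, p = heapq.heappop(heap)
            if done[p]:
                continue
            vals = [out[p[0] + dx, p[1] + dy] for dx, dy in nbrs
                    if 0 <= p[0] + dx < mask.shape[0]
                    and 0 <= p[1] + dy < mask.shape[1]
                    and done[p[0] + dx, p[1] + dy]
                    and sel[p[0] + dx, p[1] + dy]]
            ref = float(np.mean(vals))
            n = np.round((ref - out[p]) / period)
            out[p] += n * period
            done[p] = True
            for dx, dy in nbrs:
                pn = (p[0] + dx, p[1] + dy)
                if 0 <= pn[0] < mask.shape[0] and 0 <= pn[1] < mask.shape[1] \
                        and sel[pn] and not done[pn]:
                    counter += 1
                    heapq.heappush(heap, (-quality[pn], counter, pn))
        # re-center the component's median into the base band
        out[sel] -= period * np.round(np.median(out[sel]) / period)
    return B0Map(delta=out, wrapped=False, mask=mask.copy(),
                 quality=wrapped.quality)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def build_train(cfg: PipelineConfig) -> PulseTrain:
    seq = cfg.sequence
    selective = seq.pulse_mode == "waveform"
    block = build_optimized_block(seq.trp_ms, selective=selective,
                                  pulse_duration=seq.pulse_duration_ms,
                                  time_bandwidth=seq.time_bandwidth)
    return build_pulse_train(block, seq.n_blocks, seq.delay_ms,
                             seq.readout_start_offset_ms)


def build_fit_dictionary(cfg: PipelineConfig, train: PulseTrain):
    """Band-limited-Delta fitting grid, dictionary and contrast subspace."""
    fit = cfg.fit
    grid = make_param_grid(
        t1_range=fit.t1_range, t2_range=fit.t2_range,
        delta_range=band_delta_range(cfg.sequence.trp_ms, fit.delta_steps),
        b1_range=fit.b1_range,
        t1_steps=fit.t1_steps, t2_steps=fit.t2_steps,
        delta_steps=fit.delta_steps, b1_steps=fit.b1_steps)
    ens = None
    if fit.mode == "mu":
        e = cfg.ensemble
        ens = SlabEnsemble(n_subspins=e.n_subspins,
                           slab_factor=e.slab_factor,
                           n_zencodes=e.n_zencodes,
                           slab_width_mm=e.slab_width_mm)
    dic = build_dictionary(grid, train, mode=fit.mode, ensemble=ens)
    sub = compute_subspace(dic, cfg.recon.d1)
    return dic, sub


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full two-pass pipeline on synthetic (or stored) data.

    Returns a dict with the fitted parameter maps (``t1``, ``t2``,
    ``delta``, ``b1``, ``i0``), the ground-truth phantom (synthetic
    runs), intermediate B0 maps and a provenance log; writes NIfTI maps
    and the log when ``cfg.out_dir`` is set.
    """
    t_start = time.time()
    log: dict = {"config": cfg.to_dict(), "stages": {}}
    train = build_train(cfg)
    n = cfg.phantom.matrix
    samp = cfg.sampling

    # --- inputs: digital phantom + coils + sampling ----------------------
    pmap = None
    if cfg.kspace_path is not None:
        arr = load_kspace_arrays(cfg.kspace_path)
        if arr["coilmaps"] is None:
            raise ValueError("pipeline aborted at stage 'load': k-space "
                             "container lacks coil maps")
        from .sampling import SpiralTrajectory, UndersamplingSchedule
        traj = SpiralTrajectory(k_coords=arr["k_coords"],
                                tau=arr["tau_ms"],
                                readout_ms=arr["readout_ms"],
                                n_arms_full=arr["n_arms_full"],
                                fov_mm=arr["fov_mm"])
        sched = UndersamplingSchedule(n_arms_full=arr["n_arms_full"],
                                      acceleration=arr["acceleration"],
                                      arm_index=arr["schedule"])
        n = arr["grid_shape"][0]
        op = build_operator(traj, sched, arr["grid_shape"])
        coils = CoilMaps(maps=arr["coilmaps"])
        kdata = KSpaceData(data=arr["kdata"],
                           noise_sd=arr["noise_sd"],
                           seed=None if arr["seed"] < 0 else arr["seed"])
        mask = None  # derived from the first-pass images below
    else:
        pmap = make_phantom((n, n), tube_t1=cfg.phantom.tube_t1,
                            tube_t2=cfg.phantom.tube_t2,
                            tube_radius_frac=cfg.phantom.tube_radius_frac,
                            b0_poly=cfg.phantom.b0_poly,
                            b1_radial=cfg.phantom.b1_radial)
        coils = make_coilmaps(samp.n_coils, (n, n),
                              smoothness=samp.coil_smoothness)
        traj = design_spiral(n, fov=samp.fov_mm, n_arms=samp.n_arms,
                             readout_ms=samp.readout_ms,
                             n_samples=samp.n_samples)
        sched = schedule_arms(train.n_contrasts, samp.n_arms,
                              samp.acceleration)
        op = build_operator(traj, sched, (n, n))
        kdata = synthesize_kspace(pmap, train, op, coils,
                                  noise_sd=cfg.noise_sd, seed=cfg.seed)
        mask = pmap.mask
        if not mask.any():
            raise ValueError(
                "pipeline aborted at stage 'phantom': empty mask")

    dic, sub = build_fit_dictionary(cfg, train)
    log["stages"]["dictionary"] = {
        "n_atoms": dic.n_atoms,
        "d1": sub.d1,
        "energy_fraction_d1": sub.energy_fraction(),
    }
    rc = cfg.recon

    # --- pass 1: uncompensated recon -> wrapped Delta ---------------------
    comp1 = scr(kdata, coils, op, sub, max_iter=rc.max_iter, tol=rc.tol)
    images1 = compose_contrasts(sub, comp1).images
    if mask is None:
        mag = np.abs(images1).mean(axis=0)
        mask = mag > 0.1 * mag.max()
    res1 = match_dictionary(images1[:, mask].T, dic, subspace=sub)
    delta1 = np.zeros((n, n))
    quality = np.zeros((n, n))
    delta1[mask] = np.nan_to_num(res1["delta"])
    quality[mask] = np.abs(res1["i0"])
    b0_wrapped = B0Map(delta=delta1, wrapped=True, mask=mask.copy(),
                       quality=quality)
    b0 = unwrap_b0(b0_wrapped, cfg.sequence.trp_ms)
    log["stages"]["b0"] = {
        "wrapped_range_hz": [float(b0_wrapped.delta[mask].min()),
                             float(b0_wrapped.delta[mask].max())],
        "unwrapped_range_hz": [float(b0.delta[mask].min()),
                               float(b0.delta[mask].max())],
    }

    # --- pass 2: compensated recon + final fit ----------------------------
    ps = phase_subspace(b0.delta * mask, traj.tau, d2=rc.d2)
    log["stages"]["phase_subspace"] = {
        "d2": ps.d2, "energy_fraction": ps.energy_fraction()}
    if rc.method == "sense":
        images = sense_b0(kdata, coils, op, ps,
                          max_iter=rc.max_iter, tol=rc.tol).images
    elif rc.method in ("scr", "scr-b0"):
        phase = None if rc.method == "scr" else ps
        comp = scr_b0(kdata, coils, op, sub, phase,
                      max_iter=rc.max_iter, tol=rc.tol)
        images = compose_contrasts(sub, comp).images
    else:
        raise ValueError(f"unknown recon method {rc.method!r}")

    res = match_dictionary(images[:, mask].T, dic, subspace=sub)
    period = wrap_period_hz(cfg.sequence.trp_ms)
    maps = {}
    for name, fill in (("t1", np.nan), ("t2", np.nan), ("b1", np.nan)):
        arr = np.full((n, n), fill)
        arr[mask] = res[name]
        maps[name] = arr
    # re-apply the unwrapped integer wrap offsets to the final band fit
    dfit = np.full((n, n), np.nan)
    dfit[mask] = res["delta"]
    k = np.round((b0.delta - np.nan_to_num(dfit)) / period)
    maps["delta"] = dfit + k * period
    i0 = np.zeros((n, n), dtype=complex)
    i0[mask] = res["i0"]
    maps["i0"] = i0

    log["stages"]["fit"] = {
        "n_voxels": int(mask.sum()),
        "invalid": int((~res["valid"]).sum()),
    }
    log["elapsed_s"] = time.time() - t_start

    out = dict(maps=maps, phantom=pmap, b0_wrapped=b0_wrapped,
               b0_unwrapped=b0, images=ContrastImages(images=images),
               log=log)
    if cfg.out_dir is not None:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_maps_nifti(out_dir, maps)
        with open(out_dir / "provenance.json", "w") as f:
            json.dump(log, f, indent=2, default=str)
    return out


def save_maps_nifti(out_dir, maps: dict) -> None:
    """Write parameter maps as single-volume NIfTI files."""
    out_dir = Path(out_dir)
    affine = np.eye(4)
    named = {
        "t1_ms": maps["t1"], "t2_ms": maps["t2"],
        "delta_hz": maps["delta"], "b1": maps["b1"],
        "i0_magnitude": np.abs(maps["i0"]),
        "i0_phase": np.angle(maps["i0"]),
    }
    for name, arr in named.items():
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine)
        nib.save(img, str(out_dir / f"{name}.nii.gz"))
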