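"""Configuration dataclasses for the end-to-end pipeline.

Defaults follow the reference 3D protocol (TRp 30 ms, 12 blocks, 3 s
recovery delay, 16-arm stack-of-spirals with 22 ms readouts) at
desk-scale matrix sizes; every block can be overridden from a YAML file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["SequenceConfig", "EnsembleConfig", "PhantomConfig",
           "SamplingConfig", "ReconConfig", "FitConfig", "PipelineConfig",
           "load_config"]


@dataclass
class SequenceConfig:
    trp_ms: float = 30.0
    n_blocks: int = 12
    delay_ms: float = 3000.0
    readout_start_offset_ms: float = 2.0
    pulse_mode: str = "instant"        # 'instant' or 'waveform'
    pulse_duration_ms: float = 1.0     # waveform mode only
    time_bandwidth: float = 16.0


@dataclass
class EnsembleConfig:
    n_subspins: int = 64
    slab_factor: float = 1.8
    n_zencodes: int = 8
    slab_width_mm: float = 132.0
    hard_pulse_max_deg: float = 2.0


@dataclass
class PhantomConfig:
    matrix: int = 32
    tube_t1: tuple = (300.0, 600.0, 1000.0, 1500.0)
    tube_t2: tuple = (50.0, 80.0, 120.0, 200.0)
    tube_radius_frac: float = 0.16
    b0_poly: tuple = (0.0, 20.0, 10.0, 30.0)
    b1_radial: tuple = (1.05, -0.2)


@dataclass
class SamplingConfig:
    fov_mm: float = 240.0
    n_arms: int = 16
    readout_ms: float = 22.0
    n_samples: int = 336
    acceleration: float = 2.0
    n_coils: int = 4
    coil_smoothness: float = 0.6


@dataclass
class ReconConfig:
    method: str = "scr-b0"             # 'sense', 'scr', 'scr-b0'
    d1: int = 12
    d2: int | None = None              # None = automatic (0.999 energy)
    max_iter: int = 40
    tol: float = 1e-6


@dataclass
class FitConfig:
    mode: str = "mu"                   # 'mu' (slab-resolved) or 'si'
    t1_steps: int = 40
    t2_steps: int = 40
    delta_steps: int = 15              # over one wrap band
    b1_steps: int = 9
    t1_range: tuple = (100.0, 2500.0)
    t2_range: tuple = (20.0, 300.0)
    b1_range: tuple = (0.8, 1.2)


@dataclass
class PipelineConfig:
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    noise_sd: float = 0.0
    seed: int = 0
    kspace_path: str | None = None     # reconstruct stored data instead
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = {}
        sections = dict(sequence=SequenceConfig, ensemble=EnsembleConfig,
                        phantom=PhantomConfig, sampling=SamplingConfig,
                        recon=ReconConfig, fit=FitConfig)
        for key, val in d.items():
            if key in sections:
                kw[key] = sections[key](**val)
            else:
                kw[key] = val
        return cls(**kw)


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as f:
        d = yaml.safe_load(f) or {}
    return PipelineConfig.from_dict(d)
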