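"""Pulse-train definition for the MP-b-nSSFP sequence.

The sequence repeats an optimized block of four RF pulses
(30deg_x, 175deg_y, 30deg_y, 175deg_x) at a fixed inter-pulse repetition
time TRp, with a balanced spiral readout after every pulse.  Each readout
is a distinct *contrast*; a train of ``n_blocks`` blocks therefore yields
``4 * n_blocks`` contrasts.  After the train a long delay lets the
magnetization recover toward equilibrium.

All timing is in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RFPulse",
    "SequenceBlock",
    "PulseTrain",
    "build_optimized_block",
    "build_pulse_train",
    "dead_time_fraction",
    "windowed_sinc_envelope",
]

#: flip angles (deg) of the optimized 4-pulse block
BLOCK_FLIP_DEG = (30.0, 175.0, 30.0, 175.0)
#: rotation-axis azimuths (deg) of the optimized block: x, y, y, x
BLOCK_PHASE_DEG = (0.0, 90.0, 90.0, 0.0)


def windowed_sinc_envelope(time_bandwidth: float = 16.0,
                           n_samples: int = 256) -> np.ndarray:
    """Hamming-windowed sinc amplitude envelope (unit dwell, arbitrary units).

    A surrogate for the SLR slab-selective pulses used on the scanner; the
    time-bandwidth product controls the number of sinc lobes and hence the
    sharpness of the excited slab profile.

    Parameters
    ----------
    time_bandwidth:
        Dimensionless time-bandwidth product (default 16).
    n_samples:
        Number of uniformly spaced envelope samples.

    Returns
    -------
    numpy.ndarray
        Real amplitude samples; the caller scales the integral to the flip
        angle.
    """
    if time_bandwidth <= 0:
        raise ValueError("time_bandwidth must be positive")
    if n_samples < 8:
        raise ValueError("need at least 8 envelope samples")
    t = np.linspace(-0.5, 0.5, n_samples)  # normalized time in [-1/2, 1/2]
    env = np.sinc(time_bandwidth * t)
    env *= np.hamming(n_samples)
    return env


@dataclass(frozen=True)
class RFPulse:
    """One RF pulse of the train.

    Attributes
    ----------
    flip_angle:
        Nominal on-resonance flip angle in degrees (at B1 = 1).
    phase_axis:
        Azimuth of the rotation axis in the transverse plane, degrees
        (0 = x, 90 = y).
    duration:
        Pulse duration in ms; 0 means an instantaneous rotation.
    envelope:
        Optional sampled amplitude waveform (uniform dwell); required for
        selective pulses simulated with finite duration.
    selective:
        Whether the pulse is slab-selective (played with a slice-select
        gradient).
    time_bandwidth:
        Time-bandwidth product of a selective pulse (dimensionless).
    """

    flip_angle: float
    phase_axis: float = 0.0
    duration: float = 0.0
    envelope: np.ndarray | None = field(default=None, repr=False)
    selective: bool = False
    time_bandwidth: float = 16.0

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_angle < 360.0:
            raise ValueError("flip_angle must lie in (0, 360) degrees")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.selective and self.duration > 0 and self.envelope is None:
            # build the default windowed-sinc surrogate
            object.__setattr__(
                self, "envelope",
                windowed_sinc_envelope(self.time_bandwidth))

    @property
    def bandwidth_khz(self) -> float:
        """RF bandwidth in kHz (selective, finite-duration pulses only)."""
        if not self.selective or self.duration <= 0:
            raise ValueError("bandwidth defined only for selective pulses "
                             "with finite duration")
        return self.time_bandwidth / self.duration

    def flip_increments(self, max_step_deg: float = 2.0,
                        b1_max: float = 1.2) -> np.ndarray:
        """Discretize the pulse into hard-pulse rotation increments (deg).

        The envelope is resampled so that no sub-step rotates by more than
        ``max_step_deg`` degrees at transmit scale ``b1_max``; the increments
        sum exactly to ``flip_angle``.
        """
        if self.envelope is None or self.duration == 0:
            return np.array([self.flip_angle])
        env = np.asarray(self.envelope, dtype=float)
        t_old = (np.arange(env.size) + 0.5) / env.size

        def increments(n):
            if n == env.size:
                e = env
            else:
                t_new = (np.arange(n) + 0.5) / n
                e = np.interp(t_new, t_old, env)
            return e * (self.flip_angle / e.sum())

        inc = increments(env.size)
        # refine the uniform dwell until the peak rotation is within bound
        for _ in range(32):
            peak = np.abs(inc).max() * b1_max
            if peak <= max_step_deg:
                break
            n = int(np.ceil(inc.size * peak / max_step_deg))
            inc = increments(n)
        return inc


@dataclass(frozen=True)
class SequenceBlock:
    """The repeated block of exactly four RF pulses separated by TRp."""

    pulses: tuple[RFPulse, RFPulse, RFPulse, RFPulse]
    trp: float  # ms between successive pulse centers

    def __post_init__(self) -> None:
        if len(self.pulses) != 4:
            raise ValueError("a sequence block holds exactly 4 pulses")
        if self.trp <= 0:
            raise ValueError("trp must be positive")
        for p in self.pulses:
            if self.trp <= p.duration:
                raise ValueError("trp must exceed every pulse duration")

    @property
    def duration_ms(self) -> float:
        return 4.0 * self.trp


@dataclass(frozen=True)
class PulseTrain:
    """A train of repeated blocks followed by a recovery delay.

    ``readout_start_offset`` is the time (ms) from each pulse center to the
    first readout sample; the magnetization *state* used by the signal model
    is defined at that instant and within-readout time offsets tau count
    from it (tau_1 = 0).
    """

    block: SequenceBlock
    n_blocks: int
    inter_train_delay: float = 3000.0
    readout_start_offset: float = 2.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.inter_train_delay < 0:
            raise ValueError("inter_train_delay must be non-negative")
        if not 0 <= self.readout_start_offset < self.block.trp:
            raise ValueError("readout_start_offset must lie within TRp")

    @property
    def n_contrasts(self) -> int:
        return 4 * self.n_blocks

    @property
    def train_duration_ms(self) -> float:
        return self.n_blocks * self.block.duration_ms

    @property
    def pulses(self) -> list[RFPulse]:
        """All pulses of the train in temporal order."""
        return list(self.block.pulses) * self.n_blocks


def build_optimized_block(trp: float = 30.0, *, selective: bool = False,
                          pulse_duration: float = 1.0,
                          time_bandwidth: float = 16.0) -> SequenceBlock:
    """Build the optimized 4-pulse block (30x, 175y, 30y, 175x).

    Parameters
    ----------
    trp:
        Inter-pulse repetition time in ms (must be positive).
    selective:
        If True, pulses are slab-selective windowed-sinc pulses of
        ``pulse_duration`` ms with the given time-bandwidth product;
        otherwise instantaneous non-selective rotations.
    """
    if trp <= 0:
        raise ValueError("trp must be positive")
    dur = pulse_duration if selective else 0.0
    pulses = tuple(
        RFPulse(flip_angle=fa, phase_axis=ph, duration=dur,
                selective=selective, time_bandwidth=time_bandwidth)
        for fa, ph in zip(BLOCK_FLIP_DEG, BLOCK_PHASE_DEG)
    )
    return SequenceBlock(pulses=pulses, trp=trp)


def build_pulse_train(block: SequenceBlock, n_blocks: int = 12,
                      delay: float = 3000.0,
                      readout_start_offset: float = 2.0) -> PulseTrain:
    """Assemble a pulse train of ``n_blocks`` repetitions plus delay (ms)."""
    return PulseTrain(block=block, n_blocks=n_blocks,
                      inter_train_delay=delay,
                      readout_start_offset=readout_start_offset)


def dead_time_fraction(train: PulseTrain) -> float:
    """Fraction of the repetition spent in the recovery delay, in [0, 1).

    delay / (train duration + delay); with the 12-block train at TRp 30 ms
    and 3000 ms delay this is 3000/4440, i.e. about 67%.
    """
    total = train.train_duration_ms + train.inter_train_delay
    return train.inter_train_delay / total
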