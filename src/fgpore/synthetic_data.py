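"""Synthetic generators standing in for the wet-lab instruments.

Every generator returns its ground truth alongside the data so that each
downstream analysis stage has a recovery test:

* patch-clamp-like current traces: a flat baseline with Poisson-placed
  trapezoidal blockade dips (log-normal dwell times, truncated-normal
  blockade amplitudes) plus white and 1/f noise;
* parametric axisymmetric protein-density fields (uniform, centre-peaked,
  ring-shaped) emulating the characteristic in-pore distributions of
  cohesive wildtype FG domains, their hydrophilic SG mutants, and
  collapsed ring-forming FG domains respectively;
* random test chains with controlled charged/hydrophobic composition.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .density_analysis import DensityGrid3D
from .sequences import ProteinSequence
from .trace_analysis import CurrentTrace, Event


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given linear mean and sd."""
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


@dataclass
class TraceSpec:
    """Statistical description of a synthetic current trace.

    Defaults emulate a bare ~50 nm pore at 100 mV with transport-receptor
    translocations: 1.7 events/s, dwell times log-normal with linear mean
    0.29 ms and sd 0.16 ms, blockades 0.22 +- 0.07 nS.
    """

    duration: float = 60.0          # s
    sampling_rate: float = 50000.0  # Hz
    baseline: float = 7.0           # nA
    voltage: float = 100.0          # mV
    event_rate: float = 1.7         # Hz (Poisson)
    dwell_mean: float = 0.29e-3     # s
    dwell_sd: float = 0.16e-3       # s
    blockade_mean: float = 0.22     # nS
    blockade_sd: float = 0.07       # nS
    white_noise_sd: float = 0.003   # nA
    pink_amplitude: float = 0.0     # nA^2 at 1 Hz (0 disables 1/f noise)
    pink_exponent: float = 1.0
    seed: int = 0


def gen_trace(spec: TraceSpec) -> tuple[CurrentTrace, list[Event]]:
    """Synthesize a current trace; returns (trace, ground-truth events).

    Events are trapezoidal dips with 2-sample rising/falling edges placed
    at Poisson times; overlapping placements are rejected (a warning is
    issued if the requested occupancy makes that impossible to respect).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration * spec.sampling_rate)
    dt = 1.0 / spec.sampling_rate
    if spec.event_rate * spec.dwell_mean > 0.5:
        warnings.warn("event occupancy above 0.5: events will overlap heavily")
    current = np.full(n, spec.baseline)
    mu, s = lognormal_params(spec.dwell_mean, spec.dwell_sd) if spec.dwell_sd > 0 \
        else (math.log(spec.dwell_mean), 0.0)
    n_events = rng.poisson(spec.event_rate * spec.duration)
    starts = np.sort(rng.uniform(0.0, spec.duration, size=n_events))
    truth: list[Event] = []
    last_end = -math.inf
    v_volts = abs(spec.voltage) / 1000.0
    for t0 in starts:
        dwell = float(rng.lognormal(mu, s))
        if t0 <= last_end:  # reject overlap
            continue
        dg = 0.0
        while dg <= 0.0:
            dg = rng.normal(spec.blockade_mean, spec.blockade_sd)
        depth = dg * v_volts
        i0 = int(t0 * spec.sampling_rate)
        width = max(3, int(round(dwell / dt)))
        i1 = min(i0 + width, n)
        if i1 - i0 < 3:
            continue
        profile = np.full(i1 - i0, depth)
        profile[0] *= 0.5   # 2-sample edges
        profile[-1] *= 0.5
        current[i0:i1] -= profile
        truth.append(Event(start=t0, dwell=width * dt, blockade=dg, amplitude=depth))
        last_end = t0 + dwell + 2 * dt
    current += rng.normal(0.0, spec.white_noise_sd, size=n)
    if spec.pink_amplitude > 0:
        current += _pink_noise(n, spec.sampling_rate, spec.pink_amplitude,
                               spec.pink_exponent, rng)
    return CurrentTrace(current=current, sampling_rate=spec.sampling_rate,
                        voltage=spec.voltage), truth


def _pink_noise(n: int, fs: float, amplitude: float, alpha: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha noise by spectral shaping of white noise.

    ``amplitude`` is the one-sided PSD at 1 Hz in nA^2/Hz.
    """
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    # white noise of unit variance has one-sided PSD 2/fs; rescale to the
    # requested PSD amplitude at 1 Hz
    scale = math.sqrt(amplitude * fs / 2.0)
    return np.fft.irfft(spec * shape, n=n) * scale


@dataclass
class DensityFieldSpec:
    """Axisymmetric density family inside a pore cylinder.

    family "uniform": constant amplitude for r < R (SG-mutant-like);
    "center_peaked": wings + (peak - wings) * exp(-r^2 / 2 s^2) (wildtype-
    like, maximum on the axis); "ring": peak * exp(-(r-r0)^2 / 2 w^2)
    (collapsed, donut-like FG domains with an open central conduit).
    """

    family: str = "uniform"
    amplitude: float = 50.0        # mg/ml (peak value)
    wings: float = 70.0            # mg/ml, centre-peaked background
    peak_width: float = 8.0        # nm, Gaussian width of the centre peak
    ring_radius: float = 9.0       # nm
    ring_width: float = 3.0        # nm
    pore_diameter: float = 45.0    # nm
    pore_height: float = 20.0      # nm
    box: tuple[float, float, float] = (60.0, 60.0, 100.0)
    cell: float = 0.5


def density_profile_function(spec: DensityFieldSpec):
    """The generating radial profile rho(r) of the family (mg/ml)."""
    if spec.amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    R = spec.pore_diameter / 2.0

    if spec.family == "uniform":
        def rho(r):
            return np.where(r <= R, spec.amplitude, 0.0)
    elif spec.family == "center_peaked":
        def rho(r):
            val = spec.wings + (spec.amplitude - spec.wings) * np.exp(
                -(r**2) / (2.0 * spec.peak_width**2))
            return np.where(r <= R, val, 0.0)
    elif spec.family == "ring":
        def rho(r):
            val = spec.amplitude * np.exp(
                -((r - spec.ring_radius) ** 2) / (2.0 * spec.ring_width**2))
            return np.where(r <= R, val, 0.0)
    else:
        raise ValueError(f"unknown density family {spec.family!r}")
    return rho


def gen_density(spec: DensityFieldSpec) -> DensityGrid3D:
    """Realize the family on a (0.5 nm)^3 grid, nonzero for |z| < height/2."""
    rho = density_profile_function(spec)
    half = np.asarray(spec.box) / 2.0
    edges = tuple(np.arange(-h, h + spec.cell / 2, spec.cell) for h in half)
    centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
    rr = np.hypot(centers[0][:, None], centers[1][None, :])
    in_z = np.abs(centers[2]) < spec.pore_height / 2.0
    grid = rho(rr)[:, :, None] * in_z[None, None, :]
    return DensityGrid3D(edges=edges, density=grid, n_frames=1, cell=spec.cell)


_COMPOSITION_PRESETS = {
    "all_serine": {"S": 1.0},
    "neutral_zwitterion": {"K": 0.5, "E": 0.5},
    "fg_like": {"F": 0.15, "G": 0.3, "S": 0.25, "N": 0.15, "K": 0.08, "E": 0.07},
}


def gen_test_chain(
    n_beads: int,
    recipe: dict[str, float] | str = "fg_like",
    seed: int = 0,
) -> ProteinSequence:
    """Random sequence with the given residue-frequency recipe."""
    if n_beads < 2:
        raise ValueError("need at least two beads")
    if isinstance(recipe, str):
        recipe = _COMPOSITION_PRESETS[recipe]
    codes = sorted(recipe)
    fracs = np.array([recipe[c] for c in codes], float)
    if np.any(fracs < 0) or not math.isclose(fracs.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("recipe fractions must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(codes, size=n_beads, p=fracs / fracs.sum()))
    return ProteinSequence(id=f"synthetic-{n_beads}", residues=residues)
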