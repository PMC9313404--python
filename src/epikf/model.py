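"""Wendling-type neural mass model of hippocampal electrical activity.

The model lumps four interacting neuron populations — pyramidal cells, an
excitatory interneuron loop, slow (GABA_A,slow) and fast (GABA_A,fast)
inhibitory interneurons — each represented by a second-order synaptic
transfer function plus a sigmoidal wave-to-pulse conversion.  The balance
between the slow inhibitory gain ``B`` and the excitatory gain ``A``
controls the dynamical regime: low ``B/A`` produces fast low-amplitude
epileptiform oscillation, intermediate ratios sustain limit cycles
(rhythmic spiking), and high ratios give noise-driven background activity.

Two outputs are produced by :func:`simulate`:

``z(t) = x2 - x3 - x4``
    the summed postsynaptic potential of the pyramidal population,
    with its DC component intact;
``y(t) = C_S * x11``
    ``z`` passed through the first-order high-pass stage ``s / (s + 0.5)``
    that mimics the AC coupling of a conventional EEG recorder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SigmoidParameters",
    "ModelParameters",
    "Segment",
    "TypePreset",
    "sigmoid",
    "model_derivatives",
    "simulate",
    "generate_type_set",
    "default_presets",
    "three_band_presets",
    "N_MODEL_STATES",
]

N_MODEL_STATES = 11


@dataclass(frozen=True)
class SigmoidParameters:
    """Wave-to-pulse sigmoid S(v) = 2*e_s / (1 + exp(h_s*(v_s - v))).

    e_s : half-maximum firing rate (s^-1)
    h_s : steepness at the inflection point (mV^-1)
    v_s : half-activation postsynaptic potential (mV)
    """

    e_s: float = 2.5
    h_s: float = 0.56
    v_s: float = 6.0

    def __post_init__(self) -> None:
        if not (self.e_s > 0 and self.h_s > 0):
            raise ValueError("sigmoid constants e_s and h_s must be positive")


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the neural mass model.

    Defaults are the standard parameterization of the Wendling hippocampal
    model: synaptic gains in mV, reciprocal time constants in s^-1,
    dimensionless connectivity constants C1..C7 expressed as fractions of
    C = 135.  ``input_mean``/``input_sd`` give the law of the stochastic
    afferent pulse density u1 (s^-1).  ``A`` and ``B`` are the two gains
    adjusted to move the network between normal and epileptiform regimes.
    """

    A: float = 5.0
    B: float = 15.0
    G: float = 10.0
    a: float = 100.0
    b: float = 50.0
    g: float = 500.0
    C1: float = 135.0
    C2: float = 108.0
    C3: float = 33.75
    C4: float = 33.75
    C5: float = 40.5
    C6: float = 13.5
    C7: float = 108.0
    C_S: float = 1.0
    sigmoid: SigmoidParameters = field(default_factory=SigmoidParameters)
    input_mean: float = 90.0
    input_sd: float = 30.0

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.G) < 0:
            raise ValueError("synaptic gains A, B, G must be non-negative")
        if min(self.a, self.b, self.g) <= 0:
            raise ValueError("time constants a, b, g must be positive")
        if min(self.C1, self.C2, self.C3, self.C4, self.C5, self.C6, self.C7) < 0:
            raise ValueError("connectivity constants must be non-negative")
        if self.input_sd < 0:
            raise ValueError("input_sd must be non-negative")

    def with_gains(self, A: float | None = None, B: float | None = None) -> "ModelParameters":
        """Copy with the excitatory and/or slow-inhibitory gain replaced."""
        kwargs = {}
        if A is not None:
            kwargs["A"] = A
        if B is not None:
            kwargs["B"] = B
        return replace(self, **kwargs)

    @property
    def ratio(self) -> float:
        """Inhibition/excitation ratio B/A."""
        return self.B / self.A


@dataclass
class Segment:
    """A fixed-rate window of signal: model output, simulated EEG or recording."""

    samples: np.ndarray
    fs: float
    kind: str = "z"  # one of {"z", "y", "recorded"}
    label: str = "unknown"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.kind not in ("z", "y", "recorded"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class TypePreset:
    """(A, B) gain combination generating one activity type."""

    label: str
    A: float
    B: float

    @property
    def ratio(self) -> float:
        return self.B / self.A


#: Canonical B/A ratios of the five activity regimes.  Type I sits just
#: above the Hopf point (fast oscillation), II and III inside the
#: limit-cycle range, IV slightly above the saddle-node fold (irregular
#: escape spiking), Normal well beyond it (noise-driven fluctuation about
#: the stable node).
TYPE_RATIOS: dict[str, float] = {
    "I": 3.0,
    "II": 4.0,
    "III": 6.0,
    "IV": 8.0,
    "Normal": 10.0,
}


def default_presets(A: float = 5.0) -> list[TypePreset]:
    """The five activity-type presets at a single excitatory gain."""
    return [TypePreset(label, A, ratio * A) for label, ratio in TYPE_RATIOS.items()]


def three_band_presets(A_values: Sequence[float] = (4.0, 5.0, 6.0)) -> list[TypePreset]:
    """Presets replicated across several A values (three amplitude bands)."""
    return [p for A in A_values for p in default_presets(A)]


def sigmoid(v, p: SigmoidParameters):
    """Population wave-to-pulse conversion; strictly increasing, in (0, 2*e_s)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid input must be finite")
    out = 2.0 * p.e_s / (1.0 + np.exp(p.h_s * (p.v_s - v)))
    return out if out.ndim else float(out)


def model_derivatives(x: np.ndarray, u1: float, p: ModelParameters) -> np.ndarray:
    """Right-hand side of the 11-state model.

    States x1..x5 are postsynaptic potentials (mV), x6..x10 their time
    derivatives, and x11 the state of the EEG-recorder high-pass stage
    s/(s+0.5) applied to z = x2-x3-x4 (realized in derivative form, driven
    by x7-x8-x9).  The fast interneurons receive pyramidal excitation and
    slow inhibition, C5*x1 - C6*x5.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != N_MODEL_STATES:
        raise ValueError(f"expected {N_MODEL_STATES} states, got {x.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.isfinite(u1)):
        raise ValueError("model_derivatives requires finite inputs")
    s = p.sigmoid
    S = lambda v: 2.0 * s.e_s / (1.0 + np.exp(s.h_s * (s.v_s - v)))
    x1, x2, x3, x4, x5, x6, x7, x8, x9, x10, x11 = x
    A, B, G, a, b, g = p.A, p.B, p.G, p.a, p.b, p.g
    dx = np.empty(N_MODEL_STATES)
    dx[0] = x6
    dx[1] = x7
    dx[2] = x8
    dx[3] = x9
    dx[4] = x10
    dx[5] = A * a * S(x2 - x3 - x4) - 2 * a * x6 - a * a * x1
    dx[6] = A * a * (u1 + p.C2 * S(p.C1 * x1)) - 2 * a * x7 - a * a * x2
    dx[7] = B * b * p.C4 * S(p.C3 * x1) - 2 * b * x8 - b * b * x3
    dx[8] = G * g * p.C7 * S(p.C5 * x1 - p.C6 * x5) - 2 * g * x9 - g * g * x4
    dx[9] = B * b * S(p.C3 * x1) - 2 * b * x10 - b * b * x5
    dx[10] = -0.5 * x11 + (x7 - x8 - x9)
    return dx


class IntegrationError(RuntimeError):
    """Raised when a trajectory leaves the configured amplitude bound."""


def simulate(
    p: ModelParameters,
    duration: float,
    fs: float = 480.0,
    seed: int | None = None,
    *,
    burn_in: float = 2.0,
    internal_fs: float = 4800.0,
    x0: np.ndarray | None = None,
    divergence_bound: float = 1e6,
    u_path: np.ndarray | None = None,
) -> tuple[Segment, Segment]:
    """Integrate the model and return the (z, y) segment pair.

    Stochastic Euler integration at ``internal_fs`` with per-step
    independent Gaussian draws of the afferent input u1; the trajectory is
    decimated to ``fs`` and a burn-in interval is discarded so transients
    from the initial condition do not contaminate the returned window.
    Identical seeds give bit-identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 480:
        raise ValueError("sampling rate must be at least 480 Hz")
    decim = internal_fs / fs
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError("internal_fs must be an integer multiple of fs")
    decim = int(round(decim))

    n_out = int(round(duration * fs))
    n_burn = int(round(burn_in * internal_fs))
    n_steps = n_burn + n_out * decim
    dt = 1.0 / internal_fs

    if u_path is not None:
        u = np.asarray(u_path, dtype=float)
        if u.shape != (n_steps,):
            raise ValueError(f"u_path must have {n_steps} entries, got {u.shape}")
    elif p.input_sd > 0:
        rng = np.random.default_rng(seed)
        u = rng.normal(p.input_mean, p.input_sd, size=n_steps)
    else:
        u = np.full(n_steps, p.input_mean)

    s = p.sigmoid
    two_e, h, v0 = 2.0 * s.e_s, s.h_s, s.v_s
    A, B, G, a, b, g = p.A, p.B, p.G, p.a, p.b, p.g
    C1, C2, C3, C4, C5, C6, C7 = p.C1, p.C2, p.C3, p.C4, p.C5, p.C6, p.C7
    exp = math.exp

    if x0 is None:
        st = [0.0] * N_MODEL_STATES
    else:
        st = [float(v) for v in np.asarray(x0, dtype=float)]
        if len(st) != N_MODEL_STATES:
            raise ValueError(f"x0 must have {N_MODEL_STATES} components")
    x1, x2, x3, x4, x5, x6, x7, x8, x9, x10, x11 = st

    z_out = np.empty(n_out)
    y_out = np.empty(n_out)
    bound = divergence_bound
    j = 0
    for k in range(n_steps):
        v = x2 - x3 - x4
        S_v = two_e / (1.0 + exp(h * (v0 - v)))
        S_1 = two_e / (1.0 + exp(h * (v0 - C1 * x1)))
        S_3 = two_e / (1.0 + exp(h * (v0 - C3 * x1)))
        S_f = two_e / (1.0 + exp(h * (v0 - (C5 * x1 - C6 * x5))))
        d6 = A * a * S_v - 2 * a * x6 - a * a * x1
        d7 = A * a * (u[k] + C2 * S_1) - 2 * a * x7 - a * a * x2
        d8 = B * b * C4 * S_3 - 2 * b * x8 - b * b * x3
        d9 = G * g * C7 * S_f - 2 * g * x9 - g * g * x4
        d10 = B * b * S_3 - 2 * b * x10 - b * b * x5
        d11 = -0.5 * x11 + (x7 - x8 - x9)
        x1 += dt * x6
        x2 += dt * x7
        x3 += dt * x8
        x4 += dt * x9
        x5 += dt * x10
        x6 += dt * d6
        x7 += dt * d7
        x8 += dt * d8
        x9 += dt * d9
        x10 += dt * d10
        x11 += dt * d11
        if abs(x2) > bound or abs(x3) > bound or abs(x4) > bound or abs(x11) > bound:
            raise IntegrationError(
                f"trajectory exceeded |x| = {bound:g} at step {k} "
                f"(t = {k * dt:.4f} s); check parameters"
            )
        kk = k + 1 - n_burn
        if kk > 0 and kk % decim == 0:
            z_out[j] = x2 - x3 - x4
            y_out[j] = p.C_S * x11
            j += 1

    label = "unknown"
    z = Segment(z_out, fs, kind="z", label=label, seed=seed)
    y = Segment(y_out, fs, kind="y", label=label, seed=seed)
    return z, y


def _segment_seed(master_seed: int, preset_index: int, segment_index: int) -> int:
    """Deterministic per-segment seed stream, kept within 32 bits."""
    mix = np.random.SeedSequence([master_seed, preset_index, segment_index])
    return int(mix.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def generate_type_set(
    presets: Sequence[TypePreset],
    n_segments: int,
    duration: float = 5.0,
    fs: float = 480.0,
    seed: int = 0,
    *,
    base: ModelParameters | None = None,
    **simulate_kwargs,
) -> list[tuple[Segment, Segment]]:
    """Generate ``n_segments`` labelled (z, y) pairs per preset.

    Each pair gets its own reproducible seed derived from the master seed,
    the preset index and the segment index, so any single segment can be
    regenerated in isolation.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be at least 1")
    base = base if base is not None else ModelParameters()
    out: list[tuple[Segment, Segment]] = []
    for pi, preset in enumerate(presets):
        p = base.with_gains(A=preset.A, B=preset.B)
        for si in range(n_segments):
            sseed = _segment_seed(seed, pi, si)
            try:
                z, y = simulate(p, duration, fs, sseed, **simulate_kwargs)
            except IntegrationError as err:
                raise IntegrationError(
                    f"preset {preset.label!r} segment {si}: {err}"
                ) from err
            z.label = y.label = preset.label
            out.append((z, y))
    return out
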