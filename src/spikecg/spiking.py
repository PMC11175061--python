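"""Discrete-time leaky integrate-and-fire (LIF) dynamics and spike encoding.

The discrete neuron follows

    U_j(t) = lambda * U_j(t-1) + sum_i w_ij s_i(t)

with a *strict* threshold test ``U_j(t) > V_th`` producing a binary spike,
after which the membrane is reset (to ``V_r`` by default, or by threshold
subtraction) and an optional refractory countdown holds the membrane
constant and suppresses output.  The continuous reference model

    tau dU/dt = -U + R I(t)

is integrated by forward Euler and matches the discrete update under
``lambda = 1 - dt/tau`` with drive ``(dt/tau) * R * I`` on subthreshold
inputs; this equivalence is exercised in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "LIFParams",
    "LIFState",
    "SpikeTensor",
    "lif_step",
    "lif_run",
    "lif_continuous",
    "encode_segment",
    "surrogate_gradient",
]


@dataclass(frozen=True)
class LIFParams:
    """LIF neuron constants.

    ``leak_lambda`` is the per-step membrane retention factor (1 keeps a pure
    integrator); ``v_threshold``/``v_reset`` are in membrane-potential units;
    ``refractory_steps`` counts timesteps of post-spike lockout.  ``tau`` and
    ``input_resistance`` parameterize the continuous reference model only.
    ``reset_mode`` is ``"to_rest"`` (membrane := v_reset, the default) or
    ``"subtract"`` (membrane -= v_threshold, used for rate-faithful
    ANN-converted networks).
    """

    leak_lambda: float = 0.9
    v_threshold: float = 1.0
    v_reset: float = 0.0
    refractory_steps: int = 0
    tau: float = 0.02
    input_resistance: float = 1.0
    reset_mode: str = "to_rest"

    def __post_init__(self) -> None:
        if not 0.0 < self.leak_lambda <= 1.0:
            raise ValueError("leak_lambda must be in (0, 1]")
        if self.v_threshold <= self.v_reset:
            raise ValueError("v_threshold must exceed v_reset")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be >= 0")
        if self.reset_mode not in {"to_rest", "subtract"}:
            raise ValueError("reset_mode must be 'to_rest' or 'subtract'")


@dataclass
class LIFState:
    """Per-neuron dynamic state: membrane potential and refractory countdown."""

    membrane: np.ndarray
    refractory_remaining: np.ndarray

    @classmethod
    def zeros(cls, n_neurons: int, v_init: float = 0.0) -> "LIFState":
        return cls(
            membrane=np.full(n_neurons, float(v_init)),
            refractory_remaining=np.zeros(n_neurons, dtype=int),
        )


@dataclass
class SpikeTensor:
    """Binary spike activity over (timesteps, neurons)."""

    values: np.ndarray
    timestep_count: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("spike values must be binary")

    def rates(self) -> np.ndarray:
        """Per-neuron firing rate (spikes per timestep)."""
        return self.values.mean(axis=0)


def lif_step(
    state: LIFState, drive: np.ndarray, params: LIFParams
) -> tuple[LIFState, np.ndarray]:
    """Advance every neuron one timestep.

    Non-refractory neurons leak and integrate the drive; a neuron spikes iff
    its membrane strictly exceeds ``v_threshold``, is then reset and enters
    the refractory period.  Refractory neurons hold their membrane constant,
    emit no spike and count down.
    """
    drive = np.asarray(drive, dtype=float)
    if not np.all(np.isfinite(drive)):
        raise ValueError("drive must be finite")
    membrane = state.membrane.copy()
    refractory = state.refractory_remaining.copy()

    active = refractory <= 0
    membrane[active] = params.leak_lambda * membrane[active] + drive[active]
    spikes = np.zeros_like(membrane)
    fired = active & (membrane > params.v_threshold)
    spikes[fired] = 1.0
    if params.reset_mode == "subtract":
        membrane[fired] -= params.v_threshold
    else:
        membrane[fired] = params.v_reset
    refractory[fired] = params.refractory_steps
    refractory[~active] -= 1
    return LIFState(membrane=membrane, refractory_remaining=refractory), spikes


def lif_run(
    drive_sequence: np.ndarray,
    params: LIFParams,
    initial: LIFState | None = None,
) -> tuple[SpikeTensor, np.ndarray]:
    """Iterate :func:`lif_step` over a (T, n_neurons) drive sequence.

    Returns the full spike raster and the membrane trace recorded *after*
    each step (post-reset).
    """
    drive_sequence = np.atleast_2d(np.asarray(drive_sequence, dtype=float))
    T, n = drive_sequence.shape
    if T < 1:
        raise ValueError("drive sequence must contain at least one timestep")
    state = initial if initial is not None else LIFState.zeros(n)
    spikes = np.zeros((T, n))
    trace = np.zeros((T, n))
    for t in range(T):
        state, s = lif_step(state, drive_sequence[t], params)
        spikes[t] = s
        trace[t] = state.membrane
    return SpikeTensor(values=spikes, timestep_count=T), trace


def lif_continuous(
    drive_fn: Callable[[float], float | np.ndarray],
    params: LIFParams,
    horizon: float,
    dt: float,
    u0: float | np.ndarray = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler integration of ``tau dU/dt = -U + R I(t)`` (no spiking).

    Serves as the continuous reference against which the discrete update with
    ``lambda = 1 - dt/tau`` is validated.  Returns (times, membrane trace)
    with the trace sampled *after* each Euler step.
    """
    if dt >= params.tau / 10.0:
        raise ValueError("dt must be smaller than tau/10 for a faithful Euler step")
    n_steps = int(round(horizon / dt))
    u = np.asarray(u0, dtype=float)
    times = np.empty(n_steps)
    trace_list = []
    for k in range(n_steps):
        t = k * dt
        i_t = np.asarray(drive_fn(t), dtype=float)
        u = u + (dt / params.tau) * (-u + params.input_resistance * i_t)
        times[k] = (k + 1) * dt
        trace_list.append(np.array(u, copy=True))
    return times, np.squeeze(np.stack(trace_list)) if trace_list else np.empty(0)


def encode_segment(
    samples: np.ndarray,
    T: int,
    scheme: str = "direct",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Turn an analog beat segment into the T-timestep drive of the network.

    ``direct`` repeats the analog vector as constant drive at every timestep
    (the first spiking layer performs the analog-to-spike conversion);
    ``rate`` emits seeded Bernoulli spikes with probability equal to the
    min-max-normalized sample value.
    """
    x = np.asarray(samples, dtype=float)
    if T < 1:
        raise ValueError("T must be >= 1")
    if scheme == "direct":
        return np.tile(x, (T, 1))
    if scheme == "rate":
        lo, hi = x.min(), x.max()
        p = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("rate coding requires normalized values in [0, 1]")
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        return (gen.random((T, x.size)) < p).astype(float)
    raise ValueError(f"unknown encoding scheme {scheme!r}")


def surrogate_gradient(
    u: np.ndarray, v_threshold: float, kind: str = "arctan", alpha: float = 2.0
) -> np.ndarray:
    """Pseudo-derivative of the spike Heaviside used for backpropagation.

    ``arctan``: d/du [ (1/pi) arctan(pi/2 * alpha * (u - V_th)) + 1/2 ];
    ``rectangular``: a box of width ``1/alpha`` and height ``alpha`` centred
    on the threshold.
    """
    x = np.asarray(u, dtype=float) - v_threshold
    if kind == "arctan":
        return alpha / (2.0 * (1.0 + (np.pi / 2.0 * alpha * x) ** 2))
    if kind == "rectangular":
        return alpha * (np.abs(x) < 0.5 / alpha)
    raise ValueError(f"unknown surrogate kind {kind!r}")
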