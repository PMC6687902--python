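"""Canonical-microcircuit network model of the frontoparietal attention system.

Each cortical source is a canonical microcircuit (CMC) of four neuronal
populations — spiny stellate cells, superficial pyramidal cells, inhibitory
interneurons and deep pyramidal cells — each described by a damped
second-order synaptic convolution (voltage/conductance pair).  Sources are
coupled by laminar-specific extrinsic connections: ascending (forward)
connections arise from superficial pyramidal cells and target spiny stellate
and deep pyramidal populations of the higher source; descending (backward)
connections arise from deep pyramidal cells and inhibit superficial pyramidal
and inhibitory-interneuron populations of the lower source.

All connection strengths are parameterised by log-scaling parameters: the
effective gain of a connection is its fixed template strength times
``exp(scaling)``, so gains are strictly positive and an excitatory connection
can never become inhibitory (nor vice versa).  Condition-specific effects
enter as additional log-slopes ``b`` on a designated subset of extrinsic
edges, multiplied by a per-condition covariate.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Population",
    "NetworkSpec",
    "ModelParameters",
    "EffectiveGains",
    "build_attention_network",
    "effective_gains",
    "firing_rate",
    "cmc_flow",
    "flow_matrices",
    "linearized_jacobian",
    "voltage_indices",
    "conductance_indices",
    "state_index",
    "parameter_names",
    "apply_parameter_vector",
    "N_POPULATIONS",
    "STATES_PER_SOURCE",
    "KAPPA_TEMPLATE",
    "INTRINSIC_TEMPLATE",
    "INTRINSIC_CLASS",
    "FORWARD_TEMPLATE",
    "BACKWARD_TEMPLATE",
    "INPUT_TEMPLATE",
    "INTRINSIC_CLASSES",
]


class Population(enum.IntEnum):
    """The four CMC populations; integer value is the within-source index."""

    SPINY_STELLATE = 0
    SUPERFICIAL_PYRAMIDAL = 1
    INHIBITORY_INTERNEURON = 2
    DEEP_PYRAMIDAL = 3

    @property
    def label(self) -> str:
        return self.name.lower()


N_POPULATIONS = 4
# Per source: 4 populations x (voltage, conductance).  Using the 1-based
# subscript convention, odd subscripts (x1, x3, ...) are voltages and even
# subscripts conductances; in 0-based array indexing voltages sit at even
# offsets 0, 2, 4, 6 and conductances at 1, 3, 5, 7.
STATES_PER_SOURCE = 2 * N_POPULATIONS

# --- connectivity templates -------------------------------------------------
#
# Prior-mean (template) strengths.  Rate constants kappa are per-population
# inverse time constants in s^-1 (time constants 4, 8, 16, 31 ms), giving
# sub-100 ms impulse-response peaks per population.  Connection templates are
# in units of mV per unit presynaptic firing; the DC transfer of a pathway is
# template / kappa_target, kept of order one so that activity propagates
# across the hierarchy without blowing up.
KAPPA_TEMPLATE = np.array([256.0, 128.0, 64.0, 32.0])  # ss, sp, ii, dp

# Intrinsic (within-source) wiring, rows = target population, cols = source
# population.  Wiring set: recurrent self-inhibition on every population;
# stellate excitation of both pyramidal populations and of interneurons;
# interneuron inhibition of both pyramidal populations.  The intrinsic graph
# (ignoring self-loops) is feed-forward, which keeps each source
# unconditionally stable at the template parameters.
_SS, _SP, _II, _DP = range(4)
INTRINSIC_TEMPLATE = np.zeros((4, 4))
INTRINSIC_TEMPLATE[_SS, _SS] = -128.0
INTRINSIC_TEMPLATE[_SP, _SP] = -64.0
INTRINSIC_TEMPLATE[_II, _II] = -32.0
INTRINSIC_TEMPLATE[_DP, _DP] = -16.0
INTRINSIC_TEMPLATE[_SP, _SS] = +128.0
INTRINSIC_TEMPLATE[_II, _SS] = +64.0
INTRINSIC_TEMPLATE[_DP, _SS] = +32.0
INTRINSIC_TEMPLATE[_SP, _II] = -64.0
INTRINSIC_TEMPLATE[_DP, _II] = -16.0

INTRINSIC_CLASSES = ("self", "excitatory", "inhibitory")
# class index per nonzero intrinsic entry: diagonal -> self, stellate
# efferents -> excitatory, interneuron efferents -> inhibitory
INTRINSIC_CLASS = np.full((4, 4), -1)
for _t in range(4):
    INTRINSIC_CLASS[_t, _t] = 0
for _t in (_SP, _II, _DP):
    INTRINSIC_CLASS[_t, _SS] = 1
for _t in (_SP, _DP):
    INTRINSIC_CLASS[_t, _II] = 2
INTRINSIC_CLASS[_SS, _SS] = 0

# Extrinsic sub-pathway templates per edge (positive magnitudes; descending
# pathways enter the flow with a minus sign).  Forward: superficial pyramidal
# -> spiny stellate (A1) and -> deep pyramidal (A2) of the higher source.
# Backward: deep pyramidal -> superficial pyramidal (A3) and -> inhibitory
# interneurons (A4) of the lower source.
FORWARD_TEMPLATE = np.array([256.0, 64.0])  # (A1, A2)
BACKWARD_TEMPLATE = np.array([64.0, 32.0])  # (A3, A4)

# Exogenous (geniculate-like) drive template onto spiny stellate cells.
INPUT_TEMPLATE = 128.0


# --- network specification ---------------------------------------------------


Edge = tuple[str, str]


@dataclass(frozen=True)
class NetworkSpec:
    """Sources, typed extrinsic edges, input targets, modulation mask, design.

    ``modulated_edges`` is an ordered tuple; its order defines the effect
    numbering used everywhere (effect 1 is ``modulated_edges[0]``).
    ``design`` holds one covariate value per experimental condition; the
    log-slope ``b`` of a modulated edge multiplies this covariate, so a
    design of ``[0, 1]`` is a baseline/modulated contrast and ``[0..15]`` a
    linear parametric effect over events.
    """

    sources: tuple[str, ...]
    forward_edges: tuple[Edge, ...]
    backward_edges: tuple[Edge, ...]
    input_targets: tuple[str, ...]
    modulated_edges: tuple[Edge, ...]
    design: tuple[float, ...] = (0.0, 1.0)
    condition_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.sources)) != len(self.sources):
            raise ValueError("duplicate source labels")
        fwd, bwd = set(self.forward_edges), set(self.backward_edges)
        if fwd & bwd:
            raise ValueError("forward and backward edge sets must be disjoint")
        for u, v in fwd | bwd:
            if u not in self.sources or v not in self.sources:
                raise ValueError(f"edge ({u}, {v}) references unknown source")
        if not set(self.modulated_edges) <= (fwd | bwd):
            raise ValueError("modulated edges must be existing extrinsic edges")
        if not set(self.input_targets) <= set(self.sources):
            raise ValueError("input targets must be sources")
        if self.condition_labels is not None and len(self.condition_labels) != len(self.design):
            raise ValueError("condition_labels length must match design")

    # -- sizes and indexing
    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_states(self) -> int:
        return STATES_PER_SOURCE * self.n_sources

    @property
    def n_conditions(self) -> int:
        return len(self.design)

    @property
    def labels(self) -> tuple[str, ...]:
        if self.condition_labels is not None:
            return self.condition_labels
        return tuple(f"condition_{i}" for i in range(self.n_conditions))

    def source_index(self, label: str) -> int:
        return self.sources.index(label)

    def covariate(self, condition_index: int) -> float:
        if not 0 <= condition_index < self.n_conditions:
            raise IndexError(
                f"condition index {condition_index} outside 0..{self.n_conditions - 1}"
            )
        return float(self.design[condition_index])

    def with_design(self, design: Sequence[float], labels: Sequence[str] | None = None) -> "NetworkSpec":
        return replace(
            self,
            design=tuple(float(x) for x in design),
            condition_labels=None if labels is None else tuple(labels),
        )

    # -- serialization (lossless YAML/JSON round trip)
    def to_dict(self) -> dict:
        return {
            "sources": list(self.sources),
            "forward_edges": [list(e) for e in self.forward_edges],
            "backward_edges": [list(e) for e in self.backward_edges],
            "input_targets": list(self.input_targets),
            "modulated_edges": [list(e) for e in self.modulated_edges],
            "design": list(self.design),
            "condition_labels": None if self.condition_labels is None else list(self.condition_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            sources=tuple(d["sources"]),
            forward_edges=tuple(tuple(e) for e in d["forward_edges"]),
            backward_edges=tuple(tuple(e) for e in d["backward_edges"]),
            input_targets=tuple(d["input_targets"]),
            modulated_edges=tuple(tuple(e) for e in d["modulated_edges"]),
            design=tuple(float(x) for x in d["design"]),
            condition_labels=None if d.get("condition_labels") is None else tuple(d["condition_labels"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_attention_network(design: Sequence[float] = (0.0, 1.0),
                            condition_labels: Sequence[str] | None = ("early", "late")) -> NetworkSpec:
    """The five-source dorsal/ventral attention network.

    Bilateral dorsal sources (FEF and IPS in each hemisphere) plus the right
    temporoparietal junction (rTPJ) representing the ventral network.  The
    rTPJ sits lower in the visual hierarchy than the FEFs, so rTPJ->FEF
    connections are forward and FEF->rTPJ backward; IPS->FEF is likewise
    treated as forward within the dorsal network.  The modulation mask is the
    four TPJ<->FEF edges, numbered 1: rTPJ->lFEF, 2: rTPJ->rFEF,
    3: lFEF->rTPJ, 4: rFEF->rTPJ.  Exogenous (visual) input drives the rTPJ
    and both IPS sources.
    """
    if condition_labels is not None and len(condition_labels) != len(design):
        condition_labels = None
    return NetworkSpec(
        sources=("lFEF", "rFEF", "lIPS", "rIPS", "rTPJ"),
        forward_edges=(("rTPJ", "lFEF"), ("rTPJ", "rFEF"),
                       ("lIPS", "lFEF"), ("rIPS", "rFEF")),
        backward_edges=(("lFEF", "rTPJ"), ("rFEF", "rTPJ"),
                        ("lFEF", "lIPS"), ("rFEF", "rIPS")),
        input_targets=("rTPJ", "lIPS", "rIPS"),
        modulated_edges=(("rTPJ", "lFEF"), ("rTPJ", "rFEF"),
                         ("lFEF", "rTPJ"), ("rFEF", "rTPJ")),
        design=tuple(float(x) for x in design),
        condition_labels=None if condition_labels is None else tuple(condition_labels),
    )


# --- parameters ---------------------------------------------------------------


def _default_lead_gain(n_channels: int, n_sources: int) -> np.ndarray:
    """Fixed synthetic lead field: documented constant, full row rank."""
    base = np.array(
        [
            [1.0, 0.5, -0.3, 0.2, 0.4],
            [-0.4, 1.0, 0.2, -0.3, 0.5],
            [0.3, -0.2, 1.0, 0.5, -0.4],
            [0.2, 0.3, -0.5, 1.0, 0.6],
        ]
    )
    if n_channels <= 4 and n_sources <= 5:
        return base[:n_channels, :n_sources].copy()
    # deterministic extension for non-default shapes
    rng = np.random.default_rng(12345)
    return rng.standard_normal((n_channels, n_sources)) * 0.5


@dataclass
class ModelParameters:
    """All model parameters; log-scalings default to zero (= template values).

    With every log-scaling at zero the effective connectivity equals the
    prior-mean template exactly.  ``b`` carries one log-slope per modulated
    edge (multiplying the per-condition covariate), ``g`` one log-scaling per
    intrinsic connection class, ``kappa`` one log-scaling per population's
    rate constant.  ``input_onset`` and ``input_dispersion`` are in seconds.
    """

    spec: NetworkSpec
    a_fwd: np.ndarray = None  # type: ignore[assignment]
    a_bwd: np.ndarray = None  # type: ignore[assignment]
    b: np.ndarray = None  # type: ignore[assignment]
    g: np.ndarray = None  # type: ignore[assignment]
    c: np.ndarray = None  # type: ignore[assignment]
    kappa: np.ndarray = None  # type: ignore[assignment]
    input_onset: float = 0.060
    input_dispersion: float = 0.016
    input_amplitude: float = 1.0
    lead_gain: np.ndarray = None  # type: ignore[assignment]
    log_noise_precision: float = 4.0
    n_channels: int = 4

    def __post_init__(self) -> None:
        s = self.spec
        if self.a_fwd is None:
            self.a_fwd = np.zeros(len(s.forward_edges))
        if self.a_bwd is None:
            self.a_bwd = np.zeros(len(s.backward_edges))
        if self.b is None:
            self.b = np.zeros(len(s.modulated_edges))
        if self.g is None:
            self.g = np.zeros(len(INTRINSIC_CLASSES))
        if self.c is None:
            self.c = np.zeros(len(s.input_targets))
        if self.kappa is None:
            self.kappa = np.zeros(N_POPULATIONS)
        if self.lead_gain is None:
            self.lead_gain = _default_lead_gain(self.n_channels, s.n_sources)
        self.a_fwd = np.asarray(self.a_fwd, dtype=float)
        self.a_bwd = np.asarray(self.a_bwd, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.lead_gain = np.asarray(self.lead_gain, dtype=float)
        if self.input_dispersion <= 0:
            raise ValueError("input_dispersion must be positive")
        _expect = {
            "a_fwd": len(s.forward_edges),
            "a_bwd": len(s.backward_edges),
            "b": len(s.modulated_edges),
            "g": len(INTRINSIC_CLASSES),
            "c": len(s.input_targets),
            "kappa": N_POPULATIONS,
        }
        for name, n in _expect.items():
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            spec=self.spec,
            a_fwd=self.a_fwd.copy(), a_bwd=self.a_bwd.copy(), b=self.b.copy(),
            g=self.g.copy(), c=self.c.copy(), kappa=self.kappa.copy(),
            input_onset=self.input_onset, input_dispersion=self.input_dispersion,
            input_amplitude=self.input_amplitude, lead_gain=self.lead_gain.copy(),
            log_noise_precision=self.log_noise_precision, n_channels=self.n_channels,
        )

    def rates(self) -> np.ndarray:
        """Effective per-population rate constants, s^-1."""
        return KAPPA_TEMPLATE * np.exp(self.kappa)

    # -- serialization
    def to_dict(self) -> dict:
        return {
            "a_fwd": self.a_fwd.tolist(), "a_bwd": self.a_bwd.tolist(),
            "b": self.b.tolist(), "g": self.g.tolist(), "c": self.c.tolist(),
            "kappa": self.kappa.tolist(),
            "input_onset": self.input_onset,
            "input_dispersion": self.input_dispersion,
            "input_amplitude": self.input_amplitude,
            "lead_gain": self.lead_gain.tolist(),
            "log_noise_precision": self.log_noise_precision,
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, spec: NetworkSpec, d: dict) -> "ModelParameters":
        return cls(
            spec=spec,
            a_fwd=np.array(d["a_fwd"]), a_bwd=np.array(d["a_bwd"]),
            b=np.array(d["b"]), g=np.array(d["g"]), c=np.array(d["c"]),
            kappa=np.array(d["kappa"]),
            input_onset=float(d["input_onset"]),
            input_dispersion=float(d["input_dispersion"]),
            input_amplitude=float(d.get("input_amplitude", 1.0)),
            lead_gain=np.array(d["lead_gain"]),
            log_noise_precision=float(d["log_noise_precision"]),
            n_channels=int(d["n_channels"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, spec: NetworkSpec, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(spec, json.load(fh))


# --- named parameter vector ---------------------------------------------------

# Default free set for inversion: extrinsic, modulatory, input-gain, intrinsic
# and rate-constant log-scalings.  Lead gains and input timing are held at
# their (known, synthetic) templates unless explicitly freed.
DEFAULT_FREE = ("a_fwd", "a_bwd", "b", "c", "g", "kappa")


def parameter_names(spec: NetworkSpec, free: Sequence[str] = DEFAULT_FREE) -> list[str]:
    """Ordered names for the free-parameter vector."""
    names: list[str] = []
    for block in free:
        if block == "a_fwd":
            names += [f"a_fwd[{u}->{v}]" for u, v in spec.forward_edges]
        elif block == "a_bwd":
            names += [f"a_bwd[{u}->{v}]" for u, v in spec.backward_edges]
        elif block == "b":
            names += [f"b[{i + 1}:{u}->{v}]" for i, (u, v) in enumerate(spec.modulated_edges)]
        elif block == "c":
            names += [f"c[{s}]" for s in spec.input_targets]
        elif block == "g":
            names += [f"g[{cls}]" for cls in INTRINSIC_CLASSES]
        elif block == "kappa":
            names += [f"kappa[{Population(i).label}]" for i in range(N_POPULATIONS)]
        elif block == "lead":
            names += ["lead_log_gain"]
        else:
            raise ValueError(f"unknown parameter block {block!r}")
    return names


def apply_parameter_vector(base: ModelParameters, theta: np.ndarray,
                           free: Sequence[str] = DEFAULT_FREE) -> ModelParameters:
    """Return a copy of ``base`` with the free blocks overwritten from ``theta``."""
    theta = np.asarray(theta, dtype=float)
    p = base.copy()
    i = 0
    for block in free:
        if block == "lead":
            p.lead_gain = p.lead_gain * np.exp(theta[i])
            i += 1
            continue
        arr = getattr(p, block)
        n = arr.shape[0]
        setattr(p, block, theta[i:i + n].copy())
        i += n
    if i != theta.shape[0]:
        raise ValueError(f"parameter vector length {theta.shape[0]}, expected {i}")
    return p


# --- gains, firing and flow ---------------------------------------------------


@dataclass(frozen=True)
class EffectiveGains:
    """Positive pathway strengths for one condition.

    ``forward``/``backward``: (n_edges, 2) sub-pathway magnitudes (A1, A2) /
    (A3, A4); descending pathways are applied with a minus sign in the flow.
    ``intrinsic``: signed 4x4 within-source matrix.  ``input_gain``: drive
    strength per input target.
    """

    forward: np.ndarray
    backward: np.ndarray
    intrinsic: np.ndarray
    input_gain: np.ndarray


def effective_gains(params: ModelParameters, spec: NetworkSpec,
                    condition_index: int) -> EffectiveGains:
    """Template-times-exp(log-scaling) connection strengths for a condition.

    Modulated edges get an extra ``exp(b_e * X_j)`` factor, where ``X_j`` is
    the condition's design covariate; all returned extrinsic magnitudes are
    strictly positive, so condition effects rescale but never re-sign a
    connection.
    """
    x = spec.covariate(condition_index)
    mod = {e: params.b[i] * x for i, e in enumerate(spec.modulated_edges)}
    fwd = np.empty((len(spec.forward_edges), 2))
    for i, e in enumerate(spec.forward_edges):
        fwd[i] = FORWARD_TEMPLATE * np.exp(params.a_fwd[i] + mod.get(e, 0.0))
    bwd = np.empty((len(spec.backward_edges), 2))
    for i, e in enumerate(spec.backward_edges):
        bwd[i] = BACKWARD_TEMPLATE * np.exp(params.a_bwd[i] + mod.get(e, 0.0))
    gcls = np.exp(params.g)[INTRINSIC_CLASS.clip(0)]
    intrinsic = INTRINSIC_TEMPLATE * np.where(INTRINSIC_CLASS >= 0, gcls, 0.0)
    input_gain = INPUT_TEMPLATE * np.exp(params.c)
    return EffectiveGains(forward=fwd, backward=bwd, intrinsic=intrinsic,
                          input_gain=input_gain)


def firing_rate(v, gain: float = 1.0, bound: float = 4.0):
    """Presynaptic transform: centered sigmoid, f(0)=0, slope ``gain`` at 0.

    Implemented as a scaled tanh (a logistic sigmoid recentred at the
    origin), odd and bounded by ``±bound`` (mV-equivalent units), so the zero
    state is a fixed point of the unforced dynamics.
    """
    v = np.asarray(v, dtype=float)
    return bound * np.tanh(gain * v / bound)


def flow_matrices(params: ModelParameters, spec: NetworkSpec,
                  condition_index: int = 0):
    """Assemble (W, C, kappa) for the flow.

    ``W`` ((4n, 4n)) maps per-population firing rates to afferent drive,
    ``C`` ((4n,)) scales the per-source exogenous input onto spiny stellate
    populations, ``kappa`` ((4n,)) the per-population rate constants.
    """
    n = spec.n_sources
    gains = effective_gains(params, spec, condition_index)
    npop = N_POPULATIONS * n
    W = np.zeros((npop, npop))

    def p_ix(source: int, pop: int) -> int:
        return source * N_POPULATIONS + pop

    for s in range(n):
        rows = slice(s * N_POPULATIONS, (s + 1) * N_POPULATIONS)
        W[rows, rows] = gains.intrinsic
    for i, (lo, hi) in enumerate(spec.forward_edges):
        a1, a2 = gains.forward[i]
        lo_i, hi_i = spec.source_index(lo), spec.source_index(hi)
        W[p_ix(hi_i, _SS), p_ix(lo_i, _SP)] += a1
        W[p_ix(hi_i, _DP), p_ix(lo_i, _SP)] += a2
    for i, (hi, lo) in enumerate(spec.backward_edges):
        a3, a4 = gains.backward[i]
        hi_i, lo_i = spec.source_index(hi), spec.source_index(lo)
        W[p_ix(lo_i, _SP), p_ix(hi_i, _DP)] -= a3
        W[p_ix(lo_i, _II), p_ix(hi_i, _DP)] -= a4

    C = np.zeros(npop)
    for j, tgt in enumerate(spec.input_targets):
        C[p_ix(spec.source_index(tgt), _SS)] = gains.input_gain[j]

    kappa = np.tile(params.rates(), n)
    return W, C, kappa


def cmc_flow(x: np.ndarray, u: np.ndarray, params: ModelParameters,
             spec: NetworkSpec, condition_index: int = 0) -> np.ndarray:
    """Deterministic flow dx/dt of the coupled CMC network.

    ``x`` has shape (..., 8 n_sources) with interleaved (voltage,
    conductance) pairs per population; ``u`` is the exogenous drive per
    source (shape (n_sources,) or scalar broadcast).  Each population obeys
    voltage' = conductance and conductance' = kappa*(afferent) -
    2*kappa*conductance - kappa^2*voltage, with afferent drive summing
    intrinsic and extrinsic firing-rate inputs plus exogenous drive on input
    targets.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != spec.n_states:
        raise ValueError(f"state dimension {x.shape[-1]} != {spec.n_states}")
    u = np.broadcast_to(np.asarray(u, dtype=float), (spec.n_sources,))
    W, C, kappa = flow_matrices(params, spec, condition_index)
    u_pop = np.repeat(u, N_POPULATIONS)
    v = x[..., 0::2]
    g = x[..., 1::2]
    afferent = firing_rate(v) @ W.T + C * u_pop
    dx = np.empty_like(x)
    dx[..., 0::2] = g
    dx[..., 1::2] = kappa * afferent - 2.0 * kappa * g - kappa**2 * v
    return dx


def voltage_indices(spec: NetworkSpec) -> np.ndarray:
    """0-based indices of voltage states (odd subscripts in 1-based notation)."""
    return np.arange(0, spec.n_states, 2)


def conductance_indices(spec: NetworkSpec) -> np.ndarray:
    return np.arange(1, spec.n_states, 2)


def state_index(spec: NetworkSpec, source: str, population: Population,
                which: str = "voltage") -> int:
    """Flat state index of a (source, population) voltage or conductance."""
    offset = 0 if which == "voltage" else 1
    return (spec.source_index(source) * STATES_PER_SOURCE
            + 2 * int(population) + offset)


def linearized_jacobian(params: ModelParameters, spec: NetworkSpec,
                        condition_index: int = 0) -> np.ndarray:
    """Jacobian of the flow at the zero fixed point (firing slope = 1).

    Used both for stability checks (all eigenvalues must have negative real
    part at prior-mean parameters) and as the closed-form oracle for
    small-amplitude responses via the matrix exponential.
    """
    W, _, kappa = flow_matrices(params, spec, condition_index)
    npop = W.shape[0]
    J = np.zeros((2 * npop, 2 * npop))
    vix = np.arange(0, 2 * npop, 2)
    gix = np.arange(1, 2 * npop, 2)
    J[vix, gix] = 1.0
    J[np.ix_(gix, vix)] = kappa[:, None] * W
    J[gix, vix] -= kappa**2
    J[gix, gix] = -2.0 * kappa
    return J
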