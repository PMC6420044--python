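"""Compartmental cable model: discretization, dynamics, and voltage clamp.

The membrane equation per compartment is

    C dV/dt = -g_L (V - eps_L) - sum_syn g_syn(t) (V - eps_syn)
              + axial coupling + I_inj ,

with all potentials relative to rest.  Consistent unit triple throughout:
mV, nA, μS (so resistances are MΩ), capacitance in nF, time in ms.

Time integration is an implicit trapezoid rule (Crank-Nicolson) with one
exact linear solve per step; synaptic conductances are evaluated at the half
step, which keeps the scheme second-order and unconditionally stable at the
default dt of 0.1 ms.  An ideal somatic clamp is imposed by node
substitution: the clamped row of the linear system is replaced by
V = holding, and the clamp current is recovered afterwards from the
eliminated current-balance equation.
"""

from __future__ import annotations

import json
import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NumericalInstabilityError
from .morphology import Morphology, ROOT_PARENT

DEFAULT_DT = 0.1  # ms
DEFAULT_SETTLE = 200.0  # ms

# unit conversion factors (geometry in μm, parameters in the usual
# specific units, model in mV/nA/μS/nF/MΩ/ms)
_AXIAL_MOHM = 1e-2   # Ω·cm × μm / μm² -> MΩ
_CAP_NF = 1e-5       # μF/cm² × μm² -> nF
_LEAK_US = 1e-2      # S/cm² × μm² -> μS


@dataclass
class CableModel:
    """Discretized compartmental circuit on a morphology tree.

    ``parent[i]`` is the parent compartment (-1 for the soma root) and
    ``axial_conductance[i]`` couples i to its parent (μS; entry 0 unused).
    """

    parent: np.ndarray               # (n,) int
    axial_conductance: np.ndarray    # (n,) μS, to parent
    capacitance: np.ndarray          # (n,) nF
    leak_conductance: np.ndarray     # (n,) μS
    leak_reversal: float             # mV
    soma_index: int
    compartment_distance: np.ndarray  # (n,) μm path distance from soma
    area: np.ndarray                 # (n,) μm² membrane area
    morphology_node: np.ndarray      # (n,) morphology node each compartment lies on

    def __post_init__(self):
        n = self.n_compartments
        if not (self.axial_conductance[1:] > 0).all():
            raise ValueError("axial conductances must be positive")
        if not (self.capacitance > 0).all() or not (self.leak_conductance > 0).all():
            raise ValueError("capacitances and leak conductances must be positive")
        if not 0 <= self.soma_index < n:
            raise ValueError("soma_index out of range")

    @property
    def n_compartments(self) -> int:
        return len(self.parent)

    def conductance_matrix(self) -> np.ndarray:
        """Dense nodal conductance matrix G (μS): leak plus axial Laplacian."""
        n = self.n_compartments
        G = np.zeros((n, n))
        np.fill_diagonal(G, self.leak_conductance)
        for i in range(1, n):
            p = self.parent[i]
            g = self.axial_conductance[i]
            G[i, i] += g
            G[p, p] += g
            G[i, p] -= g
            G[p, i] -= g
        return G

    def nearest_compartment(self, distance: float) -> int:
        """Compartment whose path distance from the soma is closest."""
        return int(np.argmin(np.abs(self.compartment_distance - distance)))

    def model_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.parent, self.axial_conductance, self.capacitance,
                    self.leak_conductance, self.compartment_distance):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(np.float64(self.leak_reversal).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class SynapticEvent:
    """A double-exponential conductance transient at one compartment.

    ``reversal`` is in mV relative to rest; ``polarity_tag`` is "E" or "I"
    and is informational only (the reversal drives the physics).
    """

    site: int
    onset: float            # ms
    peak_conductance: float  # μS
    tau_rise: float          # ms
    tau_decay: float         # ms
    reversal: float          # mV relative to rest
    polarity_tag: str = "E"

    def __post_init__(self):
        if self.peak_conductance < 0:
            raise ValueError("peak_conductance must be >= 0")
        if self.tau_rise == self.tau_decay:
            raise ValueError("tau_rise must differ from tau_decay "
                             "(alpha-function kernels are not supported)")
        if not math.isfinite(self.reversal):
            raise ValueError("reversal must be finite")

    def conductance(self, t: np.ndarray) -> np.ndarray:
        return double_exponential_conductance(
            t, self.onset, self.peak_conductance, self.tau_rise, self.tau_decay)

    def shifted(self, dt_onset: float) -> "SynapticEvent":
        return SynapticEvent(self.site, self.onset + dt_onset,
                             self.peak_conductance, self.tau_rise,
                             self.tau_decay, self.reversal, self.polarity_tag)

    def with_reversal(self, reversal: float) -> "SynapticEvent":
        return SynapticEvent(self.site, self.onset, self.peak_conductance,
                             self.tau_rise, self.tau_decay, reversal,
                             self.polarity_tag)


@dataclass(frozen=True)
class ClampSpec:
    """Ideal voltage clamp: hold ``site`` at ``holding`` mV (relative).

    ``settle_time`` is the pre-stimulus interval used to read the baseline
    holding current; schedule stimuli after it.
    """

    site: int
    holding: float
    settle_time: float = DEFAULT_SETTLE

    def __post_init__(self):
        if self.settle_time < 0:
            raise ValueError("settle_time must be >= 0")


@dataclass(frozen=True)
class CurrentInjection:
    """Constant or time-series current (nA) injected at one compartment."""

    site: int
    waveform: float | np.ndarray

    def sample(self, t: np.ndarray, dt: float) -> np.ndarray:
        if np.isscalar(self.waveform):
            if not math.isfinite(self.waveform):
                raise ValueError("injection waveform must be finite")
            return np.full(len(t), float(self.waveform))
        w = np.asarray(self.waveform, dtype=float)
        if not np.isfinite(w).all():
            raise ValueError("injection waveform must be finite")
        # waveform is defined on the sample grid; interpolate to t
        t_w = np.arange(len(w)) * dt
        return np.interp(t, t_w, w, left=w[0] if len(w) else 0.0,
                         right=w[-1] if len(w) else 0.0)


@dataclass
class TraceSet:
    """Time-gridded simulation output.

    ``voltage`` has one row per recorded site (mV relative to rest).  When a
    clamp was active, ``clamp_current`` is the injected current (nA),
    ``baseline_current`` the steady pre-stimulus holding current, and
    ``syn_current = baseline_current - clamp_current`` — positive for an
    excitatory input held below its reversal.
    """

    time: np.ndarray
    sites: list[int]
    voltage: np.ndarray               # (n_sites, n_t)
    clamp_current: np.ndarray | None = None
    baseline_current: float | None = None
    syn_current: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def voltage_at(self, site: int) -> np.ndarray:
        return self.voltage[self.sites.index(site)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, site in enumerate(self.sites):
            rows.append(pd.DataFrame({
                "time": self.time, "site": site,
                "variable": "voltage", "value": self.voltage[i]}))
        if self.clamp_current is not None:
            rows.append(pd.DataFrame({
                "time": self.time, "site": self.metadata.get("clamp_site", -1),
                "variable": "clamp_current", "value": self.clamp_current}))
            rows.append(pd.DataFrame({
                "time": self.time, "site": self.metadata.get("clamp_site", -1),
                "variable": "syn_current", "value": self.syn_current}))
        df = pd.concat(rows, ignore_index=True)
        df["holding"] = self.metadata.get("holding", np.nan)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path, key: str = "traces") -> None:
        import h5py

        with h5py.File(path, "a") as fh:
            if key in fh:
                del fh[key]
            grp = fh.create_group(key)
            grp.create_dataset("time", data=self.time)
            grp.create_dataset("sites", data=np.asarray(self.sites))
            grp.create_dataset("voltage", data=self.voltage)
            if self.clamp_current is not None:
                grp.create_dataset("clamp_current", data=self.clamp_current)
                grp.create_dataset("syn_current", data=self.syn_current)
                grp.attrs["baseline_current"] = self.baseline_current
            grp.attrs["metadata"] = json.dumps(self.metadata, default=str)

    @classmethod
    def from_hdf5(cls, path, key: str = "traces") -> "TraceSet":
        import h5py

        with h5py.File(path, "r") as fh:
            grp = fh[key]
            clamped = "clamp_current" in grp
            return cls(
                time=grp["time"][:],
                sites=[int(s) for s in grp["sites"][:]],
                voltage=grp["voltage"][:],
                clamp_current=grp["clamp_current"][:] if clamped else None,
                baseline_current=(float(grp.attrs["baseline_current"])
                                  if clamped else None),
                syn_current=grp["syn_current"][:] if clamped else None,
                metadata=json.loads(grp.attrs["metadata"]),
            )


# ---------------------------------------------------------------------------
# kernels


def double_exponential_conductance(t, onset, peak, tau_rise, tau_decay):
    """Peak-normalized double-exponential conductance waveform (μS).

    g(t) = peak * |exp(-(t-onset)/tau_decay) - exp(-(t-onset)/tau_rise)| / N
    for t >= onset and zero before, where N is the analytic maximum of the
    two-exponential difference, so the returned series peaks at ``peak``
    (to grid resolution) regardless of the sign order of the printed kernel.
    """
    if tau_rise == tau_decay:
        raise ValueError("tau_rise must differ from tau_decay")
    if peak < 0:
        raise ValueError("peak must be >= 0")
    t = np.asarray(t, dtype=float)
    s = t - onset
    with np.errstate(over="ignore"):
        wave = np.where(
            s >= 0,
            np.abs(np.exp(-np.clip(s, 0, None) / tau_decay)
                   - np.exp(-np.clip(s, 0, None) / tau_rise)),
            0.0,
        )
    return peak * wave / double_exponential_normalizer(tau_rise, tau_decay)


def double_exponential_normalizer(tau_rise, tau_decay):
    """Analytic peak of |exp(-s/tau_decay) - exp(-s/tau_rise)|."""
    s_star = double_exponential_peak_time(tau_rise, tau_decay)
    return abs(math.exp(-s_star / tau_decay) - math.exp(-s_star / tau_rise))


def double_exponential_peak_time(tau_rise, tau_decay):
    """Time-to-peak of the kernel measured from onset (ms)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * math.log(tau_decay / tau_rise))


# ---------------------------------------------------------------------------
# active channels (generic gating interface + a textbook Na/K pair)


class GatingChannel:
    """Hodgkin-Huxley-style channel: gbar * prod(gates^exponent) * (eps - V).

    Gates advance with the exponential (Rush-Larsen) update, exact for
    frozen voltage over one step.  ``rate_fns`` maps gate name to a
    (alpha(Vabs), beta(Vabs)) pair in 1/ms with Vabs in absolute mV.
    """

    def __init__(self, gbar: np.ndarray, reversal: float, gates: dict,
                 rest_absolute: float = -65.0):
        self.gbar = np.asarray(gbar, dtype=float)   # μS per compartment
        self.reversal = float(reversal)             # mV relative to rest
        self.gates = gates                          # name -> (exponent, alpha, beta)
        self.rest_absolute = rest_absolute
        self.state: dict[str, np.ndarray] = {}

    def init_state(self, v_rel: np.ndarray) -> None:
        v = v_rel + self.rest_absolute
        self.state = {}
        for name, (_, alpha, beta) in self.gates.items():
            a, b = alpha(v), beta(v)
            self.state[name] = a / (a + b)

    def advance(self, v_rel: np.ndarray, dt: float) -> np.ndarray:
        """Advance gates one step; return channel conductance (μS)."""
        v = v_rel + self.rest_absolute
        g = self.gbar.copy()
        for name, (exponent, alpha, beta) in self.gates.items():
            a, b = alpha(v), beta(v)
            tau = 1.0 / (a + b)
            inf = a * tau
            x = inf + (self.state[name] - inf) * np.exp(-dt / tau)
            self.state[name] = x
            g = g * x ** exponent
        return g


def _vtrap(x, y):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x / (np.exp(x / y) - 1.0)
    return np.where(np.abs(x / y) < 1e-6, y * (1.0 - x / y / 2.0), out)


def standard_na_k_channels(model: CableModel,
                           gna_density: float = 1e-4,
                           gk_density: float = 3e-5,
                           ena: float = 115.0,
                           ek: float = -12.0) -> list[GatingChannel]:
    """Textbook squid-axon Na (m³h) and delayed-rectifier K (n⁴) channels.

    Densities in S/cm² applied uniformly; defaults are small so the model
    stays quiescent near rest (used to probe approximate reciprocity in an
    active membrane, not to reproduce any particular cell's channel set).
    Reversals in mV relative to rest.
    """
    gna = gna_density * model.area * _LEAK_US
    gk = gk_density * model.area * _LEAK_US
    na = GatingChannel(gna, ena, {
        "m": (3,
              lambda v: 0.1 * _vtrap(-(v + 40.0), 10.0),
              lambda v: 4.0 * np.exp(-(v + 65.0) / 18.0)),
        "h": (1,
              lambda v: 0.07 * np.exp(-(v + 65.0) / 20.0),
              lambda v: 1.0 / (np.exp(-(v + 35.0) / 10.0) + 1.0)),
    })
    k = GatingChannel(gk, ek, {
        "n": (4,
              lambda v: 0.01 * _vtrap(-(v + 55.0), 10.0),
              lambda v: 0.125 * np.exp(-(v + 65.0) / 80.0)),
    })
    return [na, k]


# ---------------------------------------------------------------------------
# discretization


def discretize(m: Morphology, max_segment_length: float = 20.0) -> CableModel:
    """Compartmentalize a morphology.

    The soma (possibly multi-point) collapses to a single isopotential
    compartment; each dendritic edge becomes a chain of frustum segments no
    longer than ``max_segment_length``.  Membrane area uses frustum lateral
    area (sphere area for a single-point soma); axial resistance between
    compartment centres sums the two half-segment frustum resistances
    R = Ra l / (pi r1 r2).
    """
    if max_segment_length <= 0:
        raise ValueError("max_segment_length must be positive")
    p = m.passive

    soma_nodes = [n for n in m.nodes if n.region_tag == "soma"]
    soma_ids = {n.id for n in soma_nodes}
    if m.root.region_tag != "soma":
        raise ValueError("root node must belong to the soma")

    if len(soma_nodes) == 1:
        soma_area = 4.0 * math.pi * soma_nodes[0].radius ** 2
    else:
        soma_area = 0.0
        for n in soma_nodes:
            if n.parent_id in soma_ids:
                parent = m.nodes[n.parent_id]
                ell = m.edge_length(n.id)
                slant = math.hypot(ell, parent.radius - n.radius)
                soma_area += math.pi * (parent.radius + n.radius) * slant
        if soma_area == 0.0:
            soma_area = 4.0 * math.pi * max(n.radius for n in soma_nodes) ** 2

    parents = [ROOT_PARENT]
    axial = [0.0]
    areas = [soma_area]
    half_res_proximal = [0.0]  # MΩ from compartment centre to its proximal end
    half_res_distal = [0.0]    # soma is isopotential: zero internal resistance
    distances = [0.0]
    morph_node = [m.root.id]

    # map morphology node -> compartment carrying its distal end
    node_comp = {n.id: 0 for n in soma_nodes}
    node_dist = {n.id: 0.0 for n in soma_nodes}

    for node in m.nodes:
        if node.region_tag == "soma" or node.id == m.root.id:
            continue
        parent_node = m.nodes[node.parent_id]
        ell = m.edge_length(node.id)
        if ell == 0.0:
            warnings.warn(
                f"zero-length segment at node {node.id}; collapsed into parent",
                stacklevel=2)
            node_comp[node.id] = node_comp[parent_node.id]
            node_dist[node.id] = node_dist[parent_node.id]
            continue
        # radius at the proximal end: parent's, unless parent is the soma
        # (a dendrite sprouting off the soma keeps its own calibre)
        r0 = node.radius if parent_node.id in soma_ids else parent_node.radius
        r1 = node.radius
        n_seg = max(1, math.ceil(ell / max_segment_length))
        seg_len = ell / n_seg
        prev_comp = node_comp[parent_node.id]
        base_dist = node_dist[parent_node.id]
        for s in range(n_seg):
            ra = r0 + (r1 - r0) * s / n_seg
            rb = r0 + (r1 - r0) * (s + 1) / n_seg
            rm = 0.5 * (ra + rb)
            slant = math.hypot(seg_len, rb - ra)
            comp = len(parents)
            parents.append(prev_comp)
            areas.append(math.pi * (ra + rb) * slant)
            hr_prox = (p.axial_resistivity * (seg_len / 2)
                       / (math.pi * ra * rm) * _AXIAL_MOHM)
            hr_dist = (p.axial_resistivity * (seg_len / 2)
                       / (math.pi * rm * rb) * _AXIAL_MOHM)
            half_res_proximal.append(hr_prox)
            half_res_distal.append(hr_dist)
            axial.append(1.0 / (hr_prox + half_res_distal[prev_comp]))
            distances.append(base_dist + seg_len * (s + 0.5))
            morph_node.append(node.id)
            prev_comp = comp
        node_comp[node.id] = prev_comp
        node_dist[node.id] = base_dist + ell

    areas = np.asarray(areas)
    return CableModel(
        parent=np.asarray(parents, dtype=int),
        axial_conductance=np.asarray(axial),
        capacitance=p.specific_capacitance * areas * _CAP_NF,
        leak_conductance=p.specific_leak_conductance * areas * _LEAK_US,
        leak_reversal=p.leak_reversal,
        soma_index=0,
        compartment_distance=np.asarray(distances),
        area=areas,
        morphology_node=np.asarray(morph_node, dtype=int),
    )


# ---------------------------------------------------------------------------
# steady state


def steady_state_solve(model: CableModel,
                       constant_injections: dict[int, float] | None = None,
                       constant_conductances: dict[int, tuple[float, float]]
                       | None = None) -> np.ndarray:
    """Exact passive steady state (mV per compartment).

    ``constant_injections`` maps site -> nA; ``constant_conductances`` maps
    site -> (g μS, reversal mV).  Raises on a singular system.
    """
    n = model.n_compartments
    G = model.conductance_matrix()
    s = np.full(n, model.leak_reversal) * model.leak_conductance
    if constant_injections:
        for site, current in constant_injections.items():
            s[site] += current
    if constant_conductances:
        for site, (g, eps) in constant_conductances.items():
            G[site, site] += g
            s[site] += g * eps
    try:
        v = np.linalg.solve(G, s)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular steady-state system: {exc}") from None
    residual = G @ v - s
    scale = max(np.abs(s).max(), np.abs(G).max() * max(np.abs(v).max(), 1.0))
    if scale > 0 and np.abs(residual).max() / scale > 1e-10:
        raise np.linalg.LinAlgError("steady-state residual too large")
    return v


# ---------------------------------------------------------------------------
# time integration


def simulate(model: CableModel,
             synapses: list[SynapticEvent] | None = None,
             injections: list[CurrentInjection] | None = None,
             clamp: ClampSpec | None = None,
             duration: float = 300.0,
             dt: float = DEFAULT_DT,
             record_sites: list[int] | None = None,
             channels: list[GatingChannel] | None = None,
             initial_voltage: np.ndarray | None = None,
             seed: int | None = None) -> TraceSet:
    """Integrate the compartmental model and return a :class:`TraceSet`.

    With a clamp, the clamped site is pinned to the holding level exactly;
    ``syn_current`` is the baseline holding current minus the instantaneous
    clamp current, which realizes the measured synaptic current increment.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    synapses = synapses or []
    injections = injections or []
    if clamp is not None and duration <= clamp.settle_time:
        raise ValueError("duration must exceed the clamp settle_time")

    n = model.n_compartments
    t = np.arange(0.0, duration + dt / 2, dt)
    n_t = len(t)
    t_half = t[:-1] + dt / 2

    for ev in synapses:
        if not 0 <= ev.site < n:
            raise ValueError(f"synapse site {ev.site} out of range")
    for inj in injections:
        if not 0 <= inj.site < n:
            raise ValueError(f"injection site {inj.site} out of range")

    # conductance per synapse on half and full grids
    g_half = np.array([ev.conductance(t_half) for ev in synapses]) \
        if synapses else np.zeros((0, n_t - 1))
    g_full = np.array([ev.conductance(t) for ev in synapses]) \
        if synapses else np.zeros((0, n_t))
    syn_sites = np.array([ev.site for ev in synapses], dtype=int)
    syn_eps = np.array([ev.reversal for ev in synapses])

    inj_half = np.zeros((len(injections), n_t - 1))
    inj_full = np.zeros((len(injections), n_t))
    for i, inj in enumerate(injections):
        inj_half[i] = inj.sample(t_half, dt)
        inj_full[i] = inj.sample(t, dt)
    inj_sites = np.array([inj.site for inj in injections], dtype=int)

    G0 = model.conductance_matrix()
    C = model.capacitance
    leak_src = model.leak_conductance * model.leak_reversal

    if initial_voltage is not None:
        V = np.asarray(initial_voltage, dtype=float).copy()
    else:
        V = np.zeros(n)
        if clamp is not None:
            V[clamp.site] = clamp.holding

    for ch in channels or []:
        ch.init_state(V)

    Vrec = np.empty((n, n_t))
    Vrec[:, 0] = V
    eye_over_dt = np.zeros((n, n))
    np.fill_diagonal(eye_over_dt, C / dt)

    # conductance of each channel at sample times (for clamp-current readout)
    ch_g_full = [np.empty((n, n_t)) for _ in (channels or [])]
    for ci, ch in enumerate(channels or []):
        ch_g_full[ci][:, 0] = ch.gbar * np.prod(
            [ch.state[name] ** exp for name, (exp, _, _) in ch.gates.items()],
            axis=0)

    if channels:
        for step in range(n_t - 1):
            Gh = G0.copy()
            src = leak_src.copy()
            if len(synapses):
                gs = g_half[:, step]
                np.add.at(Gh, (syn_sites, syn_sites), gs)
                np.add.at(src, syn_sites, gs * syn_eps)
            if len(injections):
                np.add.at(src, inj_sites, inj_half[:, step])
            for ci, ch in enumerate(channels):
                g_ch = ch.advance(V, dt)
                Gh[np.arange(n), np.arange(n)] += g_ch
                src += g_ch * ch.reversal
                ch_g_full[ci][:, step + 1] = g_ch

            A = 0.5 * Gh + eye_over_dt
            b = (C / dt) * V - 0.5 * (Gh @ V) + src
            if clamp is not None:
                A[clamp.site, :] = 0.0
                A[clamp.site, clamp.site] = 1.0
                b[clamp.site] = clamp.holding
            V = np.linalg.solve(A, b)
            Vrec[:, step + 1] = V
            vmax = np.abs(V).max()
            if vmax > 500.0:
                raise NumericalInstabilityError(dt, t[step + 1], vmax)
    else:
        # Passive fast path.  Only the synapse-site diagonal entries of the
        # system matrix change in time, so factorize the constant part once
        # and apply rank-s Sherman-Morrison-Woodbury corrections per step.
        from scipy.linalg import lu_factor, lu_solve

        A0 = 0.5 * G0 + eye_over_dt
        if clamp is not None:
            A0[clamp.site, :] = 0.0
            A0[clamp.site, clamp.site] = 1.0
        lu = lu_factor(A0)
        # synapse sites that actually perturb the factorized matrix
        upd = [j for j in range(len(synapses))
               if clamp is None or syn_sites[j] != clamp.site]
        upd_sites = syn_sites[upd] if upd else np.array([], dtype=int)
        if len(upd):
            U = np.zeros((n, len(upd)))
            U[upd_sites, np.arange(len(upd))] = 1.0
            Z = lu_solve(lu, U)          # A0^{-1} e_s, n x s
            S = Z[upd_sites, :]          # s x s
        C_over_dt = C / dt
        for step in range(n_t - 1):
            src = leak_src.copy()
            gV_extra = np.zeros(n)
            if len(synapses):
                gs = g_half[:, step]
                np.add.at(src, syn_sites, gs * syn_eps)
                np.add.at(gV_extra, syn_sites, gs * V[syn_sites])
            if len(injections):
                np.add.at(src, inj_sites, inj_half[:, step])
            b = C_over_dt * V - 0.5 * (G0 @ V) - 0.5 * gV_extra + src
            if clamp is not None:
                b[clamp.site] = clamp.holding
            y = lu_solve(lu, b)
            if len(upd):
                d = 0.5 * g_half[upd, step]
                M = np.eye(len(upd)) + d[:, None] * S
                w = np.linalg.solve(M, d * y[upd_sites])
                V = y - Z @ w
            else:
                V = y
            Vrec[:, step + 1] = V
            vmax = np.abs(V).max()
            if vmax > 500.0:
                raise NumericalInstabilityError(dt, t[step + 1], vmax)

    clamp_current = None
    baseline = None
    syn_current = None
    if clamp is not None:
        cs = clamp.site
        vs = Vrec[cs]
        balance = model.leak_conductance[cs] * (vs - model.leak_reversal)
        for i in range(1, n):
            p = model.parent[i]
            g = model.axial_conductance[i]
            if i == cs:
                balance = balance + g * (vs - Vrec[p])
            elif p == cs:
                balance = balance + g * (vs - Vrec[i])
        for j in range(len(synapses)):
            if syn_sites[j] == cs:
                balance = balance + g_full[j] * (vs - syn_eps[j])
        for ci, ch in enumerate(channels or []):
            balance = balance + ch_g_full[ci][cs] * (vs - ch.reversal)
        for i in range(len(injections)):
            if inj_sites[i] == cs:
                balance = balance - inj_full[i]
        clamp_current = balance
        i_base = int(np.searchsorted(t, clamp.settle_time, side="right")) - 1
        baseline = float(clamp_current[max(i_base, 0)])
        syn_current = baseline - clamp_current

    sites = list(record_sites) if record_sites is not None else list(range(n))
    meta = {
        "dt": dt,
        "holding": clamp.holding if clamp is not None else None,
        "clamp_site": clamp.site if clamp is not None else None,
        "settle_time": clamp.settle_time if clamp is not None else None,
        "seed": seed,
        "model_hash": model.model_hash(),
    }
    return TraceSet(
        time=t,
        sites=sites,
        voltage=Vrec[sites],
        clamp_current=clamp_current,
        baseline_current=baseline,
        syn_current=syn_current,
        metadata=meta,
    )
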