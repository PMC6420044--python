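"""Protocol orchestration: schedules, clamp experiments, and error scans.

These routines compose the simulator with the estimators into the full
measurement workflow: generate an input schedule, run the somatic clamp at
several holding levels and two inhibitory reversal potentials, fit the
per-time-point I-V lines, and compare the slope-and-intercept (SIM) and
intercept (IM) decompositions against single-polarity references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cable import CableModel, ClampSpec, SynapticEvent, simulate, \
    steady_state_solve
from .estimators import (ConductanceTrace, ErrorSummary, HoldingSeries,
                         error_summary, fit_iv_per_timepoint, im_estimate,
                         reference_from_intercept, reference_from_point_model,
                         sim_estimate)
from .fixtures import (E_KERNEL, EPS_E, EPS_I, EPS_I_PRIME, HOLDING_LEVELS,
                       I_KERNEL, SCAN_PEAKS)
from .statics import SimSolution, im_solve, sim_error_prediction, sim_solve


@dataclass
class InputSchedule:
    """Seeded synaptic event list with its generating parameters."""

    events: list[SynapticEvent]
    n_E_sites: int
    n_I_sites: int
    rate: float    # Hz per site
    window: float  # ms
    seed: int

    @property
    def e_events(self) -> list[SynapticEvent]:
        return [ev for ev in self.events if ev.polarity_tag == "E"]

    @property
    def i_events(self) -> list[SynapticEvent]:
        return [ev for ev in self.events if ev.polarity_tag == "I"]


def gen_schedule(model: CableModel, n_E: int, n_I: int, rate: float,
                 window: float, seed: int,
                 e_kernel: tuple = E_KERNEL, i_kernel: tuple = I_KERNEL,
                 eps_E: float = EPS_E, eps_I: float = EPS_I) -> InputSchedule:
    """Distribute E and I input sites over the dendrite and draw onsets.

    Each site fires exactly round(rate * window / 1000) times, onsets drawn
    uniformly on [0, window] — a fixed event count per site rather than a
    Poisson draw, so totals are reproducible.  Site assignment is uniform
    over dendritic compartments from the same seeded stream.
    """
    rng = np.random.default_rng(seed)
    dendritic = np.nonzero(model.compartment_distance > 0)[0]
    if len(dendritic) == 0:
        raise ValueError("model has no dendritic compartments")
    n_events = int(round(rate * window / 1000.0))
    if n_events < 1 and (n_E + n_I) > 0:
        warnings.warn("rate * window < 1 event per site: empty schedule",
                      stacklevel=2)
    events = []
    for polarity, count, kernel, eps in (("E", n_E, e_kernel, eps_E),
                                         ("I", n_I, i_kernel, eps_I)):
        tau_r, tau_d, peak = kernel
        sites = rng.choice(dendritic, size=count, replace=True)
        for site in sites:
            onsets = rng.uniform(0.0, window, size=n_events)
            for onset in onsets:
                events.append(SynapticEvent(int(site), float(onset), peak,
                                            tau_r, tau_d, eps, polarity))
    return InputSchedule(events, n_E, n_I, rate, window, seed)


# ---------------------------------------------------------------------------
# clamp protocol


@dataclass
class ProtocolResult:
    """Everything the estimators produce for one clamp experiment."""

    holding: HoldingSeries          # pair input, base eps_I
    holding_prime: HoldingSeries    # pair input, shifted eps_I
    sim_E: ConductanceTrace
    sim_I: ConductanceTrace
    im_E: ConductanceTrace
    im_I: ConductanceTrace
    ref_E: ConductanceTrace         # intercept reference, single E input
    ref_I: ConductanceTrace         # intercept reference, single I input
    ref_E_point: ConductanceTrace   # point-model reference, unclamped
    ref_I_point: ConductanceTrace
    metadata: dict = field(default_factory=dict)

    def summaries(self, reference: str = "intercept") \
            -> dict[str, dict[str, ErrorSummary]]:
        refs = {"intercept": (self.ref_E, self.ref_I),
                "point": (self.ref_E_point, self.ref_I_point)}[reference]
        return {
            "SIM": {"E": error_summary(self.sim_E, refs[0]),
                    "I": error_summary(self.sim_I, refs[1])},
            "IM": {"E": error_summary(self.im_E, refs[0]),
                   "I": error_summary(self.im_I, refs[1])},
        }


def _clamp_series(model, events, holding_levels, settle, duration, dt, tag):
    """Clamp at each level; drop the settle segment (charging transient)."""
    traces = []
    for holding in holding_levels:
        clamp = ClampSpec(model.soma_index, holding, settle_time=settle)
        traces.append(simulate(model, synapses=events, clamp=clamp,
                               duration=duration, dt=dt,
                               record_sites=[model.soma_index]))
    return HoldingSeries.from_tracesets(traces, eps_tag=tag,
                                        start_time=settle)


def _point_model_params(model: CableModel) -> tuple[float, float]:
    """Equivalent somatic point model: g_L = 1/K_SS, c = tau_m / K_SS."""
    v = steady_state_solve(model, {model.soma_index: 1.0})
    k_ss = float(v[model.soma_index])
    tau_m = float(model.capacitance[model.soma_index]
                  / model.leak_conductance[model.soma_index])
    return tau_m / k_ss, 1.0 / k_ss  # (c nF, g_L μS)


def run_protocol(model: CableModel, schedule: InputSchedule,
                 holding_levels=HOLDING_LEVELS,
                 eps_I_variants: tuple[float, float] = (EPS_I, EPS_I_PRIME),
                 dt: float = 0.1, settle: float = 120.0,
                 tail: float = 100.0, eps_E: float = EPS_E) -> ProtocolResult:
    """Run the full intercept-method protocol on one input schedule.

    2 x len(holding_levels) clamp runs with the combined schedule (only the
    inhibitory reversal differing between the two blocks), one block of
    single-polarity clamp runs for the intercept references, and two
    unclamped runs for the point-model references.
    """
    eps_I, eps_I_prime = eps_I_variants
    if eps_I == eps_I_prime:
        raise ValueError("the two inhibitory reversal variants must differ")
    duration = settle + schedule.window + tail
    shift = settle

    e_events = [ev.shifted(shift) for ev in schedule.e_events]
    i_events = [ev.shifted(shift).with_reversal(eps_I)
                for ev in schedule.i_events]
    i_events_prime = [ev.with_reversal(eps_I_prime) for ev in i_events]

    holding = _clamp_series(model, e_events + i_events, holding_levels,
                            settle, duration, dt, tag=f"eps_I={eps_I}")
    holding_prime = _clamp_series(model, e_events + i_events_prime,
                                  holding_levels, settle, duration, dt,
                                  tag=f"eps_I={eps_I_prime}")
    iv = fit_iv_per_timepoint(holding)
    iv_prime = fit_iv_per_timepoint(holding_prime)
    sim_E, sim_I = sim_estimate(iv, eps_E, eps_I)
    im_E, im_I = im_estimate(iv, iv_prime, eps_E, eps_I, eps_I_prime)

    h_e = _clamp_series(model, e_events, holding_levels, settle, duration,
                        dt, tag="single-E")
    h_i = _clamp_series(model, i_events, holding_levels, settle, duration,
                        dt, tag="single-I")
    ref_E = reference_from_intercept(fit_iv_per_timepoint(h_e), eps_E, "E")
    ref_I = reference_from_intercept(fit_iv_per_timepoint(h_i), eps_I, "I")

    c_pt, gl_pt = _point_model_params(model)
    tr_e = simulate(model, synapses=e_events, duration=duration, dt=dt,
                    record_sites=[model.soma_index])
    tr_i = simulate(model, synapses=i_events, duration=duration, dt=dt,
                    record_sites=[model.soma_index])
    i0 = int(np.searchsorted(tr_e.time, settle))
    ref_E_point = reference_from_point_model(
        tr_e.time[i0:], tr_e.voltage[0][i0:], c_pt, gl_pt, eps_E, "E")
    ref_I_point = reference_from_point_model(
        tr_i.time[i0:], tr_i.voltage[0][i0:], c_pt, gl_pt, eps_I, "I")

    return ProtocolResult(
        holding, holding_prime, sim_E, sim_I, im_E, im_I,
        ref_E, ref_I, ref_E_point, ref_I_point,
        metadata={"dt": dt, "settle": settle, "duration": duration,
                  "holding_levels": list(holding_levels),
                  "eps_E": eps_E, "eps_I_variants": list(eps_I_variants),
                  "seed": schedule.seed, "model_hash": model.model_hash()})


# ---------------------------------------------------------------------------
# spatial error scan


@dataclass
class ErrorMap:
    """Per-(E,I)-location error summaries and negativity flags."""

    table: pd.DataFrame  # columns: dist_E, dist_I, method, polarity,
    #                       peak_error, time_avg_error, negative

    def cell(self, dist_E: float, dist_I: float, method: str,
             polarity: str) -> pd.Series:
        t = self.table
        sel = t[(t.dist_E == dist_E) & (t.dist_I == dist_I)
                & (t.method == method) & (t.polarity == polarity)]
        return sel.iloc[0]


def spatial_error_map(model: CableModel, distances,
                      g_peaks: tuple[float, float] = SCAN_PEAKS,
                      pairs=None, onset: float = 10.0,
                      holding_levels=HOLDING_LEVELS,
                      eps_I_variants=(EPS_I, EPS_I_PRIME),
                      dt: float = 0.1, settle: float = 120.0,
                      window: float = 110.0, seed: int = 0) -> ErrorMap:
    """Scan a pair of transient E and I inputs over dendritic locations.

    ``pairs`` gives explicit (dist_E, dist_I) μm tuples; by default the full
    grid over ``distances`` is scanned.  Unrealizable distances (further
    than any compartment) are skipped with a log entry in the table.
    """
    if pairs is None:
        pairs = [(dE, dI) for dE in distances for dI in distances]
    max_dist = model.compartment_distance.max()
    rows = []
    for dist_E, dist_I in pairs:
        if dist_E > max_dist or dist_I > max_dist:
            warnings.warn(f"skipped unreachable cell ({dist_E}, {dist_I}) μm",
                          stacklevel=2)
            continue
        site_E = model.nearest_compartment(dist_E)
        site_I = model.nearest_compartment(dist_I)
        events = [
            SynapticEvent(site_E, onset, g_peaks[0], *E_KERNEL[:2], EPS_E, "E"),
            SynapticEvent(site_I, onset, g_peaks[1], *I_KERNEL[:2],
                          eps_I_variants[0], "I"),
        ]
        schedule = InputSchedule(events, 1, 1, rate=0.0, window=window,
                                 seed=seed)
        result = run_protocol(model, schedule, holding_levels,
                              eps_I_variants, dt=dt, settle=settle,
                              tail=window - onset)
        summaries = result.summaries()
        traces = {"SIM": {"E": result.sim_E, "I": result.sim_I},
                  "IM": {"E": result.im_E, "I": result.im_I}}
        refs = {"E": result.ref_E, "I": result.ref_I}
        for method in ("SIM", "IM"):
            for polarity in ("E", "I"):
                s = summaries[method][polarity]
                est = traces[method][polarity]
                ref = refs[polarity]
                rows.append({
                    "dist_E": dist_E, "dist_I": dist_I,
                    "site_E": site_E, "site_I": site_I,
                    "method": method, "polarity": polarity,
                    "peak_error": s.peak_relative_error,
                    "time_avg_error": s.time_averaged_relative_error,
                    "negative": est.has_negative,
                    "est_min": float(np.nanmin(est.g)),
                    "ref_min": float(np.nanmin(ref.g)),
                    "ref_peak": ref.peak})
    return ErrorMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# static demonstration and robustness checks


def static_demo_alpha(alphas, gE_eff: float, gI_eff: float,
                      eps_E: float = EPS_E, eps_I: float = EPS_I,
                      eps_I_prime: float = EPS_I_PRIME) -> pd.DataFrame:
    """Tabulate SIM vs IM on first-order co-located I-V lines.

    For each prefactor alpha the first-order slope/intercept of a true
    effective pair (gE_eff, gI_eff) is constructed, both methods are solved,
    and SIM's deviations are compared with the closed-form error laws
    (which they match identically in this co-located regime).
    """
    rows = []
    for alpha in alphas:
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        k = alpha * (gE_eff + gI_eff)
        b = gE_eff * eps_E + gI_eff * eps_I
        b_prime = gE_eff * eps_E + gI_eff * eps_I_prime
        sim: SimSolution = sim_solve(k, b, eps_E, eps_I)
        im_E, im_I = im_solve(b, b_prime, eps_E, eps_I, eps_I_prime)
        dgE_pred, dgI_pred = sim_error_prediction(k, alpha, eps_E, eps_I)
        rows.append({
            "alpha": alpha, "k": k, "b": b,
            "gE_true": gE_eff, "gI_true": gI_eff,
            "gE_SIM": sim.g_E, "gI_SIM": sim.g_I,
            "gE_IM": im_E, "gI_IM": im_I,
            "dgE_SIM": sim.g_E - gE_eff, "dgI_SIM": sim.g_I - gI_eff,
            "dgE_predicted": dgE_pred, "dgI_predicted": dgI_pred,
            "SIM_negative": sim.negative,
        })
    return pd.DataFrame(rows)


def add_noise(h: HoldingSeries, sigma: float, seed: int) -> HoldingSeries:
    """Add i.i.d. zero-mean Gaussian current noise (nA), reproducibly."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = h.syn_current + rng.normal(0.0, sigma, size=h.syn_current.shape) \
        if sigma > 0 else h.syn_current.copy()
    return HoldingSeries(h.holding_levels.copy(), h.time.copy(), noisy,
                         eps_tag=h.eps_tag,
                         metadata={**h.metadata, "noise_sigma": sigma,
                                   "noise_seed": seed})


def reversal_invariance_check(model: CableModel, site: int, eps_values,
                              kernel: tuple = E_KERNEL,
                              polarity_tag: str = "E",
                              holding_levels=HOLDING_LEVELS,
                              dt: float = 0.1, settle: float = 120.0,
                              onset: float = 10.0,
                              window: float = 100.0) -> float:
    """Coefficient of variation of the peak effective conductance across a
    reversal-potential sweep.

    For each reversal value the effective conductance of a single input is
    estimated from the intercept of the clamp I-V relation; a well-defined
    effective conductance must not depend on the driving force used to probe
    it, so std/mean of the peak amplitudes should be small.
    """
    eps_values = list(eps_values)
    if len(eps_values) < 3:
        raise ValueError("need >= 3 reversal values")
    tau_r, tau_d, peak = kernel
    peaks = []
    for eps in eps_values:
        if eps == 0:
            raise ValueError("a reversal equal to rest has no driving force")
        events = [SynapticEvent(site, settle + onset, peak, tau_r, tau_d,
                                eps, polarity_tag)]
        h = _clamp_series(model, events, holding_levels, settle,
                          settle + onset + window, dt, tag=f"eps={eps}")
        ref = reference_from_intercept(fit_iv_per_timepoint(h), eps,
                                       polarity_tag)
        peaks.append(ref.peak)
    peaks = np.asarray(peaks)
    return float(peaks.std() / peaks.mean())
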