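"""Turn clamp-protocol trace sets into conductance time courses.

The pipeline mirrors the experimental workflow: record the measured
synaptic current at several holding levels, fit the linear I-V relation at
every time point, then read conductances out of the fitted line either the
traditional way (slope-and-intercept, SIM) or from intercepts alone at two
inhibitory reversal potentials (intercept method, IM).  Reference effective
conductances come from a pure input, either through the point-model
inversion of the unclamped somatic voltage or through the intercept itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cable import TraceSet, double_exponential_conductance
from .errors import AlignmentError, FitFailureError, SingularityError


@dataclass
class HoldingSeries:
    """Measured synaptic currents at >= 2 distinct holding levels.

    ``syn_current`` has one row per holding level, on a shared time grid.
    ``eps_tag`` records which inhibitory-reversal variant produced the data.
    """

    holding_levels: np.ndarray   # (L,) mV relative to rest
    time: np.ndarray             # (T,) ms
    syn_current: np.ndarray      # (L, T) nA
    eps_tag: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.holding_levels = np.asarray(self.holding_levels, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.syn_current = np.asarray(self.syn_current, dtype=float)
        if len(np.unique(self.holding_levels)) < 2:
            raise ValueError("need >= 2 distinct holding levels")
        if self.syn_current.shape != (len(self.holding_levels), len(self.time)):
            raise ValueError("syn_current must be (levels, time)")

    @classmethod
    def from_tracesets(cls, traces: list[TraceSet], eps_tag: str = "",
                       start_time: float | None = None) -> "HoldingSeries":
        """Stack clamped trace sets; ``start_time`` drops the pre-stimulus
        settle segment (whose charging transient is not synaptic current)."""
        t0 = traces[0].time
        for tr in traces[1:]:
            if len(tr.time) != len(t0) or not np.allclose(tr.time, t0):
                raise AlignmentError("trace sets do not share a time grid")
        i0 = int(np.searchsorted(t0, start_time)) if start_time else 0
        return cls(
            holding_levels=np.array([tr.metadata["holding"] for tr in traces]),
            time=t0[i0:].copy(),
            syn_current=np.vstack([tr.syn_current[i0:] for tr in traces]),
            eps_tag=eps_tag,
            metadata={"dt": traces[0].dt},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"time": self.time, "holding": h,
                              "syn_current": self.syn_current[i]})
                for i, h in enumerate(self.holding_levels)]
        df = pd.concat(rows, ignore_index=True)
        df["eps_tag"] = self.eps_tag
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, eps_tag: str | None = None) -> "HoldingSeries":
        df = pd.read_csv(path)
        levels = np.sort(df["holding"].unique())
        time = np.sort(df[df["holding"] == levels[0]]["time"].to_numpy())
        cur = np.vstack([
            df[df["holding"] == h].sort_values("time")["syn_current"].to_numpy()
            for h in levels])
        tag = eps_tag if eps_tag is not None else \
            (str(df["eps_tag"].iloc[0]) if "eps_tag" in df else "")
        return cls(levels, time, cur, tag)


@dataclass
class IVSeries:
    """Per-time-point fitted I-V line I_syn = -k V + b with fit quality."""

    time: np.ndarray
    k: np.ndarray          # μS
    b: np.ndarray          # nA
    r_squared: np.ndarray  # in [0, 1]


@dataclass
class ConductanceTrace:
    """Effective-conductance time course with provenance tags.

    Negative excursions are preserved (``has_negative`` flags them) because
    unphysical negativity is a finding, not a numerical defect.
    """

    time: np.ndarray
    g: np.ndarray            # μS
    polarity_tag: str        # "E" | "I"
    method_tag: str          # "SIM" | "IM" | "per-level" | "reference"
    reversal_used: float | None = None

    @property
    def has_negative(self) -> bool:
        return bool(np.nanmin(self.g) < 0)

    @property
    def peak(self) -> float:
        return float(np.nanmax(self.g))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time, "g_uS": self.g,
            "polarity": self.polarity_tag, "method": self.method_tag})


@dataclass(frozen=True)
class ErrorSummary:
    """Relative errors of an estimated trace against a reference trace."""

    peak_relative_error: float
    time_averaged_relative_error: float


# ---------------------------------------------------------------------------
# I-V regression and method solvers


def fit_iv_per_timepoint(h: HoldingSeries) -> IVSeries:
    """Ordinary least squares of I_syn on V at each time sample.

    Returns k as the negated regression slope (convention I = -k V + b).
    With exactly two levels the fit is exact interpolation (r² = 1).
    """
    V = h.holding_levels
    I = h.syn_current
    if not np.isfinite(I).all():
        raise ValueError("syn_current contains non-finite samples")
    vc = V - V.mean()
    denom = float(vc @ vc)
    if denom == 0:
        raise np.linalg.LinAlgError("holding levels are all identical")
    slope = (vc @ I) / denom
    intercept = I.mean(axis=0) - slope * V.mean()
    fitted = np.outer(V, slope) + intercept
    ss_res = ((I - fitted) ** 2).sum(axis=0)
    ss_tot = ((I - I.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot <= 1e-300, 1.0, r2)
    return IVSeries(time=h.time.copy(), k=-slope, b=intercept,
                    r_squared=np.clip(r2, 0.0, 1.0))


def sim_estimate(iv: IVSeries, eps_E: float, eps_I: float) \
        -> tuple[ConductanceTrace, ConductanceTrace]:
    """Traditional slope-and-intercept decomposition, per time point."""
    if eps_E == eps_I:
        raise SingularityError("eps_E must differ from eps_I")
    gE = (iv.b - iv.k * eps_I) / (eps_E - eps_I)
    gI = (iv.k * eps_E - iv.b) / (eps_E - eps_I)
    return (ConductanceTrace(iv.time.copy(), gE, "E", "SIM", eps_E),
            ConductanceTrace(iv.time.copy(), gI, "I", "SIM", eps_I))


def im_estimate(iv: IVSeries, iv_prime: IVSeries, eps_E: float,
                eps_I: float, eps_I_prime: float) \
        -> tuple[ConductanceTrace, ConductanceTrace]:
    """Intercept method: per-time-point solve of the two intercept lines."""
    if len(iv.time) != len(iv_prime.time) or \
            not np.allclose(iv.time, iv_prime.time):
        raise AlignmentError("the two I-V series do not share a time grid")
    if eps_I == eps_I_prime:
        raise SingularityError("the two inhibitory reversals must differ")
    gI = (iv.b - iv_prime.b) / (eps_I - eps_I_prime)
    gE = (iv.b - gI * eps_I) / eps_E
    return (ConductanceTrace(iv.time.copy(), gE, "E", "IM", eps_E),
            ConductanceTrace(iv.time.copy(), gI, "I", "IM", eps_I))


def per_level_conductance(h: HoldingSeries, eps: float,
                          polarity_tag: str = "E") -> list[ConductanceTrace]:
    """g_inj(t) = I_syn(t)/(eps - V_hold), one trace per holding level.

    Levels where the holding equals the reversal (vanishing driving force)
    are excluded with a warning — in a point neuron all returned traces are
    identical; their spread on a spatial neuron is direct evidence of the
    nonlinear clamp-synapse interaction.
    """
    traces = []
    skipped = []
    for i, v in enumerate(h.holding_levels):
        if eps == v:
            skipped.append(v)
            continue
        traces.append(ConductanceTrace(
            h.time.copy(), h.syn_current[i] / (eps - v),
            polarity_tag, "per-level", eps))
    if skipped:
        warnings.warn(f"excluded holding level(s) {skipped} equal to the "
                      f"reversal potential {eps}", stacklevel=2)
    if not traces:
        raise SingularityError("all holding levels equal the reversal potential")
    return traces


# ---------------------------------------------------------------------------
# waveform fitting


def fit_double_exponential(trace: ConductanceTrace, max_restarts: int = 6) \
        -> tuple[float, float, float, float]:
    """Least-squares fit of the peak-normalized two-exponential kernel.

    Returns (peak μS, tau_rise ms, tau_decay ms, onset ms).  Raises
    :class:`FitFailureError` when the trace has no usable transient or no
    restart converges.
    """
    t, g = trace.time, np.asarray(trace.g, dtype=float)
    finite = np.isfinite(g)
    t, g = t[finite], g[finite]
    peak0 = g.max() if g.size else 0.0
    if peak0 <= 0 or not (np.abs(g) > 0.05 * peak0).any():
        raise FitFailureError("trace has no dominant positive transient")
    i_peak = int(np.argmax(g))
    above = np.nonzero(g[:i_peak + 1] > 0.05 * peak0)[0]
    onset0 = t[above[0]] if len(above) else t[0]

    def residual(params):
        peak, tr, td, onset = params
        return double_exponential_conductance(t, onset, peak, tr, td) - g

    span = max(t[-1] - t[0], 1.0)
    best = None
    seeds = [(5.0, 7.8), (6.0, 18.0), (1.0, 10.0),
             (2.0, 30.0), (0.5, 5.0), (10.0, 40.0)][:max_restarts]
    for tr0, td0 in seeds:
        try:
            res = least_squares(
                residual, x0=[peak0, tr0, td0, max(onset0 - tr0, t[0])],
                bounds=([0.0, 1e-3, 2e-3, t[0] - span],
                        [10 * peak0 + 1e-12, span, 2 * span, t[-1]]),
                xtol=1e-12, ftol=1e-12)
        except ValueError:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError("double-exponential fit did not converge "
                              f"after {len(seeds)} restarts")
    peak, tr_fit, td_fit, onset = best.x
    if tr_fit > td_fit:  # kernel is symmetric in the two constants
        tr_fit, td_fit = td_fit, tr_fit
    return float(peak), float(tr_fit), float(td_fit), float(onset)


# ---------------------------------------------------------------------------
# reference conductances


def reference_from_point_model(time: np.ndarray, V: np.ndarray, c: float,
                               g_L: float, eps: float,
                               polarity_tag: str = "E") -> ConductanceTrace:
    """Invert the point-neuron equation on an unclamped somatic voltage.

    g_eff(t) = (c dV/dt + g_L V)/(eps - V) with centred finite differences
    (one-sided at the endpoints).  Samples where V crosses the reversal are
    masked to NaN with a warning.
    """
    time = np.asarray(time, dtype=float)
    V = np.asarray(V, dtype=float)
    dVdt = np.gradient(V, time)
    drive = eps - V
    bad = np.abs(drive) < 1e-9 * max(abs(eps), 1.0)
    if bad.any():
        warnings.warn(f"masked {int(bad.sum())} samples where the somatic "
                      "voltage reached the reversal potential", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (c * dVdt + g_L * V) / drive
    g[bad] = np.nan
    return ConductanceTrace(time.copy(), g, polarity_tag, "reference", eps)


def reference_from_intercept(iv: IVSeries, eps: float,
                             polarity_tag: str = "E") -> ConductanceTrace:
    """For a single-polarity input the intercept is the effective reversal
    current, so g_eff(t) = b(t)/eps."""
    if eps == 0:
        raise SingularityError("eps must be nonzero")
    return ConductanceTrace(iv.time.copy(), iv.b / eps, polarity_tag,
                            "reference", eps)


# ---------------------------------------------------------------------------
# error metrics


def error_summary(est: ConductanceTrace, ref: ConductanceTrace) -> ErrorSummary:
    """Peak-amplitude and time-averaged relative errors.

    peak = |max(est) - max(ref)| / max(ref);
    time-averaged = integral |est - ref| dt / integral |ref| dt
    (ratio of integrals, so near-zero reference samples cannot blow up).
    """
    if len(est.time) != len(ref.time) or not np.allclose(est.time, ref.time):
        raise AlignmentError("estimate and reference do not share a time grid")
    ge = np.asarray(est.g, dtype=float)
    gr = np.asarray(ref.g, dtype=float)
    ok = np.isfinite(ge) & np.isfinite(gr)
    ge, gr, t = ge[ok], gr[ok], est.time[ok]
    ref_peak = gr.max()
    if ref_peak <= 0:
        raise ValueError("reference trace has non-positive peak")
    peak_err = abs(ge.max() - ref_peak) / ref_peak
    denom = np.trapezoid(np.abs(gr), t)
    tavg = np.trapezoid(np.abs(ge - gr), t) / denom
    return ErrorSummary(float(peak_err), float(tavg))
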