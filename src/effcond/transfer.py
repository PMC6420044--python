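"""Transfer resistances K_AB, somatic prefactor maps, and reciprocity.

K_AB (MΩ) is the steady-state voltage change at B per unit current injected
at A.  For a passive tree it is exactly symmetric (K_AB = K_BA); the ratio
K_XS/K_SS is the prefactor that attenuates a dendritic conductance as seen
from the soma and lies in (0, 1] with value 1 at the soma itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cable import CableModel, CurrentInjection, GatingChannel, simulate, \
    steady_state_solve

DEFAULT_PROBE_NA = 0.01


@dataclass
class TransferMatrix:
    """K[i][j] = voltage at sites[j] per unit current at sites[i] (MΩ)."""

    sites: list[int]
    K: np.ndarray
    probe_current: float
    method_tag: str  # "analytic-steady-state" | "simulated-small-signal"

    def __post_init__(self):
        if not np.isfinite(self.K).all():
            raise ValueError("transfer matrix entries must be finite")
        if self.K.shape[0] == self.K.shape[1] and \
                not (np.diag(self.K) > 0).all():
            raise ValueError("diagonal transfer resistances must be positive")

    def entry(self, site_from: int, site_to: int) -> float:
        return float(self.K[self.sites.index(site_from),
                            self.sites.index(site_to)])

    def to_frame(self, model: CableModel | None = None) -> pd.DataFrame:
        rows = []
        for i, si in enumerate(self.sites):
            for j, sj in enumerate(self.sites):
                row = {"site_from": si, "site_to": sj, "K_MOhm": self.K[i, j]}
                if model is not None:
                    row["distance_from_um"] = model.compartment_distance[si]
                    row["distance_to_um"] = model.compartment_distance[sj]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path, model: CableModel | None = None) -> None:
        self.to_frame(model).to_csv(path, index=False)


@dataclass
class PrefactorMap:
    """Per-compartment K_XS/K_SS with the matching soma path distance."""

    ratio: np.ndarray
    distance: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.ratio[np.argmin(self.distance)], 1.0):
            raise ValueError("prefactor at the soma must be 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_um": self.distance,
                             "K_XS_over_K_SS": self.ratio})


def measure_transfer_matrix(model: CableModel,
                            sites: list[int],
                            probe_current: float = DEFAULT_PROBE_NA,
                            channels: list[GatingChannel] | None = None,
                            step_duration: float = 500.0,
                            dt: float = 0.1) -> TransferMatrix:
    """Measure K between all pairs of ``sites``.

    Passive models use the exact steady-state solve.  Active models inject a
    small current step and average the voltage deflection over the last 20%
    of a ``step_duration`` window (against a no-input baseline run), which
    must be long enough for gating variables to settle.
    """
    if probe_current <= 0:
        raise ValueError("probe_current must be positive")
    n = model.n_compartments
    for s in sites:
        if not 0 <= s < n:
            raise ValueError(f"site {s} out of range")

    m = len(sites)
    K = np.empty((m, m))
    if not channels:
        for i, si in enumerate(sites):
            v = steady_state_solve(model, {si: probe_current})
            K[i] = v[list(sites)] / probe_current
        return TransferMatrix(list(sites), K, probe_current,
                              "analytic-steady-state")

    import copy

    window = slice(int(0.8 * (step_duration / dt)), None)
    base = simulate(model, channels=copy.deepcopy(channels),
                    duration=step_duration, dt=dt)
    v_base = base.voltage[:, window].mean(axis=1)
    if np.abs(base.voltage[:, window] - v_base[:, None]).max() > 1e-3:
        raise RuntimeError("active model failed to reach steady state "
                           "within the probe window")
    for i, si in enumerate(sites):
        tr = simulate(model,
                      injections=[CurrentInjection(si, probe_current)],
                      channels=copy.deepcopy(channels),
                      duration=step_duration, dt=dt)
        v = tr.voltage[:, window].mean(axis=1) - v_base
        if np.abs(tr.voltage[:, window]
                  - tr.voltage[:, window].mean(axis=1, keepdims=True)).max() > 1e-3:
            raise RuntimeError("active model failed to reach steady state "
                               "within the probe window")
        K[i] = v[list(sites)] / probe_current
    return TransferMatrix(list(sites), K, probe_current,
                          "simulated-small-signal")


def prefactor_map(model: CableModel,
                  probe_current: float = DEFAULT_PROBE_NA) -> PrefactorMap:
    """K_XS/K_SS for every compartment X of a passive tree.

    By reciprocity a single somatic injection suffices: K_XS = K_SX =
    V_X / I for current injected at the soma.
    """
    v = steady_state_solve(model, {model.soma_index: probe_current})
    ratio = v / v[model.soma_index]
    return PrefactorMap(ratio=ratio, distance=model.compartment_distance.copy())


def reciprocity_deviation(K: TransferMatrix | np.ndarray) -> float:
    """Max over pairs of |K_ij - K_ji| / max(|K_ij|, |K_ji|)."""
    M = K.K if isinstance(K, TransferMatrix) else np.asarray(K, dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError("transfer matrix must be square")
    denom = np.maximum(np.abs(M), np.abs(M.T))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(M - M.T) / denom
    rel[denom == 0] = 0.0
    return float(rel.max()) if rel.size else 0.0
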