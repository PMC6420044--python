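"""Closed-form static theory of conductance measurement under somatic clamp.

A neuron receiving constant E and I conductances on the dendrite while the
soma is voltage-clamped behaves, at steady state, as a three-port resistive
network parameterized by the transfer resistances K_EE, K_II, K_SS, K_ES,
K_IS, K_EI.  This module evaluates:

* the effective conductance — the conductance the soma actually sees,
  g_eff = V_S / (K_SS (eps - V_S)), proportional to the local dendritic
  conductance to first order with prefactor K_qS/K_SS;
* the exact somatic voltage and measured synaptic current for arbitrary
  injected current, and the exact linear I-V relation I_syn = -k V_S + b;
* the slope-and-intercept method (SIM: k = gE + gI, b = gE epsE + gI epsI)
  and the intercept method (IM: two intercepts at two inhibitory
  reversals), with SIM's closed-form error laws in the co-located case;
* the witness that no transform can map SIM output onto the local
  conductance (slope and intercept constrain the same Taylor coefficient to
  two different values whenever K_qS differs from K_SS).

Units: μS·mV = nA throughout; resistances in MΩ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import SingularityError


@dataclass(frozen=True)
class TwoPortParams:
    """Transfer resistances (MΩ) and reversal potentials (mV rel. rest).

    Symmetry of the underlying passive network is assumed: K_SE = K_ES,
    K_SI = K_IS, K_IE = K_EI.
    """

    K_EE: float
    K_II: float
    K_SS: float
    K_ES: float
    K_IS: float
    K_EI: float
    eps_E: float = 70.0
    eps_I: float = -10.0

    def __post_init__(self):
        if not self.K_SS > 0:
            raise ValueError("K_SS must be positive")

    @property
    def K_EIS(self) -> float:
        """Composite third-order resistance entering the exact I-V line."""
        return (self.K_EE * self.K_II * self.K_SS
                + 2 * self.K_EI * self.K_ES * self.K_IS
                - self.K_ES ** 2 * self.K_II
                - self.K_IS ** 2 * self.K_EE
                - self.K_EI ** 2 * self.K_SS)

    @classmethod
    def co_located(cls, alpha: float, K_SS: float, K_local: float,
                   eps_E: float = 70.0, eps_I: float = -10.0) -> "TwoPortParams":
        """E and I at the same dendritic site: K_ES = K_IS = alpha K_SS and
        K_EE = K_II = K_EI = K_local."""
        return cls(K_EE=K_local, K_II=K_local, K_ES=alpha * K_SS,
                   K_IS=alpha * K_SS, K_EI=K_local, K_SS=K_SS,
                   eps_E=eps_E, eps_I=eps_I)

    @classmethod
    def from_transfer(cls, tm, e_site: int, i_site: int, soma_site: int,
                      eps_E: float = 70.0, eps_I: float = -10.0) -> "TwoPortParams":
        """Build from a measured :class:`~effcond.transfer.TransferMatrix`."""
        return cls(
            K_EE=tm.entry(e_site, e_site),
            K_II=tm.entry(i_site, i_site),
            K_SS=tm.entry(soma_site, soma_site),
            K_ES=tm.entry(e_site, soma_site),
            K_IS=tm.entry(i_site, soma_site),
            K_EI=tm.entry(e_site, i_site),
            eps_E=eps_E, eps_I=eps_I,
        )


class IVLine(NamedTuple):
    """Linear I-V relation I_syn = -k V_S + b."""

    k: float  # μS
    b: float  # nA


class SimSolution(NamedTuple):
    g_E: float
    g_I: float
    negative: bool  # unphysical negativity — the diagnostic of SIM failure


# ---------------------------------------------------------------------------
# effective conductance


def effective_conductance_exact(g: float, K_qS: float, K_SS: float,
                                K_qq: float, eps_q: float) -> float:
    """Exact effective conductance for a single constant input.

    V_S = g K_qS eps_q / (1 + g K_qq), then g_eff = V_S / (K_SS (eps_q - V_S)).
    For an input at the soma (K_qS = K_qq = K_SS) this returns g exactly.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    if g == 0:
        return 0.0
    denom = 1.0 + g * K_qq
    if denom == 0:
        raise SingularityError("1 + g K_qq vanishes")
    v_s = g * K_qS * eps_q / denom
    drive = eps_q - v_s
    if drive == 0:
        raise SingularityError("somatic voltage reached the reversal potential")
    return v_s / (K_SS * drive)


def first_order_expansion_error(x: float) -> float:
    """Relative error of the first-order expansion of 1/(1-x), i.e. x².

    ``x`` is the ratio V_S/eps of the somatic deflection to the synaptic
    reversal potential; at x = 0.3 (a -3 mV IPSP against a -10 mV reversal)
    the truncation error is 0.09.
    """
    x = float(x)
    if not abs(x) < 1:
        raise ValueError("|x| must be < 1")
    return 1.0 - (1.0 + x) * (1.0 - x)


# ---------------------------------------------------------------------------
# exact three-port algebra


def _denominator(p: TwoPortParams, gE: float, gI: float) -> float:
    d = (1.0 + gE * p.K_EE + gI * p.K_II
         + gE * gI * (p.K_EE * p.K_II - p.K_EI ** 2))
    if d == 0:
        raise SingularityError("three-port denominator vanishes")
    return d


def exact_soma_voltage(p: TwoPortParams, gE: float, gI: float,
                       I_inj: float) -> float:
    """Exact clamped/unclamped somatic voltage of the three-port system."""
    d = _denominator(p, gE, gI)
    syn_part = (gE * p.eps_E * (p.K_ES + gI * (p.K_ES * p.K_II
                                               - p.K_EI * p.K_IS))
                + gI * p.eps_I * (p.K_IS + gE * (p.K_IS * p.K_EE
                                                 - p.K_EI * p.K_ES)))
    inj_part = I_inj * (p.K_SS
                        + gE * (p.K_EE * p.K_SS - p.K_ES ** 2)
                        + gI * (p.K_II * p.K_SS - p.K_IS ** 2))
    cross = I_inj * gE * gI * (p.K_ES ** 2 * p.K_II
                               + p.K_EE * p.K_IS ** 2
                               + p.K_EI ** 2 * p.K_SS
                               - p.K_EE * p.K_II * p.K_SS
                               - 2 * p.K_EI * p.K_ES * p.K_IS)
    return (syn_part + inj_part - cross) / d


def exact_syn_current(p: TwoPortParams, gE: float, gI: float,
                      I_inj: float) -> float:
    """Measured synaptic current I_syn = V_S/K_SS - I_inj, exactly.

    The I_inj coefficient exhibits the nonlinear interaction between the
    clamp current and the dendritic synaptic current.
    """
    return exact_soma_voltage(p, gE, gI, I_inj) / p.K_SS - I_inj


def iv_line_exact(p: TwoPortParams, gE: float, gI: float) -> IVLine:
    """Full-order slope and intercept of I_syn = -k V_S + b."""
    denom = (p.K_SS
             + gE * (p.K_EE * p.K_SS - p.K_ES ** 2)
             + gI * (p.K_II * p.K_SS - p.K_IS ** 2)
             + gE * gI * p.K_EIS)
    if denom == 0:
        raise SingularityError("I-V line denominator vanishes")
    k = (gE * p.K_ES ** 2 + gI * p.K_IS ** 2
         + gE * gI * (p.K_ES ** 2 * p.K_II + p.K_IS ** 2 * p.K_EE
                      - 2 * p.K_EI * p.K_ES * p.K_IS)) / (p.K_SS * denom)
    b = (gE * p.eps_E * p.K_ES + gI * p.eps_I * p.K_IS
         + gE * gI * (p.eps_E * (p.K_ES * p.K_II - p.K_EI * p.K_IS)
                      + p.eps_I * (p.K_IS * p.K_EE - p.K_EI * p.K_ES))) / denom
    return IVLine(k=k, b=b)


def iv_line_first_order(p: TwoPortParams, gE: float, gI: float) -> IVLine:
    """First-order slope and intercept.

    k = (K_ES/K_SS)² gE + (K_IS/K_SS)² gI — the squared prefactors are why
    the slope is not the total conductance — and b = (K_ES/K_SS) gE eps_E +
    (K_IS/K_SS) gI eps_I, the effective reversal current.  For soma-located
    inputs both prefactors are 1 and the traditional relations re-emerge.
    """
    rE = p.K_ES / p.K_SS
    rI = p.K_IS / p.K_SS
    return IVLine(k=rE ** 2 * gE + rI ** 2 * gI,
                  b=rE * gE * p.eps_E + rI * gI * p.eps_I)


# ---------------------------------------------------------------------------
# solvers


def sim_solve(k: float, b: float, eps_E: float, eps_I: float) -> SimSolution:
    """Slope-and-intercept method: solve k = gE + gI, b = gE epsE + gI epsI.

    Negative outputs are returned un-clipped and flagged; unphysical
    negativity is the key diagnostic of space-clamp failure.
    """
    if eps_E == eps_I:
        raise SingularityError("eps_E must differ from eps_I")
    gE = (b - k * eps_I) / (eps_E - eps_I)
    gI = (k * eps_E - b) / (eps_E - eps_I)
    return SimSolution(gE, gI, negative=bool(gE < 0 or gI < 0))


def im_solve(b: float, b_prime: float, eps_E: float, eps_I: float,
             eps_I_prime: float) -> tuple[float, float]:
    """Intercept method: two intercepts at two inhibitory reversals.

    b = gE_eff epsE + gI_eff epsI and b' = gE_eff epsE + gI_eff epsI' give
    gI_eff = (b - b')/(epsI - epsI') and gE_eff = (b - gI_eff epsI)/epsE.
    """
    if eps_I == eps_I_prime:
        raise SingularityError("the two inhibitory reversals must differ")
    if eps_E == 0:
        raise SingularityError("eps_E must be nonzero")
    gI_eff = (b - b_prime) / (eps_I - eps_I_prime)
    gE_eff = (b - gI_eff * eps_I) / eps_E
    return gE_eff, gI_eff


def sim_error_prediction(k: float, alpha: float, eps_E: float,
                         eps_I: float) -> tuple[float, float]:
    """Closed-form SIM errors for co-located inputs with prefactor alpha.

    dgE = k epsI (1 - 1/alpha)/(epsI - epsE) and
    dgI = k epsE (1 - 1/alpha)/(epsE - epsI); both are <= 0 for alpha <= 1
    (SIM always under-estimates) and dgE : dgI = -epsI : epsE identically.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    factor = 1.0 - 1.0 / alpha
    dgE = k * eps_I * factor / (eps_I - eps_E)
    dgI = k * eps_E * factor / (eps_E - eps_I)
    return dgE, dgI


class TransformWitness(NamedTuple):
    F1_slope: float
    F1_intercept: float
    G1_slope: float
    G1_intercept: float

    @property
    def contradiction(self) -> bool:
        """True when no transform local->measured conductance can exist."""
        return not math.isclose(self.F1_slope, self.F1_intercept,
                                rel_tol=0.0, abs_tol=1e-15)


def no_transform_witness(p: TwoPortParams) -> TransformWitness:
    """First-order Taylor coefficients forced by the slope vs the intercept.

    The slope equation forces F1 = (K_ES/K_SS)² while the intercept forces
    F1 = K_ES/K_SS (and likewise G1 for inhibition); off the soma the two
    disagree, so no transform between local and SIM-measured conductance
    exists.
    """
    rE = p.K_ES / p.K_SS
    rI = p.K_IS / p.K_SS
    return TransformWitness(F1_slope=rE ** 2, F1_intercept=rE,
                            G1_slope=rI ** 2, G1_intercept=rI)


# ---------------------------------------------------------------------------
# independent numerical oracle (used by the tests, kept here so the CLI can
# expose a self-check; solves the raw three-port equations as a linear
# system without any of the closed forms above)


def solve_three_port_numeric(p: TwoPortParams, gE: float, gI: float,
                             I_inj: float) -> tuple[float, float, float]:
    """Solve the raw port equations numerically; returns (V_S, I_E, I_I).

    Unknowns are the two synaptic currents: I_q = g_q (eps_q - V_q) with
    V_E, V_I, V_S linear in (I_E, I_I, I_inj) through the K matrix.
    """
    A = np.array([
        [1.0 + gE * p.K_EE, gE * p.K_EI],
        [gI * p.K_EI, 1.0 + gI * p.K_II],
    ])
    rhs = np.array([
        gE * (p.eps_E - p.K_ES * I_inj),
        gI * (p.eps_I - p.K_IS * I_inj),
    ])
    I_E, I_I = np.linalg.solve(A, rhs)
    V_S = p.K_ES * I_E + p.K_IS * I_I + p.K_SS * I_inj
    return float(V_S), float(I_E), float(I_I)
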