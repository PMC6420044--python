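"""Packaged synthetic neuron fixtures and canonical synaptic kernels.

These stand-ins are synthetic morphologies generated in code; no archive
reconstruction is bundled.  The long-stick neuron is sized so that the
somatic prefactor K_XS/K_SS spans roughly 0.95 near the soma down to ~0.25
at the distal end of the main dendrite — the regime in which the
slope-and-intercept method visibly fails — while the side branches load the
soma to keep input resistances physiological.
"""

from __future__ import annotations

import numpy as np

from .cable import CableModel, discretize
from .morphology import (MorphNode, Morphology, PassiveParams, ROOT_PARENT,
                         build_ball_and_stick, build_random_tree)

# canonical double-exponential kernels: (tau_rise ms, tau_decay ms, peak μS)
E_KERNEL = (5.0, 7.8, 2.5e-3)   # AMPA-like, 2.5 nS
I_KERNEL = (6.0, 18.0, 4.0e-3)  # GABA_A-like, 4 nS

# reversal potentials relative to a -70 mV rest
EPS_E = 70.0          # AMPA at 0 mV absolute
EPS_I = -10.0         # GABA_A at -80 mV absolute
EPS_I_PRIME = -20.0   # GABA_A shifted to -90 mV absolute

# five clamp levels, -90..-50 mV absolute
HOLDING_LEVELS = (-20.0, -10.0, 0.0, 10.0, 20.0)


def point_neuron(soma_diameter: float = 20.0,
                 passive: PassiveParams | None = None) -> CableModel:
    """Single-compartment model: the regime where SIM is exact."""
    m = build_ball_and_stick(soma_diameter, 0.0, 1.0, passive)
    return discretize(m, max_segment_length=20.0)


def long_stick_morphology(main_length: float = 2600.0,
                          main_diameter: float = 4.0,
                          side_length: float = 400.0,
                          side_diameter: float = 3.0,
                          n_side: int = 5,
                          soma_diameter: float = 20.0,
                          passive: PassiveParams | None = None) -> Morphology:
    """Soma with one long thin main dendrite plus loading side branches."""
    nodes = [MorphNode(0, ROOT_PARENT, 0.0, 0.0, 0.0, soma_diameter / 2,
                       "soma")]
    spacing = 50.0

    def add_stick(direction, length, radius):
        n_pts = max(1, int(np.ceil(length / spacing)))
        parent = 0
        for i in range(1, n_pts + 1):
            pos = np.asarray(direction) * (length * i / n_pts)
            nodes.append(MorphNode(len(nodes), parent, *pos, radius,
                                   "dendrite"))
            parent = len(nodes) - 1

    add_stick([1.0, 0.0, 0.0], main_length, main_diameter / 2)
    angles = np.linspace(0, 2 * np.pi, n_side, endpoint=False) + np.pi / 2
    for th in angles:
        add_stick([np.cos(th), np.sin(th), 0.0], side_length,
                  side_diameter / 2)
    return Morphology(nodes, passive or PassiveParams())


def long_stick_neuron(max_segment_length: float = 40.0,
                      **kwargs) -> CableModel:
    return discretize(long_stick_morphology(**kwargs), max_segment_length)


# packaged scan distances along the main dendrite (μm) and the conductance
# amplitudes used for location scans: single-synapse-scale 0.3/0.48 nS
# (keeping the 1:1.6 E:I ratio of the canonical kernels) so a pair of
# inputs stays in the regime where the effective conductance is first-order
# in the local conductance and scan errors isolate the estimator mechanism
# rather than strong-shunt corrections
SCAN_DISTANCES = (100.0, 800.0, 1600.0, 2400.0)
SCAN_PEAKS = (0.3e-3, 0.48e-3)


def branched_neuron(seed: int = 7, depth: int = 3, branch_prob: float = 0.5,
                    max_segment_length: float = 20.0,
                    passive: PassiveParams | None = None) -> CableModel:
    """Small random branched tree for scans needing non-trivial topology."""
    m = build_random_tree(depth, branch_prob, seed, passive)
    return discretize(m, max_segment_length)
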