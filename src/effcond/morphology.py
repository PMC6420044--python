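"""Neuron morphologies: SWC I/O, synthetic builders, and path distances.

A morphology is a rooted tree of 3-D points with radii, split into a soma
region and a dendritic region.  Distances are measured along the tree path
(the "zig-zag" convention), not as straight-line soma-to-site distances.
All coordinates and radii are in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import StructuralError, SWCParseError

ROOT_PARENT = -1

# SWC structure-type codes.  The analysis only distinguishes soma from
# dendrite, so every non-soma type (axon, apical, custom) maps to dendrite.
_SWC_SOMA = 1
_SWC_DENDRITE = 3


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane parameters.

    axial_resistivity : Ω·cm
    specific_capacitance : μF/cm²
    specific_leak_conductance : S/cm²
    leak_reversal : mV relative to rest (0 means leak pulls toward rest)
    """

    axial_resistivity: float = 150.0
    specific_capacitance: float = 1.0
    specific_leak_conductance: float = 5e-5
    leak_reversal: float = 0.0

    def __post_init__(self):
        for name in ("axial_resistivity", "specific_capacitance",
                     "specific_leak_conductance"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not math.isfinite(self.leak_reversal):
            raise ValueError("leak_reversal must be finite")


@dataclass(frozen=True)
class MorphNode:
    """One point of the morphology tree; ``parent_id`` is -1 at the root."""

    id: int
    parent_id: int
    x: float
    y: float
    z: float
    radius: float
    region_tag: str  # "soma" | "dendrite"
    label: int | None = None  # original SWC id, if loaded from file

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"node {self.id}: radius must be positive")
        if self.region_tag not in ("soma", "dendrite"):
            raise ValueError(f"node {self.id}: unknown region {self.region_tag!r}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Morphology:
    """Rooted tree of :class:`MorphNode` plus passive membrane parameters.

    Nodes are stored in topological order (parent before child) with
    contiguous ids 0..n-1.  Exactly one root; the soma region is non-empty.
    """

    nodes: list[MorphNode]
    passive: PassiveParams = field(default_factory=PassiveParams)

    def __post_init__(self):
        ids = [n.id for n in self.nodes]
        if ids != list(range(len(self.nodes))):
            raise StructuralError("node ids must be contiguous 0..n-1 in order")
        roots = [n for n in self.nodes if n.parent_id == ROOT_PARENT]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root, found {len(roots)}")
        for n in self.nodes:
            if n.parent_id != ROOT_PARENT and not (0 <= n.parent_id < n.id):
                raise StructuralError(
                    f"node {n.id}: parent {n.parent_id} does not precede it"
                )
        if not any(n.region_tag == "soma" for n in self.nodes):
            raise StructuralError("morphology has no soma node")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> MorphNode:
        return self.nodes[0]

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != ROOT_PARENT:
                out[n.parent_id].append(n.id)
        return out

    def edges(self) -> list[tuple[int, int]]:
        return [(n.parent_id, n.id) for n in self.nodes if n.parent_id != ROOT_PARENT]

    def edge_length(self, child_id: int) -> float:
        child = self.nodes[child_id]
        parent = self.nodes[child.parent_id]
        return float(np.linalg.norm(child.position - parent.position))

    def with_passive(self, passive: PassiveParams) -> "Morphology":
        return Morphology(list(self.nodes), passive)


def path_distance(m: Morphology, a: int, b: int) -> float:
    """Length (μm) of the unique tree path between nodes ``a`` and ``b``.

    Sums 3-D segment lengths, so a tortuous dendrite measures longer than
    its straight-line extent.  Symmetric in its arguments.
    """
    n = len(m.nodes)
    for node_id in (a, b):
        if not 0 <= node_id < n:
            raise KeyError(f"unknown node id {node_id}")
    # depth-accumulated distance to root, then lowest common ancestor
    dist_to_root = _root_distances(m)
    pa, pb = a, b
    seen = set()
    while pa != ROOT_PARENT:
        seen.add(pa)
        pa = m.nodes[pa].parent_id
    lca = b
    while lca not in seen:
        lca = m.nodes[lca].parent_id
    return dist_to_root[a] + dist_to_root[b] - 2.0 * dist_to_root[lca]


def _root_distances(m: Morphology) -> np.ndarray:
    d = np.zeros(len(m.nodes))
    for node in m.nodes[1:]:
        d[node.id] = d[node.parent_id] + m.edge_length(node.id)
    return d


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path, passive: PassiveParams | None = None) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Columns: id, type, x, y, z, radius, parent; '#' starts a comment.  Type 1
    is soma; every other type is treated as dendrite.  Node ids are remapped
    to contiguous topological order; original ids are kept as ``label``.
    """
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"expected 7 columns, found {len(parts)}", lineno)
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"non-numeric field ({exc})", lineno) from None
            if nid in rows:
                raise SWCParseError(f"duplicate node id {nid}", lineno)
            rows[nid] = (ntype, x, y, z, radius, parent)

    if not rows:
        raise SWCParseError("file contains no data rows")

    roots = [nid for nid, r in rows.items() if r[5] == ROOT_PARENT]
    if len(roots) != 1:
        raise StructuralError(f"expected exactly one root, found {len(roots)}")
    children: dict[int, list[int]] = {nid: [] for nid in rows}
    for nid, r in rows.items():
        parent = r[5]
        if parent == ROOT_PARENT:
            continue
        if parent not in rows:
            raise StructuralError(f"node {nid}: parent {parent} does not exist")
        children[parent].append(nid)

    # breadth-first remap; unreached nodes imply a cycle among themselves
    order: list[int] = []
    queue = [roots[0]]
    while queue:
        nid = queue.pop(0)
        order.append(nid)
        queue.extend(sorted(children[nid]))
    if len(order) != len(rows):
        raise StructuralError("graph contains a cycle (nodes unreachable from root)")

    new_id = {nid: i for i, nid in enumerate(order)}
    nodes = []
    for nid in order:
        ntype, x, y, z, radius, parent = rows[nid]
        nodes.append(MorphNode(
            id=new_id[nid],
            parent_id=ROOT_PARENT if parent == ROOT_PARENT else new_id[parent],
            x=x, y=y, z=z, radius=radius,
            region_tag="soma" if ntype == _SWC_SOMA else "dendrite",
            label=nid,
        ))
    return Morphology(nodes, passive or PassiveParams())


def write_swc(m: Morphology, path) -> None:
    """Write the morphology as standard 7-column SWC (ids are 1-based)."""
    with open(path, "w") as fh:
        fh.write("# exported by effcond\n")
        fh.write("# id type x y z radius parent\n")
        for n in m.nodes:
            ntype = _SWC_SOMA if n.region_tag == "soma" else _SWC_DENDRITE
            parent = ROOT_PARENT if n.parent_id == ROOT_PARENT else n.parent_id + 1
            fh.write(f"{n.id + 1} {ntype} {n.x:.17g} {n.y:.17g} {n.z:.17g} "
                     f"{n.radius:.17g} {parent}\n")


# ---------------------------------------------------------------------------
# Synthetic builders


def build_ball_and_stick(
    soma_diameter: float,
    stick_length: float,
    stick_diameter: float,
    passive: PassiveParams | None = None,
    node_spacing: float = 20.0,
) -> Morphology:
    """Spherical soma with one unbranched cylindrical dendrite.

    A stick of length zero gives a soma-only morphology.  The stick runs
    along +x with nodes at most ``node_spacing`` μm apart.
    """
    if soma_diameter <= 0 or stick_diameter <= 0 or stick_length < 0:
        raise ValueError("geometry must be positive (stick_length may be zero)")
    if node_spacing <= 0:
        raise ValueError("node_spacing must be positive")
    nodes = [MorphNode(0, ROOT_PARENT, 0.0, 0.0, 0.0, soma_diameter / 2, "soma")]
    if stick_length > 0:
        n_pts = max(1, math.ceil(stick_length / node_spacing))
        for i in range(1, n_pts + 1):
            nodes.append(MorphNode(
                i, i - 1, stick_length * i / n_pts, 0.0, 0.0,
                stick_diameter / 2, "dendrite"))
    return Morphology(nodes, passive or PassiveParams())


def build_random_tree(
    depth: int,
    branch_prob: float,
    seed: int,
    passive: PassiveParams | None = None,
    segment_length: float = 120.0,
    trunk_diameter: float = 2.0,
    taper: float = 0.8,
    soma_diameter: float = 20.0,
    points_per_segment: int = 3,
    wiggle: float = 0.35,
) -> Morphology:
    """Random branched dendritic tree, reproducible for a fixed seed.

    Starting from a single trunk, each growing tip either bifurcates (with
    probability ``branch_prob``) or continues unbranched, for ``depth``
    levels.  Daughter diameters shrink by ``taper`` per level and segment
    directions jitter by ``wiggle`` radians to mimic dendritic tortuosity.
    With ``depth=1, branch_prob=0`` this reduces to a ball-and-stick.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= branch_prob <= 1.0:
        raise ValueError("branch_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [MorphNode(0, ROOT_PARENT, 0.0, 0.0, 0.0, soma_diameter / 2, "soma")]

    # each tip: (attach node id, unit direction, radius)
    tips = [(0, np.array([1.0, 0.0, 0.0]), trunk_diameter / 2)]
    for _ in range(depth):
        new_tips = []
        for attach, direction, radius in tips:
            n_daughters = 2 if rng.random() < branch_prob else 1
            for _ in range(n_daughters):
                d = _jitter(direction, wiggle, rng)
                parent = attach
                step = segment_length / points_per_segment
                pos = nodes[attach].position
                for _ in range(points_per_segment):
                    d = _jitter(d, wiggle / 2, rng)
                    pos = pos + d * step
                    node = MorphNode(len(nodes), parent, *pos, radius, "dendrite")
                    nodes.append(node)
                    parent = node.id
                new_tips.append((parent, d, max(radius * taper, 0.25)))
        tips = new_tips
    return Morphology(nodes, passive or PassiveParams())


def _jitter(direction: np.ndarray, angle: float, rng: np.random.Generator):
    if angle <= 0:
        return direction
    perturbed = direction + rng.normal(scale=angle, size=3)
    return perturbed / np.linalg.norm(perturbed)


def n_leaves(m: Morphology) -> int:
    """Number of terminal dendritic tips (nodes without children)."""
    has_child = {n.id: False for n in m.nodes}
    for n in m.nodes:
        if n.parent_id != ROOT_PARENT:
            has_child[n.parent_id] = True
    return sum(1 for n in m.nodes
               if n.region_tag == "dendrite" and not has_child[n.id])
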