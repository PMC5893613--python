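"""Synthetic morphologies and receptive fields with VS-like statistics.

These generators make every pipeline stage testable without downloads:
analytic fixtures (cylinders, Rall-matched binary trees), branched VS-like
trees whose summary morphometrics fall in the range of real vertical-system
cells, branchlet receptive fields obeying the measured magnitude structure
(one or two dominant vectors > 0.7 and the bulk of vectors < 0.4 after
max-normalization, with a dorso-ventral retinotopy), and a forward model
that produces a ground-truth axonal field from known weights and filtering.

All generators are pure functions of (spec, seed): identical inputs give
byte-identical SWC/CSV artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphology import (
    Morphology,
    STRUCT_DENDRITE,
    STRUCT_SOMA,
)
from .receptive_field import ReceptiveField, normalize
from .integration import predict_axonal_rf

__all__ = [
    "SynthMorphSpec",
    "SynthRFSpec",
    "make_cylinder",
    "make_binary_tree",
    "make_vs_like_tree",
    "visual_field_grid",
    "make_branchlet_rfs",
    "make_ground_truth_axon",
]


# ---------------------------------------------------------------------------
# Morphologies
# ---------------------------------------------------------------------------

def make_cylinder(
    diameter_um: float, length_um: float, n_nodes: int = 11, struct: int = STRUCT_DENDRITE
) -> Morphology:
    """Unbranched constant-diameter cable along +x (analytic-oracle fixture)."""
    if diameter_um <= 0 or length_um <= 0:
        raise ValueError("diameter and length must be positive")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    xs = np.linspace(0.0, length_um, n_nodes)
    ids = np.arange(1, n_nodes + 1)
    return Morphology(
        ids=ids,
        struct=np.full(n_nodes, struct),
        xyz=np.column_stack([xs, np.zeros(n_nodes), np.zeros(n_nodes)]),
        radius=np.full(n_nodes, diameter_um / 2.0),
        parent=np.concatenate([[-1], ids[:-1]]),
        name=f"cylinder_d{diameter_um:g}_l{length_um:g}",
    )


def make_binary_tree(
    depth: int,
    branch_length_um: float | list[float] = 100.0,
    root_diameter_um: float = 2.0,
    rall: bool = True,
    seed: int = 0,
) -> Morphology:
    """Full binary tree: the root node carries two subtrees of the given depth.

    With ``rall=True`` child diameters obey the 3/2-power matching rule
    d_parent^{3/2} = Σ d_child^{3/2}, so the whole tree reduces to an
    equivalent cylinder (Rall reduction). ``branch_length_um`` may be a
    per-level list. A depth-d tree has 2^d terminals and 2^{d+1} − 2
    branchlets. Deterministic per seed (the seed only perturbs layout angles).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    lengths = (
        [float(branch_length_um)] * depth
        if np.isscalar(branch_length_um)
        else list(branch_length_um)
    )
    if len(lengths) != depth:
        raise ValueError("need one branch length per level")
    rng = np.random.default_rng(seed)
    taper = 2.0 ** (-2.0 / 3.0) if rall else 1.0

    ids = [1]
    struct = [STRUCT_DENDRITE]
    xyz = [(0.0, 0.0, 0.0)]
    radius = [root_diameter_um / 2.0]
    parent = [-1]

    def add(pid: int, pos: tuple[float, float, float], d: float) -> int:
        nid = len(ids) + 1
        ids.append(nid)
        struct.append(STRUCT_DENDRITE)
        xyz.append(pos)
        radius.append(d / 2.0)
        parent.append(pid)
        return nid

    def grow(parent_id: int, level: int, angle: float, d: float) -> None:
        if level == depth:
            return
        spread = math.pi / (2.0 ** (level + 1))
        for sgn in (-1.0, 1.0):
            a = angle + sgn * spread / 2.0 + rng.normal(0.0, 0.01)
            px, py, _ = xyz[parent_id - 1]
            L = lengths[level]
            # coincident start node so the branch is a uniform cylinder of
            # diameter d (the zero-length lead-in segment carries no cable)
            start = add(parent_id, (px, py, 0.0), d)
            nid = add(start, (px + L * math.cos(a), py + L * math.sin(a), 0.0), d)
            grow(nid, level + 1, a, d * taper)

    grow(1, 0, 0.0, root_diameter_um * taper)
    return Morphology(
        ids=np.array(ids),
        struct=np.array(struct),
        xyz=np.array(xyz),
        radius=np.array(radius),
        parent=np.array(parent),
        name=f"binary_tree_depth{depth}",
    )


@dataclass(frozen=True)
class SynthMorphSpec:
    """Parameters of the VS-like tree generator.

    Defaults target the summary morphometrics of real VS cells: a few
    thousand μm of dendrite distributed over ~450 branchlets (~225
    terminals), a thick proximal trunk tapering to ~1 μm terminal branchlets.
    """

    n_terminals: int = 224
    trunk_length_um: tuple[float, float] = (80.0, 10.0)  # (mean, sd)
    branch_length_um: tuple[float, float] = (10.0, 3.0)
    proximal_diameter_um: float = 6.0
    terminal_diameter_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terminals < 2 or self.n_terminals % 2:
            raise ValueError("n_terminals must be an even count >= 2")
        if min(self.trunk_length_um[0], self.branch_length_um[0]) <= 0:
            raise ValueError("lengths must be positive")
        if not 0 < self.terminal_diameter_um <= self.proximal_diameter_um:
            raise ValueError("need 0 < terminal diameter <= proximal diameter")


def make_vs_like_tree(spec: SynthMorphSpec) -> Morphology:
    """Branched VS-like morphology: a somatic root with two main trunks
    (dorsal and ventral) whose terminals are ordered along the y axis, the
    dorso-ventral proxy. Binary branching, lognormal-ish branch lengths,
    geometric diameter taper with branch order. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    max_depth = max(1, math.ceil(math.log2(spec.n_terminals / 2)))
    taper = (spec.terminal_diameter_um / spec.proximal_diameter_um) ** (
        1.0 / (max_depth + 1)
    )

    ids = [1]
    struct = [STRUCT_SOMA]
    xyz = [(0.0, 0.0, 0.0)]
    radius = [spec.proximal_diameter_um / 2.0]
    parent = [-1]

    def draw(mean_sd: tuple[float, float]) -> float:
        mean, sd = mean_sd
        return float(max(0.2 * mean, rng.normal(mean, sd)))

    def add_node(pid: int, pos: tuple[float, float, float], d: float) -> int:
        nid = len(ids) + 1
        ids.append(nid)
        struct.append(STRUCT_DENDRITE)
        xyz.append(pos)
        radius.append(d / 2.0)
        parent.append(pid)
        return nid

    def grow(pid: int, n_term: int, depth: int, y_lo: float, y_hi: float) -> None:
        """Grow a branch from node pid toward the slot band [y_lo, y_hi]."""
        px, py, _ = xyz[pid - 1]
        target_y = 0.5 * (y_lo + y_hi)
        L = draw(spec.trunk_length_um if depth == 0 else spec.branch_length_um)
        dy = target_y - py
        dx = math.sqrt(max(L**2 - dy**2, (0.3 * L) ** 2))
        norm = math.hypot(dx, dy)
        pos = (px + L * dx / norm, py + L * dy / norm, 0.0)
        d = spec.proximal_diameter_um * taper ** (depth + 1)
        d = max(d, spec.terminal_diameter_um)
        nid = add_node(pid, pos, d)
        if n_term == 1:
            return
        n1 = n_term // 2
        y_mid = y_lo + (y_hi - y_lo) * n1 / n_term
        grow(nid, n1, depth + 1, y_lo, y_mid)
        grow(nid, n_term - n1, depth + 1, y_mid, y_hi)

    half = spec.n_terminals // 2
    # dorso-ventral extent per trunk, kept within reach of the branch lengths
    band = 0.9 * (spec.trunk_length_um[0] + max_depth * spec.branch_length_um[0])
    grow(1, half, 0, 10.0, band)  # dorsal trunk
    grow(1, half, 0, -band, -10.0)  # ventral trunk
    return Morphology(
        ids=np.array(ids),
        struct=np.array(struct),
        xyz=np.array(xyz),
        radius=np.array(radius),
        parent=np.array(parent),
        name=f"vs_like_seed{spec.seed}",
    )


# ---------------------------------------------------------------------------
# Receptive fields
# ---------------------------------------------------------------------------

def visual_field_grid(n_locations: int = 50) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared visual-field grid: ids ordered from dorsal (high elevation) to
    ventral. 50 locations lay out as 5 elevation rows × 10 azimuth columns."""
    n_rows = max(1, round(math.sqrt(n_locations / 2)))
    n_cols = math.ceil(n_locations / n_rows)
    el_rows = np.linspace(45.0, -45.0, n_rows)
    az_cols = np.linspace(-150.0, 150.0, n_cols)
    ids, az, el = [], [], []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if k >= n_locations:
                break
            ids.append(k + 1)
            el.append(el_rows[r])
            az.append(az_cols[c])
            k += 1
    return np.array(ids), np.array(az), np.array(el)


@dataclass(frozen=True)
class SynthRFSpec:
    """Parameters of the branchlet receptive-field generator.

    Dominant vectors are drawn in (0.85, 1.0] and backgrounds in (0, 0.28],
    so that after max-normalization each field has exactly ``n_dominant``
    vectors above 0.7 and well over 80% of vectors below 0.4 — the magnitude
    structure reported for real branchlet fields. ``noise_sd`` is an angular
    jitter (radians) applied to every vector, which perturbs directions
    without touching the magnitude constraints. The retinotopy maps branchlet
    order monotonically onto the elevation axis of the grid (dorsal
    branchlets see the upper visual field).
    """

    n_branchlets: int = 13
    n_locations: int = 50
    n_dominant: int = 1
    dominant_range: tuple[float, float] = (0.85, 1.0)
    background_cap: float = 0.28
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dominant not in (1, 2):
            raise ValueError("n_dominant must be 1 or 2")
        if self.n_dominant > self.n_locations:
            raise ValueError("more dominant vectors than locations")
        if not 0 < self.background_cap < 0.7 * self.dominant_range[0]:
            raise ValueError("background cap too large for the >0.7 contract")


def make_branchlet_rfs(spec: SynthRFSpec) -> list[ReceptiveField]:
    """Generate normalized branchlet receptive fields per the spec."""
    rng = np.random.default_rng(spec.seed)
    ids, az, el = visual_field_grid(spec.n_locations)
    rfs = []
    for b in range(spec.n_branchlets):
        # retinotopy: branchlet order -> grid index, monotone in elevation
        dom = int(math.floor(b * spec.n_locations / spec.n_branchlets))
        dom_idx = [dom]
        if spec.n_dominant == 2:
            dom_idx.append(dom + 1 if dom + 1 < spec.n_locations else dom - 1)
        mags = rng.uniform(1e-3, spec.background_cap, spec.n_locations)
        lo, hi = spec.dominant_range
        mags[dom_idx] = rng.uniform(lo, hi, len(dom_idx))
        angles = rng.uniform(0.0, 2.0 * math.pi, spec.n_locations)
        # coherent downward preferred direction at the dominant locations,
        # rotating slightly with elevation
        angles[dom_idx] = -math.pi / 2.0 + math.radians(el[dom] / 6.0)
        if spec.noise_sd > 0:
            angles = angles + rng.normal(0.0, spec.noise_sd, spec.n_locations)
        vec = mags[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
        rfs.append(
            normalize(
                ReceptiveField(
                    location_ids=ids,
                    azimuth_deg=az,
                    elevation_deg=el,
                    vectors=vec,
                    source_label=str(b + 1),
                )
            )
        )
    return rfs


def make_ground_truth_axon(
    rfs,
    weights,
    delta: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "axon",
) -> ReceptiveField:
    """Forward model: the predicted axonal field from known weights and δ,
    plus independent 2-D Gaussian vector noise, re-normalized. With
    ``noise_sd = 0`` this is exactly the noiseless prediction."""
    pred = predict_axonal_rf(rfs, weights, delta)
    if noise_sd == 0:
        return pred.with_vectors(pred.vectors, label=label)
    rng = np.random.default_rng(seed)
    noisy = pred.vectors + rng.normal(0.0, noise_sd, pred.vectors.shape)
    return normalize(pred.with_vectors(noisy, label=label))
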