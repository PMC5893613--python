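"""Steady-state passive cable model of a reconstructed neuron.

The morphology is discretized into iso-potential compartments connected by
axial conductances (one RC element per compartment, with the capacitance
dropped: only the steady state is solved). For a segment of diameter ``d``
and length ``l`` the membrane conductance is ``area / Rm`` and the axial
resistance is ``4 Ri l / (π d²)``. Solving the nodal balance ``G V = I`` on
the tree yields voltages everywhere for any set of injected currents, from
which input resistances, branchlet-to-axon transfer resistances and the
full pairwise transfer-resistance matrix follow.

Electrotonic distances are computed directly on the morphology as the path
integral of ``dx / λ(x)`` with the local space constant
``λ = sqrt(Rm d / (4 Ri))``.

Unit regime: geometry in μm at the interface, CGS (cm, Ω·cm) internally,
resistances reported in MΩ, voltages in mV, currents in nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import Morphology, enumerate_sections, enumerate_branchlets

__all__ = [
    "CableParams",
    "Locus",
    "ROOT_LOCUS",
    "CompartmentalModel",
    "build_model",
    "solve_steady_state",
    "input_resistance",
    "transfer_resistance",
    "transfer_resistance_matrix",
    "electrotonic_distance",
    "electrotonic_dendrogram",
    "space_constant_um",
    "default_axon_locus",
]

_UM_TO_CM = 1e-4
_UM2_TO_CM2 = 1e-8


@dataclass(frozen=True)
class CableParams:
    """Passive cable constants.

    rm_ohm_cm2 : specific membrane resistivity R_m (Ω·cm²), default 2,000.
    ri_ohm_cm : axial (cytoplasmic) resistivity R_i (Ω·cm), default 40.
    cm_uf_cm2 : specific capacitance; carried for completeness, unused in
        the steady-state solve.
    """

    rm_ohm_cm2: float = 2000.0
    ri_ohm_cm: float = 40.0
    cm_uf_cm2: float | None = None

    def __post_init__(self) -> None:
        if self.rm_ohm_cm2 <= 0 or self.ri_ohm_cm <= 0:
            raise ValueError("Rm and Ri must be positive")


@dataclass(frozen=True)
class Locus:
    """A position on the cell: a section (branchlet) id and a fraction of its
    arc length measured from the proximal attachment (0) to the distal end (1).
    Section id 0 denotes the root of the tree."""

    branchlet_id: int
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")


ROOT_LOCUS = Locus(0, 0.0)


def space_constant_um(params: CableParams, diameter_um: float) -> float:
    """Space constant λ in μm for a cylinder of the given diameter."""
    d_cm = diameter_um * _UM_TO_CM
    lam_cm = math.sqrt(params.rm_ohm_cm2 * d_cm / (4.0 * params.ri_ohm_cm))
    return lam_cm / _UM_TO_CM


# ---------------------------------------------------------------------------
# Section geometry shared by the discretizer and the electrotonic metrics
# ---------------------------------------------------------------------------

@dataclass
class _SectionGeom:
    id: int
    parent: int  # parent section id (0 = root)
    node_path: tuple[int, ...]
    seg_len: np.ndarray  # μm per inter-node segment
    seg_diam: np.ndarray  # mean endpoint diameter per segment, μm
    seg_r0: np.ndarray  # proximal radius per segment, μm
    seg_r1: np.ndarray
    struct: int

    @property
    def length(self) -> float:
        return float(self.seg_len.sum())


def _section_geometry(m: Morphology) -> dict[int, _SectionGeom]:
    sections = enumerate_sections(m)
    owner: dict[int, int] = {}
    for s in sections:
        for node in s.node_path[1:]:
            owner[node] = s.id
    out: dict[int, _SectionGeom] = {}
    for s in sections:
        rows = [m.row(i) for i in s.node_path]
        pts = m.xyz[rows]
        r = m.radius[rows]
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        attach = s.node_path[0]
        out[s.id] = _SectionGeom(
            id=s.id,
            parent=0 if attach == m.root_id else owner[attach],
            node_path=s.node_path,
            seg_len=seg_len,
            seg_diam=r[:-1] + r[1:],
            seg_r0=r[:-1].copy(),
            seg_r1=r[1:].copy(),
            struct=s.struct,
        )
    return out


# ---------------------------------------------------------------------------
# Compartmental model
# ---------------------------------------------------------------------------

@dataclass
class CompartmentalModel:
    """Discretized electrical network on the morphological tree.

    Compartment arrays are parallel; branch points and the root are
    represented by explicit zero-area junction nodes so that connections
    through half-compartment axial resistances are exact. ``section_comps``
    maps a section id to its ordered compartment indices with arc-length
    centres, which backs the (branchlet, fraction) locus lookup.
    """

    params: CableParams
    comp_section: np.ndarray  # section id per compartment (0 for root junction)
    comp_arc: np.ndarray  # centre position along the section, μm
    comp_len: np.ndarray  # μm (0 for junctions)
    comp_diam: np.ndarray  # μm (mean diameter; 0 for junctions)
    comp_area_cm2: np.ndarray
    g_membrane: np.ndarray  # S per compartment
    edges: list[tuple[int, int, float]]  # (i, j, axial conductance S)
    section_comps: dict[int, tuple[np.ndarray, np.ndarray]]  # id -> (idx, arc)
    section_length: dict[int, float]
    junction_comp: dict[int, int]  # node id -> junction compartment index
    root_comp: int

    _lu: spla.SuperLU | None = field(default=None, repr=False)

    @property
    def n_compartments(self) -> int:
        return len(self.g_membrane)

    def conductance_matrix(self) -> sp.csc_matrix:
        n = self.n_compartments
        rows, cols, vals = [], [], []
        for i, j, g in self.edges:
            rows += [i, j, i, j]
            cols += [j, i, i, j]
            vals += [-g, -g, g, g]
        G = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        return G + sp.diags(self.g_membrane).tocsc()

    def _factor(self) -> spla.SuperLU:
        if self._lu is None:
            self._lu = spla.splu(self.conductance_matrix())
        return self._lu

    def solve(self, currents_A: np.ndarray) -> np.ndarray:
        """Voltages (V) for a vector of injected currents (A)."""
        return self._factor().solve(currents_A)

    def locus_to_comp(self, locus: "Locus | int") -> int:
        """Resolve a locus to the nearest compartment (junctions included)."""
        if isinstance(locus, (int, np.integer)):
            return int(locus)
        if locus.branchlet_id == 0:
            return self.root_comp
        if locus.branchlet_id not in self.section_comps:
            raise KeyError(f"unknown branchlet id {locus.branchlet_id}")
        idx, arc = self.section_comps[locus.branchlet_id]
        target = locus.fraction * self.section_length[locus.branchlet_id]
        k = int(np.argmin(np.abs(arc - target)))
        return int(idx[k])


def build_model(
    m: Morphology,
    params: CableParams,
    resolution_um: float | None = None,
) -> CompartmentalModel:
    """Discretize a morphology into a steady-state compartmental model.

    Each inter-node frustum is split so that compartment length does not
    exceed ``resolution_um`` (default: ``min(2 μm, λ_local / 50)`` computed
    per segment). Membrane conductance is lateral area / Rm; adjacent
    compartment centres are coupled through the sum of their half-compartment
    axial resistances, with explicit junction nodes at the root and at every
    branch point.
    """
    if resolution_um is not None and resolution_um <= 0:
        raise ValueError("resolution_um must be positive")
    geoms = _section_geometry(m)

    comp_section: list[int] = []
    comp_arc: list[float] = []
    comp_len: list[float] = []
    comp_diam: list[float] = []
    comp_area: list[float] = []
    edges: list[tuple[int, int, float]] = []
    section_comps: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    section_length: dict[int, float] = {}
    junction_comp: dict[int, int] = {}

    ri = params.ri_ohm_cm

    def new_comp(section: int, arc: float, length: float, diam: float, area_um2: float) -> int:
        comp_section.append(section)
        comp_arc.append(arc)
        comp_len.append(length)
        comp_diam.append(diam)
        comp_area.append(area_um2 * _UM2_TO_CM2)
        return len(comp_section) - 1

    def half_res(idx: int) -> float:
        # axial resistance of half a compartment, Ω
        l_cm = 0.5 * comp_len[idx] * _UM_TO_CM
        d_cm = comp_diam[idx] * _UM_TO_CM
        return 4.0 * ri * l_cm / (math.pi * d_cm**2)

    # root junction
    root = new_comp(0, 0.0, 0.0, 0.0, 0.0)
    junction_comp[m.root_id] = root

    # junctions at every section end that has children
    children_of: dict[int, list[int]] = {}
    for g in geoms.values():
        children_of.setdefault(g.parent, []).append(g.id)
    for g in geoms.values():
        if g.id in children_of:  # section end is a branch/transition point
            junction_comp.setdefault(
                g.node_path[-1], new_comp(g.id, g.length, 0.0, 0.0, 0.0)
            )

    for g in geoms.values():
        idx_list: list[int] = []
        arc0 = 0.0
        for k in range(len(g.seg_len)):
            L = float(g.seg_len[k])
            if L == 0.0:
                continue
            d = float(g.seg_diam[k])
            if resolution_um is None:
                res = min(2.0, space_constant_um(params, d) / 50.0)
            else:
                res = resolution_um
            n_sub = max(1, math.ceil(L / res))
            dl = L / n_sub
            r0, r1 = float(g.seg_r0[k]), float(g.seg_r1[k])
            for s_i in range(n_sub):
                ra = r0 + (r1 - r0) * (s_i / n_sub)
                rb = r0 + (r1 - r0) * ((s_i + 1) / n_sub)
                area = math.pi * (ra + rb) * dl  # frustum lateral area, μm²
                centre = arc0 + (s_i + 0.5) * dl
                idx_list.append(new_comp(g.id, centre, dl, ra + rb, area))
            arc0 += L
        if not idx_list:
            raise ValueError(
                f"section {g.id} received no compartments (zero length?)"
            )
        # chain within the section
        for a, b in zip(idx_list[:-1], idx_list[1:]):
            edges.append((a, b, 1.0 / (half_res(a) + half_res(b))))
        # proximal attachment junction
        attach = junction_comp[g.node_path[0]]
        edges.append((attach, idx_list[0], 1.0 / half_res(idx_list[0])))
        # distal junction, if this section ends at a branch point
        if g.node_path[-1] in junction_comp and junction_comp[g.node_path[-1]] != attach:
            edges.append(
                (idx_list[-1], junction_comp[g.node_path[-1]], 1.0 / half_res(idx_list[-1]))
            )
        arcs = np.array([comp_arc[i] for i in idx_list])
        section_comps[g.id] = (np.array(idx_list, dtype=int), arcs)
        section_length[g.id] = g.length

    area_arr = np.array(comp_area)
    model = CompartmentalModel(
        params=params,
        comp_section=np.array(comp_section, dtype=int),
        comp_arc=np.array(comp_arc),
        comp_len=np.array(comp_len),
        comp_diam=np.array(comp_diam),
        comp_area_cm2=area_arr,
        g_membrane=area_arr / params.rm_ohm_cm2,
        edges=edges,
        section_comps=section_comps,
        section_length=section_length,
        junction_comp=junction_comp,
        root_comp=root,
    )
    return model


# ---------------------------------------------------------------------------
# Steady-state solves
# ---------------------------------------------------------------------------

def solve_steady_state(
    model: CompartmentalModel, injections: Mapping[Locus | int, float]
) -> np.ndarray:
    """Steady-state voltage (mV) per compartment for current injections in nA.

    The nodal balance ``G V = I`` is linear, so superposition holds exactly.
    """
    if not injections:
        raise ValueError("at least one injection required")
    I = np.zeros(model.n_compartments)
    for locus, nA in injections.items():
        I[model.locus_to_comp(locus)] += nA * 1e-9
    return model.solve(I) * 1e3


def _resistance_column(model: CompartmentalModel, comp: int) -> np.ndarray:
    """Column of G⁻¹ in MΩ (voltage per unit injected current)."""
    e = np.zeros(model.n_compartments)
    e[comp] = 1.0
    return model.solve(e) / 1e6


def input_resistance(model: CompartmentalModel, locus: Locus | int) -> float:
    """V/I at the injection site, MΩ."""
    c = model.locus_to_comp(locus)
    return float(_resistance_column(model, c)[c])


def transfer_resistance(
    model: CompartmentalModel, locus_a: Locus | int, locus_b: Locus | int
) -> float:
    """Voltage at ``locus_b`` per unit current injected at ``locus_a``, MΩ.

    Symmetric in its arguments for a passive network (reciprocity).
    """
    ca = model.locus_to_comp(locus_a)
    cb = model.locus_to_comp(locus_b)
    return float(_resistance_column(model, ca)[cb])


def transfer_resistance_matrix(
    model: CompartmentalModel, loci: Sequence[Locus | int]
) -> np.ndarray:
    """Pairwise transfer-resistance matrix (MΩ); diagonal = input resistances.

    One sparse solve per locus on the shared factorization.
    """
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    comps = [model.locus_to_comp(l) for l in loci]
    cols = np.column_stack([_resistance_column(model, c) for c in comps])
    return cols[comps, :]


# ---------------------------------------------------------------------------
# Electrotonic distance (on the morphology, not the discretization)
# ---------------------------------------------------------------------------

def _section_x(geom: _SectionGeom, params: CableParams) -> np.ndarray:
    """Per-segment electrotonic increments Δ(x/λ) for one section."""
    lam = np.array([space_constant_um(params, d) for d in geom.seg_diam])
    return geom.seg_len / lam


def _locus_x(
    geoms: dict[int, _SectionGeom],
    x_start: dict[int, float],
    params: CableParams,
    locus: Locus,
) -> float:
    if locus.branchlet_id == 0:
        return 0.0
    g = geoms[locus.branchlet_id]
    target = locus.fraction * g.length
    x = x_start[g.id]
    run = 0.0
    for L, dX in zip(g.seg_len, _section_x(g, params)):
        if L == 0:
            continue
        if run + L >= target:
            x += dX * (target - run) / L
            return x
        x += dX
        run += L
    return x


def _ancestors(geoms: dict[int, _SectionGeom], sec: int) -> list[int]:
    chain = [sec]
    while chain[-1] != 0:
        chain.append(geoms[chain[-1]].parent)
    return chain


def electrotonic_distance(
    m: Morphology,
    params: CableParams,
    locus: Locus,
    reference_locus: Locus = ROOT_LOCUS,
) -> float:
    """Dimensionless cable distance x/λ along the unique tree path.

    The integral uses the per-segment mean diameter, so a uniform cylinder of
    diameter d and length λ(d) has electrotonic length exactly 1.
    """
    geoms = _section_geometry(m)
    for loc in (locus, reference_locus):
        if loc.branchlet_id != 0 and loc.branchlet_id not in geoms:
            raise KeyError(f"unknown branchlet id {loc.branchlet_id}")
    # cumulative x/λ at the start of each section
    x_start: dict[int, float] = {0: 0.0}
    x_end: dict[int, float] = {0: 0.0}
    pending = sorted(geoms)
    while pending:
        remaining = []
        for sid in pending:
            p = geoms[sid].parent
            if p in x_end:
                x_start[sid] = x_end[p]
                x_end[sid] = x_start[sid] + float(_section_x(geoms[sid], params).sum())
            else:
                remaining.append(sid)
        pending = remaining
    xa = _locus_x(geoms, x_start, params, locus)
    xb = _locus_x(geoms, x_start, params, reference_locus)
    chain_a = _ancestors(geoms, locus.branchlet_id)
    chain_b = _ancestors(geoms, reference_locus.branchlet_id)
    if locus.branchlet_id in chain_b or reference_locus.branchlet_id in chain_a:
        return abs(xa - xb)
    set_b = set(chain_b)
    lca = next(s for s in chain_a if s in set_b)
    return (xa - x_end[lca]) + (xb - x_end[lca])


def electrotonic_dendrogram(
    m: Morphology,
    params: CableParams,
    reference_locus: Locus = ROOT_LOCUS,
) -> pd.DataFrame:
    """Electrotonic distance of every branchlet's distal end from a reference.

    With a proximal reference (the axonal measurement point), X is
    non-decreasing from root to tips along every path.
    """
    rows = [
        {
            "branchlet_id": b.id,
            "is_terminal": b.is_terminal,
            "x_distal": electrotonic_distance(
                m, params, Locus(b.id, 1.0), reference_locus
            ),
        }
        for b in enumerate_branchlets(m)
    ]
    return pd.DataFrame(rows)


def default_axon_locus(m: Morphology) -> Locus:
    """The axonal measurement point: the most distal axon-labelled node
    (largest path distance from the root), else the root itself."""
    geoms = _section_geometry(m)
    axon_secs = {sid: g for sid, g in geoms.items() if g.struct == 2}
    if not axon_secs:
        return ROOT_LOCUS
    # path length from root to each section start
    len_start: dict[int, float] = {0: 0.0}
    pending = sorted(geoms)
    while pending:
        remaining = []
        for sid in pending:
            p = geoms[sid].parent
            if p in len_start:
                len_start[sid] = len_start[p] + (geoms[p].length if p else 0.0)
            else:
                remaining.append(sid)
        pending = remaining
    best = max(axon_secs, key=lambda sid: len_start[sid] + axon_secs[sid].length)
    return Locus(best, 1.0)
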