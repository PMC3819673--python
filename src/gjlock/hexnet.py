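"""Hexagonal resistive network model of a gap-junction-coupled cell sheet.

Each cell is a node of a pointy-top hexagonal lattice.  Adjacent nodes are
linked by a uniform junctional conductance ``g_j`` (nS); every node leaks to
ground through a membrane conductance ``g_m`` (nS); the patch pipette is a
voltage source of amplitude ``v0`` (mV) connected to one node through an
access resistance ``R_a`` (MOhm).  The model is purely resistive (membrane
and dye time constants are negligible at the 0.5 Hz carrier), so the 35 mV
sinusoidal command maps onto a single steady-state solve per conductance
value, and time-varying coupling is handled quasi-statically.

Units are fixed to {mV, nS, MOhm}: nS * mV = pA and mV / MOhm = nA, so the
source conductance 1/R_a is converted to nS as 1e3 / R_a.

Nodal equations (currents in pA), for each node i:

    g_m V_i + sum_j g_j (V_i - V_j) = delta_{i,stim} * (v0 - V_i) * 1e3 / R_a
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .exceptions import InvalidParameterError

__all__ = [
    "HexLattice",
    "NetworkParams",
    "NetworkSolution",
    "UncouplingSchedule",
    "build_lattice",
    "solve_steady_state",
    "amplitude_profile",
    "simulate_dynamic",
    "predicted_suprathreshold_cells",
    "DEFAULT_CELL_AREA_UM2",
    "DEFAULT_CELL_SPACING_UM",
]

#: average footprint of one cochlear non-sensory cell (um^2)
DEFAULT_CELL_AREA_UM2 = 210.0
#: centre-to-centre spacing of a regular hexagon of that area:
#: spacing = sqrt(2 A / sqrt(3))
DEFAULT_CELL_SPACING_UM = float(np.sqrt(2.0 * DEFAULT_CELL_AREA_UM2 / np.sqrt(3.0)))


@dataclass
class HexLattice:
    """Pointy-top hexagonal (triangular) lattice with open boundaries.

    ``n_rows`` (Nx) nodes lie along the long axis (the cochlear coiling axis
    in the anatomy the model mirrors) in each of ``n_cols`` (Ny) lines.
    Axial indexing is used: node ``(i, j)``, i in [0, Nx), j in [0, Ny),
    has index ``i * n_cols + j`` and position ``x = (i + j/2) s``,
    ``y = j sqrt(3)/2 s`` with s the centre-to-centre spacing, so the patch
    is a rhombus.  Interior nodes have exactly six neighbours at distance s
    and the patch is symmetric under 180-degree rotation about the centre
    node of an odd-by-odd lattice (which makes the two-sided profile
    averaging exact).
    """

    n_rows: int
    n_cols: int
    spacing_um: float = DEFAULT_CELL_SPACING_UM
    positions: np.ndarray = field(init=False, repr=False)
    edges: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError("lattice dimensions must be >= 1")
        if self.spacing_um <= 0:
            raise InvalidParameterError("cell spacing must be positive")
        nx, ny, s = self.n_rows, self.n_cols, self.spacing_um
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        x = (ii + 0.5 * jj) * s
        y = jj * (np.sqrt(3.0) / 2.0) * s
        self.positions = np.column_stack([x.ravel(), y.ravel()])
        edges = []
        for i in range(nx):
            for j in range(ny):
                a = self.node_index(i, j)
                # along the long axis
                if i + 1 < nx:
                    edges.append((a, self.node_index(i + 1, j)))
                # across lines: axial neighbours (i, j+1) and (i-1, j+1)
                if j + 1 < ny:
                    for di in (0, -1):
                        if 0 <= i + di < nx:
                            edges.append((a, self.node_index(i + di, j + 1)))
        self.edges = (
            np.asarray(edges, dtype=int) if edges else np.empty((0, 2), dtype=int)
        )

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def node_index(self, i: int, j: int) -> int:
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise InvalidParameterError(f"node ({i}, {j}) outside the lattice")
        return i * self.n_cols + j

    def node_coords(self, index: int) -> tuple[int, int]:
        return divmod(index, self.n_cols)

    @property
    def center_node(self) -> int:
        return self.node_index(self.n_rows // 2, self.n_cols // 2)

    def neighbors(self, index: int) -> np.ndarray:
        """Indices of the (at most six) adjacent nodes."""
        mask = (self.edges[:, 0] == index) | (self.edges[:, 1] == index)
        pairs = self.edges[mask]
        return np.where(pairs[:, 0] == index, pairs[:, 1], pairs[:, 0])

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency matrix."""
        n = self.n_nodes
        if self.edges.size == 0:
            return sparse.csr_matrix((n, n))
        r = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        c = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        return sparse.csr_matrix((np.ones(r.size), (r, c)), shape=(n, n))


def build_lattice(
    n_rows: int, n_cols: int, cell_spacing_um: float = DEFAULT_CELL_SPACING_UM
) -> HexLattice:
    """Build the Nx-by-Ny hexagonal lattice (standard model: 45 x 15)."""
    return HexLattice(n_rows=n_rows, n_cols=n_cols, spacing_um=cell_spacing_um)


@dataclass(frozen=True)
class NetworkParams:
    """Electrical parameters of the network in {mV, nS, MOhm}.

    Defaults are the standard cochlear-culture model: membrane conductance
    8.3 nS, access resistance 7.8 MOhm, 35 mV command.  ``stim_node=None``
    selects the lattice centre.
    """

    g_j_ns: float
    g_m_ns: float = 8.3
    r_a_mohm: float = 7.8
    v0_mv: float = 35.0
    stim_node: int | None = None

    def __post_init__(self) -> None:
        if self.g_j_ns < 0:
            raise InvalidParameterError("g_j must be >= 0")
        if self.g_m_ns <= 0:
            raise InvalidParameterError("g_m must be > 0")
        if self.r_a_mohm <= 0:
            raise InvalidParameterError("R_a must be > 0")


@dataclass
class NetworkSolution:
    """Steady-state node voltages plus source diagnostics.

    ``input_current_na = (v0 - V_stim) / R_a``;
    ``input_resistance_mohm = V_stim / input_current`` is the network's
    input resistance seen from the stimulated node, excluding R_a.
    """

    voltages_mv: np.ndarray
    stim_node: int
    input_current_na: float
    input_resistance_mohm: float
    g_j_ns: float


def _conductance_matrix(
    lattice: HexLattice, params: NetworkParams, g_j_ns: float
) -> tuple[sparse.csr_matrix, np.ndarray, int, float]:
    n = lattice.n_nodes
    stim = params.stim_node if params.stim_node is not None else lattice.center_node
    if not (0 <= stim < n):
        raise InvalidParameterError(f"stim_node {stim} out of range")
    g_a = 1.0e3 / params.r_a_mohm  # 1/MOhm = uS -> nS
    diag = np.full(n, params.g_m_ns)
    diag[stim] += g_a
    if lattice.edges.size and g_j_ns > 0:
        deg = np.bincount(lattice.edges.ravel(), minlength=n)
        diag += g_j_ns * deg
        r = np.concatenate([lattice.edges[:, 0], lattice.edges[:, 1]])
        c = np.concatenate([lattice.edges[:, 1], lattice.edges[:, 0]])
        off = sparse.csr_matrix((-g_j_ns * np.ones(r.size), (r, c)), shape=(n, n))
        mat = sparse.diags(diag).tocsr() + off
    else:
        mat = sparse.diags(diag).tocsr()
    rhs = np.zeros(n)
    rhs[stim] = g_a * params.v0_mv
    return mat, rhs, stim, g_a


def solve_steady_state(
    lattice: HexLattice, params: NetworkParams, g_j_ns: float | None = None
) -> NetworkSolution:
    """Solve the nodal equations by a sparse direct solve.

    ``g_j_ns`` overrides ``params.g_j_ns`` (used by the dynamic and fitting
    paths without rebuilding the parameter object).
    """
    gj = params.g_j_ns if g_j_ns is None else float(g_j_ns)
    if gj < 0:
        raise InvalidParameterError("g_j must be >= 0")
    mat, rhs, stim, _ = _conductance_matrix(lattice, params, gj)
    v = spsolve(mat.tocsc(), rhs)
    if not np.all(np.isfinite(v)):
        raise InvalidParameterError("singular nodal system")
    i_na = (params.v0_mv - v[stim]) / params.r_a_mohm
    r_in = v[stim] / i_na if i_na != 0 else np.inf
    return NetworkSolution(
        voltages_mv=v,
        stim_node=stim,
        input_current_na=float(i_na),
        input_resistance_mohm=float(r_in),
        g_j_ns=gj,
    )


def amplitude_profile(
    solution: NetworkSolution, lattice: HexLattice, max_order: int | None = None
) -> pd.DataFrame:
    """Relative amplitude versus coupling order along the long (row) axis.

    Order k averages the two nodes k steps from the stimulated node along
    the lattice line through it (one-sided with a warning when the
    stimulated node sits nearer than k to a boundary).  Columns: ``order``,
    ``distance_um``, ``rel_amplitude``, ``n_nodes``; order 0 is 1 by
    construction.
    """
    i0, j0 = lattice.node_coords(solution.stim_node)
    v = solution.voltages_mv
    v1 = v[solution.stim_node]
    if v1 <= 0:
        raise InvalidParameterError("stimulated-node voltage must be positive")
    if max_order is None:
        max_order = max(i0, lattice.n_rows - 1 - i0)
    one_sided = False
    rows = []
    for k in range(max_order + 1):
        vals = []
        for i in (i0 - k, i0 + k) if k > 0 else (i0,):
            if 0 <= i < lattice.n_rows:
                vals.append(v[lattice.node_index(i, j0)])
        if not vals:
            break
        if k > 0 and len(vals) < 2:
            one_sided = True
        rows.append((k, k * lattice.spacing_um, float(np.mean(vals)) / v1, len(vals)))
    if one_sided:
        warnings.warn(
            "stimulated node near a boundary: one-sided averaging for some orders",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["order", "distance_um", "rel_amplitude", "n_nodes"])


@dataclass(frozen=True)
class UncouplingSchedule:
    """Exponential junctional-conductance decay, g(t) in nS.

    ``g(t) = g_end + (g_start - g_end) exp(-(t - t0)/tau)`` for t >= t0 and
    ``g_start`` before; the standard CO2 uncoupling protocol decays 206 nS
    to 2 nS with tau = 7 s starting at t0 = 25 s.
    """

    g_start_ns: float = 206.0
    g_end_ns: float = 2.0
    tau_s: float = 7.0
    t0_s: float = 25.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise InvalidParameterError("tau must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        g = self.g_end_ns + (self.g_start_ns - self.g_end_ns) * np.exp(
            -(t - self.t0_s) / self.tau_s
        )
        return np.where(t < self.t0_s, self.g_start_ns, g)


def simulate_dynamic(
    lattice: HexLattice,
    params: NetworkParams,
    schedule: UncouplingSchedule,
    times,
) -> list[NetworkSolution]:
    """Quasi-static solves at each time with g_j = schedule(t).

    Exact for this purely resistive model: with no capacitance the network
    has no memory, so each instant is an independent steady state.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise InvalidParameterError("times must be sorted")
    return [solve_steady_state(lattice, params, g_j_ns=float(schedule(t))) for t in times]


def predicted_suprathreshold_cells(
    solution: NetworkSolution,
    threshold_mv: float,
    cell_area_um2: float = DEFAULT_CELL_AREA_UM2,
) -> tuple[int, float]:
    """Model-predicted count of cells above threshold and the implied area.

    Bridges the network solution to the imaging suprathreshold-area readout:
    each node whose amplitude exceeds ``threshold_mv`` contributes one cell
    footprint (default 210 um^2).
    """
    if threshold_mv <= 0:
        raise InvalidParameterError("threshold must be positive")
    if cell_area_um2 <= 0:
        raise InvalidParameterError("cell area must be positive")
    count = int(np.count_nonzero(np.abs(solution.voltages_mv) > threshold_mv))
    return count, count * cell_area_um2
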