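"""Network hemodynamics: Poiseuille pressures/flows, Fahraeus-Lindqvist
apparent viscosity, phase separation of hematocrit at bifurcations, and the
self-consistent alternating solve.

Blood is treated as a Newtonian fluid per segment with an apparent
viscosity eta = eta_plasma * eta_rel(d, H) taken from the empirical
parameterisations of Pries and co-workers (in-vivo law by default, the
older in-vitro law selectable). Mass conservation sum_v q_v = 0 holds at
every interior node; RBC conservation sum_v H_v q_v = 0 holds at every
node once hematocrit has been propagated downstream from the inlets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import (ARTERIAL_ROOT, INTERIOR, MMHG_TO_PA, VENOUS_ROOT,
                   HemoParams, VesselNetwork)

__all__ = [
    "FlowState", "relative_viscosity", "segment_conductance",
    "solve_pressures", "phase_separation_split", "propagate_hematocrit",
    "solve_hemodynamics",
]


@dataclass
class FlowState:
    pressure: np.ndarray      # per node, mmHg
    q: np.ndarray             # per segment, um^3/s, signed a->b
    f: np.ndarray             # wall shear stress per segment, Pa
    eta: np.ndarray           # apparent viscosity per segment, mPa*s
    converged: bool = True
    iterations: int = 1


def relative_viscosity(r, H, law: str = "invivo"):
    """Relative apparent blood viscosity eta_rel(r, H) (dimensionless).

    ``law="invivo"`` is the in-vivo parameterisation (includes the
    endothelial surface layer, so even at H=0 the value is
    (d/(d-1.1))^2 > 1); ``law="invitro"`` is the glass-tube law whose
    plasma limit is exactly 1. ``r`` is the vessel radius in um.
    """
    r = np.asarray(r, dtype=float)
    H = np.asarray(H, dtype=float)
    d = np.maximum(2.0 * r, 1.3)  # diameter, guarded away from the ESL pole
    C = (0.8 + np.exp(-0.075 * d)) * (-1.0 + 1.0 / (1.0 + 1e-11 * d ** 12)) \
        + 1.0 / (1.0 + 1e-11 * d ** 12)
    hfac = ((1.0 - H) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    if law == "invivo":
        eta45 = 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d ** 0.645)
        esl = (d / (d - 1.1)) ** 2
        return (1.0 + (eta45 - 1.0) * hfac * esl) * esl
    if law == "invitro":
        eta45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d ** 0.645)
        return 1.0 + (eta45 - 1.0) * hfac
    raise ValueError(f"unknown viscosity law {law!r}")


def segment_conductance(r, l, eta):
    """Poiseuille conductance g = pi r^4 / (8 eta l) in um^3/(s*mmHg).

    ``r``, ``l`` in um, ``eta`` in mPa*s. Raises on zero length.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("segment with non-positive length")
    return np.pi * np.asarray(r, float) ** 4 * MMHG_TO_PA / (
        8.0 * np.asarray(eta, float) * 1e-3 * l)


def _root_radii(net: VesselNetwork) -> dict[int, float]:
    """Radius assigned to each root node = max radius of incident segments."""
    roots = np.flatnonzero(net.role != INTERIOR)
    rr = {int(n): 0.0 for n in roots}
    for arr_end in (net.a, net.b):
        sel = np.isin(arr_end, roots)
        for s in np.flatnonzero(sel):
            n = int(arr_end[s])
            rr[n] = max(rr[n], float(net.r[s]))
    return rr


def solve_pressures(net: VesselNetwork, params: HemoParams,
                    eta: np.ndarray | None = None) -> FlowState:
    """Solve the nodal-pressure linear system with Dirichlet root pressures.

    Mass conservation at interior nodes + fixed radius-dependent pressures
    at root nodes. Uses the compressed radius ``r_tilde`` for conductances.
    Raises ``ValueError`` naming a connected component that contains no
    root (the reduced system would be singular there).
    """
    n, m = net.n_nodes, net.n_segments
    if eta is None:
        eta = params.eta_plasma * relative_viscosity(
            net.r_tilde, net.H, params.viscosity_law)
    g = segment_conductance(net.r_tilde, net.l, eta)

    is_root = net.role != INTERIOR
    # singular-component check
    adj = sp.coo_matrix((np.ones(m), (net.a, net.b)), shape=(n, n))
    ncomp, labels = sp.csgraph.connected_components(adj, directed=False)
    root_labels = set(labels[is_root].tolist())
    has_seg = np.zeros(n, bool)
    has_seg[net.a] = True
    has_seg[net.b] = True
    for c in range(ncomp):
        members = np.flatnonzero(labels == c)
        if c not in root_labels and has_seg[members].any():
            raise ValueError(
                f"connected component {c} (e.g. node {members[0]}) has no "
                "root node; pressure system singular")

    p_bc = np.zeros(n)
    rr = _root_radii(net)
    for nid, r in rr.items():
        p_bc[nid] = params.root_pressure(r, int(net.role[nid]))

    # weighted graph Laplacian, reduced to interior unknowns
    rows = np.concatenate([net.a, net.b, net.a, net.b])
    cols = np.concatenate([net.b, net.a, net.a, net.b])
    vals = np.concatenate([-g, -g, g, g])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # orphan interior nodes (no incident segment) are inert: exclude them
    interior = np.flatnonzero(~is_root & has_seg)
    p = p_bc.copy()
    if len(interior):
        Aii = A[interior][:, interior].tocsc()
        rhs = -A[interior][:, np.flatnonzero(is_root)] @ p_bc[is_root]
        p[interior] = spla.spsolve(Aii, rhs)

    q = g * (p[net.a] - p[net.b])
    dp_pa = np.abs(p[net.a] - p[net.b]) * MMHG_TO_PA
    f = net.r_tilde * dp_pa / (2.0 * net.l)
    return FlowState(pressure=p, q=q, f=f, eta=np.broadcast_to(eta, (m,)).copy())


def phase_separation_split(q_p, H_p, d_p, q1, d1, q2, d2,
                           law: str = "pries1990") -> tuple[float, float]:
    """Daughter hematocrits at an arterial bifurcation.

    Empirical RBC-flux partitioning (fractional RBC flux into daughter 1 as
    a function of its fractional blood flow); RBC conservation
    H_p q_p = H_1 q_1 + H_2 q_2 is exact up to the physical cap H <= 0.99.
    Zero parent flow returns (H_p, H_p) by convention.
    """
    q_p, q1, q2 = abs(q_p), abs(q1), abs(q2)
    if q_p <= 0.0:
        return H_p, H_p
    if q1 <= 0.0:
        return H_p, H_p * q_p / max(q2, 1e-300)
    if q2 <= 0.0:
        return H_p * q_p / q1, H_p
    fqb = q1 / (q1 + q2)
    if law == "pries1990":
        A = -6.96 / d_p * np.log(d1 / d2)
        B = 1.0 + 6.98 * (1.0 - H_p) / d_p
        X0 = 0.4 / d_p
    elif law == "invivo2005":
        A = -13.29 * ((d1 ** 2 - d2 ** 2) / (d1 ** 2 + d2 ** 2)) \
            * (1.0 - H_p) / d_p
        B = 1.0 + 6.98 * (1.0 - H_p) / d_p
        X0 = 0.964 * (1.0 - H_p) / d_p
    else:
        raise ValueError(f"unknown phase separation law {law!r}")
    X0 = min(X0, 0.49)
    if fqb <= X0:
        fqe = 0.0
    elif fqb >= 1.0 - X0:
        fqe = 1.0
    else:
        x = (fqb - X0) / (1.0 - 2.0 * X0)
        logit = A + B * np.log(x / (1.0 - x))
        fqe = 1.0 / (1.0 + np.exp(-logit))
    rbc = H_p * q_p
    H1 = fqe * rbc / q1
    H2 = (1.0 - fqe) * rbc / q2
    if H1 > 0.99:
        H1 = 0.99
        H2 = (rbc - H1 * q1) / q2
    if H2 > 0.99:
        H2 = 0.99
        H1 = min(0.99, (rbc - H2 * q2) / q1)
    return max(H1, 0.0), max(H2, 0.0)


def flow_topology(net: VesselNetwork, q: np.ndarray, q_eps: float | None = None):
    """Per-node in/out segment lists under the current flow directions and
    a topological order of the flow-directed graph (Kahn). Returns
    (order, in_segs, out_segs, acyclic): nodes left out of ``order``
    participate in flow-directed cycles. Segments with |q| below ``q_eps``
    (default 1e-9 of the peak flow: numerical noise on dead-end branches)
    are treated as unperfused."""
    if q_eps is None:
        q_eps = 1e-9 * (np.max(np.abs(q)) if len(q) else 1.0)
    n = net.n_nodes
    in_segs = [[] for _ in range(n)]
    out_segs = [[] for _ in range(n)]
    qa = np.where(np.abs(q) > q_eps, q, 0.0)
    for s in range(net.n_segments):
        if qa[s] > 0:
            out_segs[net.a[s]].append(s)
            in_segs[net.b[s]].append(s)
        elif qa[s] < 0:
            out_segs[net.b[s]].append(s)
            in_segs[net.a[s]].append(s)
    indeg = np.array([len(x) for x in in_segs])
    order = []
    stack = list(np.flatnonzero(indeg == 0))
    seg_head = np.where(qa >= 0, net.b, net.a)  # downstream node of segment
    remaining = indeg.copy()
    while stack:
        u = stack.pop()
        order.append(u)
        for s in out_segs[u]:
            v = int(seg_head[s])
            remaining[v] -= 1
            if remaining[v] == 0:
                stack.append(v)
    acyclic = len(order) == n
    return order, in_segs, out_segs, acyclic


def propagate_hematocrit(net: VesselNetwork, flow: FlowState,
                         params: HemoParams) -> np.ndarray:
    """Assign per-segment hematocrit downstream from the inlets.

    Arterial bifurcations (one inflow, two outflows) use the empirical
    phase-separation law; merge nodes use flow-weighted mixing (RBC flux
    conservation); root nodes feed their outflows with the inlet value
    H^(BC). Flow-directed cycles (possible in remodeled tumor networks)
    are handled by iterative relaxation until the per-segment change is
    below 1e-6.
    """
    q = flow.q
    H = net.H.copy()
    order, in_segs, out_segs, acyclic = flow_topology(net, q)

    def sweep(node_iter, H):
        Hn = H.copy()
        for u in node_iter:
            outs = out_segs[u]
            if not outs:
                continue
            ins = in_segs[u]
            if net.role[u] != INTERIOR:
                # boundary node: outflows restart at the inlet hematocrit
                for s in outs:
                    Hn[s] = params.H_bc
                continue
            if not ins:
                continue   # interior source (unperfused pocket): keep H
            rbc_in = sum(abs(q[s]) * Hn[s] for s in ins)
            q_in = sum(abs(q[s]) for s in ins)
            if len(outs) == 1:
                s = outs[0]
                Hn[s] = min(0.99, rbc_in / max(abs(q[s]), 1e-300))
            elif len(ins) == 1 and len(outs) == 2:
                s0 = ins[0]
                s1, s2 = outs
                h1, h2 = phase_separation_split(
                    q_in, Hn[s0], 2 * net.r_tilde[s0],
                    abs(q[s1]), 2 * net.r_tilde[s1],
                    abs(q[s2]), 2 * net.r_tilde[s2],
                    params.phase_separation_law)
                Hn[s1], Hn[s2] = h1, h2
            else:
                # degenerate multi-in/multi-out: flow-weighted mixing
                h_mix = rbc_in / max(q_in, 1e-300)
                for s in outs:
                    Hn[s] = min(0.99, h_mix)
        return Hn

    H = sweep(order, H)
    if not acyclic:
        in_order = set(order)
        rest = [u for u in np.argsort(-flow.pressure) if u not in in_order]
        for _ in range(50):
            Hn = sweep(order + rest, H)
            if np.max(np.abs(Hn - H)) < 1e-6:
                H = Hn
                break
            H = Hn
    # zero-flow segments keep their previous hematocrit
    return H


def solve_hemodynamics(net: VesselNetwork, params: HemoParams) -> FlowState:
    """Alternate pressure solves and hematocrit propagation to the coupled
    fixed point (max per-segment |dH| < tol and stable flow directions).

    Mutates ``net.H`` to the converged hematocrit, ``net.q`` to the flows
    and ``net.pressure`` to the nodal pressures; also returns the
    FlowState. Non-convergence returns the best iterate flagged."""
    flow = None
    prev_dir = None
    for it in range(1, params.max_iter + 1):
        flow = solve_pressures(net, params)
        q_eps = 1e-9 * (np.max(np.abs(flow.q)) if net.n_segments else 1.0)
        perfused = np.abs(flow.q) > q_eps
        H_new = propagate_hematocrit(net, flow, params)
        dH = float(np.max(np.abs((H_new - net.H)[perfused]))) \
            if perfused.any() else 0.0
        net.H = (1.0 - params.relax_H) * net.H + params.relax_H * H_new
        direction = np.where(perfused, np.sign(flow.q), 0.0)
        dir_stable = prev_dir is not None and np.array_equal(direction, prev_dir)
        prev_dir = direction
        if dH < params.tol_H and (dir_stable or it == 1):
            flow.converged = True
            flow.iterations = it
            break
    else:
        flow.converged = False
        flow.iterations = params.max_iter
    net.q = flow.q
    net.pressure = flow.pressure
    return flow
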