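"""Programmatic test fixtures: small, fully specified vascular systems
with analytic reference closures. Fixtures are code, not data files."""

from __future__ import annotations

import numpy as np

from .core import (ARTERIAL_ROOT, ARTERY, CAPILLARY, VEIN, VENOUS_ROOT,
                   OxygenParams, VesselNetwork)
from .oxygen import mass_transfer_coefficient

__all__ = ["make_single_tube", "make_bifurcation", "make_ladder",
           "make_random_network", "make_two_class_network"]


def make_single_tube(r: float = 3.0, l: float = 1000.0, box: float = 2000.0,
                     H: float = 0.45, n_pieces: int = 1,
                     params: OxygenParams | None = None):
    """Axis-aligned tube through the box center; arterial root at the
    upstream end, venous at the downstream end.

    Returns ``(net, ref)`` where ``ref`` holds analytic closures:

    - ``ref["po2_plasma"](x, P_in, P_t, q)`` — the H=0 exponential axial
      profile P_t + (P_in - P_t) exp(-2 pi r gamma x / (q alpha_p));
    - ``ref["krogh"](rho, P_wall, M)`` — the Krogh-cylinder radial tissue
      profile around the tube for zeroth-order consumption M, with tissue
      cylinder radius volume-matched to the box.
    """
    params = params or OxygenParams()
    net = VesselNetwork()
    c = box / 2.0
    x0, x1 = (box - l) / 2.0, (box + l) / 2.0
    xs = np.linspace(x0, x1, n_pieces + 1)
    ids = net.add_nodes([[x, c, c] for x in xs])
    net.role[ids[0]] = ARTERIAL_ROOT
    net.role[ids[-1]] = VENOUS_ROOT
    net.add_segments(ids[:-1], ids[1:], r, H=H, flags=CAPILLARY)

    gamma = float(mass_transfer_coefficient(r, params))

    def po2_plasma(x, P_in, P_t, q):
        k = 2.0 * np.pi * r * gamma / (abs(q) * params.alpha_p)
        return P_t + (P_in - P_t) * np.exp(-k * np.asarray(x, float))

    R_t = box / np.sqrt(np.pi)   # pi R_t^2 = box^2 (volume-matched cylinder)

    def krogh(rho, P_wall, M):
        rho = np.asarray(rho, dtype=float)
        A = M / (params.alpha_t * params.D_t)
        return (P_wall + A / 4.0 * (rho ** 2 - r ** 2)
                - A * R_t ** 2 / 2.0 * np.log(rho / r))

    return net, {"po2_plasma": po2_plasma, "krogh": krogh, "gamma": gamma,
                 "R_tissue": R_t}


def make_bifurcation(r_parent: float = 5.0, r1: float = 4.0, r2: float = 4.0,
                     l: float = 200.0, H: float = 0.45, box: float = 1000.0):
    """Y-shaped fixture: one parent splitting into two daughters that drain
    to separate venous roots. Parent root is arterial."""
    net = VesselNetwork()
    c = box / 2.0
    n0 = net.add_node([c - l, c, c], role=ARTERIAL_ROOT)
    n1 = net.add_node([c, c, c])
    n2 = net.add_node([c + l / np.sqrt(2), c + l / np.sqrt(2), c],
                      role=VENOUS_ROOT)
    n3 = net.add_node([c + l / np.sqrt(2), c - l / np.sqrt(2), c],
                      role=VENOUS_ROOT)
    net.add_segment(n0, n1, r_parent, H=H, flags=ARTERY)
    net.add_segment(n1, n2, r1, H=H, flags=CAPILLARY)
    net.add_segment(n1, n3, r2, H=H, flags=CAPILLARY)
    return net


def make_ladder(n_rungs: int = 8, spacing: float = 150.0, r_spine: float = 8.0,
                r_rung: float = 3.0, box: float | None = None,
                H: float = 0.45):
    """Arterio-venous ladder ("comb") network: an arterial spine and a
    venous spine joined by capillary rungs; every segment is perfused.
    Suitable as a miniature full-connectivity smoke-test system."""
    L = box if box is not None else (n_rungs + 1) * spacing
    net = VesselNetwork()
    y_a, y_v = L / 3.0, 2.0 * L / 3.0
    zc = L / 2.0
    xs = np.linspace(spacing / 2.0, L - spacing / 2.0, n_rungs)
    a_ids = net.add_nodes([[x, y_a, zc] for x in xs])
    v_ids = net.add_nodes([[x, y_v, zc] for x in xs])
    net.role[a_ids[0]] = ARTERIAL_ROOT
    net.role[v_ids[-1]] = VENOUS_ROOT
    net.add_segments(a_ids[:-1], a_ids[1:], r_spine, H=H, flags=ARTERY)
    net.add_segments(v_ids[:-1], v_ids[1:], r_spine, H=H, flags=VEIN)
    net.add_segments(a_ids, v_ids, r_rung, H=H, flags=CAPILLARY)
    return net


def make_random_network(n_nodes: int = 30, seed: int = 0, box: float = 2000.0,
                        H_spread: bool = True):
    """Random degree-<=3 tree over uniform points plus roots at the first
    and last node; for serialization round-trips and dense-solver oracles."""
    rng = np.random.default_rng(seed)
    net = VesselNetwork()
    pos = rng.uniform(50.0, box - 50.0, size=(n_nodes, 3))
    ids = net.add_nodes(pos)
    net.role[ids[0]] = ARTERIAL_ROOT
    net.role[ids[-1]] = VENOUS_ROOT
    deg = np.zeros(n_nodes, dtype=int)
    for i in range(1, n_nodes):
        cand = [j for j in range(i) if deg[j] < (2 if j in (0, n_nodes - 1) else 3)]
        j = int(rng.choice(cand))
        r = float(rng.uniform(2.5, 12.0))
        h = float(rng.uniform(0.2, 0.6)) if H_spread else 0.45
        net.add_segment(j, i, r, H=h, flags=CAPILLARY)
        deg[i] += 1
        deg[j] += 1
    net.w = rng.uniform(0.0, 5.0, net.n_segments)
    net.tau = rng.uniform(0.0, 10.0, net.n_segments)
    return net


def make_two_class_network(n_each: int = 5, box: float = 2000.0):
    """Fixture with a few high-caliber segments and many capillaries; used
    for the caliber-sensitivity contrast between the RBC-volume-weighted
    saturation Y and the length-weighted <S>."""
    net = VesselNetwork()
    c = box / 2.0
    l = 400.0
    for i in range(n_each):
        y = 100.0 + i * 150.0
        a = net.add_node([c - l / 2, y, c], role=ARTERIAL_ROOT)
        b = net.add_node([c + l / 2, y, c], role=VENOUS_ROOT)
        net.add_segment(a, b, 12.0, H=0.45, flags=ARTERY)
    for i in range(n_each):
        y = 100.0 + i * 150.0
        a = net.add_node([c - l / 2, y, c + 300.0], role=ARTERIAL_ROOT)
        b = net.add_node([c + l / 2, y, c + 300.0], role=VENOUS_ROOT)
        net.add_segment(a, b, 3.0, H=0.45, flags=CAPILLARY)
    return net
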