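"""Tumor growth and vascular remodeling.

A spherical tumor of radius R_tum(t) = R_tum(0) + v_tum * t expands from
the domain center. Within each Delta t = 1 h step the stochastic
remodeling processes run (angiogenic sprouting in the shell
R_tum < |x| < R_tum + R_g, sprout migration/connection, circumferential
growth and wall degradation inside the tumor, shear-gated collapse and
dead-end regression), then hemodynamics is recomputed and t and R_tum
advance. The CMPR scenario additionally compresses tumor vessel radii by
the radial profile psi(|x|).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (CAPILLARY, SPROUT, GrowthParams, SimConfig, VesselNetwork)
from .hemodynamics import solve_hemodynamics
from .netgen import _OFFSETS, fine_subdivide

__all__ = ["TumorState", "TumorSimulation", "psi_compression",
           "apply_compression", "run_tumor_growth"]

_Q_CIRCULATED = 1e-3    # um^3/s: a sprout carrying more flow is circulated
_SNAP_FRAC = 0.45       # connect a migrating tip within this fraction of a bond


@dataclass
class TumorState:
    R_tum: float
    t: float
    center: np.ndarray

    @classmethod
    def initial(cls, growth: GrowthParams, center) -> "TumorState":
        return cls(R_tum=growth.R_tum0, t=0.0,
                   center=np.asarray(center, dtype=float))

    def advance(self, growth: GrowthParams) -> None:
        self.t += growth.dt
        self.R_tum = growth.R_tum0 + growth.v_tum * self.t


def psi_compression(d, R: float, xi: float, w_cpr: float):
    """Radial compression profile: xi inside R - w_cpr, 1 outside
    R + w_cpr, linear in between."""
    d = np.asarray(d, dtype=float)
    ramp = xi - (d - R + w_cpr) / (2.0 * w_cpr) * (xi - 1.0)
    return np.where(d < R - w_cpr, xi,
                    np.where(d > R + w_cpr, 1.0, ramp))


def apply_compression(net: VesselNetwork, center, R_tum: float, xi: float,
                      w_cpr: float = 200.0) -> None:
    """Set the compressed radii r_tilde = psi(|x - center|) * r."""
    if not (0.5 <= xi <= 1.0):
        raise ValueError("xi_cpr must lie in [0.5, 1]")
    d = np.linalg.norm(net.midpoints() - np.asarray(center, float), axis=1)
    net.r_tilde = psi_compression(d, R_tum, xi, w_cpr) * net.r


class TumorSimulation:
    """Mutable simulation state: the network plus per-segment residence
    time inside the tumor (which gates circumferential growth)."""

    def __init__(self, net: VesselNetwork, config: SimConfig, rng=None):
        g = config.growth
        if net.n_segments and net.l.max() > 1.5 * g.fine_h:
            net = fine_subdivide(net, g.fine_h)
        self.net = net
        self.config = config
        self.rng = np.random.default_rng(config.seed + 1) if rng is None else rng
        self.tumor = TumorState.initial(g, config.center)
        self.t_in = np.zeros(net.n_segments)
        self.f_last = np.full(net.n_segments, np.inf)   # shear at last solve
        self.flow = None
        self.log: list[dict] = []
        # in-loop hemodynamics: relaxed hematocrit tolerance (the state
        # changes every step anyway); run() ends with the strict solve
        from dataclasses import replace as _replace
        self._hemo = _replace(config.hemo,
                              tol_H=max(1e-3, config.hemo.tol_H),
                              max_iter=10)

    # -- bookkeeping ------------------------------------------------------
    def _append_aux(self, k: int) -> None:
        self.t_in = np.concatenate([self.t_in, np.zeros(k)])
        self.f_last = np.concatenate([self.f_last, np.full(k, np.inf)])

    def _keep(self, mask) -> None:
        self.net.keep_segments(mask)
        self.t_in = self.t_in[mask]
        self.f_last = self.f_last[mask]

    def _seg_dist(self) -> np.ndarray:
        return np.linalg.norm(self.net.midpoints() - self.tumor.center, axis=1)

    def _node_dist(self) -> np.ndarray:
        return np.linalg.norm(self.net.pos - self.tumor.center, axis=1)

    # -- process A: sprout initiation ------------------------------------
    def eligible_sprout_sites(self) -> np.ndarray:
        """Nodes in the angiogenic shell, outside the tumor, with degree
        <= 2 and network path distance >= d_br_min to any branch point."""
        net = self.net
        g = self.config.growth
        d = self._node_dist()
        deg = net.degrees()
        shell = (d > self.tumor.R_tum) & (d < self.tumor.R_tum + g.R_g) \
            & (deg >= 1) & (deg <= 2)
        cand = np.flatnonzero(shell)
        if not len(cand):
            return cand
        # multi-source Dijkstra from branch points, truncated at d_br_min
        branch = np.flatnonzero(deg >= 3)
        dist = self._path_distance_from(branch, g.d_br_min)
        return cand[dist[cand] >= g.d_br_min]

    def _path_distance_from(self, sources, cutoff: float) -> np.ndarray:
        net = self.net
        n = net.n_nodes
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for s in range(net.n_segments):
            a, b, l = int(net.a[s]), int(net.b[s]), float(net.l[s])
            adj[a].append((b, l))
            adj[b].append((a, l))
        dist = np.full(n, np.inf)
        h = []
        for u in sources:
            dist[u] = 0.0
            heapq.heappush(h, (0.0, int(u)))
        while h:
            du, u = heapq.heappop(h)
            if du > dist[u] or du > cutoff:
                continue
            for v, l in adj[u]:
                nd = du + l
                if nd < dist[v]:
                    dist[v] = nd
                    heapq.heappush(h, (nd, v))
        return dist

    def step_sprout_init(self) -> int:
        g = self.config.growth
        sites = self.eligible_sprout_sites()
        if not len(sites):
            return 0
        p = g.dt / g.t_sprout
        fire = sites[self.rng.uniform(size=len(sites)) < p]
        if not len(fire):
            return 0
        tree = cKDTree(self.net.pos)
        count = 0
        deg = self.net.degrees()
        dirs = np.asarray(_OFFSETS, dtype=float) / np.sqrt(2.0)
        for u in fire:
            if deg[u] >= 3:
                continue
            # uniformly random among the free adjacent bonds
            for dvec in dirs[self.rng.permutation(len(dirs))]:
                pnew = self.net.pos[u] + dvec * g.fine_h
                if np.any(pnew < 0) or np.any(pnew > self.config.L):
                    continue
                if tree.query(pnew, k=1)[0] < _SNAP_FRAC * g.fine_h:
                    continue    # bond occupied by an existing vessel
                v = self.net.add_node(pnew)
                self.net.add_segment(u, v, g.r_sprout, H=0.0, flags=SPROUT,
                                     w=min(g.r_sprout / 2.0, 10.0), tau=1.0)
                self._append_aux(1)
                count += 1
                break
        return count

    # -- process B: sprout migration / connection ------------------------
    def step_sprout_migrate(self) -> tuple[int, int]:
        net = self.net
        g = self.config.growth
        sprout_mask = (net.flags & SPROUT) != 0
        deg = net.degrees()
        tips = []
        for s in np.flatnonzero(sprout_mask):
            for node in (net.a[s], net.b[s]):
                if deg[node] == 1 and net.role[node] == 0:
                    tips.append((s, int(node)))
        extended = connected = 0
        if tips:
            tree = cKDTree(net.pos)
            dirs = np.asarray(_OFFSETS, dtype=float) / np.sqrt(2.0)
            p = g.dt / g.t_sprout
            for s, tip in tips:
                if self.rng.uniform() >= p:
                    continue
                other = net.b[s] if net.a[s] == tip else net.a[s]
                away = net.pos[tip] - net.pos[other]
                cand_dirs = dirs[self.rng.permutation(len(dirs))]
                for dvec in cand_dirs:
                    step = dvec * g.fine_h
                    if np.dot(step, away) < 0:
                        continue        # no immediate backtracking
                    pnew = net.pos[tip] + step
                    if np.any(pnew < 0) or np.any(pnew > self.config.L):
                        continue
                    dist, j = tree.query(pnew, k=1)
                    if dist < _SNAP_FRAC * g.fine_h:
                        j = int(j)
                        if j == tip or deg[j] >= 3:
                            continue    # would create a degree-4 junction
                        net.add_segment(tip, j, g.r_sprout, H=0.0,
                                        flags=SPROUT, w=min(g.r_sprout / 2, 10.0),
                                        tau=net.tau[s])
                        self._append_aux(1)
                        connected += 1
                    else:
                        v = net.add_node(pnew)
                        net.add_segment(tip, v, g.r_sprout, H=0.0,
                                        flags=SPROUT, w=min(g.r_sprout / 2, 10.0),
                                        tau=net.tau[s])
                        self._append_aux(1)
                        extended += 1
                    break
        # age all sprouts, retire the expired uncirculated ones
        sprout_mask = (net.flags & SPROUT) != 0
        net.tau[sprout_mask] += g.dt
        expired = sprout_mask & (net.tau > g.t_migr)
        if expired.any():
            self._keep(~expired)
        return extended, connected

    def mark_circulated(self) -> int:
        """Sprouts that carry flow become normal (capillary) vessels."""
        net = self.net
        m = ((net.flags & SPROUT) != 0) & (np.abs(net.q) > _Q_CIRCULATED)
        net.flags[m] = (net.flags[m] & ~SPROUT) | CAPILLARY
        net.tau[m] = 0.0
        return int(m.sum())

    # -- process E: circumferential growth -------------------------------
    def step_circumferential(self) -> None:
        g = self.config.growth
        inside = self._seg_dist() <= self.tumor.R_tum
        self.t_in[inside] += g.dt
        grow = inside & (self.t_in >= g.t_switch) & (self.net.r < g.r_max)
        factor = 2.0 ** (g.dt / g.t_prol)   # EC count doubles every t_prol
        self.net.r[grow] = np.minimum(self.net.r[grow] * factor, g.r_max)
        if self.config.scenario != "CMPR":
            # uncompressed radii track the anatomical radii exactly
            self.net.r_tilde[grow] = self.net.r[grow]

    # -- process C: wall degradation --------------------------------------
    def step_wall_degrade(self) -> None:
        g = self.config.growth
        tum = self._seg_dist() <= self.tumor.R_tum
        self.net.w[tum] = np.maximum(0.0, self.net.w[tum] - g.dw * g.dt)

    # -- process D: collapse and regression -------------------------------
    def step_collapse(self) -> int:
        g = self.config.growth
        f = self.f_last
        unstable = (self.net.w <= 0.0) & (f < g.f_coll)
        fire = unstable & (self.rng.uniform(size=len(unstable)) < g.p_coll)
        removed = int(fire.sum())
        if removed:
            self._keep(~fire)
        removed += self.prune_dead_ends()
        return removed

    def prune_dead_ends(self) -> int:
        """Iteratively strip dead-end chains back to perfused junctions;
        root nodes and still-active sprout tips are exempt."""
        net = self.net
        g = self.config.growth
        total = 0
        while True:
            deg = net.degrees()
            sprout_live = ((net.flags & SPROUT) != 0) & (net.tau <= g.t_migr)
            protect = np.zeros(net.n_nodes, dtype=bool)
            protect[net.role != 0] = True
            for s in np.flatnonzero(sprout_live):
                protect[net.a[s]] = protect[net.b[s]] = True
            leaf_node = (deg == 1) & ~protect
            kill = leaf_node[net.a] | leaf_node[net.b]
            kill &= ~sprout_live
            if not kill.any():
                break
            total += int(kill.sum())
            self._keep(~kill)
        # components unreachable from any root (e.g. looped islands left
        # behind by collapse) regress entirely
        if net.n_segments:
            import scipy.sparse as sp
            n = net.n_nodes
            adj = sp.coo_matrix((np.ones(net.n_segments), (net.a, net.b)),
                                shape=(n, n))
            _, labels = sp.csgraph.connected_components(adj, directed=False)
            rooted = np.zeros(labels.max() + 1, dtype=bool)
            rooted[labels[net.role != 0]] = True
            kill = ~rooted[labels[net.a]]
            if kill.any():
                total += int(kill.sum())
                self._keep(~kill)
        return total

    # -- main loop ---------------------------------------------------------
    def step(self) -> dict:
        cfg = self.config
        g = cfg.growth
        n_sprout = self.step_sprout_init()
        n_ext, n_conn = self.step_sprout_migrate()
        self.step_circumferential()
        self.step_wall_degrade()
        n_coll = self.step_collapse()
        if cfg.scenario == "CMPR" and cfg.xi_cpr is not None:
            apply_compression(self.net, self.tumor.center, self.tumor.R_tum,
                              cfg.xi_cpr, g.w_cpr)
        try:
            self.flow = solve_hemodynamics(self.net, self._hemo)
        except ValueError as e:
            raise RuntimeError(
                f"flow solve failed at t={self.tumor.t:.0f} h (network "
                f"disconnected from roots?): {e}") from e
        self.f_last = self.flow.f.copy()
        n_circ = self.mark_circulated()
        self.tumor.advance(g)
        rec = {"t": self.tumor.t, "R_tum": self.tumor.R_tum,
               "n_segments": self.net.n_segments, "sprouts": n_sprout,
               "extensions": n_ext, "connections": n_conn,
               "circulated": n_circ, "collapsed": n_coll}
        self.log.append(rec)
        return rec

    def run(self, t_end: float | None = None) -> "TumorSimulation":
        g = self.config.growth
        t_end = g.t_end if t_end is None else t_end
        self.flow = solve_hemodynamics(self.net, self._hemo)
        self.f_last = self.flow.f.copy()
        while self.tumor.t < t_end - 1e-9:
            self.step()
        # strict final solve for the downstream oxygen computation
        self.flow = solve_hemodynamics(self.net, self.config.hemo)
        self.f_last = self.flow.f.copy()
        return self


def run_tumor_growth(net: VesselNetwork, config: SimConfig, rng=None,
                     t_end: float | None = None
                     ) -> tuple[VesselNetwork, TumorState, TumorSimulation]:
    """Simulate tumor growth from t=0 on ``net``; returns the remodeled
    network, the final tumor state and the simulation record."""
    sim = TumorSimulation(net.copy(), config, rng=rng)
    sim.run(t_end)
    return sim.net, sim.tumor, sim
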