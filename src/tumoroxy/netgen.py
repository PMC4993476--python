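"""Construction of the initial (t=0) arterio-venous networks.

Interdigitating arterial and venous trees are grown by random addition of
linear and tripod elements on a face-centered-cubic lattice (nearest-
neighbour bond length h_gen), starting from root nodes placed according
to one of nine boundary configurations RC1..RC9. Nearby open ends of
opposite type are joined by capillaries, radii follow Murray's law
upward from fixed terminal calibres, and a wall-shear-stress guided
prune/extend loop runs until the capillary count plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (ARTERIAL_ROOT, ARTERY, CAPILLARY, INTERIOR, VEIN,
                   VENOUS_ROOT, HemoParams, SimConfig, VesselNetwork)
from .hemodynamics import solve_hemodynamics, solve_pressures

__all__ = ["FccLattice", "RootPlacement", "place_roots", "grow_trees",
           "connect_capillaries", "assign_radii_murray",
           "murray_parent_radius", "plateau_reached",
           "shear_guided_refinement", "generate_initial_network",
           "build_network", "fine_subdivide"]

R_CAPILLARY = 2.5       # um
R_TERM_ART = 2.5
R_TERM_VEIN = 3.8
MURRAY_ALPHA = 3.0

_OFFSETS = [(1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
            (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
            (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1)]


class FccLattice:
    """FCC lattice on [0, K*s]^3 with s = h_gen/sqrt(2); sites are integer
    triples (i, j, k) with even coordinate sum, nearest neighbours at the
    12 face-diagonal offsets, bond length h_gen."""

    def __init__(self, L: float, h_gen: float):
        self.s = h_gen / np.sqrt(2.0)
        self.h_gen = h_gen
        self.K = int(np.floor(L / self.s + 1e-9))
        self.L = L

    def inside(self, site) -> bool:
        i, j, k = site
        return 0 <= i <= self.K and 0 <= j <= self.K and 0 <= k <= self.K

    def position(self, site) -> np.ndarray:
        return np.asarray(site, dtype=float) * self.s

    def neighbors(self, site):
        i, j, k = site
        for di, dj, dk in _OFFSETS:
            n = (i + di, j + dj, k + dk)
            if self.inside(n):
                yield n

    def face_sites(self, axis: int, high: bool):
        """All lattice sites on one boundary face."""
        v = self.K if high else 0
        out = []
        for a in range(self.K + 1):
            for b in range(self.K + 1):
                site = [0, 0, 0]
                site[axis] = v
                site[(axis + 1) % 3] = a
                site[(axis + 2) % 3] = b
                if (site[0] + site[1] + site[2]) % 2 == 0:
                    out.append(tuple(site))
        return out


@dataclass
class RootPlacement:
    scheme: str
    roots: list = field(default_factory=list)     # (site, role)
    chains: list = field(default_factory=list)    # (list of sites, role)
    p_root: float | None = None

    def positions_roles(self, lat: FccLattice):
        return [(lat.position(s), role) for s, role in self.roots]


def _alt_role(site) -> int:
    """Checkerboard arterial/venous alternation on a boundary face."""
    return ARTERIAL_ROOT if ((site[0] + site[1] + site[2]) // 2) % 2 == 0 \
        else VENOUS_ROOT


def _diag_site(lat: FccLattice, axis: int, high: bool, frac: float):
    """Site nearest to ``frac`` of the face diagonal, parity-adjusted."""
    v = lat.K if high else 0
    t = int(round(frac * lat.K))
    site = [0, 0, 0]
    site[axis] = v
    site[(axis + 1) % 3] = t
    site[(axis + 2) % 3] = t
    if sum(site) % 2 != 0:
        site[(axis + 1) % 3] = min(t + 1, lat.K)
    return tuple(site)


def _x_chain(lat: FccLattice, start, n_steps: int):
    """Zig-zag chain of FCC bonds advancing along +x or -x."""
    i, j, k = start
    direction = 1 if i == 0 else -1
    sites = [start]
    for step in range(n_steps):
        dj = 1 if step % 2 == 0 else -1
        nxt = (i + direction, j + dj, k)
        if not lat.inside(nxt):
            nxt = (i + direction, j - dj, k)
            if not lat.inside(nxt):
                break
        sites.append(nxt)
        i, j, k = nxt
    return sites


def place_roots(scheme: str, L: float, h_gen: float, rng,
                p_root: float | None = None) -> tuple[RootPlacement, FccLattice]:
    """Root nodes (and RC7/RC8 parent-vessel chains) for the nine boundary
    configurations. RC9 draws p_root ~ U(0,1) when not given and redraws
    (bounded) until at least one arterial and one venous root exist."""
    lat = FccLattice(L, h_gen)
    pl = RootPlacement(scheme=scheme)
    if scheme in ("RC1", "RC2", "RC3"):
        faces = {"RC1": [(0, False)],
                 "RC2": [(0, False), (0, True)],
                 "RC3": [(0, False), (0, True), (1, False), (1, True)]}[scheme]
        for axis, high in faces:
            for s in lat.face_sites(axis, high):
                pl.roots.append((s, _alt_role(s)))
    elif scheme == "RC4":
        pl.roots.append((_diag_site(lat, 0, False, 1 / 3), ARTERIAL_ROOT))
        pl.roots.append((_diag_site(lat, 0, False, 2 / 3), VENOUS_ROOT))
    elif scheme == "RC5":
        pl.roots.append((_diag_site(lat, 0, False, 1 / 3), ARTERIAL_ROOT))
        pl.roots.append((_diag_site(lat, 0, True, 2 / 3), VENOUS_ROOT))
    elif scheme == "RC6":
        pl.roots.append((_diag_site(lat, 0, False, 1 / 3), ARTERIAL_ROOT))
        pl.roots.append((_diag_site(lat, 0, True, 1 / 3), VENOUS_ROOT))
        pl.roots.append((_diag_site(lat, 1, False, 2 / 3), ARTERIAL_ROOT))
        pl.roots.append((_diag_site(lat, 1, True, 2 / 3), VENOUS_ROOT))
    elif scheme in ("RC7", "RC8"):
        n_steps = int(round(0.6 * lat.K))
        n_pairs = 1 if scheme == "RC7" else 2
        fracs = [0.5] if n_pairs == 1 else [0.3, 0.7]
        for fr in fracs:
            ja = int(round(fr * lat.K))
            sa = _parity_fix(lat, (0, ja, int(round(0.35 * lat.K))))
            sv = _parity_fix(lat, (lat.K, ja, int(round(0.65 * lat.K))))
            pl.chains.append((_x_chain(lat, sa, n_steps), ARTERIAL_ROOT))
            pl.chains.append((_x_chain(lat, sv, n_steps), VENOUS_ROOT))
    elif scheme == "RC9":
        all_faces = [lat.face_sites(ax, hi) for ax in range(3)
                     for hi in (False, True)]
        sites = sorted(set(s for f in all_faces for s in f))
        for _ in range(100):
            p = float(rng.uniform(0.0, 1.0)) if p_root is None else p_root
            pl.roots = [(s, _alt_role(s)) for s in sites if rng.uniform() < p]
            roles = {r for _, r in pl.roots}
            if ARTERIAL_ROOT in roles and VENOUS_ROOT in roles:
                pl.p_root = p
                break
        else:
            raise RuntimeError("RC9: no accepted root draw in 100 attempts")
    else:
        raise ValueError(f"unknown root geometry {scheme!r}")
    roles = {r for _, r in pl.roots} | {r for _, r in pl.chains}
    if ARTERIAL_ROOT not in roles or VENOUS_ROOT not in roles:
        raise ValueError(f"{scheme}: configuration lacks arterial or venous root")
    return pl, lat


def _parity_fix(lat: FccLattice, site):
    i, j, k = (min(max(c, 0), lat.K) for c in site)
    if (i + j + k) % 2 != 0:
        k = k + 1 if k + 1 <= lat.K else k - 1
    return (i, j, k)


class Forest:
    """Growing arterial/venous trees on the lattice. Per occupied site:
    owner tree, parent site (None at roots) and children list."""

    def __init__(self, lat: FccLattice, p_tripod: float = 0.5):
        self.lat = lat
        self.p_tripod = p_tripod
        self.owner: dict = {}      # site -> tree index
        self.parent: dict = {}     # site -> site | None
        self.children: dict = {}   # site -> list of sites
        self.tree_role: list[int] = []
        self.tree_root: list = []
        self.protected: set = set()   # sites never pruned (roots, parents)

    def new_tree(self, root_site, role: int) -> int:
        t = len(self.tree_role)
        self.tree_role.append(role)
        self.tree_root.append(root_site)
        self.owner[root_site] = t
        self.parent[root_site] = None
        self.children[root_site] = []
        self.protected.add(root_site)
        return t

    def add_site(self, parent_site, site):
        self.owner[site] = self.owner[parent_site]
        self.parent[site] = parent_site
        self.children[site] = []
        self.children[parent_site].append(site)

    def remove_leaf(self, site):
        p = self.parent[site]
        self.children[p].remove(site)
        del self.owner[site], self.parent[site], self.children[site]

    def degree(self, site) -> int:
        return len(self.children[site]) + (0 if self.parent[site] is None else 1)

    def leaves(self):
        return [s for s, ch in self.children.items()
                if not ch and self.parent[s] is not None]

    def bonds(self):
        for s, p in self.parent.items():
            if p is not None:
                yield (p, s)


def _try_extend(forest: Forest, site, rng) -> list:
    """Attach a linear or tripod element at ``site`` (must have degree < 3);
    returns the list of newly created leaf sites (empty on failure)."""
    lat = forest.lat
    free = [n for n in lat.neighbors(site) if n not in forest.owner]
    if not free:
        return []
    tripod_first = rng.uniform() < forest.p_tripod
    for kind in (("tripod", "linear") if tripod_first else ("linear", "tripod")):
        if kind == "linear":
            c = free[int(rng.integers(len(free)))]
            forest.add_site(site, c)
            return [c]
        # tripod: new site c with two further free neighbours
        cands = list(free)
        rng.shuffle(cands)
        for c in cands:
            sub = [n for n in lat.neighbors(c)
                   if n not in forest.owner and n != site]
            if len(sub) >= 2:
                pick = rng.choice(len(sub), size=2, replace=False)
                forest.add_site(site, c)
                forest.add_site(c, sub[int(pick[0])])
                forest.add_site(c, sub[int(pick[1])])
                return [sub[int(pick[0])], sub[int(pick[1])]]
    return []


def regrow_to_jamming(forest: Forest, rng, sites=None) -> None:
    """Extend randomly selected terminal branches until no element can be
    added without overlap (also used after refinement pruning to refill
    freed lattice space)."""
    if sites is None:
        active = [s for s, ch in forest.children.items()
                  if not ch or forest.degree(s) < 3]
    else:
        active = [s for s in sites if s in forest.owner]
    while active:
        i = int(rng.integers(len(active)))
        site = active[i]
        new_leaves = [] if forest.degree(site) >= 3 \
            else _try_extend(forest, site, rng)
        if not new_leaves:
            active[i] = active[-1]
            active.pop()
            continue
        active.extend(new_leaves)


def grow_trees(placement: RootPlacement, lat: FccLattice, rng,
               p_tripod: float = 0.5) -> Forest:
    """Random growth by linear/tripod elements at randomly selected
    terminal branches until no element can be added without overlap."""
    forest = Forest(lat, p_tripod=p_tripod)
    active = []
    for site, role in placement.roots:
        if site in forest.owner:
            continue
        forest.new_tree(site, role)
        active.append(site)
    for chain, role in placement.chains:
        t = forest.new_tree(chain[0], role)
        for a, b in zip(chain[:-1], chain[1:]):
            forest.add_site(a, b)
            forest.protected.add(b)
        active.extend(chain)
    regrow_to_jamming(forest, rng, sites=active)
    return forest


_OFFSETS_2ND = [(2, 0, 0), (-2, 0, 0), (0, 2, 0), (0, -2, 0),
                (0, 0, 2), (0, 0, -2)]


def connect_capillaries(forest: Forest, rng, max_shell: int = 2) -> list[tuple]:
    """Join nearby opposite-type open ends with capillary segments.

    First-shell (one lattice bond) pairs are connected first; with
    ``max_shell=2`` unmatched open ends may also bridge to the second FCC
    shell (sqrt(2) h chords, which pass through no lattice site). Each
    open end hosts at most two capillaries.
    """
    caps = []
    in_seen: set = set()
    used_v: dict = {}
    leaves = forest.leaves()
    art_leaves = [s for s in leaves
                  if forest.tree_role[forest.owner[s]] == ARTERIAL_ROOT]
    ven_leafset = {s for s in leaves
                   if forest.tree_role[forest.owner[s]] == VENOUS_ROOT}
    shells = [_OFFSETS] if max_shell < 2 else [_OFFSETS, _OFFSETS_2ND]
    used_a: dict = {}
    pool = list(art_leaves)
    for shell in shells:
        for round_ in range(2):      # open ends may host up to two capillaries
            order = np.arange(len(pool))
            rng.shuffle(order)
            for idx in order:
                a = pool[idx]
                if used_a.get(a, 0) > round_:
                    continue
                cands = []
                for di, dj, dk in shell:
                    n = (a[0] + di, a[1] + dj, a[2] + dk)
                    if n in ven_leafset and used_v.get(n, 0) < 2 \
                            and (a, n) not in in_seen:
                        cands.append(n)
                if not cands:
                    continue
                v = cands[int(rng.integers(len(cands)))]
                caps.append((a, v))
                in_seen.add((a, v))
                used_v[v] = used_v.get(v, 0) + 1
                used_a[a] = used_a.get(a, 0) + 1
    return caps


def murray_parent_radius(radii, alpha: float = MURRAY_ALPHA) -> float:
    """r_parent = (sum_i r_i^alpha)^(1/alpha)."""
    radii = np.asarray(radii, dtype=float)
    return float((radii ** alpha).sum() ** (1.0 / alpha))


def assign_radii_murray(forest: Forest, alpha: float = MURRAY_ALPHA) -> dict:
    """Bottom-up Murray radii per bond (keyed by the downstream site):
    terminal bonds get the fixed arterial/venous calibres."""
    radius: dict = {}
    for t, root in enumerate(forest.tree_root):
        role = forest.tree_role[t]
        r_term = R_TERM_ART if role == ARTERIAL_ROOT else R_TERM_VEIN
        # post-order traversal
        stack = [(root, False)]
        while stack:
            site, done = stack.pop()
            if not done:
                stack.append((site, True))
                for c in forest.children[site]:
                    stack.append((c, False))
            else:
                ch = forest.children[site]
                if not ch:
                    radius[site] = r_term
                else:
                    radius[site] = murray_parent_radius(
                        [radius[c] for c in ch], alpha)
    return radius


def build_network(forest: Forest, caps, radius: dict,
                  H: float = 0.45) -> VesselNetwork:
    """Materialize forest + capillaries into a VesselNetwork."""
    lat = forest.lat
    net = VesselNetwork()
    node_of: dict = {}
    positions: list = []

    def node(site):
        if site not in node_of:
            node_of[site] = len(positions)
            positions.append(lat.position(site))
        return node_of[site]

    aa, bb, rr, ww, ff = [], [], [], [], []
    for p, s in forest.bonds():
        role = forest.tree_role[forest.owner[s]]
        aa.append(node(p))
        bb.append(node(s))
        rr.append(radius[s])
        ww.append(min(radius[s] / 2.0, 10.0))
        ff.append(ARTERY if role == ARTERIAL_ROOT else VEIN)
    for a, v in caps:
        aa.append(node(a))
        bb.append(node(v))
        rr.append(R_CAPILLARY)
        ww.append(min(R_CAPILLARY / 2.0, 10.0))
        ff.append(CAPILLARY)
    net.add_nodes(positions)
    for t, root in enumerate(forest.tree_root):
        if root in node_of:
            net.role[node_of[root]] = forest.tree_role[t]
    if aa:
        net.add_segments(aa, bb, rr, H=H, w=ww, flags=ff)
    return net


def plateau_reached(counts, window: int = 5, tol: float = 0.02) -> bool:
    """Capillary-count plateau: the last ``window`` counts vary by less
    than ``tol`` relative to their mean."""
    if len(counts) < window:
        return False
    tail = np.asarray(counts[-window:], dtype=float)
    return float(tail.max() - tail.min()) <= tol * float(tail.mean())


def shear_guided_refinement(forest: Forest, hemo: HemoParams, rng,
                            max_sweeps: int = 20, window: int = 5,
                            tol: float = 0.02, p_event: float = 0.5):
    """Prune/extend terminal branches with wall-shear-stress dependent
    probabilities until the capillary count plateaus.

    Removal probability decreases, attachment probability increases, in
    the local shear via a logistic centred on the median terminal shear
    (self-scaling, so the loop balances turnover without an absolute
    shear calibration). Returns (capillary list, count history).
    """
    counts: list[int] = []
    caps = connect_capillaries(forest, rng)
    for sweep in range(max_sweeps):
        radius = assign_radii_murray(forest)
        net = build_network(forest, caps, radius, H=hemo.H_bc)
        try:
            flow = solve_pressures(net, hemo)
        except ValueError:
            break
        counts.append(len(caps))
        if plateau_reached(counts, window, tol):
            break
        # shear of the terminal bond of each leaf: segments were added in
        # bonds() order, keyed by their downstream site
        f_of_leaf = {}
        for seg_i, (p, s) in enumerate(forest.bonds()):
            f_of_leaf[s] = flow.f[seg_i]
        leaves = forest.leaves()
        fvals = np.array([f_of_leaf.get(s, 0.0) for s in leaves])
        if len(fvals) == 0:
            break
        f_ref = float(np.median(fvals))
        f_scale = max(0.2 * f_ref, 1e-6)
        order = np.arange(len(leaves))
        rng.shuffle(order)
        for li in order:
            s = leaves[li]
            if s not in forest.owner or s in forest.protected:
                continue
            if forest.children[s]:
                continue
            f = f_of_leaf.get(s, 0.0)
            z = float(np.clip((f - f_ref) / f_scale, -50.0, 50.0))
            p_att = p_event / (1.0 + np.exp(-z))
            p_rem = p_event / (1.0 + np.exp(z))
            u = rng.uniform()
            if u < p_rem:
                forest.remove_leaf(s)
            elif u < p_rem + p_att:
                _try_extend(forest, s, rng)
        # refill freed lattice space: the surviving (better-perfused)
        # terminals reclaim it, reallocating sites between trees
        regrow_to_jamming(forest, rng)
        caps = connect_capillaries(forest, rng)
    return caps, counts


def prune_unmatched(forest: Forest, caps) -> list[tuple]:
    """Erode terminal chains whose open end carries no capillary, so that
    every terminal branch ends in a capillary connection or a root."""
    matched = set()
    for a, v in caps:
        matched.add(a)
        matched.add(v)
    while True:
        removable = [s for s in forest.leaves()
                     if s not in matched and s not in forest.protected]
        if not removable:
            break
        for s in removable:
            forest.remove_leaf(s)
    return caps


def generate_initial_network(config: SimConfig, rng=None) -> VesselNetwork:
    """Full t=0 pipeline: roots -> tree growth -> shear-guided refinement
    -> capillary closure (every open end matched or pruned) -> Murray
    radii -> converged hemodynamics."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    placement, lat = place_roots(config.root_geometry, config.L,
                                 config.growth.h_gen, rng)
    forest = grow_trees(placement, lat, rng,
                        p_tripod=config.growth.p_tripod)
    caps, _ = shear_guided_refinement(forest, config.hemo, rng)
    for _ in range(4):
        prune_unmatched(forest, caps)
        regrow_to_jamming(forest, rng)
        caps = connect_capillaries(forest, rng)
    prune_unmatched(forest, caps)
    radius = assign_radii_murray(forest)
    net = build_network(forest, caps, radius, H=config.hemo.H_bc)
    solve_hemodynamics(net, config.hemo)
    return net


def fine_subdivide(net: VesselNetwork, fine_h: float) -> VesselNetwork:
    """Resample segments onto ~``fine_h`` pieces (chain nodes inserted);
    run before tumor remodeling so sprouting and regression operate at the
    fine lattice scale."""
    out = VesselNetwork()
    out.pos = net.pos.copy()
    out.role = net.role.copy()
    out.pressure = net.pressure.copy()
    new_pos: list = []
    aa, bb, src = [], [], []
    next_id = net.n_nodes
    for s in range(net.n_segments):
        n_pieces = max(1, int(round(net.l[s] / fine_h)))
        a, b = int(net.a[s]), int(net.b[s])
        prev = a
        for i in range(1, n_pieces + 1):
            if i == n_pieces:
                nid = b
            else:
                t = i / n_pieces
                new_pos.append(net.pos[a] * (1 - t) + net.pos[b] * t)
                nid = next_id
                next_id += 1
            aa.append(prev)
            bb.append(nid)
            src.append(s)
            prev = nid
    if new_pos:
        out.add_nodes(new_pos)
    src = np.asarray(src, dtype=np.int64)
    out.add_segments(aa, bb, net.r[src], H=net.H[src], w=net.w[src],
                     flags=net.flags[src], tau=net.tau[src],
                     r_tilde=net.r_tilde[src])
    return out
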