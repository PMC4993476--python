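"""Domain types, unit conventions, validation and serialization.

Internal unit conventions
-------------------------
lengths        micrometres (um)
time           seconds (remodeling parameters are stated in hours and
               converted where used)
pressure       mmHg at the interface; Poiseuille conductances absorb the
               mmHg -> Pa factor so segment flows come out in um^3/s
flow           um^3/s, signed positive from node ``a`` to node ``b``
viscosity      mPa*s (= 1e-3 Pa*s)
oxygen content mlO2 per ml (equivalently um^3 O2 per um^3)

All conversion factors live here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

#: hemoglobin tetramer molar mass, g/mol (used for the umol/l conversion of c_Hb)
HEMOGLOBIN_MOLAR_MASS = 64500.0

# node roles
INTERIOR, ARTERIAL_ROOT, VENOUS_ROOT = 0, 1, 2

# segment flag bits
ARTERY = 1
VEIN = 2
CAPILLARY = 4
TUMOR = 8
SPROUT = 16
BOUNDARY = 32


@dataclass
class OxygenParams:
    """Parameters of the blood / tissue oxygen model.

    Defaults are the standard parameter set used throughout; pressures in
    mmHg, diffusivities in um^2/s, solubilities in mlO2 ml^-1 mmHg^-1,
    consumption rates in mlO2 ml^-1 s^-1.
    """

    n: float = 2.7                      # Hill exponent
    P_S50: float = 27.0                 # half-saturation PO2 of hemoglobin
    alpha_p: float = 3.1e-5             # plasma O2 solubility
    alpha_t: float = 2.8e-5             # tissue O2 solubility
    c0: float = 0.5                     # O2 capacity of saturated RBCs, mlO2/ml
    D_t: float = 2410.0                 # tissue O2 diffusivity
    D_p: float = 2750.0                 # plasma O2 diffusivity
    P_M50_normal: float = 4.0           # Michaelis pressure, normal tissue
    P_M50_tumor: float = 2.0            # Michaelis pressure, tumor tissue
    M0_normal: float = 3.7e-3 / 60.0    # max consumption, normal (mlO2/ml/s)
    M0_tumor: float = 14.8e-3 / 60.0    # max consumption, tumor (mlO2/ml/s)
    # Nusselt-number fit Nu(r) = p2*(1 - exp(-r/p1))
    nu_p1: float = 8.0
    nu_p2: float = 4.7
    # arterial inlet PO2 curve P_bc(r) = min(P0 + dP*r, Pc)
    P0_bc: float = 55.0
    dP_bc: float = 1.0
    Pc_bc: float = 100.0
    h: float = 40.0                     # tissue grid constant, um
    h_v: float = 4.0                    # vessel integration step, um
    eps: float = 0.1                    # fixed-point stopping tolerance, mmHg
    max_iter: int = 2000


@dataclass
class HemoParams:
    """Hemodynamics parameters: plasma viscosity, boundary conditions and
    the empirical-law parameterisations."""

    eta_plasma: float = 1.2             # mPa*s
    H_bc: float = 0.45                  # inlet (discharge) hematocrit
    viscosity_law: str = "invivo"       # "invivo" (default) or "invitro"
    phase_separation_law: str = "pries1990"  # or "invivo2005"
    # root pressure curves p(r), mmHg; saturating exponentials. Defaults were
    # set with scripts/calibrate_bc.py against the t=0 perfusion target.
    p_cap: float = 23.0                 # pressure scale at capillary calibre
    p_art_max: float = 85.0             # large-arteriole asymptote
    p_ven_min: float = 10.0             # large-venule asymptote
    r_scale_art: float = 10.0           # um, radius scale of the arterial curve
    r_scale_ven: float = 10.0
    relax_H: float = 0.5                # under-relaxation on hematocrit
    tol_H: float = 1e-4
    max_iter: int = 100

    def root_pressure(self, r: float, role: int) -> float:
        """Radius-dependent root pressure boundary condition, mmHg."""
        if role == ARTERIAL_ROOT:
            return self.p_cap + (self.p_art_max - self.p_cap) * (
                1.0 - np.exp(-r / self.r_scale_art))
        if role == VENOUS_ROOT:
            return self.p_cap - (self.p_cap - self.p_ven_min) * (
                1.0 - np.exp(-r / self.r_scale_ven))
        raise ValueError("root_pressure only defined for root nodes")


@dataclass
class GrowthParams:
    """Tumor growth / vascular remodeling parameters (times in hours)."""

    R_tum0: float = 250.0               # initial tumor radius, um
    v_tum: float = 2.0                  # radial expansion speed, um/h
    R_g: float = 200.0                  # growth-factor diffusion range, um
    t_switch: float = 12.0              # delay before circumferential growth, h
    t_sprout: float = 2.0               # sprouting timescale, h
    t_migr: float = 50.0                # sprout lifetime, h
    d_br_min: float = 80.0              # min path distance to branch point, um
    t_prol: float = 144.0               # endothelial doubling time, h
    r_sprout: float = 2.6               # initial sprout radius, um
    r_max: float = 10.0                 # dilatation cap (14 in CMPR), um
    p_coll: float = 1.0                 # collapse probability
    dw: float = 0.05                    # wall degradation rate, um/h
    f_coll: float = 0.25                # collapse shear threshold, Pa
    h_gen: float = 130.0                # generation lattice constant, um
    p_tripod: float = 0.5               # tripod (vs linear) element weight
    fine_h: float = 10.0                # remodeling lattice constant, um
    dt: float = 1.0                     # time step, h
    t_end: float = 600.0                # end of growth, h
    w_cpr: float = 200.0                # compression transition half-width, um


@dataclass
class SimConfig:
    """Full configuration of one simulation run."""

    oxygen: OxygenParams = field(default_factory=OxygenParams)
    hemo: HemoParams = field(default_factory=HemoParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    scenario: str = "BASE"              # BASE | CMPR | METAB
    root_geometry: str = "RC1"          # RC1..RC9
    L: float = 8000.0                   # domain edge length, um
    seed: int = 0
    xi_cpr: float | None = None         # CMPR compression factor (drawn per run)
    M0_tumor_draw: float | None = None  # METAB per-run tumor M0 (mlO2/ml/s)

    def __post_init__(self):
        if self.scenario not in ("BASE", "CMPR", "METAB"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.xi_cpr is not None and not (0.5 <= self.xi_cpr <= 1.0):
            raise ValueError("xi_cpr must lie in [0.5, 1]")
        if self.scenario == "CMPR" and self.growth.r_max == 10.0:
            # CMPR compensates overall compression by a larger dilatation cap
            self.growth.r_max = 14.0

    @property
    def center(self) -> np.ndarray:
        return np.full(3, self.L / 2.0)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SimConfig":
        d = json.loads(s)
        d["oxygen"] = OxygenParams(**d["oxygen"])
        d["hemo"] = HemoParams(**d["hemo"])
        d["growth"] = GrowthParams(**d["growth"])
        return cls(**d)


class VesselNetwork:
    """Graph of vessel segments with per-node and per-segment state.

    Nodes carry a position (um), a role (interior / arterial root / venous
    root) and the last solved blood pressure (mmHg). Segments carry radius
    ``r``, compressed radius ``r_tilde`` (= r outside tumor influence),
    length ``l``, hematocrit ``H``, signed flow ``q`` (positive a->b),
    wall stability ``w``, bit flags and sprout age ``tau`` (hours).
    """

    NODE_FIELDS = ("pos", "role", "pressure")
    SEG_FIELDS = ("a", "b", "r", "r_tilde", "l", "H", "q", "w", "flags", "tau")

    def __init__(self):
        self.pos = np.zeros((0, 3), dtype=float)
        self.role = np.zeros(0, dtype=np.int8)
        self.pressure = np.zeros(0, dtype=float)
        self.a = np.zeros(0, dtype=np.int64)
        self.b = np.zeros(0, dtype=np.int64)
        self.r = np.zeros(0, dtype=float)
        self.r_tilde = np.zeros(0, dtype=float)
        self.l = np.zeros(0, dtype=float)
        self.H = np.zeros(0, dtype=float)
        self.q = np.zeros(0, dtype=float)
        self.w = np.zeros(0, dtype=float)
        self.flags = np.zeros(0, dtype=np.int32)
        self.tau = np.zeros(0, dtype=float)

    # -- construction -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.pos)

    @property
    def n_segments(self) -> int:
        return len(self.a)

    def add_nodes(self, pos, role=INTERIOR, pressure=0.0) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        k = len(pos)
        ids = np.arange(self.n_nodes, self.n_nodes + k)
        self.pos = np.vstack([self.pos, pos])
        self.role = np.concatenate([self.role, np.broadcast_to(
            np.asarray(role, dtype=np.int8), (k,)).copy()])
        self.pressure = np.concatenate([self.pressure, np.broadcast_to(
            np.asarray(pressure, dtype=float), (k,)).copy()])
        return ids

    def add_node(self, pos, role=INTERIOR, pressure=0.0) -> int:
        return int(self.add_nodes([pos], role, pressure)[0])

    def add_segments(self, a, b, r, H=0.45, w=0.0, flags=0, tau=0.0,
                     r_tilde=None) -> np.ndarray:
        a = np.atleast_1d(np.asarray(a, dtype=np.int64))
        b = np.atleast_1d(np.asarray(b, dtype=np.int64))
        k = len(a)
        ids = np.arange(self.n_segments, self.n_segments + k)
        r = np.broadcast_to(np.asarray(r, dtype=float), (k,)).copy()
        l = np.linalg.norm(self.pos[b] - self.pos[a], axis=1)
        self.a = np.concatenate([self.a, a])
        self.b = np.concatenate([self.b, b])
        self.r = np.concatenate([self.r, r])
        self.r_tilde = np.concatenate(
            [self.r_tilde, r.copy() if r_tilde is None else
             np.broadcast_to(np.asarray(r_tilde, float), (k,)).copy()])
        self.l = np.concatenate([self.l, l])
        for name, val in (("H", H), ("q", 0.0), ("w", w), ("tau", tau)):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate(
                [arr, np.broadcast_to(np.asarray(val, float), (k,)).copy()]))
        self.flags = np.concatenate([self.flags, np.broadcast_to(
            np.asarray(flags, np.int32), (k,)).copy()])
        return ids

    def add_segment(self, a, b, r, **kw) -> int:
        return int(self.add_segments([a], [b], r, **kw)[0])

    def remove_segments(self, seg_ids) -> None:
        keep = np.ones(self.n_segments, dtype=bool)
        keep[np.asarray(seg_ids, dtype=np.int64)] = False
        self.keep_segments(keep)

    def keep_segments(self, keep_mask) -> None:
        for name in self.SEG_FIELDS:
            setattr(self, name, getattr(self, name)[keep_mask])

    # -- topology helpers -------------------------------------------------
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.a, 1)
        np.add.at(deg, self.b, 1)
        return deg

    def incident_segments(self):
        """List of incident segment ids per node."""
        inc = [[] for _ in range(self.n_nodes)]
        for s in range(self.n_segments):
            inc[self.a[s]].append(s)
            inc[self.b[s]].append(s)
        return inc

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.pos[self.a] + self.pos[self.b])

    def arterial_roots(self) -> np.ndarray:
        return np.flatnonzero(self.role == ARTERIAL_ROOT)

    def venous_roots(self) -> np.ndarray:
        return np.flatnonzero(self.role == VENOUS_ROOT)

    def copy(self) -> "VesselNetwork":
        out = VesselNetwork()
        for name in self.NODE_FIELDS + self.SEG_FIELDS:
            setattr(out, name, getattr(self, name).copy())
        return out


def validate_network(net: VesselNetwork, L: float | None = None) -> list[str]:
    """Check the structural invariants; returns a list of violation strings
    (empty iff the network is valid). Reporting only, never raises."""
    v: list[str] = []
    if net.n_segments and (net.a.max() >= net.n_nodes or net.b.max() >= net.n_nodes
                           or net.a.min() < 0 or net.b.min() < 0):
        bad = np.flatnonzero((net.a >= net.n_nodes) | (net.b >= net.n_nodes)
                             | (net.a < 0) | (net.b < 0))
        for s in bad:
            v.append(f"segment {s}: endpoint does not exist")
        return v  # other checks would index out of bounds
    deg = net.degrees()
    for nid in np.flatnonzero(deg > 3):
        v.append(f"node {nid}: degree {deg[nid]} > 3")
    if L is not None and net.n_nodes:
        out = np.flatnonzero(((net.pos < -1e-6) | (net.pos > L + 1e-6)).any(axis=1))
        for nid in out:
            v.append(f"node {nid}: position outside [0, L]^3")
    for s in np.flatnonzero(net.r <= 0):
        v.append(f"segment {s}: radius {net.r[s]} <= 0")
    for s in np.flatnonzero(net.r_tilde > net.r + 1e-9):
        v.append(f"segment {s}: compressed radius exceeds radius")
    for s in np.flatnonzero((net.H < 0) | (net.H > 1)):
        v.append(f"segment {s}: hematocrit {net.H[s]} outside [0, 1]")
    for s in np.flatnonzero(net.w < 0):
        v.append(f"segment {s}: wall stability {net.w[s]} < 0")
    if net.n_segments:
        d = np.linalg.norm(net.pos[net.b] - net.pos[net.a], axis=1)
        bad = np.flatnonzero(np.abs(d - net.l) > 1e-6 * np.maximum(1.0, d))
        for s in bad:
            v.append(f"segment {s}: stored length {net.l[s]:.6g} != "
                     f"endpoint distance {d[s]:.6g}")
        zero = np.flatnonzero(net.l <= 0)
        for s in zero:
            v.append(f"segment {s}: length {net.l[s]} <= 0")
    if not len(net.arterial_roots()):
        v.append("network: no arterial root")
    if not len(net.venous_roots()):
        v.append("network: no venous root")
    return v


def save_network(net: VesselNetwork, path, config: SimConfig | None = None) -> None:
    """Write a network to HDF5 (/nodes, /segments, /meta)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("nodes")
        g.create_dataset("id", data=np.arange(net.n_nodes))
        g.create_dataset("x", data=net.pos[:, 0])
        g.create_dataset("y", data=net.pos[:, 1])
        g.create_dataset("z", data=net.pos[:, 2])
        g.create_dataset("role", data=net.role)
        g.create_dataset("pressure", data=net.pressure)
        g = f.create_group("segments")
        g.create_dataset("id", data=np.arange(net.n_segments))
        for name in ("a", "b", "r", "r_tilde", "l", "H", "q", "w", "flags", "tau"):
            g.create_dataset(name, data=getattr(net, name))
        meta = f.create_group("meta")
        if config is not None:
            meta.attrs["config"] = config.to_json()


def load_network(path) -> tuple[VesselNetwork, SimConfig | None]:
    """Read a network written by :func:`save_network`.

    Raises ``KeyError`` naming the missing record on malformed files.
    """
    net = VesselNetwork()
    with h5py.File(path, "r") as f:
        try:
            g = f["nodes"]
            net.pos = np.column_stack([g["x"][:], g["y"][:], g["z"][:]])
            net.role = g["role"][:].astype(np.int8)
            net.pressure = g["pressure"][:]
            g = f["segments"]
            for name in ("a", "b", "r", "r_tilde", "l", "H", "q", "w",
                         "flags", "tau"):
                setattr(net, name, g[name][:])
        except KeyError as e:
            raise KeyError(f"malformed network file {path}: missing {e}") from e
        net.a = net.a.astype(np.int64)
        net.b = net.b.astype(np.int64)
        net.flags = net.flags.astype(np.int32)
        cfg = None
        if "meta" in f and "config" in f["meta"].attrs:
            cfg = SimConfig.from_json(f["meta"].attrs["config"])
    return net, cfg


@dataclass
class TissueGrid:
    """Regular cubic grid of tissue oxygen partial pressure over (0, L)^3.

    Grid sites sit at ``i*h`` for i = 0..N with N = L/h, so ``shape`` is
    (N+1, N+1, N+1) and values are PO2 in mmHg.
    """

    h: float
    L: float
    values: np.ndarray  # 3-d array, mmHg

    @classmethod
    def empty(cls, L: float, h: float, fill: float = 0.0) -> "TissueGrid":
        n = int(round(L / h)) + 1
        return cls(h=h, L=L, values=np.full((n, n, n), fill, dtype=float))

    @property
    def shape(self):
        return self.values.shape

    def site_positions_1d(self) -> np.ndarray:
        return np.arange(self.shape[0]) * self.h


@dataclass
class OxygenSolution:
    """Converged intravascular PO2 samples + tissue field."""

    point_offsets: np.ndarray   # (n_seg+1,) CSR offsets into point arrays
    P: np.ndarray               # PO2 at integration points, mmHg
    S_mean: np.ndarray          # per-segment length-averaged saturation
    tissue: TissueGrid
    iterations: int
    converged: bool
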