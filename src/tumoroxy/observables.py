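"""Tissue-level derived quantities: vascular morphology densities,
hemoglobin concentrations, saturations, perfusion and oxygen metabolics.

Conventions: microvessel density is reported as the line density L_D
(total centerline length per volume, mm/mm^3 printed as mm^-2); rBV in %;
perfusion in ml g^-1 min^-1 with tissue mass density 1 g/ml; hemoglobin
in umol/l using the 64.5 kg/mol tetramer molar mass; MRO2 and rJ_in in
ulO2 ml^-1 min^-1. A segment belongs to a region if its midpoint does;
radial profiles clip segments to shells by length fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (ARTERIAL_ROOT, HEMOGLOBIN_MOLAR_MASS, VENOUS_ROOT,
                   OxygenParams, OxygenSolution, VesselNetwork)
from .hemodynamics import FlowState
from .oxygen import hill_saturation, mm_consumption

MCHC = 0.34          # mean corpuscular hemoglobin concentration, g/ml
HUEFNER = 1.36       # hemoglobin O2 binding capacity, mlO2/g

__all__ = [
    "tissue_hemoglobin", "tissue_blood_oxygen_saturation",
    "length_weighted_saturation", "vascular_densities", "perfusion",
    "oxygen_metabolics", "estimate_M0_zeroth_order", "radial_profiles",
    "regional_hematocrit_ratio", "observable_record",
]


def _mask(net: VesselNetwork, mask):
    if mask is None:
        return np.ones(net.n_segments, dtype=bool)
    return np.asarray(mask, dtype=bool)


def tissue_hemoglobin(net: VesselNetwork, volume: float, mask=None,
                      mchc: float = MCHC) -> float:
    """Tissue total hemoglobin concentration, umol/l.

    c_Hb = MCHC * (RBC volume fraction) = MCHC/|Omega| * sum pi r^2 l H.
    """
    m = _mask(net, mask)
    if not m.any():
        raise ValueError("empty region")
    rrbcv = float(np.sum(np.pi * net.r_tilde[m] ** 2 * net.l[m] * net.H[m])
                  / volume)
    g_per_ml = mchc * rrbcv
    return g_per_ml * 1e9 / HEMOGLOBIN_MOLAR_MASS   # -> umol/l


def tissue_blood_oxygen_saturation(net: VesselNetwork, sol: OxygenSolution,
                                   mask=None) -> float:
    """Y = c_HbO / c_Hb: RBC-volume-weighted mean of the per-segment
    length-averaged saturation."""
    m = _mask(net, mask)
    w = np.pi * net.r_tilde[m] ** 2 * net.l[m] * net.H[m]
    tot = w.sum()
    if tot <= 0:
        raise ValueError("zero total RBC volume in region")
    return float((w * sol.S_mean[m]).sum() / tot)


def length_weighted_saturation(net: VesselNetwork, sol: OxygenSolution,
                               mask=None) -> float:
    """<S> = sum l_v S_v / sum l_v (caliber-insensitive)."""
    m = _mask(net, mask)
    if not m.any():
        raise ValueError("empty region")
    return float((net.l[m] * sol.S_mean[m]).sum() / net.l[m].sum())


def vascular_densities(net: VesselNetwork, volume: float, mask=None) -> dict:
    """Line density L_D (mm^-2), rBV (%), surface density S_D (mm^-1),
    S_D/rBV (um^-1) and the length-weighted mean radius (um)."""
    m = _mask(net, mask)
    l = net.l[m]
    r = net.r_tilde[m]
    tot_l = l.sum()
    vol_v = float(np.sum(np.pi * r ** 2 * l))
    surf = float(np.sum(2.0 * np.pi * r * l))
    return {
        "L_D": tot_l / volume * 1e6,            # um^-2 -> mm^-2
        "rBV": vol_v / volume * 100.0,          # %
        "S_D": surf / volume * 1e3,             # um^-1 -> mm^-1
        "S_D_over_rBV": surf / vol_v if vol_v > 0 else np.nan,
        "mean_r": float((l * r).sum() / tot_l) if tot_l > 0 else np.nan,
    }


def perfusion(net: VesselNetwork, flow: FlowState, volume: float,
              center=None, R_sphere: float | None = None, L: float | None = None
              ) -> dict:
    """Perfusion measures in ml g^-1 min^-1 (tissue density 1 g/ml).

    ``rBF`` is the total arterial-root inflow over ``volume``;
    ``rBF_out`` the venous-root outflow (equal by conservation);
    if ``R_sphere`` is given, ``rBF_sph`` is the inward blood flux through
    the sphere surface around ``center`` divided by the sphere volume.
    """
    q_in = 0.0
    q_out = 0.0
    for s in range(net.n_segments):
        for node, sign in ((net.a[s], +1.0), (net.b[s], -1.0)):
            role = net.role[node]
            qs = sign * flow.q[s]     # flow out of `node` into the segment
            if role == ARTERIAL_ROOT and qs > 0:
                q_in += qs
            if role == ARTERIAL_ROOT and qs < 0:
                q_out += -qs
            if role == VENOUS_ROOT and qs < 0:
                q_out += -qs
            if role == VENOUS_ROOT and qs > 0:
                q_in += qs
    out = {"rBF": q_in / volume * 60.0, "rBF_out": q_out / volume * 60.0}
    if R_sphere is not None:
        center = np.asarray(center, dtype=float)
        if L is not None and (np.any(center - R_sphere < 0)
                              or np.any(center + R_sphere > L)):
            raise ValueError("sphere exceeds the simulation domain")
        da = np.linalg.norm(net.pos[net.a] - center, axis=1)
        db = np.linalg.norm(net.pos[net.b] - center, axis=1)
        influx = 0.0
        for s in np.flatnonzero((da < R_sphere) != (db < R_sphere)):
            a_in = da[s] < R_sphere
            q = flow.q[s]
            inward = (q > 0 and not a_in) or (q < 0 and a_in)
            if inward:
                influx += abs(q)
        vol_sph = 4.0 / 3.0 * np.pi * R_sphere ** 3
        out["rBF_sph"] = influx / vol_sph * 60.0
    return out


def oxygen_metabolics(net: VesselNetwork, flow: FlowState,
                      sol: OxygenSolution, params: OxygenParams,
                      volume: float, mask=None, grid_mask=None) -> dict:
    """MRO2, rJ_in, OEF and mean intravascular / tissue PO2.

    rJ_in = c0 <H S_in>_q * rBF uses the flow-weighted hemoglobin-bound
    oxygen at the arterial roots; OEF = MRO2 / rJ_in.
    """
    Pt = sol.tissue.values.ravel()
    gm = np.ones(Pt.shape, bool) if grid_mask is None \
        else np.asarray(grid_mask, bool).ravel()
    M = mm_consumption(Pt[gm], sol._M0_site[gm], sol._PM50_site[gm])
    mro2 = float(M.mean()) * 60.0 * 1e3       # mlO2/ml/s -> ulO2/ml/min

    q_in = 0.0
    bound_in = 0.0
    disc = sol._disc
    for u in np.flatnonzero(net.role == ARTERIAL_ROOT):
        for s in disc.out_segs[disc.out_off[u]:disc.out_off[u + 1]]:
            q = abs(flow.q[s])
            q_in += q
            bound_in += q * net.H[s] * params.c0 \
                * float(hill_saturation(sol._P_up[s], params))
    rj_in = bound_in / volume * 60.0 * 1e3    # ulO2/ml/min
    if rj_in <= 0:
        raise ValueError("zero oxygen supply; OEF undefined")
    m = _mask(net, mask)
    # per-segment mean P (trapezoid over samples)
    meanP = np.empty(net.n_segments)
    for s in range(net.n_segments):
        k0, k1 = sol.point_offsets[s], sol.point_offsets[s + 1]
        w = np.ones(k1 - k0)
        w[0] = w[-1] = 0.5
        meanP[s] = (sol.P[k0:k1] * w).sum() / w.sum()
    return {
        "MRO2": mro2,
        "rJ_in": rj_in,
        "OEF": mro2 / rj_in,
        "mean_P": float((net.l[m] * meanP[m]).sum() / net.l[m].sum()),
        "mean_Pt": float(Pt[gm].mean()),
        "S_in_q": bound_in / (params.c0 * q_in * 0.45) if q_in > 0 else np.nan,
    }


def estimate_M0_zeroth_order(rBV: float = 0.008, rBF: float = 0.06,
                             c_Hb_blood: float = 14.0,
                             huefner: float = HUEFNER,
                             OEF: float = 0.32) -> float:
    """Zeroth-order estimate of the maximal consumption rate M0,
    ulO2 ml^-1 min^-1.

    With MRO2 = M0 and mean transit time MTT = rBV/rBF, the extracted
    oxygen per tissue volume is OEF * (huefner * c_Hb_blood) * rBV, so
    M0 = OEF * huefner * c_Hb_blood * rBV / MTT — the rBV factors cancel
    into the familiar M0 = OEF * CaO2 * rBF. ``c_Hb_blood`` in g/dl,
    ``rBF`` in min^-1.
    """
    if rBF <= 0:
        raise ValueError("rBF must be positive")
    ca_o2 = huefner * c_Hb_blood / 100.0       # mlO2 per ml blood
    mtt = rBV / rBF
    m0 = OEF * ca_o2 * rBV / mtt               # mlO2 ml^-1 min^-1
    return m0 * 1e3                            # -> ulO2 ml^-1 min^-1


def radial_profiles(net: VesselNetwork, center, shell_width: float,
                    r_max: float, grid=None, sample_step: float = 20.0
                    ) -> pd.DataFrame:
    """Per-shell MVD (L_D), rBV, length-weighted mean H and mean tissue
    PO2 versus distance from ``center``. Segments are clipped to shells
    by sampling their centerlines at ``sample_step`` resolution."""
    if shell_width <= 0:
        raise ValueError("shell width must be positive")
    edges = np.arange(0.0, r_max + shell_width, shell_width)
    nsh = len(edges) - 1
    length = np.zeros(nsh)
    vol_v = np.zeros(nsh)
    rbc_l = np.zeros(nsh)
    center = np.asarray(center, dtype=float)
    for s in range(net.n_segments):
        npc = max(1, int(np.ceil(net.l[s] / sample_step)))
        t = (np.arange(npc) + 0.5) / npc
        pts = net.pos[net.a[s]] * (1 - t[:, None]) + net.pos[net.b[s]] * t[:, None]
        d = np.linalg.norm(pts - center, axis=1)
        dl = net.l[s] / npc
        idx = np.floor(d / shell_width).astype(int)
        ok = idx < nsh
        np.add.at(length, idx[ok], dl)
        np.add.at(vol_v, idx[ok], dl * np.pi * net.r_tilde[s] ** 2)
        np.add.at(rbc_l, idx[ok], dl * net.H[s])
    vol_sh = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    df = pd.DataFrame({
        "r_inner": edges[:-1], "r_outer": edges[1:],
        "shell_volume": vol_sh,
        "MVD": length / vol_sh * 1e6,
        "rBV": vol_v / vol_sh * 100.0,
        "mean_H": np.where(length > 0, rbc_l / np.maximum(length, 1e-300),
                           np.nan),
    })
    if grid is not None:
        xs = grid.site_positions_1d()
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        d = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2
                    + (Z - center[2]) ** 2).ravel()
        idx = np.floor(d / shell_width).astype(int)
        pt = np.full(nsh, np.nan)
        for i in range(nsh):
            sel = idx == i
            if sel.any():
                pt[i] = grid.values.ravel()[sel].mean()
        df["mean_Pt"] = pt
    return df


def regional_hematocrit_ratio(net: VesselNetwork, center, R_tum: float,
                              baseline_H: float) -> tuple[float, float]:
    """(core ratio, rim ratio) of length-weighted mean hematocrit relative
    to the t=0 baseline: core = sphere interior more than 100 um beyond
    the invasive edge; rim = a 100 um-wide annulus straddling the edge
    (composed of 50 um shells)."""
    if baseline_H <= 0:
        raise ValueError("baseline hematocrit must be positive")
    mid = net.midpoints()
    d = np.linalg.norm(mid - np.asarray(center, float), axis=1)
    core = d < max(R_tum - 100.0, 0.0)
    rim = (d >= R_tum - 50.0) & (d < R_tum + 50.0)
    out = []
    for m in (core, rim):
        if not m.any():
            raise ValueError("empty region for hematocrit ratio")
        out.append(float((net.l[m] * net.H[m]).sum() / net.l[m].sum())
                   / baseline_H)
    return out[0], out[1]


def observable_record(net: VesselNetwork, flow: FlowState,
                      sol: OxygenSolution, params: OxygenParams, L: float,
                      region: str = "whole_domain", center=None,
                      R_tum: float = 0.0) -> dict:
    """One row of derived quantities for a converged simulation state."""
    volume = L ** 3
    mask = None
    grid_mask = None
    if region == "tumor_sphere":
        mid = net.midpoints()
        d = np.linalg.norm(mid - np.asarray(center, float), axis=1)
        mask = d <= R_tum
        volume = 4.0 / 3.0 * np.pi * R_tum ** 3
        xs = sol.tissue.site_positions_1d()
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        dg = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2
                     + (Z - center[2]) ** 2)
        grid_mask = dg <= R_tum
    rec = {"region": region}
    rec.update(vascular_densities(net, volume, mask))
    rec["c_Hb"] = tissue_hemoglobin(net, volume, mask)
    rec["Y"] = tissue_blood_oxygen_saturation(net, sol, mask)
    rec["S_mean_lw"] = length_weighted_saturation(net, sol, mask)
    rec["c_HbO"] = rec["c_Hb"] * rec["Y"]
    rec.update(perfusion(net, flow, L ** 3))
    rec.update(oxygen_metabolics(net, flow, sol, params, L ** 3,
                                 mask, grid_mask))
    return rec
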