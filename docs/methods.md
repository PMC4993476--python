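# Methods

`tumoroxy` simulates the vascular origin of optical-mammography
observables: it grows synthetic arterio-venous networks for normal breast
tissue, remodels them under an expanding tumor spheroid, solves network
hemodynamics with hematocrit phase separation, and couples intravascular
oxygen transport to tissue diffusion and consumption. This note records
the model equations as implemented, the parameter conventions, the
numerical choices, and the limits of what the synthetic setting can show.

## Initial vascular networks

Arterial and venous trees interdigitate on a face-centered-cubic (FCC)
lattice with nearest-neighbour bond length `h_gen = 130 um` over a cubic
domain `(0, L)^3`. Root nodes sit on boundary lattice sites in one of nine
configurations (`RC1`–`RC9`): whole-face alternating checkerboards on
one/two/four faces (RC1–RC3), isolated roots at 33%/66% of face diagonals
(RC4–RC6), pre-laid parent vessels penetrating 60% of the box along x with
every parent site a growth root (RC7/RC8; one arterial + one venous parent
for RC7, two of each for RC8 — the multiplicity is our reading), and
Bernoulli(p_root)-occupied boundary sites with p_root ~ U(0,1) redrawn
until both types occur (RC9).

Growth adds structural elements at randomly selected terminal branches —
a linear element (one bond) or a tripod (a new site with three incident
bonds), chosen with weight `p_tripod = 0.5` — until no element fits
without overlap (site-disjoint trees; bond reuse impossible by
construction). Nearby open ends of opposite type are then joined by
capillaries (`r = 2.5 um`): first within one lattice bond, then, for ends
still unmatched, across the second FCC shell (`sqrt(2) h_gen` chords,
which pass through no lattice site); each open end hosts at most two
capillaries. Terminal arterial/venous segments get radii 2.5/3.8 um and
parents follow Murray's law `r_c^3 = r_a^3 + r_b^3` leaf-to-root.

A shear-guided refinement loop then alternates: solve network flow at
uniform hematocrit, remove terminal segments with probability decreasing
in local wall shear stress and extend them with probability increasing in
it (logistic centred on the median terminal shear, scale 20% of it — the
self-scaling avoids an absolute shear calibration), regrow freed space to
jamming, and reconnect capillaries. It stops when the capillary count
plateaus (within 2% over 5 sweeps, capped at 20 sweeps). Finally,
terminal chains whose open end found no capillary partner are eroded, so
every terminal branch ends in a capillary or a root; without this closure
step unperfused dead-end chains (zero flow, tissue-equilibrated oxygen)
would contaminate every blood-borne observable.

With these rules the t=0 line density at `h_gen = 130 um` comes out near
`L_D ~ 100–103 mm^-2`. A hard geometric ceiling applies: an FCC lattice at
130 um bond length holds ~`1.41/h_gen^3` sites, so fully jammed trees
contribute ~87 mm^-2 and capillaries the remainder; reported literature
values slightly above this ceiling would require a denser bond set than
nearest-neighbour FCC while keeping 130 um segments, a combination the
lattice does not admit.

## Tumor growth and remodeling

A spherical tumor of radius `R_tum(t) = 250 um + (2 um/h) t` expands from
the domain center to `t_end = 600 h` (diameter ~2.9 mm). Before
remodeling, segments are resampled into ~`fine_h` pieces (10 um by
default) so the processes act at capillary scale. Each `dt = 1 h` step
applies, in order: sprout initiation, sprout migration, circumferential
growth, wall degradation, collapse/regression, then a hemodynamics
update; afterwards `t` and `R_tum` advance.

- **Sprouting**: every vessel node of degree <= 2 lying in the shell
  `R_tum < |x| < R_tum + R_g` (`R_g = 200 um`) and at network path
  distance >= `d_br_min = 80 um` from any branch point spawns, with
  probability `dt/t_sprout` (`t_sprout = 2 h`), a sprout segment
  (`r = 2.6 um`, age tau = 1) along a uniformly chosen free lattice
  direction. Eligibility is evaluated once per step (truncated
  multi-source Dijkstra from branch points).
- **Migration**: each sprout tip extends one bond with probability
  `dt/t_sprout`, avoiding immediate backtracking; a tip landing on an
  existing vessel connects unless that would create a degree-4 junction.
  tau increments globally each step; sprouts never circulated by
  `t_migr = 50 h` are removed. Sprouts that carry flow after the
  hemodynamics update become normal vessels.
- **Circumferential growth**: segments resident inside the sphere for at
  least `t_switch = 12 h` dilate as `dr/dt = ln2 * r / t_prol`
  (`t_prol = 144 h`; the wall endothelial-cell count, proportional to r,
  doubles every proliferation time), capped at `r_max` (10 um; 14 um in
  the compression scenario).
- **Wall degradation**: tumor segments lose stability at
  `dw = 0.05 um/h` until `w = 0`. The initial stability is tied to a
  healthy wall thickness, `w0(r) = min(r/2, 10 um)`; only the decay rate
  and the `w = 0` gate matter for the dynamics.
- **Collapse/regression**: segments with `w = 0` and wall shear stress
  below `f_coll = 0.25 Pa` are removed (probability `p_coll = 1`).
  Emerging dead ends are pruned back to perfused junctions (roots and
  live sprout tips exempt), and components unreachable from any root —
  including looped islands that leaf-stripping cannot reach — regress
  entirely.

During remodeling the hematocrit fixed point is solved to a relaxed
tolerance (1e-3, at most 10 alternations, warm-started from the previous
step) since the network changes again immediately; the final state gets
the strict solve before any oxygen computation.

**Compression (CMPR)**: all radii entering flow and oxygen computations
are replaced by `r_tilde = psi(|x|) r` with `psi = xi_cpr` deeper than
`w_cpr = 200 um` inside the boundary, 1 outside it, and linear across the
`2 w_cpr` transition; `xi_cpr ~ U(0.5, 1)` once per simulation, and the
profile follows `R_tum(t)` continuously during growth.

**METAB**: tumor networks identical to BASE, but the tumor maximal
consumption rate is drawn per simulation from a natural-log lognormal
with median 0.0149 ml O2/ml/min (equal to BASE) and sigma = 0.3 (STD
~32% of the median).

## Hemodynamics

Poiseuille flow `q = pi r^4 dp / (8 eta l)` on the graph, mass
conservation at interior nodes, Dirichlet pressures at roots. The
apparent viscosity is `eta_plasma * eta_rel(d, H)` with the in-vivo
parameterisation of the Fahraeus–Lindqvist effect (endothelial surface
layer included; the plasma limit is therefore `(d/(d-1.1))^2`, not 1);
the in-vitro law is selectable. RBC partitioning at arterial bifurcations
follows the empirical logit law (1990 parameter set by default, the
in-vivo 2005 set selectable), with exact RBC-flux conservation up to a
physical cap `H <= 0.99`. Hematocrit propagates downstream in topological
order of the flow-directed graph; flow-directed cycles fall back to
iterative relaxation; root nodes are boundary nodes whose outflows
restart at the inlet hematocrit 0.45. Pressures and hematocrit alternate
(under-relaxation 0.5) until the per-segment change falls below 1e-4 with
stable flow directions. Segments whose flow is below 1e-9 of the peak are
treated as unperfused — their direction is numerical noise.

The linear systems are solved with a sparse direct factorization
(SuperLU); the tissue diffusion systems below use Jacobi-preconditioned
conjugate gradients. At desk scale (<= ~1e5 unknowns) both are far from
their limits.

**Root pressure curve.** The radius-dependent root pressures are monotone
saturating exponentials: arterial
`p(r) = p_cap + (p_art - p_cap)(1 - e^{-r/r_s})` and the mirrored venous
curve. The amplitudes are not directly measured; they are calibrated
(`scripts/calibrate_bc.py`) so the t=0 ensemble reproduces the normal
breast perfusion `rBF ~ 0.053 ml g^-1 min^-1`. Defaults: `p_cap = 23`,
`p_art = 85`, `p_ven = 10 mmHg`, `r_s = 10 um`.

## Oxygen transport

Hemoglobin binding follows the Hill curve `S(P) = P^n/(P^n + P_S50^n)`
(`n = 2.7`, `P_S50 = 27 mmHg`); blood oxygen content is
`c = alpha_p P + H c0 S(P)` (`c0 = 0.5 mlO2/ml`). Along each perfused
segment,

    dP/dx = - 2 pi r gamma (P - P_t) / ( q [H c0 S'(P) + alpha_p] ),

with the transvascular mass-transfer coefficient
`gamma(r) = Nu(r) D_p alpha_p / (2r)`, `Nu(r) = 4.7 (1 - e^{-r/8um})`
(the saturation dependence of Nu is dropped, as appropriate near S ~ 0.9).
Arterial inlets carry `P(r) = min(55 + 1*r, 100) mmHg`. At junctions the
inflowing RBCs assume a common equilibrium PO2 found by bisection (1e-8)
on the oxygen mass balance; root nodes are boundary nodes (their outflows
restart on the inlet curve — mass leaves/enters the domain there).

Tissue PO2 obeys `alpha_t D_t lap(P_t) - M(P_t) + Q = 0` with Neumann
boundaries, Michaelis–Menten consumption `M(P) = M0 P/(P + P_M50)`
(normal: `M0 = 3.7 ulO2/ml/min`, `P_M50 = 4 mmHg`; tumor: 4x / 0.5x), and
the vessels as line sources of strength `2 pi r gamma (P - P_t)`.
Discretization: trilinear (P1) elements on a cubic grid (`h = 40 um`),
which with trapezoidal quadrature reduces to the 7-point stencil plus
per-site exchange terms; consumption is linearized about the previous
iterate; the vessel–tissue coupling matrix is diagonalized by sampling
`P_t` at the host site (the full 27-point coupling is available and
changes the means negligibly). Integration points are spaced ~`h_v = 4 um`
(`ceil(l/h_v)+1` per segment, endpoints half-weighted).

The axial ODE uses implicit Euler; each scalar step is solved by
safeguarded Newton with a bisection bracket `[min(P_k, P_t), max]` to
1e-9 mmHg. Where a single step would change P by more than 0.5 mmHg
(slowly perfused segments equilibrate within one spatial step) the step
is subdivided internally, and the quadrature receives the interval-mean
PO2 — this keeps the recorded transvascular source consistent with the
blood-side content change, closing the global oxygen balance to well
under 2% rather than tens of percent. Zero-flow segments take the local
tissue PO2 (no axial transport, zero net exchange at the current
iterate).

Network sweeps (topological order; cycles broken at the remaining nodes
in descending-pressure order and relaxed across outer iterations) and
tissue solves alternate from the initial guess `P_t = P_root,max/2` until
both fields change by less than `eps = 0.1 mmHg` in max-norm (cap 2000).
Small perfused boxes converge in ~30–80 iterations.

## Observables

Reported per region (whole domain, the t=0 network as "normal", or the
tumor sphere; a segment belongs to a region if its midpoint does):
line density `L_D` (mm^-2), `rBV` (%), surface density `S_D`,
length-weighted mean radius; `c_Hb = MCHC * rRBCV` in umol/l (MCHC =
0.34 g/ml, hemoglobin tetramer molar mass 64.5 kg/mol);
`Y = c_HbO/c_Hb` (RBC-volume-weighted mean segment saturation) and the
length-weighted `<S>`; perfusion `rBF` from root influx (tissue density
1 g/ml) and sphere-surface influx variants with the scaled quantity
`rBF_scaled = rBF_norm * rBF_tum/rBF_sph,norm`; `MRO2` as the volume mean
of `M(P_t)`; `rJ_in = c0 <H S_in>_q * rBF` from the arterial roots; and
`OEF = MRO2/rJ_in`. The zeroth-order consumption estimate
`M0 = OEF * (Hufner * c_Hb,blood) * rBF` reproduces 3.7 ulO2/ml/min from
the reference inputs (the MTT form `MRO2*MTT = eps_Hb c_Hb,blood rBV OEF`
needs the rBV factor on the right for dimensional consistency). Radial
profiles use concentric shells (100 um default) with segments clipped by
centerline sampling; regional hematocrit ratios compare the
length-weighted mean H of the core (>100 um inside the edge) and a
100-um annulus straddling the edge against the t=0 baseline.

## Desk-scale profiles and what the tests show

The published study conditions are an 8 mm box, 9 x 10 networks and
600 h of growth — CPU-days of work. The package defaults keep all
physical parameters at the study values and reduce only problem sizes:
test networks use L ~ 1.6–3 mm (with L chosen near a multiple of both the
lattice period 91.9 um and the grid constant 40 um to limit boundary
margins), reduced ensembles of 2–3 geometries, remodeling lattices of
65 um, and growth to 150–300 h. At these sizes perfusion, Y, OEF, MRO2,
mean intravascular and tissue PO2, and the tumor direction-of-effect
signatures (core hematocrit enrichment above baseline with rim depletion,
tumor c_Hb and rBV above host, core less vascularized than rim) are
reproduced within the published ensemble spreads. c_Hb and rBV are
systematically depressed at desk scale: Murray trunk calibres are
truncated with the box (the radius of a feeding vessel grows with the
number of downstream terminals), so the RBC volume fraction rises with L;
`scripts/finite_size_check.py` runs the long single-network check at
L ~ 4.6 mm where c_Hb reaches the published normal-tissue range. Absolute
tumor-state means at 600 h / 8 mm are not asserted at desk scale.

The generator emulates topology, calibre structure and perfusion of real
microvasculature but not anatomical tortuosity, pulsatility, vessel
compliance, lymphatics, or patient geometry; passing tests therefore
validate the transport and remodeling machinery on lattice-grown
networks, not clinical prediction.

## Known limitations

- The t=0 line density saturates ~7–8% below the literature target (the
  FCC ceiling above); all density-derived quantities inherit part of
  this deficit at t=0.
- Flow-directed cycles in remodeled tumor networks are handled by
  relaxation rather than exactly; their hematocrit can oscillate at the
  1e-3 level, which is why the in-loop solver tolerance is relaxed.
- The rim hematocrit depletion deepens with tumor age; at 150 h desk
  scale it sits near 0.8 of baseline versus ~0.66 for full-scale 600 h
  tumors.
- Sprout geometry is step-wise on lattice directions with node snapping,
  not a strict shared-lattice occupancy model.
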