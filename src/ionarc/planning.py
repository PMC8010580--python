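"""Spot placement, dose-influence computation and spot-weight optimization.

Plans cover the target in beam's-eye view per angle with a rectangular spot
raster at the ion's clinical lateral spacing. Arc (SHArc) plans use the full
360 deg rotation in 2 deg steps with a single beam energy whose R80 reaches
the isocenter; static 1F/2F/3F plans use range-stacked energy layers whose
R80 ladder spans the target depth extent (SOBP-like coverage).

Desk-scale representation: spots sharing (angle, energy, lateral offset u)
form one column along the target height (v = z) with a common weight, and the
dose is computed on the central axial slab of the phantom. The per-voxel
influence stores total physical dose, dose x LET_D and dose x alpha_mMKM per
unit spot weight; inside the target it additionally keeps the per-component
(dose, alpha, RQE) decomposition needed for hypoxic effective dose.

The RBE-weighted-dose objective (quadratic penalties on target coverage,
shell fall-off, normal tissue and OAR) is nonconvex; it is solved by
projected-gradient descent with the voxel RBE factors re-linearized in outer
iterations, accepting only objective-decreasing steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.ndimage import distance_transform_edt, uniform_filter1d

from ionarc.beam import BeamLibrary, BeamModelOptions, DepthProfileTable, energy_for_r80
from ionarc.ions import IonSpecies
from ionarc.mkm import MKMParams, PhotonLQParams, effective_dose_from_lq, z1d_star
from ionarc.scenario import PHANTOM_RADIUS, Scenario, beam_unit_vectors

TECHNIQUES = ("sharc", "1f", "2f", "3f", "sharc_subarc")
_STATIC_ANGLES = {"1f": (90.0,), "2f": (0.0, 180.0), "3f": (0.0, 90.0, 180.0)}


@dataclass(frozen=True)
class Spot:
    gantry_angle: float
    u: float
    v: float
    energy: float
    weight: float = 0.0


@dataclass(frozen=True)
class ObjectiveWeights:
    """Relative penalty multipliers of the plan objective."""

    target_under: float = 2.0
    target_over: float = 1.0
    shell: float = 0.3
    normal: float = 0.03
    oar: float = 30.0


@dataclass(frozen=True)
class PlanConfig:
    ion: IonSpecies
    technique: str = "sharc"
    prescription: float = 3.0       # GyRBE per fraction
    upper_frac: float = 1.06
    lower_frac: float = 0.97
    falloff_low: float = 0.25       # GyRBE allowed 5 mm outside the target
    falloff_dist: float = 5.0       # mm
    normal_max: float = 0.35        # GyRBE soft cap beyond the fall-off shell
    oar_max: float = 0.5            # GyRBE clinical cap (case B)
    oar_objective_margin: float = 0.9   # optimize against margin x cap
    arc_step_deg: float = 2.0
    subarc_width_deg: float = 14.0
    subarc_range_shifts: tuple = (-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0)
    static_layer_step: float = 3.0  # mm between static-field R80 layers
    spot_spacing: float | None = None
    slab_thickness: float = 20.0    # mm, evaluated axial slab
    lateral_cutoff_sigma: float = 3.2
    sparsity_cutoff: float = 1e-6   # drop influence entries below this x spot max
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    n_outer: int = 3
    n_inner: int = 120
    physical_dose_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")

    @property
    def spacing(self) -> float:
        return self.spot_spacing or self.ion.default_spot_spacing

    @property
    def d_lower(self) -> float:
        return self.lower_frac * self.prescription

    @property
    def d_upper(self) -> float:
        return self.upper_frac * self.prescription


@dataclass
class SpotSet:
    """Spot columns: one weight per (angle, energy, u); v spans the target height."""

    ion: IonSpecies
    angles: np.ndarray     # (n_groups,)
    energies: np.ndarray   # (n_groups,)
    us: np.ndarray         # (n_groups,)
    v_positions: np.ndarray
    weights: np.ndarray | None = None

    @property
    def n_groups(self) -> int:
        return self.angles.size

    @property
    def n_v(self) -> int:
        return self.v_positions.size

    def spots(self) -> list:
        """Expand to individual :class:`Spot` records."""
        w = self.weights if self.weights is not None else np.zeros(self.n_groups)
        return [
            Spot(float(a), float(u), float(v), float(e), float(wi))
            for a, u, e, wi in zip(self.angles, self.us, self.energies, w)
            for v in self.v_positions
        ]


def _raster(half_extent: float, spacing: float) -> np.ndarray:
    """Symmetric raster covering [-half_extent, half_extent]."""
    k = int(np.floor(half_extent / spacing))
    return spacing * np.arange(-k, k + 1, dtype=float)


def select_energies(config: PlanConfig, target_radius: float = 30.0,
                    beam_options: BeamModelOptions | None = None) -> dict:
    """Per-angle beam energies (MeV/u) of the plan technique.

    SHArc uses one energy with R80 at the isocenter depth (100 mm); static
    fields a range ladder spanning [100 - r_t, 100 + r_t]; the sub-arc
    variant 7 energies with R80 at 100 +/- {0,2,4,6} mm cycled over 14 deg
    sub-arcs.
    """
    iso_depth = PHANTOM_RADIUS
    if config.technique == "sharc":
        e = energy_for_r80(config.ion, iso_depth, beam_options)
        angles = np.arange(0.0, 360.0, config.arc_step_deg)
        return {float(a): (e,) for a in angles}
    if config.technique == "sharc_subarc":
        energies = tuple(
            energy_for_r80(config.ion, iso_depth + s, beam_options)
            for s in config.subarc_range_shifts
        )
        angles = np.arange(0.0, 360.0, config.arc_step_deg)
        n_e = len(energies)
        return {
            float(a): (energies[int(a // config.subarc_width_deg) % n_e],)
            for a in angles
        }
    # static fields: identical SOBP-like ladder per field
    r80s = np.arange(iso_depth - target_radius, iso_depth + target_radius + 1e-9,
                     config.static_layer_step)
    ladder = tuple(energy_for_r80(config.ion, float(r), beam_options) for r in r80s)
    return {float(a): ladder for a in _STATIC_ANGLES[config.technique]}


def place_spots(scenario: Scenario, config: PlanConfig,
                beam_options: BeamModelOptions | None = None) -> SpotSet:
    """Lay out spot columns covering the target BEV plus one spacing margin."""
    from ionarc.scenario import TARGET_HEIGHT, TARGET_RADIUS

    sp = config.spacing
    half_u = TARGET_RADIUS + sp
    half_v = TARGET_HEIGHT / 2 + sp
    us = _raster(half_u, sp)
    vs = _raster(half_v, sp)
    if us.size == 0 or vs.size == 0:
        raise ValueError("empty beam's-eye-view projection")

    per_angle = select_energies(config, TARGET_RADIUS, beam_options)
    angles, energies, u_all = [], [], []
    for a in sorted(per_angle):
        for e in per_angle[a]:
            angles.extend([a] * us.size)
            energies.extend([e] * us.size)
            u_all.extend(us.tolist())
    return SpotSet(
        ion=config.ion,
        angles=np.asarray(angles),
        energies=np.asarray(energies),
        us=np.asarray(u_all),
        v_positions=vs,
    )


@dataclass
class DoseInfluence:
    """Sparse per-voxel influence of every spot column (per unit spot weight)."""

    A: sparse.csr_matrix          # physical dose, Gy per particle
    A_let: sparse.csr_matrix      # dose x LET_D, Gy keV/um
    A_alpha: sparse.csr_matrix    # dose x alpha_mMKM, Gy/Gy
    voxel_coords: np.ndarray      # (N, 3) voxel indices in the scenario grid
    slab_rows: np.ndarray         # flat scenario indices of the N rows
    spotset: SpotSet
    photon: PhotonLQParams
    # target-restricted per-component decomposition (COO over target rows)
    t_row: np.ndarray = None      # indices into 0..N-1
    t_col: np.ndarray = None      # group indices
    t_dose: np.ndarray = None
    t_dose_alpha: np.ndarray = None
    t_rqe: np.ndarray = None

    _AT: sparse.csr_matrix = None

    @property
    def n_voxels(self) -> int:
        return self.A.shape[0]

    @property
    def AT(self) -> sparse.csr_matrix:
        """Cached CSR transpose of A for fast gradient products."""
        if self._AT is None:
            self._AT = self.A.T.tocsr()
        return self._AT

    def release(self) -> None:
        """Drop the sparse matrices and component arrays to free memory.

        Keeps the light bookkeeping (voxel coordinates, spot set) so already-
        computed evaluations remain usable; further dose computations with
        this influence are not.
        """
        self.A = self.A_let = self.A_alpha = self._AT = None
        self.t_row = self.t_col = None
        self.t_dose = self.t_dose_alpha = self.t_rqe = None

    def mask_rows(self, mask3d: np.ndarray) -> np.ndarray:
        """Restrict a scenario-grid boolean mask to the influence rows."""
        return mask3d.ravel()[self.slab_rows]


def _table_arrays(table: DepthProfileTable, voxel_size: float,
                  photon: PhotonLQParams, mkm: MKMParams) -> dict:
    """Voxel-averaged depth arrays of a table, with mMKM biology attached."""
    key = (round(voxel_size, 6), photon, mkm)
    cache = getattr(table, "_voxel_cache", None)
    if cache is None:
        cache = table._voxel_cache = {}
    if key in cache:
        return cache[key]

    dz = table.depth[1] - table.depth[0]
    size = max(int(round(voxel_size / dz)), 1)
    box = lambda a: uniform_filter1d(a, size, mode="nearest")

    dose = box(table.dose_per_primary)
    dose_let = box(sum(c.dose * c.track_let for c in table.components))
    comp = []
    dose_alpha = np.zeros_like(dose)
    for c in table.components:
        alpha_c = photon.alpha_x + photon.beta_x * z1d_star(c.species_label, c.energy,
                                                           mkm, photon)
        d_c = box(c.dose)
        da_c = box(c.dose * alpha_c)
        dose_alpha += da_c
        comp.append({"dose": d_c, "dose_alpha": da_c, "rqe": c.rqe})
    out = {
        "depth": table.depth,
        "dose": dose,
        "dose_let": dose_let,
        "dose_alpha": dose_alpha,
        "sigma": table.lateral_sigma,
        "components": comp,
    }
    cache[key] = out
    return out


def compute_influence(scenario: Scenario, spotset: SpotSet, library: BeamLibrary,
                      config: PlanConfig,
                      photon: PhotonLQParams = PhotonLQParams(),
                      mkm: MKMParams = MKMParams()) -> DoseInfluence:
    """Pencil-beam superposition of every spot column onto the central slab."""
    h = scenario.voxel_size
    x, y, z = scenario.axes()
    nz_half = max(int(round(config.slab_thickness / 2.0 / h)), 1)
    iz0 = scenario.shape[2] // 2 - nz_half
    iz1 = scenario.shape[2] // 2 + nz_half
    slab3d = np.zeros(scenario.shape, dtype=bool)
    slab3d[:, :, iz0:iz1] = True
    slab3d &= scenario.phantom
    coords = np.argwhere(slab3d)
    slab_rows = np.ravel_multi_index(coords.T, scenario.shape)
    px, py, pz = x[coords[:, 0]], y[coords[:, 1]], z[coords[:, 2]]
    n_vox = coords.shape[0]
    target_rows = scenario.target.ravel()[slab_rows]

    tabs = {}
    for e in np.unique(spotset.energies):
        tab = library.get(spotset.ion, float(e))
        tabs[float(e)] = (tab, _table_arrays(tab, h, photon, mkm))

    rows, cols, v_dose, v_let, v_alpha = [], [], [], [], []
    t_row, t_col, t_dose, t_da, t_rqe = [], [], [], [], []

    group_ids = np.arange(spotset.n_groups)
    vs = spotset.v_positions
    for angle in np.unique(spotset.angles):
        d_vec, u_lat = beam_unit_vectors(angle)
        s_d = px * d_vec[0] + py * d_vec[1]
        l1 = px * u_lat[0] + py * u_lat[1]
        depth = s_d + np.sqrt(np.maximum(PHANTOM_RADIUS**2 - l1**2, 0.0))
        sel_a = spotset.angles == angle
        for e in np.unique(spotset.energies[sel_a]):
            tab, arrs = tabs[float(e)]
            zt = arrs["depth"]
            dd = np.interp(depth, zt, arrs["dose"], right=0.0)
            dlet = np.interp(depth, zt, arrs["dose_let"], right=0.0)
            dalpha = np.interp(depth, zt, arrs["dose_alpha"], right=0.0)
            sig = np.interp(depth, zt, arrs["sigma"])
            norm = 1.0 / (np.sqrt(2.0 * np.pi) * sig)
            s_v = np.zeros(n_vox)
            for vk in vs:
                s_v += np.exp(-0.5 * ((pz - vk) / sig) ** 2)
            s_v *= norm
            gsel = np.nonzero(sel_a & (spotset.energies == e))[0]
            for gid in gsel:
                lat = l1 - spotset.us[gid]
                keep = np.abs(lat) < config.lateral_cutoff_sigma * sig
                if not keep.any():
                    continue
                g = np.exp(-0.5 * (lat[keep] / sig[keep]) ** 2) * norm[keep]
                dose = dd[keep] * g * s_v[keep]
                cut = config.sparsity_cutoff * dose.max()
                fine = dose > cut
                if not fine.any():
                    continue
                idx = np.nonzero(keep)[0][fine]
                gk = g[fine] * s_v[keep][fine]
                rows.append(idx)
                cols.append(np.full(idx.size, gid, dtype=np.int32))
                v_dose.append((dd[idx] * gk).astype(np.float32))
                v_let.append((dlet[idx] * gk).astype(np.float32))
                v_alpha.append((dalpha[idx] * gk).astype(np.float32))
                # per-component decomposition inside the target
                tt = target_rows[idx]
                if tt.any():
                    ti = idx[tt]
                    tg = gk[tt]
                    dpt = depth[ti]
                    for cinfo in arrs["components"]:
                        dc = np.interp(dpt, zt, cinfo["dose"], right=0.0) * tg
                        nz = dc > 0
                        if not nz.any():
                            continue
                        t_row.append(ti[nz])
                        t_col.append(np.full(nz.sum(), gid, dtype=np.int32))
                        t_dose.append(dc[nz].astype(np.float32))
                        t_da.append((np.interp(dpt, zt, cinfo["dose_alpha"], right=0.0)[nz]
                                     * tg[nz]).astype(np.float32))
                        t_rqe.append(np.interp(dpt, zt, cinfo["rqe"])[nz].astype(np.float32))

    if not rows:
        raise RuntimeError("no influence entries: spots miss the phantom slab")
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    shape = (n_vox, spotset.n_groups)
    # build one CSR then share its index structure across the three matrices
    order = np.lexsort((c, r))
    r, c = r[order], c[order]
    A = sparse.csr_matrix(
        (np.concatenate(v_dose)[order], (r, c)), shape=shape, dtype=np.float32)
    A.sum_duplicates()

    def _like(vals):
        m = sparse.csr_matrix((np.concatenate(vals)[order], (r, c)),
                              shape=shape, dtype=np.float32)
        m.sum_duplicates()
        return sparse.csr_matrix((m.data, A.indices, A.indptr), shape=shape)

    infl = DoseInfluence(
        A=A,
        A_let=_like(v_let),
        A_alpha=_like(v_alpha),
        voxel_coords=coords,
        slab_rows=slab_rows,
        spotset=spotset,
        photon=photon,
        t_row=np.concatenate(t_row) if t_row else np.empty(0, dtype=np.int64),
        t_col=np.concatenate(t_col) if t_col else np.empty(0, dtype=np.int32),
        t_dose=np.concatenate(t_dose) if t_dose else np.empty(0, dtype=np.float32),
        t_dose_alpha=np.concatenate(t_da) if t_da else np.empty(0, dtype=np.float32),
        t_rqe=np.concatenate(t_rqe) if t_rqe else np.empty(0, dtype=np.float32),
    )
    return infl


@dataclass
class Plan:
    spotset: SpotSet
    config: PlanConfig
    objective_history: list
    converged: bool
    pruned: bool = False
    n_pruned: int = 0

    @property
    def weights(self) -> np.ndarray:
        return self.spotset.weights


class _Objective:
    """Quadratic-penalty objective on re-linearized effective dose."""

    def __init__(self, influence: DoseInfluence, scenario: Scenario,
                 config: PlanConfig):
        self.cfg = config
        self.infl = influence
        self.photon = influence.photon
        self.target = influence.mask_rows(scenario.target)
        oar3d = scenario.oar if scenario.oar is not None else np.zeros(scenario.shape, bool)
        self.oar = influence.mask_rows(oar3d)

        # distance-graded fall-off shell and normal-tissue cap
        sub = np.zeros(scenario.shape, dtype=bool)
        sub.ravel()[influence.slab_rows] = True
        dist3d = distance_transform_edt(~scenario.target, sampling=scenario.voxel_size)
        dist = dist3d.ravel()[influence.slab_rows]
        self.shell = (~self.target) & (~self.oar) & (dist <= config.falloff_dist)
        self.normal = (~self.target) & (~self.oar) & (~self.shell)
        ramp = config.prescription - (config.prescription - config.falloff_low) \
            * dist / config.falloff_dist
        self.limit = np.where(self.shell, ramp, np.inf)
        self.limit[self.normal] = config.normal_max
        # a quadratic penalty only approaches its cap from above: plan against
        # a small margin so the delivered maximum respects the clinical cap
        self.limit[self.oar] = config.oar_objective_margin * config.oar_max
        w = config.weights
        self.w_vox = np.zeros(influence.n_voxels)
        self.w_vox[self.shell] = w.shell / max(self.shell.sum(), 1)
        self.w_vox[self.normal] = w.normal / max(self.normal.sum(), 1)
        self.w_vox[self.oar] = w.oar / max(self.oar.sum(), 1)
        self.w_t = 1.0 / max(self.target.sum(), 1)

    def rbe_factor(self, w: np.ndarray) -> np.ndarray:
        """Per-voxel ratio r = D_RBE/D at the current weights (frozen alpha_bar)."""
        if self.cfg.physical_dose_mode:
            return np.ones(self.infl.n_voxels)
        d = self.infl.A @ w
        da = self.infl.A_alpha @ w
        ax = self.photon.alpha_x
        alpha_bar = np.where(d > 0, da / np.maximum(d, 1e-30), ax)
        d_rbe = effective_dose_from_lq(alpha_bar, self.photon.beta_x, d, self.photon)
        r = np.where(d > 0, d_rbe / np.maximum(d, 1e-30), alpha_bar / ax)
        return r

    def value_grad_dr(self, dr: np.ndarray):
        cfg, w = self.cfg, self.cfg.weights
        f = 0.0
        g = np.zeros_like(dr)
        t = self.target
        under = np.maximum(cfg.d_lower - dr[t], 0.0)
        over = np.maximum(dr[t] - cfg.d_upper, 0.0)
        f += self.w_t * (w.target_under * under**2 + w.target_over * over**2).sum()
        g[t] = self.w_t * 2.0 * (w.target_over * over - w.target_under * under)
        rest = ~t
        excess = np.maximum(dr[rest] - self.limit[rest], 0.0)
        f += (self.w_vox[rest] * excess**2).sum()
        g[rest] = self.w_vox[rest] * 2.0 * excess
        return f, g

    def value(self, dr: np.ndarray) -> float:
        return self.value_grad_dr(dr)[0]


def _projected_gradient(obj: _Objective, r: np.ndarray, w: np.ndarray,
                        lb: np.ndarray, ub: np.ndarray, n_iter: int,
                        history: list) -> np.ndarray:
    A, AT = obj.infl.A, obj.infl.AT
    r32 = r.astype(np.float32)
    proj = lambda v: np.clip(v, lb, ub)
    w = proj(w)
    dr = r * (A @ w.astype(np.float32))
    f, _ = obj.value_grad_dr(dr)
    history.append(f)
    t = None
    for _ in range(n_iter):
        _, g_dr = obj.value_grad_dr(dr)
        grad = (AT @ (r32 * g_dr.astype(np.float32))).astype(np.float64)
        if t is None:
            gnorm = float(np.linalg.norm(grad))
            t = (0.1 * max(float(np.linalg.norm(w)), 1.0) / gnorm) if gnorm > 0 else 1.0
        accepted = False
        for _ in range(25):
            w_new = proj(w - t * grad)
            if not np.any(w_new != w):
                break
            dr_new = r * (A @ w_new.astype(np.float32))
            f_new = obj.value(dr_new)
            if f_new < f:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        w, dr, f = w_new, dr_new, f_new
        history.append(f)
        t *= 1.4
    return w


def optimize_weights(influence: DoseInfluence, scenario: Scenario,
                     config: PlanConfig, w0: np.ndarray | None = None,
                     lb: np.ndarray | None = None,
                     ub: np.ndarray | None = None) -> Plan:
    """Optimize nonnegative spot weights against the plan objectives.

    Projected gradient on the quadratic-penalty objective, with the voxel
    RBE factors re-linearized ``n_outer`` times; the objective is
    non-increasing over accepted steps within each linearization.
    """
    n = influence.spotset.n_groups
    if n == 0:
        raise ValueError("no spots to optimize")
    obj = _Objective(influence, scenario, config)
    lb = np.zeros(n) if lb is None else lb
    ub = np.full(n, np.inf) if ub is None else ub
    w = np.clip(np.ones(n) if w0 is None else w0.copy(), lb, ub)

    history: list = []
    for outer in range(config.n_outer):
        r = obj.rbe_factor(w)
        if outer == 0 and w0 is None:
            d_t = (r * (influence.A @ w))[obj.target]
            mean = float(d_t.mean()) if d_t.size else 0.0
            if mean > 0:
                w *= config.prescription / mean
                r = obj.rbe_factor(w)
        phase: list = []
        w = _projected_gradient(obj, r, w, lb, ub, config.n_inner, phase)
        history.append(phase)

    converged = len(history[-1]) > 1 and (
        abs(history[-1][-1] - history[-1][-2]) <= 1e-6 * max(history[-1][0], 1e-30)
        or len(history[-1]) < config.n_inner + 1
    )
    ss = replace_weights(influence.spotset, w)
    return Plan(spotset=ss, config=config, objective_history=history,
                converged=converged)


def replace_weights(spotset: SpotSet, w: np.ndarray) -> SpotSet:
    return SpotSet(ion=spotset.ion, angles=spotset.angles, energies=spotset.energies,
                   us=spotset.us, v_positions=spotset.v_positions, weights=w)


def prune_spots(plan: Plan, influence: DoseInfluence, scenario: Scenario) -> Plan:
    """Remove sub-threshold spots and re-optimize the survivors.

    Surviving spot weights are kept at or above the ion's minimum fluence per
    spot by the re-optimization bounds; if every spot falls below threshold
    the plan is rejected.
    """
    cfg = plan.config
    thr = cfg.ion.min_fluence_threshold
    w = plan.weights.copy()
    if not (w >= thr).any():
        raise ValueError("all spots below the minimum fluence threshold")
    if (w[w > 0] >= thr).all():
        return replace(plan, pruned=True, n_pruned=0)
    # staged spot-number minimization: tighten the fluence floor in rounds so
    # the surviving spots can absorb the removed fluence gradually
    replan = plan
    removed = np.zeros_like(w, dtype=bool)
    for level in (0.3, 0.6, 1.0):
        floor = level * thr
        removed |= w < floor
        if removed.all():
            raise ValueError("all spots below the minimum fluence threshold")
        lb = np.where(removed, 0.0, floor)
        ub = np.where(removed, 0.0, np.inf)
        w[removed] = 0.0
        replan = optimize_weights(influence, scenario, cfg, w0=w, lb=lb, ub=ub)
        w = replan.weights.copy()
    return replace(replan, pruned=True, n_pruned=int(removed.sum()))


def plan_subarc(scenario: Scenario, config: PlanConfig, library: BeamLibrary,
                photon: PhotonLQParams = PhotonLQParams(),
                mkm: MKMParams = MKMParams()):
    """Convenience wrapper: sub-arc energy-modulated SHArc plan end to end."""
    if config.technique != "sharc_subarc":
        raise ValueError("plan_subarc requires technique='sharc_subarc'")
    return run_plan(scenario, config, library, photon, mkm)


def run_plan(scenario: Scenario, config: PlanConfig, library: BeamLibrary,
             photon: PhotonLQParams = PhotonLQParams(),
             mkm: MKMParams = MKMParams()):
    """place -> influence -> optimize -> prune; returns (Plan, DoseInfluence)."""
    spotset = place_spots(scenario, config, library.options)
    infl = compute_influence(scenario, spotset, library, config, photon, mkm)
    plan = optimize_weights(infl, scenario, config)
    plan = prune_spots(plan, infl, scenario)
    return plan, infl
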