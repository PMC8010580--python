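"""Plan evaluation: dose/LET grids, DVH-type curves, TCP and hypoxia metrics.

Works on the slab voxel set of a :class:`~ionarc.planning.DoseInfluence`.
Normoxic quantities (physical dose, dose-averaged LET, mMKM effective dose)
come from the stored influence moments; hypoxic effective dose applies each
target component's own HRF (at the voxel pO2) before mixing, using the
per-component decomposition kept inside the target mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ionarc.hypoxia import HypoxiaParams, hrf_ion
from ionarc.mkm import PhotonLQParams, effective_dose_from_lq
from ionarc.planning import DoseInfluence, Plan
from ionarc.scenario import Scenario


@dataclass(frozen=True)
class TCPParams:
    """Poisson TCP bookkeeping: n identical fractions, clonogen density p."""

    n_fractions: int = 10
    cell_density: float = 1e4    # cells / mm^3
    voxel_volume: float = 1.0    # mm^3 accounting unit (density is per mm^3)

    def __post_init__(self):
        if self.n_fractions < 1:
            raise ValueError("need at least one fraction")


@dataclass
class HistogramCurve:
    """Cumulative volume curve V(x) = fraction of voxels with value >= x."""

    edges: np.ndarray
    volume_fraction: np.ndarray

    def dx(self, x_percent: float) -> float:
        return metric_dx(self, x_percent)


def cumulative_histogram(values: np.ndarray, mask: np.ndarray | None = None,
                         bin_width: float | None = None) -> HistogramCurve:
    """Cumulative (DVH-style) histogram of ``values`` over ``mask``."""
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[mask]
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty mask")
    vmax = float(v.max())
    if bin_width is None:
        bin_width = max(vmax / 400.0, 1e-6)
    edges = np.arange(0.0, vmax + 2 * bin_width, bin_width)
    frac = (v[None, :] >= edges[:, None]).mean(axis=1) if v.size * edges.size < 4e6 \
        else 1.0 - np.searchsorted(np.sort(v), edges, side="left") / v.size
    return HistogramCurve(edges=edges, volume_fraction=frac)


def metric_dx(curve: HistogramCurve, x_percent: float) -> float:
    """Value received by the hottest x% of the volume (inverse cumulative curve)."""
    if not 0 < x_percent < 100:
        raise ValueError("x must lie in (0, 100)")
    frac = x_percent / 100.0
    vf = curve.volume_fraction
    # vf is non-increasing from 1 to 0; find where it crosses frac
    idx = np.nonzero(vf >= frac)[0]
    if idx.size == 0:
        return float(curve.edges[0])
    i = idx[-1]
    if i + 1 >= vf.size or vf[i] == vf[i + 1]:
        return float(curve.edges[i])
    # linear interpolation between the bracketing edges
    w = (vf[i] - frac) / (vf[i] - vf[i + 1])
    return float(curve.edges[i] + w * (curve.edges[i + 1] - curve.edges[i]))


@dataclass
class PlanEvaluation:
    """Per-voxel result grids over the influence rows, plus masks."""

    scenario: Scenario
    influence: DoseInfluence
    plan: Plan
    dose: np.ndarray             # Gy per fraction
    letd: np.ndarray             # keV/um (nan where no dose)
    alpha_bar: np.ndarray        # Gy^-1
    beta_bar: float              # Gy^-2 (constant under mMKM)
    d_rbe: np.ndarray            # GyRBE per fraction
    d_oer: np.ndarray | None = None      # GyRBE, target rows only (nan elsewhere)
    alpha_bar_h: np.ndarray | None = None
    sqrt_beta_bar_h: np.ndarray | None = None
    masks: dict = field(default_factory=dict)

    def grid(self, name: str) -> np.ndarray:
        """Scatter a row-vector quantity back onto the full scenario grid (nan fill)."""
        out = np.full(self.scenario.shape, np.nan)
        out.ravel()[self.influence.slab_rows] = getattr(self, name)
        return out


def evaluate_plan(plan: Plan, influence: DoseInfluence, scenario: Scenario,
                  hypoxia: HypoxiaParams | None = None) -> PlanEvaluation:
    """Compute dose, LET_D, D_RBE (and optionally D_OER,RBE) for a plan."""
    w = plan.weights
    photon = influence.photon
    d = influence.A @ w
    dlet = influence.A_let @ w
    dalpha = influence.A_alpha @ w
    pos = d > 0
    letd = np.full_like(d, np.nan)
    letd[pos] = dlet[pos] / d[pos]
    alpha_bar = np.where(pos, dalpha / np.maximum(d, 1e-30), photon.alpha_x)
    d_rbe = effective_dose_from_lq(alpha_bar, photon.beta_x, d, photon)

    masks = {
        "target": influence.mask_rows(scenario.target),
        "core": influence.mask_rows(scenario.core),
        "normal": influence.mask_rows(scenario.normal),
        "phantom": influence.mask_rows(scenario.phantom),
    }
    if scenario.oar is not None:
        masks["oar"] = influence.mask_rows(scenario.oar)

    ev = PlanEvaluation(
        scenario=scenario, influence=influence, plan=plan,
        dose=d, letd=letd, alpha_bar=alpha_bar, beta_bar=photon.beta_x,
        d_rbe=d_rbe, masks=masks,
    )
    if hypoxia is not None:
        _attach_hypoxia(ev, hypoxia)
    return ev


def _attach_hypoxia(ev: PlanEvaluation, hypoxia: HypoxiaParams) -> None:
    """Hypoxic mixed-field moments over target rows from the component COO."""
    infl, scen, photon = ev.influence, ev.scenario, ev.influence.photon
    if scen.pO2 is None:
        raise ValueError("scenario has no pO2 map; call build_po2_map first")
    po2_rows = scen.pO2.ravel()[infl.slab_rows]
    w = ev.plan.weights
    n = infl.n_voxels

    contrib = infl.t_dose * w[infl.t_col].astype(np.float64)
    h = hrf_ion(infl.t_rqe.astype(np.float64), po2_rows[infl.t_row], hypoxia)
    d_h_alpha = np.bincount(infl.t_row,
                            infl.t_dose_alpha * w[infl.t_col] / h, minlength=n)
    d_h_sqrtb = np.bincount(infl.t_row,
                            contrib * np.sqrt(photon.beta_x) / h, minlength=n)
    d_tot = np.bincount(infl.t_row, contrib, minlength=n)

    pos = d_tot > 0
    alpha_h = np.where(pos, d_h_alpha / np.maximum(d_tot, 1e-30), photon.alpha_x)
    sqrt_beta_h = np.where(pos, d_h_sqrtb / np.maximum(d_tot, 1e-30),
                           np.sqrt(photon.beta_x))
    d_oer = np.full(n, np.nan)
    t = ev.masks["target"]
    d_oer[t] = effective_dose_from_lq(alpha_h[t], sqrt_beta_h[t] ** 2,
                                      ev.dose[t], photon)
    ev.d_oer = d_oer
    ev.alpha_bar_h = alpha_h
    ev.sqrt_beta_bar_h = sqrt_beta_h


def letd_grid(ev: PlanEvaluation) -> np.ndarray:
    """Dose-averaged LET on the scenario grid (nan where undefined)."""
    return ev.grid("letd")


def tcp(survival: np.ndarray, params: TCPParams,
        voxel_volume_mm3: float | None = None) -> float:
    """Poisson tumor control probability over voxels with per-fraction survival.

    TCP = prod_i exp(-S_i^n v_i p), computed in log space; the empty product
    is 1.
    """
    s = np.asarray(survival, dtype=float)
    if s.size == 0:
        return 1.0
    if np.any((s < 0) | (s > 1)):
        raise ValueError("survival fractions must lie in [0, 1]")
    v = params.voxel_volume if voxel_volume_mm3 is None else voxel_volume_mm3
    with np.errstate(divide="ignore"):
        log_sn = params.n_fractions * np.log(np.maximum(s, 1e-300))
    expected = np.exp(log_sn) * v * params.cell_density
    expected[s == 0] = 0.0
    return float(np.exp(-expected.sum()))


def _tcp_at_scale(ev: PlanEvaluation, scale: float, params: TCPParams,
                  hypoxic: bool) -> float:
    t = ev.masks["target"]
    d = scale * ev.dose[t]
    if hypoxic:
        if ev.alpha_bar_h is None:
            raise ValueError("hypoxic moments missing; evaluate with hypoxia params")
        a, b = ev.alpha_bar_h[t], ev.sqrt_beta_bar_h[t] ** 2
    else:
        a, b = ev.alpha_bar[t], np.full(t.sum(), ev.beta_bar)
    s = np.exp(-(a * d + b * d**2))
    vol = ev.scenario.voxel_size**3
    return tcp(s, params, voxel_volume_mm3=vol)


def mean_target_effective_dose(ev: PlanEvaluation, scale: float = 1.0) -> float:
    """Mean normoxic D_RBE over target voxels at a dose-scaling factor."""
    t = ev.masks["target"]
    d_rbe = effective_dose_from_lq(ev.alpha_bar[t], ev.beta_bar,
                                   scale * ev.dose[t], ev.influence.photon)
    return float(d_rbe.mean())


def tcp50(ev: PlanEvaluation, params: TCPParams = TCPParams(),
          hypoxic: bool = False, tol_gy: float = 0.01) -> float:
    """Total effective dose (GyRBE) at which TCP crosses 50%.

    The per-fraction physical dose is scaled uniformly (fraction number
    fixed); the crossing is bisected to ``tol_gy`` on the total-normoxic-
    effective-dose axis so hypoxic and normoxic runs share a dose scale.
    """
    lo, hi = 1e-3, 1.0
    for _ in range(60):
        if _tcp_at_scale(ev, hi, params, hypoxic) >= 0.5:
            break
        hi *= 1.6
        if hi > 1e3:
            raise RuntimeError("TCP never reaches 0.5 in the scaling sweep "
                               f"(bracket up to scale {hi:.1f})")
    if _tcp_at_scale(ev, lo, params, hypoxic) >= 0.5:
        raise RuntimeError("TCP already above 0.5 at near-zero dose")
    while (params.n_fractions
           * abs(mean_target_effective_dose(ev, hi) - mean_target_effective_dose(ev, lo))
           > tol_gy):
        mid = 0.5 * (lo + hi)
        if _tcp_at_scale(ev, mid, params, hypoxic) >= 0.5:
            hi = mid
        else:
            lo = mid
    s50 = 0.5 * (lo + hi)
    return params.n_fractions * mean_target_effective_dose(ev, s50)


def angular_fluence_map(plan: Plan) -> dict:
    """Total delivered particles per beam angle, plus a max-normalized copy."""
    ss = plan.spotset
    totals = {}
    for a in np.unique(ss.angles):
        sel = ss.angles == a
        totals[float(a)] = float(ss.weights[sel].sum() * ss.n_v)
    peak = max(totals.values()) or 1.0
    normalized = {a: t / peak for a, t in totals.items()}
    return {"particles": totals, "normalized": normalized}


def delta_oer_vh(ev: PlanEvaluation, mask_rows: np.ndarray,
                 bin_width: float = 0.005) -> HistogramCurve:
    """Cumulative histogram of Delta_OER = D_RBE/D_OER over a row mask.

    Zero-dose voxels are excluded (their ratio is undefined).
    """
    if ev.d_oer is None:
        raise ValueError("hypoxic effective dose not evaluated")
    sel = mask_rows & (ev.dose > 0) & np.isfinite(ev.d_oer)
    ratio = ev.d_rbe[sel] / ev.d_oer[sel]
    return cumulative_histogram(ratio, bin_width=bin_width)


@dataclass
class MetricsReport:
    """Flat metric dictionary plus named curves, JSON-serializable."""

    metrics: dict
    curves: dict = field(default_factory=dict)


def summarize(ev: PlanEvaluation, tcp_params: TCPParams | None = None) -> MetricsReport:
    """Standard metric set: coverage, OAR, core LET statistics, TCP."""
    m: dict = {}
    t = ev.masks["target"]
    core = ev.masks["core"]
    m["mean_target_d_rbe"] = float(ev.d_rbe[t].mean())
    dvh_t = cumulative_histogram(ev.d_rbe, t, bin_width=0.01)
    m["d2_target"] = metric_dx(dvh_t, 2.0)
    m["d95_target"] = metric_dx(dvh_t, 95.0)
    letd_core = ev.letd[core]
    letd_core = letd_core[np.isfinite(letd_core)]
    m["core_letd_max"] = float(letd_core.max())
    m["core_letd_50"] = metric_dx(
        cumulative_histogram(letd_core), 50.0)
    fin = np.isfinite(ev.letd)
    m["normal_letd_max"] = float(ev.letd[ev.masks["normal"] & fin].max())
    if "oar" in ev.masks:
        oar = ev.masks["oar"]
        m["oar_d_max"] = float(ev.d_rbe[oar].max())
        m["oar_d2"] = metric_dx(cumulative_histogram(ev.d_rbe, oar, bin_width=0.005), 2.0)
    if tcp_params is not None:
        m["tcp50_normoxic"] = tcp50(ev, tcp_params, hypoxic=False)
        if ev.d_oer is not None:
            m["tcp50_hypoxic"] = tcp50(ev, tcp_params, hypoxic=True)
            m["tcp50_shift"] = m["tcp50_hypoxic"] - m["tcp50_normoxic"]
            sel = core & (ev.dose > 0)
            m["core_delta_oer_median"] = float(np.median(ev.d_rbe[sel] / ev.d_oer[sel]))
    curves = {"dvh_target": dvh_t}
    return MetricsReport(metrics=m, curves=curves)
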