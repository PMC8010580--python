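"""Analytical per-ion, per-energy depth profiles in water.

Each :class:`DepthProfileTable` carries, on a fine depth grid, the
central-axis integrated dose per primary particle (Gy mm^2), a component
decomposition (primary + effective fragment groups) with per-depth track LET,
velocity and (Z_eff/beta)^2, the lateral Gaussian sigma, and the distal 80%
fall-off depth R80.

Model ingredients
-----------------
* primary term: Bethe stopping power at the dose-averaged residual energy,
  broadened by Gaussian range straggling (sigma_R = k R^0.935 / sqrt(A), plus
  a 1.5 mm ripple-filter term for carbon) and attenuated exponentially by
  nuclear interactions;
* fragment build-up for Z >= 2 beams: one (He) or two (C) effective
  light-fragment groups whose dose grows linearly to the Bragg peak and
  decays exponentially beyond it, extending past R80;
* a fixed beamline water-equivalent thickness (vacuum window, monitor
  chambers) between the accelerator energy and the phantom surface;
* lateral spread: initial focus sigma plus a Highland-type multiple
  Coulomb scattering integral, added in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq

from ionarc.ions import IonSpecies, get_ion, beta_from_energy, rqe, NUCLEON_REST_ENERGY_MEV
from ionarc.stopping import (
    stopping_power,
    csda_range,
    energy_at_range,
    MEV_PER_MM_TO_GY_MM2,
)

#: radiation length of water, mm
X0_WATER_MM = 360.8
#: Highland constant, MeV
HIGHLAND_ES_MEV = 14.1


@dataclass(frozen=True)
class FragmentGroup:
    """One effective fragment group of a beam.

    ``species_label`` identifies the (Z, A) used for LET/RQE/biology;
    ``track_let`` (keV/um) fixes the group's representative energy;
    ``amplitude`` scales the group dose relative to the primary entrance dose;
    the dose ramps linearly up to ``growth_end_frac * range`` and decays
    exponentially beyond it with length ``tail_tau_mm``.
    """

    species_label: str
    track_let: float
    amplitude: float
    tail_tau_mm: float
    growth_end_frac: float = 1.0


_DEFAULT_FRAGMENTS = {
    # secondary protons from nuclear interactions stay within the primary
    # range; their amplitude restores ~60% of the attenuated primary energy
    "proton": (FragmentGroup("proton", 1.0, 0.17, 4.0, growth_end_frac=0.9),),
    "helium": (FragmentGroup("proton", 2.0, 0.10, 30.0),),
    "carbon": (
        FragmentGroup("helium", 4.0, 0.18, 30.0),
        FragmentGroup("proton", 1.0, 0.12, 35.0),
    ),
}


@dataclass(frozen=True)
class BeamModelOptions:
    """Generation parameters of the analytical beam model (mm unless noted)."""

    depth_step: float = 0.1
    nozzle_wet: float = 3.0
    straggling_coeff: float = 1.2 / 100.0**0.935
    straggling_power: float = 0.935
    ripple_sigma_carbon: float = 1.5
    nuclear_mfp: tuple = (("proton", 850.0), ("helium", 450.0), ("carbon", 255.0))
    tail_length: float = 120.0
    lateral_cutoff_sigma: float = 3.2

    def mfp(self, label: str) -> float:
        return dict(self.nuclear_mfp)[label]


@dataclass
class ComponentProfile:
    """Per-depth arrays of one field component of a table."""

    name: str
    species_label: str
    dose: np.ndarray        # Gy mm^2 per primary
    energy: np.ndarray      # MeV/u (dose-averaged for the primary)
    track_let: np.ndarray   # keV/um
    beta: np.ndarray
    rqe: np.ndarray


@dataclass(frozen=True)
class FieldComponent:
    """A single component of the local mixed field at one depth."""

    species_label: str
    dose_fraction: float
    track_LET: float
    RQE: float
    beta: float
    energy: float = 0.0


@dataclass
class DepthProfileTable:
    ion: IonSpecies
    energy: float
    depth: np.ndarray
    dose_per_primary: np.ndarray
    components: list
    lateral_sigma: np.ndarray
    R80: float
    options: BeamModelOptions = field(default_factory=BeamModelOptions)

    def letd(self) -> np.ndarray:
        """Dose-averaged LET profile, keV/um (nan where dose vanishes)."""
        num = sum(c.dose * c.track_let for c in self.components)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.dose_per_primary > 0, num / self.dose_per_primary, np.nan)

    def components_at(self, depth_mm: float) -> list:
        """Mixed-field decomposition at one depth as :class:`FieldComponent` s."""
        total = float(np.interp(depth_mm, self.depth, self.dose_per_primary))
        out = []
        if total <= 0:
            return out
        for c in self.components:
            d = float(np.interp(depth_mm, self.depth, c.dose))
            if d <= 0:
                continue
            out.append(
                FieldComponent(
                    species_label=c.species_label,
                    dose_fraction=d / total,
                    track_LET=float(np.interp(depth_mm, self.depth, c.track_let)),
                    RQE=float(np.interp(depth_mm, self.depth, c.rqe)),
                    beta=float(np.interp(depth_mm, self.depth, c.beta)),
                    energy=float(np.interp(depth_mm, self.depth, c.energy)),
                )
            )
        return out

    def sigma_at(self, depth_mm) -> np.ndarray:
        return np.interp(depth_mm, self.depth, self.lateral_sigma)


def _fragment_energy(species_label: str, track_let: float) -> float:
    """Representative kinetic energy (MeV/u) of a fragment group from its LET."""
    ion = get_ion(species_label)
    lo, hi = 5.0, 1000.0
    f = lambda e: stopping_power(ion.Z, ion.A, e) - track_let
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(f"fragment LET {track_let} keV/um not invertible for {species_label}")
    return brentq(f, lo, hi, xtol=1e-6)


def _highland_sigma(ion: IonSpecies, energy: float, depth: np.ndarray,
                    r_eff: float) -> np.ndarray:
    """Multiple-scattering sigma (mm) at each depth via the Highland integral.

    sigma^2(d) = int_0^min(d,R) [E_s Z / (p v)]^2 (d - z)^2 / X0 dz; beyond the
    primary range the already-accumulated angular spread keeps drifting, so
    the integrand is truncated at R while the lever arm keeps growing.
    """
    z = depth
    e_res = np.where(z < r_eff, energy_at_range(ion, np.maximum(r_eff - z, 1e-6)), 1.0)
    e_res = np.maximum(e_res, 1.0)
    pc = np.sqrt(e_res * (e_res + 2.0 * NUCLEON_REST_ENERGY_MEV))  # MeV per nucleon
    beta = beta_from_energy(e_res)
    pv = ion.A * pc * beta
    q = (HIGHLAND_ES_MEV * ion.Z / pv) ** 2 / X0_WATER_MM
    q = np.where(z < r_eff, q, 0.0)
    dz = np.gradient(z)
    q0 = np.cumsum(q * dz)
    q1 = np.cumsum(q * z * dz)
    q2 = np.cumsum(q * z**2 * dz)
    sig2 = z**2 * q0 - 2.0 * z * q1 + q2
    return np.sqrt(np.maximum(sig2, 0.0))


def build_depth_profile(ion: IonSpecies, energy: float,
                        options: BeamModelOptions | None = None) -> DepthProfileTable:
    """Build the depth-resolved physics table for one (ion, energy)."""
    opts = options or BeamModelOptions()
    if opts.depth_step <= 0:
        raise ValueError("depth_step must be positive")
    r_csda = csda_range(ion, energy)
    r_eff = r_csda - opts.nozzle_wet
    if r_eff <= 5.0:
        raise ValueError(f"energy {energy} MeV/u does not reach past the beamline material")

    sigma_straggle = opts.straggling_coeff * r_eff**opts.straggling_power / np.sqrt(ion.A)
    if ion.label == "carbon":
        sigma_straggle = float(np.hypot(sigma_straggle, opts.ripple_sigma_carbon))
    if sigma_straggle <= 0:
        raise ValueError("straggling sigma must be positive")

    dz = opts.depth_step
    edges = np.arange(0.0, r_eff + opts.tail_length + dz, dz)
    z = 0.5 * (edges[:-1] + edges[1:])

    # unstraggled primary along the path; the Bragg spike is integrated
    # exactly per grid cell (energy lost between the cell edges), which
    # conserves energy independently of the grid alignment
    resid_edge = r_eff - edges
    e_edge = np.where(resid_edge > 0,
                      energy_at_range(ion, np.maximum(resid_edge, 1e-9)), 0.0)
    resid = r_eff - z
    inside = resid > 0
    e_res = np.where(inside, energy_at_range(ion, np.maximum(resid, 1e-9)), 0.0)
    s_let = np.where(inside, stopping_power(ion.Z, ion.A, np.maximum(e_res, 1.0)), 0.0)
    fluence = np.exp(-z / opts.mfp(ion.label))
    w = ion.A * (e_edge[:-1] - e_edge[1:]) / dz * fluence  # raw dose, MeV/mm per primary

    sig_pix = sigma_straggle / dz
    smooth = lambda a: gaussian_filter1d(a, sig_pix, mode="nearest")
    d_prim = smooth(w)
    with np.errstate(invalid="ignore", divide="ignore"):
        let_prim = np.where(d_prim > 0, smooth(w * s_let) / d_prim, 0.0)
        e_prim = np.where(d_prim > 0, smooth(w * e_res) / d_prim, 0.0)
    e_prim = np.maximum(e_prim, 1.0)
    beta_prim = beta_from_energy(e_prim)

    comps = [
        ComponentProfile(
            name=ion.label,
            species_label=ion.label,
            dose=d_prim * MEV_PER_MM_TO_GY_MM2,
            energy=e_prim,
            track_let=let_prim,
            beta=beta_prim,
            rqe=rqe(ion.Z, beta_prim),
        )
    ]

    d_ent = w[0]
    for grp in _DEFAULT_FRAGMENTS[ion.label]:
        z_knee = grp.growth_end_frac * r_eff
        shape = np.where(
            z <= z_knee,
            z / z_knee,
            np.exp(-(z - z_knee) / grp.tail_tau_mm),
        )
        d_frag = smooth(grp.amplitude * d_ent * shape) * MEV_PER_MM_TO_GY_MM2
        e_frag = _fragment_energy(grp.species_label, grp.track_let)
        b_frag = beta_from_energy(e_frag)
        sp = get_ion(grp.species_label)
        comps.append(
            ComponentProfile(
                name=f"frag_{grp.species_label}",
                species_label=grp.species_label,
                dose=d_frag,
                energy=np.full_like(z, e_frag),
                track_let=np.full_like(z, grp.track_let),
                beta=np.full_like(z, b_frag),
                rqe=np.full_like(z, rqe(sp.Z, b_frag)),
            )
        )

    total = sum(c.dose for c in comps)

    # distal 80% fall-off depth of the total curve
    i_peak = int(np.argmax(total))
    level = 0.8 * total[i_peak]
    distal = total[i_peak:]
    below = np.nonzero(distal < level)[0]
    if below.size == 0:
        raise RuntimeError("no distal 80% crossing found")
    j = below[0]
    z1, z2 = z[i_peak + j - 1], z[i_peak + j]
    d1, d2 = distal[j - 1], distal[j]
    r80 = float(z1 + (d1 - level) / (d1 - d2) * (z2 - z1))

    sigma_mcs = _highland_sigma(ion, energy, z, r_eff)
    sigma = np.hypot(ion.initial_spot_sigma, sigma_mcs)

    return DepthProfileTable(
        ion=ion,
        energy=float(energy),
        depth=z,
        dose_per_primary=total,
        components=comps,
        lateral_sigma=sigma,
        R80=r80,
        options=opts,
    )


def depth_letd(table: DepthProfileTable, depth_mm: float) -> float:
    """Dose-averaged LET (keV/um) of the table's mixed field at one depth.

    Returns nan where the total dose vanishes (undefined, not zero).
    """
    if depth_mm < table.depth[0] or depth_mm > table.depth[-1]:
        raise ValueError("depth outside table grid")
    comps = table.components_at(depth_mm)
    total = sum(c.dose_fraction for c in comps)
    if not comps or total <= 0:
        return float("nan")
    return sum(c.dose_fraction * c.track_LET for c in comps) / total


@lru_cache(maxsize=256)
def _cached_table(label: str, energy: float, opts: BeamModelOptions) -> DepthProfileTable:
    return build_depth_profile(get_ion(label), energy, opts)


def get_table(ion: IonSpecies, energy: float,
              options: BeamModelOptions | None = None) -> DepthProfileTable:
    """Memoized :func:`build_depth_profile`."""
    return _cached_table(ion.label, float(energy), options or BeamModelOptions())


def lateral_sigma(ion: IonSpecies, energy: float, depth_mm,
                  options: BeamModelOptions | None = None) -> np.ndarray:
    """Total lateral Gaussian sigma (mm) of the pencil beam at ``depth_mm``."""
    if np.any(np.asarray(depth_mm) < 0):
        raise ValueError("depth must be non-negative")
    return get_table(ion, energy, options).sigma_at(depth_mm)


def energy_for_r80(ion: IonSpecies, depth_mm: float,
                   options: BeamModelOptions | None = None) -> float:
    """Beam energy (MeV/u) whose table R80 equals ``depth_mm``.

    Inverse of the forward R80 computation, solved with a bracketed root
    finder; raises if ``depth_mm`` is outside the admissible window.
    """
    opts = options or BeamModelOptions()
    lo_mm, hi_mm = 15.0, 330.0
    if not (lo_mm <= depth_mm <= hi_mm):
        raise ValueError(f"R80 depth {depth_mm} mm outside admissible window"
                         f" [{lo_mm}, {hi_mm}] mm")
    e_guess = energy_at_range(ion, depth_mm + opts.nozzle_wet)
    f = lambda e: get_table(ion, e, opts).R80 - depth_mm
    lo, hi = 0.85 * e_guess, 1.18 * e_guess
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"R80 = {depth_mm} mm not bracketed for {ion.label};"
                         f" admissible window is [{lo_mm}, {hi_mm}] mm")
    return brentq(f, lo, hi, xtol=1e-4)


@dataclass
class BeamLibrary:
    """Map ion -> energy -> depth table, plus the generation parameters."""

    options: BeamModelOptions = field(default_factory=BeamModelOptions)
    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, ion: IonSpecies, energy: float) -> DepthProfileTable:
        tab = get_table(ion, energy, self.options)
        self.tables.setdefault(ion.label, {})[float(energy)] = tab
        return tab

    def get(self, ion: IonSpecies, energy: float) -> DepthProfileTable:
        try:
            return self.tables[ion.label][float(energy)]
        except KeyError:
            return self.add(ion, energy)

    def check(self, tol_mm: float = 0.1) -> None:
        """Verify each stored R80 is reproduced by regenerating its table."""
        for label, by_e in self.tables.items():
            for e, tab in by_e.items():
                fresh = build_depth_profile(get_ion(label), e, self.options)
                if abs(fresh.R80 - tab.R80) > tol_mm:
                    raise AssertionError(
                        f"{label} @ {e} MeV/u: stored R80 {tab.R80:.3f} != "
                        f"regenerated {fresh.R80:.3f}"
                    )

    def generation_parameters(self) -> dict:
        d = asdict(self.options)
        d["nuclear_mfp"] = dict(self.options.nuclear_mfp)
        return d
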