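# Methods

`ionarc` reproduces, at desk scale, the physics and radiobiology of a
single-energy spot-scanning hadron-arc (SHArc) planning study on cylindrical
water phantoms, for the three clinical ion beams p, ⁴He and ¹²C. This note
records the models, their parameters and the design choices that were
genuinely open.

## Beam model

Depth profiles are analytical, built per (ion, energy) on a 0.1 mm grid.

**Stopping power and range.** Electronic stopping power follows the Bethe
formula for liquid water with mean excitation energy I = 75 eV and the Barkas
effective charge Z_eff = Z(1 − exp(−125 β Z^(−2/3))); shell and density
corrections are omitted (sub-percent above a few MeV/u), and below 1 MeV/u
the stopping power is frozen at its 1 MeV/u value, which affects only the
last ~0.05 mm of track. The proton range table is one numerical integration
of 1/S(E) at import; other ions use the exact A/Z² per-nucleon scaling of
the Bethe theory, and range–energy interpolation is log–log (a locally exact
Bragg–Kleeman power law). A fixed beamline water-equivalent thickness of
3.0 mm (vacuum window, monitor chambers) separates the accelerator energy
from the phantom surface; it is part of the forward model used when
inverting beam energy from a requested R₈₀. With these ingredients the
energies whose R₈₀ reaches the 100 mm isocenter depth are ~117.4 (p),
~117.4 (He) and ~220.7 MeV/u (C), within ~1% of the clinical values the
study design quotes.

**Bragg curve.** The primary term integrates the energy lost between depth
cell edges exactly (so the Bragg spike conserves energy independently of
grid alignment), attenuates the primary fluence exponentially with nuclear
interaction lengths λ = 850/450/255 mm for p/He/C, and convolves with a
Gaussian range-straggling kernel σ_R = k·R^0.935/√A with k set so that
σ_R = 1.2 mm at R = 100 mm for protons. Carbon additionally carries a 1.5 mm
ripple-filter broadening in quadrature. Per-depth component properties
(residual energy, track LET, β, (Z_eff/β)²) are dose-averaged through the
same kernel.

**Fragments.** Nuclear products are modeled as effective groups whose dose
rises linearly to the Bragg peak and decays exponentially beyond it:
a light-fragment group at 2 keV/μm for helium beams, a two-group He-like
(4 keV/μm) + H-like (1 keV/μm) mix for carbon, and a secondary-proton group
for proton beams that stays within the primary range (growth to 0.9 R, 4 mm
decay) whose amplitude restores roughly 60% of the attenuated primary
energy locally. Each group's representative energy — hence β, RQE and its
mMKM α — follows from inverting the species' stopping power at the group
LET. Amplitudes (0.17 p, 0.10 He, 0.18+0.12 C, relative to the primary
entrance dose) reproduce the qualitative tail magnitudes of measured Bragg
curves; they are the least constrained part of the model.

**Lateral spread.** σ(z) = √(σ₀² + σ_MCS(z)²) with initial focus sigmas
σ₀ = 5.1/3.4/2.5 mm (p/He/C) and a Highland-type multiple-Coulomb-scattering
integral σ_MCS²(d) = ∫ (14.1 MeV · Z/pv)² (d−z)²/X₀ dz, X₀ = 360.8 mm.
Proton pencils spread most, carbon least, matching the clinical ordering.

**R₈₀** is read off the distal 80%-of-maximum crossing of the total
(straggled, fragment-inclusive) curve; energy inversion brackets and solves
this forward map, so table and inverse agree by construction (≤0.2 mm).

## mMKM effective dose

Per-component LQ parameters use the modified microdosimetric kinetic model
with domain radius R_d = 0.3 μm, nucleus radius R_n = 3.6 μm and the photon
reference (α/β)_x = 2 Gy (α_x = 0.05 Gy⁻¹, β_x = 0.025 Gy⁻²):
α_ion = α_x + β_x · z*₁D, β_ion = β_x. The saturation-corrected dose-mean
specific energy per event z*₁D comes from an amorphous-track calculation:
the Kiefer–Chatterjee radial dose (core radius 0.0116 β μm, 1/r² penumbra
to 0.0616 E^1.7 μm, normalized to the track LET) is averaged over the
domain cross-section at impact parameter b, and overkill is applied through
the y* construction with saturation parameter
z₀ = (R_n²/R_d)·√(2/(β_x(R_d²+R_n²))) ≈ 107 Gy (y₀ ≈ 189 keV/μm) — the
canonical magnitude, determined by the nucleus radius. z*₁D(ion, E) is
tabulated on a 90-point log-energy grid per species and interpolated. The
resulting carbon α(LET) peaks near 250 keV/μm, the expected overkill
position for a low-(α/β) tissue. Mixed fields mix dose-weighted (α linear,
√β linear), and RBE-weighted dose inverts the photon LQ at equal log
survival.

## Hypoxia (HRF) model

The hypoxia reduction factor is parameterized in oxygen tension and
radiation quality RQE = (Z_eff/β)²:

    HRF_ph(pO₂) = (mK + pO₂)/(K + pO₂),  m = 2.94, K = 0.129 %O₂
    HRF_ion(RQE, pO₂) = (a·HRF_ph + RQE^γ)/(a + RQE^γ),  a = 2.988×10⁶, γ = 2.169

HRF acts as a dose-modifying factor: α → α/HRF, β → β/HRF². The printed
survival-based extraction formula carries an ambiguous trailing β-ratio
factor; it is implemented at first power, the unique reading under which
dose-modifying inputs (α/H, β/H²) return exactly H at every survival level —
the property the dose-modifying assumption requires. Each mixed-field
component is reduced by the HRF at its own RQE before mixing (a per-voxel
dose-averaged-RQE shortcut was considered and rejected: it biases the core
where low- and high-RQE components coexist).

## Scenarios

Water cylinder H = 200 mm, r = 100 mm; target cylinder H = 60 mm, r = 30 mm
at isocenter; r = 5 mm core over the full target height (the core's axial
extent is not otherwise constrained); case B adds a cylindrical OAR
(r = 10 mm, H = 60 mm) at a 5 mm radial surface gap on the +x side. The pO₂
map assigns nine log-spaced levels from 5% (outer ring) to 0.25% (r ≤ 5 mm
core) on nine equal-width radial shells between r = 30 and r = 5 mm — the
log spacing is read as applying to the levels, not the shell radii — and
21% outside the target. Grids default to 2 mm voxels, isocenter at the
origin, gantry angle clockwise from +y; depth in the homogeneous phantom is
geometric.

## Planning

Arc plans use 360° in 2° steps with one beam energy (R₈₀ at isocenter);
the sub-arc variant cycles 7 energies (R₈₀ = 100 ± {0,2,4,6} mm) over 14°
sub-arcs. Static 1F/2F/3F fields (90°, 0/180°, 0/90/180°) use a
range-stacked energy ladder with R₈₀ every 3 mm across the target depth
extent: a monoenergetic static field cannot cover the 60 mm target and
would park its LET maximum at isocenter rather than at the distal edge, so
the SOBP-like ladder is the faithful stand-in for clinical energy stacks.
Spots sit on a rectangular raster at the clinical lateral spacings
(4.8/2.4/2.4 mm) covering the target's beam's-eye view plus one spacing.

**Desk-scale representation.** Spots sharing (angle, energy, lateral offset)
form one column along the target height with a common weight, and dose is
computed on the central axial slab (default 20 mm) of the phantom. The
study geometry is z-invariant there, and every reported metric (core LET,
OAR D₂%/D_max, mean target dose, Δ_OER, TCP orderings) is an axial-plane
quantity; superior–inferior fall-off is not optimized. Full-3D independent
weights at 2 mm voxels would exceed a desktop memory budget without
changing those metrics.

**Objective and optimizer.** Quadratic penalties on re-linearized effective
dose: target coverage band 0.97–1.06 × 3 GyRBE (underdose weighted 2:1 over
overdose, the usual clinical priority), a fall-off shell whose allowance
decays linearly from prescription at the target surface to 0.25 GyRBE at
5 mm, a 0.35 GyRBE soft cap on remaining normal tissue, and (case B) an OAR
cap of 0.5 GyRBE optimized against a 10% internal margin — a quadratic
penalty only approaches its cap from above, and the margin is what lets the
delivered maximum respect the clinical limit. The nonconvex effective-dose
objective is solved by projected-gradient descent with Armijo backtracking
(objective non-increasing over accepted steps) and the per-voxel RBE
factors re-linearized in three outer rounds. Spot-number minimization is
staged: fluence floors at 30%, 60% and 100% of the clinical per-spot
threshold are applied in rounds, removing sub-floor spots and re-optimizing
the survivors, whose weights end at or above threshold. Everything is
deterministic; the seed only tags run configurations.

Static single-field plans in case B trade target coverage against the OAR
cap (the OAR lies in the beam path) and settle around 2.2 GyRBE mean target
dose — the same tension the original study reports for static fields near
an OAR.

## Evaluation

DVH-type curves are cumulative (V(x) = fraction of voxels ≥ x); D_x% is
their inverse. LET_D grids are dose-averaged over every spot/component
contribution via stored influence moments. TCP is Poisson over target
voxels, TCP = Π exp(−Sᵢⁿ vᵢ p), with p = 10⁴ cells/mm³, voxel-volume
weighting, and n = 10 fractions of the 3 GyRBE plan by default (the
fraction number is otherwise unconstrained; TCP₅₀ is reported as total
effective dose so shifts are comparable across n). TCP₅₀ scales the
per-fraction physical dose at fixed fraction number and bisects the 50%
crossing to 0.01 GyRBE; hypoxic survival uses the per-voxel mixed-field
(ᾱ_h, β̄_h) after per-component HRF application. Hypoxic effective dose is
evaluated inside the target mask, where pO₂ < 21%; outside it HRF ≈ 1 and
D_OER,RBE = D_RBE by construction.

## Known limitations

* The fragment model is a two-group caricature: no isotope-resolved spectra,
  no angular emission; tail magnitudes are qualitative.
* The proton low-dose halo (second Gaussian) is off by default; HIT-specific
  nozzle scattering is not modeled, so case-B proton OAR doses are
  optimistic relative to the original facility.
* Static plans share the arc's single-field geometry with an idealized
  ladder; clinical energy-stack spacing and spot weights per layer differ.
* The slab evaluation ignores superior–inferior edge effects; TCP values are
  therefore partial-volume quantities, meaningful in comparisons (shifts,
  orderings), not as absolute control probabilities.
* Helium arc plans show a larger hypoxic TCP₅₀ shift than helium static
  plans here: the arc's normoxic TCP benefits strongly from the
  mid-LET core boost that hypoxia then erases, while the original study
  reported a small arc advantage for helium — a fidelity gap tied to the
  analytic beam/tissue configuration, noted rather than hidden.
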