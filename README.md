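# ionarc

Analytical treatment-planning and radiobiology toolkit for **single-energy
ion-arc (SHArc) therapy** studies on cylindrical water phantoms, with proton,
helium and carbon beams.

Rotational (arc) delivery of a single-energy particle beam stacks every
field's Bragg peak at the rotation center: the highest dose *and* the highest
dose-averaged LET concentrate in the tumor core instead of at the distal
field edge where conventional static fields put them. That matters for
hypoxic tumors — radio-resistance from low oxygen tension is strongest for
sparsely ionizing radiation and fades at high LET — so a carbon arc may
partly neutralize a hypoxic core without ever measuring pO₂. `ionarc` lets
you study this quantitatively on phantom geometry: it builds analytical beam
tables, places and optimizes spots for arc and static plans, computes
mMKM RBE-weighted dose, dose-averaged LET, DVHs, TCP, and the effect of a
pO₂ gradient through an HRF/OER model.

## Models in brief

* **Beam physics** — Bethe stopping power (I = 75 eV) with Barkas effective
  charge, Gaussian range straggling, exponential nuclear attenuation,
  effective fragment groups, Highland lateral spread. Tables resolve dose,
  LET, β and (Z_eff/β)² per field component at every depth.
* **Biology** — modified microdosimetric kinetic model (mMKM):
  α_ion = α_x + β_x·z*₁D with R_d = 0.3 μm, R_n = 3.6 μm, (α/β)_x = 2 Gy;
  amorphous-track (Kiefer–Chatterjee) computation of the saturation-corrected
  dose-mean specific energy z*₁D. Mixed fields mix dose-weighted; effective
  dose D_RBE inverts the photon LQ curve at equal log-survival.
* **Hypoxia** — hypoxia reduction factor
  HRF_ion(RQE, pO₂) = (a·HRF_ph(pO₂) + RQE^γ)/(a + RQE^γ) with
  HRF_ph = (mK + pO₂)/(K + pO₂), m = 2.94, K = 0.129 %O₂, a = 2.988×10⁶,
  γ = 2.169; applied as a dose-modifying factor per field component
  (α→α/HRF, β→β/HRF²). Δ_OER = D_RBE/D_OER,RBE and Poisson TCP
  (p = 10⁴ cells/mm³) quantify the cost of a 5%→0.25% pO₂ gradient.
* **Planning** — 360° arc in 2° steps at one energy (R₈₀ at isocenter) vs
  1F/2F/3F static fields with a range-stacked ladder; quadratic-penalty
  objectives (3 GyRBE prescription, 97/106% band, lateral fall-off,
  0.5 GyRBE OAR cap), projected-gradient optimization with RBE
  re-linearization, and clinical minimum-fluence spot pruning
  (5.8×10⁵ / 1.3×10⁵ / 1.5×10⁴ particles for p/He/C).

See `docs/methods.md` for the full model description, parameter table and
limitations.

## Worked example

```python
from ionarc import PROTON, HELIUM, CARBON
from ionarc.beam import energy_for_r80, get_table, depth_letd
from ionarc.hypoxia import hrf_ion, hrf_photon
from ionarc.ions import rqe_from_energy

for ion in (PROTON, HELIUM, CARBON):
    e = energy_for_r80(ion, 100.0)      # arc energy: R80 at isocenter depth
    tab = get_table(ion, e)
    print(ion.label, round(e, 2), round(tab.R80, 2),
          round(depth_letd(tab, 1.0), 2))
```

prints (MeV/u, mm, keV/μm):

```
proton 117.35 100.0 0.66
helium 117.36 100.01 2.62
carbon 220.74 100.0 15.31
```

i.e. the single energies whose distal 80% fall-off reaches the 100 mm
isocenter depth — within ~1% of the clinical values 118.14/118.51/218.52
MeV/u — together with the entrance dose-averaged LET of each beam. The
hypoxia model then shows why carbon arcs are special: at the anoxic-core
oxygen tension of 0.25 %O₂ the photon-like hypoxia reduction factor is

```python
>>> round(hrf_photon(0.25), 3)
1.66
>>> q = rqe_from_energy(CARBON, 12.0)    # carbon near the Bragg peak
>>> round(hrf_ion(q, 0.25), 3)
1.201
```

a stopping carbon ion (RQE ≈ 1400) cuts the needed dose escalation from 66%
to 20%, while a proton near its peak (RQE ≈ 94) still sees HRF ≈ 1.656.

End-to-end plans run through the pipeline or the CLI:

```bash
ionarc plan run --ion carbon --technique sharc --case B --hypoxia --outdir out/
ionarc beamlib build --ion carbon --r80 100
ionarc hypoxia curves --out hrf_curves.csv
```

`plan run` writes D_RBE/LET_D (and D_OER,RBE) volumes as NRRD, DVH and
LET-volume-histogram curves as CSV, the spot list, angular fluence map and a
metrics JSON (mean target dose, D₂%, core LET_D,50, OAR D_max, TCP₅₀
shift, …) with a checksum manifest.

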