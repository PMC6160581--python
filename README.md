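# coshnet

Oxygen transport through cortical capillary networks, and the damping of
**capillary outflow saturation heterogeneity (COSH)** by diffusive
interaction.

Tissue regions fed by capillaries with long transit times or low hematocrit
receive blood whose hemoglobin saturation S has dropped the most; they are
the first at risk of hypoxia. COSH — the RBC-flow-weighted standard
deviation of S at the distal ends of capillary paths — measures that risk.
Oxygen also diffuses through the shared tissue between red blood cells and
between neighbouring capillaries ("diffusive interaction"), which transfers
oxygen from well-supplied to poorly-supplied regions and damps COSH. This
package quantifies both effects on capillary network graphs.

## What it computes

Given a capillary network (node/edge files with 3-D centerlines and
diameters) and sparse RBC velocity measurements:

1. **Flow reconstruction** — boundary pressures minimizing hydraulic power
   Σ q²R plus a weighted misfit to the measured speeds, iterated to a
   self-consistent hematocrit field (Pries–Secomb viscosity and
   phase-separation closures).
2. **Tissue territories** — geometric (nearest-centerline voxel partition)
   and functional (fitted so the transport model reproduces each vessel's
   saturation drop), as equivalent Krogh radii via V = Lπ(r_t² − r_w²).
3. **Saturation transport, three ways** —
   * the saturation balance `Q_O2(S) dS/dx = −j_t` propagated through the
     network with discrete saturation distributions merged at converging
     bifurcations, using *geometric* radii (no diffusive interaction);
   * the same with *functional* radii (capillary interaction only);
   * a particle surrogate with individual moving RBCs exchanging oxygen
     with coupled tissue compartments (full interaction plus hematocrit
     fluctuations).
4. **Heterogeneity metrics** — COSH per model and the percent reduction by
   diffusive interaction, transit-time heterogeneity (CTH), coefficients of
   variation, correlation battery, and a functional/geometric tissue-volume
   conservation check.

Networks matching published cortical statistics (~90 vessels, d = 5 ± 1.5 μm,
v = 0.9 ± 0.5 mm/s, ~22 converging bifurcations in a ~220×220×170 μm box)
can be generated synthetically, so the whole analysis runs without imaging
data.

## Worked example

```python
from coshnet import CapillaryOxygenTransport, NetworkStatsTarget

model = CapillaryOxygenTransport.from_synthetic(
    NetworkStatsTarget.mouse_cortex_1(), seed=1)   # network + emulated line scans
results = model.fit(seed=101)
print(results.summary())
```

```
Capillary oxygen transport analysis
======================================================
Flow solution
==============================================
vessels                         92
converging bifurcations         18
|v_rbc| mean ± SD         0.732 ± 0.555 mm/s
tube hematocrit           0.231 ± 0.104
volume conservation       7.41e-14
RBC-flux conservation     2.63e-16
outer iterations                38
measurement misfit RMS     19.488%
------------------------------------------------------
paths (inflow→outflow)             57
mean transit time               0.808 s
CTH (weighted SD of transit)    0.566 s
CoV transit / CoV ΔS            0.701 / 0.267
COSH  ODE geometric radii      0.1604
COSH  ODE functional radii     0.1061
COSH  moving-RBC surrogate     0.0756
COSH reduction by interaction    52.9 %
mean outflow S (surrogate)      0.317
RBC flow with S_v < 0.2           8.1 %
tissue volume discrepancy        0.89 %  (85 vessels)
r(ΔS, transit)                   0.80  (p = 0)
r(ΔS, length)                    0.62  (p = 1.5e-157)
r(r_fun, r_geo)                  0.35  (p = 0.0014)
r(r_fun, S̄)                     0.75  (p = 5e-16)
r(r_fun, RBC flow)               0.59  (p = 9.1e-09)
```

Reading this: the reconstructed flow conserves mass to machine precision
and lands near the target velocity statistics. Without diffusive
interaction (geometric radii) the outflow saturation spread is 0.160; the
functional-radius model, which carries capillary interaction only, gives
0.106, and the full particle model 0.076 — a 53% reduction on this seed.
The saturation drop correlates more strongly with transit time (r = 0.80)
than with path length (r = 0.62), and the fitted (functional) tissue radii
correlate with each vessel's saturation and RBC flow rather than with the
anatomical (geometric) radii — tissue is supplied by whoever can supply it,
not by whoever is nearest. The functional and geometric tissue volume
totals agree to 0.9%, the steady-state consistency check.

A command-line interface wraps the same pipeline:

```sh
coshnet generate --seed 1 --out net/          # network + measurements files
coshnet run --seed 1 --out results/           # full analysis, writes CSV/JSON/VTK
```

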