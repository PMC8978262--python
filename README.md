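# tetradose

Monte Carlo simulation of light propagation in tetrahedral tissue meshes,
with treatment-plan evaluation and optimization for interstitial
photodynamic therapy (iPDT).

iPDT destroys solid tumours by activating a photosensitizing drug with
light delivered through implanted fibres.  Whether a plan works hinges on
the fluence-rate field Φ(r) [mW/cm²] that a given set of sources produces
inside optically turbid tissue — a quantity that must be computed by
Monte Carlo photon transport in realistic geometries.  `tetradose`
provides:

* a photon-packet transport engine on tetrahedral meshes — exponential
  free paths (interaction coefficient μt = μa + μs), weight deposition
  μa/μt per interaction, Henyey–Greenstein scattering with anisotropy g,
  unpolarised Fresnel reflection/refraction at refractive-index
  mismatches, Russian-roulette termination, and an always-on energy
  conservation ledger;
* six source models: point, pencil beam, cut-end cone fibre, cylindrical
  diffuser (with optional per-segment emission weights), ball, and
  surface/volume-region emitters;
* dosimetry: absorption and track-length fluence estimators, dose–volume
  histograms, the photodynamic threshold model (tissue necrosed where
  dose ≥ a tissue-specific threshold), coverage metrics, and the
  diffusion-theory point-source solution Φ(r) = P·e^(−μeff·r)/(4πDr) for
  validation;
* planning: per-source unit-power dose matrices, a two-phase linear
  program that allocates source powers to reach a tumour-coverage target
  (default ≥ 98 % of tumour volume at threshold) while minimizing
  organ-at-risk overdose, surface fluence-rate capping (e.g. 300 mW/cm²
  at a vessel intima), and optional simulated-annealing refinement of
  source positions;
* workflows: optical-property lookup-table sweeps over (μa, μs′) grids
  with detector-signal inversion, and vessel diffuser dose escalation;
* a phantom generator (box, slab stack, sphere-in-box, vessel-in-box)
  so every pipeline is testable with synthetic geometry.

Meshes are read and written as legacy-ASCII VTK unstructured grids with a
per-cell integer `region` array; all internal lengths are mm and optical
coefficients mm⁻¹.

## Worked example

```python
import numpy as np
import tetradose as td

# 40 mm soft-tissue cube, one 100 mW isotropic point source at the centre
mesh = td.generate_phantom(
    td.PhantomSpec(kind="box", extents=(40, 40, 40), cells=(10, 10, 10))
)
materials = {0: td.Material.from_reduced(0, "tissue", mu_a=0.01, mu_s_prime=1.0,
                                         g=0.0, n=1.0)}
source = td.PointSource(position=(20, 20, 20), power=100.0)

score = td.run_mc(mesh, materials, [source],
                  td.SimConfig(n_packets=200_000, seed=1))
print("ledger:", {k: round(v, 6) for k, v in score.ledger.items()})

field = td.fluence_from_score(score, mesh, materials, total_power=100.0)
r = np.linalg.norm(mesh.centroids - 20.0, axis=1)
for rr in (5.0, 10.0):
    mc = field.phi[np.abs(r - rr) < 1.5].mean()
    ref = td.analytic_point_fluence(rr, 100.0, 0.01, 1.0)
    print(f"r = {rr:4.1f} mm   MC {mc:8.3f}   diffusion theory {ref:8.3f}  mW/cm^2")
```

prints

```
ledger: {'emitted': 200000.0, 'absorbed_total': 173971.322876, 'exited_total': 26028.676836, 'roulette_net': 0.000288, 'residual': 0.0}
r =  5.0 mm   MC  211.336   diffusion theory  201.965  mW/cm^2
r = 10.0 mm   MC   40.165   diffusion theory   42.292  mW/cm^2
```

The ledger shows the conservation identity (emitted = absorbed + exited +
roulette balance, residual 0 to machine precision), and the shell-averaged
Monte Carlo fluence rate tracks the diffusion closed form within a few
percent at these radii.

There is also a CLI (`tetradose phantom | simulate | dvh | optimize |
sweep | escalate`); run `tetradose --help` for the options of each
subcommand.

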