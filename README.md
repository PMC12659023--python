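# poreflux

Electrohydrodynamic analysis of nanopore molecular-dynamics
trajectories: windowed ionic currents from charge-weighted axial
displacements, species-resolved (cation/anion) current decomposition,
electroosmotic water flux, block-average and replica error bars, I–V
conductance fitting and electrolyte conductivity, cylindrical (r, z)
ion/water density maps with an L2 ensemble-comparison distance, and
viscosity/conductivity rescaling of transport estimates across force
fields and water models.

A built-in drift–diffusion generator produces synthetic trajectories
with closed-form expected currents, fluxes, conductivities and density
profiles, so the entire pipeline is verifiable without running MD.

## Units

Å / ps / elementary charge / mV internally; currents in nA
(1 e/ps = 160.2176634 nA), water flux in molecules/ns, conductance in
nS, conductivity in S/m. Positive current means net positive charge
moving toward +z (trans → cis with the default axis convention).

## CLI

```sh
# generate a synthetic run with known ground truth
poreflux simulate --spec spec.json --out-traj run.tsv \
    --out-particles particles.tsv --out-truth truth.tsv

# windowed ionic current (mean ± block error)
poreflux current --traj run.tsv --particles particles.tsv \
    --tau 20 --block 10000 --discard 10000 --species all

# electroosmotic flow
poreflux eof --traj run.tsv --particles particles.tsv

# conductivity from an I-V sweep manifest
poreflux conductivity --runs sweep.tsv --through-origin

# cylindrical density map / group comparison inputs
poreflux density --traj run.tsv --particles particles.tsv \
    --species cation --cell 1 --axis auto --out map.tsv

# viscosity/conductivity rescaling
poreflux rescale --mode eof --value 10 --error 1 --label OPC

# full manifest → aggregated report
poreflux run --manifest manifest.tsv --out report.tsv
```

Trajectories may be DCD, XTC, or the plain-TSV table dialect (one
`frame id x y z` row per particle per frame plus `#box` headers).
Particle tables are TSV with columns `id species charge`, species one
of `cation`, `anion`, `water_oxygen`, `other`.

## Layout

- `poreflux.core_io` — trajectory/particle-table types and readers/writers
- `poreflux.flux` — current & EOF estimators, block/replica errors, selectivity
- `poreflux.conductivity` — field–voltage relation, conductance fits, σ
- `poreflux.density` — 3-D binning, cylindrical maps, map distance, group stats
- `poreflux.rescale` — transport-constant rescaling and negligibility rule
- `poreflux.synthetic` — drift–diffusion generator with analytic ground truth
- `poreflux.pipeline` / `poreflux.cli` — manifest orchestration and CLI
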