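# memtide

Quantitative analysis toolkit for cationic peptide–anionic lipid bilayer
interactions: equilibrium binding isotherms, Gouy–Chapman–Stern (GCS)
membrane surface electrostatics with charge regulation, zeta-potential
conversions, isothermal titration calorimetry (ITC) thermodynamics,
fluorescence-derived membrane statistics, and a coupled-equilibrium model
of peptide-modulated Ca²⁺ accumulation at the membrane interface.

## Modules

| module | contents |
|---|---|
| `memtide.membranes` | lipid species, bilayer compositions, site areas, intrinsic surface charge density |
| `memtide.spectro` | blank subtraction, laurdan/prodan generalized polarization, anisotropy, Stern–Volmer, saturation fits |
| `memtide.binding` | single-site Langmuir quadratic (exact, no free≈total approximation), peptide/lipid titration fits, global salt-series fits, Scatchard transforms, partition coefficients |
| `memtide.gcs` | Debye constant, mixed-valence Grahame relation, Stern charge-regulation solver, peptide-modified surface charge with a −30 mV non-reversal floor, zeta ↔ surface-potential conversions, potential/ion profiles |
| `memtide.itc` | forward heat model with perfusion dilution, Wiseman-plot fitting, ΔG/ΔS decomposition |
| `memtide.calcium` | three-way Ca²⁺ mass balance among bulk, indicator and membrane interface (diffuse + Stern sequestration) |
| `memtide.synth` | seeded generators for every input the fitting modules consume |
| `memtide.cli` | YAML-config-driven command line (`memtide run config.yaml`) |

## Command line

Each task is driven by one YAML config and writes a self-describing JSON
report (parameters, standard errors, conventions, engaged model switches,
config echo):

```yaml
# gcs.yaml — surface potential and double-layer profile
task: gcs
membrane: {TOCL: 0.2, POPC: 0.8}
electrolyte:
  ions:
    - {name: K, valence: 1, conc: 0.02, stern_k: 0.6}
    - {name: Cl, valence: -1, conc: 0.02}
output_dir: out
```

```sh
memtide run gcs.yaml        # writes out/gcs.json and out/gcs_profile.csv
```

Tasks: `fit-isotherm`, `fit-itc`, `gcs`, `ca-sim`, `simulate`.
Titration CSVs use columns `titrant_conc` (M), `signal`, optional `blank`;
ITC CSVs use `injection_volume_uL`, `heat_uJ`.

## Conventions

- Only the outer vesicle leaflet binds peptide: effective lipid
  concentration is half the total.
- `n` is lipids per bound peptide; `K_D` the per-site dissociation
  constant; `n·K_D` the per-lipid-monomer constant.
- Partition coefficients are reported under an explicit convention
  (`site_free` or `water_normalized`, [W] = 55.3 M).
- ΔG uses the 1 M standard state.
- Default constants: T = 298.15 K, ε_r = 78.5, η = 0.89 mPa·s, shear
  plane at 2 Å, Stern constants 0.6 M⁻¹ (monovalent) / 12 M⁻¹ (Ca²⁺) —
  all overridable.
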