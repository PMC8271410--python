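# pbde-synergy

Toolkit for evaluating and improving the plant–microbe synergistic
degradation of PBDE-type pollutants in soil. It covers five analysis stages,
each usable as a library module or a CLI subcommand:

- **queuing scoring** (`pbde_synergy.queuing`): rank docking scores per
  endpoint (plant enzyme PS, microbial enzyme MS), map ranks linearly onto a
  0–100 single score, and combine them into a weighted composite synergy
  score (CS).
- **3D-QSAR** (`pbde_synergy.qsar`): CoMFA-style steric (Lennard-Jones) and
  electrostatic (Coulomb, ε(r)=r) probe fields on a lattice over aligned
  conformers, PLS regression with leave-one-out q², internal (R², SEE, F)
  and external (r²pred) validation, and steric/electrostatic field
  contribution fractions.
- **derivative screening** (`pbde_synergy.screening`): relative-change
  arithmetic, the strict all-models-improved functional screen, the
  environmental screen (C–Br bond enthalpy, EC50, logBCF, vapor pressure),
  and bond-dissociation-enthalpy bookkeeping.
- **DOE screening** (`pbde_synergy.doe`): Taguchi L12 (Plackett–Burman) and
  full-factorial designs, larger-the-better SNR factor effects and rankings,
  and binding-energy scheme evaluation with synergy averages.
- **binding analysis** (`pbde_synergy.binding`): contact-distance
  statistics, halogen-bond counts, hydrophobic-residue fractions, and
  MM/PBSA-style energy-ledger arithmetic.

Seeded synthetic-data generators (`pbde_synergy.simulate`) provide
statistically structured inputs for every stage, so the whole pipeline is
testable offline. The published worked-example tables ship as plain-CSV
fixtures under `pbde_synergy/data/`.

## CLI

The `synergy` entry point exposes one subcommand per stage:

```sh
# composite synergy scores from a molecule_id,PS,MS table
synergy score --in scores.csv --weight-mode own --ties average --out cs.csv

# derivative screening against the template molecule
synergy screen --predictions table3_predictions.csv --env table4_env.csv

# factorial regulatory-scheme evaluation (prints the best scheme)
synergy doe-factorial --responses table6_responses.csv

# Taguchi L12 SNR factor effects per system
synergy doe-taguchi --factors 11 --responses responses.csv

# contact statistics and mean bond-length change
synergy bonds --in interactions.csv --compare BDEs-3:BDEs-3-19

# field-based QSAR from per-atom CSV structures (element,x,y,z,charge)
synergy qsar-fit --structures structures/ --activity cs.csv --seed 1
synergy qsar-predict --model model.json --structures new_structures/

# synthetic inputs
synergy simulate scores --seed 7 --out synthetic/

# run the configured stages end to end
synergy run --config cfg.yaml
```

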