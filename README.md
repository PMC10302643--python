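# kinetree

Rate-constant prediction for Pd-catalyzed Sonogashira couplings of aryl
bromides, built around a mechanism-informed decomposition of the activation
free energy and a tree-structured topological descriptor for phosphine
ligands.

## Who this is for

Chemists and cheminformaticians studying ligand effects in cross-coupling
catalysis who have a *small* table of measured rate constants (hundreds of
reactions, not hundreds of thousands) for combinations of trialkyl/arylalkyl
phosphines and substituted aryl bromides, and who want both predictions and
mechanistic insight into the rate-limiting oxidative addition (OA) step.

## The model

Each reaction's rate constant k interconverts with an activation free
energy through the Eyring equation,

    k = (k_B T / h) · exp(−ΔG‡ / RT),        ΔG‡ in kcal/mol,

and the barrier is modelled as a sum of two non-negative parts,

    ΔG‡ = ΔG‡(L) + ΔG‡(L-S),

where ΔG‡(L) depends on the **ligand only** (the steric contribution of the
phosphine — bulky ligands accelerate OA) and ΔG‡(L-S) couples **ligand and
substrate** (the cooperative term, which falls as the aryl bromide becomes
more electron-poor).

* **Ligands** are encoded as P-rooted trees: carbon atoms are nodes,
  stratified into layers by bond distance from phosphorus, sibling branches
  ordered by CIP-style priorities, ring closures kept as extra edges with
  bond orders (1 / 1.5 / 2). Every ligand maps into a frozen slot template so
  all encodings have equal length. A scalar-state message-passing network
  (shared bias-free weights, LeakyReLU 0.01, 3–5 iterations) turns the
  aligned graph into the GNN output vector.
* **Substrates** are 2-element Hammett vectors (σ_meta, σ_para) looked up
  from a bundled Hansch–Leo–Taft σ table; the unsubstituted position is 0.
* Two single-unit sigmoid heads (no bias, L2-regularized; the ligand head
  and the final combination weights constrained non-negative) produce the
  two energy components.

Training is two-staged: first the net regresses Eyring-converted energies
(MAE loss) until a batch loss falls under a 5–7 kcal/mol cutoff, then it
fine-tunes directly against rate constants. Runs whose batch losses
oscillate are rejected; the up-to-10 surviving runs with the highest
validation R² (and validation MAE under threshold) form an ensemble whose
averaged prediction is the model output.

## Worked example

```
kinetree simulate --n-ligands 17 --seed 7 --out-dir demo
kinetree train --reactions demo/reactions.csv --ligands demo/ligands.json \
               --trials 30 --max-epochs 600 --seed 7 --out-dir demo/run
```

which prints (340 synthetic reactions; ~2–3 min on one CPU):

```
wrote 340 reactions for 17 ligands to demo
10 ensemble members; held-out test R^2 = 0.991; artifacts in demo/run
```

`demo/run/predictions.csv` holds per-reaction ensemble means of dG_L,
dG_LS, dG_total (kcal/mol) and k_pred; `demo/run/ligand_dG_L_summary.csv`
is the per-ligand boxplot summary (min/q1/median/q3/max of the fitted
ligand barrier across ensemble members, sorted by median) — in a healthy
fit the median falls as the ligand gets bulkier. Other commands: `encode`,
`cv` (fixed-test-fold 5-fold cross-validation), `tune` (random grid
search), `predict`, `baseline` (one-hot / fingerprint / user-supplied
buried-volume & cone-angle descriptors, through the same heads with the
GNN removed, or through a non-negative zero-intercept linear regression),
`report`.

The library mirrors the CLI: `build_tree` / `canonicalize` /
`encode_graph`, `encode_substrate`, `run_mpnn`, `forward` /
`eyring_rate_from_energy`, `train_two_stage` / `select_and_ensemble` /
`cross_validate`, `generate_ligand_set` / `generate_reaction_dataset`.

## Layout

```
src/kinetree/
  ligand_tree.py   tree build/canonicalize/template/encode (+ SMILES opt-in)
  substrate.py     Hammett table & 2-element substrate vectors
  mpnn.py          message passing + hand-derived reverse pass
  energy.py        decomposed energy head, Eyring conversions
  training.py      two-stage protocol, termination, ensembling, CV, tuning
  baselines.py     descriptor swaps & non-negative linear regression
  synthetic.py     study-condition generator with recorded ground truth
  experiments.py   end-to-end parameter-recovery experiment
  io.py / cli.py   tables, reports, command-line interface
  data/            Hammett σ CSV, 9 reference phosphine tree-specs
```
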