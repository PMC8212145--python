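# pathcause

Causal pathway extraction from (phospho)proteomic profiles.

Cell-signaling knowledge bases curate hundreds of thousands of mechanisms —
kinase–substrate phosphorylations, phosphatase actions, transcription-factor
regulation — but for any one experiment only a small subset of them is
active. `pathcause` takes a signed, site-annotated **prior network** of such
relations plus a normalized proteomic data table and identifies the priors
whose direction logic is consistent with the observed changes (a
test-vs-control comparison) or pairwise correlations (an uncontrolled
cohort, as is common in cancer proteomics). Each hit is a concrete,
falsifiable *causal conjecture*: "the change in this upstream feature can
explain the change in that downstream feature through this curated
mechanism." Permutation tests then ask whether the data align with the
priors more than chance (network-size test) and which proteins explain more
downstream targets than chance (downstream-size test).

It is a library first (with a synthetic-data module so every stage is
testable offline), plus a thin `pathcause` command for running a configured
analysis end to end.

## The sign logic

Every quantity is ternary — `true`, `false`, or `unknown`. A prior relation
with sign *s* (true for phosphorylation and expression upregulation, false
for dephosphorylation and downregulation) explains a feature pair when the
parity equation holds:

* comparison setting: `c_source ⊕ e_source ⊕ s ⊕ ¬c_target = true`
* correlation setting: `corr(source, target) ⊕ e_source ⊕ s = true`

where `⊕` is ternary XOR, `c` is a feature's change direction (up/down, or
`unknown` when insignificant after Benjamini–Hochberg FDR control), `corr`
is the sign of a significant pairwise correlation, and `e` is the effect of
the source feature on its protein's activity — `true` for total protein or
an activating phosphosite, `false` for an inhibiting site, `unknown` for an
uncurated one. Any `unknown` operand vetoes the explanation. Structural
constraints apply first: phospho relations may only explain phosphosite
features on matching sites (with an optional ±2-residue tolerance for
shifted literature coordinates), expression relations only total-protein
(optionally RNA) features; sources must be protein-level evidence.
Unmeasured perturbations — ligand stimulation, drug-target inhibition — can
be injected as *activity hypotheses* with a fixed direction.

## Worked example

`examples/comparison_analysis.py` builds a two-relation cascade
(ligand → receptor → adaptor), a six-sample table where the receptor site
Y1068 and adaptor site Y406 rise after stimulation, and injects the
unmeasured ligand as an activation hypothesis:

```
accepted relations: 2
  EGF -phosphorylates-> EGFR @ Y1068 (source effect: true)
  EGFR -phosphorylates-> GAB1 @ Y406 (source effect: true)
```

Both priors are accepted because every parity term is determined and
consistent: the active ligand explains the receptor-site increase, and the
activating receptor site explains the adaptor-site increase.

`examples/correlation_cohort.py` runs the cohort setting at realistic scale
(50 proteins, 122 prior relations, 27 planted with latent correlation 0.8
across 100 samples, 10% missing values) and scores recovery against the
generator's ground truth:

```
prior relations: 122  planted: 27
accepted relations: 27
precision: 1.000  recall: 1.000
network-size permutation p (1000 permutations): 0.000999
```

The permutation p-value sits at its floor of 1/1001: label randomization
never reproduces the observed network size.

`examples/precision_validation.py` computes the three precision estimators
over 32 inhibitor-validation cases (29 changed in the expected direction, 3
contrary; 19 significant at 0.1 FDR, 18 of them expected):

```
naive precision:            0.91  (29/32)
significant-only precision: 0.56  (18/32)
noise-adjusted precision:   0.81  (26/32 after symmetric-noise correction)
```

## Command-line use

```
pathcause parameters.txt [-o OUTPUT_DIR]
```

The parameters file is flat `key = value` lines (repeat `test-column`,
`control-column`, `hypothesis-activated`, … for lists); unknown keys are
errors. Outputs are `results.sif` (one accepted relation per line),
`results.json` (conjecture-level evidence plus significance),
`report.txt` and `run.log`.

## Layout

- `src/pathcause/priors.py` — prior network + site-effect library I/O,
  neighborhood restriction
- `src/pathcause/dataset.py` — proteomic tables, change/correlation
  assessments, BH FDR, activity hypotheses
- `src/pathcause/ternary.py`, `engine.py` — the sign logic and network
  assembly
- `src/pathcause/significance.py` — label-permutation tests
- `src/pathcause/results.py`, `config.py`, `cli.py` — serialization,
  recurrence ranking, precision estimators, configuration, CLI
- `src/pathcause/synthetic.py` — generators with planted ground truth
- `docs/methods.md` — models, assumptions, numerical choices, limitations
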