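# idrscape

Classification of intrinsic disorder in ribonucleoprotein (RNP)
proteomes — built around the kind of annotation scheme used for the
human spliceosomal proteome, where roughly half of the combined protein
sequence is predicted to be intrinsically disordered and the disorder
falls into functionally distinct classes.

`idrscape` is for structural bioinformaticians who already have
per-residue predictions (disorder probability, secondary structure,
coiled-coil, burial, homology support) from their favourite external
predictors and want a reproducible, tested pipeline that turns those
tracks plus sequences into a region-level annotation:

* **consensus segmentation** — a residue is disordered iff a strict
  majority of disorder predictors call it disordered; a deterministic
  *globular override* flips long disordered windows that are mostly
  buried, mostly covered by secondary structure and homology-supported;
* **disorder with secondary structure (SS)** — SS elements inside an
  intrinsically disordered region (IDR) whose connecting loops are
  < 20 residues merge into one disorder-with-SS region (a coiled-coil
  subclass when helices overlap coiled-coil consensus);
* **compositionally biased IDR subclasses** — SS-free stretches of
  ≥ 25 residues are tested for compositional bias (some residue with
  frequency > 20 % or > 5× its vertebrate background; overrepresented
  residues are those > 20 % or > 3× background) and assigned, in
  specific-to-generic precedence, to RS-like, hnRNP-like G-rich
  (short ≤ 100 / long > 100 residues), poly-P/Q, charged (RKDE) or
  noncharged (PQMGVWA) classes;
* **linear motifs** — ULM (`[RK]{1,}[RK]x{0,1}[RK]{1,}x{0,1}Wx{0,2}[DE]{1,}`),
  two G-rich repeat patterns (`[RSY]GG-x{1,50}-[RSY]GG-x{1,50}-[RSY]GG`
  and `R[AGT][AGTFIVR]-x{1,25}-RGG-x{1,25}-R[AGT][AGTFIVR]`) and P/Q
  runs, reported non-overlapping leftmost-then-longest with disorder
  context;
* **PTM mapping** — modification sites counted per (modification type ×
  region class), with share and length-normalised enrichment statistics;
* **proteome statistics** — per-residue and per-protein disorder means,
  IDR length counts (≥ 30 / ≥ 70 residues), SS-disorder share, and
  RNA/protein mass fractions with stoichiometric copy numbers;
* **synthetic proteomes** — a seeded generator that plants region
  classes, predictor tracks with tunable error rate ε, and
  class-enriched PTM sites, so the entire pipeline is testable end to
  end with known ground truth.

## Worked example

```python
from idrscape.synthetic import SyntheticConfig, generate_proteome, evaluate_recovery
from idrscape.pipeline import analyze

cfg = SyntheticConfig(n_proteins=50, epsilon=0.0, seed=7)
proteins, tracks, sites, truth = generate_proteome(cfg)
result = analyze(proteins, tracks, sites)
report = evaluate_recovery(result.regions, truth)
print(f"residue accuracy: {report.accuracy}")
print(result.count_table["total"].to_dict())
```

prints

```
residue accuracy: 1.0
{'phosphorylation': 211, 'lysine_N_acetylation': 45, 'other_N_acetylation': 7,
 'arginine_methylation': 54, 'lysine_methylation': 5, 'cysteine_methyl_ester': 0}
```

With error-free tracks the pipeline recovers every planted region class
exactly (accuracy 1.0 over all residues), and the PTM count table's
grand total equals the number of planted sites — phosphorylation
dominates because it is planted preferentially on S/T/Y in RS-like
segments, and arginine methylation clusters in G-rich segments.

The same analysis is available from the shell:

```bash
idrscape simulate --seed 7 --n-proteins 50 --out sim/
idrscape run config.yaml        # or: validate / segment / classify / scan / map-ptms / stats
```

where `config.yaml` names the FASTA, track TSV and optional PTM/metadata
tables plus any threshold overrides (see `idrscape.pipeline.DEFAULT_PARAMS`).

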