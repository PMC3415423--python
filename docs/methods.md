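# Methods

## The annotation model

`idrscape` annotates a proteome at residue resolution in three layers.

**Consensus.** The pipeline never runs a disorder predictor itself; it
consumes per-residue tracks from any external ensemble. Probability
tracks are binarised at `disorder_cutoff` (default 0.5, a value ≥ the
cutoff counts as a disorder call) and a residue is called disordered iff
*strictly more than half* of the disorder predictors agree. Ties
therefore fall to order. This is the conservative reading of
majority-vote consensus; it biases the annotation toward order in the
same direction as the globular override below, so borderline residues
are not inflated into disorder. Secondary-structure labels take the
plurality over SS tracks (ties break to coil `C`); coiled-coil calls
take a strict majority of coiled-coil tracks.

**Globular override.** Expert curation of disorder predictions commonly
reclassifies windows that every structural signal says are globular.
The package recasts that judgement as a deterministic rule: a maximal
disordered run of at least `min_window` residues (default 30) is flipped
to order when (i) at least `burial_frac` of its residues are predicted
buried (default 0.5 — the operationalisation of "a high fraction"),
(ii) SS consensus covers at least half of the window, and (iii) every
residue carries homology support to known globular structures. When no
homology track is supplied the condition can be waived by config
(`override.require_homology: false`); by default an absent track means
no flips, never a silent waiver. The rule is idempotent. The two
thresholds are configuration, not inferred fact: the source curation was
qualitative and any quantitative surrogate is a design choice.

**Segmentation and classes.** Maximal disordered runs become IDRs.
Inside each IDR, helices of ≥ `min_helix` (4) and strands of ≥
`min_strand` (3) consensus residues are detected; elements separated by
loops shorter than `merge_gap` (20, strict) cluster together, and each
cluster's *span* — first element start to last element end — becomes one
disorder-with-SS region (`disorder_with_coiled_coil` when a helix in the
cluster overlaps coiled-coil consensus). Only the span is claimed, so
long SS-free flanks remain available to the composition classifier;
SS and compositionally biased regions are disjoint classes by design.
The element minima follow standard secondary-structure conventions (one
helical turn; the shortest β-strand that pairs).

SS-free stretches are classified by composition. A stretch is *biased*
when some residue type has frequency > 20 % or > 5× its vertebrate
background; *overrepresented* residues are those with frequency > 20 %
or > 3× background. `X` residues are excluded from numerator and
denominator. Stretches shorter than 25 residues, or without bias, are
`other_disorder`. Biased stretches are assigned by the first matching
rule:

1. **RS-like** — both R and S overrepresented;
2. **hnRNP-like G-rich** — G-rich repeat patterns (`[RSY]GG…` or
   `R[AGT][AGTFIVR]…RGG…`) cover at least half the stretch
   (`grich_cover`, default 0.5 — the source description is qualitative,
   so density is exposed as config); `short` iff ≤ 100 residues, else
   `long`;
3. **poly-P/Q** — no charged residue (RKDE) overrepresented and the
   stretch contains a {P,Q}-run of ≥ 3 (joint-alphabet reading, so
   `PQP` counts; a config switch restricts to homopolymer runs);
4. **charged** — overrepresented set ⊆ {R,K,D,E};
5. **noncharged** — overrepresented set ⊆ {P,Q,M,G,V,W,A};
6. otherwise `other_disorder`.

Precedence runs specific → generic because the named classes carry
functional meaning (RS domains, RGG boxes, polyproline ligands) while
charged/noncharged are catch-alls; a stretch that satisfies both the RS
and the charged rule is RS-like. The literature this scheme follows
never states a tie-break, so the order is a declared design decision.

The background frequency table ships as a packaged default (vertebrate
average composition after King & Jukes, normalised to sum to 1). The
original source table is no longer online; the packaged values are a
documented default replaceable via a two-column TSV, not ground truth.

## Motif scanning

Patterns are matched with non-overlapping, leftmost-then-longest
(POSIX-style) semantics: at the leftmost start with any match the
longest match is taken and scanning resumes after its end. Python's
backtracking `re` engine returns leftmost-*greedy* matches, which is not
the same thing, so the scanner explicitly probes for the longest end at
each start. A brute-force oracle that tests every substring against the
pattern grammar backs the scanner in the test suite; an
overlap-permitting mode exists for sensitivity analysis. Two ULM
variants are provided: the stringent consensus (default, chosen to limit
false positives) and the more lenient literature pattern
(`ULM_LENIENT`). Matches are annotated `disordered` / `ordered` /
`mixed` against the region tiling.

## PTM mapping and statistics

Sites are validated against the sequence (position in range, residue
identity) and counted into a modification-type × region-class matrix;
the coiled-coil subclass folds into the disorder-with-SS column.
Different modifications at the same residue are distinct records.
Sites whose annotation status is "by similarity" or
"potential/probable" are kept by default (removing them is a flag;
in the data this scheme was built for it does not change the overall
statistics). Share statistics are exact internally and rounded to one
decimal only for display. Enrichment is site share divided by length
share of the class.

Proteome statistics keep the two averaging conventions separate:
per-residue (disordered residues over total length — length-weighted)
and per-protein (mean of per-protein fractions). For IDR length
statistics an IDR is a maximal run of non-ordered residues, merging
contiguous disorder regions of different classes, because segment
lengths logically precede classification; the mean IDR length averages
over IDRs (not proteins), and a proteome with no IDRs reports mean 0
with an explicit `n_idrs = 0` rather than NaN. Mass fractions use
packaged average residue masses (Da, residue = monomer − water) and an
average RNA nucleotide mass of 321 Da; copy numbers weight every chain,
so stoichiometric repeats (e.g. the seven-membered ring proteins shared
across snRNP subunits) count each copy toward complex weight, while
disorder-content statistics count each distinct protein once.

## The synthetic generator

The generator emulates the *structure* of an RNP proteome annotation
problem, not protein evolution. Proteins alternate ordered segments
(30–80 residues) with 1–3 disordered segments (30–120 residues) whose
classes are drawn from a weight table covering all seven disorder
classes. Composition models are class-specific (e.g. RS segments are
35 % R / 35 % S; G-rich segments are built from `RGG` + short
G/Y/A/N/F spacers; poly-P/Q segments carry a planted 4-residue P/Q run).
Every biased segment is rejection-sampled until its sequence satisfies
its class's defining thresholds, and every "other disorder" segment
until it is verifiably unbiased — the planted truth is valid by
construction for any seed. Disorder-with-SS segments plant 6-residue
helices every 18 residues with forced coverage of both segment ends, so
the SS-cluster span reproduces the segment exactly.

Predictor tracks equal the truth with independent per-residue errors at
rate ε ∈ [0, 0.5): disorder and coiled-coil calls flip; SS labels are
replaced by one of the other two labels. Independence across residues
and predictors is the simplest model under which majority voting is
analyzable — the consensus error per residue is the upper tail of
Binomial(K, ε). Burial and homology tracks are noise-free complements
of the truth. PTM sites are planted only on chemically compatible
residues (phospho → S/T/Y, acetylation/lysine methylation → K, arginine
methylation → R, cysteine methyl ester → C, N-terminal acetylation →
position 1 if in MGASTV), with phosphorylation enriched in RS-like and
arginine methylation in G-rich segments; ~93 % of sites are
"experimental", the rest "by similarity" or "potential".

What passing tests show — and do not show. Noise-free recovery at
accuracy 1.0 demonstrates that the classification rules are mutually
consistent and the segment boundaries are sharp; it does not show that
real predictor ensembles, whose errors are strongly correlated along
the sequence and between methods, would be recovered equally well. The
monotonicity suite (accuracy at ε = 0.1 exceeds ε = 0.3 over 10 seeds,
one-sided sign test) checks graceful degradation under the independence
assumption only.

## Numerical and procedural choices

* Coordinates are 1-based inclusive throughout; conversion to Python
  slices happens only at the boundary (`records.to_slice`).
* Threshold comparisons are strict (`>` 20 %, `>` fold × background;
  loops `<` 20 merge; override windows `≥` 30), matching the wording of
  the criteria they implement; the ≥ 25 gate is inclusive.
* Degenerate inputs: an all-`X` stretch has no composition signal and
  falls to `other_disorder`; empty groups, zero grand totals and zero
  total masses raise typed `ValidationError`s rather than returning
  NaN.
* Determinism: region output is sorted by (protein, start) and
  independent of input order; the generator is byte-stable given
  (config, seed).
* Problem sizes in the test and acceptance suites (50-protein noise-free
  proteomes, 10-seed noise sweeps, 1,000 random 200-mers plus exhaustive
  enumeration of 6-letter pattern-alphabet strings to length 7 for the
  scanner oracle) were chosen to exercise every rule path at tight
  runtime; the statistics they compute are reported by
  `scripts/acceptance.py` at run time.

## Known limitations

* The pipeline consumes predictor tracks; adapters from native predictor
  output formats are the user's responsibility.
* The globular override is a deterministic surrogate for what is, in
  practice, expert judgement; its thresholds have no claim to being the
  curators' implicit values.
* Classification applies to whole SS-free stretches, not sliding
  windows; a long stretch with two different biased halves is assigned
  a single class by the precedence rules.
* G-rich region boundaries are the stretch boundaries, not the raw
  pattern span.
* The synthetic generator does not model correlated predictor errors,
  sequence conservation, or realistic length distributions beyond the
  configured ranges.
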