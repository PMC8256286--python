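# Methods

## The screen

The screen model treats candidate discovery as a filtered differential
abundance problem. Input is a MaxQuant proteinGroups table of label-free
quantification (LFQ) intensities with a fixed design: three wild-type
replicates and, per C-mannosyltransferase knockout, two independent clones of
three replicates each (pooled to n = 6 per knockout). Zeros in the table are
treated as missing — MaxQuant writes 0 for proteins it could not quantify in
a run.

Filters are applied sequentially and their counts reported: decoy removal
(contaminant, reverse, only-identified-by-site), the extracellular
compartment filter (any group member annotated with one of the GO-CC slim
terms *extracellular matrix*, *extracellular region*, *extracellular space*;
accessions without annotation are conservatively treated as not
extracellular and tallied), and an identification filter (≥ 2 peptides and
detection in ≥ 2 WT replicates or in ≥ 1 replicate of each clone of the same
knockout). The report's counts are non-increasing by construction; the
"detected in all cell lines" count additionally requires ≥ 1 detection in WT
and in each individual clone.

### Imputation

Missingness in LFQ data is abundance-dependent (missing not at random): low
abundance proteins drop below the detection limit. After log2
transformation, each missing cell in sample column *c* is drawn from

  N(μ_c − downshift·σ_c, (width·σ_c)²),

with μ_c, σ_c the mean and SD (ddof = 1) of the observed values of that
column, width = 0.3 and downshift = 1.8 by default, separately per column.
This mimics the established practice for secretome screens of this layout.
The generator seed is a mandatory, recorded parameter; identical seeds give
byte-identical outputs. A column with fewer than two observed values cannot
define the distribution and raises an error naming the column, rather than
guessing.

Imputation is applied after filtering. Imputing before restriction to the
extracellular set would draw from slightly different column moments; the
package fixes the filter-then-impute order and records it in the output
provenance.

### Testing

Each knockout group is compared to WT by a row-wise **equal-variance
(Student) two-sample t-test**, two-sided, on the imputed log2 matrix. (A
Perseus-style S0 moderation constant of zero reduces that statistic to the
plain t, which is what is implemented; Welch is available via
`equal_var=False`.) Fold change is mean(KO) − mean(WT) in log2. Significance
is thresholded at raw p ≤ 0.05 with **no multiple-testing correction** by
default — the screen is a candidate generator, not a confirmatory analysis —
and the per-protein p-values are exposed so Benjamini–Hochberg can be applied
downstream if desired. Degenerate rows (zero variance on both sides) get
p = 1 when the means are equal and the smallest positive float otherwise, so
p ∈ (0, 1] always holds. Per-clone fold changes against the WT mean, and
their per-knockout means, are computed for display of individual samples.

### Candidates and enrichment

The motif call is group-level with **any-member semantics**: a protein group
is motif-positive if any member with an available sequence contains a
WxxW/WxxC window. Members without a sequence are recorded as unresolved —
absence of a sequence is never evidence of absence of a motif, and a group
with only unresolved members has an *unknown* (not negative) call and is
excluded from the motif-positive set. Candidates are significant ∩
motif-positive per knockout, plus their union.

Domain enrichment uses the one-sided Fisher exact test, computed as the
hypergeometric survival function P[X ≥ k] of the 2×2 table
(k, n−k, K−k, N−n−K+k) where n is the candidate-set size and N the filtered
background size. One-sided is the default because the question is
enrichment; a two-sided flag exists. Domains absent from the foreground are
skipped. The background rescreen simply returns every background group with
≥ 1 member carrying the requested domain (default TSP_1), to surface
domain-bearing proteins the significance screen missed.

## Motif scanning

Positions are 1-based. A consensus site is W at position i with W or C at
i + 3; "x" is any residue, including W or C, and overlapping sites are all
reported — in the TSR ladder WxxWxxWxxC the three sites overlap by
construction (W1 and W2 as WxxW, W3 as WxxC). Windows containing
non-standard letters (X, U, B, Z, gaps, stops) never match; this is the
conservative choice for ambiguous sequence.

## Glycopeptide arithmetic

Monoisotopic constants: hexose 162.05282 Da, deoxyhexose (fucose)
146.05791 Da, glucose = hexose, water 18.010565 Da, proton 1.007276 Da,
carbamidomethyl (fixed on Cys by default) 57.02146 Da. Residue masses come
from the standard monoisotopic table. The number of C-mannosylatable
tryptophans of a peptide is caller-specified rather than inferred from the
peptide sequence, because consensus context can extend beyond a proteolytic
peptide's boundaries (a WxxC whose C lies in the next peptide).

Glycoform ladders enumerate Hex 0…n crossed with the fucosyl states
(none, Fuc, Fuc–Glc) available to the peptide, in a fixed order. Fragment
ions are singly protonated b/y; C-mannose is treated as non-labile, so a
glycan's mass is carried by every fragment containing its residue. The
ladder runs to index n − 1 (the full-length b/y ions are not emitted);
higher product charges are out of the default scope.

EIC extraction sums centroid intensities within an **absolute** tolerance
(default 0.3 Da) of the target m/z, one point per MS1 scan. Absolute Da
matches the behaviour of vendor mass-chromatogram tools at this resolution;
a ppm mode would suit high-resolution data but is not the default.
Glycoform quantification reports each species' EIC apex (max point; an
integrated-area flag exists) normalised to the most intense species, plus
the absolute maximum — the display convention for glycoform ladder panels.
Optional Savitzky–Golay smoothing (window 7, order 2) can be applied before
apex picking; it is off by default because the synthetic traces are already
smooth. Isotope envelopes are not modelled; annotation is by monoisotopic
centroid.

## MRM enumeration

All precursor charges 2–4 crossed with all singly charged b/y products,
filtered to the instrument window (default 250–1250 m/z). Product ions
default to charge 1+ — standard practice on QTrap-class instruments and the
parsimonious reading of "all b and y ions". Glycan-bearing product ions are
available behind a flag when the hexose positions are supplied. Collision
energies are linear seeds CE = a·(m/z) + b per precursor charge
(a, b) = (0.050, 5.0), (0.040, 4.0), (0.035, 3.0) for 2+/3+/4+ — values in
the QTrap range, monotone in charge, and explicitly meant to be overridden
per transition after empirical optimisation. Scheduling centres a 300-s
window (1.8-s target scan time) on each transition's expected RT; RT
calibration itself (e.g. against indexed-RT standards) is out of scope and
expected RTs are caller-supplied.

## Synthetic data

`simulate_protein_db` draws sequences of length 100–800 over an alphabet
**without W and C**, then plants WxxW, WxxC or full TSR windows (filler
residues also W/C-free, plantings ≥ 4 residues apart), so the planted sites
are provably the only consensus sites — truth is exact, not re-scanned.
Disabling depletion allows spurious sites for robustness testing.

`simulate_lfq_experiment` emulates the screen's study conditions: base log2
abundance ~ N(25, 2²) (typical LFQ magnitudes), replicate noise N(0, 0.5²),
the WT(3) + 2 knockouts × 2 clones × 3 layout, a −1.5 log2 effect planted on
20 of 400 proteins by default (each affected protein assigned to one
knockout, or both with probability 0.2, biased toward TSP_1-bearing motif
proteins so domain enrichment is recoverable), decoy rows injected, and
missingness P(missing | x) = logistic((22 − x)/1) of the underlying log2
value. Under these defaults the realised missingness is ≈ 8–14% overall and
concentrated on low-abundance cells, the regime where left-shifted
imputation is standard. What the generator does **not** emulate: correlated
protein co-regulation, batch/run-order effects, peptide-level variation
feeding protein inference, compositional (normalisation) artefacts, or
heavy-tailed noise. Passing recovery tests therefore shows the statistical
chain is correct under its own model assumptions, not that real secretomes
meet those assumptions.

`simulate_ms1_run` places one Gaussian elution profile per glycoform
(centroid exactly at the species m/z) on a fixed scan cadence (3 s), plus a
uniform noise floor at base/SNR; species with m/z within 0.6 Da are flagged
as overlapping in the truth record. All generators are pure functions of
(parameters, seed).

## Problem sizes and tolerances

The test-suite and acceptance-script simulations use 400 proteins × 15
samples and 50 seeds for the seed-median properties, 1000 random sequences
(length ≤ 500) for the motif oracle, 10⁴ draws for the imputation moments,
and 50 random peptides for the MRM oracle; these sizes give stable medians
while keeping the whole suite fast. Mass identities are asserted to 1e−9 Da
(implementation-internal) or ~1e−3 Da against the independently frozen
residue table (whose values differ from the implementation's table in the
fifth decimal); the Fisher/hypergeometric agreement is asserted to 1e−12.

## Known limitations

- No peptide-to-protein inference or FDR machinery: the package consumes an
  upstream search engine's protein groups as given.
- The motif scanner predicts consensus presence, not actual modification;
  structure-based TSR detection is out of scope.
- EIC quantification assumes centroided MS1 and resolves species only by
  m/z and RT; co-eluting isobaric glycoforms are not deconvolved.
- The imputation model is the screen's convention, not an inferential model
  of the dropout process; its parameters (0.3/1.8) are conventions, and
  conclusions sensitive to them should be checked at other settings.
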