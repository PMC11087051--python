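# Methods

`peptidergic` implements the in-silico core of a neuropeptide–GPCR
deorphanization workflow: mining mature peptides from precursor proteins,
corroborating them by mass matching, characterizing receptor–peptide pairs
pharmacologically, and assembling a cell-type signaling network. This note
documents the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic data do and do not establish.

## Cleavage grammar and peptide maturation

Proneuropeptide precursors are processed by prohormone convertases at basic
sites and finished by carboxypeptidase trimming, glycine-derived
C-terminal amidation and N-terminal pyroglutamate formation. The grammar
(`peptidergic.mining`) recognizes:

- **Dibasic sites** — any maximal run of ≥ 2 basic residues (K/R in any
  combination). The whole run is treated as linker and removed; the site is
  labeled by its first two residues. Treating the run as one site is the
  tie-break for overlapping motifs such as KRR.
- **Monobasic Rxx-R sites** — a lone R at the cut with a second R three
  positions upstream. The supporting R must not itself belong to a dibasic
  site; without this restriction the R inside e.g. `KR|GPRGG` would
  spuriously license a cut inside a PRGamide-style tetrapeptide.
- **Acidic two-residue flanks** (EE/DD/ED/DE) — accepted as cuts only when
  the downstream peptide starts with Q or carries a proline at position 2
  or 3. Whether acidic flanks cut *unconditionally* is genuinely open;
  `CleavageRuleSet(acidic_alone=True)` switches the permissive reading on.
- **Peptide-initial cues** — an N-terminal Q, or P at position 2 (xP) or 3
  (xxP), supported by an acidic residue 1–2 positions upstream. These add
  *alternative* N-terminal cuts inside a segment, producing overlapping
  shorter versions of the same peptide (stepwise processing). The acidic
  support is required by default (`require_acidic_support`) because an
  ungated reading would cut at every internal Q/P.

Maturation (`apply_maturation`): a trailing G followed by a basic residue
(GR/GK amide-donor motif) becomes a C-terminal amide (G removed, −0.98 Da);
an N-terminal Q cyclizes to pyroglutamate (−17.03 Da). E-pyroglutamate
(−18.01 Da) is opt-in since Q is the overwhelmingly common case.
Coordinates are 0-based half-open throughout; `precursor[start:end]` always
reproduces the raw (pre-maturation) segment.

The signal-peptide boundary is consumed as an annotation (TSV id→index);
signal-peptide *prediction* is out of scope. Peptides are kept at matured
lengths 3–50 by default — most mature neuropeptides are 3–20 residues, and
the generous upper bound costs nothing. Each peptide carries a
site-confidence tier (`dibasic` / `monobasic` / `acidic/Q` / `proline` /
`signal-edge`) because non-dibasic evidence is weaker than a convertase
consensus site.

## Masses, ion ladders and identification triage

Neutral monoisotopic masses are the exchange currency (upstream charge
deconvolution is assumed). Residue masses come from pyteomics; water is
18.010565 Da and the proton 1.007276 Da. Modification deltas at full
precision: pyroGlu-Q −17.026549, pyroGlu-E −18.010565, amidation −0.984016,
half-cystine −1.007825, Met-oxidation +15.994915 Da — full precision
matters because 5 ppm at 1 kDa is 0.005 Da. Intact-mass matching uses a
5 ppm default tolerance; fragments 0.02 Da.

b ions are cumulative N-terminal residue sums + proton (pyroGlu applied);
y ions cumulative C-terminal sums + water + proton (amidation applied).
Internal modifications shift only the intact mass. Ladder evidence is
scored on the *merged* b/y series: residue junction *j* is resolved when
either b_j or y_(n−j) is observed within the fragment tolerance. Whether
gap counting should instead be per-series is unstated in common practice;
merged is the default here and the statistics are exposed so a per-series
policy can be layered on. `max_gap` (longest run of unresolved junctions)
drives the triage: ≤ 2 with no caveats → *confident*; exactly 3, or a
signal-peptide overlap, disulfide, or suspected-intermediate flag →
*uncertain*; > 3 or low-intensity evidence → *poor*. Low intensity is an
input flag on the peak, not computed — intensity models are
instrument-specific.

## Receptor candidate filters

`count_tm_segments` is an explicit hydropathy stand-in for a dedicated
topology predictor: Kyte–Doolittle window means (window 19, threshold 1.6),
maximal supra-threshold runs merged when closer than 3 residues. External
TM annotations override it. Candidates are kept with 4–9 predicted TM
segments — tolerant of truncated or over-predicted 7-TM models.
`reduce_redundancy` is a greedy longest-first clusterer over full
dynamic-programming global-alignment identity (matches / alignment
length); exact identity is affordable at candidate-set sizes and avoids
the approximations of k-mer screens. Thresholds 0.85 (transcript
collapsing) and 0.95 (protein redundancy) are both in common use; the
threshold is a parameter.

## Dose-response model and fitting

The four-parameter log-logistic (LL.4) model is

    f(x) = c + (d − c) / (1 + exp(b (ln x − ln e)))

with lower/upper asymptotes c, d, Hill slope b and EC50 e (molar). In this
convention an increasing agonist curve has b < 0; `hill_slope` is reported
as |b| to match the positive slopes conventionally printed. The synthetic
plate generator uses the positive-slope (increasing) convention and 10
log-spaced concentrations from 1e-13 to 1e-4 M with 9 replicates per
concentration; replicate noise is Gaussian on the response scale with sd
expressed as a fraction (default 5%) of the dynamic range — no published
noise model exists for such plates, and response-scale Gaussian noise is
the simplest assumption consistent with replicate scatter.

Fitting is bounded multi-start nonlinear least squares over
(b, c, d, log10 e): EC50 starts at the observed midpoint crossing, the
geometric mean of the concentrations, and each tested concentration; slope
starts at {0.5, 1, 2} of the sign suggested by the response trend, then the
opposite sign. log10 e is bounded to the tested range ± 3 decades. The
replicate pure-error SSE bounds what any curve can achieve, so iteration
over starts stops once a fit is within 10% of it. A fit whose dynamic
range |d − c| does not exceed 4× the residual RMSE is flagged
non-converged (flat or uninformative data) instead of returning silent
numbers. Tolerances of 1e-14 give exact recovery (≤ 1e-6 relative) on
noise-free plates. Pinning parameters (`fixed_params`) supports
baseline-adjusted fitting of constitutively active receptors; the exact
published adjustment is not specified, so the baseline is a supplied
constant here.

Screening cascade: mixes are called hits when the peak well response
clears the buffer-control mean by k control standard deviations (k = 3 by
default — an unstated threshold in practice, chosen as the conventional
3-sigma rule); hits feed single-peptide deconvolution and then dose
series. `summarize_pairs` reports the lowest EC50 per receptor and the
receptor count per peptide.

## Connectome

Edges run from peptide-expressing to receptor-expressing cell types, one
layer per (peptide, receptor) pair, with weight
`sqrt(PeptideExpr · ReceptorExpr) · |log10(EC50 in M)|` — the geometric
mean of the two expression levels weighted by pharmacological sensitivity.
The log is decadic (the natural reading of the weighting); EC50 is in
molar, so sub-molar EC50s give positive weights and weight 0 edges are
dropped. Self-edges are allowed (autocrine signaling). The expression
floor defaults to 0 (any strictly positive expression connects); no
published threshold exists and it is a parameter.

Modules are detected with Leiden (RB-configuration modularity) on the
weight-collapsed undirected projection — parallel and antiparallel layer
edges are summed because modularity on directed multigraphs is
ill-specified. The partition is deterministic for a fixed seed; isolated
nodes become singleton modules. Hubs are ranked by total incident
strength (in + out). Graphs serialize to GEXF for Gephi.

## Synthetic data: what it emulates, what it does not

The generators plant known structure so every stage can be scored without
external downloads:

- **Precursors** — an initial M plus an 18–24 residue stretch from
  {A,L,V,I,F,M,W} emulates the signal peptide (downstream code only needs a
  boundary, not a realistic signal); linkers are drawn from an alphabet
  with no K/R/D/E/Q/P/G so they can never complete a motif; planted
  peptides are flanked only by grammar motifs. The bundled peptide library
  is synthetic, modeled on short amidated cnidarian-style neuropeptides
  (PRGamide/RFamide/LRWamide-like), and covers every motif class. Peptides
  whose own residues would license an internal alternative cut next to an
  acidic flank are planted behind dibasic flanks instead, and peptides
  ending in G or K/R are always planted amidated, since their unamidated
  forms are grammatically indistinguishable in context. Published peptide
  mix compositions are not reproduced; mix composition for screening
  simulations is configurable.
- **Peak lists** — one peak per peptide within a bounded uniform ppm
  jitter; decoys sampled uniformly over the true-mass range and rejected
  within 10 ppm of any truth, guaranteeing unambiguous scoring at 5 ppm.
  No MS2 intensity simulation.
- **Plates** — LL.4 mean plus Gaussian replicate noise as above.
- **Expression** — planted module partition; module cell types express
  their pairs' genes at a common within-module mean, everything else at a
  background mean, both under small lognormal jitter. This is a
  mean-expression table, not a count model: passing module-recovery tests
  shows the network machinery recovers block structure at the planted
  contrast, not that real single-cell atlases would decompose as cleanly.

Every generator is a pure function of its spec and seed. Ground-truth
tables carry coordinates and flags sufficient to score recall/precision
without re-reading the FASTA.

## Problem sizes and reproducibility

The bundled recovery study simulates 100 plates per receptor–peptide pair
(9000 wells) and the miner validation uses 500 precursors — sizes at which
the medians are stable and the whole validation runs in a couple of
minutes on one core. All pipeline randomness flows from a single global
seed through named per-stage substreams; manifests exclude wall-clock
information so identical config + seed reproduces them byte for byte.

## Known limitations

- The grammar is a reconstruction from observed cleavage regularities;
  exact production rules of any particular lab's scripts may differ
  (notably around unconditional acidic flanks, which are exposed as a
  switch rather than guessed).
- The TM counter is a hydropathy heuristic, not a topology model; it is
  meant for coarse candidate filtering with external annotations preferred.
- Charge-state deconvolution, de novo sequencing, FDR estimation and
  retention-time modeling are out of scope; peak lists are assumed to be
  neutral monoisotopic masses.
- EC50s below ~1e-12 M or slopes below ~0.3 approach the information limit
  of the 1e-13..1e-4 M grid; fits there are increasingly asymptote-limited.
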