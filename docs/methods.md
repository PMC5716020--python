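# Methods

## Data model

Coordinates are 1-based rCRS positions; the HVS-I window is the closed
interval [16051, 16384] (334 bp).  A sample's genotype is a *motif*: the
set of HVS-I positions at which it differs from the reference, plus typed
coding-region diagnostics and special length markers (the COII/tRNA-Lys
9-bp deletion).  Motif shorthand follows the field convention "16000+X";
a trailing base letter marks a transversion, a bare number a transition.

The packaged reference window is a synthetic stand-in for the rCRS
sequence (a seeded random draw with HVS-like base composition), since the
motif algebra only requires a fixed anchor, not the database sequence.
The four positions carrying printed transversions in the packaged sample
table (16182, 16183, 16232, 16257) are pinned to the true rCRS alleles so
every printed derived base is a genuine variant.  All sequence-level
results (distances, networks, simulations) are internally consistent with
this anchor; absolute sequences are not comparable with GenBank records.

The packaged sample table transcribes the study's 55-sample haplotype
table verbatim (haplotype IDs, haplogroup labels, coding SNPs, motifs).
Haplotype identity is carried by the printed ID, not recomputed from
motifs: rows printed with identical motifs but distinct IDs differ at
untyped sites and keep a `haplotype_tag` marking that distinction.
Sequence-level modules that operate on reconstructed sequences (the
temporal network) collapse on sequence identity only, so such pairs merge
there.  Per-sample grave assignments are not published; the fixture
assigns carriers of one haplotype to one synthetic grave, which matches
the reported within-grave haplotype sharing and reproduces the printed
kinship-corrected unit count (46).

## Haplogroup calling

The mtDNA rule tree encodes exactly the diagnostics typed in the study
panel.  A node is supported when any of its coding diagnostics (position
presence, APLP-style), special markers, or — for the motif-led M25 node —
its exact HVS-I transition motif is present.  The call is the deepest
node whose ancestors with positive definitions are all supported.  Two
deliberate softenings:

* *Depth dominance.*  Support for a deeper node on one branch dominates
  shallower support on another (the shallower node is recorded in
  `conflicts`); only equal-depth support on divergent branches yields an
  ambiguous call.  This resolves the printed haplogroup-A rows, which
  carry both the A diagnostic (663) and the M-clade marker 10400, without
  silent picks elsewhere.
* *Private variants never veto.*  Extra HVS-I variants are expected
  (hypermutability) and never block a call.

Star labels (D*, N*) are emitted when the parent is supported and no
typed child diagnostic is present; N is defined negatively (absence of
10400), used only when nothing positive matches.  The Y caller walks the
marker panel: derived at a node with derived-where-typed ancestors;
ancestral blocks the branch; missing markers cap depth without blocking.
Both trees ship as editable plain-text files.

## Kinship correction and statistics

Frequencies are computed on haplotype *units*: one unit per haplotype per
grave (unknown grave = singleton).  The correction is idempotent and
deterministic (ordered by haplotype ID).  Percentages are rounded
half-up to two decimals.

Pairwise distances between sequences are raw difference counts with a gap
run of any length counting one event, and no substitution-model
correction — the standard convention for haplotype-level mtDNA data.
Φ<sub>ST</sub> is the among-population variance fraction of the AMOVA
decomposition on those counts (treated as squared Euclidean distances);
negative estimates are floored at zero when used as distances but kept in
a side table.  Permutation p-values use the (b+1)/(m+1) estimator, which
is exact for the uniform null and never zero; the default is 1000
permutations.  The hierarchical AMOVA uses the standard unbalanced-design
expected-mean-square coefficients; the three permutation schemes are:
populations among groups (Φ<sub>CT</sub>), individuals among populations
within groups (Φ<sub>SC</sub>), individuals among populations
(Φ<sub>ST</sub>).

MDS starts from the classical (Torgerson) solution and refines it by
SMACOF stress majorisation; the reported stress is Kruskal stress-1.
Axis signs are fixed by making the first nonzero loading positive.  PCA
is a column-centred SVD of the frequency table.

## Temporal networks

Within a layer, haplotypes (exact-identity classes; an `N` matches any
base when the carrying sequence has ≤ 2 Ns and all other positions agree)
are joined by the minimum spanning network: processing distance classes
in increasing order, an edge is kept iff its endpoints are in different
components of the strictly-smaller graph, so all ties co-minimal with
some minimum spanning tree are retained.  Identical haplotypes in
different layers are joined by identity edges; the sharing report counts
carriers per layer for each global identity class.

## Serial-sampling coalescent

Demes are constant-size and haploid: k lineages in a deme of size
N<sub>e</sub> coalesce at rate k(k−1)/(2N<sub>e</sub>) per generation.
Event ages are given in years BP and divided once by the generation time
(default 25 years, a common mtDNA convention; the source study does not
state one, so it is configuration).  Backward in time, sampling events
inject lineages at their age, an admixture pulse moves each lineage of
the sink deme to the source deme with probability *a*, and a divergence
moves all lineages of the child deme into its parent; pulses are
processed before divergences at the same instant.  Model validation
requires a unique root, a single divergence per deme, and that no deme is
sampled or pulsed after it has merged.

Mutations are a Poisson process of rate μ·L per year on the genealogy
(μ = 9.883 × 10⁻⁸ per site per year, the ancient-DNA-calibrated
control-region rate; L = 334), assigned to branches proportionally to
length and to sites uniformly.  The default scheme is finite-sites,
transition-only (A↔G, C↔T), matching HVS-I hypermutability; multiple
hits are allowed and a Jukes–Cantor-like equal-rates scheme is available.
Sequences are propagated from the packaged reference at the root.  The
simulator is cross-checked in the test suite against closed-form
coalescent expectations (E[π] = 2N<sub>e</sub>gμL; the serial-sampling
form μL(Δ + 2N<sub>e</sub>g); Watterson's E[S]) and against msprime
configured with the same demography and mutation matrix.

## The four demographic scenarios

Three demes — Mogou (sampled at 4000 yr BP), Hengbei (3000 yr BP),
Northern Han (present) — with haploid sizes N_MOGOU, N_HENGBEI, N_HAN.

* **model1** — Mogou splits from the Hengbei lineage at T1; the Northern
  Han branch springs from the sampled Hengbei point (3000 yr BP); at T2 a
  pulse of proportion *a* flows from Mogou into the Han ancestry — into
  the common Hengbei/Han stem when T2 predates the Hengbei sampling,
  into the Han deme otherwise.  T2 is thus the "admixture time between
  Mogou and Hengbei" with the Han lineage as the downstream recipient.
* **model2** — the mirror image: Han descends from the Mogou lineage
  (branch point 4000 yr BP), Hengbei splits at T1, the pulse flows from
  Hengbei.
* **model3** — Han is a Hengbei offshoot at T2 with no admixture.
* **model4** — Mogou and Hengbei are a sister pair splitting at T2 whose
  ancestor split from the Han lineage at T1.

Priors are uniform: sizes 1–100,000 (haploid), T1 and T2 1–20,000 yr BP
with T2 < T1, *a* 0.01–1.  Draws are additionally rejected when a
divergence would predate a sampled deme's sampling age (e.g. T1 > 4000
where Mogou merges at T1).  Models are data (templates), not code, and
can be replaced by the caller.

## ABC engine

Each dataset is reduced to a fixed-order summary vector: per population
the number of haplotypes, haplotype diversity, segregating sites, mean
pairwise differences and Tajima's D (encoded 0 and masked when S = 0);
per population pair Φ<sub>ST</sub> (floored at 0), the mean
between-population difference d<sub>xy</sub>, and the shared-haplotype
count.  The exact statistic list used by the source study is unpublished;
this set is standard mtDNA ABC practice — d<sub>xy</sub> is included
because absolute divergence carries the topological signal (which pair of
populations is closest) that the ratio statistic Φ<sub>ST</sub> loses
when diversity saturates.  The set is config-overridable.

Distances are Euclidean over statistics scaled by their pooled median
absolute deviation (robust to coalescent heavy tails); statistics masked
in the observed vector are dropped.  Rejection keeps the ⌈ε·total⌉
nearest replicates pooled across models (ties broken by replicate index);
ε defaults to 0.005 at desk scale.  Model probabilities are reported two
ways: the acceptance–rejection share per model, and a multinomial
logistic regression of the model label on the (re-standardised) summaries
over the accepted set with Epanechnikov weights in distance, evaluated at
the observed vector (ridge-penalised, as in the standard R
implementation; single-model acceptances fall back to the AR shares).

Parameter posteriors use local-linear regression adjustment with the
same weights.  Parameters with finite prior bounds are adjusted on the
logit scale of their normalised value and back-transformed — without
this, the narrow-ε regression extrapolates weakly-identified bounded
parameters (notably *a*) far outside the support and the clamped draws
pile up at the bounds, producing spuriously narrow, mis-centred
intervals.  The adjustment is applied per parameter only when the local
regression is stable and identified: the accepted set must contain at
least ten draws per covariate (the classical one-in-ten rule) and the
overfitting-corrected (adjusted) R² must reach 0.1, the usual
reliability bar for ABC parameter estimates.  Outside that regime — at
ε = 0.005 the desk design has ~24 correlated covariates for ~100
accepted draws — the fitted slope is dominated by noise and shifting
draws by it demonstrably destroys interval calibration, so the
calibrated rejection sample is kept instead.  Point estimates are the weighted mean and the Gaussian-KDE
mode; intervals are shortest 95% HPD over the (weight-resampled) draws.
The analytic-toy tests exercise both regimes (identified slope at wide ε,
unidentified at narrow ε).

The validation suite draws pseudo-observed datasets from the prior under
each model, selects models by LR, and estimates parameters conditional
on the true model; it reports the confusion matrix, the type-I error
(fraction whose true model is not selected) and per-parameter R²,
relative bias, relative RMSE, factor-2 fraction and 95% HPD coverage
(both fraction and percent forms are derivable; the report stores
fractions).

## Desk-scale problem sizes

The package's standard validation run uses 20,000 reference replicates
per model, 200 pseudo-observed per model, ε = 0.005 and a reduced
sampling design of 20/20/60 (Mogou/Hengbei/Han); the full study design
(46/64/521 and 10⁶ replicates per model) is configuration away but far
beyond a desk run.  Under the stated uniform priors most draws have
N<sub>e</sub> (tens of thousands of generations of coalescent time
scale) far exceeding the deepest event (20,000 yr ≈ 800 generations), so
the four scenarios generate nearly indistinguishable data over much of
the prior volume.  A consequence measured by the validation suite, and
confirmed by training an unrestricted gradient-boosting classifier on
the pooled reference table (which does no better), is that the
desk-scale model-choice type-I error sits near 45–50%: the
discrimination limit is informational, not a property of the
rejection/LR machinery.  Parameter recovery at the informative operating
point (sizes in the hundreds-to-thousands, *a* = 0.15) is calibrated:
the 95% HPD for *a* covers the truth at well above 80% in the recovery
test, with honestly wide intervals reflecting a single-locus design.

## What the synthetic data does and does not emulate

Scenario datasets share the real pipeline end to end (motif notation,
callers, networks, statistics) and are anchored on the packaged
reference, but they are neutral coalescent samples: no aDNA damage,
sequencing error, heteroplasmy, or realistic haplogroup motif structure
(synthetic sequences rarely hit real diagnostic motifs, so calls on them
are typically "unassigned" — by design).  Passing tests therefore
establish the correctness and calibration of the machinery, not the
historical conclusions drawn from the real comparative data, most of
which (the comparative population sequences) are not published and are
out of scope here.

## Known limitations

* Real-data quantities that depend on the unpublished comparative
  sequence panels (pairwise F<sub>ST</sub> values, MDS stress values,
  AMOVA group-variance percentages, the real-data model probabilities
  and posterior estimates) cannot be recomputed and are not targets of
  the test suite.
* The Y-SNP panel covers the typed markers only; deeper clades carry
  state tokens without printed alleles.
* Insertions are not representable in the fixed alignment window and are
  skipped in sequence reconstruction; the 9-bp deletion is a coding-side
  marker and does not enter HVS-I distances.
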