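# Methods

## Data model and score conventions

A variant record is one single-residue substitution with an abundance score
and (optionally) a score standard deviation.  Scores are assumed to be
normalised per dataset so that 0 anchors at nonsense-variant-like and 1 at
wild-type-like abundance; `normalise_from_bin_weights` implements the
min-max map score = (W_var − W_nonsense)/(W_wt − W_nonsense) for tables
that arrive unnormalised, but published tables are used as-is.  Pooling
across proteins is plain concatenation — no cross-dataset rescaling — so
every downstream mean is a mean of scores on this common, if imperfect,
scale.  Synonymous and nonsense rows, and records in per-protein excluded
ranges (e.g. a transmembrane segment), are removed before any analysis.

Noise ceilings are estimated by redrawing every score independently from
Normal(score, sd) 100 times and averaging Pearson/Spearman correlations
between original and redrawn vectors.  Draws are not clipped to [0, 1]:
reported scores themselves exceed that range, and clipping would bias the
ceiling upward.  The ceiling is the correlation a *perfect* predictor could
reach against the noisy data; the closed form for additive Gaussian noise,
r ≈ s/√(s² + σ²) with s the spread of true scores, is used as an oracle in
the tests.

## Structural descriptors

* **rASA** — rolling-probe SASA (Shrake–Rupley as implemented in biotite,
  probe 1.4 Å, heavy atoms, ProtOr radii with a single-element fallback for
  coarse models) divided by a per-residue-type theoretical maximum
  accessibility shipped as `data/max_asa.csv`.  The maxima are defined for
  a residue flanked by glycines, so rASA can exceed 1 for unusually exposed
  residues; burial calls only need the low end of the scale.  SASA of a
  chain is always computed in the context of every chain present in the
  input assembly, which is what makes monomer-vs-dimer comparisons
  meaningful.
* **WCN** — WCNᵢ = Σ_{j≠i} s(rᵢⱼ), s(r) = (1−(r/r₀)⁶)/(1−(r/r₀)¹²),
  r₀ = 7 Å, evaluated as the algebraically identical 1/(1+(r/r₀)⁶) to avoid
  the removable singularity at r = r₀ (where s = 1/2).  rᵢⱼ is the shortest
  heavy-atom distance between side chains; if either residue is glycine (or
  has no side-chain atoms) the shortest distance over all atom pairs is
  used.
* **Secondary structure** — read from DSSP-format files and collapsed to
  three classes: H/G/I → helix, E/B → strand, everything else → loop.  An
  `alpha_only` mode (helix ⇔ H) exists solely for the helix-propensity
  analysis.  A coarse φ/ψ-window fallback assigner is provided for
  synthetic fixtures only; it is not a substitute for a hydrogen-bond-based
  assignment on real structures.
* **Dihedrals** — standard backbone φ/ψ via biotite; termini and residues
  with missing backbone atoms yield NaN rather than errors.
* **Interface residues** — exposed in the monomer (rASA > 0.1), buried in
  the dimer (rASA ≤ 0.1), and losing more than 0.01 rASA upon
  dimerisation.  The Δ-filter removes residues that change class through a
  numerically trivial change at the cutoff.

## Burial classification and matrices

Buried ⇔ rASA ≤ c_rASA ∧ WCN ≥ c_WCN, with defaults c_rASA = 0.1 and
c_WCN = 0 (any WCN passes, so the default rule is pure rASA).  Matrix cells
are plain arithmetic means (no pseudocounts, no per-cell minimum count —
the count matrix is always carried alongside so users can filter).
Diagonal cells are structurally missing; they are set to 1.0 only at the
entry to clustering/PCA, where a synonymous substitution logically has
wild-type-like abundance.  Matrix storage order is alphabetical one-letter;
any sorted display order is presentation only.

Schemes: `global` (1 matrix), `exposure` (buried/exposed), `secondary`
(helix/strand/loop), `combined` (2 × 3).  Each scheme's labels partition
the residues, so per-scheme counts conserve the pool size.

## Prediction and evaluation

The prediction for a variant is the matrix cell of (environment of its
wild-type residue, wt→var), with matrices always rebuilt excluding the
entire dataset of the protein being predicted.  When an
environment-specific cell is empty the global-matrix cell is used as a
fallback, and failing that the prediction is missing (excluded from
evaluation, counted).  The fallback hierarchy keeps the environment signal
primary while avoiding needless prediction gaps; provenance strings record
which level produced every prediction.  Evaluation reports Pearson r,
Spearman r_s (average-rank ties), and MAE per protein; confidence intervals
on across-protein means use a 10,000-draw percentile bootstrap of the
per-protein values.

The cutoff grid search scans c_rASA ∈ {0, 0.05, …, 0.5} ×
c_WCN ∈ {0, 1, …, 20} by default (step sizes are a package choice) and
scores each pair by LOPO mean r and mean MAE.  The dataset-combination
analysis predicts each protein from every non-empty subset of the others,
quantifying how accuracy grows with training data.

External stability changes (ΔΔG) are consumed as tables: Rosetta energy
units are divided by 2.9 REU/(kcal/mol), and values obtained by mutating
both chains of a homodimer are halved to a per-residue change.  External
alignment-style matrices (e.g. BLOSUM-format) are consumed as 20×20 lookup
baselines.

## Resampling profile classifiers

A residue's substitution profile (≥ 5 scored variants required) is redrawn
10,000 times from per-variant Gaussians, independently across variants.

* *Buried-like vs exposed-like*: per resample, RMSD to the buried and to
  the exposed average profile of the residue's amino-acid type are
  compared over their joint non-missing overlap.  A call requires one RMSD
  to be strictly smaller in more than 95% of resamples; exact ties count
  against the buried side (only reachable at sd = 0).  Reference matrices
  are built leave-target-protein-out with monomer-based classification, so
  the classifier can be pointed at dimer interfaces without circularity.
* *ΔΔG-favoured vs matrix-favoured*: computed only when the observed
  profile has both −r_s,ΔΔG > 0 and r_s,matrix > 0; per resample the two
  Spearman coefficients are recomputed and a method is favoured when its
  strict inequality holds in ≥ 95% of resamples.  Exact ties (identical
  rankings) count for neither method, so rank-identical predictors are
  reported as similar.

No multiple-testing correction is applied across residues; the 95%
resampling criterion is a per-residue consistency statement, not a
family-wise error rate.

## Matrix-level analyses

Clustering: average linkage on Euclidean distances, along both axes
(rows = mutation-from profiles, columns = mutation-to), after synonymous
cells are set to 1.0 and missing cells are imputed with their row mean of
defined cells (counts accompany all outputs so the imputation is
auditable).  PCA: each amino acid is a 40-vector of its from-profile and
to-profile means; input is centred but not scaled; component signs are
fixed by orienting each loading vector's largest-magnitude entry positive
so results are deterministic.  Helix propensity: P_ij = ΔΔG_i − ΔΔG_j
(antisymmetric by construction) correlated against the α-only helix matrix
over defined off-diagonal cells; the shipped scale
(`data/helix_propensity.csv`) is the Pace–Scholtz set, kcal/mol relative to
alanine.  Left-handed-loop analysis: loop residues with
0° < φ < 180° and −90° < ψ < 90° (open intervals) that are resolved in the
experimental structure; the restricted matrix's column means, with
standard deviations and per-wild-type residue counts, summarise which
variant types this backbone conformation tolerates.

## Synthetic benchmark

`simulate.make_benchmark(seed=…)` is the package's study system
(preset `benchmark6`): 6 proteins × 150 residues, uniform amino-acid
composition, per-variant Gaussian noise of sd 0.05 with the sd reported
alongside each score, 80% mutational completeness (the middle of the range
real assays span), two of the six proteins homodimeric.

Structures are coarse globules: Cα positions on jittered concentric
spherical shells traversed by an ≈3.8 Å spiral, plus one or two
pseudo-side-chain atoms (CB at 1.8 Å, CG at 3.3 Å for non-small residues)
in a random direction.  The jitter matters: it makes computed rASA a
continuum rather than a lattice-induced two-point distribution, so burial
cutoffs below and above the generating threshold genuinely misclassify
residues and the cutoff grid search has a well-defined optimum.  Dimers
mirror the chain through a plane at a flat face cut into the globule,
producing an emergent contact patch of roughly a dozen residues that are
exposed in the monomer and buried in the dimer.

Ground truth: a residue's environment is buried ⇔ its computed rASA in the
*generating assembly* (dimer for dimer proteins) is ≤ 0.1, making 0.1 the
planted threshold.  Scores are drawn around two generating matrices —
buried means fall with a hydropathy/volume dissimilarity between wild-type
and variant (range ≈ 0.05–0.85), exposed means sit near 0.95 except
substitutions to proline (0.35) — with three classes of planted
exceptions: interface residues (buried by the dimer context), degron-like
surface sites (drawn from the buried matrix despite exposure), and
left-handed-loop sites (variant-type profile: glycine 0.9; P/I/V/W 0.1;
threonine 0.3; others 0.6).  Secondary structure and dihedrals are planted
per residue consistently in both feature frames, with left-handed sites
inside the Ramachandran window and everything else outside it.

What the benchmark does **not** emulate: real per-variant error
heterogeneity (a single noise sd is used), assay-specific score
distribution shapes, correlated errors within a residue, structural
realism beyond burial geometry, and any relationship between amino-acid
identity and burial.  Passing the recovery tests therefore demonstrates
that the *machinery* is correct — unbiased matrix estimation, leakage-free
cross-validation, calibrated resampling classification — not that any
particular accuracy level will be reached on real proteins.

## Numerical choices and degenerate inputs

* All stochastic operations take an explicit seed; per-residue resampling
  streams are spawned from one root seed so results are independent of
  scan order.  Identical configuration ⇒ byte-identical generator output.
* SASA uses 500 sphere points per atom by default (doubling changes
  per-residue rASA by < 2% on fixtures).
* Spearman ties use average ranks; resampled Spearman coefficients are
  computed as Pearson correlations of ranks, which is the same estimator
  vectorised over resamples.
* Constant score vectors make correlations undefined: they are flagged
  (`degenerate`) rather than silently NaN.
* Matrices with an empty cell report NaN mean and zero count; asymmetry
  and difference propagate missingness.
* Profiles with fewer than five scores, or with fewer than five variants
  shared with the references, are `not-evaluated`, never guessed.

## Known limitations

* The burial rule is a hard threshold; residues near rASA = 0.1 flip class
  under small numerical changes (e.g. PDB coordinate rounding).  The grid
  search quantifies, rather than removes, this sensitivity.
* The φ/ψ fallback secondary-structure assigner is deliberately crude and
  only suitable for synthetic fixtures.
* Mean-based matrix cells are sensitive to dataset composition when one
  protein dominates a cell; the exclusion machinery and count matrices
  expose this but the package does not reweight.
* The per-cell recovery tolerance of three standard errors is a per-cell
  statement; across hundreds of cells a ~0.3–1% chance-violation rate is
  statistically inevitable for an unbiased estimator, and the test suite's
  distribution-level check (≥ 99% of cells within 3 SEM, none beyond 5)
  is the operative correctness property.
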