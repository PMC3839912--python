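# Methods

This note documents the models, parameter choices and numerical decisions
behind `siliprot`, and what the synthetic-data generators do and do not
emulate.

## Partitioning model

Spot volumes are treated as relative abundances: each gel is normalized to
its total intensity, so the AP/NAP ratio is invariant to gel-wide scaling
(exposure time, label activity).  Thresholds are stored at full precision
(10^±0.2), not the rounded 1.58/0.63; rounding is presentational.  Both
threshold inequalities are strict, so boundary equality lands in the
intermediate group.  Proteins with nonzero volume in exactly one gel are
informative — exclusive presence in the non-adsorbed gel is evidence of
resistance to adsorption — so they are labelled by presence, with the
ratio flagged (+∞ for adsorbed-only, NaN for non-adsorbed-only) to keep
them out of numeric distribution summaries.  A protein listed with zero
volume in both gels is `unmatched`.

## Feature battery

The registry computes 34 features per protein: 8 residue-class fractions,
20 per-residue fractions, length (aa), molecular weight (Da, average
masses plus one water, 18.0153 Da — average rather than monoisotopic
because that matches conventional protein MW reporting), isoelectric
point, GRAVY, and two charge-cluster ratios.  It is a deliberately compact
registry: broad descriptor families (CTD, autocorrelation,
secondary-structure prediction) are out of scope; the residue-class
fractions act as secondary-structure proxies.

* **Isoelectric point.** Henderson–Hasselbalch net charge with the EMBOSS
  pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
  R 12.5, Y 10.1), solved by bisection on pH ∈ [0, 14] until
  |charge| < 1e-4.  The charge function is strictly decreasing in pH and
  the termini are always present, so bisection always converges.
* **Charge clusters.** Contiguous windows of 12 residues; a window is
  "charged" when it contains ≥ 3 residues of one sign (positive set
  {R, K} — His is excluded, matching the basic residue class; negative
  set {D, E}).  The threshold is a ≥ comparison and both window and
  threshold are configurable.  The ratio's denominator is the total
  number of windows (L − 11); sequences shorter than the window yield NaN
  and are dropped per-feature in the group statistics, with per-test n
  reported.

## Statistical battery

All tests are two-sided.  The Brunner–Munzel test is the primary
comparison because roughly a third of composition features are non-Gaussian
and some are heteroscedastic across groups, which invalidates both the
t-test and, formally, the Wilcoxon–Mann–Whitney test.  Implementation
follows the studentized midrank form: relative effect
p̂ = (R̄₂ − (n₂+1)/2)/n₁, within-sample rank variances
S_i² = Σ_k (R_ik − R*_ik − R̄_i + (n_i+1)/2)² / (n_i − 1), statistic
W = n₁n₂(R̄₂ − R̄₁)/(N √(n₁S₁² + n₂S₂²)) with Satterthwaite degrees of
freedom.  When both rank variances vanish the result is flagged degenerate
and the limiting values are reported: complete separation (p̂ ∈ {0, 1})
gives W = ±∞ and p = 0 — the continuous limit of the statistic, and the
correct ordering signal for a ranked table — while fully tied samples give
W = 0 and p = 1.

The robust Jarque–Bera statistic replaces the moment-based spread with the
average absolute deviation from the sample median scaled by √(π/2), using
the classical normalizing constants 6 and 64 against χ²(2); it is slightly
conservative in finite samples, which the calibration test's 3-standard-
error band accommodates.  Brown–Forsythe is the median-centered Levene
ANOVA.  Benjamini–Hochberg adjustment is applied across the full feature
registry as one family; NaN entries (tests that could not run) pass
through without counting toward the family size.  The direction column
("more"/"less" in AP) is decided by arithmetic group means by default
(configurable to medians); the table reports both raw and adjusted
p-values rather than guessing which a reader wants.

## Interaction census

Detectors operate on derived per-residue atom groups: cations (Arg
NE/NH1/NH2, Lys NZ — His is not a cation at neutral pH and participates
only as a π partner), anions (Asp OD1/OD2, Glu OE1/OE2), aromatic ring
centroids (Phe/Tyr 6-ring, His 5-ring, Trp the mean of all 9 ring heavy
atoms as a single π system; a centroid requires the complete ring),
side-chain N/O donors and acceptors by residue type, and side-chain C/S
atoms of the hydrophobic class.  Choices the data forced:

* **Pairs counted once per residue pair per type**, not per atom pair:
  the census unit is interactions per amino acid, and per-atom counting
  would inflate multi-atom groups (Arg, Glu).
* **Distance-only hydrogen bonds (3.5 Å default)**: hydrogens are often
  absent from crystal structures, so no angle criterion is applied; the
  cutoff is configurable.
* **Minimum sequence separation 2** excludes trivial i,i+1 contacts;
  configurable.
* **Normalization denominator** is the number of residues actually parsed
  in the monomer, so census and denominator share support.
* **Monomer rule**: first model, first chain (or a named chain), HETATM /
  waters / non-blank altlocs / non-standard residues dropped with counts
  logged.

Group summaries are unweighted per-structure means of per-amino-acid
values (not pooled counts over pooled residues), with percent increase
100·(B − A)/A, undefined when the reference mean is zero.  Percent values
are conventionally printed with one decimal below 10% and as integers
above.

## Langmuir fitting

Unweighted nonlinear least squares on Γ(c) = Γ_max·K·c/(1 + K·c), with
initial values from the double-reciprocal linearization
1/Γ = 1/Γ_max + (1/(Γ_max K))·(1/c) over the positive points (fallback:
plateau maximum and half-saturation at the median concentration).
Parameters are bounded positive.  Requires ≥ 3 points with ≥ 2 distinct
concentrations and a nonzero response.

## Synthetic data: what it emulates and what it does not

* **Sequences** are i.i.d. draws from S. cerevisiae proteome residue
  frequencies with log-normal lengths (μ = 5.86, σ = 0.55 on the log
  scale, truncated to 50–1500 aa — a yeast-like globular pool).  The AP
  group's frequencies are aromatic-depleted (δ = 0.5 by default) and
  Arg/Glu-enriched (ε = 0.2, a moderate effect mirroring the weaker
  charged-residue signal), then renormalized.  Default group sizes are
  31/46, the AP/NAP split of the motivating study design.  Real proteins
  are not i.i.d. residue strings: composition variance across proteins is
  larger in reality, so synthetic p-values are far smaller than any real
  analysis would produce.  Passing tests therefore demonstrate recovery of
  planted effect *ordering and direction*, not realistic effect sizes.
* **Structures** are Cα-plus-side-chain toy residues with exact regular
  polygon rings, placed as rigid units (a planted pair or an inert filler)
  on a jittered cubic lattice whose spacing is derived from the largest
  unit radius, guaranteeing ≥ 12 Å between units — outside every
  detection window.  Planted pairs use residue types and distance bands
  chosen so exactly one interaction type can fire (e.g. His–His stacks for
  π-π, so no hydrophobic or H-bond contact can co-occur), making the
  expected census a construction-time ground truth independent of the
  detectors.  These are not protein folds; they validate geometry
  detection, not biology.
* **Spot tables** draw log-normal base volumes and plant post-normalization
  log₁₀ ratios in [0.35, 0.9] (AP), [−0.9, −0.35] (NAP) and ±0.08
  (intermediate).  Because per-gel normalization rescales all ratios by a
  common factor, gel weights are rebalanced by one linear solve so that
  Σ volume·ratio = Σ volume, after which normalization leaves every
  planted ratio exact and partitioning recovers 100% of labels.  A label
  set whose ratios would all sit on one side of 1 cannot satisfy this
  constraint and is rejected as infeasible.

## Problem sizes

The validation suites use 200 random 50-residue structures for
detector/brute-force equivalence, exhaustive multiset scans up to n = 6
over {1, 2, 3} for the relative-effect oracle, 100 label shuffles ×
34 features for null calibration, 100 seeded pools for planted-effect
ranking, and 100 noisy 12-point isotherms for Langmuir recovery — sizes at
which the Monte-Carlo bands quoted in the tests are comfortably stable.

## Known limitations

* The PDB reader keeps the first chain of the first model; multi-chain
  biological assemblies, mmCIF and NMR ensembles are out of scope.
* Solvent accessibility, molecular dynamics observables (RMSD, B-factors)
  and stacking-geometry classification are not computed.
* The feature registry is extensible but intentionally smaller than
  full-descriptor packages; isoelectric points depend on the chosen pKa
  set and differ between conventions by a few tenths of a pH unit.
* The census's H-bond criterion accepts any donor/acceptor N/O pair within
  the cutoff; without hydrogens or angles this overcounts marginal
  geometries, uniformly across groups.
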