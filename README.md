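# siliprot

Comparative analysis of which proteins in a mixture adsorb to silica
nanoparticle surfaces — and why.

When a pool of soluble proteins meets silica nanoparticles, some proteins
coat the surface (the protein corona) and others stay in solution.
`siliprot` implements the comparative strategy for finding the
physicochemical determinants of that split: partition the pool into
adsorbed (AP) and non-adsorbed (NAP) groups from two-dimensional gel
electrophoresis spot intensities, compare dozens of sequence-derived
features between the groups with a heteroscedasticity-robust rank-test
battery, census the intramolecular noncovalent interactions of the groups'
3D structures, and handle the adsorption-isotherm arithmetic.  It is a
library for structural bioinformaticians and nano-bio interface
researchers, driven from Python; `examples/` holds one short script per
capability.

## The methods at its core

**Spot-ratio partitioning.** Each gel is normalized to its total spot
intensity; for each protein the ratio

r = (relative intensity in the adsorbed-fraction gel) / (relative intensity in the non-adsorbed-fraction gel)

classifies it as adsorbed (r > 10^0.2 ≈ 1.58), non-adsorbed
(r < 10^-0.2 ≈ 0.63) or intermediate.  Proteins seen in only one gel are
classified by presence, with the ratio flagged (±∞/NaN) so they stay out
of numeric distributions.

**Feature battery and group statistics.** Per protein: eight residue-class
fractions (aromatic {F,W,Y,H}, polar {R,K,E,D,Q,N}, β-strand
{V,I,Y,C,W,F,T}, hydrophobic {C,L,V,I,M,F,W}, α-helix {E,A,L,M,Q,K,R,H},
basic {R,K}, acidic {E,D}, neutral = rest), the 20 per-residue fractions,
length, molecular weight, isoelectric point (Henderson–Hasselbalch
bisection, EMBOSS pKa set), Kyte–Doolittle GRAVY, and sliding-window
charge-cluster ratios (12-residue window, ≥ 3 same-sign charges).  Each
feature is compared between AP and NAP with the Brunner–Munzel test of
stochastic equality H₀: P(X < Y) = P(X > Y), whose statistic

W = n₁n₂(R̄₂ − R̄₁) / (N √(n₁S₁² + n₂S₂²))

is referred to a t distribution with Satterthwaite degrees of freedom, and
whose relative effect p̂ = P(X < Y) + ½P(X = Y) is estimated from
midranks.  Wilcoxon–Mann–Whitney cross-checks, robust Jarque–Bera
normality screening, Brown–Forsythe variance screening and
Benjamini–Hochberg FDR adjustment complete the battery.

**Interaction census.** Five distance-cutoff detectors count, once per
residue pair: ionic contacts (cation–anion atoms ≤ 6 Å), cation–π
(Arg/Lys cation atom to aromatic ring centroid ≤ 6 Å), π-π (ring
centroids within 4.5–7 Å; His counts as aromatic), side-chain–side-chain
hydrogen bonds (donor/acceptor N/O ≤ 3.5 Å) and hydrophobic contacts
(side-chain C/S of the hydrophobic class ≤ 5 Å).  Counts are normalized
per amino acid and summarized per group with percent increases.

**Langmuir isotherm.** Γ(c) = Γ_max·K·c/(1 + K·c) fitted by nonlinear
least squares with a double-reciprocal initialization, plus the surface
dose arithmetic (NP concentration × volume × S_BET).

A synthetic-data module generates all inputs with known ground truth:
yeast-like sequence pools with planted compositional shifts, toy
structures with planted interaction pairs, and spot tables whose
post-normalization ratios match planted labels exactly.

## Worked example

```bash
python examples/group_comparison.py
```

```
    feature direction  bm_estimate      p_value   p_adjusted
   aromatic      less     0.997195 1.748161e-62 5.943747e-61
          F      less     0.962833 3.235828e-27 5.500908e-26
beta_strand      less     0.902525 6.520382e-17 7.389767e-16
          H      less     0.894109 8.145682e-16 6.923830e-15
      polar      more     0.120617 4.561573e-15 3.101870e-14
...
```

The synthetic adsorbed group was generated with aromatic frequencies
halved and Arg/Glu enriched by 20%; the battery recovers exactly that
signature: the aromatic fraction is the top-ranked discriminating feature
("less" in the adsorbed group, p̂ ≈ 1 means nearly every AP value lies
below every NAP value), followed by individual aromatic residues, while
polar/charged features run the other way ("more" in AP).

```bash
python examples/langmuir_fit.py
```

```
surface dose: 0.168 m^2
Gamma_max = 1.630 +- 0.027 mg/m^2
K         = 1.610 +- 0.140 L/g
```

A 12-point isotherm simulated around a 1.58 mg/m² monolayer capacity with
3% noise refits within one standard error; 5 g/L of nanoparticles with
168 m²/g in 0.2 mL offer 0.168 m² of surface.

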