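# Methods

This note records the models implemented in `phytascan`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
generators do and do not establish.

## Reference catalog and clade clustering

The bundled catalog lists biochemically or structurally characterized
phytases of the four families (BPP, HAP, CP, PAP), each clade named by its
representative accession prefix, with the representative's conserved motifs
and their 1-based anchor positions. Homologous accessions sharing >28%
identity with a representative are catalogued as clade members.

**Pairwise identity** is identical residues divided by aligned columns of a
global alignment (Biopython `PairwiseAligner`, BLOSUM62, gap open 10,
extend 0.5, end gaps penalized). Internal gap columns count toward the
denominator; terminal gap columns do not. End gaps are penalized
deliberately: with free end gaps the score-optimal alignment of two
unrelated ~100-residue proteins collapses onto a short well-matching core
and reports identities above 30%, which would defeat the 0.28 clustering
threshold.

**Clustering** is greedy representative linkage: sequences are processed in
descending length order (input order breaks ties, and the catalog lists
representatives before members), each sequence joining the seed it matches
best with identity strictly above the threshold, otherwise seeding a new
clade. Clustering runs within families, so clades never straddle family
boundaries. This reproduces the catalogued 4/8/2/2 clade structure and is
deterministic. Whether the >28% grouping convention measures identity against the
representative or against all members is ambiguous; representative
linkage is this package's documented choice. Count monotonicity in the
threshold holds on clade-structured data (and is property-tested there) but
is not a theorem for greedy linkage in general.

## Homology search

Each clade representative (or an alignment of clade members) becomes a
position-specific scoring profile. Column emission probabilities mix
observed residue frequencies with a Swiss-Prot-like background,
`(f + w·bg)/(1 + w)`, with pseudocount weight `w = 1` by default; columns
with more than 50% gaps are dropped (match-column rule). Scores are
log₂-odds (bits).

A candidate's score is the **best ungapped local segment** over all
profile/query diagonals (maximal-segment score). This is the regime in
which extreme-value statistics hold; fixed-window sums were rejected
because their variance is dominated by sequence-length variation, which
flattens the fitted tail and destroys the cutoff semantics. Empirically the
fitted decay constant is close to ln 2 per bit, as expected for log₂-odds
scores.

**E-values** come from a Gumbel fit to maximal scores of seeded random
background sequences (default 500–1000 sequences, lengths ~N(300, 60²)
emulating predicted metagenome proteins):
`E(s) = N_db · κ · exp(−λ s)`, clipped to `(0, N_db]`. The reporting cutoff
defaults to 10⁻³⁰ and is applied per profile–query pair; each query then
reports its best clade per family. Because planted homologs at 60% identity
score hundreds of bits above the random maximum, decisions are insensitive
to the exact tail fit. An optional pyhmmer backend implements the same
`Hit` contract with true profile HMMs; the two engines must (and in tests
do) qualify identical sequence sets after screening.

## Motif screening

A hit qualifies only if every family motif is located in the candidate.
Motif grammar: fixed residues, `X` (any standard residue, never a gap),
bracketed sets (`[D/E]`), and whole-motif alternates (`HD/HAE`). A clade's
screening pattern is the family consensus with the representative's own
concrete motif accepted as an extra alternate — several catalogued
representatives (e.g. the CP clade with `YF` in place of the WPD-loop `DH`)
deviate from the family consensus, and must themselves qualify.

Anchors are projected from the representative onto the candidate through
the global alignment map; positions falling in gaps are extrapolated from
the nearest aligned column. The candidate is searched nearest-first within
±10 residues of the projected anchor. The window absorbs small indels while
keeping the random-match probability per motif low; requiring *all* motifs
makes chance qualification of a random sequence negligible (screening
specificity is tested at zero false qualifications across 20 seeded random
proteomes). Candidates shorter than the earliest anchor minus the window
are rejected as too short. A quorum (`min_motifs`) is exposed but the
default requires all motifs.

For clades without validated structures a neighbor-joining tree
(p-distance, skbio NJ, negative branch lengths clamped) supports an
advisory screen: tips outside the subtree spanned by validated members are
flagged, and excluded only in strict mode. Flagging is the default because
subtree membership in an unrooted tree is sensitive to root placement.

## Abundance and taxonomy

Relative gene abundance is `count / mean(marker counts)` per sample, with
ten universal single-copy marker COGs (COG0012, COG0016, COG0018, COG0172,
COG0215, COG0495, COG0525, COG0533, COG0541, COG0552) as the default
normalizer set; counts may be fractional. The statistic is exactly
invariant to per-sample depth scaling. Samples with zero marker mean are
dropped with a warning.

Taxonomy consumes precomputed best-hit tables: per query the maximal
bitscore wins, ties broken by lower e-value then subject id; unresolvable
lineages become `unclassified` rather than being dropped. Class frequencies
are normalized to 1 within each sample type; shared-class counts use
exclusive-region Venn semantics (classes present in all members of a subset
and absent everywhere else), so exclusive regions sum to the union size.

## Community ecology

Bray–Curtis (`Σ|x−y| / Σ(x+y)`) via scipy. PCoA double-centers the squared
dissimilarities and eigendecomposes; when negative eigenvalues appear the
Lingoes correction (adding 2c to squared off-diagonal dissimilarities,
c = |most negative eigenvalue|) is applied and reported, and variance
fractions use the corrected positive spectrum. tb-RDA Hellinger-transforms
the community table (square root of row-relative abundances), centers both
sides, projects onto the least-squares fit of the encoded design
(categoricals one-hot with first level dropped; rank-deficient designs are
rejected naming the collinear columns), and eigendecomposes the fitted
values; axis fractions are relative to total inertia. Distance decay is an
OLS fit of pairwise similarity on log₁₀ geographic distance (haversine
kilometres) with a 95% CI on the slope. Group differences in richness use
two-sided rank-sum tests; a PERMANOVA wrapper (skbio, 999 permutations) is
provided as supporting output for ordinations.

### Normalized stochasticity ratio

NST quantifies how far observed pairwise dissimilarities depart from a null
model, on a 0–100% scale with 50% as the stochastic/deterministic boundary.
The R package implementing the original framework is not available here, so
the statistic is implemented in-package:

- **Null model ("PF")** — per sample, keep the observed richness and the
  observed abundance-value distribution, but reassign which taxa carry those
  values: taxa are drawn without replacement from the regional pool (all
  occupied columns of the full matrix) with probability proportional to
  occupancy frequency, and the sample's nonzero abundance values are
  permuted onto them. Per-sample random streams are keyed by (seed,
  replicate, sample id), which makes results invariant to row and column
  order.
- **Pairwise ratio** — with observed dissimilarity `D`, null expectation
  `E` (mean over replicates) and maximum 1: `ST = D/E` if `D < E`
  (communities more similar than the null: homogeneous selection),
  `ST = (1−D)/(1−E)` if `D > E` (variable selection), 1 at equality.
- **Normalization** — `ST` is divided by the null model's own expected
  ratio (the mean `ST` of null replicates against `E`), clipped to [0, 1],
  and averaged over within-group pairs. Communities drawn from the null
  itself therefore score ≈100%.

The default dissimilarity is Ružička (abundance-based Jaccard); Bray–Curtis
and incidence Jaccard are options, and the variant used is recorded in the
result. Default 1000 replicates; a seed is required. Groups under 3 samples
are skipped.

## Biochemical calculations

InsP species are sets of phosphorylated ring positions; the formula is
C₆H₁₂O₆ plus one HPO₃ per phosphate. Monoisotopic masses use C = 12,
H = 1.0078250319, O = 15.9949146221, P = 30.97376151; negative-mode ions
are `(M − |z|·1.00727646688)/|z|` for z ∈ {−1,−2,−3}. The theoretical
phytate ions round to m/z 658.85 ([M−H]⁻) and 328.92 ([M−2H]²⁻).

Dephosphorylation is modelled as stepwise removal in a per-class order.
Contractual invariants are the initiating-site class and the terminal
products — BPP stops at Ins(2,4,6)P₃ (3 phosphates released from phytate),
acid phytases at Ins(2)P (5 released; the axial 2-phosphate resists
phytases) — while the intermediate order is configurable because it varies
between enzymes even within a family. Defaults: BPP (3,1,5) (a 3-phytase
removing alternating positions), HAP (3,4,5,6,1), CP (5,4,6,3,1),
PAP (5,6,4,3,1). Phosphate balance (released + remaining = initial) holds
for every class and substrate.

Kinetics: the primary fit is the double-reciprocal (Lineweaver–Burk)
regression of 1/v on 1/S with Km = slope/intercept and Vmax = 1/intercept,
since that is the conventional analysis for this assay; it is exact on
noiseless data but weights low-rate points heavily under noise, so a direct
nonlinear least-squares fit is provided as a labelled alternative, never
silently substituted. kcat = Vmax (µmol·min⁻¹·mg⁻¹) × Mw (Da) / 60000,
interpreted per total protein. qPCR gene abundance is the cycle ratio
Cp_ref/Cp_target. Degradation rates are negated least-squares slopes of
concentration (µM) versus time (days) per gram of sample, optionally
blank-corrected by a control series; negative rates clip to zero with a
warning.

## Synthetic data: what it emulates and what it does not

All generators are deterministic from their seed, and truth tables suffice
to score search and screening exactly.

- **Background proteomes** — i.i.d. residues from a Swiss-Prot-like
  composition, lengths ~N(300, 60²) floored at 30. No real protein
  structure, domains, or compositional bias.
- **Reference stand-ins** — since real reference sequences are not
  redistributed, each representative gets a random-background sequence with
  its concrete motifs written at the catalogued anchors (fixed internal
  seed: the stand-ins are a fixture, not a condition), and homolog
  accessions get motif-preserving mutated copies at 80% identity —
  comfortably above the 0.28 threshold so that clustering recovers the
  catalogued clade structure regardless of seeding order. Inter-clade
  identity is at random-background level.
- **Planted homologs** — point substitutions only (keeping motif
  coordinates exact), avoiding motif columns when intact; when broken,
  every motif is disrupted at a consensus-constrained residue and verified
  unmatched within the screening window, so decoys fail screening by
  construction. Default planted identity 0.6.
- **Count tables** — Poisson counts around depth × marker_mean × abundance;
  the marker normalizer is recovered unbiasedly.
- **Community assembly** — neutral mode: multinomial draws (depth 2000, 120
  taxa) from a shared lognormal metacommunity with strong per-sample
  lognormal drift (σ = 1.5), so taxon identities carry no deterministic
  signal; selection mode: all samples drawn from one fixed composition on a
  third of the taxon pool with 5% lognormal noise, emulating strong
  environmental filtering. Under these conditions NST reads ≈98–99% for
  neutral and ≈20–25% for selective assembly, on the correct sides of the
  50% boundary.
- **Kinetics data** — Michaelis–Menten rates with optional truncated
  Gaussian noise; grids that do not bracket Km are flagged as
  ill-conditioned.

Passing tests on these generators demonstrates the pipeline's decision
logic (scores, cutoffs, screening, normalization, null-model behavior) with
known ground truth. It does not demonstrate sensitivity on real
metagenomes, where homologs diverge by indels and domain rearrangement, the
background is not i.i.d., abundances are coverage-derived, and communities
mix assembly regimes.

## Problem sizes and numerical conventions

Default analysis sizes used throughout tests and the acceptance script:
1000-protein backgrounds with 10 intact + 5 broken planted homologs (20
seeds), 500–1000 calibration sequences, 20-sample × 120-taxon community
matrices with 1000 null replicates, 8-point kinetic grids spanning
0.25–32 × Km. E-values are clamped to (0, N_db]; dissimilarities live in
[0, 1]; PCoA eigenvalues below 10⁻⁸ of the spectrum maximum are treated as
zero; NJ branch lengths are clamped non-negative; ties in representative
selection break lexicographically by accession.

## Known limitations

- The built-in search is ungapped at the scoring stage; strongly indel-rich
  homologs rely on the alignment-based screening stage (or the pyhmmer
  backend) rather than the scanner.
- The NST implementation follows the original framework's logic but is an
  independent implementation with one null-model family; numerical equality
  with other software is not claimed.
- Whether screening should require all motifs or a quorum is undocumented
  in the source material; all-motifs is the default, `min_motifs` the
  escape hatch. The same applies to the per-profile application of the
  E-value cutoff (recorded in output metadata).
- The alkaline-phosphatase catalog namespace supports E-value-only searches;
  no motif screening is defined for it.
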