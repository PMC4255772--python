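# Methods

`ifacevol` measures how the structural context of a residue — inter-chain
contact, solvent exposure, interface burial — conditions its rate of protein
evolution, in protein complexes assembled from subunits encoded by two
genomes (the motivating system is a mitochondrially/nuclear co-encoded
respiratory complex).  This note records the models, conventions and
numerical choices the implementation commits to, and what the synthetic-data
tests do and do not establish.

## Residue classification

Every residue of a designated (mtDNA-encoded) chain is assigned to exactly
one of four classes by the following decision tree:

1. **Contact** if its minimal heavy-atom distance to any residue of another
   *polypeptide* chain is below the cutoff (default 4 Å, the upper limit of
   weak non-covalent interactions).  Hetero groups (hemes, lipids, ions)
   never create contacts.  Contact residues split by the genome of origin of
   their partners: any nuclear-encoded partner takes precedence
   (`MT_NU_CONTACT`), otherwise `MT_MT_CONTACT`.  The precedence rule is a
   deliberate reading of "contacts with the other genome" as the stronger
   label for mixed-partner residues.
2. Noncontact residues are **buried** when their relative solvent
   accessibility *in the complex* — ASA₂ divided by the residue's
   theoretical maximum ASA (Tien et al. 2013 table) — falls below a
   configurable threshold (default 0.05).
3. The remaining **exposed noncontact** residues carry an `interface` flag:
   `True` iff ΔASA = ASA₁ − ASA₂ > 0, where ASA₁ is computed on the chain in
   isolation and ASA₂ in the assembled complex.  ΔASA > 0 marks burial in an
   interface without atomic contact.

Solvent accessible surface areas use the Shrake–Rupley algorithm with a
deterministic golden-spiral point set (default 960 points, probe 1.4 Å,
element-specific van der Waals radii).  Because ASA₁ and ASA₂ are evaluated
with the same point set and the complex only adds occluding atoms, ΔASA is
exactly nonnegative; a negative value beyond numerical tolerance is treated
as a data error.  Alternate locations resolve to the highest-occupancy
conformer (ties: first record), hydrogens and waters are dropped, and
residues are keyed by (chain, number, insertion code).  When the input
crystal contains more than one copy of the complex, the chain filter should
select a single functional monomer; cross-copy contacts are out of scope.

Heme proximity profiles report, per residue, the minimum heavy-atom
distance to any heme hetero group.

## Codon sorting

Alignment columns are tied to structure residues through the ungapped
codons of a reference taxon (the structure's species): the k-th ungapped
reference codon maps to residue `first_residue_number + k − 1` of the
configured chain.  Columns where the reference is gapped cannot be
structurally labelled; they are tagged `UNMAPPED` and excluded from every
class.  Columns with many gapped taxa are retained — the pairwise estimators
handle gaps per pair.  Codons containing any gap character are normalised to
fully gapped.  The default genetic code for mtDNA-encoded genes is the
vertebrate mitochondrial code (NCBI table 2; stops TAA/TAG/AGA/AGG, 60 sense
codons); internal stops in the data are reported by the reader and rejected
by the likelihood machinery.

## Pairwise divergence, ΣdN and the interaction ratio

dN (nonsynonymous substitutions per nonsynonymous site) is estimated per
unordered sequence pair by counting methods:

* **NG86** — per-codon synonymous site fractions with stop-codon mutations
  excluded from numerator and denominator (so s + n = 3 per codon), averaged
  over the two sequences; multi-hit codons averaged over minimal mutational
  pathways, excluding pathways through stop codons (all pathways are used if
  every one is blocked); Jukes–Cantor correction d = −(3/4) ln(1 − 4p/3).
  This tier is exactly hand-checkable and matches an independent
  implementation (Bio.codonalign) wherever stop-neighbour conventions cannot
  differ.
* **YN00** (default) — κ estimated per pair from fourfold-degenerate and
  nondegenerate positions via K80, averaged with site-count weights
  (fallback κ = 2 for sparse or saturated data); synonymous/nonsynonymous
  site opportunities weighted by κ and F3×4 codon frequencies; pathway
  averaging weighted by κ per step; K80-style corrections applied separately
  to the transition and transversion components of pS and pN.  The
  ω-iteration refinement of the original method (reweighting pathways by an
  evolving dN/dS) is deliberately omitted; at the divergences analysed here
  its effect is far below the resampling noise the pipeline quantifies.

Pairs whose corrected distance is undefined (p at or beyond saturation, or
no usable codons) are excluded from ΣdN and counted.  ΣdN is the sum of
pairwise dN over all unordered pairs of a codon subset; the interaction
ratio is the quotient of two ΣdN values, read as "numerator class evolves
faster" when above 1.  Because all counting statistics are additive over
columns (the nonlinear correction applies only to aggregates), a per-column
cache evaluates ΣdN for arbitrary column subsets by array sums — resampling
nulls and bootstrap standard errors are exactly consistent with the direct
estimator.  The standard error of ΣdN is a codon-column bootstrap (default
200 resamples); the estimator behind the published-style "SE below 2.5%"
claims is not specified anywhere we could follow, so the column bootstrap is
this package's choice.

## Resampling null

The null distribution of ΣdN for a subset of size m draws, B times
(default 10⁴), m distinct columns uniformly without replacement from the
chain's full alignment and records the subset ΣdN.  Empirical tail
probabilities use add-one smoothing, p = (1 + r)/(B + 1), so p ∈ (0, 1];
the tail is explicit per call (lower for conservation claims, upper for
variability claims).  Under the null, p is uniform up to the 1/(B+1)
discretisation, which the acceptance suite verifies by a KS test across 200
simulated data sets.

## Codon-model maximum likelihood

The substitution process is a GY94-style reversible codon model over the
sense codons of the configured genetic code: single-nucleotide moves only,
target-frequency proportional (F3×4), ×κ for transitions, ×ω for
nonsynonymous changes, generator scaled so branch lengths are expected
nucleotide substitutions per codon.  F3×4 frequencies are floored at 1e-6
and renormalised before entering the generator: unobserved codons in short
alignments would otherwise make the symmetrised generator numerically
singular.  Transition probabilities come from the symmetric eigendecomposition
of D^{1/2} Q D^{-1/2} (D = diag π), with eigenvalues clipped at zero;
exp(Qt) rows then sum to one to 1e-10 over the branch-length range used.

Likelihoods use Felsenstein pruning with per-node rescaling and site-pattern
compression.  Gapped or ambiguous codons at a tip are fully ambiguous states
(partial likelihood one over all sense codons); stop codons in the data are
an error naming the site.  Trees are unrooted binary (2n − 3 branches);
rooted Newick input is de-rooted by merging the basal bifurcation.  The
likelihood is invariant to the internal rooting used for the computation.

Model structures:

* **M0** — single ω; optimised jointly with κ and all branch lengths
  (L-BFGS-B on log-transformed parameters; bounds ω ∈ [1e-4, 99],
  κ ∈ [0.01, 100], branch length ∈ [1e-8, 50]).  The fitted branch lengths
  are held fixed by all downstream fits, which keeps the partitioned
  analyses tractable at large taxon counts.
* **fixed-sites** — one ω per predefined site partition, κ shared across
  partitions (the sharing is this package's choice), branch lengths fixed.
  Each partition's generator is normalised to unit expected rate, so
  partitions share branch lengths in substitutions per codon while ω governs
  the nonsynonymous/synonymous composition.  Standard errors come from the
  numeric curvature of the per-ω profile at the optimum.
* **M1a / M2a** — nearly-neutral {ω₀ < 1, ω₁ = 1} and positive-selection
  {ω₀ < 1, ω₁ = 1, ω₂ > 1} site mixtures with unknown proportions,
  optimised on unconstrained transforms (softmax proportions), three starts
  for M2a.  The LRT statistic 2(lnL_M2a − lnL_M1a) is floored at zero and
  referred to χ² with 2 degrees of freedom.

**Per-branch dN** is apportioned by conditional expected labelled Markov
counts: for each branch, the posterior expectation (given the tip data,
under the fitted partition model) of the number of nonsynonymous transitions
of the underlying chain, computed analytically in the eigenbasis via the
standard integral of exp(Qs) C exp(Q(t−s)) with C the nonsynonymous part of
Q.  The count is divided by the partition's nonsynonymous site count under
the mutational-opportunity definition consistent with the fitted κ and π.
This is a deliberate proxy for refitting a free-ratio model with one ω per
branch — hundreds of extra parameters for the tree sizes this analysis
targets; numeric equivalence with reconstruction-based counting in other
packages is not claimed, but the per-branch difference statistic
dN(inter-genome contacts) − dN(intra-genome contacts) depends only on the
contrast between partitions, which the simulation tests recover.

## Synthetic data and what the tests show

The generator plants every ground truth the pipeline estimates:

* **Toy complexes** — straight-backbone chains of glycine-like
  single-heavy-atom residues at 14 Å inter-chain spacing, with designed
  events at globally unique columns: inter-chain approaches at 3.5 Å
  (contact), 5.5 Å (ASA occlusion without contact, i.e. interface), and
  48-atom same-chain cages that seal planted buried residues from the
  solvent probe.  The column spacing (12 Å) exceeds both the ASA occlusion
  radius (6.2 Å for carbon pairs) and the cage extent, so no unplanned
  relation can arise and classification must recover the planted classes
  exactly — which the acceptance suite requires at 100%.
* **Trees** — random unrooted binary topologies grown by uniform branch
  splitting; branch lengths i.i.d. exponential.
* **Codon alignments** — exact matrix-exponential sampling of the GY94
  process along the tree, per column independently, with
  partition-specific ω; stop codons cannot be emitted because the state
  space excludes them.
* **ΔΔG tables** — per-residue Normal draws with class-dependent mean/sd
  (defaults: contact classes ≈ 1.8–1.9 kJ/mol, exposed noncontact 1.4,
  buried 2.6 — the destabilisation ordering expected of an alanine scan of
  a membrane complex).

The default study conditions mirror the analysed system's shape: a
"full" preset with 13 chains (3 mt-encoded), per-class ω ordering
intra-genome contacts (0.05) < inter-genome contacts (0.20) < exposed
noncontact (0.40), buried 0.10, and the first mt chain's exposed surface
planted as exceptionally conserved (ω = 0.04) — the signature the
resampling null is designed to detect from both tails.  Taxon counts are
reduced (6–12) relative to a several-hundred-genome study; this keeps the
full pipeline and its calibration runs within desk-scale compute, and the
ω-recovery and LRT-calibration checks are run at matching sizes (6 taxa ×
600 codons × 20 replicates; 12 taxa for the positive-selection power check,
where few-taxon data are genuinely uninformative).

What passing tests do **not** show about real data: the generator has no
indels, no alignment error, no among-site rate variation beyond the planted
ω classes, no selection on synonymous codon usage, equal expected
substitution rate across partitions, and geometrically trivial structures.
Classification accuracy on real crystal structures depends on the ASA
method and exposure threshold in ways the planted geometry cannot probe;
distance-based contact counts are parameter-exact, ASA-derived counts are
not.

## Numerical and degenerate-input conventions

* Branch lengths are floored at 1e-8 to keep exp(Qt) well-conditioned.
* Identical-sequence alignments drive fitted branch lengths to the floor;
  the ΣdN of any subset is exactly zero.
* Zero-width classes produce explicit empty markers; empty partitions are
  skipped with a warning, and an all-empty partition set is an error.
* A zero denominator in the interaction ratio yields NaN rather than an
  exception, so reports can flag the comparison as undefined.
* Welch's unequal-variance t-test (two-sided) backs the ΔΔG group
  contrasts, with significance tiers at 0.05 and 0.0005 and no
  multiple-testing correction; zero-variance pairs are flagged degenerate
  instead of tested.  Group dispersion is reported both as SD and SE.
* The ΣdN–ΔΔG relation uses Pearson correlation with a t-distributed
  two-sided P (n − 2 df) and supports leave-one-out re-runs for leverage
  checks.

## Known limitations

* The YN00 tier omits the ω-iteration pathway reweighting; its dN is
  expected to track, not numerically equal, the original program's output.
* mmCIF structures, structure repair, and ΔΔG prediction are out of scope;
  ΔΔG values are consumed from an externally produced table.
* Free-ratio branch models, branch-site models and among-site rate
  variation beyond the fixed-sites/M1a/M2a structures are not implemented.
* The per-column cache used by the resampling machinery freezes per-pair κ
  and F3×4 weights at their full-alignment values; subset ΣdN under YN00
  therefore reuses the full-alignment mutation model, which is also what
  makes the null draws comparable to the observed subset.
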