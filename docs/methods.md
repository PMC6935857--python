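# Methods

This note records the models behind each module, the defaults that matter,
and the design decisions taken where more than one reasonable choice
existed.

## Redundancy filtering

Within one species, transcripts are collapsed longest-first: a transcript
is removed iff some larger retained transcript aligns to it locally with
nucleotide identity strictly greater than `identity_min` (default 0.98)
over a span covering at least `coverage_min` (default 0.70) of the shorter
sequence.  Identity is matches over aligned non-gap columns of the local
alignment (Smith–Waterman scoring 1/−1, gap open −2, extend −0.5, via
Biopython's PairwiseAligner); N never counts as a match.  Because
single-cell transcripts are unstranded, the reverse complement is also
compared (`both_strands=True`).  Length ties are broken by id, the earlier
transcript counting as the larger, which is what makes exact duplicates
collapse to one copy.  The thresholds are part of the published filtering
rule; the alignment scheme and strand handling are this package's choices
and are configurable.

## Transcript diversity

The substrate is a species × gene-family matrix of unique-transcript
counts.  Group means are taken over all (species, GF) cells by default
(zeros included; `include_zeros=False` restricts to occupied cells), which
makes the include-zeros mean a lower bound on the exclude-zeros mean.
Dispersion is IQR/median with type-7 (linear-interpolation) quantiles —
stated because the ratio depends on the convention.  The
"single-transcript GF" fraction counts a GF when no species of the group
exceeds one transcript (`strict=True` instead requires exactly one in every
species).  Group comparisons use Kruskal–Wallis across groups and two-sided
Mann–Whitney for pairs, both tie-corrected, on per-cell values by default
(per-GF group averages optional).

## Stop-codon usage and genetic-code inference

For each transcript and each scheme s ∈ {TAA, TAG, TGA}, a forced ORF is
the longest run of codons free of s.  Two procedural safeguards matter and
were set after a pilot quantified the artifacts (both configurable):

* **Frame anchoring.**  Scanning all six frames independently per scheme
  lets wrong-strand runs win whenever the forced stop is a reassigned
  (frequent) codon, flooding the counts with random off-frame stops.  The
  reading frame is therefore fixed first: candidate frames are those whose
  longest forced ORF (over schemes) is within 10% of the overall longest —
  the scheme matching the true code leaves the coding frame unbroken, so
  the coding frame is always a candidate — and among candidates the frame
  with the longest worst-scheme run wins, which rejects frames that merely
  happen to lack one stop codon over the whole transcript.
* **Tail trimming.**  Under a scheme that does not match the true stop, the
  forced ORF sweeps past the real termination codon into the 3'UTR and
  poly(A) tail.  The last `orf_tail_trim` codons (default 25) of each run
  are excluded from the stop tally (the denominator keeps the full run
  length), which removes the true-stop/UTR artifact of order 1/L per codon
  while shrinking genuine usage estimates by only the trimmed fraction.

In-frame frequencies are per codon scanned, pooled over the two schemes
where a codon is not the forced stop, over ORFs of at least
`min_orf_codons` (default 30).  A codon is classified a functional stop iff
its pooled frequency is ≤ `floor` (default 0.002) or ≤ `ratio_threshold`
(default 0.3) times the maximum of the three.  The two clauses serve
different codes: the floor recognizes the universal code, where all three
frequencies are residual artifact (~1e-3 from terminal stops that survive
in rare anchoring failures); the ratio clause recognizes single- and
double-stop codes, where the reassigned codons appear at coding density
(~1e-2 at the default usage rate) and dwarf the functional stop.  When no
codon passes either clause the pattern is flagged context-dependent (all
three stops reassigned, the Condylostoma situation); translation semantics
of such codes are not modeled, only detected.

Reassignments are read off reference protein alignments: in columns where
the query carries an in-frame stop (markers `*`, `#`, `@` for TAA, TAG,
TGA) and the modal reference amino acid exceeds 50% of the non-gap
reference residues (strictly; query excluded), the modal residue is tallied
for that codon.  A call requires `min_sites` (default 10) tallied columns
and a unique argmax, otherwise "uncertain" — ties are reported, never
guessed.  Building the alignments (aligner choice) is treated as plumbing;
tests and the generators construct them directly from known frames.

## Codon substitution model

The engine is an MG94×REV-style reversible model on the sense codons of
the working genetic code (61 states for the universal code, up to 64 for
fully reassigned codes): single-nucleotide neighbor rates are
exchangeability × target-codon frequency, times ω for nonsynonymous
changes under that code.  Frequencies default to F3x4 (positional
nucleotide frequencies with a 0.5 pseudo-count, product form restricted to
sense codons); exchangeabilities default to an HKY pattern with a single
transition/transversion ratio κ.

Rate matrices are normalized by the equilibrium rate of the *neutral*
(ω = 1) matrix with the same frequencies and exchangeabilities, not each by
its own rate.  Branch lengths are therefore expected substitutions per
codon under neutrality, and — decisive for mixtures — categories at
different ω keep their relative speeds.  Normalizing every category
separately would reduce ω to a pattern-only parameter and destroys most of
the power of branch-site tests; this was verified directly during
development.

Likelihoods use Felsenstein pruning on compressed site patterns with
per-node scaling.  Gaps and ambiguous codons are missing data (partial
likelihood 1), so a fully ambiguous column contributes zero log-likelihood.
All transition matrices come from one symmetric eigendecomposition per
distinct ω (the model is reversible), batched over branch lengths and
cached; this is what keeps maximum-likelihood fits at interactive speed.
Eigenvalues are clipped to ≤ 0 and rows that underflow entirely (enormous
effective rates) are replaced by the stationary distribution.

Two mixture conventions are implemented: per-branch mixtures, in which
each branch-site combination draws its rate class independently and the
branch's transition matrix is the weight-averaged P (the convention of
branch-site random-effects selection tests — this is what the group and
branch tests use), and shared site-level categories
(`tree_log_likelihood`), where one class applies to every branch of a
site.

## Group-level selection-intensity test

Branches are partitioned into a reference group (default NEF), up to three
test groups and a nuisance set by the labeling rule (a branch keeps a group
label iff all descendant branches share it).  Reference and test branches
share a 3-bin distribution 0 ≤ ω₁ ≤ ω₂ ≤ 1 ≤ ω₃ with free proportions;
test group g raises each ω to K[g] (clamped to [1e−9, 1e4] after
exponentiation for numerical safety — an effective ω beyond the ω₃ bound
is indistinguishable in the likelihood).  Nuisance branches get their own
3-bin distribution.  The null pins every K[g] = 1; the alternative frees
one K per test group present in the tree (groups without branches are
dropped with a warning and the degrees of freedom reduced).  Significance
is a likelihood-ratio test against χ² with df = number of free K.

Numerical choices: ordering is enforced by reparameterization (ω₂ =
σ(a₂), ω₁ = σ(a₁)·ω₂, ω₃ = 1 + eᵘ, weights by softmax); K is optimized on
the log scale within [0.01, 50].  Branch lengths and κ are fixed from a
3-parameter prefit (global tree scale, κ, single ω) and held constant
across the nested fits — joint per-branch optimization is out of scope at
desk scale.  Optimization is bounded L-BFGS-B with finite differences,
convergence target 1e−4 in absolute log-likelihood, iteration caps
(~60), one full run plus two short perturbed probe runs (the best probe is
polished); the alternative warm-starts from the null solution, which also
guarantees the nesting inequality logL_alt ≥ logL_null.  The exploratory
fit (every group its own distribution) warm-starts from the alternative
mapped exactly through the K powers, so logL_exploratory ≥ logL_alt as
well.

The estimate K̂ is heavy-tailed at these data sizes: when ω₁ is far below 1
the likelihood flattens in K beyond the truth, so K̂ frequently hits the
upper bound while the LRT stays well behaved.  Interpret the direction of
K̂ and the test's p-value, not the magnitude.

Conditional negative-selection means are Σ pᵢωᵢ / Σ pᵢ over bins with
ω ≤ 1 — bins at exactly 1 included by default because the exploratory
summaries are described that way; a strict ω < 1 mode exists.  The
ordered-trend statistic is Jonckheere–Terpstra (sum of pairwise
Mann–Whitney counts over ordered group pairs, ties counted ½), with a
tie-corrected normal approximation, full enumeration for pooled n ≤ 12,
or Monte Carlo permutation.  The implemented default ordering for the
biological question is the a priori Karyorelictea < NEF < Heterotrichea <
EF on the negative-selection means.

## Per-branch episodic selection

A simplified two-class branch-site test: background branches share one ω;
the focal branch mixes a constrained class (ω₁ ≤ 1, free weight) with a
free class ω₂ ≥ 1; the null pins ω₂ = 1.  Adaptive selection of the number
of ω classes per branch — the defining refinement of the full
branch-site procedure this simplifies — is deliberately not implemented;
two classes keep every fit a 3–4 parameter problem.  P-values use the
boundary mixture ½χ²₀ + ½χ²₁ and are Holm-corrected across the branches
tested in one tree.  Paralog branches are terminal branches whose species
contributes ≥ 2 sequences to the alignment (internal branches are excluded
from both fractions; a subtree-based definition is not asserted).  Per
alignment and group, the fractions of selected branches among paralogs and
orthologs are compared across alignments by a paired two-sided Wilcoxon
signed-rank test (≥ 5 pairs required; all-zero differences give p = 1).
Alignments shorter than `min_codons` (default 20) are flagged
unidentifiable with p = 1 rather than fitted.

## Synthetic data

The generators are pure functions of their configs (the seed fixes every
stream; identical configs give identical bytes) and each dataset ships a
ground-truth record.

* **Transcriptomes**: coding codons drawn from an AT-rich product-form
  codon distribution (positional nucleotide frequencies 0.3/0.2/0.2/0.3,
  canonical stops excluded), reassigned stops inserted in frame at a
  configurable total rate (default 0.02 per codon, split uniformly among
  the code's reassigned stops), then a terminal functional stop, a short
  random 3'UTR (default 15 nt) and a poly(A) tail (default 30 nt).  Default
  size 50 transcripts × 300 codons.  True proteins are emitted for
  reference alignments, whose rows are the truth perturbed by random
  substitutions (default rate 0.1 across 8 references).  Not emulated:
  sequencing error, assembly artifacts, chimeras, expression-level
  variation, 5' truncation — so code-recovery results bound what clean
  data allow, not what noisy assemblies deliver.
* **GF count matrices**: zero-inflated Poisson per (species, GF) with
  group-specific mean and inflation; the Poisson rate is mean/(1 −
  inflation) so the marginal mean equals the configured group mean.
  Defaults echo the four focal groups: means H 1.25, EF 0.92, NEF 0.67,
  K 0.18 over 509 GFs and 8/12/15/11 species, inflation 0.35/0.4/0.45/0.6
  (zero-heavier for sparser groups; chosen once as a plausible shape, not
  fitted to data).  Real matrices have correlated species and GF effects
  that the independent-cell model lacks.
* **Trees**: random joins within monophyletic group blocks (4 taxa per
  group by default), then across blocks, exponential branch lengths (mean
  0.1 substitutions/codon); species listed with extra copies contribute
  paralog leaves.  A mixing switch interleaves groups to exercise nuisance
  labeling.
* **Codon alignments**: root states from the equilibrium distribution (a
  product form, so F3x4 is correctly specified), each branch-site drawing
  its ω bin independently with shared proportions, branch ω = reference
  ω^K[group], nuisance branches defaulting to the reference distribution,
  per-branch overrides available for planting episodic selection.  Default
  200 codons, reference distribution (0.05, 0.4, 2.0) with weights (0.6,
  0.3, 0.1), κ = 2.

At the default simulation sizes (16 taxa, 200 codons, mean branch 0.1) the
group test holds its nominal level, but its power against K = 2 on one
group is modest and K̂ is noisy — the evidence per dataset is genuinely
small, as the flat likelihood profiles at the true parameters show.
Likewise, the partitioned exploratory fits are weakly identified per group
at this size: the maximum-likelihood 3-bin shape often collapses the two
ω ≤ 1 bins toward 0 and absorbs intermediate sites into the ω₃ bin (this
collapse scores a genuinely higher likelihood than the generating
distribution, so it is not an optimizer artifact), which makes the
conditional negative-selection means a noisy per-alignment summary.
Genome-scale analyses of this kind aggregate hundreds of alignments;
nothing at desk scale substitutes for that.

## Known limitations

* Reference alignments for reassignment inference are inputs; no aligner
  is bundled, and badly aligned references will mislead the conserved-
  column vote.
* The context-dependent (Condylostoma-type) pattern is detected, not
  modeled: no 3'UTR-proximity term enters any likelihood.
* Branch lengths are rescaled once globally, not re-optimized per model;
  confidence intervals on K are not computed.
* The codon model has no synonymous rate variation and no amino-acid-level
  exchangeability structure.
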