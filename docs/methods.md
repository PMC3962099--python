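# Methods

## Counting model

All statistics are computed from ordered residue-pair counts over a protein
sequence set. A pair at gap *g* is the ordered couple of residues at
positions (i, i+g+1); windows overlap with step 1, so a clean sequence of
length L contributes L−1−g windows ("AAA" contributes two AA pairs). Only
the 20 standard residues are counted: non-standard letters (B, J, O, U, X,
Z) are retained in sequences but excluded as window *endpoints* — at g > 0
they may freely appear between the endpoints, since the intercalated
residues are by construction "of any type". The `'*'` character is a hard
separator that no window may cross; it appears in translations of coding
sequences at stop codons, so no dipeptide ever spans a stop. Dropping whole
sequences that contain a stray non-standard letter would waste data;
excluding only the affected windows does not bias the remaining counts.

A leading N-terminal methionine can optionally be removed before counting
(`skip_initial_met`, default off). Databases retain the initiator Met
inconsistently, which inflates MX counts relative to XM; the default is to
observe rather than correct this bias, matching how the phenomenon was
originally reported.

## Asymmetry and propensity

For each of the 190 unordered pairs of distinct residues,
c190 = |n_AB − n_BA| / ((n_AB + n_BA)/2), reported ×100. The statistic is
scale-invariant (doubling all counts leaves it unchanged), symmetric in its
arguments, 0 for balance and 200 in the one-sided extreme. The signed
variant keeps the sign of n_AB − n_BA in the alphabetical orientation of
the pair. Same-residue pairs carry no orientation and are ignored.

The propensity P(BJ) = (n_BJ/n_XJ)/(n_BX/n_XX) measures enrichment of B
before J relative to independence. It satisfies the algebraic identity
Σ_B P(BJ)·(n_BX/n_XX) = 1 for every column J with n_XJ > 0, which the test
suite verifies to 1e-9 on random tables.

Zero denominators (a pair never observed in either orientation; a zero
marginal) are flagged undefined and excluded from averages and rankings —
never silently zeroed. Per-residue averages are taken over the residue's
defined pairs with the divisor reduced accordingly; the standard error uses
the n−1 sample standard deviation over √n, reported as 0 when a single
value remains. Reports round to 2 decimals; internal arithmetic is full
precision. Ranking ties break alphabetically (ties never occur at printed
precision on real-scale data).

## FPPP subsampling

To ask whether a set is large enough for stable c190 estimates, the set is
randomly permuted (seeded), cut into floor(N/size) disjoint subsets of
exactly `size` proteins (leftovers discarded), and the 190 statistics are
recomputed per subset. The per-pair mean and standard error across subsets
are tabulated for increasing sizes next to the full-set value. A
random-permutation partition is used rather than input-order chunking to
avoid input-ordering artifacts (database order is rarely exchangeable).
The classic subset-size ladder {1000, 3000, 6000, 12000} is the default
configuration; tests use smaller ladders scaled to their synthetic sets.
A sequence-level bootstrap (resampling whole proteins with replacement) is
provided for per-pair standard errors of the full-set estimate.

## Synthetic ground truth

Sequence sets are generated from a first-order Markov chain over the
20-residue alphabet — the minimal family with controllable adjacent-pair
asymmetry and an exact closed form: at stationarity the expected gap-g
count is E[n_AB] = (L−1−g)·π[A]·(T^(g+1))[A][B], so every pair's analytic
c190 is available and lengths cancel.

Two presets:

- `symmetric` — the uniform chain; every pair's analytic c190 is exactly 0.
  Eight pairs (AR, CD, DV, EY, FT, HT, PR, ST) are designated null
  controls.
- `table3_asymmetric` — the uniform chain perturbed so seven pairs (EP,
  PW, MW, GP, AM, IP, CP) reach asymmetries of roughly 21–34 (×100 scale),
  the magnitudes of the strongest pairs seen in large natural sets, with
  the naturally dominant orientations. The perturbation multiplies the
  dominant transition T[A][B] by (1+δ) and its mirror by (1−δ) with row
  renormalization; δ is solved per pair by Brent root-finding on the signed
  analytic c190, with three coordinate sweeps because five of the seven
  pairs share the proline row. The preset stores the analytic values
  recomputed from the final matrix, so recovery tests compare generated
  data against the model's exact truth, not the nominal targets.

Because the perturbed chain mixes rapidly, T^6 is nearly uniform and the
analytic gap-5 asymmetry of every engineered pair is orders of magnitude
below its gap-0 value — the model reproduces the observation that
separating the residues by five positions collapses the asymmetry.

What the generator does *not* emulate: residue composition bias, domain and
repeat structure, length variation, phylogenetic redundancy, and any
correlation beyond first order. Passing recovery tests therefore
demonstrates the pipeline's correctness on a known truth, not that natural
proteomes are first-order Markov.

Reverse translation maps each residue independently to a synonymous codon
of the standard genetic code, uniform over synonyms by default (a
codon-usage vector per residue can be supplied). Translation of the result
recovers the protein exactly for stop-free sequences.

## Mutagenesis experiment

For each gene and mutation scheme, mutants are generated from a single
seeded stream: deletions remove k distinct uniformly chosen bases
(preserving order); substitutions replace k distinct uniformly chosen bases
by one of the three alternatives, uniformly. The four standard schemes —
delete 1, delete 5, substitute 10, substitute 50 bases, 100 mutants per
gene (configurable; desk-scale tests use 20) — ship as a preset.
Translation is frame 1, forward strand, standard code, `'*'` emitted at
stops and translation continuing to the end (batch-translator behaviour;
truncating at the first stop would discard most of a frameshifted gene).
Mutant translations are pooled across genes and mutants before computing
statistics, mirroring how a natural set is pooled; per-pair deltas
(mutant − wild type) are reported for c190 and propensity.

**Known limitation / finding.** Frameshifting mutations do *not* leave the
dipeptide statistics unchanged in this generative model. Codons read out of
frame are strongly directional: the frame-shifted translation of
uniform-synonymous-codon DNA has systematic pair asymmetries up to c190 ≈
120 (e.g. DW), far above sampling noise. Deletion mutants therefore pool
wild-type-like and shifted-frame material and differ systematically from
wild type, while substitution schemes (no frameshift; every mutant window
aligns with its wild-type window) match wild type closely. The
corresponding invariance test asserts the strict claim — no pair moves by
more than 3 pooled standard errors under any scheme — and accordingly
fails for the deletion schemes while passing for substitutions; the
assertion is kept strict because it documents the precise sense in which
the invariance claim does and does not hold. Pooled SE combines wild-type
and mutant FPPP standard errors (10 subsets each) in quadrature.

The experiment's desk-scale conditions are 500 genes of 900 bases obtained
by reverse-translating proteins drawn from the symmetric preset — the
correct null for "do random mutations create asymmetry?" (an asymmetric
source would confound the question with dilution of its engineered signal
by frameshift-scrambled material).

## Numerical and interface choices

- Stationary distributions come from the eigendecomposition of Tᵀ; the
  unit eigenvalue must be simple and the fixed-point residual below 1e-10,
  otherwise the chain is rejected as reducible. Tests cross-check against
  power iteration.
- All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces every generated set, partition, mutant and report
  bit-for-bit.
- Sampling-noise scale for a balanced pair with total count n is
  ≈ 200/√n (×100 scale); stochastic tests use 3–4 SE bands derived from
  bootstrap, FPPP or binomial approximations, never fixed magic tolerances.
- TSV everywhere, with `#`-prefixed metadata headers (tool version, config,
  seed) so files remain machine-parseable; logging goes to stderr. CLI exit
  codes: 0 success, 1 user error, 2 internal (argument-parsing errors exit
  2, the click convention).
- Test problem sizes (e.g. 2,000×500-residue recovery sets, 200 null
  replicates of 100×200, the 500-gene experiment with 20 mutants per gene)
  are chosen so that each engineered effect exceeds its sampling noise by a
  comfortable factor while the whole suite stays fast.
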