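# Methods

`photoevol` implements a molecular-evolution analysis of highly conserved,
plastid-encoded photosystem proteins: it maps amino-acid substitutions onto
the branches of a fixed species phylogeny, asks which of them recur more
often than a neutral model of sequence evolution predicts, classifies
site-wise selection from codon data, annotates sites with structural context
(cofactor binding, intersubunit interfaces), and scores the predicted effect
of substitutions on interface stability. Because the real inputs (hundreds of
plastid genomes, cryo-EM photosystem structures, web-service free-energy
predictions) cannot be bundled, a synthetic-data generator reproduces every
input type at desk scale with recorded ground truth.

## Substitution model

Sequence evolution is a reversible continuous-time Markov chain on the 4- or
20-state alphabet. A model is a triple (S, π, {(r_c, w_c)}): symmetric
exchangeabilities S, stationary frequencies π, and a rate-category mixture.
The generator Q_ij = S_ij·π_j (off-diagonal) is rescaled so that
−Σ_i π_i Q_ii = 1, and category rates are normalized so Σ_c w_c r_c = 1;
branch lengths therefore read directly in expected substitutions per site.
Transition probabilities P(t) = exp(Q r_c t) are computed through the
symmetric eigendecomposition of D^{1/2} Q D^{−1/2} (D = diag π), which is
exact, numerically stable, and cheap enough to cache per branch length.

Shipped empirical amino-acid exchangeabilities: JTT (default), WAG, LG, in
PAML-format data files; '+F' frequencies are counted from the alignment with
ambiguity codes contributing fractionally. Among-site rate variation is
either an explicit free-rate list or a discretized gamma with mean-of-
quantile bins (shape α, n equal-weight categories; the category mean is
exactly 1 by construction). Free-rate category values estimated by external
tools can be passed straight in; the package itself estimates only branch
lengths.

## Likelihood, branch lengths, ancestral states

The pruning (sum-product) algorithm runs over postorder-indexed arrays of
shape (categories, sites, states) with per-node log-space rescaling, so
alignments of hundreds of taxa do not underflow. Gaps and ambiguity codes
are missing data: their conditional likelihood is 1 over every compatible
state.

Branch lengths on the fixed topology are fitted by coordinate-wise bounded
scalar minimization (Brent), sweeping all branches until the total
log-likelihood improves by less than `tol` (default 1e-6, at most 50
sweeps); a proposal is accepted only if it does not decrease the
likelihood, so the trajectory is monotone. Non-convergence returns a
flagged result rather than raising.

Ancestral reconstruction is marginal: an inside/outside pass yields, for
every internal node and site, the posterior over states per rate category;
categories are mixed by their per-site posterior weights
w_c L_c(site)/Σ_c' w_c' L_c'(site), and the MAP state breaks ties toward
the lowest alphabet index (PAML residue order), deterministically. No
posterior cutoff is imposed; posteriors are recorded for downstream
filtering.

## Substitution events and recurrence

Events are endpoint comparisons along every parent→child edge (leaves use
observed rows, internal nodes their MAP sequences); a site yields an event
only when both states are concrete. Branches inside a tagged outgroup
clade are excluded. Multiple hits on one branch collapse into a single
observable difference — the counting matches what any parent/child
comparison can see. Per-site count matrices store parents in columns and
children in rows.

A recurrent substitution is an X→Y replacement with count k ≥ 2 at one
site. Its significance is judged against a simulation null that includes
reconstruction error: each replicate re-simulates the alignment from the
fitted model, tree, and reconstructed root sequence (per-site rate category
drawn once from the mixture weights), re-runs marginal reconstruction on
the simulated leaves, and re-counts recurrences. Replicate r uses spawned
child stream r of the master seed, so replicates are independently
reproducible. A key is significant when no replicate reaches its observed
count; the empirical p-value is reported with the add-one rule
p = (m+1)/(N+1), and a flag notes when N is too small for p < 0.001.

Two matching modes are exposed. The default, `per-site`, compares the
observed count at (site, X→Y) with the null count at the same key — the
literal reading of the definition. The alternative, `per-type-max`,
compares it with the maximum count of X→Y over all sites within each
replicate. The per-site mode is anti-conservative in a specific,
quantifiable sense: only keys with k ≥ 2 are tested, and conditioning on
that rare event breaks the naive "1/(N+1) per tested key" intuition (the
exchangeability bound holds over all possible keys, most of which are never
tested). In a seeded experiment with observed and null data drawn from the
identical process, per-site matching called ~13% of tested keys
significant, while per-type-max called ~0.6% against the 0.50% bound.
Calibration claims in this package's validation suite therefore use
per-type-max; per-site remains the default because it is the definition's
literal reading, and its empirical p-values are reported unchanged.

Power was verified by injection: a column re-simulated with root state X
(re-drawn until at least 80% of background leaves carry X), with Y written
onto all leaves below 8 well-separated terminal branches (pairwise path
separation ≥ 0.05 substitutions/site; adjacent origins would be merged into
one ancestral event by reconstruction, and large injected clades can even
flip the inferred direction at saturated sites). Under the default study
conditions the injected site is recovered with k = 8 and flagged
significant in ≥ 80% of seeded repetitions at N = 200.

## Site-wise selection (counting classifier)

The package does not re-implement likelihood site-model machinery (per-site
ML rate estimation or Bayesian posterior grids). Instead, a documented
counting classifier operates on branch-mapped codon changes: single-step
changes are classified by the genetic code (default: translation table 11,
the plastid/bacterial code); multi-step codon changes average N/S counts
over all orderings of the single steps, excluding orderings that pass
through a stop codon. Each site's neutral nonsynonymous proportion p_N is
computed from the parent codons observed at its events: the nine
single-nucleotide neighbors are weighted by the nucleotide model's relative
rates, mutations to stops are excluded, and p_N is the weighted
nonsynonymous fraction (codons with no synonymous neighbor, e.g. Trp and
Met, give p_N = 1 and are clipped into the open interval for the test).
One-sided binomial tails of N_obs against p_N at n = N_obs + S_obs give
positive- and purifying-direction p-values; classes additionally require
the corresponding rate-analogue direction (β > α or α > β). Raw p-values
drive the default classification (threshold 0.1); Benjamini–Hochberg
adjusted columns are reported alongside. Externally computed site tables
with a posterior P(β > α) column can be imported and thresholded at 0.9.

## Structural context and interface effects

Cofactor-binding residues are polymer residues with at least one heavy atom
strictly closer than 4.0 Å to any heavy atom of a selected hetero residue;
interface residues are the symmetric inter-chain analogue. Neighbor
searches use a k-d tree and are property-tested for exact set equality
against the all-pairs scan. The distance rule is a stated approximation to
curated interface databases, with the cutoff configurable and external
residue lists accepted as drop-in input. Structure chains are mapped onto
alignment columns by global pairwise alignment (match +1, mismatch −1, gap
open −5, extend −1); columns that are gaps in the reference row are
unmapped, and maps below 30% identity carry a warning flag.

Interface-effect classification takes per-substitution ΔΔG values
(kcal/mol) as input: ΔΔG ≤ −0.5 stabilizes the interface, ≥ +0.5
destabilizes, the rest is negligible. The threshold is applied inclusively
(|ΔΔG| ≥ 0.5); no value in the packaged 19-row table sits on the boundary.
ΔΔG computation itself is out of scope — values come from external
predictors.

## Enrichment statistics

Residue-set overlaps use the exact hypergeometric tail (enrichment
P(X ≥ x), depletion P(X ≤ x)); group comparisons use Welch's two-sample or
the one-sample t-test (two identical zero-variance groups give p = 1 by
convention, flagged); the site-count-versus-length relation uses ordinary
least squares with R², slope, and the two-sided slope p-value. The residue
universe for overlap tests is configurable (structure-resolved positions or
all alignment columns) and is echoed in the report.

## Synthetic data

The generator emulates the study inputs: Yule trees (two lineages from the
root, Exp(n·λ) waiting times, branch lengths rescaled to a requested
root-to-tip height), alignments evolved down the tree with recorded true
histories, optional injected convergence, two-chain poly-alanine toy
structures with a ligand at exactly requested distances, and the packaged
ΔΔG table. Everything is a pure function of (parameters, seed);
text outputs are byte-identical across runs.

Default study shape (the packaged scenario): 50 leaves, root-to-tip height
0.2 substitutions/site, three amino-acid genes (200/150/100 sites) under
JTT+F with 4 gamma categories (α = 1), one 100-codon gene under a
transition-biased GTR, N = 200 null replicates, no injected convergence.
The height was chosen to mirror the extreme conservation of the real
system — most sites invariant, per-residue substitution counts of order
one across the whole tree; at height 0.5 fast-category sites saturate and
marginal reconstruction can flip the direction of a convergent column
(the root posterior drifts toward the stationary frequencies). The two
extra amino-acid genes exist so the per-protein regression and the
between-gene comparisons execute in the default run.

What the generator does not emulate: indels (alignments are gap-free unless
supplied), codon-level selection (convergence is injected by construction,
not by ω > 1), non-reversible or lineage-heterogeneous processes, and real
structure geometry. Passing tests therefore show the machinery is correct
under the model's own assumptions, not that the biological conclusions of
any particular dataset are reproduced.

## Numerical choices and limitations

- Likelihood scaling is per node, category and site; site likelihoods below
  1e-300 are floored before logs, never silently zeroed.
- Transition matrices are clipped to [0, 1] and row-renormalized after
  eigendecomposition reconstruction (deviations are at round-off level).
- MAP ties break toward the lowest index in PAML residue order.
- Branch-length optimization is bounded at 50 substitutions/site; sequences
  with no variation drive lengths to the 0 bound.
- The pipeline runs each stage from files in the run directory, so stages
  can be re-run individually; the manifest records config, seed, package
  version and stage timings (timings are the only non-deterministic output).
- The recurrence null conditions on the reconstructed root sequence and the
  estimated branch lengths; both estimation steps make the observed side
  slightly non-exchangeable with the null. This is inherent to the design
  (the real ancestors are unknown) and is quantified by the calibration
  experiment above.
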