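# Methods

## Model and assumptions

The method treats pathway association as a network-proximity problem.  Its
core assumption is that genes whose basal expression correlates with a
compound's response (RCGs) are concentrated near the mediating pathway in
the gene–gene interaction network, even when they are not members of it.
Three ingredients encode that assumption:

1. **Heterogeneous network.**  Genes and pathways are nodes of one
   symmetric graph H = [[A, B], [Bᵀ, 0]]: weighted gene–gene edges (A,
   weights in [0, 1]), binary gene–pathway membership edges (B), and no
   pathway–pathway edges.  Pathways therefore interact only through their
   members and the members' network neighbourhoods.
2. **Diffusion states.**  A random walk with restart from source node i
   has stationary visitation distribution s_i solving
   s_i = r·e_i + (1−r)·s_i·P, with P the row-stochastic transition matrix
   of H.  The rows of S are network-context fingerprints: two nodes whose
   walks visit the same neighbourhoods get similar rows.  Zero-degree
   nodes keep the walker in place (transition row = indicator), which
   embeds them as near-isolated rather than making normalization
   undefined.
3. **Diffusion component analysis (closed form).**  S is compressed by
   L = log(S + c) − log c with pseudocount c = 1/(n+m), followed by a
   truncated SVD and V = U_d·√Σ_d.  The log transform turns the
   multiplicative, heavy-tailed visitation probabilities into an
   approximately additive similarity that SVD factorizes well.  We chose
   the closed-form variant over gradient-based KL optimization because it
   is deterministic and dependency-light while serving as an accurate
   surrogate; any embedding meeting the same contract (similar vectors for
   network-proximal nodes) could stand behind the same interface.  The
   SVD sign ambiguity is fixed by making each singular vector's
   largest-magnitude entry positive; cosine scores are invariant to that
   choice, but outputs become bitwise reproducible.

   One property worth stating precisely: with V = U_d·√Σ_d the cosines of
   rows of V at full rank equal the cosines of rows of U·Σ only up to the
   singular-value weighting; the lossless-factorization check in the test
   suite is therefore phrased on U·Σ and on the spectrum of V, not on V's
   raw cosines.

The compound–pathway score is the correlation-weighted sum of cosines
between the pathway vector and the RCG vectors,
s_ij = Σ_k w_k·cos(V_k, V_{i+n}).  The displayed sum (not the mean) is the
primary definition; a `normalize="mean"` option exists because the mean
variant changes cross-compound comparability but never a within-compound
ranking.  Scores only rank pathways: a negative score indicates lack of
evidence, not negative association.

## Empirical p-values

For a compound with q usable RCGs we draw k random gene sets of size q
uniformly from the embedded genes, assign them the observed weight vector
in permuted order (preserving the weight profile; an all-ones alternative
is available), and score each set against all m pathways.  The observed
score's p-value is its add-one fractional rank in the pooled k·m null
scores, p = (1 + #{null ≥ s}) / (1 + k·m).  The add-one correction avoids
p = 0 and is the standard permutation-test form; it makes p values live on
(0, 1] with granularity 1/(k·m+1).  Random sets are drawn from the
embedded-gene universe because scores are undefined off-embedding.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| restart probability r | 0.5 | balance of local vs global network context; results are stable over a broad middle range |
| embedding dimension d | 100 | enough to separate ~hundreds of pathway neighbourhoods; tests use 4–32 at fixture scale |
| DCA pseudocount c | 1/(n+m) | keeps log finite; scales with network size |
| RCG threshold | p < 1e-4, Bonferroni | per-compound family by default (matches the per-compound construction of RCG sets); global or numeric multipliers are options |
| RCG cap | 250 | at most the top 250 most significant genes per compound |
| compound filter | > 5 RCGs | pathway analysis is meaningless with very few correlated genes |
| null size k | 10,000 | p-value granularity 1/(k·m+1) |
| Fisher universe | expression ∩ network genes | keeps the baseline and the embedding method comparable; configurable |
| DEG rule | top 250 by max \|z\| across conditions, \|z\| > 2 | symmetric treatment of up-/down-regulation; a signed-max mode is available |

Statistical conventions: Pearson p-values use the t transform with n−2
degrees of freedom after pairwise-complete deletion of missing values
(pairs with fewer than 3 shared cell lines or zero variance are recorded
missing); Fisher enrichment is one-sided (upper tail) with
Benjamini–Hochberg FDR across the pathways of one compound; the
Kruskal–Wallis baseline uses the full correlation profile (all genes, not
only RCGs), tie-corrected H with a chi-square p at 1 df, and returns
H = 0, p = 1 when every value is tied rather than dividing by a zero tie
correction; the degree-association test is a two-sided Mann–Whitney
rank-sum on weighted degrees (a paired signed-rank test is ill-defined for
two independent, unequally sized gene groups); AUROC uses midrank tie
handling.  Ranking tie-breaks are deterministic everywhere (score ties by
pathway id, p ties by larger |r| then gene id), and RCG genes are
canonically ordered before summation so scores are bitwise independent of
input order.

## What the synthetic generator emulates

`pacer.synthetic` plants all the structure the method exploits, at desk
scale (defaults: 400 genes in 20 communities of 20, one pathway per
community, 200 cell lines, 10 compounds, effect size 0.5):

- **Network**: a stochastic block model (p_in = 0.4 within communities,
  p_out = 0.01 across, edge weights U(0.5, 1)).  Communities give a
  controllable notion of network proximity, which is the property the
  embedding uses; a preferential-attachment graph would not.
- **Pathways**: random subsets of communities (80% of a community in
  `member` mode; half of it in `adjacent_only` mode, with the other half
  reserved so planted genes are community neighbours but never members —
  and each reserved gene is guaranteed at least one edge into the
  pathway).
- **Pharmacology**: each compound's planted genes and its response load on
  a shared latent factor, x_g = √ρ·f + √(1−ρ)·ε and y = √ρ·f + √(1−ρ)·η,
  so every planted gene has marginal expression–response correlation
  exactly ρ for any number of planted genes (8 by default), and planted
  genes are mutually correlated the way co-regulated pathway genes are.
  An additive independent-gene model cannot reach per-gene correlation
  0.5 with 8 planted genes, which is why the factor form is used.
  Effect size 0 produces a pure-null scenario.
- **Perturbation profiles**: planted DEGs get |z| > 2 in one random
  condition; background z is N(0, 0.5), so background genes rarely pass.

What it does **not** emulate: microarray noise structure, batch effects,
dose–response curve estimation, overlapping or nested pathways, scale-free
degree distributions, and identifier-mapping problems.  Passing the
planted-recovery benchmarks therefore shows that the implementation
exploits network proximity as designed — not that the method will attain
any particular accuracy on real pharmacogenomic data.

## Numerical choices

- RWR is solved directly (S = r(I − (1−r)P)⁻¹) for networks up to 2,000
  nodes and iteratively above that; the test bench proves the two agree to
  1e-8.  Iteration stops when the maximum row-L1 change falls below 1e-12
  (geometric convergence at rate 1−r) and errors with the residual on
  non-convergence.
- Cosine of a zero vector is 0 by convention: an unreachable node carries
  no evidence for any pathway.
- Null-set scoring is chunked so peak memory stays bounded at realistic
  sizes (k = 10,000, 250-gene sets, hundreds of pathways).
- Benchmarks report per-seed results at the default desk scale; a full
  member-plus-adjacent run (2 × 20 seeds) plus the 500-replicate null
  calibration completes in well under a minute on one CPU.

## Known limitations

- The embedding is transductive: adding a gene or pathway requires
  re-fitting; there is no out-of-sample transform.
- Empirical p-values pool nulls across pathways, as the score definition
  prescribes; pathways with atypical embedding geometry (e.g. very large
  or very peripheral ones) inherit a shared null that may be mildly mis-
  calibrated per pathway even though the pooled p-values are uniform under
  the null.
- Gene identifiers are opaque strings; cross-namespace mapping (probe IDs,
  STRING protein IDs, HGNC symbols) is deliberately out of scope, as is
  computing STRING's per-channel scores (only their Bayesian combination
  is provided).
- The perturbation-concordance protocol is granularity-limited at desk
  scale: with m = 20 pathways and single-pathway predicted/reference sets,
  the smallest attainable overlap p is exactly 1/20 = 0.05, so the strict
  p < 0.05 rule can never fire.  The protocol becomes informative only
  with a pathway universe in the hundreds (as in real collections) or
  multi-pathway predictions; at fixture scale the machinery is validated
  against enumeration oracles instead.
- Dense diffusion/SVD at >10,000 nodes is memory-hungry; the intended
  operating point of this implementation is method development and
  benchmarking, not genome-scale production runs.
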