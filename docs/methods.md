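# Methods

## Model and procedure

The package operationalizes a three-stage construction per tumor sample.

**1. Sample-specific network.** Let X be a gene × sample expression matrix
(FPKM-scale, used as provided — no log transform) with n reference (normal)
samples and a set of case (tumor) samples, and let B be an undirected
background network over gene symbols. For every background edge the
reference weight is pcc_n, the Pearson correlation of the endpoint genes
over the n reference samples. For case sample d, pcc_{n+1} is the same
correlation over the reference samples plus d, and Δpcc = pcc_{n+1} − pcc_n.
For a case sample drawn from the reference population, Δpcc has mean 0 and
null scale

    s = (1 − pcc_n²)/(n − 1),

and the edge statistic is z = Δpcc / s with a two-tailed standard-normal
p-value. A point to be explicit about, because the notation invites error:
the dispersion of a one-sample correlation update is O(1/n), and s above is
the **standard deviation** of Δpcc, not its variance — dividing Δpcc by
√s would shrink z by a factor of ~√n and no edge would ever be retained.
The suite verifies by simulation that sd(Δpcc)/s ≈ 1 at n = 100 for
pcc_n ∈ {0, 0.5, 0.8}. Edges with p < `alpha_ssn` (default 0.01) form the
SSN of sample d. No multiple-testing correction is applied across edges;
the threshold is a raw per-edge level.

Degenerate cases are excluded rather than forced: background edges with an
endpoint missing from the expression matrix, edges whose reference
correlation is undefined (constant gene) or |pcc_n| = 1 (zero null scale),
and edges whose (n+1)-sample correlation is undefined. All exclusions are
counted and logged.

**2. Alteration profiles.** The mutation matrix M is binary on genes ×
case samples (any positive nonsynonymous count → 1). Methylation
processing: probes with missing values in strictly more than
`max_na_fraction` (default 0.10) of samples are removed; remaining gaps are
imputed from the `knn_k` (default 10) nearest probe rows by NaN-aware
Euclidean distance with uniform averaging (scikit-learn's KNNImputer, which
implements exactly these semantics; a probe with no usable donor falls back
to its row mean). Promoter probes — regions TSS1500, TSS200, 5′UTR,
1stExon — are consolidated per gene and sample by the median; genes without
promoter probes are absent from the output, and a probe annotated to
several genes contributes to each. The Hampel filter then flags, per gene
across samples, values strictly below MED − 3·MAD as −1 and strictly above
MED + 3·MAD as +1, with MAD the raw (unscaled) median absolute deviation.
Values exactly at a bound are not flagged, and the comparison carries a
1e-9 relative guard so binary floating-point representation cannot flip an
exact-boundary value. When MAD = 0 the literal rule applies (any departure
from MED is flagged) and the per-run flagged fraction is logged so such
genes are visible. MED/MAD are computed over the case samples the matrix is
built from; `hampel_ternary` accepts an explicit sample list for callers
who want to include normals.

**3. Driver modules.** Hub genes of an SSN are the nodes whose degree
reaches the degree at rank ⌈0.20 · |nodes|⌉ (ties included, so the hub set
is order-independent and at least the ceiling size). Given seed genes S
(mutated, or |MT| = 1, intersected with SSN nodes), the retained edges are

    {(s,u) : s ∈ S, u ∈ N(s), u hub}  ∪  {(u,w) : s ∈ S, u ∈ N(s) hub, w ∈ N(u), w hub}.

The 2-order/hub principle is stated in the literature as two conditions,
not an algorithm; this edge rule is the literal reading ("neighbors and
neighbors' neighbors must be hubs") with one deliberate exemption: seeds
themselves need not be hubs, since altered genes empirically sit at low
degree and requiring hub status of seeds would empty most modules. A
seed–seed edge is therefore retained only if one endpoint qualifies as a
hub. The co-driver module is the edge union of the sample's mutation and
methylation modules.

**Aggregation.** Edge frequency = fraction of samples whose module
contains the edge, over the full background universe (unseen edges have
frequency 0). The Monte Carlo cutoff draws `mc_edges_per_iter` edges
uniformly with replacement per iteration (without-replacement available by
flag), takes the empirical (1 − `mc_alpha`) quantile of their frequencies
(type-7 linear interpolation, numpy's default), and averages over
`mc_iterations` iterations; the cohort module keeps edges with frequency
strictly greater than the cutoff. As iterations grow the cutoff converges
to the exact quantile of the full frequency table, which is what the oracle
test checks at reduced scale. Subtype modules keep edges with
within-subtype frequency strictly above `subtype_threshold` (default 0.60)
of that subtype's co-driver modules; shared edges are the intersection over
subtypes, specific edges those in exactly one subtype module. Module-size
comparisons across subtypes use Kruskal–Wallis, with an all-pairs Nemenyi
post-hoc computed from rank sums via the studentized range distribution;
two-group comparisons use the Wilcoxon rank-sum test with continuity
correction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_ssn` | 0.01 | per-edge two-tailed retention level of the SSN test |
| `hub_fraction` | 0.20 | top degree fraction defining hubs |
| `hampel_k` | 3 | MAD multiplier of the methylation outlier rule |
| `knn_k` | 10 | neighbour count for probe imputation |
| `max_na_fraction` | 0.10 | probe missingness tolerance (strict >) |
| `mc_iterations` | 10,000 | Monte Carlo iterations for the frequency cutoff |
| `mc_edges_per_iter` | 10,000 | edges drawn per iteration |
| `mc_alpha` | 0.05 | upper-tail mass defining the per-iteration cutoff |
| `subtype_threshold` | 0.60 | within-subtype frequency for subtype modules |
| `seed` | 1 | Monte Carlo seed (mandatory for reproducibility) |

All are surfaced in `PipelineConfig` and as CLI options; the defaults are
the method's published operating point.

## Synthetic cohorts

The generator exists so every stage can be tested against known truth.
Reference co-expression is induced by one shared latent factor per
background edge with per-endpoint loading budget c = min(r, 1/deg), which
is a valid construction (unit variances, any graph, any r in (−1,1)) and
yields edge correlation √(c_u c_v): exactly r whenever r·deg ≤ 1 at both
endpoints — always true for the disjoint-pair networks the calibration uses
— and attenuated at hubs of the scale-free (Barabási–Albert, m = 2)
background. FPKM-likeness comes from exponentiating 0.25 × the latent
Gaussian (log-normal marginals; at this scale pairwise Pearson correlations
stay within ~1 % of their latent targets). Defaults: 300 genes, 100
reference and 50 case samples, r = 0.4, a 2 % per-gene-per-sample mutation
rate, Beta(4,4) probe betas with 2 % missingness, 3 promoter + 1 gene-body
probe per gene — a desk-scale cohort with moderate co-expression and
realistic sparsity of alterations. Planted signals: a perturbed edge forces
the sample's two endpoint genes to opposite 5-SD latent extremes
(decoupling the pair); a methylation outlier sets the gene's promoter
probes to beta 0.995 / 0.005, beyond MED ± 4·MAD of the Beta(4,4)
consolidated distribution; subtype-planted edges appear with probability
0.9 in their subtype and 0.1 elsewhere. One RNG stream per generator, all
spawned from the master seed, so outputs are fully reproducible and adding
a generator never shifts another's draws.

What the generator does **not** emulate: heavy-tailed FPKM dispersion,
correlated mutation/methylation co-occurrence, batch structure,
subtype-structured expression, or realistic breast-cancer effect sizes.
Passing recovery tests therefore shows the algorithms implement their
definitions and detect signals of the planted kind — not that the method's
biological claims transfer to any particular real cohort.

## Numerical choices

- Correlations are computed per edge from cached reference sums, so one
  case sample costs O(|edges|) and memory never holds a gene × gene matrix.
- Two-tailed p = 2·(1 − Φ(|z|)); the rank-based (U-test) variant of the
  edge test is not implemented.
- Eigenvector centrality: power iteration per connected component at
  tolerance 1e-10, normalized globally to unit maximum (modules are often
  disconnected); isolated nodes score 0. Betweenness is reported
  unnormalized (a 5-node star center scores 6); normalization is a flag.
- Jaccard of two empty sets is 0 by convention, with a warning.
- Empty SSNs, empty seed sets and empty modules are all legal: the sample
  stays in cohort counts with an empty edge set, and each such event is
  logged.
- All edge sets are stored canonically (lexicographic endpoint order) and
  written sorted, which is what makes repeated runs byte-identical.

## Known limitations

- **Tail behaviour of the edge test.** The normal null for Δpcc is correct
  in scale but not in shape: conditionally on the reference, Δpcc is
  governed by a product-of-normals influence term, whose excess kurtosis
  does not vanish as n grows. Consequently the per-edge type-I error at a
  nominal two-tailed 0.01 is ≈ 0.03 (and ≈ 0.066 at 0.05) — the
  calibration scripts report this honestly. Retention thresholds should be
  read as ranking devices, not exact error rates.
- The reference cohort is treated as fixed and clean. A normal sample can
  be scored by listing it as a case sample, but the package never removes
  it from the reference first — callers wanting leave-one-out behaviour
  must partition the roles themselves.
- Gene identity is the bare case-sensitive symbol; users must harmonize
  symbols across omics files beforehand.
- Pathway enrichment and survival analysis are out of scope; module gene
  lists are exported as plain text for external tools.
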