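# Methods

## The model in brief

`coexcliques` partitions a genome into disjoint *expression cliques* —
groups of genes that rise and fall together across a large compendium of
expression experiments — and then uses that fixed partition as the unit
of analysis for individual differential-expression experiments. "Clique"
here is the field's historical name for these groups; they are **not**
complete subgraphs in the graph-theoretic sense.

The pipeline assumes the input matrix is already normalized (log-scale
intensities or equivalent); normalization of raw data is out of scope.

## Co-expression rank database

For every gene pair the Pearson product-moment correlation is computed
over pairwise-complete observations (both values present). A pair with
fewer than `min_pairs` (default 3) complete observations, or a
zero-variance gene, has an *undefined* correlation. Each gene's partner
list is sorted by descending correlation; undefined correlations sort
after all defined ones, and remaining ties break by ascending gene id.
Correlations are rounded to 12 decimals before ranking so the tie
structure — and hence the whole downstream pipeline — is identical
across platforms and input orderings.

Probe-level matrices are first collapsed to genes: probes sharing a gene
name are averaged per sample over non-missing values, and probes without
a gene name keep their probe id (the behaviour of array platforms whose
control probes and a few probe sets carry no gene symbol). Collapsing
happens **before** ranking.

An external rank database (e.g. a COXPRESdb-style export) can be loaded
in the same one-row-per-gene dialect and used for clique *evaluation*;
building a network, however, requires stored correlation values, because
the edge sort key below is a correlation, not a rank.

## Network and clique separation

Each gene contributes directed connections to its rank-1…K partners
(default K = 10). The undirected projection records, per unique gene
pair, multiplicity (listed by one gene or both) and strength — the
maximum of the two directional correlations; with the symmetric Pearson
coefficient the two are equal, but the maximum is the defined contract
should an asymmetric rank source ever supply the values.

Unique edges are processed in order of descending strength (ties by
lexicographic gene pair, for determinism; multiplicity plays no role in
sorting) under four rules: new clique / join / fuse-if-small / protect.
"Small" means at most T genes (protection threshold, default 5); fusion
happens whenever **at least one** side is small, protection only when
both exceed T. Consequences, both tested:

* every gene is assigned exactly once (disjoint, exhaustive partition);
* with K ≥ T+1, every final clique has more than T genes — an
  undersized clique always has an edge to the outside (each gene has K
  distinct partners), and that edge would have joined or fused it.

Cliques are named `G1-G2` after the two members with the highest
intra-clique degree (unique edges; ties lexicographic, higher degree
first).

Separation quality is measured as average intra-clique vs inter-clique
database rank: the mean rank over ordered pairs within a clique against
the mean rank from clique members towards outsiders. Smaller is
stronger; scrambled clique sets give the no-structure baseline.

## Enrichment and p_Selection

Enrichment of a clique (n genes) in a term (K annotated genes in the
universe of N clique-set genes, k of them in the clique) is the
hypergeometric upper tail P(X ≥ k), reported as −log10 p_Enriched and
computed via the log-gamma survival function, so values deep in the tail
(beyond 100 on the −log10 scale) remain accurate; probabilities are
floored at 10⁻³⁰⁰. The universe is the clique-set gene union;
unannotated genes count in N and n but never in K or k. Per clique the
best GO term and the best three TFs per discipline (binding, activating,
inhibiting) are retained, ties by term name.

Because "best term" is a selected maximum, its significance is
calibrated empirically: the identical selection runs on `n_scrambles`
(default 20) scrambled clique sets — same size multiset, genes permuted
uniformly — and the best −log10 p_Enriched values are pooled **per
(category, clique size)**. The observed value becomes
Z = (observed − null mean)/null sd and converts to the one-sided normal
upper tail, reported as −log10 p_Selection. At the conventional
p_Selection < 10⁻⁴ the Z threshold is 3.72; the corresponding
−log10 p_Enriched threshold is data-dependent (null mean + 3.719·sd per
clique size). A clique size whose null sd is 0 (e.g. a term annotating
every gene) is flagged not-evaluable rather than given an infinite Z.

**Known limitation.** The normal tail of a right-skewed maximum is
mildly anticonservative: under annotations independent of the cliques
the measured fraction of cliques reaching p_Selection < 0.05 is about
0.06–0.075 with 20 scrambles (approaching ~0.06 as the scramble count
grows). The scramble calibration is the method's only multiple-testing
device; no FDR correction is layered on top.

## Per-experiment scoring

Given a profile of per-gene differences (log2 fold changes), each clique
receives three statistics over the universe of genes present in both the
profile and the clique set:

* **average difference** — the mean over measured clique genes
  (unmeasured genes are simply excluded; a clique with none is
  not-evaluable);
* **UpRegScore** — with meanrank the clique's average position in the
  descending hit ranking of all N profiled genes,
  score = (N + 1 − 2·meanrank)/(N − 1): +1 when the clique monopolises
  the top, −1 the bottom, 0 expected under random placement. Tied
  differences share their average rank (midranks): a fully tied profile
  scores 0 for every clique instead of inheriting spurious structure
  from gene-id order, and negating the profile exactly negates the
  score;
* **Top-n enrichment** — hypergeometric upper tail of the clique's
  overlap with the n_top (default 200, capped at the universe) most up-
  and most down-regulated genes. Ties at the list boundary are resolved
  lexicographically so the lists are deterministic.

The first two statistics are calibrated against scrambled clique sets
drawn from the profile∩clique-set universe with preserved (restricted)
clique sizes; each clique collects `n_scrambles` null values of its own
(per-clique pooling — unlike enrichment there is no selection step, so
size-pooling would only mix clique identities). Z-scores convert to
one-sided tails in both directions. A clique is flagged `up` when either
calibrated statistic clears alpha (default 10⁻⁴) upward and neither
clears it downward; mirrored for `down`; otherwise `ns`. Note the
scrambled baseline absorbs any global shift of the profile, so in an
experiment with one strongly induced clique the remaining cliques sit
slightly *below* baseline; this is inherent to the baseline definition.

Replicate comparison joins two score tables and keeps a direction only
when both experiments call it independently. External gene sets (GMT)
are related to the cliques by the five cliques sharing the most genes,
flagging shares ≥ 30%.

## Synthetic data

`make_expression` draws gene g of module m as
x = λ·f_m + √(1−λ²)·ε with standard-normal per-sample factors f and
independent noise, giving expected within-module correlation λ²
(default λ = 0.95 → r ≈ 0.90, the strong-signal regime) and background
genes pure noise. Default geometry: five 20-gene modules, 50 background
genes, 50 samples. `make_profile` adds N(0, noise_sd²) noise (default
0.2) to planted per-clique shifts and can drop genes at a stated rate;
`make_annotations` plants one true term per clique at a fidelity
fraction over uniform background annotations.

What the generator does **not** emulate: probe-level artifacts,
intensity-dependent correlation, batch structure, overlapping regulons,
or the heavy-tailed clique-size distribution of a real genome. Passing
recovery tests therefore demonstrates the algorithmic contract (the
pipeline finds block-correlation structure and calibrates its
statistics), not performance on any particular organism's compendium.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which each claim is meaningful: separation guarantees
on 20 seeded networks of 300–1000 genes (20 samples each); partition
recovery on five 12-gene modules × 40 samples over 20 seeds; detection
power on six 10-gene cliques (universe 60, n_top = 10) over 40 seeded
runs at effect +1.0 and noise sd 0.2; null calibration over 200
replicates of four 10-gene cliques. Genome-scale runs (thousands of
genes) use the same code paths; the rank database is the only
quadratic-memory object (an n×n float64 correlation matrix plus an
n×(n−1) int64 order array).

All randomness flows through `numpy.random.default_rng` seeded
explicitly; identical inputs and seeds give byte-identical outputs,
including across gene input orderings (sorting tie-breaks are total).
Sample standard deviations (ddof = 1) are used for all scramble nulls.
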