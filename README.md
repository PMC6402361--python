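# coexcliques

Genome-wide co-expression cliques for bulk transcriptomics: build a
ranked co-expression database from a normalized expression compendium,
separate **all** genes into disjoint *expression cliques*, validate the
cliques by annotation enrichment against scrambled-clique nulls, and use
the fixed clique set to score individual differential-expression
experiments.

The motivation: classical microarray analyses look at the strongest few
hundred up/down-regulated genes and discard the rest of the response.
If the genome is instead partitioned *a priori* into co-regulation
cliques — built once from thousands of public arrays — every experiment
can be read out as a small vector of per-clique statistics, exposing
weak but concerted responses that single-gene rankings miss.

## Method

**Rank database.** For genes g, h with expression vectors over the
compendium samples, the Pearson correlation r(g,h) is computed over
pairwise-complete observations. Each gene's partners are sorted by
descending r (rank 1 = strongest partner; undefined correlations last,
ties by gene id).

**Top-K network.** Every gene is connected to its rank-1…K partners
(default K = 10). The undirected projection keeps edge strength
max(r(g→h), r(h→g)) and multiplicity (1 or 2).

**Clique separation.** Unique edges are processed strongest-first under
four rules: (1) two unassigned genes found a new clique; (2) an
unassigned gene joins its partner's clique; (3) two cliques connected by
a new edge are fused while at least one has ≤ T genes (protection
threshold, default T = 5); (4) two cliques both larger than T stay
separate. With K ≥ T+1 every final clique has at least T+1 genes, and
every gene lands in exactly one clique. Cliques are named after their
two best intra-connected genes (`RPS24A-RPL20A` style).

**Enrichment with selection calibration.** Per clique the best GO term
(top 1) and TF regulators (top 3 per discipline: binding / activating /
inhibiting) are selected by the upper-tail hypergeometric probability
p_Enriched, computed in log space. Because selecting the *best* term is
itself biased, the same selection runs on scrambled clique sets (same
sizes, permuted genes, default 20 scrambles); the observed
−log10 p_Enriched becomes a Z-score against that null and converts to a
one-sided normal tail p_Selection. At p_Selection = 10⁻⁴ the Z threshold
is 3.72.

**Experiment scoring.** For a profile of per-gene expression differences
each clique gets: the average difference; the UpRegScore
(N + 1 − 2·meanrank)/(N − 1) ∈ [−1, 1] over the genome-wide hit ranking;
and the hypergeometric enrichment of the Top-n (default 200) most up-
and down-regulated genes. The first two are calibrated against 20
scrambled clique sets exactly as above.

## Worked example

```python
import coexcliques as cx

# a seeded compendium with five planted 12-gene modules
spec = cx.SyntheticSpec(module_sizes=(12,)*5, n_background_genes=0,
                        n_samples=40, loading=0.95, seed=1)
mat, modules = cx.make_expression(spec)

est = cx.CliqueSeparation(n_neighbors=10, protection_threshold=5).fit(mat)
print(est.clique_names_)
print(est.network_.stats())
```

prints

```
['M01G001-M01G002', 'M02G002-M02G005', 'M03G001-M03G004', 'M04G001-M04G004', 'M05G001-M05G002']
{'n_genes': 60, 'directed_connections': 600, 'unique_edges': 318,
 'possible_connections': 1770, 'average_edge_count': 1.8867924528301887,
 'density_pct': 17.966101694915253}
```

— the five planted modules are recovered exactly (one clique per module,
named after the two best-connected member genes), and the top-10 network
over 60 genes realised 318 of the 1770 possible gene pairs, each listed
1.9 times on average. Scoring a differential experiment against the
cliques:

```python
profile = cx.make_profile(est.clique_set_, {est.clique_names_[0]: 1.0},
                          noise_sd=0.2, seed=2)
table = cx.score_significance(profile, est.clique_set_, n_scrambles=20,
                              seed=3, n_top=10)
print(table[["avg_diff", "upreg_score", "z_avg", "direction"]].round(2))
```

```
                 avg_diff  upreg_score  z_avg direction
clique
M01G001-M01G002      1.01         0.81   8.32        up
M02G002-M02G005      0.00        -0.25  -2.08        ns
M03G001-M03G004      0.00        -0.22  -1.66        ns
M04G001-M04G004      0.01        -0.23  -1.94        ns
M05G001-M05G002      0.05        -0.12  -1.71        ns
```

Only the clique carrying the planted +1.0 shift is called up at the
default p < 10⁻⁴; the unshifted cliques sit slightly below the scrambled
baseline (which absorbs the global shift) but stay non-significant.

The same pipeline is available from the shell:

```bash
coexcliques synth -o demo/                      # seeded fixture
coexcliques corrdb --matrix demo/expression.tsv -o demo/db.tsv --corr-output demo/r.tsv
coexcliques cliques --db demo/db.tsv --corr demo/r.tsv -K 10 -T 5 -o demo/cliques.tsv
coexcliques analyze --cliques demo/cliques.tsv --profile demo/profile.tsv -o demo/scores.tsv
```

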