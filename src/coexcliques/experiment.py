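"""Score a differential-expression experiment against a clique set.

Three complementary statistics are computed per clique:

* the average expression difference of its measured genes;
* the UpRegScore — a rank statistic over the genome-wide hit ranking,
  score = (N + 1 - 2 * meanrank) / (N - 1), so +1 means the clique
  monopolises the top of the ranking, -1 the bottom and 0 is the random
  expectation;
* the hypergeometric enrichment of the Top-n (default 200) most up- and
  downregulated genes within the clique.

Significance of the first two is estimated against scrambled clique sets
(same sizes, gene labels permuted within the profile/clique-set universe):
Z = (observed - null mean) / null sd, converted to one-sided normal tail
probabilities in both directions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cliques import CliqueSet, scramble_cliques
from .enrichment import (
    DEFAULT_ALPHA,
    DEFAULT_N_SCRAMBLES,
    log10_hypergeom_tail,
    z_to_neglog10_p,
)

DEFAULT_N_TOP = 200


def clique_avg_diff(profile: pd.Series, clique_genes) -> float:
    """Mean expression difference over the clique genes the profile
    measured; ``nan`` when none were measured."""
    present = profile.index.intersection(sorted(clique_genes))
    if present.empty:
        return float("nan")
    return float(profile[present].mean())


def _hit_ranks(profile: pd.Series) -> pd.Series:
    """1-based ranks of all profile genes, most upregulated first.

    Tied differences share their average rank (midranks), so a clique of
    tied genes scores 0 rather than inheriting spurious structure from
    gene-id ordering; the ranking stays fully deterministic."""
    return profile.rank(ascending=False, method="average")


def upreg_score(profile: pd.Series, clique_genes, ranks: pd.Series | None = None) -> float:
    """Rank-based up/downregulation score of a clique, in [-1, 1]."""
    n = len(profile)
    if n < 2:
        raise ValueError("UpRegScore needs at least 2 profiled genes")
    if ranks is None:
        ranks = _hit_ranks(profile)
    present = ranks.index.intersection(sorted(clique_genes))
    if present.empty:
        return float("nan")
    meanrank = float(ranks[present].mean())
    return (n + 1 - 2.0 * meanrank) / (n - 1)


def topn_enrichment(
    profile: pd.Series, cliques: CliqueSet, n_top: int = DEFAULT_N_TOP
) -> pd.DataFrame:
    """Hypergeometric Top-n enrichment per clique, both directions.

    The universe is the intersection of profiled genes and clique-set
    genes; ``n_top`` is capped at the universe size.  Ties at the list
    boundary are resolved lexicographically so the lists are
    deterministic.  Returns a DataFrame indexed by clique with columns
    ``top_up_neglog10_p`` and ``top_down_neglog10_p``.
    """
    universe = profile.index.intersection(sorted(cliques.genes))
    if universe.empty:
        raise ValueError("no gene is shared between the profile and the clique set")
    n_universe = len(universe)
    n_top = min(n_top, n_universe)
    sub = profile[universe]
    by_up = sorted(universe, key=lambda g: (-sub[g], g))
    up = frozenset(by_up[:n_top])
    down = frozenset(sorted(universe, key=lambda g: (sub[g], g))[:n_top])
    rows = {}
    uset = frozenset(universe)
    for name, genes in cliques.items():
        in_universe = genes & uset
        n = len(in_universe)
        rows[name] = (
            log10_hypergeom_tail(len(in_universe & up), n, n_top, n_universe),
            log10_hypergeom_tail(len(in_universe & down), n, n_top, n_universe),
        )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["top_up_neglog10_p", "top_down_neglog10_p"]
    )


def _restrict_to_universe(cliques: CliqueSet, universe: frozenset) -> CliqueSet:
    """Clique set cut down to the genes a profile actually measured."""
    kept = {
        name: genes & universe
        for name, genes in cliques.items()
        if genes & universe
    }
    return CliqueSet(kept, k=cliques.k, t=cliques.t)


def score_significance(
    profile: pd.Series,
    cliques: CliqueSet,
    n_scrambles: int = DEFAULT_N_SCRAMBLES,
    seed: int | np.random.Generator = 0,
    alpha: float = DEFAULT_ALPHA,
    n_top: int = DEFAULT_N_TOP,
) -> pd.DataFrame:
    """Full per-clique score table for one experiment.

    Scrambled clique sets keep the (universe-restricted) clique sizes and
    permute only genes present in both the profile and the clique set, so
    the null matches the measured gene pool.  Each clique collects
    ``n_scrambles`` null values of both statistics; Z-scores and one-sided
    p-values follow.  A zero null sd marks the clique not-evaluable
    (``z`` = ``nan``).

    Columns: ``n_genes_with_values``, ``avg_diff``, ``upreg_score``,
    ``top_up_neglog10_p``, ``top_down_neglog10_p``, ``z_avg``,
    ``z_upreg``, ``avg_up_neglog10_p``, ``avg_down_neglog10_p``,
    ``upreg_up_neglog10_p``, ``upreg_down_neglog10_p``, ``direction``.
    """
    if n_scrambles < 2:
        raise ValueError("need at least 2 scrambles for a standard deviation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = frozenset(profile.index) & cliques.genes
    if not universe:
        raise ValueError("no gene is shared between the profile and the clique set")
    restricted = _restrict_to_universe(cliques, universe)
    sub = profile[profile.index.isin(universe)]
    ranks = _hit_ranks(sub)

    observed_avg = {}
    observed_upreg = {}
    for name, genes in restricted.items():
        observed_avg[name] = clique_avg_diff(sub, genes)
        observed_upreg[name] = upreg_score(sub, genes, ranks=ranks)

    null_avg = {name: [] for name in restricted}
    null_upreg = {name: [] for name in restricted}
    for _ in range(n_scrambles):
        sc = scramble_cliques(restricted, rng)
        for sc_name, genes in sc.items():
            name = sc_name.rsplit("~", 1)[0]
            null_avg[name].append(clique_avg_diff(sub, genes))
            null_upreg[name].append(upreg_score(sub, genes, ranks=ranks))

    top = topn_enrichment(sub, restricted, n_top=n_top)
    cutoff = -np.log10(alpha)
    rows = []
    for name, genes in restricted.items():
        z_avg = _z(observed_avg[name], null_avg[name])
        z_upreg = _z(observed_upreg[name], null_upreg[name])
        p = {
            "avg_up": z_to_neglog10_p(z_avg) if np.isfinite(z_avg) else np.nan,
            "avg_down": z_to_neglog10_p(-z_avg) if np.isfinite(z_avg) else np.nan,
            "upreg_up": z_to_neglog10_p(z_upreg) if np.isfinite(z_upreg) else np.nan,
            "upreg_down": z_to_neglog10_p(-z_upreg) if np.isfinite(z_upreg) else np.nan,
        }
        sig_up = max(_nz(p["avg_up"]), _nz(p["upreg_up"])) > cutoff
        sig_down = max(_nz(p["avg_down"]), _nz(p["upreg_down"])) > cutoff
        if sig_up and not sig_down:
            direction = "up"
        elif sig_down and not sig_up:
            direction = "down"
        else:
            direction = "ns"
        rows.append(
            {
                "clique": name,
                "n_genes_with_values": len(genes),
                "avg_diff": observed_avg[name],
                "upreg_score": observed_upreg[name],
                "top_up_neglog10_p": top.loc[name, "top_up_neglog10_p"],
                "top_down_neglog10_p": top.loc[name, "top_down_neglog10_p"],
                "z_avg": z_avg,
                "z_upreg": z_upreg,
                "avg_up_neglog10_p": p["avg_up"],
                "avg_down_neglog10_p": p["avg_down"],
                "upreg_up_neglog10_p": p["upreg_up"],
                "upreg_down_neglog10_p": p["upreg_down"],
                "direction": direction,
            }
        )
    return pd.DataFrame(rows).set_index("clique")


def _z(observed: float, null_values) -> float:
    m = float(np.mean(null_values))
    s = float(np.std(null_values, ddof=1))
    if s == 0.0 or not np.isfinite(observed):
        return float("nan")
    return (observed - m) / s


def _nz(x: float) -> float:
    return x if np.isfinite(x) else -np.inf


def compare_replicates(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Join two score tables and flag cliques consistent across replicates.

    A clique is flagged ``up`` (``down``) only when both experiments call
    it significant in that same direction at ``alpha``; everything else is
    ``ns``.
    """
    joined = table_a.join(table_b, how="inner", lsuffix="_a", rsuffix="_b")

    def consistent(row) -> str:
        if row["direction_a"] == row["direction_b"] != "ns":
            return row["direction_a"]
        return "ns"

    joined["consistent"] = joined.apply(consistent, axis=1) if len(joined) else []
    return joined


def gene_set_overlap(
    gene_set: frozenset,
    cliques: CliqueSet,
    top_m: int = 5,
    share_threshold: float = 0.30,
) -> pd.DataFrame:
    """The ``top_m`` cliques sharing the most genes with an external set.

    ``share`` is the fraction of the gene set found in the clique; cliques
    at or above ``share_threshold`` are flagged.  Ties in the shared-gene
    count are broken by lexicographic clique name.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    counts = sorted(
        ((name, len(gene_set & genes)) for name, genes in cliques.items()),
        key=lambda x: (-x[1], x[0]),
    )[:top_m]
    rows = [
        {
            "clique": name,
            "n_shared": k,
            "share": k / len(gene_set),
            "flagged": k / len(gene_set) >= share_threshold,
        }
        for name, k in counts
    ]
    return pd.DataFrame(rows).set_index("clique")
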