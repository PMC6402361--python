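"""Hypergeometric clique enrichment with scramble-calibrated significance.

Per clique and annotation category the most enriched terms are selected by
the upper-tail hypergeometric probability p_Enriched (top term for GO, top
three for each of the TF disciplines).  Because picking the *best* term is
itself a selection, its significance is calibrated empirically: the same
selection is run on scrambled clique sets (same sizes, permuted genes),
the best -log10 p values are pooled per clique size, and the observed best
value is expressed as a Z-score against that null, converted to the
one-sided normal tail probability p_Selection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log, log10
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cliques import CliqueSet, scramble_cliques

_LN10 = log(10.0)
#: probability floor: p below 1e-300 is reported as exactly 300 on the
#: -log10 scale to avoid overflow
NEGLOG10_CAP = 300.0

DEFAULT_ALPHA = 1e-4
DEFAULT_N_SCRAMBLES = 20


def log10_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """-log10 P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` annotated genes observed in a clique of ``n`` genes, drawn from a
    universe of ``N`` genes of which ``K`` carry the annotation.  Computed
    in log space (log-gamma based survival function), accurate far into
    the tail — observed values beyond 100 on the -log10 scale stay finite.
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if k > K:
        raise ValueError(f"k={k} annotated genes in the clique exceed K={K} in the universe")
    if k == 0:
        return 0.0
    logsf = stats.hypergeom.logsf(k - 1, N, K, n)
    return min(-logsf / _LN10, NEGLOG10_CAP)


def z_to_neglog10_p(z: float) -> float:
    """-log10 of the one-sided upper-tail standard normal probability.

    Log-space stable: usable for Z well beyond 40 (where p underflows a
    naive ``1 - cdf``).
    """
    return min(-stats.norm.logsf(z) / _LN10, NEGLOG10_CAP)


@dataclass(frozen=True)
class EnrichmentResult:
    """One selected term for one clique."""

    clique: str
    term: str
    category: str
    k: int  #: annotated genes in the clique
    n: int  #: clique size
    K: int  #: annotated genes in the universe
    N: int  #: universe size
    enrichment_factor: float  #: (k/n) / (K/N)
    neglog10_p_enriched: float
    z_selection: float | None = None
    neglog10_p_selection: float | None = None


@dataclass(frozen=True)
class NullCalibration:
    """Scrambled-clique null of the best -log10 p_Enriched.

    ``stats`` maps (category, clique size) to (mean, sd, n_values); the
    scrambled sets share the real size multiset, so every real clique finds
    its own size here.
    """

    stats: Mapping[tuple[str, int], tuple[float, float, int]]
    n_scrambles: int

    def mean_sd(self, category: str, size: int) -> tuple[float, float]:
        m, s, _ = self.stats[(category, size)]
        return m, s


#: how many top terms are retained per annotation category
TOP_TERMS = {"GO": 1, "TF_binding": 3, "TF_activating": 3, "TF_inhibiting": 3}


def _category_term_genes(annotations: pd.DataFrame, universe: frozenset):
    """{category: {term: set of universe genes}} from an annotation table."""
    ann = annotations[annotations["gene"].isin(universe)]
    out: dict[str, dict[str, frozenset]] = {}
    for (cat, term), grp in ann.groupby(["category", "term"], sort=True):
        out.setdefault(cat, {})[term] = frozenset(grp["gene"])
    return out


def enrich_clique(
    clique_name: str,
    clique_genes: frozenset,
    annotations: pd.DataFrame,
    universe: frozenset,
) -> dict[str, list[EnrichmentResult]]:
    """Best terms per category for one clique (top 1 for GO, top 3 per TF
    discipline), ties broken by lexicographic term."""
    term_map = _category_term_genes(annotations, universe)
    return {
        cat: _best_terms(clique_name, clique_genes, cat, terms, len(universe))
        for cat, terms in term_map.items()
    }


def _best_terms(
    clique_name: str,
    clique_genes: frozenset,
    category: str,
    terms: Mapping[str, frozenset],
    N: int,
    top: int | None = None,
) -> list[EnrichmentResult]:
    n = len(clique_genes)
    results = []
    for term in sorted(terms):
        genes = terms[term]
        K = len(genes)
        k = len(clique_genes & genes)
        p = log10_hypergeom_tail(k, n, K, N)
        factor = (k / n) / (K / N) if K else 0.0
        results.append(
            EnrichmentResult(clique_name, term, category, k, n, K, N, factor, p)
        )
    results.sort(key=lambda r: (-r.neglog10_p_enriched, r.term))
    keep = TOP_TERMS.get(category, 1) if top is None else top
    return results[:keep]


def _best_neglog10_by_category(
    cliques: CliqueSet, term_map, N: int
) -> dict[str, dict[str, float]]:
    """{category: {clique: best -log10 p}} using a prebuilt term map."""
    out: dict[str, dict[str, float]] = {cat: {} for cat in term_map}
    for name, genes in cliques.items():
        for cat, terms in term_map.items():
            best = _best_terms(name, genes, cat, terms, N, top=1)
            out[cat][name] = best[0].neglog10_p_enriched if best else 0.0
    return out


def calibrate_selection(
    cliques: CliqueSet,
    annotations: pd.DataFrame,
    n_scrambles: int = DEFAULT_N_SCRAMBLES,
    seed: int | np.random.Generator = 0,
) -> NullCalibration:
    """Empirical null of the best -log10 p_Enriched per clique size.

    Runs the top-term selection on ``n_scrambles`` scrambled clique sets
    and pools the best values by (category, clique size).  Standard
    deviations use the sample convention (ddof=1); at least two scrambles
    are required.
    """
    if n_scrambles < 2:
        raise ValueError("need at least 2 scrambles for a standard deviation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = cliques.genes
    term_map = _category_term_genes(annotations, universe)
    pooled: dict[tuple[str, int], list[float]] = {}
    for _ in range(n_scrambles):
        sc = scramble_cliques(cliques, rng)
        best = _best_neglog10_by_category(sc, term_map, len(universe))
        sizes = sc.sizes
        for cat, per_clique in best.items():
            for cname, value in per_clique.items():
                pooled.setdefault((cat, sizes[cname]), []).append(value)
    stats_map = {
        key: (float(np.mean(vals)), float(np.std(vals, ddof=1)), len(vals))
        for key, vals in pooled.items()
    }
    return NullCalibration(stats=stats_map, n_scrambles=n_scrambles)


def significance_threshold(
    calibration: NullCalibration, alpha: float = DEFAULT_ALPHA
) -> dict[tuple[str, int], float]:
    """Minimum -log10 p_Enriched a clique needs to reach p_Selection < alpha.

    threshold = null mean + z(alpha) * null sd, with z(1e-4) ~ 3.719.  A
    degenerate null (sd = 0) leaves the threshold at the mean; downstream
    significance for such cliques is flagged not-evaluable.
    """
    z_alpha = float(stats.norm.isf(alpha))
    return {
        key: m + z_alpha * s
        for key, (m, s, _) in calibration.stats.items()
    }


def enrich_clique_set(
    cliques: CliqueSet,
    annotations: pd.DataFrame,
    n_scrambles: int = DEFAULT_N_SCRAMBLES,
    seed: int | np.random.Generator = 0,
) -> list[EnrichmentResult]:
    """Full enrichment of a clique set: best terms per category with
    scramble-calibrated Z-scores and p_Selection values.

    Cliques whose size has a zero-sd null get ``z_selection`` and
    ``neglog10_p_selection`` of ``None`` (not evaluable).
    """
    universe = cliques.genes
    term_map = _category_term_genes(annotations, universe)
    calibration = calibrate_selection(cliques, annotations, n_scrambles, seed)
    results: list[EnrichmentResult] = []
    for name, genes in cliques.items():
        size = len(genes)
        for cat, terms in term_map.items():
            best = _best_terms(name, genes, cat, terms, len(universe))
            m, s = calibration.mean_sd(cat, size)
            for rank_pos, res in enumerate(best):
                if rank_pos == 0 and s > 0:
                    z = (res.neglog10_p_enriched - m) / s
                    res = replace(
                        res,
                        z_selection=z,
                        neglog10_p_selection=z_to_neglog10_p(z),
                    )
                results.append(res)
    return results


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results into a DataFrame (one row per term)."""
    return pd.DataFrame([r.__dict__ for r in results])


def summarize_significant(
    cliques: CliqueSet,
    results: Iterable[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
    category: str = "GO",
) -> tuple[int, int]:
    """Genes covered by significantly annotated cliques, and direct hits.

    Counts (total genes in cliques whose selected ``category`` term reaches
    p_Selection < alpha, genes among those directly annotated with the
    selected term).
    """
    cutoff = -log10(alpha)
    genes_covered = 0
    direct_hits = 0
    seen: set[str] = set()
    for res in results:
        if res.category != category or res.neglog10_p_selection is None:
            continue
        if res.clique in seen:
            continue  # only the top-selected term of each clique counts
        seen.add(res.clique)
        if res.neglog10_p_selection > cutoff:
            genes_covered += len(cliques[res.clique])
            direct_hits += res.k
    return genes_covered, direct_hits
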