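"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from coexcliques import CliqueSet, CoexpressionRankDB


def exhaustive_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by enumerating every size-n subset of an N-gene universe.

    The first K genes carry the annotation.  Exact rational arithmetic;
    independent of any log-gamma machinery.  Feasible for N <= 12.
    """
    hits = 0
    total = 0
    for subset in combinations(range(N), n):
        total += 1
        if sum(1 for g in subset if g < K) >= k:
            hits += 1
    return float(Fraction(hits, total))


def brute_force_rankings(mat: pd.DataFrame, min_pairs: int = 3) -> dict[str, list[str]]:
    """Definitional per-gene partner rankings, plain Python loops.

    Correlations from the raw product-moment sums over pairwise-complete
    positions; undefined (too few pairs / zero variance) sorts last; ties
    by partner id.  Oracle for build_rank_db on tiny inputs.
    """

    def corr(xs: list[float], ys: list[float]) -> float | None:
        pairs = [(x, y) for x, y in zip(xs, ys) if not (math.isnan(x) or math.isnan(y))]
        if len(pairs) < min_pairs:
            return None
        n = len(pairs)
        sx = sum(p[0] for p in pairs) / n
        sy = sum(p[1] for p in pairs) / n
        vx = sum((p[0] - sx) ** 2 for p in pairs)
        vy = sum((p[1] - sy) ** 2 for p in pairs)
        if vx == 0 or vy == 0:
            return None
        cov = sum((p[0] - sx) * (p[1] - sy) for p in pairs)
        return cov / math.sqrt(vx * vy)

    genes = list(mat.index)
    rows = {g: [float(v) for v in mat.loc[g]] for g in genes}
    out = {}
    for g in genes:
        scored = []
        for h in genes:
            if h == g:
                continue
            r = corr(rows[g], rows[h])
            key = (1, 0.0, h) if r is None else (0, -round(r, 12), h)
            scored.append((key, h))
        scored.sort()
        out[g] = [h for _, h in scored]
    return out


def db_from_rankings(rankings: dict[str, list[str]], corr=None) -> CoexpressionRankDB:
    """Build a rank database directly from explicit partner lists."""
    genes = list(rankings)
    index = {g: i for i, g in enumerate(genes)}
    order = np.array([[index[p] for p in rankings[g]] for g in genes])
    return CoexpressionRankDB(genes, order, corr=corr)


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    """4 genes x 5 samples with one missing value."""
    rng = np.random.default_rng(42)
    mat = pd.DataFrame(
        rng.normal(size=(4, 5)),
        index=["geneA", "geneB", "geneC", "geneD"],
        columns=[f"s{i}" for i in range(5)],
    )
    mat.iloc[1, 2] = np.nan
    return mat


@pytest.fixture
def two_cliques() -> CliqueSet:
    return CliqueSet(
        {"alpha": frozenset({"A", "B", "C"}), "beta": frozenset({"D", "E", "F"})}
    )
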