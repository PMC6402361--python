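"""All-pairs Pearson correlation and per-gene partner rankings.

The rank database is the backbone of the whole pipeline: for every gene it
stores all other genes ordered by descending Pearson correlation (rank 1 =
strongest co-expression partner).  Correlations are computed over
pairwise-complete observations so compendia with missing cells still work;
pairs with fewer than ``min_pairs`` complete observations, or a
zero-variance series, yield an undefined correlation which sorts after all
defined ones.  Remaining ties are broken by ascending lexicographic partner
id, and correlations are rounded to 12 decimals before ranking, so the
database is deterministic across platforms and input orderings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: decimals kept before ranking, to stabilise cross-platform tie behaviour
RANK_DECIMALS = 12


def pearson(x, y, min_pairs: int = 3) -> float:
    """Product-moment correlation over pairwise-complete observations.

    Returns ``nan`` (the undefined-correlation signal) when fewer than
    ``min_pairs`` positions have values in both series or when either
    series has zero variance on the complete positions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series have different lengths")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_pairs:
        return float("nan")
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy))
    return max(-1.0, min(1.0, r))


class CoexpressionRankDB:
    """Per-gene rankings of all co-expression partners.

    Parameters
    ----------
    genes
        Ordered unique gene identifiers.
    order
        Integer array of shape ``(n, n-1)``; row i lists the indices of
        gene i's partners in descending-correlation order.
    corr
        Optional symmetric ``(n, n)`` correlation matrix (``nan`` where
        undefined and on the diagonal).
    """

    def __init__(self, genes, order, corr=None):
        self.genes = list(genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        n = len(self.genes)
        order = np.asarray(order, dtype=np.int64)
        if order.shape != (n, n - 1):
            raise ValueError(f"order must have shape ({n}, {n - 1})")
        expect = np.arange(n)
        for i in range(n):
            if not np.array_equal(np.sort(order[i]), np.delete(expect, i)):
                raise ValueError(
                    f"row for gene {self.genes[i]!r} is not a permutation "
                    "of the other genes"
                )
        self.order = order
        if corr is not None:
            corr = np.asarray(corr, dtype=float)
            if corr.shape != (n, n):
                raise ValueError("corr must be square over the genes")
        self.corr = corr
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoexpressionRankDB):
            return NotImplemented
        if self.genes != other.genes or not np.array_equal(self.order, other.order):
            return False
        if (self.corr is None) != (other.corr is None):
            return False
        return self.corr is None or np.allclose(
            self.corr, other.corr, equal_nan=True
        )

    def partners(self, gene: str) -> list[str]:
        """All other genes, strongest co-expression first."""
        i = self._index[gene]
        return [self.genes[j] for j in self.order[i]]

    def top(self, gene: str, k: int) -> list[str]:
        i = self._index[gene]
        return [self.genes[j] for j in self.order[i, :k]]

    def rank(self, gene: str, partner: str) -> int:
        """1-based rank of ``partner`` in ``gene``'s list."""
        i, j = self._index[gene], self._index[partner]
        if i == j:
            raise ValueError("a gene has no rank in its own list")
        return int(np.nonzero(self.order[i] == j)[0][0]) + 1

    def rank_matrix(self) -> np.ndarray:
        """``(n, n)`` array R with R[i, j] = rank of gene j in gene i's
        list (0 on the diagonal)."""
        n = len(self.genes)
        ranks = np.zeros((n, n), dtype=np.int64)
        rows = np.repeat(np.arange(n), n - 1)
        ranks[rows, self.order.ravel()] = np.tile(np.arange(1, n), n)
        return ranks

    def correlation(self, gene: str, partner: str) -> float:
        if self.corr is None:
            raise ValueError("this rank database stores no correlation values")
        return float(self.corr[self._index[gene], self._index[partner]])


def build_rank_db(mat: pd.DataFrame, min_pairs: int = 3) -> CoexpressionRankDB:
    """Build the co-expression rank database from an expression matrix.

    ``mat`` is genes x samples.  Needs at least 2 genes and 3 samples.
    """
    n_genes, n_samples = mat.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes to rank partners")
    if n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    genes = [str(g) for g in mat.index]

    # pairwise-complete Pearson; pairs below min_pairs become NaN
    corr = mat.T.corr(method="pearson", min_periods=min_pairs).to_numpy(dtype=float)
    np.fill_diagonal(corr, np.nan)

    rounded = np.round(corr, RANK_DECIMALS)
    # lexicographic position of each gene id, for deterministic tie-breaks
    lexrank = np.empty(n_genes, dtype=np.int64)
    lexrank[np.argsort(np.asarray(genes, dtype=object))] = np.arange(n_genes)

    order = np.empty((n_genes, n_genes - 1), dtype=np.int64)
    all_idx = np.arange(n_genes)
    for i in range(n_genes):
        others = np.delete(all_idx, i)
        key = rounded[i, others]
        key = np.where(np.isnan(key), -np.inf, key)
        # primary: descending correlation (undefined last); secondary: id
        order[i] = others[np.lexsort((lexrank[others], -key))]
    return CoexpressionRankDB(genes, order, corr=corr)


def write_rank_db(path, db: CoexpressionRankDB, corr_path=None) -> None:
    """Write the database: one row per gene, ordered partner ids.

    With ``corr_path`` given, a parallel table of the correlation values in
    the same partner order is written (17 significant digits, exact
    float64 round trip).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for i, g in enumerate(db.genes):
            fh.write("\t".join([g, *(db.genes[j] for j in db.order[i])]) + "\n")
    if corr_path is not None:
        if db.corr is None:
            raise ValueError("database stores no correlation values to write")
        with open(corr_path, "w", encoding="utf-8") as fh:
            for i, g in enumerate(db.genes):
                vals = (f"{db.corr[i, j]:.17g}" for j in db.order[i])
                fh.write("\t".join([g, *vals]) + "\n")


def read_rank_db(path, corr_path=None) -> CoexpressionRankDB:
    """Read a rank database written by :func:`write_rank_db`.

    Also accepts any external ranking (e.g. a COXPRESdb-style export) in
    the same dialect; each row must be a permutation of the other genes.
    """
    rows: list[tuple[str, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields == [""]:
                continue
            rows.append((fields[0], fields[1:]))
    genes = [g for g, _ in rows]
    index = {g: i for i, g in enumerate(genes)}
    if len(index) != len(genes):
        raise ValueError("duplicate gene row in rank database")
    n = len(genes)
    order = np.empty((n, n - 1), dtype=np.int64)
    for i, (g, partners) in enumerate(rows):
        if len(partners) != n - 1:
            raise ValueError(f"row for {g!r} lists {len(partners)} partners, expected {n - 1}")
        try:
            order[i] = [index[p] for p in partners]
        except KeyError as exc:
            raise ValueError(f"unknown partner id {exc.args[0]!r} in row {g!r}") from exc
    corr = None
    if corr_path is not None:
        corr = np.full((n, n), np.nan)
        with open(corr_path, encoding="utf-8") as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if fields == [""]:
                    continue
                i = index[fields[0]]
                corr[i, order[i]] = [float(v) for v in fields[1:]]
    return CoexpressionRankDB(genes, order, corr=corr)
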