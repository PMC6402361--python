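"""scikit-learn style estimator for the clique-separation stage.

:class:`CliqueSeparation` is a clusterer over genes: ``fit`` takes a
genes x samples expression matrix, builds the co-expression rank database
and the top-K network, and separates the genes into named cliques.  It
follows the scikit-learn contract (``get_params``/``set_params``, fitted
attributes with a trailing underscore, ``fit_predict``), so it composes
with sklearn model-selection utilities — note that the *rows* are the
items being clustered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .cliques import build_topk_network, name_cliques, separate_cliques
from .coexpression import build_rank_db


class CliqueSeparation(ClusterMixin, BaseEstimator):
    """Greedy edge-sorted clique separation of a gene expression matrix.

    Parameters
    ----------
    n_neighbors : int, default=10
        K — how many top co-expression partners of each gene enter the
        network.
    protection_threshold : int, default=5
        T — cliques larger than T are never absorbed into another clique.
        With ``n_neighbors >= protection_threshold + 1`` every final
        clique has more than T genes.
    min_pairs : int, default=3
        Minimum pairwise-complete observations for a defined correlation.

    Attributes
    ----------
    gene_ids_ : list of str
        Row identifiers, in input order.
    rank_db_ : CoexpressionRankDB
    network_ : CoexprNetwork
    clique_set_ : CliqueSet
        The named cliques.
    labels_ : ndarray of int
        Clique index per gene (order of ``clique_names_``).
    clique_names_ : list of str
    """

    def __init__(self, n_neighbors: int = 10, protection_threshold: int = 5,
                 min_pairs: int = 3):
        self.n_neighbors = n_neighbors
        self.protection_threshold = protection_threshold
        self.min_pairs = min_pairs

    def fit(self, X, y=None):
        """Cluster the genes (rows) of ``X`` into expression cliques.

        ``X`` may be a DataFrame (index = gene ids) or an array, in which
        case genes are named ``g0 .. g{n-1}``.
        """
        if isinstance(X, pd.DataFrame):
            mat = X.astype(float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be a 2-D genes x samples matrix")
            mat = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])])
        self.gene_ids_ = [str(g) for g in mat.index]
        self.rank_db_ = build_rank_db(mat, min_pairs=self.min_pairs)
        self.network_ = build_topk_network(self.rank_db_, k=self.n_neighbors)
        cliques = separate_cliques(self.network_, t=self.protection_threshold)
        self.clique_set_ = name_cliques(cliques, self.network_)
        self.clique_names_ = list(self.clique_set_)
        index = {name: i for i, name in enumerate(self.clique_names_)}
        member = self.clique_set_.membership()
        self.labels_ = np.array([index[member[g]] for g in self.gene_ids_])
        return self
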