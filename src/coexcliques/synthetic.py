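"""Seeded synthetic fixtures with the correlation structure the pipeline
assumes.

Expression follows a per-module latent-factor model: gene g of module m in
sample s is  x_gs = lambda * f_ms + sqrt(1 - lambda^2) * eps_gs  with
standard-normal factor and noise, so genes of one module share an expected
pairwise correlation of lambda^2 while background genes are pure noise.
The pipeline consumes only correlation *ranks*, so any block-correlation
generator would do; the latent-factor form makes the target correlation an
explicit dial.

Differential profiles plant a signed mean shift per clique plus Gaussian
noise; annotation tables plant one true term per clique at a chosen
fidelity over uniform background annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cliques import CliqueSet


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-module expression compendium.

    ``loading`` is the latent-factor loading lambda; the expected
    within-module Pearson correlation is lambda squared (0.95 -> ~0.90).
    """

    module_sizes: tuple[int, ...] = (20, 20, 20, 20, 20)
    n_background_genes: int = 50
    n_samples: int = 50
    loading: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not self.module_sizes or any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must all be >= 1")
        if self.n_background_genes < 0 or self.n_samples < 1:
            raise ValueError("gene and sample counts must be positive")
        if not (0.0 < self.loading < 1.0):
            raise ValueError("loading must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def make_expression(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a genes x samples matrix and the planted module labels.

    Module genes are named ``M<m>G<i>``, background genes ``BG<i>``;
    background labels are the empty string.
    """
    rng = np.random.default_rng(spec.seed)
    lam = spec.loading
    resid = np.sqrt(1.0 - lam * lam)
    blocks = []
    genes: list[str] = []
    labels: list[str] = []
    for m, size in enumerate(spec.module_sizes, start=1):
        factor = rng.standard_normal(spec.n_samples)
        noise = rng.standard_normal((size, spec.n_samples))
        blocks.append(lam * factor + resid * noise)
        genes += [f"M{m:02d}G{i:03d}" for i in range(1, size + 1)]
        labels += [f"M{m:02d}"] * size
    if spec.n_background_genes:
        blocks.append(rng.standard_normal((spec.n_background_genes, spec.n_samples)))
        genes += [f"BG{i:03d}" for i in range(1, spec.n_background_genes + 1)]
        labels += [""] * spec.n_background_genes
    values = np.vstack(blocks)
    samples = [f"S{j:03d}" for j in range(1, spec.n_samples + 1)]
    mat = pd.DataFrame(values, index=genes, columns=samples)
    return mat, pd.Series(labels, index=genes, name="module")


def planted_clique_set(spec: SyntheticSpec) -> CliqueSet:
    """The ground-truth partition of a :func:`make_expression` compendium
    as a clique set (background genes pooled into one ``BG`` clique)."""
    _, labels = make_expression(spec)
    groups: dict[str, set[str]] = {}
    for gene, lab in labels.items():
        groups.setdefault(lab or "BG", set()).add(gene)
    return CliqueSet({n: frozenset(g) for n, g in sorted(groups.items())})


def make_profile(
    cliques: CliqueSet,
    effects: dict[str, float],
    noise_sd: float = 0.2,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> pd.Series:
    """Differential profile with planted per-clique mean shifts.

    Every gene's difference is its clique's effect (0 when unlisted) plus
    N(0, noise_sd) noise; with ``missing_rate`` > 0 that fraction of genes
    is dropped, emulating probes the experiment did not measure.
    """
    unknown = set(effects) - set(cliques)
    if unknown:
        raise ValueError(f"effect given for unknown clique {sorted(unknown)[0]!r}")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = sorted(cliques.genes)
    member = cliques.membership()
    mean = np.array([effects.get(member[g], 0.0) for g in genes])
    diffs = mean + (rng.normal(0.0, noise_sd, len(genes)) if noise_sd > 0 else 0.0)
    profile = pd.Series(diffs, index=genes)
    if missing_rate > 0:
        keep = rng.random(len(genes)) >= missing_rate
        profile = profile[keep]
    return profile


def make_annotations(
    cliques: CliqueSet,
    fidelity: float = 1.0,
    background_rate: float = 0.0,
    seed: int = 0,
    category: str = "GO",
) -> pd.DataFrame:
    """Annotation table with one planted true term per clique.

    Each clique's term ``T_<clique>`` covers a ``fidelity`` fraction of its
    genes (rounded); additionally every (gene, term) pair is annotated with
    probability ``background_rate``, independent of the cliques.  At
    fidelity 1 and no background, the planted term is the unique minimal-p
    hit for its clique.
    """
    if not (0.0 <= fidelity <= 1.0):
        raise ValueError("fidelity must lie in [0, 1]")
    if not (0.0 <= background_rate <= 1.0):
        raise ValueError("background_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str]] = []
    terms = [f"T_{name}" for name in cliques]
    for name, genes in cliques.items():
        ordered = sorted(genes)
        n_true = int(round(fidelity * len(ordered)))
        chosen = rng.choice(len(ordered), size=n_true, replace=False) if n_true else []
        for i in sorted(chosen):
            records.append((ordered[i], f"T_{name}", category))
    all_genes = sorted(cliques.genes)
    if background_rate > 0:
        hits = rng.random((len(all_genes), len(terms))) < background_rate
        for gi, ti in zip(*np.nonzero(hits)):
            records.append((all_genes[gi], terms[ti], category))
    df = pd.DataFrame(records, columns=["gene", "term", "category"])
    return df.drop_duplicates(ignore_index=True)
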