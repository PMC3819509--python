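"""Genomic relationship matrix, K-means folds and realized DGV accuracy.

Cross-validation groups are built so that genomic relatedness is high
within and low between groups: animals are clustered on the squared
genomic distance induced by the VanRaden relationship matrix into K=6
groups, the two smallest merged to give 5 folds.  Leave-one-group-out
training then yields, for every animal, a DGV predicted without its own
phenotype or those of close relatives.  Realized accuracy is the pooled
validation correlation between DGV and phenotype divided by sqrt(h2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_config import RunConfig, TraitTable, logger
from .wgr_sampler import (MixturePrior, build_design, dgv,
                          elicit_priors_bayesC, run_chain, summarize)

__all__ = ["compute_grm", "kmeans_folds", "cross_validate",
           "realized_accuracy", "ValidationResult"]


def compute_grm(dosages: np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G = M M' / (2 sum_j p_j (1-p_j)) with M the dosage matrix whose
    columns are centered at twice the observed allele frequency.
    Monomorphic SNPs contribute nothing to either numerator or
    denominator.  Rows of G sum to zero by construction.
    """
    Z = np.asarray(dosages, dtype=float)
    if Z.shape[0] < 2:
        raise ValueError("need >=2 animals")
    p = Z.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic: GRM undefined")
    M = Z[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    return (M @ M.T) / denom


@dataclass
class FoldAssignment:
    """Fold label (1..n_folds) per animal, from K-means then merging."""

    labels: np.ndarray
    cluster_sizes: list[int]   # sizes of the original K clusters

    def fold_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


def kmeans_folds(grm: np.ndarray, k: int = 6, n_folds: int = 5,
                 seed: int = 0, n_init: int = 25,
                 embedding: str = "dissimilarity") -> FoldAssignment:
    """Cluster animals on genomic distance; merge smallest clusters to folds.

    The dissimilarity ``d_ij = g_ii + g_jj - 2 g_ij`` is the squared
    distance induced by G as an inner product.  Animals are embedded
    either as the rows of this matrix (default) or by classical MDS of it
    (``embedding="mds"``; equivalent to the leading eigenvectors of the
    double-centered G), then clustered by K-means (k-means++, ``n_init``
    restarts, best within-cluster SS kept).  The ``k - n_folds + 1``
    smallest clusters are merged into the final fold.
    """
    G = np.asarray(grm, dtype=float)
    n = G.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} animals")
    d = np.diag(G)
    D = d[:, None] + d[None, :] - 2.0 * G
    if embedding == "mds":
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D @ J
        w, V = np.linalg.eigh(B)
        keep = w > max(w.max(), 0) * 1e-9
        feats = V[:, keep] * np.sqrt(w[keep])
    else:
        feats = D
    if np.unique(np.round(feats, 12), axis=0).shape[0] < k:
        raise ValueError(
            f"fewer than {k} distinct animals: cannot form {k} clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(feats)
    raw = km.labels_
    sizes = pd.Series(raw).value_counts()
    # merge the smallest clusters into one fold, relabel the rest by size
    order = sizes.sort_values(ascending=False).index.tolist()
    large, small = order[: n_folds - 1], order[n_folds - 1:]
    labels = np.empty(n, dtype=int)
    for fold, cl in enumerate(large, start=1):
        labels[raw == cl] = fold
    for cl in small:
        labels[raw == cl] = n_folds
    logger.info("K-means cluster sizes %s merged to folds %s",
                sizes.sort_index().tolist(),
                pd.Series(labels).value_counts().sort_index().tolist())
    return FoldAssignment(labels=labels,
                          cluster_sizes=sizes.sort_index().tolist())


@dataclass
class ValidationResult:
    per_fold: pd.DataFrame     # fold, n, b, r
    pooled_b: float
    pooled_r: float
    h2: float
    accuracy: float


def realized_accuracy(pooled_r: float, h2: float) -> float:
    """accuracy = pooled_r / sqrt(h2); sign is preserved."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    return pooled_r / np.sqrt(h2)


def cross_validate(dosages: np.ndarray, traits: TraitTable, trait: str,
                   folds: np.ndarray, cfg: RunConfig,
                   prior: MixturePrior | None = None,
                   h2: float | None = None) -> ValidationResult:
    """Leave-one-group-out cross-validation of DGV.

    For each fold the sampler is trained on the remaining folds, DGVs are
    predicted for the held-out animals, and their phenotypes — adjusted by
    the training fixed-effect estimates, so contemporary-group structure
    does not masquerade as genomic signal — are regressed on (b) and
    correlated with (r) the DGVs.  b and r are pooled across folds
    weighted by fold size.  The prior and the heritability in the accuracy
    denominator default to a single full-data elicitation run.
    """
    y, X, kept_ids, _ = build_design(traits, trait)
    Z = np.asarray(dosages, dtype=float)
    id_index = {a: i for i, a in
                enumerate(traits.table["animal_id"].astype(str))}
    rows = np.array([id_index[a] for a in kept_ids])
    Z = Z[rows]
    folds = np.asarray(folds)[rows]

    if prior is None or h2 is None:
        full_prior, full_summary = elicit_priors_bayesC(y, X, Z, cfg)
        prior = prior or full_prior
        h2 = h2 if h2 is not None else full_summary.h2

    fold_ids = np.unique(folds)
    records = []
    for f in fold_ids:
        val = folds == f
        trn = ~val
        if val.sum() < 2:
            raise ValueError(f"fold {f} has fewer than 2 animals")
        cfg_f = replace(cfg, seed=cfg.seed + int(f))
        chain = run_chain(y[trn], X[trn], Z[trn], prior, cfg_f)
        summ = summarize(chain)
        pred = dgv(Z[val], summ.u_hat)
        adj = y[val] - X[val] @ summ.b_hat
        if np.var(pred) == 0:
            logger.warning("fold %s: constant DGV, excluded from pooling", f)
            continue
        slope = float(np.cov(adj, pred, ddof=1)[0, 1] / np.var(pred, ddof=1))
        r = float(np.corrcoef(adj, pred)[0, 1])
        records.append({"fold": int(f), "n": int(val.sum()),
                        "b": slope, "r": r})
    per_fold = pd.DataFrame(records)
    if per_fold.empty:
        raise ValueError("no fold produced a defined correlation")
    wts = per_fold["n"] / per_fold["n"].sum()
    pooled_b = float((per_fold["b"] * wts).sum())
    pooled_r = float((per_fold["r"] * wts).sum())
    return ValidationResult(per_fold=per_fold, pooled_b=pooled_b,
                            pooled_r=pooled_r, h2=h2,
                            accuracy=realized_accuracy(pooled_r, h2))
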