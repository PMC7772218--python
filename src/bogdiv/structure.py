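"""Population structure: PCA, Ward clustering, and ancestry estimation.

PCA follows the panel's convention: dosages 0/1/2 are recoded to
-1/0/+1, missing entries are mean-imputed per marker, columns centered,
and the decomposition is a plain SVD.

Ancestry is a Structure-like sparse factorization of the individual
allele-frequency matrix X = dosage/2 into Q (n x K ancestry proportions,
rows on the simplex) and F (K x L ancestral allele frequencies in
[0, 1]) by alternating nonnegative least squares. Model choice for K
uses masked cross-entropy: a random fraction of observed genotype
entries is held out per replicate and scored under the binomial
log-loss of the fitted Q F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as hier
from scipy.optimize import nnls

from .genotype_io import MISSING, GenotypeMatrix

EPS = 1e-6  # log-clipping for cross-entropy


class StructureError(ValueError):
    pass


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, C)
    explained: np.ndarray  # fraction of variance per component
    accession_ids: list[str]
    coding: str = "-1/0/+1, per-marker mean imputation, column centering"


@dataclass
class WardTree:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    newick: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class AncestryFit:
    K: int
    Q: np.ndarray  # (n, K), rows sum to 1
    F: np.ndarray  # (K, L) in [0, 1]
    cross_entropy: float  # masked (held-out) CE of this replicate
    train_ce_path: list[float]
    replicate: int
    seed: int
    converged: bool
    accession_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _coded_imputed(G: GenotypeMatrix) -> np.ndarray:
    """-1/0/+1 coding with per-marker mean imputation of missing calls."""
    X = G.dosages_float() - 1.0
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    ix = np.where(np.isnan(X))
    X[ix] = mu[ix[1]]
    return X


def pca(G: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """SVD principal components of the centered -1/0/+1 genotype matrix."""
    X = _coded_imputed(G)
    X = X - X.mean(axis=0)
    if not np.any(np.abs(X) > 1e-12):
        raise StructureError("constant genotype matrix: PCA undefined")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    scores = U * s
    if n_components is not None:
        scores = scores[:, :n_components]
        explained = explained[:n_components]
    return PcaResult(scores=scores, explained=explained, accession_ids=list(G.accession_ids))


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hier.to_tree(Z)

    def rec(node, parent_h):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_h:.6g}"
        bl = max(parent_h - node.dist, 0.0)
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{bl:.6g}"

    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"


def ward_tree(
    X: np.ndarray | GenotypeMatrix, labels: list[str] | None = None
) -> WardTree:
    """Ward minimum-variance agglomeration on Euclidean distances.

    Accepts either a raw score/feature matrix or a GenotypeMatrix (which
    is then PCA-coded and imputed the same way as :func:`pca`).
    """
    if isinstance(X, GenotypeMatrix):
        labels = list(X.accession_ids)
        X = _coded_imputed(X)
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise StructureError("need at least 2 observations to cluster")
    if labels is None:
        labels = [f"obs{i}" for i in range(X.shape[0])]
    Z = hier.ward(X)
    return WardTree(linkage=Z, labels=list(labels), newick=_linkage_to_newick(Z, list(labels)))


def cut_tree(tree: WardTree, k: int) -> np.ndarray:
    """Cluster assignment for the top *k*-group split of the Ward tree."""
    return hier.fcluster(tree.linkage, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# Sparse-NMF-style ancestry
# ---------------------------------------------------------------------------

def _batched_nnls(D: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||D x - b||, x >= 0 for every column b of B.

    Fast path: unconstrained least squares for all columns at once, with
    per-column active-set NNLS only where negativity appears.
    """
    X, *_ = np.linalg.lstsq(D, B, rcond=None)
    bad = np.flatnonzero((X < -1e-12).any(axis=0))
    for j in bad:
        X[:, j], _ = nnls(D, B[:, j])
    return np.clip(X, 0.0, None)


def _cross_entropy(dos: np.ndarray, P: np.ndarray, where: np.ndarray) -> float:
    """Binomial log-loss of predicted allele frequencies on selected entries."""
    g = dos[where].astype(float)
    f = np.clip(P[where], EPS, 1.0 - EPS)
    ll = g * np.log(f) + (2.0 - g) * np.log(1.0 - f)
    return float(-ll.sum() / (2.0 * len(g)))


def snmf_fit(
    G: GenotypeMatrix,
    K: int,
    n_replicates: int = 5,
    mask_fraction: float = 0.05,
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> AncestryFit:
    """Fit the Q x F ancestry factorization; return the best replicate.

    Per replicate, a random *mask_fraction* of observed entries is held
    out; missing genotypes never enter the loss. Alternating nonnegative
    least squares on an EM-filled matrix (held-out/missing entries are
    replaced by the current prediction Q F each sweep), Q rows projected
    back to the simplex after each update. The replicate with the lowest
    held-out cross-entropy wins. Replicate seeds are spawned from *seed*.
    """
    n, L = G.dosages.shape
    if not (1 <= K <= n):
        raise StructureError(f"K={K} outside [1, n={n}]")
    dos = G.dosages
    observed = dos != MISSING
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]

    best: AncestryFit | None = None
    for rep, rseed in enumerate(rep_seeds):
        rng = np.random.default_rng(rseed)
        hold = observed & (rng.random((n, L)) < mask_fraction)
        train = observed & ~hold
        if not hold.any():  # tiny matrices: hold out one entry
            i, j = np.argwhere(observed)[0]
            hold = np.zeros_like(observed)
            hold[i, j] = True
            train = observed & ~hold

        X = np.where(train, dos, 0).astype(float) / 2.0
        Q = rng.dirichlet(np.ones(K), size=n)
        F = np.clip(rng.uniform(0.05, 0.95, size=(K, L)), 0, 1)

        ce_path = []
        converged = False
        for it in range(max_iter):
            P = Q @ F
            Xf = np.where(train, X, P)  # EM fill of masked/missing entries
            if K == 1:
                F = Xf.mean(axis=0, keepdims=True)
                Q = np.ones((n, 1))
            else:
                F = np.clip(_batched_nnls(Q, Xf), 0.0, 1.0)
                Qt = _batched_nnls(F.T, Xf.T)  # (K, n)
                Q = Qt.T
                rs = Q.sum(axis=1, keepdims=True)
                dead = rs[:, 0] <= 0
                if dead.any():
                    Q[dead] = 1.0 / K
                    rs[dead] = 1.0
                Q = Q / rs
            ce = _cross_entropy(dos, Q @ F, train)
            ce_path.append(ce)
            if it > 0 and abs(ce_path[-2] - ce) < tol * max(abs(ce_path[-2]), 1e-12):
                converged = True
                break
        fit = AncestryFit(
            K=K,
            Q=Q,
            F=np.clip(F, 0.0, 1.0),
            cross_entropy=_cross_entropy(dos, Q @ F, hold),
            train_ce_path=ce_path,
            replicate=rep,
            seed=rseed,
            converged=converged,
            accession_ids=list(G.accession_ids),
        )
        if best is None or fit.cross_entropy < best.cross_entropy:
            best = fit
    assert best is not None
    return best


def select_k(fits: dict[int, list[AncestryFit]] | list[AncestryFit]) -> tuple[int, pd.DataFrame]:
    """Choose K minimizing mean masked cross-entropy (ties -> smallest K).

    Accepts either a flat list of fits or a dict K -> fits. Returns the
    selected K and the full CE-by-K table.
    """
    if isinstance(fits, dict):
        flat = [f for fl in fits.values() for f in fl]
    else:
        flat = list(fits)
    if len({f.K for f in flat}) < 2:
        raise StructureError("need fits for at least two values of K")
    df = (
        pd.DataFrame({"K": [f.K for f in flat], "ce": [f.cross_entropy for f in flat]})
        .groupby("K", as_index=False)
        .agg(mean_ce=("ce", "mean"), n_reps=("ce", "size"))
        .sort_values("K", ignore_index=True)
    )
    best_ce = df["mean_ce"].min()
    k_star = int(df.loc[np.isclose(df["mean_ce"], best_ce), "K"].min())
    return k_star, df


def align_q(Q_hat: np.ndarray, Q_true: np.ndarray) -> tuple[np.ndarray, float]:
    """Best column-permutation alignment of an estimated Q to a reference.

    Ancestry labels are identifiable only up to permutation; returns the
    permuted Q_hat and its RMSE against Q_true.
    """
    from itertools import permutations

    K = Q_true.shape[1]
    best_perm, best_rmse = None, np.inf
    for perm in permutations(range(K)):
        rmse = float(np.sqrt(np.mean((Q_hat[:, perm] - Q_true) ** 2)))
        if rmse < best_rmse:
            best_rmse, best_perm = rmse, perm
    return Q_hat[:, list(best_perm)], best_rmse
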