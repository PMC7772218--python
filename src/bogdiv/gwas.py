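"""Structure-aware mixed-linear-model association scans.

Kinship is the VanRaden additive relationship matrix
A = W W' / (2 sum_j p_j (1 - p_j)) with W the mean-imputed, 2p-centered
dosage matrix. Single-marker tests follow the EMMAX / P3D scheme: the
kinship is eigendecomposed once, the variance ratio delta = s2_e / s2_g
is REML-estimated under the covariates-only null model, and every marker
is then tested by generalized least squares with a Wald t-test.
Population-structure covariates (PC1-10, ancestry proportions) enter the
fixed part; ancestry Q matrices contribute K-1 columns to dodge their
sum-to-one collinearity. Discoveries use Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genotype_io import MISSING, GenotypeMatrix, PanelMetadata


class GwasError(ValueError):
    pass


@dataclass
class KinshipMatrix:
    matrix: np.ndarray  # (n, n)
    accession_ids: list[str]
    freqs: np.ndarray  # allele frequencies used for centering

    def __post_init__(self) -> None:
        A = self.matrix
        if not np.allclose(A, A.T, atol=1e-10):
            raise GwasError("kinship must be symmetric")
        if np.any(np.diag(A) <= 0):
            raise GwasError("kinship diagonal must be positive")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.accession_ids, columns=self.accession_ids)


@dataclass
class MlmScanResult:
    table: pd.DataFrame  # chrom, pos, beta, se, p, q, flag
    trait: str
    subset: str
    delta: float  # s2_e / s2_g under the null
    sigma2_g: float
    sigma2_e: float
    covariate_names: list[str]
    n_used: int
    fdr_alpha: float
    discoveries: pd.DataFrame = field(default_factory=pd.DataFrame)


def vanraden_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden additive relationship matrix from the dosage matrix.

    Missing calls are mean-imputed per marker; in-sample allele
    frequencies center the matrix. Monomorphic markers contribute
    nothing to the denominator, so an all-monomorphic input errors.
    """
    X = G.dosages_float()
    p = np.nanmean(X, axis=0) / 2.0
    ix = np.where(np.isnan(X))
    X[ix] = (2.0 * p)[ix[1]]
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise GwasError("need >= 2 polymorphic markers for kinship")
    W = X - 2.0 * p
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    A = (W @ W.T) / denom
    return KinshipMatrix(matrix=A, accession_ids=list(G.accession_ids), freqs=p)


# ---------------------------------------------------------------------------
# EMMAX core
# ---------------------------------------------------------------------------

def _null_reml_delta(yt: np.ndarray, Xt: np.ndarray, S: np.ndarray) -> float:
    """REML estimate of delta = s2_e/s2_g on eigen-rotated data."""
    n, p = Xt.shape

    def neg_reml(log_delta: float) -> float:
        d = np.exp(log_delta)
        w = 1.0 / (S + d)
        XtW = Xt * w[:, None]
        XtWX = Xt.T @ XtW
        try:
            beta = np.linalg.solve(XtWX, XtW.T @ yt)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Xt @ beta
        rss = float(np.sum(w * r * r))
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0 or rss <= 0:
            return np.inf
        return 0.5 * (
            (n - p) * np.log(rss)
            + np.sum(np.log(S + d))
            + logdet_xwx
        )

    res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded")
    return float(np.exp(res.x))


def mlm_scan(
    G: GenotypeMatrix,
    y: pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    K: KinshipMatrix | pd.DataFrame | np.ndarray | None = None,
    subset: np.ndarray | list[str] | None = None,
    trait: str = "trait",
    subset_label: str = "all",
    fdr_alpha: float = 0.10,
    min_subset_maf: float = 0.05,
) -> MlmScanResult:
    """EMMAX-style single-marker scan.

    *y* is accession-indexed; *covariates* rows align with the accession
    order of *G* (or share y's index when a DataFrame). *subset* may name
    accessions (or give row indices) for per-subgroup scans; markers with
    subset MAF below *min_subset_maf* and markers collinear with the
    covariates are flagged and not tested.
    """
    ids = list(G.accession_ids)
    if subset is not None:
        subset = list(subset)
        if subset and isinstance(subset[0], str):
            pos = {a: i for i, a in enumerate(ids)}
            rows = np.array([pos[a] for a in subset if a in pos], dtype=int)
        else:
            rows = np.asarray(subset, dtype=int)
    else:
        rows = np.arange(len(ids))

    sub_ids = [ids[i] for i in rows]
    yv = y.reindex(sub_ids)
    ok = yv.notna().to_numpy()
    rows = rows[ok]
    sub_ids = [s for s, o in zip(sub_ids, ok) if o]
    n = len(rows)
    if n < 30:
        raise GwasError(f"need >= 30 phenotyped accessions in subset, got {n}")
    yv = yv.dropna().to_numpy(dtype=float)

    if covariates is None:
        C = np.empty((n, 0))
        cov_names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        C = covariates.reindex(sub_ids).to_numpy(dtype=float)
        if np.isnan(C).any():
            raise GwasError("covariates missing for some accessions in subset")
        cov_names = [str(c) for c in covariates.columns]
    else:
        C = np.asarray(covariates, dtype=float)[rows]
        cov_names = [f"cov{i}" for i in range(C.shape[1])]
    X0 = np.column_stack([np.ones(n), C])

    if K is None:
        Ksub = np.eye(n)
    else:
        if isinstance(K, KinshipMatrix):
            Kf = K.frame()
        elif isinstance(K, pd.DataFrame):
            Kf = K
        else:
            Kf = pd.DataFrame(np.asarray(K, float), index=ids, columns=ids)
        Ksub = Kf.reindex(index=sub_ids, columns=sub_ids).to_numpy(dtype=float)
        if np.isnan(Ksub).any():
            raise GwasError("kinship does not cover the subset")
    S, U = np.linalg.eigh(Ksub)
    if S.min() < -1e-6:
        raise GwasError(f"kinship not PSD (min eigenvalue {S.min():.3g})")
    S = np.clip(S, 1e-9, None)

    yt = U.T @ yv
    X0t = U.T @ X0
    delta = _null_reml_delta(yt, X0t, S)
    w = 1.0 / (S + delta)

    # null variance components for reporting
    XtWX = X0t.T @ (X0t * w[:, None])
    beta0 = np.linalg.solve(XtWX, (X0t * w[:, None]).T @ yt)
    r0 = yt - X0t @ beta0
    s2_g = float(np.sum(w * r0 * r0) / (n - X0.shape[1]))
    s2_e = s2_g * delta

    # per-marker GLS
    dos = G.dosages[rows, :].astype(float)
    miss = dos == MISSING
    dos[miss] = np.nan
    p_hat = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p_hat, 1 - p_hat)
    ix = np.where(np.isnan(dos))
    dos[ix] = (2 * p_hat)[ix[1]]

    L = dos.shape[1]
    beta = np.full(L, np.nan)
    se = np.full(L, np.nan)
    pval = np.full(L, np.nan)
    flag = np.array(["ok"] * L, dtype=object)

    Xt_all = U.T @ dos  # rotate all markers at once
    p_full = X0.shape[1] + 1
    df = n - p_full
    sw = np.sqrt(w)
    X0w = X0t * sw[:, None]
    yw = yt * sw
    # residualize y and markers against covariates in the whitened space
    Q0, _ = np.linalg.qr(X0w)
    y_res = yw - Q0 @ (Q0.T @ yw)
    M = Xt_all * sw[:, None]
    M_res = M - Q0 @ (Q0.T @ M)
    xtx = np.sum(M_res * M_res, axis=0)
    xty = M_res.T @ y_res
    yty = float(y_res @ y_res)

    var_whiten = np.sum(M * M, axis=0)
    collinear = xtx <= 1e-8 * np.maximum(var_whiten, 1e-12)
    low_maf = (subset is not None) & (maf < min_subset_maf)
    testable = ~collinear & ~low_maf & (maf > 0)

    b = np.where(testable, xty / np.where(xtx > 0, xtx, 1.0), np.nan)
    rss = yty - b * xty
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = rss / df
        se_all = np.sqrt(s2 / np.where(xtx > 0, xtx, np.nan))
        tstat = b / se_all
    pv = 2.0 * stats.t.sf(np.abs(tstat), df)
    pv = np.clip(pv, np.finfo(float).tiny, 1.0)

    beta[testable] = b[testable]
    se[testable] = se_all[testable]
    pval[testable] = pv[testable]
    flag[collinear] = "collinear"
    flag[low_maf & ~collinear] = "low_maf"
    flag[(maf == 0) & ~collinear] = "monomorphic"

    qv = np.full(L, np.nan)
    tested = np.isfinite(pval)
    if tested.any():
        qv[tested], _ = bh_fdr(pval[tested], alpha=fdr_alpha)

    table = pd.DataFrame(
        {
            "chrom": G.markers["chrom"].to_numpy(),
            "pos": G.markers["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": pval,
            "q": qv,
            "flag": flag,
        }
    )
    disc = table[(table["q"] <= fdr_alpha) & tested].copy()
    return MlmScanResult(
        table=table,
        trait=trait,
        subset=subset_label,
        delta=delta,
        sigma2_g=s2_g,
        sigma2_e=s2_e,
        covariate_names=cov_names,
        n_used=n,
        fdr_alpha=fdr_alpha,
        discoveries=disc,
    )


def bh_fdr(p_values: np.ndarray, alpha: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (monotone q-values, rejection mask)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise GwasError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise GwasError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def structure_covariates(pca_result, ancestry_fit, n_pcs: int = 10) -> pd.DataFrame:
    """PC1-10 plus K-1 ancestry-proportion columns, accession-indexed."""
    n_pcs = min(n_pcs, pca_result.scores.shape[1])
    cols = {f"PC{i+1}": pca_result.scores[:, i] for i in range(n_pcs)}
    if ancestry_fit is not None and ancestry_fit.K >= 2:
        for k in range(ancestry_fit.K - 1):  # drop one: rows sum to 1
            cols[f"Q{k+1}"] = ancestry_fit.Q[:, k]
    return pd.DataFrame(cols, index=pca_result.accession_ids)


def stratification_audit(
    G: GenotypeMatrix,
    marker_index: int,
    y: pd.Series,
    meta: PanelMetadata,
    p_threshold: float = 0.05,
) -> dict:
    """Genotype x subgroup breakdown of one association.

    Returns per-(subgroup, genotype class) counts and means, the
    within-subgroup additive effect for each subgroup, and a
    ``confounded`` flag set when no subgroup shows a nominally
    significant within-subgroup effect (the association lives entirely
    between subgroups).
    """
    dose = G.dosages[:, marker_index].astype(float)
    dose[dose == MISSING] = np.nan
    df = pd.DataFrame(
        {"accession_id": G.accession_ids, "dose": dose}
    ).merge(meta.table[["accession_id", "subgroup"]], on="accession_id")
    df["y"] = y.reindex(df["accession_id"]).to_numpy()
    df = df.dropna(subset=["dose", "y"])

    cells = (
        df.groupby(["subgroup", "dose"])["y"]
        .agg(n="size", mean="mean")
        .reset_index()
    )
    effects = []
    for sg, sub in df.groupby("subgroup"):
        if sub["dose"].nunique() < 2 or len(sub) < 3:
            effects.append({"subgroup": sg, "slope": np.nan, "p": np.nan, "n": len(sub)})
            continue
        res = stats.linregress(sub["dose"], sub["y"])
        effects.append(
            {"subgroup": sg, "slope": float(res.slope), "p": float(res.pvalue), "n": len(sub)}
        )
    eff = pd.DataFrame(effects)
    within_sig = eff["p"].dropna() < p_threshold
    confounded = not bool(within_sig.any())
    marker = G.markers.iloc[marker_index]
    return {
        "chrom": marker["chrom"],
        "pos": int(marker["pos"]),
        "cells": cells,
        "within_subgroup_effects": eff,
        "confounded": confounded,
    }
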