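"""Genomic BLUPs from multi-year field records with spatial adjustment.

Model per trait, on plot-level records:

    y = X tau + Z_g u_g + Z_y u_y + Z_s u_s + e

with u_g ~ N(0, sigma2_g K) the accession genetic values (K a genomic
relationship matrix), u_y iid year effects, u_s the penalized part of a
tensor-product B-spline surface over field (row, col) in its mixed-model
reparameterization, and e iid residuals. The unpenalized polynomial
trend of the spline (its penalty null space, which cannot carry a
finite-variance prior) forms the fixed effects X.

Variance components are estimated by EM-REML (monotone in the restricted
likelihood); BLUPs and BLUEs come from the resulting GLS equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

TRAITS = ("yield", "fruit_weight", "fruit_rot", "TACy", "brix", "acids")

TRAIT_UNITS = {
    "yield": "g",
    "fruit_weight": "g",
    "fruit_rot": "%",
    "TACy": "mg/gFW",
    "brix": "degBx",
    "acids": "mg/gFW",
}

RECORD_COLUMNS = ("accession_id", "trait", "value", "year", "row", "col")


class BlupError(ValueError):
    pass


@dataclass
class BlupTable:
    trait: str
    blups: pd.DataFrame  # columns accession_id, blup, n_records, raw_mean
    varcomp: dict[str, float]  # genomic, year, spatial, residual
    loglik_path: list[float]
    converged: bool
    n_records: int

    def series(self) -> pd.Series:
        return self.blups.set_index("accession_id")["blup"]


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise BlupError(f"phenotype records missing columns {sorted(missing)}")
    r = records.copy()
    if not np.isfinite(r["value"].to_numpy(dtype=float)).all():
        raise BlupError("non-finite phenotype values")
    return r


# ---------------------------------------------------------------------------
# Tensor-product P-spline surface, mixed-model reparameterization
# ---------------------------------------------------------------------------

def _bspline_design(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo if hi > lo else 1.0
    u = (x - lo) / span
    inner = np.linspace(0.0, 1.0, n_basis - degree + 1)
    t = np.concatenate([np.zeros(degree), inner, np.ones(degree)])
    return BSpline.design_matrix(np.clip(u, 0, 1), t, degree).toarray()


def spatial_design(
    row: np.ndarray, col: np.ndarray, n_basis: int = 8, degree: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed (penalty null space) and random parts of the spline surface.

    Tensor-product B-spline basis (n_basis x n_basis) with a second-order
    difference penalty in each direction (Kronecker sum). The penalty is
    eigendecomposed; near-zero eigenvalues span the unpenalized bilinear
    trend -> fixed columns; the rest are rescaled by 1/sqrt(eigenvalue)
    so the surface coefficients become iid random effects.
    """
    Br = _bspline_design(np.asarray(row, float), n_basis, degree)
    Bc = _bspline_design(np.asarray(col, float), n_basis, degree)
    B = (Br[:, :, None] * Bc[:, None, :]).reshape(len(Br), -1)
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    P1 = D.T @ D
    P = np.kron(P1, np.eye(n_basis)) + np.kron(np.eye(n_basis), P1)
    lam, E = np.linalg.eigh(P)
    null = lam < 1e-8
    X_fix = B @ E[:, null]
    Z_rand = B @ E[:, ~null] / np.sqrt(lam[~null])
    return X_fix, Z_rand


# ---------------------------------------------------------------------------
# EM-REML for a sum of known-covariance random terms
# ---------------------------------------------------------------------------

def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[tuple[str, np.ndarray]],
    max_iter: int = 200,
    tol: float = 1e-7,
    floor: float = 1e-10,
) -> dict:
    """EM-REML for y ~ N(X tau, sum_k sigma2_k H_k + sigma2_e I).

    ``terms``: (name, H_k) with H_k = Z_k G_k Z_k' the n x n covariance
    structure of term k; ``rank_k`` (the EM divisor) is taken as the
    number of underlying levels, estimated as rank(H_k). The update
    sigma2 <- sigma2 + sigma2^2 (y'P H P y - tr(P H)) / q is the
    classical EM step and never decreases the restricted likelihood.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = len(y)
    names = [t[0] for t in terms]
    Hs = [np.asarray(t[1], float) for t in terms]
    qs = [int(np.linalg.matrix_rank(H, tol=1e-8)) for H in Hs]
    vary = float(np.var(y)) or 1.0
    s = {name: vary / (len(terms) + 1) for name in names}
    s_e = vary / (len(terms) + 1)

    # fixed-effect design must be full column rank for the REML determinant
    from scipy.linalg import qr as _qr

    _, Rq, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    rank = int(np.sum(diag > 1e-10 * max(diag.max(), 1.0)))
    X = X[:, np.sort(piv[:rank])]

    ll_path: list[float] = []
    converged = False
    for _ in range(max_iter):
        V = s_e * np.eye(n)
        for name, H in zip(names, Hs):
            V += s[name] * H
        c, low = cho_factor(V, lower=True)
        Vi = cho_solve((c, low), np.eye(n))
        ViX = Vi @ X
        XtViX = X.T @ ViX
        cx = np.linalg.cholesky(XtViX)
        P = Vi - ViX @ cho_solve((cx, True), ViX.T)
        Py = P @ y
        logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
        logdet_X = 2.0 * np.sum(np.log(np.diag(cx)))
        ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
        ll_path.append(ll)

        for name, H, q in zip(names, Hs, qs):
            grad = float(Py @ H @ Py) - float(np.sum(P * H))
            s[name] = max(s[name] + (s[name] ** 2) * grad / q, floor)
        grad_e = float(Py @ Py) - float(np.trace(P))
        s_e = max(s_e + (s_e**2) * grad_e / n, floor)

        if len(ll_path) > 1 and abs(ll_path[-1] - ll_path[-2]) < tol * (
            1.0 + abs(ll_path[-2])
        ):
            converged = True
            break

    # final GLS solve at converged components
    V = s_e * np.eye(n)
    for name, H in zip(names, Hs):
        V += s[name] * H
    c, low = cho_factor(V, lower=True)
    Vi = cho_solve((c, low), np.eye(n))
    ViX = Vi @ X
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ (Vi @ y))
    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    return {
        "sigma2": s,
        "sigma2_e": s_e,
        "beta": beta,
        "P": P,
        "Py": P @ y,
        "loglik_path": ll_path,
        "converged": converged,
        "X": X,
    }


def fit_gblup(
    records: pd.DataFrame,
    kinship: pd.DataFrame | np.ndarray,
    trait: str,
    kinship_ids: list[str] | None = None,
    n_spline_basis: int = 8,
    max_iter: int = 200,
) -> BlupTable:
    """Fit the spatial GBLUP model for one trait and predict genetic values.

    *kinship* is the additive relationship matrix over accessions (a
    DataFrame indexed by accession id, or an array plus *kinship_ids*);
    it must cover every phenotyped accession. Returns per-accession
    BLUPs and REML variance components.
    """
    r = validate_records(records)
    r = r[r["trait"] == trait]
    if r.empty:
        raise BlupError(f"no records for trait {trait!r}")
    if isinstance(kinship, pd.DataFrame):
        kin_ids = [str(i) for i in kinship.index]
        Kfull = kinship.to_numpy(dtype=float)
    else:
        if kinship_ids is None:
            raise BlupError("kinship_ids required with an array kinship")
        kin_ids = [str(i) for i in kinship_ids]
        Kfull = np.asarray(kinship, dtype=float)

    accs = sorted(set(r["accession_id"].astype(str)))
    unknown = [a for a in accs if a not in set(kin_ids)]
    if unknown:
        raise BlupError(f"accessions missing from kinship: {unknown[:5]}")
    pos = {a: i for i, a in enumerate(kin_ids)}
    sel = [pos[a] for a in accs]
    K = Kfull[np.ix_(sel, sel)]
    K = K + 1e-6 * np.eye(len(K))  # guard against singular relationship

    # sort records for an order-invariant fit
    r = r.sort_values(["accession_id", "year", "row", "col"], ignore_index=True)
    y = r["value"].to_numpy(dtype=float)
    n = len(y)

    acc_idx = pd.Categorical(r["accession_id"].astype(str), categories=accs).codes
    Zg = np.zeros((n, len(accs)))
    Zg[np.arange(n), acc_idx] = 1.0
    Hg = Zg @ K @ Zg.T

    years = sorted(set(r["year"]))
    terms = [("genomic", Hg)]
    if len(years) >= 2:
        yr_idx = pd.Categorical(r["year"], categories=years).codes
        Zy = np.zeros((n, len(years)))
        Zy[np.arange(n), yr_idx] = 1.0
        terms.append(("year", Zy @ Zy.T))

    row = r["row"].to_numpy(dtype=float)
    col = r["col"].to_numpy(dtype=float)
    spatial_ok = len(np.unique(row)) >= 2 and len(np.unique(col)) >= 2
    if spatial_ok:
        X_fix, Zs = spatial_design(row, col, n_basis=n_spline_basis)
        terms.append(("spatial", Zs @ Zs.T))
        X = X_fix  # spans the intercept direction
    else:
        X = np.ones((n, 1))

    fit = em_reml(y, X, terms, max_iter=max_iter)
    s_g = fit["sigma2"]["genomic"]
    u_g = s_g * (K @ (Zg.T @ fit["Py"]))  # BLUP of accession genetic values

    raw = r.groupby("accession_id")["value"].agg(["mean", "size"])
    blups = pd.DataFrame(
        {
            "accession_id": accs,
            "blup": u_g,
            "n_records": raw.loc[accs, "size"].to_numpy(),
            "raw_mean": raw.loc[accs, "mean"].to_numpy(),
        }
    )
    varcomp = {
        "genomic": float(s_g),
        "year": float(fit["sigma2"].get("year", 0.0)),
        "spatial": float(fit["sigma2"].get("spatial", 0.0)),
        "residual": float(fit["sigma2_e"]),
    }
    return BlupTable(
        trait=trait,
        blups=blups,
        varcomp=varcomp,
        loglik_path=fit["loglik_path"],
        converged=fit["converged"],
        n_records=n,
    )


# ---------------------------------------------------------------------------
# Subgroup comparisons and trait correlations
# ---------------------------------------------------------------------------

@dataclass
class SubgroupComparison:
    trait: str
    omnibus_f: float
    omnibus_p: float
    group_stats: pd.DataFrame  # subgroup, n, min, mean, max
    pairwise: pd.DataFrame  # Tukey HSD table


def subgroup_compare(
    values: pd.Series | pd.DataFrame, meta, trait: str
) -> SubgroupComparison:
    """One-way ANOVA + Tukey HSD of per-accession values across subgroups.

    *values*: accession-indexed Series (e.g. BLUPs or accession means),
    or a BlupTable-style frame with accession_id / blup columns.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if isinstance(values, pd.DataFrame):
        values = values.set_index("accession_id")["blup"]
    sg = meta.subgroup_of()
    df = pd.DataFrame({"value": values}).join(sg.rename("subgroup"), how="inner")
    df = df.dropna()
    groups = [g["value"].to_numpy() for _, g in df.groupby("subgroup")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise BlupError("need >= 2 subgroups with >= 2 accessions each")
    f, p = stats.f_oneway(*groups)
    tuk = pairwise_tukeyhsd(df["value"].to_numpy(), df["subgroup"].to_numpy())
    pairwise = pd.DataFrame(
        tuk.summary().data[1:], columns=tuk.summary().data[0]
    )
    gstats = (
        df.groupby("subgroup")["value"]
        .agg(n="size", min="min", mean="mean", max="max")
        .reset_index()
    )
    return SubgroupComparison(
        trait=trait,
        omnibus_f=float(f),
        omnibus_p=float(max(p, np.finfo(float).tiny)),
        group_stats=gstats,
        pairwise=pairwise,
    )


def trait_correlations(values: pd.DataFrame) -> pd.DataFrame:
    """Signed pairwise Pearson correlations with p-values.

    *values*: accessions x traits. Returns long-format rows
    (trait_a, trait_b, r, p, n) over pairwise-complete observations.
    """
    cols = list(values.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            sub = values[[a, b] if a != b else [a]].dropna()
            va, vb = sub.iloc[:, 0], sub.iloc[:, -1]
            if len(sub) < 3:
                raise BlupError(f"fewer than 3 paired observations for {a}/{b}")
            if va.std() == 0 or vb.std() == 0:
                raise BlupError(f"constant trait in pair {a}/{b}")
            if a == b:
                r, p = 1.0, 0.0
            else:
                r, p = stats.pearsonr(va, vb)
            rows.append({"trait_a": a, "trait_b": b, "r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)
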