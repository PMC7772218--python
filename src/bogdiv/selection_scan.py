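"""Selection scans: per-locus F_ST with permutation nulls, and ROD.

F_ST uses the Weir & Cockerham (1984) two-population moment estimator
theta-hat built from the among-population (a), among-individual (b) and
within-individual (c) variance components; heterozygote counts enter
through the observed heterozygosity term, so no Hardy-Weinberg
assumption is made. Nei-style G_ST is available as a sensitivity switch.

Significance thresholds come from membership-permutation nulls: each
iteration reshuffles the pooled labels of the two subgroups (preserving
group sizes) and recomputes every per-locus theta-hat; by default all
defined permuted values across iterations are pooled and the empirical
95th percentile is the threshold.

ROD (reduction of diversity) for a breeding step (ancestral, derived) is
1 - He_derived / He_ancestral per locus, He = 2p(1-p); ROD = 1 means the
derived subgroup lost all diversity at a locus still segregating in its
ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import expected_het, subgroup_freqs
from .genotype_io import MISSING, GenotypeMatrix, PanelMetadata

#: Breeding-step taxonomy: step -> (ancestral subgroup, derived subgroup).
ROD_STEPS: dict[str, tuple[str, str]] = {
    "step1": ("WLD", "NS"),
    "step2": ("NS", "CLT1"),
    "step3a": ("CLT1", "CLT2"),
    "step3b": ("NS", "CLT2"),
}

#: ROD report bins: the four headline categories plus the two remainder
#: categories (mid-range and negative) so that everything is accounted for.
ROD_BIN_LABELS = (
    "rod_eq_0",
    "rod_0_to_0.2",
    "rod_0.8_to_1",
    "rod_eq_1",
    "rod_mid_0.2_to_0.8",
    "rod_negative",
)


class ScanError(ValueError):
    pass


@dataclass
class FstScan:
    subgroup_a: str
    subgroup_b: str
    theta: np.ndarray  # per-locus theta-hat, nan where undefined
    markers: pd.DataFrame
    mean_fst: float
    mean_fst_ratio_of_sums: float
    max_fst: float
    estimator: str = "wc84"
    perm_threshold_p95: float | None = None
    n_significant: int | None = None
    n_permutations: int | None = None
    quantile: float | None = None
    seed: int | None = None
    null_mode: str | None = None


@dataclass
class RodScan:
    step: str
    ancestral: str
    derived: str
    rod: np.ndarray  # nan where ancestral He = 0
    he_ancestral: np.ndarray
    he_derived: np.ndarray
    markers: pd.DataFrame
    bin_counts: dict[str, int]
    n_undefined: int

    def __post_init__(self) -> None:
        total = sum(self.bin_counts.values()) + self.n_undefined
        if total != len(self.rod):
            raise ScanError("ROD bin counts do not cover all loci")


# ---------------------------------------------------------------------------
# Weir-Cockerham theta-hat
# ---------------------------------------------------------------------------

def _wc84_components(n1, p1, h1, n2, p2, h2):
    """Vectorized WC84 two-population variance components (a, b, c).

    n: individuals genotyped, p: alt-allele frequency, h: observed
    heterozygote frequency, per population.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
    c = hbar / 2.0
    return a, b, c


def wc_fst_locus(
    counts_a: tuple[int, int, int], counts_b: tuple[int, int, int]
) -> float:
    """WC84 theta-hat at one locus from dosage-class counts (n0, n1, n2).

    ``n0, n1, n2`` are the numbers of individuals carrying 0, 1, 2 copies
    of the alt allele. Returns ``nan`` when undefined (a subgroup with
    fewer than two genotyped individuals, or no variance anywhere).
    """
    a0, a1, a2 = (float(x) for x in counts_a)
    b0, b1, b2 = (float(x) for x in counts_b)
    n1, n2 = a0 + a1 + a2, b0 + b1 + b2
    if n1 < 2 or n2 < 2:
        return float("nan")
    p1, p2 = (a1 + 2 * a2) / (2 * n1), (b1 + 2 * b2) / (2 * n2)
    h1, h2 = a1 / n1, b1 / n2
    a, b, c = _wc84_components(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float(a / denom)


def _theta_vector(dos_a: np.ndarray, dos_b: np.ndarray) -> np.ndarray:
    """Per-locus theta-hat for two dosage submatrices (rows=individuals)."""
    def stats(d):
        obs = d != MISSING
        n = obs.sum(axis=0).astype(float)
        alt = np.where(obs, d, 0).sum(axis=0).astype(float)
        het = ((d == 1) & obs).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = alt / (2.0 * n)
            h = het / n
        return n, p, h

    n1, p1, h1 = stats(dos_a)
    n2, p2, h2 = stats(dos_b)
    a, b, c = _wc84_components(n1, p1, h1, n2, p2, h2)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / (a + b + c)
    theta = np.where((n1 < 2) | (n2 < 2) | (a + b + c == 0), np.nan, theta)
    return theta


def _gst_vector(dos_a: np.ndarray, dos_b: np.ndarray) -> np.ndarray:
    """Nei-style G_ST = 1 - Hs/Ht (sensitivity alternative)."""
    def freq(d):
        obs = d != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(obs, d, 0).sum(axis=0) / (2.0 * n)
        return n, p

    n1, p1 = freq(dos_a)
    n2, p2 = freq(dos_b)
    hs = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
    pbar = 0.5 * (p1 + p2)
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 - hs / ht
    return np.where((n1 < 2) | (n2 < 2) | (ht == 0), np.nan, g)


_ESTIMATORS = {"wc84": _theta_vector, "gst": _gst_vector}


def fst_scan(
    G: GenotypeMatrix,
    meta: PanelMetadata,
    pair: tuple[str, str],
    estimator: str = "wc84",
) -> FstScan:
    """Per-locus F_ST scan between a subgroup pair.

    ``mean_fst`` is the arithmetic mean of defined per-locus estimates
    (negative values retained); the ratio-of-sums (sum a / sum a+b+c)
    variant is reported alongside for the WC84 estimator.
    """
    sg_a, sg_b = pair
    ia = meta.members(sg_a, G.accession_ids)
    ib = meta.members(sg_b, G.accession_ids)
    if len(ia) == 0 or len(ib) == 0:
        raise ScanError(f"empty subgroup in pair {pair}")
    if set(ia) == set(ib):
        raise ScanError(f"pair {pair} has identical membership sets")
    if estimator not in _ESTIMATORS:
        raise ScanError(f"unknown estimator {estimator!r}")
    dos_a, dos_b = G.dosages[ia, :], G.dosages[ib, :]
    theta = _ESTIMATORS[estimator](dos_a, dos_b)

    ratio = float("nan")
    if estimator == "wc84":
        # ratio-of-sums over defined loci
        def stats(d):
            obs = d != MISSING
            n = obs.sum(axis=0).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(obs, d, 0).sum(axis=0) / (2.0 * n)
                h = ((d == 1) & obs).sum(axis=0) / n
            return n, p, h

        n1, p1, h1 = stats(dos_a)
        n2, p2, h2 = stats(dos_b)
        a, b, c = _wc84_components(n1, p1, h1, n2, p2, h2)
        ok = np.isfinite(theta)
        denom = np.nansum((a + b + c)[ok])
        if denom > 0:
            ratio = float(np.nansum(a[ok]) / denom)

    defined = theta[np.isfinite(theta)]
    if defined.size == 0:
        raise ScanError("no defined loci for this pair")
    return FstScan(
        subgroup_a=sg_a,
        subgroup_b=sg_b,
        theta=theta,
        markers=G.markers.copy(),
        mean_fst=float(defined.mean()),
        mean_fst_ratio_of_sums=ratio,
        max_fst=float(defined.max()),
        estimator=estimator,
    )


def fst_permutation_threshold(
    G: GenotypeMatrix,
    meta: PanelMetadata,
    pair: tuple[str, str],
    R: int = 1000,
    q: float = 0.95,
    seed: int | None = None,
    estimator: str = "wc84",
    null_mode: str = "pooled",
) -> FstScan:
    """Membership-permutation F_ST threshold and significant-locus count.

    Each iteration shuffles the pooled membership labels of the two
    subgroups (group sizes preserved) and recomputes every per-locus
    estimate. ``null_mode='pooled'`` (default) pools all defined permuted
    values across iterations and takes their empirical *q*-quantile;
    ``'per_iteration_max'`` takes the *q*-quantile of the per-iteration
    genome-wide maxima (family-wise control).
    """
    if R < 1:
        raise ScanError("R must be >= 1")
    if not (0.0 < q < 1.0):
        raise ScanError("quantile must lie in (0, 1)")
    if null_mode not in ("pooled", "per_iteration_max"):
        raise ScanError(f"unknown null_mode {null_mode!r}")
    scan = fst_scan(G, meta, pair, estimator=estimator)
    ia = meta.members(pair[0], G.accession_ids)
    ib = meta.members(pair[1], G.accession_ids)
    pool = np.concatenate([ia, ib])
    na = len(ia)
    rng = np.random.default_rng(seed)
    est = _ESTIMATORS[estimator]

    null_vals = []
    for _ in range(R):
        perm = rng.permutation(pool)
        th = est(G.dosages[perm[:na], :], G.dosages[perm[na:], :])
        th = th[np.isfinite(th)]
        if null_mode == "pooled":
            null_vals.append(th)
        else:
            if th.size:
                null_vals.append(np.array([th.max()]))
    null = np.concatenate(null_vals)
    if null.size == 0:
        raise ScanError("permutation null is empty")
    thr = float(np.quantile(null, q))
    scan.perm_threshold_p95 = thr
    scan.n_significant = int(np.nansum(scan.theta > thr))
    scan.n_permutations = R
    scan.quantile = q
    scan.seed = seed
    scan.null_mode = null_mode
    return scan


# ---------------------------------------------------------------------------
# Reduction of diversity
# ---------------------------------------------------------------------------

def rod_locus(he_ancestral: float, he_derived: float) -> float:
    """ROD = 1 - He_derived / He_ancestral; nan when He_ancestral = 0.

    May be negative when the derived subgroup is more diverse than its
    ancestor; values are never clamped.
    """
    if he_ancestral == 0 or not np.isfinite(he_ancestral):
        return float("nan")
    return 1.0 - he_derived / he_ancestral


def _rod_bins(rod: np.ndarray) -> dict[str, int]:
    ok = np.isfinite(rod)
    r = rod[ok]
    return {
        "rod_eq_0": int(np.sum(r == 0.0)),
        "rod_0_to_0.2": int(np.sum((r > 0.0) & (r <= 0.2))),
        "rod_0.8_to_1": int(np.sum((r >= 0.8) & (r < 1.0))),
        "rod_eq_1": int(np.sum(r == 1.0)),
        "rod_mid_0.2_to_0.8": int(np.sum((r > 0.2) & (r < 0.8))),
        "rod_negative": int(np.sum(r < 0.0)),
    }


def rod_scan(G: GenotypeMatrix, meta: PanelMetadata, step: str) -> RodScan:
    """Per-locus ROD for one breeding step, with binned counts.

    Steps: step1 NS from WLD; step2 CLT1 from NS; step3a CLT2 from CLT1;
    step3b CLT2 directly from NS.
    """
    if step not in ROD_STEPS:
        raise ScanError(f"unknown step {step!r}; known: {sorted(ROD_STEPS)}")
    anc, der = ROD_STEPS[step]
    F = subgroup_freqs(G, meta)
    he = expected_het(F)
    he_a = he[he["subgroup"] == anc]["he"].to_numpy()
    he_d = he[he["subgroup"] == der]["he"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rod = 1.0 - he_d / he_a
    rod = np.where((he_a == 0) | ~np.isfinite(he_a) | ~np.isfinite(he_d), np.nan, rod)
    bins = _rod_bins(rod)
    return RodScan(
        step=step,
        ancestral=anc,
        derived=der,
        rod=rod,
        he_ancestral=he_a,
        he_derived=he_d,
        markers=G.markers.copy(),
        bin_counts=bins,
        n_undefined=int(np.sum(~np.isfinite(rod))),
    )
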