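"""Intra-chromosomal linkage disequilibrium decay.

Unphased composite LD: r^2 is the squared Pearson correlation of allele
dosages between two loci, computed on pairwise-complete observations.
Decay curves pool all intra-chromosomal pairs up to a maximum distance
into non-overlapping 10-kb bins; the half-decay distance is the upper
edge of the first bin whose mean r^2 falls to half the first-bin mean
(no asymptote subtraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PanelMetadata


class LdError(ValueError):
    pass


@dataclass
class LdDecayCurve:
    subgroup: str
    bin_edges: np.ndarray  # length B+1 (bp)
    mean_r2: np.ndarray  # (B,), nan for empty bins
    pair_counts: np.ndarray  # (B,)
    half_decay_bp: int
    n_pairs_total: int
    per_chromosome: dict[str, pd.DataFrame] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "n_pairs": self.pair_counts.astype(int),
                "mean_r2": self.mean_r2,
            }
        )


def pair_r2(x_dosages: np.ndarray, y_dosages: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete observations (entries missing in either vector
    are dropped); requires >= 3 complete pairs and both loci polymorphic
    on the complete subset, else returns ``nan``.
    """
    x = np.asarray(x_dosages, dtype=float)
    y = np.asarray(y_dosages, dtype=float)
    ok = (x != MISSING) & (y != MISSING) & ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return float("nan")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2_matrix(dos: np.ndarray) -> np.ndarray:
    """All-pairs pairwise-complete r^2 for one chromosome block.

    ``dos``: (n, Lc) int dosages with MISSING sentinel. Every per-pair
    moment over jointly observed entries is a matrix product, so the
    whole block vectorizes.
    """
    V = (dos != MISSING).astype(float)
    A = np.where(dos == MISSING, 0.0, dos).astype(float)
    A2 = A * A
    N = V.T @ V
    Sx = A.T @ V
    Sy = Sx.T
    Sxy = A.T @ A
    Sxx = A2.T @ V
    Syy = Sxx.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = N * Sxy - Sx * Sy
        varx = N * Sxx - Sx * Sx
        vary = N * Syy - Sy * Sy
        r2 = (cov * cov) / (varx * vary)
    r2[(N < 3) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


def decay_curve(
    G: GenotypeMatrix,
    meta: PanelMetadata | None,
    subgroup: str | None,
    bin_bp: int = 10_000,
    max_bp: int = 500_000,
) -> LdDecayCurve:
    """LD decay curve for one subgroup (or the whole panel).

    All intra-chromosomal pairs with 0 < distance <= *max_bp* are binned
    by ``floor(dist / bin_bp)`` and pooled across chromosomes; duplicate
    positions (distance 0) are excluded. Per-chromosome curves are kept
    alongside the pooled one.
    """
    if subgroup is not None:
        if meta is None:
            raise LdError("metadata required to subset a subgroup")
        idx = meta.members(subgroup, G.accession_ids)
        if len(idx) == 0:
            raise LdError(f"subgroup {subgroup!r} empty")
        dosages = G.dosages[idx, :]
        label = subgroup
    else:
        dosages = G.dosages
        label = "ALL"

    n_bins = int(np.ceil(max_bp / bin_bp))
    edges = np.arange(n_bins + 1) * bin_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    per_chrom: dict[str, pd.DataFrame] = {}

    any_pairs = False
    for chrom in pd.unique(G.markers["chrom"]):
        cidx = np.flatnonzero((G.markers["chrom"] == chrom).to_numpy())
        if len(cidx) < 2:
            continue
        pos = G.markers["pos"].to_numpy()[cidx]
        r2 = _pairwise_r2_matrix(dosages[:, cidx])
        iu, ju = np.triu_indices(len(cidx), k=1)
        dist = pos[ju] - pos[iu]
        keep = (dist > 0) & (dist <= max_bp)
        vals = r2[iu[keep], ju[keep]]
        d = dist[keep]
        ok = np.isfinite(vals)
        if not ok.any():
            continue
        any_pairs = True
        b = (d[ok] // bin_bp).astype(int)
        csums = np.zeros(n_bins)
        ccounts = np.zeros(n_bins, dtype=int)
        np.add.at(csums, b, vals[ok])
        np.add.at(ccounts, b, 1)
        sums += csums
        counts += ccounts
        with np.errstate(invalid="ignore"):
            cmean = np.where(ccounts > 0, csums / np.maximum(ccounts, 1), np.nan)
        per_chrom[str(chrom)] = pd.DataFrame(
            {
                "bin_start": edges[:-1],
                "bin_end": edges[1:],
                "n_pairs": ccounts,
                "mean_r2": cmean,
            }
        )
    if not any_pairs:
        raise LdError("no eligible intra-chromosomal pairs")

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    half_decay = _half_decay_bp(mean_r2, edges)
    return LdDecayCurve(
        subgroup=label,
        bin_edges=edges,
        mean_r2=mean_r2,
        pair_counts=counts,
        half_decay_bp=half_decay,
        n_pairs_total=int(counts.sum()),
        per_chromosome=per_chrom,
    )


def _half_decay_bp(mean_r2: np.ndarray, edges: np.ndarray) -> int:
    """Upper edge of the first bin whose mean r^2 <= half the first-bin mean."""
    defined = np.flatnonzero(np.isfinite(mean_r2))
    if defined.size == 0:
        raise LdError("no defined bins in decay curve")
    first = defined[0]
    target = mean_r2[first] / 2.0
    for b in defined:
        if mean_r2[b] <= target:
            return int(edges[b + 1])
    # curve never falls to half its starting value within max distance
    # (no resolvable decay scale, e.g. unlinked loci): report the first bin
    return int(edges[first + 1])
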