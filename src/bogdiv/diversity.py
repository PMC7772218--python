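"""Per-subgroup allele-frequency summaries.

MAF spectra, joint-MAF two-way contingency tables between subgroup pairs,
polymorphic-SNP fractions, and expected heterozygosity He = 2p(1-p) —
the diversity measure that the reduction-of-diversity statistic is built
on downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PanelMetadata


class DiversityError(ValueError):
    pass


@dataclass
class FreqTable:
    """Per (subgroup, marker) alt-allele frequency summary.

    ``table`` columns: subgroup, chrom, pos, p, maf, n_obs. Markers with
    zero non-missing calls in a subgroup carry ``p = maf = nan`` and are
    treated as undefined by every consumer.
    """

    table: pd.DataFrame
    subgroup_sizes: dict[str, int]
    n_markers: int

    def per_subgroup(self, subgroup: str) -> pd.DataFrame:
        sub = self.table[self.table["subgroup"] == subgroup]
        if sub.empty:
            raise DiversityError(f"no frequencies for subgroup {subgroup!r}")
        return sub.reset_index(drop=True)


@dataclass
class JointMafTable:
    """B x B joint MAF histogram between two subgroups."""

    subgroup_a: str
    subgroup_b: str
    counts: np.ndarray  # (B, B), rows = A bins, cols = B bins
    bin_edges: np.ndarray  # length B+1
    diagonal_mass: float
    n_markers: int  # markers with defined MAF in both subgroups


@dataclass
class PolymorphicSummary:
    subgroup: str
    n_polymorphic: int
    n_defined: int
    n_total: int
    #: count / markers with a defined frequency in the subgroup
    fraction_defined: float
    #: count / full filtered marker set
    fraction_total: float


def subgroup_freqs(G: GenotypeMatrix, meta: PanelMetadata) -> FreqTable:
    """Alt-allele frequency, MAF and observation count per subgroup x marker."""
    X = G.dosages_float()
    frames = []
    sizes: dict[str, int] = {}
    for sg in sorted(set(meta.table["subgroup"])):
        idx = meta.members(sg, G.accession_ids)
        if len(idx) == 0:
            raise DiversityError(f"subgroup {sg!r} has no accessions in the matrix")
        sizes[sg] = len(idx)
        sub = X[idx, :]
        n_obs = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            tot = np.nansum(sub, axis=0)
            p = np.where(n_obs > 0, tot / (2.0 * np.maximum(n_obs, 1)), np.nan)
        if not np.any(n_obs > 0):
            raise DiversityError(f"subgroup {sg!r} has no non-missing calls")
        frames.append(
            pd.DataFrame(
                {
                    "subgroup": sg,
                    "chrom": G.markers["chrom"].to_numpy(),
                    "pos": G.markers["pos"].to_numpy(),
                    "p": p,
                    "maf": np.minimum(p, 1.0 - p),
                    "n_obs": n_obs,
                }
            )
        )
    return FreqTable(
        pd.concat(frames, ignore_index=True), sizes, G.n_markers
    )


def polymorphic_fraction(F: FreqTable, subgroup: str) -> PolymorphicSummary:
    """Count and fraction of markers segregating (0 < p < 1) in a subgroup.

    Two denominators are reported: markers with a defined frequency in the
    subgroup, and the full filtered marker set.
    """
    sub = F.per_subgroup(subgroup)
    defined = sub["p"].notna()
    poly = defined & (sub["p"] > 0.0) & (sub["p"] < 1.0)
    n_def = int(defined.sum())
    n_poly = int(poly.sum())
    return PolymorphicSummary(
        subgroup=subgroup,
        n_polymorphic=n_poly,
        n_defined=n_def,
        n_total=F.n_markers,
        fraction_defined=n_poly / n_def if n_def else float("nan"),
        fraction_total=n_poly / F.n_markers,
    )


def maf_bin_edges(bin_width: float = 0.05) -> np.ndarray:
    nbins = 0.5 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise DiversityError(f"bin_width {bin_width} does not divide 0.5")
    return np.round(np.arange(round(nbins) + 1) * bin_width, 12)


def _bin_maf(maf: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [l, l+w) with the final bin closed at 0.5."""
    b = np.digitize(maf, edges, right=False) - 1
    return np.clip(b, 0, len(edges) - 2)


def joint_maf(
    F: FreqTable,
    subgroup_a: str,
    subgroup_b: str,
    bin_width: float = 0.05,
) -> JointMafTable:
    """Two-way MAF contingency table between a pair of subgroups.

    Only markers with a defined MAF in both subgroups contribute. The
    diagonal mass (fraction of markers falling in identical bins) is a
    scalar similarity summary: subsequent breeding stages show higher
    diagonal mass than stages separated by a strong bottleneck.
    """
    edges = maf_bin_edges(bin_width)
    a = F.per_subgroup(subgroup_a)["maf"].to_numpy()
    b = F.per_subgroup(subgroup_b)["maf"].to_numpy()
    ok = ~np.isnan(a) & ~np.isnan(b)
    if not ok.any():
        raise DiversityError(
            f"no common defined markers between {subgroup_a} and {subgroup_b}"
        )
    ia, ib = _bin_maf(a[ok], edges), _bin_maf(b[ok], edges)
    B = len(edges) - 1
    counts = np.zeros((B, B), dtype=int)
    np.add.at(counts, (ia, ib), 1)
    return JointMafTable(
        subgroup_a=subgroup_a,
        subgroup_b=subgroup_b,
        counts=counts,
        bin_edges=edges,
        diagonal_mass=float(np.trace(counts) / counts.sum()),
        n_markers=int(ok.sum()),
    )


def expected_het(F: FreqTable) -> pd.DataFrame:
    """Expected heterozygosity He = 2 p (1 - p) per (subgroup, marker)."""
    out = F.table.copy()
    out["he"] = 2.0 * out["p"] * (1.0 - out["p"])
    return out
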