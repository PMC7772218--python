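"""Genotype and metadata I/O for the diversity panel.

Reads biallelic SNP genotypes from VCF into an allele-dosage matrix,
applies the panel's marker filters (missingness, then minor allele
frequency), and round-trips matrices and metadata through plain TSV.

Dosage coding: 0/1/2 copies of the ALT allele; missing calls are stored
as the reserved sentinel :data:`MISSING` (never 0). Coordinates are
1-based inclusive, as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Reserved missing-genotype sentinel in dosage matrices (int8-safe).
MISSING: int = -1

#: The twelve chromosomes of the cranberry reference used by default for
#: matrix-file validation. Pass ``valid_chroms=None`` to accept any label.
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 13))

#: Breeding-stage subgroups: wild clones, native (first-generation)
#: selections, first-generation hybrid cultivars, advanced selections.
SUBGROUPS: tuple[str, ...] = ("WLD", "NS", "CLT1", "CLT2")

MARKER_COLUMNS = ("chrom", "pos", "ref", "alt")


class GenotypeIOError(ValueError):
    """Raised for malformed genotype/metadata inputs."""


@dataclass
class GenotypeMatrix:
    """n accessions x L markers allele-dosage matrix with coordinates.

    Parameters
    ----------
    dosages
        ``(n, L)`` integer array with entries in {0, 1, 2} or :data:`MISSING`.
    accession_ids
        Length-n accession identifiers (unique).
    markers
        Length-L frame with columns ``chrom, pos, ref, alt``; positions
        strictly increasing within each chromosome.
    """

    dosages: np.ndarray
    accession_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.markers = self.markers.reset_index(drop=True)
        n, L = self.dosages.shape
        if n < 2:
            raise GenotypeIOError(f"need at least 2 accessions, got {n}")
        if L < 1:
            raise GenotypeIOError("need at least 1 marker")
        if len(self.accession_ids) != n:
            raise GenotypeIOError("accession_ids length does not match dosage rows")
        if len(set(self.accession_ids)) != n:
            raise GenotypeIOError("duplicate accession ids")
        if list(self.markers.columns[:4]) != list(MARKER_COLUMNS):
            raise GenotypeIOError(
                f"marker table must have columns {MARKER_COLUMNS}, got {list(self.markers.columns)}"
            )
        if len(self.markers) != L:
            raise GenotypeIOError("marker table length does not match dosage columns")
        vals = np.unique(self.dosages)
        bad = set(vals.tolist()) - {MISSING, 0, 1, 2}
        if bad:
            raise GenotypeIOError(f"invalid dosage values {sorted(bad)}")
        if (self.markers["pos"] < 1).any():
            raise GenotypeIOError("positions must be >= 1 (1-based)")
        same = self.markers["ref"].astype(str) == self.markers["alt"].astype(str)
        if same.any():
            raise GenotypeIOError("ref and alt alleles must differ at every marker")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeIOError(
                    f"positions not strictly increasing on {chrom}"
                )

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask of missing calls."""
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing entries set to ``nan``."""
        X = self.dosages.astype(float)
        X[self.dosages == MISSING] = np.nan
        return X

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset markers by positional index, preserving order."""
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.accession_ids),
            self.markers.iloc[np.asarray(idx)].reset_index(drop=True),
        )

    def take_accessions(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx, :],
            [self.accession_ids[i] for i in idx],
            self.markers.copy(),
        )


@dataclass
class PanelMetadata:
    """Accession -> subgroup/origin assignment for the panel."""

    table: pd.DataFrame  # columns: accession_id, subgroup, origin

    def __post_init__(self) -> None:
        req = {"accession_id", "subgroup", "origin"}
        missing = req - set(self.table.columns)
        if missing:
            raise GenotypeIOError(f"metadata missing columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["accession_id"].astype(str)
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise GenotypeIOError(f"duplicate accessions in metadata: {dups[:5]}")
        bad = set(self.table["subgroup"]) - set(SUBGROUPS)
        if bad:
            raise GenotypeIOError(
                f"unknown subgroup labels {sorted(bad)}; expected {SUBGROUPS}"
            )

    def subgroup_of(self) -> pd.Series:
        return self.table.set_index("accession_id")["subgroup"]

    def members(self, subgroup: str, accession_ids: list[str]) -> np.ndarray:
        """Row indices (into *accession_ids*) belonging to *subgroup*."""
        mine = set(
            self.table.loc[self.table["subgroup"] == subgroup, "accession_id"]
        )
        return np.array([i for i, a in enumerate(accession_ids) if a in mine], dtype=int)

    def counts(self) -> pd.Series:
        return self.table["subgroup"].value_counts()


@dataclass
class FilterReport:
    """Sequential attribution of marker removals (missingness first)."""

    n_input_snps: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int
    max_missing: float
    min_maf: float
    n_skipped_nonbiallelic: int = 0
    n_collapsed_duplicates: int = 0

    def __post_init__(self) -> None:
        if self.n_input_snps != (
            self.n_removed_missing + self.n_removed_maf + self.n_retained
        ):
            raise GenotypeIOError("filter report counts do not add up")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(
    path: str,
    metadata_path: str | None = None,
    valid_chroms: tuple[str, ...] | None = None,
) -> tuple[GenotypeMatrix, PanelMetadata | None]:
    """Read a VCF into a :class:`GenotypeMatrix` (+ metadata if given).

    Non-biallelic / non-SNP records are skipped with a logged count;
    duplicate (chrom, pos) records are collapsed to the first occurrence.
    Every VCF sample must be present in the metadata when metadata is
    supplied.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)

    rows = []
    dosage_cols: list[np.ndarray] = []
    n_skipped = 0
    n_dup = 0
    seen: set[tuple[str, int]] = set()
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        key = (v.CHROM, v.POS)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        # gts012: 0/1/2 = alt-dosage, 3 = unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        dosage_cols.append(g)
    vcf.close()
    if n_skipped:
        log.info("skipped %d non-biallelic-SNP records", n_skipped)
    if n_dup:
        log.info("collapsed %d duplicate-position records to first occurrence", n_dup)
    if not rows:
        raise GenotypeIOError(f"no biallelic SNP records in {path}")

    markers = pd.DataFrame(rows, columns=list(MARKER_COLUMNS))
    if valid_chroms is not None:
        bad = set(markers["chrom"]) - set(valid_chroms)
        if bad:
            raise GenotypeIOError(f"unknown chromosome label(s): {sorted(bad)}")
    dosages = np.stack(dosage_cols, axis=1)  # (n, L)
    G = GenotypeMatrix(dosages, samples, markers)
    G.n_skipped_nonbiallelic = n_skipped  # type: ignore[attr-defined]
    G.n_collapsed_duplicates = n_dup  # type: ignore[attr-defined]

    meta = None
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        known = set(meta.table["accession_id"].astype(str))
        absent = [s for s in samples if s not in known]
        if absent:
            raise GenotypeIOError(
                f"samples absent from metadata: {absent[:5]}"
                + ("..." if len(absent) > 5 else "")
            )
    return G, meta


def read_metadata(path: str) -> PanelMetadata:
    """Read the accession metadata TSV (accession_id, subgroup, origin)."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    return PanelMetadata(t)


def write_metadata(meta: PanelMetadata, path: str) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

def panel_maf(G: GenotypeMatrix) -> np.ndarray:
    """Panel-wide minor allele frequency per marker (non-missing calls).

    Markers with zero non-missing calls get ``nan``.
    """
    X = G.dosages_float()
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_markers(
    G: GenotypeMatrix,
    max_missing: float = 0.30,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the panel's marker filters: missingness, then MAF.

    A marker is retained iff its missing fraction is <= *max_missing* and
    its panel-wide MAF (computed on non-missing calls, among the markers
    that survived the missingness filter) is >= *min_maf*. Removal counts
    are attributed sequentially in that order.
    """
    if not (0.0 <= max_missing <= 1.0) or not (0.0 <= min_maf <= 1.0):
        raise GenotypeIOError("thresholds must lie in [0, 1]")
    n, L = G.dosages.shape
    miss_frac = (G.dosages == MISSING).mean(axis=0)
    pass_miss = miss_frac <= max_missing

    maf = panel_maf(G)
    # nan MAF (no calls at all) can only occur with max_missing == 1
    with np.errstate(invalid="ignore"):
        pass_maf = maf >= min_maf
    pass_maf &= ~np.isnan(maf)

    keep = pass_miss & pass_maf
    n_removed_missing = int((~pass_miss).sum())
    n_removed_maf = int((pass_miss & ~pass_maf).sum())
    n_retained = int(keep.sum())
    if n_retained == 0:
        raise GenotypeIOError(
            "all markers removed by filtering "
            f"(max_missing={max_missing}, min_maf={min_maf})"
        )
    report = FilterReport(
        n_input_snps=L,
        n_removed_missing=n_removed_missing,
        n_removed_maf=n_removed_maf,
        n_retained=n_retained,
        max_missing=max_missing,
        min_maf=min_maf,
        n_skipped_nonbiallelic=getattr(G, "n_skipped_nonbiallelic", 0),
        n_collapsed_duplicates=getattr(G, "n_collapsed_duplicates", 0),
    )
    return G.take_markers(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# TSV matrix round-trip
# ---------------------------------------------------------------------------

def write_matrix(G: GenotypeMatrix, path: str) -> None:
    """Write a markers x accessions dosage TSV; missing encoded as ``NA``."""
    dos = G.dosages.T.astype(object)  # (L, n)
    dos[dos == MISSING] = "NA"
    df = pd.concat(
        [G.markers, pd.DataFrame(dos, columns=G.accession_ids)], axis=1
    )
    df.to_csv(path, sep="\t", index=False)


def read_matrix(
    path: str, valid_chroms: tuple[str, ...] | None = CHROMOSOMES
) -> GenotypeMatrix:
    """Read a dosage TSV written by :func:`write_matrix` (lossless)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    if list(df.columns[:4]) != list(MARKER_COLUMNS):
        raise GenotypeIOError(
            f"matrix header must start with {MARKER_COLUMNS}, got {list(df.columns[:4])}"
        )
    if df.shape[1] < 6:
        raise GenotypeIOError("matrix file must contain at least two sample columns")
    if len(df) == 0:
        raise GenotypeIOError("matrix file contains no markers")
    markers = df[list(MARKER_COLUMNS)].copy()
    if valid_chroms is not None:
        bad = set(markers["chrom"]) - set(valid_chroms)
        if bad:
            raise GenotypeIOError(f"unknown chromosome label(s): {sorted(bad)}")
    samples = list(df.columns[4:])
    dos = df[samples].to_numpy(dtype=object)
    out = np.empty(dos.shape, dtype=np.int8)
    is_na = pd.isna(dos) | (dos == "NA")
    out[is_na] = MISSING
    out[~is_na] = np.asarray(dos[~is_na], dtype=float).astype(np.int8)
    return GenotypeMatrix(out.T, samples, markers)


# ---------------------------------------------------------------------------
# VCF output (plain-text VCF 4.2; consumed back through read_vcf)
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write the dosage matrix as an unphased biallelic-SNP VCF 4.2 file."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bogdiv\n")
        for chrom, sub in G.markers.groupby("chrom", sort=False):
            fh.write(
                f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.accession_ids)
            + "\n"
        )
        m = G.markers
        for l in range(G.n_markers):
            gts = "\t".join(gt_map[int(d)] for d in G.dosages[:, l])
            fh.write(
                f"{m.at[l, 'chrom']}\t{int(m.at[l, 'pos'])}\t"
                f"{m.at[l, 'chrom']}_{int(m.at[l, 'pos'])}\t"
                f"{m.at[l, 'ref']}\t{m.at[l, 'alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
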