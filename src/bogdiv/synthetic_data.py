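"""Ground-truth domestication simulator.

Generates genotype + phenotype panels under a four-stage nested
bottleneck mirroring the breeding history the rest of the package
analyses: wild clones (WLD) sampled from substructured demes; native
selections (NS) obtained by truncation selection of wild individuals on
a polygenic trait; first-generation cultivars (CLT1) bred in two
generations of crosses from 7 NS founders; advanced selections (CLT2)
from crosses constrained to 8 grandparents (the 7 founders plus one
extra NS).

Wild haplotypes carry intra-chromosomal LD from a first-order Markov
chain along each chromosome: adjacent alleles have Pearson correlation
exp(-gap / d0), so the correlation between any two loci on a chromosome
is exp(-distance / d0) by the chain product — a closed-form decay target
for the LD module. Deme allele frequencies follow the Balding-Nichols
distribution around the ancestral frequency, giving a closed-form
expected F_ST. Crosses recombine with Poisson crossovers, phenotypes add
year effects, a smooth spatial field over the trial grid, and residual
noise at configured heritabilities, and genotypes are masked completely
at random.

All randomness flows from one master seed through numpy SeedSequence
spawning (one child stream per simulation stage, in a fixed order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .genotype_io import (
    CHROMOSOMES,
    MISSING,
    GenotypeMatrix,
    PanelMetadata,
    write_matrix,
    write_metadata,
    write_vcf,
)
from .phenotype_blup import TRAITS


class SimulationError(ValueError):
    pass


@dataclass
class QtlSpec:
    trait: str
    marker_index: int  # index into the simulated marker map
    effect: float  # additive effect per alt allele, phenotype SD units


@dataclass
class ScenarioConfig:
    """Study conditions for the four-stage domestication scenario.

    Defaults follow the diversity panel: subgroup sizes 121/111/26/104,
    12 chromosomes with ~22 kb mean marker gap, LD scale d0 = 30 kb,
    4 wild demes at F = 0.05, 7 founders for the cultivar step and
    8 grandparents for advanced selections, 15% missing genotypes.
    """

    n_wld: int = 121
    n_ns: int = 111
    n_clt1: int = 26
    n_clt2: int = 104
    n_markers: int = 1200
    n_chromosomes: int = 12
    mean_gap_bp: float = 22_000.0
    maf_beta: tuple[float, float] = (0.4, 0.4)  # ancestral freq ~ Beta, many rare alleles
    n_demes: int = 4
    deme_fst: float = 0.05
    ld_scale_bp: float | None = 30_000.0  # None -> unlinked loci
    n_founders_stage2: int = 7
    n_grandparents_stage3: int = 8
    wild_pool_factor: float = 3.0  # NS candidates per NS slot
    candidate_factor: int = 3  # cross candidates per selected slot
    selection_h2: float = 0.5  # accuracy^2 of historical phenotypic selection
    n_causal: int = 100  # polygenic loci per trait
    qtls: list[QtlSpec] = field(default_factory=list)
    heritabilities: dict[str, float] = field(
        default_factory=lambda: {
            "yield": 0.4,
            "fruit_weight": 0.5,
            "fruit_rot": 0.3,
            "TACy": 0.5,
            "brix": 0.4,
            "acids": 0.3,
        }
    )
    year_var_share: float = 0.15
    spatial_var_share: float = 0.10
    spatial_smoothness: float = 2.0  # gaussian-filter sigma on the trial grid
    years: tuple[int, ...] = (2006, 2007, 2008, 2009, 2010, 2014, 2015)
    missing_rate: float = 0.15
    crossovers_per_chrom: float = 1.0
    clonal_duplication: bool = False  # optional clonal copies of selected plants
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_wld", "n_ns", "n_clt1", "n_clt2", "n_markers", "n_demes"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if not (0.0 <= self.deme_fst < 1.0):
            raise SimulationError("deme_fst must lie in [0, 1)")
        if self.ld_scale_bp is not None and self.ld_scale_bp <= 0:
            raise SimulationError("ld_scale_bp must be positive")
        if not (0.0 <= self.missing_rate <= 0.30):
            raise SimulationError("missing_rate must lie in [0, 0.30]")
        for t, h2 in self.heritabilities.items():
            if not (0.0 <= h2 <= 1.0):
                raise SimulationError(f"heritability for {t} outside [0,1]")
        if self.n_founders_stage2 > self.n_ns:
            raise SimulationError("more stage-2 founders than NS accessions")
        if self.n_grandparents_stage3 > self.n_ns:
            raise SimulationError("more stage-3 grandparents than NS accessions")
        if self.n_grandparents_stage3 < self.n_founders_stage2:
            raise SimulationError("grandparent set must contain the founders")


TRAIT_SCALE = {  # phenotype location/scale used to place traits on field units
    "yield": (125.0, 60.0),
    "fruit_weight": (1.7, 0.5),
    "fruit_rot": (15.0, 12.0),
    "TACy": (20.0, 10.0),
    "brix": (9.4, 0.8),
    "acids": (2.2, 0.25),
}


@dataclass
class TruthRecord:
    ancestral_freqs: np.ndarray
    deme_freqs: np.ndarray  # (n_demes, L)
    stage_freqs: dict[str, np.ndarray]  # recomputed from emitted genotypes
    founder_ids: list[str]
    grandparent_ids: list[str]
    qtls: list[QtlSpec]
    true_bv: pd.DataFrame  # accessions x traits
    spatial_field: np.ndarray
    year_effects: dict[str, dict[int, float]]
    heritabilities: dict[str, float]
    positions: pd.DataFrame


@dataclass
class SimulatedPanel:
    genotypes: GenotypeMatrix  # masked (missing injected)
    metadata: PanelMetadata
    phenotypes: pd.DataFrame
    truth: TruthRecord
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _marker_map(rng: np.random.Generator, cfg: ScenarioConfig) -> pd.DataFrame:
    per = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes, dtype=int)
    per[: cfg.n_markers % cfg.n_chromosomes] += 1
    bases = np.array(list("ACGT"))
    rows = []
    for c in range(cfg.n_chromosomes):
        gaps = rng.exponential(cfg.mean_gap_bp, size=per[c]).astype(int) + 200
        pos = np.cumsum(gaps)
        ref = rng.choice(4, size=per[c])
        alt = (ref + rng.integers(1, 4, size=per[c])) % 4
        chrom = CHROMOSOMES[c] if c < len(CHROMOSOMES) else f"chr{c+1}"
        for p, rf, al in zip(pos, ref, alt):
            rows.append((chrom, int(p), bases[rf], bases[al]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def _chrom_slices(markers: pd.DataFrame) -> list[tuple[int, int]]:
    out = []
    start = 0
    for _, sub in markers.groupby("chrom", sort=False):
        out.append((start, start + len(sub)))
        start += len(sub)
    return out


def balding_nichols_freqs(
    rng: np.random.Generator, p_anc: np.ndarray, fst: float, n_pops: int
) -> np.ndarray:
    """Per-population allele frequencies around ancestral p at divergence F."""
    if fst <= 0:
        return np.tile(p_anc, (n_pops, 1))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    out = rng.beta(np.tile(a, (n_pops, 1)), np.tile(b, (n_pops, 1)))
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def _markov_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    freqs: np.ndarray,
    markers: pd.DataFrame,
    d0: float | None,
) -> np.ndarray:
    """(n_hap, L) 0/1 haplotypes with adjacent-allele correlation exp(-gap/d0)."""
    L = len(freqs)
    H = np.empty((n_hap, L), dtype=np.int8)
    pos = markers["pos"].to_numpy()
    for s, e in _chrom_slices(markers):
        H[:, s] = rng.random(n_hap) < freqs[s]
        for l in range(s + 1, e):
            p_prev, p_cur = freqs[l - 1], freqs[l]
            if d0 is None:
                cond = np.full(n_hap, p_cur)
            else:
                rho = np.exp(-(pos[l] - pos[l - 1]) / d0)
                sd_ratio = np.sqrt(
                    p_cur * (1 - p_cur) / (p_prev * (1 - p_prev))
                )
                cond = p_cur + rho * sd_ratio * (H[:, l - 1] - p_prev)
                np.clip(cond, 0.0, 1.0, out=cond)
            H[:, l] = rng.random(n_hap) < cond
    return H


def _gamete(
    rng: np.random.Generator,
    hap_pair: np.ndarray,  # (2, L)
    slices: list[tuple[int, int]],
    xover_rate: float,
) -> np.ndarray:
    out = np.empty(hap_pair.shape[1], dtype=np.int8)
    for s, e in slices:
        L_c = e - s
        n_x = rng.poisson(xover_rate)
        cur = int(rng.integers(2))
        if n_x == 0:
            out[s:e] = hap_pair[cur, s:e]
            continue
        cuts = np.sort(rng.integers(1, L_c, size=n_x))
        prev = 0
        for cut in list(cuts) + [L_c]:
            out[s + prev : s + cut] = hap_pair[cur, s + prev : s + cut]
            cur = 1 - cur
            prev = cut
    return out


def _cross(rng, hp_a, hp_b, slices, xover_rate):
    return np.stack([
        _gamete(rng, hp_a, slices, xover_rate),
        _gamete(rng, hp_b, slices, xover_rate),
    ])


# ---------------------------------------------------------------------------
# main scenario
# ---------------------------------------------------------------------------

def simulate_panel(config: ScenarioConfig | None = None, **overrides) -> SimulatedPanel:
    """Simulate the four-stage panel with full ground truth."""
    if config is None:
        config = ScenarioConfig(**overrides)
    elif overrides:
        raise SimulationError("pass either a config or keyword overrides, not both")
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_map, rng_freq, rng_wild, rng_breed, rng_arch, rng_pheno, rng_miss, rng_field = (
        np.random.default_rng(s) for s in streams
    )

    markers = _marker_map(rng_map, cfg)
    L = len(markers)
    slices = _chrom_slices(markers)

    a, b = cfg.maf_beta
    p_anc = np.clip(rng_freq.beta(a, b, size=L), 0.02, 0.98)
    deme_p = balding_nichols_freqs(rng_freq, p_anc, cfg.deme_fst, cfg.n_demes)

    # --- trait architecture ---------------------------------------------
    qtls = list(cfg.qtls)
    if not qtls:
        qtls = [QtlSpec("fruit_weight", int(rng_arch.integers(L)), 0.6)]
    causal: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for t in TRAITS:
        idx = rng_arch.choice(L, size=min(cfg.n_causal, L), replace=False)
        eff = rng_arch.normal(0.0, 1.0 / np.sqrt(len(idx)), size=len(idx))
        causal[t] = (idx, eff)

    def breeding_values(dosage: np.ndarray) -> dict[str, np.ndarray]:
        bv = {}
        for t in TRAITS:
            idx, eff = causal[t]
            v = dosage[:, idx] @ eff
            for q in qtls:
                if q.trait == t:
                    v = v + q.effect * dosage[:, q.marker_index]
            bv[t] = v
        return bv

    # --- wild stage ------------------------------------------------------
    n_pool = int(np.ceil(cfg.n_ns * cfg.wild_pool_factor))
    n_wild_total = cfg.n_wld + n_pool
    deme_of = rng_wild.integers(cfg.n_demes, size=n_wild_total)
    haps = np.empty((n_wild_total, 2, L), dtype=np.int8)
    for d in range(cfg.n_demes):
        rows = np.flatnonzero(deme_of == d)
        if rows.size == 0:
            continue
        hh = _markov_haplotypes(
            rng_wild, 2 * rows.size, deme_p[d], markers, cfg.ld_scale_bp
        )
        haps[rows] = hh.reshape(rows.size, 2, L)

    dos_wild_all = haps.sum(axis=1)
    bv_all = breeding_values(dos_wild_all)
    # historical selection criterion: yield + fruit weight index, observed
    # with accuracy sqrt(selection_h2)
    index_bv = (
        _standardize(bv_all["yield"]) + _standardize(bv_all["fruit_weight"])
    ) / np.sqrt(2)
    noise = rng_breed.normal(size=n_wild_total)
    crit = np.sqrt(cfg.selection_h2) * index_bv + np.sqrt(1 - cfg.selection_h2) * noise

    wld_rows = np.arange(cfg.n_wld)  # unselected wild clones
    pool_rows = np.arange(cfg.n_wld, n_wild_total)
    ns_rows = pool_rows[np.argsort(crit[pool_rows])[::-1][: cfg.n_ns]]
    if cfg.clonal_duplication and cfg.n_ns >= 2:
        # propagate the top selection clonally into the last NS slot
        ns_rows = ns_rows.copy()
        ns_rows[-1] = ns_rows[0]

    # --- stage 2: cultivars from 7 NS founders --------------------------
    founder_local = ns_rows[np.argsort(crit[ns_rows])[::-1][: cfg.n_founders_stage2]]
    f1 = []
    n_f1 = max(3 * cfg.n_founders_stage2, 20)
    for _ in range(n_f1):
        if cfg.n_founders_stage2 >= 2:
            i, j = rng_breed.choice(cfg.n_founders_stage2, size=2, replace=False)
        else:
            i = j = 0  # single founder: selfing (the species is self-fertile)
        f1.append(
            _cross(rng_breed, haps[founder_local[i]], haps[founder_local[j]],
                   slices, cfg.crossovers_per_chrom)
        )
    f1 = np.stack(f1)
    n_cand1 = cfg.candidate_factor * cfg.n_clt1
    cand1 = np.stack([
        _cross(rng_breed, f1[i], f1[j], slices, cfg.crossovers_per_chrom)
        for i, j in (
            rng_breed.choice(len(f1), size=2, replace=False) for _ in range(n_cand1)
        )
    ])
    bv_c1 = breeding_values(cand1.sum(axis=1))
    idx1 = _select(rng_breed, bv_c1, cfg.selection_h2, cfg.n_clt1)
    clt1 = cand1[idx1]

    # --- stage 3: advanced selections, 8 grandparents -------------------
    extra = [r for r in ns_rows if r not in set(founder_local)]
    n_extra = cfg.n_grandparents_stage3 - cfg.n_founders_stage2
    extra_gp = np.array(extra[:n_extra], dtype=int)
    bridge = []  # NS-grandparent x founder crosses (the CLT1 x NS route)
    for g in extra_gp:
        for _ in range(6):
            j = int(rng_breed.integers(cfg.n_founders_stage2))
            bridge.append(
                _cross(rng_breed, haps[g], haps[founder_local[j]],
                       slices, cfg.crossovers_per_chrom)
            )
    bridge = np.stack(bridge) if bridge else np.empty((0, 2, L), dtype=np.int8)
    n_cand2 = cfg.candidate_factor * cfg.n_clt2
    parents_a = clt1
    cand2 = []
    for _ in range(n_cand2):
        if len(bridge) and rng_breed.random() < 0.3:
            pa = parents_a[rng_breed.integers(len(parents_a))]
            pb = bridge[rng_breed.integers(len(bridge))]
        else:
            i, j = rng_breed.choice(len(parents_a), size=2, replace=False)
            pa, pb = parents_a[i], parents_a[j]
        cand2.append(_cross(rng_breed, pa, pb, slices, cfg.crossovers_per_chrom))
    cand2 = np.stack(cand2)
    bv_c2 = breeding_values(cand2.sum(axis=1))
    idx2 = _select(rng_breed, bv_c2, cfg.selection_h2, cfg.n_clt2)
    clt2 = cand2[idx2]

    # --- assemble panel --------------------------------------------------
    ids, sgs, origins, dosages = [], [], [], []

    def add(stage, hp_block, origin_fn):
        dos = hp_block.sum(axis=1)
        for i in range(len(dos)):
            ids.append(f"{stage}{i+1:03d}")
            sgs.append(stage)
            origins.append(origin_fn(i))
            dosages.append(dos[i])

    add("WLD", haps[wld_rows], lambda i: f"deme{deme_of[wld_rows[i]]+1}")
    add("NS", haps[ns_rows], lambda i: f"deme{deme_of[ns_rows[i]]+1}")
    add("CLT1", clt1, lambda i: "bred")
    add("CLT2", clt2, lambda i: "bred")
    dosage = np.stack(dosages).astype(np.int8)
    n_total = len(ids)

    meta = PanelMetadata(
        pd.DataFrame({"accession_id": ids, "subgroup": sgs, "origin": origins})
    )

    founder_ids = [f"NS{np.flatnonzero(ns_rows == r)[0]+1:03d}" for r in founder_local]
    gp_ids = founder_ids + [
        f"NS{np.flatnonzero(ns_rows == r)[0]+1:03d}" for r in extra_gp
    ]

    # --- phenotypes ------------------------------------------------------
    bv_panel = breeding_values(dosage.astype(float))
    true_bv = pd.DataFrame(bv_panel, index=ids)

    grid = int(np.ceil(np.sqrt(n_total)))
    fld = rng_field.standard_normal((grid, grid))
    fld = gaussian_filter(fld, sigma=cfg.spatial_smoothness, mode="reflect")
    fld = fld / (fld.std() or 1.0)
    cells = rng_field.permutation(grid * grid)[:n_total]
    rows_ = cells // grid + 1
    cols_ = cells % grid + 1

    records = []
    year_effects: dict[str, dict[int, float]] = {}
    for t in TRAITS:
        h2 = cfg.heritabilities.get(t, 0.4)
        g = bv_panel[t]
        var_g = float(np.var(g)) or 1.0
        var_tot = var_g / max(h2, 1e-6)
        v_year = cfg.year_var_share * var_tot
        v_spat = cfg.spatial_var_share * var_tot
        v_res = max(var_tot - var_g - v_year - v_spat, 1e-8)
        ye = {y: rng_pheno.normal(0.0, np.sqrt(v_year)) for y in cfg.years}
        year_effects[t] = ye
        mu, sd_target = TRAIT_SCALE.get(t, (0.0, 1.0))
        scale = sd_target / np.sqrt(var_tot)
        for k, y in enumerate(cfg.years):
            eps = rng_pheno.normal(0.0, np.sqrt(v_res), size=n_total)
            spat = np.sqrt(v_spat) * fld[rows_ - 1, cols_ - 1]
            val = mu + scale * (g - g.mean() + ye[y] + spat + eps)
            for i in range(n_total):
                records.append(
                    (ids[i], t, float(val[i]), int(y), int(rows_[i]), int(cols_[i]))
                )
    phenotypes = pd.DataFrame(
        records, columns=["accession_id", "trait", "value", "year", "row", "col"]
    )

    # --- stage frequencies (truth, pre-masking) --------------------------
    stage_freqs = {}
    for sg in ("WLD", "NS", "CLT1", "CLT2"):
        rows = [i for i, s in enumerate(sgs) if s == sg]
        stage_freqs[sg] = dosage[rows].mean(axis=0) / 2.0

    # --- masking ---------------------------------------------------------
    masked = dosage.copy()
    if cfg.missing_rate > 0:
        m = rng_miss.random(masked.shape) < cfg.missing_rate
        masked[m] = MISSING

    G = GenotypeMatrix(masked, ids, markers)
    truth = TruthRecord(
        ancestral_freqs=p_anc,
        deme_freqs=deme_p,
        stage_freqs=stage_freqs,
        founder_ids=founder_ids,
        grandparent_ids=gp_ids,
        qtls=qtls,
        true_bv=true_bv,
        spatial_field=fld,
        year_effects=year_effects,
        heritabilities=dict(cfg.heritabilities),
        positions=markers.copy(),
    )
    return SimulatedPanel(G, meta, phenotypes, truth, cfg)


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / (s if s > 0 else 1.0)


def _select(rng, bv: dict[str, np.ndarray], sel_h2: float, n: int) -> np.ndarray:
    index_bv = (_standardize(bv["yield"]) + _standardize(bv["fruit_weight"])) / np.sqrt(2)
    crit = np.sqrt(sel_h2) * index_bv + np.sqrt(1 - sel_h2) * rng.normal(size=len(index_bv))
    return np.argsort(crit)[::-1][:n]


# ---------------------------------------------------------------------------
# focused generators for calibration / recovery experiments
# ---------------------------------------------------------------------------

def simulate_structured_population(
    n_per_group: tuple[int, int] = (100, 100),
    L: int = 2000,
    fst: float = 0.05,
    seed: int | None = None,
    d0: float | None = None,
    labels: tuple[str, str] = ("WLD", "NS"),
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, PanelMetadata, np.ndarray]:
    """Two Balding-Nichols demes (fst=0 -> one panmictic population).

    Loci are unlinked unless *d0* is given. Returns the genotypes, a
    metadata table labelling the two demes, and the ancestral
    frequencies.
    """
    rng = np.random.default_rng(seed)
    cfg = ScenarioConfig(n_markers=L, mean_gap_bp=22_000.0)
    markers = _marker_map(rng, cfg)
    p_anc = np.clip(rng.uniform(0.05, 0.95, size=L), 0.05, 0.95)
    pops = balding_nichols_freqs(rng, p_anc, fst, 2)
    blocks, ids, sgs = [], [], []
    for g, (n_g, lab) in enumerate(zip(n_per_group, labels)):
        H = _markov_haplotypes(rng, 2 * n_g, pops[g], markers, d0)
        blocks.append(H.reshape(n_g, 2, L).sum(axis=1))
        ids += [f"{lab}{i+1:03d}" for i in range(n_g)]
        sgs += [lab] * n_g
    dosage = np.concatenate(blocks).astype(np.int8)
    if missing_rate > 0:
        m = rng.random(dosage.shape) < missing_rate
        dosage[m] = MISSING
    G = GenotypeMatrix(dosage, ids, markers)
    meta = PanelMetadata(
        pd.DataFrame({"accession_id": ids, "subgroup": sgs, "origin": "sim"})
    )
    return G, meta, p_anc


def simulate_admixed(
    n: int = 60,
    L: int = 300,
    K: int = 3,
    fst: float = 0.25,
    alpha: float = 0.2,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Admixed individuals from K ancestral populations with known Q, F.

    Genotypes are Binomial(2, (QF)_il). Returns (G, Q_true, F_true).
    """
    rng = np.random.default_rng(seed)
    cfg = ScenarioConfig(n_markers=L)
    markers = _marker_map(rng, cfg)
    p_anc = rng.uniform(0.05, 0.95, size=L)
    F = balding_nichols_freqs(rng, p_anc, fst, K)
    Q = rng.dirichlet(np.full(K, alpha), size=n)
    P = Q @ F
    dosage = rng.binomial(2, P).astype(np.int8)
    ids = [f"WLD{i+1:03d}" for i in range(n)]
    G = GenotypeMatrix(dosage, ids, markers)
    return G, Q, F


def simulate_trait(
    G: GenotypeMatrix,
    h2_poly: float = 0.3,
    qtl_index: int | None = None,
    qtl_var: float = 0.0,
    n_causal: int = 50,
    seed: int | None = None,
) -> tuple[pd.Series, dict]:
    """Phenotype on an existing panel: polygenic + optional major QTL.

    Variance shares: *qtl_var* for the QTL, *h2_poly* for the polygenic
    background, remainder residual. Returns the accession-indexed trait
    and an info dict with the causal truth.
    """
    if h2_poly + qtl_var >= 1.0:
        raise SimulationError("h2_poly + qtl_var must be < 1")
    rng = np.random.default_rng(seed)
    X = G.dosages_float()
    p = np.nanmean(X, axis=0) / 2.0
    ix = np.where(np.isnan(X))
    X[ix] = (2 * p)[ix[1]]
    L = X.shape[1]
    poly_pool = [l for l in range(L) if l != qtl_index and 0 < p[l] < 1]
    idx = rng.choice(poly_pool, size=min(n_causal, len(poly_pool)), replace=False)
    eff = rng.normal(size=len(idx))
    g_poly = X[:, idx] @ eff
    g_poly = _standardize(g_poly) * np.sqrt(h2_poly)
    y = g_poly.copy()
    beta_qtl = 0.0
    if qtl_index is not None and qtl_var > 0:
        x_q = X[:, qtl_index]
        if x_q.std() == 0:
            raise SimulationError("QTL marker is monomorphic")
        beta_qtl = np.sqrt(qtl_var) / x_q.std()
        y = y + beta_qtl * (x_q - x_q.mean())
    resid_sd = np.sqrt(max(1.0 - h2_poly - qtl_var, 1e-9))
    y = y + rng.normal(0.0, resid_sd, size=len(y))
    info = {"causal_idx": idx, "effects": eff, "qtl_index": qtl_index, "beta_qtl": beta_qtl}
    return pd.Series(y, index=G.accession_ids), info


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def fixture_config(seed: int = 2026) -> ScenarioConfig:
    """Tiny deterministic panel (n = 40, L = 200) for unit tests."""
    return ScenarioConfig(
        n_wld=14,
        n_ns=12,
        n_clt1=6,
        n_clt2=8,
        n_markers=200,
        mean_gap_bp=8000.0,
        n_causal=40,
        years=(2006, 2007),
        missing_rate=0.10,
        seed=seed,
    )


def write_panel(panel: SimulatedPanel, out_dir) -> dict[str, str]:
    """Emit the VCF/TSV dialects the I/O module consumes, plus truth tables."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "panel.vcf"),
        "gmat": os.path.join(out_dir, "gmat.tsv"),
        "meta": os.path.join(out_dir, "panel_meta.tsv"),
        "pheno": os.path.join(out_dir, "phenotypes.tsv"),
        "truth_freqs": os.path.join(out_dir, "truth_freqs.tsv"),
        "truth_bv": os.path.join(out_dir, "truth_bv.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_vcf(panel.genotypes, paths["vcf"])
    write_matrix(panel.genotypes, paths["gmat"])
    write_metadata(panel.metadata, paths["meta"])
    panel.phenotypes.to_csv(paths["pheno"], sep="\t", index=False)
    tf = panel.truth.positions.copy()
    tf["p_ancestral"] = panel.truth.ancestral_freqs
    for sg, f in panel.truth.stage_freqs.items():
        tf[f"p_{sg}"] = f
    tf.to_csv(paths["truth_freqs"], sep="\t", index=False)
    panel.truth.true_bv.to_csv(paths["truth_bv"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "founder_ids": panel.truth.founder_ids,
                "grandparent_ids": panel.truth.grandparent_ids,
                "qtls": [q.__dict__ for q in panel.truth.qtls],
                "heritabilities": panel.truth.heritabilities,
                "seed": panel.config.seed,
            },
            fh,
            indent=2,
        )
    return paths


def make_fixtures(out_dir, seed: int = 2026) -> dict[str, str]:
    """Deterministic tiny test panel; same seed -> byte-identical files."""
    panel = simulate_panel(fixture_config(seed))
    return write_panel(panel, out_dir)
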