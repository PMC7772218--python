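"""End-to-end orchestration of the panel analysis.

Runs filter -> diversity -> F_ST/ROD -> LD -> structure -> BLUP -> GWAS
from a single YAML config, writing each stage's tabular outputs under
``out_dir/<stage>/`` and a machine-readable run manifest (seeds, input
checksums, output paths) at ``out_dir/manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diversity as dv
from . import gwas as gw
from . import ld as ldm
from . import phenotype_blup as pb
from . import selection_scan as ss
from . import structure as st
from .genotype_io import (
    GenotypeMatrix,
    PanelMetadata,
    filter_markers,
    read_matrix,
    read_metadata,
    read_vcf,
    write_matrix,
)

log = logging.getLogger("bogdiv.pipeline")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    vcf: str | None = None
    gmat: str | None = None
    meta: str = ""
    phenotypes: str | None = None
    out_dir: str = "bogdiv_out"
    max_missing: float = 0.30
    min_maf: float = 0.05
    fst_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("WLD", "CLT2"), ("WLD", "CLT1"), ("NS", "CLT2"),
            ("NS", "WLD"), ("NS", "CLT1"), ("CLT2", "CLT1"),
        ]
    )
    rod_steps: list[str] = field(
        default_factory=lambda: ["step1", "step2", "step3a", "step3b"]
    )
    permutations: int = 1000
    ld_bin_bp: int = 10_000
    ld_max_bp: int = 500_000
    k_min: int = 2
    k_max: int = 10
    k_replicates: int = 5
    n_pcs: int = 10
    traits: list[str] = field(default_factory=lambda: list(pb.TRAITS))
    fdr: float = 0.10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.fst_pairs = [tuple(p) for p in cfg.fst_pairs]
        return cfg

    def validate(self) -> None:
        if self.vcf is None and self.gmat is None:
            raise PipelineError("config must give a vcf or a gmat path")
        for p in (self.vcf, self.gmat, self.meta, self.phenotypes):
            if p and not os.path.exists(p):
                raise PipelineError(f"input path does not exist: {p}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_dir(out_dir: str, stage: str) -> str:
    d = os.path.join(out_dir, stage)
    os.makedirs(d, exist_ok=True)
    return d


def _dump_json(obj, path: str) -> None:
    def clean(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(type(x))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=clean)


def run_all(config: RunConfig) -> dict:
    """Run every configured stage; abort on failure naming the stage."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "stages": [],
    }
    for name in ("vcf", "gmat", "meta", "phenotypes"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": p, "sha256": _sha256(p)}

    stage = "load"
    try:
        meta = read_metadata(config.meta)
        if config.vcf:
            G_raw, _ = read_vcf(config.vcf, config.meta)
        else:
            G_raw = read_matrix(config.gmat, valid_chroms=None)
        log.info("[load] %d accessions x %d markers", G_raw.n_accessions, G_raw.n_markers)

        stage = "filter"
        t0 = time.time()
        G, report = filter_markers(G_raw, config.max_missing, config.min_maf)
        d = _stage_dir(config.out_dir, stage)
        write_matrix(G, os.path.join(d, "gmat_filtered.tsv"))
        _dump_json(report.as_dict(), os.path.join(d, "filter_report.json"))
        _record(manifest, stage, d, t0)

        stage = "diversity"
        t0 = time.time()
        d = _stage_dir(config.out_dir, stage)
        F = dv.subgroup_freqs(G, meta)
        F.table.to_csv(os.path.join(d, "freqs.tsv"), sep="\t", index=False)
        poly = {}
        for sg in sorted(F.subgroup_sizes):
            s = dv.polymorphic_fraction(F, sg)
            poly[sg] = s.__dict__
        _dump_json(poly, os.path.join(d, "polymorphic.json"))
        subgroups = sorted(F.subgroup_sizes)
        jm_summary = {}
        for i, a in enumerate(subgroups):
            for b in subgroups[i + 1:]:
                jm = dv.joint_maf(F, a, b)
                pd.DataFrame(jm.counts).to_csv(
                    os.path.join(d, f"joint_maf_{a}_{b}.tsv"), sep="\t", index=False
                )
                jm_summary[f"{a}_{b}"] = {
                    "diagonal_mass": jm.diagonal_mass, "n_markers": jm.n_markers
                }
        _dump_json(jm_summary, os.path.join(d, "joint_maf_summary.json"))
        _record(manifest, stage, d, t0)

        stage = "fst"
        t0 = time.time()
        d = _stage_dir(config.out_dir, stage)
        fst_summary = {}
        present = set(meta.table["subgroup"])
        for pair in config.fst_pairs:
            if not set(pair) <= present:
                log.info("[fst] skipping pair %s (subgroup absent)", pair)
                continue
            scan = ss.fst_permutation_threshold(
                G, meta, pair, R=config.permutations, seed=config.seed
            )
            out = scan.markers.copy()
            out["theta"] = scan.theta
            out.to_csv(os.path.join(d, f"fst_{pair[0]}_{pair[1]}.tsv"), sep="\t", index=False)
            fst_summary[f"{pair[0]}_{pair[1]}"] = {
                "mean": scan.mean_fst,
                "mean_ratio_of_sums": scan.mean_fst_ratio_of_sums,
                "max": scan.max_fst,
                "p95_threshold": scan.perm_threshold_p95,
                "n_significant": scan.n_significant,
                "R": scan.n_permutations,
                "seed": scan.seed,
            }
        _dump_json(fst_summary, os.path.join(d, "fst_summary.json"))
        _record(manifest, stage, d, t0)

        stage = "rod"
        t0 = time.time()
        d = _stage_dir(config.out_dir, stage)
        rod_summary = {}
        for step in config.rod_steps:
            anc, der = ss.ROD_STEPS[step]
            if not {anc, der} <= present:
                log.info("[rod] skipping %s (subgroup absent)", step)
                continue
            scan = ss.rod_scan(G, meta, step)
            out = scan.markers.copy()
            out["he_anc"] = scan.he_ancestral
            out["he_der"] = scan.he_derived
            out["rod"] = scan.rod
            out.to_csv(os.path.join(d, f"rod_{step}.tsv"), sep="\t", index=False)
            rod_summary[step] = {
                "bins": scan.bin_counts, "n_undefined": scan.n_undefined
            }
        _dump_json(rod_summary, os.path.join(d, "rod_summary.json"))
        _record(manifest, stage, d, t0)

        stage = "ld"
        t0 = time.time()
        d = _stage_dir(config.out_dir, stage)
        ld_summary = {}
        for sg in sorted(present):
            curve = ldm.decay_curve(
                G, meta, sg, bin_bp=config.ld_bin_bp, max_bp=config.ld_max_bp
            )
            curve.table().to_csv(os.path.join(d, f"ld_{sg}.tsv"), sep="\t", index=False)
            ld_summary[sg] = {
                "half_decay_bp": curve.half_decay_bp,
                "n_pairs": curve.n_pairs_total,
            }
        _dump_json(ld_summary, os.path.join(d, "ld_summary.json"))
        _record(manifest, stage, d, t0)

        stage = "structure"
        t0 = time.time()
        d = _stage_dir(config.out_dir, stage)
        pca_res = st.pca(G)
        pd.DataFrame(
            pca_res.scores[:, : config.n_pcs],
            index=pca_res.accession_ids,
            columns=[f"PC{i+1}" for i in range(min(config.n_pcs, pca_res.scores.shape[1]))],
        ).to_csv(os.path.join(d, "pca_scores.tsv"), sep="\t")
        pd.DataFrame({"explained": pca_res.explained}).to_csv(
            os.path.join(d, "pca_variance.tsv"), sep="\t", index=False
        )
        tree = st.ward_tree(G)
        with open(os.path.join(d, "tree.nwk"), "w") as fh:
            fh.write(tree.newick + "\n")
        fits: dict[int, list] = {}
        ss_seed = np.random.SeedSequence(config.seed).spawn(config.k_max + 1)
        best_fits = {}
        for K in range(config.k_min, config.k_max + 1):
            kseed = int(ss_seed[K].generate_state(1)[0] % (2**31))
            fit = st.snmf_fit(G, K, n_replicates=config.k_replicates, seed=kseed)
            fits[K] = [fit]
            best_fits[K] = fit
            pd.DataFrame(
                fit.Q, index=fit.accession_ids,
                columns=[f"anc{k+1}" for k in range(K)],
            ).to_csv(os.path.join(d, f"q_matrix_K{K}.tsv"), sep="\t")
        if len(fits) >= 2:
            k_star, ce_table = st.select_k(fits)
            ce_table.to_csv(os.path.join(d, "ce_by_k.tsv"), sep="\t", index=False)
        else:
            k_star = next(iter(fits))
            log.info("[structure] single K=%d fitted; no model selection", k_star)
        _dump_json({"selected_k": k_star}, os.path.join(d, "k_selection.json"))
        _record(manifest, stage, d, t0)

        blup_tables: dict[str, pb.BlupTable] = {}
        if config.phenotypes:
            stage = "blup"
            t0 = time.time()
            d = _stage_dir(config.out_dir, stage)
            records = pd.read_csv(config.phenotypes, sep="\t")
            kin = gw.vanraden_kinship(G)
            varcomps = {}
            for trait in config.traits:
                if trait not in set(records["trait"]):
                    log.info("[blup] trait %s absent; skipped", trait)
                    continue
                bt = pb.fit_gblup(records, kin.frame(), trait)
                blup_tables[trait] = bt
                bt.blups.to_csv(os.path.join(d, f"blups_{trait}.tsv"), sep="\t", index=False)
                varcomps[trait] = bt.varcomp
            _dump_json(varcomps, os.path.join(d, "varcomp.json"))
            wide = pd.DataFrame(
                {t: bt.series() for t, bt in blup_tables.items()}
            )
            if len(wide.columns) >= 2:
                pb.trait_correlations(wide).to_csv(
                    os.path.join(d, "trait_correlations.tsv"), sep="\t", index=False
                )
            comp_rows = []
            for t, bt in blup_tables.items():
                try:
                    comp = pb.subgroup_compare(bt.blups, meta, t)
                    comp_rows.append(
                        {"trait": t, "omnibus_f": comp.omnibus_f, "omnibus_p": comp.omnibus_p}
                    )
                except pb.BlupError as e:
                    log.info("[blup] comparison skipped for %s: %s", t, e)
            pd.DataFrame(comp_rows).to_csv(
                os.path.join(d, "comparisons.tsv"), sep="\t", index=False
            )
            _record(manifest, stage, d, t0)

            stage = "gwas"
            t0 = time.time()
            d = _stage_dir(config.out_dir, stage)
            covs = gw.structure_covariates(pca_res, best_fits.get(k_star), n_pcs=config.n_pcs)
            gwas_summary = {}
            for trait, bt in blup_tables.items():
                y = bt.series()
                try:
                    res = gw.mlm_scan(
                        G, y, covariates=covs, K=kin, trait=trait,
                        fdr_alpha=config.fdr,
                    )
                except gw.GwasError as e:
                    log.info("[gwas] %s skipped: %s", trait, e)
                    continue
                res.table.to_csv(
                    os.path.join(d, f"gwas_{trait}_all.tsv"), sep="\t", index=False
                )
                gwas_summary[trait] = {
                    "n_discoveries": int(len(res.discoveries)),
                    "delta": res.delta,
                    "n_used": res.n_used,
                }
            _dump_json(gwas_summary, os.path.join(d, "gwas_summary.json"))
            _record(manifest, stage, d, t0)
        else:
            log.info("no phenotype table configured; BLUP and GWAS stages skipped")
            manifest["skipped"] = ["blup", "gwas"]

    except Exception as e:  # noqa: BLE001 - annotate failing stage
        raise PipelineError(f"stage '{stage}' failed: {e}") from e

    _dump_json(manifest, os.path.join(config.out_dir, "manifest.json"))
    return manifest


def _record(manifest: dict, stage: str, stage_dir: str, t0: float) -> None:
    files = sorted(os.listdir(stage_dir))
    manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 3)})
    manifest["outputs"][stage] = {
        f: _sha256(os.path.join(stage_dir, f)) for f in files
    }
    log.info("[%s] done in %.1fs (%d files)", stage, time.time() - t0, len(files))
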