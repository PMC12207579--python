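"""Config-driven orchestration of the full diallel analysis.

A YAML run configuration names the input files (or a simulation block), the
traits with their model options, the covariance structures to fit, and the
cross-validation settings.  ``run_all`` executes
traitprep -> kinship -> REML -> BLUP -> CV -> correlations and writes
summary TSVs plus a line-oriented log into the output directory.  All
randomness flows from the single root seed in the config.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossval, io, kinship, lmm, multitrait, simdiallel, traitprep

__all__ = ["RunConfig", "run_all", "summarize_parent_ebvs"]

log = logging.getLogger("diallelgp")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 1
    pedigree: str | None = None
    phenotypes: str | None = None
    dosages: str | None = None
    simulate: dict | None = None
    traits: list = field(default_factory=list)   # [{name, line_nested_in_year}]
    matrices: list = field(default_factory=lambda: ["A"])
    double_reduction: float = 0.0
    tau: float = 1.0
    omega: float = 1.0
    cv: dict = field(default_factory=lambda: {"k": 8, "repeats": 10})
    correlations: bool = False
    dixon_confidence: float = 0.95
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self):
        needs_geno = any(m in ("G", "H") for m in self.matrices)
        if self.simulate is None:
            for name in ("pedigree", "phenotypes"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config lacks {name} input")
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            if needs_geno:
                if self.dosages is None:
                    raise ValueError("matrix kinds G/H require dosages")
                if not Path(self.dosages).exists():
                    raise FileNotFoundError(self.dosages)
        return self


def _build_sim_config(block: dict) -> simdiallel.SimConfig:
    block = dict(block or {})
    traits = block.pop("traits", None)
    cfg = simdiallel.SimConfig(**block)
    if traits is not None:
        cfg.traits = [simdiallel.TraitConfig(**t) for t in traits]
    return cfg


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage; returns a dict of output paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    t0 = time.time()
    outputs = {}
    try:
        # ---- inputs -------------------------------------------------------
        if config.simulate is not None:
            log.info("stage=simulate seed=%d", config.seed)
            sim_cfg = _build_sim_config(config.simulate)
            sim = simdiallel.simulate_population(sim_cfg, seed=config.seed)
            paths = simdiallel.export(sim, outdir / "sim")
            ped, pheno, dosages = sim.pedigree, sim.phenotypes, sim.dosages
            outputs.update({f"sim_{k}": str(v) for k, v in paths.items()})
        else:
            log.info("stage=load")
            ped = io.read_pedigree(config.pedigree)
            pheno = io.read_phenotypes(config.phenotypes)
            dosages = (io.read_dosages(config.dosages)
                       if config.dosages else None)

        cyto = (pd.Series(ped.set_index("clone_id")["cytoplasm_type"])
                if "cytoplasm_type" in ped.columns else None)

        # ---- trait preparation -------------------------------------------
        log.info("stage=traitprep")
        stats = traitprep.descriptive_stats(pheno)
        stats.to_csv(outdir / "trait_stats.tsv", sep="\t")
        outputs["trait_stats"] = str(outdir / "trait_stats.tsv")

        # ---- relationship matrices ---------------------------------------
        log.info("stage=kinship matrices=%s", config.matrices)
        mats = {}
        A = kinship.build_A_tetraploid(ped, config.double_reduction)
        if "A" in config.matrices or "H" in config.matrices:
            mats["A"] = A
        if dosages is not None and ("G" in config.matrices
                                    or "H" in config.matrices):
            G = kinship.build_G_vanraden(dosages)
            A22 = A.subset(list(G.ids))
            G_adj = kinship.adjust_G_scale(G, A22)
            if "G" in config.matrices:
                mats["G"] = G_adj
            if "H" in config.matrices:
                mats["H"] = kinship.build_H(A, G_adj, list(G.ids),
                                            tau=config.tau,
                                            omega=config.omega)
        for kind, M in mats.items():
            io.write_matrix(M, outdir / f"matrix_{kind}.tsv")
        inbr = kinship.pedigree_inbreeding(A)
        log.info("pedigree inbreeding F=%.5f", inbr.coefficient)

        # ---- per-trait models --------------------------------------------
        trait_cfgs = config.traits or [
            {"name": t} for t in sorted(pheno["trait"].unique())]
        vc_rows, ebv_tables, cv_rows, contrast_tables = [], [], [], []
        fits = {}
        for tc in trait_cfgs:
            name = tc["name"]
            for kind in config.matrices:
                if kind not in mats:
                    continue
                spec = lmm.ModelSpec(
                    trait=name, matrix_kind=kind,
                    line_nested_in_year=tc.get("line_nested_in_year", False))
                M = mats[kind]
                log.info("stage=reml trait=%s matrix=%s", name, kind)
                vc = lmm.fit_reml(spec, pheno, M, ped, cyto)
                sol = lmm.solve_mme(spec, pheno, M, vc, ped, cyto)
                fits[(name, kind)] = (spec, vc, sol, M)
                n_rep = int(pheno[pheno["trait"] == name]
                            .groupby("clone_id").size().median())
                h2 = lmm.heritability(vc, n_rep)
                vc_rows.append({
                    "trait": name, "matrix": kind, **vc.as_dict(),
                    "h2_plot": h2["h2_plot"], "h2_design": h2["h2_design"],
                    "sca_gca_ratio": lmm.sca_gca_ratio(vc),
                    "neg2loglik": vc.neg2loglik,
                })
                ebv = pd.DataFrame({
                    "clone_id": sol.ebv.index, "trait": name, "matrix": kind,
                    "ebv": sol.ebv.values, "pev": sol.pev.values,
                })
                ebv["ci_low"] = ebv["ebv"] - 1.96 * np.sqrt(ebv["pev"])
                ebv["ci_high"] = ebv["ebv"] + 1.96 * np.sqrt(ebv["pev"])
                ebv_tables.append(ebv)
                if cyto is not None:
                    contr = lmm.cytoplasm_contrasts(sol).reset_index()
                    contr.insert(0, "trait", name)
                    contr.insert(1, "matrix", kind)
                    contrast_tables.append(contr)
                if config.cv:
                    log.info("stage=cv trait=%s matrix=%s", name, kind)
                    plan = crossval.make_folds(
                        sorted(set(pheno.loc[pheno["trait"] == name,
                                             "clone_id"]) & set(M.ids)),
                        k=config.cv.get("k", 8),
                        repeats=config.cv.get("repeats", 10),
                        seed=config.seed)
                    cvm = crossval.run_cv(spec, pheno, M, plan, vc, ped, cyto)
                    cv_rows.append({
                        "trait": name, "matrix": kind,
                        "mean_r": cvm.mean_r, "sd_r": cvm.sd_r,
                        "accuracy": cvm.accuracy,
                        "dispersion": cvm.dispersion,
                        "h2_design": cvm.h2_design,
                    })

        if contrast_tables:
            pd.concat(contrast_tables).to_csv(
                outdir / "cytoplasm_contrasts.tsv", sep="\t", index=False)
            outputs["cytoplasm_contrasts"] = str(
                outdir / "cytoplasm_contrasts.tsv")
        pd.DataFrame(vc_rows).to_csv(outdir / "variance_components.tsv",
                                     sep="\t", index=False)
        outputs["variance_components"] = str(outdir / "variance_components.tsv")
        if ebv_tables:
            pd.concat(ebv_tables).to_csv(outdir / "ebv.tsv", sep="\t",
                                         index=False)
            outputs["ebv"] = str(outdir / "ebv.tsv")
        if cv_rows:
            pd.DataFrame(cv_rows).to_csv(outdir / "cv_summary.tsv", sep="\t",
                                         index=False)
            outputs["cv_summary"] = str(outdir / "cv_summary.tsv")

        parents = summarize_parent_ebvs(fits, ped)
        parents.to_csv(outdir / "parent_ebv.tsv", sep="\t", index=False)
        outputs["parent_ebv"] = str(outdir / "parent_ebv.tsv")

        # ---- correlations -------------------------------------------------
        if config.correlations and len(trait_cfgs) > 1 and "A" in mats:
            log.info("stage=correlations")
            corr = multitrait.correlation_matrix(
                [tc["name"] for tc in trait_cfgs], pheno, mats["A"], ped, cyto)
            corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
            outputs["correlations"] = str(outdir / "correlations.tsv")

        log.info("stage=done elapsed=%.1fs", time.time() - t0)
        return outputs
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def summarize_parent_ebvs(fits: dict, ped: pd.DataFrame) -> pd.DataFrame:
    """Parent EBVs with 95% confidence bounds, per trait and matrix kind."""
    founders = [str(c) for c, s, d in zip(ped["clone_id"], ped["sire_id"],
                                          ped["dam_id"])
                if str(s) == "0" and str(d) == "0"]
    rows = []
    for (trait, kind), (_spec, _vc, sol, _M) in fits.items():
        for p in founders:
            if p not in sol.ebv.index:
                continue
            ebv = float(sol.ebv[p])
            pev = float(sol.pev[p])
            half = 1.96 * np.sqrt(max(pev, 0.0))
            rows.append({
                "parent": p, "trait": trait, "matrix": kind,
                "ebv": ebv, "pev": pev,
                "ci_low": ebv - half, "ci_high": ebv + half,
            })
    return pd.DataFrame(rows)
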