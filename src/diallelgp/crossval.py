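"""Repeated random k-fold cross-validation of breeding-value prediction.

Clones are split into k equal-size folds, repeatedly; for each fold the
validation clones' phenotype records are masked (their pedigree/genomic
links remain, mirroring the single-step use case), the mixed model
equations are re-solved at the full-data variance components, and the
validation EBVs are correlated with the clones' mean corrected phenotypes
(records adjusted for the full-model fixed effects, then averaged per
clone).  Summary metrics: per-repeat Pearson prediction correlation, its
mean and SD, prediction accuracy r / sqrt(design h2), and the dispersion
slope of corrected means on EBVs (1 = correctly scaled; > 1 = EBVs
over-shrunk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .lmm import (ModelSpec, VarianceComponents, build_problem, fit_reml,
                  heritability)

__all__ = [
    "FoldPlan",
    "CVMetrics",
    "make_folds",
    "corrected_phenotype_means",
    "prediction_accuracy",
    "dispersion_bias",
    "run_cv",
]


@dataclass
class FoldPlan:
    assignments: pd.DataFrame   # columns: repeat, fold, clone_id
    k: int
    repeats: int
    seed: int

    def fold_ids(self, repeat: int, fold: int) -> list[str]:
        a = self.assignments
        sub = a[(a["repeat"] == repeat) & (a["fold"] == fold)]
        return list(sub["clone_id"])


@dataclass
class CVMetrics:
    per_repeat: pd.DataFrame    # repeat, r, beta, n_validated
    mean_r: float
    sd_r: float
    accuracy: float
    dispersion: float
    h2_design: float
    n_rep_pheno: int
    excluded_repeats: list


def make_folds(clone_ids, k: int = 8, repeats: int = 30,
               seed: int = 0) -> FoldPlan:
    """Deterministic equal-size fold assignments, one partition per repeat.

    Per-repeat randomness derives from ``SeedSequence([seed, repeat])`` so
    plans are reproducible and repeats independent.  Fold sizes differ by at
    most one.
    """
    clone_ids = list(clone_ids)
    n = len(clone_ids)
    if n < k:
        raise ValueError(f"cannot split {n} clones into {k} folds")
    rows = []
    for rep in range(1, repeats + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        perm = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, k), start=1):
            for i in chunk:
                rows.append((rep, fold, clone_ids[i]))
    return FoldPlan(pd.DataFrame(rows, columns=["repeat", "fold", "clone_id"]),
                    k, repeats, seed)


def corrected_phenotype_means(y: np.ndarray, X: np.ndarray, b: np.ndarray,
                              clone_of_obs) -> pd.Series:
    """Per-clone mean of fixed-effect-corrected records ``mean(y - X b)``."""
    resid = np.asarray(y, dtype=float) - np.asarray(X) @ np.asarray(b)
    return pd.Series(resid).groupby(pd.Series(list(clone_of_obs))).mean()


def prediction_accuracy(r: float, h2_design: float) -> float:
    """Prediction accuracy ``r / sqrt(h2_design)``."""
    if not 0.0 < h2_design <= 1.0:
        raise ValueError(f"design heritability must be in (0, 1], got {h2_design}")
    return r / np.sqrt(h2_design)


def dispersion_bias(ebv, yc) -> float:
    """OLS slope of mean corrected phenotypes on EBVs.

    beta = 1 means correctly dispersed predictions; beta > 1 means extreme
    EBVs are deflated (over-shrunk), beta < 1 the converse.
    """
    ebv = np.asarray(ebv, dtype=float)
    yc = np.asarray(yc, dtype=float)
    if ebv.size < 3 or np.var(ebv) == 0:
        return float("nan")
    return float(np.cov(ebv, yc, ddof=1)[0, 1] / np.var(ebv, ddof=1))


def run_cv(spec: ModelSpec, pheno: pd.DataFrame, M: RelationshipMatrix,
           plan: FoldPlan, vc: VarianceComponents | None = None,
           ped: pd.DataFrame | None = None,
           cytoplasm: pd.Series | None = None,
           validate_ids=None) -> CVMetrics:
    """Cross-validated prediction correlation, accuracy and dispersion.

    Variance components are estimated once on the full data (or supplied)
    and held fixed as priors in every training solve.  By default only
    clones with known parents (the F1 generation, when ``ped`` is given)
    enter the validation correlations; parents act as information donors
    only.
    """
    if vc is None:
        vc = fit_reml(spec, pheno, M, ped, cytoplasm)

    problem, meta = build_problem(spec, pheno, M, ped, cytoplasm)
    obs = meta["obs"]
    comps = {"additive": vc.sigma_a, "resid": vc.sigma_e}
    if any(t.name == "line" for t in problem.terms):
        comps["line"] = vc.sigma_l or 0.0
    if any(t.name == "family" for t in problem.terms):
        comps["family"] = vc.sigma_f

    full = problem.solve(comps, compute_pev=False)
    yc = corrected_phenotype_means(problem.y, problem.X, full.fixed,
                                   obs["clone_id"])

    if validate_ids is None:
        if ped is not None:
            p = ped.copy()
            p["clone_id"] = p["clone_id"].astype(str)
            f1 = set(p.loc[(p["sire_id"].astype(str) != "0")
                           & (p["dam_id"].astype(str) != "0"), "clone_id"])
            validate_ids = [c for c in yc.index if c in f1]
        else:
            validate_ids = list(yc.index)
    validate_ids = [c for c in validate_ids if c in yc.index]

    clone_arr = obs["clone_id"].to_numpy()
    a_idx = {c: i for i, c in enumerate(M.ids)}
    n_rep_pheno = int(obs.groupby("clone_id").size().median())
    h2d = heritability(vc, n_rep=n_rep_pheno)["h2_design"]

    rows, excluded = [], []
    for rep in sorted(plan.assignments["repeat"].unique()):
        pred, seen = {}, set()
        for fold in sorted(plan.assignments["fold"].unique()):
            val = [c for c in plan.fold_ids(rep, fold) if c in set(validate_ids)]
            if not val:
                continue
            val_set = set(val)
            train_mask = ~np.isin(clone_arr, list(val_set))
            sub = _sub_problem(problem, train_mask)
            sol = sub.solve(comps, compute_pev=False)
            a_hat = sol.random["additive"]
            for c in val:
                pred[c] = a_hat[a_idx[c]]
            seen |= val_set
        common = [c for c in validate_ids if c in pred]
        e = np.array([pred[c] for c in common])
        t = yc.loc[common].to_numpy()
        if len(common) < 3 or np.std(t) == 0 or np.std(e) == 0:
            excluded.append(rep)
            continue
        rows.append({"repeat": rep,
                     "r": float(np.corrcoef(e, t)[0, 1]),
                     "beta": dispersion_bias(e, t),
                     "n_validated": len(common)})
    per = pd.DataFrame(rows)
    if per.empty:
        raise RuntimeError("all repeats degenerate; no CV metrics")
    mean_r = float(per["r"].mean())
    return CVMetrics(
        per_repeat=per,
        mean_r=mean_r,
        sd_r=float(per["r"].std(ddof=1)) if len(per) > 1 else 0.0,
        accuracy=prediction_accuracy(mean_r, h2d),
        dispersion=float(per["beta"].mean()),
        h2_design=h2d,
        n_rep_pheno=n_rep_pheno,
        excluded_repeats=excluded,
    )


def _sub_problem(problem, keep_mask: np.ndarray):
    """Clone of a REML problem with a subset of observation rows.

    Term structures (and their factorised K inverses) are shared, so
    repeated training solves only pay for the MME factorisation.
    """
    from .reml import RandomTerm, REMLProblem

    new_terms = [RandomTerm(t.name, t.Z[keep_mask], q=t.q, d=t.d, K=t.K,
                            K_inv=t.K_inv, logdet_K=t.logdet_K,
                            labels=t.labels)
                 for t in problem.terms]
    return REMLProblem(problem.y[keep_mask], problem.X[keep_mask],
                       new_terms)
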