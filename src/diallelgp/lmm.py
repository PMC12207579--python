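"""Univariate mixed-model analysis of diallel phenotypes.

The working model is

    y = X b + Z_a a + Z_l l + Z_f f + e

with fixed block-by-year and cytoplasm-type effects, additive genetic
effects ``a ~ N(0, M sigma_a^2)`` over any relationship matrix M (pedigree
A, genomic G, or single-step H), clone "line" effects ``l ~ N(0, I
sigma_l^2)`` capturing repeatable non-transmissible deviations (nested
within year for multi-year traits, omitted for unreplicated traits), and
full-sib family effects ``f ~ N(0, I sigma_f^2)`` keyed by the unordered
sire-dam pair (the SCA term).  Variance components are estimated by
AI-REML; breeding values and their prediction error variances come from
Henderson's mixed model equations at the estimates.

A parent's EBV equals twice its general combining ability; the SCA/GCA
variance ratio is ``sigma_f^2 / (sigma_a^2 / 4)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .kinship import RelationshipMatrix, build_A_tetraploid
from .reml import RandomTerm, REMLProblem, REMLResult

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "BlupSolution",
    "family_keys",
    "build_problem",
    "fit_reml",
    "solve_mme",
    "heritability",
    "sca_gca_ratio",
    "cytoplasm_contrasts",
    "profile_double_reduction",
]

CYTO_REFERENCE = "W/g"


@dataclass
class ModelSpec:
    """Which trait to analyse and which model terms to include."""

    trait: str
    matrix_kind: str = "A"            # label only: {"A_pop","A_panel","G","H"}
    include_line: bool | None = None  # None = automatic (replicates present?)
    line_nested_in_year: bool = False
    include_family: bool = True
    cytoplasm_reference: str = CYTO_REFERENCE


@dataclass
class VarianceComponents:
    sigma_a: float
    sigma_f: float
    sigma_e: float
    sigma_l: float | None
    se: dict
    neg2loglik: float
    converged: bool
    n_iter: int
    boundary: list
    matrix_kind: str
    n_obs: int
    reml: REMLResult | None = None

    def as_dict(self) -> dict:
        out = {"sigma2_a": self.sigma_a, "sigma2_f": self.sigma_f,
               "sigma2_e": self.sigma_e}
        if self.sigma_l is not None:
            out["sigma2_l"] = self.sigma_l
        return out

    @property
    def total(self) -> float:
        return (self.sigma_a + self.sigma_f + self.sigma_e
                + (self.sigma_l or 0.0))


@dataclass
class BlupSolution:
    fixed: pd.Series
    fixed_se: pd.Series
    fixed_cov: np.ndarray
    ebv: pd.Series                 # additive breeding value per clone
    pev: pd.Series                 # prediction error variance per clone
    family_effects: pd.Series      # SCA effect per sire-dam family
    line_effects: pd.Series | None
    trait_mean: float
    cytoplasm_reference: str | None


def family_keys(ped: pd.DataFrame) -> pd.Series:
    """Unordered sire-dam family key per clone (NaN for founders)."""
    def key(r):
        if r.sire_id == "0" or r.dam_id == "0":
            return np.nan
        return "x".join(sorted([str(r.sire_id), str(r.dam_id)]))
    ped = ped.copy()
    ped["sire_id"] = ped["sire_id"].astype(str)
    ped["dam_id"] = ped["dam_id"].astype(str)
    return pd.Series([key(r) for r in ped.itertuples(index=False)],
                     index=ped["clone_id"].astype(str))


def _dummies(labels: pd.Series, drop: str | None, prefix: str):
    levels = sorted(labels.unique())
    if drop is not None and drop in levels:
        levels = [drop] + [l for l in levels if l != drop]
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((labels == lev).to_numpy(dtype=float))
        names.append(f"{prefix}[{lev}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(labels), 0)), []


def build_design(pheno_t: pd.DataFrame, spec: ModelSpec,
                 cytoplasm: pd.Series | None):
    """Fixed-effect design for one trait: intercept + block-year + cytoplasm.

    Returns ``(X, labels)``; the reference levels (first block-year and the
    spec's cytoplasm reference) are absorbed into the intercept.
    """
    n = len(pheno_t)
    parts = [np.ones((n, 1))]
    labels = ["intercept"]
    by = (pheno_t["year"].astype(str) + ":" + pheno_t["block"].astype(str))
    Xby, names = _dummies(by, None, "block_year")
    parts.append(Xby)
    labels += names
    if cytoplasm is not None:
        cy = pheno_t["clone_id"].map(cytoplasm).astype(str)
        if cy.isna().any() or (cy == "nan").any():
            raise ValueError("missing cytoplasm type for some phenotyped clones")
        Xcy, names = _dummies(cy, spec.cytoplasm_reference, "cytoplasm")
        parts.append(Xcy)
        labels += names
    return np.hstack(parts), labels


def _indicator(labels, level_index: dict, n_levels: int) -> sp.csr_matrix:
    rows, cols = [], []
    for i, lab in enumerate(labels):
        j = level_index.get(lab)
        if j is not None:
            rows.append(i)
            cols.append(j)
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                         shape=(len(labels), n_levels))


def build_problem(spec: ModelSpec, pheno: pd.DataFrame, M: RelationshipMatrix,
                  ped: pd.DataFrame | None = None,
                  cytoplasm: pd.Series | None = None):
    """Assemble the REML problem for one trait.

    ``pheno`` is the long-format trait table; observations of clones absent
    from M are dropped (logged on the returned metadata).  ``ped`` supplies
    the family (sire-dam) grouping; without it the family term is omitted.
    """
    sub = pheno[pheno["trait"] == spec.trait].copy()
    sub["clone_id"] = sub["clone_id"].astype(str)
    sub = sub.dropna(subset=["value"])
    in_m = sub["clone_id"].isin(set(M.ids))
    n_dropped = int((~in_m).sum())
    sub = sub[in_m].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"no usable observations for trait {spec.trait!r}")

    y = sub["value"].to_numpy(dtype=float)
    X, labels = build_design(sub, spec, cytoplasm)

    pos = M.index
    Za = _indicator(sub["clone_id"], pos, len(M.ids))
    terms = [RandomTerm("additive", Za, q=len(M.ids), K=M.values,
                        labels=list(M.ids))]

    include_line = spec.include_line
    if include_line is None:
        include_line = bool(sub.duplicated(subset=["clone_id"]).any())
    if include_line:
        if spec.line_nested_in_year:
            keys = sub["clone_id"] + "@" + sub["year"].astype(str)
        else:
            keys = sub["clone_id"]
        levels = sorted(keys.unique())
        lidx = {k: i for i, k in enumerate(levels)}
        Zl = _indicator(keys, lidx, len(levels))
        terms.append(RandomTerm("line", Zl, q=len(levels), labels=levels))

    if spec.include_family and ped is not None:
        fam = family_keys(ped)
        fam_of_obs = sub["clone_id"].map(fam)
        levels = sorted(fam_of_obs.dropna().unique())
        fidx = {k: i for i, k in enumerate(levels)}
        Zf = _indicator(fam_of_obs.fillna("__none__"), fidx, len(levels))
        if levels:
            terms.append(RandomTerm("family", Zf, q=len(levels),
                                    labels=levels))

    problem = REMLProblem(y, X, terms)
    meta = {"labels": labels, "obs": sub, "n_dropped": n_dropped,
            "include_line": include_line}
    return problem, meta


def _components_from_result(res: REMLResult, spec: ModelSpec, meta,
                            n_obs: int) -> VarianceComponents:
    def get(name, s=0):
        return (float(res.components[name][0, 0]) if name in res.components
                else None)

    def gse(name):
        return (float(res.se[name][0, 0]) if name in res.se else np.nan)

    return VarianceComponents(
        sigma_a=get("additive"),
        sigma_f=get("family") if "family" in res.components else 0.0,
        sigma_e=float(res.components["resid"][0, 0]),
        sigma_l=get("line") if "line" in res.components else None,
        se={"sigma2_a": gse("additive"), "sigma2_f": gse("family"),
            "sigma2_l": gse("line"), "sigma2_e": gse("resid")},
        neg2loglik=res.neg2loglik,
        converged=res.converged,
        n_iter=res.n_iter,
        boundary=res.boundary,
        matrix_kind=spec.matrix_kind,
        n_obs=n_obs,
        reml=res,
    )


def fit_reml(spec: ModelSpec, pheno: pd.DataFrame, M: RelationshipMatrix,
             ped: pd.DataFrame | None = None,
             cytoplasm: pd.Series | None = None,
             max_iter: int = 100, tol: float = 1e-8) -> VarianceComponents:
    """AI-REML variance components for one trait over covariance M."""
    problem, meta = build_problem(spec, pheno, M, ped, cytoplasm)
    res = problem.fit(max_iter=max_iter, tol=tol)
    return _components_from_result(res, spec, meta, problem.n)


def solve_mme(spec: ModelSpec, pheno: pd.DataFrame, M: RelationshipMatrix,
              vc: VarianceComponents, ped: pd.DataFrame | None = None,
              cytoplasm: pd.Series | None = None,
              compute_pev: bool = True) -> BlupSolution:
    """BLUE/BLUP solutions of the mixed model equations at fixed components."""
    problem, meta = build_problem(spec, pheno, M, ped, cytoplasm)
    comps = {"additive": vc.sigma_a, "resid": vc.sigma_e}
    if any(t.name == "line" for t in problem.terms):
        comps["line"] = vc.sigma_l if vc.sigma_l is not None else 0.0
        if comps["line"] <= 0:
            raise ValueError("line term present but sigma_l not positive")
    if any(t.name == "family" for t in problem.terms):
        comps["family"] = vc.sigma_f
        if comps["family"] <= 0:
            raise ValueError("family term present but sigma_f not positive")
    if vc.sigma_a <= 0 or vc.sigma_e <= 0:
        raise ValueError("additive and residual variances must be positive")

    sol = problem.solve(comps, compute_pev=compute_pev,
                        pev_terms=["additive"])
    labels = [l for i, l in enumerate(meta["labels"])
              if i not in problem.dropped_cols]
    fixed = pd.Series(sol.fixed, index=labels)
    fixed_se = pd.Series(sol.fixed_se, index=labels) \
        if sol.fixed_se is not None else pd.Series(dtype=float)

    term_labels = {t.name: t.labels for t in problem.terms}
    ebv = pd.Series(sol.random["additive"], index=term_labels["additive"])
    pev = pd.Series(sol.pev.get("additive", np.full(len(ebv), np.nan)),
                    index=term_labels["additive"])
    fam = pd.Series(sol.random.get("family", []),
                    index=term_labels.get("family", []))
    line = (pd.Series(sol.random["line"], index=term_labels["line"])
            if "line" in sol.random else None)
    return BlupSolution(
        fixed=fixed, fixed_se=fixed_se, fixed_cov=sol.fixed_cov,
        ebv=ebv, pev=pev, family_effects=fam, line_effects=line,
        trait_mean=float(meta["obs"]["value"].mean()),
        cytoplasm_reference=(spec.cytoplasm_reference
                             if cytoplasm is not None else None),
    )


def heritability(vc: VarianceComponents, n_rep: int = 1) -> dict:
    """Plot heritability and design heritability of replicate-averaged records.

    ``h2_plot   = sa^2 / (sa^2 + sf^2 + sl^2 + se^2)``
    ``h2_design = sa^2 / (sa^2 + sf^2 + sl^2 + se^2 / n_rep)``
    """
    sl = vc.sigma_l or 0.0
    total = vc.sigma_a + vc.sigma_f + sl + vc.sigma_e
    if total <= 0:
        raise ValueError("total variance is zero; heritability undefined")
    return {
        "h2_plot": vc.sigma_a / total,
        "h2_design": vc.sigma_a / (vc.sigma_a + vc.sigma_f + sl
                                   + vc.sigma_e / n_rep),
    }


def sca_gca_ratio(vc) -> float:
    """SCA/GCA variance ratio ``sigma_f^2 / (sigma_a^2 / 4)``.

    Accepts a VarianceComponents or an (sigma_a^2, sigma_f^2) pair.
    Returns NaN when the additive variance is zero.
    """
    if isinstance(vc, VarianceComponents):
        sa, sf = vc.sigma_a, vc.sigma_f
    else:
        sa, sf = vc
    if sa <= 0:
        return float("nan")
    return sf / (sa / 4.0)


def cytoplasm_contrasts(sol: BlupSolution,
                        trait_mean: float | None = None) -> pd.DataFrame:
    """Cytoplasm-type contrasts relative to the reference type.

    Returns one row per type with the contrast, its SE, the absolute effect
    as a percentage of the trait mean, and a 95%-CI significance flag.  The
    reference type appears with contrast 0.
    """
    mean = trait_mean if trait_mean is not None else sol.trait_mean
    rows = []
    ref = sol.cytoplasm_reference
    if ref is not None:
        rows.append({"cytoplasm_type": ref, "contrast": 0.0, "se": 0.0,
                     "percent_of_mean": 0.0, "significant": False})
    for label in sol.fixed.index:
        if not label.startswith("cytoplasm["):
            continue
        ctype = label[len("cytoplasm["):-1]
        c = float(sol.fixed[label])
        se = float(sol.fixed_se.get(label, np.nan))
        rows.append({
            "cytoplasm_type": ctype,
            "contrast": c,
            "se": se,
            "percent_of_mean": 100.0 * abs(c) / mean,
            "significant": bool(abs(c) > 1.96 * se) if np.isfinite(se) else False,
        })
    return pd.DataFrame(rows).set_index("cytoplasm_type")


def profile_double_reduction(spec: ModelSpec, pheno: pd.DataFrame,
                             ped: pd.DataFrame, grid,
                             cytoplasm: pd.Series | None = None,
                             max_iter: int = 100) -> pd.DataFrame:
    """-2log(L) profile over a grid of double-reduction rates.

    Rebuilds the pedigree A matrix and refits REML at each grid point;
    non-converging points are recorded with NaN likelihood and excluded from
    the argmin (kept in the table).  The attribute ``argmin`` on the result
    holds the best w.
    """
    rows = []
    for w in grid:
        if not 0.0 <= w <= 0.25:
            raise ValueError("double-reduction grid must lie within [0, 0.25]")
        A = build_A_tetraploid(ped, w)
        try:
            vc = fit_reml(spec, pheno, A, ped, cytoplasm, max_iter=max_iter)
            rows.append({"w": w, "neg2loglik": vc.neg2loglik,
                         "converged": vc.converged})
        except Exception as err:  # noqa: BLE001 - record and continue
            rows.append({"w": w, "neg2loglik": np.nan, "converged": False,
                         "error": str(err)})
    out = pd.DataFrame(rows)
    ok = out.dropna(subset=["neg2loglik"])
    out.attrs["argmin"] = (float(ok.loc[ok["neg2loglik"].idxmin(), "w"])
                           if len(ok) else np.nan)
    return out
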