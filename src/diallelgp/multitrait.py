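"""Pairwise bivariate mixed models and trait correlations.

For a trait pair the stacked model

    [y1; y2] = blockdiag(X1, X2) [b1; b2] + Z_a [a1; a2] + Z_l [l1; l2]
             + Z_f [f1; f2] + [e1; e2]

is fitted by AI-REML with Kronecker covariances: additive effects
``N(0, C (x) M)`` with a 2x2 additive covariance C, line and family effects
with 2x2 identity-structured covariances, and residuals correlated only for
observations recorded on the same plot (same clone/year/block/replicate).
When the two traits share no plots the residual covariance is not
estimable: it is fixed at zero and flagged, and the phenotypic correlation
is reported as undefined.

Derived statistics:

* genetic correlation  ``r_g = C12 / sqrt(C11 C22)``
* phenotypic correlation ``r_p = (sum of additive+line+family+residual
  covariances) / sqrt(product of the two total phenotypic variances)``,
  where the line covariance enters only if both traits carry a line term.

Confidence intervals use the delta method on the inverse-AI parameter
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .kinship import RelationshipMatrix
from .lmm import ModelSpec, build_design, family_keys
from .reml import RandomTerm, REMLProblem, ResidualSpec, REMLResult

__all__ = [
    "BivariateComponents",
    "CorrelationEstimate",
    "fit_bivariate_reml",
    "genetic_correlation",
    "phenotypic_correlation",
    "correlation_matrix",
]


@dataclass
class BivariateComponents:
    traits: tuple[str, str]
    additive: np.ndarray          # 2x2
    line: np.ndarray | None       # 2x2, 1x1 or None
    line_traits: tuple            # traits carrying a line term
    family: np.ndarray | None
    residual: np.ndarray          # 2x2 (off-diagonal 0 if not estimable)
    resid_cov_estimable: bool
    reml: REMLResult
    converged: bool
    neg2loglik: float


@dataclass
class CorrelationEstimate:
    r: float
    kind: str                     # "genetic" or "phenotypic"
    ci_low: float
    ci_high: float
    defined: bool = True


def _stack_trait(pheno, trait, spec, M, cytoplasm):
    sub = pheno[pheno["trait"] == trait].copy()
    sub["clone_id"] = sub["clone_id"].astype(str)
    sub = sub.dropna(subset=["value"])
    sub = sub[sub["clone_id"].isin(set(M.ids))].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"no usable observations for trait {trait!r}")
    X, labels = build_design(sub, spec, cytoplasm)
    return sub, X, [f"{trait}:{l}" for l in labels]


def fit_bivariate_reml(trait1: str, trait2: str, pheno: pd.DataFrame,
                       M: RelationshipMatrix,
                       ped: pd.DataFrame | None = None,
                       cytoplasm: pd.Series | None = None,
                       line_nested_in_year: bool = False,
                       max_iter: int = 100,
                       tol: float = 1e-8) -> BivariateComponents:
    """Bivariate REML for a pair of traits over covariance structure M."""
    if trait1 == trait2:
        raise ValueError("need two distinct traits")
    spec1 = ModelSpec(trait1, line_nested_in_year=line_nested_in_year)
    spec2 = ModelSpec(trait2, line_nested_in_year=line_nested_in_year)
    sub1, X1, lab1 = _stack_trait(pheno, trait1, spec1, M, cytoplasm)
    sub2, X2, lab2 = _stack_trait(pheno, trait2, spec2, M, cytoplasm)
    n1, n2 = len(sub1), len(sub2)
    y = np.concatenate([sub1["value"].to_numpy(float),
                        sub2["value"].to_numpy(float)])
    X = np.block([[X1, np.zeros((n1, X2.shape[1]))],
                  [np.zeros((n2, X1.shape[1])), X2]])
    trait_idx = np.concatenate([np.zeros(n1, int), np.ones(n2, int)])

    pos = M.index
    q = len(M.ids)

    def a_cols(sub, t):
        return np.array([t * q + pos[c] for c in sub["clone_id"]])

    rows = np.arange(n1 + n2)
    cols = np.concatenate([a_cols(sub1, 0), a_cols(sub2, 1)])
    Za = sp.csr_matrix((np.ones(n1 + n2), (rows, cols)),
                       shape=(n1 + n2, 2 * q))
    terms = [RandomTerm("additive", Za, q=q, d=2, K=M.values,
                        labels=list(M.ids))]

    # line effects: only for traits with replicated clones
    has_line1 = bool(sub1.duplicated("clone_id").any())
    has_line2 = bool(sub2.duplicated("clone_id").any())
    line_traits = tuple(t for t, h in ((trait1, has_line1), (trait2, has_line2))
                        if h)
    if has_line1 and has_line2:
        def lkey(sub, t):
            if line_nested_in_year:
                return (sub["clone_id"] + "@" + sub["year"].astype(str)).tolist()
            return sub["clone_id"].tolist()
        keys1, keys2 = lkey(sub1, 0), lkey(sub2, 1)
        levels = sorted(set(keys1) | set(keys2))
        lidx = {k: i for i, k in enumerate(levels)}
        ql = len(levels)
        cols = np.concatenate([[lidx[k] for k in keys1],
                               [ql + lidx[k] for k in keys2]])
        Zl = sp.csr_matrix((np.ones(n1 + n2), (rows, cols)),
                           shape=(n1 + n2, 2 * ql))
        terms.append(RandomTerm("line", Zl, q=ql, d=2, labels=levels))
    elif has_line1 or has_line2:
        sub = sub1 if has_line1 else sub2
        offset = 0 if has_line1 else n1
        levels = sorted(sub["clone_id"].unique())
        lidx = {k: i for i, k in enumerate(levels)}
        r = offset + np.arange(len(sub))
        c = np.array([lidx[k] for k in sub["clone_id"]])
        Zl = sp.csr_matrix((np.ones(len(sub)), (r, c)),
                           shape=(n1 + n2, len(levels)))
        terms.append(RandomTerm("line", Zl, q=len(levels), d=1,
                                labels=levels))

    if ped is not None:
        fam = family_keys(ped)
        f1 = sub1["clone_id"].map(fam)
        f2 = sub2["clone_id"].map(fam)
        levels = sorted(set(f1.dropna()) | set(f2.dropna()))
        if levels:
            fidx = {k: i for i, k in enumerate(levels)}
            qf = len(levels)
            rr, cc = [], []
            for i, k in enumerate(f1):
                if isinstance(k, str):
                    rr.append(i); cc.append(fidx[k])
            for i, k in enumerate(f2):
                if isinstance(k, str):
                    rr.append(n1 + i); cc.append(qf + fidx[k])
            Zf = sp.csr_matrix((np.ones(len(rr)), (rr, cc)),
                               shape=(n1 + n2, 2 * qf))
            terms.append(RandomTerm("family", Zf, q=qf, d=2, labels=levels))

    # residual pairing by plot
    def plot_key(sub):
        return (sub["clone_id"].astype(str) + "|" + sub["year"].astype(str)
                + "|" + sub["block"].astype(str) + "|"
                + sub["replicate"].astype(str))
    keys = pd.concat([plot_key(sub1), plot_key(sub2)], ignore_index=True)
    # units shared across traits only; within-trait duplicates stay separate
    combined = keys + "#" + pd.Series(trait_idx).astype(str)
    shared = set(plot_key(sub1)) & set(plot_key(sub2))
    unit_codes = np.where(keys.isin(shared), keys, combined)
    unit = pd.factorize(unit_codes)[0]
    resid = ResidualSpec(trait=trait_idx, unit=unit, d=2)

    problem = REMLProblem(y, X, terms, resid=resid)
    res = problem.fit(max_iter=max_iter, tol=tol)

    line_mat = res.components.get("line")
    return BivariateComponents(
        traits=(trait1, trait2),
        additive=res.components["additive"],
        line=line_mat,
        line_traits=line_traits,
        family=res.components.get("family"),
        residual=res.components["resid"],
        resid_cov_estimable=res.cross_resid_estimable,
        reml=res,
        converged=res.converged,
        neg2loglik=res.neg2loglik,
    )


def _delta_ci(r: float, grad: dict, reml: REMLResult) -> tuple[float, float]:
    """95% CI by the delta method over the free REML parameters."""
    g = np.zeros(len(reml.param_index))
    for i, key in enumerate(reml.param_index):
        g[i] = grad.get(key, 0.0)
    var = float(g @ reml.param_cov @ g)
    if not np.isfinite(var) or var < 0:
        return (float("nan"), float("nan"))
    half = 1.96 * np.sqrt(var)
    return (r - half, r + half)


def genetic_correlation(bc: BivariateComponents) -> CorrelationEstimate:
    """Additive genetic correlation ``C12 / sqrt(C11 C22)`` with 95% CI."""
    C = bc.additive
    if C[0, 0] <= 0 or C[1, 1] <= 0:
        return CorrelationEstimate(float("nan"), "genetic",
                                   float("nan"), float("nan"), defined=False)
    r = float(C[0, 1] / np.sqrt(C[0, 0] * C[1, 1]))
    grad = {
        ("additive", 0, 0): -r / (2 * C[0, 0]),
        ("additive", 0, 1): 1.0 / np.sqrt(C[0, 0] * C[1, 1]),
        ("additive", 1, 1): -r / (2 * C[1, 1]),
    }
    lo, hi = _delta_ci(r, grad, bc.reml)
    return CorrelationEstimate(r, "genetic", lo, hi, defined=True)


def phenotypic_correlation(bc: BivariateComponents) -> CorrelationEstimate:
    """Phenotypic correlation from the summed random-effect covariances.

    Undefined (flagged) when the residual covariance between the traits is
    not estimable, e.g. for traits recorded in disjoint years.
    """
    if not bc.resid_cov_estimable:
        return CorrelationEstimate(float("nan"), "phenotypic",
                                   float("nan"), float("nan"), defined=False)
    mats = {"additive": bc.additive, "resid": bc.residual}
    if bc.line is not None and np.atleast_2d(bc.line).shape == (2, 2):
        mats["line"] = bc.line
    if bc.family is not None:
        mats["family"] = bc.family
    # per-trait totals include every term the trait carries
    tot = np.zeros(2)
    for t in range(2):
        tot[t] = bc.additive[t, t] + bc.residual[t, t]
        if bc.family is not None:
            tot[t] += bc.family[t, t]
        if bc.line is not None:
            lm = np.atleast_2d(bc.line)
            if lm.shape == (2, 2):
                tot[t] += lm[t, t]
            elif bc.traits[t] in bc.line_traits:
                tot[t] += lm[0, 0]
    cov = float(sum(m[0, 1] for m in mats.values()))
    denom = float(np.sqrt(tot[0] * tot[1]))
    r = cov / denom

    grad = {}
    for name, m in mats.items():
        grad[(name, 0, 1)] = 1.0 / denom
    for name in ("additive", "line", "family", "resid"):
        mat = {"additive": bc.additive, "line": bc.line,
               "family": bc.family, "resid": bc.residual}[name]
        if mat is None:
            continue
        lm = np.atleast_2d(mat)
        if lm.shape == (2, 2):
            grad[(name, 0, 0)] = -r / (2 * tot[0])
            grad[(name, 1, 1)] = -r / (2 * tot[1])
        else:
            t = bc.traits.index(bc.line_traits[0]) if bc.line_traits else 0
            grad[(name, 0, 0)] = -r / (2 * tot[t])
    lo, hi = _delta_ci(r, grad, bc.reml)
    return CorrelationEstimate(r, "phenotypic", lo, hi, defined=True)


def correlation_matrix(traits, pheno, M, ped=None, cytoplasm=None,
                       **kwargs) -> pd.DataFrame:
    """Long-format table of pairwise phenotypic and genetic correlations."""
    rows = []
    traits = list(traits)
    for i in range(len(traits)):
        for j in range(i + 1, len(traits)):
            bc = fit_bivariate_reml(traits[i], traits[j], pheno, M, ped,
                                    cytoplasm, **kwargs)
            for est in (genetic_correlation(bc), phenotypic_correlation(bc)):
                rows.append({
                    "trait1": traits[i], "trait2": traits[j],
                    "kind": est.kind, "r": est.r,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "defined": est.defined,
                })
    return pd.DataFrame(rows)
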