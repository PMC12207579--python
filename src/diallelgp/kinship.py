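"""Relationship matrices for autotetraploid populations.

Four covariance structures are supported for the additive genetic effect:

* ``A``      tetrasomic pedigree relationships, built by the autotetraploid
             kinship recursion with an optional double-reduction rate ``w``,
* ``G``      VanRaden genomic relationships from 0-4 allele dosages with the
             ploidy-4 denominator ``4 * sum_j p_j (1 - p_j)``,
* ``G_adj``  G rescaled so its mean diagonal matches the pedigree matrix of
             the genotyped clones (A22),
* ``H``      the single-step matrix blending A and G_adj (Martini tau/omega).

Coancestry convention: theta_ij is the probability that one allele drawn at
random from clone i and one drawn at random from clone j are identical by
descent (draws with replacement for i = j).  The additive relationship is
A = 4 * theta, so a non-inbred founder has diagonal 1 and the inbreeding
coefficient of clone i is F_i = (A_ii - 1) / 3.  An offspring of sire s and
dam d receives a diploid gamete from each parent; with double-reduction rate
w the two alleles of a gamete from p are copies of a single homolog with
probability w (IBD probability 1) and otherwise two distinct homologs (IBD
probability F_p), giving the gamete-internal IBD phi_p = w + (1 - w) F_p and

    F_offspring = (phi_s + phi_d) / 6 + (2/3) theta_sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "RelationshipMatrix",
    "InbreedingSummary",
    "sort_pedigree",
    "build_A_tetraploid",
    "pedigree_inbreeding",
    "genomic_inbreeding",
    "build_G_vanraden",
    "adjust_G_scale",
    "build_H",
]

PLOIDY = 4
UNKNOWN = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, missing parent record)."""


@dataclass
class RelationshipMatrix:
    """Symmetric covariance structure over named clones."""

    values: np.ndarray
    ids: list[str]
    kind: str  # one of {"A", "A22", "G", "G_adj", "H"}
    ploidy: int = PLOIDY
    double_reduction: float | None = None
    tau: float | None = None
    omega: float | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match the id index")

    @property
    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.ids)}

    def subset(self, ids) -> "RelationshipMatrix":
        pos = self.index
        try:
            idx = [pos[c] for c in ids]
        except KeyError as e:
            raise KeyError(f"clone {e.args[0]!r} not in matrix") from None
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)], list(ids),
            "A22" if self.kind == "A" else self.kind,
            self.ploidy, self.double_reduction, self.tau, self.omega,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def ensure_psd(self, tol: float = 1e-8) -> "RelationshipMatrix":
        """Clip eigenvalues below ``-tol`` to zero (logged) and symmetrise."""
        sym = 0.5 * (self.values + self.values.T)
        w = np.linalg.eigvalsh(sym)
        if w[0] < -tol:
            evals, evecs = np.linalg.eigh(sym)
            clipped = np.clip(evals, 0.0, None)
            sym = (evecs * clipped) @ evecs.T
            self.log.append(
                f"clipped {int(np.sum(evals < -tol))} negative eigenvalues "
                f"(min {w[0]:.3e})"
            )
        self.values = sym
        return self


@dataclass
class InbreedingSummary:
    coefficient: float
    source: str  # "pedigree" or "genomic"
    per_clone: pd.Series | None = None


def sort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Topologically order a pedigree so parents precede offspring.

    ``ped`` needs columns ``clone_id``, ``sire_id``, ``dam_id`` ("0" or
    empty = unknown).  Parents referenced but absent from ``clone_id`` are
    prepended as founders.  Raises :class:`PedigreeError` on cycles.
    """
    ped = ped.copy()
    for col in ("clone_id", "sire_id", "dam_id"):
        ped[col] = ped[col].astype(str).replace({"": UNKNOWN, "nan": UNKNOWN})
    known = set(ped["clone_id"])
    if len(known) != len(ped):
        raise PedigreeError("duplicate clone_id in pedigree")
    parents_only = sorted(
        (set(ped["sire_id"]) | set(ped["dam_id"])) - known - {UNKNOWN}
    )
    if parents_only:
        pad = pd.DataFrame({
            "clone_id": parents_only,
            "sire_id": UNKNOWN,
            "dam_id": UNKNOWN,
        })
        for col in ped.columns:
            if col not in pad:
                pad[col] = np.nan
        ped = pd.concat([pad[ped.columns], ped], ignore_index=True)

    rows = {r.clone_id: r for r in ped.itertuples(index=False)}
    order: list[str] = []
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    for root in ped["clone_id"]:
        if root in state:
            continue
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise PedigreeError(f"pedigree cycle involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            row = rows[node]
            for par in (row.sire_id, row.dam_id):
                if par != UNKNOWN and state.get(par) != 1:
                    if state.get(par) == 0:
                        raise PedigreeError(f"pedigree cycle involving {par!r}")
                    stack.append((par, False))
    return ped.set_index("clone_id").loc[order].reset_index()


def build_A_tetraploid(ped: pd.DataFrame, double_reduction: float = 0.0) -> RelationshipMatrix:
    """Tetrasomic additive relationship matrix from a pedigree.

    Unknown parents are treated as unrelated, non-inbred founders.  See the
    module docstring for the recursion; entries are validated elsewhere
    against a gene-dropping Monte-Carlo oracle.
    """
    w = float(double_reduction)
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"double_reduction must be in [0, 1], got {w}")
    ped = sort_pedigree(ped)
    ids = list(ped["clone_id"])
    pos = {c: i for i, c in enumerate(ids)}
    n = len(ids)
    theta = np.zeros((n, n))
    F = np.zeros(n)

    sires = [pos.get(s, -1) for s in ped["sire_id"]]
    dams = [pos.get(d, -1) for d in ped["dam_id"]]

    for k in range(n):
        s, d = sires[k], dams[k]
        if s < 0 and d < 0:
            F[k] = 0.0
            theta[k, k] = 0.25
            continue
        # cross-relationships with everything already processed
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * theta[s]
        if d >= 0:
            row += 0.5 * theta[d]
        theta[k, :k] = row[:k]
        theta[:k, k] = row[:k]
        phi_s = w + (1.0 - w) * (F[s] if s >= 0 else 0.0)
        phi_d = w + (1.0 - w) * (F[d] if d >= 0 else 0.0)
        theta_sd = theta[s, d] if (s >= 0 and d >= 0) else 0.0
        F[k] = (phi_s + phi_d) / 6.0 + (2.0 / 3.0) * theta_sd
        theta[k, k] = (1.0 + 3.0 * F[k]) / 4.0

    return RelationshipMatrix(4.0 * theta, ids, "A", double_reduction=w)


def pedigree_inbreeding(A: RelationshipMatrix) -> InbreedingSummary:
    """Population inbreeding ``F = (mean(diag(A)) - 1) / (ploidy - 1)``."""
    if A.kind not in ("A", "A22"):
        raise ValueError("expected a pedigree relationship matrix")
    d = np.diag(A.values)
    per = pd.Series((d - 1.0) / (A.ploidy - 1.0), index=A.ids)
    return InbreedingSummary(float(per.mean()), "pedigree", per)


def genomic_inbreeding(G: RelationshipMatrix) -> InbreedingSummary:
    """Population genomic inbreeding from the G diagonal (same formula as A)."""
    d = np.diag(G.values)
    per = pd.Series((d - 1.0) / (G.ploidy - 1.0), index=G.ids)
    return InbreedingSummary(float(per.mean()), "genomic", per)


def build_G_vanraden(dosages: pd.DataFrame) -> RelationshipMatrix:
    """VanRaden genomic relationships from 0-4 allele dosages.

    ``dosages`` is clones x markers with entries in [0, 4] (non-integer
    allowed) and NaN for missing.  Missing entries are imputed to the marker
    mean; allele frequencies ``p_j`` come from the observed entries only;
    ``Z = dosage - 4 p`` and ``G = Z Z' / (4 * sum_j p_j (1 - p_j))``.
    """
    M = dosages.to_numpy(dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least two clones")
    with np.errstate(invalid="ignore"):
        if np.nanmin(M) < 0 or np.nanmax(M) > PLOIDY:
            raise ValueError("dosages must lie in [0, 4]")
    col_mean = np.nanmean(M, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("marker with no observed dosages")
    p = col_mean / PLOIDY
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers; G would be degenerate")
    M = M[:, poly]
    p = p[poly]
    # mean imputation of missing entries
    nan_mask = np.isnan(M)
    if nan_mask.any():
        M = np.where(nan_mask, (PLOIDY * p)[None, :], M)
    Z = M - PLOIDY * p[None, :]
    denom = PLOIDY * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, list(dosages.index.astype(str)), "G")


def adjust_G_scale(G: RelationshipMatrix, A22: RelationshipMatrix) -> RelationshipMatrix:
    """Rescale G so its mean diagonal equals that of A22 (idempotent)."""
    if list(G.ids) != list(A22.ids):
        raise IndexError("G and A22 must index the same clones in the same order")
    factor = np.mean(np.diag(A22.values)) / np.mean(np.diag(G.values))
    return RelationshipMatrix(G.values * factor, list(G.ids), "G_adj",
                              double_reduction=A22.double_reduction)


def _solve_spd(mat: np.ndarray, rhs: np.ndarray, log: list[str], label: str,
               max_jitter: float = 1e-4) -> np.ndarray:
    """Cholesky solve with escalating jitter on near-singular matrices."""
    from scipy.linalg import cho_factor, cho_solve

    jitter = 0.0
    scale = np.mean(np.diag(mat))
    while True:
        try:
            c = cho_factor(mat + jitter * np.eye(mat.shape[0]), lower=True)
            if jitter:
                log.append(f"{label}: added jitter {jitter:.1e} to factorize")
            return cho_solve(c, rhs)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * scale if jitter == 0 else jitter * 10
            if jitter > max_jitter * scale:
                raise np.linalg.LinAlgError(
                    f"{label} is singular beyond the jitter tolerance"
                ) from None


def build_H(A: RelationshipMatrix, G_adj: RelationshipMatrix, genotyped_ids,
            tau: float = 1.0, omega: float = 1.0) -> RelationshipMatrix:
    """Single-step relationship matrix combining pedigree A and genomic G_adj.

    At ``tau = omega = 1`` the direct block identity is used:

        H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21
        H12 = A12 A22^-1 G
        H22 = G

    General ``tau``/``omega`` go through the blended inverse
    ``H^-1 = A^-1 + [0 0; 0 (tau G + (1-omega) A22)^-1 - A22^-1]``.
    Clone order of the result equals A's order.
    """
    genotyped_ids = list(genotyped_ids)
    pos = A.index
    missing = [c for c in genotyped_ids if c not in pos]
    if missing:
        raise KeyError(f"genotyped clones not in A: {missing[:5]}")
    if list(G_adj.ids) != genotyped_ids:
        raise IndexError("G_adj must be indexed by genotyped_ids in order")

    g_idx = np.array([pos[c] for c in genotyped_ids])
    p_idx = np.array([i for i in range(len(A.ids)) if i not in set(g_idx)],
                     dtype=int)
    log: list[str] = []
    A22 = A.values[np.ix_(g_idx, g_idx)]
    G = G_adj.values

    H = A.values.copy()
    if tau == 1.0 and omega == 1.0:
        A12 = A.values[np.ix_(p_idx, g_idx)]
        # B = A12 A22^-1  (solve A22 X = A21 and transpose)
        B = _solve_spd(A22, A12.T, log, "A22").T
        delta = G - A22
        H[np.ix_(p_idx, p_idx)] = (A.values[np.ix_(p_idx, p_idx)]
                                   + B @ delta @ B.T)
        H12 = B @ G
        H[np.ix_(p_idx, g_idx)] = H12
        H[np.ix_(g_idx, p_idx)] = H12.T
        H[np.ix_(g_idx, g_idx)] = G
    else:
        n = len(A.ids)
        Ainv = _solve_spd(A.values, np.eye(n), log, "A")
        blend = tau * G + (1.0 - omega) * A22
        blend_inv = _solve_spd(blend, np.eye(len(g_idx)), log, "tau*G+(1-omega)*A22")
        A22_inv = _solve_spd(A22, np.eye(len(g_idx)), log, "A22")
        Hinv = Ainv.copy()
        Hinv[np.ix_(g_idx, g_idx)] += blend_inv - A22_inv
        H = _solve_spd(Hinv, np.eye(n), log, "H^-1")
    H = 0.5 * (H + H.T)
    out = RelationshipMatrix(H, list(A.ids), "H",
                             double_reduction=A.double_reduction,
                             tau=tau, omega=omega)
    out.log.extend(log)
    return out
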