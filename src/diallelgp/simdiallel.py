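"""Synthetic tetrasomic incomplete-diallel populations.

The generator emulates the structure of an elite-potato diallel experiment:
a small set of tetraploid parents with maternally inherited cytoplasm types
(T/b, D, W/g), cytoplasmic male sterility (W/g parents never serve as sire),
an incomplete crossing table (a fraction of permitted crosses fails), large
full-sib families, biallelic marker genotypes on the 0-4 dosage scale with
missingness, and phenotypes with the additive + line + family + residual
variance structure used by the mixed-model machinery.

Breeding values are *genotypic*: each clone's additive value is the sum of
marker allele effects over its four homologs, propagated by gene dropping
through tetrasomic meiosis (with an optional double-reduction rate).  This
makes pedigree, genomic and single-step relationship matrices mutually
consistent by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraitConfig",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_founders",
    "make_gametes",
    "simulate_cross_plan",
    "simulate_population",
    "simulate_phenotypes",
    "gene_drop_relationships",
    "export",
]

CYTO_TYPES = ("T/b", "D", "W/g")


@dataclass
class TraitConfig:
    """Variance structure and layout of one simulated trait."""

    name: str = "dry_matter"
    mean: float = 20.26
    sigma2_a: float = 2.42
    sigma2_f: float = 0.38
    sigma2_l: float = 4.61
    sigma2_e: float = 0.70
    reps_per_year: tuple[int, ...] = (1, 2)
    line_nested_in_year: bool = False
    cytoplasm_effects: dict = field(default_factory=dict)  # shift per type

    @property
    def n_rep(self) -> int:
        return int(sum(self.reps_per_year))


def _default_traits() -> list[TraitConfig]:
    # Dry-matter-like trait: multi-year layout (1 rep year 1, 2 reps year 2),
    # line effect nested within year, cytoplasm contrasts relative to W/g.
    return [TraitConfig(
        name="dry_matter",
        mean=20.26,
        sigma2_a=2.42, sigma2_f=0.38, sigma2_l=4.61, sigma2_e=0.70,
        reps_per_year=(1, 2),
        line_nested_in_year=True,
        cytoplasm_effects={"T/b": -2.24, "D": -1.45, "W/g": 0.0},
    )]


@dataclass
class SimConfig:
    """Desk-scale tetrasomic diallel (about 1000 clones by default)."""

    n_parents: int = 12
    offspring_per_family: int = 25
    infertile_fraction: float = 0.35
    cytoplasm_freqs: dict = field(
        default_factory=lambda: {"T/b": 0.56, "D": 0.25, "W/g": 0.19})
    extra_male_sterile: int = 2     # sterile parents beyond the W/g ones
    allow_reciprocal: bool = False
    double_reduction: float = 0.0
    n_markers: int = 500
    missing_rate: float = 0.17
    genotyped_fraction: float = 0.15   # offspring fraction with marker data
    freq_beta: tuple[float, float] = (2.0, 2.0)
    block_size: int = 28
    block_sd: float = 0.5
    traits: list[TraitConfig] = field(default_factory=_default_traits)
    genetic_correlations: dict = field(default_factory=dict)   # (t1,t2) -> rho
    residual_correlations: dict = field(default_factory=dict)  # (t1,t2) -> rho

    def __post_init__(self):
        total = sum(self.cytoplasm_freqs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("cytoplasm frequencies must sum to 1")
        if not 0.0 <= self.double_reduction <= 1.0:
            raise ValueError("double_reduction must be in [0, 1]")

    @classmethod
    def full_scale(cls) -> "SimConfig":
        """18-parent layout approximating the full experimental design."""
        return cls(n_parents=18, offspring_per_family=42,
                   infertile_fraction=0.17, extra_male_sterile=3)


@dataclass
class SimTruth:
    """Latent quantities of a simulated population, for validation only."""

    breeding_values: pd.DataFrame      # clones x traits
    family_effects: dict               # trait -> {family_key: f}
    line_effects: dict                 # trait -> {line_key: l}
    realized_var_a: dict               # trait -> var of a over all clones
    realized_genetic_corr: dict        # (t1, t2) -> realized corr of a
    params: dict


@dataclass
class SimResult:
    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame
    dosages: pd.DataFrame              # genotyped clones x markers, NaN missing
    genotyped_ids: list
    truth: SimTruth
    genomes: np.ndarray                # n_clones x 4 x n_markers, allele 0/1
    clone_ids: list


# ---------------------------------------------------------------------------
# founders and meiosis


def simulate_founders(cfg: SimConfig, rng: np.random.Generator):
    """Draw founder homolog genotypes and per-trait marker effects.

    Marker allele frequencies are Beta(*cfg.freq_beta*) draws; each founder
    carries four independently sampled homologs.  Allele effects are drawn
    standard normal per marker (jointly, with the configured cross-trait
    correlation) and rescaled so the population-level additive variance of
    each trait equals its configured ``sigma2_a`` exactly at the generating
    allele frequencies.

    Returns ``(genomes, freqs, effects)`` with ``genomes`` of shape
    ``(n_parents, 4, n_markers)`` and ``effects`` of shape
    ``(n_markers, n_traits)``.
    """
    m = cfg.n_markers
    if m < 1:
        raise ValueError("need at least one marker")
    p = rng.beta(*cfg.freq_beta, size=m)
    genomes = (rng.random((cfg.n_parents, 4, m)) < p).astype(np.int8)

    traits = [t.name for t in cfg.traits]
    nt = len(traits)
    corr = np.eye(nt)
    for (t1, t2), rho in cfg.genetic_correlations.items():
        i, j = traits.index(t1), traits.index(t2)
        corr[i, j] = corr[j, i] = rho
    chol = np.linalg.cholesky(corr)
    alpha = rng.standard_normal((m, nt)) @ chol.T

    weights = 4.0 * p * (1.0 - p)
    for j, t in enumerate(cfg.traits):
        norm = np.sqrt(np.sum(weights * alpha[:, j] ** 2))
        alpha[:, j] *= np.sqrt(t.sigma2_a) / norm
    return genomes, p, alpha


def make_gametes(parent_genomes: np.ndarray, w: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Diploid gametes from tetraploid parents, one per input genome.

    ``parent_genomes`` has shape ``(n, 4, m)``.  Markers segregate
    independently (no linkage): at each marker, with probability ``w`` the
    gamete duplicates a single homolog allele (double reduction), otherwise
    it takes two distinct homologs sampled without replacement.
    Returns ``(n, 2, m)``.
    """
    n, _, m = parent_genomes.shape
    first = rng.integers(0, 4, size=(n, m))
    offset = rng.integers(1, 4, size=(n, m))
    second = np.where(rng.random((n, m)) < w, first, (first + offset) % 4)
    rows = np.arange(n)[:, None]
    cols = np.arange(m)[None, :]
    return np.stack([parent_genomes[rows, first, cols],
                     parent_genomes[rows, second, cols]], axis=1)


# ---------------------------------------------------------------------------
# crossing plan and pedigree


def _assign_cytoplasm(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder allocation of cytoplasm types."""
    n = cfg.n_parents
    types, freqs = zip(*sorted(cfg.cytoplasm_freqs.items(),
                               key=lambda kv: -kv[1]))
    counts = [int(np.floor(f * n)) for f in freqs]
    remainders = [f * n - c for f, c in zip(freqs, counts)]
    for i in np.argsort(remainders)[::-1]:
        if sum(counts) == n:
            break
        counts[i] += 1
    assignment = [t for t, c in zip(types, counts) for _ in range(c)]
    rng.shuffle(assignment)
    return assignment


def simulate_cross_plan(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Incomplete diallel family table (dam, sire, offspring count).

    W/g-cytoplasm parents are always male sterile, plus ``extra_male_sterile``
    randomly chosen others; crosses with a sterile sire are excluded, a
    further ``infertile_fraction`` of the permitted crosses is dropped at
    random, and (by default) reciprocal crosses are excluded by keeping one
    direction per unordered pair.
    """
    parents = [f"P{i + 1:02d}" for i in range(cfg.n_parents)]
    cyto = _assign_cytoplasm(cfg, rng)
    sterile = {p for p, c in zip(parents, cyto) if c == "W/g"}
    fertile_pool = [p for p in parents if p not in sterile]
    extra = min(cfg.extra_male_sterile, max(len(fertile_pool) - 1, 0))
    if extra:
        sterile |= set(rng.choice(fertile_pool, size=extra, replace=False))

    pairs = []
    for i in range(cfg.n_parents):
        for j in range(i + 1, cfg.n_parents):
            a, b = parents[i], parents[j]
            dirs = [(dam, sire) for dam, sire in ((a, b), (b, a))
                    if sire not in sterile]
            if not dirs:
                continue
            if cfg.allow_reciprocal:
                pairs.extend(dirs)
            else:
                pairs.append(dirs[rng.integers(len(dirs))]
                             if len(dirs) > 1 else dirs[0])
    if not pairs:
        raise ValueError("no fertile cross is possible with this configuration")

    keep = rng.random(len(pairs)) >= cfg.infertile_fraction
    if not keep.any():
        keep[rng.integers(len(pairs))] = True
    fams = [pairs[i] for i in np.flatnonzero(keep)]
    plan = pd.DataFrame(fams, columns=["dam_id", "sire_id"])
    plan["n_offspring"] = cfg.offspring_per_family
    plan.insert(0, "family", [f"F{i + 1:03d}" for i in range(len(plan))])
    meta = pd.DataFrame({
        "parent": parents,
        "cytoplasm_type": cyto,
        "male_sterile": [p in sterile for p in parents],
    })
    plan.attrs["parents"] = meta
    return plan


def simulate_population(cfg: SimConfig, seed: int) -> SimResult:
    """Full simulated diallel: pedigree, genomes, dosages, phenotypes, truth."""
    rng = np.random.default_rng(seed)
    founder_genomes, freqs, alpha = simulate_founders(cfg, rng)
    plan = simulate_cross_plan(cfg, rng)
    parents_meta = plan.attrs["parents"]
    parent_ids = list(parents_meta["parent"])
    cyto_map = dict(zip(parents_meta["parent"], parents_meta["cytoplasm_type"]))

    clone_ids = list(parent_ids)
    ped_rows = [{"clone_id": p, "sire_id": "0", "dam_id": "0",
                 "cytoplasm_type": cyto_map[p], "generation": 0}
                for p in parent_ids]
    genomes = [founder_genomes]

    pidx = {p: i for i, p in enumerate(parent_ids)}
    counter = 0
    for fam in plan.itertuples(index=False):
        k = fam.n_offspring
        dam_g = np.repeat(founder_genomes[pidx[fam.dam_id]][None], k, axis=0)
        sire_g = np.repeat(founder_genomes[pidx[fam.sire_id]][None], k, axis=0)
        gam_d = make_gametes(dam_g, cfg.double_reduction, rng)
        gam_s = make_gametes(sire_g, cfg.double_reduction, rng)
        genomes.append(np.concatenate([gam_s, gam_d], axis=1))
        for _ in range(k):
            counter += 1
            cid = f"C{counter:05d}"
            clone_ids.append(cid)
            ped_rows.append({"clone_id": cid, "sire_id": fam.sire_id,
                             "dam_id": fam.dam_id,
                             "cytoplasm_type": cyto_map[fam.dam_id],
                             "generation": 1})
    genomes = np.concatenate(genomes, axis=0)
    pedigree = pd.DataFrame(ped_rows)

    # genotyped panel: all parents plus a random offspring subset
    offspring = clone_ids[len(parent_ids):]
    n_geno = int(round(cfg.genotyped_fraction * len(offspring)))
    chosen = sorted(rng.choice(len(offspring), size=n_geno, replace=False)) \
        if n_geno else []
    genotyped_ids = parent_ids + [offspring[i] for i in chosen]
    gpos = [clone_ids.index(c) for c in genotyped_ids]
    dosage = genomes[gpos].sum(axis=1).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan
    dosages = pd.DataFrame(
        dosage, index=genotyped_ids,
        columns=[f"M{j + 1:04d}" for j in range(cfg.n_markers)])

    # genotypic breeding values, centred on the population mean
    dose_all = genomes.sum(axis=1)
    bv = dose_all @ alpha
    bv = bv - bv.mean(axis=0)
    bv_df = pd.DataFrame(bv, index=clone_ids,
                         columns=[t.name for t in cfg.traits])

    phenotypes, truth = simulate_phenotypes(cfg, pedigree, bv_df, rng)
    truth.params["seed"] = seed
    truth.params["marker_freq_beta"] = list(cfg.freq_beta)
    return SimResult(pedigree, phenotypes, dosages, genotyped_ids, truth,
                     genomes, clone_ids)


def simulate_phenotypes(cfg: SimConfig, pedigree: pd.DataFrame,
                        breeding_values: pd.DataFrame,
                        rng: np.random.Generator):
    """Phenotype records ``y = mu + block + cytoplasm + a + l + f + e``.

    Block-by-year effects are N(0, block_sd^2) shifts shared by plots in the
    same block; line effects are iid per clone (or per clone-year when
    nested); family effects are iid per sire-dam pair; residuals iid per
    plot.  Returns ``(PhenotypeTable, SimTruth)``.
    """
    clone_ids = list(pedigree["clone_id"])
    cyto = dict(zip(pedigree["clone_id"], pedigree["cytoplasm_type"]))
    fam_key = {
        r.clone_id: "x".join(sorted([r.sire_id, r.dam_id]))
        for r in pedigree.itertuples(index=False)
        if r.sire_id != "0" and r.dam_id != "0"
    }

    # field layouts are shared across traits: the same (year, replicate)
    # places every clone on the same plot for every trait, so cross-trait
    # residual covariances are identifiable from same-plot records
    layouts = {}

    def layout(year, rep):
        if (year, rep) not in layouts:
            order = rng.permutation(len(clone_ids))
            blocks = [f"Y{year}R{rep}B{i // cfg.block_size + 1:03d}"
                      for i in range(len(order))]
            layouts[(year, rep)] = (order, blocks)
        return layouts[(year, rep)]

    # plot residuals are drawn jointly across traits with the configured
    # residual correlations, so e1/e2 of the same plot can covary
    names = [t.name for t in cfg.traits]
    nt = len(names)
    rcorr_mat = np.eye(nt)
    for (t1, t2), rho in cfg.residual_correlations.items():
        i, j = names.index(t1), names.index(t2)
        rcorr_mat[i, j] = rcorr_mat[j, i] = rho
    sds = np.array([np.sqrt(t.sigma2_e) for t in cfg.traits])
    Rcov = rcorr_mat * np.outer(sds, sds)
    try:
        Lr = np.linalg.cholesky(Rcov)
    except np.linalg.LinAlgError:  # zero or semi-definite residual cov
        evals, evecs = np.linalg.eigh(Rcov)
        Lr = evecs * np.sqrt(np.clip(evals, 0.0, None))
    resid_cache = {}

    def plot_residuals(year, rep):
        if (year, rep) not in resid_cache:
            resid_cache[(year, rep)] = (
                rng.standard_normal((len(clone_ids), nt)) @ Lr.T)
        return resid_cache[(year, rep)]

    records = []
    fam_effects_all, line_effects_all = {}, {}
    rvar, rcorr = {}, {}
    bv = breeding_values
    for ti, t in enumerate(cfg.traits):
        fams = sorted(set(fam_key.values()))
        f_eff = dict(zip(fams, rng.normal(0, np.sqrt(t.sigma2_f), len(fams))))
        line_eff = {}
        for year_i, n_rep in enumerate(t.reps_per_year):
            year = 2013 + year_i
            for c in clone_ids:
                key = (c, year) if t.line_nested_in_year else c
                if key not in line_eff:
                    line_eff[key] = rng.normal(0, np.sqrt(t.sigma2_l))
            for rep in range(1, n_rep + 1):
                order, blocks = layout(year, rep)
                block_ids = sorted(set(blocks))
                block_eff = dict(zip(
                    block_ids, rng.normal(0, cfg.block_sd, len(block_ids))))
                e_mat = plot_residuals(year, rep)
                for plot_i, ci in enumerate(order):
                    c = clone_ids[ci]
                    b = blocks[plot_i]
                    key = (c, year) if t.line_nested_in_year else c
                    y = (t.mean
                         + block_eff[b]
                         + t.cytoplasm_effects.get(cyto[c], 0.0)
                         + bv.loc[c, t.name]
                         + line_eff[key]
                         + f_eff.get(fam_key.get(c), 0.0)
                         + e_mat[ci, ti])
                    records.append({
                        "clone_id": c, "trait": t.name, "value": y,
                        "year": year, "block": b,
                        "replicate": rep,
                    })
        fam_effects_all[t.name] = f_eff
        line_effects_all[t.name] = {str(k): v for k, v in line_eff.items()}
        rvar[t.name] = float(bv[t.name].var(ddof=1))
    names = [t.name for t in cfg.traits]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rcorr[(names[i], names[j])] = float(
                np.corrcoef(bv[names[i]], bv[names[j]])[0, 1])

    truth = SimTruth(
        breeding_values=bv.copy(),
        family_effects=fam_effects_all,
        line_effects=line_effects_all,
        realized_var_a=rvar,
        realized_genetic_corr=rcorr,
        params={"config": {k: v for k, v in asdict(cfg).items()
                           if k != "traits"},
                "traits": [asdict(t) for t in cfg.traits]},
    )
    return pd.DataFrame(records), truth


# ---------------------------------------------------------------------------
# gene-dropping oracle


def gene_drop_relationships(ped: pd.DataFrame, double_reduction: float = 0.0,
                            n_rep: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo additive relationships by dropping labelled alleles.

    Every founder receives four uniquely labelled alleles; alleles are
    propagated through tetrasomic meiosis with the given double-reduction
    rate.  The estimated additive relationship is ``4 * theta_ij`` with
    ``theta_ij`` the probability that one allele drawn at random from i and
    one from j carry the same founder label (draws with replacement), i.e.
    the mean pairwise label-match fraction over the 4 x 4 allele pairs.

    Independent of the pedigree recursion; used as its oracle.
    """
    from .kinship import sort_pedigree

    ped = sort_pedigree(ped)
    ids = list(ped["clone_id"])
    pos = {c: i for i, c in enumerate(ids)}
    n = len(ids)
    rng = np.random.default_rng(seed)
    w = double_reduction

    alleles = np.zeros((n, n_rep, 4), dtype=np.int64)
    next_label = 0

    def founder_block():
        nonlocal next_label
        block = np.tile(np.arange(next_label, next_label + 4), (n_rep, 1))
        next_label += 4
        return block

    def gamete(genome):
        first = rng.integers(0, 4, size=n_rep)
        offset = rng.integers(1, 4, size=n_rep)
        second = np.where(rng.random(n_rep) < w, first, (first + offset) % 4)
        rows = np.arange(n_rep)
        return np.stack([genome[rows, first], genome[rows, second]], axis=1)

    for k, row in enumerate(ped.itertuples(index=False)):
        s, d = pos.get(row.sire_id), pos.get(row.dam_id)
        if s is None and d is None:
            alleles[k] = founder_block()
        else:
            sg = gamete(alleles[s]) if s is not None else founder_block()[:, :2]
            dg = gamete(alleles[d]) if d is not None else founder_block()[:, :2]
            alleles[k] = np.concatenate([sg, dg], axis=1)

    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            match = alleles[i][:, :, None] == alleles[j][:, None, :]
            theta = match.mean()
            A[i, j] = A[j, i] = 4.0 * theta
    return pd.DataFrame(A, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# export


def export(result: SimResult, outdir) -> dict[str, Path]:
    """Write pedigree CSV, phenotype CSV, dosage TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "dosages": outdir / "dosages.tsv",
        "truth": outdir / "truth.json",
    }
    result.pedigree.to_csv(paths["pedigree"], index=False)
    result.phenotypes.to_csv(paths["phenotypes"], index=False)
    dos = result.dosages.copy()
    dos.insert(0, "clone_id", dos.index)
    dos.to_csv(paths["dosages"], sep="\t", index=False, na_rep="NA")
    truth = result.truth
    payload = {
        "breeding_values": {
            t: dict(zip(truth.breeding_values.index.astype(str),
                        truth.breeding_values[t].round(10)))
            for t in truth.breeding_values.columns
        },
        "family_effects": truth.family_effects,
        "realized_var_a": truth.realized_var_a,
        "realized_genetic_corr": {
            f"{a}|{b}": v for (a, b), v in truth.realized_genetic_corr.items()
        },
        "params": truth.params,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, default=str))
    return paths
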