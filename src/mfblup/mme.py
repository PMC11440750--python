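"""Multitrait mixed-model equations for BLUP and single-step GBLUP.

The full model (contemporary group as the only fixed effect, phenotypes
assumed pre-adjusted for everything else) is

    y = X b + Z_a u + Z_m u_m + Z_mpe mpe + Z_sfy sfy + e

with Var(u, u_m) = G0 (x) K where K is A, A_Γ or an H matrix depending on
the grouping method and on whether genotypes are supplied,
Var(mpe) = M0 (x) I, Var(sfy) = S0 (x) I, Var(e) = R0 (x) I.  Under the
UPG (QP) parameterisation the group effects g enter as extra random
columns with Var(g) = G0 (x) I; under metafounders the groups are pedigree
entities inside A_Γ / H_Γ.  Variance components are inputs, never
estimated.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import yaml

from .data import Dataset
from .errors import DataError, ValidationError
from .groups import GroupDefinition, GammaMatrix, assign_groups, estimate_gamma_gls, group_fractions
from . import relmat

MISSING_PARENT = -1


# ----------------------------------------------------------------------
# Variance components
# ----------------------------------------------------------------------
@dataclass
class VarianceComponents:
    """Covariance structure of the multitrait maternal animal model.

    ``G0`` is ordered slot-major: direct effects for every trait first,
    then maternal effects for ``maternal_traits``.  ``M0``/``S0`` are
    per-trait diagonal variances; ``R0`` is the residual covariance.
    ``cg_var`` is only used by the simulator to draw contemporary-group
    effects.
    """

    traits: list
    G0: np.ndarray
    R0: np.ndarray
    maternal_traits: list = field(default_factory=list)
    sfy_traits: list = field(default_factory=list)
    M0: dict = field(default_factory=dict)
    S0: dict = field(default_factory=dict)
    cg_var: float = 0.25

    def __post_init__(self) -> None:
        self.G0 = np.asarray(self.G0, dtype=float)
        self.R0 = np.asarray(self.R0, dtype=float)
        k = len(self.traits) + len(self.maternal_traits)
        if self.G0.shape != (k, k):
            raise ValidationError(f"G0 must be {k}x{k} for these traits")
        if self.R0.shape != (len(self.traits),) * 2:
            raise ValidationError("R0 dimension must equal the number of traits")
        for name, M in (("G0", self.G0), ("R0", self.R0)):
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValidationError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-8:
                raise ValidationError(f"{name} must be positive semidefinite")
        for name, d, traits in (("M0", self.M0, self.maternal_traits),
                                ("S0", self.S0, self.sfy_traits)):
            for t in traits:
                if d.get(t, 0.0) < 0:
                    raise ValidationError(f"{name}[{t}] must be non-negative")

    @property
    def slots(self) -> list:
        return [(t, "direct") for t in self.traits] + [(t, "maternal") for t in self.maternal_traits]

    def submodel(self, traits: list) -> "VarianceComponents":
        """Restrict to a trait subset (maternal/mpe/sfy follow along)."""
        keep_m = [t for t in self.maternal_traits if t in traits]
        keep_s = [t for t in self.sfy_traits if t in traits]
        slot_idx = [i for i, (t, _) in enumerate(self.slots)
                    if t in traits and (_ == "direct" or t in keep_m)]
        t_idx = [self.traits.index(t) for t in traits]
        return VarianceComponents(
            traits=list(traits),
            G0=self.G0[np.ix_(slot_idx, slot_idx)],
            R0=self.R0[np.ix_(t_idx, t_idx)],
            maternal_traits=keep_m,
            sfy_traits=keep_s,
            M0={t: self.M0[t] for t in keep_m},
            S0={t: self.S0[t] for t in keep_s},
            cg_var=self.cg_var,
        )

    # -- stock parameter sets ------------------------------------------
    @classmethod
    def default_wool(cls) -> "VarianceComponents":
        """Three yearling traits (fibre diameter, greasy fleece weight,
        liveweight) with h2 = 0.74 / 0.57 / 0.38 on a unit phenotypic
        scale; maternal effects on the last two."""
        traits = ["yfd", "ygfw", "ywt"]
        sd = np.sqrt([0.74, 0.57, 0.38, 0.08, 0.10])
        corr = np.array([
            [1.0, 0.3, 0.3, -0.1, -0.1],
            [0.3, 1.0, 0.3, -0.1, -0.1],
            [0.3, 0.3, 1.0, -0.1, -0.1],
            [-0.1, -0.1, -0.1, 1.0, 0.2],
            [-0.1, -0.1, -0.1, 0.2, 1.0],
        ])
        G0 = corr * np.outer(sd, sd)
        r_sd = np.sqrt([0.26, 0.26, 0.40])
        r_corr = np.full((3, 3), 0.2) + 0.8 * np.eye(3)
        R0 = r_corr * np.outer(r_sd, r_sd)
        return cls(
            traits=traits, G0=G0, R0=R0,
            maternal_traits=["ygfw", "ywt"], sfy_traits=["ygfw", "ywt"],
            M0={"ygfw": 0.05, "ywt": 0.07}, S0={"ygfw": 0.04, "ywt": 0.05},
        )

    @classmethod
    def single_trait(cls, h2: float = 0.38, name: str = "trait") -> "VarianceComponents":
        return cls(traits=[name], G0=np.array([[h2]]), R0=np.array([[1.0 - h2]]))

    # -- YAML exchange -------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            "traits": self.traits,
            "maternal_traits": self.maternal_traits,
            "sfy_traits": self.sfy_traits,
            "G0": self.G0.tolist(),
            "R0": self.R0.tolist(),
            "M0": {k: float(v) for k, v in self.M0.items()},
            "S0": {k: float(v) for k, v in self.S0.items()},
            "cg_var": self.cg_var,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VarianceComponents":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            traits=d["traits"], G0=np.array(d["G0"]), R0=np.array(d["R0"]),
            maternal_traits=d.get("maternal_traits", []), sfy_traits=d.get("sfy_traits", []),
            M0=d.get("M0", {}), S0=d.get("S0", {}), cg_var=d.get("cg_var", 0.25),
        )


@dataclass
class ModelSpec:
    """Which evaluation to run: grouping method, genomic or not, traits."""

    grouping: str = "mf"            # 'upg' | 'mf'
    use_genomics: bool = True
    gamma_method: str = "gls"       # 'gls' | 'trend' (metafounder models)
    traits: list | None = None      # default: all traits of the varcomp

    def __post_init__(self) -> None:
        if self.grouping not in ("upg", "mf"):
            raise ValidationError("grouping must be 'upg' or 'mf'")
        if self.gamma_method not in ("gls", "trend"):
            raise ValidationError("gamma_method must be 'gls' or 'trend'")

    @property
    def name(self) -> str:
        base = "ssGBLUP" if self.use_genomics else "BLUP"
        tag = "UPG" if self.grouping == "upg" else (
            "MetaGLS" if self.gamma_method == "gls" else "MetaTrend")
        return f"{base}-{tag}"


# ----------------------------------------------------------------------
# Assembly
# ----------------------------------------------------------------------
@dataclass
class EquationIndex:
    traits: list
    slots: list                     # genetic (trait, effect) slots
    cg_levels: dict                 # trait -> list of cg codes
    cg_offset: dict                 # trait -> first equation
    gen_offset: int
    n_ext: int                      # animals + groups
    mpe_levels: dict
    mpe_offset: dict
    sfy_levels: dict
    sfy_offset: dict
    n_eq: int
    n_animals: int
    n_groups: int
    animal_ids: np.ndarray

    def genetic_col(self, slot_idx: int, ext_pos: int) -> int:
        return self.gen_offset + slot_idx * self.n_ext + ext_pos


@dataclass
class AssembledSystem:
    LHS: sp.csr_matrix
    RHS: np.ndarray
    index: EquationIndex


def build_mme(
    dataset: Dataset,
    varcomp: VarianceComponents,
    relationship,
    groupdef: GroupDefinition,
) -> AssembledSystem:
    """Assemble the sparse multitrait Henderson system.

    ``relationship`` is a PedigreeRelationship or HInverse whose matrix
    spans animals + group columns in pedigree order.  Missing traits per
    record are handled through per-pattern residual sub-block inverses.
    """
    ped = dataset.pedigree
    K, n_animals, n_groups, kind = _relationship_parts(relationship)
    if n_animals != ped.n:
        raise DataError("relationship matrix does not match the pedigree")
    traits = [t for t in varcomp.traits]
    phen = dataset.phenotypes
    y_cols = {t: phen[t].to_numpy(dtype=float) if t in phen.columns
              else np.full(len(phen), np.nan) for t in traits}
    observed = {t: ~np.isnan(y_cols[t]) for t in traits}
    any_obs = np.logical_or.reduce([observed[t] for t in traits]) if traits else np.array([], bool)
    phen = phen.loc[any_obs].reset_index(drop=True)
    y_cols = {t: y_cols[t][any_obs] for t in traits}
    observed = {t: observed[t][any_obs] for t in traits}
    n_rec = len(phen)

    animal_pos = ped.positions(phen["id"]) if n_rec else np.array([], dtype=int)
    sire_idx, dam_idx = ped.parent_indices()
    rec_sire = sire_idx[animal_pos] if n_rec else np.array([], dtype=int)
    rec_dam = dam_idx[animal_pos] if n_rec else np.array([], dtype=int)
    pop = ped.df["pop"].astype(str).to_numpy()
    years = ped.df["year"].to_numpy()
    flocks = ped.df["flock"].to_numpy()
    # group column used when a record's dam is unknown (maternal effect of
    # the phantom dam): offspring's population x cohort group
    rec_dam_group = np.array(
        [groupdef.group_of(pop[a], int(years[a])) for a in animal_pos], dtype=int
    ) if n_rec else np.array([], dtype=int)
    cg_codes = phen["cg"].astype(str).to_numpy()

    # ---- equation layout ---------------------------------------------
    slots = varcomp.slots
    cg_levels, cg_offset = {}, {}
    offset = 0
    for t in traits:
        levels = sorted(set(cg_codes[observed[t]]))
        cg_levels[t] = levels
        cg_offset[t] = offset
        offset += len(levels)
    gen_offset = offset
    n_ext = n_animals + n_groups
    offset += len(slots) * n_ext
    mpe_levels, mpe_offset = {}, {}
    for t in varcomp.maternal_traits:
        dams = sorted(set(int(ped.ids[d]) for d, ok in zip(rec_dam, observed[t]) if ok and d >= 0))
        mpe_levels[t] = {d: i for i, d in enumerate(dams)}
        mpe_offset[t] = offset
        offset += len(dams)
    sfy_levels, sfy_offset = {}, {}
    for t in varcomp.sfy_traits:
        keys = sorted(set(
            (int(ped.ids[s]), str(flocks[a]), int(years[a]))
            for s, a, ok in zip(rec_sire, animal_pos, observed[t]) if ok and s >= 0
        ))
        sfy_levels[t] = {k: i for i, k in enumerate(keys)}
        sfy_offset[t] = offset
        offset += len(keys)
    n_eq = offset
    index = EquationIndex(
        traits, slots, cg_levels, cg_offset, gen_offset, n_ext,
        mpe_levels, mpe_offset, sfy_levels, sfy_offset, n_eq,
        n_animals, n_groups, ped.ids,
    )

    # ---- per-trait design matrices -----------------------------------
    designs = {}
    slot_pos = {s: i for i, s in enumerate(slots)}
    for t in traits:
        rows, cols = [], []
        cg_map = {c: i for i, c in enumerate(cg_levels[t])}
        obs = observed[t]
        for r in np.flatnonzero(obs):
            rows.append(r); cols.append(cg_offset[t] + cg_map[cg_codes[r]])
            rows.append(r); cols.append(index.genetic_col(slot_pos[(t, "direct")], animal_pos[r]))
            if t in varcomp.maternal_traits:
                mcol = (rec_dam[r] if rec_dam[r] >= 0 else n_animals + rec_dam_group[r])
                rows.append(r); cols.append(index.genetic_col(slot_pos[(t, "maternal")], mcol))
                if rec_dam[r] >= 0:
                    rows.append(r)
                    cols.append(mpe_offset[t] + mpe_levels[t][int(ped.ids[rec_dam[r]])])
            if t in varcomp.sfy_traits and rec_sire[r] >= 0:
                key = (int(ped.ids[rec_sire[r]]), str(flocks[animal_pos[r]]), int(years[animal_pos[r]]))
                rows.append(r); cols.append(sfy_offset[t] + sfy_levels[t][key])
        designs[t] = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n_rec, n_eq)
        )

    # ---- data part, grouped by missing-trait pattern ------------------
    LHS = sp.csr_matrix((n_eq, n_eq))
    RHS = np.zeros(n_eq)
    patterns = {}
    obs_mat = np.column_stack([observed[t] for t in traits]) if traits else np.empty((n_rec, 0), bool)
    for r in range(n_rec):
        patterns.setdefault(tuple(obs_mat[r]), []).append(r)
    for key, rows in patterns.items():
        O = [i for i, flag in enumerate(key) if flag]
        if not O:
            continue
        Rsub = varcomp.R0[np.ix_(O, O)]
        Rinv = np.linalg.inv(Rsub)
        rows = np.asarray(rows)
        for a, ti in enumerate(O):
            Dt = designs[traits[ti]][rows]
            for b, ui in enumerate(O):
                c = Rinv[a, b]
                if c == 0.0:
                    continue
                Du = designs[traits[ui]][rows]
                LHS = LHS + c * (Dt.T @ Du)
                RHS += c * np.asarray(Dt.T @ y_cols[traits[ui]][rows]).ravel()

    # ---- covariance structure ----------------------------------------
    G0inv = np.linalg.inv(varcomp.G0)
    LHS = LHS + _embed(sp.kron(sp.csr_matrix(G0inv), K, format="csr"), gen_offset, n_eq)
    if kind == "upg":
        sel = sp.diags(np.r_[np.zeros(n_animals), np.ones(n_groups)])
        LHS = LHS + _embed(sp.kron(sp.csr_matrix(G0inv), sel, format="csr"), gen_offset, n_eq)
    for t in varcomp.maternal_traits:
        nlev = len(mpe_levels[t])
        if nlev and varcomp.M0.get(t, 0.0) > 0:
            LHS = LHS + _embed(sp.identity(nlev) / varcomp.M0[t], mpe_offset[t], n_eq)
    for t in varcomp.sfy_traits:
        nlev = len(sfy_levels[t])
        if nlev and varcomp.S0.get(t, 0.0) > 0:
            LHS = LHS + _embed(sp.identity(nlev) / varcomp.S0[t], sfy_offset[t], n_eq)
    return AssembledSystem(LHS.tocsr(), RHS, index)


def _relationship_parts(relationship):
    if isinstance(relationship, relmat.HInverse):
        return relationship.matrix, relationship.n_animals, relationship.n_groups, relationship.kind
    if isinstance(relationship, relmat.PedigreeRelationship):
        kind = "upg" if relationship.kind == "upg" else "mf"
        return relationship.A_inv, relationship.n_animals, relationship.n_groups, kind
    raise DataError("relationship must be a PedigreeRelationship or HInverse")


def _embed(M: sp.spmatrix, offset: int, n_eq: int) -> sp.csr_matrix:
    coo = sp.coo_matrix(M)
    return sp.coo_matrix(
        (coo.data, (coo.row + offset, coo.col + offset)), shape=(n_eq, n_eq)
    ).tocsr()


# ----------------------------------------------------------------------
# Solving
# ----------------------------------------------------------------------
@dataclass
class Solutions:
    x: np.ndarray
    index: EquationIndex
    model_name: str = ""
    iterations: int = 0
    relative_residual: float = 0.0
    solver: str = "pcg"

    def ebv(self, trait: str, effect: str = "direct") -> pd.Series:
        """(G)EBVs of all pedigree animals for one trait/effect."""
        slot = self.index.slots.index((trait, effect))
        start = self.index.gen_offset + slot * self.index.n_ext
        vals = self.x[start:start + self.index.n_animals]
        return pd.Series(vals, index=self.index.animal_ids, name=f"{trait}_{effect}")

    def group_effects(self, trait: str, effect: str = "direct") -> np.ndarray:
        slot = self.index.slots.index((trait, effect))
        start = self.index.gen_offset + slot * self.index.n_ext + self.index.n_animals
        return self.x[start:start + self.index.n_groups]

    def fixed_effects(self, trait: str) -> pd.Series:
        off = self.index.cg_offset[trait]
        levels = self.index.cg_levels[trait]
        return pd.Series(self.x[off:off + len(levels)], index=levels, name=f"cg_{trait}")

    def to_csv(self, path, model_tag: str | None = None) -> None:
        tag = model_tag or self.model_name
        frames = []
        for trait, effect in self.index.slots:
            s = self.ebv(trait, effect)
            frames.append(pd.DataFrame({
                "id": s.index, "trait": trait, "effect": effect, "value": s.to_numpy(),
                "model": tag,
            }))
        pd.concat(frames).to_csv(path, index=False)


def solve(
    system: AssembledSystem,
    tol: float = 1e-10,
    max_iter: int | None = None,
    method: str = "auto",
) -> Solutions:
    """Solve the assembled system.

    Preconditioned conjugate gradients (Jacobi preconditioner) is the
    workhorse; small systems or PCG failures fall back to a sparse direct
    factorisation.
    """
    A, b = system.LHS, system.RHS
    n = A.shape[0]
    if not np.any(b):
        return Solutions(np.zeros(n), system.index, solver="trivial")
    if method not in ("auto", "pcg", "direct"):
        raise ValidationError("method must be auto|pcg|direct")
    if method in ("auto", "pcg"):
        diag = A.diagonal()
        diag = np.where(diag > 0, diag, 1.0)
        M = spla.LinearOperator((n, n), matvec=lambda v: v / diag)
        max_iter = max_iter or max(2000, 5 * n)
        x, info = spla.cg(A, b, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
        res = float(np.linalg.norm(A @ x - b) / np.linalg.norm(b))
        if info == 0 and res <= max(tol * 100, 1e-8):
            return Solutions(x, system.index, iterations=max_iter, relative_residual=res)
        if method == "pcg":
            raise DataError(f"PCG failed to converge (relative residual {res:.2e})")
        warnings.warn(f"PCG stalled (residual {res:.2e}); falling back to direct solve")
    if n > 200_000:
        raise DataError("system too large for the direct fallback")
    lu = spla.splu(A.tocsc())
    x = lu.solve(b)
    res = float(np.linalg.norm(A @ x - b) / np.linalg.norm(b))
    return Solutions(x, system.index, relative_residual=res, solver="direct")


# ----------------------------------------------------------------------
# End-to-end evaluation
# ----------------------------------------------------------------------
def build_relationship(
    dataset: Dataset,
    spec: ModelSpec,
    groupdef: GroupDefinition,
    gamma: GammaMatrix | None = None,
):
    """Construct the relationship inverse required by a model variant."""
    ped = dataset.pedigree
    genotyped = dataset.genotypes is not None and dataset.genotypes.n_animals > 0
    use_geno = spec.use_genomics and genotyped
    if spec.grouping == "upg":
        base = relmat.a_inverse(ped, groupdef)
        if not use_geno:
            return base
        geno = dataset.genotypes
        idx = ped.positions(geno.animal_ids)
        A = relmat.a_dense(ped)
        A22 = A[np.ix_(idx, idx)]
        G = relmat.g_vanraden(geno, "observed")
        G05 = relmat.blend(G, A22)
        A22_inv = np.linalg.inv(A22)
        Q2 = group_fractions(ped, groupdef).rows(geno.animal_ids)
        return relmat.h_inverse_upg(base, G05, A22_inv, Q2, geno.animal_ids)
    # metafounders
    if gamma is None:
        if dataset.genotypes is None:
            raise DataError("metafounder model needs a Γ matrix or genotypes to estimate one")
        gamma = estimate_gamma_gls(dataset.genotypes, group_fractions(ped, groupdef))
    base = relmat.a_gamma(ped, groupdef, gamma)
    if not use_geno:
        return base
    geno = dataset.genotypes
    idx = ped.positions(geno.animal_ids)
    Ag = relmat.a_gamma_dense(ped, groupdef, base.gamma)
    Ag22 = Ag[np.ix_(idx, idx)]
    G = relmat.g_vanraden(geno, "0.5")
    G05 = relmat.blend(G, Ag22)
    Ag22_inv = np.linalg.inv(Ag22)
    return relmat.h_inverse_mf(base, G05, Ag22_inv, geno.animal_ids)


def run_evaluation(
    dataset: Dataset,
    spec: ModelSpec,
    varcomp: VarianceComponents,
    groupdef: GroupDefinition | None = None,
    gamma: GammaMatrix | None = None,
    tol: float = 1e-10,
    log: list | None = None,
) -> Solutions:
    """Relationship construction, assembly and solve for one model variant."""
    t0 = time.time()
    if spec.traits:
        varcomp = varcomp.submodel(spec.traits)
    if groupdef is None:
        groupdef = assign_groups(dataset.pedigree)
    relationship = build_relationship(dataset, spec, groupdef, gamma)
    system = build_mme(dataset, varcomp, relationship, groupdef)
    sol = solve(system, tol=tol)
    sol.model_name = spec.name
    if log is not None:
        log.append({
            "model": spec.name, "n_equations": system.index.n_eq,
            "n_groups": groupdef.n_groups, "solver": sol.solver,
            "relative_residual": sol.relative_residual,
            "seconds": round(time.time() - t0, 2),
        })
    return sol
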