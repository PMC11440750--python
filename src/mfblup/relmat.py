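"""Pedigree, genomic and single-step relationship matrices.

Three families of matrices are produced:

* the numerator relationship matrix A (Henderson rules with inbreeding),
  optionally augmented with unknown-parent-group columns in the Quaas "QP"
  form, giving the sparse blocks [[A^-1, -A^-1 Q], [-Q'A^-1, Q'A^-1 Q]];
* the metafounder variant A_Γ, in which base populations enter the
  pedigree as correlated pseudo-parents with self-relationship Γ_gg, so a
  founder assigned to metafounder g has diagonal 1 + Γ_gg / 2;
* VanRaden genomic matrices G (observed-frequency or 0.5 centring),
  blended with the pedigree block for invertibility, and the two
  single-step H-inverses:

      H*_QΣ  = A*_Σ + [[0, 0, 0],
                       [0,  G^-1 - A22^-1,        -(G^-1 - A22^-1) Q2],
                       [0, -Q2'(G^-1 - A22^-1), Q2'(G^-1 - A22^-1) Q2]]

      H_Γ^-1 = A_Γ^-1 + [[0, 0, 0], [0, G05^-1 - A_Γ22^-1, 0], [0, 0, 0]]

Dense tabular construction is the desk-scale backbone (gated by size);
inverses are always assembled sparsely from Mendelian-sampling variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DataError, ValidationError
from .groups import GammaMatrix, GroupDefinition
from .pedigree import Pedigree
from .popstruct import GenotypeSet

DENSE_GATE = 6000  # largest pedigree for on-demand dense matrices


# ----------------------------------------------------------------------
# Dense tabular relationship matrices
# ----------------------------------------------------------------------
def a_dense(ped: Pedigree) -> np.ndarray:
    """Classical numerator relationship matrix by the tabular method."""
    n = ped.n
    if n > DENSE_GATE:
        raise DataError(f"dense A gated at {DENSE_GATE} animals (got {n})")
    sire, dam = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def a_gamma_dense(ped: Pedigree, groupdef: GroupDefinition, gamma: GammaMatrix) -> np.ndarray:
    """Γ-augmented relationship matrix, animals first then metafounders.

    Metafounders act as pseudo-parents filling every unknown slot; their
    block is Γ itself and founder diagonals become 1 + Γ_gg / 2.
    """
    n, g = ped.n, groupdef.n_groups
    if n + g > DENSE_GATE:
        raise DataError(f"dense A_Γ gated at {DENSE_GATE} entities")
    sire, dam = ped.parent_indices()
    pop = ped.df["pop"].astype(str).to_numpy()
    years = ped.df["year"].to_numpy()
    # build with metafounders first (parents must precede offspring)
    m = g + n
    A = np.zeros((m, m))
    A[:g, :g] = gamma.matrix
    for i in range(n):
        s = g + sire[i] if sire[i] >= 0 else groupdef.group_of(pop[i], int(years[i]))
        d = g + dam[i] if dam[i] >= 0 else groupdef.group_of(pop[i], int(years[i]))
        k = g + i
        row = 0.5 * (A[s, :k] + A[d, :k])
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + 0.5 * A[s, d]
    # permute to animals-first ordering
    perm = np.r_[np.arange(g, m), np.arange(g)]
    return A[np.ix_(perm, perm)]


def pedigree_inbreeding(ped: Pedigree) -> np.ndarray:
    """Classical pedigree inbreeding F (Meuwissen-Luo style).

    Uses the T D T' decomposition of A: for animal i with parents s, d,
    F_i = 0.5 * sum_j t_sj t_dj D_j over shared ancestors j, where D_j is
    the Mendelian-sampling variance of j.
    """
    sire, dam = ped.parent_indices()
    n = ped.n
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * F[max(s, d)]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        ts = _t_row(s, sire, dam)
        td = _t_row(d, sire, dam)
        small, big = (ts, td) if len(ts) <= len(td) else (td, ts)
        a_sd = 0.0
        for j, c in small.items():
            cb = big.get(j)
            if cb is not None:
                a_sd += c * cb * D[j]
        F[i] = 0.5 * a_sd
    return F


def _t_row(idx: int, sire: np.ndarray, dam: np.ndarray) -> dict:
    """Row of the gene-flow matrix T for one animal: expected genetic
    contribution of every ancestor."""
    coeff = {idx: 1.0}
    for k in range(idx, -1, -1):
        c = coeff.get(k)
        if c is None:
            continue
        for p in (sire[k], dam[k]):
            if p >= 0:
                coeff[p] = coeff.get(p, 0.0) + 0.5 * c
    return coeff


# ----------------------------------------------------------------------
# Sparse inverses by Henderson rules
# ----------------------------------------------------------------------
@dataclass
class PedigreeRelationship:
    """A relationship inverse plus bookkeeping.

    ``A_inv`` spans ``n_animals + n_groups`` equations (group columns empty
    for the plain classical matrix).  ``F`` is classical pedigree
    inbreeding; under Γ-augmentation ``F_gamma`` holds the Γ-scaled
    self-relationship minus one.
    """

    ids: np.ndarray
    A_inv: sp.csr_matrix
    F: np.ndarray
    kind: str                      # 'classical' | 'upg' | 'gamma'
    n_animals: int
    n_groups: int = 0
    group_labels: list = field(default_factory=list)
    F_gamma: np.ndarray | None = None
    groupdef: GroupDefinition | None = None
    gamma: GammaMatrix | None = None

    def dense(self) -> np.ndarray:
        return self.A_inv.toarray()


def _henderson_assemble(entries: list, size: int) -> sp.csr_matrix:
    rows, cols, vals = zip(*entries)
    M = sp.coo_matrix((vals, (rows, cols)), shape=(size, size))
    return M.tocsr()


def a_inverse(ped: Pedigree, groupdef: GroupDefinition | None = None) -> PedigreeRelationship:
    """Sparse A^-1 by Henderson rules with inbreeding.

    With ``groupdef`` the unknown-parent slots point at group columns,
    yielding the Quaas group-augmented blocks (without any group-variance
    term: randomness of groups is added at model assembly).
    """
    sire, dam = ped.parent_indices()
    F = pedigree_inbreeding(ped)
    n = ped.n
    g = groupdef.n_groups if groupdef is not None else 0
    pop = ped.df["pop"].astype(str).to_numpy()
    years = ped.df["year"].to_numpy()
    entries: list = []
    for i in range(n):
        s, d = sire[i], dam[i]
        n_known = int(s >= 0) + int(d >= 0)
        if n_known == 2:
            m_i = 0.5 - 0.25 * (F[s] + F[d])
        elif n_known == 1:
            m_i = 0.75 - 0.25 * F[max(s, d)]
        else:
            m_i = 1.0
        w = 1.0 / m_i
        coeff = [(i, 1.0)]
        for p in (s, d):
            if p >= 0:
                coeff.append((p, -0.5))
            elif groupdef is not None:
                coeff.append((n + groupdef.group_of(pop[i], int(years[i])), -0.5))
        for a, ca in coeff:
            for b, cb in coeff:
                entries.append((a, b, w * ca * cb))
    A_inv = _henderson_assemble(entries, n + g)
    return PedigreeRelationship(
        ids=ped.ids, A_inv=A_inv, F=F, kind="upg" if groupdef is not None else "classical",
        n_animals=n, n_groups=g,
        group_labels=groupdef.labels if groupdef is not None else [],
        groupdef=groupdef,
    )


def a_gamma(ped: Pedigree, groupdef: GroupDefinition, gamma: GammaMatrix) -> PedigreeRelationship:
    """Sparse inverse of the Γ-augmented relationship matrix.

    Metafounders are pseudo-parents: every animal has two parents (real or
    metafounder), the Mendelian-sampling variance is
    m_i = 0.5 - (F_s + F_d) / 4 with metafounder "inbreeding"
    F_g = Γ_gg - 1, and Γ^-1 is added to the group block.
    """
    from .groups import check_gamma

    gamma = check_gamma(gamma)
    G = gamma.matrix
    n, g = ped.n, groupdef.n_groups
    if G.shape != (g, g):
        raise ValidationError("Γ dimension does not match the group definition")
    sire, dam = ped.parent_indices()
    pop = ped.df["pop"].astype(str).to_numpy()
    years = ped.df["year"].to_numpy()

    # Γ-scale self-relationships: recursion over diag only needs parents'
    # diagonals and the parental cross term, obtained from the dense matrix
    # when affordable, else by T-row traversal.
    Fg = _gamma_inbreeding(ped, groupdef, G)
    Fg_meta = np.diag(G) - 1.0

    entries: list = []
    for i in range(n):
        ps = ("a", sire[i]) if sire[i] >= 0 else ("g", groupdef.group_of(pop[i], int(years[i])))
        pd_ = ("a", dam[i]) if dam[i] >= 0 else ("g", groupdef.group_of(pop[i], int(years[i])))
        fvals = [Fg[p[1]] if p[0] == "a" else Fg_meta[p[1]] for p in (ps, pd_)]
        m_i = 0.5 - 0.25 * sum(fvals)
        if m_i <= 0:
            raise DataError(f"non-positive Mendelian variance for animal {ped.ids[i]}")
        w = 1.0 / m_i
        coeff = [(i, 1.0)]
        for kind, p in (ps, pd_):
            coeff.append((p if kind == "a" else n + p, -0.5))
        for a, ca in coeff:
            for b, cb in coeff:
                entries.append((a, b, w * ca * cb))
    if g:
        # singular Γ (e.g. the zero matrix of the classical reduction) gets
        # a pseudo-inverse: the animal block still reduces exactly
        try:
            Ginv = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            Ginv = np.linalg.pinv(G)
    else:
        Ginv = np.empty((0, 0))
    for a in range(g):
        for b in range(g):
            if Ginv[a, b] != 0.0:
                entries.append((n + a, n + b, Ginv[a, b]))
    A_inv = _henderson_assemble(entries, n + g)
    return PedigreeRelationship(
        ids=ped.ids, A_inv=A_inv, F=pedigree_inbreeding(ped), kind="gamma",
        n_animals=n, n_groups=g, group_labels=groupdef.labels,
        F_gamma=Fg, groupdef=groupdef, gamma=gamma,
    )


def _gamma_inbreeding(ped: Pedigree, groupdef: GroupDefinition, G: np.ndarray) -> np.ndarray:
    """Γ-augmented self-relationship minus one, for every animal."""
    n, g = ped.n, groupdef.n_groups
    if n + g <= DENSE_GATE:
        Ad = a_gamma_dense(ped, groupdef, GammaMatrix(
            pd.DataFrame(G, index=groupdef.labels, columns=groupdef.labels)))
        return np.diag(Ad)[:n] - 1.0
    # T-row fallback: a_ii = q_i' Γ q_i + Σ_k t_ik^2 m_k over real ancestors
    sire, dam = ped.parent_indices()
    pop = ped.df["pop"].astype(str).to_numpy()
    years = ped.df["year"].to_numpy()
    Fg = np.zeros(n)
    m = np.zeros(n)
    Fg_meta = np.diag(G) - 1.0
    for i in range(n):
        s, d = sire[i], dam[i]
        gi = groupdef.group_of(pop[i], int(years[i]))
        fs = Fg[s] if s >= 0 else Fg_meta[gi]
        fd = Fg[d] if d >= 0 else Fg_meta[gi]
        m[i] = 0.5 - 0.25 * (fs + fd)
        # diagonal via T row
        coeff = {i: 1.0}
        qvec = np.zeros(g)
        acc = 0.0
        for k in range(i, -1, -1):
            c = coeff.get(k)
            if c is None:
                continue
            acc += c * c * m[k]
            gk = groupdef.group_of(pop[k], int(years[k]))
            for p in (sire[k], dam[k]):
                if p >= 0:
                    coeff[p] = coeff.get(p, 0.0) + 0.5 * c
                else:
                    qvec[gk] += 0.5 * c
        Fg[i] = acc + qvec @ G @ qvec - 1.0
    return Fg


# ----------------------------------------------------------------------
# Genomic relationship matrices
# ----------------------------------------------------------------------
@dataclass
class GenomicRelationship:
    G: np.ndarray
    freq_convention: str           # 'observed' | '0.5'
    animal_ids: np.ndarray
    frequencies: np.ndarray
    monomorphic_markers: list = field(default_factory=list)
    G05: np.ndarray | None = None  # blended matrix, set by blend()


def g_vanraden(g: GenotypeSet, freq_convention: str = "observed") -> GenomicRelationship:
    """VanRaden genomic relationship matrix G = ZZ'/s.

    Z = M - 2p with p the observed allele frequencies (s = 2 Σ p(1-p)) or
    p = 0.5 for the metafounder convention (s = n/2).  Monomorphic markers
    contribute nothing under observed frequencies and are reported.
    """
    if (g.calls == -1).any():
        raise DataError("G requires complete genotype calls")
    M = g.calls.astype(float)
    if freq_convention == "observed":
        p = M.mean(axis=0) / 2.0
        mono = (p == 0) | (p == 1)
        s = float(2.0 * np.sum(p * (1 - p)))
        monomorphic = list(np.asarray(g.marker_ids)[mono])
    elif freq_convention == "0.5":
        p = np.full(g.n_markers, 0.5)
        s = g.n_markers / 2.0
        monomorphic = []
    else:
        raise ValidationError(f"unknown frequency convention {freq_convention!r}")
    if s <= 0:
        raise DataError("all markers monomorphic; G undefined")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / s
    return GenomicRelationship(G, freq_convention, g.animal_ids, p, monomorphic)


def blend(
    gr: GenomicRelationship | np.ndarray,
    a_ref_block: np.ndarray,
    wG: float = 0.95,
    wA: float = 0.05,
) -> np.ndarray:
    """G05 = wG * G + wA * A-block (A22 or A_Γ22 depending on the model)."""
    if abs(wG + wA - 1.0) > 1e-12:
        raise ValidationError("blending weights must sum to 1")
    G = gr.G if isinstance(gr, GenomicRelationship) else np.asarray(gr)
    A = np.asarray(a_ref_block)
    if G.shape != A.shape:
        raise DataError(f"blend dimension mismatch: {G.shape} vs {A.shape}")
    out = wG * G + wA * A
    if isinstance(gr, GenomicRelationship):
        gr.G05 = out
    return out


def _inv_pd(M: np.ndarray, what: str) -> np.ndarray:
    try:
        c = np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise DataError(f"{what} is singular/not positive definite; consider blending") from exc
    ident = np.eye(M.shape[0])
    inv = np.linalg.solve(M, ident)
    del c
    return 0.5 * (inv + inv.T)


# ----------------------------------------------------------------------
# Single-step H-inverses
# ----------------------------------------------------------------------
@dataclass
class HInverse:
    matrix: sp.csr_matrix          # (n_animals + n_groups) square
    genotyped_ids: np.ndarray
    kind: str                      # 'upg' | 'mf'
    n_animals: int
    n_groups: int


def h_inverse_upg(
    a_star: PedigreeRelationship,
    G05: np.ndarray,
    A22_inv: np.ndarray,
    Q2: np.ndarray,
    genotyped_ids,
) -> HInverse:
    """QP-model single-step inverse: the (G^-1 - A22^-1) block with its
    group couplings added onto the group-augmented pedigree inverse."""
    n, g = a_star.n_animals, a_star.n_groups
    idx = _geno_positions(a_star.ids, genotyped_ids)
    D = _inv_pd(G05, "blended G05") - np.asarray(A22_inv)
    Q2 = np.asarray(Q2, dtype=float)
    if Q2.shape != (len(idx), g):
        raise DataError("Q2 must be genotyped-animals x groups")
    H = sp.lil_matrix((n + g, n + g))
    H[np.ix_(idx, idx)] = D
    DQ = D @ Q2
    gcols = np.arange(n, n + g)
    H[np.ix_(idx, gcols)] = -DQ
    H[np.ix_(gcols, idx)] = -DQ.T
    H[np.ix_(gcols, gcols)] = Q2.T @ DQ
    return HInverse((a_star.A_inv + H.tocsr()).tocsr(), np.asarray(genotyped_ids), "upg", n, g)


def h_inverse_mf(
    a_gamma_rel: PedigreeRelationship,
    G05: np.ndarray,
    A_g22_inv: np.ndarray,
    genotyped_ids,
) -> HInverse:
    """Metafounder single-step inverse: only the genotyped block changes;
    groups live inside A_Γ so no coupling blocks appear."""
    n, g = a_gamma_rel.n_animals, a_gamma_rel.n_groups
    idx = _geno_positions(a_gamma_rel.ids, genotyped_ids)
    D = _inv_pd(G05, "blended G05") - np.asarray(A_g22_inv)
    H = sp.lil_matrix((n + g, n + g))
    H[np.ix_(idx, idx)] = D
    return HInverse((a_gamma_rel.A_inv + H.tocsr()).tocsr(), np.asarray(genotyped_ids), "mf", n, g)


def _geno_positions(ids: np.ndarray, genotyped_ids) -> np.ndarray:
    index = {int(a): i for i, a in enumerate(ids)}
    try:
        return np.array([index[int(a)] for a in genotyped_ids], dtype=int)
    except KeyError as exc:
        raise DataError(f"genotyped animal {exc.args[0]} absent from pedigree") from exc


# ----------------------------------------------------------------------
# Coordinate-format exchange
# ----------------------------------------------------------------------
def write_triplets(M: sp.spmatrix, path, ids=None) -> None:
    """Write a sparse symmetric matrix as (i, j, value) triplets with an
    optional id-map sidecar ``<path>.ids``."""
    coo = sp.coo_matrix(M)
    pd.DataFrame({"i": coo.row, "j": coo.col, "value": coo.data}).to_csv(path, index=False)
    if ids is not None:
        pd.DataFrame({"index": np.arange(len(ids)), "id": ids}).to_csv(f"{path}.ids", index=False)


def read_triplets(path) -> sp.csr_matrix:
    df = pd.read_csv(path)
    size = int(max(df["i"].max(), df["j"].max())) + 1
    return sp.coo_matrix((df["value"], (df["i"], df["j"])), shape=(size, size)).tocsr()
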