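"""Genetic grouping: metafounders / unknown-parent groups and the Γ matrix.

Groups are defined as population x 5-year birth cohort (a population whose
recorded years fit inside one interval keeps a single group).  The ancestral
relationship matrix Γ between groups is estimated two ways:

* **GLS**: base allele frequencies per group are solved from genotypes
  against the group-fraction design, and Γ entries follow from
  Γ0 = (2/n) Σ (2p_i - 1)^2 and γ_kl = (2/n) Σ (2p_i(k) - 1)(2p_i(l) - 1).
* **Trend**: within a population, relatedness between consecutive cohorts
  grows linearly with the yearly increase in metafounder-scaled inbreeding
  ΔF(γ) = ΔF (1 - Γ0/2), where ΔF comes from a linear model of pedigree
  inbreeding on birth year; between-population blocks are constant γ_kl.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ValidationError
from .pedigree import Pedigree
from .popstruct import GenotypeSet, MISSING


# ----------------------------------------------------------------------
# Group definition and expected group fractions
# ----------------------------------------------------------------------
@dataclass
class GroupDefinition:
    """Metafounder/UPG layout: one group per population x year interval."""

    groups: list  # of (population, (year_lo, year_hi)) in time order per population
    interval_years: int = 5

    def __post_init__(self) -> None:
        self._by_pop: dict[str, list[int]] = {}
        for idx, (pop, _) in enumerate(self.groups):
            self._by_pop.setdefault(pop, []).append(idx)
        for pop, idxs in self._by_pop.items():
            spans = [self.groups[i][1] for i in idxs]
            if any(spans[i][1] + 1 != spans[i + 1][0] for i in range(len(spans) - 1)):
                raise ValidationError(f"year intervals of population {pop!r} do not partition its range")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def labels(self) -> list[str]:
        return [f"{pop}|{lo}-{hi}" for pop, (lo, hi) in self.groups]

    @property
    def populations(self) -> list[str]:
        return list(self._by_pop)

    def groups_of_population(self, pop: str) -> list[int]:
        """Group indices of one population, in time order."""
        return self._by_pop[pop]

    def group_of(self, pop: str, year: int) -> int:
        """Group index for an unknown parent of an animal of this
        population born in this year."""
        idxs = self._by_pop.get(pop)
        if idxs is None:
            raise DataError(f"population {pop!r} has no groups defined")
        for i in idxs:
            lo, hi = self.groups[i][1]
            if lo <= year <= hi:
                return i
        # clamp years outside the recorded range to the nearest cohort
        first, last = self.groups[idxs[0]][1], self.groups[idxs[-1]][1]
        return idxs[0] if year < first[0] else idxs[-1]

    def to_yaml(self, path) -> None:
        data = {
            "interval_years": self.interval_years,
            "groups": [{"population": p, "years": [int(lo), int(hi)]} for p, (lo, hi) in self.groups],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroupDefinition":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        groups = [(g["population"], (g["years"][0], g["years"][1])) for g in data["groups"]]
        return cls(groups, interval_years=data.get("interval_years", 5))


def assign_groups(
    pedigree: Pedigree,
    population_labels=None,
    interval_years: int = 5,
) -> GroupDefinition:
    """Define one group per population x ``interval_years`` birth cohort.

    A population whose recorded years span at most one interval keeps a
    single group.  Intervals are anchored at each population's earliest
    birth year.
    """
    df = pedigree.df
    pop = (np.asarray(population_labels) if population_labels is not None
           else df["pop"].astype(str).to_numpy())
    years = df["year"].to_numpy()
    if np.isnan(years.astype(float)).any():
        raise ValidationError("every animal needs a birth year for group assignment")
    groups: list = []
    for p in pd.unique(pop):
        sel = pop == p
        lo, hi = int(years[sel].min()), int(years[sel].max())
        span = hi - lo + 1
        if span <= interval_years:
            groups.append((p, (lo, hi)))
            continue
        start = lo
        while start <= hi:
            end = min(start + interval_years - 1, hi)
            groups.append((p, (start, end)))
            start = end + 1
    return GroupDefinition(groups, interval_years=interval_years)


@dataclass
class GroupQ:
    """Animal x group expected fractions; rows sum to one."""

    values: np.ndarray
    animal_ids: np.ndarray
    group_labels: list

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.animal_ids, columns=self.group_labels)

    def rows(self, animal_ids) -> np.ndarray:
        index = {int(a): i for i, a in enumerate(self.animal_ids)}
        return self.values[[index[int(a)] for a in animal_ids]]


def group_fractions(pedigree: Pedigree, groupdef: GroupDefinition) -> GroupQ:
    """Expected group fractions by recursive parental averaging.

    An unknown parent contributes 1/2 to the group of its offspring's
    population and birth cohort; a founder (both parents unknown) is a unit
    vector on its own group.
    """
    sire_idx, dam_idx = pedigree.parent_indices()
    pop = pedigree.df["pop"].astype(str).to_numpy()
    years = pedigree.df["year"].to_numpy()
    Q = np.zeros((pedigree.n, groupdef.n_groups))
    for i in range(pedigree.n):
        for p in (sire_idx[i], dam_idx[i]):
            if p >= 0:
                Q[i] += 0.5 * Q[p]
            else:
                Q[i, groupdef.group_of(pop[i], int(years[i]))] += 0.5
    return GroupQ(Q, pedigree.ids, groupdef.labels)


# ----------------------------------------------------------------------
# Base allele frequencies and Γ entries
# ----------------------------------------------------------------------
def base_allele_frequencies(
    g: GenotypeSet, Q: np.ndarray, labels=None
) -> tuple[pd.DataFrame, int]:
    """Least-squares base frequencies per origin: 2 p_hat_i = (Q'Q)^-1 Q' m_i.

    ``Q`` holds one fraction row per genotyped animal (aligned with
    ``g.animal_ids``).  Returns the origin x marker frequency table and the
    number of entries clipped into [0, 1].
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] != g.n_animals:
        raise DataError("Q must have one row per genotyped animal")
    if (g.calls == MISSING).any():
        raise DataError("base-frequency solve requires complete genotype calls")
    represented = Q.sum(axis=0)
    empty = np.flatnonzero(represented <= 0)
    labels = list(labels) if labels is not None else [f"origin{j}" for j in range(Q.shape[1])]
    if empty.size:
        raise DataError(f"origins without genomic representation: {[labels[j] for j in empty]}")
    QtQ = Q.T @ Q
    if np.linalg.matrix_rank(QtQ) < Q.shape[1]:
        raise DataError(f"singular Q'Q design over origins {labels}")
    M = g.calls.astype(float)
    P = np.linalg.solve(QtQ, Q.T @ M) / 2.0
    n_clipped = int(np.sum((P < 0) | (P > 1)))
    P = np.clip(P, 0.0, 1.0)
    return pd.DataFrame(P, index=labels, columns=g.marker_ids), n_clipped


def gamma_ancestral(p: np.ndarray) -> float:
    """Self-relationship of an ancestral metafounder: (2/n) Σ (2p_i - 1)^2."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DataError("empty frequency vector")
    return float(2.0 * np.mean((2.0 * p - 1.0) ** 2))


def gamma_between(p_k: np.ndarray, p_l: np.ndarray) -> float:
    """Cross-relationship of two metafounders: (2/n) Σ (2p_k - 1)(2p_l - 1)."""
    p_k = np.asarray(p_k, dtype=float)
    p_l = np.asarray(p_l, dtype=float)
    if p_k.shape != p_l.shape:
        raise DataError("frequency vectors of unequal length")
    return float(2.0 * np.mean((2.0 * p_k - 1.0) * (2.0 * p_l - 1.0)))


def delta_f_gamma(delta_f: float, gamma0: float) -> float:
    """Metafounder-scaled yearly inbreeding increase: ΔF(γ) = ΔF (1 - Γ0/2)."""
    if not 0.0 <= gamma0 <= 2.0:
        raise ValidationError(f"Γ0={gamma0} outside [0, 2]")
    if delta_f < 0:
        raise ValidationError("ΔF must be non-negative")
    return float(delta_f * (1.0 - gamma0 / 2.0))


# ----------------------------------------------------------------------
# Inbreeding trend fit
# ----------------------------------------------------------------------
@dataclass
class InbreedingTrendFit:
    populations: list
    b: np.ndarray          # per-population baseline inbreeding
    c: float               # shared year slope
    d: np.ndarray          # per-population year slope
    delta_f: np.ndarray    # resolved ΔF_j after the non-positive-value rule
    c_used: bool


def resolve_delta_f(d: np.ndarray, c: float = 0.0, c_tol: float = 1e-3) -> tuple[np.ndarray, bool]:
    """Resolve per-population ΔF from trend-fit slopes.

    The shared slope c is folded in only when |c| >= ``c_tol`` per year;
    non-positive values (biologically impossible in closed populations) are
    replaced by the mean of the strictly positive ones.
    """
    c_used = abs(c) >= c_tol
    raw = np.asarray(d, dtype=float) + (c if c_used else 0.0)
    positive = raw[raw > 0]
    fill = float(positive.mean()) if positive.size else 0.0
    resolved = np.where(raw > 0, raw, fill)
    return resolved, c_used


def fit_inbreeding_trend(
    pedigree: Pedigree,
    Q_pop: np.ndarray,
    populations=None,
    inbreeding: np.ndarray | None = None,
    c_tol: float = 1e-3,
) -> InbreedingTrendFit:
    """OLS fit of f_i = Σ_j q_ij b_j + t_i c + Σ_j t_i q_ij d_j + e_i.

    Only animals with both parents known enter the fit; t_i is birth year
    centred on the pedigree's earliest year.  ``Q_pop`` holds per-animal
    population fractions aligned with the pedigree rows.
    """
    Q_pop = np.asarray(Q_pop, dtype=float)
    if Q_pop.shape[0] != pedigree.n:
        raise DataError("Q_pop must have one row per pedigree animal")
    populations = list(populations) if populations is not None else [
        f"pop{j}" for j in range(Q_pop.shape[1])
    ]
    if inbreeding is None:
        from .relmat import pedigree_inbreeding

        inbreeding = pedigree_inbreeding(pedigree)
    sire_idx, dam_idx = pedigree.parent_indices()
    both = (sire_idx >= 0) & (dam_idx >= 0)
    if not both.any():
        raise DataError("no animals with both parents known; trend fit impossible")
    rep = Q_pop[both].sum(axis=0)
    absent = [populations[j] for j in np.flatnonzero(rep <= 0)]
    if absent:
        raise DataError(f"populations absent from fully-pedigreed animals: {absent}")
    t = (pedigree.df["year"].to_numpy() - pedigree.df["year"].min()).astype(float)[both]
    Q = Q_pop[both]
    X = np.hstack([Q, t[:, None], t[:, None] * Q])
    f = np.asarray(inbreeding, dtype=float)[both]
    k = Q_pop.shape[1]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # when ancestry fractions sum to one, t is an exact combination of
        # the per-population t*q columns and c is not identifiable; drop it
        warnings.warn("shared year slope collinear with per-population slopes; fitting c = 0")
        X = np.hstack([Q, t[:, None] * Q])
        beta, _, _, _ = np.linalg.lstsq(X, f, rcond=None)
        b, c, d = beta[:k], 0.0, beta[k:]
    else:
        beta, _, _, _ = np.linalg.lstsq(X, f, rcond=None)
        b, c, d = beta[:k], float(beta[k]), beta[k + 1:]
    delta_f, c_used = resolve_delta_f(d, c, c_tol)
    return InbreedingTrendFit(populations, b, c, d, delta_f, c_used)


# ----------------------------------------------------------------------
# Γ matrices
# ----------------------------------------------------------------------
@dataclass
class GammaMatrix:
    """Group x group ancestral relationship matrix."""

    values: pd.DataFrame
    method: str = "trend"            # 'gls' | 'trend'
    gamma0: dict = field(default_factory=dict)       # per-population Γ0
    delta_f_gamma: dict = field(default_factory=dict)  # per-population ΔF(γ)
    representation: dict = field(default_factory=dict)  # per-group effective n

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("Γ must be symmetric")

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# method: {self.method}\n")
            if self.gamma0:
                fh.write(f"# gamma0: {self.gamma0}\n")
            self.values.to_csv(fh)

    @classmethod
    def from_csv(cls, path) -> "GammaMatrix":
        method = "unknown"
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for ln in lines:
            if ln.startswith("#"):
                if "method:" in ln:
                    method = ln.split("method:")[1].strip()
            else:
                body.append(ln)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)), index_col=0)
        return cls(df, method=method)


def build_gamma_trend(
    groupdef: GroupDefinition,
    gamma0_per_pop: dict,
    gamma_between_pops: dict,
    delta_f_gamma_per_pop: dict,
) -> GammaMatrix:
    """Trend-form Γ: within-population cohort blocks grow linearly.

    For cohorts r <= s of population k (1-based time order, interval of
    ``n`` years):  Γ[r, s] = Γ0(k) + (r - 1) * n * 2ΔF(γ, k).
    Between-population blocks are filled with the constant γ_kl.
    """
    G = np.zeros((groupdef.n_groups, groupdef.n_groups))
    n_years = groupdef.interval_years
    for pop in groupdef.populations:
        idxs = groupdef.groups_of_population(pop)
        g0 = gamma0_per_pop[pop]
        dfg = delta_f_gamma_per_pop.get(pop, 0.0)
        for a, ia in enumerate(idxs):
            for b, ib in enumerate(idxs):
                r = min(a, b)  # 0-based (r-1) of the 1-based formula
                G[ia, ib] = g0 + r * n_years * 2.0 * dfg
    pops = groupdef.populations
    for i, k in enumerate(pops):
        for l in pops[i + 1:]:
            gkl = gamma_between_pops.get((k, l), gamma_between_pops.get((l, k)))
            if gkl is None:
                raise DataError(f"missing between-population γ for pair ({k}, {l})")
            for ia in groupdef.groups_of_population(k):
                for ib in groupdef.groups_of_population(l):
                    G[ia, ib] = G[ib, ia] = gkl
    df = pd.DataFrame(G, index=groupdef.labels, columns=groupdef.labels)
    return GammaMatrix(df, method="trend", gamma0=dict(gamma0_per_pop),
                       delta_f_gamma=dict(delta_f_gamma_per_pop))


def estimate_gamma_gls(g: GenotypeSet, Q_groups: GroupQ | np.ndarray, labels=None) -> GammaMatrix:
    """Γ estimated from genotypes: per-marker group base frequencies are
    solved by least squares against the group-fraction design, then Γ
    entries follow from the ancestral-relationship formulas.

    Every group must carry nonzero genomic representation.
    """
    if isinstance(Q_groups, GroupQ):
        labels = Q_groups.group_labels
        Q = Q_groups.rows(g.animal_ids)
    else:
        Q = np.asarray(Q_groups, dtype=float)
    P, _ = base_allele_frequencies(g, Q, labels=labels)
    labels = list(P.index)
    Pm = P.to_numpy()
    n_groups = Pm.shape[0]
    G = np.empty((n_groups, n_groups))
    centered = 2.0 * Pm - 1.0
    G = 2.0 * (centered @ centered.T) / Pm.shape[1]
    df = pd.DataFrame(G, index=labels, columns=labels)
    rep = {lab: float(s) for lab, s in zip(labels, Q.sum(axis=0))}
    return GammaMatrix(df, method="gls", representation=rep)


def check_gamma(gamma: GammaMatrix, tol: float = 1e-8) -> GammaMatrix:
    """Validate Γ: symmetric and PSD; an indefinite matrix is projected to
    the nearest PSD matrix (eigenvalue clipping) with a logged warning."""
    V = gamma.matrix
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValidationError("Γ must be symmetric")
    w, U = np.linalg.eigh(V)
    if w.min() >= -tol:
        return gamma
    proj = (U * np.clip(w, 0.0, None)) @ U.T
    proj = 0.5 * (proj + proj.T)
    warnings.warn(
        f"Γ projected to nearest PSD matrix; max adjustment {np.abs(proj - V).max():.3g}"
    )
    df = pd.DataFrame(proj, index=gamma.values.index, columns=gamma.values.columns)
    return GammaMatrix(df, method=gamma.method, gamma0=gamma.gamma0,
                       delta_f_gamma=gamma.delta_f_gamma, representation=gamma.representation)
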