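"""Population-structure characterisation.

Genotype quality control, allele frequencies, Wright's pairwise Fst,
genotype PCA and the PCA-boundary breed assignment used to split a joint
sheep dataset into purebred Merino-like (M), purebred Dohne-like (D) and
crossbred (C) strata.

The Fst estimator for populations b, b' over n loci is

    Fst = mean_i (p_i^b' - p_i^b)^2
          -------------------------------------------
          mean_i [p_i^b'(1 - p_i^b) + p_i^b(1 - p_i^b')]

computed over loci with defined frequencies in both populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .pedigree import Pedigree

MISSING = -1  # missing genotype call


@dataclass
class GenotypeSet:
    """{0,1,2} genotype calls, animals x markers, with MISSING = -1."""

    calls: np.ndarray  # int8, shape (n_animals, n_markers)
    animal_ids: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.animal_ids = np.asarray(self.animal_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        if self.calls.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise DataError(
                f"call matrix shape {self.calls.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.marker_ids)} markers"
            )
        for name, ids in (("animal", self.animal_ids), ("marker", self.marker_ids)):
            if len(np.unique(ids)) != len(ids):
                raise DataError(f"duplicate {name} ids in genotype set")

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset(self, animal_ids=None, marker_ids=None) -> "GenotypeSet":
        calls = self.calls
        aid, mid = self.animal_ids, self.marker_ids
        if animal_ids is not None:
            pos = _positions(aid, animal_ids)
            calls, aid = calls[pos], aid[pos]
        if marker_ids is not None:
            pos = _positions(mid, marker_ids)
            calls, mid = calls[:, pos], mid[pos]
        return GenotypeSet(calls.copy(), aid.copy(), mid.copy())

    # -- PLINK .raw-style text I/O -------------------------------------
    def to_raw(self, path) -> None:
        """Write PLINK .raw-style text (FID IID SNP...; NA for missing)."""
        df = pd.DataFrame(self.calls, columns=self.marker_ids)
        df = df.astype(object).where(self.calls != MISSING, "NA")
        df.insert(0, "IID", self.animal_ids)
        df.insert(0, "FID", self.animal_ids)
        df.to_csv(path, sep=" ", index=False)

    @classmethod
    def from_raw(cls, path) -> "GenotypeSet":
        df = pd.read_csv(path, sep=r"\s+")
        meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
        snp_cols = [c for c in df.columns if c not in meta]
        calls = df[snp_cols].to_numpy(dtype=float)
        calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
        ids = df["IID"].to_numpy() if "IID" in df.columns else np.arange(1, len(df) + 1)
        return cls(calls, ids, np.array(snp_cols))

    @classmethod
    def from_vcf(cls, path) -> "GenotypeSet":
        """Read genotypes from a VCF, converting GT fields to {0,1,2} dosages."""
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        samples = np.array(vcf.samples)
        rows, mids = [], []
        for var in vcf:
            gt = np.asarray(var.gt_types)  # 0=hom ref,1=het,2=hom alt(cyvcf2:3),3=unknown
            dose = np.select([gt == 0, gt == 1, gt == 3, gt == 2], [0, 1, 2, MISSING])
            rows.append(dose.astype(np.int8))
            mids.append(var.ID or f"{var.CHROM}:{var.POS}")
        calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), np.int8)
        return cls(calls, samples, np.array(mids))


def _positions(haystack: np.ndarray, needles) -> np.ndarray:
    index = {v: i for i, v in enumerate(haystack)}
    return np.array([index[v] for v in np.atleast_1d(needles)], dtype=int)


# ----------------------------------------------------------------------
# Quality control
# ----------------------------------------------------------------------
@dataclass
class QCReport:
    removed_animals: list  # (animal_id, reason)
    removed_markers: list  # (marker_id, reason)
    thresholds: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = [("animal", a, r) for a, r in self.removed_animals]
        rows += [("marker", m, r) for m, r in self.removed_markers]
        pd.DataFrame(rows, columns=["kind", "id", "reason"]).to_csv(path, sep="\t", index=False)


def qc_genotypes(
    g: GenotypeSet,
    min_call_rate: float = 0.90,
    max_het: float = 0.50,
    min_maf: float = 0.05,
    pedigree: Pedigree | None = None,
    conflict_rate: float = 0.01,
) -> tuple[GenotypeSet, QCReport]:
    """Filter animals (call rate, then heterozygosity), then markers
    (MAF on the retained animals, then Mendelian-conflict rate when a
    pedigree is supplied)."""
    for name, thr in (("min_call_rate", min_call_rate), ("max_het", max_het),
                      ("min_maf", min_maf), ("conflict_rate", conflict_rate)):
        if not 0.0 <= thr <= 1.0:
            raise ConfigurationError(f"{name}={thr} outside [0, 1]")

    calls = g.calls
    observed = calls != MISSING
    removed_animals: list = []

    call_rate = observed.mean(axis=1) if g.n_markers else np.ones(g.n_animals)
    bad = call_rate < min_call_rate
    removed_animals += [(a, "call_rate") for a in g.animal_ids[bad]]
    keep_a = ~bad

    with np.errstate(invalid="ignore"):
        het = np.where(
            observed.sum(axis=1) > 0,
            (calls == 1).sum(axis=1) / np.maximum(observed.sum(axis=1), 1),
            0.0,
        )
    bad_het = keep_a & (het > max_het)
    removed_animals += [(a, "heterozygosity") for a in g.animal_ids[bad_het]]
    keep_a &= ~bad_het

    sub = calls[keep_a]
    sub_obs = sub != MISSING
    removed_markers: list = []
    n_obs = sub_obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.where(sub_obs, sub, 0).sum(axis=0) / (2 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(p, 1 - p)
    bad_m = np.isnan(maf) | (maf < min_maf)
    removed_markers += [(m, "maf") for m in g.marker_ids[bad_m]]
    keep_m = ~bad_m

    if pedigree is not None:
        rate = mendelian_conflict_rate(
            GenotypeSet(calls[keep_a][:, keep_m], g.animal_ids[keep_a], g.marker_ids[keep_m]),
            pedigree,
        )
        bad_c = rate > conflict_rate
        removed_markers += [(m, "mendelian_conflict") for m in g.marker_ids[keep_m][bad_c]]
        full_bad = np.zeros(g.n_markers, dtype=bool)
        full_bad[np.flatnonzero(keep_m)[bad_c]] = True
        keep_m &= ~full_bad

    if not keep_a.any() or not keep_m.any():
        raise DataError("no data retained after quality control")

    out = GenotypeSet(calls[keep_a][:, keep_m].copy(), g.animal_ids[keep_a], g.marker_ids[keep_m])
    report = QCReport(
        removed_animals,
        removed_markers,
        {"min_call_rate": min_call_rate, "max_het": max_het,
         "min_maf": min_maf, "conflict_rate": conflict_rate},
    )
    return out, report


def mendelian_conflict_rate(g: GenotypeSet, pedigree: Pedigree) -> np.ndarray:
    """Per-marker fraction of checkable parent-offspring pairs with
    opposing homozygotes (0 vs 2)."""
    geno_pos = {int(a): i for i, a in enumerate(g.animal_ids)}
    sire_idx, dam_idx = pedigree.parent_indices()
    ids = pedigree.ids
    pairs = []
    for i in range(pedigree.n):
        ci = geno_pos.get(int(ids[i]))
        if ci is None:
            continue
        for par in (sire_idx[i], dam_idx[i]):
            if par >= 0:
                pi = geno_pos.get(int(ids[par]))
                if pi is not None:
                    pairs.append((ci, pi))
    n_markers = g.n_markers
    if not pairs:
        return np.zeros(n_markers)
    conflicts = np.zeros(n_markers)
    checkable = np.zeros(n_markers)
    for ci, pi in pairs:
        c, p = g.calls[ci], g.calls[pi]
        ok = (c != MISSING) & (p != MISSING)
        checkable += ok
        conflicts += ok & (np.abs(c.astype(int) - p.astype(int)) == 2)
    with np.errstate(invalid="ignore"):
        return np.where(checkable > 0, conflicts / np.maximum(checkable, 1), 0.0)


# ----------------------------------------------------------------------
# Allele frequencies and Fst
# ----------------------------------------------------------------------
def allele_frequencies(g: GenotypeSet, animal_subset=None) -> np.ndarray:
    """Per-marker alternate-allele frequency = mean(calls)/2 over
    non-missing entries; NaN where all calls are missing."""
    calls = g.calls if animal_subset is None else g.calls[_positions(g.animal_ids, animal_subset)]
    if calls.shape[0] == 0:
        raise DataError("empty animal subset for allele frequencies")
    obs = calls != MISSING
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n)
    return np.where(n > 0, p, np.nan)


def fst(p_b: np.ndarray, p_bp: np.ndarray) -> float:
    """Pairwise Wright's Fst from two allele-frequency vectors.

    Loci with a missing (NaN) frequency in either population are excluded
    pairwise; both the numerator and denominator average over the same
    retained-locus set.
    """
    p_b = np.asarray(p_b, dtype=float)
    p_bp = np.asarray(p_bp, dtype=float)
    if p_b.shape != p_bp.shape:
        raise DataError("frequency vectors of unequal length")
    keep = ~(np.isnan(p_b) | np.isnan(p_bp))
    p_b, p_bp = p_b[keep], p_bp[keep]
    if p_b.size == 0:
        raise DataError("no loci with defined frequencies in both populations")
    if ((p_b < 0) | (p_b > 1) | (p_bp < 0) | (p_bp > 1)).any():
        raise DataError("allele frequencies outside [0, 1]")
    num = np.mean((p_bp - p_b) ** 2)
    den = np.mean(p_bp * (1 - p_b) + p_b * (1 - p_bp))
    if den == 0.0:
        raise DataError("Fst undefined: both populations fixed for the same allele at every locus")
    return float(num / den)


def fst_matrix(g: GenotypeSet, population_labels) -> pd.DataFrame:
    """Symmetric pairwise-Fst table over the populations in ``population_labels``
    (one label per animal in ``g``, aligned with ``g.animal_ids``)."""
    labels = np.asarray(population_labels)
    if labels.shape[0] != g.n_animals:
        raise DataError("one population label per genotyped animal required")
    pops = list(pd.unique(labels))
    if len(pops) < 2:
        raise DataError("at least two populations required for an Fst matrix")
    freqs = {}
    for pop in pops:
        members = g.animal_ids[labels == pop]
        if len(members) < 2:
            warnings.warn(f"population {pop!r} has < 2 animals; its pairs are skipped")
            continue
        freqs[pop] = allele_frequencies(g, members)
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            if a in freqs and b in freqs:
                val = fst(freqs[a], freqs[b])
            else:
                val = np.nan
            out.loc[a, b] = out.loc[b, a] = val
    return out


# ----------------------------------------------------------------------
# PCA and breed assignment
# ----------------------------------------------------------------------
@dataclass
class PCAScores:
    coordinates: pd.DataFrame        # index animal id, columns PC1..PCk
    explained_variance_fraction: np.ndarray

    def to_csv(self, path) -> None:
        self.coordinates.rename_axis("id").to_csv(path)


def genotype_pca(g: GenotypeSet, k: int = 2, standardize: bool = False) -> PCAScores:
    """PCA of the column-centered (optionally standardized) call matrix.

    Scores are the projections on the leading right-singular directions of
    the animals x markers matrix; explained fractions are eigenvalue shares.
    """
    if (g.calls == MISSING).any():
        raise DataError("genotype PCA requires complete calls (run QC first)")
    X = g.calls.astype(float)
    X -= X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X /= sd
    rank_cap = min(X.shape)
    if k > rank_cap:
        warnings.warn(f"k={k} exceeds matrix rank bound {rank_cap}; reduced")
        k = rank_cap
    total = float(np.sum(X**2))
    if min(X.shape) <= 600:
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        U, s = U[:, :k], s[:k]
    else:
        from scipy.sparse.linalg import svds

        U, s, _ = svds(X, k=k)
        order = np.argsort(s)[::-1]
        U, s = U[:, order], s[order]
    scores = U * s
    frac = s**2 / total if total > 0 else np.zeros(k)
    coords = pd.DataFrame(scores, index=g.animal_ids, columns=[f"PC{i+1}" for i in range(k)])
    return PCAScores(coords, frac)


def assign_breed(
    scores: PCAScores,
    boundary_a: float = 0.40,
    offset_upper: float = 5.0,
    offset_lower: float = 42.0,
) -> pd.Series:
    """Label animals M / C / D from their (PC1, PC2) coordinates.

    M if PC2 - a*PC1 + offset_upper >= 0, D if PC2 - a*PC1 + offset_lower <= 0,
    C otherwise.  Constants are configurable because PCA axes are sign- and
    scale-indeterminate across datasets.
    """
    if offset_lower <= offset_upper:
        raise ConfigurationError(
            "offset_lower must exceed offset_upper; otherwise both boundary "
            "inequalities can hold simultaneously"
        )
    c = scores.coordinates
    if "PC1" not in c.columns or "PC2" not in c.columns:
        raise DataError("breed assignment needs PC1 and PC2 scores")
    disc = c["PC2"] - boundary_a * c["PC1"]
    labels = np.where(disc + offset_upper >= 0, "M", np.where(disc + offset_lower <= 0, "D", "C"))
    return pd.Series(labels, index=c.index, name="breed")


def fit_assignment_boundaries(
    scores: PCAScores, known_labels: pd.Series, boundary_a: float = 0.40
) -> tuple[float, float]:
    """Fit dataset-specific offsets from labelled purebreds.

    The discriminant d = PC2 - a*PC1 is computed for animals labelled M and
    D; the offsets place the two boundaries at the midpoints between the
    adjacent 1%/99% quantiles of the two groups, so a re-oriented PCA still
    yields a sensible three-way split.
    """
    c = scores.coordinates
    d = c["PC2"] - boundary_a * c["PC1"]
    lab = known_labels.reindex(c.index)
    d_m, d_d = d[lab == "M"], d[lab == "D"]
    if len(d_m) == 0 or len(d_d) == 0:
        raise DataError("need labelled M and D animals to fit boundaries")
    if d_m.mean() < d_d.mean():  # PCA sign flip: M should sit above D
        d_m, d_d = d_d, d_m
    q_m, q_d = d_m.quantile(0.01), d_d.quantile(0.99)
    mid = 0.5 * (q_m + q_d)
    gap = max(q_m - q_d, 0.0)
    # boundaries flank the gap midpoint, leaving the central quarter-gap
    # band as the crossbred region
    upper = -(mid + gap / 4.0)
    lower = -(mid - gap / 4.0)
    lower = max(lower, upper + 1e-9)
    return float(upper), float(lower)


# ----------------------------------------------------------------------
# Pedigree-expected breed fractions
# ----------------------------------------------------------------------
def breed_fractions(
    pedigree: Pedigree,
    founder_population_labels: dict | None = None,
    unknown_label: str = "unknown",
) -> pd.DataFrame:
    """Animal x population expected-ancestry table.

    Founders (both parents unknown) are unit vectors for their labelled
    population; every other row is the parental average, an unknown parent
    contributing the offspring's own population label.  Rows sum to 1.
    """
    sire_idx, dam_idx = pedigree.parent_indices()
    pop = pedigree.df["pop"].astype(str).to_numpy()
    if founder_population_labels:
        pop = pop.copy()
        for aid, lab in founder_population_labels.items():
            pop[pedigree.positions(aid)[0]] = lab
    labels = list(pd.unique(pop))
    if any(p is None or p == "" or (isinstance(p, float) and np.isnan(p)) for p in labels):
        warnings.warn("unlabeled founders assigned to population 'unknown'")
        pop = np.where([(p is None or p == "") for p in pop], unknown_label, pop)
        labels = list(pd.unique(pop))
    col = {lab: j for j, lab in enumerate(labels)}
    Q = np.zeros((pedigree.n, len(labels)))
    for i in range(pedigree.n):
        s, d = sire_idx[i], dam_idx[i]
        if s < 0 and d < 0:
            Q[i, col[pop[i]]] = 1.0
            continue
        for p in (s, d):
            if p >= 0:
                Q[i] += 0.5 * Q[p]
            else:
                Q[i, col[pop[i]]] += 0.5
    return pd.DataFrame(Q, index=pedigree.ids, columns=labels)
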