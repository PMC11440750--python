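"""LR-method validation: scenario construction and metrics.

A 'Partial' evaluation removes the phenotypes of the focal (validation)
animals — genotyped and phenotyped animals born during or after the cutoff
year — and the phenotypes+genotypes of pre-cutoff genotyped animals whose
breed is outside the scenario's reference composition; records of
phenotyped but non-genotyped animals are always retained.  A 'Whole'
evaluation adds the validation phenotypes back.  From the focal animals'
partial and whole (G)EBVs:

    Δ̂p  = mean(û_p) - mean(û_w)                     (bias)
    b_p  = cov(û_w, û_p) / var(û_p)                  (dispersion)
    ρ    = cor(û_w, û_p)                             (accuracy ratio)
    acc  = sqrt( cov(û_p, û_w) / denominator )

with denominator (1 - F̄ + mean diag(QQ') - mean(QQ')) σ²_a for UPG models
(random groups with covariance I σ²_a) and (1 - F̄) σ²_a for metafounder
models, F̄ the average classical pedigree inbreeding of the focal animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .errors import DataError, ValidationError
from .groups import GroupDefinition, GammaMatrix, assign_groups, group_fractions
from .mme import ModelSpec, VarianceComponents, build_mme, build_relationship, solve
from .relmat import pedigree_inbreeding

REFERENCE_COMPOSITIONS = {
    "All": {"M", "C", "D"},
    "M": {"M"},
    "C": {"C"},
    "D": {"D"},
    "M+C": {"M", "C"},
    "C+D": {"C", "D"},
}


@dataclass
class ScenarioDef:
    """Reference composition and cutoff defining one validation scenario."""

    reference: str = "All"           # key of REFERENCE_COMPOSITIONS
    cutoff_year: int = 2021
    validation_breeds: tuple = ("M", "C", "D")

    def __post_init__(self) -> None:
        if self.reference not in REFERENCE_COMPOSITIONS:
            raise ValidationError(
                f"unknown reference composition {self.reference!r}; "
                f"choose from {sorted(REFERENCE_COMPOSITIONS)}"
            )

    @property
    def composition(self) -> set:
        return REFERENCE_COMPOSITIONS[self.reference]


@dataclass
class LRMetrics:
    delta_p: float
    delta_p_ci: tuple
    b_p: float
    b_p_ci: tuple
    rho: float
    acc: float
    n_focal: int
    extras: dict = field(default_factory=dict)


def validation_ids(dataset: Dataset, cutoff_year: int) -> np.ndarray:
    """Genotyped AND phenotyped animals born during or after the cutoff."""
    if dataset.genotypes is None:
        return np.array([], dtype=int)
    ped = dataset.pedigree.df.set_index("id")
    phen_ids = set(int(a) for a in dataset.phenotypes["id"])
    out = [int(a) for a in dataset.genotypes.animal_ids
           if int(a) in phen_ids and ped.loc[int(a), "year"] >= cutoff_year]
    return np.array(out, dtype=int)


def make_scenario_datasets(dataset: Dataset, scenario: ScenarioDef) -> tuple[Dataset, Dataset]:
    """Build the (partial, whole) dataset pair for one scenario."""
    if dataset.breed_labels is None:
        raise DataError("scenario construction needs breed labels for genotyped animals")
    ped_years = dataset.pedigree.df.set_index("id")["year"]
    labels = dataset.breed_labels
    geno_ids = dataset.genotyped_ids
    focal = validation_ids(dataset, scenario.cutoff_year)
    focal_set = set(int(a) for a in focal)

    # pre-cutoff genotyped animals outside the composition: drop phenotypes
    # AND genotypes
    excluded = set(
        int(a) for a in geno_ids
        if ped_years.loc[int(a)] < scenario.cutoff_year
        and labels.loc[a] not in scenario.composition
    )
    keep_geno = np.array([a for a in geno_ids if int(a) not in excluded])
    genotypes = dataset.genotypes.subset(animal_ids=keep_geno) if len(keep_geno) else None

    phen = dataset.phenotypes
    is_focal = phen["id"].astype(int).isin(focal_set)
    is_excluded = phen["id"].astype(int).isin(excluded)
    partial_phen = phen.loc[~is_focal & ~is_excluded].reset_index(drop=True)
    whole_phen = phen.loc[~is_excluded].reset_index(drop=True)
    if len(partial_phen) == 0:
        raise DataError("empty reference after scenario masking")
    reference_ids = [
        int(a) for a in (keep_geno if genotypes is not None else [])
        if int(a) not in focal_set
        and int(a) in set(int(x) for x in phen["id"])
    ]
    partial = dataset.copy_with(phenotypes=partial_phen, genotypes=genotypes)
    whole = dataset.copy_with(phenotypes=whole_phen, genotypes=genotypes)
    partial.__dict__["reference_ids"] = np.array(reference_ids, dtype=int)
    partial.__dict__["focal_ids"] = focal
    whole.__dict__["focal_ids"] = focal
    return partial, whole


# ----------------------------------------------------------------------
# Metrics
# ----------------------------------------------------------------------
def regression_ci(u_p: np.ndarray, u_w: np.ndarray, level: float = 0.95):
    """OLS of û_w on û_p; CIs for the slope and for Δ̂p.

    The construction treats focal EBVs as equally accurate and unrelated,
    which is reasonable for large focal groups with similar information.
    """
    import statsmodels.api as sm
    from scipy import stats

    u_p = np.asarray(u_p, dtype=float)
    u_w = np.asarray(u_w, dtype=float)
    if u_p.size < 3:
        raise DataError("need at least 3 focal animals for confidence intervals")
    if np.var(u_p) == 0:
        raise DataError("degenerate regression: zero variance of partial EBVs")
    res = sm.OLS(u_w, sm.add_constant(u_p)).fit()
    slope = float(res.params[1])
    lo, hi = res.conf_int(alpha=1 - level)[1]
    diff = u_p - u_w
    se = diff.std(ddof=1) / np.sqrt(diff.size)
    t = stats.t.ppf(0.5 + level / 2, diff.size - 1)
    d = float(diff.mean())
    return {"b_p": slope, "b_p_ci": (float(lo), float(hi)),
            "delta_p": d, "delta_p_ci": (d - t * se, d + t * se)}


def lr_metrics(
    u_p: np.ndarray,
    u_w: np.ndarray,
    model_kind: str,
    F_bar: float,
    sigma2_a: float,
    qq_terms: tuple | None = None,
    level: float = 0.95,
) -> LRMetrics:
    """All four LR metrics for one focal group.

    ``model_kind`` picks the accuracy denominator: 'upg' needs
    ``qq_terms = (mean diag(QQ'), mean(QQ'))``; 'mf' uses (1 - F̄) σ²_a.
    σ²_{a,∞} is taken equal to σ²_a.
    """
    u_p = np.asarray(u_p, dtype=float)
    u_w = np.asarray(u_w, dtype=float)
    if u_p.shape != u_w.shape:
        raise DataError("partial and whole EBV vectors must align")
    if sigma2_a <= 0:
        raise ValidationError("genetic variance must be positive")
    if np.var(u_p) == 0:
        raise DataError("b_p undefined: zero variance of partial EBVs")
    cov = float(np.cov(u_p, u_w, ddof=1)[0, 1])
    b_p = cov / float(np.var(u_p, ddof=1))
    rho = float(np.corrcoef(u_p, u_w)[0, 1])
    if model_kind == "upg":
        if qq_terms is None:
            raise ValidationError("UPG accuracy needs (mean diag(QQ'), mean(QQ'))")
        mdiag, mall = qq_terms
        denom = (1.0 - F_bar + mdiag - mall) * sigma2_a
    elif model_kind == "mf":
        denom = (1.0 - F_bar) * sigma2_a
    else:
        raise ValidationError("model_kind must be 'upg' or 'mf'")
    acc = float(np.sqrt(max(cov, 0.0) / denom)) if denom > 0 else np.nan
    ci = regression_ci(u_p, u_w, level)
    return LRMetrics(
        delta_p=float(np.mean(u_p) - np.mean(u_w)), delta_p_ci=ci["delta_p_ci"],
        b_p=b_p, b_p_ci=ci["b_p_ci"], rho=rho, acc=acc, n_focal=u_p.size,
        extras={"cov": cov, "denominator": denom},
    )


def focal_accuracy_terms(
    dataset: Dataset, focal_ids: np.ndarray, groupdef: GroupDefinition
) -> tuple[float, tuple]:
    """F̄ (classical pedigree inbreeding) and the QQ' means over the focal
    rows, for the accuracy denominators."""
    ped = dataset.pedigree
    F = pedigree_inbreeding(ped)
    pos = ped.positions(focal_ids)
    F_bar = float(F[pos].mean())
    Q = group_fractions(ped, assign_groups(ped) if groupdef is None else groupdef)
    Qf = Q.rows(focal_ids)
    QQ = Qf @ Qf.T
    return F_bar, (float(np.mean(np.diag(QQ))), float(np.mean(QQ)))


# ----------------------------------------------------------------------
# Scenario grid
# ----------------------------------------------------------------------
def run_scenario(
    dataset: Dataset,
    scenario: ScenarioDef,
    spec: ModelSpec,
    varcomp: VarianceComponents,
    trait: str,
    groupdef: GroupDefinition | None = None,
    gamma: GammaMatrix | None = None,
    tol: float = 1e-10,
) -> dict:
    """Partial + whole solves for one scenario/model; LR metrics per
    validation breed group (evaluated separately within the joint solve)."""
    if groupdef is None:
        groupdef = assign_groups(dataset.pedigree)
    partial, whole = make_scenario_datasets(dataset, scenario)
    focal = partial.__dict__["focal_ids"]
    if len(focal) == 0:
        warnings.warn("no validation animals; empty metrics")
        return {}
    vc = varcomp.submodel(spec.traits) if spec.traits else varcomp
    # partial and whole share the genotype set, hence the relationship
    relationship = build_relationship(partial, spec, groupdef, gamma)
    sols = {}
    for tag, ds in (("partial", partial), ("whole", whole)):
        system = build_mme(ds, vc, relationship, groupdef)
        sols[tag] = solve(system, tol=tol)
    u_p_all = sols["partial"].ebv(trait)
    u_w_all = sols["whole"].ebv(trait)
    slot = vc.slots.index((trait, "direct"))
    t_idx = vc.traits.index(trait)
    sigma2_a = float(vc.G0[slot, slot])
    labels = dataset.breed_labels
    out = {}
    for breed in scenario.validation_breeds:
        ids = np.array([a for a in focal if labels.loc[a] == breed])
        if len(ids) < 3:
            continue
        F_bar, qq = focal_accuracy_terms(dataset, ids, groupdef)
        out[breed] = lr_metrics(
            u_p_all.loc[ids].to_numpy(), u_w_all.loc[ids].to_numpy(),
            "upg" if spec.grouping == "upg" else "mf",
            F_bar, sigma2_a, qq_terms=qq,
        )
    return out


def run_scenario_grid(
    dataset: Dataset,
    scenarios: list,
    model_variants: list,
    varcomp: VarianceComponents,
    traits: list | None = None,
    groupdef: GroupDefinition | None = None,
    gammas: dict | None = None,
    genetic_sd_scale: bool = False,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Full grid: scenario x model x trait x validation breed.

    Returns a tidy table keyed validation-reference-model with columns
    n_focal, delta_p (+CI), b_p (+CI), rho, acc.  With
    ``genetic_sd_scale`` the bias columns are divided by σ_a.
    """
    if groupdef is None:
        groupdef = assign_groups(dataset.pedigree)
    traits = traits or list(varcomp.traits)
    rows = []
    for scen in scenarios:
        for spec in model_variants:
            gamma = None
            if spec.grouping == "mf" and gammas is not None:
                gamma = gammas.get(spec.gamma_method)
            for trait in traits:
                sub = ModelSpec(spec.grouping, spec.use_genomics, spec.gamma_method,
                                traits=[trait])
                per_breed = run_scenario(
                    dataset, scen, sub, varcomp, trait, groupdef, gamma, tol=tol)
                for breed, m in per_breed.items():
                    scale = np.sqrt(varcomp.G0[varcomp.slots.index((trait, "direct")),
                                               varcomp.slots.index((trait, "direct"))]) \
                        if genetic_sd_scale else 1.0
                    rows.append({
                        "scenario": f"{breed}-{scen.reference}",
                        "reference": scen.reference, "validation_group": breed,
                        "model": sub.name, "trait": trait, "n_focal": m.n_focal,
                        "delta_p": m.delta_p / scale,
                        "delta_p_lo": m.delta_p_ci[0] / scale,
                        "delta_p_hi": m.delta_p_ci[1] / scale,
                        "b_p": m.b_p, "b_p_lo": m.b_p_ci[0], "b_p_hi": m.b_p_ci[1],
                        "rho": m.rho, "acc": m.acc,
                    })
    return pd.DataFrame(rows)
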