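"""Synthetic multi-population sheep data generator.

Emulates the statistical structure the downstream analysis assumes: several
closely related founder populations (pairwise Fst on the 0.002-0.05 scale)
drifted from shared ancestral allele frequencies, directed crossing that
produces an admixed stratum, a fraction of unrecorded dams, birth years
spanning multiple 5-year cohorts, and three moderately-to-highly heritable
traits (h2 = 0.74 / 0.57 / 0.38) with maternal effects on two of them.

True breeding values are sums of marker effects (every simulated marker
acts as a QTL with per-marker effect covariance G0 / (2 Σ p̄(1-p̄))), so
genotypes are informative about genetic merit and gene dropping gives
pedigree-consistent inheritance with cost linear in pedigree size.
Phenotypes are exact sums of the drawn components (contemporary group,
direct TBV, maternal TBV of the biological dam, maternal permanent
environment, sire x flock-year, residual), stored in a truth table.

Selection is OFF by default (random mating) so the LR-method calibration
properties hold; a truncation-selection switch exists for robustness
experiments only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .mme import VarianceComponents
from .pedigree import Pedigree
from .popstruct import GenotypeSet


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------
@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic population."""

    n_populations: int = 7
    population_names: list = field(default_factory=list)
    ancestral_freq_range: tuple = (0.05, 0.95)
    drift_F: list = field(default_factory=list)   # per-population divergence
    n_markers: int = 2000
    years: tuple = (2000, 2019)
    n_flocks_per_pop: int | dict = 2
    n_per_year_per_flock: int | dict = 12
    max_parent_age: int = 5
    crossing_rates: dict = field(default_factory=dict)  # dam_pop -> {sire_pop: rate}
    crossbred_label: str = "C"
    missing_dam_rate: float = 0.10
    immigrant_rate: float = 0.05    # founders entering after the first year
    genotype_rates: dict = field(default_factory=dict)  # pop -> rate
    genotype_from_year: int | None = None
    phenotype_rate: float = 1.0
    varcomp: VarianceComponents = field(default_factory=VarianceComponents.default_wool)
    selection: str = "random"       # 'random' | 'truncation'
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.population_names:
            self.population_names = [f"P{i+1}" for i in range(self.n_populations)]
        if len(self.population_names) != self.n_populations:
            raise ConfigurationError("population_names length must equal n_populations")
        if not self.drift_F:
            # defaults on the observed Fst scale: one outlier line, the rest
            # weakly differentiated
            base = [0.010, 0.075, 0.004, 0.008, 0.002, 0.006, 0.002]
            self.drift_F = [base[i % len(base)] for i in range(self.n_populations)]
        if len(self.drift_F) != self.n_populations:
            raise ConfigurationError("drift_F length must equal n_populations")
        if any(f < 0 for f in self.drift_F):
            raise ConfigurationError("drift parameters must be >= 0")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ConfigurationError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
        if not 0 <= self.missing_dam_rate <= 1:
            raise ConfigurationError("missing_dam_rate must be a probability")
        if not 0 <= self.immigrant_rate <= 1:
            raise ConfigurationError("immigrant_rate must be a probability")
        if self.n_markers < 1:
            raise ConfigurationError("need at least one marker")
        for dam_pop, row in self.crossing_rates.items():
            if dam_pop not in self.population_names:
                raise ConfigurationError(f"unknown population {dam_pop!r} in crossing_rates")
            total = sum(row.values())
            if total > 1 + 1e-12 or any(v < 0 for v in row.values()):
                raise ConfigurationError(
                    f"crossing rates for {dam_pop!r} must be non-negative and sum to <= 1"
                )
        if self.selection not in ("random", "truncation"):
            raise ConfigurationError("selection must be 'random' or 'truncation'")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def flocks_of(self, pop: str) -> int:
        v = self.n_flocks_per_pop
        return int(v.get(pop, v.get("default", 1))) if isinstance(v, dict) else int(v)

    def per_year_of(self, pop: str) -> int:
        v = self.n_per_year_per_flock
        return int(v.get(pop, v.get("default", 10))) if isinstance(v, dict) else int(v)


@dataclass
class SimulatedPopulation:
    """Pedigree + genotypes + truth produced by the generator."""

    pedigree: Pedigree
    genotypes: GenotypeSet                 # calls for every animal
    true_breeding_values: pd.DataFrame     # animal x genetic slot
    population_fractions: pd.DataFrame     # animal x founder population
    phenotypes: pd.DataFrame | None = None  # id, traits..., cg
    truth_components: pd.DataFrame | None = None
    founder_frequencies: pd.DataFrame | None = None
    ancestral_frequencies: np.ndarray | None = None
    true_parents: pd.DataFrame | None = None  # pre-erasure sire/dam ids


# ----------------------------------------------------------------------
# Founder allele frequencies
# ----------------------------------------------------------------------
def simulate_founder_frequencies(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Per-population marker frequencies drifted from shared ancestral ones.

    p_pop ~ Normal(p, F_pop * p(1-p)) clipped to the open unit interval;
    the expected pairwise Fst between populations k and l is about
    (F_k + F_l) / 2 under the cross-heterozygosity estimator.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, size=cfg.n_markers)
    table = {}
    for name, F in zip(cfg.population_names, cfg.drift_F):
        if F == 0:
            table[name] = p.copy()
        else:
            drifted = rng.normal(p, np.sqrt(F * p * (1 - p)))
            table[name] = np.clip(drifted, 1e-3, 1 - 1e-3)
    df = pd.DataFrame(table, index=[f"M{j+1}" for j in range(cfg.n_markers)]).T
    df.attrs["ancestral"] = p
    return df


# ----------------------------------------------------------------------
# Pedigree + genotype simulation
# ----------------------------------------------------------------------
def simulate_pedigree_and_genotypes(
    cfg: SimConfig, founder_freqs: pd.DataFrame | None = None
) -> SimulatedPopulation:
    """Gene-dropping simulation of the multi-flock, multi-year population.

    Founders draw alleles from their population's frequencies; offspring
    inherit one allele per parent per locus.  Crossbred matings follow
    ``crossing_rates``; a ``missing_dam_rate`` fraction of recorded dams is
    erased afterwards (the biological dam still transmits genes and
    maternal effects, as in incompletely recorded field data).
    """
    rng = np.random.default_rng(cfg.seed)
    if founder_freqs is None:
        founder_freqs = simulate_founder_frequencies(cfg, rng)
    pops = cfg.population_names
    freq = {p: founder_freqs.loc[p].to_numpy() for p in pops}
    y0, y1 = cfg.years

    ids: list[int] = []
    sires: list[int] = []
    dams: list[int] = []
    true_sires: list[int] = []
    true_dams: list[int] = []
    years_: list[int] = []
    flocks: list[str] = []
    labels: list[str] = []
    sexes: list[int] = []           # 0 = male, 1 = female
    calls_rows: list[np.ndarray] = []
    frac_rows: list[np.ndarray] = []
    pop_col = {p: j for j, p in enumerate(pops)}
    # registry of live animals per population for parent sampling
    males: dict[str, list[int]] = {p: [] for p in pops}
    females: dict[str, list[int]] = {p: [] for p in pops}
    birth_year: list[int] = []
    next_id = 1

    def new_founder(pop: str, year: int, flock: str) -> int:
        nonlocal next_id
        i = len(ids)
        ids.append(next_id); next_id += 1
        sires.append(0); dams.append(0); true_sires.append(0); true_dams.append(0)
        years_.append(year); flocks.append(flock); labels.append(pop)
        sexes.append(int(rng.integers(2)))
        calls_rows.append(rng.binomial(2, freq[pop]).astype(np.int8))
        v = np.zeros(len(pops)); v[pop_col[pop]] = 1.0
        frac_rows.append(v)
        birth_year.append(year)
        (females[pop] if sexes[i] else males[pop]).append(i)
        return i

    def gamete(parent_row: np.ndarray) -> np.ndarray:
        het = parent_row == 1
        allele = (parent_row == 2).astype(np.int8)
        allele[het] = rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
        return allele

    def eligible(cands: list[int], year: int) -> list[int]:
        return [i for i in cands
                if year - cfg.max_parent_age <= birth_year[i] <= year - 1]

    for year in range(y0, y1 + 1):
        born_this_year: list[tuple] = []
        for pop in pops:
            cross_row = cfg.crossing_rates.get(pop, {})
            for fi in range(cfg.flocks_of(pop)):
                flock = f"{pop}_F{fi+1}"
                for _ in range(cfg.per_year_of(pop)):
                    if year == y0 or rng.random() < cfg.immigrant_rate:
                        new_founder(pop, year, flock)
                        continue
                    u = rng.random()
                    sire_pop, acc = pop, 0.0
                    for sp, rate in cross_row.items():
                        acc += rate
                        if u < acc:
                            sire_pop = sp
                            break
                    cand_d = eligible(females[pop], year)
                    cand_s = eligible(males[sire_pop], year)
                    if not cand_d or not cand_s:
                        new_founder(pop, year, flock)
                        continue
                    if cfg.selection == "truncation" and len(cand_s) > 2:
                        # robustness switch: sires from the top half on
                        # total ancestry-weighted call sum (proxy merit)
                        sums = [calls_rows[i].sum() for i in cand_s]
                        order = np.argsort(sums)[::-1]
                        cand_s = [cand_s[k] for k in order[: max(2, len(cand_s) // 2)]]
                    d = cand_d[int(rng.integers(len(cand_d)))]
                    s = cand_s[int(rng.integers(len(cand_s)))]
                    born_this_year.append((pop, sire_pop, s, d, year, flock))
        for pop, sire_pop, s, d, year_b, flock in born_this_year:
            i = len(ids)
            ids.append(next_id); next_id += 1
            sires.append(ids[s]); true_sires.append(ids[s])
            true_dams.append(ids[d])
            dams.append(0 if rng.random() < cfg.missing_dam_rate else ids[d])
            years_.append(year_b); flocks.append(flock)
            label = pop if sire_pop == pop and labels[s] == pop and labels[d] == pop \
                else cfg.crossbred_label
            labels.append(label)
            sexes.append(int(rng.integers(2)))
            calls_rows.append(gamete(calls_rows[s]) + gamete(calls_rows[d]))
            frac_rows.append(0.5 * (frac_rows[s] + frac_rows[d]))
            birth_year.append(year_b)
            # crossbreds stay in the dam population's breeding pool
            (females[pop] if sexes[i] else males[pop]).append(i)

    ped_df = pd.DataFrame({
        "id": ids, "sire": sires, "dam": dams,
        "year": years_, "flock": flocks, "pop": labels,
    })
    ped = Pedigree(ped_df)
    calls = np.vstack(calls_rows)
    genotypes = GenotypeSet(calls, np.array(ids), founder_freqs.columns.to_numpy())
    fractions = pd.DataFrame(np.vstack(frac_rows), index=ids, columns=pops)
    ancestral = founder_freqs.attrs.get("ancestral")
    tbv = _marker_tbv(cfg, calls, ancestral, rng)
    true_parents = pd.DataFrame({"id": ids, "true_sire": true_sires, "true_dam": true_dams})
    return SimulatedPopulation(
        pedigree=ped, genotypes=genotypes, true_breeding_values=pd.DataFrame(
            tbv, index=ids, columns=[f"{t}_{e}" for t, e in cfg.varcomp.slots]),
        population_fractions=fractions,
        founder_frequencies=founder_freqs, ancestral_frequencies=ancestral,
        true_parents=true_parents,
    )


def _marker_tbv(cfg: SimConfig, calls: np.ndarray, ancestral, rng) -> np.ndarray:
    """Marker-effect breeding values: u = (M - 2 p̄) α with
    α_j ~ N(0, G0 / (2 Σ p̄(1-p̄)))."""
    vc = cfg.varcomp
    k = len(vc.slots)
    p = np.asarray(ancestral) if ancestral is not None else np.full(calls.shape[1], 0.5)
    sbar = float(2.0 * np.sum(p * (1 - p)))
    L = np.linalg.cholesky(vc.G0 + 1e-10 * np.eye(k))
    alpha = rng.standard_normal((calls.shape[1], k)) @ L.T / np.sqrt(sbar)
    Z = calls.astype(float) - 2.0 * p
    return Z @ alpha


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------
def simulate_phenotypes(
    pop: SimulatedPopulation, varcomp: VarianceComponents, seed: int,
    phenotype_rate: float = 1.0,
) -> pd.DataFrame:
    """Draw phenotypes as exact sums of simulated components.

    Trait 1: contemporary group + direct TBV + residual.  Maternal traits
    additionally receive the biological dam's maternal TBV, a maternal
    permanent environmental draw (per dam) and a sire x flock-year draw.
    Animals without a recorded (or biological) parent receive fresh
    base-level draws for the corresponding components.
    """
    for name, M in (("G0", varcomp.G0), ("R0", varcomp.R0)):
        if np.linalg.eigvalsh(M).min() < -1e-8:
            raise ValidationError(f"{name} must be positive semidefinite")
    rng = np.random.default_rng(seed)
    ped = pop.pedigree
    ids = ped.ids
    n = ped.n
    slots = varcomp.slots
    tbv = pop.true_breeding_values
    if list(tbv.columns) != [f"{t}_{e}" for t, e in slots]:
        raise ValidationError("TBV table does not match the variance components")
    true_dam = (pop.true_parents.set_index("id")["true_dam"]
                if pop.true_parents is not None else ped.df.set_index("id")["dam"])
    true_sire = (pop.true_parents.set_index("id")["true_sire"]
                 if pop.true_parents is not None else ped.df.set_index("id")["sire"])

    flock = ped.df["flock"].to_numpy()
    year = ped.df["year"].to_numpy()
    cg_codes = np.array([f"{f}_{y}" for f, y in zip(flock, year)])
    cg_effects = {c: rng.normal(0.0, np.sqrt(varcomp.cg_var)) for c in pd.unique(cg_codes)}

    recorded = rng.random(n) < phenotype_rate
    resid = rng.multivariate_normal(
        np.zeros(len(varcomp.traits)), varcomp.R0, size=n, method="cholesky")

    mpe_draw: dict = {}
    sfy_draw: dict = {}
    phantom_maternal: dict = {}

    rows = []
    comps = []
    for i in range(n):
        if not recorded[i]:
            continue
        aid = int(ids[i])
        rec = {"id": aid, "cg": cg_codes[i]}
        comp = {"id": aid}
        for ti, t in enumerate(varcomp.traits):
            val = cg_effects[cg_codes[i]]
            comp[f"{t}_cg"] = cg_effects[cg_codes[i]]
            direct = tbv.loc[aid, f"{t}_direct"]
            val += direct
            comp[f"{t}_direct"] = direct
            if t in varcomp.maternal_traits:
                dmid = int(true_dam.loc[aid])
                if dmid != 0:
                    mat = tbv.loc[dmid, f"{t}_maternal"]
                else:
                    mslot = slots.index((t, "maternal"))
                    if aid not in phantom_maternal:
                        phantom_maternal[aid] = rng.standard_normal(len(slots))
                    mat = phantom_maternal[aid][mslot] * np.sqrt(varcomp.G0[mslot, mslot])
                mkey = (dmid if dmid != 0 else -aid, t)
                if mkey not in mpe_draw:
                    mpe_draw[mkey] = rng.normal(0.0, np.sqrt(varcomp.M0.get(t, 0.0)))
                val += mat + mpe_draw[mkey]
                comp[f"{t}_maternal"] = mat
                comp[f"{t}_mpe"] = mpe_draw[mkey]
            if t in varcomp.sfy_traits:
                sid = int(true_sire.loc[aid])
                skey = ((sid if sid != 0 else -aid), flock[i], int(year[i]), t)
                if skey not in sfy_draw:
                    sfy_draw[skey] = rng.normal(0.0, np.sqrt(varcomp.S0.get(t, 0.0)))
                val += sfy_draw[skey]
                comp[f"{t}_sfy"] = sfy_draw[skey]
            val += resid[i, ti]
            comp[f"{t}_resid"] = resid[i, ti]
            rec[t] = val
        rows.append(rec)
        comps.append(comp)
    phen = pd.DataFrame(rows, columns=["id"] + varcomp.traits + ["cg"])
    pop.phenotypes = phen
    pop.truth_components = pd.DataFrame(comps)
    return phen


def simulate(cfg: SimConfig) -> SimulatedPopulation:
    """Full generator run: frequencies -> pedigree/genotypes -> phenotypes."""
    freqs = simulate_founder_frequencies(cfg)
    pop = simulate_pedigree_and_genotypes(cfg, freqs)
    simulate_phenotypes(pop, cfg.varcomp, cfg.seed + 1, cfg.phenotype_rate)
    return pop


# ----------------------------------------------------------------------
# Dataset adaptor and fixture bundles
# ----------------------------------------------------------------------
def genotyped_subset(pop: SimulatedPopulation, cfg: SimConfig) -> GenotypeSet:
    """Genotypes released to the evaluation: animals born from
    ``genotype_from_year`` on, sampled at the per-population rate."""
    rng = np.random.default_rng(cfg.seed + 7)
    ped = pop.pedigree.df
    from_year = cfg.genotype_from_year if cfg.genotype_from_year is not None \
        else (cfg.years[0] + cfg.years[1]) // 2
    keep = []
    for i, (aid, yr, lab) in enumerate(zip(ped["id"], ped["year"], ped["pop"])):
        rate = cfg.genotype_rates.get(lab, cfg.genotype_rates.get("default", 0.5))
        if yr >= from_year and rng.random() < rate:
            keep.append(aid)
    return pop.genotypes.subset(animal_ids=np.array(keep, dtype=ped["id"].dtype))


def breed_labels_from_fractions(
    fractions: pd.DataFrame, groups: dict, threshold: float = 0.875,
    crossbred_label: str = "C",
) -> pd.Series:
    """Map true ancestry fractions to breed labels.

    ``groups`` maps label -> list of founder populations (e.g.
    {"M": [...Merino lines...], "D": ["DM"]}); an animal below the purity
    threshold for every label is crossbred.
    """
    out = pd.Series(crossbred_label, index=fractions.index, dtype=object)
    for label, pops in groups.items():
        purity = fractions[pops].sum(axis=1)
        out[purity >= threshold] = label
    return out


def to_dataset(pop: SimulatedPopulation, cfg: SimConfig, breed_groups: dict | None = None):
    """Package a simulation as a Dataset with released genotypes and labels."""
    from .data import Dataset

    geno = genotyped_subset(pop, cfg)
    labels = None
    if breed_groups is not None:
        labels = breed_labels_from_fractions(
            pop.population_fractions, breed_groups, crossbred_label=cfg.crossbred_label
        ).loc[geno.animal_ids]
    return Dataset(pop.pedigree, pop.phenotypes, geno, labels, list(cfg.varcomp.traits))


def write_bundle(pop: SimulatedPopulation, outdir) -> None:
    """Write the fixture bundle: pedigree.csv, genotypes.raw,
    phenotypes.csv, truth.csv."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pop.pedigree.to_csv(out / "pedigree.csv")
    pop.genotypes.to_raw(out / "genotypes.raw")
    if pop.phenotypes is not None:
        pop.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    pop.true_breeding_values.rename_axis("id").to_csv(out / "truth.csv")
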