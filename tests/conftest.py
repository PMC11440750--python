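import numpy as np
import pandas as pd
import pytest

from mfblup import groups, mme, simdata
from mfblup.pedigree import Pedigree


@pytest.fixture(scope="session")
def trio_pedigree():
    return Pedigree(pd.DataFrame({
        "id": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2],
        "year": [2000, 2000, 2001], "flock": "f", "pop": "P",
    }))


@pytest.fixture(scope="session")
def small_sim():
    """Two-population simulation with crossing and missing dams, reused by
    structure/grouping/relationship tests."""
    cfg = simdata.SimConfig(
        n_populations=2, population_names=["M", "D"], drift_F=[0.01, 0.05],
        n_markers=300, years=(2010, 2022), n_flocks_per_pop=2,
        n_per_year_per_flock=8, crossing_rates={"M": {"D": 0.2}},
        missing_dam_rate=0.15, immigrant_rate=0.05,
        genotype_rates={"default": 0.7}, genotype_from_year=2017,
        varcomp=mme.VarianceComponents.single_trait(0.38, "ywt"), seed=11,
    )
    pop = simdata.simulate(cfg)
    return cfg, pop


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    cfg, pop = small_sim
    ds = simdata.to_dataset(pop, cfg, {"M": ["M"], "D": ["D"]})
    gd = groups.assign_groups(ds.pedigree)
    return cfg, pop, ds, gd


@pytest.fixture(scope="session")
def wool_sim():
    """Three-trait population with maternal effects for the full-model tests."""
    cfg = simdata.SimConfig(
        n_populations=2, population_names=["M", "D"], drift_F=[0.01, 0.05],
        n_markers=200, years=(2010, 2022), n_flocks_per_pop=1,
        n_per_year_per_flock=10, crossing_rates={"M": {"D": 0.2}},
        missing_dam_rate=0.1, genotype_rates={"default": 0.6},
        genotype_from_year=2018, seed=5,
    )
    pop = simdata.simulate(cfg)
    ds = simdata.to_dataset(pop, cfg, {"M": ["M"], "D": ["D"]})
    gd = groups.assign_groups(ds.pedigree)
    gamma = groups.check_gamma(
        groups.estimate_gamma_gls(ds.genotypes, groups.group_fractions(ds.pedigree, gd)))
    return cfg, pop, ds, gd, gamma


def brute_force_group_fractions(ped: Pedigree, groupdef) -> np.ndarray:
    """Independent oracle: expand every ancestry path to its terminal
    (unknown-parent) group."""
    sire, dam = ped.parent_indices()
    pop = ped.df["pop"].astype(str).to_numpy()
    years = ped.df["year"].to_numpy()
    n_g = groupdef.n_groups

    def expand(i: int) -> np.ndarray:
        out = np.zeros(n_g)
        for p in (sire[i], dam[i]):
            if p >= 0:
                out += 0.5 * expand(p)
            else:
                out[groupdef.group_of(pop[i], int(years[i]))] += 0.5
        if sire[i] < 0 and dam[i] < 0:
            pass  # handled above: two half-contributions to the same group
        return out

    return np.vstack([expand(i) for i in range(ped.n)])
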