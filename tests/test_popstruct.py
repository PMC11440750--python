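import numpy as np
import pandas as pd
import pytest

from mfblup import popstruct, simdata
from mfblup.errors import ConfigurationError, DataError
from mfblup.pedigree import Pedigree
from mfblup.popstruct import MISSING, GenotypeSet


def make_genos(calls, animal_ids=None, marker_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeSet(
        calls,
        animal_ids if animal_ids is not None else np.arange(1, n + 1),
        marker_ids if marker_ids is not None else np.array([f"M{j}" for j in range(m)]),
    )


# ----------------------------------------------------------------------
# Fst
# ----------------------------------------------------------------------
@pytest.mark.parametrize("p_b, p_bp, expected", [
    ([0.3, 0.6, 0.1], [0.3, 0.6, 0.1], 0.0),            # identical populations
    ([1.0, 1.0], [0.0, 0.0], 1.0),                       # complete fixation
    ([0.2], [0.4], 0.04 / 0.44),                         # hand evaluation
])
def test_fst_hand_values(p_b, p_bp, expected):
    assert popstruct.fst(p_b, p_bp) == pytest.approx(expected, abs=1e-12)


def test_fst_undefined_when_both_fixed_same_allele():
    with pytest.raises(DataError):
        popstruct.fst([0.0, 0.0], [0.0, 0.0])


def test_fst_excludes_nan_loci_pairwise():
    val = popstruct.fst([0.2, np.nan], [0.4, 0.9])
    assert val == pytest.approx(0.04 / 0.44)


def test_allele_frequencies_counting_oracle():
    rng = np.random.default_rng(1)
    calls = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    g = make_genos(calls)
    p = popstruct.allele_frequencies(g)
    for j in range(30):
        col = calls[:, j]
        obs = col[col != MISSING]
        expected = obs.sum() / (2 * len(obs)) if len(obs) else np.nan
        if np.isnan(expected):
            assert np.isnan(p[j])
        else:
            assert p[j] == pytest.approx(expected)


def test_allele_frequencies_simple_cases():
    g = make_genos([[1, 0], [1, 1], [1, 2]])
    p = popstruct.allele_frequencies(g)
    assert p[0] == pytest.approx(0.5)   # all heterozygous
    assert p[1] == pytest.approx(0.5)   # {0,1,2} over three animals


def test_fst_matrix_matches_pairwise_loop(small_dataset):
    _, pop, ds, _ = small_dataset
    labels = pop.pedigree.df.set_index("id").loc[ds.genotypes.animal_ids, "pop"].to_numpy()
    M = popstruct.fst_matrix(ds.genotypes, labels)
    pops = list(M.index)
    for i, a in enumerate(pops):
        assert M.loc[a, a] == 0.0
        for b in pops[i + 1:]:
            pa = popstruct.allele_frequencies(ds.genotypes, ds.genotypes.animal_ids[labels == a])
            pb = popstruct.allele_frequencies(ds.genotypes, ds.genotypes.animal_ids[labels == b])
            assert M.loc[a, b] == pytest.approx(popstruct.fst(pa, pb))
            assert M.loc[a, b] == M.loc[b, a]


def test_fst_monotone_in_drift():
    """Expected pairwise Fst is about (F_k + F_l)/2; more drift, more Fst."""
    wins = 0
    for seed in range(10):
        lo = simdata.SimConfig(n_populations=2, population_names=["A", "B"],
                               drift_F=[0.01, 0.01], n_markers=2000, seed=seed)
        hi = lo.replace(drift_F=[0.05, 0.05])
        f_lo = simdata.simulate_founder_frequencies(lo)
        f_hi = simdata.simulate_founder_frequencies(hi)
        fst_lo = popstruct.fst(f_lo.loc["A"], f_lo.loc["B"])
        fst_hi = popstruct.fst(f_hi.loc["A"], f_hi.loc["B"])
        wins += fst_hi > fst_lo
    assert wins == 10


# ----------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------
def qc_fixture():
    """10 animals x 20 markers, fully typed except animal 3 (call rate
    0.85); marker 7 rare (MAF below 0.05 on the retained animals);
    everything else clean."""
    rng = np.random.default_rng(7)
    calls = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
    # keep every other marker comfortably polymorphic
    calls[:5, :] = np.where(calls[:5, :] == calls[5:, :], (calls[:5, :] + 1) % 3, calls[:5, :])
    calls[:, 7] = 0
    calls[2, 7] = 1  # only copy of the minor allele sits on the dropped animal
    calls[2, :3] = MISSING  # animal id 3: 17/20 = 0.85 call rate
    return make_genos(calls)


def test_qc_exact_removals():
    g = qc_fixture()
    out, report = popstruct.qc_genotypes(g, min_call_rate=0.90, max_het=0.95, min_maf=0.05)
    assert [a for a, _ in report.removed_animals] == [3]
    assert report.removed_animals[0][1] == "call_rate"
    assert [m for m, _ in report.removed_markers] == ["M7"]
    assert 3 not in out.animal_ids and "M7" not in out.marker_ids


def test_qc_idempotent():
    g = qc_fixture()
    once, _ = popstruct.qc_genotypes(g, max_het=0.95)
    twice, rep2 = popstruct.qc_genotypes(once, max_het=0.95)
    assert not rep2.removed_animals and not rep2.removed_markers
    assert np.array_equal(once.calls, twice.calls)


def test_qc_heterozygosity_removal():
    calls = np.array([[1] * 20, [0, 2] * 10, [2, 0] * 10], dtype=np.int8)
    g = make_genos(calls)
    _, report = popstruct.qc_genotypes(g, max_het=0.50, min_maf=0.0)
    assert (1, "heterozygosity") in report.removed_animals


def test_qc_mendelian_conflict_marker_removed():
    ped = Pedigree(pd.DataFrame({
        "id": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2],
        "year": [0, 0, 1], "flock": "f", "pop": "P"}))
    calls = np.array([
        [2, 1, 1, 0],   # sire
        [0, 1, 1, 2],   # dam
        [0, 1, 1, 1],   # offspring: conflicts with sire at marker 0
    ], dtype=np.int8)
    g = make_genos(calls)
    rate = popstruct.mendelian_conflict_rate(g, ped)
    assert rate[0] == pytest.approx(0.5)  # 1 conflicted of 2 checkable pairs
    _, report = popstruct.qc_genotypes(g, min_maf=0.0, max_het=1.0, pedigree=ped,
                                       conflict_rate=0.01)
    assert ("M0", "mendelian_conflict") in report.removed_markers


def test_qc_nothing_removed_on_clean_data():
    rng = np.random.default_rng(3)
    calls = rng.integers(0, 3, size=(20, 15)).astype(np.int8)
    calls[0, :] = 1  # guard against monomorphic columns
    calls[1, :] = 0
    calls[2, :] = 2
    g = make_genos(calls)
    out, report = popstruct.qc_genotypes(g, max_het=1.0)
    assert not report.removed_animals and not report.removed_markers
    assert out.calls.shape == g.calls.shape


def test_qc_empty_result_raises():
    g = make_genos(np.full((3, 4), MISSING, dtype=np.int8))
    with pytest.raises(DataError):
        popstruct.qc_genotypes(g)


# ----------------------------------------------------------------------
# PCA and breed assignment
# ----------------------------------------------------------------------
def test_pca_matches_dense_svd_oracle():
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 3, size=(50, 80)).astype(np.int8)
    g = make_genos(calls)
    scores = popstruct.genotype_pca(g, k=3)
    X = calls.astype(float) - calls.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    for j in range(3):
        got = scores.coordinates.iloc[:, j].to_numpy()
        want = U[:, j] * s[j]
        sign = np.sign(got @ want) or 1.0
        assert np.allclose(got, sign * want, atol=1e-8)
    assert np.all(np.diff(scores.explained_variance_fraction) <= 1e-12)
    assert scores.explained_variance_fraction.sum() <= 1 + 1e-9


def test_pca_separates_divergent_populations():
    cfg = simdata.SimConfig(n_populations=2, population_names=["A", "B"],
                            drift_F=[0.3, 0.3], n_markers=500, seed=2)
    freqs = simdata.simulate_founder_frequencies(cfg)
    rng = np.random.default_rng(0)
    calls = np.vstack([
        rng.binomial(2, freqs.loc["A"], size=(40, 500)),
        rng.binomial(2, freqs.loc["B"], size=(40, 500)),
    ]).astype(np.int8)
    scores = popstruct.genotype_pca(make_genos(calls), k=4)
    pc1 = scores.coordinates["PC1"].to_numpy()
    assert (pc1[:40].mean() > 0) != (pc1[40:].mean() > 0)
    gap = abs(pc1[:40].mean() - pc1[40:].mean())
    assert gap > 3 * (pc1[:40].std() + pc1[40:].std()) / 2
    assert scores.explained_variance_fraction[0] > scores.explained_variance_fraction[1:].max()


def test_pca_duplicated_animals_and_marker_permutation():
    rng = np.random.default_rng(9)
    calls = rng.integers(0, 3, size=(20, 40)).astype(np.int8)
    dup = np.vstack([calls, calls[:1]])
    g = make_genos(dup, animal_ids=np.arange(1, 22))
    scores = popstruct.genotype_pca(g, k=2)
    assert np.allclose(scores.coordinates.iloc[0], scores.coordinates.iloc[20], atol=1e-9)
    perm = rng.permutation(40)
    g2 = make_genos(calls[:, perm], marker_ids=np.array([f"M{j}" for j in perm]))
    s1 = popstruct.genotype_pca(make_genos(calls), k=2).coordinates.to_numpy()
    s2 = popstruct.genotype_pca(g2, k=2).coordinates.to_numpy()
    for j in range(2):
        sign = np.sign(s1[:, j] @ s2[:, j]) or 1.0
        assert np.allclose(s1[:, j], sign * s2[:, j], atol=1e-8)


@pytest.mark.parametrize("pc1, pc2, label", [
    (0.0, 0.0, "M"),      # 0 - 0 + 5 >= 0
    (0.0, -50.0, "D"),    # -50 + 42 <= 0
    (0.0, -20.0, "C"),    # fails both boundaries
])
def test_assign_breed_boundary_evaluation(pc1, pc2, label):
    scores = popstruct.PCAScores(
        pd.DataFrame({"PC1": [pc1], "PC2": [pc2]}, index=[1]), np.array([0.6, 0.4]))
    assert popstruct.assign_breed(scores).loc[1] == label


def test_assign_breed_misconfigured_offsets():
    scores = popstruct.PCAScores(
        pd.DataFrame({"PC1": [0.0], "PC2": [0.0]}, index=[1]), np.array([1.0]))
    with pytest.raises(ConfigurationError):
        popstruct.assign_breed(scores, offset_upper=42, offset_lower=5)


def test_fit_assignment_boundaries_recovers_split():
    rng = np.random.default_rng(4)
    pc2 = np.r_[rng.normal(30, 3, 50), rng.normal(-30, 3, 50)]
    coords = pd.DataFrame({"PC1": np.zeros(100), "PC2": pc2}, index=np.arange(100))
    scores = popstruct.PCAScores(coords, np.array([0.5, 0.3]))
    labels = pd.Series(["M"] * 50 + ["D"] * 50, index=coords.index)
    up, low = popstruct.fit_assignment_boundaries(scores, labels)
    assigned = popstruct.assign_breed(scores, offset_upper=up, offset_lower=low)
    assert (assigned[:50] == "M").all() and (assigned[50:] == "D").all()


# ----------------------------------------------------------------------
# Breed fractions
# ----------------------------------------------------------------------
def test_breed_fractions_purebred_and_f1():
    ped = Pedigree(pd.DataFrame({
        "id": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2],
        "year": [0, 0, 1], "flock": "f", "pop": ["A", "B", "C"]}))
    Q = popstruct.breed_fractions(ped)
    assert Q.loc[1, "A"] == 1.0 and Q.loc[2, "B"] == 1.0
    assert Q.loc[3, "A"] == 0.5 and Q.loc[3, "B"] == 0.5


def test_breed_fractions_deep_pedigree_oracle(small_sim):
    _, pop = small_sim
    ped = pop.pedigree
    sub = Pedigree(ped.df.iloc[:50].reset_index(drop=True))
    Q = popstruct.breed_fractions(sub)
    sire, dam = sub.parent_indices()
    pops = sub.df["pop"].astype(str).to_numpy()

    def expand(i):
        out = {}
        if sire[i] < 0 and dam[i] < 0:
            return {pops[i]: 1.0}
        for p in (sire[i], dam[i]):
            contrib = expand(p) if p >= 0 else {pops[i]: 1.0}
            for k, v in contrib.items():
                out[k] = out.get(k, 0.0) + 0.5 * v
        return out

    for i in range(50):
        want = expand(i)
        for lab in Q.columns:
            assert Q.iloc[i][lab] == pytest.approx(want.get(lab, 0.0), abs=1e-12)
    assert np.allclose(Q.sum(axis=1), 1.0)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def test_raw_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(6, 10)).astype(np.int8)
    calls[0, 0] = MISSING
    g = make_genos(calls)
    path = tmp_path / "g.raw"
    g.to_raw(path)
    back = GenotypeSet.from_raw(path)
    assert np.array_equal(back.calls, g.calls)
    assert list(back.animal_ids) == list(g.animal_ids)


def test_vcf_reader(tmp_path):
    cyvcf2 = pytest.importorskip("cyvcf2")  # optional dependency
    vcf = tmp_path / "tiny.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t10\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t20\trs2\tC\tT\t.\t.\t.\tGT\t1/1\t./.\t0/0\n"
    )
    g = GenotypeSet.from_vcf(vcf)
    assert list(g.animal_ids) == ["S1", "S2", "S3"]
    assert np.array_equal(g.calls, np.array([[0, 2], [1, MISSING], [2, 0]], dtype=np.int8))
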