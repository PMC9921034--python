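"""Diversity, F-statistics, kinship and distance estimators against
hand arithmetic, scalar-transcription oracles and generator truth."""

import numpy as np
import pandas as pd
import pytest

import progarray as pa
from progarray.popgen_stats import PopgenError, mean_offdiag, weir_cockerham_fst


def _pop(dos, ids=None):
    dos = np.asarray(dos, dtype=float)
    ids = ids or [f"s{i}" for i in range(dos.shape[0])]
    return pa.GenotypeMatrix.from_arrays(dos, ids, [f"L{j}" for j in range(dos.shape[1])])


class TestHeterozygosity:
    def test_all_heterozygous(self):
        m = _pop(np.ones((6, 4)))
        res = pa.heterozygosity(m, {"p": m.sample_ids})
        assert res.per_population.loc["p", "Ho"] == 1.0

    def test_monomorphic_contributes_zero(self):
        m = _pop(np.zeros((5, 3)))
        res = pa.heterozygosity(m, {"p": m.sample_ids})
        assert res.per_population.loc["p", "Ho"] == 0.0
        assert res.per_population.loc["p", "He"] == 0.0

    def test_small_sample_correction(self):
        # n=5, p_hat=0.5 at one locus: He = 0.5 * 10/9
        dos = np.array([[0.0], [0.0], [1.0], [1.0], [2.0]])
        dos = np.array([[0.0], [1.0], [1.0], [1.0], [2.0]])  # alt count 5/10 = 0.5
        m = _pop(dos)
        res = pa.heterozygosity(m, {"p": m.sample_ids})
        assert res.per_population.loc["p", "He"] == pytest.approx(0.5 * 10 / 9)
        res0 = pa.heterozygosity(m, {"p": m.sample_ids}, bias_correction=False)
        assert res0.per_population.loc["p", "He"] == pytest.approx(0.5)

    def test_empty_population_rejected(self):
        m = _pop(np.zeros((2, 2)))
        with pytest.raises(PopgenError):
            pa.heterozygosity(m, {"p": []})


class TestFis:
    def test_zero_when_ho_equals_he(self):
        rng = np.random.default_rng(4)
        dos = rng.choice([0.0, 1.0, 2.0], size=(200, 500), p=[0.25, 0.5, 0.25])
        m = _pop(dos)
        est = pa.fis(m, {"p": m.sample_ids}).per_population["Fis"].iloc[0]
        assert abs(est) < 0.02

    def test_maximal_heterozygote_excess(self):
        m = _pop(np.ones((100, 50)))
        est = pa.fis(m, {"p": m.sample_ids}).per_population["Fis"].iloc[0]
        assert est == pytest.approx(-1.0, abs=0.02)

    def test_sign_matches_he_minus_ho(self, small_landscape):
        adults, _, pops = small_landscape
        res = pa.fis(adults, pops)
        for _, row in res.per_population.iterrows():
            assert np.sign(row["Fis"]) == np.sign(row["He"] - row["Ho"]) or row["Fis"] == 0

    def test_monomorphic_reported_missing_with_warning(self):
        m = _pop(np.zeros((4, 3)))
        res = pa.fis(m, {"p": m.sample_ids})
        assert np.isnan(res.per_population["Fis"].iloc[0])
        assert res.provenance["warnings"]


def _wc_oracle_two_pops(dos_a, dos_b):
    """Literal scalar transcription of the 1984 theta (ratio of sums)."""
    num = den = 0.0
    r = 2
    for l in range(dos_a.shape[1]):
        cols = []
        for block in (dos_a, dos_b):
            col = block[:, l]
            col = col[~np.isnan(col)]
            cols.append(col)
        n = [len(c) for c in cols]
        if min(n) == 0:
            continue
        p = [c.sum() / (2 * len(c)) for c in cols]
        h = [(c == 1).mean() for c in cols]
        nbar = (n[0] + n[1]) / 2
        if nbar <= 1:
            continue
        nc = (sum(n) - (n[0] ** 2 + n[1] ** 2) / sum(n)) / (r - 1)
        pbar = (n[0] * p[0] + n[1] * p[1]) / sum(n)
        if pbar in (0.0, 1.0):
            continue
        s2 = (n[0] * (p[0] - pbar) ** 2 + n[1] * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n[0] * h[0] + n[1] * h[1]) / sum(n)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestFst:
    def test_fixed_opposite_alleles(self):
        a = np.zeros((5, 20))
        b = np.full((5, 20), 2.0)
        assert weir_cockerham_fst([a, b]) == pytest.approx(1.0)

    def test_null_panmixia(self):
        rng = np.random.default_rng(8)
        q = rng.uniform(0.1, 0.5, 10_000)
        geno = lambda n: rng.binomial(2, q, (n, q.size)).astype(float)
        est = weir_cockerham_fst([geno(15), geno(15)])
        assert abs(est) < 0.02

    def test_matches_scalar_oracle_with_missing_data(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 3, (8, 60)).astype(float)
        b = rng.integers(0, 3, (12, 60)).astype(float)
        a[rng.random(a.shape) < 0.1] = np.nan
        b[rng.random(b.shape) < 0.1] = np.nan
        assert weir_cockerham_fst([a, b]) == pytest.approx(
            _wc_oracle_two_pops(a, b), abs=1e-12
        )

    def test_symmetry_and_population_of_one_rejected(self, small_landscape):
        adults, _, pops = small_landscape
        res = pa.pairwise_fst(adults, pops)
        df = res.per_pair
        assert weir_cockerham_fst(
            [adults.dosages(pops["P02"]), adults.dosages(pops["P01"])]
        ) == pytest.approx(df.iloc[0]["fst"])
        with pytest.raises(PopgenError):
            pa.pairwise_fst(adults, {"a": pops["P01"], "b": pops["P02"][:1]})

    def test_ordered_by_divergence_target(self):
        ests = []
        for t in (0.3, 0.7):
            cfg = pa.LandscapeConfig(n_populations=2, n_loci=3000, fst_target=t,
                                     n_adults_per_pop=20, seed=31)
            m, _, pops = pa.generate_landscape(cfg)
            ests.append(pa.pairwise_fst(m, pops).per_pair["fst"].iloc[0])
        assert ests[0] < ests[1]


class TestIsolationByDistance:
    def _div(self, fsts, coords):
        pairs = []
        names = list(coords)
        k = 0
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                pairs.append({"pop_a": a, "pop_b": b, "fst": fsts[k],
                              "distance_km": pa.haversine_km(coords[a], coords[b])})
                k += 1
        return pa.DiversityResult(per_pair=pd.DataFrame(pairs))

    def test_constant_fst_zero_slope(self):
        coords = {"a": (150, -33), "b": (151, -33), "c": (153, -35)}
        res = pa.isolation_by_distance(self._div([0.2, 0.2, 0.2], coords))
        assert res["slope_per_km"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_geometry_rejected(self):
        coords = {"a": (150, -33), "b": (150, -33), "c": (150, -33)}
        with pytest.raises(PopgenError):
            pa.isolation_by_distance(self._div([0.1, 0.2, 0.3], coords))

    def test_stepping_stone_positive_slope(self):
        # build divergence increasing in chain distance from simulated drift
        coords = {f"p{i}": (150.0 + 0.5 * i, -33.0) for i in range(5)}
        rng = np.random.default_rng(12)
        anc = rng.uniform(0.2, 0.8, 2000)
        pops, freqs = {}, {}
        drift = 0.04
        q = anc
        blocks = {}
        for i in range(5):
            q = np.clip(q + rng.normal(0, np.sqrt(drift * q * (1 - q))), 0.01, 0.99)
            blocks[f"p{i}"] = rng.binomial(2, q, (15, q.size)).astype(float)
        pairs = []
        names = list(coords)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                pairs.append({"pop_a": a, "pop_b": b,
                              "fst": weir_cockerham_fst([blocks[a], blocks[b]]),
                              "distance_km": pa.haversine_km(coords[a], coords[b])})
        res = pa.isolation_by_distance(pa.DiversityResult(per_pair=pd.DataFrame(pairs)))
        assert res["slope_per_km"] > 0
        assert res["spearman_rho"] > 0.5


def _pedigree_ibd_oracle(rng, n_pairs, selfed, L=5000):
    """Brute-force kinship by tracking labelled allele copies.

    Mother alleles carry unique labels; pollen alleles carry fresh labels.
    The realized kinship of a pair is the probability a random allele from
    each is identical by descent (same label), averaged over loci.
    """
    vals = []
    for _ in range(n_pairs):
        ibd = 0.0
        for l in range(L):
            mom = (2 * l, 2 * l + 1)
            g1 = mom[rng.integers(0, 2)]
            g2 = mom[rng.integers(0, 2)] if selfed else -1 - l  # fresh pollen label
            child = (g1, g2)
            # P(IBD) over the 4 allele draws
            ibd += np.mean([a == b for a in mom for b in child])
        vals.append(ibd / L)
    return float(np.mean(vals))


@pytest.fixture(scope="module")
def sim():
    cfg = pa.LandscapeConfig(n_populations=1, n_loci=4000, fst_target=0.0,
                             inbreeding_f=0.0, n_adults_per_pop=30, seed=17)
    return pa.generate_landscape(cfg)


class TestKinship:

    def test_self_kinship_half(self, sim):
        adults, freqs, _ = sim
        res = pa.kinship_mom(adults, freqs, [("P01_A001", "P01_A001")], "P01")
        assert res.per_pair["kinship"].iloc[0] == pytest.approx(0.5, abs=0.03)

    def test_mother_outcrossed_progeny_quarter(self, sim):
        adults, freqs, _ = sim
        m, fam, _ = pa.generate_families(
            adults, pa.FamilyDesign(), 0.0, freqs,
            pa.NoiseModel(error_rate_epsilon=0.0, locus_missing_rate=0.0),
            seed=18, site="P01",
        )
        pairs = list(zip(fam.entries["mother_id"], fam.entries["progeny_id"]))
        res = pa.kinship_mom(m, freqs, pairs, "P01")
        assert res.per_pair["kinship"].mean() == pytest.approx(0.25, abs=0.02)

    def test_mother_selfed_progeny_vs_pedigree_oracle(self, sim):
        adults, freqs, _ = sim
        m, fam, _ = pa.generate_families(
            adults, pa.FamilyDesign(), 1.0, freqs,
            pa.NoiseModel(error_rate_epsilon=0.0, locus_missing_rate=0.0),
            seed=19, site="P01",
        )
        pairs = list(zip(fam.entries["mother_id"], fam.entries["progeny_id"]))
        est = pa.kinship_mom(m, freqs, pairs, "P01").per_pair["kinship"].mean()
        oracle = _pedigree_ibd_oracle(np.random.default_rng(0), 40, selfed=True)
        # phi(mother, selfed offspring) = phi(mother, mother) = (1+F)/2 = 0.5
        assert oracle == pytest.approx(0.5, abs=0.01)
        assert est == pytest.approx(oracle, abs=0.02)

    def test_unrelated_pairs_near_zero(self, sim):
        adults, freqs, _ = sim
        ids = adults.sample_ids
        pairs = [(ids[i], ids[i + 15]) for i in range(15)]
        res = pa.kinship_mom(adults, freqs, pairs, "P01")
        assert abs(res.per_pair["kinship"].mean()) < 0.01


class TestDistances:
    def test_identical_vectors(self):
        m = _pop(np.tile([0.0, 1.0, 2.0], (2, 1)))
        d = pa.euclidean_distances(m)
        assert d.iloc[0, 1] == 0.0

    def test_closed_form_extremes(self):
        L = 9
        m = _pop(np.vstack([np.zeros(L), np.full(L, 2.0)]))
        d = pa.euclidean_distances(m)
        assert d.iloc[0, 1] == pytest.approx(2 * np.sqrt(L))

    def test_masked_locus_rescaling(self):
        dos = np.array([[0.0, 2.0, 1.0], [2.0, np.nan, 0.0]])
        m = _pop(dos)
        d = pa.euclidean_distances(m)
        # shared loci: (0-2)^2 + (1-0)^2 = 5, rescaled by L/|C| = 3/2
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(3 / 2 * 5))

    def test_no_shared_loci_rejected(self):
        dos = np.array([[0.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(PopgenError):
            pa.euclidean_distances(_pop(dos))

    def test_mean_offdiag(self):
        df = pd.DataFrame([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        assert mean_offdiag(df) == pytest.approx(2.0)


class TestIsogenicLines:
    def test_all_identical_one_group(self):
        m = _pop(np.tile([0.0, 1.0, 2.0, 0.0], (5, 1)))
        assert len(pa.isogenic_lines(m)) == 1

    def test_all_distinct(self):
        rng = np.random.default_rng(22)
        m = _pop(rng.integers(0, 3, (6, 300)).astype(float))
        assert len(pa.isogenic_lines(m)) == 6

    def test_recovers_planted_clonal_families(self):
        rng = np.random.default_rng(23)
        founders = rng.integers(0, 3, (4, 2000)).astype(float)
        rows = []
        for f in founders:
            for _ in range(5):
                g = f.copy()
                flip = rng.random(g.size) < 0.002
                g[flip] = rng.integers(0, 3, flip.sum())
                rows.append(g)
        m = _pop(np.array(rows))
        groups = pa.isogenic_lines(m, identity_threshold=0.99)
        assert len(groups) == 4
        assert sorted(len(g) for g in groups) == [5, 5, 5, 5]
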