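"""Selfing estimators against enumeration oracles, trivial solves and
simulation truth."""

import itertools

import numpy as np
import pandas as pd
import pytest

import progarray as pa
from progarray.mating_system import (
    CnnSpec,
    MatingSimConfig,
    _flip_matrix,
    _true_genotype_probs,
    predict_cnn_batch,
    recovery_experiment,
    train_cnn,
)


def _enumerate_terms(gm: int, q: float, eps: float) -> tuple[float, float]:
    """Exhaustive (d, e) oracle: sum P(observed call) over the 3x3 grid of
    true progeny genotype x observed call under the per-allele flip model,
    restricted to observed calls incompatible with the homozygous mother."""
    flip = _flip_matrix(eps)
    if gm == 0:
        incompatible = lambda obs: obs >= 1       # carries the alt allele
    elif gm == 2:
        incompatible = lambda obs: obs <= 1       # carries the ref allele
    else:
        return 0.0, 0.0

    def prob_incompatible(true_probs):
        total = 0.0
        for true_g, obs in itertools.product(range(3), range(3)):
            if incompatible(obs):
                total += true_probs[true_g] * flip[true_g, obs]
        return total

    m_arr = np.array([float(gm)])
    q_arr = np.array([q])
    d = prob_incompatible(_true_genotype_probs(m_arr, q_arr, selfed=False)[0])
    e = prob_incompatible(_true_genotype_probs(m_arr, q_arr, selfed=True)[0])
    return d, e


class TestLocusTerms:
    def test_error_free_definitions(self):
        X, d, e, inf = pa.locus_selfing_terms(
            np.array([0.0]), np.array([0.0]), np.array([0.4]), 0.0
        )
        assert (X[0], d[0], e[0]) == (0.0, pytest.approx(0.4), 0.0)
        assert inf[0]

    def test_het_mother_uninformative(self):
        for prog in (0.0, 1.0, 2.0):
            X, d, e, inf = pa.locus_selfing_terms(
                np.array([1.0]), np.array([prog]), np.array([0.3]), 0.01
            )
            assert (X[0], d[0], e[0]) == (0.0, 0.0, 0.0)
            assert not inf[0]

    @pytest.mark.parametrize("eps", [0.0, 0.01, 0.05])
    @pytest.mark.parametrize("gm", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, gm, eps):
        for q in (0.1, 0.3, 0.5, 0.9):
            d_oracle, e_oracle = _enumerate_terms(gm, q, eps)
            for go in (0.0, 1.0, 2.0):
                X, d, e, _ = pa.locus_selfing_terms(
                    np.array([float(gm)]), np.array([go]), np.array([q]), eps
                )
                assert d[0] == pytest.approx(d_oracle, abs=1e-12)
                assert e[0] == pytest.approx(e_oracle, abs=1e-12)
                if gm == 0:
                    assert X[0] == float(go >= 1)
                elif gm == 2:
                    assert X[0] == float(go <= 1)

    def test_missing_calls_skipped(self):
        X, d, e, inf = pa.locus_selfing_terms(
            np.array([0.0, np.nan]), np.array([np.nan, 1.0]),
            np.array([0.3, 0.3]), 0.01
        )
        assert not inf.any()


class TestMme:
    def _estimate(self, X, d, e):
        """Direct linear solve used to cross-check trivial cases."""
        return (d.sum() - X.sum()) / (d.sum() - e.sum())

    def test_zero_outcross_signal_gives_one(self):
        mother = np.zeros(60)
        progeny = np.zeros(60)
        q = np.full(60, 0.5)   # D = 30, T = 0, E = 0
        est = pa.mme_selfing(mother, progeny, q, 0.0)
        assert est.s_hat == 1.0
        assert est.n_informative_loci == 60

    def test_linear_solve_half(self):
        mother = np.zeros(120)
        progeny = np.zeros(120)
        progeny[:30] = 1.0     # T = 30, D = 120 * 0.5 = 60, E = 0
        q = np.full(120, 0.5)
        est = pa.mme_selfing(mother, progeny, q, 0.0)
        assert est.s_hat == pytest.approx(0.5)
        assert est.uncertainty > 0

    def test_uninformative_flag_not_crash(self):
        mother = np.ones(10)   # all heterozygous
        est = pa.mme_selfing(mother, np.ones(10), np.full(10, 0.5), 0.01)
        assert est.status == "uninformative"
        assert np.isnan(est.s_hat)

    def test_grid_recovery_small(self):
        df = recovery_experiment([0.0, 0.5, 1.0], 60, 2000, 0.005, seed=101)
        means = df.groupby("s_true")["MME"].mean()
        for s, m in means.items():
            assert abs(m - s) <= 0.06
        # monotone response of the mean estimate to true s
        assert means.loc[0.0] < means.loc[0.5] < means.loc[1.0]


class TestMlOracle:
    def test_zero_signal_gives_one(self):
        mother = np.zeros(60)
        progeny = np.zeros(60)
        q = np.full(60, 0.5)
        est = pa.ml_selfing_oracle(mother, progeny, q, 0.0)
        assert est.s_hat == pytest.approx(1.0, abs=1e-6)

    def test_flat_likelihood_flagged(self):
        est = pa.ml_selfing_oracle(
            np.array([1.0]), np.array([1.0]), np.array([0.5]), 0.0
        )
        assert est.status == "uninformative"

    def test_impossible_data_flagged(self):
        # mother hom-ref, progeny hom-alt, no error: impossible under both modes
        est = pa.ml_selfing_oracle(
            np.array([0.0]), np.array([2.0]), np.array([0.5]), 0.0
        )
        assert est.status == "impossible"

    def test_concordance_with_mme(self):
        df = recovery_experiment(
            [0.0, 0.5, 1.0], 25, 2000, 0.005, seed=102, methods=("MME", "ML")
        )
        ok = df[["MME", "ML"]].dropna()
        assert (ok["MME"] - ok["ML"]).abs().mean() <= 0.05


class TestHeterozygosityLaws:
    def test_selfing_halves_ho_and_raises_kinship(self, sim_mating):
        adults, freqs, _ = sim_mating
        noise = pa.NoiseModel(error_rate_epsilon=0.0, locus_missing_rate=0.0)
        m1, fam1, _ = pa.generate_families(adults, pa.FamilyDesign(), 1.0, freqs,
                                           noise, seed=55, site="P01")
        m0, fam0, _ = pa.generate_families(adults, pa.FamilyDesign(), 0.0, freqs,
                                           noise, seed=56, site="P01")
        ho = lambda m, ids: float(np.nanmean(m.dosages(list(ids)) == 1.0))
        mothers = fam1.entries["mother_id"].unique()
        ho_m = ho(m1, mothers)
        ho_selfed = ho(m1, fam1.entries["progeny_id"])
        assert ho_selfed == pytest.approx(ho_m / 2, rel=0.02)
        kin = lambda m, fam: pa.kinship_mom(
            m, freqs, list(zip(fam.entries["mother_id"], fam.entries["progeny_id"])),
            "P01",
        ).per_pair["kinship"].mean()
        assert kin(m1, fam1) > kin(m0, fam0)


@pytest.fixture(scope="module")
def tiny_ensemble(sim_mating):
    adults, freqs, _ = sim_mating
    return train_cnn(
        adults, freqs, "P01",
        MatingSimConfig(n_examples=700, epsilon=0.005, seed=60),
        CnnSpec(input_length=400, ensemble_size=2, epochs=15),
    ), adults, freqs


class TestCnn:

    def test_deterministic_given_seed(self, sim_mating):
        adults, freqs, _ = sim_mating
        kw = dict(
            sim=MatingSimConfig(n_examples=120, epsilon=0.005, seed=61),
            spec=CnnSpec(input_length=300, ensemble_size=1, epochs=2),
        )
        e1 = train_cnn(adults, freqs, "P01", **kw)
        e2 = train_cnn(adults, freqs, "P01", **kw)
        rng = np.random.default_rng(0)
        x = rng.random((3, 300, 4)).astype(np.float32)
        assert np.array_equal(e1.members[0].predict(x), e2.members[0].predict(x))

    def test_separates_selfed_from_outcrossed(self, tiny_ensemble):
        ens, adults, freqs = tiny_ensemble
        df = recovery_experiment(
            [0.0, 1.0], 25, 800, 0.005, seed=62, methods=("CNN",),
            cnn_ensemble=ens, mothers=adults, freqs=freqs,
        )
        means = df.groupby("s_true")["CNN"].mean()
        assert means.loc[0.0] < 0.3
        assert means.loc[1.0] > 0.7

    def test_duplicate_progeny_identical_prediction(self, tiny_ensemble):
        ens, adults, freqs = tiny_ensemble
        q = freqs.alt_freqs("P01").to_numpy()
        rng = np.random.default_rng(63)
        mom = adults.dosages()[0]
        prog = pa.simulate_progeny_dosages(mom, q, True, rng, 0.005)
        e1 = pa.predict_cnn(ens, mom, prog)
        e2 = pa.predict_cnn(ens, mom, prog)
        assert e1.s_hat == e2.s_hat
        assert e1.uncertainty >= 0

    def test_site_mismatch_rejected(self, tiny_ensemble):
        ens, adults, _ = tiny_ensemble
        with pytest.raises(ValueError, match="site"):
            pa.predict_cnn(ens, adults.dosages()[0], adults.dosages()[1], site="P09")

    def test_save_load_round_trip(self, tiny_ensemble, tmp_path):
        ens, adults, freqs = tiny_ensemble
        path = tmp_path / "ens.npz"
        ens.save(path)
        back = pa.CnnEnsemble.load(path)
        rng = np.random.default_rng(1)
        mom = adults.dosages()[2]
        prog = pa.simulate_progeny_dosages(
            mom, freqs.alt_freqs("P01").to_numpy(), False, rng, 0.0
        )
        assert pa.predict_cnn(back, mom, prog).s_hat == pytest.approx(
            pa.predict_cnn(ens, mom, prog).s_hat, abs=1e-6
        )


class TestSiteFlags:
    def test_monomorphic_site_flagged(self):
        m = pa.GenotypeMatrix.from_arrays(
            np.zeros((5, 100)), [f"m{i}" for i in range(5)],
            [f"L{j}" for j in range(100)],
        )
        flags = pa.flag_uninformative_sites(m, {"PT": m.sample_ids})
        assert bool(flags.loc[0, "flagged"])

    def test_diverse_site_not_flagged(self, sim_mating):
        adults, _, pops = sim_mating
        flags = pa.flag_uninformative_sites(adults, {"P01": pops["P01"][:10]})
        assert not flags["flagged"].any()

    def test_single_isogenic_line_flagged_by_group_count(self):
        rng = np.random.default_rng(70)
        founder = rng.integers(0, 3, 1000).astype(float)
        rows = []
        for _ in range(6):
            g = founder.copy()
            flip = rng.random(g.size) < 0.002
            g[flip] = rng.integers(0, 3, flip.sum())
            rows.append(g)
        m = pa.GenotypeMatrix.from_arrays(
            np.array(rows), [f"m{i}" for i in range(6)],
            [f"L{j}" for j in range(1000)],
        )
        flags = pa.flag_uninformative_sites(m, {"PT": m.sample_ids},
                                            he_threshold=0.0)
        assert flags.loc[0, "n_isogenic_groups"] == 1
        assert bool(flags.loc[0, "flagged"])


class TestComparisons:
    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(80)
        a = rng.random(50)
        res = pa.compare_groups(a, a.copy())
        assert res["p_value"] > 0.9

    def test_monotone_decreasing_rho(self):
        s = np.linspace(0, 1, 10)
        res = pa.het_selfing_correlation(s, -s)
        assert res["rho"] == pytest.approx(-1.0)

    def test_all_tied_rho_missing(self):
        res = pa.het_selfing_correlation([0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])
        assert np.isnan(res["rho"])

    def test_selfing_negatively_correlates_with_het_gain(self, sim_mating):
        adults, freqs, _ = sim_mating
        noise = pa.NoiseModel(error_rate_epsilon=0.005, locus_missing_rate=0.0)
        rows = []
        for s, seed in ((0.1, 90), (0.9, 91)):
            m, fam, _ = pa.generate_families(adults, pa.FamilyDesign(), s, freqs,
                                             noise, seed=seed, site="P01")
            q = freqs.alt_freqs("P01").to_numpy()
            for _, r in fam.entries.iterrows():
                md = m.genotypes.loc[r.mother_id].to_numpy(float)
                pdos = m.genotypes.loc[r.progeny_id].to_numpy(float)
                est = pa.mme_selfing(md, pdos, q, 0.005)
                ho_diff = float(np.nanmean(pdos == 1) - np.nanmean(md == 1))
                rows.append((est.s_hat, ho_diff))
        df = pd.DataFrame(rows, columns=["s_hat", "ho_diff"]).dropna()
        res = pa.het_selfing_correlation(df["s_hat"], df["ho_diff"])
        assert res["rho"] < 0
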