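"""Generator unit tests: pedigree construction, Balding-Nichols frequencies,
founder genotypes, gene dropping and the trait model."""
import numpy as np
import pandas as pd
import pytest

from pedstrat import genoio, simulate
from pedstrat.simulate import AncestryModel, ConfigError, SimulationConfig


def _founder_only_pedigree(n: int, fid: str = "1") -> genoio.Pedigree:
    return genoio.Pedigree(
        pd.DataFrame(
            {
                "fid": fid,
                "iid": [f"{fid}_{i}" for i in range(n)],
                "father": "0",
                "mother": "0",
                "sex": [1, 2] * (n // 2) + [1] * (n % 2),
                "founder": True,
            }
        )
    )


class TestPedigree:
    def test_sizes_and_count_match_config(self):
        cfg = SimulationConfig(seed=1, n_families=20, family_size_range=(22, 86))
        ped = simulate.build_pedigree(cfg)
        sizes = ped.family_sizes()
        assert len(sizes) == 20
        assert sizes.between(22, 86).all()
        ped.validate()

    def test_trio_is_two_founders_and_child(self):
        cfg = SimulationConfig(seed=2, n_families=1, family_size_range=(3, 3))
        ped = simulate.build_pedigree(cfg)
        t = ped.table
        assert len(t) == 3
        assert t["founder"].sum() == 2
        child = t[~t["founder"]].iloc[0]
        assert {child["father"], child["mother"]} == set(t[t["founder"]]["iid"])

    def test_multigenerational_depth(self):
        cfg = SimulationConfig(seed=3, n_families=3, family_size_range=(25, 30))
        ped = simulate.build_pedigree(cfg)
        # depth: founders are generation 0; expect >= 3 generations somewhere
        info = ped.table.set_index("iid")
        depth = {}
        for iid in ped.topological_order():
            r = info.loc[iid]
            if r["founder"]:
                depth[iid] = 0
            else:
                depth[iid] = 1 + max(depth[r["father"]], depth[r["mother"]])
        assert max(depth.values()) >= 2  # grandchildren exist

    def test_same_seed_reproduces_exactly(self):
        cfg = SimulationConfig(seed=42, n_families=4, family_size_range=(10, 20))
        a = simulate.build_pedigree(cfg).table
        b = simulate.build_pedigree(cfg).table
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_sizes_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, family_size_range=(1, 2)).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, family_size_range=(50, 20)).validate()


class TestAncestralFreqs:
    def test_variance_matches_balding_nichols_closed_form(self):
        # at fixed base p, across-population variance should be fst*p*(1-p)
        rng = np.random.default_rng(0)
        p, fst = 0.5, 0.2
        f = simulate.draw_ancestral_freqs(10_000, 4, fst, rng, p_range=(p, p))
        assert f.shape == (10_000, 4)
        emp_var = f.var(axis=1, ddof=1).mean()
        assert emp_var == pytest.approx(fst * p * (1 - p), rel=0.05)
        assert f.mean() == pytest.approx(p, abs=0.01)

    def test_small_fst_limit_approaches_base(self):
        rng = np.random.default_rng(1)
        f = simulate.draw_ancestral_freqs(2_000, 3, 1e-4, rng, p_range=(0.4, 0.4))
        assert np.abs(f - 0.4).max() < 0.05

    def test_single_population(self):
        rng = np.random.default_rng(2)
        f = simulate.draw_ancestral_freqs(100, 1, 0.2, rng)
        assert f.shape == (100, 1)
        assert ((f > 0) & (f < 1)).all()

    def test_fst_out_of_range(self):
        rng = np.random.default_rng(0)
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ConfigError):
                simulate.draw_ancestral_freqs(10, 2, bad, rng)


class TestFounderGenotypes:
    def test_degenerate_mixture_uses_single_population(self):
        rng = np.random.default_rng(3)
        freqs = np.column_stack([np.full(200, 0.9), np.full(200, 0.1)])
        ped = _founder_only_pedigree(500)
        admix = pd.DataFrame([[1.0, 0.0]], index=pd.Index(["1"], name="fid"))
        model = AncestryModel(2, freqs, 0.2, admix)
        gm = simulate.draw_founder_genotypes(model, ped, rng)
        # observed allele frequency ~ population-1 frequency 0.9
        assert gm.dosage.mean() / 2 == pytest.approx(0.9, abs=0.01)

    def test_observed_frequency_matches_admixture_weight(self):
        rng = np.random.default_rng(4)
        freqs = np.column_stack([np.full(1, 0.8), np.full(1, 0.2)])
        ped = _founder_only_pedigree(1000)
        admix = pd.DataFrame([[0.25, 0.75]], index=pd.Index(["1"], name="fid"))
        model = AncestryModel(2, freqs, 0.2, admix)
        gm = simulate.draw_founder_genotypes(model, ped, rng)
        expected = 0.25 * 0.8 + 0.75 * 0.2  # 0.35
        se = np.sqrt(expected * (1 - expected) / (2 * 1000))
        assert abs(gm.dosage.mean() / 2 - expected) < 4 * se

    def test_near_fixed_frequency_gives_dosage_two(self):
        rng = np.random.default_rng(5)
        freqs = np.full((50, 2), 1 - 1e-12)
        ped = _founder_only_pedigree(20)
        admix = pd.DataFrame([[0.5, 0.5]], index=pd.Index(["1"], name="fid"))
        model = AncestryModel(2, freqs, 0.2, admix)
        gm = simulate.draw_founder_genotypes(model, ped, rng)
        assert (gm.dosage == 2.0).all()

    def test_missing_admixture_vector_rejected(self):
        rng = np.random.default_rng(6)
        freqs = np.full((5, 2), 0.5)
        ped = _founder_only_pedigree(4, fid="99")
        admix = pd.DataFrame([[0.5, 0.5]], index=pd.Index(["1"], name="fid"))
        model = AncestryModel(2, freqs, 0.2, admix)
        with pytest.raises(ConfigError):
            simulate.draw_founder_genotypes(model, ped, rng)


def _trio_pedigree() -> genoio.Pedigree:
    return genoio.Pedigree(
        pd.DataFrame(
            {
                "fid": "1",
                "iid": ["f", "m", "c"],
                "father": ["0", "0", "f"],
                "mother": ["0", "0", "m"],
                "sex": [1, 2, 1],
                "founder": [True, True, False],
            }
        )
    )


def _trio_founders(dosage_f: float, dosage_m: float, m: int) -> genoio.GenotypeMatrix:
    variants = pd.DataFrame(
        {"id": [f"v{j}" for j in range(m)], "chrom": "3",
         "pos": np.arange(1, m + 1), "ref": "A", "alt": "C"}
    )
    return genoio.GenotypeMatrix(
        np.vstack([np.full(m, dosage_f), np.full(m, dosage_m)]),
        variants,
        pd.DataFrame({"fid": "1", "iid": ["f", "m"]}),
    )


class TestGeneDrop:
    @pytest.mark.parametrize("parental,expected", [(0.0, 0.0), (2.0, 2.0)])
    def test_forced_transmission(self, parental, expected):
        rng = np.random.default_rng(7)
        full = simulate.gene_drop(_trio_pedigree(), _trio_founders(parental, parental, 100), rng)
        child = full.dosage[full.row_of("c")]
        assert (child == expected).all()

    def test_het_by_het_segregates_quarter_half_quarter(self):
        rng = np.random.default_rng(8)
        full = simulate.gene_drop(_trio_pedigree(), _trio_founders(1.0, 1.0, 10_000), rng)
        child = full.dosage[full.row_of("c")]
        frac = np.array([(child == d).mean() for d in (0, 1, 2)])
        assert np.abs(frac - [0.25, 0.5, 0.25]).max() < 0.02

    def test_frequency_conserved_across_generations(self, small_data):
        gm, ped = small_data.genotypes, small_data.pedigree
        founders = ped.table[ped.table["founder"]]["iid"].tolist()
        p_founder = np.nanmean(gm.subset_individuals(founders).dosage, axis=0) / 2
        p_all = np.nanmean(gm.dosage, axis=0) / 2
        # drift only: mean absolute difference should be small
        assert np.abs(p_founder - p_all).mean() < 0.05

    def test_ungenotyped_founder_rejected(self):
        rng = np.random.default_rng(9)
        founders = _trio_founders(1.0, 1.0, 10).subset_individuals(["f"])
        with pytest.raises(genoio.DataError):
            simulate.gene_drop(_trio_pedigree(), founders, rng)


class TestIndividualAdmixture:
    def test_founders_vary_and_children_average_parents(self, small_data):
        anc = small_data.ancestry
        ped = small_data.pedigree.table.set_index("iid")
        nonf = ped[~ped["founder"]]
        for iid in nonf.index[:20]:
            expect = 0.5 * (anc.loc[nonf.loc[iid, "father"]] + anc.loc[nonf.loc[iid, "mother"]])
            np.testing.assert_allclose(anc.loc[iid].to_numpy(), expect.to_numpy(), atol=1e-12)
        founders = ped[ped["founder"]].index
        assert anc.loc[founders].iloc[:, 0].std() > 0.01  # within-family heterogeneity

    def test_rows_sum_to_one(self, small_data):
        np.testing.assert_allclose(small_data.ancestry.sum(axis=1), 1.0, atol=1e-9)


class TestTraits:
    def test_ols_recovers_generating_coefficients(self):
        # homogeneous ancestry + zero family variance -> the generating model
        # is an ordinary linear model; OLS on ~5,000 individuals must recover
        # every fixed-effect coefficient within its 95% CI
        import statsmodels.api as sm

        cfg = SimulationConfig(
            seed=21, n_families=250, family_size_range=(18, 22),
            n_variants=10, n_causal=2, admixture="shared",
            plant_divergent_pairs=False, sigma2_family=0.0,
        )
        d = simulate.simulate_dataset(cfg)
        t = d.traits
        g = d.genotypes.dosage[:, d.genotypes.variant_indexer(d.causal["variant_id"])]
        X = pd.DataFrame(
            {
                "medication": t["medication"], "sex": t["sex"], "age": t["age"],
                "sex_age": t["sex"] * t["age"],
                "g1": g[:, 0], "g2": g[:, 1],
            }
        )
        fit = sm.OLS(t["trait"].to_numpy(), sm.add_constant(X)).fit()
        truth = {
            "const": cfg.beta_intercept, "medication": cfg.beta_medication,
            "sex": cfg.beta_sex, "age": cfg.beta_age, "sex_age": cfg.beta_sex_age,
            "g1": d.causal["beta"].iloc[0], "g2": d.causal["beta"].iloc[1],
        }
        ci = fit.conf_int()
        for name, value in truth.items():
            lo, hi = ci.loc[name]
            assert lo <= value <= hi, f"{name}: {value} outside [{lo}, {hi}]"

    def test_null_trait_uncorrelated_with_causal_dosage(self, small_data):
        d = small_data
        g = d.genotypes.dosage[:, d.genotypes.variant_indexer(d.causal["variant_id"])]
        n = len(d.traits)
        for j in range(g.shape[1]):
            r = np.corrcoef(d.traits["null_trait"], g[:, j])[0, 1]
            assert abs(r) < 5 / np.sqrt(n)

    def test_dominant_signal_limit(self):
        cfg = SimulationConfig(
            seed=22, n_families=5, family_size_range=(20, 30), n_variants=50,
            n_causal=1, sigma2_family=0.0, sigma2_resid=1e-4,
            beta_medication=0.0, beta_sex=0.0, beta_age=0.0, beta_sex_age=0.0,
            beta_ancestry=0.0,
        )
        d = simulate.simulate_dataset(cfg)
        d.causal.loc[0, "beta"] = 50.0
        traits, _ = simulate.simulate_traits(
            d.genotypes, d.pedigree, cfg, np.random.default_rng(1), causal=d.causal
        )
        g = d.genotypes.dosage[:, d.genotypes.variant_indexer(d.causal["variant_id"])][:, 0]
        assert np.corrcoef(traits["trait"], g)[0, 1] > 0.99

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, sigma2_family=-1.0).validate()


class TestDataset:
    def test_determinism_byte_for_byte(self, tmp_path):
        cfg = SimulationConfig(
            seed=33, n_families=4, family_size_range=(6, 10), n_variants=60, n_causal=3
        )
        pa, pb = tmp_path / "a", tmp_path / "b"
        simulate.write_dataset(simulate.simulate_dataset(cfg), pa)
        simulate.write_dataset(simulate.simulate_dataset(cfg), pb)
        for f in sorted(pa.iterdir()):
            assert f.read_bytes() == (pb / f.name).read_bytes(), f.name

    def test_shared_mode_has_no_ancestry_variation(self, shared_small):
        anc = shared_small.ancestry
        assert float(anc.iloc[:, 0].std()) == pytest.approx(0.0, abs=1e-12)
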