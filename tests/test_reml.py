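import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smoltqg.pedigree import pedigree_from_frame
from smoltqg.reml import (
    ModelSpec,
    VarianceComponents,
    fit_bivariate_reml,
    fit_univariate_reml,
    genetic_correlation,
    heritability,
    lrt_random_effect,
    maternal_proportion,
    wald_fixed_effects,
)
from smoltqg.synthetic import (
    PedigreeConfig,
    SimulationConfig,
    TraitSpec,
    simulate_pedigree,
    simulate_phenotypes,
)

CFG = PedigreeConfig().scaled(0.12)


def _simulate(h2=0.4, vf=0.1, seed=0, cfg=CFG, **kw):
    ped = simulate_pedigree(cfg, seed=seed)
    sim = SimulationConfig(
        pedigree=cfg, traits=[TraitSpec("y", Va=h2, Vf=vf, Vr=1 - h2 - vf, **kw)]
    )
    return ped, simulate_phenotypes(ped, sim, seed=seed + 10_000)


class TestUnivariate:
    def test_null_additive_variance(self):
        cfg = PedigreeConfig().scaled(0.2)
        ped, ph = _simulate(h2=0.0, vf=0.1, seed=1, cfg=cfg)
        fit = fit_univariate_reml(ph, ped, ModelSpec("y", fixed=(), random=("family", "animal")))
        h2, _ = heritability(fit)
        assert fit.vc.components["Va"] < 0.05
        assert h2 < 0.05

    def test_balanced_halfsib_matches_sire_anova_oracle(self):
        # 60 unrelated sires x 15 offspring from unrelated dams; the
        # mean-squares sire-model estimate 4*V_sire/V_P is the oracle
        rng = np.random.default_rng(5)
        n_s, n_o, h2 = 60, 15, 0.4
        rows = [(f"s{i}", "0", "0") for i in range(n_s)]
        rows += [(f"d{i}_{j}", "0", "0") for i in range(n_s) for j in range(n_o)]
        rows += [(f"o{i}_{j}", f"s{i}", f"d{i}_{j}") for i in range(n_s) for j in range(n_o)]
        ped = pedigree_from_frame(
            pd.DataFrame(rows, columns=["id", "sire", "dam"]).assign(
                generation="G", cross_type="AxA", family="f")
        )
        sire_bv = rng.normal(0, np.sqrt(h2), n_s)
        recs = []
        for i in range(n_s):
            for j in range(n_o):
                y = 0.5 * sire_bv[i] + rng.normal(0, np.sqrt(1 - 0.25 * h2))
                recs.append((f"o{i}_{j}", f"fam{i}", y))
        ph = pd.DataFrame(recs, columns=["individual_id", "family", "y"])
        # ANOVA oracle
        ymat = ph["y"].to_numpy().reshape(n_s, n_o)
        msb = n_o * ymat.mean(axis=1).var(ddof=1)
        msw = ymat.var(axis=1, ddof=1).mean()
        v_sire = (msb - msw) / n_o
        h2_oracle = 4 * v_sire / (v_sire + msw)
        fit = fit_univariate_reml(ph, ped, ModelSpec("y", fixed=(), random=("animal",)))
        h2_hat, _ = heritability(fit)
        assert h2_hat == pytest.approx(h2_oracle, abs=0.08)

    def test_boundary_flagged(self):
        ped, ph = _simulate(h2=0.0, vf=0.0, seed=3)
        fit = fit_univariate_reml(ph, ped, ModelSpec("y", fixed=(), random=("family", "animal")))
        assert set(fit.vc.boundary) >= {"Va"} or fit.vc.components["Va"] < 1e-3


class TestRatios:
    def test_heritability_closed_forms(self):
        vc = VarianceComponents({"Va": 0.6, "Vr": 0.4}, {}, 0.0)
        assert heritability(vc)[0] == pytest.approx(0.6)
        vc0 = VarianceComponents({"Va": 0.0, "Vr": 1.0}, {}, 0.0)
        assert heritability(vc0)[0] == 0.0

    def test_reported_component_table_row(self):
        # 24-month fork length: Vf=32.51, Va=273.26, Vr=439.9 gives
        # h2 = 273.26 / 745.67 ~= 0.37
        vc = VarianceComponents({"Vf": 32.51, "Va": 273.26, "Vr": 439.9}, {}, 0.0)
        assert heritability(vc)[0] == pytest.approx(0.37, abs=0.005)

    def test_maternal_proportion(self):
        # the RelW3-style decomposition with a maternal term
        vc = VarianceComponents({"Vf": 9.31, "Vm": 13.91, "Va": 33.31, "Vr": 30.0}, {}, 0.0)
        m2, _ = maternal_proportion(vc)
        assert m2 == pytest.approx(13.91 / 86.53, abs=1e-6)
        assert m2 == pytest.approx(0.16, abs=0.01)
        full = VarianceComponents({"Vm": 2.0}, {}, 0.0)
        assert maternal_proportion(full)[0] == 1.0

    def test_zero_vp_errors(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents({"Va": 0.0, "Vr": 0.0}, {}, 0.0))


class TestLRT:
    def test_identical_fits(self):
        ped, ph = _simulate(seed=4)
        spec = ModelSpec("y", fixed=(), random=("family", "animal"))
        fit = fit_univariate_reml(ph, ped, spec)
        t = lrt_random_effect(fit, fit)
        assert t.statistic == 0.0 and t.p_value == 1.0

    def test_mismatched_rows_error(self):
        ped, ph = _simulate(seed=5)
        spec = ModelSpec("y", fixed=(), random=("family", "animal"))
        fit = fit_univariate_reml(ph, ped, spec)
        fit2 = fit_univariate_reml(ph.iloc[:-5], ped, spec)
        with pytest.raises(ValueError):
            lrt_random_effect(fit, fit2)

    def test_strong_signal_rejects(self):
        """A clearly heritable trait is decisively detected (scaled design)."""
        cfg = PedigreeConfig().scaled(0.25)
        ped, ph = _simulate(h2=0.6, vf=0.05, seed=6, cfg=cfg)
        full = fit_univariate_reml(ph, ped, ModelSpec("y", fixed=(), random=("family", "animal")))
        red = fit_univariate_reml(ph, ped, ModelSpec("y", fixed=(), random=("family",)))
        t = lrt_random_effect(full, red)
        assert t.p_value < 0.01


class TestWald:
    def test_null_fixed_effect_p_uniform(self):
        # zero-effect 2-level factor: p-values across replicates are uniform
        rng = np.random.default_rng(11)
        pvals = []
        rows = [(f"i{k}", "0", "0") for k in range(160)]
        ped = pedigree_from_frame(
            pd.DataFrame(rows, columns=["id", "sire", "dam"]).assign(
                generation="G", cross_type="AxA", family="f")
        )
        for rep in range(120):
            ph = pd.DataFrame({
                "individual_id": [f"i{k}" for k in range(160)],
                "family": [f"fam{k % 8}" for k in range(160)],
                "grp": rng.choice(["a", "b"], 160),
                "y": rng.normal(size=160),
            })
            fit = fit_univariate_reml(ph, ped, ModelSpec("y", fixed=("grp",), random=("family",)))
            pvals.append(wald_fixed_effects(fit)["grp"].p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_large_effect_detected(self):
        ped, ph = _simulate(seed=12, gen_effects={"F2": 2.0})
        fit = fit_univariate_reml(
            ph, ped, ModelSpec("y", fixed=("generation",), random=("family", "animal"))
        )
        assert wald_fixed_effects(fit)["generation"].p_value < 0.001

    def test_single_level_factor_non_estimable(self):
        ped, ph = _simulate(seed=13)
        ph["const"] = "only"
        fit = fit_univariate_reml(
            ph, ped, ModelSpec("y", fixed=("const",), random=("family",))
        )
        assert wald_fixed_effects(fit)["const"].kind == "non-estimable"


class TestBivariate:
    def _biv(self, rg, seed, cfg=None, h2=0.4):
        cfg = cfg or PedigreeConfig().scaled(0.15)
        ped = simulate_pedigree(cfg, seed=seed)
        sim = SimulationConfig(
            pedigree=cfg,
            traits=[TraitSpec("y1", Va=h2, Vf=0.0, Vr=1 - h2),
                    TraitSpec("y2", Va=h2, Vf=0.0, Vr=1 - h2)],
            genetic_corr=np.array([[1, rg], [rg, 1]]),
        )
        ph = simulate_phenotypes(ped, sim, seed=seed + 1)
        return ped, ph

    def test_self_copy_unit_correlation(self):
        ped, ph = self._biv(0.0, 20)
        ph["y2"] = ph["y1"]
        fit = fit_bivariate_reml(
            ph, ped, ModelSpec("y1", fixed=(), random=("animal",)),
            ModelSpec("y2", fixed=(), random=("animal",)))
        r, _ = genetic_correlation(fit)
        assert r > 0.99

    def test_null_correlation_small(self):
        rs = []
        for seed in (30, 31, 32):
            ped, ph = self._biv(0.0, seed, cfg=PedigreeConfig().scaled(0.2))
            fit = fit_bivariate_reml(
                ph, ped, ModelSpec("y1", fixed=(), random=("animal",)),
                ModelSpec("y2", fixed=(), random=("animal",)))
            rs.append(genetic_correlation(fit)[0])
        assert abs(np.mean(rs)) < 0.2

    def test_recovery_with_lrt(self):
        ped, ph = self._biv(0.7, 40, cfg=PedigreeConfig().scaled(0.25))
        s1 = ModelSpec("y1", fixed=(), random=("animal",))
        s2 = ModelSpec("y2", fixed=(), random=("animal",))
        full = fit_bivariate_reml(ph, ped, s1, s2)
        red = fit_bivariate_reml(ph, ped, s1, s2, constrain_cov_a=True)
        r, t = genetic_correlation(full, red)
        assert r == pytest.approx(0.7, abs=0.25)
        assert t.p_value < 0.05

    def test_fast_and_dense_paths_agree(self):
        ped, ph = self._biv(0.5, 50, cfg=PedigreeConfig().scaled(0.08))
        s1 = ModelSpec("y1", fixed=(), random=("animal",))
        s2 = ModelSpec("y2", fixed=(), random=("animal",))
        fast = fit_bivariate_reml(ph, ped, s1, s2)
        dense = fit_bivariate_reml(ph, ped, s1, s2, random=("animal",),
                                   constrain_cov_a=False, A=None)
        # force the dense path by adding a dummy family term with ~zero var
        dense = fit_bivariate_reml(
            ph, ped,
            ModelSpec("y1", fixed=(), random=("family", "animal")),
            ModelSpec("y2", fixed=(), random=("family", "animal")))
        r_fast, _ = genetic_correlation(fast)
        r_dense, _ = genetic_correlation(dense)
        assert r_fast == pytest.approx(r_dense, abs=0.06)


class TestInvariances:
    def test_factor_label_recoding(self):
        ped, ph = _simulate(seed=60, gen_effects={"F2": 0.5})
        spec = ModelSpec("y", fixed=("generation",), random=("family", "animal"))
        f1 = fit_univariate_reml(ph, ped, spec)
        ph2 = ph.copy()
        ph2["generation"] = ph2["generation"].map({"F1": "zzz_late", "F2": "aaa_early"})
        f2 = fit_univariate_reml(ph2, ped, spec)
        for k in f1.vc.components:
            assert f1.vc.components[k] == pytest.approx(f2.vc.components[k], abs=1e-5)
        assert heritability(f1)[0] == pytest.approx(heritability(f2)[0], abs=1e-6)

    def test_h2_in_unit_interval(self):
        for seed in (70, 71):
            ped, ph = _simulate(h2=0.5, seed=seed)
            fit = fit_univariate_reml(ph, ped, ModelSpec("y", fixed=(), random=("family", "animal")))
            h2, _ = heritability(fit)
            assert 0.0 <= h2 <= 1.0
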