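"""Bayesian logit-threshold animal model for a binary life history.

Simulates the migratory/resident decision on a scaled study pedigree at
liability-scale h2 = 0.6 and summarizes the posterior (mode, 95% HPD,
lag-1 autocorrelations). The residual variance is fixed at 1 and the
link variance pi^2/3 enters the heritability denominator.
"""

import numpy as np

from smoltqg.mcmc import (ChainSettings, ThresholdModelSpec, binary_heritability,
                          chain_diagnostics, fit_binary_animal_mcmc)
from smoltqg.synthetic import (LINK_VARIANCE, PedigreeConfig, SimulationConfig,
                               TraitSpec, simulate_pedigree, simulate_phenotypes)
from smoltqg.traits import binarize_life_history

cfg = PedigreeConfig(
    f1_families={"AxA": 4, "AxR": 3, "RxR": 3, "RxA": 3},
    f2_families={"AxA": 3, "AxR": 2, "RxR": 2, "RxA": 2, "ARxAR": 1, "RAxRA": 1},
    f1_mean_size=88, f2_mean_size=137, n_dams_p1=14, n_sires_p1=10,
)
Vf = 0.3
Va = 0.6 * (Vf + 1 + LINK_VARIANCE) / 0.4  # liability h2 = 0.6
ped = simulate_pedigree(cfg, seed=11)
sim = SimulationConfig(
    pedigree=cfg,
    traits=[TraitSpec("liab", Va=Va, Vf=Vf, distribution="liability")],
    liability_trait="liab", liability_cuts=(0.0, 0.0, 0.0),
)
pheno = simulate_phenotypes(ped, sim, seed=12)
smolt, _ = binarize_life_history(pheno["life_history"])
pheno["LHSmolt"] = smolt

spec = ThresholdModelSpec("LHSmolt", fixed=(), random=("family", "animal"))
post = fit_binary_animal_mcmc(
    pheno, ped, spec, seed=13,
    chain=ChainSettings(iterations=10000, burnin=2000, thin=8))
h2_draws, mode, (lo, hi) = binary_heritability(post)
print(f"n = {len(pheno)} fish; smolt prevalence {np.nanmean(smolt):.2f}")
print(f"h2 mode {mode:.2f}, 95% HPD ({lo:.2f}, {hi:.2f}); simulated truth 0.6")
print("residual draws all exactly 1:", bool((post.draws['Vr'] == 1).all()))
print(chain_diagnostics(post).to_string(index=False))
print("\nThis short demo chain leaves lag-1 autocorrelation above the 0.1")
print("threshold; the packaged life-history preset (1.1M iterations,")
print("thinning 1000) is what the diagnostics are designed to pass.")
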