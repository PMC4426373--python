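"""Life-history class comparisons and discriminant classification.

Runs the study-style summary statistics on a simulated dataset: one-way
ANOVA across classes, Tukey-Kramer pairwise comparisons, a mixed
Pearson/Spearman correlation matrix, and an LDA of life history scored
by resubstitution.
"""

import numpy as np

from smoltqg.class_stats import (anova_by_class, classify_and_score,
                                 correlation_matrix, fit_dfa, tukey_kramer)
from smoltqg.synthetic import (simulate_pedigree, simulate_phenotypes,
                               study_simulation_config)
from smoltqg.traits import derive_phenotypes

sim = study_simulation_config(scale=0.15)
ped = simulate_pedigree(sim.pedigree, seed=21)
pheno = derive_phenotypes(simulate_phenotypes(ped, sim, seed=22))

t = anova_by_class(pheno, "mo24Length")
print(f"ANOVA of mo24Length across classes: F = {t.statistic:.1f}, p = {t.p_value:.2g}")
print(tukey_kramer(pheno, "mo24Length").head(3).round(3).to_string(index=False))

traits = ["mo12Length", "mo24Length", "mo24Kfact", "IGRL1", "LHSmolt", "LHMature"]
cm = correlation_matrix(pheno, traits)
print(f"\n{cm.n_pairs()} trait pairs, {cm.n_significant()} significant at alpha=0.05")
print(cm.estimates.round(2).to_string())

preds = ["mo12Length", "mo12Weight", "mo15Length", "mo15Weight",
         "mo24Length", "mo24Weight"]
complete = pheno.dropna(subset=preds + ["life_history"])
counts = complete["life_history"].value_counts()
ok = counts[counts > len(preds) + 1].index
model = fit_dfa(pheno[pheno["life_history"].isin(ok)], preds)
_, acc, conf = classify_and_score(model, pheno[pheno["life_history"].isin(ok)])
print(f"\nDFA resubstitution accuracy: {acc:.1f}% over {model.n} complete cases")
print(conf.to_string())
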