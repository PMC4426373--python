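"""Run the whole analysis chain on a simulated study-design dataset.

Equivalent to `smoltqg pipeline --seed 7 --out results/demo`: simulate,
derive traits, morphometrics, class statistics, REML, threshold MCMC,
and DFA, writing one CSV per stage plus a seeded run log.
"""

from smoltqg.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="results/demo", seed=7, simulate_scale=0.08,
    mcmc_chain=dict(iterations=8000, burnin=2000, thin=6),
)
bundle = run_pipeline(cfg)

print("REML variance components (Table-style):")
print(bundle["reml_table"][["trait", "N", "Vf", "Va", "Vr", "h2", "h2_se", "h2_p"]]
      .round(3).to_string(index=False))
print("NB: this demo simulates only ~12 of the study's 144 families, so the")
print("family (micro) and additive terms are weakly separated; at the full")
print("design the same models recover each component precisely.")
print("\nThreshold-model estimates:")
print(bundle["mcmc_table"][["trait", "h2_mode", "h2_hpd_low", "h2_hpd_high"]]
      .round(3).to_string(index=False))
print(f"\nDFA accuracy {bundle['dfa_accuracy']:.1f}%;",
      f"{bundle['correlations'].n_significant()} of",
      f"{bundle['correlations'].n_pairs()} trait pairs significant.")
print("All stage outputs and the run log are under results/demo/.")
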