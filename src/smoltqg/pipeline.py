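"""End-to-end orchestration: simulate/load -> derived traits ->
morphometrics -> class statistics -> REML -> MCMC -> DFA.

Each stage writes CSV tables to the output directory and never mutates
another stage's outputs; a run log records the seed and settings so a
rerun with the same configuration reproduces the REML tables exactly and
the MCMC summaries statistically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from smoltqg import morphometrics as morpho
from smoltqg import synthetic
from smoltqg.class_stats import anova_by_class, correlation_matrix, fit_dfa, classify_and_score
from smoltqg.mcmc import (
    ChainSettings,
    ThresholdModelSpec,
    binary_heritability,
    chain_diagnostics,
    fit_binary_animal_mcmc,
    hpd_interval,
    posterior_mode,
)
from smoltqg.pedigree import Pedigree, read_pedigree, write_pedigree
from smoltqg.presets import load_presets
from smoltqg.reml import (
    ModelSpec,
    fit_univariate_reml,
    heritability,
    lrt_random_effect,
    maternal_proportion,
)
from smoltqg.traits import derive_phenotypes, read_phenotypes, write_phenotypes

SIZE_TRAITS = [
    "mo12Length", "mo12Weight", "mo12Kfact", "mo15Length", "mo15Weight",
    "mo15Kfact", "IGRL1", "IGRW1", "mo24Length", "mo24Weight", "mo24Kfact",
    "IGRL2", "IGRW2",
]


@dataclass
class RunConfig:
    """Inputs, module toggles, and model presets for one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    # either provide input files ...
    pedigree_path: str = None
    phenotype_path: str = None
    landmark_path: str = None
    # ... or simulate at this fraction of the study design (family count
    # scales; family sizes stay at the study's 88/137)
    simulate_scale: float = 0.08
    stages: tuple = ("simulate", "traits", "morpho", "stats", "reml", "mcmc", "dfa")
    reml_traits: tuple = ("mo12Length", "mo24Length", "mo24Kfact")
    mcmc_traits: tuple = ("LHSmolt",)
    mcmc_chain: dict = field(default_factory=lambda: dict(iterations=20000, burnin=4000, thin=16))
    exclude_warps: tuple = (1,)  # the anesthesia-artifact axis
    n_landmark_fish: int = 300
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self, presets) -> None:
        for t in list(self.reml_traits):
            if t not in presets["reml"]:
                raise ValueError(f"no preset model for trait {t!r}")
        for t in list(self.mcmc_traits):
            if t not in presets["mcmc"]:
                raise ValueError(f"no preset model for binary trait {t!r}")
        for p in (self.pedigree_path, self.phenotype_path, self.landmark_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def summarize_families(ped: Pedigree, data: pd.DataFrame) -> pd.DataFrame:
    """Per-group min/mean/max family proportions of smolt and mature fish.

    Rows per cross type, per generation, and a global row, with family and
    individual counts — the layout of the study's family-proportion table.
    Families without any classified offspring are excluded with a warning.
    """
    import warnings

    sub = data.dropna(subset=["LHMature"]).copy()
    sub["is_smolt"] = sub["life_history"] == "smolt"
    sub["is_mature"] = sub["life_history"] == "mature"
    all_fams = data["family"].unique()
    empty = set(all_fams) - set(sub["family"].unique())
    if empty:
        warnings.warn(f"{len(empty)} families with no classified offspring excluded",
                      stacklevel=2)
    fam = sub.groupby(["family", "cross_type", "generation"]).agg(
        p_smolt=("is_smolt", "mean"), p_mature=("is_mature", "mean"), n=("is_smolt", "size")
    ).reset_index()

    def rows_for(key, label):
        out = []
        for g, grp in fam.groupby(key):
            out.append({
                "group": g, "level": label,
                "smolt_min": grp["p_smolt"].min(), "smolt_mean": grp["p_smolt"].mean(),
                "smolt_max": grp["p_smolt"].max(),
                "mature_min": grp["p_mature"].min(), "mature_mean": grp["p_mature"].mean(),
                "mature_max": grp["p_mature"].max(),
                "n_families": len(grp), "n_individuals": int(grp["n"].sum()),
            })
        return out

    rows = rows_for("cross_type", "cross_type") + rows_for("generation", "generation")
    rows.append({
        "group": "Global", "level": "global",
        "smolt_min": fam["p_smolt"].min(), "smolt_mean": fam["p_smolt"].mean(),
        "smolt_max": fam["p_smolt"].max(),
        "mature_min": fam["p_mature"].min(), "mature_mean": fam["p_mature"].mean(),
        "mature_max": fam["p_mature"].max(),
        "n_families": len(fam), "n_individuals": int(fam["n"].sum()),
    })
    return pd.DataFrame(rows)


def _spec_from_preset(trait, preset) -> ModelSpec:
    return ModelSpec(
        response=trait,
        fixed=tuple(preset.get("fixed", ())),
        random=tuple(preset.get("random", ("family", "animal"))),
        covariates=tuple(preset.get("covariates", ())),
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns a result bundle (also written to ``cfg.out_dir``); raises on
    the first failing stage after persisting the outputs of earlier ones.
    """
    presets = load_presets()
    cfg.validate(presets)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    log = {"seed": cfg.seed, "config": {k: str(v) for k, v in dataclasses.asdict(cfg).items()},
           "stages": {}}
    bundle = {}

    def stage_done(name, t0, **info):
        log["stages"][name] = {"seconds": round(time.time() - t0, 2),
                               "when": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    # --- inputs
    t0 = time.time()
    if cfg.pedigree_path:
        ped = read_pedigree(cfg.pedigree_path)
        pheno = read_phenotypes(cfg.phenotype_path)
        shapes = morpho.read_tps(cfg.landmark_path) if cfg.landmark_path else None
        stage_done("load", t0, n_pedigree=ped.n)
    elif "simulate" in cfg.stages:
        sim = synthetic.study_simulation_config(scale=cfg.simulate_scale)
        ped = synthetic.simulate_pedigree(sim.pedigree, seed=int(rng.integers(2**31 - 1)))
        pheno = synthetic.simulate_phenotypes(ped, sim, seed=int(rng.integers(2**31 - 1)))
        shapes = synthetic.simulate_landmarks(
            synthetic.LandmarkConfig(), n=cfg.n_landmark_fish, seed=int(rng.integers(2**31 - 1))
        )
        # landmarked fish are a subset of phenotyped fish
        ids = pheno["individual_id"].sample(
            n=min(cfg.n_landmark_fish, len(pheno)), random_state=int(rng.integers(2**31 - 1))
        ).tolist()
        for s, iid in zip(shapes, ids):
            s.individual_id = iid
        write_pedigree(ped, out / "pedigree.csv")
        morpho.write_tps(shapes, out / "landmarks.tps")
        stage_done("simulate", t0, n_pedigree=ped.n, n_phenotyped=len(pheno))
    else:
        raise ValueError("no inputs: provide paths or enable the simulate stage")
    bundle["pedigree"] = ped

    # --- derived traits
    if "traits" in cfg.stages:
        t0 = time.time()
        pheno = derive_phenotypes(pheno)
        write_phenotypes(pheno, out / "phenotypes.csv")
        stage_done("traits", t0, n_rows=len(pheno))
    bundle["phenotypes"] = pheno

    # --- morphometrics
    if "morpho" in cfg.stages and shapes is not None:
        t0 = time.time()
        dec = morpho.decompose_shapes(shapes)
        scores, labels = morpho.exclude_warps(dec, cfg.exclude_warps)
        warp_df = pd.DataFrame(scores, columns=labels)
        warp_df.insert(0, "individual_id", dec.ids)
        warp_df.insert(1, "CentroidSize", dec.centroid_size)
        pheno = pheno.merge(warp_df, on="individual_id", how="left")
        pve = pd.DataFrame({"warp": dec.warp_labels, "pve": dec.pve})
        pve.to_csv(out / "relative_warp_pve.csv", index=False)
        warp_df.to_csv(out / "warp_scores.csv", index=False)
        bundle["shape_decomposition"] = dec
        stage_done("morpho", t0, n_shapes=len(dec.ids), n_warps=len(dec.warp_labels))
    bundle["phenotypes"] = pheno

    # --- class statistics
    if "stats" in cfg.stages:
        t0 = time.time()
        fam_summary = summarize_families(ped, pheno)
        fam_summary.to_csv(out / "family_proportions.csv", index=False)
        anova_rows = []
        for trait in SIZE_TRAITS:
            if trait in pheno and pheno[trait].notna().sum() > 8:
                ts = anova_by_class(pheno, trait)
                anova_rows.append((trait, ts.statistic, ts.df, ts.p_value))
        pd.DataFrame(anova_rows, columns=["trait", "F", "df", "p"]).to_csv(
            out / "anova_by_class.csv", index=False)
        corr_traits = [t for t in SIZE_TRAITS + ["LHSmolt", "LHMature"] if t in pheno]
        cm = correlation_matrix(pheno, corr_traits)
        cm.to_long().to_csv(out / "phenotypic_correlations.csv", index=False)
        bundle["family_summary"] = fam_summary
        bundle["correlations"] = cm
        stage_done("stats", t0, n_corr_pairs=cm.n_pairs(),
                   n_significant=cm.n_significant(cfg.alpha))

    # --- REML animal models
    if "reml" in cfg.stages:
        t0 = time.time()
        rows = []
        for trait in cfg.reml_traits:
            spec = _spec_from_preset(trait, presets["reml"][trait])
            fit = fit_univariate_reml(pheno, ped, spec)
            h2, h2_se = heritability(fit)
            m2, m2_se = maternal_proportion(fit)
            reduced = fit_univariate_reml(
                pheno, ped, dataclasses.replace(
                    spec, random=tuple(r for r in spec.random if r != "animal"))
            ) if "animal" in spec.random else None
            lrt = lrt_random_effect(fit, reduced) if reduced else None
            row = {"trait": trait, "N": fit.n}
            row.update({k: v for k, v in fit.vc.components.items()})
            row.update({f"{k}_se": v for k, v in fit.vc.se.items()})
            row.update({"h2": h2, "h2_se": h2_se, "m2": m2, "m2_se": m2_se,
                        "h2_p": lrt.p_value if lrt else np.nan})
            rows.append(row)
        reml_table = pd.DataFrame(rows)
        reml_table.to_csv(out / "reml_variance_components.csv", index=False)
        bundle["reml_table"] = reml_table
        stage_done("reml", t0, n_traits=len(rows))

    # --- Bayesian threshold models
    if "mcmc" in cfg.stages:
        t0 = time.time()
        rows = []
        for trait in cfg.mcmc_traits:
            pr = presets["mcmc"][trait]
            spec = ThresholdModelSpec(
                response=trait, fixed=tuple(pr.get("fixed", ())),
                random=tuple(pr.get("random", ("family", "animal"))),
            )
            chain = ChainSettings(**cfg.mcmc_chain)
            post = fit_binary_animal_mcmc(
                pheno, ped, spec, seed=int(rng.integers(2**31 - 1)), chain=chain)
            h2d, mode, hpd = binary_heritability(post)
            diag = chain_diagnostics(post)
            row = {"trait": trait, "h2_mode": mode, "h2_hpd_low": hpd[0],
                   "h2_hpd_high": hpd[1], "diagnostics_pass": bool(diag.attrs["pass"])}
            for c in post.draws.columns:
                row[f"{c}_mode"] = posterior_mode(post.draws[c])
                lo, hi = hpd_interval(post.draws[c])
                row[f"{c}_hpd_low"], row[f"{c}_hpd_high"] = lo, hi
            rows.append(row)
        mcmc_table = pd.DataFrame(rows)
        mcmc_table.to_csv(out / "mcmc_threshold_estimates.csv", index=False)
        bundle["mcmc_table"] = mcmc_table
        stage_done("mcmc", t0, n_traits=len(rows))

    # --- discriminant classification
    if "dfa" in cfg.stages:
        t0 = time.time()
        preds = [t for t in SIZE_TRAITS if t in pheno]
        # classes with fewer complete cases than predictors cannot enter the
        # discriminant fit (only an issue for heavily scaled-down runs)
        complete = pheno.dropna(subset=preds + ["life_history"])
        counts = complete["life_history"].value_counts()
        ok_classes = counts[counts > len(preds) + 1].index
        dfa_data = pheno[pheno["life_history"].isin(ok_classes)]
        model = fit_dfa(dfa_data, preds)
        _, acc, conf = classify_and_score(model, dfa_data)
        conf.to_csv(out / "dfa_confusion.csv")
        (out / "dfa_report.json").write_text(json.dumps(
            {"predictors": preds, "n": model.n, "accuracy_percent": acc}, indent=2))
        bundle["dfa_accuracy"] = acc
        stage_done("dfa", t0, accuracy=acc)

    return bundle
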