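"""Synthetic data with the statistical structure the analysis assumes.

The generator's defaults emulate the three-generation experimental design
of the study population: wild P1 founders (42 dams, 31 sires), 75 F1
full/half-sib families (mean 88 offspring) of cross types AxA, AxR, RxA,
RxR, and 69 F2 families (mean 137 offspring) adding ARxAR and RAxRA —
roughly 16,000 individuals.  Phenotypes are built from fixed generation
and cross-type effects, family (micro), maternal, additive genetic
(via Mendelian sampling down the pedigree) and residual components.
Binary life histories arise from a single shared liability with cut
points, so the logit-scale heritability formula used by the threshold
model is exactly the generative estimand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from smoltqg.morphometrics import LandmarkSet, tangent_basis
from smoltqg.pedigree import UNKNOWN, Pedigree, pedigree_from_frame

LINK_VARIANCE = np.pi**2 / 3  # logistic link variance on the liability scale

# F1/F2 family counts per cross type; chosen to reproduce the printed
# per-cross-type totals across both generations (38/25/29/32 + 10 + 10)
# together with 75 F1 and 69 F2 families.
DEFAULT_F1_FAMILIES = {"AxA": 22, "AxR": 14, "RxR": 18, "RxA": 21}
DEFAULT_F2_FAMILIES = {
    "AxA": 16,
    "AxR": 11,
    "RxR": 11,
    "RxA": 11,
    "ARxAR": 10,
    "RAxRA": 10,
}


@dataclass
class PedigreeConfig:
    """Design of the simulated three-generation pedigree."""

    f1_families: dict = field(default_factory=lambda: dict(DEFAULT_F1_FAMILIES))
    f2_families: dict = field(default_factory=lambda: dict(DEFAULT_F2_FAMILIES))
    f1_mean_size: float = 88.0
    f2_mean_size: float = 137.0
    nb_dispersion: float = 8.0  # negative-binomial size parameter for family sizes
    n_dams_p1: int = 42
    n_sires_p1: int = 31
    half_sib_rate: float = 0.5  # probability a new family reuses an already-used sire

    def scaled(self, factor: float) -> "PedigreeConfig":
        """A proportionally smaller design (same structure, fewer/smaller families)."""
        import math

        def shrink(d):
            return {k: max(2, math.ceil(v * factor)) for k, v in d.items()}

        return PedigreeConfig(
            f1_families=shrink(self.f1_families),
            f2_families=shrink(self.f2_families),
            f1_mean_size=max(4.0, self.f1_mean_size * factor),
            f2_mean_size=max(4.0, self.f2_mean_size * factor),
            nb_dispersion=self.nb_dispersion,
            n_dams_p1=max(6, int(self.n_dams_p1 * factor * 2)),
            n_sires_p1=max(6, int(self.n_sires_p1 * factor * 2)),
            half_sib_rate=self.half_sib_rate,
        )


@dataclass
class TraitSpec:
    """Variance-component specification of one simulated trait.

    ``Va`` is the additive genetic variance (diagonal of G); genetic
    covariances across traits come from the config-level genetic
    correlation matrix.  ``distribution`` is ``gaussian`` or
    ``liability`` (the latter adds a N(0,1) residual plus logistic link
    noise of variance pi^2/3, matching the threshold-model parameterization
    with residual variance fixed at 1).
    """

    name: str
    mean: float = 0.0
    Va: float = 1.0
    Vf: float = 0.0
    Vm: float = 0.0
    Vs: float = 0.0
    Vr: float = 1.0
    gen_effects: dict = field(default_factory=dict)  # {"F1": x, "F2": y}
    xtype_effects: dict = field(default_factory=dict)
    distribution: str = "gaussian"
    missing_rate: float = 0.0


@dataclass
class SimulationConfig:
    """Traits, their genetic correlations, and life-history cut points."""

    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    traits: list = field(default_factory=list)
    genetic_corr: np.ndarray = None  # (T, T); identity when None
    # liability cut points for mature < c1 <= parr < c2 <= indeterminate < c3 <= smolt;
    # defaults target the study's class frequencies (12.7/11.7/4/71.6 %)
    liability_cuts: tuple = None
    liability_trait: str = None  # name of the TraitSpec supplying the shared liability


def _nb_sizes(rng, mean, dispersion, n):
    """Family sizes: negative binomial with the given mean, at least 1."""
    p = dispersion / (dispersion + mean)
    sizes = rng.negative_binomial(dispersion, p, size=n)
    return np.maximum(sizes, 1)


def simulate_pedigree(cfg: PedigreeConfig = None, seed: int = 0) -> Pedigree:
    """Simulate the three-generation study pedigree.

    P1 founders carry an anadromous (A) or resident (R) ecotype; F1
    families realize the four pure P1 cross types; F2 families draw
    unrelated F1 parents from families of the matching type (ARxAR from
    AxR families, RAxRA from RxA).  Sires are shared across dams at the
    configured rate, producing paternal half-sib families.  Deterministic
    under ``seed``.
    """
    cfg = cfg or PedigreeConfig()
    rng = np.random.default_rng(seed)
    rows = []

    # --- P1 founders, split between ecotypes by the demand of F1 crosses
    def founder_split(n_total, demand_a, demand_r):
        tot = demand_a + demand_r
        n_a = max(2, int(round(n_total * demand_a / tot))) if tot else n_total // 2
        return n_a, max(2, n_total - n_a)

    f1_items = sorted(cfg.f1_families.items())
    dam_a_need = sum(v for k, v in f1_items if k[0] == "A")
    dam_r_need = sum(v for k, v in f1_items if k[0] == "R")
    sire_a_need = sum(v for k, v in f1_items if k.split("x")[1] == "A")
    sire_r_need = sum(v for k, v in f1_items if k.split("x")[1] == "R")
    n_dam_a, n_dam_r = founder_split(cfg.n_dams_p1, dam_a_need, dam_r_need)
    n_sire_a, n_sire_r = founder_split(cfg.n_sires_p1, sire_a_need, sire_r_need)

    dams = {"A": [f"P1D_A{i}" for i in range(n_dam_a)],
            "R": [f"P1D_R{i}" for i in range(n_dam_r)]}
    sires = {"A": [f"P1S_A{i}" for i in range(n_sire_a)],
             "R": [f"P1S_R{i}" for i in range(n_sire_r)]}
    for eco in ("A", "R"):
        for iid in dams[eco] + sires[eco]:
            rows.append((iid, "0", "0", "P1", "founder", "0"))

    def make_families(parent_pool_dam, parent_pool_sire, families, mean_size, gen):
        """Create families; returns list of (family_id, cross, dam, sire, size)."""
        out = []
        for cross, n_fam in sorted(families.items()):
            if n_fam == 0:
                continue
            d_pool = parent_pool_dam[cross]
            s_pool = parent_pool_sire[cross]
            if not d_pool or not s_pool:
                raise ValueError(f"infeasible config: no parents for cross {cross}")
            sizes = _nb_sizes(rng, mean_size, cfg.nb_dispersion, n_fam)
            used_sires = []
            used_pairs = set()
            for j in range(n_fam):
                for _ in range(200):
                    dam = d_pool[rng.integers(len(d_pool))]
                    if used_sires and rng.random() < cfg.half_sib_rate:
                        sire = used_sires[rng.integers(len(used_sires))]
                    else:
                        sire = s_pool[rng.integers(len(s_pool))]
                    if (dam, sire) not in used_pairs and dam != sire:
                        break
                else:
                    raise ValueError(
                        f"infeasible config: more {cross} families than parent pairs"
                    )
                used_pairs.add((dam, sire))
                used_sires.append(sire)
                out.append((f"{gen}_{cross}_fam{j}", cross, dam, sire, sizes[j]))
        return out

    # --- F1: parent pools keyed by cross type
    f1_dam_pool = {c: dams[c[0]] for c in cfg.f1_families}
    f1_sire_pool = {c: sires[c.split("x")[1]] for c in cfg.f1_families}
    f1_fams = make_families(f1_dam_pool, f1_sire_pool, cfg.f1_families, cfg.f1_mean_size, "F1")
    f1_members: dict = {}
    for fam_id, cross, dam, sire, size in f1_fams:
        for k in range(size):
            iid = f"{fam_id}_{k}"
            rows.append((iid, sire, dam, "F1", cross, fam_id))
            f1_members.setdefault(cross, []).append((iid, fam_id))

    # --- F2: parents are F1 fish from families of the source cross type
    source = {"AxA": "AxA", "AxR": "AxR", "RxA": "RxA", "RxR": "RxR",
              "ARxAR": "AxR", "RAxRA": "RxA"}
    f2_dam_pool, f2_sire_pool = {}, {}
    for cross in cfg.f2_families:
        pool = f1_members.get(source[cross], [])
        if len(pool) < 4:
            raise ValueError(f"infeasible config: no F1 parents for F2 cross {cross}")
        perm = rng.permutation(len(pool))
        half = len(pool) // 2
        f2_dam_pool[cross] = [pool[i][0] for i in perm[:half]]
        f2_sire_pool[cross] = [pool[i][0] for i in perm[half:]]
    f2_fams = make_families(f2_dam_pool, f2_sire_pool, cfg.f2_families, cfg.f2_mean_size, "F2")
    for fam_id, cross, dam, sire, size in f2_fams:
        for k in range(size):
            rows.append((f"{fam_id}_{k}", sire, dam, "F2", cross, fam_id))

    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "cross_type", "family"])
    return pedigree_from_frame(df)


def random_pedigree(n: int, seed: int = 0, n_founders: int = None) -> Pedigree:
    """A small random acyclic pedigree (for oracles and property tests)."""
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(4, n // 5)
    rows = []
    for i in range(n):
        if i < n_founders:
            rows.append((f"I{i}", "0", "0", "P1", "founder", "0"))
        else:
            s = int(rng.integers(0, i))
            d = int(rng.integers(0, i))
            while d == s:
                d = int(rng.integers(0, i))
            rows.append((f"I{i}", f"I{s}", f"I{d}", "F", "AxA", f"fam{s}_{d}"))
    return pedigree_from_frame(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "cross_type", "family"])
    )


def simulate_breeding_values(ped: Pedigree, G, seed: int = 0) -> np.ndarray:
    """Multivariate breeding values down the pedigree.

    Founders ~ N(0, G); offspring = parent average + Mendelian-sampling
    deviation with covariance G/2 scaled by 1 - (F_s + F_d)/2 (a missing
    parent contributes half the population variance instead).
    Returns an (n, T) array aligned with ``ped.ids``.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    T = G.shape[0]
    w, V = np.linalg.eigh(G)
    if np.any(w < -1e-8 * max(w.max(), 1)):
        raise ValueError("G must be positive semidefinite")
    Lfull = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rng = np.random.default_rng(seed)
    F = ped.inbreeding()
    n = ped.n
    bv = np.zeros((n, T))
    z = rng.standard_normal((n, T))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            bv[i] = Lfull @ z[i]
            continue
        mean = np.zeros(T)
        ms_scale = 0.0  # Mendelian sampling variance multiplier of G
        for p in (s, d):
            if p != UNKNOWN:
                mean += 0.5 * bv[p]
                ms_scale += 0.25 * (1.0 - F[p])
            else:
                ms_scale += 0.5  # unknown parent: its whole variance share
        # both parents known: ms_scale = 0.5 - (Fs+Fd)/4; one known: 0.75 - F_p/4
        bv[i] = mean + np.sqrt(ms_scale) * (Lfull @ z[i])
    return bv


DEFAULT_LIABILITY_CUTS_FREQS = (0.127, 0.117, 0.04)  # mature, parr, indeterminate


def _default_cuts(liab: np.ndarray) -> tuple:
    q1, q2, q3 = np.cumsum(DEFAULT_LIABILITY_CUTS_FREQS)
    return tuple(np.quantile(liab, [q1, q2, q3]))


def simulate_phenotypes(
    ped: Pedigree, cfg: SimulationConfig, seed: int = 0, bvs: np.ndarray = None
) -> pd.DataFrame:
    """Phenotype table for every non-founder in the pedigree.

    Each trait is mean + generation effect + cross-type effect + family
    effect N(0, Vf) + maternal effect N(0, Vm) + paternal effect N(0, Vs)
    + breeding value + residual.  A ``liability`` trait adds N(0,1) +
    logistic noise and, if named by ``cfg.liability_trait``, is cut into
    the four life-history classes.
    """
    traits = cfg.traits
    T = len(traits)
    if T == 0:
        raise ValueError("no traits configured")
    rng = np.random.default_rng(seed)
    Rg = np.eye(T) if cfg.genetic_corr is None else np.asarray(cfg.genetic_corr, float)
    sd = np.sqrt([t.Va for t in traits])
    G = Rg * np.outer(sd, sd)
    if bvs is None:
        bvs = simulate_breeding_values(ped, G, seed=int(rng.integers(2**31 - 1)))

    measured = ~ped.is_founder
    idx = np.flatnonzero(measured)
    n = len(idx)
    fam_codes, fams = pd.factorize(np.asarray(ped.family, dtype=object)[idx])
    dam_codes = ped.dam[idx]
    sire_codes = ped.sire[idx]
    gen = np.asarray(ped.generation, dtype=object)[idx]
    xtype = np.asarray(ped.cross_type, dtype=object)[idx]

    out = pd.DataFrame({"individual_id": [ped.ids[i] for i in idx]})
    out["generation"] = gen
    out["cross_type"] = xtype
    out["family"] = [fams[c] for c in fam_codes]
    liability_values = None

    for t_i, tr in enumerate(traits):
        y = np.full(n, tr.mean)
        y += np.array([tr.gen_effects.get(g, 0.0) for g in gen])
        y += np.array([tr.xtype_effects.get(x, 0.0) for x in xtype])
        if tr.Vf > 0:
            y += (np.sqrt(tr.Vf) * rng.standard_normal(len(fams)))[fam_codes]
        if tr.Vm > 0:
            eff = np.sqrt(tr.Vm) * rng.standard_normal(ped.n)
            y += np.where(dam_codes >= 0, eff[dam_codes], 0.0)
        if tr.Vs > 0:
            eff = np.sqrt(tr.Vs) * rng.standard_normal(ped.n)
            y += np.where(sire_codes >= 0, eff[sire_codes], 0.0)
        y += bvs[idx, t_i]
        if tr.distribution == "liability":
            y += rng.standard_normal(n)  # threshold-model residual, variance 1
            y += rng.logistic(0.0, 1.0, size=n)  # link noise, variance pi^2/3
        else:
            y += np.sqrt(tr.Vr) * rng.standard_normal(n)
        if tr.missing_rate > 0:
            y[rng.random(n) < tr.missing_rate] = np.nan
        out[tr.name] = y
        if cfg.liability_trait == tr.name:
            liability_values = y

    if liability_values is not None:
        cuts = cfg.liability_cuts or _default_cuts(liability_values)
        c1, c2, c3 = cuts
        cls = np.where(
            liability_values < c1,
            "mature",
            np.where(
                liability_values < c2,
                "parr",
                np.where(liability_values < c3, "indeterminate", "smolt"),
            ),
        ).astype(object)
        cls[np.isnan(liability_values)] = None
        out["life_history"] = cls
    return out


def study_simulation_config(scale: float = 1.0) -> SimulationConfig:
    """The default study-condition simulation: body sizes at three ages
    plus the shared life-history liability.

    Variance components follow the study's fitted estimates (e.g.
    mo24Length V_f=32.5, V_A=273.3, V_R=439.9; liability V_A=5.35,
    V_f=0.555 with the threshold-model residual); trait means match the
    observed phenotype summary (mo12Length 86.47 mm, ...).  Genetic
    correlations use a plausible positive structure among sizes and a
    moderate link to the liability, projected to the nearest correlation
    matrix.  ``scale`` shrinks the number of families while keeping the
    study's family sizes (88/137): per-family size is a design feature the
    analyses depend on (small families destabilize the threshold models),
    so proportional shrinking reduces the family count instead.
    """
    base = PedigreeConfig()
    if scale >= 1.0:
        ped = base
    else:
        ped = PedigreeConfig(
            f1_families={k: max(1, round(v * scale)) for k, v in base.f1_families.items()},
            f2_families={k: max(1, round(v * scale)) for k, v in base.f2_families.items()},
            f1_mean_size=base.f1_mean_size,
            f2_mean_size=base.f2_mean_size,
            n_dams_p1=max(6, int(base.n_dams_p1 * min(1.0, scale * 2))),
            n_sires_p1=max(6, int(base.n_sires_p1 * min(1.0, scale * 2))),
        )
    traits = [
        TraitSpec("mo12Length", mean=86.47, Va=17.87, Vf=7.6, Vr=87.4,
                  gen_effects={"F2": 3.0}),
        TraitSpec("mo12Weight", mean=7.46, Va=0.86, Vf=0.54, Vr=7.68,
                  gen_effects={"F2": 0.5}),
        TraitSpec("mo15Length", mean=168.65, Va=120.58, Vf=22.47, Vr=297.81,
                  gen_effects={"F2": 5.0}),
        TraitSpec("mo15Weight", mean=65.71, Va=111.52, Vf=34.05, Vr=613.52,
                  gen_effects={"F2": 4.0}),
        TraitSpec("mo24Length", mean=211.95, Va=273.26, Vf=32.51, Vr=439.9,
                  gen_effects={"F2": 6.0}),
        TraitSpec("mo24Weight", mean=107.44, Va=423.82, Vf=60.61, Vr=1514.7,
                  gen_effects={"F2": 8.0}),
        TraitSpec("AvgPix", mean=48.08, Va=232.51, Vf=0.0, Vr=578.65,
                  missing_rate=0.0),
        TraitSpec("lh_liability", Va=5.35, Vf=0.555, distribution="liability"),
    ]
    # genetic correlations: strong within age (length-weight), decaying
    # across ages, moderate liability links (longer fish more migratory)
    T = len(traits)
    C = np.eye(T)
    size_idx = list(range(6))
    age = [12, 12, 15, 15, 24, 24]
    for i in size_idx:
        for j in size_idx:
            if i != j:
                C[i, j] = 0.9 if age[i] == age[j] else 0.9 * 0.8 ** (abs(age[i] - age[j]) / 9)
    liab = T - 1
    pix = T - 2
    for i in size_idx:
        C[liab, i] = C[i, liab] = 0.45
    C[pix, liab] = C[liab, pix] = 0.8
    # nearest PSD projection, renormalized to unit diagonal
    w, V = np.linalg.eigh(C)
    C = V @ np.diag(np.clip(w, 1e-6, None)) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    return SimulationConfig(
        pedigree=ped,
        traits=traits,
        genetic_corr=C,
        liability_trait="lh_liability",
        liability_cuts=None,  # quantile cuts target the observed class rates
    )


# ---------------------------------------------------------------------------
# Landmark shapes

#: consensus 13-landmark left-side fish outline (arbitrary mm units),
#: numbered snout tip, top of head, dorsal-fin front/back, adipose fin,
#: dorsal peduncle, fork, ventral peduncle, anal fin, pelvic fin,
#: pectoral fin, lower opercle, lower jaw.
FISH_CONSENSUS = np.array(
    [
        [0.0, 0.0],
        [35.0, 18.0],
        [85.0, 24.0],
        [125.0, 20.0],
        [160.0, 14.0],
        [185.0, 6.0],
        [200.0, 0.0],
        [185.0, -6.0],
        [150.0, -14.0],
        [95.0, -20.0],
        [45.0, -18.0],
        [25.0, -12.0],
        [5.0, -6.0],
    ]
)


@dataclass
class LandmarkConfig:
    consensus: np.ndarray = None  # defaults to the fish outline
    # tangent-space (unit-centroid-size) variances per shape axis; the
    # default spectrum gives realistic ~2% rms shape variation
    axis_variances: tuple = (4e-4, 2e-4, 1e-4)
    scale_sd: float = 0.25  # lognormal sd of nuisance size
    noise_sd: float = 0.0  # isotropic per-landmark jitter (within tangent space it adds)


def simulate_landmarks(cfg: LandmarkConfig = None, n: int = 100, seed: int = 0):
    """Landmark configurations: consensus + tangent-space shape variation
    plus random rotation/translation/scale nuisance."""
    cfg = cfg or LandmarkConfig()
    cons = FISH_CONSENSUS if cfg.consensus is None else np.asarray(cfg.consensus, float)
    k = cons.shape[0]
    cons0 = cons - cons.mean(axis=0)
    cons0 = cons0 / np.sqrt((cons0**2).sum())
    B, _ = tangent_basis(cons0)  # (2k, 2k-4) orthonormal
    p = B.shape[1]
    var = np.asarray(cfg.axis_variances, float)
    if len(var) > p:
        raise ValueError(f"at most {p} shape axes for {k} landmarks")
    rng = np.random.default_rng(seed)
    shapes = []
    for i in range(n):
        dev = B[:, : len(var)] @ (np.sqrt(var) * rng.standard_normal(len(var)))
        X = cons0 + dev.reshape(k, 2)
        if cfg.noise_sd > 0:
            X = X + cfg.noise_sd * rng.standard_normal((k, 2))
        # similarity nuisance
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        s = 1800.0 * np.exp(cfg.scale_sd * rng.standard_normal())
        t = rng.uniform(-100, 100, size=2)
        shapes.append(LandmarkSet(individual_id=f"fish{i}", coordinates=s * X @ R.T + t))
    return shapes
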