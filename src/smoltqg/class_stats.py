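"""Life-history class comparisons, phenotypic correlations, and
discriminant classification.

ANOVA and Tukey-Kramer pairwise comparisons test trait differences among
the four life-history classes (mature / parr / indeterminate / smolt);
pairwise-complete correlation matrices use Pearson's coefficient for
quantitative pairs and Spearman's whenever a binary life-history trait is
involved; linear discriminant analysis asks how well the measured traits
predict the life-history class, scored as resubstitution accuracy with
proportional class priors (the convention behind the study's 87-90%
assignment rates; no cross-validation is applied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from smoltqg.reml import TestResult


def anova_by_class(data: pd.DataFrame, trait: str, class_col: str = "life_history") -> TestResult:
    """One-way F test of a trait across life-history classes."""
    sub = data[[trait, class_col]].dropna()
    groups = [g[trait].to_numpy() for _, g in sub.groupby(class_col) if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two classes with >= 2 observations")
    F, p = stats.f_oneway(*groups)
    df = len(groups) - 1
    return TestResult(statistic=float(F), df=df, p_value=float(p), kind="ANOVA-F")


def tukey_kramer(
    data: pd.DataFrame, trait: str, class_col: str = "life_history", alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise class comparisons with the Tukey-Kramer adjustment.

    Unequal group sizes use Kramer's standard errors on the pooled
    within-class variance.  Returns a tidy frame (group1, group2,
    meandiff, p_adj, lower, upper, reject).
    """
    sub = data[[trait, class_col]].dropna()
    counts = sub[class_col].value_counts()
    keep = counts[counts >= 2].index
    sub = sub[sub[class_col].isin(keep)]
    if sub[class_col].nunique() < 2:
        raise ValueError("Tukey-Kramer needs at least two classes")
    res = pairwise_tukeyhsd(sub[trait].to_numpy(), sub[class_col].to_numpy(), alpha=alpha)
    import itertools

    pairs = list(itertools.combinations(res.groupsunique, 2))
    ci = res.confint
    return pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "lower": ci[:, 0],
            "upper": ci[:, 1],
            "reject": res.reject,
        }
    )


@dataclass
class CorrelationMatrix:
    traits: list
    estimates: pd.DataFrame  # symmetric, unit diagonal
    p_values: pd.DataFrame
    n: pd.DataFrame
    methods: pd.DataFrame  # 'pearson' | 'spearman' per pair

    def n_significant(self, alpha: float = 0.05) -> int:
        """Count of significant off-diagonal pairs (each pair once)."""
        ps = self.p_values.to_numpy()
        iu = np.triu_indices_from(ps, k=1)
        vals = ps[iu]
        return int(np.sum(vals[~np.isnan(vals)] < alpha))

    def n_pairs(self) -> int:
        t = len(self.traits)
        return t * (t - 1) // 2

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.traits):
            for j in range(i + 1, len(self.traits)):
                b = self.traits[j]
                rows.append(
                    (a, b, self.methods.iloc[i, j], self.estimates.iloc[i, j],
                     self.p_values.iloc[i, j], self.n.iloc[i, j])
                )
        return pd.DataFrame(rows, columns=["trait1", "trait2", "method", "r", "p", "n"])


def correlation_matrix(
    data: pd.DataFrame, traits, binary_traits=("LHSmolt", "LHMature"), min_n: int = 3
) -> CorrelationMatrix:
    """Pairwise-complete trait correlations.

    Pearson for quantitative pairs; Spearman whenever a binary
    life-history trait is in the pair.  Constant columns yield missing
    cells with a warning.
    """
    import warnings

    traits = list(traits)
    t = len(traits)
    est = np.full((t, t), np.nan)
    pv = np.full((t, t), np.nan)
    nn = np.zeros((t, t), dtype=int)
    meth = np.empty((t, t), dtype=object)
    np.fill_diagonal(est, 1.0)
    np.fill_diagonal(pv, 0.0)
    for i in range(t):
        nn[i, i] = data[traits[i]].notna().sum()
        for j in range(i + 1, t):
            a, b = traits[i], traits[j]
            sub = data[[a, b]].dropna()
            method = "spearman" if (a in binary_traits or b in binary_traits) else "pearson"
            meth[i, j] = meth[j, i] = method
            nn[i, j] = nn[j, i] = len(sub)
            if len(sub) < min_n:
                continue
            if sub[a].nunique() < 2 or sub[b].nunique() < 2:
                warnings.warn(f"constant column in pair ({a}, {b}); cell left missing",
                              stacklevel=2)
                continue
            if method == "pearson":
                r, p = stats.pearsonr(sub[a], sub[b])
            else:
                r, p = stats.spearmanr(sub[a], sub[b])
            est[i, j] = est[j, i] = r
            pv[i, j] = pv[j, i] = p
    mk = lambda m: pd.DataFrame(m, index=traits, columns=traits)
    return CorrelationMatrix(traits, mk(est), mk(pv), mk(nn), mk(meth))


@dataclass
class DiscriminantModel:
    lda: LinearDiscriminantAnalysis
    predictors: list
    classes: np.ndarray
    n: int


def fit_dfa(data: pd.DataFrame, predictors, class_col: str = "life_history") -> DiscriminantModel:
    """Linear discriminant analysis of life history on complete cases.

    Rows missing any predictor or the class are removed (the complete-case
    convention); class priors are proportional to observed frequencies.
    """
    predictors = list(predictors)
    sub = data[predictors + [class_col]].dropna()
    y = sub[class_col].to_numpy()
    X = sub[predictors].to_numpy(float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if np.any(counts <= len(predictors)):
        small = classes[counts <= len(predictors)].tolist()
        raise ValueError(f"classes with fewer cases than predictors: {small}")
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(X, y)
    # aliased (collinear) predictors surface as near-zero singular values
    return DiscriminantModel(lda=lda, predictors=predictors, classes=classes, n=len(sub))


def classify_and_score(model: DiscriminantModel, data: pd.DataFrame,
                       class_col: str = "life_history"):
    """Hard assignments plus percent correctly assigned (resubstitution).

    Returns ``(predictions_frame, accuracy_percent, confusion_matrix)``.
    """
    sub = data[model.predictors + [class_col]].dropna()
    X = sub[model.predictors].to_numpy(float)
    y = sub[class_col].to_numpy()
    pred = model.lda.predict(X)
    post = model.lda.predict_proba(X)
    acc = 100.0 * float(np.mean(pred == y))
    conf = pd.crosstab(pd.Series(y, name="observed"), pd.Series(pred, name="predicted"))
    frame = pd.DataFrame(
        {"observed": y, "predicted": pred},
        index=sub.index,
    )
    for k, c in enumerate(model.lda.classes_):
        frame[f"p_{c}"] = post[:, k]
    return frame, acc, conf
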