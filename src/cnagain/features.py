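"""Elastic-net biomarker selection for drug response.

Models per-compound AUC from binary genomic features (mutations; gain, loss
and amplification indicators per genomic bin; one-hot cancer type and subtype)
with cross-validated elastic net, run in replicate; only features selected in
every replicate are reported as stable, and each is separately tested in an
ANOVA containing only cancer type, subtype and that feature.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from ._stats import estimate_qvalues

logger = logging.getLogger(__name__)

TYPE_PREFIXES = ("type_", "subtype_")


@dataclass
class ElasticNetConfig:
    """Cross-validation settings for the selection procedure.

    `alpha_grid` is the l1/l2 mixing grid (glmnet's alpha); the regularisation
    path (glmnet's lambda) is chosen by `lambda_rule`: 'one_se' (default) takes
    the strongest penalty within one standard error of the CV minimum, 'cv_min'
    the CV-minimising penalty. The one-SE rule is the default because the
    CV-minimum model routinely carries dozens of small noise coefficients that
    survive replicate intersection (replicates share the data and differ only
    in fold assignment), defeating the stability intent of the triplicate.
    """

    alpha_grid: tuple = (0.1, 0.5, 0.9)
    lambda_rule: str = "one_se"
    folds: int = 5
    replicates: int = 3
    n_lambdas: int = 50
    standardize: bool = False

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.lambda_rule not in ("cv_min", "one_se"):
            raise ValueError("lambda_rule must be 'cv_min' or 'one_se'")


def build_feature_matrix(
    mutations: pd.DataFrame | None,
    bin_states: pd.DataFrame | None,
    amp_calls: pd.DataFrame | None,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Binary feature matrix over the cell lines shared by all inputs.

    Columns carry kind prefixes: ``mut_<gene>``, ``bin_gain_<bin>``,
    ``bin_loss_<bin>``, ``bin_amp_<bin>``, ``type_<t>``, ``subtype_<s>``.
    Gain/loss indicators come from a categorical state matrix (values in
    {gain, loss, neutral, missing}); amplification indicators are encoded
    independently of gain. Constant columns are dropped with a log message.
    """
    parts = [metadata.index]
    for df in (mutations, bin_states, amp_calls):
        if df is not None:
            parts.append(df.index)
    lines = parts[0]
    for idx in parts[1:]:
        lines = lines.intersection(idx)
    if len(lines) == 0:
        raise ValueError("no cell lines shared across inputs")
    blocks = []
    if mutations is not None:
        blocks.append(mutations.loc[lines].astype(int).add_prefix("mut_"))
    if bin_states is not None:
        st = bin_states.loc[lines]
        blocks.append((st == "gain").astype(int).add_prefix("bin_gain_"))
        blocks.append((st == "loss").astype(int).add_prefix("bin_loss_"))
    if amp_calls is not None:
        blocks.append(amp_calls.loc[lines].astype(int).add_prefix("bin_amp_"))
    meta = metadata.loc[lines]
    for col, prefix in (("type", "type_"), ("subtype", "subtype_")):
        if col in meta.columns:
            blocks.append(pd.get_dummies(meta[col], prefix=prefix.rstrip("_")).astype(int))
    X = pd.concat(blocks, axis=1)
    constant = X.columns[X.nunique() <= 1]
    if len(constant):
        logger.info("dropping %d constant feature columns", len(constant))
        X = X.drop(columns=constant)
    return X


def elastic_net_select(
    X: pd.DataFrame, y: pd.Series, config: ElasticNetConfig, seed: int
) -> pd.DataFrame:
    """One replicate of CV elastic-net selection.

    Fits the CV path over the alpha grid and lambda path with `folds`-fold CV
    (fold assignment seeded by `seed`), refits at the chosen penalty, and
    returns the nonzero features with coefficients and signs. The response is
    centred per compound; binary predictors are left unstandardised so
    indicator coefficients stay interpretable (`config.standardize` switches).
    A constant response yields an empty selection with a warning.
    """
    y = y.loc[X.index].astype(float)
    mask = y.notna()
    Xv, yv = X.loc[mask].to_numpy(dtype=float), y.loc[mask].to_numpy()
    if len(yv) <= config.folds:
        raise ValueError("need more observations than CV folds")
    if np.std(yv) == 0:
        logger.warning("constant response; empty selection")
        return pd.DataFrame(columns=["coef", "sign"])
    if config.standardize:
        sd = Xv.std(axis=0)
        sd[sd == 0] = 1.0
        Xv = (Xv - Xv.mean(axis=0)) / sd
    yc = yv - yv.mean()
    cv = KFold(n_splits=config.folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=list(config.alpha_grid),
        alphas=config.n_lambdas,
        cv=cv,
        fit_intercept=True,
        max_iter=5000,
    )
    model.fit(Xv, yc)
    if config.lambda_rule == "one_se":
        li = list(model.l1_ratio).index(model.l1_ratio_) if np.ndim(model.l1_ratio) else 0
        mse = model.mse_path_[li] if model.mse_path_.ndim == 3 else model.mse_path_
        mean = mse.mean(axis=1)
        se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
        alphas = model.alphas_[li] if model.alphas_.ndim == 2 else model.alphas_
        best = int(np.argmin(mean))
        limit = mean[best] + se[best]
        admissible = np.where(mean <= limit)[0]
        lam = float(alphas[admissible].max())
        final = ElasticNet(alpha=lam, l1_ratio=model.l1_ratio_, fit_intercept=True, max_iter=5000)
        final.fit(Xv, yc)
        coefs = final.coef_
    else:
        coefs = model.coef_
    nz = np.flatnonzero(coefs)
    out = pd.DataFrame(
        {"coef": coefs[nz], "sign": np.sign(coefs[nz]).astype(int)},
        index=X.columns[nz],
    )
    out.index.name = "feature"
    return out


def intersect_replicates(replicate_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Features selected in every replicate, with consistent signs.

    Features whose coefficient sign flips across replicates are dropped with a
    warning. Returns feature -> (sign, present_in_replicates).
    """
    if not replicate_sets:
        return pd.DataFrame(columns=["sign", "present_in_replicates"])
    common = set(replicate_sets[0].index)
    for rep in replicate_sets[1:]:
        common &= set(rep.index)
    rows = []
    for feat in sorted(common):
        signs = {int(rep.loc[feat, "sign"]) for rep in replicate_sets}
        if len(signs) > 1:
            logger.warning("feature %r has conflicting signs across replicates; dropped", feat)
            continue
        rows.append((feat, signs.pop(), len(replicate_sets)))
    return pd.DataFrame(
        rows, columns=["feature", "sign", "present_in_replicates"]
    ).set_index("feature")


def select_stable_features(
    X: pd.DataFrame, y: pd.Series, config: ElasticNetConfig, seeds
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Run the replicate elastic nets and intersect the selections.

    `seeds` supplies one fold-assignment seed per replicate. Cancer type and
    subtype indicators stay in the models but are excluded from the reported
    stable list.
    """
    seeds = list(seeds)
    if len(seeds) != config.replicates:
        raise ValueError("need exactly one seed per replicate")
    reps = [elastic_net_select(X, y, config, seed) for seed in seeds]
    stable = intersect_replicates(reps)
    keep = [f for f in stable.index if not f.startswith(TYPE_PREFIXES)]
    return stable.loc[keep], reps


def _is_collinear_with(feature: np.ndarray, design: np.ndarray) -> bool:
    coef, *_ = np.linalg.lstsq(design, feature, rcond=None)
    resid = feature - design @ coef
    return float(np.abs(resid).max()) < 1e-8


def feature_anova(
    y: pd.Series, cancer_type: pd.Series, subtype: pd.Series, feature: pd.Series
) -> float:
    """ANOVA p-value for one feature after cancer type and subtype.

    Fits AUC ~ type + subtype + feature by OLS and returns the type-II ANOVA
    p-value of the feature term. Returns NaN (untestable) when the feature is
    constant or exactly collinear with the type/subtype design within the
    tested lines.
    """
    df = pd.DataFrame(
        {"y": y, "ctype": cancer_type, "subtype": subtype, "feat": feature}
    ).dropna()
    x = df["feat"].to_numpy(dtype=float)
    if np.std(x) == 0:
        return float("nan")
    design = pd.get_dummies(df[["ctype", "subtype"]].astype(str)).to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(df)), design])
    if _is_collinear_with(x, design):
        return float("nan")
    model = smf.ols("y ~ C(ctype) + C(subtype) + feat", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return float(table.loc["feat", "PR(>F)"])


def anova_qvalues(pairs: pd.DataFrame) -> pd.DataFrame:
    """q-values over a collection of (compound, feature) ANOVA p-values."""
    out = pairs.copy()
    out["anova_q"] = estimate_qvalues(out["anova_p"].to_numpy())
    return out
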