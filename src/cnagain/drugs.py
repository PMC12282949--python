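"""Copy-number status of compound targets (and arbitrary genomic bins) versus
drug response, on-target flags, expression correlates and positional enrichment.

AUC follows the large-screen convention: higher area under the dose-response
curve means more resistant, so a negative AUC difference (gained minus
non-gained lines) indicates increased sensitivity with gain.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import estimate_qvalues, welch_ttest
from .calling import GAIN_STATUSES

logger = logging.getLogger(__name__)

NO_GAIN_STATUSES = ("neutral", "loss")


def _direction(delta: float) -> str:
    if not np.isfinite(delta) or delta == 0:
        return "none"
    return "sensitivity" if delta < 0 else "resistance"


def target_gain_response(
    auc: pd.DataFrame,
    status: pd.DataFrame,
    annotation: pd.DataFrame,
    min_group: int = 2,
    q_sig: float = 0.1,
) -> pd.DataFrame:
    """Per-(compound, target) Welch t-test of AUC, low-amplitude gain vs no gain.

    Lines are grouped by the target gene's status: low-amplitude gain
    (arm-level + focal) versus no gain (neutral + loss); amplified lines are
    excluded as their own class. Multi-target compounds yield one record per
    pair. q-values run across all tested pairs; `significant` applies q <
    `q_sig`. Compounds without an annotated target are skipped.
    """
    lines = auc.index.intersection(status.index)
    rows = []
    for r in annotation.itertuples():
        if r.compound not in auc.columns:
            continue
        if r.target not in status.columns:
            logger.info("target %r not in status matrix; skipped", r.target)
            continue
        st = status.loc[lines, r.target]
        resp = auc.loc[lines, r.compound]
        a = resp[st.isin(GAIN_STATUSES) & resp.notna()]
        b = resp[st.isin(NO_GAIN_STATUSES) & resp.notna()]
        if len(a) < min_group or len(b) < min_group:
            rows.append((r.compound, r.target, len(a), len(b), np.nan, np.nan, "none"))
            continue
        delta, _t, p = welch_ttest(a, b)
        rows.append((r.compound, r.target, len(a), len(b), delta, p, _direction(delta)))
    out = pd.DataFrame(
        rows, columns=["compound", "target", "n_gain", "n_nogain", "delta_auc", "p", "direction"]
    )
    out["q"] = estimate_qvalues(out["p"].to_numpy())
    out["significant"] = out["q"] < q_sig
    return out


def on_target_compounds(
    auc: pd.DataFrame,
    dep: pd.DataFrame,
    annotation: pd.DataFrame,
    r_min: float = 0.3,
    p_max: float = 1e-10,
    min_lines: int = 30,
) -> pd.DataFrame:
    """Flag compounds whose response tracks dependency on their annotated target.

    A compound is on-target when the Pearson correlation between target-gene
    dependency score and AUC over shared lines satisfies r > `r_min` AND
    p < `p_max` (both required). More dependent (negative score) lines being
    more sensitive (low AUC) gives a positive r. Pairs with fewer than
    `min_lines` shared lines are untestable.
    """
    rows = []
    for r in annotation.itertuples():
        if r.compound not in auc.columns or r.target not in dep.columns:
            rows.append((r.compound, r.target, 0, np.nan, np.nan, False, False))
            continue
        joined = pd.concat(
            [dep[r.target].rename("dep"), auc[r.compound].rename("auc")], axis=1, join="inner"
        ).dropna()
        n = len(joined)
        if n < min_lines:
            rows.append((r.compound, r.target, n, np.nan, np.nan, False, False))
            continue
        corr, p = stats.pearsonr(joined["dep"], joined["auc"])
        rows.append((r.compound, r.target, n, corr, p, bool(corr > r_min and p < p_max), True))
    return pd.DataFrame(
        rows, columns=["compound", "target", "n_lines", "r_dep_auc", "p_corr", "on_target", "testable"]
    )


def direction_summary(records: pd.DataFrame, on_target: pd.DataFrame | None = None) -> pd.DataFrame:
    """Counts of significant sensitivity/resistance associations, overall and on-target."""
    rec = records.copy()
    if on_target is not None:
        flags = on_target.set_index(["compound", "target"])["on_target"]
        rec = rec.join(flags, on=["compound", "target"])
        rec["on_target"] = rec["on_target"].fillna(False)
    else:
        rec["on_target"] = False
    if "significant" in rec.columns:
        mask = rec["significant"].fillna(False).astype(bool)
    else:
        mask = pd.Series(False, index=rec.index)
    sig = rec[mask]
    rows = []
    screens = sig["screen"].unique() if "screen" in sig.columns else ["all"]
    for screen in screens:
        sub = sig if screen == "all" else sig[sig["screen"] == screen]
        rows.append(
            (
                screen,
                int((sub["direction"] == "sensitivity").sum()),
                int((sub["direction"] == "resistance").sum()),
                int(((sub["direction"] == "sensitivity") & sub["on_target"]).sum()),
                int(((sub["direction"] == "resistance") & sub["on_target"]).sum()),
            )
        )
    if not rows:
        rows = [("all", 0, 0, 0, 0)]
    return pd.DataFrame(
        rows,
        columns=["screen", "n_sensitivity", "n_resistance",
                 "n_sensitivity_on_target", "n_resistance_on_target"],
    )


def region_drug_screen(
    gained: pd.Series, auc: pd.DataFrame, min_group: int = 2
) -> pd.DataFrame:
    """Every compound tested against one genomic region's gain status.

    `gained` is a boolean per-line indicator for the region (e.g. one bin's
    gain call). Welch t-test per compound, gained vs not; volcano-ready
    output with q-values. Compounds with a degenerate group are untestable.
    """
    lines = gained.index.intersection(auc.index)
    g = gained.loc[lines].astype(bool)
    rows = []
    for compound in auc.columns:
        resp = auc.loc[lines, compound]
        a = resp[g & resp.notna()]
        b = resp[~g & resp.notna()]
        if len(a) < min_group or len(b) < min_group:
            rows.append((compound, len(a), len(b), np.nan, np.nan, "none", False))
            continue
        delta, _t, p = welch_ttest(a, b)
        rows.append((compound, len(a), len(b), delta, p, _direction(delta), True))
    out = pd.DataFrame(
        rows, columns=["compound", "n_gain", "n_nogain", "delta_auc", "p", "direction", "testable"]
    ).set_index("compound")
    out["q"] = estimate_qvalues(out["p"].to_numpy())
    return out


def region_compound_grid(
    bin_gained: pd.DataFrame, auc: pd.DataFrame, compounds=None, min_group: int = 2
) -> pd.DataFrame:
    """Signed -log10 p grid over (bin, compound) pairs for heatmap-style views.

    Positive values mean resistance with gain (positive AUC difference),
    negative values sensitivity; untestable pairs are NaN.
    """
    compounds = list(compounds) if compounds is not None else list(auc.columns)
    out = pd.DataFrame(np.nan, index=bin_gained.columns, columns=compounds)
    for b in bin_gained.columns:
        rec = region_drug_screen(bin_gained[b], auc[compounds], min_group=min_group)
        signed = np.sign(rec["delta_auc"]) * (-np.log10(np.clip(rec["p"], np.finfo(float).tiny, None)))
        out.loc[b, :] = signed.where(rec["testable"]).to_numpy()
    return out


def expression_response_correlates(
    expression: pd.DataFrame,
    auc: pd.Series,
    gene_arm: pd.Series,
    target_arm: str,
    q_max: float = 0.05,
    min_lines: int = 30,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene expression-response correlation and positional arm enrichment.

    Correlates each gene's expression with one compound's AUC (Pearson) over
    shared lines, computes q-values, then tests whether significant correlates
    are enriched on `target_arm` ("chrom:arm" key in `gene_arm`) with a Fisher
    exact test on the 2x2 (significant x on-arm) table. Constant-expression
    genes are skipped.
    """
    lines = expression.index.intersection(auc.dropna().index)
    if len(lines) < min_lines:
        raise ValueError(f"only {len(lines)} shared lines; need >= {min_lines}")
    y = auc.loc[lines].to_numpy(dtype=float)
    rows = []
    for gene in expression.columns:
        x = expression.loc[lines, gene].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            logger.info("gene %r has constant expression; skipped", gene)
            continue
        corr, p = stats.pearsonr(x, y)
        rows.append((gene, corr, min(max(p, np.finfo(float).tiny), 1.0)))
    rec = pd.DataFrame(rows, columns=["gene", "r", "p"]).set_index("gene")
    rec["q"] = estimate_qvalues(rec["p"].to_numpy())
    rec["significant"] = rec["q"] < q_max
    on_arm = gene_arm.reindex(rec.index) == target_arm
    if on_arm.sum() == 0:
        return rec, {"testable": False, "odds_ratio": np.nan, "p": np.nan}
    a = int((rec["significant"] & on_arm).sum())
    b = int((rec["significant"] & ~on_arm).sum())
    c = int((~rec["significant"] & on_arm).sum())
    d = int((~rec["significant"] & ~on_arm).sum())
    oddsratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    enrichment = {
        "testable": True,
        "n_sig_on_arm": a,
        "n_sig_off_arm": b,
        "odds_ratio": float(oddsratio),
        "p": float(p),
    }
    return rec, enrichment
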