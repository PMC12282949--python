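"""Gene copy-number status versus CRISPR/RNAi dependency: differential tests,
confounder filtering, ranking, preranked gene-set enrichment, cross-dataset
candidate selection, mutation co-occurrence and expression checks.

Dependency scores follow the screening convention: more negative means the
cell line is more dependent on the gene, so a negative group-mean difference
(gain minus neutral) indicates increased dependency in gained lines.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import estimate_qvalues, welch_ttest
from .calling import GAIN_STATUSES

logger = logging.getLogger(__name__)

CONTRASTS = {
    "combined": GAIN_STATUSES,          # low-amplitude gain: arm-level + focal
    "arm_only": ("arm_gain",),
}


def differential_dependency(
    dep: pd.DataFrame,
    status: pd.DataFrame,
    contrast: str = "combined",
    min_group: int = 2,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test of dependency, gained versus neutral lines.

    The gain group is the low-amplitude-gain classes (`contrast="combined"`,
    arm-level plus focal) or arm-level only (`contrast="arm_only"`); the
    reference group is neutral copy number. Loss and amplification lines are
    excluded from both groups. Welch's unequal-variance test by default
    (`pooled=True` switches to the pooled-variance form). Genes with fewer
    than `min_group` lines in either group get NaN statistics; q-values are
    estimated across the genes actually tested.

    Returns a table indexed by gene: n_gain, n_neutral, delta (gain - neutral
    mean), t_stat, p, q.
    """
    gain_states = CONTRASTS[contrast]
    genes = [g for g in dep.columns if g in status.columns]
    skipped = set(dep.columns) - set(genes)
    if skipped:
        logger.info("skipping %d genes absent from the status matrix", len(skipped))
    lines = dep.index.intersection(status.index)
    scores = dep.loc[lines, genes].to_numpy(dtype=float)
    st = status.loc[lines, genes].to_numpy(dtype=object)
    finite = np.isfinite(scores)
    in_gain = np.isin(st, gain_states) & finite
    in_neut = (st == "neutral") & finite
    # vectorised Welch/pooled t across all genes; masked group moments
    n_a = in_gain.sum(axis=0)
    n_b = in_neut.sum(axis=0)
    valid = (n_a >= min_group) & (n_b >= min_group)

    def _moments(mask):
        n = mask.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(mask, scores, 0.0).sum(axis=0) / n
            ss = np.where(mask, (scores - mean) ** 2, 0.0).sum(axis=0)
            var = ss / np.maximum(n - 1, 1)
        return n, mean, var

    na, ma, va = _moments(in_gain)
    nb, mb, vb = _moments(in_neut)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = ma - mb
        if pooled:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = sp2 * (1 / na + 1 / nb)
            df = na + nb - 2
        else:
            se2 = va / na + vb / nb
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = delta / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    delta = np.where((n_a > 0) & (n_b > 0), delta, np.nan)
    t = np.where(valid, t, np.nan)
    p = np.where(valid, p, np.nan)
    out = pd.DataFrame(
        {"n_gain": n_a, "n_neutral": n_b, "delta": delta, "t_stat": t, "p": p},
        index=pd.Index(genes, name="gene"),
    )
    out["q"] = estimate_qvalues(out["p"].to_numpy())
    return out


def filter_confounded(
    records: pd.DataFrame, importance: pd.Series, cutoff: float = 0.05
) -> pd.DataFrame:
    """Drop genes whose combined experimental-confounder importance exceeds `cutoff`.

    `importance` maps gene -> combined importance of experimental confounders
    in the best external prediction model for that gene (consumed as an input
    table). Strictly greater than the cutoff removes; genes absent from the
    table are retained with a log message.
    """
    imp = importance.reindex(records.index)
    missing = imp.isna().sum()
    if missing:
        logger.info("%d genes missing from confounder table; retained", missing)
    keep = ~(imp > cutoff)
    return records[keep]


def rank_genes(records: pd.DataFrame) -> pd.Series:
    """Signed significance ranking: sign(delta) * -log10(q), sorted descending.

    Zero q-values are clamped to the smallest positive float. Ties are broken
    by |delta| (larger first) and then gene label for a deterministic order.
    """
    rec = records.dropna(subset=["q", "delta"])
    q = rec["q"].to_numpy(dtype=float)
    n_zero = (q == 0).sum()
    if n_zero:
        logger.info("clamped %d zero q-values to float tiny", n_zero)
    q = np.clip(q, np.finfo(float).tiny, None)
    metric = np.sign(rec["delta"].to_numpy()) * (-np.log10(q))
    order = pd.DataFrame(
        {"metric": metric, "absdelta": rec["delta"].abs(), "gene": rec.index}
    )
    order = order.sort_values(
        ["metric", "absdelta", "gene"], ascending=[False, False, True], kind="mergesort"
    )
    return pd.Series(order["metric"].to_numpy(), index=order["gene"].to_numpy(), name="metric")


def _running_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score for a sorted membership mask."""
    w_hit = np.where(in_set, weights, 0.0)
    hit_total = w_hit.sum()
    n_miss = (~in_set).sum()
    if hit_total == 0 or n_miss == 0:
        return 0.0
    p_hit = np.cumsum(w_hit) / hit_total
    p_miss = np.cumsum(~in_set) / n_miss
    run = p_hit - p_miss
    return float(run[np.argmax(np.abs(run))])


def gsea_preranked(
    ranked: pd.Series, sets: dict, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Preranked gene-set enrichment on a signed metric.

    `ranked` is a gene -> metric series sorted descending. The enrichment
    score is the weighted Kolmogorov-Smirnov running-sum statistic with weight
    |metric|; negative scores mean enrichment at the negative
    (more-dependent-when-gained) end. NES and the permutation p-value come
    from `n_perm` seeded gene-label permutations (random sets of the same
    size). Sets with no overlap with the ranked list are flagged untestable.
    """
    ranked = ranked.sort_values(ascending=False, kind="mergesort")
    genes = ranked.index.to_numpy()
    weights = np.abs(ranked.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets.items():
        members = set(members)
        in_set = np.fromiter((g in members for g in genes), bool, len(genes))
        k = int(in_set.sum())
        if k == 0 or k == len(genes):
            rows.append((name, k, np.nan, np.nan, np.nan, False))
            continue
        es = _running_es(in_set, weights)
        perm_es = np.empty(n_perm)
        mask = np.zeros(len(genes), dtype=bool)
        for b in range(n_perm):
            mask[:] = False
            mask[rng.choice(len(genes), size=k, replace=False)] = True
            perm_es[b] = _running_es(mask, weights)
        same_sign = perm_es * np.sign(es) > 0
        denom = max(int(same_sign.sum()), 1)
        p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + denom)
        mean_same = np.abs(perm_es[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
        rows.append((name, k, es, nes, p, True))
    return pd.DataFrame(
        rows, columns=["set", "n_members", "ES", "NES", "p", "testable"]
    ).set_index("set")


def select_candidates(
    datasets: dict,
    q_max: float = 0.3,
    delta_max: float = -0.05,
    min_datasets: int = 2,
) -> pd.DataFrame:
    """Cross-dataset candidate driver genes.

    A gene is listed when it shows q < `q_max` and dependency difference
    delta < `delta_max` in at least `min_datasets` of the supplied association
    tables (dataset name -> differential_dependency output). Per-dataset
    evidence columns are retained; the result is invariant to dataset order.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    names = sorted(datasets)
    all_genes = sorted(set().union(*(d.index for d in datasets.values())))
    ev = pd.DataFrame(index=all_genes)
    sig = pd.DataFrame(False, index=all_genes, columns=names)
    for name in names:
        rec = datasets[name].reindex(all_genes)
        ev[f"q_{name}"] = rec["q"]
        ev[f"delta_{name}"] = rec["delta"]
        sig[name] = (rec["q"] < q_max) & (rec["delta"] < delta_max)
    ev["n_datasets_significant"] = sig.sum(axis=1)
    out = ev[ev["n_datasets_significant"] >= min_datasets].copy()
    out.index.name = "gene"
    return out.sort_index()


def mutation_gain_cooccurrence(mutations: pd.DataFrame, status: pd.DataFrame) -> pd.DataFrame:
    """Fisher exact test of mutation versus low-amplitude gain per gene.

    Builds the 2x2 (mutated x gained) table over shared samples; an odds ratio
    above 1 labels the gene co-occurring, below 1 exclusive. Degenerate
    margins (all/none mutated or gained) are flagged untestable.
    """
    samples = mutations.index.intersection(status.index)
    genes = [g for g in mutations.columns if g in status.columns]
    rows = []
    for gene in genes:
        mut = mutations.loc[samples, gene].astype(bool)
        gained = status.loc[samples, gene].isin(GAIN_STATUSES)
        a = int((mut & gained).sum())
        b = int((mut & ~gained).sum())
        c = int((~mut & gained).sum())
        d = int((~mut & ~gained).sum())
        if min(a + b, c + d, a + c, b + d) == 0:
            rows.append((gene, a, b, c, d, np.nan, np.nan, "untestable", False))
            continue
        oddsratio, p = stats.fisher_exact([[a, b], [c, d]])
        p = min(max(p, np.finfo(float).tiny), 1.0)
        direction = "co-occurring" if oddsratio > 1 else "exclusive"
        rows.append((gene, a, b, c, d, oddsratio, p, direction, True))
    out = pd.DataFrame(
        rows,
        columns=["gene", "mut_gain", "mut_nogain", "wt_gain", "wt_nogain",
                 "odds_ratio", "p", "direction", "testable"],
    ).set_index("gene")
    out["q"] = estimate_qvalues(out["p"].to_numpy())
    return out


def expression_by_gain_status(
    expression: pd.DataFrame, status: pd.DataFrame, q_max: float = 0.05, min_group: int = 2
) -> pd.DataFrame:
    """Label genes as upregulated in gained samples versus neutral.

    One-sided unequal-variance t-test (gain > neutral, directional claim);
    q < `q_max` across evaluable genes yields 'upregulated'; insufficient
    group sizes yield 'unevaluable'.
    """
    samples = expression.index.intersection(status.index)
    genes = [g for g in expression.columns if g in status.columns]
    rows = []
    for gene in genes:
        expr = expression.loc[samples, gene]
        st = status.loc[samples, gene]
        a = expr[st.isin(GAIN_STATUSES) & expr.notna()]
        b = expr[(st == "neutral") & expr.notna()]
        if len(a) < min_group or len(b) < min_group:
            rows.append((gene, len(a), len(b), np.nan, np.nan))
            continue
        delta, _t, p = welch_ttest(a, b, alternative="greater")
        rows.append((gene, len(a), len(b), delta, p))
    out = pd.DataFrame(
        rows, columns=["gene", "n_gain", "n_neutral", "delta", "p"]
    ).set_index("gene")
    out["q"] = estimate_qvalues(out["p"].to_numpy())
    label = np.where(out["p"].isna(), "unevaluable",
                     np.where(out["q"] < q_max, "upregulated", "not_upregulated"))
    out["label"] = label
    return out


def stratified_dependency(
    dep: pd.DataFrame,
    status: pd.DataFrame,
    stratum: pd.Series,
    contrast: str = "combined",
    min_group: int = 2,
) -> pd.DataFrame:
    """Differential dependency run separately within each stratum.

    `stratum` labels each sample (e.g. hotspot-mutant vs wild-type); strata
    with fewer than two samples are skipped with a log message. Returns the
    concatenated per-stratum association tables with a `stratum` column.
    """
    parts = []
    for label, samples in stratum.groupby(stratum).groups.items():
        samples = dep.index.intersection(samples)
        if len(samples) < 2:
            logger.info("stratum %r has <2 samples; skipped", label)
            continue
        rec = differential_dependency(
            dep.loc[samples], status.loc[status.index.intersection(samples)],
            contrast=contrast, min_group=min_group,
        )
        rec["stratum"] = label
        parts.append(rec)
    if not parts:
        return pd.DataFrame(
            columns=["n_gain", "n_neutral", "delta", "t_stat", "p", "q", "stratum"]
        )
    return pd.concat(parts)
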