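"""Discrete copy-number calls: gain/loss states, arm-level gains, sample-relative
amplifications, five-way per-gene status, and cohort frequency/z-score tracks.

All thresholds act on the ploidy-normalised log2 scale with strict
inequalities; a value exactly at a threshold falls in the lower category.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinCopyMatrix, GenomeBuild, SegmentedProfile

logger = logging.getLogger(__name__)

STATUSES = ["loss", "neutral", "arm_gain", "focal_gain", "amplification"]
GAIN_STATUSES = ("arm_gain", "focal_gain")


@dataclass(frozen=True)
class CallThresholds:
    """Log2-ratio thresholds for discrete calls.

    t_gain/t_loss separate gain and loss from neutral; arm_fraction is the
    minimum fraction of an arm's covered length that must exceed t_gain for an
    arm-level gain (>0.8 by default); amp_fallback classifies amplifications in
    samples without any gained arm.
    """

    t_gain: float = 0.1
    t_loss: float = -0.1
    arm_fraction: float = 0.8
    amp_fallback: float = 0.9

    def __post_init__(self):
        if not (self.t_loss < 0 < self.t_gain):
            raise ValueError("need t_loss < 0 < t_gain")
        if not (0 < self.arm_fraction < 1):
            raise ValueError("arm_fraction must lie in (0, 1)")


def call_states(matrix: BinCopyMatrix | pd.DataFrame, th: CallThresholds) -> pd.DataFrame:
    """Per-(sample, bin) state in {gain, loss, neutral, missing}.

    gain iff cn > t_gain, loss iff cn < t_loss (strict); NaN propagates as
    'missing'.
    """
    cn = matrix.cn if isinstance(matrix, BinCopyMatrix) else matrix
    vals = cn.to_numpy(dtype=float)
    out = np.full(vals.shape, "neutral", dtype=object)
    out[vals > th.t_gain] = "gain"
    out[vals < th.t_loss] = "loss"
    out[~np.isfinite(vals)] = "missing"
    return pd.DataFrame(out, index=cn.index, columns=cn.columns)


def call_arm_gains(profile: SegmentedProfile, build: GenomeBuild, th: CallThresholds) -> pd.DataFrame:
    """Arm-level gain calls for one sample.

    An arm is gained when the segment length with cn > t_gain exceeds
    `arm_fraction` of the arm length for which copy-number data are available
    (the covered length, not the full arm length). Arms with zero covered
    length are flagged missing.
    """
    rows = []
    for r in build.arms().itertuples():
        seg = profile.segments
        seg = seg[seg["chrom"] == r.chrom]
        ov = np.clip(
            np.minimum(seg["end"].to_numpy(), r.end) - np.maximum(seg["start"].to_numpy(), r.start),
            0,
            None,
        ).astype(float)
        covered = ov.sum()
        if covered == 0:
            rows.append((profile.sample_id, r.chrom, r.arm, np.nan, np.nan, False, True))
            continue
        cn_vals = seg["cn"].to_numpy()
        gained_len = ov[cn_vals > th.t_gain].sum()
        frac = gained_len / covered
        arm_cn = float((ov * cn_vals).sum() / covered)
        rows.append(
            (profile.sample_id, r.chrom, r.arm, arm_cn, frac, bool(frac > th.arm_fraction), False)
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "arm", "arm_cn", "covered_fraction_gained", "gained", "missing"],
    )


def arm_call_table(profiles, build: GenomeBuild, th: CallThresholds) -> pd.DataFrame:
    """Arm calls for a cohort, one row per (sample, chrom, arm)."""
    return pd.concat(
        [call_arm_gains(p, build, th) for p in profiles], ignore_index=True
    )


def max_armgain_cn(arm_table: pd.DataFrame) -> pd.Series:
    """Per-sample maximum weighted-mean copy number over gained arms (NaN if none)."""
    gained = arm_table[arm_table["gained"] & ~arm_table["missing"]]
    out = gained.groupby("sample")["arm_cn"].max()
    return out.reindex(arm_table["sample"].unique())


def call_amplifications(
    gene_cn: pd.DataFrame, arm_table: pd.DataFrame, th: CallThresholds
) -> pd.DataFrame:
    """Sample-relative amplification flags for a samples x genes copy-number table.

    A gene is amplified when its copy number strictly exceeds the highest
    whole-arm-gain copy number of the same sample; samples without any gained
    arm fall back to the absolute `amp_fallback` threshold. Missing gene copy
    numbers are never amplified.
    """
    maxarm = max_armgain_cn(arm_table).reindex(gene_cn.index)
    thresh = maxarm.fillna(th.amp_fallback).to_numpy()[:, None]
    vals = gene_cn.to_numpy(dtype=float)
    amp = np.isfinite(vals) & (vals > thresh)
    return pd.DataFrame(amp, index=gene_cn.index, columns=gene_cn.columns)


def classify_gene_status(
    gene_cn: pd.DataFrame,
    gene_arm: pd.Series,
    arm_table: pd.DataFrame,
    amp_flags: pd.DataFrame,
    th: CallThresholds,
) -> pd.DataFrame:
    """Five-way per-(sample, gene) status.

    Precedence: amplification > arm_gain (gene above t_gain AND its arm gained)
    > focal_gain (gene above t_gain) > loss (below t_loss) > neutral. A gene
    below t_gain on a gained arm stays neutral: the call reflects the gene's
    own copy number. Missing gene copy number yields 'missing'.

    `gene_arm` maps gene name -> "chrom:arm" key; `arm_table` comes from
    arm_call_table.
    """
    unknown = [g for g in gene_cn.columns if g not in gene_arm.index]
    if unknown:
        raise ValueError(f"genes without arm assignment: {unknown[:5]}")
    armkey = arm_table["chrom"].astype(str) + ":" + arm_table["arm"].astype(str)
    gained_wide = (
        arm_table.assign(key=armkey)
        .pivot_table(index="sample", columns="key", values="gained", aggfunc="first")
        .astype(bool)
    )
    samples = gene_cn.index
    arm_gained = np.zeros(gene_cn.shape, dtype=bool)
    for j, gene in enumerate(gene_cn.columns):
        key = gene_arm[gene]
        if key in gained_wide.columns:
            arm_gained[:, j] = gained_wide[key].reindex(samples).fillna(False).to_numpy()
    vals = gene_cn.to_numpy(dtype=float)
    amp = amp_flags.reindex(index=samples, columns=gene_cn.columns).to_numpy()
    status = np.full(vals.shape, "neutral", dtype=object)
    status[vals < th.t_loss] = "loss"
    is_gain = vals > th.t_gain
    status[is_gain] = "focal_gain"
    status[is_gain & arm_gained] = "arm_gain"
    status[amp & np.isfinite(vals)] = "amplification"
    status[~np.isfinite(vals)] = "missing"
    return pd.DataFrame(status, index=samples, columns=gene_cn.columns)


def cna_frequencies(states: pd.DataFrame) -> pd.DataFrame:
    """Per-bin gain/loss frequencies among non-missing samples."""
    if states.shape[1] < 2:
        raise ValueError("need at least 2 bins for a frequency track")
    n_obs = (states != "missing").sum(axis=0)
    with np.errstate(invalid="ignore"):
        f_gain = (states == "gain").sum(axis=0) / n_obs
        f_loss = (states == "loss").sum(axis=0) / n_obs
    return pd.DataFrame({"f_gain": f_gain, "f_loss": f_loss})


def frequency_zscores(track: pd.DataFrame) -> pd.DataFrame:
    """Z-scores of gain/loss frequencies across bins within the cohort.

    Standardises each bin's frequency against the mean and standard deviation
    over all bins; an all-equal track yields zeros with a warning. This
    cross-bin standardisation is a documented approximation of the original
    z-score derivation.
    """
    out = track.copy()
    for kind in ("gain", "loss"):
        f = track[f"f_{kind}"].to_numpy(dtype=float)
        sd = np.nanstd(f, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"zero variance in f_{kind}; z-scores set to 0")
            out[f"z_{kind}"] = 0.0
        else:
            out[f"z_{kind}"] = (f - np.nanmean(f)) / sd
    return out
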