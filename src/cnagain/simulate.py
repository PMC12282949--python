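"""Synthetic cohorts with planted copy-number, dependency, drug, mutation and
survival effects, plus a machine-readable truth ledger.

The generator emulates the statistical structure of segmented tumour/cell-line
copy-number profiles and the paired screening data: arm-level gains and losses,
focal low-amplitude gains, high-level amplifications, Gaussian segment noise on
the log2 scale, dependency/AUC matrices with status-dependent mean shifts,
mutations with a planted odds ratio against gain status, and exponential
survival with per-bin hazard ratios. Every planted effect is recorded in a
TruthTable so recovery tests consume only the ledger.

All genomic breakpoints are drawn on a fixed lattice (`segment_unit`, 100 kb by
default) so brute-force per-position oracles over lattice units agree exactly
with per-base arithmetic.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome import Chromosome, GenomeBuild, SegmentedProfile

logger = logging.getLogger(__name__)

MB = 1_000_000


def toy_build(n_chrom: int = 4, length: int = 120 * MB,
              cen_start: int = 55 * MB, cen_end: int = 65 * MB) -> GenomeBuild:
    """Default toy genome: 4 chromosomes of 120 Mb with centromeres around 60 Mb.

    Large enough to distinguish arm-level from focal events at 25-Mb and 1-Mb
    binning, small enough for brute-force oracles.
    """
    return GenomeBuild.from_chromosomes(
        Chromosome(f"chr{i + 1}", length, cen_start, cen_end) for i in range(n_chrom)
    )


def toy_genes(build: GenomeBuild | None = None, per_arm: int = 3,
              gene_length: int = 1 * MB) -> pd.DataFrame:
    """Evenly spaced synthetic genes, `per_arm` on every arm of the build."""
    build = build or toy_build()
    rows, k = [], 0
    for r in build.arms().itertuples():
        span = r.end - r.start
        for j in range(per_arm):
            start = r.start + int(span * (j + 1) / (per_arm + 1))
            rows.append((r.chrom, start, start + gene_length, f"G{k:03d}"))
            k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TruthTable:
    """Ledger of planted effects: one record per (kind, unit, value)."""

    def __init__(self):
        self.records: list[dict] = []

    def add(self, kind: str, unit: str, value) -> None:
        self.records.append({"kind": kind, "unit": unit, "value": value})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["kind", "unit", "value"])

    def lookup(self, kind: str) -> dict:
        return {r["unit"]: r["value"] for r in self.records if r["kind"] == kind}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        t = cls()
        with open(path) as fh:
            t.records = json.load(fh)
        return t


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Copy-number levels are ploidy-normalised log2 ratios: single-copy-scale
    gains/losses at +/-0.3, amplifications at +1.2, segment noise sd 0.1.
    Downstream effect defaults mirror the magnitudes the pipeline is meant to
    detect: a dependency ladder of -0.28 (focal) / -0.44 (arm) / -0.64
    (amplification) versus neutral, a drug-response AUC shift of -0.11 for a
    sensitivity biomarker, a mutation-gain odds ratio of 2.2, and a survival
    hazard ratio of 2.6 on one bin with a 40% event rate.
    """

    seed: int = 0
    n_samples: int = 200
    arm_gain_prob: float = 0.15
    arm_loss_prob: float = 0.10
    focal_rate: float = 0.8          # mean focal gains per sample
    focal_length: tuple = (2 * MB, 20 * MB)
    amp_rate: float = 0.1            # mean amplification events per sample
    amp_length: tuple = (1 * MB, 5 * MB)
    gain_level: float = 0.3
    loss_level: float = -0.3
    amp_level: float = 1.2
    noise_sd: float = 0.1
    extra_breaks: float = 2.0        # mean passenger breakpoints per arm
    segment_unit: int = 100_000
    dependency_sd: float = 0.3
    dependency_ladder: dict = field(
        default_factory=lambda: {"focal_gain": -0.28, "arm_gain": -0.44, "amplification": -0.64}
    )
    auc_baseline: float = 0.5
    auc_sd: float = 0.15
    drug_effect: float = -0.11
    mutation_rate: float = 0.2
    mutation_odds_ratio: float = 2.2
    hazard_ratio: float = 2.6
    base_hazard: float = 1.0 / 1000  # events per day at baseline
    event_rate: float = 0.4

    def build(self) -> GenomeBuild:
        return toy_build()


def _snap(x: float, unit: int) -> int:
    return int(round(x / unit)) * unit


def simulate_genomes(config: SimulationConfig, rng: np.random.Generator | None = None,
                     truth: TruthTable | None = None):
    """Segmented profiles with planted arm/focal/amplification events.

    Returns (profiles, events, truth): `events` is a per-sample table of the
    planted aberrations (sample, chrom, arm, kind, start, end, level) and
    `truth` the cumulative ledger including the generating rates.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = truth if truth is not None else TruthTable()
    build = config.build()
    arms = build.arms()
    truth.add("arm_gain_prob", "*", config.arm_gain_prob)
    truth.add("arm_loss_prob", "*", config.arm_loss_prob)
    unit = config.segment_unit
    profiles, event_rows = [], []
    for i in range(config.n_samples):
        sample = f"S{i:04d}"
        seg_rows = []
        arm_level: dict[tuple, float] = {}
        for r in arms.itertuples():
            u = rng.random()
            if u < config.arm_gain_prob:
                arm_level[(r.chrom, r.arm)] = config.gain_level
                event_rows.append((sample, r.chrom, r.arm, "arm_gain", r.start, r.end,
                                   config.gain_level))
            elif u < config.arm_gain_prob + config.arm_loss_prob:
                arm_level[(r.chrom, r.arm)] = config.loss_level
                event_rows.append((sample, r.chrom, r.arm, "arm_loss", r.start, r.end,
                                   config.loss_level))
            else:
                arm_level[(r.chrom, r.arm)] = 0.0
        focal_events = []
        for kind, rate, lengths, level in (
            ("focal_gain", config.focal_rate, config.focal_length, config.gain_level),
            ("amplification", config.amp_rate, config.amp_length, config.amp_level),
        ):
            for _ in range(rng.poisson(rate)):
                for _attempt in range(20):
                    arm = arms.iloc[rng.integers(len(arms))]
                    length = _snap(rng.uniform(*lengths), unit)
                    length = max(length, unit)
                    if length <= arm.end - arm.start:
                        break
                    logger.debug("focal length %d exceeds arm; resampled", length)
                start = _snap(rng.uniform(arm.start, arm.end - length), unit)
                start = min(max(start, arm.start), arm.end - length)
                focal_events.append((arm.chrom, arm.arm, kind, start, start + length, level))
                event_rows.append((sample, arm.chrom, arm.arm, kind, start, start + length, level))
        for r in arms.itertuples():
            bounds = {r.start, r.end}
            for c, a, _k, s, e, _lv in focal_events:
                if c == r.chrom and a == r.arm:
                    bounds.update((s, e))
            for _ in range(rng.poisson(config.extra_breaks)):
                bounds.add(_snap(rng.uniform(r.start, r.end), unit))
            bounds = sorted(b for b in bounds if r.start <= b <= r.end)
            for s, e in zip(bounds[:-1], bounds[1:]):
                if s >= e:
                    continue
                level = arm_level[(r.chrom, r.arm)]
                for c, a, _k, fs, fe, lv in focal_events:
                    if c == r.chrom and a == r.arm and fs <= s and e <= fe:
                        level += lv
                cn = level + rng.normal(0.0, config.noise_sd)
                seg_rows.append((r.chrom, s, e, cn))
        profiles.append(
            SegmentedProfile(sample, pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "cn"]))
        )
    events = pd.DataFrame(
        event_rows, columns=["sample", "chrom", "arm", "kind", "start", "end", "level"]
    )
    return profiles, events, truth


def true_gene_status(events: pd.DataFrame, genes: pd.DataFrame, samples) -> pd.DataFrame:
    """Planted per-(sample, gene) status from the event table (no noise).

    Precedence amplification > arm_gain > focal_gain > loss, mirroring the
    caller's classification.
    """
    status = pd.DataFrame("neutral", index=list(samples), columns=genes["name"].tolist())
    rank = {"neutral": 0, "loss": 1, "focal_gain": 2, "arm_gain": 3, "amplification": 4}
    for ev in events.itertuples():
        for g in genes.itertuples():
            if g.chrom != ev.chrom:
                continue
            if ev.kind in ("arm_gain", "arm_loss"):
                hit = ev.start <= g.start and g.end <= ev.end
                label = "arm_gain" if ev.kind == "arm_gain" else "loss"
            else:
                hit = not (g.end <= ev.start or ev.end <= g.start)
                label = ev.kind
            if hit and rank[label] > rank[status.at[ev.sample, g.name]]:
                status.at[ev.sample, g.name] = label
    return status


def simulate_dependency(status: pd.DataFrame, effects: dict, sd: float = 0.3,
                        baseline: float = 0.0, rng: np.random.Generator | None = None,
                        truth: TruthTable | None = None) -> pd.DataFrame:
    """Dependency scores = baseline + planted shift(status) + Gaussian noise.

    `effects` maps gene -> {status: mean shift}; genes absent from the map get
    pure noise. More negative scores mean stronger dependency.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    dep = pd.DataFrame(
        rng.normal(baseline, sd, size=status.shape), index=status.index, columns=status.columns
    )
    for gene, shifts in effects.items():
        if gene not in status.columns:
            raise ValueError(f"planted dependency gene {gene!r} absent from status matrix")
        for st, shift in shifts.items():
            dep.loc[status[gene] == st, gene] += shift
            if truth is not None:
                truth.add("dependency_shift", f"{gene}:{st}", shift)
    return dep


def simulate_expression(status: pd.DataFrame, effects: dict, sd: float = 1.0,
                        baseline: float = 5.0, rng: np.random.Generator | None = None,
                        truth: TruthTable | None = None) -> pd.DataFrame:
    """Expression matrix with status-dependent mean shifts (log-scale additive)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    expr = pd.DataFrame(
        rng.normal(baseline, sd, size=status.shape), index=status.index, columns=status.columns
    )
    for gene, shifts in effects.items():
        for st, shift in shifts.items():
            expr.loc[status[gene] == st, gene] += shift
            if truth is not None:
                truth.add("expression_shift", f"{gene}:{st}", shift)
    return expr


def simulate_drug_response(gain: pd.DataFrame, effects: dict, compounds,
                           baseline: float = 0.5, sd: float = 0.15,
                           rng: np.random.Generator | None = None,
                           truth: TruthTable | None = None) -> pd.DataFrame:
    """AUC matrix (higher = more resistant) with planted target-gain shifts.

    `gain` is a boolean cell-line x unit (gene or bin) indicator; `effects`
    maps compound -> (unit, delta_auc). A negative delta plants sensitivity in
    gained lines.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    compounds = list(compounds)
    auc = pd.DataFrame(
        rng.normal(baseline, sd, size=(len(gain), len(compounds))),
        index=gain.index, columns=compounds,
    )
    for compound, (unit, delta) in effects.items():
        auc.loc[gain[unit].astype(bool), compound] += delta
        if truth is not None:
            truth.add("drug_effect", f"{compound}:{unit}", delta)
    return auc


def _cooccurrence_rates(gain_freq: float, base_rate: float, odds_ratio: float):
    """Mutation rates (p_gain, p_nogain) matching a marginal rate and odds ratio."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")

    def p1(p0):
        o = odds_ratio * p0 / (1 - p0)
        return o / (1 + o)

    f = lambda p0: gain_freq * p1(p0) + (1 - gain_freq) * p0 - base_rate
    eps = 1e-9
    p0 = brentq(f, eps, 1 - eps)
    return p1(p0), p0


def simulate_mutations(gain: pd.DataFrame, odds_ratios: dict, base_rate: float = 0.2,
                       rng: np.random.Generator | None = None,
                       truth: TruthTable | None = None) -> pd.DataFrame:
    """Binary mutation table with planted mutation-gain co-occurrence.

    `odds_ratios` maps gene -> OR of mutation given gain status; unlisted genes
    in the gain table are mutated independently at `base_rate`.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    out = {}
    for gene in gain.columns:
        g = gain[gene].astype(bool).to_numpy()
        ratio = odds_ratios.get(gene)
        if ratio is None:
            out[gene] = rng.random(len(g)) < base_rate
        else:
            freq = g.mean()
            p1, p0 = _cooccurrence_rates(freq, base_rate, ratio) if 0 < freq < 1 else (base_rate, base_rate)
            out[gene] = rng.random(len(g)) < np.where(g, p1, p0)
            if truth is not None:
                truth.add("mutation_odds_ratio", gene, ratio)
    return pd.DataFrame(out, index=gain.index).astype(int)


def simulate_survival(indicators: pd.DataFrame, hazard_ratios: dict,
                      base_hazard: float = 1.0 / 1000, event_rate: float = 0.4,
                      rng: np.random.Generator | None = None,
                      truth: TruthTable | None = None) -> pd.DataFrame:
    """Exponential survival with per-sample hazard prop. to exp(sum beta * indicator).

    Censoring is independent exponential, calibrated so the baseline event
    probability is approximately `event_rate`. Returns (sample, time, event).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    log_hr = np.zeros(len(indicators))
    for unit, hr in hazard_ratios.items():
        log_hr += np.log(hr) * indicators[unit].astype(float).to_numpy()
        if truth is not None:
            truth.add("survival_hr", unit, hr)
    hazard = base_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    cens_rate = base_hazard * (1 - event_rate) / event_rate
    t_cens = rng.exponential(1.0 / cens_rate, size=len(indicators))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"sample": indicators.index, "time": time, "event": event}).set_index(
        "sample"
    )


def simulate_cohort(config: SimulationConfig) -> dict:
    """Full synthetic cohort under one seed: profiles, statuses, screens, survival.

    Plants the default dependency ladder on the first gene, the drug effect on
    one compound targeting that gene, the mutation odds ratio on that gene, and
    the hazard ratio on that gene's indicator; all recorded in the truth ledger.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    profiles, events, truth = simulate_genomes(config, rng, truth)
    build = config.build()
    genes = toy_genes(build)
    status = true_gene_status(events, genes, [p.sample_id for p in profiles])
    target = genes["name"].iloc[0]
    dep = simulate_dependency(
        status, {target: config.dependency_ladder}, sd=config.dependency_sd, rng=rng, truth=truth
    )
    expr = simulate_expression(
        status, {target: {s: 1.0 for s in config.dependency_ladder}}, rng=rng, truth=truth
    )
    gain = status.isin(["arm_gain", "focal_gain"])
    compounds = [f"C{i:03d}" for i in range(20)]
    annotation = pd.DataFrame(
        {"compound": compounds, "target": list(genes["name"].iloc[: len(compounds)]),
         "screen": "sim"}
    )
    auc = simulate_drug_response(
        gain, {compounds[0]: (target, config.drug_effect)}, compounds,
        baseline=config.auc_baseline, sd=config.auc_sd, rng=rng, truth=truth,
    )
    mutations = simulate_mutations(
        gain, {target: config.mutation_odds_ratio}, base_rate=config.mutation_rate,
        rng=rng, truth=truth,
    )
    survival = simulate_survival(
        gain, {target: config.hazard_ratio}, base_hazard=config.base_hazard,
        event_rate=config.event_rate, rng=rng, truth=truth,
    )
    meta = pd.DataFrame(
        {
            "sample": [p.sample_id for p in profiles],
            "type": [f"T{i % 3}" for i in range(len(profiles))],
            "subtype": [f"ST{i % 6}" for i in range(len(profiles))],
        }
    ).set_index("sample")
    return {
        "config": config,
        "build": build,
        "genes": genes,
        "profiles": profiles,
        "events": events,
        "status": status,
        "dependency": dep,
        "expression": expr,
        "auc": auc,
        "annotation": annotation,
        "mutations": mutations,
        "survival": survival,
        "metadata": meta,
        "truth": truth,
    }


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["focal_length"] = list(d["focal_length"])
    d["amp_length"] = list(d["amp_length"])
    return d
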