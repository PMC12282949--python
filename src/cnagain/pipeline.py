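"""End-to-end orchestration: one config, staged execution, checksum-cached
re-runs, and a run manifest.

Stages run in dependency order (simulate -> bins -> call -> depassoc ->
drugassoc -> enet -> survival). Each stage's cache key is the SHA-256 of its
config section plus its input files; a re-run with unchanged inputs skips the
stage. Results are only written to the output directory; the manifest is
written atomically at run end.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calling, dependency, drugs, features, genome, simulate, survival

logger = logging.getLogger(__name__)

STAGES = ["simulate", "bins", "call", "depassoc", "drugassoc", "enet", "survival"]

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "cnagain_run",
    "stages": STAGES,
    "simulate": {},               # SimulationConfig overrides
    "bins": {"bin_size": 25_000_000, "per_arm": False},
    "call": {"t_gain": 0.1, "t_loss": -0.1, "arm_fraction": 0.8, "amp_fallback": 0.9},
    "depassoc": {"contrast": "combined", "min_group": 2},
    "candidates": {"q_max": 0.3, "delta_max": -0.05, "min_datasets": 2},
    "drugassoc": {"q_sig": 0.1, "r_min": 0.3, "p_max": 1e-10, "min_lines": 30},
    "enet": {
        "feature_bin_size": 10_000_000,
        "compounds": None,        # default: first compound only
        "replicates": 3,
        "alpha_grid": [0.1, 0.5, 0.9],
        "lambda_rule": "one_se",
    },
    "survival": {"min_events": 10, "min_group": 3},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see DEFAULT_CONFIG for the schema)."""

    data: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = {}
        for key, default in DEFAULT_CONFIG.items():
            val = self.data.get(key, default)
            if isinstance(default, dict):
                unknown = set(val) - set(default) if key != "simulate" else set()
                if unknown:
                    raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
                merged[key] = {**default, **val}
            else:
                merged[key] = val
        unknown = set(self.data) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        bad = set(merged["stages"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        self.data = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.data[key]


def _sha256(obj) -> str:
    if isinstance(obj, (str, Path)) and Path(obj).exists():
        h = hashlib.sha256()
        with open(obj, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _stage_key(section: dict, seed, input_files: list[Path]) -> str:
    parts = [_sha256({"cfg": section, "seed": seed})] + [_sha256(p) for p in input_files]
    return hashlib.sha256("".join(parts).encode()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the run manifest.

    Stage outputs are TSV files in the output directory; the manifest records
    the config hash, per-stage cache keys, row counts and wall-clock seconds,
    and is written atomically to manifest.json at the end.
    """
    out = Path(outdir if outdir is not None else config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh).get("stages", {})
    manifest = {"config_hash": _sha256(config.data), "seed": config["seed"], "stages": {}}
    selected = [s for s in STAGES if s in config["stages"]]
    th = calling.CallThresholds(**{k: config["call"][k] for k in
                                   ("t_gain", "t_loss", "arm_fraction", "amp_fallback")})

    def finish(stage, key, outputs, t0, cached=False, note=None):
        rec = {"key": key, "cached": cached, "seconds": round(time.time() - t0, 3),
               "outputs": {}}
        for p in outputs:
            if Path(p).exists():
                if str(p).endswith(".tsv"):
                    with open(p) as fh:
                        n = sum(1 for _ in fh) - 1
                else:
                    n = os.path.getsize(p)
                rec["outputs"][Path(p).name] = n
        if note:
            rec["note"] = note
        manifest["stages"][stage] = rec

    def cached_ok(stage, key, outputs):
        prev = previous.get(stage)
        return (
            prev is not None
            and prev.get("key") == key
            and not prev.get("failed")
            and all(Path(p).exists() for p in outputs)
        )

    try:
        for stage in selected:
            t0 = time.time()
            if stage == "simulate":
                sim_cfg = simulate.SimulationConfig(seed=config["seed"], **config["simulate"])
                outputs = [out / f for f in (
                    "segments.seg", "build.tsv", "genes.bed", "true_status.tsv",
                    "dependency.tsv", "expression.tsv", "auc.tsv", "annotation.tsv",
                    "mutations.tsv", "survival.tsv", "metadata.tsv", "truth.json")]
                key = _stage_key(simulate.config_to_dict(sim_cfg), config["seed"], [])
                if cached_ok(stage, key, outputs):
                    finish(stage, key, outputs, t0, cached=True)
                    continue
                cohort = simulate.simulate_cohort(sim_cfg)
                genome.write_segments(cohort["profiles"], out / "segments.seg")
                cohort["build"].to_tsv(out / "build.tsv")
                cohort["genes"].to_csv(out / "genes.bed", sep="\t", index=False, header=False)
                _write_tsv(cohort["status"], out / "true_status.tsv")
                _write_tsv(cohort["dependency"], out / "dependency.tsv")
                _write_tsv(cohort["expression"], out / "expression.tsv")
                _write_tsv(cohort["auc"], out / "auc.tsv")
                _write_tsv(cohort["annotation"], out / "annotation.tsv", index=False)
                _write_tsv(cohort["mutations"], out / "mutations.tsv")
                _write_tsv(cohort["survival"], out / "survival.tsv")
                _write_tsv(cohort["metadata"], out / "metadata.tsv")
                cohort["truth"].to_json(out / "truth.json")
                finish(stage, key, outputs, t0)

            elif stage == "bins":
                inputs = [out / "build.tsv", out / "segments.seg"]
                outputs = [out / "bins.tsv", out / "bin_cn.tsv", out / "bin_cov.tsv"]
                key = _stage_key(config["bins"], config["seed"], inputs)
                if cached_ok(stage, key, outputs):
                    finish(stage, key, outputs, t0, cached=True)
                    continue
                build = genome.GenomeBuild.from_tsv(out / "build.tsv")
                bins = genome.build_bins(build, config["bins"]["bin_size"],
                                         per_arm=config["bins"]["per_arm"])
                profiles = genome.read_segments(out / "segments.seg")
                mat = genome.bin_copy_matrix(profiles, bins, build)
                _write_tsv(bins, out / "bins.tsv", index=False)
                _write_tsv(mat.cn, out / "bin_cn.tsv")
                _write_tsv(mat.covered, out / "bin_cov.tsv")
                finish(stage, key, outputs, t0)

            elif stage == "call":
                inputs = [out / "bin_cn.tsv", out / "segments.seg", out / "build.tsv",
                          out / "genes.bed"]
                outputs = [out / "states.tsv", out / "arms.tsv", out / "gene_cn.tsv",
                           out / "gene_status.tsv", out / "frequency.tsv"]
                key = _stage_key(config["call"], config["seed"], inputs)
                if cached_ok(stage, key, outputs):
                    finish(stage, key, outputs, t0, cached=True)
                    continue
                build = genome.GenomeBuild.from_tsv(out / "build.tsv")
                profiles = genome.read_segments(out / "segments.seg")
                cn = pd.read_csv(out / "bin_cn.tsv", sep="\t", index_col=0)
                states = calling.call_states(cn, th)
                arm_table = calling.arm_call_table(profiles, build, th)
                genes = genome.read_gene_bed(out / "genes.bed")
                gbins = genome.gene_bins(genes, build)
                gmat = genome.bin_copy_matrix(profiles, gbins, build)
                amp = calling.call_amplifications(gmat.cn, arm_table, th)
                gene_arm = pd.Series(
                    (gbins["chrom"] + ":" + gbins["arm"]).to_numpy(), index=gbins["bin_id"]
                )
                status = calling.classify_gene_status(gmat.cn, gene_arm, arm_table, amp, th)
                freq = calling.frequency_zscores(calling.cna_frequencies(states))
                _write_tsv(states, out / "states.tsv")
                _write_tsv(arm_table, out / "arms.tsv", index=False)
                _write_tsv(gmat.cn, out / "gene_cn.tsv")
                _write_tsv(status, out / "gene_status.tsv")
                _write_tsv(freq, out / "frequency.tsv")
                finish(stage, key, outputs, t0)

            elif stage == "depassoc":
                inputs = [out / "dependency.tsv", out / "gene_status.tsv"]
                outputs = [out / "dep_assoc.tsv"]
                key = _stage_key(config["depassoc"], config["seed"], inputs)
                if cached_ok(stage, key, outputs):
                    finish(stage, key, outputs, t0, cached=True)
                    continue
                dep = pd.read_csv(out / "dependency.tsv", sep="\t", index_col=0)
                status = pd.read_csv(out / "gene_status.tsv", sep="\t", index_col=0)
                rec = dependency.differential_dependency(
                    dep, status, contrast=config["depassoc"]["contrast"],
                    min_group=config["depassoc"]["min_group"],
                )
                _write_tsv(rec, out / "dep_assoc.tsv")
                finish(stage, key, outputs, t0)

            elif stage == "drugassoc":
                inputs = [out / "auc.tsv", out / "gene_status.tsv", out / "annotation.tsv",
                          out / "dependency.tsv"]
                outputs = [out / "drug_assoc.tsv", out / "on_target.tsv",
                           out / "drug_summary.tsv"]
                key = _stage_key(config["drugassoc"], config["seed"], inputs)
                if cached_ok(stage, key, outputs):
                    finish(stage, key, outputs, t0, cached=True)
                    continue
                auc = pd.read_csv(out / "auc.tsv", sep="\t", index_col=0)
                status = pd.read_csv(out / "gene_status.tsv", sep="\t", index_col=0)
                ann = pd.read_csv(out / "annotation.tsv", sep="\t")
                dep = pd.read_csv(out / "dependency.tsv", sep="\t", index_col=0)
                cfg = config["drugassoc"]
                rec = drugs.target_gain_response(auc, status, ann, q_sig=cfg["q_sig"])
                flags = drugs.on_target_compounds(
                    auc, dep, ann, r_min=cfg["r_min"], p_max=cfg["p_max"],
                    min_lines=cfg["min_lines"],
                )
                rec = rec.merge(ann[["compound", "target", "screen"]],
                                on=["compound", "target"], how="left")
                summary = drugs.direction_summary(rec, flags)
                _write_tsv(rec, out / "drug_assoc.tsv", index=False)
                _write_tsv(flags, out / "on_target.tsv", index=False)
                _write_tsv(summary, out / "drug_summary.tsv", index=False)
                finish(stage, key, outputs, t0)

            elif stage == "enet":
                inputs = [out / "auc.tsv", out / "mutations.tsv", out / "states.tsv",
                          out / "metadata.tsv", out / "segments.seg", out / "build.tsv"]
                outputs = [out / "enet_selected.tsv"]
                key = _stage_key(config["enet"], config["seed"], inputs)
                if cached_ok(stage, key, outputs):
                    finish(stage, key, outputs, t0, cached=True)
                    continue
                cfg = config["enet"]
                build = genome.GenomeBuild.from_tsv(out / "build.tsv")
                profiles = genome.read_segments(out / "segments.seg")
                fbins = genome.build_bins(build, cfg["feature_bin_size"])
                fmat = genome.bin_copy_matrix(profiles, fbins, build)
                fstates = calling.call_states(fmat.cn, th)
                arm_table = calling.arm_call_table(profiles, build, th)
                amp = calling.call_amplifications(fmat.cn, arm_table, th)
                mutations = pd.read_csv(out / "mutations.tsv", sep="\t", index_col=0)
                meta = pd.read_csv(out / "metadata.tsv", sep="\t", index_col=0)
                auc = pd.read_csv(out / "auc.tsv", sep="\t", index_col=0)
                X = features.build_feature_matrix(mutations, fstates, amp, meta)
                encfg = features.ElasticNetConfig(
                    alpha_grid=tuple(cfg["alpha_grid"]), lambda_rule=cfg["lambda_rule"],
                    replicates=cfg["replicates"],
                )
                compounds = cfg["compounds"] or [auc.columns[0]]
                seeds = [config["seed"] * 1000 + i for i in range(encfg.replicates)]
                parts = []
                for compound in compounds:
                    stable, _ = features.select_stable_features(X, auc[compound], encfg, seeds)
                    stable = stable.reset_index()
                    stable.insert(0, "compound", compound)
                    for r in stable.itertuples():
                        stable.loc[r.Index, "anova_p"] = features.feature_anova(
                            auc[compound], meta["type"], meta["subtype"], X[r.feature]
                        )
                    parts.append(stable)
                sel = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
                if len(sel):
                    sel = features.anova_qvalues(sel)
                _write_tsv(sel, out / "enet_selected.tsv", index=False)
                finish(stage, key, outputs, t0)

            elif stage == "survival":
                inputs = [out / "states.tsv", out / "survival.tsv"]
                outputs = [out / "cox.tsv"]
                key = _stage_key(config["survival"], config["seed"], inputs)
                if cached_ok(stage, key, outputs):
                    finish(stage, key, outputs, t0, cached=True)
                    continue
                states = pd.read_csv(out / "states.tsv", sep="\t", index_col=0)
                surv = pd.read_csv(out / "survival.tsv", sep="\t", index_col=0)
                cfg = config["survival"]
                rec = survival.cox_per_bin(
                    states, surv, min_events=cfg["min_events"], min_group=cfg["min_group"]
                )
                _write_tsv(rec, out / "cox.tsv", index=False)
                finish(stage, key, outputs, t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _atomic_json(manifest, manifest_path)
        raise
    _atomic_json(manifest, manifest_path)
    return manifest


def _atomic_json(obj: dict, path: Path) -> None:
    tmp = path.with_suffix(".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=1)
    os.replace(tmp, path)
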