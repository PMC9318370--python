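"""End-to-end reproducible runs: simulate -> segment -> features -> rank ->
evaluate, plus report rendering.

One master seed drives everything; each stage gets its own seed derived by
hashing (master seed, stage name), so stages can be re-run independently
and two runs with the same config are identical.  Feature ranking only ever
sees training-split rows — the pipeline splits patients before ranking and
passes the training rows alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import features as feat
from . import harness, preprocessing, ranking, synthetic
from ._errors import ConfigurationError

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RankingOptions:
    method: str = "mrmr"
    bins: int = 16
    criterion: str = "MIQ"
    redundancy: str = "nmi"
    exclude: tuple[str, ...] = ("pRR50",)  # the contrast pool drops these


@dataclass
class HarnessOptions:
    families: tuple[str, ...] | None = None  # None -> all seven
    k_max: int = 6
    modes: tuple[str, ...] = ("cv5", "blindfold")
    k_folds: int = 5
    dor_correction: str = "haldane"
    compact_grids: bool = False
    train_fraction: float = 2.0 / 3.0


@dataclass
class RunConfig:
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    segmentation: preprocessing.SegmentationConfig = field(
        default_factory=preprocessing.SegmentationConfig)
    ranking: RankingOptions = field(default_factory=RankingOptions)
    harness: HarnessOptions = field(default_factory=HarnessOptions)
    master_seed: int = 0
    make_plots: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.get("generator", {})
        sr = synthetic.SRParams(**gen.pop("sr_params", {}))
        af = synthetic.AFParams(**gen.pop("af_params", {}))
        return cls(
            generator=synthetic.GeneratorConfig(sr_params=sr, af_params=af, **gen),
            segmentation=preprocessing.SegmentationConfig(**raw.get("segmentation", {})),
            ranking=RankingOptions(**{k: tuple(v) if k == "exclude" else v
                                      for k, v in raw.get("ranking", {}).items()}),
            harness=HarnessOptions(**{k: tuple(v) if k in ("families", "modes") else v
                                      for k, v in raw.get("harness", {}).items()}),
            master_seed=int(raw.get("master_seed", 0)),
            make_plots=bool(raw.get("make_plots", False)),
        )


@dataclass
class RunResult:
    out_dir: Path
    feature_table: pd.DataFrame
    rankings: dict[str, ranking.RankingResult]
    auc_ranking: ranking.RankingResult
    report: pd.DataFrame
    filtering_summary: pd.DataFrame
    split: harness.SplitAssignment


def _write_rankings(rankings: dict, auc_res, path: Path) -> None:
    payload = {}
    for name, res in {**rankings, "auc": auc_res}.items():
        payload[name] = {
            "method": res.method, "pool": list(res.pool), "order": list(res.order),
            "scores": {k: float(v) for k, v in res.scores.items()},
            "binning": res.binning, "criterion": res.criterion,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Execute the five stages and persist every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.master_seed

    # 1. simulate
    gen_cfg = dataclasses.replace(config.generator, seed=stage_seed(master, "simulate"))
    recordings, manifest = synthetic.generate_cohort(gen_cfg)
    log.info("simulated %d recordings", len(recordings))

    # 2. segment
    segments, qcs = preprocessing.segment_cohort(recordings, config.segmentation)
    if not segments:
        raise ConfigurationError("segmentation produced no usable segments")

    # 3. features
    table, exclusions = feat.build_feature_table(segments)

    # 4. split, then rank on training rows only
    split = harness.split_by_patient(manifest, config.harness.train_fraction,
                                     seed=stage_seed(master, "split"))
    train_table, _ = harness.table_split(table, split)
    pool = list(feat.FEATURE_NAMES)
    ropts = config.ranking
    rankings = {
        "full": ranking.mrmr_rank(train_table, pool, bins=ropts.bins,
                                  criterion=ropts.criterion, redundancy=ropts.redundancy),
    }
    reduced = [f for f in pool if f not in ropts.exclude]
    if reduced != pool:
        excl_name = "no_" + "_".join(ropts.exclude)
        rankings[excl_name] = ranking.mrmr_rank(
            train_table, reduced, bins=ropts.bins,
            criterion=ropts.criterion, redundancy=ropts.redundancy)
    auc_res = ranking.auc_rank(train_table, pool)

    # 5. evaluate
    specs = harness.default_classifier_specs(compact=config.harness.compact_grids)
    if config.harness.families:
        specs = {f: specs[f] for f in config.harness.families}
    report = harness.run_experiment_matrix(
        table, split, rankings, specs, k_max=config.harness.k_max,
        modes=config.harness.modes, seed=stage_seed(master, "evaluate"),
        k_folds=config.harness.k_folds, dor_correction=config.harness.dor_correction)

    # persist artifacts (text only; stamped with the config hash)
    split_map = {pid: "Training" for pid, _ in split.train_patients}
    split_map.update({pid: "Test" for pid, _ in split.test_patients})
    filtering = preprocessing.summarize_filtering(qcs, split_map)

    table.to_csv(out / "features.csv", index=False)
    preprocessing.write_segments(segments, out / "segments.csv")
    report.to_csv(out / "report.csv", index=False)
    filtering.to_csv(out / "filtering_counts.csv")
    _write_rankings(rankings, auc_res, out / "rankings.yaml")
    manifest.to_csv(out / "cohort_manifest.csv", index=False)
    run_manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: stage_seed(master, s) for s in ("simulate", "split", "evaluate")},
        "n_segments": int(len(table)),
        "feature_exclusions": exclusions,
        "train_patients": sorted(map(list, split.train_patients)),
        "test_patients": sorted(map(list, split.test_patients)),
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(run_manifest, fh, sort_keys=True)

    result = RunResult(out, table, rankings, auc_res, report, filtering, split)
    render_report(result, out, make_plots=config.make_plots)
    return result


def render_report(result: RunResult, out_dir: str | Path, *,
                  make_plots: bool = False) -> None:
    """Emit summary tables (and optional plots) from a completed run.

    Tables: per-feature AUC, MRMR scores per pool, accuracy/DOR vs number
    of features per family and mode, the filtering bookkeeping, and the
    mean +/- SD CV-accuracy grid.
    """
    out = Path(out_dir)
    auc = result.auc_ranking
    pd.DataFrame({"feature": auc.order,
                  "auc": [auc.scores[f] for f in auc.order]},
                 ).to_csv(out / "auc_table.csv", index=False)
    for name, res in result.rankings.items():
        pd.DataFrame({"feature": res.order,
                      "mrmr_score": [res.scores[f] for f in res.order]},
                     ).to_csv(out / f"mrmr_table_{name}.csv", index=False)

    rep = result.report
    for metric in ("accuracy_pct", "dor"):
        pivot = rep.pivot_table(index=["pool", "family"], columns="n_features",
                                values=metric, aggfunc="first", observed=True)
        pivot.to_csv(out / f"{metric}_vs_k.csv")
    cv = rep[rep["mode"] == "cv5"]
    if len(cv):
        grid = cv[cv["pool"] == sorted(rep["pool"].unique())[0]].pivot_table(
            index="family", columns="n_features",
            values=["cv_accuracy_mean_pct", "cv_accuracy_sd_pct"], aggfunc="first")
        grid.to_csv(out / "cv_accuracy_grid.csv")
    result.filtering_summary.to_csv(out / "filtering_counts.csv")

    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax.bar(auc.order, [auc.scores[f] for f in auc.order])
        ax.set_ylabel("AUC")
        ax.set_ylim(0.5, 1.0)
        ax.tick_params(axis="x", rotation=60)
        fig.tight_layout()
        fig.savefig(out / "auc_bars.png", dpi=120)
        plt.close(fig)

        for mode in rep["mode"].unique():
            fig, ax = plt.subplots(figsize=(7, 4))
            sub = rep[(rep["mode"] == mode)]
            for (pool, family), grp in sub.groupby(["pool", "family"], observed=True):
                grp = grp.sort_values("n_features")
                ax.plot(grp["n_features"], grp["accuracy_pct"],
                        marker="o", label=f"{family} ({pool})", alpha=0.7)
            ax.set_xlabel("number of features")
            ax.set_ylabel("accuracy [%]")
            ax.set_title(f"{mode} accuracy")
            ax.legend(fontsize=6, ncol=2)
            fig.tight_layout()
            fig.savefig(out / f"accuracy_{mode}.png", dpi=120)
            plt.close(fig)


__all__ = ["RunConfig", "RankingOptions", "HarnessOptions", "RunResult",
           "run_pipeline", "render_report", "stage_seed"]
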