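"""End-to-end orchestration: files in, tables and a run report out."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io
from .model import CongruenceModel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and analysis settings of one pipeline run."""

    registry_csv: str
    aliases_json: str
    corpus_jsonl: str
    demographics_csv: str
    out_dir: str
    gold_jsonl: str | None = None
    distance_threshold: int | None = None  # None = quarter-length rule
    tau_variant: str = "b"
    min_district_n: int = 2
    unlabeled_policy: str = "keep"
    dedupe_mentions: bool = True
    eval_sample_fraction: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def check_inputs(self) -> None:
        for name in ("registry_csv", "aliases_json", "corpus_jsonl", "demographics_csv"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.gold_jsonl and not Path(self.gold_jsonl).exists():
            raise FileNotFoundError(f"gold_jsonl: {self.gold_jsonl} does not exist")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute extraction -> ranking -> congruence -> regression, write all
    output tables under ``config.out_dir`` and return the run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    meta = {"config_hash": io.config_hash(config.to_dict()), "seed": config.seed}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        config.check_inputs()
        model = CongruenceModel.from_files(
            config.registry_csv,
            config.aliases_json,
            config.corpus_jsonl,
            config.demographics_csv,
            gold_jsonl=config.gold_jsonl,
            distance_threshold=config.distance_threshold,
            tau_variant=config.tau_variant,
            min_district_n=config.min_district_n,
            unlabeled_policy=config.unlabeled_policy,
            dedupe_mentions=config.dedupe_mentions,
            eval_sample_fraction=config.eval_sample_fraction,
            seed=config.seed,
        )
    except Exception as err:
        raise PipelineError("load", err) from err

    try:
        results = model.fit()
    except Exception as err:
        raise PipelineError("analysis", err) from err

    try:
        io.write_mentions_jsonl(results.mentions, out / "mentions.jsonl", meta)
        io.write_table_csv(results.ranking, out / "ranking.csv", meta)
        io.write_table_csv(results.congruence, out / "congruence.csv", meta)
        io.write_table_csv(
            results.correlations.round(12), out / "correlations.csv", meta, index=True
        )
        for dep, res in results.ols.items():
            if res is not None:
                io.write_table_csv(
                    res.to_frame().reset_index(), out / f"regression_{dep}.csv", meta
                )
    except Exception as err:
        raise PipelineError("write", err) from err

    report: dict = {
        "config_hash": meta["config_hash"],
        "seed": config.seed,
        "stage_counts": results.stage_counts,
        "flags": results.flags,
        "excluded_districts": results.excluded_districts,
    }
    if results.eval_metrics is not None:
        m = results.eval_metrics
        report["extraction_evaluation"] = {
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
            "n_messages": m.n_messages,
        }
    for dep, res in results.ols.items():
        if res is not None:
            report[f"adjusted_r2_{dep}"] = res.adjusted_r2
    io.write_report_json(report, out / "report.json", meta)
    return report
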