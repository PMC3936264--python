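"""Model/Results facade over the full congruence analysis.

``CongruenceModel`` holds the data of one study — forum corpus, clinic
registry, alias dictionary, district covariates and (optionally) gold
annotations — together with the analysis settings.  ``fit()`` runs the
chain candidate filtering -> dictionary extraction -> sentiment filter ->
per-district rankings -> rank-correlation congruence -> OLS of congruence
on covariates, and returns a ``CongruenceResults`` carrying the estimates,
their uncertainties and diagnostics, with a ``summary()`` table in the
spirit of statsmodels results objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .congruence import congruence_table
from .corpus import AliasDictionary, GroundTruth, Hospital, MentionRecord, Message, Thread
from .demographics import DistrictDemographics, demographics_frame
from .extract import (
    EvalMetrics,
    evaluate_extraction,
    extract_mentions,
    filter_candidates,
    filter_sentiment,
)
from .ranking import RankingPair, build_ranking_pairs, count_mentions, ranking_frame
from .regression import RegressionResult, correlation_matrix, fit_ols

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = [
    "birthrate",
    "education_mean",
    "education_sd",
    "population_density",
    "doctors_per_clinic",
    "availability",
]

__all__ = ["CongruenceModel", "CongruenceResults", "COVARIATE_COLUMNS"]


class CongruenceModel:
    """The congruence study as a fittable model.

    Parameters
    ----------
    messages, threads :
        Forum content; threads may be None (derived from messages).
    registry :
        Official clinic registry with antibiotic rates.
    aliases :
        Canonical-name -> surface-form dictionary.
    demographics :
        District covariates, as a DataFrame indexed by district or a list
        of :class:`DistrictDemographics`.
    gold :
        Optional ground-truth mention sets; enables extraction evaluation.
    distance_threshold :
        Edit-distance threshold for alias matching (int, callable, or None
        for the default quarter-length rule).
    tau_variant :
        "b" (tie-corrected, default) or "a".
    min_district_n :
        Minimum commonly rankable clinics for a district to enter the
        congruence table.
    unlabeled_policy :
        What the sentiment filter does with unlabeled mentions.
    dedupe_mentions :
        Message-level deduplication of (message, hospital) pairs (default)
        versus occurrence-level counting.
    eval_sample_fraction, seed :
        Message sampling for extraction evaluation.
    """

    def __init__(
        self,
        messages: Sequence[Message],
        registry: Sequence[Hospital],
        aliases: AliasDictionary,
        demographics: pd.DataFrame | Sequence[DistrictDemographics],
        threads: Sequence[Thread] | None = None,
        gold: GroundTruth | None = None,
        *,
        distance_threshold=None,
        tau_variant: str = "b",
        min_district_n: int = 2,
        unlabeled_policy: str = "keep",
        dedupe_mentions: bool = True,
        eval_sample_fraction: float = 1.0,
        seed: int = 0,
    ):
        self.messages = list(messages)
        self.registry = list(registry)
        self.aliases = aliases
        self.threads = list(threads) if threads is not None else None
        self.gold = gold
        if isinstance(demographics, pd.DataFrame):
            self.demographics = demographics.copy()
        else:
            self.demographics = demographics_frame(list(demographics))
        missing = [c for c in COVARIATE_COLUMNS if c not in self.demographics.columns]
        if missing:
            raise ValueError(f"demographics missing covariates: {missing}")
        self.distance_threshold = distance_threshold
        self.tau_variant = tau_variant
        self.min_district_n = min_district_n
        self.unlabeled_policy = unlabeled_policy
        self.dedupe_mentions = dedupe_mentions
        self.eval_sample_fraction = eval_sample_fraction
        self.seed = seed

    @classmethod
    def from_simulation(cls, config=None, **kwargs) -> "CongruenceModel":
        """Build the model from a synthetic study generated at
        ``config`` (a :class:`~crowdcongruence.simulate.SimulationConfig`
        or None for defaults)."""
        from .simulate import SimulationConfig, generate_study

        config = config if config is not None else SimulationConfig()
        study = generate_study(config)
        kwargs.setdefault("seed", config.seed)
        return cls(
            messages=study.messages,
            registry=study.registry,
            aliases=study.aliases,
            demographics=study.demographics,
            threads=study.threads,
            gold=study.gold,
            **kwargs,
        )

    @classmethod
    def from_files(
        cls,
        registry_csv,
        aliases_json,
        corpus_jsonl,
        demographics_csv,
        gold_jsonl=None,
        **kwargs,
    ) -> "CongruenceModel":
        from . import io

        registry = io.read_registry_csv(registry_csv)
        aliases = io.read_aliases_json(aliases_json)
        threads, messages = io.read_corpus_jsonl(corpus_jsonl)
        demographics = io.read_demographics_csv(demographics_csv)
        gold = io.read_gold_jsonl(gold_jsonl) if gold_jsonl else None
        return cls(
            messages=messages,
            registry=registry,
            aliases=aliases,
            demographics=demographics,
            threads=threads,
            gold=gold,
            **kwargs,
        )

    def fit(self) -> "CongruenceResults":
        """Run the full analysis chain and collect results."""
        flags: list[str] = []
        stage_counts: dict[str, int] = {"messages": len(self.messages)}

        candidates = filter_candidates(self.threads, self.messages)
        stage_counts["candidates"] = len(candidates)

        mentions = extract_mentions(
            candidates,
            self.aliases,
            threshold=self.distance_threshold,
            dedupe=self.dedupe_mentions,
        )
        stage_counts["mentions"] = len(mentions)

        retained = filter_sentiment(mentions, unlabeled_policy=self.unlabeled_policy)
        stage_counts["retained_mentions"] = len(retained)

        freq = count_mentions(retained, self.registry)
        pairs, excluded = build_ranking_pairs(
            freq, self.registry, min_n=self.min_district_n
        )
        stage_counts["districts_with_mentions"] = len(pairs)
        stage_counts["districts_excluded"] = len(excluded)
        if excluded:
            flags.append(
                f"excluded districts below min_n={self.min_district_n}: "
                + ", ".join(excluded)
            )

        ctable = congruence_table(pairs, tau_variant=self.tau_variant)
        stage_counts["districts_analyzed"] = len(ctable)

        features = self.demographics[COVARIATE_COLUMNS].astype(float)
        corr_r, corr_p = correlation_matrix(features)

        ols: dict[str, RegressionResult | None] = {}
        merged = ctable.set_index("district_id")
        common = features.index.intersection(merged.index)
        for dep in ("kendall_tau", "spearman_rho"):
            y = merged[dep].reindex(common)
            try:
                ols[dep] = fit_ols(features.loc[common], y, dependent=dep)
            except ValueError as err:
                flags.append(f"regression on {dep} not fitted: {err}")
                logger.warning("regression on %s not fitted: %s", dep, err)
                ols[dep] = None

        metrics = None
        if self.gold is not None:
            candidate_ids = [m.message_id for m in candidates]
            metrics = evaluate_extraction(
                mentions,
                self.gold,
                sample_fraction=self.eval_sample_fraction,
                seed=self.seed,
                message_ids=candidate_ids,
            )

        return CongruenceResults(
            model=self,
            stage_counts=stage_counts,
            flags=flags,
            mentions=mentions,
            retained_mentions=retained,
            eval_metrics=metrics,
            ranking_pairs=pairs,
            excluded_districts=excluded,
            congruence=ctable,
            correlations=corr_r,
            correlation_pvalues=corr_p,
            ols=ols,
        )


@dataclass
class CongruenceResults:
    """Everything one fit produced."""

    model: CongruenceModel
    stage_counts: dict[str, int]
    flags: list[str]
    mentions: list[MentionRecord]
    retained_mentions: list[MentionRecord]
    eval_metrics: EvalMetrics | None
    ranking_pairs: list[RankingPair]
    excluded_districts: list[str]
    congruence: pd.DataFrame
    correlations: pd.DataFrame
    correlation_pvalues: pd.DataFrame
    ols: dict[str, RegressionResult | None] = field(default_factory=dict)

    @property
    def ranking(self) -> pd.DataFrame:
        return ranking_frame(self.ranking_pairs)

    def summary(self) -> str:
        s = self.stage_counts
        lines = [
            "Crowdsourced-vs-official hospital-quality congruence",
            "=" * 52,
            f"messages {s.get('messages', 0)}, candidates {s.get('candidates', 0)}, "
            f"mentions {s.get('mentions', 0)} "
            f"(retained after sentiment filter {s.get('retained_mentions', 0)})",
            f"districts analyzed {s.get('districts_analyzed', 0)}, "
            f"excluded {s.get('districts_excluded', 0)}",
        ]
        if self.eval_metrics is not None:
            m = self.eval_metrics
            lines.append(
                f"extraction vs gold (n={m.n_messages} messages): "
                f"precision {m.precision:.3f}, recall {m.recall:.3f}, F1 {m.f1:.3f}"
            )
        if len(self.congruence):
            tau = self.congruence["kendall_tau"]
            rho = self.congruence["spearman_rho"]
            lines.append(
                f"congruence: mean tau {tau.mean():.3f} "
                f"(min {tau.min():.3f}, max {tau.max():.3f}), mean rho {rho.mean():.3f}"
            )
        for dep, res in self.ols.items():
            lines.append("")
            if res is None:
                lines.append(f"[{dep}] regression not fitted")
            else:
                lines.append(res.summary())
        if self.flags:
            lines.append("")
            lines.extend(f"note: {f}" for f in self.flags)
        return "\n".join(lines)

    def regression_frame(self, dependent: str = "kendall_tau") -> pd.DataFrame:
        res = self.ols.get(dependent)
        if res is None:
            raise ValueError(f"no fitted regression for {dependent!r}")
        return res.to_frame()

    def mention_counts_frame(self) -> pd.DataFrame:
        return count_mentions(self.retained_mentions, self.model.registry)

    def retained_fraction(self) -> float:
        """Share of extracted mentions surviving the sentiment filter."""
        n = self.stage_counts.get("mentions", 0)
        return self.stage_counts.get("retained_mentions", 0) / n if n else float("nan")
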