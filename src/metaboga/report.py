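"""Biomarker intersection logic and the end-to-end pipeline.

Within each pairwise stage comparison, the metabolites shared by the three
classifiers' forward-selected models are split into four disjoint sets: the
triple intersection and the three pairwise intersections minus the triple.
Across comparisons, metabolites whose reported sets recur in two or more
comparisons are nominated as progression biomarker candidates.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datasets import ConfigurationError
from .forward import ForwardModel, best_models_table, forward_select
from .ga import GAConfig, GARunResult, run_blast
from .preprocess import PQNConfig, apply_inclusion, make_comparisons, pqn_normalize
from .table import FeatureTable, read_table

__all__ = [
    "normalize_metabolite_name",
    "within_comparison_sets",
    "cross_comparison",
    "IntersectionReport",
    "build_intersection_report",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

SET_KEYS = ("knn_nearcent_svm", "knn_nearcent", "knn_svm", "nearcent_svm")

_DOT_BETWEEN_WORDS = re.compile(r"(?<=\w)\.(?=\w)")


def normalize_metabolite_name(name: str) -> str:
    """Canonical metabolite identity for set matching.

    Whitespace is collapsed and a ``.`` sandwiched between word characters
    becomes a space -- data-frame exports commonly mangle spaces in names
    that way (e.g. ``Butyl.methacrylate`` for ``Butyl methacrylate``).
    """
    name = _DOT_BETWEEN_WORDS.sub(" ", name.strip())
    return re.sub(r"\s+", " ", name)


def _norm_set(names: Iterable[str]) -> set[str]:
    return {normalize_metabolite_name(n) for n in names}


def within_comparison_sets(
    knn_feats: Iterable[str],
    nearcent_feats: Iterable[str],
    svm_feats: Iterable[str],
) -> dict[str, set[str]]:
    """Four disjoint intersection sets of the three models' metabolites.

    Keys: ``knn_nearcent_svm`` (triple intersection), then each pairwise
    intersection with the triple removed.
    """
    a, b, c = _norm_set(knn_feats), _norm_set(nearcent_feats), _norm_set(svm_feats)
    triple = a & b & c
    return {
        "knn_nearcent_svm": triple,
        "knn_nearcent": (a & b) - triple,
        "knn_svm": (a & c) - triple,
        "nearcent_svm": (b & c) - triple,
    }


def cross_comparison(
    reported_sets: Mapping[str, Mapping[str, Iterable[str]] | Iterable[str]],
    min_count: int = 2,
) -> tuple[dict[str, list[str]], list[tuple[str, int]]]:
    """Metabolites recurring across comparisons.

    ``reported_sets`` maps a comparison name to either the four-set dict of
    :func:`within_comparison_sets` or a flat iterable of names.  Returns
    the per-metabolite membership (comparison lists, in input order) and
    the progression candidates: metabolites present in at least
    ``min_count`` comparisons, sorted by count descending then name.
    """
    if len(reported_sets) < 2:
        raise ConfigurationError("cross-comparison needs at least 2 comparisons")
    membership: dict[str, list[str]] = {}
    for comparison, sets in reported_sets.items():
        if isinstance(sets, Mapping):
            names: set[str] = set()
            for part in sets.values():
                names |= _norm_set(part)
        else:
            names = _norm_set(sets)
        for name in sorted(names):
            membership.setdefault(name, [])
            if comparison not in membership[name]:
                membership[name].append(comparison)
    candidates = sorted(
        ((n, len(c)) for n, c in membership.items() if len(c) >= min_count),
        key=lambda nc: (-nc[1], nc[0]),
    )
    return membership, candidates


@dataclass
class IntersectionReport:
    """Common metabolites per comparison plus cross-comparison candidates."""

    per_comparison: dict[str, dict[str, list[str]]]
    cross_comparison: dict[str, list[str]]
    progression_candidates: list[tuple[str, int]]

    def to_json_dict(self) -> dict:
        return {
            "per_comparison": self.per_comparison,
            "cross_comparison": self.cross_comparison,
            "progression_candidates": [
                {"metabolite": n, "n_comparisons": c}
                for n, c in self.progression_candidates
            ],
        }

    def to_markdown(self) -> str:
        lines = ["# Metabolite intersection report", ""]
        for comparison, sets in self.per_comparison.items():
            lines.append(f"## {comparison}")
            for key in SET_KEYS:
                members = sets.get(key, [])
                pretty = " and ".join(part.upper() for part in key.split("_"))
                lines.append(f"- **{pretty}**: " + (", ".join(members) or "(none)"))
            lines.append("")
        lines.append("## Progression candidates (in >= 2 comparisons)")
        for name, count in self.progression_candidates:
            where = ", ".join(self.cross_comparison[name])
            lines.append(f"- {name}: {count} comparisons ({where})")
        lines.append("")
        return "\n".join(lines)


def build_intersection_report(
    models_by_comparison: Mapping[str, Mapping[str, Iterable[str]]],
    min_count: int = 2,
) -> IntersectionReport:
    """Intersection report from per-comparison {method: metabolite list} maps."""
    per_comparison: dict[str, dict[str, list[str]]] = {}
    flat: dict[str, dict[str, set[str]]] = {}
    for comparison, by_method in models_by_comparison.items():
        sets = within_comparison_sets(
            by_method.get("knn", ()),
            by_method.get("nearcent", ()),
            by_method.get("svm", ()),
        )
        flat[comparison] = sets
        per_comparison[comparison] = {k: sorted(v) for k, v in sets.items()}
    membership, candidates = cross_comparison(flat, min_count=min_count)
    # keep only metabolites that made it into some reported set
    membership = {n: c for n, c in membership.items() if c}
    return IntersectionReport(per_comparison, membership, candidates)


# -- end-to-end pipeline ---------------------------------------------------

@dataclass
class PipelineConfig:
    """Settings for :func:`run_pipeline`.

    One master seed drives everything: the CV folds and each (comparison,
    method) blast receive child seeds through a stateless splitting rule,
    so reruns are byte-identical.
    """

    pqn: PQNConfig = field(default_factory=PQNConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    methods: tuple[str, ...] = ("knn", "nearcent", "svm")
    forward_max_size: int = 30
    forward_tolerance: float = 0.01
    seed: int = 0


@dataclass
class PipelineResult:
    """Everything the pipeline produced, writable as a report bundle."""

    filter_log: pd.DataFrame
    quotients: pd.Series
    blasts: dict[tuple[str, str], GARunResult]
    forward_models: dict[tuple[str, str], ForwardModel]
    summary: pd.DataFrame
    intersections: IntersectionReport

    def report_json(self) -> str:
        payload = {
            "summary": self.summary.to_dict(orient="records"),
            "forward_models": {
                f"{comparison}::{method}": model.to_json_dict()
                for (comparison, method), model in self.forward_models.items()
            },
            "intersections": self.intersections.to_json_dict(),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.report_json())
        (out / "report.md").write_text(self.intersections.to_markdown())
        self.filter_log.to_csv(out / "filter_log.tsv", sep="\t", index=False)
        self.quotients.to_frame().to_csv(out / "pqn_quotients.tsv", sep="\t")
        for (comparison, method), blast in self.blasts.items():
            stem = f"{comparison}_{method}".replace("/", "_")
            names = blast.feature_names or [str(i) for i in range(blast.n_features)]
            rank_frame = pd.DataFrame(
                {
                    "rank": np.arange(1, blast.n_features + 1),
                    "feature": [names[i] for i in blast.gene_rank],
                    "frequency": blast.gene_frequency[blast.gene_rank],
                }
            )
            rank_frame.to_csv(out / f"generank_{stem}.tsv", sep="\t", index=False)


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    table: FeatureTable | str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Inclusion -> PQN -> five comparisons -> (3 methods x GA blast ->
    forward selection) -> accuracy summary -> intersection report.

    ``table`` may be a :class:`FeatureTable` or a CSV path.  Fully
    deterministic under ``config.seed``.
    """
    config = config or PipelineConfig()
    if not isinstance(table, FeatureTable):
        table = read_table(table)

    try:
        filtered, log = apply_inclusion(table)
        normalized, quotients = pqn_normalize(filtered, config.pqn)
        comparisons = make_comparisons(normalized)
    except Exception as exc:  # noqa: BLE001 -- annotate with the stage
        raise type(exc)(f"[preprocess] {exc}") from exc

    blasts: dict[tuple[str, str], GARunResult] = {}
    forward_models: dict[tuple[str, str], ForwardModel] = {}
    for ci, comp in enumerate(comparisons):
        for mi, method in enumerate(config.methods):
            spec = replace(config.ga.classifier, method=method)
            cfg = replace(
                config.ga,
                classifier=spec,
                cv=replace(config.ga.cv, seed=_child_seed(config.seed, ci)),
                seed=_child_seed(config.seed, ci, mi),
            )
            try:
                blast = run_blast(comp, cfg)
                model = forward_select(
                    blast.gene_rank,
                    comp,
                    classifier=spec,
                    scheme=cfg.cv,
                    max_size=config.forward_max_size,
                    tolerance=config.forward_tolerance,
                )
            except Exception as exc:  # noqa: BLE001
                raise type(exc)(f"[{comp.name}/{method}] {exc}") from exc
            blasts[(comp.name, method)] = blast
            forward_models[(comp.name, method)] = model

    summary = best_models_table(forward_models.values())
    models_by_comparison = {
        comp.name: {
            method: forward_models[(comp.name, method)].features
            for method in config.methods
        }
        for comp in comparisons
    }
    intersections = build_intersection_report(models_by_comparison)
    return PipelineResult(
        filter_log=log,
        quotients=quotients,
        blasts=blasts,
        forward_models=forward_models,
        summary=summary,
        intersections=intersections,
    )
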