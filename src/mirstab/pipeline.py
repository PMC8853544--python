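"""End-to-end orchestration: filter, normalize, rank, test, compare.

``run_full_analysis`` executes, for every requested group (each annotated
tissue group plus the pooled union by default):

1. low-count filtering,
2. the combined rank-sum stability table (written as ``stability_<group>.tsv``),
3. top-5 vs next-5 composite paired dispersion tests under each ranking
   strategy (``composite_tests_<group>.json``),
4. all six pairwise strategy comparisons with BH adjustment
   (``strategy_comparison_<group>.json``),

plus a ``manifest.json`` recording parameters, seeds and filter survivor
counts so any output can be reproduced. Stages that a group cannot support
(too few retained probes, unresolvable top-k normalizer) are skipped with
a logged warning rather than aborting the whole run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .datamodel import POOLED, CountMatrix
from .filtering import FilterRule, filter_probes
from .io import write_comparison, write_stability_table
from .normalization import DEFAULT_TOP_K
from .paired_dispersion import DegenerateInputError, compare_top5_next5
from .stability import DEFAULT_RANKING_STRATEGIES, combined_rank_sum
from .strategy_comparison import compare_all_strategies

logger = logging.getLogger("mirstab")


@dataclass
class RunConfig:
    out_dir: Path
    groups: list[str] | None = None  # default: annotated groups + pooled
    filter_rule: FilterRule = field(default_factory=FilterRule)
    ranking_strategies: tuple[str, ...] = DEFAULT_RANKING_STRATEGIES
    top_report: int = 10
    n_top: int = 5
    n_next: int = 5
    comparison_k: int = 5
    top_k: int = DEFAULT_TOP_K
    permutation_mode: str = "exhaustive"
    n_mc: int = 100_000
    seed: int = 0


def run_full_analysis(matrix: CountMatrix, config: RunConfig) -> dict:
    """Run every stage for every group; returns the manifest dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = config.groups if config.groups is not None else matrix.groups + [POOLED]

    manifest: dict = {
        "parameters": {
            "filter_rule": dataclasses.asdict(config.filter_rule),
            "ranking_strategies": list(config.ranking_strategies),
            "top_report": config.top_report,
            "n_top": config.n_top,
            "n_next": config.n_next,
            "comparison_k": config.comparison_k,
            "top_k": config.top_k,
            "permutation_mode": config.permutation_mode,
            "n_mc": config.n_mc,
            "seed": config.seed,
        },
        "n_probes": len(matrix.probe_ids),
        "n_samples": len(matrix.sample_ids),
        "codesets": sorted(set(matrix.samples.get("codeset", []))),
        "groups": {},
    }

    for group in groups:
        entry: dict = {"outputs": {}, "warnings": []}
        retained = filter_probes(matrix, group, config.filter_rule)
        entry["n_retained"] = len(retained)
        entry["n_samples"] = len(matrix.group_samples(group))
        logger.info("group %s: %d probes survive the low-count filter", group, len(retained))

        try:
            table = combined_rank_sum(
                matrix, group, retained, config.ranking_strategies, top_k=config.top_k
            )
        except Exception as exc:  # unresolvable strategy for this group
            entry["warnings"].append(f"stability: {exc}")
            logger.warning("group %s: stability stage skipped (%s)", group, exc)
            manifest["groups"][group] = entry
            continue
        stab_path = out_dir / f"stability_{group}.tsv"
        write_stability_table(table, stab_path)
        entry["outputs"]["stability"] = stab_path.name
        entry["top_stable"] = table.ordering[: config.top_report]

        composite: dict = {}
        for strategy in config.ranking_strategies:
            try:
                gram, bs = compare_top5_next5(
                    matrix,
                    group,
                    strategy,
                    rule=config.filter_rule,
                    n_top=config.n_top,
                    n_next=config.n_next,
                    top_k=config.top_k,
                )
            except (ValueError, DegenerateInputError) as exc:
                entry["warnings"].append(f"composite[{strategy}]: {exc}")
                logger.warning(
                    "group %s: composite test under %s skipped (%s)", group, strategy, exc
                )
                continue
            composite[strategy] = [dataclasses.asdict(gram), dataclasses.asdict(bs)]
        comp_path = out_dir / f"composite_tests_{group}.json"
        comp_path.write_text(json.dumps(composite, indent=2) + "\n")
        entry["outputs"]["composite_tests"] = comp_path.name

        try:
            results = compare_all_strategies(
                matrix,
                group,
                k=config.comparison_k,
                rule=config.filter_rule,
                top_k=config.top_k,
                mode=config.permutation_mode,
                n_mc=config.n_mc,
                seed=config.seed,
            )
        except Exception as exc:
            entry["warnings"].append(f"strategy_comparison: {exc}")
            logger.warning("group %s: strategy comparison skipped (%s)", group, exc)
        else:
            cmp_path = out_dir / f"strategy_comparison_{group}.json"
            write_comparison(results, cmp_path)
            entry["outputs"]["strategy_comparison"] = cmp_path.name

        manifest["groups"][group] = entry

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
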