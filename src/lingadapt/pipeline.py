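"""End-to-end orchestration: simulate, analyse, and summarise robustness.

One entry point runs the enabled stages in dependency order on a simulated
world — generation, the independence-constrained percentile test, the
measurement-agreement report with bias tests, the random-effect ablation of
the Poisson tone model, vowel-space areas plus the vowel mixed models, the
corpus analyses, and the causal-graph screening check — and writes per-stage
CSV/JSON artifacts plus one machine-readable robustness report.  All
randomness derives from a single seed (per-stage child seeds are spawned
deterministically), so a rerun with the same config is byte-identical apart
from the log's timings.

Significance conventions in the summary: the percentile test counts as a
positive result when the proportion exceeds 0.95 at the lowest percentile;
model-based tests are positive when their likelihood-ratio p-value is below
0.05.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_report, bias_test
from .causal_dag import humidity_tone_example_graph, screening_set, write_graph
from .corpus_stats import seasonal_contour
from .mixed_models import ablation_sweep, vowel_models
from .sampling_test import PercentileTestConfig, percentile_test
from .vowel_geometry import vowel_space_table
from .world_sim import (
    WorldConfig,
    generate_corpus,
    generate_formants,
    generate_world,
    write_language_table,
)

__all__ = ["RunConfig", "RobustnessReport", "run", "ALL_STAGES"]

ALL_STAGES = (
    "simulate",
    "percentile_test",
    "agreement",
    "tone_models",
    "vowel_models",
    "corpus",
    "dag",
)

PROPORTION_THRESHOLD = 0.95
ALPHA = 0.05


@dataclass(frozen=True)
class RunConfig:
    world: WorldConfig = WorldConfig()
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str = "lingadapt_run"
    seed: int = 0
    n_iterations: int = 1000  # percentile-test iterations
    verbosity: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        order = [s for s in ALL_STAGES if s in self.stages]
        if tuple(order) != tuple(self.stages):
            raise ValueError("stages must be listed in dependency order "
                             f"{ALL_STAGES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        world = WorldConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("world", {}).items()
        })
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(world=world, **raw)


@dataclass
class RobustnessReport:
    """Per-stage result blocks plus the yes/no summary rows."""

    seed: int
    blocks: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary_rows(self) -> list[dict]:
        rows = []
        for stage, block in self.blocks.items():
            verdict = block.get("significant")
            rows.append(
                {
                    "stage": stage,
                    "test": block.get("test", ""),
                    "result": {True: "Yes", False: "No", None: "NA"}[verdict],
                    "detail": block.get("detail", ""),
                }
            )
        return rows


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def run(config: RunConfig) -> RobustnessReport:
    """Execute the enabled stages; artifacts are written under out_dir.

    A stage failure is recorded in the report (and in the exit status of the
    CLI); stages that depend on simulation output are skipped if simulation
    failed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RobustnessReport(seed=config.seed)
    seeds = dict(zip(ALL_STAGES, _child_seeds(config.seed, len(ALL_STAGES))))
    log_lines = [f"lingadapt {__version__} run, seed={config.seed}"]
    world = None

    def log(msg: str) -> None:
        log_lines.append(msg)
        if config.verbosity:
            print(msg)

    for stage in config.stages:
        if stage != "simulate" and world is None and "simulate" in config.stages:
            if "simulate" in report.errors:
                report.errors[stage] = "skipped: simulation failed"
                continue
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                world_cfg = WorldConfig(**{
                    **{f.name: getattr(config.world, f.name) for f in fields(WorldConfig)},
                    "seed": seeds["simulate"],
                })
                world = generate_world(world_cfg)
                write_language_table(world, out / "languages.csv")
                report.blocks["simulate"] = {
                    "test": "world generation",
                    "significant": None,
                    "detail": f"{len(world)} languages, "
                    f"{world['family_id'].nunique()} families, "
                    f"{world['area_id'].nunique()} areas",
                    "seed": seeds["simulate"],
                }
            elif stage == "percentile_test":
                res = percentile_test(
                    world,
                    PercentileTestConfig(
                        n_iterations=config.n_iterations, seed=seeds[stage]
                    ),
                )
                props = {str(k): v for k, v in res.proportions.items()}
                lowest = min(res.proportions)
                sig = res.proportions[lowest] > PROPORTION_THRESHOLD
                (out / "percentile_test.json").write_text(
                    json.dumps({"proportions": props, "seed": seeds[stage],
                                "n_iterations": res.n_iterations}, indent=2)
                )
                report.blocks[stage] = {
                    "test": f"percentile test (proportion > {PROPORTION_THRESHOLD} "
                    f"at {lowest:.0%})",
                    "significant": bool(sig),
                    "detail": json.dumps(props),
                    "seed": seeds[stage],
                }
            elif stage == "agreement":
                rep = agreement_report(world["n_tones"], world["n_tones_alt"])
                bias = bias_test(
                    world["n_tones_alt"] - world["n_tones"],
                    world["family_id"], world["area_id"], world["humidity"],
                )
                block = {
                    "test": "measurement agreement and bias",
                    "significant": bool(bias.p_covariate < ALPHA),
                    "detail": f"weighted kappa={rep.weighted_kappa:.3f}, "
                    f"r={rep.pearson_r:.3f}, agreement={rep.percent_agreement:.2f}; "
                    f"bias p(family)={bias.p_family:.3f}, p(area)={bias.p_area:.3f}, "
                    f"p(humidity)={bias.p_covariate:.3f}",
                    "seed": seeds[stage],
                }
                (out / "agreement.json").write_text(json.dumps(block, indent=2))
                report.blocks[stage] = block
            elif stage == "tone_models":
                table = ablation_sweep(world)
                table.to_csv(out / "tone_ablation.csv", index=False)
                full_p = float(table.loc[table["model"] == "Full model", "p"].iloc[0])
                report.blocks[stage] = {
                    "test": "Poisson tone model, humidity effect (full model Wald p)",
                    "significant": bool(full_p < ALPHA),
                    "detail": table.to_json(orient="records"),
                    "seed": seeds[stage],
                }
            elif stage == "vowel_models":
                rng = np.random.default_rng(seeds[stage])
                scales = {
                    lid: 0.8 + 0.4 * rng.random() for lid in world["language_id"]
                }
                formants = generate_formants(scales, seed=seeds[stage] + 1)
                formants.to_csv(out / "formants.csv", index=False)
                areas = vowel_space_table(formants)
                areas.to_csv(out / "vowel_areas.csv", index=False)
                res = vowel_models(world, hull_areas=areas)
                _, _, p_hum = res.ratio_lrt_humidity
                block = {
                    "test": "vowel-ratio mixed model, humidity LRT",
                    "significant": bool(p_hum < ALPHA),
                    "detail": f"humidity LRT p={p_hum:.4f}, interaction LRT "
                    f"p={res.ratio_lrt_interaction[2]:.4f}, vowel-area humidity LRT "
                    f"p={res.area_lrt_humidity[2]:.4f}",
                    "seed": seeds[stage],
                }
                (out / "vowel_models.json").write_text(json.dumps(block, indent=2))
                report.blocks[stage] = block
            elif stage == "corpus":
                tokens, monthly = generate_corpus(
                    shift_tone3=0.0, monthly_contour_effect=0.0,
                    n_tokens=500, seed=seeds[stage],
                )
                tokens.to_csv(out / "tokens.csv", index=False)
                res = seasonal_contour(tokens, monthly)
                p = res.lrt_humidity[2] if res.lrt_humidity else float("nan")
                report.blocks[stage] = {
                    "test": "seasonal contour-tone LRT",
                    "significant": None if res.degenerate else bool(p < ALPHA),
                    "detail": f"humidity LRT p={p:.4f}, "
                    f"{res.n_excluded_months} months excluded",
                    "seed": seeds[stage],
                }
            elif stage == "dag":
                g = humidity_tone_example_graph()
                write_graph(g, out / "causal_graph.json")
                remaining = screening_set(
                    g, "humidity", "tone_inventory", {"contact"}
                )
                report.blocks[stage] = {
                    "test": "backdoor screening with contact controlled",
                    "significant": None,
                    "detail": f"open backdoor variables: {remaining or 'none'}",
                    "seed": seeds[stage],
                }
            log(f"[{stage}] done in {time.perf_counter() - t0:.1f}s")
        except Exception as exc:
            report.errors[stage] = str(exc)
            log(f"[{stage}] FAILED: {exc}")

    rows = report.summary_rows()
    summary_md = ["# Robustness summary", "",
                  f"seed: {config.seed}", "",
                  "| Stage | Test | Result |", "|---|---|---|"]
    summary_md += [f"| {r['stage']} | {r['test']} | {r['result']} |" for r in rows]
    (out / "summary.md").write_text("\n".join(summary_md) + "\n")
    (out / "report.json").write_text(
        json.dumps(
            {"seed": config.seed, "version": __version__,
             "blocks": report.blocks, "errors": report.errors},
            indent=2,
        )
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
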