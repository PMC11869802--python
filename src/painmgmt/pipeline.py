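"""End-to-end pipeline: simulate/load -> code -> describe -> fit -> counterfactuals.

`run_pipeline` executes the stages in order and writes plain CSV/JSON
artifacts plus a manifest (versions, seeds, input hashes) for
reproducibility. Every random draw flows from the single config seed through
named substreams (one per stage), so changing how many draws one stage
consumes does not perturb the others. Any stage failure aborts with the
stage name and removes the partial outputs of this run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boosting import BRTParams
from .counterfactual import (
    Scenario,
    preset_all_benefits,
    preset_all_familiarity,
    preset_most_important,
)
from .descriptives import group_comparison_grid, tabulate
from .model import PharmUseBRT
from .schema import SurveySchema, build_coded_matrix, read_survey_csv
from .simulate import GeneratorConfig, generate_survey

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_reports",
           "substream_seed"]


def substream_seed(seed: int, name: str) -> int:
    """Named substream: a deterministic child seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``data_path`` (survey CSV) and ``generator`` (synthetic
    mode) must be set.
    """

    out_dir: str = "painmgmt_out"
    seed: int = 0
    data_path: str | None = None
    generator: GeneratorConfig | None = None
    schema: SurveySchema = field(default_factory=SurveySchema.default)
    brt: BRTParams = field(default_factory=BRTParams)
    scenarios: list = field(default_factory=list)  # Scenario objects
    pool: list | None = None
    max_i: int = 8
    n_bootstrap: int = 1000
    verbose: bool = True

    def __post_init__(self):
        if (self.data_path is None) == (self.generator is None):
            raise ValueError("exactly one of data_path / generator must be set")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kw = {}
        for key in ("out_dir", "seed", "data_path", "max_i", "n_bootstrap", "verbose"):
            if key in raw:
                kw[key] = raw[key]
        if "schema" in raw:
            kw["schema"] = SurveySchema.from_yaml(raw["schema"]) if isinstance(
                raw["schema"], str) else SurveySchema(**raw["schema"])
        if "generator" in raw:
            kw["generator"] = GeneratorConfig(**raw["generator"])
        if "brt" in raw:
            kw["brt"] = BRTParams(**raw["brt"])
        if "scenarios" in raw:
            kw["scenarios"] = [
                Scenario(overrides=s["overrides"], label=s.get("label", ""))
                for s in raw["scenarios"]
            ]
        if "pool" in raw:
            kw["pool"] = list(raw["pool"])
        return cls(**kw)


@dataclass
class ReportBundle:
    """Paths and in-memory objects produced by one pipeline run."""

    out_dir: Path
    coded: object
    descriptives: pd.DataFrame
    or_grid: pd.DataFrame
    results: object
    estimates: list
    path: object  # IterativePath
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    t_start = time.time()
    stage_times = {}
    log = print if config.verbose else (lambda *a, **k: None)

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        created.append(path)
        return path

    current_stage = "setup"
    try:
        # -- stage 1: obtain records and code them -------------------------
        current_stage = "code"
        t0 = time.time()
        if config.generator is not None:
            gen = config.generator
            gen = type(gen)(**{**gen.__dict__,
                               "seed": substream_seed(config.seed, "generate"),
                               "schema": config.schema})
            records = generate_survey(gen)
        else:
            records = read_survey_csv(config.data_path, config.schema)
        coded = build_coded_matrix(records, config.schema)
        emit("coded.csv", lambda p: coded.to_csv(p, coding_path=out / "coding.json"))
        created.append(out / "coding.json")
        stage_times["code"] = time.time() - t0
        log(f"[code] {len(records)} records -> {coded.X.shape[1]} predictors "
            f"({stage_times['code']:.1f}s)")

        # -- stage 2: descriptive tables -----------------------------------
        current_stage = "describe"
        t0 = time.time()
        desc_rows = []
        for item in list(config.schema.demographics) + ["pain_last_year",
                                                        "opioid_risk_training"]:
            try:
                tab = tabulate(records, item, schema=config.schema)
            except Exception:
                continue
            frame = tab.rows.assign(item=item)
            desc_rows.append(frame)
        descriptives = pd.concat(desc_rows, ignore_index=True)
        emit("descriptives.csv", lambda p: descriptives.to_csv(p, index=False))
        stage_times["describe"] = time.time() - t0
        log(f"[describe] {len(descriptives)} table rows ({stage_times['describe']:.1f}s)")

        # -- stage 3: odds-ratio grid --------------------------------------
        current_stage = "or_grid"
        t0 = time.time()
        or_grid = group_comparison_grid(coded)
        emit("or_grid.csv", lambda p: or_grid.to_csv(p, index=False))
        stage_times["or_grid"] = time.time() - t0
        log(f"[or_grid] {len(or_grid)} cells, "
            f"{int(or_grid['significant'].sum())} significant "
            f"({stage_times['or_grid']:.1f}s)")

        # -- stage 4: fit the ensemble, relative influence ------------------
        current_stage = "fit"
        t0 = time.time()
        params = BRTParams(**{**config.brt.__dict__,
                              "seed": substream_seed(config.seed, "fit")})
        results = PharmUseBRT.from_coded(coded, params=params).fit()
        results.save(out / "model.json")
        created.append(out / "model.json")
        ri = results.relative_influence().summary_frame()
        ri.index.name = "predictor"
        emit("relative_influence.csv", lambda p: ri.to_csv(p))
        stage_times["fit"] = time.time() - t0
        log(f"[fit] deviance {results.train_deviance[0]:.3f} -> "
            f"{results.train_deviance[-1]:.3f}; "
            f"{int(ri['above_threshold'].sum())} predictors above "
            f"{results.influence_threshold:.1f}% ({stage_times['fit']:.1f}s)")

        # -- stage 5: counterfactual scenarios ------------------------------
        current_stage = "counterfactual"
        t0 = time.time()
        scenarios = list(config.scenarios)
        if not scenarios:
            top = preset_most_important(results.model, config.schema, k=6)
            singles = [Scenario.single(c) for c in top.overrides]
            scenarios = singles + [
                top,
                preset_all_familiarity(config.schema),
                preset_all_benefits(config.schema),
            ]
        boot_seed = substream_seed(config.seed, "bootstrap")
        estimates = results.combined_scenarios(
            scenarios, n_bootstrap=config.n_bootstrap, seed=boot_seed
        )
        emit("scenarios.json", lambda p: p.write_text(
            json.dumps([e.as_dict() for e in estimates], indent=2)))
        stage_times["counterfactual"] = time.time() - t0
        log(f"[counterfactual] {len(estimates)} scenarios "
            f"({stage_times['counterfactual']:.1f}s)")

        # -- stage 6: iterative best-set search ------------------------------
        current_stage = "search"
        t0 = time.time()
        pool = config.pool
        if pool is None:
            ri_series = results.relative_influence().per_predictor
            mods = [c for c in ri_series.sort_values(ascending=False).index
                    if c in set(config.schema.modifiable_columns)]
            pool = mods[:10]
        path = results.iterative_search(
            pool, max_i=min(config.max_i, len(pool)),
            n_bootstrap=config.n_bootstrap,
            seed=substream_seed(config.seed, "search"),
        )
        emit("iterative.csv", lambda p: path.as_frame().to_csv(p, index=False))
        stage_times["search"] = time.time() - t0
        log(f"[search] {len(path.steps)} steps ({stage_times['search']:.1f}s)")

        # -- manifest --------------------------------------------------------
        current_stage = "manifest"
        manifest = {
            "painmgmt_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "substreams": {name: substream_seed(config.seed, name)
                           for name in ("generate", "fit", "bootstrap", "search")},
            "inputs": {},
            "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        if config.data_path:
            manifest["inputs"][config.data_path] = _sha256(Path(config.data_path))
        for p in created:
            if p.exists():
                manifest["inputs"][p.name] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log(f"[done] {time.time() - t_start:.1f}s -> {out}")
        return ReportBundle(
            out_dir=out, coded=coded, descriptives=descriptives, or_grid=or_grid,
            results=results, estimates=estimates, path=path, manifest=manifest,
        )
    except Exception as err:
        for p in created:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {err}") from err


def render_reports(bundle: ReportBundle, figures: bool = True) -> dict:
    """Forest-plot CSVs/figures and a markdown summary of the estimates."""
    out = bundle.out_dir
    paths = {}

    rows = [e.as_dict() for e in bundle.estimates]
    forest = pd.DataFrame(rows)
    if rows:
        forest = forest.sort_values("point_percent", ascending=False)
    forest_path = out / "forest.csv"
    forest.to_csv(forest_path, index=False)
    paths["forest"] = forest_path

    lines = ["# Counterfactual reduction estimates", ""]
    if not rows:
        lines.append("no scenarios evaluated")
    else:
        lines.append("| scenario | reduction % | 95% CI |")
        lines.append("|---|---|---|")
        for r in forest.itertuples():
            lines.append(
                f"| {r.label} | {r.point_percent:.1f} | "
                f"({r.ci95_low:.1f}, {r.ci95_high:.1f}) |"
            )
        if bundle.path.steps:
            lines += ["", "## Iterative best-set path", "",
                      "| step | added factor | cumulative reduction % | 95% CI |",
                      "|---|---|---|---|"]
            for r in bundle.path.as_frame().itertuples():
                lines.append(
                    f"| {r.step} | {r.added_factor} | {r.point_percent:.1f} | "
                    f"({r.ci95_low:.1f}, {r.ci95_high:.1f}) |"
                )
    md_path = out / "report.md"
    md_path.write_text("\n".join(lines) + "\n")
    paths["markdown"] = md_path

    if figures and rows:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 0.45 * len(forest) + 1.5))
        ys = np.arange(len(forest))[::-1]
        pt = forest["point_percent"].to_numpy()
        ax.errorbar(
            pt, ys,
            xerr=[pt - forest["ci95_low"].to_numpy(),
                  forest["ci95_high"].to_numpy() - pt],
            fmt="o", capsize=3,
        )
        ax.axvline(0.0, color="grey", lw=1)
        ax.set_yticks(ys)
        ax.set_yticklabels(forest["label"])
        ax.set_xlabel("estimated % reduction in pharmacological use (95% CI)")
        fig.tight_layout()
        fig_path = out / "forest.svg"
        fig.savefig(fig_path)
        plt.close(fig)
        paths["forest_figure"] = fig_path

        if bundle.path.steps:
            frame = bundle.path.as_frame()
            fig, ax = plt.subplots(figsize=(7, 4))
            pt = frame["point_percent"].to_numpy()
            ax.errorbar(
                frame["step"].to_numpy(), pt,
                yerr=[pt - frame["ci95_low"].to_numpy(),
                      frame["ci95_high"].to_numpy() - pt],
                fmt="-o", capsize=3,
            )
            ax.axhline(0.0, color="grey", lw=1)
            ax.set_xlabel("number of factors in the intervention set")
            ax.set_ylabel("cumulative % reduction (95% CI)")
            fig.tight_layout()
            fig_path = out / "iterative.svg"
            fig.savefig(fig_path)
            plt.close(fig)
            paths["iterative_figure"] = fig_path
    return paths
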