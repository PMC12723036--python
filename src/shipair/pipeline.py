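"""End-to-end orchestration: world -> training -> evaluation -> scenarios ->
health burden -> cost-benefit -> consolidated report.

Every stage is independently runnable, seeded deterministically from the
global seed, resumable (existing artifacts are reused when ``resume`` is
set), and writes plain artifacts (NetCDF / CSV / JSON) into the run
directory.  A stage failure raises :class:`StageError` carrying the stage
name; artifacts of completed stages persist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, costs, evaluation, health, scenarios
from . import emulator as em
from . import synthetic_world as sw

log = logging.getLogger("shipair")

STAGES = ("world", "train", "evaluate", "scenarios", "health", "costs", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; YAML round-trippable."""

    seed: int = 0
    nx: int = 48
    ny: int = 48
    cell_km: float = 36.0
    n_years: int = 5
    months: tuple = sw.MONTHS
    train: em.TrainConfig = field(default_factory=lambda: em.TrainConfig(
        pretrain_iters=100, pretrain_lr=3e-3, formal_max_iters=300,
        formal_lr0=3e-3, width=16, n_res_blocks=8))
    variants: tuple = ("full",)
    with_rf: bool = True
    scenario_engine: str = "emulator"   # or "truth"
    region: str = "all-coastal"
    population_total: float = 4.0e8
    vsl_usd: float = 1.0e6
    premium_usd_per_ton: float = costs.DEFAULT_PREMIUM
    resume: bool = True
    out_dir: str = "runs/default"

    def stage_seed(self, stage: str, k: int = 0) -> int:
        return (self.seed * 1000 + STAGES.index(stage) * 100 + k) % (2 ** 31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        train_raw = raw.pop("train", {})
        cfg = cls(**{k: v for k, v in raw.items() if k != "train"})
        cfg.train = em.TrainConfig(**{**dataclasses.asdict(cfg.train), **train_raw})
        cfg.months = tuple(cfg.months)
        cfg.variants = tuple(cfg.variants)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["months"] = list(self.months)
        d["variants"] = list(self.variants)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def _artifact(run_dir: Path, name: str) -> Path:
    return run_dir / name


def run_pipeline(cfg: RunConfig, stages=None) -> dict:
    """Run the requested stages (all by default); returns artifact paths."""
    stages = list(stages or STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise StageError(unknown[0], "unknown stage name")
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    artifacts = {}
    state = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("stage %s (seed %d)", stage, cfg.stage_seed(stage))
        try:
            _STAGE_FNS[stage](cfg, run_dir, state, artifacts)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
    return artifacts


def _load_world(cfg, run_dir, state):
    if "samples" not in state:
        ds_path = _artifact(run_dir, "dataset.nc")
        if not ds_path.exists():
            raise StageError("world", f"missing dataset artifact {ds_path}; "
                             "run the world stage first")
        state["samples"], state["grid"], state["params"] = sw.load_dataset(ds_path)
    return state["samples"], state["grid"], state["params"]


def _stage_world(cfg, run_dir, state, artifacts):
    path = _artifact(run_dir, "dataset.nc")
    if cfg.resume and path.exists():
        log.info("world: reusing %s", path)
    else:
        grid = sw.build_grid(cfg.nx, cfg.ny, cfg.cell_km,
                             seed=cfg.stage_seed("world"))
        params = sw.WorldParams()
        samples = sw.make_dataset(grid, params, cfg.n_years,
                                  seed=cfg.stage_seed("world", 1))
        sw.save_dataset(path, samples, grid, params)
    state.pop("samples", None)
    artifacts["dataset"] = path
    _load_world(cfg, run_dir, state)


def _ckpt_path(run_dir, variant, month):
    return _artifact(run_dir, f"model_{variant}_{month}.npz")


def _stage_train(cfg, run_dir, state, artifacts):
    samples, grid, params = _load_world(cfg, run_dir, state)
    train_samples = [s for s in samples if not s.is_test]
    traces = []
    for variant in cfg.variants:
        for k, month in enumerate(cfg.months):
            path = _ckpt_path(run_dir, variant, month)
            if cfg.resume and path.exists():
                continue
            vcfg = baselines.build_variant(variant, cfg.train)
            vcfg = dataclasses.replace(
                vcfg, seed=cfg.stage_seed("train", k))
            model = em.train_emulator(train_samples, vcfg, month=month,
                                      with_discriminator=vcfg.w_adv != 0.0)
            em.save_emulator(path, model)
            for i, (pre, form) in enumerate(
                    [(l, None) for l in model.pretrain_trace] +
                    [(None, l) for l in model.formal_trace]):
                traces.append({"variant": variant, "month": month, "step": i,
                               "pretrain_loss": pre, "formal_loss": form})
    if traces:
        pd.DataFrame(traces).to_csv(_artifact(run_dir, "train_traces.csv"),
                                    index=False)
    artifacts["checkpoints"] = [
        _ckpt_path(run_dir, v, m) for v in cfg.variants for m in cfg.months]


def _load_models(cfg, run_dir, variant):
    models = {}
    for month in cfg.months:
        path = _ckpt_path(run_dir, variant, month)
        if not path.exists():
            raise FileNotFoundError(f"missing checkpoint {path}")
        models[month] = em.load_emulator(path)
    return models


def _stage_evaluate(cfg, run_dir, state, artifacts):
    samples, grid, params = _load_world(cfg, run_dir, state)
    test = [s for s in samples if s.is_test and s.month_label in cfg.months]
    train_samples = [s for s in samples if not s.is_test]
    predictions = {}
    for variant in cfg.variants:
        models = _load_models(cfg, run_dir, variant)
        predictions[variant] = {
            month: (lambda s, m=models[month]:
                    em.predict_shipping_pm(m, s).shipping["pm25"])
            for month in cfg.months}
    if cfg.with_rf:
        rf_cfg = baselines.RFConfig(seed=cfg.stage_seed("evaluate"))
        rf_months = {}
        for month in cfg.months:
            table = baselines.rf_featurize(
                [s for s in train_samples if s.month_label == month],
                rf_cfg.window)
            model, _ = baselines.rf_train_cv(table, rf_cfg, run_cv=False)
            rf_months[month] = (lambda s, m=model, w=rf_cfg.window:
                                baselines.rf_predict_field(m, s, w))
        predictions["rf"] = rf_months
    table = evaluation.compare_models(
        predictions, test, truth_fn=lambda s: s.truth.shipping_pm25())
    path = _artifact(run_dir, "metrics.csv")
    table.to_csv(path, index=False)
    artifacts["metrics"] = path


def _shipping_pm_fn(cfg, run_dir, params):
    if cfg.scenario_engine == "truth":
        return scenarios.truth_shipping_pm(params)
    models = _load_models(cfg, run_dir, cfg.variants[0])
    return scenarios.emulator_shipping_pm(models)


def _baseline_year(samples, cfg):
    last = max(s.year_index for s in samples)
    return [s for s in samples if s.year_index == last and
            s.month_label in cfg.months]


def _stage_scenarios(cfg, run_dir, state, artifacts):
    samples, grid, params = _load_world(cfg, run_dir, state)
    baseline = _baseline_year(samples, cfg)
    fn = _shipping_pm_fn(cfg, run_dir, params)
    rows = []
    for sc in scenarios.build_idealized_set() + scenarios.build_policy_set():
        res = scenarios.benefit(fn, baseline, sc, grid)
        rows.append({"scenario": sc.id, "zone": sc.zone,
                     **{f"benefit_{k}": v for k, v in res.regional_means.items()}})
    path = _artifact(run_dir, "scenario_benefits.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    artifacts["scenario_benefits"] = path


def _policy_total_fields(cfg, run_dir, state):
    """Baseline and per-policy-scenario 4-month-mean total PM2.5 fields."""
    samples, grid, params = _load_world(cfg, run_dir, state)
    baseline = _baseline_year(samples, cfg)
    zones = scenarios.coastal_zones(grid)
    if cfg.scenario_engine == "truth":
        def total_fn(s):
            return sw.surrogate_chemistry(s.emissions, s.met, params).total_pm25()
    else:
        models = _load_models(cfg, run_dir, cfg.variants[0])

        def total_fn(s):
            return em.predict_shipping_pm(models[s.month_label], s).total["pm25"]

    base_field = np.mean([total_fn(s) for s in baseline], axis=0)
    fields = {}
    for sc in scenarios.build_policy_set():
        scen = []
        for s in baseline:
            scaled = scenarios.apply_scenario(s.emissions, sc, zones)
            s2 = sw.MonthSample(year_index=s.year_index,
                                month_label=s.month_label, emissions=scaled,
                                met=s.met, truth=s.truth, is_test=s.is_test)
            scen.append(total_fn(s2))
        fields[sc.id] = np.mean(scen, axis=0)
    return base_field, fields, grid


def _stage_health(cfg, run_dir, state, artifacts):
    base_field, fields, grid = _policy_total_fields(cfg, run_dir, state)
    pop = health.synthetic_population(grid, total=cfg.population_total)
    bmr = health.synthetic_mortality_table()
    valuation = health.ValuationParams(vsl_usd=cfg.vsl_usd)
    out = {}
    for sid, scen_field in fields.items():
        res = health.avoided_deaths_and_value(
            base_field, scen_field, pop, bmr, valuation=valuation,
            scenario_id=sid)
        out[sid] = {
            "avoided_deaths": res.avoided_total,
            "by_endpoint": {k: float(v)
                            for k, v in res.avoided_by_endpoint.items()},
            "value_usd": res.value_usd,
        }
    path = _artifact(run_dir, "burden.json")
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
    artifacts["burden"] = path


def _stage_costs(cfg, run_dir, state, artifacts):
    burden_path = _artifact(run_dir, "burden.json")
    if not burden_path.exists():
        raise StageError("costs", "missing burden.json; run the health stage")
    with open(burden_path) as fh:
        burden = json.load(fh)
    cost_map = {}
    for sc in scenarios.build_policy_set():
        cost_map[sc.id] = costs.policy_scenario_cost(
            sc.id, sc.zone, premium=cfg.premium_usd_per_ton)
    benefit_map = {sid: rec["value_usd"] for sid, rec in burden.items()}
    table = costs.policy_cost_benefit(cost_map, benefit_map)
    path = _artifact(run_dir, "cost_benefit.csv")
    table.to_csv(path)
    artifacts["cost_benefit"] = path


def _stage_report(cfg, run_dir, state, artifacts):
    paths = write_report(run_dir)
    artifacts.update(paths)


_STAGE_FNS = {
    "world": _stage_world, "train": _stage_train, "evaluate": _stage_evaluate,
    "scenarios": _stage_scenarios, "health": _stage_health,
    "costs": _stage_costs, "report": _stage_report,
}

_REPORT_INPUTS = {
    "metrics": "metrics.csv",
    "scenario_benefits": "scenario_benefits.csv",
    "burden": "burden.json",
    "cost_benefit": "cost_benefit.csv",
}


def write_report(run_dir) -> dict:
    """Consolidate run artifacts into report.json and report.txt.

    Raises FileNotFoundError listing every missing artifact if the run is
    incomplete.
    """
    run_dir = Path(run_dir)
    missing = [name for name in _REPORT_INPUTS.values()
               if not (run_dir / name).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run directory {run_dir}: missing {missing}")
    metrics = pd.read_csv(run_dir / "metrics.csv")
    bens = pd.read_csv(run_dir / "scenario_benefits.csv")
    with open(run_dir / "burden.json") as fh:
        burden = json.load(fh)
    cb = pd.read_csv(run_dir / "cost_benefit.csv")
    policy_ids = {sc.id for sc in scenarios.build_policy_set()}
    report = {
        "model_comparison": metrics.to_dict(orient="records"),
        "idealized_scenarios": bens[~bens["scenario"].isin(policy_ids)]
            .to_dict(orient="records"),
        "policy_scenarios": bens[bens["scenario"].isin(policy_ids)]
            .to_dict(orient="records"),
        "health_burden": burden,
        "cost_benefit": cb.to_dict(orient="records"),
    }
    json_path = run_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    lines = ["shipair run report", "=" * 40, "",
             "Model comparison (test year):",
             metrics.to_string(index=False), "",
             f"Idealized scenarios: {len(report['idealized_scenarios'])} rows "
             "(see scenario_benefits.csv)", "",
             "Policy scenarios (avoided deaths, monetized):"]
    for sid, rec in burden.items():
        lines.append(f"  {sid}: {rec['avoided_deaths']:.1f} deaths avoided, "
                     f"USD {rec['value_usd'] / 1e6:.1f} M")
    lines += ["", "Cost-benefit:", cb.to_string(index=False), ""]
    txt_path = run_dir / "report.txt"
    txt_path.write_text("\n".join(lines))
    return {"report_json": json_path, "report_txt": txt_path}
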