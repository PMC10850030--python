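"""End-to-end experiment: train surrogates, project periods, compare.

Stages per workplace: (1) obtain a training-era outdoor and indoor series,
(2) fill indoor PET, (3) train one surrogate per target (indoor air
temperature and indoor PET), (4) project the historical period from the
reference outdoor series, (5) per scenario member, bias-correct and
project the future period, (6) exposure metrics per period, (7) ensemble
aggregation per scenario label and period deltas.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import comfort, metrics, qdm, surrogate, synthetic
from .series import IndoorSeries, MeteoSeries

logger = logging.getLogger("indoorclim")

WORKPLACE_TYPES = (
    "office",
    "laboratory/workshop",
    "production",
    "storage/logistics",
    "agriculture/forestry",
)


@dataclass
class PeriodSpec:
    """Start year and length of a projection period."""

    start_year: int
    n_years: int
    label: str


@dataclass
class WorkplaceConfig:
    """One workplace: building (synthetic mode) or sensor path (ingest)."""

    workplace_id: str = "wp01"
    type_label: str = "office"
    building: synthetic.BuildingParameters | None = field(
        default_factory=synthetic.BuildingParameters
    )
    sensor_path: str | None = None
    climate: synthetic.OutdoorClimateConfig = field(
        default_factory=synthetic.OutdoorClimateConfig
    )
    person: comfort.PersonParameters = field(default_factory=comfort.PersonParameters)
    seed: int = 0
    training_years: int = 2
    training_start_year: int = 2021
    historical: PeriodSpec = field(
        default_factory=lambda: PeriodSpec(1970, 3, "historical")
    )
    future: PeriodSpec = field(default_factory=lambda: PeriodSpec(2070, 3, "future"))
    run_method: str = "within-year"
    hyper: surrogate.Hyperparameters | None = None

    def validate(self) -> None:
        if (self.building is None) == (self.sensor_path is None):
            raise ValueError("exactly one of building parameters / sensor path must be set")
        if self.type_label not in WORKPLACE_TYPES:
            raise ValueError(f"unknown workplace type {self.type_label!r}")


@dataclass
class MemberProjection:
    """Future projection of one scenario ensemble member."""

    label: str
    member: str
    report: metrics.HeatMetricsReport
    correction_log: qdm.CorrectionLog
    outdoor_mean_ta: float
    outdoor_mean_ta_djf: float
    outdoor_mean_ta_jja: float


@dataclass
class ProjectionReport:
    """Full per-workplace result: historical, members, ensembles, deltas."""

    workplace_id: str
    type_label: str
    historical: metrics.HeatMetricsReport
    historical_outdoor: dict[str, float]
    members: list[MemberProjection]
    ensembles: dict[str, dict]
    deltas: dict[str, dict]
    models: dict[str, surrogate.SurrogateModel]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "workplace_id": self.workplace_id,
            "type_label": self.type_label,
            "seed": self.seed,
            "historical": self.historical.to_flat_dict(),
            "historical_outdoor": self.historical_outdoor,
            "members": [
                {
                    "label": m.label,
                    "member": m.member,
                    "metrics": m.report.to_flat_dict(),
                    "outdoor_mean_ta": m.outdoor_mean_ta,
                    "outdoor_mean_ta_DJF": m.outdoor_mean_ta_djf,
                    "outdoor_mean_ta_JJA": m.outdoor_mean_ta_jja,
                    "qdm_repairs": m.correction_log.repairs,
                }
                for m in self.members
            ],
            "ensembles": self.ensembles,
            "deltas": self.deltas,
            "model_metadata": {
                target: {
                    "test_mae": model.test_mae,
                    "epochs_run": model.epochs_run,
                    "best_epoch": model.best_epoch,
                }
                for target, model in self.models.items()
            },
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, default=float)


_STAGE_SEEDS = {
    "training-weather": 11,
    "indoor": 23,
    "split-ti": 31,
    "split-pet": 37,
    "train-ti": 41,
    "train-pet": 43,
    "historical-weather": 53,
    "member-weather": 61,
    "member-hist-weather": 67,
}


def _seed_for(master: int, stage: str, extra: int = 0) -> int:
    return int(
        np.random.SeedSequence([master, _STAGE_SEEDS[stage], extra]).generate_state(1)[0]
    )


def _training_series(cfg: WorkplaceConfig) -> tuple[MeteoSeries, IndoorSeries]:
    climate = replace(
        cfg.climate,
        span_years=cfg.training_years,
        start_year=cfg.training_start_year,
        seed=_seed_for(cfg.seed, "training-weather"),
    )
    outdoor = synthetic.generate_outdoor_series(climate)
    if cfg.sensor_path is not None:
        indoor = IndoorSeries.from_csv(cfg.sensor_path, step_hours=outdoor.step_hours)
        if not indoor.data.index.equals(outdoor.data.index):
            indoor.data = indoor.data.reindex(outdoor.data.index).dropna()
    else:
        indoor = synthetic.simulate_indoor(
            outdoor, cfg.building, seed=_seed_for(cfg.seed, "indoor")
        )
    return outdoor, indoor


def _train_models(
    cfg: WorkplaceConfig, outdoor: MeteoSeries, indoor: IndoorSeries
) -> dict[str, surrogate.SurrogateModel]:
    X = surrogate.build_feature_matrix(outdoor)
    models = {}
    for target in ("ti", "pet"):
        y = indoor.data.loc[X.index, target]
        split = surrogate.split_dataset(len(X), seed=_seed_for(cfg.seed, f"split-{target}"))
        model = surrogate.train_surrogate(
            X,
            y,
            split,
            hyper=cfg.hyper,
            seed=_seed_for(cfg.seed, f"train-{target}"),
            workplace_id=cfg.workplace_id,
            target=target,
        )
        logger.info(
            "workplace %s target %s: test MAE %.3f K, stopped at epoch %d (best %d)",
            cfg.workplace_id,
            target,
            model.test_mae,
            model.epochs_run,
            model.best_epoch,
        )
        models[target] = model
    return models


def _project_period(
    models: dict[str, surrogate.SurrogateModel],
    outdoor: MeteoSeries,
    period: str,
    step_hours: int,
    run_method: str,
) -> metrics.HeatMetricsReport:
    ti_pred = metrics.to_noleap(surrogate.predict_series(models["ti"], outdoor))
    pet_pred = metrics.to_noleap(surrogate.predict_series(models["pet"], outdoor))
    return metrics.compute_report(
        ti_pred, pet_pred, step_hours, period=period, run_method=run_method
    )


def _outdoor_means(series: MeteoSeries) -> dict[str, float]:
    ta = metrics.to_noleap(series.data["ta"])
    return {
        "mean_ta": float(ta.mean()),
        "mean_ta_DJF": float(ta[ta.index.month.isin((12, 1, 2))].mean()),
        "mean_ta_JJA": float(ta[ta.index.month.isin((6, 7, 8))].mean()),
    }


def aggregate_ensemble(member_flats: list[dict[str, float]], label: str) -> dict:
    """Mean, median and min-max range per metric across members."""
    if not member_flats:
        raise ValueError("need at least one member")
    keys = sorted(set().union(*(m.keys() for m in member_flats)))
    summary: dict = {"label": label, "n_members": len(member_flats), "metrics": {}}
    for key in keys:
        values = np.array([m[key] for m in member_flats if key in m], dtype=float)
        summary["metrics"][key] = {
            "mean": float(values.mean()),
            "median": float(np.median(values)),
            "min": float(values.min()),
            "max": float(values.max()),
        }
    return summary


def compare_periods(hist: dict[str, float], fut: dict[str, float]) -> dict[str, dict]:
    """Absolute deltas and percent changes (None where historical is 0)."""
    out = {}
    for key in sorted(set(hist) & set(fut)):
        delta = fut[key] - hist[key]
        pct = None if hist[key] == 0 else 100.0 * delta / hist[key]
        out[key] = {"historical": hist[key], "future": fut[key], "delta": delta, "pct": pct}
    return out


def run_workplace_projection(
    cfg: WorkplaceConfig, scenarios: list[synthetic.ScenarioConfig]
) -> ProjectionReport:
    """Execute all stages for one workplace and a scenario ensemble."""
    cfg.validate()
    if not scenarios:
        raise ValueError("need at least one scenario")

    logger.info("stage 1-2: training data for %s", cfg.workplace_id)
    train_outdoor, indoor = _training_series(cfg)
    if indoor.data["pet"].isna().any():
        comfort.fill_pet(indoor, person=cfg.person)

    logger.info("stage 3: surrogate training")
    models = _train_models(cfg, train_outdoor, indoor)

    logger.info("stage 4: historical projection")
    hist_climate = replace(
        cfg.climate,
        span_years=cfg.historical.n_years,
        start_year=cfg.historical.start_year,
        seed=_seed_for(cfg.seed, "historical-weather"),
    )
    obs_hist = synthetic.generate_outdoor_series(hist_climate)
    hist_report = _project_period(
        models, obs_hist, cfg.historical.label, obs_hist.step_hours, cfg.run_method
    )

    members: list[MemberProjection] = []
    for k, scn in enumerate(scenarios):
        logger.info("stage 5: member %s/%s", scn.label, scn.member)
        bias_only = synthetic.ScenarioConfig(
            label=scn.label, member=scn.member, bias=dict(scn.bias)
        )
        mod_hist_raw = synthetic.generate_outdoor_series(
            replace(hist_climate, seed=_seed_for(cfg.seed, "member-hist-weather", k))
        )
        mod_hist = synthetic.apply_climate_scenario(mod_hist_raw, bias_only)

        fut_climate = replace(
            cfg.climate,
            span_years=cfg.future.n_years,
            start_year=cfg.future.start_year,
            seed=_seed_for(cfg.seed, "member-weather", k),
        )
        mod_fut = synthetic.apply_climate_scenario(
            synthetic.generate_outdoor_series(fut_climate), scn
        )
        corrected, log = qdm.correct_scenario(obs_hist, mod_hist, mod_fut)
        if log.total_repairs():
            logger.info("QDM repairs for %s/%s: %s", scn.label, scn.member, log.repairs)

        report = _project_period(
            models, corrected, cfg.future.label, corrected.step_hours, cfg.run_method
        )
        means = _outdoor_means(corrected)
        members.append(
            MemberProjection(
                label=scn.label,
                member=scn.member,
                report=report,
                correction_log=log,
                outdoor_mean_ta=means["mean_ta"],
                outdoor_mean_ta_djf=means["mean_ta_DJF"],
                outdoor_mean_ta_jja=means["mean_ta_JJA"],
            )
        )

    logger.info("stage 6-7: aggregation and deltas")
    hist_flat = hist_report.to_flat_dict()
    ensembles, deltas = {}, {}
    for label in sorted({m.label for m in members}):
        flats = [m.report.to_flat_dict() for m in members if m.label == label]
        ensembles[label] = aggregate_ensemble(flats, label)
        ens_mean = {k: v["mean"] for k, v in ensembles[label]["metrics"].items()}
        deltas[label] = compare_periods(hist_flat, ens_mean)

    return ProjectionReport(
        workplace_id=cfg.workplace_id,
        type_label=cfg.type_label,
        historical=hist_report,
        historical_outdoor=_outdoor_means(obs_hist),
        members=members,
        ensembles=ensembles,
        deltas=deltas,
        models=models,
        seed=cfg.seed,
    )
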