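"""End-to-end benchmark orchestration.

``run_benchmark`` wires the full study together: simulate (or load) a
cohort, impute and scale, train every requested architecture under the
common protocol with repeated contiguous splits, evaluate the seven
metrics and the Parkes grid per horizon, build per-fold-per-patient RMSE
loss matrices, and run the three comparison procedures at 30, 60 and the
combined 30∪60 horizons. Ensembles are evaluated from cached member
predictions, so each member architecture is trained exactly once per
(patient, fold, horizon).

One config plus one seed determines every output byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import LossMatrix, mcs, multi_horizon, pl_ranking, spa
from .metrics import compute_metrics, aggregate_patients
from .parkes import peg_summary
from .series import read_series_csv, unscale_bg
from .simulate import SimConfig, inject_gaps, simulate_cohort
from .training import (
    TrainingProtocol,
    fold_split,
    preprocess_series,
    train_model,
    _subset,
)
from .zoo import (
    BASE_SPEC_IDS,
    ENSEMBLE_MEMBERS,
    PredictionSet,
    SPEC_IDS,
    ensemble_predict,
)

__all__ = ["BenchmarkConfig", "run_benchmark"]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Fully serializable description of one benchmark run."""

    specs: tuple = SPEC_IDS
    horizons: tuple = (30, 60, 120)
    sim: SimConfig = field(default_factory=SimConfig)
    csv_path: str | None = None  # load instead of simulate when given
    split_path: str | None = None
    with_gaps: bool = True
    protocol: TrainingProtocol = field(default_factory=TrainingProtocol)
    compare: bool = True
    alpha: float = 0.05
    n_bootstrap: int = 1000
    block_length: float = 5.0
    pl_samples: int = 2000
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.specs) - set(SPEC_IDS)
        if unknown:
            raise ValueError(f"unknown specs: {sorted(unknown)}")
        for spec in self.specs:
            for member in ENSEMBLE_MEMBERS.get(spec, ()):
                if member not in self.specs:
                    raise ValueError(f"{spec} requires member {member} in specs")


def _base_specs_needed(specs) -> list:
    needed = []
    for spec in specs:
        for s in ENSEMBLE_MEMBERS.get(spec, (spec,)):
            if s in BASE_SPEC_IDS and s not in needed:
                needed.append(s)
    return needed


def run_benchmark(config: BenchmarkConfig, out_dir=None) -> dict:
    """Execute the benchmark; optionally write the report bundle to disk.

    Returns a dict with metric tables, Parkes summaries, loss matrices,
    comparison reports, the training log, and a manifest. When ``out_dir``
    is given, tables are written as delimited text plus a JSON manifest
    with content hashes.
    """
    config.validate()
    # one global seed drives simulation, training and comparison streams
    sim_cfg = replace(config.sim, seed=config.seed)
    protocol = replace(config.protocol, seed=config.seed)

    if config.csv_path is not None:
        cohort = read_series_csv(config.csv_path, config.split_path)
    else:
        cohort = simulate_cohort(sim_cfg)
        if config.with_gaps and sim_cfg.gap_rate > 0:
            cohort = [inject_gaps(s, sim_cfg) for s in cohort]

    needs_khadem = "khadem" in config.specs
    window_horizons = tuple(
        sorted(set(config.horizons) | ({30, 60} if needs_khadem else set()))
    )
    prepared = {s.patient_id: preprocess_series(s, window_horizons) for s in cohort}

    base_specs = _base_specs_needed(config.specs)
    training_log: list = []
    # cache: (spec, horizon, patient, fold) -> predicted mg/dL on test windows
    pred_cache: dict = {}
    prediction_sets: list = []

    for horizon in config.horizons:
        for pid, (train_w, test_w) in prepared.items():
            actual = unscale_bg(test_w.targets[horizon])
            for fold in range(protocol.folds):
                tr_idx, va_idx = fold_split(len(train_w), fold, protocol)
                proto_f = replace(protocol, seed=protocol.seed + fold)
                for spec in base_specs:
                    model, _ = train_model(
                        spec,
                        _subset(train_w, tr_idx),
                        _subset(train_w, va_idx),
                        horizon,
                        proto_f,
                    )
                    training_log.append((spec, horizon, pid, fold))
                    pred_cache[(spec, horizon, pid, fold)] = model.predict(test_w.inputs)
                for spec in config.specs:
                    if spec in ENSEMBLE_MEMBERS:
                        predicted = ensemble_predict(
                            [
                                pred_cache[(m, horizon, pid, fold)]
                                for m in ENSEMBLE_MEMBERS[spec]
                            ]
                        )
                    else:
                        predicted = pred_cache[(spec, horizon, pid, fold)]
                    prediction_sets.append(
                        (fold, PredictionSet(pid, horizon, actual, predicted, spec))
                    )

    report = _evaluate(config, prediction_sets)
    report["training_log"] = training_log
    report["manifest"] = _manifest(config, report)
    if out_dir is not None:
        _write_bundle(report, Path(out_dir))
    return report


def _evaluate(config: BenchmarkConfig, prediction_sets) -> dict:
    metric_tables = {}
    peg_tables = {}
    loss_matrices = {}
    for horizon in config.horizons:
        rows = []
        peg_rows = []
        for spec in config.specs:
            sets = [
                (f, ps)
                for f, ps in prediction_sets
                if ps.model_id == spec and ps.horizon == horizon
            ]
            # per-patient rows: metrics averaged over folds
            by_patient: dict = {}
            for f, ps in sets:
                by_patient.setdefault(ps.patient_id, []).append(compute_metrics(ps))
            for pid, fold_rows in by_patient.items():
                df = pd.DataFrame(fold_rows)
                mean_row = df.drop(columns=["model_id", "patient_id"]).mean().to_dict()
                mean_row.update(model_id=spec, patient_id=pid, horizon=horizon)
                rows.append(mean_row)
            pooled = PredictionSet(
                "pooled",
                horizon,
                np.concatenate([ps.actual for _, ps in sets]),
                np.concatenate([ps.predicted for _, ps in sets]),
                spec,
            )
            res = peg_summary(pooled)
            peg_rows.append(
                {
                    "model_id": spec,
                    "horizon": horizon,
                    **{f"pct_{z}": res.percentages[z] for z in res.counts},
                    "pct_AB": res.ab_percent,
                    "n": res.n,
                }
            )
        metric_tables[horizon] = aggregate_patients(rows)
        peg_tables[horizon] = pd.DataFrame(peg_rows)
        # loss matrix: rows ordered by (patient, fold)
        units = sorted(
            {(ps.patient_id, f) for f, ps in prediction_sets if ps.horizon == horizon}
        )
        cols = []
        for spec in config.specs:
            lookup = {
                (ps.patient_id, f): np.sqrt(np.mean((ps.predicted - ps.actual) ** 2))
                for f, ps in prediction_sets
                if ps.model_id == spec and ps.horizon == horizon
            }
            cols.append([lookup[u] for u in units])
        arr = np.array(cols).T
        if len(config.specs) >= 2:
            loss_matrices[horizon] = LossMatrix(
                arr, tuple(config.specs), horizon=str(horizon)
            )
        else:  # a single model cannot be compared, but its losses are reported
            from types import SimpleNamespace

            loss_matrices[horizon] = SimpleNamespace(
                losses=arr, model_ids=tuple(config.specs), horizon=str(horizon)
            )

    report = {
        "metrics": metric_tables,
        "peg": peg_tables,
        "loss_matrices": loss_matrices,
        "comparisons": {},
    }
    if config.compare:
        tags = {}
        for h in (30, 60):
            if h in loss_matrices:
                tags[str(h)] = loss_matrices[h]
        if len(tags) == 2:
            tags["30∪60"] = multi_horizon(loss_matrices[30], loss_matrices[60])
        for tag, lm in tags.items():
            entry = {}
            if len(config.specs) >= 2:
                entry["pl"] = pl_ranking(
                    lm, n_samples=config.pl_samples, seed=config.seed
                )
                if lm.n_obs >= 10:
                    entry["mcs"] = mcs(
                        lm,
                        alpha=config.alpha,
                        n_bootstrap=config.n_bootstrap,
                        block_length=config.block_length,
                        seed=config.seed,
                    )
                    entry["spa"] = {
                        spec: spa(
                            lm,
                            spec,
                            n_bootstrap=config.n_bootstrap,
                            block_length=config.block_length,
                            seed=config.seed,
                        )
                        for spec in config.specs
                    }
            report["comparisons"][tag] = entry
    return report


def _manifest(config: BenchmarkConfig, report: dict) -> dict:
    digest = hashlib.sha256()
    for horizon in sorted(report["metrics"]):
        digest.update(
            report["metrics"][horizon].round(10).to_csv(index=False).encode()
        )
        digest.update(np.round(report["loss_matrices"][horizon].losses, 10).tobytes())
    return {
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "n_trainings": len(report.get("training_log", [])),
        "results_sha256": digest.hexdigest(),
    }


def _write_bundle(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for horizon, table in report["metrics"].items():
        table.to_csv(out_dir / f"metrics_{horizon}.csv", index=False)
    for horizon, table in report["peg"].items():
        table.to_csv(out_dir / f"peg_{horizon}.csv", index=False)
    for horizon, lm in report["loss_matrices"].items():
        pd.DataFrame(lm.losses, columns=lm.model_ids).to_csv(
            out_dir / f"losses_{horizon}.csv", index=False
        )
    for tag, entry in report["comparisons"].items():
        safe = tag.replace("∪", "u")
        if "pl" in entry:
            pl = entry["pl"]
            pd.DataFrame(
                {
                    "model_id": pl.model_ids,
                    "p_best": pl.p_best,
                    "ci_low": pl.ci_low,
                    "ci_high": pl.ci_high,
                }
            ).to_csv(out_dir / f"pl_{safe}.csv", index=False)
        if "mcs" in entry:
            m = entry["mcs"]
            pd.DataFrame(
                {
                    "model_id": list(m.model_ids),
                    "p_value": [m.p_values[k] for k in m.model_ids],
                    "in_set": [k in m.survivors for k in m.model_ids],
                }
            ).to_csv(out_dir / f"mcs_{safe}.csv", index=False)
        if "spa" in entry:
            pd.DataFrame(
                [
                    {
                        "benchmark": k,
                        "p_lower": v.p_lower,
                        "p_consistent": v.p_consistent,
                        "p_upper": v.p_upper,
                    }
                    for k, v in entry["spa"].items()
                ]
            ).to_csv(out_dir / f"spa_{safe}.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(report["manifest"], fh, indent=1, sort_keys=True)
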