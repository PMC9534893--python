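"""Stage orchestration: simulate -> measure -> train -> evaluate ->
sensitivity -> optimize -> report.

Every stage reads and writes files under ``config["output_dir"]``; CSV
artifacts start with a comment header recording the config hash and the
seed, so reruns are diffable and exactly reproducible.  A stage whose
upstream artifact is missing raises :class:`PipelineError` naming the
stage to run first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, sensitivity as sens
from .config import config_hash, load_config
from .exceptions import PipelineError
from .models import MLPConfig
from .morphometry import CalibrationSettings, measure_directory
from .optimize import NSGAConfig, VariableBounds, run_nsga2
from .preprocessing import DataSplit, FeatureEncoding, encode_records, split_data
from .surrogate import TraitSurrogate, fit_surrogate
from .synthetic import (
    ExperimentDesign,
    LeafShapeSpec,
    TRAITS,
    default_generator_params,
    generate_morphology,
    render_leaf_image,
)

log = logging.getLogger("gabamorph")

STAGES = ("simulate", "measure", "train", "evaluate", "sensitivity", "optimize", "report")


def _write_csv(frame: pd.DataFrame, path: Path, config: dict) -> None:
    header = f"# gabamorph config={config_hash(config)} seed={config['seed']}\n"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


def _read_csv(path: Path, upstream: str) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(f"missing artifact {path.name}; run the '{upstream}' stage first")
    return pd.read_csv(path, comment="#")


def _out(config: dict) -> Path:
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _design(config: dict) -> ExperimentDesign:
    d = config["design"]
    return ExperimentDesign(
        cultivars=tuple(d["cultivars"]),
        gaba_levels_mM=tuple(d["gaba_levels_mM"]),
        stress_levels=tuple(d["stress_levels"]),
        timepoints_days=tuple(d["timepoints_days"]),
        replicates=int(d["replicates"]),
    )


def _generator_params(config: dict):
    params = default_generator_params(seed=int(config["seed"]))
    for key, value in config.get("generator", {}).items():
        if not hasattr(params, key):
            raise PipelineError(f"unknown generator parameter: {key}")
        setattr(params, key, value)
    params.__post_init__()  # re-validate after overrides
    return params


def _encoding(config: dict) -> FeatureEncoding:
    return FeatureEncoding(one_hot=bool(config["encoding"].get("one_hot", False)))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict) -> None:
    out = _out(config)
    params = _generator_params(config)
    data = generate_morphology(_design(config), params)
    _write_csv(data, out / "dataset.csv", config)

    img_cfg = config["images"]
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    import imageio.v3 as iio

    rng = np.random.default_rng(int(config["seed"]))
    truths = {}
    for i in range(int(img_cfg["n_leaves"])):
        length = float(rng.uniform(5.5, 8.0))
        width = length * float(rng.uniform(0.35, 0.48))
        spec = LeafShapeSpec(
            length_cm=length,
            width_cm=width,
            px_per_cm=float(img_cfg["px_per_cm"]),
            speckle_rate=float(img_cfg["speckle_rate"]),
            hole_rate=float(img_cfg["hole_rate"]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, gt = render_leaf_image(spec)
        name = f"leaf_{i:03d}"
        iio.imwrite(img_dir / f"{name}.png", image)
        truths[name] = {k: v for k, v in gt.items() if k != "mask"}
    (img_dir / "ground_truth.json").write_text(json.dumps(truths, indent=1))
    log.info("simulate: %d records, %d leaf images", len(data), int(img_cfg["n_leaves"]))


def stage_measure(config: dict) -> None:
    out = _out(config)
    img_dir = out / "images"
    if not img_dir.exists():
        raise PipelineError("missing artifact images/; run the 'simulate' stage first")
    table = measure_directory(
        img_dir,
        CalibrationSettings(px_per_cm=float(config["images"]["px_per_cm"])),
        min_component_px=int(config["morphometry"]["min_component_px"]),
        petiole_opening_radius=int(config["morphometry"]["petiole_opening_radius"]),
    )
    _write_csv(table, out / "morphometry.csv", config)
    log.info("measure: %d leaves measured", len(table))


def stage_train(config: dict) -> None:
    out = _out(config)
    data = _read_csv(out / "dataset.csv", "simulate")
    encoding = _encoding(config)
    X, Y = encode_records(data, encoding)
    split = split_data(len(data), float(config["split"]["train_frac"]), int(config["seed"]))
    (out / "split.json").write_text(json.dumps(split.to_jsonable()))

    mlp_cfg = MLPConfig(
        hidden_layers=tuple(config["mlp"]["hidden_layers"]),
        l2=float(config["mlp"]["l2"]),
        max_iter=int(config["mlp"]["max_iter"]),
        seed=int(config["seed"]),
    )
    rbf_params = {
        "k": int(config["rbf"]["k"]),
        "ridge": float(config["rbf"]["ridge"]),
        "seed": int(config["seed"]),
    }
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for kind, kwargs in (("mlp", {"mlp_config": mlp_cfg}), ("rbf", {"rbf_params": rbf_params})):
        model = fit_surrogate(
            X, Y, train_idx=split.train_idx, kind=kind, encoding=encoding, **kwargs
        )
        model.save(models_dir / f"{kind}.json")
    log.info("train: MLP and RBF surrogates fitted on %d rows", len(split.train_idx))


def _load_trained(config: dict, kind: str):
    out = _out(config)
    path = out / "models" / f"{kind}.json"
    if not path.exists() or not (out / "split.json").exists():
        raise PipelineError(f"missing trained model {kind}; run the 'train' stage first")
    split = DataSplit.from_jsonable(json.loads((out / "split.json").read_text()))
    return TraitSurrogate.load(path), split


def stage_evaluate(config: dict) -> None:
    out = _out(config)
    data = _read_csv(out / "dataset.csv", "simulate")
    mlp, split = _load_trained(config, "mlp")
    rbf, _ = _load_trained(config, "rbf")
    X, Y = encode_records(data, _encoding(config))
    report = evaluation.evaluate_models({"MLP": mlp, "RBF": rbf}, X, Y, split)
    _write_csv(report, out / "metrics.csv", config)
    for cultivar in data["cultivar"].unique():
        corr = evaluation.trait_correlations(data, cultivar)
        _write_csv(
            corr.reset_index(names="trait"), out / f"correlations_{cultivar}.csv", config
        )
        _correlation_heatmap(corr, cultivar, out / f"correlations_{cultivar}.png")
    log.info("evaluate: best model by test RMSE = %s", evaluation.select_best_model(report))


def _correlation_heatmap(corr: pd.DataFrame, cultivar: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns)
    ax.set_yticks(range(len(corr)), corr.index)
    for (i, j), val in np.ndenumerate(corr.to_numpy()):
        ax.text(j, i, f"{val:.2f}", ha="center", va="center", fontsize=8)
    ax.set_title(f"Trait correlations - {cultivar}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def stage_sensitivity(config: dict) -> None:
    out = _out(config)
    data = _read_csv(out / "dataset.csv", "simulate")
    kind = config["sensitivity"]["model"]
    _, split = _load_trained(config, kind)
    encoding = _encoding(config)
    X, Y = encode_records(data, encoding)
    if kind == "mlp":
        fitter = sens.surrogate_fitter(
            "mlp",
            mlp_config=MLPConfig(
                hidden_layers=tuple(config["mlp"]["hidden_layers"]),
                l2=float(config["mlp"]["l2"]),
                max_iter=int(config["mlp"]["max_iter"]),
                seed=int(config["seed"]),
            ),
        )
    else:
        fitter = sens.surrogate_fitter(
            "rbf",
            rbf_params={
                "k": int(config["rbf"]["k"]),
                "ridge": float(config["rbf"]["ridge"]),
                "seed": int(config["seed"]),
            },
        )
    table = sens.sensitivity_analysis(
        X,
        Y,
        split.train_idx,
        fitter,
        var_names=encoding.input_names,
        mode=config["sensitivity"]["mode"],
    )
    _write_csv(table, out / "sensitivity.csv", config)
    _write_csv(sens.sensitivity_wide(table), out / "sensitivity_wide.csv", config)
    log.info("sensitivity: %s mode on %s surrogate", config["sensitivity"]["mode"], kind)


def stage_optimize(config: dict) -> None:
    out = _out(config)
    mlp, _ = _load_trained(config, "mlp")
    nsga = NSGAConfig(
        pop_size=int(config["nsga"]["pop_size"]),
        generations=int(config["nsga"]["generations"]),
        crossover_prob=float(config["nsga"]["crossover_prob"]),
        mutation_rate=float(config["nsga"]["mutation_rate"]),
        seed=int(config["seed"]),
    )
    enc = mlp.encoding
    bounds = VariableBounds(
        cultivar_codes=tuple(float(v) for v in enc.cultivar_codes.values()),
        stress_codes=tuple(float(v) for v in enc.stress_codes.values()),
    )
    result = run_nsga2(mlp, nsga, bounds)
    _write_csv(result.pareto, out / "pareto.csv", config)
    _write_csv(pd.DataFrame([result.recommendation]), out / "recommendation.csv", config)
    _write_csv(result.history, out / "convergence.csv", config)
    log.info("optimize: best F = %.4f", result.history["best_F"].iloc[-1])


def stage_report(config: dict) -> None:
    out = _out(config)
    needed = {
        "metrics.csv": "evaluate",
        "sensitivity_wide.csv": "sensitivity",
        "recommendation.csv": "optimize",
    }
    parts = [f"# gabamorph summary (config {config_hash(config)}, seed {config['seed']})\n"]
    for name, upstream in needed.items():
        frame = _read_csv(out / name, upstream)
        parts.append(f"\n## {name}\n\n{frame.to_string(index=False)}\n")
    metrics = _read_csv(out / "metrics.csv", "evaluate")
    parts.append(
        f"\nBest model by mean test RMSE: {evaluation.select_best_model(metrics)}\n"
    )
    (out / "report.md").write_text("".join(parts))
    log.info("report: wrote %s", out / "report.md")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "measure": stage_measure,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "sensitivity": stage_sensitivity,
    "optimize": stage_optimize,
    "report": stage_report,
}


def run_stage(name: str, config: dict | None = None) -> None:
    """Run one named stage with the given (already merged) config."""
    if name not in _STAGE_FUNCS:
        raise PipelineError(f"unknown stage '{name}'; choose from {STAGES}")
    _STAGE_FUNCS[name](config or load_config())


def run_all(config: dict | None = None) -> None:
    config = config or load_config()
    for name in STAGES:
        run_stage(name, config)
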