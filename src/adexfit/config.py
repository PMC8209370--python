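"""Experiment configuration parsing, validation and end-to-end execution.

A YAML (or JSON) file configures one fitting experiment: search bounds,
stimulation protocols, feature weights, simulation and optimizer settings,
and the reference source (a target file, or a synthetic ground-truth
block).  Every omitted block falls back to the full-scale study defaults:
Table-of-bounds box, weights 1/1000/1, steps of 10/16/22 pA for 1 s,
sinusoids of 6/8 pA over a 12 pA offset for 22.5 s across a theta-band
frequency grid, and optimizer settings M=100, N=10,000,000, r=0.7, l=50.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .adex import (
    DEFAULT_BOUNDS,
    PARAM_NAMES,
    AdExParameters,
    ParameterBounds,
    SimulationConfig,
    StimulusProtocol,
    build_sinusoid_protocol,
    build_step_protocol,
)
from .analysis import (
    classical_mds,
    pairwise_distances,
    parameter_summary,
    population_to_frame,
    rank_and_decompose,
)
from .features import FeatureConfig
from .fitness import FeatureWeights, ReferenceFeatures
from .reference import (
    EXAMPLE_GRC_PARAMS,
    GroundTruth,
    NoiseSpec,
    generate_reference,
    read_reference,
    write_reference,
    write_reference_csv,
)
from .uego import UEGOConfig, make_neuron_objective, run_uego

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "default_step_protocols",
    "default_sinusoid_protocols",
    "default_protocol_suite",
    "parse_config",
    "run_experiment",
]

DEFAULT_STEP_AMPLITUDES_PA = (10.0, 16.0, 22.0)
DEFAULT_STEP_DURATION_S = 1.0
DEFAULT_SIN_AMPLITUDES_PA = (6.0, 8.0)
DEFAULT_SIN_OFFSET_PA = 12.0
DEFAULT_SIN_DURATION_S = 22.5
#: Stimulation frequency grid spanning the theta band targeted in vitro.
DEFAULT_SIN_FREQUENCIES_HZ = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)


class ConfigError(ValueError):
    """Raised for malformed experiment configurations; names the field."""


def default_step_protocols(
    amplitudes_pA: Sequence[float] = DEFAULT_STEP_AMPLITUDES_PA,
    duration_s: float = DEFAULT_STEP_DURATION_S,
    onset_s: float = 0.0,
) -> list:
    return [build_step_protocol(a, duration_s, onset_s) for a in amplitudes_pA]


def default_sinusoid_protocols(
    amplitudes_pA: Sequence[float] = DEFAULT_SIN_AMPLITUDES_PA,
    offset_pA: float = DEFAULT_SIN_OFFSET_PA,
    frequencies_Hz: Sequence[float] = DEFAULT_SIN_FREQUENCIES_HZ,
    duration_s: float = DEFAULT_SIN_DURATION_S,
    onset_s: float = 0.0,
) -> list:
    return [
        build_sinusoid_protocol(a, offset_pA, f, duration_s, onset_s)
        for a in amplitudes_pA
        for f in frequencies_Hz
    ]


def default_protocol_suite() -> list:
    return default_step_protocols() + default_sinusoid_protocols()


@dataclass
class ExperimentConfig:
    """Validated, defaults-filled description of one experiment."""

    bounds: ParameterBounds = field(default_factory=lambda: DEFAULT_BOUNDS)
    protocols: list = field(default_factory=default_protocol_suite)
    weights: FeatureWeights = field(default_factory=FeatureWeights)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    uego: UEGOConfig = field(default_factory=UEGOConfig)
    reference_file: Optional[str] = None
    ground_truth_params: Optional[AdExParameters] = None
    ground_truth_noise: Optional[NoiseSpec] = None
    ground_truth_seed: int = 0
    output_dir: str = "results"


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _parse_protocols(block: dict) -> list:
    _check_keys(block, {"steps", "sinusoids", "list"}, "protocols")
    if "list" in block:
        return [StimulusProtocol.from_dict(d) for d in block["list"]]
    steps = block.get("steps", {})
    _check_keys(steps, {"amplitudes_pA", "duration_s", "onset_s"}, "protocols.steps")
    sines = block.get("sinusoids", {})
    _check_keys(
        sines,
        {"amplitudes_pA", "offset_pA", "frequencies_Hz", "duration_s", "onset_s"},
        "protocols.sinusoids",
    )
    return default_step_protocols(
        amplitudes_pA=steps.get("amplitudes_pA", DEFAULT_STEP_AMPLITUDES_PA),
        duration_s=steps.get("duration_s", DEFAULT_STEP_DURATION_S),
        onset_s=steps.get("onset_s", 0.0),
    ) + default_sinusoid_protocols(
        amplitudes_pA=sines.get("amplitudes_pA", DEFAULT_SIN_AMPLITUDES_PA),
        offset_pA=sines.get("offset_pA", DEFAULT_SIN_OFFSET_PA),
        frequencies_Hz=sines.get("frequencies_Hz", DEFAULT_SIN_FREQUENCIES_HZ),
        duration_s=sines.get("duration_s", DEFAULT_SIN_DURATION_S),
        onset_s=sines.get("onset_s", 0.0),
    )


def _parse_reference(block: dict, cfg: ExperimentConfig) -> None:
    _check_keys(block, {"file", "synthetic"}, "reference")
    if "file" in block and "synthetic" in block:
        raise ConfigError("reference: give either 'file' or 'synthetic', not both")
    if "file" in block:
        cfg.reference_file = str(block["file"])
        return
    synth = block.get("synthetic")
    if synth is None:
        raise ConfigError("reference: needs a 'file' path or a 'synthetic' block")
    _check_keys(synth, {"params", "example", "noise", "seed"}, "reference.synthetic")
    if "example" in synth:
        name = synth["example"]
        if name not in EXAMPLE_GRC_PARAMS:
            raise ConfigError(
                f"reference.synthetic.example: unknown example {name!r}; "
                f"available: {sorted(EXAMPLE_GRC_PARAMS)}"
            )
        cfg.ground_truth_params = EXAMPLE_GRC_PARAMS[name]
    elif "params" in synth:
        try:
            cfg.ground_truth_params = AdExParameters.from_dict(synth["params"])
        except ValueError as exc:
            raise ConfigError(f"reference.synthetic.params: {exc}") from exc
    else:
        raise ConfigError("reference.synthetic: needs 'params' or 'example'")
    if "noise" in synth:
        _check_keys(
            synth["noise"],
            {"mean_frequency_sd_Hz", "latency_sd_s", "burst_frequency_sd_Hz"},
            "reference.synthetic.noise",
        )
        cfg.ground_truth_noise = NoiseSpec(**synth["noise"])
    cfg.ground_truth_seed = int(synth.get("seed", 0))


def config_from_dict(doc: dict) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from a parsed mapping."""
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    allowed = {
        "bounds", "protocols", "weights", "simulation", "features",
        "uego", "reference", "output_dir",
    }
    _check_keys(doc, allowed, "configuration root")
    cfg = ExperimentConfig()
    if "bounds" in doc:
        base = DEFAULT_BOUNDS.to_dict()
        _check_keys(doc["bounds"], set(base), "bounds")
        for name, pair in doc["bounds"].items():
            if len(pair) != 2:
                raise ConfigError(f"bounds.{name}: expected [lower, upper]")
            base[name] = [float(pair[0]), float(pair[1])]
        try:
            cfg.bounds = ParameterBounds.from_dict(base)
        except ValueError as exc:
            raise ConfigError(f"bounds: {exc}") from exc
    if "protocols" in doc:
        cfg.protocols = _parse_protocols(doc["protocols"])
    if "weights" in doc:
        _check_keys(
            doc["weights"], {"mean_frequency", "latency", "burst_frequency"}, "weights"
        )
        cfg.weights = FeatureWeights(**doc["weights"])
    if "simulation" in doc:
        _check_keys(
            doc["simulation"],
            {"dt_ms", "w_init_pA", "v_init_mV", "exp_clip", "record_traces"},
            "simulation",
        )
        cfg.sim = SimulationConfig(**doc["simulation"])
    if "features" in doc:
        _check_keys(
            doc["features"],
            {"n_cycles", "analysis_onset_s", "phase_offset_deg"},
            "features",
        )
        cfg.features = FeatureConfig(**doc["features"])
    if "uego" in doc:
        _check_keys(
            doc["uego"],
            {"max_species", "max_evaluations", "min_radius", "levels", "seed"},
            "uego",
        )
        cfg.uego = UEGOConfig(**doc["uego"])
    if "reference" in doc:
        _parse_reference(doc["reference"], cfg)
    if "output_dir" in doc:
        cfg.output_dir = str(doc["output_dir"])
    return cfg


def parse_config(path) -> ExperimentConfig:
    """Read and validate a YAML/JSON experiment configuration file."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON ({exc})") from exc
    return config_from_dict(doc)


def resolve_reference(cfg: ExperimentConfig) -> ReferenceFeatures:
    """Load the target features from file, or synthesize them."""
    if cfg.reference_file is not None:
        return read_reference(cfg.reference_file)
    if cfg.ground_truth_params is None:
        raise ConfigError(
            "reference: no target file and no synthetic ground-truth block"
        )
    gt = GroundTruth(
        params=cfg.ground_truth_params,
        protocols=cfg.protocols,
        sim_config=cfg.sim,
        feature_config=cfg.features,
        noise=cfg.ground_truth_noise,
        seed=cfg.ground_truth_seed,
    )
    return generate_reference(gt)


def run_experiment(cfg: ExperimentConfig, log=print) -> dict:
    """Execute the full pipeline and write the result bundle.

    Resolves the reference, runs the multimodal optimization, ranks and
    decomposes the surviving candidates, embeds them with classical MDS,
    summarizes their parameter distributions, and writes everything (JSON +
    CSV mirrors + a per-level progress log) under ``cfg.output_dir``.
    Outputs carry no timestamps, so equal seeds give byte-identical files.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list = []

    def _log(msg: str) -> None:
        log_lines.append(msg)
        if log is not None:
            log(msg)

    reference = resolve_reference(cfg)
    if cfg.reference_file is None:
        write_reference(reference, out / "reference.json", cfg.protocols)
        write_reference_csv(reference, out / "reference.csv")

    objective = make_neuron_objective(
        cfg.bounds, cfg.protocols, reference, cfg.weights, cfg.sim, cfg.features
    )

    level_state = {}

    def observer(event, level, population):
        if event in ("init", "fuse2"):
            level_state[level] = len(population)

    population, ledger = run_uego(
        objective, cfg.bounds.dim, cfg.uego, observer=observer
    )
    for level, (used, best) in enumerate(
        zip(ledger.per_level, ledger.best_per_level), start=1
    ):
        _log(
            f"level {level:3d}  species {level_state.get(level, len(population)):3d}  "
            f"evaluations {used:8d}  best {best:.6g}"
        )
    _log(f"total evaluations {ledger.total}  best score {ledger.best:.6g}")

    table = rank_and_decompose(
        population, cfg.bounds, cfg.protocols, reference,
        cfg.weights, cfg.sim, cfg.features,
    )
    table.to_csv(out / "candidates.csv", index=False)

    if len(population) >= 2:
        D = pairwise_distances(population, cfg.bounds, space="physical")
        embedding = classical_mds(D, dims=2)
        emb = pd.DataFrame(
            {
                "candidate": np.arange(len(population)),
                "x": embedding.coordinates[:, 0],
                "y": embedding.coordinates[:, 1],
                "total": [
                    float(table.loc[table["candidate"] == k, "total"].iloc[0])
                    for k in range(len(population))
                ],
            }
        )
        emb.to_csv(out / "embedding.csv", index=False)

    summary = parameter_summary(population_to_frame(population, cfg.bounds))
    summary.to_csv(out / "parameter_summary.csv")

    result = {
        "reference_provenance": reference.provenance,
        "ledger": {
            "total_evaluations": int(ledger.total),
            "per_level": [int(v) for v in ledger.per_level],
            "best_per_level": [float(v) for v in ledger.best_per_level],
            "best": float(ledger.best),
        },
        "candidates": [
            {
                "rank": int(row["rank"]),
                "parameters": {n: float(row[n]) for n in PARAM_NAMES},
                "normalized_center": [
                    float(v) for v in population[int(row["candidate"])].center
                ],
                "radius": float(row["radius"]),
                "scores": {
                    "mean_frequency": float(row["score_mean_frequency"]),
                    "latency": float(row["score_latency"]),
                    "burst_frequency": float(row["score_burst_frequency"]),
                    "total": float(row["total"]),
                },
            }
            for _, row in table.iterrows()
        ],
    }
    (out / "result.json").write_text(json.dumps(result, indent=1, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return result
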