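"""Synthetic reference targets and reference-file input/output.

The fitting pipeline needs per-stimulus target features (mean frequency,
first-spike latency, burst frequency).  In an experimental setting these
come from patch-clamp recordings; this module emulates them by running a
chosen ground-truth parameter set through the protocol suite, optionally
adding feature-level Gaussian noise, so the whole pipeline is exercisable
and testable with no external data.  A candidate identical to the ground
truth scores exactly zero against its own noise-free reference.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .adex import AdExParameters, SimulationConfig, StimulusProtocol
from .features import FeatureConfig, extract_feature_set
from .fitness import ReferenceFeatures

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "EXAMPLE_GRC_PARAMS",
    "generate_reference",
    "perturb_reference",
    "write_reference",
    "read_reference",
    "write_reference_csv",
    "read_reference_csv",
]

#: Two example granule-cell-like AdEx configurations, shipped as plausible
#: synthetic ground truths for demonstrations and tests.  Both spike
#: regularly under 10-22 pA steps and burst under theta-band sinusoids.
EXAMPLE_GRC_PARAMS = {
    "grc_like_1": AdExParameters(
        C_m=4.226, g_L=0.333, E_L=-79.225, V_T=-20.446, Delta_T=55.881,
        V_peak=-19.981, V_r=-76.638, a=0.123, b=-0.999, tau_w=7.138,
    ),
    "grc_like_2": AdExParameters(
        C_m=4.400, g_L=0.001, E_L=-67.194, V_T=-38.149, Delta_T=54.382,
        V_peak=-7.078, V_r=-43.458, a=0.202, b=0.140, tau_w=73.441,
    ),
}

_FEATURE_UNITS = {
    "mean_frequency": "Hz",
    "first_spike_latency": "s",
    "burst_frequency": "Hz",
}


@dataclass(frozen=True)
class NoiseSpec:
    """Per-feature Gaussian noise standard deviations (all >= 0).

    Frequencies in Hz, latency in seconds.  Noise is applied at the feature
    level (not to spike trains): the objective consumes features, so this is
    where measurement scatter enters the scoring.
    """

    mean_frequency_sd_Hz: float = 0.0
    latency_sd_s: float = 0.0
    burst_frequency_sd_Hz: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mean_frequency_sd_Hz", "latency_sd_s", "burst_frequency_sd_Hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """A known parameter set plus the protocol suite that defines its targets."""

    params: AdExParameters
    protocols: Sequence[StimulusProtocol]
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    noise: Optional[NoiseSpec] = None
    seed: int = 0


def generate_reference(gt: GroundTruth) -> ReferenceFeatures:
    """Run the ground truth through the suite and freeze its features as targets.

    Deterministic for a fixed seed and configuration.  If ``gt.noise`` is
    set, feature-level Gaussian noise seeded by ``gt.seed`` is applied; the
    noise-free path is the default.  A diverged ground truth raises — a
    ground truth must be well-behaved.
    """
    fs = extract_feature_set(gt.params, gt.protocols, gt.sim_config, gt.feature_config)
    if not fs.valid:
        raise ValueError("ground-truth simulation diverged; pick a well-behaved set")
    ref = ReferenceFeatures(
        mean_frequency=dict(fs.mean_frequency),
        latency=dict(fs.latency),
        burst_frequency=dict(fs.burst_mean),
        provenance="synthetic",
    )
    if gt.noise is not None:
        ref = perturb_reference(ref, gt.noise, np.random.default_rng(gt.seed))
    return ref


def perturb_reference(
    ref: ReferenceFeatures, noise: NoiseSpec, rng: np.random.Generator
) -> ReferenceFeatures:
    """Add independent Gaussian noise per feature; frequencies clipped at 0."""
    mf = {
        k: max(0.0, v + noise.mean_frequency_sd_Hz * rng.standard_normal())
        if noise.mean_frequency_sd_Hz > 0 else v
        for k, v in sorted(ref.mean_frequency.items())
    }
    lat = {
        k: v + noise.latency_sd_s * rng.standard_normal()
        if noise.latency_sd_s > 0 else v
        for k, v in sorted(ref.latency.items())
    }
    bf = {
        k: max(0.0, v + noise.burst_frequency_sd_Hz * rng.standard_normal())
        if noise.burst_frequency_sd_Hz > 0 else v
        for k, v in sorted(ref.burst_frequency.items())
    }
    return ReferenceFeatures(
        mean_frequency=mf, latency=lat, burst_frequency=bf,
        provenance="synthetic-perturbed",
    )


def _targets(ref: ReferenceFeatures) -> list:
    rows = []
    for pid in sorted(ref.mean_frequency):
        rows.append(
            {"protocol_id": pid, "feature": "mean_frequency",
             "value": float(ref.mean_frequency[pid]), "units": "Hz"}
        )
    for pid in sorted(ref.latency):
        rows.append(
            {"protocol_id": pid, "feature": "first_spike_latency",
             "value": float(ref.latency[pid]), "units": "s"}
        )
    for pid in sorted(ref.burst_frequency):
        rows.append(
            {"protocol_id": pid, "feature": "burst_frequency",
             "value": float(ref.burst_frequency[pid]), "units": "Hz"}
        )
    return rows


def write_reference(
    ref: ReferenceFeatures,
    path,
    protocols: Optional[Sequence[StimulusProtocol]] = None,
) -> None:
    """Serialize a reference to JSON: {provenance, protocols, targets}."""
    doc = {
        "provenance": ref.provenance,
        "protocols": [p.to_dict() for p in protocols] if protocols else [],
        "targets": _targets(ref),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _parse_targets(rows, where: str) -> ReferenceFeatures:
    groups = {"mean_frequency": {}, "first_spike_latency": {}, "burst_frequency": {}}
    for k, row in enumerate(rows):
        missing = {"protocol_id", "feature", "value", "units"} - set(row)
        if missing:
            raise ValueError(f"{where}: target {k} is missing field(s) {sorted(missing)}")
        feature = row["feature"]
        if feature not in _FEATURE_UNITS:
            raise ValueError(f"{where}: target {k} has unknown feature {feature!r}")
        expected = _FEATURE_UNITS[feature]
        if row["units"] != expected:
            raise ValueError(
                f"{where}: target {k} ({feature} for {row['protocol_id']}) "
                f"must be in {expected!r}, got units {row['units']!r}"
            )
        pid = row["protocol_id"]
        if pid in groups[feature]:
            raise ValueError(f"{where}: duplicate target for {feature} of {pid}")
        groups[feature][pid] = float(row["value"])
    return ReferenceFeatures(
        mean_frequency=groups["mean_frequency"],
        latency=groups["first_spike_latency"],
        burst_frequency=groups["burst_frequency"],
        provenance="file",
    )


def read_reference(path) -> ReferenceFeatures:
    """Parse and schema-validate a JSON reference file."""
    doc = json.loads(Path(path).read_text())
    if "targets" not in doc:
        raise ValueError(f"{path}: reference file lacks the 'targets' list")
    ref = _parse_targets(doc["targets"], str(path))
    provenance = doc.get("provenance", "file")
    object.__setattr__(ref, "provenance", str(provenance))
    return ref


def read_reference_protocols(path) -> list:
    """Return the protocol suite embedded in a JSON reference file."""
    doc = json.loads(Path(path).read_text())
    return [StimulusProtocol.from_dict(d) for d in doc.get("protocols", [])]


def write_reference_csv(ref: ReferenceFeatures, path) -> None:
    """Flat CSV mirror of the targets: protocol_id, feature, value, units."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["protocol_id", "feature", "value", "units"])
        writer.writeheader()
        for row in _targets(ref):
            writer.writerow({**row, "value": repr(row["value"])})


def read_reference_csv(path) -> ReferenceFeatures:
    """Parse the CSV mirror back into :class:`ReferenceFeatures`."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return _parse_targets(rows, str(path))
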