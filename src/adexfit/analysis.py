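"""Post-processing of a final candidate population.

Ranks candidates by total score, decomposes scores per feature (with the
burst component split per sinusoidal stimulation amplitude), embeds the
population in two dimensions with classical (Torgerson) multidimensional
scaling, and summarizes parameter distributions with quartiles and 5/95
percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .adex import PARAM_NAMES, REPORT_ORDER, ParameterBounds, SimulationConfig, StimulusProtocol
from .features import FeatureConfig, extract_feature_set
from .fitness import FeatureWeights, ReferenceFeatures, total_score
from .uego import Species, denormalize

__all__ = [
    "EmbeddingResult",
    "rank_and_decompose",
    "pairwise_distances",
    "classical_mds",
    "parameter_summary",
    "population_to_frame",
]


@dataclass(frozen=True)
class EmbeddingResult:
    """Low-dimensional coordinates plus the eigenvalue spectrum of the
    centered Gram matrix.  Coordinates are centered on the origin."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray


def population_to_frame(population: Sequence[Species], bounds: ParameterBounds) -> pd.DataFrame:
    """Physical-unit parameter table of a population, one row per species."""
    rows = [denormalize(sp.center, bounds).to_dict() for sp in population]
    return pd.DataFrame(rows, columns=list(PARAM_NAMES))


def rank_and_decompose(
    population: Sequence[Species],
    bounds: ParameterBounds,
    protocols: Sequence[StimulusProtocol],
    reference: ReferenceFeatures,
    weights: FeatureWeights = FeatureWeights(),
    sim_config: SimulationConfig = SimulationConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Score table sorted by ascending total, one row per candidate.

    Scores are recomputed from scratch through the simulation pipeline and
    asserted to sum exactly to the reported total.  The burst component is
    additionally split per sinusoidal stimulation amplitude
    (``score_burst_<amp>pA`` columns).
    """
    if not population:
        raise ValueError("population is empty")
    amp_of = {
        p.protocol_id: p.amplitude_pA for p in protocols if p.kind == "sinusoid"
    }
    amplitudes = sorted(set(amp_of.values()))
    rows = []
    for idx, sp in enumerate(population):
        params = denormalize(sp.center, bounds)
        fs = extract_feature_set(params, protocols, sim_config, feature_config)
        bd = total_score(fs, reference, weights)
        assert bd.total == bd.mean_frequency + bd.latency + bd.burst_frequency
        row = {"candidate": idx, **{n: getattr(params, n) for n in REPORT_ORDER}}
        row["score_mean_frequency"] = bd.mean_frequency
        row["score_latency"] = bd.latency
        for amp in amplitudes:
            row[f"score_burst_{amp:g}pA"] = sum(
                v for pid, v in bd.burst_by_protocol.items() if amp_of[pid] == amp
            )
        row["score_burst_frequency"] = bd.burst_frequency
        row["total"] = bd.total
        row["radius"] = sp.radius
        row["cached_fitness"] = sp.fitness
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("total", kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def pairwise_distances(
    population: Sequence[Species],
    bounds: Optional[ParameterBounds] = None,
    space: str = "physical",
) -> np.ndarray:
    """Euclidean distance matrix between candidate parameter vectors.

    ``space="physical"`` (default) measures distances between raw-unit
    parameter vectors — each candidate's full vector viewed as a point, the
    "landscape" being compared; ``space="normalized"`` uses the unit-box
    centers instead.
    """
    if len(population) < 2:
        raise ValueError("need at least two candidates for a distance matrix")
    if space == "physical":
        if bounds is None:
            raise ValueError("physical-space distances require bounds")
        X = population_to_frame(population, bounds).to_numpy()
    elif space == "normalized":
        X = np.vstack([sp.center for sp in population])
    else:
        raise ValueError(f"unknown space {space!r}")
    return squareform(pdist(X, metric="euclidean"))


def classical_mds(distances: np.ndarray, dims: int = 2) -> EmbeddingResult:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix, eigendecomposes it, and
    returns the top-``dims`` coordinates scaled by the square roots of the
    eigenvalues (negative eigenvalues truncated at zero).  When the input
    distances are realizable in ``dims`` Euclidean dimensions they are
    reproduced exactly up to numerical precision.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    top = np.clip(eigval[:dims], 0.0, None)
    coords = eigvec[:, :dims] * np.sqrt(top)
    # deterministic sign convention: largest-magnitude entry positive per axis
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return EmbeddingResult(coordinates=coords, eigenvalues=eigval)


def parameter_summary(
    params_table: pd.DataFrame, ranks: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """Quartile table per parameter: median, Q1, Q3, and 5/95 percentiles.

    ``params_table`` holds one candidate per row in physical units (see
    :func:`population_to_frame`); ``ranks`` optionally restricts to a
    subset of row positions.  Quantiles use linear interpolation between
    closest ranks (the numpy default).
    """
    if ranks is not None:
        params_table = params_table.iloc[list(ranks)]
    if params_table.empty:
        raise ValueError("candidate subset is empty")
    stats = {
        "median": params_table.quantile(0.5),
        "q1": params_table.quantile(0.25),
        "q3": params_table.quantile(0.75),
        "p5": params_table.quantile(0.05),
        "p95": params_table.quantile(0.95),
    }
    return pd.DataFrame(stats)
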