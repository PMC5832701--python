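"""Comparison of simulated journeys against observed tracking data.

For each species with geolocator observations of adequate sample size
(n >= 6 individuals), repeated random subsamples of the simulated
journey distribution — matched in size to the observed sample — are
compared against the observations with a two-sided Mann-Whitney test
(asymptotic, tie-corrected); the mean U and mean p across repeats
summarise agreement, and a verdict records the direction of any bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidInputError, InvalidMetricError, SampleSizeError
from .journeys import JourneyEnsemble

__all__ = ["TrackRecord", "ComparisonResult", "compare_with_tracks",
           "MIN_TRACK_SAMPLE", "METRICS"]

MIN_TRACK_SAMPLE = 6
METRICS = ("distance_km", "duration_days", "n_stopovers")


@dataclass(frozen=True)
class TrackRecord:
    """Observed per-individual values of one metric for one species."""

    species_id: str
    metric: str
    observations: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations",
                           tuple(float(v) for v in self.observations))
        if any(v < 0 for v in self.observations):
            raise InvalidInputError("observations must be non-negative")

    @property
    def n_individuals(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class ComparisonResult:
    species_id: str
    metric: str
    mean_U: float
    mean_p: float
    n_repeats: int
    observed_mean: float
    simulated_mean: float
    verdict: str  # consistent | under_predicted | over_predicted


def compare_with_tracks(ensemble: JourneyEnsemble, tracks: TrackRecord,
                        alpha: float = 0.05, n_repeats: int = 1000,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> ComparisonResult:
    """Mann-Whitney comparison of observed tracks with repeated simulation subsamples.

    Each repeat draws ``tracks.n_individuals`` simulated values without
    replacement from the ensemble and tests them against the observations
    (two-sided).  The verdict is ``consistent`` when the mean p across
    repeats is >= ``alpha``; otherwise the sign of simulated minus
    observed mean labels the bias (``under_predicted`` when the
    simulation falls short of the observations).
    """
    n = tracks.n_individuals
    if n < MIN_TRACK_SAMPLE:
        raise SampleSizeError(
            f"{tracks.species_id}: n = {n} below the acceptable sample size "
            f"(n >= {MIN_TRACK_SAMPLE})"
        )
    if tracks.metric not in ensemble.journeys.columns:
        raise InvalidMetricError(tracks.metric)
    sim = ensemble.metric_values(tracks.metric)
    if sim.size < n:
        raise InvalidInputError(
            f"ensemble has only {sim.size} journeys; cannot subsample {n}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    obs = np.asarray(tracks.observations, dtype=float)
    # one subsample (without replacement) per repeat, tested in a single
    # vectorised asymptotic Mann-Whitney call
    draws = np.empty((n_repeats, n))
    for i in range(n_repeats):
        draws[i] = rng.choice(sim, size=n, replace=False)
    res = stats.mannwhitneyu(draws, obs[None, :], alternative="two-sided",
                             method="asymptotic", axis=-1)
    mean_u = float(np.mean(res.statistic))
    mean_p = float(np.mean(res.pvalue))

    sim_mean = float(sim.mean())
    obs_mean = float(obs.mean())
    if mean_p >= alpha:
        verdict = "consistent"
    elif sim_mean < obs_mean:
        verdict = "under_predicted"
    else:
        verdict = "over_predicted"
    return ComparisonResult(
        species_id=tracks.species_id, metric=tracks.metric,
        mean_U=mean_u, mean_p=mean_p, n_repeats=n_repeats,
        observed_mean=obs_mean, simulated_mean=sim_mean, verdict=verdict,
    )
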