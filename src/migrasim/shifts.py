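"""Range thresholding, range centres, shift vectors and comparative statistics.

Covers the comparative-statistics layer of the pipeline: converting
suitability surfaces to binary ranges, locating suitability-weighted
range centres on the sphere, measuring bearing/distance of range shifts
between scenarios, and the tests used to compare them (Watson-Williams
circular ANOVA for directions, paired t-tests for magnitudes, and a
regression slope-versus-unity test for disproportionate change).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from . import geo
from .errors import EmptyRangeError, InvalidInputError
from .grids import BinaryRange, SuitabilityGrid
from .journeys import _presence_weights

__all__ = [
    "ShiftVector",
    "CircularAnovaResult",
    "SlopeTestResult",
    "PairedTResult",
    "threshold_grid",
    "range_centre",
    "shift_vector",
    "circular_anova",
    "paired_t",
    "slope_vs_unity",
]


@dataclass(frozen=True)
class ShiftVector:
    """Bearing and distance of a range-centre shift between two scenarios."""

    species_id: str
    season: str
    bearing: float        # degrees clockwise from north, [0, 360)
    shift_km: float
    centre_now: tuple[float, float]
    centre_future: tuple[float, float]


@dataclass(frozen=True)
class CircularAnovaResult:
    """Watson-Williams test for equal mean directions among groups."""

    F_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_mean_directions: tuple[float, ...]
    kappa: float
    low_concentration: bool


@dataclass(frozen=True)
class SlopeTestResult:
    """OLS slope with a t-test of H0: slope = 1."""

    slope: float
    se: float
    t_statistic: float
    p_value: float
    intercept: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairedTResult:
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float
    degenerate: bool = False


def threshold_grid(grid: SuitabilityGrid,
                   reference_presence: np.ndarray | None = None,
                   threshold: float = 0.5) -> BinaryRange:
    """Convert a suitability surface to a binary presence range.

    When a reference presence lattice is supplied, the threshold is chosen
    by maxSSS — maximising sensitivity + specificity against the reference
    over all observed suitability values (lowest threshold on ties).
    Otherwise the fixed ``threshold`` (default 0.5) is applied.  An empty
    result is allowed but warned about.
    """
    suit = grid.suitability
    valid = grid.mask
    if reference_presence is not None:
        ref = np.asarray(reference_presence, dtype=bool)
        if ref.shape != suit.shape:
            raise InvalidInputError("reference presence shape mismatch")
        pos = ref & valid
        neg = ~ref & valid
        if not pos.any():
            raise InvalidInputError("reference presence has no positive cells")
        s_pos = suit[pos]
        s_neg = suit[neg]
        candidates = np.unique(suit[valid])
        # sensitivity: fraction of positives at/above t; specificity: negatives below
        sens = (s_pos[None, :] >= candidates[:, None]).mean(axis=1)
        if s_neg.size:
            spec = (s_neg[None, :] < candidates[:, None]).mean(axis=1)
        else:
            spec = np.ones_like(sens)
        thr = float(candidates[np.argmax(sens + spec)])
    else:
        thr = float(threshold)
    presence = (suit >= thr) & valid
    if not presence.any():
        warnings.warn(
            f"threshold {thr:.3g} yields an empty range for "
            f"{grid.species_id or 'grid'} {grid.season} {grid.scenario}",
            UserWarning, stacklevel=2,
        )
    return BinaryRange(lon=grid.lon, lat=grid.lat, presence=presence,
                       threshold_used=thr)


def range_centre(grid: SuitabilityGrid, range_: BinaryRange,
                 n_samples: int = 1000,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Suitability-weighted range centre (lon, lat).

    Draws ``n_samples`` presence cells weighted by suitability, averages
    their unit vectors on the sphere and renormalises — robust near the
    antimeridian, and equivalent to an arithmetic mean at continental
    scales.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lons, lats, p = _presence_weights(grid, range_)
    if lons.size == 1:
        return float(lons[0]), float(lats[0])
    idx = rng.choice(lons.size, size=n_samples, replace=True, p=p)
    lam = np.radians(lons[idx])
    phi = np.radians(lats[idx])
    x = np.cos(phi) * np.cos(lam)
    y = np.cos(phi) * np.sin(lam)
    z = np.sin(phi)
    vx, vy, vz = x.mean(), y.mean(), z.mean()
    norm = np.sqrt(vx ** 2 + vy ** 2 + vz ** 2)
    if norm < 1e-12:
        raise EmptyRangeError("degenerate range: mean vector has zero length")
    lat_c = np.degrees(np.arcsin(vz / norm))
    lon_c = np.degrees(np.arctan2(vy, vx))
    return float(lon_c), float(lat_c)


def shift_vector(centre_now: tuple[float, float],
                 centre_future: tuple[float, float],
                 species_id: str = "", season: str = "") -> ShiftVector:
    """Great-circle bearing and distance from a current to a future centre."""
    d = geo.great_circle_distance(centre_now[0], centre_now[1],
                                  centre_future[0], centre_future[1])
    bearing = geo.initial_bearing(centre_now[0], centre_now[1],
                                  centre_future[0], centre_future[1])
    return ShiftVector(species_id=species_id, season=season,
                       bearing=float(bearing), shift_km=float(d),
                       centre_now=tuple(centre_now),
                       centre_future=tuple(centre_future))


def _mean_resultant(angles_rad: np.ndarray) -> tuple[float, float]:
    """(mean direction rad, resultant length R = n * r) of a sample of angles."""
    c = np.cos(angles_rad).sum()
    s = np.sin(angles_rad).sum()
    return float(np.arctan2(s, c)), float(np.hypot(c, s))


def _kappa_from_rbar(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from mean resultant length."""
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)


def circular_anova(bearing_groups: list[np.ndarray]) -> CircularAnovaResult:
    """Watson-Williams high-concentration F test for equal mean directions.

    ``bearing_groups`` is a list of >= 2 arrays of bearings in degrees,
    each with >= 2 observations.  Applies the standard correction factor
    ``1 + 3 / (8 kappa)`` with kappa estimated from the pooled mean
    resultant length; warns (and flags the result) when kappa < 2, where
    the high-concentration assumption is doubtful.
    """
    if len(bearing_groups) < 2:
        raise InvalidInputError("need at least two groups of bearings")
    groups = [np.radians(np.asarray(g, dtype=float)) for g in bearing_groups]
    if any(g.size < 2 for g in groups):
        raise InvalidInputError("every group needs at least two observations")
    k = len(groups)
    n_total = sum(g.size for g in groups)

    means = []
    resultants = []
    for g in groups:
        mu, r_len = _mean_resultant(g)
        if r_len < 1e-9:
            raise InvalidInputError(
                "a group has zero resultant length: mean direction undefined"
            )
        means.append(np.degrees(mu) % 360.0)
        resultants.append(r_len)
    sum_ri = float(np.sum(resultants))
    _, r_all = _mean_resultant(np.concatenate(groups))

    rbar_w = sum_ri / n_total
    kappa = _kappa_from_rbar(rbar_w)
    low = kappa < 2.0
    if low:
        warnings.warn(
            f"Watson-Williams assumptions doubtful: estimated kappa = {kappa:.2f} < 2",
            UserWarning, stacklevel=2,
        )
    correction = 1.0 + 3.0 / (8.0 * kappa)
    df_b, df_w = k - 1, n_total - k
    denom = n_total - sum_ri
    if denom <= 0:  # all observations identical within groups
        f_stat = np.inf if sum_ri - r_all > 1e-12 else 0.0
    else:
        f_stat = correction * (df_w * (sum_ri - r_all)) / (df_b * denom)
    f_stat = max(float(f_stat), 0.0)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return CircularAnovaResult(
        F_statistic=f_stat, df_between=df_b, df_within=df_w, p_value=p,
        group_mean_directions=tuple(means), kappa=float(kappa),
        low_concentration=low,
    )


def paired_t(values_now, values_future) -> PairedTResult:
    """Paired t-test on per-species means (future minus current)."""
    x = np.asarray(values_now, dtype=float)
    y = np.asarray(values_future, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidInputError("need two equal-length vectors with n >= 2")
    d = y - x
    sd = d.std(ddof=1)
    df = d.size - 1
    if sd == 0.0:
        if np.all(d == 0.0):
            return PairedTResult(0.0, df, 1.0, 0.0, degenerate=False)
        return PairedTResult(float(np.sign(d.mean()) * np.inf), df, 0.0,
                             float(d.mean()), degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedTResult(t, df, p, float(d.mean()))


def slope_vs_unity(x, y) -> SlopeTestResult:
    """OLS regression of future on current means, testing H0: slope = 1.

    A slope significantly different from 1 indicates disproportionate
    change of the response relative to the baseline.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidInputError("need two equal-length vectors with n >= 3")
    if np.var(x) == 0.0:
        return SlopeTestResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                               degenerate=True)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    intercept = float(fit.params[0])
    y_scale = float(np.dot(y, y)) or 1.0
    if se == 0.0 or fit.ssr <= 1e-20 * y_scale:  # numerically exact fit
        on_unity = abs(slope - 1.0) <= 1e-8 * max(1.0, abs(slope))
        t = 0.0 if on_unity else float(np.sign(slope - 1.0) * np.inf)
        p = 1.0 if on_unity else 0.0
        return SlopeTestResult(slope, se, t, p, intercept,
                               degenerate=not np.isfinite(t))
    t = (slope - 1.0) / se
    p = float(2.0 * stats.t.sf(abs(t), fit.df_resid))
    return SlopeTestResult(slope, se, float(t), p, intercept)
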