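"""Analytic race model for ribosome collisions.

A collision forms when a trailing ribosome catches up to a slower leading
ribosome on the same mRNA.  In the collided state the two P sites sit a
fixed number of codons apart (the *footprint*, ~10 codons for the mammalian
disome), so the lead must advance at least ``footprint + 1`` codons (the
*escape distance*) during the time the trailing ribosome needs to close the
inter-ribosomal distance (IRD).  Treating the trailing velocity as a random
draw from the cellular elongation-rate distribution turns this race into a
collision probability:

    P(collision) = P(V_trail > v_lead * IRD / escape)

where ``V_trail`` follows a zero-truncated normal with mean 5.6 codons/s and
SD 2.5 codons/s (transcriptome-wide averages).  With the genome-average IRD
of 66 codons the deterministic threshold works out to ~1 codon/s, i.e. a
lead ribosome must slow to less than one-fifth of the average rate over a
10-codon window before collisions become appreciable; on densely initiated
mRNAs (IRD 20-40 codons) a mere ~2-fold slowdown suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "VelocityModel",
    "CollisionGeometry",
    "CollisionQuery",
    "HeatmapGrid",
    "deterministic_threshold_velocity",
    "fold_slowdown_threshold",
    "closure_time",
    "lead_escapes",
    "min_escape_advance",
    "collision_probability",
    "collision_heatmap",
    "velocity_for_fold",
    "fold_for_velocity",
]

_VELOCITY_FAMILIES = ("truncated_normal",)


@dataclass(frozen=True)
class CollisionGeometry:
    """Geometry of the collided di-ribosome interface, in codons.

    ``footprint_codons`` is the P-site separation enforced by the collided
    40S-40S interface; ``escape_codons`` (always ``footprint + 1``) is the
    minimal lead advance that keeps the pair out of contact while the
    trailing ribosome closes the gap.
    """

    footprint_codons: int = 10

    def __post_init__(self) -> None:
        if not isinstance(self.footprint_codons, (int, np.integer)):
            raise ParameterError("footprint_codons must be an integer")
        if self.footprint_codons < 1:
            raise ParameterError("footprint_codons must be >= 1")

    @property
    def escape_codons(self) -> int:
        return self.footprint_codons + 1


@dataclass(frozen=True)
class VelocityModel:
    """Elongation-rate distribution of the trailing ribosome.

    The only supported family is a normal truncated at zero (renormalized),
    the simplest strictly positive reading of a mean +/- SD summary.
    With ``sd_velocity == 0`` the model degenerates to a point mass at
    ``mean_velocity``.
    """

    mean_velocity: float = 5.6
    sd_velocity: float = 2.5
    family: str = "truncated_normal"

    def __post_init__(self) -> None:
        if self.mean_velocity <= 0:
            raise ParameterError("mean_velocity must be > 0")
        if self.sd_velocity < 0:
            raise ParameterError("sd_velocity must be >= 0")
        if self.family not in _VELOCITY_FAMILIES:
            raise ParameterError(f"unknown velocity family {self.family!r}")

    def _frozen(self):
        a = -self.mean_velocity / self.sd_velocity
        return stats.truncnorm(a, np.inf, loc=self.mean_velocity, scale=self.sd_velocity)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` strictly positive velocities."""
        if n < 1:
            raise ParameterError("n must be >= 1")
        if self.sd_velocity == 0:
            return np.full(n, self.mean_velocity)
        return np.asarray(self._frozen().rvs(size=n, random_state=rng))

    def tail_probability(self, v):
        """P(V > v) under the truncated distribution (elementwise)."""
        if self.sd_velocity == 0:
            return np.where(np.asarray(v) < self.mean_velocity, 1.0, 0.0)[()]
        return self._frozen().sf(v)


@dataclass(frozen=True)
class CollisionQuery:
    """One point of the race model: an inter-ribosomal distance (codons
    between P sites) and the velocity of the slowed leading ribosome."""

    ird_codons: float
    lead_velocity: float

    def __post_init__(self) -> None:
        if self.ird_codons <= 0:
            raise ParameterError("ird_codons must be > 0")
        if self.lead_velocity < 0:
            raise ParameterError("lead_velocity must be >= 0")


def _check_ird(ird: float, geometry: CollisionGeometry) -> None:
    if ird < geometry.footprint_codons:
        raise ParameterError(
            f"ird ({ird}) must be >= collided footprint ({geometry.footprint_codons})"
        )


def deterministic_threshold_velocity(
    ird: float, geometry: CollisionGeometry, mean_velocity: float
) -> float:
    """Minimal lead velocity (codons/s) that escapes a collision when the
    trailing ribosome closes the IRD at exactly ``mean_velocity``.

    The trailing ribosome needs ``ird / mean_velocity`` seconds to cover
    the IRD, during which the lead must advance ``escape_codons`` codons:
    v* = escape * mean_velocity / ird.  Leads slower than v* collide;
    leads at or above v* escape.
    """
    if mean_velocity <= 0:
        raise ParameterError("mean_velocity must be > 0")
    _check_ird(ird, geometry)
    return geometry.escape_codons * mean_velocity / ird


def fold_slowdown_threshold(ird: float, geometry: CollisionGeometry) -> float:
    """Fold-slowdown of the lead (relative to the trailing mean velocity) at
    the deterministic collision threshold: ``ird / escape_codons``.

    Independent of the velocity scale; at the genome-average IRD of 66
    codons this is 6.0, while short-IRD transcripts tolerate only ~2-fold.
    """
    _check_ird(ird, geometry)
    return ird / geometry.escape_codons


def closure_time(ird: float, velocity: float) -> float:
    """Seconds for a ribosome at ``velocity`` to elongate ``ird`` codons."""
    if velocity <= 0:
        raise ParameterError("velocity must be > 0")
    if ird < 0:
        raise ParameterError("ird must be >= 0")
    return ird / velocity


def lead_escapes(advance_codons: float, geometry: CollisionGeometry) -> bool:
    """Whether a lead advance during trailing closure avoids the collision.

    Escape requires advancing at least the escape distance; an advance of
    exactly ``escape_codons`` counts as escape.
    """
    if advance_codons < 0:
        raise ParameterError("advance_codons must be >= 0")
    return advance_codons >= geometry.escape_codons


def min_escape_advance(geometry: CollisionGeometry, max_advance: int = 10_000) -> int:
    """Smallest integer codon advance of the lead classified as escape."""
    for k in range(max_advance + 1):
        if lead_escapes(k, geometry):
            return k
    raise ParameterError("no escape advance found below max_advance")


def collision_probability(
    query: CollisionQuery,
    vmodel: VelocityModel,
    geometry: CollisionGeometry,
    method: str = "analytic",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> float:
    """Probability that the trailing ribosome collides with the lead.

    The trailing velocity is a single draw V held constant during closure;
    the lead advances ``lead_velocity * ird / V`` codons in that time and
    escapes iff the advance reaches ``escape_codons``.  Equivalently the
    collision event is {V > lead_velocity * ird / escape_codons}.

    ``method="analytic"`` evaluates the truncated-normal upper tail;
    ``method="monte_carlo"`` draws ``n_samples`` velocities (``seed``
    mandatory, for reproducibility) and evaluates the same predicate.
    """
    _check_ird(query.ird_codons, geometry)
    threshold = query.lead_velocity * query.ird_codons / geometry.escape_codons
    if method == "analytic":
        return float(vmodel.tail_probability(threshold))
    if method == "monte_carlo":
        if seed is None:
            raise ParameterError("monte_carlo requires an explicit seed")
        if n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        v = vmodel.sample(n_samples, rng)
        advance = query.lead_velocity * query.ird_codons / v
        return float(np.mean(advance < geometry.escape_codons))
    raise ParameterError(f"unknown method {method!r}")


@dataclass(frozen=True)
class HeatmapGrid:
    """Collision probability over an (IRD x lead-velocity) grid.

    Rows follow ``ird_axis``, columns ``lead_velocity_axis``; every cell is
    a probability, non-increasing along both axes.
    """

    ird_axis: np.ndarray
    lead_velocity_axis: np.ndarray
    probabilities: np.ndarray
    _validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ird_axis", np.asarray(self.ird_axis, dtype=float))
        object.__setattr__(
            self, "lead_velocity_axis", np.asarray(self.lead_velocity_axis, dtype=float)
        )
        object.__setattr__(self, "probabilities", np.asarray(self.probabilities, dtype=float))
        p = self.probabilities
        if p.shape != (self.ird_axis.size, self.lead_velocity_axis.size):
            raise ParameterError("probabilities shape does not match the axes")
        if self._validate:
            if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
                raise ParameterError("probabilities must lie in [0, 1]")
            if p.shape[1] > 1 and np.any(np.diff(p, axis=1) > 1e-9):
                raise ParameterError("rows must be non-increasing in lead velocity")
            if p.shape[0] > 1 and np.any(np.diff(p, axis=0) > 1e-9):
                raise ParameterError("columns must be non-increasing in ird")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.probabilities, index=self.ird_axis, columns=self.lead_velocity_axis
        )


def _check_axis(axis, name: str) -> np.ndarray:
    arr = np.asarray(axis, dtype=float)
    if arr.size == 0:
        raise ParameterError(f"{name} must be nonempty")
    if arr.size > 1 and np.any(np.diff(arr) <= 0):
        raise ParameterError(f"{name} must be strictly increasing")
    return arr


def collision_heatmap(
    ird_axis,
    lead_velocity_axis,
    vmodel: VelocityModel,
    geometry: CollisionGeometry,
) -> HeatmapGrid:
    """Analytic collision probability over the grid of IRD (rows) and lead
    velocity (columns)."""
    irds = _check_axis(ird_axis, "ird_axis")
    lvs = _check_axis(lead_velocity_axis, "lead_velocity_axis")
    if np.any(lvs < 0):
        raise ParameterError("lead velocities must be >= 0")
    for ird in irds:
        _check_ird(ird, geometry)
    thresholds = np.outer(irds, lvs) / geometry.escape_codons
    probs = np.asarray(vmodel.tail_probability(thresholds), dtype=float)
    return HeatmapGrid(irds, lvs, probs)


def velocity_for_fold(fold: float, vmodel: VelocityModel) -> float:
    """Absolute lead velocity corresponding to an x-fold slowdown of the
    trailing mean velocity."""
    if fold <= 0:
        raise ParameterError("fold must be > 0")
    return vmodel.mean_velocity / fold


def fold_for_velocity(lead_velocity: float, vmodel: VelocityModel) -> float:
    """Fold-slowdown corresponding to an absolute lead velocity."""
    if lead_velocity <= 0:
        raise ParameterError("lead_velocity must be > 0")
    return vmodel.mean_velocity / lead_velocity
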