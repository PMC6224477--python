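"""Collision-triggered quality control: ubiquitination, commitment, removal.

The sensor ligase (ZNF598 in mammals) recognises the composite 40S-40S
surface of a collided di-ribosome and ubiquitinates the *trailing* ribosome
of each collided interface; isolated (monosome) ribosomes are never
substrates.  Downstream consequences are abstracted as a two-step kinetic
scheme layered onto the traffic simulator:

* ``k_ub``     - a currently collided, unmodified trailing ribosome gains
                 the ubiquitin mark.
* ``k_commit`` - a ribosome whose collided trailing partner is marked
                 commits: it stops elongating and its complex is destined
                 for disassembly.
* ``k_res``    - a committed complex (the committed ribosome plus the
                 contiguous collided run behind it) is removed from the
                 transcript ("resolution").

This module also provides the dual-colour stall-reporter readout: the
fraction of ribosomes that traverse a slow region before their queue is
committed, as a function of initiation rate.  Lowering initiation (e.g. by
titrating an initiation inhibitor) spaces ribosomes out, starves the stall
of collisions, and raises read-through - but only when the sensor is
present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "QCParams",
    "ReadthroughResult",
    "expected_modified_fraction",
    "run_readthrough_assay",
]


@dataclass(frozen=True)
class QCParams:
    """Kinetic parameters of the collision-sensing layer (all events/s).

    ``sensor_present=False`` models a sensor-knockout cell: the
    ubiquitination rate is forced to zero, which silences commitment and
    resolution as well (both require an upstream mark).
    """

    sensor_present: bool = True
    k_ub: float = 0.1
    k_commit: float = 0.05
    k_res: float = 0.01

    def __post_init__(self) -> None:
        for name in ("k_ub", "k_commit", "k_res"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not self.sensor_present and self.k_ub != 0:
            object.__setattr__(self, "k_ub", 0.0)


def expected_modified_fraction(queue_size: int) -> float:
    """Saturating per-ribosome modified fraction of a queue of ``queue_size``.

    Every collided interface marks its trailing member and the lead is never
    marked, so a queue of n ribosomes carries n - 1 marks: fraction
    (n - 1)/n.  Monosomes (n = 1) are never modified; larger queues are
    modified more effectively per ribosome, saturating at 1.
    """
    if not isinstance(queue_size, (int, np.integer)) or queue_size < 1:
        raise ParameterError("queue_size must be an integer >= 1")
    return (queue_size - 1) / queue_size


@dataclass(frozen=True)
class ReadthroughResult:
    """Per-initiation-rate outcome of the stall-reporter assay."""

    initiation_rate: float
    n_initiated: int
    n_entered_stall: int
    n_readthrough: int
    n_removed: int
    n_censored: int
    readthrough_fraction: float
    sensor_present: bool
    seed: int

    def __post_init__(self) -> None:
        if self.n_readthrough + self.n_removed + self.n_censored != self.n_entered_stall:
            raise ParameterError("stall-encounter counts are inconsistent")
        f = self.readthrough_fraction
        if not math.isnan(f) and not 0.0 <= f <= 1.0:
            raise ParameterError("readthrough_fraction must lie in [0, 1]")


def run_readthrough_assay(
    reporter,
    alpha_values,
    qc: QCParams,
    n_mrnas: int,
    seed: int,
    geometry=None,
    t_max: float | None = None,
) -> list[ReadthroughResult]:
    """Simulate the stall reporter across a grid of initiation rates.

    For each rate ``alpha``, ``n_mrnas`` independent transcripts are
    simulated.  Every ribosome that enters the slow region is scored:
    *read-through* if it steps past the region's 3' edge, *removed* if its
    complex is resolved first, *censored* if the simulation ends while it is
    still on the transcript.  The reported fraction is
    readthrough / (readthrough + removed), the stochastic analogue of the
    reporter's downstream:upstream fluorescence ratio.

    With ``alpha == 0`` a single ribosome is pre-placed at the start codon
    (no trailing ribosome can ever arrive, so no collision is possible).
    """
    from .collision_model import CollisionGeometry
    from .polysome_sim import (
        DrugModel,
        InitiationSpec,
        SimulationParams,
        simulate,
    )

    if geometry is None:
        geometry = CollisionGeometry()
    if not reporter.rate_overrides:
        raise ParameterError("reporter has no rate_overrides (nothing to stall on)")
    if n_mrnas < 1:
        raise ParameterError("n_mrnas must be >= 1")
    alphas = [float(a) for a in alpha_values]
    if any(a < 0 for a in alphas):
        raise ParameterError("initiation rates must be >= 0")

    region_start, region_end = reporter.slow_regions()[0]
    region_len = region_end - region_start + 1
    if t_max is None:
        slow_min = min(reporter.rate_overrides[p] for p in range(region_start, region_end + 1)
                       if p in reporter.rate_overrides)
        if slow_min <= 0:
            raise ParameterError("slow region rate must be > 0 for a read-through assay")
        t_max = (
            2.0 * region_start / reporter.base_rate
            + 3.0 * region_len / slow_min
            + 2.0 * (reporter.length_codons - region_end) / reporter.base_rate
            + 30.0
        )

    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=(len(alphas), n_mrnas))

    results = []
    for ai, alpha in enumerate(alphas):
        n_initiated = n_entered = n_rt = n_removed = n_censored = 0
        for mi in range(n_mrnas):
            if alpha > 0:
                initiation = InitiationSpec(rate=alpha, enabled=True)
                initial = ()
            else:
                initiation = InitiationSpec(rate=0.0, enabled=False)
                initial = (1,)
            params = SimulationParams(
                geometry=geometry,
                initiation=initiation,
                drug=DrugModel(),
                qc=qc,
                t_max=t_max,
                seed=int(child_seeds[ai, mi]),
                snapshot_interval=None,
                initial_positions=initial,
            )
            _, log = simulate(reporter, params)
            n_initiated += sum(1 for e in log if e.kind == "initiation") + len(initial)
            entered, succeeded, removed = set(), set(), set()
            for e in log:
                if e.kind == "elongation" and e.position == region_start:
                    entered.add(e.ribosome_id)
                elif e.kind == "readthrough":
                    succeeded.add(e.ribosome_id)
                elif e.kind == "resolution":
                    removed.add(e.ribosome_id)
            for rid in entered:
                if rid in succeeded:
                    n_rt += 1
                elif rid in removed:
                    n_removed += 1
                else:
                    n_censored += 1
            n_entered += len(entered)
        decided = n_rt + n_removed
        fraction = n_rt / decided if decided else float("nan")
        results.append(
            ReadthroughResult(
                initiation_rate=alpha,
                n_initiated=n_initiated,
                n_entered_stall=n_entered,
                n_readthrough=n_rt,
                n_removed=n_removed,
                n_censored=n_censored,
                readthrough_fraction=fraction,
                sensor_present=qc.sensor_present,
                seed=seed,
            )
        )
    return results
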