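"""Event-driven stochastic simulation of ribosome traffic on one mRNA.

The transcript is a 1-based codon lattice.  Each ribosome occupies a P-site
codon and advances one codon at a time with exponential waiting times set
by a codon-resolved rate map (an exclusion process); it may never approach
a leading neighbour closer than the collided footprint, and a pair at a gap
of exactly the footprint is *collided*.  Initiation places a ribosome at
codon 1 whenever the first ``footprint`` codons are clear; termination
removes a ribosome from the stop codon at its own rate.  Elongation
inhibitors are modelled either as irreversible stochastic arrest (each
completed step arrests the ribosome with a fixed probability after drug
onset - the low-dose regime that *creates* collisions) or as global arrest
of every ribosome at onset (the high-dose regime that freezes traffic in
place and prevents queue formation).  Quality-control kinetics
(ubiquitination of collided trailing ribosomes, commitment and removal of
marked complexes; see :mod:`ribocollide.quality_control`) run inside the
same event loop.

The simulation is exact (one event at a time, no fixed time step) and fully
reproducible: identical inputs and seed give bit-identical event logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .collision_model import CollisionGeometry
from .errors import ParameterError
from .quality_control import QCParams

__all__ = [
    "EVENT_KINDS",
    "Event",
    "EventLog",
    "TranscriptSpec",
    "InitiationSpec",
    "DrugModel",
    "RibosomeState",
    "PolysomeSnapshot",
    "SimulationParams",
    "simulate",
    "queue_decomposition",
    "steady_state_ird",
]

EVENT_KINDS = (
    "initiation",
    "elongation",
    "collision",
    "arrest",
    "ubiquitination",
    "commitment",
    "resolution",
    "termination",
    "readthrough",
)

_DRUG_MODES = ("none", "stochastic_arrest", "global_arrest")


@dataclass(frozen=True)
class Event:
    time: float
    kind: str
    ribosome_id: int
    position: int


class EventLog:
    """Chronological record of simulation events."""

    __slots__ = ("records",)

    def __init__(self, records=None) -> None:
        self.records: list[Event] = list(records) if records else []

    def append(self, time: float, kind: str, ribosome_id: int, position: int) -> None:
        self.records.append(Event(time, kind, ribosome_id, position))

    def of_kind(self, kind: str) -> list[Event]:
        if kind not in EVENT_KINDS:
            raise ParameterError(f"unknown event kind {kind!r}")
        return [e for e in self.records if e.kind == kind]

    def __iter__(self) -> Iterator[Event]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventLog) and self.records == other.records


@dataclass(frozen=True)
class TranscriptSpec:
    """Codon-resolved kinetic map of one mRNA.

    ``rate_overrides`` maps codon index -> elongation rate and defines slow
    or stall regions (e.g. a poly(A)/poly-lysine stretch); ``termination_rate``
    is the exit rate from the stop codon, with 0 modelling a trapped
    termination complex (dominant-negative release factor).
    """

    length_codons: int
    base_rate: float = 5.6
    rate_overrides: dict[int, float] = field(default_factory=dict)
    termination_rate: float = 5.6
    label: str = ""

    def __post_init__(self) -> None:
        if self.length_codons < 2:
            raise ParameterError("length_codons must be >= 2")
        if self.base_rate < 0 or self.termination_rate < 0:
            raise ParameterError("rates must be >= 0")
        for idx, rate in self.rate_overrides.items():
            if not 1 <= idx <= self.length_codons:
                raise ParameterError(f"rate override index {idx} outside [1, length]")
            if rate < 0:
                raise ParameterError(f"rate override at codon {idx} must be >= 0")

    def rate_at(self, p: int) -> float:
        return self.rate_overrides.get(p, self.base_rate)

    def slow_regions(self) -> list[tuple[int, int]]:
        """Maximal contiguous runs of overridden codons, as (start, end)."""
        idx = sorted(self.rate_overrides)
        regions: list[tuple[int, int]] = []
        for i in idx:
            if regions and i == regions[-1][1] + 1:
                regions[-1] = (regions[-1][0], i)
            else:
                regions.append((i, i))
        return regions


@dataclass(frozen=True)
class InitiationSpec:
    rate: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ParameterError("initiation rate must be >= 0")


@dataclass(frozen=True)
class DrugModel:
    """Elongation-inhibitor regime.

    ``stochastic_arrest``: after ``onset_time`` each completed elongation
    step irreversibly arrests the ribosome with probability
    ``arrest_probability_per_step`` (mean run length 1/q steps).
    ``global_arrest``: every ribosome arrests at ``onset_time``.
    """

    mode: str = "none"
    arrest_probability_per_step: float = 0.0
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in _DRUG_MODES:
            raise ParameterError(f"unknown drug mode {self.mode!r}")
        if not 0.0 <= self.arrest_probability_per_step <= 1.0:
            raise ParameterError("arrest_probability_per_step must lie in [0, 1]")
        if self.onset_time < 0:
            raise ParameterError("onset_time must be >= 0")


@dataclass(frozen=True)
class RibosomeState:
    id: int
    p_site: int
    arrested: bool = False
    collided: bool = False
    ubiquitinated: bool = False
    committed: bool = False
    birth_time: float = 0.0


@dataclass(frozen=True)
class PolysomeSnapshot:
    """Positions and flags of every ribosome at one instant, ordered 3'->5'
    (strictly decreasing P site)."""

    time: float
    ribosomes: tuple[RibosomeState, ...]

    def __post_init__(self) -> None:
        ps = [r.p_site for r in self.ribosomes]
        if any(b >= a for a, b in zip(ps, ps[1:])):
            raise ParameterError("ribosomes must be ordered by strictly decreasing p_site")

    def positions(self) -> list[int]:
        return [r.p_site for r in self.ribosomes]


@dataclass(frozen=True)
class SimulationParams:
    """Everything the simulator needs besides the transcript.

    ``initial_positions`` pre-places ribosomes (P sites, any order) before
    the clock starts; ``allow_collided_resume=False`` makes a ribosome that
    has ever collided elongation-incompetent even after the gap reopens
    (steric-hindrance variant of the collided state).
    """

    t_max: float
    seed: int
    geometry: CollisionGeometry = CollisionGeometry()
    initiation: InitiationSpec = InitiationSpec()
    drug: DrugModel = DrugModel()
    qc: QCParams = QCParams()
    snapshot_interval: float | None = None
    initial_positions: tuple[int, ...] = ()
    allow_collided_resume: bool = True

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ParameterError("t_max must be > 0")
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ParameterError("an integer seed is required")
        if self.snapshot_interval is not None and self.snapshot_interval <= 0:
            raise ParameterError("snapshot_interval must be > 0 when given")


class _Rib:
    __slots__ = ("id", "p", "arrested", "ubiquitinated", "committed", "ever_collided", "birth")

    def __init__(self, rid: int, p: int, birth: float) -> None:
        self.id = rid
        self.p = p
        self.arrested = False
        self.ubiquitinated = False
        self.committed = False
        self.ever_collided = False
        self.birth = birth


def _snapshot(time: float, ribs: list[_Rib], fp: int) -> PolysomeSnapshot:
    states = []
    for i, r in enumerate(ribs):
        collided = i > 0 and ribs[i - 1].p - r.p == fp
        states.append(
            RibosomeState(
                id=r.id,
                p_site=r.p,
                arrested=r.arrested,
                collided=collided,
                ubiquitinated=r.ubiquitinated,
                committed=r.committed,
                birth_time=r.birth,
            )
        )
    return PolysomeSnapshot(time, tuple(states))


def simulate(
    transcript: TranscriptSpec, params: SimulationParams
) -> tuple[list[PolysomeSnapshot], EventLog]:
    """Run one exact stochastic trajectory.

    Returns the list of snapshots (t = 0, every ``snapshot_interval``, and
    t_max) and the full event log.  Bookkeeping invariant:
    initiations + pre-placed = on transcript + terminated + resolved.
    """
    geom = params.geometry
    fp = geom.footprint_codons
    L = transcript.length_codons
    if L < fp + 1:
        raise ParameterError("transcript shorter than footprint + 1")

    rng = np.random.default_rng(params.seed)
    log = EventLog()

    ribs: list[_Rib] = []
    for pos in sorted(set(int(p) for p in params.initial_positions), reverse=True):
        if not 1 <= pos <= L:
            raise ParameterError(f"initial position {pos} outside [1, length]")
        if ribs and ribs[-1].p - pos < fp:
            raise ParameterError("initial positions violate the exclusion footprint")
        ribs.append(_Rib(len(ribs) + 1, pos, 0.0))
    for i in range(1, len(ribs)):
        if ribs[i - 1].p - ribs[i].p == fp:
            log.append(0.0, "collision", ribs[i].id, ribs[i].p)
            ribs[i].ever_collided = True

    n_init = len(ribs)
    n_term = 0
    n_res = 0

    alpha = params.initiation.rate if params.initiation.enabled else 0.0
    drug = params.drug
    stochastic = drug.mode == "stochastic_arrest"
    global_pending = drug.mode == "global_arrest"
    q_arrest = drug.arrest_probability_per_step
    sensor = params.qc.sensor_present
    k_ub, k_commit, k_res = params.qc.k_ub, params.qc.k_commit, params.qc.k_res
    term_rate = transcript.termination_rate
    resume_ok = params.allow_collided_resume
    exit_positions = {end + 1 for _, end in transcript.slow_regions() if end < L}

    snapshots: list[PolysomeSnapshot] = []
    interval = params.snapshot_interval
    next_snap: float | None = 0.0

    def flush_snapshots(tcut: float) -> None:
        nonlocal next_snap
        while next_snap is not None and next_snap <= tcut:
            snapshots.append(_snapshot(next_snap, ribs, fp))
            next_snap = next_snap + interval if interval else None
            if next_snap is not None and next_snap > params.t_max:
                next_snap = None

    def arrest_all(t: float) -> None:
        for r in ribs:
            if not r.arrested:
                r.arrested = True
                log.append(t, "arrest", r.id, r.p)

    t = 0.0
    if global_pending and drug.onset_time <= 0.0:
        flush_snapshots(0.0)
        arrest_all(0.0)
        global_pending = False

    # action codes: 0 initiation, 1 termination, 2 elongation,
    #               3 ubiquitination, 4 commitment, 5 resolution
    while True:
        acts: list[tuple[float, int, int]] = []
        if alpha > 0 and (not ribs or ribs[-1].p > fp):
            acts.append((alpha, 0, -1))
        for i, r in enumerate(ribs):
            lead_gap = ribs[i - 1].p - r.p if i > 0 else None
            movable = (
                not r.arrested
                and not r.committed
                and (lead_gap is None or lead_gap > fp)
                and (resume_ok or not r.ever_collided)
            )
            if movable:
                if r.p == L:
                    if term_rate > 0:
                        acts.append((term_rate, 1, i))
                else:
                    k = transcript.rate_at(r.p)
                    if k > 0:
                        acts.append((k, 2, i))
            if sensor and k_ub > 0 and not r.ubiquitinated and lead_gap == fp:
                acts.append((k_ub, 3, i))
            if (
                k_commit > 0
                and not r.committed
                and i + 1 < len(ribs)
                and r.p - ribs[i + 1].p == fp
                and ribs[i + 1].ubiquitinated
            ):
                acts.append((k_commit, 4, i))
            if k_res > 0 and r.committed:
                acts.append((k_res, 5, i))

        total = sum(a[0] for a in acts)
        t_next = t + rng.exponential(1.0 / total) if total > 0 else math.inf

        if global_pending and t_next >= drug.onset_time:
            if drug.onset_time >= params.t_max:
                global_pending = False
                continue
            tcut = max(drug.onset_time, t)
            flush_snapshots(tcut)
            t = tcut
            arrest_all(t)
            global_pending = False
            continue
        if t_next >= params.t_max:
            break
        flush_snapshots(t_next)
        t = t_next

        u = rng.random() * total
        acc = 0.0
        chosen = acts[-1]
        for a in acts:
            acc += a[0]
            if u < acc:
                chosen = a
                break
        _, code, i = chosen

        if code == 0:
            n_init += 1
            new = _Rib(n_init, 1, t)
            ribs.append(new)
            log.append(t, "initiation", new.id, 1)
            if len(ribs) >= 2 and ribs[-2].p - 1 == fp:
                log.append(t, "collision", new.id, 1)
                new.ever_collided = True
            # under saturating drug, a ribosome initiating after onset
            # arrests before it can take a step
            if drug.mode == "global_arrest" and t >= drug.onset_time:
                new.arrested = True
                log.append(t, "arrest", new.id, 1)
        elif code == 1:
            r = ribs.pop(i)
            n_term += 1
            log.append(t, "termination", r.id, r.p)
        elif code == 2:
            r = ribs[i]
            r.p += 1
            log.append(t, "elongation", r.id, r.p)
            if i > 0 and ribs[i - 1].p - r.p == fp:
                log.append(t, "collision", r.id, r.p)
                r.ever_collided = True
            if r.p in exit_positions:
                log.append(t, "readthrough", r.id, r.p)
            if stochastic and t >= drug.onset_time and q_arrest > 0:
                if rng.random() < q_arrest:
                    r.arrested = True
                    log.append(t, "arrest", r.id, r.p)
        elif code == 3:
            r = ribs[i]
            r.ubiquitinated = True
            log.append(t, "ubiquitination", r.id, r.p)
        elif code == 4:
            r = ribs[i]
            r.committed = True
            log.append(t, "commitment", r.id, r.p)
        else:
            j = i
            while j + 1 < len(ribs) and ribs[j].p - ribs[j + 1].p == fp:
                j += 1
            removed = ribs[i : j + 1]
            del ribs[i : j + 1]
            n_res += len(removed)
            for r in removed:
                log.append(t, "resolution", r.id, r.p)

    flush_snapshots(params.t_max)
    if not snapshots or snapshots[-1].time != params.t_max:
        snapshots.append(_snapshot(params.t_max, ribs, fp))

    assert n_init == len(ribs) + n_term + n_res, "ribosome bookkeeping violated"
    return snapshots, log


def queue_decomposition(snapshot: PolysomeSnapshot, geometry: CollisionGeometry) -> list[int]:
    """Sizes of maximal collided runs, 3' to 5'.

    Neighbours at a gap of exactly the footprint belong to one queue;
    isolated ribosomes are queues of size 1.  Sizes sum to the ribosome
    count.
    """
    fp = geometry.footprint_codons
    sizes: list[int] = []
    current = 0
    prev = None
    for r in snapshot.ribosomes:
        if prev is not None and prev.p_site - r.p_site == fp:
            current += 1
        else:
            if current:
                sizes.append(current)
            current = 1
        prev = r
    if current:
        sizes.append(current)
    return sizes


def steady_state_ird(
    trajectory: list[PolysomeSnapshot],
    window: float,
    geometry: CollisionGeometry | None = None,
    exclude_collided: bool = False,
) -> float:
    """Mean P-site gap (codons) between adjacent ribosomes over the last
    ``window`` seconds of a trajectory.

    Returns NaN when no snapshot in the window holds two or more ribosomes
    (e.g. vanishing initiation).  ``exclude_collided`` drops gaps equal to
    the footprint, isolating freely spaced pairs.
    """
    if not trajectory:
        raise ParameterError("empty trajectory")
    if exclude_collided and geometry is None:
        raise ParameterError("exclude_collided requires a geometry")
    t_end = trajectory[-1].time
    gaps: list[int] = []
    for snap in trajectory:
        if snap.time < t_end - window:
            continue
        ps = snap.positions()
        for a, b in zip(ps, ps[1:]):
            gap = a - b
            if exclude_collided and gap == geometry.footprint_codons:
                continue
            gaps.append(gap)
    return float(np.mean(gaps)) if gaps else float("nan")
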