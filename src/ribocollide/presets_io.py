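"""Experimental-regime presets, configuration files, and tabular output.

The presets emulate the study conditions the package is built around:

* ``genome_average`` - free-flowing traffic calibrated to the
  transcriptome-wide mean inter-ribosomal distance of ~66 codons at a mean
  elongation rate of 5.6 codons/s.
* ``globin``         - a short, very frequently initiated ORF (~140 codons,
  4-6 ribosomes, spacing 20-40 codons).
* ``reporter_polyA`` - a stall reporter with a 21-codon poly-lysine slow
  region mid-ORF.
* ``eRF1AAQ_stall``  - a trapped termination complex (termination rate 0)
  that nucleates a queue at the stop codon.
* ``emetine_low`` / ``emetine_high`` - stochastic irreversible arrest of a
  subset of ribosomes versus instantaneous global arrest.

Initiation rates are calibrated so the realised steady-state spacing hits
the target: a new ribosome blocks the first ``footprint`` codons while it
clears them, so the mean headway is ``footprint/v + 1/alpha`` and the rate
that realises a spacing ``d`` is ``alpha = v / (d - footprint)``.

All tabular output is TSV (header row, tab separator, '.' decimal); every
run writes a JSON metadata record that includes the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collision_model import CollisionGeometry, HeatmapGrid
from .errors import ConfigError, ParameterError
from .polysome_sim import (
    DrugModel,
    EventLog,
    InitiationSpec,
    PolysomeSnapshot,
    RibosomeState,
    SimulationParams,
    TranscriptSpec,
)
from .quality_control import QCParams

__all__ = [
    "PRESET_NAMES",
    "Preset",
    "make_preset",
    "make_reporter",
    "spacing_to_initiation_rate",
    "generate_snapshot",
    "read_config",
    "write_config",
    "preset_to_dict",
    "preset_from_dict",
    "write_outputs",
    "read_snapshots_tsv",
    "write_heatmap_tsv",
    "read_heatmap_tsv",
]

PRESET_NAMES = (
    "genome_average",
    "globin",
    "reporter_polyA",
    "eRF1AAQ_stall",
    "emetine_low",
    "emetine_high",
)

_MEAN_V = 5.6


@dataclass(frozen=True)
class Preset:
    name: str
    transcript: TranscriptSpec
    params: SimulationParams


def spacing_to_initiation_rate(
    spacing_codons: float, mean_velocity: float = _MEAN_V, geometry: CollisionGeometry = CollisionGeometry()
) -> float:
    """Initiation rate realising a target steady-state P-site spacing.

    A freshly initiated ribosome occludes the initiation site until its P
    site clears the footprint, so consecutive initiations are separated by
    ``footprint/v + 1/alpha`` on average and downstream spacing is velocity
    times that headway.  Inverting gives ``alpha = v/(spacing - footprint)``.
    """
    if spacing_codons <= geometry.footprint_codons:
        raise ParameterError("target spacing must exceed the footprint")
    return mean_velocity / (spacing_codons - geometry.footprint_codons)


def make_reporter(
    length_codons: int = 550,
    stall_start: int = 301,
    stall_len: int = 21,
    slow_rate: float = 0.2,
    base_rate: float = _MEAN_V,
    label: str = "stall_reporter",
) -> TranscriptSpec:
    """A stall-reporter transcript: uniform elongation with one contiguous
    slow region (default: 21 codons, emulating a poly-lysine stretch)."""
    overrides = {p: slow_rate for p in range(stall_start, stall_start + stall_len)}
    return TranscriptSpec(
        length_codons=length_codons,
        base_rate=base_rate,
        rate_overrides=overrides,
        termination_rate=2.0,
        label=label,
    )


def make_preset(name: str, seed: int) -> Preset:
    """Build one of the named experimental-regime presets."""
    geometry = CollisionGeometry()
    if name == "genome_average":
        transcript = TranscriptSpec(600, _MEAN_V, {}, 2.0, "genome_average")
        params = SimulationParams(
            t_max=600.0,
            seed=seed,
            geometry=geometry,
            initiation=InitiationSpec(rate=spacing_to_initiation_rate(66.0)),
            snapshot_interval=5.0,
        )
    elif name == "globin":
        transcript = TranscriptSpec(140, _MEAN_V, {}, 2.0, "globin")
        params = SimulationParams(
            t_max=400.0,
            seed=seed,
            geometry=geometry,
            initiation=InitiationSpec(rate=spacing_to_initiation_rate(28.0)),
            snapshot_interval=2.0,
        )
    elif name == "reporter_polyA":
        transcript = make_reporter()
        params = SimulationParams(
            t_max=600.0,
            seed=seed,
            geometry=geometry,
            initiation=InitiationSpec(rate=0.05),
            snapshot_interval=5.0,
        )
    elif name == "eRF1AAQ_stall":
        transcript = TranscriptSpec(300, _MEAN_V, {}, 0.0, "eRF1AAQ_stall")
        params = SimulationParams(
            t_max=400.0,
            seed=seed,
            geometry=geometry,
            initiation=InitiationSpec(rate=spacing_to_initiation_rate(66.0)),
            snapshot_interval=5.0,
        )
    elif name in ("emetine_low", "emetine_high"):
        transcript = TranscriptSpec(600, _MEAN_V, {}, 2.0, name)
        drug = (
            DrugModel("stochastic_arrest", arrest_probability_per_step=0.002, onset_time=120.0)
            if name == "emetine_low"
            else DrugModel("global_arrest", onset_time=120.0)
        )
        params = SimulationParams(
            t_max=400.0,
            seed=seed,
            geometry=geometry,
            initiation=InitiationSpec(rate=spacing_to_initiation_rate(66.0)),
            drug=drug,
            qc=QCParams(sensor_present=False),
            snapshot_interval=5.0,
        )
    else:
        raise ParameterError(f"unknown preset {name!r}")
    return Preset(name=name, transcript=transcript, params=params)


def generate_snapshot(
    n_ribosomes: int,
    spacing_model: str = "fixed_gap",
    gap_param: float = 10,
    seed: int = 0,
    geometry: CollisionGeometry = CollisionGeometry(),
    start: int = 100,
    time: float = 0.0,
) -> PolysomeSnapshot:
    """Construct a valid polysome snapshot without running the simulator.

    ``fixed_gap`` places ribosomes at a constant P-site gap (>= footprint;
    a gap equal to the footprint builds a fully collided queue).
    ``poisson_gaps`` draws gaps as footprint + Poisson(gap_param -
    footprint), reproducibly from ``seed``.  The trailing-most ribosome
    sits at codon ``start``.
    """
    if n_ribosomes < 0:
        raise ParameterError("n_ribosomes must be >= 0")
    fp = geometry.footprint_codons
    if n_ribosomes == 0:
        return PolysomeSnapshot(time, ())
    if spacing_model == "fixed_gap":
        gap = int(gap_param)
        if gap < fp:
            raise ParameterError("fixed gap below the exclusion footprint")
        gaps = [gap] * (n_ribosomes - 1)
    elif spacing_model == "poisson_gaps":
        if gap_param < fp:
            raise ParameterError("mean gap below the exclusion footprint")
        rng = np.random.default_rng(seed)
        gaps = (fp + rng.poisson(gap_param - fp, size=n_ribosomes - 1)).tolist()
    else:
        raise ParameterError(f"unknown spacing model {spacing_model!r}")
    positions = [start]
    for g in gaps:
        positions.append(positions[-1] + int(g))
    positions = positions[::-1]  # decreasing
    states = []
    for i, p in enumerate(positions):
        collided = i > 0 and positions[i - 1] - p == fp
        states.append(RibosomeState(id=i + 1, p_site=p, collided=collided))
    return PolysomeSnapshot(time, tuple(states))


# --------------------------------------------------------------------------
# configuration serialization


def preset_to_dict(preset: Preset) -> dict:
    d = {
        "name": preset.name,
        "transcript": asdict(preset.transcript),
        "params": asdict(preset.params),
    }
    d["transcript"]["rate_overrides"] = {
        str(k): v for k, v in preset.transcript.rate_overrides.items()
    }
    d["params"]["initial_positions"] = list(preset.params.initial_positions)
    return d


def _require(d: dict, key: str, context: str):
    if key not in d:
        raise ConfigError(f"missing required key '{key}' in {context}")
    return d[key]


def _build(cls, d: dict, context: str, converters=None):
    converters = converters or {}
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(d) - fields
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in {context}")
    kwargs = {k: converters.get(k, lambda x: x)(v) for k, v in d.items()}
    try:
        return cls(**kwargs)
    except ParameterError as exc:
        raise ConfigError(f"invalid value in {context}: {exc}") from exc


def transcript_from_dict(d: dict) -> TranscriptSpec:
    d = dict(d)
    _require(d, "length_codons", "transcript")
    if "rate_overrides" in d:
        try:
            d["rate_overrides"] = {int(k): float(v) for k, v in d["rate_overrides"].items()}
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid key 'rate_overrides' in transcript: {exc}") from exc
    return _build(TranscriptSpec, d, "transcript")


def params_from_dict(d: dict) -> SimulationParams:
    d = dict(d)
    _require(d, "t_max", "params")
    _require(d, "seed", "params")
    converters = {
        "geometry": lambda g: _build(CollisionGeometry, g, "params.geometry"),
        "initiation": lambda g: _build(InitiationSpec, g, "params.initiation"),
        "drug": lambda g: _build(DrugModel, g, "params.drug"),
        "qc": lambda g: _build(QCParams, g, "params.qc"),
        "initial_positions": lambda v: tuple(int(p) for p in v),
        "seed": int,
    }
    return _build(SimulationParams, d, "params", converters)


def preset_from_dict(d: dict) -> Preset:
    if "preset" in d:
        preset = make_preset(d["preset"], seed=int(_require(d, "seed", "config")))
        allowed = {"preset", "seed", "t_max"}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in config")
        if "t_max" in d:
            from dataclasses import replace

            preset = Preset(
                preset.name, preset.transcript, replace(preset.params, t_max=float(d["t_max"]))
            )
        return preset
    transcript = transcript_from_dict(_require(d, "transcript", "config"))
    params = params_from_dict(_require(d, "params", "config"))
    return Preset(name=str(d.get("name", "custom")), transcript=transcript, params=params)


def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_config(path) -> Preset:
    """Read a YAML/JSON run configuration into a :class:`Preset`.

    Accepts either ``{"preset": <name>, "seed": <int>}`` or a full
    ``{"transcript": ..., "params": ...}`` specification; a missing seed is
    always rejected.
    """
    path = Path(path)
    data = _load_structured(path)
    if not isinstance(data, dict):
        raise ConfigError(f"config root in {path} must be a mapping")
    return preset_from_dict(data)


def write_config(preset: Preset, path) -> None:
    path = Path(path)
    data = preset_to_dict(preset)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# --------------------------------------------------------------------------
# run outputs


def snapshots_to_frame(trajectory: list[PolysomeSnapshot]) -> pd.DataFrame:
    rows = []
    for snap in trajectory:
        for r in snap.ribosomes:
            rows.append(
                {
                    "time": snap.time,
                    "ribosome_id": r.id,
                    "p_site": r.p_site,
                    "arrested": int(r.arrested),
                    "collided": int(r.collided),
                    "ubiquitinated": int(r.ubiquitinated),
                    "committed": int(r.committed),
                    "birth_time": r.birth_time,
                }
            )
    columns = [
        "time",
        "ribosome_id",
        "p_site",
        "arrested",
        "collided",
        "ubiquitinated",
        "committed",
        "birth_time",
    ]
    return pd.DataFrame(rows, columns=columns)


def events_to_frame(log: EventLog) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"time": e.time, "kind": e.kind, "ribosome_id": e.ribosome_id, "position": e.position}
            for e in log
        ],
        columns=["time", "kind", "ribosome_id", "position"],
    )


def write_outputs(out_dir, preset: Preset, trajectory, log: EventLog, extra_metadata=None) -> dict:
    """Write snapshots.tsv, events.tsv and run_metadata.json for one run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snapshots_to_frame(trajectory).to_csv(out / "snapshots.tsv", sep="\t", index=False)
    events_to_frame(log).to_csv(out / "events.tsv", sep="\t", index=False)
    metadata = {
        "version": __version__,
        "seed": int(preset.params.seed),
        "preset": preset_to_dict(preset),
    }
    if extra_metadata:
        metadata.update(extra_metadata)
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    return metadata


def read_snapshots_tsv(path) -> list[PolysomeSnapshot]:
    """Read a snapshots.tsv back into snapshot objects (grouped by time)."""
    df = pd.read_csv(path, sep="\t")
    trajectory = []
    for time, group in df.groupby("time", sort=True):
        group = group.sort_values("p_site", ascending=False)
        states = tuple(
            RibosomeState(
                id=int(row.ribosome_id),
                p_site=int(row.p_site),
                arrested=bool(row.arrested),
                collided=bool(row.collided),
                ubiquitinated=bool(row.ubiquitinated),
                committed=bool(row.committed),
                birth_time=float(row.birth_time),
            )
            for row in group.itertuples()
        )
        trajectory.append(PolysomeSnapshot(float(time), states))
    return trajectory


def write_heatmap_tsv(grid: HeatmapGrid, path) -> None:
    """TSV matrix: header row = lead-velocity axis, first column = IRD."""
    df = grid.to_dataframe()
    df.index.name = "ird_codons"
    df.to_csv(path, sep="\t")


def read_heatmap_tsv(path) -> HeatmapGrid:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return HeatmapGrid(
        ird_axis=df.index.to_numpy(dtype=float),
        lead_velocity_axis=np.asarray([float(c) for c in df.columns]),
        probabilities=df.to_numpy(dtype=float),
    )
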