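"""Configuration files, record serialization, and seed management.

Configs are human-readable YAML mappings mirroring the package's
dataclasses; unspecified fields fall back to the model defaults (all
printed constants), unknown keys are load errors, and cross-field
constraints (substeps x substep_dt = control_dt, max_steps x
control_dt = time_limit) are validated with precise messages.  Joint
angles in config files are given in degrees and converted to radians
on load.

Episode records are written as one flat steps CSV (one row per control
step, with an episode index column) plus a JSON sidecar file carrying
the per-episode scalars (target, success, movement time, seed,
termination); the round trip is lossless at full float precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .actuation import MuscleParams, NoiseParams
from .arm import DEG, ArmConfig, JointSpec, default_arm_config
from .curriculum import CurriculumState
from .environment import EpisodeConfig, EpisodeRecord, Target, Workspace
from .tasks import EllipseSpec
from .training import SACConfig

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "write_records",
    "read_records",
    "seed_streams",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunConfig:
    arm: ArmConfig
    muscle: MuscleParams
    noise: NoiseParams
    episode: EpisodeConfig
    workspace: Workspace
    curriculum: CurriculumState
    sac: SACConfig
    ellipse: EllipseSpec
    seed: int = 0
    out_dir: str = "runs"


def _build(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'"
        )
    try:
        return cls(**{k: _coerce(v) for k, v in data.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section '{section}': {exc}") from exc


def _coerce(v):
    return tuple(v) if isinstance(v, list) else v


def _build_arm(data: dict) -> ArmConfig:
    data = dict(data)
    joints_spec = data.pop("joints", None)
    kwargs = {}
    for key in ("segment_lengths", "segment_masses", "segment_inertias",
                "gravity", "shoulder_origin"):
        if key in data:
            kwargs[key] = tuple(data.pop(key))
    if data:
        raise ConfigError(f"unknown key(s) {sorted(data)} in section 'arm'")
    if joints_spec is None:
        return default_arm_config(**kwargs)
    joints = []
    for row in joints_spec:
        try:
            joints.append(
                JointSpec(
                    name=row["name"],
                    angle_min=row["angle_min_deg"] * DEG,
                    angle_max=row["angle_max_deg"] * DEG,
                    torque_scale=row["torque_scale"],
                )
            )
        except KeyError as exc:
            raise ConfigError(f"joint entry missing key {exc}") from exc
    return ArmConfig(joints=tuple(joints), **kwargs)


_SECTIONS = {
    "muscle": MuscleParams,
    "noise": NoiseParams,
    "episode": EpisodeConfig,
    "workspace": Workspace,
    "curriculum": CurriculumState,
    "sac": SACConfig,
    "ellipse": EllipseSpec,
}


def load_config(path: str | Path | None = None, data: dict | None = None
                ) -> RunConfig:
    """Load and validate a run configuration.

    Either a YAML file path or an already-parsed mapping can be given;
    an empty file yields all defaults.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            path = Path(path)
            if not path.exists():
                raise ConfigError(f"config file not found: {path}")
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    data = dict(data)
    known = set(_SECTIONS) | {"arm", "seed", "out_dir"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    sections = {
        name: _build(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(
        arm=_build_arm(data.get("arm", {}) or {}),
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", "runs")),
        **sections,
    )


def _dump_arm(arm: ArmConfig) -> dict:
    return {
        "joints": [
            {
                "name": j.name,
                "angle_min_deg": j.angle_min / DEG,
                "angle_max_deg": j.angle_max / DEG,
                "torque_scale": j.torque_scale,
            }
            for j in arm.joints
        ],
        "segment_lengths": list(arm.segment_lengths),
        "segment_masses": list(arm.segment_masses),
        "segment_inertias": list(arm.segment_inertias),
        "gravity": list(arm.gravity),
        "shoulder_origin": list(arm.shoulder_origin),
    }


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective configuration back to YAML."""
    out = {"arm": _dump_arm(cfg.arm), "seed": cfg.seed, "out_dir": cfg.out_dir}
    for name in _SECTIONS:
        section = getattr(cfg, name)
        out[name] = {
            f.name: (
                list(v) if isinstance(v := getattr(section, f.name), tuple)
                else v
            )
            for f in dataclasses.fields(section)
        }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def write_records(directory: str | Path, records: list[EpisodeRecord]) -> None:
    """Serialize records to <dir>/steps.csv + <dir>/episodes.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = []
    sidecars = []
    for i, rec in enumerate(records):
        df = rec.to_dataframe()
        df.insert(0, "episode", i)
        frames.append(df)
        sidecars.append(rec.sidecar())
    # %.17g round-trips float64 exactly through text
    pd.concat(frames, ignore_index=True).to_csv(
        directory / "steps.csv", index=False, float_format="%.17g"
    )
    with open(directory / "episodes.json", "w") as fh:
        json.dump({"format": "reachlaw-records-v1", "episodes": sidecars},
                  fh, indent=1)


def read_records(directory: str | Path) -> list[EpisodeRecord]:
    """Load records written by :func:`write_records`."""
    directory = Path(directory)
    with open(directory / "episodes.json") as fh:
        payload = json.load(fh)
    if payload.get("format") != "reachlaw-records-v1":
        raise ValueError(
            f"unrecognized record format {payload.get('format')!r}"
        )
    steps = pd.read_csv(directory / "steps.csv", float_precision="round_trip")
    records = []
    for i, side in enumerate(payload["episodes"]):
        df = steps[steps["episode"] == i]
        vec7 = lambda stem: df[[f"{stem}{k}" for k in range(1, 8)]].to_numpy()
        vec3 = lambda stem: df[[f"{stem}{ax}" for ax in "xyz"]].to_numpy()
        side = dict(side)
        target = Target(
            np.array(side.pop("target_center")), side.pop("target_radius")
        )
        records.append(
            EpisodeRecord(
                time=df["time_s"].to_numpy(),
                q=vec7("q"),
                qdot=vec7("qd"),
                sigma=vec7("sig"),
                sigma_dot=vec7("sigd"),
                ee_pos=vec3("ee_"),
                ee_vel=vec3("ee_v"),
                ee_acc=vec3("ee_a"),
                action=vec7("act"),
                control=vec7("ctrl"),
                reward=df["reward"].to_numpy(),
                dist=df["dist_to_target"].to_numpy(),
                in_target=df["in_target"].to_numpy().astype(bool),
                target=target,
                success=side.pop("success"),
                movement_time=side.pop("movement_time_s"),
                total_time=side.pop("total_time_s"),
                termination=side.pop("termination"),
                meta=side,
            )
        )
    return records


def seed_streams(master_seed: int, names: list[str]) -> dict:
    """Derive one independent, reproducible Generator per named stream."""
    seq = np.random.SeedSequence(master_seed)
    children = seq.spawn(len(names))
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, children)
    }
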