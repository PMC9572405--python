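"""File formats: extended-XYZ trajectories, YAML configuration, run manifests.

Everything on disk is in reduced units.  The extended-XYZ dialect is: first
line the bead count, comment line ``key=value`` pairs (``time``, ``piston_x``,
``config_hash``), then one ``El x y z [vx vy vz]`` line per bead.  Floats are
written with 17 significant digits so a write/read round trip is bitwise
lossless.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .config import ConfigError, HelixChannel, Protocol, SimulationConfig
from .dynamics import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "load_config",
    "save_config",
    "RunManifest",
    "TrajectoryParseError",
]


class TrajectoryParseError(ValueError):
    pass


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write the sampled frames as extended XYZ (lossless float round trip)."""
    path = Path(path)
    h = traj.metadata.get("config_hash", traj.config.config_hash())
    with open(path, "w") as f:
        for fi in range(traj.n_frames):
            pos = traj.positions[fi]
            vel = traj.velocities[fi] if len(traj.velocities) else None
            f.write(f"{len(pos)}\n")
            f.write(
                f"time={traj.times[fi]:.17g} piston_x={traj.piston_x[fi]:.17g} "
                f"config_hash={h} seed={traj.seed}\n"
            )
            for bi in range(len(pos)):
                line = "C %.17g %.17g %.17g" % tuple(pos[bi])
                if vel is not None:
                    line += " %.17g %.17g %.17g" % tuple(vel[bi])
                f.write(line + "\n")
    return path


def read_trajectory(path: str | Path) -> dict:
    """Read an extended-XYZ trajectory written by this package (or foreign).

    Returns a dict with ``positions`` (n_frames, N, 3), ``velocities`` (same
    shape, or None if the file carries none), ``times``, ``piston_x`` and
    ``comments``.  Malformed frames raise TrajectoryParseError naming the
    offending line.
    """
    path = Path(path)
    frames, vels, times, pistons, comments = [], [], [], [], []
    has_velocities = True
    with open(path) as f:
        lines = f.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as e:
            raise TrajectoryParseError(f"line {i + 1}: expected bead count") from e
        if i + 2 + n > len(lines):
            raise TrajectoryParseError(
                f"line {i + 1}: truncated frame (frame {len(frames) + 1}, "
                f"expected {n} beads)"
            )
        comment = lines[i + 1].strip()
        kv = {}
        for tok in comment.split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                kv[k] = v
        comments.append(kv)
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        frame_has_vel = True
        for b in range(n):
            parts = lines[i + 2 + b].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"line {i + 3 + b}: malformed bead line in frame {len(frames) + 1}"
                )
            pos[b] = [float(parts[1]), float(parts[2]), float(parts[3])]
            if len(parts) >= 7:
                vel[b] = [float(parts[4]), float(parts[5]), float(parts[6])]
            else:
                frame_has_vel = False
        frames.append(pos)
        vels.append(vel if frame_has_vel else None)
        has_velocities = has_velocities and frame_has_vel
        times.append(float(kv.get("time", len(frames) - 1)))
        pistons.append(float(kv.get("piston_x", "nan")))
        i += 2 + n
    if not frames:
        raise TrajectoryParseError("empty trajectory file")
    return {
        "positions": np.array(frames),
        "velocities": np.array(vels) if has_velocities else None,
        "times": np.array(times),
        "piston_x": np.array(pistons),
        "comments": comments,
        "has_velocities": has_velocities,
    }


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_CHANNEL_KEYS = {f.name for f in dataclasses.fields(HelixChannel)} | {"R_H_fraction"}
_PROTOCOL_KEYS = {f.name for f in dataclasses.fields(Protocol)}


def load_config(path: str | Path) -> tuple[SimulationConfig, HelixChannel | None, Protocol]:
    """Load a YAML config with ``chain``, ``channel`` and ``protocol`` blocks.

    Unknown keys are rejected; invariant violations raise ConfigError naming
    the invariant.  ``channel`` may be absent (free chain) and supports
    ``R_H_fraction`` (R_H as a fraction of R_ch) as an alternative to ``R_H``.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    for block in raw:
        if block not in ("chain", "channel", "protocol"):
            raise ConfigError(f"unknown config block {block!r}")
    chain_raw = raw.get("chain", {}) or {}
    unknown = set(chain_raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown chain keys: {sorted(unknown)}")
    config = SimulationConfig(**chain_raw)
    channel = None
    if "channel" in raw and raw["channel"] is not None:
        ch_raw = dict(raw["channel"])
        unknown = set(ch_raw) - _CHANNEL_KEYS
        if unknown:
            raise ConfigError(f"unknown channel keys: {sorted(unknown)}")
        frac = ch_raw.pop("R_H_fraction", None)
        if frac is not None:
            if "R_H" in ch_raw:
                raise ConfigError("give either R_H or R_H_fraction, not both")
            ch_raw["R_H"] = frac * ch_raw.get("R_ch", 5.0)
        channel = HelixChannel(**ch_raw)
    proto_raw = raw.get("protocol", {}) or {}
    unknown = set(proto_raw) - _PROTOCOL_KEYS
    if unknown:
        raise ConfigError(f"unknown protocol keys: {sorted(unknown)}")
    protocol = Protocol(**proto_raw)
    return config, channel, protocol


def save_config(
    path: str | Path,
    config: SimulationConfig,
    channel: HelixChannel | None = None,
    protocol: Protocol | None = None,
) -> Path:
    path = Path(path)
    doc = {"chain": dataclasses.asdict(config)}
    if channel is not None:
        doc["channel"] = dataclasses.asdict(channel)
    if protocol is not None:
        doc["protocol"] = dataclasses.asdict(protocol)
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunManifest:
    """Reproducibility record: config hash, seeds and output paths per stage."""

    config_hash: str
    seeds: list[int]
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)
    tool_version: str = "0.1.0"
    wall_status: dict[str, str] = dataclasses.field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, sort_keys=True)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as f:
            return cls(**json.load(f))
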