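"""Trajectory data model and channel-frame geometry.

A membrane water channel is analysed in a *channel frame*: a per-monomer
coordinate system whose +z axis points from the intracellular (IC) to the
extracellular (EC) side and whose origin is placed so that the dividing
plane — the most constricted point of the pore — sits at ``z = z_divide``
(0 by default).  Waters are followed as one-dimensional tracks of their
channel-frame axial coordinate; everything downstream (crossing-event
detection, linear density, the TST rate constant) consumes these tracks.

The module reads standard MD formats (PDB/PSF topologies, DCD/XTC/multi-
model-PDB trajectories) through MDAnalysis, unwraps coordinates across
periodic images so each molecule's series is continuous, and assigns
waters to monomers of an oligomeric channel by nearest axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DataError,
    FormatError,
    GeometryError,
    TruncationError,
)

#: Default atom selection for water oxygens (covers TIP3/TIP3P/SPC naming).
DEFAULT_WATER_SELECTION = (
    "(resname TIP3 TIP3P TIP4 SPC SPCE SOL WAT HOH) and (name O OW OH2)"
)

_AXIS_NORM_TOL = 1e-8


@dataclass(frozen=True)
class ChannelFrame:
    """Per-monomer channel coordinate system.

    Parameters
    ----------
    monomer_id:
        Label of the monomer this frame belongs to.
    origin:
        Point (Å, lab frame) that maps to z = 0; by convention the
        channel's most constricted point, i.e. the dividing plane.
    axis:
        Unit vector along the pore, IC → EC positive.
    z_divide:
        Dividing-plane position in the channel frame (Å).  0 by default;
        configurable because the constriction of a deposited structure
        need not coincide with the frame origin.
    z_bulk_ec, z_bulk_ic:
        Axial thresholds (Å) beyond which a water counts as having
        reached the EC (resp. IC) bulk reservoir.
    radius_gate:
        Lateral cutoff (Å) deciding whether a molecule inside the slab
        ``z_bulk_ic < z < z_bulk_ec`` belongs to this monomer's pore.
    """

    monomer_id: str
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    z_divide: float = 0.0
    z_bulk_ec: float = 15.0
    z_bulk_ic: float = -15.0
    radius_gate: float = 6.0

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        norm = float(np.linalg.norm(axis))
        if norm < _AXIS_NORM_TOL:
            raise GeometryError(
                f"channel axis of monomer {self.monomer_id!r} is degenerate "
                f"(norm {norm:.3e})"
            )
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis", axis / norm)
        if not (self.z_bulk_ic < self.z_divide < self.z_bulk_ec):
            raise ConfigurationError(
                "need z_bulk_ic < z_divide < z_bulk_ec, got "
                f"{self.z_bulk_ic} / {self.z_divide} / {self.z_bulk_ec}"
            )
        if not self.radius_gate > 0:
            raise ConfigurationError("radius_gate must be positive")


@dataclass
class ParticleTrack:
    """Channel-frame time series of one tagged molecule.

    ``z`` is the axial coordinate (Å), unwrapped across periodic images so
    that no step exceeds half the box; ``vz`` (Å/ps) is optional and only
    needed for velocity diagnostics.  ``lateral_ok`` marks frames on which
    the molecule is inside this monomer's lateral gate (outside the slab
    it is True by definition: the molecule is in bulk).
    """

    particle_id: int
    times: np.ndarray
    z: np.ndarray
    vz: np.ndarray | None = None
    lateral_ok: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.ndim != 1 or self.z.shape != self.times.shape:
            raise DataError("times and z must be 1-D series of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise DataError("track times must be strictly increasing")
        if self.vz is not None:
            self.vz = np.asarray(self.vz, dtype=float)
            if self.vz.shape != self.times.shape:
                raise DataError("vz must match times in length")
        if self.lateral_ok is not None:
            self.lateral_ok = np.asarray(self.lateral_ok, dtype=bool)
            if self.lateral_ok.shape != self.times.shape:
                raise DataError("lateral_ok must match times in length")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class TrajectoryBundle:
    """Container for one analysed trajectory.

    ``tracks`` maps monomer id → list of :class:`ParticleTrack`.  Raw lab-
    frame positions are kept (when available) so channel frames can be
    re-projected without re-reading the trajectory.
    """

    frames_count: int
    dt_frame: float
    tracks: dict[str, list[ParticleTrack]]
    temperature: float = 298.15
    box: np.ndarray | None = None
    raw_positions: np.ndarray | None = None  # (frames, particles, 3), unwrapped
    particle_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frames_count < 2:
            raise DataError("a trajectory needs at least 2 frames")
        if not self.dt_frame > 0:
            raise DataError("dt_frame must be positive")
        if not self.temperature > 0:
            raise DataError("temperature must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames_count) * self.dt_frame

    def all_tracks(self) -> Iterable[ParticleTrack]:
        for tracks in self.tracks.values():
            yield from tracks


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------

def unwrap_coordinates(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from per-particle coordinate series.

    Applies the minimum-image convention to each consecutive displacement:
    any per-frame step larger than half the (orthorhombic) box length in a
    dimension is shifted by an integer number of box lengths.

    Parameters
    ----------
    positions:
        ``(n_frames, n_particles, 3)`` wrapped coordinates (Å).
    box:
        ``(n_frames, 3)`` or ``(3,)`` box lengths (Å).

    Returns
    -------
    Unwrapped coordinates of the same shape.  The wrapped coordinate is
    recoverable modulo the box length.
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    if box.ndim == 1:
        box = np.broadcast_to(box, (positions.shape[0], 3))
    out = positions.copy()
    disp = np.diff(positions, axis=0)
    # minimum-image correction per step, using the box of the earlier frame
    shift = np.round(disp / box[:-1, None, :]) * box[:-1, None, :]
    out[1:] = positions[0] + np.cumsum(disp - shift, axis=0)
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_topology_and_trajectory(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    water_selection: str = DEFAULT_WATER_SELECTION,
    frame_stride: int = 1,
    channel_frames: Sequence[ChannelFrame] | None = None,
    temperature: float = 298.15,
    box: Sequence[float] | None = None,
) -> TrajectoryBundle:
    """Read an MD topology + trajectory into a :class:`TrajectoryBundle`.

    Accepts any topology/trajectory pair MDAnalysis can open (PDB, PSF /
    DCD, XTC, multi-model PDB...).  Selected water oxygens become one
    track each; coordinates are unwrapped so every z series is continuous.

    If ``channel_frames`` is given, tracks are produced per monomer via
    :func:`assign_tracks`; otherwise a single identity frame labelled
    ``"all"`` is used (lab z axis, no lateral gating).

    ``box`` supplies periodic box lengths (Å) for formats that do not
    carry them per frame (e.g. some PDB files); per-frame dimensions from
    the trajectory take precedence.  Without box information coordinates
    are taken as already unwrapped.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FormatError(f"topology not found: {topology_path}")
    try:
        if trajectory_path is None:
            u = mda.Universe(str(topology_path))
        else:
            trajectory_path = Path(trajectory_path)
            if not trajectory_path.exists():
                raise FormatError(f"trajectory not found: {trajectory_path}")
            u = mda.Universe(str(topology_path), str(trajectory_path))
    except FormatError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted types on mismatch
        raise FormatError(
            f"could not open {topology_path.name}"
            + (f" + {Path(trajectory_path).name}" if trajectory_path else "")
            + f": {exc}"
        ) from exc

    sel = u.select_atoms(water_selection)
    if len(sel) == 0:
        raise ConfigurationError(
            f"water selection {water_selection!r} matched no atoms"
        )
    if frame_stride < 1:
        raise ConfigurationError("frame_stride must be >= 1")

    positions = []
    boxes = []
    n_read = 0
    try:
        for ts in u.trajectory[::frame_stride]:
            positions.append(sel.positions.astype(float).copy())
            dims = ts.dimensions
            if dims is not None and np.all(np.asarray(dims[:3]) > 0):
                boxes.append(np.asarray(dims[:3], dtype=float))
            elif box is not None:
                boxes.append(np.asarray(box, dtype=float)[:3])
            else:
                boxes.append(np.full(3, np.inf))
            n_read += 1
    except Exception as exc:
        raise TruncationError(
            f"trajectory unreadable after frame {n_read - 1} "
            f"(stride {frame_stride}): {exc}",
            last_good_frame=n_read - 1,
        ) from exc

    if n_read < 2:
        raise DataError(f"only {n_read} frame(s) read; need at least 2")

    pos = np.stack(positions)
    box = np.stack(boxes)
    finite = np.isfinite(box)
    if finite.any():
        pos_unwrapped = unwrap_coordinates(pos, np.where(finite, box, 1e12))
    else:
        pos_unwrapped = pos

    dt = getattr(u.trajectory, "dt", None) or 1.0
    bundle = TrajectoryBundle(
        frames_count=n_read,
        dt_frame=float(dt) * frame_stride,
        tracks={},
        temperature=temperature,
        box=box,
        raw_positions=pos_unwrapped,
        particle_ids=sel.ids.astype(int)
        if hasattr(sel, "ids")
        else np.arange(len(sel)),
    )
    if channel_frames is None:
        channel_frames = [
            ChannelFrame(monomer_id="all", radius_gate=1e9)
        ]
    bundle.tracks = assign_tracks(bundle, channel_frames)
    return bundle


# ---------------------------------------------------------------------------
# channel frames
# ---------------------------------------------------------------------------

def build_channel_frames(
    monomer_spec: Mapping | Sequence[Mapping],
    topology_path: str | Path | None = None,
    channel: Mapping | None = None,
) -> list[ChannelFrame]:
    """Construct :class:`ChannelFrame` objects from a config mapping.

    ``monomer_spec`` is either the full config dict (with ``monomers`` and
    optional ``channel`` blocks) or the list of monomer entries directly.
    Each monomer entry provides either

    * ``origin`` and ``axis`` explicitly, or
    * ``ec_residues`` and ``ic_residues`` — two atom selections whose
      centroids define the axis (EC centroid − IC centroid, normalised);
      the origin defaults to the midpoint of the two centroids and may be
      shifted with ``origin``.

    Residue-group mode requires ``topology_path``.
    """
    if isinstance(monomer_spec, Mapping):
        channel = monomer_spec.get("channel", channel)
        monomers = monomer_spec.get("monomers")
        if monomers is None:
            raise ConfigurationError("config has no 'monomers' block")
    else:
        monomers = list(monomer_spec)
    if not monomers:
        raise ConfigurationError("at least one monomer must be specified")

    channel = dict(channel or {})
    frame_kwargs = {
        key: float(channel[key])
        for key in ("z_divide", "z_bulk_ec", "z_bulk_ic", "radius_gate")
        if key in channel
    }

    universe = None
    frames: list[ChannelFrame] = []
    for i, entry in enumerate(monomers):
        monomer_id = str(entry.get("id", f"M{i}"))
        if "axis" in entry:
            origin = np.asarray(entry.get("origin", (0.0, 0.0, 0.0)), float)
            axis = np.asarray(entry["axis"], float)
        elif "ec_residues" in entry and "ic_residues" in entry:
            if topology_path is None:
                raise ConfigurationError(
                    f"monomer {monomer_id!r} uses residue groups but no "
                    "topology was given"
                )
            if universe is None:
                import MDAnalysis as mda

                universe = mda.Universe(str(topology_path))
            ec = universe.select_atoms(str(entry["ec_residues"]))
            ic = universe.select_atoms(str(entry["ic_residues"]))
            if len(ec) == 0 or len(ic) == 0:
                raise ConfigurationError(
                    f"residue groups of monomer {monomer_id!r} matched no atoms"
                )
            ec_c = ec.positions.mean(axis=0)
            ic_c = ic.positions.mean(axis=0)
            axis = ec_c - ic_c
            origin = np.asarray(entry.get("origin", 0.5 * (ec_c + ic_c)), float)
        else:
            raise ConfigurationError(
                f"monomer {monomer_id!r} needs either 'axis' or "
                "'ec_residues'+'ic_residues'"
            )
        frames.append(
            ChannelFrame(monomer_id=monomer_id, origin=origin, axis=axis,
                         **frame_kwargs)
        )
    ids = [f.monomer_id for f in frames]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate monomer ids: {ids}")
    return frames


def project_to_channel_frame(
    bundle: TrajectoryBundle, frame: ChannelFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Project raw positions onto one channel frame.

    Returns ``(z, lateral_ok)``, both of shape ``(n_frames, n_particles)``.
    ``z = (r − origin)·axis``; ``lateral_ok`` is the lateral distance test
    against ``radius_gate``, evaluated only inside the slab
    ``z_bulk_ic < z < z_bulk_ec`` (outside, True by definition: bulk).
    """
    if bundle.raw_positions is None:
        raise DataError("bundle carries no raw positions to project")
    rel = bundle.raw_positions - frame.origin
    z = rel @ frame.axis
    lateral = rel - z[..., None] * frame.axis
    r2 = np.einsum("...i,...i->...", lateral, lateral)
    in_slab = (z > frame.z_bulk_ic) & (z < frame.z_bulk_ec)
    lateral_ok = np.where(in_slab, r2 <= frame.radius_gate**2, True)
    return z, lateral_ok


def assign_tracks(
    bundle: TrajectoryBundle, frames: Sequence[ChannelFrame]
) -> dict[str, list[ParticleTrack]]:
    """Build per-monomer particle tracks from raw positions.

    Inside the slab a water belongs to at most one monomer per frame: the
    one whose axis is laterally nearest, provided it is within that
    monomer's ``radius_gate`` (ties broken by monomer order, i.e. lowest
    id first in ``frames``).  Outside the slab the water is in bulk and
    ``lateral_ok`` is True for every monomer.
    """
    if bundle.raw_positions is None:
        raise DataError("bundle carries no raw positions to assign")
    n_frames, n_particles, _ = bundle.raw_positions.shape
    times = bundle.times
    ids = (
        bundle.particle_ids
        if bundle.particle_ids is not None
        else np.arange(n_particles)
    )

    z_all = np.empty((len(frames), n_frames, n_particles))
    r2_all = np.empty_like(z_all)
    in_slab_all = np.empty(z_all.shape, dtype=bool)
    for k, frame in enumerate(frames):
        rel = bundle.raw_positions - frame.origin
        z = rel @ frame.axis
        lateral = rel - z[..., None] * frame.axis
        z_all[k] = z
        r2_all[k] = np.einsum("...i,...i->...", lateral, lateral)
        in_slab_all[k] = (z > frame.z_bulk_ic) & (z < frame.z_bulk_ec)

    gates2 = np.array([f.radius_gate**2 for f in frames])
    within = r2_all <= gates2[:, None, None]
    # nearest eligible axis wins; argmin on masked distances keeps the
    # first (lowest-index) monomer on exact ties
    masked = np.where(within & in_slab_all, r2_all, np.inf)
    winner = np.argmin(masked, axis=0)
    any_winner = np.isfinite(np.min(masked, axis=0))

    out: dict[str, list[ParticleTrack]] = {}
    for k, frame in enumerate(frames):
        member = np.where(
            in_slab_all[k], (winner == k) & any_winner, True
        )
        out[frame.monomer_id] = [
            ParticleTrack(
                particle_id=int(ids[p]),
                times=times,
                z=z_all[k, :, p],
                lateral_ok=member[:, p],
            )
            for p in range(n_particles)
        ]
    return out


# ---------------------------------------------------------------------------
# on-disk cache
# ---------------------------------------------------------------------------

def save_bundle(bundle: TrajectoryBundle, path: str | Path) -> None:
    """Write a bundle to ``path`` (.npz) plus a JSON metadata sidecar."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {
        "frames_count": bundle.frames_count,
        "dt_frame": bundle.dt_frame,
        "temperature": bundle.temperature,
        "monomers": {},
    }
    if bundle.box is not None:
        arrays["box"] = bundle.box
    if bundle.raw_positions is not None:
        arrays["raw_positions"] = bundle.raw_positions
    if bundle.particle_ids is not None:
        arrays["particle_ids"] = bundle.particle_ids
    for mono, tracks in bundle.tracks.items():
        meta["monomers"][mono] = []
        for j, tr in enumerate(tracks):
            key = f"trk_{mono}_{j}"
            arrays[f"{key}_t"] = tr.times
            arrays[f"{key}_z"] = tr.z
            entry = {"particle_id": tr.particle_id, "key": key,
                     "has_vz": tr.vz is not None,
                     "has_lat": tr.lateral_ok is not None}
            if tr.vz is not None:
                arrays[f"{key}_v"] = tr.vz
            if tr.lateral_ok is not None:
                arrays[f"{key}_l"] = tr.lateral_ok
            meta["monomers"][mono].append(entry)
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta))


def load_bundle(path: str | Path) -> TrajectoryBundle:
    """Read a bundle written by :func:`save_bundle` (bit-exact round trip)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not path.exists() or not sidecar.exists():
        raise FormatError(f"cache {path} (or its JSON sidecar) not found")
    meta = json.loads(sidecar.read_text())
    data = np.load(path)
    tracks: dict[str, list[ParticleTrack]] = {}
    for mono, entries in meta["monomers"].items():
        tracks[mono] = []
        for entry in entries:
            key = entry["key"]
            tracks[mono].append(
                ParticleTrack(
                    particle_id=int(entry["particle_id"]),
                    times=data[f"{key}_t"],
                    z=data[f"{key}_z"],
                    vz=data[f"{key}_v"] if entry["has_vz"] else None,
                    lateral_ok=data[f"{key}_l"] if entry["has_lat"] else None,
                )
            )
    return TrajectoryBundle(
        frames_count=int(meta["frames_count"]),
        dt_frame=float(meta["dt_frame"]),
        tracks=tracks,
        temperature=float(meta["temperature"]),
        box=data["box"] if "box" in data else None,
        raw_positions=data["raw_positions"] if "raw_positions" in data else None,
        particle_ids=data["particle_ids"] if "particle_ids" in data else None,
    )
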