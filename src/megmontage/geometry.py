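"""Sensor arrays, spherical head models, regional-source sets and cortical grids.

All geometry lives in a right-handed head coordinate frame in metres
(+x right, +y anterior, +z superior), with the conducting sphere centred
at the origin by default.  Magnetometer noise is expressed in tesla,
planar-gradiometer noise in T/m; the common clinical figures of 200 fT
and 50 fT/cm correspond to 2e-13 T and 5e-12 T/m.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MAGNETOMETER",
    "PLANAR_GRADIOMETER",
    "SensorChannel",
    "SensorArray",
    "SphereModel",
    "SourceLocation",
    "RegionalSourceSet",
    "CorticalGrid",
    "DEFAULT_MAG_NOISE_SD",
    "DEFAULT_GRAD_NOISE_SD",
    "DEFAULT_GRAD_BASELINE",
    "tangential_basis",
    "make_synthetic_helmet",
    "make_br29_locations",
    "subdivide_octahedron",
    "make_hemisphere_grids",
    "nearest_sensor_distance",
]

MAGNETOMETER = "magnetometer"
PLANAR_GRADIOMETER = "planar_gradiometer"

#: default per-channel noise SD: 200 fT for magnetometers
DEFAULT_MAG_NOISE_SD = 2e-13
#: default per-channel noise SD: 50 fT/cm = 5e-12 T/m for planar gradiometers
DEFAULT_GRAD_NOISE_SD = 5e-12
#: physical two-point differencing baseline of a planar gradiometer, metres
DEFAULT_GRAD_BASELINE = 0.0168

_UNIT_TOL = 1e-9


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite")
    return v


def _json_text(source) -> str:
    """Accept a path or a literal JSON string."""
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if s.lstrip().startswith("{"):
        return s
    return Path(s).read_text()


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


@dataclass
class SensorChannel:
    """A single MEG measurement channel.

    For magnetometers ``orientation`` is the field-sensitive axis (the coil
    normal).  For planar gradiometers ``orientation`` is the tangential
    differencing axis, ``field_axis`` the coil normal onto which the field
    is projected before differencing, and ``baseline`` the physical
    two-point separation in metres.
    """

    name: str
    position: np.ndarray
    orientation: np.ndarray
    kind: str
    noise_sd: float
    baseline: float | None = None
    field_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = _as_vec3(self.position, "position")
        self.orientation = _as_vec3(self.orientation, "orientation")
        if abs(np.linalg.norm(self.orientation) - 1.0) > _UNIT_TOL:
            raise ValueError(f"orientation of {self.name!r} must be unit-norm")
        if self.kind not in (MAGNETOMETER, PLANAR_GRADIOMETER):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd of {self.name!r} must be positive")
        if self.kind == PLANAR_GRADIOMETER:
            if self.baseline is None or not self.baseline > 0:
                raise ValueError(
                    f"gradiometer {self.name!r} requires a positive baseline"
                )
            if self.field_axis is None:
                # coil normal defaults to the radial direction at the site
                self.field_axis = _unit(self.position)
            else:
                self.field_axis = _unit(_as_vec3(self.field_axis, "field_axis"))
        else:
            if self.baseline is not None:
                raise ValueError(f"magnetometer {self.name!r} takes no baseline")
            self.field_axis = None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "kind": self.kind,
            "position_m": self.position.tolist(),
            "orientation": self.orientation.tolist(),
            "noise_sd": self.noise_sd,
        }
        if self.kind == PLANAR_GRADIOMETER:
            d["baseline_m"] = self.baseline
            d["field_axis"] = self.field_axis.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SensorChannel":
        return cls(
            name=d["name"],
            position=d["position_m"],
            orientation=d["orientation"],
            kind=d["kind"],
            noise_sd=d["noise_sd"],
            baseline=d.get("baseline_m"),
            field_axis=d.get("field_axis"),
        )


@dataclass
class SensorArray:
    """Ordered collection of channels; the order fixes the rows of data
    matrices and lead fields."""

    channels: list[SensorChannel]
    frame: str = "head"

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("SensorArray needs at least one channel")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.channels])

    @property
    def kinds(self) -> np.ndarray:
        return np.array([c.kind for c in self.channels])

    @property
    def noise_sds(self) -> np.ndarray:
        return np.array([c.noise_sd for c in self.channels])

    def subset(self, kind: str | None = None, names: Sequence[str] | None = None) -> "SensorArray":
        """Channel subset by kind and/or explicit names, preserving order."""
        chans = self.channels
        if kind is not None:
            if kind not in (MAGNETOMETER, PLANAR_GRADIOMETER):
                raise ValueError(f"unknown channel kind {kind!r}")
            chans = [c for c in chans if c.kind == kind]
        if names is not None:
            wanted = set(names)
            missing = wanted - {c.name for c in chans}
            if missing:
                raise KeyError(f"unknown channel names: {sorted(missing)}")
            chans = [c for c in chans if c.name in wanted]
        if not chans:
            raise ValueError("subset selects no channels")
        return SensorArray(channels=chans, frame=self.frame)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"frame": self.frame, "channels": [c.to_dict() for c in self.channels]},
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SensorArray":
        d = json.loads(_json_text(source))
        return cls(
            channels=[SensorChannel.from_dict(c) for c in d["channels"]],
            frame=d.get("frame", "head"),
        )


@dataclass
class SphereModel:
    """Homogeneous spherical volume conductor; only the centre matters for
    the magnetic field of internal current dipoles."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.center = _as_vec3(self.center, "center")


def tangential_basis(position, sphere: SphereModel) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangential pair (e_theta, e_phi) at ``position``.

    Uses standard spherical coordinates about the sphere centre with the
    +z axis as pole; on the polar axis the pair degenerates and we fall
    back to (x_hat, y_hat), which is a valid tangential basis there.
    """
    r = _as_vec3(position, "position") - sphere.center
    rn = np.linalg.norm(r)
    if rn == 0:
        raise ValueError("position coincides with the sphere center")
    rho = math.hypot(r[0], r[1])
    if rho < 1e-12 * rn:
        return np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    cos_t = r[2] / rn
    sin_t = rho / rn
    cos_p = r[0] / rho
    sin_p = r[1] / rho
    e_theta = np.array([cos_t * cos_p, cos_t * sin_p, -sin_t])
    e_phi = np.array([-sin_p, cos_p, 0.0])
    return e_theta, e_phi


@dataclass
class SourceLocation:
    """One regional-source location with its tangential dipole basis."""

    label: str
    position: np.ndarray
    e_theta: np.ndarray
    e_phi: np.ndarray

    def __post_init__(self) -> None:
        self.position = _as_vec3(self.position, "position")
        self.e_theta = _as_vec3(self.e_theta, "e_theta")
        self.e_phi = _as_vec3(self.e_phi, "e_phi")
        for v, nm in ((self.e_theta, "e_theta"), (self.e_phi, "e_phi")):
            if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
                raise ValueError(f"{nm} of {self.label!r} must be unit-norm")
        if abs(self.e_theta @ self.e_phi) > 1e-8:
            raise ValueError(f"tangential basis of {self.label!r} not orthogonal")

    @classmethod
    def at(cls, label: str, position, sphere: SphereModel) -> "SourceLocation":
        et, ep = tangential_basis(position, sphere)
        return cls(label=label, position=np.asarray(position, float), e_theta=et, e_phi=ep)

    def tangential_direction(self, weights=(1.0, 1.0)) -> np.ndarray:
        """Unit vector along weights[0]*e_theta + weights[1]*e_phi."""
        return _unit(weights[0] * self.e_theta + weights[1] * self.e_phi)


@dataclass
class RegionalSourceSet:
    """Labelled regional-source locations; two tangential components per
    location for MEG, so P = 2 * len(locations)."""

    locations: list[SourceLocation]
    sphere: SphereModel

    def __post_init__(self) -> None:
        labels = [s.label for s in self.locations]
        if len(set(labels)) != len(labels):
            raise ValueError("source labels must be unique")
        for loc in self.locations:
            r = loc.position - self.sphere.center
            if np.linalg.norm(r) == 0:
                raise ValueError(f"{loc.label!r} sits at the sphere center")
            rhat = r / np.linalg.norm(r)
            for v, nm in ((loc.e_theta, "e_theta"), (loc.e_phi, "e_phi")):
                if abs(v @ rhat) > 1e-8:
                    raise ValueError(f"{nm} of {loc.label!r} is not tangential")

    def __len__(self) -> int:
        return len(self.locations)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.locations]

    @property
    def n_components(self) -> int:
        return 2 * len(self.locations)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.locations])

    def __getitem__(self, label: str) -> SourceLocation:
        for loc in self.locations:
            if loc.label == label:
                return loc
        raise KeyError(label)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "sphere_center_m": self.sphere.center.tolist(),
                "locations": [
                    {
                        "label": s.label,
                        "position_m": s.position.tolist(),
                        "e_theta": s.e_theta.tolist(),
                        "e_phi": s.e_phi.tolist(),
                    }
                    for s in self.locations
                ],
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "RegionalSourceSet":
        d = json.loads(_json_text(source))
        sphere = SphereModel(center=d.get("sphere_center_m", [0.0, 0.0, 0.0]))
        locs = []
        for s in d["locations"]:
            if "e_theta" in s:
                locs.append(
                    SourceLocation(
                        label=s["label"],
                        position=s["position_m"],
                        e_theta=s["e_theta"],
                        e_phi=s["e_phi"],
                    )
                )
            else:
                locs.append(SourceLocation.at(s["label"], s["position_m"], sphere))
        return cls(locations=locs, sphere=sphere)


# --------------------------------------------------------------------------
# synthetic helmet

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def make_synthetic_helmet(
    n_sites: int = 102,
    helmet_radius: float = 0.12,
    coverage_angle: float = 2.2,
    seed: int = 0,
    mag_noise_sd: float = DEFAULT_MAG_NOISE_SD,
    grad_noise_sd: float = DEFAULT_GRAD_NOISE_SD,
    grad_baseline: float = DEFAULT_GRAD_BASELINE,
) -> SensorArray:
    """Quasi-uniform whole-head helmet of sensor triplets.

    Each site carries one radial magnetometer plus two planar gradiometers
    whose differencing axes are the orthogonal tangential directions at the
    site.  Sites follow a Fibonacci lattice over a spherical cap of
    half-angle ``coverage_angle`` about +z; ``seed`` fixes a deterministic
    azimuthal rotation of the whole lattice.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    if not helmet_radius > 0:
        raise ValueError("helmet_radius must be positive")
    if not 0 < coverage_angle <= math.pi:
        raise ValueError("coverage_angle must lie in (0, pi]")

    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * math.pi)
    cos_min = math.cos(coverage_angle)
    sphere = SphereModel()
    channels: list[SensorChannel] = []
    for i in range(n_sites):
        u = 1.0 - (i + 0.5) / n_sites * (1.0 - cos_min)  # cos(theta)
        theta = math.acos(u)
        phi = phi0 + i * _GOLDEN_ANGLE
        pos = helmet_radius * np.array(
            [
                math.sin(theta) * math.cos(phi),
                math.sin(theta) * math.sin(phi),
                math.cos(theta),
            ]
        )
        radial = pos / helmet_radius
        e_t, e_p = tangential_basis(pos, sphere)
        channels.append(
            SensorChannel(
                name=f"MAG{i:03d}",
                position=pos,
                orientation=radial,
                kind=MAGNETOMETER,
                noise_sd=mag_noise_sd,
            )
        )
        for suffix, axis in (("A", e_t), ("B", e_p)):
            channels.append(
                SensorChannel(
                    name=f"GRD{i:03d}{suffix}",
                    position=pos,
                    orientation=axis,
                    kind=PLANAR_GRADIOMETER,
                    noise_sd=grad_noise_sd,
                    baseline=grad_baseline,
                    field_axis=radial,
                )
            )
    return SensorArray(channels=channels)


# --------------------------------------------------------------------------
# canonical 29-region montage layout

# (region code, polar angle from vertex in degrees, azimuth from anterior
# toward the lateral side in degrees).  Midline regions use azimuth 0
# (anterior) or 180 (posterior).  This layout is a documented synthetic
# stand-in distributing the 29 regions over frontal, central, temporal,
# parietal and occipital cortex of both hemispheres and the midline; the
# true clinical coordinates can be substituted via a JSON file.
_BR29_MIDLINE = [
    ("FpM", 65.0, 0.0),
    ("FCM", 30.0, 0.0),
    ("CM", 0.0, 0.0),
    ("PM", 30.0, 180.0),
    ("OM", 70.0, 180.0),
]
_BR29_PAIRS = [
    ("Fp", 65.0, 25.0),
    ("F", 45.0, 35.0),
    ("FC2", 25.0, 50.0),
    ("FC6", 50.0, 70.0),
    ("C2", 25.0, 95.0),
    ("C6", 55.0, 90.0),
    ("TA", 85.0, 65.0),
    ("TP", 85.0, 110.0),
    ("CP", 35.0, 130.0),
    ("P", 45.0, 155.0),
    ("PO", 62.0, 150.0),
    ("O", 75.0, 172.0),
]


def _shell_point(theta_deg: float, azimuth_deg: float, side: str, radius: float) -> np.ndarray:
    """Point on a shell: polar angle from +z, azimuth from +y (anterior)
    rotating toward +x for the right hemisphere, toward -x for the left."""
    th = math.radians(theta_deg)
    az = math.radians(azimuth_deg)
    lateral = math.sin(th) * math.sin(az)
    if side == "L":
        lateral = -lateral
    return radius * np.array([lateral, math.sin(th) * math.cos(az), math.cos(th)])


def make_br29_locations(
    sphere: SphereModel | None = None, shell_radius: float = 0.07
) -> RegionalSourceSet:
    """Canonical 29-region source layout on a spherical shell.

    Five midline regions plus twelve left/right pairs (labels such as
    ``FC6R``, ``TPL``, ``FpM``), each with its tangential dipole basis
    attached.  ``shell_radius`` defaults to 70 mm.
    """
    if not shell_radius > 0:
        raise ValueError("shell_radius must be positive")
    sphere = sphere or SphereModel()
    locs: list[SourceLocation] = []
    for code, theta, az in _BR29_MIDLINE:
        pos = sphere.center + _shell_point(theta, az, "M", shell_radius)
        locs.append(SourceLocation.at(code, pos, sphere))
    for code, theta, az in _BR29_PAIRS:
        for side in ("L", "R"):
            pos = sphere.center + _shell_point(theta, az, side, shell_radius)
            locs.append(SourceLocation.at(f"{code}{side}", pos, sphere))
    return RegionalSourceSet(locations=locs, sphere=sphere)


# --------------------------------------------------------------------------
# cortical grids

@dataclass
class CorticalGrid:
    """Triangulated spherical source grid standing in for a cortical
    surface: vertices with outward normals, faces, and 1-ring adjacency."""

    vertices: np.ndarray
    normals: np.ndarray
    faces: np.ndarray
    adjacency: list[list[int]]
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")

    def __len__(self) -> int:
        return len(self.vertices)

    def patch(self, vertex: int) -> list[int]:
        """Seed vertex plus its 1-ring neighbours."""
        return [vertex] + list(self.adjacency[vertex])

    def triangle_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def subdivide_octahedron(
    levels: int,
    scale: float = 1.0,
    center=(0.0, 0.0, 0.0),
    hemisphere: str = "left",
) -> CorticalGrid:
    """Recursive 4-way subdivision of a unit octahedron projected to the
    sphere, scaled and translated; vertex count is 4**(levels+1) + 2."""
    if levels < 0:
        raise ValueError("levels must be non-negative")
    if levels > 7:
        raise ValueError("levels above 7 are impractically dense")

    verts = [
        np.array(v, dtype=float)
        for v in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    ]
    faces = [
        (0, 2, 4), (2, 1, 4), (1, 3, 4), (3, 0, 4),
        (2, 0, 5), (1, 2, 5), (3, 1, 5), (0, 3, 5),
    ]
    for _ in range(levels):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in cache:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces

    v = np.array(verts)
    normals = v.copy()  # radial on the unit sphere
    center = np.asarray(center, dtype=float)
    positions = center + scale * v
    adjacency: list[set[int]] = [set() for _ in range(len(v))]
    for a, b, c in faces:
        adjacency[a].update((b, c))
        adjacency[b].update((a, c))
        adjacency[c].update((a, b))
    return CorticalGrid(
        vertices=positions,
        normals=normals,
        faces=np.array(faces),
        adjacency=[sorted(s) for s in adjacency],
        hemisphere=hemisphere,
    )


def make_hemisphere_grids(
    levels: int = 5,
    radius: float = 0.045,
    lateral_offset: float = 0.022,
    vertical_offset: float = 0.01,
) -> list[CorticalGrid]:
    """Left and right spherical source grids standing in for the cortical
    surfaces of the two hemispheres.

    Each hemisphere is a subdivided sphere of ``radius`` whose centre is
    shifted laterally off the head-model centre, so surface normals are
    oblique — not radial — with respect to the conducting sphere, and
    vertex depths below the helmet vary over a realistic range.
    """
    grids = []
    for side, sign in (("left", -1.0), ("right", 1.0)):
        grids.append(
            subdivide_octahedron(
                levels,
                scale=radius,
                center=(sign * lateral_offset, 0.0, vertical_offset),
                hemisphere=side,
            )
        )
    return grids


def nearest_sensor_distance(source: SourceLocation, array: SensorArray) -> float:
    """Euclidean distance from a source to the nearest sensor (D1)."""
    if len(array) == 0:
        raise ValueError("sensor array is empty")
    return float(np.min(np.linalg.norm(array.positions - source.position, axis=1)))
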