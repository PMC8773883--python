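"""Current-dipole forward model in a homogeneous conducting sphere.

The magnetic field outside a spherically symmetric conductor has a closed
form (the Sarvas solution) that depends only on the dipole position
relative to the sphere centre, not on the sphere radius or conductivity
profile; radially oriented dipoles are magnetically silent.  Magnetometers
are treated as point field sensors; planar gradiometers as two-point
finite differences of the radial field component at the physical baseline.

Lead-field units: T per A·m for magnetometer rows, T/m per A·m for
gradiometer rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    MAGNETOMETER,
    PLANAR_GRADIOMETER,
    RegionalSourceSet,
    SensorArray,
    SensorChannel,
    SphereModel,
    _as_vec3,
)

__all__ = [
    "DipoleSource",
    "LeadField",
    "dipole_field",
    "dipole_field_magnetometer",
    "dipole_response_gradiometer",
    "channel_response",
    "build_leadfield",
]

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass
class DipoleSource:
    """A current dipole: position (m) and moment Q (A·m)."""

    position: np.ndarray
    moment: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.position = _as_vec3(self.position, "position")
        self.moment = _as_vec3(self.moment, "moment")


def dipole_field(dipole: DipoleSource, points: np.ndarray, sphere: SphereModel) -> np.ndarray:
    """Magnetic field B (tesla) of a current dipole in a conducting sphere,
    evaluated at ``points`` (n x 3, metres).  Vectorized Sarvas formula.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = pts - sphere.center  # field points relative to sphere centre
    r0 = dipole.position - sphere.center
    q = dipole.moment

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("field point coincides with the dipole position")
    rn = np.linalg.norm(r, axis=1)
    ar = np.einsum("ij,ij->i", a_vec, r)

    F = a * (rn * a + rn**2 - r @ r0)
    if np.any(np.abs(F) < 1e-30):
        raise ValueError("singular geometry: Sarvas factor F vanished")
    # grad F
    gF = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + ar / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxr0 - (r @ qxr0)[:, None] * gF)
    return B


def dipole_field_magnetometer(
    dipole: DipoleSource, sensor_position, sensor_axis, sphere: SphereModel
) -> float:
    """Field projection (T) on a point magnetometer's sensitive axis."""
    B = dipole_field(dipole, np.atleast_2d(sensor_position), sphere)[0]
    return float(B @ np.asarray(sensor_axis, dtype=float))


def dipole_response_gradiometer(
    dipole: DipoleSource, channel: SensorChannel, sphere: SphereModel
) -> float:
    """Planar-gradiometer response (T/m): two-point central difference of
    the field projected on the coil normal, along the differencing axis."""
    if channel.kind != PLANAR_GRADIOMETER:
        raise ValueError(f"{channel.name!r} is not a planar gradiometer")
    d = channel.baseline
    axis = channel.orientation
    pts = np.array([channel.position + 0.5 * d * axis, channel.position - 0.5 * d * axis])
    B = dipole_field(dipole, pts, sphere)
    return float((B[0] - B[1]) @ channel.field_axis / d)


def channel_response(dipole: DipoleSource, channel: SensorChannel, sphere: SphereModel) -> float:
    if channel.kind == MAGNETOMETER:
        return dipole_field_magnetometer(dipole, channel.position, channel.orientation, sphere)
    return dipole_response_gradiometer(dipole, channel, sphere)


def _array_response(dipole: DipoleSource, array: SensorArray, sphere: SphereModel) -> np.ndarray:
    """Response of every channel to one dipole, in canonical channel order.

    Evaluates the field once at all magnetometer positions and at both
    pickup points of every gradiometer.
    """
    mag_idx = [i for i, c in enumerate(array.channels) if c.kind == MAGNETOMETER]
    grad_idx = [i for i, c in enumerate(array.channels) if c.kind == PLANAR_GRADIOMETER]
    out = np.zeros(len(array))

    if mag_idx:
        pos = np.array([array.channels[i].position for i in mag_idx])
        axes = np.array([array.channels[i].orientation for i in mag_idx])
        B = dipole_field(dipole, pos, sphere)
        out[mag_idx] = np.einsum("ij,ij->i", B, axes)

    if grad_idx:
        chans = [array.channels[i] for i in grad_idx]
        p = np.array([c.position for c in chans])
        ax = np.array([c.orientation for c in chans])
        d = np.array([c.baseline for c in chans])
        normals = np.array([c.field_axis for c in chans])
        pts = np.concatenate([p + 0.5 * d[:, None] * ax, p - 0.5 * d[:, None] * ax])
        B = dipole_field(dipole, pts, sphere)
        n = len(chans)
        diff = np.einsum("ij,ij->i", B[:n] - B[n:], normals) / d
        out[grad_idx] = diff
    return out


@dataclass
class LeadField:
    """M x P lead-field matrix: column j is the response of all channels to
    a 1 A·m dipole along basis direction j."""

    matrix: np.ndarray
    row_channels: list[str]
    col_components: list[tuple[str, str]]
    sphere: SphereModel = field(default_factory=SphereModel)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        M, P = self.matrix.shape
        if M != len(self.row_channels) or P != len(self.col_components):
            raise ValueError("lead-field dimensions inconsistent with labels")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_components(self) -> int:
        return self.matrix.shape[1]

    def restrict(self, array: SensorArray) -> "LeadField":
        """Rows restricted (and re-ordered) to the channels of ``array``."""
        index = {name: i for i, name in enumerate(self.row_channels)}
        missing = [n for n in array.names if n not in index]
        if missing:
            raise KeyError(f"channels absent from lead field: {missing}")
        rows = [index[n] for n in array.names]
        return LeadField(
            matrix=self.matrix[rows],
            row_channels=list(array.names),
            col_components=list(self.col_components),
            sphere=self.sphere,
        )


def build_leadfield(
    sources: RegionalSourceSet | list[DipoleSource],
    array: SensorArray,
    sphere: SphereModel | None = None,
) -> LeadField:
    """Assemble the lead field for a regional-source set (two tangential
    unit dipoles per location) or an explicit list of basis dipoles."""
    if isinstance(sources, RegionalSourceSet):
        sphere = sphere or sources.sphere
        basis: list[tuple[str, str, DipoleSource]] = []
        for loc in sources.locations:
            basis.append(
                (loc.label, "theta", DipoleSource(loc.position, loc.e_theta, loc.label))
            )
            basis.append(
                (loc.label, "phi", DipoleSource(loc.position, loc.e_phi, loc.label))
            )
    else:
        if sphere is None:
            raise ValueError("sphere model required for explicit dipole lists")
        basis = [
            (d.label or f"dip{i}", "moment", d) for i, d in enumerate(sources)
        ]
    if not basis:
        raise ValueError("no source components")
    cols = [
        _array_response(dip, array, sphere) for (_, _, dip) in basis
    ]
    return LeadField(
        matrix=np.column_stack(cols),
        row_channels=list(array.names),
        col_components=[(lbl, comp) for (lbl, comp, _) in basis],
        sphere=sphere,
    )
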