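"""Simulated MEG recordings: sinusoidal dipole bursts over background noise.

The study conditions are 4-cycle 20-Hz bursts of a 100-nAm dipole, one
200-ms burst per second (placed in the last 200 ms of each 1-s epoch so
the preceding 800 ms serve as the baseline), superposed on band-limited
background activity and filtered to 2–70 Hz with a zero-phase
fourth-order Butterworth filter.  Three scenario families are provided:
dipoles at the 29 montage locations, 50 tangential dipoles at scattered
cortical locations, and patch sources seeded at every vertex of the
cortical grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import scipy.signal

from .geometry import (
    CorticalGrid,
    RegionalSourceSet,
    SensorArray,
    SourceLocation,
    SphereModel,
    make_br29_locations,
    make_hemisphere_grids,
    make_synthetic_helmet,
    tangential_basis,
)
from .forward import DipoleSource, _array_response

__all__ = [
    "BurstSpec",
    "Recording",
    "ScenarioSpec",
    "StudyGeometry",
    "make_burst_waveform",
    "synth_background",
    "bandpass_filter",
    "simulate_recording",
    "run_scenario",
]

DEFAULT_BAND = (2.0, 70.0)
DEFAULT_FS = 1000.0
NOMINAL_AMPLITUDE = 1e-7  # 100 nAm


@dataclass
class BurstSpec:
    """Sinusoidal burst repeated once per period."""

    freq: float = 20.0
    n_cycles: int = 4
    amplitude: float = NOMINAL_AMPLITUDE
    repeat_period: float = 1.0
    burst_offset: float = 0.8

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.duration + self.burst_offset > self.repeat_period + 1e-12:
            raise ValueError("burst does not fit inside the repeat period")

    @property
    def duration(self) -> float:
        return self.n_cycles / self.freq


def make_burst_waveform(spec: BurstSpec, fs: float, duration: float) -> np.ndarray:
    """Source time course (A·m): spec.n_cycles cycles of a sinusoid at
    spec.freq placed at spec.burst_offset within each repeat period."""
    if fs < 4 * spec.freq:
        raise ValueError("sampling rate too low for the burst frequency")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = t % spec.repeat_period
    active = (phase >= spec.burst_offset) & (phase < spec.burst_offset + spec.duration)
    out = np.zeros(n)
    out[active] = spec.amplitude * np.sin(
        2 * np.pi * spec.freq * (phase[active] - spec.burst_offset)
    )
    return out


@dataclass
class Recording:
    """Multichannel time series (channel units) with its array and
    ground-truth annotations."""

    data: np.ndarray
    fs: float
    array: SensorArray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.array):
            raise ValueError("data must be M x T matching the sensor array")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def reorder(self, names: list[str]) -> "Recording":
        """Channel subset/reordering by name (e.g. to match a montage
        operator built on a channel subset)."""
        index = {n: i for i, n in enumerate(self.array.names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"recording lacks channels: {missing}")
        rows = [index[n] for n in names]
        return Recording(
            data=self.data[rows],
            fs=self.fs,
            array=SensorArray(
                channels=[self.array.channels[i] for i in rows],
                frame=self.array.frame,
            ),
            annotations=dict(self.annotations),
        )


def synth_background(
    array: SensorArray, fs: float, duration: float, seed: int, band=None
) -> Recording:
    """Background activity: independent Gaussian noise per channel with the
    channel's nominal noise SD, optionally band-limited."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    data = array.noise_sds[:, None] * rng.standard_normal((len(array), n))
    if band is not None:
        data = bandpass_filter(data, fs, band)
    return Recording(
        data=data, fs=fs, array=array, annotations={"kind": "background", "seed": seed}
    )


def bandpass_filter(data: np.ndarray, fs: float, band=DEFAULT_BAND, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2}) or inverted")
    sos = scipy.signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def simulate_recording(
    dipoles: DipoleSource | list[DipoleSource],
    waveform: np.ndarray,
    background: Recording,
    sphere: SphereModel,
    band=DEFAULT_BAND,
) -> Recording:
    """Forward-project ``waveform`` (A·m) through one or more dipoles,
    superpose on the background, and band-pass filter the result.

    Each dipole's moment is taken as a direction/weight vector; the sensor
    signal is (sum of channel responses) x waveform.  Annotations carry the
    ground truth.
    """
    if isinstance(dipoles, DipoleSource):
        dipoles = [dipoles]
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1 or waveform.size != background.n_samples:
        raise ValueError("waveform length must match the background recording")
    gain = np.zeros(len(background.array))
    for dip in dipoles:
        gain += _array_response(dip, background.array, sphere)
    data = gain[:, None] * waveform[None, :] + background.data
    if band is not None:
        data = bandpass_filter(data, background.fs, band)
    centroid = np.mean([d.position for d in dipoles], axis=0)
    return Recording(
        data=data,
        fs=background.fs,
        array=background.array,
        annotations={
            "kind": "simulation",
            "dipoles": [
                {"position_m": d.position.tolist(), "moment_weights": d.moment.tolist()}
                for d in dipoles
            ],
            "source_position_m": centroid.tolist(),
            "peak_amplitude_Am": float(np.max(np.abs(waveform), initial=0.0)),
            "background_seed": background.annotations.get("seed"),
        },
    )


@dataclass
class StudyGeometry:
    """Everything a scenario needs: helmet, head model, regional sources
    and cortical grids."""

    array: SensorArray
    sphere: SphereModel
    sources: RegionalSourceSet
    grids: list[CorticalGrid] = field(default_factory=list)

    @classmethod
    def default(cls, seed: int = 0, grid_levels: int = 5) -> "StudyGeometry":
        sphere = SphereModel()
        return cls(
            array=make_synthetic_helmet(seed=seed),
            sphere=sphere,
            sources=make_br29_locations(sphere),
            grids=make_hemisphere_grids(levels=grid_levels),
        )


@dataclass
class ScenarioSpec:
    """One simulation scenario: which source family, how long, at what
    rate, with what burst and noise seed."""

    scenario: str = "montage_locations"
    duration: float = 10.0
    fs: float = DEFAULT_FS
    seed: int = 0
    burst: BurstSpec = field(default_factory=BurstSpec)
    band: tuple = DEFAULT_BAND

    def __post_init__(self) -> None:
        if self.scenario not in ("montage_locations", "fifty_tangential", "cortical_grid"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        n_per = self.duration / self.burst.repeat_period
        if abs(n_per - round(n_per)) > 1e-9:
            raise ValueError("duration must be a whole number of burst periods")


def _scatter_tangential_dipoles(
    sphere: SphereModel, rng: np.random.Generator, n_per_hemisphere: int = 25
) -> list[DipoleSource]:
    """Procedural scattered tangential dipoles, n per hemisphere, at
    cortex-like radii (35–70 mm) above the base of the head model."""
    dipoles = []
    for side, sign in (("L", -1.0), ("R", 1.0)):
        count = 0
        while count < n_per_hemisphere:
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            if sign * v[0] < 0.15 or v[2] < -0.45:
                continue  # wrong hemisphere or below the head model
            radius = rng.uniform(0.035, 0.07)
            pos = sphere.center + radius * v
            e_t, e_p = tangential_basis(pos, sphere)
            angle = rng.uniform(0, 2 * np.pi)
            direction = np.cos(angle) * e_t + np.sin(angle) * e_p
            dipoles.append(DipoleSource(pos, direction, label=f"S{side}{count:02d}"))
            count += 1
    return dipoles


def run_scenario(
    spec: ScenarioSpec, geometry: StudyGeometry
) -> Iterator[tuple[Recording, dict]]:
    """Yield (recording, ground-truth) pairs for the chosen scenario.

    montage_locations: one 100-nAm tangential dipole along
    (e_theta + e_phi)/sqrt(2) at each of the 29 regional-source locations.
    fifty_tangential: 25 scattered tangential dipoles per hemisphere.
    cortical_grid: one patch per grid vertex (seed vertex + 1-ring
    neighbours, dipoles along the local surface normals, total moment
    100 nAm split equally).

    Every recording draws its background from a seed derived from
    (spec.seed, item index), so the output is a pure function of the spec.
    """
    waveform = make_burst_waveform(spec.burst, spec.fs, spec.duration)
    root = np.random.SeedSequence(spec.seed)

    def background(stream: int) -> Recording:
        child_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        # spawn() advances deterministically; stream index kept for the record
        bg = synth_background(geometry.array, spec.fs, spec.duration, child_seed)
        bg.annotations["stream"] = stream
        return bg

    if spec.scenario == "montage_locations":
        for i, loc in enumerate(geometry.sources.locations):
            direction = loc.tangential_direction()
            dip = DipoleSource(loc.position, direction, label=loc.label)
            rec = simulate_recording(dip, waveform, background(i), geometry.sphere, spec.band)
            truth = {
                "label": loc.label,
                "position_m": loc.position.tolist(),
                "orientation": direction.tolist(),
                "amplitude_Am": spec.burst.amplitude,
            }
            rec.annotations["truth"] = truth
            yield rec, truth

    elif spec.scenario == "fifty_tangential":
        rng = np.random.default_rng(root.spawn(1)[0])
        for i, dip in enumerate(_scatter_tangential_dipoles(geometry.sphere, rng)):
            rec = simulate_recording(dip, waveform, background(i), geometry.sphere, spec.band)
            truth = {
                "label": dip.label,
                "position_m": dip.position.tolist(),
                "orientation": dip.moment.tolist(),
                "amplitude_Am": spec.burst.amplitude,
            }
            rec.annotations["truth"] = truth
            yield rec, truth

    elif spec.scenario == "cortical_grid":
        if not geometry.grids:
            raise ValueError("geometry bundle holds no cortical grids")
        item = 0
        for grid in geometry.grids:
            for v in range(len(grid)):
                members = grid.patch(v)
                w = 1.0 / len(members)
                dipoles = [
                    DipoleSource(grid.vertices[m], w * grid.normals[m]) for m in members
                ]
                rec = simulate_recording(
                    dipoles, waveform, background(item), geometry.sphere, spec.band
                )
                truth = {
                    "label": f"{grid.hemisphere}:{v}",
                    "hemisphere": grid.hemisphere,
                    "vertex": v,
                    "position_m": grid.vertices[v].tolist(),
                    "patch_size": len(members),
                    "amplitude_Am": spec.burst.amplitude,
                }
                rec.annotations["truth"] = truth
                yield rec, truth
                item += 1
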