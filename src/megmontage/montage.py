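"""Regularized, noise-whitened, depth-weighted source-montage operators.

Given a lead field L, a per-channel noise model and a regularization
fraction lambda, the montage is the stored linear map

    s_hat = Ws^-1 (Ln' Ln + lambda I)^-1 Ln' Wb b,     Ln = Wb L Ws^-1,

where Wb whitens the channels (1/sigma_i in the diagonal case), Ws holds
the column norms of Wb L (depth weighting), and the Gram matrix
G = Ln' Ln has unit diagonal, so lambda is directly a percentage of the
per-component signal power.  Applying the operator to raw channel data
yields physical source amplitudes in A·m.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .geometry import SensorArray
from .forward import LeadField

__all__ = [
    "NoiseModel",
    "MontageOperator",
    "SourceWaveforms",
    "OrientationEstimate",
    "build_whitener",
    "build_montage",
    "apply_montage",
    "rms_mode",
    "principal_mode",
    "condition_number",
]


@dataclass
class NoiseModel:
    """Per-channel noise description: diagonal (per-channel SDs, in channel
    units) or a full M x M covariance."""

    kind: str = "diagonal"
    sds: np.ndarray | None = None
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "diagonal":
            if self.sds is None:
                raise ValueError("diagonal noise model requires per-channel sds")
            self.sds = np.asarray(self.sds, dtype=float)
            if np.any(self.sds <= 0):
                raise ValueError("noise SDs must be strictly positive")
        elif self.kind == "full":
            if self.covariance is None:
                raise ValueError("full noise model requires a covariance matrix")
            self.covariance = np.asarray(self.covariance, dtype=float)
            C = self.covariance
            if C.ndim != 2 or C.shape[0] != C.shape[1]:
                raise ValueError("covariance must be square")
            if not np.allclose(C, C.T, rtol=1e-10, atol=0):
                raise ValueError("covariance must be symmetric")
        else:
            raise ValueError(f"unknown noise model kind {self.kind!r}")

    @classmethod
    def from_array(cls, array: SensorArray) -> "NoiseModel":
        """Diagonal model from the per-channel noise SDs of the array
        (defaults: 200 fT magnetometers, 50 fT/cm gradiometers)."""
        return cls(kind="diagonal", sds=array.noise_sds)

    @property
    def n_channels(self) -> int:
        return len(self.sds) if self.kind == "diagonal" else self.covariance.shape[0]


def build_whitener(noise: NoiseModel) -> np.ndarray:
    """Whitening operator Wb.

    Diagonal case: the vector (1/sigma_1, ..., 1/sigma_M), to be applied
    elementwise.  Full case: the symmetric inverse matrix square root of
    the covariance, satisfying Wb C Wb' = I.
    """
    if noise.kind == "diagonal":
        return 1.0 / noise.sds
    vals, vecs = np.linalg.eigh(noise.covariance)
    if np.any(vals <= 0):
        raise ValueError("noise covariance is not positive definite")
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def _whiten(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    if W.ndim == 1:
        return W[:, None] * X if X.ndim == 2 else W * X
    return W @ X


@dataclass
class MontageOperator:
    """Stored P x M spatial filter mapping raw channel data to source
    amplitudes (A·m), with its regularization and normalization state."""

    transform: np.ndarray
    lambda_frac: float
    whitener: np.ndarray
    depth_weights: np.ndarray
    gram: np.ndarray
    channel_order: list[str]
    component_order: list[tuple[str, str]]

    @property
    def n_components(self) -> int:
        return self.transform.shape[0]

    @property
    def n_channels(self) -> int:
        return self.transform.shape[1]

    @property
    def location_labels(self) -> list[str]:
        seen: list[str] = []
        for lbl, _ in self.component_order:
            if lbl not in seen:
                seen.append(lbl)
        return seen

    def apply(self, recording) -> "SourceWaveforms":
        return apply_montage(self, recording)

    def save(self, path: str | Path) -> None:
        payload = {
            "lambda_frac": self.lambda_frac,
            "transform": self.transform.tolist(),
            "whitener": self.whitener.tolist(),
            "depth_weights": self.depth_weights.tolist(),
            "gram": self.gram.tolist(),
            "channel_order": self.channel_order,
            "component_order": [list(c) for c in self.component_order],
            "units": "A·m per channel unit",
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MontageOperator":
        d = json.loads(Path(path).read_text())
        return cls(
            transform=np.array(d["transform"]),
            lambda_frac=d["lambda_frac"],
            whitener=np.array(d["whitener"]),
            depth_weights=np.array(d["depth_weights"]),
            gram=np.array(d["gram"]),
            channel_order=list(d["channel_order"]),
            component_order=[tuple(c) for c in d["component_order"]],
        )


def build_montage(L: LeadField, noise: NoiseModel, lambda_frac: float) -> MontageOperator:
    """Build the regularized whitened depth-weighted montage operator.

    ``lambda_frac`` is the regularization fraction added to the
    unit-diagonal Gram matrix (2% -> 0.02).
    """
    if lambda_frac < 0:
        raise ValueError("lambda_frac must be non-negative")
    if noise.n_channels != L.n_channels:
        raise ValueError("noise model and lead field disagree on channel count")

    Wb = build_whitener(noise)
    WL = _whiten(Wb, L.matrix)
    ws = np.linalg.norm(WL, axis=0)
    dead = np.flatnonzero(ws == 0)
    if dead.size:
        names = [L.col_components[i] for i in dead]
        raise ValueError(f"magnetically silent source components: {names}")
    Ln = WL / ws
    G = Ln.T @ Ln + lambda_frac * np.eye(L.n_components)

    if lambda_frac == 0:
        cond = np.linalg.cond(G)
        if cond > 1e12:
            warnings.warn(
                f"unregularized Gram matrix is ill-conditioned (cond={cond:.2e})",
                RuntimeWarning,
            )
    # G is symmetric positive (semi-)definite; solve via Cholesky when possible
    try:
        cho = scipy.linalg.cho_factor(G)
        GinvLnT = scipy.linalg.cho_solve(cho, Ln.T)
    except np.linalg.LinAlgError:
        GinvLnT = scipy.linalg.solve(G, Ln.T, assume_a="sym")
    transform = (GinvLnT * (Wb if Wb.ndim == 1 else 1.0)) / ws[:, None]
    if Wb.ndim == 2:
        transform = transform @ Wb
    return MontageOperator(
        transform=transform,
        lambda_frac=float(lambda_frac),
        whitener=Wb,
        depth_weights=ws,
        gram=G,
        channel_order=list(L.row_channels),
        component_order=list(L.col_components),
    )


@dataclass
class SourceWaveforms:
    """Source-space time series: 2 components per location in ``components``
    mode, one trace per location in ``rms`` or ``principal`` mode."""

    data: np.ndarray
    fs: float
    labels: list
    mode: str = "components"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.labels):
            raise ValueError("row count does not match labels")
        if self.mode not in ("components", "rms", "principal"):
            raise ValueError(f"unknown display mode {self.mode!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def location_labels(self) -> list[str]:
        if self.mode == "components":
            seen: list[str] = []
            for lbl, _ in self.labels:
                if lbl not in seen:
                    seen.append(lbl)
            return seen
        return list(self.labels)


def apply_montage(op: MontageOperator, recording) -> SourceWaveforms:
    """Apply the stored spatial filter sample-by-sample to a recording.

    The recording's channel order must match the operator's; use
    :func:`megmontage.simulate.Recording.reorder` to align by name first.
    """
    if list(recording.array.names) != op.channel_order:
        raise ValueError(
            "recording channel order does not match the montage operator; "
            "align channels by name before applying"
        )
    return SourceWaveforms(
        data=op.transform @ recording.data,
        fs=recording.fs,
        labels=list(op.component_order),
        mode="components",
    )


def rms_mode(waveforms: SourceWaveforms) -> SourceWaveforms:
    """Per-location root mean square of the component amplitudes."""
    if waveforms.mode != "components":
        raise ValueError("rms_mode expects components-mode waveforms")
    P, T = waveforms.data.shape
    if P % 2:
        raise ValueError("components mode must hold an even number of rows")
    pairs = waveforms.data.reshape(P // 2, 2, T)
    return SourceWaveforms(
        data=np.sqrt(np.mean(pairs**2, axis=1)),
        fs=waveforms.fs,
        labels=waveforms.location_labels(),
        mode="rms",
    )


@dataclass
class OrientationEstimate:
    """Principal dipole orientation of one regional source over an analysis
    window: eigenpairs of the 2 x 2 component covariance, descending."""

    label: str
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    defined: bool = True

    @property
    def principal(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def angle(self) -> float:
        """Principal orientation angle (radians) in the (e_theta, e_phi)
        plane, folded to [0, pi)."""
        u = self.principal
        a = np.arctan2(u[1], u[0])
        return float(a % np.pi)


_DEGENERATE_RATIO = 1 + 1e-9


def principal_mode(
    waveforms: SourceWaveforms, window: slice | None = None
) -> tuple[SourceWaveforms, list[OrientationEstimate]]:
    """Project each location's component pair onto its principal
    orientation estimated over ``window`` (default: all samples).

    The 2 x 2 matrix S S' of the windowed component block S is
    eigendecomposed; the leading eigenvector is the best fixed dipole
    orientation for the window, and the output trace is the projection of
    the full-length component pair onto it.  Near-degenerate eigenvalues
    fall back to the eigenvector with the larger e_theta weight; the sign
    is fixed so the windowed peak of the projection is positive.
    """
    if waveforms.mode != "components":
        raise ValueError("principal_mode expects components-mode waveforms")
    window = window if window is not None else slice(None)
    P, T = waveforms.data.shape
    locations = waveforms.location_labels()
    out = np.empty((P // 2, T))
    estimates: list[OrientationEstimate] = []
    for j, label in enumerate(locations):
        S = waveforms.data[2 * j : 2 * j + 2]
        Sw = S[:, window]
        if Sw.shape[1] == 0:
            raise ValueError("analysis window is empty")
        M2 = Sw @ Sw.T
        vals, vecs = np.linalg.eigh(M2)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        if vals[0] <= 0:
            # silent window: orientation undefined, report a zero trace
            estimates.append(
                OrientationEstimate(
                    label=label,
                    eigenvalues=np.zeros(2),
                    eigenvectors=np.eye(2),
                    defined=False,
                )
            )
            out[j] = 0.0
            continue
        if vals[1] > 0 and vals[0] / vals[1] < _DEGENERATE_RATIO:
            # degenerate (rotating) source: prefer the e_theta-dominant axis
            pick = int(np.argmax(np.abs(vecs[0, :])))
            if pick != 0:
                vals = vals[::-1]
                vecs = vecs[:, ::-1]
        u = vecs[:, 0]
        proj_w = u @ Sw
        if proj_w[np.argmax(np.abs(proj_w))] < 0:
            u = -u
            vecs = vecs.copy()
            vecs[:, 0] = u
        out[j] = u @ S
        estimates.append(
            OrientationEstimate(label=label, eigenvalues=vals, eigenvectors=vecs)
        )
    return (
        SourceWaveforms(data=out, fs=waveforms.fs, labels=locations, mode="principal"),
        estimates,
    )


def condition_number(op: MontageOperator) -> float:
    """Ratio of the extreme eigenvalues of the regularized Gram matrix."""
    vals = np.linalg.eigvalsh(op.gram)
    return float(vals[-1] / vals[0])
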