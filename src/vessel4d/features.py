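"""Per-voxel image features for vessel classification in 4D CT.

The dynamic acquisition is collapsed into two exposure-weighted maps.  With
weights :math:`\\omega_i = E_i / \\sum_j E_j` derived from the per-time-point
exposures :math:`E_i` (quantum noise scales as :math:`1/\\sqrt{E}`, so
exposure weighting maximises signal-to-noise):

.. math::

   \\mathrm{WTA}_{xyz} = \\sum_i \\omega_i I_{xyz,i}, \\qquad
   \\mathrm{WTV}_{xyz} = \\sqrt{\\sum_i \\omega_i
        (\\mathrm{WTA}_{xyz} - I_{xyz,i})^2}.

The WTV is large only where attenuation changes over time, i.e. where
contrast agent passes — vessels — and is the carrier image for the local
histogram and Hessian features below.

The full 24-column feature vector per voxel is: WTA, WTV, the first time
point T0 (minimal-contrast tissue), the signed Euclidean distance to the
intracranial-cavity border (negative inside), four local-histogram
parameters (mean, standard deviation, mode, entropy) of the WTV in 5x5x5
and 9x9x9 neighbourhoods, and the three Hessian eigenvalues of the WTV at
scales 0.5, 1.0, 1.5 and 2.0 mm.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .io import AcquisitionProtocol, BinaryMask3D, Volume3D, Volume4D

__all__ = [
    "TemporalWeights",
    "FeatureMatrix",
    "compute_weights",
    "weighted_temporal_average",
    "weighted_temporal_variance",
    "local_histogram_params",
    "signed_cavity_distance",
    "hessian_eigenvalues",
    "extract_t0",
    "feature_column_names",
    "assemble_features",
    "assemble_features_at",
]


@dataclass
class TemporalWeights:
    """Exposure-proportional temporal weights, normalised to sum to 1."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 1 or self.omega.size == 0:
            raise ValueError("weights must be a nonempty 1D sequence")
        if np.any(self.omega < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.omega.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return int(self.omega.size)


def compute_weights(protocol: AcquisitionProtocol) -> TemporalWeights:
    """omega_i = E_i / sum(E), one weight per time point."""
    e = protocol.exposures
    return TemporalWeights(omega=e / e.sum())


def weighted_temporal_average(vol: Volume4D, w: TemporalWeights) -> Volume3D:
    if len(w) != vol.n_timepoints:
        raise ValueError(f"{len(w)} weights for {vol.n_timepoints} time points")
    wta = np.tensordot(vol.data.astype(np.float64), w.omega, axes=([3], [0]))
    return Volume3D(data=wta, spacing=vol.spacing)


def weighted_temporal_variance(
    vol: Volume4D, w: TemporalWeights, wta: Volume3D | None = None
) -> Volume3D:
    if len(w) != vol.n_timepoints:
        raise ValueError(f"{len(w)} weights for {vol.n_timepoints} time points")
    if wta is None:
        wta = weighted_temporal_average(vol, w)
    diff2 = (wta.data[..., None] - vol.data.astype(np.float64)) ** 2
    wtv = np.sqrt(np.tensordot(diff2, w.omega, axes=([3], [0])))
    return Volume3D(data=wtv, spacing=vol.spacing)


def extract_t0(vol: Volume4D) -> Volume3D:
    """The first time point: tissue with minimal contrast enhancement."""
    return Volume3D(data=vol.data[..., 0].copy(), spacing=vol.spacing)


# ---------------------------------------------------------------------------
# Local histogram features
# ---------------------------------------------------------------------------


def _patch_values(padded: np.ndarray, indices: np.ndarray, shape, edge: int) -> np.ndarray:
    """Gather the edge^3 neighbourhood of each linear index as rows.

    ``padded`` is the image replicate-padded by edge//2 on every side, so
    border neighbourhoods are well defined without shrinking the map.
    """
    r = edge // 2
    ix, iy, iz = np.unravel_index(indices, shape)
    off = np.arange(-r, r + 1)
    ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
    ox, oy, oz = ox.ravel(), oy.ravel(), oz.ravel()
    # padded coordinates: original index + r + offset
    return padded[
        (ix[:, None] + r + ox[None, :]),
        (iy[:, None] + r + oy[None, :]),
        (iz[:, None] + r + oz[None, :]),
    ]


def _histogram_stats(patches: np.ndarray, n_bins: int, eps: float) -> tuple[np.ndarray, ...]:
    """mean/std/mode/entropy per row of a (N, K) patch matrix.

    Bins span each neighbourhood's own [min, max] range (local-range
    binning); mean and std use the raw values, mode is the centre of the
    most populated bin (lowest bin wins ties) and entropy is
    ``-sum_i p_i log2(p_i + eps)``.  A flat neighbourhood degenerates to a
    single occupied bin: entropy -log2(1 + eps), mode = the constant value.
    """
    n, k = patches.shape
    mean = patches.mean(axis=1)
    std = patches.std(axis=1)
    lo = patches.min(axis=1)
    hi = patches.max(axis=1)
    span = hi - lo
    flat = span <= 0
    width = np.where(flat, 1.0, span) / n_bins

    bin_idx = np.floor((patches - lo[:, None]) / width[:, None]).astype(np.int64)
    np.clip(bin_idx, 0, n_bins - 1, out=bin_idx)
    counts = np.zeros((n, n_bins), dtype=np.int64)
    rows = np.repeat(np.arange(n), k)
    np.add.at(counts, (rows, bin_idx.ravel()), 1)

    p = counts / float(k)
    entropy = -(p * np.log2(p + eps)).sum(axis=1)
    mode_bin = counts.argmax(axis=1)  # argmax takes the lowest index on ties
    mode = lo + (mode_bin + 0.5) * width
    mode = np.where(flat, lo, mode)
    return mean, std, mode, entropy


def _histogram_stats_at(
    data: np.ndarray,
    indices: np.ndarray,
    edge: int,
    n_bins: int,
    eps: float,
    chunk: int = 4096,
) -> tuple[np.ndarray, ...]:
    if edge % 2 == 0:
        raise ValueError(f"neighbourhood edge must be odd, got {edge}")
    if any(edge > s for s in data.shape):
        raise ValueError(f"neighbourhood {edge}^3 larger than grid {data.shape}")
    r = edge // 2
    padded = np.pad(data.astype(np.float64), r, mode="edge")
    outs = [np.empty(indices.size) for _ in range(4)]
    for start in range(0, indices.size, chunk):
        sel = indices[start : start + chunk]
        patches = _patch_values(padded, sel, data.shape, edge)
        for out, vals in zip(outs, _histogram_stats(patches, n_bins, eps)):
            out[start : start + chunk] = vals
    return tuple(outs)


def local_histogram_params(
    wtv: Volume3D, neighborhood_edge: int, n_bins: int = 32, eps: float = 1e-4
) -> tuple[Volume3D, Volume3D, Volume3D, Volume3D]:
    """Mean, std, mode and entropy maps of the local WTV histogram.

    Computed for every voxel; for feature assembly restricted to candidate
    voxels use :func:`assemble_features`, which only evaluates where needed.
    """
    indices = np.arange(wtv.data.size)
    mean, std, mode, entropy = _histogram_stats_at(wtv.data, indices, neighborhood_edge, n_bins, eps)
    return tuple(
        Volume3D(data=a.reshape(wtv.data.shape), spacing=wtv.spacing)
        for a in (mean, std, mode, entropy)
    )


# ---------------------------------------------------------------------------
# Distance and Hessian features
# ---------------------------------------------------------------------------


def signed_cavity_distance(cavity: BinaryMask3D) -> Volume3D:
    """Signed Euclidean distance (mm) to the intracranial-cavity border.

    Negative inside the mask, positive outside, zero on border voxels
    (foreground voxels with at least one background 6-neighbour).  The
    internal carotid arteries and jugular veins lie outside the cavity, so
    a graded distance rather than a binary inside/outside flag lets the
    classifier keep them.
    """
    m = cavity.data
    if not m.any():
        raise ValueError("cavity mask is empty: border undefined")
    if m.all():
        raise ValueError("cavity mask covers the whole grid: border undefined")
    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1))
    border = m & ~eroded
    dist = ndimage.distance_transform_edt(~border, sampling=cavity.spacing)
    signed = np.where(m, -dist, dist)
    return Volume3D(data=signed, spacing=cavity.spacing)


def hessian_eigenvalues(
    wtv: Volume3D, scales_mm: Sequence[float] = (0.5, 1.0, 1.5, 2.0)
) -> list[Volume3D]:
    """Scale-normalised Hessian eigenvalues of the WTV at each scale.

    For each scale sigma (mm) the Hessian is built from Gaussian
    derivatives with per-axis sigma expressed in voxels (sigma / spacing),
    multiplied by sigma^2 (gamma-normalisation with gamma = 1), and
    eigen-decomposed per voxel.  Eigenvalues are returned sorted by
    ascending absolute value — the convention of tubular-structure filters,
    where a bright tube shows |lambda_1| ~ 0 and lambda_2, lambda_3 < 0.

    Returns ``3 * len(scales_mm)`` maps, scale-major.
    """
    data = wtv.data.astype(np.float64)
    spacing = np.asarray(wtv.spacing)
    maps: list[Volume3D] = []
    for sigma_mm in scales_mm:
        if sigma_mm <= 0:
            raise ValueError("Hessian scale must be positive")
        if sigma_mm < 0.5 * spacing.min():
            warnings.warn(
                f"Hessian scale {sigma_mm} mm is below half the smallest voxel "
                f"spacing {spacing.min()} mm; derivatives will be noise-dominated",
                stacklevel=2,
            )
        sigma_vox = sigma_mm / spacing
        h = np.empty(data.shape + (3, 3))
        for a in range(3):
            for b in range(a, 3):
                order = [0, 0, 0]
                order[a] += 1
                order[b] += 1
                # derivatives w.r.t. physical mm: ndimage differentiates per
                # voxel step, so divide by the step sizes
                # truncate=6 keeps the kernel's residual (nonzero sum of the
                # derivative taps) negligible on near-constant regions
                d = ndimage.gaussian_filter(data, sigma=sigma_vox, order=order, truncate=6.0)
                d /= spacing[a] * spacing[b]
                h[..., a, b] = d
                h[..., b, a] = d
        h *= sigma_mm**2
        eigs = np.linalg.eigvalsh(h.reshape(-1, 3, 3)).reshape(data.shape + (3,))
        order_abs = np.argsort(np.abs(eigs), axis=-1)
        eigs = np.take_along_axis(eigs, order_abs, axis=-1)
        for j in range(3):
            maps.append(Volume3D(data=eigs[..., j].copy(), spacing=wtv.spacing))
    return maps


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------


def feature_column_names(config: PipelineConfig | None = None) -> list[str]:
    config = config or PipelineConfig()
    names = ["wta", "wtv", "t0", "cavity_distance_mm"]
    for edge in config.histogram_neighborhoods:
        for p in ("mean", "std", "mode", "entropy"):
            names.append(f"hist{edge}_{p}")
    for s in config.hessian_scales_mm:
        for j in (1, 2, 3):
            names.append(f"hessian_{s:g}mm_l{j}")
    return names


@dataclass
class FeatureMatrix:
    """Per-voxel feature vectors keyed by linear index into the 3D grid."""

    indices: np.ndarray  # (N,) linear voxel indices (C order)
    values: np.ndarray  # (N, n_features)
    columns: list[str]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.indices.size, len(self.columns)):
            raise ValueError("values shape must be (len(indices), len(columns))")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    @property
    def manifest_hash(self) -> str:
        return hashlib.sha256("|".join(self.columns).encode()).hexdigest()[:16]

    def rows_for(self, indices: np.ndarray) -> np.ndarray:
        """Rows for the requested linear voxel indices (KeyError if absent)."""
        lookup = {int(ix): r for r, ix in enumerate(self.indices)}
        try:
            rows = [lookup[int(ix)] for ix in indices]
        except KeyError as exc:
            raise KeyError(f"voxel index {exc} has no feature row") from exc
        return self.values[rows]

    def save_csv(self, path) -> None:
        header = "index," + ",".join(self.columns)
        table = np.column_stack([self.indices.astype(float), self.values])
        np.savetxt(path, table, delimiter=",", header=header, comments="")

    @classmethod
    def load_csv(cls, path, shape) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(
            indices=table[:, 0].astype(np.int64),
            values=table[:, 1:],
            columns=header[1:],
            shape=tuple(shape),
        )


def assemble_features_at(
    vol: Volume4D,
    cavity: BinaryMask3D,
    indices: np.ndarray,
    config: PipelineConfig | None = None,
    *,
    wtv: Volume3D | None = None,
    wta: Volume3D | None = None,
) -> FeatureMatrix:
    """Feature matrix for an explicit set of linear voxel indices.

    Precomputed WTA/WTV maps may be passed to avoid recomputation when the
    caller already derived them (e.g. for candidate selection).
    """
    config = config or PipelineConfig()
    if cavity.shape != vol.spatial_shape:
        raise ValueError("cavity mask grid does not match the volume")
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size == 0:
        raise ValueError("empty voxel index set: nothing to featurise")

    exposures = vol.exposures if config.exposures is None else np.asarray(config.exposures)
    w = compute_weights(AcquisitionProtocol(exposures=exposures))
    if wta is None:
        wta = weighted_temporal_average(vol, w)
    if wtv is None:
        wtv = weighted_temporal_variance(vol, w, wta=wta)
    t0 = extract_t0(vol)
    dist = signed_cavity_distance(cavity)

    cols = [
        wta.data.ravel()[indices],
        wtv.data.ravel()[indices],
        t0.data.ravel()[indices].astype(np.float64),
        dist.data.ravel()[indices],
    ]
    for edge in config.histogram_neighborhoods:
        stats = _histogram_stats_at(
            wtv.data, indices, edge, config.histogram_bins, config.histogram_epsilon
        )
        cols.extend(stats)
    for m in hessian_eigenvalues(wtv, config.hessian_scales_mm):
        cols.append(m.data.ravel()[indices])

    return FeatureMatrix(
        indices=indices,
        values=np.column_stack(cols),
        columns=feature_column_names(config),
        shape=vol.spatial_shape,
    )


def assemble_features(
    vol: Volume4D,
    cavity: BinaryMask3D,
    candidates: BinaryMask3D,
    config: PipelineConfig | None = None,
    **precomputed,
) -> FeatureMatrix:
    """One feature row per candidate voxel, in fixed column order."""
    if candidates.shape != vol.spatial_shape:
        raise ValueError("candidate mask grid does not match the volume")
    indices = np.flatnonzero(candidates.data.ravel())
    if indices.size == 0:
        raise ValueError("empty candidate mask: nothing to featurise")
    return assemble_features_at(vol, cavity, indices, config, **precomputed)
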