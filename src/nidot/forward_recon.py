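"""Analytic optical forward model, Tikhonov reconstruction, ROI aggregation.

The fluence model is the continuous-wave diffusion approximation for a
semi-infinite homogeneous medium with an extrapolated boundary: sources sit
one transport mean free path below the surface and each has a negative image
source above the extrapolated boundary. Channel sensitivities to nodal
absorption changes follow the Rytov/adjoint product-of-Green's-functions
form. This replaces finite-element fluence modeling on a layered infant head
mesh with a desk-scale model sharing the same algebraic interfaces.

Coordinates: the scalp is the z = 0 plane, z > 0 points into the head
(depth, mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import optics
from .containers import ChannelTimeseries, ProbeLayout

DEFAULT_LAMBDA = 0.01
DEFAULT_SEP_RANGE_MM = (12.0, 45.0)

#: The six frontal regions of interest.
ROI_NAMES = ("L_mPFC", "R_mPFC", "L_mSFG", "R_mSFG", "L_midPFC", "R_midPFC")


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous optical properties (mm^-1) and refractive index."""

    mua: float = 0.017
    musp: float = 0.74
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.musp <= 0:
            raise ValueError("mua and musp must be positive")

    @property
    def diffusion(self) -> float:
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def mu_eff(self) -> float:
        return float(np.sqrt(3.0 * self.mua * (self.mua + self.musp)))

    @property
    def z0(self) -> float:
        """Effective isotropic source depth: one transport mean free path."""
        return 1.0 / (self.mua + self.musp)

    @property
    def zb(self) -> float:
        """Extrapolated-boundary distance above the surface."""
        n = self.refractive_index
        r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
        return 2.0 * self.diffusion * (1.0 + r_eff) / (1.0 - r_eff)


@dataclass
class SensitivityMatrix:
    """Channel x node Jacobian (OD per unit absorption change per node)."""

    J: np.ndarray
    node_positions: np.ndarray
    pair_table: pd.DataFrame
    medium: OpticalMedium
    node_volume_mm3: float = 1.0


@dataclass
class ROIDefinition:
    name: str
    node_mask: np.ndarray
    channel_weights: np.ndarray  # aligned with the sensitivity pair table
    admitted: np.ndarray  # bool, separation window
    pair_weights: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.channel_weights
        if np.any(w < 0):
            raise ValueError("ROI channel weights must be non-negative")
        if w.sum() > 0 and not np.isclose(w.sum(), 1.0):
            raise ValueError("ROI channel weights must sum to 1")


@dataclass
class ImageResult:
    """Node-wise images with the reconstruction's provenance."""

    hbo: np.ndarray | None
    hbr: np.ndarray | None
    mua_images: dict[float, np.ndarray] = field(default_factory=dict)
    lam: float = DEFAULT_LAMBDA
    scaling: str = "lambda * max diag(J J^T)"


def _green(r: np.ndarray, medium: OpticalMedium) -> np.ndarray:
    r = np.maximum(r, 1e-6)
    return np.exp(-medium.mu_eff * r) / (4.0 * np.pi * medium.diffusion * r)


def _fluence(points: np.ndarray, origin_xy: np.ndarray, medium: OpticalMedium) -> np.ndarray:
    """Semi-infinite fluence from a surface optode at ``origin_xy`` (z = 0).

    Real source at depth z0, negative image at -(z0 + 2 zb).
    """
    src = np.array([origin_xy[0], origin_xy[1], medium.z0])
    img = np.array([origin_xy[0], origin_xy[1], -(medium.z0 + 2.0 * medium.zb)])
    r1 = np.linalg.norm(points - src, axis=-1)
    r2 = np.linalg.norm(points - img, axis=-1)
    return _green(r1, medium) - _green(r2, medium)


def compute_sensitivity(
    probe: ProbeLayout,
    medium: OpticalMedium | None = None,
    nodes: np.ndarray | None = None,
    node_volume_mm3: float = 1.0,
) -> SensitivityMatrix:
    """Rytov sensitivity of each source-detector pair to nodal absorption.

    J[c, n] = Phi(source -> node) * Phi(node -> detector) / Phi(source ->
    detector) * node volume. Nodes must lie strictly below the surface
    (z > 0). One matrix serves both wavelengths: the default medium is not
    wavelength-resolved.
    """
    medium = medium or OpticalMedium()
    if nodes is None:
        nodes = default_node_grid(probe)
    nodes = np.asarray(nodes, dtype=float)
    if np.any(nodes[:, 2] <= 0):
        raise ValueError("all nodes must lie below the scalp surface (z > 0)")
    pairs = probe.pair_table()
    J = np.empty((len(pairs), len(nodes)))
    det_surface = np.column_stack(
        [probe.detectors[:, 0], probe.detectors[:, 1], np.zeros(len(probe.detectors))]
    )
    for i, row in enumerate(pairs.itertuples(index=False)):
        s_xy = probe.sources[int(row.source), :2]
        d_xy = probe.detectors[int(row.detector), :2]
        phi_s = _fluence(nodes, s_xy, medium)
        phi_d = _fluence(nodes, d_xy, medium)
        phi_sd = _fluence(det_surface[int(row.detector)][None, :], s_xy, medium)[0]
        J[i] = phi_s * phi_d / phi_sd * node_volume_mm3
    return SensitivityMatrix(J=J, node_positions=nodes, pair_table=pairs, medium=medium, node_volume_mm3=node_volume_mm3)


def default_node_grid(
    probe: ProbeLayout,
    spacing_mm: float = 6.0,
    depth_range_mm: tuple[float, float] = (8.0, 26.0),
    margin_mm: float = 10.0,
) -> np.ndarray:
    """Regular node grid under the probe patch (toy cortex)."""
    xy = np.vstack([probe.sources[:, :2], probe.detectors[:, :2]])
    x = np.arange(xy[:, 0].min() - margin_mm, xy[:, 0].max() + margin_mm + 1e-9, spacing_mm)
    y = np.arange(xy[:, 1].min() - margin_mm, xy[:, 1].max() + margin_mm + 1e-9, spacing_mm)
    z = np.arange(depth_range_mm[0], depth_range_mm[1] + 1e-9, spacing_mm)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def tikhonov_reconstruct(J: np.ndarray, y: np.ndarray, lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Zeroth-order Tikhonov inverse: x = J^T (J J^T + lam*s*I)^-1 y.

    ``s`` is the largest diagonal entry of J J^T (scaling convention recorded
    in :class:`ImageResult`). ``y`` may be a vector or (channels, k) matrix.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    J = np.asarray(J, dtype=float)
    if not np.any(J):
        raise ValueError("sensitivity matrix is all zero")
    y = np.asarray(y, dtype=float)
    JJt = J @ J.T
    s = float(np.max(np.diag(JJt)))
    x = J.T @ np.linalg.solve(JJt + lam * s * np.eye(JJt.shape[0]), y)
    return x


def reconstruct_hb(
    sens: SensitivityMatrix,
    od_by_wavelength: dict[float, np.ndarray],
    lam: float = DEFAULT_LAMBDA,
    extinction: np.ndarray | None = None,
) -> ImageResult:
    """Reconstruct per-wavelength absorption images and unmix to HbO/HbR.

    ``od_by_wavelength`` maps wavelength (nm) to a channel OD vector aligned
    with the sensitivity pair table. Node-wise unmixing solves
    dmu_a(lambda) = E[lambda] . (dHbO, dHbR).
    """
    wavelengths = tuple(sorted(od_by_wavelength))
    if len(wavelengths) != 2:
        raise ValueError("reconstruction requires exactly two wavelengths")
    E = optics.extinction_matrix(wavelengths) if extinction is None else np.asarray(extinction)
    mua_imgs = {wl: tikhonov_reconstruct(sens.J, od_by_wavelength[wl], lam=lam) for wl in wavelengths}
    stacked = np.vstack([mua_imgs[wl] for wl in wavelengths])
    hb = np.linalg.solve(E, stacked)
    return ImageResult(hbo=hb[0], hbr=hb[1], mua_images=mua_imgs, lam=lam)


def default_rois(sens: SensitivityMatrix, radius_mm: float = 14.0) -> dict[str, np.ndarray]:
    """Six disk-shaped ROI node masks on the toy cortex.

    Disks at fixed positions stand in for atlas parcels: medial prefrontal
    (mPFC) near the patch midline low on the cap, medial superior frontal
    (mSFG) at the midline top, middle prefrontal lateral on each side.
    """
    nodes = sens.node_positions
    xy = nodes[:, :2]
    x_mid = 0.5 * (xy[:, 0].min() + xy[:, 0].max())
    y_lo = xy[:, 1].min() + (xy[:, 1].max() - xy[:, 1].min()) * 0.25
    y_hi = xy[:, 1].min() + (xy[:, 1].max() - xy[:, 1].min()) * 0.75
    dx = (xy[:, 0].max() - xy[:, 0].min()) * 0.28
    centers = {
        "L_mPFC": (x_mid - 0.35 * dx, y_lo),
        "R_mPFC": (x_mid + 0.35 * dx, y_lo),
        "L_mSFG": (x_mid - 0.35 * dx, y_hi),
        "R_mSFG": (x_mid + 0.35 * dx, y_hi),
        "L_midPFC": (x_mid - 1.5 * dx, 0.5 * (y_lo + y_hi)),
        "R_midPFC": (x_mid + 1.5 * dx, 0.5 * (y_lo + y_hi)),
    }
    return {
        name: np.linalg.norm(xy - np.asarray(c), axis=1) <= radius_mm
        for name, c in centers.items()
    }


def roi_weights(
    sens: SensitivityMatrix,
    roi_mask: np.ndarray,
    sep_range_mm: tuple[float, float] = DEFAULT_SEP_RANGE_MM,
    name: str = "ROI",
) -> ROIDefinition:
    """Sensitivity-weighted channel weights for one ROI.

    Channels admitted by the separation window (default 12-45 mm) receive
    weight proportional to their total |J| over the ROI's nodes, normalized
    to sum 1; channels with zero ROI sensitivity get weight 0.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    dist = sens.pair_table["distance_mm"].to_numpy()
    admitted = (dist >= sep_range_mm[0]) & (dist <= sep_range_mm[1])
    raw = np.abs(sens.J[:, roi_mask]).sum(axis=1)
    raw = np.where(admitted, raw, 0.0)
    total = raw.sum()
    if total == 0:
        raise ValueError(f"ROI {name!r} has zero total sensitivity over admitted channels")
    w = raw / total
    pairs = {
        (int(s), int(d)): float(wi)
        for s, d, wi in zip(sens.pair_table["source"], sens.pair_table["detector"], w)
    }
    return ROIDefinition(name=name, node_mask=roi_mask, channel_weights=w, admitted=admitted, pair_weights=pairs)


def roi_timeseries(ts: ChannelTimeseries, rois: list[ROIDefinition]) -> pd.DataFrame:
    """Weighted-average ROI series per chromophore from hemoglobin channels.

    Returns a long-ish frame indexed by (roi, chromophore) with a ``series``
    column of arrays. Channels with missing data are renormalized out; an
    ROI whose channels are all missing yields a missing series with a
    warning.
    """
    import warnings as _warnings

    if ts.kind != "hb":
        raise ValueError("roi_timeseries expects hemoglobin data")
    tbl = ts.channels.reset_index(drop=True)
    pair_key = list(zip(tbl["source"].astype(int), tbl["detector"].astype(int)))
    rows = []
    for roi in rois:
        pairs = roi.pair_weights
        for chrom in ("HbO", "HbR"):
            sel = [i for i, c in enumerate(tbl["chromophore"]) if c == chrom]
            w = np.array([pairs.get(pair_key[i], 0.0) for i in sel])
            X = ts.data[sel]
            ok = w > 0
            ok &= ~np.isnan(X).any(axis=1)
            if not ok.any() or w[ok].sum() == 0:
                _warnings.warn(f"ROI {roi.name}/{chrom}: all contributing channels missing")
                series = np.full(ts.n_times, np.nan)
            else:
                wn = w[ok] / w[ok].sum()
                series = wn @ X[ok]
            rows.append({"roi": roi.name, "chromophore": chrom, "series": series})
    return pd.DataFrame(rows)
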