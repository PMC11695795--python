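"""X-ray CT pore-space analysis around a penetrometer imprint.

Works on 3D voxel volumes (first index = depth, increasing downwards) of a
cylindrical soil subsample.  The cone imprint — the void left by the
penetrometer — is isolated from the granular pore background by a
scale/median-filter/watershed procedure, and the soil deformation around it
is quantified as radial profiles of visible porosity ``eps_vis`` (the pore
fraction detectable at the scan resolution) and relative compactness change

    delta_c(d) = 1 - eps_vis'(d) / eps_vis_ref,

where ``eps_vis_ref`` is the visible porosity of unpenetrated reference
samples.  The drop in visible porosity also yields estimates of local total
porosity and bulk density:

    eps'  = (1 - rho_b/rho_p) - (eps_vis_ref - eps_vis')
    rho_b' = (1 - eps') rho_p.

Connectivity conventions: 26-neighbourhood for pore-cluster labelling,
6-neighbourhood (radius-1 cross) structuring element for erosion/dilation.
Radial shells use the city-block distance transform, which is exactly the
result of iterating the cross-shaped dilation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from skimage.measure import block_reduce
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

__all__ = [
    "VoxelVolume",
    "ImprintResult",
    "RadialProfile",
    "StructuralEstimates",
    "segment_pores",
    "exclude_rim",
    "label_pores",
    "isolate_imprint",
    "region_masks",
    "pore_metrics",
    "radial_porosity_profile",
    "compactness",
    "structural_estimates",
    "fit_compaction_decay",
    "REFERENCE_DOMAIN_MM3",
]

_CROSS = ndi.generate_binary_structure(3, 1)
_FULL = np.ones((3, 3, 3), dtype=bool)

#: In-cylinder analysis volume of a full-size scan: 18 mm inner diameter
#: minus the 0.6 mm rim, 24 mm scanned height (mm^3).  Region volumes for
#: reduced-size volumes are scaled by the ratio of the actual domain volume
#: to this reference.
REFERENCE_DOMAIN_MM3 = float(np.pi * 8.4**2 * 24.0)


@dataclass
class VoxelVolume:
    """A 3D scan or phantom with physical voxel size.

    ``values`` is a (depth, y, x) array, either greyscale or binary
    (pore=1 / matrix=0); ``voxel_edge_um`` the voxel edge length in
    micrometres; ``domain_mask`` marks in-cylinder voxels (``None`` means an
    inscribed cylinder spanning the grid).
    """

    values: np.ndarray
    voxel_edge_um: float
    domain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.voxel_edge_um <= 0:
            raise ValueError("voxel_edge_um must be positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D (depth, y, x) array")

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_edge_um / 1000.0) ** 3

    @property
    def is_binary(self) -> bool:
        return self.values.dtype == bool or set(np.unique(self.values)) <= {0, 1}

    def domain(self) -> np.ndarray:
        """Boolean in-cylinder mask (inscribed cylinder if none was set)."""
        if self.domain_mask is not None:
            return self.domain_mask
        return cylinder_mask(self.values.shape, self.values.shape[1] / 2.0 - 0.5)

    def binary(self) -> np.ndarray:
        """Pore mask restricted to the domain."""
        if not self.is_binary:
            raise ValueError("volume is not binary; segment it first")
        return (self.values.astype(bool)) & self.domain()


def cylinder_mask(shape: tuple[int, int, int], radius_vox: float) -> np.ndarray:
    """Axis-aligned cylindrical mask centred in the (y, x) plane."""
    _, ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    return np.broadcast_to(r2 <= radius_vox**2, shape).copy()


@dataclass
class ImprintResult:
    """Isolated cone imprint and the remaining pore space."""

    imprint_mask: np.ndarray
    imprint_volume_mm3: float
    residual_pores: np.ndarray


@dataclass
class RadialProfile:
    """Visible porosity as a function of distance from the imprint surface.

    ``distance_um`` holds the outer edge of each contiguous shell (shell
    width = ``step_voxels`` * voxel edge, 60 um at the native 12 um
    resolution); ``midpoint_um`` the shell midpoints used for decay fits.
    """

    distance_um: np.ndarray
    eps_vis: np.ndarray
    shell_voxels: np.ndarray
    delta_c: np.ndarray | None = None

    @property
    def midpoint_um(self) -> np.ndarray:
        width = self.distance_um[0]
        return self.distance_um - width / 2.0


@dataclass
class StructuralEstimates:
    """Porosity / bulk-density estimates derived from visible porosity."""

    eps_vis_prime: np.ndarray
    eps_vis_ref: float
    eps: float
    delta_eps_vis: np.ndarray
    eps_prime: np.ndarray
    rho_b: float
    rho_b_prime: np.ndarray
    rho_p: float


def segment_pores(
    vol: VoxelVolume, threshold: float, polarity: str = "dark"
) -> VoxelVolume:
    """Binarize a greyscale volume with one global threshold.

    ``polarity='dark'`` maps voxels strictly below the threshold to pore
    (air is dark in absorption CT); ``'bright'`` maps voxels >= threshold
    to pore.  An all-pore or all-matrix result triggers a warning.
    """
    if polarity == "dark":
        binary = vol.values < threshold
    elif polarity == "bright":
        binary = vol.values >= threshold
    else:
        raise ValueError("polarity must be 'dark' or 'bright'")
    dom = vol.domain()
    inside = binary[dom]
    if inside.all() or not inside.any():
        warnings.warn(
            "segmentation produced an all-pore or all-matrix volume",
            UserWarning,
            stacklevel=2,
        )
    return VoxelVolume(binary, vol.voxel_edge_um, vol.domain_mask)


def exclude_rim(vol: VoxelVolume, rim_mm: float = 0.6) -> VoxelVolume:
    """Shrink the cylindrical domain radially by ``rim_mm`` (sampling rim).

    The rim is converted to voxels by rounding ``rim_mm / voxel_edge`` to
    the nearest integer (0.6 mm = 50 voxels at 12 um).
    """
    if rim_mm < 0:
        raise ValueError("rim must be non-negative")
    rim_vox = int(round(rim_mm * 1000.0 / vol.voxel_edge_um))
    base_radius = vol.values.shape[1] / 2.0 - 0.5
    new_radius = base_radius - rim_vox
    if new_radius <= 0:
        raise ValueError("rim larger than the sample radius")
    mask = cylinder_mask(vol.values.shape, new_radius)
    if vol.domain_mask is not None:
        mask &= vol.domain_mask
    return VoxelVolume(vol.values, vol.voxel_edge_um, mask)


def label_pores(binary: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Connected-component labelling of a binary pore volume."""
    if connectivity == 26:
        structure = _FULL
    elif connectivity == 6:
        structure = _CROSS
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndi.label(binary, structure=structure)
    return labels, n


def _binary_median(binary: np.ndarray, size: int = 5) -> np.ndarray:
    # Median of a binary neighbourhood == strict majority vote; a box-mean
    # threshold computes it exactly and far faster than a rank filter.
    counts = ndi.uniform_filter(binary.astype(np.float32), size=size, mode="constant")
    return counts > 0.5


def _split_largest(binary: np.ndarray, h: float = 2.0) -> np.ndarray:
    """Watershed-split a pore cluster and keep its largest piece.

    Markers are the h-maxima (h in voxels) of the Euclidean distance map;
    the watershed partitions the cluster, necks land on basin boundaries,
    and the largest basin (lowest label on ties) is smoothed by two
    iterations of cross-erosion then cross-dilation restricted to the
    original pore space, which restores its boundary without re-annexing
    the severed neighbours.
    """
    dist = ndi.distance_transform_edt(binary)
    peaks = h_maxima(dist, h)
    markers, n_markers = ndi.label(peaks, structure=_FULL)
    if n_markers == 0:
        markers, n_markers = ndi.label(binary, structure=_FULL)
    ws = watershed(-dist, markers, mask=binary)
    sizes = np.bincount(ws.ravel())
    sizes[0] = 0
    mask = ws == int(sizes.argmax())
    eroded = ndi.binary_erosion(mask, structure=_CROSS, iterations=2)
    if not eroded.any():  # cluster thinner than the opening: keep as is
        return mask
    return ndi.binary_dilation(eroded, structure=_CROSS, iterations=2, mask=binary)


def _upscale2(mask: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    up = mask
    for ax in range(3):
        up = np.repeat(up, 2, axis=ax)
    out = np.zeros(shape, dtype=bool)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(shape, up.shape))
    out[sl] = up[sl]
    return out


def _bbox(mask: np.ndarray, pad: int) -> tuple[slice, slice, slice]:
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(i.min()) - pad, 0), min(int(i.max()) + pad + 1, n))
        for i, n in zip(idx, mask.shape)
    )


def isolate_imprint(vol: VoxelVolume) -> ImprintResult:
    """Isolate the cone imprint from the binary pore space.

    Procedure: (1) downscale by factor 0.5 (block majority); (2) 3D binary
    median filter (5-voxel kernel, removing pores below ~5 downscaled
    voxels across); (3) distance-transform watershed split; (4) two
    iterations of erosion then dilation (volume-preserving pairing);
    (5) connected-component labelling, largest cluster by voxel count
    (lowest label on ties); (6) upscale to the original grid; (7) one more
    watershed + erosion/dilation pass at full resolution to detach residual
    pore clusters.  The imprint is, by construction of the experiment, the
    largest pore cluster by a wide margin.
    """
    binary = vol.binary()
    if not binary.any():
        raise ValueError("empty pore space")
    small = block_reduce(binary, (2, 2, 2), np.mean) >= 0.5
    small = _binary_median(small, size=5)
    if not small.any():
        raise ValueError("no pore cluster survives the median filter")
    core_small = _split_largest(small)
    core = _upscale2(core_small, binary.shape)

    # full-resolution refinement is local: the pore space at native
    # resolution may percolate, so the candidate is the pore neighbourhood
    # of the coarse core, not its whole connected component
    cand = binary & ndi.binary_dilation(core, structure=_CROSS, iterations=2)
    if not cand.any():
        raise ValueError("imprint core lost during upscaling")

    box = _bbox(cand, pad=3)
    imprint = np.zeros_like(binary)
    imprint[box] = _split_largest(cand[box])
    residual = binary & ~imprint
    return ImprintResult(
        imprint_mask=imprint,
        imprint_volume_mm3=float(imprint.sum()) * vol.voxel_volume_mm3,
        residual_pores=residual,
    )


def region_masks(
    imprint: ImprintResult,
    vol: VoxelVolume,
    below_mm3: float = 1000.0,
    around_mm3: float = 2000.0,
    scale: float | None = None,
) -> dict[str, np.ndarray]:
    """Analysis regions below and around the cone imprint.

    ``below`` is the full domain cross-section under the deepest imprint
    voxel, clipped in depth to the target volume; ``around`` is the radial
    shell of nearest non-imprint voxels (city-block distance from the
    imprint surface, deterministic index tie-break) clipped to its target
    volume.  Targets default to the full-size 1000 / 2000 mm^3 and are
    scaled by ``scale`` (``None`` = ratio of the domain volume to the
    full-size reference domain).
    """
    dom = vol.domain()
    mask = imprint.imprint_mask
    if not mask.any():
        raise ValueError("empty imprint")
    vv = vol.voxel_volume_mm3
    if scale is None:
        scale = float(dom.sum()) * vv / REFERENCE_DOMAIN_MM3
    n_below = int(round(below_mm3 * scale / vv))
    n_around = int(round(around_mm3 * scale / vv))

    tip_z = int(np.nonzero(mask.any(axis=(1, 2)))[0].max())
    below = np.zeros_like(mask)
    total = 0
    z = tip_z + 1
    while total < n_below:
        if z >= mask.shape[0]:
            raise ValueError("requested below-tip volume exceeds the domain")
        below[z] = dom[z]
        total += int(dom[z].sum())
        z += 1

    cand = dom & ~mask & ~below
    cand[tip_z + 1 :] = False  # around = radial shell, not below the tip
    dist = ndi.distance_transform_cdt(~mask, metric="taxicab")
    flat = np.nonzero(cand.ravel())[0]
    if flat.size < n_around:
        raise ValueError("requested around volume exceeds the domain")
    order = np.argsort(dist.ravel()[flat], kind="stable")
    around = np.zeros(mask.size, dtype=bool)
    around[flat[order[:n_around]]] = True
    return {"below_tip": below, "around": around.reshape(mask.shape)}


def pore_metrics(
    pores: np.ndarray,
    region: np.ndarray,
    voxel_edge_um: float,
    connectivity: int = 26,
) -> dict[str, float]:
    """Visible porosity and mean pore diameter of a region.

    Mean pore diameter is the volume-weighted mean equivalent-sphere
    diameter of the labelled pore clusters intersecting the region
    (clusters clipped to the region), in micrometres.
    """
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("empty region")
    sub = pores & region
    porosity = float(sub.sum()) / n_region
    labels, n = label_pores(sub, connectivity)
    if n == 0:
        return {"visible_porosity": porosity, "mean_pore_diameter_um": float("nan")}
    counts = np.bincount(labels.ravel())[1:].astype(float)
    vols_um3 = counts * voxel_edge_um**3
    diam = (6.0 * vols_um3 / np.pi) ** (1.0 / 3.0)
    return {
        "visible_porosity": porosity,
        "mean_pore_diameter_um": float(np.average(diam, weights=vols_um3)),
    }


def radial_porosity_profile(
    imprint: ImprintResult,
    vol: VoxelVolume,
    max_distance_mm: float,
    step_voxels: int = 5,
) -> RadialProfile:
    """Visible porosity in contiguous shells around the imprint.

    Shell ``j`` (j >= 1) is the band between ``(j-1)`` and ``j`` dilations
    of the imprint by ``step_voxels`` iterations of the radius-1 cross —
    computed equivalently as city-block distance bands of width
    ``step_voxels`` — intersected with the analysis domain.  Shells beyond
    the domain are truncated with a warning.
    """
    dom = vol.domain()
    mask = imprint.imprint_mask
    step_um = step_voxels * vol.voxel_edge_um
    n_shells = int(np.ceil(max_distance_mm * 1000.0 / step_um))
    if n_shells < 1:
        return RadialProfile(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    dist = ndi.distance_transform_cdt(~mask, metric="taxicab")
    shell_id = np.ceil(dist / step_voxels).astype(int)  # 0 inside imprint
    shell_id[~dom | mask] = 0
    counts = np.bincount(shell_id.ravel(), minlength=n_shells + 1)
    pore_counts = np.bincount(
        shell_id.ravel(), weights=imprint.residual_pores.ravel(), minlength=n_shells + 1
    )
    counts, pore_counts = counts[1:], pore_counts[1:]
    if counts.size > n_shells:
        counts, pore_counts = counts[:n_shells], pore_counts[:n_shells]
    filled = counts > 0
    if not filled.all():
        warnings.warn(
            "profile truncated: requested distance extends beyond the domain",
            UserWarning,
            stacklevel=2,
        )
        last = int(np.nonzero(filled)[0].max()) + 1 if filled.any() else 0
        counts, pore_counts = counts[:last], pore_counts[:last]
    eps = np.divide(pore_counts, counts, out=np.zeros_like(pore_counts), where=counts > 0)
    edges = step_um * np.arange(1, counts.size + 1, dtype=float)
    return RadialProfile(edges, eps, counts.astype(int))


def compactness(eps_vis_prime: np.ndarray | float, eps_vis_ref: float):
    """Relative compactness change ``delta_c = 1 - eps_vis' / eps_vis_ref``."""
    if eps_vis_ref <= 0:
        raise ValueError("reference visible porosity must be positive")
    out = 1.0 - np.asarray(eps_vis_prime, dtype=float) / eps_vis_ref
    return float(out) if out.ndim == 0 else out


def structural_estimates(
    eps_vis_prime: np.ndarray | float,
    eps_vis_ref: float,
    rho_b: float = 1.4,
    rho_p: float = 2.56,
) -> StructuralEstimates:
    """Estimated total porosity and bulk density after penetration.

    Total porosity before penetration is taken as ``eps = 1 - rho_b/rho_p``
    (0.453125 for the defaults) so that a zero visible-porosity change
    recovers the packing bulk density exactly.  Changes in sub-resolution
    porosity are neglected: the estimates carry only the visible change.
    """
    if rho_b <= 0 or rho_p <= 0 or rho_b >= rho_p:
        raise ValueError("need 0 < rho_b < rho_p")
    evp = np.atleast_1d(np.asarray(eps_vis_prime, dtype=float))
    eps = 1.0 - rho_b / rho_p
    d_eps_vis = eps_vis_ref - evp
    eps_prime = eps - d_eps_vis
    if np.any(eps_prime < 0) or np.any(eps_prime > 1):
        raise ValueError("estimated total porosity outside [0, 1]")
    return StructuralEstimates(
        eps_vis_prime=evp,
        eps_vis_ref=eps_vis_ref,
        eps=eps,
        delta_eps_vis=d_eps_vis,
        eps_prime=eps_prime,
        rho_b=rho_b,
        rho_b_prime=(1.0 - eps_prime) * rho_p,
        rho_p=rho_p,
    )


def fit_compaction_decay(
    distance_mm: np.ndarray, delta_c: np.ndarray
) -> tuple[float, float]:
    """Fit ``delta_c(d) = A exp(-d / lam)``; returns ``(A, lam)`` in mm."""
    d = np.asarray(distance_mm, dtype=float)
    y = np.asarray(delta_c, dtype=float)
    keep = np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("need at least 3 finite profile points")
    p0 = (max(float(y[keep].max()), 0.1), max(float(d[keep].mean()), 1e-3))
    popt, _ = curve_fit(lambda x, a, lam: a * np.exp(-x / lam), d[keep], y[keep], p0=p0)
    return float(popt[0]), float(popt[1])
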