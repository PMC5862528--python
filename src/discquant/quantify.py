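"""Per-disc volumetry and pH3+ proliferation quantification.

Turns segmentation masks into the per-disc quantities reported for each
condition: connected-component clone labelling (26-connectivity), per-clone
volumes in um^3, the tumor-volume percent (100 x summed clone volume /
DAPI tissue volume), and phospho-histone-H3 spot counts partitioned inside
versus outside GFP+ clones with per-mm^3 density normalisation (whole
tissue, GFP+ volume, GFP- volume respectively).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageStack
from .segmentation import VoxelClassifier, compute_tissue_mask, predict_clone_mask

__all__ = [
    "QuantConfig",
    "Ph3Partition",
    "DiscMeasurement",
    "label_clones",
    "clone_table",
    "tumor_volume_percent",
    "detect_ph3_spots",
    "partition_ph3",
    "ph3_densities",
    "measure_disc",
]

UM3_PER_MM3 = 1e9
_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _ellipsoid_structure(radius_um: float, voxel_size_um) -> np.ndarray:
    """Binary ellipsoid of the given physical radius on an anisotropic grid."""
    half = [max(1, int(np.ceil(radius_um / v))) for v in voxel_size_um]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * v for h, v in zip(half, voxel_size_um)], indexing="ij"
    )
    return sum(g**2 for g in grids) <= radius_um**2


def label_clones(clone_mask: np.ndarray) -> np.ndarray:
    """Label spatially distinct clones: 26-connected components, labels 1..K."""
    labels, _ = ndimage.label(np.asarray(clone_mask, dtype=bool), structure=_CONN26)
    return labels


def clone_table(labels: np.ndarray, voxel_size_um: tuple[float, float, float]) -> pd.DataFrame:
    """Per-clone voxel counts, physical volumes and centroids.

    Returns a DataFrame with columns clone_id, voxel_count, volume_um3 and
    centroid_{z,y,x}_um. Non-contiguous label ids are relabelled 1..K with
    a warning.
    """
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("label volume must be non-negative")
    if any(v <= 0 for v in voxel_size_um):
        raise ValueError("voxel sizes must be positive")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
        warnings.warn("non-contiguous clone labels; relabelling 1..K")
        remap = np.zeros(labels.max() + 1, dtype=labels.dtype)
        remap[ids] = np.arange(1, ids.size + 1)
        labels = remap[labels]
        ids = np.arange(1, ids.size + 1)
    voxel_volume = float(np.prod(voxel_size_um))
    rows = []
    if ids.size:
        counts = np.bincount(labels.ravel())[1:]
        centroids = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
        for cid, cnt, cen in zip(ids, counts, centroids):
            rows.append(
                {
                    "clone_id": int(cid),
                    "voxel_count": int(cnt),
                    "volume_um3": float(cnt * voxel_volume),
                    "centroid_z_um": float(cen[0] * voxel_size_um[0]),
                    "centroid_y_um": float(cen[1] * voxel_size_um[1]),
                    "centroid_x_um": float(cen[2] * voxel_size_um[2]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id",
            "voxel_count",
            "volume_um3",
            "centroid_z_um",
            "centroid_y_um",
            "centroid_x_um",
        ],
    )


def tumor_volume_percent(clones: pd.DataFrame, tissue_volume_um3: float) -> float:
    """100 x (sum of all GFP+ clone volumes) / (DAPI tissue volume)."""
    if tissue_volume_um3 <= 0:
        raise ValueError("tissue volume must be > 0")
    return 100.0 * float(clones["volume_um3"].sum()) / float(tissue_volume_um3)


def detect_ph3_spots(
    stack: ImageStack,
    ph3_channel: str = "pH3",
    tissue_mask: np.ndarray | None = None,
    nuclear_radius_um: float = 2.5,
    rel_threshold: float = 0.3,
    min_response: float = 0.02,
) -> np.ndarray:
    """Detect pH3+ nuclei as Laplacian-of-Gaussian blobs.

    The LoG scale is matched to ``nuclear_radius_um`` (sigma = r / sqrt(3));
    local maxima of the negated LoG response above
    ``max(rel_threshold * peak response, min_response)`` are kept, maxima
    closer than one nuclear radius (physical distance) are merged keeping
    the stronger one, and spots outside the tissue mask are discarded.

    Returns an (n, 3) float array of voxel coordinates (z, y, x).
    """
    if nuclear_radius_um <= 0:
        raise ValueError("nuclear radius must be > 0")
    img = stack.channel(ph3_channel).astype(np.float32)
    voxel = stack.voxel_size_um
    sigma = tuple(nuclear_radius_um / np.sqrt(3.0) / v for v in voxel)
    response = -ndimage.gaussian_laplace(img, sigma)
    peak = float(response.max())
    if peak <= min_response:
        return np.zeros((0, 3))
    size = tuple(max(3, 2 * int(round(nuclear_radius_um / v / 2)) + 1) for v in voxel)
    local_max = response == ndimage.maximum_filter(response, size=size)
    cut = max(rel_threshold * peak, min_response)
    cand = np.argwhere(local_max & (response > cut))
    if cand.size and tissue_mask is not None:
        # tolerate one nuclear radius: an edge nucleus still belongs to the
        # tissue even if the DAPI mask stops at its rim
        tol = _ellipsoid_structure(nuclear_radius_um, voxel)
        tissue_mask = ndimage.binary_dilation(tissue_mask, structure=tol)
    if cand.size == 0:
        return np.zeros((0, 3))
    # strongest-first greedy merge of maxima within one nuclear radius
    strengths = response[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.argsort(strengths, kind="stable")[::-1]
    cand = cand[order]
    phys = cand * np.asarray(voxel)
    kept: list[int] = []
    for i in range(len(cand)):
        if all(
            np.linalg.norm(phys[i] - phys[j]) >= nuclear_radius_um for j in kept
        ):
            kept.append(i)
    spots = cand[kept].astype(float)
    if tissue_mask is not None:
        vox = np.round(spots).astype(int)
        inside = tissue_mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        spots = spots[inside]
    return spots


@dataclass
class Ph3Partition:
    """pH3+ spot counts split by compartment; inside + outside == whole."""

    n_whole: int
    n_inside: int
    n_outside: int
    positions: np.ndarray  # (n, 3) voxel coordinates
    inside: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        if self.n_inside + self.n_outside != self.n_whole:
            raise ValueError("compartment counts must sum to the whole-tissue count")


def partition_ph3(
    spots: np.ndarray, clone_mask: np.ndarray, tissue_mask: np.ndarray
) -> Ph3Partition:
    """Assign each spot inside (centroid voxel in a clone) or outside."""
    if clone_mask.shape != tissue_mask.shape:
        raise ValueError("clone and tissue masks must share the same geometry")
    spots = np.asarray(spots, dtype=float).reshape(-1, 3)
    vox = np.round(spots).astype(int)
    if len(vox) and (
        (vox < 0).any() or (vox >= np.asarray(clone_mask.shape)).any()
    ):
        raise ValueError("spot centroid outside the volume bounds")
    if len(vox):
        inside = clone_mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    else:
        inside = np.zeros(0, dtype=bool)
    return Ph3Partition(
        n_whole=len(vox),
        n_inside=int(inside.sum()),
        n_outside=int((~inside).sum()),
        positions=spots,
        inside=inside,
    )


def ph3_densities(
    part: Ph3Partition, tissue_volume_um3: float, clone_volume_um3: float
) -> tuple[float, float | None, float | None]:
    """Spot densities per mm^3 of whole tissue, GFP+ and GFP- volume.

    A compartment of zero volume has no defined density and is reported as
    ``None`` (a clone-free disc has no 'inside clones' density).
    """
    if clone_volume_um3 < 0 or tissue_volume_um3 <= 0:
        raise ValueError("volumes must be non-negative with tissue volume > 0")
    if clone_volume_um3 > tissue_volume_um3:
        raise ValueError("clone volume cannot exceed tissue volume")
    tissue_mm3 = tissue_volume_um3 / UM3_PER_MM3
    clone_mm3 = clone_volume_um3 / UM3_PER_MM3
    outside_mm3 = tissue_mm3 - clone_mm3
    whole = part.n_whole / tissue_mm3
    inside = part.n_inside / clone_mm3 if clone_mm3 > 0 else None
    outside = part.n_outside / outside_mm3 if outside_mm3 > 0 else None
    return whole, inside, outside


@dataclass(frozen=True)
class QuantConfig:
    """Channel names and stage parameters for :func:`measure_disc`."""

    dapi_channel: str = "DAPI"
    gfp_channel: str = "GFP"
    ph3_channel: str = "pH3"
    threshold: float = 0.5
    min_size_um3: float = 50.0
    nuclear_radius_um: float = 2.5
    ph3_rel_threshold: float = 0.3
    measure_ph3: bool = True


@dataclass
class DiscMeasurement:
    """All per-disc quantities for one stack."""

    tissue_volume_um3: float
    total_clone_volume_um3: float
    tumor_volume_percent: float
    n_clones: int
    clones: pd.DataFrame
    ph3: Ph3Partition | None = None
    ph3_density_whole_per_mm3: float | None = None
    ph3_density_inside_per_mm3: float | None = None
    ph3_density_outside_per_mm3: float | None = None

    def to_row(self, disc_id: str = "", condition: str = "") -> dict:
        """Flat dict for one row of the per-disc results TSV."""
        return {
            "disc_id": disc_id,
            "condition": condition,
            "tissue_volume_um3": self.tissue_volume_um3,
            "total_clone_volume_um3": self.total_clone_volume_um3,
            "tumor_volume_percent": self.tumor_volume_percent,
            "n_clones": self.n_clones,
            "ph3_whole": self.ph3.n_whole if self.ph3 else None,
            "ph3_inside": self.ph3.n_inside if self.ph3 else None,
            "ph3_outside": self.ph3.n_outside if self.ph3 else None,
            "ph3_density_whole_per_mm3": self.ph3_density_whole_per_mm3,
            "ph3_density_inside_per_mm3": self.ph3_density_inside_per_mm3,
            "ph3_density_outside_per_mm3": self.ph3_density_outside_per_mm3,
        }


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    """Pipeline failure tagged with the stage it occurred in."""


def measure_disc(
    stack: ImageStack, clf: VoxelClassifier, config: QuantConfig = QuantConfig()
) -> DiscMeasurement:
    """Run the full per-disc pipeline: masks -> clones -> volumes -> pH3.

    Deterministic given the classifier and configuration. pH3 quantities
    are filled only when the stack has the configured pH3 channel and
    ``config.measure_ph3`` is set.
    """
    with _stage("tissue_mask"):
        tissue = compute_tissue_mask(stack, dapi_channel=config.dapi_channel)
    with _stage("clone_mask"):
        masks = predict_clone_mask(
            stack,
            clf,
            threshold=config.threshold,
            min_size_um3=config.min_size_um3,
            tissue_mask=tissue,
        )
    voxel_volume = stack.voxel_volume_um3
    with _stage("volumetry"):
        labels = label_clones(masks.clone_mask)
        clones = clone_table(labels, stack.voxel_size_um)
        tissue_volume = float(tissue.sum()) * voxel_volume
        clone_volume = float(clones["volume_um3"].sum())
        percent = tumor_volume_percent(clones, tissue_volume)

    meas = DiscMeasurement(
        tissue_volume_um3=tissue_volume,
        total_clone_volume_um3=clone_volume,
        tumor_volume_percent=percent,
        n_clones=int(len(clones)),
        clones=clones,
    )
    if config.measure_ph3 and config.ph3_channel in stack.channel_names:
        with _stage("ph3"):
            spots = detect_ph3_spots(
                stack,
                ph3_channel=config.ph3_channel,
                tissue_mask=tissue,
                nuclear_radius_um=config.nuclear_radius_um,
                rel_threshold=config.ph3_rel_threshold,
            )
            part = partition_ph3(spots, masks.clone_mask, tissue)
            whole, inside, outside = ph3_densities(part, tissue_volume, clone_volume)
        meas.ph3 = part
        meas.ph3_density_whole_per_mm3 = whole
        meas.ph3_density_inside_per_mm3 = inside
        meas.ph3_density_outside_per_mm3 = outside
    return meas
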