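"""ROI atlas handling: seed definitions, spherical masks, time-series extraction.

The packaged default atlas holds 36 spherical seeds (5 mm radius) grouped
into four large-scale brain networks (LBNs) implicated in emotion
regulation.  Matrix row/column ``i`` throughout the package always refers to
ROI ``i`` in atlas order, so the ordering of the table is part of the
contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ATLAS_COLUMNS = ["roi_id", "name", "hemisphere", "network", "x", "y", "z"]

#: Default rendering grid: 3 mm isotropic MNI space, 61 x 73 x 61 voxels.
#: The affine maps voxel (0, 0, 0) to MNI (-90, -126, -72).
DEFAULT_GRID_SHAPE = (61, 73, 61)
DEFAULT_GRID_AFFINE = np.array(
    [
        [3.0, 0.0, 0.0, -90.0],
        [0.0, 3.0, 0.0, -126.0],
        [0.0, 0.0, 3.0, -72.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


class AtlasError(ValueError):
    """Raised when an ROI table violates the atlas invariants."""


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid in millimetre (MNI) space."""

    shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    affine: np.ndarray = field(default_factory=lambda: DEFAULT_GRID_AFFINE.copy())

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise AtlasError("affine must be 4x4")
        if np.any(aff[:3, :3] != np.diag(np.diag(aff[:3, :3]))):
            raise AtlasError("grid must be axis-aligned (diagonal affine)")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.abs(np.diag(self.affine[:3, :3]))

    def mni_to_voxel(self, xyz: Sequence[float]) -> np.ndarray:
        """Continuous voxel coordinates of an MNI point."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.affine[:3, 3]) / np.diag(self.affine[:3, :3])

    def voxel_to_mni(self, ijk: Sequence[float]) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.diag(self.affine[:3, :3]) + self.affine[:3, 3]


@dataclass(frozen=True)
class ROIDefinition:
    roi_id: int
    name: str
    hemisphere: str
    network_id: int
    center_mni: tuple[float, float, float]
    radius_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.network_id not in (1, 2, 3, 4):
            raise AtlasError(
                f"ROI {self.roi_id}: network_id {self.network_id} outside 1-4"
            )
        if self.radius_mm < 0:
            raise AtlasError(f"ROI {self.roi_id}: negative radius")
        if self.hemisphere not in ("L", "R", "B"):
            raise AtlasError(
                f"ROI {self.roi_id}: hemisphere {self.hemisphere!r} not in L/R/B"
            )


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered ROI collection plus the grid used to render masks."""

    rois: tuple[ROIDefinition, ...]
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if not self.rois:
            raise AtlasError("atlas has no ROIs")
        ids = [r.roi_id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise AtlasError("duplicate roi_id values")
        if ids != list(range(1, len(ids) + 1)):
            raise AtlasError("roi_id values must be contiguous from 1 in table order")

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def n_networks(self) -> int:
        return len({r.network_id for r in self.rois})

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def network_members(self, network_id: int) -> list[int]:
        """0-based indices of the ROIs belonging to one network."""
        return [i for i, r in enumerate(self.rois) if r.network_id == network_id]


def load_roi_table(path: str | Path | None = None, grid: GridSpec | None = None) -> ROIAtlas:
    """Load an ROI table (tab-separated) into an :class:`ROIAtlas`.

    With ``path=None`` the packaged 36-seed emotion-network atlas is used.
    The table must carry columns ``roi_id name hemisphere network x y z``
    (``radius_mm`` optional, default 5).
    """
    if path is None:
        src = resources.files("dfcstates.data").joinpath("lbn36_atlas.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise AtlasError("ROI table is empty")
    missing = [c for c in _ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasError(f"ROI table missing columns: {missing}")
    if "radius_mm" not in df.columns:
        df = df.assign(radius_mm=5.0)
    if df["roi_id"].duplicated().any():
        dupes = df.loc[df["roi_id"].duplicated(), "roi_id"].tolist()
        raise AtlasError(f"duplicate roi_id values: {dupes}")
    bad = df[~df["network"].isin([1, 2, 3, 4])]
    if len(bad):
        row = bad.iloc[0]
        raise AtlasError(
            f"row with roi_id {row['roi_id']}: network {row['network']} outside 1-4"
        )
    df = df.sort_values("roi_id")
    rois = tuple(
        ROIDefinition(
            roi_id=int(r.roi_id),
            name=str(r.name),
            hemisphere=str(r.hemisphere),
            network_id=int(r.network),
            center_mni=(float(r.x), float(r.y), float(r.z)),
            radius_mm=float(r.radius_mm),
        )
        for r in df.itertuples()
    )
    return ROIAtlas(rois=rois, grid=grid or GridSpec())


def build_sphere_mask(roi: ROIDefinition, grid: GridSpec) -> np.ndarray:
    """Voxel indices (n x 3 int array) whose centres lie within the ROI sphere.

    Membership is voxel-centre Euclidean distance <= radius.  The result is
    never empty: the voxel nearest the centre is always included, so a
    zero-radius seed yields exactly one voxel.
    """
    center_vox = grid.mni_to_voxel(roi.center_mni)
    nearest = np.rint(center_vox).astype(int)
    if np.any(nearest < 0) or np.any(nearest >= np.asarray(grid.shape)):
        raise AtlasError(
            f"ROI {roi.roi_id} centre {roi.center_mni} falls outside the grid"
        )
    # bounding box in voxel units, then exact distance test on voxel centres
    half = np.ceil(roi.radius_mm / grid.voxel_sizes).astype(int) + 1
    lo = np.maximum(nearest - half, 0)
    hi = np.minimum(nearest + half + 1, grid.shape)
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij"
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = vox * np.diag(grid.affine[:3, :3]) + grid.affine[:3, 3]
    dist = np.linalg.norm(centers - np.asarray(roi.center_mni), axis=1)
    inside = vox[dist <= roi.radius_mm + 1e-9]
    if len(inside) == 0:
        inside = nearest[None, :]
    return inside


def atlas_masks(atlas: ROIAtlas) -> list[np.ndarray]:
    """Sphere masks for every ROI, warning once about overlapping seeds."""
    masks = [build_sphere_mask(r, atlas.grid) for r in atlas.rois]
    seen: dict[tuple[int, int, int], int] = {}
    for idx, m in enumerate(masks):
        for v in map(tuple, m):
            if v in seen:
                logger.info(
                    "ROI %d overlaps ROI %d at voxel %s; extracting independently",
                    atlas.rois[idx].roi_id,
                    atlas.rois[seen[v]].roi_id,
                    v,
                )
                break
            seen[v] = idx
    return masks


def extract_timeseries(image, atlas: ROIAtlas):
    """Mean ROI signal per volume from a 4D NIfTI image.

    Parameters
    ----------
    image : nibabel spatial image or path
        4D volume on the atlas grid (same shape and affine).
    atlas : ROIAtlas

    Returns
    -------
    SubjectTimeSeries with a T x R data matrix (column i = ROI i mean).
    """
    import nibabel as nib

    from .windows import SubjectTimeSeries

    img = nib.load(str(image)) if isinstance(image, (str, Path)) else image
    if img.ndim != 4:
        raise AtlasError("expected a 4D image")
    if tuple(img.shape[:3]) != tuple(atlas.grid.shape) or not np.allclose(
        img.affine, atlas.grid.affine
    ):
        raise AtlasError("image grid does not match the atlas grid")
    data = np.asanyarray(img.dataobj, dtype=float)
    masks = atlas_masks(atlas)
    out_of_image = [
        atlas.rois[i].roi_id
        for i, m in enumerate(masks)
        if np.any(m < 0) or np.any(m >= np.asarray(atlas.grid.shape))
    ]
    if out_of_image:
        raise AtlasError(f"ROI masks outside the image: {out_of_image}")
    ts = np.column_stack(
        [data[m[:, 0], m[:, 1], m[:, 2], :].mean(axis=0) for m in masks]
    )
    return SubjectTimeSeries(
        subject_id="extracted", group="HC", session="baseline", data=ts
    )
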