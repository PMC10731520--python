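"""Atlas alignment of the cortical window via anatomical key-points.

Three landmarks are identifiable through a transcranial window: bregma,
a point on the superior sagittal sinus posterior to bregma, and the
boundary between the olfactory bulb and frontal cortex anterior to it.
All three sit on the midline, which is enough to constrain a similarity
transform (rotation + isotropic scale + translation) between atlas
millimeter coordinates and image pixels.  Ten named regions of interest
are then placed from their (AP, ML) offsets relative to bregma.

Atlas frame convention: x = ML in mm (positive toward the image +x side
of the midline), y = AP in mm (positive anterior).  Image frame: x =
columns rightward, y = rows downward, 0-based pixel centers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default region coordinates (AP_mm, ML_mm) relative to bregma.  The ten
#: names cover the putative motor, somatosensory, parietal, retrosplenial
#: and visual regions used throughout the correlation analyses.  These are
#: editable defaults drawn from standard Common Coordinate Framework
#: positions, not measured values.
DEFAULT_REGIONS_MM: dict[str, tuple[float, float]] = {
    "ALM": (2.5, 1.5),
    "M2": (1.7, 0.75),
    "wM1": (1.0, 1.0),
    "FL": (0.25, 2.25),
    "HL": (-0.5, 1.5),
    "aBC": (-0.75, 3.0),
    "pBC": (-1.75, 3.25),
    "lPTA": (-2.0, 1.7),
    "RS": (-2.75, 0.6),
    "V1": (-3.5, 2.5),
}

#: Atlas-side key-point coordinates in the (ML, AP) mm frame.  Bregma is
#: the origin; the sinus point lies on the posterior midline and the
#: olfactory-bulb/frontal boundary on the anterior midline.
DEFAULT_ATLAS_KEYPOINTS_MM: dict[str, tuple[float, float]] = {
    "bregma": (0.0, 0.0),
    "sinus": (0.0, -4.5),
    "ob_frontal": (0.0, 3.8),
}

KEYPOINT_NAMES = ("bregma", "sinus", "ob_frontal")


class FitError(ValueError):
    """Raised when the key-point configuration cannot constrain a fit."""


class PlacementError(ValueError):
    """Raised when a region lands outside the image bounds."""


@dataclass(frozen=True)
class KeyPoints:
    """Image-space landmark pixels: bregma, sagittal-sinus point, and the
    olfactory-bulb/frontal-cortex boundary."""

    bregma_px: tuple[float, float]
    sinus_px: tuple[float, float]
    ob_frontal_px: tuple[float, float]

    def __post_init__(self) -> None:
        pts = self.as_array()
        if any(
            np.allclose(pts[i], pts[j])
            for i in range(3)
            for j in range(i + 1, 3)
        ):
            raise FitError("key-points must be distinct")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.bregma_px, self.sinus_px, self.ob_frontal_px], dtype=float
        )

    @classmethod
    def from_dict(cls, d: dict[str, tuple[float, float]]) -> "KeyPoints":
        return cls(
            tuple(d["bregma"]), tuple(d["sinus"]), tuple(d["ob_frontal"])
        )


@dataclass
class SimilarityTransform:
    """Maps atlas (ML, AP) mm to image pixels: p = s * R(theta) @ a + t."""

    scale_px_per_mm: float
    rotation_rad: float
    translation_px: np.ndarray

    def __post_init__(self) -> None:
        if self.scale_px_per_mm <= 0:
            raise FitError("scale must be positive")
        self.translation_px = np.asarray(self.translation_px, dtype=float)

    @property
    def mm_per_px(self) -> float:
        return 1.0 / self.scale_px_per_mm

    @property
    def um_per_px(self) -> float:
        return 1000.0 / self.scale_px_per_mm

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        return self.scale_px_per_mm * np.array([[c, -s], [s, c]])

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = pts @ self.matrix.T + self.translation_px
        return out if np.asarray(points_mm).ndim == 2 else out[0]

    def invert(self, points_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        inv = np.linalg.inv(self.matrix)
        out = (pts - self.translation_px) @ inv.T
        return out if np.asarray(points_px).ndim == 2 else out[0]

    def to_dict(self) -> dict:
        return {
            "scale_px_per_mm": float(self.scale_px_per_mm),
            "rotation_rad": float(self.rotation_rad),
            "translation_px": [float(v) for v in self.translation_px],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            d["scale_px_per_mm"], d["rotation_rad"], np.array(d["translation_px"])
        )


@dataclass
class RegionSet:
    """Named cortical ROIs: (AP, ML) mm from bregma, plus their pixel
    locations once a transform has been fitted."""

    regions_mm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS_MM)
    )
    pixel_coords: dict[str, tuple[float, float]] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.regions_mm)

    def mirrored(self) -> "RegionSet":
        """Same regions in the opposite hemisphere (ML sign flipped)."""
        return RegionSet(
            {name: (ap, -ml) for name, (ap, ml) in self.regions_mm.items()}
        )

    def pixel_index(self, name: str) -> tuple[int, int]:
        x, y = self.pixel_coords[name]
        return int(round(x)), int(round(y))


def fit_transform(
    kp: KeyPoints,
    atlas_kp_mm: dict[str, tuple[float, float]] | None = None,
) -> SimilarityTransform:
    """Least-squares similarity transform from atlas mm to image pixels.

    Closed-form Procrustes on the three matched key-points; the bregma ->
    sinus axis thereby maps onto the atlas midline.  Rotation-only
    (det = +1): the three landmarks are collinear on the midline, so a
    reflection cannot be distinguished from a 180-degree rotation and the
    ML-handedness convention of the atlas frame is taken as given.
    """
    if atlas_kp_mm is None:
        atlas_kp_mm = DEFAULT_ATLAS_KEYPOINTS_MM
    src = np.array([atlas_kp_mm[n] for n in KEYPOINT_NAMES], dtype=float)
    dst = kp.as_array()
    if np.allclose(src.std(axis=0), 0):
        raise FitError("atlas key-points are coincident")

    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    src_var = float((src_c**2).sum())
    if src_var == 0:
        raise FitError("degenerate atlas key-points")
    # cross-covariance; SVD-based orthogonal Procrustes with det forced +1
    H = dst_c.T @ src_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    scale = float((S * np.diag(D)).sum() / src_var)
    if scale <= 0:
        raise FitError("non-positive scale from key-point fit")
    t = dst.mean(axis=0) - scale * R @ src.mean(axis=0)
    rotation = float(np.arctan2(R[1, 0], R[0, 0]))
    return SimilarityTransform(scale, rotation, t)


def place_regions(
    t: SimilarityTransform,
    rs: RegionSet,
    mask: np.ndarray,
) -> RegionSet:
    """Map each region's (AP, ML) mm offset through the transform.

    Regions whose pixel falls outside the mask are flagged (the window may
    not cover every region in every animal); a region outside the image
    bounds altogether raises ``PlacementError`` naming it.
    """
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    placed = dict(rs.regions_mm)
    coords: dict[str, tuple[float, float]] = {}
    flagged: list[str] = []
    for name, (ap, ml) in placed.items():
        x, y = t.apply(np.array([ml, ap]))
        xi, yi = int(round(x)), int(round(y))
        if not (0 <= xi < W and 0 <= yi < H):
            raise PlacementError(
                f"region {name!r} maps outside the image at ({x:.1f}, {y:.1f})"
            )
        coords[name] = (float(x), float(y))
        if not mask[yi, xi]:
            flagged.append(name)
    return RegionSet(placed, coords, flagged)
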