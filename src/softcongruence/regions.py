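"""Facial aesthetic-unit segmentation.

The analysis restricts the distance map to seven anatomic areas derived
from the facial aesthetic units — nose, upper cheek, lower cheek, upper
lip, lower lip, both lips (upper + lower pooled) and chin — plus the
total face (union of the six elementary units).

The units are cut by deterministic, landmark-anchored fences in the
aligned head frame (x antero-posterior, y lateral, z cranio-caudal,
z increasing cranially):

* horizontal planes through subnasale (nose / upper-lip), stomion
  (upper / lower lip), sublabiale (lips / chin), the exocanthion level
  (cranial cap of the face patch) and menton (caudal cap);
* per-side oblique alare-to-cheilion lines separating the lip units
  from the cheeks, continued vertically below the cheilion;
* vertical lines through the cheilions bounding the chin laterally;
* a cheilion-level horizontal plane splitting upper from lower cheek;
* vertical lines through the zygia bounding the face patch laterally.

A vertex exactly on a fence goes to the more cranial, then the more
medial unit (fixed tie-break).  Segmentation is evaluated on the
simulation surface, where the distance map lives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .distance import DistanceMap
from .mesh_io import LandmarkSet, LandmarkError, TriangleMesh

logger = logging.getLogger(__name__)

#: The six disjoint elementary units, in cranial-to-caudal report order.
ELEMENTARY_UNITS = (
    "nose",
    "upper_cheek",
    "upper_lip",
    "lower_lip",
    "lower_cheek",
    "chin",
)
#: All report regions (composites last).
REGION_NAMES = ("face_total",) + ELEMENTARY_UNITS[:1] + (
    "upper_cheek",
    "lower_cheek",
    "upper_lip",
    "lower_lip",
    "both_lips",
    "chin",
)

#: Integer labels used for per-vertex unit channels (0 = outside).
UNIT_LABELS = {name: i + 1 for i, name in enumerate(ELEMENTARY_UNITS)}
LABEL_OUTSIDE = 0

#: Landmarks the fence construction requires (beyond the 15 RPS points).
FENCE_ANCHORS = (
    "nasion",
    "subnasale",
    "stomion",
    "sublabiale",
    "menton",
    "alare_l",
    "alare_r",
    "cheilion_l",
    "cheilion_r",
    "exocanthion_l",
    "exocanthion_r",
    "zygion_l",
    "zygion_r",
)


@dataclass
class RegionFences:
    """Landmark-derived fence geometry in the aligned head frame."""

    z_top: float  # exocanthion level (cranial cap of the face patch)
    z_subnasale: float
    z_stomion: float
    z_sublabiale: float
    z_cheilion: float  # upper/lower cheek split
    z_bottom: float  # menton level (caudal cap)
    y_face_l: float  # signed lateral face bounds (left = +y by convention)
    y_face_r: float
    y_nose_l: float
    y_nose_r: float
    # per-side alare->cheilion lip fences: (y_at_subnasale, y_at_cheilion)
    lip_l: tuple[float, float]
    lip_r: tuple[float, float]
    y_chin_l: float
    y_chin_r: float

    def _lip_bound(self, z: np.ndarray, side: str) -> np.ndarray:
        """Lateral lip fence at height z (linear alare->cheilion, clamped)."""
        y_al, y_ch = self.lip_l if side == "l" else self.lip_r
        z0, z1 = self.z_subnasale, self.z_cheilion
        if z0 == z1:
            return np.full_like(z, y_ch)
        t = np.clip((self.z_subnasale - z) / (z0 - z1), 0.0, 1.0)
        return y_al + t * (y_ch - y_al)

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Per-point elementary-unit labels (0 = outside the face patch).

        Tie-break on fences: the more cranial unit wins (z comparisons
        are >= at a band's cranial fence), then the more medial (lateral
        bounds are inclusive toward the midline unit).
        """
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        y, z = pts[:, 1], pts[:, 2]
        labels = np.full(len(pts), LABEL_OUTSIDE, dtype=np.int8)

        inside = (
            (z >= self.z_bottom)
            & (z <= self.z_top)
            & (y <= self.y_face_l)
            & (y >= self.y_face_r)
        )
        band_nose = inside & (z >= self.z_subnasale)
        band_ul = inside & (z >= self.z_stomion) & (z < self.z_subnasale)
        band_ll = inside & (z >= self.z_sublabiale) & (z < self.z_stomion)
        band_chin = inside & (z < self.z_sublabiale)

        nose = band_nose & (y <= self.y_nose_l) & (y >= self.y_nose_r)
        ul = band_ul & (y <= self._lip_bound(z, "l")) & (y >= self._lip_bound(z, "r"))
        ll = band_ll & (y <= self._lip_bound(z, "l")) & (y >= self._lip_bound(z, "r"))
        chin = band_chin & (y <= self.y_chin_l) & (y >= self.y_chin_r)

        cheek = inside & ~(nose | ul | ll | chin)
        upper_cheek = cheek & (z >= self.z_cheilion)
        lower_cheek = cheek & (z < self.z_cheilion)

        labels[nose] = UNIT_LABELS["nose"]
        labels[upper_cheek] = UNIT_LABELS["upper_cheek"]
        labels[ul] = UNIT_LABELS["upper_lip"]
        labels[ll] = UNIT_LABELS["lower_lip"]
        labels[lower_cheek] = UNIT_LABELS["lower_cheek"]
        labels[chin] = UNIT_LABELS["chin"]
        return labels


@dataclass
class RegionMasks:
    """Region name -> vertex-index array on a host mesh."""

    masks: dict
    n_vertices: int

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self):
        return list(self.masks)

    def check(self) -> None:
        for name, idx in self.masks.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= self.n_vertices):
                raise ValueError(f"region {name!r} has out-of-range vertex indices")
        elem = [set(self.masks[u].tolist()) for u in ELEMENTARY_UNITS]
        for i in range(len(elem)):
            for j in range(i + 1, len(elem)):
                if elem[i] & elem[j]:
                    raise ValueError(
                        f"units {ELEMENTARY_UNITS[i]} and {ELEMENTARY_UNITS[j]} overlap"
                    )
        union = set().union(*elem)
        if union != set(self.masks["face_total"].tolist()):
            raise ValueError("face_total is not the union of the elementary units")
        lips = set(self.masks["upper_lip"].tolist()) | set(
            self.masks["lower_lip"].tolist()
        )
        if lips != set(self.masks["both_lips"].tolist()):
            raise ValueError("both_lips is not upper_lip + lower_lip")

    def to_json_dict(self) -> dict:
        return {k: v.tolist() for k, v in self.masks.items()}

    def labels(self) -> np.ndarray:
        """Per-vertex integer unit labels (0 = outside)."""
        out = np.full(self.n_vertices, LABEL_OUTSIDE, dtype=np.int8)
        for unit in ELEMENTARY_UNITS:
            out[self.masks[unit]] = UNIT_LABELS[unit]
        return out


def build_fences(landmarks: LandmarkSet) -> RegionFences:
    """Derive the fence geometry from an extended landmark set.

    Requires the anchors in :data:`FENCE_ANCHORS`; raises
    :class:`~softcongruence.mesh_io.LandmarkError` naming anything missing.
    """
    missing = [n for n in FENCE_ANCHORS if not landmarks.has(n)]
    if missing:
        raise LandmarkError(f"missing segmentation anchor(s): {missing}")
    g = landmarks.get
    y_al_l, y_al_r = g("alare_l")[1], g("alare_r")[1]
    y_ch_l, y_ch_r = g("cheilion_l")[1], g("cheilion_r")[1]
    z_ch = 0.5 * (g("cheilion_l")[2] + g("cheilion_r")[2])
    return RegionFences(
        z_top=0.5 * (g("exocanthion_l")[2] + g("exocanthion_r")[2]),
        z_subnasale=g("subnasale")[2],
        z_stomion=g("stomion")[2],
        z_sublabiale=g("sublabiale")[2],
        z_cheilion=z_ch,
        z_bottom=g("menton")[2],
        y_face_l=max(g("zygion_l")[1], g("zygion_r")[1]),
        y_face_r=min(g("zygion_l")[1], g("zygion_r")[1]),
        y_nose_l=max(y_al_l, y_al_r),
        y_nose_r=min(y_al_l, y_al_r),
        lip_l=(max(y_al_l, y_al_r), max(y_ch_l, y_ch_r)),
        lip_r=(min(y_al_l, y_al_r), min(y_ch_l, y_ch_r)),
        y_chin_l=max(y_ch_l, y_ch_r),
        y_chin_r=min(y_ch_l, y_ch_r),
    )


def masks_from_labels(labels: np.ndarray) -> RegionMasks:
    """Assemble :class:`RegionMasks` (with composites) from unit labels."""
    labels = np.asarray(labels)
    masks = {}
    for unit, code in UNIT_LABELS.items():
        masks[unit] = np.where(labels == code)[0]
    masks["both_lips"] = np.sort(
        np.concatenate([masks["upper_lip"], masks["lower_lip"]])
    )
    masks["face_total"] = np.where(labels != LABEL_OUTSIDE)[0]
    return RegionMasks(masks, len(labels))


def assign_regions(mesh: TriangleMesh, fences: RegionFences) -> RegionMasks:
    """Partition the mesh vertices into the aesthetic units.

    Vertices outside the face patch (rim, neck, anything beyond the
    fences) are excluded from ``face_total``.  Empty elementary units
    produce a warning, not an error.
    """
    labels = fences.classify(mesh.vertices)
    out = masks_from_labels(labels)
    for unit in ELEMENTARY_UNITS:
        if len(out[unit]) == 0:
            warnings.warn(f"aesthetic unit {unit!r} contains no vertices")
    out.check()
    return out


def restrict(dmap: DistanceMap, mask: np.ndarray) -> np.ndarray:
    """Valid signed distances at the masked vertices (may be empty)."""
    mask = np.asarray(mask, dtype=np.int64)
    keep = dmap.valid[mask]
    return dmap.distances[mask[keep]]
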