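"""Point-cloud 3D disc height: directed least-distance averaging, five-zone
anatomical partition, zone-matched 3D-DHI and four-bin categorisation.

The 3D disc height (3D-DH) of a motion segment is the mean, over every point
of the *inferior* endplate cloud, of the least Euclidean distance to the
*superior* endplate cloud.  The measurement is directed (inferior to
superior); a symmetrised variant is available for sensitivity checks but is
not the default.

The disc footprint is split into five anatomical zones — anterior, posterior,
left-lateral and right-lateral annulus fibrosus (AF) plus the central nucleus
pulposus (NP) — by fitting an ellipse to the projected inferior footprint:
points inside the co-axial ellipse shrunk by ``np_fraction`` on both
semi-axes belong to the NP; annulus points are assigned by azimuth from the
anterior axis (anterior within +/-45 deg, posterior within 45 deg of 180,
laterals otherwise by side).

Zone heights are normalised against the matched zone of the non-injected
reference disc of the same animal, giving the per-zone 3D disc height index
(3D-DHI, percent), which is then categorised into the four reporting bins
<70, 70-<80, 80-<90 and >=90 % (lower-inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ZONES",
    "BIN_LABELS",
    "EndplateCloud",
    "DiscFrame",
    "ZonePartition",
    "ZoneHeightTable",
    "least_distance_height",
    "fit_disc_frame",
    "partition_zones",
    "zone_heights",
    "three_d_dhi",
    "dhi_bin",
]

#: Anatomical zones in reporting order.
ZONES = ("posterior", "anterior", "l_lateral", "r_lateral", "np")

#: 3D-DHI category bins, half-open and lower-inclusive: a value of exactly
#: 70 falls in "70-<80", exactly 90 in ">=90".
BIN_LABELS = ("<70", "70-<80", "80-<90", ">=90")
_BIN_EDGES = (70.0, 80.0, 90.0)


@dataclass
class EndplateCloud:
    """One endplate's 3D point set in a disc-centred frame.

    Coordinates are millimetres; by convention +x is anterior, +y left and
    +z points from the inferior toward the superior vertebra.
    """

    points: np.ndarray
    side: str  # "inferior" | "superior"
    level: str | None = None
    animal: int | None = None
    week: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(self.points) == 0:
            raise ValueError("empty endplate cloud")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("endplate cloud contains non-finite coordinates")
        if self.side not in ("inferior", "superior"):
            raise ValueError(f"side must be 'inferior' or 'superior', got {self.side!r}")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DiscFrame:
    """Mid-plane frame of a motion segment: origin at the pooled centroid,
    ``normal`` along the mid-plane normal (toward the superior plate),
    ``e_anterior``/``e_left`` spanning the plane."""

    origin: np.ndarray
    normal: np.ndarray
    e_anterior: np.ndarray
    e_left: np.ndarray

    def project(self, points: np.ndarray) -> np.ndarray:
        """In-plane (u, v) coordinates (anterior, left) of 3D points."""
        rel = np.asarray(points, float) - self.origin
        return np.column_stack([rel @ self.e_anterior, rel @ self.e_left])


@dataclass
class ZonePartition:
    """Zone label per inferior point plus the fitted footprint ellipse."""

    labels: np.ndarray  # array of zone-name strings, one per inferior point
    center_uv: np.ndarray  # footprint centre in frame (u, v) coordinates
    semi_axes: tuple[float, float]  # (a, b) of the fitted ellipse, mm
    axes_uv: np.ndarray  # 2x2, principal axes as rows in (u, v) coords
    np_fraction: float = 0.5

    def counts(self) -> dict[str, int]:
        return {z: int(np.sum(self.labels == z)) for z in ZONES}


@dataclass
class ZoneHeightTable:
    """Per-zone and whole-disc 3D-DH, and (after normalisation) 3D-DHI.

    Empty zones carry NaN heights ("undefined", never zero).  The whole-disc
    height is the mean over *all* per-point least distances, i.e. the
    point-count-weighted mean of the zone heights, not their plain mean.
    """

    level: str | None
    animal: int | None
    week: int | None
    zone_height_mm: dict[str, float]
    whole_height_mm: float
    zone_dhi_pct: dict[str, float] = field(default_factory=dict)
    whole_dhi_pct: float | None = None
    zone_bin: dict[str, str] = field(default_factory=dict)


def least_distance_height(
    inferior: EndplateCloud,
    superior: EndplateCloud,
    symmetric: bool = False,
) -> tuple[float, np.ndarray]:
    """Directed least-distance 3D disc height.

    For every point of the inferior cloud the minimum Euclidean distance to
    any superior point is found (KD-tree accelerated; ties in the nearest
    neighbour do not affect the distance value and are resolved toward the
    smaller point index).  The mean of these per-point least distances is
    the 3D-DH.  With ``symmetric=True`` the reverse direction is averaged in
    as a sensitivity variant; the default follows the directed definition.

    Returns ``(mean_mm, per_point_distances)`` where the distances are those
    of the inferior points (directed case).
    """
    if len(inferior) == 0 or len(superior) == 0:
        raise ValueError("both endplate clouds must be non-empty")
    d_inf, _ = cKDTree(superior.points).query(inferior.points, k=1)
    if symmetric:
        d_sup, _ = cKDTree(inferior.points).query(superior.points, k=1)
        mean = 0.5 * (float(np.mean(d_inf)) + float(np.mean(d_sup)))
    else:
        mean = float(np.mean(d_inf))
    return mean, d_inf


def fit_disc_frame(
    inferior: EndplateCloud,
    superior: EndplateCloud,
    anterior_hint: np.ndarray | tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> DiscFrame:
    """Least-squares mid-plane through the pooled clouds.

    The plane normal is the smallest principal axis of the pooled, centred
    point set, oriented from the inferior toward the superior centroid; the
    in-plane anterior axis is the supplied anatomical hint projected onto
    the plane.
    """
    pooled = np.vstack([inferior.points, superior.points])
    centroid = pooled.mean(axis=0)
    centered = pooled - centroid
    # SVD of the centred cloud: last right-singular vector = plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point cloud; cannot fit a plane")
    normal = vt[2]
    sup_dir = superior.points.mean(axis=0) - inferior.points.mean(axis=0)
    if np.dot(normal, sup_dir) < 0:
        normal = -normal
    hint = np.asarray(anterior_hint, float)
    e_ant = hint - np.dot(hint, normal) * normal
    n_ant = np.linalg.norm(e_ant)
    if n_ant < 1e-12:
        raise ValueError("anterior_hint is parallel to the mid-plane normal")
    e_ant /= n_ant
    e_left = np.cross(normal, e_ant)
    return DiscFrame(origin=centroid, normal=normal, e_anterior=e_ant, e_left=e_left)


def _fit_footprint_ellipse(uv: np.ndarray, anterior_first: bool = True):
    """Principal-axis ellipse fit to projected footprint points.

    For a uniformly sampled ellipse the per-axis standard deviation is half
    the semi-axis, so the fitted semi-axes are twice the principal standard
    deviations.  Axes are ordered/oriented so the first axis points along
    +anterior (u) and the second along +left (v).
    """
    center = uv.mean(axis=0)
    cov = np.cov((uv - center).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    ax = evecs.T.copy()  # rows = principal directions
    if anterior_first and abs(ax[0, 0]) < abs(ax[1, 0]):
        ax = ax[::-1]
        evals = evals[::-1]
    # orient toward +u / +v so azimuths are anatomically signed
    if ax[0, 0] < 0:
        ax[0] = -ax[0]
    if ax[1, 1] < 0:
        ax[1] = -ax[1]
    semi_axes = 2.0 * np.sqrt(np.maximum(evals, 0.0))
    return center, (float(semi_axes[0]), float(semi_axes[1])), ax


def partition_zones(
    inferior: EndplateCloud,
    frame: DiscFrame,
    np_fraction: float = 0.5,
) -> ZonePartition:
    """Assign every inferior point to one of the five anatomical zones.

    Points are projected onto the mid-plane; an ellipse is fitted to the
    footprint (principal axes).  Points inside the centred co-axial ellipse
    scaled by ``np_fraction`` on both semi-axes are NP; the remaining
    annulus is split by azimuth theta measured from the +anterior axis:
    anterior for |theta| <= 45 deg, posterior for |theta - 180| <= 45 deg,
    left/right lateral otherwise by the sign of the left coordinate.
    """
    if not 0.0 < np_fraction < 1.0:
        raise ValueError("np_fraction must lie in (0, 1)")
    uv = frame.project(inferior.points)
    center, (a, b), ax = _fit_footprint_ellipse(uv)
    if a <= 0 or b <= 0:
        raise ValueError("degenerate footprint; cannot fit an ellipse")
    rel = uv - center
    u = rel @ ax[0]
    v = rel @ ax[1]
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # normalised elliptical radius
    theta = np.degrees(np.arctan2(v, u))
    labels = np.empty(len(uv), dtype=object)
    labels[np.abs(theta) <= 45.0] = "anterior"
    labels[np.abs(theta) >= 135.0] = "posterior"
    lateral = (np.abs(theta) > 45.0) & (np.abs(theta) < 135.0)
    labels[lateral & (v > 0)] = "l_lateral"
    labels[lateral & (v <= 0)] = "r_lateral"
    labels[rho <= np_fraction] = "np"
    return ZonePartition(
        labels=labels.astype(str),
        center_uv=center,
        semi_axes=(a, b),
        axes_uv=ax,
        np_fraction=np_fraction,
    )


def zone_heights(
    inferior: EndplateCloud,
    superior: EndplateCloud,
    partition: ZonePartition,
    symmetric: bool = False,
) -> ZoneHeightTable:
    """Per-zone mean least distance plus the whole-disc 3D-DH.

    A zone with no points gets a NaN ("undefined") height; it is never
    reported as zero.
    """
    if len(partition.labels) != len(inferior):
        raise ValueError("partition does not cover the inferior cloud")
    whole, d = least_distance_height(inferior, superior, symmetric=symmetric)
    zh: dict[str, float] = {}
    for z in ZONES:
        mask = partition.labels == z
        zh[z] = float(np.mean(d[mask])) if mask.any() else float("nan")
    return ZoneHeightTable(
        level=inferior.level,
        animal=inferior.animal,
        week=inferior.week,
        zone_height_mm=zh,
        whole_height_mm=whole,
    )


def dhi_bin(dhi_pct: float) -> str:
    """Four-category bin of a 3D-DHI percent value (lower-inclusive)."""
    if not np.isfinite(dhi_pct):
        raise ValueError("cannot bin an undefined 3D-DHI")
    if dhi_pct < _BIN_EDGES[0]:
        return BIN_LABELS[0]
    if dhi_pct < _BIN_EDGES[1]:
        return BIN_LABELS[1]
    if dhi_pct < _BIN_EDGES[2]:
        return BIN_LABELS[2]
    return BIN_LABELS[3]


def three_d_dhi(
    table: ZoneHeightTable,
    reference: ZoneHeightTable,
    mode: str = "zone_matched",
) -> ZoneHeightTable:
    """Normalise a zone-height table against the reference (NI) disc.

    ``mode='zone_matched'`` (default) divides each zone height by the same
    zone of the reference disc; ``mode='whole_disc'`` divides every zone by
    the reference's whole-disc 3D-DH (sensitivity variant).  Returns a new
    table carrying 3D-DHI percents and bins.
    """
    if mode not in ("zone_matched", "whole_disc"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    zone_dhi: dict[str, float] = {}
    zone_bin: dict[str, str] = {}
    for z in ZONES:
        h = table.zone_height_mm[z]
        ref = reference.zone_height_mm[z] if mode == "zone_matched" else reference.whole_height_mm
        if not np.isfinite(ref) or ref == 0:
            raise ValueError(f"reference height undefined or zero for zone {z!r}")
        val = 100.0 * h / ref if np.isfinite(h) else float("nan")
        zone_dhi[z] = val
        if np.isfinite(val):
            zone_bin[z] = dhi_bin(val)
    if not np.isfinite(reference.whole_height_mm) or reference.whole_height_mm == 0:
        raise ValueError("reference whole-disc height undefined or zero")
    whole = 100.0 * table.whole_height_mm / reference.whole_height_mm
    return ZoneHeightTable(
        level=table.level,
        animal=table.animal,
        week=table.week,
        zone_height_mm=dict(table.zone_height_mm),
        whole_height_mm=table.whole_height_mm,
        zone_dhi_pct=zone_dhi,
        whole_dhi_pct=whole,
        zone_bin=zone_bin,
    )
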