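"""Reference frames, gaze rays, and gaze-target geometry.

The head frame follows the avian convention used throughout the package:
+x through the two eyes (right positive), +y through the beak, +z up,
origin at the midpoint of the eyes. World orientation of the head is a
unit quaternion; all quaternion algebra goes through
``scipy.spatial.transform.Rotation``. Quaternion arrays at interfaces are
scalar-first (w, x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .config import ArenaConfig, EyeCalibration

LEFT, RIGHT = 0, 1


def rotations_from_wxyz(quat_wxyz: np.ndarray) -> Rotation:
    """Build a Rotation from scalar-first quaternions, validating norm."""
    q = np.atleast_2d(np.asarray(quat_wxyz, dtype=float))
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("quaternions must be unit norm (within 1e-6)")
    return Rotation.from_quat(q[:, [1, 2, 3, 0]])  # to scalar-last


def wxyz_from_rotations(rot: Rotation) -> np.ndarray:
    q = np.atleast_2d(rot.as_quat())
    return q[:, [3, 0, 1, 2]]


def head_frame_from_landmarks(left_eye, right_eye, beak_tip):
    """Construct the head frame from three landmark positions.

    Returns ``(origin, axes)`` where ``axes`` is a 3x3 matrix whose columns
    are the world directions of the head x, y, z axes (a right-handed
    orthonormal basis). Raises ``ValueError`` for (near-)collinear
    landmarks.
    """
    left_eye = np.asarray(left_eye, float)
    right_eye = np.asarray(right_eye, float)
    beak_tip = np.asarray(beak_tip, float)
    origin = 0.5 * (left_eye + right_eye)
    x = right_eye - left_eye
    nx = np.linalg.norm(x)
    if nx == 0:
        raise ValueError("left and right eye coincide")
    x = x / nx
    y = beak_tip - origin
    y = y - np.dot(y, x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9 * max(1.0, np.linalg.norm(beak_tip - origin)) or ny == 0:
        raise ValueError("landmarks are collinear; head frame is degenerate")
    y = y / ny
    z = np.cross(x, y)
    axes = np.column_stack([x, y, z])
    return origin, axes


@dataclass
class GazeSample:
    """World-frame gaze rays for both eyes over a block of samples.

    ``origins`` and ``directions`` have shape (n, 2, 3); eye index 0 is the
    left eye, 1 the right eye.
    """

    origins: np.ndarray
    directions: np.ndarray

    def __len__(self):
        return len(self.origins)


def calibrated_gaze_axes(calib: EyeCalibration) -> np.ndarray:
    """Head-frame gaze directions: optical axes pitched down about head x."""
    down = Rotation.from_euler("x", -calib.gaze_down_offset, degrees=True)
    return down.apply(calib.optical_axis_in_head)


def gaze_rays(position, quat_wxyz, calib: EyeCalibration) -> GazeSample:
    """World-frame gaze rays for head poses.

    ``position`` is (n, 3) mm, ``quat_wxyz`` (n, 4) unit quaternions. The
    downward gaze offset is applied in the head frame before rotating into
    the world.
    """
    position = np.atleast_2d(np.asarray(position, float))
    rot = rotations_from_wxyz(quat_wxyz)
    axes_head = calibrated_gaze_axes(calib)  # (2, 3)
    n = len(position)
    origins = np.empty((n, 2, 3))
    directions = np.empty((n, 2, 3))
    for eye in (LEFT, RIGHT):
        origins[:, eye] = position + rot.apply(calib.eye_position_in_head[eye])
        directions[:, eye] = rot.apply(np.tile(axes_head[eye], (n, 1)))
    return GazeSample(origins=origins, directions=directions)


def site_positions_3d(arena: ArenaConfig) -> np.ndarray:
    """Site centers as 3D points on the arena floor (z = 0)."""
    xy = arena.site_positions
    return np.c_[xy, np.zeros(len(xy))]


def angular_distances_to_sites(sample: GazeSample, arena: ArenaConfig) -> np.ndarray:
    """Angle (deg) between each eye's gaze and the direction to each site.

    Returns an array of shape (n, 2, n_sites) with values in [0, 180]. An
    eye exactly at a site center gets deviation 0 by convention.
    """
    sites = site_positions_3d(arena)  # (s, 3)
    to_site = sites[None, None, :, :] - sample.origins[:, :, None, :]
    dist = np.linalg.norm(to_site, axis=-1)
    safe = np.where(dist > 0, dist, 1.0)
    unit = to_site / safe[..., None]
    cosang = np.einsum("nek,nesk->nes", sample.directions, unit)
    ang = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return np.where(dist > 0, ang, 0.0)


def project_gaze_to_floor(
    origin,
    direction,
    cone_radius: float,
    arena: ArenaConfig,
    n_bins: int = 40,
) -> np.ndarray:
    """Floor bins intersected by a gaze cone.

    Returns a boolean (n_bins, n_bins) mask over the arena floor grid; a
    bin is inside the region when the direction from the eye to its center
    lies within ``cone_radius`` degrees of the gaze direction. A cone that
    never meets the floor yields an empty mask. ``cone_radius`` 0 selects
    exactly the bin the gaze ray pierces (if any).
    """
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    centers = floor_bin_centers(arena, n_bins)  # (n_bins, n_bins, 3)
    to_bin = centers - origin
    dist = np.linalg.norm(to_bin, axis=-1)
    cosang = np.einsum("ijk,k->ij", to_bin, direction) / np.where(dist > 0, dist, 1.0)
    ang = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if cone_radius > 0:
        return ang <= cone_radius
    # radius 0: the single bin containing the ray-floor intersection
    mask = np.zeros((n_bins, n_bins), dtype=bool)
    if direction[2] >= 0 or origin[2] <= 0:
        return mask
    tt = -origin[2] / direction[2]
    pt = origin + tt * direction
    half = arena.arena_side / 2.0
    if not (-half <= pt[0] < half and -half <= pt[1] < half):
        return mask
    bw = arena.arena_side / n_bins
    ix = int((pt[0] + half) // bw)
    iy = int((pt[1] + half) // bw)
    mask[iy, ix] = True
    return mask


def floor_bin_centers(arena: ArenaConfig, n_bins: int = 40) -> np.ndarray:
    half = arena.arena_side / 2.0
    edges = np.linspace(-half, half, n_bins + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    gx, gy = np.meshgrid(c, c)  # row index = y bin, column index = x bin
    return np.dstack([gx, gy, np.zeros_like(gx)])


def _direction_to_targets_in_head(quat_wxyz, positions, targets_xy):
    """Unit direction to each target expressed in the head frame."""
    rot = rotations_from_wxyz(quat_wxyz)
    targets = np.c_[np.atleast_2d(targets_xy), np.zeros(len(np.atleast_2d(targets_xy)))]
    d_world = targets - np.atleast_2d(positions)
    d_world /= np.linalg.norm(d_world, axis=1, keepdims=True)
    return rot.apply(d_world, inverse=True)


def classify_gaze_strategy(
    quat_wxyz,
    positions,
    saccade_index_from_dash,
    dash_targets_xy,
    calib: EyeCalibration,
    hit_threshold: float = 20.0,
    max_back: int = 8,
):
    """Frontal vs lateral gaze hits for saccades preceding dashes.

    Parameters are per-saccade: the head pose at the post-saccade fixation,
    the saccade's backward index from the next dash (0 = the saccade
    immediately preceding the dash), and the dash target position. Ideal
    frontal and lateral vectors are estimated from the density of
    target-in-head directions: the peak azimuth near the beak, and the peak
    azimuths near each eye (averaged across eyes via mirror symmetry).

    Returns a dict with per-saccade hit labels and the hit-probability time
    course (fraction of hits with binomial standard errors) for backward
    indices ``0..max_back``.
    """
    quat_wxyz = np.atleast_2d(quat_wxyz)
    if len(quat_wxyz) == 0:
        return {
            "frontal_hit": np.zeros(0, bool),
            "lateral_hit": np.zeros(0, bool),
            "index_from_dash": np.zeros(0, int),
            "time_course": np.zeros((0, 5)),
        }
    d_head = _direction_to_targets_in_head(quat_wxyz, positions, dash_targets_xy)
    azim = np.rad2deg(np.arctan2(d_head[:, 0], d_head[:, 1]))  # 0 = beak
    # Ideal vectors: density peaks near the beak and near each eye azimuth.
    half_eye = calib.inter_eye_angle / 2.0
    grid = np.arange(-180.0, 180.0, 1.0)
    diff = np.abs((azim[None, :] - grid[:, None] + 180.0) % 360.0 - 180.0)
    density = np.exp(-(diff**2) / (2 * 10.0**2)).sum(axis=1)

    def _peak(center, width=40.0):
        sel = np.abs((grid - center + 180.0) % 360.0 - 180.0) <= width
        sub = np.where(sel, density, -np.inf)
        return grid[int(np.argmax(sub))]

    frontal_az = _peak(0.0)
    lateral_az = 0.5 * (abs(_peak(-half_eye)) + abs(_peak(half_eye)))

    def _head_vec(az_deg, elev_deg):
        az, el = np.deg2rad(az_deg), np.deg2rad(elev_deg)
        return np.array([np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)])

    elev = np.rad2deg(np.arcsin(np.clip(np.median(d_head[:, 2]), -1, 1)))
    frontal_vec = _head_vec(frontal_az, elev)
    lateral_vecs = np.array([_head_vec(-lateral_az, elev), _head_vec(lateral_az, elev)])

    def _angle(v):
        c = np.clip(d_head @ v, -1.0, 1.0)
        return np.rad2deg(np.arccos(c))

    frontal_hit = _angle(frontal_vec) <= hit_threshold
    lateral_hit = np.minimum(_angle(lateral_vecs[0]), _angle(lateral_vecs[1])) <= hit_threshold

    idx = np.asarray(saccade_index_from_dash, int)
    rows = []
    for k in range(max_back + 1):
        sel = idx == k
        n = int(sel.sum())
        if n == 0:
            rows.append((k, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        pf = frontal_hit[sel].mean()
        pl = lateral_hit[sel].mean()
        sef = np.sqrt(pf * (1 - pf) / n)
        sel_ = np.sqrt(pl * (1 - pl) / n)
        rows.append((k, pf, sef, pl, sel_, n))
    time_course = np.array(rows, dtype=float)
    return {
        "frontal_hit": frontal_hit,
        "lateral_hit": lateral_hit,
        "index_from_dash": idx,
        "time_course": time_course,  # columns: k, p_frontal, se, p_lateral, se, n
    }


def aim_orientation(gaze_axis_head: np.ndarray, target_dir_world: np.ndarray) -> np.ndarray:
    """Head quaternion (wxyz) pointing a head-frame axis at a world direction.

    The orientation is a yaw about the world z axis followed by a pitch
    about the (yawed) head x axis, keeping head roll at zero — the natural
    posture for a perched bird. Raises if the target elevation is
    unreachable without roll.
    """
    a = np.asarray(gaze_axis_head, float)
    d = np.asarray(target_dir_world, float)
    d = d / np.linalg.norm(d)
    c = np.hypot(a[1], a[2])
    if c < abs(d[2]) - 1e-12:
        raise ValueError("target elevation unreachable without head roll")
    delta = np.arctan2(a[2], a[1])
    phi = np.arcsin(np.clip(d[2] / c, -1.0, 1.0)) - delta
    rx = Rotation.from_euler("x", phi)
    h = rx.apply(a)
    psi = np.arctan2(d[1], d[0]) - np.arctan2(h[1], h[0])
    rot = Rotation.from_euler("z", psi) * rx
    return wxyz_from_rotations(rot)[0]
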