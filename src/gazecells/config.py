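"""Session configuration objects and their YAML serialization.

Angles are degrees at interfaces, positions are millimetres, times are
seconds from session start. These conventions hold everywhere in the
package; internal trigonometry converts to radians locally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

X_OUTER_DISTANCE_MM = 340.0  # outer sites sit 34 cm from the central site
ARENA_SIDE_MM = 610.0  # central open space, 61 cm on each side


@dataclass
class ArenaConfig:
    """Geometry of the behavioral arena and its feeder sites.

    ``x_shape`` is a central site plus four outer sites on the diagonals
    (dashes run along the arms of the X); ``pentagon`` is five outer sites
    with no center (dashes run between every pair).
    """

    layout: str = "x_shape"
    arena_side: float = ARENA_SIDE_MM
    site_positions: Optional[np.ndarray] = None  # (n_sites, 2) mm
    n_outer_sites: int = 4
    center_site_index: Optional[int] = 0

    def __post_init__(self):
        if self.layout not in ("x_shape", "pentagon"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.site_positions is None:
            if self.layout == "x_shape":
                ang = np.deg2rad([45.0, 135.0, 225.0, 315.0])
                outer = X_OUTER_DISTANCE_MM * np.c_[np.cos(ang), np.sin(ang)]
                self.site_positions = np.vstack([[0.0, 0.0], outer])
                self.n_outer_sites = 4
                self.center_site_index = 0
            else:
                ang = np.deg2rad(90.0 + 72.0 * np.arange(5))
                radius = 280.0
                self.site_positions = radius * np.c_[np.cos(ang), np.sin(ang)]
                self.n_outer_sites = 5
                self.center_site_index = None
        self.site_positions = np.asarray(self.site_positions, dtype=float)
        if self.layout == "x_shape":
            if self.center_site_index is None or len(self.site_positions) != 5:
                raise ValueError("x_shape layout requires 5 sites incl. a center")
        else:
            if self.center_site_index is not None:
                raise ValueError("pentagon layout has no center site")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def outer_site_indices(self) -> list[int]:
        return [i for i in range(self.n_sites) if i != self.center_site_index]

    def paths(self) -> list[tuple[int, int]]:
        """Site pairs between which dashes occur (undirected)."""
        if self.layout == "x_shape":
            c = self.center_site_index
            return [(c, j) for j in self.outer_site_indices]
        n = self.n_sites
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def adjacent(self, i: int, j: int) -> bool:
        """Pentagon ring adjacency (used by the all-to-all target rules)."""
        if self.layout != "pentagon":
            raise ValueError("adjacency is defined for the pentagon layout")
        return (abs(i - j) % self.n_sites) in (1, self.n_sites - 1)


@dataclass
class BehaviorConfig:
    """Kinematic statistics of the synthetic bird.

    Defaults encode the study conditions: head saccades of 76 +/- 21 ms,
    instantaneous saccade rates of 3.8 +/- 1.4 Hz (reciprocal inter-saccade
    interval), a 54 +/- 6 mm head height, a 106 deg angle between the two
    eyes' optical axes, and gaze vectors pitched 5 deg below those axes.
    ``eye_in_head_mad`` records the scale of residual eye-in-head motion
    that the head-based gaze estimate ignores (5.4 deg median absolute
    deviation); the generator treats the eyes as fixed in the head.
    """

    sample_rate: float = 300.0
    saccade_duration_mean: float = 0.076
    saccade_duration_sd: float = 0.021
    saccade_rate_mean: float = 3.8
    saccade_rate_sd: float = 1.4
    fixation_jitter_sd: float = 1.0  # deg, stationary sd of fixation jitter
    jitter_corr_time: float = 0.25  # s, correlation time of fixation jitter
    eye_in_head_mad: float = 5.4  # deg (documented, not simulated)
    inter_eye_angle: float = 106.0  # deg between the two optical axes
    gaze_down_offset: float = 5.0  # deg, gaze pitched below the optical axis
    head_height_mean: float = 54.0  # mm
    head_height_sd: float = 6.0  # mm
    dash_speed: float = 1000.0  # mm/s, peak speed of the dash profile
    # Peak angular velocity per degree of amplitude implied by the Hann
    # velocity pulse at the mean duration: v_peak = (2 / D) * A.
    main_sequence_slope: float = 2.0 / 0.076
    aim_sd: float = 5.0  # deg, per-fixation aiming error around the target
    p_gaze_site: float = 0.75  # probability a search fixation aims at a site
    min_saccade_amplitude: float = 10.0  # deg, redraw closer fixation pairs
    reaction_time: float = 0.15  # s, light onset -> movement planning
    feed_duration_mean: float = 1.5  # s
    feed_duration_sd: float = 0.3  # s
    rng_seed: int = 0

    def __post_init__(self):
        if self.sample_rate < 100.0:
            raise ValueError("sample_rate must be at least 100 Hz")
        for name in (
            "saccade_duration_mean",
            "saccade_duration_sd",
            "saccade_rate_mean",
            "saccade_rate_sd",
            "dash_speed",
            "feed_duration_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class TaskConfig:
    """Closed-loop task logic shared by the three task variants."""

    variant: str = "random"  # random | blocked | all_to_all
    gaze_trigger_threshold: float = 15.0  # deg, within the 10-20 deg range
    gaze_trigger_min_samples: int = 3
    trigger_latency_median: float = 0.040  # s, detection -> light onset
    block_length: int = 6  # trials per block (blocked variant)
    catch_per_block: int = 2
    reward_probability: float = 0.8
    eligible_eyes: str = "both"  # both | contra_only

    def __post_init__(self):
        if self.variant not in ("random", "blocked", "all_to_all"):
            raise ValueError(f"unknown task variant {self.variant!r}")
        if not (10.0 <= self.gaze_trigger_threshold <= 20.0):
            raise ValueError("gaze_trigger_threshold must lie in [10, 20] deg")
        if self.catch_per_block >= self.block_length:
            raise ValueError("catch_per_block must be < block_length")
        if self.eligible_eyes not in ("both", "contra_only"):
            raise ValueError(f"unknown eligible_eyes {self.eligible_eyes!r}")


@dataclass
class EyeCalibration:
    """Per-bird eye geometry in the head reference frame.

    The head frame has +x through the eyes (right positive), +y through the
    beak, +z up, origin at the midpoint of the eyes. Optical axes default to
    symmetric azimuths of +/- inter_eye_angle/2 from the beak direction; the
    gaze vector used for analysis is the optical axis pitched down by
    ``gaze_down_offset`` about the head x axis.
    """

    eye_position_in_head: np.ndarray = None  # (2, 3) mm; rows: left, right
    optical_axis_in_head: np.ndarray = None  # (2, 3) unit vectors
    gaze_down_offset: float = 5.0  # deg
    inter_eye_angle: float = 106.0  # deg, for validation

    def __post_init__(self):
        if self.eye_position_in_head is None:
            self.eye_position_in_head = np.array(
                [[-7.0, 0.0, 0.0], [7.0, 0.0, 0.0]]
            )
        if self.optical_axis_in_head is None:
            half = np.deg2rad(self.inter_eye_angle / 2.0)
            self.optical_axis_in_head = np.array(
                [
                    [-np.sin(half), np.cos(half), 0.0],
                    [np.sin(half), np.cos(half), 0.0],
                ]
            )
        self.eye_position_in_head = np.asarray(self.eye_position_in_head, float)
        self.optical_axis_in_head = np.asarray(self.optical_axis_in_head, float)
        norms = np.linalg.norm(self.optical_axis_in_head, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("optical axes must be unit vectors")
        cosang = float(np.dot(*self.optical_axis_in_head))
        ang = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if abs(ang - self.inter_eye_angle) > 5.0:
            raise ValueError(
                f"angle between optical axes ({ang:.1f} deg) is inconsistent "
                f"with inter_eye_angle ({self.inter_eye_angle} deg)"
            )


@dataclass
class NeuronSpec:
    """Ground-truth tuning of one synthetic neuron.

    Excitatory cells combine a spatial place field with saccade-locked gaze
    responses: an early (predictive) kernel at +17 ms and a late (visual)
    kernel at +187 ms after peak saccade velocity, each scaled by the
    Gaussian angular closeness exp(-alpha^2 / (2 tau^2)) of the relevant
    fixation to the preferred site. Interneurons carry a saccade-locked
    quasi-sinusoidal modulation whose phase distinguishes the two subtypes.
    """

    cell_type: str = "excitatory"  # excitatory | inh_peak | inh_trough
    baseline_rate: float = 1.0  # Hz
    preferred_site: int = 1
    place_gain: float = 8.0  # Hz at the field center
    place_field_sigma: float = 90.0  # mm
    gaze_gain: float = 10.0  # Hz, peak of the gaze kernels at closeness 1
    gaze_tuning_width: float = 45.0  # deg, tau of the angular closeness
    early_amplitude: float = 1.0  # relative weight of the early kernel
    late_amplitude: float = 1.0  # relative weight of the late kernel
    early_latency: float = 0.017  # s after peak saccade velocity
    late_latency: float = 0.187  # s
    early_width: float = 0.025  # s, Gaussian sd of the early kernel
    late_width: float = 0.040  # s, Gaussian sd of the late kernel
    light_modulation: float = 1.0  # gain on the late kernel when light is on
    prediction_modulation: float = 1.0  # gain on the early kernel if expected
    contra_fraction: float = 1.0  # weight of the contralateral eye
    early_prev_weight: float = 0.0  # early dependence on the previous fixation
    early_next_weight: float = 1.0  # early dependence on the upcoming fixation
    phase_offset: float = 0.0  # rad, interneuron response phase
    cycle_period: float = 0.27  # s, quasiperiodic cycle of interneuron kernels

    def __post_init__(self):
        if self.cell_type not in ("excitatory", "inh_peak", "inh_trough"):
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        for name in ("early_latency", "late_latency"):
            v = getattr(self, name)
            if not (-0.1 <= v <= 0.4):
                raise ValueError(f"{name} must lie within [-0.1, 0.4] s")


_CONFIG_TYPES = {
    "arena": ArenaConfig,
    "behavior": BehaviorConfig,
    "task": TaskConfig,
    "calibration": EyeCalibration,
}


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_configs(path, **configs) -> None:
    """Write named config dataclasses to one flat YAML file."""
    doc = {}
    for name, cfg in configs.items():
        doc[name] = {
            f.name: _to_plain(getattr(cfg, f.name))
            for f in dataclasses.fields(cfg)
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_configs(path) -> dict:
    """Read configs written by :func:`save_configs`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for name, payload in doc.items():
        cls = _CONFIG_TYPES.get(name)
        if cls is None:
            out[name] = payload
        else:
            out[name] = cls(**payload)
    return out
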