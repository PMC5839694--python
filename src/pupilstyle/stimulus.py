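"""Kinematic model of the bistable rotating-cylinder stimulus.

Two superimposed dot fields move horizontally in opposite directions across
an 8 x 14 deg aperture; dots are black when moving one way and white the
other.  Projected onto the screen, a dot on a cylinder of radius R rotating
at angular velocity omega has x(t) = R sin(theta0 + omega t), so its linear
velocity follows a cosine of its phase angle — zero at the silhouette
edges, maximal at the screen centre.  Depth order is not a property of the
kinematics: front/back is an interpretation supplied by the observer, which
is exactly what makes the stimulus bistable.

Nothing is rendered; positions/velocities are exact closed forms, and a
speed-increment scheduler produces the event streams used by the
detection task (events every 3 s on average with a hard 2-s minimum
separation, each lasting one 120-Hz frame).

Note: with the default geometry (R = 4 deg, omega = 60 deg/s) the linear
speed at the screen centre is R * omega_rad = 4 * pi/3 ≈ 4.19 deg/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CylinderSpec",
    "DEFAULT_CYLINDER",
    "FRAME_RATE_HZ",
    "dot_state",
    "swap_directions",
    "schedule_increments",
]

FRAME_RATE_HZ = 120.0  # display frame rate defining "1 frame" increment duration


@dataclass(frozen=True)
class CylinderSpec:
    n_dots: int = 300
    width_deg: float = 8.0
    height_deg: float = 14.0
    angular_velocity: float = 60.0   # deg/s about the vertical axis
    dot_diameter_deg: float = 0.30   # metadata only; dots are kinematic points
    black_direction: str = "rightward"
    luminance_black: float = 0.05    # cd/m^2
    luminance_white: float = 55.0    # cd/m^2
    background_luminance: float = 12.4  # cd/m^2

    def __post_init__(self):
        if self.n_dots <= 0:
            raise ValueError("n_dots must be positive")
        if self.angular_velocity == 0:
            raise ValueError("angular_velocity must be non-zero")
        if self.black_direction not in ("rightward", "leftward"):
            raise ValueError("black_direction must be 'rightward' or 'leftward'")
        if not (self.luminance_black < self.background_luminance
                < self.luminance_white):
            raise ValueError("luminances must satisfy black < background < white")

    @property
    def radius_deg(self) -> float:
        return self.width_deg / 2.0

    @property
    def revolution_period_s(self) -> float:
        return 360.0 / abs(self.angular_velocity)


DEFAULT_CYLINDER = CylinderSpec()


def dot_state(
    spec: CylinderSpec,
    phase_angle_0: float,
    t: float,
    dot_index: int = 0,
    y_deg: float = 0.0,
) -> tuple[float, float, float, str]:
    """Exact state of one dot at time t.

    Returns ``(x_deg, y_deg, horizontal_speed_deg_per_s, luminance_tag)``.
    The rotation direction alternates with dot parity so that at any instant
    half of the dots move each way; x = R sin(theta), dx/dt = R omega_rad
    cos(theta).  The luminance tag follows the sign of the horizontal speed
    per ``spec.black_direction`` (dots at a silhouette edge, speed exactly
    zero, keep the tag of the direction they are about to move in).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    R = spec.radius_deg
    sign = 1.0 if dot_index % 2 == 0 else -1.0
    omega = math.radians(spec.angular_velocity) * sign
    theta = math.radians(phase_angle_0) + omega * t
    x = R * math.sin(theta)
    vx = R * omega * math.cos(theta)
    moving_right = vx > 0 or (vx == 0 and R * omega * math.cos(theta + 1e-9) > 0)
    if spec.black_direction == "rightward":
        tag = "black" if moving_right else "white"
    else:
        tag = "white" if moving_right else "black"
    return x, y_deg, vx, tag


def swap_directions(spec: CylinderSpec) -> CylinderSpec:
    """Swapped-direction condition: toggle which color moves rightward."""
    new = "leftward" if spec.black_direction == "rightward" else "rightward"
    return replace(spec, black_direction=new)


def schedule_increments(
    duration: float,
    mean_interval: float = 3.0,
    min_separation: float = 2.0,
    seed: int | np.random.Generator = 0,
    magnitude: float = 600.0,
    duration_frames: int = 1,
) -> pd.DataFrame:
    """Schedule speed-increment events over one recording.

    Inter-event gaps are min_separation + Exponential(mean_interval -
    min_separation), so the mean gap is ``mean_interval`` while no two
    events are ever closer than ``min_separation``.  Each event is tagged
    with the dot color it affects (fair coin).

    Returns a DataFrame with columns ``t_s``, ``dot_color``,
    ``magnitude_deg_s``, ``duration_frames``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (mean_interval > min_separation > 0):
        raise ValueError("require mean_interval > min_separation > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    times = []
    t = min_separation + rng.exponential(mean_interval - min_separation)
    while t < duration:
        times.append(t)
        t += min_separation + rng.exponential(mean_interval - min_separation)
    colors = rng.choice(["black", "white"], size=len(times))
    return pd.DataFrame(
        {
            "t_s": np.asarray(times, dtype=float),
            "dot_color": colors,
            "magnitude_deg_s": magnitude,
            "duration_frames": duration_frames,
        }
    )
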