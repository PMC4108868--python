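"""Test configuration and polar stimulus geometry.

A halo test presents a bright central disc on a dark screen and flashes
faint peripheral spots along radial spokes ("semiaxes") at a small number
of fixed distances ("rings").  An observer who perceives a halo around the
central glare source fails to detect the innermost spots; the pattern of
misses, weighted by squared distance, becomes the visual disturbance index
computed in :mod:`halometry.scoring`.

This module validates a test configuration, realises it as explicit screen
coordinates, and converts pixel extents to visual angles.  The default
configuration is the one used in the alcohol-consumption study that the
package ships as its reference protocol: a 25 px central disc, 1 px
peripheral spots on 18 semiaxes with 4 rings out to 60 px, each spot shown
twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field


class ConfigurationError(ValueError):
    """Raised when a test configuration violates one or more invariants.

    The message lists *every* violated invariant with its field name, not
    only the first, so a hand-edited configuration file can be fixed in one
    pass.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid test configuration: " + "; ".join(self.problems))


class TestConfiguration(BaseModel):
    """All spatial, temporal and weighting parameters of one halo test.

    Field defaults reproduce the reference study protocol, so an empty
    override mapping yields the standard 72-stimulus test.  Luminances are
    recorded metadata only; nothing in the package renders calibrated
    light.  ``pixel_pitch_mm`` has no default because the physical monitor
    is unknown: visual-angle conversions are available only when it is
    supplied.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    main_radius_px: float = 25.0
    peripheral_radius_px: float = 1.0
    max_radius_px: float = 60.0
    n_per_semiaxis: int = 4
    n_semiaxes: int = 18
    darkness_s: float = 180.0
    main_adapt_s: float = 60.0
    exposure_s: float = 1.0
    refresh_min_s: float = 0.8
    refresh_max_s: float = 2.0
    weight: int = 2
    viewing_distance_m: float = 2.5
    screen_resolution: tuple[int, int] = (1024, 768)
    pixel_pitch_mm: float | None = None
    luminance_main: float = 175.6
    luminance_peripheral: float = 61.4
    luminance_background: float = 0.72

    def check_invariants(self) -> None:
        problems: list[str] = []
        if self.main_radius_px <= 0:
            problems.append("main_radius_px must be > 0")
        if self.peripheral_radius_px <= 0:
            problems.append("peripheral_radius_px must be > 0")
        if self.max_radius_px <= 0:
            problems.append("max_radius_px must be > 0")
        inner = self.main_radius_px + self.peripheral_radius_px
        if self.n_per_semiaxis > 1 and self.max_radius_px <= inner:
            problems.append(
                "max_radius_px must exceed main_radius_px + peripheral_radius_px "
                "when n_per_semiaxis > 1"
            )
        if self.n_per_semiaxis == 1 and self.max_radius_px < inner:
            problems.append(
                "max_radius_px must be at least main_radius_px + peripheral_radius_px"
            )
        if self.n_per_semiaxis < 1:
            problems.append("n_per_semiaxis must be >= 1")
        if self.n_semiaxes < 1:
            problems.append("n_semiaxes must be >= 1")
        if self.weight < 1:
            problems.append("weight must be >= 1")
        if self.refresh_min_s <= 0:
            problems.append("refresh_min_s must be > 0")
        if self.refresh_max_s < self.refresh_min_s:
            problems.append("refresh_max_s must be >= refresh_min_s")
        if self.exposure_s <= 0:
            problems.append("exposure_s must be > 0")
        if self.darkness_s < 0:
            problems.append("darkness_s must be >= 0")
        if self.main_adapt_s < 0:
            problems.append("main_adapt_s must be >= 0")
        if self.pixel_pitch_mm is not None and self.pixel_pitch_mm <= 0:
            problems.append("pixel_pitch_mm must be > 0 when given")
        w, h = self.screen_resolution
        if w < 1 or h < 1:
            problems.append("screen_resolution dimensions must be >= 1")
        if problems:
            raise ConfigurationError(problems)

    @property
    def n_stimuli(self) -> int:
        return self.n_semiaxes * self.n_per_semiaxis


#: The reference study protocol (all defaults).
STUDY_DEFAULT = TestConfiguration()


def validate_config(raw: Mapping | TestConfiguration | None = None) -> TestConfiguration:
    """Build a validated configuration, filling gaps with study defaults.

    Parameters
    ----------
    raw
        A mapping of field overrides (possibly empty or ``None``), or an
        existing :class:`TestConfiguration` to re-validate.

    Raises
    ------
    ConfigurationError
        Listing every violated invariant with its field name.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, TestConfiguration):
        cfg = raw
    else:
        cfg = TestConfiguration(**dict(raw))
    cfg.check_invariants()
    return cfg


def _ceil_px(x: float) -> int:
    # guard against 48.999999999 from float division before ceiling
    nearest = round(x)
    if abs(x - nearest) < 1e-9:
        return int(nearest)
    return int(math.ceil(x))


def ring_radii(
    main_radius_px: float,
    peripheral_radius_px: float,
    max_radius_px: float,
    n_per_semiaxis: int,
) -> list[int]:
    """Centre-to-centre distances of the peripheral rings, in whole pixels.

    The innermost ring is tangent to the central disc (distance
    ``main_radius_px + peripheral_radius_px``), the outermost sits exactly
    at ``max_radius_px``, and intermediate rings are equally spaced between
    them with fractional positions rounded up to whole pixels.  For the
    reference protocol (25, 1, 60, 4) this yields [26, 38, 49, 60].
    """
    if n_per_semiaxis < 1:
        raise ValueError("n_per_semiaxis must be >= 1")
    inner = main_radius_px + peripheral_radius_px
    if n_per_semiaxis == 1:
        if max_radius_px < inner:
            raise ValueError("max_radius_px smaller than the tangent ring distance")
        return [_ceil_px(max_radius_px)]
    if inner >= max_radius_px:
        raise ValueError(
            "inner tangent ring at or beyond max_radius_px; "
            "cannot place multiple rings"
        )
    step = (max_radius_px - inner) / (n_per_semiaxis - 1)
    radii = [_ceil_px(inner + k * step) for k in range(n_per_semiaxis)]
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError(f"ring radii not strictly increasing after rounding: {radii}")
    return radii


@dataclass(frozen=True)
class PeripheralStimulus:
    """One peripheral spot: polar placement plus screen coordinates.

    ``r_px`` is the centre-to-centre distance from the central disc — the
    r_i that weights this stimulus in the disturbance index.  Screen
    coordinates follow the raster convention (origin top-left, y grows
    downward), so a semiaxis at angle a (counter-clockwise from rightward)
    maps to ``centre + r (cos a, -sin a)``.
    """

    stimulus_id: int
    semiaxis_index: int
    ring_index: int
    r_px: float
    angle_deg: float
    x_px: float
    y_px: float


@dataclass(frozen=True)
class StimulusLayout:
    """The full set of peripheral stimuli realised from a configuration."""

    config: TestConfiguration
    stimuli: tuple[PeripheralStimulus, ...]

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def radii(self) -> np.ndarray:
        """r_i per stimulus, ordered by stimulus_id."""
        return np.array([s.r_px for s in self.stimuli], dtype=float)

    @property
    def stimulus_ids(self) -> np.ndarray:
        return np.array([s.stimulus_id for s in self.stimuli], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": [s.stimulus_id for s in self.stimuli],
                "semiaxis_index": [s.semiaxis_index for s in self.stimuli],
                "ring_index": [s.ring_index for s in self.stimuli],
                "r_px": [s.r_px for s in self.stimuli],
                "angle_deg": [s.angle_deg for s in self.stimuli],
                "x_px": [s.x_px for s in self.stimuli],
                "y_px": [s.y_px for s in self.stimuli],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_layout(config: TestConfiguration | Mapping | None = None) -> StimulusLayout:
    """Realise a configuration as explicit stimulus positions.

    Semiaxis ``k`` points at ``k * 360 / n_semiaxes`` degrees, starting
    rightward on screen and proceeding counter-clockwise; every semiaxis
    carries the same ring distances.  Stimulus ids run ring-major within
    semiaxis: ``id = semiaxis_index * n_per_semiaxis + ring_index``.
    """
    cfg = validate_config(config)
    radii = ring_radii(
        cfg.main_radius_px, cfg.peripheral_radius_px, cfg.max_radius_px, cfg.n_per_semiaxis
    )
    cx = cfg.screen_resolution[0] / 2.0
    cy = cfg.screen_resolution[1] / 2.0
    stimuli = []
    for k in range(cfg.n_semiaxes):
        angle = k * 360.0 / cfg.n_semiaxes
        a = math.radians(angle)
        for j, r in enumerate(radii):
            stimuli.append(
                PeripheralStimulus(
                    stimulus_id=k * cfg.n_per_semiaxis + j,
                    semiaxis_index=k,
                    ring_index=j,
                    r_px=float(r),
                    angle_deg=angle,
                    x_px=cx + r * math.cos(a),
                    y_px=cy - r * math.sin(a),
                )
            )
    return StimulusLayout(config=cfg, stimuli=tuple(stimuli))


def pixels_to_degrees(
    length_px: float,
    viewing_distance_m: float,
    pixel_pitch_mm: float,
    mode: Literal["radius", "diameter"] = "radius",
) -> float:
    """Visual angle, in degrees, subtended by a pixel extent.

    ``mode="radius"`` treats the extent as measured from the line of sight
    (angle = atan(L / d)); ``mode="diameter"`` treats it as centred on the
    line of sight (angle = 2 atan(L / 2d)).  The caller must say which,
    because published subtenses are quoted both ways.
    """
    if length_px < 0:
        raise ValueError("length_px must be >= 0")
    if viewing_distance_m <= 0 or pixel_pitch_mm <= 0:
        raise ValueError("viewing_distance_m and pixel_pitch_mm must be > 0")
    length_m = length_px * pixel_pitch_mm / 1000.0
    if mode == "radius":
        return math.degrees(math.atan(length_m / viewing_distance_m))
    if mode == "diameter":
        return 2.0 * math.degrees(math.atan(length_m / (2.0 * viewing_distance_m)))
    raise ValueError(f"unknown mode {mode!r}")
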