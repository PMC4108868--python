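"""Visual disturbance index and results rendering.

The visual disturbance index (VDI) summarises a detection matrix as the
squared-distance-weighted fraction of missed presentations:

    VDI = sum_i p_i * r_i**2 / (p * sum_i r_i**2)

where r_i is the centre-to-centre distance of stimulus i, p the number of
times each stimulus was shown, and p_i how many of those showings were
missed.  Squared-distance weighting makes a miss far from the glare source
— where a healthy observer detects easily — cost more than a miss close
in.  VDI ranges from 0 (everything detected) to 1 (nothing detected); its
complement, the visual discrimination index VDiscI = 1 - VDI, quantifies
detection.  The per-semiaxis extent of contiguous fully-missed rings
traces the shape of the perceived halo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import StimulusLayout
from .protocol import DetectionMatrix


def _aligned(matrix: DetectionMatrix, layout: StimulusLayout) -> pd.DataFrame:
    """Join matrix counts onto layout geometry by stimulus id; strict match."""
    if sorted(matrix.stimulus_ids.tolist()) != sorted(layout.stimulus_ids.tolist()):
        raise ValueError("detection matrix ids do not match the layout")
    geo = layout.to_frame()
    counts = matrix.to_frame()
    return geo.merge(counts, on="stimulus_id").sort_values("stimulus_id").reset_index(drop=True)


def compute_vdi(matrix: DetectionMatrix, layout: StimulusLayout) -> float:
    """Squared-distance-weighted miss fraction, in [0, 1]."""
    joined = _aligned(matrix, layout)
    p = joined["presentations"].to_numpy(dtype=float)
    if np.any(p <= 0):
        raise ValueError("every stimulus needs at least one presentation")
    if joined["presentations"].nunique() != 1:
        raise ValueError("presentations must equal the common weight p for all stimuli")
    weight = float(p[0])
    r2 = joined["r_px"].to_numpy(dtype=float) ** 2
    misses = joined["misses"].to_numpy(dtype=float)
    denom = weight * r2.sum()
    if denom == 0:
        raise ValueError("all stimulus radii are zero")
    return float((misses * r2).sum() / denom)


def compute_vdisci(vdi: float) -> float:
    """Visual discrimination index: 1 - VDI."""
    if not 0.0 <= vdi <= 1.0:
        raise ValueError("vdi must lie in [0, 1]")
    return 1.0 - vdi


def halo_extent(
    matrix: DetectionMatrix,
    layout: StimulusLayout,
    miss_fraction_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-semiaxis radius of the contiguous missed core.

    Walking outward along each semiaxis, the extent is the largest ring
    radius such that every ring up to and including it has miss fraction
    p_i/p at or above the threshold; 0 if the innermost ring already falls
    below it.  The default threshold 1.0 counts only complete misses, so
    the extents trace the core of the perceived halo.
    """
    if not 0.0 < miss_fraction_threshold <= 1.0:
        raise ValueError("miss_fraction_threshold must lie in (0, 1]")
    joined = _aligned(matrix, layout)
    joined["miss_fraction"] = joined["misses"] / joined["presentations"]
    extents = []
    for semiaxis, grp in joined.groupby("semiaxis_index"):
        grp = grp.sort_values("ring_index")
        extent = 0.0
        for _, row in grp.iterrows():
            if row["miss_fraction"] >= miss_fraction_threshold:
                extent = float(row["r_px"])
            else:
                break
        extents.append(
            {
                "semiaxis_index": int(semiaxis),
                "angle_deg": float(grp["angle_deg"].iloc[0]),
                "extent_px": extent,
            }
        )
    return pd.DataFrame(extents)


@dataclass
class TestResult:
    """Scored session: indices, per-stimulus detection map, halo extents."""

    vdi: float
    vdisci: float
    detection_map: pd.DataFrame  # stimulus_id, r_px, angle_deg, x_px, y_px, presentations, misses
    extents: pd.DataFrame  # semiaxis_index, angle_deg, extent_px
    false_positive_count: int
    pupil_mm: float | None = None

    def to_dict(self) -> dict:
        return {
            "vdi": self.vdi,
            "vdisci": self.vdisci,
            "false_positive_count": self.false_positive_count,
            "pupil_mm": self.pupil_mm,
            "stimuli": self.detection_map.to_dict(orient="records"),
            "extents": self.extents.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def score_session(
    matrix: DetectionMatrix,
    layout: StimulusLayout,
    *,
    miss_fraction_threshold: float = 1.0,
    pupil_mm: float | None = None,
) -> TestResult:
    """Compute VDI, VDiscI, the detection map and halo extents in one call."""
    vdi = compute_vdi(matrix, layout)
    joined = _aligned(matrix, layout)
    return TestResult(
        vdi=vdi,
        vdisci=compute_vdisci(vdi),
        detection_map=joined[
            ["stimulus_id", "semiaxis_index", "ring_index", "r_px", "angle_deg",
             "x_px", "y_px", "presentations", "misses"]
        ],
        extents=halo_extent(matrix, layout, miss_fraction_threshold),
        false_positive_count=matrix.false_positive_count,
        pupil_mm=pupil_mm,
    )


def _glyph(presentations: int, misses: int) -> str:
    # X only when never detected; otherwise the detected count (so "1"
    # covers a stimulus detected once and missed once at weight 2)
    detected = presentations - misses
    return "X" if detected == 0 else str(detected)


def render_text_map(result: TestResult, width: int = 61) -> str:
    """Plain-text polar detection map.

    ``X`` marks a never-detected stimulus; a digit gives the detected
    count.  ``O`` marks the central disc.  Character cells are twice as
    tall as wide, so the horizontal scale is doubled to keep the map
    roughly circular.  A footer reports VDI (rho, two decimals as in
    printed reports) and pupil diameter (phi) when known.
    """
    dm = result.detection_map
    max_r = dm["r_px"].max()
    half_cols = max(width // 2, 1)
    half_rows = max(half_cols // 2, 1)
    grid = [[" "] * (2 * half_cols + 1) for _ in range(2 * half_rows + 1)]
    grid[half_rows][half_cols] = "O"
    for _, row in dm.iterrows():
        a = np.radians(row["angle_deg"])
        col = half_cols + int(round(np.cos(a) * row["r_px"] / max_r * half_cols))
        r_ = half_rows - int(round(np.sin(a) * row["r_px"] / max_r * half_rows))
        grid[r_][col] = _glyph(int(row["presentations"]), int(row["misses"]))
    lines = ["".join(r).rstrip() for r in grid]
    footer = f"rho (VDI) = {result.vdi:.2f}"
    if result.pupil_mm is not None:
        footer += f"   phi (pupil) = {result.pupil_mm:.1f} mm"
    if result.false_positive_count:
        footer += f"   false positives = {result.false_positive_count}"
    return "\n".join(lines + [footer])


def render_figure(result: TestResult, path=None):
    """Vector detection map: green detected counts, red X marks.

    Returns the matplotlib figure; saves it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dm = result.detection_map
    max_r = dm["r_px"].max()
    main_r = result.detection_map["r_px"].min() - 1  # tangent ring radius minus spot
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.add_patch(plt.Circle((0, 0), max(main_r, 1), color="0.85", zorder=1))
    for _, row in dm.iterrows():
        a = np.radians(row["angle_deg"])
        x, y = row["r_px"] * np.cos(a), row["r_px"] * np.sin(a)
        glyph = _glyph(int(row["presentations"]), int(row["misses"]))
        ax.text(
            x, y, glyph,
            color="red" if glyph == "X" else "green",
            ha="center", va="center", fontsize=9, fontweight="bold", zorder=2,
        )
    lim = max_r * 1.15
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xlabel("pixels")
    title = f"rho (VDI) = {result.vdi:.2f}"
    if result.pupil_mm is not None:
        title += f",  phi = {result.pupil_mm:.1f} mm"
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
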