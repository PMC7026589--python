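"""Comet detection and scoring on the microwell grid.

The regular array layout is exploited end to end: lattice rotation is found
by maximizing the sharpness of the axis projections, pitch by the first
autocorrelation peak of the projections, and phase by the circular mean of
projection-peak positions.  Each lattice node then yields one analysis
window, and each window is collapsed to a 1-D profile along the
electrophoresis axis and split into head and tail by the reflection rule:
the head is the smoothed-profile peak plus twice the leading (anti-tail)
mass, i.e. the leading half of the comet mirrored about its center; the
tail is everything else.  ``percent_tail = 100 * tail / total``.

Coordinates are 0-based row-major pixel indices; axis 1 (columns) is the
electrophoresis/tail axis; tails extend toward increasing column index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .model import ValidationError
from .synth import CometField

__all__ = [
    "NoGridFound",
    "GridFit",
    "QuantConfig",
    "CometRecord",
    "Window",
    "register_grid",
    "extract_windows",
    "segment_comet",
    "reflect_split",
    "quantify_field",
    "qc_filter",
    "RECORD_COLUMNS",
]

SATURATION_LEVEL = np.iinfo(np.uint16).max


class NoGridFound(RuntimeError):
    """The field shows no detectable lattice periodicity."""


@dataclass
class GridFit:
    pitch_px: float
    pitch_um: float
    rotation_deg: float
    offset: Tuple[float, float]  # (row0, col0) in the derotated frame
    nodes: np.ndarray  # (n, 2) node centers, derotated frame
    node_index: np.ndarray  # (n, 2) integer lattice (row, col)
    score: float  # mean normalized autocorrelation peak height

    def __post_init__(self) -> None:
        if self.pitch_px <= 0:
            raise ValidationError("pitch_px must be > 0")


@dataclass(frozen=True)
class QuantConfig:
    """Segmentation parameters (px units unless noted)."""

    head_anchor_frac: float = 0.35  # head position from window's left edge
    # Window end past the node: long enough for ~99% of the longest tails,
    # short enough to exclude the downstream neighbor's head wing (4 sigma).
    window_ahead_frac: float = 0.75
    smooth_px: int = 15  # odd boxcar width for projection-phase smoothing
    coarse_px: int = 7  # boxcar width for the coarse head-peak search
    refine_px: int = 7  # raw-profile refinement half-width around the peak
    tau_k: float = 2.5  # anti-tail tie-break tolerance, in column-noise sigmas
    search_frac: float = 0.30  # peak search half-width around anchor, pitches
    bg_margin_frac: float = 0.20  # transverse margin rows used for background
    empty_rel: float = 0.10  # empty_well: total < empty_rel * field ref total
    low_rel: float = 0.40  # low_signal: total < low_rel * field ref total
    angle_limit_deg: float = 3.0
    min_pitch_px: int = 12


DEFAULT_CONFIG = QuantConfig()

RECORD_COLUMNS = [
    "field",
    "row",
    "col",
    "y",
    "x",
    "total",
    "head",
    "tail",
    "percent_tail",
    "tail_moment_px",
    "tail_moment_um",
    "flags",
]


@dataclass
class CometRecord:
    field_id: object
    row: int
    col: int
    cy: float
    cx: float
    total: float
    head: float
    tail: float
    percent_tail: float
    tail_moment_px: float
    tail_moment_um: float
    flags: frozenset = field(default_factory=frozenset)

    @property
    def clean(self) -> bool:
        return not self.flags


@dataclass
class Window:
    image: np.ndarray
    origin: Tuple[int, int]  # (row, col) of window's top-left, derotated frame
    node: Tuple[float, float]
    node_index: Tuple[int, int]
    expected_head: int  # column index of the expected head inside the window
    flags: frozenset = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Grid registration
# ---------------------------------------------------------------------------


def _projection_sharpness(img: np.ndarray) -> float:
    return float(np.var(img.mean(axis=0)) + np.var(img.mean(axis=1)))


def _estimate_rotation(img: np.ndarray, limit: float) -> float:
    """Angle (deg) whose *derotation* maximizes projection sharpness."""

    def score(a: float) -> float:
        rot = ndimage.rotate(img, -a, reshape=False, order=1, mode="nearest")
        return _projection_sharpness(rot)

    coarse = np.arange(-limit, limit + 1e-9, 0.5)
    s = [score(a) for a in coarse]
    best = coarse[int(np.argmax(s))]
    fine = np.arange(best - 0.5, best + 0.5 + 1e-9, 0.1)
    s = [score(a) for a in fine]
    i = int(np.argmax(s))
    # parabolic refinement on the fine grid (spacing 0.1 deg)
    if 0 < i < len(fine) - 1:
        y0, y1, y2 = s[i - 1], s[i], s[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            return float(fine[i] + 0.05 * (y0 - y2) / denom)
    return float(fine[i])


def _refine_peak(y: np.ndarray, i: int) -> float:
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom != 0:
            return i + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i)


def _pitch_from_projection(proj: np.ndarray, min_lag: int) -> Tuple[float, float]:
    """(pitch, normalized peak height) from the projection autocorrelation."""
    p = proj - proj.mean()
    n = len(p)
    ac = signal.correlate(p, p, mode="full")[n - 1 :]
    if ac[0] <= 0:
        raise NoGridFound("flat projection")
    ac = ac / ac[0]
    peaks, props = signal.find_peaks(ac[min_lag : n // 2], prominence=0.02)
    if len(peaks) == 0:
        raise NoGridFound("no periodic structure in projection")
    best = peaks[int(np.argmax(props["prominences"]))]
    lag = best + min_lag
    return float(_refine_peak(ac, lag)), float(ac[lag])


def _offset_from_projection(proj: np.ndarray, pitch: float, smooth: int) -> float:
    sm = ndimage.uniform_filter1d(proj, max(3, smooth))
    peaks, _ = signal.find_peaks(sm, distance=max(2, int(0.7 * pitch)))
    if len(peaks) == 0:
        raise NoGridFound("no projection peaks for phase estimate")
    heights = sm[peaks]
    keep = peaks[heights > sm.mean()]
    if len(keep) == 0:
        keep = peaks
    ang = 2 * math.pi * (np.asarray(keep, dtype=float) % pitch) / pitch
    phase = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
    return (phase / (2 * math.pi) * pitch) % pitch


def register_grid(
    field: CometField, config: QuantConfig = DEFAULT_CONFIG
) -> GridFit:
    """Estimate lattice pitch, rotation and phase from the periodic
    intensity structure of the field.  Raises :class:`NoGridFound` on
    blank or aperiodic fields."""
    img = np.asarray(field.image, dtype=float)
    if img.size == 0:
        raise NoGridFound("empty image")
    img = img - np.median(img)
    rotation = _estimate_rotation(img, config.angle_limit_deg)
    work = _derotate(img, rotation)
    proj_r = work.mean(axis=1)
    proj_c = work.mean(axis=0)
    pitch_r, score_r = _pitch_from_projection(proj_r, config.min_pitch_px)
    pitch_c, score_c = _pitch_from_projection(proj_c, config.min_pitch_px)
    if abs(pitch_r - pitch_c) > 0.15 * max(pitch_r, pitch_c):
        raise NoGridFound(
            f"inconsistent pitch estimates along the two axes "
            f"({pitch_r:.1f} vs {pitch_c:.1f} px)"
        )
    pitch = 0.5 * (pitch_r + pitch_c)
    smooth = config.smooth_px
    off_r = _offset_from_projection(proj_r, pitch, smooth)
    off_c = _offset_from_projection(proj_c, pitch, smooth)
    h, w = work.shape
    rows = np.arange(off_r, h, pitch)
    cols = np.arange(off_c, w, pitch)
    nodes = np.array([(r, c) for r in rows for c in cols])
    idx = np.array(
        [(i, j) for i in range(len(rows)) for j in range(len(cols))], dtype=int
    )
    return GridFit(
        pitch_px=pitch,
        pitch_um=pitch * field.um_per_px,
        rotation_deg=rotation,
        offset=(float(off_r), float(off_c)),
        nodes=nodes,
        node_index=idx,
        score=0.5 * (score_r + score_c),
    )


def _derotate(img: np.ndarray, rotation_deg: float) -> np.ndarray:
    if abs(rotation_deg) < 0.05:
        return img
    return ndimage.rotate(img, -rotation_deg, reshape=False, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# Window extraction and segmentation
# ---------------------------------------------------------------------------


def extract_windows(
    field: CometField,
    grid: GridFit,
    config: QuantConfig = DEFAULT_CONFIG,
) -> List[Window]:
    """One candidate window per lattice node.

    The window spans one pitch transversely and from ``head_anchor_frac``
    pitches before the node to ``window_ahead_frac`` pitches after it along
    the tail axis; windows clipped by the raster border are flagged edge.
    """
    img = _derotate(np.asarray(field.image, dtype=float), grid.rotation_deg)
    h, w = img.shape
    p = grid.pitch_px
    back = config.head_anchor_frac * p
    ahead = config.window_ahead_frac * p
    half = 0.5 * p
    out: List[Window] = []
    for (r, c), (i, j) in zip(grid.nodes, grid.node_index):
        y0, y1 = int(round(r - half)), int(round(r + half))
        x0, x1 = int(round(c - back)), int(round(c + ahead))
        flags = set()
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            flags.add("edge")
        cy0, cx0 = max(0, y0), max(0, x0)
        cy1, cx1 = min(h, y1), min(w, x1)
        out.append(
            Window(
                image=img[cy0:cy1, cx0:cx1],
                origin=(cy0, cx0),
                node=(float(r), float(c)),
                node_index=(int(i), int(j)),
                expected_head=int(round(c)) - cx0,
                flags=frozenset(flags),
            )
        )
    return out


def reflect_split(profile: np.ndarray, center: int) -> Tuple[float, float]:
    """Head/tail split of a 1-D intensity profile by the reflection rule.

    The head is the profile value at ``center`` plus twice the mass before
    it (the leading, anti-tail half mirrored about the center); the tail is
    the remainder.  The head is capped at the total so both parts stay
    nonnegative and sum exactly to the total.
    """
    profile = np.asarray(profile, dtype=float)
    total = float(profile.sum())
    head = float(profile[center] + 2.0 * profile[:center].sum())
    head = min(head, total)
    return head, total - head


def _tail_centroid_px(profile: np.ndarray, center: int) -> float:
    """Intensity-weighted distance of the tail excess from the head center."""
    n = len(profile)
    excess = []
    dist = []
    for i in range(center + 1, n):
        mirror = 2 * center - i
        lead = profile[mirror] if mirror >= 0 else 0.0
        e = profile[i] - lead
        if e > 0:
            excess.append(e)
            dist.append(i - center)
    if not excess:
        return 0.0
    excess_a = np.asarray(excess)
    return float((excess_a * np.asarray(dist)).sum() / excess_a.sum())


def segment_comet(
    window: Window,
    um_per_px: float = 1.0,
    config: QuantConfig = DEFAULT_CONFIG,
    field_id: object = 0,
    empty_floor: float = 0.0,
    low_floor: float = 0.0,
) -> CometRecord:
    """Score one window into a :class:`CometRecord`.

    Background is the median of the transverse margin rows (a local robust
    percentile); the subtraction is *not* clipped at zero, so residual
    counting noise stays mean-zero instead of rectifying into signal.  The
    window is collapsed along the transverse axis; the head center is found
    by a boxcar-smoothed coarse peak search, refined on the raw profile,
    with ties (values within one column-noise sigma of the maximum)
    breaking toward the smallest index — the anti-tail side, biasing toward
    counting migration as tail.  The profile is then split by
    :func:`reflect_split`.
    """
    raw = np.asarray(window.image, dtype=float)
    flags = set(window.flags)
    if raw.size == 0 or not np.any(raw):
        return _empty_record(window, field_id, flags | {"empty_well"})
    if raw.max() >= SATURATION_LEVEL:
        flags.add("saturated")
    m = max(1, int(round(config.bg_margin_frac * raw.shape[0])))
    margin = np.concatenate([raw[:m], raw[-m:]], axis=0)
    bg = float(np.median(margin))
    profile = (raw - bg).sum(axis=0)
    total = float(profile.sum())
    if total <= empty_floor or total <= 0.0:
        return _empty_record(window, field_id, flags | {"empty_well"})
    if low_floor > 0 and total < low_floor:
        flags.add("low_signal")
    # Column-noise scale for the tie-break tolerance (zero on clean renders):
    # background noise per column plus the counting noise of the peak column.
    # The tolerance can be generous because the profile *jumps* at the head
    # center (the tail is one-sided), so walking left past it is blocked by a
    # gap much larger than the plateau fluctuations to its right.
    # Both terms scale with the measured per-pixel margin variance, so the
    # tolerance is exactly zero on noiseless renders.
    var_pix = float(margin.var())
    noise_var = raw.shape[0] * var_pix + max(float(profile.max()), 0.0) * var_pix / max(bg, 1.0)
    tau = config.tau_k * math.sqrt(max(noise_var, 0.0))
    sm = ndimage.uniform_filter1d(profile, config.coarse_px)
    n = len(profile)
    if window.expected_head >= 0:
        half = max(3, int(round(config.search_frac * n / (config.head_anchor_frac + config.window_ahead_frac))))
        lo = max(0, window.expected_head - half)
        hi = min(n, window.expected_head + half + 1)
    else:
        lo, hi = 0, max(1, int(0.6 * n))
    c0 = lo + int(np.argmax(sm[lo:hi]))
    l2 = max(0, c0 - config.refine_px)
    seg = profile[l2 : min(n, c0 + config.refine_px + 1)]
    center = l2 + int(np.nonzero(seg >= seg.max() - tau)[0][0])
    head, tail = reflect_split(profile, center)
    pct = float(np.clip(100.0 * tail / total, 0.0, 100.0))
    cen_px = _tail_centroid_px(profile, center)
    tm_px = pct / 100.0 * cen_px
    oy, ox = window.origin
    return CometRecord(
        field_id=field_id,
        row=window.node_index[0],
        col=window.node_index[1],
        cy=window.node[0],
        cx=float(ox + center),
        total=total,
        head=head,
        tail=tail,
        percent_tail=pct,
        tail_moment_px=tm_px,
        tail_moment_um=tm_px * um_per_px,
        flags=frozenset(flags),
    )


def _empty_record(window: Window, field_id: object, flags: set) -> CometRecord:
    return CometRecord(
        field_id=field_id,
        row=window.node_index[0],
        col=window.node_index[1],
        cy=window.node[0],
        cx=window.node[1],
        total=0.0,
        head=0.0,
        tail=0.0,
        percent_tail=float("nan"),
        tail_moment_px=float("nan"),
        tail_moment_um=float("nan"),
        flags=frozenset(flags),
    )


def quantify_field(
    field: CometField,
    grid: Optional[GridFit] = None,
    config: QuantConfig = DEFAULT_CONFIG,
    field_id: object = 0,
) -> pd.DataFrame:
    """Register (if needed), window and score a whole field.

    empty_well / low_signal floors are set relative to the robust per-field
    comet intensity (75th percentile of window totals), so they adapt to
    exposure without per-image configuration.
    """
    if grid is None:
        grid = register_grid(field, config)
    windows = extract_windows(field, grid, config)
    totals = []
    for wdw in windows:
        raw = np.asarray(wdw.image, dtype=float)
        if raw.size == 0:
            totals.append(0.0)
            continue
        m = max(1, int(round(config.bg_margin_frac * raw.shape[0])))
        bg = float(np.median(np.concatenate([raw[:m], raw[-m:]], axis=0)))
        totals.append(float((raw - bg).sum()))
    ref = float(np.percentile(totals, 75)) if totals else 0.0
    records = [
        segment_comet(
            wdw,
            um_per_px=field.um_per_px,
            config=config,
            field_id=field_id,
            empty_floor=config.empty_rel * ref,
            low_floor=config.low_rel * ref,
        )
        for wdw in windows
    ]
    return records_to_frame(records)


def records_to_frame(records: Sequence[CometRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "field": [r.field_id for r in records],
            "row": [r.row for r in records],
            "col": [r.col for r in records],
            "y": [r.cy for r in records],
            "x": [r.cx for r in records],
            "total": [r.total for r in records],
            "head": [r.head for r in records],
            "tail": [r.tail for r in records],
            "percent_tail": [r.percent_tail for r in records],
            "tail_moment_px": [r.tail_moment_px for r in records],
            "tail_moment_um": [r.tail_moment_um for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )


def qc_filter(
    records: pd.DataFrame,
    condition_col: str = "condition",
    min_comets: int = 100,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop flagged records and apply the minimum-comet gate per condition.

    Returns ``(clean records from passing conditions, per-condition status)``
    where status has columns condition / n_clean / qc_pass.  Conditions with
    fewer than ``min_comets`` clean comets are excluded from analysis.
    """
    if condition_col not in records.columns:
        records = records.assign(**{condition_col: "all"})
    clean = records[(records["flags"] == "") & records["percent_tail"].notna()]
    counts = (
        clean.groupby(condition_col, sort=False)
        .size()
        .reindex(records[condition_col].unique(), fill_value=0)
    )
    status = pd.DataFrame(
        {
            "condition": counts.index,
            "n_clean": counts.values,
            "qc_pass": counts.values >= min_comets,
        }
    )
    passing = set(status.loc[status["qc_pass"], "condition"])
    return clean[clean[condition_col].isin(passing)].copy(), status
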