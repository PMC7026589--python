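"""Synthetic CometChip field renderer with exact ground truth.

Comets sit on a regular microwell lattice (~240 um pitch, ~45 um wells).
Each comet is rendered as an isotropic Gaussian head plus a half-Gaussian
tail decaying along the electrophoresis axis (image axis 1, increasing
column index).  The head receives a fraction ``1 - f`` and the tail a
fraction ``f`` of the comet's photon budget, where ``f`` is the true tail
fraction, so the ground truth is exact by construction.  Kernels are
normalized by their discrete sum, which makes photon conservation exact up
to raster-border clipping.  Per-pixel Poisson counting noise is added on
top of a constant background offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import (
    AgentPreset,
    DamageScenario,
    ModelParams,
    DEFAULT_PARAMS,
    ValidationError,
    scenario_tail_pct,
)

__all__ = [
    "ArrayGeometry",
    "CometSpec",
    "GroundTruthManifest",
    "CometField",
    "grid_centers",
    "render_field",
    "make_condition_images",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Physical layout of the microwell array and imaging scale.

    pitch_um : center-to-center microwell spacing.
    well_diameter_um : microwell (and hence comet head) diameter.
    um_per_px : physical pixel size of the raster (4x-objective regime).
    rotation_deg : in-plane lattice rotation, degrees counterclockwise.
    tail_l0_um / tail_l1_um : tail length scale L(f) = l0 + l1 * f.
    """

    pitch_um: float = 240.0
    well_diameter_um: float = 45.0
    um_per_px: float = 1.6
    rotation_deg: float = 0.0
    margin_pitches: float = 0.8
    # Tail length scale L(f) = l0 + l1*f, chosen so a fully migrated comet
    # (4 L plus the head) stays within one 240 um pitch and neighbors on the
    # lattice never overlap.
    tail_l0_um: float = 12.0
    tail_l1_um: float = 48.0
    tail_sigma_frac: float = 0.8  # transverse tail width / head sigma

    def __post_init__(self) -> None:
        if not self.pitch_um > self.well_diameter_um > 0:
            raise ValidationError("need pitch_um > well_diameter_um > 0")
        if self.um_per_px <= 0:
            raise ValidationError("um_per_px must be > 0")
        if abs(self.rotation_deg) > 5.0:
            raise ValidationError("rotation_deg must lie within +/-5 degrees")

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.um_per_px

    @property
    def head_sigma_px(self) -> float:
        return self.well_diameter_um / 4.0 / self.um_per_px

    def tail_scale_px(self, tail_frac: float) -> float:
        return (self.tail_l0_um + self.tail_l1_um * tail_frac) / self.um_per_px


@dataclass
class CometSpec:
    """Ground-truth description of one rendered comet."""

    row: int
    col: int
    cy: float  # px
    cx: float  # px
    budget: float  # total photons pre-noise
    tail_frac: float  # in [0, 1]
    occupied: bool = True

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValidationError("photon budget must be >= 0")
        if not 0.0 <= self.tail_frac <= 1.0:
            raise ValidationError("tail_frac must lie in [0, 1]")


@dataclass
class GroundTruthManifest:
    comets: pd.DataFrame  # row, col, cy, cx, budget, tail_frac, occupied
    geometry: ArrayGeometry
    seed: Optional[int]
    background: float
    noise: str

    def to_csv(self, path: str | Path) -> None:
        self.comets.to_csv(path, index=False)

    @property
    def occupied(self) -> pd.DataFrame:
        return self.comets[self.comets["occupied"]]


@dataclass
class CometField:
    """A single imaged field: 2-D intensity raster plus physical scale."""

    image: np.ndarray
    um_per_px: float
    axis: int = 1  # electrophoresis/tail axis (columns)
    manifest: Optional[GroundTruthManifest] = None
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """Write the raster as grayscale TIFF with a YAML sidecar."""
        path = Path(path)
        img = self.image
        if img.dtype.kind == "f":
            img = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(path, img)
        sidecar = {"um_per_px": float(self.um_per_px), "axis": int(self.axis)}
        sidecar.update(self.meta)
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "CometField":
        path = Path(path)
        img = tifffile.imread(path)
        meta = {}
        side = path.with_suffix(".yaml")
        if side.exists():
            meta = yaml.safe_load(side.read_text()) or {}
        return cls(
            image=np.asarray(img),
            um_per_px=float(meta.pop("um_per_px", 1.0)),
            axis=int(meta.pop("axis", 1)),
            meta=meta,
        )


def grid_centers(
    geometry: ArrayGeometry, n_rows: int, n_cols: int
) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Lattice centers (px) for an ``n_rows x n_cols`` grid, plus the raster
    shape that holds it with the configured margin.  The lattice is rotated
    by ``rotation_deg`` about the raster center."""
    p = geometry.pitch_px
    margin = geometry.margin_pitches * p
    height = int(math.ceil((n_rows - 1) * p + 2 * margin))
    width = int(math.ceil((n_cols - 1) * p + 2 * margin))
    ys = margin + p * np.arange(n_rows)
    xs = margin + p * np.arange(n_cols)
    cy, cx = np.meshgrid(ys, xs, indexing="ij")
    centers = np.stack([cy.ravel(), cx.ravel()], axis=1)
    theta = math.radians(geometry.rotation_deg)
    if theta:
        c0 = np.array([(height - 1) / 2.0, (width - 1) / 2.0])
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        centers = (centers - c0) @ rot.T + c0
    return centers, (height, width)


def _gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k


def _stamp(canvas: np.ndarray, cy: float, cx: float, kernel: np.ndarray,
           oy: int, ox: int) -> None:
    """Add ``kernel`` to ``canvas`` with its (oy, ox) element at the nearest
    pixel to (cy, cx), clipping at the raster borders."""
    iy, ix = int(round(cy)), int(round(cx))
    h, w = canvas.shape
    kh, kw = kernel.shape
    y0, x0 = iy - oy, ix - ox
    sy0, sx0 = max(0, -y0), max(0, -x0)
    sy1, sx1 = min(kh, h - y0), min(kw, w - x0)
    if sy1 <= sy0 or sx1 <= sx0:
        return
    canvas[y0 + sy0 : y0 + sy1, x0 + sx0 : x0 + sx1] += kernel[sy0:sy1, sx0:sx1]


def _render_comet(canvas: np.ndarray, spec: CometSpec, geometry: ArrayGeometry) -> None:
    sigma = geometry.head_sigma_px
    f = spec.tail_frac
    # Head: isotropic Gaussian, discrete-sum normalized.
    r = int(math.ceil(4 * sigma))
    k1 = _gaussian_kernel_1d(sigma, r)
    head = np.outer(k1, k1)
    head *= (1.0 - f) * spec.budget / head.sum()
    _stamp(canvas, spec.cy, spec.cx, head, r, r)
    if f <= 0:
        return
    # Tail: half-Gaussian along +x from the head center, Gaussian transverse.
    L = geometry.tail_scale_px(f)
    st = geometry.tail_sigma_frac * sigma
    rt = int(math.ceil(4 * st))
    nx = int(math.ceil(4 * L)) + 1
    hx = np.exp(-0.5 * (np.arange(nx) / L) ** 2)
    hy = _gaussian_kernel_1d(st, rt)
    tail = np.outer(hy, hx)
    tail *= f * spec.budget / tail.sum()
    _stamp(canvas, spec.cy, spec.cx, tail, rt, 0)


def render_field(
    specs: Sequence[CometSpec],
    geometry: ArrayGeometry = ArrayGeometry(),
    shape: Optional[Tuple[int, int]] = None,
    background: float = 20.0,
    noise: str = "poisson",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[CometField, GroundTruthManifest]:
    """Render one field from explicit per-comet specs.

    ``noise='poisson'`` produces a uint16 raster of Poisson counts around
    signal + background (bit-identical for identical seeds);
    ``noise='none'`` returns the float64 expectation (background included),
    used for oracle tests.
    """
    if shape is None:
        if specs:
            my = max(s.cy for s in specs) + geometry.margin_pitches * geometry.pitch_px
            mx = max(s.cx for s in specs) + geometry.margin_pitches * geometry.pitch_px
            shape = (int(math.ceil(my)), int(math.ceil(mx)))
        else:
            p = geometry.pitch_px
            shape = (int(4 * p), int(4 * p))
    canvas = np.zeros(shape, dtype=float)
    for s in specs:
        if not (0 <= s.cy < shape[0] and 0 <= s.cx < shape[1]):
            raise ValidationError(
                f"comet center ({s.cy:.1f}, {s.cx:.1f}) outside raster {shape}"
            )
        if s.occupied and s.budget > 0:
            _render_comet(canvas, s, geometry)
    clean = canvas + background
    if noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(seed)
        img: np.ndarray = rng.poisson(clean).astype(np.uint32)
        img = np.minimum(img, np.iinfo(np.uint16).max).astype(np.uint16)
    elif noise == "none":
        img = clean
    else:
        raise ValidationError(f"unknown noise model {noise!r}")
    comets = pd.DataFrame(
        {
            "row": [s.row for s in specs],
            "col": [s.col for s in specs],
            "cy": [s.cy for s in specs],
            "cx": [s.cx for s in specs],
            "budget": [s.budget for s in specs],
            "tail_frac": [s.tail_frac for s in specs],
            "occupied": [s.occupied for s in specs],
        }
    )
    manifest = GroundTruthManifest(
        comets=comets, geometry=geometry, seed=seed, background=background, noise=noise
    )
    fld = CometField(
        image=img,
        um_per_px=geometry.um_per_px,
        manifest=manifest,
        meta={"seed": seed, "background": background, "noise": noise},
    )
    return fld, manifest


def make_condition_images(
    scenario: DamageScenario,
    preset: AgentPreset,
    n_wells: int = 3,
    grid_shape: Tuple[int, int] = (8, 6),
    occupancy: float = 0.9,
    kappa: float = 60.0,
    well_sd: float = 1.0,
    budget: float = 2.0e5,
    budget_cv: float = 0.1,
    geometry: ArrayGeometry = ArrayGeometry(),
    background: float = 20.0,
    noise: str = "poisson",
    seed: Optional[int] = None,
    params: ModelParams = DEFAULT_PARAMS,
) -> List[Tuple[CometField, GroundTruthManifest]]:
    """Simulate replicate wells for one biological condition.

    The damage model supplies the condition's true mean % tail DNA; each
    well jitters that mean by ``Normal(0, well_sd)`` (percentage points) and
    each comet draws its tail fraction from a Beta distribution with that
    mean and concentration ``kappa`` (``kappa = 0`` means no dispersion).
    Microwell occupancy is Bernoulli(``occupancy``); photon budgets are
    lognormal around ``budget`` with CV ``budget_cv``.
    """
    if n_wells < 1 or min(grid_shape) < 1:
        raise ValidationError("need n_wells >= 1 and a nonempty grid")
    rng = np.random.default_rng(seed)
    true_pct = scenario_tail_pct(scenario, preset, params)
    n_rows, n_cols = grid_shape
    centers, shape = grid_centers(geometry, n_rows, n_cols)
    out = []
    for _ in range(n_wells):
        well_mean = float(np.clip(true_pct + rng.normal(0.0, well_sd), 0.5, 99.5))
        m = well_mean / 100.0
        specs = []
        for idx, (cy, cx) in enumerate(centers):
            occ = bool(rng.random() < occupancy)
            if kappa > 0:
                f = float(rng.beta(m * kappa, (1.0 - m) * kappa))
            else:
                f = m
            b = float(budget * rng.lognormal(0.0, budget_cv)) if budget_cv > 0 else budget
            specs.append(
                CometSpec(
                    row=idx // n_cols,
                    col=idx % n_cols,
                    cy=float(cy),
                    cx=float(cx),
                    budget=b,
                    tail_frac=f,
                    occupied=occ,
                )
            )
        out.append(
            render_field(
                specs,
                geometry=geometry,
                shape=shape,
                background=background,
                noise=noise,
                rng=rng,
            )
        )
    return out
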