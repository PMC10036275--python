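"""Synthetic post-fire scene generator.

Emulates drone photogrammetry acquisitions over fixed-radius conifer plots:
a colored, height-normalized point cloud (~640 points/m²), a ~4.4-cm RGB
orthomosaic rendered from it, and a ground-truth stem table. Crowns are cones;
foliage color encodes fire damage — green below-noise-free GLI > 0 for living
needles, brown/red (GLI < 0) for scorched needles, sparse dark bole points
where the crown was consumed. Shadowing and sensor noise are modeled as a
multiplicative darkening of a random point subset followed by additive
per-band Gaussian noise.

The generator is the test substrate for every downstream stage: each scene
carries per-point provenance labels so filters and classifiers can be checked
against the exact rule that colored each point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cloud import ColoredPointCloud, RasterGrid

__all__ = [
    "TreeTruth",
    "SceneConfig",
    "Scene",
    "generate_tree_points",
    "generate_scene",
    "render_orthomosaic",
    "random_truths",
    "LIVING_COLOR",
    "SCORCHED_COLOR",
    "BOLE_COLOR",
    "GROUND_COLOR",
]

# Palette conventions: values chosen only so that sign(GLI) encodes the class
# (strictly positive for living foliage, strictly negative for everything else;
# an exact zero would be sign-ambiguous for the downstream rules).
LIVING_COLOR = (60, 140, 60)  # GLI = +0.40
SCORCHED_COLOR = (150, 90, 50)  # GLI = -0.053
BOLE_COLOR = (40, 34, 30)  # GLI = -0.015
GROUND_COLOR = (115, 95, 85)  # GLI = -0.026

CROWN_CLASSES = ("dominant", "codominant", "intermediate", "suppressed")

# point-kind codes in Scene.point_kind
KIND_GROUND = 0
KIND_LIVING = 1
KIND_SCORCHED = 2
KIND_BOLE = 3


@dataclass
class TreeTruth:
    """Ground truth for one simulated tree.

    ``scorch_height`` is meters above ground: 0 means unburned, total_height
    means fully scorched. ``consumed_above`` (optional) is the height above
    which foliage was consumed by the fire and no foliage points exist.
    """

    tree_id: int
    stem_x: float
    stem_y: float
    total_height: float
    crown_base_height: float
    scorch_height: float
    crown_radius: float
    crown_class: str = "codominant"
    consumed_above: Optional[float] = None

    def validate(self) -> None:
        if not self.total_height > 2:
            raise ValueError(f"total_height must exceed 2 m, got {self.total_height}")
        if not 0 <= self.crown_base_height < self.total_height:
            raise ValueError(
                f"crown_base_height must be in [0, total_height), got "
                f"{self.crown_base_height}"
            )
        if not 0 <= self.scorch_height <= self.total_height:
            raise ValueError(
                f"scorch_height must be in [0, total_height], got {self.scorch_height}"
            )
        if not self.crown_radius > 0:
            raise ValueError(f"crown_radius must be positive, got {self.crown_radius}")
        if self.crown_class not in CROWN_CLASSES:
            raise ValueError(f"crown_class must be one of {CROWN_CLASSES}")
        if self.consumed_above is not None and not (
            self.crown_base_height <= self.consumed_above <= self.total_height
        ):
            raise ValueError(
                f"consumed_above must lie within the crown, got {self.consumed_above}"
            )

    @property
    def crown_length(self) -> float:
        return self.total_height - self.crown_base_height

    @property
    def burned(self) -> bool:
        return self.scorch_height > self.crown_base_height

    @property
    def cls_true(self) -> float:
        """True crown length scorched, m."""
        return float(
            np.clip(self.scorch_height - self.crown_base_height, 0, self.crown_length)
        )

    @property
    def cvs_true(self) -> float:
        """True crown volume scorched, percent, under conical crown geometry."""
        cl, cls = self.crown_length, self.cls_true
        return float(np.clip(100.0 * cls * (2 * cl - cls) / cl**2, 0.0, 100.0))


@dataclass
class SceneConfig:
    """Acquisition parameters of a simulated plot."""

    plot_radius: float = 11.28  # m, fixed-radius field plot
    point_density: float = 640.0  # points / m²
    ortho_cell: float = 0.0441  # m, orthomosaic resolution
    n_trees: int = 12
    burned_fraction: float = 0.5
    color_noise_sd: float = 10.0  # 8-bit counts per band
    shadow_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("plot_radius", "point_density", "ortho_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("burned_fraction", "shadow_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.color_noise_sd < 0:
            raise ValueError("color_noise_sd must be non-negative")


@dataclass
class Scene:
    """A generated scene: cloud + truth table + per-point provenance."""

    cloud: ColoredPointCloud
    truths: pd.DataFrame
    point_tree: np.ndarray  # tree_id per point, -1 for ground
    point_kind: np.ndarray  # KIND_* code per point

    def __iter__(self):  # allow (cloud, truths) unpacking
        return iter((self.cloud, self.truths))


def _apply_color_model(colors: np.ndarray, cfg: SceneConfig, rng) -> np.ndarray:
    """Shadow a random subset (multiplicative darkening), then add noise."""
    colors = colors.astype(float)
    n = len(colors)
    if cfg.shadow_fraction > 0 and n:
        n_shadow = int(round(cfg.shadow_fraction * n))
        idx = rng.choice(n, size=n_shadow, replace=False)
        colors[idx] *= rng.uniform(0.1, 0.4, size=(n_shadow, 1))
    if cfg.color_noise_sd > 0 and n:
        colors += rng.normal(0, cfg.color_noise_sd, size=colors.shape)
    return np.clip(np.rint(colors), 0, 255).astype(int)


def generate_tree_points(
    truth: TreeTruth, cfg: SceneConfig, seed=None
) -> tuple[ColoredPointCloud, np.ndarray]:
    """Sample the colored points of one tree crown.

    Foliage fills a cone from (crown_base_height, crown_radius) to
    (total_height, 0); height is sampled uniformly along the crown so that
    thin vertical slices are evenly populated, and radial placement within
    each slice is biased toward the cone surface (density ∝ radius³), since
    nadir photogrammetry reconstructs the visible outer envelope of the
    crown far more densely than its interior.

    Returns the cloud and a per-point kind array (KIND_LIVING, KIND_SCORCHED
    or KIND_BOLE).
    """
    truth.validate()
    cfg.validate()
    rng = np.random.default_rng(seed)

    n_foliage = max(int(round(cfg.point_density * np.pi * truth.crown_radius**2)), 20)
    z = rng.uniform(truth.crown_base_height, truth.total_height, n_foliage)
    # cone taper: radius shrinks linearly to 0 at the apex
    taper = (truth.total_height - z) / max(truth.crown_length, 1e-9)
    rad = truth.crown_radius * taper * rng.uniform(0, 1, n_foliage) ** 0.25
    ang = rng.uniform(0, 2 * np.pi, n_foliage)
    x = truth.stem_x + rad * np.cos(ang)
    y = truth.stem_y + rad * np.sin(ang)

    scorched = z < truth.scorch_height
    kind = np.where(scorched, KIND_SCORCHED, KIND_LIVING)

    if truth.consumed_above is not None:
        keep = z <= truth.consumed_above
        x, y, z, kind = x[keep], y[keep], z[keep], kind[keep]
        # sparse dark bole points where foliage was consumed
        span = truth.total_height - truth.consumed_above
        n_bole = max(int(round(40 * span)), 5)
        zb = rng.uniform(truth.consumed_above, truth.total_height, n_bole)
        rb = 0.15 * np.sqrt(rng.uniform(0, 1, n_bole))
        ab = rng.uniform(0, 2 * np.pi, n_bole)
        x = np.concatenate([x, truth.stem_x + rb * np.cos(ab)])
        y = np.concatenate([y, truth.stem_y + rb * np.sin(ab)])
        z = np.concatenate([z, zb])
        kind = np.concatenate([kind, np.full(n_bole, KIND_BOLE)])

    palette = np.array([GROUND_COLOR, LIVING_COLOR, SCORCHED_COLOR, BOLE_COLOR])
    colors = _apply_color_model(palette[kind], cfg, rng)
    cloud = ColoredPointCloud(x, y, z, colors[:, 0], colors[:, 1], colors[:, 2])
    return cloud, kind


def generate_scene(truths: list[TreeTruth], cfg: SceneConfig) -> Scene:
    """Assemble a plot scene: per-tree clouds plus ground points near z = 0.

    Fully determined by ``cfg.seed``. Ground points are kept at z in
    [0, 0.2] m so the 2-m height filter removes them downstream.
    """
    cfg.validate()
    seen: set[tuple[float, float]] = set()
    for t in truths:
        t.validate()
        key = (round(t.stem_x, 6), round(t.stem_y, 6))
        if key in seen:
            warnings.warn(f"duplicate stem position {key}", stacklevel=2)
        seen.add(key)
        if np.hypot(t.stem_x, t.stem_y) > cfg.plot_radius:
            raise ValueError(f"tree {t.tree_id} stem outside plot radius")

    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.spawn(len(truths) + 1)
    rng_ground = np.random.default_rng(child_seeds[-1])

    clouds, kinds, tree_ids = [], [], []
    for t, cs in zip(truths, child_seeds):
        cl, kind = generate_tree_points(t, cfg, seed=cs)
        clouds.append(cl)
        kinds.append(kind)
        tree_ids.append(np.full(len(cl), t.tree_id))

    n_ground = int(round(cfg.point_density * np.pi * cfg.plot_radius**2))
    rad = cfg.plot_radius * np.sqrt(rng_ground.uniform(0, 1, n_ground))
    ang = rng_ground.uniform(0, 2 * np.pi, n_ground)
    gx, gy = rad * np.cos(ang), rad * np.sin(ang)
    gz = rng_ground.uniform(0, 0.2, n_ground)
    gcol = _apply_color_model(
        np.tile(GROUND_COLOR, (n_ground, 1)), cfg, rng_ground
    )
    clouds.append(
        ColoredPointCloud(gx, gy, gz, gcol[:, 0], gcol[:, 1], gcol[:, 2])
    )
    kinds.append(np.full(n_ground, KIND_GROUND))
    tree_ids.append(np.full(n_ground, -1))

    cloud = ColoredPointCloud.concatenate(clouds)
    table = pd.DataFrame(
        {
            "tree_id": [t.tree_id for t in truths],
            "stem_x": [t.stem_x for t in truths],
            "stem_y": [t.stem_y for t in truths],
            "total_height": [t.total_height for t in truths],
            "crown_base_height": [t.crown_base_height for t in truths],
            "scorch_height": [t.scorch_height for t in truths],
            "crown_radius": [t.crown_radius for t in truths],
            "crown_class": [t.crown_class for t in truths],
            "burned": [t.burned for t in truths],
            "cvs_true": [t.cvs_true for t in truths],
        }
    )
    return Scene(cloud, table, np.concatenate(tree_ids), np.concatenate(kinds))


def render_orthomosaic(
    cloud: ColoredPointCloud, cell: float, ground_color=GROUND_COLOR
) -> RasterGrid:
    """Render a 3-band orthomosaic: each cell takes its highest point's color.

    A real orthomosaic is a gap-free image, so cells that receive no point
    borrow the color of the nearest painted cell (within 3 cells); cells
    farther from any point take the ground color. A stand-in for the stitched
    photogrammetric orthomosaic, which is similarly a top-of-canopy view.
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    if len(cloud) == 0:
        raise ValueError("cannot render an empty cloud")
    x0, y0 = cloud.x.min(), cloud.y.min()
    n_cols = max(int(np.ceil((cloud.x.max() - x0) / cell)), 1)
    n_rows = max(int(np.ceil((cloud.y.max() - y0) / cell)), 1)
    img = np.tile(np.asarray(ground_color, dtype=np.uint8), (n_rows, n_cols, 1))
    grid = RasterGrid(img, x0, y0, cell)
    row, col = grid.cell_index(cloud.x, cloud.y)
    row, col = np.clip(row, 0, n_rows - 1), np.clip(col, 0, n_cols - 1)
    order = np.argsort(cloud.z, kind="stable")  # highest written last wins
    img[row[order], col[order]] = cloud.colors[order]
    painted = np.zeros((n_rows, n_cols), dtype=bool)
    painted[row, col] = True
    if not painted.all():
        from scipy.ndimage import distance_transform_edt

        dist, idx = distance_transform_edt(~painted, return_indices=True)
        near = (~painted) & (dist <= 3.0)
        img[near] = img[idx[0][near], idx[1][near]]
    return grid


def random_truths(
    n_trees: int,
    cfg: SceneConfig,
    seed=None,
    burned_fraction: Optional[float] = None,
    min_spacing: float = 0.0,
    height_range: tuple[float, float] = (8.0, 24.0),
    consumed_fraction: float = 0.0,
    full_scorch_fraction: float = 0.5,
    partial_scorch_range: tuple[float, float] = (0.55, 1.0),
) -> list[TreeTruth]:
    """Draw a plausible mixed-severity conifer stand.

    Stems are placed uniformly in the plot (rejection-sampled to honor
    ``min_spacing``); heights are uniform over ``height_range``; crown base
    sits at 15-35% of total height; crown radius scales weakly with height.

    A ``burned_fraction`` of trees are fire-damaged. Post-fire severity in
    conifer stands is strongly top-heavy — around half of damaged trees carry
    complete crown scorch — so ``full_scorch_fraction`` of burned trees are
    fully scorched (a ``consumed_fraction`` of those additionally lose their
    upper foliage to consumption), and the rest get a scorch height uniform
    over ``partial_scorch_range`` as a fraction of crown length above the
    crown base. The default lower bound of 0.55 keeps the damage visible in
    a nadir view: a cone scorched over less than half its length from below
    shows mostly green foliage from above and is not detectably burned in an
    orthomosaic, which is the known failure pathway of top-down severity
    assessment rather than a condition the generator emulates by default.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if burned_fraction is None:
        burned_fraction = cfg.burned_fraction
    truths: list[TreeTruth] = []
    placed: list[tuple[float, float]] = []
    for i in range(n_trees):
        for _ in range(2000):
            r = cfg.plot_radius * np.sqrt(rng.uniform())
            a = rng.uniform(0, 2 * np.pi)
            sx, sy = r * np.cos(a), r * np.sin(a)
            if all(np.hypot(sx - px, sy - py) >= min_spacing for px, py in placed):
                break
        else:
            raise RuntimeError("could not place stems at requested spacing")
        placed.append((sx, sy))
        th = rng.uniform(*height_range)
        cbh = rng.uniform(0.15, 0.35) * th
        radius = np.clip(0.08 * th + rng.uniform(0.4, 1.0), 0.8, 3.0)
        burned = rng.uniform() < burned_fraction
        consumed = None
        if burned:
            if rng.uniform() < full_scorch_fraction:
                scorch = th
                if rng.uniform() < consumed_fraction:
                    consumed = rng.uniform(0.5 * (cbh + th), th)
            else:
                lo, hi = partial_scorch_range
                scorch = cbh + rng.uniform(lo, hi) * (th - cbh)
        else:
            scorch = 0.0
        klass = CROWN_CLASSES[int(rng.integers(0, 4))]
        truths.append(
            TreeTruth(
                tree_id=i + 1,
                stem_x=float(sx),
                stem_y=float(sy),
                total_height=float(th),
                crown_base_height=float(cbh),
                scorch_height=float(scorch),
                crown_radius=float(radius),
                crown_class=klass,
                consumed_above=consumed,
            )
        )
    return truths
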