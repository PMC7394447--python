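"""Procedural generation of vernier / shape-group stimuli.

All images are float64 grayscale arrays in [0, 1], drawn as 1-px outlines
with a single foreground intensity (no anti-aliasing) so pixel counts are
exactly testable. Geometry is fully configurable; the defaults put one
shape inside the receptive field of a primary capsule of the default
network configuration.

Experiment 1 uses a vernier plus six flanker shape classes shown in groups
of 1/3/5. Experiment 2 uses verniers, vertical line groups, and pairs of
facing perspective cuboids (plus scrambled cuboids built from the same
line segments).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

EXP1_SHAPES = ("square", "circle", "hexagon", "octagon", "diamond", "star")
EXP1_CLASSES = ("vernier",) + EXP1_SHAPES
EXP2_CLASSES = ("vernier", "lines", "cuboids", "scrambled_cuboids")

OFFSET_DIRECTIONS = ("left", "right")


# ---------------------------------------------------------------------- types
@dataclass
class StimulusConfig:
    """Pixel geometry of the canvas and all stimulus elements."""

    height: int = 44
    width: int = 95   # odd width keeps centered stimuli mirror-symmetric
    shape_size: int = 14          # bounding box of one flanker shape
    group_spacing: int = 2        # gap between shapes in a group
    bar_length: int = 4           # one vernier bar
    bar_width: int = 2
    bar_gap: int = 2              # vertical gap between the two bars
    offset_px: int = 3            # horizontal vernier offset
    foreground: float = 1.0
    location_jitter: int = 3      # centering jitter for shape groups
    vernier_jitter: tuple[int, int] | None = None  # (x, y); None -> wide default
    # experiment 2 geometry (flanker line length matches vernier extent,
    # mirroring the 84' flanker / 40'+4'+40' vernier of the human stimuli)
    flanker_line_length: int = 10
    flanker_distance: int = 4     # vernier center to flanking line
    cuboid_width: int = 7
    cuboid_depth: int = 3         # 135-degree oblique extent

    def __post_init__(self):
        if self.vernier_jitter is None:
            self.vernier_jitter = (self.location_jitter, self.location_jitter)

    @property
    def vernier_patch_shape(self) -> tuple[int, int]:
        return (2 * self.bar_length + self.bar_gap,
                self.bar_width + self.offset_px)

    @classmethod
    def small(cls) -> "StimulusConfig":
        """Reduced canvas for CPU-scale training runs and tests."""
        return cls(height=32, width=71, shape_size=11, group_spacing=1,
                   bar_length=3, location_jitter=2,
                   flanker_line_length=8, flanker_distance=3,
                   cuboid_width=6, cuboid_depth=3)


@dataclass
class AugmentationConfig:
    noise_mean: float = 0.0
    noise_sd_range: tuple[float, float] = (0.0, 0.2)
    brightness_shift_range: tuple[float, float] = (-0.1, 0.1)
    contrast_factor_range: tuple[float, float] = (0.6, 1.2)

    def __post_init__(self):
        if self.noise_sd_range[0] < 0:
            raise ValueError("noise_sd_range lower bound must be >= 0")
        if self.contrast_factor_range[0] < 0:
            raise ValueError("contrast_factor_range lower bound must be >= 0")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        return cls(noise_sd_range=(0.0, 0.0), brightness_shift_range=(0.0, 0.0),
                   contrast_factor_range=(1.0, 1.0))


@dataclass
class StimulusFrame:
    image: np.ndarray
    shape_class: str
    n_repetitions: int
    vernier_offset: str                 # 'left' | 'right' | 'none'
    target_location: tuple[int, int]    # (x, y) centroid in pixels
    condition_name: str = ""

    def validate(self) -> None:
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities outside [0, 1]")
        if self.vernier_offset not in ("left", "right", "none"):
            raise ValueError(f"bad vernier_offset {self.vernier_offset!r}")


@dataclass
class Exp2ShapeSpec:
    kind: str                       # vernier | line_group | cuboid_pair | scrambled_cuboid_pair
    line_count: int = 2
    pair_spacing: int = 2

    def __post_init__(self):
        kinds = ("vernier", "line_group", "cuboid_pair", "scrambled_cuboid_pair")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if not 1 <= self.pair_spacing <= 6:
            raise ValueError("pair_spacing must be within [1, 6]")


@dataclass
class TestCondition:
    """One test configuration: flanker layout plus vernier placement."""

    __test__ = False  # not a pytest class

    name: str
    flanker_layout: tuple[str, ...]     # shape classes left-to-right; () = none
    vernier_placement: str              # 'inside' | 'outside' | 'alone'
    experiment: int = 1
    baseline_name: str | None = None    # matching central-flanker-alone condition

    def __post_init__(self):
        if self.vernier_placement not in ("inside", "outside", "alone"):
            raise ValueError(f"bad placement {self.vernier_placement!r}")
        if self.vernier_placement == "alone" and self.flanker_layout:
            raise ValueError("'alone' conditions cannot carry flankers")


# ------------------------------------------------------------------- drawing
def _bresenham(mask: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> None:
    """Draw a 1-px line segment onto a boolean mask (endpoints inclusive)."""
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    if dc >= dr:
        err = dc // 2
        r = r0
        for c in range(c0, c1 + sc, sc):
            mask[r, c] = True
            err -= dr
            if err < 0:
                r += sr
                err += dc
    else:
        err = dr // 2
        c = c0
        for r in range(r0, r1 + sr, sr):
            mask[r, c] = True
            err -= dc
            if err < 0:
                c += sc
                err += dr


def _polygon_patch(size: int, vertices: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    pts = [(int(round(r)), int(round(c))) for r, c in vertices]
    for (r0, c0), (r1, c1) in zip(pts, pts[1:] + pts[:1]):
        _bresenham(mask, r0, c0, r1, c1)
    return mask


def shape_patch(shape_class: str, size: int) -> np.ndarray:
    """Boolean outline of one flanker shape inside a size x size box."""
    r = (size - 1) / 2.0
    c = r
    if shape_class == "square":
        mask = np.zeros((size, size), dtype=bool)
        mask[0, :] = mask[-1, :] = True
        mask[:, 0] = mask[:, -1] = True
        return mask
    if shape_class == "circle":
        yy, xx = np.mgrid[0:size, 0:size]
        dist = np.sqrt((yy - r) ** 2 + (xx - c) ** 2)
        return np.abs(dist - r) < 0.5
    if shape_class == "diamond":
        yy, xx = np.mgrid[0:size, 0:size]
        return np.abs(yy - r) + np.abs(xx - c) == round(r)
    if shape_class in ("hexagon", "octagon"):
        n = 6 if shape_class == "hexagon" else 8
        phase = np.pi / n  # flat-ish top
        verts = [(r + r * np.sin(2 * np.pi * k / n + phase),
                  c + r * np.cos(2 * np.pi * k / n + phase)) for k in range(n)]
        return _polygon_patch(size, verts)
    if shape_class == "star":
        verts = []
        for k in range(10):
            radius = r if k % 2 == 0 else 0.45 * r
            ang = -np.pi / 2 + k * np.pi / 5
            verts.append((r + radius * np.sin(ang), c + radius * np.cos(ang)))
        return _polygon_patch(size, verts)
    raise ValueError(f"unknown shape class {shape_class!r}")


def vernier_patch(cfg: StimulusConfig, direction: str) -> np.ndarray:
    """Two vertical bars with a horizontal offset; 'right' mirrors 'left'."""
    if direction not in OFFSET_DIRECTIONS:
        raise ValueError(f"direction must be in {OFFSET_DIRECTIONS}")
    h, w = cfg.vernier_patch_shape
    mask = np.zeros((h, w), dtype=bool)
    # left: top bar on the left edge, bottom bar on the right edge
    mask[:cfg.bar_length, :cfg.bar_width] = True
    mask[cfg.bar_length + cfg.bar_gap:, w - cfg.bar_width:] = True
    if direction == "right":
        mask = mask[:, ::-1]
    return mask


def _cuboid_segments(cfg: StimulusConfig) -> list[list[tuple[int, int, int, int]]]:
    """Pixel-disjoint line segments of a left-side perspective cuboid.

    Returns segments as (r0, c0, r1, c1) in a patch of shape
    (line_length + depth) x (cuboid_width + depth + 1). The innermost
    (rightmost) vertical edge equals the flanking line of the line
    condition. Segments are trimmed at shared corners so that the total
    pixel count equals the sum of per-segment counts, which keeps the
    scrambled variant's pixel count identical by construction.
    """
    L, wc, d = cfg.flanker_line_length, cfg.cuboid_width, cfg.cuboid_depth
    W = wc + d + 1
    inner, outer = W - 1, W - 1 - wc
    segs = [
        (d, inner, d + L - 1, inner),               # inner vertical (the line)
        (d, outer, d + L - 1, outer),               # outer vertical
        (d, outer + 1, d, inner - 1),               # front top edge
        (d + L - 1, outer + 1, d + L - 1, inner - 1),   # front bottom edge
        (d - 1, inner - 1, 0, inner - d),           # oblique from top-inner
        (d - 1, outer - 1, 0, outer - d),           # oblique from top-outer
        (0, outer - d + 1, 0, inner - d - 1),       # back top edge
        (d + L - 2, outer - 1, L - 1, outer - d),   # oblique from bottom-outer
        (1, outer - d, L - 2, outer - d),           # back outer vertical
    ]
    return segs


def cuboid_patch(cfg: StimulusConfig, side: str) -> np.ndarray:
    """One perspective cuboid; 'left' has its line edge on the right."""
    L, wc, d = cfg.flanker_line_length, cfg.cuboid_width, cfg.cuboid_depth
    mask = np.zeros((L + d, wc + d + 1), dtype=bool)
    for r0, c0, r1, c1 in _cuboid_segments(cfg):
        _bresenham(mask, r0, c0, r1, c1)
    if side == "right":
        mask = mask[:, ::-1]
    elif side != "left":
        raise ValueError("side must be 'left' or 'right'")
    return mask


def scrambled_cuboid_patch(cfg: StimulusConfig, side: str,
                           rng: np.random.Generator) -> np.ndarray:
    """Same segments as the cuboid, translated to random disjoint positions."""
    L, wc, d = cfg.flanker_line_length, cfg.cuboid_width, cfg.cuboid_depth
    H, W = L + d, wc + d + 1
    seg_masks = []
    for r0, c0, r1, c1 in _cuboid_segments(cfg):
        m = np.zeros((H, W), dtype=bool)
        _bresenham(m, r0, c0, r1, c1)
        rows, cols = np.nonzero(m)
        seg_masks.append((rows - rows.min(), cols - cols.min(),
                          rows.max() - rows.min(), cols.max() - cols.min()))
    order = np.argsort([-(len(s[0])) for s in seg_masks])  # largest first
    for _restart in range(50):
        out = np.zeros((H, W), dtype=bool)
        ok = True
        for idx in order:
            rows, cols, hh, ww = seg_masks[idx]
            placed = False
            for _try in range(100):
                r = int(rng.integers(0, H - hh))
                c = int(rng.integers(0, W - ww))
                if not out[rows + r, cols + c].any():
                    out[rows + r, cols + c] = True
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            if side == "right":
                out = out[:, ::-1]
            return out
    raise RuntimeError("could not place scrambled cuboid segments")


# ------------------------------------------------------------------ canvases
def _blank(cfg: StimulusConfig) -> np.ndarray:
    return np.zeros((cfg.height, cfg.width), dtype=np.float64)


def _paste(canvas: np.ndarray, patch: np.ndarray, center_rc: tuple[int, int],
           intensity: float) -> None:
    """Additively paste a boolean patch centered at (row, col); clip to 1."""
    h, w = patch.shape
    r0 = center_rc[0] - h // 2
    c0 = center_rc[1] - w // 2
    if r0 < 0 or c0 < 0 or r0 + h > canvas.shape[0] or c0 + w > canvas.shape[1]:
        raise ValueError(
            f"patch {h}x{w} at center {center_rc} exceeds canvas "
            f"{canvas.shape[0]}x{canvas.shape[1]}")
    region = canvas[r0:r0 + h, c0:c0 + w]
    region += patch * intensity
    np.clip(region, 0.0, 1.0, out=region)


def _centroid(image: np.ndarray) -> tuple[int, int]:
    rows, cols = np.nonzero(image)
    if len(rows) == 0:
        return (image.shape[1] // 2, image.shape[0] // 2)
    return (int(round(cols.mean())), int(round(rows.mean())))


# ---------------------------------------------------------------- operations
def render_vernier(offset_direction: str, cfg: StimulusConfig | None = None,
                   center: tuple[int, int] | None = None) -> StimulusFrame:
    """A lone vernier: two vertical bars with a horizontal offset."""
    cfg = cfg or StimulusConfig()
    canvas = _blank(cfg)
    rc = (cfg.height // 2, cfg.width // 2) if center is None else (center[1], center[0])
    _paste(canvas, vernier_patch(cfg, offset_direction), rc, cfg.foreground)
    return StimulusFrame(canvas, "vernier", 1, offset_direction,
                         _centroid(canvas), "vernier_alone")


def render_shape_group(shape_class: str, n_repetitions: int,
                       spacing: int | None = None,
                       cfg: StimulusConfig | None = None,
                       center: tuple[int, int] | None = None) -> StimulusFrame:
    """A horizontal group of identical shapes, roughly centered."""
    cfg = cfg or StimulusConfig()
    if n_repetitions not in (1, 3, 5):
        raise ValueError("n_repetitions must be 1, 3 or 5")
    if shape_class not in EXP1_SHAPES:
        raise ValueError(f"shape_class must be one of {EXP1_SHAPES}")
    spacing = cfg.group_spacing if spacing is None else spacing
    patch = shape_patch(shape_class, cfg.shape_size)
    pitch = cfg.shape_size + spacing
    canvas = _blank(cfg)
    rc = (cfg.height // 2, cfg.width // 2) if center is None else (center[1], center[0])
    for i in range(n_repetitions):
        offset = (i - (n_repetitions - 1) / 2) * pitch
        _paste(canvas, patch, (rc[0], rc[1] + int(round(offset))), cfg.foreground)
    return StimulusFrame(canvas, shape_class, n_repetitions, "none",
                         _centroid(canvas), f"{shape_class}_{n_repetitions}")


def render_exp2_stimulus(spec: Exp2ShapeSpec, cfg: StimulusConfig | None = None,
                         rng: np.random.Generator | None = None,
                         center: tuple[int, int] | None = None) -> StimulusFrame:
    """One experiment-2 training stimulus (lines / cuboid pair / scramble)."""
    cfg = cfg or StimulusConfig()
    rng = rng or np.random.default_rng()
    if spec.kind == "vernier":
        direction = OFFSET_DIRECTIONS[int(rng.integers(0, 2))]
        return render_vernier(direction, cfg, center)
    canvas = _blank(cfg)
    rc = (cfg.height // 2, cfg.width // 2) if center is None else (center[1], center[0])
    if spec.kind == "line_group":
        line = np.ones((cfg.flanker_line_length, 1), dtype=bool)
        pitch = 1 + spec.pair_spacing
        start = rc[1] - round((spec.line_count - 1) * pitch / 2)
        for i in range(spec.line_count):
            _paste(canvas, line, (rc[0], start + i * pitch), cfg.foreground)
        label = "lines"
        n_rep = spec.line_count
    else:
        scram = spec.kind == "scrambled_cuboid_pair"
        left = (scrambled_cuboid_patch(cfg, "left", rng) if scram
                else cuboid_patch(cfg, "left"))
        right = (scrambled_cuboid_patch(cfg, "right", rng) if scram
                 else cuboid_patch(cfg, "right"))
        # inner edges separated by pair_spacing background pixels
        w = left.shape[1]
        left_inner = rc[1] - (spec.pair_spacing + 1) // 2 - 1
        right_inner = left_inner + spec.pair_spacing + 1
        lc_center = left_inner - (w - 1 - w // 2)
        rc_center = right_inner + w // 2
        _paste(canvas, left, (rc[0], lc_center), cfg.foreground)
        _paste(canvas, right, (rc[0], rc_center), cfg.foreground)
        label = "scrambled_cuboids" if scram else "cuboids"
        n_rep = 2
    return StimulusFrame(canvas, label, n_rep, "none", _centroid(canvas),
                         spec.kind)


def _layout_centers(n: int, cfg: StimulusConfig,
                    center_rc: tuple[int, int]) -> list[tuple[int, int]]:
    pitch = cfg.shape_size + cfg.group_spacing
    return [(center_rc[0], center_rc[1] + int(round((i - (n - 1) / 2) * pitch)))
            for i in range(n)]


def compose_test_stimulus(vernier: StimulusFrame, condition: TestCondition,
                          cfg: StimulusConfig | None = None,
                          rng: np.random.Generator | None = None) -> StimulusFrame:
    """Place a vernier inside / outside a flanker configuration."""
    cfg = cfg or StimulusConfig()
    if condition.vernier_placement == "alone" and not condition.flanker_layout:
        out = replace(vernier, condition_name=condition.name)
        return out
    canvas = _blank(cfg)
    center_rc = (cfg.height // 2, cfg.width // 2)
    flanker_rc = center_rc
    if condition.vernier_placement == "outside":
        # the vernier keeps its usual (trained) central position and the
        # flanker configuration moves up until the target is clear of its
        # bounding region
        dy = cfg.shape_size // 2 + (2 * cfg.bar_length + cfg.bar_gap) // 2 + 2
        flanker_rc = (center_rc[0] - dy, center_rc[1])
        if flanker_rc[0] - cfg.shape_size // 2 < 0:
            raise ValueError("canvas too short for the vernier-outside control")
    if condition.experiment == 1:
        centers = _layout_centers(len(condition.flanker_layout), cfg, flanker_rc)
        for shape, rc in zip(condition.flanker_layout, centers):
            _paste(canvas, shape_patch(shape, cfg.shape_size), rc, cfg.foreground)
    else:
        rng = rng or np.random.default_rng()
        kind = condition.flanker_layout[0]
        if kind == "lines":
            line = np.ones((cfg.flanker_line_length, 1), dtype=bool)
            for dc in (-cfg.flanker_distance, cfg.flanker_distance):
                _paste(canvas, line, (flanker_rc[0], flanker_rc[1] + dc),
                       cfg.foreground)
        elif kind in ("cuboids", "scrambled_cuboids"):
            for side, sign in (("left", -1), ("right", 1)):
                patch = (cuboid_patch(cfg, side) if kind == "cuboids"
                         else scrambled_cuboid_patch(cfg, side, rng))
                w = patch.shape[1]
                # align the inner edge at +-flanker_distance from the center
                if side == "left":
                    cc = flanker_rc[1] - cfg.flanker_distance - (w - 1 - w // 2)
                else:
                    cc = flanker_rc[1] + cfg.flanker_distance + w // 2
                _paste(canvas, patch, (flanker_rc[0], cc), cfg.foreground)
        else:
            raise ValueError(f"unknown experiment-2 flanker {kind!r}")
    flanker_pixels = canvas > 0
    bbox_rows, bbox_cols = np.nonzero(flanker_pixels)
    vmask = vernier.image > 0
    vrows, vcols = np.nonzero(vmask)
    vpatch = vmask[vrows.min():vrows.max() + 1, vcols.min():vcols.max() + 1]
    target_rc = center_rc
    if condition.vernier_placement == "outside":
        # sanity: the target must be clear of the flanker bounding region
        if bbox_rows.max() >= target_rc[0] - vpatch.shape[0] // 2:
            raise ValueError("flanker configuration overlaps the outside target")
    _paste(canvas, vpatch, target_rc, cfg.foreground)
    # additive drawing must preserve every vernier pixel at full contrast
    h, w = vpatch.shape
    r0, c0 = target_rc[0] - h // 2, target_rc[1] - w // 2
    if not np.all(canvas[r0:r0 + h, c0:c0 + w][vpatch] >= cfg.foreground - 1e-12):
        raise ValueError("flanker drawing erased vernier pixels")
    return StimulusFrame(canvas, condition.flanker_layout[0], len(condition.flanker_layout),
                         vernier.vernier_offset,
                         (target_rc[1], target_rc[0]), condition.name)


def augment(frame: StimulusFrame, config: AugmentationConfig,
            rng: np.random.Generator) -> StimulusFrame:
    """Gaussian noise + brightness shift and contrast scale in random order."""
    img = frame.image.astype(np.float64)
    sd = rng.uniform(*config.noise_sd_range)
    shift = rng.uniform(*config.brightness_shift_range)
    contrast = rng.uniform(*config.contrast_factor_range)
    shift_first = bool(rng.integers(0, 2))
    if shift_first:
        img = (img + shift) * contrast
    else:
        img = img * contrast + shift
    if sd > 0:
        img = img + rng.normal(config.noise_mean, sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return replace(frame, image=img)


def build_training_set(experiment: int, n_frames: int,
                       rng: np.random.Generator,
                       cfg: StimulusConfig | None = None,
                       aug: AugmentationConfig | None = None,
                       line_counts: tuple[int, ...] = (2, 4, 6),
                       vernier_fraction: float | None = None) -> list[StimulusFrame]:
    """Training frames: lone verniers or lone shape groups, never both.

    ``vernier_fraction`` overrides the uniform class draw with a fixed
    probability of sampling a vernier frame (shape classes stay uniform).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    cfg = cfg or StimulusConfig()
    aug = aug or AugmentationConfig()
    frames = []
    classes = EXP1_CLASSES if experiment == 1 else EXP2_CLASSES
    j = cfg.location_jitter
    jx, jy = cfg.vernier_jitter
    for _ in range(n_frames):
        if vernier_fraction is None:
            cls = classes[int(rng.integers(0, len(classes)))]
        elif rng.random() < vernier_fraction:
            cls = "vernier"
        else:
            cls = classes[1 + int(rng.integers(0, len(classes) - 1))]
        center = (cfg.width // 2 + int(rng.integers(-j, j + 1)),
                  cfg.height // 2 + int(rng.integers(-j, j + 1)))
        if cls == "vernier":
            direction = OFFSET_DIRECTIONS[int(rng.integers(0, 2))]
            center = (cfg.width // 2 + int(rng.integers(-jx, jx + 1)),
                      cfg.height // 2 + int(rng.integers(-jy, jy + 1)))
            frame = render_vernier(direction, cfg, center)
        elif experiment == 1:
            n_rep = (1, 3, 5)[int(rng.integers(0, 3))]
            frame = render_shape_group(cls, n_rep, None, cfg, center)
        else:
            spacing = int(rng.integers(1, 7))
            if cls == "lines":
                spec = Exp2ShapeSpec("line_group",
                                     line_count=int(rng.choice(line_counts)),
                                     pair_spacing=spacing)
            elif cls == "cuboids":
                spec = Exp2ShapeSpec("cuboid_pair", pair_spacing=spacing)
            else:
                spec = Exp2ShapeSpec("scrambled_cuboid_pair", pair_spacing=spacing)
            frame = render_exp2_stimulus(spec, cfg, rng, center)
        frames.append(augment(frame, aug, rng))
    return frames


def build_test_battery(experiment: int,
                       shapes: tuple[str, ...] = EXP1_SHAPES) -> list[TestCondition]:
    """All test conditions of the given experiment, with baselines."""
    conditions: list[TestCondition] = [
        TestCondition("vernier_alone", (), "alone", experiment)]
    if experiment == 1:
        for s in shapes:
            conditions.append(TestCondition(f"{s}_1", (s,), "inside", 1,
                                            baseline_name=f"{s}_1"))
            conditions.append(TestCondition(f"{s}_5", (s,) * 5, "inside", 1,
                                            baseline_name=f"{s}_1"))
            conditions.append(TestCondition(f"{s}_1_outside", (s,), "outside", 1,
                                            baseline_name=f"{s}_1"))
            conditions.append(TestCondition(f"{s}_5_outside", (s,) * 5, "outside", 1,
                                            baseline_name=f"{s}_1"))
        for s in shapes:
            for t in shapes:
                if s == t:
                    continue
                layout = (s, t, s, t, s)
                conditions.append(TestCondition(f"{s}-{t}_alt", layout, "inside",
                                                1, baseline_name=f"{s}_1"))
    elif experiment == 2:
        conditions.append(TestCondition("lines_pair", ("lines",), "inside", 2))
        conditions.append(TestCondition("cuboids_pair", ("cuboids",), "inside", 2))
    else:
        raise ValueError("experiment must be 1 or 2")
    return conditions


# ------------------------------------------------------------------- export
def write_stimulus_set(frames: list[StimulusFrame], out_dir: str | Path) -> Path:
    """PNG per frame plus a CSV label table; returns the CSV path."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "labels.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_id", "shape_class", "n_repetitions",
                         "vernier_offset", "x", "y", "condition_name"])
        for i, fr in enumerate(frames):
            name = f"frame_{i:06d}.png"
            Image.fromarray((fr.image * 255).astype(np.uint8)).save(out_dir / name)
            writer.writerow([name, fr.shape_class, fr.n_repetitions,
                             fr.vernier_offset, fr.target_location[0],
                             fr.target_location[1], fr.condition_name])
    return csv_path
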