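"""Synthetic templates, pain-drawing cohorts, and scan renders.

The generator stands in for a clinical cohort of ~25 drawings per group
on A4 template sheets.  Defaults emulate the study conditions: group
sizes 24 (sexless outline) and 26 (female outline), pain concentrated in
the abdominal/pelvic band with some dorsal involvement, per-drawing
marked-pixel totals log-normal around 10^3.3 pixels at ~150 dpi (the
scale of the observed log10 pixel-count distribution), and scan noise of
a flatbed workflow: small rotation/translation/scale perturbations plus
intensity noise.

Everything is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .raster_model import BodyTemplate, PainDrawing

__all__ = ["CohortConfig", "NoiseConfig", "make_template", "sample_cohort",
           "render_scan", "ScanRender"]

# printed-sheet intensity levels (0 = black ink, 255 = blank paper)
PAPER_LEVEL = 255
OUTLINE_GRAY = 160
FIDUCIAL_LEVEL = 20
PEN_LEVEL = 30


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def _torso_halfwidth_profile(sex_label: str, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Control points (row, half-width) of the torso silhouette.

    Shoulders/chest/waist differ between the female and sexless variants;
    the abdomen-to-crotch band (rows 0.36h-0.48h) is identical across
    variants so the clinically critical drawable area is matched.
    """
    if sex_label == "female":
        shoulders, chest, waist = 0.100, 0.108, 0.062
    else:  # sexless / other: broader shoulders, flatter chest, wider waist
        shoulders, chest, waist = 0.112, 0.100, 0.075
    rows = np.array([0.150, 0.180, 0.240, 0.310, 0.360, 0.440, 0.480]) * h
    hws = np.array([0.060, shoulders, chest, waist, 0.082, 0.108, 0.100]) * h
    return rows, hws


def _panel_mask(height: int, width: int, col0: int, col1: int,
                sex_label: str) -> np.ndarray:
    """Rasterize one body silhouette into columns [col0, col1)."""
    h = float(height)
    cx = (col0 + col1) / 2.0
    rr = np.arange(height, dtype=float)[:, None]
    cc = np.arange(width, dtype=float)[None, :]
    mask = np.zeros((height, width), dtype=bool)

    # head
    head_r, head_c, head_rad = 0.080 * h, cx, 0.045 * h
    mask |= (rr - head_r) ** 2 + (cc - head_c) ** 2 <= head_rad**2
    # neck
    mask |= (rr >= 0.115 * h) & (rr < 0.155 * h) & (np.abs(cc - cx) <= 0.020 * h)
    # torso: per-row half-width interpolated through sex-dependent controls
    t_rows, t_hws = _torso_halfwidth_profile(sex_label, h)
    hw_at = np.interp(rr, t_rows, t_hws, left=0.0, right=0.0)
    mask |= (rr >= t_rows[0]) & (rr <= t_rows[-1]) & (np.abs(cc - cx) <= hw_at)
    # arms: straight limbs alongside the torso
    arm_off = np.interp(rr, t_rows, t_hws + 0.030 * h, left=0.0, right=0.0)
    arms = (rr >= 0.185 * h) & (rr <= 0.460 * h) & (
        np.abs(np.abs(cc - cx) - arm_off) <= 0.016 * h)
    mask |= arms
    # legs: two tapering columns below the crotch
    leg_top, leg_bot = 0.480 * h, 0.950 * h
    taper = np.clip((rr - leg_top) / (leg_bot - leg_top), 0.0, 1.0)
    leg_hw = (0.048 - 0.026 * taper) * h
    leg_off = 0.052 * h
    legs = (rr >= leg_top) & (rr <= leg_bot) & (
        np.abs(np.abs(cc - cx) - leg_off) <= leg_hw)
    mask |= legs
    # clip to panel columns
    mask &= (cc >= col0) & (cc < col1)
    return mask


def make_template(sex_label: str = "sexless", width: int = 1240,
                  height: int = 1754,
                  template_id: str | None = None) -> BodyTemplate:
    """Deterministic parametric body-outline template (frontal + dorsal).

    Default size approximates an A4 sheet at 150 dpi.  The frontal view
    occupies the left half of the sheet and the dorsal view the right
    half; both use the same silhouette.  Three filled corner fiducials
    with pairwise-distinct distances sit outside the drawable region.
    """
    if width < 200 or height < 200:
        raise ValueError("template must be at least 200x200 pixels")
    if template_id is None:
        template_id = f"synthetic-{sex_label}-{width}x{height}"
    half = width // 2
    mask = _panel_mask(height, width, 0, half, sex_label)
    mask |= _panel_mask(height, width, half, width, sex_label)

    h = float(height)
    # scalene fiducial triangle near the page corners (distinct pairwise
    # distances make the detected/template correspondence unambiguous);
    # inset far enough that scan rotation/translation keeps them on-page
    fiducials = np.array([
        [0.060 * height, 0.080 * width],
        [0.055 * height, 0.920 * width],
        [0.940 * height, 0.100 * width],
    ])
    fid_radius = max(4.0, round(0.004 * h))

    def panel_rect(r0, r1, c0f, c1f, panel):
        off = 0 if panel == "frontal" else half
        pw = half
        return (int(r0 * h), int(off + c0f * pw), int(r1 * h), int(off + c1f * pw))

    view_layout = {"frontal": (0, 0, height, half),
                   "dorsal": (0, half, height, width)}
    regions = {
        "head": panel_rect(0.03, 0.13, 0.30, 0.70, "frontal"),
        "chest": panel_rect(0.20, 0.30, 0.25, 0.75, "frontal"),
        "abdomen": panel_rect(0.36, 0.48, 0.20, 0.80, "frontal"),
        "legs": panel_rect(0.52, 0.90, 0.15, 0.85, "frontal"),
        "back": panel_rect(0.20, 0.36, 0.25, 0.75, "dorsal"),
        "lower_back": panel_rect(0.36, 0.48, 0.20, 0.80, "dorsal"),
    }
    return BodyTemplate(
        template_id=template_id, outline_mask=mask, fiducials=fiducials,
        sex_label=sex_label, view_layout=view_layout, regions=regions,
        fiducial_radius=fid_radius,
    )


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Synthetic cohort layout and optional between-group effect.

    Defaults mirror the study scale: 24 drawings on the sexless template
    vs 26 on the female template, 1-4 pain blobs per drawing, total
    marked area log-normal with log10 mean 3.3 and SD 0.45 (pixel counts
    at ~150 dpi), pain concentrated in the abdominal band with dorsal
    and leg involvement.
    """

    n_a: int = 24
    n_b: int = 26
    blob_count: tuple[int, int] = (1, 4)
    area_log10_mean: float = 3.3
    area_log10_sd: float = 0.45
    region_weights: dict[str, float] = field(default_factory=lambda: {
        "abdomen": 0.45, "lower_back": 0.20, "back": 0.15,
        "chest": 0.08, "legs": 0.12,
    })
    effect: str = "none"                    # {"none", "area_shift", "region_shift"}
    area_multiplier: float = 1.0            # group B area scale (area_shift)
    region_weights_b: dict[str, float] | None = None  # group B (region_shift)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("group sizes must be >= 1")
        if self.blob_count[0] < 1 or self.blob_count[1] < self.blob_count[0]:
            raise ValueError("invalid blob_count range")
        if self.effect not in ("none", "area_shift", "region_shift"):
            raise ValueError("unknown effect type")
        for w in self.region_weights.values():
            if w < 0:
                raise ValueError("region weights must be nonnegative")
        if self.effect == "region_shift" and self.region_weights_b is None:
            raise ValueError("region_shift effect requires region_weights_b")


def _region_mask(template: BodyTemplate, name: str) -> np.ndarray:
    r0, c0, r1, c1 = template.regions[name]
    mask = np.zeros(template.shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask & template.outline_mask


def _grow_blob(allowed: np.ndarray, seed_pixel: tuple[int, int],
               target_area: int, rng: np.random.Generator) -> np.ndarray:
    """Eden-style random growth: add random frontier pixels until the
    target area is reached or the allowed region is exhausted."""
    h, w = allowed.shape
    blob = np.zeros((h, w), dtype=bool)
    r0, c0 = seed_pixel
    blob[r0, c0] = True
    frontier: list[tuple[int, int]] = []

    def push_neighbors(r, c):
        if r > 0 and allowed[r - 1, c] and not blob[r - 1, c]:
            frontier.append((r - 1, c))
        if r + 1 < h and allowed[r + 1, c] and not blob[r + 1, c]:
            frontier.append((r + 1, c))
        if c > 0 and allowed[r, c - 1] and not blob[r, c - 1]:
            frontier.append((r, c - 1))
        if c + 1 < w and allowed[r, c + 1] and not blob[r, c + 1]:
            frontier.append((r, c + 1))

    push_neighbors(r0, c0)
    area = 1
    while area < target_area and frontier:
        k = rng.integers(len(frontier))
        frontier[k], frontier[-1] = frontier[-1], frontier[k]
        r, c = frontier.pop()
        if blob[r, c]:
            continue
        blob[r, c] = True
        area += 1
        push_neighbors(r, c)
    return blob


def sample_cohort(template_a: BodyTemplate, template_b: BodyTemplate,
                  config: CohortConfig,
                  rng: np.random.Generator | None = None):
    """Draw a two-group synthetic cohort with retained ground truth.

    Returns ``(drawings_a, drawings_b, truth)`` where ``truth`` is a list
    of per-drawing dicts (blob seeds, target and realized areas).  Group
    B is modified according to ``config.effect``.  Fully reproducible
    from ``config.seed``.
    """
    if template_a.shape != template_b.shape:
        raise ValueError("templates must share one raster shape")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    def group_prefix(template: BodyTemplate) -> str:
        return {"female": "F", "sexless": "N"}.get(template.sex_label, "X")

    def sample_group(template, n, weights, area_mult, label):
        names = sorted(weights)
        w = np.array([weights[k] for k in names], dtype=float)
        if w.sum() <= 0:
            raise ValueError("region weights sum to zero")
        w = w / w.sum()
        masks = {k: _region_mask(template, k) for k in names}
        pixels = {k: np.flatnonzero(masks[k].ravel()) for k in names}
        for k in names:
            if weights[k] > 0 and len(pixels[k]) == 0:
                raise ValueError(f"region {k!r} has no drawable pixel")
        drawings, truths = [], []
        prefix = group_prefix(template)
        for i in range(n):
            total_area = int(round(
                10.0 ** rng.normal(config.area_log10_mean, config.area_log10_sd)
            ) * area_mult)
            total_area = max(total_area, 1)
            k_blobs = int(rng.integers(config.blob_count[0],
                                       config.blob_count[1] + 1))
            per_blob = max(total_area // k_blobs, 1)
            marks = np.zeros(template.shape, dtype=bool)
            blob_info = []
            for _ in range(k_blobs):
                region = names[rng.choice(len(names), p=w)]
                flat = pixels[region]
                seed_flat = int(flat[rng.integers(len(flat))])
                seed_pixel = divmod(seed_flat, template.width)
                blob = _grow_blob(template.outline_mask, seed_pixel,
                                  per_blob, rng)
                realized = int(blob.sum())
                if realized < per_blob:
                    import warnings

                    warnings.warn("blob growth capped by outline area",
                                  stacklevel=2)
                marks |= blob
                blob_info.append({"region": region, "seed": seed_pixel,
                                  "target_area": per_blob,
                                  "realized_area": realized})
            drawing = PainDrawing(
                drawing_id=f"{prefix}_{i + 1}",
                template_id=template.template_id,
                group_label=label,
                marks=marks,
                provenance="synthetic",
                source=f"seed={config.seed}",
            )
            drawings.append(drawing)
            truths.append({"drawing_id": drawing.drawing_id, "group": label,
                           "n_marked": drawing.n_marked,
                           "target_total": total_area, "blobs": blob_info})
        return drawings, truths

    weights_b = (config.region_weights_b if config.effect == "region_shift"
                 else config.region_weights)
    mult_b = config.area_multiplier if config.effect == "area_shift" else 1.0

    drawings_a, truth_a = sample_group(
        template_a, config.n_a, config.region_weights, 1.0,
        template_a.sex_label)
    label_b = template_b.sex_label
    if label_b == template_a.sex_label:
        label_b = label_b + "_b"  # same-template calibration cohorts
    drawings_b, truth_b = sample_group(
        template_b, config.n_b, weights_b, mult_b, label_b)
    return drawings_a, drawings_b, truth_a + truth_b


# ---------------------------------------------------------------------------
# Scan rendering
# ---------------------------------------------------------------------------

@dataclass
class NoiseConfig:
    """Flatbed-scan perturbation model (all ranges symmetric around 0).

    Defaults: rotation up to ±3°, translation up to ±10 px, isotropic
    scale jitter ±2%, additive Gaussian intensity noise sigma 8 (of 255),
    salt-and-pepper corruption of 0.1% of pixels, and 1% pen dropout
    (random mark pixels left unpainted, emulating fiber-pen gaps).
    """

    rotation_deg: float = 3.0
    translation_px: float = 10.0
    scale_jitter: float = 0.02
    intensity_sigma: float = 8.0
    salt_pepper_rate: float = 0.001
    pen_gap_rate: float = 0.01
    seed: int | None = None

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(rotation_deg=0.0, translation_px=0.0, scale_jitter=0.0,
                   intensity_sigma=0.0, salt_pepper_rate=0.0, pen_gap_rate=0.0)


@dataclass
class ScanRender:
    """A rendered sheet plus the exact template->scan affine applied."""

    pixels: np.ndarray            # uint8 grayscale
    affine: np.ndarray            # 2x3, template (row,col,1) -> scan (row,col)
    drawing_id: str


def _ideal_sheet(drawing: PainDrawing, template: BodyTemplate,
                 pen_gap_rate: float, rng: np.random.Generator) -> np.ndarray:
    sheet = np.full(template.shape, PAPER_LEVEL, dtype=np.uint8)
    # gray outline: a ~2 px contour of the drawable region
    interior = ndimage.binary_erosion(template.outline_mask, iterations=2)
    contour = template.outline_mask & ~interior
    sheet[contour] = OUTLINE_GRAY
    marks = drawing.marks
    if pen_gap_rate > 0:
        keep = rng.random(marks.shape) >= pen_gap_rate
        marks = marks & keep
    sheet[marks] = PEN_LEVEL
    h, w = template.shape
    rr, cc = np.ogrid[:h, :w]
    for r, c in template.fiducials:
        disc = (rr - r) ** 2 + (cc - c) ** 2 <= template.fiducial_radius**2
        sheet[disc] = FIDUCIAL_LEVEL
    return sheet


def render_scan(drawing: PainDrawing, template: BodyTemplate,
                noise: NoiseConfig | None = None,
                rng: np.random.Generator | None = None) -> ScanRender:
    """Render a drawing onto its template sheet and simulate a scan.

    The sheet is perturbed by a random similarity transform about the
    page center (rotation, translation, scale per ``noise``) and by
    intensity noise.  Returns the scan together with the exact affine
    applied, template coordinates to scan coordinates, for round-trip
    verification.
    """
    if noise is None:
        noise = NoiseConfig()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    sheet = _ideal_sheet(drawing, template, noise.pen_gap_rate, rng)

    theta = np.deg2rad(rng.uniform(-noise.rotation_deg, noise.rotation_deg)) \
        if noise.rotation_deg else 0.0
    scale = 1.0 + (rng.uniform(-noise.scale_jitter, noise.scale_jitter)
                   if noise.scale_jitter else 0.0)
    shift = (rng.uniform(-noise.translation_px, noise.translation_px, size=2)
             if noise.translation_px else np.zeros(2))
    h, w = template.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rot = scale * np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
    offset = center + shift - rot @ center
    affine = np.hstack([rot, offset[:, None]])  # template -> scan

    # scan[y] = sheet[T^{-1} y]
    inv = np.linalg.inv(rot)
    scan = ndimage.affine_transform(
        sheet.astype(np.float64), inv, offset=-inv @ offset,
        output_shape=template.shape, order=1, mode="constant",
        cval=float(PAPER_LEVEL),
    )
    if noise.intensity_sigma > 0:
        scan = scan + rng.normal(0.0, noise.intensity_sigma, scan.shape)
    if noise.salt_pepper_rate > 0:
        u = rng.random(scan.shape)
        scan[u < noise.salt_pepper_rate / 2] = 0.0
        scan[(u >= noise.salt_pepper_rate / 2)
             & (u < noise.salt_pepper_rate)] = 255.0
    scan = np.clip(np.rint(scan), 0, 255).astype(np.uint8)
    return ScanRender(pixels=scan, affine=affine, drawing_id=drawing.drawing_id)


def replace_noise(noise: NoiseConfig, **kwargs) -> NoiseConfig:
    """Convenience: a copy of ``noise`` with fields replaced."""
    return replace(noise, **kwargs)
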