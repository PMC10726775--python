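"""Core data model for template pain drawings.

A *template* is the printed sheet: a body outline defining the drawable
region, plus three fiducial registration marks.  A *pain drawing* is one
subject's binary raster of marked pixels on that template, and a *pain
profile* is the per-pixel marking proportion over a group of drawings.

Raster convention: 0-based ``(row, col)`` indices, origin at the top-left,
row-major arrays.  Rectangular extents are half-open ``(r0, c0, r1, c1)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

PAIN_JSON_SCHEMA = "paindraw-extent-1"

SEX_LABELS = ("female", "sexless", "other")


class TemplateError(ValueError):
    """Invalid template definition (fiducials, mask, layout)."""


class PainJsonError(ValueError):
    """Malformed or inconsistent pain-extent JSON."""


def _triangle_area(points: np.ndarray) -> float:
    (r0, c0), (r1, c1), (r2, c2) = np.asarray(points, dtype=float)
    return 0.5 * abs((r1 - r0) * (c2 - c0) - (r2 - r0) * (c1 - c0))


@dataclass
class BodyTemplate:
    """A body-outline template: the pixel domain all drawings share.

    Parameters
    ----------
    template_id : str
        Identifier recorded in every drawing exported from this template.
    outline_mask : ndarray of bool, shape (height, width)
        True where a pixel lies inside a body outline (drawable).
    fiducials : ndarray, shape (3, 2)
        Registration-mark centers as (row, col), outside the outline.
    sex_label : {"female", "sexless", "other"}
    view_layout : dict
        Maps view names ("frontal", "dorsal") to half-open rectangles
        (r0, c0, r1, c1).  The two views must not overlap.
    regions : dict, optional
        Named anatomical sub-regions as half-open rectangles, used by the
        synthetic cohort generator to place pain blobs.
    fiducial_radius : float
        Nominal printed radius of a fiducial disc, in pixels.
    """

    template_id: str
    outline_mask: np.ndarray
    fiducials: np.ndarray
    sex_label: str
    view_layout: dict[str, tuple[int, int, int, int]]
    regions: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    fiducial_radius: float = 7.0

    def __post_init__(self) -> None:
        self.outline_mask = np.asarray(self.outline_mask, dtype=bool)
        self.fiducials = np.asarray(self.fiducials, dtype=float)
        self.validate()

    # -- geometry ----------------------------------------------------------
    @property
    def height(self) -> int:
        return self.outline_mask.shape[0]

    @property
    def width(self) -> int:
        return self.outline_mask.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.outline_mask.shape

    def validate(self) -> None:
        if self.outline_mask.ndim != 2:
            raise TemplateError("outline_mask must be a 2-D raster")
        if not self.outline_mask.any():
            raise TemplateError("outline_mask has no drawable pixel")
        if self.sex_label not in SEX_LABELS:
            raise TemplateError(f"sex_label must be one of {SEX_LABELS}")
        if self.fiducials.shape != (3, 2):
            raise TemplateError("exactly 3 fiducials (row, col) are required")
        if _triangle_area(self.fiducials) <= 0.0:
            raise TemplateError("fiducials are collinear")
        h, w = self.shape
        for r, c in self.fiducials:
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w):
                raise TemplateError("fiducial outside raster bounds")
            if self.outline_mask[ri, ci]:
                raise TemplateError("fiducial lies inside the body outline")
        front = self.view_layout.get("frontal")
        dorsal = self.view_layout.get("dorsal")
        if front is not None and dorsal is not None:
            if _rects_overlap(front, dorsal):
                raise TemplateError("frontal and dorsal extents overlap")

    def fiducial_exclusion_mask(self, factor: float = 1.5) -> np.ndarray:
        """Boolean mask of the never-markable discs around each fiducial."""
        h, w = self.shape
        rr, cc = np.ogrid[:h, :w]
        out = np.zeros(self.shape, dtype=bool)
        radius = factor * self.fiducial_radius
        for r, c in self.fiducials:
            out |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
        return out


def _rects_overlap(a, b) -> bool:
    ar0, ac0, ar1, ac1 = a
    br0, bc0, br1, bc1 = b
    return ar0 < br1 and br0 < ar1 and ac0 < bc1 and bc0 < ac1


@dataclass
class PainDrawing:
    """One subject's binary pain raster on a template.

    ``marks`` must be a subset of the template's drawable region; use
    :func:`clip_to_outline` to enforce the contract on foreign rasters.
    Drawing ids follow the study convention ``<letter>_<number>``
    (e.g. ``F_21``) but any string is accepted.
    """

    drawing_id: str
    template_id: str
    group_label: str
    marks: np.ndarray
    provenance: str = "synthetic"  # {"scan", "json", "synthetic"}
    source: str | None = None

    def __post_init__(self) -> None:
        self.marks = np.asarray(self.marks, dtype=bool)
        if self.marks.ndim != 2:
            raise ValueError("marks must be a 2-D raster")
        if self.provenance not in ("scan", "json", "synthetic"):
            raise ValueError("provenance must be scan, json or synthetic")
        if self.n_marked == 0:
            logger.warning("drawing %s has no marked pixel", self.drawing_id)

    @property
    def n_marked(self) -> int:
        return int(self.marks.sum())

    def validate_against(self, template: BodyTemplate) -> None:
        if self.template_id != template.template_id:
            raise ValueError(
                f"drawing {self.drawing_id} belongs to template "
                f"{self.template_id!r}, not {template.template_id!r}"
            )
        if self.marks.shape != template.shape:
            raise ValueError("marks shape differs from template shape")
        if (self.marks & ~template.outline_mask).any():
            raise ValueError("marked pixels outside the body outline")


def clip_to_outline(drawing: PainDrawing, template: BodyTemplate) -> PainDrawing:
    """Drop marked pixels outside the outline (idempotent).

    Digitized sheets may contain strokes that spill over the outline; the
    analysis domain is the outline interior only, so such pixels are
    removed with a warning.
    """
    if drawing.marks.shape != template.shape:
        raise ValueError("marks shape differs from template shape")
    outside = drawing.marks & ~template.outline_mask
    n_out = int(outside.sum())
    if n_out:
        warnings.warn(
            f"drawing {drawing.drawing_id}: clipped {n_out} pixels outside "
            "the body outline",
            stacklevel=2,
        )
    return PainDrawing(
        drawing_id=drawing.drawing_id,
        template_id=drawing.template_id,
        group_label=drawing.group_label,
        marks=drawing.marks & template.outline_mask,
        provenance=drawing.provenance,
        source=drawing.source,
    )


@dataclass
class PainProfile:
    """Per-pixel marking proportion for a group of drawings."""

    template_id: str
    proportions: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.min() < 0 or self.proportions.max() > 1:
            raise ValueError("proportions must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("profile needs at least one drawing")


# ---------------------------------------------------------------------------
# Pain-extent JSON (run-length encoded per row)
# ---------------------------------------------------------------------------

def _marks_to_runs(marks: np.ndarray) -> list[dict[str, int]]:
    runs: list[dict[str, int]] = []
    padded = np.zeros((marks.shape[0], marks.shape[1] + 2), dtype=np.int8)
    padded[:, 1:-1] = marks
    diff = np.diff(padded, axis=1)
    for row in range(marks.shape[0]):
        starts = np.flatnonzero(diff[row] == 1)
        ends = np.flatnonzero(diff[row] == -1)
        for s, e in zip(starts, ends):
            runs.append({"row": int(row), "col": int(s), "len": int(e - s)})
    return runs


def _runs_to_marks(runs, height: int, width: int) -> np.ndarray:
    marks = np.zeros((height, width), dtype=bool)
    for run in runs:
        try:
            row, col, length = int(run["row"]), int(run["col"]), int(run["len"])
        except (KeyError, TypeError) as exc:
            raise PainJsonError(f"malformed run {run!r}") from exc
        if length < 0:
            raise PainJsonError(f"negative run length in {run!r}")
        if not (0 <= row < height) or col < 0 or col + length > width:
            raise PainJsonError(f"run {run!r} extends past raster bounds")
        marks[row, col : col + length] = True
    return marks


def write_pain_json(drawing: PainDrawing, path: str | Path) -> None:
    """Serialize a drawing's marked extent to JSON.

    The payload is a per-row run-length encoding of the mark raster with
    sorted keys and no float formatting, so two writes of the same drawing
    are byte-identical.
    """
    payload = {
        "schema": PAIN_JSON_SCHEMA,
        "drawing_id": drawing.drawing_id,
        "template_id": drawing.template_id,
        "group_label": drawing.group_label,
        "width": int(drawing.marks.shape[1]),
        "height": int(drawing.marks.shape[0]),
        "n_marked": drawing.n_marked,
        "runs": _marks_to_runs(drawing.marks),
    }
    text = json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"
    Path(path).write_text(text, encoding="ascii")


def read_pain_json(path: str | Path, template: BodyTemplate) -> PainDrawing:
    """Load a pain-extent JSON file against its template.

    Marked pixels outside the outline are dropped with a warning (the
    clipping contract); structural problems raise :class:`PainJsonError`.
    """
    try:
        payload = json.loads(Path(path).read_text(encoding="ascii"))
    except json.JSONDecodeError as exc:
        raise PainJsonError(f"{path}: not valid JSON") from exc
    if payload.get("schema") != PAIN_JSON_SCHEMA:
        raise PainJsonError(
            f"{path}: unsupported schema {payload.get('schema')!r}"
        )
    for key in ("drawing_id", "template_id", "group_label", "width", "height",
                "n_marked", "runs"):
        if key not in payload:
            raise PainJsonError(f"{path}: missing key {key!r}")
    if payload["template_id"] != template.template_id:
        raise PainJsonError(
            f"{path}: template {payload['template_id']!r} does not match "
            f"{template.template_id!r}"
        )
    if (payload["height"], payload["width"]) != template.shape:
        raise PainJsonError(f"{path}: raster size differs from template")
    marks = _runs_to_marks(payload["runs"], payload["height"], payload["width"])
    if int(marks.sum()) != int(payload["n_marked"]):
        raise PainJsonError(f"{path}: n_marked does not match runs")
    drawing = PainDrawing(
        drawing_id=payload["drawing_id"],
        template_id=payload["template_id"],
        group_label=payload["group_label"],
        marks=marks,
        provenance="json",
        source=str(path),
    )
    return clip_to_outline(drawing, template)


# ---------------------------------------------------------------------------
# Template I/O (PNG mask + JSON metadata)
# ---------------------------------------------------------------------------

def save_template(template: BodyTemplate, mask_png: str | Path,
                  meta_json: str | Path) -> None:
    """Write a template as an 8-bit mask PNG (0 outside, 255 inside) + meta."""
    img = Image.fromarray(np.where(template.outline_mask, 255, 0).astype(np.uint8))
    img.save(Path(mask_png), format="PNG")
    meta = {
        "template_id": template.template_id,
        "sex_label": template.sex_label,
        "fiducials": [[float(r), float(c)] for r, c in template.fiducials],
        "fiducial_radius": float(template.fiducial_radius),
        "views": {k: [int(v) for v in rect]
                  for k, rect in template.view_layout.items()},
        "regions": {k: [int(v) for v in rect]
                    for k, rect in template.regions.items()},
    }
    Path(meta_json).write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n", encoding="ascii"
    )


def load_template(mask_png: str | Path, meta_json: str | Path) -> BodyTemplate:
    """Load and validate a template from its mask PNG and metadata JSON."""
    img = Image.open(Path(mask_png))
    if img.mode not in ("L", "1", "I;16", "P"):
        raise TemplateError(f"mask PNG must be single-channel, got {img.mode}")
    mask = np.asarray(img.convert("L")) >= 128
    meta = json.loads(Path(meta_json).read_text(encoding="ascii"))
    fiducials = np.asarray(meta["fiducials"], dtype=float)
    if fiducials.shape != (3, 2):
        raise TemplateError("metadata must list exactly 3 fiducials")
    return BodyTemplate(
        template_id=meta["template_id"],
        outline_mask=mask,
        fiducials=fiducials,
        sex_label=meta["sex_label"],
        view_layout={k: tuple(v) for k, v in meta.get("views", {}).items()},
        regions={k: tuple(v) for k, v in meta.get("regions", {}).items()},
        fiducial_radius=float(meta.get("fiducial_radius", 7.0)),
    )
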