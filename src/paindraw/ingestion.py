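"""Digitize a scanned template sheet into a pain drawing.

Pipeline: find the three printed fiducial discs among the dark blobs of
the scan, match them to the template's fiducial triad by their pairwise
distance pattern, solve the scan->template affine exactly from the three
correspondences, resample the scan into template coordinates, and
threshold pen marks inside the body outline.

Intensity model: pen ink is near-black (< ~40 of 255), fiducials are
black, the printed outline is mid-gray (~160), paper is white.  Marks
are resampled bilinearly and thresholded at the pen/paper midpoint
(~142): the interpolated intensity crosses the midpoint at the true ink
boundary, so the recovered mark edge is subpixel-accurate instead of
carrying the half-pixel jitter of nearest-neighbor resampling.  The
printed outline gray (160) stays above the threshold; scans whose
outline prints darker should lower ``mark_threshold`` accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .raster_model import BodyTemplate, PainDrawing

__all__ = ["ScanImage", "RegistrationResult", "detect_fiducials", "register",
           "extract_marks", "ingest_scan", "FiducialError", "RegistrationError"]

DEFAULT_FIDUCIAL_THRESHOLD = 60
DEFAULT_MARK_THRESHOLD = 142    # midpoint of pen ink (~30) and paper (255)
RESIDUAL_TOLERANCE_PX = 2.0
MATCH_TOLERANCE = 0.05          # max relative pairwise-distance deviation
DESPECKLE_MAX_SIZE = 2          # isolated dark specks up to this are dropped


class FiducialError(RuntimeError):
    """Fiducial detection failed (too few candidates or ambiguous match)."""


class RegistrationError(RuntimeError):
    """Degenerate or out-of-tolerance registration."""


@dataclass
class ScanImage:
    """Single-channel scan, intensities 0 (black) to 255 (white)."""

    pixels: np.ndarray
    dpi: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("scan must be single-channel (2-D)")


@dataclass
class RegistrationResult:
    """Exact affine fit of the detected fiducials to the template triad."""

    affine: np.ndarray            # 2x3, scan (row,col,1) -> template (row,col)
    residual: float               # max px distance on the fiducials
    detected_fiducials: np.ndarray  # 3x2, in template fiducial order

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (2, 3):
            raise ValueError("affine must be 2x3")
        if abs(np.linalg.det(self.affine[:, :2])) < 1e-12:
            raise RegistrationError("registration transform is degenerate")
        if self.residual < 0:
            raise ValueError("residual must be nonnegative")


def _pairwise_distances(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    return np.array([np.linalg.norm(p[i] - p[j])
                     for i, j in ((0, 1), (0, 2), (1, 2))])


def detect_fiducials(scan: ScanImage, template: BodyTemplate,
                     expected_area_px: float | None = None,
                     fiducial_threshold: int = DEFAULT_FIDUCIAL_THRESHOLD,
                     match_tolerance: float = MATCH_TOLERANCE) -> np.ndarray:
    """Locate the template's three fiducial marks on a scan.

    Dark connected components whose area lies within [0.5, 2] x the
    expected fiducial area are candidates; the triple whose sorted
    pairwise distances best match the template triad (within
    ``match_tolerance``, relative) wins.  Returns centroids (3x2) ordered
    to correspond to ``template.fiducials``.  Raises
    :class:`FiducialError` when fewer than 3 candidates exist, no triple
    matches, or two disjoint-cost triples both match.
    """
    if expected_area_px is None:
        expected_area_px = float(np.pi * template.fiducial_radius**2)
    dark = scan.pixels < fiducial_threshold
    labels = measure.label(dark, connectivity=2)
    candidates = [
        np.array(region.centroid)
        for region in measure.regionprops(labels)
        if 0.5 * expected_area_px <= region.area <= 2.0 * expected_area_px
    ]
    if len(candidates) < 3:
        raise FiducialError(
            f"fewer than 3 fiducial candidates (found {len(candidates)})"
        )
    ref = np.sort(_pairwise_distances(template.fiducials))
    matches = []
    for triple in combinations(range(len(candidates)), 3):
        pts = np.array([candidates[i] for i in triple])
        d = np.sort(_pairwise_distances(pts))
        cost = float(np.max(np.abs(d - ref) / ref))
        if cost <= match_tolerance:
            matches.append((cost, pts))
    if not matches:
        raise FiducialError("no candidate triple matches the fiducial layout")
    if len(matches) > 1:
        matches.sort(key=lambda m: m[0])
        raise FiducialError(
            f"ambiguous fiducial match: {len(matches)} triples within tolerance"
        )
    pts = matches[0][1]
    # canonical order: permutation minimizing summed pairwise-distance error
    tmpl_d = {frozenset((i, j)): np.linalg.norm(
        template.fiducials[i] - template.fiducials[j])
        for i, j in combinations(range(3), 2)}
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(3)):
        cost = sum(
            abs(np.linalg.norm(pts[perm[i]] - pts[perm[j]]) - tmpl_d[frozenset((i, j))])
            for i, j in combinations(range(3), 2)
        )
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    return pts[list(best_perm)]


def register(scan: ScanImage, detected: np.ndarray,
             template: BodyTemplate) -> RegistrationResult:
    """Solve the scan->template affine from the 3 fiducial correspondences.

    Three non-collinear point pairs determine the affine map exactly, so
    the residual on the fiducials themselves is zero up to numerics.
    """
    detected = np.asarray(detected, dtype=float)
    if detected.shape != (3, 2):
        raise ValueError("expected 3 detected fiducials")
    v1 = detected[1] - detected[0]
    v2 = detected[2] - detected[0]
    if abs(v1[0] * v2[1] - v1[1] * v2[0]) < 1e-9:
        raise RegistrationError("detected fiducials are collinear")
    X = np.hstack([detected, np.ones((3, 1))])        # 3x3
    affine = np.linalg.solve(X, template.fiducials).T  # 2x3
    mapped = (X @ affine.T)
    residual = float(np.max(np.linalg.norm(mapped - template.fiducials, axis=1)))
    return RegistrationResult(affine=affine, residual=residual,
                              detected_fiducials=detected)


def extract_marks(scan: ScanImage, registration: RegistrationResult,
                  template: BodyTemplate, group_label: str = "",
                  drawing_id: str = "scan",
                  mark_threshold: int = DEFAULT_MARK_THRESHOLD,
                  residual_tolerance: float = RESIDUAL_TOLERANCE_PX,
                  despeckle_max_size: int = DESPECKLE_MAX_SIZE) -> PainDrawing:
    """Binarize pen marks in template coordinates.

    The scan is resampled onto the template grid bilinearly; a pixel is
    marked iff its interpolated intensity falls below ``mark_threshold``,
    it lies in the body outline, and it is outside the fiducial exclusion
    discs.  Isolated specks of at most ``despeckle_max_size`` pixels
    (salt-and-pepper artifacts) are removed.
    """
    if registration.residual > residual_tolerance:
        raise RegistrationError(
            f"registration residual {registration.residual:.3f} px exceeds "
            f"tolerance {residual_tolerance} px"
        )
    A = registration.affine[:, :2]
    t = registration.affine[:, 2]
    # affine maps scan->template; resampling template grid needs the inverse
    inv = np.linalg.inv(A)
    warped = ndimage.affine_transform(
        scan.pixels.astype(np.float64), inv, offset=-inv @ t,
        output_shape=template.shape, order=1, mode="constant", cval=255.0,
    )
    raw = (warped < mark_threshold) & template.outline_mask
    raw &= ~template.fiducial_exclusion_mask()
    cleaned = morphology.remove_small_objects(raw, max_size=despeckle_max_size)
    return PainDrawing(
        drawing_id=drawing_id, template_id=template.template_id,
        group_label=group_label, marks=cleaned, provenance="scan",
        source="ingested scan",
    )


def ingest_scan(scan: ScanImage, template: BodyTemplate,
                group_label: str = "", drawing_id: str = "scan",
                mark_threshold: int = DEFAULT_MARK_THRESHOLD) -> tuple[
                    PainDrawing, RegistrationResult]:
    """Full digitization: detect fiducials, register, extract marks."""
    detected = detect_fiducials(scan, template)
    registration = register(scan, detected, template)
    drawing = extract_marks(scan, registration, template,
                            group_label=group_label, drawing_id=drawing_id,
                            mark_threshold=mark_threshold)
    return drawing, registration
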