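"""Pain profiles, the Ružička similarity index, and pairwise structure.

The Ružička index generalizes Jaccard similarity to nonnegative weights:

    RZI(x, y) = sum_i min(x_i, y_i) / sum_i max(x_i, y_i)

On binary rasters it reduces to |x ∩ y| / |x ∪ y|.  It compares only
pixels that are marked in at least one input, which suits sparse pain
rasters better than accuracy-style measures dominated by the empty
background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .raster_model import BodyTemplate, PainDrawing, PainProfile  # noqa: E402

__all__ = [
    "ruzicka",
    "build_profile",
    "pairwise_similarity",
    "summarize_groups",
    "export_heatmap",
    "export_boxplots",
    "SimilarityMatrix",
    "GroupSimilaritySummary",
]

HEATMAP_LOG_FLOOR = 1e-3


def ruzicka(x: np.ndarray, y: np.ndarray) -> float:
    """Ružička similarity of two nonnegative arrays of identical shape.

    Returns a value in [0, 1]; 1 means identical on the union support,
    0 means disjoint supports.  Two all-zero inputs are identical, so the
    degenerate 0/0 case returns 1.0 (with a warning, since it usually
    signals empty drawings upstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Ruzicka similarity requires nonnegative values")
    denom = np.maximum(x, y).sum()
    if denom == 0.0:
        warnings.warn("Ruzicka similarity of two all-zero inputs; returning 1.0",
                      stacklevel=2)
        return 1.0
    return float(np.minimum(x, y).sum() / denom)


def build_profile(drawings: list[PainDrawing],
                  template: BodyTemplate | None = None) -> PainProfile:
    """Per-pixel marking proportion over a group of drawings.

    ``proportions[p]`` is the fraction of drawings whose raster marks
    pixel ``p``; with ``n`` drawings every value is ``k/n`` for an integer
    ``k``.  All drawings must share one template.
    """
    if len(drawings) == 0:
        raise ValueError("cannot build a profile from an empty group")
    template_ids = {d.template_id for d in drawings}
    shapes = {d.marks.shape for d in drawings}
    if len(shapes) != 1:
        raise ValueError("drawings have mismatched raster shapes")
    if template is not None:
        for d in drawings:
            d.validate_against(template)
        template_id = template.template_id
    else:
        # cross-template profiles are legal when rasters share one shape
        # (the study compares groups drawn on same-size outline variants)
        template_id = sorted(template_ids)[0] if len(template_ids) == 1 else "+".join(
            sorted(template_ids))
    counts = np.zeros(drawings[0].marks.shape, dtype=np.int64)
    for d in drawings:
        counts += d.marks
    return PainProfile(template_id=template_id,
                       proportions=counts / len(drawings),
                       n=len(drawings))


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Ružička similarities between drawings."""

    drawing_ids: list[str]
    group_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.drawing_ids)
        if self.values.shape != (n, n) or len(self.group_labels) != n:
            raise ValueError("inconsistent similarity-matrix dimensions")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("similarities must lie in [0, 1]")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.drawing_ids,
                            columns=self.drawing_ids)


def pairwise_similarity(drawings: list[PainDrawing]) -> SimilarityMatrix:
    """All-pairs Ružička similarity between individual drawings.

    Rows/columns are ordered with the first group's block first (heatmap
    quadrant layout); order within a group follows input order.
    """
    if len(drawings) < 2:
        raise ValueError("need at least 2 drawings")
    group_order: list[str] = []
    for d in drawings:
        if d.group_label not in group_order:
            group_order.append(d.group_label)
    ordered = [d for g in group_order for d in drawings if d.group_label == g]
    n = len(ordered)
    # float64 keeps intersection/union counts exact (they are integers)
    flat = np.stack([d.marks.ravel() for d in ordered]).astype(np.float64)
    sizes = flat.sum(axis=1)
    inter = flat @ flat.T  # binary rasters: sum of minima = intersection
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        values = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    if (union == 0).any():
        warnings.warn("empty drawing pair(s): similarity set to 1.0",
                      stacklevel=2)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, np.where(sizes > 0, 1.0, 1.0))
    return SimilarityMatrix(
        drawing_ids=[d.drawing_id for d in ordered],
        group_labels=[d.group_label for d in ordered],
        values=values,
    )


def _stats(vals: np.ndarray) -> dict[str, float]:
    return {
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
        "mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
        # sample SD (ddof=1); undefined for a single pair
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        "n_pairs": int(len(vals)),
    }


@dataclass
class GroupSimilaritySummary:
    """Within/between-group similarity statistics over unordered pairs.

    ``classes`` maps ``within_<A>``, ``within_<B>`` and ``between`` to
    min/max/mean/median/sd over the distinct off-diagonal pairs of that
    class; ``pair_values`` keeps the raw values for plotting.  A group with
    fewer than 2 members has no within-pairs and is reported as None.
    """

    group_a: str
    group_b: str
    classes: dict[str, dict[str, float] | None]
    pair_values: dict[str, np.ndarray]


def summarize_groups(matrix: SimilarityMatrix) -> GroupSimilaritySummary:
    labels = np.asarray(matrix.group_labels)
    uniq = list(dict.fromkeys(matrix.group_labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, found {uniq}")
    a, b = uniq
    idx_a = np.flatnonzero(labels == a)
    idx_b = np.flatnonzero(labels == b)
    v = matrix.values

    def upper_pairs(idx):
        vals = []
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                vals.append(v[idx[i], idx[j]])
        return np.asarray(vals)

    within_a = upper_pairs(idx_a)
    within_b = upper_pairs(idx_b)
    between = v[np.ix_(idx_a, idx_b)].ravel()
    classes: dict[str, dict[str, float] | None] = {
        f"within_{a}": _stats(within_a) if len(within_a) else None,
        f"within_{b}": _stats(within_b) if len(within_b) else None,
        "between": _stats(between),
    }
    return GroupSimilaritySummary(
        group_a=a,
        group_b=b,
        classes=classes,
        pair_values={f"within_{a}": within_a, f"within_{b}": within_b,
                     "between": between},
    )


def export_heatmap(matrix: SimilarityMatrix, path) -> None:
    """Log10-scaled similarity heatmap with group-block separators.

    Zero similarities are clamped to a floor of 1e-3 before the log so
    fully disjoint pairs render at the bottom of the color scale.
    """
    logged = np.log10(np.maximum(matrix.values, HEATMAP_LOG_FLOOR))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(logged, cmap="viridis", interpolation="nearest",
                   vmin=np.log10(HEATMAP_LOG_FLOOR), vmax=0.0)
    labels = matrix.group_labels
    boundaries = [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]
    for b in boundaries:
        ax.axhline(b - 0.5, color="white", lw=1.0)
        ax.axvline(b - 0.5, color="white", lw=1.0)
    ax.set_title("log10 Ruzicka similarity")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log10 RZI")
    fig.savefig(path, dpi=100, metadata={"Software": "paindraw"})
    plt.close(fig)


def export_boxplots(summary: GroupSimilaritySummary, path) -> None:
    """Boxplots of pairwise similarities for the three pair classes."""
    order = [f"within_{summary.group_a}", f"within_{summary.group_b}", "between"]
    data = [summary.pair_values[k] for k in order if len(summary.pair_values[k])]
    names = [k for k in order if len(summary.pair_values[k])]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=names)
    ax.set_ylabel("Ruzicka similarity")
    ax.set_ylim(-0.02, 1.02)
    fig.savefig(path, dpi=100, metadata={"Software": "paindraw"})
    plt.close(fig)
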