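"""Shared fixtures: scaled-down templates and tiny drawing builders."""

from __future__ import annotations

import numpy as np
import pytest

from paindraw import BodyTemplate, CohortConfig, PainDrawing, make_template


@pytest.fixture(scope="session")
def small_template() -> BodyTemplate:
    """Sexless template at roughly A4 / 25 dpi (fast to generate and sample)."""
    return make_template("sexless", 248, 350)


@pytest.fixture(scope="session")
def small_template_female() -> BodyTemplate:
    return make_template("female", 248, 350)


@pytest.fixture(scope="session")
def medium_template() -> BodyTemplate:
    """Half-resolution template; large enough for default scan noise."""
    return make_template("sexless", 620, 877)


def small_cohort_config(n_a: int, n_b: int, seed: int, **kwargs) -> CohortConfig:
    """Cohort defaults rescaled to the small test templates.

    Marked areas scale with pixel count (s^2 for linear scale s), so at
    1/5 of the default raster width the default log10 area 3.3 becomes
    3.3 + 2*log10(1/5) ~ 1.9; everything else keeps the standard
    configuration (blob_count reduced to keep tiny blobs connected).
    """
    base = dict(n_a=n_a, n_b=n_b, blob_count=(1, 2), area_log10_mean=1.9,
                area_log10_sd=0.3, seed=seed)
    base.update(kwargs)
    return CohortConfig(**base)


def make_tiny_drawing(bits, drawing_id="d", group="g",
                      template_id="tiny") -> PainDrawing:
    """Drawing over an arbitrary small raster given 0/1 rows."""
    return PainDrawing(drawing_id=drawing_id, template_id=template_id,
                       group_label=group,
                       marks=np.asarray(bits, dtype=bool),
                       provenance="synthetic")


def random_drawing_on(template: BodyTemplate, rng: np.random.Generator,
                      density: float = 0.02, drawing_id="d",
                      group="g") -> PainDrawing:
    """Random marks inside the outline (not spatially clustered)."""
    marks = (rng.random(template.shape) < density) & template.outline_mask
    return PainDrawing(drawing_id=drawing_id,
                       template_id=template.template_id,
                       group_label=group, marks=marks, provenance="synthetic")
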