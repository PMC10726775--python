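"""End-to-end orchestration: data in, full analysis run directory out.

A run chains: input acquisition (simulate a cohort, load pain-extent
JSON files, or ingest scans) -> group pain profiles -> permutation test
-> pairwise similarity structure -> pixel-count comparison, and writes
every artifact plus a manifest (config, config hash, seed, versions)
into one output directory.  With a fixed seed, reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .cohort_stats import pixel_count_comparison
from .ingestion import ScanImage, ingest_scan
from .permutation_test import export_histogram, permutation_test
from .profile_similarity import (build_profile, export_boxplots,
                                 export_heatmap, pairwise_similarity,
                                 summarize_groups)
from .raster_model import (BodyTemplate, load_template, read_pain_json,
                           save_template)
from .synthetic_data import (CohortConfig, NoiseConfig, make_template,
                             sample_cohort)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one input mode:

    - ``simulate``: generate a synthetic two-group cohort (``cohort``);
    - ``json``: load pain-extent JSON files from ``group_a_dir`` /
      ``group_b_dir`` against the template in ``template_dir``;
    - ``scans``: ingest scan PNGs from those directories instead.
    """

    mode: str = "simulate"                  # {"simulate", "json", "scans"}
    out_dir: str = "paindraw-run"
    seed: int = 0
    B: int = 1000
    alpha: float = 0.05
    tail: str = "lower"
    mark_threshold: int = 142
    template_dir: str | None = None         # json/scans modes
    group_a_dir: str | None = None
    group_b_dir: str | None = None
    group_a_label: str = "sexless"
    group_b_label: str = "female"
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    template_size: tuple[int, int] = (1240, 1754)  # (width, height)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "json", "scans"):
            raise ValueError("mode must be simulate, json or scans")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "template_size" in data:
            data["template_size"] = tuple(data["template_size"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{name}: {exc}") from exc
        return inner
    return wrap


@_stage("synthetic_data")
def _acquire_simulate(config: RunConfig):
    w, h = config.template_size
    tpl_a = make_template(config.group_a_label
                          if config.group_a_label in ("female", "sexless")
                          else "sexless", w, h)
    tpl_b = make_template(config.group_b_label
                          if config.group_b_label in ("female", "sexless")
                          else "sexless", w, h)
    cohort = CohortConfig(seed=config.seed, **config.cohort)
    a, b, truth = sample_cohort(tpl_a, tpl_b, cohort)
    return a, b, {"truth": truth, "templates": (tpl_a, tpl_b)}


@_stage("raster_model")
def _acquire_json(config: RunConfig):
    tdir = Path(config.template_dir or "")
    mask = tdir / "template_mask.png"
    meta = tdir / "template_meta.json"
    if not mask.exists() or not meta.exists():
        raise FileNotFoundError(f"template not found under {tdir}")
    template = load_template(mask, meta)
    groups = []
    for d in (config.group_a_dir, config.group_b_dir):
        files = sorted(Path(d).glob("*.json"))
        if not files:
            raise FileNotFoundError(f"no pain-extent JSON files in {d}")
        groups.append([read_pain_json(f, template) for f in files])
    return groups[0], groups[1], {"templates": (template, template)}


@_stage("ingestion")
def _acquire_scans(config: RunConfig):
    tdir = Path(config.template_dir or "")
    template = load_template(tdir / "template_mask.png",
                             tdir / "template_meta.json")
    groups = []
    for d, label in ((config.group_a_dir, config.group_a_label),
                     (config.group_b_dir, config.group_b_label)):
        files = sorted(Path(d).glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no scan PNGs in {d}")
        drawings = []
        for f in files:
            scan = ScanImage(np.asarray(Image.open(f).convert("L")))
            drawing, reg = ingest_scan(scan, template, group_label=label,
                                       drawing_id=f.stem,
                                       mark_threshold=config.mark_threshold)
            logger.info("ingested %s: residual %.3g px, %d marked",
                        f.stem, reg.residual, drawing.n_marked)
            drawings.append(drawing)
        groups.append(drawings)
    return groups[0], groups[1], {"templates": (template, template)}


def _write_profile(profile, stem: Path) -> None:
    img = np.rint(255 * (1.0 - profile.proportions)).astype(np.uint8)
    Image.fromarray(img).save(stem.with_suffix(".png"), format="PNG")
    rows, cols = np.nonzero(profile.proportions)
    pd.DataFrame({
        "row": rows, "col": cols,
        "proportion": profile.proportions[rows, cols],
    }).to_csv(stem.with_suffix(".csv"), index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full analysis run; returns the output directory.

    Outputs: ``manifest.json``, per-group profile PNG + sparse CSV,
    ``permutation.json`` + ``permutation_hist.png``, similarity matrix
    CSV + heatmap + boxplots, and ``pixel_counts.csv`` +
    ``pixel_count_tests.json``.  Deterministic given the config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        group_a, group_b, extra = _acquire_simulate(config)
    elif config.mode == "json":
        group_a, group_b, extra = _acquire_json(config)
    else:
        group_a, group_b, extra = _acquire_scans(config)

    tpl_a, tpl_b = extra["templates"]
    if config.mode == "simulate":
        save_template(tpl_a, out / "template_a_mask.png",
                      out / "template_a_meta.json")
        save_template(tpl_b, out / "template_b_mask.png",
                      out / "template_b_meta.json")
        pd.DataFrame([
            {"drawing_id": t["drawing_id"], "group": t["group"],
             "n_marked": t["n_marked"], "target_total": t["target_total"]}
            for t in extra["truth"]
        ]).to_csv(out / "ground_truth.csv", index=False)

    try:
        prof_a = build_profile(group_a)
        prof_b = build_profile(group_b)
        _write_profile(prof_a, out / "profile_a")
        _write_profile(prof_b, out / "profile_b")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"profile_similarity: {exc}") from exc

    try:
        perm = permutation_test(group_a, group_b, B=config.B,
                                tail=config.tail, alpha=config.alpha,
                                seed=config.seed)
        result = perm.to_dict()
        result["config_hash"] = config.config_hash()
        (out / "permutation.json").write_text(
            json.dumps(result, sort_keys=True, indent=1) + "\n")
        export_histogram(perm, out / "permutation_hist.png")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"permutation_test: {exc}") from exc

    try:
        matrix = pairwise_similarity(group_a + group_b)
        matrix.to_dataframe().to_csv(out / "similarity_matrix.csv")
        summary = summarize_groups(matrix)
        export_heatmap(matrix, out / "similarity_heatmap.png")
        export_boxplots(summary, out / "similarity_boxplots.png")
        (out / "similarity_summary.json").write_text(json.dumps(
            {"seed": config.seed, "config_hash": config.config_hash(),
             "classes": summary.classes},
            sort_keys=True, indent=1, allow_nan=True) + "\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"profile_similarity: {exc}") from exc

    try:
        counts = pixel_count_comparison(group_a, group_b)
        counts.to_dataframe().to_csv(out / "pixel_counts.csv", index=False)
        (out / "pixel_count_tests.json").write_text(json.dumps({
            "seed": config.seed, "config_hash": config.config_hash(),
            "group_a": counts.group_a, "group_b": counts.group_b,
            "summary_a": counts.summary_a, "summary_b": counts.summary_b,
            "rank_sum_w": counts.rank_sum_w,
            "u_statistic": counts.u_statistic,
            "rank_sum_p": counts.rank_sum_p,
            "t_statistic": counts.t_statistic, "t_p": counts.t_p,
            "notes": counts.notes,
        }, sort_keys=True, indent=1) + "\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"cohort_stats: {exc}") from exc

    manifest = {
        "package": "paindraw",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "p_value": perm.p_value,
        "origin_rzi": perm.origin_rzi,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str) + "\n")
    return out
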