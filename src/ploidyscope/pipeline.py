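"""End-to-end orchestration: simulate -> quantify -> summarize -> compare.

All randomness flows from one root seed: each heart's scene receives a
child seed spawned from ``numpy.random.SeedSequence(root_seed)``, so a run
is reproducible end to end and hearts are statistically independent.

Two quantification modes exist. ``image`` renders every scene and runs the
full measurement pipeline (segmentation, typing, viability filtering,
endothelial-median ploidy calling). ``truth`` summarizes the generator's
drawn ground truth directly — the same composition sampling without pixels —
and is the fast path for replicate simulations (null calibration, power).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cells import CellTyper, filter_viable
from .config import SceneConfig, plan_image_shape
from .ploidy import (GroupComparison, HeartSummary, PloidyClassifier,
                     call_ploidy_class, compare_groups, summarize_heart)
from .segment import NucleusSegmenter
from .synth import GroundTruth, ImageStack, generate_scene, sample_truth

__all__ = ["quantify_scene", "summarize_truth", "simulate_and_summarize",
           "run_experiment", "ExperimentResult", "RunManifest"]

log = logging.getLogger(__name__)


def _child_seed(root: int, index: int) -> int:
    """Deterministic 31-bit child seed for heart `index` of a run."""
    return int(np.random.SeedSequence([root, index]).generate_state(1)[0]
               & 0x7FFFFFFF)


def quantify_scene(stack: ImageStack, truth: GroundTruth | None = None,
                   cell_mask_from: str = "markers",
                   dapi_threshold="otsu", min_ec: int = 30,
                   refine_8n: bool = False,
                   boundary_2n4n: float | None = None,
                   segmenter: NucleusSegmenter | None = None,
                   typer: CellTyper | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Measure one scene: returns ``(nuclei, cells, calls)`` tables.

    ``cell_mask_from="truth"`` uses the ground-truth cell mask (requires
    `truth`); ``"markers"`` derives cell masks from the marker channels.
    """
    segmenter = segmenter or NucleusSegmenter(dapi_threshold=dapi_threshold)
    typer = typer or CellTyper()
    nuclei, _ = segmenter.segment(stack)
    if cell_mask_from == "truth":
        if truth is None or truth.cell_mask is None:
            raise ValueError("cell_mask_from='truth' requires a ground-truth mask")
        mask = truth.cell_mask
    elif cell_mask_from == "markers":
        mask = None
    else:
        raise ValueError(f"cell_mask_from must be 'truth' or 'markers', "
                         f"got {cell_mask_from!r}")
    cells, nuclei = typer.assign(nuclei, stack, cell_mask=mask)
    kwargs = {} if boundary_2n4n is None else {"boundary_2n4n": boundary_2n4n}
    clf = PloidyClassifier(min_ec=min_ec, refine_8n=refine_8n, **kwargs)
    calls = clf.fit(nuclei, cells).calls(nuclei, cells)
    return nuclei, cells, calls


def summarize_truth(truth: GroundTruth, min_cells: int = 600,
                    heart_id: str = "heart") -> HeartSummary:
    """Heart summary straight from ground truth (no imaging, no measurement)."""
    cells = truth.cells.copy()
    cells["nucleation_binned"] = cells["nucleation"].clip(upper=4)
    calls = pd.DataFrame({
        "nucleus_id": truth.nuclei["nucleus_id"],
        "cell_id": truth.nuclei["cell_id"],
        "ploidy_class": np.where(truth.nuclei["ploidy_class"] == "2N",
                                 "2N", ">=4N"),
    })
    viable = filter_viable(cells)
    return summarize_heart(viable, calls, min_cells=min_cells,
                           heart_id=heart_id)


def simulate_and_summarize(config: SceneConfig, seed: int,
                           mode: str = "image", min_cells: int = 600,
                           heart_id: str = "heart",
                           cell_mask_from: str = "markers",
                           ) -> HeartSummary:
    """Simulate one heart and summarize it in the requested mode."""
    cfg = config.replace(seed=seed)
    if mode == "truth":
        return summarize_truth(sample_truth(cfg), min_cells=min_cells,
                               heart_id=heart_id)
    if mode != "image":
        raise ValueError(f"mode must be 'image' or 'truth', got {mode!r}")
    stack, truth = generate_scene(cfg)
    nuclei, cells, calls = quantify_scene(stack, truth,
                                          cell_mask_from=cell_mask_from)
    viable = filter_viable(cells)
    return summarize_heart(viable, calls, min_cells=min_cells,
                           heart_id=heart_id)


def simulate_and_quantify(config: SceneConfig, seed: int,
                          min_cells: int = 600, heart_id: str = "heart",
                          cell_mask_from: str = "markers"):
    """Render one heart, run the full measurement pipeline.

    Returns ``(summary, viable_cells, calls)`` so callers can pool
    nucleus-level quantities across hearts as well as use the per-heart
    summary.
    """
    stack, truth = generate_scene(config.replace(seed=seed))
    nuclei, cells, calls = quantify_scene(stack, truth,
                                          cell_mask_from=cell_mask_from)
    viable = filter_viable(cells)
    summary = summarize_heart(viable, calls, min_cells=min_cells,
                              heart_id=heart_id)
    return summary, viable, calls


@dataclass
class RunManifest:
    """Reproducibility record of one experiment run."""

    tool_version: str
    seed: int
    mode: str
    n_hearts_per_group: int
    metric: str
    config_a: dict
    config_b: dict
    heart_seeds: dict[str, list[int]]
    timestamp: str
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ExperimentResult:
    summaries_a: pd.DataFrame
    summaries_b: pd.DataFrame
    comparison: GroupComparison
    manifest: RunManifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config_a: SceneConfig, config_b: SceneConfig,
                   n_hearts_per_group: int, seed: int,
                   metric: str = "mono_pct", mode: str = "image",
                   min_cells: int = 600, welch: bool = False,
                   label_a: str = "A", label_b: str = "B",
                   cell_mask_from: str = "markers",
                   out_dir=None) -> ExperimentResult:
    """Simulate two groups of hearts and compare a per-heart metric.

    Raises a stage-labelled error if any heart fails, and writes summary
    tables, the comparison and a manifest when `out_dir` is given.
    """
    if n_hearts_per_group < 2:
        raise ValueError("n_hearts_per_group must be >= 2 for a t-test")
    groups = {label_a: config_a, label_b: config_b}
    heart_seeds: dict[str, list[int]] = {}
    summaries: dict[str, list[dict]] = {}
    for gi, (label, cfg) in enumerate(groups.items()):
        heart_seeds[label] = [
            _child_seed(seed, gi * n_hearts_per_group + h)
            for h in range(n_hearts_per_group)]
        rows = []
        for h, hs in enumerate(heart_seeds[label]):
            t0 = time.perf_counter()
            try:
                s = simulate_and_summarize(
                    cfg, hs, mode=mode, min_cells=min_cells,
                    heart_id=f"{label}{h + 1}", cell_mask_from=cell_mask_from)
            except Exception as exc:
                raise RuntimeError(
                    f"group {label}, heart {h + 1}: {exc}") from exc
            log.info("group %s heart %d done in %.1fs", label, h + 1,
                     time.perf_counter() - t0)
            rows.append(s.as_dict())
        summaries[label] = rows
    df_a = pd.DataFrame(summaries[label_a])
    df_b = pd.DataFrame(summaries[label_b])
    comparison = compare_groups(df_a, df_b, metric=metric, welch=welch,
                                label_a=label_a, label_b=label_b)
    manifest = RunManifest(
        tool_version=__version__, seed=seed, mode=mode,
        n_hearts_per_group=n_hearts_per_group, metric=metric,
        config_a=config_a.to_dict(), config_b=config_b.to_dict(),
        heart_seeds=heart_seeds,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df_a.to_csv(out / f"summaries_{label_a}.csv", index=False)
        df_b.to_csv(out / f"summaries_{label_b}.csv", index=False)
        with open(out / "comparison.json", "w") as fh:
            json.dump(comparison.as_dict(), fh, indent=2)
        for f in (f"summaries_{label_a}.csv", f"summaries_{label_b}.csv",
                  "comparison.json"):
            manifest.outputs[f] = _sha256(out / f)
        manifest.to_json(out / "manifest.json")
    return ExperimentResult(summaries_a=df_a, summaries_b=df_b,
                            comparison=comparison, manifest=manifest)
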