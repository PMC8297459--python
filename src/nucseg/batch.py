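"""Parent-workers batch execution over image folders.

Parallelism is embarrassingly per-image: the parent partitions the
sorted file list across a local process pool and collects one record
per image. Results are byte-identical for any worker count — each
image is processed independently and label-map bytes are deterministic
— so the worker count is purely a throughput knob.
"""

from __future__ import annotations

import json
import logging
import os
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .image_io import ImageIOError, read_image, read_label_map, write_label_map
from .metrics import DatasetReport, evaluate_dataset
from .watershed import count_cells, segment_image

__all__ = ["ImageRecord", "RunManifest", "run_folder", "evaluate_folders"]

logger = logging.getLogger("nucseg")

_EXTENSIONS = (".png", ".tif", ".tiff")


@dataclass
class ImageRecord:
    """Outcome of processing one input image."""

    input_path: str
    count: int | None
    label_path: str | None
    wall_time_s: float
    error: str | None = None


@dataclass
class RunManifest:
    """One record per input image plus the exact configuration used."""

    records: list[ImageRecord]
    config: dict
    version: str = __version__

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def counts_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"input_path": r.input_path, "count": r.count, "error": r.error}
             for r in self.records]
        )


def _list_images(input_dir: str) -> list[str]:
    files = sorted(
        os.path.join(input_dir, name)
        for name in os.listdir(input_dir)
        if name.lower().endswith(_EXTENSIONS)
    )
    if not files:
        raise FileNotFoundError(f"no readable images in {input_dir!r}")
    return files


def _process_one(args: tuple[str, str, dict]) -> ImageRecord:
    path, output_dir, cfg_dict = args
    cfg = PipelineConfig.from_dict(cfg_dict)
    start = time.perf_counter()
    # keep the input basename so predictions pair with ground truth by name
    out_path = os.path.join(output_dir, os.path.basename(path))
    try:
        img = read_image(path)
        labels = segment_image(img, cfg)
        write_label_map(labels, out_path)
        elapsed = time.perf_counter() - start
        return ImageRecord(path, count_cells(labels), out_path, elapsed)
    except (ImageIOError, ValueError) as exc:
        elapsed = time.perf_counter() - start
        return ImageRecord(path, None, None, elapsed, error=str(exc))


def run_folder(
    input_dir: str,
    cfg: PipelineConfig | None = None,
    output_dir: str | None = None,
) -> RunManifest:
    """Segment every image in a folder, writing label maps and tables.

    Unreadable images are recorded with their error and the run
    continues. With ``cfg.workers > 1`` images are partitioned across
    worker processes; outputs are byte-identical to the single-worker
    run.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if output_dir is None:
        output_dir = cfg.output_dir
    if os.path.abspath(output_dir) == os.path.abspath(input_dir):
        raise ValueError("output_dir must differ from input_dir "
                         "(label maps keep the input file names)")
    os.makedirs(output_dir, exist_ok=True)
    files = _list_images(input_dir)
    cfg_dict = cfg.to_dict()
    jobs = [(path, output_dir, cfg_dict) for path in files]

    if cfg.workers == 1:
        records = [_process_one(job) for job in jobs]
    else:
        with ProcessPoolExecutor(max_workers=cfg.workers) as pool:
            records = list(pool.map(_process_one, jobs))
    for rec in records:
        if rec.error:
            logger.warning("failed %s: %s", rec.input_path, rec.error)
        else:
            logger.info("%s: %d nuclei in %.2fs", rec.input_path,
                        rec.count, rec.wall_time_s)

    manifest = RunManifest(records=records, config=cfg_dict)
    manifest.counts_table().to_csv(os.path.join(output_dir, "counts.csv"),
                                   index=False)
    manifest.to_json(os.path.join(output_dir, "manifest.json"))
    return manifest


def evaluate_folders(pred_dir: str, gt_dir: str,
                     report_csv: str | None = None) -> DatasetReport:
    """Score label maps in ``pred_dir`` against same-named files in ``gt_dir``."""
    pred_names = {n for n in os.listdir(pred_dir)
                  if n.lower().endswith(_EXTENSIONS)}
    gt_names = {n for n in os.listdir(gt_dir)
                if n.lower().endswith(_EXTENSIONS)}
    unmatched = pred_names ^ gt_names
    if unmatched:
        raise FileNotFoundError(
            f"unmatched files between folders: {sorted(unmatched)}"
        )
    names = sorted(pred_names)
    preds = [read_label_map(os.path.join(pred_dir, n)) for n in names]
    gts = [read_label_map(os.path.join(gt_dir, n)) for n in names]
    report = evaluate_dataset(preds, gts, names=names)
    if report_csv:
        report.to_csv(report_csv)
    return report
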