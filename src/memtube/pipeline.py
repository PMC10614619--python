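"""End-to-end driver: segmentation -> object geometry -> tubulation ratios.

The classifier is trained on seeded synthetic scenes (no bundled weights),
so identical config + inputs reproduce byte-identical result CSVs.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import memtube
from memtube import io as mio
from memtube.config import PipelineConfig, RunManifest, config_hash, file_hash
from memtube.pixelclass import (
    PixelClassifier,
    extract_objects,
    predict_labels,
    reassign_by_shape,
    train_classifier,
)
from memtube.synthgen import DEFAULT_OPTICS, make_tubulation_scene
from memtube.tubstats import TubulationResult, tubulation_ratio

__all__ = ["train_default_classifier", "run_pipeline", "PipelineError"]

log = logging.getLogger("memtube.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def train_default_classifier(config: PipelineConfig) -> PixelClassifier:
    """Train the pixel classifier on seeded synthetic tubulation scenes."""
    images, truths = [], []
    for i in range(config.n_train_scenes):
        target = config.train_target_ratios[i % len(config.train_target_ratios)]
        img, truth = make_tubulation_scene(
            target_ratio=target,
            n_objects=8,
            optics=DEFAULT_OPTICS,
            seed=config.seed + 1000 + i,
            pixel_size_nm=config.pixel_size_nm,
        )
        images.append(img)
        truths.append(truth.true_label_map)
    log.info("training classifier on %d synthetic scenes (seed=%d)", len(images), config.seed)
    return train_classifier(images, truths, scales=config.scales, seed=config.seed)


def run_pipeline(
    config: PipelineConfig,
    image_paths: list[str | Path],
    classifier: PixelClassifier | None = None,
) -> tuple[list[TubulationResult], RunManifest]:
    """Segment each input image, measure objects, and tabulate tubulation ratios.

    Writes per-image object CSVs, label-map TIFFs, a ratio table, and a
    manifest into ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if classifier is None:
        try:
            classifier = train_default_classifier(config)
        except Exception as exc:
            raise PipelineError("train", str(exc)) from exc

    results: list[TubulationResult] = []
    for path in image_paths:
        path = Path(path)
        image_id = path.stem
        try:
            image = mio.read_image(path, pixel_size_nm=config.pixel_size_nm)
        except Exception as exc:
            raise PipelineError("read", f"{path}: {exc}") from exc
        try:
            labels = predict_labels(classifier, image, image_id=image_id)
            objects = extract_objects(
                labels, min_object_area_px=config.criteria.min_object_area_px
            )
            objects = reassign_by_shape(objects, config.criteria)
        except Exception as exc:
            raise PipelineError("segment", f"{path}: {exc}") from exc
        result = tubulation_ratio(objects, image_id=image_id)
        if not result.defined:
            log.warning("image %s: no membrane objects; ratio undefined, excluded", image_id)
        results.append(result)
        mio.write_label_map(out / f"{image_id}_labels.tif", labels)
        mio.objects_to_csv(out / f"{image_id}_objects.csv", objects)
        log.info("image %s: ratio=%s", image_id, result.ratio)

    mio.results_to_csv(out / "tubulation_ratios.csv", results)
    manifest = RunManifest(
        tool_version=memtube.__version__,
        config_hash=config_hash(config),
        input_hashes={str(p): file_hash(p) for p in image_paths},
        seed=config.seed,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")
    return results, manifest
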