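"""Single-image classification pipeline: load -> segment -> features ->
classify -> packetize.

Mirrors the on-device program flow: the raw image is preprocessed and
classified locally, and its bytes are framed for transmission to the
host for expert verification.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from . import ann, protocol
from .errors import InvalidImageError, PestPipeError
from .features import FEATURE_NAMES, extract_features
from .segmentation import SegmentationConfig, rgb_to_hsv, segment
from .synthetic_data import DEFAULT_BAND

log = logging.getLogger("pestpipe")


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(band=DEFAULT_BAND)
    )
    model_path: str | None = None
    link: protocol.LinkConfig = field(default_factory=protocol.LinkConfig)
    frames_out: str | None = None  # write serialized frames here if set


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config.

    Recognized keys: ``segmentation.band`` (two floats),
    ``segmentation.auto``, ``segmentation.connectivity``, ``model``,
    ``link.timeout``, ``link.max_retries_before_reset``,
    ``link.retry_budget``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    seg = doc.get("segmentation", {})
    band = seg.get("band")
    seg_cfg = SegmentationConfig(
        band=tuple(band) if band else (None if seg.get("auto") else DEFAULT_BAND),
        auto=bool(seg.get("auto", False)),
        connectivity=int(seg.get("connectivity", 8)),
    )
    link = doc.get("link", {})
    link_cfg = protocol.LinkConfig(
        timeout=float(link.get("timeout", 1.0)),
        max_retries_before_reset=int(link.get("max_retries_before_reset", 5)),
        retry_budget=int(link.get("retry_budget", 100)),
    )
    return PipelineConfig(
        segmentation=seg_cfg,
        model_path=doc.get("model"),
        link=link_cfg,
    )


def load_image(path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as e:
        raise InvalidImageError(f"cannot read image {path}: {e}") from e
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]  # drop alpha
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(f"{path} is not an RGB image (shape {arr.shape})")
    return np.ascontiguousarray(arr[..., :3], dtype=np.uint8)


def run_pipeline(image_path, cfg: PipelineConfig) -> dict:
    """Classify one image and frame its bytes for transmission.

    Returns a report dict with the predicted label, class scores, the
    13 features, per-stage timings, and the number of frames the image
    payload packs into.  Stage failures propagate as the stage's own
    exception type so the CLI can map them to distinct exit codes.
    """
    if cfg.model_path is None:
        raise PestPipeError("no model configured")
    model = ann.load_model(cfg.model_path)
    report: dict = {"image": str(image_path), "stages": {}}

    t0 = time.perf_counter()
    img = load_image(image_path)
    report["stages"]["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    hsv = rgb_to_hsv(img)
    mask = segment(img, cfg.segmentation)
    report["stages"]["segment"] = time.perf_counter() - t0
    report["region_size"] = int(mask.sum())

    t0 = time.perf_counter()
    feats = extract_features(img, mask, hsv=hsv)
    report["stages"]["features"] = time.perf_counter() - t0
    report["features"] = dict(zip(FEATURE_NAMES, (float(v) for v in feats)))

    t0 = time.perf_counter()
    label, scores = ann.predict(model, feats)
    report["stages"]["classify"] = time.perf_counter() - t0
    report["label"] = label
    report["scores"] = {c: float(s) for c, s in zip(model.class_names, scores)}

    t0 = time.perf_counter()
    payload = Path(image_path).read_bytes()
    frames = protocol.packetize(payload)
    report["stages"]["packetize"] = time.perf_counter() - t0
    report["n_frames"] = len(frames)
    report["payload_bytes"] = len(payload)
    if cfg.frames_out:
        with open(cfg.frames_out, "wb") as fh:
            for f in frames:
                fh.write(f.serialize())
        report["frames_out"] = cfg.frames_out

    for stage, dt in report["stages"].items():
        log.info("stage %-10s %.1f ms", stage, dt * 1e3)
    return report
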