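"""End-to-end pipeline: segment → measure → classify → summarize.

One call takes a multichannel section image (or an in-memory phantom) to a
per-sample summary, writing every intermediate table plus a run manifest
(configuration, seed, input digest, library versions) sufficient to
reproduce the run bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ChannelThresholds, classify_fibers, detect_nuclei, score_pax7
from .io import read_section, write_table
from .morphometry import measure_labelmap
from .phantom import CHANNELS, Phantom
from .segmentation import LabelMap, SegmentationConfig, segment_fibers
from .stats import SampleSummary, summarize_sample

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("regenquant")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, JSON-serialisable for the manifest."""

    channel_order: dict[str, int] | None = None  # name -> page index; None = metadata
    pixel_size: float | None = None  # µm/px; None = from image metadata
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    thresholds: ChannelThresholds = field(default_factory=ChannelThresholds)
    outdir: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"
    count_nuclei: bool = True

    def __post_init__(self) -> None:
        if self.channel_order is not None:
            idx = list(self.channel_order.values())
            if len(set(self.channel_order)) != len(self.channel_order) or len(set(idx)) != len(idx):
                raise ValueError("channel names and indices must be unique")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = None if self.outdir is None else str(self.outdir)
        return d


@dataclass
class PipelineResult:
    summary: SampleSummary
    labelmap: LabelMap
    morphometry: pd.DataFrame
    calls: pd.DataFrame
    nuclei: pd.DataFrame | None
    pax7_per_fiber: float | None
    manifest: dict


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def run_pipeline(
    image,
    config: PipelineConfig = PipelineConfig(),
    sample_id: str = "sample",
    age: float = float("nan"),
    status: str = "DMD",
) -> PipelineResult:
    """Run the full quantification on one section.

    ``image`` is a path to a multichannel TIFF, or a :class:`Phantom`.
    Channels named laminin, emhc and igg are required; dapi and pax7 enable
    the satellite-cell count when present.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if isinstance(image, Phantom):
        channels = {n: image.channels[i] for i, n in enumerate(CHANNELS)}
        pixel_size = image.params.pixel_size
        source = f"phantom(seed={image.params.seed})"
    else:
        channels, pixel_size = read_section(image, config.channel_order, config.pixel_size)
        source = str(image)
    if config.pixel_size is not None:
        pixel_size = config.pixel_size

    for required in ("laminin", "emhc", "igg"):
        if required not in channels:
            raise ValueError(f"missing channel {required!r} (have {sorted(channels)})")

    logger.info("segmenting %s (%s px, %.3g µm/px)", sample_id,
                "x".join(map(str, channels["laminin"].shape)), pixel_size)
    labelmap = segment_fibers(channels["laminin"], config.segmentation, pixel_size=pixel_size)
    logger.info("%d fibers segmented", labelmap.n_fibers)

    morpho = measure_labelmap(labelmap)
    calls = classify_fibers(labelmap, channels["emhc"], channels["igg"], config.thresholds)
    calls_df = pd.DataFrame(
        [
            {
                "fiber_id": c.fiber_id,
                "mean_emhc": c.mean_emhc,
                "mean_igg": c.mean_igg,
                "is_emhc_pos": c.is_emhc_pos,
                "is_igg_pos": c.is_igg_pos,
            }
            for c in calls
        ]
    )

    nuclei_df = None
    pax7_per_fiber = None
    if config.count_nuclei and "dapi" in channels and "pax7" in channels:
        nuclei = detect_nuclei(channels["dapi"], config.thresholds, pixel_size=pixel_size)
        scored, pax7_per_fiber = score_pax7(nuclei, channels["pax7"], labelmap, config.thresholds)
        nuclei_df = pd.DataFrame(
            [
                {
                    "nucleus_id": s.nucleus_id,
                    "centroid_y": s.centroid[0],
                    "centroid_x": s.centroid[1],
                    "mean_pax7": s.mean_pax7,
                    "is_pax7_pos": s.is_pax7_pos,
                    "fiber_context": s.fiber_context,
                }
                for s in scored
            ]
        )

    n_igg = float(calls_df["is_igg_pos"].sum())
    n_emhc = float(calls_df["is_emhc_pos"].sum())
    n_total = float(len(calls_df))
    summary = summarize_sample((n_igg, n_emhc, n_total), sample_id, age, status=status)

    manifest = {
        "package": "regenquant",
        "version": __version__,
        "sample_id": sample_id,
        "source": source,
        "pixel_size_um": pixel_size,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "input_digests": {n: _digest(a) for n, a in sorted(channels.items())},
        "versions": _library_versions(),
        "n_fibers": int(labelmap.n_fibers),
        "n_igg": n_igg,
        "n_emhc": n_emhc,
        "ri": summary.ri.value,
        "ri_status": summary.ri.status,
        "pax7_per_fiber": pax7_per_fiber,
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        labelmap.write_tiff(outdir / f"{sample_id}_labels.tif")
        write_table(morpho, outdir / f"{sample_id}_morphometry.csv", "morphometry")
        write_table(calls_df, outdir / f"{sample_id}_calls.csv", "calls")
        if nuclei_df is not None:
            write_table(nuclei_df, outdir / f"{sample_id}_nuclei.csv", "nuclei")
        pd.DataFrame([summary.to_row()]).to_csv(outdir / f"{sample_id}_summary.csv", index=False)
        with open(outdir / f"{sample_id}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        summary=summary,
        labelmap=labelmap,
        morphometry=morpho,
        calls=calls_df,
        nuclei=nuclei_df,
        pax7_per_fiber=pax7_per_fiber,
        manifest=manifest,
    )


def _library_versions() -> dict[str, str]:
    import pandas
    import scipy
    import skimage

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-image": skimage.__version__,
    }
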