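"""File formats, manifests, and run configuration.

Conventions: image coordinates are 0-based (row, col); genomic coordinates
are 1-based in SAM/variant contexts and 0-based half-open in BED outputs
(conversions live here and nowhere else). CSV files are comma-separated,
UTF-8, with a header row. JSON reports are schema-versioned and embed the
fully resolved configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .insertion_locator import InsertionLocus
from .nucleus_segmentation import NucleusLabelMap, SegmentationConfig
from .puncta_detection import PunctaConfig, PunctaSet
from .synthetic_data import FISHImage, ReadRecord

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, with the published defaults."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    percentile: float = 0.95
    override_threshold: dict = field(default_factory=dict)  # probe -> count
    min_match: int = 100            # bp of cassette alignment per anchored mate
    cluster_window: int = 1000      # bp, locus single-linkage window
    verdict_tolerance: int = 1000   # bp around the expected junction
    alpha: float = 0.001
    z_min: float = 10.0
    r_min: float = 0.9
    latency_window_ms: float = 10.0
    n_resamples: int = 1999

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "segmentation" in data:
            data["segmentation"] = SegmentationConfig(**data["segmentation"])
        if "puncta" in data:
            data["puncta"] = PunctaConfig(**data["puncta"])
        cfg = cls(**data)
        if not 0 < cfg.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if cfg.min_match < 1 or cfg.cluster_window < 1:
            raise ValueError("min_match and cluster_window must be >= 1")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class Manifest:
    """One sample: line and region labels plus channel-to-probe mapping."""

    sample_id: str
    line: str                       # e.g. D1-Cre | A2a-Cre | control
    region: str
    image: str                      # TIFF path
    dapi_channel: str = "DAPI"
    cre_probe: str = "iCre"
    target_probe: str = "Drd1a"
    offtarget_probe: str = "Adora2a"

    def probe_channels(self) -> list[str]:
        return [self.cre_probe, self.target_probe, self.offtarget_probe]

    def validate(self, image: FISHImage) -> None:
        missing = [
            ch
            for ch in [self.dapi_channel, *self.probe_channels()]
            if ch not in image.channels
        ]
        if missing:
            raise ValueError(
                f"manifest channels not present in image: {missing}; "
                f"image has {sorted(image.channels)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Manifest":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_fish_tiff(image: FISHImage, path: str | Path) -> None:
    """Multi-page TIFF, one page per channel, labels in the description."""
    stack = np.stack([image.channels[c] for c in image.channel_order])
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        description=json.dumps(
            {"channels": list(image.channel_order),
             "pixel_depth": image.pixel_depth}
        ),
    )


def read_fish_tiff(path: str | Path,
                   channel_order: Sequence[str] | None = None) -> FISHImage:
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    if stack.ndim == 2:
        stack = stack[None]
    names = list(
        channel_order
        or meta.get("channels")
        or [f"channel_{i}" for i in range(len(stack))]
    )
    if len(names) != len(stack):
        raise ValueError(f"{path}: {len(stack)} pages but {len(names)} names")
    return FISHImage(
        channels={n: stack[i] for i, n in enumerate(names)},
        pixel_depth=int(meta.get("pixel_depth", 16)),
        channel_order=tuple(names),
    )


def write_label_map(labels: NucleusLabelMap, tiff_path: str | Path,
                    csv_path: str | Path | None = None) -> None:
    """16-bit label TIFF plus per-label CSV (label, area, centroid)."""
    tifffile.imwrite(str(tiff_path), labels.labels.astype(np.uint16))
    if csv_path is not None:
        from scipy import ndimage as ndi

        ids = sorted(labels.areas)
        if ids:
            coms = ndi.center_of_mass(
                np.ones_like(labels.labels), labels.labels, ids
            )
        else:
            coms = []
        pd.DataFrame(
            {
                "label": ids,
                "area_px": [labels.areas[i] for i in ids],
                "centroid_row": [c[0] for c in coms],
                "centroid_col": [c[1] for c in coms],
            }
        ).to_csv(csv_path, index=False)


def write_puncta_csv(puncta: PunctaSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "row": puncta.centroids[:, 0],
            "col": puncta.centroids[:, 1],
            "size_px": puncta.object_sizes,
        }
    ).to_csv(path, index=False)


def read_puncta_csv(path: str | Path, channel: str = "") -> PunctaSet:
    df = pd.read_csv(path)
    return PunctaSet(
        channel=channel,
        centroids=df[["row", "col"]].to_numpy(dtype=float).reshape(-1, 2),
        object_sizes=df["size_px"].to_numpy(dtype=int),
    )


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(records: Sequence[ReadRecord], genome: dict[str, str],
              path: str | Path) -> None:
    """Standard SAM with the cassette as an extra reference contig."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    ref_ids = {name: i for i, name in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq or "N" * rec.aligned_length
            a.flag = (
                0x1
                | 0x2
                | (0x40 if rec.is_read1 else 0x80)
                | (0x10 if rec.is_reverse else 0x0)
            )
            a.reference_id = ref_ids[rec.contig]
            a.reference_start = rec.pos - 1
            a.mapping_quality = 60
            a.cigarstring = f"{rec.aligned_length}M"
            a.next_reference_id = ref_ids[rec.mate_contig]
            a.next_reference_start = rec.mate_pos - 1
            a.template_length = 0
            fh.write(a)


def write_loci_bed(loci: Sequence[InsertionLocus], path: str | Path) -> None:
    """Loci as BED intervals (0-based half-open, length 1 at the median)."""
    with open(path, "w", encoding="utf-8") as fh:
        for locus in loci:
            start = int(round(locus.position)) - 1
            fh.write(
                f"{locus.contig}\t{start}\t{start + 1}\t"
                f"support={locus.support};span={locus.span}\n"
            )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report(payload: dict, path: str | Path, config: RunConfig | None,
                 seed: int | None, timestamp: str | None = None) -> None:
    """JSON report with schema version + full provenance block."""
    body = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "config": config.to_dict() if config else None,
            "seed": seed,
            "timestamp": timestamp,
        },
    }
    body.update(_jsonable(payload))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(body, fh, indent=2, sort_keys=True)
        fh.write("\n")
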