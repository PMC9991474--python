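"""Cluster-pixel-distribution features and the DAT on-disk table format.

The feature of one ROI is the histogram of its segmentation: the number of
pixels falling in each of the K intensity clusters, taken in canonical
(ascending-centroid) order so that feature i is comparable across images.
Feature tables are persisted as tab-delimited DAT text files with a header
line ``id  c1..cK  label``; a missing label (prediction time) is written as
``?``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from osteoseg.segmentation import SegmentationResult

MISSING_LABEL = "?"
VALID_LABELS = ("nonosteoporosis", "osteoporosis")


@dataclass
class FeatureVector:
    """Per-cluster pixel counts of one segmented ROI.

    ``counts[i]`` is the number of pixels in the i-th (darkest-first)
    cluster; the counts sum to the pixel count of the image.
    """

    counts: np.ndarray
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("counts must be a nonempty 1-D vector")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        self.counts = c

    @property
    def K(self) -> int:
        return int(self.counts.size)


@dataclass
class FeatureTable:
    """A rectangular collection of feature vectors sharing the same K."""

    rows: list[FeatureVector]
    K: int

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.K != self.K:
                raise ValueError(f"row {row.source_id!r} has K={row.K}, table has K={self.K}")

    def __len__(self) -> int:
        return len(self.rows)

    def matrix(self) -> np.ndarray:
        """n x K count matrix (float64)."""
        return np.array([r.counts for r in self.rows], dtype=np.float64).reshape(len(self.rows), self.K)

    def labels(self) -> list[str | None]:
        return [r.label for r in self.rows]


def pixel_distribution(
    seg: SegmentationResult, label: str | None = None, source_id: str = ""
) -> FeatureVector:
    """Count the pixels of each cluster, in canonical centroid order."""
    counts = np.bincount(seg.labels.reshape(-1), minlength=seg.K)
    return FeatureVector(counts=counts, label=label, source_id=source_id)


def write_dat(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as tab-delimited DAT text (lossless for counts)."""
    path = Path(path)
    header = ["id"] + [f"c{i + 1}" for i in range(table.K)] + ["label"]
    lines = ["\t".join(header)]
    for row in table.rows:
        fields = [row.source_id or MISSING_LABEL]
        fields += [str(int(c)) for c in row.counts]
        fields.append(row.label if row.label is not None else MISSING_LABEL)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_dat(path: str | Path) -> FeatureTable:
    """Read a DAT file back into a FeatureTable; round-trips ``write_dat``."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty DAT file (missing header)")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "id" or header[-1] != "label":
        raise ValueError(f"{path}:1: malformed DAT header {lines[0]!r}")
    K = len(header) - 2
    rows: list[FeatureVector] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != K + 2:
            raise ValueError(f"{path}:{lineno}: expected {K + 2} fields, found {len(fields)}")
        try:
            counts = np.array([int(f) for f in fields[1 : K + 1]], dtype=np.int64)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer count field: {exc}") from exc
        label = None if fields[-1] == MISSING_LABEL else fields[-1]
        source_id = "" if fields[0] == MISSING_LABEL else fields[0]
        rows.append(FeatureVector(counts=counts, label=label, source_id=source_id))
    return FeatureTable(rows=rows, K=K)
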