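"""Sequencing-level quality metrics.

Mapping metrics come only from pipeline metadata (they cannot be recomputed
from panel counts); depth metrics come only from the read-count matrix.  The
serialized form labels the provenance of each metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset import ScdnaDataset


class EmptyDatasetError(ValueError):
    pass


@dataclass
class SequencingMetrics:
    n_cells: int
    total_panel_reads: int
    mean_read_pairs_per_amplicon_per_cell: float
    mean_reads_per_cell: float
    per_amplicon_mean: np.ndarray
    n_read_pairs: Optional[int] = None
    n_read_pairs_mapped: Optional[int] = None
    mapping_rate: Optional[float] = None

    def to_dict(self) -> dict:
        """Flat dict for TSV/JSON emission, with provenance labels."""
        d = {
            "n_cells": self.n_cells,
            "total_panel_reads": self.total_panel_reads,
            "mean_read_pairs_per_amplicon_per_cell": self.mean_read_pairs_per_amplicon_per_cell,
            "mean_reads_per_cell": self.mean_reads_per_cell,
            "provenance.depth_metrics": "read_counts matrix",
            "provenance.mapping_metrics": "pipeline metadata",
        }
        for k in ("n_read_pairs", "n_read_pairs_mapped", "mapping_rate"):
            val = getattr(self, k)
            if val is not None:
                d[k] = val
        return d


def compute_sequencing_metrics(dataset: ScdnaDataset) -> SequencingMetrics:
    """Compute the sequencing-tab metrics for one dataset.

    Metadata-only fields (`n_read_pairs`, `n_read_pairs_mapped`,
    `mapping_rate`) stay ``None`` when the corresponding metadata keys are
    absent — they are never silently zero.
    """
    n, a = dataset.n_cells, dataset.n_amplicons
    if n == 0:
        raise EmptyDatasetError("dataset contains no cells")
    total = int(dataset.read_counts.sum())
    meta = dataset.run_metadata
    n_rp = _meta_int(meta, "n_read_pairs")
    n_rpm = _meta_int(meta, "n_read_pairs_mapped")
    rate = None
    if n_rp is not None and n_rpm is not None and n_rp > 0:
        rate = n_rpm / n_rp
    return SequencingMetrics(
        n_cells=n,
        total_panel_reads=total,
        mean_read_pairs_per_amplicon_per_cell=total / (n * a) if a else 0.0,
        mean_reads_per_cell=total / n,
        per_amplicon_mean=dataset.read_counts.mean(axis=0) if a else np.zeros(0),
        n_read_pairs=n_rp,
        n_read_pairs_mapped=n_rpm,
        mapping_rate=rate,
    )


def _meta_int(meta: dict, key: str) -> Optional[int]:
    if key not in meta:
        return None
    try:
        return int(float(meta[key]))
    except (TypeError, ValueError):
        return None
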