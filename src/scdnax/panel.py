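"""Panel-level analysis: read-count normalization, amplicon annotation and
per-amplicon performance summaries.

Normalization is the standard Tapestri-style three-step scheme: divide each
cell's row by its total, divide each amplicon's column by its median over
cells, and multiply by 2 so the per-amplicon median represents diploid copy
number.  Cells with zero total reads are excluded; amplicons with zero
median are reported as degenerate and set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import Amplicon, ScdnaDataset

VALID_BUILDS = ("GRCh37", "GRCh38")

ANNOTATION_COLUMNS = ["chrom", "start", "end", "gene", "exon", "transcript_id", "build"]


class EmptyNormalizationError(ValueError):
    pass


class BuildMismatchError(ValueError):
    pass


@dataclass
class NormalizedCounts:
    matrix: np.ndarray  # cells x A, excluded-cell rows are all-zero
    excluded_cells: list[int]  # zero-total cells
    degenerate_amplicons: list[int]  # zero-median columns


def normalize_read_counts(read_counts: np.ndarray) -> NormalizedCounts:
    """Normalize raw amplicon read counts to diploid-centred copy numbers.

    Steps (on cells with nonzero totals): row / row-total, then
    column / column-median, then x2.  Per-amplicon medians over included
    cells therefore equal 2 for every non-degenerate amplicon.
    """
    rc = np.asarray(read_counts, dtype=float)
    if rc.ndim != 2:
        raise ValueError("read_counts must be a 2-D cells x amplicons matrix")
    if rc.size and (rc < 0).any():
        raise ValueError("read_counts must be non-negative")
    totals = rc.sum(axis=1)
    included = totals > 0
    if not included.any():
        raise EmptyNormalizationError("every cell has zero total reads")
    excluded = np.flatnonzero(~included).tolist()

    norm = np.zeros_like(rc)
    norm[included] = rc[included] / totals[included, None]
    medians = np.median(norm[included], axis=0)  # midpoint convention
    degenerate = np.flatnonzero(medians == 0).tolist()
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(medians > 0, norm / medians, 0.0)
    norm[~included] = 0.0
    return NormalizedCounts(
        matrix=2.0 * norm,
        excluded_cells=excluded,
        degenerate_amplicons=degenerate,
    )


def load_amplicon_annotation(path) -> pd.DataFrame:
    """Load a TSV amplicon annotation table (1-based inclusive coordinates)."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    bad_build = set(table["build"].unique()) - set(VALID_BUILDS)
    if bad_build:
        raise ValueError(f"unknown genome builds in table: {sorted(bad_build)}")
    if (table["start"] > table["end"]).any():
        raise ValueError("annotation rows with start > end")
    return table


def annotate_amplicons(
    amplicons: list[Amplicon], table: pd.DataFrame, build: str
) -> list[Amplicon]:
    """Attach gene/exon/transcript annotation by maximal interval overlap.

    Each amplicon takes the table row (of the requested build) with the
    largest overlap in bases; ties go to the smallest row index.  Amplicons
    with no overlapping row keep absent annotation fields.
    """
    if build not in VALID_BUILDS:
        raise BuildMismatchError(f"unknown genome build {build!r}")
    builds = set(table["build"].unique()) if len(table) else set()
    if builds and builds != {build}:
        raise BuildMismatchError(
            f"annotation table carries builds {sorted(builds)}, requested {build}"
        )
    out = []
    for amp in amplicons:
        rows = table[table["chrom"] == amp.chrom]
        best_idx, best_overlap = None, 0
        for idx, row in rows.iterrows():
            overlap = min(amp.end, row["end"]) - max(amp.start, row["start"]) + 1
            if overlap > best_overlap:  # strict > keeps the first row on ties
                best_overlap, best_idx = overlap, idx
        if best_idx is None:
            out.append(replace(amp))
        else:
            row = table.loc[best_idx]
            out.append(
                replace(
                    amp,
                    gene=_opt(row["gene"]),
                    exon=_opt(row["exon"]),
                    transcript_id=_opt(row["transcript_id"]),
                )
            )
    return out


def _opt(value):
    if pd.isna(value):
        return None
    return str(value)


def amplicon_summary(
    dataset: ScdnaDataset, uniformity_threshold: float = 0.2
) -> pd.DataFrame:
    """Per-amplicon coverage summary plus the panel uniformity flag.

    An amplicon is uniform when its mean raw coverage is at least
    ``uniformity_threshold`` (20% by default) of the panel-wide mean; the
    panel uniformity is the fraction of amplicons flagged uniform
    (``.attrs["panel_uniformity"]``).
    """
    rc = dataset.read_counts
    if dataset.n_cells == 0 or dataset.n_amplicons == 0:
        raise ValueError("dataset has no cells or no amplicons")
    means = rc.mean(axis=0)
    panel_mean = means.mean()
    nc = normalize_read_counts(rc)
    included = [i for i in range(dataset.n_cells) if i not in set(nc.excluded_cells)]
    norm_mean = (
        nc.matrix[included].mean(axis=0) if included else np.zeros(dataset.n_amplicons)
    )
    uniform = means >= uniformity_threshold * panel_mean
    table = pd.DataFrame(
        {
            "amplicon_id": [a.amplicon_id for a in dataset.amplicons],
            "chrom": [a.chrom for a in dataset.amplicons],
            "start": [a.start for a in dataset.amplicons],
            "end": [a.end for a in dataset.amplicons],
            "gene": [a.gene for a in dataset.amplicons],
            "mean_reads": means,
            "median_reads": np.median(rc, axis=0),
            "total_reads": rc.sum(axis=0),
            "normalized_mean": norm_mean,
            "uniform": uniform,
        }
    )
    table.attrs["panel_uniformity"] = float(uniform.mean())
    table.attrs["n_genes"] = len(
        {a.gene for a in dataset.amplicons if a.gene is not None}
    )
    return table
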