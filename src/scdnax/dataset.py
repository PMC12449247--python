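"""In-memory model of a Tapestri-style single-cell DNA dataset.

A :class:`ScdnaDataset` is the in-memory twin of one ``.h5`` file produced by
the Tapestri pipeline: a cells x amplicons read-count matrix plus four
cells x variants call layers —

* ``af``  — variant allele frequency (VAF) per cell, percent in [0, 100]
* ``dp``  — read depth per call, non-negative
* ``gq``  — genotype quality, 0–99
* ``ngt`` — genotype code: 0 wild-type, 1 heterozygous, 2 homozygous
  alternate, 3 missing

together with the amplicon panel, the variant list and run metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

NGT_WT = 0
NGT_HET = 1
NGT_HOM = 2
NGT_MISSING = 3

#: metadata keys the validity check treats as required
REQUIRED_METADATA_KEYS = (
    "sample_name",
    "panel_name",
    "genome_build",
    "n_read_pairs",
    "n_read_pairs_mapped",
)


@dataclass
class Amplicon:
    """A PCR-targeted genomic interval of the panel (1-based, inclusive)."""

    amplicon_id: str
    chrom: str
    start: int
    end: int
    gene: Optional[str] = None
    exon: Optional[str] = None
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"amplicon {self.amplicon_id}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class VariantAnnotation:
    """Biological annotation of a variant (offline table driven)."""

    gene: Optional[str] = None
    protein_change: Optional[str] = None
    coding_effect: Optional[str] = None
    function_class: Optional[str] = None
    clinvar: Optional[str] = None
    dbsnp_id: Optional[str] = None
    dann: Optional[float] = None  # deleteriousness score in [0, 1]

    def __post_init__(self) -> None:
        if self.dann is not None and not (0.0 <= self.dann <= 1.0):
            raise ValueError(f"DANN score {self.dann} outside [0, 1]")

    def is_empty(self) -> bool:
        return all(
            getattr(self, f) is None
            for f in (
                "gene",
                "protein_change",
                "coding_effect",
                "function_class",
                "clinvar",
                "dbsnp_id",
                "dann",
            )
        )


@dataclass
class Variant:
    """A single-nucleotide variant keyed by (chrom, pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: Optional[VariantAnnotation] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"variant {self.key}: ref equals alt")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}/{self.alt}"


@dataclass
class ValidationReport:
    """Outcome of the file validity check: one entry per check."""

    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return all(passed for _, passed, _ in self.checks)

    def add(self, name: str, passed: bool, message: str = "") -> None:
        self.checks.append((name, passed, message))

    def failures(self) -> list[tuple[str, str]]:
        return [(n, m) for n, p, m in self.checks if not p]

    def __str__(self) -> str:
        lines = [f"valid: {self.valid}"]
        for name, passed, msg in self.checks:
            status = "PASS" if passed else "FAIL"
            lines.append(f"  [{status}] {name}" + (f": {msg}" if msg else ""))
        return "\n".join(lines)


class SchemaError(ValueError):
    """A required HDF5 group/dataset is missing."""


class ConsistencyError(ValueError):
    """Matrix dimensions or invariants disagree."""


@dataclass
class ScdnaDataset:
    """One Tapestri-style run: read counts, call layers, panel and metadata."""

    cell_barcodes: list[str]
    amplicons: list[Amplicon]
    variants: list[Variant]
    read_counts: np.ndarray  # cells x A, int
    af: np.ndarray  # cells x V, percent
    dp: np.ndarray  # cells x V, int
    gq: np.ndarray  # cells x V, int
    ngt: np.ndarray  # cells x V, codes {0,1,2,3}
    run_metadata: dict[str, str] = field(default_factory=dict)
    #: calls coerced to missing on read because DP = 0 (not compared by equals)
    n_calls_coerced_missing: int = 0

    # -- basic shape accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicons)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_keys(self) -> list[tuple[str, int, str, str]]:
        return [v.key for v in self.variants]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    # -- invariants ------------------------------------------------------------

    def invariant_violations(self) -> list[str]:
        """Return human-readable descriptions of every violated invariant."""
        out: list[str] = []
        n, a, v = self.n_cells, self.n_amplicons, self.n_variants
        if self.read_counts.shape != (n, a):
            out.append(
                f"read_counts shape {self.read_counts.shape} != ({n}, {a})"
            )
        for name in ("af", "dp", "gq", "ngt"):
            m = getattr(self, name)
            if m.shape != (n, v):
                out.append(f"{name} shape {m.shape} != ({n}, {v})")
        if out:  # shape errors make element checks meaningless
            return out
        if len(set(self.cell_barcodes)) != n:
            out.append("cell barcodes are not unique")
        keys = self.variant_keys
        if len(set(keys)) != v:
            out.append("variant keys (chrom,pos,ref,alt) are not unique")
        if not np.isin(self.ngt, (0, 1, 2, 3)).all():
            bad = np.unique(self.ngt[~np.isin(self.ngt, (0, 1, 2, 3))])
            out.append(f"NGT contains codes outside {{0,1,2,3}}: {bad.tolist()}")
        if self.af.size and ((self.af < 0) | (self.af > 100)).any():
            out.append("AF contains values outside [0, 100]")
        if self.dp.size and (self.dp < 0).any():
            out.append("DP contains negative values")
        if self.gq.size and ((self.gq < 0) | (self.gq > 99)).any():
            out.append("GQ contains values outside [0, 99]")
        if self.read_counts.size and (self.read_counts < 0).any():
            out.append("read_counts contains negative values")
        zero_dp = self.dp == 0
        if zero_dp.any():
            if (self.af[zero_dp] != 0).any():
                out.append("AF nonzero at calls with DP = 0")
            if (self.ngt[zero_dp] != NGT_MISSING).any():
                out.append("NGT not missing (3) at calls with DP = 0")
        return out

    def check_invariants(self) -> None:
        """Raise :class:`ConsistencyError` listing all violated invariants."""
        bad = self.invariant_violations()
        if bad:
            raise ConsistencyError("; ".join(bad))

    # -- operations ------------------------------------------------------------

    def subset(
        self,
        keep_cells: Optional[Sequence[int]] = None,
        keep_variants: Optional[Sequence[int]] = None,
    ) -> "ScdnaDataset":
        """Select cells (rows) and variants (call-layer columns), in order.

        ``read_counts`` keeps all amplicons — the panel is a property of the
        run, not of the variant selection.  Passing ``None`` keeps that axis
        untouched.
        """
        if keep_cells is None:
            keep_cells = range(self.n_cells)
        if keep_variants is None:
            keep_variants = range(self.n_variants)
        ci = _checked_index(keep_cells, self.n_cells, "cell")
        vi = _checked_index(keep_variants, self.n_variants, "variant")
        return ScdnaDataset(
            cell_barcodes=[self.cell_barcodes[i] for i in ci],
            amplicons=list(self.amplicons),
            variants=[self.variants[j] for j in vi],
            read_counts=self.read_counts[ci, :].copy(),
            af=self.af[np.ix_(ci, vi)].copy() if len(ci) and len(vi) else
            np.zeros((len(ci), len(vi)), dtype=self.af.dtype),
            dp=_take2(self.dp, ci, vi),
            gq=_take2(self.gq, ci, vi),
            ngt=_take2(self.ngt, ci, vi),
            run_metadata=dict(self.run_metadata),
        )

    def copy(self) -> "ScdnaDataset":
        return ScdnaDataset(
            cell_barcodes=list(self.cell_barcodes),
            amplicons=[replace(a) for a in self.amplicons],
            variants=[replace(v) for v in self.variants],
            read_counts=self.read_counts.copy(),
            af=self.af.copy(),
            dp=self.dp.copy(),
            gq=self.gq.copy(),
            ngt=self.ngt.copy(),
            run_metadata=dict(self.run_metadata),
        )

    def equals(self, other: "ScdnaDataset", af_atol: float = 1e-9) -> bool:
        """Field-by-field equality; integer layers exact, AF within tolerance."""
        if self.cell_barcodes != other.cell_barcodes:
            return False
        if [a.amplicon_id for a in self.amplicons] != [
            a.amplicon_id for a in other.amplicons
        ]:
            return False
        if self.variant_keys != other.variant_keys:
            return False
        for name in ("read_counts", "dp", "gq", "ngt"):
            if not np.array_equal(getattr(self, name), getattr(other, name)):
                return False
        if self.af.shape != other.af.shape:
            return False
        if self.af.size and not np.allclose(self.af, other.af, atol=af_atol):
            return False
        return self.run_metadata == other.run_metadata


def _take2(m: np.ndarray, ci: np.ndarray, vi: np.ndarray) -> np.ndarray:
    if len(ci) and len(vi):
        return m[np.ix_(ci, vi)].copy()
    return np.zeros((len(ci), len(vi)), dtype=m.dtype)


def _checked_index(idx: Sequence[int], n: int, what: str) -> np.ndarray:
    arr = np.asarray(list(idx), dtype=np.intp)
    if arr.size and (arr.min() < 0 or arr.max() >= n):
        raise IndexError(f"{what} index out of range [0, {n})")
    if len(np.unique(arr)) != len(arr):
        raise IndexError(f"duplicate {what} indices")
    return arr


def subset(
    dataset: ScdnaDataset,
    keep_cells: Optional[Sequence[int]] = None,
    keep_variants: Optional[Sequence[int]] = None,
) -> ScdnaDataset:
    """Functional alias for :meth:`ScdnaDataset.subset`."""
    return dataset.subset(keep_cells, keep_variants)
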