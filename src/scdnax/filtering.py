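"""Variant filtering and annotation.

The filter is a fixed three-stage single pass:

1. **Mask low-quality calls** — a call is recoded missing (NGT = 3) if its
   depth is below ``min_dp``, its genotype quality below ``min_gq``, or it
   is a mutant call (het/hom) with VAF below ``min_vaf_mut``.  AF/DP/GQ are
   preserved for transparency.
2. **Drop variants** genotyped in too few cells, or mutated in too few /
   too many cells (fractions over *all* cells).
3. **Drop cells** genotyped in too small a fraction of the surviving
   variants.

All thresholds are user-adjustable via :class:`FilterConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ScdnaDataset, Variant, VariantAnnotation

VARIANT_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "coding_effect",
    "function_class",
    "clinvar",
    "dbsnp_id",
    "dann",
]


@dataclass
class FilterConfig:
    """Adjustable thresholds; defaults follow the Tapestri Insights/mosaic
    convention the workflow adapts."""

    min_dp: int = 10
    min_gq: int = 30
    min_vaf_mut: float = 20.0  # percent; applies to calls with NGT in {1,2}
    min_genotyped_cells_frac: float = 0.5
    min_mutated_cells_frac: float = 0.01
    max_mutated_cells_frac: float = 1.0
    min_cell_genotyped_frac: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "min_genotyped_cells_frac",
            "min_mutated_cells_frac",
            "max_mutated_cells_frac",
            "min_cell_genotyped_frac",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.min_dp < 0 or self.min_gq < 0 or self.min_vaf_mut < 0:
            raise ValueError("thresholds must be non-negative")

    def to_dict(self) -> dict:
        return {
            "min_dp": self.min_dp,
            "min_gq": self.min_gq,
            "min_vaf_mut": self.min_vaf_mut,
            "min_genotyped_cells_frac": self.min_genotyped_cells_frac,
            "min_mutated_cells_frac": self.min_mutated_cells_frac,
            "max_mutated_cells_frac": self.max_mutated_cells_frac,
            "min_cell_genotyped_frac": self.min_cell_genotyped_frac,
        }


@dataclass
class FilterReport:
    n_variants_in: int
    n_cells_in: int
    n_calls_masked: int
    n_variants_out: int
    n_cells_out: int
    per_rule: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_variants_in": self.n_variants_in,
            "n_cells_in": self.n_cells_in,
            "n_calls_masked": self.n_calls_masked,
            "n_variants_out": self.n_variants_out,
            "n_cells_out": self.n_cells_out,
            "per_rule": dict(self.per_rule),
        }

    def __str__(self) -> str:
        lines = [
            f"variants: {self.n_variants_in} -> {self.n_variants_out}",
            f"cells:    {self.n_cells_in} -> {self.n_cells_out}",
            f"calls masked: {self.n_calls_masked}",
        ]
        for rule, n in self.per_rule.items():
            lines.append(f"  {rule}: {n}")
        return "\n".join(lines)


def mask_low_quality_calls(
    dataset: ScdnaDataset, config: FilterConfig
) -> tuple[ScdnaDataset, int]:
    """Recode failing calls as missing; returns the new dataset and count.

    Already-missing calls are not recounted.  The VAF rule applies only to
    mutant (het/hom) calls, so confident wild-type calls with VAF 0 pass.
    """
    ds = dataset.copy()
    mutant = np.isin(ds.ngt, (1, 2))
    fail = (ds.dp < config.min_dp) | (ds.gq < config.min_gq) | (
        mutant & (ds.af < config.min_vaf_mut)
    )
    newly = fail & (ds.ngt != 3)
    ds.ngt[newly] = 3
    return ds, int(newly.sum())


def filter_variants(
    dataset: ScdnaDataset, config: FilterConfig | None = None
) -> tuple[ScdnaDataset, FilterReport]:
    """Run the full mask -> variant-drop -> cell-drop pipeline, once."""
    if config is None:
        config = FilterConfig()
    n_in, v_in = dataset.n_cells, dataset.n_variants
    masked_ds, n_masked = mask_low_quality_calls(dataset, config)

    genotyped = masked_ds.ngt != 3
    mutated = np.isin(masked_ds.ngt, (1, 2))
    geno_frac = genotyped.mean(axis=0) if n_in else np.zeros(v_in)
    mut_frac = mutated.mean(axis=0) if n_in else np.zeros(v_in)

    fail_geno = geno_frac < config.min_genotyped_cells_frac
    fail_mut = (mut_frac < config.min_mutated_cells_frac) | (
        mut_frac > config.max_mutated_cells_frac
    )
    keep_variants = np.flatnonzero(~(fail_geno | fail_mut))

    after_vars = masked_ds.subset(keep_variants=keep_variants)
    if len(keep_variants):
        cell_geno_frac = (after_vars.ngt != 3).mean(axis=1)
    else:
        cell_geno_frac = np.zeros(n_in)
    keep_cells = np.flatnonzero(cell_geno_frac >= config.min_cell_genotyped_frac)
    out = after_vars.subset(keep_cells=keep_cells)

    report = FilterReport(
        n_variants_in=v_in,
        n_cells_in=n_in,
        n_calls_masked=n_masked,
        n_variants_out=out.n_variants,
        n_cells_out=out.n_cells,
        per_rule={
            "variants_low_genotyped_fraction": int(fail_geno.sum()),
            "variants_mutated_fraction_out_of_bounds": int(
                (fail_mut & ~fail_geno).sum()
            ),
            "cells_low_genotyped_fraction": int(n_in - len(keep_cells)),
        },
    )
    return out, report


class AnnotationTableError(ValueError):
    pass


def load_variant_annotation(path) -> pd.DataFrame:
    """Load a variant annotation TSV keyed by (chrom, pos, ref, alt).

    Enforces DANN scores in [0, 1]; a violating row raises with its line
    number (1-based, counting the header as line 1).
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in VARIANT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise AnnotationTableError(f"annotation table missing columns: {missing}")
    dann = pd.to_numeric(table["dann"], errors="coerce")
    bad = table.index[dann.notna() & ((dann < 0) | (dann > 1))]
    if len(bad):
        line = int(bad[0]) + 2  # header + 1-based
        raise AnnotationTableError(
            f"line {line}: DANN score {table.loc[bad[0], 'dann']} outside [0, 1]"
        )
    table["dann"] = dann
    return table


def annotate_variants(variants: list[Variant], table: pd.DataFrame) -> list[Variant]:
    """Attach annotations by exact (chrom, pos, ref, alt) match, preserving
    input order; non-matches get an empty annotation."""
    index = {
        (str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"])): r
        for _, r in table.iterrows()
    }
    out = []
    for v in variants:
        row = index.get(v.key)
        if row is None:
            ann = VariantAnnotation()
        else:
            dann = row["dann"]
            ann = VariantAnnotation(
                gene=_opt(row["gene"]),
                protein_change=_opt(row["protein_change"]),
                coding_effect=_opt(row["coding_effect"]),
                function_class=_opt(row["function_class"]),
                clinvar=_opt(row["clinvar"]),
                dbsnp_id=_opt(row["dbsnp_id"]),
                dann=None if pd.isna(dann) else float(dann),
            )
        out.append(Variant(v.chrom, v.pos, v.ref, v.alt, annotation=ann))
    return out


def _opt(value):
    if pd.isna(value):
        return None
    return str(value)


def vaf_genotype_strata(
    dataset: ScdnaDataset, variant_index: int, bounds: tuple[float, float]
) -> tuple[float, float]:
    """Fractions of cells with VAF 0 and VAF inside ``bounds`` at a variant.

    Both numerators count only genotyped cells (NGT != 3); both fractions
    are relative to all cells in the dataset.
    """
    low, high = bounds
    if low > high:
        raise ValueError(f"lower bound {low} exceeds upper bound {high}")
    if not (0 <= variant_index < dataset.n_variants):
        raise IndexError(f"variant index {variant_index} out of range")
    af = dataset.af[:, variant_index]
    called = dataset.ngt[:, variant_index] != 3
    n = dataset.n_cells
    frac_zero = float((called & (af == 0)).sum() / n)
    frac_in = float((called & (af >= low) & (af <= high)).sum() / n)
    return frac_zero, frac_in


def variants_to_vcf(variants: list[Variant], path) -> None:
    """Export filtered variants as a minimal VCF (annotation in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene name">\n')
        fh.write('##INFO=<ID=DANN,Number=1,Type=Float,Description="DANN score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            ann = v.annotation or VariantAnnotation()
            vid = ann.dbsnp_id or "."
            info = []
            if ann.gene:
                info.append(f"GENE={ann.gene}")
            if ann.dann is not None:
                info.append(f"DANN={ann.dann:.4f}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t"
                + (";".join(info) or ".")
                + "\n"
            )
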