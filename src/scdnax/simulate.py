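"""Synthetic Tapestri-style datasets with known clonal ground truth.

The generator emulates a K-clone cell mixture genotyped over a targeted
amplicon panel:

* each cell is drawn from one clone (categorical over clone fractions);
* per variant call, read depth is negative-binomial, alternate-read counts
  binomial given the clone genotype's expected VAF
  (``100*eps`` for wild-type, 50 for het, ``100*(1-eps)`` for hom-alt);
* allele dropout (ADO) relabels a heterozygous genotype to hom-ref or
  hom-alt with a fair coin before reads are drawn;
* calls may additionally be forced missing (NGT = 3);
* per-amplicon read-pair counts are negative-binomial with lognormal
  amplicon efficiencies and lognormal cell size factors.

All randomness comes from one seeded :class:`numpy.random.Generator`;
identical configs produce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Amplicon, ScdnaDataset, Variant

_CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulated run.

    ``clone_genotypes`` is K x V with codes {0 wild-type, 1 het, 2 hom-alt};
    ``mean_depth`` is the expected reads per variant call, ``counts_mean``
    the expected read pairs per amplicon per cell, ``depth_dispersion`` the
    shared negative-binomial size parameter.
    """

    n_cells: int = 1000
    clone_fractions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    clone_genotypes: tuple[tuple[int, ...], ...] = (
        (0, 0, 0, 0),
        (1, 0, 2, 0),
        (2, 1, 0, 1),
        (1, 2, 1, 2),
    )
    n_amplicons: int = 24
    mean_depth: float = 80.0
    depth_dispersion: float = 8.0
    error_rate: float = 0.01
    ado_rate: float = 0.05
    missing_rate: float = 0.05
    counts_mean: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.clone_fractions, dtype=float)
        if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("clone_fractions must be non-negative and sum to 1")
        g = np.asarray(self.clone_genotypes)
        if g.ndim != 2 or g.shape[0] != len(fr):
            raise ValueError(
                f"clone_genotypes must be K x V with K = {len(fr)}, got shape {g.shape}"
            )
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("clone genotype codes must be in {0, 1, 2}")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")
        for name in ("ado_rate", "missing_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0 or self.counts_mean <= 0:
            raise ValueError("mean_depth, depth_dispersion and counts_mean must be > 0")

    @property
    def n_clones(self) -> int:
        return len(self.clone_fractions)

    @property
    def n_variants(self) -> int:
        return len(self.clone_genotypes[0])


@dataclass
class SimTruth:
    """Ground truth emitted with each simulated dataset."""

    clone_label: np.ndarray  # per cell, in [0, K)
    clone_genotypes: np.ndarray  # K x V, codes {0,1,2}
    expected_vaf: np.ndarray  # K x V, percent, pre-dropout
    amplicon_efficiency: np.ndarray = field(default=None)  # length A, mean 1


def expected_vaf(clone_genotypes: np.ndarray, error_rate: float) -> np.ndarray:
    """Expected VAF (percent) per genotype code: 100*eps / 50 / 100*(1-eps)."""
    g = np.asarray(clone_genotypes)
    mu = np.empty(g.shape, dtype=float)
    mu[g == 0] = 100.0 * error_rate
    mu[g == 1] = 50.0
    mu[g == 2] = 100.0 * (1.0 - error_rate)
    return mu


def _negbin(rng: np.random.Generator, mean, size_param: float, shape) -> np.ndarray:
    """Negative binomial parameterized by (mean, size)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), shape)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=shape)


def simulate_dataset(config: SimConfig) -> tuple[ScdnaDataset, SimTruth]:
    """Draw one dataset + ground truth from the generative model above."""
    rng = np.random.default_rng(config.seed)
    n, k, v, a = config.n_cells, config.n_clones, config.n_variants, config.n_amplicons
    genotypes = np.asarray(config.clone_genotypes, dtype=np.int64)

    clone = rng.choice(k, size=n, p=np.asarray(config.clone_fractions, dtype=float))
    g = genotypes[clone, :]  # cells x V realized (pre-ADO) genotypes

    # allele dropout: het -> hom-ref or hom-alt with a fair coin
    if config.ado_rate > 0:
        het = g == 1
        drop = het & (rng.random(g.shape) < config.ado_rate)
        g = np.where(drop, np.where(rng.random(g.shape) < 0.5, 0, 2), g)

    mu = expected_vaf(g, config.error_rate) / 100.0
    dp = _negbin(rng, config.mean_depth, config.depth_dispersion, (n, v)).astype(np.int64)
    alt = rng.binomial(dp, mu)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(dp > 0, 100.0 * alt / np.maximum(dp, 1), 0.0)

    ngt = g.copy()
    forced = rng.random((n, v)) < config.missing_rate
    ngt[forced | (dp == 0)] = 3
    af[dp == 0] = 0.0
    gq = np.where(ngt != 3, np.minimum(99, np.round(3 * dp)).astype(np.int64), 0)

    # amplicon read counts: efficiency- and cell-size-structured negative binomial
    eff = rng.lognormal(0.0, 0.25, size=a)
    eff = eff / eff.mean()
    size_factor = rng.lognormal(0.0, 0.1, size=n)
    size_factor = size_factor / size_factor.mean()
    rc_mean = config.counts_mean * np.outer(size_factor, eff)
    read_counts = _negbin(rng, rc_mean, config.depth_dispersion, (n, a)).astype(np.int64)

    amp_chrom = rng.choice(_CHROMS, size=a)
    amp_start = rng.integers(1_000_000, 200_000_000, size=a)
    amplicons = [
        Amplicon(
            amplicon_id=f"AMPL{i:04d}",
            chrom=str(amp_chrom[i]),
            start=int(amp_start[i]),
            end=int(amp_start[i]) + 249,
        )
        for i in range(a)
    ]
    var_chrom = rng.choice(_CHROMS, size=v)
    var_pos = rng.integers(1_000_000, 200_000_000, size=v)
    refs = rng.integers(0, 4, size=v)
    alts = (refs + rng.integers(1, 4, size=v)) % 4  # always differs from ref
    variants = [
        Variant(
            chrom=str(var_chrom[j]),
            pos=int(var_pos[j]),
            ref=str(_BASES[refs[j]]),
            alt=str(_BASES[alts[j]]),
        )
        for j in range(v)
    ]
    # regenerate any accidentally duplicated variant keys deterministically
    seen: set = set()
    for j, var in enumerate(variants):
        while var.key in seen:
            var.pos += 1
        seen.add(var.key)

    total_reads = int(read_counts.sum())
    dataset = ScdnaDataset(
        cell_barcodes=[f"CELL{i:06d}" for i in range(n)],
        amplicons=amplicons,
        variants=variants,
        read_counts=read_counts,
        af=af,
        dp=dp,
        gq=gq,
        ngt=ngt,
        run_metadata={
            "sample_name": "synthetic-clone-mix",
            "panel_name": f"synthetic-panel-{a}",
            "genome_build": "GRCh38",
            "n_read_pairs": str(int(round(total_reads / 0.9))),
            "n_read_pairs_mapped": str(total_reads),
        },
    )
    dataset.check_invariants()
    truth = SimTruth(
        clone_label=clone,
        clone_genotypes=genotypes,
        expected_vaf=expected_vaf(genotypes, config.error_rate),
        amplicon_efficiency=eff,
    )
    return dataset, truth
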