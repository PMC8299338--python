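"""Variant- and sample-level quality control.

Variant filters (applied in a fixed order so per-filter counts are
reproducible): genotype call rate, minor-allele frequency, Hardy-Weinberg
exact test, duplicated (chrom, pos).  Sample filter: greedy pruning of
pairs with method-of-moments PI_HAT relatedness above a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import MISSING, HaplotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Thresholds for variant/sample filtering.

    min_call_rate : minimum fraction of non-missing genotypes per SNP.
    min_maf       : minimum minor-allele frequency.
    hwe_p_floor   : SNPs with exact-test p below this are removed.
    pihat_max     : sample pairs with PI_HAT above this trigger pruning.
    prune_related : whether to run the relatedness pruning step.  Off by
                    default: in a small closed herd background kinship sits
                    near the threshold and greedy pruning removes most of
                    the sample; enable it for samples expected to be
                    mostly unrelated.
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_p_floor: float = 0.001
    pihat_max: float = 0.1
    prune_related: bool = False

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_floor", "pihat_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_variants_in: int = 0
    n_samples_in: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_duplicate: int = 0
    removed_samples_related: int = 0
    related_sample_ids: list = field(default_factory=list)
    n_variants_out: int = 0
    n_samples_out: int = 0

    def check(self) -> None:
        removed = (
            self.removed_call_rate + self.removed_maf
            + self.removed_hwe + self.removed_duplicate
        )
        assert removed + self.n_variants_out == self.n_variants_in
        assert self.removed_samples_related + self.n_samples_out == self.n_samples_in

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [(k, getattr(self, k)) for k in (
            "n_variants_in", "n_samples_in", "removed_call_rate", "removed_maf",
            "removed_hwe", "removed_duplicate", "removed_samples_related",
            "n_variants_out", "n_samples_out")]
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
            path, sep="\t", index=False)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditional on the observed allele counts, the p-value is the summed
    probability of every heterozygote configuration whose probability is
    no larger than that of the observed configuration.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("all genotype counts zero")
    n_a = 2 * n_aa + n_Aa  # minor-allele copies (either allele works)
    n_a = min(n_a, 2 * n - n_a)
    # P(het = h | n, allele counts) ∝ n! / (nAA! h! naa!) * 2^h
    hets = np.arange(n_a % 2, n_a + 1, 2)
    n_hom_rare = (n_a - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(n_hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.where(hets == n_Aa)[0][0]]
    # small relative slack so float ties count as ties
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _genotype_counts(genotypes: np.ndarray):
    """Per-SNP counts of (hom-ref, het, hom-alt) ignoring missing."""
    n_aa = (genotypes == 0).sum(axis=0)
    n_het = (genotypes == 1).sum(axis=0)
    n_AA = (genotypes == 2).sum(axis=0)
    return n_aa, n_het, n_AA


def filter_variants(
    mat: HaplotypeMatrix, qc: QCConfig | None = None
) -> tuple[HaplotypeMatrix, QCReport]:
    """Apply the variant filters in order call-rate -> MAF -> HWE ->
    duplicate positions; each filter sees only the survivors of the
    previous one."""
    qc = qc or QCConfig()
    report = QCReport(
        n_variants_in=mat.n_loci,
        n_samples_in=mat.n_samples,
        n_samples_out=mat.n_samples,
    )
    g = mat.genotypes()
    valid = g != MISSING
    keep = np.ones(mat.n_loci, dtype=bool)

    call_rate = valid.mean(axis=0)
    fail = keep & (call_rate < qc.min_call_rate)
    report.removed_call_rate = int(fail.sum())
    keep &= ~fail

    with np.errstate(invalid="ignore", divide="ignore"):
        n_alleles = 2.0 * valid.sum(axis=0)
        alt = np.where(valid, g, 0).sum(axis=0)
        p = np.divide(alt, n_alleles, out=np.zeros(mat.n_loci), where=n_alleles > 0)
    maf = np.minimum(p, 1.0 - p)
    fail = keep & (maf < qc.min_maf)
    report.removed_maf = int(fail.sum())
    keep &= ~fail

    n0, n1, n2 = _genotype_counts(np.where(valid, g, MISSING))
    hwe_fail = np.zeros(mat.n_loci, dtype=bool)
    for j in np.where(keep)[0]:
        if n0[j] + n1[j] + n2[j] == 0:
            continue
        if hwe_exact_p(int(n2[j]), int(n1[j]), int(n0[j])) < qc.hwe_p_floor:
            hwe_fail[j] = True
    report.removed_hwe = int(hwe_fail.sum())
    keep &= ~hwe_fail

    seen: set[tuple] = set()
    dup = np.zeros(mat.n_loci, dtype=bool)
    vm = mat.variant_map
    for j in np.where(keep)[0]:
        key = (vm["chrom"].iat[j], int(vm["pos"].iat[j]))
        if key in seen:
            dup[j] = True
        seen.add(key)
    report.removed_duplicate = int(dup.sum())
    keep &= ~dup

    report.n_variants_out = int(keep.sum())
    report.check()
    if report.n_variants_out == 0:
        logger.warning("all variants removed by QC")
    return mat.take_loci(np.where(keep)[0]), report


def pihat_matrix(mat: HaplotypeMatrix) -> np.ndarray:
    """Pairwise PI_HAT (n_samples x n_samples, diagonal NaN).

    Method-of-moments IBD estimation: per pair, observed IBS-state counts
    are compared with their expectations under IBD states 0/1/2 given the
    sample allele frequencies; negative component estimates are truncated
    to 0 and the triple renormalized.  PI_HAT = P(IBD=2) + P(IBD=1)/2.
    """
    if mat.n_samples < 2:
        raise ValueError("need at least two samples")
    g = mat.genotypes().astype(np.float64)
    valid = g != MISSING

    n_al = 2.0 * valid.sum(axis=0)
    alt = np.where(valid, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.divide(alt, n_al, out=np.full(mat.n_loci, np.nan), where=n_al > 0)
    poly = valid.any(axis=0) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic loci: IBD moments undefined")
    g = g[:, poly]
    valid = valid[:, poly]
    p = p[poly]
    q = 1.0 - p

    # per-locus IBS-state probabilities under each IBD state
    e0_ibs0 = 2.0 * p**2 * q**2
    e0_ibs1 = 4.0 * p**3 * q + 4.0 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4.0 * p**2 * q**2
    e1_ibs1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e1_ibs2 = p**2 + q**2 + 2.0 * p * q  # == 1 - e1_ibs1 but kept explicit

    V = valid.astype(np.float64)
    I0 = ((g == 0) & valid).astype(np.float64)
    I1 = ((g == 1) & valid).astype(np.float64)
    I2 = ((g == 2) & valid).astype(np.float64)

    n_valid = V @ V.T
    ibs2 = I0 @ I0.T + I1 @ I1.T + I2 @ I2.T
    ibs0 = I0 @ I2.T + I2 @ I0.T
    ibs1 = n_valid - ibs2 - ibs0

    E0_0 = (V * e0_ibs0) @ V.T
    E0_1 = (V * e0_ibs1) @ V.T
    E0_2 = (V * e0_ibs2) @ V.T
    E1_1 = (V * e1_ibs1) @ V.T
    E1_2 = (V * e1_ibs2) @ V.T

    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = ibs0 / E0_0
        z1 = (ibs1 - z0 * E0_1) / E1_1
        z2 = (ibs2 - z0 * E0_2 - z1 * E1_2) / n_valid
    z = np.stack([z0, z1, z2])
    z = np.clip(z, 0.0, None)
    tot = z.sum(axis=0)
    tot[tot == 0] = 1.0
    z /= tot
    pihat = z[2] + 0.5 * z[1]
    pihat = np.clip(pihat, 0.0, 1.0)
    pihat = 0.5 * (pihat + pihat.T)
    np.fill_diagonal(pihat, np.nan)
    return pihat


def exclude_related(
    mat: HaplotypeMatrix, pihat_max: float = 0.1
) -> tuple[HaplotypeMatrix, list[str]]:
    """Greedy relatedness pruning.

    Repeatedly remove the sample participating in the most pairs with
    PI_HAT above the threshold (ties broken by lexicographically smallest
    sample id) until no such pair remains.
    """
    pihat = pihat_matrix(mat)
    adj = np.triu(pihat > pihat_max, k=1)
    adj = adj | adj.T
    removed: list[str] = []
    active = np.ones(mat.n_samples, dtype=bool)
    while True:
        degree = (adj & active[None, :] & active[:, None]).sum(axis=1)
        degree[~active] = 0
        if degree.max() == 0:
            break
        top = degree.max()
        candidates = [i for i in np.where(degree == top)[0]]
        victim = min(candidates, key=lambda i: mat.sample_ids[i])
        active[victim] = False
        removed.append(mat.sample_ids[victim])
    if removed:
        logger.info("removed %d related samples: %s", len(removed), removed)
    return mat.take_samples(np.where(active)[0]), removed
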