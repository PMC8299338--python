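"""Forward Wright-Fisher simulator for phased SNP data.

Generates the statistical structure the scan assumes without any external
download: a neutral, LD-bearing background (discrete-generation random
mating with recombination among standing variants), an optional hard
selective sweep at a known focal SNP (additive viability selection on
standing variation planted at a low start frequency), and a
founder/descendant subpopulation split with extra drift generations for
the FST contrast.

No new mutations arise during the simulation, so every locus stays
biallelic and the focal-site bookkeeping is exact.  Founder allele
frequencies follow a Beta(0.5, 0.5) truncated to [0.05, 0.95] -- the
U-shaped spectrum of an ascertained SNP array, kept clear of the MAF
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MAP_COLUMNS, HaplotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SweepSimConfig:
    """Simulation parameters.

    n_diploids     : breeding population size (default 200).
    n_snps         : SNPs per chromosome (default 2,000).
    n_chroms       : chromosomes (default 3); unlinked to each other.
    snp_spacing_bp : physical spacing between adjacent SNPs (25 kb).
    recomb_rate    : per-interval per-meiosis crossover probability (1e-3).
    s              : additive selection coefficient (0.05; 0 => neutral,
                     no sweep planted).
    f0             : beneficial-allele start frequency (0.05).
    sweep_chrom    : 0-based index of the swept chromosome.
    sweep_index    : 0-based SNP index of the focal site on that
                     chromosome (None => middle SNP).
    burnin_gens    : neutral generations building LD and drift (200).
    selection_gens : generations of selection after planting (150).
    sample_n       : diploids sampled without replacement at the end (150).
    seed           : random seed.
    """

    n_diploids: int = 200
    n_snps: int = 2_000
    n_chroms: int = 3
    snp_spacing_bp: int = 25_000
    recomb_rate: float = 1e-3
    s: float = 0.05
    f0: float = 0.05
    sweep_chrom: int = 0
    sweep_index: int | None = None
    burnin_gens: int = 200
    selection_gens: int = 150
    sample_n: int = 150
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 outside [0, 1]")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0 <= self.sweep_chrom < self.n_chroms:
            raise ValueError("sweep_chrom out of range")
        if self.sweep_index is not None and not (
            0 <= self.sweep_index < self.n_snps
        ):
            raise ValueError("sweep_index out of range")
        if self.sample_n > self.n_diploids:
            raise ValueError("sample_n exceeds n_diploids")

    @property
    def focal_index(self) -> int:
        """Global (all-chromosome) index of the focal SNP."""
        local = self.sweep_index if self.sweep_index is not None else self.n_snps // 2
        return self.sweep_chrom * self.n_snps + local


@dataclass
class SimTruth:
    """Ground truth recorded for a replicate."""

    seed_used: int | None
    sweep_chrom: str | None            # None for neutral replicates
    sweep_pos: int | None
    sweep_global_index: int | None
    final_freq: float | None           # beneficial-allele frequency at sampling
    n_restarts: int = 0
    subpop: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.sweep_chrom is None:
            return pd.DataFrame(
                columns=["chrom", "pos", "global_index", "final_freq"]
            )
        return pd.DataFrame(
            [{"chrom": self.sweep_chrom, "pos": self.sweep_pos,
              "global_index": self.sweep_global_index,
              "final_freq": self.final_freq}]
        )


def _wf_generation(
    haps: np.ndarray,
    chrom_bounds: list[tuple[int, int]],
    recomb_rate: float,
    rng: np.random.Generator,
    fitness: np.ndarray | None = None,
    n_offspring: int | None = None,
) -> np.ndarray:
    """One discrete Wright-Fisher generation.

    Each offspring haplotype is a recombinant mosaic of one random
    parent's two haplotypes (parent drawn proportional to ``fitness``
    when given); chromosomes assort independently.
    """
    n_par = haps.shape[0] // 2
    n_off = n_offspring if n_offspring is not None else n_par
    n_gam = 2 * n_off
    n_loci = haps.shape[1]
    if fitness is None:
        parents = rng.integers(0, n_par, size=n_gam)
    else:
        w = fitness / fitness.sum()
        parents = rng.choice(n_par, size=n_gam, p=w)
    hapA = haps[2 * parents]
    hapB = haps[2 * parents + 1]
    # sparse crossover indicators; xor-accumulate gives the gamete phase
    ind = np.zeros((n_gam, n_loci), dtype=np.int8)
    for lo, hi in chrom_bounds:
        width = hi - lo
        counts = rng.binomial(width - 1, recomb_rate, size=n_gam)
        total = int(counts.sum())
        if total:
            pos = rng.integers(lo + 1, hi, size=total)
            rows = np.repeat(np.arange(n_gam), counts)
            np.add.at(ind, (rows, pos), 1)
        # fresh random starting haplotype per chromosome (independent assortment)
        ind[:, lo] = rng.integers(0, 2, size=n_gam, dtype=np.int8)
    ind &= 1
    phase = np.bitwise_xor.accumulate(ind, axis=1)
    return hapA ^ ((hapA ^ hapB) & phase)


def _default_map(cfg: SweepSimConfig) -> pd.DataFrame:
    rows = []
    for c in range(cfg.n_chroms):
        chrom = str(c + 1)
        for i in range(cfg.n_snps):
            pos = (i + 1) * cfg.snp_spacing_bp
            rows.append((chrom, pos, f"snp_{chrom}_{pos}", "A", "G"))
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


def _chrom_bounds(cfg: SweepSimConfig) -> list[tuple[int, int]]:
    return [
        (c * cfg.n_snps, (c + 1) * cfg.n_snps) for c in range(cfg.n_chroms)
    ]


def simulate_population(cfg: SweepSimConfig) -> tuple[HaplotypeMatrix, SimTruth]:
    """Simulate one replicate: founders -> burn-in -> (sweep) -> sample.

    If the beneficial allele is lost before sampling the replicate is
    restarted with an incremented seed, up to 10 times.
    """
    last_err = None
    for attempt in range(10):
        seed = None if cfg.seed is None else cfg.seed + attempt
        rng = np.random.default_rng(seed)
        result = _simulate_once(cfg, rng)
        if result is not None:
            mat, truth = result
            truth.seed_used = seed
            truth.n_restarts = attempt
            return mat, truth
        last_err = f"beneficial allele lost (seed {seed})"
        logger.info("restarting replicate: %s", last_err)
    raise RuntimeError(f"sweep failed after 10 restarts: {last_err}")


def _simulate_once(cfg: SweepSimConfig, rng: np.random.Generator):
    n_loci = cfg.n_chroms * cfg.n_snps
    n_hap = 2 * cfg.n_diploids
    bounds = _chrom_bounds(cfg)

    # founder frequencies: Beta(0.5, 0.5) truncated to [0.05, 0.95]
    lo, hi = sps.beta.cdf([0.05, 0.95], 0.5, 0.5)
    u = rng.uniform(lo, hi, size=n_loci)
    freqs = sps.beta.ppf(u, 0.5, 0.5)
    haps = (rng.random((n_hap, n_loci)) < freqs).astype(np.int8)

    for _ in range(cfg.burnin_gens):
        haps = _wf_generation(haps, bounds, cfg.recomb_rate, rng)

    truth = SimTruth(None, None, None, None, None)
    if cfg.s > 0:
        focal = cfg.focal_index
        n_carrier = max(1, round(cfg.f0 * n_hap))
        # hard sweep: one mutational origin, so the f0-fraction of carriers
        # must share a local haplotype background.  Seed a random haplotype
        # and assign the allele to the n_carrier haplotypes closest to it
        # around the focal site (random tie-break).
        lo = max(focal - 10, cfg.sweep_chrom * cfg.n_snps)
        hi = min(focal + 11, (cfg.sweep_chrom + 1) * cfg.n_snps)
        seed_hap = haps[rng.integers(0, n_hap), lo:hi]
        dist = (haps[:, lo:hi] != seed_hap).sum(axis=1).astype(float)
        dist += rng.random(n_hap)  # random tie-break
        carriers = np.argsort(dist)[:n_carrier]
        col = np.zeros(n_hap, dtype=np.int8)
        col[carriers] = 1
        haps[:, focal] = col
        for _ in range(cfg.selection_gens):
            dosage = haps[::2, focal].astype(np.int64) + haps[1::2, focal]
            fitness = 1.0 + cfg.s * dosage
            haps = _wf_generation(haps, bounds, cfg.recomb_rate, rng, fitness)
            if haps[:, focal].sum() == 0:
                return None
        vm = _default_map(cfg)
        truth = SimTruth(
            None,
            vm["chrom"].iat[focal],
            int(vm["pos"].iat[focal]),
            focal,
            float(haps[:, focal].mean()),
        )
    else:
        for _ in range(cfg.selection_gens):
            haps = _wf_generation(haps, bounds, cfg.recomb_rate, rng)

    pick = np.sort(rng.choice(cfg.n_diploids, size=cfg.sample_n, replace=False))
    hap_idx = np.stack([2 * pick, 2 * pick + 1], axis=1).ravel()
    sample_ids = [f"ind_{i:04d}" for i in range(cfg.sample_n)]
    mat = HaplotypeMatrix(haps[hap_idx], _default_map(cfg), sample_ids)
    return mat, truth


def split_subpopulations(
    mat: HaplotypeMatrix,
    founder_fraction: float = 0.25,
    drift_gens: int = 25,
    recomb_rate: float = 1e-3,
    seed: int | None = None,
) -> HaplotypeMatrix:
    """Create a founder / farm-born contrast.

    The first ``round(founder_fraction * n)`` samples are labelled
    ``founder`` and frozen; the remaining samples are replaced by
    descendants bred from the full sampled population for ``drift_gens``
    Wright-Fisher generations, so differentiation between the groups
    grows with ``drift_gens``.
    """
    if drift_gens < 0:
        raise ValueError("drift_gens must be >= 0")
    rng = np.random.default_rng(seed)
    n = mat.n_samples
    n_founder = round(founder_fraction * n)
    n_desc = n - n_founder
    labels = ["founder"] * n_founder + ["farm_born"] * n_desc

    # chromosome bounds from the map
    bounds = []
    for _, idx in mat.chrom_slices().items():
        bounds.append((int(idx[0]), int(idx[-1]) + 1))

    if drift_gens == 0:
        desc_rows = mat.alleles[2 * n_founder:]
    else:
        desc = mat.alleles.copy()
        for _ in range(drift_gens):
            desc = _wf_generation(
                desc, bounds, recomb_rate, rng, n_offspring=mat.n_samples
            )
        desc_rows = desc[: 2 * n_desc]
    alleles = np.vstack([mat.alleles[: 2 * n_founder], desc_rows])
    return HaplotypeMatrix(alleles, mat.variant_map.copy(), list(mat.sample_ids), labels)


def write_simulation(
    mat: HaplotypeMatrix, truth: SimTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write phased VCF + subpopulation table + truth TSV; all re-readable
    by the I/O module with exact allele equality."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_path = outdir / "simulated.vcf"
    subpop_path = outdir / "subpops.tsv"
    truth_path = outdir / "truth.tsv"
    write_phased_vcf(mat, vcf_path)
    with open(subpop_path, "w") as fh:
        fh.write("sample\tsubpop\n")
        labels = mat.subpop or ["all"] * mat.n_samples
        for sid, lab in zip(mat.sample_ids, labels):
            fh.write(f"{sid}\t{lab}\n")
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    return {"vcf": vcf_path, "subpops": subpop_path, "truth": truth_path}


def write_phased_vcf(mat: HaplotypeMatrix, path: str | Path) -> None:
    """Minimal phased VCF 4.2 writer (GT only)."""
    vm = mat.variant_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in vm.groupby("chrom", sort=False):
            fh.write(
                f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n"
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(mat.sample_ids) + "\n"
        )
        a = mat.alleles
        for j in range(mat.n_loci):
            gts = []
            for i in range(mat.n_samples):
                a0, a1 = a[2 * i, j], a[2 * i + 1, j]
                gts.append(
                    f"{'.' if a0 < 0 else a0}|{'.' if a1 < 0 else a1}"
                )
            fh.write(
                f"{vm['chrom'].iat[j]}\t{vm['pos'].iat[j]}\t{vm['id'].iat[j]}\t"
                f"{vm['ref'].iat[j]}\t{vm['alt'].iat[j]}\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


# -- synthetic annotation fixtures ------------------------------------------

def synthetic_gene_gtf(
    vmap: pd.DataFrame, path: str | Path, gene_every_bp: int = 150_000,
    gene_len_bp: int = 40_000, seed: int | None = None,
) -> int:
    """Write a synthetic gene GTF tiling the simulated map (a stand-in for
    a real genome annotation; coordinates only, no biology).  Returns the
    gene count."""
    rng = np.random.default_rng(seed)
    n = 0
    with open(path, "w") as fh:
        fh.write("#!synthetic gene annotation\n")
        for chrom, grp in vmap.groupby("chrom", sort=False):
            last = int(grp["pos"].max())
            start = int(rng.integers(1, gene_every_bp))
            while start + gene_len_bp < last:
                n += 1
                fh.write(
                    f"{chrom}\tsynthetic\tgene\t{start}\t{start + gene_len_bp - 1}"
                    f"\t.\t+\t.\tgene_id \"G{n:05d}\"; gene_name \"GENE{n:05d}\";\n"
                )
                start += gene_every_bp
    return n


def synthetic_qtl_gff(
    vmap: pd.DataFrame, path: str | Path, n_qtl_per_chrom: int = 60,
    qtl_len_bp: int = 120_000, seed: int | None = None,
    class_weights: dict[str, float] | None = None,
) -> int:
    """Write a synthetic Animal-QTLdb-style GFF3 over the simulated map
    (synthetic stand-in; traits are generic labels).  Returns the record
    count."""
    from .annotation import QTL_CLASSES

    rng = np.random.default_rng(seed)
    classes = list(QTL_CLASSES)
    if class_weights is None:
        weights = np.ones(len(classes)) / len(classes)
    else:
        weights = np.array([class_weights.get(c, 0.0) for c in classes])
        weights = weights / weights.sum()
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, grp in vmap.groupby("chrom", sort=False):
            last = int(grp["pos"].max())
            for _ in range(n_qtl_per_chrom):
                start = int(rng.integers(1, max(2, last - qtl_len_bp)))
                qclass = classes[rng.choice(len(classes), p=weights)]
                trait = f"{qclass}_trait_{int(rng.integers(1, 6))}"
                n += 1
                fh.write(
                    f"{chrom}\tsynthetic\tQTL\t{start}\t{start + qtl_len_bp - 1}"
                    f"\t.\t.\t.\tID=QTL{n:05d};Name=QTL{n:05d};"
                    f"trait={trait};qtl_class={qclass}\n"
                )
    return n
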