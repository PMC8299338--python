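"""Genotype and track I/O.

The central container is :class:`HaplotypeMatrix`: a ``(2 * n_samples,
n_loci)`` matrix of phased alleles (0/1, with ``MISSING = -1`` for a
missing allele) together with a variant map (chromosome, 1-based position,
id, ref/alt) and optional per-sample subpopulation labels.  All selection
statistics operate on this container.

Coordinates are 1-based inclusive internally (the VCF convention); BED
output is 0-based half-open.  Readers never reorder samples; loci are
sorted by (chromosome, position) with natural-numeric chromosome order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing allele; never a valid allele code
MISSING: int = -1

MAP_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class GenotypeIOError(ValueError):
    """Malformed genotype input (unphased record, ragged row, ...)."""


def chrom_sort_key(chrom: str) -> tuple:
    """Natural-numeric sort key for chromosome names ('2' < '10' < 'X')."""
    s = str(chrom)
    m = re.fullmatch(r"(?:chr)?(\d+)", s, flags=re.IGNORECASE)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, s)


def _validated_map(vmap: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in MAP_COLUMNS if c not in vmap.columns]
    if missing_cols:
        raise GenotypeIOError(f"variant map lacks columns {missing_cols}")
    vmap = vmap.reset_index(drop=True)
    vmap["chrom"] = vmap["chrom"].astype(str)
    vmap["pos"] = vmap["pos"].astype(np.int64)
    for chrom, grp in vmap.groupby("chrom", sort=False):
        d = np.diff(grp["pos"].to_numpy())
        # duplicates (d == 0) are allowed pre-QC; the QC stage removes them
        if (d < 0).any():
            raise GenotypeIOError(
                f"positions not sorted on chromosome {chrom}"
            )
    return vmap


@dataclass
class HaplotypeMatrix:
    """Phased biallelic genotypes plus variant map and sample metadata.

    Parameters
    ----------
    alleles
        ``int8`` array of shape ``(2 * n_samples, n_loci)``; entries in
        ``{0, 1, MISSING}``.  Row ``2*i`` and ``2*i + 1`` are the two
        haplotypes of sample ``i``.
    variant_map
        DataFrame with columns chrom, pos, id, ref, alt; one row per locus,
        sorted by (chrom, pos).
    sample_ids
        Sample identifiers, one per diploid individual.
    subpop
        Optional subpopulation label per sample (e.g. founder / farm-born).
    """

    alleles: np.ndarray
    variant_map: pd.DataFrame
    sample_ids: list[str]
    subpop: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise GenotypeIOError("alleles must be 2-D")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise GenotypeIOError(
                f"{self.alleles.shape[0]} haplotype rows for "
                f"{len(self.sample_ids)} samples (need 2 per sample)"
            )
        ok = np.isin(self.alleles, (0, 1, MISSING))
        if not ok.all():
            bad = np.unique(self.alleles[~ok])
            raise GenotypeIOError(f"invalid allele codes {bad.tolist()}")
        self.variant_map = _validated_map(self.variant_map)
        if len(self.variant_map) != self.alleles.shape[1]:
            raise GenotypeIOError(
                f"map has {len(self.variant_map)} entries for "
                f"{self.alleles.shape[1]} loci"
            )
        if self.subpop is not None and len(self.subpop) != len(self.sample_ids):
            raise GenotypeIOError("subpop labels must match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def genotypes(self) -> np.ndarray:
        """Diploid dosage matrix (n_samples x n_loci); MISSING if either
        allele is missing."""
        a = self.alleles.reshape(self.n_samples, 2, self.n_loci)
        g = a.sum(axis=1).astype(np.int8)
        g[(a == MISSING).any(axis=1)] = MISSING
        return g

    def take_loci(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles[:, idx],
            self.variant_map.iloc[np.asarray(idx)].reset_index(drop=True),
            list(self.sample_ids),
            list(self.subpop) if self.subpop is not None else None,
        )

    def take_samples(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return HaplotypeMatrix(
            self.alleles[hap_idx],
            self.variant_map.copy(),
            [self.sample_ids[i] for i in idx],
            [self.subpop[i] for i in idx] if self.subpop is not None else None,
        )

    def chromosomes(self) -> list[str]:
        return sorted(set(self.variant_map["chrom"]), key=chrom_sort_key)

    def chrom_slices(self) -> dict[str, np.ndarray]:
        """Locus indices per chromosome, in map order."""
        return {
            chrom: grp.index.to_numpy()
            for chrom, grp in self.variant_map.groupby("chrom", sort=False)
        }


def _sort_map_and_alleles(
    vmap: pd.DataFrame, alleles: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray]:
    order = sorted(
        range(len(vmap)),
        key=lambda i: (chrom_sort_key(vmap["chrom"].iat[i]), vmap["pos"].iat[i]),
    )
    return vmap.iloc[order].reset_index(drop=True), alleles[:, order]


def read_subpop_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample id, label), no header required unless the
    first line starts with 'sample'."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "sample":
                continue
            if len(parts) < 2:
                raise GenotypeIOError(f"bad subpop line: {line!r}")
            table[parts[0]] = parts[1]
    return table


def read_phased_vcf(
    path: str | Path, subpop_table: dict[str, str] | None = None
) -> HaplotypeMatrix:
    """Read a phased, biallelic SNP VCF into a :class:`HaplotypeMatrix`.

    Multiallelic or non-SNP records are skipped (with a logged count).  An
    unphased GT separator at any retained record raises
    :class:`GenotypeIOError` naming the record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    recs: list[tuple] = []
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a0, a1, phased = g[0], g[1], g[-1]
            if not phased and a0 >= 0 and a1 >= 0:
                raise GenotypeIOError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{var.CHROM}:{var.POS}"
                )
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        rows.append(col)
        recs.append(
            (str(var.CHROM), int(var.POS), var.ID or f"{var.CHROM}:{var.POS}",
             var.REF, alts[0])
        )
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records", n_skipped)
    if not recs:
        raise GenotypeIOError(f"no usable SNP records in {path}")
    vmap = pd.DataFrame(recs, columns=MAP_COLUMNS)
    alleles = np.stack(rows, axis=1)
    vmap, alleles = _sort_map_and_alleles(vmap, alleles)

    subpop = None
    if subpop_table is not None:
        missing = [s for s in samples if s not in subpop_table]
        if missing:
            raise GenotypeIOError(
                f"samples absent from subpopulation table: {missing}"
            )
        subpop = [subpop_table[s] for s in samples]
    mat = HaplotypeMatrix(alleles, vmap, samples, subpop)
    mat.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return mat


# -- haplotype TSV fixture format -------------------------------------------
# header: hap_id, subpop (optional), then one column per locus id;
# one row per haplotype.  Side-car map file: MAP_COLUMNS as TSV.


def _map_path(path: str | Path) -> Path:
    return Path(str(path) + ".map")


def write_haplotype_tsv(mat: HaplotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        cols = ["hap_id"]
        if mat.subpop is not None:
            cols.append("subpop")
        fh.write("\t".join(cols + list(mat.variant_map["id"])) + "\n")
        for h in range(mat.n_haplotypes):
            s = h // 2
            fields = [f"{mat.sample_ids[s]}|{h % 2}"]
            if mat.subpop is not None:
                fields.append(mat.subpop[s])
            fields.extend(str(int(a)) for a in mat.alleles[h])
            fh.write("\t".join(fields) + "\n")
    mat.variant_map.to_csv(_map_path(path), sep="\t", index=False)


def read_haplotype_tsv(path: str | Path) -> HaplotypeMatrix:
    path = Path(path)
    vmap = pd.read_csv(_map_path(path), sep="\t", dtype={"chrom": str})
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_subpop = len(header) > 1 and header[1] == "subpop"
        n_meta = 2 if has_subpop else 1
        n_loci = len(header) - n_meta
        sample_ids: list[str] = []
        subpop: list[str] = []
        rows: list[list[int]] = []
        for ridx, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise GenotypeIOError(
                    f"row {ridx}: {len(parts)} fields, header has {len(header)}"
                )
            hap_id = parts[0]
            sid, phase = hap_id.rsplit("|", 1)
            if phase == "0":
                sample_ids.append(sid)
                if has_subpop:
                    subpop.append(parts[1])
            rows.append([int(x) for x in parts[n_meta:]])
    alleles = np.asarray(rows, dtype=np.int8)
    if alleles.shape[1] != n_loci:
        raise GenotypeIOError("allele columns do not match header")
    return HaplotypeMatrix(
        alleles, vmap, sample_ids, subpop if has_subpop else None
    )


# -- pipeline outputs --------------------------------------------------------

STAT_NAMES = ["fst", "h1", "h12", "tajima_d", "pi"]


def write_scan_tsv(scan: pd.DataFrame, path: str | Path) -> None:
    """Write the per-SNP scan table.

    Expected columns: chrom, pos, the five raw statistics, the five
    smoothed statistics (``*_smooth``), the five rank p-values (``p_*``),
    dcms, p, q.
    """
    required = (
        ["chrom", "pos"]
        + STAT_NAMES
        + [f"{s}_smooth" for s in STAT_NAMES]
        + [f"p_{s}" for s in STAT_NAMES]
        + ["dcms", "p", "q"]
    )
    missing = [c for c in required if c not in scan.columns]
    if missing:
        raise GenotypeIOError(f"scan table lacks columns {missing}")
    try:
        order = sorted(
            range(len(scan)),
            key=lambda i: (chrom_sort_key(scan["chrom"].iat[i]), scan["pos"].iat[i]),
        )
    except TypeError as exc:  # pragma: no cover - defensive
        raise GenotypeIOError(f"unsortable chromosomes: {exc}") from exc
    scan.iloc[order][required].to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_regions_bed(regions, path: str | Path) -> None:
    """Write called regions as BED (0-based half-open); name = region id,
    score column carries the peak q-value."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tpeak_q\tn_snps\n")
        for i, r in enumerate(
            sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start_pos))
        ):
            fh.write(
                f"{r.chrom}\t{r.start_pos - 1}\t{r.end_pos}\t"
                f"region_{i + 1}\t{r.peak_q:.6g}\t{r.n_snps}\n"
            )
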