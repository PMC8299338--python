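"""Gene/QTL annotation of called regions and bootstrap QTL enrichment.

Genes come from a GTF (gene rows), QTLs from an Animal-QTLdb-style GFF3
whose attributes carry a trait name and a QTL class.  Regions are
intersected with both (1-based inclusive coordinates, >= 1 bp overlap).
Enrichment per (trait, chromosome) compares the observed annotated count
with a bootstrap null that resamples records from the database restricted
to the same chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import chrom_sort_key
from .regions import GenomicRegion

logger = logging.getLogger(__name__)

QTL_CLASSES = (
    "Milk", "Production", "Exterior", "Reproduction", "Health",
    "Meat_and_Carcass",
)


@dataclass(frozen=True)
class FeatureRecord:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    kind: str   # "gene" or "QTL"
    name: str
    trait: str | None = None
    qtl_class: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.name}: start > end")
        if (self.kind == "QTL") != (self.qtl_class is not None):
            raise ValueError("qtl_class present iff kind == 'QTL'")


def _feature_from_line(line: str):
    from gffutils.feature import feature_from_line

    if len(line.split("\t")) != 9:
        raise ValueError("expected 9 tab-separated GFF/GTF fields")
    return feature_from_line(line)


def parse_gtf(path) -> tuple[list[FeatureRecord], int]:
    """Gene records from a GTF; malformed rows are skipped and counted."""
    records: list[FeatureRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = _feature_from_line(line)
                if f.featuretype != "gene":
                    continue
                name = (
                    f.attributes.get("gene_name", [None])[0]
                    or f.attributes.get("gene_id", ["?"])[0]
                )
                records.append(
                    FeatureRecord(str(f.seqid), int(f.start), int(f.end),
                                  "gene", name)
                )
            except Exception:
                n_skipped += 1
    if n_skipped:
        logger.info("skipped %d malformed GTF rows", n_skipped)
    return records, n_skipped


def parse_qtl_gff(path) -> tuple[list[FeatureRecord], int]:
    """QTL records from a GFF3 with ``trait`` and ``qtl_class``
    attributes; rows lacking a trait (or otherwise malformed) are skipped
    and counted.  Classes outside the canonical six map to 'Other'."""
    records: list[FeatureRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = _feature_from_line(line)
                trait = f.attributes.get("trait", [None])[0]
                if trait is None:
                    n_skipped += 1
                    continue
                qclass = f.attributes.get("qtl_class", ["Other"])[0]
                if qclass not in QTL_CLASSES:
                    logger.warning("unknown QTL class %r mapped to 'Other'", qclass)
                    qclass = "Other"
                name = f.attributes.get("Name", [trait])[0]
                records.append(
                    FeatureRecord(str(f.seqid), int(f.start), int(f.end),
                                  "QTL", name, trait=trait, qtl_class=qclass)
                )
            except Exception:
                n_skipped += 1
    if n_skipped:
        logger.info("skipped %d malformed/trait-less GFF rows", n_skipped)
    return records, n_skipped


def overlap_features(
    regions: list[GenomicRegion], features: list[FeatureRecord]
) -> dict[int, list[FeatureRecord]]:
    """Features overlapping each region by >= 1 bp on the same chromosome.

    Returns {region index -> features sorted by (chrom, start, name)}.
    Warns when region chromosomes are absent from the feature set.
    """
    trees: dict[str, IntervalTree] = {}
    for f in features:
        # IntervalTree is half-open; +1 converts the inclusive end
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end + 1, f)
    unmatched = sorted(
        {r.chrom for r in regions} - set(trees), key=chrom_sort_key
    )
    if unmatched and features:
        logger.warning("region chromosomes missing from annotation: %s", unmatched)
    out: dict[int, list[FeatureRecord]] = {}
    for i, r in enumerate(regions):
        tree = trees.get(r.chrom)
        hits = [iv.data for iv in tree.overlap(r.start_pos, r.end_pos + 1)] if tree else []
        hits.sort(key=lambda f: (chrom_sort_key(f.chrom), f.start, f.name))
        out[i] = hits
    return out


def qtl_class_proportions(annotated: list[FeatureRecord]) -> pd.DataFrame:
    """Percentage of annotated QTLs per class (sums to 100)."""
    qtls = [f for f in annotated if f.kind == "QTL"]
    if not qtls:
        return pd.DataFrame(columns=["qtl_class", "n", "percent"])
    counts = pd.Series([f.qtl_class for f in qtls]).value_counts()
    df = counts.rename_axis("qtl_class").reset_index(name="n")
    df["percent"] = 100.0 * df["n"] / df["n"].sum()
    return df


def qtl_enrichment_bootstrap(
    annotated: list[FeatureRecord],
    qtl_db: list[FeatureRecord],
    n_iter: int = 1000,
    seed: int | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Chromosome-based bootstrap QTL enrichment.

    For each chromosome carrying annotated QTLs, each bootstrap iteration
    resamples (with replacement) as many records from the database
    restricted to that chromosome as were annotated there, and counts each
    trait.  p_emp = (1 + #{null count >= observed}) / (n_iter + 1);
    Benjamini-Hochberg FDR across all (trait, chromosome) pairs.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    from .dcms import bh_qvalues

    rng = np.random.default_rng(seed)
    ann = [f for f in annotated if f.kind == "QTL"]
    db = [f for f in qtl_db if f.kind == "QTL"]
    rows = []
    chroms = sorted({f.chrom for f in ann}, key=chrom_sort_key)
    for chrom in chroms:
        ann_c = [f for f in ann if f.chrom == chrom]
        db_c = [f for f in db if f.chrom == chrom]
        m = len(ann_c)
        traits = sorted(
            {f.trait for f in ann_c} | {f.trait for f in db_c}
        )
        db_traits = np.array([f.trait for f in db_c], dtype=object)
        if len(db_c) > 0:
            draws = rng.integers(0, len(db_c), size=(n_iter, m))
            drawn_traits = db_traits[draws]
        else:
            drawn_traits = np.empty((n_iter, 0), dtype=object)
        for trait in traits:
            observed = sum(f.trait == trait for f in ann_c)
            null_counts = (drawn_traits == trait).sum(axis=1)
            expected = float(null_counts.mean()) if null_counts.size else 0.0
            p_emp = (1.0 + int((null_counts >= observed).sum())) / (n_iter + 1.0)
            rows.append(
                dict(trait=trait, chrom=chrom, observed=observed,
                     n_db_chrom=len(db_c), expected_mean=expected, p_emp=p_emp)
            )
    result = pd.DataFrame(
        rows, columns=["trait", "chrom", "observed", "n_db_chrom",
                       "expected_mean", "p_emp"]
    )
    if len(result):
        result["p_fdr"] = bh_qvalues(result["p_emp"].to_numpy())
        result["significant"] = result["p_fdr"] <= fdr_alpha
    else:
        result["p_fdr"] = []
        result["significant"] = []
    return result
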