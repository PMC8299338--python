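"""Significant-region calling from the per-SNP q-value track.

A region is a maximal run of consecutive SNPs whose q-values stay at or
below the boundary threshold, provided the run contains at least
``core_min`` consecutive SNPs below the significance threshold.  Runs are
never merged across chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import chrom_sort_key


@dataclass
class RegionConfig:
    """sig_q: core significance threshold (default 0.05); boundary_q:
    region-extension threshold (default 0.1); core_min: consecutive
    significant SNPs required (default 2, configurable down to 1)."""

    sig_q: float = 0.05
    boundary_q: float = 0.1
    core_min: int = 2

    def __post_init__(self) -> None:
        if self.sig_q > self.boundary_q:
            raise ValueError("sig_q must not exceed boundary_q")
        if self.core_min < 1:
            raise ValueError("core_min must be >= 1")


@dataclass
class GenomicRegion:
    chrom: str
    start_pos: int   # 1-based inclusive, first member SNP
    end_pos: int     # 1-based inclusive, last member SNP
    n_snps: int
    peak_q: float
    peak_pos: int
    snp_indices: np.ndarray | None = None  # indices into the scan table

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


def _has_core(sig: np.ndarray, core_min: int) -> bool:
    run = 0
    for s in sig:
        run = run + 1 if s else 0
        if run >= core_min:
            return True
    return False


def call_regions(
    scan: pd.DataFrame, cfg: RegionConfig | None = None
) -> list[GenomicRegion]:
    """Call regions from a table with columns chrom, pos, q (rows sorted
    by position within chromosome)."""
    cfg = cfg or RegionConfig()
    regions: list[GenomicRegion] = []
    for chrom, grp in scan.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        q = grp["q"].to_numpy()
        idx = grp.index.to_numpy()
        below = q <= cfg.boundary_q
        # maximal runs of `below`
        start = None
        for i in range(len(q) + 1):
            inside = i < len(q) and below[i]
            if inside and start is None:
                start = i
            elif not inside and start is not None:
                sl = slice(start, i)
                if _has_core(q[sl] < cfg.sig_q, cfg.core_min):
                    peak = start + int(np.argmin(q[sl]))
                    regions.append(
                        GenomicRegion(
                            chrom=str(chrom),
                            start_pos=int(pos[start]),
                            end_pos=int(pos[i - 1]),
                            n_snps=i - start,
                            peak_q=float(q[peak]),
                            peak_pos=int(pos[peak]),
                            snp_indices=idx[sl],
                        )
                    )
                start = None
    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start_pos))
    return regions


def summarize_regions(regions: list[GenomicRegion]) -> dict:
    """Region-summary row: count, mean +/- SD length (kb), min (kb),
    max (Mb), total SNPs, total size (Mb).  Sample SD; a single region
    reports SD 0."""
    if not regions:
        return {
            "n_regions": 0, "mean_kb": 0.0, "sd_kb": 0.0, "min_kb": 0.0,
            "max_mb": 0.0, "n_snps": 0, "total_mb": 0.0,
        }
    lengths_kb = np.array([r.length_bp / 1_000.0 for r in regions])
    sd = float(np.std(lengths_kb, ddof=1)) if len(lengths_kb) > 1 else 0.0
    return {
        "n_regions": len(regions),
        "mean_kb": float(lengths_kb.mean()),
        "sd_kb": sd,
        "min_kb": float(lengths_kb.min()),
        "max_mb": float(lengths_kb.max() / 1_000.0),
        "n_snps": int(sum(r.n_snps for r in regions)),
        "total_mb": float(lengths_kb.sum() / 1_000.0),
    }


def summary_table(regions: list[GenomicRegion], n_genes: int | None = None) -> pd.DataFrame:
    s = summarize_regions(regions)
    row = {
        "N regions": s["n_regions"],
        "Average (KB)": round(s["mean_kb"], 2),
        "SD (KB)": round(s["sd_kb"], 2),
        "Min (KB)": round(s["min_kb"], 2),
        "Max (MB)": round(s["max_mb"], 2),
        "N SNP": s["n_snps"],
        "Total size (Mb)": round(s["total_mb"], 2),
    }
    if n_genes is not None:
        row["N genes"] = n_genes
    return pd.DataFrame([row])
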