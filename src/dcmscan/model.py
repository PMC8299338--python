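"""Model/Results interface to the composite selection scan.

:class:`SelectionScan` is constructed from a :class:`~dcmscan.io.HaplotypeMatrix`
plus the stage configurations; :meth:`SelectionScan.fit` runs
QC -> per-chromosome statistics -> smoothing -> fractional-rank p-values
-> robust MCD correlation -> DCMS -> robust normal fit -> upper-tail p ->
BH q, and returns a :class:`ScanResults` carrying the per-SNP tracks, the
de-correlation weights, the normal-fit parameters and diagnostics.
Region calling, annotation, summaries and plotting hang off the results
object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann
from .dcms import DCMSConfig, dcms_track
from .io import STAT_NAMES, HaplotypeMatrix, write_regions_bed, write_scan_tsv
from .qc import QCConfig, QCReport, exclude_related, filter_variants
from .regions import GenomicRegion, RegionConfig, call_regions, summary_table
from .stats import STAT_TAILS, WindowConfig, compute_stat_panel

logger = logging.getLogger(__name__)


class SelectionScan:
    """Composite selection-signature scan of a phased genotype matrix.

    Parameters
    ----------
    data
        Phased genotypes with variant map; subpopulation labels are
        required for the FST component (``data.subpop``).
    qc, windows, dcms, regions
        Stage configurations; defaults follow standard SNP-array practice
        (call rate 0.95, MAF 0.05, HWE 1e-3, PI_HAT 0.1, 14-SNP haplotype
        windows, 31-SNP running median, MCD alpha 0.75, region thresholds
        q < 0.05 core / q <= 0.1 boundary).
    """

    def __init__(
        self,
        data: HaplotypeMatrix,
        qc: QCConfig | None = None,
        windows: WindowConfig | None = None,
        dcms: DCMSConfig | None = None,
        regions: RegionConfig | None = None,
        run_qc: bool = True,
    ) -> None:
        self.data = data
        self.qc = qc or QCConfig()
        self.windows = windows or WindowConfig()
        self.dcms = dcms or DCMSConfig()
        self.regions_config = regions or RegionConfig()
        self.run_qc = run_qc

    @classmethod
    def from_vcf(cls, path, subpop_table=None, **kwargs) -> "SelectionScan":
        from .io import read_phased_vcf, read_subpop_table

        table = read_subpop_table(subpop_table) if subpop_table else None
        return cls(read_phased_vcf(path, table), **kwargs)

    def fit(self, seed: int | None = None) -> "ScanResults":
        """Run the full scan; ``seed`` drives the MCD subset sampling."""
        mat = self.data
        qc_report = None
        removed_ids: list[str] = []
        if self.run_qc:
            mat, qc_report = filter_variants(mat, self.qc)
            if self.qc.prune_related and mat.n_samples >= 2:
                mat, removed_ids = exclude_related(mat, self.qc.pihat_max)
                qc_report.removed_samples_related = len(removed_ids)
                qc_report.related_sample_ids = removed_ids
                qc_report.n_samples_out = mat.n_samples
                qc_report.check()
        panel = compute_stat_panel(mat, self.windows, labels=mat.subpop)
        smooth = panel[[f"{s}_smooth" for s in STAT_NAMES]].to_numpy()
        tails = [STAT_TAILS[s] for s in STAT_NAMES]
        track = dcms_track(smooth, tails, self.dcms, seed=seed)

        scan = mat.variant_map[["chrom", "pos", "id"]].copy()
        for s in STAT_NAMES:
            scan[s] = panel[s].to_numpy()
            scan[f"{s}_smooth"] = panel[f"{s}_smooth"].to_numpy()
        for t, s in enumerate(STAT_NAMES):
            scan[f"p_{s}"] = track["stat_pvalues"][:, t]
        scan["dcms"] = track["dcms"]
        scan["p"] = track["p"]
        scan["q"] = track["q"]
        return ScanResults(
            model=self,
            matrix=mat,
            scan=scan,
            qc_report=qc_report,
            removed_related=removed_ids,
            correlation=track["correlation"],
            correlation_meta=track["correlation_meta"],
            weights=track["weights"],
            mu=track["mu"],
            sigma=track["sigma"],
            seed=seed,
        )


@dataclass
class ScanResults:
    """Fitted scan: per-SNP tracks plus estimates and diagnostics."""

    model: SelectionScan
    matrix: HaplotypeMatrix
    scan: pd.DataFrame
    qc_report: QCReport | None
    removed_related: list[str]
    correlation: np.ndarray
    correlation_meta: dict
    weights: np.ndarray
    mu: float
    sigma: float
    seed: int | None = None
    _regions: list[GenomicRegion] | None = field(default=None, repr=False)

    def regions(self, config: RegionConfig | None = None) -> list[GenomicRegion]:
        cfg = config or self.model.regions_config
        if config is None and self._regions is not None:
            return self._regions
        regs = call_regions(self.scan, cfg)
        if config is None:
            self._regions = regs
        return regs

    def region_summary(self, n_genes: int | None = None) -> pd.DataFrame:
        return summary_table(self.regions(), n_genes=n_genes)

    def annotate(
        self, gene_records, qtl_records, n_iter: int = 1000,
        seed: int | None = None,
    ) -> dict:
        """Intersect called regions with gene/QTL records and run the
        bootstrap enrichment.  Returns per-region feature lists, the QTL
        class proportions and the enrichment table."""
        regs = self.regions()
        genes = ann.overlap_features(regs, gene_records)
        qtls = ann.overlap_features(regs, qtl_records)
        annotated = sorted(
            {f for hits in qtls.values() for f in hits},
            key=lambda f: (f.chrom, f.start, f.name),
        )
        gene_hits = sorted(
            {f for hits in genes.values() for f in hits},
            key=lambda f: (f.chrom, f.start, f.name),
        )
        return {
            "genes_by_region": genes,
            "qtls_by_region": qtls,
            "n_genes": len(gene_hits),
            "class_proportions": ann.qtl_class_proportions(annotated),
            "enrichment": ann.qtl_enrichment_bootstrap(
                annotated, qtl_records, n_iter=n_iter, seed=seed
            ),
        }

    def summary(self) -> str:
        """Human-readable summary of the fitted scan."""
        lines = ["Composite selection scan (DCMS)", "=" * 34]
        if self.qc_report is not None:
            r = self.qc_report
            lines += [
                f"QC: {r.n_variants_in} -> {r.n_variants_out} SNPs "
                f"(call-rate {r.removed_call_rate}, MAF {r.removed_maf}, "
                f"HWE {r.removed_hwe}, duplicate {r.removed_duplicate})",
                f"    {r.n_samples_in} -> {r.n_samples_out} samples "
                f"({r.removed_samples_related} related removed)",
            ]
        lines += [
            f"Loci scanned: {len(self.scan)}"
            f" on {self.scan['chrom'].nunique()} chromosomes",
            f"Normal fit: mu = {self.mu:.4f}, sigma = {self.sigma:.4f}",
            "De-correlation weights: "
            + ", ".join(
                f"{s}={w:.3f}" for s, w in zip(STAT_NAMES, self.weights)
            ),
            f"SNPs with q < 0.05: {(self.scan['q'] < 0.05).sum()}",
        ]
        regs = self.regions()
        lines.append(f"Regions called: {len(regs)}")
        if regs:
            lines.append(self.region_summary().to_string(index=False))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        write_scan_tsv(self.scan, path)

    def regions_to_bed(self, path) -> None:
        write_regions_bed(self.regions(), path)

    def plot_track(self, path=None, ax=None):
        """Per-chromosome -log10(q) track with the 0.05 threshold line."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            fig, ax = plt.subplots(figsize=(10, 3))
        else:
            fig = ax.figure
        offset = 0
        ticks, labels = [], []
        for i, (chrom, grp) in enumerate(self.scan.groupby("chrom", sort=False)):
            x = offset + np.arange(len(grp))
            ax.scatter(
                x, -np.log10(grp["q"]), s=2,
                color="steelblue" if i % 2 == 0 else "darkorange",
            )
            ticks.append(offset + len(grp) / 2)
            labels.append(str(chrom))
            offset += len(grp)
        ax.axhline(-np.log10(0.05), color="red", lw=0.8, ls="--")
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10} q$")
        ax.set_title("DCMS scan")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return ax
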