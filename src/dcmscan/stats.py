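"""Per-SNP selection statistics.

Five statistics feed the composite scan:

* Weir-Cockerham (1984) theta per SNP between two subpopulations
  (right tail: differentiation elevates it),
* Garud's H1 and H12 haplotype homozygosity in sliding SNP windows
  (right tail: sweeps extend haplotypes),
* Tajima's D in non-overlapping physical bins (left tail: sweeps push it
  negative),
* per-site nucleotide diversity pi (left tail: sweeps deplete it),

plus a running-median smoother (R ``runmed`` with the constant end rule)
applied per chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, STAT_NAMES, HaplotypeMatrix

logger = logging.getLogger(__name__)

#: tail direction used when converting each statistic to rank p-values
STAT_TAILS = {
    "fst": "right",
    "h1": "right",
    "h12": "right",
    "tajima_d": "left",
    "pi": "left",
}


@dataclass
class WindowConfig:
    """Windowing/smoothing parameters.

    h_window      : SNPs per haplotype-homozygosity window (default 14).
    h_step        : window step in SNPs (default 1).
    tajima_bin_bp : physical bin for Tajima's D (default 300 kb).
    smooth_k      : running-median width in SNPs, odd (default 31).
    smooth_stats  : statistics the smoother is applied to; the rest pass
                    through (missing still imputed to 0).  Default: FST,
                    Tajima's D and pi; H1/H12 are already window
                    statistics and keep their native resolution.
    """

    h_window: int = 14
    h_step: int = 1
    tajima_bin_bp: int = 300_000
    smooth_k: int = 31
    smooth_stats: tuple[str, ...] = ("fst", "tajima_d", "pi")

    def __post_init__(self) -> None:
        if self.h_window < 2:
            raise ValueError("h_window must be >= 2")
        if self.smooth_k < 3 or self.smooth_k % 2 == 0:
            raise ValueError("smooth_k must be odd and >= 3")


def weir_cockerham_fst(mat: HaplotypeMatrix, labels=None) -> np.ndarray:
    """Per-SNP Weir-Cockerham theta between exactly two subpopulations.

    Computed from diploid genotype counts with the heterozygosity
    correction; negative estimates are clamped to 0; SNPs monomorphic
    across both subpopulations (or with fewer than two genotyped samples
    in either) are NaN.
    """
    labels = labels if labels is not None else mat.subpop
    if labels is None:
        raise ValueError("subpopulation labels required for FST")
    labels = np.asarray(labels)
    pops = sorted(set(labels.tolist()))
    if len(pops) != 2:
        raise ValueError(f"need exactly two subpopulations, got {pops}")
    g = mat.genotypes()
    valid = g != MISSING
    r = 2.0
    n_i, p_i, h_i = [], [], []
    for pop in pops:
        rows = labels == pop
        gp = g[rows]
        vp = valid[rows]
        n = vp.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(vp, gp, 0).sum(axis=0) / (2.0 * n)
            h = ((gp == 1) & vp).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.stack(n_i)
    p_i = np.stack(p_i)
    h_i = np.stack(h_i)

    ok = (n_i >= 2).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where((denom != 0) & ok, a / denom, np.nan)
    theta = np.where(np.isnan(theta), np.nan, np.clip(theta, 0.0, 1.0))
    return theta


def _window_h_stats(codes: np.ndarray) -> tuple[float, float]:
    """H1 and H12 from one window's haplotype codes (missing excluded)."""
    _, counts = np.unique(codes, return_counts=True)
    freqs = np.sort(counts / counts.sum())[::-1]
    h1 = float((freqs**2).sum())
    if len(freqs) >= 2:
        h12 = float((freqs[0] + freqs[1]) ** 2 + (freqs[2:] ** 2).sum())
    else:
        h12 = h1
    return h1, h12


def haplotype_homozygosity(
    mat: HaplotypeMatrix, h_window: int = 14, h_step: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Garud H1/H12 in sliding windows of ``h_window`` SNPs (per
    chromosome), assigned to the SNP at 0-based window offset
    ``h_window // 2``.  SNPs with no assigned window are NaN."""
    h1 = np.full(mat.n_loci, np.nan)
    h12 = np.full(mat.n_loci, np.nan)
    for chrom, idx in mat.chrom_slices().items():
        L = len(idx)
        if L < h_window:
            logger.warning(
                "chromosome %s has %d SNPs (< window %d): H1/H12 missing",
                chrom, L, h_window,
            )
            continue
        sub = mat.alleles[:, idx]
        any_missing = (sub == MISSING).any()
        # encode windows as integers when they fit into 63 bits
        if h_window <= 62 and not any_missing:
            from numpy.lib.stride_tricks import sliding_window_view

            windows = sliding_window_view(sub, h_window, axis=1)
            pow2 = (1 << np.arange(h_window)).astype(np.int64)
            codes = windows.astype(np.int64) @ pow2  # (n_hap, n_windows)
            for w in range(0, L - h_window + 1, h_step):
                center = idx[w + h_window // 2]
                h1[center], h12[center] = _window_h_stats(codes[:, w])
        else:
            for w in range(0, L - h_window + 1, h_step):
                block = sub[:, w : w + h_window]
                rows = block[~(block == MISSING).any(axis=1)]
                center = idx[w + h_window // 2]
                if len(rows) == 0:
                    continue
                strings = [r.tobytes() for r in rows]
                _, counts = np.unique(strings, return_counts=True)
                freqs = np.sort(counts / counts.sum())[::-1]
                h1[center] = float((freqs**2).sum())
                h12[center] = float(
                    (freqs[0] + (freqs[1] if len(freqs) > 1 else 0.0)) ** 2
                    + (freqs[2:] ** 2).sum()
                )
    return h1, h12


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sequences."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def site_pi(mat: HaplotypeMatrix) -> np.ndarray:
    """Per-site nucleotide diversity 2 j (n - j) / (n (n - 1)) with j the
    alt-allele count among the n non-missing alleles; NaN if n < 2."""
    a = mat.alleles
    valid = a != MISSING
    n = valid.sum(axis=0).astype(float)
    j = np.where(valid, a, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def tajimas_d(mat: HaplotypeMatrix, tajima_bin_bp: int = 300_000) -> np.ndarray:
    """Binned Tajima's D, one value per SNP (every SNP in a bin gets the
    bin's value).  Bins with no segregating sites are 0."""
    n = mat.n_haplotypes
    if n < 4:
        raise ValueError("Tajima's D requires >= 4 haplotypes")
    const = tajima_constants(n)
    pi_site = site_pi(mat)
    d = np.zeros(mat.n_loci)
    vm = mat.variant_map
    a = mat.alleles
    valid = a != MISSING
    alt = np.where(valid, a, 0).sum(axis=0)
    nn = valid.sum(axis=0)
    seg = (alt > 0) & (alt < nn)
    bins = (vm["pos"].to_numpy() - 1) // tajima_bin_bp
    for chrom, idx in mat.chrom_slices().items():
        for b in np.unique(bins[idx]):
            sites = idx[bins[idx] == b]
            S = int(seg[sites].sum())
            if S == 0:
                continue
            pi_hat = np.nansum(pi_site[sites])
            var = const["e1"] * S + const["e2"] * S * (S - 1.0)
            d[sites] = (pi_hat - S / const["a1"]) / np.sqrt(var)
    return d


def running_median(values: np.ndarray, smooth_k: int = 31) -> np.ndarray:
    """Centered running median with the constant end rule (as in R's
    ``runmed(..., endrule="constant")``); NaN imputed to 0 beforehand."""
    x = np.asarray(values, dtype=float).copy()
    x[np.isnan(x)] = 0.0
    L = len(x)
    if L == 0:
        return x
    k = min(smooth_k, L if L % 2 == 1 else L - 1)
    if k < 3:
        return x
    from numpy.lib.stride_tricks import sliding_window_view

    med = np.median(sliding_window_view(x, k), axis=1)
    h = k // 2
    out = np.empty(L)
    out[h : L - h] = med
    out[:h] = med[0]
    out[L - h :] = med[-1]
    return out


def smooth_by_chromosome(
    mat: HaplotypeMatrix, values: np.ndarray, smooth_k: int = 31
) -> np.ndarray:
    out = np.empty(mat.n_loci)
    for _, idx in mat.chrom_slices().items():
        out[idx] = running_median(values[idx], smooth_k)
    return out


def compute_stat_panel(
    mat: HaplotypeMatrix,
    windows: WindowConfig | None = None,
    labels=None,
) -> pd.DataFrame:
    """All five raw statistics plus their smoothed layers.

    Returns a DataFrame indexed like the variant map with columns
    ``fst, h1, h12, tajima_d, pi`` and ``*_smooth`` counterparts.
    """
    windows = windows or WindowConfig()
    panel = pd.DataFrame(index=mat.variant_map.index)
    panel["fst"] = weir_cockerham_fst(mat, labels)
    h1, h12 = haplotype_homozygosity(mat, windows.h_window, windows.h_step)
    panel["h1"] = h1
    panel["h12"] = h12
    panel["tajima_d"] = tajimas_d(mat, windows.tajima_bin_bp)
    panel["pi"] = site_pi(mat)
    for stat in STAT_NAMES:
        raw = panel[stat].to_numpy()
        if stat in windows.smooth_stats:
            panel[f"{stat}_smooth"] = smooth_by_chromosome(mat, raw, windows.smooth_k)
        else:
            panel[f"{stat}_smooth"] = np.nan_to_num(raw, nan=0.0)
    return panel
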