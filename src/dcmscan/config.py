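"""Pipeline configuration: one structured YAML file covering every stage.

Unknown keys are rejected before any stage runs.  A single global seed
deterministically derives the per-stage seeds (``stage_seed``), so a
stage rerun in isolation reproduces its full-run output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dcms import DCMSConfig
from .qc import QCConfig
from .regions import RegionConfig
from .simulate import SweepSimConfig
from .stats import WindowConfig

logger = logging.getLogger(__name__)

#: fixed stage order used to derive per-stage seeds from the global seed
STAGE_NAMES = ("simulate", "split", "mcd", "enrich", "annotation_fixtures")


def stage_seed(seed: int | None, stage: str) -> int | None:
    """Derive a stage seed from the global seed via SeedSequence.spawn;
    stage index is the position in :data:`STAGE_NAMES`."""
    if seed is None:
        return None
    children = np.random.SeedSequence(seed).spawn(len(STAGE_NAMES))
    idx = STAGE_NAMES.index(stage)
    return int(children[idx].generate_state(1)[0] % (2**31))


@dataclass
class EnrichmentConfig:
    n_iter: int = 1000
    fdr_alpha: float = 0.05


@dataclass
class PipelineConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    dcms: DCMSConfig = field(default_factory=DCMSConfig)
    regions: RegionConfig = field(default_factory=RegionConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    simulation: SweepSimConfig = field(default_factory=SweepSimConfig)
    founder_fraction: float = 0.25
    drift_gens: int = 25
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {
            "qc": QCConfig, "windows": WindowConfig, "dcms": DCMSConfig,
            "regions": RegionConfig, "enrichment": EnrichmentConfig,
            "simulation": SweepSimConfig,
        }
        scalars = {"founder_fraction", "drift_gens", "seed", "log_level"}
        unknown = set(raw) - set(sections) - scalars
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, klass in sections.items():
            sub = raw.get(name, {})
            if not isinstance(sub, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(klass)}
            bad = set(sub) - valid
            if bad:
                raise ValueError(f"unknown keys in {name!r}: {sorted(bad)}")
            if name == "windows" and "smooth_stats" in sub:
                sub = dict(sub, smooth_stats=tuple(sub["smooth_stats"]))
            kwargs[name] = klass(**sub)
        for name in scalars:
            if name in raw:
                kwargs[name] = raw[name]
        return cls(**kwargs)

    def log_parameters(self) -> None:
        """Log every stage default at startup (reproducibility record)."""
        logger.info(
            "QC: call_rate>=%.2f maf>=%.2f hwe_p>=%g pihat<=%.2f",
            self.qc.min_call_rate, self.qc.min_maf, self.qc.hwe_p_floor,
            self.qc.pihat_max,
        )
        logger.info(
            "windows: h_window=%d h_step=%d tajima_bin=%d smooth_k=%d",
            self.windows.h_window, self.windows.h_step,
            self.windows.tajima_bin_bp, self.windows.smooth_k,
        )
        logger.info(
            "dcms: mcd_alpha=%.2f mcd_nsamp=%d huber_c=%.3f",
            self.dcms.mcd_alpha, self.dcms.mcd_nsamp, self.dcms.huber_c,
        )
        logger.info(
            "regions: sig_q=%.3g boundary_q=%.3g core_min=%d",
            self.regions.sig_q, self.regions.boundary_q, self.regions.core_min,
        )
        logger.info(
            "enrichment: n_iter=%d fdr_alpha=%.2f seed=%s",
            self.enrichment.n_iter, self.enrichment.fdr_alpha, self.seed,
        )
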