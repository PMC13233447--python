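"""Screening thresholds, YAML configuration, and pipeline logging.

Every filter in the pipeline compares with a *strict* inequality against
these thresholds; the defaults are the conventional suggestive-association
and effect-size cutoffs for this kind of triage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

log = logging.getLogger("splicescreen")


@dataclass(frozen=True)
class ScreenThresholds:
    """Cutoffs applied across the triage pipeline.

    Attributes
    ----------
    gwas_p : float
        Suggestive GWAS association cutoff (variant kept iff p < gwas_p).
    de_abs_log2fc : float
        Differential-expression effect cutoff (|log2FC| > de_abs_log2fc).
    de_p : float
        Differential-expression p cutoff (p < de_p).
    dpsi_min : float
        Differential-splicing effect cutoff on the fraction scale
        (|dPSI| > dpsi_min; 0.1 means 10 percentage points).
    fdr_max : float
        BH-adjusted q cutoff for splicing calls (q < fdr_max).
    flank_len : int
        Intronic flank length in bases for motif-scan windows.
    survival_p : float
        Wald p cutoff for calling a hazard estimate significant.
    """

    gwas_p: float = 0.05
    de_abs_log2fc: float = 1.0
    de_p: float = 0.05
    dpsi_min: float = 0.1
    fdr_max: float = 0.05
    flank_len: int = 200
    survival_p: float = 0.05

    def __post_init__(self):
        for name in ("gwas_p", "de_p", "fdr_max", "survival_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.dpsi_min <= 1:
            raise ValueError(f"dpsi_min must be in [0, 1], got {self.dpsi_min}")
        if self.de_abs_log2fc < 0:
            raise ValueError("de_abs_log2fc must be >= 0")
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")


_FIELD_TYPES = {f.name: f.type for f in fields(ScreenThresholds)}


def load_thresholds(path: str | Path | None = None, **overrides) -> ScreenThresholds:
    """Build thresholds from an optional YAML file plus keyword overrides.

    The YAML file may contain any subset of the :class:`ScreenThresholds`
    fields; unknown keys are rejected.  The resolved thresholds are echoed
    to the log for provenance.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        unknown = set(loaded) - set(_FIELD_TYPES)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    thr = ScreenThresholds(**values)
    log.info("thresholds: %s", thr)
    return thr


def log_funnel(stage: str, n_in: int, n_out: int, detail: str = "") -> None:
    """Log a filtering stage's input/output counts (funnel reporting)."""
    log.info("%s: %d in -> %d out%s", stage, n_in, n_out,
             f" ({detail})" if detail else "")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
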