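"""Deterministic bench-assay calculators.

Relative qPCR quantification (delta-delta-Ct), qPCR-based PSI, LDH-release
cytotoxicity, and caliper tumor volume.  These are exact formulas, not
statistics; out-of-range results are reported as-is (clipping would hide
assay problems) with a logged warning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import log


def ddct_fold(ct_target_case: float, ct_ref_case: float,
              ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression by the 2^(-ddCt) method.

    dCt = Ct(target) - Ct(reference) within each condition;
    ddCt = dCt(case) - dCt(control); fold change = 2^(-ddCt).
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if any(c is None or not math.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def qpcr_psi(rel_inclusion: float, rel_skipping: float) -> float:
    """PSI from isoform-specific qPCR abundances: 100*incl/(incl+skip).

    Inputs are reference-normalised relative abundances of the
    inclusion and skipping isoforms (equal amplification efficiencies
    assumed, so the normalisation cancels in the ratio).
    """
    if rel_inclusion < 0 or rel_skipping < 0:
        raise ValueError("relative abundances must be >= 0")
    total = rel_inclusion + rel_skipping
    if total == 0:
        raise ValueError("PSI undefined: both isoform abundances are zero")
    return 100.0 * rel_inclusion / total


@dataclass(frozen=True)
class LdhPlate:
    """Net ODs (OD490 - OD680) for the LDH-release well classes."""

    mix: float  # effector/target co-culture
    effector_control: float
    low_control: float  # spontaneous target release
    high_control: float  # maximal target release (detergent lysis)

    @classmethod
    def from_raw(cls, od490: dict[str, float], od680: dict[str, float],
                 ) -> "LdhPlate":
        net = {k: od490[k] - od680[k] for k in
               ("mix", "effector_control", "low_control", "high_control")}
        return cls(**net)


def ldh_cytotoxicity(plate: LdhPlate) -> float:
    """Specific lysis percentage from LDH release.

    Cytotoxicity (%) = (mix - effector control - low control)
                       / (high control - low control) * 100,
    on net ODs.  Noisy plates may yield values outside [0, 100]; they are
    reported unclipped with a warning.
    """
    denom = plate.high_control - plate.low_control
    if denom == 0:
        raise ZeroDivisionError("high and low controls are equal")
    pct = 100.0 * (plate.mix - plate.effector_control - plate.low_control) / denom
    if not 0 <= pct <= 100:
        log.warning("cytotoxicity %.1f%% outside [0, 100]; reported as-is", pct)
    return pct


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume V = L * W^2 / 2 (mm^3)."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor dimensions must be positive")
    return length_mm * width_mm ** 2 / 2.0
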