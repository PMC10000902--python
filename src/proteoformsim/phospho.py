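"""Phosphoproteoform analysis on both measurement sides.

Gel side: lambda-phosphatase treatment shifts phosphoproteoforms toward
higher pI, so the volume ratio untreated/treated at a phospho spot position
exceeds 1 for genuinely phosphorylated spots; a strict ratio > 1.5 is the
classification rule. Under the package's stoichiometric spot model the
noise-free expected ratio is ``1/(1 - o*e)`` for occupancy ``o`` and
treatment efficiency ``e``, so at full efficiency exactly the spots with
occupancy above 1/3 are flagged.

Shotgun side: phosphopeptide-intensity to iBAQ ratios approximate
phosphorylation stoichiometry against the (mostly unphosphorylated) protein
background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhosphoCall",
    "ppase_ratio_classify",
    "phospho_fraction",
    "spot_pair_stoichiometry",
    "ibaq_ppeptide_ratio",
]

DEFAULT_RATIO_THRESHOLD = 1.5


@dataclass
class PhosphoCall:
    spot_id: str
    vol_untreated: float
    vol_treated: float
    ratio: float  # untreated / treated; inf when fully shifted
    threshold: float
    flagged: bool
    shift_class: str  # "ratio" | "fully_shifted" | "unflagged"


def ppase_ratio_classify(
    pairs: pd.DataFrame,
    threshold: float = DEFAULT_RATIO_THRESHOLD,
    detection_floor: float = 0.0,
) -> pd.DataFrame:
    """Classify spots as phosphorylated from paired untreated/treated volumes.

    ``pairs`` needs columns vol_untreated and vol_treated (indexed by spot).
    A spot is flagged iff untreated/treated is strictly above the threshold.
    Spots whose treated volume fell to or below the detection floor while the
    untreated volume is above it are flagged through the "fully_shifted"
    branch instead of a division.
    """
    out = pairs.copy()
    vu = out["vol_untreated"].to_numpy(dtype=float)
    vt = out["vol_treated"].to_numpy(dtype=float)
    fully = (vt <= detection_floor) & (vu > detection_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vt > detection_floor, vu / vt, np.inf)
    ratio = np.where(vu <= detection_floor, np.nan, ratio)
    flagged = np.where(np.isnan(ratio), False, (ratio > threshold) | fully)
    out["ratio"] = ratio
    out["threshold"] = threshold
    out["flagged"] = flagged.astype(bool)
    out["shift_class"] = np.select(
        [fully & (vu > detection_floor), out["flagged"]],
        ["fully_shifted", "ratio"],
        default="unflagged",
    )
    return out


def phospho_fraction(flagged: int, total: int) -> tuple[int, float]:
    """Share of flagged spots among all 100%-matched spots, in percent.

    Returns (headline integer percent rounded half-up, unrounded percent).
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    pct = 100.0 * flagged / total
    return int(math.floor(pct + 0.5)), pct


def spot_pair_stoichiometry(
    phospho_volume: float | None, dephospho_volume: float | None
) -> tuple[float | None, str]:
    """Phospho-to-unphospho spot volume ratio, with one-sided labels.

    When only one of the pair is detectable the ratio is undefined and the
    label says which side was seen ("phospho-only" / "dephospho-only").
    """
    has_p = phospho_volume is not None and phospho_volume > 0
    has_d = dephospho_volume is not None and dephospho_volume > 0
    if has_p and has_d:
        return float(phospho_volume) / float(dephospho_volume), "ratio"
    if has_p:
        return None, "phospho-only"
    if has_d:
        return None, "dephospho-only"
    return None, "undetected"


def ibaq_ppeptide_ratio(
    phosphopeptides: pd.DataFrame, ibaq: pd.Series
) -> tuple[pd.Series, float]:
    """Phosphopeptide intensity / protein iBAQ, and the fraction below 1.

    ``phosphopeptides`` needs columns accession and intensity; ``ibaq`` maps
    accession to the protein's iBAQ. Records whose protein lacks an iBAQ are
    skipped with a logged count.
    """
    prot_ibaq = phosphopeptides["accession"].map(ibaq)
    ok = prot_ibaq.notna() & (prot_ibaq > 0)
    skipped = int((~ok).sum())
    if skipped:
        logger.info("ibaq_ppeptide_ratio: skipped %d records without iBAQ", skipped)
    ratios = phosphopeptides.loc[ok, "intensity"] / prot_ibaq[ok]
    frac_below_1 = float((ratios < 1.0).mean()) if len(ratios) else float("nan")
    return ratios, frac_below_1
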