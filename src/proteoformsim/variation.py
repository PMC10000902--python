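"""Core comparison statistics: raw-scale CVs, reproducibility counts and
spot-level versus proteoform-summed rank correlations.

The coefficient of variation is always computed on the raw (non-log) scale:
100 * sample standard deviation / mean. Applying the same formula to
log2-transformed values - a common mistake in the literature - yields
systematically smaller, non-comparable numbers; :func:`cv_on_log2` implements
that wrong estimator deliberately so the distortion can be demonstrated and
tested, and flags its output as non-comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "VariationSummary",
    "CorrelationResult",
    "coefficient_of_variation",
    "cv_on_log2",
    "summarize_variation",
    "reproducible_entities",
    "spearman",
    "proteoform_sum_correlation",
]


@dataclass
class VariationSummary:
    """Per-method CV summary over the complete (no-missing) entities."""

    per_entity: pd.DataFrame  # entity_id x [cv_tech, cv_total]
    median_cv_tech: float
    median_cv_total: float
    n_tech: int
    n_bio: int
    method: str
    n_excluded_missing: int


@dataclass
class CorrelationResult:
    r_s: float
    n: int
    level: str  # "per-spot" | "per-protein-summed"
    entities: tuple[str, ...]


def _check_values(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D array of at least two values")
    if not np.all(values > 0):
        raise ValueError("CV is defined here only for strictly positive values")
    return values


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """Raw-scale CV in percent: 100 * sd / mean (sample sd by default)."""
    values = _check_values(values)
    return float(100.0 * values.std(ddof=ddof) / values.mean())


def cv_on_log2(values, ddof: int = 1) -> tuple[float, str]:
    """The *wrong* CV: same formula applied to log2-transformed values.

    Returned with a warning flag marking it non-comparable to raw-scale CVs.
    For multiplicative data with raw CV above a few percent this comes out
    far smaller, which is exactly the distortion it exists to demonstrate.
    Values must exceed 1 so the logs are positive.
    """
    values = _check_values(values)
    if not np.all(values > 1):
        raise ValueError("log2-scale CV needs all values > 1 (positive logs)")
    logs = np.log2(values)
    cv = float(100.0 * logs.std(ddof=ddof) / logs.mean())
    return cv, "log2-scale CV; not comparable to raw-scale CV"


def summarize_variation(
    table: pd.DataFrame,
    tech_cols: list[str],
    bio_cols: list[str] | None = None,
    method: str = "2D-DIGE",
    ddof: int = 1,
) -> VariationSummary:
    """CV_tech and CV_total per entity plus cohort medians.

    ``tech_cols`` are technical replicates of one sample; ``bio_cols`` are
    biological replicates (their spread is technical + biological, hence
    "total"). Entities with any missing value in the used columns are
    excluded with a logged count - never imputed.
    """
    used = list(tech_cols) + list(bio_cols or [])
    sub = table[used]
    complete = sub.dropna()
    n_excluded = len(sub) - len(complete)
    if n_excluded:
        logger.info("summarize_variation: excluded %d entities with missing values", n_excluded)
    rows = {}
    for eid, row in complete.iterrows():
        tech = row[tech_cols].to_numpy(dtype=float)
        rows[eid] = {"cv_tech": coefficient_of_variation(tech, ddof=ddof)}
        if bio_cols:
            bio = row[bio_cols].to_numpy(dtype=float)
            rows[eid]["cv_total"] = coefficient_of_variation(bio, ddof=ddof)
    per_entity = pd.DataFrame.from_dict(rows, orient="index")
    return VariationSummary(
        per_entity=per_entity,
        median_cv_tech=float(per_entity["cv_tech"].median()) if len(per_entity) else float("nan"),
        median_cv_total=float(per_entity["cv_total"].median())
        if bio_cols and len(per_entity)
        else float("nan"),
        n_tech=len(tech_cols),
        n_bio=len(bio_cols or []),
        method=method,
        n_excluded_missing=n_excluded,
    )


def reproducible_entities(
    table: pd.DataFrame, by_range: pd.Series | None = None
) -> dict[str, int]:
    """Count entities present (non-missing) in every replicate column.

    With ``by_range`` (entity -> pH-range label) the count is also reported
    per range; the composed count is the sum over the disjoint ranges.
    """
    complete = table.notna().all(axis=1)
    out = {"composed": int(complete.sum())}
    if by_range is not None:
        for rng_label, idx in table.groupby(by_range).groups.items():
            out[str(rng_label)] = int(complete.loc[idx].sum())
    return out


def spearman(x, y) -> float:
    """Spearman rank correlation with midrank tie handling.

    Thin validated wrapper over the standard rank-correlation estimator
    (Pearson correlation of midranks); ties get average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    return float(stats.spearmanr(x, y).statistic)


def proteoform_sum_correlation(
    spot_volumes: pd.Series,
    spot_to_accession: pd.Series,
    protein_lfq: pd.Series,
    level: str = "per-protein-summed",
) -> CorrelationResult:
    """Correlate 2D spot volumes with protein-level shotgun LFQ values.

    level "per-spot": each spot's volume is paired with its parent protein's
    LFQ (the LFQ value repeats across a protein's spots; midranks absorb the
    ties). level "per-protein-summed": spot volumes are first summed per
    accession, giving one pair per protein. Spots mapping to no accession in
    the LFQ table are excluded with a logged count.
    """
    mapped = spot_to_accession.reindex(spot_volumes.index)
    ok = mapped.notna() & mapped.isin(protein_lfq.dropna().index)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("proteoform_sum_correlation: dropped %d unmapped spots", n_dropped)
    vols = spot_volumes[ok]
    accs = mapped[ok]
    if level == "per-spot":
        x = vols.to_numpy()
        y = protein_lfq.loc[accs].to_numpy()
        entities = tuple(vols.index.astype(str))
    elif level == "per-protein-summed":
        summed = vols.groupby(accs).sum()
        x = summed.to_numpy()
        y = protein_lfq.loc[summed.index].to_numpy()
        entities = tuple(summed.index.astype(str))
    else:
        raise ValueError(f"unknown level {level!r}")
    return CorrelationResult(r_s=spearman(x, y), n=len(x), level=level, entities=entities)
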