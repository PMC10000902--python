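"""The packaged DU145 benchmark spot panel and its correlation report.

The panel transcribes a published-style comparison table: 36 2D-gel spots
(proteoforms) of 11 proteins, each protein also quantified as one canonical
LFQ intensity by shotgun. It is the worked example for the spot-level versus
proteoform-summed correlation question: pairing every spot with its
protein's LFQ gives a weak rank correlation, while summing a protein's spot
volumes first raises it substantially. The two CALM1 spots are excluded from
the correlations (34 spots / 10 proteins enter), matching the curated
comparison the panel reproduces.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .variation import proteoform_sum_correlation

__all__ = [
    "FixtureValidationError",
    "SpotPanel",
    "load_spot_panel",
    "spot_panel_report",
    "spot_panel_sha256",
]

EXPECTED_COLUMNS = [
    "spot_id", "label_as_printed", "gene", "protein_name", "identified_by",
    "ph_range", "practical_pi", "theoretical_pi", "practical_mw_kda",
    "theoretical_mw_kda", "dige_cv_tech", "dige_sum_cv_tech", "dige_cv_total",
    "dige_sum_cv_total", "shotgun_cv_tech", "shotgun_cv_total", "spot_size",
    "lfq_intensity", "excluded_from_correlation",
]
N_ROWS = 36
N_GENES = 11
_NUMERIC = [
    "practical_pi", "theoretical_pi", "practical_mw_kda", "theoretical_mw_kda",
    "dige_cv_tech", "dige_sum_cv_tech", "dige_cv_total", "dige_sum_cv_total",
    "shotgun_cv_tech", "shotgun_cv_total", "spot_size", "lfq_intensity",
]


class FixtureValidationError(ValueError):
    """The spot-panel file does not match the documented schema."""


@dataclass
class SpotPanel:
    spots: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return sorted(self.spots["gene"].unique())

    @property
    def included(self) -> pd.DataFrame:
        return self.spots[~self.spots["excluded_from_correlation"]]

    def gene_lfq(self) -> pd.Series:
        return self.spots.groupby("gene")["lfq_intensity"].first()

    def gene_spot_sums(self, included_only: bool = True) -> pd.Series:
        df = self.included if included_only else self.spots
        return df.groupby("gene")["spot_size"].sum()


def _default_path() -> Path:
    return Path(str(resources.files("proteoformsim.data").joinpath("du145_spot_panel.tsv")))


def spot_panel_sha256(path: str | Path | None = None) -> str:
    """Checksum of the packaged panel file, for drift detection."""
    p = Path(path) if path else _default_path()
    return hashlib.sha256(p.read_bytes()).hexdigest()


def load_spot_panel(path: str | Path | None = None) -> SpotPanel:
    """Load and validate the 36-row spot panel.

    Raises :class:`FixtureValidationError` on a missing column, wrong row
    count, non-numeric quantitative cell or a duplicate spot_id. The
    duplicated *printed* label ("31") is expected and preserved in
    ``label_as_printed``; ``spot_id`` itself must be unique.
    """
    p = Path(path) if path else _default_path()
    try:
        df = pd.read_csv(
            p, sep="\t", comment="#", na_values=["NA"], keep_default_na=False
        )
    except Exception as exc:  # pragma: no cover - pass through as validation error
        raise FixtureValidationError(f"cannot parse {p}: {exc}") from exc
    if list(df.columns) != EXPECTED_COLUMNS:
        raise FixtureValidationError(
            f"header mismatch: got {list(df.columns)[:5]}..., expected the documented schema"
        )
    if len(df) != N_ROWS:
        raise FixtureValidationError(f"expected {N_ROWS} rows, found {len(df)}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise FixtureValidationError(f"non-numeric cell(s) in column {col!r}")
        df[col] = coerced
    if df["spot_id"].duplicated().any():
        raise FixtureValidationError("spot_id values must be unique")
    if df["gene"].nunique() != N_GENES:
        raise FixtureValidationError(
            f"expected {N_GENES} distinct genes, found {df['gene'].nunique()}"
        )
    df["excluded_from_correlation"] = df["excluded_from_correlation"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    if df["excluded_from_correlation"].isna().any():
        raise FixtureValidationError("excluded_from_correlation must be true/false")
    lfq_var = df.groupby("gene")["lfq_intensity"].nunique()
    if (lfq_var != 1).any():
        raise FixtureValidationError("lfq_intensity must be identical within a gene")
    if (df["spot_size"] <= 0).any():
        raise FixtureValidationError("spot_size must be > 0")
    return SpotPanel(df.set_index("spot_id"))


def spot_panel_report(panel: SpotPanel | None = None) -> dict:
    """Correlations at both levels plus per-gene sums and the exclusion list.

    per-spot: every included spot's size against its protein's LFQ (ties in
    LFQ handled by midranks); per-protein-summed: spot sizes summed per gene
    first. Returns a plain dict ready for JSON serialization.
    """
    panel = panel or load_spot_panel()
    inc = panel.included
    lfq = panel.gene_lfq()
    spot_vols = inc["spot_size"]
    spot_gene = inc["gene"]
    per_spot = proteoform_sum_correlation(spot_vols, spot_gene, lfq, level="per-spot")
    summed = proteoform_sum_correlation(
        spot_vols, spot_gene, lfq, level="per-protein-summed"
    )
    excluded_genes = sorted(
        panel.spots.loc[panel.spots["excluded_from_correlation"], "gene"].unique()
    )
    return {
        "per_spot": {"r_s": per_spot.r_s, "n": per_spot.n},
        "per_protein_summed": {"r_s": summed.r_s, "n": summed.n},
        "gene_spot_sums": panel.gene_spot_sums().round(4).to_dict(),
        "gene_lfq": lfq.to_dict(),
        "excluded_genes": excluded_genes,
        "n_spots_total": len(panel.spots),
        "n_genes_total": len(panel.genes),
    }
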