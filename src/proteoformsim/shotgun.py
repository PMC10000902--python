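"""Label-free bottom-up (shotgun) measurement simulation.

All proteoforms are digested into one shared peptide pool, so a peptide's
true intensity sums the abundances of every proteoform containing it - the
proteoform-information loss characteristic of bottom-up proteomics is built
in on purpose. Data-dependent acquisition is emulated by a stochastic
detection probability that increases with intensity (weak precursors are
skipped, as in top-N selection), with a strong extra penalty for
phosphopeptides, mirroring how rarely direct (enrichment-free) shotgun runs
see them. Detected peptides are reassembled to canonical accessions, and
protein quantities are computed as LFQ (median-ratio normalized intensity
sums) and iBAQ (intensity sum over the count of theoretically measurable
tryptic peptides).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chemistry
from .chemistry import DigestRule, TRYPSIN
from .proteome import NoiseModel, ProteomeModel

__all__ = [
    "ShotgunParams",
    "simulate_runs",
    "infer_protein_groups",
    "compute_lfq",
    "compute_ibaq",
    "phosphosite_accounting",
]


@dataclass
class ShotgunParams:
    """Digestion and acquisition parameters for the shotgun simulator."""

    rule: DigestRule = TRYPSIN
    max_missed_cleavages: int = 2
    ionization_sigma: float = 1.0  # ln-scale spread of per-peptide response factors
    # share of technical variance acting jointly on all peptides of a protein in a
    # run (digestion efficiency, LC drift); the rest is independent per peptide.
    # Without this, summing ~dozens of peptides would average protein-level CV away.
    protein_noise_share: float = 0.8
    localization_alpha: float = 8.0  # Beta(alpha, beta) simulated site confidence
    localization_beta: float = 1.5
    localization_threshold: float = 0.75

    @property
    def length_bounds(self) -> tuple[int, int]:
        return self.rule.peptide_length_bounds


def _peptide_pool(model: ProteomeModel, params: ShotgunParams) -> pd.DataFrame:
    """Flatten all proteoforms into peptide rows with occupancy-split weights.

    For a phosphoproteoform with occupancy ``o``, the peptide covering the
    site contributes ``o`` of the proteoform abundance as a phosphopeptide
    and ``1 - o`` as its unmodified version; all other peptides contribute
    fully as unmodified. Only peptides inside the measurable length bounds
    are retained.
    """
    lo, hi = params.length_bounds
    digests: dict[str, list[chemistry.Peptide]] = {}
    seqs, mods_sites, accs, pfids, weights = [], [], [], [], []
    for p in model.proteoforms:
        if p.sequence not in digests:
            digests[p.sequence] = [
                pep
                for pep in chemistry.digest(
                    p.sequence, params.rule, max_missed=params.max_missed_cleavages
                )
                if lo <= len(pep.sequence) <= hi
            ]
        phospho_sites = [(s, o) for s, n, o in p.modifications if n == "phospho"]
        for pep in digests[p.sequence]:
            covered = [(s, o) for s, o in phospho_sites if pep.start <= s < pep.end]
            if covered:
                site, occ = covered[0]
                if occ > 0:
                    seqs.append(pep.sequence)
                    mods_sites.append(site - pep.start)
                    accs.append(p.parent_accession)
                    pfids.append(p.proteoform_id)
                    weights.append(p.base_abundance * occ)
                if occ < 1:
                    seqs.append(pep.sequence)
                    mods_sites.append(-1)
                    accs.append(p.parent_accession)
                    pfids.append(p.proteoform_id)
                    weights.append(p.base_abundance * (1.0 - occ))
            else:
                seqs.append(pep.sequence)
                mods_sites.append(-1)
                accs.append(p.parent_accession)
                pfids.append(p.proteoform_id)
                weights.append(p.base_abundance)
    pool = pd.DataFrame(
        {
            "sequence": seqs,
            "phospho_site": mods_sites,  # -1 = unmodified
            "accession": accs,
            "proteoform_id": pfids,
            "weight": weights,
        }
    )
    return pool


def simulate_runs(
    model: ProteomeModel,
    abundances: pd.DataFrame,
    params: ShotgunParams | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    *,
    runs: list[str] | None = None,
) -> pd.DataFrame:
    """Per-run peptide observations with stochastic DDA-style detection.

    ``abundances`` columns name the runs (one LC-MS run per column unless
    ``runs`` restricts them). Peptide true intensity sums contributing
    proteoform abundances (occupancy-weighted for modified forms), times a
    peptide-specific ionization factor fixed across runs, times run-level
    log-normal technical noise. Detection probability is logistic in log
    intensity, multiplied by ``phospho_detection_penalty`` for
    phosphopeptides. Returns a long frame: run_id, sequence, phospho_site,
    accession, intensity, localization_prob (NaN for unmodified), plus the
    ground-truth contributing proteoform ids.
    """
    params = params or ShotgunParams()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    runs = list(runs or abundances.columns)

    pool = _peptide_pool(model, params)
    # per-run proteoform multiplier relative to base abundance
    pf_scale = pd.Series({p.proteoform_id: p.base_abundance for p in model.proteoforms})
    rel = abundances.div(pf_scale.reindex(abundances.index), axis=0)

    key = ["sequence", "phospho_site", "accession"]
    agg = pool.groupby(key).agg(
        weight=("weight", "sum"),
        proteoform_ids=("proteoform_id", lambda s: tuple(sorted(set(s)))),
        n_proteoforms=("proteoform_id", "nunique"),
    )
    # one ionization factor per peptide species, fixed across runs
    ion = np.exp(params.ionization_sigma * rng.standard_normal(len(agg)))
    agg["ion_factor"] = ion

    # per-run relative biological factor for each peptide: weighted mean of its
    # contributors' relative abundances (exact when contributors move together)
    pool = pool.join(rel, on="proteoform_id")
    wsum = {}
    for run in runs:
        pool["_wx"] = pool["weight"] * pool[run]
        wsum[run] = pool.groupby(key)["_wx"].sum()
    base_int = agg["weight"].to_numpy() * agg["ion_factor"].to_numpy()
    is_phospho = np.asarray(agg.index.get_level_values("phospho_site") >= 0)
    median_log = np.log(np.median(base_int[base_int > 0]))

    acc_codes, acc_uniques = pd.factorize(agg.index.get_level_values("accession"))
    sigma_shared = noise.sigma_tech_shotgun * np.sqrt(params.protein_noise_share)
    sigma_indep = noise.sigma_tech_shotgun * np.sqrt(1.0 - params.protein_noise_share)
    frames = []
    for run in runs:
        true_int = wsum[run].to_numpy() * agg["ion_factor"].to_numpy()
        tech = np.ones(len(agg))
        if sigma_shared > 0:
            tech *= np.exp(sigma_shared * rng.standard_normal(len(acc_uniques)))[acc_codes]
        if sigma_indep > 0:
            tech *= np.exp(sigma_indep * rng.standard_normal(len(agg)))
        inten = true_int * tech
        with np.errstate(divide="ignore"):
            z = noise.shotgun_detect_slope * (
                np.log(np.maximum(inten, 1e-300)) - median_log - noise.shotgun_detect_midpoint
            )
        p = noise.shotgun_detect_floor + (
            noise.shotgun_detect_ceiling - noise.shotgun_detect_floor
        ) / (1.0 + np.exp(-z))
        p = np.where(is_phospho, p * noise.phospho_detection_penalty, p)
        p = np.where(inten > 0, p, 0.0)
        det = rng.uniform(size=len(agg)) < p
        sub = agg.reset_index()[["sequence", "phospho_site", "accession", "proteoform_ids", "n_proteoforms"]]
        sub["run_id"] = run
        sub["intensity"] = inten
        loc = np.full(len(agg), np.nan)
        nph = int(is_phospho.sum())
        if nph:
            loc[is_phospho] = rng.beta(
                params.localization_alpha, params.localization_beta, size=nph
            )
        sub["localization_prob"] = loc
        frames.append(sub[det])
    return pd.concat(frames, ignore_index=True)


def infer_protein_groups(peptides: pd.DataFrame) -> pd.DataFrame:
    """Assemble detected peptides into canonical protein groups per run.

    Proteoform identity is deliberately not an output: all proteoforms of one
    accession collapse into one group. Peptide sequences observed under
    several accessions are assigned to the accession with more distinct
    detected peptides (ties broken lexicographically). Returns one row per
    (run_id, accession) with intensity sum, peptide counts and the
    ground-truth number of collapsed proteoforms.
    """
    pep = peptides.copy()
    # evidence per accession: distinct peptide sequences across all runs
    evidence = (
        pep.groupby("accession")["sequence"].nunique().rename("n_distinct").to_frame()
    )
    shared = pep.groupby(["sequence", "phospho_site"])["accession"].transform("nunique")
    if (shared > 1).any():
        def _winner(accessions: pd.Series) -> str:
            ev = evidence.loc[sorted(set(accessions)), "n_distinct"]
            return ev.sort_index().sort_values(kind="stable", ascending=False).index[0]

        winners = (
            pep.groupby(["sequence", "phospho_site"])["accession"]
            .agg(_winner)
            .rename("assigned")
        )
        pep = pep.join(winners, on=["sequence", "phospho_site"])
        pep["accession"] = pep["assigned"]
        pep = pep.drop(columns="assigned")

    def _n_forms(ids: pd.Series) -> int:
        return len(set().union(*ids))

    groups = (
        pep.groupby(["run_id", "accession"])
        .agg(
            intensity_sum=("intensity", "sum"),
            n_peptides=("sequence", "nunique"),
            n_phosphopeptides=("phospho_site", lambda s: int((s >= 0).sum())),
            n_proteoforms_collapsed=("proteoform_ids", _n_forms),
        )
        .reset_index()
    )
    return groups


def compute_lfq(
    groups: pd.DataFrame, peptides: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-run LFQ intensities: median-ratio normalization then summation.

    Each run is scaled by the median ratio of shared protein intensity sums
    to the reference run (the first run); LFQ is the normalized intensity sum
    per group. Groups with no detected peptides in a run stay missing - no
    imputation. Returns an accession x run matrix.
    """
    mat = groups.pivot(index="accession", columns="run_id", values="intensity_sum")
    runs = list(mat.columns)
    ref = runs[0]
    factors = {}
    for run in runs:
        both = mat[[ref, run]].dropna()
        if run == ref or both.empty:
            factors[run] = 1.0
        else:
            factors[run] = float(np.median(both[ref] / both[run]))
    lfq = mat.mul(pd.Series(factors), axis=1)
    lfq.columns.name = "run_id"
    return lfq


def compute_ibaq(
    groups: pd.DataFrame,
    model: ProteomeModel,
    params: ShotgunParams | None = None,
) -> pd.DataFrame:
    """iBAQ per (run, accession): intensity sum / theoretical peptide count.

    The denominator counts fully cleaved peptides of the canonical sequence
    inside the measurable length bounds; accessions with zero theoretical
    peptides get a missing iBAQ.
    """
    params = params or ShotgunParams()
    counts = {
        acc: chemistry.theoretical_peptide_count(seq, params.rule)
        for acc, seq in model.proteins.items()
    }
    out = groups.copy()
    out["theoretical_peptides"] = out["accession"].map(counts)
    out["ibaq"] = np.where(
        out["theoretical_peptides"] > 0,
        out["intensity_sum"] / out["theoretical_peptides"].replace(0, np.nan),
        np.nan,
    )
    return out


def phosphosite_accounting(
    untreated: pd.DataFrame,
    treated: pd.DataFrame,
    localization_threshold: float = 0.75,
) -> dict:
    """Detected/localized/quantified phosphopeptide accounting with overlaps.

    A phosphopeptide is *detected* if observed in any run of the condition,
    *localized* if its simulated site-confidence exceeds the threshold, and
    *quantified* if it carries a positive intensity. Returns counts per
    condition plus the exact three-way set overlap (untreated-only, both,
    treated-only) of localized-and-quantified phosphopeptides and their
    parent proteins.
    """

    def _sets(df: pd.DataFrame) -> tuple[set, set, dict]:
        ph = df[df["phospho_site"] >= 0]
        detected = set(zip(ph["sequence"], ph["phospho_site"]))
        ok = ph[
            (ph["localization_prob"] > localization_threshold)
            & (ph["intensity"] > 0)
        ]
        quantified = set(zip(ok["sequence"], ok["phospho_site"]))
        proteins = set(ok["accession"])
        stats = {
            "detected": len(detected),
            "localized_quantified": len(quantified),
            "proteins": len(proteins),
        }
        return quantified, proteins, stats

    pep_u, prot_u, stats_u = _sets(untreated)
    pep_t, prot_t, stats_t = _sets(treated)
    return {
        "untreated": stats_u,
        "treated": stats_t,
        "peptide_overlap": {
            "only_untreated": len(pep_u - pep_t),
            "both": len(pep_u & pep_t),
            "only_treated": len(pep_t - pep_u),
        },
        "protein_overlap": {
            "only_untreated": len(prot_u - prot_t),
            "both": len(prot_u & prot_t),
            "only_treated": len(prot_t - prot_u),
        },
    }
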