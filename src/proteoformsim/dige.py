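"""Simulation of the 2D-DIGE measurement process.

Intact proteoforms are laid out on (pI, MW) coordinates; forms closer than
the gel's resolution merge into one spot. Each gel carries up to three dye
channels, one of which is always the pooled internal standard (IS). Raw spot
volumes get a channel gain and multiplicative technical noise; weak spots go
missing stochastically (more often in the technically harder pH 6-9 range).
Quantification follows the internal-standard convention: volumes are first
normalized within a channel, then divided by the same spot's normalized
volume in the IS channel of the same gel, giving the standardized abundance
(SA) that is comparable across gels. No imputation happens anywhere; analyses
downstream use only spots matched in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .proteome import NoiseModel, ProteomeModel, dephosphorylate

__all__ = [
    "GelDesign",
    "MatchedSpotTable",
    "technical_replicate_design",
    "biological_replicate_design",
    "form_spots",
    "simulate_gels",
    "standardize_abundance",
    "match_spots",
    "reconstruct_spot_volume",
    "simulate_ppase_contrast",
]

IS_CHANNEL = "Cy2"


@dataclass
class GelDesign:
    """Gel layout: pH ranges, channel-to-sample assignments, resolution.

    ``gels`` maps gel_id to {channel: sample}; every gel must carry the
    internal standard on ``is_channel``. ``delta_pi`` and ``delta_mw_relative``
    are both the spot-merge resolution and the cross-gel matching tolerance.
    """

    gels: dict[str, dict[str, str]]
    ph_ranges: tuple[tuple[float, float], ...] = ((4.0, 7.0), (6.0, 9.0))
    is_channel: str = IS_CHANNEL
    is_sample: str = "IS"
    delta_pi: float = 0.05
    delta_mw_relative: float = 0.02

    def __post_init__(self) -> None:
        for lo, hi in self.ph_ranges:
            if not lo < hi:
                raise ValueError(f"pH range ({lo}, {hi}) must have lower < upper")
        for gel_id, channels in self.gels.items():
            if self.is_channel not in channels:
                raise ValueError(f"gel {gel_id!r} lacks the IS channel {self.is_channel!r}")

    @property
    def replicate_channels(self) -> list[tuple[str, str, str]]:
        """(gel_id, channel, sample) for every non-IS channel, in design order."""
        return [
            (g, ch, s)
            for g, channels in self.gels.items()
            for ch, s in channels.items()
            if ch != self.is_channel
        ]


def technical_replicate_design(n_gels: int = 3, **kwargs) -> GelDesign:
    """Six technical replicates of the pooled sample on three gels.

    Each gel runs the IS pool on Cy3 and Cy5 and normalizes over the Cy2 IS -
    the layout used to estimate pure technical variation.
    """
    gels = {
        f"gel{t+1}": {"Cy3": "IS", "Cy5": "IS", IS_CHANNEL: "IS"}
        for t in range(n_gels)
    }
    return GelDesign(gels=gels, **kwargs)


def biological_replicate_design(samples: list[str] | None = None, **kwargs) -> GelDesign:
    """One gel per biological sample (sample on Cy5, IS pool on Cy2)."""
    samples = samples or ["bio1", "bio2", "bio3"]
    gels = {f"gel_{s}": {"Cy5": s, IS_CHANNEL: "IS"} for s in samples}
    return GelDesign(gels=gels, **kwargs)


def _cluster_positions(
    pi: np.ndarray, mw: np.ndarray, delta_pi: float, delta_mw_rel: float
) -> np.ndarray:
    """Greedy single-pass merge of (pI, MW) positions within tolerance.

    Positions are visited in pI order; each joins the first earlier cluster
    whose representative (its first member) is within delta_pi in pI and
    within delta_mw_rel relatively in MW. Deterministic and order-independent
    given identical inputs.
    """
    order = np.argsort(pi, kind="stable")
    labels = np.full(len(pi), -1, dtype=int)
    reps: list[tuple[float, float, int]] = []  # (pi, mw, label) of open cluster reps
    next_label = 0
    for idx in order:
        p, m = pi[idx], mw[idx]
        assigned = -1
        for rp, rm, lab in reversed(reps):
            if p - rp >= delta_pi:
                break
            if abs(m - rm) < delta_mw_rel * max(rm, m):
                assigned = lab
                break
        if assigned < 0:
            assigned = next_label
            next_label += 1
        labels[idx] = assigned
        reps.append((p, m, assigned))
    return labels


def form_spots(
    model_or_frame: ProteomeModel | pd.DataFrame,
    abundances: pd.DataFrame,
    design: GelDesign,
) -> pd.DataFrame:
    """Ground-truth spot map: merged proteoforms with summed true volumes.

    Proteoforms whose pI differs by less than ``design.delta_pi`` and whose
    MW differs relatively by less than ``design.delta_mw_relative`` fuse into
    one spot; proteoforms outside a pH range are dropped for that range. The
    returned frame has one row per (ph_range, spot) with the member proteoform
    ids and one true-volume column per abundance column.
    """
    if isinstance(model_or_frame, ProteomeModel):
        pf = model_or_frame.proteoform_frame().set_index("proteoform_id")
    else:
        pf = model_or_frame.set_index("proteoform_id")
    pf = pf.loc[abundances.index]
    out_rows = []
    for lo, hi in design.ph_ranges:
        rng_label = f"{lo:g}-{hi:g}"
        in_range = pf[(pf["pi"] >= lo) & (pf["pi"] <= hi)]
        if in_range.empty:
            continue
        labels = _cluster_positions(
            in_range["pi"].to_numpy(),
            in_range["mw_kda"].to_numpy(),
            design.delta_pi,
            design.delta_mw_relative,
        )
        sub = in_range.assign(_label=labels)
        ab = abundances.loc[in_range.index]
        for lab, members in sub.groupby("_label"):
            vols = ab.loc[members.index].sum(axis=0)
            w = members["base_abundance"].to_numpy()
            w = w / w.sum()
            row = {
                "spot_id": f"ph{rng_label}_s{lab}",
                "ph_range": rng_label,
                "pi": float(np.average(members["pi"], weights=w)),
                "mw_kda": float(np.average(members["mw_kda"], weights=w)),
                "proteoform_ids": tuple(members.index),
                "n_proteoforms": len(members),
                "parent_accessions": tuple(sorted(set(members["parent_accession"]))),
            }
            row.update({c: float(vols[c]) for c in abundances.columns})
            out_rows.append(row)
    spots = pd.DataFrame(out_rows)
    return spots.set_index("spot_id") if len(spots) else spots


def _detect_prob(
    log_volume: np.ndarray, ref_log: float, noise: NoiseModel, ph69: np.ndarray
) -> np.ndarray:
    z = noise.dige_detect_slope * (log_volume - ref_log - noise.dige_detect_midpoint)
    p = noise.dige_detect_floor + (
        noise.dige_detect_ceiling - noise.dige_detect_floor
    ) / (1.0 + np.exp(-z))
    return np.where(ph69, p * noise.ph69_detect_penalty, p)


def simulate_gels(
    spot_map: pd.DataFrame,
    abundances: pd.DataFrame,
    design: GelDesign,
    noise: NoiseModel | None = None,
    seed: int = 0,
    *,
    gain_sigma: float = 0.2,
    pi_jitter: float = 0.01,
    mw_rel_jitter: float = 0.005,
) -> pd.DataFrame:
    """Observed spot tables: one row per (gel, channel, detected spot).

    Raw volume = true spot volume x channel gain x log-normal technical
    noise; detection is Bernoulli with probability logistic in log volume
    (weak spots vanish more often) and penalized in the pH 6-9 range.
    Observed positions carry small jitter, below the matching tolerance.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    samples_needed = {s for _g, _c, s in design.replicate_channels} | {design.is_sample}
    missing = samples_needed - set(abundances.columns) - {design.is_sample}
    # the IS pool is the mean of all sample columns unless provided explicitly
    if missing:
        raise ValueError(f"abundance table lacks sample column(s): {sorted(missing)}")

    truevol = {c: spot_map[c].to_numpy(dtype=float) for c in abundances.columns}
    if design.is_sample not in truevol:
        truevol[design.is_sample] = np.mean(
            [truevol[c] for c in abundances.columns], axis=0
        )
    n = len(spot_map)
    ph69 = spot_map["ph_range"].str.startswith("6").to_numpy()
    median_log = np.log(np.median(np.concatenate([v[v > 0] for v in truevol.values()])))
    rows = []
    for gel_id, channels in design.gels.items():
        for channel, sample in channels.items():
            gain = float(np.exp(gain_sigma * rng.standard_normal())) if gain_sigma > 0 else 1.0
            # sigma_tech_dige parameterizes the SA-level dispersion; SA divides two
            # independently noisy channel measurements, so each channel gets sigma/sqrt(2)
            sigma_ch = noise.sigma_tech_dige / np.sqrt(2.0)
            tech = (
                np.exp(sigma_ch * rng.standard_normal(n))
                if sigma_ch > 0
                else np.ones(n)
            )
            vols = truevol[sample] * gain * tech
            with np.errstate(divide="ignore"):
                logv = np.where(vols > 0, np.log(np.maximum(vols, 1e-300)), -np.inf)
            p = _detect_prob(logv, median_log, noise, ph69)
            p = np.where(vols > 0, p, 0.0)
            detected = rng.uniform(size=n) < p
            obs_pi = spot_map["pi"].to_numpy() + (
                pi_jitter * rng.standard_normal(n) if pi_jitter > 0 else 0.0
            )
            obs_mw = spot_map["mw_kda"].to_numpy() * np.exp(
                mw_rel_jitter * rng.standard_normal(n) if mw_rel_jitter > 0 else 0.0
            )
            sub = pd.DataFrame(
                {
                    "gel_id": gel_id,
                    "channel": channel,
                    "sample": sample,
                    "spot_id": spot_map.index,
                    "ph_range": spot_map["ph_range"].to_numpy(),
                    "pi": obs_pi,
                    "mw_kda": obs_mw,
                    "raw_volume": vols,
                }
            )[detected]
            rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def standardize_abundance(observations: pd.DataFrame, design: GelDesign) -> pd.DataFrame:
    """Add channel-normalized volumes and internal-standard SA values.

    ``norm_volume`` is the spot's share of its channel's total raw volume
    (within one gel and pH range); ``sa`` divides it by the same spot's
    normalized volume in the gel's IS channel. SA is NaN where the IS did not
    detect the spot; SA of the IS channel itself is exactly 1.
    """
    obs = observations.copy()
    totals = obs.groupby(["gel_id", "ph_range", "channel"])["raw_volume"].transform("sum")
    obs["norm_volume"] = obs["raw_volume"] / totals
    is_obs = obs[obs["channel"] == design.is_channel]
    is_norm = is_obs.set_index(["gel_id", "ph_range", "spot_id"])["norm_volume"]
    key = pd.MultiIndex.from_frame(obs[["gel_id", "ph_range", "spot_id"]])
    obs["sa"] = obs["norm_volume"].to_numpy() / is_norm.reindex(key).to_numpy()
    return obs


@dataclass
class MatchedSpotTable:
    """Cross-replicate matched spots with explicit missing entries.

    ``sa`` and ``norm_volume`` are spot x replicate matrices (NaN = missing);
    ``positions`` holds the master-spot coordinates; replicates are the
    design's non-IS channels labelled ``gel/channel``.
    """

    sa: pd.DataFrame
    norm_volume: pd.DataFrame
    positions: pd.DataFrame
    matched_truth: pd.DataFrame  # master spot -> ground-truth spot_id per replicate

    @property
    def fully_matched(self) -> pd.Series:
        return self.sa.notna().all(axis=1)

    def complete(self) -> pd.DataFrame:
        """The 100%-matched subset of the SA table."""
        return self.sa[self.fully_matched]


def match_spots(
    observations: pd.DataFrame,
    design: GelDesign,
    *,
    use_truth_ids: bool = False,
) -> MatchedSpotTable:
    """Match spots across replicates against a master list by (pI, MW).

    The first replicate (first gel, first non-IS channel) serves as master
    per pH range; every other replicate's spots are matched greedily to the
    nearest master spot within ``delta_pi`` / ``delta_mw_relative``, one to
    one, closest pairs first. With ``use_truth_ids`` the simulator's
    ground-truth spot ids short-circuit the geometry (for oracle checks).
    """
    reps = [(g, c) for g, c, _s in design.replicate_channels]
    if len(reps) < 2:
        raise ValueError("matching needs at least two replicates")
    rep_label = {(g, c): f"{g}/{c}" for g, c in reps}
    sa_cols: dict[str, pd.Series] = {}
    nv_cols: dict[str, pd.Series] = {}
    truth_cols: dict[str, pd.Series] = {}
    pos_frames = []

    for ph, obs_ph in observations.groupby("ph_range"):
        master_gel, master_ch = reps[0]
        master = obs_ph[(obs_ph["gel_id"] == master_gel) & (obs_ph["channel"] == master_ch)]
        master = master.reset_index(drop=True)
        master_ids = ph + "|" + master["spot_id"].astype(str)
        pos_frames.append(
            pd.DataFrame(
                {"pi": master["pi"].to_numpy(), "mw_kda": master["mw_kda"].to_numpy(),
                 "ph_range": ph},
                index=master_ids,
            )
        )
        scale_pi = design.delta_pi
        master_xy = np.column_stack(
            [master["pi"] / scale_pi, np.log(master["mw_kda"]) / design.delta_mw_relative]
        )
        tree = cKDTree(master_xy)
        for gel, ch in reps:
            lbl = rep_label[(gel, ch)]
            rep_obs = obs_ph[(obs_ph["gel_id"] == gel) & (obs_ph["channel"] == ch)]
            rep_obs = rep_obs.reset_index(drop=True)
            if use_truth_ids:
                merged = master.merge(
                    rep_obs, on="spot_id", how="left", suffixes=("", "_r")
                )
                sa_vals = merged["sa_r"].to_numpy()
                nv_vals = merged["norm_volume_r"].to_numpy()
                tid = merged["spot_id"].where(merged["sa_r"].notna())
            else:
                xy = np.column_stack(
                    [rep_obs["pi"] / scale_pi, np.log(rep_obs["mw_kda"]) / design.delta_mw_relative]
                )
                dist, idx = tree.query(xy, distance_upper_bound=1.0)
                pairs = sorted(
                    (d, j, i) for j, (d, i) in enumerate(zip(dist, idx)) if np.isfinite(d)
                )
                assign = np.full(len(master), -1, dtype=int)
                used_rep: set[int] = set()
                for d, j, i in pairs:
                    if assign[i] < 0 and j not in used_rep:
                        assign[i] = j
                        used_rep.add(j)
                sa_vals = np.full(len(master), np.nan)
                nv_vals = np.full(len(master), np.nan)
                tid = pd.Series([None] * len(master))
                hit = assign >= 0
                sa_vals[hit] = rep_obs["sa"].to_numpy()[assign[hit]]
                nv_vals[hit] = rep_obs["norm_volume"].to_numpy()[assign[hit]]
                tid[hit] = rep_obs["spot_id"].to_numpy()[assign[hit]]
            sa_cols.setdefault(lbl, pd.Series(dtype=float))
            nv_cols.setdefault(lbl, pd.Series(dtype=float))
            truth_cols.setdefault(lbl, pd.Series(dtype=object))
            sa_cols[lbl] = pd.concat([sa_cols[lbl], pd.Series(sa_vals, index=master_ids)])
            nv_cols[lbl] = pd.concat([nv_cols[lbl], pd.Series(nv_vals, index=master_ids)])
            truth_cols[lbl] = pd.concat(
                [truth_cols[lbl], pd.Series(tid.to_numpy(), index=master_ids)]
            )
    positions = pd.concat(pos_frames)
    return MatchedSpotTable(
        sa=pd.DataFrame(sa_cols),
        norm_volume=pd.DataFrame(nv_cols),
        positions=positions,
        matched_truth=pd.DataFrame(truth_cols),
    )


def reconstruct_spot_volume(matched: MatchedSpotTable) -> pd.Series:
    """Representative spot volume: mean normalized volume over all replicates.

    Computed only for 100%-matched spots; spots with any missing replicate
    are excluded rather than imputed.
    """
    nv = matched.norm_volume[matched.fully_matched]
    return nv.mean(axis=1)


def simulate_ppase_contrast(
    model: ProteomeModel,
    noise: NoiseModel | None = None,
    efficiency: float = 1.0,
    seed: int = 0,
    design: GelDesign | None = None,
) -> pd.DataFrame:
    """Paired untreated/treated spot volumes for phosphatase classification.

    The treated channel is generated from the dephosphorylated model; spots
    are laid out on the union of both models' proteoform positions so each
    position yields an (untreated, treated) volume pair after SA-equivalent
    correction (channel gains cancel). Technical noise multiplies each
    channel independently. Ground-truth phospho status and abundance-weighted
    occupancy ride along for validation.
    """
    noise = noise or NoiseModel()
    design = design or GelDesign(gels={"gel1": {"Cy3": "U", "Cy5": "T", IS_CHANNEL: "IS"}})
    treated = dephosphorylate(model, efficiency)

    def _frame(m: ProteomeModel, col: str) -> pd.DataFrame:
        f = m.proteoform_frame()
        f = (
            f.groupby(["proteoform_id", "parent_accession", "pi", "mw_kda"], as_index=False)
            .agg(
                base_abundance=("base_abundance", "sum"),
                is_phospho=("is_phospho", "any"),
                phospho_occupancy=("phospho_occupancy", "max"),
            )
        )
        f[col] = f["base_abundance"]
        return f

    fu = _frame(model, "vol_untreated")
    ft = _frame(treated, "vol_treated")
    # union of positions: outer merge on exact (pi, mw) via the cluster pass
    allpos = pd.concat(
        [
            fu.assign(_side="U", _vol=fu["vol_untreated"]),
            ft.assign(_side="T", _vol=ft["vol_treated"]),
        ],
        ignore_index=True,
    )
    labels = _cluster_positions(
        allpos["pi"].to_numpy(),
        allpos["mw_kda"].to_numpy(),
        design.delta_pi,
        design.delta_mw_relative,
    )
    allpos["_label"] = labels
    rng = np.random.default_rng(seed)
    rows = []
    for lab, grp in allpos.groupby("_label"):
        vu = float(grp.loc[grp["_side"] == "U", "_vol"].sum())
        vt = float(grp.loc[grp["_side"] == "T", "_vol"].sum())
        w = grp["_vol"].to_numpy()
        wsum = w.sum()
        occ = grp.loc[grp["_side"] == "U", "phospho_occupancy"]
        occ_max = float(occ.max()) if len(occ) and np.isfinite(occ.max()) else 0.0
        rows.append(
            {
                "spot_id": f"pp_s{lab}",
                "pi": float(np.average(grp["pi"], weights=w) if wsum > 0 else grp["pi"].mean()),
                "mw_kda": float(np.average(grp["mw_kda"], weights=w) if wsum > 0 else grp["mw_kda"].mean()),
                "vol_untreated": vu,
                "vol_treated": vt,
                "true_phospho": bool(grp.loc[grp["_side"] == "U", "is_phospho"].any()),
                "true_occupancy": occ_max,
                "n_untreated_members": int((grp["_side"] == "U").sum()),
                "n_treated_members": int((grp["_side"] == "T").sum()),
            }
        )
    out = pd.DataFrame(rows).set_index("spot_id")
    sigma_ch = noise.sigma_tech_dige / np.sqrt(2.0)
    if sigma_ch > 0:
        out["vol_untreated"] *= np.exp(sigma_ch * rng.standard_normal(len(out)))
        out["vol_treated"] *= np.exp(sigma_ch * rng.standard_normal(len(out)))
    return out
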