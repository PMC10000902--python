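"""2D-DIGE simulator: spot formation, SA normalization, matching, phosphatase pairs."""

import numpy as np
import pandas as pd
import pytest

from proteoformsim import dige
from proteoformsim.dige import (
    GelDesign,
    form_spots,
    match_spots,
    reconstruct_spot_volume,
    simulate_gels,
    simulate_ppase_contrast,
    standardize_abundance,
    technical_replicate_design,
)
from proteoformsim.proteome import NoiseModel, ProteomeConfig, generate_proteome


def _noise_free():
    return NoiseModel(
        sigma_tech_dige=0.0,
        dige_detect_floor=1.0,
        ph69_detect_penalty=1.0,
    )


def _frame(rows):
    return pd.DataFrame(
        rows,
        columns=["proteoform_id", "parent_accession", "pi", "mw_kda", "base_abundance"],
    )


def test_identical_positions_merge_into_one_spot():
    pf = _frame([("a", "P1", 5.0, 50.0, 10.0), ("b", "P1", 5.0, 50.0, 5.0)])
    ab = pd.DataFrame({"IS": [10.0, 5.0]}, index=["a", "b"])
    design = technical_replicate_design(n_gels=1)
    spots = form_spots(pf, ab, design)
    assert len(spots) == 1
    assert spots.iloc[0]["IS"] == pytest.approx(15.0)
    assert set(spots.iloc[0]["proteoform_ids"]) == {"a", "b"}


def test_well_separated_forms_stay_distinct():
    pf = _frame(
        [("a", "P1", 4.5, 50.0, 1.0), ("b", "P1", 5.5, 50.0, 1.0), ("c", "P2", 6.5, 20.0, 1.0)]
    )
    ab = pd.DataFrame({"IS": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
    spots = form_spots(pf, ab, technical_replicate_design(n_gels=1))
    # pH 4-7 holds all three; the 6-9 range re-hosts only the pI 6.5 form
    assert (spots["ph_range"] == "4-7").sum() == 3
    assert (spots["ph_range"] == "6-9").sum() == 1


def test_out_of_range_proteoforms_dropped():
    pf = _frame([("a", "P1", 3.0, 50.0, 1.0), ("b", "P2", 5.0, 50.0, 1.0)])
    ab = pd.DataFrame({"IS": [1.0, 1.0]}, index=["a", "b"])
    spots = form_spots(pf, ab, technical_replicate_design(n_gels=1))
    members = {m for t in spots["proteoform_ids"] for m in t}
    assert members == {"b"}


def test_zero_noise_full_detection_recovers_true_volumes(small_model, base_abundances):
    design = technical_replicate_design(n_gels=1)
    spots = form_spots(small_model, base_abundances, design)
    obs = simulate_gels(
        spots, base_abundances, design, _noise_free(), seed=0,
        gain_sigma=0.0, pi_jitter=0.0, mw_rel_jitter=0.0,
    )
    one = obs[(obs.gel_id == "gel1") & (obs.channel == "Cy3")].set_index("spot_id")
    assert np.allclose(one.loc[spots.index, "raw_volume"], spots["IS"])
    # conservation: total observed volume equals total in-range true abundance
    assert one["raw_volume"].sum() == pytest.approx(spots["IS"].sum(), rel=1e-9)


def test_channel_gain_cancels_in_normalized_volume(small_model, base_abundances):
    design = technical_replicate_design(n_gels=1)
    spots = form_spots(small_model, base_abundances, design)
    kw = dict(gain_sigma=0.0, pi_jitter=0.0, mw_rel_jitter=0.0)
    obs = simulate_gels(spots, base_abundances, design, _noise_free(), seed=0, **kw)
    obs = standardize_abundance(obs, design)
    scaled = obs.copy()
    mask = scaled["channel"] == "Cy3"
    scaled.loc[mask, "raw_volume"] *= 37.5
    scaled = standardize_abundance(scaled.drop(columns=["norm_volume", "sa"]), design)
    pd.testing.assert_series_equal(obs["norm_volume"], scaled["norm_volume"])
    pd.testing.assert_series_equal(obs["sa"], scaled["sa"])


def test_sa_of_is_channel_is_exactly_one(small_model, base_abundances):
    design = technical_replicate_design(n_gels=2)
    spots = form_spots(small_model, base_abundances, design)
    obs = standardize_abundance(
        simulate_gels(spots, base_abundances, design, NoiseModel(), seed=4), design
    )
    is_sa = obs.loc[obs["channel"] == design.is_channel, "sa"]
    assert np.allclose(is_sa, 1.0)


def test_sa_direct_ratio():
    # spot with normalized volumes 0.002 (sample) vs 0.001 (IS) -> SA = 2
    obs = pd.DataFrame(
        {
            "gel_id": ["g1"] * 4,
            "ph_range": ["4-7"] * 4,
            "channel": ["Cy3", "Cy3", "Cy2", "Cy2"],
            "spot_id": ["s1", "s2", "s1", "s2"],
            "raw_volume": [2.0, 998.0, 1.0, 999.0],
        }
    )
    design = GelDesign(gels={"g1": {"Cy3": "A", "Cy2": "IS"}})
    out = standardize_abundance(obs, design)
    sa = out[(out.channel == "Cy3") & (out.spot_id == "s1")]["sa"].iloc[0]
    assert sa == pytest.approx(0.002 / 0.001)


def test_missing_is_spot_propagates_as_missing():
    obs = pd.DataFrame(
        {
            "gel_id": ["g1"] * 3,
            "ph_range": ["4-7"] * 3,
            "channel": ["Cy3", "Cy3", "Cy2"],
            "spot_id": ["s1", "s2", "s2"],
            "raw_volume": [5.0, 5.0, 4.0],
        }
    )
    design = GelDesign(gels={"g1": {"Cy3": "A", "Cy2": "IS"}})
    out = standardize_abundance(obs, design)
    assert np.isnan(out[(out.channel == "Cy3") & (out.spot_id == "s1")]["sa"].iloc[0])


def test_matching_recovers_truth_under_small_jitter(small_model, base_abundances):
    design = technical_replicate_design(n_gels=3)
    spots = form_spots(small_model, base_abundances, design)
    obs = simulate_gels(
        spots, base_abundances, design, _noise_free(), seed=11,
        gain_sigma=0.1, pi_jitter=0.005, mw_rel_jitter=0.002,
    )
    obs = standardize_abundance(obs, design)
    matched = match_spots(obs, design)
    truth = matched.matched_truth
    master_truth = truth.iloc[:, 0]
    agree = (truth.apply(lambda col: col == master_truth).to_numpy()).mean()
    assert agree >= 0.99
    assert matched.fully_matched.all()


def test_unmatched_spot_excluded_from_complete_subset(small_model, base_abundances):
    design = technical_replicate_design(n_gels=3)
    spots = form_spots(small_model, base_abundances, design)
    obs = standardize_abundance(
        simulate_gels(
            spots, base_abundances, design, _noise_free(), seed=2,
            gain_sigma=0.0, pi_jitter=0.0, mw_rel_jitter=0.0,
        ),
        design,
    )
    # drop one spot from one replicate
    victim = obs[(obs.gel_id == "gel2") & (obs.channel == "Cy5")].index[0]
    vid = obs.loc[victim, "spot_id"]
    obs = obs.drop(index=victim)
    matched = match_spots(obs, design, use_truth_ids=True)
    incomplete = matched.sa[~matched.fully_matched]
    assert len(incomplete) == 1
    assert incomplete.index[0].endswith(vid)


def test_reconstruct_spot_volume_mean():
    sa = pd.DataFrame({"r1": [1.0], "r2": [1.0], "r3": [1.0]}, index=["s"])
    nv = pd.DataFrame({"r1": [1.0], "r2": [2.0], "r3": [3.0]}, index=["s"])
    pos = pd.DataFrame({"pi": [5.0], "mw_kda": [50.0], "ph_range": ["4-7"]}, index=["s"])
    m = dige.MatchedSpotTable(sa=sa, norm_volume=nv, positions=pos, matched_truth=sa)
    assert reconstruct_spot_volume(m)["s"] == pytest.approx(2.0)


def test_median_cv_increases_with_sigma(small_model, base_abundances):
    design = technical_replicate_design(n_gels=3)
    spots = form_spots(small_model, base_abundances, design)
    medians = []
    for sigma in (0.02, 0.08, 0.25):
        noise = NoiseModel(sigma_tech_dige=sigma, dige_detect_floor=1.0)
        obs = standardize_abundance(
            simulate_gels(spots, base_abundances, design, noise, seed=13), design
        )
        matched = match_spots(obs, design, use_truth_ids=True)
        comp = matched.complete()
        cv = 100 * comp.std(axis=1, ddof=1) / comp.mean(axis=1)
        medians.append(cv.median())
    assert medians[0] < medians[1] < medians[2]


def test_more_entities_than_parent_proteins(small_model, base_abundances):
    # top-down resolves proteoforms: 2D entity count >= protein count in range
    design = technical_replicate_design(n_gels=1)
    spots = form_spots(small_model, base_abundances, design)
    in_47 = spots[spots["ph_range"] == "4-7"]
    parents = {a for t in in_47["parent_accessions"] for a in t}
    assert len(in_47) >= len(parents)


# ---------------------------------------------------- phosphatase contrast


def test_ppase_contrast_phospho_free_ratio_one():
    model = generate_proteome(ProteomeConfig(n_proteins=30, phospho_fraction=0.0), seed=6)
    pairs = simulate_ppase_contrast(model, _noise_free(), 1.0, seed=1)
    ratio = pairs["vol_untreated"] / pairs["vol_treated"]
    assert np.allclose(ratio, 1.0)


def test_ppase_contrast_full_occupancy_fully_shifts():
    from proteoformsim.proteome import ProteomeModel, Proteoform

    seq = "ACDEFGSKRLMNPQRSTVWYKK"
    pf = Proteoform("A.1", "A", seq, ((6, "phospho", 1.0),), 4.8, 2.4, 100.0)
    base = Proteoform("A.0", "A", seq, (), 6.0, 2.4, 50.0)
    model = ProteomeModel({"A": seq}, [base, pf], ProteomeConfig(n_proteins=1))
    pairs = simulate_ppase_contrast(model, _noise_free(), 1.0, seed=1)
    phospho_spot = pairs[pairs["true_phospho"]]
    assert len(phospho_spot) == 1
    assert phospho_spot["vol_treated"].iloc[0] == pytest.approx(0.0)
    # all mass arrives at the unmodified position
    unmod = pairs[~pairs["true_phospho"]]
    assert unmod["vol_treated"].sum() == pytest.approx(150.0)


def test_ppase_contrast_conserves_parent_totals(small_model):
    pairs = simulate_ppase_contrast(small_model, _noise_free(), 1.0, seed=2)
    assert pairs["vol_treated"].sum() == pytest.approx(
        pairs["vol_untreated"].sum(), rel=1e-9
    )


def test_design_validation():
    with pytest.raises(ValueError):
        GelDesign(gels={"g": {"Cy3": "A"}})  # no IS channel
    with pytest.raises(ValueError):
        GelDesign(gels={"g": {"Cy2": "IS"}}, ph_ranges=((7.0, 4.0),))
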