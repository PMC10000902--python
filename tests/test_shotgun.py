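"""Shotgun simulator: peptide pools, protein inference, LFQ, iBAQ, phospho sets."""

import numpy as np
import pandas as pd
import pytest

from proteoformsim.proteome import ProteomeConfig, ProteomeModel, Proteoform, NoiseModel
from proteoformsim.shotgun import (
    ShotgunParams,
    compute_ibaq,
    compute_lfq,
    infer_protein_groups,
    phosphosite_accounting,
    simulate_runs,
)


def _noise_free_params():
    params = ShotgunParams(ionization_sigma=0.0, protein_noise_share=0.0)
    noise = NoiseModel(
        sigma_tech_shotgun=0.0, shotgun_detect_floor=1.0, phospho_detection_penalty=1.0
    )
    return params, noise


def _toy_model(proteoforms, proteins):
    return ProteomeModel(proteins, proteoforms, ProteomeConfig(n_proteins=len(proteins)))


def _base_table(model):
    return pd.DataFrame(
        {"r1": [p.base_abundance for p in model.proteoforms]},
        index=[p.proteoform_id for p in model.proteoforms],
    )


SEQ_A = "AAAAAAKCCCCCCCKDDDDDDDK"  # three measurable tryptic peptides


def test_noise_free_intensity_equals_parent_abundance():
    pf = Proteoform("A.0", "A", SEQ_A, (), 5.0, 2.0, 42.0)
    model = _toy_model([pf], {"A": SEQ_A})
    params, noise = _noise_free_params()
    params.max_missed_cleavages = 0
    peps = simulate_runs(model, _base_table(model), params, noise, seed=0)
    assert len(peps) == 3
    assert np.allclose(peps["intensity"], 42.0)


def test_shared_peptide_sums_full_length_and_truncation():
    full = Proteoform("A.0", "A", SEQ_A, (), 5.0, 2.0, 10.0)
    trunc = Proteoform("A.1", "A", SEQ_A[:15], (), 5.2, 1.3, 4.0, truncation=(0, 15))
    model = _toy_model([full, trunc], {"A": SEQ_A})
    params, noise = _noise_free_params()
    params.max_missed_cleavages = 0
    peps = simulate_runs(model, _base_table(model), params, noise, seed=0)
    by_seq = peps.set_index("sequence")["intensity"]
    assert by_seq["AAAAAAK"] == pytest.approx(14.0)  # shared by both forms
    assert by_seq["DDDDDDDK"] == pytest.approx(10.0)  # full-length only


def test_occupancy_splits_phosphopeptide_intensity():
    site = SEQ_A.index("C")  # make one site phosphorylatable via S instead
    seq = "AAASAAKCCCCCCCK"
    pf = Proteoform("A.0", "A", seq, ((3, "phospho", 0.25),), 5.0, 1.5, 100.0)
    model = _toy_model([pf], {"A": seq})
    params, noise = _noise_free_params()
    params.max_missed_cleavages = 0
    peps = simulate_runs(model, _base_table(model), params, noise, seed=0)
    mod = peps[peps["phospho_site"] >= 0].set_index("sequence")["intensity"]
    unmod = peps[peps["phospho_site"] < 0].set_index("sequence")["intensity"]
    assert mod["AAASAAK"] == pytest.approx(25.0)
    assert unmod["AAASAAK"] == pytest.approx(75.0)


def test_proteoform_collapse_to_canonical_groups(small_model, base_abundances):
    params, noise = _noise_free_params()
    peps = simulate_runs(
        small_model, base_abundances.rename(columns={"IS": "r1"}), params, noise, seed=0
    )
    groups = infer_protein_groups(peps)
    assert groups["accession"].nunique() == len(small_model.proteins)
    assert groups["accession"].nunique() <= small_model.n_proteoforms
    multi = (
        small_model.proteoform_frame().groupby("parent_accession").size().max()
    )
    assert multi > 1  # the collapse actually erased proteoform structure


def test_group_peptide_count_is_distinct_sequences():
    pf = Proteoform("A.0", "A", SEQ_A, (), 5.0, 2.0, 10.0)
    model = _toy_model([pf], {"A": SEQ_A})
    params, noise = _noise_free_params()
    peps = simulate_runs(model, _base_table(model), params, noise, seed=0)
    groups = infer_protein_groups(peps)
    assert groups["n_peptides"].iloc[0] == peps["sequence"].nunique()


def test_shared_peptide_assignment_matches_maximal_evidence():
    # toy: B's only peptide also occurs in A, which has more distinct evidence
    obs = pd.DataFrame(
        {
            "run_id": ["r1"] * 4,
            "sequence": ["PEPTIDEK", "AAAAAAK", "CCCCCCK", "PEPTIDEK"],
            "phospho_site": [-1, -1, -1, -1],
            "accession": ["A", "A", "A", "B"],
            "intensity": [10.0, 5.0, 5.0, 10.0],
            "localization_prob": [np.nan] * 4,
            "proteoform_ids": [("A.0",), ("A.0",), ("A.0",), ("B.0",)],
        }
    )
    groups = infer_protein_groups(obs)
    # brute force over assignments: A keeps 3 distinct peptides, B would keep 1
    assert set(groups["accession"]) == {"A"}
    assert groups.loc[groups["accession"] == "A", "n_peptides"].iloc[0] == 3


def test_lfq_single_run_is_plain_sum():
    groups = pd.DataFrame(
        {"run_id": ["r1", "r1"], "accession": ["A", "B"], "intensity_sum": [30.0, 12.0]}
    )
    lfq = compute_lfq(groups)
    assert lfq.loc["A", "r1"] == pytest.approx(30.0)


def test_lfq_normalization_removes_global_scaling():
    groups = pd.DataFrame(
        {
            "run_id": ["r1"] * 3 + ["r2"] * 3,
            "accession": ["A", "B", "C"] * 2,
            "intensity_sum": [10.0, 20.0, 30.0, 100.0, 200.0, 300.0],
        }
    )
    lfq = compute_lfq(groups)
    pd.testing.assert_series_equal(
        lfq["r1"], lfq["r2"], check_names=False
    )


def test_lfq_two_run_median_ratio_hand_example():
    # hand computation: ratios ref/run2 = {10/8, 20/10, 30/40} -> median 1.25
    groups = pd.DataFrame(
        {
            "run_id": ["r1"] * 3 + ["r2"] * 3,
            "accession": ["A", "B", "C"] * 2,
            "intensity_sum": [10.0, 20.0, 30.0, 8.0, 10.0, 40.0],
        }
    )
    lfq = compute_lfq(groups)
    assert lfq.loc["A", "r2"] == pytest.approx(8.0 * 1.25)
    assert lfq.loc["C", "r2"] == pytest.approx(40.0 * 1.25)


def test_ibaq_definition_and_missing_denominator():
    seq = SEQ_A  # 3 theoretical peptides within 6-30 residues
    model = _toy_model([Proteoform("A.0", "A", seq, (), 5.0, 2.0, 1.0)], {"A": seq})
    groups = pd.DataFrame(
        {"run_id": ["r1"], "accession": ["A"], "intensity_sum": [30.0]}
    )
    out = compute_ibaq(groups, model)
    assert out["theoretical_peptides"].iloc[0] == 3
    assert out["ibaq"].iloc[0] == pytest.approx(10.0)
    # a protein with no measurable peptide -> missing iBAQ
    short_model = _toy_model(
        [Proteoform("B.0", "B", "AAAK", (), 5.0, 0.4, 1.0)], {"B": "AAAK"}
    )
    out2 = compute_ibaq(
        pd.DataFrame({"run_id": ["r1"], "accession": ["B"], "intensity_sum": [7.0]}),
        short_model,
    )
    assert np.isnan(out2["ibaq"].iloc[0])


def test_ibaq_never_exceeds_intensity_sum(small_model, base_abundances):
    params, noise = _noise_free_params()
    peps = simulate_runs(
        small_model, base_abundances.rename(columns={"IS": "r1"}), params, noise, seed=0
    )
    out = compute_ibaq(infer_protein_groups(peps), small_model)
    ok = out.dropna(subset=["ibaq"])
    assert (ok["ibaq"] <= ok["intensity_sum"] + 1e-9).all()


def test_phosphosite_accounting_set_algebra():
    def mk(rows):
        return pd.DataFrame(
            rows,
            columns=["run_id", "sequence", "phospho_site", "accession", "intensity", "localization_prob"],
        )

    u = mk([("r1", "PEPSK", 3, "A", 5.0, 0.9), ("r1", "TTTTK", 0, "B", 2.0, 0.9)])
    t = mk([("r1", "PEPSK", 3, "A", 1.0, 0.9), ("r1", "YYYYK", 0, "C", 3.0, 0.9)])
    res = phosphosite_accounting(u, t)
    assert res["peptide_overlap"] == {"only_untreated": 1, "both": 1, "only_treated": 1}
    assert res["protein_overlap"]["both"] == 1
    # disjoint sets -> zero overlap; identical sets -> full overlap
    res2 = phosphosite_accounting(u, mk([("r1", "QQQSK", 3, "D", 1.0, 0.9)]))
    assert res2["peptide_overlap"]["both"] == 0
    res3 = phosphosite_accounting(u, u)
    assert res3["peptide_overlap"]["both"] == res3["untreated"]["localized_quantified"]


def test_low_localization_confidence_not_counted():
    u = pd.DataFrame(
        {
            "run_id": ["r1"],
            "sequence": ["PEPSK"],
            "phospho_site": [3],
            "accession": ["A"],
            "intensity": [5.0],
            "localization_prob": [0.5],  # below the 0.75 threshold
        }
    )
    res = phosphosite_accounting(u, u.iloc[:0])
    assert res["untreated"]["detected"] == 1
    assert res["untreated"]["localized_quantified"] == 0


def test_detection_midpoint_controls_missingness(small_model, base_abundances):
    runs = base_abundances.rename(columns={"IS": "r1"})
    params = ShotgunParams(ionization_sigma=0.0)
    rates = []
    for mid in (2.0, 0.0, -2.0):
        noise = NoiseModel(sigma_tech_shotgun=0.0, shotgun_detect_midpoint=mid)
        peps = simulate_runs(small_model, runs, params, noise, seed=5)
        rates.append(len(peps))
    assert rates[0] < rates[1] < rates[2]
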