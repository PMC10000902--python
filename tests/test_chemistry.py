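"""Sequence chemistry: masses, charge curves, pI root-finding, digestion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proteoformsim import chemistry
from proteoformsim.chemistry import (
    AMINO_ACIDS,
    DigestRule,
    InvalidSequenceError,
    LYSC,
    ModificationPlacementError,
    TRYPSIN,
    digest,
    isoelectric_point,
    load_default_chemistry,
    molecular_weight,
    net_charge,
    theoretical_peptide_count,
)

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


# ---------------------------------------------------------------- mass


def test_molecular_weight_hand_sums():
    # hand sums over the shipped residue-mass table: G=57.0519, water=18.0153
    assert molecular_weight("G") == pytest.approx(75.0672, abs=0.01)
    assert molecular_weight("GG") == pytest.approx(132.1191, abs=0.01)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seq=st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=80), data=st.data())
def test_mass_additivity_under_cleavage(seq, data):
    k = data.draw(st.integers(min_value=1, max_value=len(seq) - 1))
    water = load_default_chemistry().water_mass[0]
    lhs = molecular_weight(seq[:k]) + molecular_weight(seq[k:]) - water
    assert lhs == pytest.approx(molecular_weight(seq), rel=1e-6)


def test_phospho_mass_delta_about_80():
    delta = molecular_weight("ASA", [(1, "phospho")]) - molecular_weight("ASA")
    assert delta == pytest.approx(79.98, abs=0.05)


def test_invalid_sequence_and_placement():
    with pytest.raises(InvalidSequenceError):
        molecular_weight("")
    with pytest.raises(InvalidSequenceError):
        molecular_weight("AXZ")
    with pytest.raises(ModificationPlacementError):
        molecular_weight("AS", [(5, "phospho")])
    with pytest.raises(ModificationPlacementError):
        molecular_weight("AA", [(1, "phospho")])  # A is not phosphorylatable


# ---------------------------------------------------------------- charge / pI


def test_charge_limit_cases():
    # fully protonated at pH 0: one positive per K/R/H plus the N-terminus
    assert net_charge("AKAHARA", pH=0.0) == pytest.approx(4.0, abs=1e-3)
    # fully deprotonated at pH 14: three E side chains plus the C-terminus
    assert net_charge("EEE", pH=14.0) == pytest.approx(-4.0, abs=1e-3)


def test_charge_strictly_decreasing_in_ph(rng):
    for _ in range(10):
        n = rng.integers(3, 40)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        grid = np.linspace(0, 14, 200)
        charges = np.array([net_charge(seq, pH=p) for p in grid])
        assert np.all(np.diff(charges) < 0)


def _grid_pi_oracle(seq, mods=()):
    """Dense-grid zero crossing of the charge curve (independent oracle)."""
    grid = np.arange(0.0, 14.0001, 1e-4)
    chem = load_default_chemistry()
    groups = chemistry._charge_groups(seq, list(mods), chem)
    q = np.zeros_like(grid)
    for pol, pka, cnt in groups:
        if pol == "base":
            q += cnt / (1.0 + 10.0 ** (grid - pka))
        else:
            q -= cnt / (1.0 + 10.0 ** (pka - grid))
    return float(grid[np.argmin(np.abs(q))])


def test_pi_bisection_matches_grid_oracle(rng):
    for _ in range(100):
        n = rng.integers(5, 60)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        assert isoelectric_point(seq) == pytest.approx(_grid_pi_oracle(seq), abs=1e-3)


def test_pi_basic_exceeds_acidic():
    assert isoelectric_point("KKK") > isoelectric_point("EEE")


def test_phospho_never_raises_pi(rng):
    for _ in range(25):
        n = rng.integers(8, 60)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        sites = [i for i, aa in enumerate(seq) if aa in "STY"]
        if not sites:
            continue
        site = int(rng.choice(sites))
        pi_mod = isoelectric_point(seq, [(site, "phospho")])
        assert pi_mod < isoelectric_point(seq) + 1e-9
        assert pi_mod == pytest.approx(_grid_pi_oracle(seq, [(site, "phospho")]), abs=1e-3)


def test_charge_near_zero_at_pi(rng):
    for _ in range(20):
        n = rng.integers(5, 50)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        pi = isoelectric_point(seq)
        if 0.0 < pi < 14.0:
            assert abs(net_charge(seq, pH=pi)) < 1e-4


# ---------------------------------------------------------------- digestion


@pytest.mark.parametrize(
    "seq,rule,missed,expected",
    [
        ("AAAA", TRYPSIN, 0, ["AAAA"]),
        ("AKRPCKR", TRYPSIN, 0, ["AK", "RPCK", "R"]),  # R before P not cleaved
        ("AKCK", TRYPSIN, 1, ["AK", "AKCK", "CK"]),
        ("ARCK", LYSC, 0, ["ARCK"]),  # Lys-C ignores R
    ],
)
def test_digest_examples(seq, rule, missed, expected):
    got = sorted({p.sequence for p in digest(seq, rule, max_missed=missed)})
    assert got == sorted(set(expected))


def _exhaustive_fragments(seq, max_missed):
    """Oracle: enumerate all cut-site subsets by the stated trypsin rule."""
    sites = [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in "KR" and seq[i] != "P"
    ]
    bounds = [0] + sites + [len(seq)]
    frags = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            frags.add((bounds[i], bounds[j], j - i - 1))
    return {(seq[s:e], m) for s, e, m in frags}


@settings(deadline=None, max_examples=80, derandomize=True)
@given(seq=seq_strategy, missed=st.integers(min_value=0, max_value=3))
def test_digest_matches_exhaustive_enumeration(seq, missed):
    got = {(p.sequence, p.missed_cleavages) for p in digest(seq, TRYPSIN, max_missed=missed)}
    assert got == _exhaustive_fragments(seq, missed)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seq=seq_strategy)
def test_zero_missed_peptides_tile_sequence(seq):
    parts = [p.sequence for p in digest(seq, TRYPSIN, max_missed=0)]
    assert "".join(parts) == seq


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("AAAA", 0),  # single 4-mer below the 6-residue floor
        ("AAAAAAKCCCCCCC", 2),  # AAAAAAK and CCCCCCC both measurable
    ],
)
def test_theoretical_peptide_count(seq, expected):
    assert theoretical_peptide_count(seq, TRYPSIN) == expected


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seq=seq_strategy)
def test_theoretical_count_bounded_by_fragments(seq):
    n_frag = len(digest(seq, TRYPSIN, max_missed=0))
    assert 0 <= theoretical_peptide_count(seq, TRYPSIN) <= n_frag


def test_digest_rule_validation():
    with pytest.raises(ValueError):
        DigestRule("bad", frozenset("K"), peptide_length_bounds=(0, 5))
    with pytest.raises(ValueError):
        DigestRule("bad", frozenset("K"), peptide_length_bounds=(10, 5))
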