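"""Sequence-level physico-chemical computation.

Molecular weight by residue-mass summation, net charge and isoelectric point
via Henderson-Hasselbalch with the Bjellqvist pKa table, and rule-based
proteolytic digestion (trypsin, Lys-C). These primitives position intact
proteoforms on a 2D gel (pI x MW) and turn them into peptides on the shotgun
side, so both measurement simulators are built on this module.

The residue masses, ionizable-group pKas and modification deltas are shipped
as plain-text TSV tables under ``proteoformsim/data`` so they are auditable
and swappable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "AMINO_ACIDS",
    "ResidueChemistry",
    "DigestRule",
    "TRYPSIN",
    "LYSC",
    "Peptide",
    "InvalidSequenceError",
    "ModificationPlacementError",
    "load_default_chemistry",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "digest",
    "theoretical_peptide_count",
    "read_fasta",
]


class InvalidSequenceError(ValueError):
    """Sequence empty or containing letters outside the 20-residue alphabet."""


class ModificationPlacementError(ValueError):
    """Modification site index outside the sequence, or residue not modifiable."""


@dataclass(frozen=True)
class Modification:
    name: str
    mass_delta_average: float
    mass_delta_mono: float
    adds_groups: tuple[str, ...]
    removes_site_group: bool
    allowed_residues: str  # e.g. "STY"; "nterm" handled separately


@dataclass(frozen=True)
class ResidueChemistry:
    """Residue masses, ionizable groups and modification chemistry.

    ``residue_masses`` maps residue letter to (average, monoisotopic) mass in
    Da; ``ionizable_groups`` maps group name to (polarity, pKa) where polarity
    is "acid" or "base"; ``modifications`` maps modification name to its
    :class:`Modification` record.
    """

    residue_masses: dict[str, tuple[float, float]]
    water_mass: tuple[float, float]
    ionizable_groups: dict[str, tuple[str, float]]
    modifications: dict[str, Modification]

    def __post_init__(self) -> None:
        for aa, (avg, mono) in self.residue_masses.items():
            if avg <= 0 or mono <= 0:
                raise ValueError(f"non-positive mass for residue {aa!r}")
        if not (17.9 < self.water_mass[0] < 18.1):
            raise ValueError("water mass must be ~18.02 Da on the average scale")
        for grp, (pol, pka) in self.ionizable_groups.items():
            if pol not in ("acid", "base"):
                raise ValueError(f"bad polarity for group {grp!r}: {pol!r}")
            if not (0.0 < pka < 14.0):
                raise ValueError(f"pKa of group {grp!r} outside (0, 14)")


def _read_data_tsv(name: str) -> list[list[str]]:
    with resources.files("proteoformsim.data").joinpath(name).open() as fh:
        rows = []
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            rows.append(cells)
    return rows


@lru_cache(maxsize=1)
def load_default_chemistry() -> ResidueChemistry:
    """Load the packaged residue-chemistry tables (cached)."""
    masses: dict[str, tuple[float, float]] = {}
    water = (18.0153, 18.010565)
    for aa, avg, mono in _read_data_tsv("residue_masses.tsv"):
        if aa == "water":
            water = (float(avg), float(mono))
        else:
            masses[aa] = (float(avg), float(mono))
    groups = {
        grp: (pol, float(pka))
        for grp, pol, pka in _read_data_tsv("ionizable_groups.tsv")
    }
    mods: dict[str, Modification] = {}
    for name, avg, mono, adds, removes, allowed in _read_data_tsv("modifications.tsv"):
        mods[name] = Modification(
            name=name,
            mass_delta_average=float(avg),
            mass_delta_mono=float(mono),
            adds_groups=tuple(g for g in adds.split(";") if g and g != "-"),
            removes_site_group=removes == "yes",
            allowed_residues=allowed.replace(",", ""),
        )
    return ResidueChemistry(masses, water, groups, mods)


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise InvalidSequenceError(f"unknown residue letter(s): {sorted(bad)}")


ModPlacement = tuple[int, str]  # (0-based site index, modification name)


def _validate_mods(
    sequence: str, mods: Iterable[ModPlacement], chem: ResidueChemistry
) -> list[ModPlacement]:
    out = []
    for site, name in mods:
        if name not in chem.modifications:
            raise ModificationPlacementError(f"unknown modification {name!r}")
        if not (0 <= site < len(sequence)):
            raise ModificationPlacementError(
                f"site {site} out of range for length-{len(sequence)} sequence"
            )
        allowed = chem.modifications[name].allowed_residues
        if "nterm" in allowed and site == 0:
            pass
        elif sequence[site] not in allowed:
            raise ModificationPlacementError(
                f"{name} not allowed on residue {sequence[site]!r} at {site}"
            )
        out.append((site, name))
    return out


def molecular_weight(
    sequence: str,
    mods: Sequence[ModPlacement] = (),
    *,
    scale: str = "average",
    chem: ResidueChemistry | None = None,
) -> float:
    """Mass in Da: sum of residue masses + one water + modification deltas."""
    chem = chem or load_default_chemistry()
    _validate_sequence(sequence)
    mods = _validate_mods(sequence, mods, chem)
    idx = 0 if scale == "average" else 1
    mass = chem.water_mass[idx] + sum(chem.residue_masses[aa][idx] for aa in sequence)
    for _site, name in mods:
        m = chem.modifications[name]
        mass += m.mass_delta_average if idx == 0 else m.mass_delta_mono
    return mass


def _charge_groups(
    sequence: str, mods: Sequence[ModPlacement], chem: ResidueChemistry
) -> list[tuple[str, float, int]]:
    """Collapse a (sequence, mods) pair into [(polarity, pKa, count)] terms."""
    mods = _validate_mods(sequence, mods, chem)
    silenced: set[int] = set()
    extra: list[str] = []
    nterm_silenced = False
    for site, name in mods:
        m = chem.modifications[name]
        extra.extend(m.adds_groups)
        if m.removes_site_group:
            if site == 0 and sequence[site] not in m.allowed_residues:
                nterm_silenced = True
            else:
                silenced.add(site)
    counts: dict[str, int] = {}
    for i, aa in enumerate(sequence):
        if aa in chem.ionizable_groups and i not in silenced:
            counts[aa] = counts.get(aa, 0) + 1
    counts["C_term"] = 1
    if not nterm_silenced:
        counts["N_term"] = 1
    for g in extra:
        counts[g] = counts.get(g, 0) + 1
    return [
        (chem.ionizable_groups[g][0], chem.ionizable_groups[g][1], n)
        for g, n in counts.items()
    ]


def net_charge(
    sequence: str,
    mods: Sequence[ModPlacement] = (),
    pH: float = 7.0,
    *,
    chem: ResidueChemistry | None = None,
) -> float:
    """Henderson-Hasselbalch net charge at a given pH (elementary charges).

    Basic groups contribute ``1/(1 + 10**(pH - pKa))``, acidic groups
    ``-1/(1 + 10**(pKa - pH))``; the result is strictly decreasing in pH.
    """
    if not (0.0 <= pH <= 14.0):
        raise ValueError(f"pH {pH} outside [0, 14]")
    chem = chem or load_default_chemistry()
    _validate_sequence(sequence)
    return _charge_from_groups(_charge_groups(sequence, mods, chem), pH)


def _charge_from_groups(groups: list[tuple[str, float, int]], pH: float) -> float:
    q = 0.0
    for pol, pka, n in groups:
        if pol == "base":
            q += n / (1.0 + 10.0 ** (pH - pka))
        else:
            q -= n / (1.0 + 10.0 ** (pka - pH))
    return q


def isoelectric_point(
    sequence: str,
    mods: Sequence[ModPlacement] = (),
    *,
    chem: ResidueChemistry | None = None,
    charge_tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge curve is continuous and strictly decreasing, so the zero
    crossing is unique; iteration stops once ``|charge| < charge_tol``. If the
    charge does not change sign inside [0, 14] (all-basic or all-acidic
    peptides), the nearer interval edge is returned.
    """
    chem = chem or load_default_chemistry()
    _validate_sequence(sequence)
    groups = _charge_groups(sequence, mods, chem)
    lo, hi = 0.0, 14.0
    q_lo = _charge_from_groups(groups, lo)
    q_hi = _charge_from_groups(groups, hi)
    if q_lo <= 0:
        return lo
    if q_hi >= 0:
        return hi
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        q = _charge_from_groups(groups, mid)
        if abs(q) < charge_tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# digestion


@dataclass(frozen=True)
class DigestRule:
    """Protease specificity and what counts as a measurable peptide.

    ``cleave_after`` residues cut C-terminally unless the next residue is in
    ``block_next``. ``peptide_length_bounds`` delimit "theoretically
    measurable" peptides for the iBAQ denominator.
    """

    name: str
    cleave_after: frozenset[str]
    block_next: frozenset[str] = frozenset()
    max_missed_cleavages: int = 0
    peptide_length_bounds: tuple[int, int] = (6, 30)

    def __post_init__(self) -> None:
        lo, hi = self.peptide_length_bounds
        if lo < 1 or hi < lo:
            raise ValueError("peptide_length_bounds must satisfy 1 <= min <= max")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")

    def cleavage_sites(self, sequence: str) -> list[int]:
        """Positions i such that the bond after sequence[i-1] is cut (1-based split points)."""
        sites = []
        for i in range(1, len(sequence)):
            if sequence[i - 1] in self.cleave_after and sequence[i] not in self.block_next:
                sites.append(i)
        return sites


TRYPSIN = DigestRule(
    name="trypsin",
    cleave_after=frozenset("KR"),
    block_next=frozenset("P"),
    max_missed_cleavages=2,
)
LYSC = DigestRule(name="lysc", cleave_after=frozenset("K"), max_missed_cleavages=2)


@dataclass(frozen=True)
class Peptide:
    sequence: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    missed_cleavages: int


def digest(
    sequence: str, rule: DigestRule = TRYPSIN, *, max_missed: int | None = None
) -> list[Peptide]:
    """All peptides with up to ``max_missed`` internal cleavage sites.

    The 0-missed peptides partition the sequence exactly; higher missed-
    cleavage peptides are concatenations of adjacent 0-missed fragments.
    """
    _validate_sequence(sequence)
    if max_missed is None:
        max_missed = rule.max_missed_cleavages
    bounds = [0] + rule.cleavage_sites(sequence) + [len(sequence)]
    peptides: list[Peptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(min(max_missed, n_frag - 1 - i) + 1):
            s, e = bounds[i], bounds[i + 1 + m]
            peptides.append(Peptide(sequence[s:e], s, e, m))
    return peptides


def theoretical_peptide_count(
    sequence: str, rule: DigestRule = TRYPSIN, *, chem: ResidueChemistry | None = None
) -> int:
    """iBAQ denominator: fully cleaved peptides inside the length bounds."""
    lo, hi = rule.peptide_length_bounds
    return sum(
        1
        for p in digest(sequence, rule, max_missed=0)
        if lo <= len(p.sequence) <= hi
    )


# --------------------------------------------------------------------------
# FASTA input


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (accession, sequence) pairs from a multi-record FASTA file."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        _validate_sequence(seq)
        records.append((rec.id, seq))
    return records
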