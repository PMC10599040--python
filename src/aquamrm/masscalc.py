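"""Monoisotopic mass and MRM transition arithmetic for derivatized histone peptides.

Implements neutral/precursor/fragment m/z computation for peptides carrying
positioned chemical modifications (propionyl from derivatization, acetyl as
the PTM of interest) and an optional C-terminal heavy-arginine label
(13C6 15N4, +10.008269 Da), the isobaric positional-isomer interference
filter, and construction/round-tripping of the 12-transition assay list.

Conventions
-----------
* The canonical mass of a peptide is its NEUTRAL monoisotopic mass.  The
  assay documentation reports masses with one extra hydrogen atom; use
  ``table_convention_mass`` to reproduce those printed values.
* Precursors are doubly protonated, products singly protonated y ions for
  all assay transitions; b ions are generated only for interference checks.
* m/z values are displayed to one decimal, rounded half away from zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

# Monoisotopic constants (Da), >= 6 decimals.
WATER_MASS = 18.010565
PROTON_MASS = 1.007276
HYDROGEN_ATOM_MASS = 1.007825

#: Match tolerance of the acquisition method (m/z).
METHOD_MATCH_TOLERANCE = 0.25


class MassCalcError(ValueError):
    """Fatal input error in mass/transition arithmetic."""


@dataclass(frozen=True)
class ResidueMassTable:
    """One-letter residue symbol -> monoisotopic residue mass (Da)."""

    residues: dict[str, float] = field(
        default_factory=lambda: dict(_pmass.std_aa_mass)
    )
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS
    hydrogen_atom_mass: float = HYDROGEN_ATOM_MASS

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.residues.values()):
            raise MassCalcError("residue masses must be strictly positive")

    def __getitem__(self, symbol: str) -> float:
        try:
            return self.residues[symbol]
        except KeyError:
            raise MassCalcError(f"unknown residue symbol: {symbol!r}") from None


DEFAULT_MASS_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class Modification:
    """A positioned chemical/PTM modification by name and monoisotopic delta."""

    name: str
    target: str  # residue symbol or "N-term"/"C-term"
    delta_mass: float


#: Propionylation of lysine (chemical derivatization blocking tryptic cleavage).
PROPIONYL = Modification("Poy", "K", 56.026215)
#: Lysine epsilon-acetylation, the PTM whose stoichiometry is measured.
ACETYL = Modification("Ac", "K", 42.010565)

MODIFICATIONS = {m.name: m for m in (PROPIONYL, ACETYL)}


@dataclass(frozen=True)
class HeavyLabel:
    """Stable-isotope label on the C-terminal residue (SIL standards)."""

    residue: str = "R"
    position: str = "C-term"
    delta_mass: float = 10.008269  # 13C6 15N4 arginine


HEAVY_R = HeavyLabel()


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence plus positioned modifications and optional heavy label.

    ``modifications`` positions are 1-based within the peptide sequence.
    """

    sequence: str
    modifications: tuple[tuple[int, Modification], ...] = ()
    heavy: HeavyLabel | None = None
    display_name: str = ""

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pos, mod in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise MassCalcError(
                    f"modification position {pos} outside sequence of "
                    f"length {len(self.sequence)}"
                )
            if pos in seen:
                raise MassCalcError(f"more than one modification at position {pos}")
            seen.add(pos)
            residue = self.sequence[pos - 1]
            if mod.target not in (residue, "N-term", "C-term"):
                raise MassCalcError(
                    f"modification {mod.name!r} targets {mod.target!r} but "
                    f"position {pos} is {residue!r}"
                )
        if self.heavy is not None and self.sequence[-1] != self.heavy.residue:
            raise MassCalcError(
                f"heavy label requires C-terminal {self.heavy.residue!r}, "
                f"sequence ends in {self.sequence[-1]!r}"
            )

    @property
    def label_state(self) -> str:
        return "heavy" if self.heavy is not None else "light"

    def residue_mass(self, position: int, table: ResidueMassTable) -> float:
        """Modified monoisotopic mass of the residue at 1-based ``position``.

        The heavy-label delta is carried by the C-terminal residue.
        """
        m = table[self.sequence[position - 1]]
        for pos, mod in self.modifications:
            if pos == position:
                m += mod.delta_mass
        if self.heavy is not None and position == len(self.sequence):
            m += self.heavy.delta_mass
        return m

    def mod_spec(self) -> str:
        """Serialize modifications as e.g. ``"1:Poy;6:Ac"``."""
        return ";".join(f"{pos}:{mod.name}" for pos, mod in self.modifications)


def parse_mod_spec(spec: str) -> tuple[tuple[int, Modification], ...]:
    """Parse a ``position:name`` modification spec like ``"1:Poy;6:Ac"``."""
    if not spec or spec in ("-", "none"):
        return ()
    mods = []
    for token in spec.split(";"):
        pos_s, _, name = token.partition(":")
        if name not in MODIFICATIONS:
            raise MassCalcError(f"unknown modification name: {name!r}")
        mods.append((int(pos_s), MODIFICATIONS[name]))
    return tuple(mods)


@dataclass(frozen=True)
class Transition:
    """One Q1/Q3 pair of the MRM assay."""

    peptide: ModifiedPeptide
    q1_mz: float
    q1_charge: int
    q3_mz: float
    q3_charge: int
    ion_type: str
    ion_index: int
    label: str
    declared: bool = False


def neutral_monoisotopic_mass(
    peptide: ModifiedPeptide, table: ResidueMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Neutral monoisotopic mass: residues + water + mod deltas + heavy delta."""
    total = table.water_mass
    for i in range(1, len(peptide.sequence) + 1):
        total += peptide.residue_mass(i, table)
    return total


def table_convention_mass(
    peptide: ModifiedPeptide, table: ResidueMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Neutral mass plus one hydrogen atom — the assay-documentation convention."""
    return neutral_monoisotopic_mass(peptide, table) + table.hydrogen_atom_mass


def precursor_mz(
    peptide: ModifiedPeptide,
    charge: int,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    if charge < 1:
        raise MassCalcError(f"precursor charge must be >= 1, got {charge}")
    neutral = neutral_monoisotopic_mass(peptide, table)
    return (neutral + charge * table.proton_mass) / charge


def fragment_mz(
    peptide: ModifiedPeptide,
    ion_type: str,
    ion_index: int,
    charge: int = 1,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """m/z of a b or y fragment ion.

    y_n sums the n C-terminal modified residues (including the heavy label)
    plus water and ``charge`` protons; b_n sums the n N-terminal modified
    residues plus the protons, no water.
    """
    L = len(peptide.sequence)
    if not 1 <= ion_index < L:
        raise MassCalcError(
            f"ion index {ion_index} out of range for length-{L} peptide"
        )
    if charge < 1:
        raise MassCalcError(f"fragment charge must be >= 1, got {charge}")
    if ion_type == "y":
        positions = range(L - ion_index + 1, L + 1)
        neutral = sum(peptide.residue_mass(p, table) for p in positions)
        neutral += table.water_mass
    elif ion_type == "b":
        positions = range(1, ion_index + 1)
        neutral = sum(peptide.residue_mass(p, table) for p in positions)
    else:
        raise MassCalcError(f"ion type must be 'y' or 'b', got {ion_type!r}")
    return (neutral + charge * table.proton_mass) / charge


def display_mz(mz: float, decimals: int = 1) -> float:
    """Round half away from zero, the printing convention for assay m/z."""
    scale = 10.0**decimals
    return math.floor(abs(mz) * scale + 0.5) / scale * (1 if mz >= 0 else -1)


def all_fragment_mzs(
    peptide: ModifiedPeptide, charge: int = 1, table: ResidueMassTable = DEFAULT_MASS_TABLE
) -> list[tuple[str, int, float]]:
    """Every b and y ion of ``peptide`` at the given charge."""
    out = []
    for ion_type in ("y", "b"):
        for idx in range(1, len(peptide.sequence)):
            out.append((ion_type, idx, fragment_mz(peptide, ion_type, idx, charge, table)))
    return out


def isobaric_overlap_filter(
    target: ModifiedPeptide,
    isobar: ModifiedPeptide,
    candidate_ions: Sequence[tuple[str, int]],
    tolerance: float = METHOD_MATCH_TOLERANCE,
    charge: int = 1,
    cross_type: bool = False,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> tuple[list[tuple[str, int]], list[tuple[tuple[str, int], tuple[str, int]]]]:
    """Split candidate fragment ions into interference-free and interfering sets.

    A candidate ion of ``target`` is excluded when a same-series fragment ion
    of the isobaric positional isomer (same ion type and charge) lies within
    ``tolerance`` m/z of it — such a transition cannot distinguish the two
    forms.  With ``cross_type=True`` the candidate is additionally screened
    against the isobar's other ion series (a stricter diagnostic; for these
    arginine-terminated tryptic peptides CID product spectra are dominated by
    the y series, so the same-series rule is the operative one).

    Returns ``(retained, excluded)`` where each exclusion records the first
    matching isobar ion as ``((ion_type, index), (isobar_ion_type, index))``.
    """
    if len(target.sequence) != len(isobar.sequence):
        raise MassCalcError(
            "isobaric comparison requires equal-length sequences "
            f"({len(target.sequence)} vs {len(isobar.sequence)})"
        )
    isobar_ions = all_fragment_mzs(isobar, charge, table)
    retained: list[tuple[str, int]] = []
    excluded: list[tuple[tuple[str, int], tuple[str, int]]] = []
    for ion_type, idx in candidate_ions:
        mz = fragment_mz(target, ion_type, idx, charge, table)
        match = next(
            (
                (i_type, i_idx)
                for i_type, i_idx, i_mz in isobar_ions
                if (cross_type or i_type == ion_type) and abs(i_mz - mz) <= tolerance
            ),
            None,
        )
        if match is None:
            retained.append((ion_type, idx))
        else:
            excluded.append(((ion_type, idx), match))
    return retained, excluded


def build_transition_set(
    peptides: Sequence[ModifiedPeptide],
    ions: Sequence[tuple[str, int]],
    precursor_charge: int = 2,
    product_charge: int = 1,
    label_prefix: str = "MRM",
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> list[Transition]:
    """Cross peptides with product ions into a labeled transition list.

    Labels run ``MRM1, MRM2, ...`` in (peptide, ion) order, matching the
    assay's published numbering when called with the four study peptides and
    ions y7, y8, y6.
    """
    seen: set[tuple[str, str, str, int]] = set()
    transitions: list[Transition] = []
    n = 0
    for pep in peptides:
        q1 = precursor_mz(pep, precursor_charge, table)
        for ion_type, idx in ions:
            key = (pep.display_name, pep.label_state, ion_type, idx)
            if key in seen:
                raise MassCalcError(f"duplicate transition for {key}")
            seen.add(key)
            n += 1
            transitions.append(
                Transition(
                    peptide=pep,
                    q1_mz=q1,
                    q1_charge=precursor_charge,
                    q3_mz=fragment_mz(pep, ion_type, idx, product_charge, table),
                    q3_charge=product_charge,
                    ion_type=ion_type,
                    ion_index=idx,
                    label=f"{label_prefix}{n}",
                )
            )
    return transitions


TRANSITION_COLUMNS = [
    "peptide_name",
    "sequence",
    "modification_spec",
    "label_state",
    "q1_mz",
    "q1_charge",
    "q3_mz",
    "q3_charge",
    "ion_type",
    "ion_index",
    "transition_label",
]


def transitions_to_frame(transitions: Iterable[Transition]) -> pd.DataFrame:
    rows = [
        {
            "peptide_name": t.peptide.display_name,
            "sequence": t.peptide.sequence,
            "modification_spec": t.peptide.mod_spec(),
            "label_state": t.peptide.label_state,
            "q1_mz": t.q1_mz,
            "q1_charge": t.q1_charge,
            "q3_mz": t.q3_mz,
            "q3_charge": t.q3_charge,
            "ion_type": t.ion_type,
            "ion_index": t.ion_index,
            "transition_label": t.label,
        }
        for t in transitions
    ]
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def write_transitions(transitions: Iterable[Transition], path: str | Path) -> None:
    """Write the delimited transition-list file (tab-separated)."""
    transitions_to_frame(transitions).to_csv(path, sep="\t", index=False, float_format="%.9f")


def read_transitions(path: str | Path) -> list[Transition]:
    """Load a transition-list file, recomputing and checking declared m/z.

    Declared Q3 values within 0.05 m/z of the computed fragment are taken as
    computed; a 0.05-0.25 m/z disagreement is accepted as a declared
    instrument value with a warning; beyond the 0.25 m/z method match
    tolerance is an error.
    """
    df = pd.read_csv(path, sep="\t")
    transitions: list[Transition] = []
    for row in df.itertuples(index=False):
        pep = ModifiedPeptide(
            sequence=row.sequence,
            modifications=parse_mod_spec(
                "" if pd.isna(row.modification_spec) else str(row.modification_spec)
            ),
            heavy=HEAVY_R if row.label_state == "heavy" else None,
            display_name=row.peptide_name,
        )
        computed_q3 = fragment_mz(pep, row.ion_type, int(row.ion_index), int(row.q3_charge))
        dev = abs(float(row.q3_mz) - computed_q3)
        declared = dev > 0.05
        if dev > METHOD_MATCH_TOLERANCE:
            raise MassCalcError(
                f"declared Q3 {row.q3_mz} for {row.transition_label} deviates "
                f"{dev:.3f} m/z from computed {computed_q3:.4f} "
                f"(> {METHOD_MATCH_TOLERANCE} method match tolerance)"
            )
        if declared:
            logger.warning(
                "transition %s: declared Q3 %.4f differs from computed %.4f by %.3f m/z; "
                "kept as declared instrument value",
                row.transition_label,
                row.q3_mz,
                computed_q3,
                dev,
            )
        transitions.append(
            Transition(
                peptide=pep,
                q1_mz=float(row.q1_mz),
                q1_charge=int(row.q1_charge),
                q3_mz=float(row.q3_mz),
                q3_charge=int(row.q3_charge),
                ion_type=str(row.ion_type),
                ion_index=int(row.ion_index),
                label=str(row.transition_label),
                declared=declared,
            )
        )
    return transitions


# ---------------------------------------------------------------------------
# The study's peptide panel: histone H3 3-17 tryptic peptide KSTGGKAPR.
# K9 of H3 is position 1 of the peptide; K14 is position 6.

H3_3_17_SEQUENCE = "KSTGGKAPR"
K9_POSITION = 1
K14_POSITION = 6

#: Product ions quantified by the assay, in published transition order.
STUDY_IONS: tuple[tuple[str, int], ...] = (("y", 7), ("y", 8), ("y", 6))


def make_peptide(k14_mod: Modification, heavy: bool) -> ModifiedPeptide:
    """One of the four assay forms: K9 propionyl, K14 acetyl or propionyl."""
    name = f"K9[Poy]K14[{k14_mod.name}]" + ("-heavy" if heavy else "")
    return ModifiedPeptide(
        sequence=H3_3_17_SEQUENCE,
        modifications=((K9_POSITION, PROPIONYL), (K14_POSITION, k14_mod)),
        heavy=HEAVY_R if heavy else None,
        display_name=name,
    )


def study_peptides() -> list[ModifiedPeptide]:
    """The four assay peptides in published order: Ac, Ac-heavy, Poy, Poy-heavy."""
    return [
        make_peptide(ACETYL, heavy=False),
        make_peptide(ACETYL, heavy=True),
        make_peptide(PROPIONYL, heavy=False),
        make_peptide(PROPIONYL, heavy=True),
    ]


def isobaric_isomer(heavy: bool = False) -> ModifiedPeptide:
    """K9[Ac]K14[Poy]: same mass as K9[Poy]K14[Ac] with the mods swapped."""
    name = "K9[Ac]K14[Poy]" + ("-heavy" if heavy else "")
    return ModifiedPeptide(
        sequence=H3_3_17_SEQUENCE,
        modifications=((K9_POSITION, ACETYL), (K14_POSITION, PROPIONYL)),
        heavy=HEAVY_R if heavy else None,
        display_name=name,
    )


def study_transitions() -> list[Transition]:
    """The 12-transition assay (4 peptides x y7/y8/y6), labeled MRM1-MRM12."""
    return build_transition_set(study_peptides(), STUDY_IONS)
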