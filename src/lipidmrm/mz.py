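"""Molecular formulas and monoisotopic m/z for lipid precursor and product ions.

Neutral formulas follow the standard ester/amide bookkeeping:

* glycerolipids (MAG/DAG/TAG) = glycerol + n fatty acids - n H2O;
* glycerophospholipids = head-group backbone (glycerophospho-X) + 2 acids - 2 H2O;
* lyso-phospholipids  = same backbone + 1 acid - 1 H2O (equivalently the
  diacyl formula minus one acyl ketene);
* CE = cholesterol + acid - H2O;
* SM / Cer use the fixed d18:1 sphingoid backbone in closed form on totals.

Adduct arithmetic adds/removes a proton (+-1.00728), ammonium (+18.03383) or
acetate (+59.01331); all ions are singly charged. Class rules for the default
panel: positive mode uses [M+H]+ for SM/Cer and [M+NH4]+ for the neutral
lipids (CE/MAG/DAG/TAG); negative mode uses [M-H]- for phospholipids except
PC/LPC which are measured as the acetate adduct [M+CH3COO]-.
"""

from __future__ import annotations

from dataclasses import dataclass

from .elements import PROTON_MASS
from .formula import ElementFormula, monoisotopic_mass
from .species import (
    FattyAcyl,
    LipidSpecies,
    LYSO_CLASSES,
    N_CHAINS,
)

__all__ = [
    "Adduct",
    "ADDUCTS",
    "CLASS_ADDUCT",
    "CLASS_ION_MODE",
    "formula_of_species",
    "free_fatty_acid_formula",
    "precursor_mz",
    "product_mz_neutral_loss_fa",
    "fa_carboxylate_mz",
    "headgroup_product_mz",
    "NH3_MASS",
    "H2O_MASS",
]

H2O_MASS = monoisotopic_mass(ElementFormula.parse("H2O"))
NH3_MASS = monoisotopic_mass(ElementFormula.parse("NH3"))


@dataclass(frozen=True)
class Adduct:
    """A singly charged adduct: name, charge sign and mass delta (Da)."""

    name: str
    charge: int  # +1 or -1
    delta: float


ADDUCTS: dict[str, Adduct] = {
    "M+H": Adduct("M+H", +1, +PROTON_MASS),
    "M+NH4": Adduct("M+NH4", +1, +(NH3_MASS + PROTON_MASS)),
    "M-H": Adduct("M-H", -1, -PROTON_MASS),
    "M+CH3COO": Adduct(
        "M+CH3COO", -1, +(monoisotopic_mass(ElementFormula.parse("C2H4O2")) - PROTON_MASS)
    ),
}

#: Default precursor adduct per lipid class.
CLASS_ADDUCT: dict[str, str] = {
    "SM": "M+H", "Cer": "M+H",
    "CE": "M+NH4", "MAG": "M+NH4", "DAG": "M+NH4", "TAG": "M+NH4",
    "PC": "M+CH3COO", "LPC": "M+CH3COO",
    "PA": "M-H", "PE": "M-H", "LPE": "M-H", "PG": "M-H", "LPG": "M-H",
    "PI": "M-H", "LPI": "M-H", "PS": "M-H", "LPS": "M-H",
}

CLASS_ION_MODE: dict[str, str] = {
    cls: ("positive" if ADDUCTS[add].charge > 0 else "negative")
    for cls, add in CLASS_ADDUCT.items()
}

# Backbone residues: diacyl/lyso formula = backbone + n x free acid - n x H2O.
_BACKBONES: dict[str, ElementFormula] = {
    "glycerol": ElementFormula.parse("C3H8O3"),
    "cholesterol": ElementFormula.parse("C27H46O"),
    "PA": ElementFormula.parse("C3H9O6P"),      # glycerophosphate
    "PC": ElementFormula.parse("C8H20NO6P"),    # glycerophosphocholine
    "PE": ElementFormula.parse("C5H14NO6P"),
    "PG": ElementFormula.parse("C6H15O8P"),
    "PI": ElementFormula.parse("C9H19O11P"),
    "PS": ElementFormula.parse("C6H14NO8P"),
}


def free_fatty_acid_formula(fa: FattyAcyl) -> ElementFormula:
    """Neutral free fatty acid CnH(2n-2d)O2, with deuterium substitutions."""
    f = ElementFormula(
        C=fa.carbons, H=2 * fa.carbons - 2 * fa.double_bonds, O=2
    )
    return f.substitute_deuterium(fa.deuterium)


def _acyl_sum_formula(carbons: int, double_bonds: int, n_chains: int) -> ElementFormula:
    """Sum formula of ``n_chains`` free acids with the given totals."""
    return ElementFormula(
        C=carbons, H=2 * carbons - 2 * double_bonds, O=2 * n_chains
    )


def formula_of_species(species: LipidSpecies) -> ElementFormula:
    """Neutral molecular formula of a lipid species (deuterium included)."""
    cls = species.lipid_class
    c, d = species.total_carbons, species.total_double_bonds
    if cls == "SM":
        # SM(d18:1/n:d) = C(23+n)H(47+2n-2d')N2O6P with totals c=18+n, d=1+d'.
        f = ElementFormula(C=c + 5, H=2 * c - 2 * d + 13, N=2, O=6, P=1)
    elif cls == "Cer":
        f = ElementFormula(C=c, H=2 * c - 2 * d + 1, N=1, O=3)
    elif cls == "CE":
        f = _BACKBONES["cholesterol"] + _acyl_sum_formula(c, d, 1) - ElementFormula(H=2, O=1)
    elif cls in ("MAG", "DAG", "TAG"):
        n = N_CHAINS[cls]
        f = (
            _BACKBONES["glycerol"]
            + _acyl_sum_formula(c, d, n)
            - ElementFormula(H=2 * n, O=n)
        )
    else:
        diacyl = cls[1:] if cls in LYSO_CLASSES else cls
        n = 1 if cls in LYSO_CLASSES else 2
        f = (
            _BACKBONES[diacyl]
            + _acyl_sum_formula(c, d, n)
            - ElementFormula(H=2 * n, O=n)
        )
    return f.substitute_deuterium(species.deuterium_count)


def precursor_mz(species: LipidSpecies, adduct: Adduct | str | None = None) -> float:
    """Monoisotopic m/z of the (singly charged) precursor ion.

    When ``adduct`` is omitted the class rule applies. Passing an adduct that
    the class rule does not permit raises ``ValueError``.
    """
    rule = CLASS_ADDUCT[species.lipid_class]
    if adduct is None:
        adduct = ADDUCTS[rule]
    elif isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if adduct.name != rule:
        raise ValueError(
            f"{adduct.name} is not the panel adduct for {species.lipid_class} "
            f"(expected {rule})"
        )
    return monoisotopic_mass(formula_of_species(species)) + adduct.delta


def _remaining_realizable(species: LipidSpecies, lost: FattyAcyl) -> bool:
    n_rem = N_CHAINS[species.lipid_class] - 1
    c_rem = species.total_carbons - lost.carbons
    d_rem = species.total_double_bonds - lost.double_bonds
    if c_rem < 2 * n_rem or d_rem < 0:
        return False
    # each remaining chain can carry at most (C-2)/2 double bonds
    return d_rem <= (c_rem - 2 * n_rem) // 2


def product_mz_neutral_loss_fa(
    species: LipidSpecies,
    lost_fa: FattyAcyl,
    adduct: Adduct | str = "M+NH4",
) -> float:
    """Product m/z after neutral loss of one sn-position fatty acid + NH3.

    This is the TAG/DAG isomer-resolving fragment: from the [M+NH4]+
    precursor, the free acid (RCOOH) of one chain and ammonia are lost.
    """
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if adduct.name != "M+NH4":
        raise ValueError("neutral-loss product ions require the M+NH4 adduct")
    if species.chains is not None:
        stripped = FattyAcyl(lost_fa.carbons, lost_fa.double_bonds, lost_fa.deuterium)
        if stripped not in species.chains:
            raise ValueError(f"{lost_fa} is not a chain of {species}")
    elif not _remaining_realizable(species, lost_fa):
        raise ValueError(
            f"loss of {lost_fa} from {species} leaves no realizable chains"
        )
    return (
        precursor_mz(species, adduct)
        - monoisotopic_mass(free_fatty_acid_formula(lost_fa))
        - NH3_MASS
    )


def fa_carboxylate_mz(fa: FattyAcyl) -> float:
    """m/z of the fatty-acid carboxylate anion [RCOO]- (deuterium included)."""
    return monoisotopic_mass(free_fatty_acid_formula(fa)) - PROTON_MASS


def headgroup_product_mz(lipid_class: str) -> float:
    """Class-diagnostic product-ion m/z for the head-group fragment rules.

    SM (positive mode) yields protonated phosphocholine (184.073); Cer the
    dehydrated sphingoid fragment (264.269); CE the cholestadienyl cation
    (369.352). These are the standard class fragments; classes monitored via
    fatty-acyl products have no fixed head-group fragment and raise.
    """
    if lipid_class == "SM":
        return monoisotopic_mass(ElementFormula.parse("C5H14NO4P")) + PROTON_MASS
    if lipid_class == "Cer":
        sphingosine = ElementFormula.parse("C18H37NO2")
        return monoisotopic_mass(sphingosine) - 2 * H2O_MASS + PROTON_MASS
    if lipid_class == "CE":
        return monoisotopic_mass(_BACKBONES["cholesterol"]) - H2O_MASS + PROTON_MASS
    raise ValueError(f"no head-group fragment rule for class {lipid_class!r}")
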