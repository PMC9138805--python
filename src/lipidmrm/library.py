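"""MRM transition library assembly.

A transition is a (Q1, Q3) m/z pair with polarity, expected retention time,
scheduling attributes (window halfwidth, dwell weight) and compound-dependent
voltages. Libraries are assembled class by class from declarative
``ClassRuleSet`` configurations; each class carries exactly one product-ion
rule:

* ``headgroup``        -- one transition per species, class-diagnostic fragment
  (SM: phosphocholine; Cer: sphingoid; CE: cholestadienyl);
* ``dehydration``      -- one transition per species, [M+NH4 - NH3 - H2O]+ (MAG);
* ``fa-neutral-loss``  -- one transition per (species, feasible lost fatty
  acid): shared Q1, distinct Q3 (TAG/DAG sn-isomer transitions);
* ``fa-carboxylate``   -- one transition per distinct fatty acid listed in a
  species' compositions, negative mode (phospholipids).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import mz as _mz
from .species import FattyAcyl, LipidSpecies, N_CHAINS

__all__ = [
    "MrmTransition",
    "SpeciesEntry",
    "RtModel",
    "ClassRuleSet",
    "TransitionLibrary",
    "DuplicateTransitionError",
    "build_class_transitions",
    "assemble_library",
    "library_summary",
]

RUN_LENGTH_MIN = 24.0

PRODUCT_RULES = ("headgroup", "dehydration", "fa-neutral-loss", "fa-carboxylate")


class DuplicateTransitionError(ValueError):
    """Two library entries collide on (Q1, Q3, ion mode)."""


@dataclass
class MrmTransition:
    """A single Q1/Q3 monitoring instruction."""

    id: str
    species: LipidSpecies
    q1: float
    q3: float
    ion_mode: str  # "positive" | "negative"
    expected_rt: float  # minutes
    dp: float = 0.0
    ep: float = 0.0
    ce: float = 0.0
    cxp: float = 0.0
    rt_halfwidth: float | None = None  # minutes; None until scheduled
    dwell_weight: float = 1.0
    is_internal_standard: bool = False
    lost_fa: FattyAcyl | None = None
    product_rule: str = "headgroup"

    def __post_init__(self) -> None:
        if self.q1 <= self.q3:
            raise ValueError(f"{self.id}: Q1 ({self.q1}) must exceed Q3 ({self.q3})")
        if not 0.0 <= self.expected_rt <= RUN_LENGTH_MIN:
            raise ValueError(
                f"{self.id}: expected RT {self.expected_rt} outside "
                f"[0, {RUN_LENGTH_MIN}] min"
            )
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"bad ion mode {self.ion_mode!r}")

    @property
    def key(self) -> tuple[float, float, str]:
        return (round(self.q1, 4), round(self.q3, 4), self.ion_mode)


@dataclass(frozen=True)
class SpeciesEntry:
    """One configured library species.

    ``lost_fas`` drive the fa-neutral-loss rule (one transition per loss);
    ``compositions`` drive the fa-carboxylate rule (one transition per
    distinct chain across the listed compositions). Both empty means the
    class-level default applies (head-group / dehydration rules).
    """

    species: LipidSpecies
    lost_fas: tuple[FattyAcyl, ...] = ()
    compositions: tuple[tuple[FattyAcyl, ...], ...] = ()
    expected_rt: float | None = None


@dataclass(frozen=True)
class RtModel:
    """Expected retention time: class anchor + linear offset in (C, DB).

    rt = anchor + carbon_coeff * (C - ref_carbons) + db_coeff * (DB - ref_db),
    clipped to the class elution range [rt_min, rt_max].
    """

    anchor: float
    rt_min: float
    rt_max: float
    carbon_coeff: float = 0.0
    db_coeff: float = 0.0
    ref_carbons: float = 0.0
    ref_db: float = 0.0

    def predict(self, species: LipidSpecies) -> float:
        rt = (
            self.anchor
            + self.carbon_coeff * (species.total_carbons - self.ref_carbons)
            + self.db_coeff * (species.total_double_bonds - self.ref_db)
        )
        rt = min(max(rt, self.rt_min), self.rt_max)
        return min(max(rt, 0.0), RUN_LENGTH_MIN)


@dataclass(frozen=True)
class ClassRuleSet:
    """Per-class enumeration rules: adduct, product rule, voltages, RT model."""

    lipid_class: str
    product_rule: str
    entries: tuple[SpeciesEntry, ...]
    rt_model: RtModel
    dp: float = 0.0
    ep: float = 0.0
    ce: float = 0.0
    cxp: float = 0.0

    def __post_init__(self) -> None:
        if self.product_rule not in PRODUCT_RULES:
            raise ValueError(f"unknown product rule {self.product_rule!r}")

    @property
    def adduct(self) -> _mz.Adduct:
        return _mz.ADDUCTS[_mz.CLASS_ADDUCT[self.lipid_class]]

    @property
    def ion_mode(self) -> str:
        return _mz.CLASS_ION_MODE[self.lipid_class]


@dataclass
class TransitionLibrary:
    """An assembled library: analyte transitions plus internal standards."""

    transitions: list[MrmTransition] = field(default_factory=list)
    standards: list[MrmTransition] = field(default_factory=list)

    @property
    def all_transitions(self) -> list[MrmTransition]:
        return self.transitions + self.standards

    @property
    def n_species(self) -> int:
        """Library entries at species granularity, excluding standards."""
        return len(self.transitions)

    @property
    def n_transitions(self) -> int:
        """All monitored Q1/Q3 pairs, standards included."""
        return len(self.transitions) + len(self.standards)


def _species_id(species: LipidSpecies, lost_fa: FattyAcyl | None = None,
                q3_fa: FattyAcyl | None = None) -> str:
    base = f"{species.lipid_class}_{species.total_carbons}:{species.total_double_bonds}"
    if species.deuterium_count:
        base += f"(d{species.deuterium_count})"
    if lost_fa is not None:
        base += f"/FA{lost_fa.carbons}:{lost_fa.double_bonds}"
    if q3_fa is not None:
        base += f"/{q3_fa.carbons}:{q3_fa.double_bonds}"
    return base


def _pool_feasible(species: LipidSpecies, lost: FattyAcyl) -> bool:
    """Remaining chains realizable within the library bounds (14-22 C, 0-6 DB)."""
    n_rem = N_CHAINS[species.lipid_class] - 1
    c_rem = species.total_carbons - lost.carbons
    d_rem = species.total_double_bonds - lost.double_bonds
    return (
        14 * n_rem <= c_rem <= 22 * n_rem
        and 0 <= d_rem <= 6 * n_rem
        and d_rem <= (c_rem - 2 * n_rem) // 2
    )


def build_class_transitions(
    rules: ClassRuleSet, fa_pool: list[FattyAcyl] | None = None
) -> list[MrmTransition]:
    """Expand one class configuration into its MRM transitions.

    For the ``fa-neutral-loss`` rule, an entry's explicit ``lost_fas`` take
    precedence; otherwise the feasible subset of ``fa_pool`` is used (an
    empty pool yields no transitions for that rule, which is not an error).
    """
    volts = dict(dp=rules.dp, ep=rules.ep, ce=rules.ce, cxp=rules.cxp)
    out: list[MrmTransition] = []
    for entry in rules.entries:
        sp = entry.species
        if sp.lipid_class != rules.lipid_class:
            raise ValueError(
                f"entry {sp} does not belong to class {rules.lipid_class}"
            )
        rt = entry.expected_rt if entry.expected_rt is not None else rules.rt_model.predict(sp)
        q1 = _mz.precursor_mz(sp, rules.adduct)
        if rules.product_rule == "headgroup":
            q3 = _mz.headgroup_product_mz(sp.lipid_class)
            out.append(MrmTransition(_species_id(sp), sp, q1, q3, rules.ion_mode,
                                     rt, **volts, product_rule="headgroup"))
        elif rules.product_rule == "dehydration":
            q3 = q1 - _mz.NH3_MASS - _mz.H2O_MASS
            out.append(MrmTransition(_species_id(sp), sp, q1, q3, rules.ion_mode,
                                     rt, **volts, product_rule="dehydration"))
        elif rules.product_rule == "fa-neutral-loss":
            losses = entry.lost_fas
            if not losses:
                losses = tuple(
                    fa for fa in (fa_pool or []) if _pool_feasible(sp, fa)
                )
            for fa in losses:
                q3 = _mz.product_mz_neutral_loss_fa(sp, fa, rules.adduct)
                out.append(MrmTransition(
                    _species_id(sp, lost_fa=fa), sp, q1, q3, rules.ion_mode,
                    rt, **volts, lost_fa=fa, product_rule="fa-neutral-loss",
                ))
        else:  # fa-carboxylate
            seen: set[float] = set()
            for comp in entry.compositions:
                for fa in comp:
                    q3 = _mz.fa_carboxylate_mz(fa)
                    if round(q3, 4) in seen:
                        continue
                    seen.add(round(q3, 4))
                    out.append(MrmTransition(
                        _species_id(sp, q3_fa=fa), sp, q1, q3, rules.ion_mode,
                        rt, **volts, product_rule="fa-carboxylate",
                    ))
    return out


def assemble_library(
    class_configs: list[ClassRuleSet],
    standards: list[MrmTransition] | None = None,
    fa_pool: list[FattyAcyl] | None = None,
) -> TransitionLibrary:
    """Concatenate per-class builds and internal standards into one library.

    (Q1, Q3, ion mode) must be unique across the result; a collision raises
    :class:`DuplicateTransitionError` naming both offending entries.
    """
    lib = TransitionLibrary()
    seen: dict[tuple[float, float, str], str] = {}
    for rules in class_configs:
        for tr in build_class_transitions(rules, fa_pool):
            if tr.key in seen:
                raise DuplicateTransitionError(
                    f"(Q1={tr.key[0]}, Q3={tr.key[1]}, {tr.ion_mode}) shared "
                    f"by {seen[tr.key]!r} and {tr.id!r}"
                )
            seen[tr.key] = tr.id
            lib.transitions.append(tr)
    for std in standards or []:
        std = replace(std, is_internal_standard=True)
        if std.key in seen:
            raise DuplicateTransitionError(
                f"(Q1={std.key[0]}, Q3={std.key[1]}, {std.ion_mode}) shared "
                f"by {seen[std.key]!r} and {std.id!r}"
            )
        seen[std.key] = std.id
        lib.standards.append(std)
    return lib


def library_summary(lib: TransitionLibrary) -> dict:
    """Per-class and per-mode transition counts (standards included in modes)."""
    per_class: dict[str, int] = {}
    per_mode = {"positive": 0, "negative": 0}
    for tr in lib.transitions:
        per_class[tr.species.lipid_class] = per_class.get(tr.species.lipid_class, 0) + 1
        per_mode[tr.ion_mode] += 1
    for std in lib.standards:
        per_mode[std.ion_mode] += 1
    return {
        "per_class": per_class,
        "per_mode": per_mode,
        "n_species": lib.n_species,
        "n_standards": len(lib.standards),
        "n_transitions": lib.n_transitions,
    }
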