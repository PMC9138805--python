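"""The default 17-class plasma screening panel configuration.

The published per-class library sizes (SM 12, CE 21, Cer 62, TAG 445, DAG 50,
MAG 17, LPC 16, PC 79, LPE 16, PE 142, LPG 16, PG 78, LPI 16, PI 77, LPS 16,
PS 78, PA 77 -- 1218 entries plus 12 internal standards) are reproduced by
explicit species enumeration. The enumeration itself is a configuration
default, not a claim about the exact species identities of any particular
instrument panel: species are generated in canonical (carbons, double-bonds)
order within chemically sensible per-class bounds and truncated at the
configured class size.

TAG entries are sn-isomer transitions -- one per (species, lost fatty acid)
with the lost acid drawn from a nine-acid pool of chains common in plasma
(14:0, 16:0, 16:1, 18:0, 18:1, 18:2, 18:3, 20:4, 22:6). Diacyl phospholipid
entries designate a single quantifier chain (an even split of the totals) for
the negative-mode carboxylate product; richer isomer-resolving composition
lists can be configured per species (see ``SpeciesEntry.compositions``).

Retention-time expectations follow the class-anchored linear model: the class
internal standard's retention time anchors the class, a small linear offset
in carbons and double bonds spreads species over the class elution range, and
predictions are clipped to that range (PC 9.09-11.59 min and SM 11.74-12.38
min per the HILIC class windows; other ranges are configuration defaults
around each class anchor).
"""

from __future__ import annotations

from .library import ClassRuleSet, MrmTransition, RtModel, SpeciesEntry
from . import mz as _mz
from .species import FattyAcyl, LipidSpecies, parse_species

__all__ = [
    "TABLE_CLASS_COUNTS",
    "DEFAULT_TAG_FA_POOL",
    "default_class_configs",
    "default_standards",
    "default_library",
]

#: Published per-class library sizes (species granularity; TAG at isomer
#: granularity as published).
TABLE_CLASS_COUNTS: dict[str, int] = {
    "SM": 12, "CE": 21, "Cer": 62, "TAG": 445, "DAG": 50, "MAG": 17,
    "LPC": 16, "PC": 79, "LPE": 16, "PE": 142, "LPG": 16, "PG": 78,
    "LPI": 16, "PI": 77, "LPS": 16, "PS": 78, "PA": 77,
}

#: Default pool of sn-position fatty-acid losses for TAG isomer transitions.
DEFAULT_TAG_FA_POOL: tuple[FattyAcyl, ...] = (
    FattyAcyl(14, 0), FattyAcyl(16, 0), FattyAcyl(16, 1),
    FattyAcyl(18, 0), FattyAcyl(18, 1), FattyAcyl(18, 2), FattyAcyl(18, 3),
    FattyAcyl(20, 4), FattyAcyl(22, 6),
)

_POS_VOLTS = dict(dp=80.0, ep=10.0, cxp=15.0)
_NEG_VOLTS = dict(dp=-80.0, ep=-10.0, ce=-50.0, cxp=-15.0)

# (anchor_rt, rt_min, rt_max, carbon_coeff, db_coeff, ref_c, ref_d).
# Anchors are the class internal-standard retention times; PC and SM ranges
# are the printed class elution windows, other ranges are defaults around the
# anchor. Coefficients spread each class over its window.
_RT_PARAMS: dict[str, tuple[float, float, float, float, float, float, float]] = {
    "TAG": (2.39, 1.80, 3.40, 0.050, -0.040, 54, 3),
    "DAG": (2.46, 2.10, 2.90, 0.040, -0.013, 36, 6),
    "MAG": (2.46, 2.20, 3.00, 0.080, -0.023, 18, 3),
    "CE":  (2.58, 2.20, 3.00, 0.080, -0.023, 18, 3),
    "Cer": (2.58, 2.30, 3.10, 0.080, -0.023, 36, 3),
    "SM":  (11.89, 11.74, 12.38, 0.064, -0.018, 36, 3),
    "PC":  (9.73, 9.09, 11.59, 0.125, -0.042, 36, 6),
    "PE":  (10.61, 10.11, 11.11, 0.050, -0.017, 36, 6),
    "PG":  (6.59, 6.09, 7.09, 0.050, -0.017, 36, 6),
    "PI":  (13.09, 12.59, 13.59, 0.050, -0.017, 36, 6),
    "PS":  (9.78, 9.28, 10.28, 0.050, -0.017, 36, 6),
    "PA":  (11.85, 11.35, 12.35, 0.050, -0.017, 36, 6),
    "LPC": (12.63, 12.13, 13.13, 0.100, -0.029, 18, 3),
    "LPE": (13.09, 12.59, 13.59, 0.100, -0.029, 18, 3),
    "LPG": (6.59, 6.09, 7.09, 0.100, -0.029, 18, 3),
    "LPI": (13.09, 12.59, 13.59, 0.100, -0.029, 18, 3),
    "LPS": (9.78, 9.28, 10.28, 0.100, -0.029, 18, 3),
}

# Table-1 collision energies differ for a few positive classes.
_CE_VOLTS = {"SM": 43.0, "CE": 43.0, "Cer": 43.0, "MAG": 25.0, "TAG": 38.0, "DAG": 25.0}


def _rt_model(cls: str) -> RtModel:
    a, lo, hi, cc, dc, rc, rd = _RT_PARAMS[cls]
    return RtModel(a, lo, hi, cc, dc, rc, rd)


def _split_chains(carbons: int, double_bonds: int) -> tuple[FattyAcyl, FattyAcyl]:
    """Deterministic even split of diacyl totals into two library chains."""
    k1 = carbons // 2
    k2 = carbons - k1
    d2 = min(double_bonds, 6, (k2 - 2) // 2)
    d1 = double_bonds - d2
    return FattyAcyl(k1, d1), FattyAcyl(k2, d2)


def _single_chain_entries(cls: str, n: int) -> tuple[SpeciesEntry, ...]:
    """Acyl enumeration for single-chain classes (CE/MAG/lyso) and SM/Cer."""
    entries = []
    for k in range(14, 23):
        for dk in range(0, 7):
            if dk > (k - 2) // 2:
                continue
            if cls == "Cer" and (k, dk) == (17, 0):
                continue  # reserved for the Cer(d18:1/17:0) internal standard
            if cls in ("SM", "Cer"):
                sp = LipidSpecies(cls, 18 + k, 1 + dk)
            else:
                sp = LipidSpecies(cls, k, dk)
            entries.append(SpeciesEntry(sp, compositions=((FattyAcyl(k, dk),),)
                                        if cls.startswith("L") else ()))
            if len(entries) == n:
                return tuple(entries)
    raise ValueError(f"cannot enumerate {n} species for {cls}")


def _diacyl_entries(cls: str, n: int) -> tuple[SpeciesEntry, ...]:
    """Diacyl enumeration (phospholipids and DAG) over 28-44 C, 0-12 DB."""
    entries = []
    for c in range(28, 45):
        for d in range(0, 13):
            if d > (c - 4) // 2:
                continue
            fa1, fa2 = _split_chains(c, d)
            sp = LipidSpecies(cls, c, d)
            if cls == "DAG":
                entries.append(SpeciesEntry(sp, lost_fas=(fa1,)))
            else:
                entries.append(SpeciesEntry(sp, compositions=((fa2,),)))
            if len(entries) == n:
                return tuple(entries)
    raise ValueError(f"cannot enumerate {n} species for {cls}")


def _tag_entries(n: int) -> tuple[SpeciesEntry, ...]:
    """TAG sn-isomer enumeration: (species, lost FA) pairs to exactly ``n``."""
    entries = []
    count = 0
    for c in range(42, 67):
        for d in range(0, 8):
            sp = LipidSpecies("TAG", c, d)
            losses = []
            for fa in DEFAULT_TAG_FA_POOL:
                c_rem = c - fa.carbons
                d_rem = d - fa.double_bonds
                if (
                    28 <= c_rem <= 44
                    and 0 <= d_rem <= 12
                    and d_rem <= (c_rem - 4) // 2
                ):
                    losses.append(fa)
            if not losses:
                continue
            if count + len(losses) > n:
                losses = losses[: n - count]
            entries.append(SpeciesEntry(sp, lost_fas=tuple(losses)))
            count += len(losses)
            if count == n:
                return tuple(entries)
    raise ValueError(f"cannot enumerate {n} TAG isomer transitions")


def default_class_configs(
    class_counts: dict[str, int] | None = None
) -> list[ClassRuleSet]:
    """Build the 17 default class rule sets (counts overridable per class)."""
    counts = dict(TABLE_CLASS_COUNTS)
    if class_counts:
        counts.update(class_counts)
    configs: list[ClassRuleSet] = []
    for cls, n in counts.items():
        if n == 0:
            continue
        if cls == "TAG":
            entries = _tag_entries(n)
            rule = "fa-neutral-loss"
        elif cls == "DAG":
            entries = _diacyl_entries(cls, n)
            rule = "fa-neutral-loss"
        elif cls in ("SM", "Cer", "CE"):
            entries = _single_chain_entries(cls, n)
            rule = "headgroup"
        elif cls == "MAG":
            entries = _single_chain_entries(cls, n)
            rule = "dehydration"
        elif cls.startswith("L"):
            entries = _single_chain_entries(cls, n)
            rule = "fa-carboxylate"
        else:
            entries = _diacyl_entries(cls, n)
            rule = "fa-carboxylate"
        if _mz.CLASS_ION_MODE[cls] == "positive":
            volts = dict(_POS_VOLTS, ce=_CE_VOLTS[cls])
        else:
            volts = dict(_NEG_VOLTS)
        configs.append(ClassRuleSet(cls, rule, entries, _rt_model(cls), **volts))
    return configs


# Internal standards: species text, retention time (min) and voltages as
# shipped with the panel; Q1/Q3 are computed, never transcribed.
_STANDARDS: list[tuple[str, str, float, float]] = [
    # (class, species text, RT, CE volt)
    ("SM", "SM(d18:1/18:1(d9))", 11.89, 43.0),
    ("Cer", "Cer(d18:1/17:0)", 2.58, 43.0),
    ("TAG", "TAG(15:0/18:1(d7)/15:0)", 2.39, 38.0),
    ("DAG", "DAG(15:0/18:1(d7))", 2.46, 25.0),
    ("LPC", "LPC 18:1(d7)", 12.63, -50.0),
    ("PC", "PC(15:0/18:1(d7))", 9.73, -50.0),
    ("LPE", "LPE 18:1(d7)", 13.09, -50.0),
    ("PE", "PE(15:0/18:1(d7))", 10.61, -50.0),
    ("PG", "PG(15:0/18:1(d7))", 6.59, -50.0),
    ("PI", "PI(15:0/18:1(d7))", 13.09, -50.0),
    ("PS", "PS(15:0/18:1(d7))", 9.78, -50.0),
    ("PA", "PA(15:0/18:1(d7))", 11.85, -50.0),
]

_OLEATE_D7 = FattyAcyl(18, 1, 7)
_PENTADECANOATE = FattyAcyl(15, 0)


def default_standards() -> list[MrmTransition]:
    """The 12 deuterated class internal standards with computed Q1/Q3."""
    out = []
    for cls, text, rt, ce in _STANDARDS:
        sp = parse_species(text)
        q1 = _mz.precursor_mz(sp)
        mode = _mz.CLASS_ION_MODE[cls]
        if cls in ("SM", "Cer"):
            q3 = _mz.headgroup_product_mz(cls)
            rule = "headgroup"
        elif cls in ("TAG", "DAG"):
            q3 = _mz.product_mz_neutral_loss_fa(sp, _PENTADECANOATE)
            rule = "fa-neutral-loss"
        else:
            q3 = _mz.fa_carboxylate_mz(_OLEATE_D7)
            rule = "fa-carboxylate"
        sign = 1.0 if mode == "positive" else -1.0
        out.append(
            MrmTransition(
                id=f"ISTD_{cls}", species=sp, q1=q1, q3=q3, ion_mode=mode,
                expected_rt=rt, dp=sign * 80.0, ep=sign * 10.0, ce=ce,
                cxp=sign * 15.0, is_internal_standard=True, product_rule=rule,
            )
        )
    return out


def default_library(class_counts: dict[str, int] | None = None):
    """Assemble the full default panel (1218 entries + 12 standards)."""
    from .library import assemble_library

    return assemble_library(
        default_class_configs(class_counts),
        default_standards(),
        fa_pool=list(DEFAULT_TAG_FA_POOL),
    )
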