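"""Vendor-flavored transition-list CSV reader/writer.

Columns: id, species, Q1, Q3, ion_mode, RT, DP, EP, CE, CXP, rt_window,
dwell_weight, is_internal_standard, lost_fa, product_rule. m/z values are
written at 4 decimals and round-trip bit-identically at that precision.
"""

from __future__ import annotations

import pandas as pd

from .library import MrmTransition, TransitionLibrary
from .species import FattyAcyl, parse_species

__all__ = ["library_to_frame", "write_library_csv", "read_library_csv"]

_COLUMNS = [
    "id", "species", "Q1", "Q3", "ion_mode", "RT", "DP", "EP", "CE", "CXP",
    "rt_window", "dwell_weight", "is_internal_standard", "lost_fa",
    "product_rule",
]


def _fa_str(fa: FattyAcyl | None) -> str:
    return "" if fa is None else str(fa)


def _parse_fa(text: str) -> FattyAcyl | None:
    if not text:
        return None
    body, deut = text, 0
    if "(d" in text:
        body, rest = text.split("(d")
        deut = int(rest.rstrip(")"))
    c, d = body.split(":")
    return FattyAcyl(int(c), int(d), deut)


def library_to_frame(lib: TransitionLibrary) -> pd.DataFrame:
    rows = []
    for tr in lib.all_transitions:
        rows.append({
            "id": tr.id,
            "species": str(tr.species),
            "Q1": round(tr.q1, 4),
            "Q3": round(tr.q3, 4),
            "ion_mode": tr.ion_mode,
            "RT": round(tr.expected_rt, 4),
            "DP": tr.dp, "EP": tr.ep, "CE": tr.ce, "CXP": tr.cxp,
            "rt_window": "" if tr.rt_halfwidth is None else round(tr.rt_halfwidth, 4),
            "dwell_weight": tr.dwell_weight,
            "is_internal_standard": tr.is_internal_standard,
            "lost_fa": _fa_str(tr.lost_fa),
            "product_rule": tr.product_rule,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_library_csv(lib: TransitionLibrary, path) -> None:
    library_to_frame(lib).to_csv(path, index=False)


def read_library_csv(path) -> TransitionLibrary:
    df = pd.read_csv(path, keep_default_na=False, dtype={"lost_fa": str, "rt_window": str})
    lib = TransitionLibrary()
    for row in df.itertuples(index=False):
        tr = MrmTransition(
            id=row.id,
            species=parse_species(row.species),
            q1=float(row.Q1),
            q3=float(row.Q3),
            ion_mode=row.ion_mode,
            expected_rt=float(row.RT),
            dp=float(row.DP), ep=float(row.EP), ce=float(row.CE), cxp=float(row.CXP),
            rt_halfwidth=float(row.rt_window) if row.rt_window != "" else None,
            dwell_weight=float(row.dwell_weight),
            is_internal_standard=bool(row.is_internal_standard),
            lost_fa=_parse_fa(row.lost_fa),
            product_rule=row.product_rule,
        )
        (lib.standards if tr.is_internal_standard else lib.transitions).append(tr)
    return lib
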