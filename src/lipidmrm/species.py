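"""Lipid species and fatty-acyl chain identities.

A ``LipidSpecies`` is the chemical identity everything downstream derives
from: a lipid class, a total carbon / double-bond count, optionally the
individual fatty-acyl chains (when the composition is known) and an optional
deuterium label. Sphingolipids (SM, Cer) are fixed on the d18:1 sphingoid
backbone; when chains are given for them, the first chain is the sphingoid.

Text conventions accepted by :func:`parse_species` (separators ``/``, ``-``
or the en-dash as printed in vendor lists):

* ``"PC 38:4"`` -- class plus totals;
* ``"PC(16:0/22:4)"`` -- known composition;
* ``"PA(15:0-18:1(d7))"`` -- composition with a deuterated chain;
* ``"Cer(d18:1/17:0)"`` -- sphingolipid with explicit sphingoid backbone;
* ``"LPC 18:1(d7)"`` -- single-chain species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "FattyAcyl",
    "LipidSpecies",
    "LIPID_CLASSES",
    "SPHINGOID_CLASSES",
    "LYSO_CLASSES",
    "parse_species",
]

#: The 17 supported lipid classes.
LIPID_CLASSES = frozenset(
    {
        "SM", "Cer", "CE", "MAG", "DAG", "TAG",
        "PA", "LPC", "PC", "LPE", "PE", "LPI", "PI",
        "LPG", "PG", "LPS", "PS",
    }
)

SPHINGOID_CLASSES = frozenset({"SM", "Cer"})
LYSO_CLASSES = frozenset({"LPC", "LPE", "LPG", "LPI", "LPS"})

#: Number of fatty-acyl chains per class (sphingoid backbone counted for SM/Cer).
N_CHAINS = {
    "MAG": 1, "DAG": 2, "TAG": 3, "CE": 1,
    "PA": 2, "PC": 2, "PE": 2, "PG": 2, "PI": 2, "PS": 2,
    "LPC": 1, "LPE": 1, "LPG": 1, "LPI": 1, "LPS": 1,
    "SM": 2, "Cer": 2,
}


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty-acyl chain: carbons, double bonds, optional deuterium count.

    Library chains run 14-22 carbons with 0-6 double bonds; internal
    standards may fall outside (e.g. 15:0), so only chemical realizability
    is enforced here and library bounds are a separate predicate.
    """

    carbons: int
    double_bonds: int
    deuterium: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"fatty acyl needs >= 2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds <= (self.carbons - 2) // 2:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} is not a realizable chain "
                f"(double bonds must lie in [0, (C-2)/2])"
            )
        if self.deuterium < 0:
            raise ValueError("deuterium count must be >= 0")

    @property
    def in_library_bounds(self) -> bool:
        """True when within the library panel bounds (14-22 C, 0-6 DB)."""
        return 14 <= self.carbons <= 22 and 0 <= self.double_bonds <= 6

    def __str__(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.deuterium:
            s += f"(d{self.deuterium})"
        return s


#: The fixed sphingoid backbone (d18:1) used for SM and Cer.
SPHINGOID_D18_1 = FattyAcyl(18, 1)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species identified by class and acyl composition."""

    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    chains: tuple[FattyAcyl, ...] | None = None
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unsupported lipid class {self.lipid_class!r}")
        if self.total_carbons <= 0 or self.total_double_bonds < 0:
            raise ValueError("totals must be positive carbons, non-negative DB")
        if self.chains is not None:
            if len(self.chains) != N_CHAINS[self.lipid_class]:
                raise ValueError(
                    f"{self.lipid_class} takes {N_CHAINS[self.lipid_class]} "
                    f"chains, got {len(self.chains)}"
                )
            if self.lipid_class in SPHINGOID_CLASSES:
                sph = self.chains[0]
                if (sph.carbons, sph.double_bonds) != (18, 1):
                    raise ValueError(
                        f"{self.lipid_class} backbone is fixed to d18:1, "
                        f"got {sph}"
                    )
            c = sum(ch.carbons for ch in self.chains)
            d = sum(ch.double_bonds for ch in self.chains)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise ValueError(
                    f"chains sum to {c}:{d}, totals say "
                    f"{self.total_carbons}:{self.total_double_bonds}"
                )
        if self.label is not None and not re.fullmatch(r"d\d+", self.label):
            raise ValueError(f"label must look like 'd7', got {self.label!r}")

    @property
    def deuterium_count(self) -> int:
        """Number of H->D substitutions carried by the species."""
        if self.chains is not None:
            n = sum(ch.deuterium for ch in self.chains)
            if n:
                return n
        if self.label is not None:
            return int(self.label[1:])
        return 0

    def __str__(self) -> str:
        if self.chains is not None:
            parts = []
            for i, ch in enumerate(self.chains):
                if i == 0 and self.lipid_class in SPHINGOID_CLASSES:
                    parts.append(f"d{ch}")
                else:
                    parts.append(str(ch))
            return f"{self.lipid_class}({'/'.join(parts)})"
        s = f"{self.lipid_class} {self.total_carbons}:{self.total_double_bonds}"
        if self.label:
            s += f"({self.label})"
        return s


_CHAIN = re.compile(r"(d?)(\d+):(\d+)(?:\(d(\d+)\))?$")
_SEPARATORS = re.compile(r"[/–—_]|(?<=\))-|-(?=d?\d+:)")


def _parse_chain(token: str) -> tuple[FattyAcyl, bool]:
    m = _CHAIN.fullmatch(token.strip())
    if not m:
        raise ValueError(f"cannot parse chain token {token!r}")
    sphingoid = bool(m.group(1))
    fa = FattyAcyl(int(m.group(2)), int(m.group(3)), int(m.group(4) or 0))
    return fa, sphingoid


def parse_species(text: str) -> LipidSpecies:
    """Parse a species string (see module docstring for accepted forms)."""
    text = text.strip()
    m = re.fullmatch(r"([A-Za-z]+)\s*\((.+)\)", text)
    if m and ":" in m.group(2):
        cls, body = m.group(1), m.group(2)
    else:
        m = re.fullmatch(r"([A-Za-z]+)\s+(.+)", text)
        if not m:
            raise ValueError(f"cannot parse species {text!r}")
        cls, body = m.group(1), m.group(2)
    if cls not in LIPID_CLASSES:
        raise ValueError(f"unsupported lipid class {cls!r}")

    label = None
    lm = re.fullmatch(r"(.+?)\s*\((d\d+)\)", body)
    # A trailing (dN) is a chain label when it follows a chain token; treat it
    # as a species-level label only for the totals form "CLASS C:D(d7)".
    if lm and re.fullmatch(r"\d+:\d+", lm.group(1).strip()) and N_CHAINS[cls] > 1:
        body, label = lm.group(1).strip(), lm.group(2)

    tokens = [t for t in _SEPARATORS.split(body) if t and t.strip()]
    if len(tokens) == 1 and N_CHAINS[cls] > 1:
        fa, sph = _parse_chain(tokens[0])
        if sph:
            raise ValueError(f"lone sphingoid chain in {text!r}")
        return LipidSpecies(cls, fa.carbons, fa.double_bonds, None,
                            label or (f"d{fa.deuterium}" if fa.deuterium else None))
    chains: list[FattyAcyl] = []
    sphingoid_seen = False
    for tok in tokens:
        fa, sph = _parse_chain(tok)
        sphingoid_seen = sphingoid_seen or sph
        chains.append(fa)
    if len(chains) == 1 and N_CHAINS[cls] == 1:
        fa = chains[0]
        return LipidSpecies(cls, fa.carbons, fa.double_bonds, (fa,))
    if cls in SPHINGOID_CLASSES:
        if not sphingoid_seen:
            raise ValueError(f"{cls} composition must carry the d18:1 backbone: {text!r}")
    c = sum(ch.carbons for ch in chains)
    d = sum(ch.double_bonds for ch in chains)
    return LipidSpecies(cls, c, d, tuple(chains), label)
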