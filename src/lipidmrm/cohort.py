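"""Synthetic two-group lipidomics cohort generation.

The generator emulates the structure of a case/control plasma screen: two
groups of roughly equal size, log-normally distributed species areas with
per-class species counts inherited from the screening panel, a handful of
planted fold-change effects, additive/multiplicative batch effects on the
log scale, a sex covariate with small per-species effects, and sparse
missing values. Everything is deterministic under the design's seed.

It emulates realistic *marginal* structure; it does not model correlated
lipid co-regulation networks, class-wide shifts, or abundance-dependent
missingness, so pipeline results on it speak to statistical calibration and
power, not to biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import LipidMatrix

__all__ = ["CohortDesign", "generate_cohort", "default_cohort_species"]

# Per-class share of the retained panel (scaled from the screening library's
# class sizes to the 759 consistently observed species).
_PANEL_CLASS_COUNTS = {
    "SM": 12, "CE": 21, "Cer": 62, "TAG": 445, "DAG": 50, "MAG": 17,
    "LPC": 16, "PC": 79, "LPE": 16, "PE": 142, "LPG": 16, "PG": 78,
    "LPI": 16, "PI": 77, "LPS": 16, "PS": 78, "PA": 77,
}


def default_cohort_species(n_species: int = 759) -> pd.Series:
    """Species -> class map with per-class counts scaled from the panel."""
    total = sum(_PANEL_CLASS_COUNTS.values())
    names: list[str] = []
    classes: list[str] = []
    scaled = {
        cls: max(2, round(cnt * n_species / total))
        for cls, cnt in _PANEL_CLASS_COUNTS.items()
    }
    # fix rounding drift on the largest class
    drift = n_species - sum(scaled.values())
    scaled["TAG"] += drift
    for cls, cnt in scaled.items():
        for i in range(cnt):
            c = 28 + (i % 17)
            d = (i // 17) % 7
            names.append(f"{cls} {c}:{d}#{i}")
            classes.append(cls)
    return pd.Series(classes, index=names, name="lipid_class")


def _default_planted(species: pd.Series) -> tuple[tuple[str, float], ...]:
    """18 planted effects (|FC| >= 1.5): TAG-heavy up, a few down."""
    by_cls = {cls: list(species.index[species == cls]) for cls in species.unique()}
    planted: list[tuple[str, float]] = []
    tag = by_cls.get("TAG", [])
    ups = [1.5, 1.6, 1.7, 1.8, 1.9, 2.0, 1.5, 1.6, 1.7, 1.8, 2.2]
    for name, fc in zip(tag[10 : 10 + len(ups)], ups):
        planted.append((name, fc))
    planted.append((tag[30], 1 / 1.6))  # one down-regulated TAG
    planted.append((by_cls["LPC"][3], 1 / 1.7))
    planted.append((by_cls["PA"][5], 1 / 1.5))
    for name, fc in zip(by_cls["PC"][4:6], (1.5, 1.8)):
        planted.append((name, fc))
    for name, fc in zip(by_cls["PE"][7:9], (1.6, 2.0)):
        planted.append((name, fc))
    return tuple(planted)


@dataclass(frozen=True)
class CohortDesign:
    """Synthetic cohort parameters.

    Defaults mirror the screening study's structure: 47 deficient vs 46
    normal samples, 759 species, 18 planted effects with fold changes of
    at least 1.5 in magnitude, two acquisition batches and a sex covariate.
    ``sigma_log`` is the natural-log biological + technical SD per species
    (0.35 corresponds to an area CV of ~36%, the lower end of reported
    between-subject variability, appropriate because class-sum
    normalization removes variation shared within a class).
    """

    n_deficient: int = 47
    n_normal: int = 46
    species_class: pd.Series | None = None  # default: 759-species panel
    planted: tuple[tuple[str, float], ...] | None = None  # default: 18 effects
    n_batches: int = 2
    batch_loc_sd: float = 0.3  # natural-log additive batch effect SD
    batch_scale_sd: float = 0.1  # log of multiplicative scale factor SD
    sigma_log: float = 0.35
    sex_effect_sd: float = 0.05
    base_log10_mean: float = 6.0
    base_log10_sd: float = 0.8
    planted_log10_mean: float = 5.5
    planted_log10_sd: float = 0.3
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_deficient < 2 or self.n_normal < 2:
            raise ValueError("need >= 2 samples per group")
        if self.planted is not None and self.species_class is not None:
            missing = [s for s, _ in self.planted if s not in self.species_class.index]
            if missing:
                raise ValueError(f"planted species not in panel: {missing[:3]}")
        if self.planted is not None and any(fc <= 0 for _, fc in self.planted):
            raise ValueError("fold changes must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def generate_cohort(design: CohortDesign | None = None) -> LipidMatrix:
    """Draw one synthetic cohort matrix per the design (seed-deterministic)."""
    design = design or CohortDesign()
    species = (
        design.species_class
        if design.species_class is not None
        else default_cohort_species()
    )
    planted = (
        design.planted if design.planted is not None else _default_planted(species)
    )
    rng = np.random.default_rng(design.seed)
    n = design.n_deficient + design.n_normal
    p = species.size
    groups = np.array(
        ["deficient"] * design.n_deficient + ["normal"] * design.n_normal
    )
    # balanced batch assignment within group to avoid confounding
    batch = np.empty(n, dtype=int)
    for g in ("deficient", "normal"):
        idx = np.flatnonzero(groups == g)
        batch[idx] = np.arange(idx.size) % design.n_batches
    sex = rng.choice(["F", "M"], size=n, p=[0.58, 0.42])
    age = rng.integers(25, 60, size=n)

    # Log-normal base abundances: within-class profiles are heavy-tailed but
    # not single-species dominated, as in real plasma class compositions.
    mu = np.log(10.0) * rng.normal(design.base_log10_mean, design.base_log10_sd, p)
    log_fc = np.zeros(p)
    cols = list(species.index)
    col_pos = {name: j for j, name in enumerate(cols)}
    for name, fc in planted:
        j = col_pos[name]
        log_fc[j] = np.log(fc)
        # Planted species sit at moderate abundance so their shifts leave the
        # class totals essentially unaltered (individual species change while
        # classes as a whole do not) and class-sum normalization does not
        # leak the planted effects into null species.
        mu[j] = np.log(10.0) * rng.normal(
            design.planted_log10_mean, design.planted_log10_sd
        )
    batch_loc = rng.normal(0.0, design.batch_loc_sd, (design.n_batches, p))
    batch_scale = np.exp(rng.normal(0.0, design.batch_scale_sd, (design.n_batches, p)))
    sex_eff = rng.normal(0.0, design.sex_effect_sd, p)

    eps = rng.normal(0.0, design.sigma_log, (n, p))
    log_area = (
        mu
        + np.where(groups == "deficient", 1.0, 0.0)[:, None] * log_fc
        + batch_loc[batch]
        + batch_scale[batch] * eps
        + np.where(sex == "F", 1.0, 0.0)[:, None] * sex_eff
    )
    areas = np.exp(log_area)
    if design.missing_rate > 0:
        mask = rng.random((n, p)) < design.missing_rate
        areas = np.where(mask, np.nan, areas)

    sample_ids = [f"S{i:03d}" for i in range(n)]
    return LipidMatrix(
        areas=pd.DataFrame(areas, index=sample_ids, columns=cols),
        sample_meta=pd.DataFrame(
            {"group": groups, "batch": batch, "sex": sex, "age": age},
            index=sample_ids,
        ),
        species_class=species,
    )
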