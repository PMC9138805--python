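"""Two-group differential lipid screening.

The analysis chain mirrors common practice for targeted lipidomics cohorts:

1. drop species missing in too many samples, impute the rest with the
   species median, and sum-normalize within lipid class per sample;
2. remove batch (and preserve group/sex) effects with parametric
   empirical-Bayes adjustment (:class:`~lipidmrm.combat.ComBatAdjuster`,
   applied on the log scale);
3. screen species by two-sided Wilcoxon rank-sum p-value and group
   fold change;
4. Benjamini-Hochberg adjust the p-values;
5. run Boruta-style random-forest selection on the screened candidates.

Fold change is the deficient/normal ratio of group means of the normalized
values (a median-ratio variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .boruta import BorutaSelector
from .combat import ComBatAdjuster

__all__ = [
    "LipidMatrix",
    "DEResult",
    "preprocess",
    "class_sum_normalize",
    "batch_adjust",
    "wilcoxon_screen",
    "bh_adjust",
    "boruta_select",
    "abundance_shares",
    "run_differential_pipeline",
]

GROUP_LEVELS = ("deficient", "normal")


@dataclass
class LipidMatrix:
    """Samples x species area table with sample and species annotations.

    ``areas`` holds non-negative areas (NaN marks missing values);
    ``sample_meta`` is indexed like the rows and carries at least ``group``
    (deficient | normal) and ``batch``; ``species_class`` maps each column
    to its lipid class.
    """

    areas: pd.DataFrame
    sample_meta: pd.DataFrame
    species_class: pd.Series

    def __post_init__(self) -> None:
        if not self.areas.index.equals(self.sample_meta.index):
            raise ValueError("areas and sample_meta must share the sample index")
        unlabeled = [c for c in self.areas.columns if c not in self.species_class.index]
        if unlabeled:
            raise ValueError(f"species without class labels: {unlabeled[:3]}")
        if "group" not in self.sample_meta:
            raise ValueError("sample_meta needs a 'group' column")
        bad = set(self.sample_meta["group"]) - set(GROUP_LEVELS)
        if bad:
            raise ValueError(f"group labels must be in {GROUP_LEVELS}, got {bad}")
        vals = self.areas.to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise ValueError("areas must be non-negative")

    def copy_with(self, areas: pd.DataFrame) -> "LipidMatrix":
        return LipidMatrix(
            areas, self.sample_meta, self.species_class.loc[list(areas.columns)]
        )


def class_sum_normalize(matrix: LipidMatrix) -> LipidMatrix:
    """Divide each species by its lipid-class total within each sample."""
    areas = matrix.areas.astype(float).copy()
    classes = matrix.species_class.loc[list(areas.columns)]
    for cls in classes.unique():
        cols = list(classes.index[classes == cls])
        totals = areas[cols].sum(axis=1)
        if (totals == 0).any():
            raise ValueError(f"class {cls} sums to zero in some sample")
        areas[cols] = areas[cols].div(totals, axis=0)
    return matrix.copy_with(areas)


def preprocess(
    matrix: LipidMatrix, missing_sample_cutoff: int = 10
) -> LipidMatrix:
    """Filter, impute and class-sum-normalize a raw cohort matrix.

    Species missing in ``missing_sample_cutoff`` or more samples are
    removed; remaining missing values are imputed with the species median
    pooled across both groups; each sample is then normalized within lipid
    class.
    """
    areas = matrix.areas.astype(float)
    n_missing = areas.isna().sum(axis=0)
    keep = n_missing[n_missing < missing_sample_cutoff].index
    if (areas[keep].isna().all(axis=0)).any():
        raise ValueError("species with all values missing survived the filter")
    areas = areas[keep].fillna(areas[keep].median(axis=0))
    return class_sum_normalize(matrix.copy_with(areas))


def batch_adjust(
    matrix: LipidMatrix,
    covariates: tuple[str, ...] = ("group", "sex"),
    log_scale: bool = True,
) -> LipidMatrix:
    """ComBat-style batch adjustment preserving biological covariates.

    The adjustment runs on log2 areas by default (multiplicative batch
    effects become location/scale effects there) and is exponentiated
    back. Batch confounded with group raises.
    """
    meta = matrix.sample_meta
    if "batch" not in meta:
        raise ValueError("sample_meta needs a 'batch' column")
    cov_cols = []
    for name in covariates:
        if name not in meta:
            continue
        col = meta[name]
        if col.dtype.kind in "OUSb":
            col = pd.Categorical(col).codes
        cov_cols.append(np.asarray(col, dtype=float))
    cov = np.column_stack(cov_cols) if cov_cols else None
    vals = matrix.areas.to_numpy(dtype=float)
    if log_scale:
        if np.any(vals <= 0):
            raise ValueError("log-scale adjustment needs strictly positive areas")
        vals = np.log2(vals)
    adjusted = ComBatAdjuster().fit_transform(
        vals, batch=meta["batch"].to_numpy(), covariates=cov
    )
    if log_scale:
        adjusted = np.exp2(adjusted)
    return matrix.copy_with(
        pd.DataFrame(adjusted, index=matrix.areas.index, columns=matrix.areas.columns)
    )


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    normal approximation with tie correction otherwise."""
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0
    pooled = np.concatenate([x, y])
    exact = pooled.size <= 20 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def wilcoxon_screen(
    matrix: LipidMatrix,
    fc_threshold: float = 1.3,
    p_threshold: float = 0.05,
    fc_stat: str = "mean",
) -> pd.DataFrame:
    """Per-species fold change and rank-sum p, with the screening gate.

    Returns a frame indexed by species with columns ``fold_change``,
    ``p_value`` and ``candidate`` (|log FC| beyond the threshold AND
    p below the threshold). Fold change is deficient over normal.
    """
    groups = matrix.sample_meta["group"]
    a = matrix.areas[groups == "deficient"].to_numpy(dtype=float)
    b = matrix.areas[groups == "normal"].to_numpy(dtype=float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    stat = np.mean if fc_stat == "mean" else np.median
    fc = stat(a, axis=0) / stat(b, axis=0)
    pvals = np.array([_rank_sum_p(a[:, j], b[:, j]) for j in range(a.shape[1])])
    candidate = ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)) & (
        pvals < p_threshold
    )
    return pd.DataFrame(
        {"fold_change": fc, "p_value": pvals, "candidate": candidate},
        index=matrix.areas.columns,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def boruta_select(
    matrix: LipidMatrix,
    candidates: list[str],
    seed: int = 0,
    max_iter: int = 100,
    n_estimators: int = 100,
    alpha: float = 0.01,
) -> pd.Series:
    """Boruta decisions for the screened candidate species.

    The forest is fit on log2 of the candidate columns against the group
    label; returns a Series species -> confirmed/rejected/tentative.
    """
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate species")
    X = np.log2(matrix.areas[candidates].to_numpy(dtype=float))
    y = (matrix.sample_meta["group"] == "deficient").to_numpy(dtype=int)
    sel = BorutaSelector(
        n_estimators=n_estimators, max_iter=max_iter, alpha=alpha,
        random_state=seed,
    ).fit(X, y)
    return pd.Series(sel.decisions_, index=candidates)


def abundance_shares(
    areas: pd.DataFrame,
    species_col: str = "species",
    isomer_col: str = "isomer",
    area_col: str = "area",
) -> tuple[pd.Series, pd.Series]:
    """Fractional abundances at species and isomer level.

    ``areas`` is long-format with one row per isomer. Returns
    ``(species_shares, isomer_shares)``: each species' share of the grand
    total, and each isomer's share within its own species. Shares sum to 1
    at both levels.
    """
    if (areas[area_col] < 0).any():
        raise ValueError("areas must be non-negative")
    grand = areas[area_col].sum()
    if grand == 0:
        raise ValueError("zero grand total")
    species_totals = areas.groupby(species_col)[area_col].sum()
    species_shares = species_totals / grand
    isomer_shares = areas.set_index([species_col, isomer_col])[area_col] / areas.groupby(
        species_col
    )[area_col].transform("sum").to_numpy()
    return species_shares, isomer_shares


@dataclass
class DEResult:
    """Differential screening outcome."""

    table: pd.DataFrame  # species x (fold_change, p_value, q_value, candidate, decision)
    confirmed: list[str] = field(default_factory=list)

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[self.table["candidate"]])


def run_differential_pipeline(
    matrix: LipidMatrix,
    seed: int = 0,
    missing_sample_cutoff: int = 10,
    fc_threshold: float = 1.3,
    p_threshold: float = 0.05,
    adjust_batches: bool = True,
    boruta_kwargs: dict | None = None,
) -> DEResult:
    """preprocess -> batch adjust -> Wilcoxon/FC screen -> BH -> Boruta."""
    mat = preprocess(matrix, missing_sample_cutoff)
    if adjust_batches and "batch" in mat.sample_meta:
        mat = batch_adjust(mat)
    screen = wilcoxon_screen(mat, fc_threshold, p_threshold)
    screen["q_value"] = bh_adjust(screen["p_value"].to_numpy())
    decisions = pd.Series("not screened", index=screen.index, dtype=object)
    cands = list(screen.index[screen["candidate"]])
    if len(cands) >= 2:
        decisions.loc[cands] = boruta_select(
            mat, cands, seed=seed, **(boruta_kwargs or {})
        )
    screen["decision"] = decisions
    confirmed = list(screen.index[screen["decision"] == "confirmed"])
    return DEResult(screen, confirmed)
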