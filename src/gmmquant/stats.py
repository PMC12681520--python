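"""Cohort-level statistics on the analysis-ready concentration matrix.

Covers the study's statistical layer: ordinary-least-squares group
comparison of log concentrations adjusted for age and sex (group coefficient
= the PD log-offset), Mann-Whitney U subgroup tests with Holm-Sidak
step-down adjustment, Pearson chi-square on 2x2 contingency tables without
continuity correction, Spearman correlation matrices with Benjamini-Hochberg
adjustment, per-group composition profiles, PCA on standardised
concentrations, median +/- MAD clinical summaries, and the fecal/plasma Venn
partition of significant entities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .qc import QuantMatrix

__all__ = [
    "adjusted_group_test",
    "subgroup_mannwhitney",
    "mannwhitney_exact",
    "chi_square_2x2",
    "spearman_bh",
    "composition_profile",
    "pca_scores",
    "median_mad_summary",
    "venn_partition",
    "significance_label",
    "holm_sidak_adjust",
    "benjamini_hochberg_adjust",
]

#: Significance-star thresholds used for figure labels.
_STARS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sorted ascending, adjusted p_i = max over j <= i of
    1 - (1 - p_(j))^(m - j + 1), clipped to 1; monotone non-decreasing.
    """
    return multipletests(np.asarray(p_values, dtype=float), method="holm-sidak")[1]


def benjamini_hochberg_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def significance_label(p: float) -> str:
    for thr, label in _STARS:
        if p < thr:
            return label
    return "ns"


# ---------------------------------------------------------------------------
# Adjusted group comparison
# ---------------------------------------------------------------------------

def adjusted_group_test(
    qm: QuantMatrix,
    covariates: Optional[pd.DataFrame] = None,
    log_transform: bool = True,
    adjust_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-entity OLS of (log) concentration on group + age + sex.

    The matrix must be complete (post-cascade). Group is encoded HC=0/PD=1 so
    the reported effect is the PD offset on the analysis scale; sex enters as
    a female indicator, age linearly in years. Raw two-sided p-values for
    the group coefficient are adjusted across entities (Benjamini-Hochberg
    by default) and entities are returned ranked by p.

    Entities with a constant response yield an undefined test and are
    flagged (NaN p, ``constant`` flag) rather than dropped.
    """
    if not qm.is_complete():
        raise ValueError("quant matrix has missing cells; run the cascade first")
    meta = qm.sample_meta.loc[qm.values.index]
    if covariates is not None:
        meta = covariates.set_index("subject_id") if "subject_id" in covariates else covariates
        meta = meta.loc[qm.values.index]
    design = pd.DataFrame(index=qm.values.index)
    design["group"] = (meta["group"] == "PD").astype(float)
    design["age"] = meta["age"].astype(float)
    design["sex"] = (meta["sex"] == "F").astype(float)
    X = sm.add_constant(design)
    n_hc = int((design["group"] == 0).sum())
    n_pd = int((design["group"] == 1).sum())
    rows = []
    for entity in qm.entities:
        y = qm.values[entity].astype(float)
        if log_transform:
            if (y <= 0).any():
                rows.append(
                    {"entity": entity, "effect": np.nan, "p_raw": np.nan,
                     "flag": "nonpositive_values"}
                )
                continue
            y = np.log(y)
        if np.ptp(y.to_numpy()) == 0:
            rows.append(
                {"entity": entity, "effect": np.nan, "p_raw": np.nan,
                 "flag": "constant"}
            )
            continue
        fit = sm.OLS(y, X).fit()
        rows.append(
            {
                "entity": entity,
                "effect": float(fit.params["group"]),
                "p_raw": float(fit.pvalues["group"]),
                "flag": "",
            }
        )
    res = pd.DataFrame(rows)
    ok = res["p_raw"].notna()
    res["p_adjusted"] = np.nan
    if ok.any():
        res.loc[ok, "p_adjusted"] = multipletests(
            res.loc[ok, "p_raw"], method=adjust_method
        )[1]
    res["adjust_method"] = adjust_method
    res["test"] = "ols_log_group_age_sex" if log_transform else "ols_group_age_sex"
    res["covariates"] = "age,sex"
    res["n_hc"] = n_hc
    res["n_pd"] = n_pd
    return res.sort_values("p_raw", na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Nonparametric subgroup tests
# ---------------------------------------------------------------------------

def mannwhitney_exact(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when both groups have <= ``exact_max_n``
    observations and no ties straddle the groups; tie-corrected normal
    approximation (with continuity correction) otherwise.

    Returns ``(U, p)`` where U is the statistic of the first sample.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    use_exact = a.size <= exact_max_n and b.size <= exact_max_n and not has_ties
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
    )
    return (float(res.statistic), float(res.pvalue))


def subgroup_mannwhitney(
    family: Sequence[tuple[Sequence[float], Sequence[float]]],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Mann-Whitney U over a family of comparisons with Holm-Sidak adjustment.

    ``family`` is a list of (values_a, values_b) pairs tested together; the
    step-down Holm-Sidak adjustment (adjusted p_i = max over j <= i of
    1 - (1 - p_(j))^(m - j + 1), clipped to 1) is applied across the family.
    """
    if not len(family):
        raise ValueError("empty test family")
    stats_p = [mannwhitney_exact(a, b) for a, b in family]
    p_raw = np.array([p for _u, p in stats_p])
    p_adj = holm_sidak_adjust(p_raw)
    return pd.DataFrame(
        {
            "label": labels if labels is not None else list(range(len(family))),
            "U": [u for u, _p in stats_p],
            "p_raw": p_raw,
            "p_holm_sidak": p_adj,
        }
    )


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    Returns ``(statistic, p)``. The uncorrected statistic is the convention
    under which the cohort sex table (32, 25; 7, 21) yields p = 0.00677.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = scipy.stats.chi2_contingency(arr, correction=False)
    return (float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def spearman_bh(
    qm_or_frame,
    variables: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman rank correlations entity x variable with BH adjustment.

    Pairwise deletion: each pair uses its complete observations; pairs with
    fewer than ``min_pairs`` points are skipped (logged with NaN rho). The BH
    step-up adjustment runs across the full computed family; significance is
    adjusted p < alpha.
    """
    entities = (
        qm_or_frame.values if isinstance(qm_or_frame, QuantMatrix) else qm_or_frame
    )
    rows = []
    for entity in entities.columns:
        for var in variables.columns:
            paired = pd.concat(
                [entities[entity], variables[var]], axis=1, join="inner"
            ).dropna()
            if len(paired) < min_pairs:
                rows.append(
                    {"entity": entity, "variable": var, "n": len(paired),
                     "rho": np.nan, "p_raw": np.nan}
                )
                continue
            rho, p = scipy.stats.spearmanr(
                paired.iloc[:, 0], paired.iloc[:, 1]
            )
            rows.append(
                {"entity": entity, "variable": var, "n": len(paired),
                 "rho": float(rho), "p_raw": float(p)}
            )
    res = pd.DataFrame(rows)
    ok = res["p_raw"].notna()
    res["p_bh"] = np.nan
    if ok.any():
        res.loc[ok, "p_bh"] = benjamini_hochberg_adjust(res.loc[ok, "p_raw"])
    res["significant"] = res["p_bh"] < alpha
    return res


# ---------------------------------------------------------------------------
# Profiles, PCA, summaries
# ---------------------------------------------------------------------------

def composition_profile(
    qm: QuantMatrix, center: str = "mean"
) -> pd.DataFrame:
    """Per-group percentage of each entity in the summed panel total.

    Entity share = 100 x group mean (or median) concentration / sum of
    centers over entities; shares sum to 100 within each group.
    """
    if (qm.values.to_numpy() < 0).any():
        raise ValueError("negative concentrations in composition profile")
    groups = qm.groups()
    agg = qm.values.groupby(groups).mean() if center == "mean" else (
        qm.values.groupby(groups).median()
    )
    totals = agg.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero group in composition profile")
    return 100.0 * agg.div(totals, axis=0)


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_columns: tuple[str, ...] = ()


def pca_scores(
    qm_or_frame,
    scaling: str = "unit_variance",
    log_transform: bool = True,
    n_components: Optional[int] = None,
) -> PcaResult:
    """Principal component analysis of the concentration matrix.

    Columns are log-transformed (optional), centred and unit-variance scaled
    by default; zero-variance columns are dropped with a warning under unit
    scaling. Explained-variance fractions over all components sum to 1.
    """
    import warnings

    X = (
        qm_or_frame.values if isinstance(qm_or_frame, QuantMatrix) else qm_or_frame
    ).astype(float)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("PCA needs >= 2 entities and >= 3 samples")
    if log_transform:
        X = np.log(X)
    dropped: tuple[str, ...] = ()
    sd = X.std(axis=0, ddof=1)
    if scaling == "unit_variance":
        zero = sd[sd == 0].index
        if len(zero):
            warnings.warn(
                f"dropping zero-variance columns under unit scaling: {list(zero)}",
                stacklevel=2,
            )
            dropped = tuple(zero)
            X = X.drop(columns=zero)
            sd = sd.drop(zero)
        Z = (X - X.mean()) / sd
    elif scaling == "center":
        Z = X - X.mean()
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=X.columns, columns=comp_names
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_columns=dropped,
    )


def median_mad_summary(values: Sequence[float]) -> tuple[float, float]:
    """Median and raw median absolute deviation (no consistency factor)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("empty value list")
    med = float(np.median(arr))
    return (med, float(np.median(np.abs(arr - med))))


def venn_partition(
    significant_fecal: set, significant_plasma: set
) -> tuple[set, set, set]:
    """Partition significant entities into (fecal-only, shared, plasma-only)."""
    fecal = set(significant_fecal)
    plasma = set(significant_plasma)
    return (fecal - plasma, fecal & plasma, plasma - fecal)
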