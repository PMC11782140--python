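"""Covariate-adjusted nonparametric group comparison.

Each scalar EEG feature is first residualized against age, sex and
education (ordinary least squares pooled over both groups; group
membership is deliberately *not* in the design, so group differences
survive in the residuals). Residuals are compared between AD and HC
with the two-sided Mann-Whitney U test, and p-values are Bonferroni
corrected within a family. The correction family defaults to one
(metric, band, condition) block -- e.g. the 28 pairs of a connectivity
matrix, or the 8 channels of the theta/beta ratio -- and the family
size is recorded in each result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigError, DataError
from .io import FeatureTable, SubjectMeta, format_feature_name, parse_feature_name

logger = logging.getLogger(__name__)

COVARIATES = ("age", "sex", "education")


@dataclass
class GroupTestResult:
    feature: str
    u_statistic: float
    p_raw: float
    p_adj: float
    family: str
    family_size: int
    significant: bool  # at alpha after correction
    n_group1: int
    n_group2: int


def _covariate_matrix(
    metas: Sequence[SubjectMeta], subjects: Sequence[str], covariates: Sequence[str]
) -> np.ndarray:
    by_id = {m.subject_id: m for m in metas}
    missing = [s for s in subjects if s not in by_id]
    if missing:
        raise DataError(f"no metadata for subjects {missing}")
    cols = [np.ones(len(subjects))]
    for cov in covariates:
        if cov == "age":
            cols.append(np.array([by_id[s].age for s in subjects], float))
        elif cov == "sex":
            cols.append(np.array([1.0 if by_id[s].sex == "F" else 0.0 for s in subjects]))
        elif cov == "education":
            cols.append(np.array([float(by_id[s].education) for s in subjects]))
        else:
            raise ConfigError(f"unknown covariate {cov!r}")
    return np.column_stack(cols)


def residualize(
    table: FeatureTable,
    metas: Sequence[SubjectMeta],
    covariates: Sequence[str] = COVARIATES,
) -> FeatureTable:
    """OLS residuals of every feature on [intercept, covariates], pooled.

    A collinear covariate column is dropped with a warning rather than
    failing the fit.
    """
    subjects = table.subjects
    if len(subjects) < len(covariates) + 2:
        raise DataError(
            f"need at least {len(covariates) + 2} subjects to fit "
            f"{len(covariates)} covariates, got {len(subjects)}"
        )
    x = _covariate_matrix(metas, subjects, covariates)
    kept = list(covariates)
    # greedily drop covariates that do not add rank (constant/collinear)
    while np.linalg.matrix_rank(x) < x.shape[1]:
        for j in range(x.shape[1] - 1, 0, -1):
            reduced = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(x):
                dropped = kept.pop(j - 1)
                warnings.warn(f"covariate {dropped!r} is collinear; dropped", stacklevel=2)
                x = reduced
                break
        else:  # pragma: no cover - intercept alone is always full rank
            break
    y = table.df.to_numpy(float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return FeatureTable(pd.DataFrame(resid, index=table.df.index, columns=table.df.columns))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (midranks) of two independent samples.

    Exact p by enumeration when n1+n2 <= 16 and the pooled values are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections. Identical constant samples give p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and x.size + y.size <= 16) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values: Sequence[float], family_size: int) -> np.ndarray:
    """p_adj = min(1, p * family_size)."""
    p = np.asarray(p_values, float)
    if family_size < p.size:
        raise ConfigError(f"family_size {family_size} smaller than {p.size} p-values")
    return np.minimum(1.0, p * family_size)


def _family_key(feature: str, mode: str) -> str:
    metric, band, _item, cond = parse_feature_name(feature)
    if mode == "metric_band_condition":
        return f"{metric}_{band}_{cond}"
    if mode == "metric_condition":  # bands corrected jointly
        return f"{metric}_{cond}"
    if mode == "global":
        return "all"
    raise ConfigError(f"unknown family mode {mode!r}")


def build_ec_minus_eo(ec: FeatureTable, eo: FeatureTable) -> FeatureTable:
    """EC - EO difference features for every feature present in both."""
    common_subjects = [s for s in ec.subjects if s in set(eo.subjects)]
    dropped = sorted(set(ec.subjects) ^ set(eo.subjects))
    if dropped:
        warnings.warn(f"subjects missing one condition excluded: {dropped}", stacklevel=2)
    cols = {}
    eo_by_key = {}
    for c in eo.feature_names:
        metric, band, item, _ = parse_feature_name(c)
        eo_by_key[(metric, band, item if isinstance(item, str) else "-".join(item))] = c
    for c in ec.feature_names:
        metric, band, item, _ = parse_feature_name(c)
        key = (metric, band, item if isinstance(item, str) else "-".join(item))
        if key in eo_by_key:
            name = format_feature_name(metric, band, key[2], "ECminusEO")
            cols[name] = (
                ec.df.loc[common_subjects, c].to_numpy()
                - eo.df.loc[common_subjects, eo_by_key[key]].to_numpy()
            )
    return FeatureTable(pd.DataFrame(cols, index=pd.Index(common_subjects, name="subject_id")))


def group_difference_report(
    tables_by_condition: Mapping[str, FeatureTable],
    metas: Sequence[SubjectMeta],
    alpha: float = 0.05,
    covariates: Sequence[str] = COVARIATES,
    family_mode: str = "metric_band_condition",
    include_ec_minus_eo: bool = True,
) -> tuple[list[GroupTestResult], pd.DataFrame]:
    """AD-vs-HC tests over EC, EO and (optionally) EC-EO features.

    Returns the per-feature results and a tidy report frame
    (metric, band, item, condition, U, p_raw, p_adj, family, significant).
    """
    parts = [tables_by_condition[c] for c in ("EC", "EO") if c in tables_by_condition]
    if not parts:
        raise DataError("no condition tables supplied")
    if include_ec_minus_eo and "EC" in tables_by_condition and "EO" in tables_by_condition:
        parts.append(build_ec_minus_eo(tables_by_condition["EC"], tables_by_condition["EO"]))
    common = set(parts[0].subjects)
    for t in parts[1:]:
        common &= set(t.subjects)
    order = [s for s in parts[0].subjects if s in common]
    full = FeatureTable(pd.concat([t.df.loc[order] for t in parts], axis=1))

    resid = residualize(full, metas, covariates)
    by_id = {m.subject_id: m for m in metas}
    is_ad = np.array([by_id[s].group == "AD" for s in order])
    if is_ad.all() or not is_ad.any():
        raise DataError("both groups must be present")

    families: dict[str, list[str]] = {}
    for feat in resid.feature_names:
        families.setdefault(_family_key(feat, family_mode), []).append(feat)

    results: list[GroupTestResult] = []
    for fam, feats in families.items():
        logger.info("family=%s size=%d", fam, len(feats))
        stats = [
            mann_whitney_u(
                resid.df.loc[is_ad, f].to_numpy(), resid.df.loc[~is_ad, f].to_numpy()
            )
            for f in feats
        ]
        p_adj = bonferroni_adjust([p for _, p in stats], len(feats))
        for f, (u, p), pa in zip(feats, stats, p_adj):
            results.append(
                GroupTestResult(
                    feature=f,
                    u_statistic=u,
                    p_raw=p,
                    p_adj=float(pa),
                    family=fam,
                    family_size=len(feats),
                    significant=bool(pa < alpha),
                    n_group1=int(is_ad.sum()),
                    n_group2=int((~is_ad).sum()),
                )
            )

    rows = []
    for r in results:
        metric, band, item, cond = parse_feature_name(r.feature)
        rows.append(
            {
                "metric": metric,
                "band": band,
                "item": item if isinstance(item, str) else "-".join(item),
                "condition": cond,
                "U": r.u_statistic,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "family": r.family,
                "family_size": r.family_size,
                "significant": r.significant,
            }
        )
    return results, pd.DataFrame(rows)
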