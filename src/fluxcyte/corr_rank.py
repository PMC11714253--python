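"""Cross-cohort correlation ranking against T-cell cytotoxicity.

For each feature (a gene's expression, or a module's predicted flux) the
Pearson correlation with per-sample relative cytotoxicity is computed within
every cohort, averaged across the cohorts where it is defined (plain
unweighted mean), and the features are ranked by average coefficient in
increasing order — the most negatively correlated feature ranks first.  The
same machinery correlates module fluxes against individual effector-gene
expression (the branch-discrimination analysis).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .immunoscore import cytotoxicity_profile

__all__ = [
    "Cohort",
    "CohortCollection",
    "pearson",
    "rank_features",
    "flux_effector_correlation",
]

log = logging.getLogger(__name__)

#: minimum pairwise-complete observations for a defined coefficient
MIN_PAIRS = 3


@dataclass
class Cohort:
    """One dataset: expression (gene x sample), optional flux, cytotoxicity."""

    name: str
    expr: pd.DataFrame
    profile: pd.DataFrame
    flux: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not set(self.profile.index) <= set(self.expr.columns):
            raise ValueError(f"cohort {self.name}: profile samples not in expression")
        if self.flux is not None and not set(self.flux.index) <= set(self.expr.columns):
            raise ValueError(f"cohort {self.name}: flux samples not in expression")

    @classmethod
    def from_expression(cls, name: str, expr: pd.DataFrame,
                        flux: pd.DataFrame | None = None, **profile_kw) -> "Cohort":
        return cls(name=name, expr=expr, flux=flux,
                   profile=cytotoxicity_profile(expr, **profile_kw))


@dataclass
class CohortCollection:
    cohorts: list[Cohort] = field(default_factory=list)

    def __iter__(self):
        return iter(self.cohorts)

    def __len__(self) -> int:
        return len(self.cohorts)


def pearson(x, y) -> float:
    """Pearson coefficient with pairwise-complete observations.

    Returns NaN (logged, not raised) when fewer than three complete pairs
    remain or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < MIN_PAIRS:
        log.debug("pearson: fewer than %d complete pairs", MIN_PAIRS)
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.debug("pearson: constant vector")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _feature_vector(cohort: Cohort, feature: str, use_flux: bool) -> pd.Series | None:
    if use_flux:
        if cohort.flux is None or feature not in cohort.flux.columns:
            return None
        return cohort.flux[feature]
    index_map = {str(g).strip().upper(): g for g in cohort.expr.index}
    key = feature.strip().upper()
    if key not in index_map:
        return None
    return cohort.expr.loc[index_map[key]]


def rank_features(
    cohorts: CohortCollection | list[Cohort],
    features: list[str] | str = "modules",
) -> pd.DataFrame:
    """Per-cohort and average Pearson coefficients vs relative cytotoxicity.

    ``features`` is a gene list, or the string ``"modules"`` to correlate
    module fluxes instead.  Output rows are features; columns are one PCC per
    cohort, ``avg_pcc``, and ``rank`` (ascending average, most negative
    first, ties broken lexicographically by feature id; features with no
    defined average are unranked).
    """
    cohort_list = list(cohorts)
    if not cohort_list:
        raise ValueError("no cohorts")
    use_flux = isinstance(features, str) and features == "modules"
    if use_flux:
        names: dict[str, None] = {}
        for c in cohort_list:
            if c.flux is not None:
                for m in c.flux.columns:
                    names.setdefault(m, None)
        feature_list = list(names)
        if not feature_list:
            raise ValueError("no cohort carries a flux matrix")
    else:
        feature_list = list(features)

    table = {}
    for cohort in cohort_list:
        cyto = cohort.profile["relative_cytotoxicity"]
        col = {}
        for f in feature_list:
            vec = _feature_vector(cohort, f, use_flux)
            if vec is None:
                col[f] = np.nan
                continue
            aligned = pd.concat([vec.reindex(cyto.index), cyto], axis=1)
            col[f] = pearson(aligned.iloc[:, 0], aligned.iloc[:, 1])
        table[cohort.name] = col
    out = pd.DataFrame(table, index=feature_list)
    out["avg_pcc"] = out.mean(axis=1, skipna=True)
    order = out["avg_pcc"].to_frame().assign(_id=out.index.astype(str))
    ranked = order.sort_values(["avg_pcc", "_id"], na_position="last")
    rank = pd.Series(np.nan, index=out.index)
    defined = ranked["avg_pcc"].notna()
    rank[ranked.index[defined]] = np.arange(1, int(defined.sum()) + 1)
    out["rank"] = rank
    return out


def flux_effector_correlation(
    flux: pd.DataFrame,
    expr: pd.DataFrame,
    effector_genes: list[str] = ("GZMA", "TNF", "IFNG", "PRF1"),
) -> pd.DataFrame:
    """Modules x effector-genes table of Pearson coefficients.

    Correlates each module's per-sample flux with each effector gene's
    expression over the shared samples.  Absent genes yield an all-NaN
    column (logged).
    """
    shared = [s for s in flux.index if s in expr.columns]
    if not shared:
        raise ValueError("no shared samples between flux and expression")
    index_map = {str(g).strip().upper(): g for g in expr.index}
    out = pd.DataFrame(index=flux.columns, columns=list(effector_genes), dtype=float)
    for gene in effector_genes:
        key = str(gene).strip().upper()
        if key not in index_map:
            log.warning("effector gene %s absent from expression", gene)
            continue
        g = expr.loc[index_map[key], shared].astype(float)
        for mod in flux.columns:
            out.loc[mod, gene] = pearson(flux.loc[shared, mod], g)
    return out
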