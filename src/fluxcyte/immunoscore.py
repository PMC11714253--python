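"""CD8+ T-cell abundance, cytotoxic level, and relative cytotoxicity.

Bulk tumor expression mixes tumor, stromal, and immune cells.  Two marker
signatures summarize the CD8+ T-cell compartment per sample: an *abundance*
score over pan-T-cell markers (CD3E, CD2, CD3G, CD3D, SIRPG, CD6, TIGIT) and
a *cytotoxic level* over effector-program markers (CD8A, SLA2, NKG7, PRF1,
GZMA, GZMH).  The relative cytotoxicity statistic is their ratio

    relative_cytotoxicity_j = cytotoxic_level_j / cd8_abundance_j ,

i.e., per-cell effector activity rather than infiltration amount.  Scores are
the mean log1p expression of the present markers — a simple rank-stable
stand-in for a full deconvolution-based estimate; downstream analyses
(grouping, correlation ranking) consume it only through ranks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MarkerSet",
    "TCELL_MARKERS",
    "CYTOTOXICITY_MARKERS",
    "SignatureScorer",
    "signature_score",
    "cytotoxicity_profile",
    "group_by_expression",
]


@dataclass(frozen=True)
class MarkerSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker set {self.name!r} is empty")


TCELL_MARKERS = MarkerSet(
    "t_cell", ("CD3E", "CD2", "CD3G", "CD3D", "SIRPG", "CD6", "TIGIT")
)
CYTOTOXICITY_MARKERS = MarkerSet(
    "cytotoxicity", ("CD8A", "SLA2", "NKG7", "PRF1", "GZMA", "GZMH")
)


def _present_markers(expr: pd.DataFrame, markers: MarkerSet):
    index_map = {str(g).strip().upper(): g for g in expr.index}
    present = [index_map[g.upper()] for g in markers.genes if g.upper() in index_map]
    missing = [g for g in markers.genes if g.upper() not in index_map]
    if not present:
        raise ValueError(f"no marker of set {markers.name!r} present in matrix")
    return present, missing


def signature_score(expr: pd.DataFrame, markers: MarkerSet) -> pd.Series:
    """Mean log1p expression over the present markers, per sample.

    ``expr`` is gene-by-sample and non-negative; missing markers are dropped
    (an all-missing set raises).  The score is non-negative and invariant to
    sample order.
    """
    present, _ = _present_markers(expr, markers)
    score = np.log1p(expr.loc[present].astype(float)).mean(axis=0)
    score.name = markers.name
    return score


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Transformer wrapping :func:`signature_score` for pipeline use.

    ``fit`` records which markers are present; ``transform`` maps a
    samples x genes matrix to a single-column score matrix.
    """

    def __init__(self, markers: MarkerSet = TCELL_MARKERS) -> None:
        self.markers = markers

    def fit(self, X: pd.DataFrame, y=None) -> "SignatureScorer":
        present, missing = _present_markers(X.T, self.markers)
        self.present_markers_ = present
        self.missing_markers_ = missing
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return signature_score(X.T, self.markers).to_frame()


def cytotoxicity_profile(
    expr: pd.DataFrame,
    tcell_markers: MarkerSet = TCELL_MARKERS,
    cyto_markers: MarkerSet = CYTOTOXICITY_MARKERS,
    floor: float = 1e-8,
) -> pd.DataFrame:
    """Per-sample CD8 abundance, cytotoxic level, and their ratio.

    Samples whose abundance score falls below ``floor`` get an undefined
    (NaN) ratio rather than a division blow-up; such samples are excluded
    from downstream correlations.
    """
    abundance = signature_score(expr, tcell_markers)
    cytotoxic = signature_score(expr, cyto_markers)
    ratio = cytotoxic / abundance.where(abundance >= floor)
    return pd.DataFrame(
        {
            "cd8_abundance": abundance,
            "cytotoxic_level": cytotoxic,
            "relative_cytotoxicity": ratio,
        }
    )


def group_by_expression(
    expr: pd.DataFrame,
    gene: str,
    top_frac: float = 0.4,
    bottom_frac: float = 0.4,
) -> tuple[list[str], list[str]]:
    """Sample ids in the top and bottom expression fractions of one gene.

    Group sizes are ``floor(n * frac)``; ties are broken by the stable sample
    order of the matrix.
    """
    if not (0 < top_frac and 0 < bottom_frac and top_frac + bottom_frac <= 1):
        raise ValueError("fractions must be positive and sum to at most 1")
    index_map = {str(g).strip().upper(): g for g in expr.index}
    key = str(gene).strip().upper()
    if key not in index_map:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    values = expr.loc[index_map[key]].astype(float)
    order = values.sort_values(kind="stable", ascending=False).index
    n = len(order)
    n_top = int(n * top_frac)
    n_bot = int(n * bottom_frac)
    top = list(order[:n_top])
    bottom = list(order[n - n_bot:])
    return top, bottom
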