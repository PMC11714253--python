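"""Flux-balance loss terms.

The training objective for sample-wise module fluxes is

    L = sum_j sum_k ( sum_{m in F_in(C_k)} Flux[j,m]
                      - sum_{m' in F_out(C_k)} Flux[j,m'] )^2
        + alpha * sum_{j,m} ( |Flux[j,m]| - Flux[j,m] )
        + beta  * sum_j ( sum_m Flux[j,m] - TA_j )^2

summed over intermediate metabolites C_k only.  TA_j, the per-sample total
metabolic activity, anchors the otherwise scale-free flux solution and is the
raw (untransformed) sum of expression over the network's gene universe.
Default weights: alpha = 1, beta = 0.1.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .network import MetabolicFactorGraph, module_gene_slice

__all__ = [
    "total_activity",
    "balance_matrix",
    "imbalance_loss",
    "nonneg_penalty",
    "scale_penalty",
    "total_loss",
]


def total_activity(expr: pd.DataFrame, graph: MetabolicFactorGraph) -> pd.Series:
    """Per-sample total expression of the network's genes (TA_j).

    ``expr`` is gene-by-sample; genes outside the network universe are
    ignored.  Raises if no network gene is present at all.
    """
    index_map = {str(g).strip().upper(): g for g in expr.index}
    rows = [index_map[g.upper()] for g in graph.gene_universe if g.upper() in index_map]
    if not rows:
        raise ValueError("expression matrix contains no network gene")
    ta = expr.loc[rows].sum(axis=0)
    ta.name = "total_activity"
    return ta


def balance_matrix(
    graph: MetabolicFactorGraph, module_order: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Signed incidence matrix B (intermediates x modules).

    B[k, m] = +1 if module m produces intermediate k, -1 if it consumes it.
    The per-sample imbalance vector is then ``flux @ B.T``.
    """
    if module_order is None:
        module_order = graph.module_ids
    col = {m: i for i, m in enumerate(module_order)}
    inter = graph.intermediates()
    B = np.zeros((len(inter), len(module_order)))
    for k, met in enumerate(inter):
        for m in graph.producers(met):
            B[k, col[m]] += 1.0
        for m in graph.consumers(met):
            B[k, col[m]] -= 1.0
    return B, inter


def _as_flux_array(flux, module_order: list[str]) -> np.ndarray:
    if isinstance(flux, pd.DataFrame):
        missing = [m for m in module_order if m not in flux.columns]
        if missing:
            raise ValueError(f"flux matrix lacks module columns {missing}")
        return flux[module_order].to_numpy(dtype=float)
    arr = np.asarray(flux, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(module_order):
        raise ValueError(
            f"flux must be n_samples x {len(module_order)} modules, got {arr.shape}"
        )
    return arr


def imbalance_loss(flux, graph: MetabolicFactorGraph) -> float:
    """Sum of squared in/out flux imbalances over intermediate metabolites."""
    order = graph.module_ids
    F = _as_flux_array(flux, order)
    B, _ = balance_matrix(graph, order)
    return float(np.sum((F @ B.T) ** 2))


def nonneg_penalty(flux) -> float:
    """sum(|Flux| - Flux) == 2 * sum of negative parts."""
    F = np.asarray(flux, dtype=float) if not isinstance(flux, pd.DataFrame) else flux.to_numpy(float)
    return float(np.sum(np.abs(F) - F))


def scale_penalty(flux, ta) -> float:
    """Squared deviation of per-sample total flux from total activity TA_j."""
    if isinstance(flux, pd.DataFrame) and isinstance(ta, pd.Series):
        if list(flux.index) != list(ta.index):
            raise ValueError("flux and total-activity samples are misaligned")
    F = flux.to_numpy(float) if isinstance(flux, pd.DataFrame) else np.asarray(flux, float)
    t = ta.to_numpy(float) if isinstance(ta, pd.Series) else np.asarray(ta, float)
    if F.shape[0] != t.shape[0]:
        raise ValueError("flux and total-activity samples are misaligned")
    return float(np.sum((F.sum(axis=1) - t) ** 2))


def total_loss(
    flux,
    graph: MetabolicFactorGraph,
    ta,
    alpha: float = 1.0,
    beta: float = 0.1,
) -> tuple[float, dict[str, float]]:
    """Weighted total loss and its per-term breakdown."""
    terms = {
        "imbalance": imbalance_loss(flux, graph),
        "nonneg": nonneg_penalty(flux),
        "scale": scale_penalty(flux, ta),
    }
    total = terms["imbalance"] + alpha * terms["nonneg"] + beta * terms["scale"]
    return float(total), terms
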