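"""Synthetic cohorts with known ground truth.

Every pipeline stage is testable without external downloads: this module
generates toy factor graphs, exactly balanced ground-truth flux matrices,
expression matrices produced from those fluxes by a known monotone gene
response, and multi-cohort collections with planted immune structure (T-cell
and cytotoxicity marker signals, one metabolic gene anti-correlated with
latent relative cytotoxicity, and a glutathione-branch flux coupled
negatively to effector-gene expression).

The generative direction is deliberately the inverse of the flux model: the
model maps genes -> flux, the generator maps flux -> genes with per-gene
monotone response (power law with exponent in [0.5, 1.5]) times log-normal
noise, so recovery tests are not circular.

All randomness flows from one seed through named substreams (flux, weights,
noise, immune), so individual stages reproduce in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .immunoscore import CYTOTOXICITY_MARKERS, TCELL_MARKERS
from .network import MetabolicFactorGraph, Metabolite, ReactionModule

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "make_toy_graph",
    "simulate_balanced_flux",
    "simulate_expression",
    "simulate_cohorts",
    "GLNLIKE6_M27_ANALOG",
    "GLNLIKE6_M28_ANALOG",
    "EFFECTOR_GENES",
]

#: CD8+ T-cell effector genes used in the branch-discrimination analysis
EFFECTOR_GENES = ("GZMA", "TNF", "IFNG", "PRF1")

#: glnlike6 module ids mimicking the Glu->GSH and Glu->2-OG branches
GLNLIKE6_M27_ANALOG = "M3"
GLNLIKE6_M28_ANALOG = "M4"


@dataclass
class SimulationSpec:
    """Conditions of a synthetic study; identical spec -> identical outputs."""

    graph_spec: str = "glnlike6"
    n_samples: int = 100
    noise_sd: float = 0.2
    effect_size: float = 1.0
    seed: int = 7


@dataclass
class GroundTruth:
    true_flux: pd.DataFrame | list[pd.DataFrame]
    true_group_labels: pd.Series | list[pd.Series] | None = None
    true_planted_features: list[str] = field(default_factory=list)


def _substream(seed: int, name: str) -> np.random.Generator:
    tag = int.from_bytes(name.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


# ---------------------------------------------------------------------------
# toy graphs
# ---------------------------------------------------------------------------

def _graph_from_rows(rows) -> MetabolicFactorGraph:
    modules = {
        mid: ReactionModule(id=mid, name=name, substrates=tuple(subs),
                            products=tuple(prods), genes=tuple(genes))
        for mid, name, subs, prods, genes in rows
    }
    g = MetabolicFactorGraph(modules=modules)
    mets: dict[str, None] = {}
    for mod in modules.values():
        for met in (*mod.substrates, *mod.products):
            mets.setdefault(met, None)
    for met in mets:
        produced = any(met in m.products for m in modules.values())
        consumed = any(met in m.substrates for m in modules.values())
        kind = "intermediate" if (produced and consumed) else "end"
        g.metabolites[met] = Metabolite(id=met, name=met, kind=kind)
    g.validate()
    return g


def make_toy_graph(name: str) -> MetabolicFactorGraph:
    """Small validated factor graphs for testing.

    chain3    A -M1-> B -M2-> C -M3-> D (2 intermediates)
    branch5   chain with a branch point carrying two consumers
    glnlike6  glutamine-like topology: uptake -> glutaminase -> branch into a
              glutathione-like arm (M3, the Glu->GSH analog) and a
              2-oxoglutarate-like arm (M4, the Glu->2-OG analog), each
              draining to an end metabolite.
    """
    if name == "chain3":
        rows = [
            ("M1", "A to B", ["A"], ["B"], ["g1a", "g1b"]),
            ("M2", "B to C", ["B"], ["C"], ["g2a"]),
            ("M3", "C to D", ["C"], ["D"], ["g3a", "g3b"]),
        ]
    elif name == "branch5":
        rows = [
            ("M1", "A to B", ["A"], ["B"], ["g1a", "g1b"]),
            ("M2", "B to C", ["B"], ["C"], ["g2a", "g2b"]),
            ("M3", "B to D", ["B"], ["D"], ["g3a"]),
            ("M4", "C to E", ["C"], ["E"], ["g4a", "g4b"]),
            ("M5", "D to F", ["D"], ["F"], ["g5a"]),
        ]
    elif name == "glnlike6":
        rows = [
            ("M1", "glutamine uptake", ["GLN_e"], ["GLN"], ["t1", "t2"]),
            ("M2", "glutaminase", ["GLN"], ["GLU"], ["GLS_SIM", "GLS2_SIM"]),
            ("M3", "glutamate to GSH", ["GLU"], ["GSH"], ["GCLC_SIM", "GCLM_SIM", "GSS_SIM"]),
            ("M4", "glutamate to 2-OG", ["GLU"], ["OG"], ["GLUD1_SIM", "GLUD2_SIM"]),
            ("M5", "GSH oxidation", ["GSH"], ["GSSG"], ["GPX_SIM", "GSR_SIM"]),
            ("M6", "2-OG to succinate", ["OG"], ["SUC"], ["OGDH_SIM", "DLST_SIM"]),
        ]
    else:
        raise ValueError(f"unknown toy graph {name!r}")
    return _graph_from_rows(rows)


# ---------------------------------------------------------------------------
# balanced flux
# ---------------------------------------------------------------------------

def _module_dag(graph: MetabolicFactorGraph) -> nx.DiGraph:
    """Module-level DAG: edge m1 -> m2 if m1 produces an intermediate m2 consumes."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.module_ids)
    for met in graph.intermediates():
        for a in graph.producers(met):
            for b in graph.consumers(met):
                g.add_edge(a, b)
    return g


def simulate_balanced_flux(
    graph: MetabolicFactorGraph, n_samples: int, seed: int = 0
) -> pd.DataFrame:
    """Draw a flux matrix that balances every intermediate metabolite exactly.

    Source modules (no intermediate substrate) get log-normal positive flux;
    interior flux is propagated along the module DAG, splitting each
    intermediate's inflow among its consumers by Dirichlet-drawn proportions
    (drawn per sample).  The result zeroes the imbalance term to float
    tolerance by construction.

    Only acyclic graphs in which each module consumes at most one
    intermediate metabolite are supported.
    """
    inter = set(graph.intermediates())
    for mod in graph.modules.values():
        if sum(1 for s in mod.substrates if s in inter) > 1:
            raise ValueError(
                f"module {mod.id} consumes multiple intermediates; "
                "balanced simulation supports at most one"
            )
    dag = _module_dag(graph)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph has a cycle through intermediate metabolites")

    rng = _substream(seed, "flux")
    order = list(nx.topological_sort(dag))
    F = pd.DataFrame(0.0, index=[f"s{i}" for i in range(n_samples)],
                     columns=graph.module_ids)
    # draw source fluxes first, in fixed module order for reproducibility
    for mid in graph.module_ids:
        mod = graph.modules[mid]
        if not any(s in inter for s in mod.substrates):
            F[mid] = rng.lognormal(mean=np.log(20.0), sigma=0.4, size=n_samples)
    # propagate: an intermediate's inflow is split among its consumers the
    # first time a consuming module is reached in topological order
    done: set[str] = set()
    for mid in order:
        mod = graph.modules[mid]
        inter_subs = [s for s in mod.substrates if s in inter]
        if not inter_subs:
            continue
        met = inter_subs[0]
        if met in done:
            continue
        producers = sorted(graph.producers(met))
        consumers = sorted(graph.consumers(met))
        inflow = F[producers].sum(axis=1).to_numpy()
        if len(consumers) == 1:
            F[consumers[0]] = inflow
        else:
            props = rng.dirichlet(np.full(len(consumers), 2.0), size=n_samples)
            for i, c in enumerate(consumers):
                F[c] = inflow * props[:, i]
        done.add(met)
    return F


# ---------------------------------------------------------------------------
# expression from flux
# ---------------------------------------------------------------------------

def simulate_expression(
    true_flux: pd.DataFrame,
    graph: MetabolicFactorGraph,
    noise_sd: float = 0.2,
    seed: int = 0,
    n_background: int = 200,
) -> pd.DataFrame:
    """Gene-by-sample expression generated from known module fluxes.

    Each module gene g gets ``w_g * Flux_m ** e_g * exp(N(0, noise_sd^2))``
    with weight w_g ~ LogNormal(0, 0.25) and exponent e_g ~ U[0.5, 1.5];
    ``n_background`` non-network genes get log-normal expression so gene
    matching and the total-activity restriction are exercised.
    """
    wrng = _substream(seed, "weights")
    nrng = _substream(seed, "noise")
    n = true_flux.shape[0]
    rows, names = [], []
    for mid in graph.module_ids:
        flux = true_flux[mid].to_numpy()
        for g in graph.modules[mid].genes:
            w = wrng.lognormal(0.0, 0.25)
            e = wrng.uniform(0.5, 1.5)
            noise = np.exp(nrng.normal(0.0, noise_sd, size=n)) if noise_sd > 0 else 1.0
            rows.append(w * np.power(flux, e) * noise)
            names.append(g)
    for i in range(n_background):
        rows.append(nrng.lognormal(1.0, 1.0, size=n))
        names.append(f"BG{i}")
    return pd.DataFrame(rows, index=names, columns=true_flux.index)


# ---------------------------------------------------------------------------
# immune-structured cohorts
# ---------------------------------------------------------------------------

def _immune_cohort(
    spec: SimulationSpec, graph: MetabolicFactorGraph, cohort_idx: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """One cohort: expression, true flux, and latent relative cytotoxicity.

    Latent per-sample T-cell abundance a_j and relative cytotoxicity r_j are
    log-normal; marker genes respond proportionally (T-cell markers to a_j,
    cytotoxic/effector markers to a_j * r_j).  The planted metabolic gene
    responds as exp(-effect_size * z(log r_j)).  The M27-analog flux is drawn
    as a decreasing function of r_j while the M28-analog flux is independent
    of it; the branch-parent flux is their sum, and the upstream/downstream
    chain is filled in to keep every intermediate balanced exactly.
    """
    seed = (int(spec.seed) % (2**31)) * 101 + cohort_idx
    irng = _substream(seed, "immune")
    n = spec.n_samples
    samples = [f"c{cohort_idx}_s{i}" for i in range(n)]

    log_a = irng.normal(1.0, 0.5, size=n)
    log_r = irng.normal(0.0, 0.5, size=n)
    abundance = np.exp(log_a)
    rel_cyto = np.exp(log_r)
    z_r = (log_r - log_r.mean()) / log_r.std()

    # --- flux: children first, parent by summation (M3 coupled, M4 free)
    frng = _substream(seed, "flux")
    m3 = np.exp(np.log(10.0) - 0.8 * z_r + frng.normal(0.0, 0.2, size=n))
    m4 = frng.lognormal(np.log(10.0), 0.5, size=n)
    parent = m3 + m4
    F = pd.DataFrame(
        {
            "M1": parent, "M2": parent,
            GLNLIKE6_M27_ANALOG: m3, GLNLIKE6_M28_ANALOG: m4,
            "M5": m3, "M6": m4,
        },
        index=samples,
    )[graph.module_ids]

    expr = simulate_expression(F, graph, noise_sd=spec.noise_sd, seed=seed)
    expr.columns = samples

    nrng = _substream(seed, "markers")
    marker_rows, marker_names = [], []
    for g in TCELL_MARKERS.genes:
        w = nrng.lognormal(1.0, 0.2)
        marker_rows.append(w * abundance * np.exp(nrng.normal(0, 0.2, n)))
        marker_names.append(g)
    for g in set(CYTOTOXICITY_MARKERS.genes) | set(EFFECTOR_GENES):
        w = nrng.lognormal(1.0, 0.2)
        marker_rows.append(w * abundance * rel_cyto * np.exp(nrng.normal(0, 0.2, n)))
        marker_names.append(g)
    # planted metabolic gene: linearly decreasing in the latent cytotoxicity
    # z-score (floored to stay positive), so its anti-correlation survives on
    # the raw expression scale where Pearson is computed
    planted = np.maximum(4.0 - spec.effect_size * z_r, 0.1) \
        * np.exp(nrng.normal(0, 0.1, n))
    marker_rows.append(planted)
    marker_names.append("PLANTED_METAB")
    markers = pd.DataFrame(marker_rows, index=marker_names, columns=samples)

    expr = pd.concat([expr, markers])
    truth = pd.Series(rel_cyto, index=samples, name="latent_relative_cytotoxicity")
    return expr, F, truth


def simulate_cohorts(
    spec: SimulationSpec, n_cohorts: int = 9
) -> tuple[list[tuple[str, pd.DataFrame, pd.DataFrame]], GroundTruth]:
    """Multi-cohort collection emulating a panel of CRC expression datasets.

    Returns ``(cohorts, truth)`` where cohorts is a list of
    ``(name, expression, true_flux)`` with disjoint sample ids, and truth
    bundles per-cohort true flux, the latent relative-cytotoxicity labels,
    and the planted feature names.
    """
    graph = make_toy_graph(spec.graph_spec)
    cohorts, fluxes, labels = [], [], []
    for c in range(n_cohorts):
        expr, F, truth = _immune_cohort(spec, graph, c)
        cohorts.append((f"cohort{c + 1}", expr, F))
        fluxes.append(F)
        labels.append(truth)
    gt = GroundTruth(
        true_flux=fluxes,
        true_group_labels=labels,
        true_planted_features=["PLANTED_METAB"],
    )
    return cohorts, gt
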