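"""Compartmentalized metabolic factor graphs.

A metabolic map is represented as a directed bipartite factor graph: reaction
*modules* (lumped sets of consecutive reactions, each carrying a gene set) are
factor nodes, and metabolites are variable nodes.  Edges run metabolite->module
(the module consumes it) and module->metabolite (the module produces it).
*Intermediate* metabolites have at least one producing and one consuming
module and carry a flux-balance constraint; *end* metabolites sit on the
network boundary (sources or sinks) and are exempt from balance.

The bundled curated network (``load_central_metabolism``) is a reconstruction
of a compartmentalized central-metabolism map — glycolysis, the upper and
lower TCA cycle, glutaminolysis, glutamine/glutamate metabolism, glutathione
metabolism, and three minor branches (nucleotide synthesis, serine synthesis,
and the aspartate–malate shuttle) — assembled here from public pathway
knowledge as a synthetic stand-in for an externally curated reaction set.  It
has 31 modules, 16 intermediate and 15 end metabolites, and 253 distinct
genes, with module M27 the glutamate-to-glutathione step (GCLC/GCLM/GSS) and
M28 the glutamate-to-2-oxoglutarate step (GLUD1/GLUD2).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Metabolite",
    "ReactionModule",
    "MetabolicFactorGraph",
    "NetworkError",
    "load_network",
    "load_central_metabolism",
    "write_network",
    "balance_sets",
    "module_gene_slice",
]

COMPARTMENTS = ("cytosol", "mitochondrion", "extracellular")

#: metabolite-id suffix -> compartment, used when no explicit table is given
_SUFFIX_COMPARTMENT = {"_c": "cytosol", "_m": "mitochondrion", "_e": "extracellular"}


class NetworkError(ValueError):
    """Raised when a network table violates the factor-graph invariants."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    kind: str = "intermediate"  # "intermediate" | "end"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(f"unknown compartment {self.compartment!r} for {self.id}")
        if self.kind not in ("intermediate", "end"):
            raise NetworkError(f"unknown metabolite kind {self.kind!r} for {self.id}")


@dataclass(frozen=True)
class ReactionModule:
    """A flux-carrying reaction module (factor node) with its gene set."""

    id: str
    name: str = ""
    compartment: str = "cytosol"
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()
    group: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(f"unknown compartment {self.compartment!r} for {self.id}")
        if not self.substrates and not self.products:
            raise NetworkError(f"module {self.id} has neither substrates nor products")
        overlap = set(self.substrates) & set(self.products)
        if overlap:
            raise NetworkError(
                f"module {self.id} lists {sorted(overlap)} as both substrate and product"
            )


@dataclass
class MetabolicFactorGraph:
    """Directed bipartite graph of reaction modules and metabolites."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    modules: dict[str, ReactionModule] = field(default_factory=dict)

    # -- basic queries ---------------------------------------------------
    @property
    def module_ids(self) -> list[str]:
        return list(self.modules)

    @property
    def gene_universe(self) -> list[str]:
        """Distinct genes across all modules, in first-appearance order."""
        seen: dict[str, None] = {}
        for mod in self.modules.values():
            for g in mod.genes:
                seen.setdefault(g, None)
        return list(seen)

    def intermediates(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.kind == "intermediate"]

    def ends(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.kind == "end"]

    def producers(self, metabolite_id: str) -> set[str]:
        return {m.id for m in self.modules.values() if metabolite_id in m.products}

    def consumers(self, metabolite_id: str) -> set[str]:
        return {m.id for m in self.modules.values() if metabolite_id in m.substrates}

    def edges(self) -> list[tuple[str, str, str]]:
        """(source, target, edge_type) triples; edge_type in {C->R, R->C}."""
        out: list[tuple[str, str, str]] = []
        for mod in self.modules.values():
            for s in mod.substrates:
                out.append((s, mod.id, "C->R"))
            for p in mod.products:
                out.append((mod.id, p, "R->C"))
        return out

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check all factor-graph invariants; raise NetworkError on failure."""
        if not self.modules:
            raise NetworkError("no modules")
        for mod in self.modules.values():
            if not mod.genes:
                raise NetworkError(f"module {mod.id} has zero genes")
            for met in (*mod.substrates, *mod.products):
                if met not in self.metabolites:
                    raise NetworkError(
                        f"module {mod.id} references unknown metabolite {met!r}"
                    )
        for met in self.metabolites.values():
            if met.kind == "intermediate":
                if not self.producers(met.id) or not self.consumers(met.id):
                    raise NetworkError(
                        f"intermediate metabolite {met.id} lacks a producer or consumer"
                    )

    def summary(self) -> dict[str, int]:
        return {
            "modules": len(self.modules),
            "genes": len(self.gene_universe),
            "metabolites": len(self.metabolites),
            "intermediates": len(self.intermediates()),
            "ends": len(self.ends()),
        }


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def _clean_gene(g: str) -> str:
    return g.strip().upper()


def _split_list(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    return [x.strip() for x in str(cell).split(";") if x.strip()]


def _str_cell(value, default: str = "") -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    return str(value) or default


def load_network(
    module_table: str | Path,
    gene_table: str | Path | None = None,
    metabolite_table: str | Path | None = None,
) -> MetabolicFactorGraph:
    """Load a factor graph from tab-separated tables.

    ``module_table`` has one module per row with columns ``module_id``,
    ``name``, ``compartment``, ``substrates``, ``products`` (semicolon lists),
    and optionally ``genes`` (semicolon list) and ``group``.  A long-format
    ``gene_table`` (``module_id``, ``gene``) may supply genes instead of, or
    in addition to, the embedded column.  Metabolite kind is taken from an
    explicit ``metabolite_table`` (``metabolite_id``, ``kind``) when given,
    otherwise inferred: intermediate iff the metabolite has at least one
    producing and one consuming module.  Metabolite compartments are inferred
    from id suffixes ``_c`` / ``_m`` / ``_e`` (default cytosol).

    Gene symbols are matched case-insensitively after trimming; duplicates
    within a module are dropped with a warning.
    """
    mod_df = pd.read_csv(module_table, sep="\t", dtype=str, comment="#")
    if mod_df.empty:
        raise NetworkError("no modules")
    required = {"module_id", "substrates", "products"}
    missing_cols = required - set(mod_df.columns)
    if missing_cols:
        raise NetworkError(f"module table missing columns {sorted(missing_cols)}")

    genes_by_module: dict[str, list[str]] = {}
    if "genes" in mod_df.columns:
        for _, row in mod_df.iterrows():
            genes_by_module[row["module_id"]] = [
                _clean_gene(g) for g in _split_list(row["genes"])
            ]
    if gene_table is not None:
        gene_df = pd.read_csv(gene_table, sep="\t", dtype=str, comment="#")
        known = set(mod_df["module_id"])
        for _, row in gene_df.iterrows():
            mid = str(row["module_id"]).strip()
            if mid not in known:
                raise NetworkError(f"gene table references unknown module {mid!r}")
            genes_by_module.setdefault(mid, []).append(_clean_gene(row["gene"]))

    modules: dict[str, ReactionModule] = {}
    for _, row in mod_df.iterrows():
        mid = str(row["module_id"]).strip()
        if mid in modules:
            raise NetworkError(f"duplicate module id {mid!r}")
        raw_genes = genes_by_module.get(mid, [])
        deduped: list[str] = list(dict.fromkeys(raw_genes))
        if len(deduped) < len(raw_genes):
            warnings.warn(f"module {mid}: duplicate genes de-duplicated", stacklevel=2)
        if not deduped:
            raise NetworkError(f"module {mid} has zero genes")
        modules[mid] = ReactionModule(
            id=mid,
            name=_str_cell(row.get("name")),
            compartment=_str_cell(row.get("compartment"), "cytosol"),
            substrates=tuple(_split_list(row["substrates"])),
            products=tuple(_split_list(row["products"])),
            genes=tuple(deduped),
            group=_str_cell(row.get("group")),
        )

    explicit_kind: dict[str, str] = {}
    if metabolite_table is not None:
        met_df = pd.read_csv(metabolite_table, sep="\t", dtype=str, comment="#")
        explicit_kind = dict(zip(met_df["metabolite_id"], met_df["kind"]))

    graph = MetabolicFactorGraph(modules=modules)
    met_ids: dict[str, None] = {}
    for mod in modules.values():
        for met in (*mod.substrates, *mod.products):
            met_ids.setdefault(met, None)
    for mid in met_ids:
        produced = any(mid in m.products for m in modules.values())
        consumed = any(mid in m.substrates for m in modules.values())
        kind = explicit_kind.get(
            mid, "intermediate" if (produced and consumed) else "end"
        )
        comp = _SUFFIX_COMPARTMENT.get(mid[-2:], "cytosol")
        graph.metabolites[mid] = Metabolite(id=mid, name=mid, compartment=comp, kind=kind)

    graph.validate()
    return graph


def load_central_metabolism() -> MetabolicFactorGraph:
    """Load the bundled curated central-metabolism reconstruction.

    31 modules / 16 intermediates / 15 ends / 253 genes; see module docstring
    for provenance and caveats.
    """
    data = resources.files("fluxcyte") / "data"
    with resources.as_file(data / "central_metabolism_modules.tsv") as mod_path:
        return load_network(mod_path)


def write_network(graph: MetabolicFactorGraph, module_table: str | Path) -> None:
    """Write a canonicalized module table (TSV) round-trippable by load_network."""
    rows = []
    for mid in sorted(graph.modules):
        mod = graph.modules[mid]
        rows.append(
            {
                "module_id": mod.id,
                "name": mod.name,
                "compartment": mod.compartment,
                "substrates": ";".join(mod.substrates),
                "products": ";".join(mod.products),
                "genes": ";".join(mod.genes),
                "group": mod.group,
            }
        )
    pd.DataFrame(rows).to_csv(module_table, sep="\t", index=False)


def write_edge_list(graph: MetabolicFactorGraph, path: str | Path) -> None:
    """Export a plain edge-list TSV (source, target, edge_type)."""
    pd.DataFrame(graph.edges(), columns=["source", "target", "edge_type"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# queries used by the flux model
# ---------------------------------------------------------------------------

def balance_sets(
    graph: MetabolicFactorGraph, metabolite_id: str
) -> tuple[set[str], set[str]]:
    """Producer/consumer module sets (F_in, F_out) for an intermediate metabolite.

    F_in are modules listing the metabolite as a product (in-flux), F_out the
    modules listing it as a substrate (out-flux).  Balance is only defined for
    intermediate metabolites; requesting an end metabolite raises.
    """
    met = graph.metabolites.get(metabolite_id)
    if met is None:
        raise NetworkError(f"unknown metabolite {metabolite_id!r}")
    if met.kind != "intermediate":
        raise NetworkError(
            f"balance sets undefined for end metabolite {metabolite_id!r}"
        )
    return graph.producers(metabolite_id), graph.consumers(metabolite_id)


def module_gene_slice(
    graph: MetabolicFactorGraph,
    module_id: str,
    expr: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict a gene-by-sample expression matrix to one module's genes.

    Returns ``(slice, missing)`` where the slice rows follow module-table gene
    order restricted to genes present in ``expr`` (matched case-insensitively)
    and ``missing`` lists module genes absent from the matrix.
    """
    if module_id not in graph.modules:
        raise NetworkError(f"unknown module {module_id!r}")
    index_map = {str(g).strip().upper(): g for g in expr.index}
    present, missing = [], []
    for g in graph.modules[module_id].genes:
        key = g.strip().upper()
        if key in index_map:
            present.append(index_map[key])
        else:
            missing.append(g)
    return expr.loc[present], missing
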