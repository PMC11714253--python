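"""Shared fixtures: tiny network tables and random factor-graph generators."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fluxcyte.network import MetabolicFactorGraph, Metabolite, ReactionModule


CHAIN3_MODULES = """\
module_id\tname\tcompartment\tsubstrates\tproducts\tgenes
M1\tA to B\tcytosol\tA\tB\tg1a;g1b
M2\tB to C\tcytosol\tB\tC\tg2a
M3\tC to D\tcytosol\tC\tD\tg3a;g3b
"""

BRANCH_MODULES = """\
module_id\tname\tcompartment\tsubstrates\tproducts\tgenes
M1\tA to B\tcytosol\tA\tB\tg1
M2\tB to C\tcytosol\tB\tC\tg2
M3\tB to D\tcytosol\tB\tD\tg3
"""


@pytest.fixture
def chain3_table(tmp_path):
    path = tmp_path / "chain3_modules.tsv"
    path.write_text(CHAIN3_MODULES)
    return path


@pytest.fixture
def branch_table(tmp_path):
    path = tmp_path / "branch_modules.tsv"
    path.write_text(BRANCH_MODULES)
    return path


def random_factor_graph(rng: np.random.Generator) -> MetabolicFactorGraph:
    """A random valid acyclic factor graph grown module by module.

    Each new module consumes one existing metabolite and produces a fresh
    one; kinds are inferred, so the result always satisfies the invariants.
    """
    n_modules = int(rng.integers(3, 9))
    modules = {}
    metabolites = ["C0"]
    for i in range(n_modules):
        sub = metabolites[int(rng.integers(0, len(metabolites)))]
        prod = f"C{i + 1}"
        metabolites.append(prod)
        modules[f"M{i + 1}"] = ReactionModule(
            id=f"M{i + 1}", substrates=(sub,), products=(prod,),
            genes=(f"g{i + 1}",),
        )
    graph = MetabolicFactorGraph(modules=modules)
    for met in metabolites:
        produced = any(met in m.products for m in modules.values())
        consumed = any(met in m.substrates for m in modules.values())
        kind = "intermediate" if (produced and consumed) else "end"
        graph.metabolites[met] = Metabolite(id=met, name=met, kind=kind)
    graph.validate()
    return graph


def random_expression(rng: np.random.Generator, genes, n_samples: int) -> pd.DataFrame:
    return pd.DataFrame(
        rng.lognormal(1.0, 0.8, size=(len(genes), n_samples)),
        index=list(genes),
        columns=[f"s{i}" for i in range(n_samples)],
    )
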