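"""Topology-derived prior for the drug influence coefficient rho.

The influence coefficient rho[j, d] is, conceptually, the fraction of the
activity increase caused by an alteration of gene j that a drug d can
reach: close to 1 when the drug's target lies downstream of j on the only
route to the pathway terminals, smaller when only some branches pass
through a target.  The fitted model keeps rho free; this module formalises
the narrative into a quantitative prior usable as an initializer.

Unit flux is injected at the altered gene and propagated along directed
edges, dividing equally over out-edges at every branch point.  A drug
target absorbs all flux entering it (complete blockade at the target; the
fitted drug effect alpha models partial inhibition); a node with no
out-edges is a terminal.  The prior is the absorbed fraction.

Real pathway graphs contain cycles, for which the flow narrative gives no
rule; flux is propagated level-by-level until the circulating residual
drops below a tolerance, and whatever remains trapped is truncated and
reported.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .data import DrugPanel, PathwayGraph

__all__ = ["FlowResult", "propagate_flow", "flow_influence", "rho_prior_matrix"]

#: residual circulating flux below which propagation stops
FLOW_TOLERANCE = 1e-9
#: hard cap on propagation sweeps (guards non-decaying cycles)
MAX_SWEEPS = 10_000


@dataclass(frozen=True)
class FlowResult:
    """Outcome of propagating unit flux from ``source``.

    ``absorbed_at_targets + reached_terminals <= 1`` (flux trapped in
    cycles is truncated); ``node_flux`` records the total flux that passed
    through each node.
    """

    source: str
    absorbed_at_targets: float
    reached_terminals: float
    truncated: float
    node_flux: dict[str, float] = field(default_factory=dict)


def propagate_flow(
    graph: PathwayGraph,
    source: str,
    targets: frozenset[str] | set[str],
    tol: float = FLOW_TOLERANCE,
    max_sweeps: int = MAX_SWEEPS,
) -> FlowResult:
    """Propagate unit flux from ``source``, splitting equally at branches.

    If ``source`` itself is a target the whole unit is absorbed by
    convention (the drug acts directly on the altered gene).
    """
    if source not in graph.nodes:
        raise KeyError(f"source gene {source!r} not in graph")
    targets = set(targets)
    if source in targets:
        return FlowResult(source, 1.0, 0.0, 0.0, {source: 1.0})

    successors: dict[str, list[str]] = defaultdict(list)
    for u, w in graph.edges:
        successors[u].append(w)

    node_flux: dict[str, float] = defaultdict(float)
    node_flux[source] = 1.0
    current: dict[str, float] = {source: 1.0}
    absorbed = 0.0
    terminal = 0.0
    sweeps = 0
    while current and sum(current.values()) > tol and sweeps < max_sweeps:
        nxt: dict[str, float] = defaultdict(float)
        for u, f in current.items():
            succ = successors.get(u)
            if not succ:
                terminal += f
                continue
            share = f / len(succ)
            for w in succ:
                node_flux[w] += share
                if w in targets:
                    absorbed += share
                else:
                    nxt[w] += share
        current = dict(nxt)
        sweeps += 1
    truncated = float(sum(current.values()))
    return FlowResult(source, float(absorbed), float(terminal), truncated, dict(node_flux))


def flow_influence(
    graph: PathwayGraph, source: str, targets: frozenset[str] | set[str]
) -> float:
    """Fraction of the activity from ``source`` that passes drug targets.

    Always in [0, 1]; on a DAG, absorbed + reached-terminal flux sums to 1.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    return propagate_flow(graph, source, targets).absorbed_at_targets


def rho_prior_matrix(
    graph: PathwayGraph, genes, panel: DrugPanel
) -> np.ndarray:
    """Vectorize ``flow_influence`` into a (genes x drugs) prior matrix.

    Genes absent from the graph, and drugs with an empty target set, get a
    column/row of zeros (with a warning for missing genes).
    """
    genes = list(genes)
    out = np.zeros((len(genes), len(panel.drugs)))
    nodeset = set(graph.nodes)
    missing = [g for g in genes if g not in nodeset]
    if missing:
        warnings.warn(
            f"genes absent from pathway graph get prior 0: {missing}",
            stacklevel=2,
        )
    for j, gene in enumerate(genes):
        if gene not in nodeset:
            continue
        for d, rec in enumerate(panel.drugs):
            if not rec.targets:
                continue
            out[j, d] = flow_influence(graph, gene, rec.targets)
    return out
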