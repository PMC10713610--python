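"""Continental origin and trait ancestry from nodal reconstructions.

A species' origin is found by walking rootward from its tip until an
*ancestral source node* is reached: the first ancestor whose probability of
being Eurasian (Palearctic + Indomalaya) or Australo-Papuan exceeds 75%.
Composite range states are split evenly among their constituent areas, so a
node that is certainly "Australo-Papua + Wallacea" counts as 50%
Australo-Papuan.  Species that never cross the threshold before the root
are left unresolved and excluded from downstream group comparisons.

At the source node, elevational ancestry uses the 50/50 split of combined
Lowland+Montane probability, whereas migratory ancestry uses inclusion
summation (the probability of, say, Sedentary is the summed probability of
every state containing Sedentary).  The two rules are deliberately
different and must not be unified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dec_model import AreaCatalog, ReconstructionResult, StateSpace
from .treekit import TimeTree

__all__ = [
    "AreaGroup",
    "SourceClassification",
    "EURASIAN",
    "AUSTRALO_PAPUAN",
    "area_group_probability",
    "trace_source_node",
    "montane_ancestry_probability",
    "migration_ancestry",
    "dedupe_source_nodes",
    "classify_species",
    "classifications_to_frame",
]

#: strict probability threshold for calling an ancestral source node
SOURCE_THRESHOLD = 0.75


class TracingError(ValueError):
    pass


@dataclass(frozen=True)
class AreaGroup:
    name: str
    members: tuple[str, ...]


EURASIAN = AreaGroup("Eurasian", ("Palearctic", "Indomalaya"))
AUSTRALO_PAPUAN = AreaGroup("Australo-Papuan", ("Australo-Papua",))


def _group_weights(space: StateSpace, group: AreaGroup) -> np.ndarray:
    """Per-state weight |state ∩ group| / |state| (0 for the null range)."""
    cat = space.catalog
    gmask = 0
    for name in group.members:
        if name in cat.names:
            gmask |= 1 << cat.index(name)
    w = np.zeros(space.n_states)
    for i, m in enumerate(space.states):
        m = int(m)
        if m:
            w[i] = (m & gmask).bit_count() / m.bit_count()
    return w


def area_group_probability(
    state_probs: np.ndarray, space: StateSpace, group: AreaGroup
) -> float:
    """Probability mass attributed to a group after splitting composite
    states evenly among their constituent areas."""
    state_probs = np.asarray(state_probs, dtype=float)
    ni = space.null_index
    if ni is not None and state_probs[ni] > 1e-9:
        raise TracingError(
            "null-range probability must be marginalized before group scoring"
        )
    return float(state_probs @ _group_weights(space, group))


@dataclass
class SourceClassification:
    """Per-species origin call and trait-ancestry probabilities."""

    species: str
    origin: str  # "Eurasian" | "Australo-Papuan" | "unresolved"
    source_node: int | None
    nodes_counted: int
    p_origin: float
    source_node_age: float | None = None
    tree_id: str | None = None
    p_montane_ancestry: float | None = None
    migration: dict[str, float] | None = None

    def __post_init__(self):
        if self.origin != "unresolved":
            assert self.p_origin > SOURCE_THRESHOLD
            assert self.nodes_counted >= 1


def trace_source_node(
    tree: TimeTree,
    recon: ReconstructionResult,
    tip: str,
    threshold: float = SOURCE_THRESHOLD,
    tree_id: str | None = None,
) -> SourceClassification:
    """Walk rootward from a tip to its ancestral source node.

    The tip's parent is node 1 of the walk (the tip itself is observed
    data, not a reconstruction).  The first node whose Eurasian or
    Australo-Papuan group probability strictly exceeds ``threshold`` is the
    source node; if the root is passed without crossing, the species is
    unresolved.
    """
    node = tree.tip_index(tip)
    ages = tree.node_ages()
    count = 0
    best = 0.0
    node = int(tree.parent[node])
    while node >= 0:
        count += 1
        probs = recon.node_probs[node]
        p_eur = area_group_probability(probs, recon.space, EURASIAN)
        p_aus = area_group_probability(probs, recon.space, AUSTRALO_PAPUAN)
        if p_eur > threshold and p_aus > threshold:
            # disjoint groups cannot both hold >75% of a distribution
            raise TracingError(
                f"both source groups exceed {threshold} at node {node}"
            )
        best = max(best, p_eur, p_aus)
        if p_eur > threshold or p_aus > threshold:
            return SourceClassification(
                species=tip,
                origin="Eurasian" if p_eur > threshold else "Australo-Papuan",
                source_node=node,
                nodes_counted=count,
                p_origin=max(p_eur, p_aus),
                source_node_age=float(ages[node]),
                tree_id=tree_id,
            )
        node = int(tree.parent[node])
    return SourceClassification(
        species=tip,
        origin="unresolved",
        source_node=None,
        nodes_counted=count,
        p_origin=best,
        tree_id=tree_id,
    )


def montane_ancestry_probability(
    elev_probs: np.ndarray, space: StateSpace
) -> float:
    """P(Montane) + 0.5 P(Lowland+Montane): the combined state is split
    evenly between the montane and lowland scores."""
    cat = space.catalog
    m = cat.mask("Montane")
    lm = cat.mask("Lowland", "Montane")
    p = np.asarray(elev_probs, dtype=float)
    out = p[space.index[m]] + 0.5 * p[space.index[lm]]
    return float(out)


def migration_ancestry(
    mig_probs: np.ndarray, space: StateSpace
) -> dict[str, float]:
    """Inclusion probability of each movement class at a node.

    Each class's probability sums over every state containing it (a state
    is a set of movement classes shown by the ancestor's populations);
    ``any_movement`` sums states containing Short or Long.  Note this is
    NOT the even splitting used for elevational ancestry.
    """
    cat = space.catalog
    p = np.asarray(mig_probs, dtype=float)
    out: dict[str, float] = {}
    for cls, key in (("Sedentary", "sedentary"), ("Short", "short"), ("Long", "long")):
        bit = 1 << cat.index(cls)
        out[key] = float(
            sum(p[i] for i, m in enumerate(space.states) if int(m) & bit)
        )
    move = (1 << cat.index("Short")) | (1 << cat.index("Long"))
    out["any_movement"] = float(
        sum(p[i] for i, m in enumerate(space.states) if int(m) & move)
    )
    return out


def classify_species(
    tree: TimeTree,
    geo_recon: ReconstructionResult,
    elev_recon: ReconstructionResult | None = None,
    mig_recon: ReconstructionResult | None = None,
    threshold: float = SOURCE_THRESHOLD,
    tree_id: str | None = None,
    tips: list[str] | None = None,
) -> list[SourceClassification]:
    """Trace every tip; attach elevational and migratory ancestry read at
    each species' source node (identified from the geographic
    reconstruction)."""
    out = []
    for tip in tips if tips is not None else tree.tip_labels:
        cl = trace_source_node(tree, geo_recon, tip, threshold, tree_id)
        if cl.source_node is not None:
            if elev_recon is not None:
                cl.p_montane_ancestry = montane_ancestry_probability(
                    elev_recon.node_probs[cl.source_node], elev_recon.space
                )
            if mig_recon is not None:
                cl.migration = migration_ancestry(
                    mig_recon.node_probs[cl.source_node], mig_recon.space
                )
        out.append(cl)
    return out


def dedupe_source_nodes(
    classifications: list[SourceClassification],
) -> tuple[set[tuple[str | None, int]], float, float]:
    """Unique (tree id, node id) source nodes among resolved species.

    Returns the unique node set, their mean age (over unique nodes), and
    the mean nodes-counted walk depth (over species).
    """
    resolved = [c for c in classifications if c.source_node is not None]
    if not resolved:
        return set(), float("nan"), float("nan")
    unique = {(c.tree_id, c.source_node) for c in resolved}
    ages: dict[tuple, float] = {}
    for c in resolved:
        if c.source_node_age is not None:
            ages[(c.tree_id, c.source_node)] = c.source_node_age
    mean_age = float(np.mean(list(ages.values()))) if ages else float("nan")
    mean_depth = float(np.mean([c.nodes_counted for c in resolved]))
    return unique, mean_age, mean_depth


def classifications_to_frame(
    classifications: list[SourceClassification],
) -> pd.DataFrame:
    rows = []
    for c in classifications:
        row = {
            "species": c.species,
            "origin": c.origin,
            "tree_id": c.tree_id,
            "source_node": c.source_node,
            "nodes_counted": c.nodes_counted,
            "p_origin": c.p_origin,
            "source_node_age": c.source_node_age,
            "p_montane_ancestry": c.p_montane_ancestry,
        }
        if c.migration:
            for k, v in c.migration.items():
                row[f"p_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
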