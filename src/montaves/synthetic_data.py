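"""Synthetic trees, trait histories, and montane-island-population tables.

The generator emulates the statistical shape of the empirical study system:
passerine clades ~5-15 Ma old with 4-185 ingroup tips (mean ~30), geographic
ranges evolving over nine biogeographic regions, elevational states with
lowland/montane turnover, migratory states, and an island-population table
at the scale of ~110 species with montane populations across ~31 islands in
two archipelagos.

The forward DEC simulator here is the independent twin of the likelihood
machinery in :mod:`montaves.dec_model`: it is written directly from the
process definition (exact event-time simulation of anagenesis, direct
enumeration of cladogenetic events over area sets) and shares no transition
code with the likelihood, so it can serve as a parameter-recovery and
cross-validation oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from .dec_model import (
    AreaCatalog,
    DECParams,
    ELEVATION_AREAS,
    MIGRATION_AREAS,
    NINE_REGIONS,
)
from .treekit import TimeTree

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SyntheticStudy",
    "sim_birth_death_tree",
    "sim_dec_history",
    "generate_study",
]


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------
# birth-death trees


def sim_birth_death_tree(
    n_tips: int,
    birth: float,
    death: float = 0.0,
    seed: int | None = None,
    max_retries: int = 1000,
) -> TimeTree:
    """Ultrametric bifurcating tree with exactly ``n_tips`` extant tips.

    Forward Gillespie simulation from a single lineage; the clock stops at
    the last instant before the extant lineage count would leave
    ``n_tips``.  Runs that go extinct before reaching ``n_tips`` are
    retried (simulate-and-prune conditioning); extinct side branches are
    pruned away.  Extant tips are labeled ``t1 .. tN``.
    """
    if not birth > death >= 0:
        raise SimulationError("need birth > death >= 0")
    if n_tips < 2:
        raise SimulationError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        tree = _one_bd_attempt(n_tips, birth, death, rng)
        if tree is not None:
            return tree
    raise SimulationError(
        f"extinction in {max_retries} consecutive birth-death attempts"
    )


def _one_bd_attempt(n_tips, birth, death, rng) -> TimeTree | None:
    # node records: parent, children, start time of subtending branch
    parent = [-1]
    children: list[list[int]] = [[]]
    start = [0.0]
    alive = [0]
    t = 0.0
    while True:
        n = len(alive)
        if n == 0:
            return None
        rate = n * (birth + death)
        dt = rng.exponential(1.0 / rate)
        if n == n_tips:
            # freeze just before the event that would change the count
            t += dt
            break
        t += dt
        k = alive[rng.integers(n)]
        if rng.random() < birth / (birth + death):
            for _ in range(2):
                parent.append(k)
                children[k].append(len(parent) - 1)
                children.append([])
                start.append(t)
            alive.remove(k)
            alive.extend(children[k])
        else:
            alive.remove(k)  # lineage dies; leaves a dead tip
    end = {}
    for i in range(len(parent)):
        if children[i]:
            end[i] = start[children[i][0]]
        elif i in alive:
            end[i] = t
        else:
            end[i] = None  # dead tip; branch end time unknown -> drop
    # drop dead subtrees by keeping only ancestors of living tips
    keep = set()
    for i in alive:
        j = i
        while j >= 0 and j not in keep:
            keep.add(j)
            j = parent[j]
    # suppress unary survivors (nodes with one living child)
    label = {}
    for k, i in enumerate(sorted(alive)):
        label[i] = f"t{k + 1}"

    new_parent: list[int] = []
    new_children: list[list[int]] = []
    new_brlen: list[float] = []
    new_labels: list[str | None] = []

    def living_children(i):
        return [c for c in children[i] if c in keep]

    root = 0
    while len(living_children(root)) == 1:
        root = living_children(root)[0]

    def add(i, par, length):
        j = len(new_parent)
        new_parent.append(par)
        new_children.append([])
        new_brlen.append(length)
        new_labels.append(label.get(i))
        if par >= 0:
            new_children[par].append(j)
        return j

    rj = add(root, -1, 0.0)
    stack = [(c, rj, start[c]) for c in living_children(root)]
    while stack:
        i, par, s0 = stack.pop()
        ch = living_children(i)
        if len(ch) == 1:
            stack.append((ch[0], par, s0))
            continue
        length = (end[i] if ch else t) - s0
        j = add(i, par, length)
        for c in ch:
            stack.append((c, j, start[c]))

    tree = TimeTree(
        np.array(new_parent), new_children, np.array(new_brlen), new_labels, root=0
    )
    return tree


def rescale_to_age(tree: TimeTree, root_age: float) -> TimeTree:
    """Uniformly rescale branch lengths so the root sits at ``root_age`` Ma."""
    out = tree.copy()
    cur = out.root_age
    if cur <= 0:
        raise SimulationError("cannot rescale a zero-depth tree")
    out.brlen = out.brlen * (root_age / cur)
    return out


# ---------------------------------------------------------------------
# forward DEC simulation (independent of the likelihood machinery)


def _mask_to_set(mask: int, n: int) -> frozenset[int]:
    return frozenset(a for a in range(n) if mask >> a & 1)


def _set_to_mask(s) -> int:
    m = 0
    for a in s:
        m |= 1 << a
    return m


#: stepping-stone dispersal multipliers between the nine regions, used only
#: by the study generator to emulate geographic structure (the likelihood
#: model remains plain DEC).  Order follows NINE_REGIONS.  1 = adjacent,
#: intermediate values = across one barrier, 0.02 = effectively disjunct.
REGION_ADJACENCY = np.full((9, 9), 0.02)
for _i, _j, _w in [
    (0, 1, 1.0),   # Palearctic - Indomalaya
    (0, 7, 0.2), (0, 8, 0.2),          # Palearctic - Afrotropics/Americas
    (1, 2, 1.0), (1, 3, 1.0), (1, 7, 0.2),  # Indomalaya outward
    (2, 3, 1.0), (2, 6, 0.2),          # Philippines - Wallacea/Pacific
    (3, 4, 1.0), (3, 5, 0.5),          # Wallacea - Australo-Papua/Bismarcks
    (4, 5, 1.0), (4, 6, 0.5),          # Australo-Papua outward
    (5, 6, 1.0),                       # Bismarcks+Solomons - Pacific
]:
    REGION_ADJACENCY[_i, _j] = REGION_ADJACENCY[_j, _i] = _w
np.fill_diagonal(REGION_ADJACENCY, 0.0)


def _simulate_branch(state: frozenset, t: float, n_areas, d, e, rng, rel=None):
    """Exact event-time CTMC along one branch; returns None on extinction.

    ``rel`` optionally modulates per-source-area dispersal (an area-by-area
    multiplier matrix); with ``rel=None`` the gain rate into area ``a`` is
    the plain-DEC ``d * |R|``.
    """
    while t > 0:
        occupied = len(state)
        if rel is None:
            gains = [(a, d * occupied) for a in range(n_areas) if a not in state]
        else:
            gains = [
                (a, d * sum(rel[s, a] for s in state))
                for a in range(n_areas)
                if a not in state
            ]
        losses = [(a, e) for a in state]
        total = sum(r for _, r in gains) + sum(r for _, r in losses)
        if total == 0:
            return state
        wait = rng.exponential(1.0 / total)
        if wait >= t:
            return state
        t -= wait
        u = rng.random() * total
        acc = 0.0
        for a, r in gains:
            acc += r
            if u < acc:
                state = state | {a}
                break
        else:
            for a, r in losses:
                acc += r
                if u < acc:
                    state = state - {a}
                    break
        if not state:
            return None  # range lost entirely: lineage extinct
    return state


def _clado_draw(state: frozenset, n_areas, params: DECParams, rng):
    """Draw an ordered cladogenetic daughter pair from the event weights.

    Direct enumeration from the process definition (sympatric copy for
    single areas, subset sympatry, single-area vicariance, founder jumps),
    kept deliberately separate from the likelihood's event table.
    """
    events: list[tuple[frozenset, frozenset, float]] = []
    if len(state) == 1:
        events.append((state, state, 2 * params.y))
    else:
        for a in state:
            single = frozenset([a])
            events.append((single, state, params.s))
            events.append((state, single, params.s))
            rest = state - single
            events.append((single, rest, params.v))
            if len(rest) > 1:  # avoid double-listing the 2-area split
                events.append((rest, single, params.v))
    if params.j > 0:
        for a in range(n_areas):
            if a not in state:
                single = frozenset([a])
                events.append((state, single, params.j))
                events.append((single, state, params.j))
    weights = np.array([w for _, _, w in events])
    k = rng.choice(len(events), p=weights / weights.sum())
    return events[k][0], events[k][1]


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated history."""

    node_states: dict[int, int]  # node -> bitmask before cladogenesis
    tip_states: dict[str, int]
    params: DECParams
    root_state: int
    branch_retries: int = 0


def sim_dec_history(
    tree: TimeTree,
    catalog: AreaCatalog,
    params: DECParams,
    root_state: int,
    seed: int | None = None,
    max_branch_retries: int = 1000,
    relative_rates: np.ndarray | None = None,
) -> tuple[dict[str, int], TruthRecord]:
    """Forward-simulate a DEC(+J) history down a tree.

    A branch whose lineage loses all areas (hits the null range) is
    resimulated from its starting state, conditioning the history on
    survival; the retry count is recorded in the returned truth record.
    ``relative_rates`` (area-by-area multipliers) can impose geographic
    structure on dispersal; leave ``None`` for the plain process matched
    by the likelihood machinery.
    """
    if root_state == 0:
        raise SimulationError("root state must be non-null")
    rng = np.random.default_rng(seed)
    n = catalog.n
    node_states: dict[int, int] = {}
    tip_states: dict[str, int] = {}
    retries = 0

    def recurse(node: int, incoming: frozenset):
        nonlocal retries
        node_states[node] = _set_to_mask(incoming)
        if tree.is_tip(node):
            tip_states[tree.labels[node]] = _set_to_mask(incoming)
            return
        left, right = tree.children[node]
        dl, dr = _clado_draw(incoming, n, params, rng)
        for child, dstate in ((left, dl), (right, dr)):
            t = float(tree.brlen[child])
            for attempt in itertools.count():
                out = _simulate_branch(dstate, t, n, params.d, params.e, rng,
                                       rel=relative_rates)
                if out is not None:
                    break
                retries += 1
                if attempt >= max_branch_retries:
                    raise SimulationError(
                        "branch resimulation cap exceeded (pervasive extinction)"
                    )
            recurse(child, out)

    tree.require_bifurcating()
    recurse(tree.root, _mask_to_set(root_state, n))
    truth = TruthRecord(
        node_states=node_states,
        tip_states=tip_states,
        params=params,
        root_state=root_state,
        branch_retries=retries,
    )
    return tip_states, truth


# ---------------------------------------------------------------------
# full synthetic study


@dataclass
class SimConfig:
    """Declarative configuration of a synthetic study.

    Defaults state the world the analysis assumes: clades 5-15 Ma old with
    4-185 tips (mean ~30), nine geographic regions, ~110 species carrying
    montane island populations across 31 islands split between two
    archipelagos.  Effect sizes are expressed as differences in root
    states, elevational turnover, and the probability that an island
    population is montane between the two continental source pools.
    """

    seed: int = 0
    n_clades: int = 4
    tips_range: tuple[int, int] = (4, 185)
    tips_mean: float = 30.0
    clade_age_range: tuple[float, float] = (5.0, 15.0)
    birth: float = 0.4
    death: float = 0.1
    target_species: int = 110
    n_islands: int = 31
    n_wallacea_islands: int = 17  # remainder: Bismarcks/Solomons
    geo_params: DECParams = field(default_factory=lambda: DECParams(d=0.08, e=0.08))
    #: modulate dispersal by the stepping-stone region graph so clades show
    #: the regional structure real avifaunas do
    structured_geography: bool = True
    elev_params_eurasian: DECParams = field(
        default_factory=lambda: DECParams(d=0.02, e=0.02)
    )
    elev_params_austral: DECParams = field(
        default_factory=lambda: DECParams(d=0.10, e=0.06)
    )
    mig_params: DECParams = field(default_factory=lambda: DECParams(d=0.03, e=0.05))
    #: probability that an island population of a montane-capable species is
    #: itself montane, per source pool
    p_mip_eurasian: float = 0.9
    p_mip_austral: float = 0.45
    #: mean number of island populations per species (geometric)
    mean_populations: float = 2.2
    max_clades: int = 40

    @classmethod
    def strong_effect(cls, seed: int = 0, **kw) -> "SimConfig":
        """The default world: clearly separated source pools."""
        return cls(seed=seed, **kw)

    @classmethod
    def zero_effect(cls, seed: int = 0, **kw) -> "SimConfig":
        """Both pools share elevational dynamics and MIP propensity, for
        type-I-error checks of the downstream group comparisons."""
        return cls(
            seed=seed,
            elev_params_austral=DECParams(d=0.02, e=0.02),
            p_mip_austral=0.9,
            **kw,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Load a config from a YAML file.

        Flat keys mirror the dataclass fields; the DEC-parameter sections
        (``geo_params``, ``elev_params_eurasian``, ``elev_params_austral``,
        ``mig_params``) are nested mappings with ``d``/``e``/``j`` keys,
        e.g.::

            seed: 7
            target_species: 60
            geo_params: {d: 0.08, e: 0.08}
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SimulationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("geo_params", "elev_params_eurasian",
                    "elev_params_austral", "mig_params"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = DECParams(**raw[key])
        for key in ("tips_range", "clade_age_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticStudy:
    """A complete synthetic input bundle plus ground truth."""

    config: SimConfig
    clade_names: list[str]
    trees: dict[str, TimeTree]
    geo_states: dict[str, dict[str, int]]  # clade -> tip -> bitmask
    elev_states: dict[str, dict[str, int]]
    mig_states: dict[str, dict[str, int]]
    populations: pd.DataFrame  # island-population table
    species_table: pd.DataFrame  # species, clade, true origin, migration
    truth: dict[str, dict[str, TruthRecord]]  # clade -> system -> record
    geo_catalog: AreaCatalog = field(
        default_factory=lambda: AreaCatalog(NINE_REGIONS)
    )
    elev_catalog: AreaCatalog = field(
        default_factory=lambda: AreaCatalog(ELEVATION_AREAS)
    )
    mig_catalog: AreaCatalog = field(
        default_factory=lambda: AreaCatalog(MIGRATION_AREAS)
    )

    def trait_frame(self, system: str) -> pd.DataFrame:
        """Tip-state table for one trait system across all clades."""
        states = {
            "geographic": (self.geo_states, self.geo_catalog),
            "elevational": (self.elev_states, self.elev_catalog),
            "migration": (self.mig_states, self.mig_catalog),
        }[system]
        per_clade, catalog = states
        rows = []
        for clade, tipmap in per_clade.items():
            for tip, mask in tipmap.items():
                row = {"species": tip, "clade": clade}
                for i, name in enumerate(catalog.names):
                    row[name] = int(mask >> i & 1)
                rows.append(row)
        return pd.DataFrame(rows)


def _true_origin(
    tree: TimeTree, truth: TruthRecord, tip_label: str, catalog: AreaCatalog
) -> str:
    """Origin label implied by the true (simulated) node states: walk
    rootward splitting composite ranges evenly among their areas."""
    eurasian = {catalog.index("Palearctic"), catalog.index("Indomalaya")}
    austral = {catalog.index("Australo-Papua")}
    node = tree.tip_index(tip_label)
    node = int(tree.parent[node])
    while node >= 0:
        areas = _mask_to_set(truth.node_states[node], catalog.n)
        if areas:
            p_eur = len(areas & eurasian) / len(areas)
            p_aus = len(areas & austral) / len(areas)
            if p_eur > 0.75:
                return "Eurasian"
            if p_aus > 0.75:
                return "Australo-Papuan"
        node = int(tree.parent[node])
    return "unresolved"


def _draw_tip_count(cfg: SimConfig, rng) -> int:
    lo, hi = cfg.tips_range
    # lognormal shape: many small clades, occasional large radiations
    mu = np.log(cfg.tips_mean) - 0.5
    n = int(np.round(rng.lognormal(mean=mu, sigma=1.0)))
    return int(np.clip(n, lo, hi))


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a full synthetic study bundle.

    Clades alternate between the Eurasian and Australo-Papuan source pools.
    Eurasian clades start from a Palearctic+Indomalaya root with montane
    elevational roots and low elevational turnover; Australo-Papuan clades
    start from an Australo-Papua root with lowland roots and faster
    turnover.  Clades are added until the island-population table holds
    close to ``target_species`` species (within 10%).
    """
    rng = np.random.default_rng(config.seed)
    geo_cat = AreaCatalog(NINE_REGIONS)
    elev_cat = AreaCatalog(ELEVATION_AREAS)
    mig_cat = AreaCatalog(MIGRATION_AREAS)

    focal_bits = {geo_cat.index("Wallacea"), geo_cat.index("Bismarcks+Solomons")}
    eurasian_root = geo_cat.mask("Palearctic", "Indomalaya")
    austral_root = geo_cat.mask("Australo-Papua")

    trees: dict[str, TimeTree] = {}
    geo_states: dict[str, dict[str, int]] = {}
    elev_states: dict[str, dict[str, int]] = {}
    mig_states: dict[str, dict[str, int]] = {}
    truth: dict[str, dict[str, TruthRecord]] = {}
    clade_names: list[str] = []
    species_rows: list[dict] = []
    mip_candidates: list[dict] = []

    lo_t, hi_t = 0.90 * config.target_species, 1.10 * config.target_species
    k = 0
    while k < config.max_clades:
        if k >= config.n_clades and len(mip_candidates) >= lo_t:
            break
        pool = "Eurasian" if k % 2 == 0 else "Australo-Papuan"
        name = f"clade{k + 1:02d}"
        n_tips = _draw_tip_count(config, rng)
        age = rng.uniform(*config.clade_age_range)
        tree = rescale_to_age(
            sim_birth_death_tree(
                n_tips, config.birth, config.death,
                seed=int(rng.integers(2**31)),
            ),
            age,
        )
        # unique species names per clade
        relabeled = tree.copy()
        for i in relabeled.tips():
            relabeled.labels[i] = f"{name}_{relabeled.labels[i]}"
        tree = relabeled

        geo_root = eurasian_root if pool == "Eurasian" else austral_root
        elev_root = (
            elev_cat.mask("Montane") if pool == "Eurasian" else elev_cat.mask("Lowland")
        )
        elev_par = (
            config.elev_params_eurasian
            if pool == "Eurasian"
            else config.elev_params_austral
        )
        mig_root = (
            mig_cat.mask("Sedentary", "Short")
            if pool == "Eurasian"
            else mig_cat.mask("Sedentary")
        )

        g_tips, g_truth = sim_dec_history(
            tree, geo_cat, config.geo_params, geo_root,
            seed=int(rng.integers(2**31)),
            relative_rates=REGION_ADJACENCY if config.structured_geography else None,
        )
        e_tips, e_truth = sim_dec_history(
            tree, elev_cat, elev_par, elev_root, seed=int(rng.integers(2**31))
        )
        m_tips, m_truth = sim_dec_history(
            tree, mig_cat, config.mig_params, mig_root,
            seed=int(rng.integers(2**31)),
        )

        trees[name] = tree
        geo_states[name] = g_tips
        elev_states[name] = e_tips
        mig_states[name] = m_tips
        truth[name] = {"geographic": g_truth, "elevational": e_truth,
                       "migration": m_truth}
        clade_names.append(name)

        for tip, gmask in g_tips.items():
            origin = _true_origin(tree, g_truth, tip, geo_cat)
            in_focal = bool(_mask_to_set(gmask, geo_cat.n) & focal_bits)
            montane = bool(e_tips[tip] & elev_cat.mask("Montane"))
            has_continent = bool(
                gmask & (eurasian_root | geo_cat.mask("Afrotropics",
                                                      "Americas"))
            )
            species_rows.append(
                {
                    "species": tip,
                    "clade": name,
                    "pool": pool,
                    "true_origin": origin,
                    "in_focal_archipelagos": in_focal,
                    "montane_capable": montane,
                    "has_continental_population": has_continent,
                    "short_migrant": bool(m_tips[tip] & mig_cat.mask("Short")),
                    "long_migrant": bool(m_tips[tip] & mig_cat.mask("Long")),
                }
            )
            if in_focal and montane:
                mip_candidates.append(species_rows[-1])
        k += 1

    rng.shuffle(mip_candidates)
    mip_species = mip_candidates[: int(hi_t)]

    populations = _build_population_table(mip_species, config, rng)
    species_table = pd.DataFrame(species_rows)

    study = SyntheticStudy(
        config=config,
        clade_names=clade_names,
        trees=trees,
        geo_states=geo_states,
        elev_states=elev_states,
        mig_states=mig_states,
        populations=populations,
        species_table=species_table,
        truth=truth,
    )
    _assert_consistent(study)
    return study


def _build_population_table(mip_species, config: SimConfig, rng) -> pd.DataFrame:
    islands = [f"island{i + 1:02d}" for i in range(config.n_islands)]
    archipelago = {
        isl: ("Wallacea" if i < config.n_wallacea_islands else "Bismarcks/Solomons")
        for i, isl in enumerate(islands)
    }
    rows = []
    for rec in mip_species:
        pool = rec["pool"]
        p_mip = config.p_mip_eurasian if pool == "Eurasian" else config.p_mip_austral
        n_pops = 1 + rng.geometric(1.0 / config.mean_populations)
        n_pops = min(n_pops, config.n_islands)
        occ = rng.choice(islands, size=n_pops, replace=False)
        is_mip = rng.random(n_pops) < p_mip
        if not is_mip.any():
            is_mip[rng.integers(n_pops)] = True  # every listed species has >=1 MIP
        genus = f"genus_{rec['clade']}_{rng.integers(6)}"
        family = f"family_{rec['clade']}"
        for isl, mip in zip(occ, is_mip):
            if mip:
                mn = rng.uniform(100, 1500)
                mx = mn + rng.uniform(300, 1500)
            else:
                mn = rng.uniform(0, 99)
                mx = mn + rng.uniform(500, 2000)
            rows.append(
                {
                    "species": rec["species"],
                    "island": isl,
                    "archipelago": archipelago[isl],
                    "min_masl": round(float(mn)),
                    "max_masl": round(float(mx)),
                    "genus": genus,
                    "family": family,
                }
            )
    return pd.DataFrame(rows)


def _assert_consistent(study: SyntheticStudy) -> None:
    """Ground truth and emitted tables must agree (checked at generation)."""
    for clade in study.clade_names:
        tree = study.trees[clade]
        for system, states in (
            ("geographic", study.geo_states[clade]),
            ("elevational", study.elev_states[clade]),
            ("migration", study.mig_states[clade]),
        ):
            rec = study.truth[clade][system]
            assert rec.tip_states == states, f"{clade}/{system} truth mismatch"
            for tip, mask in states.items():
                assert mask != 0
                assert tree.tip_index(tip) >= 0
    listed = set(study.populations["species"])
    known = set(study.species_table["species"])
    assert listed <= known
    mips = study.populations[study.populations["min_masl"] >= 100]
    assert set(mips["species"]) == listed  # every listed species has a MIP
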