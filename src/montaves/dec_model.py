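"""Dispersal-Extinction-Cladogenesis (DEC, DEC+J) ancestral reconstruction.

The model describes the evolution of a set-valued character — classically a
geographic range over discrete areas — on a time-calibrated tree.  Along
branches (anagenesis) a lineage gains areas at rate ``d`` per (source area,
gainable area) pair and loses areas at rate ``e``; at speciation
(cladogenesis) the range is partitioned among the daughters by sympatric
copying, subset sympatry, single-area vicariance, and — in the +J variant —
founder events that place one daughter in an area outside the ancestral
range, weighted ``j``.

Ranges are bitmasks over an :class:`AreaCatalog`.  The same machinery is
reused for elevational ranges (2-area catalog Lowland/Montane) and
migratory behavior (3-area catalog Sedentary/Short/Long): those traits
evolve by gaining and losing "areas" exactly as a geographic range does.

Likelihoods use Felsenstein pruning with matrix-exponential branch
transitions and cladogenetic mixing at internal nodes; the root is weighted
uniformly over non-null states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse
from scipy.sparse.linalg import expm_multiply

from .treekit import TimeTree, TreeError

__all__ = [
    "AreaCatalog",
    "StateSpace",
    "DECParams",
    "ReconstructionResult",
    "NINE_REGIONS",
    "ELEVATION_AREAS",
    "MIGRATION_AREAS",
    "build_state_space",
    "build_q_matrix",
    "clado_event_table",
    "log_likelihood",
    "fit_ml",
    "marginal_node_probs",
    "read_tip_states",
    "write_reconstruction",
]

#: the nine biogeographic regions used for geographic range scoring
NINE_REGIONS = (
    "Palearctic",
    "Indomalaya",
    "Philippines",
    "Wallacea",
    "Australo-Papua",
    "Bismarcks+Solomons",
    "Pacific",
    "Afrotropics",
    "Americas",
)

#: elevational character: breeding range spans lowlands, mountains, or both
ELEVATION_AREAS = ("Lowland", "Montane")

#: migratory character: movement classes shown by a species' populations
MIGRATION_AREAS = ("Sedentary", "Short", "Long")


class DECError(ValueError):
    """Invalid DEC input or state."""


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the best point found so far."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class AreaCatalog:
    """Ordered discrete areas, optionally with a lumping map.

    ``merge_map`` sends several original area names to one merged name
    (used e.g. to lump several island regions into a single region when a
    lone widespread species would otherwise confound nodal certainty).
    """

    names: tuple[str, ...]
    merge_map: dict[str, str] | None = None

    def __post_init__(self):
        if not 1 <= len(self.names) <= 16:
            raise DECError("area catalog must hold between 1 and 16 areas")
        if len(set(self.names)) != len(self.names):
            raise DECError("area names must be unique")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def mask(self, *names: str) -> int:
        """Bitmask for a set of area names."""
        m = 0
        for nm in names:
            m |= 1 << self.index(nm)
        return m

    def label(self, mask: int) -> str:
        if mask == 0:
            return "null"
        return "+".join(n for i, n in enumerate(self.names) if mask >> i & 1)

    def merged(self) -> tuple["AreaCatalog", dict[int, int]]:
        """Apply the merge map.

        Returns the merged catalog and a bit-to-bit map: original area bit
        index -> merged area bit index, for recoding tip bitmasks before
        state-space construction.
        """
        if not self.merge_map:
            return self, {i: i for i in range(self.n)}
        new_names: list[str] = []
        bitmap: dict[int, int] = {}
        for i, nm in enumerate(self.names):
            tgt = self.merge_map.get(nm, nm)
            if tgt not in new_names:
                new_names.append(tgt)
            bitmap[i] = new_names.index(tgt)
        return AreaCatalog(tuple(new_names)), bitmap

    def recode_mask(self, mask: int, bitmap: dict[int, int]) -> int:
        out = 0
        for i in range(self.n):
            if mask >> i & 1:
                out |= 1 << bitmap[i]
        return out


@dataclass
class StateSpace:
    """All non-empty area subsets up to ``max_range_size``, plus optionally
    the null (empty) range used inside the likelihood machinery.

    States are ordered by popcount then by bitmask value, so the null range
    (if included) is state 0 and single areas come next.
    """

    catalog: AreaCatalog
    max_range_size: int
    include_null: bool
    states: np.ndarray = field(init=False)
    index: dict[int, int] = field(init=False)

    def __post_init__(self):
        if not 1 <= self.max_range_size <= self.catalog.n:
            raise DECError("max_range_size must be in [1, number of areas]")
        masks = [
            m
            for m in range(1, 1 << self.catalog.n)
            if m.bit_count() <= self.max_range_size
        ]
        if self.include_null:
            masks.append(0)
        masks.sort(key=lambda m: (m.bit_count(), m))
        self.states = np.array(masks, dtype=np.int64)
        self.index = {int(m): i for i, m in enumerate(masks)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def null_index(self) -> int | None:
        return self.index.get(0)

    def nonnull_mask(self) -> np.ndarray:
        return self.states != 0

    def labels(self) -> list[str]:
        return [self.catalog.label(int(m)) for m in self.states]


def build_state_space(
    catalog: AreaCatalog, max_range_size: int | None = None, include_null: bool = True
) -> StateSpace:
    if max_range_size is None:
        max_range_size = catalog.n
    return StateSpace(catalog, max_range_size, include_null)


@dataclass(frozen=True)
class DECParams:
    """Anagenetic rates (per Ma) and cladogenetic weights.

    ``d``: area-gain (dispersal) rate per source area; ``e``: area-loss
    (extirpation) rate; ``j``: founder-event weight (0 recovers plain DEC).
    The sympatry/subset/vicariance weights ``y``, ``s``, ``v`` are fixed
    at 1.
    """

    d: float
    e: float
    j: float = 0.0
    y: float = 1.0
    s: float = 1.0
    v: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.d) and np.isfinite(self.e) and np.isfinite(self.j)):
            raise DECError("non-finite DEC parameters")
        if self.d < 0 or self.e < 0:
            raise DECError("rates d and e must be non-negative")
        if not 0 <= self.j <= 3:
            raise DECError("founder weight j must lie in [0, 3]")


def _q_basis(space: StateSpace):
    """Parameter-independent decomposition Q = d * Qd + e * Qe, cached on
    the state space (the sparsity structure never changes)."""
    cached = getattr(space, "_q_basis", None)
    if cached is not None:
        return cached
    n_areas = space.catalog.n
    rows_d, cols_d, vals_d = [], [], []
    rows_e, cols_e, vals_e = [], [], []
    for i, m in enumerate(space.states):
        m = int(m)
        if m == 0:
            continue  # null range is absorbing
        size = m.bit_count()
        for a in range(n_areas):
            bit = 1 << a
            if m & bit:
                tgt = space.index[m & ~bit]  # loss (null for single areas)
                rows_e += [i, i]
                cols_e += [tgt, i]
                vals_e += [1.0, -1.0]
            else:
                tgt = space.index.get(m | bit)
                if tgt is not None:  # respects the range-size cap
                    rows_d += [i, i]
                    cols_d += [tgt, i]
                    vals_d += [float(size), -float(size)]
    shape = (space.n_states, space.n_states)
    qd = scipy.sparse.csr_matrix((vals_d, (rows_d, cols_d)), shape=shape)
    qe = scipy.sparse.csr_matrix((vals_e, (rows_e, cols_e)), shape=shape)
    space._q_basis = (qd, qe)
    return qd, qe


def build_q_matrix(space: StateSpace, params: DECParams) -> scipy.sparse.csr_matrix:
    """Anagenetic rate matrix over the state space.

    From range ``R``: rate ``d * |R|`` to each ``R + {a}`` with ``a`` not in
    ``R`` (every occupied area is a potential source of the colonist); rate
    ``e`` to each ``R - {a}``; single areas extirpate to the null range,
    which is absorbing.  Rows sum to zero.
    """
    if space.null_index is None:
        raise DECError("Q matrix requires a state space built with the null range")
    if not (np.isfinite(params.d) and np.isfinite(params.e)):
        raise DECError("non-finite rates")
    qd, qe = _q_basis(space)
    return (params.d * qd + params.e * qe).tocsr()


def clado_event_table(
    space: StateSpace, params: DECParams
) -> dict[int, list[tuple[int, int, float]]]:
    """Per-ancestor-state cladogenetic events with normalized probabilities.

    Ordered daughter assignments are enumerated: for ancestor range ``R``,

    - sympatric copy (single-area ``R`` only): ``(R, R)``, weight ``y`` per
      order (two orders, coinciding);
    - subset sympatry (``|R| >= 2``): one daughter ``R``, the other a single
      area within ``R``, weight ``s`` per ordered pair;
    - vicariance (``|R| >= 2``): disjoint split with one single-area
      daughter, weight ``v`` per ordered pair;
    - founder (``j > 0``): one daughter ``R``, the other a single area
      outside ``R``, weight ``j`` per ordered pair.

    Returns ``{ancestor_mask: [(left_mask, right_mask, prob), ...]}`` with
    probabilities summing to 1 for each ancestor.
    """
    n_areas = space.catalog.n
    table: dict[int, list[tuple[int, int, float]]] = {}
    for m in space.states:
        m = int(m)
        if m == 0:
            continue
        weights: dict[tuple[int, int], float] = {}

        def add(left: int, right: int, w: float):
            if w > 0:
                weights[(left, right)] = weights.get((left, right), 0.0) + w

        bits = [1 << a for a in range(n_areas) if m >> a & 1]
        if len(bits) == 1:
            add(m, m, 2 * params.y)  # both orders of the identical copy
        else:
            for b in bits:
                add(b, m, params.s)
                add(m, b, params.s)
            vic = {(b, m & ~b) for b in bits} | {(m & ~b, b) for b in bits}
            for left, right in vic:
                add(left, right, params.v)
        for a in range(n_areas):
            b = 1 << a
            if not m & b:
                add(m, b, params.j)
                add(b, m, params.j)
        total = sum(weights.values())
        table[m] = [(l, r, w / total) for (l, r), w in weights.items()]
    return table


# -- likelihood machinery ----------------------------------------------

#: state-space size above which branch transitions switch from cached dense
#: matrix exponentials to sparse exponential actions
_DENSE_LIMIT = 64


def _clado_structure(space: StateSpace):
    """Event skeleton (ancestor, left, right, weight class), cached on the
    state space; weight classes are 0: sympatric copy (counted for both
    orders), 1: subset sympatry, 2: vicariance, 3: founder."""
    cached = getattr(space, "_clado_struct", None)
    if cached is not None:
        return cached
    n_areas = space.catalog.n
    anc, left, right, kind = [], [], [], []

    def add(m, l, r, k):
        anc.append(space.index[m])
        left.append(space.index[l])
        right.append(space.index[r])
        kind.append(k)

    for m in space.states:
        m = int(m)
        if m == 0:
            continue
        bits = [1 << a for a in range(n_areas) if m >> a & 1]
        if len(bits) == 1:
            add(m, m, m, 0)
        else:
            for b in bits:
                add(m, b, m, 1)
                add(m, m, b, 1)
            vic = {(b, m & ~b) for b in bits} | {(m & ~b, b) for b in bits}
            for l, r in vic:
                add(m, l, r, 2)
        for a in range(n_areas):
            b = 1 << a
            if not m & b:
                add(m, m, b, 3)
                add(m, b, m, 3)
    cached = (
        np.array(anc), np.array(left), np.array(right), np.array(kind)
    )
    space._clado_struct = cached
    return cached


class _CladoArrays:
    """Clado events flattened to index arrays for vectorized mixing."""

    def __init__(self, space: StateSpace, params: DECParams):
        anc, left, right, kind = _clado_structure(space)
        w = np.array([2 * params.y, params.s, params.v, params.j])[kind]
        norm = np.bincount(anc, weights=w, minlength=space.n_states)
        self.anc = anc
        self.left = left
        self.right = right
        self.prob = w / norm[anc]
        self.n_states = space.n_states

    def mix_down(self, down_left: np.ndarray, down_right: np.ndarray) -> np.ndarray:
        """Conditional likelihood at the ancestor just before cladogenesis."""
        out = np.zeros(self.n_states)
        np.add.at(
            out, self.anc, self.prob * down_left[self.left] * down_right[self.right]
        )
        return out

    def outside_daughter(
        self, out_parent: np.ndarray, down_sibling: np.ndarray, first: bool
    ) -> np.ndarray:
        """Outside weight at the top of a daughter branch.

        ``first`` selects whether the daughter takes the left or the right
        slot of the ordered event table.
        """
        own = self.left if first else self.right
        sib = self.right if first else self.left
        out = np.zeros(self.n_states)
        np.add.at(
            out, own, self.prob * out_parent[self.anc] * down_sibling[sib]
        )
        return out


class _BranchPropagator:
    """exp(Q t) actions: dense cached matrix exponentials for small state
    spaces; uniformization (Poisson-weighted sparse matvec series) for
    large ones, where per-call overhead of generic exponential-action
    routines would dominate."""

    #: truncation tolerance of the uniformization series
    _UNIF_TOL = 1e-14

    def __init__(self, q: scipy.sparse.csr_matrix):
        self.q = q
        self.n = q.shape[0]
        self._dense_cache: dict[float, np.ndarray] = {}
        self._use_dense = self.n <= _DENSE_LIMIT
        if self._use_dense:
            self._qd = q.toarray()
            # spectral shortcut: P(t) from one eigendecomposition instead
            # of a matrix exponential per distinct branch length
            self._spectral = None
            try:
                w, v = scipy.linalg.eig(self._qd)
                vinv = np.linalg.inv(v)
                if np.linalg.cond(v) < 1e7:
                    self._spectral = (w, v, vinv)
            except np.linalg.LinAlgError:
                pass
        else:
            self._rate = float(max(-q.diagonal().min(), 0.0))
            if self._rate > 0:
                eye = scipy.sparse.identity(self.n, format="csr")
                self._m = (eye + q / self._rate).tocsr()
                self._mt = self._m.T.tocsr()

    def _dense_p(self, t: float) -> np.ndarray:
        p = self._dense_cache.get(t)
        if p is None:
            if self._spectral is not None:
                w, v, vinv = self._spectral
                p = ((v * np.exp(w * t)) @ vinv).real
            else:
                p = scipy.linalg.expm(self._qd * t)
            self._dense_cache[t] = p
        return p

    def _uniformized(self, m: scipy.sparse.csr_matrix, t: float,
                     v: np.ndarray) -> np.ndarray:
        """exp(Q t) v = e^{-Λt} Σ_k (Λt)^k/k! M^k v with M = I + Q/Λ."""
        lam_t = self._rate * t
        if lam_t > 4000:  # extreme rates: defer to the generic routine
            a = self.q * t if m is self._m else self.q.T * t
            return expm_multiply(a, v)
        # Poisson weights in log space to survive large Λt
        log_w = -lam_t
        out = np.exp(log_w) * v
        term = v
        k = 0
        tail = 1.0 - np.exp(log_w)
        while tail > self._UNIF_TOL and k < 10_000:
            k += 1
            term = m @ term
            log_w += np.log(lam_t) - np.log(k)
            w = np.exp(log_w)
            out += w * term
            tail -= w
        return out

    def forward(self, t: float, v: np.ndarray) -> np.ndarray:
        """exp(Q t) @ v — integrates a conditional likelihood up a branch."""
        if t == 0:
            return v.copy()
        if self._use_dense:
            return self._dense_p(t) @ v
        if self._rate == 0:
            return v.copy()
        return self._uniformized(self._m, t, v)

    def backward(self, t: float, v: np.ndarray) -> np.ndarray:
        """exp(Q t).T @ v — pushes an outside weight down a branch."""
        if t == 0:
            return v.copy()
        if self._use_dense:
            return self._dense_p(t).T @ v
        if self._rate == 0:
            return v.copy()
        return self._uniformized(self._mt, t, v)


def _tip_vectors(
    tree: TimeTree, tip_states: dict[str, int], space: StateSpace
) -> dict[int, np.ndarray]:
    vecs: dict[int, np.ndarray] = {}
    for i in tree.tips():
        lab = tree.labels[i]
        if lab not in tip_states:
            raise DECError(f"tip {lab!r} has no observed state")
        mask = int(tip_states[lab])
        if mask == 0:
            raise DECError(f"tip {lab!r} has an empty observed range")
        if mask not in space.index:
            raise DECError(
                f"tip {lab!r} state {space.catalog.label(mask)} exceeds the "
                "range-size cap of the state space"
            )
        v = np.zeros(space.n_states)
        v[space.index[mask]] = 1.0
        vecs[i] = v
    return vecs


class _Pruning:
    """One Felsenstein pruning pass; retains per-node vectors for reuse by
    the marginal-probability up-pass."""

    def __init__(
        self,
        tree: TimeTree,
        tip_states: dict[str, int],
        space: StateSpace,
        params: DECParams,
    ):
        tree.require_bifurcating()
        self.tree = tree
        self.space = space
        self.params = params
        self.q = build_q_matrix(space, params)
        self.prop = _BranchPropagator(self.q)
        self.clado = _CladoArrays(space, params)
        self.cond = _tip_vectors(tree, tip_states, space)  # L_v, scaled
        self.down: dict[int, np.ndarray] = {}  # per-branch, at parent end
        self.log_scale = 0.0
        self._run()

    def _run(self):
        tree = self.tree
        for v in tree.postorder():
            if not tree.is_tip(v):
                c1, c2 = tree.children[v]
                cond = self.clado.mix_down(self.down[c1], self.down[c2])
                scale = cond.max()
                if scale <= 0:
                    raise DECError("conditional likelihood vanished; data "
                                   "impossible under the model")
                cond /= scale
                self.log_scale += np.log(scale)
                self.cond[v] = cond
            if v != tree.root:
                self.down[v] = self.prop.forward(
                    float(tree.brlen[v]), self.cond[v]
                )

    @property
    def root_prior(self) -> np.ndarray:
        pi = self.space.nonnull_mask().astype(float)
        return pi / pi.sum()

    @property
    def lnL(self) -> float:
        like = float(self.root_prior @ self.cond[self.tree.root])
        if like <= 0:
            return -np.inf
        return np.log(like) + self.log_scale


def log_likelihood(
    tree: TimeTree,
    tip_states: dict[str, int],
    params: DECParams,
    space: StateSpace | None = None,
    catalog: AreaCatalog | None = None,
) -> float:
    """DEC(+J) log-likelihood of observed tip ranges on a dated tree."""
    if space is None:
        if catalog is None:
            raise DECError("provide a StateSpace or an AreaCatalog")
        space = build_state_space(catalog)
    return _Pruning(tree, tip_states, space, params).lnL


@dataclass
class ReconstructionResult:
    """Fitted model plus marginal nodal state probabilities.

    ``node_probs[node_id]`` is a probability vector over ``space.states``
    giving the marginal state distribution immediately before cladogenesis
    at that node; tip rows are indicator vectors of the observed states.
    """

    space: StateSpace
    params: DECParams
    lnL: float
    aic: float
    model: str
    node_probs: dict[int, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def state_prob(self, node: int, mask: int) -> float:
        return float(self.node_probs[node][self.space.index[int(mask)]])

    def to_frame(self, tree: TimeTree) -> pd.DataFrame:
        """Long-format table: node id, state label, probability (>1e-12)."""
        rows = []
        labels = self.space.labels()
        for node, probs in sorted(self.node_probs.items()):
            for k, p in enumerate(probs):
                if p > 1e-12:
                    rows.append(
                        {
                            "node": node,
                            "tip_label": tree.labels[node] if tree.is_tip(node) else "",
                            "state": labels[k],
                            "probability": p,
                        }
                    )
        return pd.DataFrame(rows)


#: multi-start grid for (d, e) in per-Ma units; spans slow to fast regimes
_START_RATES = (0.01, 0.1, 1.0)
#: upper bound of 2 events/Ma/area is far beyond any plausible regime
_RATE_BOUNDS = (1e-9, 2.0)
_J_BOUNDS = (0.0, 3.0)


def fit_ml(
    tree: TimeTree,
    tip_states: dict[str, int],
    model: str = "DEC",
    space: StateSpace | None = None,
    catalog: AreaCatalog | None = None,
    seed: int | None = None,
    start_rates: tuple[float, ...] = _START_RATES,
) -> ReconstructionResult:
    """Maximum-likelihood fit of DEC or DEC+J with AIC.

    Bounded L-BFGS-B from a fixed small multi-start grid (optionally
    jittered by ``seed``); ``AIC = 2k - 2 lnL`` with ``k = 2`` (DEC) or
    ``3`` (DEC+J).  Marginal nodal probabilities are computed at the ML
    parameters.
    """
    model = model.upper().replace("+", "")
    if model not in ("DEC", "DECJ"):
        raise DECError(f"unknown model {model!r}; use 'DEC' or 'DEC+J'")
    plus_j = model == "DECJ"
    if space is None:
        if catalog is None:
            raise DECError("provide a StateSpace or an AreaCatalog")
        space = build_state_space(catalog)

    def objective(x: np.ndarray) -> float:
        d, e = np.exp(x[0]), np.exp(x[1])
        j = x[2] if plus_j else 0.0
        try:
            ll = log_likelihood(
                tree, tip_states, DECParams(d=d, e=e, j=j), space=space
            )
        except DECError:
            return 1e10
        return 1e10 if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts = []
    for d0 in start_rates:
        for e0 in start_rates:
            s = [np.log(d0), np.log(e0)]
            if plus_j:
                s.append(0.1)
            starts.append(np.array(s))
    if seed is not None:
        starts = [s + rng.normal(scale=0.05, size=s.shape) for s in starts]

    log_bounds = [tuple(np.log(_RATE_BOUNDS))] * 2
    bounds = log_bounds + ([_J_BOUNDS] if plus_j else [])
    best = None
    for s in starts:
        res = scipy.optimize.minimize(
            objective, s, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e10:
        raise FitError("DEC optimization failed from every start point", best=best)

    params = DECParams(
        d=float(np.exp(best.x[0])),
        e=float(np.exp(best.x[1])),
        j=float(best.x[2]) if plus_j else 0.0,
    )
    lnL = -float(best.fun)
    k = 3 if plus_j else 2
    result = marginal_node_probs(tree, tip_states, params, space=space)
    result.lnL = lnL
    result.aic = 2 * k - 2 * lnL
    result.model = "DEC+J" if plus_j else "DEC"
    result.metadata.update(
        {"k": k, "root_prior": "uniform over non-null states",
         "optimizer": "L-BFGS-B multi-start", "seed": seed}
    )
    return result


def marginal_node_probs(
    tree: TimeTree,
    tip_states: dict[str, int],
    params: DECParams,
    space: StateSpace | None = None,
    catalog: AreaCatalog | None = None,
) -> ReconstructionResult:
    """Marginal state probabilities at every node for fixed parameters.

    Down-pass conditionals (Felsenstein pruning) are combined with an
    up-pass of outside weights; each node's vector refers to its state
    immediately before cladogenesis and sums to 1.  Tips keep their
    observed indicator vectors.
    """
    if space is None:
        if catalog is None:
            raise DECError("provide a StateSpace or an AreaCatalog")
        space = build_state_space(catalog)
    pr = _Pruning(tree, tip_states, space, params)
    tree_ = pr.tree

    outside: dict[int, np.ndarray] = {tree_.root: pr.root_prior}
    node_probs: dict[int, np.ndarray] = {}
    for v in tree_.preorder():
        if tree_.is_tip(v):
            node_probs[v] = pr.cond[v].copy()
            continue
        m = outside[v] * pr.cond[v]
        total = m.sum()
        if total <= 0:
            raise DECError(f"zero marginal likelihood at node {v}")
        node_probs[v] = m / total
        c1, c2 = tree_.children[v]
        for child, sib, first in ((c1, c2, True), (c2, c1, False)):
            top = pr.clado.outside_daughter(outside[v], pr.down[sib], first)
            out_child = pr.prop.backward(float(tree_.brlen[child]), top)
            s = out_child.max()
            outside[child] = out_child / s if s > 0 else out_child

    k = 3 if params.j > 0 else 2
    return ReconstructionResult(
        space=space,
        params=params,
        lnL=pr.lnL,
        aic=2 * k - 2 * pr.lnL,
        model="DEC+J" if params.j > 0 else "DEC",
        node_probs=node_probs,
        metadata={"root_prior": "uniform over non-null states"},
    )


# -- tabular I/O -------------------------------------------------------


def read_tip_states(
    path_or_buf, catalog: AreaCatalog, sep: str = "\t"
) -> dict[str, int]:
    """Read a delimited tip-state table: tip label column plus one 0/1
    column per area (column names must match the catalog).  The catalog's
    merge map, if any, is applied to the returned bitmasks."""
    df = pd.read_csv(path_or_buf, sep=sep)
    label_col = df.columns[0]
    missing = [n for n in catalog.names if n not in df.columns]
    if missing:
        raise DECError(f"trait table lacks area column(s): {missing}")
    merged_cat, bitmap = catalog.merged()
    states: dict[str, int] = {}
    for _, row in df.iterrows():
        mask = 0
        for i, name in enumerate(catalog.names):
            if int(row[name]):
                mask |= 1 << i
        states[str(row[label_col])] = catalog.recode_mask(mask, bitmap)
    return states


def write_reconstruction(
    result: ReconstructionResult, tree: TimeTree, path, sep: str = "\t"
) -> None:
    result.to_frame(tree).to_csv(path, sep=sep, index=False)
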