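"""Assembly and integration of the coupled reaction-diffusion system.

Diffusion on a branched 1D morphology discretizes into a linear system with
tree-structured sparsity: ordered parent-before-child, every row touches
only itself and its parent, so one leaf-to-root elimination sweep followed
by a root-to-leaf substitution solves it exactly in O(n) operations
(:class:`TreeMatrix` / :func:`tree_solve`).  Section ends meet at explicit
zero-volume *conservation nodes* whose algebraic rows force the net flux
through each junction to zero; those rows sum to zero, and the matrix is in
general asymmetric because volume rows are scaled by the local compartment
volume.

Time stepping is operator-split implicit Euler: each step advances diffusion
first (one tree solve per species/region block), then the reactions (one
linearized implicit-Euler/Newton solve per spatial location, using exact
symbolic Jacobian blocks).  The splitting error vanishes as dt → 0.  For
adaptive integration the model exposes a method-of-lines right-hand side
plus Jacobians (:meth:`Model.rhs_full`, :meth:`Model.full_jacobian`, and the
split approximate solve :meth:`Model.approx_jacobian_solve`); the bundled
driver :meth:`Model.run_adaptive` hands these to scipy's stiff BDF
integrator.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .expressions import (
    CompileError,
    compile_expression,
    differentiate,
    references,
)
from .morphology import Section
from .regions import Region
from .reactions import (
    GeneralizedReaction,
    MM_PER_MOLECULE_PER_UM3,
    MultiCompartmentReaction,
    ReactionError,
)
from .species import Node, Parameter, Species, SpeciesOnRegion, State

logger = logging.getLogger("dendrochem")

__all__ = [
    "ModelError",
    "StepFailure",
    "SingularMatrixError",
    "TreeMatrix",
    "tree_solve",
    "assemble_diffusion",
    "Model",
]

#: retry limit for dt-halving after a failed step
MAX_STEP_RETRIES = 10


class ModelError(RuntimeError):
    """Model mis-specification or unrecoverable integration failure."""


class StepFailure(RuntimeError):
    """A single implicit step failed (singular block or non-finite update)."""


class SingularMatrixError(StepFailure):
    """Zero pivot during tree elimination; names the offending node."""


# ---------------------------------------------------------------------------
# tree-structured linear algebra
# ---------------------------------------------------------------------------


class TreeMatrix:
    """A linear system whose sparsity graph is a forest.

    Rows are ordered so every parent index precedes its children.  Row ``i``
    holds ``diag[i]`` on the diagonal and ``lower[i]`` in the parent column
    ``parent[i]``; the transposed coupling ``upper[i]`` sits at
    ``(parent[i], i)``.  ``upper`` need not equal ``lower`` — entries depend
    on the volumes of the two compartments they connect.  Rows flagged in
    ``is_junction`` are algebraic conservation rows (zero volume) and sum to
    zero across their entries.
    """

    def __init__(self, parent, diag, lower, upper, is_junction=None, labels=None,
                 indices=None):
        self.parent = np.asarray(parent, dtype=np.intp)
        self.diag = np.asarray(diag, dtype=float)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.n = len(self.diag)
        self.is_junction = (
            np.zeros(self.n, bool) if is_junction is None
            else np.asarray(is_junction, bool)
        )
        self.labels = labels
        #: global state-vector index per row (local rows are tree-ordered)
        self.indices = (
            np.arange(self.n) if indices is None
            else np.asarray(indices, dtype=np.intp)
        )
        self.last_op_count = 0
        if np.any(self.parent >= np.arange(self.n)):
            raise ModelError("tree ordering violated: parent index must precede child")

    def _label(self, i: int) -> str:
        return self.labels[i] if self.labels else f"node {i}"

    def solve(self, rhs) -> np.ndarray:
        """Exact solve by leaf-to-root elimination, root-to-leaf substitution.

        Runs in O(n): one elimination and one substitution operation per
        node (tracked in ``last_op_count``).  Raises
        :class:`SingularMatrixError` on a zero pivot, naming the node.
        """
        d = self.diag.copy()
        b = np.array(rhs, dtype=float)
        if b.shape != (self.n,):
            raise ValueError(f"rhs must have shape ({self.n},)")
        parent, lower, upper = self.parent, self.lower, self.upper
        ops = 0
        for i in range(self.n - 1, -1, -1):
            p = parent[i]
            if p < 0:
                continue
            if d[i] == 0.0:
                raise SingularMatrixError(f"zero pivot at {self._label(i)}")
            f = upper[i] / d[i]
            d[p] -= f * lower[i]
            b[p] -= f * b[i]
            ops += 1
        x = np.empty(self.n)
        for i in range(self.n):
            if d[i] == 0.0:
                raise SingularMatrixError(f"zero pivot at {self._label(i)}")
            p = parent[i]
            if p < 0:
                x[i] = b[i] / d[i]
            else:
                x[i] = (b[i] - lower[i] * x[p]) / d[i]
            ops += 1
        self.last_op_count = ops
        return x

    def to_dense(self) -> np.ndarray:
        """Dense copy (for oracles and inspection only)."""
        a = np.zeros((self.n, self.n))
        a[np.arange(self.n), np.arange(self.n)] = self.diag
        for i in range(self.n):
            p = self.parent[i]
            if p >= 0:
                a[i, p] = self.lower[i]
                a[p, i] = self.upper[i]
        return a


def tree_solve(matrix: TreeMatrix, rhs) -> np.ndarray:
    """Solve ``matrix @ x = rhs`` in O(n) via the tree elimination."""
    return matrix.solve(rhs)


# ---------------------------------------------------------------------------
# diffusion block assembly
# ---------------------------------------------------------------------------


def _region_vertices(sections: Sequence[Section]) -> dict:
    """Partition the ends of ``sections`` into shared junction vertices.

    Returns {(section_position, end): vertex id} considering only
    connections internal to the given section set.
    """
    pos = {id(s): k for k, s in enumerate(sections)}
    uf: dict = {}

    def find(k):
        while uf.get(k, k) != k:
            uf[k] = uf.get(uf[k], uf[k])
            k = uf[k]
        return k

    for sec in sections:
        if sec.parent is not None and id(sec.parent) in pos:
            a = (pos[id(sec)], 0)
            b = (pos[id(sec.parent)], sec.parent_x)
            ra, rb = find(a), find(b)
            if ra != rb:
                uf[ra] = rb
    vid: dict = {}
    out: dict = {}
    for k in range(len(sections)):
        for end in (0, 1):
            r = find((k, end))
            if r not in vid:
                vid[r] = len(vid)
            out[(k, end)] = vid[r]
    return out


class _DiffusionBlock:
    """Cached tree system for one (species, region) pair.

    Holds the local node ordering (parent-before-child), per-edge diffusive
    conductances g = D·A/Δx (µm³/ms), volumes, the global state indices, and
    junction adjacency; produces implicit-Euler :class:`TreeMatrix` systems
    for any dt and the junction-eliminated sparse operator used for
    method-of-lines integration.
    """

    def __init__(self, model: "Model", species: Species, region: Region):
        self.species = species
        self.region = region
        D = species.d
        sections = region.sections

        # node keys: ('s', k, i) segment, ('j', vid) junction vertex
        vert = _region_vertices(sections)
        seg_gidx = {}
        for k, sec in enumerate(sections):
            for i in range(sec.nseg):
                seg_gidx[(k, i)] = model._node_index[(id(species), id(region),
                                                      id(sec), i)]
        jun_gidx = model._junction_index.get((id(species), id(region)), {})

        adj: dict = {}

        def add_edge(a, b, g):
            adj.setdefault(a, []).append((b, g))
            adj.setdefault(b, []).append((a, g))

        # conductances are 0 when the species does not diffuse; the edges
        # still order the nodes and identify junction neighbors
        for k, sec in enumerate(sections):
            dx = sec.dx
            for i in range(sec.nseg):
                adj.setdefault(("s", k, i), [])
            for i in range(1, sec.nseg):
                g = D * region.neighbor_area(sec, i) / dx
                add_edge(("s", k, i - 1), ("s", k, i), g)
            g0 = D * region.neighbor_area(sec, 0) / (dx / 2.0)
            add_edge(("j", vert[(k, 0)]), ("s", k, 0), g0)
            g1 = D * region.neighbor_area(sec, sec.nseg) / (dx / 2.0)
            add_edge(("j", vert[(k, 1)]), ("s", k, sec.nseg - 1), g1)
        for vid in set(vert.values()):
            adj.setdefault(("j", vid), [])

        # depth-first ordering, parent before child
        order: list = []
        parent_of: dict = {}
        g_of: dict = {}
        visited: set = set()
        for start in sorted(adj, key=_node_sort_key):
            if start in visited:
                continue
            stack = [(start, None, 0.0)]
            while stack:
                node, par, g = stack.pop()
                if node in visited:
                    continue
                visited.add(node)
                parent_of[node] = par
                g_of[node] = g
                order.append(node)
                for nb, gg in adj[node]:
                    if nb not in visited:
                        stack.append((nb, node, gg))

        local = {key: i for i, key in enumerate(order)}
        n = len(order)
        self.n = n
        self.parent = np.array(
            [-1 if parent_of[k] is None else local[parent_of[k]] for k in order],
            dtype=np.intp,
        )
        self.g_parent = np.array([g_of[k] for k in order])
        self.is_junction = np.array([k[0] == "j" for k in order])
        self.volumes = np.array(
            [
                0.0 if k[0] == "j"
                else region.volume(sections[k[1]], k[2])
                for k in order
            ]
        )
        self.gsum = np.zeros(n)
        for key in order:
            self.gsum[local[key]] = sum(g for _, g in adj[key])
        self.global_idx = np.array(
            [
                jun_gidx[k[1]] if k[0] == "j" else seg_gidx[(k[1], k[2])]
                for k in order
            ],
            dtype=np.intp,
        )
        self.labels = [
            (
                f"junction {k[1]} ({species!r} on {region.name})"
                if k[0] == "j"
                else f"{sections[k[1]].name}({(k[2] + 0.5) / sections[k[1]].nseg:.3g})"
                f" ({species!r} on {region.name})"
            )
            for k in order
        ]
        # junction adjacency in local indices, for refresh + reduced operator
        self.junction_neighbors = {
            local[key]: [(local[nb], g) for nb, g in adj[key]]
            for key in order
            if key[0] == "j"
        }
        self._matrices: dict = {}
        self._reduced = None

    def matrix(self, dt: float) -> TreeMatrix:
        """Implicit-Euler system for step dt.

        Volume rows: (V + dt·Σg)·c_i − dt·g·c_nb = V·c_old.  Junction rows
        are algebraic: Σg·c_j − Σ g·c_nb = 0 (they sum to zero).
        """
        tm = self._matrices.get(dt)
        if tm is not None:
            return tm
        jun = self.is_junction
        diag = np.where(jun, self.gsum, self.volumes + dt * self.gsum)
        # make isolated junction rows (d == 0) trivially nonsingular
        diag = np.where(jun & (self.gsum == 0.0), 1.0, diag)
        row_scale = np.where(jun, 1.0, dt)
        lower = -row_scale * self.g_parent
        parent_scale = np.where(
            (self.parent >= 0) & jun[np.maximum(self.parent, 0)], 1.0, dt
        )
        upper = -parent_scale * self.g_parent
        tm = TreeMatrix(self.parent, diag, lower, upper, jun, self.labels,
                        indices=self.global_idx)
        self._matrices[dt] = tm
        return tm

    def step(self, state: np.ndarray, dt: float) -> None:
        """One implicit-Euler diffusion advance for this block (in place)."""
        tm = self.matrix(dt)
        c = state[self.global_idx]
        rhs = np.where(self.is_junction, 0.0, self.volumes * c)
        state[self.global_idx] = tm.solve(rhs)

    def update_junctions(self, state: np.ndarray) -> None:
        """Set junction entries to their flux-consistent interpolated values."""
        for j, nbs in self.junction_neighbors.items():
            if not nbs:
                continue
            gtot = sum(g for _, g in nbs)
            if gtot > 0:
                val = sum(g * state[self.global_idx[i]] for i, g in nbs) / gtot
            else:  # no diffusion: plain average of the adjacent segment ends
                val = np.mean([state[self.global_idx[i]] for i, _ in nbs])
            state[self.global_idx[j]] = val

    def reduced_entries(self):
        """COO entries (global rows, cols, values) of the junction-eliminated
        operator: dc/dt = R·c restricted to segment nodes."""
        if self._reduced is not None:
            return self._reduced
        rows: list = []
        cols: list = []
        vals: list = []
        pair_flux: dict = {}

        def add_flux(a, b, g):
            pair_flux[(a, b)] = pair_flux.get((a, b), 0.0) + g

        for i in range(self.n):
            p = self.parent[i]
            if p < 0 or self.g_parent[i] == 0.0:
                continue
            if not self.is_junction[i] and not self.is_junction[p]:
                add_flux(i, p, self.g_parent[i])
                add_flux(p, i, self.g_parent[i])
        for _, nbs in self.junction_neighbors.items():
            gtot = sum(g for _, g in nbs)
            if gtot <= 0:
                continue
            for a, ga in nbs:
                for b, gb in nbs:
                    if a != b:
                        add_flux(a, b, ga * gb / gtot)
        for (a, b), g in pair_flux.items():
            ga_over_v = g / self.volumes[a]
            rows.append(self.global_idx[a])
            cols.append(self.global_idx[b])
            vals.append(ga_over_v)
            rows.append(self.global_idx[a])
            cols.append(self.global_idx[a])
            vals.append(-ga_over_v)
        self._reduced = (
            np.array(rows, dtype=np.intp),
            np.array(cols, dtype=np.intp),
            np.array(vals, dtype=float),
        )
        return self._reduced


def _node_sort_key(key):
    return (0, key[1], key[2]) if key[0] == "s" else (1, key[1], 0)


def assemble_diffusion(
    model: "Model", species: Species, region: Region, dt: Optional[float] = None
) -> TreeMatrix:
    """The implicit-Euler tree system for one species/region block."""
    model._require_ready()
    for block in model._blocks:
        if block.species is species and block.region is region:
            return block.matrix(model.dt if dt is None else dt)
    raise ModelError(f"no diffusion block for {species!r} on {region.name!r}")


# ---------------------------------------------------------------------------
# reaction compilation
# ---------------------------------------------------------------------------


class _CompiledReaction:
    """A reaction bound to its active locations and the state vector."""

    def __init__(self, model: "Model", rxn: GeneralizedReaction):
        self.rxn = rxn
        flux = rxn.flux_expression()
        refs = references(flux)
        targets = rxn.net_stoichiometry()
        all_actors = list(targets) + [r for r in refs if r not in targets]

        unqualified = [
            a for a in all_actors if isinstance(a, (Species, State))
        ]
        qualified = [a for a in all_actors if isinstance(a, SpeciesOnRegion)]
        params = [a for a in all_actors if isinstance(a, Parameter)]

        if isinstance(rxn, MultiCompartmentReaction) and unqualified:
            raise ReactionError(
                "MultiCompartmentReaction references must be region-qualified"
            )

        # candidate regions: override, else every region hosting all
        # unqualified actors; purely qualified reactions use one pass.
        if rxn.regions is not None:
            candidates: list = list(rxn.regions)
        elif unqualified:
            candidates = [
                r
                for r in unqualified[0].regions
                if all(r in a.regions for a in unqualified[1:])
            ]
        else:
            candidates = [None]

        membrane = getattr(rxn, "membrane", None)
        locations: list = []  # (region-or-None, section, i)
        for cand in candidates:
            if cand is not None:
                secs = list(cand.sections)
            else:
                secs = list(qualified[0].region.sections) if qualified else []
            for sec in secs:
                if any(sec not in q.region.sections for q in qualified):
                    continue
                if any(
                    p.regions is not None
                    and not any(sec in r.sections for r in p.regions)
                    for p in params
                ):
                    continue
                if membrane is not None and not membrane.covers(sec):
                    continue
                for i in range(sec.nseg):
                    locations.append((cand, sec, i))

        self.n_loc = len(locations)
        if self.n_loc == 0:
            self.targets = []
            self.jac_terms = []
            return

        def idx_of(actor, loc):
            cand, sec, i = loc
            if isinstance(actor, SpeciesOnRegion):
                return model._node_index[
                    (id(actor.species), id(actor.region), id(sec), i)
                ]
            try:
                return model._node_index[(id(actor), id(cand), id(sec), i)]
            except KeyError:
                raise CompileError(
                    f"{actor!r} has no node on {cand!r} at "
                    f"{sec.name}({(i + 0.5) / sec.nseg:.3g})"
                ) from None

        index_map: dict = {}
        for actor in all_actors:
            if isinstance(actor, Parameter):
                index_map[actor] = actor.value
            else:
                index_map[actor] = np.array(
                    [idx_of(actor, loc) for loc in locations], dtype=np.intp
                )

        self.index_map = index_map
        self.flux_fn = compile_expression(flux, index_map)

        # geometric scale factors per target
        def scales(ref) -> np.ndarray:
            if not isinstance(rxn, MultiCompartmentReaction):
                return np.ones(self.n_loc)
            out = np.empty(self.n_loc)
            for k, (_, sec, i) in enumerate(locations):
                vol = ref.region.volume(sec, i)
                if vol <= 0:
                    raise ReactionError(
                        f"zero volume compartment for {ref!r} at {sec.name}({i})"
                    )
                area = rxn.membrane.area(sec, i) if rxn.scale_by_area else 1.0
                out[k] = area * MM_PER_MOLECULE_PER_UM3 / vol
            return out

        self.targets = [
            (index_map[ref], float(m), scales(ref))
            for ref, m in targets.items()
            if m != 0
        ]

        # symbolic Jacobian terms: d(rate at target)/d(state at wrt)
        dynamic_refs = [
            a for a in refs if not isinstance(a, Parameter)
        ]
        self.jac_terms = []
        for t_idx, coef, scale in self.targets:
            for w in dynamic_refs:
                d = differentiate(flux, w)
                if d.kind == "const" and d.value == 0.0:
                    continue
                dfn = compile_expression(d, index_map)
                self.jac_terms.append((t_idx, index_map[w], coef, scale, dfn))

        self.current_factor = (
            rxn.current_density_factor()
            if isinstance(rxn, MultiCompartmentReaction) and rxn.membrane_flux
            else None
        )

    def flux(self, state: np.ndarray) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.flux_fn(state), float), (self.n_loc,)
        )

    def add_rhs(self, state: np.ndarray, out: np.ndarray) -> None:
        if self.n_loc == 0:
            return
        f = self.flux(state)
        for t_idx, coef, scale in self.targets:
            np.add.at(out, t_idx, coef * scale * f)

    def jac_entries(self, state: np.ndarray):
        """Yield (rows, cols, values) triples of the reaction Jacobian."""
        for t_idx, w_idx, coef, scale, dfn in self.jac_terms:
            v = np.broadcast_to(np.asarray(dfn(state), float), (self.n_loc,))
            yield t_idx, w_idx, coef * scale * v


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class Model:
    """A complete reaction-diffusion model: actors, kinetics, and state.

    Parameters
    ----------
    species:
        Species and State objects (order fixes the state-vector layout).
    reactions:
        Rate / Reaction / MultiCompartmentReaction objects.
    dt:
        Default fixed time step (ms).
    atol:
        Absolute tolerance used by the adaptive driver and by the
        negative-concentration diagnostic (a warning is logged whenever any
        state drops below −10·atol; values are never clamped).
    """

    def __init__(self, species=(), reactions=(), morphology=None, dt: float = 0.025,
                 atol: float = 1e-13):
        self.species: list = list(species)
        self.reactions: list = list(reactions)
        self.morphology = morphology
        self.dt = float(dt)
        self.atol = float(atol)
        self.t = 0.0
        self.state: Optional[np.ndarray] = None
        self._initialized = False
        self._needs_rebuild = False
        self._warned_negative = False
        self._jac_cache: dict = {}
        self._jac_version = 0

    # -- registration ------------------------------------------------------

    def add(self, obj) -> None:
        """Register a species/state or a reaction (forces re-assembly)."""
        if isinstance(obj, (Species, State)):
            self.species.append(obj)
        elif isinstance(obj, GeneralizedReaction):
            self.reactions.append(obj)
        else:
            raise ModelError(f"cannot register {obj!r}")
        if self._initialized:
            self._needs_rebuild = True

    # -- initialization ----------------------------------------------------

    def initialize(self) -> np.ndarray:
        """Build nodes and the state vector, apply initial values, assemble
        and cache the diffusion systems, and compile the reactions.

        Explicit ``initial`` arguments win over any prior per-node
        assignment.  Junction entries are initialized flux-consistently from
        their neighbors.  Returns the state vector.
        """
        if not self.species:
            raise ModelError("a model needs at least one species or state")
        self._node_index: dict = {}
        self._junction_index: dict = {}
        self._nodes: dict = {}
        idx = 0
        for actor in self.species:
            if not isinstance(actor, (Species, State)):
                raise ModelError(f"{actor!r} is not a Species or State")
            for region in actor.regions:
                nodes = []
                for sec in region.sections:
                    for i in range(sec.nseg):
                        vol = region.volume(sec, i)
                        if not (vol > 0):
                            raise ModelError(
                                f"non-positive volume at {sec.name}({i}) on "
                                f"{region.name}"
                            )
                        node = Node(actor, region, sec, i, vol, idx, self)
                        self._node_index[(id(actor), id(region), id(sec), i)] = idx
                        nodes.append(node)
                        idx += 1
                self._nodes[(id(actor), id(region))] = nodes
                if isinstance(actor, Species):
                    vert = _region_vertices(region.sections)
                    jmap = {}
                    for vid in sorted(set(vert.values())):
                        jmap[vid] = idx
                        idx += 1
                    self._junction_index[(id(actor), id(region))] = jmap
        if idx == 0:
            raise ModelError("model has no nodes")

        self.state = np.zeros(idx)
        self.t = 0.0
        for actor in self.species:
            actor._model = self
            init = actor.initial
            for region in actor.regions:
                for node in self._nodes[(id(actor), id(region))]:
                    if callable(init):
                        self.state[node.index] = float(init(node))
                    elif init is not None:
                        self.state[node.index] = float(init)

        self._initialized = True
        self._needs_rebuild = False
        self._blocks = [
            _DiffusionBlock(self, actor, region)
            for actor in self.species
            if isinstance(actor, Species)
            for region in actor.regions
        ]
        for block in self._blocks:
            block.update_junctions(self.state)
        self._compiled = [_CompiledReaction(self, r) for r in self.reactions]
        self._jac_is_diagonal = all(
            np.array_equal(t, w)
            for cr in self._compiled
            for (t, w, *_rest) in cr.jac_terms
        )
        self._diffusion_jacobian_cache = None
        self._jac_cache = {}
        self._jac_version += 1
        return self.state

    def _require_ready(self) -> None:
        if not self._initialized:
            raise ModelError("model not initialized; call initialize() first")
        if self._needs_rebuild:
            self._rebuild()

    def _rebuild(self) -> None:
        """Re-assemble after late registration, preserving node values."""
        saved = {key: self.state[i] for key, i in self._node_index.items()}
        t = self.t
        self.initialize()
        for key, val in saved.items():
            if key in self._node_index:
                self.state[self._node_index[key]] = val
        for block in self._blocks:
            block.update_junctions(self.state)
        self.t = t

    def _nodes_of(self, actor, region) -> list:
        self._require_ready()
        try:
            return self._nodes[(id(actor), id(region))]
        except KeyError:
            raise ModelError(f"{actor!r} has no nodes on {region!r}") from None

    @property
    def nodes(self) -> list:
        self._require_ready()
        return [n for nodes in self._nodes.values() for n in nodes]

    def gather(self) -> np.ndarray:
        """Copy of the flat state vector."""
        self._require_ready()
        return self.state.copy()

    def scatter(self, values) -> None:
        """Write a flat vector back into the states (inverse of gather)."""
        self._require_ready()
        values = np.asarray(values, float)
        if values.shape != self.state.shape:
            raise ModelError("scatter: shape mismatch")
        self.state[:] = values

    # -- fixed-step integration -------------------------------------------

    def diffusion_step(self, dt: Optional[float] = None) -> np.ndarray:
        """Implicit-Euler diffusion advance of every species/region block."""
        self._require_ready()
        dt = self.dt if dt is None else float(dt)
        for block in self._blocks:
            if block.species.d > 0:
                block.step(self.state, dt)
        return self.state

    def reaction_step(self, dt: Optional[float] = None) -> np.ndarray:
        """One linearized implicit-Euler (single Newton) reaction advance.

        Solves (I − dt·J)Δc = dt·r(c) per spatial location using the exact
        symbolic Jacobian blocks, then applies c += Δc.  Raises
        :class:`StepFailure` on singular blocks or non-finite updates.
        """
        self._require_ready()
        dt = self.dt if dt is None else float(dt)
        if not self._compiled:
            return self.state
        n = len(self.state)
        r = np.zeros(n)
        for cr in self._compiled:
            cr.add_rhs(self.state, r)
        if self._jac_is_diagonal:
            den = np.ones(n)
            for cr in self._compiled:
                for rows, _cols, vals in cr.jac_entries(self.state):
                    np.add.at(den, rows, -dt * vals)
            if not np.all(np.isfinite(den)) or np.any(np.abs(den) < 1e-300):
                raise StepFailure("singular reaction block (diagonal solve)")
            delta = dt * r / den
        else:
            rows_all, cols_all, vals_all = [], [], []
            for cr in self._compiled:
                for rows, cols, vals in cr.jac_entries(self.state):
                    rows_all.append(rows)
                    cols_all.append(cols)
                    vals_all.append(vals)
            jac = sp.coo_matrix(
                (np.concatenate(vals_all),
                 (np.concatenate(rows_all), np.concatenate(cols_all))),
                shape=(n, n),
            ).tocsc()
            a = sp.identity(n, format="csc") - dt * jac
            try:
                delta = spla.spsolve(a, dt * r)
            except RuntimeError as exc:
                raise StepFailure(f"singular reaction system: {exc}") from None
        if not np.all(np.isfinite(delta)):
            raise StepFailure("non-finite reaction update")
        self.state += delta
        return self.state

    def advance(self, dt: Optional[float] = None) -> float:
        """One operator-split step: diffusion first, then reactions.

        On a step failure the step is retried as two half steps, up to
        ``MAX_STEP_RETRIES`` halvings, then aborts with diagnostics.
        Returns the time reached.
        """
        self._require_ready()
        dt = self.dt if dt is None else float(dt)
        self._advance(dt, 0, 0)
        self._check_negative()
        return self.t

    def _advance(self, dt: float, depth: int, retries: int) -> None:
        backup = self.state.copy()
        try:
            self.diffusion_step(dt)
            self.reaction_step(dt)
            if not np.all(np.isfinite(self.state)):
                raise StepFailure("non-finite state after step")
        except StepFailure as exc:
            self.state[:] = backup
            if depth >= MAX_STEP_RETRIES:
                raise ModelError(
                    f"step failed after {MAX_STEP_RETRIES} dt halvings at "
                    f"t={self.t} (dt={dt}): {exc}"
                ) from exc
            logger.debug("t=%g dt=%g step failed (%s); retrying at dt/2",
                         self.t, dt, exc)
            self._advance(dt / 2.0, depth + 1, retries + 1)
            self._advance(dt / 2.0, depth + 1, retries + 1)
            return
        self.t += dt
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "t=%g dt=%g max|dc|=%.3e retries=%d",
                self.t, dt, float(np.max(np.abs(self.state - backup))), retries,
            )

    def run_fixed(self, t_end: float, dt: Optional[float] = None) -> float:
        """Advance with fixed steps until ``t_end`` (last step shortened)."""
        dt = self.dt if dt is None else float(dt)
        while self.t < t_end - 1e-12:
            self.advance(min(dt, t_end - self.t))
        return self.t

    def _check_negative(self) -> None:
        threshold = -10.0 * self.atol
        if not self._warned_negative and np.any(self.state < threshold):
            self._warned_negative = True
            logger.warning(
                "concentration dropped below %.3g (min %.3g): possible "
                "integration error (values are not clamped)",
                threshold, float(self.state.min()),
            )

    # -- method of lines / adaptive contract --------------------------------

    def rhs_full(self, state) -> np.ndarray:
        """Combined diffusion + reaction right-hand side (method of lines).

        Junction entries are algebraic and carry zero derivative; the
        diffusion part uses the junction-eliminated operator, which is
        exactly equivalent to the conservation rows.
        """
        self._require_ready()
        state = np.asarray(state, float)
        out = np.zeros_like(state)
        for block in self._blocks:
            if block.species.d > 0:
                rows, cols, vals = block.reduced_entries()
                np.add.at(out, rows, vals * state[cols])
        for cr in self._compiled:
            cr.add_rhs(state, out)
        return out

    def _diffusion_jacobian(self) -> sp.csc_matrix:
        if self._diffusion_jacobian_cache is None:
            n = len(self.state)
            rows_all, cols_all, vals_all = [], [], []
            for block in self._blocks:
                if block.species.d > 0:
                    rows, cols, vals = block.reduced_entries()
                    rows_all.append(rows)
                    cols_all.append(cols)
                    vals_all.append(vals)
            if rows_all:
                mat = sp.coo_matrix(
                    (np.concatenate(vals_all),
                     (np.concatenate(rows_all), np.concatenate(cols_all))),
                    shape=(n, n),
                ).tocsc()
            else:
                mat = sp.csc_matrix((n, n))
            self._diffusion_jacobian_cache = mat
        return self._diffusion_jacobian_cache

    def full_jacobian(self, state=None) -> sp.csc_matrix:
        """Sparse Jacobian of :meth:`rhs_full` (diffusion + reactions)."""
        self._require_ready()
        state = self.state if state is None else np.asarray(state, float)
        n = len(self.state)
        jac = self._diffusion_jacobian().copy()
        rows_all, cols_all, vals_all = [], [], []
        for cr in self._compiled:
            for rows, cols, vals in cr.jac_entries(state):
                rows_all.append(rows)
                cols_all.append(cols)
                vals_all.append(vals)
        if rows_all:
            jac = jac + sp.coo_matrix(
                (np.concatenate(vals_all),
                 (np.concatenate(rows_all), np.concatenate(cols_all))),
                shape=(n, n),
            ).tocsc()
        return jac

    def refresh_jacobian(self) -> None:
        """Re-evaluate and re-cache the reaction-block factorizations.

        Called by an adaptive driver when its integrator requests a Jacobian
        update; :meth:`approx_jacobian_solve` reuses the cached factors until
        the next refresh.
        """
        self._jac_version += 1
        self._jac_cache = {}

    def approx_jacobian_solve(self, gamma: float, b) -> np.ndarray:
        """Approximately solve (I − γ·J)x = b by operator splitting.

        Tree-solves the diffusion part, then applies the per-location
        reaction-block solves (factorizations cached per γ until
        :meth:`refresh_jacobian`).  Exact when only one split component is
        present; usable as the linear-solve callback of an adaptive stiff
        integrator, where the approximation only shrinks the accepted step,
        never adds error.
        """
        self._require_ready()
        b = np.asarray(b, float)
        if gamma == 0.0:
            return b.copy()
        x = b.copy()
        for block in self._blocks:
            if block.species.d > 0:
                tm = block.matrix(gamma)
                c = x[block.global_idx]
                rhs = np.where(block.is_junction, 0.0, block.volumes * c)
                x[block.global_idx] = tm.solve(rhs)
        if not self._compiled:
            return x
        key = (gamma, self._jac_version)
        solver = self._jac_cache.get(key)
        if solver is None:
            n = len(self.state)
            if self._jac_is_diagonal:
                den = np.ones(n)
                for cr in self._compiled:
                    for rows, _cols, vals in cr.jac_entries(self.state):
                        np.add.at(den, rows, -gamma * vals)
                solver = ("diag", den)
            else:
                rows_all, cols_all, vals_all = [], [], []
                for cr in self._compiled:
                    for rows, cols, vals in cr.jac_entries(self.state):
                        rows_all.append(rows)
                        cols_all.append(cols)
                        vals_all.append(vals)
                jac = sp.coo_matrix(
                    (np.concatenate(vals_all),
                     (np.concatenate(rows_all), np.concatenate(cols_all))),
                    shape=(n, n),
                ).tocsc()
                solver = ("lu", spla.factorized(
                    (sp.identity(n, format="csc") - gamma * jac).tocsc()
                ))
            self._jac_cache[key] = solver
        kind, data = solver
        if kind == "diag":
            return x / data
        return data(x)

    def run_adaptive(
        self,
        t_end: float,
        t_eval=None,
        atol: Optional[float] = None,
        rtol: float = 1e-7,
        method: str = "BDF",
    ):
        """Integrate to ``t_end`` with scipy's stiff adaptive integrator.

        Returns ``(times, states)`` with one state-vector row per requested
        time.  The model's state and clock are left at ``t_end``.
        """
        from scipy.integrate import solve_ivp

        self._require_ready()
        atol = self.atol if atol is None else float(atol)
        y0 = self.state.copy()

        sol = solve_ivp(
            lambda _t, y: self.rhs_full(y),
            (self.t, t_end),
            y0,
            method=method,
            t_eval=t_eval,
            atol=atol,
            rtol=rtol,
            jac=lambda _t, y: self.full_jacobian(y),
        )
        if not sol.success:  # pragma: no cover - defensive
            raise ModelError(f"adaptive integration failed: {sol.message}")
        self.state[:] = sol.y[:, -1]
        self.t = float(sol.t[-1])
        for block in self._blocks:
            block.update_junctions(self.state)
        self._check_negative()
        return sol.t, sol.y.T

    # -- observables and checkpointing --------------------------------------

    def membrane_currents(self) -> dict:
        """Current density (mA/cm², outward positive) per flux-inducing
        multi-compartment reaction, one value per active location."""
        self._require_ready()
        out = {}
        for cr in self._compiled:
            if cr.current_factor is not None:
                out[cr.rxn] = cr.flux(self.state) * cr.current_factor
        return out

    def save_state(self, stream) -> None:
        """Checkpoint the state vector as CSV (index,concentration)."""
        self._require_ready()
        close = False
        if isinstance(stream, str):
            stream = open(stream, "w")
            close = True
        try:
            stream.write("index,concentration\n")
            for i, v in enumerate(self.state):
                stream.write(f"{i},{float(v)!r}\n")
        finally:
            if close:
                stream.close()

    def load_state(self, stream) -> None:
        """Restore a checkpoint written by :meth:`save_state`."""
        self._require_ready()
        close = False
        if isinstance(stream, str):
            stream = open(stream)
            close = True
        try:
            header = stream.readline()
            if not header.startswith("index,"):
                raise ModelError("not a state checkpoint")
            for line in stream:
                if not line.strip():
                    continue
                i, v = line.split(",")
                self.state[int(i)] = float(v)
        finally:
            if close:
                stream.close()
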