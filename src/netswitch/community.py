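"""Multilayer modularity, generalized ordinal Louvain, and derived measures.

A window stack A_ijs is treated as a multilayer network whose layers are the
sliding windows. The quality function is

    Q(gamma, omega) = (1/2mu) * sum_{ijs} [A_ijs - gamma_s k_is k_js / (2 m_s)]
                                 * delta(M_is, M_js)
                    + (1/2mu) * sum over same-node, adjacent-layer ordered pairs
                                 of omega * delta(M_is, M_ir)

with k_is the node strength in layer s, m_s the layer's total edge weight,
and 2mu the total multilayer strength (intra-layer strengths plus all
inter-layer couplings). Optimization follows the greedy move-and-aggregate
(Louvain) scheme on the supra-modularity matrix, with coupling restricted to
temporally adjacent layers (ordinal coupling). Community labels are stabilized
by re-clustering a co-assignment consensus stack built from repeated runs.

Node *switching* (flexibility) is the fraction of adjacent-layer transitions
in which a node changes community; *allegiance* of a node pair is the fraction
of layers they share a community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .connectivity import WindowStack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class ModularityParams:
    """Resolution, coupling, and optimizer settings.

    ``gamma`` may be a scalar (uniform across layers) or one value per layer;
    ``omega`` couples each node to itself in adjacent layers only.
    """

    gamma: float | np.ndarray = 1.0
    omega: float = 1.0
    n_runs: int = 10
    seed: int = 0

    def gamma_per_layer(self, n_layers: int) -> np.ndarray:
        g = np.broadcast_to(np.asarray(self.gamma, float), (n_layers,))
        if np.any(g <= 0):
            raise ValueError("gamma must be > 0")
        return g.copy()

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class MultilayerNetwork:
    """A window stack plus its strength normalizers.

    k[i, s] is node i's strength in layer s, m[s] half the layer's total
    strength, and mu the total multilayer strength normalizer including the
    ordinal couplings.
    """

    A: np.ndarray  # node x node x layer
    omega: float
    k: np.ndarray = field(init=False)
    m: np.ndarray = field(init=False)
    mu: float = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float)
        n, _, L = self.A.shape
        self.k = self.A.sum(axis=1)  # node x layer
        self.m = self.k.sum(axis=0) / 2.0
        # 2mu = sum of intra-layer strengths + 2*omega*N*(L-1) ordinal couplings
        self.mu = self.k.sum() / 2.0 + self.omega * n * (L - 1)

    @classmethod
    def from_stack(cls, stack: WindowStack, omega: float) -> "MultilayerNetwork":
        return cls(stack.weights, omega)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_layers(self) -> int:
        return self.A.shape[2]


@dataclass
class CommunityAssignment:
    """Node x layer community labels, contiguous positive integers."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be node x layer")
        uniq = np.unique(self.labels)
        if uniq.min() < 1 or not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("labels must be contiguous integers starting at 1")

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]


@dataclass
class SwitchingProfile:
    """Per-node switching proportions and their mean (global switching)."""

    per_node: np.ndarray
    global_mean: float

    def __post_init__(self) -> None:
        self.per_node = np.asarray(self.per_node, float)
        if np.any((self.per_node < 0) | (self.per_node > 1)):
            raise ValueError("switching proportions must lie in [0, 1]")
        if not np.isclose(self.global_mean, self.per_node.mean()):
            raise ValueError("global_mean must equal the mean of per-node values")


def canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel communities 1..K in order of first appearance (C order)."""
    flat = np.asarray(raw).ravel()
    _, first = np.unique(flat, return_index=True)
    order = flat[np.sort(first)]
    mapping = {int(c): i + 1 for i, c in enumerate(order)}
    return np.vectorize(mapping.__getitem__)(np.asarray(raw))


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------


def _supra_modularity_matrix(
    net: MultilayerNetwork, params: ModularityParams
) -> np.ndarray:
    """Dense supra-modularity matrix B over supra-nodes (i, s), ordered
    layer-major (index = s * n_nodes + i)."""
    n, L = net.n_nodes, net.n_layers
    gamma = params.gamma_per_layer(L)
    B = np.zeros((n * L, n * L))
    for s in range(L):
        block = net.A[:, :, s].copy()
        if net.m[s] > 0:
            block -= gamma[s] * np.outer(net.k[:, s], net.k[:, s]) / (2 * net.m[s])
        else:
            log.warning("layer %d has zero strength; null-model term set to 0", s)
        sl = slice(s * n, (s + 1) * n)
        B[sl, sl] = block
    if params.omega > 0:
        idx = np.arange(n * (L - 1))
        B[idx, idx + n] += params.omega
        B[idx + n, idx] += params.omega
    return B


def modularity_Q(
    net: MultilayerNetwork,
    assignment: CommunityAssignment,
    params: ModularityParams,
) -> float:
    """Evaluate Q(gamma, omega) for a given assignment.

    Sums run over ordered supra-node pairs (the single-layer Newman-Girvan
    value is recovered at omega=0, L=1), normalized by 2mu.
    """
    n, L = net.n_nodes, net.n_layers
    if assignment.labels.shape != (n, L):
        raise ValueError("assignment dimensions do not match the network")
    gamma = params.gamma_per_layer(L)
    total = 0.0
    for s in range(L):
        lab = assignment.labels[:, s]
        same = lab[:, None] == lab[None, :]
        block = net.A[:, :, s].copy()
        if net.m[s] > 0:
            block = block - gamma[s] * np.outer(net.k[:, s], net.k[:, s]) / (
                2 * net.m[s]
            )
        total += block[same].sum()
    if params.omega > 0 and L > 1:
        agree = assignment.labels[:, :-1] == assignment.labels[:, 1:]
        total += 2.0 * params.omega * agree.sum()
    return float(total / (2 * net.mu))


# ---------------------------------------------------------------------------
# generalized ordinal Louvain
# ---------------------------------------------------------------------------


def _greedy_sweeps(B: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """In-place greedy node moves until no move improves the quality.

    A node moves to the community maximizing the sum of B over its members;
    ties are broken toward staying, then toward the lowest candidate label.
    Returns True if any move was made.
    """
    n = B.shape[0]
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            cur = labels[i]
            s = np.bincount(labels, weights=B[i], minlength=n)
            stay = s[cur] - B[i, i]
            s[cur] = stay
            best = int(np.argmax(s))  # argmax returns the lowest index on ties
            if s[best] > stay + 1e-12 and best != cur:
                labels[i] = best
                improved = True
                moved_any = True
    return moved_any


@dataclass
class LouvainResult:
    assignment: CommunityAssignment
    q: float
    q_history: list[float]

    def __iter__(self):
        return iter((self.assignment, self.q))


def generalized_louvain(
    net: WindowStack | MultilayerNetwork,
    params: ModularityParams,
    *,
    seed: int | None = None,
) -> LouvainResult:
    """Greedy move-and-aggregate optimization of multilayer modularity.

    Node-move sweeps over the supra-modularity matrix are followed by
    community aggregation, iterated until no move improves Q. The recorded
    ``q_history`` (Q after each aggregation level) is non-decreasing.
    Deterministic given the seed (``params.seed`` unless overridden).
    """
    if isinstance(net, WindowStack):
        net = MultilayerNetwork.from_stack(net, params.omega)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n, L = net.n_nodes, net.n_layers
    B = _supra_modularity_matrix(net, params)
    n_supra = n * L

    full = np.arange(n_supra)  # supra-node -> community
    Bcur = B
    labels = np.arange(n_supra)
    history: list[float] = []

    def q_of(full_labels: np.ndarray) -> float:
        same = full_labels[:, None] == full_labels[None, :]
        return float(B[same].sum() / (2 * net.mu))

    while True:
        labels = np.arange(Bcur.shape[0])
        moved = _greedy_sweeps(Bcur, labels, rng)
        uniq, compact = np.unique(labels, return_inverse=True)
        full = compact[full]
        history.append(q_of(full))
        if not moved or uniq.size == Bcur.shape[0]:
            break
        onehot = np.zeros((Bcur.shape[0], uniq.size))
        onehot[np.arange(Bcur.shape[0]), compact] = 1.0
        Bcur = onehot.T @ Bcur @ onehot

    lab = canonical_labels(full.reshape(L, n).T)
    assignment = CommunityAssignment(lab)
    return LouvainResult(assignment, history[-1], history)


def consensus_assignment(
    stack: WindowStack, params: ModularityParams
) -> CommunityAssignment:
    """Stabilize community labels by re-clustering a consensus stack.

    The optimizer is run ``params.n_runs`` times with distinct seeds; for each
    layer, the node-pair co-assignment fraction matrix over runs forms a
    consensus layer, and one final optimizer run on this consensus stack
    yields the returned assignment.
    """
    if params.n_runs < 2:
        raise ValueError("consensus requires n_runs >= 2")
    ss = np.random.SeedSequence(params.seed, spawn_key=(17,))
    seeds = ss.generate_state(params.n_runs + 1) % (2**31)
    n, L = stack.n_nodes, stack.n_layers
    co = np.zeros((n, n, L))
    for r in range(params.n_runs):
        res = generalized_louvain(stack, params, seed=int(seeds[r]))
        lab = res.assignment.labels
        for s in range(L):
            co[:, :, s] += lab[:, s][:, None] == lab[:, s][None, :]
    co /= params.n_runs
    for s in range(L):
        np.fill_diagonal(co[:, :, s], 0.0)
    consensus = WindowStack(co, stack.window_length, stack.step, stack.node_labels)
    final = generalized_louvain(consensus, params, seed=int(seeds[-1]))
    return final.assignment


# ---------------------------------------------------------------------------
# derived measures
# ---------------------------------------------------------------------------


def switching(assignment: CommunityAssignment) -> SwitchingProfile:
    """Fraction of adjacent-layer transitions at which each node changes
    community; the global mean is the arithmetic mean over nodes."""
    if assignment.n_layers < 2:
        raise ValueError("switching requires at least 2 layers")
    changes = assignment.labels[:, 1:] != assignment.labels[:, :-1]
    per_node = changes.mean(axis=1)
    return SwitchingProfile(per_node, float(per_node.mean()))


def allegiance(assignment: CommunityAssignment, node_a: int, node_b: int) -> float:
    """Fraction of layers in which two nodes share a community label."""
    if node_a == node_b:
        return 1.0
    la = assignment.labels[node_a]
    lb = assignment.labels[node_b]
    return float(np.mean(la == lb))


def allegiance_matrix(assignment: CommunityAssignment) -> np.ndarray:
    """Full pairwise allegiance matrix (diagonal 1)."""
    lab = assignment.labels
    same = lab[:, None, :] == lab[None, :, :]
    mat = same.mean(axis=2)
    np.fill_diagonal(mat, 1.0)
    return mat


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle (small problems only)
# ---------------------------------------------------------------------------


def _all_partitions(n_items: int) -> np.ndarray:
    """All set partitions of n items as restricted-growth label arrays."""
    if n_items > 12:
        raise ValueError("enumeration beyond 12 items is not tractable")
    parts = np.zeros((1, 1), dtype=np.int8)
    maxl = np.zeros(1, dtype=np.int8)
    for _ in range(1, n_items):
        counts = maxl.astype(np.int64) + 2
        idx = np.repeat(np.arange(parts.shape[0]), counts)
        ends = np.cumsum(counts)
        newcol = (np.arange(ends[-1]) - np.repeat(ends - counts, counts)).astype(
            np.int8
        )
        parts = np.concatenate([parts[idx], newcol[:, None]], axis=1)
        maxl = np.maximum(maxl[idx], newcol)
    return parts


def exhaustive_optimum(
    net: WindowStack | MultilayerNetwork,
    params: ModularityParams,
    batch: int = 200_000,
) -> tuple[CommunityAssignment, float]:
    """Globally optimal assignment by enumerating every set partition of the
    supra-nodes. Only feasible for n_nodes * n_layers <= 12."""
    if isinstance(net, WindowStack):
        net = MultilayerNetwork.from_stack(net, params.omega)
    n, L = net.n_nodes, net.n_layers
    B = _supra_modularity_matrix(net, params)
    parts = _all_partitions(n * L)
    best_q = -np.inf
    best = None
    for start in range(0, parts.shape[0], batch):
        chunk = parts[start : start + batch]
        same = chunk[:, :, None] == chunk[:, None, :]
        q = np.einsum("pij,ij->p", same, B)
        j = int(np.argmax(q))
        if q[j] > best_q:
            best_q = float(q[j])
            best = chunk[j].copy()
    lab = canonical_labels(best.astype(int).reshape(L, n).T + 1)
    return CommunityAssignment(lab), best_q / (2 * net.mu)
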