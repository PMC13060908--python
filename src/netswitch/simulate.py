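"""Synthetic cohort generation.

Everything the downstream pipeline consumes can be generated here without any
external data: BOLD-like node time series with planted, arousal-state-dependent
community dynamics; pupil/eye-closure traces spanning the staging bins; per-second
EEG vigilance ranks; and task-accuracy outcomes carrying a planted
switching-by-arousal interaction.

All randomness flows from a single root seed through
``numpy.random.SeedSequence(root, spawn_key=...)`` so that every artifact is
exactly reproducible and independent sub-streams never collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALERT = "alert"
DROWSY = "drowsy"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class NodeTimeSeries:
    """A node-by-time real matrix with node labels and a repetition time.

    This is the pipeline's atomic input: one row per node (a network or a
    parcel), one column per time point, sampled every ``tr`` seconds.
    """

    values: np.ndarray
    node_labels: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D node x time matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 nodes")
        if len(self.node_labels) != self.values.shape[0]:
            raise ValueError("node_labels length must match the number of rows")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class EyeTrace:
    """A pupil-size sample sequence; 0 encodes eye closure."""

    samples: np.ndarray
    sampling_rate: float
    scan_onset_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive (Hz)")
        if not 0 <= self.scan_onset_index:
            raise ValueError("scan_onset_index must be non-negative")


@dataclass
class VigilanceRankSeries:
    """Per-second EEG vigilance ranks, each in {2, 3, 4, 5, 6}.

    Higher ranks indicate higher arousal. The staging algorithm that produces
    these ranks is upstream of this package; the rank sequence is the interface.
    """

    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        if self.ranks.ndim != 1 or self.ranks.size == 0:
            raise ValueError("ranks must be a non-empty 1-D sequence")
        if not np.all((self.ranks >= 2) & (self.ranks <= 6)):
            raise ValueError("every rank must lie in {2,3,4,5,6}")


def _default_template(n_nodes: int) -> dict[str, int]:
    labels = [f"N{i+1:02d}" for i in range(n_nodes)]
    # three roughly equal starting communities
    return {lab: (i * 3) // n_nodes + 1 for i, lab in enumerate(labels)}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``switch_rate_*`` are expected community re-assignment events per node per
    100 windows (one window advance = one sample at the default step of 1 TR).
    ``within_community_corr`` is the planted correlation between same-community
    nodes before the shared global component is mixed in; cross-community
    correlation is 0. ``global_loading`` is each node's correlation with the
    shared global component (an AR(1) process, phi=0.3, unit variance).
    """

    n_nodes: int = 14
    n_time: int = 300
    tr: float = 1.0
    n_scans_alert: int = 20
    n_scans_drowsy: int = 20
    switch_rate_alert: float = 0.5
    switch_rate_drowsy: float = 2.0
    community_template: dict[str, int] | None = None
    within_community_corr: float = 0.6
    global_loading: float | np.ndarray = 0.3
    node_means: np.ndarray | None = None
    node_sds: np.ndarray | None = None
    window_length: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")
        if self.n_time < 2 * self.window_length:
            raise ValueError("n_time must be at least twice the window length")
        if not 0 <= self.within_community_corr < 1:
            raise ValueError(
                "within_community_corr must lie in [0, 1): the same-community "
                "block covariance is otherwise not positive semidefinite"
            )
        if self.switch_rate_alert < 0 or self.switch_rate_drowsy < 0:
            raise ValueError("switch rates must be >= 0")
        if self.community_template is None:
            self.community_template = _default_template(self.n_nodes)
        if len(self.community_template) != self.n_nodes:
            raise ValueError("community_template must cover every node")
        if len(set(self.community_template.values())) < 2:
            raise ValueError("community_template must contain >= 2 communities")
        load = np.broadcast_to(np.asarray(self.global_loading, float), (self.n_nodes,))
        if np.any(np.abs(load) >= 1):
            raise ValueError("global_loading entries must lie in (-1, 1)")
        self.global_loading = load.copy()
        if self.node_means is None:
            self.node_means = np.zeros(self.n_nodes)
        if self.node_sds is None:
            self.node_sds = np.ones(self.n_nodes)
        self.node_means = np.broadcast_to(
            np.asarray(self.node_means, float), (self.n_nodes,)
        ).copy()
        self.node_sds = np.broadcast_to(
            np.asarray(self.node_sds, float), (self.n_nodes,)
        ).copy()
        if np.any(self.node_sds < 0):
            raise ValueError("node_sds must be >= 0")

    @property
    def node_labels(self) -> list[str]:
        return list(self.community_template)

    def switch_rate(self, state: str) -> float:
        if state == ALERT:
            return self.switch_rate_alert
        if state == DROWSY:
            return self.switch_rate_drowsy
        raise ValueError(f"unknown arousal state {state!r}")


# ---------------------------------------------------------------------------
# scan generation
# ---------------------------------------------------------------------------


def _rng(seed: int, *path: int) -> np.random.Generator:
    """Documented seed-splitting scheme: one root, integer spawn path."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(path)))


def _membership_path(
    config: SimulationConfig, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Epoch boundaries and per-epoch community membership.

    Re-assignment events form a Poisson process with total rate
    ``n_nodes * rate / 100`` per sample; each event moves one uniformly chosen
    node into a uniformly chosen *other* currently-occupied community, always
    keeping at least two communities alive.
    """
    n, t = config.n_nodes, config.n_time
    membership = np.array([config.community_template[l] for l in config.node_labels])
    boundaries = [0]
    memberships = [membership.copy()]
    if rate > 0:
        total_rate = n * rate / 100.0
        pos = 0.0
        while True:
            pos += rng.exponential(1.0 / total_rate)
            if pos >= t:
                break
            cur = memberships[-1].copy()
            for _ in range(100):  # retry until a legal move is found
                node = rng.integers(n)
                others = np.unique(cur[np.arange(n) != node])
                others = others[others != cur[node]]
                if others.size == 0:
                    continue
                # keep >= 2 communities alive
                if np.sum(cur == cur[node]) == 1 and np.unique(cur).size <= 2:
                    continue
                cur[node] = others[rng.integers(others.size)]
                break
            boundaries.append(int(np.ceil(pos)))
            memberships.append(cur)
    boundaries.append(t)
    return np.asarray(boundaries), np.asarray(memberships)


def generate_scan(config: SimulationConfig, state: str, seed: int) -> NodeTimeSeries:
    """Generate one piecewise-stationary BOLD-like scan.

    Within each epoch, node i is ``lam_i * g + sqrt(1-lam_i^2) * y_i`` where g
    is the shared AR(1) global component and y has the planted block
    correlation (``within_community_corr`` inside the current communities, 0
    across). The epoch structure re-assigns community membership at
    exponentially distributed intervals with the state's switch rate. Finally
    each row is scaled and shifted to ``node_sds`` / ``node_means``.
    """
    rate = config.switch_rate(state)
    rng = _rng(seed, 0)
    n, t = config.n_nodes, config.n_time
    w = config.within_community_corr

    boundaries, memberships = _membership_path(config, rate, rng)

    # shared global component: AR(1), phi=0.3, unit marginal variance
    phi = 0.3
    innov = rng.standard_normal(t) * np.sqrt(1 - phi**2)
    g = np.empty(t)
    g[0] = rng.standard_normal()
    for s in range(1, t):
        g[s] = phi * g[s - 1] + innov[s]

    x = np.empty((n, t))
    eps = rng.standard_normal((n, t))
    for b0, b1, member in zip(boundaries[:-1], boundaries[1:], memberships):
        if b1 <= b0:
            continue
        # one latent factor per community in this epoch
        comms = np.unique(member)
        fac = rng.standard_normal((comms.size, b1 - b0))
        idx = np.searchsorted(comms, member)
        y = np.sqrt(w) * fac[idx] + np.sqrt(1 - w) * eps[:, b0:b1]
        lam = config.global_loading[:, None]
        x[:, b0:b1] = lam * g[b0:b1][None, :] + np.sqrt(1 - lam**2) * y

    values = config.node_means[:, None] + config.node_sds[:, None] * x
    return NodeTimeSeries(values, config.node_labels, config.tr)


# ---------------------------------------------------------------------------
# eye traces and vigilance ranks
# ---------------------------------------------------------------------------


def generate_eye_trace(
    closure_fraction: float,
    n_blinks_short: int = 0,
    seed: int = 0,
    *,
    duration_s: float = 300.0,
    sampling_rate: float = 60.0,
    pre_onset_s: float = 2.0,
    n_closures_long: int | None = None,
) -> EyeTrace:
    """Generate a pupil trace whose post-preprocessing closure fraction is
    ``closure_fraction`` (within +-1%).

    Long closures (>= 1 s, not interpolated downstream) carry the closure
    budget; ``n_blinks_short`` sub-second blinks are added in open stretches
    (they are interpolated away downstream and contribute nothing to the
    closure fraction). When ``closure_fraction > 0.5`` one sub-100 ms open
    burst is inserted between two long closure halves; the burst is zeroed
    downstream, so its samples are budgeted as closure.
    """
    if not 0 <= closure_fraction <= 1:
        raise ValueError("closure_fraction must lie in [0, 1]")
    rng = _rng(seed, 1)
    fs = sampling_rate
    n_post = int(round(duration_s * fs))
    n_pre = int(round(pre_onset_s * fs))
    closure_target = int(round(closure_fraction * n_post))
    one_s = int(np.ceil(fs))

    if n_closures_long is None:
        n_closures_long = 0 if closure_target == 0 else max(
            1, min(5, closure_target // (3 * one_s))
        )
    if closure_target == 0 and n_closures_long > 0:
        raise ValueError(
            "infeasible request: closure_fraction=0 cannot accommodate long closures"
        )
    if 0 < closure_target < one_s:
        # closures shorter than 1 s are interpolated away downstream, so the
        # smallest surviving closure is 1 s; use it if within the 1% tolerance
        if one_s / n_post - closure_fraction <= 0.01:
            closure_target = one_s
        else:
            raise ValueError(
                "infeasible request: the closure budget is below one second "
                "and rounding up to a single 1 s closure would miss the "
                "target fraction by more than 1%"
            )
    if n_closures_long > 0 and closure_target < n_closures_long * one_s:
        raise ValueError(
            "infeasible request: closure budget smaller than the minimum length "
            f"of {n_closures_long} closures of >= 1 s"
        )

    # open-eye baseline: positive pupil size with mild wander
    samples = 5.0 + 0.3 * rng.standard_normal(n_post).cumsum() / np.sqrt(n_post)
    samples = np.clip(samples, 1.0, None)

    # each group is a contiguous run of (length, kind) pieces; kind 0 = closure,
    # kind 1 = sub-100 ms open burst (zeroed downstream, budgeted as closure)
    groups: list[list[tuple[int, int]]] = []
    if closure_target > 0:
        lengths = np.full(n_closures_long, one_s)
        spare = closure_target - int(lengths.sum())
        add = rng.multinomial(spare, np.ones(n_closures_long) / n_closures_long)
        lengths = lengths + add
        burst_j = -1
        if closure_fraction > 0.5:
            # split the longest closure by a sub-100 ms open burst
            burst_len = max(1, int(0.08 * fs))
            burst_j = int(np.argmax(lengths))
            if lengths[burst_j] < 2 * one_s + burst_len:
                deficit = 2 * one_s + burst_len - lengths[burst_j]
                lengths[burst_j] += deficit
                for k in np.argsort(lengths)[::-1]:  # rebalance, keep total exact
                    if k == burst_j or deficit <= 0:
                        continue
                    take = min(deficit, lengths[k] - one_s)
                    lengths[k] -= take
                    deficit -= take
        for i, l in enumerate(lengths):
            if i == burst_j:
                half = (int(l) - burst_len) // 2
                groups.append(
                    [(half, 0), (burst_len, 1), (int(l) - burst_len - half, 0)]
                )
            else:
                groups.append([(int(l), 0)])

    closed_total = sum(l for grp in groups for l, _ in grp)
    open_total = n_post - closed_total
    if open_total < 0:
        raise ValueError("infeasible request: closure budget exceeds scan length")

    trace = samples.copy()
    gap = open_total // (len(groups) + 1) if groups else 0
    cursor = gap
    for grp in groups:
        for length, kind in grp:
            trace[cursor : cursor + length] = 3.0 if kind == 1 else 0.0
            cursor += length
        cursor += gap

    # short blinks (< 1 s) in open stretches; interpolated away downstream.
    # A 2-sample open margin keeps each blink a separate sub-second run.
    blink_len = max(1, min(int(0.4 * fs), max(1, open_total // (3 * max(1, n_blinks_short)))))
    placed = 0
    attempts = 0
    while placed < n_blinks_short and attempts < 5000:
        attempts += 1
        start = int(rng.integers(2, max(3, n_post - blink_len - 2)))
        seg = trace[start - 2 : start + blink_len + 2]
        if np.all(seg > 0):
            trace[start : start + blink_len] = 0.0
            placed += 1
    if placed < n_blinks_short:
        raise ValueError("could not place the requested number of short blinks")

    pre = 4.0 + 0.1 * rng.standard_normal(n_pre)
    return EyeTrace(np.concatenate([pre, trace]), fs, scan_onset_index=n_pre)


def generate_vigilance_ranks(
    state: str, n_seconds: int = 300, seed: int = 0
) -> VigilanceRankSeries:
    """Per-second vigilance ranks consistent with the requested state.

    Alert scans fluctuate in 4-6 (mean > 3.5), drowsy in 2-3 (mean < 3.5);
    ``state='transition'`` starts high (4-6) and decays to low (2-3).
    """
    rng = _rng(seed, 2)
    if state == ALERT:
        ranks = rng.choice([4, 5, 6], size=n_seconds, p=[0.3, 0.5, 0.2])
    elif state == DROWSY:
        ranks = rng.choice([2, 3], size=n_seconds, p=[0.6, 0.4])
    elif state == "transition":
        half = n_seconds // 2
        ranks = np.concatenate(
            [
                rng.choice([4, 5, 6], size=half, p=[0.3, 0.5, 0.2]),
                rng.choice([2, 3], size=n_seconds - half, p=[0.6, 0.4]),
            ]
        )
    else:
        raise ValueError(f"unknown state {state!r}")
    return VigilanceRankSeries(ranks)


# ---------------------------------------------------------------------------
# task accuracy with a planted interaction
# ---------------------------------------------------------------------------


@dataclass
class AccuracyModel:
    """Planted linear model: accuracy = b0 + b1*switching + b2*drowsy
    + beta_interaction*switching*drowsy + N(0, noise_sd^2)."""

    accuracy: np.ndarray
    beta0: float
    beta1: float
    beta2: float
    beta_interaction: float
    noise_sd: float


def generate_accuracy(
    switching: np.ndarray,
    arousal: list[str],
    beta_interaction: float,
    noise_sd: float,
    seed: int = 0,
    *,
    beta0: float = 80.0,
    beta1: float = 10.0,
    beta2: float = -5.0,
) -> AccuracyModel:
    """Task-accuracy outcomes with a planted switching-by-arousal interaction."""
    switching = np.asarray(switching, float)
    if len(arousal) != switching.size:
        raise ValueError("switching and arousal must have equal lengths")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    drowsy = np.array([1.0 if a == DROWSY else 0.0 for a in arousal])
    rng = _rng(seed, 3)
    acc = (
        beta0
        + beta1 * switching
        + beta2 * drowsy
        + beta_interaction * switching * drowsy
        + noise_sd * rng.standard_normal(switching.size)
    )
    return AccuracyModel(acc, beta0, beta1, beta2, beta_interaction, noise_sd)
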