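"""Localist parallel-constraint-satisfaction (PCS) attitude networks.

The network is the receiver's mental representation of a choice between
options (here: vehicle types).  It follows the HOTCO architecture: a
clamped *special* unit whose outgoing priority links encode per-goal
importance, a *valence* unit whose links encode affective associations,
a layer of goal units and a layer of option units.  Links are symmetric
and dimensionless: priority links (special-goal) lie in [0, 1], all
other links in [-1, 1].  There are no intra-layer links and no
special-option links; option units are deliberately not mutually
inhibitory, so both options can be evaluated positively at once.

Settling spreads activation synchronously from the clamped units until
the pattern stabilises; the final activation of an option unit is the
simulated attitude toward that option.  Coherence of the settled state
is scored by the Hopfield-style energy

    E = - sum_i sum_j w_ij a_i a_j        (ordered pairs, w_ii = 0),

lower energy meaning a more coherent representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .scales import IMPORTANCE6, LIKERT6, SEMANTIC_DIFFERENTIAL

__all__ = [
    "NetworkTopology",
    "ActivationParams",
    "AttitudeNetwork",
    "SettleResult",
    "build_network",
    "net_input",
    "settle",
    "settle_batch",
    "energy",
    "energy_batch",
    "attitude_of",
    "DEFAULT_GOALS",
    "DEFAULT_OPTIONS",
]

DEFAULT_GOALS = (
    "independence",
    "comfort",
    "eco_friendliness",
    "driving_experience",
    "good_conscience",
)
DEFAULT_OPTIONS = ("ice_car", "e_car")


@dataclass(frozen=True)
class NetworkTopology:
    """Node labels of a PCS attitude network.

    The node order is fixed as (special, valence, goals..., options...);
    all weight matrices in this package use that order.
    """

    special_id: str = "special"
    valence_id: str = "valence"
    goal_ids: tuple = DEFAULT_GOALS
    option_ids: tuple = DEFAULT_OPTIONS

    def __post_init__(self):
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        if len(self.goal_ids) < 1:
            raise ValueError("need at least one goal")
        if len(self.option_ids) < 1:
            raise ValueError("need at least one option")

    @property
    def labels(self) -> tuple:
        return (self.special_id, self.valence_id, *self.goal_ids, *self.option_ids)

    @property
    def n_nodes(self) -> int:
        return 2 + len(self.goal_ids) + len(self.option_ids)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    @property
    def goal_indices(self) -> np.ndarray:
        return np.arange(2, 2 + len(self.goal_ids))

    @property
    def option_indices(self) -> np.ndarray:
        g = len(self.goal_ids)
        return np.arange(2 + g, 2 + g + len(self.option_ids))

    def link_mask(self, intra_layer: bool = False) -> np.ndarray:
        """Boolean (n, n) mask of admissible links.

        Admissible: special-goal (priority), valence-goal,
        valence-option, goal-option.  ``intra_layer=True`` additionally
        admits goal-goal links (an off-by-default variant; option-option
        links are never admitted).
        """
        n = self.n_nodes
        mask = np.zeros((n, n), dtype=bool)
        gi, oi = self.goal_indices, self.option_indices
        mask[np.ix_([0], gi)] = True  # priority links
        mask[np.ix_([1], gi)] = True  # valence-goal
        mask[np.ix_([1], oi)] = True  # valence-option
        mask[np.ix_(gi, oi)] = True  # beliefs
        if intra_layer:
            mask[np.ix_(gi, gi)] = True
            np.fill_diagonal(mask, False)
        return mask | mask.T


@dataclass(frozen=True)
class ActivationParams:
    """Settling-dynamics constants.

    ``decay`` (d = 0.05) bleeds activation each cycle; ``min``/``max``
    bound activations at [-1, +1]; settling stops when the largest
    per-node change drops below ``convergence_threshold`` or after
    ``max_iterations`` synchronous updates.  The cap is a safety valve:
    default-population networks typically settle in tens of cycles, but
    rare frustrated constraint patterns contract slowly and can need a
    few hundred.
    """

    decay: float = 0.05
    min: float = -1.0
    max: float = 1.0
    convergence_threshold: float = 1e-4
    max_iterations: int = 400

    def __post_init__(self):
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must lie in (0, 1)")
        if not self.min < 0.0 < self.max:
            raise ValueError("activation bounds must straddle 0")
        if self.convergence_threshold <= 0:
            raise ValueError("convergence threshold must be positive")


@dataclass
class SettleResult:
    """Outcome of one settling run."""

    activations: np.ndarray
    iterations: int
    converged: bool
    energy_trace: np.ndarray
    topology: NetworkTopology

    def activation(self, label: str) -> float:
        return float(self.activations[self.topology.index(label)])

    @property
    def energy(self) -> float:
        return float(self.energy_trace[-1])


class AttitudeNetwork:
    """A PCS attitude network: topology, symmetric weights, clamped units.

    Weights are stored as a dense symmetric (n, n) matrix with zero
    diagonal; only links admitted by the topology may be non-zero.  The
    special unit is always clamped at +1.0 (it is the activation
    source); by default the valence unit is also clamped at +1.0 so that
    valence-link weights directly inject affect into the network
    (configurable via ``clamp_valence``).
    """

    def __init__(
        self,
        topology: NetworkTopology,
        weights: np.ndarray | None = None,
        clamp_valence: bool = True,
        allow_intra_layer: bool = False,
    ):
        self.topology = topology
        n = topology.n_nodes
        self._mask = topology.link_mask(intra_layer=allow_intra_layer)
        self.allow_intra_layer = allow_intra_layer
        if weights is None:
            weights = np.zeros((n, n))
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n, n):
            raise ValueError(f"weights must be ({n}, {n})")
        self.weights = weights
        self.clamped: dict[str, float] = {topology.special_id: 1.0}
        if clamp_valence:
            self.clamped[topology.valence_id] = 1.0
        self.activations = self.initial_activations()
        self.validate()

    # -- construction / bookkeeping ------------------------------------

    def copy(self) -> "AttitudeNetwork":
        new = AttitudeNetwork.__new__(AttitudeNetwork)
        new.topology = self.topology
        new._mask = self._mask
        new.allow_intra_layer = self.allow_intra_layer
        new.weights = self.weights.copy()
        new.clamped = dict(self.clamped)
        new.activations = self.activations.copy()
        return new

    def initial_activations(self) -> np.ndarray:
        """All nodes at 0 except clamped units at their clamp value."""
        a = np.zeros(self.topology.n_nodes)
        for label, value in self.clamped.items():
            a[self.topology.index(label)] = value
        return a

    @property
    def clamped_indices(self) -> np.ndarray:
        return np.array([self.topology.index(l) for l in self.clamped], dtype=int)

    @property
    def clamped_values(self) -> np.ndarray:
        return np.array(list(self.clamped.values()))

    def get_weight(self, a: str, b: str) -> float:
        return float(self.weights[self.topology.index(a), self.topology.index(b)])

    def set_weight(self, a: str, b: str, w: float) -> None:
        """Set a symmetric link weight, enforcing admissibility and range."""
        i, j = self.topology.index(a), self.topology.index(b)
        if i == j:
            raise ValueError("no self-links")
        if not self._mask[i, j]:
            raise ValueError(f"link {a!r}-{b!r} is not admissible in this topology")
        lo = 0.0 if 0 in (i, j) else -1.0
        if not lo <= w <= 1.0:
            raise ValueError(f"weight {w} for link {a!r}-{b!r} outside [{lo}, 1]")
        self.weights[i, j] = w
        self.weights[j, i] = w

    def validate(self) -> None:
        """Check symmetry, zero diagonal, admissibility and weight ranges."""
        W = self.weights
        if not np.array_equal(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("self-weights must be zero")
        if np.any(W[~self._mask & ~np.eye(len(W), dtype=bool)] != 0.0):
            raise ValueError("non-admissible link carries non-zero weight")
        if np.any(np.abs(W) > 1.0 + 1e-12):
            raise ValueError("weights must lie in [-1, 1]")
        if np.any(W[0] < 0.0):
            raise ValueError("priority weights must lie in [0, 1]")

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        top = self.topology
        triples = []
        n = top.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] != 0.0:
                    triples.append([top.labels[i], top.labels[j], self.weights[i, j]])
        doc = {
            "topology": {
                "special_id": top.special_id,
                "valence_id": top.valence_id,
                "goal_ids": list(top.goal_ids),
                "option_ids": list(top.option_ids),
            },
            "weights": triples,
            "clamped": self.clamped,
            "activations": self.activations.tolist(),
            "allow_intra_layer": self.allow_intra_layer,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AttitudeNetwork":
        doc = json.loads(text)
        top = NetworkTopology(
            special_id=doc["topology"]["special_id"],
            valence_id=doc["topology"]["valence_id"],
            goal_ids=tuple(doc["topology"]["goal_ids"]),
            option_ids=tuple(doc["topology"]["option_ids"]),
        )
        net = cls(
            top,
            clamp_valence=False,
            allow_intra_layer=doc.get("allow_intra_layer", False),
        )
        net.clamped = {k: float(v) for k, v in doc["clamped"].items()}
        for a, b, w in doc["weights"]:
            net.set_weight(a, b, float(w))
        net.activations = np.asarray(doc["activations"], dtype=float)
        net.validate()
        return net


def build_network(
    profile,
    topology: NetworkTopology | None = None,
    clamp_valence: bool = True,
) -> AttitudeNetwork:
    """Parameterize a receiver network from one participant's ratings.

    Priority links are rescaled goal importances (six-point scale to
    [0, 1]); valence links are rescaled semantic-differential ratings
    (to [-1, 1]); goal-option links are rescaled beliefs (six-point
    scale to [-1, 1], midpoint 3.5 mapping to 0).  All other links are
    zero.
    """
    top = topology or NetworkTopology()
    profile.validate(top)
    net = AttitudeNetwork(top, clamp_valence=clamp_valence)
    for g in top.goal_ids:
        net.set_weight(top.special_id, g, IMPORTANCE6.rescale(profile.importances[g]))
        net.set_weight(top.valence_id, g, SEMANTIC_DIFFERENTIAL.rescale(profile.valences[g]))
    for o in top.option_ids:
        net.set_weight(top.valence_id, o, SEMANTIC_DIFFERENTIAL.rescale(profile.valences[o]))
        for g in top.goal_ids:
            net.set_weight(g, o, LIKERT6.rescale(profile.beliefs[(g, o)]))
    return net


def net_input(network: AttitudeNetwork, node: str) -> float:
    """Net input to a node: sum_i w_ij a_i, clamped to [-1, +1].

    The clamp keeps the one-step update map inside the activation
    bounds (the bounding terms of the update rule presume |net| <= 1).
    """
    j = network.topology.index(node)
    raw = float(network.weights[:, j] @ network.activations)
    return float(np.clip(raw, -1.0, 1.0))


def settle_batch(
    W: np.ndarray,
    clamp_idx: np.ndarray,
    clamp_val: np.ndarray,
    params: ActivationParams | None = None,
    return_trace: bool = False,
):
    """Settle a batch of networks sharing clamping structure.

    Parameters
    ----------
    W:
        Weight stack of shape (B, n, n), each symmetric.
    clamp_idx, clamp_val:
        Indices and values of clamped units (shared across the batch).
    return_trace:
        If true, also return the per-iteration energy trace (B, T).

    Returns
    -------
    activations (B, n), iterations (B,), converged (B,) and, when
    requested, the energy trace.

    Updates are synchronous (Grossberg rule with decay in both
    branches); iteration counting starts at 1 with the first update.
    """
    p = params or ActivationParams()
    W = np.asarray(W, dtype=float)
    B, n, _ = W.shape
    a = np.zeros((B, n))
    a[:, clamp_idx] = clamp_val
    free = np.ones(n, dtype=bool)
    free[clamp_idx] = False

    iters = np.zeros(B, dtype=int)
    converged = np.zeros(B, dtype=bool)
    traces = [] if return_trace else None

    # networks that reach their fixed point are frozen and dropped from
    # the active batch; their state no longer changes
    active = np.arange(B)
    Wa = W
    aa = a
    for t in range(1, p.max_iterations + 1):
        net = np.einsum("bij,bi->bj", Wa, aa)
        np.clip(net, -1.0, 1.0, out=net)
        grow = net * (p.max - aa)
        shrink = net * (aa - p.min)
        new = aa * (1.0 - p.decay) + np.where(net > 0.0, grow, shrink)
        # the raw rule can overshoot by up to d when |net| is near 1;
        # activations are hard-bounded at [min, max]
        np.clip(new, p.min, p.max, out=new)
        new[:, clamp_idx] = clamp_val
        if not np.all(np.isfinite(new)):
            raise FloatingPointError(
                "non-finite activation during settling; check weight invariants"
            )
        if free.any():
            delta = np.max(np.abs(new - aa)[:, free], axis=1)
        else:
            delta = np.zeros(len(active))
        aa = new
        a[active] = aa
        if return_trace:
            traces.append(-np.einsum("bi,bij,bj->b", a, W, a))
        done = delta < p.convergence_threshold
        if done.any():
            idx = active[done]
            iters[idx] = t
            converged[idx] = True
            keep = ~done
            active = active[keep]
            if len(active) == 0:
                break
            Wa = Wa[keep]
            aa = aa[keep]
    iters[~converged] = p.max_iterations
    if return_trace:
        return a, iters, converged, np.stack(traces, axis=1)
    return a, iters, converged


def settle(network: AttitudeNetwork, params: ActivationParams | None = None) -> SettleResult:
    """Run synchronous settling on one network until stable.

    Starts from the network's initial activations (clamped units at
    their clamp value, all other units at 0) and applies the two-branch
    update

        a_j(t+1) = a_j(t)(1-d) + net_j (max - a_j(t))   if net_j > 0
        a_j(t+1) = a_j(t)(1-d) + net_j (a_j(t) - min)   otherwise

    with net_j clamped to [-1, 1].  Clamped units are never updated.
    """
    a, iters, conv, trace = settle_batch(
        network.weights[None, :, :],
        network.clamped_indices,
        network.clamped_values,
        params,
        return_trace=True,
    )
    network.activations = a[0]
    return SettleResult(
        activations=a[0],
        iterations=int(iters[0]),
        converged=bool(conv[0]),
        energy_trace=trace[0, : int(iters[0])] if conv[0] else trace[0],
        topology=network.topology,
    )


def energy(network: AttitudeNetwork, activations: np.ndarray | None = None) -> float:
    """Coherence score: E = -sum_i sum_j w_ij a_i a_j over ordered pairs."""
    a = network.activations if activations is None else np.asarray(activations, float)
    if a.shape != (network.topology.n_nodes,):
        raise ValueError("activation vector has wrong shape")
    return float(-(a @ network.weights @ a))


def energy_batch(W: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Energies for a (B, n, n) weight stack and (B, n) activations."""
    return -np.einsum("bi,bij,bj->b", a, W, a)


def attitude_of(result: SettleResult, option_id: str) -> float:
    """Settled activation of an option unit: the simulated attitude."""
    if option_id not in result.topology.option_ids:
        raise KeyError(f"unknown option {option_id!r}")
    return result.activation(option_id)
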