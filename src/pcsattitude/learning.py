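"""Error-correction weight learning for persuasive communication.

A persuasion event transmits some of a sender network's link weights to
a receiver.  Each transmitted link is adjusted by a second-order
polynomial in the dissonance ``delta = w_s - w_r`` (sender minus
receiver weight) and the receiver's prior weight ``w_r``:

    dw = b1*delta + b2*w_r + b3*delta*w_r + b4*w_r**2 + b5*delta**2

with the five coefficients b1..b5 free in [-1, 1] per experimental
condition.  The new receiver weight is ``clip(w_r + dw, -1, 1)``,
applied symmetrically; links not named by the transmission plan are
untouched.  b1 > 0 moves the receiver toward the sender (assimilation);
the interaction and quadratic terms allow contrast/backfire responses.

Coefficients are fitted per condition by minimizing the mean squared
error D between the simulated post-treatment option activation (A_sim)
and the reported post-treatment attitude (A_emp), via a seeded
coarse-to-fine grid search at resolution 0.1 (the granularity of the
reported optima), with deterministic tie-breaking by smallest L1 norm
then lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import SenderNetwork, TransmissionPlan, Vignette, encode_vignette, transmission_plan
from .network import (
    ActivationParams,
    AttitudeNetwork,
    SettleResult,
    attitude_of,
    energy,
    settle,
    settle_batch,
)

__all__ = [
    "LearningParams",
    "TreatmentRecord",
    "TreatmentDataset",
    "FitConfig",
    "delta_w",
    "apply_persuasion",
    "simulate_treatment",
    "simulate_sequence",
    "error_D",
    "fit_params",
    "REPORTED_PARAMS",
]

#: Published best-fitting coefficients per condition (b1..b5).
REPORTED_PARAMS = {
    "rational": (0.0, 0.7, -0.3, 0.0, -0.3),
    "emotional": (0.0, 0.7, -0.3, 0.3, -0.7),
    "combined": (0.0, 1.0, -0.3, 0.7, -0.3),
}


@dataclass(frozen=True)
class LearningParams:
    """The five polynomial coefficients of the weight-adjustment rule."""

    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    condition: str | None = None

    def __post_init__(self):
        for name in ("b1", "b2", "b3", "b4", "b5"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")

    @classmethod
    def from_array(cls, b, condition: str | None = None) -> "LearningParams":
        b1, b2, b3, b4, b5 = (float(x) for x in b)
        return cls(b1, b2, b3, b4, b5, condition)

    @classmethod
    def zero(cls, condition: str | None = None) -> "LearningParams":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, condition)

    @classmethod
    def reported(cls, condition: str) -> "LearningParams":
        """The published per-condition optima."""
        return cls.from_array(REPORTED_PARAMS[condition], condition)

    def as_array(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3, self.b4, self.b5])


@dataclass
class TreatmentRecord:
    """One sender-to-receiver persuasion event."""

    agent_id: str
    vignette: Vignette
    links: list  # of dicts {link, w_s, w_r_pre, w_r_post}
    A_base: float | None = None
    A_sim: float | None = None
    A_emp: float | None = None
    energy_pre: float | None = None
    energy_post: float | None = None
    converged: bool = True


def _features(delta, w_r):
    """Polynomial basis (delta, w_r, delta*w_r, w_r^2, delta^2)."""
    delta = np.asarray(delta, dtype=float)
    w_r = np.asarray(w_r, dtype=float)
    return np.stack(
        [delta, w_r, delta * w_r, np.square(w_r), np.square(delta)], axis=-1
    )


def delta_w(w_s, w_r, params: LearningParams):
    """Raw (unclipped) weight adjustment for transmitted link(s).

    Accepts scalars or arrays; the dissonance is ``w_s - w_r``.
    """
    out = _features(np.asarray(w_s, float) - np.asarray(w_r, float), w_r) @ params.as_array()
    return float(out) if np.isscalar(w_s) and np.isscalar(w_r) else out


def apply_persuasion(
    receiver: AttitudeNetwork,
    sender: SenderNetwork,
    plan: TransmissionPlan,
    params: LearningParams,
    agent_id: str = "",
) -> tuple[AttitudeNetwork, TreatmentRecord]:
    """Adjust the receiver's transmitted link weights toward/away the sender.

    Returns a modified copy of the receiver (the input is untouched)
    plus a record of the per-link weight changes.  Only links named by
    the transmission plan change; each is set to
    ``clip(w_r + dw, -1, 1)``, symmetrically.
    """
    updated = receiver.copy()
    link_log = []
    for link in plan.links:
        a, b = tuple(link)
        w_s = sender.weight(a, b)
        w_r = receiver.get_weight(a, b)
        new_w = float(np.clip(w_r + delta_w(w_s, w_r, params), -1.0, 1.0))
        updated.set_weight(a, b, new_w)
        link_log.append({"link": link, "w_s": w_s, "w_r_pre": w_r, "w_r_post": new_w})
    record = TreatmentRecord(
        agent_id=agent_id, vignette=sender.vignette, links=link_log
    )
    return updated, record


def simulate_treatment(
    receiver: AttitudeNetwork,
    vignette: Vignette,
    params: LearningParams,
    act_params: ActivationParams | None = None,
    baseline: SettleResult | None = None,
    agent_id: str = "",
) -> TreatmentRecord:
    """Run one persuasion event against an agent's baseline network.

    The event is applied to a fresh copy of the baseline network
    (treatments are independent across vignettes), the modified network
    is re-settled from its initial activations, and the record collects
    the vignette option's pre/post activation and the pre/post network
    energy.  A non-convergent settle flags the record (``converged =
    False``) so it can be excluded from fitting.
    """
    ap = act_params or ActivationParams()
    if baseline is None:
        baseline = settle(receiver.copy(), ap)
    sender = encode_vignette(vignette, receiver.topology)
    plan = transmission_plan(vignette, receiver.topology)
    updated, record = apply_persuasion(receiver, sender, plan, params, agent_id=agent_id)
    post = settle(updated, ap)
    record.A_base = attitude_of(baseline, vignette.option)
    record.A_sim = attitude_of(post, vignette.option)
    record.energy_pre = energy(receiver, baseline.activations)
    record.energy_post = energy(updated, post.activations)
    record.converged = bool(baseline.converged and post.converged)
    return record


def simulate_sequence(
    receiver: AttitudeNetwork,
    vignettes,
    params: LearningParams,
    act_params: ActivationParams | None = None,
    cumulative: bool = False,
    agent_id: str = "",
) -> list[TreatmentRecord]:
    """Run an agent's vignette sequence in presentation order.

    With ``cumulative=False`` (the default reading of per-vignette
    self-reports) every event hits a fresh copy of the baseline
    network.  With ``cumulative=True`` each event is applied to the
    network left behind by the previous one, and A_base tracks the
    attitude immediately before each event.
    """
    ap = act_params or ActivationParams()
    current = receiver.copy()
    baseline = settle(current.copy(), ap)
    records = []
    for vig in vignettes:
        rec = simulate_treatment(
            current, vig, params, ap, baseline=baseline, agent_id=agent_id
        )
        records.append(rec)
        if cumulative:
            sender = encode_vignette(vig, current.topology)
            plan = transmission_plan(vig, current.topology)
            current, _ = apply_persuasion(current, sender, plan, params, agent_id)
            baseline = settle(current.copy(), ap)
    return records


def error_D(a_sim, a_emp) -> float:
    """Mean squared error D between simulated and reported attitudes."""
    a_sim = np.asarray(a_sim, dtype=float)
    a_emp = np.asarray(a_emp, dtype=float)
    if a_sim.size == 0:
        raise ValueError("no treatments to score")
    if a_sim.shape != a_emp.shape:
        raise ValueError("A_sim and A_emp differ in length")
    return float(np.mean(np.square(a_sim - a_emp)))


# ---------------------------------------------------------------------
# Vectorized treatment batches and the grid-search fit
# ---------------------------------------------------------------------


@dataclass
class TreatmentDataset:
    """Array-compiled persuasion events of one condition, for fitting.

    ``base_W`` stacks each event's baseline receiver weight matrix;
    ``link_i``/``link_j`` index the transmitted links (all events of a
    condition transmit the same number of links), ``w_s`` the sender
    weights, ``option_idx`` the vignette option node and ``A_emp`` the
    reported post-treatment attitude.
    """

    condition: str
    base_W: np.ndarray  # (B, n, n)
    link_i: np.ndarray  # (B, L)
    link_j: np.ndarray  # (B, L)
    w_s: np.ndarray  # (B, L)
    option_idx: np.ndarray  # (B,)
    A_emp: np.ndarray  # (B,)
    clamp_idx: np.ndarray
    clamp_val: np.ndarray
    agent_ids: list = field(default_factory=list)
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.base_W)

    @property
    def w_r(self) -> np.ndarray:
        b = np.arange(self.n)[:, None]
        return self.base_W[b, self.link_i, self.link_j]

    @classmethod
    def from_events(cls, events, condition: str | None = None) -> "TreatmentDataset":
        """Compile (receiver network, vignette, A_emp) triples.

        All events must share one condition and clamping structure.
        Events whose baseline settle does not converge are dropped and
        counted in ``n_excluded``.
        """
        events = list(events)
        if not events:
            raise ValueError("no events")
        conds = {v.condition for _, v, _ in events}
        if condition is None:
            if len(conds) != 1:
                raise ValueError(f"mixed conditions {sorted(conds)}; fit per condition")
            condition = conds.pop()
        top = events[0][0].topology
        base_W, li, lj, ws, opt, aemp, ids = [], [], [], [], [], [], []
        for net, vig, a_emp in events:
            plan = transmission_plan(vig, top)
            sender = encode_vignette(vig, top)
            base_W.append(net.weights)
            li.append([top.index(sorted(l)[0]) for l in plan.links])
            lj.append([top.index(sorted(l)[1]) for l in plan.links])
            ws.append([sender.weight(*tuple(l)) for l in plan.links])
            opt.append(top.index(vig.option))
            aemp.append(np.nan if a_emp is None else float(a_emp))
            ids.append(getattr(net, "agent_id", ""))
        return cls(
            condition=condition,
            base_W=np.array(base_W),
            link_i=np.array(li),
            link_j=np.array(lj),
            w_s=np.array(ws),
            option_idx=np.array(opt),
            A_emp=np.array(aemp),
            clamp_idx=events[0][0].clamped_indices,
            clamp_val=events[0][0].clamped_values,
            agent_ids=ids,
        )

    def subsample(self, k: int) -> "TreatmentDataset":
        """Evenly spaced deterministic subset of at most ``k`` events."""
        if self.n <= k:
            return self
        idx = np.linspace(0, self.n - 1, k).round().astype(int)
        return TreatmentDataset(
            condition=self.condition,
            base_W=self.base_W[idx],
            link_i=self.link_i[idx],
            link_j=self.link_j[idx],
            w_s=self.w_s[idx],
            option_idx=self.option_idx[idx],
            A_emp=self.A_emp[idx],
            clamp_idx=self.clamp_idx,
            clamp_val=self.clamp_val,
            agent_ids=[self.agent_ids[i] for i in idx],
        )


def simulate_A_sim(
    dataset: TreatmentDataset,
    b: np.ndarray,
    act_params: ActivationParams | None = None,
    max_batch: int = 40000,
) -> tuple[np.ndarray, np.ndarray]:
    """A_sim for each event of ``dataset`` under candidate coefficient
    vectors ``b`` of shape (K, 5).  Returns (A_sim (K, B), converged (K, B)).
    """
    ap = act_params or ActivationParams()
    b = np.atleast_2d(np.asarray(b, dtype=float))
    K = len(b)
    B, L = dataset.w_s.shape
    n = dataset.base_W.shape[1]
    w_r = dataset.w_r  # (B, L)
    feats = _features(dataset.w_s - w_r, w_r)  # (B, L, 5)
    rows_b = np.arange(B)
    A_sim = np.empty((K, B))
    conv = np.empty((K, B), dtype=bool)
    kc = max(1, max_batch // max(B, 1))
    for k0 in range(0, K, kc):
        bc = b[k0 : k0 + kc]  # (Kc, 5)
        Kc = len(bc)
        dw = np.einsum("blf,kf->kbl", feats, bc)
        post = np.clip(w_r[None, :, :] + dw, -1.0, 1.0)  # (Kc, B, L)
        W = np.broadcast_to(dataset.base_W, (Kc, B, n, n)).reshape(Kc * B, n, n).copy()
        rows = np.arange(Kc * B)[:, None]
        li = np.broadcast_to(dataset.link_i, (Kc, B, L)).reshape(Kc * B, L)
        lj = np.broadcast_to(dataset.link_j, (Kc, B, L)).reshape(Kc * B, L)
        flat_post = post.reshape(Kc * B, L)
        W[rows, li, lj] = flat_post
        W[rows, lj, li] = flat_post
        a, _, c = settle_batch(W, dataset.clamp_idx, dataset.clamp_val, ap)
        opt = np.broadcast_to(dataset.option_idx, (Kc, B)).reshape(-1)
        A_sim[k0 : k0 + kc] = a[np.arange(Kc * B), opt].reshape(Kc, B)
        conv[k0 : k0 + kc] = c.reshape(Kc, B)
    return A_sim, conv


def _evaluate_D(dataset, b, act_params):
    """D per candidate row of ``b``; non-convergent settles excluded."""
    A_sim, conv = simulate_A_sim(dataset, b, act_params)
    err = np.square(A_sim - dataset.A_emp[None, :])
    err = np.where(conv, err, np.nan)
    with np.errstate(invalid="ignore"):
        D = np.nanmean(err, axis=1)
    n_excl = (~conv).sum(axis=1)
    return D, n_excl


@dataclass(frozen=True)
class FitConfig:
    """Search configuration for :func:`fit_params`.

    A full factorial grid at ``coarse_step`` is scored on an evenly
    spaced subsample of events; the ``top_k`` coarse candidates are
    re-scored on all events and the best seeds a cyclic coordinate
    descent on the ``grid_step`` lattice (full line search per
    coordinate) until a sweep changes nothing.
    """

    grid_step: float = 0.1
    coarse_step: float = 0.5
    bounds: tuple = (-1.0, 1.0)
    coarse_subsample: int = 256
    search_subsample: int = 512
    top_k: int = 16
    n_starts: int = 3
    n_full_starts: int = 2
    polish: bool = True
    de_popsize: int = 16
    de_seed: int = 0
    de_maxiter: int = 50
    max_sweeps: int = 20
    tie_tol: float = 1e-12


def _grid(step: float, bounds) -> np.ndarray:
    lo, hi = bounds
    k = int(round((hi - lo) / step))
    return np.round(np.linspace(lo, hi, k + 1), 10)


def _tie_key(b_row: np.ndarray) -> tuple:
    return (float(np.abs(b_row).sum()), tuple(b_row))


def _select(b_cands: np.ndarray, D: np.ndarray, tol: float) -> int:
    """Index of the best candidate: min D, then min L1, then lexicographic."""
    finite = np.isfinite(D)
    if not finite.any():
        raise ValueError("all candidates failed to converge")
    d_min = np.min(D[finite])
    tied = np.where(finite & (D <= d_min + tol))[0]
    return int(min(tied, key=lambda i: _tie_key(b_cands[i])))


def fit_params(
    dataset: TreatmentDataset,
    config: FitConfig | None = None,
    act_params: ActivationParams | None = None,
) -> tuple[LearningParams, dict]:
    """Fit b1..b5 for one condition by coarse-to-fine grid search.

    Minimizes the mean squared error D between simulated and reported
    post-treatment attitudes over the lattice of step ``grid_step`` on
    [-1, 1]^5.  Ties (within ``tie_tol``) break toward the smallest L1
    norm, then lexicographically.  Returns the fitted coefficients and
    a diagnostics dict (final D, event counts, evaluation count).
    """
    cfg = config or FitConfig()
    ap = act_params or ActivationParams()
    if dataset.n == 0 or np.isnan(dataset.A_emp).any():
        raise ValueError("dataset must contain events with reported attitudes")
    n_evals = 0

    # stage 1: coarse factorial grid on a subsample
    coarse_vals = _grid(cfg.coarse_step, cfg.bounds)
    mesh = np.meshgrid(*([coarse_vals] * 5), indexing="ij")
    coarse = np.stack([m.ravel() for m in mesh], axis=1)
    sub = dataset.subsample(cfg.coarse_subsample)
    D_sub, _ = _evaluate_D(sub, coarse, ap)
    n_evals += len(coarse)
    order = np.argsort(D_sub, kind="stable")[: cfg.top_k]

    # stage 2: re-score the shortlist on a larger search subsample
    search = dataset.subsample(cfg.search_subsample)
    shortlist = coarse[order]
    D_short, _ = _evaluate_D(search, shortlist, ap)
    n_evals += len(shortlist)
    start_order = np.argsort(D_short, kind="stable")
    starts = [shortlist[i].copy() for i in start_order[: cfg.n_starts]]

    # stage 3 (optional): seeded global search in the continuous box
    # (differential evolution, vectorized over whole populations) on
    # the search subsample; its rounded end point joins the starts
    if cfg.polish:
        from scipy.optimize import differential_evolution

        counter = {"n": 0}

        def _objective(bv):
            # vectorized: bv has shape (5, S)
            bv = np.atleast_2d(bv.T if bv.ndim == 2 else bv)
            counter["n"] += len(bv)
            D, _ = _evaluate_D(search, bv, ap)
            return D if len(D) > 1 else D[0]

        res = differential_evolution(
            _objective,
            bounds=[cfg.bounds] * 5,
            seed=cfg.de_seed,
            init="sobol",
            popsize=cfg.de_popsize,
            maxiter=cfg.de_maxiter,
            tol=1e-10,
            polish=False,
            vectorized=True,
            updating="deferred",
            x0=starts[0],
        )
        n_evals += counter["n"]
        rounded = np.clip(
            np.round(res.x / cfg.grid_step) * cfg.grid_step,
            cfg.bounds[0],
            cfg.bounds[1],
        ).round(10)
        starts.insert(0, rounded)

    # stage 4: cyclic coordinate descent on the fine lattice with
    # pairwise +/-step escape moves; first on the search subsample per
    # start, then on all events from the best end points
    fine_vals = _grid(cfg.grid_step, cfg.bounds)
    sweeps = 0

    def _descend(ds, b0):
        nonlocal n_evals, sweeps
        best = b0.copy()
        D_cur, _ = _evaluate_D(ds, best[None, :], ap)
        n_evals += 1
        for _ in range(cfg.max_sweeps):
            sweeps += 1
            changed = False
            for c in range(5):
                cands = np.tile(best, (len(fine_vals), 1))
                cands[:, c] = fine_vals
                D_line, _ = _evaluate_D(ds, cands, ap)
                n_evals += len(cands)
                pick = _select(cands, D_line, cfg.tie_tol)
                if D_line[pick] < D_cur[0] - cfg.tie_tol or (
                    D_line[pick] <= D_cur[0] + cfg.tie_tol
                    and _tie_key(cands[pick]) < _tie_key(best)
                ):
                    best, D_cur = cands[pick].copy(), D_line[pick : pick + 1]
                    changed = True
            if not changed:
                # pairwise escape: +/-step on every coordinate pair
                pair_moves = []
                s = cfg.grid_step
                for c1 in range(5):
                    for c2 in range(c1 + 1, 5):
                        for s1 in (-s, s):
                            for s2 in (-s, s):
                                cand = best.copy()
                                cand[c1] = np.clip(cand[c1] + s1, *cfg.bounds)
                                cand[c2] = np.clip(cand[c2] + s2, *cfg.bounds)
                                pair_moves.append(np.round(cand, 10))
                pair_moves = np.unique(np.array(pair_moves), axis=0)
                D_pair, _ = _evaluate_D(ds, pair_moves, ap)
                n_evals += len(pair_moves)
                pick = _select(pair_moves, D_pair, cfg.tie_tol)
                if D_pair[pick] < D_cur[0] - cfg.tie_tol:
                    best, D_cur = pair_moves[pick].copy(), D_pair[pick : pick + 1]
                else:
                    break
        return best, D_cur[0]

    sub_results = [_descend(search, s) for s in starts]
    sub_finals = np.unique(np.array([b for b, _ in sub_results]), axis=0)
    D_sub_finals, _ = _evaluate_D(dataset, sub_finals, ap)
    n_evals += len(sub_finals)
    full_order = np.argsort(D_sub_finals, kind="stable")
    full_results = [
        _descend(dataset, sub_finals[i].copy())
        for i in full_order[: cfg.n_full_starts]
    ]
    finals = np.array([b for b, _ in full_results])
    D_finals = np.array([d for _, d in full_results])
    best = finals[_select(finals, D_finals, cfg.tie_tol)].copy()

    D_best, n_excl = _evaluate_D(dataset, best[None, :], ap)
    params = LearningParams.from_array(best, dataset.condition)
    diagnostics = {
        "D": float(D_best[0]),
        "n_treatments": int(dataset.n),
        "n_excluded": int(n_excl[0]) + int(dataset.n_excluded),
        "grid_step": cfg.grid_step,
        "n_evals": int(n_evals),
        "sweeps": sweeps,
    }
    return params, diagnostics
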