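"""Single-threshold mixed Yule/coalescent lineage delimitation.

A time threshold T splits an ultrametric tree into a diversification
(Yule) regime above T and independent coalescent regimes within each
cluster below T.  Branching is modelled as competing exponential waiting
times: in a slice of duration x the contribution is ``-b*x`` with total
rate ``b = lam1 * n_d**p1 + lam2 * sum_j (n_j*(n_j-1))**p2`` (n_d branches
above T, n_j branches in cluster j below T), plus ``log(b)`` of the slice
ending in each branching event.

The module provides the exact log-likelihood, ML fitting over candidate
thresholds with profiled rates, a likelihood-ratio test against the
single-process null, and a Metropolis-Hastings sampler that aggregates
cluster posteriors over a sample of trees into a conspecificity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from evoreserve.trees import TreeValidationError, UltrametricTree

log = logging.getLogger(__name__)

DEFAULT_P_BOUNDS = (-2.0, 3.0)
_TERMINAL_TOL = 1e-12


@dataclass
class BranchingIntervals:
    """Ordered branching events and inter-event intervals of a tree."""

    events: np.ndarray  # internal node heights, ascending from present
    durations: np.ndarray  # interval lengths; durations.sum() == root height
    branch_counts: np.ndarray  # lineages present during each interval


@dataclass
class GMYCModel:
    threshold: float
    lam1: float
    p1: float
    lam2: float
    p2: float
    loglik: float
    clusters: list[list[str]]
    null_loglik: float = np.nan

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def assignment(self) -> pd.Series:
        """Tip label -> 0-based lineage id."""
        out = {}
        for k, tips in enumerate(self.clusters):
            for t in tips:
                out[t] = k
        return pd.Series(out, name="lineage")


@dataclass
class BGMYCResult:
    conspecificity: pd.DataFrame  # tip x tip, fraction of samples conspecific
    samples: pd.DataFrame  # retained parameter samples (pooled over trees)
    settings: dict
    acceptance_rate: float


def compute_intervals(tree: UltrametricTree) -> BranchingIntervals:
    """Branching events (internal node heights) and waiting intervals."""
    tree.validate()
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    events = tree.internal_heights()
    bounds = np.concatenate([[0.0], events])
    durations = np.diff(bounds)
    counts = tree.n_tips - np.arange(len(events))
    return BranchingIntervals(events, durations, counts)


def validate_no_identical_haplotypes(tree: UltrametricTree) -> None:
    """Reject trees with zero-height internal nodes (identical haplotypes)."""
    events = tree.internal_heights()
    if events.size and events[0] <= _TERMINAL_TOL:
        raise TreeValidationError(
            "tree contains a zero-length terminal pair; remove identical haplotypes upstream"
        )


# ---------------------------------------------------------------------------
# likelihood


class _Profile:
    """Per-(tree, threshold) slice censuses for fast likelihood evaluation.

    Time is sliced at every internal node height plus the threshold.  Each
    slice carries its duration, its Yule branch census (zero below T), the
    coalescent pair products m = n_j*(n_j-1) of its clusters, and whether
    it ends in a branching event; the log-likelihood is then a vectorized
    sum of ``log(b) - b*x`` over slices.
    """

    __slots__ = ("threshold", "x", "nd", "has_event", "m_flat", "s_flat", "n_slices", "clusters")

    def __init__(self, tree: UltrametricTree, threshold: float):
        self.threshold = threshold
        root_h = tree.root_height
        clusters = tree.clusters_at(min(threshold, root_h))
        self.clusters = [list(np.asarray(tree.tip_labels, dtype=object)[c]) for c in clusters]
        cluster_of_tip = np.full(tree.n_tips, -1, dtype=int)
        for j, c in enumerate(clusters):
            cluster_of_tip[c] = j
        counts = np.array([len(c) for c in clusters], dtype=float)

        internal = [i for i in range(tree.n_nodes) if tree.children[i]]
        internal.sort(key=lambda i: tree.heights[i])

        x: list[float] = []
        nd: list[float] = []
        has_event: list[bool] = []
        m_flat: list[float] = []
        s_flat: list[int] = []

        def push_coal_slice(dt: float) -> None:
            s = len(x)
            x.append(dt)
            nd.append(0.0)
            has_event.append(False)
            for m in counts * (counts - 1):
                if m > 0:
                    m_flat.append(m)
                    s_flat.append(s)

        t = 0.0
        below = True  # the walk starts at the present, always below T
        n_d = float(len(clusters))
        for node in internal:
            h = float(tree.heights[node])
            if below and h >= threshold:
                push_coal_slice(threshold - t)  # partial slice ending at T
                t = threshold
                below = False
            if below:
                push_coal_slice(h - t)
                has_event[-1] = True
                j = cluster_of_tip[tree.tips_below(node)[0]]
                counts[j] -= 1
            else:
                x.append(h - t)
                nd.append(n_d)
                has_event.append(True)
                n_d -= 1
            t = h

        self.x = np.asarray(x)
        self.nd = np.asarray(nd)
        self.has_event = np.asarray(has_event)
        self.m_flat = np.asarray(m_flat)
        self.s_flat = np.asarray(s_flat, dtype=int)
        self.n_slices = len(x)

    def rates(self, lam1: float, lam2: float, p1: float, p2: float) -> np.ndarray:
        """Total branching rate b per slice."""
        b = np.zeros(self.n_slices)
        yule = self.nd > 0
        if yule.any():
            b[yule] = lam1 * self.nd[yule] ** p1
        if self.m_flat.size:
            b += lam2 * np.bincount(
                self.s_flat, weights=self.m_flat**p2, minlength=self.n_slices
            )
        return b

    def loglik(self, lam1: float, lam2: float, p1: float, p2: float) -> float:
        if lam1 < 0 or lam2 < 0:
            return -np.inf
        b = self.rates(lam1, lam2, p1, p2)
        b_ev = b[self.has_event]
        if (b_ev <= 0).any():
            return -np.inf  # an observed event in a zero-rate regime
        return float(np.log(b_ev).sum() - (b * self.x).sum())


def gmyc_loglik(
    tree: UltrametricTree, threshold: float, lam1: float, p1: float, lam2: float, p2: float
) -> float:
    """Exact mixed-model log-likelihood at explicit parameters.

    Returns -inf (rather than raising) when an observed event falls in a
    process whose rate is zero.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if lam1 < 0 or lam2 < 0:
        raise ValueError("rates must be nonnegative")
    return _Profile(tree, threshold).loglik(lam1, lam2, p1, p2)


def candidate_thresholds(tree: UltrametricTree) -> np.ndarray:
    """Midpoints between consecutive distinct event levels, plus one above root.

    The level below the shallowest node gives the all-singleton (pure Yule)
    extreme; the level above the root gives the single-cluster (pure
    coalescent) null.
    """
    heights = np.unique(tree.internal_heights())
    levels = np.concatenate([[0.0], heights])
    mids = 0.5 * (levels[:-1] + levels[1:])
    return np.concatenate([mids, [tree.root_height * 1.5]])


_LOG_LAM_BOUNDS = (-18.0, 14.0)
# deterministic multi-starts in (log lam1, p1, log lam2, p2)
_STARTS = ((0.0, 1.0, 0.0, 1.0), (0.0, 0.0, 3.0, 1.0), (1.0, 1.0, 5.0, 0.5))


def _optimize_profile(prof: _Profile, p_bounds: tuple[float, float]):
    """Maximize the likelihood over (lam1, p1, lam2, p2), rates on log scale."""

    def neg(z: np.ndarray) -> float:
        ll = prof.loglik(np.exp(z[0]), np.exp(z[2]), z[1], z[3])
        return 1e12 if not np.isfinite(ll) else -ll

    bounds = [_LOG_LAM_BOUNDS, p_bounds, _LOG_LAM_BOUNDS, p_bounds]
    best = None
    for start in _STARTS:
        x0 = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            log.warning("optimizer failure at threshold %.4g: %s", prof.threshold, exc)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e12:
        return None
    z = best.x
    return -best.fun, float(np.exp(z[0])), float(z[1]), float(np.exp(z[2])), float(z[3])


def fit_gmyc(
    tree: UltrametricTree, p_bounds: tuple[float, float] = DEFAULT_P_BOUNDS
) -> GMYCModel:
    """ML fit: scan candidate thresholds, optimize parameters at each.

    The rates are profiled out analytically, leaving a 2-D bounded
    optimization in the scaling exponents per candidate threshold.
    """
    tree.validate()
    validate_no_identical_haplotypes(tree)
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips to fit the mixed model")
    best_model: GMYCModel | None = None
    null_ll = np.nan
    for thr in candidate_thresholds(tree):
        prof = _Profile(tree, thr)
        fit = _optimize_profile(prof, p_bounds)
        if fit is None:
            log.warning("skipping candidate threshold %.4g (no optimum)", thr)
            continue
        ll, lam1, p1, lam2, p2 = fit
        if len(prof.clusters) == 1:
            null_ll = max(ll, null_ll) if np.isfinite(null_ll) else ll
        if best_model is None or ll > best_model.loglik:
            best_model = GMYCModel(thr, lam1, p1, lam2, p2, ll, prof.clusters)
    if best_model is None:
        raise RuntimeError("no candidate threshold could be fitted")
    best_model.null_loglik = null_ll
    return best_model


def lr_test(model: GMYCModel, df: int = 3) -> dict[str, float]:
    """Likelihood-ratio test of the mixed model against the single-process null.

    The null is the best whole-tree single-process fit (one rate, one
    scaling), which the candidate scan always evaluates (threshold above
    the root).  p-value from chi-square with ``df`` degrees of freedom.
    """
    if not np.isfinite(model.null_loglik):
        raise ValueError("model carries no null log-likelihood; fit with fit_gmyc")
    lr = max(0.0, 2.0 * (model.loglik - model.null_loglik))
    return {"LR": lr, "p_value": float(stats.chi2.sf(lr, df))}


def delimit(tree: UltrametricTree, alpha: float = 0.05) -> tuple[pd.Series, GMYCModel]:
    """Fit + LRT: returns (tip -> lineage id) collapsing to one lineage when
    the mixed model is not significantly better than the null."""
    if tree.n_tips == 1:
        return pd.Series({tree.tip_labels[0]: 0}, name="lineage"), None
    model = fit_gmyc(tree)
    if lr_test(model)["p_value"] >= alpha or model.n_clusters == 1:
        return pd.Series({t: 0 for t in tree.tip_labels}, name="lineage"), model
    return model.assignment(), model


# ---------------------------------------------------------------------------
# Bayesian variant


DEFAULT_PRIORS = {
    "lam_max": 100.0,
    "p_bounds": DEFAULT_P_BOUNDS,
    # threshold prior: "time" puts T ~ Uniform(0, t_max_factor * root height),
    # weighting each candidate partition by the length of the time interval
    # that produces it; "index" is uniform over the candidate set.
    "t_prior": "time",
    "t_max_factor": 6.0,
}


def bgmyc_sample(
    trees: list[UltrametricTree] | UltrametricTree,
    generations: int = 100_000,
    burnin: int = 10_000,
    thinning: int = 100,
    priors: dict | None = None,
    seed: int = 0,
) -> BGMYCResult:
    """Metropolis-Hastings sampling of the mixed model over a tree sample.

    The state is (lam1, p1, lam2, p2, threshold index); priors are uniform
    (rates on (0, lam_max), exponents within bounds, threshold uniform in
    time by default — see DEFAULT_PRIORS).  Proposal scales are tuned
    during burn-in toward 20-40% acceptance.  Cluster partitions of
    retained samples, pooled over all trees, give the tip-pair
    conspecificity matrix.
    """
    if isinstance(trees, UltrametricTree):
        trees = [trees]
    if not trees:
        raise ValueError("need at least one tree")
    if generations <= burnin:
        raise ValueError("generations must exceed burnin")
    pr = dict(DEFAULT_PRIORS, **(priors or {}))
    lam_max = pr["lam_max"]
    p_lo, p_hi = pr["p_bounds"]
    rng = np.random.default_rng(seed)

    labels = sorted(trees[0].tip_labels)
    lab_index = {lb: i for i, lb in enumerate(labels)}
    n = len(labels)
    co = np.zeros((n, n))
    n_samples = 0
    rows = []
    accepted_total = 0
    proposed_total = 0

    for tree in trees:
        tree.validate()
        profs = [_Profile(tree, thr) for thr in candidate_thresholds(tree)]
        # prior over the threshold candidates
        if pr["t_prior"] == "time":
            levels = np.concatenate([[0.0], np.unique(tree.internal_heights())])
            gaps = np.diff(levels)
            top = max(pr["t_max_factor"] - 1.0, 0.0) * tree.root_height
            t_weights = np.concatenate([gaps, [top]])
        elif pr["t_prior"] == "index":
            t_weights = np.ones(len(profs))
        else:
            raise ValueError(f"unknown t_prior {pr['t_prior']!r}")
        t_weights = t_weights / t_weights.sum()
        log_t_prior = np.log(np.where(t_weights > 0, t_weights, 1e-300))
        # partition as an integer label vector per candidate threshold
        partitions = []
        for prof in profs:
            lab = np.zeros(n, dtype=int)
            for j, tips in enumerate(prof.clusters):
                for t in tips:
                    lab[lab_index[t]] = j
            partitions.append(lab)

        # per-threshold ML parameters: chain start and anchors for jump proposals
        anchors = []
        for prof in profs:
            fit = _optimize_profile(prof, (p_lo, p_hi))
            if fit is None:
                anchors.append(np.array([1.0, 1.0, 1.0, 1.0]))
            else:
                _, lam1, p1, lam2, p2 = fit
                anchors.append(
                    np.array([min(lam1, 0.9 * lam_max), p1, min(lam2, 0.9 * lam_max), p2])
                )
        anchors = np.asarray(anchors)
        lls = np.array([pr.loglik(a[0], a[2], a[1], a[3]) for pr, a in zip(profs, anchors)])
        t_idx = int(np.argmax(lls))
        state = anchors[t_idx].copy()
        cur_ll = lls[t_idx]
        scale = np.array([0.5, 0.3, 0.5, 0.3])
        # per-anchor jump scales, wide in the rates so drifted chains can re-enter
        jump_scales = np.maximum(np.abs(anchors) * 0.5, [1.0, 0.4, 1.0, 0.4])

        def log_q(theta: np.ndarray, idx: int) -> float:
            s = jump_scales[idx]
            return float(-0.5 * (((theta - anchors[idx]) / s) ** 2).sum() - np.log(s).sum())

        acc_window = 0
        for gen in range(generations):
            prop = state.copy()
            prop_idx = t_idx
            log_hastings = 0.0
            u = rng.random()
            if u < 0.5:  # symmetric random walk on parameters
                prop = state + rng.normal(size=4) * scale
            else:
                # jump: threshold drawn from its prior (cancels in the ratio),
                # parameters proposed near that threshold's ML anchor; u >= 0.9
                # re-anchors within the current threshold to aid basin hopping
                prop_idx = t_idx if u >= 0.9 else int(rng.choice(len(profs), p=t_weights))
                prop = anchors[prop_idx] + rng.normal(size=4) * jump_scales[prop_idx]
                log_hastings = log_q(state, t_idx) - log_q(prop, prop_idx)
            in_support = (
                0 < prop[0] < lam_max
                and 0 < prop[2] < lam_max
                and p_lo <= prop[1] <= p_hi
                and p_lo <= prop[3] <= p_hi
            )
            proposed_total += 1
            if in_support:
                prop_ll = profs[prop_idx].loglik(prop[0], prop[2], prop[1], prop[3])
                if np.log(rng.random()) < prop_ll - cur_ll + log_hastings:
                    state, t_idx, cur_ll = prop, prop_idx, prop_ll
                    acc_window += 1
                    accepted_total += 1
            if gen < burnin and (gen + 1) % 200 == 0:
                rate = acc_window / 200.0
                if rate < 0.2:
                    scale *= 0.8
                elif rate > 0.4:
                    scale *= 1.25
                acc_window = 0
            if gen >= burnin and (gen - burnin) % thinning == 0:
                lab = partitions[t_idx]
                co += lab[:, None] == lab[None, :]
                n_samples += 1
                rows.append((state[0], state[1], state[2], state[3], profs[t_idx].threshold))

    if accepted_total == 0:
        raise RuntimeError(
            f"MCMC accepted no proposals ({proposed_total} proposed); "
            "check priors/starting state"
        )
    C = pd.DataFrame(co / n_samples, index=labels, columns=labels)
    samples = pd.DataFrame(rows, columns=["lam1", "p1", "lam2", "p2", "threshold"])
    settings = {
        "generations": generations,
        "burnin": burnin,
        "thinning": thinning,
        "n_trees": len(trees),
        "seed": seed,
    }
    return BGMYCResult(C, samples, settings, accepted_total / proposed_total)


def consensus_clusters(C: pd.DataFrame, cutoff: float = 0.5) -> pd.Series:
    """Lineages = connected components of the conspecificity graph at ``cutoff``."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    adj = sparse.csr_matrix((C.to_numpy() >= cutoff).astype(int))
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    return pd.Series(labels, index=C.index, name="lineage")
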