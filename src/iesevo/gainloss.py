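"""Two-rate presence/absence continuous-time Markov model on fixed gene trees.

The model is the classic binary-character CTMC used for gain/loss of
germline-limited elements: one rate of gain ``g`` (absent -> present, per
unit branch length) and one rate of loss ``l`` (present -> absent), shared
by all loci of a gene family.  Priors follow a hierarchical exponential:
g, l ~ Exp(alpha) with alpha ~ Exp(1).  Inference is Metropolis-within-
Gibbs (multiplicative proposals for g and l tuned during an initial phase;
alpha Gibbs-sampled exactly from its Gamma full conditional), and marginal
ancestral posteriors are obtained by two-pass (up-down) message passing
averaged over retained MCMC samples.

State order throughout: index 0 = absent, index 1 = present.
Tip observations: 0, 1, or -1 for uncertain (partial likelihood (1, 1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trees import Tree

ABSENT, PRESENT, UNCERTAIN = 0, 1, -1


def transition_matrix(g: float, l: float, t: float) -> np.ndarray:
    """2x2 transition probabilities of the gain/loss chain over time ``t``.

    P(absent->present) = g/(g+l) * (1 - exp(-(g+l) t)); rows sum to one;
    the degenerate g + l = 0 chain is the identity.
    """
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    rate = g + l
    if rate == 0.0:
        return np.eye(2)
    w = 1.0 - math.exp(-rate * t)
    p01 = g / rate * w
    p10 = l / rate * w
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def stationary_distribution(g: float, l: float) -> np.ndarray:
    if g + l == 0.0:
        return np.array([0.5, 0.5])
    return np.array([l / (g + l), g / (g + l)])


def _resolve_root_prior(root_prior, g: float, l: float) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            return stationary_distribution(g, l)
        if root_prior == "uniform":
            return np.array([0.5, 0.5])
        raise ValueError(f"unknown root prior {root_prior!r}")
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (2,) or prior.min() < 0 or not np.isclose(prior.sum(), 1.0):
        raise ValueError("root prior must be a length-2 distribution")
    return prior


def _tip_partials(tree: Tree, tip_states: dict[str, int | np.ndarray],
                  n_loci: int) -> dict[int, np.ndarray]:
    """Per-tip partial likelihood arrays of shape (n_loci, 2)."""
    partials = {}
    for leaf in tree.leaves():
        name = tree.nodes[leaf].name
        if name not in tip_states:
            raise ValueError(f"no observation for tip {name!r}")
        obs = np.atleast_1d(np.asarray(tip_states[name]))
        if obs.shape[0] != n_loci:
            raise ValueError(f"tip {name!r}: {obs.shape[0]} states for "
                             f"{n_loci} loci")
        part = np.ones((n_loci, 2))
        part[obs == ABSENT] = (1.0, 0.0)
        part[obs == PRESENT] = (0.0, 1.0)
        partials[leaf] = part
    return partials


def _get_kernels():
    """Compiled up/down passes (numba; compiled once per process)."""
    global _KERNELS
    if _KERNELS is not None:
        return _KERNELS
    from numba import njit

    @njit(cache=True)
    def up_pass(tip0, tip1, child, parent, p01, p10):
        up0 = tip0.copy()
        up1 = tip1.copy()
        E = child.shape[0]
        L = tip0.shape[1]
        msg0 = np.empty((E, L))
        msg1 = np.empty((E, L))
        for e in range(E):
            c = child[e]
            p = parent[e]
            a = p01[e]
            b = p10[e]
            for j in range(L):
                m0 = (1.0 - a) * up0[c, j] + a * up1[c, j]
                m1 = b * up0[c, j] + (1.0 - b) * up1[c, j]
                msg0[e, j] = m0
                msg1[e, j] = m1
                up0[p, j] *= m0
                up1[p, j] *= m1
        return up0, up1, msg0, msg1

    @njit(cache=True)
    def down_pass(root, prior0, prior1, child, parent, sib, p01, p10,
                  msg0, msg1, n_nodes):
        E = child.shape[0]
        L = msg0.shape[1]
        down0 = np.empty((n_nodes, L))
        down1 = np.empty((n_nodes, L))
        for j in range(L):
            down0[root, j] = prior0
            down1[root, j] = prior1
        for e in range(E - 1, -1, -1):
            c = child[e]
            p = parent[e]
            s = sib[e]
            a = p01[e]
            b = p10[e]
            for j in range(L):
                s0 = down0[p, j]
                s1 = down1[p, j]
                if s >= 0:
                    s0 *= msg0[s, j]
                    s1 *= msg1[s, j]
                down0[c, j] = s0 * (1.0 - a) + s1 * b
                down1[c, j] = s0 * a + s1 * (1.0 - b)
        return down0, down1

    _KERNELS = (up_pass, down_pass)
    return _KERNELS


_KERNELS = None


class _FastModel:
    """Tree flattened to postorder edge arrays for repeated likelihood and
    marginal evaluations at different (g, l) — the MCMC hot path.

    No per-node rescaling: two-state partials on trees of tens of tips
    stay far above the float64 underflow threshold.  The compiled down
    pass assumes binary nodes (sibling lookup); polytomies would need the
    reference implementation.
    """

    def __init__(self, tree: Tree, tip_states: dict):
        self.tree = tree
        order = list(tree.postorder())
        self.order = order
        self.index = {nid: i for i, nid in enumerate(order)}
        children = [[self.index[c] for c in tree.nodes[nid].children]
                    for nid in order]
        if any(len(ch) > 2 for ch in children):
            raise ValueError("gain/loss model requires binary trees")
        self.root = self.index[tree.root]
        # postorder edge arrays (edge e ends at child[e])
        edge_child, edge_parent, edge_len = [], [], []
        edge_of_child = {}
        for i, nid in enumerate(order):
            p = tree.nodes[nid].parent
            if p is None:
                continue
            edge_of_child[i] = len(edge_child)
            edge_child.append(i)
            edge_parent.append(self.index[p])
            edge_len.append(tree.nodes[nid].length)
        self.edge_child = np.array(edge_child, dtype=np.int64)
        self.edge_parent = np.array(edge_parent, dtype=np.int64)
        self.edge_len = np.array(edge_len)
        sib = np.full(len(edge_child), -1, dtype=np.int64)
        for ch in children:
            if len(ch) == 2:
                e0, e1 = edge_of_child[ch[0]], edge_of_child[ch[1]]
                sib[e0], sib[e1] = e1, e0
        self.edge_sib = sib
        n_loci = int(np.atleast_1d(
            np.asarray(next(iter(tip_states.values())))).shape[0])
        self.n_loci = n_loci
        partials = _tip_partials(tree, tip_states, n_loci)
        self.tip0 = np.ones((len(order), n_loci))
        self.tip1 = np.ones((len(order), n_loci))
        for leaf, part in partials.items():
            i = self.index[leaf]
            self.tip0[i] = part[:, 0]
            self.tip1[i] = part[:, 1]

    def _edge_probs(self, g: float, l: float):
        rate = g + l
        if rate == 0.0:
            z = np.zeros(len(self.edge_len))
            return z, z
        w = 1.0 - np.exp(-rate * self.edge_len)
        return (g / rate) * w, (l / rate) * w

    def _up(self, g: float, l: float):
        p01, p10 = self._edge_probs(g, l)
        up_pass, _ = _get_kernels()
        up0, up1, msg0, msg1 = up_pass(self.tip0, self.tip1,
                                       self.edge_child, self.edge_parent,
                                       p01, p10)
        return up0, up1, msg0, msg1, p01, p10

    def loglik(self, g: float, l: float, root_prior="stationary") -> float:
        prior = _resolve_root_prior(root_prior, g, l)
        up0, up1, *_ = self._up(g, l)
        lik = prior[0] * up0[self.root] + prior[1] * up1[self.root]
        if np.any(lik <= 0.0):
            return -np.inf
        return float(np.log(lik).sum())

    def marginals(self, g: float, l: float,
                  root_prior="stationary") -> dict[int, np.ndarray]:
        prior = _resolve_root_prior(root_prior, g, l)
        up0, up1, msg0, msg1, p01, p10 = self._up(g, l)
        _, down_pass = _get_kernels()
        down0, down1 = down_pass(self.root, prior[0], prior[1],
                                 self.edge_child, self.edge_parent,
                                 self.edge_sib, p01, p10, msg0, msg1,
                                 len(self.order))
        joint1 = up1 * down1
        total = up0 * down0 + joint1
        total[total == 0.0] = 1.0
        post = joint1 / total
        return {nid: post[self.index[nid]] for nid in self.order}


def pruning_loglik(tree: Tree, tip_states: dict, g: float, l: float,
                   root_prior="stationary") -> float:
    """Log-likelihood of all loci (summed) by Felsenstein pruning."""
    return _FastModel(tree, tip_states).loglik(g, l, root_prior)


def marginal_posteriors(tree: Tree, tip_states: dict, g: float, l: float,
                        root_prior="stationary") -> dict[int, np.ndarray]:
    """Per-node marginal probability of presence, shape (n_loci,) per node.

    Up-down message passing: the downward message at a node is the
    likelihood of everything outside its subtree; the marginal is the
    normalized elementwise product with the upward partial.
    """
    return _FastModel(tree, tip_states).marginals(g, l, root_prior)


# ----------------------------------------------------------------------
# MCMC

@dataclass
class McmcResult:
    samples: np.ndarray              # (n_kept, 3): g, l, alpha
    acceptance: dict[str, float]
    ess: dict[str, float]
    split_rhat: dict[str, float]
    posteriors: dict[int, np.ndarray] | None  # posterior-mean P(present)
    diagnostics: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.diagnostics


def _log_prior(g: float, l: float, alpha: float) -> float:
    if g < 0 or l < 0 or alpha <= 0:
        return -np.inf
    # g, l ~ Exp(alpha); alpha ~ Exp(1)
    return 2.0 * math.log(alpha) - alpha * (g + l) - alpha


def _ess(x: np.ndarray) -> float:
    import arviz
    return float(arviz.ess(np.asarray(x)[None, :]))


def _split_rhat(x: np.ndarray) -> float:
    import arviz
    half = len(x) // 2
    if half < 2:
        return float("nan")
    return float(arviz.rhat(np.stack([x[:half], x[half:2 * half]])))


def mcmc_sample(matrix, tree: Tree, n_iter: int = 500_000,
                tuning_iter: int = 10_000, tuning_interval: int = 1_000,
                seed: int = 0, thin: int = 50, burnin_frac: float = 0.10,
                root_prior="stationary", prior_only: bool = False,
                compute_posteriors: bool = True) -> McmcResult:
    """Sample (g, l, alpha) and posterior-mean ancestral states.

    ``matrix`` maps tip name -> per-locus observed states (0/1/-1), the
    per-family presence/absence matrix.  Proposals for g and l are
    multiplicative (log-normal) with step sizes tuned toward 20-50%
    acceptance during the initial ``tuning_iter`` iterations only; alpha
    is Gibbs-drawn from its exact Gamma(3, 1 + g + l) full conditional.
    """
    rng = np.random.default_rng(seed)
    model = None if prior_only else _FastModel(tree, matrix)

    def loglik(g, l):
        if prior_only:
            return 0.0
        return model.loglik(g, l, root_prior)

    # crude data-driven start: fraction of present entries
    obs = np.concatenate([np.atleast_1d(np.asarray(v)) for v in matrix.values()])
    frac = float(np.mean(obs[obs != UNCERTAIN] == PRESENT)) if np.any(obs != UNCERTAIN) else 0.5
    frac = min(max(frac, 0.02), 0.98)
    g, l = max(frac, 0.05), max(1.0 - frac, 0.05)
    alpha = 1.0
    ll = loglik(g, l)
    if not np.isfinite(ll):
        raise RuntimeError("cannot compute a starting probability; family skipped")

    steps = {"g": 0.5, "l": 0.5}
    accepted = {"g": 0, "l": 0}
    proposed = {"g": 0, "l": 0}
    window_acc = {"g": 0, "l": 0}
    window_n = {"g": 0, "l": 0}

    kept = []
    post_sum: dict[int, np.ndarray] | None = None
    n_post = 0
    burnin = int(burnin_frac * n_iter)

    total = tuning_iter + n_iter
    for it in range(total):
        tuning = it < tuning_iter
        for name in ("g", "l"):
            cur = g if name == "g" else l
            prop = cur * math.exp(steps[name] * rng.normal())
            g2, l2 = (prop, l) if name == "g" else (g, prop)
            ll2 = loglik(g2, l2)
            # Hastings ratio of the multiplicative proposal is prop/cur
            logr = (ll2 + _log_prior(g2, l2, alpha)
                    - ll - _log_prior(g, l, alpha)
                    + math.log(prop / cur))
            proposed[name] += 1
            window_n[name] += 1
            if math.log(rng.uniform()) < logr:
                g, l, ll = g2, l2, ll2
                accepted[name] += 1
                window_acc[name] += 1
        # exact Gibbs step for the hyperparameter
        alpha = rng.gamma(3.0, 1.0 / (1.0 + g + l))

        if tuning and (it + 1) % tuning_interval == 0:
            for name in ("g", "l"):
                rate = window_acc[name] / max(window_n[name], 1)
                if rate < 0.20:
                    steps[name] *= 0.7
                elif rate > 0.50:
                    steps[name] *= 1.4
                window_acc[name] = window_n[name] = 0

        post_it = it - tuning_iter
        if post_it >= burnin and (post_it - burnin) % thin == 0:
            kept.append((g, l, alpha))
            if compute_posteriors and not prior_only:
                post = model.marginals(g, l, root_prior)
                if post_sum is None:
                    post_sum = {k: v.copy() for k, v in post.items()}
                else:
                    for k, v in post.items():
                        post_sum[k] += v
                n_post += 1

    samples = np.array(kept)
    diagnostics = []
    ess, rhat = {}, {}
    for idx, name in enumerate(("g", "l", "alpha")):
        x = samples[:, idx]
        if np.var(x) == 0.0:
            diagnostics.append(f"zero-variance chain for {name}")
            ess[name], rhat[name] = 0.0, float("inf")
        else:
            ess[name] = _ess(x)
            rhat[name] = _split_rhat(x)

    posteriors = None
    if post_sum is not None and n_post:
        posteriors = {k: v / n_post for k, v in post_sum.items()}

    acc = {k: accepted[k] / max(proposed[k], 1) for k in accepted}
    return McmcResult(samples, acc, ess, rhat, posteriors, diagnostics)
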