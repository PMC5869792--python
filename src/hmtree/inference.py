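"""Exact belief propagation on the tree and maximum-likelihood estimation.

The upward-downward algorithm is the tree analogue of forward-backward for
hidden Markov chains, in its scaled (numerically stable) formulation: the
upward pass produces, per node, the normalized quantity
``τ_i(k) = P(S_i = k | subtree p-values)`` together with a normalizer N_i
whose logs sum to the log-likelihood; the downward pass produces the
complementary-evidence ratio κ_i(k), and the smoothed posterior is the
product τ_i(k)·κ_i(k).

Maximum-likelihood estimation is EM (a tree Baum-Welch): the E-step reads
the needed expectations directly off the τ/κ quantities; the M-step updates
π and ω in closed form and the two emission blocks by bounded numerical
maximization of their weighted log-likelihoods.  Because the likelihood is
multimodal, fitting runs plain EM from many random starts plus one
deterministic-annealing run (responsibilities from emission densities raised
to an inverse temperature that is stepped up to 1), keeping whichever ends
with the larger likelihood.

All passes are vectorized over the nodes of a depth level, so a full sweep
costs O(N_T) with small constants even on ontology-scale trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy import optimize, special

from .errors import InputError, NumericalError
from .go_graph import GoTree
from .model import HmtmParams, clip_pvalues, emission_matrix, validate_params

logger = logging.getLogger(__name__)

__all__ = [
    "Beliefs",
    "EStepStats",
    "EmConfig",
    "FitResult",
    "marginal_state_probs",
    "upward_pass",
    "downward_pass",
    "posterior_beliefs",
    "e_step",
    "m_step",
    "fit_em",
    "read_pvalue_tsv",
    "write_beliefs_tsv",
]

# optimizer boxes are inset from the open parameter bounds
_BOX_EPS = 1e-6
_SHAPE_MAX = 1e6


@dataclass
class Beliefs:
    """Per-node belief-propagation quantities for a fixed θ.

    Arrays are (N_T, 2) with column k the state; ``tau_edge`` row i holds
    τ_{ρ(i),i}(k) (the root row is unused).  ``posterior`` is the smoothed
    marginal P(S_i = k | all p-values); ``loglik`` = Σ_i log N_i.
    """

    prior: np.ndarray
    tau: np.ndarray
    tau_edge: np.ndarray
    norm: np.ndarray
    loglik: float
    kappa: np.ndarray | None = None
    posterior: np.ndarray | None = None


@dataclass
class EStepStats:
    """Conditional expectations needed by the M-step.

    ``w[i]`` = E(S_i | p, θ); ``e11[i]``/``e10[i]`` = E[I(S_ρ(i)=1, S_i=k)]
    for non-root i (index 0 unused); ``p11``/``p10`` are their totals.
    """

    w: np.ndarray
    e11: np.ndarray
    e10: np.ndarray
    p11: float
    p10: float


@dataclass
class RestartRecord:
    index: int
    kind: str  # "em" or "da"
    theta0: HmtmParams
    theta: HmtmParams
    loglik: float
    converged: bool
    n_iter: int
    fallback_blocks: int = 0


@dataclass
class EmConfig:
    """Fitting configuration; ``seed`` drives every random draw."""

    seed: int
    n_restarts: int = 20
    max_iter: int = 500
    tol: float = 1e-8
    param_tol: float = 1e-6
    annealing_ladder: tuple[float, ...] = (0.1, 0.3, 0.5, 0.8, 1.0)
    da_iters_per_rung: int = 25


@dataclass
class FitResult:
    theta: HmtmParams
    loglik: float
    trace: list[float]
    restarts: list[RestartRecord]
    best_index: int
    converged: bool
    flat_likelihood: bool = False


# ---------------------------------------------------------------------------
# belief propagation


def marginal_state_probs(tree: GoTree, pi: float, omega: float) -> np.ndarray:
    """Prior state marginals P(S_i = k): the root is DE with probability π
    and persistence decays it down the tree, P(S_i = 1) = π·ω^depth(i)."""
    p1 = pi * np.power(omega, tree.depth.astype(float))
    if np.any(p1 < 1e-300):
        raise NumericalError(
            "prior P(S_i=1) underflowed; the tree is too deep for the "
            "current ω — consider collapsing chains or bounding depth"
        )
    return np.column_stack([1.0 - p1, p1])


def upward_pass(
    tree: GoTree,
    pvals: np.ndarray,
    theta: HmtmParams,
    temper: float = 1.0,
) -> Beliefs:
    """Leaves-to-root recursion producing τ, edge τ, normalizers, and the
    log-likelihood.  ``temper`` raises the emission densities to an inverse
    temperature (1 = the true likelihood), used by annealed EM."""
    n = tree.n_nodes
    pvals = clip_pvalues(pvals)
    if pvals.shape != (n,):
        raise InputError(f"expected {n} p-values, got shape {pvals.shape}")
    prior = marginal_state_probs(tree, theta.pi, theta.omega)
    e = emission_matrix(pvals, theta)
    if temper != 1.0:
        e = e**temper
    omega = theta.omega

    tau = np.zeros((n, 2))
    tau_edge = np.zeros((n, 2))
    norm = np.zeros(n)
    child_prod = np.ones((n, 2))  # running ∏_ν τ_{i,ν}(k)

    for level in reversed(tree.levels()):
        unnorm = e[level] * prior[level] * child_prod[level]
        n_level = unnorm.sum(axis=1)
        if not np.all(np.isfinite(n_level)) or np.any(n_level <= 0.0):
            bad = level[~(np.isfinite(n_level) & (n_level > 0.0))][0]
            raise NumericalError(f"non-finite normalizer at node {tree.ids[bad]!r}")
        norm[level] = n_level
        tau[level] = unnorm / n_level[:, None]
        nonroot = level[level != 0]
        if nonroot.size:
            r0 = tau[nonroot, 0] / prior[nonroot, 0]
            r1 = tau[nonroot, 1] / prior[nonroot, 1]
            # τ_{ρ(i),i}(k) = Σ_j τ_i(j) q_{kj} / P(S_i=j) with q01 = 0
            tau_edge[nonroot, 0] = r0
            tau_edge[nonroot, 1] = (1.0 - omega) * r0 + omega * r1
            np.multiply.at(child_prod[:, 0], tree.parent[nonroot], tau_edge[nonroot, 0])
            np.multiply.at(child_prod[:, 1], tree.parent[nonroot], tau_edge[nonroot, 1])

    return Beliefs(
        prior=prior,
        tau=tau,
        tau_edge=tau_edge,
        norm=norm,
        loglik=float(np.sum(np.log(norm))),
    )


def _guarded_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    """num/den treating 0/0 as 0 (the impossible-state case under q01 = 0);
    x/0 with x > 0 is a genuine numerical failure."""
    zero = den == 0.0
    if np.any(zero & (num != 0.0)):
        raise NumericalError(f"division by zero in {what}")
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~zero)
    return out


def downward_pass(tree: GoTree, beliefs: Beliefs, theta: HmtmParams) -> Beliefs:
    """Root-to-leaves recursion filling κ and the smoothed posteriors
    P(S_i = k | p) = τ_i(k)·κ_i(k)."""
    n = tree.n_nodes
    omega = theta.omega
    kappa = np.zeros((n, 2))
    kappa[0] = 1.0
    tau, tau_edge, prior = beliefs.tau, beliefs.tau_edge, beliefs.prior
    for level in tree.levels()[1:]:
        par = tree.parent[level]
        m = tau[par] * kappa[par]
        t0 = _guarded_ratio(m[:, 0], tau_edge[level, 0], "kappa recursion (state 0)")
        t1 = _guarded_ratio(m[:, 1], tau_edge[level, 1], "kappa recursion (state 1)")
        kappa[level, 0] = (t0 + (1.0 - omega) * t1) / prior[level, 0]
        kappa[level, 1] = omega * t1 / prior[level, 1]
    beliefs.kappa = kappa
    beliefs.posterior = tau * kappa
    return beliefs


def posterior_beliefs(
    tree: GoTree, pvals: np.ndarray, theta: HmtmParams, temper: float = 1.0
) -> Beliefs:
    """Full upward+downward sweep for a fixed θ."""
    return downward_pass(tree, upward_pass(tree, pvals, theta, temper), theta)


# ---------------------------------------------------------------------------
# EM


def e_step(tree: GoTree, beliefs: Beliefs, theta: HmtmParams) -> EStepStats:
    """Read the M-step expectations off the belief quantities."""
    if beliefs.posterior is None:
        raise InputError("downward_pass must run before e_step")
    n = tree.n_nodes
    w = beliefs.posterior[:, 1]
    e11 = np.zeros(n)
    e10 = np.zeros(n)
    if n > 1:
        i = np.arange(1, n)
        par = tree.parent[i]
        denom = beliefs.tau_edge[i, 1]
        e11[i] = _guarded_ratio(
            beliefs.tau[i, 1] * theta.omega * w[par],
            beliefs.prior[i, 1] * denom,
            "E-step joint expectation (1,1)",
        )
        e10[i] = _guarded_ratio(
            beliefs.tau[i, 0] * (1.0 - theta.omega) * w[par],
            beliefs.prior[i, 0] * denom,
            "E-step joint expectation (1,0)",
        )
        both = np.concatenate([e11[i], e10[i]])
        if np.any(both < -1e-10) or np.any(both > 1.0 + 1e-10):
            raise NumericalError("E-step expectation outside [0, 1]")
        np.clip(e11, 0.0, 1.0, out=e11)
        np.clip(e10, 0.0, 1.0, out=e10)
    return EStepStats(
        w=w, e11=e11, e10=e10, p11=float(e11.sum()), p10=float(e10.sum())
    )


def _fit_alt_block(
    pvals: np.ndarray, w: np.ndarray, alpha: float, beta: float
) -> tuple[float, float, bool]:
    """Maximize Σ w_i log beta(p_i; α, β) over α ∈ (0,1], β ∈ (1,∞).

    The weighted beta log-likelihood depends on the data only through
    Σ w log p and Σ w log(1−p), so each objective evaluation is O(1)."""
    total = float(w.sum())
    if total <= 0.0:
        return alpha, beta, False
    a_stat = float(np.dot(w, np.log(pvals)))
    b_stat = float(np.dot(w, np.log1p(-pvals)))

    def nll(x):
        a, b = x
        return -((a - 1.0) * a_stat + (b - 1.0) * b_stat - total * special.betaln(a, b))

    def grad(x):
        a, b = x
        dab = special.digamma(a + b)
        return np.array(
            [
                -(a_stat - total * (special.digamma(a) - dab)),
                -(b_stat - total * (special.digamma(b) - dab)),
            ]
        )

    x0 = np.array([alpha, beta])
    res = optimize.minimize(
        nll,
        x0,
        jac=grad,
        method="L-BFGS-B",
        bounds=[(_BOX_EPS, 1.0), (1.0 + _BOX_EPS, _SHAPE_MAX)],
    )
    if np.isfinite(res.fun) and res.fun <= nll(x0) + 1e-9:
        return float(res.x[0]), float(res.x[1]), True
    return alpha, beta, False


def _fit_null_block(
    pvals: np.ndarray,
    v: np.ndarray,
    lam: float,
    alpha0: float,
    beta0: float,
) -> tuple[float, float, float, bool]:
    """Maximize Σ v_i log[λ + (1−λ)·beta(p_i; α0, β0)] over the null box."""
    if float(v.sum()) <= 0.0:
        return lam, alpha0, beta0, False
    logp = np.log(pvals)
    log1mp = np.log1p(-pvals)

    def nll(x):
        lm, a0, b0 = x
        comp = np.exp((a0 - 1.0) * logp + (b0 - 1.0) * log1mp - special.betaln(a0, b0))
        dens = lm + (1.0 - lm) * comp
        if np.any(dens <= 0.0) or not np.all(np.isfinite(dens)):
            return 1e12  # finite penalty keeps numerical gradients usable
        return -float(np.dot(v, np.log(dens)))

    x0 = np.array([lam, alpha0, beta0])
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[
            (0.0, 1.0),
            (1.0 + _BOX_EPS, _SHAPE_MAX),
            (1.0 + _BOX_EPS, _SHAPE_MAX),
        ],
    )
    if np.isfinite(res.fun) and res.fun <= nll(x0) + 1e-9:
        return float(res.x[0]), float(res.x[1]), float(res.x[2]), True
    return lam, alpha0, beta0, False


def m_step(
    stats: EStepStats, pvals: np.ndarray, theta_t: HmtmParams
) -> tuple[HmtmParams, int]:
    """Closed-form updates for π, ω and bounded numerical maximization for
    the two emission blocks.  Returns the new θ and the number of emission
    blocks that fell back to their previous values (optimizer failure)."""
    pvals = clip_pvalues(pvals)
    pi = float(np.clip(stats.w[0], _BOX_EPS, 1.0 - _BOX_EPS))
    denom = stats.p11 + stats.p10
    if denom > 0.0:
        omega = float(np.clip(stats.p11 / denom, _BOX_EPS, 1.0 - _BOX_EPS))
    else:
        omega = theta_t.omega
    fallbacks = 0
    alpha, beta, ok = _fit_alt_block(pvals, stats.w, theta_t.alpha, theta_t.beta)
    fallbacks += not ok
    lam, alpha0, beta0, ok = _fit_null_block(
        pvals, 1.0 - stats.w, theta_t.lam, theta_t.alpha0, theta_t.beta0
    )
    fallbacks += not ok
    theta = HmtmParams(
        pi=pi, omega=omega, alpha=alpha, beta=beta, lam=lam, alpha0=alpha0, beta0=beta0
    )
    return validate_params(theta), fallbacks


def _param_vector(theta: HmtmParams) -> np.ndarray:
    return np.array(
        [theta.pi, theta.omega, theta.alpha, theta.beta, theta.lam, theta.alpha0, theta.beta0]
    )


def _em_iterations(
    tree: GoTree,
    pvals: np.ndarray,
    theta: HmtmParams,
    max_iter: int,
    tol: float,
    param_tol: float,
    temper: float = 1.0,
) -> tuple[HmtmParams, list[float], bool, int]:
    """Iterate E/M until the relative log-likelihood change drops below tol
    or parameters stop moving.  Returns (θ, trace, converged, fallbacks)."""
    trace: list[float] = []
    converged = False
    fallbacks = 0
    for it in range(max_iter):
        beliefs = posterior_beliefs(tree, pvals, theta, temper)
        trace.append(beliefs.loglik)
        stats = e_step(tree, beliefs, theta)
        theta_new, fb = m_step(stats, pvals, theta)
        fallbacks += fb
        if it > 0:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0)
            dpar = np.max(np.abs(_param_vector(theta_new) - _param_vector(theta)))
            if rel < tol or dpar < param_tol:
                converged = True
                theta = theta_new
                break
        theta = theta_new
    return theta, trace, converged, fallbacks


def _draw_initial(rng: np.random.Generator) -> HmtmParams:
    """Random starting point covering the plausible parameter region."""
    return HmtmParams(
        pi=rng.uniform(0.05, 0.95),
        omega=rng.uniform(0.05, 0.95),
        alpha=rng.uniform(0.1, 1.0),
        beta=rng.uniform(1.5, 20.0),
        lam=rng.uniform(0.5, 1.0),
        alpha0=rng.uniform(1.1, 5.0),
        beta0=rng.uniform(1.1, 5.0),
    )


def fit_em(tree: GoTree, pvals: np.ndarray, config: EmConfig) -> FitResult:
    """Maximum-likelihood fit: plain EM from ``n_restarts`` random starting
    points plus one deterministic-annealing run, keeping the run with the
    largest final log-likelihood."""
    pvals = clip_pvalues(np.asarray(pvals, dtype=float))
    rng = np.random.default_rng(config.seed)
    records: list[RestartRecord] = []
    traces: list[list[float]] = []

    for r in range(config.n_restarts):
        theta0 = _draw_initial(rng)
        theta, trace, conv, fb = _em_iterations(
            tree, pvals, theta0, config.max_iter, config.tol, config.param_tol
        )
        final_ll = upward_pass(tree, pvals, theta).loglik
        records.append(
            RestartRecord(r, "em", theta0, theta, final_ll, conv, len(trace), fb)
        )
        traces.append(trace)

    # deterministic annealing: flatten the objective early, then cool to 1
    theta0 = _draw_initial(rng)
    theta = theta0
    fb_total = 0
    for temper in config.annealing_ladder:
        if temper >= 1.0:
            break
        theta, _, _, fb = _em_iterations(
            tree,
            pvals,
            theta,
            config.da_iters_per_rung,
            max(config.tol, 1e-6),
            config.param_tol,
            temper=temper,
        )
        fb_total += fb
    theta, trace, conv, fb = _em_iterations(
        tree, pvals, theta, config.max_iter, config.tol, config.param_tol
    )
    final_ll = upward_pass(tree, pvals, theta).loglik
    records.append(
        RestartRecord(
            len(records), "da", theta0, theta, final_ll, conv, len(trace), fb_total + fb
        )
    )
    traces.append(trace)

    logliks = np.array([rec.loglik for rec in records])
    best = int(np.argmax(logliks))
    if not any(rec.converged for rec in records):
        logger.warning("no EM run converged; returning best non-converged fit")

    # a flat likelihood (e.g. uninformative emissions) shows up as runs that
    # agree on the likelihood while disagreeing on the parameters
    span = float(logliks.max() - logliks.min())
    spread = float(
        np.max(
            np.abs(
                np.array([_param_vector(rec.theta)[:2] for rec in records])
                - _param_vector(records[best].theta)[:2]
            )
        )
    )
    flat = bool(len(records) > 1 and span < 1e-6 and spread > 0.1)
    if flat:
        logger.warning(
            "likelihood is flat across restarts while (pi, omega) differ; "
            "the model may be unidentifiable on these p-values"
        )

    return FitResult(
        theta=records[best].theta,
        loglik=records[best].loglik,
        trace=traces[best],
        restarts=records,
        best_index=best,
        converged=records[best].converged,
        flat_likelihood=flat,
    )


# ---------------------------------------------------------------------------
# I/O


def read_pvalue_tsv(path: str | Path, tree: GoTree) -> np.ndarray:
    """Read `node_id<TAB>p_value` rows and align them with tree positions."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"p-value file not found: {path}")
    values: dict[str, float] = {}
    with open(path) as fh:
        fh.readline()
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            node, raw = parts
            try:
                p = float(raw)
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: bad p-value {raw!r}") from exc
            if not (np.isfinite(p) and 0.0 <= p <= 1.0):
                raise InputError(f"{path}:{ln}: p-value {p!r} outside [0, 1]")
            values[node] = p
    missing = [t for t in tree.ids if t not in values]
    if missing:
        raise InputError(f"p-values missing for {len(missing)} tree nodes, "
                         f"e.g. {missing[:5]}")
    return clip_pvalues(np.array([values[t] for t in tree.ids]))


def write_beliefs_tsv(path: str | Path, tree: GoTree, beliefs: Beliefs) -> None:
    """Write `node_id, tau1, kappa1, posterior1` for every tree node."""
    if beliefs.posterior is None or beliefs.kappa is None:
        raise InputError("beliefs must include the downward pass")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("node_id\ttau1\tkappa1\tposterior1\n")
        for i, node in enumerate(tree.ids):
            fh.write(
                f"{node}\t{beliefs.tau[i, 1]:.12g}\t{beliefs.kappa[i, 1]:.12g}"
                f"\t{beliefs.posterior[i, 1]:.12g}\n"
            )
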