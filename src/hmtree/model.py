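"""Model parameters and p-value emission densities.

Hidden states live on the tree nodes: state 1 means the node's gene set is
differentially expressed (DE), state 0 means it is null.  The transition
structure encodes the logical constraint that a null parent forces null
children (q00 = 1, q01 = 0) while a DE parent passes state 1 on with
persistence probability ω.  The root is DE with probability π.

Emissions are densities on the unit interval: a DE node's p-value follows
beta(α, β) with α ≤ 1 < β, hence a strictly decreasing density; a null
node's p-value follows λ·U(0,1) + (1−λ)·beta(α0, β0) with α0, β0 > 1 — an
"empirical null" whose unimodal beta component absorbs mild deviations from
uniformity caused by gene-set overlap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import special

from .errors import ParameterError

__all__ = [
    "HmtmParams",
    "validate_params",
    "null_density",
    "alt_density",
    "log_emission",
    "clip_pvalues",
    "P_EPS",
]

# beta densities with a shape below 1 diverge at the boundary; external
# tests can emit exact 0/1, so p-values are clipped to the interior
P_EPS = 1e-15


@dataclass(frozen=True)
class HmtmParams:
    """θ = {π, ω, α, β, λ, α0, β0}, the full parameter vector."""

    pi: float
    omega: float
    alpha: float
    beta: float
    lam: float
    alpha0: float
    beta0: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HmtmParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    @property
    def transition_matrix(self) -> np.ndarray:
        """q[j, k] = P(child state k | parent state j)."""
        return np.array([[1.0, 0.0], [1.0 - self.omega, self.omega]])


def validate_params(theta: HmtmParams) -> HmtmParams:
    """Check every parameter bound; raise :class:`ParameterError` naming the
    offending field, otherwise return theta unchanged."""
    checks = [
        ("pi", 0.0 < theta.pi < 1.0, "pi must be in (0, 1)"),
        ("omega", 0.0 < theta.omega < 1.0, "omega must be in (0, 1)"),
        ("alpha", 0.0 < theta.alpha <= 1.0, "alpha must be in (0, 1]"),
        ("beta", theta.beta > 1.0, "beta must be > 1"),
        ("lam", 0.0 <= theta.lam <= 1.0, "lam must be in [0, 1]"),
        ("alpha0", theta.alpha0 > 1.0, "alpha0 must be > 1"),
        ("beta0", theta.beta0 > 1.0, "beta0 must be > 1"),
    ]
    for name, ok, msg in checks:
        value = getattr(theta, name)
        if not (ok and np.isfinite(value)):
            raise ParameterError(f"{msg} (got {name}={value!r})")
    return theta


def clip_pvalues(p: np.ndarray | float) -> np.ndarray:
    """Clip p-values into [P_EPS, 1 - P_EPS]."""
    return np.clip(np.asarray(p, dtype=float), P_EPS, 1.0 - P_EPS)


def _beta_pdf(p: np.ndarray, a: float, b: float) -> np.ndarray:
    logpdf = (a - 1.0) * np.log(p) + (b - 1.0) * np.log1p(-p) - special.betaln(a, b)
    return np.exp(logpdf)


def null_density(p, lam: float, alpha0: float, beta0: float):
    """Null emission f0(p) = λ + (1−λ)·beta(p; α0, β0)."""
    p = clip_pvalues(p)
    return lam + (1.0 - lam) * _beta_pdf(p, alpha0, beta0)


def alt_density(p, alpha: float, beta: float):
    """Alternative emission f1(p) = beta(p; α, β), decreasing for α ≤ 1 < β."""
    p = clip_pvalues(p)
    return _beta_pdf(p, alpha, beta)


def emission_matrix(p: np.ndarray, theta: HmtmParams) -> np.ndarray:
    """(n, 2) array of emission densities: column k is f(p | S = k)."""
    p = clip_pvalues(p)
    return np.column_stack(
        [
            null_density(p, theta.lam, theta.alpha0, theta.beta0),
            alt_density(p, theta.alpha, theta.beta),
        ]
    )


def log_emission(p, state: int, theta: HmtmParams):
    """Log emission density for a node in the given state (diagnostics and
    the brute-force oracle; the recursions use normalized quantities)."""
    if state == 0:
        return np.log(null_density(p, theta.lam, theta.alpha0, theta.beta0))
    if state == 1:
        return np.log(alt_density(p, theta.alpha, theta.beta))
    raise ParameterError(f"state must be 0 or 1, got {state!r}")
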