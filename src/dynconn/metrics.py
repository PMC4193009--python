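"""Network-, node- and edge-level descriptive measures.

Three measures summarize a condition-mean connectivity matrix:

* integration — overall statistical dependence of the network,
  I = -1/2 log det(R) for the correlation matrix R (Marrelec's measure,
  non-negative, in nats).  The sign-flipped "literal" variant
  +1/2 log det(M) is kept as an option.
* node strength — the sum of (signed) edge weights incident to a node.
* weighted clustering coefficient — mean triangle intensity around a node,
  cube-root-product form, with weights scaled to [0, 1]; the denominator
  uses the binary degree (the cited toolbox convention) by default, with
  the strength-based literal reading available.

Graph weights derive from a Fisher-z condition matrix by the tanh
back-transform: signed tanh(z) for strength, |tanh(z)| for clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .glasso import ConditionMatrix

__all__ = [
    "MetricSet",
    "integration",
    "node_strength",
    "clustering_coefficient",
    "network_density",
    "condition_metrics",
]

log = logging.getLogger(__name__)

#: eigenvalue floor applied before a log-determinant
_PD_FLOOR = 1e-8


def _as_correlation(mat: np.ndarray, input_kind: str) -> np.ndarray:
    """Correlation-scale matrix from a covariance or Fisher-z matrix."""
    mat = np.asarray(mat, dtype=float)
    if input_kind == "fisher_z":
        R = np.tanh(mat)
        np.fill_diagonal(R, 1.0)
        return R
    if input_kind == "covariance":
        d = np.sqrt(np.diag(mat))
        if np.any(d <= 0):
            raise ValueError("covariance has non-positive diagonal")
        return mat / np.outer(d, d)
    raise ValueError(f"unknown input_kind {input_kind!r}")


def _floored_logdet(mat: np.ndarray) -> float:
    evals = np.linalg.eigvalsh(mat)
    if evals[0] <= 0:
        log.warning(
            "matrix not PD (min eigenvalue %.3g); floored at %.1g",
            evals[0], _PD_FLOOR,
        )
        evals = np.maximum(evals, _PD_FLOOR)
    if not np.all(np.isfinite(np.log(evals))):
        raise ValueError("matrix singular even after eigenvalue repair")
    return float(np.sum(np.log(evals)))


def integration(
    mat: np.ndarray | ConditionMatrix,
    mode: str = "marrelec",
    input_kind: str | None = None,
) -> float:
    """Network integration in nats.

    ``mode='marrelec'`` (default): I = -1/2 log det(R) with R the
    correlation-scale matrix — zero for an empty network, growing with any
    statistical dependence.  ``mode='literal'``: I = +1/2 log det of the
    matrix as supplied (sign as printed in the source formula).
    ``input_kind`` is ``'fisher_z'`` or ``'covariance'``; a
    ConditionMatrix implies ``'fisher_z'``.
    """
    if isinstance(mat, ConditionMatrix):
        if input_kind not in (None, "fisher_z"):
            raise ValueError("ConditionMatrix input is always fisher_z")
        input_kind = "fisher_z"
        mat = mat.matrix
    if input_kind is None:
        input_kind = "covariance"
    if mode == "marrelec":
        R = _as_correlation(mat, input_kind)
        return -0.5 * _floored_logdet(R)
    if mode == "literal":
        A = _as_correlation(mat, input_kind) if input_kind == "fisher_z" else np.asarray(mat, float)
        return 0.5 * _floored_logdet(A)
    raise ValueError(f"unknown integration mode {mode!r}")


def node_strength(weights: np.ndarray) -> np.ndarray:
    """Row sums of the (signed) symmetric weight matrix, zero diagonal."""
    E = np.asarray(weights, dtype=float)
    if not np.allclose(E, E.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    E = E.copy()
    np.fill_diagonal(E, 0.0)
    return E.sum(axis=1)


def clustering_coefficient(
    weights: np.ndarray, degree_kind: str = "binary"
) -> np.ndarray:
    """Weighted clustering coefficient, cube-root-product form.

    Negative weights are set to zero (logged) and the remainder scaled by
    the maximum weight so all lie in [0, 1].  The numerator for node i sums
    (w_ij w_ih w_jh)^(1/3) over ordered pairs (j, h); the denominator is
    k_i (k_i - 1) with k_i the binary degree (``degree_kind='binary'``,
    the toolbox convention) or the strength of the normalized weights
    (``degree_kind='strength'``).  Nodes with binary degree < 2 get 0.
    """
    E = np.asarray(weights, dtype=float)
    if not np.allclose(E, E.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    W = E.copy()
    np.fill_diagonal(W, 0.0)
    n_neg = int(np.sum(W < 0))
    if n_neg:
        log.warning("clustering: %d negative weights set to 0", n_neg)
        W[W < 0] = 0.0
    top = W.max()
    if top > 0:
        W = W / top
    W13 = np.cbrt(W)
    numer = np.diag(W13 @ W13 @ W13)
    deg = (W > 0).sum(axis=1)
    if degree_kind == "binary":
        k = deg.astype(float)
    elif degree_kind == "strength":
        k = W.sum(axis=1)
    else:
        raise ValueError(f"unknown degree_kind {degree_kind!r}")
    denom = k * (k - 1)
    C = np.zeros(len(W))
    valid = (deg >= 2) & (denom > 0)
    C[valid] = numer[valid] / denom[valid]
    return C


def network_density(n_edges: int, n_nodes: int) -> float:
    """Fraction of node pairs carrying a (significant) connection."""
    if n_nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    return float(n_edges) / (n_nodes * (n_nodes - 1) / 2)


@dataclass
class MetricSet:
    """Per-subject, per-condition metric bundle."""

    subject_id: str
    condition: str
    integration: float
    strength: np.ndarray
    clustering: np.ndarray
    density: float | None = None


def condition_metrics(
    cm: ConditionMatrix,
    integration_mode: str = "marrelec",
    degree_kind: str = "binary",
) -> MetricSet:
    """All node/network metrics of one condition-mean matrix.

    Strength uses the signed tanh back-transform of the Fisher-z matrix;
    clustering uses its magnitude (so the coefficient stays in [0, 1]).
    """
    signed = np.tanh(cm.matrix)
    np.fill_diagonal(signed, 0.0)
    return MetricSet(
        subject_id=cm.subject_id,
        condition=cm.condition,
        integration=integration(cm, mode=integration_mode),
        strength=node_strength(signed),
        clustering=clustering_coefficient(np.abs(signed),
                                          degree_kind=degree_kind),
    )
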