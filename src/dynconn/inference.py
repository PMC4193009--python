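"""Nonparametric group inference for the paired four-condition design.

Small groups (six subjects per cohort) rule out asymptotics, so every test
here is exact or permutation-based:

* exact Wilcoxon signed-rank (full sign-assignment distribution, midrank
  ties) for network- and node-level paired comparisons;
* Benjamini-Hochberg step-up FDR over each comparison family;
* the network-based statistic (NBS) at the edge level: per-edge paired
  t-statistics, a primary threshold, connected supra-threshold components
  scored by extent, and family-wise error control by within-subject
  sign-flip permutation;
* inverse-Wishart posterior sampling of each subject's covariance for the
  group-level integration estimate (Jeffreys prior).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import integration

__all__ = [
    "WilcoxonResult",
    "FdrResult",
    "NbsResult",
    "IntegrationPosterior",
    "wilcoxon_signed_rank_exact",
    "fdr_bh",
    "nbs_paired",
    "nbs_one_sample",
    "bayesian_group_integration",
]

log = logging.getLogger(__name__)

#: largest n for which the exact sign-assignment distribution is used
EXACT_LIMIT = 20


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of positive-difference ranks)
    p_value: float
    n_used: int       # pairs remaining after zero-difference removal
    exact: bool


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all sign assignments.

    ``ranks2`` are the doubled midranks (integers).  Returns counts indexed
    by the doubled statistic; total mass is 2**n.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(
    a: np.ndarray, b: np.ndarray | None = None
) -> WilcoxonResult:
    """Two-sided exact Wilcoxon signed-rank test on paired data.

    Pass two aligned condition vectors, or a single difference vector.
    Zero differences are dropped (Wilcoxon convention); ties in |d| get
    midranks.  For n <= 20 the p-value enumerates all 2**n sign
    assignments: p = 2 * min(P(W+ >= obs), P(W+ <= obs)), capped at 1.
    Larger n falls back to the normal approximation.  All-zero differences
    give p = 1 with a warning; a single usable pair raises.
    """
    a = np.asarray(a, dtype=float)
    d = a - np.asarray(b, dtype=float) if b is not None else a
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all differences are zero; p = 1")
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, exact=True)
    if len(d) < 2:
        raise ValueError("need at least 2 nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n = len(d)
    if n <= EXACT_LIMIT:
        ranks2 = np.round(2 * ranks).astype(int)
        counts = _signed_rank_distribution(ranks2)
        total = counts.sum()
        obs2 = int(round(2 * w_pos))
        p_ge = counts[obs2:].sum() / total
        p_le = counts[: obs2 + 1].sum() / total
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(statistic=w_pos, p_value=p, n_used=n, exact=True)
    res = stats.wilcoxon(d, alternative="two-sided", method="approx")
    return WilcoxonResult(statistic=w_pos, p_value=float(res.pvalue),
                          n_used=n, exact=False)


@dataclass
class FdrResult:
    reject: np.ndarray           # mask at the requested q
    reject_lenient: np.ndarray   # mask at q = 0.1 (reported alongside)
    p_adjusted: np.ndarray
    q: float


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up over one comparison family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    reject_lenient = p_adj < 0.1
    return FdrResult(reject=reject, reject_lenient=reject_lenient,
                     p_adjusted=p_adj, q=q)


@dataclass
class NbsResult:
    """Connected supra-threshold components and their corrected p-values."""

    components: list[list[tuple[int, int]]]
    extents: list[int]
    p_fwe: list[float]
    null_max_extent: np.ndarray
    n_permutations: int
    threshold_t: float
    t_values: np.ndarray          # full symmetric edge t-matrix (nan where excluded)
    significant: list[bool] = field(default_factory=list)
    seed: int | None = None

    @property
    def significant_components(self) -> list[list[tuple[int, int]]]:
        return [c for c, s in zip(self.components, self.significant) if s]


def _edge_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t per edge column; nan where the difference variance is 0."""
    s_subj = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(s_subj))
    t[sd == 0] = np.nan
    return t


def _components_from_edges(
    edge_idx: np.ndarray, iu: tuple[np.ndarray, np.ndarray], n_nodes: int
) -> list[list[tuple[int, int]]]:
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for e in edge_idx:
        g.add_edge(int(iu[0][e]), int(iu[1][e]))
    comps = []
    for nodes in nx.connected_components(g):
        edges = [tuple(sorted(e)) for e in g.subgraph(nodes).edges]
        if edges:
            comps.append(sorted(edges))
    # deterministic order: largest first, then lexicographic
    comps.sort(key=lambda c: (-len(c), c))
    return comps


def _max_extent(mask: np.ndarray, iu, n_nodes: int) -> int:
    comps = _components_from_edges(np.flatnonzero(mask), iu, n_nodes)
    return max((len(c) for c in comps), default=0)


def _nbs_core(
    diffs_mat: np.ndarray,
    primary_p: float,
    n_perm: int,
    seed: int | None,
    alpha: float,
) -> NbsResult:
    s_subj, n_nodes, _ = diffs_mat.shape
    if s_subj < 2:
        raise ValueError("NBS needs at least 2 subjects")
    iu = np.triu_indices(n_nodes, k=1)
    D = diffs_mat[:, iu[0], iu[1]]  # (S, E)
    t_obs = _edge_t(D)
    n_excluded = int(np.sum(np.isnan(t_obs)))
    if n_excluded:
        log.info("NBS: %d edge(s) with zero difference variance excluded",
                 n_excluded)
    t_crit = float(stats.t.ppf(1 - primary_p / 2, df=s_subj - 1))
    supra = np.abs(np.nan_to_num(t_obs, nan=0.0)) > t_crit
    components = _components_from_edges(np.flatnonzero(supra), iu, n_nodes)
    extents = [len(c) for c in components]

    # null distribution of the maximal extent under within-subject sign flips
    full = 2**s_subj <= n_perm
    if full:
        signs_iter = itertools.product((1.0, -1.0), repeat=s_subj)
        sign_rows = [s for s in signs_iter if any(x < 0 for x in s)]
    else:
        rng = np.random.default_rng(seed)
        sign_rows = list(rng.choice([1.0, -1.0], size=(n_perm - 1, s_subj)))
    null = np.empty(len(sign_rows))
    for i, s in enumerate(sign_rows):
        t_perm = _edge_t(np.asarray(s)[:, None] * D)
        mask = np.abs(np.nan_to_num(t_perm, nan=0.0)) > t_crit
        null[i] = _max_extent(mask, iu, n_nodes)
    n_draws = len(sign_rows) + 1  # identity flip always included
    p_fwe = [
        float((1 + np.sum(null >= ext)) / n_draws) for ext in extents
    ]
    t_full = np.full((n_nodes, n_nodes), np.nan)
    t_full[iu] = t_obs
    t_full.T[iu] = t_obs
    return NbsResult(
        components=components,
        extents=extents,
        p_fwe=p_fwe,
        null_max_extent=null,
        n_permutations=n_draws,
        threshold_t=t_crit,
        t_values=t_full,
        significant=[p < alpha for p in p_fwe],
        seed=seed,
    )


def nbs_paired(
    mats_a: list[np.ndarray] | np.ndarray,
    mats_b: list[np.ndarray] | np.ndarray,
    primary_p: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> NbsResult:
    """Network-based statistic for two paired conditions.

    Per-edge paired t-statistics on the within-subject differences are
    thresholded two-sided at ``primary_p`` (df = S - 1); connected
    components of the supra-threshold graph are scored by extent (edge
    count).  The null permutes condition labels within subject (sign flips
    of the differences): all 2**S patterns when 2**S <= n_perm, otherwise
    ``n_perm`` random draws with the identity always included.  The
    corrected p of a component is
    (1 + #{null max extent >= observed}) / (1 + #draws).
    """
    A = np.asarray(mats_a, dtype=float)
    B = np.asarray(mats_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("condition matrix stacks must have equal shape")
    _check_stack(A)
    return _nbs_core(A - B, primary_p, n_perm, seed, alpha)


def nbs_one_sample(
    mats: list[np.ndarray] | np.ndarray,
    primary_p: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> NbsResult:
    """One-sample NBS against zero (which edges are present per condition)."""
    A = np.asarray(mats, dtype=float)
    _check_stack(A)
    return _nbs_core(A, primary_p, n_perm, seed, alpha)


def _check_stack(A: np.ndarray) -> None:
    if A.ndim != 3 or A.shape[1] != A.shape[2]:
        raise ValueError("expected a stack of square matrices (S, N, N)")
    if not np.allclose(A, np.transpose(A, (0, 2, 1)), atol=1e-8):
        raise ValueError("condition matrices must be symmetric")


@dataclass
class IntegrationPosterior:
    """Posterior draws of group-mean network integration."""

    samples: np.ndarray
    mean: float
    sd: float


def bayesian_group_integration(
    subject_covariances: list[np.ndarray],
    observations_per_subject: int | list[int],
    n_samples: int = 1000,
    seed: int | None = None,
) -> IntegrationPosterior:
    """Posterior of the group-mean integration by numerical sampling.

    Each subject's covariance is drawn from its inverse-Wishart posterior
    under the Jeffreys prior — IW(df = n, scale = n * S_hat) for n
    observations and plug-in covariance S_hat — the Marrelec integration
    is computed per draw, and draws are averaged across subjects.  Raises
    when any subject's n is not above N + 1 (improper posterior scale).
    """
    covs = [np.asarray(c, dtype=float) for c in subject_covariances]
    if not covs:
        raise ValueError("need at least one subject covariance")
    p = covs[0].shape[0]
    n_subj = len(covs)
    if np.isscalar(observations_per_subject):
        n_obs = [int(observations_per_subject)] * n_subj
    else:
        n_obs = [int(v) for v in observations_per_subject]
    for c, n in zip(covs, n_obs):
        if c.shape != (p, p):
            raise ValueError("subject covariances differ in size")
        if np.linalg.eigvalsh(0.5 * (c + c.T))[0] <= 0:
            raise ValueError("subject covariance not positive definite")
        if n <= p + 1:
            raise ValueError(
                f"effective sample size {n} must exceed N + 1 = {p + 1}"
            )
    ss = np.random.SeedSequence(seed).spawn(n_subj)
    draws = np.zeros((n_samples, n_subj))
    for j, (c, n) in enumerate(zip(covs, n_obs)):
        rng = np.random.default_rng(ss[j])
        sigma_draws = stats.invwishart.rvs(
            df=n, scale=n * c, size=n_samples, random_state=rng
        )
        for i in range(n_samples):
            draws[i, j] = integration(sigma_draws[i], mode="marrelec",
                                      input_kind="covariance")
    group = draws.mean(axis=1)
    return IntegrationPosterior(samples=group, mean=float(group.mean()),
                                sd=float(group.std(ddof=0)))
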