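"""Per-subject and group orchestration of the full analysis.

One subject runs: window assignment around each event, taper-weighted
covariance per window, per-subject cross-validated penalty, penalized
precision fit per window, Fisher transform, condition-mean GLM, and graph
metrics.  The group stage compares the four conditions pairwise at the
network level (exact Wilcoxon on integration, FDR over the six pairs), the
node level (Wilcoxon per node on strength and clustering, FDR over the 14
nodes per measure and pair) and the edge level (paired NBS), plus a
one-sample NBS per condition.  A sensitivity wrapper repeats everything
across window lengths.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import EventTable
from .glasso import (
    ConditionMatrix,
    LambdaSelection,
    condition_mean_glm,
    fisher_transform_matrix,
    glasso_fit,
    select_lambda_cv,
)
from .inference import (
    fdr_bh,
    nbs_one_sample,
    nbs_paired,
    wilcoxon_signed_rank_exact,
)
from .metrics import MetricSet, condition_metrics, network_density
from .regions import RegionTable
from .series import RoiSeries
from .windows import (
    CONDITIONS,
    assign_wois,
    make_taper,
    windowed_covariance,
    wois_to_frame,
)

__all__ = [
    "PipelineConfig",
    "SubjectResult",
    "GroupResult",
    "run_subject",
    "run_group",
    "run_sensitivity",
    "export_brainnet",
    "read_brainnet_edge",
]

log = logging.getLogger(__name__)

CONDITION_PAIRS = list(itertools.combinations(CONDITIONS, 2))


@dataclass
class PipelineConfig:
    """All tunable parameters of one analysis, YAML round-trippable."""

    window_length: int = 8
    taper_sigma: float = 2.0
    n_lambdas: int = 20
    lambda_grid: list[float] | None = None
    penalize_diagonal: bool = True
    glasso_tol: float = 1e-5
    glasso_max_iter: int = 2000
    integration_mode: str = "marrelec"
    degree_kind: str = "binary"
    primary_p: float = 0.05
    n_perm: int = 10_000
    q: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be at least 2 TRs")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text(encoding="utf-8") if Path(
            str(source)
        ).exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def provenance(self) -> dict:
        digest = hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
        return {"config_sha256": digest, "seed": self.seed,
                "version": __version__}


@dataclass
class SubjectResult:
    subject_id: str
    n_events: int
    n_valid_events: int
    window_counts: dict[str, int]
    lambda_selected: float
    lambda_selection: LambdaSelection
    condition_matrices: dict[str, ConditionMatrix]
    metric_sets: dict[str, MetricSet]
    n_nonconverged_fits: int

    @property
    def integration_by_condition(self) -> dict[str, float]:
        return {c: m.integration for c, m in self.metric_sets.items()}


def run_subject(
    series: RoiSeries,
    events: EventTable,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> SubjectResult:
    """Run the full single-subject chain on a conditioned series.

    Raises when no event survives the window-validity rules, listing the
    per-event reasons.  When ``out_dir`` is given, every intermediate
    (window audit table, condition matrices, metrics, lambda curve, log
    counts) is written there as TSV/JSON.
    """
    config = config or PipelineConfig()
    L = config.window_length
    wois = assign_wois(events, L, series.run_boundaries)
    valid = [w for w in wois if w.valid]
    if not valid:
        reasons = {w.event_index: w.invalidity_reason for w in wois}
        raise ValueError(
            f"subject {series.subject_id}: no valid events for L={L}; "
            f"per-event reasons: {reasons}"
        )
    taper = make_taper(L, config.taper_sigma)
    wincovs = [
        windowed_covariance(series, w.intervals[cond], taper,
                            condition=cond, event_index=w.event_index)
        for w in valid
        for cond in CONDITIONS
    ]
    grid = np.asarray(config.lambda_grid, float) if config.lambda_grid else None
    sel = select_lambda_cv(
        wincovs, grid=grid, n_lambdas=config.n_lambdas,
        tol=config.glasso_tol, max_iter=config.glasso_max_iter,
        penalize_diagonal=config.penalize_diagonal,
    )
    # warm start every window fit from the subject-mean fit at lambda*
    mean_cov = np.mean([wc.matrix for wc in wincovs], axis=0)
    mean_fit = glasso_fit(mean_cov, sel.lam, tol=config.glasso_tol,
                          max_iter=config.glasso_max_iter,
                          penalize_diagonal=config.penalize_diagonal)
    z_mats = []
    n_bad = 0
    for wc in wincovs:
        fit = glasso_fit(wc, sel.lam, tol=config.glasso_tol,
                         max_iter=config.glasso_max_iter,
                         penalize_diagonal=config.penalize_diagonal,
                         precision_init=mean_fit.precision)
        if not fit.converged:
            n_bad += 1
        z_mats.append((wc.condition, fisher_transform_matrix(fit.covariance)))
    cms = condition_mean_glm(z_mats, subject_id=series.subject_id)
    metric_sets = {
        c: condition_metrics(cm, integration_mode=config.integration_mode,
                             degree_kind=config.degree_kind)
        for c, cm in cms.items()
    }
    counts = {c: sum(1 for wc in wincovs if wc.condition == c)
              for c in CONDITIONS}
    if len(set(counts.values())) != 1:
        raise AssertionError(f"unbalanced condition windows: {counts}")
    log.info(
        "subject %s: %d/%d valid events, %d windows, lambda=%.4g, "
        "%d non-converged fits",
        series.subject_id, len(valid), len(wois), len(wincovs), sel.lam, n_bad,
    )
    result = SubjectResult(
        subject_id=series.subject_id,
        n_events=len(wois),
        n_valid_events=len(valid),
        window_counts=counts,
        lambda_selected=sel.lam,
        lambda_selection=sel,
        condition_matrices=cms,
        metric_sets=metric_sets,
        n_nonconverged_fits=n_bad,
    )
    if out_dir is not None:
        _write_subject(result, wois, series, config, Path(out_dir))
    return result


def _write_matrix_tsv(mat: np.ndarray, region_ids: list[str],
                      path: Path) -> None:
    pd.DataFrame(mat, index=region_ids, columns=region_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def _write_subject(result: SubjectResult, wois, series: RoiSeries,
                   config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    wois_to_frame(wois).to_csv(out / "windows.tsv", sep="\t", index=False)
    for cond, cm in result.condition_matrices.items():
        _write_matrix_tsv(cm.matrix, series.region_ids,
                          out / f"condition_{cond}.tsv")
    rows = []
    for cond, ms in result.metric_sets.items():
        for i, rid in enumerate(series.region_ids):
            rows.append({"condition": cond, "region": rid,
                         "strength": ms.strength[i],
                         "clustering": ms.clustering[i]})
    pd.DataFrame(rows).to_csv(out / "node_metrics.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"condition": list(result.integration_by_condition),
         "integration": list(result.integration_by_condition.values())}
    ).to_csv(out / "integration.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"lambda": result.lambda_selection.grid,
         "mean_heldout_loglik": result.lambda_selection.mean_scores}
    ).to_csv(out / "lambda_cv.tsv", sep="\t", index=False)
    meta = {
        "subject_id": result.subject_id,
        "n_events": result.n_events,
        "n_valid_events": result.n_valid_events,
        "window_counts": result.window_counts,
        "lambda_selected": result.lambda_selected,
        "n_nonconverged_fits": result.n_nonconverged_fits,
        **config.provenance(),
    }
    (out / "subject.json").write_text(json.dumps(meta, indent=1) + "\n",
                                      encoding="utf-8")


@dataclass
class GroupResult:
    """All pairwise condition comparisons at the three scales."""

    n_subjects: int
    network_level: pd.DataFrame       # pair, W+, p, FDR verdicts
    node_level: pd.DataFrame          # pair x measure x node
    edge_level: dict[tuple[str, str], object]   # pair -> NbsResult
    per_condition_nbs: dict[str, object]        # condition -> NbsResult
    densities: dict[str, float]
    mean_integration: dict[str, float]

    def to_json_dict(self) -> dict:
        edge = {}
        for pair, res in self.edge_level.items():
            edge["_vs_".join(pair)] = {
                "extents": res.extents,
                "p_fwe": res.p_fwe,
                "significant": res.significant,
                "n_permutations": res.n_permutations,
                "threshold_t": res.threshold_t,
                "seed": res.seed,
            }
        return {
            "n_subjects": self.n_subjects,
            "network_level": self.network_level.to_dict("records"),
            "node_level_significant": self.node_level[
                self.node_level["fdr_reject"]
            ].to_dict("records"),
            "edge_level": edge,
            "densities": self.densities,
            "mean_integration": self.mean_integration,
        }


def run_group(
    subject_results: list[SubjectResult],
    config: PipelineConfig | None = None,
    region_ids: list[str] | None = None,
    out_dir: str | Path | None = None,
) -> GroupResult:
    """Compare the four conditions across subjects at all three scales."""
    config = config or PipelineConfig()
    if len(subject_results) < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    n = subject_results[0].condition_matrices[CONDITIONS[0]].matrix.shape[0]
    for r in subject_results:
        if r.condition_matrices[CONDITIONS[0]].matrix.shape[0] != n:
            raise ValueError("subjects have mismatched region sets")
    if region_ids is None:
        region_ids = [f"R{i:02d}" for i in range(n)]
    if len(region_ids) != n:
        raise ValueError("region_ids length does not match matrices")

    integ = {
        c: np.array([r.metric_sets[c].integration for r in subject_results])
        for c in CONDITIONS
    }
    strength = {
        c: np.stack([r.metric_sets[c].strength for r in subject_results])
        for c in CONDITIONS
    }
    clustering = {
        c: np.stack([r.metric_sets[c].clustering for r in subject_results])
        for c in CONDITIONS
    }
    mats = {
        c: np.stack([r.condition_matrices[c].matrix for r in subject_results])
        for c in CONDITIONS
    }

    # network level: one family of six pairwise tests on integration
    net_rows = []
    for a, b in CONDITION_PAIRS:
        res = wilcoxon_signed_rank_exact(integ[a], integ[b])
        net_rows.append({"condition_a": a, "condition_b": b,
                         "w_statistic": res.statistic, "p": res.p_value,
                         "mean_diff": float(np.mean(integ[a] - integ[b]))})
    net = pd.DataFrame(net_rows)
    fdr = fdr_bh(net["p"].to_numpy(), q=config.q)
    net["p_fdr"] = fdr.p_adjusted
    net["fdr_reject"] = fdr.reject
    net["fdr_reject_lenient"] = fdr.reject_lenient

    # node level: family = 14 nodes, per measure x condition pair
    node_rows = []
    for measure, data in (("strength", strength), ("clustering", clustering)):
        for a, b in CONDITION_PAIRS:
            pvals, stats_w = [], []
            for i in range(n):
                res = wilcoxon_signed_rank_exact(data[a][:, i], data[b][:, i])
                pvals.append(res.p_value)
                stats_w.append(res.statistic)
            fdr_n = fdr_bh(np.asarray(pvals), q=config.q)
            for i in range(n):
                node_rows.append({
                    "measure": measure, "condition_a": a, "condition_b": b,
                    "region": region_ids[i], "w_statistic": stats_w[i],
                    "p": pvals[i], "p_fdr": fdr_n.p_adjusted[i],
                    "fdr_reject": bool(fdr_n.reject[i]),
                    "fdr_reject_lenient": bool(fdr_n.reject_lenient[i]),
                })
    node = pd.DataFrame(node_rows)

    # edge level: paired NBS per condition pair; one-sample NBS per condition
    rng = np.random.default_rng(config.seed)
    edge_level = {}
    for a, b in CONDITION_PAIRS:
        edge_level[(a, b)] = nbs_paired(
            mats[a], mats[b], primary_p=config.primary_p,
            n_perm=config.n_perm, seed=int(rng.integers(2**31)),
            alpha=config.q,
        )
    per_condition = {}
    densities = {}
    for c in CONDITIONS:
        res = nbs_one_sample(
            mats[c], primary_p=config.primary_p, n_perm=config.n_perm,
            seed=int(rng.integers(2**31)), alpha=config.q,
        )
        per_condition[c] = res
        n_sig_edges = sum(len(comp) for comp, sig
                          in zip(res.components, res.significant) if sig)
        densities[c] = network_density(n_sig_edges, n)

    result = GroupResult(
        n_subjects=len(subject_results),
        network_level=net,
        node_level=node,
        edge_level=edge_level,
        per_condition_nbs=per_condition,
        densities=densities,
        mean_integration={c: float(integ[c].mean()) for c in CONDITIONS},
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        net.to_csv(out / "network_level.tsv", sep="\t", index=False)
        node.to_csv(out / "node_level.tsv", sep="\t", index=False)
        payload = result.to_json_dict()
        payload.update(config.provenance())
        (out / "group.json").write_text(json.dumps(payload, indent=1) + "\n",
                                        encoding="utf-8")
        for (a, b), res in edge_level.items():
            rows = [
                {"component": k, "region_a": region_ids[i],
                 "region_b": region_ids[j], "p_fwe": res.p_fwe[k]}
                for k, comp in enumerate(res.components)
                for (i, j) in comp
                if res.significant[k]
            ]
            pd.DataFrame(
                rows, columns=["component", "region_a", "region_b", "p_fwe"]
            ).to_csv(out / f"nbs_{a}_vs_{b}.tsv", sep="\t", index=False)
    return result


def run_sensitivity(
    cohort: list[tuple[RoiSeries, EventTable]],
    config: PipelineConfig | None = None,
    lengths: tuple[int, ...] = (6, 8, 10),
    out_dir: str | Path | None = None,
) -> dict:
    """Repeat the subject+group analysis per window length.

    Returns per-length group results, a per-length table of group-mean
    integration, and whether the condition ordering of mean integration
    agrees across lengths.  A length that is infeasible for the event
    trains is skipped with a warning.
    """
    import dataclasses
    import warnings as _warnings

    config = config or PipelineConfig()
    by_length = {}
    for L in lengths:
        cfg = dataclasses.replace(config, window_length=L)
        try:
            subj = [run_subject(series, events, cfg)
                    for series, events in cohort]
            by_length[L] = (subj, run_group(
                subj, cfg, region_ids=cohort[0][0].region_ids))
        except ValueError as err:
            _warnings.warn(f"window length {L} skipped: {err}")
    if not by_length:
        raise ValueError("no feasible window length")
    table = pd.DataFrame(
        [
            {"window_length": L, **grp.mean_integration}
            for L, (_, grp) in sorted(by_length.items())
        ]
    )
    orderings = {
        L: tuple(sorted(CONDITIONS, key=grp.mean_integration.get))
        for L, (_, grp) in by_length.items()
    }
    agree = len(set(orderings.values())) == 1
    out = {
        "by_length": by_length,
        "integration_table": table,
        "orderings": orderings,
        "ordering_agreement": agree,
    }
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        table.to_csv(outp / "sensitivity_integration.tsv", sep="\t",
                     index=False)
        (outp / "sensitivity.json").write_text(
            json.dumps({"orderings": {str(k): list(v)
                                      for k, v in orderings.items()},
                        "ordering_agreement": agree}, indent=1) + "\n",
            encoding="utf-8",
        )
    return out


# --------------------------------------------------------------- BrainNet
def export_brainnet(
    edge_matrix: np.ndarray,
    region_table: RegionTable,
    node_path: str | Path,
    edge_path: str | Path,
    node_sizes: np.ndarray | None = None,
    node_colors: np.ndarray | None = None,
) -> None:
    """Write BrainNet Viewer .node and .edge text files.

    .node rows are ``x y z color size label``; .edge is the N x N
    space-delimited weight matrix.  Node size defaults to the number of
    nonzero connections, color to 1.
    """
    E = np.asarray(edge_matrix, dtype=float)
    n = len(region_table)
    if E.shape != (n, n):
        raise ValueError(
            f"edge matrix {E.shape} does not match the {n}-region table"
        )
    if node_sizes is None:
        node_sizes = (E != 0).sum(axis=1).astype(float)
    if node_colors is None:
        node_colors = np.ones(n)
    lines = []
    for i in range(n):
        x, y, z = region_table.mni_xyz[i]
        label = f"{region_table.labels[i]}_{region_table.hemispheres[i]}"
        lines.append(
            f"{x:g} {y:g} {z:g} {node_colors[i]:g} {node_sizes[i]:g} {label}"
        )
    Path(node_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    rows = [" ".join(f"{v:.10g}" for v in row) for row in E]
    Path(edge_path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_brainnet_edge(path: str | Path) -> np.ndarray:
    """Parse a .edge file back into a matrix (round-trip audit)."""
    return np.loadtxt(path)
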