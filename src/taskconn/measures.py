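"""Node-level graph measures and feature-model assembly.

Strength, weighted local efficiency and the participation coefficient are
computed on the rectified connectivity matrices; together with the
task-activation contrasts they form the 11 feature models used for
classification: {strength, local efficiency, participation} x
{phasic safe>look, phasic safe+look, tonic} plus activation
{safe>look, safe+look}.  One feature per node, so a 121-node parcellation
yields 121 features per model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .cohort import ModuleAssignment
from .design import DesignMatrix
from .phasic import ConnectivityMatrix
from .tonic import _check_rank

#: canonical feature-model order (also the inner-loop tie-break order)
MODEL_TAGS = (
    "phasic_safe_gt_look_strength",
    "phasic_safe_gt_look_local_efficiency",
    "phasic_safe_gt_look_participation",
    "phasic_safe_plus_look_strength",
    "phasic_safe_plus_look_local_efficiency",
    "phasic_safe_plus_look_participation",
    "tonic_strength",
    "tonic_local_efficiency",
    "tonic_participation",
    "activation_safe_gt_look",
    "activation_safe_plus_look",
)


@dataclass(frozen=True)
class NodeMeasureVector:
    values: np.ndarray
    measure: str
    source_tag: str
    node_labels: tuple[str, ...]


@dataclass
class FeatureTable:
    """Subjects x nodes feature matrix with group/site labels attached."""

    data: pd.DataFrame  # index: subject_id; columns: node labels
    model_tag: str
    groups: pd.Series
    sites: pd.Series

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError(f"missing entries in feature table "
                             f"{self.model_tag!r}")
        if not (self.data.index.equals(self.groups.index)
                and self.data.index.equals(self.sites.index)):
            raise ValueError("feature rows misaligned with subject manifest")

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def feature_labels(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "site", self.sites)
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="subject",
                   float_format="%.17g")


def _require_rectified(W: ConnectivityMatrix) -> np.ndarray:
    if np.any(W.values < 0):
        raise ValueError("measure requires a rectified (non-negative) matrix")
    return W.values


def strength(W: ConnectivityMatrix) -> NodeMeasureVector:
    """Node strength: row sum of connection weights."""
    vals = _require_rectified(W) if W.rectified else W.values
    return NodeMeasureVector(vals.sum(axis=1), "strength",
                             W.condition_tag, W.node_labels)


def local_efficiency(W: ConnectivityMatrix) -> NodeMeasureVector:
    """Weighted local efficiency.

    For node i with neighbours N(i): the efficiency of the neighbour
    subgraph, mean over ordered pairs (j, h) in N(i) of 1 / d_jh, where
    d is the shortest path over connection lengths L = 1/W restricted to
    the subgraph.  Nodes with fewer than two neighbours score 0.
    """
    A = _require_rectified(W)
    n = A.shape[0]
    out = np.zeros(n)
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, 1.0 / A, np.inf)
    for i in range(n):
        nbrs = np.flatnonzero(A[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        sub = L[np.ix_(nbrs, nbrs)].copy()
        sub[~np.isfinite(sub)] = 0.0  # csgraph: 0 == no edge
        d = dijkstra(sub, directed=False)
        inv = 1.0 / d[~np.eye(k, dtype=bool)]
        inv[~np.isfinite(inv)] = 0.0
        out[i] = inv.sum() / (k * (k - 1))
    return NodeMeasureVector(out, "local_efficiency",
                             W.condition_tag, W.node_labels)


def participation_coefficient(
    W: ConnectivityMatrix, modules: ModuleAssignment,
) -> NodeMeasureVector:
    """P_i = 1 - sum_m (kappa_im / s_i)^2; 0 for isolated nodes."""
    A = _require_rectified(W)
    labels = W.node_labels
    missing = [l for l in labels if l not in modules.mapping]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing}")
    mods = sorted({modules.mapping[l] for l in labels})
    mod_idx = {m: j for j, m in enumerate(mods)}
    member = np.zeros((len(labels), len(mods)))
    for i, l in enumerate(labels):
        member[i, mod_idx[modules.mapping[l]]] = 1.0
    kappa = A @ member  # node x module summed weight
    s = A.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(s[:, None] > 0, kappa / s[:, None], 0.0)
    P = np.where(s > 0, 1.0 - (frac ** 2).sum(axis=1), 0.0)
    return NodeMeasureVector(P, "participation", W.condition_tag, W.node_labels)


def task_activation_run(ts_run: np.ndarray,
                        design: DesignMatrix) -> dict[str, np.ndarray]:
    """Per-node task-condition effects for one run.

    OLS of each node's series on [intercept, safe, look, confounds];
    returns the beta_safe - beta_look and beta_safe + beta_look contrasts.
    """
    ts_run = np.asarray(ts_run, dtype=float)
    T = design.n_timepoints
    if ts_run.shape[1] != T:
        raise ValueError("time dimension does not match design")
    X = np.column_stack([np.ones(T), design.task_matrix(),
                         design.confound_matrix()])
    _check_rank(X, ["intercept", *design.column_labels])
    beta, *_ = np.linalg.lstsq(X, ts_run.T, rcond=None)
    b_safe, b_look = beta[1], beta[2]
    return {"safe_gt_look": b_safe - b_look, "safe_plus_look": b_safe + b_look}


def task_activation_subject(ts_runs: np.ndarray,
                            designs: list[DesignMatrix]) -> dict[str, np.ndarray]:
    """Run-averaged activation contrasts for one subject."""
    per_run = [task_activation_run(run, dm)
               for run, dm in zip(ts_runs, designs)]
    return {c: np.mean([r[c] for r in per_run], axis=0)
            for c in ("safe_gt_look", "safe_plus_look")}


def build_feature_models(
    phasic: dict[str, dict[str, ConnectivityMatrix]],
    tonic: dict[str, ConnectivityMatrix],
    activation: dict[str, dict[str, np.ndarray]],
    modules: ModuleAssignment,
    groups: pd.Series,
    sites: pd.Series,
) -> dict[str, FeatureTable]:
    """Assemble the 11 feature models, one feature per node.

    ``phasic[subject][tag]`` holds the thresholded contrast matrices,
    ``tonic[subject]`` the tonic matrix, ``activation[subject][tag]`` the
    run-averaged contrast vectors.  Raises when any subject is missing
    from any source.
    """
    subject_ids = list(groups.index)
    for name, source in (("phasic", phasic), ("tonic", tonic),
                         ("activation", activation)):
        for sid in subject_ids:
            if sid not in source:
                raise KeyError(f"subject {sid!r} missing from {name} source")
    some = tonic[subject_ids[0]]
    node_labels = list(some.node_labels)

    def table(tag: str, rows: dict[str, np.ndarray]) -> FeatureTable:
        df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=node_labels).loc[subject_ids]
        return FeatureTable(df, tag, groups, sites)

    measure_funcs = {
        "strength": lambda W: strength(W).values,
        "local_efficiency": lambda W: local_efficiency(W).values,
        "participation":
            lambda W: participation_coefficient(W, modules).values,
    }
    out: dict[str, FeatureTable] = {}
    for tag in MODEL_TAGS:
        if tag.startswith("activation_"):
            contrast_key = tag.removeprefix("activation_")
            rows = {sid: activation[sid][contrast_key] for sid in subject_ids}
        elif tag.startswith("tonic_"):
            fn = measure_funcs[tag.removeprefix("tonic_")]
            rows = {sid: fn(tonic[sid]) for sid in subject_ids}
        else:
            rest = tag.removeprefix("phasic_")
            for m in measure_funcs:
                if rest.endswith("_" + m):
                    contrast_key, fn = rest[: -len(m) - 1], measure_funcs[m]
                    break
            rows = {sid: fn(phasic[sid][contrast_key]) for sid in subject_ids}
        out[tag] = table(tag, rows)
    return out
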