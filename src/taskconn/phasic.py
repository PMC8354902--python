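"""Phasic (task-modulated) connectivity via whole-brain pairwise PPI.

Every node serves once as the source: its series is multiplied with each
mean-centred task regressor to form psychophysiological-interaction (PPI)
terms, and each other node's series is regressed on
[intercept, source, safe, look, PPI_safe, PPI_look, confounds].  The PPI
coefficients fill per-condition connectivity matrices, which are then
symmetrised, averaged over runs, contrasted (safe>look and safe+look),
rectified and proportionally thresholded.

PPI terms are formed at the BOLD level (no deconvolution), the standard
choice for blocked designs; both psychological and physiological factors
are mean-centred before multiplication to limit collinearity with the main
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .design import CONDITIONS, DesignMatrix

CONDITION_TAGS = ("safe", "look", "safe_gt_look", "safe_plus_look", "tonic")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Square symmetric weighted connectivity matrix with provenance flags."""

    values: np.ndarray
    condition_tag: str
    node_labels: tuple[str, ...]
    thresholded: bool = False
    rectified: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if self.condition_tag not in CONDITION_TAGS:
            raise ValueError(f"unknown condition tag {self.condition_tag!r}")
        if len(self.node_labels) != v.shape[0]:
            raise ValueError("node_labels length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def compute_ppi_regressors(
    design: DesignMatrix, source_ts: np.ndarray,
) -> dict[str, np.ndarray]:
    """PPI_c(t) = (taskreg_c - mean) * (source - mean) for each condition."""
    source_ts = np.asarray(source_ts, dtype=float)
    if source_ts.shape != (design.n_timepoints,):
        raise ValueError(
            f"source series length {source_ts.shape} does not match design "
            f"n_timepoints {design.n_timepoints}")
    src_c = source_ts - source_ts.mean()
    return {c: (design.task_regressors[c] - design.task_regressors[c].mean())
            * src_c for c in CONDITIONS}


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [labels[i] for i in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: {bad}")


def estimate_phasic_run(
    ts_run: np.ndarray, design: DesignMatrix,
) -> dict[str, np.ndarray]:
    """PPI coefficient matrices for one run.

    ``ts_run`` is nodes x time.  For each ordered (source, target) pair the
    entry (source, target) of the ``safe`` (``look``) output is the
    coefficient of the safe (look) PPI term; diagonals are zero.
    """
    ts_run = np.asarray(ts_run, dtype=float)
    n, T = ts_run.shape
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if T != design.n_timepoints:
        raise ValueError("time dimension does not match design")
    conf = design.confound_matrix()
    task = design.task_matrix()
    out = {c: np.zeros((n, n)) for c in CONDITIONS}
    labels = (["intercept", "source", *CONDITIONS,
               "ppi_safe", "ppi_look", *design.confound_regressors])
    icol = {"ppi_safe": 4, "ppi_look": 5}
    for i in range(n):
        ppi = compute_ppi_regressors(design, ts_run[i])
        X = np.column_stack([np.ones(T), ts_run[i], task,
                             ppi["safe"], ppi["look"], conf])
        _check_rank(X, labels)
        targets = np.delete(np.arange(n), i)
        beta, *_ = np.linalg.lstsq(X, ts_run[targets].T, rcond=None)
        out["safe"][i, targets] = beta[icol["ppi_safe"]]
        out["look"][i, targets] = beta[icol["ppi_look"]]
    return out


def symmetrize(M: np.ndarray, condition_tag: str,
               node_labels: tuple[str, ...]) -> ConnectivityMatrix:
    """(M + M.T) / 2 with the diagonal forced to zero."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got {M.shape}")
    out = (M + M.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(out, condition_tag, tuple(node_labels))


def average_runs(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of same-tag, same-shape run matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    tag = matrices[0].condition_tag
    shape = matrices[0].values.shape
    for m in matrices[1:]:
        if m.condition_tag != tag:
            raise ValueError(
                f"condition tag mismatch: {m.condition_tag!r} != {tag!r}")
        if m.values.shape != shape:
            raise ValueError("shape mismatch across runs")
    mean = np.mean([m.values for m in matrices], axis=0)
    return replace(matrices[0], values=mean)


def contrast(safe: ConnectivityMatrix,
             look: ConnectivityMatrix) -> dict[str, ConnectivityMatrix]:
    """Form the safe>look (difference) and safe+look (sum) contrasts."""
    if safe.values.shape != look.values.shape:
        raise ValueError("shape mismatch between safe and look matrices")
    return {
        "safe_gt_look": replace(safe, values=safe.values - look.values,
                                condition_tag="safe_gt_look"),
        "safe_plus_look": replace(safe, values=safe.values + look.values,
                                  condition_tag="safe_plus_look"),
    }


def rectify(M: ConnectivityMatrix) -> ConnectivityMatrix:
    return replace(M, values=np.abs(M.values), rectified=True)


def rectify_and_threshold(M: ConnectivityMatrix,
                          proportion: float = 0.05) -> ConnectivityMatrix:
    """Take absolute values and keep only the strongest edges.

    Retains floor(proportion * E) upper-triangle entries (E = n(n-1)/2) by
    absolute weight; ties are broken by row-major upper-triangle order.
    """
    if not 0.0 < proportion <= 1.0:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    a = np.abs(M.values)
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    w = a[iu]
    keep = int(np.floor(proportion * len(w)))
    order = np.argsort(-w, kind="stable")  # stable => row-major tie-break
    mask = np.zeros(len(w), dtype=bool)
    mask[order[:keep]] = True
    out = np.zeros_like(a)
    out[iu[0][mask], iu[1][mask]] = w[mask]
    out = out + out.T
    return replace(M, values=out, rectified=True, thresholded=True)


def estimate_phasic_subject(
    ts_runs: np.ndarray,
    designs: list[DesignMatrix],
    node_labels: tuple[str, ...],
    proportion: float | None = 0.05,
) -> dict[str, ConnectivityMatrix]:
    """Full per-subject phasic pipeline.

    Per run estimate and symmetrise, average over runs, contrast, then
    rectify and (optionally) threshold.  Returns the ``safe_gt_look`` and
    ``safe_plus_look`` matrices.
    """
    per_run: dict[str, list[ConnectivityMatrix]] = {c: [] for c in CONDITIONS}
    for r, (run, dm) in enumerate(zip(ts_runs, designs)):
        try:
            mats = estimate_phasic_run(run, dm)
        except Exception as exc:
            raise RuntimeError(f"phasic estimation failed in run {r + 1}: "
                               f"{exc}") from exc
        for c in CONDITIONS:
            per_run[c].append(symmetrize(mats[c], c, node_labels))
    averaged = {c: average_runs(per_run[c]) for c in CONDITIONS}
    contrasts = contrast(averaged["safe"], averaged["look"])
    if proportion is None:
        return {tag: rectify(m) for tag, m in contrasts.items()}
    return {tag: rectify_and_threshold(m, proportion)
            for tag, m in contrasts.items()}


# -- serialization -----------------------------------------------------------

def write_matrix(M: ConnectivityMatrix, path: str | Path) -> None:
    """Square delimited-text table plus a JSON sidecar of tags/flags."""
    path = Path(path)
    pd.DataFrame(M.values, index=M.node_labels, columns=M.node_labels).to_csv(
        path, sep="\t", float_format="%.17g")
    sidecar = {"condition_tag": M.condition_tag,
               "thresholded": M.thresholded, "rectified": M.rectified}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ConnectivityMatrix(tab.to_numpy(), meta["condition_tag"],
                              tuple(tab.columns), meta["thresholded"],
                              meta["rectified"])
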