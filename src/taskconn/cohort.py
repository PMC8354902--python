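"""Synthetic multi-site task-fMRI cohort generator.

Emulates the structure of a three-group (BPD / CLC / NPC), three-site
emotion-regulation study: per subject, four runs of region-by-time BOLD-like
series over a 121-node parcellation grouped into functional modules
(emotion, motivation, cognitive control, default mode, other).

The generative model per subject and run is

    u_t = tonic + activation + confound leak + AR(1) noise
    u_t[target] += gamma * taskreg_c(t) * u_t[source]      (phasic coupling)
    x_t = site_gain * u_t + site_mean

where the tonic component is Gaussian with a known sparse modular precision
matrix (optionally group-adjusted at designated hub nodes), and the phasic
term is exactly the condition-gated coupling a PPI regression estimates —
so every downstream stage has ground truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import (
    CONDITIONS,
    DesignMatrix,
    HRFParams,
    TaskDesign,
    TimingConfig,
    build_design_matrix,
    build_task_design,
    read_events,
    write_events,
)

GROUPS = ("BPD", "CLC", "NPC")
MODULES = ("emotion", "motivation", "cognitive_control", "default_mode", "other")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    site: str
    n_runs: int
    n_timepoints: int


@dataclass(frozen=True)
class SiteConfig:
    """Scanner-site properties: run length plus additive/multiplicative shift."""

    n_timepoints: int
    mean_shift: float = 0.0
    gain: float = 1.0


@dataclass(frozen=True)
class PrecisionSpec:
    """Random modular precision-matrix structure for the tonic component."""

    within_prob: float = 0.15
    within_weight: tuple[float, float] = (0.2, 0.4)
    between_prob: float = 0.02
    between_weight: tuple[float, float] = (0.05, 0.15)
    min_eig: float = 0.2
    #: every node gets at least this many within-module edges, so hub
    #: effects planted on any node act on a non-empty neighbourhood
    min_degree: int = 1


@dataclass(frozen=True)
class TonicEffect:
    """Scale off-diagonal precision rows/columns of ``nodes`` for one group."""

    group: str
    nodes: tuple[str, ...]
    multiplier: float


@dataclass(frozen=True)
class PhasicEffect:
    """Condition-gated coupling target += gamma * taskreg_c * source."""

    group: str
    condition: str
    source: str
    target: str
    gamma: float


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"BPD": 51, "CLC": 26, "NPC": 44})
    n_nodes: int = 121
    module_sizes: dict[str, int] = field(
        default_factory=lambda: {"emotion": 25, "motivation": 20,
                                 "cognitive_control": 30, "default_mode": 26,
                                 "other": 20})
    sites: dict[str, SiteConfig] = field(
        default_factory=lambda: {
            "maastricht": SiteConfig(240, 0.0, 1.0),
            "freiburg": SiteConfig(252, 0.2, 1.1),
            "luebeck": SiteConfig(252, -0.2, 0.9),
        })
    n_runs: int = 4
    trials_per_run: int = 24
    tr: float = 2.0
    timing: TimingConfig = field(default_factory=TimingConfig)
    hrf: HRFParams = field(default_factory=HRFParams)
    precision_spec: PrecisionSpec = field(default_factory=PrecisionSpec)
    tonic_effects: tuple[TonicEffect, ...] = ()
    phasic_effects: tuple[PhasicEffect, ...] = ()
    task_activation_amp: float = 0.5
    ar_coef: float = 0.3
    noise_sd: float = 0.5
    motion_leak_sd: float = 0.05
    event_leak: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes.values()) != self.n_nodes:
            raise ValueError("module sizes must sum to n_nodes")
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")


@dataclass(frozen=True)
class ModuleAssignment:
    """Node label -> functional module."""

    mapping: dict[str, str]

    def module_of(self, node: str) -> str:
        return self.mapping[node]

    def nodes_of(self, module: str) -> list[str]:
        return [n for n, m in self.mapping.items() if m == module]

    @property
    def modules(self) -> list[str]:
        seen: list[str] = []
        for m in self.mapping.values():
            if m not in seen:
                seen.append(m)
        return seen


@dataclass
class RegionTimeSeriesSet:
    """Per-subject (runs, nodes, time) arrays; sites differ in run length."""

    values: dict[str, np.ndarray]
    node_labels: list[str]
    tr: float

    def get(self, subject_id: str) -> np.ndarray:
        return self.values[subject_id]


@dataclass
class GroundTruth:
    base_precision: np.ndarray
    group_precisions: dict[str, np.ndarray]
    tonic_effects: tuple[TonicEffect, ...]
    phasic_effects: tuple[PhasicEffect, ...]
    hub_nodes: list[str]


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    timeseries: RegionTimeSeriesSet
    modules: ModuleAssignment
    ground_truth: GroundTruth | None
    designs: dict[str, TaskDesign]
    design_matrices: dict[str, list[DesignMatrix]]
    motion: dict[str, np.ndarray]
    config: CohortConfig | None = None

    @property
    def node_labels(self) -> list[str]:
        return self.timeseries.node_labels

    def group_labels(self) -> pd.Series:
        return pd.Series({s.subject_id: s.group for s in self.subjects})


def default_node_labels(module_sizes: dict[str, int]) -> list[str]:
    """Synthetic parcellation labels; the first two emotion nodes are the
    amygdalae so hub effects can be planted on a named region."""
    labels: list[str] = []
    for mod, size in module_sizes.items():
        for i in range(size):
            if mod == "emotion" and i == 0:
                labels.append("amygdala_L")
            elif mod == "emotion" and i == 1:
                labels.append("amygdala_R")
            else:
                labels.append(f"{mod}_{i + 1:03d}")
    return labels


def planted_effects(
    tonic_multiplier: float = 2.0,
    gamma: float = 0.5,
) -> tuple[tuple[TonicEffect, ...], tuple[PhasicEffect, ...]]:
    """Reference non-null configuration: elevated left-amygdala tonic hub
    strength in the BPD group plus safe-condition phasic coupling from the
    left amygdala into a cognitive-control node.  Effect sizes are arbitrary
    reference values (the null configuration is the baseline case)."""
    tonic = (TonicEffect("BPD", ("amygdala_L",), tonic_multiplier),)
    phasic = (PhasicEffect("BPD", "safe", "amygdala_L",
                           "cognitive_control_001", gamma),)
    return tonic, phasic


def build_module_assignment(config: CohortConfig) -> ModuleAssignment:
    labels = default_node_labels(config.module_sizes)
    mapping: dict[str, str] = {}
    i = 0
    for mod, size in config.module_sizes.items():
        for _ in range(size):
            mapping[labels[i]] = mod
            i += 1
    return ModuleAssignment(mapping)


def _random_modular_precision(
    config: CohortConfig, modules: ModuleAssignment, rng: np.random.Generator,
) -> np.ndarray:
    """Sparse SPD precision with stronger within-module partial correlations.

    Off-diagonals are negative (positive partial correlation); diagonal is
    loaded so the smallest eigenvalue is at least ``min_eig`` and then
    rescaled to a unit diagonal.
    """
    spec = config.precision_spec
    labels = list(modules.mapping)
    p = len(labels)
    mod_idx = np.array([MODULES.index(modules.mapping[l])
                        if modules.mapping[l] in MODULES else -1
                        for l in labels])
    theta = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            same = mod_idx[i] == mod_idx[j]
            prob = spec.within_prob if same else spec.between_prob
            lo, hi = spec.within_weight if same else spec.between_weight
            if rng.random() < prob:
                w = rng.uniform(lo, hi)
                theta[i, j] = theta[j, i] = -w
    lo, hi = spec.within_weight
    for i in range(p):
        deg = int((theta[i] != 0).sum()) - 1
        mates = np.flatnonzero((mod_idx == mod_idx[i])
                               & (np.arange(p) != i) & (theta[i] == 0))
        n_add = min(spec.min_degree - deg, len(mates))
        for j in rng.choice(mates, size=max(n_add, 0), replace=False):
            w = rng.uniform(lo, hi)
            theta[i, j] = theta[j, i] = -w
    lam = np.linalg.eigvalsh(theta)[0]
    if lam < spec.min_eig:
        theta += (spec.min_eig - lam) * np.eye(p)
    d = np.sqrt(np.diag(theta))
    return theta / np.outer(d, d)


def _apply_tonic_effects(
    base: np.ndarray, labels: list[str], effects: tuple[TonicEffect, ...],
) -> dict[str, np.ndarray]:
    out = {g: base.copy() for g in GROUPS}
    idx = {l: k for k, l in enumerate(labels)}
    for eff in effects:
        theta = out[eff.group]
        for node in eff.nodes:
            k = idx[node]
            off = np.ones(len(labels), dtype=bool)
            off[k] = False
            theta[k, off] *= eff.multiplier
            theta[off, k] *= eff.multiplier
        if np.linalg.eigvalsh(theta)[0] <= 1e-8:
            raise ValueError(
                f"group-adjusted precision for group {eff.group!r} is not "
                f"positive definite; reduce the tonic multiplier")
        out[eff.group] = theta
    return out


def _smooth_random_walk(rng, n: int, k: int = 6, sd: float = 0.05) -> np.ndarray:
    steps = rng.normal(0.0, sd, size=(n + k, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(k) / k
    sm = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"),
                             0, walk)
    return sm[:n]


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Simulate the cohort; bit-reproducible for a fixed config/seed."""
    config = config or CohortConfig()
    modules = build_module_assignment(config)
    labels = list(modules.mapping)
    idx = {l: k for k, l in enumerate(labels)}
    root = np.random.SeedSequence(config.seed)
    struct_rng = np.random.default_rng(root.spawn(1)[0])

    base_theta = _random_modular_precision(config, modules, struct_rng)
    group_theta = _apply_tonic_effects(base_theta, labels, config.tonic_effects)
    group_chol = {g: np.linalg.cholesky(np.linalg.inv(t))
                  for g, t in group_theta.items()}

    site_names = list(config.sites)
    subjects: list[SubjectRecord] = []
    k = 0
    for group, size in config.group_sizes.items():
        for i in range(size):
            site = site_names[k % len(site_names)]
            subjects.append(SubjectRecord(
                subject_id=f"sub-{k + 1:03d}", group=group, site=site,
                n_runs=config.n_runs,
                n_timepoints=config.sites[site].n_timepoints))
            k += 1

    act_nodes = [idx[l] for l in modules.nodes_of("emotion")]
    phasic_by_group: dict[str, list[PhasicEffect]] = {g: [] for g in GROUPS}
    for eff in config.phasic_effects:
        if eff.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {eff.condition!r}")
        phasic_by_group[eff.group].append(eff)

    ts: dict[str, np.ndarray] = {}
    designs: dict[str, TaskDesign] = {}
    dmats: dict[str, list[DesignMatrix]] = {}
    motion_all: dict[str, np.ndarray] = {}
    subj_seeds = root.spawn(len(subjects) + 1)[1:]
    for sub, seq in zip(subjects, subj_seeds):
        rng = np.random.default_rng(seq)
        site = config.sites[sub.site]
        T = site.n_timepoints
        design = build_task_design(
            config.n_runs, config.trials_per_run, config.timing,
            seed=int(seq.generate_state(1)[0] % 2**31))
        designs[sub.subject_id] = design
        runs = np.empty((config.n_runs, config.n_nodes, T))
        dm_list = []
        motion_runs = np.empty((config.n_runs, T, 6))
        leak = rng.normal(0.0, config.motion_leak_sd,
                          size=(config.n_nodes, 6))
        for r in range(config.n_runs):
            motion = _smooth_random_walk(rng, T)
            motion_runs[r] = motion
            dm = build_design_matrix(design, r + 1, T, config.tr,
                                     config.hrf, motion)
            dm_list.append(dm)
            u = group_chol[sub.group] @ rng.standard_normal((config.n_nodes, T))
            for cond in CONDITIONS:  # common task activation, nuisance
                u[act_nodes] += (config.task_activation_amp
                                 * dm.task_regressors[cond])
            u += leak @ motion.T
            u += config.event_leak * (dm.confound_regressors["cue"]
                                      + dm.confound_regressors["rating"])
            noise = rng.normal(0.0, config.noise_sd,
                               size=(config.n_nodes, T))
            u += lfilter([1.0], [1.0, -config.ar_coef], noise, axis=1)
            for eff in phasic_by_group[sub.group]:
                u[idx[eff.target]] += (eff.gamma
                                       * dm.task_regressors[eff.condition]
                                       * u[idx[eff.source]])
            runs[r] = site.gain * u + site.mean_shift
        ts[sub.subject_id] = runs
        dmats[sub.subject_id] = dm_list
        motion_all[sub.subject_id] = motion_runs

    gt = GroundTruth(
        base_precision=base_theta, group_precisions=group_theta,
        tonic_effects=config.tonic_effects,
        phasic_effects=config.phasic_effects,
        hub_nodes=sorted({n for e in config.tonic_effects for n in e.nodes}))
    return Cohort(subjects=subjects,
                  timeseries=RegionTimeSeriesSet(ts, labels, config.tr),
                  modules=modules, ground_truth=gt, designs=designs,
                  design_matrices=dmats, motion=motion_all, config=config)


# -- on-disk layout ----------------------------------------------------------

def write_cohort(directory: str | Path, cohort: Cohort,
                 overwrite: bool = False) -> None:
    """Write the cohort as a plain-text file tree.

    manifest.tsv, modules.tsv, per-subject events, and per-subject-run
    time-series and motion tables (full float64 precision).  Ground truth
    is a runtime object and is not serialized.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    pd.DataFrame([vars(s) for s in cohort.subjects]).to_csv(
        manifest_path, sep="\t", index=False)
    pd.DataFrame(
        {"node": list(cohort.modules.mapping),
         "module": list(cohort.modules.mapping.values())},
    ).to_csv(directory / "modules.tsv", sep="\t", index=False)
    cfg = cohort.config
    meta = {"tr": cohort.timeseries.tr,
            "timing": vars(cfg.timing) if cfg else vars(TimingConfig()),
            "hrf": vars(cfg.hrf) if cfg else vars(HRFParams())}
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    for sub in cohort.subjects:
        sid = sub.subject_id
        write_events(cohort.designs[sid], directory / f"{sid}_events.tsv")
        arr = cohort.timeseries.get(sid)
        for r in range(sub.n_runs):
            pd.DataFrame(arr[r].T, columns=cohort.node_labels).to_csv(
                directory / f"{sid}_run-{r + 1}_timeseries.tsv",
                sep="\t", index=False, float_format="%.17g")
            pd.DataFrame(
                cohort.motion[sid][r],
                columns=[f"motion_{i + 1}" for i in range(6)],
            ).to_csv(directory / f"{sid}_run-{r + 1}_motion.tsv",
                     sep="\t", index=False, float_format="%.17g")


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`; rebuilds design
    matrices from the stored events and motion tables."""
    directory = Path(directory)
    manifest_path = directory / "manifest.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest table: {manifest_path}")
    modules_path = directory / "modules.tsv"
    if not modules_path.exists():
        raise FileNotFoundError(f"missing module table: {modules_path}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    mod_tab = pd.read_csv(modules_path, sep="\t")
    modules = ModuleAssignment(dict(zip(mod_tab["node"], mod_tab["module"])))
    meta = json.loads((directory / "meta.json").read_text())
    timing = TimingConfig(**meta["timing"])
    hrf = HRFParams(**meta["hrf"])
    tr = float(meta["tr"])

    subjects, ts, designs, dmats, motion_all = [], {}, {}, {}, {}
    labels = list(modules.mapping)
    for row in manifest.itertuples():
        sub = SubjectRecord(row.subject_id, row.group, row.site,
                            int(row.n_runs), int(row.n_timepoints))
        subjects.append(sub)
        sid = sub.subject_id
        designs[sid] = read_events(directory / f"{sid}_events.tsv", timing)
        runs, dm_list, motions = [], [], []
        for r in range(sub.n_runs):
            tstab = pd.read_csv(
                directory / f"{sid}_run-{r + 1}_timeseries.tsv", sep="\t",
                float_precision="round_trip")
            mot = pd.read_csv(
                directory / f"{sid}_run-{r + 1}_motion.tsv", sep="\t",
                float_precision="round_trip").to_numpy()
            runs.append(tstab[labels].to_numpy().T)
            motions.append(mot)
            dm_list.append(build_design_matrix(
                designs[sid], r + 1, sub.n_timepoints, tr, hrf, mot))
        ts[sid] = np.stack(runs)
        dmats[sid] = dm_list
        motion_all[sid] = np.stack(motions)
    return Cohort(subjects=subjects,
                  timeseries=RegionTimeSeriesSet(ts, labels, tr),
                  modules=modules, ground_truth=None, designs=designs,
                  design_matrices=dmats, motion=motion_all, config=None)
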