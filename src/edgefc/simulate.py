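"""Synthetic cohorts with known edge-community structure.

Generative model: k* independent standard-normal latent community signals
s_c(t); node i's raw series is sum_c w_ic * s_c(t) + noise_sd * eps_i(t),
where the nonnegative loading rows w_i sum to 1.  This latent mixture gives
analytically known ground truth at every pipeline stage:

* planted edge community of pair (i, j): argmax_c w_ic * w_jc (ties to the
  lowest community index);
* planted node overlap: normalized entropy of the loading row w_i.

Group differences are planted by overriding the loadings of designated
networks' components for group-2 subjects (e.g. rows pushed toward uniform
raise that network's overlap entropy).  The model is a statistical stand-in
for parcellated BOLD data, not a physiological claim.  Everything derives
deterministically from a single master seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .edges import EdgeIndex
from .panels import NetworkAtlas, SubjectTable, TimeSeriesPanel, write_panel

__all__ = [
    "SimulationDesign",
    "SyntheticCohort",
    "mixed_loadings",
    "planted_edge_labels",
    "loading_entropy",
    "simulate_panel",
    "simulate_cohort",
    "write_cohort",
    "cohort_design",
    "community_recovery_design",
]

GROUP_LABELS = ("g1", "g2")

# covariate name -> (mean, sd, group2 mean shift); sex is Bernoulli(p).
DEFAULT_COVARIATES = {
    "age": (21.5, 6.0, 0.5),
    "education": (13.9, 3.5, -2.7),
    "symptom_score": (11.2, 5.5, 1.0),
}
DEFAULT_SEX_P = (0.45, 0.27)  # P(female) per group


@dataclasses.dataclass
class SimulationDesign:
    """Full specification of a two-group synthetic cohort."""

    n_components: int
    n_timepoints: int
    networks: list[tuple[str, int]]  # (name, n member components), in order
    n_latent: int
    loadings: np.ndarray  # N x k*, rows sum to 1
    noise_sd: float
    n_subjects: tuple[int, int] = (33, 44)
    loadings_group2: np.ndarray | None = None
    target_networks: list[str] = dataclasses.field(default_factory=list)
    covariate_spec: dict[str, tuple[float, float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    sex_p: tuple[float, float] = DEFAULT_SEX_P

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        n, k = self.loadings.shape
        if n != self.n_components or k != self.n_latent:
            raise ValueError("loading matrix shape must be N x k*")
        if self.n_latent < 2:
            raise ValueError("need at least 2 latent communities")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if np.any(self.loadings < 0) or np.any(
            np.abs(self.loadings.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValueError("loading rows must be nonnegative and sum to 1")
        if sum(s for _, s in self.networks) != self.n_components:
            raise ValueError("network sizes must sum to n_components")
        if self.loadings_group2 is not None:
            self.loadings_group2 = np.asarray(self.loadings_group2, np.float64)
            if self.loadings_group2.shape != self.loadings.shape:
                raise ValueError("group-2 loadings must match shape")
            diff = np.flatnonzero(
                np.abs(self.loadings_group2 - self.loadings).sum(axis=1) > 1e-12
            )
            allowed = set()
            for name in self.target_networks:
                allowed.update(self.network_members(name))
            if not set(diff.tolist()) <= allowed:
                raise ValueError(
                    "group-2 override touches components outside target networks"
                )

    @property
    def component_ids(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_components)]

    def network_members(self, name: str) -> list[int]:
        start = 0
        for net, size in self.networks:
            if net == name:
                return list(range(start, start + size))
            start += size
        raise KeyError(f"unknown network {name!r}")

    def atlas(self) -> NetworkAtlas:
        mapping: dict[str, str] = {}
        ids = self.component_ids
        start = 0
        for net, size in self.networks:
            for i in range(start, start + size):
                mapping[ids[i]] = net
            start += size
        return NetworkAtlas(
            mapping=mapping, network_order=[n for n, _ in self.networks]
        )

    def group_loadings(self, group: int) -> np.ndarray:
        if group == 2 and self.loadings_group2 is not None:
            return self.loadings_group2
        return self.loadings


@dataclasses.dataclass
class SyntheticCohort:
    """Simulated panels plus all ground truth, ready for the pipeline."""

    design: SimulationDesign
    panels: list[TimeSeriesPanel]
    subjects: SubjectTable
    true_edge_labels: dict[str, np.ndarray]  # subject_id -> length-M labels
    true_node_entropy: dict[str, np.ndarray]  # subject_id -> length-N values
    master_seed: int


def mixed_loadings(
    node_communities: np.ndarray, n_latent: int, alpha: np.ndarray | float
) -> np.ndarray:
    """Loading rows (1-alpha)*onehot(community) + alpha/k* (sum to 1).

    ``alpha`` in [0, 1] controls overlap per node: 0 is a one-hot row, 1 a
    uniform row.  Scalar alpha applies to every node.
    """
    comm = np.asarray(node_communities, dtype=np.int64)
    n = comm.size
    a = np.broadcast_to(np.asarray(alpha, dtype=np.float64), (n,))
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must lie in [0, 1]")
    w = np.tile((a / n_latent)[:, None], (1, n_latent))
    w[np.arange(n), comm] += 1.0 - a
    return w


def planted_edge_labels(loadings: np.ndarray) -> np.ndarray:
    """Ground-truth community (1..k*) of each edge: argmax_c w_ic * w_jc.

    Ties resolve to the lowest community index (argmax convention).  Edge
    order is the canonical upper-triangle order of EdgeIndex.
    """
    w = np.asarray(loadings, dtype=np.float64)
    idx = EdgeIndex(w.shape[0])
    prod = w[idx.rows] * w[idx.cols]  # M x k*
    return np.argmax(prod, axis=1) + 1


def loading_entropy(loadings: np.ndarray) -> np.ndarray:
    """Normalized entropy of each loading row (planted node overlap)."""
    w = np.asarray(loadings, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(w > 0, w * np.log2(np.where(w > 0, w, 1.0)), 0.0)
    return -terms.sum(axis=1) / np.log2(w.shape[1])


def simulate_panel(
    design: SimulationDesign,
    subject_seed: int | np.random.SeedSequence,
    group: int = 1,
    subject_id: str = "sim",
) -> tuple[TimeSeriesPanel, np.ndarray, np.ndarray]:
    """Draw one subject's raw panel.

    Returns (panel, planted edge labels, planted node overlap entropy).
    The panel is *not* z-scored; feed it through the normal pipeline.
    """
    rng = np.random.default_rng(subject_seed)
    w = design.group_loadings(group)
    latent = rng.standard_normal((design.n_latent, design.n_timepoints))
    noise = rng.standard_normal((design.n_components, design.n_timepoints))
    values = w @ latent + design.noise_sd * noise
    panel = TimeSeriesPanel(
        subject_id=subject_id,
        values=values,
        component_ids=design.component_ids,
        zscored=False,
    )
    return panel, planted_edge_labels(w), loading_entropy(w)


def simulate_cohort(design: SimulationDesign, master_seed: int) -> SyntheticCohort:
    """Simulate both groups; deterministic given the master seed.

    Subject seeds are spawned from the master seed by a fixed rule, so any
    subject can be regenerated independently.  Covariates are drawn from
    the design's normal specs (with group-2 mean shifts) plus a Bernoulli
    sex code, to exercise residualization downstream.
    """
    ss = np.random.SeedSequence(master_seed)
    n1, n2 = design.n_subjects
    panel_seeds = ss.spawn(n1 + n2)
    cov_rng = np.random.default_rng(ss.spawn(1)[0])

    panels: list[TimeSeriesPanel] = []
    rows: list[dict] = []
    true_labels: dict[str, np.ndarray] = {}
    true_entropy: dict[str, np.ndarray] = {}
    i = 0
    for group, n_group in ((1, n1), (2, n2)):
        label = GROUP_LABELS[group - 1]
        for j in range(n_group):
            sid = f"{label}_s{j + 1:03d}"
            panel, labels, ent = simulate_panel(
                design, panel_seeds[i], group=group, subject_id=sid
            )
            i += 1
            panels.append(panel)
            true_labels[sid] = labels
            true_entropy[sid] = ent
            row = {"subject_id": sid, "group": label}
            for name, (mu, sd, shift) in design.covariate_spec.items():
                row[name] = mu + (shift if group == 2 else 0.0) + sd * float(
                    cov_rng.standard_normal()
                )
            row["sex"] = int(cov_rng.random() < design.sex_p[group - 1])
            rows.append(row)

    subjects = SubjectTable(frame=pd.DataFrame(rows))
    return SyntheticCohort(
        design=design,
        panels=panels,
        subjects=subjects,
        true_edge_labels=true_labels,
        true_node_entropy=true_entropy,
        master_seed=master_seed,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write panels/atlas/subjects in the formats the readers consume.

    Ground truth goes to a separate ``ground_truth.json`` that the analysis
    pipeline never reads.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel_dir = outdir / "panels"
    panel_dir.mkdir(exist_ok=True)
    for panel in cohort.panels:
        write_panel(panel, panel_dir / f"{panel.subject_id}.tsv")
    atlas = cohort.design.atlas()
    pd.DataFrame(
        {
            "component_id": list(atlas.mapping),
            "network": [atlas.mapping[c] for c in atlas.mapping],
        }
    ).to_csv(outdir / "atlas.tsv", sep="\t", index=False)
    cohort.subjects.frame.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    truth = {
        "master_seed": cohort.master_seed,
        "edge_labels": {s: v.tolist() for s, v in cohort.true_edge_labels.items()},
        "node_entropy": {s: v.tolist() for s, v in cohort.true_node_entropy.items()},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth))


def community_recovery_design(
    n_nodes: int = 24,
    n_timepoints: int = 400,
    noise_sd: float = 0.5,
    shared: float = 0.2,
) -> SimulationDesign:
    """Design with 3 planted edge communities recoverable from eFC.

    Nodes split into two equal groups; group A loads ``1 - shared`` on
    latent community 1 and ``shared`` on a communal third latent; group B
    likewise on community 2 plus the communal latent.  The resulting edges
    fall into exactly three co-fluctuation families — within-A (dominated
    by s1^2), within-B (s2^2), and across (s1*s2) — and the planted argmax
    labels name those same three families (the communal latent breaks the
    zero-product tie on across edges in favour of community 3).  That
    alignment is what makes k-means on eFC recover the planted partition.
    """
    if n_nodes % 2:
        raise ValueError("n_nodes must be even")
    if not 0 < shared < 0.5:
        raise ValueError("shared loading must be in (0, 0.5)")
    half = n_nodes // 2
    w = np.zeros((n_nodes, 3))
    w[:half, 0] = 1.0 - shared
    w[half:, 1] = 1.0 - shared
    w[:, 2] = shared
    networks = [("blockA", half), ("blockB", n_nodes - half)]
    return SimulationDesign(
        n_components=n_nodes,
        n_timepoints=n_timepoints,
        networks=networks,
        n_latent=3,
        loadings=w,
        noise_sd=noise_sd,
        n_subjects=(1, 1),
    )


def overlap_gradient_design(
    n_nodes: int = 24,
    n_timepoints: int = 400,
    noise_sd: float = 0.5,
) -> SimulationDesign:
    """Design whose nodes span the full overlap range, for entropy recovery.

    Two latent communities; node i's loading row is (1 - a_i, a_i) with a_i
    on an even grid from 0 to 1.  Planted node overlap (loading-row entropy)
    rises from 0 at the ends of the grid to 1 at a = 1/2; clustering eFC at
    k=2 recovers node entropies whose ordering tracks that gradient.
    """
    a = np.linspace(0.0, 1.0, n_nodes)
    w = np.column_stack([1.0 - a, a])
    return SimulationDesign(
        n_components=n_nodes,
        n_timepoints=n_timepoints,
        networks=[("all", n_nodes)],
        n_latent=2,
        loadings=w,
        noise_sd=noise_sd,
        n_subjects=(1, 1),
    )


def cohort_design(
    n_networks: int = 16,
    components_per_network: int = 2,
    n_timepoints: int = 230,
    noise_sd: float = 0.5,
    n_subjects: tuple[int, int] = (33, 44),
    target_networks: list[str] | None = None,
    uniformity_shift: float = 0.7,
    alpha_lo: float = 0.05,
    alpha_hi: float = 0.95,
) -> SimulationDesign:
    """Study-scale cohort: two latent communities, graded node overlap.

    Component loadings are (1 - a, a) with mixing weights ``a`` on an even
    grid over [alpha_lo, alpha_hi], dealt round-robin so each network's
    components sit at spread-out grid positions.  The two-latent gradient
    keeps the k=2 edge-community boundary anchored by all components, so a
    per-network override perturbs only that network's overlap.

    If ``target_networks`` is given, group-2 subjects get those networks'
    mixing weights pulled toward 1/2 (rows toward uniform, i.e. higher
    planted overlap) by ``uniformity_shift``: a' = 1/2 + (a - 1/2) * (1 -
    uniformity_shift).
    """
    n = n_networks * components_per_network
    networks = [(f"net{m + 1:02d}", components_per_network) for m in range(n_networks)]
    grid = np.linspace(alpha_lo, alpha_hi, n)
    # round-robin deal: network m's components get grid[m], grid[m + 16], ...
    alpha = np.empty(n)
    comp_net = np.repeat(np.arange(n_networks), components_per_network)
    for m in range(n_networks):
        members = np.flatnonzero(comp_net == m)
        alpha[members] = grid[m::n_networks]
    w = np.column_stack([1.0 - alpha, alpha])
    w2 = None
    targets = list(target_networks or [])
    if targets:
        if not 0 < uniformity_shift <= 1:
            raise ValueError("uniformity_shift must be in (0, 1]")
        name_to_idx = {name: m for m, (name, _) in enumerate(networks)}
        alpha2 = alpha.copy()
        for name in targets:
            if name not in name_to_idx:
                raise KeyError(f"unknown network {name!r}")
            members = np.flatnonzero(comp_net == name_to_idx[name])
            alpha2[members] = 0.5 + (alpha[members] - 0.5) * (1 - uniformity_shift)
        w2 = np.column_stack([1.0 - alpha2, alpha2])
    return SimulationDesign(
        n_components=n,
        n_timepoints=n_timepoints,
        networks=networks,
        n_latent=2,
        loadings=w,
        noise_sd=noise_sd,
        n_subjects=n_subjects,
        loadings_group2=w2,
        target_networks=targets,
    )
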