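"""Synthetic methylation cohorts with a planted class hierarchy.

The generator emulates the structure of a multi-cohort 450K pan-cancer
collection at desk scale: cancer *types* nested in taxonomy *groups*,
clinical *subtypes* nested in types, per-class differentially methylated
marker CpGs, beta-distributed measurement noise, per-cohort batch shifts,
missing cells and sex-chromosome probes.

Generative model
----------------
* Each background probe gets a baseline mean drawn from a bimodal
  distribution over (0, 1) (mixture of Beta(2, 8) and Beta(8, 2)),
  mimicking the characteristic hypo/hyper-methylated peaks of array data.
* Group signatures evolve along a random planted ultrametric binary tree by
  cumulative Brownian-style mean drift carried by a dedicated ~1% subset of
  background probes ("lineage probes", intermediate baseline), so
  between-group Pearson distance grows with tree distance.  Each tree
  edge's drift increment has fixed per-probe magnitude (scaled by the
  square root of the edge duration) and is orthogonalised against the
  baseline and all other edges, which makes the planted between-group
  correlation distance an exact monotone function of the merge height —
  the planted structure is UPGMA-recoverable by construction, and what a
  recovery test then measures is the robustness of the tree-building
  pipeline to measurement noise, jitter and probe selection.
* A marker probe for a class (group or type) keeps a flat baseline in every
  other class and is shifted by +/- ``marker_delta`` in the marked class
  only, so the minimum mean gap to all other classes is the planted delta.
* Per-sample values are Beta draws with the subtype mean m and concentration
  kappa, i.e. shape parameters (m * kappa, (1 - m) * kappa); only means are
  ever clipped, never draws.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import write_beta_matrix, write_manifest

_MEAN_LO, _MEAN_HI = 0.02, 0.98


@dataclass
class SyntheticSpec:
    """Parameters of a planted-hierarchy methylation cohort.

    Defaults mirror the pan-cancer regime coarsely but desk-sized: 12
    groups holding 30 cancer types (group sizes 1-4, three singleton
    groups), two clinical subtypes per type, 20 samples per subtype,
    5000 background probes, 40 group-marker and 30 type-marker CpGs per
    class with a planted effect of delta-beta 0.3, and beta noise of
    concentration 50 (per-probe s.d. about 0.06 at intermediate means).
    """

    n_groups: int = 12
    types_per_group: tuple[int, ...] | int = (1, 2, 1, 2, 4, 4, 2, 2, 1, 3, 4, 4)
    subtypes_per_type: int = 2
    samples_per_subtype: int = 20
    n_background_probes: int = 5000
    n_markers_per_group: int = 40
    n_markers_per_type: int = 30
    marker_delta: float = 0.3
    noise_precision: float = 50.0
    drift_scale: float = 0.22      # root-to-leaf s.d. of Brownian group drift
    n_lineage_probes: int | None = None  # lineage-drift probes; None = ~1% of probes
    subtype_jitter: float = 0.01   # per-subtype mean perturbation s.d.
    batch_shift: float = 0.0       # additive mean offset of cohort 2 vs cohort 1
    n_cohorts: int = 2
    missing_rate: float = 0.0
    n_sex_probes: int = 100
    seed: int = 0

    def resolved_types_per_group(self) -> tuple[int, ...]:
        if isinstance(self.types_per_group, int):
            return (self.types_per_group,) * self.n_groups
        tpg = tuple(self.types_per_group)
        if len(tpg) != self.n_groups:
            raise ValueError("types_per_group length must equal n_groups")
        return tpg

    def validate(self) -> None:
        tpg = self.resolved_types_per_group()
        if any(t < 1 for t in tpg):
            raise ValueError("every group needs at least one type")
        if not 0 < self.marker_delta < 1:
            raise ValueError("marker_delta must be in (0, 1)")
        for name in ("subtypes_per_type", "samples_per_subtype",
                     "n_background_probes", "n_cohorts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_markers_per_group", "n_markers_per_type", "n_sex_probes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.noise_precision <= 0:
            raise ValueError("noise_precision must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    planted_tree: str                       # Newick over group labels
    group_of_type: dict[str, str]
    marker_probes: dict[str, frozenset]     # class label (group or type) -> probes
    sample_labels: pd.DataFrame             # copy of the emitted manifest
    planted_means: pd.DataFrame             # probes x subtypes, pre-batch means
    subtype_of_sample: dict[str, str] = field(default_factory=dict)

    @property
    def group_marker_classes(self) -> list[str]:
        return [c for c in self.marker_probes if c in set(self.group_of_type.values())]

    @property
    def background_probes(self) -> frozenset:
        planted = set()
        for probes in self.marker_probes.values():
            planted |= probes
        return frozenset(set(self.planted_means.index) - planted)


# ---------------------------------------------------------------------------
# planted tree
# ---------------------------------------------------------------------------

def _random_join_tree(labels: list[str], rng: np.random.Generator):
    """Random ultrametric binary tree over ``labels``.

    Built by successive random joins; the m-th merge sits at height
    m / (n - 1), so every leaf is at unit depth below the root.  Returned
    as nested (left, right, height) tuples with string leaves.
    """
    n = len(labels)
    nodes: list = list(labels)
    for m in range(1, n):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append((left, right, m / (n - 1)))
    return nodes[0]


def _node_height(node) -> float:
    return node[2] if isinstance(node, tuple) else 0.0


def _newick(node) -> str:
    if isinstance(node, tuple):
        return f"({_newick(node[0])},{_newick(node[1])})"
    return str(node)


def _collect_edges(node, edges: list) -> None:
    """(duration, child-subtree) for every edge, in deterministic order."""
    if isinstance(node, tuple):
        for child in node[:2]:
            edges.append((_node_height(node) - _node_height(child), child))
            _collect_edges(child, edges)


def _leaves(node) -> list[str]:
    if isinstance(node, tuple):
        return _leaves(node[0]) + _leaves(node[1])
    return [node]


def _lineage_drift(topology, baseline: np.ndarray, scale: float,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-group drift vectors over the lineage probes.

    Each tree edge gets a fixed-magnitude (Rademacher-sign) increment of
    per-probe size scale * sqrt(edge duration), orthogonalised against a
    constant vector, the centred baseline, and all previously drawn edges;
    a leaf's drift is the sum over its root-to-leaf path.  With exact
    orthogonality the centred between-leaf inner products equal the shared
    path length exactly, so the planted correlation distance is an exact
    monotone function of the pair's merge height (ultrametric).
    """
    m = baseline.shape[0]
    edges: list = []
    _collect_edges(topology, edges)
    basis = [np.ones(m) / np.sqrt(m)]
    b_c = baseline - baseline.mean()
    nb = np.linalg.norm(b_c)
    if nb > 1e-12:
        basis.append(b_c / nb)
    if len(edges) + len(basis) > m:
        raise ValueError(
            f"need at least {len(edges) + len(basis)} lineage probes for "
            f"{len(edges)} tree edges")
    drift = {leaf: np.zeros(m) for leaf in _leaves(topology)}
    for duration, child in edges:
        c = scale * np.sqrt(max(duration, 0.0))
        unit = None
        for attempt in range(8):
            # Rademacher signs; Gaussian retries if the draw happens to lie
            # (almost) inside the span of the existing basis
            raw = (rng.choice([-1.0, 1.0], size=m) if attempt == 0
                   else rng.normal(size=m))
            for q in basis:
                raw -= (raw @ q) * q
            norm = np.linalg.norm(raw)
            if norm > 1e-8 * np.sqrt(m):
                unit = raw / norm
                break
        if unit is None:
            raise ValueError("degenerate drift direction; increase lineage probes")
        basis.append(unit)
        w = unit * (c * np.sqrt(m))
        for leaf in _leaves(child):
            drift[leaf] += w
    return drift


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: SyntheticSpec):
    """Generate one cohort: (beta matrix, manifest, annotation, ground truth).

    Fully reproducible from ``spec.seed``.  Raises before any sampling if a
    marker mean shifted by ``marker_delta`` cannot stay inside (0, 1).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tpg = spec.resolved_types_per_group()

    groups = [f"G{i + 1:02d}" for i in range(spec.n_groups)]
    group_of_type: dict[str, str] = {}
    types: list[str] = []
    t = 0
    for g, n_types in zip(groups, tpg):
        for _ in range(n_types):
            t += 1
            label = f"T{t:02d}"
            types.append(label)
            group_of_type[label] = g
    letters = string.ascii_lowercase
    subtypes_of_type = {
        ty: [f"{ty}.{letters[i]}" for i in range(spec.subtypes_per_type)]
        for ty in types
    }
    subtypes = [s for ty in types for s in subtypes_of_type[ty]]

    # probe layout: ids are sequential, roles interleaved by a permutation
    n_group_markers = spec.n_groups * spec.n_markers_per_group
    n_type_markers = len(types) * spec.n_markers_per_type
    n_probes = (spec.n_background_probes + n_group_markers
                + n_type_markers + spec.n_sex_probes)
    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])
    role_perm = rng.permutation(n_probes)
    pos = 0
    background_idx = role_perm[pos:pos + spec.n_background_probes]
    pos += spec.n_background_probes
    marker_idx: dict[str, np.ndarray] = {}
    for g in groups:
        marker_idx[g] = role_perm[pos:pos + spec.n_markers_per_group]
        pos += spec.n_markers_per_group
    for ty in types:
        marker_idx[ty] = role_perm[pos:pos + spec.n_markers_per_type]
        pos += spec.n_markers_per_type
    sex_idx = role_perm[pos:]

    # baseline means: bimodal over (0,1)
    lo = rng.beta(2.0, 8.0, size=n_probes)
    hi = rng.beta(8.0, 2.0, size=n_probes)
    baseline = np.where(rng.random(n_probes) < 0.5, lo, hi)
    baseline = np.clip(baseline, _MEAN_LO, _MEAN_HI)

    # lineage probes: the subset of background probes that carries the
    # group drift; intermediate baseline so drifted means stay in range
    n_edges = max(2 * spec.n_groups - 2, 0)
    if spec.n_lineage_probes is None:
        n_lineage = max(int(np.ceil(0.01 * n_probes)), n_edges + 2, 10)
    else:
        n_lineage = int(spec.n_lineage_probes)
    if n_lineage > spec.n_background_probes:
        raise ValueError("n_lineage_probes exceeds n_background_probes")
    lineage_idx = background_idx[:n_lineage]
    baseline[lineage_idx] = rng.uniform(0.45, 0.55, size=n_lineage)

    # feasibility of every planted marker shift, before any sampling
    delta = spec.marker_delta
    directions: dict[str, np.ndarray] = {}
    for cls, idx in marker_idx.items():
        b = baseline[idx]
        up_ok = b + delta <= _MEAN_HI
        down_ok = b - delta >= _MEAN_LO
        if np.any(~up_ok & ~down_ok):
            bad = probe_ids[idx[~up_ok & ~down_ok]][:3]
            raise ValueError(
                f"marker_delta={delta} infeasible for class {cls} at probes {list(bad)}"
            )
        directions[cls] = np.where(up_ok, 1.0, -1.0)

    # group drift along the planted tree (lineage probes only)
    topology = _random_join_tree(groups, rng)
    drift = _lineage_drift(topology, baseline[lineage_idx], spec.drift_scale, rng)

    # per-subtype planted means
    means = np.tile(baseline[:, None], (1, len(subtypes)))
    sub_col = {s: j for j, s in enumerate(subtypes)}
    for ty in types:
        g = group_of_type[ty]
        cols = [sub_col[s] for s in subtypes_of_type[ty]]
        means[np.ix_(lineage_idx, cols)] += drift[g][:, None]
        means[marker_idx[g][:, None], cols] = (
            baseline[marker_idx[g]] + directions[g] * delta
        )[:, None]
        means[marker_idx[ty][:, None], cols] = (
            baseline[marker_idx[ty]] + directions[ty] * delta
        )[:, None]
    means += rng.normal(0.0, spec.subtype_jitter, size=means.shape)
    means = np.clip(means, _MEAN_LO, _MEAN_HI)

    # samples
    rows = []
    n_samples = len(subtypes) * spec.samples_per_subtype
    counter = 0
    for ty in types:
        for s in subtypes_of_type[ty]:
            for _ in range(spec.samples_per_subtype):
                counter += 1
                rows.append({
                    "sample_id": f"S{counter:05d}",
                    "cancer_type": ty,
                    "subtype": s,
                    "cohort": f"cohort{1 + (counter - 1) % spec.n_cohorts}",
                    "split": "unassigned",
                })
    manifest = pd.DataFrame(rows)

    cohort_index = (manifest.index.to_numpy() % spec.n_cohorts).astype(float)
    offsets = cohort_index * spec.batch_shift
    col_of_sample = np.array([sub_col[s] for s in manifest["subtype"]])
    sample_means = means[:, col_of_sample] + offsets[None, :]
    sample_means = np.clip(sample_means, _MEAN_LO, _MEAN_HI)

    kappa = spec.noise_precision
    values = rng.beta(sample_means * kappa, (1.0 - sample_means) * kappa)

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.astype(float)
        values[mask] = np.nan

    matrix = pd.DataFrame(values, index=probe_ids, columns=manifest["sample_id"].to_numpy())

    autosomes = rng.choice([f"chr{i}" for i in range(1, 23)], size=n_probes)
    chromosome = autosomes.astype(object)
    chromosome[sex_idx] = np.where(np.arange(len(sex_idx)) % 2 == 0, "chrX", "chrY")
    annotation = pd.DataFrame({"probe_id": probe_ids, "chromosome": chromosome})

    truth = GroundTruth(
        planted_tree=_newick(topology) + ";",
        group_of_type=group_of_type,
        marker_probes={cls: frozenset(probe_ids[idx]) for cls, idx in marker_idx.items()},
        sample_labels=manifest.copy(),
        planted_means=pd.DataFrame(means, index=probe_ids, columns=subtypes),
        subtype_of_sample=dict(zip(manifest["sample_id"], manifest["subtype"])),
    )
    assert n_samples == len(manifest)
    return matrix, manifest, annotation, truth


# ---------------------------------------------------------------------------
# generator diagnostics
# ---------------------------------------------------------------------------

def planted_delta_check(matrix: pd.DataFrame, truth: GroundTruth) -> pd.DataFrame:
    """Realized minimum mean gap of every planted marker probe.

    For a group marker: the minimum over all other groups of the absolute
    difference in empirical group means at that probe.  For a type marker:
    the same over all other types.  Columns: class, level, probe_id,
    min_abs_delta.
    """
    manifest = truth.sample_labels
    group_labels = manifest["cancer_type"].map(truth.group_of_type)
    records = []
    group_set = set(truth.group_of_type.values())
    for cls, probes in truth.marker_probes.items():
        level = "group" if cls in group_set else "type"
        labels = group_labels if level == "group" else manifest["cancer_type"]
        probes = sorted(probes)
        sub = matrix.loc[probes]
        by_class = sub.T.groupby(labels.to_numpy()).mean().T  # probes x classes
        others = [c for c in by_class.columns if c != cls]
        gaps = (by_class[others].sub(by_class[cls], axis=0)).abs().min(axis=1)
        for p in probes:
            records.append({"class": cls, "level": level, "probe_id": p,
                            "min_abs_delta": float(gaps.loc[p])})
    return pd.DataFrame(records)


def realized_background_delta(matrix: pd.DataFrame, truth: GroundTruth,
                              n_probes: int = 200, seed: int = 0) -> pd.Series:
    """Minimum between-group mean gap for a sample of background probes."""
    rng = np.random.default_rng(seed)
    bg = sorted(truth.background_probes)
    if len(bg) > n_probes:
        bg = list(rng.choice(bg, size=n_probes, replace=False))
    manifest = truth.sample_labels
    group_labels = manifest["cancer_type"].map(truth.group_of_type)
    by_group = matrix.loc[bg].T.groupby(group_labels.to_numpy()).mean().T
    gaps = {}
    for g in by_group.columns:
        others = [c for c in by_group.columns if c != g]
        gaps[g] = (by_group[others].sub(by_group[g], axis=0)).abs().min(axis=1)
    return pd.DataFrame(gaps).min(axis=1)


def write_cohort(out_dir, matrix: pd.DataFrame, manifest: pd.DataFrame,
                 annotation: pd.DataFrame, truth: GroundTruth) -> None:
    """Write the cohort in the same TSV formats ``data_io`` reads, plus the
    ground truth as Newick (planted tree) and TSV (marker map)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(matrix, out / "beta_matrix.tsv")
    write_manifest(manifest, out / "manifest.tsv")
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    (out / "planted_tree.nwk").write_text(truth.planted_tree + "\n")
    marker_rows = [
        {"class": cls, "probe_id": p}
        for cls, probes in truth.marker_probes.items()
        for p in sorted(probes)
    ]
    pd.DataFrame(marker_rows).to_csv(out / "planted_markers.tsv", sep="\t", index=False)
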