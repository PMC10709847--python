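"""Small worked examples used by the docs and the reproduction script.

The routing example builds a deliberately tiny cohort — two multi-type
groups with disjoint type pairs plus two singleton groups — and exercises
hierarchical top-2 routing at both extremes of the candidate-set size:
both selected groups multi-type (4 candidates) and both singleton
(2 candidates).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import data_io, evaluate, feature_select
from .classifier import HierarchicalModel, ForestConfig, PanelSet, build_hierarchical_model
from .synthetic import SyntheticSpec, generate_cohort
from .taxonomy import GroupAssignment


@dataclass
class RoutingExample:
    model: HierarchicalModel
    matrix: pd.DataFrame
    manifest: pd.DataFrame
    assignment: GroupAssignment
    n_samples: int
    multi_candidates: list[str]      # candidate set when top-2 groups are multi-type
    singleton_candidates: list[str]  # candidate set when top-2 groups are singletons


def _assignment_from_truth(manifest: pd.DataFrame, group_of_type: dict) -> GroupAssignment:
    class_of_subtype = dict(zip(manifest["subtype"], manifest["cancer_type"]))
    return GroupAssignment(
        group_of_subtype={s: group_of_type[t] for s, t in class_of_subtype.items()},
        class_of_subtype=class_of_subtype,
        group_of_class=dict(group_of_type),
        n_groups=len(set(group_of_type.values())),
    )


def build_tiny_model(seed: int = 7):
    """A small hierarchical model with two multi-type and two singleton groups.

    The taxonomy is taken from the planted hierarchy (the point of the
    example is routing, not tree recovery) and panels come from the
    ANOVA + Tukey-Kramer stages.
    """
    spec = SyntheticSpec(
        n_groups=4, types_per_group=(2, 2, 1, 1), subtypes_per_type=1,
        samples_per_subtype=15, n_background_probes=400,
        n_markers_per_group=15, n_markers_per_type=10, n_sex_probes=20,
        seed=seed)
    matrix, manifest, annotation, truth = generate_cohort(spec)
    matrix = data_io.filter_probes(matrix, annotation)
    manifest = data_io.stratified_split(manifest, 0.8, seed=seed)
    assignment = _assignment_from_truth(manifest, truth.group_of_type)

    train = manifest[manifest["split"] == "train"]
    mat_train = matrix[train["sample_id"].to_numpy()]
    group_labels = assignment.group_labels_for(train)
    class_labels = assignment.class_labels_for(train)

    screened = feature_select.anova_screen(mat_train, group_labels)
    layer1 = feature_select.select_markers(
        mat_train.loc[screened.index], group_labels, min_markers=5).all_probes
    by_group = {}
    for grp in assignment.multi_type_groups:
        idx = group_labels[group_labels == grp].index
        sub = mat_train[list(idx)]
        scr = feature_select.anova_screen(sub, class_labels.loc[idx])
        by_group[grp] = feature_select.select_markers(
            sub.loc[scr.index], class_labels.loc[idx], min_markers=5).all_probes

    model = build_hierarchical_model(matrix, manifest, assignment,
                       PanelSet(layer1=layer1, by_group=by_group),
                       ForestConfig(seed=seed))
    return model, matrix, manifest, assignment


def _blend_sample(matrix: pd.DataFrame, manifest: pd.DataFrame,
                  assignment: GroupAssignment, groups: list[str],
                  weight: float) -> pd.Series:
    """Mixture of the mean profiles of one type per group — a sample
    engineered to route its top-2 first-layer picks to ``groups``."""
    parts = []
    for grp in groups:
        ty = assignment.classes_in_group(grp)[0]
        sids = manifest.loc[manifest["cancer_type"] == ty, "sample_id"]
        parts.append(matrix[list(sids)].mean(axis=1))
    return weight * parts[0] + (1.0 - weight) * parts[1]


def _candidates_for_group_pattern(model, matrix, manifest, assignment,
                                  wanted_pool: set[str], k: int = 2) -> list[str]:
    """Candidate set of a test sample whose top-k groups all fall in
    ``wanted_pool``; falls back to a blended sample when no held-out sample
    routes that way naturally."""
    test = manifest[manifest["split"] == "test"]
    preds = evaluate.predict_batch(model, matrix[test["sample_id"].to_numpy()], k=k)
    for p in preds:
        top = {g for g, _ in p.layer1_probs[:k]}
        if top <= wanted_pool and len(top) == k:
            return p.candidate_set
    import itertools

    for pair in itertools.combinations(sorted(wanted_pool), 2):
        for weight in (0.5, 0.4, 0.6, 0.3, 0.7):
            blend = _blend_sample(matrix, manifest, assignment, list(pair), weight)
            p = evaluate.predict_topk2(model, blend, k=k)
            top = {g for g, _ in p.layer1_probs[:k]}
            if top <= wanted_pool and len(top) == k:
                return p.candidate_set
    raise RuntimeError("could not construct the requested routing pattern")


def routing_worked_example(seed: int = 7) -> RoutingExample:
    """Candidate-set sizes at the two routing extremes of top-2 prediction."""
    model, matrix, manifest, assignment = build_tiny_model(seed)
    multi = set(assignment.multi_type_groups)
    single = set(assignment.singleton_groups)
    return RoutingExample(
        model=model, matrix=matrix, manifest=manifest, assignment=assignment,
        n_samples=matrix.shape[1],
        multi_candidates=_candidates_for_group_pattern(
            model, matrix, manifest, assignment, multi),
        singleton_candidates=_candidates_for_group_pattern(
            model, matrix, manifest, assignment, single),
    )
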