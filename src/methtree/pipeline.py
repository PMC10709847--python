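"""End-to-end training: preprocessing -> taxonomy -> marker cascade -> model.

This is the orchestration layer the CLI and the evaluation scripts use;
every step is an exported function of its own module and can be run (and
tested) independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import data_io, feature_select, taxonomy
from .classifier import HierarchicalModel, ForestConfig, PanelSet, build_hierarchical_model
from .feature_select import MarkerPanel

logger = logging.getLogger("methtree")


@dataclass
class PipelineResult:
    model: HierarchicalModel
    tree: taxonomy.TaxonomyTree
    assignment: taxonomy.GroupAssignment
    panels: PanelSet
    manifest: pd.DataFrame               # filtered manifest with splits
    matrix: pd.DataFrame                 # filtered beta matrix
    layer1_panel_detail: MarkerPanel | None = None
    layer2_panel_detail: dict[str, MarkerPanel] = field(default_factory=dict)


def select_panel(matrix: pd.DataFrame, labels: pd.Series,
                 anova_alpha: float = 0.05,
                 delta_schedule: Sequence[float] = feature_select.DEFAULT_DELTA_SCHEDULE,
                 p_threshold: float = 0.01, min_markers: int = 20,
                 boruta: bool = True, boruta_max_iter: int = 30,
                 seed: int = 0) -> tuple[list[str], MarkerPanel]:
    """Run the full marker cascade for one classification problem.

    Returns (final probe panel, the Tukey-stage MarkerPanel detail).
    """
    screened = feature_select.anova_screen(matrix, labels, alpha=anova_alpha)
    logger.info("ANOVA retained %d / %d probes", len(screened), matrix.shape[0])
    panel = feature_select.select_markers(
        matrix.loc[screened.index], labels,
        delta_schedule=delta_schedule, p_threshold=p_threshold,
        min_markers=min_markers)
    probes = panel.all_probes
    logger.info("Tukey-Kramer selection: %d candidate probes", len(probes))
    if boruta and probes:
        confirmed = feature_select.boruta_confirm(
            matrix.loc[probes].T, labels.reindex(matrix.columns).to_numpy(),
            max_iter=boruta_max_iter, seed=seed)
        if confirmed:
            probes = confirmed
            logger.info("Boruta confirmed %d probes", len(probes))
        else:
            logger.warning("Boruta confirmed nothing; keeping Tukey panel")
    return probes, panel


def train_from_cohort(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    config: ForestConfig | None = None,
    split_ratio: float = 0.8,
    top_fraction: float = 0.01,
    k_range: Sequence[int] | None = None,
    overrides: Mapping[str, str] | None = None,
    anova_alpha: float = 0.05,
    delta_schedule: Sequence[float] = feature_select.DEFAULT_DELTA_SCHEDULE,
    p_threshold: float = 0.01,
    min_markers: int = 20,
    boruta: bool = True,
    boruta_max_iter: int = 30,
) -> PipelineResult:
    """Train a full hierarchical model from a beta matrix and manifest.

    Steps: probe and subtype filtering, stratified 4:1 split (when the
    manifest has no split yet), taxonomy construction on all retained
    samples, then the marker cascade and forest training on the training
    split only — once over groups for layer 1 and once within each
    multi-type group for layer 2.
    """
    config = config or ForestConfig()

    matrix = data_io.filter_probes(matrix, annotation)
    manifest, removed = data_io.filter_subtypes(manifest)
    if len(removed):
        logger.info("removed %d under-represented subtypes", len(removed))
    manifest = manifest[manifest["sample_id"].isin(matrix.columns)].reset_index(drop=True)
    matrix = matrix[manifest["sample_id"].to_numpy()]
    if (manifest["split"] == "unassigned").all():
        manifest = data_io.stratified_split(manifest, ratio=split_ratio,
                                            seed=config.seed)

    # taxonomy over all retained samples
    clustering_probes = taxonomy.top_variance_probes(matrix, top_fraction)
    profiles = taxonomy.subtype_means(matrix.loc[clustering_probes], manifest)
    distances = taxonomy.pearson_distance(profiles)
    tree = taxonomy.upgma(distances)
    type_of_subtype = dict(zip(manifest["subtype"], manifest["cancer_type"]))
    assignment = taxonomy.choose_groups(tree, distances, type_of_subtype,
                                        k_range=k_range, overrides=overrides)
    logger.info("taxonomy: %d groups over %d subtypes (silhouette argmax)",
                assignment.n_groups, tree.n_leaves)

    train = manifest[manifest["split"] == "train"]
    mat_train = matrix[train["sample_id"].to_numpy()]
    group_labels = assignment.group_labels_for(train)
    class_labels = assignment.class_labels_for(train)

    layer1_probes, layer1_detail = select_panel(
        mat_train, group_labels, anova_alpha=anova_alpha,
        delta_schedule=delta_schedule, p_threshold=p_threshold,
        min_markers=min_markers, boruta=boruta,
        boruta_max_iter=boruta_max_iter, seed=config.seed)

    by_group: dict[str, list[str]] = {}
    layer2_detail: dict[str, MarkerPanel] = {}
    for grp in assignment.multi_type_groups:
        in_group = group_labels[group_labels == grp].index
        sub = mat_train[list(in_group)]
        probes, detail = select_panel(
            sub, class_labels.loc[in_group], anova_alpha=anova_alpha,
            delta_schedule=delta_schedule, p_threshold=p_threshold,
            min_markers=min_markers, boruta=boruta,
            boruta_max_iter=boruta_max_iter, seed=config.seed + 1)
        by_group[grp] = probes
        layer2_detail[grp] = detail

    panels = PanelSet(layer1=layer1_probes, by_group=by_group)
    model = build_hierarchical_model(matrix, manifest, assignment, panels, config)
    return PipelineResult(
        model=model, tree=tree, assignment=assignment, panels=panels,
        manifest=manifest, matrix=matrix,
        layer1_panel_detail=layer1_detail, layer2_panel_detail=layer2_detail,
    )
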