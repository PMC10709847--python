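"""Two-layer hierarchical random-forest classifier over the taxonomy.

The first layer predicts the taxonomy *group* of a sample from the
group-level marker panel; each multi-type group then has its own
second-layer forest predicting the cancer type within that group from the
group's own panel.  Singleton groups are predicted directly by the first
layer.  Per-feature training means are stored so prediction-time inputs
from other platforms with missing panel probes can be mean-imputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .taxonomy import GroupAssignment

logger = logging.getLogger("methtree")

_BUNDLE_VERSION = 1


@dataclass
class ForestConfig:
    """Random-forest hyperparameters shared by both layers.

    200 trees with balanced class weighting by default; tree depth and
    features-per-split are left at estimator defaults but exposed.
    """

    n_trees: int = 200
    class_weight_mode: str = "balanced"   # {"balanced", "none"}
    seed: int = 0
    max_depth: int | None = None
    max_features: str | int | float = "sqrt"
    missing_feature_threshold: float = 0.5

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.class_weight_mode not in ("balanced", "none"):
            raise ValueError("class_weight_mode must be 'balanced' or 'none'")

    @property
    def sklearn_class_weight(self):
        return "balanced" if self.class_weight_mode == "balanced" else None


@dataclass
class LayerModel:
    """One fitted forest plus the bookkeeping needed to apply it."""

    forest: RandomForestClassifier
    classes: list[str]
    feature_ids: list[str]
    feature_means: pd.Series
    missing_feature_threshold: float = 0.5

    def predict_proba(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Class probabilities for each sample (matrix is probes x samples).

        Panel probes absent from the input are imputed with the stored
        training means (with a per-sample warning); a sample missing more
        than the configured fraction of panel features is an error.
        """
        X = matrix.reindex(self.feature_ids).T.astype(float)  # samples x features
        n_missing = X.isna().sum(axis=1)
        frac = n_missing / len(self.feature_ids)
        over = frac > self.missing_feature_threshold
        if over.any():
            bad = list(X.index[over])[:5]
            raise ValueError(
                f"samples missing more than {self.missing_feature_threshold:.0%} "
                f"of panel features, e.g. {bad}")
        for sid in X.index[n_missing > 0]:
            logger.warning("sample %s: imputed %d/%d missing panel features",
                           sid, int(n_missing[sid]), len(self.feature_ids))
        X = X.fillna(self.feature_means)
        probs = self.forest.predict_proba(X.to_numpy())
        return pd.DataFrame(probs, index=X.index, columns=list(self.forest.classes_))


def train_layer(matrix: pd.DataFrame, labels: pd.Series,
                panel: Sequence[str], config: ForestConfig) -> LayerModel:
    """Fit one forest on the panel features of the labelled samples."""
    panel = list(panel)
    missing = [p for p in panel if p not in matrix.index]
    if missing:
        raise ValueError(f"panel probes absent from matrix: {missing[:5]}")
    if not panel:
        raise ValueError("empty feature panel")
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some matrix samples")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a layer")
    X = matrix.loc[panel].T.to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        class_weight=config.sklearn_class_weight,
        max_depth=config.max_depth,
        max_features=config.max_features,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, labels.to_numpy())
    return LayerModel(
        forest=forest,
        classes=list(forest.classes_),
        feature_ids=panel,
        feature_means=pd.Series(X.mean(axis=0), index=panel),
        missing_feature_threshold=config.missing_feature_threshold,
    )


@dataclass
class PanelSet:
    """Marker panels for the whole tree: one for layer 1, one per group."""

    layer1: list[str]
    by_group: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class HierarchicalModel:
    """The assembled hierarchical classifier."""

    assignment: GroupAssignment
    layer1: LayerModel
    layer2: dict[str, LayerModel]
    config: ForestConfig

    def validate_routing(self) -> None:
        """Every class label must be reachable: its group is either a
        singleton (direct layer-1 prediction) or has a layer-2 model that
        knows the class."""
        for cls, grp in self.assignment.group_of_class.items():
            members = self.assignment.classes_in_group(grp)
            if len(members) == 1:
                if grp not in self.layer1.classes:
                    raise ValueError(f"group {grp} unknown to layer 1")
            else:
                if grp not in self.layer2:
                    raise ValueError(f"multi-type group {grp} has no layer-2 model")
                if cls not in self.layer2[grp].classes:
                    raise ValueError(f"class {cls} unknown to layer-2 model of {grp}")

    # -- serialization ------------------------------------------------------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "bundle_version": _BUNDLE_VERSION,
            "config": dataclasses.asdict(self.config),
            "assignment": {
                "group_of_subtype": self.assignment.group_of_subtype,
                "class_of_subtype": self.assignment.class_of_subtype,
                "group_of_class": self.assignment.group_of_class,
                "n_groups": self.assignment.n_groups,
                "silhouette_by_k": {str(k): v for k, v in
                                    self.assignment.silhouette_by_k.items()},
                "split_types": self.assignment.split_types,
            },
            "layer2_groups": sorted(self.layer2),
        }
        (out / "metadata.json").write_text(json.dumps(meta, indent=2))
        _save_layer(self.layer1, out / "layer1")
        for grp, model in self.layer2.items():
            _save_layer(model, out / f"layer2_{grp}")

    @classmethod
    def load(cls, in_dir) -> "HierarchicalModel":
        src = Path(in_dir)
        meta = json.loads((src / "metadata.json").read_text())
        if meta.get("bundle_version") != _BUNDLE_VERSION:
            raise ValueError("unsupported model bundle version")
        config = ForestConfig(**meta["config"])
        a = meta["assignment"]
        assignment = GroupAssignment(
            group_of_subtype=a["group_of_subtype"],
            class_of_subtype=a["class_of_subtype"],
            group_of_class=a["group_of_class"],
            n_groups=a["n_groups"],
            silhouette_by_k={int(k): v for k, v in a["silhouette_by_k"].items()},
            split_types=a["split_types"],
        )
        layer1 = _load_layer(src / "layer1")
        layer2 = {g: _load_layer(src / f"layer2_{g}") for g in meta["layer2_groups"]}
        model = cls(assignment=assignment, layer1=layer1, layer2=layer2, config=config)
        model.validate_routing()
        return model


def _save_layer(layer: LayerModel, stem: Path) -> None:
    joblib.dump(layer.forest, stem.with_suffix(".joblib"))
    meta = {
        "classes": layer.classes,
        "feature_ids": layer.feature_ids,
        "feature_means": {k: float(v) for k, v in layer.feature_means.items()},
        "missing_feature_threshold": layer.missing_feature_threshold,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta))


def _load_layer(stem: Path) -> LayerModel:
    forest = joblib.load(stem.with_suffix(".joblib"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return LayerModel(
        forest=forest,
        classes=meta["classes"],
        feature_ids=meta["feature_ids"],
        feature_means=pd.Series(meta["feature_means"]),
        missing_feature_threshold=meta["missing_feature_threshold"],
    )


def build_hierarchical_model(matrix: pd.DataFrame, manifest: pd.DataFrame,
               assignment: GroupAssignment, panels: PanelSet,
               config: ForestConfig) -> HierarchicalModel:
    """Train the two-layer model from training-split samples.

    Layer 1 is fitted on group labels over all training samples; every
    multi-type group gets a layer-2 model fitted on that group's training
    samples with that group's panel.  Singleton groups get no layer-2
    model — the first layer predicts them directly.
    """
    train = manifest[manifest["split"] == "train"]
    if train.empty:
        train = manifest  # unsplit input: train on everything
    mat = matrix[train["sample_id"].to_numpy()]
    group_labels = assignment.group_labels_for(train)
    class_labels = assignment.class_labels_for(train)

    layer1 = train_layer(mat, group_labels, panels.layer1, config)
    layer2: dict[str, LayerModel] = {}
    for grp in assignment.multi_type_groups:
        if grp not in panels.by_group:
            raise ValueError(f"no marker panel for multi-type group {grp}")
        in_group = group_labels[group_labels == grp].index
        sub = mat[list(in_group)]
        layer2[grp] = train_layer(sub, class_labels.loc[in_group],
                                  panels.by_group[grp], config)
    model = HierarchicalModel(assignment=assignment, layer1=layer1,
                      layer2=layer2, config=config)
    model.validate_routing()
    return model


def train_flat_baseline(matrix: pd.DataFrame, manifest: pd.DataFrame,
                        config: ForestConfig,
                        class_labels: pd.Series | None = None,
                        panel: Sequence[str] | None = None,
                        anova_alpha: float = 0.05,
                        delta_schedule=(0.2, 0.15, 0.1),
                        p_threshold: float = 0.01,
                        min_markers: int = 20) -> tuple[LayerModel, list[str]]:
    """Flat (single-layer) baseline over all type labels for comparison.

    Runs the same marker cascade once with every type as its own class —
    the flat panel is the union of the per-type one-vs-all selections —
    then fits a single forest.  Returns (model, panel used).
    """
    from .feature_select import anova_screen, select_markers

    train = manifest[manifest["split"] == "train"]
    if train.empty:
        train = manifest
    mat = matrix[train["sample_id"].to_numpy()]
    if class_labels is None:
        class_labels = pd.Series(train["cancer_type"].to_numpy(),
                                 index=train["sample_id"].to_numpy())
    labels = class_labels.reindex(mat.columns)
    if panel is None:
        screened = anova_screen(mat, labels, alpha=anova_alpha)
        flat_panel = select_markers(mat.loc[screened.index], labels,
                                    delta_schedule=delta_schedule,
                                    p_threshold=p_threshold,
                                    min_markers=min_markers)
        panel = flat_panel.all_probes
    model = train_layer(mat, labels, panel, config)
    return model, list(panel)
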