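"""End-to-end orchestration: generate -> segment -> profile -> morphotype ->
classify -> statistics, with deterministic seeding throughout.

``profile_dataset`` streams scenes (images are dropped once profiled, so the
paper-scale run fits comfortably in memory); ``analyze_dataset`` reproduces
the analysis stage: z-scoring, validity-guided k selection, Ward morphs,
feature pruning, the random-forest classifier with its held-out weighted F1,
morph prediction for clumped cells, and the headline statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classification, morphotyping, profiling, stats
from .catalog import METADATA_COLUMNS, STAINING_GROUPS, morphology_feature_names
from .segmentation import SegmentationResult, segment_scene
from .synthetic import SceneRecord, iter_scenes, resolve_profile

logger = logging.getLogger(__name__)


@dataclass
class ProfiledDataset:
    """Feature tables and ground-truth bookkeeping of one pipeline run."""

    features_by_group: dict[str, pd.DataFrame]
    ground_truth: pd.DataFrame  # one row per profiled cell, gt annotations
    n_detected: int
    n_retained: int
    n_clumped: int

    @property
    def morphology_table(self) -> pd.DataFrame:
        """Metadata + the 150 morphology/context features for all cells."""
        cols = list(METADATA_COLUMNS) + morphology_feature_names()
        parts = [t[cols] for t in self.features_by_group.values()]
        return (
            pd.concat(parts, ignore_index=True)
            .sort_values("cell_id")
            .reset_index(drop=True)
        )


def _match_ground_truth(
    seg: SegmentationResult, rec: SceneRecord
) -> dict[int, pd.Series]:
    """Match segmented cells to ground-truth cells by maximum mask overlap."""
    gt_labels = rec.ground_truth.cell_labels
    table = rec.ground_truth.table.set_index("label")
    out: dict[int, pd.Series] = {}
    for cid in seg.profiled:
        mask = seg.cell_labels == cid
        overlap = gt_labels[mask]
        overlap = overlap[overlap != 0]
        if len(overlap) == 0:
            continue
        vals, counts = np.unique(overlap, return_counts=True)
        out[cid] = table.loc[int(vals[np.argmax(counts)])]
    return out


def profile_dataset(
    profile: str | object, seed: int, *, keep_masks: bool = False
) -> ProfiledDataset:
    """Generate, segment and profile a full dataset, one scene at a time."""
    prof = resolve_profile(profile)
    rows_by_group: dict[str, list[dict]] = {g: [] for g in STAINING_GROUPS}
    meta_by_group: dict[str, list[dict]] = {g: [] for g in STAINING_GROUPS}
    gt_rows: list[dict] = []
    n_detected = n_retained = n_clumped = 0
    cell_id = 1

    for rec in iter_scenes(prof, seed):
        seg = segment_scene(rec.image.channels, rec.image.pixel_size_um)
        n_detected += len(seg.context_set)
        n_retained += len(seg.retained)
        n_clumped += len(seg.clumped)
        markers = tuple(m for m in STAINING_GROUPS[rec.staining_group])
        channels = {m: rec.image.channels[m.upper()] for m in markers}
        match = _match_ground_truth(seg, rec)
        centroids, areas = profiling.scene_centroids_and_areas(seg.cell_labels)

        for cid in sorted(seg.profiled):
            cell_mask = seg.cell_labels == cid
            nucleus_mask = seg.nucleus_labels == cid
            try:
                feats = profiling.profile_cell(
                    cell_mask,
                    nucleus_mask,
                    rec.image.pixel_size_um,
                    channels,
                    markers,
                )
            except profiling.InvalidObjectError as exc:
                logger.warning("scene %s cell %d dropped: %s", rec.scene_id, cid, exc)
                continue
            feats.update(
                profiling.context_features(
                    seg.cell_labels,
                    cid,
                    rec.image.pixel_size_um,
                    centroids=centroids,
                    areas=areas,
                )
            )
            meta = {
                "cell_id": cell_id,
                "scene_id": rec.scene_id,
                "stiffness_kpa": rec.stiffness_kpa,
                "staining_group": rec.staining_group,
                "clumped": cid in seg.clumped,
            }
            rows_by_group[rec.staining_group].append(feats)
            meta_by_group[rec.staining_group].append(meta)
            gt = match.get(cid)
            gt_rows.append(
                {
                    **meta,
                    "gt_morph": int(gt["morph_id"]) if gt is not None else -1,
                    "gt_clumped": bool(gt["clumped"]) if gt is not None else False,
                    "gt_area_um2": float(gt["area_um2"]) if gt is not None else np.nan,
                    "gt_nucleus_area_um2": (
                        float(gt["nucleus_area_um2"]) if gt is not None else np.nan
                    ),
                }
            )
            cell_id += 1

    features_by_group = {
        g: profiling.assemble_table(rows_by_group[g], meta_by_group[g], g)
        for g in STAINING_GROUPS
        if rows_by_group[g]
    }
    return ProfiledDataset(
        features_by_group=features_by_group,
        ground_truth=pd.DataFrame(gt_rows),
        n_detected=n_detected,
        n_retained=n_retained,
        n_clumped=n_clumped,
    )


@dataclass
class AnalysisResult:
    """Outputs of the analysis stage on a profiled dataset."""

    chosen_k: int
    validity_traces: pd.DataFrame
    assignment: morphotyping.MorphAssignment
    single_table: pd.DataFrame  # z-scored morphology table of single cells
    selected_features: list[str]
    excluded_features: list[str]
    classifier_report: classification.ClassifierReport
    clumped_predictions: pd.Series
    clumped_morph3_pct: float
    composition: pd.DataFrame
    mi_ranking: pd.Series
    ncr_association: dict[str, float]
    extras: dict = field(default_factory=dict)


def analyze_dataset(
    morphology: pd.DataFrame,
    seed: int,
    *,
    k: int | None = None,
    run_k_selection: bool = True,
    rf_iter: int = classification.SEARCH_DRAWS,
) -> AnalysisResult:
    """The full analysis stage on a 150-feature morphology table.

    ``morphology`` must hold metadata plus the morphology/context features for
    every profiled cell (single and clumped).  Clumped cells are excluded
    from clustering and training and only classified at the end.
    """
    singles = morphology[~morphology["clumped"]].reset_index(drop=True)
    clumped = morphology[morphology["clumped"]].reset_index(drop=True)

    z_singles = morphotyping.zscore(singles)
    feat_cols_all = morphotyping.feature_matrix(z_singles).columns
    n_missing = int(z_singles[feat_cols_all].isna().sum().sum())
    if n_missing:
        # Sentinel NaNs (e.g. nearest-neighbour distances in degenerate
        # scenes) are set to the column mean (0 after z-scoring).
        logger.info("analysis: imputing %d missing feature values with 0", n_missing)
        z_singles[feat_cols_all] = z_singles[feat_cols_all].fillna(0.0)
    chosen_k, traces = (
        morphotyping.estimate_k(z_singles, seed=seed)
        if run_k_selection
        else (0, pd.DataFrame())
    )
    k_use = k if k is not None else (chosen_k if chosen_k else 3)
    assignment = morphotyping.cluster_morphs(z_singles, k_use)
    mi = morphotyping.feature_importance_mi(z_singles, assignment.labels, seed=seed)
    composition = morphotyping.composition_by_condition(
        assignment.labels, singles[["scene_id", "stiffness_kpa"]]
    )

    feat_cols = morphotyping.feature_matrix(z_singles).columns
    reduced, excluded = classification.select_features(z_singles[feat_cols])
    model, report = classification.train_rf(
        reduced, assignment.labels.to_numpy(), seed=seed, n_iter=rf_iter
    )

    # Clumped cells: z-score with the single-cell statistics, then classify.
    mu = singles[feat_cols].mean()
    sd = singles[feat_cols].std(ddof=1)
    z_clumped = ((clumped[feat_cols] - mu) / sd).fillna(0.0)
    pred, _ = classification.predict_morphs(model, z_clumped, list(reduced.columns))
    morph3_pct = float((pred == 3).mean() * 100.0) if len(pred) else float("nan")

    ncr_assoc = stats.stiffness_association(singles, "ncr")

    return AnalysisResult(
        chosen_k=chosen_k,
        validity_traces=traces,
        assignment=assignment,
        single_table=z_singles,
        selected_features=list(reduced.columns),
        excluded_features=excluded,
        classifier_report=report,
        clumped_predictions=pred,
        clumped_morph3_pct=morph3_pct,
        composition=composition,
        mi_ranking=mi,
        ncr_association=ncr_assoc,
    )
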