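"""Morphotype discovery: z-scoring, validity-guided k selection, Ward
clustering, medoids, feature ranking and per-condition composition.

The number of morphotypes is chosen by repeated 30% subsampling: for every
candidate k the subsample is Ward-clustered and two internal validity indices
are recorded (silhouette, higher better; Davies-Bouldin, lower better).  The
consensus k maximises the median silhouette across replicates, with the
median Davies-Bouldin as confirmatory evidence and ties resolved toward the
larger k (finer structure).

Cluster labels are relabelled canonically by ascending median cell
circularity, so label 1 is the least circular (irregular, lamellipodial)
morph, label 2 the large flattened morph and label 3 the small round morph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .catalog import METADATA_COLUMNS

logger = logging.getLogger(__name__)

K_RANGE_DEFAULT = range(2, 7)
SUBSAMPLE_FRACTION = 0.30
N_REPLICATES = 30


@dataclass
class MorphAssignment:
    """Per-cell morph labels plus the clustering evidence behind them."""

    labels: pd.Series  # indexed like the feature table, values in 1..k
    chosen_k: int
    linkage_record: np.ndarray
    medoid_ids: dict[int, int] = field(default_factory=dict)
    validity_traces: pd.DataFrame | None = None


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Drop metadata columns, keeping only catalogue features."""
    cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    return table[cols]


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score normalisation (sample SD, ddof=1).

    Zero-variance columns are removed (and logged); metadata columns pass
    through untouched.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    meta = [c for c in table.columns if c in METADATA_COLUMNS]
    feats = [c for c in table.columns if c not in METADATA_COLUMNS]
    X = table[feats].astype(float)
    sd = X.std(ddof=1)
    # Zero variance up to floating-point noise (a bitwise-constant column can
    # report sd ~ 1e-17 through the sum-of-squares path) counts as constant.
    keep = sd > (X.abs().mean() + 1e-12) * 1e-12
    dropped = [c for c in feats if not keep[c]]
    if dropped:
        logger.info("zscore: removed %d zero-variance columns: %s", len(dropped), dropped)
    if not any(keep):
        raise ValueError("all feature columns have zero variance")
    Z = (X.loc[:, keep] - X.loc[:, keep].mean()) / sd[keep]
    return pd.concat([table[meta], Z], axis=1)


def _ward_labels(X: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def estimate_k(
    table: pd.DataFrame,
    k_range: range = K_RANGE_DEFAULT,
    n_reps: int = N_REPLICATES,
    frac: float = SUBSAMPLE_FRACTION,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Consensus cluster count from subsampled validity indices.

    Returns (chosen_k, traces) where traces has one row per (replicate, k)
    with the silhouette and Davies-Bouldin values of the Ward partition of
    that subsample.
    """
    X = feature_matrix(table).to_numpy(dtype=float)
    n = len(X)
    m = int(round(frac * n))
    if n < 10 / frac:
        raise ValueError(f"need at least {int(10 / frac)} rows, got {n}")
    if max(k_range) >= m:
        raise ValueError("k_range exceeds the subsample size")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        sub = X[idx]
        for k in k_range:
            labels = _ward_labels(sub, k)
            rows.append(
                {
                    "replicate": rep,
                    "k": k,
                    "silhouette": silhouette_score(sub, labels),
                    "davies_bouldin": davies_bouldin_score(sub, labels),
                }
            )
    traces = pd.DataFrame(rows)
    med = traces.groupby("k").median(numeric_only=True)
    best_sil = med["silhouette"].max()
    candidates = med.index[med["silhouette"] >= best_sil - 1e-12]
    chosen_k = int(max(candidates))  # ties toward finer structure
    db_best = int(med["davies_bouldin"].idxmin())
    logger.info(
        "estimate_k: silhouette argmax k=%s (median %.3f), Davies-Bouldin argmin "
        "k=%s -> chosen k=%d",
        list(candidates),
        best_sil,
        db_best,
        chosen_k,
    )
    return chosen_k, traces


def cluster_morphs(table: pd.DataFrame, k: int) -> MorphAssignment:
    """Ward-variance agglomeration over all z-scored features, cut at k.

    Deterministic for fixed input.  Labels are canonicalised by ascending
    median ``cell_circularity`` when that feature is present (else by
    descending cluster size).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = feature_matrix(table).to_numpy(dtype=float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds {len(X)} rows")
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _canonical_labels(raw, table)
    assignment = MorphAssignment(
        labels=pd.Series(labels, index=table.index, name="morph"),
        chosen_k=k,
        linkage_record=Z,
    )
    assignment.medoid_ids = medoids(table, assignment)
    return assignment


def _canonical_labels(raw: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    clusters = list(np.unique(raw))
    has_shape = "cell_circularity" in table.columns and "cell_area" in table.columns
    if has_shape and len(clusters) == 3:
        # morph 1: least circular (irregular); of the rest, morph 2 is the
        # larger-footprint cluster and morph 3 the small round one.
        circ = {
            c: float(table.loc[raw == c, "cell_circularity"].median()) for c in clusters
        }
        area = {c: float(table.loc[raw == c, "cell_area"].median()) for c in clusters}
        c1 = min(clusters, key=lambda c: circ[c])
        rest = [c for c in clusters if c != c1]
        c2 = max(rest, key=lambda c: area[c])
        c3 = [c for c in rest if c != c2][0]
        mapping = {c1: 1, c2: 2, c3: 3}
    elif "cell_area" in table.columns:
        order = sorted(
            clusters,
            key=lambda c: -float(table.loc[raw == c, "cell_area"].median()),
        )
        mapping = {c: i + 1 for i, c in enumerate(order)}
    else:
        order = sorted(clusters, key=lambda c: -(raw == c).sum())
        mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in raw])


def medoids(table: pd.DataFrame, assignment: MorphAssignment) -> dict[int, int]:
    """Per-cluster medoid: the member minimising mean distance to co-members.

    Ties break toward the lowest cell id (row index).  Returns
    {morph label -> row index of medoid}.
    """
    X = feature_matrix(table).to_numpy(dtype=float)
    out: dict[int, int] = {}
    labels = assignment.labels.to_numpy()
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        sub = X[idx]
        d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2))
        mean_d = d.mean(axis=1)
        best = idx[int(np.argmin(mean_d))]  # argmin takes the first == lowest id
        out[int(lab)] = int(table.index[best])
    return out


def feature_importance_mi(
    table: pd.DataFrame, labels: pd.Series | np.ndarray, seed: int = 0
) -> pd.Series:
    """Mutual information of each feature with the cluster label, ranked.

    Nearest-neighbour MI estimator with 3 neighbours and a fixed seed;
    estimator noise is clipped at 0.
    """
    X = feature_matrix(table)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 clusters")
    mi = mutual_info_classif(
        X.to_numpy(dtype=float), y, n_neighbors=3, random_state=seed
    )
    return pd.Series(np.clip(mi, 0.0, None), index=X.columns).sort_values(
        ascending=False
    )


def composition_by_condition(
    labels: pd.Series | np.ndarray,
    metadata: pd.DataFrame,
    group_col: str = "stiffness_kpa",
) -> pd.DataFrame:
    """Morph composition per condition with scene-grouped t-based 95% CIs.

    Proportions are first computed per scene; the per-condition mean and its
    95% CI are then taken across scenes (CIs are flagged unavailable when a
    condition has fewer than 2 scenes).
    """
    from scipy import stats as sps

    df = metadata[["scene_id", group_col]].copy()
    df["morph"] = np.asarray(labels)
    morphs = sorted(df["morph"].unique())
    scene_props = (
        df.groupby(["scene_id", group_col])["morph"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=morphs, fill_value=0.0)
        .reset_index()
    )
    rows = []
    for cond, sub in scene_props.groupby(group_col):
        for morph in morphs:
            vals = sub[morph].to_numpy(dtype=float)
            mean = float(vals.mean())
            if len(vals) >= 2:
                sem = vals.std(ddof=1) / np.sqrt(len(vals))
                tcrit = sps.t.ppf(0.975, df=len(vals) - 1)
                lo, hi = mean - tcrit * sem, mean + tcrit * sem
            else:
                lo = hi = float("nan")
            rows.append(
                {
                    group_col: cond,
                    "morph": morph,
                    "proportion": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_scenes": len(vals),
                }
            )
    return pd.DataFrame(rows)
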