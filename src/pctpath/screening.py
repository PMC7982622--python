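"""ROC-AUC + PCA feature screening.

The screening chain reduces the 49-feature texture panel to the subset
that actually discriminates lesion stages:

1. per-feature ROC AUC (rank-sum / Mann-Whitney formulation with tie
   correction), folded to max(AUC, 1-AUC) so anti-correlated features are
   not discarded; with multiclass stage labels the default contrast is
   stage-vs-rest, keeping each feature's maximum folded AUC;
2. keep features with folded AUC above a threshold (default 0.75);
3. PCA on the standardized selected features (eigendecomposition of the
   correlation matrix); retain components with eigenvalue > 1 (Kaiser
   criterion) and report the cumulative contribution rate against 90%;
4. per-stage mean +/- SD of the per-sample sum of retained component
   scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ScreeningResult",
    "feature_auc",
    "select_features",
    "pca_screen",
    "stage_scores",
    "screen_pipeline",
]


@dataclass
class ScreeningResult:
    """Outputs of the AUC + PCA screening chain."""

    auc_table: pd.DataFrame | None = None        # feature, auc (folded), sorted desc
    selected: list[str] = field(default_factory=list)
    eigenvalues: np.ndarray | None = None        # all, descending
    contribution_rates: np.ndarray | None = None  # percent of total variance
    cumulative_rate: float | None = None         # of the retained set, percent
    n_retained: int | None = None
    loadings: np.ndarray | None = None           # (n_features, n_retained)
    scores: np.ndarray | None = None             # (n_samples, n_retained)
    stage_summary: pd.DataFrame | None = None    # stage, mean, sd, n


def feature_auc(values, labels) -> float:
    """ROC AUC of one feature against binary labels (1 = positive class).

    Mann-Whitney formulation: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos *
    n_neg) with midranks, so tied pairs contribute 1/2.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(x)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _folded_auc(values, labels) -> float:
    auc = feature_auc(values, labels)
    return max(auc, 1.0 - auc)


def select_features(
    feature_matrix,
    labels,
    threshold: float = 0.75,
) -> tuple[list[str], pd.DataFrame]:
    """Per-feature folded AUC screening at the given threshold.

    ``feature_matrix`` is a DataFrame (or array) of samples x features;
    ``labels`` may be binary or multiclass stage labels.  For multiclass
    labels each feature's AUC is the maximum folded AUC over the
    one-vs-rest contrasts.  Returns the selected feature names and the
    full AUC table sorted descending.
    """
    if isinstance(feature_matrix, pd.DataFrame):
        X = feature_matrix.to_numpy(dtype=float)
        names = list(feature_matrix.columns)
    else:
        X = np.asarray(feature_matrix, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels must contain at least two classes")
    contrasts = [y == classes[1]] if classes.size == 2 else [y == c for c in classes]
    aucs = np.array(
        [max(_folded_auc(X[:, j], c) for c in contrasts) for j in range(X.shape[1])]
    )
    table = (
        pd.DataFrame({"feature": names, "auc": aucs})
        .sort_values("auc", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    selected = [n for n, a in zip(names, aucs) if a > threshold]
    return selected, table


def pca_screen(selected_matrix, kaiser: float = 1.0) -> ScreeningResult:
    """PCA of standardized features with Kaiser eigenvalue retention.

    Features are z-scored; the correlation matrix is eigendecomposed;
    components are sorted by eigenvalue descending and those with
    eigenvalue > ``kaiser`` are retained.  Component signs are fixed so
    each retained component's largest-magnitude loading is positive.
    Zero-variance features are dropped with a warning beforehand.
    """
    if isinstance(selected_matrix, pd.DataFrame):
        X = selected_matrix.to_numpy(dtype=float)
        names = list(selected_matrix.columns)
    else:
        X = np.asarray(selected_matrix, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    usable = sd > 0
    if not np.all(usable):
        warnings.warn(
            f"dropping {int(np.sum(~usable))} zero-variance feature(s) before PCA",
            RuntimeWarning,
            stacklevel=2,
        )
        X, names = X[:, usable], [n for n, u in zip(names, usable) if u]
        sd = sd[usable]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 usable features for PCA")

    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    retained = eigvals > kaiser
    n_ret = int(np.sum(retained))
    load = eigvecs[:, :n_ret].copy()
    for k in range(n_ret):                        # sign convention
        if load[np.argmax(np.abs(load[:, k])), k] < 0:
            load[:, k] = -load[:, k]
    contrib = eigvals / eigvals.sum() * 100.0
    result = ScreeningResult(
        selected=names,
        eigenvalues=eigvals,
        contribution_rates=contrib,
        cumulative_rate=float(contrib[:n_ret].sum()),
        n_retained=n_ret,
        loadings=load,
        scores=Z @ load,
    )
    return result


def stage_scores(scores, stage_labels, stage_order=None) -> pd.DataFrame:
    """Per-stage mean +/- SD of the summed retained-component scores.

    Each sample's summed score is the sum of its retained component
    scores; samples are grouped by stage and the group mean, SD (ddof=1)
    and size are reported in stage order.
    """
    s = np.asarray(scores, dtype=float)
    summed = s.sum(axis=1) if s.ndim == 2 else s
    stages = np.asarray(stage_labels)
    if stages.size != summed.size:
        raise ValueError("one stage label per sample required")
    order = list(stage_order) if stage_order is not None else sorted(set(stages.tolist()))
    rows = []
    for stage in order:
        sel = summed[stages == stage]
        if sel.size == 0:
            raise ValueError(f"stage {stage!r} has no samples")
        rows.append({
            "stage": stage,
            "mean": float(sel.mean()),
            "sd": float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
            "n": int(sel.size),
        })
    return pd.DataFrame(rows)


def screen_pipeline(
    feature_table: pd.DataFrame,
    stage_col: str = "label",
    auc_threshold: float = 0.75,
) -> ScreeningResult:
    """Full chain: folded-AUC selection, PCA retention, stage summaries."""
    stages = feature_table[stage_col].to_numpy()
    X = feature_table.drop(columns=[stage_col])
    selected, table = select_features(X, stages, threshold=auc_threshold)
    if len(selected) < 2:
        raise ValueError("fewer than 2 features passed the AUC threshold")
    result = pca_screen(X[selected])
    result.auc_table = table
    result.stage_summary = stage_scores(result.scores, stages)
    return result
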