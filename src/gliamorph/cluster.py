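"""Phenotypic clustering in (CI, CEA) space and sub-population assignment.

Two complementary views of the same feature plane:

* unsupervised k-means (k = 4 by default) on z-scored (CI, CEA), with
  clusters renumbered by descending frequency;
* supervised quadrant classes SP1-SP4 cut at the control-group means:
  SP1 = low CEA / low CI (-/-), SP2 = low CEA / high CI (-/+),
  SP3 = high CEA / low CI (+/-), SP4 = high CEA / high CI (+/+).

Amoeboid cells (CI = 1, no branch nodes) play a distinct functional role
and are excluded from both by default; ``include_amoeboid=True`` restores
them for sensitivity analysis.  A correlation/PCA screen checks that CI
and CEA are not collinear before clustering is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .errors import DataError

__all__ = [
    "ClusterModel",
    "SubPopulationCutoffs",
    "SUBPOPULATION_LABELS",
    "feature_correlation_screen",
    "kmeans_ci_cea",
    "compute_cutoffs",
    "assign_subpopulations",
    "subpopulation_frequencies",
]

FEATURES = ("CI", "CEA_um2")
SUBPOPULATION_LABELS = ("SP1", "SP2", "SP3", "SP4", "amoeboid")


def _non_amoeboid(records: pd.DataFrame, include_amoeboid: bool) -> pd.DataFrame:
    if include_amoeboid:
        return records
    if "is_amoeboid" in records.columns:
        return records[~records["is_amoeboid"].astype(bool)]
    return records[records["CI"] > 1.0]


@dataclass
class CorrelationScreen:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    pca_loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    collinearity_warning: bool
    undefined: bool = False


def feature_correlation_screen(records: pd.DataFrame) -> CorrelationScreen:
    """Pearson/Spearman correlation of CI vs CEA plus 2-feature PCA.

    Flags collinearity when |r| > 0.7; a constant feature yields an
    undefined-correlation flag instead of a number.
    """
    if len(records) < 3:
        raise DataError("need at least 3 cells for the correlation screen")
    x = records["CI"].to_numpy(dtype=float)
    y = records["CEA_um2"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationScreen(
            np.nan, np.nan, np.nan, np.nan, np.full((2, 2), np.nan),
            np.full(2, np.nan), collinearity_warning=False, undefined=True,
        )
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    z = np.column_stack([(x - x.mean()) / x.std(), (y - y.mean()) / y.std()])
    cov = np.cov(z.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return CorrelationScreen(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        pca_loadings=evecs[:, order].T,
        explained_variance_ratio=evals[order] / evals.sum(),
        collinearity_warning=bool(abs(pr.statistic) > 0.7),
    )


@dataclass
class ClusterModel:
    """Fitted k-means state on (CI, CEA), in canonical frequency order."""

    k: int
    feature_names: tuple[str, str]
    mean_: np.ndarray
    scale_: np.ndarray
    centroids_std: np.ndarray  # (k, 2) in z-score units, frequency-ordered
    centroids_raw: np.ndarray  # (k, 2) in (CI, um^2) units
    labels: np.ndarray  # per-cell cluster index, 0 = most frequent
    frequencies: np.ndarray
    seed: int
    n_init: int
    inertia: float
    record_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def transform(self, records: pd.DataFrame) -> np.ndarray:
        z = (records[list(self.feature_names)].to_numpy(dtype=float) - self.mean_) / self.scale_
        d = ((z[:, None, :] - self.centroids_std[None]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "feature_names": list(self.feature_names),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "centroids_std": self.centroids_std.tolist(),
            "centroids_raw": self.centroids_raw.tolist(),
            "frequencies": self.frequencies.tolist(),
            "seed": self.seed,
            "n_init": self.n_init,
            "inertia": self.inertia,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            feature_names=tuple(d["feature_names"]),
            mean_=np.asarray(d["mean"]),
            scale_=np.asarray(d["scale"]),
            centroids_std=np.asarray(d["centroids_std"]),
            centroids_raw=np.asarray(d["centroids_raw"]),
            labels=np.empty(0, dtype=int),
            frequencies=np.asarray(d["frequencies"]),
            seed=d["seed"],
            n_init=d["n_init"],
            inertia=d["inertia"],
        )


def kmeans_ci_cea(
    records: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    include_amoeboid: bool = False,
) -> ClusterModel:
    """k-means clustering of cells in z-scored (CI, CEA).

    CEA spans hundreds to thousands of um^2 while CI stays below ~10, so
    the features are standardized before clustering; k-means++ with
    ``n_init`` restarts keeps the best inertia.  Clusters are renumbered
    by descending frequency (cluster 0 = most frequent).
    """
    sub = _non_amoeboid(records, include_amoeboid)
    X = sub[list(FEATURES)].to_numpy(dtype=float)
    if len(X) < k:
        raise DataError(f"need at least k={k} non-amoeboid cells, got {len(X)}")
    if len(np.unique(X, axis=0)) < k:
        raise DataError("fewer than k distinct points: clustering degenerate")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(Z)
    counts = np.bincount(raw_labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw_labels]
    centroids_std = km.cluster_centers_[order]
    return ClusterModel(
        k=k,
        feature_names=FEATURES,
        mean_=mean,
        scale_=scale,
        centroids_std=centroids_std,
        centroids_raw=centroids_std * scale + mean,
        labels=labels,
        frequencies=counts[order] / counts.sum(),
        seed=seed,
        n_init=n_init,
        inertia=float(km.inertia_),
        record_index=sub.index.to_numpy(),
    )


@dataclass
class SubPopulationCutoffs:
    """Quadrant cutoffs: control-group mean CI and CEA."""

    ci_cutoff: float
    cea_cutoff_um2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ci_cutoff) and np.isfinite(self.cea_cutoff_um2)):
            raise DataError("cutoffs must be finite")
        if self.ci_cutoff <= 0 or self.cea_cutoff_um2 <= 0:
            raise DataError("cutoffs must be positive")


def compute_cutoffs(
    control_records: pd.DataFrame, include_amoeboid: bool = False
) -> SubPopulationCutoffs:
    """Cell-pooled arithmetic means of CI and CEA over the control group."""
    sub = _non_amoeboid(control_records, include_amoeboid)
    if sub.empty:
        raise DataError("empty control set")
    return SubPopulationCutoffs(
        ci_cutoff=float(sub["CI"].mean()),
        cea_cutoff_um2=float(sub["CEA_um2"].mean()),
    )


def assign_subpopulations(
    records: pd.DataFrame,
    cutoffs: SubPopulationCutoffs,
    include_amoeboid: bool = False,
) -> pd.Series:
    """Label each cell SP1-SP4 by its (CI, CEA) quadrant, or amoeboid.

    "High" means strictly greater than the cutoff; values exactly at the
    cutoff are low (deterministic tie-break).  Amoeboid cells (CI = 1)
    are labelled separately regardless of CEA unless ``include_amoeboid``.
    """
    ci_high = records["CI"].to_numpy(dtype=float) > cutoffs.ci_cutoff
    cea_high = records["CEA_um2"].to_numpy(dtype=float) > cutoffs.cea_cutoff_um2
    quadrant = np.select(
        [
            ~cea_high & ~ci_high,
            ~cea_high & ci_high,
            cea_high & ~ci_high,
            cea_high & ci_high,
        ],
        ["SP1", "SP2", "SP3", "SP4"],
        default="SP1",
    )
    if not include_amoeboid:
        if "is_amoeboid" in records.columns:
            amoe = records["is_amoeboid"].astype(bool).to_numpy()
        else:
            amoe = records["CI"].to_numpy(dtype=float) <= 1.0
        quadrant = np.where(amoe, "amoeboid", quadrant)
    return pd.Series(quadrant, index=records.index, name="subpopulation")


def subpopulation_frequencies(
    labels: pd.Series, grouping: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-group SP1-SP4 proportions (amoeboid frequency reported aside).

    ``grouping`` may carry ``region``/``condition`` columns aligned with
    the labels; rows sum to 1 over SP1-SP4.
    """
    df = pd.DataFrame({"subpopulation": labels})
    if grouping is not None:
        for col in ("region", "condition"):
            if col in grouping.columns:
                df[col] = grouping[col].to_numpy()
    group_cols = [c for c in ("region", "condition") if c in df.columns]
    out_rows = []
    groups = df.groupby(group_cols, sort=True) if group_cols else [((), df)]
    for key, sub in groups:
        if sub.empty:
            continue
        sp = sub[sub["subpopulation"] != "amoeboid"]
        n_sp = len(sp)
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        for lbl in ("SP1", "SP2", "SP3", "SP4"):
            row[lbl] = (sp["subpopulation"] == lbl).sum() / n_sp if n_sp else np.nan
        row["amoeboid_fraction"] = (sub["subpopulation"] == "amoeboid").mean()
        row["n_cells"] = len(sub)
        out_rows.append(row)
    return pd.DataFrame(out_rows)
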