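"""Multi-metric proximity ranking of field cultivars against ideotypes.

Coefficient vectors are min-max scaled over the combined cultivar +
ideotype set (raw scales span four orders of magnitude), distances are
computed under Euclidean, Manhattan and cosine metrics, each metric is
normalized by its own maximum before averaging, and the averaged distance
is mapped to a similarity score ``1 - d/max(d)`` in [0, 1]. Top-k lists per
metric feed a frequency consensus; a PCA projection provides an
independent check of the rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "CultivarPanel",
    "SimilarityReport",
    "PCAResult",
    "scale_panel",
    "pairwise_distances",
    "similarity_index",
    "topk_frequency",
    "pca_validate",
    "analyze",
    "DEFAULT_METRICS",
    "PANEL_COEFFICIENTS",
]

PANEL_COEFFICIENTS = ("P1", "P5", "P2R", "PHINT", "P2O", "G1", "G2", "G3")
DEFAULT_METRICS = ("euclidean", "manhattan", "cosine")
GROUPS = ("indica", "japonica", "hybrid", "ideotype")


@dataclass
class CultivarPanel:
    """Named, group-labeled coefficient vectors over the 8-coefficient set."""

    names: list[str]
    groups: list[str]
    values: np.ndarray  # (n, 8)
    coefficients: tuple[str, ...] = PANEL_COEFFICIENTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.groups) or len(self.names) != self.values.shape[0]:
            raise ValueError("names/groups/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("cultivar names must be unique")
        if self.values.shape[1] != len(self.coefficients):
            raise ValueError("coefficient column mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel contains missing or non-finite values")

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.coefficients))
        frame.insert(0, "group", self.groups)
        frame.insert(0, "name", self.names)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CultivarPanel":
        frame = pd.read_csv(path)
        missing = [c for c in ("name", "group", *PANEL_COEFFICIENTS) if c not in frame]
        if missing:
            raise ValueError(f"panel CSV missing columns: {missing}")
        return cls(
            names=frame["name"].astype(str).tolist(),
            groups=frame["group"].astype(str).tolist(),
            values=frame[list(PANEL_COEFFICIENTS)].to_numpy(dtype=float),
        )

    @classmethod
    def concat(cls, *panels: "CultivarPanel") -> "CultivarPanel":
        return cls(
            names=[n for p in panels for n in p.names],
            groups=[g for p in panels for g in p.groups],
            values=np.vstack([p.values for p in panels]),
        )


def scale_panel(values: np.ndarray) -> np.ndarray:
    """Per-column min-max scaling to [0, 1]; constant columns map to zero."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=0)
    rng = values.max(axis=0) - lo
    out = np.zeros_like(values)
    nz = rng > 0
    out[:, nz] = (values[:, nz] - lo[nz]) / rng[nz]
    return out


def pairwise_distances(
    ideotypes: np.ndarray,
    cultivars: np.ndarray,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> np.ndarray:
    """Distance tensor of shape (n_ideotypes, n_cultivars, n_metrics).

    Cosine distance is 1 - cosine similarity; any pair involving an all-zero
    vector gets cosine distance 1 by convention.
    """
    ideotypes = np.atleast_2d(np.asarray(ideotypes, dtype=float))
    cultivars = np.atleast_2d(np.asarray(cultivars, dtype=float))
    if ideotypes.shape[1] != cultivars.shape[1]:
        raise ValueError("dimension mismatch between ideotypes and cultivars")
    tensor = np.empty((ideotypes.shape[0], cultivars.shape[0], len(metrics)))
    for m, metric in enumerate(metrics):
        if metric == "manhattan":
            d = cdist(ideotypes, cultivars, metric="cityblock")
        elif metric == "cosine":
            d = cdist(ideotypes, cultivars, metric="cosine")
            zero_i = np.linalg.norm(ideotypes, axis=1) == 0
            zero_c = np.linalg.norm(cultivars, axis=1) == 0
            d[zero_i, :] = 1.0
            d[:, zero_c] = 1.0
        else:
            d = cdist(ideotypes, cultivars, metric=metric)
        tensor[:, :, m] = d
    return tensor


def similarity_index(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(averaged distance, similarity) matrices from the distance tensor.

    Each metric slice is divided by its own maximum before averaging, so no
    metric dominates by magnitude; similarity is ``1 - d/max(d)``. All-equal
    inputs (max distance 0) define similarity 1 everywhere.
    """
    tensor = np.asarray(tensor, dtype=float)
    scaled = np.zeros_like(tensor)
    for m in range(tensor.shape[2]):
        mx = tensor[:, :, m].max()
        if mx > 0:
            scaled[:, :, m] = tensor[:, :, m] / mx
    dbar = scaled.mean(axis=2)
    dmax = dbar.max()
    if dmax == 0:
        return dbar, np.ones_like(dbar)
    return dbar, 1.0 - dbar / dmax


def topk_frequency(
    tensor: np.ndarray,
    cultivar_names: Sequence[str],
    ideotype_names: Sequence[str],
    k: int = 4,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-ideotype frequency tables and the aggregated global ranking.

    For each ideotype the top-k nearest cultivars under every metric are
    concatenated and counted. Ties sort by lower averaged distance, then by
    name; the global ranking aggregates frequencies over ideotypes.
    """
    n_ideo, n_cult, n_metrics = tensor.shape
    if k > n_cult:
        raise ValueError(f"k={k} exceeds cultivar count {n_cult}")
    dbar, _ = similarity_index(tensor)
    per_ideotype: dict[str, pd.DataFrame] = {}
    global_counts: dict[str, int] = {}
    for v, ideo in enumerate(ideotype_names):
        counts: dict[str, int] = {}
        for m in range(n_metrics):
            order = np.lexsort((np.array(cultivar_names, dtype=object), tensor[v, :, m]))
            for idx in order[:k]:
                name = cultivar_names[idx]
                counts[name] = counts.get(name, 0) + 1
                global_counts[name] = global_counts.get(name, 0) + 1
        rows = [
            {
                "cultivar": name,
                "frequency": freq,
                "avg_distance": dbar[v, list(cultivar_names).index(name)],
            }
            for name, freq in counts.items()
        ]
        frame = pd.DataFrame(rows).sort_values(
            by=["frequency", "avg_distance", "cultivar"],
            ascending=[False, True, True],
        ).reset_index(drop=True)
        per_ideotype[ideo] = frame
    mean_dbar = dbar.mean(axis=0)
    global_rows = [
        {
            "cultivar": name,
            "frequency": freq,
            "mean_avg_distance": mean_dbar[list(cultivar_names).index(name)],
        }
        for name, freq in global_counts.items()
    ]
    global_ranking = pd.DataFrame(global_rows).sort_values(
        by=["frequency", "mean_avg_distance", "cultivar"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
    return per_ideotype, global_ranking


@dataclass
class PCAResult:
    scores: np.ndarray              # (n, n_components)
    variance_fractions: np.ndarray
    components: np.ndarray          # (n_components, n_features)
    pc_distances: np.ndarray        # ideotypes x cultivars, top-3 PC space
    nearest: dict[str, list[str]]   # per ideotype, by PC-space distance


def pca_validate(
    values: np.ndarray,
    ideotype_index: Sequence[int],
    cultivar_index: Sequence[int],
    names: Sequence[str],
    n_components: int = 3,
    top_k: int = 4,
) -> PCAResult:
    """Z-score PCA of the combined matrix; distances in top-PC space.

    Rank-deficient inputs are truncated to components with positive
    variance. Euclidean nearest cultivars per ideotype in the leading
    component space are reported as an independent validation of the
    metric-consensus ranking.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("PCA needs at least 3 entries")
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    # SVD of the centered matrix == eigendecomposition of the covariance
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2 / values.shape[0]
    keep = var > 1e-12 * max(var.max(), 1.0)
    s, vt, var = s[keep], vt[keep], var[keep]
    fractions = var / var.sum()
    scores = z @ vt.T
    n_comp = min(n_components, scores.shape[1])
    top = scores[:, :n_comp]
    ideo = np.asarray(ideotype_index, dtype=int)
    cult = np.asarray(cultivar_index, dtype=int)
    pc_dist = cdist(top[ideo], top[cult])
    nearest = {}
    cult_names = [names[i] for i in cult]
    for row, i in enumerate(ideo):
        order = np.lexsort((np.array(cult_names, dtype=object), pc_dist[row]))
        nearest[names[i]] = [cult_names[j] for j in order[:top_k]]
    return PCAResult(
        scores=scores,
        variance_fractions=fractions,
        components=vt,
        pc_distances=pc_dist,
        nearest=nearest,
    )


@dataclass
class SimilarityReport:
    ideotype_names: list[str]
    cultivar_names: list[str]
    metrics: tuple[str, ...]
    distance_tensor: np.ndarray
    avg_distance: np.ndarray
    similarity: np.ndarray
    per_ideotype_frequency: dict[str, pd.DataFrame]
    global_ranking: pd.DataFrame
    pca: PCAResult | None

    def similarity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.similarity, index=self.ideotype_names, columns=self.cultivar_names
        )

    def export(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.similarity_frame().to_csv(outdir / "similarity_matrix.csv")
        self.global_ranking.to_csv(outdir / "frequency_global.csv", index=False)
        for ideo, frame in self.per_ideotype_frequency.items():
            frame.to_csv(outdir / f"frequency_{ideo}.csv", index=False)
        if self.pca is not None:
            pd.DataFrame(
                self.pca.scores,
                index=self.ideotype_names + self.cultivar_names,
                columns=[f"PC{i+1}" for i in range(self.pca.scores.shape[1])],
            ).to_csv(outdir / "pca_scores.csv")


def analyze(
    ideotypes: CultivarPanel,
    cultivars: CultivarPanel,
    metrics: Sequence[str] = DEFAULT_METRICS,
    k: int = 4,
    with_pca: bool = True,
) -> SimilarityReport:
    """Full similarity layer: scale -> distances -> consensus -> PCA check."""
    combined = np.vstack([ideotypes.values, cultivars.values])
    scaled = scale_panel(combined)
    n_ideo = len(ideotypes)
    tensor = pairwise_distances(scaled[:n_ideo], scaled[n_ideo:], metrics)
    dbar, sim = similarity_index(tensor)
    per_ideo, global_rank = topk_frequency(
        tensor, cultivars.names, ideotypes.names, k=min(k, len(cultivars))
    )
    pca = None
    if with_pca and combined.shape[0] >= 3:
        pca = pca_validate(
            combined,
            ideotype_index=range(n_ideo),
            cultivar_index=range(n_ideo, combined.shape[0]),
            names=ideotypes.names + cultivars.names,
            top_k=min(k, len(cultivars)),
        )
    return SimilarityReport(
        ideotype_names=list(ideotypes.names),
        cultivar_names=list(cultivars.names),
        metrics=tuple(metrics),
        distance_tensor=tensor,
        avg_distance=dbar,
        similarity=sim,
        per_ideotype_frequency=per_ideo,
        global_ranking=global_rank,
        pca=pca,
    )
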