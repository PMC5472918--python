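"""Movement-pattern classification with a self-organizing map (SOM).

The six movement parameters of every 5-s segment, min-max normalized to
[0, 1], are projected onto a 14 x 10 Kohonen grid.  For an input vector x the
winning node (best matching unit, BMU) minimizes the Euclidean distance

    d_j = sqrt(sum_i (x_i - w_ij)^2),       i = 1..P parameters,

and the codebook is updated toward the input,

    w_ij(t+1) = w_ij(t) + alpha(t) * h_j(t) * (x_i - w_ij(t)),

with a Gaussian neighborhood h_j = exp(-dist_grid(j, bmu)^2 / (2 radius^2))
that equals 1 at the BMU.  Training is sequential over randomly sampled rows
in two phases (rough ordering, then fine tuning) with linearly decaying
learning rate and radius.

The trained codebook is grouped by Ward-linkage hierarchical clustering into
nine clusters (linkage heights rescaled to 0-100%), and the nine clusters are
mapped onto four movement patterns -- active, circling, zigzag, and stop --
by ranking cluster profiles (fixed 3/1/3/2 partition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, ward
from scipy.spatial.distance import cdist, pdist

from .kinematics import FEATURE_COLUMNS, LABEL_COLUMNS

GRID_ROWS, GRID_COLS = 14, 10
N_CLUSTERS = 9
PATTERNS = ("active", "circling", "zigzag", "stop")
#: Number of clusters assigned to each pattern (3 active + 1 circling +
#: 3 zigzag + 2 stop partitions the nine clusters).
PATTERN_SIZES = {"active": 3, "circling": 1, "zigzag": 3, "stop": 2}

#: Two-phase training schedule: linear decay of learning rate and Gaussian
#: neighborhood radius within each phase; iterations = passes * n_rows capped
#: per phase so training time is bounded on large cohorts.
DEFAULT_SCHEDULE = {
    "phases": [
        {"passes": 10, "alpha": (0.5, 0.05), "radius": (5.0, 1.0), "max_iterations": 150_000},
        {"passes": 40, "alpha": (0.05, 0.01), "radius": (1.0, 0.5), "max_iterations": 600_000},
    ]
}


class DegenerateScaleError(ValueError):
    """A parameter column is constant and cannot be min-max scaled."""


class LabelingError(ValueError):
    """The cluster profiles do not support the 4-pattern labeling rule."""


class ClassificationError(ValueError):
    """The feature table does not match the model's normalization bounds."""


@dataclass
class SOMModel:
    """A trained (or freshly initialized) 14 x 10 codebook.

    ``weights`` has one row per node in row-major grid order; ``bounds`` holds
    the per-parameter (min, max) used for normalization so later data can be
    scaled identically.
    """

    weights: np.ndarray
    bounds: pd.DataFrame
    rows: int = GRID_ROWS
    cols: int = GRID_COLS
    feature_names: tuple[str, ...] = FEATURE_COLUMNS
    schedule: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_SCHEDULE)))
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.rows * self.cols, len(self.feature_names)):
            raise ValueError("weights shape does not match grid and parameters")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        b = self.bounds
        if not np.all(b["max"].to_numpy() > b["min"].to_numpy()):
            raise ValueError("normalization bounds must have max > min")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def grid_coordinates(self) -> np.ndarray:
        """(n_nodes, 2) array of (row, col) positions, row-major."""
        r, c = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([r, c]).astype(float)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "bounds": {
                "min": self.bounds["min"].tolist(),
                "max": self.bounds["max"].tolist(),
            },
            "schedule": self.schedule,
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMModel":
        payload = json.loads(Path(path).read_text())
        names = tuple(payload["feature_names"])
        bounds = pd.DataFrame(
            {"min": payload["bounds"]["min"], "max": payload["bounds"]["max"]},
            index=list(names),
        )
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            bounds=bounds,
            rows=payload["rows"],
            cols=payload["cols"],
            feature_names=names,
            schedule=payload["schedule"],
            seed=payload["seed"],
        )


def _feature_matrix(table: pd.DataFrame | np.ndarray, names: Sequence[str]) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        missing = [c for c in names if c not in table.columns]
        if missing:
            raise ClassificationError(f"feature column(s) missing: {missing}")
        return table[list(names)].to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def normalize_features(
    table: pd.DataFrame,
    bounds: pd.DataFrame | None = None,
    feature_names: Sequence[str] = FEATURE_COLUMNS,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Min-max scale each parameter to [0, 1].

    When ``bounds`` is None they are computed from the data (NaN-ignoring min
    and max) and returned for reuse; when given, values outside them are
    clipped.  Undefined entries (NaN meander / locomotory rate of fully
    stopped segments) are imputed as 0 *after* scaling -- a fully stopped
    segment is legitimately minimal-activity input -- and reported via the
    per-column ``<name>_undefined`` flags on the returned frame's ``attrs``.

    Returns ``(normalized, bounds, n_clipped)``.
    """
    X = _feature_matrix(table, feature_names)
    undefined = np.isnan(X)
    if bounds is None:
        with np.errstate(all="ignore"):
            lo = np.nanmin(X, axis=0)
            hi = np.nanmax(X, axis=0)
        if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)) or np.any(hi <= lo):
            bad = [
                feature_names[i]
                for i in range(len(feature_names))
                if not (np.isfinite(lo[i]) and np.isfinite(hi[i]) and hi[i] > lo[i])
            ]
            raise DegenerateScaleError(
                f"constant or empty parameter column(s): {bad}"
            )
        bounds = pd.DataFrame({"min": lo, "max": hi}, index=list(feature_names))
    lo = bounds["min"].to_numpy(dtype=float)
    hi = bounds["max"].to_numpy(dtype=float)
    Z = (X - lo) / (hi - lo)
    out_of_range = ((Z < 0) | (Z > 1)) & ~undefined
    n_clipped = int(out_of_range.sum())
    Z = np.clip(Z, 0.0, 1.0)
    Z[undefined] = 0.0
    norm = pd.DataFrame(Z, columns=list(feature_names), index=getattr(table, "index", None))
    norm.attrs["n_clipped"] = n_clipped
    norm.attrs["n_imputed"] = int(undefined.sum())
    return norm, bounds, n_clipped


def find_bmu(x: np.ndarray, model: SOMModel) -> int:
    """Index of the node minimizing Euclidean distance to ``x``; ties break to
    the lowest node index."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.weights.shape[1],):
        raise ValueError(
            f"input has {x.shape} entries, model expects {model.weights.shape[1]}"
        )
    d2 = ((model.weights - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def _bmu_batch(X: np.ndarray, model: SOMModel, chunk: int = 8192) -> np.ndarray:
    out = np.empty(len(X), dtype=int)
    for i in range(0, len(X), chunk):
        d = cdist(X[i : i + chunk], model.weights, metric="sqeuclidean")
        out[i : i + chunk] = np.argmin(d, axis=1)
    return out


def update_weights(
    model: SOMModel, x: np.ndarray, bmu: int, alpha: float, radius: float
) -> SOMModel:
    """One Kohonen update toward ``x`` (in place; the model is returned).

    h_j = exp(-grid_dist(j, bmu)^2 / (2 radius^2)); at radius <= 0 only the
    BMU moves (h = 1 there by convention).
    """
    x = np.asarray(x, dtype=float)
    coords = model.grid_coordinates()
    if radius <= 0:
        model.weights[bmu] += alpha * (x - model.weights[bmu])
        return model
    d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
    h = np.exp(-d2 / (2.0 * radius * radius))
    model.weights += alpha * h[:, None] * (x - model.weights)
    return model


def quantization_error(table: pd.DataFrame | np.ndarray, model: SOMModel) -> float:
    """Mean distance between each input row and its BMU's weights."""
    X = _feature_matrix(table, model.feature_names)
    if len(X) == 0:
        raise ValueError("empty table")
    best = np.full(len(X), np.inf)
    for i in range(0, len(X), 8192):
        d = cdist(X[i : i + 8192], model.weights)
        best[i : i + 8192] = d.min(axis=1)
    return float(best.mean())


def train_som(
    table: pd.DataFrame | np.ndarray,
    schedule: dict | None = None,
    seed: int = 0,
    rows: int = GRID_ROWS,
    cols: int = GRID_COLS,
    bounds: pd.DataFrame | None = None,
    feature_names: Sequence[str] = FEATURE_COLUMNS,
) -> SOMModel:
    """Train a SOM on a normalized feature table (values in [0, 1]).

    Weights are initialized uniformly at random from the seed; training is
    sequential over randomly sampled rows with the two-phase schedule.  The
    same seed and data give bit-identical models.
    """
    X = _feature_matrix(table, feature_names)
    if len(X) == 0:
        raise ValueError("empty training table")
    if np.isnan(X).any():
        raise ValueError("training table contains NaN; normalize (and impute) first")
    schedule = schedule if schedule is not None else DEFAULT_SCHEDULE
    rng = np.random.default_rng(seed)
    P = X.shape[1]
    n_nodes = rows * cols
    weights = rng.uniform(0.0, 1.0, size=(n_nodes, P))
    if bounds is None:
        bounds = pd.DataFrame(
            {"min": np.zeros(P), "max": np.ones(P)}, index=list(feature_names)
        )
    model = SOMModel(
        weights=weights,
        bounds=bounds,
        rows=rows,
        cols=cols,
        feature_names=tuple(feature_names),
        schedule=json.loads(json.dumps(schedule)),
        seed=seed,
    )
    coords = model.grid_coordinates()
    # pairwise squared grid distances, looked up per BMU during training
    gd2 = cdist(coords, coords, metric="sqeuclidean")
    n = len(X)
    W = model.weights
    for phase in schedule["phases"]:
        iters = int(phase["passes"]) * n
        cap = int(phase.get("max_iterations", iters))
        iters = min(iters, cap)
        if iters <= 0:
            continue
        a0, a1 = phase["alpha"]
        r0, r1 = phase["radius"]
        idx = rng.integers(0, n, size=iters)
        frac = np.linspace(0.0, 1.0, iters, endpoint=False)
        alphas = a0 + (a1 - a0) * frac
        radii = r0 + (r1 - r0) * frac
        inv2r2 = 1.0 / (2.0 * radii * radii)
        for t in range(iters):
            x = X[idx[t]]
            diff = x - W
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = np.exp(-gd2[bmu] * inv2r2[t])
            W += (alphas[t] * h)[:, None] * diff
    return model


@dataclass
class ClusterModel:
    """Ward clustering of the codebook plus the cluster -> pattern mapping.

    Cluster ids run 1..k in dendrogram leaf order; ``heights_pct`` are the
    linkage heights rescaled to 0-100%.
    """

    node_cluster: np.ndarray
    linkage: np.ndarray
    heights_pct: np.ndarray
    k: int
    pattern_map: dict[int, str] | None = None

    def patterns_of_nodes(self) -> np.ndarray:
        if self.pattern_map is None:
            raise LabelingError("clusters have not been labeled with patterns")
        return np.array([self.pattern_map[int(c)] for c in self.node_cluster])


def cluster_codebook(model: SOMModel, k: int = N_CLUSTERS) -> ClusterModel:
    """Agglomerative Ward clustering of the node weight vectors, cut at ``k``."""
    n = model.n_nodes
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    Z = ward(pdist(model.weights))
    heights = Z[:, 2]
    heights_pct = 100.0 * heights / heights.max() if heights.max() > 0 else heights
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 1..k in dendrogram leaf order for stable, readable ids
    order = leaves_list(Z)
    relabel: dict[int, int] = {}
    for node in order:
        c = int(raw[node])
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    node_cluster = np.array([relabel[int(c)] for c in raw])
    return ClusterModel(
        node_cluster=node_cluster, linkage=Z, heights_pct=heights_pct, k=k
    )


def label_patterns(model: SOMModel, clusters: ClusterModel) -> ClusterModel:
    """Map the nine clusters onto the four movement patterns (3/1/3/2).

    Clusters are ranked on their mean normalized codebook profiles: the two
    lowest-speed clusters are *stop*; of the rest, the three highest-meander
    clusters are *zigzag*; of the remaining four, the one with the highest
    meander-to-speed ratio is *circling*; the other three are *active*.
    """
    if clusters.k != N_CLUSTERS:
        raise LabelingError(f"pattern labeling requires k = {N_CLUSTERS} clusters")
    names = list(model.feature_names)
    i_speed = names.index("speed")
    i_meander = names.index("meander")
    ids = np.arange(1, clusters.k + 1)
    if any((clusters.node_cluster == c).sum() == 0 for c in ids):
        raise LabelingError(
            "degenerate clustering: some clusters are empty (no activity gradient)"
        )
    speed = np.array(
        [model.weights[clusters.node_cluster == c, i_speed].mean() for c in ids]
    )
    meander = np.array(
        [model.weights[clusters.node_cluster == c, i_meander].mean() for c in ids]
    )
    if speed.max() - speed.min() < 1e-9:
        raise LabelingError("no activity gradient across clusters")
    order_speed = np.argsort(speed, kind="stable")
    stop_ids = set(ids[order_speed[:2]])
    rest = [c for c in ids if c not in stop_ids]
    rest_meander = {c: meander[c - 1] for c in rest}
    zigzag_ids = set(sorted(rest, key=lambda c: -rest_meander[c])[:3])
    remaining = [c for c in rest if c not in zigzag_ids]
    ratio = {c: meander[c - 1] / max(speed[c - 1], 1e-9) for c in remaining}
    circling_id = max(remaining, key=lambda c: ratio[c])
    pattern_map: dict[int, str] = {}
    for c in ids:
        if c in stop_ids:
            pattern_map[int(c)] = "stop"
        elif c in zigzag_ids:
            pattern_map[int(c)] = "zigzag"
        elif c == circling_id:
            pattern_map[int(c)] = "circling"
        else:
            pattern_map[int(c)] = "active"
    return replace(clusters, pattern_map=pattern_map)


@dataclass
class EthogramResult:
    """Per-segment assignments and per-group pattern time budgets."""

    assignments: pd.DataFrame  # labels + node, cluster, pattern
    pattern_fractions: pd.DataFrame  # per (strain, treatment, session), % per pattern


def classify_segments(
    table: pd.DataFrame,
    model: SOMModel,
    clusters: ClusterModel,
) -> EthogramResult:
    """Assign every segment its BMU, cluster, and movement pattern, and compute
    per-group pattern percentages (segment counts / group total x 100).

    ``table`` is a raw (unnormalized) feature table with cohort labels; it is
    scaled with the model's stored bounds (out-of-range values clipped).
    """
    if clusters.pattern_map is None:
        raise LabelingError("clusters must be labeled before classification")
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ClassificationError(f"feature column(s) missing: {missing}")
    norm, _, _ = normalize_features(table, bounds=model.bounds, feature_names=model.feature_names)
    X = norm.to_numpy(dtype=float)
    nodes = _bmu_batch(X, model)
    cluster_ids = clusters.node_cluster[nodes]
    patterns = np.array([clusters.pattern_map[int(c)] for c in cluster_ids])
    label_cols = [c for c in LABEL_COLUMNS if c in table.columns]
    assignments = table[label_cols].copy()
    assignments["node"] = nodes
    assignments["cluster"] = cluster_ids
    assignments["pattern"] = patterns
    group_cols = [c for c in ("strain", "treatment", "session") if c in table.columns]
    if group_cols:
        counts = (
            assignments.groupby(group_cols)["pattern"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=list(PATTERNS), fill_value=0)
        )
        fractions = counts.div(counts.sum(axis=1), axis=0) * 100.0
        fractions = fractions.reset_index()
    else:
        counts = assignments["pattern"].value_counts().reindex(list(PATTERNS), fill_value=0)
        fractions = (counts / counts.sum() * 100.0).to_frame().T
    return EthogramResult(assignments=assignments, pattern_fractions=fractions)
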