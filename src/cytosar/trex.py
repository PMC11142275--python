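"""KNN-enrichment comparison of two cell conditions in an embedding (T-REX).

The procedure: subsample each condition to equal size, embed the pooled
arcsinh-scaled marker matrix in two dimensions (t-SNE by default), and for
every cell compute the fraction of its k nearest embedded neighbors coming
from the test condition.  Cells in neighborhoods almost purely test
(fraction >= 0.95, "red") or almost purely reference (<= 0.05, "blue") are
hotspots; the *degree of difference* is

    D = (#red + #blue) / total cells,

0 for indistinguishable conditions, approaching 1 when the conditions
occupy disjoint phenotypic regions.  Two vehicle wells give D < 1%; strong
treatments give D well above any vehicle-derived threshold.

Neighbor search uses exact pairwise distances with a stable sort, so ties
in distance are broken by event index and results are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import EventTable

__all__ = [
    "EmbedParams",
    "EmbeddingCoords",
    "TrexConfig",
    "TrexResult",
    "equal_subsample",
    "embed",
    "knn_neighbors",
    "knn_enrichment",
    "degree_of_difference",
    "island_quantify",
]

log = logging.getLogger(__name__)


@dataclass
class EmbedParams:
    """Embedding backend and its parameters.

    method: ``"tsne"`` (Barnes-Hut, default) or ``"umap"``.
    ``max_iter`` trades runtime for refinement; 750 iterations is ample for
    the neighbor structure this analysis consumes.
    """

    method: str = "tsne"
    perplexity: float = 60.0
    max_iter: int = 750
    early_exaggeration: float = 12.0
    n_neighbors: int = 15  # umap only
    min_dist: float = 0.1  # umap only


@dataclass
class EmbeddingCoords:
    """2-D embedding with provenance (backend, parameters, seed, markers)."""

    coords: np.ndarray
    provenance: dict = field(default_factory=dict)
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if self.coords.size and not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class TrexConfig:
    """k and the hotspot cutoffs on the test-neighbor fraction."""

    k: int = 60
    hotspot_hi: float = 0.95
    hotspot_lo: float = 0.05

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.hotspot_lo < self.hotspot_hi <= 1.0:
            raise ValueError("require 0 <= hotspot_lo < hotspot_hi <= 1")


@dataclass
class TrexResult:
    """Per-cell test-neighbor fractions and hotspot labels."""

    fraction_from_test: np.ndarray
    hotspot: np.ndarray  # "red" | "blue" | "none"
    group_sizes: dict[str, int]
    config: TrexConfig

    @property
    def n_red(self) -> int:
        return int(np.sum(self.hotspot == "red"))

    @property
    def n_blue(self) -> int:
        return int(np.sum(self.hotspot == "blue"))

    @property
    def degree_of_difference(self) -> float:
        return degree_of_difference(self)


def degree_of_difference(result: TrexResult) -> float:
    """(#red + #blue) / total cells, exactly; 0 when there are no hotspots."""
    total = len(result.hotspot)
    if total == 0:
        raise ValueError("empty result")
    return (result.n_red + result.n_blue) / total


# ---------------------------------------------------------------------------
# equal-representation subsampling


def equal_subsample(
    groups: Mapping[str, EventTable],
    per_group_n: int,
    seed: int,
    group_key: str = "group",
) -> EventTable:
    """Sample exactly equal counts per group, uniformly without replacement.

    If any group is smaller than the request, every group is downsampled to
    the minimum available size (logged).  Group labels are retained as an
    annotation column.
    """
    if not groups:
        raise ValueError("no groups given")
    for name, tab in groups.items():
        if tab.n_events == 0:
            raise ValueError(f"group {name!r} is empty")
    smallest = min(t.n_events for t in groups.values())
    n = per_group_n
    if smallest < n:
        log.warning("smallest group has %d events; lowering per-group sample from %d",
                    smallest, per_group_n)
        n = smallest
    rng = np.random.default_rng(seed)
    parts = []
    for name in groups:  # insertion order: deterministic
        tab = groups[name]
        idx = rng.choice(tab.n_events, size=n, replace=False)
        sub = tab.subset(np.isin(np.arange(tab.n_events), idx))
        sub.annotations[group_key] = name
        parts.append(sub)
    return EventTable.concat(parts)


# ---------------------------------------------------------------------------
# embedding


def embed(
    table: EventTable,
    markers: Sequence[str] | None = None,
    params: EmbedParams | None = None,
    seed: int = 0,
) -> EmbeddingCoords:
    """Embed the arcsinh-scaled marker matrix in 2-D.

    Requires at least ``3 * perplexity`` events for the t-SNE backend.
    """
    params = params or EmbedParams()
    markers = list(markers) if markers is not None else table.functional_markers
    x = table.values(markers)
    if params.method == "tsne":
        if len(x) < 3 * params.perplexity:
            raise ValueError(
                f"t-SNE with perplexity {params.perplexity} needs >= "
                f"{int(3 * params.perplexity)} events, got {len(x)}"
            )
        from sklearn.manifold import TSNE

        spread = np.ptp(x, axis=0)
        if not spread.any():
            # All rows identical: the Barnes-Hut tree cannot partition
            # coincident points, so separate them by a negligible jitter.
            log.warning("embedding input has zero spread; adding 1e-6 jitter")
            x = x + np.random.default_rng(seed).normal(0.0, 1e-6, size=x.shape)
        coords = TSNE(
            n_components=2,
            perplexity=params.perplexity,
            max_iter=params.max_iter,
            early_exaggeration=params.early_exaggeration,
            learning_rate="auto",
            init="pca" if x.shape[1] >= 2 else "random",
            random_state=seed,
        ).fit_transform(x)
    elif params.method == "umap":
        import umap

        coords = umap.UMAP(
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            n_components=2,
            random_state=seed,
        ).fit_transform(x)
    else:
        raise ValueError(f"unknown embedding method {params.method!r}")
    prov = {"method": params.method, "seed": seed, "perplexity": params.perplexity,
            "max_iter": params.max_iter, "early_exaggeration": params.early_exaggeration}
    return EmbeddingCoords(np.asarray(coords, float), prov, markers)


# ---------------------------------------------------------------------------
# KNN enrichment


def knn_neighbors(coords: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """Indices of the k nearest neighbors (self excluded) per point.

    Exact squared Euclidean distances, sorted with a stable sort so equal
    distances are broken by event index.  Chunked to bound memory.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k >= n:
        raise ValueError(f"k={k} must be < number of events {n}")
    sq = np.einsum("ij,ij->i", coords, coords)
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = coords[start:stop]
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * block @ coords.T
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return out


def knn_enrichment(
    coords: EmbeddingCoords | np.ndarray,
    labels: Sequence[str],
    config: TrexConfig | None = None,
) -> TrexResult:
    """Per-cell fraction of k nearest neighbors labeled ``test``.

    ``labels`` holds "test"/"reference" per embedded cell.  A cell is a
    "red" hotspot when its fraction >= ``hotspot_hi`` and "blue" when
    <= ``hotspot_lo``.
    """
    config = config or TrexConfig()
    xy = coords.coords if isinstance(coords, EmbeddingCoords) else np.asarray(coords, float)
    labels = np.asarray(labels)
    if len(labels) != len(xy):
        raise ValueError("labels length must match coords")
    uniq = set(labels.tolist())
    if uniq != {"test", "reference"}:
        raise ValueError(f"labels must contain both 'test' and 'reference', got {uniq}")
    is_test = (labels == "test").astype(np.float64)
    nbrs = knn_neighbors(xy, config.k)
    frac = is_test[nbrs].mean(axis=1)
    hotspot = np.full(len(xy), "none", dtype=object)
    hotspot[frac >= config.hotspot_hi] = "red"
    hotspot[frac <= config.hotspot_lo] = "blue"
    sizes = {"test": int(is_test.sum()), "reference": int(len(xy) - is_test.sum())}
    return TrexResult(frac, hotspot, sizes, config)


# ---------------------------------------------------------------------------
# island gating


def _points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd crossing test with half-open edges.

    An edge is counted when the point's y lies in [y_lo, y_hi) of the edge,
    so points exactly on a horizontal boundary belong to the polygon below
    them and shared edges are never double-counted.
    """
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edge never crosses the half-open band
        crosses = (y1 <= y) != (y2 <= y)
        x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < x_at)
    return inside


def island_quantify(
    coords: EmbeddingCoords | np.ndarray,
    polygon: Sequence[Sequence[float]],
    groups: Sequence[str],
    all_groups: Sequence[str] | None = None,
) -> dict[str, float | None]:
    """Percent of each group's cells inside a polygon gate on the embedding.

    Groups with no cells are reported as None (missing), not 0.  The gate
    polygon must be simple with >= 3 vertices.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or len(poly) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if _self_intersects(poly):
        raise ValueError("polygon must be simple (non-self-intersecting)")
    xy = coords.coords if isinstance(coords, EmbeddingCoords) else np.asarray(coords, float)
    groups = np.asarray(groups)
    if len(groups) != len(xy):
        raise ValueError("groups length must match coords")
    inside = _points_in_polygon(xy, poly)
    out: dict[str, float | None] = {}
    for g in all_groups if all_groups is not None else np.unique(groups):
        mask = groups == g
        out[str(g)] = 100.0 * inside[mask].mean() if mask.any() else None
    return out


def _self_intersects(poly: np.ndarray) -> bool:
    n = len(poly)

    def seg_intersect(p1, p2, p3, p4) -> bool:
        d1 = np.cross(p4 - p3, p1 - p3)
        d2 = np.cross(p4 - p3, p2 - p3)
        d3 = np.cross(p2 - p1, p3 - p1)
        d4 = np.cross(p2 - p1, p4 - p1)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (0, 1) or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if seg_intersect(poly[i], poly[(i + 1) % n], poly[j], poly[(j + 1) % n]):
                return True
    return False
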