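"""Plate-level screening statistics.

Covers the quantitative backbone of a phospho-flow chemical screen:

* per-compound, per-marker **fold change** on arcsinh scale, as the
  difference of scaled medians (treated minus vehicle 1), so 0 means no
  change and +1 is roughly an e-fold raw increase in the logarithmic range;
* **hit selection** against the vehicle-derived threshold
  ``median + 3 x IQR`` of vehicle fold-change values;
* **chemotype composition** of the library and of the hit set;
* gate-based **percent positive** per well, **cell-type specificity** as a
  log2 ratio, hierarchical **clustering** of fold-change profiles;
* the **Wilcoxon rank-sum test** (exact for small tie-free samples,
  normal approximation with tie and continuity corrections otherwise);
* **four-parameter log-logistic (4PL) dose-response fits** yielding EC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import EventTable

__all__ = [
    "HitThreshold",
    "DoseResponseFit",
    "ClusteredHeatmap",
    "fold_change",
    "select_hits",
    "chemotype_composition",
    "percent_positive",
    "specificity_ratio",
    "cluster_heatmap",
    "rank_sum_test",
    "fit_4pl",
    "four_pl",
]


# ---------------------------------------------------------------------------
# fold change


def _scaled_medians(table: EventTable, markers: Sequence[str]) -> pd.Series:
    if table.n_events == 0:
        raise ValueError("empty well")
    for m in markers:
        if m not in table.scaled:
            raise ValueError(f"marker {m!r} is not arcsinh-scaled")
    return pd.Series({m: float(np.median(table.data[m])) for m in markers})


def fold_change(
    treated: EventTable,
    vehicle: EventTable,
    markers: Sequence[str],
    mode: Literal["difference", "arcsinh_ratio"] = "difference",
) -> pd.Series:
    """Per-marker arcsinh fold change of treated vs. vehicle.

    Default (``difference``): scaled_median(treated) - scaled_median(vehicle),
    the field-standard log-like ratio (0 = no change, antisymmetric under
    swapping the wells).  ``arcsinh_ratio`` instead evaluates
    asinh(MFI_treated / MFI_vehicle) on raw medians — provided for
    comparison; note it maps "no change" to asinh(1) != 0.
    """
    if mode == "difference":
        return _scaled_medians(treated, markers) - _scaled_medians(vehicle, markers)
    if mode == "arcsinh_ratio":
        out = {}
        for m in markers:
            cf = treated.channels[m].cofactor or 1.0
            t_raw = np.sinh(np.median(treated.data[m])) * cf if m in treated.scaled \
                else np.median(treated.data[m])
            v_raw = np.sinh(np.median(vehicle.data[m])) * cf if m in vehicle.scaled \
                else np.median(vehicle.data[m])
            out[m] = float(np.arcsinh(t_raw / v_raw))
        return pd.Series(out)
    raise ValueError(f"unknown fold-change mode {mode!r}")


# ---------------------------------------------------------------------------
# hit selection


@dataclass
class HitThreshold:
    """Vehicle-derived bioactivity threshold: median + 3 x IQR.

    ``per_readout`` holds one threshold per marker when computed per
    readout; ``value`` holds the pooled threshold otherwise.
    """

    value: float | None
    per_readout: dict[str, float] | None
    mode: str
    vehicle_median: float | dict[str, float]

    def threshold_for(self, marker: str) -> float:
        if self.per_readout is not None:
            return self.per_readout[marker]
        assert self.value is not None
        return self.value


def _median_plus_3iqr(vals: np.ndarray) -> tuple[float, float]:
    med = float(np.median(vals))
    q75, q25 = np.percentile(vals, [75, 25])
    return med, med + 3.0 * (q75 - q25)


def select_hits(
    deltas: pd.DataFrame,
    vehicle_deltas: pd.DataFrame,
    mode: Literal["pooled", "per_readout"] = "pooled",
    readouts: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, HitThreshold]:
    """Flag compounds whose fold change exceeds the vehicle-derived threshold.

    ``deltas``: compounds x markers fold changes; ``vehicle_deltas``: the
    same statistic for vehicle wells (vs. vehicle 1).  The threshold is the
    vehicle median + 3 x IQR, over all vehicle fold-change values pooled
    (default) or per readout.  A compound is a hit on a readout when its
    delta strictly exceeds the threshold; overall hit = hit on any readout.
    """
    if len(vehicle_deltas) == 0:
        raise ValueError("no vehicle wells")
    if len(vehicle_deltas) < 2:
        warnings.warn("single vehicle well: IQR is 0 and the threshold collapses "
                      "to the vehicle median", stacklevel=2)
    readouts = list(readouts) if readouts is not None else list(deltas.columns)
    if mode == "pooled":
        med, thr = _median_plus_3iqr(vehicle_deltas[readouts].to_numpy().ravel())
        threshold = HitThreshold(thr, None, "pooled", med)
    elif mode == "per_readout":
        per, meds = {}, {}
        for m in readouts:
            meds[m], per[m] = _median_plus_3iqr(vehicle_deltas[m].to_numpy())
        threshold = HitThreshold(None, per, "per_readout", meds)
    else:
        raise ValueError(f"unknown hit mode {mode!r}")
    per_readout_hits = pd.DataFrame(
        {m: deltas[m] > threshold.threshold_for(m) for m in readouts},
        index=deltas.index,
    )
    overall = per_readout_hits.any(axis=1)
    overall.name = "hit"
    return per_readout_hits, overall, threshold


def chemotype_composition(
    chemotypes: pd.Series,
    hit_flags: pd.Series,
) -> pd.DataFrame:
    """Per-chemotype counts and percentages in the library and the hit set.

    ``chemotypes`` maps compound -> chemotype; ``hit_flags`` maps compound
    -> bool.  Percentages are reported to one decimal place.
    """
    chemotypes = chemotypes.astype(str)
    hit_flags = hit_flags.reindex(chemotypes.index).fillna(False).astype(bool)
    n_total = len(chemotypes)
    n_hits = int(hit_flags.sum())
    rows = []
    for ct, members in chemotypes.groupby(chemotypes):
        n_lib = len(members)
        n_hit = int(hit_flags[members.index].sum())
        rows.append({
            "chemotype": ct,
            "n_library": n_lib,
            "pct_library": round(100.0 * n_lib / n_total, 1),
            "n_hits": n_hit,
            "pct_hits": round(100.0 * n_hit / n_hits, 1) if n_hits else np.nan,
        })
    return pd.DataFrame(rows).set_index("chemotype").sort_index()


# ---------------------------------------------------------------------------
# percent positive and specificity


def percent_positive(
    well: EventTable,
    marker: str,
    cutoff: float | None = None,
    vehicle: EventTable | None = None,
    q: float = 99.0,
) -> float:
    """Percent of events above a scaled-intensity cutoff.

    Either pass an explicit ``cutoff`` or a ``vehicle`` table, in which case
    the cutoff is the vehicle's q-th percentile (default 99) of the marker —
    so a vehicle well scored against itself reads ~(100 - q)%.
    """
    if well.n_events == 0:
        raise ValueError("empty well")
    if (cutoff is None) == (vehicle is None):
        raise ValueError("pass exactly one of cutoff or vehicle")
    if cutoff is None:
        cutoff = float(np.percentile(vehicle.data[marker].to_numpy(), q))
    vals = well.data[marker].to_numpy()
    return 100.0 * float(np.mean(vals > cutoff))


def specificity_ratio(pct_a: float, pct_b: float, eps: float = 0.1) -> float:
    """log2((pct_a + eps) / (pct_b + eps)); the pseudo-count guards zero
    denominators (0.1 percentage point by default)."""
    if pct_a < 0 or pct_b < 0:
        raise ValueError("percentages must be >= 0")
    return float(np.log2((pct_a + eps) / (pct_b + eps)))


# ---------------------------------------------------------------------------
# clustered heatmap


@dataclass
class ClusteredHeatmap:
    """Row/column linkages and deterministic leaf orders for a fold-change
    matrix (missing values imputed as 0 = no change, flagged)."""

    matrix: pd.DataFrame
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list
    col_order: list
    imputed: int = 0


def cluster_heatmap(
    deltas: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusteredHeatmap:
    """Agglomerative clustering of compounds (rows) and markers (columns).

    Input rows are sorted by label before linkage so leaf order does not
    depend on input row order.
    """
    mat = deltas.sort_index(axis=0).sort_index(axis=1)
    imputed = int(mat.isna().to_numpy().sum())
    if imputed:
        warnings.warn(f"imputing {imputed} missing fold changes as 0", stacklevel=2)
        mat = mat.fillna(0.0)

    def _link(m: np.ndarray):
        if len(m) < 2:
            return None, list(range(len(m)))
        lk = hierarchy.linkage(pdist(m, metric=metric), method=method)
        return lk, list(hierarchy.leaves_list(lk))

    row_linkage, row_idx = _link(mat.to_numpy())
    col_linkage, col_idx = _link(mat.to_numpy().T)
    return ClusteredHeatmap(
        matrix=mat,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        row_order=[mat.index[i] for i in row_idx],
        col_order=[mat.columns[i] for i in col_idx],
        imputed=imputed,
    )


# ---------------------------------------------------------------------------
# rank-sum test


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample is small (<= ``exact_max_n``)
    and tie-free; otherwise the normal approximation with midrank tie
    correction and continuity correction.  Returns (rank-sum statistic of
    group A, two-sided p).  Identical constant samples give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_a = float(ranks[: len(a)].sum())
    if np.ptp(pooled) == 0:
        return w_a, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(pooled) <= exact_max_n:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
    return w_a, float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# 4PL dose-response


@dataclass
class DoseResponseFit:
    """Four-parameter log-logistic curve f(x) = c + (d-c)/(1 + (x/e)^b).

    ``b`` hill slope (negative for responses increasing with dose in this
    parameterization), ``c``/``d`` lower/upper asymptotes (%), ``e`` the
    EC50 in dose units.  Canonical form has c <= d (the (b,c,d) and
    (-b,d,c) parameterizations describe the same curve).
    """

    b: float
    c: float
    d: float
    e: float
    rmse: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.e > 0:
            raise ValueError("EC50 (e) must be positive")
        if self.c > self.d:  # canonicalize
            self.c, self.d = self.d, self.c
            self.b = -self.b

    def __call__(self, x) -> np.ndarray:
        return four_pl(x, self.b, self.c, self.d, self.e)


def four_pl(x, b: float, c: float, d: float, e: float) -> np.ndarray:
    """Evaluate the 4PL curve; dose 0 is the asymptote limit (no log
    singularity): d for b > 0, c for b < 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    zero = x == 0
    out[zero] = d if b > 0 else c
    with np.errstate(over="ignore"):
        u = np.power(x[~zero] / e, b)
    out[~zero] = c + (d - c) / (1.0 + u)
    return out


def fit_4pl(
    doses: Sequence[float],
    responses: Sequence[float],
    max_nfev: int = 2000,
) -> DoseResponseFit:
    """Least-squares 4PL fit of percent response vs. dose.

    Needs >= 5 dose levels (dose 0 allowed and handled as the asymptote
    limit).  Initialization: asymptotes from the response range, EC50 from
    the dose bracketing the half response, unit hill slope signed by the
    response trend.  Non-convergence returns a flagged fit rather than
    raising; constant responses raise ("no dose effect").
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) != len(y):
        raise ValueError("doses and responses must align")
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 dose levels")
    if np.any(x < 0):
        raise ValueError("doses must be nonnegative")
    if np.ptp(y) == 0:
        raise ValueError("no dose effect: responses are constant")

    c0, d0 = float(np.min(y)), float(np.max(y))
    mid = (c0 + d0) / 2.0
    pos = x > 0
    e0 = float(x[pos][np.argmin(np.abs(y[pos] - mid))]) if pos.any() else 1.0
    # increasing response => negative b in the (x/e)^b form
    slope_sign = np.corrcoef(np.log1p(x), y)[0, 1]
    b0 = -1.0 if slope_sign >= 0 else 1.0

    def residuals(p):
        b, c, d, log_e = p
        return four_pl(x, b, c, d, np.exp(log_e)) - y

    p0 = np.array([b0, c0, d0, np.log(e0)])
    res = optimize.least_squares(residuals, p0, max_nfev=max_nfev, method="lm")
    b, c, d, log_e = res.x
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return DoseResponseFit(float(b), float(c), float(d), float(np.exp(log_e)),
                           rmse=rmse, converged=bool(res.success))
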