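"""Mixture-based deconvolution of fluorescent cell barcodes.

Wells are pooled after each one is labeled with a unique pair of dye
intensity levels (e.g. 8 levels of Pacific Blue x 6 of Pacific Orange = 48
wells).  Because the grid design factorizes, each dye is deconvoluted
independently with a one-dimensional Gaussian mixture on the arcsinh-scaled
dye intensity; an event is assigned to the (level_i, level_j) pair
maximizing the product of the per-dye posterior responsibilities, and that
product is its confidence.  Low-confidence events are left unassigned and
excluded from downstream statistics.

Quantile-based initialization and a fixed seed make fits deterministic and
order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .io import EventTable
from .synthetic import BarcodeScheme

__all__ = ["LevelModel", "BarcodeAssignment", "fit_levels", "assign_wells", "debarcode"]


@dataclass
class LevelModel:
    """Fitted 1-D Gaussian mixture for one dye, components sorted by center."""

    dye: str
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    cofactor: float

    def responsibilities(self, scaled: np.ndarray) -> np.ndarray:
        """Posterior P(level | value) for each event, shape (n, n_levels)."""
        z = (scaled[:, None] - self.means[None, :]) / self.sds[None, :]
        log_like = -0.5 * z**2 - np.log(self.sds[None, :]) + np.log(self.weights[None, :])
        log_like -= log_like.max(axis=1, keepdims=True)
        like = np.exp(log_like)
        return like / like.sum(axis=1, keepdims=True)


@dataclass
class BarcodeAssignment:
    """Per-event well assignment with confidence; None marks unassigned."""

    well_id: np.ndarray  # object array of str | None
    confidence: np.ndarray
    models: dict[str, LevelModel]

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.well_id != None))  # noqa: E711 — element-wise

    @property
    def n_unassigned(self) -> int:
        return len(self.well_id) - self.n_assigned


def _scaled_dye(table: EventTable, dye: str, cofactor: float) -> np.ndarray:
    return np.arcsinh(table.data[dye].to_numpy() / cofactor)


def fit_levels(
    table: EventTable,
    scheme: BarcodeScheme,
    seed: int = 0,
    min_weight_floor: float | None = None,
) -> dict[str, LevelModel]:
    """Fit one 1-D Gaussian mixture per dye on arcsinh-scaled intensity.

    Components are initialized at evenly spaced quantiles of the data (so
    the fit is invariant to event order) and returned sorted by center.  A
    component collapsing below the weight floor (default ``1 / (20 * L)``)
    raises a diagnostic error naming the dye.
    """
    total_levels = sum(scheme.levels_per_dye)
    if table.n_events < 10 * total_levels:
        raise ValueError(
            f"need >= {10 * total_levels} events to fit {total_levels} levels"
        )
    models: dict[str, LevelModel] = {}
    for dye, n_levels in zip(scheme.dyes, scheme.levels_per_dye):
        if dye not in table.channel_names:
            raise ValueError(f"dye channel {dye!r} missing from table")
        cofactor = scheme.dye_cofactors[dye]
        x = _scaled_dye(table, dye, cofactor)
        qs = (np.arange(n_levels) + 0.5) / n_levels
        means_init = np.quantile(x, qs)[:, None]
        if n_levels == 1:
            # degenerate scheme: single component = sample mean
            models[dye] = LevelModel(dye, np.array([x.mean()]),
                                     np.array([max(x.std(), 1e-6)]),
                                     np.array([1.0]), cofactor)
            continue
        gm = GaussianMixture(
            n_components=n_levels,
            covariance_type="spherical",
            means_init=means_init,
            random_state=seed,
            n_init=1,
            reg_covar=1e-6,
        ).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        floor = min_weight_floor if min_weight_floor is not None else 1.0 / (20 * n_levels)
        weights = gm.weights_[order]
        if weights.min() < floor:
            raise ValueError(
                f"degenerate mixture fit for dye {dye!r}: component weight "
                f"{weights.min():.4g} below floor {floor:.4g}"
            )
        models[dye] = LevelModel(
            dye,
            gm.means_.ravel()[order],
            np.sqrt(gm.covariances_.ravel()[order]),
            weights,
            cofactor,
        )
    return models


def assign_wells(
    table: EventTable,
    models: dict[str, LevelModel],
    scheme: BarcodeScheme,
    min_confidence: float = 0.9,
) -> BarcodeAssignment:
    """Assign each event to the well whose level pair maximizes the product
    of per-dye posterior responsibilities; below ``min_confidence`` the
    event is unassigned."""
    resp = []
    best = []
    for dye in scheme.dyes:
        model = models[dye]
        r = model.responsibilities(_scaled_dye(table, dye, model.cofactor))
        resp.append(r)
        best.append(np.argmax(r, axis=1))
    conf = resp[0][np.arange(len(best[0])), best[0]] * resp[1][
        np.arange(len(best[1])), best[1]
    ]
    inv = {v: k for k, v in scheme.well_assignment.items()}
    wells = np.array(
        [inv[(int(i), int(j))] for i, j in zip(best[0], best[1])], dtype=object
    )
    wells[conf < min_confidence] = None
    return BarcodeAssignment(wells, conf, models)


def debarcode(
    table: EventTable,
    scheme: BarcodeScheme,
    min_confidence: float = 0.9,
    seed: int = 0,
) -> tuple[dict[str, EventTable], BarcodeAssignment]:
    """Fit level models and split the pool into per-well tables.

    Returns only confidently assigned events, grouped by well; the
    assignment object retains the full per-event record so
    assigned + unassigned always reconciles with the pooled count.
    """
    models = fit_levels(table, scheme, seed=seed)
    assignment = assign_wells(table, models, scheme, min_confidence)
    out: dict[str, EventTable] = {}
    for well in scheme.wells:
        mask = assignment.well_id == well
        if mask.any():
            sub = table.subset(mask)
            sub.annotations["well_id"] = well
            out[well] = sub
    return out, assignment
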