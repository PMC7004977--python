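"""Effort-reduction engine: bias / variance / cost surfaces per method.

The question answered here is "what would the density estimate have
looked like had we sampled less?".  For the two data-driven methods the
answer comes from bootstrap subsampling of the observed (or synthetic)
data — fewer transects/occasions for fecal CR, rectangular camera
subgrids and shorter day windows for SECR — each replicate refit from
scratch and compared to the full-data fit through the scaled bias
(D_reduced - D_full) / D_full.  Removal trapping cannot be subsampled
without breaking closure (removed animals stay removed), so reduced
trap designs are evaluated by forward simulation from a clustered
population with known density, plus a linear model for the effective
area a trap design samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from wildens import closed_cr, costs, removal, secr

log = logging.getLogger(__name__)


@dataclass
class ReductionCell:
    """Aggregated outcome of one effort configuration."""

    effort: costs.EffortConfig
    scaled_bias: float
    variance: float
    cost_usd: float
    prop_converged: float
    n_replicates: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_converged <= 1.0:
            raise ValueError("prop_converged must lie in [0, 1]")

    @property
    def abs_scaled_bias(self) -> float:
        return abs(self.scaled_bias)


@dataclass
class SimTruth:
    """Known truth behind a simulated population."""

    true_density: float  # realized animals per km^2
    centroids: np.ndarray  # (N, 2) km activity centres
    sigma_move_km: float
    encounter_scale_km: float
    mean_cluster_size: float
    extent_km: tuple[float, float]

    @property
    def n_animals(self) -> int:
        return len(self.centroids)


@dataclass
class AreaModel:
    """Linear model for the effective area sampled by a trap design.

    The implied-area surface is convex in (traps, days), so a plane
    underestimates the smallest designs; predictions are floored at the
    smallest implied area observed during calibration (``min_area_km2``)
    to keep the conversion to density defined everywhere.
    """

    intercept: float
    coef_days: float
    coef_traps: float
    r_squared: float
    resid_se: float
    min_area_km2: float = 0.0

    def predict(self, n_traps: int, n_days: int) -> float:
        area = self.intercept + self.coef_days * n_days + self.coef_traps * n_traps
        area = max(area, self.min_area_km2)
        if area <= 0:
            raise ValueError("predicted effective area is not positive")
        return area


def enumerate_camera_subgrids(
    rows: int = 4, cols: int = 5, min_cameras: int = 6, exclude_full: bool = True
) -> list[tuple[int, int, int, int]]:
    """All axis-aligned contiguous sub-rectangles of the camera array.

    Returns (row0, col0, n_rows, n_cols) tuples with camera count
    >= ``min_cameras``, distinct in position and shape, optionally
    excluding the full array.  The full 4x5 grid yields 47 reduced
    configurations at the 6-camera floor.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    out = []
    for h in range(1, rows + 1):
        for w in range(1, cols + 1):
            if h * w < min_cameras:
                continue
            if exclude_full and h == rows and w == cols:
                continue
            for r0 in range(rows - h + 1):
                for c0 in range(cols - w + 1):
                    out.append((r0, c0, h, w))
    return out


def scaled_bias(d_reduced: float, d_full: float) -> float:
    """Relative difference of a reduced-effort estimate from the full fit."""
    if d_full <= 0:
        raise ValueError("full-data density must be positive")
    return (d_reduced - d_full) / d_full


def camera_grid_coords(rows: int = 4, cols: int = 5, spacing_km: float = 0.75) -> np.ndarray:
    """Row-major (K, 2) coordinates of the camera grid."""
    return np.array(
        [(c * spacing_km, r * spacing_km) for r in range(rows) for c in range(cols)]
    )


def subgrid_indices(spec: tuple[int, int, int, int], rows: int = 4, cols: int = 5) -> list[int]:
    """Row-major detector indices covered by a subgrid spec."""
    r0, c0, h, w = spec
    return [r * cols + c for r in range(r0, r0 + h) for c in range(c0, c0 + w)]


# --- fecal DNA bootstrap ----------------------------------------------------


def histories_from_detections(
    det: pd.DataFrame, n_occasions: int, occasions: list[int] | None = None
) -> list[closed_cr.CaptureHistory]:
    """Build per-habitat capture histories from a long detections table.

    ``det`` columns: individual, transect, occasion, habitat.  When
    ``occasions`` is given, only those occasions are kept and occasions
    are re-indexed to consecutive columns.
    """
    if occasions is not None:
        det = det[det["occasion"].isin(occasions)]
        remap = {occ: i for i, occ in enumerate(sorted(occasions))}
        K = len(occasions)
    else:
        remap = {occ: occ - 1 for occ in range(1, n_occasions + 1)}
        K = n_occasions
    hists = []
    for hab, g in det.groupby("habitat", sort=True):
        ids = sorted(g["individual"].unique())
        idx = {v: i for i, v in enumerate(ids)}
        mat = np.zeros((len(ids), K), dtype=int)
        for row in g.itertuples():
            mat[idx[row.individual], remap[row.occasion]] = 1
        if len(ids):
            hists.append(closed_cr.CaptureHistory(hab, mat, K, individual_ids=ids))
    return hists


def _fecal_density(det, n_occasions, transects, occasions, design, structure):
    """Pooled density (total N over total area) for one data subset."""
    sub = det[det["transect"].isin(transects)]
    hists = histories_from_detections(sub, n_occasions, occasions=sorted(occasions))
    if not hists or any(h.n_occasions < 2 for h in hists):
        raise ValueError("subset leaves no estimable history")
    model, ests = closed_cr.fit_closed_cr(hists, structure=structure)
    if not model.converged:
        raise RuntimeError("closed CR refit did not converge")
    fp = costs.transect_footprint(
        n_transects=len(transects),
        length_km=design["transect_length_km"],
        spacing_km=design["spacing_km"],
        buffer_km=1.123,
    )
    area = costs.buffered_area(fp)
    n_hab = len(hists)
    total_N = sum(e.N_hat for e in ests.values())
    return total_N / (area * n_hab)


def reduce_fecal(
    det: pd.DataFrame,
    n_transects: int,
    n_occasions_kept: int,
    n_boot: int = 100,
    seed: int = 0,
    design: dict | None = None,
    structure: str = "Mb_habitat",
) -> ReductionCell:
    """Bootstrap a reduced fecal design (fewer transects and/or occasions).

    Each replicate keeps a uniform subset of transects and occasions,
    rebuilds per-habitat histories (individuals no longer detected
    drop out), refits the closed CR model and converts to density over
    the reduced transect footprint.  Full effort is deterministic and
    has scaled bias exactly zero.
    """
    if n_boot < 1:
        raise ValueError("need at least one bootstrap replicate")
    design = design or {
        "n_transects": 4,
        "transect_length_km": 4.0,
        "spacing_km": 0.75,
        "n_occasions": 6,
    }
    all_transects = sorted(det["transect"].unique())
    all_occasions = sorted(det["occasion"].unique())
    K_full = design["n_occasions"]
    if n_transects > len(all_transects) or n_occasions_kept > len(all_occasions):
        raise ValueError("cannot keep more transects/occasions than available")

    d_full = _fecal_density(det, K_full, all_transects, all_occasions, design, structure)

    rng = np.random.default_rng(seed)
    full = n_transects == len(all_transects) and n_occasions_kept == len(all_occasions)
    reps = 1 if full else n_boot
    biases, dens = [], []
    n_fail = 0
    for _ in range(reps):
        tr = sorted(rng.choice(all_transects, size=n_transects, replace=False))
        oc = sorted(rng.choice(all_occasions, size=n_occasions_kept, replace=False))
        try:
            d_red = _fecal_density(det, K_full, tr, oc, design, structure)
        except (ValueError, RuntimeError):
            n_fail += 1
            continue
        dens.append(d_red)
        biases.append(scaled_bias(d_red, d_full))

    cost = costs.calibrated_cost("fecal", n_transects, n_occasions_kept)
    return ReductionCell(
        effort=costs.EffortConfig("fecal", n_transects, n_occasions_kept),
        scaled_bias=float(np.mean(biases)) if biases else np.nan,
        variance=float(np.var(dens, ddof=1)) if len(dens) > 1 else 0.0,
        cost_usd=cost,
        prop_converged=(reps - n_fail) / reps,
        n_replicates=reps,
    )


# --- camera subgrid bootstrap ----------------------------------------------


def _restrict_session(
    sess: secr.SpatialDetections, det_indices: list[int], window: range
) -> secr.SpatialDetections:
    keep = {d: i for i, d in enumerate(det_indices)}
    occ_map = {occ: i + 1 for i, occ in enumerate(window)}
    events = {
        (ind, occ_map[occ], keep[d])
        for ind, occ, d in sess.detections
        if d in keep and occ in occ_map
    }
    return secr.SpatialDetections(
        habitat=sess.habitat,
        detectors=sess.detectors[det_indices],
        n_occasions=len(occ_map),
        detections=events,
    )


def reduce_camera(
    sessions: list[secr.SpatialDetections],
    subgrid: tuple[int, int, int, int],
    n_days: int,
    n_boot: int = 100,
    seed: int = 0,
    rows: int = 4,
    cols: int = 5,
    spec: secr.SECRModelSpec | None = None,
    d_full: float | None = None,
) -> ReductionCell:
    """Bootstrap a reduced camera design (subgrid + contiguous day window).

    Replicates restrict detections to the subgrid's cameras and a
    uniformly placed contiguous window of ``n_days`` occasions, then
    refit SECR.  Replicates failing the sufficiency rule or the
    optimizer count against ``prop_converged``.
    """
    if n_boot < 1:
        raise ValueError("need at least one bootstrap replicate")
    spec = spec or secr.SECRModelSpec(behavior=False, time="none")
    T_full = sessions[0].n_occasions
    if n_days > T_full:
        raise ValueError("day window exceeds the study duration")
    idx = subgrid_indices(subgrid, rows, cols)

    if d_full is None:
        model_full, _ = secr.fit_secr(sessions, spec=spec)
        d_full = model_full.D

    rng = np.random.default_rng(seed)
    full = len(idx) == rows * cols and n_days == T_full
    reps = 1 if full else n_boot
    dens, biases = [], []
    n_fail = 0
    for _ in range(reps):
        start = int(rng.integers(1, T_full - n_days + 2))
        window = range(start, start + n_days)
        subs = [_restrict_session(s, idx, window) for s in sessions]
        ok, _, _ = secr.check_sufficiency(subs)
        if not ok:
            n_fail += 1
            continue
        try:
            model, _ = secr.fit_secr(subs, spec=spec)
        except (secr.InsufficientData, ValueError, FloatingPointError):
            n_fail += 1
            continue
        if not model.converged:
            n_fail += 1
            continue
        dens.append(model.D)
        biases.append(scaled_bias(model.D, d_full))

    n_cams = len(idx)
    cost = costs.calibrated_cost("camera", n_cams, n_days)
    return ReductionCell(
        effort=costs.EffortConfig("camera", n_cams, n_days),
        scaled_bias=float(np.mean(biases)) if biases else np.nan,
        variance=float(np.var(dens, ddof=1)) if len(dens) > 1 else 0.0,
        cost_usd=cost,
        prop_converged=(reps - n_fail) / reps,
        n_replicates=reps,
    )


# --- removal-trapping simulation -------------------------------------------


def clustered_centroids(
    density: float,
    extent_km: tuple[float, float],
    mean_cluster_size: float = 6.0,
    scatter_sd_km: float = 0.3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Clustered activity centres mimicking gregarious social groups.

    Cluster centres follow a Poisson process with intensity
    density / mean_cluster_size; cluster sizes are zero-truncated
    Poisson; members scatter around the centre with isotropic normal
    displacement.  With mean_cluster_size = 1 this reduces to a plain
    Poisson process.
    """
    rng = rng or np.random.default_rng()
    w, h = extent_km
    area = w * h
    n_clusters = rng.poisson(density * area / mean_cluster_size)
    pts = []
    for _ in range(n_clusters):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        if mean_cluster_size <= 1.0:
            size = 1
        else:
            size = 0
            while size == 0:  # zero-truncated Poisson
                size = rng.poisson(mean_cluster_size)
        members = np.column_stack(
            [
                rng.normal(cx, scatter_sd_km, size),
                rng.normal(cy, scatter_sd_km, size),
            ]
        )
        pts.append(members)
    if not pts:
        return np.empty((0, 2))
    out = np.vstack(pts)
    # keep centres on the landscape (reflect at the edges)
    out[:, 0] = np.clip(np.abs(out[:, 0]), 0, None)
    out[:, 0] = np.where(out[:, 0] > w, 2 * w - out[:, 0], out[:, 0])
    out[:, 1] = np.clip(np.abs(out[:, 1]), 0, None)
    out[:, 1] = np.where(out[:, 1] > h, 2 * h - out[:, 1], out[:, 1])
    return out


def place_traps(
    n_traps: int,
    extent_km: tuple[float, float],
    cell_km: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Spatially balanced trap placement: one trap per contiguous 1 km^2 cell.

    The cell block (two rows when more than five traps) is centred on
    the landscape; each trap lands uniformly within its own cell.
    """
    rng = rng or np.random.default_rng()
    w, h = extent_km
    n_rows = 2 if n_traps > 5 else 1
    n_cols = int(np.ceil(n_traps / n_rows))
    if n_cols * cell_km > w or n_rows * cell_km > h:
        raise ValueError("landscape too small for the requested trap block")
    x0 = (w - n_cols * cell_km) / 2
    y0 = (h - n_rows * cell_km) / 2
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)][:n_traps]
    return np.array(
        [
            (
                x0 + (c + rng.uniform()) * cell_km,
                y0 + (r + rng.uniform()) * cell_km,
            )
            for r, c in cells
        ]
    )


THETA_GIVEN_ENCOUNTER_DEFAULT = 0.025  # calibrated so ~20 pigs are removed
# by 10 traps over 14 nights at density 2.5 / km^2 (see docs/methods.md)


def simulate_removal_landscape(
    true_density: float = 2.5,
    extent_km: tuple[float, float] = (9.0, 6.0),
    n_traps: int = 10,
    n_nights: int = 14,
    sigma_move_km: float = 0.7,
    theta_given_encounter: float = THETA_GIVEN_ENCOUNTER_DEFAULT,
    mean_cluster_size: float = 6.0,
    scatter_sd_km: float = 0.3,
    truncation_sigmas: float = 3.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    centroids: np.ndarray | None = None,
) -> tuple[SimTruth, removal.RemovalSeries]:
    """Forward-simulate a removal series from a clustered population.

    Nightly, each surviving animal encounters each active trap with a
    truncated-Gaussian probability exp(-d^2 / (2 sigma^2)) (zero beyond
    ``truncation_sigmas`` * sigma), is captured given encounter with
    probability ``theta_given_encounter``, and is permanently removed.
    """
    rng = rng or np.random.default_rng(seed)
    w, h = extent_km
    if centroids is None:
        centroids = clustered_centroids(
            true_density, extent_km, mean_cluster_size, scatter_sd_km, rng
        )
    realized_density = len(centroids) / (w * h)
    if len(centroids) < 1:
        log.warning("simulated landscape holds no animals")
    traps = place_traps(n_traps, extent_km, rng=rng)

    if len(centroids):
        d2 = ((centroids[:, None, :] - traps[None, :, :]) ** 2).sum(-1)
        q = np.exp(-d2 / (2 * sigma_move_km**2))
        q[np.sqrt(d2) > truncation_sigmas * sigma_move_km] = 0.0
        p_catch = 1.0 - np.prod(1.0 - q * theta_given_encounter, axis=1)
    else:
        p_catch = np.empty(0)

    alive = np.ones(len(centroids), dtype=bool)
    removals = np.zeros(n_nights, dtype=int)
    for t in range(n_nights):
        caught = alive & (rng.uniform(size=len(centroids)) < p_catch)
        removals[t] = int(caught.sum())
        alive &= ~caught

    truth = SimTruth(
        true_density=realized_density,
        centroids=centroids,
        sigma_move_km=sigma_move_km,
        encounter_scale_km=sigma_move_km,
        mean_cluster_size=mean_cluster_size,
        extent_km=extent_km,
    )
    series = removal.RemovalSeries(
        habitat="sim", removals=removals, effort=np.full(n_nights, float(n_traps))
    )
    return truth, series


def effective_area_regression(records: list[dict]) -> AreaModel:
    """OLS of implied effective area on trap count and nights.

    Each record needs N_hat, true_density, n_traps, n_days; the implied
    area is N_hat / true_density.
    """
    df = pd.DataFrame(records)
    if df[["n_traps", "n_days"]].drop_duplicates().shape[0] < 3:
        raise ValueError("need at least 3 distinct (traps, days) design points")
    y = df["N_hat"] / df["true_density"]
    X = sm.add_constant(df[["n_days", "n_traps"]].astype(float))
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("collinear design: cannot separate trap and day effects")
    fit = sm.OLS(y, X).fit()
    r2 = 1.0 if np.isclose(y.var(), 0.0) else float(fit.rsquared)
    return AreaModel(
        intercept=float(fit.params["const"]),
        coef_days=float(fit.params["n_days"]),
        coef_traps=float(fit.params["n_traps"]),
        r_squared=r2,
        resid_se=float(np.sqrt(fit.mse_resid)),
        min_area_km2=float(max(y.min(), 1e-6)),
    )


def fit_area_model(
    trap_grid=(1, 2, 4, 6, 8, 10),
    day_grid=(4, 8, 12, 16, 20),
    n_sims: int = 5,
    seed: int = 0,
    **sim_kwargs,
) -> AreaModel:
    """Calibrate the effective-area model by simulation over a design grid."""
    rng = np.random.default_rng(seed)
    records = []
    for R in trap_grid:
        for Dd in day_grid:
            for _ in range(n_sims):
                truth, series = simulate_removal_landscape(
                    n_traps=R, n_nights=Dd, rng=rng, **sim_kwargs
                )
                if series.total_removed < 1:
                    continue
                try:
                    post = removal.fit_removal(series)
                except ValueError:
                    continue
                records.append(
                    {
                        "N_hat": post.N0_median,
                        "true_density": truth.true_density,
                        "n_traps": R,
                        "n_days": Dd,
                    }
                )
    return effective_area_regression(records)


def removal_bias_surface(
    trap_grid=tuple(range(1, 11)),
    day_grid=tuple(range(4, 21, 2)),
    n_sims: int = 20,
    seed: int = 0,
    area_model: AreaModel | None = None,
    **sim_kwargs,
) -> list[ReductionCell]:
    """Simulated true-bias / variance / cost surface for removal designs.

    Density per simulation is the posterior-median abundance divided by
    the area the effort-area model predicts for that design; bias is
    relative to the simulation's true density.
    """
    if n_sims < 1:
        raise ValueError("need at least one simulation per cell")
    if area_model is None:
        area_model = fit_area_model(seed=seed, **sim_kwargs)
    rng = np.random.default_rng(seed + 1)
    cells = []
    for R in trap_grid:
        for Dd in day_grid:
            biases, dens = [], []
            n_fail = 0
            for _ in range(n_sims):
                truth, series = simulate_removal_landscape(
                    n_traps=R, n_nights=Dd, rng=rng, **sim_kwargs
                )
                if series.total_removed < 1 or truth.true_density <= 0:
                    n_fail += 1
                    continue
                try:
                    post = removal.fit_removal(series)
                except ValueError:
                    n_fail += 1
                    continue
                d_hat = post.N0_median / area_model.predict(R, Dd)
                dens.append(d_hat)
                biases.append((d_hat - truth.true_density) / truth.true_density)
                if not post.converged:
                    n_fail += 1
            cells.append(
                ReductionCell(
                    effort=costs.EffortConfig("removal", R, Dd),
                    scaled_bias=float(np.mean(biases)) if biases else np.nan,
                    variance=float(np.var(dens, ddof=1)) if len(dens) > 1 else 0.0,
                    cost_usd=costs.calibrated_cost("removal", R, Dd),
                    prop_converged=max(0.0, (n_sims - n_fail) / n_sims),
                    n_replicates=n_sims,
                )
            )
    return cells


def surface_frame(cells: list[ReductionCell]) -> pd.DataFrame:
    """Tidy CSV-ready view of a list of reduction cells."""
    return pd.DataFrame(
        [
            {
                "method": c.effort.method,
                "n_units": c.effort.n_units,
                "n_days": c.effort.n_days,
                "scaled_bias": c.scaled_bias,
                "abs_scaled_bias": c.abs_scaled_bias,
                "variance": c.variance,
                "cost_usd": c.cost_usd,
                "prop_converged": c.prop_converged,
                "n_replicates": c.n_replicates,
            }
            for c in cells
        ]
    )


__all__ = [
    "ReductionCell",
    "SimTruth",
    "AreaModel",
    "enumerate_camera_subgrids",
    "scaled_bias",
    "camera_grid_coords",
    "subgrid_indices",
    "histories_from_detections",
    "reduce_fecal",
    "reduce_camera",
    "clustered_centroids",
    "place_traps",
    "simulate_removal_landscape",
    "effective_area_regression",
    "fit_area_model",
    "removal_bias_surface",
    "surface_frame",
    "THETA_GIVEN_ENCOUNTER_DEFAULT",
]
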