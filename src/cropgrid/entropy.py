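"""Cross-entropy allocation: informed priors plus a constrained KL projection.

The allocator minimizes sum s*ln(s/pi) over pixel shares s of each
(crop, system) physical-area target, subject to

* adding-up: shares of each (crop, system) sum to 1 within the SRU;
* capacity: total physical area per pixel <= (possibly adjusted) cropland;
* elementwise caps: irrigated area per pixel, and (optionally) the suitable
  area per (pixel, crop, system).

The problem decomposes by SRU. Each SRU subproblem is solved through its
smooth concave Lagrangian dual: given multipliers, the primal is closed-form
(prior times a negative exponential of the priced constraints, normalized),
and the dual is maximized with L-BFGS-B. This is deterministic and scales to
tens of thousands of variables.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import (
    AllocationInfeasibleError,
    ConvergenceError,
    DegeneratePriorError,
    ValidationError,
)
from .types import (
    IRRIGATED,
    SYSTEMS,
    AllocationResult,
    AncillaryLayers,
    CropDefinition,
    EntropyConfig,
    Landscape,
    PriorShares,
    validate_sru_table,
)

#: Capacity floor (ha) granted to zero-cropland pixels of an SRU whose
#: cropland had to be expanded; lets the solver spill onto such pixels, which
#: is how modeled presence shares can exceed 100 percent.
_ADJUST_FLOOR = 1e-3


def access_weight(
    rural_pop_density: np.ndarray, *, subsistence: bool = False
) -> np.ndarray:
    """Bounded, monotone-increasing market-access weight from population.

    Commercial systems are favored near people (market proximity proxy);
    the subsistence system uses the reciprocal weight.
    """
    d = np.asarray(rural_pop_density, dtype=float)
    scale = d.mean() if d.mean() > 0 else 1.0
    w = 1.0 + d / (d + scale)  # in [1, 2)
    return 1.0 / w if subsistence else w


def build_priors(
    landscape: Landscape,
    ancillary: AncillaryLayers,
    crops: list[CropDefinition],
    config: EntropyConfig,
    *,
    on_degenerate: str = "raise",
) -> PriorShares:
    """Informed prior shares pi(pixel, crop, system).

    pi is proportional to suitable area times potential revenue (potential
    yield, times price when ``use_prices``) times the access weight, then
    normalized per (crop, system). ``on_degenerate`` selects behaviour when a
    (crop, system) prior is identically zero: ``"raise"`` or ``"cropland"``
    (fall back to a cropland-proportional prior).
    """
    if on_degenerate not in ("raise", "cropland"):
        raise ValidationError(f"unknown on_degenerate mode {on_degenerate!r}")
    landscape.validate()
    ancillary.validate(landscape)
    n_crops, n_sys = len(crops), len(SYSTEMS)
    pi = np.zeros((n_crops, n_sys, *landscape.shape))
    for ci, crop in enumerate(crops):
        aci = ancillary.crop_index(crop.crop_id)
        for s in range(n_sys):
            value = ancillary.potential_yield[aci, s]
            if config.use_prices:
                value = value * crop.price
            w = ancillary.suitable_area[aci, s] * value
            if config.use_market_access:
                w = w * access_weight(
                    ancillary.rural_pop_density,
                    subsistence=SYSTEMS[s] == "rainfed_subsistence",
                )
            w = np.where(landscape.country_mask, w, 0.0)
            total = w.sum()
            if total <= 0:
                if on_degenerate == "raise":
                    raise DegeneratePriorError(
                        f"all-zero prior for crop {crop.crop_id}, system {SYSTEMS[s]}"
                    )
                w = np.where(landscape.country_mask, landscape.cropland, 0.0)
                total = w.sum()
                if total <= 0:
                    raise DegeneratePriorError("no cropland to fall back on")
            pi[ci, s] = w / total
    prior = PriorShares(crop_ids=tuple(c.crop_id for c in crops), pi=pi)
    prior.validate()
    return prior


def _system_shares(
    landscape: Landscape,
    ancillary: AncillaryLayers,
    mask: np.ndarray,
    config: EntropyConfig,
) -> np.ndarray:
    """Default split of an SRU's harvested area across production systems."""
    crop_total = float(landscape.cropland[mask].sum())
    irr_total = float(ancillary.irrigated_area[mask].sum())
    irr_share = min(irr_total / crop_total, 1.0) if crop_total > 0 else 0.0
    shares = np.empty(len(SYSTEMS))
    shares[IRRIGATED] = irr_share
    shares[1:] = (1.0 - irr_share) * np.asarray(config.rainfed_split)
    return shares


def physical_targets(
    sru_rows,
    crops_by_id: dict[int, CropDefinition],
    shares: np.ndarray,
) -> dict[int, np.ndarray]:
    """Per-crop physical-area targets by system: harvested*share/CI."""
    targets = {}
    for row in sru_rows.itertuples():
        crop = crops_by_id[int(row.crop_id)]
        ci = np.asarray(crop.cropping_intensity, dtype=float)
        with np.errstate(divide="ignore"):
            t = np.where(ci > 0, row.harvested_area_ha * shares / np.maximum(ci, 1e-300), 0.0)
        targets[int(row.crop_id)] = t
    return targets


def adjust_cropland(
    landscape: Landscape,
    sru_table,
    crops: list[CropDefinition],
    slack: float,
    *,
    ancillary: AncillaryLayers | None = None,
    config: EntropyConfig | None = None,
) -> tuple[np.ndarray, dict[int, bool]]:
    """Per-pixel capacity, expanded minimally where an SRU is over-committed.

    Where the physical area an SRU must absorb exceeds its cropland, every
    pixel's capacity in that SRU is scaled by the minimal restoring factor
    (zero-cropland pixels receive a small floor first, so spill-over onto
    them — and presence shares above 100% — is representable). A factor
    beyond ``slack`` is a hard infeasibility.
    """
    if slack < 1:
        raise ValidationError("slack must be >= 1")
    validate_sru_table(sru_table)
    config = config or EntropyConfig()
    crops_by_id = {c.crop_id: c for c in crops}
    capacity = landscape.cropland.copy()
    flags: dict[int, bool] = {}
    for (sid, level), rows in sru_table.groupby(["sru_id", "admin_level"]):
        mask = landscape.unit_mask(int(level), int(sid))
        if not mask.any():
            raise ValidationError(f"SRU {sid} (level {level}) has no pixels")
        if ancillary is not None:
            shares = _system_shares(landscape, ancillary, mask, config)
        else:
            shares = np.array([0.0, *config.rainfed_split])
        targets = physical_targets(rows, crops_by_id, shares)
        required = float(sum(t.sum() for t in targets.values()))
        available = float(landscape.cropland[mask].sum())
        flags[int(sid)] = False
        if required <= available or required == 0:
            continue
        base = np.maximum(landscape.cropland[mask], 0.0)
        if available <= 0:
            base = np.full(mask.sum(), _ADJUST_FLOOR)
            available = float(base.sum())
        factor = required / available
        if factor > slack:
            raise AllocationInfeasibleError(
                f"SRU {sid}: required {required:.1f} ha exceeds cropland "
                f"{available:.1f} ha by more than the allowed slack {slack}",
                sru_id=int(sid),
            )
        capacity[mask] = np.maximum(base, _ADJUST_FLOOR) * factor
        flags[int(sid)] = True
    return capacity, flags


def _solve_sru_dual(
    log_pi: np.ndarray,  # (n_var, n_px) log prior per (crop,sys) row
    targets: np.ndarray,  # (n_var,) physical-area targets
    cap: np.ndarray,  # (n_px,) pixel capacity
    upper: np.ndarray,  # (n_var, n_px) elementwise area caps (inf allowed)
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, dict]:
    """Maximize the dual of the per-SRU KL projection; return shares s."""
    n_var, n_px = log_pi.shape
    # normalize the area unit so dual gradients are O(1)
    sigma = float(max(targets.max(), 1e-12))
    targets = targets / sigma
    cap = cap / sigma
    upper = upper / sigma
    t = targets[:, None]  # broadcast over pixels
    fin = np.isfinite(upper) & (log_pi > -np.inf)
    n_gamma = int(fin.sum())

    def primal(alpha: np.ndarray, gamma_flat: np.ndarray) -> np.ndarray:
        expo = np.zeros((n_var, n_px))
        expo[fin] = gamma_flat
        logq = log_pi - t * (alpha[None, :] + expo)
        log_z = logsumexp(logq, axis=1, keepdims=True)
        return np.exp(logq - log_z)

    def neg_dual(x: np.ndarray):
        alpha, gamma_flat = x[:n_px], x[n_px:]
        expo = np.zeros((n_var, n_px))
        expo[fin] = gamma_flat
        logq = log_pi - t * (alpha[None, :] + expo)
        log_z = logsumexp(logq, axis=1)
        s = np.exp(logq - log_z[:, None])
        area = t * s
        g = -(log_z.sum()) - alpha @ cap - gamma_flat @ upper[fin]
        grad_alpha = area.sum(axis=0) - cap
        grad_gamma = (area - upper)[fin]
        return -g, -np.concatenate([grad_alpha, grad_gamma])

    def residuals(x: np.ndarray):
        s = primal(x[:n_px], x[n_px:])
        area = t * s
        scale = max(cap.max(initial=0.0), targets.max(), 1.0)
        cap_viol = float(np.max(area.sum(axis=0) - cap, initial=0.0)) / scale
        up_viol = (
            float(np.max((area - upper)[fin], initial=0.0)) / scale if n_gamma else 0.0
        )
        return s, max(cap_viol, up_viol, 0.0), {"capacity": cap_viol, "upper": up_viol}

    x = np.zeros(n_px + n_gamma)
    bounds = [(0.0, None)] * (n_px + n_gamma)
    n_it = 0
    gtol = 1e-10
    s = primal(x[:n_px], x[n_px:])
    resid_detail: dict = {}
    for attempt in range(4):
        res = minimize(
            neg_dual,
            x,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": max_iter,
                "maxfun": 10 * max_iter,
                "ftol": 1e-18,
                "gtol": gtol,
            },
        )
        x = res.x
        n_it += int(res.nit)
        s, resid, resid_detail = residuals(x)
        if resid <= max(tol, 1e-13):
            break
        gtol *= 1e-2  # tighten and restart from the current multipliers
    else:
        # L-BFGS-B can stall within line-search rounding of the optimum;
        # squeeze out the residual violation with a multiplicative
        # feasibility polish (scale overloaded pixels down, renormalize)
        for _ in range(200):
            area = t * s
            load = area.sum(axis=0)
            shrink = np.where(load > cap, np.where(load > 0, cap / np.maximum(load, 1e-300), 1.0), 1.0)
            s = s * shrink[None, :]
            if n_gamma:
                over = np.where(
                    (t * s > upper) & fin, upper / np.maximum(t * s, 1e-300), 1.0
                )
                s = s * over
            s = s / s.sum(axis=1, keepdims=True)
            area = t * s
            scale = max(cap.max(initial=0.0), targets.max(), 1.0)
            cap_viol = float(np.max(area.sum(axis=0) - cap, initial=0.0)) / scale
            up_viol = (
                float(np.max((area - upper)[fin], initial=0.0)) / scale
                if n_gamma
                else 0.0
            )
            resid = max(cap_viol, up_viol, 0.0)
            resid_detail = {"capacity": cap_viol, "upper": up_viol}
            if resid <= max(tol, 1e-13):
                break
        if resid > max(tol, 1e-13):
            raise ConvergenceError(
                f"entropy solver residual {resid:.3g} exceeds tolerance "
                f"{tol:.3g} after {n_it} iterations",
                residuals=resid_detail,
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_terms = np.where(s > 0, s * (np.log(np.where(s > 0, s, 1.0)) - log_pi), 0.0)
    objective = float(kl_terms.sum())
    info = {"objective": objective, "residual": resid, "n_iter": n_it}
    return s, objective, info


def allocate_cross_entropy(
    priors: PriorShares,
    sru_table,
    landscape: Landscape,
    ancillary: AncillaryLayers,
    crops: list[CropDefinition],
    config: EntropyConfig | None = None,
) -> AllocationResult:
    """Allocate SRU statistics to pixels by constrained cross-entropy.

    Returns harvested area, production and yield per pixel and crop (systems
    summed / area-weighted). Per-(SRU, crop) harvested and production totals
    match the table exactly by construction.
    """
    config = config or EntropyConfig()
    validate_sru_table(sru_table)
    priors.validate()
    crops_by_id = {c.crop_id: c for c in crops}
    n_crops, n_sys = len(crops), len(SYSTEMS)
    crop_pos = {c.crop_id: i for i, c in enumerate(crops)}
    shape = landscape.shape

    capacity, flags = adjust_cropland(
        landscape, sru_table, crops, config.cropland_slack,
        ancillary=ancillary, config=config,
    )

    physical = np.zeros((n_crops, n_sys, *shape))
    solver_log: dict[int, dict] = {}

    for (sid, level), rows in sru_table.groupby(["sru_id", "admin_level"]):
        sid, level = int(sid), int(level)
        mask = landscape.unit_mask(level, sid)
        px = np.nonzero(mask)
        n_px = len(px[0])
        shares = _system_shares(landscape, ancillary, mask, config)
        targets = physical_targets(rows, crops_by_id, shares)

        # irrigated entitlement cannot exceed what the irrigated/suitability
        # caps can hold; shift any excess (in harvested units, preserving
        # conservation) onto the rainfed systems
        for cid, tvec in targets.items():
            crop = crops_by_id[cid]
            aci = ancillary.crop_index(cid)
            u_irr = ancillary.irrigated_area[mask]
            if config.use_suitability_constraint:
                u_irr = np.minimum(u_irr, ancillary.suitable_area[aci, IRRIGATED][mask])
            cap_irr = 0.95 * float(u_irr.sum())
            if tvec[IRRIGATED] > cap_irr:
                ci_vec = np.asarray(crop.cropping_intensity, dtype=float)
                h_excess = (tvec[IRRIGATED] - cap_irr) * ci_vec[IRRIGATED]
                tvec[IRRIGATED] = cap_irr
                split = np.asarray(config.rainfed_split)
                with np.errstate(divide="ignore"):
                    tvec[1:] += np.where(
                        ci_vec[1:] > 0,
                        h_excess * split / np.maximum(ci_vec[1:], 1e-300),
                        0.0,
                    )

        var_keys = []  # (crop_id, system index)
        t_list = []
        for cid, tvec in sorted(targets.items()):
            for s in range(n_sys):
                if tvec[s] > 0:
                    var_keys.append((cid, s))
                    t_list.append(tvec[s])
        if not var_keys:
            solver_log[sid] = {"objective": 0.0, "residual": 0.0, "n_iter": 0}
            continue
        t_arr = np.asarray(t_list)
        cap = capacity[mask]

        upper = np.full((len(var_keys), n_px), np.inf)
        pi_local = np.empty((len(var_keys), n_px))
        for v, (cid, s) in enumerate(var_keys):
            aci = ancillary.crop_index(cid)
            if s == IRRIGATED:
                upper[v] = np.minimum(upper[v], ancillary.irrigated_area[mask])
            if config.use_suitability_constraint:
                upper[v] = np.minimum(upper[v], ancillary.suitable_area[aci, s][mask])
            pi_local[v] = priors.pi[crop_pos[cid], s][mask]

        # pixels with no capacity (or a zero cap) can never hold area
        blocked = (cap[None, :] <= 0) | (upper <= 0)
        pi_local = np.where(blocked, 0.0, pi_local)
        row_tot = pi_local.sum(axis=1)
        dead = row_tot <= 0
        if dead.any():
            cid, s = var_keys[int(np.argmax(dead))]
            raise DegeneratePriorError(
                f"SRU {sid}: prior for crop {cid}, system {SYSTEMS[s]} is zero "
                "on every feasible pixel"
            )
        pi_local = pi_local / row_tot[:, None]

        # quick feasibility screens with named culprits
        for v, (cid, s) in enumerate(var_keys):
            u = upper[v]
            u_tot = u[np.isfinite(u)].sum() + (np.inf if np.isinf(u).any() else 0.0)
            if u_tot < t_arr[v] * (1 - 1e-12):
                raise AllocationInfeasibleError(
                    f"SRU {sid}: caps for crop {cid}/{SYSTEMS[s]} sum to "
                    f"{u_tot:.1f} ha < target {t_arr[v]:.1f} ha",
                    sru_id=sid, crop_id=cid,
                )
        if cap.sum() < t_arr.sum() * (1 - 1e-12):
            raise AllocationInfeasibleError(
                f"SRU {sid}: capacity {cap.sum():.1f} ha < total target "
                f"{t_arr.sum():.1f} ha",
                sru_id=sid,
            )

        with np.errstate(divide="ignore"):
            log_pi = np.log(pi_local)
        s_opt, objective, info = _solve_sru_dual(
            log_pi, t_arr, cap, upper, config.solver_tol, config.max_iter
        )
        solver_log[sid] = info
        area = t_arr[:, None] * s_opt
        for v, (cid, s) in enumerate(var_keys):
            plane = physical[crop_pos[cid], s]
            plane[px] = plane[px] + area[v]

    result = _to_result(
        physical, sru_table, landscape, ancillary, crops,
        method="entropy", config=config, flags=flags,
    )
    result.provenance["solver"] = solver_log
    return result


def _to_result(
    physical: np.ndarray,
    sru_table,
    landscape: Landscape,
    ancillary: AncillaryLayers | None,
    crops: list[CropDefinition],
    *,
    method: str,
    config: EntropyConfig | None,
    flags: dict[int, bool],
) -> AllocationResult:
    """Convert physical area to harvested/production/yield rasters.

    Production uses per-system potential yields rescaled so every
    (SRU, crop) production total matches the statistics table.
    """
    n_crops = len(crops)
    shape = landscape.shape
    crop_pos = {c.crop_id: i for i, c in enumerate(crops)}
    harvested_sys = np.empty_like(physical)
    for i, crop in enumerate(crops):
        harvested_sys[i] = physical[i] * np.asarray(crop.cropping_intensity)[:, None, None]
    harvested = harvested_sys.sum(axis=1)

    production = np.zeros((n_crops, *shape))
    for (sid, level), rows in sru_table.groupby(["sru_id", "admin_level"]):
        mask = landscape.unit_mask(int(level), int(sid))
        for row in rows.itertuples():
            i = crop_pos[int(row.crop_id)]
            if ancillary is not None:
                aci = ancillary.crop_index(int(row.crop_id))
                raw = harvested_sys[i][:, mask] * ancillary.potential_yield[aci][:, mask]
            else:
                raw = harvested_sys[i][:, mask]
            raw_tot = raw.sum()
            if raw_tot > 0:
                production[i][mask] = raw.sum(axis=0) * (row.production_mt / raw_tot)
            elif row.production_mt > 0 and harvested[i][mask].sum() > 0:
                h = harvested[i][mask]
                production[i][mask] = row.production_mt * h / h.sum()

    with np.errstate(divide="ignore", invalid="ignore"):
        yield_ = np.where(harvested > 0, production / np.maximum(harvested, 1e-300), 0.0)

    return AllocationResult(
        crop_ids=tuple(c.crop_id for c in crops),
        systems=SYSTEMS,
        physical_area=physical,
        harvested_area=harvested,
        production=production,
        yield_=yield_,
        provenance={
            "method": method,
            "config": None if config is None else vars(config).copy(),
        },
        adjust_flags=flags,
    )
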