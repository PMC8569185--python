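"""Quantification of binding, cAMP and BRET assays at the kappa-opioid receptor.

Competition displacement curves are fit on the raw cpm scale with a
three-parameter logistic Hill equation (slope fixed at 1) and converted to
inhibition constants with the Cheng-Prusoff approximation
Ki = IC50 / (1 + [L]/Kd). cAMP concentration-response data are normalized to
the inhibition elicited by the reference agonist (dyn A 1-13) at 10 uM
(= 100%) and fit with the monophasic inhibition equation
y = Emax / (1 + EC50/c) (bottom fixed at 0). Ligand-induced BRET is the
pointwise difference of acceptor/donor emission ratios between ligand and
vehicle traces; relative recruitment is the windowed mean (default
311-2411 s) divided by the reference ligand's windowed mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from blennymine.assays import BindingDataset, BRETTrace, DoseResponseDataset
from blennymine.exceptions import FitError, InputError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_BRET_WINDOW = (311.0, 2411.0)
EMAX_SANITY_BOUND = 120.0  # percent; exceeding it only warns
_FIT_TOL = 1e-12


@dataclass
class FitResult:
    """Result of a logistic concentration-response fit.

    ``c50`` is the fitted midpoint on the nM scale (IC50 for displacement,
    EC50 for activation); derived quantities (``ki``, ``ec50``, ``emax``) are
    populated by the higher-level fit wrappers.
    """

    top: float
    bottom: float
    log_c50: float
    sse: float
    converged: bool
    degenerate: bool = False
    stderr: dict[str, float] | None = None
    ki: float | None = None
    ec50: float | None = None
    emax: float | None = None

    @property
    def c50(self) -> float:
        return 10.0 ** self.log_c50


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputError("points must be (concentration, response) pairs")
    conc, resp = arr[:, 0], arr[:, 1]
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be positive")
    if not np.all(np.isfinite(resp)):
        raise InputError("responses must be finite")
    return conc, resp


def fit_logistic3(points, direction: str = "decreasing") -> FitResult:
    """Least-squares three-parameter logistic fit with Hill slope fixed at 1.

    Fits y = bottom + (top - bottom) / (1 + 10**(s*(log10 c - log10 c50)))
    with s = +1 for ``decreasing`` responses (displacement, cpm falls with
    concentration) and s = -1 for ``increasing``. Uses three deterministic
    starts (data-driven midpoint and +-1 log-unit shifts) and reports
    convergence; flat data yield a degenerate, non-converged result.
    """
    if direction not in ("decreasing", "increasing"):
        raise ParameterError(f"direction must be decreasing/increasing, got {direction}")
    conc, resp = _as_points(points)
    if len(np.unique(conc)) < 4:
        raise FitError("fit_logistic3 requires >= 4 distinct concentrations")
    if np.ptp(resp) == 0.0:
        return FitResult(
            top=float(resp[0]),
            bottom=float(resp[0]),
            log_c50=math.nan,
            sse=0.0,
            converged=False,
            degenerate=True,
        )
    s = 1.0 if direction == "decreasing" else -1.0
    logc = np.log10(conc)

    def model(lc, top, bottom, log_c50):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (s * (lc - log_c50)))

    # Data-driven initialization: extremes from the concentration ordering,
    # midpoint from the concentration whose mean response is nearest mid-range.
    order = np.argsort(conc)
    lo_resp = float(np.mean(resp[order][: max(1, len(resp) // 6)]))
    hi_resp = float(np.mean(resp[order][-max(1, len(resp) // 6):]))
    if direction == "decreasing":
        top0, bottom0 = lo_resp, hi_resp
    else:
        top0, bottom0 = hi_resp, lo_resp
    mid = (top0 + bottom0) / 2.0
    grid = np.unique(conc)
    means = np.array([resp[conc == c].mean() for c in grid])
    log_c50_0 = float(np.log10(grid[np.argmin(np.abs(means - mid))]))

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for shift in (0.0, -1.0, 1.0):
        p0 = (top0, bottom0, log_c50_0 + shift)
        try:
            popt, pcov = curve_fit(
                model, logc, resp, p0=p0, maxfev=20_000,
                xtol=_FIT_TOL, ftol=_FIT_TOL, gtol=_FIT_TOL,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(logc, *popt) - resp) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return FitResult(
            top=math.nan, bottom=math.nan, log_c50=math.nan,
            sse=math.inf, converged=False,
        )
    sse, popt, pcov = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [math.nan] * 3
    return FitResult(
        top=float(popt[0]),
        bottom=float(popt[1]),
        log_c50=float(popt[2]),
        sse=sse,
        converged=True,
        stderr={"top": float(perr[0]), "bottom": float(perr[1]), "log_c50": float(perr[2])},
    )


def cheng_prusoff(ic50: float, ligand_conc: float, kd: float) -> float:
    """Cheng-Prusoff approximation: Ki = IC50 / (1 + [L]/Kd)."""
    if ic50 <= 0 or ligand_conc <= 0 or kd <= 0:
        raise ParameterError("cheng_prusoff requires positive IC50, [L] and Kd")
    return ic50 / (1.0 + ligand_conc / kd)


def fit_binding(dataset: BindingDataset) -> FitResult:
    """Fit a displacement curve on raw cpm and derive Ki via Cheng-Prusoff.

    The bottom plateau is left free (not pinned to the naloxone-defined
    nonspecific level), mirroring determination of nonspecific binding both
    from the curve fit and experimentally.
    """
    result = fit_logistic3(dataset.replicates, direction="decreasing")
    if result.converged:
        result.ki = cheng_prusoff(
            result.c50, dataset.radioligand_conc, dataset.radioligand_kd
        )
    return result


def normalize_camp(
    dataset: DoseResponseDataset, reference_raw_at_10uM: float | None = None
) -> DoseResponseDataset:
    """Express raw cAMP-inhibition responses as percent of the reference effect.

    The reference effect (inhibition by 10 uM dyn A 1-13) maps to 100%.
    """
    reference = (
        dataset.reference_response_at_10uM
        if reference_raw_at_10uM is None
        else reference_raw_at_10uM
    )
    if reference == 0:
        raise ParameterError("reference effect is zero; cannot normalize")
    if dataset.scale == "percent":
        return dataset
    replicates = [(c, 100.0 * y / reference) for c, y in dataset.replicates]
    return DoseResponseDataset(
        ligand_id=dataset.ligand_id,
        replicates=replicates,
        reference_response_at_10uM=100.0,
        scale="percent",
    )


def fit_inhibition(dataset: DoseResponseDataset) -> FitResult:
    """Fit the monophasic inhibition equation y = Emax / (1 + EC50/c).

    Requires percent-scale data (bottom fixed at 0, Hill slope 1). The fitted
    plateau is Emax; an Emax above 120% triggers a warning only.
    """
    if dataset.scale != "percent":
        raise InputError("fit_inhibition expects a percent-scale dataset; normalize first")
    conc, resp = _as_points(dataset.replicates)
    if len(np.unique(conc)) < 4:
        raise FitError("fit_inhibition requires >= 4 distinct concentrations")
    if np.ptp(resp) == 0.0:
        return FitResult(
            top=float(resp[0]), bottom=0.0, log_c50=math.nan,
            sse=0.0, converged=False, degenerate=True,
        )
    logc = np.log10(conc)

    def model(lc, emax, log_ec50):
        return emax / (1.0 + 10.0 ** (log_ec50 - lc))

    emax0 = float(np.quantile(resp, 0.95))
    grid = np.unique(conc)
    means = np.array([resp[conc == c].mean() for c in grid])
    log_ec50_0 = float(np.log10(grid[np.argmin(np.abs(means - emax0 / 2.0))]))
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for shift in (0.0, -1.0, 1.0):
        try:
            popt, pcov = curve_fit(
                model, logc, resp, p0=(emax0, log_ec50_0 + shift), maxfev=20_000,
                xtol=_FIT_TOL, ftol=_FIT_TOL, gtol=_FIT_TOL,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(logc, *popt) - resp) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return FitResult(
            top=math.nan, bottom=0.0, log_c50=math.nan, sse=math.inf, converged=False
        )
    sse, popt, pcov = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [math.nan] * 2
    result = FitResult(
        top=float(popt[0]),
        bottom=0.0,
        log_c50=float(popt[1]),
        sse=sse,
        converged=True,
        stderr={"emax": float(perr[0]), "log_ec50": float(perr[1])},
        ec50=float(10.0 ** popt[1]),
        emax=float(popt[0]),
    )
    if result.emax is not None and result.emax > EMAX_SANITY_BOUND:
        logger.warning(
            "fit_inhibition: fitted Emax %.1f%% exceeds the %.0f%% sanity bound",
            result.emax,
            EMAX_SANITY_BOUND,
        )
    return result


def bret_ligand_induced(ligand: BRETTrace, vehicle: BRETTrace) -> pd.Series:
    """Ligand-induced BRET: (em510/em460)_ligand - (em510/em460)_vehicle.

    Computed pointwise on the ligand time grid; an unequal vehicle grid is
    linearly interpolated onto it (and must cover it).
    """
    lig_ratio = ligand.ratio
    if np.array_equal(ligand.times, vehicle.times):
        veh_ratio = vehicle.ratio
    else:
        if vehicle.times[0] > ligand.times[0] or vehicle.times[-1] < ligand.times[-1]:
            raise InputError("vehicle trace does not cover the ligand time grid")
        veh_ratio = np.interp(ligand.times, vehicle.times, vehicle.ratio)
    return pd.Series(lig_ratio - veh_ratio, index=pd.Index(ligand.times, name="time_s"))


def bret_relative(
    ligand_delta: pd.Series,
    reference_delta: pd.Series,
    window: tuple[float, float] = DEFAULT_BRET_WINDOW,
) -> float:
    """Windowed-mean ligand-induced BRET as percent of the reference ligand.

    Samples with window[0] <= t <= window[1] (endpoints inclusive) enter the
    means. Invariant to any common positive rescaling of both emission
    channels, since only emission ratios are involved.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ParameterError(f"empty BRET window {window}")
    lig = ligand_delta[(ligand_delta.index >= t0) & (ligand_delta.index <= t1)]
    ref = reference_delta[(reference_delta.index >= t0) & (reference_delta.index <= t1)]
    if lig.empty or ref.empty:
        raise ParameterError("no samples inside the BRET quantification window")
    return 100.0 * float(lig.mean()) / float(ref.mean())


def assemble_summary(per_ligand: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """Summarize per-ligand metrics as mean +- sample SD over experiments.

    ``per_ligand`` maps ligand -> metric -> list of values from independent
    experiments (e.g. {"blenniorphin 1-8": {"ki_nM": [...], "ec50_nM": [...]}}).
    SD uses the n-1 denominator and is NaN for a single experiment.
    """
    if not per_ligand or not any(
        values for metrics in per_ligand.values() for values in metrics.values()
    ):
        logger.error("assemble_summary: no converged fits to summarize")
        return pd.DataFrame(columns=["ligand"])
    rows = []
    for ligand, metrics in per_ligand.items():
        row: dict[str, float | str | int] = {"ligand": ligand}
        for metric, values in metrics.items():
            arr = np.asarray(values, dtype=float)
            row[f"{metric}_mean"] = float(arr.mean()) if arr.size else math.nan
            row[f"{metric}_sd"] = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
            row[f"{metric}_n"] = int(arr.size)
        rows.append(row)
    return pd.DataFrame(rows)
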