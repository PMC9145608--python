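"""Dual-stain viability, IC50 dose-response, and mechanism classification.

Dead cells take up propidium iodide (PI); live cells convert calcein-AM to
fluorescent calcein. Two counting modes mirror bench practice: gate both
stains, or — when calcein contouring fails — count everything with Hoechst
and subtract the PI-positive dead cells (``live = total - dead`` exactly).

Growth of a treated well is its total cell number (live + dead) as a
percentage of the untreated mean. Growth versus concentration is fitted
with a four-parameter logistic (4PL) on log10 concentration, and the IC50
is the concentration where the *fitted curve* crosses 50% growth; a curve
that never crosses 50% inside the tested range is reported as "> cmax".
The % of dead cells near the IC50 classifies the drug mechanism into four
bins from primarily cytostatic (growth arrest) to mainly cytotoxic (cell
killing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .gating import Gate

MECHANISM_CLASSES = (
    "primarily cytostatic",
    "cytostatic >= cytotoxic",
    "cytostatic <= cytotoxic",
    "mainly cytotoxic",
)

# lower bin edges (% dead), lower bound closed: [0,30) [30,50) [50,70) [70,100]
_MECHANISM_EDGES = (30.0, 50.0, 70.0)


@dataclass
class WellViability:
    """Live/dead tally for one well; live + dead = total always holds."""

    well_id: str
    n_total: int
    n_dead: int
    n_live: int
    n_double_positive: int = 0  # PI+ and calcein+ in dual-gate mode (QC)
    flags: list[str] = field(default_factory=list)

    @property
    def percent_dead(self) -> float:
        return 100.0 * self.n_dead / self.n_total if self.n_total else 0.0


def quantify_live_dead(
    cells: pd.DataFrame,
    pi_gate: Gate,
    live_mode: str = "hoechst_subtraction",
    calcein_gate: Gate | None = None,
    min_cells: int = 100,
) -> WellViability:
    """Count dead (PI-positive) and live cells in one well's cell table.

    ``hoechst_subtraction``: live = total - dead (the fallback used when
    calcein contouring is unreliable; the partition identity is exact).
    ``calcein_gate``: live = calcein-positive and PI-negative; cells positive
    for both stains are counted dead (PI dominance) and tallied for QC.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    well_id = str(cells["well_id"].iloc[0]) if "well_id" in cells.columns else ""
    dead_mask = pi_gate.is_positive(cells)
    n_total = len(cells)
    n_dead = int(dead_mask.sum())
    flags = []
    if n_total < min_cells:
        flags.append(f"low_cell_count:{n_total}")
        warnings.warn(
            f"well {well_id!r}: only {n_total} cells for viability statistics",
            RuntimeWarning,
            stacklevel=2,
        )
    if live_mode == "hoechst_subtraction":
        # total from the Hoechst count; live = total - dead, exactly
        n_live = n_total - n_dead
        n_double = 0
    elif live_mode == "calcein_gate":
        if calcein_gate is None:
            raise ValueError("live_mode='calcein_gate' requires calcein_gate")
        cal_mask = calcein_gate.is_positive(cells)
        n_double = int((cal_mask & dead_mask).sum())  # PI dominance: dead
        n_live = int((cal_mask & ~dead_mask).sum())
        n_unclassified = int((~cal_mask & ~dead_mask).sum())
        # total = stained cells only, keeping live + dead = total exact
        n_total = n_live + n_dead
        if n_double:
            flags.append(f"double_positive:{n_double}")
        if n_unclassified:
            flags.append(f"unstained:{n_unclassified}")
    else:
        raise ValueError(f"unknown live_mode {live_mode!r}")
    return WellViability(
        well_id=well_id,
        n_total=n_total,
        n_dead=n_dead,
        n_live=n_live,
        n_double_positive=n_double,
        flags=flags,
    )


def growth_percent(treated: WellViability, untreated_mean_total: float) -> float:
    """Total cells (live + dead) as % of the untreated mean total."""
    if untreated_mean_total <= 0:
        raise ValueError("untreated mean total must be positive")
    return 100.0 * treated.n_total / untreated_mean_total


@dataclass
class DoseResponseResult:
    """Fitted dose-response curve and mechanism call for one drug series."""

    concentrations: np.ndarray  # uM, the distinct tested concentrations
    growth_percent_mean: np.ndarray  # % of untreated, per concentration
    params: dict  # 4PL parameters: top, bottom, ic50 (curve midpoint), hill
    ic50: float  # uM where fitted growth = 50; NaN when out of range
    ic50_label: str  # printable: "1.02" or "> 100"
    extrapolated: bool
    percent_dead_at_reference: float = float("nan")
    reference_concentration: float = float("nan")
    mechanism_class: str = ""
    flags: list[str] = field(default_factory=list)

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        p = self.params
        with np.errstate(divide="ignore"):
            frac = np.where(
                c > 0, c ** p["hill"] / (c ** p["hill"] + p["ic50"] ** p["hill"]), 0.0
            )
        return p["top"] + (p["bottom"] - p["top"]) * frac


def _fit_4pl(log_c: np.ndarray, growth: np.ndarray):
    def model(x, top, bottom, log_mid, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - log_mid)))

    g0 = growth[np.argsort(log_c)]
    mid_guess = float(np.interp(50.0, g0[::-1], np.sort(log_c)[::-1],
                                left=np.sort(log_c)[0], right=np.sort(log_c)[-1])) \
        if g0.min() < 50.0 < g0.max() else float(np.median(log_c))
    p0 = [min(float(growth.max()), 110.0), max(float(growth.min()), -10.0),
          mid_guess, 1.0]
    bounds = (
        [50.0, -10.0, log_c.min() - 3.0, 0.1],
        [110.0, 49.0, log_c.max() + 3.0, 10.0],
    )
    p0 = [float(np.clip(v, lo, hi)) for v, lo, hi in zip(p0, *bounds)]
    popt, _ = curve_fit(model, log_c, growth, p0=p0, bounds=bounds,
                        maxfev=20000)
    return popt, model


def fit_ic50(
    concentrations,
    growth_percents,
    cmax: float | None = None,
) -> DoseResponseResult:
    """Fit a 4PL growth-inhibition curve and read off the IC50.

    ``concentrations`` / ``growth_percents`` are flat, replicate-expanded
    arrays (repeat the concentration for each replicate). Concentration
    zero anchors the 100% normalisation upstream and is excluded from the
    log-scale fit. Requires >= 4 distinct non-zero concentrations. The top
    is constrained to <= 110% and the bottom to >= -10%.
    """
    conc = np.asarray(concentrations, dtype=float)
    growth = np.asarray(growth_percents, dtype=float)
    if conc.shape != growth.shape:
        raise ValueError("concentrations and growth_percents must align")
    nz = conc > 0
    distinct = np.unique(conc[nz])
    if len(distinct) < 4:
        raise ValueError(
            f"need >= 4 distinct non-zero concentrations, got {len(distinct)}"
        )
    cmax = float(cmax if cmax is not None else distinct.max())
    cmin = float(distinct.min())
    log_c = np.log10(conc[nz])
    g = growth[nz]

    flags = []
    try:
        popt, _ = _fit_4pl(log_c, g)
    except RuntimeError as err:
        raise RuntimeError(
            f"4PL fit did not converge on {len(g)} points "
            f"(growth range {g.min():.1f}-{g.max():.1f}%): {err}"
        ) from err
    top, bottom, log_mid, hill = (float(v) for v in popt)
    mid = 10.0 ** log_mid
    params = {"top": top, "bottom": bottom, "ic50": mid, "hill": hill}

    # concentration where the fitted curve crosses growth = 50%
    if bottom < 50.0 < top:
        ratio = (top - 50.0) / (50.0 - bottom)
        c50 = mid * ratio ** (1.0 / hill)
    else:
        c50 = float("inf")
    extrapolated = not (cmin <= c50 <= cmax)
    if c50 > cmax or not np.isfinite(c50):
        ic50, label = float("nan"), f"> {cmax:g}"
        flags.append("ic50_above_range")
    elif c50 < cmin:
        ic50, label = float(c50), f"< {cmin:g}"
        flags.append("ic50_below_range")
    else:
        ic50, label = float(c50), f"{c50:g}"

    means = np.array([growth[conc == c].mean() for c in distinct])
    # flag non-monotone dose-response beyond replicate noise
    resid = growth[nz] - (top + (bottom - top) * (conc[nz] ** hill)
                          / (conc[nz] ** hill + mid ** hill))
    rises = np.diff(means)
    if np.any(rises > max(10.0, 3.0 * resid.std())):
        flags.append("non_monotone_growth")
        warnings.warn("growth is non-monotone in concentration beyond noise",
                      RuntimeWarning, stacklevel=2)

    return DoseResponseResult(
        concentrations=distinct,
        growth_percent_mean=means,
        params=params,
        ic50=ic50,
        ic50_label=label,
        extrapolated=extrapolated,
        flags=flags,
    )


def classify_mechanism(percent_dead_at_reference: float) -> str:
    """Four-bin cytostatic/cytotoxic call from % dead near the IC50.

    Bins (% dead, lower bound closed): [0, 30) primarily cytostatic;
    [30, 50) cytostatic >= cytotoxic; [50, 70) cytostatic <= cytotoxic;
    [70, 100] mainly cytotoxic.
    """
    p = float(percent_dead_at_reference)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent dead must be in [0, 100], got {p}")
    idx = int(np.searchsorted(_MECHANISM_EDGES, p, side="right"))
    return MECHANISM_CLASSES[idx]


def pick_reference_concentration(concentrations, ic50: float) -> float:
    """Tested non-zero concentration nearest the fitted IC50 (log scale).

    Falls back to the highest tested concentration when the IC50 is not
    finite (curve never reached 50% within range).
    """
    conc = np.asarray(concentrations, dtype=float)
    conc = np.unique(conc[conc > 0])
    if len(conc) == 0:
        raise ValueError("no non-zero concentrations")
    if not np.isfinite(ic50) or ic50 <= 0:
        return float(conc.max())
    return float(conc[np.argmin(np.abs(np.log10(conc) - np.log10(ic50)))])


def dose_response_from_wells(
    wells: pd.DataFrame,
    percent_dead_col: str = "percent_dead",
) -> DoseResponseResult:
    """Full dose-response analysis from a per-well summary frame.

    ``wells`` needs columns ``concentration``, ``n_total`` and (optionally)
    ``percent_dead``. Untreated wells (concentration 0) define the 100%
    growth anchor; the mechanism class is evaluated at the tested
    concentration nearest the fitted IC50.
    """
    required = {"concentration", "n_total"}
    if not required.issubset(wells.columns):
        raise ValueError(f"wells frame needs columns {sorted(required)}")
    untreated = wells[wells["concentration"] == 0]
    if len(untreated) == 0:
        raise ValueError("no untreated (concentration 0) wells; cannot normalise")
    baseline = float(untreated["n_total"].mean())
    if baseline <= 0:
        raise ValueError("untreated wells contain no cells")
    treated = wells[wells["concentration"] > 0]
    growth = 100.0 * treated["n_total"].to_numpy() / baseline
    result = fit_ic50(treated["concentration"].to_numpy(), growth)
    if percent_dead_col in wells.columns:
        ref = pick_reference_concentration(
            treated["concentration"].to_numpy(), result.ic50
        )
        at_ref = wells[wells["concentration"] == ref]
        pdead = float(at_ref[percent_dead_col].mean())
        result.reference_concentration = ref
        result.percent_dead_at_reference = pdead
        result.mechanism_class = classify_mechanism(min(max(pdead, 0.0), 100.0))
    return result
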