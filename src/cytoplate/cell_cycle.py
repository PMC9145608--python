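"""Cell-cycle phase calling from per-nucleus DNA (Hoechst) content.

A DNA-content histogram of a cycling population is bimodal: a 2N peak
(G0/G1), a 4N peak at twice its position (G2/M), and an S-phase bridge in
between. This module locates the two peaks on a kernel-smoothed histogram,
places symmetric windows around them (default half-width 0.15x the peak
position — the visible "box gates" of the instrument output), and calls
five compartments: sub-G1 below the G1 window, G0/G1, S between the
windows, G2/M, and >4N above the G2 window.

Window counting alone over-counts G1 and G2/M, because S-phase cells near
2N or 4N fall inside the peak windows. The reported ``fractions`` therefore
apply a rectangular S-bridge correction: the S density is estimated from
the inter-window region (where only S-phase cells live), extrapolated over
the full 2N-4N span, and the corresponding share is moved out of the two
peak windows. Raw window counts remain available as ``window_fractions``,
and the per-cell ``assign_phase`` lookup stays a pure window rule. This is
deliberately *not* Dean-Jett-Fox mixture deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .gating import Gate, percent_positive

PHASES = ("sub-G1", "G0/G1", "S", "G2/M", ">4N")
CYCLE_PHASES = ("G0/G1", "S", "G2/M")


@dataclass
class CellCycleFit:
    """Fitted DNA-content model for one cell population.

    ``fractions`` are the S-bridge-corrected compartment probabilities over
    :data:`PHASES`; ``window_fractions`` the raw window-count ones. Both sum
    to 1. ``flags`` records fallbacks (e.g. no G2 mode found, peak ratio
    outside [1.8, 2.2]).
    """

    g1_peak: float
    g2_peak: float
    g1_window: tuple[float, float]
    g2_window: tuple[float, float]
    fractions: dict[str, float]
    window_fractions: dict[str, float]
    n_cells: int
    window_halfwidth_frac: float = 0.15
    flags: list[str] = field(default_factory=list)

    def three_phase_fractions(self, corrected: bool = True) -> dict[str, float]:
        """G0/G1 / S / G2/M renormalised without sub-G1 and >4N debris."""
        src = self.fractions if corrected else self.window_fractions
        total = sum(src[p] for p in CYCLE_PHASES)
        if total <= 0:
            return {p: float("nan") for p in CYCLE_PHASES}
        return {p: src[p] / total for p in CYCLE_PHASES}

    def to_dict(self) -> dict:
        return {
            "g1_peak": self.g1_peak,
            "g2_peak": self.g2_peak,
            "g1_window": list(self.g1_window),
            "g2_window": list(self.g2_window),
            "fractions": self.fractions,
            "window_fractions": self.window_fractions,
            "n_cells": self.n_cells,
            "window_halfwidth_frac": self.window_halfwidth_frac,
            "flags": self.flags,
        }


def _smoothed_histogram(values: np.ndarray, bins: int,
                        smooth_sigma_bins: float):
    upper = float(np.quantile(values, 0.999)) * 1.25
    lower = 0.0
    if upper <= lower:
        upper = float(values.max()) * 1.25 or 1.0
    edges = np.linspace(lower, upper, bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    smooth = gaussian_filter1d(counts.astype(float), smooth_sigma_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts, smooth


def _find_modes(centers: np.ndarray, smooth: np.ndarray) -> pd.DataFrame:
    # pad so modes in the first/last bin are still detected
    padded = np.concatenate([[0.0], smooth, [0.0]])
    idx, props = find_peaks(padded, prominence=0.02 * max(smooth.max(), 1e-12))
    idx = idx - 1
    return pd.DataFrame(
        {"position": centers[idx], "height": smooth[idx],
         "prominence": props["prominences"]}
    )


def fit_dna_histogram(
    hoechst_intensities,
    bins: int = 256,
    window_halfwidth_frac: float = 0.15,
    min_cells: int = 200,
    smooth_sigma_bins: float = 2.0,
) -> CellCycleFit:
    """Locate the 2N/4N peaks and call compartment fractions.

    The G1/G2 peak pair is chosen among smoothed-histogram modes whose
    position ratio lies in [1.6, 2.4], maximising combined height; with a
    single usable mode the G2 peak falls back to exactly 2x G1 (flagged).
    Everything scales with the data, so the fit is invariant under
    multiplying all intensities by a constant.
    """
    values = np.asarray(hoechst_intensities, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_cells:
        raise ValueError(
            f"need at least {min_cells} cells for a DNA histogram fit, "
            f"got {len(values)}"
        )
    flags: list[str] = []
    centers, _, smooth = _smoothed_histogram(values, bins, smooth_sigma_bins)
    modes = _find_modes(centers, smooth)

    g1 = g2 = None
    if len(modes) >= 2:
        best = -np.inf
        for i in range(len(modes)):
            for j in range(len(modes)):
                p, q = modes.loc[i, "position"], modes.loc[j, "position"]
                if p <= 0:
                    continue
                if 1.6 <= q / p <= 2.4:
                    score = modes.loc[i, "height"] + modes.loc[j, "height"]
                    if score > best:
                        best = score
                        g1, g2 = float(p), float(q)
    if g1 is None:
        if len(modes):
            g1 = float(modes.loc[modes["height"].idxmax(), "position"])
        else:  # pathological: flat histogram
            g1 = float(np.median(values))
            flags.append("no_mode_found")
        g2 = 2.0 * g1
        flags.append("g2_fallback_2x")

    if not 1.8 * g1 <= g2 <= 2.2 * g1:
        flags.append("peak_ratio_out_of_range")

    h = window_halfwidth_frac
    g1_win = (g1 * (1 - h), g1 * (1 + h))
    g2_win = (g2 * (1 - h), g2 * (1 + h))
    if g1_win[1] >= g2_win[0]:  # overlapping windows: split at the midpoint
        mid = 0.5 * (g1 + g2)
        g1_win = (g1_win[0], mid)
        g2_win = (mid, g2_win[1])
        flags.append("windows_overlap_split_at_midpoint")

    n = len(values)
    counts = {
        "sub-G1": int((values < g1_win[0]).sum()),
        "G0/G1": int(((values >= g1_win[0]) & (values <= g1_win[1])).sum()),
        "S": int(((values > g1_win[1]) & (values < g2_win[0])).sum()),
        "G2/M": int(((values >= g2_win[0]) & (values <= g2_win[1])).sum()),
        ">4N": int((values > g2_win[1]).sum()),
    }
    window_fractions = {p: counts[p] / n for p in PHASES}

    # rectangular S-bridge correction: S cells are ~uniform on [g1, g2], so
    # their density can be read off the inter-window region and the share
    # hidden under each peak window subtracted back out.
    s_span = g2_win[0] - g1_win[1]
    corrected = dict(counts)
    if s_span > 0 and g2 > g1:
        s_density = counts["S"] / s_span  # cells per intensity unit
        s_total = s_density * (g2 - g1)
        under_g1 = s_density * max(0.0, g1_win[1] - g1)
        under_g2 = s_density * max(0.0, g2 - g2_win[0])
        corrected["G0/G1"] = max(0.0, counts["G0/G1"] - under_g1)
        corrected["G2/M"] = max(0.0, counts["G2/M"] - under_g2)
        corrected["S"] = s_total
    total = sum(corrected.values())
    fractions = {p: corrected[p] / total for p in PHASES}

    return CellCycleFit(
        g1_peak=g1,
        g2_peak=g2,
        g1_window=g1_win,
        g2_window=g2_win,
        fractions=fractions,
        window_fractions=window_fractions,
        n_cells=n,
        window_halfwidth_frac=window_halfwidth_frac,
        flags=flags,
    )


def assign_phases(intensities, fit: CellCycleFit) -> np.ndarray:
    """Vectorised window lookup; boundary values belong to the window."""
    v = np.asarray(intensities, dtype=float)
    out = np.full(v.shape, "S", dtype=object)
    out[v < fit.g1_window[0]] = "sub-G1"
    out[(v >= fit.g1_window[0]) & (v <= fit.g1_window[1])] = "G0/G1"
    out[(v >= fit.g2_window[0]) & (v <= fit.g2_window[1])] = "G2/M"
    out[v > fit.g2_window[1]] = ">4N"
    return out


def assign_phase(intensity: float, fit: CellCycleFit) -> str:
    """Phase of a single cell from its integrated Hoechst intensity."""
    return str(assign_phases([intensity], fit)[0])


def marker_by_phase(
    cells: pd.DataFrame,
    gate: Gate,
    fit: CellCycleFit,
    hoechst_channel: str = "hoechst",
) -> pd.DataFrame:
    """Joint fractions of marker positivity by cell-cycle phase.

    Returns a 2 x 5 cross-tab (rows ``positive`` / ``negative``, columns the
    phases) of fractions over all cells; the grand total is 1, the column
    sums equal the window-assignment phase fractions, and the row sums equal
    the gate's % positive / 100.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    col = f"{hoechst_channel}_integrated"
    if col not in cells.columns:
        raise KeyError(f"Hoechst channel {hoechst_channel!r} not in table")
    phases = assign_phases(cells[col].to_numpy(), fit)
    positive = gate.is_positive(cells)
    n = len(cells)
    data = {
        phase: [
            float(((phases == phase) & positive).sum()) / n,
            float(((phases == phase) & ~positive).sum()) / n,
        ]
        for phase in PHASES
    }
    tab = pd.DataFrame(data, index=["positive", "negative"])
    tab.attrs["percent_positive"] = percent_positive(cells, gate).percent_positive
    return tab
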