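"""Flow-cytometry-like statistics on per-cell tables.

A *gate* is a 1D positivity threshold on a channel's background-corrected
integrated intensity, anchored on the background-control condition (CT:
untreated cells carrying only the secondary antibody). Cells strictly above
the threshold are positive; ties are negative, so a degenerate control
distribution gates 0% of itself positive. On top of single gates the module
provides % positive and positive-mean statistics per condition, fold
changes versus untreated, 2-3 marker quadrant multiplexing, a single-stain
channel-overlap (bleed-through) check, and a replicate t-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats


def _intensity(cells: pd.DataFrame, channel: str) -> np.ndarray:
    col = f"{channel}_integrated"
    if col not in cells.columns:
        raise KeyError(f"channel {channel!r} not present in cell table")
    return cells[col].to_numpy(dtype=float)


@dataclass(frozen=True)
class Gate:
    """Positivity threshold for one channel (on integrated intensity, a.u.)."""

    channel: str
    threshold: float
    q: float | None = None
    source_wells: tuple[str, ...] = ()
    n_control: int = 0
    method: str = "ct_quantile"

    def is_positive(self, cells: pd.DataFrame) -> np.ndarray:
        """Strict-threshold positivity per record."""
        return _intensity(cells, self.channel) > self.threshold


class GateSet(dict):
    """Mapping channel -> Gate with YAML round-tripping."""

    def add(self, gate: Gate) -> "GateSet":
        self[gate.channel] = gate
        return self

    def to_yaml(self, path) -> None:
        payload = [
            {
                "channel": g.channel,
                "threshold": float(g.threshold),
                "q": g.q,
                "source_wells": list(g.source_wells),
                "n_control": g.n_control,
                "method": g.method,
            }
            for g in self.values()
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GateSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        gs = cls()
        for item in payload:
            item["source_wells"] = tuple(item.get("source_wells", ()))
            gs.add(Gate(**item))
        return gs


@dataclass
class MarkerStats:
    """Per-condition marker summary (the flow-style readout)."""

    channel: str
    condition: str
    n_cells: int
    percent_positive: float
    mean_integrated_intensity_of_positives: float  # NaN when no positives
    n_positive: int
    threshold: float


def define_gate(
    ct_cells: pd.DataFrame,
    channel: str,
    q: float = 0.99,
    min_cells: int = 100,
) -> Gate:
    """Place a gate at the empirical q-quantile of the CT distribution.

    The CT condition measures pure background fluorescence, so by
    construction roughly ``(1-q)`` of control cells exceed the gate (the
    nominal false-positive rate of every downstream % positive).
    """
    vals = _intensity(ct_cells, channel)
    if len(vals) < min_cells:
        raise ValueError(
            f"only {len(vals)} CT cells for channel {channel!r} "
            f"(minimum {min_cells}); pool additional CT wells"
        )
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    threshold = float(np.quantile(vals, q))
    wells = tuple(sorted(map(str, ct_cells["well_id"].unique()))) \
        if "well_id" in ct_cells.columns else ()
    return Gate(channel=channel, threshold=threshold, q=q,
                source_wells=wells, n_control=len(vals))


def otsu_gate(cells: pd.DataFrame, channel: str) -> Gate:
    """Bimodal split of a channel without a dedicated control condition.

    Otsu's criterion on the integrated intensities; used for the viability
    stains (PI / calcein), whose positive population carries real stain
    signal and whose negative population scatters around zero after
    background correction. Pool wells across the plate so both populations
    are represented before gating.
    """
    from skimage.filters import threshold_otsu

    vals = _intensity(cells, channel)
    vals = vals[np.isfinite(vals)]
    if vals.max() == vals.min():
        thr = float(vals.max())  # degenerate: nothing gated positive
    else:
        thr = float(threshold_otsu(vals))
    return Gate(channel=channel, threshold=thr, q=None, method="otsu",
                n_control=len(vals))


def percent_positive(
    cells: pd.DataFrame,
    gate: Gate,
    condition: str = "",
) -> MarkerStats:
    """% of cells strictly above the gate, and the mean intensity of those.

    With zero positives the positive-mean is NaN (flagged, not an error).
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    vals = _intensity(cells, gate.channel)
    pos = vals > gate.threshold
    n_pos = int(pos.sum())
    return MarkerStats(
        channel=gate.channel,
        condition=condition,
        n_cells=len(vals),
        percent_positive=100.0 * n_pos / len(vals),
        mean_integrated_intensity_of_positives=(
            float(vals[pos].mean()) if n_pos else float("nan")
        ),
        n_positive=n_pos,
        threshold=gate.threshold,
    )


def fold_change(treated: MarkerStats, untreated: MarkerStats) -> float:
    """Ratio of treated to untreated % positive (the drug-effect readout).

    A zero untreated percentage yields inf with an explicit warning rather
    than failing silently.
    """
    if untreated.percent_positive == 0:
        warnings.warn(
            f"untreated % positive is 0 for channel {treated.channel!r}; "
            "fold change is undefined (reported as inf)",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return treated.percent_positive / untreated.percent_positive


def intensity_fold_change(treated: MarkerStats, untreated: MarkerStats) -> float:
    """Fold change of the positive-population mean intensity."""
    denom = untreated.mean_integrated_intensity_of_positives
    if not np.isfinite(denom) or denom == 0:
        warnings.warn(
            "untreated positive-mean intensity undefined or 0; "
            "intensity fold change reported as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return treated.mean_integrated_intensity_of_positives / denom


@dataclass
class QuadrantResult:
    """Joint positivity partition over 2-3 gated markers.

    ``table`` has one row per +/- combination (4 rows for 2 markers, 8 for
    3) with boolean status columns, ``count`` and ``fraction``; fractions
    partition the cells (sum to 1). ``marginals`` maps each channel to its
    marginal % positive.
    """

    channels: tuple[str, ...]
    table: pd.DataFrame
    marginals: dict[str, float] = field(default_factory=dict)
    n_cells: int = 0

    def fraction(self, **status: bool) -> float:
        """Fraction of cells with the given +/- pattern, e.g. gH2AX=True."""
        sel = np.ones(len(self.table), dtype=bool)
        for ch, val in status.items():
            if ch not in self.channels:
                raise KeyError(f"{ch!r} not among gated channels {self.channels}")
            sel &= self.table[ch].to_numpy() == bool(val)
        return float(self.table.loc[sel, "fraction"].sum())


def quadrant_analysis(cells: pd.DataFrame,
                      gates: GateSet | dict | list[Gate]) -> QuadrantResult:
    """Assign every cell to exactly one joint +/- combination of the gates."""
    if len(cells) == 0:
        raise ValueError("empty cell table")
    if not isinstance(gates, dict):
        gate_list = list(gates)
        channels = [g.channel for g in gate_list]
        if len(channels) != len(set(channels)):
            raise ValueError(f"duplicate channels in gate set: {channels}")
        gates = {g.channel: g for g in gate_list}
    channels = list(gates)
    if len(channels) != len(set(channels)):
        raise ValueError("duplicate channels in gate set")
    if not 1 <= len(channels) <= 3:
        raise ValueError("quadrant analysis supports 1-3 gated markers")
    status = {ch: gates[ch].is_positive(cells) for ch in channels}
    n = len(cells)
    rows = []
    for combo in itertools.product([True, False], repeat=len(channels)):
        sel = np.ones(n, dtype=bool)
        for ch, flag in zip(channels, combo):
            sel &= status[ch] if flag else ~status[ch]
        count = int(sel.sum())
        label = "/".join(
            f"{ch}{'+' if flag else '-'}" for ch, flag in zip(channels, combo)
        )
        rows.append({**dict(zip(channels, combo)), "combination": label,
                     "count": count, "fraction": count / n})
    table = pd.DataFrame(rows)
    marginals = {ch: 100.0 * status[ch].mean() for ch in channels}
    return QuadrantResult(channels=tuple(channels), table=table,
                          marginals=marginals, n_cells=n)


def channel_overlap_check(
    single_stain_tables: dict[str, pd.DataFrame],
    gates: GateSet | dict,
    tolerance: float | None = None,
) -> pd.DataFrame:
    """Validate the absence of fluorescence overlap between channels.

    Each table must come from a well stained for exactly one marker; the
    check measures the % positive that this single stain produces in every
    *other* marker's channel. The default tolerance is the gates' nominal
    false-positive rate plus 2 percentage points. Returns a report with one
    row per (stained marker, off-target channel) and a ``passed`` flag;
    ``report.attrs["passed"]`` aggregates it.
    """
    channels = list(gates)
    missing = [ch for ch in channels if ch not in single_stain_tables]
    if missing:
        raise ValueError(
            f"missing single-stain tables for markers: {missing}"
        )
    rows = []
    for stained in channels:
        cells = single_stain_tables[stained]
        for other in channels:
            if other == stained:
                continue
            gate = gates[other]
            off = percent_positive(cells, gate).percent_positive
            q = gate.q if gate.q is not None else 0.99
            tol = tolerance if tolerance is not None else (1.0 - q) * 100.0 + 2.0
            rows.append(
                {
                    "stained_marker": stained,
                    "off_target_channel": other,
                    "off_target_percent": off,
                    "tolerance_percent": tol,
                    "passed": off <= tol,
                }
            )
    report = pd.DataFrame(
        rows,
        columns=["stained_marker", "off_target_channel", "off_target_percent",
                 "tolerance_percent", "passed"],
    )
    report.attrs["passed"] = bool(report["passed"].all()) if len(report) else True
    return report


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.01


def compare_replicates(stats_a, stats_b, alpha: float = 0.01) -> TTestResult:
    """Two-sided two-sample Student's t-test on replicate-level values.

    Significance follows the study convention p < 0.01. Two groups with
    zero variance and equal means are identical: p = 1 by convention.
    """
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, False, alpha)
        return TTestResult(float("inf"), 0.0, True, alpha)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), bool(p < alpha), alpha)
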