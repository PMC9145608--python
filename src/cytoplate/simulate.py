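"""Synthetic plate generator with exact per-cell ground truth.

Emulates the staining designs of a fluorescence plate imager well enough to
test every downstream stage against known truth:

* a Hoechst (DNA) channel whose per-nucleus integrated signal is proportional
  to DNA content — G0/G1 cells carry one genome equivalent, G2/M cells two,
  S-phase cells a uniform value in between (the "S bridge" of a DNA-content
  histogram);
* marker channels (e.g. gH2AX / pATM / pATR) drawn from a two-component
  log-normal mixture of marker-negative and marker-positive cells;
* mutually exclusive PI (dead) and calcein (live) viability stains, with dead
  cells retaining their Hoechst signal so they still count toward the total;
* constant background, additive Gaussian read noise, and an optional linear
  bleed-through mixing matrix across channels.

Nuclei are rendered as isotropic Gaussian spots (sigma = radius/2, truncated
at 3 sigma) whose discrete pixel sums are normalised to the cell's true
integrated signal, so the ground-truth ledger is exact by construction.
Placement keeps the truncated footprints disjoint, which makes per-cell
intensity recovery by segmentation well defined.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

HOECHST = "hoechst"
PI = "pi"
CALCEIN = "calcein"

PHASE_NAMES = ("G0/G1", "S", "G2/M")


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


@dataclass(frozen=True)
class MarkerModel:
    """Log-normal intensity mixture for one marker channel.

    ``negative_mean`` / ``positive_mean`` are arithmetic means of the
    integrated intensity (a.u.) of marker-negative / marker-positive cells;
    ``lognormal_sigma`` is the common log-scale spread.
    """

    positive_fraction: float
    negative_mean: float = 2000.0
    positive_mean: float = 20000.0
    lognormal_sigma: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.positive_mean <= self.negative_mean:
            raise ValueError("positive_mean must exceed negative_mean")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be non-negative")


@dataclass
class WellSimParams:
    """Full parameterisation of one simulated well.

    Units: intensities in arbitrary units (a.u.) of integrated per-cell
    signal; lengths in pixels. ``g1_dna_intensity`` is the mean integrated
    Hoechst signal of a G0/G1 cell; ``dna_cv`` the cell-to-cell coefficient
    of variation of DNA staining; ``phase_fractions`` the (G0/G1, S, G2/M)
    probabilities. ``bleedthrough`` is a square mixing matrix over
    ``channels`` (row i, column j = fraction of channel i's signal added to
    channel j; identity = no bleed-through).
    """

    n_cells: int = 200
    image_shape: tuple[int, int] = (1024, 1024)
    nucleus_radius_px: float = 8.0
    radius_cv: float = 0.15
    g1_dna_intensity: float = 20000.0
    dna_cv: float = 0.05
    phase_fractions: tuple[float, float, float] = (0.55, 0.25, 0.20)
    marker_models: dict[str, MarkerModel] = field(default_factory=dict)
    dead_fraction: float = 0.0
    viability_stains: bool = False
    pi_intensity_mean: float = 15000.0
    calcein_intensity_mean: float = 15000.0
    stain_lognormal_sigma: float = 0.3
    background_level: float = 100.0
    noise_sd: float = 2.0
    bleedthrough: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def channels(self) -> list[str]:
        """Canonical channel order: Hoechst, markers, then viability stains."""
        chans = [HOECHST, *self.marker_models.keys()]
        if self.viability_stains:
            chans += [PI, CALCEIN]
        return chans

    def validate(self) -> None:
        pf = np.asarray(self.phase_fractions, dtype=float)
        if pf.shape != (3,):
            raise ValueError("phase_fractions must have three entries (G0/G1, S, G2/M)")
        if abs(pf.sum() - 1.0) > 1e-9:
            raise ValueError(f"phase_fractions must sum to 1, got {pf.sum():.12f}")
        if np.any(pf < 0) or np.any(pf > 1):
            raise ValueError("phase_fractions must lie in [0, 1]")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be positive")
        if self.bleedthrough is not None:
            m = np.asarray(self.bleedthrough, dtype=float)
            c = len(self.channels)
            if m.shape != (c, c):
                raise ValueError(
                    f"bleedthrough must be {c}x{c} for channels {self.channels}"
                )
            if np.any(m < 0):
                raise ValueError("bleedthrough entries must be non-negative")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("bleedthrough diagonal must be 1 (unit self-signal)")


@dataclass(frozen=True)
class DrugResponseModel:
    """Generative dose-response model for a simulated drug.

    Expected cell number per well follows a 4PL (Hill) inhibition curve of
    the concentration; the dead-cell fraction follows a rising logistic
    curve. ``baseline_dead`` is the spontaneous dead fraction of untreated
    wells (the dead-fraction curve's value at concentration zero).
    """

    ic50_true: float = 1.0  # uM
    hill: float = 2.0
    max_inhibition: float = 1.0
    ec50_dead: float = 2.0  # uM
    hill_dead: float = 2.0
    max_dead: float = 0.8
    baseline_dead: float = 0.05
    baseline_cells_per_well: int = 200

    def expected_growth(self, conc: np.ndarray | float) -> np.ndarray | float:
        """Expected cell number relative to untreated (1.0 at c=0)."""
        c = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            inhib = self.max_inhibition * c**self.hill / (
                c**self.hill + self.ic50_true**self.hill
            )
        out = 1.0 - np.where(np.isfinite(inhib), inhib, self.max_inhibition)
        return out if out.ndim else float(out)

    def expected_dead_fraction(self, conc: np.ndarray | float) -> np.ndarray | float:
        c = np.asarray(conc, dtype=float)
        rise = c**self.hill_dead / (c**self.hill_dead + self.ec50_dead**self.hill_dead)
        out = self.baseline_dead + (self.max_dead - self.baseline_dead) * rise
        return out if out.ndim else float(out)


@dataclass
class WellImageSet:
    """Per-well stack of single-channel 2D intensity images (float, a.u.)."""

    images: dict[str, np.ndarray]
    well_id: str = ""

    @property
    def channels(self) -> list[str]:
        return list(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.images.values()))
        return first.shape

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.images[channel]


def _lognormal_unit(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative log-normal noise with mean exactly 1 and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float,
                    size: int) -> np.ndarray:
    """Log-normal draws with arithmetic mean ``mean`` and log-sd ``sigma``."""
    if sigma <= 0:
        return np.full(size, float(mean))
    return mean * np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def _place_centers(params: WellSimParams, radii: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping nucleus centers.

    Centers keep (a) at least 2.2x the mean radius between any pair and
    (b) the truncated 3-sigma rendering footprints disjoint, so each cell's
    pixels belong to it alone.
    """
    n = len(radii)
    if n == 0:
        return np.empty((0, 2))
    rows, cols = params.image_shape
    # footprint radius = 3*sigma = 1.5*radius; keep fully inside the frame
    margins = 1.5 * radii + 2.0
    if np.any(rows - 2 * margins <= 0) or np.any(cols - 2 * margins <= 0):
        raise PlacementError(
            f"image_shape {params.image_shape} too small for nucleus radius "
            f"{radii.max():.1f} px"
        )
    base_sep = 2.2 * params.nucleus_radius_px
    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = max(2000, 400 * n)
    while placed < n:
        if attempts >= max_attempts:
            area = rows * cols
            density = placed / area
            raise PlacementError(
                f"could only place {placed}/{n} nuclei after {attempts} attempts; "
                f"achievable density at radius {params.nucleus_radius_px:.1f} px is "
                f"~{density:.2e} cells/px^2 — enlarge the image or reduce n_cells"
            )
        attempts += 1
        m = margins[placed]
        cand = np.array([
            rng.uniform(m, rows - m),
            rng.uniform(m, cols - m),
        ])
        if placed:
            d = np.hypot(*(centers[:placed] - cand).T)
            min_sep = np.maximum(base_sep, 1.5 * (radii[:placed] + radii[placed]) + 1.0)
            if np.any(d < min_sep):
                continue
        centers[placed] = cand
        placed += 1
    return centers


def draw_ground_truth(params: WellSimParams,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample the per-cell ground-truth ledger (no rendering).

    Returns one row per cell: position, radius, phase, viability, and the
    true integrated signal on every channel (``true_<channel>`` columns,
    plus ``<marker>_positive`` status flags).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_cells
    radii = params.nucleus_radius_px * _lognormal_unit(rng, params.radius_cv, n)
    radii = np.maximum(radii, 2.0)
    centers = _place_centers(params, radii, rng)

    phase_idx = rng.choice(3, size=n, p=np.asarray(params.phase_fractions, float))
    content = np.ones(n)
    content[phase_idx == 1] = rng.uniform(1.0, 2.0, int((phase_idx == 1).sum()))
    content[phase_idx == 2] = 2.0
    dna = params.g1_dna_intensity * content * _lognormal_unit(rng, params.dna_cv, n)

    gt = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "row": centers[:, 0],
            "col": centers[:, 1],
            "radius": radii,
            "phase": np.asarray(PHASE_NAMES)[phase_idx] if n else np.array([], dtype=object),
            f"true_{HOECHST}": dna,
        }
    )

    for name, model in params.marker_models.items():
        positive = rng.random(n) < model.positive_fraction
        neg = _lognormal_mean(rng, model.negative_mean, model.lognormal_sigma, n)
        pos = _lognormal_mean(rng, model.positive_mean, model.lognormal_sigma, n)
        gt[f"{name}_positive"] = positive
        gt[f"true_{name}"] = np.where(positive, pos, neg)

    dead = rng.random(n) < params.dead_fraction
    gt["viability"] = np.where(dead, "dead", "live")
    if params.viability_stains:
        pi_sig = _lognormal_mean(
            rng, params.pi_intensity_mean, params.stain_lognormal_sigma, n
        )
        cal_sig = _lognormal_mean(
            rng, params.calcein_intensity_mean, params.stain_lognormal_sigma, n
        )
        # dead cells take up PI and lose calcein; live cells the reverse
        gt[f"true_{PI}"] = np.where(dead, pi_sig, 0.0)
        gt[f"true_{CALCEIN}"] = np.where(dead, 0.0, cal_sig)
    return gt


def _render_spot(image: np.ndarray, r0: float, c0: float, radius: float,
                 signal: float) -> None:
    """Add a truncated-Gaussian spot whose pixel sum equals ``signal``."""
    sigma = radius / 2.0
    extent = 3.0 * sigma
    rlo = int(np.floor(r0 - extent))
    rhi = int(np.ceil(r0 + extent)) + 1
    clo = int(np.floor(c0 - extent))
    chi = int(np.ceil(c0 + extent)) + 1
    rr = np.arange(rlo, rhi)[:, None] - r0
    cc = np.arange(clo, chi)[None, :] - c0
    d2 = rr * rr + cc * cc
    w = np.exp(-d2 / (2.0 * sigma * sigma))
    w[d2 > extent * extent] = 0.0
    total = w.sum()
    if total > 0:
        image[rlo:rhi, clo:chi] += (signal / total) * w


def render_well(params: WellSimParams, gt: pd.DataFrame,
                rng: np.random.Generator | None = None) -> WellImageSet:
    """Render the ground-truth ledger into per-channel images.

    Applies, in order: spot rendering, bleed-through mixing, constant
    background, additive Gaussian noise, and clipping at zero.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    chans = params.channels
    shape = tuple(params.image_shape)
    stack = np.zeros((len(chans),) + shape)
    for ci, ch in enumerate(chans):
        col = f"true_{ch}"
        for r0, c0, radius, signal in zip(
            gt["row"].to_numpy(), gt["col"].to_numpy(),
            gt["radius"].to_numpy(), gt[col].to_numpy(),
        ):
            if signal > 0:
                _render_spot(stack[ci], r0, c0, radius, signal)
    if params.bleedthrough is not None:
        m = np.asarray(params.bleedthrough, dtype=float)
        stack = np.einsum("ij,ihw->jhw", m, stack)
    images = {}
    for ci, ch in enumerate(chans):
        img = stack[ci] + params.background_level
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, shape)
        images[ch] = np.clip(img, 0.0, None)
    return WellImageSet(images=images)


def simulate_well(params: WellSimParams) -> tuple[WellImageSet, pd.DataFrame]:
    """Simulate one well: deterministic given ``params`` (including seed)."""
    rng = np.random.default_rng(params.seed)
    gt = draw_ground_truth(params, rng)
    images = render_well(params, gt, rng)
    return images, gt


def ground_truth_to_table(gt: pd.DataFrame, well_id: str = "sim",
                          **metadata) -> pd.DataFrame:
    """Convert a ground-truth ledger into a CellTable-shaped frame.

    The true integrated signals become the ``<channel>_integrated`` columns,
    so gating / cell-cycle / viability statistics can be exercised directly
    on generator truth without rendering and re-segmenting images.
    """
    out = pd.DataFrame(
        {
            "well_id": well_id,
            "cell_label": gt["cell_id"].to_numpy(),
            "centroid_row": gt["row"].to_numpy(),
            "centroid_col": gt["col"].to_numpy(),
            "area": np.pi * gt["radius"].to_numpy() ** 2,
        }
    )
    for col in gt.columns:
        if col.startswith("true_"):
            ch = col[len("true_"):]
            out[f"{ch}_integrated"] = gt[col].to_numpy()
            out[f"{ch}_mean"] = out[f"{ch}_integrated"] / out["area"]
    # carry the truth labels so recovery tests can compare against the
    # realized (not just nominal) per-cell status
    for col in gt.columns:
        if col.endswith("_positive") or col in ("phase", "viability"):
            out[col] = gt[col].to_numpy()
    for key, val in metadata.items():
        out[key] = val
    return out


def well_seed(master_seed: int, well_id: str) -> int:
    """Stable per-well seed: master seed XOR CRC32 of the well identifier."""
    return (int(master_seed) ^ zlib.crc32(well_id.encode())) & 0x7FFFFFFF


@dataclass
class SimulatedWell:
    well_id: str
    concentration: float
    replicate: int
    params: WellSimParams
    images: WellImageSet
    ground_truth: pd.DataFrame


def simulate_dose_plate(
    model: DrugResponseModel,
    concentrations: list[float],
    replicates: int,
    seed: int,
    base_params: WellSimParams | None = None,
    count_cv: float = 0.10,
    render: bool = True,
) -> list[SimulatedWell]:
    """Simulate a dose-response plate (one well per concentration x replicate).

    Expected cell number follows the model's 4PL inhibition curve and the
    dead fraction its logistic curve; realised counts get multiplicative
    Gaussian jitter with CV ``count_cv``. Per-well seeds derive from the
    master seed and the well identifier, independent of iteration order.
    """
    concs = [float(c) for c in concentrations]
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be non-negative")
    if not any(c == 0.0 for c in concs):
        raise ValueError(
            "at least one zero (untreated) concentration is required; growth "
            "normalization is undefined without it"
        )
    if base_params is None:
        base_params = WellSimParams(viability_stains=True)
    wells: list[SimulatedWell] = []
    for ci, conc in enumerate(concs):
        expected = model.baseline_cells_per_well * model.expected_growth(conc)
        dead_frac = float(np.clip(model.expected_dead_fraction(conc), 0.0, 1.0))
        for rep in range(1, replicates + 1):
            wid = f"C{ci:02d}R{rep}"
            ws = well_seed(seed, wid)
            wrng = np.random.default_rng(ws)
            jitter = 1.0 + wrng.normal(0.0, count_cv) if count_cv > 0 else 1.0
            n = int(max(0, round(expected * jitter)))
            params = dataclasses.replace(
                base_params,
                n_cells=n,
                dead_fraction=dead_frac,
                viability_stains=True,
                seed=(ws + 1) & 0x7FFFFFFF,
            )
            rng = np.random.default_rng(params.seed)
            gt = draw_ground_truth(params, rng)
            images = (
                render_well(params, gt, rng)
                if render
                else WellImageSet(images={}, well_id=wid)
            )
            images.well_id = wid
            wells.append(SimulatedWell(wid, conc, rep, params, images, gt))
    return wells


# --- packaged scenarios -----------------------------------------------------

_DDR_PANEL = ("gH2AX", "pATM", "pATR")


def _multiplex_params(fractions: dict[str, float], phases=(0.55, 0.25, 0.20),
                      **kw) -> WellSimParams:
    markers = {name: MarkerModel(positive_fraction=f) for name, f in fractions.items()}
    return WellSimParams(
        n_cells=kw.pop("n_cells", 1000),
        image_shape=kw.pop("image_shape", (2048, 2048)),
        phase_fractions=phases,
        marker_models=markers,
        **kw,
    )


def scenario_library(name: str) -> WellSimParams:
    """Packaged generator parameterisations mimicking printed study outcomes.

    These encode the *ground-truth* fractions the pipeline should recover in
    end-to-end smoke tests (recovery of generator truth); they do not
    validate any biology. Unknown names raise ``KeyError`` listing the
    catalog.
    """
    catalog: dict[str, WellSimParams] = {
        # topoisomerase-II inhibition arrests cells in G2/M
        "etoposide-treated": _multiplex_params(
            {"gH2AX": 0.70}, phases=(0.22, 0.12, 0.66)
        ),
        "etoposide-untreated": _multiplex_params(
            {"gH2AX": 0.10}, phases=(0.56, 0.22, 0.22)
        ),
        # triple-marker multiplex after topoisomerase-I inhibition
        "SN38-multiplex": _multiplex_params(
            {"gH2AX": 0.90, "pATM": 0.80, "pATR": 0.60}
        ),
        "SN38-multiplex-untreated": _multiplex_params(
            {"gH2AX": 0.25, "pATM": 0.25, "pATR": 0.25}
        ),
        # ATR inhibitor + platinum combination: S-phase collapse, G2/M pile-up
        "VOX": _multiplex_params(
            {"gH2AX": 0.55, "pATM": 0.46, "pATR": 0.55},
            phases=(0.40, 0.05, 0.55),
        ),
        "VOX-untreated": _multiplex_params(
            {"gH2AX": 0.019, "pATM": 0.10, "pATR": 0.26},
            phases=(0.56, 0.22, 0.22),
        ),
        "oxaliplatin": _multiplex_params(
            {"gH2AX": 0.19, "pATM": 0.46, "pATR": 0.55}
        ),
        # secondary-antibody-only background control: nothing is positive
        "CT": _multiplex_params({m: 0.0 for m in _DDR_PANEL}),
    }
    try:
        return catalog[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(catalog)}"
        ) from None


# --- disk I/O ---------------------------------------------------------------

def write_well_images(images: WellImageSet, directory: str | Path,
                      well_id: str) -> list[Path]:
    """Write one 16-bit grayscale TIFF per channel: <dir>/<well>_<channel>.tif."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch, img in images.images.items():
        arr = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        path = directory / f"{well_id}_{ch}.tif"
        tifffile.imwrite(path, arr)
        paths.append(path)
    return paths


def read_well_images(directory: str | Path, well_id: str,
                     channels: list[str]) -> WellImageSet:
    directory = Path(directory)
    images = {}
    for ch in channels:
        path = directory / f"{well_id}_{ch}.tif"
        if not path.exists():
            raise FileNotFoundError(f"missing image for well {well_id}: {path}")
        images[ch] = tifffile.imread(path).astype(float)
    return WellImageSet(images=images, well_id=well_id)


def params_to_yaml(params: WellSimParams, path: str | Path) -> None:
    """Echo generator parameters to YAML for provenance."""
    d = dataclasses.asdict(params)
    if d.get("bleedthrough") is not None:
        d["bleedthrough"] = np.asarray(d["bleedthrough"]).tolist()
    d["image_shape"] = list(d["image_shape"])
    d["phase_fractions"] = list(d["phase_fractions"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
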