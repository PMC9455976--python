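"""Synthetic ATR-FTIR honey cohorts with class-dependent marker bands.

The study's real spectra are not deposited, so this module generates a
statistical stand-in with the same factorial label structure: 109 samples
whose botanical x harvest-year x region margins reproduce the published
cohort, on a 550-4000 cm^-1 grid whose fingerprint window [550, 1775]
holds exactly 1246 variables.

Each spectrum is a sum of Gaussian bands (truncated at +/-4 sigma so class
effects are strictly local), modulated by

* per-band class-effect amplitude multipliers (and optional centre shifts)
  for the sample's botanical class, harvest year and region,
* mean-one log-normal per-band amplitude jitter (within-class variability),
* a mean-one log-normal global scatter factor,
* a random polynomial baseline, and
* i.i.d. Gaussian noise.

Harvest-year effects sit on narrow bands inside 550-700 and 1050-1100
cm^-1 and around 1419 cm^-1; botanical effects inside 550-1000 and
1550-1700 cm^-1; region effects inside 550-700 cm^-1 plus narrow bands
near 710, 810, 870 and 1180 cm^-1 — the marker regions the corresponding
real-data models report, so marker-recovery tests are meaningful.  Effect
multipliers are paired across classes so that the cohort's unbalanced
margins do not turn one factor's bands into proxies for another factor.
Everything is driven by a single seed; identical configs give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra_io import SpectrumSet

__all__ = [
    "BandSpec",
    "ClassEffect",
    "CohortDesign",
    "GeneratorConfig",
    "GRID_SPACING",
    "default_band_library",
    "default_effects",
    "default_generator_config",
    "default_study_design",
    "generate_spectrum",
    "generate_cohort",
    "noise_free_template",
    "informative_indices",
    "config_to_yaml",
    "config_from_yaml",
    "load_preset",
]

#: default grid spacing (cm^-1): the closed window [550, 1775] then holds
#: exactly 1246 grid points, matching the fingerprint dimensionality the
#: models are built on.
GRID_SPACING = 1225.0 / 1245.0

#: widest allowed band truncation; every band vanishes outside
#: +/-4 sigma of its centre (narrower per-band supports are allowed).
BAND_SUPPORT_SIGMA = 4.0


@dataclass(frozen=True)
class BandSpec:
    center: float        # cm^-1
    width: float         # Gaussian sigma, cm^-1
    amplitude: float     # absorbance units
    support: float = 4.0  # truncation half-width, in sigmas

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")
        if not 0 < self.support <= BAND_SUPPORT_SIGMA:
            raise ValueError("band support must be in (0, 4] sigmas")


@dataclass(frozen=True)
class ClassEffect:
    factor: str                     # botanical | year | region
    level: str
    band_index: int                 # into the band library
    amplitude_multiplier: float = 1.0
    center_shift: float = 0.0       # cm^-1

    def __post_init__(self) -> None:
        if self.factor not in ("botanical", "year", "region"):
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.amplitude_multiplier <= 0:
            raise ValueError("amplitude multiplier must be positive")


@dataclass
class CohortDesign:
    """Sample counts per (botanical, year, region) cell; region may be None."""

    counts: dict[tuple[str, str, str | None], int]

    def __post_init__(self) -> None:
        for cell, count in self.counts.items():
            if count < 0:
                raise ValueError(f"negative count for cell {cell}")

    @property
    def n_samples(self) -> int:
        return sum(self.counts.values())

    def marginal(self, factor: str) -> dict[str, int]:
        pos = {"botanical": 0, "year": 1, "region": 2}[factor]
        out: dict[str, int] = {}
        for cell, count in self.counts.items():
            level = cell[pos]
            if level is None:
                continue
            out[level] = out.get(level, 0) + count
        return out

    def cells(self) -> list[tuple[tuple[str, str, str | None], int]]:
        """Cells in a deterministic order (unlabelled region last)."""
        return sorted(
            self.counts.items(),
            key=lambda kv: (kv[0][0], kv[0][1], kv[0][2] is None, kv[0][2] or ""),
        )


@dataclass
class GeneratorConfig:
    grid_start: float = 550.0
    grid_stop: float = 4000.0
    grid_spacing: float = GRID_SPACING
    band_library: list[BandSpec] = field(default_factory=list)
    effects: list[ClassEffect] = field(default_factory=list)
    noise_sd: float = 0.001            # absorbance
    baseline_order: int = 2
    baseline_sd: float = 0.0005        # absorbance, per polynomial coefficient
    scatter_sd: float = 0.005          # dimensionless (log-scale sd)
    within_class_amp_sd: float = 0.05  # dimensionless (log-scale sd)
    effect_strength_sd: float = 0.0    # per-sample spread of class-effect strength
    seed: int = 20200901

    def __post_init__(self) -> None:
        if self.grid_start >= self.grid_stop:
            raise ValueError("grid_start must be below grid_stop")
        if min(self.noise_sd, self.baseline_sd, self.scatter_sd,
               self.within_class_amp_sd, self.effect_strength_sd) < 0:
            raise ValueError("noise magnitudes must be non-negative")
        for eff in self.effects:
            if not 0 <= eff.band_index < len(self.band_library):
                raise ValueError(
                    f"effect on {eff.factor}={eff.level} references band "
                    f"{eff.band_index}, library has {len(self.band_library)}"
                )

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.grid_stop - self.grid_start) / self.grid_spacing + 1e-9)) + 1
        return self.grid_start + np.arange(n) * self.grid_spacing


# ---------------------------------------------------------------------------
# Default study design (cohort margins of the published sample table)
# ---------------------------------------------------------------------------

# 3-way allocation: the published table fixes botanical x year and botanical x
# region margins only; within each botanical class the region labels are
# spread across the two years proportionally (rounded), which keeps the
# region/year association weak.
_STUDY_CELLS: dict[tuple[str, str, str | None], int] = {
    ("acacia", "2020", "Transylvania"): 7,
    ("acacia", "2020", "Others"): 3,
    ("acacia", "2020", None): 10,
    ("acacia", "2021", "Transylvania"): 7,
    ("acacia", "2021", "Others"): 3,
    ("acacia", "2021", None): 11,
    ("linden", "2020", "Transylvania"): 4,
    ("linden", "2020", "Others"): 4,
    ("linden", "2020", None): 11,
    ("linden", "2021", "Transylvania"): 3,
    ("linden", "2021", "Others"): 2,
    ("linden", "2021", None): 6,
    ("colza", "2020", "Transylvania"): 2,
    ("colza", "2020", "Others"): 2,
    ("colza", "2020", None): 4,
    ("colza", "2021", "Transylvania"): 3,
    ("colza", "2021", "Others"): 2,
    ("colza", "2021", None): 5,
    ("honeydew", "2020", "Transylvania"): 5,
    ("honeydew", "2020", "Others"): 3,
    ("honeydew", "2020", None): 5,
    ("honeydew", "2021", "Transylvania"): 3,
    ("honeydew", "2021", "Others"): 1,
    ("honeydew", "2021", None): 3,
}


def default_study_design() -> CohortDesign:
    """The 109-sample design matching the published cohort margins.

    Botanical totals 41/18/20/30, years 60/49, regions 34 Transylvania +
    20 Others with the remaining 55 samples region-unlabelled (the
    geographical model uses only the 54 labelled ones).
    """
    return CohortDesign(counts=dict(_STUDY_CELLS))


# ---------------------------------------------------------------------------
# Default band library and class effects
# ---------------------------------------------------------------------------

def _snap_node(target: float, start: float = 550.0, spacing: float = GRID_SPACING) -> float:
    """Snap a position onto the nearest grid node."""
    return start + round((target - start) / spacing) * spacing


#: marker lines are one grid point wide: sigma well below the grid spacing
#: and support tight enough that exactly one grid node is touched
LINE_SIGMA = 0.3 * GRID_SPACING
LINE_SUPPORT = 1.0
LINE_AMPLITUDE = 0.3
LINES_PER_CLUSTER = 10


def _cluster_centers(target: float) -> list[float]:
    """Ten consecutive grid nodes spanning ~10 cm^-1 around a target position.

    Modelled as unresolved fine structure: every line carries its own
    amplitude jitter, so each marker grid point holds independent class
    information rather than being redundant with its band neighbours.
    """
    k = round((target - 550.0) / GRID_SPACING)
    return [550.0 + (k - 5 + j) * GRID_SPACING for j in range(LINES_PER_CLUSTER)]


_BROAD_BANDS = [
    # (center, sigma, amplitude): broad honey-like background structure
    (600.0, 18.0, 0.10),    # crystalline / M-O region
    (680.0, 14.0, 0.06),
    (745.0, 12.0, 0.05),    # anomeric region shoulder
    (918.0, 10.0, 0.12),
    (1030.0, 14.0, 0.55),   # carbohydrate C-O stretch (dominant)
    (1055.0, 25.0, 0.45),
    (1150.0, 12.0, 0.18),
    (1260.0, 15.0, 0.08),
    (1340.0, 14.0, 0.07),
    (1455.0, 12.0, 0.06),
    (1645.0, 22.0, 0.22),   # water bending / C=O
    (2930.0, 30.0, 0.08),   # C-H stretch
    (3300.0, 180.0, 0.45),  # broad O-H stretch
]

#: marker clusters (ten one-point lines each), keyed by nominal position;
#: clusters are mutually disjoint on the default grid
_CLUSTERS = ("c0600", "c0650", "c0710", "c0775", "c0810", "c0862", "c0872",
             "c0975", "c1060", "c1094", "c1180", "c1419", "c1640")


def default_band_library() -> list[BandSpec]:
    bands = [BandSpec(c, s, a) for c, s, a in _BROAD_BANDS]
    for name in _CLUSTERS:
        for center in _cluster_centers(float(name[1:])):
            bands.append(BandSpec(center, LINE_SIGMA, LINE_AMPLITUDE,
                                  support=LINE_SUPPORT))
    return bands


def _cluster_indices(name: str) -> list[int]:
    base = len(_BROAD_BANDS) + _CLUSTERS.index(name) * LINES_PER_CLUSTER
    return list(range(base, base + LINES_PER_CLUSTER))


def default_effects() -> list[ClassEffect]:
    """Frozen class effects of the study preset.

    Harvest year 2021 modulates four marker clusters (2020 is the reference
    level); each botanical effect is applied to a pair of classes whose
    year-margin imbalances have opposite sign, and analogously for regions,
    so cross-factor leakage from the unbalanced design approximately
    cancels at the template level.
    """
    eff: list[ClassEffect] = []
    # harvest year (reference 2020)
    for name, mult in (("c0650", 1.095), ("c1060", 0.915), ("c1094", 1.09), ("c1419", 0.915)):
        for idx in _cluster_indices(name):
            eff.append(ClassEffect("year", "2021", idx, mult))
    # botanical: each floral class raises one signature cluster, so each
    # one-vs-rest dummy response is (nearly) linear in a single cluster
    # amplitude; the shared 650 cluster keeps a mild paired effect whose
    # year-margin imbalances cancel
    botanical = [
        ("c0650", (("acacia", 1.05), ("honeydew", 1.05))),
        ("c0775", (("acacia", 1.2),)),
        ("c0862", (("colza", 1.2),)),
        ("c0975", (("honeydew", 1.2),)),
        ("c1640", (("linden", 1.2),)),
    ]
    for name, pairs in botanical:
        for level, mult in pairs:
            for idx in _cluster_indices(name):
                eff.append(ClassEffect("botanical", level, idx, mult))
    # region (reference Others)
    for name, mult in (
        ("c0600", 1.10), ("c0650", 1.04), ("c0710", 1.10),
        ("c0810", 0.91), ("c0872", 1.095), ("c1180", 0.91),
    ):
        for idx in _cluster_indices(name):
            eff.append(ClassEffect("region", "Transylvania", idx, mult))
    return eff


def default_generator_config(seed: int = 20200901) -> GeneratorConfig:
    """The frozen study preset: grid, bands, effects and noise magnitudes."""
    return GeneratorConfig(
        band_library=default_band_library(),
        effects=default_effects(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Spectrum generation
# ---------------------------------------------------------------------------

def _labels_dict(labels) -> dict[str, str | None]:
    if hasattr(labels, "botanical"):
        return {"botanical": labels.botanical, "year": labels.year, "region": labels.region}
    return {k: (None if v is None else str(v)) for k, v in dict(labels).items()}


def _band_params(cfg: GeneratorConfig, labels: dict,
                 strength: dict[str, float] | None = None):
    """Effective (center, sigma, amplitude, support) per band after effects.

    ``strength`` scales each factor's effect for one sample: a multiplier m
    is applied as m**lambda.  lambda = 1 reproduces the template; per-sample
    lambdas spread biological effect strength continuously, which is what
    makes the synthetic classes overlap rather than separate perfectly.
    """
    centers = np.array([b.center for b in cfg.band_library])
    sigmas = np.array([b.width for b in cfg.band_library])
    amps = np.array([b.amplitude for b in cfg.band_library])
    supports = np.array([b.support for b in cfg.band_library])
    for eff in cfg.effects:
        if labels.get(eff.factor) == eff.level:
            lam = 1.0 if strength is None else strength.get(eff.factor, 1.0)
            amps[eff.band_index] *= eff.amplitude_multiplier ** lam
            centers[eff.band_index] += eff.center_shift * lam
    return centers, sigmas, amps, supports


def _evaluate_bands(grid: np.ndarray, centers, sigmas, amps, supports) -> np.ndarray:
    signal = np.zeros_like(grid)
    for c, s, a, sup in zip(centers, sigmas, amps, supports):
        lo = np.searchsorted(grid, c - sup * s)
        hi = np.searchsorted(grid, c + sup * s, side="right")
        if hi > lo:
            z = (grid[lo:hi] - c) / s
            signal[lo:hi] += a * np.exp(-0.5 * z * z)
    return signal


def _lognormal_mean_one(rng: np.random.Generator, sd: float, size=None) -> np.ndarray:
    """exp(N(-sd^2/2, sd)): multiplicative jitter with expectation exactly 1."""
    z = rng.standard_normal(size)
    return np.exp(-0.5 * sd * sd + sd * z)


def noise_free_template(cfg: GeneratorConfig, labels) -> np.ndarray:
    """Deterministic band sum for a label combination (no nuisances)."""
    grid = cfg.grid()
    return _evaluate_bands(grid, *_band_params(cfg, _labels_dict(labels)))


def generate_spectrum(cfg: GeneratorConfig, labels, rng: np.random.Generator) -> np.ndarray:
    """One spectrum: jittered band sum x scatter + baseline + noise.

    The random-draw layout (per-factor effect strengths, per-band jitter,
    scatter, baseline coefficients, noise vector) is fixed, so a given rng
    state always yields the same row.
    """
    grid = cfg.grid()
    lam = rng.standard_normal(3) * cfg.effect_strength_sd + 1.0
    strength = dict(zip(("botanical", "year", "region"), lam))
    centers, sigmas, amps, supports = _band_params(cfg, _labels_dict(labels), strength)
    jitter = _lognormal_mean_one(rng, cfg.within_class_amp_sd, size=amps.size)
    signal = _evaluate_bands(grid, centers, sigmas, amps * jitter, supports)
    scatter = _lognormal_mean_one(rng, cfg.scatter_sd)
    coeffs = rng.standard_normal(cfg.baseline_order + 1) * cfg.baseline_sd
    x = (2.0 * (grid - grid[0]) / (grid[-1] - grid[0])) - 1.0
    baseline = np.polynomial.polynomial.polyval(x, coeffs)
    noise = rng.standard_normal(grid.size) * cfg.noise_sd
    return signal * scatter + baseline + noise


def generate_cohort(cfg: GeneratorConfig, design: CohortDesign) -> SpectrumSet:
    """Generate one cohort; sample order is a seeded permutation.

    Shuffling matters: venetian-blinds folds on class-sorted data would be
    systematically unbalanced.
    """
    if design.n_samples == 0:
        raise ValueError("empty cohort design")
    rows: list[tuple[str, str, str | None]] = []
    for cell, count in design.cells():
        rows.extend([cell] * count)
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(rows))
    rows = [rows[i] for i in perm]
    spectra = np.vstack([
        generate_spectrum(cfg, {"botanical": b, "year": y, "region": r}, rng)
        for b, y, r in rows
    ])
    meta = pd.DataFrame(
        {
            "sample_id": [f"H{i + 1:03d}" for i in range(len(rows))],
            "botanical": [b for b, _, _ in rows],
            "year": [y for _, y, _ in rows],
            "region": [r for _, _, r in rows],
        }
    )
    return SpectrumSet(wavenumbers=cfg.grid(), absorbance=spectra, meta=meta)


def informative_indices(cfg: GeneratorConfig, factor: str) -> np.ndarray:
    """Grid indices where noise-free templates differ across a factor's levels.

    Other factors are held absent, which selects exactly the union of the
    factor's effect-band supports (band truncation makes this exact).
    """
    levels = sorted({e.level for e in cfg.effects if e.factor == factor})
    if not levels:
        return np.array([], dtype=int)
    templates = [noise_free_template(cfg, {factor: lev}) for lev in [None] + levels]
    base = templates[0]
    differ = np.zeros(base.size, dtype=bool)
    for t in templates[1:]:
        differ |= np.abs(t - base) > 1e-12
    return np.flatnonzero(differ)


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def config_to_yaml(cfg: GeneratorConfig, path: str | Path) -> None:
    payload = {
        "grid_start": cfg.grid_start,
        "grid_stop": cfg.grid_stop,
        "grid_spacing": cfg.grid_spacing,
        "noise_sd": cfg.noise_sd,
        "baseline_order": cfg.baseline_order,
        "baseline_sd": cfg.baseline_sd,
        "scatter_sd": cfg.scatter_sd,
        "within_class_amp_sd": cfg.within_class_amp_sd,
        "effect_strength_sd": cfg.effect_strength_sd,
        "seed": cfg.seed,
        "band_library": [
            {"center": b.center, "width": b.width, "amplitude": b.amplitude,
             "support": b.support}
            for b in cfg.band_library
        ],
        "effects": [
            {
                "factor": e.factor,
                "level": e.level,
                "band_index": e.band_index,
                "amplitude_multiplier": e.amplitude_multiplier,
                "center_shift": e.center_shift,
            }
            for e in cfg.effects
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    payload = yaml.safe_load(Path(path).read_text())
    return GeneratorConfig(
        grid_start=float(payload["grid_start"]),
        grid_stop=float(payload["grid_stop"]),
        grid_spacing=float(payload["grid_spacing"]),
        band_library=[BandSpec(**b) for b in payload["band_library"]],
        effects=[ClassEffect(**e) for e in payload["effects"]],
        noise_sd=float(payload["noise_sd"]),
        baseline_order=int(payload["baseline_order"]),
        baseline_sd=float(payload["baseline_sd"]),
        scatter_sd=float(payload["scatter_sd"]),
        within_class_amp_sd=float(payload["within_class_amp_sd"]),
        effect_strength_sd=float(payload.get("effect_strength_sd", 0.0)),
        seed=int(payload["seed"]),
    )


def load_preset(name: str = "study") -> GeneratorConfig:
    """Load a shipped generator preset by name."""
    path = Path(__file__).parent / "presets" / f"{name}.yaml"
    if not path.exists():
        raise FileNotFoundError(f"no preset named {name!r}")
    return config_from_yaml(path)
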