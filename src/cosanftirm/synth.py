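"""Synthetic single-cell FTIR spectra with controlled group structure.

The generator emulates the statistical structure the downstream analysis
assumes: each cell spectrum is a sum of Gaussian component bands (protein
amide I/II, DNA phosphate, lipid CH stretches, the boron-cluster B-H
doublet at 2557/2537 cm^-1 and the cluster C-H at 3031 cm^-1), scaled by
per-group effect factors and per-cell lognormal jitter, sitting on a
low-order polynomial baseline, passed through a multiplicative scatter
transform ``a + b*(.)`` and finished with additive Gaussian noise.

Control groups carry a B-H factor of exactly 0, so the 2460-2620 cm^-1
window is signal-free for untreated cells — the property the B-H uptake
index exploits.  Treated groups gain the doublet, shift the alpha/beta
amide-I composition and lose olefinic (lipid unsaturation) intensity;
directions follow the study's findings, magnitudes are conventions of
this generator.

Draw order per cell (documented contract, single seeded Generator):
band jitters (library order), baseline coefficients, scatter (a, b),
noise vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import DEFAULT_GRID, HyperMap, Spectrum, SpectrumSet

__all__ = [
    "ComponentBand",
    "SyntheticModel",
    "default_model",
    "generate_spectrum",
    "generate_population",
    "generate_map",
    "gaussian",
]


def gaussian(nu: np.ndarray, center: float, sigma: float, amplitude: float) -> np.ndarray:
    """Gaussian band ``h * exp(-(nu-mu)^2 / (2 sigma^2))``."""
    return amplitude * np.exp(-0.5 * ((nu - center) / sigma) ** 2)


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian component band of the cell spectrum model."""

    center: float       # cm^-1
    sigma: float        # cm^-1
    amplitude: float    # AU (noiseless template peak height)
    assignment: str     # e.g. amideI_alpha, BH_main, ch2_sym

    def __post_init__(self) -> None:
        if not (2.0 <= self.sigma <= 60.0):
            raise ValueError(f"sigma {self.sigma} outside [2, 60] cm^-1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


# Band catalogue.  Centers are the study's assignments; amplitudes are
# generator conventions sized so absorbances land in a realistic 0-1 AU
# range for a single cell.
_DEFAULT_BANDS: tuple[ComponentBand, ...] = (
    ComponentBand(1610.0, 8.0, 0.10, "amideI_sidechain"),
    ComponentBand(1630.0, 10.0, 0.35, "amideI_beta"),
    ComponentBand(1652.0, 10.0, 0.80, "amideI_alpha"),
    ComponentBand(1682.0, 9.0, 0.12, "amideI_beta_turn"),
    ComponentBand(1690.0, 8.0, 0.08, "amideI_beta_anti"),
    ComponentBand(1545.0, 18.0, 0.45, "amideII"),
    ComponentBand(1236.0, 14.0, 0.22, "phosphate_asym"),
    ComponentBand(1085.0, 14.0, 0.25, "phosphate_sym"),
    ComponentBand(968.0, 10.0, 0.10, "dna_backbone"),
    ComponentBand(2852.0, 9.0, 0.25, "ch2_sym"),
    ComponentBand(2921.0, 10.0, 0.45, "ch2_asym"),
    ComponentBand(2960.0, 9.0, 0.28, "ch3_asym"),
    ComponentBand(2872.0, 8.0, 0.12, "ch3_sym"),
    ComponentBand(3010.0, 8.0, 0.05, "olefinic"),
    ComponentBand(2557.0, 8.0, 0.10, "BH_main"),
    ComponentBand(2537.0, 8.0, 0.05, "BH_sub"),
    ComponentBand(3031.0, 6.0, 0.02, "Cc_H"),
)

# Group effects: (cell_line, treatment) -> {assignment or prefix: factor}.
# Control rows carry BH factors of exactly 0.  Treated rows encode the
# reported directions: B-H present (dose-monotonic), alpha/beta ratio
# lowered, olefinic reduced; PG88 additionally shifts CH2/CH3 intensity.
_DEFAULT_EFFECTS: dict[tuple[str, str], dict[str, float]] = {
    ("GIC7", "control"): {"BH_main": 0.0, "BH_sub": 0.0, "Cc_H": 0.0},
    ("GIC7", "200uM"): {"BH_main": 0.3, "BH_sub": 0.3, "Cc_H": 0.3,
                        "amideI_alpha": 0.80, "amideI_beta": 1.20, "olefinic": 0.7},
    ("GIC7", "2mM"): {"BH_main": 1.0, "BH_sub": 1.0, "Cc_H": 1.0,
                      "amideI_alpha": 0.90, "amideI_beta": 1.05, "olefinic": 0.5},
    ("PG88", "control"): {"BH_main": 0.0, "BH_sub": 0.0, "Cc_H": 0.0,
                          "amideI_alpha": 1.30, "amideI_beta": 0.35,
                          "ch2_asym": 1.15, "ch2_sym": 1.10},
    ("PG88", "200uM"): {"BH_main": 0.45, "BH_sub": 0.45, "Cc_H": 0.45,
                        "amideI_alpha": 1.10, "amideI_beta": 0.44,
                        "ch2_asym": 0.90, "ch3_asym": 0.75, "olefinic": 0.85},
    ("PG88", "2mM"): {"BH_main": 1.3, "BH_sub": 1.3, "Cc_H": 1.3,
                      "amideI_alpha": 1.20, "amideI_beta": 0.42,
                      "ch2_asym": 0.90, "ch3_asym": 0.75, "olefinic": 0.7},
}


@dataclass(frozen=True)
class SyntheticModel:
    """Full specification of the synthetic cell-spectrum distribution."""

    bands: tuple[ComponentBand, ...] = _DEFAULT_BANDS
    group_effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_EFFECTS.items()})
    jitter_sd: float = 0.1          # lognormal sigma of per-cell amplitude jitter
    baseline_coeffs: tuple[float, float, float] = (0.05, 0.02, 0.01)
    # max |coefficient| of c0 + c1*x + c2*x^2 on x = rescaled nu in [-1, 1];
    # drawn uniformly in +/- each range per cell
    scatter_gain: tuple[float, float] = (0.7, 1.3)   # b range
    scatter_offset: float = 0.02                     # |a| range
    noise_sd: float = 0.005         # AU
    grid: tuple = tuple(DEFAULT_GRID)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise_sd and jitter_sd must be >= 0")
        for key, eff in self.group_effects.items():
            if any(v < 0 for v in eff.values()):
                raise ValueError(f"negative effect factor in group {key}")
            if key[1] == "control" and any(
                    eff.get(a, 0.0) != 0.0 for a in ("BH_main", "BH_sub")):
                raise ValueError(f"control group {key} must have BH factors 0")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.asarray(self.grid, float)

    def factor(self, cell_line: str, treatment: str, assignment: str) -> float:
        key = (cell_line, treatment)
        if key not in self.group_effects:
            raise KeyError(f"unknown group {key}; known: {sorted(self.group_effects)}")
        return self.group_effects[key].get(assignment, 1.0)

    def template(self, cell_line: str, treatment: str) -> Spectrum:
        """Noiseless, baseline-free group template (pure band sum)."""
        nu = self.wavenumbers
        a = np.zeros_like(nu)
        for band in self.bands:
            f = self.factor(cell_line, treatment, band.assignment)
            if f > 0 and band.amplitude > 0:
                a += gaussian(nu, band.center, band.sigma, band.amplitude * f)
        return Spectrum(nu, a, {"cell_line": cell_line, "treatment": treatment,
                                "template": True})


def default_model(**overrides) -> SyntheticModel:
    """The shipped study-condition model, optionally with field overrides."""
    return replace(SyntheticModel(), **overrides) if overrides else SyntheticModel()


def _draw_spectrum(m: SyntheticModel, cell_line: str, treatment: str,
                   rng: np.random.Generator) -> np.ndarray:
    """One cell's absorbance vector; draw order is part of the contract."""
    nu = m.wavenumbers
    a = np.zeros_like(nu)
    for band in m.bands:  # 1) per-band jitter, library order
        jit = float(np.exp(rng.normal(0.0, m.jitter_sd))) if m.jitter_sd > 0 else 1.0
        f = m.factor(cell_line, treatment, band.assignment)
        amp = band.amplitude * f * jit
        if amp > 0:
            a += gaussian(nu, band.center, band.sigma, amp)
    x = (2.0 * (nu - nu[0]) / (nu[-1] - nu[0])) - 1.0
    c = [rng.uniform(-r, r) for r in m.baseline_coeffs]       # 2) baseline
    a += c[0] + c[1] * x + c[2] * x * x
    off = rng.uniform(-m.scatter_offset, m.scatter_offset)    # 3) scatter a, b
    gain = rng.uniform(*m.scatter_gain)
    a = off + gain * a
    if m.noise_sd > 0:                                        # 4) noise
        a = a + rng.normal(0.0, m.noise_sd, size=nu.size)
    return a


def generate_spectrum(m: SyntheticModel, cell_line: str, treatment: str,
                      rng: np.random.Generator | int | None = None) -> Spectrum:
    """Generate one labeled cell spectrum (deterministic given the rng state)."""
    if rng is None:
        rng = np.random.default_rng(m.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    m.factor(cell_line, treatment, "amideI_alpha")  # validate group early
    a = _draw_spectrum(m, cell_line, treatment, rng)
    return Spectrum(m.wavenumbers, a,
                    {"cell_line": cell_line, "treatment": treatment, "synthetic": True})


def generate_population(m: SyntheticModel, n_per_group: int,
                        groups: list[tuple[str, str]] | None = None) -> SpectrumSet:
    """Generate a labeled population, ``n_per_group`` cells per group.

    A single seeded stream drives all draws (groups in list order, cells
    in index order), so the whole set is reproducible from ``m.seed``.
    """
    if groups is None:
        groups = list(m.group_effects)
    if not groups:
        raise ValueError("empty group list")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(m.seed)
    rows, labels = [], []
    for cell_line, treatment in groups:
        m.factor(cell_line, treatment, "amideI_alpha")
        for i in range(n_per_group):
            rows.append(_draw_spectrum(m, cell_line, treatment, rng))
            labels.append({"cell_line": cell_line, "treatment": treatment,
                           "sample_id": f"{cell_line}_{treatment}_{i:03d}"})
    return SpectrumSet(m.wavenumbers, np.asarray(rows), pd.DataFrame(labels),
                       {"seed": m.seed, "synthetic": True})


def generate_map(m: SyntheticModel, nx: int, ny: int, step_um: float,
                 nucleus_center: tuple[int, int], nucleus_radius_um: float,
                 cell_line: str = "GIC7", treatment: str = "2mM",
                 ) -> tuple[HyperMap, np.ndarray]:
    """Generate a single-cell hyperspectral map plus its nucleus mask.

    B-H band amplitudes are scaled by a radial Gaussian profile peaked at
    ``nucleus_center`` (pixel coordinates, (ix, iy)) with sigma
    ``nucleus_radius_um / 2``, emulating nuclear accumulation of the
    boron cluster; non-B-H bands fall off with a wider cell-body profile;
    background pixels carry baseline + noise only.  The returned boolean
    mask marks pixels within ``nucleus_radius_um`` of the centre.
    """
    if nucleus_radius_um <= 0:
        raise ValueError("nucleus radius must be > 0")
    cx, cy = nucleus_center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError("nucleus centre must lie inside the field")
    nu = m.wavenumbers
    rng = np.random.default_rng(m.seed)
    bh_template = np.zeros_like(nu)
    body_template = np.zeros_like(nu)
    for band in m.bands:
        f = m.factor(cell_line, treatment, band.assignment)
        if f <= 0 or band.amplitude <= 0:
            continue
        comp = gaussian(nu, band.center, band.sigma, band.amplitude * f)
        if band.assignment.startswith("BH"):
            bh_template += comp
        else:
            body_template += comp

    ix = np.arange(nx)[None, :]
    iy = np.arange(ny)[:, None]
    r_um = np.hypot((ix - cx) * step_um, (iy - cy) * step_um)
    sigma_nuc = nucleus_radius_um / 2.0
    bh_profile = np.exp(-0.5 * (r_um / sigma_nuc) ** 2)
    body_profile = np.exp(-0.5 * (r_um / (2.0 * nucleus_radius_um)) ** 2)
    mask = r_um <= nucleus_radius_um

    x = (2.0 * (nu - nu[0]) / (nu[-1] - nu[0])) - 1.0
    cube = np.empty((ny, nx, nu.size))
    for jy in range(ny):
        for jx in range(nx):
            a = (bh_profile[jy, jx] * bh_template
                 + body_profile[jy, jx] * body_template)
            c = [rng.uniform(-r, r) for r in m.baseline_coeffs]
            a = a + c[0] + c[1] * x + c[2] * x * x
            if m.noise_sd > 0:
                a = a + rng.normal(0.0, m.noise_sd, size=nu.size)
            cube[jy, jx] = a
    hmap = HyperMap(nu, cube, step_um,
                    {"seed": m.seed, "cell_line": cell_line, "treatment": treatment,
                     "nucleus_center": (cx, cy), "nucleus_radius_um": nucleus_radius_um})
    return hmap, mask
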