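"""Synthetic FT-MIR spectra with the nested 10-varieties-in-4-origins design.

The real walnut spectra behind the study were never deposited, so every
stage of the pipeline is exercised on synthetic data with a known answer.
A spectrum is a sum of Gaussian (or Lorentzian) absorption bands at the
positions chemists assign to walnut powder — the O–H stretch around
3000–3500 cm⁻¹, the C–H alkane triplet in 2800–3000 cm⁻¹, the sharp
carbonyl C=O band at 1740 cm⁻¹, amide/alkene structure in 1500–1700 cm⁻¹,
the aromatic C–C band near 1400–1500 cm⁻¹ and the C–O cluster in
1000–1275 cm⁻¹ — plus a random linear baseline and i.i.d. Gaussian noise.

Class structure is planted multiplicatively: each geographic origin scales
(and slightly shifts) a few designated bands, and each variety applies a
smaller perturbation to two further bands, nested within its origin.  The
set of axis points inside any class-affected band's +-3 sigma support is
the ground truth that wavelength selection should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra_io import REFERENCE_DESIGN, SpectralDataset

__all__ = ["BandSpec", "SyntheticSpec", "default_spec", "easy_spec",
           "generate", "templates", "ground_truth", "band_recovery"]


@dataclass(frozen=True)
class BandSpec:
    center: float          # cm^-1
    width: float           # Gaussian sigma or Lorentzian gamma, cm^-1
    amplitude: float       # absorbance at peak
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def profile(self, axis: np.ndarray, shift: float = 0.0) -> np.ndarray:
        d = axis - (self.center + shift)
        if self.shape == "gaussian":
            return np.exp(-0.5 * (d / self.width) ** 2)
        if self.shape == "lorentzian":
            return 1.0 / (1.0 + (d / self.width) ** 2)
        raise ValueError(f"unknown band shape {self.shape!r}")


#: default shared band table (center, sigma, amplitude)
_DEFAULT_BANDS = (
    BandSpec(3300.0, 120.0, 0.85),   # O-H stretch, broad
    BandSpec(2960.0, 12.0, 0.35),    # C-H alkane triplet
    BandSpec(2925.0, 14.0, 0.55),
    BandSpec(2855.0, 12.0, 0.40),
    BandSpec(1740.0, 10.0, 0.90),    # C=O carbonyl, sharp
    BandSpec(1630.0, 25.0, 0.30),    # C=C / N-H
    BandSpec(1550.0, 20.0, 0.25),
    BandSpec(1450.0, 18.0, 0.35),    # aromatic C-C
    BandSpec(1240.0, 22.0, 0.30),    # C-O cluster
    BandSpec(1160.0, 24.0, 0.45),
    BandSpec(1050.0, 28.0, 0.50),
)

#: per-origin (amplitude multiplier, centre shift) on designated bands
_DEFAULT_ORIGIN_EFFECTS = {
    "Yunnan":   {1740.0: (1.25, 3.0), 2925.0: (0.80, 0.0), 1160.0: (1.10, 0.0)},
    "Xinjiang": {1740.0: (1.10, 1.0), 2925.0: (1.20, 0.0), 1160.0: (0.85, 0.0)},
    "Shaanxi":  {1740.0: (0.90, -1.0), 2925.0: (1.05, 0.0), 1160.0: (1.20, 0.0)},
    "Hebei":    {1740.0: (0.75, -3.0), 2925.0: (0.95, 0.0), 1160.0: (0.90, 0.0)},
}

#: per-variety amplitude multipliers (~1/3 the origin effect), nested bands
_DEFAULT_VARIETY_EFFECTS = {
    "YangbiDapao":  {1450.0: (1.20, 0.0), 1050.0: (0.90, 0.0)},
    "YangbiCaoguo": {1450.0: (0.85, 0.0), 1050.0: (1.12, 0.0)},
    "Hetian185":    {1450.0: (1.18, 0.0), 1050.0: (1.15, 0.0)},
    "Xinfeng":      {1450.0: (0.95, 0.0), 1050.0: (0.82, 0.0)},
    "Xinxin2":      {1450.0: (0.80, 0.0), 1050.0: (1.05, 0.0)},
    "Liao4":        {1450.0: (1.15, 0.0), 1050.0: (0.85, 0.0)},
    "Xiangling":    {1450.0: (0.85, 0.0), 1050.0: (1.15, 0.0)},
    "Qingxiang":    {1450.0: (1.20, 0.0), 1050.0: (1.10, 0.0)},
    "Liao1":        {1450.0: (0.95, 0.0), 1050.0: (0.80, 0.0)},
    "Liao8":        {1450.0: (0.78, 0.0), 1050.0: (1.06, 0.0)},
}


@dataclass(frozen=True)
class SyntheticSpec:
    lo: float = 700.0
    hi: float = 3450.0
    step: float = 1.0
    bands: tuple = _DEFAULT_BANDS
    origin_effects: dict = field(default_factory=lambda: dict(_DEFAULT_ORIGIN_EFFECTS))
    variety_effects: dict = field(default_factory=lambda: dict(_DEFAULT_VARIETY_EFFECTS))
    #: variety -> (origin, n_samples, n_train); defaults to the published design
    design: dict = field(default_factory=lambda: dict(REFERENCE_DESIGN))
    noise_sd: float = 0.02
    baseline_offset: tuple[float, float] = (-0.03, 0.03)
    baseline_slope: tuple[float, float] = (-0.04, 0.04)
    seed: int = 0


def default_spec(**overrides) -> SyntheticSpec:
    """The study-scale default: 192 samples, 2751 axis points, noise 0.02."""
    return replace(SyntheticSpec(), **overrides) if overrides else SyntheticSpec()


def easy_spec(n_per_class: int = 18, noise_sd: float = 0.01,
              step: float = 4.0, seed: int = 0) -> SyntheticSpec:
    """An easy 4-class design: one variety per origin, well separated."""
    design = {
        "YangbiDapao": ("Yunnan", n_per_class, round(2 * n_per_class / 3)),
        "Hetian185": ("Xinjiang", n_per_class, round(2 * n_per_class / 3)),
        "Liao4": ("Shaanxi", n_per_class, round(2 * n_per_class / 3)),
        "Qingxiang": ("Hebei", n_per_class, round(2 * n_per_class / 3)),
    }
    return SyntheticSpec(step=step, design=design, noise_sd=noise_sd,
                         baseline_offset=(-0.01, 0.01),
                         baseline_slope=(-0.01, 0.01), seed=seed)


def _axis(spec: SyntheticSpec) -> np.ndarray:
    n = int(np.floor((spec.hi - spec.lo) / spec.step)) + 1
    if n < 50:
        raise ValueError(
            f"axis step {spec.step} too coarse: only {n} points (< 50)")
    return spec.lo + spec.step * np.arange(n)


def _template(spec: SyntheticSpec, axis: np.ndarray, variety: str) -> np.ndarray:
    origin = spec.design[variety][0]
    oeff = spec.origin_effects.get(origin, {})
    veff = spec.variety_effects.get(variety, {})
    y = np.zeros_like(axis)
    for b in spec.bands:
        om, osh = oeff.get(b.center, (1.0, 0.0))
        vm, vsh = veff.get(b.center, (1.0, 0.0))
        y += b.amplitude * om * vm * b.profile(axis, shift=osh + vsh)
    return y


def templates(spec: SyntheticSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Noise-free class templates: (axis, {variety: spectrum})."""
    axis = _axis(spec)
    return axis, {v: _template(spec, axis, v) for v in spec.design}


def generate(spec: SyntheticSpec) -> SpectralDataset:
    """Draw a dataset: template + linear baseline + Gaussian noise per sample."""
    axis, tpl = templates(spec)
    rng = np.random.default_rng(spec.seed)
    rows, origins, varieties, ids = [], [], [], []
    frac = (axis - axis[0]) / (axis[-1] - axis[0])
    for v, (o, n, _ntr) in spec.design.items():
        for i in range(n):
            off = rng.uniform(*spec.baseline_offset)
            slope = rng.uniform(*spec.baseline_slope)
            noise = rng.normal(0.0, spec.noise_sd, size=axis.size) \
                if spec.noise_sd > 0 else 0.0
            rows.append(tpl[v] + off + slope * frac + noise)
            origins.append(o)
            varieties.append(v)
            ids.append(f"{v}-{i:02d}")
    return SpectralDataset(absorbance=np.vstack(rows), wavenumbers=axis,
                           origin=np.array(origins, dtype=object),
                           variety=np.array(varieties, dtype=object),
                           sample_id=np.array(ids, dtype=object))


def train_sizes(spec: SyntheticSpec) -> dict[str, int]:
    """Per-variety training counts of the design (for stratified_split)."""
    return {v: ntr for v, (_o, _n, ntr) in spec.design.items()}


# ---------------------------------------------------------------------------
# ground truth

def _affected_bands(spec: SyntheticSpec,
                    level: str) -> list[tuple[BandSpec, float]]:
    """Bands whose amplitude or centre depends on the class at ``level``,
    paired with the largest |centre shift| any class applies to them."""
    out = []
    for b in spec.bands:
        hits = {"origin": False, "variety": False}
        max_shift = 0.0
        for name, table in (("origin", spec.origin_effects),
                            ("variety", spec.variety_effects)):
            for eff in table.values():
                mult, shift = eff.get(b.center, (1.0, 0.0))
                if (mult, shift) != (1.0, 0.0):
                    hits[name] = True
                    max_shift = max(max_shift, abs(shift))
        if (level == "any" and any(hits.values())) or hits.get(level, False):
            out.append((b, max_shift))
    return out


def ground_truth(spec: SyntheticSpec, level: str = "any") -> np.ndarray:
    """Indices of axis points inside any class-affected band's support
    (+-3 sigma widened by the largest class centre shift)."""
    axis = _axis(spec)
    mask = np.zeros(axis.size, dtype=bool)
    for b, shift in _affected_bands(spec, level):
        mask |= np.abs(axis - b.center) <= 3.0 * b.width + shift
    return np.nonzero(mask)[0]


def band_recovery(selected_index: np.ndarray, spec: SyntheticSpec,
                  level: str = "origin") -> float:
    """Fraction of class-affected bands hit by at least one selected variable.

    A band counts as recovered when some selected axis point falls inside
    its +-3 sigma support.
    """
    axis = _axis(spec)
    bands = _affected_bands(spec, level)
    if not bands:
        raise ValueError(f"no class-affected bands at level {level!r}")
    sel_wn = axis[np.asarray(selected_index, dtype=int)]
    hit = sum(bool(np.any(np.abs(sel_wn - b.center) <= 3.0 * b.width + sh))
              for b, sh in bands)
    return hit / len(bands)
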