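"""Forward-model generators for calibration mixtures and MSI phantoms.

The generator emulates the study conditions the calibration stage assumes:
ternary mixtures of PGE₂, PGD₂ and Δ12-PGD₂ at a fixed total concentration,
measured through three diagnostic MS³ channels (m/z 331/333/341) whose
per-isomer fragment yields are anchored to the qualitative standard spectra
(channel 331 essentially unique to PGE₂, channel 341 characteristic of
Δ12-PGD₂, channel 333 shared), plus a line-scan MSI phantom with
anatomically distinct regions and an internal-standard channel.

Channel intensities mix linearly in the molar fractions; the *relative*
abundances are therefore rational functions of the fractions, which is the
behaviour the polynomial calibration approximates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import IsomerComposition, IsomerModel, TrainingSample
from .formula import AdductSpec, adduct_mz, parse_formula
from .spectra import HIGH_RES, LOW_RES, MassSpectrum, TripletAbundance

__all__ = [
    "FragmentSignature",
    "NoiseModel",
    "PhantomLayout",
    "simulate_triplet",
    "mixing_intensities",
    "default_design",
    "make_training_set",
    "make_consistent_training_set",
    "default_phantom_layout",
    "make_msi_phantom",
    "PRECURSOR_MZ",
    "STANDARD_MZ",
    "MS3_CHAIN",
]

#: [M+107Ag]+ of C20H32O5 (the shared precursor of all three isomers).
PRECURSOR_MZ = adduct_mz(AdductSpec(parse_formula("C20H32O5")))
#: [M+107Ag]+ of the deuterated internal standard PGD2-d9 (C20H23D9O5).
STANDARD_MZ = adduct_mz(AdductSpec(parse_formula("C20H23[2H]9O5")))
#: MS³ isolation chain: precursor, then its water-loss product.
MS3_CHAIN = (459.13, 441.12)

#: Centroid positions of the diagnostic fragments as seen in the ion trap
#: (the 331 channel merges the unresolved 331.0096/331.1905 pair).
_CHANNEL_MZ = (331.01, 333.21, 341.03)

#: Default total channel intensity (arbitrary detector counts) representing
#: the 3 μM calibration-level signal.
DEFAULT_TOTAL_INTENSITY = 1.0e5


@dataclass(frozen=True)
class FragmentSignature:
    """Per-isomer relative yields of channels (331, 333, 341).

    Each isomer's yields are normalized to its own base peak = 1.  Defaults:
    PGE₂ fragments almost exclusively into 331 with the shared 333 channel at
    5 % of base; both PGD₂-type isomers have 333 as base peak with 331 below
    2 %; Δ12-PGD₂ additionally produces the characteristic 341 channel.
    """

    pge2: tuple[float, float, float] = (1.00, 0.05, 0.01)
    pgd2: tuple[float, float, float] = (0.02, 1.00, 0.02)
    d12pgd2: tuple[float, float, float] = (0.02, 1.00, 0.35)

    def __post_init__(self):
        for name in ("pge2", "pgd2", "d12pgd2"):
            y = getattr(self, name)
            if len(y) != 3 or min(y) < 0:
                raise ValueError(f"{name}: yields must be three non-negative numbers")
            if abs(max(y) - 1.0) > 1e-9:
                raise ValueError(f"{name}: yields must be normalized to base peak = 1")

    @property
    def matrix(self) -> np.ndarray:
        """3×3 matrix, rows = isomers (E2, D2, Δ12), cols = channels (331, 333, 341)."""
        return np.array([self.pge2, self.pgd2, self.d12pgd2], dtype=float)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative (CV) plus additive Gaussian intensity noise."""

    proportional_cv: float = 0.03
    additive_sd: float = 0.01 * DEFAULT_TOTAL_INTENSITY
    seed: int = 0

    def __post_init__(self):
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = clean * (1.0 + self.proportional_cv * rng.standard_normal(clean.shape))
        noisy += self.additive_sd * rng.standard_normal(clean.shape)
        return np.clip(noisy, 0.0, None)


NOISELESS = NoiseModel(proportional_cv=0.0, additive_sd=0.0)


def mixing_intensities(
    comp: IsomerComposition,
    total_intensity: float,
    sig: FragmentSignature,
) -> np.ndarray:
    """Closed-form noiseless channel intensities of a mixture.

    channel = total × Σ_isomer fraction × yield — linear mixing of the three
    isomer signatures, assuming equal per-isomer ionization and fragmentation
    efficiency.
    """
    fractions = comp.as_array() / 100.0
    return total_intensity * fractions @ sig.matrix


def simulate_triplet(
    comp: IsomerComposition,
    total_intensity: float = DEFAULT_TOTAL_INTENSITY,
    sig: FragmentSignature = FragmentSignature(),
    noise: NoiseModel = NOISELESS,
    rng: np.random.Generator | None = None,
) -> TripletAbundance:
    """Simulate the diagnostic-channel triplet of one measured mixture."""
    if total_intensity <= 0:
        raise ValueError("total_intensity must be positive")
    if not comp.valid:
        raise ValueError("cannot simulate from an invalid composition")
    clean = mixing_intensities(comp, total_intensity, sig)
    if rng is None:
        rng = noise.rng()
    i331, i333, i341 = noise.apply(clean, rng)
    return TripletAbundance(i331=i331, i333=i333, i341=i341)


def default_design(lattice_step: float = 20.0) -> list[IsomerComposition]:
    """Ternary calibration design spanning 0–100 % of each isomer.

    A simplex lattice with the given step (default 20 % → 21 compositions:
    the three pure standards, all binary mixtures, and interior points) plus
    the equimolar point.
    """
    k = int(round(100.0 / lattice_step))
    comps = []
    for i in range(k + 1):
        for j in range(k + 1 - i):
            comps.append(
                IsomerComposition.of(
                    i * lattice_step, j * lattice_step, 100.0 - (i + j) * lattice_step
                )
            )
    third = 100.0 / 3.0
    comps.append(IsomerComposition.of(third, third, 100.0 - 2 * third))
    return comps


def make_training_set(
    design: Sequence[IsomerComposition] | None = None,
    replicates: int = 3,
    sig: FragmentSignature = FragmentSignature(),
    noise: NoiseModel = NoiseModel(),
    total_intensity: float = DEFAULT_TOTAL_INTENSITY,
) -> list[TrainingSample]:
    """One TrainingSample per composition × technical replicate."""
    if design is None:
        design = default_design()
    design = list(design)
    if not design:
        raise ValueError("empty calibration design")
    rng = noise.rng()
    samples = []
    for comp in design:
        for rep in range(replicates):
            samples.append(
                TrainingSample(
                    true_composition=comp,
                    triplet=simulate_triplet(comp, total_intensity, sig, noise, rng),
                    replicate=rep,
                )
            )
    return samples


def spike_interference(
    t: TripletAbundance,
    rng: np.random.Generator,
    max_fraction: float = 0.05,
) -> TripletAbundance:
    """Add matrix-like additive interference to the 331 and 333 channels.

    Emulates isobaric background from a complex biological matrix: a total
    interference budget drawn uniformly from [0, ``max_fraction``] of the
    triplet's summed signal is split at a random proportion between the 331
    and 333 channels.  The characteristic 341 channel is left untouched (no
    interfering species was observed there).
    """
    budget = rng.uniform(0.0, max_fraction) * t.total
    split = rng.uniform(0.0, 1.0)
    return TripletAbundance(
        i331=t.i331 + split * budget,
        i333=t.i333 + (1.0 - split) * budget,
        i341=t.i341,
        n_scans=t.n_scans,
    )


def make_spiked_test_set(
    design: Sequence[IsomerComposition] | None = None,
    replicates: int = 3,
    sig: FragmentSignature = FragmentSignature(),
    noise: NoiseModel = NoiseModel(),
    total_intensity: float = DEFAULT_TOTAL_INTENSITY,
    max_interference: float = 0.05,
) -> list[TrainingSample]:
    """Mixtures measured on top of a complex-matrix interference background.

    Same forward model as :func:`make_training_set`, then additive
    interference in channels 331/333 via :func:`spike_interference`.  Used to
    evaluate a model trained on clean mixtures against matrix effects.
    """
    if design is None:
        design = default_design()
    rng = noise.rng()
    out = []
    for comp in design:
        for rep in range(replicates):
            t = simulate_triplet(comp, total_intensity, sig, noise, rng)
            out.append(
                TrainingSample(comp, spike_interference(t, rng, max_interference), rep)
            )
    return out


# ---------------------------------------------------------------------------
# Polynomial-consistent generator (recovery oracle)

#: A reference calibration whose data the polynomial model describes exactly:
#: a strictly monotone cubic for r331(%PGE₂) and a surface linear in r341
#: (p02 = 0) so that r341 can be solved for any target %Δ12.
REFERENCE_MODEL = IsomerModel(
    surface_coeffs=np.array([-1.0, -5.0, 260.0, 3.0, -40.0, 0.0]),
    cubic_coeffs=np.array([0.02, 9.5e-3, -2.0e-5, 5.0e-8]),
    r2_surface=1.0,
    r2_cubic=1.0,
    training_meta={"generator": "polynomial-consistent"},
)


def make_consistent_training_set(
    model: IsomerModel = REFERENCE_MODEL,
    n_grid: int = 6,
    replicates: int = 1,
    noise: NoiseModel = NOISELESS,
    total_intensity: float = DEFAULT_TOTAL_INTENSITY,
) -> list[TrainingSample]:
    """Training samples generated *from* a known polynomial calibration.

    For every (%PGE₂, %Δ12) grid point the channel relative abundances are
    constructed to lie exactly on the model: x = g(%PGE₂) and y solving
    f(x, y) = %Δ12 (requires a surface with p02 = 0 so y enters linearly).
    Refitting such data recovers the generating coefficients with R² = 1,
    which makes this the recovery oracle for the calibration stage.
    """
    p00, p10, p01, p20, p11, p02 = model.surface_coeffs
    if abs(p02) > 1e-12:
        raise ValueError("consistent generation requires a surface with p02 = 0")
    rng = noise.rng()
    samples = []
    grid = np.linspace(0.0, 100.0, n_grid)
    for pe in grid:
        for pd12 in grid:
            if pe + pd12 > 100.0 + 1e-9:
                continue
            x = float(model.cubic(pe))
            denom = p01 + p11 * x
            if abs(denom) < 1e-9:
                continue
            y = (pd12 - p00 - p10 * x - p20 * x * x) / denom
            if x < 0 or y < 0 or x + y > 1.0:
                continue
            intensities = total_intensity * np.array([x, 1.0 - x - y, y])
            comp = IsomerComposition.of(pe, 100.0 - pe - pd12, pd12)
            for rep in range(replicates):
                i331, i333, i341 = noise.apply(intensities, rng)
                samples.append(
                    TrainingSample(comp, TripletAbundance(i331, i333, i341), replicate=rep)
                )
    return samples


# ---------------------------------------------------------------------------
# MSI phantom


@dataclass(frozen=True)
class Region:
    label: str
    composition: IsomerComposition
    total_signal: float  # summed diagnostic-channel intensity per pixel


@dataclass
class PhantomLayout:
    """Rectangular phantom with labelled anatomical regions.

    ``labels`` is an (n_lines, n_pixels) integer grid indexing ``regions``;
    region 0 is off-tissue.  Emulates an implantation-site section with an
    antimesometrial-pole-like region, a mesometrial-pole-like region and an
    epithelium-like stripe on a low-signal background.
    """

    labels: np.ndarray
    regions: list[Region]
    standard_level: float = 500.0
    precursor_gain: float = 2.0  # SIM precursor counts per unit MS³ signal

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() >= len(self.regions):
            raise ValueError("label grid indexes outside the region list")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def truth_maps(self) -> dict[str, np.ndarray]:
        """Ground-truth composition / signal maps for round-trip tests."""
        shape = self.labels.shape
        comp = np.zeros(shape + (3,))
        total = np.zeros(shape)
        for idx, region in enumerate(self.regions):
            where = self.labels == idx
            comp[where] = region.composition.as_array()
            total[where] = region.total_signal
        return {
            "labels": self.labels.copy(),
            "composition": comp,
            "total": total,
            "standard": np.full(shape, self.standard_level),
        }


def default_phantom_layout(
    n_lines: int = 20,
    n_pixels: int = 40,
    tissue_signal: float = 2000.0,
) -> PhantomLayout:
    """A 20 × 40 phantom: off-tissue border, AM-pole, M-pole and epithelium.

    The AM-pole-like region carries the composition (35, 15, 50) % at full
    signal, the M-pole-like region a weaker signal, and the epithelium-like
    stripe sits between them; the off-tissue background is ~3 orders of
    magnitude below tissue so it falls under the tissue mask threshold.
    """
    labels = np.zeros((n_lines, n_pixels), dtype=int)
    b = 3  # off-tissue border width
    mid0, mid1 = int(n_pixels * 0.45), int(n_pixels * 0.55)
    labels[b:-b, b:mid0] = 1  # AM pole
    labels[b:-b, mid0:mid1] = 3  # luminal epithelium stripe
    labels[b:-b, mid1:-b] = 2  # M pole
    regions = [
        Region("off_tissue", IsomerComposition.of(100.0, 0.0, 0.0), tissue_signal * 5e-4),
        Region("AM_pole", IsomerComposition.of(35.0, 15.0, 50.0), tissue_signal),
        Region("M_pole", IsomerComposition.of(60.0, 25.0, 15.0), tissue_signal * 0.4),
        Region("Le", IsomerComposition.of(20.0, 40.0, 40.0), tissue_signal * 0.8),
    ]
    return PhantomLayout(labels, regions)


def _centroid_spectrum(peaks: dict[float, float], **kwargs) -> MassSpectrum:
    mzs = np.array(sorted(peaks))
    return MassSpectrum(mz=mzs, intensity=np.array([peaks[m] for m in mzs]), **kwargs)


def make_msi_phantom(
    layout: PhantomLayout | None = None,
    sig: FragmentSignature = FragmentSignature(),
    noise: NoiseModel | None = None,
    cycle_period: float = 1.55,
) -> tuple[list[list[MassSpectrum]], dict[str, np.ndarray]]:
    """Synthesize interlaced SIM + MS³ line scans plus ground-truth maps.

    Each pixel contributes one MS³ scan (ion trap, chain 459.13 → 441.12)
    with the three diagnostic channels, and one interlaced SIM scan
    (high-res) carrying the precursor at m/z 459.1295 and the deuterated
    internal standard.  Returns (line_streams, truth_maps).
    """
    if layout is None:
        layout = default_phantom_layout()
    if noise is None:
        # additive noise at 1 % of the tissue-level base peak of this layout
        base = max(
            float(mixing_intensities(r.composition, r.total_signal, sig).max())
            for r in layout.regions
        )
        noise = NoiseModel(proportional_cv=0.03, additive_sd=0.01 * base)
    rng = noise.rng()
    n_lines, n_px = layout.shape
    lines: list[list[MassSpectrum]] = []
    for li in range(n_lines):
        scans: list[MassSpectrum] = []
        for px in range(n_px):
            region = layout.regions[layout.labels[li, px]]
            t_ms3 = px * cycle_period
            clean = mixing_intensities(region.composition, region.total_signal, sig)
            i331, i333, i341 = noise.apply(clean, rng)
            # SIM scan interlaced mid-cycle, nearest in time to its pixel
            prec = region.total_signal * layout.precursor_gain
            std = layout.standard_level
            prec_n, std_n = noise.apply(np.array([prec, std]), rng)
            scans.append(
                _centroid_spectrum(
                    {PRECURSOR_MZ: prec_n, STANDARD_MZ: std_n},
                    ms_level=1,
                    scan_time=t_ms3 + 0.4 * cycle_period,
                    analyzer=HIGH_RES,
                )
            )
            scans.append(
                _centroid_spectrum(
                    dict(zip(_CHANNEL_MZ, (i331, i333, i341))),
                    ms_level=3,
                    precursor_chain=MS3_CHAIN,
                    scan_time=t_ms3,
                    analyzer=LOW_RES,
                )
            )
        scans.sort(key=lambda s: s.scan_time)
        lines.append(scans)
    return lines, layout.truth_maps()
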