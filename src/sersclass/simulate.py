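"""Synthetic SERS Raman spectrum generator with planted class markers.

The study conditions this emulates: 51 spectra (37 parental-control, 14
tumor-repopulating-cell) collected from 13 biological samples (8 control,
5 TRC) on a ~1.1 cm^-1 instrument grid.  Each synthetic spectrum is

    per-spectrum polynomial baseline
  + broad autofluorescence hump (wide Gaussian)
  + sum of Lorentzian bands (shared bands + class-differential bands),
    centers jittered per spectrum, amplitudes modulated by a shared
    per-sample random effect,
  all scaled by a per-spectrum multiplicative factor,
  + additive zero-mean Gaussian noise.

The multiplicative per-spectrum scale models the irreproducible absolute
SERS enhancement that motivates max-peak normalization downstream; the
per-sample amplitude effect induces the within-sample correlation visible
when spectra cluster by biological sample.  The generator returns the
planted differential-band centers as ground truth so marker-recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectrumSet

#: Shared (class-independent) bands: (center cm^-1, FWHM cm^-1, amplitude).
#: Centers sit on well-known cellular Raman bands (proline/collagen 728,
#: tyrosine 855, phenylalanine 1002, PO2- 1092, CH2 deformation 1449, ...).
DEFAULT_SHARED_PEAKS: tuple[tuple[float, float, float], ...] = (
    (622.0, 8.0, 0.5),
    (728.0, 10.0, 1.0),
    (855.0, 10.0, 0.6),
    (1002.0, 6.0, 1.2),
    (1092.0, 12.0, 0.9),
    (1335.0, 14.0, 0.7),
    (1449.0, 14.0, 0.9),
    (1745.0, 10.0, 0.4),
)

#: Class-differential bands: (center, FWHM, control amplitude, TRC amplitude).
#: Placed in the 1115-1665 cm^-1 region (Amide III / Amide I neighborhood)
#: where protein-backbone markers separate the cell types; TRC:control
#: amplitude ratios are ~2-2.4x in either direction.
DEFAULT_DIFFERENTIAL_PEAKS: tuple[tuple[float, float, float, float], ...] = (
    (1201.5, 10.0, 0.30, 0.70),
    (1267.6, 10.0, 0.35, 0.80),
    (1420.5, 12.0, 0.60, 0.25),
    (1610.4, 9.0, 0.30, 0.70),
    (1654.9, 12.0, 0.55, 1.20),
)


@dataclass
class GeneratorConfig:
    """Conditions for the synthetic spectrum generator.

    Defaults reproduce the study's data shape: 37 control + 14 TRC spectra
    from 8 + 5 biological samples on a 350-1800 cm^-1 grid with 1.1 cm^-1
    spacing.  Amplitudes are in arbitrary units with shared bands of order 1.
    """

    grid_start: float = 350.0
    grid_end: float = 1800.0
    grid_step: float = 1.1
    n_control: int = 37
    n_trc: int = 14
    n_samples_control: int = 8
    n_samples_trc: int = 5
    shared_peaks: tuple = DEFAULT_SHARED_PEAKS
    differential_peaks: tuple = DEFAULT_DIFFERENTIAL_PEAKS
    baseline_degree: int = 3
    baseline_scale: float = 0.5
    fluorescence_scale: float = 2.0
    intensity_jitter: float = 0.15
    shift_jitter: float = 1.0
    sample_effect_sd: float = 0.10
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_trc, self.n_samples_control, self.n_samples_trc) < 1:
            raise ValueError("spectrum and sample counts must be >= 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.grid_end <= self.grid_start:
            raise ValueError("grid_end must exceed grid_start")
        for center, width, *_ in (*self.shared_peaks, *self.differential_peaks):
            if width <= 0:
                raise ValueError(f"peak width must be positive (center {center})")
        for center, *_ in self.differential_peaks:
            if not (self.grid_start <= center <= self.grid_end):
                raise ValueError(f"differential peak {center} cm^-1 lies outside the grid")
        for center, *_ in self.shared_peaks:
            if not (self.grid_start <= center <= self.grid_end):
                raise ValueError(f"shared peak {center} cm^-1 lies outside the grid")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_end + 0.5 * self.grid_step, self.grid_step)


def lorentzian(center: float, width: float, amplitude: float, grid: np.ndarray) -> np.ndarray:
    """Lorentzian band: value ``amplitude`` at ``center``, half maximum at
    ``center +/- width/2`` (``width`` is the FWHM)."""
    if width <= 0:
        raise ValueError("width must be positive")
    hw = 0.5 * width
    return amplitude * hw**2 / ((np.asarray(grid, dtype=float) - center) ** 2 + hw**2)


def _partition(n_items: int, n_groups: int) -> np.ndarray:
    """Group index per item, groups as even as possible, in blocks."""
    sizes = np.full(n_groups, n_items // n_groups)
    sizes[: n_items % n_groups] += 1
    return np.repeat(np.arange(n_groups), sizes)


def generate(config: GeneratorConfig) -> tuple[SpectrumSet, list[float]]:
    """Generate a :class:`SpectrumSet` plus the planted marker centers.

    Randomness fans out from a single root seed: one stream for the
    per-sample amplitude effects, one stream per spectrum.  Identical
    configs therefore give bit-identical output.
    """
    grid = config.grid
    n_total = config.n_control + config.n_trc
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(1 + n_total)
    sample_rng = np.random.default_rng(children[0])

    n_samples = config.n_samples_control + config.n_samples_trc
    sample_effects = np.exp(sample_rng.normal(0.0, config.sample_effect_sd, size=n_samples))

    # Block assignment: controls to samples 0..n_samples_control-1, TRCs after.
    sample_of = np.concatenate(
        [
            _partition(config.n_control, config.n_samples_control),
            config.n_samples_control + _partition(config.n_trc, config.n_samples_trc),
        ]
    )
    labels = np.array(
        ["control"] * config.n_control + ["trc"] * config.n_trc, dtype=object
    )

    # Location counter within each sample for S##/L## identifiers.
    loc_counter: dict[int, int] = {}
    ids = []
    for s in sample_of:
        loc_counter[s] = loc_counter.get(s, 0) + 1
        ids.append(f"S{s + 1:02d}/L{loc_counter[s]:02d}")

    intensities = np.empty((n_total, grid.size))
    u = (grid - config.grid_start) / (config.grid_end - config.grid_start)
    for i in range(n_total):
        rng = np.random.default_rng(children[1 + i])
        is_trc = labels[i] == "trc"

        # Polynomial baseline in the scaled coordinate u in [0, 1].
        coefs = rng.normal(0.0, 1.0, size=config.baseline_degree + 1)
        baseline = config.baseline_scale * np.polynomial.polynomial.polyval(u, coefs)

        # Broad autofluorescence hump.
        fl_center = rng.uniform(700.0, 1500.0)
        fl_width = rng.uniform(300.0, 600.0)
        fl_amp = config.fluorescence_scale * rng.uniform(0.5, 1.5)
        baseline = baseline + fl_amp * np.exp(-0.5 * ((grid - fl_center) / fl_width) ** 2)

        signal = np.zeros_like(grid)
        bands: list[tuple[float, float, float]] = [
            (c, w, a) for (c, w, a) in config.shared_peaks
        ]
        bands += [
            (c, w, a_trc if is_trc else a_ctl)
            for (c, w, a_ctl, a_trc) in config.differential_peaks
        ]
        effect = sample_effects[sample_of[i]]
        for center, width, amp in bands:
            center = center + rng.normal(0.0, config.shift_jitter) if config.shift_jitter else center
            signal += lorentzian(center, width, amp * effect, grid)

        scale = np.exp(rng.normal(0.0, config.intensity_jitter)) if config.intensity_jitter else 1.0
        noise = rng.normal(0.0, config.noise_sd, size=grid.size) if config.noise_sd else 0.0
        intensities[i] = scale * (signal + baseline) + noise

    sset = SpectrumSet(grid, intensities, labels, np.array(ids, dtype=object))
    markers = [c for (c, *_rest) in config.differential_peaks]
    return sset, markers
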