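"""Tissue presets and cohort designs for the synthetic generator.

A :class:`TissuePreset` bundles the parameters that define one depot /
condition: the adipocyte diameter distribution (lognormal, or a lognormal
mixture for bimodal depots), the packing mode (space-filling polyhedral
cells inside tissue vs sparse spheres after extraction), the ECM wall
thickness, the exponential depth-attenuation length of the optical signal,
and the noise model of the rendered channels.

The built-in presets encode the depot contrasts of the study system: trout
visceral adipose tissue (VAT, mean diameter 81.32 µm) vs subcutaneous
(SCAT, 63.88 µm); extracted (ex situ) cells that are smaller and round;
mouse SCAT with either a single large population (Swiss, ~100 µm) or two
peaks (C57Bl6, 38 and 50 µm); and cleared (Histodenz) vs uncleared (PBS)
imaging, which differ only in attenuation length. Published sources give
depot means but no dispersion, so the coefficients of variation are free
parameters of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

PACKINGS = ("in_situ", "ex_situ")
TISSUES = ("VAT", "SCAT")


@dataclass(frozen=True)
class TissuePreset:
    """Generator parameters for one depot / imaging condition.

    Parameters
    ----------
    diameter_mean:
        Arithmetic mean of the cell diameter distribution, µm.
    diameter_cv:
        Coefficient of variation of the (lognormal) diameter distribution.
    mixture:
        Optional list of ``(weight, mean_um, cv)`` lognormal components for
        bimodal depots; overrides ``diameter_mean``/``diameter_cv`` when
        present. Weights must sum to 1.
    packing:
        ``"in_situ"`` (space-filling polyhedral cells separated by ECM
        walls) or ``"ex_situ"`` (sparse, non-touching spheres).
    ecm_thickness:
        Wall thickness between neighbouring in situ cells, µm.
    attenuation_length:
        Exponential decay constant of signal intensity with imaging depth,
        µm; ``inf`` disables attenuation.
    noise_sd:
        Standard deviation of the additive Gaussian detector noise, in
        intensity units (rendered signals peak near 100).
    background:
        Constant background offset, intensity units.
    """

    name: str
    diameter_mean: float = 60.0
    diameter_cv: float = 0.3
    mixture: Optional[tuple[tuple[float, float, float], ...]] = None
    packing: str = "in_situ"
    ecm_thickness: float = 2.3
    attenuation_length: float = float("inf")
    noise_sd: float = 0.0
    background: float = 0.0

    def __post_init__(self):
        if self.packing not in PACKINGS:
            raise ValueError(f"packing must be one of {PACKINGS}")
        if self.mixture is not None:
            object.__setattr__(
                self, "mixture", tuple(tuple(map(float, c)) for c in self.mixture)
            )
            weights = [w for w, _, _ in self.mixture]
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
            if any(m <= 0 or cv <= 0 for _, m, cv in self.mixture):
                raise ValueError("mixture means and cvs must be positive")
        elif self.diameter_mean <= 0 or self.diameter_cv <= 0:
            raise ValueError("diameter_mean and diameter_cv must be positive")
        if self.ecm_thickness < 0 or self.noise_sd < 0 or self.background < 0:
            raise ValueError("ecm_thickness, noise_sd, background must be >= 0")
        if self.attenuation_length <= 0:
            raise ValueError("attenuation_length must be positive")

    @property
    def mean_diameter(self) -> float:
        """Arithmetic mean diameter of the (possibly mixture) distribution."""
        if self.mixture is not None:
            return float(sum(w * m for w, m, _ in self.mixture))
        return self.diameter_mean

    def with_(self, **changes) -> "TissuePreset":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class SampleSpec:
    """One sample of a cohort: which subject/depot/condition it comes from,
    which preset generates it, and the master seed of its random streams."""

    sample_id: str
    subject_id: str
    tissue: str
    condition: str
    preset: TissuePreset
    n_cells_target: int
    seed: int
    sex: str = "F"
    body_weight: float = 1000.0
    shape: Optional[tuple[int, int, int]] = None  # voxels; None = auto-size


@dataclass
class CohortDesign:
    """An ordered collection of samples with unique ids."""

    samples: list[SampleSpec] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_ids: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(µ, σ) of the lognormal with given arithmetic mean and CV:
    σ² = ln(1 + cv²), µ = ln(mean) − σ²/2."""
    sigma2 = np.log1p(cv * cv)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


# Built-in depot presets. Means are the published depot means; CVs are
# generator defaults (no dispersion is published for any depot). SCAT gets
# a thicker ECM than VAT, mirroring its denser matrix.
BUILTIN_PRESETS: dict[str, TissuePreset] = {
    p.name: p
    for p in [
        TissuePreset("trout_vat_in_situ", 81.32, 0.30, packing="in_situ",
                     ecm_thickness=2.3, attenuation_length=150.0,
                     noise_sd=4.0, background=2.0),
        TissuePreset("trout_scat_in_situ", 63.88, 0.35, packing="in_situ",
                     ecm_thickness=3.45, attenuation_length=150.0,
                     noise_sd=4.0, background=2.0),
        TissuePreset("trout_vat_ex_situ", 75.0, 0.30, packing="ex_situ",
                     noise_sd=4.0, background=2.0),
        TissuePreset("trout_scat_ex_situ", 50.0, 0.30, packing="ex_situ",
                     noise_sd=4.0, background=2.0),
        TissuePreset("mouse_swiss_scat", 100.0, 0.10, packing="in_situ",
                     ecm_thickness=2.3, attenuation_length=150.0),
        TissuePreset("mouse_c57bl6_scat", mixture=((0.5, 38.0, 0.10),
                                                   (0.5, 50.0, 0.10)),
                     packing="in_situ", ecm_thickness=2.3,
                     attenuation_length=150.0),
        # Clearing contrast: identical tissue, different attenuation length.
        TissuePreset("clearing_hdz", 81.32, 0.30, packing="in_situ",
                     attenuation_length=150.0),
        TissuePreset("clearing_pbs", 81.32, 0.30, packing="in_situ",
                     attenuation_length=60.0),
    ]
}


def get_preset(name: str, **overrides) -> TissuePreset:
    """Look up a built-in preset by name, optionally overriding fields."""
    try:
        preset = BUILTIN_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(BUILTIN_PRESETS)}"
        ) from None
    return preset.with_(**overrides) if overrides else preset
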