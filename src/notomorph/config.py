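"""Configuration types for the synthetic notochord/spine generator.

The defaults emulate a larval zebrafish notochord at the stages where
vacuolated-cell morphometry is informative: a tube several hundred µm long
and tens of µm in radius, filled with large ovoid vacuolated cells packed
in a staircase pattern, with a stereotyped anteroposterior (AP) volume
pattern in the wild type.  Mutant-like phenotypes (fragmented vacuoles,
randomized volumes, central spheroid nuclei) are obtained by switching the
relevant fields; :func:`wildtype_config` and :func:`mutant_config` bundle
the two reference parameter sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "VolumeProfile",
    "Fragmentation",
    "NucleiSpec",
    "ImagingSpec",
    "CentrumSpec",
    "KinkSpec",
    "SynthConfig",
    "wildtype_config",
    "mutant_config",
]


@dataclass
class VolumeProfile:
    """AP pattern of target vacuolated-cell volumes.

    ``stereotyped`` assigns each cell the pattern value at its AP position
    (a smooth sinusoid around ``baseline``); ``randomized`` shuffles the
    same set of values among cells, destroying the AP ordering while
    keeping the marginal distribution.
    """

    baseline: float = 27000.0   # µm³
    amplitude: float = 5000.0   # µm³
    period: float = 317.0       # µm (non-commensurate with the default cell
    #                             pitch, so sampled pattern values are distinct)
    mode: str = "stereotyped"

    def validate(self) -> None:
        if self.baseline <= 0 or self.period <= 0:
            raise ValueError("volume_profile baseline and period must be positive")
        if self.amplitude < 0 or self.amplitude >= self.baseline:
            raise ValueError("volume_profile amplitude must be in [0, baseline)")
        if self.mode not in ("stereotyped", "randomized"):
            raise ValueError(f"unknown volume_profile mode {self.mode!r}")

    def pattern(self, ap: float) -> float:
        """Target volume (µm³) at AP position ``ap`` (µm)."""
        return self.baseline + self.amplitude * math.sin(2 * math.pi * ap / self.period)


@dataclass
class Fragmentation:
    """Vacuole-fragmentation phenotype: a fraction of cells is replaced by
    several disjoint fragments that together retain only part of the parent
    volume."""

    fraction_of_cells: float = 0.0
    fragments_per_cell: int = 1
    volume_retention: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.fraction_of_cells <= 1.0:
            raise ValueError("fraction_of_cells must be in [0, 1]")
        if self.fragments_per_cell < 1:
            raise ValueError("fragments_per_cell must be >= 1")
        if not 0.0 < self.volume_retention <= 1.0:
            raise ValueError("volume_retention must be in (0, 1]")
        if self.fraction_of_cells == 0.0 and self.fragments_per_cell != 1:
            raise ValueError("fragments_per_cell must be 1 when fraction_of_cells is 0")


@dataclass
class NucleiSpec:
    """Nuclear phenotype: ``peripheral_disc`` places an oblate disc nucleus
    against the outer cell boundary (high internal pressure, wild-type-like);
    ``central_sphere`` places a sphere at the cell centroid (mutant-like)."""

    mode: str = "peripheral_disc"
    volume: float = 400.0  # µm³ (≈ 9 µm diameter sphere)

    def validate(self) -> None:
        if self.mode not in ("peripheral_disc", "central_sphere"):
            raise ValueError(f"unknown nuclei mode {self.mode!r}")
        if self.volume <= 0:
            raise ValueError("nuclear volume must be positive")


@dataclass
class ImagingSpec:
    """Simple imaging model: isotropic Gaussian blur (σ in µm) followed by
    additive Gaussian noise in intensity units."""

    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)  # (ap, dv, lr) µm
    blur_sigma: float = 0.0     # µm
    noise_sigma: float = 0.0    # intensity units

    def validate(self) -> None:
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive values (ap, dv, lr)")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur/noise sigma must be non-negative")


@dataclass
class CentrumSpec:
    """One vertebral centrum: an AP span with dorsal and ventral notochord
    indentations modelled as circular arcs.  ``math.inf`` for a radius means
    a flat side (no indentation)."""

    ap_start: float
    ap_end: float
    dorsal_radius: float = math.inf   # µm
    ventral_radius: float = math.inf  # µm
    mineralized: bool = True

    def validate(self) -> None:
        if not self.ap_start < self.ap_end:
            raise ValueError(f"centrum span [{self.ap_start}, {self.ap_end}] is empty")
        for r in (self.dorsal_radius, self.ventral_radius):
            if not (r > 0):
                raise ValueError("indentation radii must be positive or inf")

    @property
    def span(self) -> float:
        return self.ap_end - self.ap_start

    @property
    def center(self) -> float:
        return 0.5 * (self.ap_start + self.ap_end)


@dataclass
class KinkSpec:
    """A bend of the spine axis: interior angle in degrees (< 180; a straight
    axis is 180 and is not representable as a kink), at a given AP position,
    in either the dorsoventral or the left-right plane."""

    ap_position: float
    interior_angle: float
    plane: str = "dorsoventral"

    def validate(self) -> None:
        if not 0.0 < self.interior_angle < 180.0:
            raise ValueError("interior_angle must be in (0, 180) degrees")
        if self.plane not in ("dorsoventral", "leftright"):
            raise ValueError(f"unknown kink plane {self.plane!r}")


@dataclass
class SynthConfig:
    """Full specification of a synthetic notochord/spine specimen.

    Identical config + seed gives bit-identical outputs from every
    generator operation.
    """

    notochord_length: float = 800.0  # µm
    notochord_radius: float = 40.0   # µm
    n_cells: int = 40
    volume_profile: VolumeProfile = field(default_factory=VolumeProfile)
    fragmentation: Fragmentation = field(default_factory=Fragmentation)
    nuclei: NucleiSpec = field(default_factory=NucleiSpec)
    centra: list[CentrumSpec] = field(default_factory=list)
    kinks: list[KinkSpec] = field(default_factory=list)
    imaging: ImagingSpec = field(default_factory=ImagingSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.notochord_length <= 0 or self.notochord_radius <= 0:
            raise ValueError("notochord length and radius must be positive")
        self.volume_profile.validate()
        self.fragmentation.validate()
        self.nuclei.validate()
        self.imaging.validate()
        prev_end = -math.inf
        for c in self.centra:
            c.validate()
            if c.ap_start < prev_end:
                raise ValueError("centra must be AP-ordered and non-overlapping")
            prev_end = c.ap_end
        for k in self.kinks:
            k.validate()
            if not 0.0 <= k.ap_position <= self.notochord_length:
                raise ValueError("kink ap_position outside the axis extent")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["imaging"]["spacing"] = list(self.imaging.spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "volume_profile" in d and isinstance(d["volume_profile"], dict):
            d["volume_profile"] = VolumeProfile(**d["volume_profile"])
        if "fragmentation" in d and isinstance(d["fragmentation"], dict):
            d["fragmentation"] = Fragmentation(**d["fragmentation"])
        if "nuclei" in d and isinstance(d["nuclei"], dict):
            d["nuclei"] = NucleiSpec(**d["nuclei"])
        if "imaging" in d and isinstance(d["imaging"], dict):
            im = dict(d["imaging"])
            im["spacing"] = tuple(im.get("spacing", (2.0, 1.0, 1.0)))
            d["imaging"] = ImagingSpec(**im)
        d["centra"] = [
            CentrumSpec(**c) if isinstance(c, dict) else c for c in d.get("centra", [])
        ]
        d["kinks"] = [
            KinkSpec(**k) if isinstance(k, dict) else k for k in d.get("kinks", [])
        ]
        cfg = cls(**d)
        cfg.validate()
        return cfg


def wildtype_config(seed: int = 0, **overrides) -> SynthConfig:
    """Reference wild-type-like parameter set: intact ovoid cells, a
    stereotyped AP volume pattern, peripheral disc nuclei."""
    cfg = SynthConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def mutant_config(seed: int = 0, **overrides) -> SynthConfig:
    """Reference vacuole-fragmentation-mutant-like parameter set: half of
    the cells fragmented with reduced retained volume, randomized AP volume
    pattern, central spheroid nuclei."""
    cfg = SynthConfig(
        volume_profile=VolumeProfile(mode="randomized"),
        fragmentation=Fragmentation(
            fraction_of_cells=0.5, fragments_per_cell=4, volume_retention=0.7
        ),
        nuclei=NucleiSpec(mode="central_sphere"),
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg
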