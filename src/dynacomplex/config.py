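"""Run configuration and physical constants.

Internal unit conventions (converters live at the boundary only):
distances in nm, times in ns (rates in 1/s), concentrations in mol/L,
temperatures in K, chemical shifts in ppm. Residue numbering is 1-based;
trajectory frames are 0-based with time = index * frame_interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

# CODATA physical constants (SI)
GAMMA_H = 267.52218708e6   # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -27.116e6        # 15N gyromagnetic ratio, rad s^-1 T^-1 (negative)
MU_0 = 1.25663706127e-6    # vacuum magnetic permeability, T m A^-1
HBAR = 1.054571817e-34     # reduced Planck constant, J s
KB = 1.380649e-23          # Boltzmann constant, J K^-1
R_GAS = 8.314462618        # gas constant, J mol^-1 K^-1
N_AVOGADRO = 6.02214076e23


@dataclass
class CorrectionFactors:
    """Linear photon-count corrections for burst transfer efficiencies.

    All factors default to the identity correction: no background, no
    crosstalk, no direct excitation, and unit detection/quantum-yield
    ratio (gamma).
    """

    background_donor: float = 0.0       # mean background counts per burst, donor channel
    background_acceptor: float = 0.0    # mean background counts per burst, acceptor channel
    crosstalk: float = 0.0              # donor leakage fraction into the acceptor channel
    direct_excitation: float = 0.0      # acceptor direct-excitation fraction
    gamma: float = 1.0                  # detection-efficiency x quantum-yield ratio

    def __post_init__(self) -> None:
        for name in ("background_donor", "background_acceptor", "crosstalk",
                     "direct_excitation", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"correction factor {name} must be >= 0")


@dataclass
class AnalysisConfig:
    """Experimental conditions shared across analysis stages."""

    temperature: float = 295.15        # K (22 C)
    spectrometer_mhz: float = 750.0    # 1H Larmor frequency, MHz
    forster_radius: float = 5.4        # nm
    ionic_strength: float = 0.165      # mol/L (total, including buffer contribution)
    random_seed: int = 0
    corrections: CorrectionFactors = field(default_factory=CorrectionFactors)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.forster_radius <= 0:
            raise ValueError("forster_radius must be > 0 nm")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


_CONFIG_KEYS = {
    "temperature": float,
    "spectrometer_mhz": float,
    "forster_radius": float,
    "ionic_strength": float,
    "random_seed": int,
}
_CORRECTION_KEYS = {
    "background_donor": float,
    "background_acceptor": float,
    "crosstalk": float,
    "direct_excitation": float,
    "gamma": float,
}


def load_config(path: str | Path, **overrides) -> AnalysisConfig:
    """Read a flat ``key = value`` text file into an :class:`AnalysisConfig`.

    Lines starting with ``#`` and blank lines are ignored. Keyword
    arguments override file values (CLI flags map onto these).
    """
    values: dict = {}
    corr: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key in _CONFIG_KEYS:
            values[key] = _CONFIG_KEYS[key](val)
        elif key in _CORRECTION_KEYS:
            corr[key] = _CORRECTION_KEYS[key](val)
        else:
            raise KeyError(f"unknown config key: {key}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    return AnalysisConfig(corrections=CorrectionFactors(**corr), **values)


def larmor_frequencies(spectrometer_mhz: float) -> tuple[float, float]:
    """Angular Larmor frequencies (|omega_H|, |omega_N|) in rad/s."""
    import math

    omega_h = 2.0 * math.pi * spectrometer_mhz * 1e6
    omega_n = omega_h * abs(GAMMA_N) / GAMMA_H
    return omega_h, omega_n
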