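"""NADH-coupled glycerol-kinase activity from 340-nm absorbance traces.

Glycerol kinase activity is followed by coupling ADP release to NADH
oxidation; NADH absorbs at 340 nm, so the reaction rate is the (negative)
slope of A340 versus time.  A background trace recorded before starting the
reaction is subtracted.  One unit (U) consumes 1 µmol NADH per minute;
specific activity is U per mg total protein in the cell-free extract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st


@dataclass(frozen=True)
class AssayConfig:
    """Constants of the spectrophotometric assay.

    extinction_coefficient: mM⁻¹·cm⁻¹ for NADH at 340 nm (6.22).
    path_length: cuvette path, cm.
    reaction_volume: total assay volume, mL.
    extract_volume: cell-free extract added, mL.
    protein_concentration: mg/mL protein in the extract (Bradford input).
    """

    extinction_coefficient: float = 6.22
    path_length: float = 1.0
    reaction_volume: float = 1.0
    extract_volume: float = 0.010
    protein_concentration: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "extinction_coefficient",
            "path_length",
            "reaction_volume",
            "extract_volume",
            "protein_concentration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AssayTrace:
    """A340 versus time (minutes) for one phase of one sample."""

    times: np.ndarray
    absorbance: np.ndarray
    phase: str = "REACTION"  # "BACKGROUND" or "REACTION"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape or self.times.ndim != 1:
            raise ValueError("times and absorbance must be 1-D and equal length")
        if len(self.times) < 2:
            raise ValueError("need at least 2 points per phase")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.phase not in ("BACKGROUND", "REACTION"):
            raise ValueError("phase must be BACKGROUND or REACTION")


def slope_abs_per_min(trace: AssayTrace) -> float:
    """Least-squares slope of absorbance vs time, in absorbance units/min.

    NADH consumption gives a negative slope; the sign is preserved.
    """
    if len(trace.times) < 2:
        raise ValueError("need at least 2 points")
    return float(_st.linregress(trace.times, trace.absorbance).slope)


def specific_activity(
    reaction_slope: float, background_slope: float, cfg: AssayConfig
) -> float:
    """Specific enzyme activity in U/mg from net A340 slope via Beer–Lambert.

    net rate (mM NADH/min in the cuvette) = |Δslope| / (ε · path);
    volumetric activity is numerically equal in U/mL of reaction mix
    (1 mM/min = 1 µmol/mL/min); specific activity scales this to the amount
    of extract protein in the cuvette.
    """
    if cfg.protein_concentration <= 0:
        raise ValueError("protein concentration must be positive")
    net_slope = reaction_slope - background_slope
    mm_per_min = abs(net_slope) / (cfg.extinction_coefficient * cfg.path_length)
    volumetric_u_per_ml = mm_per_min  # U per mL of reaction mixture
    mg_protein_per_ml_reaction = (
        cfg.extract_volume * cfg.protein_concentration / cfg.reaction_volume
    )
    return volumetric_u_per_ml / mg_protein_per_ml_reaction


def net_slope_is_expected_sign(reaction_slope: float, background_slope: float) -> bool:
    """True when net NADH consumption is in the expected (decreasing) direction."""
    return (reaction_slope - background_slope) <= 0
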