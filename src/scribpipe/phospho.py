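"""Label-free phosphorylation-site occupancy calculus.

The fraction of a protein phosphorylated at one site cannot be read off a
single label-free LC-MS run: ion intensity confounds concentration with a
peptide-specific ionization efficiency and with run-to-run spray
variation. Both nuisances cancel if each peptide of interest is ratioed
against an *unmodified co-eluting peptide of the same protein*: the pair
shares spray conditions (co-elution) and the efficiencies are constant
sequence properties, so they divide out when the same ratio is compared
between two conditions.

Writing ``mod`` and ``base`` for the phosphorylated and unmodified forms
of the site-bearing peptide, with normalizers 3 and 2 respectively:

    X = (I1_t / I3_t) / (I1_c / I3_c)        # fold change of mod
    Y = (I0_t / I2_t) / (I0_c / I2_c)        # fold change of base
    a / b = X / Y                            # occupancy-odds ratio t vs c

where ``a = mod_t / base_t`` and ``b = mod_c / base_c`` are the occupancy
*odds* (not fractions) in treatment and control. The identity ``a/b = X/Y``
holds exactly for odds; :func:`odds_to_fraction` converts when a fraction
is wanted.

The module also carries the targeted-MS (SRM) support used to verify prey
recovery: a monoisotopic peptide/precursor m/z calculator and trapezoidal
integration of fragment-ion chromatographic traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PhosphoIntensityQuartet",
    "OccupancyRatio",
    "SRMTrace",
    "ratio_X",
    "ratio_Y",
    "occupancy_ratio",
    "occupancy_from_quartets",
    "phase_series",
    "odds_to_fraction",
    "peptide_mz",
    "integrate_trace",
    "PROTON_MASS",
    "WATER_MASS",
    "PHOSPHO_MASS",
]


@dataclass(frozen=True)
class PhosphoIntensityQuartet:
    """The four ion intensities of one condition (cell-cycle phase) in one run.

    I0: unmodified (base) peptide; I1: phosphopeptide (mod); I2: normalizer
    co-eluting with base; I3: normalizer co-eluting with mod.
    """

    I0: float
    I1: float
    I2: float
    I3: float
    condition: str = ""

    def __post_init__(self) -> None:
        for name in ("I0", "I1", "I2", "I3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class OccupancyRatio:
    """X, Y and the occupancy-odds ratio a/b = X/Y for one condition pair."""

    X: float
    Y: float

    @property
    def a_over_b(self) -> float:
        return self.X / self.Y


def _require_positive(value: float, name: str) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be > 0 for ratio computation")


def ratio_X(t: PhosphoIntensityQuartet, c: PhosphoIntensityQuartet) -> float:
    """Normalized fold change of the phosphopeptide, treatment over control."""
    _require_positive(t.I3, "I3 (treatment)")
    _require_positive(c.I3, "I3 (control)")
    _require_positive(c.I1, "I1 (control)")
    return (t.I1 / t.I3) / (c.I1 / c.I3)


def ratio_Y(t: PhosphoIntensityQuartet, c: PhosphoIntensityQuartet) -> float:
    """Normalized fold change of the unmodified peptide, treatment over control."""
    _require_positive(t.I2, "I2 (treatment)")
    _require_positive(c.I2, "I2 (control)")
    _require_positive(c.I0, "I0 (control)")
    return (t.I0 / t.I2) / (c.I0 / c.I2)


def occupancy_ratio(X: float, Y: float) -> float:
    """Occupancy-odds ratio a/b = X/Y (a = mod_t/base_t, b = mod_c/base_c)."""
    if X <= 0 or Y <= 0:
        raise ValueError("X and Y must be > 0")
    return X / Y


def occupancy_from_quartets(
    t: PhosphoIntensityQuartet, c: PhosphoIntensityQuartet
) -> OccupancyRatio:
    return OccupancyRatio(X=ratio_X(t, c), Y=ratio_Y(t, c))


def odds_to_fraction(odds: float) -> float:
    """Convert mod/base odds to fractional occupancy mod/(mod+base)."""
    if odds < 0:
        raise ValueError("odds must be non-negative")
    return odds / (1.0 + odds)


def phase_series(
    quartets: Mapping[str, Sequence[PhosphoIntensityQuartet]],
    baseline: str,
) -> dict[str, tuple[float, float]]:
    """Per-phase occupancy-odds ratio relative to a baseline phase.

    ``quartets`` maps phase name to replicate quartets. Replicates are
    paired positionally with the baseline replicates; the ratio is computed
    per replicate pair and then aggregated. Returns phase -> (mean, sd)
    with the baseline at exactly (1.0, 0.0).
    """
    if baseline not in quartets:
        raise ValueError(f"baseline phase {baseline!r} missing")
    base_reps = list(quartets[baseline])
    out: dict[str, tuple[float, float]] = {}
    for phase, reps in quartets.items():
        if phase == baseline:
            out[phase] = (1.0, 0.0)
            continue
        reps = list(reps)
        n = min(len(reps), len(base_reps))
        if n == 0:
            raise ValueError(f"phase {phase!r} has no replicates")
        ratios = [
            occupancy_from_quartets(reps[i], base_reps[i]).a_over_b for i in range(n)
        ]
        mean = float(np.mean(ratios))
        sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
        out[phase] = (mean, sd)
    return out


# ---------------------------------------------------------------------------
# SRM support

PROTON_MASS = 1.00728  # Da
WATER_MASS = 18.01056  # Da, added once per peptide chain
PHOSPHO_MASS = 79.96633  # Da, HPO3 per phosphosite

# monoisotopic residue masses, Da
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

_PHOSPHO_RESIDUES = frozenset("STY")


def peptide_mz(
    sequence: str, charge: int, phospho_positions: Sequence[int] = ()
) -> float:
    """Monoisotopic m/z of a peptide ion.

    ``(sum of residue masses + water + n_phospho * 79.96633
    + charge * proton) / charge``. ``phospho_positions`` are 1-based
    residue indices and must point at S, T or Y.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    mass = WATER_MASS
    for res in seq:
        try:
            mass += RESIDUE_MASS[res]
        except KeyError:
            raise ValueError(f"unknown residue {res!r} in {sequence!r}") from None
    for pos in phospho_positions:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"phospho position {pos} outside 1..{len(seq)}")
        if seq[pos - 1] not in _PHOSPHO_RESIDUES:
            raise ValueError(
                f"position {pos} is {seq[pos - 1]!r}, not a phosphorylatable residue"
            )
        mass += PHOSPHO_MASS
    return (mass + charge * PROTON_MASS) / charge


@dataclass
class SRMTrace:
    """A fragment-ion chromatogram: retention times and intensities."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be matching 1-D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


def integrate_trace(
    trace: SRMTrace, window: tuple[float, float] | None = None
) -> float:
    """Trapezoidal integral of ion intensity over a retention window.

    The window defaults to the full trace. A single in-window point has
    zero width and integrates to 0.
    """
    t, y = trace.times, trace.intensities
    if window is not None:
        lo, hi = window
        if lo >= hi:
            raise ValueError("window must have positive width")
        mask = (t >= lo) & (t <= hi)
        t, y = t[mask], y[mask]
    if t.size == 0:
        raise ValueError("no points in integration window")
    if t.size == 1:
        return 0.0
    return float(np.trapezoid(y, t))
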