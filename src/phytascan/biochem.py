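"""Biochemical calculations for inositol phosphates and phytases.

Inositol phosphates (InsPs) are myo-inositol rings carrying one phosphate
per esterified ring position; phytate (InsP6) is the fully phosphorylated
species. This module models species composition (C6H12O6 plus one HPO3 per
phosphate), negative-mode ESI monoisotopic m/z, the stepwise
dephosphorylation pathways of the four phytase classes, Michaelis–Menten
kinetics with Lineweaver–Burk fitting and kcat conversion, qPCR Cp-ratio
gene abundance, and phytate degradation rates from time series.

Pathway contracts: β-propeller phytases (alkaline, BPP) stop at
Ins(2,4,6)P3 (3 phosphates released from phytate); the acid phytases
(HAP, CP, PAP) proceed to Ins(2)P (5 released). The intermediate removal
order varies across enzymes and is configurable; only the initiating-site
class and the terminal product are fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "InsPSpecies",
    "KineticsFit",
    "insp_monoisotopic_mz",
    "simulate_dephosphorylation",
    "mm_rate",
    "fit_lineweaver_burk",
    "fit_michaelis_menten",
    "kcat_from_vmax",
    "qpcr_gene_abundance",
    "phytate_degradation_rate",
]

#: Monoisotopic atomic masses (u).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "O": 15.9949146221,
    "P": 30.97376151,
}
PROTON_MASS = 1.00727646688

_RING_POSITIONS = frozenset(range(1, 7))


@dataclass(frozen=True)
class InsPSpecies:
    """An inositol phosphate defined by its phosphorylated ring positions."""

    phospho_positions: frozenset[int]

    def __post_init__(self) -> None:
        positions = frozenset(int(p) for p in self.phospho_positions)
        if not positions <= _RING_POSITIONS:
            raise ValueError(f"ring positions must be within 1..6, got {sorted(positions)}")
        object.__setattr__(self, "phospho_positions", positions)

    @classmethod
    def from_positions(cls, positions) -> "InsPSpecies":
        return cls(frozenset(positions))

    @classmethod
    def insp6(cls) -> "InsPSpecies":
        return cls(_RING_POSITIONS)

    @classmethod
    def from_name(cls, name: str) -> "InsPSpecies":
        """Parse canonical names: ``InsP6``, ``Ins(2,4,6)P3``, ``Ins(2)P``."""
        name = name.strip()
        if name in ("InsP6", "IP6", "phytate"):
            return cls.insp6()
        if name in ("myo-inositol", "Ins"):
            return cls(frozenset())
        import re

        m = re.fullmatch(r"Ins\(([\d,\s]+)\)P(\d?)", name)
        if not m:
            raise ValueError(f"unrecognized inositol phosphate name {name!r}")
        positions = frozenset(int(p) for p in m.group(1).split(","))
        if m.group(2) and int(m.group(2)) != len(positions):
            raise ValueError(f"{name!r}: phosphate count does not match positions")
        return cls(positions)

    @property
    def n_phosphates(self) -> int:
        return len(self.phospho_positions)

    @property
    def name(self) -> str:
        n = self.n_phosphates
        if n == 0:
            return "myo-inositol"
        if n == 6:
            return "InsP6"
        pos = ",".join(str(p) for p in sorted(self.phospho_positions))
        suffix = f"P{n}" if n > 1 else "P"
        return f"Ins({pos}){suffix}"

    @property
    def formula(self) -> dict[str, int]:
        """Element counts: C6H12O6 plus one HPO3 per phosphate."""
        n = self.n_phosphates
        return {"C": 6, "H": 12 + n, "O": 6 + 3 * n, "P": n}

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * k for el, k in self.formula.items())


def insp_monoisotopic_mz(species: InsPSpecies, charge: int) -> float:
    """Negative-mode ESI m/z of [M − |z|H]^(z−).

    ``charge`` is a negative integer in {−1, −2, −3}; deprotonation removes
    one proton mass per charge.
    """
    if charge == 0:
        raise ValueError("charge must be non-zero")
    z = abs(int(charge))
    if z not in (1, 2, 3):
        raise ValueError("supported charge states: -1, -2, -3")
    return (species.monoisotopic_mass - z * PROTON_MASS) / z


#: Default stepwise phosphate-removal orders per enzyme class. BPP is a
#: 3-phytase removing alternating positions down to Ins(2,4,6)P3; the acid
#: classes continue to Ins(2)P (the axial 2-phosphate resists phytases).
DEFAULT_REMOVAL_ORDER: dict[str, tuple[int, ...]] = {
    "BPP": (3, 1, 5),
    "HAP": (3, 4, 5, 6, 1),
    "CP": (5, 4, 6, 3, 1),
    "PAP": (5, 6, 4, 3, 1),
}

TERMINAL_POSITIONS: dict[str, frozenset[int]] = {
    "BPP": frozenset({2, 4, 6}),
    "HAP": frozenset({2}),
    "CP": frozenset({2}),
    "PAP": frozenset({2}),
}

_CLASS_ALIASES = {"AP": "HAP", "ACID": "HAP", "ALKALINE": "BPP"}


def simulate_dephosphorylation(
    enzyme_class: str,
    start: InsPSpecies | None = None,
    removal_order: Sequence[int] | None = None,
) -> tuple[list[InsPSpecies], int]:
    """Stepwise dephosphorylation of an InsP species by a phytase class.

    Returns the ordered product list and the number of phosphates released.
    A substrate already at (or below) the class's terminal state yields an
    empty product list. Phosphate balance always holds:
    released + phosphates(terminal) == phosphates(start).
    """
    key = _CLASS_ALIASES.get(enzyme_class.upper(), enzyme_class.upper())
    if key not in DEFAULT_REMOVAL_ORDER:
        raise ValueError(f"unknown enzyme class {enzyme_class!r}")
    if start is None:
        start = InsPSpecies.insp6()
    if start.n_phosphates == 0:
        raise ValueError("substrate carries no phosphate")
    order = tuple(removal_order) if removal_order is not None else DEFAULT_REMOVAL_ORDER[key]
    terminal = TERMINAL_POSITIONS[key]
    remaining = set(start.phospho_positions)
    products: list[InsPSpecies] = []
    for pos in order:
        if remaining <= terminal:
            break
        if pos not in remaining or pos in terminal:
            continue
        remaining.discard(pos)
        products.append(InsPSpecies(frozenset(remaining)))
    return products, start.n_phosphates - len(remaining)


@dataclass
class KineticsFit:
    """Michaelis–Menten parameters with fit diagnostics."""

    km: float  # mM
    vmax: float  # µmol·min⁻¹·mg⁻¹
    kcat: float | None = None  # s⁻¹ (requires molecular mass)
    mw: float | None = None  # Da
    r_squared: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    method: str = "lineweaver-burk"


def mm_rate(s, km: float, vmax: float):
    """Michaelis–Menten rate v = Vmax·S / (Km + S)."""
    if km <= 0 or vmax <= 0:
        raise ValueError("Km and Vmax must be positive")
    s = np.asarray(s, dtype=float)
    if (s < 0).any():
        raise ValueError("substrate concentrations must be non-negative")
    v = vmax * s / (km + s)
    return float(v) if v.ndim == 0 else v


def fit_lineweaver_burk(
    s: Sequence[float],
    v: Sequence[float],
    mw: float | None = None,
) -> KineticsFit:
    """Double-reciprocal (Lineweaver–Burk) fit of Michaelis–Menten data.

    Ordinary least squares of 1/v on 1/S: Km = slope/intercept,
    Vmax = 1/intercept. The reciprocal transform weights low-rate points
    heavily; :func:`fit_michaelis_menten` offers the direct nonlinear fit.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if s.shape != v.shape:
        raise ValueError("S and v differ in length")
    if s.size < 3:
        raise ValueError("need at least 3 data points")
    if (s <= 0).any():
        raise ValueError("substrate concentrations must be positive")
    if (v <= 0).any():
        raise ValueError("rates must be positive (reciprocal undefined)")
    x, y = 1.0 / s, 1.0 / v
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if intercept <= 0:
        warnings.warn(
            "Lineweaver-Burk intercept is non-positive; Km/Vmax unreliable "
            "(consider the nonlinear fit)",
            stacklevel=2,
        )
    vmax = 1.0 / intercept if intercept != 0 else float("inf")
    km = slope / intercept if intercept != 0 else float("nan")
    residuals = y - (slope * x + intercept)
    result = KineticsFit(
        km=km,
        vmax=vmax,
        mw=mw,
        r_squared=float(fit.rvalue**2),
        residuals=residuals,
        method="lineweaver-burk",
    )
    if mw is not None and vmax > 0:
        result.kcat = kcat_from_vmax(vmax, mw)
    return result


def fit_michaelis_menten(
    s: Sequence[float],
    v: Sequence[float],
    mw: float | None = None,
) -> KineticsFit:
    """Direct nonlinear least-squares Michaelis–Menten fit (labelled method)."""
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 data points")
    p0 = (float(np.median(s)), float(v.max()) or 1.0)
    (km, vmax), _ = optimize.curve_fit(
        lambda ss, km_, vmax_: vmax_ * ss / (km_ + ss), s, v, p0=p0, maxfev=20000
    )
    residuals = v - vmax * s / (km + s)
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - float((residuals**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    result = KineticsFit(
        km=float(km), vmax=float(vmax), mw=mw, r_squared=r2,
        residuals=residuals, method="nonlinear",
    )
    if mw is not None and vmax > 0:
        result.kcat = kcat_from_vmax(float(vmax), mw)
    return result


def kcat_from_vmax(vmax: float, mw: float) -> float:
    """Turnover number kcat (s⁻¹) = Vmax (µmol·min⁻¹·mg⁻¹) × Mw (Da) / 60000.

    µmol·min⁻¹·mg⁻¹ × g·mol⁻¹ = 10⁻³ mol·min⁻¹·mol⁻¹ → divide by 60 s·min⁻¹
    and 10³, i.e. by 60000, for s⁻¹ per enzyme (per total protein).
    """
    if vmax <= 0 or mw <= 0:
        raise ValueError("Vmax and Mw must be positive")
    return vmax * mw / 60000.0


def qpcr_gene_abundance(cp_ref: float, cp_target: float) -> float:
    """Relative gene abundance as the Cp-cycle ratio Cp_ref / Cp_target."""
    if cp_ref <= 0 or cp_target <= 0:
        raise ValueError("Cp values must be positive")
    return cp_ref / cp_target


def phytate_degradation_rate(
    timeseries: Sequence[tuple[float, float]] | Mapping[float, float],
    sample_mass: float,
    control: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Phytate degradation rate in µM·day⁻¹·g⁻¹ from a concentration series.

    The rate is the negated least-squares slope of concentration (µM) versus
    time (days), optionally blank-corrected by subtracting the slope of a
    no-biomass control series, divided by sample mass (g). Negative computed
    rates are clipped to 0 with a warning.
    """
    if sample_mass <= 0:
        raise ValueError("sample mass must be positive")
    pairs = list(timeseries.items()) if isinstance(timeseries, Mapping) else list(timeseries)
    if len(pairs) < 2:
        raise ValueError("need at least 2 timepoints")
    days = np.array([p[0] for p in pairs], dtype=float)
    conc = np.array([p[1] for p in pairs], dtype=float)
    slope = float(np.polyfit(days, conc, 1)[0])
    if control is not None:
        cd = np.array([p[0] for p in control], dtype=float)
        cc = np.array([p[1] for p in control], dtype=float)
        slope -= float(np.polyfit(cd, cc, 1)[0])
    rate = -slope / sample_mass
    if rate < 0:
        if rate < -1e-9:  # numerically-flat series are silently zero
            warnings.warn(
                "computed degradation rate is negative; clipping to 0", stacklevel=2
            )
        rate = 0.0
    return rate
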