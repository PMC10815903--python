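"""Quench-flow product-accumulation analysis.

Rapid chemical-quench experiments stop the polymerase reaction at defined
times; the fraction of extended primer (quantified upstream by gel
densitometry) accumulates as a single exponential under single-turnover
conditions,

    P(t) = A * (1 - exp(-kobs * t)).

Titrating the varied species (the nucleotide, or the enzyme when the
nucleotide is fixed) and plotting kobs against concentration gives the
hyperbolic saturation curve

    kobs(c) = kpol * c / (Kd + c),

from which the maximal single-turnover incorporation rate ``kpol`` and the
ground-state dissociation constant ``Kd`` follow.  The equivalent
association-constant parameterisation kobs = K·kpol·c/(K·c + 1) with
K = 1/Kd is exposed for round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ProductTimeCourse",
    "KobsPoint",
    "HyperbolaFit",
    "fit_product_exponential",
    "fit_kobs_hyperbola",
]


@dataclass
class ProductTimeCourse:
    """Fraction of extended primer over time at one titrant concentration."""

    times: np.ndarray  # s
    product_fraction: np.ndarray  # dimensionless in [0, 1]
    conc_titrant: float  # µM (dNTP or enzyme, whichever is varied)
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.product_fraction = np.asarray(self.product_fraction, dtype=float)
        if self.times.shape != self.product_fraction.shape:
            raise ValueError("times and product_fraction must match in length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.product_fraction < -1e-9) or np.any(self.product_fraction > 1 + 1e-9):
            raise ValueError("product fractions must lie in [0, 1]")
        if self.conc_titrant < 0:
            raise ValueError("conc_titrant must be >= 0")


@dataclass
class KobsPoint:
    conc: float  # µM
    kobs: float  # s⁻¹
    kobs_stderr: float  # s⁻¹
    amplitude: float = np.nan


@dataclass
class HyperbolaFit:
    Kd: float  # µM
    kpol: float  # s⁻¹
    Kd_stderr: float
    kpol_stderr: float
    rss: float
    flags: list[str] = field(default_factory=list)

    @property
    def K_association(self) -> float:
        """The association-constant form of the saturation parameter (µM⁻¹)."""
        return 1.0 / self.Kd

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.kpol * conc / (self.Kd + conc)


def fit_product_exponential(tc: ProductTimeCourse) -> KobsPoint:
    """Fit P(t) = A·(1 − exp(−kobs·t)) to one product time course."""
    if tc.times.size < 4:
        raise ValueError("need at least 4 time points to fit an exponential rise")
    t, p = tc.times, tc.product_fraction
    if p.max() <= 0:
        raise ValueError(
            "product signal is zero everywhere; no accumulation to fit "
            f"(label={tc.label!r})"
        )
    slope = np.polyfit(t, p, 1)[0]
    if slope <= 0:
        raise ValueError(
            "product signal does not increase with time; expected an "
            f"exponential rise (label={tc.label!r})"
        )

    a_guess = float(p.max())
    half = 0.5 * a_guess
    above = np.nonzero(p >= half)[0]
    t_half = t[above[0]] if above.size else t[len(t) // 2]
    k_guess = np.log(2.0) / max(t_half, 1e-9)

    def model(tt, a, k):
        return a * (1.0 - np.exp(-k * tt))

    popt, pcov = curve_fit(
        model,
        t,
        p,
        p0=(a_guess, k_guess),
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=10000,
    )
    a, k = popt
    k_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return KobsPoint(conc=tc.conc_titrant, kobs=float(k), kobs_stderr=k_se, amplitude=float(a))


def fit_kobs_hyperbola(points: list[KobsPoint], *, weighted: bool = False) -> HyperbolaFit:
    """Fit the hyperbolic concentration dependence kobs = kpol·c/(Kd + c).

    Requires at least 3 concentrations spanning a ≥3-fold range.  Flags are
    attached when the design cannot constrain Kd: ``kd_lower_bound_only``
    when only the linear (sub-Kd) regime was sampled, ``kd_unidentifiable``
    when every concentration saturates the enzyme.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 concentrations")
    c = np.array([p.conc for p in points], dtype=float)
    k = np.array([p.kobs for p in points], dtype=float)
    if c.max() < 3.0 * c.min():
        raise ValueError("concentrations must span at least a 3-fold range")
    sigma = None
    if weighted:
        se = np.array([p.kobs_stderr for p in points], dtype=float)
        if np.all(np.isfinite(se)) and np.all(se > 0):
            sigma = se

    def model(cc, kpol, kd):
        return kpol * cc / (kd + cc)

    popt, pcov = curve_fit(
        model,
        c,
        k,
        p0=(1.2 * k.max(), float(np.median(c))),
        sigma=sigma,
        absolute_sigma=sigma is not None,
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    kpol, kd = popt
    rss = float(np.sum((k - model(c, *popt)) ** 2))
    flags: list[str] = []
    if kd > 5.0 * c.max():
        flags.append("kd_lower_bound_only")
    if kd < 0.2 * c.min():
        flags.append("kd_unidentifiable")
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    return HyperbolaFit(
        Kd=float(kd),
        kpol=float(kpol),
        Kd_stderr=float(se[1]),
        kpol_stderr=float(se[0]),
        rss=rss,
        flags=flags,
    )
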