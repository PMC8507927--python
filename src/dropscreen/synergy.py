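"""Median-effect dose-response fits and the Chou-Talalay combination index.

The median-effect model writes the fraction affected fa (= 1 - relative
viability) at dose D as

    fa / fu = (D / Dm)^m,        fu = 1 - fa,

which is linear after the double-log transform: log10(fa/fu) = m*log10(D)
- m*log10(Dm).  Dm is the dose giving fa = 0.5 (the IC50 under this model)
and m is the sigmoidicity slope.  For a two-drug combination observed at
(d1, d2) producing fa, the combination index is

    CI = d1 / Dx1(fa) + d2 / Dx2(fa),

where Dx_i(fa) = Dm_i * (fa/fu)^(1/m_i) is the single-agent dose of drug i
that alone would produce fa (the mutually exclusive, Loewe-type form).
CI < 1 indicates synergism, CI ~ 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .library import ParameterError

__all__ = [
    "FA_EPS",
    "DoseResponseCurve",
    "MedianEffectFit",
    "CombinationPoint",
    "fa_from_viability",
    "fit_median_effect",
    "dose_for_effect",
    "ic50",
    "combination_index",
    "classify_ci",
    "simulate_dose_response",
]

# fa is clamped into [FA_EPS, 1-FA_EPS] before any logit transform.
FA_EPS = 0.005

# Chou's qualitative CI bands.  Synergism bands are half-open [lower, upper),
# the additive band is closed [0.90, 1.10], antagonism bands are (lower, upper].
_SYNERGY_BANDS = [
    (0.10, "very strong synergism"),
    (0.30, "strong synergism"),
    (0.70, "synergism"),
    (0.85, "moderate synergism"),
    (0.90, "slight synergism"),
]
_ANTAGONISM_BANDS = [
    (1.20, "slight antagonism"),
    (1.45, "moderate antagonism"),
    (3.30, "antagonism"),
    (10.0, "strong antagonism"),
    (np.inf, "very strong antagonism"),
]


def _clamp_fa(fa):
    return np.clip(fa, FA_EPS, 1.0 - FA_EPS)


@dataclass
class DoseResponseCurve:
    """Single-agent dose series with fraction affected at each dose (nM)."""

    doses: np.ndarray
    fa: np.ndarray
    drug_label: str = ""

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        f = np.asarray(self.fa, dtype=float)
        if d.shape != f.shape:
            raise ParameterError("doses and fa must have the same length")
        if (d <= 0).any():
            raise ParameterError("doses must be strictly positive (drop zero-dose wells)")
        if (np.diff(d) <= 0).any():
            raise ParameterError("doses must be strictly increasing")
        f = _clamp_fa(f)
        self.doses, self.fa = d, f


@dataclass
class MedianEffectFit:
    """Fitted median-effect parameters for one drug."""

    m: float          # sigmoidicity slope (dimensionless; > 0 for an inhibitor)
    Dm: float         # dose producing fa = 0.5 (nM)
    r: float          # correlation coefficient of the linearized fit
    drug_label: str = ""
    warning: str | None = None

    def __post_init__(self):
        if self.Dm <= 0:
            raise ParameterError("Dm must be positive")


@dataclass
class CombinationPoint:
    """One combination dose pair with its observed effect and CI verdict."""

    dose_1: float
    dose_2: float
    fa_combo: float
    ci: float
    label: str


def fa_from_viability(treated_signal: float, control_signal: float) -> float:
    """Fraction affected from raw viability signals: fa = 1 - treated/control.

    Clamped into [eps, 1-eps] so downstream logit transforms stay finite.
    """
    if control_signal <= 0:
        raise ParameterError("control_signal must be positive")
    if treated_signal < 0:
        raise ParameterError("treated_signal must be nonnegative")
    return float(_clamp_fa(1.0 - treated_signal / control_signal))


def fit_median_effect(curve: DoseResponseCurve) -> MedianEffectFit:
    """Ordinary least squares of log10(fa/fu) on log10(D).

    Slope is m; Dm = 10^(-intercept/m).  A non-positive slope (effect
    decreasing with dose) is returned with a warning status rather than
    raised, since screening plates occasionally produce such curves.
    """
    if len(curve.doses) < 3:
        raise ParameterError("median-effect fit needs >= 3 dose points")
    x = np.log10(curve.doses)
    y = np.log10(curve.fa / (1.0 - curve.fa))
    res = stats.linregress(x, y)
    m, intercept = float(res.slope), float(res.intercept)
    r = float(res.rvalue)
    if np.isnan(r):  # constant y (flat curve)
        r = 0.0
    warning = None
    if m <= 0:
        warning = f"non-positive slope m={m:.4f}; fit unreliable for an inhibitor"
        Dm = 1.0  # placeholder; fit flagged
    else:
        Dm = float(10.0 ** (-intercept / m))
    return MedianEffectFit(m=m, Dm=Dm, r=r, drug_label=curve.drug_label,
                           warning=warning)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dx: dose producing fraction affected fa, Dx = Dm * (fa/fu)^(1/m)."""
    if not 0.0 < fa < 1.0:
        raise ParameterError("fa must be strictly inside (0, 1)")
    if fit.m <= 0:
        raise ParameterError("cannot invert a fit with non-positive slope")
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def ic50(fit: MedianEffectFit) -> float:
    """Half-maximal inhibitory concentration; equals Dm under this model."""
    return dose_for_effect(fit, 0.5)


def combination_index(
    fa_combo: float,
    dose_1: float,
    dose_2: float,
    fit_1: MedianEffectFit,
    fit_2: MedianEffectFit,
) -> float:
    """Chou-Talalay CI at one combination point (mutually exclusive form).

    CI = d1/Dx1(fa) + d2/Dx2(fa); a zero dose contributes nothing, so a
    single-agent point at its own equivalent dose gives CI = 1 exactly.
    """
    if not 0.0 < fa_combo < 1.0:
        raise ParameterError("fa_combo must be strictly inside (0, 1)")
    if dose_1 < 0 or dose_2 < 0:
        raise ParameterError("doses must be nonnegative")
    ci = 0.0
    if dose_1 > 0:
        ci += dose_1 / dose_for_effect(fit_1, fa_combo)
    if dose_2 > 0:
        ci += dose_2 / dose_for_effect(fit_2, fa_combo)
    if ci == 0.0:
        raise ParameterError("at least one dose must be positive")
    return float(ci)


def classify_ci(ci: float) -> str:
    """Qualitative synergy verdict for a CI value, per Chou's bands.

    Bands: <0.1 very strong synergism, [0.1,0.3) strong synergism,
    [0.3,0.7) synergism, [0.7,0.85) moderate synergism, [0.85,0.9) slight
    synergism, [0.9,1.1] nearly additive, then mirrored antagonism bands up
    to >10 very strong antagonism.
    """
    if ci <= 0:
        raise ParameterError("CI must be positive")
    if ci < 0.90:
        for upper, label in _SYNERGY_BANDS:
            if ci < upper:
                return label
    if ci <= 1.10:
        return "nearly additive"
    for upper, label in _ANTAGONISM_BANDS:
        if ci <= upper:
            return label
    return _ANTAGONISM_BANDS[-1][1]


def median_effect_fa(dose, m: float, Dm: float):
    """Forward model: fa(D) = 1 / (1 + (Dm/D)^m)."""
    dose = np.asarray(dose, dtype=float)
    return 1.0 / (1.0 + (Dm / dose) ** m)


def simulate_dose_response(
    m: float,
    Dm: float,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug_label: str = "",
) -> DoseResponseCurve:
    """Generate fa values from the median-effect model plus Gaussian noise."""
    if noise_sd < 0:
        raise ParameterError("noise_sd must be nonnegative")
    if m <= 0 or Dm <= 0:
        raise ParameterError("m and Dm must be positive")
    doses = np.asarray(doses, dtype=float)
    fa = median_effect_fa(doses, m, Dm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fa = fa + rng.normal(0.0, noise_sd, size=fa.shape)
    return DoseResponseCurve(doses=doses, fa=_clamp_fa(fa), drug_label=drug_label)
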