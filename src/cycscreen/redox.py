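"""Modified Massey-method redox potentiometry.

A heme protein is slowly reduced in the presence of a reference dye (DCPIP,
midpoint +217 mV, two-electron) while dual-wavelength absorbance traces are
recorded: the reduced-heme Soret maximum at 429 nm and the oxidized-dye band
at 610 nm.  Because both couples equilibrate with the same solution
potential E, the Nernst relations

    25 mV * ln(heme_red/heme_ox)  = E_m,heme - E
    12.5 mV * ln(dye_red/dye_ox)  = E_m,dye  - E

make the transformed points fall on a line of unit slope whose intercept is
the potential difference between the heme and the dye.  Points where either
reduced/oxidized ratio is above 10 or below 0.065 are excluded (the
endpoints of a titration carry no potential information), and the heme
midpoint is the dye midpoint plus the ordinary-least-squares intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TitrationTrace",
    "NernstConfig",
    "RatioSeries",
    "RedoxFit",
    "ReplicateSummary",
    "find_peak",
    "fractions_from_trace",
    "nernst_points",
    "fit_midpoint",
    "aggregate",
    "NoPeakError",
    "UnresolvedEndpointError",
    "InsufficientDataError",
]


class NoPeakError(ValueError):
    """The spectrum has no local maximum in the requested window."""


class UnresolvedEndpointError(ValueError):
    """Plateau difference at a monitored wavelength is below the noise floor."""


class InsufficientDataError(ValueError):
    """Fewer than two usable points remain after the exclusion window."""


@dataclass
class TitrationTrace:
    """Time x wavelength absorbance matrix from a reductive titration."""

    times: np.ndarray  # seconds, ascending
    wavelengths: np.ndarray  # nm
    absorbance: np.ndarray  # (ntime, nwavelength), AU

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.times.size, self.wavelengths.size):
            raise ValueError("absorbance shape must be (ntime, nwavelength)")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")

    def at_wavelength(self, nm: float, tol: float = 0.5) -> np.ndarray:
        i = int(np.argmin(np.abs(self.wavelengths - nm)))
        if abs(self.wavelengths[i] - nm) > tol:
            raise KeyError(f"trace has no wavelength within {tol} nm of {nm}")
        return self.absorbance[:, i]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.absorbance,
            columns=[f"A{w:g}" for w in self.wavelengths],
        )
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TitrationTrace":
        """Read a trace CSV: wide (time_s, A429, A610, ...) or long
        (time_s, wavelength_nm, absorbance)."""
        df = pd.read_csv(path)
        cols = set(df.columns)
        if {"time_s", "wavelength_nm", "absorbance"} <= cols:
            wide = df.pivot(index="time_s", columns="wavelength_nm", values="absorbance")
            return cls(
                times=wide.index.to_numpy(),
                wavelengths=wide.columns.to_numpy(dtype=float),
                absorbance=wide.to_numpy(),
            )
        if "time_s" not in cols:
            raise ValueError("trace CSV needs a time_s column")
        wl_cols = [c for c in df.columns if c != "time_s"]
        wavelengths = [float(c.lstrip("A")) for c in wl_cols]
        return cls(
            times=df["time_s"].to_numpy(),
            wavelengths=np.array(wavelengths),
            absorbance=df[wl_cols].to_numpy(),
        )


@dataclass(frozen=True)
class NernstConfig:
    """Wavelengths, Nernst slopes, reference potential and exclusion window.

    Slopes are fixed at 25 mV (one-electron heme) and 12.5 mV (two-electron
    dye) per natural-log unit, i.e. RT/nF at room temperature rounded the
    way the assay arithmetic uses them.  The asymmetric exclusion window
    (0.065 to 10) is applied to both reduced/oxidized ratios.
    """

    lambda_heme: float = 429.0
    lambda_dye: float = 610.0
    slope_1e: float = 25.0
    slope_2e: float = 12.5
    E_dye: float = 217.0
    ratio_hi: float = 10.0
    ratio_lo: float = 0.065
    endpoint_window: int = 5
    #: optional 2x2 linear unmixing matrix applied to the (heme, dye)
    #: absorbance columns before fraction estimation; None = no cross-talk
    #: correction (the two bands are treated as spectrally independent)
    crosstalk: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not (self.ratio_lo < 1.0 < self.ratio_hi):
            raise ValueError("need ratio_lo < 1 < ratio_hi")
        if self.slope_1e <= 0 or self.slope_2e <= 0:
            raise ValueError("Nernst slopes must be positive")
        if self.endpoint_window < 1:
            raise ValueError("endpoint_window must be >= 1")


@dataclass
class RatioSeries:
    times: np.ndarray
    r_heme: np.ndarray  # reduced/oxidized, NaN where undefined
    r_dye: np.ndarray
    included: np.ndarray  # bool mask


@dataclass
class RedoxFit:
    points: np.ndarray  # (n, 2): x = dye transform, y = heme transform (mV)
    slope: float
    intercept: float  # mV
    E_m: float  # mV
    n_points_used: int


@dataclass
class ReplicateSummary:
    replicate_E_m: np.ndarray
    mean: float
    sd: float  # sample SD (ddof=1)


def find_peak(
    wavelengths: np.ndarray, absorbance: np.ndarray, window: tuple[float, float]
) -> float:
    """Wavelength of the dominant local maximum inside ``window``.

    The spectrum is smoothed with a 3-point moving average first; among the
    local maxima in the window the highest wins, ties going to the lowest
    wavelength.  A spectrum that is monotone or flat in the window raises
    :class:`NoPeakError`.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    lo, hi = window
    sel = (wavelengths >= lo) & (wavelengths <= hi)
    if sel.sum() < 3:
        raise NoPeakError("need at least 3 points in the window")
    smooth = absorbance.copy()
    smooth[1:-1] = (absorbance[:-2] + absorbance[1:-1] + absorbance[2:]) / 3.0
    idx = np.where(sel)[0]
    candidates = []
    for i in idx:
        if i == 0 or i == wavelengths.size - 1:
            continue
        if smooth[i] > smooth[i - 1] and smooth[i] >= smooth[i + 1]:
            candidates.append(i)
    if not candidates:
        raise NoPeakError(f"no local maximum in {lo}-{hi} nm")
    best = max(candidates, key=lambda i: (smooth[i], -wavelengths[i]))
    return float(wavelengths[best])


def _plateaus(signal: np.ndarray, w: int) -> tuple[float, float, float]:
    first = signal[:w]
    last = signal[-w:]
    sd = max(float(np.std(first)), float(np.std(last)))
    return float(np.median(first)), float(np.median(last)), sd


def fractions_from_trace(trace: TitrationTrace, cfg: NernstConfig | None = None) -> RatioSeries:
    """Reduced/oxidized ratios of heme and dye along a titration.

    Endpoint (fully oxidized / fully reduced) absorbances are plateau
    medians over the first and last ``endpoint_window`` readings.  The heme
    signal at 429 nm rises on reduction; the dye signal at 610 nm falls
    (oxidized DCPIP is the absorbing species).  The inclusion mask keeps
    times where both ratios lie inside ``[ratio_lo, ratio_hi]``.
    """
    cfg = cfg or NernstConfig()
    a_heme = trace.at_wavelength(cfg.lambda_heme)
    a_dye = trace.at_wavelength(cfg.lambda_dye)
    if cfg.crosstalk is not None:
        inv = np.linalg.inv(np.asarray(cfg.crosstalk, dtype=float))
        unmixed = np.column_stack([a_heme, a_dye]) @ inv.T
        a_heme, a_dye = unmixed[:, 0], unmixed[:, 1]

    w = cfg.endpoint_window
    heme_ox, heme_red, sd_h = _plateaus(a_heme, w)
    dye_ox, dye_red, sd_d = _plateaus(a_dye, w)
    if abs(heme_red - heme_ox) <= 10.0 * sd_h:
        raise UnresolvedEndpointError("heme plateau difference below 10x endpoint SD")
    if abs(dye_ox - dye_red) <= 10.0 * sd_d:
        raise UnresolvedEndpointError("dye plateau difference below 10x endpoint SD")
    if dye_red >= dye_ox:
        raise UnresolvedEndpointError(
            "dye absorbance must decrease over the titration (oxidized DCPIP absorbs)"
        )

    f_heme = (a_heme - heme_ox) / (heme_red - heme_ox)  # fraction reduced
    f_dye = (dye_ox - a_dye) / (dye_ox - dye_red)  # fraction reduced
    with np.errstate(divide="ignore", invalid="ignore"):
        r_heme = f_heme / (1.0 - f_heme)
        r_dye = f_dye / (1.0 - f_dye)
    r_heme[~np.isfinite(r_heme) | (r_heme <= 0)] = np.nan
    r_dye[~np.isfinite(r_dye) | (r_dye <= 0)] = np.nan
    included = inclusion_mask(r_heme, cfg) & inclusion_mask(r_dye, cfg)
    return RatioSeries(times=trace.times, r_heme=r_heme, r_dye=r_dye, included=included)


def inclusion_mask(ratio: np.ndarray, cfg: NernstConfig | None = None) -> np.ndarray:
    """The exclusion-window rule: keep ratios in ``[ratio_lo, ratio_hi]``.

    The bounds are inclusive (exclusion is strictly greater than 10 /
    strictly less than 0.065); NaN ratios are excluded.  Note the window is
    deliberately asymmetric: 0.065 is not 1/10.
    """
    cfg = cfg or NernstConfig()
    ratio = np.asarray(ratio, dtype=float)
    with np.errstate(invalid="ignore"):
        return (ratio >= cfg.ratio_lo) & (ratio <= cfg.ratio_hi)


def nernst_points(ratios: RatioSeries, cfg: NernstConfig | None = None) -> np.ndarray:
    """Nernst-transformed (x, y) pairs in mV for the included times only."""
    cfg = cfg or NernstConfig()
    mask = ratios.included.astype(bool)
    if mask.sum() < 2:
        raise InsufficientDataError("fewer than 2 included points")
    y = cfg.slope_1e * np.log(ratios.r_heme[mask])
    x = cfg.slope_2e * np.log(ratios.r_dye[mask])
    return np.column_stack([x, y])


def fit_midpoint(points: np.ndarray, cfg: NernstConfig | None = None) -> RedoxFit:
    """OLS line through the Nernst points; E_m = E_dye + intercept.

    The slope is left free and reported for quality control: it is 1 when
    both couples obey their assigned electron counts.
    """
    cfg = cfg or NernstConfig()
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise InsufficientDataError("need at least 2 points to fit")
    x, y = points[:, 0], points[:, 1]
    if np.ptp(x) == 0.0:
        raise ValueError("singular fit: all x values identical")
    res = stats.linregress(x, y)
    return RedoxFit(
        points=points,
        slope=float(res.slope),
        intercept=float(res.intercept),
        E_m=float(cfg.E_dye + res.intercept),
        n_points_used=int(points.shape[0]),
    )


def analyze_trace(trace: TitrationTrace, cfg: NernstConfig | None = None) -> RedoxFit:
    """Convenience pipeline: fractions -> Nernst points -> line fit."""
    cfg = cfg or NernstConfig()
    return fit_midpoint(nernst_points(fractions_from_trace(trace, cfg), cfg), cfg)


def aggregate(fits: Sequence[RedoxFit]) -> ReplicateSummary:
    """Mean and sample standard deviation of per-replicate midpoints."""
    if len(fits) < 2:
        raise ValueError("need at least 2 replicates for a sample SD")
    ems = np.array([f.E_m for f in fits])
    return ReplicateSummary(replicate_E_m=ems, mean=float(ems.mean()), sd=float(ems.std(ddof=1)))
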