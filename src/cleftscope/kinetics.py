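"""Michaelis-Menten fitting and activity-profile post-processing.

Initial-rate data v(S) are fitted to v = Vmax*S/(KM + S) by nonlinear least
squares (Levenberg-Marquardt via scipy), initialised from the Hanes-Woolf
linearisation S/v = S/Vmax + KM/Vmax, which gives robust closed-form starting
values.  With replicates, each replicate is fitted separately and parameters
are reported as mean +/- SD across replicates, matching the usual
"average of three measurements +/- SD" reporting; otherwise SDs come from the
fit covariance.  kcat = Vmax / [E]; catalytic efficiency kcat/KM is reported
in M^-1 s^-1 (KM given in microM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """Raised when the Michaelis-Menten fit cannot converge."""


@dataclass
class RateDataset:
    """Initial rates at a series of substrate concentrations (one replicate)."""

    concentrations: np.ndarray  # microM
    rates: np.ndarray  # same units as Vmax (e.g. microM/s)
    enzyme_conc: float  # microM
    replicate: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("substrate concentrations must be positive")
        if len(np.unique(self.concentrations)) < 4:
            raise ValueError("need >= 4 distinct substrate concentrations")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.rates = self.rates[order]
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")


@dataclass
class KineticParams:
    """Fitted KM (microM), kcat (s^-1), their SDs, and kcat/KM (M^-1 s^-1)."""

    km: float
    km_sd: float
    kcat: float
    kcat_sd: float
    km_warning: bool = False

    @property
    def efficiency(self) -> float:
        return self.kcat / (self.km * 1e-6)


def michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def _hanes_woolf_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Closed-form (Vmax, KM) starting values from S/v = S/Vmax + KM/Vmax."""
    good = v > 0
    if good.sum() < 2:
        raise FitError("all rates non-positive; cannot initialise fit")
    slope, intercept = np.polyfit(s[good], s[good] / v[good], 1)
    if slope <= 0:
        # fall back to crude saturation guesses
        return float(v.max()), float(np.median(s))
    return 1.0 / slope, max(intercept / slope, 1e-6)


def _fit_single(s: np.ndarray, v: np.ndarray) -> tuple[float, float, np.ndarray]:
    vmax0, km0 = _hanes_woolf_init(s, v)
    try:
        popt, pcov = curve_fit(michaelis_menten, s, v, p0=[vmax0, km0], maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"fit did not converge (start Vmax={vmax0:.4g}, KM={km0:.4g})") from exc
    if popt[1] <= 0:
        raise FitError(f"fit returned non-positive KM={popt[1]:.4g} "
                       f"(start Vmax={vmax0:.4g}, KM={km0:.4g})")
    return float(popt[0]), float(popt[1]), pcov


def fit_michaelis_menten(
    data: RateDataset | list[RateDataset],
    enzyme_conc: float | None = None,
) -> KineticParams:
    """Fit v = Vmax*S/(KM + S) and convert to kcat, KM.

    With a list of >= 3 replicate datasets, each replicate is fitted
    separately and parameters are averaged (SD across replicates); otherwise
    a single pooled fit reports covariance-based SDs.  A fitted KM outside
    (0, 10*max S) sets ``km_warning``.
    """
    datasets = data if isinstance(data, list) else [data]
    if enzyme_conc is None:
        enzyme_conc = datasets[0].enzyme_conc

    if len(datasets) >= 3:
        kms, kcats = [], []
        for d in datasets:
            vmax, km, _ = _fit_single(d.concentrations, d.rates)
            kms.append(km)
            kcats.append(vmax / enzyme_conc)
        km, km_sd = float(np.mean(kms)), float(np.std(kms, ddof=1))
        kcat, kcat_sd = float(np.mean(kcats)), float(np.std(kcats, ddof=1))
        smax = max(d.concentrations.max() for d in datasets)
    else:
        s = np.concatenate([d.concentrations for d in datasets])
        v = np.concatenate([d.rates for d in datasets])
        vmax, km, pcov = _fit_single(s, v)
        perr = np.sqrt(np.diag(pcov))
        kcat, kcat_sd = vmax / enzyme_conc, float(perr[0]) / enzyme_conc
        km_sd = float(perr[1])
        smax = s.max()

    smin = min(d.concentrations.min() for d in datasets)
    # a KM far outside the sampled concentration window is unidentifiable:
    # either the curve never saturates (KM >> max S) or it is flat (KM ~ 0)
    warn = not (0.01 * smin < km < 10 * smax)
    if warn:
        warnings.warn(f"fitted KM={km:.4g} microM outside the identifiable window "
                      f"({0.01 * smin:.3g}, {10 * smax:.4g}): saturation poorly determined",
                      stacklevel=2)
    return KineticParams(km, km_sd, kcat, kcat_sd, km_warning=warn)


def fit_replicates(datasets: list[RateDataset]) -> list[KineticParams]:
    """Fit each replicate dataset independently (e.g. for a median summary)."""
    return [fit_michaelis_menten(d) for d in datasets]


def efficiency_ratio(a: KineticParams | float, b: KineticParams | float) -> tuple[float, int]:
    """Ratio of catalytic efficiencies, raw and rounded to nearest integer."""
    ea = a.efficiency if isinstance(a, KineticParams) else float(a)
    eb = b.efficiency if isinstance(b, KineticParams) else float(b)
    if eb == 0:
        raise ZeroDivisionError("second efficiency is zero")
    if ea <= 0 or eb <= 0:
        raise ValueError("efficiencies must be positive")
    r = ea / eb
    return r, int(round(r))


# ---------------------------------------------------------------------------
# Activity tables
# ---------------------------------------------------------------------------

@dataclass
class ActivityTable:
    """Specific activities with percentages relative to a reference substrate."""

    activities: dict[str, float]  # substrate -> nmol min^-1 mg^-1
    reference: str
    relative: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.reference not in self.activities:
            raise KeyError(f"reference substrate {self.reference!r} not in table")
        ref = self.activities[self.reference]
        if ref <= 0:
            raise ValueError("reference activity must be positive")
        self.relative = {s: round(100.0 * v / ref, 1) for s, v in self.activities.items()}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "substrate": list(self.activities),
            "specific_activity": list(self.activities.values()),
            "relative_activity_pct": [self.relative[s] for s in self.activities],
        })


def relative_activity(table: dict[str, float], reference: str) -> ActivityTable:
    """Relative activity (%) of each substrate versus the reference substrate."""
    return ActivityTable(dict(table), reference)


# ---------------------------------------------------------------------------
# Thermal inactivation
# ---------------------------------------------------------------------------

@dataclass
class InactivationProfile:
    """Residual-activity-vs-temperature profile normalised to its maximum."""

    temperatures: np.ndarray  # degrees C
    normalized: np.ndarray  # percent of maximum
    t50: float | None  # first downward crossing of 50%, linear interpolation

    @property
    def optimum(self) -> float:
        return float(self.temperatures[int(np.argmax(self.normalized))])


def inactivation_profile(data: dict[float, float] | pd.DataFrame) -> InactivationProfile:
    """Normalise residual activities (max -> 100%) and locate T50.

    T50 is the temperature of the first downward crossing of the 50% line,
    linearly interpolated between the bracketing points; absent (None) if the
    normalised curve never drops below 50%.
    """
    if isinstance(data, pd.DataFrame):
        temps = data.iloc[:, 0].to_numpy(dtype=float)
        acts = data.iloc[:, 1].to_numpy(dtype=float)
    else:
        temps = np.array(sorted(data), dtype=float)
        acts = np.array([data[t] for t in sorted(data)], dtype=float)
    if len(temps) < 2:
        raise ValueError("need >= 2 temperatures")
    order = np.argsort(temps)
    temps, acts = temps[order], acts[order]
    norm = 100.0 * acts / acts.max()

    t50 = None
    for i in range(1, len(temps)):
        if norm[i - 1] >= 50.0 > norm[i]:
            f = (norm[i - 1] - 50.0) / (norm[i - 1] - norm[i])
            t50 = float(temps[i - 1] + f * (temps[i] - temps[i - 1]))
            break
    return InactivationProfile(temps, norm, t50)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_rate_csv(path, enzyme_conc: float, replicate_col: str | None = None) -> list[RateDataset]:
    """Read substrate_uM/rate[/rep] columns into one dataset per replicate."""
    df = pd.read_csv(path)
    if replicate_col and replicate_col in df.columns:
        return [RateDataset(g["substrate_uM"].to_numpy(), g["rate"].to_numpy(),
                            enzyme_conc, replicate=int(r))
                for r, g in df.groupby(replicate_col)]
    return [RateDataset(df["substrate_uM"].to_numpy(), df["rate"].to_numpy(), enzyme_conc)]
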