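"""Molecular volumes, volume histograms and Gaussian-mixture peak fitting.

The molecular volume of an AFM grain is the spherical-segment estimate

    Vm = (pi * h / 6) * (3 r^2 + h^2)                          [nm^3]

with ``h`` the apex height and ``r`` the radius at half height.  Volume
histograms of receptor preparations typically show one peak per species —
e.g. a free-receptor peak and a complex peak — and are fitted with a sum
of one or two Gaussians by nonlinear least squares on the bin counts.  The
fitted components then yield the proportion of particles above a cut-off
volume (area under the curve) and peak-shift z-tests between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

from .errors import ContractError, DegenerateFitError, FitError


def particle_volume(h, r):
    """Molecular volume ``(pi*h/6)*(3 r**2 + h**2)`` in nm^3.

    Vectorised over ``h`` and ``r`` (nm).  Raises :class:`ContractError`
    on negative input; zero height or radius is allowed (volume 0 or the
    pure-segment limit).
    """
    h_arr = np.asarray(h, dtype=float)
    r_arr = np.asarray(r, dtype=float)
    if np.any(h_arr < 0) or np.any(r_arr < 0):
        raise ContractError("h and r must be non-negative")
    out = np.pi * h_arr / 6.0 * (3.0 * r_arr**2 + h_arr**2)
    return float(out) if out.ndim == 0 else out


def volumes_from_table(table: pd.DataFrame, include_flagged: bool = False) -> pd.Series:
    """Per-particle molecular volumes from a particle table.

    QC-flagged particles are skipped unless ``include_flagged``; the
    returned Series is indexed by the source table's row index so each
    volume stays traceable to its particle.
    """
    if table.empty:
        return pd.Series(dtype=float, name="volume_nm3")
    sel = table if include_flagged else table[table["flags"].fillna("") == ""]
    vols = particle_volume(sel["h_nm"].to_numpy(), sel["r_nm"].to_numpy())
    return pd.Series(vols, index=sel.index, name="volume_nm3")


@dataclass(frozen=True)
class VolumeHistogram:
    """Uniformly binned molecular volumes (half-open bins, last closed)."""

    bin_edges: np.ndarray  # length nbins + 1, nm^3
    counts: np.ndarray  # length nbins, ints
    n_total: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def build_histogram(
    volumes, bin_width: float = 50.0, range_: tuple[float, float] | None = None
) -> VolumeHistogram:
    """Bin volumes into uniform bins of the given width (nm^3).

    The default range runs from 0 to the maximum volume rounded up to a
    bin multiple, so every volume is counted.  Bins are half-open
    ``[lo, hi)`` with the final bin closed (numpy convention), so a value
    on an interior edge lands in the upper bin.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size == 0:
        raise ContractError("cannot build a histogram from an empty volume list")
    if not bin_width > 0:
        raise ContractError("bin_width must be positive")
    if range_ is None:
        hi = float(np.ceil(volumes.max() / bin_width)) * bin_width
        hi = max(hi, bin_width)
        range_ = (0.0, hi)
    lo, hi = range_
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(volumes, bins=edges)
    return VolumeHistogram(bin_edges=edges, counts=counts, n_total=int(counts.sum()))


@dataclass(frozen=True)
class GaussianComponent:
    amplitude: float  # peak bin count
    mean: float  # nm^3
    sigma: float  # nm^3

    def __call__(self, v):
        return self.amplitude * np.exp(-((v - self.mean) ** 2) / (2 * self.sigma**2))

    @property
    def area(self) -> float:
        """Area under the component curve (counts x nm^3)."""
        return self.amplitude * self.sigma * math.sqrt(2 * math.pi)


@dataclass(frozen=True)
class MixtureFit:
    """Result of fitting k Gaussian peaks to a volume histogram."""

    k: int
    components: tuple[GaussianComponent, ...]  # sorted by ascending mean
    mean_se: tuple[float, ...]  # standard error of each mean, nm^3
    r_squared: float
    converged: bool
    fit_range: tuple[float, float]
    n_total: int = 0
    bin_width: float = field(default=0.0, compare=False)

    def predict(self, v):
        v = np.asarray(v, dtype=float)
        return sum(c(v) for c in self.components)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "components": [
                {
                    "amplitude": c.amplitude,
                    "mean_nm3": c.mean,
                    "sigma_nm3": c.sigma,
                    "mean_se_nm3": se,
                }
                for c, se in zip(self.components, self.mean_se)
            ],
            "r_squared": self.r_squared,
            "converged": self.converged,
            "n_total": self.n_total,
        }


def _initial_guesses(hist: VolumeHistogram, k: int) -> list[tuple[float, float, float]]:
    """Peak guesses (amplitude, mean, sigma) from a lightly smoothed histogram."""
    smooth = gaussian_filter1d(hist.counts.astype(float), sigma=1.0)
    peaks, props = signal.find_peaks(smooth, height=0.0)
    order = np.argsort(props["peak_heights"])[::-1]
    centers = hist.centers
    guesses = [
        (float(hist.counts[p]), float(centers[p]), 3.0 * hist.bin_width)
        for p in peaks[order[:k]]
    ]
    if len(guesses) < k:
        # fall back to count-weighted quantiles to seed the missing peaks
        cum = np.cumsum(hist.counts) / max(hist.n_total, 1)
        for q in np.linspace(0.2, 0.8, k)[len(guesses):]:
            idx = int(np.searchsorted(cum, q))
            idx = min(idx, len(centers) - 1)
            guesses.append(
                (max(float(hist.counts[idx]), 1.0), float(centers[idx]),
                 3.0 * hist.bin_width)
            )
    return guesses[:k]


def fit_gaussian_mixture(
    hist: VolumeHistogram,
    k: int = 2,
    init: list[float] | None = None,
    *,
    max_restarts: int = 5,
) -> MixtureFit:
    """Least-squares fit of k Gaussian peaks to histogram bin counts.

    ``init`` optionally gives starting peak positions (means, nm^3).  The
    fit is unweighted on raw counts — a histogram-curve fit — and reports
    R^2 over bins plus the standard error of each mean from the fit
    covariance.  Components come back sorted by ascending mean.

    Raises
    ------
    ContractError
        Fewer than ``3*k`` non-empty bins.
    FitError
        No convergence after bounded randomized restarts.
    DegenerateFitError
        A fitted sigma collapsed below half the bin width.
    """
    if k not in (1, 2):
        raise ContractError("k must be 1 or 2")
    nonempty = int((hist.counts > 0).sum())
    if nonempty < 3 * k:
        raise ContractError(
            f"need at least {3 * k} non-empty bins to fit k={k}, got {nonempty}"
        )
    centers = hist.centers
    counts = hist.counts.astype(float)
    lo, hi = float(hist.bin_edges[0]), float(hist.bin_edges[-1])
    span = hi - lo

    guesses = _initial_guesses(hist, k)
    if init is not None:
        if len(init) != k:
            raise ContractError(f"init must give {k} peak positions")
        guesses = [
            (max(float(np.interp(m, centers, counts)), 1.0), float(m),
             3.0 * hist.bin_width)
            for m in init
        ]

    def model(v, *params):
        out = np.zeros_like(v)
        for i in range(k):
            amp, mu, sig = params[3 * i: 3 * i + 3]
            out = out + amp * np.exp(-((v - mu) ** 2) / (2 * sig**2))
        return out

    lower = [0.0, lo, hist.bin_width / 10.0] * k
    upper = [max(counts.max() * 10.0, 1.0), hi, span] * k
    rng = np.random.default_rng(20_240_417)
    last_exc: Exception | None = None
    for attempt in range(max_restarts + 1):
        p0 = []
        for amp, mu, sig in guesses:
            if attempt > 0:
                mu = float(np.clip(mu + rng.normal(0, span / 10), lo, hi))
                sig = float(np.clip(sig * rng.uniform(0.5, 2.0),
                                    hist.bin_width / 5, span))
            p0 += [min(max(amp, 1e-6), upper[0]), mu, max(sig, lower[2])]
        try:
            popt, pcov = optimize.curve_fit(
                model, centers, counts, p0=p0, bounds=(lower, upper), maxfev=20_000
            )
            break
        except (RuntimeError, optimize.OptimizeWarning, ValueError) as exc:
            last_exc = exc
    else:
        raise FitError(
            f"mixture fit did not converge after {max_restarts + 1} attempts",
            diagnostics={"k": k, "n_total": hist.n_total, "error": str(last_exc)},
        )

    comps = [
        GaussianComponent(float(popt[3 * i]), float(popt[3 * i + 1]),
                          abs(float(popt[3 * i + 2])))
        for i in range(k)
    ]
    cov = _sandwich_covariance(centers, popt, k)
    if cov is None:
        cov = pcov
    ses = [float(np.sqrt(cov[3 * i + 1, 3 * i + 1])) for i in range(k)]
    order = np.argsort([c.mean for c in comps])
    comps = [comps[i] for i in order]
    ses = [ses[i] for i in order]
    for c in comps:
        if c.sigma < hist.bin_width / 2.0:
            raise DegenerateFitError(
                f"fitted sigma {c.sigma:.3g} nm^3 collapsed below half the "
                f"bin width ({hist.bin_width / 2:.3g} nm^3)"
            )
    resid = counts - model(centers, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    converged = bool(np.all(np.isfinite(pcov)))
    return MixtureFit(
        k=k,
        components=tuple(comps),
        mean_se=tuple(ses),
        r_squared=r2,
        converged=converged,
        fit_range=(lo, hi),
        n_total=hist.n_total,
        bin_width=hist.bin_width,
    )


def _sandwich_covariance(centers: np.ndarray, popt, k: int) -> np.ndarray | None:
    """Heteroscedasticity-robust covariance of the unweighted LS estimate.

    Bin counts are Poisson, so their variance equals the fitted mean;
    the naive LS covariance assumes one common residual variance and
    understates peak-position uncertainty near tall bins.  The sandwich
    (J'J)^-1 J' V J (J'J)^-1 with V = diag(fitted counts) restores
    calibrated standard errors while keeping the unweighted point
    estimate.  Returns None when J'J is singular.
    """
    cols = []
    for i in range(k):
        amp, mu, sig = popt[3 * i: 3 * i + 3]
        e = np.exp(-((centers - mu) ** 2) / (2 * sig**2))
        cols += [e, amp * e * (centers - mu) / sig**2,
                 amp * e * (centers - mu) ** 2 / sig**3]
    jac = np.column_stack(cols)
    jtj = jac.T @ jac
    try:
        jtj_inv = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None
    fitted = np.zeros_like(centers)
    for i in range(k):
        amp, mu, sig = popt[3 * i: 3 * i + 3]
        fitted += amp * np.exp(-((centers - mu) ** 2) / (2 * sig**2))
    var = np.maximum(fitted, 0.0)
    return jtj_inv @ (jac.T * var) @ jac @ jtj_inv


def model_selection_advisory(hist: VolumeHistogram) -> dict:
    """Advisory k=1 vs k=2 comparison by R^2 and least-squares BIC.

    The choice of k remains the caller's; this mirrors picking "the best
    fit" by eye, made explicit.  BIC here is ``n*ln(SS_res/n) + p*ln(n)``
    over bins.
    """
    out = {}
    n = len(hist.counts)
    for k in (1, 2):
        try:
            fit = fit_gaussian_mixture(hist, k)
        except (ContractError, FitError) as exc:
            out[f"k={k}"] = {"error": str(exc)}
            continue
        resid = hist.counts - fit.predict(hist.centers)
        ss_res = max(float(np.sum(resid**2)), 1e-300)
        bic = n * math.log(ss_res / n) + 3 * k * math.log(n)
        out[f"k={k}"] = {"r_squared": fit.r_squared, "bic": bic}
    candidates = {k: v["bic"] for k, v in out.items() if "bic" in v}
    if candidates:
        out["preferred_by_bic"] = min(candidates, key=candidates.get)
    return out


@dataclass(frozen=True)
class ProportionResult:
    """Fraction of the distribution below/above a volume cut-off."""

    cutoff: float
    fraction_below: float
    fraction_above: float
    method: str  # "fit_area" or "raw_count"
    cutoff_outside_range: bool = False

    def to_dict(self) -> dict:
        return {
            "cutoff_nm3": self.cutoff,
            "fraction_below": self.fraction_below,
            "fraction_above": self.fraction_above,
            "method": self.method,
            "cutoff_outside_range": self.cutoff_outside_range,
        }


def component_proportions(
    fit: MixtureFit | None,
    cutoff: float,
    method: str = "fit_area",
    volumes=None,
) -> ProportionResult:
    """Split the volume distribution at a cut-off (e.g. 800 nm^3).

    ``fit_area`` integrates the fitted Gaussian components: the fraction
    above is  sum_i A_i sigma_i (1 - Phi((c - mu_i)/sigma_i)) over the
    total area  sum_i A_i sigma_i.  ``raw_count`` is the plain fraction of
    raw volumes above the cut-off.  A cut-off outside the fitted histogram
    range is flagged, not rejected.
    """
    if method == "fit_area":
        if fit is None:
            raise ContractError("fit_area needs a MixtureFit")
        if not fit.converged:
            raise ContractError("fit_area needs a converged fit")
        weights = np.array([c.area for c in fit.components])
        tails = np.array(
            [1.0 - norm.cdf((cutoff - c.mean) / c.sigma) for c in fit.components]
        )
        frac_above = float(np.sum(weights * tails) / np.sum(weights))
        outside = not (fit.fit_range[0] <= cutoff <= fit.fit_range[1])
    elif method == "raw_count":
        if volumes is None:
            raise ContractError("raw_count needs the raw volumes")
        v = np.asarray(volumes, dtype=float)
        if v.size == 0:
            raise ContractError("raw_count needs at least one volume")
        frac_above = float(np.mean(v > cutoff))
        outside = not (v.min() <= cutoff <= v.max())
    else:
        raise ContractError(f"unknown method {method!r}")
    return ProportionResult(
        cutoff=cutoff,
        fraction_below=1.0 - frac_above,
        fraction_above=frac_above,
        method=method,
        cutoff_outside_range=outside,
    )


def peak_z(mean_a: float, se_a: float, mean_b: float, se_b: float) -> tuple[float, float]:
    """z-statistic and two-sided normal p-value for a peak shift.

    ``z = (mean_a - mean_b) / sqrt(se_a^2 + se_b^2)``; with identical
    peaks z = 0 and p = 1.
    """
    denom = math.hypot(se_a, se_b)
    if denom == 0.0:
        z = 0.0 if mean_a == mean_b else math.inf
    else:
        z = (mean_a - mean_b) / denom
    p = 2.0 * (1.0 - norm.cdf(abs(z))) if math.isfinite(z) else 0.0
    return z, p


def compare_peaks(fit_a: MixtureFit, fit_b: MixtureFit) -> list[dict]:
    """Per-component peak-shift z-tests between two fits of equal k.

    Components are matched by rank (ascending mean).  Returns one dict per
    component with the two means, their SEs, z and the two-sided p-value.
    """
    if fit_a.k != fit_b.k:
        raise ContractError(f"component counts differ: {fit_a.k} vs {fit_b.k}")
    if not (fit_a.converged and fit_b.converged):
        raise ContractError("compare_peaks requires converged fits")
    results = []
    for i, (ca, cb) in enumerate(zip(fit_a.components, fit_b.components)):
        z, p = peak_z(ca.mean, fit_a.mean_se[i], cb.mean, fit_b.mean_se[i])
        results.append(
            {
                "component": i,
                "mean_a_nm3": ca.mean,
                "se_a_nm3": fit_a.mean_se[i],
                "mean_b_nm3": cb.mean,
                "se_b_nm3": fit_b.mean_se[i],
                "z": z,
                "p_value": p,
            }
        )
    return results
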