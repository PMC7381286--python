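"""Synthetic inputs with known ground truth.

Everything the downstream pipeline consumes can be generated here:

* exact fractional Gaussian noise (fGn) and fractional Brownian motion
  (fBm) of known Hurst exponent H,
* BOLD-like series contaminated with physiological confound sinusoids
  (respiratory / cardiac bands),
* small 4D volumes with a known signal embedded in a spherical ROI,
* two-group cohorts (highIMP / lowIMP) with planted correlations between
  1−H deviation scores and connectivity covariates.

fGn synthesis is *exact*: the sample paths have the analytic fGn
autocovariance

    γ(k) = σ²/2 (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})

by circulant embedding (Davies–Harte), falling back to a Cholesky factor
of the dense Toeplitz covariance when the embedding is not
nonnegative-definite at the requested length.  Spectral approximations are
deliberately avoided: at N = 425 their covariance error would bias the
Hurst-recovery experiments this module exists to support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .timeseries import TimeSeries

__all__ = [
    "FgnSpec",
    "ConfoundSpec",
    "CohortSpec",
    "fgn_autocovariance",
    "generate_fgn",
    "generate_fbm",
    "add_confounds",
    "generate_volume_with_roi",
    "generate_cohort",
    "write_series_tsv",
    "read_series_tsv",
    "write_provenance",
]

HIGH_GROUP = "highIMP"
LOW_GROUP = "lowIMP"


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class FgnSpec:
    """Parameters of an fGn (or, via cumulation, fBm) sample path.

    hurst must lie strictly inside (0, 1); sigma is the marginal standard
    deviation of the increments.
    """

    hurst: float
    n_samples: int
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.hurst < 1.0):
            raise ValueError(f"hurst must be in (0, 1), got {self.hurst}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class ConfoundSpec:
    """Physiological confound bands added as random-phase sinusoids.

    Default band limits are the conventional respiratory (0.1–0.5 Hz) and
    cardiac (0.6–1.2 Hz) frequency ranges.  A band takes effect only when
    its amplitude is positive, and an active band must lie entirely below
    the Nyquist frequency implied by ``sampling_interval`` — at TR = 2 s
    (Nyquist 0.25 Hz) neither default band is directly representable, which
    is why the default amplitudes are zero.
    """

    respiratory_band: tuple[float, float] = (0.1, 0.5)
    cardiac_band: tuple[float, float] = (0.6, 1.2)
    amplitudes: tuple[float, float] = (0.0, 0.0)
    sampling_interval: float = 2.0

    def __post_init__(self):
        for name, (lo, hi) in self._bands().items():
            if not (0.0 < lo < hi):
                raise ValueError(f"{name} band must be a positive-width interval")
        if len(self.amplitudes) != 2:
            raise ValueError("amplitudes must give one value per band")
        if any(a < 0 or not np.isfinite(a) for a in self.amplitudes):
            raise ValueError("amplitudes must be finite and nonnegative")
        if not (self.sampling_interval > 0):
            raise ValueError("sampling_interval must be positive")

    def _bands(self) -> dict[str, tuple[float, float]]:
        return {"respiratory": tuple(self.respiratory_band),
                "cardiac": tuple(self.cardiac_band)}


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with planted deviation/covariate correlations.

    ``rho_by_group`` maps group → {covariate name → correlation between the
    group's 1−H deviation scores and that covariate}.  Default group sizes
    (38 high-impulsive vs 65 low-impulsive) and the default planted
    correlations (−0.03 / 0.36 for the ACC→l_HC connectivity estimate)
    reproduce the shape of the cohort this package's group statistics
    target.
    """

    n_high: int = 38
    n_low: int = 65
    deviation_mean_by_group: Mapping[str, float] = field(
        default_factory=lambda: {HIGH_GROUP: 0.10, LOW_GROUP: 0.05})
    deviation_sd_by_group: Mapping[str, float] = field(
        default_factory=lambda: {HIGH_GROUP: 0.12, LOW_GROUP: 0.12})
    rho_by_group: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {HIGH_GROUP: {"ACC_to_l_HC": 0.36},
                                 LOW_GROUP: {"ACC_to_l_HC": -0.03}})
    seed: int = 0

    def __post_init__(self):
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("group sizes must be positive")
        for g in (HIGH_GROUP, LOW_GROUP):
            if g not in self.deviation_mean_by_group:
                raise ValueError(f"deviation_mean_by_group missing {g}")
            if not (self.deviation_sd_by_group[g] > 0):
                raise ValueError("deviation SDs must be positive")
            for cov, rho in self.rho_by_group[g].items():
                if not (-1.0 < rho < 1.0):
                    raise ValueError(f"|rho| must be < 1 ({g}/{cov}: {rho})")

    @property
    def covariates(self) -> list[str]:
        names = list(self.rho_by_group[HIGH_GROUP])
        if set(names) != set(self.rho_by_group[LOW_GROUP]):
            raise ValueError("both groups must plant the same covariates")
        return names


# ---------------------------------------------------------------------------
# fGn / fBm


def fgn_autocovariance(hurst: float, lags, sigma: float = 1.0) -> np.ndarray:
    """Analytic fGn autocovariance γ(k) = σ²/2(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * sigma**2 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def _circulant_eigenvalues(spec: FgnSpec) -> np.ndarray:
    n = spec.n_samples
    gamma = fgn_autocovariance(spec.hurst, np.arange(n + 1), spec.sigma)
    # first row of the 2n-circulant embedding of the Toeplitz covariance
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    return np.fft.fft(row).real


def generate_fgn(spec: FgnSpec, sampling_interval: float = 2.0,
                 method: str = "auto") -> TimeSeries:
    """Draw one exact fGn sample path.

    Circulant embedding is used when its eigenvalues are all nonnegative
    (true for fGn at any H in (0,1), but checked rather than assumed);
    otherwise — or when ``method="cholesky"`` — the dense Toeplitz
    covariance is factorised instead.  Deterministic given ``spec.seed``.
    """
    if method not in ("auto", "circulant", "cholesky"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    if method != "cholesky":
        lam = _circulant_eigenvalues(spec)
        tol = -1e-9 * lam.max()
        if lam.min() < tol:
            if method == "circulant":
                raise ValueError(
                    "circulant embedding is not nonnegative-definite at this "
                    "length; use method='cholesky'")
            method = "cholesky"
        else:
            lam = np.clip(lam, 0.0, None)
            m = 2 * n
            w = np.empty(m, dtype=complex)
            w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
            w[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
            re = rng.standard_normal(n - 1)
            im = rng.standard_normal(n - 1)
            w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (re + 1j * im)
            w[n + 1:] = np.conj(w[1:n][::-1])
            values = np.fft.fft(w).real[:n]
            return TimeSeries(values, sampling_interval,
                              f"fgn(H={spec.hurst:g})")

    from scipy.linalg import cholesky, toeplitz

    cov = toeplitz(fgn_autocovariance(spec.hurst, np.arange(n), spec.sigma))
    lower = cholesky(cov, lower=True)
    values = lower @ rng.standard_normal(n)
    return TimeSeries(values, sampling_interval, f"fgn(H={spec.hurst:g})")


def generate_fbm(spec: FgnSpec, sampling_interval: float = 2.0,
                 method: str = "auto") -> TimeSeries:
    """fBm path as the cumulative sum of the fGn drawn from the same spec.

    ``np.diff`` of the output (prepending nothing) recovers the generating
    fGn bit-for-bit; the first value equals the first increment.
    """
    fgn = generate_fgn(spec, sampling_interval, method=method)
    return TimeSeries(np.cumsum(fgn.values), sampling_interval,
                      f"fbm(H={spec.hurst:g})")


# ---------------------------------------------------------------------------
# confounds


def add_confounds(ts: TimeSeries, spec: ConfoundSpec, seed: int = 0) -> TimeSeries:
    """Superimpose one random-phase sinusoid per active confound band.

    For each band with positive amplitude a frequency is drawn uniformly
    within the band and a phase uniformly in [0, 2π).  Bands with zero
    amplitude are ignored; an active band reaching at or above the Nyquist
    frequency of ``ts`` raises (alias guard).
    """
    rng = np.random.default_rng(seed)
    out = ts.values.copy()
    t = ts.times
    for (name, (lo, hi)), amp in zip(spec._bands().items(), spec.amplitudes):
        if amp == 0.0:
            continue
        if hi >= ts.nyquist:
            raise ValueError(
                f"{name} band {lo}-{hi} Hz reaches the Nyquist frequency "
                f"{ts.nyquist:g} Hz at sampling interval "
                f"{ts.sampling_interval:g} s")
        freq = rng.uniform(lo, hi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += amp * np.sin(2.0 * np.pi * freq * t + phase)
    return ts.with_values(out)


# ---------------------------------------------------------------------------
# 4D fixtures


def generate_volume_with_roi(grid_shape, voxel_size_mm, roi_center_mm,
                             roi_radius_mm, signal: TimeSeries,
                             noise_sd: float = 0.0, seed: int = 0):
    """4D NIfTI image with ``signal`` embedded in a spherical ROI.

    Voxels whose centers lie within ``roi_radius_mm`` of ``roi_center_mm``
    carry signal + independent Gaussian noise; all others carry pure noise.
    The affine is diagonal (voxel index → mm), so mm coordinates start at 0
    at the corner voxel's center.
    """
    import nibabel as nib

    from .roi_extraction import sphere_mask

    grid_shape = tuple(int(s) for s in grid_shape)
    voxel = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    center = np.asarray(roi_center_mm, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    hi = (np.array(grid_shape) - 1) * voxel
    if np.any(center - roi_radius_mm < 0) or np.any(center + roi_radius_mm > hi):
        raise ValueError("sphere does not fit inside the field of view")

    affine = np.diag([voxel[0], voxel[1], voxel[2], 1.0])
    mask = sphere_mask(center, roi_radius_mm, affine, grid_shape)

    rng = np.random.default_rng(seed)
    nt = signal.n
    data = (rng.normal(0.0, noise_sd, size=grid_shape + (nt,))
            if noise_sd > 0 else np.zeros(grid_shape + (nt,)))
    data[mask] += signal.values

    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((*voxel, signal.sampling_interval))
    return img


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Two-group cohort table with planted correlation structure.

    Per subject: a group label, a premature-response count consistent with
    the ≥3 phenotype split, a deviation score drawn from the group's
    Normal(mean, sd), and each covariate drawn jointly bivariate-normal so
    that its population correlation with the deviation equals the group's
    planted rho.  Covariates are standardised (mean 0, SD 1) within the
    generating model.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for group, size in ((HIGH_GROUP, spec.n_high), (LOW_GROUP, spec.n_low)):
        mu = spec.deviation_mean_by_group[group]
        sd = spec.deviation_sd_by_group[group]
        z = rng.standard_normal(size)
        deviation = mu + sd * z
        if group == HIGH_GROUP:
            counts = 3 + rng.poisson(2.0, size)
        else:
            counts = rng.integers(0, 3, size)
        covs = {}
        for name in spec.covariates:
            rho = spec.rho_by_group[group][name]
            covs[name] = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(size)
        for i in range(size):
            row = {"subject": f"sub-{sid:03d}", "group": group,
                   "premature_count": int(counts[i]),
                   "deviation": deviation[i]}
            row.update({name: covs[name][i] for name in covs})
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def write_series_tsv(series: Sequence[TimeSeries] | Mapping[str, TimeSeries],
                     path) -> None:
    """Write series as TSV, one column per series, header row of labels."""
    if isinstance(series, Mapping):
        items = list(series.items())
    else:
        items = [(ts.label or f"series_{i}", ts) for i, ts in enumerate(series)]
    lengths = {ts.n for _, ts in items}
    if len(lengths) != 1:
        raise ValueError("all series in one table must have equal length")
    frame = pd.DataFrame({label: ts.values for label, ts in items})
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_series_tsv(path, sampling_interval: float = 2.0) -> dict[str, TimeSeries]:
    """Read a TSV written by :func:`write_series_tsv` back into series."""
    frame = pd.read_csv(path, sep="\t")
    return {col: TimeSeries(frame[col].to_numpy(), sampling_interval, col)
            for col in frame.columns}


def write_provenance(params: Mapping, path) -> None:
    """Echo generation parameters into a YAML sidecar."""
    def _plain(obj):
        if isinstance(obj, Mapping):
            return {str(k): _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_plain(dict(params)), fh, sort_keys=False)
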