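"""Synthetic patient cohorts with controlled correlation structure.

Each cohort row holds a quantitative CT extent score (``cam_extent_pct``),
two integer visual-reader scores and their mean, and three pulmonary
function values (% predicted).  The generator draws a latent Gaussian
vector per patient and maps each coordinate through a moment-matched Beta
marginal on the variable's valid range, so no draw ever needs clipping.
Latent correlations are calibrated by Gauss-Hermite quadrature so the
*observed* Pearson correlations (including the attenuation introduced by
reader noise and integer rounding of the visual scores) land on the
requested targets; by default a small finite-sample inflation is applied
so the *expected sample* correlation at the requested n matches the
target.

Only the first row of the correlation matrix (CT extent vs the other
variables) is usually known; the remaining entries are completed under a
single-latent-severity-factor model (corr[i,j] = corr[0,i] * corr[0,j])
and the result is projected to the nearest positive semi-definite matrix.

Reader pairs are built as ``round(latent + noise)`` with independent
truncated-normal noise whose variance is calibrated (by quadrature over
the latent marginal) so that ICC(2,1) of the two reader columns equals
``reader_icc`` and the SD of the reader mean equals the requested SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .errors import ConfigurationError, CorrelationMatrixError

VARIABLES = ("cam_extent_pct", "warrick", "fvc_pct", "fev1_pct", "dlco_pct")

DEFAULT_MEAN_SD: dict[str, tuple[float, float]] = {
    "cam_extent_pct": (19.1, 9.8),
    "warrick": (12.1, 6.9),
    "fvc_pct": (89.6, 9.6),
    "fev1_pct": (83.8, 8.7),
    "dlco_pct": (70.1, 15.9),
}

DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "cam_extent_pct": (0.0, 100.0),
    "warrick": (0.0, 30.0),
    "fvc_pct": (0.0, 160.0),
    "fev1_pct": (0.0, 160.0),
    "dlco_pct": (0.0, 160.0),
}

#: correlations of the CT extent score with (warrick, fvc, fev1, dlco)
DEFAULT_CAM_ROW = (0.829, -0.490, -0.675, -0.653)

_GH_NODES = 64
_PSD_FLOOR = 1e-6
_PSD_TOLERANCE = 0.01  # most-negative eigenvalue repairable without error


@dataclass(frozen=True)
class CohortSpec:
    """Target structure of a synthetic cohort."""

    n_total: int = 79
    n_dcssc: int = 38
    n_lcssc: int = 41
    mean_sd: tuple[tuple[float, float], ...] = tuple(
        DEFAULT_MEAN_SD[v] for v in VARIABLES
    )
    ranges: tuple[tuple[float, float], ...] = tuple(
        DEFAULT_RANGES[v] for v in VARIABLES
    )
    cam_row: tuple[float, ...] = DEFAULT_CAM_ROW
    corr: tuple[tuple[float, ...], ...] | None = None  # full 5x5 override
    reader_icc: float = 0.81
    expect_sample_r: bool = True
    seed: int = 0

    @classmethod
    def from_mappings(
        cls,
        mean_sd: Mapping[str, tuple[float, float]] | None = None,
        ranges: Mapping[str, tuple[float, float]] | None = None,
        **kwargs,
    ) -> "CohortSpec":
        ms = dict(DEFAULT_MEAN_SD)
        ms.update(mean_sd or {})
        rg = dict(DEFAULT_RANGES)
        rg.update(ranges or {})
        return cls(
            mean_sd=tuple(tuple(map(float, ms[v])) for v in VARIABLES),
            ranges=tuple(tuple(map(float, rg[v])) for v in VARIABLES),
            **kwargs,
        )

    def validate(self) -> None:
        if self.n_total < 4:
            raise ConfigurationError("cohort needs at least 4 patients")
        if self.n_dcssc + self.n_lcssc != self.n_total:
            raise ConfigurationError(
                f"subtype counts {self.n_dcssc}+{self.n_lcssc} "
                f"do not sum to n_total={self.n_total}"
            )
        if min(self.n_dcssc, self.n_lcssc) < 0:
            raise ConfigurationError("subtype counts must be non-negative")
        if len(self.mean_sd) != len(VARIABLES) or len(self.ranges) != len(VARIABLES):
            raise ConfigurationError("mean_sd and ranges must cover all variables")
        for name, (mean, sd), (lo, hi) in zip(VARIABLES, self.mean_sd, self.ranges):
            if sd <= 0:
                raise ConfigurationError(f"{name}: SD must be > 0")
            if not lo < mean < hi:
                raise ConfigurationError(f"{name}: mean {mean} outside range ({lo}, {hi})")
        if not 0 < self.reader_icc <= 1:
            raise ConfigurationError("reader_icc must lie in (0, 1]")
        if len(self.cam_row) != len(VARIABLES) - 1:
            raise ConfigurationError("cam_row must have one entry per non-CT variable")
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            if c.shape != (len(VARIABLES),) * 2:
                raise ConfigurationError("corr must be a full 5x5 matrix")
            if not np.allclose(c, c.T):
                raise ConfigurationError("corr must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ConfigurationError("corr must have a unit diagonal")

    def _cache_key(self) -> tuple:
        return (
            self.n_total,
            self.mean_sd,
            self.ranges,
            self.cam_row,
            self.corr,
            self.reader_icc,
            self.expect_sample_r,
        )


# ---------------------------------------------------------------------------
# correlation-matrix plumbing


def build_correlation_matrix(spec: CohortSpec) -> np.ndarray:
    """Target observable correlation matrix: either the explicit override or
    the single-factor completion of the CT-extent row."""
    p = len(VARIABLES)
    if spec.corr is not None:
        return np.asarray(spec.corr, dtype=float)
    row = np.asarray(spec.cam_row, dtype=float)
    v = np.concatenate([[1.0], row])
    corr = np.outer(v, v)
    np.fill_diagonal(corr, 1.0)
    assert corr.shape == (p, p)
    return corr


def repair_psd(
    corr: np.ndarray,
    floor: float = _PSD_FLOOR,
    tolerance: float = _PSD_TOLERANCE,
) -> np.ndarray:
    """Project a symmetric matrix to the nearest unit-diagonal PSD matrix.

    Eigenvalues below ``-tolerance`` are considered irreparable and raise
    :class:`~ctild.errors.CorrelationMatrixError` naming the offender.
    """
    eigenvalues, eigenvectors = np.linalg.eigh(corr)
    worst = float(eigenvalues.min())
    if worst < -tolerance:
        raise CorrelationMatrixError(
            f"correlation matrix has eigenvalue {worst:.6f} below -{tolerance}; "
            "not repairable to positive semi-definite"
        )
    if worst >= floor:
        return corr
    clipped = np.maximum(eigenvalues, floor)
    repaired = eigenvectors @ np.diag(clipped) @ eigenvectors.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


# ---------------------------------------------------------------------------
# Beta marginals and Gaussian-copula correlation calibration


def _beta_ab(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Beta shape parameters matching a mean/SD on [lo, hi]."""
    span = hi - lo
    m = (mean - lo) / span
    v = (sd / span) ** 2
    if v >= m * (1 - m):
        raise ConfigurationError(
            f"SD {sd} infeasible for a bounded variable with mean {mean} "
            f"on [{lo}, {hi}]"
        )
    common = m * (1 - m) / v - 1.0
    return m * common, (1 - m) * common


def _gh_nodes() -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    return x, w / np.sqrt(2.0 * np.pi)


def _marginal_eval(z: np.ndarray, ab_range: tuple[float, float, float, float]) -> np.ndarray:
    a, b, lo, hi = ab_range
    return lo + (hi - lo) * beta_dist.ppf(ndtr(z), a, b)


def _marginal_moments(ab_range: tuple[float, float, float, float]) -> tuple[float, float]:
    a, b, lo, hi = ab_range
    mean = lo + (hi - lo) * a / (a + b)
    var = (hi - lo) ** 2 * a * b / ((a + b) ** 2 * (a + b + 1.0))
    return mean, float(np.sqrt(var))


def _copula_pearson(
    rho: float,
    m1: tuple[float, float, float, float],
    m2: tuple[float, float, float, float],
) -> float:
    """Pearson correlation of two Beta marginals joined by a Gaussian copula
    with latent correlation ``rho`` (Gauss-Hermite quadrature)."""
    x, w = _gh_nodes()
    g1 = _marginal_eval(x, m1)
    z2 = rho * x[:, None] + np.sqrt(max(1.0 - rho**2, 0.0)) * x[None, :]
    g2 = _marginal_eval(z2, m2)
    e12 = float(w @ (g2 @ w * g1))
    # moments from the same node set so quadrature error largely cancels
    mu1 = float(w @ g1)
    s1 = float(np.sqrt(w @ g1**2 - mu1**2))
    g2d = _marginal_eval(x, m2)
    mu2 = float(w @ g2d)
    s2 = float(np.sqrt(w @ g2d**2 - mu2**2))
    return (e12 - mu1 * mu2) / (s1 * s2)


def _latent_rho(
    target: float,
    m1: tuple[float, float, float, float],
    m2: tuple[float, float, float, float],
) -> float:
    if target == 0.0:
        return 0.0
    limit = 0.99999
    lo_val = _copula_pearson(-limit, m1, m2)
    hi_val = _copula_pearson(limit, m1, m2)
    if not lo_val < target < hi_val:
        raise ConfigurationError(
            f"target Pearson correlation {target:.4f} unreachable for these "
            f"marginals (achievable range [{lo_val:.4f}, {hi_val:.4f}])"
        )
    return float(
        optimize.brentq(
            lambda r: _copula_pearson(r, m1, m2) - target,
            -limit,
            limit,
            xtol=1e-10,
        )
    )


# ---------------------------------------------------------------------------
# reader-noise calibration


def _truncnorm_var(sigma: float, c: np.ndarray) -> np.ndarray:
    """Variance of N(0, sigma^2) truncated to [-c, c], elementwise in c."""
    k = c / sigma
    mass = 2.0 * ndtr(k) - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = sigma**2 * (1.0 - 2.0 * k * norm.pdf(k) / mass)
    return np.where(mass <= 0, c**2 / 3.0, v)


def _expected_reader_noise_var(
    sigma: float, warrick_marginal: tuple[float, float, float, float]
) -> float:
    """E over the latent score M of the truncated reader-noise variance,
    with truncation half-width min(M - lo, hi - M)."""
    a, b, lo, hi = warrick_marginal
    # Gauss-Legendre on the unit interval against the Beta density
    x, w = np.polynomial.legendre.leggauss(256)
    u = 0.5 * (x + 1.0)
    wu = 0.5 * w
    density = beta_dist.pdf(u, a, b)
    m = lo + (hi - lo) * u
    c = np.minimum(m - lo, hi - m)
    return float(np.sum(wu * density * _truncnorm_var(sigma, c)))


_ROUND_VAR = 1.0 / 12.0  # variance of integer-rounding error


@lru_cache(maxsize=32)
def _calibrate(cache_key: tuple) -> dict:
    """Deterministic calibration shared by all seeds of one spec shape."""
    (n_total, mean_sd, ranges, cam_row, corr, reader_icc, expect_sample_r) = cache_key
    p = len(VARIABLES)
    w_idx = VARIABLES.index("warrick")
    sd_w = mean_sd[w_idx][1]

    # reader-noise variance v_e and latent-score SD so that ICC(2,1) of the
    # reader columns hits reader_icc while SD(reader mean) stays at sd_w:
    #   icc  = var_M / (var_M + v_e + 1/12)
    #   sd_w^2 = var_M + v_e/2 + 1/24
    # finite-sample correction: the ANOVA ICC(2,1) estimator at k=2 is biased
    # low by ~ (1 - icc)(1 + icc)/n, so target a slightly higher population
    # value when the contract is on the expected sample statistic
    icc_eff = reader_icc
    if expect_sample_r and reader_icc < 1.0:
        icc_eff = min(
            reader_icc + (1.0 - reader_icc) * (1.0 + reader_icc) / n_total, 0.999
        )
    a_icc = (1.0 - icc_eff) / icc_eff
    v_e = (a_icc * sd_w**2 - a_icc * _ROUND_VAR / 2.0 - _ROUND_VAR) / (1.0 + a_icc / 2.0)
    if v_e <= 0:
        v_e = 0.0
        var_m = sd_w**2
    else:
        var_m = sd_w**2 - v_e / 2.0 - _ROUND_VAR / 2.0
    if var_m <= 0:
        raise ConfigurationError(
            f"reader_icc={reader_icc} with SD {sd_w} leaves no latent variance"
        )
    sd_m = float(np.sqrt(var_m))

    marginals = []
    for i, ((mean, sd), (lo, hi)) in enumerate(zip(mean_sd, ranges)):
        eff_sd = sd_m if i == w_idx else sd
        a, b = _beta_ab(mean, eff_sd, lo, hi)
        marginals.append((a, b, lo, hi))

    spec_like = CohortSpec(
        n_total=n_total,
        n_dcssc=0,
        n_lcssc=n_total,
        mean_sd=mean_sd,
        ranges=ranges,
        cam_row=cam_row,
        corr=corr,
        reader_icc=reader_icc,
        expect_sample_r=expect_sample_r,
    )
    target = repair_psd(build_correlation_matrix(spec_like))

    # finite-sample inflation: E[sample r] ~ r_pop (1 - (1 - r_pop^2) / (2n))
    adjusted = target.copy()
    if expect_sample_r:
        off = ~np.eye(p, dtype=bool)
        adjusted[off] = target[off] * (1.0 + (1.0 - target[off] ** 2) / (2.0 * n_total))

    # attenuation through reader noise + rounding: observable warrick column
    # is the reader mean with SD sd_w while the latent score has SD sd_m
    atten = sd_w / sd_m
    adjusted[w_idx, :] *= atten
    adjusted[:, w_idx] *= atten
    adjusted[w_idx, w_idx] = 1.0
    if np.any(np.abs(adjusted[~np.eye(p, dtype=bool)]) >= 1.0):
        raise ConfigurationError(
            "requested correlations are unreachable once reader noise is "
            "accounted for; lower the targets or raise reader_icc"
        )

    latent = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            rho = _latent_rho(float(adjusted[i, j]), marginals[i], marginals[j])
            latent[i, j] = latent[j, i] = rho
    latent = repair_psd(latent)
    chol = np.linalg.cholesky(latent + 1e-12 * np.eye(p))

    if v_e > 0:
        w_marg = marginals[w_idx]
        f = lambda s: _expected_reader_noise_var(s, w_marg) - v_e  # noqa: E731
        hi_s = np.sqrt(v_e) * 8.0
        sigma_e = float(optimize.brentq(f, 1e-9, hi_s, xtol=1e-10))
    else:
        sigma_e = 0.0

    return {
        "marginals": marginals,
        "latent_cholesky": chol,
        "sigma_e": sigma_e,
        "target_corr": target,
    }


# ---------------------------------------------------------------------------
# generation


def _truncnorm_sample(
    rng: np.random.Generator, sigma: float, c: np.ndarray, size: tuple[int, ...]
) -> np.ndarray:
    """Samples of N(0, sigma^2) truncated to [-c, c] (c broadcast over size)."""
    if sigma == 0.0:
        return np.zeros(size)
    k = c / sigma
    lo = ndtr(-k)
    hi = ndtr(k)
    u = rng.random(size)
    return sigma * ndtri(lo + u * (hi - lo))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a synthetic cohort table.

    Columns: ``id, subtype, cam_extent_pct, warrick_reader1,
    warrick_reader2, warrick_mean, fvc_pct, fev1_pct, dlco_pct``.
    Identical spec (including seed) yields an identical table.
    """
    spec.validate()
    cal = _calibrate(spec._cache_key())
    n = spec.n_total
    p = len(VARIABLES)
    w_idx = VARIABLES.index("warrick")

    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((n, p)) @ cal["latent_cholesky"].T
    x = np.empty_like(z)
    for i in range(p):
        x[:, i] = _marginal_eval(z[:, i], cal["marginals"][i])

    m = x[:, w_idx]
    _, _, lo_w, hi_w = cal["marginals"][w_idx]
    c = np.minimum(m - lo_w, hi_w - m)
    noise = _truncnorm_sample(rng, cal["sigma_e"], c[:, None], (n, 2))
    readers = np.rint(m[:, None] + noise).astype(int)
    warrick_mean = readers.mean(axis=1)

    subtype = np.full(n, "lcSSc", dtype=object)
    subtype[rng.permutation(n)[: spec.n_dcssc]] = "dcSSc"

    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "subtype": subtype,
            "cam_extent_pct": x[:, 0],
            "warrick_reader1": readers[:, 0],
            "warrick_reader2": readers[:, 1],
            "warrick_mean": warrick_mean,
            "fvc_pct": x[:, 2],
            "fev1_pct": x[:, 3],
            "dlco_pct": x[:, 4],
        }
    )
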