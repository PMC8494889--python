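"""One-way ANOVA and Dunnett's many-to-one comparisons, owned in full.

Every significance claim in the pipeline comes from a one-way ANOVA
followed by Dunnett's multiple-comparison test of each treatment group
against the shared control (vehicle) group. Both procedures are
implemented here from their defining formulas — no statistics-package
test routine is called; SciPy supplies only distribution functions and
the quadrature routine.

Model: k treatment groups and one control, homoscedastic normal errors.
With pooled within-group mean square ``MS_w`` on ``nu`` degrees of
freedom, the statistics

    t_i = (mean_i - mean_0) / sqrt(MS_w * (1/n_i + 1/n_0))

are jointly multivariate-t with correlations ``rho_ij = lambda_i *
lambda_j``, ``lambda_i = sqrt(n_i / (n_i + n_0))`` (the shared control
mean induces the correlation; unbalanced designs are handled through
the lambdas). The family-wise adjusted p-value of comparison i is

    p_i = 1 - P(max_j |T_j| <= |t_i|)

evaluated by conditioning on the control variate Z0 and the pooled
scale U = S/sigma (U^2 ~ chi2_nu / nu):

    P(max|T| <= t) = int_0^inf f_U(u) int phi(z)
        prod_j [Phi((t u + l_j z)/g_j) - Phi((-t u + l_j z)/g_j)] dz du

with ``g_j = sqrt(1 - l_j^2)``, computed by adaptive quadrature to an
absolute tolerance of 1e-8 (inner) / 1e-6 (outer) by default. For a
single treatment group the maximum reduces exactly to |T| ~ Student-t
on nu df, and the closed form is used. A seeded Monte-Carlo evaluation
of the same max-|t| null is provided for cross-validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy import stats as sps
from scipy.special import ndtr

logger = logging.getLogger(__name__)

__all__ = [
    "GroupData",
    "AnovaResult",
    "DunnettResult",
    "DegenerateDataError",
    "StatsError",
    "one_way_anova",
    "dunnett_test",
    "dunnett_max_abs_t_cdf",
    "dunnett_pvalue_mc",
    "star_level",
    "DEFAULT_STAR_LEVELS",
]

#: Printed significance levels, most stringent last.
DEFAULT_STAR_LEVELS = (0.05, 0.01, 0.001, 0.0001)


class StatsError(ValueError):
    """Invalid group structure for the requested test."""


class DegenerateDataError(StatsError):
    """Zero within-group variance everywhere; F/t undefined."""


@dataclass(frozen=True)
class GroupData:
    group_id: str
    values: tuple[float, ...]
    is_control: bool = False

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise StatsError(f"group {self.group_id}: n >= 2 required, got {len(self.values)}")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float


@dataclass(frozen=True)
class DunnettResult:
    group_id: str
    control_id: str
    t_statistic: float
    df: int
    adjusted_p: float
    significant_at: float | None  # most stringent star level reached, or None


def _check_groups(groups: Sequence[GroupData]) -> None:
    if len(groups) < 2:
        raise StatsError("at least two groups are required")
    ids = [g.group_id for g in groups]
    if len(set(ids)) != len(ids):
        raise StatsError("group ids must be unique")


def _pooled_within(groups: Sequence[GroupData]) -> tuple[float, int]:
    ssw = 0.0
    for g in groups:
        m = g.mean
        ssw += sum((x - m) ** 2 for x in g.values)
    df = sum(g.n for g in groups) - len(groups)
    return ssw, df


def one_way_anova(groups: Sequence[GroupData]) -> AnovaResult:
    """Classical fixed-effects decomposition: F = MS_between / MS_within."""
    _check_groups(groups)
    n_total = sum(g.n for g in groups)
    grand_mean = sum(sum(g.values) for g in groups) / n_total
    ssb = sum(g.n * (g.mean - grand_mean) ** 2 for g in groups)
    ssw, df_within = _pooled_within(groups)
    df_between = len(groups) - 1
    if ssw == 0.0:
        raise DegenerateDataError(
            "zero within-group variance in every group; the F statistic is undefined"
        )
    ms_between = ssb / df_between
    ms_within = ssw / df_within
    f_stat = ms_between / ms_within
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(f_stat, df_between, df_within, p, ms_within)


# the inner z-integral is analytic and rapidly decaying, so a fixed
# high-order Gauss-Legendre rule on [-9, 9] resolves it far below the
# outer tolerance; the outer u-integral stays adaptive.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)
_Z_NODES = _GL_NODES * 9.0
_Z_WEIGHTS = _GL_WEIGHTS * 9.0 * np.exp(-0.5 * _Z_NODES**2) / math.sqrt(2 * math.pi)


def _inner_two_sided(tu: float, lam: np.ndarray, gam: np.ndarray) -> float:
    lz = lam[:, None] * _Z_NODES[None, :]
    probs = ndtr((tu + lz) / gam[:, None]) - ndtr((-tu + lz) / gam[:, None])
    return float(np.dot(np.prod(probs, axis=0), _Z_WEIGHTS))


def _inner_one_sided(tu: float, lam: np.ndarray, gam: np.ndarray) -> float:
    lz = lam[:, None] * _Z_NODES[None, :]
    probs = ndtr((tu + lz) / gam[:, None])
    return float(np.dot(np.prod(probs, axis=0), _Z_WEIGHTS))


def _check_lambdas(lambdas: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    lam = np.asarray(lambdas, dtype=float)
    if np.any((lam <= 0) | (lam >= 1)):
        raise StatsError("lambdas must lie strictly in (0, 1)")
    return lam, np.sqrt(1.0 - lam**2)


def dunnett_max_abs_t_cdf(
    t: float,
    lambdas: Sequence[float],
    df: int,
    epsabs: float = 1e-6,
) -> float:
    """P(max_j |T_j| <= t) for the Dunnett null, by quadrature."""
    if t <= 0:
        return 0.0
    lam, gam = _check_lambdas(lambdas)
    sqrt_df = math.sqrt(df)
    u_lo = sps.chi.ppf(1e-14, df) / sqrt_df
    u_hi = sps.chi.isf(1e-14, df) / sqrt_df

    def outer(u: float) -> float:
        return sqrt_df * sps.chi.pdf(u * sqrt_df, df) * _inner_two_sided(t * u, lam, gam)

    val, _ = integrate.quad(outer, u_lo, u_hi, epsabs=epsabs, limit=200)
    return min(1.0, max(0.0, val))


def dunnett_pvalue_mc(
    t_obs: float,
    lambdas: Sequence[float],
    df: int,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the adjusted two-sided p (validation path)."""
    rng = np.random.default_rng(seed)
    lam = np.asarray(lambdas, dtype=float)[:, None]
    gam = np.sqrt(1.0 - lam**2)
    block = 200_000
    exceed = 0
    remaining = n_draws
    while remaining > 0:
        m = min(block, remaining)
        z0 = rng.standard_normal(m)
        y = rng.standard_normal((len(lambdas), m))
        u = np.sqrt(rng.chisquare(df, m) / df)
        t_sim = np.max(np.abs(gam * y + lam * z0), axis=0) / u
        exceed += int(np.count_nonzero(t_sim >= abs(t_obs)))
        remaining -= m
    return exceed / n_draws


def star_level(
    adjusted_p: float, levels: Sequence[float] = DEFAULT_STAR_LEVELS
) -> float | None:
    """Most stringent printed level the p-value beats, or None."""
    reached = None
    for lvl in sorted(levels, reverse=True):  # loosest first
        if adjusted_p < lvl:
            reached = lvl
    return reached


def dunnett_test(
    groups: Sequence[GroupData],
    two_sided: bool = True,
    epsabs: float = 1e-6,
    star_levels: Sequence[float] = DEFAULT_STAR_LEVELS,
) -> list[DunnettResult]:
    """Dunnett many-to-one comparisons of every treatment group against
    the single flagged control group."""
    _check_groups(groups)
    controls = [g for g in groups if g.is_control]
    if len(controls) != 1:
        raise StatsError(
            f"exactly one control group must be flagged, found {len(controls)}"
        )
    control = controls[0]
    treatments = [g for g in groups if not g.is_control]
    if not treatments:
        raise StatsError("at least one treatment group is required")

    ssw, df = _pooled_within(groups)
    if ssw == 0.0:
        raise DegenerateDataError(
            "zero within-group variance in every group; t statistics are undefined"
        )
    ms_within = ssw / df

    lambdas = [math.sqrt(g.n / (g.n + control.n)) for g in treatments]
    results: list[DunnettResult] = []
    for g in treatments:
        se = math.sqrt(ms_within * (1.0 / g.n + 1.0 / control.n))
        t_stat = (g.mean - control.mean) / se
        t_abs = abs(t_stat)
        if len(treatments) == 1:
            # exact reduction: max over one comparison is Student-t on df
            p = float(sps.t.sf(t_abs, df) * 2) if two_sided else float(sps.t.sf(t_stat, df))
        elif two_sided:
            p = 1.0 - dunnett_max_abs_t_cdf(t_abs, lambdas, df, epsabs=epsabs)
        else:
            p = 1.0 - _max_t_cdf_one_sided(t_stat, lambdas, df, epsabs=epsabs)
        p = min(1.0, max(0.0, p))
        results.append(
            DunnettResult(
                group_id=g.group_id,
                control_id=control.group_id,
                t_statistic=t_stat,
                df=df,
                adjusted_p=p,
                significant_at=star_level(p, star_levels),
            )
        )
    return results


def _max_t_cdf_one_sided(
    t: float, lambdas: Sequence[float], df: int, epsabs: float = 1e-6
) -> float:
    """P(max_j T_j <= t) (upper one-sided variant)."""
    lam, gam = _check_lambdas(lambdas)
    sqrt_df = math.sqrt(df)
    u_lo = sps.chi.ppf(1e-14, df) / sqrt_df
    u_hi = sps.chi.isf(1e-14, df) / sqrt_df
    val, _ = integrate.quad(
        lambda u: sqrt_df * sps.chi.pdf(u * sqrt_df, df) * _inner_one_sided(t * u, lam, gam),
        u_lo,
        u_hi,
        epsabs=epsabs,
        limit=200,
    )
    return min(1.0, max(0.0, val))
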