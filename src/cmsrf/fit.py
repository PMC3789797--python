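"""Expected counts, classical-ratio selection, goodness of fit and estimation.

Turns the one-locus cytonuclear model's probabilities into expected
hermaphrodite:male-sterile (H:MS) counts, selects among textbook segregation
ratios by Pearson chi-square, and estimates the transmission distortion tau
and the partial-restoration penetrance from observed tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .model import (
    CrossChain,
    CytoplasmType,
    ModelParams,
    RfGenotype,
    chain_h_prob,
)


class NonIdentifiableError(RuntimeError):
    """The requested free parameters cannot be separated by the given tables."""


@dataclass(frozen=True)
class SegCounts:
    """Observed H:MS counts for one cross class (a Table-1-style cell)."""

    label: str
    n_h: int
    n_ms: int
    chain: CrossChain | None = None

    def __post_init__(self) -> None:
        if self.n_h < 0 or self.n_ms < 0:
            raise ValueError("counts must be nonnegative")
        if int(self.n_h) != self.n_h or int(self.n_ms) != self.n_ms:
            raise ValueError("counts must be integers")

    @property
    def n(self) -> int:
        return self.n_h + self.n_ms

    @property
    def ms_fraction(self) -> float:
        if self.n == 0:
            raise ValueError("empty table")
        return self.n_ms / self.n


@dataclass(frozen=True)
class RatioModel:
    """A classical H:MS segregation ratio such as 13:3 or 1:1."""

    h_parts: int
    ms_parts: int

    def __post_init__(self) -> None:
        if self.h_parts < 0 or self.ms_parts < 0 or self.h_parts + self.ms_parts == 0:
            raise ValueError("ratio parts must be nonnegative, not both zero")

    @property
    def label(self) -> str:
        return f"{self.h_parts}:{self.ms_parts}"

    @property
    def coprime(self) -> tuple[int, int]:
        g = math.gcd(self.h_parts, self.ms_parts)
        return self.h_parts // g, self.ms_parts // g

    @property
    def p_h(self) -> float:
        return self.h_parts / (self.h_parts + self.ms_parts)

    @property
    def degenerate(self) -> bool:
        return self.h_parts == 0 or self.ms_parts == 0

    @classmethod
    def parse(cls, label: str) -> "RatioModel":
        h, ms = label.split(":")
        return cls(int(h), int(ms))


#: Ratio families arising from one or two restorer loci (dominant and/or
#: recessive) in F2 and backcross generations, plus the degenerate no-MS cases.
DEFAULT_RATIOS = tuple(
    RatioModel.parse(s)
    for s in (
        "1:0", "15:1", "13:3", "3:1", "5:3", "9:7", "1:1",
        "7:9", "3:5", "1:3", "3:13", "1:15", "0:1",
    )
)


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-square goodness-of-fit output."""

    chi2: float
    df: int
    p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected H and MS cells: exact reals plus half-up rounded integers.

    ``h_int``/``ms_int`` round each cell half-up; if (only on exact .5 ties)
    the pair misses N, the cell with the larger fractional remainder absorbs
    the difference so the integers always total N.
    """

    h_exact: float
    ms_exact: float
    h_int: int
    ms_int: int

    @property
    def n(self) -> float:
        return self.h_exact + self.ms_exact


def _half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def expected_counts(p_h: float, n: int | float) -> ExpectedCounts:
    """Expected (H, MS) cells for N plants with hermaphrodite probability p_h."""
    if n < 0:
        raise ValueError("N must be nonnegative")
    if not 0.0 <= p_h <= 1.0:
        raise ValueError(f"p_h={p_h} outside [0, 1]")
    h = p_h * n
    ms = (1.0 - p_h) * n
    hi, mi = _half_up(h), _half_up(ms)
    n_int = _half_up(n)
    if hi + mi != n_int:  # .5/.5 tie rounds both up; reconcile to N
        if (h - math.floor(h)) >= (ms - math.floor(ms)):
            mi = n_int - hi
        else:
            hi = n_int - mi
    return ExpectedCounts(h, ms, hi, mi)


def gof_chi2(
    obs: SegCounts | tuple[float, float],
    exp: ExpectedCounts | tuple[float, float],
    df: int = 1,
    alpha: float = 0.05,
) -> GofResult:
    """Pearson chi-square of an observed H:MS pair against exact expectations.

    No continuity correction, matching the study's 1-d.f. tests.
    """
    o = (obs.n_h, obs.n_ms) if isinstance(obs, SegCounts) else tuple(obs)
    e = (exp.h_exact, exp.ms_exact) if isinstance(exp, ExpectedCounts) else tuple(exp)
    if min(e) <= 0:
        raise ValueError("expected cell is zero; chi-square undefined")
    chi2 = sum((oi - ei) ** 2 / ei for oi, ei in zip(o, e))
    p = float(stats.chi2.sf(chi2, df))
    return GofResult(float(chi2), df, p, alpha)


@dataclass(frozen=True)
class RatioFit:
    """Result of classical-ratio model selection for one observed table."""

    best: RatioModel
    scores: tuple[tuple[RatioModel, GofResult | None], ...]


def classic_ratio_fit(
    obs: SegCounts,
    candidates: Sequence[RatioModel] = DEFAULT_RATIOS,
    degenerate_tol: float = 0.0,
) -> RatioFit:
    """Select the candidate ratio minimising Pearson chi-square.

    Degenerate ratios (1:0, 0:1) have a zero expected cell, so they are
    handled as exact-match specials: declared best-fitting iff the opposite
    observed class count is at most ``degenerate_tol`` (an absolute count, or,
    if a float < 1, a fraction of N — the study labels rows with a handful of
    off-class plants as 1:0).  Ties break toward fewer ratio parts.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if obs.n == 0:
        raise ValueError("empty observed table")
    tol = degenerate_tol * obs.n if 0 < degenerate_tol < 1 else degenerate_tol
    scored: list[tuple[RatioModel, GofResult | None, float]] = []
    for cand in candidates:
        if cand.degenerate:
            off = obs.n_ms if cand.ms_parts == 0 else obs.n_h
            score = 0.0 if off <= tol else math.inf
            scored.append((cand, None, score))
        else:
            res = gof_chi2(obs, expected_counts(cand.p_h, obs.n))
            scored.append((cand, res, res.chi2))
    if all(math.isinf(s) for _, _, s in scored):
        raise ValueError("no candidate ratio is admissible for this table")
    best = min(scored, key=lambda t: (t[2], sum(t[0].coprime)))[0]
    return RatioFit(best, tuple((c, r) for c, r, _ in scored))


def estimate_restoration(obs_ms: int, exp_mm: float) -> tuple[float, bool]:
    """Restoration penetrance 1 - observed MS / expected mm, clamped to [0,1].

    Returns (estimate, clamped_flag); e.g. 144 observed MS against 229.45
    expected nonrestored homozygotes gives 1 - 0.628 = 0.372.
    """
    if exp_mm <= 0:
        raise ValueError("expected mm count must be positive")
    raw = 1.0 - obs_ms / exp_mm
    clamped = not 0.0 <= raw <= 1.0
    if clamped:
        warnings.warn(
            f"restoration estimate {raw:.3f} outside [0, 1]; clamped", stacklevel=2
        )
    return min(1.0, max(0.0, raw)), clamped


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its Clopper–Pearson interval."""

    estimate: float
    n: int
    ci_low: float
    ci_high: float
    level: float = 0.95


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    a = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    return low, high


def estimate_penetrance_from_genotypes(
    table: Iterable[tuple[RfGenotype | str, CytoplasmType, str]],
    level: float = 0.95,
) -> ProportionEstimate:
    """Fraction of hermaphrodites among mm plants with CMS cytoplasm.

    ``table`` yields (Rf genotype, cytoplasm, phenotype 'H'/'MS') rows; only
    nonrestorer homozygotes carrying a CMS cytoplasm inform the estimate.
    """
    k = n = 0
    for geno, cyt, phen in table:
        g = geno.genotype_class if isinstance(geno, RfGenotype) else geno
        if g == "mm" and cyt.carries_cms:
            n += 1
            k += phen == "H"
    if n == 0:
        raise ValueError("no mm individuals with CMS cytoplasm in table")
    low, high = _clopper_pearson(k, n, level)
    return ProportionEstimate(k / n, n, low, high, level)


def estimate_tau(
    n_rr: int, n_rm: int, n_mm: int, level: float = 0.95
) -> ProportionEstimate:
    """Nonrestorer allele frequency from genotype counts at a marker.

    tau-hat = (2 n_mm + n_Rm) / 2N with a Clopper–Pearson CI on 2N allele
    draws (each of the 2N transmitted alleles treated as one Bernoulli trial).
    """
    n_ind = n_rr + n_rm + n_mm
    if n_ind == 0:
        raise ValueError("no genotype counts")
    k = 2 * n_mm + n_rm
    n2 = 2 * n_ind
    low, high = _clopper_pearson(k, n2, level)
    return ProportionEstimate(k / n2, n2, low, high, level)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimates over binomial H:MS tables."""

    params: ModelParams
    free: tuple[str, ...]
    loglik: float
    converged: bool
    at_boundary: bool


def _chain_h_probs(tables: Sequence[SegCounts], params: ModelParams) -> np.ndarray:
    ps = []
    for t in tables:
        if t.chain is None:
            raise ValueError(f"table {t.label!r} has no cross chain attached")
        ps.append(chain_h_prob(t.chain, params))
    return np.asarray(ps)


def _apply_free(base: ModelParams, free: Sequence[str], x: np.ndarray) -> ModelParams:
    kw = {}
    for name, v in zip(free, x):
        if name == "tau":
            kw["tau"] = float(v)
        elif name == "restoration":
            kw["r_r"] = kw["r_n"] = float(v)
        else:
            raise ValueError(f"unknown free parameter {name!r}")
    from dataclasses import replace

    return replace(base, **kw)


def _check_identifiable(
    tables: Sequence[SegCounts], base: ModelParams, free: Sequence[str]
) -> None:
    """Numerical identifiability: rank of the P(H) Jacobian wrt free params."""
    eps = 1e-5
    rng = np.random.default_rng(0)
    for _ in range(4):
        x0 = rng.uniform(0.2, 0.8, size=len(free))
        jac = np.empty((len(tables), len(free)))
        for j in range(len(free)):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += eps
            xm[j] -= eps
            jac[:, j] = (
                _chain_h_probs(tables, _apply_free(base, free, xp))
                - _chain_h_probs(tables, _apply_free(base, free, xm))
            ) / (2 * eps)
        if np.linalg.matrix_rank(jac, tol=1e-8) == len(free):
            return
    raise NonIdentifiableError(
        f"parameters {tuple(free)} are not jointly identifiable from these tables"
    )


def fit_model_params(
    tables: Sequence[SegCounts],
    free: Sequence[str] = ("tau", "restoration"),
    base: ModelParams | None = None,
) -> FitResult:
    """Maximise the product of binomial likelihoods Binom(n_H; N, P(H|params)).

    ``free`` selects the optimised parameters among ``tau`` and ``restoration``
    (the latter ties r_R = r_N); the rest stay at ``base`` values.  Bounded
    L-BFGS-B (1-D: bounded Brent) on the negative log-likelihood.
    """
    if not tables:
        raise ValueError("need at least one observed table")
    free = tuple(free)
    if not free:
        raise ValueError("no free parameters requested")
    base = base or ModelParams(tau=0.5, r_r=0.4, r_n=0.4)
    _check_identifiable(tables, base, free)

    nh = np.array([t.n_h for t in tables], dtype=float)
    nn = np.array([t.n for t in tables], dtype=float)

    def nll(x: np.ndarray) -> float:
        p = np.clip(_chain_h_probs(tables, _apply_free(base, free, np.atleast_1d(x))), 1e-12, 1 - 1e-12)
        return float(-np.sum(nh * np.log(p) + (nn - nh) * np.log1p(-p)))

    bounds = [(0.0, 1.0)] * len(free)
    if len(free) == 1:
        res = optimize.minimize_scalar(lambda v: nll(np.array([v])), bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-10})
        x, fun, ok = np.array([res.x]), res.fun, res.success
    else:
        best = None
        for start in ([0.5, 0.5], [0.4, 0.3], [0.6, 0.6], [0.3, 0.7]):
            r = optimize.minimize(nll, np.array(start), method="L-BFGS-B", bounds=bounds,
                                  options={"ftol": 1e-14, "gtol": 1e-10})
            if best is None or r.fun < best.fun:
                best = r
        x, fun, ok = best.x, best.fun, bool(best.success)
    params = _apply_free(base, free, x)
    at_boundary = bool(np.any((x < 1e-6) | (x > 1 - 1e-6)))
    return FitResult(params, free, -fun, ok, at_boundary)


def heterogeneity_test(rows: Sequence[SegCounts], alpha: float = 0.05) -> GofResult:
    """R x 2 contingency chi-square of H:MS proportions across crosses/families."""
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    if any(r.n == 0 for r in rows):
        raise ValueError("a row has N = 0")
    table = np.array([[r.n_h, r.n_ms] for r in rows], dtype=float)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return GofResult(float(chi2), int(df), float(p), alpha)
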