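"""Voxel-wise statistical mapping methods.

Four methods turn a :class:`~pssmap.voxel_stack.VoxelStack` into a
probabilistic stimulation map (PSM):

- ``tmap``  one-sided one-sample t-test of H1: mean improvement >= 75 %
- ``wmap``  one-sided one-sample Wilcoxon signed-rank test (Pratt zeros,
            exact tie-aware null for small samples)
- ``bmap``  directional Bayesian one-sample test reporting BF10 under an
            encompassing normal prior centred on the tested threshold
- ``lmm_map``  per-voxel linear mixed model improvement ~ EF with patient
            random effects, reporting the fixed slope and its p-value

Improvement ratings are discrete, so many voxels share the same sample
composition; the map builders therefore reduce each voxel to its counts
over the distinct improvement values and memoize statistics per
composition, which also makes label-permutation reruns cheap.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .cohort_io import CohortValidationError, GridMismatchError, VoxelGrid
from .voxel_stack import VoxelStack

__all__ = [
    "PSMap",
    "PriorSpec",
    "tmap",
    "wmap",
    "bmap",
    "lmm_map",
    "t_pvalue",
    "wilcoxon_pvalue",
    "bayes_factor_directional",
    "prior_sensitivity",
    "PriorSensitivityResult",
]

logger = logging.getLogger(__name__)

DEFAULT_MU0 = 75.0
DEFAULT_MIN_N = 3


@dataclass
class PSMap:
    """A per-voxel statistic map with its validity mask and provenance.

    ``kind`` is ``"p"`` (one-sided p-value), ``"bf"`` (BF10) or ``"lmm"``
    (two-sided p in ``stat`` plus the fixed-effect ``slope``). The statistic
    is NaN exactly where ``valid_mask`` is False.
    """

    grid: VoxelGrid
    kind: str
    stat: np.ndarray
    valid_mask: np.ndarray
    slope: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("p", "bf", "lmm"):
            raise TypeError(f"unknown PSMap kind {self.kind!r}")

    @property
    def method(self) -> str:
        return self.meta.get("method", self.kind)


# ---------------------------------------------------------------------------
# Valid-voxel bookkeeping shared by the map builders and the permutation
# correction: observations are re-indexed onto the compact set of voxels
# with at least ``min_n`` observations.
# ---------------------------------------------------------------------------

@dataclass
class _Prep:
    voxels: np.ndarray       # flat indices of valid voxels, ascending
    obs_compact: np.ndarray  # per kept observation: index into ``voxels``
    obs_record: np.ndarray   # per kept observation: record index
    n_per_voxel: np.ndarray  # observation count per valid voxel
    min_n: int


def _prepare(stack: VoxelStack, min_n: int) -> _Prep:
    n_vox = stack.grid.n_voxels
    n_all = np.bincount(stack.obs_voxel, minlength=n_vox)
    voxels = np.flatnonzero(n_all >= min_n)
    lookup = np.full(n_vox, -1, dtype=np.int64)
    lookup[voxels] = np.arange(voxels.size)
    compact = lookup[stack.obs_voxel]
    keep = compact >= 0
    return _Prep(
        voxels=voxels,
        obs_compact=compact[keep],
        obs_record=stack.obs_record[keep],
        n_per_voxel=n_all[voxels],
        min_n=min_n,
    )


def _counts_matrix(prep: _Prep, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts of each distinct improvement value per valid voxel.

    Returns ``(values, counts)`` with ``counts[v, u]`` the number of
    observations of ``values[u]`` at compact voxel ``v``.
    """
    values, code = np.unique(labels, return_inverse=True)
    obs_code = code[prep.obs_record]
    flat = prep.obs_compact * values.size + obs_code
    counts = np.bincount(flat, minlength=prep.voxels.size * values.size)
    return values, counts.reshape(prep.voxels.size, values.size)


def _fill_map(grid: VoxelGrid, voxels: np.ndarray, per_voxel: np.ndarray) -> np.ndarray:
    out = np.full(grid.n_voxels, np.nan)
    out[voxels] = per_voxel
    return out.reshape(grid.shape)


# ---------------------------------------------------------------------------
# t-test map
# ---------------------------------------------------------------------------

def t_pvalue(sample, mu0: float = DEFAULT_MU0) -> float:
    """One-sided one-sample t-test p-value for H1: mean >= mu0.

    Degenerate zero-variance samples follow the map convention: p = 0 when
    the mean exceeds mu0, p = 1 otherwise (the discrete rating scale makes
    all-equal samples common and they carry real evidence).
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    s1, s2 = x.sum(), np.sum(x * x)
    return float(_t_p_from_moments(np.array([n]), np.array([s1]), np.array([s2]), mu0)[0])


def _t_p_from_moments(n: np.ndarray, s1: np.ndarray, s2: np.ndarray, mu0: float) -> np.ndarray:
    n = n.astype(float)
    mean = s1 / n
    var = np.maximum(s2 - n * mean**2, 0.0) / np.maximum(n - 1, 1)
    scale = np.maximum(s2 / n, 1.0)
    degenerate = var <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - mu0) / np.sqrt(var / n)
    p = np.empty_like(mean)
    ok = ~degenerate
    p[ok] = stats.t.sf(t[ok], n[ok] - 1)
    p[degenerate] = np.where(mean[degenerate] > mu0, 0.0, 1.0)
    return p


def _t_pvalues(prep: _Prep, labels: np.ndarray, mu0: float) -> np.ndarray:
    imp = labels[prep.obs_record]
    m = prep.voxels.size
    s1 = np.bincount(prep.obs_compact, weights=imp, minlength=m)
    s2 = np.bincount(prep.obs_compact, weights=imp * imp, minlength=m)
    return _t_p_from_moments(prep.n_per_voxel, s1, s2, mu0)


def tmap(stack: VoxelStack, mu0: float = DEFAULT_MU0, min_n: int = DEFAULT_MIN_N) -> PSMap:
    """One-sided one-sample t-test map (H1: mean improvement >= ``mu0``)."""
    prep = _prepare(stack, min_n)
    p = _t_pvalues(prep, stack.record_improvement, mu0)
    valid = np.zeros(stack.grid.n_voxels, dtype=bool)
    valid[prep.voxels] = True
    return PSMap(
        grid=stack.grid, kind="p",
        stat=_fill_map(stack.grid, prep.voxels, p),
        valid_mask=valid.reshape(stack.grid.shape),
        meta={"method": "t", "mu0": mu0, "min_n": min_n, "alpha": 0.05,
              "improvement_threshold": mu0},
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank map
# ---------------------------------------------------------------------------

def _wilcoxon_groups(values: np.ndarray, counts: np.ndarray, mu0: float):
    """Pratt midranks by |difference| group.

    Returns (doubled midrank, multiplicity, is_positive) per non-zero group;
    zeros are ranked first (smallest |d|) and then dropped. Values with the
    same |difference| on opposite sides of mu0 share one midrank group.
    """
    entries = []  # (|d| rounded, sign, count)
    for v, c in zip(values.tolist(), counts.tolist()):
        if c > 0:
            d = v - mu0
            entries.append((round(abs(d), 9), d > 0, int(c)))
    entries.sort(key=lambda e: e[0])
    groups = []
    offset = 0
    i = 0
    while i < len(entries):
        j = i
        while j < len(entries) and entries[j][0] == entries[i][0]:
            j += 1
        m = sum(e[2] for e in entries[i:j])
        rank2 = 2 * offset + m + 1  # doubled midrank: 2*(offset + (m+1)/2)
        if entries[i][0] > 1e-9:
            for e in entries[i:j]:
                groups.append((rank2, e[2], e[1]))
        offset += m
        i = j
    return groups


def _exact_signed_rank_sf(groups, w2: float) -> float:
    """P(W+ >= w2/2) by dynamic programming over sign assignments.

    ``groups`` are (doubled midrank, multiplicity, _) of the non-zero
    differences; each observation is independently positive or negative
    with probability 1/2 under the null.
    """
    total = sum(r * m for r, m, _ in groups)
    coef = np.zeros(total + 1)
    coef[0] = 1.0
    for r, m, _ in groups:
        kernel = np.zeros(r * m + 1)
        ks = np.arange(m + 1)
        kernel[r * ks] = np.exp(
            gammaln(m + 1) - gammaln(ks + 1) - gammaln(m - ks + 1)
        ).round()
        coef = np.convolve(coef, kernel)
    n_nz = sum(m for _, m, _ in groups)
    w2i = int(np.ceil(w2 - 1e-9))
    return float(coef[w2i:].sum() / 2.0**n_nz)


def wilcoxon_p_from_counts(values: np.ndarray, counts: np.ndarray,
                           mu0: float = DEFAULT_MU0, exact_max_n: int = 25) -> float:
    """One-sided signed-rank p (H1: location >= mu0) for a counted sample."""
    groups = _wilcoxon_groups(values, counts, mu0)
    if not groups:
        return 1.0  # all differences zero: no evidence
    w2 = float(sum(r * m for r, m, pos in groups if pos))
    n_nz = sum(m for _, m, _ in groups)
    if n_nz <= exact_max_n:
        return _exact_signed_rank_sf(groups, w2)
    mean2 = sum(r * m for r, m, _ in groups) / 2.0
    var2 = sum(r * r * m for r, m, _ in groups) / 4.0
    z = (w2 - mean2 - 0.5) / math.sqrt(var2)
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def wilcoxon_pvalue(sample, mu0: float = DEFAULT_MU0, exact_max_n: int = 25) -> float:
    """One-sided one-sample Wilcoxon signed-rank p-value for H1: location >= mu0.

    Zero differences are handled by the Pratt rule (ranked, then dropped);
    tied |differences| receive midranks. The null distribution is exact
    (full enumeration via convolution) for up to ``exact_max_n`` non-zero
    differences, else a normal approximation with tie-aware variance and
    continuity correction.
    """
    x = np.asarray(sample, dtype=float)
    values, counts = np.unique(x, return_counts=True)
    return wilcoxon_p_from_counts(values, counts, mu0, exact_max_n)


def _w_pvalues(prep: _Prep, labels: np.ndarray, mu0: float,
               cache: dict | None = None) -> np.ndarray:
    values, counts = _counts_matrix(prep, labels)
    uniq, inverse = np.unique(counts, axis=0, return_inverse=True)
    if cache is None:
        cache = {}
    vkey = values.tobytes()
    p_uniq = np.empty(uniq.shape[0])
    for i, row in enumerate(uniq):
        key = (vkey, row.tobytes())
        p = cache.get(key)
        if p is None:
            p = wilcoxon_p_from_counts(values, row, mu0)
            cache[key] = p
        p_uniq[i] = p
    return p_uniq[inverse]


def wmap(stack: VoxelStack, mu0: float = DEFAULT_MU0, min_n: int = DEFAULT_MIN_N) -> PSMap:
    """One-sided Wilcoxon signed-rank map (H1: median improvement >= ``mu0``)."""
    prep = _prepare(stack, min_n)
    p = _w_pvalues(prep, stack.record_improvement, mu0)
    valid = np.zeros(stack.grid.n_voxels, dtype=bool)
    valid[prep.voxels] = True
    return PSMap(
        grid=stack.grid, kind="p",
        stat=_fill_map(stack.grid, prep.voxels, p),
        valid_mask=valid.reshape(stack.grid.shape),
        meta={"method": "wilcoxon", "mu0": mu0, "min_n": min_n, "alpha": 0.05,
              "improvement_threshold": mu0},
    )


# ---------------------------------------------------------------------------
# Directional Bayesian one-sample test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Prior on the mean improvement and the response scale.

    The location prior is centred on the tested threshold (default normal
    with scale 25, one rating-scale step) so that a sample symmetric about
    the threshold yields BF10 = 1. The residual scale sigma carries a
    half-Cauchy prior; sigma is floored at one rating point because the
    observed scores are discrete.
    """

    family: str = "normal"  # normal | cauchy | student_t
    loc: float = DEFAULT_MU0
    scale: float = 25.0
    df: float = 5.0
    sigma_scale: float = 25.0
    sigma_min: float = 1.0
    sigma_max: float = 300.0

    def mu_logpdf(self, mu: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            return stats.norm.logpdf(mu, self.loc, self.scale)
        if self.family == "cauchy":
            return stats.cauchy.logpdf(mu, self.loc, self.scale)
        if self.family == "student_t":
            return stats.t.logpdf(mu, self.df, self.loc, self.scale)
        raise TypeError(f"unknown prior family {self.family!r}")

    def sigma_logpdf(self, sigma: np.ndarray) -> np.ndarray:
        return stats.halfcauchy.logpdf(sigma, scale=self.sigma_scale)

    def prior_log_odds(self, mu0: float) -> float:
        """log [P(mu >= mu0) / P(mu < mu0)] under the location prior."""
        dist = {
            "normal": stats.norm(self.loc, self.scale),
            "cauchy": stats.cauchy(self.loc, self.scale),
            "student_t": stats.t(self.df, self.loc, self.scale),
        }[self.family]
        upper = dist.sf(mu0)
        return float(np.log(upper) - np.log1p(-upper))


def _quad_grids(values: np.ndarray, counts: np.ndarray, mu0: float, prior: PriorSpec,
                n_mu: int = 321, n_sigma: int = 41):
    n = counts.sum()
    mean = float(np.dot(values, counts) / n)
    var = float(np.dot(counts, (values - mean) ** 2) / max(n - 1, 1))
    sem = np.sqrt(max(var, 1.0) / n)
    half = max(4.0 * prior.scale, abs(mean - mu0) + 8.0 * sem + 20.0)
    mu = mu0 + np.linspace(-half, half, n_mu)  # odd n_mu: centre node at mu0
    log_sigma = np.linspace(np.log(prior.sigma_min), np.log(prior.sigma_max), n_sigma)
    return mu, np.exp(log_sigma)


def _trapz_logweights(x: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    return np.log(w)


def _directional_log_odds(values: np.ndarray, counts: np.ndarray, mu0: float,
                          prior: PriorSpec, n_mu: int = 321, n_sigma: int = 41,
                          ) -> tuple[float, float]:
    """(posterior log-odds, posterior mean) of mu >= mu0 by 2-D quadrature.

    The mu grid is symmetric about mu0 with a node exactly at mu0 whose
    trapezoid weight splits evenly between the two half-lines, so a
    likelihood symmetric about mu0 gives exactly equal half-masses.
    """
    mu, sigma = _quad_grids(values, counts, mu0, prior, n_mu, n_sigma)
    log_wmu = _trapz_logweights(mu)
    log_wsig = _trapz_logweights(np.log(sigma)) + np.log(sigma)  # d sigma = sigma d ln sigma

    n = counts.sum()
    # log joint on the (mu, sigma) grid, likelihood via the 5-level counts
    sq = ((values[None, :] - mu[:, None]) ** 2 * counts[None, :]).sum(axis=1)  # (n_mu,)
    loglik = (-n * np.log(sigma)[None, :]
              - 0.5 * n * np.log(2 * np.pi)
              - sq[:, None] / (2.0 * sigma[None, :] ** 2))
    logjoint = (loglik + prior.mu_logpdf(mu)[:, None] + prior.sigma_logpdf(sigma)[None, :]
                + log_wmu[:, None] + log_wsig[None, :])

    per_mu = logsumexp(logjoint, axis=1)
    centre = n_mu // 2  # mu[centre] == mu0
    log_half = np.log(0.5)
    upper = logsumexp(np.append(per_mu[centre + 1:], per_mu[centre] + log_half))
    lower = logsumexp(np.append(per_mu[:centre], per_mu[centre] + log_half))
    total = np.logaddexp(upper, lower)
    post_mean = float(np.sum(mu * np.exp(per_mu - total)))
    return float(upper - lower), post_mean


def _mcmc_log_odds(values: np.ndarray, counts: np.ndarray, mu0: float, prior: PriorSpec,
                   seed: int, n_walkers: int = 24, n_steps: int = 1500,
                   n_burn: int = 500) -> float:
    """Posterior log-odds of mu >= mu0 estimated by ensemble MCMC.

    With the normal location prior, mu | sigma is conjugate-normal, so the
    directional probability is Rao-Blackwellized: the exact conditional
    tail probability is averaged over the sigma chain, which resolves far
    smaller tail masses than counting mu samples. Non-normal priors fall
    back to counting mu samples with 1/2-count smoothing.
    """
    import emcee

    n = counts.sum()

    def log_prob(theta):
        m, log_s = theta
        s = np.exp(log_s)
        if not (prior.sigma_min / 4 <= s <= prior.sigma_max * 4):
            return -np.inf
        loglik = (-n * log_s - 0.5 * n * np.log(2 * np.pi)
                  - np.dot(counts, (values - m) ** 2) / (2 * s * s))
        return (loglik + float(prior.mu_logpdf(np.array([m]))[0])
                + float(prior.sigma_logpdf(np.array([s]))[0]) + log_s)

    rng = np.random.default_rng(seed)
    mean = float(np.dot(values, counts) / n)
    sd = float(np.sqrt(max(np.dot(counts, (values - mean) ** 2) / max(n - 1, 1), 1.0)))
    p0 = np.column_stack([
        rng.normal(mean, max(sd / np.sqrt(n), 1.0), n_walkers),
        np.log(np.clip(rng.normal(sd, sd / 2, n_walkers), prior.sigma_min, prior.sigma_max)),
    ])
    sampler = emcee.EnsembleSampler(n_walkers, 2, log_prob)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    if prior.family == "normal":
        sigmas = np.exp(chain[:, 1])
        prec = 1.0 / prior.scale**2 + n / sigmas**2
        cond_mean = (prior.loc / prior.scale**2
                     + n * mean / sigmas**2) / prec
        p_up = stats.norm.sf((mu0 - cond_mean) * np.sqrt(prec)).mean()
        p_up = min(max(p_up, 1e-300), 1 - 1e-16)
        return float(np.log(p_up) - np.log1p(-p_up))
    mus = chain[:, 0]
    # +1/2 smoothing keeps the odds finite when one side has no samples
    n_up = float(np.sum(mus >= mu0)) + 0.5
    n_dn = float(np.sum(mus < mu0)) + 0.5
    return float(np.log(n_up) - np.log(n_dn))


def bayes_factor_directional(sample, mu0: float = DEFAULT_MU0,
                             prior: PriorSpec | None = None,
                             backend: str = "quadrature",
                             seed: int | None = None) -> float:
    """Directional Bayes factor BF10 for H1: mean >= mu0 vs H0: mean < mu0.

    Computed as posterior odds divided by prior odds under an encompassing
    prior on the mean (the two hypotheses share the prior, truncated to
    their half-lines). The default backend is deterministic numerical
    integration; ``backend="mcmc"`` uses a seeded ensemble sampler instead.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise CohortValidationError("sample must be non-empty and finite")
    prior = prior or PriorSpec(loc=mu0)
    values, counts = np.unique(x, return_counts=True)
    if backend == "quadrature":
        post_lo, _ = _directional_log_odds(values, counts, mu0, prior)
    elif backend == "mcmc":
        if seed is None:
            raise CohortValidationError("the MCMC backend requires a seed")
        post_lo = _mcmc_log_odds(values, counts, mu0, prior, seed)
    else:
        raise TypeError(f"unknown backend {backend!r}")
    return float(np.exp(post_lo - prior.prior_log_odds(mu0)))


def bmap(stack: VoxelStack, mu0: float = DEFAULT_MU0,
         prior: PriorSpec | None = None, min_n: int = DEFAULT_MIN_N,
         backend: str = "quadrature", seed: int | None = None) -> PSMap:
    """Directional Bayesian one-sample map: BF10 per valid voxel."""
    prior = prior or PriorSpec(loc=mu0)
    prep = _prepare(stack, min_n)
    values, counts = _counts_matrix(prep, stack.record_improvement)
    uniq, inverse = np.unique(counts, axis=0, return_inverse=True)
    prior_lo = prior.prior_log_odds(mu0)
    bf_uniq = np.empty(uniq.shape[0])
    for i, row in enumerate(uniq):
        if backend == "quadrature":
            post_lo, _ = _directional_log_odds(values, row, mu0, prior)
        else:
            post_lo = _mcmc_log_odds(values, row, mu0, prior, seed=(seed or 0) + i)
        bf_uniq[i] = np.exp(min(post_lo - prior_lo, 700.0))
    bf = bf_uniq[inverse]
    valid = np.zeros(stack.grid.n_voxels, dtype=bool)
    valid[prep.voxels] = True
    return PSMap(
        grid=stack.grid, kind="bf",
        stat=_fill_map(stack.grid, prep.voxels, bf),
        valid_mask=valid.reshape(stack.grid.shape),
        meta={"method": "bayes", "mu0": mu0, "min_n": min_n, "bf_threshold": 10.0,
              "prior": vars(prior), "backend": backend, "seed": seed},
    )


@dataclass
class PriorSensitivityResult:
    """Per (sample, prior) Bayes factors plus a per-sample ratio summary."""

    table: "object"    # pandas.DataFrame: sample, prior, bf10, posterior_mean, ...
    summary: "object"  # pandas.DataFrame: sample, max_bf_ratio, same_classification


def prior_sensitivity(samples: Iterable, priors: dict[str, PriorSpec] | None = None,
                      mu0: float = DEFAULT_MU0, bf_threshold: float = 10.0,
                      ) -> PriorSensitivityResult:
    """Compare BF10 across prior families on a set of voxel samples.

    For each sample x prior: BF10, posterior mean and a quadrature
    refinement diagnostic (absolute change in log BF when the mu grid is
    halved). The summary reports the max pairwise BF ratio per sample and
    whether all priors agree on the BF >= threshold classification.
    """
    import pandas as pd

    if priors is None:
        priors = {
            "normal": PriorSpec(family="normal", loc=mu0),
            "cauchy": PriorSpec(family="cauchy", loc=mu0),
            "student_t": PriorSpec(family="student_t", loc=mu0),
        }
    rows = []
    for s_idx, sample in enumerate(samples):
        x = np.asarray(sample, dtype=float)
        values, counts = np.unique(x, return_counts=True)
        for name, prior in priors.items():
            post_lo, post_mean = _directional_log_odds(values, counts, mu0, prior)
            post_lo_coarse, _ = _directional_log_odds(values, counts, mu0, prior, n_mu=161)
            log_bf = post_lo - prior.prior_log_odds(mu0)
            rows.append({
                "sample": s_idx,
                "prior": name,
                "bf10": float(np.exp(min(log_bf, 700.0))),
                "log_bf10": float(log_bf),
                "posterior_mean": post_mean,
                "quad_refinement_dlogbf": float(abs(post_lo - post_lo_coarse)),
            })
    table = pd.DataFrame(rows)
    summaries = []
    for s_idx, grp in table.groupby("sample"):
        log_bfs = grp["log_bf10"].to_numpy()
        summaries.append({
            "sample": s_idx,
            "max_bf_ratio": float(np.exp(min(log_bfs.max() - log_bfs.min(), 700.0))),
            "same_classification": bool(
                np.all(grp["bf10"] >= bf_threshold) or np.all(grp["bf10"] < bf_threshold)
            ),
        })
    return PriorSensitivityResult(table=table, summary=pd.DataFrame(summaries))


# ---------------------------------------------------------------------------
# Linear mixed model map
# ---------------------------------------------------------------------------

def _fit_lmm_voxel(imp: np.ndarray, ef: np.ndarray, pat: np.ndarray):
    """Fit improvement ~ EF with patient random effects.

    Fallback ladder: random slopes + intercepts -> random intercepts ->
    ordinary least squares. Returns (slope, two-sided p, backend) or None.
    """
    import statsmodels.api as sm

    exog = np.column_stack([np.ones_like(ef), ef])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for re_formula in ("slope", "intercept"):
            try:
                exog_re = exog if re_formula == "slope" else exog[:, :1]
                model = sm.MixedLM(imp, exog, groups=pat, exog_re=exog_re)
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
                slope, p = float(res.fe_params[1]), float(res.pvalues[1])
                if np.isfinite(slope) and np.isfinite(p):
                    return slope, p, f"mixedlm_{re_formula}"
            except Exception:
                continue
        try:
            res = sm.OLS(imp, exog).fit()
            slope, p = float(res.params[1]), float(res.pvalues[1])
            if np.isfinite(slope) and np.isfinite(p):
                return slope, p, "ols"
        except Exception:
            pass
    return None


def lmm_map(stack: VoxelStack, candidate_mask: np.ndarray | None = None,
            min_patients: int = 3) -> PSMap:
    """Per-voxel linear mixed model: improvement ~ EF, patient random effects.

    Fit only on candidate voxels (default: every voxel with observations)
    with at least ``min_patients`` distinct patients and non-constant EF.
    The statistic is the two-sided p-value of the fixed EF slope; the slope
    itself is carried alongside so the selection rule (p < 0.05 AND
    slope > 0) can be applied downstream.
    """
    grid = stack.grid
    if candidate_mask is None:
        candidate_mask = stack.n_map > 0
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    if candidate_mask.shape != grid.shape:
        raise GridMismatchError(
            f"candidate mask shape {candidate_mask.shape} != grid {grid.shape}"
        )
    cand_flat = np.flatnonzero(candidate_mask.ravel())

    order = np.argsort(stack.obs_voxel, kind="stable")
    sorted_vox = stack.obs_voxel[order]
    starts = np.searchsorted(sorted_vox, cand_flat, side="left")
    ends = np.searchsorted(sorted_vox, cand_flat, side="right")
    imp_all = stack.obs_improvement[order]
    ef_all = stack.obs_ef[order]
    pat_all = stack.obs_patient[order]

    p_out = np.full(grid.n_voxels, np.nan)
    slope_out = np.full(grid.n_voxels, np.nan)
    valid = np.zeros(grid.n_voxels, dtype=bool)
    backends: dict[str, int] = {}
    for v, a, b in zip(cand_flat, starts, ends):
        imp, ef, pat = imp_all[a:b], ef_all[a:b], pat_all[a:b]
        if np.unique(pat).size < min_patients or np.ptp(ef) < 1e-9:
            continue
        fit = _fit_lmm_voxel(imp, ef, pat)
        if fit is None:
            continue
        slope_out[v], p_out[v], backend = fit[0], fit[1], fit[2]
        backends[backend] = backends.get(backend, 0) + 1
        valid[v] = True
    logger.info("lmm_map: %d candidate voxels, %d fitted (%s)",
                cand_flat.size, int(valid.sum()), backends)
    return PSMap(
        grid=grid, kind="lmm",
        stat=p_out.reshape(grid.shape),
        valid_mask=valid.reshape(grid.shape),
        slope=slope_out.reshape(grid.shape),
        meta={"method": "lmm", "min_patients": min_patients, "alpha": 0.05,
              "fit_backends": backends},
    )
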