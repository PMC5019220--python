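"""Mismatch distributions and sudden-expansion demographic inference.

Under an instantaneous expansion theta0 -> theta1 that happened tau
mutational units ago, the probability that a random pair of sequences
differs at j sites is

    F_j(tau, theta0, theta1)
        = Fhat_j(theta1)
        + exp(-tau (theta1 + 1) / theta1)
          * sum_{i<=j} tau^{j-i}/(j-i)! * (Fhat_i(theta0) - Fhat_i(theta1)),

where Fhat_j(theta) = theta^j / (1+theta)^(j+1) is the constant-size
equilibrium (geometric) distribution.  Parameters are fitted by least
squares between the observed and model mismatch frequencies; goodness of
fit (SSD, raggedness) and the confidence interval of tau come from a
parametric bootstrap that re-simulates samples under the fitted model and
refits each.  The expansion is dated as t = tau / (2 mu L) with mu the
per-site per-year mutation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .alignment import Alignment
from .diversity import _pairwise_raw_diffs, InsufficientSampleError
from .simulate import SuddenExpansion, ConstantSize, _panmictic_branches, \
    _sequences_from_genealogy


@dataclass
class MismatchObservation:
    """Histogram of pairwise differences over all C(n,2) pairs."""

    counts: np.ndarray
    n: int

    @property
    def total_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1


def observed_mismatch(aln: Alignment) -> MismatchObservation:
    if aln.n < 2:
        raise InsufficientSampleError("mismatch distribution needs n >= 2")
    d = np.rint(_pairwise_raw_diffs(aln)).astype(int)
    return MismatchObservation(np.bincount(d).astype(float), aln.n)


def _equilibrium(theta: float, j: np.ndarray) -> np.ndarray:
    if theta == 0:
        return (j == 0).astype(float)
    return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, d_max: int
) -> np.ndarray:
    """Model mismatch probabilities F_0..F_{d_max} (tail truncated)."""
    if min(tau, theta0, theta1) < 0:
        raise ValueError("mismatch-model parameters must be non-negative")
    j = np.arange(d_max + 1)
    if tau == 0:
        return _equilibrium(theta0, j)
    if theta1 == 0:
        return (j == 0).astype(float)
    diff = _equilibrium(theta0, j) - _equilibrium(theta1, j)
    with np.errstate(divide="ignore"):
        logpw = j * np.log(tau) - gammaln(j + 1)
    pw = np.exp(logpw)
    conv = np.convolve(pw, diff)[: d_max + 1]
    return _equilibrium(theta1, j) + np.exp(-tau * (theta1 + 1) / theta1) * conv


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness index: sum of squared successive steps of
    the frequency profile, with implicit zeros flanking the range."""
    x = np.concatenate(([0.0], np.asarray(freqs, float), [0.0]))
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    rg: float
    degenerate: bool = False
    p_ssd: float | None = None
    p_rg: float | None = None
    tau_ci: tuple[float, float] | None = None
    tau_boot: np.ndarray | None = field(default=None, repr=False)

    def time_years(self, mu_site_per_year: float, L: int) -> float:
        return expansion_time(self.tau, mu_site_per_year, L)

    def time_ci_years(
        self, mu_site_per_year: float, L: int
    ) -> tuple[float, float] | None:
        if self.tau_ci is None:
            return None
        lo, hi = self.tau_ci
        return (
            expansion_time(lo, mu_site_per_year, L),
            expansion_time(hi, mu_site_per_year, L),
        )


def _ssd(fobs: np.ndarray, tau: float, th0: float, th1: float) -> float:
    return float(np.sum((fobs - expected_mismatch(tau, th0, th1, len(fobs) - 1)) ** 2))


def _grid_search(fobs: np.ndarray) -> tuple[float, float, float, float]:
    """Coarse grid over (tau, theta0, theta1) minimising SSD (vectorised)."""
    d_max = len(fobs) - 1
    j = np.arange(d_max + 1)
    taus = np.linspace(0.0, 2.0 * max(d_max, 1), 25)
    theta0s = np.array([0.0, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0])
    theta1s = np.concatenate(
        [np.geomspace(0.1, 1e4, 12), [np.sum(fobs * j)]]  # include k-hat
    )
    eq = {th: _equilibrium(th, j) for th in np.concatenate([theta0s, theta1s])}
    best = (np.inf, 0.0, 0.0, max(float(np.sum(fobs * j)), 1e-6))
    # tau = 0 candidates (pure equilibrium, theta1 irrelevant)
    for th0 in np.concatenate([theta0s, [float(np.sum(fobs * j))]]):
        ssd = float(np.sum((fobs - _equilibrium(th0, j)) ** 2))
        if ssd < best[0]:
            best = (ssd, 0.0, float(th0), max(float(th0), 1e-6))
    for tau in taus[1:]:
        with np.errstate(divide="ignore"):
            pw = np.exp(j * np.log(tau) - gammaln(j + 1))
        # lower-triangular Toeplitz so conv = T @ diff
        T = np.zeros((d_max + 1, d_max + 1))
        for r in range(d_max + 1):
            T[r, : r + 1] = pw[r::-1]
        for th1 in theta1s:
            if th1 <= 0:
                continue
            decay = np.exp(-tau * (th1 + 1) / th1)
            base = eq[th1]
            for th0 in theta0s[theta0s <= th1]:
                F = base + decay * (T @ (eq[th0] - base))
                ssd = float(np.sum((fobs - F) ** 2))
                if ssd < best[0]:
                    best = (ssd, float(tau), float(th0), float(th1))
    return best


def fit_expansion(obs: MismatchObservation) -> ExpansionFit:
    """Least-squares fit of the sudden-expansion model to an observed
    mismatch distribution (coarse grid + Nelder-Mead refinement)."""
    fobs = obs.frequencies
    rg = raggedness(fobs)
    if obs.d_max == 0:
        return ExpansionFit(0.0, 0.0, 0.0, 0.0, rg, degenerate=True)

    ssd0, tau0, th00, th10 = _grid_search(fobs)

    # search box: theta0 in [0, 20], theta1 in [theta0, 1e4], tau bounded by
    # twice the observed range (boundary-prone theta1 mirrors the behaviour
    # of standard mismatch software on flat likelihood surfaces)
    tau_max = 2.0 * obs.d_max + 10.0

    def objective(x: np.ndarray) -> float:
        tau, th0, dth = x
        if tau < 0 or th0 < 0 or dth < 0 or tau > tau_max or th0 > 20 or th0 + dth > 1e4:
            return 1e6
        return _ssd(fobs, tau, th0, th0 + dth)

    res = minimize(
        objective,
        x0=np.array([tau0, th00, max(th10 - th00, 0.0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    if res.fun <= ssd0:
        tau, th0, dth = res.x
        fit = ExpansionFit(
            max(float(tau), 0.0),
            max(float(th0), 0.0),
            max(float(th0), 0.0) + max(float(dth), 0.0),
            float(res.fun),
            rg,
        )
    else:  # keep the grid point if the simplex wandered off
        fit = ExpansionFit(tau0, th00, th10, ssd0, rg)
    if fit.tau == 0 and fit.theta0 == 0:
        fit.degenerate = True
    return fit


def gof_bootstrap(
    aln_or_n: Alignment | int,
    fit: ExpansionFit,
    obs: MismatchObservation,
    n_reps: int = 1000,
    L: int | None = None,
    seed: int | None = 0,
    finite_sites: bool = True,
) -> ExpansionFit:
    """Parametric bootstrap of the sudden-expansion fit.

    Simulates ``n_reps`` coalescent samples of the same size under the
    fitted (tau, theta0, theta1), refits each, and fills in
    P(SSD_sim >= SSD_obs), P(rg_sim >= rg_obs) and the 2.5-97.5 percentile
    interval of the refitted tau.  With ``finite_sites`` mutations are
    scattered over L sites (recurrent hits possible), matching the data-
    generating assumptions of the rest of the package.
    """
    n = aln_or_n if isinstance(aln_or_n, int) else aln_or_n.n
    if L is None:
        L = aln_or_n.length if isinstance(aln_or_n, Alignment) else 294
    rng = np.random.default_rng(seed)
    if fit.theta1 <= 0 or (fit.tau == 0 and fit.theta0 == 0):
        demo: ConstantSize | SuddenExpansion = ConstantSize(max(fit.theta0, 0.0))
    elif fit.tau == 0:
        demo = ConstantSize(fit.theta0)
    else:
        demo = SuddenExpansion(min(fit.theta0, fit.theta1), fit.theta1, fit.tau)
    ssds = np.empty(n_reps)
    rgs = np.empty(n_reps)
    taus = np.empty(n_reps)
    for r in range(n_reps):
        branches = _panmictic_branches(n, demo.epochs(), rng)
        if finite_sites:
            seqs, _ = _sequences_from_genealogy(branches, n, L, rng)
            diffs = _hamming_condensed(seqs)
        else:
            masks = np.array([b.mask for b in branches])
            w = rng.poisson([(b.t1 - b.t0) / 2.0 for b in branches]).astype(float)
            e = w @ masks
            C = (masks.T * w) @ masks
            dm = e[:, None] + e[None, :] - 2 * C
            diffs = dm[np.triu_indices(n, 1)]
        counts = np.bincount(np.rint(diffs).astype(int)).astype(float)
        sim_obs = MismatchObservation(counts, n)
        sim_fit = fit_expansion(sim_obs)
        ssds[r] = sim_fit.ssd
        rgs[r] = sim_fit.rg
        taus[r] = sim_fit.tau
    fit.p_ssd = float((np.sum(ssds >= fit.ssd) + 1) / (n_reps + 1))
    fit.p_rg = float((np.sum(rgs >= fit.rg) + 1) / (n_reps + 1))
    fit.tau_ci = (float(np.percentile(taus, 2.5)), float(np.percentile(taus, 97.5)))
    fit.tau_boot = taus
    return fit


def _hamming_condensed(seqs: np.ndarray) -> np.ndarray:
    n = seqs.shape[0]
    out = []
    for i in range(n - 1):
        out.append((seqs[i] != seqs[i + 1 :]).sum(axis=1))
    return np.concatenate(out)


def expansion_time(tau: float, mu_site_per_year: float, L: int) -> float:
    """Years since expansion: t = tau / (2 mu L).

    mu is the per-site per-year mutation rate; mu*L is the per-sequence
    rate, and tau is in units of (pairwise) mutational time.
    """
    if mu_site_per_year <= 0 or L <= 0:
        raise ValueError("mutation rate and sequence length must be positive")
    return tau / (2.0 * mu_site_per_year * L)


#: per-site per-year control-region mutation rate used for dating
DEFAULT_MU_SITE_PER_YEAR = 0.32e-6


def fit_population(
    aln: Alignment,
    n_boot: int = 1000,
    mu_site_per_year: float = DEFAULT_MU_SITE_PER_YEAR,
    seed: int | None = 0,
) -> tuple[ExpansionFit, MismatchObservation]:
    """Full per-population workflow: observe, fit, bootstrap."""
    obs = observed_mismatch(aln)
    fit = fit_expansion(obs)
    if n_boot:
        gof_bootstrap(aln, fit, obs, n_reps=n_boot, seed=seed)
    return fit, obs
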