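"""Three-component normal emission mixture on adjusted M values.

Adjusted M values under the three binding states are modeled as

    f(m) = p * phi(m; +mu, sigma) + (1 - 2p) * phi(m; 0, sigma)
         + p * phi(m; -mu, sigma)

the middle zero-mean component being common (non-differential) binding and
the symmetric outer components stronger binding in condition 1 (+mu, since
M = ln(x1+c) - ln(x2+c) is positive when condition 1 is higher) and in
condition 2 (-mu). All components share one standard deviation.

Estimation is deliberately not full EM. Because common binding is assumed
to dominate, sigma is estimated robustly from all adjusted M values by the
median absolute deviation (x 1.4826, the consistency constant for the
normal). The remaining pair (p, mu) is then found by a hybrid
moment/maximum-likelihood scheme: the mixture's second moment gives the
constraint

    E[M^2] = 2 p mu^2 + sigma^2,

so for each candidate p on a grid, mu is pinned by the sample second
moment and the log-likelihood is evaluated; the (p, mu) pair maximizing it
wins. Emission probabilities are computed once from the fitted mixture and
stay fixed through HMM training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MAD_NORMAL_CONSTANT = 1.4826

#: states, in index order: stronger in condition 1, common, stronger in condition 2
STATE_NAMES = ("cond1_stronger", "common", "cond2_stronger")


@dataclass
class MixtureParams:
    """p: weight of EACH outer component (middle weight 1-2p); mu: |mean|
    of the outer components; sigma: shared standard deviation."""

    p: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0 < self.p < 0.5:
            raise ValueError("p must lie in (0, 0.5)")
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be > 0")

    @property
    def common_fraction(self) -> float:
        return 1.0 - 2.0 * self.p

    @property
    def means(self) -> np.ndarray:
        """Component means in state order (+mu, 0, -mu)."""
        return np.array([self.mu, 0.0, -self.mu])

    def density(self, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        w = np.array([self.p, 1 - 2 * self.p, self.p])
        return sum(wk * stats.norm.pdf(m, mk, self.sigma)
                   for wk, mk in zip(w, self.means))


@dataclass
class EstimationDiagnostics:
    sample_second_moment: float
    n: int
    grid_points_evaluated: int
    log_likelihood: float
    common_fraction: float


def estimate_sigma_mad(m_values) -> float:
    """sigma-hat = median(|M - median(M)|) * 1.4826.

    Robust to the outer components as long as they are a minority; fatal
    on degenerate input (all values identical).
    """
    m = np.asarray(m_values, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 M values to estimate sigma")
    mad = float(np.median(np.abs(m - np.median(m))))
    if mad == 0.0:
        raise ValueError("all adjusted M values identical; sigma estimate degenerate")
    return mad * MAD_NORMAL_CONSTANT


def mu_from_moment_constraint(p: float, sigma: float, sample_second_moment: float) -> float:
    """Solve 2 p mu^2 + sigma^2 = mu2-hat for mu.

    Raises when the sample second moment does not exceed sigma^2 (no real
    solution: the data carry no excess spread for the outer components).
    """
    if not 0 < p < 0.5:
        raise ValueError("p must lie in (0, 0.5)")
    excess = sample_second_moment - sigma**2
    if excess <= 0:
        raise ValueError("sample second moment <= sigma^2; moment constraint unsatisfiable")
    return float(np.sqrt(excess / (2.0 * p)))


def _grid_log_likelihoods(m: np.ndarray, sigma: float, mu2: float,
                          p_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood at each feasible grid p (mu set by the constraint);
    infeasible points get -inf and mu nan."""
    phi0 = stats.norm.pdf(m, 0.0, sigma)
    lls = np.full(p_grid.size, -np.inf)
    mus = np.full(p_grid.size, np.nan)
    excess = mu2 - sigma**2
    if excess <= 0:
        return lls, mus
    for i, p in enumerate(p_grid):
        mu = np.sqrt(excess / (2.0 * p))
        dens = (p * stats.norm.pdf(m, mu, sigma)
                + (1 - 2 * p) * phi0
                + p * stats.norm.pdf(m, -mu, sigma))
        lls[i] = float(np.sum(np.log(dens)))
        mus[i] = mu
    return lls, mus


def fit_mixture(
    m_values, sigma: float,
    p_grid: np.ndarray | None = None,
) -> tuple[MixtureParams, EstimationDiagnostics]:
    """Grid-search MLE for (p, mu) under the second-moment constraint.

    The default grid runs p = 0.001 ... 0.499 in steps of 0.001; at each p
    the constraint fixes mu, and the full mixture log-likelihood (sigma
    held at its MAD estimate) is evaluated. Returns the arg-max pair with
    diagnostics. Fatal when no grid point is feasible, i.e. the sample
    second moment does not exceed sigma^2 — there is then no detectable
    differential signal.
    """
    m = np.asarray(m_values, dtype=float)
    if p_grid is None:
        p_grid = np.arange(0.001, 0.4995, 0.001)
    mu2 = float(np.mean(m**2))
    lls, mus = _grid_log_likelihoods(m, sigma, mu2, p_grid)
    if not np.isfinite(lls).any():
        raise ValueError(
            "no feasible (p, mu) grid point: sample second moment "
            f"{mu2:.4g} <= sigma^2 {sigma**2:.4g}; no differential signal detectable"
        )
    best = int(np.argmax(lls))
    params = MixtureParams(p=float(p_grid[best]), mu=float(mus[best]), sigma=sigma)
    diag = EstimationDiagnostics(
        sample_second_moment=mu2,
        n=int(m.size),
        grid_points_evaluated=int(np.isfinite(lls).sum()),
        log_likelihood=float(lls[best]),
        common_fraction=params.common_fraction,
    )
    return params, diag


def emission_probabilities(m_values, params: MixtureParams) -> np.ndarray:
    """Per-bin emission densities (e0, e1, e2) under the three states.

    e0 = phi(m; +mu, sigma), e1 = phi(m; 0, sigma), e2 = phi(m; -mu, sigma).
    Returns an (n, 3) array; these are fixed before HMM training starts.
    """
    m = np.asarray(m_values, dtype=float).reshape(-1, 1)
    return stats.norm.pdf(m, params.means.reshape(1, 3), params.sigma)


def check_common_fraction(params: MixtureParams) -> str | None:
    """Warn when the estimated common-binding fraction drops below 50%.

    The model assumes most sites bind similarly in both conditions; when
    1 - 2p < 0.5 (strictly) that assumption is doubtful and results should
    be interpreted with care. Analysis continues either way.
    """
    if params.common_fraction < 0.5:
        msg = (
            f"estimated proportion of common binding sites with similar binding "
            f"strength is {params.common_fraction:.1%} (< 50%); the assumption "
            "that most sites are unchanged between conditions may not hold"
        )
        logger.warning(msg)
        return msg
    return None
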