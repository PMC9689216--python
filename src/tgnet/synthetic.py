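"""Ground-truthed synthetic inputs for the whole pipeline.

A :class:`Scenario` holds phase-structured true parameters: one symmetric
positive-definite precision matrix Theta* and linear term eta* per phase,
shared by all periods of that phase, with change points at the phase
boundaries.  Observations are drawn from the truncated multivariate Gaussian
TN(mu, Sigma) on the non-negative orthant, Sigma = Theta*^{-1}, mu = Sigma
eta*, by single-chain Gibbs sampling: the full conditional of coordinate j
given the rest is the univariate normal with mean
(eta_j - sum_{l != j} theta_jl y_l)/theta_jj and variance 1/theta_jj,
truncated to [0, inf).

Positive definiteness of generated Theta* is certified by diagonal
dominance: off-diagonal support is random with entries +/- effect, and each
diagonal entry is set to the absolute row sum of the off-diagonals plus one.

:func:`make_corpus` turns scenario draws into a synthetic document set
(keyword counts Poisson with rate proportional to the latent TN value,
padded with filler tokens) so the text-processing stage can be exercised
end to end without any external data.
"""

from __future__ import annotations


from dataclasses import dataclass
from datetime import date

import numpy as np
import yaml
from scipy.special import ndtr, ndtri

from .corpus import Document
from .tgm import TGMParams

__all__ = ["Scenario", "make_scenario", "sample_tn", "sample_panel", "make_corpus"]


@dataclass
class Scenario:
    """Phase-structured ground truth for M ordered periods of dimension p."""

    p: int
    M: int
    change_points: list[int]  # period indices m such that phase ends after m
    theta_true: list[np.ndarray]  # one per phase
    eta_true: list[np.ndarray]
    n_per_period: list[int]
    seed: int

    def __post_init__(self) -> None:
        n_phases = len(self.change_points) + 1
        if len(self.theta_true) != n_phases or len(self.eta_true) != n_phases:
            raise ValueError("one (Theta*, eta*) pair per phase required")
        if len(self.n_per_period) != self.M:
            raise ValueError("n_per_period must have length M")
        for T in self.theta_true:
            T = np.asarray(T)
            if not np.allclose(T, T.T):
                raise ValueError("Theta* must be symmetric")
            if np.min(np.linalg.eigvalsh(T)) <= 0:
                raise ValueError("Theta* must be positive definite")

    @property
    def n_phases(self) -> int:
        return len(self.change_points) + 1

    def phase_of(self, m: int) -> int:
        """Phase index (0-based) of period m (1-based)."""
        phase = 0
        for cp in self.change_points:
            if m > cp:
                phase += 1
        return phase

    def phase_ranges(self) -> list[tuple[int, int]]:
        bounds = [0] + list(self.change_points) + [self.M]
        return [(a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])]

    def params_for_period(self, m: int) -> TGMParams:
        ph = self.phase_of(m)
        return TGMParams(self.theta_true[ph], self.eta_true[ph])


def make_scenario(
    p: int = 10,
    M: int = 12,
    n_phases: int = 3,
    edges_per_phase: int = 8,
    effect: float = 1.0,
    seed: int = 0,
    n_per_period: int = 300,
) -> Scenario:
    """Random phase-structured ground truth.

    Each phase gets a fresh random off-diagonal support of ``edges_per_phase``
    entries at +/- ``effect``; diagonals enforce strict diagonal dominance.
    Change points split 1..M into near-equal phases.  eta* is drawn positive
    so the truncated mass is not pushed entirely onto the boundary.
    """
    if n_phases > M:
        raise ValueError("cannot have more phases than periods")
    if effect <= 0:
        raise ValueError("effect must be positive")
    max_edges = p * (p - 1) // 2
    if edges_per_phase > max_edges:
        raise ValueError(f"edges_per_phase exceeds p(p-1)/2 = {max_edges}")
    rng = np.random.default_rng(seed)
    thetas, etas = [], []
    pairs = [(l, j) for l in range(p) for j in range(l + 1, p)]
    for _ in range(n_phases):
        T = np.zeros((p, p))
        chosen = rng.choice(len(pairs), size=edges_per_phase, replace=False)
        for c in chosen:
            l, j = pairs[c]
            val = effect * rng.choice([-1.0, 1.0])
            T[l, j] = T[j, l] = val
        np.fill_diagonal(T, np.abs(T).sum(axis=1) + 1.0)
        thetas.append(T)
        etas.append(rng.uniform(0.5, 1.5, size=p))
    # near-equal phase lengths
    bounds = np.linspace(0, M, n_phases + 1).round().astype(int)
    change_points = [int(b) for b in bounds[1:-1]]
    return Scenario(p, M, change_points, thetas, etas, [n_per_period] * M, seed)


def _truncnorm_lower(rng: np.random.Generator, alpha: float) -> float:
    """Standard normal truncated to [alpha, inf), by inverse survival
    function in the complementary tail (stable for large alpha)."""
    u = rng.random()
    tail = ndtr(-alpha)  # P(Z >= alpha)
    return float(-ndtri((1.0 - u) * tail))


def sample_tn(
    theta: np.ndarray,
    eta: np.ndarray,
    n: int,
    seed: int = 0,
    burn: int = 500,
    thin: int = 2,
) -> np.ndarray:
    """Gibbs sample n draws from TN with precision theta and linear term eta.

    Single chain: ``burn`` full sweeps discarded, every ``thin``-th sweep
    kept afterwards.  Deterministic for a fixed seed.
    """
    theta = np.asarray(theta, dtype=float)
    eta = np.asarray(eta, dtype=float)
    p = theta.shape[0]
    if np.min(np.linalg.eigvalsh(theta)) <= 0:
        raise ValueError("theta must be positive definite")
    rng = np.random.default_rng(seed)
    sd = 1.0 / np.sqrt(np.diag(theta))
    y = np.maximum(np.linalg.solve(theta, eta), 0.1)  # start near the mode
    out = np.empty((n, p))
    kept = 0
    sweep = 0
    while kept < n:
        sweep += 1
        for j in range(p):
            cond_mean = (eta[j] - theta[j] @ y + theta[j, j] * y[j]) / theta[j, j]
            alpha = (0.0 - cond_mean) / sd[j]
            y[j] = cond_mean + sd[j] * _truncnorm_lower(rng, alpha)
        if sweep > burn and (sweep - burn) % thin == 0:
            out[kept] = y
            kept += 1
    return out


def sample_panel(scenario: Scenario, burn: int = 500, thin: int = 2) -> list[np.ndarray]:
    """One observation matrix per period, each period an independent chain
    with a seed derived from the scenario seed."""
    mats = []
    for m in range(1, scenario.M + 1):
        prm = scenario.params_for_period(m)
        sub_seed = (scenario.seed * 1000 + m) % (2**31 - 1)
        mats.append(
            sample_tn(prm.Theta, prm.eta, scenario.n_per_period[m - 1], sub_seed, burn, thin)
        )
    return mats


_FILLERS = [f"filler{i}" for i in range(20)]


def make_corpus(
    scenario: Scenario,
    reports_per_period: int = 40,
    tokens_per_report: int = 400,
    seed: int = 0,
    burn: int = 200,
    thin: int = 1,
) -> tuple[list[Document], list[str]]:
    """Synthetic document set: one TN draw per report, keyword counts
    Poisson with rate proportional to the latent value, filler tokens padding
    each report to ``tokens_per_report``.  Returns (documents, keywords).
    """
    if reports_per_period < 1 or tokens_per_report < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    p = scenario.p
    keywords = [f"kw{j:02d}" for j in range(p)]
    docs: list[Document] = []
    base_year = 2015
    for m in range(1, scenario.M + 1):
        prm = scenario.params_for_period(m)
        sub_seed = (seed * 7919 + m) % (2**31 - 1)
        latent = sample_tn(prm.Theta, prm.eta, reports_per_period, sub_seed, burn, thin)
        year = base_year + (m - 1) // 4
        quarter = (m - 1) % 4
        for i in range(reports_per_period):
            # rate scaled so keyword tokens occupy roughly half of a report
            rate = latent[i] / max(latent[i].sum(), 1e-12) * (tokens_per_report / 2.0)
            counts = rng.poisson(rate)
            tokens: list[str] = []
            for j, c in enumerate(counts):
                tokens.extend([keywords[j]] * int(c))
            n_fill = max(tokens_per_report - len(tokens), 0)
            tokens.extend(rng.choice(_FILLERS, size=n_fill).tolist())
            rng.shuffle(tokens)
            day = 1 + int(rng.integers(0, 28))
            month = quarter * 3 + 1 + int(rng.integers(0, 3))
            docs.append(Document(f"p{m:02d}r{i:03d}", date(year, month, day), tokens))
    return docs, keywords


def save_scenario(scenario: Scenario, outdir) -> None:
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "p": scenario.p,
        "M": scenario.M,
        "change_points": list(map(int, scenario.change_points)),
        "n_per_period": list(map(int, scenario.n_per_period)),
        "seed": int(scenario.seed),
        "n_phases": scenario.n_phases,
    }
    (outdir / "scenario.yaml").write_text(yaml.safe_dump(meta))
    for i, (T, e) in enumerate(zip(scenario.theta_true, scenario.eta_true), start=1):
        pd.DataFrame(T).to_csv(outdir / f"theta_phase{i}.csv", index=False)
        pd.DataFrame({"eta": e}).to_csv(outdir / f"eta_phase{i}.csv", index=False)
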