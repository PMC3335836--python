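"""Probabilistic sensitivity analysis, acceptability curves and
threshold-price analysis.

PSA draws transition-matrix rows from Dirichlet distributions with the
observed transition counts as concentration parameters (structural
zeros — second line back to first line — are preserved; other
zero-count destinations receive a 0.5 pseudo-count), stochastic cost
pay-offs from Gammas matched to each stratum's mean and standard error,
and symptomatic-state utilities from Betas around their means.  Each
draw is propagated through the Markov cohort model; the
cost-effectiveness acceptability curve reports, per willingness-to-pay
threshold, the fraction of draws with positive incremental net monetary
benefit.  Because the model's incremental cost is affine in the CD4
test unit price, the break-even test price for a threshold lambda has
the closed form c* = (lambda dE - dC0)/dn, with dC0 the incremental
cost at a zero test price and dn the discounted incremental number of
costed CD4 tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from artcea.markov import (
    ALIVE_STATES,
    ARM_INDEX,
    DEAD_STATE,
    FL_STATES,
    N_STATES,
    LifeTable,
    PayoffTable,
    SL_STATES,
    TransitionMatrix,
    run_cohort,
)
from artcea.trial import UtilitySet


@dataclass
class PSAInputs:
    """Everything one PSA draw needs: estimated matrices (with counts),
    pay-offs, utilities and the trial-period base case with standard
    errors."""

    tm_lcm: TransitionMatrix
    tm_cdm: TransitionMatrix
    payoffs: PayoffTable
    initial_occ_lcm: np.ndarray
    initial_occ_cdm: np.ndarray
    trial_end_years: float
    horizon_years: float = 25.0
    discount_rate: float = 0.03
    life_table: Optional[LifeTable] = None
    age0: float = 37.0
    utilities: UtilitySet = field(default_factory=UtilitySet)
    utility_se: float = 0.05
    trial_delta_cost: float = 0.0
    trial_delta_cost_se: float = 0.0
    trial_delta_qaly: float = 0.0
    trial_delta_qaly_se: float = 0.0


@dataclass
class PSASample:
    """One internally consistent parameter draw and its incremental
    outcomes."""

    index: int
    tm_lcm: np.ndarray
    tm_cdm: np.ndarray
    payoff_cost: np.ndarray
    utilities: UtilitySet
    delta_cost: float
    delta_effect: float


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness on a strictly increasing
    willingness-to-pay grid."""

    lambdas: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, float)
        self.probabilities = np.asarray(self.probabilities, float)
        if len(self.lambdas) != len(self.probabilities):
            raise ValueError("grid and probabilities must align")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambdas, "probability": self.probabilities})


def _draw_matrix(tm: TransitionMatrix, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw of each alive row with observed counts as
    concentration; structural zeros (SL back to FL) excluded."""
    if tm.counts is None:
        return tm.p.copy()
    p = np.eye(N_STATES)
    for s in ALIVE_STATES:
        allowed = list(range(N_STATES)) if s in FL_STATES else list(SL_STATES) + [DEAD_STATE]
        alpha = tm.counts[s, allowed].astype(float)
        if alpha.sum() == 0:
            p[s] = tm.p[s]
            continue
        alpha[alpha == 0] = 0.5
        row = np.zeros(N_STATES)
        row[allowed] = rng.dirichlet(alpha)
        p[s] = row
    return p


def _draw_utilities(base: UtilitySet, se: float, rng: np.random.Generator) -> UtilitySet:
    if se <= 0:
        return base
    drawn = []
    for m in (base.u2, base.u3, base.u4):
        var = se**2
        nu = m * (1 - m) / var - 1.0
        if nu <= 0:
            drawn.append(m)
        else:
            drawn.append(float(rng.beta(m * nu, (1 - m) * nu)))
    u2, u3, u4 = sorted(drawn, reverse=True)
    return UtilitySet(1.0, u2, u3, u4, base.general_population_anchor)


def _draw_payoff_cost(payoffs: PayoffTable, rng: np.random.Generator) -> np.ndarray:
    stoch = np.zeros_like(payoffs.stoch_mean)
    for i in np.ndindex(payoffs.stoch_mean.shape):
        m, se = payoffs.stoch_mean[i], payoffs.stoch_se[i]
        if m <= 0 or se <= 0:
            stoch[i] = m
        else:
            shape = (m / se) ** 2
            stoch[i] = rng.gamma(shape, se**2 / m)
    return payoffs.det_cost + stoch


def psa(inputs: PSAInputs, S: int = 500, seed: int = 0) -> list:
    """Propagate ``S`` parameter draws through the extrapolation model;
    deterministic given the seed."""
    if S < 100:
        raise ValueError("S must be at least 100")
    rng = np.random.default_rng(seed)
    n_cycles = int(np.ceil((inputs.horizon_years - inputs.trial_end_years) / (84.0 / 365.26)))
    samples = []
    for s_ix in range(S):
        p_l = _draw_matrix(inputs.tm_lcm, rng)
        p_c = _draw_matrix(inputs.tm_cdm, rng)
        cost = _draw_payoff_cost(inputs.payoffs, rng)
        util = _draw_utilities(inputs.utilities, inputs.utility_se, rng)
        qaly = inputs.payoffs.qaly(util)
        base_dc = inputs.trial_delta_cost + (
            rng.normal(0.0, inputs.trial_delta_cost_se) if inputs.trial_delta_cost_se > 0 else 0.0
        )
        base_dq = inputs.trial_delta_qaly + (
            rng.normal(0.0, inputs.trial_delta_qaly_se) if inputs.trial_delta_qaly_se > 0 else 0.0
        )
        acc = {}
        for arm, p, occ in (
            ("LCM", p_l, inputs.initial_occ_lcm),
            ("CDM", p_c, inputs.initial_occ_cdm),
        ):
            ai = ARM_INDEX[arm]
            tm = TransitionMatrix(arm, p)
            tr = run_cohort(
                occ,
                tm,
                cost[ai],
                qaly[ai],
                n_cycles,
                inputs.trial_end_years,
                inputs.discount_rate,
                inputs.life_table,
                inputs.age0,
            )
            acc[arm] = (tr["disc_cost"].sum(), tr["disc_qaly"].sum())
        dc = base_dc + acc["LCM"][0] - acc["CDM"][0]
        dq = base_dq + acc["LCM"][1] - acc["CDM"][1]
        if not (np.isfinite(dc) and np.isfinite(dq)):
            raise FloatingPointError("non-finite PSA draw")
        samples.append(
            PSASample(
                index=s_ix,
                tm_lcm=p_l,
                tm_cdm=p_c,
                payoff_cost=cost,
                utilities=util,
                delta_cost=float(dc),
                delta_effect=float(dq),
            )
        )
    return samples


DEFAULT_LAMBDA_GRID = np.arange(0.0, 5001.0, 50.0)


def ceac(samples: Sequence[PSASample], lambda_grid=None) -> CEACCurve:
    """Probability cost-effective per threshold: fraction of draws with
    positive incremental net monetary benefit (lambda dE - dC > 0)."""
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    dc = np.array([s.delta_cost for s in samples])
    de = np.array([s.delta_effect for s in samples])
    prob = np.array([(lam * de - dc > 0).mean() for lam in grid])
    return CEACCurve(grid, prob)


@dataclass
class CostDecomposition:
    """Model results decomposed for the threshold solver: incremental
    cost at a zero CD4 test price, discounted incremental number of
    costed CD4 tests, and incremental effect."""

    delta_cost_at_zero: float
    delta_tests: float
    delta_effect: float

    def delta_cost(self, cd4_price: float) -> float:
        return self.delta_cost_at_zero + cd4_price * self.delta_tests

    def icer(self, cd4_price: float) -> float:
        return self.delta_cost(cd4_price) / self.delta_effect


def cd4_price_threshold(decomp: CostDecomposition, lam: float) -> float:
    """Break-even CD4 unit cost c* with ICER(c*) = lambda (closed form;
    requires a positive incremental number of costed tests)."""
    if decomp.delta_tests <= 0:
        raise ValueError("incremental discounted CD4 test count must be positive")
    return (lam * decomp.delta_effect - decomp.delta_cost_at_zero) / decomp.delta_tests


def fixed_budget_threshold(
    cdm_cost: float, cdm_effect: float, no_art_cost: float, no_art_effect: float
) -> float:
    """Fixed-budget willingness-to-pay: the ICER of the clinically
    monitored strategy against providing no ART."""
    if cdm_effect <= no_art_effect:
        raise ValueError("CDM effect must exceed the no-ART comparator's")
    return (cdm_cost - no_art_cost) / (cdm_effect - no_art_effect)


def who_threshold(gdp_per_capita: dict, weights: Optional[dict] = None) -> float:
    """WHO benchmark threshold: three times the (weighted) per-capita
    GDP of the countries served."""
    if not gdp_per_capita:
        raise ValueError("no GDP inputs")
    if any(g <= 0 for g in gdp_per_capita.values()):
        raise ValueError("GDPs must be positive")
    if weights is None:
        weights = {k: 1.0 / len(gdp_per_capita) for k in gdp_per_capita}
    w = np.array([weights[k] for k in gdp_per_capita])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    g = np.array([gdp_per_capita[k] for k in gdp_per_capita])
    return float(3.0 * (w @ g))
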