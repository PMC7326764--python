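"""Model-based causal mediation analysis for genotype -> risk factor -> stroke.

The estimand follows the counterfactual (potential-outcome) framework under
sequential ignorability.  Two component models are fitted separately:

* mediator model  — linear (identity link):  M_i ~ T_i + X_i
* outcome model   — logistic (or linear for continuous outcomes):
                    Y_i ~ T_i + M_i + X_i

Inference is quasi-Bayesian: ``nsim`` parameter vectors are drawn from each
fitted model's asymptotic normal distribution; for each draw, potential
mediator values are simulated under treatment and control and potential
outcomes evaluated for the four treatment/mediator combinations.  The
average causal mediation effect (ACME), average direct effect (ADE) and
total effect are reported on the risk-difference (probability) scale for
binary outcomes, averaged over subjects and over the two treatment arms, so
that total = ACME + ADE holds exactly per draw.  Intervals are percentile
intervals over draws; p-values are two-sided Monte-Carlo tail probabilities
with a 1/(nsim+1) floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .io_cohort import GenotypeMatrix, PhenotypeTable, recode

_PM_CLIP = (-1.0, 2.0)
_TAU_TOL = 1e-12


class MediationError(ValueError):
    pass


@dataclass
class MediationResult:
    """ACME/ADE/total-effect/proportion-mediated estimates with MC intervals."""

    acme: float
    acme_ci: tuple[float, float]
    acme_p: float
    ade: float
    ade_ci: tuple[float, float]
    ade_p: float
    total: float
    total_ci: tuple[float, float]
    total_p: float
    prop_mediated: float
    prop_mediated_ci: tuple[float, float]
    prop_mediated_p: float
    nsim: int
    seed: int | None
    n: int
    pm_unstable: bool = False
    pm_clipped: bool = False
    draws: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for est, ci in [(self.acme, self.acme_ci), (self.ade, self.ade_ci),
                        (self.total, self.total_ci),
                        (self.prop_mediated, self.prop_mediated_ci)]:
            if not (ci[0] - 1e-12 <= est <= ci[1] + 1e-12):
                raise ValueError(f"estimate {est} outside its CI {ci}")


def _mc_p(draws: np.ndarray) -> float:
    nsim = len(draws)
    p = 2.0 * min(np.mean(draws <= 0), np.mean(draws >= 0))
    return float(max(min(p, 1.0), 1.0 / (nsim + 1)))


def _summarize(draws: np.ndarray, point: str = "mean") -> tuple[float, tuple[float, float], float]:
    est = float(np.median(draws)) if point == "median" else float(np.mean(draws))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return est, (float(lo), float(hi)), _mc_p(draws)


class MediationModel(BaseEstimator):
    """Estimator for a single treatment -> mediator -> outcome pathway.

    Parameters
    ----------
    outcome_family : "binomial" or "gaussian"
        Binomial-logit for the case/control (or subtype) outcome; gaussian
        for a continuous outcome, in which case effects are on the identity
        scale and ACME reduces to the product of coefficients in large
        samples.
    nsim : int
        Number of quasi-Bayesian parameter draws (>= 100).
    control_value, treat_value : float
        Treatment contrast; (0, 1) for a dominant genotype coding, (0, 2)
        for additive.
    seed : int or None
        Makes every reported number reproducible bit-for-bit.
    """

    def __init__(self, outcome_family: str = "binomial", nsim: int = 1000,
                 control_value: float = 0.0, treat_value: float = 1.0,
                 seed: int | None = None, keep_draws: bool = False):
        self.outcome_family = outcome_family
        self.nsim = nsim
        self.control_value = control_value
        self.treat_value = treat_value
        self.seed = seed
        self.keep_draws = keep_draws

    # -- component models ---------------------------------------------------

    def fit(self, t, m, y, x=None) -> "MediationModel":
        """Fit the mediator and outcome component models.

        Rows with a missing value in any of t, m, y or x are removed
        listwise before fitting.
        """
        if self.nsim < 100:
            raise MediationError("nsim must be >= 100")
        if self.outcome_family not in ("binomial", "gaussian"):
            raise MediationError(f"unknown outcome family {self.outcome_family!r}")
        t = np.asarray(t, dtype=float)
        m = np.asarray(m, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = [t, m, y]
        if x is not None:
            x = np.atleast_2d(np.asarray(x, dtype=float))
            if x.shape[0] != len(t):
                x = x.T
            cols.extend(x.T)
        mask = np.ones(len(t), dtype=bool)
        for c in cols:
            mask &= np.isfinite(np.asarray(c, dtype=float))
        if mask.sum() < 10:
            raise MediationError("fewer than 10 complete observations")
        t, m, y = t[mask], m[mask], y[mask]
        x = x[mask] if x is not None else None
        if self.outcome_family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
            raise MediationError("binomial outcome must be 0/1")

        zm = np.column_stack([np.ones_like(t), t] + ([x] if x is not None else []))
        zo = np.column_stack([np.ones_like(t), t, m] + ([x] if x is not None else []))
        self._check_rank(zm, ["intercept", "treatment"], "mediator")
        self._check_rank(zo, ["intercept", "treatment", "mediator"], "outcome")

        med = sm.GLM(m, zm, family=sm.families.Gaussian()).fit()
        fam = (sm.families.Binomial() if self.outcome_family == "binomial"
               else sm.families.Gaussian())
        from statsmodels.tools.sm_exceptions import PerfectSeparationError
        try:
            out = sm.GLM(y, zo, family=fam).fit()
        except PerfectSeparationError as exc:
            raise MediationError(
                "perfect separation in the outcome logistic fit; "
                "reduce the model or pool sparse genotype groups") from exc
        if self.outcome_family == "binomial":
            mu = np.asarray(out.fittedvalues)
            if (mu[y == 1] > 1 - 1e-8).all() and (mu[y == 0] < 1e-8).all():
                raise MediationError(
                    "perfect separation in the outcome logistic fit; "
                    "reduce the model or pool sparse genotype groups")
        self.mediator_result_ = med
        self.outcome_result_ = out
        self.t_, self.m_, self.y_, self.x_ = t, m, y, x
        self.n_ = int(mask.sum())
        return self

    @staticmethod
    def _check_rank(z: np.ndarray, names: list[str], which: str) -> None:
        rank = np.linalg.matrix_rank(z)
        if rank < z.shape[1]:
            # name the first column that adds no rank
            bad = []
            for j in range(1, z.shape[1]):
                if np.linalg.matrix_rank(z[:, : j + 1]) == np.linalg.matrix_rank(z[:, :j]):
                    bad.append(names[j] if j < len(names) else f"covariate_{j - len(names)}")
            raise MediationError(
                f"rank-deficient {which} design; collinear columns: {bad or names}")

    # -- quasi-Bayesian simulation ------------------------------------------

    def estimate(self) -> MediationResult:
        """Run the quasi-Bayesian algorithm and return the MediationResult."""
        if not hasattr(self, "mediator_result_"):
            raise MediationError("call fit() before estimate()")
        rng = np.random.default_rng(self.seed)
        nsim, n = self.nsim, self.n_
        med, out = self.mediator_result_, self.outcome_result_

        bm = rng.multivariate_normal(med.params, med.cov_params(), size=nsim)
        bo = rng.multivariate_normal(out.params, out.cov_params(), size=nsim)
        sigma = float(np.sqrt(med.scale))
        eps = rng.standard_normal((nsim, n)) * sigma

        xpart_m = (self.x_ @ bm[:, 2:].T).T if self.x_ is not None else 0.0
        xpart_o = (self.x_ @ bo[:, 3:].T).T if self.x_ is not None else 0.0

        def mediator_draw(tval: float) -> np.ndarray:
            return bm[:, [0]] + bm[:, [1]] * tval + xpart_m + eps

        m_ctrl = mediator_draw(self.control_value)
        m_treat = mediator_draw(self.treat_value)

        def mean_outcome(tval: float, mmat: np.ndarray) -> np.ndarray:
            eta = bo[:, [0]] + bo[:, [1]] * tval + bo[:, [2]] * mmat + xpart_o
            if self.outcome_family == "binomial":
                eta = 1.0 / (1.0 + np.exp(-eta))
            return eta.mean(axis=1)

        y00 = mean_outcome(self.control_value, m_ctrl)
        y01 = mean_outcome(self.control_value, m_treat)
        y10 = mean_outcome(self.treat_value, m_ctrl)
        y11 = mean_outcome(self.treat_value, m_treat)

        delta0, delta1 = y01 - y00, y11 - y10          # ACME under control / treatment
        zeta0, zeta1 = y10 - y00, y11 - y01            # ADE under control / treatment
        acme_d = 0.5 * (delta0 + delta1)
        ade_d = 0.5 * (zeta0 + zeta1)
        tau_d = y11 - y00                              # == acme_d + ade_d per draw

        small_tau = np.abs(tau_d) < _TAU_TOL
        pm_unstable = bool(small_tau.mean() > 0.10)
        safe_tau = np.where(small_tau, np.nan, tau_d)
        pm_raw = acme_d / safe_tau
        pm_raw = pm_raw[np.isfinite(pm_raw)]
        if pm_raw.size == 0:
            pm_raw = np.array([np.nan])
            pm_unstable = True
        pm_clipped = bool((pm_raw < _PM_CLIP[0]).any() or (pm_raw > _PM_CLIP[1]).any())
        pm_d = np.clip(pm_raw, *_PM_CLIP)

        acme, acme_ci, acme_p = _summarize(acme_d)
        ade, ade_ci, ade_p = _summarize(ade_d)
        total, total_ci, total_p = _summarize(tau_d)
        pm, pm_ci, pm_p = _summarize(pm_d, point="median")

        draws = None
        if self.keep_draws:
            draws = {"acme": acme_d, "ade": ade_d, "total": tau_d, "pm": pm_d}
        self.result_ = MediationResult(
            acme, acme_ci, acme_p, ade, ade_ci, ade_p, total, total_ci, total_p,
            pm, pm_ci, pm_p, nsim, self.seed, n,
            pm_unstable=pm_unstable, pm_clipped=pm_clipped, draws=draws)
        return self.result_


# ---------------------------------------------------------------------------
# functional wrappers


def fit_component_models(t, m, y, x=None, outcome_family: str = "binomial"):
    """Fit and return the (mediator, outcome) statsmodels results."""
    mm = MediationModel(outcome_family=outcome_family, nsim=100).fit(t, m, y, x)
    return mm.mediator_result_, mm.outcome_result_


def mediate(t, m, y, x=None, outcome_family: str = "binomial", nsim: int = 1000,
            seed: int | None = None, control_value: float = 0.0,
            treat_value: float = 1.0, keep_draws: bool = False) -> MediationResult:
    """One-shot mediation analysis for a single (T, M, Y) triple."""
    mm = MediationModel(outcome_family=outcome_family, nsim=nsim, seed=seed,
                        control_value=control_value, treat_value=treat_value,
                        keep_draws=keep_draws)
    return mm.fit(t, m, y, x).estimate()


def mediation_scan(g: GenotypeMatrix, pheno: PhenotypeTable, snps: list[str],
                   mediators: list[str], outcomes: list[str],
                   coding: str = "dominant", nsim: int = 1000,
                   seed: int | None = None, covariates: list[str] | None = None,
                   ) -> pd.DataFrame:
    """Mediation analysis over every (SNP, mediator, outcome) triple.

    ``outcomes`` entries are ``"IS"`` (case vs control) or a TOAST subtype
    name (that subtype vs everyone else).  Per-triple failures are recorded
    in the ``error`` column and the scan continues.  The master seed is
    expanded deterministically so each triple has its own stream.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(snps) * len(mediators) * len(outcomes))
    x = None
    if covariates:
        x = np.column_stack([pheno.factor(c) for c in covariates])
    rows = []
    i = 0
    for snp in snps:
        coded = recode(g, snp, coding)
        tvals = coded.values
        treat_value = 2.0 if coding == "additive" else 1.0
        for mediator in mediators:
            mvals = pheno.factor(mediator)
            for outcome in outcomes:
                yvals = (pheno.status_vector() if outcome == "IS"
                         else pheno.subtype_indicator(outcome)).astype(float)
                sub_seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
                i += 1
                row = {"snp_id": snp, "coding": coding, "mediator": mediator,
                       "outcome": outcome, "seed": sub_seed, "error": ""}
                try:
                    res = mediate(tvals, mvals, yvals, x=x, nsim=nsim,
                                  seed=sub_seed, treat_value=treat_value)
                    row.update({
                        "acme": res.acme, "acme_p": res.acme_p,
                        "ade": res.ade, "ade_p": res.ade_p,
                        "total": res.total, "total_p": res.total_p,
                        "prop_mediated": res.prop_mediated,
                        "prop_mediated_p": res.prop_mediated_p,
                        "pm_unstable": res.pm_unstable, "n": res.n,
                    })
                except (MediationError, np.linalg.LinAlgError) as exc:
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)
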