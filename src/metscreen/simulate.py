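"""Synthetic two-sex cohort generator with calibrated marginals and a
Gaussian-copula dependence structure, plus exact oracles for validation.

The generator emulates a community-screening cohort of apparently
healthy adults: per-sex normal or lognormal marginals for each
measurement, truncated to physiologic ranges by rejection, coupled
through a latent Gaussian factor model.

Latent structure
----------------
Five component factors (waist, blood pressure, glucose, triglycerides,
HDL) carry an exchangeable correlation ``rho``. Each measured variable
loads on its component's factor:

* wc, fbg, tg, hdl load 1.0 (their latent IS the factor);
* sbp and dbp load sqrt(0.6) each, giving a fixed SBP-DBP correlation of
  0.6 regardless of ``rho``;
* weight, nc and muac load 0.5 on the waist factor (adiposity cluster);
* age and height are independent.

The HDL latent's sign is flipped so that positive ``rho`` means positive
*risk* dependence (low HDL travelling with high waist/BP/glucose/TG).
Because every variable's latent is still standard normal, each marginal
component prevalence is invariant to ``rho``; only the joint (and hence
the MetS prevalence) moves. The factor construction keeps the implied
correlation matrix positive semi-definite for rho in (-1/4, 1].

Calibration
-----------
* Single-threshold marginals are solved in closed form by quantile
  matching: an exceedance target q at threshold tau gives
  mean = tau + sd * Phi^-1(q) (normal; analogous on the log scale for
  lognormal; mirrored for deficit targets).
* The compound blood-pressure component P(SBP>=130 OR DBP>=85) is solved
  by bisection on the SBP mean, evaluating the probability exactly via
  the bivariate-normal CDF at the fixed SBP-DBP latent correlation.
* The dependence parameter ``rho`` is solved by a coarse grid plus
  bisection against simulated MetS prevalence under common random
  numbers (one fixed evaluation seed).

The exact Poisson-binomial probability of >= 3 positive components under
independence (:func:`mets_prob_poisson_binomial`) serves as the
independent oracle for the rho = 0 case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .mets import ThresholdSet, classify_components_df

__all__ = [
    "MarginalSpec",
    "CohortConfig",
    "CalibrationResult",
    "STUDY_TARGETS",
    "default_cohort_config",
    "sample_cohort",
    "calibrate_marginal",
    "calibrate_compound_bp",
    "calibrate_dependence",
    "mets_prob_poisson_binomial",
    "save_config",
    "load_config",
]

#: printed study conditions the default generator is calibrated to
STUDY_TARGETS = {
    "p_male": 0.626,
    "age_mean": 42.66,
    "age_sd": 12.18,
    "elevated_wc": 0.739,
    "elevated_bp": 0.511,
    "reduced_hdl": 0.499,
    "elevated_tg": 0.196,
    "elevated_fbg": 0.195,
    "mets": 0.322,
}

#: fixed SBP-DBP latent correlation (within the BP component factor)
BP_LATENT_CORR = 0.6
#: loading of weight/nc/muac on the waist factor
ADIPOSITY_LOADING = 0.5

_FACTOR_OF = {  # variable -> (component factor, loading)
    "wc": ("f_wc", 1.0),
    "weight": ("f_wc", ADIPOSITY_LOADING),
    "nc": ("f_wc", ADIPOSITY_LOADING),
    "muac": ("f_wc", ADIPOSITY_LOADING),
    "sbp": ("f_bp", math.sqrt(BP_LATENT_CORR)),
    "dbp": ("f_bp", math.sqrt(BP_LATENT_CORR)),
    "fbg": ("f_glu", 1.0),
    "tg": ("f_tg", 1.0),
    "hdl": ("f_hdl", 1.0),
    "age": (None, 0.0),
    "height": (None, 0.0),
}
_FACTORS = ["f_wc", "f_bp", "f_glu", "f_tg", "f_hdl"]

VARIABLE_ORDER = [
    "age", "height", "weight", "wc", "nc", "muac",
    "sbp", "dbp", "fbg", "tg", "hdl",
]


@dataclass(frozen=True)
class MarginalSpec:
    """One variable's per-sex marginal distribution.

    ``mean``/``sd`` are on the natural scale for ``family="normal"`` and
    on the log scale for ``family="lognormal"``. ``target`` is an
    optional ``(threshold, probability, side)`` triple used by
    :func:`calibrate_marginal`; ``side`` is ``"high"`` for an exceedance
    target (P(X >= threshold) = probability) or ``"low"`` for a deficit
    target (P(X < threshold) = probability). ``bounds`` are physiologic
    truncation limits enforced by rejection.
    """

    name: str
    family: str  # {"normal", "lognormal"}
    mean: float
    sd: float
    target: Optional[tuple] = None  # (threshold, probability, side)
    bounds: tuple = (0.0, math.inf)

    def __post_init__(self):
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.sd > 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if self.target is not None:
            thr, q, side = self.target
            if not 0 < q < 1:
                raise ValueError(f"{self.name}: target probability must be in (0,1)")
            if side not in ("high", "low"):
                raise ValueError(f"{self.name}: target side must be 'high' or 'low'")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"{self.name}: bounds must be ordered")

    def quantile(self, u):
        """Inverse CDF (no truncation) at uniform u, vectorised."""
        z = sps.norm.ppf(u)
        return self.from_latent(z)

    def from_latent(self, z):
        """Map standard-normal latent values to the natural scale."""
        if self.family == "normal":
            return self.mean + self.sd * z
        return np.exp(self.mean + self.sd * z)


@dataclass(frozen=True)
class CalibrationResult:
    parameter: str
    value: float
    achieved: float
    target: float
    iterations: int
    converged: bool
    note: str = ""


@dataclass
class CohortConfig:
    """Full parameterisation of the synthetic generator."""

    n: int
    p_male: float
    marginals: dict  # sex -> {variable name -> MarginalSpec}
    rho: float = 0.0
    seed: int = 0
    med_flag_probs: dict = field(
        default_factory=lambda: {"on_bp_meds": 0.0, "on_lipid_meds": 0.0, "on_glucose_meds": 0.0}
    )

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.p_male <= 1:
            raise ValueError("p_male must be in [0, 1]")
        if not -0.25 < self.rho <= 1.0:
            raise ValueError(
                f"rho={self.rho} outside the feasible exchangeable range (-0.25, 1]: "
                "the 5-factor correlation matrix would have a negative eigenvalue "
                f"(smallest eigenvalue 1 + 4*rho = {1 + 4 * self.rho:.4f})"
            )
        for sex in ("male", "female"):
            if sex not in self.marginals:
                raise ValueError(f"marginals missing sex {sex!r}")
            missing = set(VARIABLE_ORDER) - set(self.marginals[sex])
            if missing:
                raise ValueError(f"{sex} marginals missing {sorted(missing)}")


def _factor_cholesky(rho: float) -> np.ndarray:
    """Cholesky factor of the 5x5 exchangeable factor correlation."""
    k = len(_FACTORS)
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < -1e-12:
        raise ValueError(
            f"factor correlation not PSD at rho={rho}: smallest eigenvalue {eigvals[0]:.4g}"
        )
    corr[np.diag_indices_from(corr)] += 1e-12  # guard exact-singular rho = -0.25, 1
    return np.linalg.cholesky(corr)


def _latent_matrix(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """n x len(VARIABLE_ORDER) standard-normal latents with the model's
    correlation structure (HDL sign already flipped to 'low is risky')."""
    chol = _factor_cholesky(rho)
    factors = rng.standard_normal((n, len(_FACTORS))) @ chol.T
    fidx = {f: i for i, f in enumerate(_FACTORS)}
    z = np.empty((n, len(VARIABLE_ORDER)))
    for j, var in enumerate(VARIABLE_ORDER):
        fac, lam = _FACTOR_OF[var]
        eps = rng.standard_normal(n)
        if fac is None:
            z[:, j] = eps
        else:
            z[:, j] = lam * factors[:, fidx[fac]] + math.sqrt(1 - lam**2) * eps
    # low HDL should co-occur with high risk on the other factors
    z[:, VARIABLE_ORDER.index("hdl")] *= -1.0
    return z


def sample_cohort(config: CohortConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw a synthetic cohort as a standard cohort DataFrame.

    Deterministic given (config, seed); ``seed=None`` uses
    ``config.seed``. Truncation bounds are enforced by redrawing the
    entire latent row of any subject with an out-of-range value, which
    preserves the copula among accepted rows.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n
    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    z = _latent_matrix(rng, n, config.rho)

    data = np.empty((n, len(VARIABLE_ORDER)))
    male_mask = sex == "male"
    for j, var in enumerate(VARIABLE_ORDER):
        for s, mask in (("male", male_mask), ("female", ~male_mask)):
            spec = config.marginals[s][var]
            data[mask, j] = spec.from_latent(z[mask, j])

    # rejection on physiologic bounds, whole-row redraw
    for _ in range(100):
        bad = np.zeros(n, bool)
        for j, var in enumerate(VARIABLE_ORDER):
            for s, mask in (("male", male_mask), ("female", ~male_mask)):
                lo, hi = config.marginals[s][var].bounds
                col = data[:, j]
                bad |= mask & ((col < lo) | (col > hi))
        # systolic must exceed diastolic for a physically sensible record
        bad |= data[:, VARIABLE_ORDER.index("sbp")] <= data[:, VARIABLE_ORDER.index("dbp")]
        if not bad.any():
            break
        nb = int(bad.sum())
        z_new = _latent_matrix(rng, nb, config.rho)
        for j, var in enumerate(VARIABLE_ORDER):
            vals = np.empty(nb)
            bad_sex = sex[bad]
            for s in ("male", "female"):
                m = bad_sex == s
                vals[m] = config.marginals[s][var].from_latent(z_new[m, j])
            data[bad, j] = vals
    else:
        raise RuntimeError("truncation resampling did not converge in 100 rounds")

    df = pd.DataFrame(data, columns=VARIABLE_ORDER)
    df.insert(0, "sex", sex)
    df.insert(0, "id", [f"S{i:06d}" for i in range(n)])
    for flag, p in config.med_flag_probs.items():
        df[flag] = rng.random(n) < p if p > 0 else np.zeros(n, bool)
    return df


def calibrate_marginal(spec: MarginalSpec) -> CalibrationResult:
    """Solve a marginal's mean so its threshold target holds exactly.

    Exceedance target q at threshold tau: mean = tau + sd * Phi^-1(q)
    (normal family; on the log scale with log(tau) for lognormal).
    Deficit targets use the mirrored form mean = tau - sd * Phi^-1(q).
    The achieved probability is recomputed from the solved mean.
    """
    if spec.target is None:
        raise ValueError(f"{spec.name}: no calibration target set")
    thr, q, side = spec.target
    tau = math.log(thr) if spec.family == "lognormal" else thr
    sign = 1.0 if side == "high" else -1.0
    mean = tau + sign * spec.sd * sps.norm.ppf(q)
    if side == "high":
        achieved = float(sps.norm.sf((tau - mean) / spec.sd))
    else:
        achieved = float(sps.norm.cdf((tau - mean) / spec.sd))
    return CalibrationResult(
        parameter=f"{spec.name}.mean",
        value=float(mean),
        achieved=achieved,
        target=q,
        iterations=0,
        converged=abs(achieved - q) <= 1e-12,
    )


def _compound_bp_prob(sbp_mean, sbp_sd, dbp_mean, dbp_sd, sbp_thr, dbp_thr, latent_corr):
    """Exact P(SBP >= sbp_thr OR DBP >= dbp_thr) on the latent scale."""
    z1 = (sbp_thr - sbp_mean) / sbp_sd
    z2 = (dbp_thr - dbp_mean) / dbp_sd
    if latent_corr == 0.0:
        p1, p2 = sps.norm.sf(z1), sps.norm.sf(z2)
        return float(p1 + p2 - p1 * p2)
    both_below = sps.multivariate_normal.cdf(
        [z1, z2], mean=[0.0, 0.0], cov=[[1.0, latent_corr], [latent_corr, 1.0]]
    )
    return float(1.0 - both_below)


def calibrate_compound_bp(
    sbp_spec: MarginalSpec,
    dbp_spec: MarginalSpec,
    target: float,
    latent_corr: float = BP_LATENT_CORR,
    sbp_threshold: float = 130.0,
    dbp_threshold: float = 85.0,
    tol: float = 0.002,
    max_iter: int = 200,
) -> CalibrationResult:
    """Bisection on the SBP mean so the OR-criterion prevalence hits
    ``target``; the DBP marginal is held fixed.

    If the DBP exceedance alone already meets or exceeds the target, the
    SBP contribution is driven toward zero and the result is flagged with
    the honestly achieved (>= target) probability.
    """
    if not 0 < target < 1:
        raise ValueError("target must be in (0, 1)")

    def prob(sbp_mean):
        return _compound_bp_prob(
            sbp_mean, sbp_spec.sd, dbp_spec.mean, dbp_spec.sd,
            sbp_threshold, dbp_threshold, latent_corr,
        )

    lo, hi = sbp_threshold - 12 * sbp_spec.sd, sbp_threshold + 12 * sbp_spec.sd
    p_lo, p_hi = prob(lo), prob(hi)  # prob is increasing in the mean
    if target <= p_lo:
        return CalibrationResult(
            parameter="sbp.mean", value=float(lo), achieved=p_lo, target=target,
            iterations=0, converged=abs(p_lo - target) <= tol,
            note="DBP alone reaches the target; SBP contribution driven to the bracket floor",
        )
    if target >= p_hi:
        return CalibrationResult(
            parameter="sbp.mean", value=float(hi), achieved=p_hi, target=target,
            iterations=0, converged=False, note="target unreachable within bracket",
        )
    it = 0
    for it in range(1, max_iter + 1):
        mid = (lo + hi) / 2.0
        p_mid = prob(mid)
        if abs(p_mid - target) <= tol * 0.1 or (hi - lo) < 1e-10:
            break
        if p_mid < target:
            lo = mid
        else:
            hi = mid
    mid = (lo + hi) / 2.0
    achieved = prob(mid)
    return CalibrationResult(
        parameter="sbp.mean", value=float(mid), achieved=achieved, target=target,
        iterations=it, converged=abs(achieved - target) <= tol,
    )


def mets_prob_poisson_binomial(component_probs: Sequence[float], k: int = 3) -> float:
    """Exact P(at least k of the independent components are positive).

    Dynamic programming over the Poisson-binomial count distribution:
    O(len(probs)^2), exact up to floating point, symmetric under
    permutation of the probabilities.
    """
    probs = list(component_probs)
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    dp = np.zeros(len(probs) + 1)
    dp[0] = 1.0
    for p in probs:
        dp[1:] = dp[1:] * (1.0 - p) + dp[:-1] * p
        dp[0] *= 1.0 - p
    return float(dp[k:].sum())


def _simulated_mets_prevalence(
    config: CohortConfig, rho: float, n: int, seed: int,
    thresholds: ThresholdSet = ThresholdSet(),
) -> float:
    cfg = replace_config(config, n=n, rho=rho)
    cohort = sample_cohort(cfg, seed=seed)
    return float(classify_components_df(cohort, thresholds)["mets"].mean())


def replace_config(config: CohortConfig, **kw) -> CohortConfig:
    """Copy a config with some fields replaced."""
    return CohortConfig(
        n=kw.get("n", config.n),
        p_male=kw.get("p_male", config.p_male),
        marginals=kw.get("marginals", config.marginals),
        rho=kw.get("rho", config.rho),
        seed=kw.get("seed", config.seed),
        med_flag_probs=kw.get("med_flag_probs", dict(config.med_flag_probs)),
    )


def calibrate_dependence(
    config: CohortConfig,
    target: float,
    eval_n: int = 200_000,
    eval_seed: int = 20_220_801,
    tol: float = 0.0015,
    grid: Optional[Sequence[float]] = None,
    max_iter: int = 40,
) -> CalibrationResult:
    """Solve the exchangeable ``rho`` so simulated MetS prevalence hits
    ``target``.

    Uses common random numbers (one fixed evaluation seed) so the
    prevalence-vs-rho map is a deterministic, empirically monotone
    function; a coarse grid brackets the target and bisection refines it.
    Marginal component prevalences are invariant to rho by construction,
    so no re-calibration of the marginals is needed inside the loop.
    """
    if not 0 < target < 1:
        raise ValueError("target must be in (0, 1)")
    if grid is None:
        grid = [-0.24, -0.18, -0.12, -0.06, 0.0, 0.1, 0.25, 0.45, 0.7, 0.95]

    def f(rho):
        return _simulated_mets_prevalence(config, rho, eval_n, eval_seed)

    vals = [f(r) for r in grid]
    it = len(grid)
    # bracket on the empirically monotone (increasing) grid
    bracket = None
    for (r_lo, v_lo), (r_hi, v_hi) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
        if min(v_lo, v_hi) <= target <= max(v_lo, v_hi):
            bracket = (r_lo, v_lo, r_hi, v_hi)
            break
    if bracket is None:
        # maybe a grid point is already close enough
        best = int(np.argmin([abs(v - target) for v in vals]))
        return CalibrationResult(
            parameter="rho", value=float(grid[best]), achieved=float(vals[best]),
            target=target, iterations=it, converged=abs(vals[best] - target) <= tol,
            note=f"target outside achieved range [{min(vals):.4f}, {max(vals):.4f}]",
        )
    r_lo, v_lo, r_hi, v_hi = bracket
    increasing = v_hi >= v_lo
    rho, achieved = r_lo, v_lo
    for _ in range(max_iter):
        rho = (r_lo + r_hi) / 2.0
        achieved = f(rho)
        it += 1
        if abs(achieved - target) <= tol or (r_hi - r_lo) < 1e-4:
            break
        if (achieved < target) == increasing:
            r_lo = rho
        else:
            r_hi = rho
    return CalibrationResult(
        parameter="rho", value=float(rho), achieved=float(achieved), target=target,
        iterations=it, converged=abs(achieved - target) <= tol,
    )


# ---------------------------------------------------------------------------
# default configuration: the study conditions
# ---------------------------------------------------------------------------

def _default_marginals(sex: str) -> dict:
    """Per-sex marginal specs with calibration targets where the study
    prints a component prevalence; means without printed counterparts are
    synthetic choices consistent with the printed index magnitudes."""
    male = sex == "male"
    t = STUDY_TARGETS
    specs = [
        MarginalSpec("age", "normal", t["age_mean"], t["age_sd"], bounds=(0.0, 120.0)),
        MarginalSpec("height", "normal", 170.0 if male else 157.0, 7.0 if male else 6.5,
                     bounds=(120.0, 210.0)),
        MarginalSpec("weight", "normal", 75.0 if male else 68.0, 12.0, bounds=(30.0, 180.0)),
        # circumference floors are just positivity: tighter floors would
        # reject left-tail rows and, through the shared waist factor,
        # bias the calibrated WC exceedance upward
        MarginalSpec("wc", "normal", 95.0, 11.0,
                     target=(90.0 if male else 80.0, t["elevated_wc"], "high"),
                     bounds=(0.0, math.inf)),
        MarginalSpec("nc", "normal", 37.8 if male else 35.6, 3.5 if male else 4.0,
                     bounds=(0.0, math.inf)),
        MarginalSpec("muac", "normal", 30.7 if male else 30.8, 3.8 if male else 4.2,
                     bounds=(0.0, math.inf)),
        MarginalSpec("sbp", "normal", 122.0, 15.0, bounds=(70.0, 260.0)),
        MarginalSpec("dbp", "normal", 80.0, 10.0, bounds=(40.0, 140.0)),
        # lognormal families are positive by construction: no truncation
        MarginalSpec("fbg", "lognormal", math.log(90.0), 0.20,
                     target=(100.0, t["elevated_fbg"], "high"), bounds=(0.0, math.inf)),
        MarginalSpec("tg", "lognormal", 0.1, 0.5,
                     target=(1.7, t["elevated_tg"], "high"), bounds=(0.0, math.inf)),
        MarginalSpec("hdl", "normal", 1.0, 0.25,
                     target=(1.03 if male else 1.29, t["reduced_hdl"], "low"),
                     bounds=(0.3, 3.5)),
    ]
    return {s.name: s for s in specs}


def default_cohort_config(
    n: int = 1065, seed: int = 0, rho: float = 0.0, calibrate: bool = True
) -> CohortConfig:
    """The default study-condition configuration.

    Sex mix 62.6% male, age 42.66 +/- 12.18 y, and (with
    ``calibrate=True``, the default) every component marginal solved so
    its prevalence matches the printed study value, including the
    compound blood-pressure criterion.
    """
    marginals = {s: _default_marginals(s) for s in ("male", "female")}
    if calibrate:
        for sex in marginals:
            for name, spec in list(marginals[sex].items()):
                if spec.target is not None:
                    res = calibrate_marginal(spec)
                    marginals[sex][name] = replace(spec, mean=res.value)
            bp = calibrate_compound_bp(
                marginals[sex]["sbp"], marginals[sex]["dbp"],
                target=STUDY_TARGETS["elevated_bp"],
            )
            if not bp.converged:
                raise RuntimeError(f"BP calibration failed for {sex}: {bp}")
            marginals[sex]["sbp"] = replace(marginals[sex]["sbp"], mean=bp.value)
    return CohortConfig(
        n=n, p_male=STUDY_TARGETS["p_male"], marginals=marginals, rho=rho, seed=seed
    )


# ---------------------------------------------------------------------------
# config (de)serialisation
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: MarginalSpec) -> dict:
    d = {
        "family": spec.family, "mean": float(spec.mean), "sd": float(spec.sd),
        "bounds": [float(spec.bounds[0]), float(spec.bounds[1])],
    }
    if spec.target is not None:
        thr, q, side = spec.target
        d["target"] = {"threshold": float(thr), "probability": float(q), "side": side}
    return d


def save_config(config: CohortConfig, path) -> None:
    """Write a config as human-editable YAML."""
    doc = {
        "n": int(config.n),
        "p_male": float(config.p_male),
        "rho": float(config.rho),
        "seed": int(config.seed),
        "med_flag_probs": {k: float(v) for k, v in config.med_flag_probs.items()},
        "marginals": {
            sex: {name: _spec_to_dict(spec) for name, spec in specs.items()}
            for sex, specs in config.marginals.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> CohortConfig:
    """Read a YAML config written by :func:`save_config`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    marginals = {}
    for sex, specs in doc["marginals"].items():
        marginals[sex] = {}
        for name, d in specs.items():
            target = None
            if "target" in d and d["target"] is not None:
                target = (d["target"]["threshold"], d["target"]["probability"], d["target"]["side"])
            marginals[sex][name] = MarginalSpec(
                name=name, family=d["family"], mean=d["mean"], sd=d["sd"],
                target=target, bounds=tuple(d.get("bounds", (0.0, math.inf))),
            )
    return CohortConfig(
        n=doc["n"], p_male=doc["p_male"], marginals=marginals,
        rho=doc.get("rho", 0.0), seed=doc.get("seed", 0),
        med_flag_probs=doc.get("med_flag_probs", {}),
    )
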