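"""Synthetic patient-level data and Monte-Carlo validation of the power formula.

Patient-level (arm, effectiveness, cost) records are drawn from a Gaussian
copula with selectable marginals, so the simulator can reproduce a target
within-arm Pearson correlation between effectiveness and cost — the
quantity whose influence on INB variance and power this package studies.
For normal marginals the copula correlation equals the Pearson correlation
exactly; for exponential effectiveness or lognormal cost marginals the
latent correlation is calibrated numerically (Gauss–Hermite quadrature of
the induced Pearson correlation, inverted with Brent's method).

``empirical_power`` replays the whole inferential pipeline per replicate —
simulate a trial, plug sample moments into the two-arm INB variance, apply
the one-sided z-test — and so serves as an independent check of the
analytic power formula.  This is validation scaffolding: it emulates the
moment structure of trial CEA data, not censoring, skew-beyond-lognormal,
or cost-accumulation dynamics.

Replicate streams are spawned from one master seed via
``numpy.random.SeedSequence``, so any replicate is reproducible in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .trial_params import ArmStats, ParameterError, TestSpec

__all__ = [
    "IPDTable",
    "SimSpec",
    "EmpiricalPower",
    "generate_ipd",
    "estimate_arm_stats",
    "empirical_power",
]

EffectDist = Literal["normal", "exponential"]
CostDist = Literal["normal", "lognormal"]


@dataclass(frozen=True)
class IPDTable:
    """Patient-level records: arm indicator (0 control / 1 experimental),
    effectiveness, and cost, as parallel arrays."""

    arm: np.ndarray
    effect: np.ndarray
    cost: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.arm) == len(self.effect) == len(self.cost)):
            raise ParameterError("arm, effect and cost must have equal length")
        for a in (0, 1):
            if int(np.sum(self.arm == a)) < 2:
                raise ParameterError(f"arm {a} must have at least 2 patients")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"arm": self.arm, "effect": self.effect, "cost": self.cost}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IPDTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            arm=df["arm"].to_numpy(int),
            effect=df["effect"].to_numpy(float),
            cost=df["cost"].to_numpy(float),
        )


@dataclass(frozen=True)
class SimSpec:
    """Generative specification: per-arm target moments (``ArmStats.n`` is
    the per-arm sample size), marginal families, and a master seed.

    The exponential effectiveness marginal is one-parameter: its SD equals
    its mean and ``sd_effect`` is ignored.  Lognormal cost matches both the
    requested mean and SD.
    """

    arm0: ArmStats
    arm1: ArmStats
    effect_dist: EffectDist = "normal"
    cost_dist: CostDist = "normal"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.effect_dist not in ("normal", "exponential"):
            raise ParameterError(f"invalid effect_dist: {self.effect_dist!r}")
        if self.cost_dist not in ("normal", "lognormal"):
            raise ParameterError(f"invalid cost_dist: {self.cost_dist!r}")
        for arm in (self.arm0, self.arm1):
            if self.effect_dist == "exponential" and arm.mean_effect <= 0:
                raise ParameterError(
                    f"invalid mean_effect: {arm.mean_effect!r} "
                    "(exponential marginal needs a positive mean)"
                )
            if self.cost_dist == "lognormal" and arm.mean_cost <= 0:
                raise ParameterError(
                    f"invalid mean_cost: {arm.mean_cost!r} "
                    "(lognormal marginal needs a positive mean)"
                )


# --- marginal machinery -----------------------------------------------------


def _effect_marginal(dist: EffectDist, mean: float, sd: float):
    """(ppf-from-standard-normal, mean, sd) of the effectiveness marginal."""
    if dist == "normal":
        return (lambda z: mean + sd * z), mean, sd
    # exponential with the given mean; implied sd = mean
    return (lambda z: -mean * np.log(norm.sf(z))), mean, mean


def _cost_marginal(dist: CostDist, mean: float, sd: float):
    if dist == "normal":
        return (lambda z: mean + sd * z), mean, sd
    # lognormal matching mean and sd
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    s = math.sqrt(s2)
    return (lambda z: np.exp(mu + s * z)), mean, sd


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(48)
_GH_Z = _GH_NODES * math.sqrt(2.0)
_GH_W = _GH_WEIGHTS / math.sqrt(math.pi)


def _induced_pearson(latent_r: float, ppf_x, mx, sx, ppf_y, my, sy) -> float:
    """Pearson correlation of (ppf_x(Z1), ppf_y(Z2)) for latent corr r,
    by 2-D Gauss–Hermite quadrature."""
    z1 = _GH_Z[:, None]
    z2 = latent_r * z1 + math.sqrt(max(0.0, 1.0 - latent_r**2)) * _GH_Z[None, :]
    exy = float(_GH_W @ (ppf_x(z1 * np.ones_like(z2)) * ppf_y(z2)) @ _GH_W)
    return (exy - mx * my) / (sx * sy)


def _latent_corr(target_rho: float, ppf_x, mx, sx, ppf_y, my, sy) -> float:
    """Latent Gaussian correlation reproducing the target Pearson rho."""
    f = lambda r: _induced_pearson(r, ppf_x, mx, sx, ppf_y, my, sy) - target_rho
    eps = 1e-6
    lo, hi = f(-1.0 + eps), f(1.0 - eps)
    if not lo <= 0.0 <= hi:
        raise ParameterError(
            f"invalid rho: {target_rho!r} not attainable for these marginals "
            f"(attainable range [{lo + target_rho:.4f}, {hi + target_rho:.4f}])"
        )
    return brentq(f, -1.0 + eps, 1.0 - eps, xtol=1e-10)


def _arm_sampler(spec: SimSpec, arm: ArmStats):
    """Closure drawing (effect, cost) arrays for one arm from an rng."""
    ppf_e, me, se = _effect_marginal(spec.effect_dist, arm.mean_effect, arm.sd_effect)
    ppf_c, mc, sc = _cost_marginal(spec.cost_dist, arm.mean_cost, arm.sd_cost)
    if spec.effect_dist == "normal" and spec.cost_dist == "normal":
        r = arm.rho
    else:
        r = _latent_corr(arm.rho, ppf_e, me, se, ppf_c, mc, sc)
    root = math.sqrt(max(0.0, 1.0 - r**2))

    def draw(rng: np.random.Generator, n: int):
        z = rng.standard_normal((n, 2))
        z2 = r * z[:, 0] + root * z[:, 1]
        return ppf_e(z[:, 0]), ppf_c(z2)

    return draw


def generate_ipd(spec: SimSpec, seed: Optional[int] = None) -> IPDTable:
    """Draw one synthetic two-arm trial.

    ``seed`` overrides ``spec.seed``; identical seeds give identical tables.
    """
    master = spec.seed if seed is None else seed
    rng = np.random.default_rng(master)
    effects, costs, arms = [], [], []
    for label, arm in ((0, spec.arm0), (1, spec.arm1)):
        e, c = _arm_sampler(spec, arm)(rng, arm.n)
        effects.append(e)
        costs.append(c)
        arms.append(np.full(arm.n, label))
    return IPDTable(
        arm=np.concatenate(arms),
        effect=np.concatenate(effects),
        cost=np.concatenate(costs),
    )


def _moments(effect: np.ndarray, cost: np.ndarray):
    se = effect.std(ddof=1)
    sc = cost.std(ddof=1)
    if se == 0 or sc == 0:
        raise ParameterError(
            "degenerate column: zero sample variance in effect or cost"
        )
    rho = float(np.corrcoef(effect, cost)[0, 1])
    return float(effect.mean()), float(se), float(cost.mean()), float(sc), rho


def estimate_arm_stats(table: IPDTable) -> tuple[ArmStats, ArmStats]:
    """Per-arm sample means, SDs (n-1 denominator) and Pearson correlations."""
    out = []
    for a in (0, 1):
        mask = table.arm == a
        me, se, mc, sc, rho = _moments(table.effect[mask], table.cost[mask])
        out.append(
            ArmStats(
                n=int(mask.sum()),
                mean_effect=me,
                sd_effect=se,
                mean_cost=mc,
                sd_cost=sc,
                rho=rho,
            )
        )
    return tuple(out)


@dataclass(frozen=True)
class EmpiricalPower:
    """Monte-Carlo rejection fraction with its binomial standard error."""

    power: float
    se: float
    rejections: int
    replicates: int


def empirical_power(
    spec: SimSpec,
    test: TestSpec,
    replicates: int = 1000,
    seed: Optional[int] = None,
) -> EmpiricalPower:
    """Monte-Carlo power of the INB z-test.

    Per replicate: simulate a trial from ``spec``, plug the per-arm sample
    moments into the two-arm INB variance, and reject H0 when the
    standardized INB estimate exceeds the normal critical value for
    ``test.direction``.  The rejection fraction estimates the true power of
    the procedure and is the independent oracle for the analytic formula.
    """
    if replicates < 100:
        raise ParameterError(f"invalid replicates: {replicates!r} (need >= 100)")
    draw0 = _arm_sampler(spec, spec.arm0)
    draw1 = _arm_sampler(spec, spec.arm1)
    n0, n1 = spec.arm0.n, spec.arm1.n
    master = spec.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(replicates)
    lam = test.wtp
    z_crit = norm.ppf(
        1.0 - (test.alpha / 2.0 if test.direction == "two_sided" else test.alpha)
    )
    rejections = 0
    for child in children:
        rng = np.random.default_rng(child)
        e0, c0 = draw0(rng, n0)
        e1, c1 = draw1(rng, n1)
        m0 = _moments(e0, c0)
        m1 = _moments(e1, c1)
        b_hat = lam * (m1[0] - m0[0]) - (m1[2] - m0[2])
        var = sum(
            (lam**2 * se**2 + sc**2 - 2.0 * lam * rho * se * sc) / n
            for (se, sc, rho, n) in (
                (m0[1], m0[3], m0[4], n0),
                (m1[1], m1[3], m1[4], n1),
            )
        )
        stat = b_hat / math.sqrt(var)
        if test.direction == "greater":
            reject = stat > z_crit
        elif test.direction == "less":
            reject = stat < -z_crit
        else:
            reject = abs(stat) > z_crit
        rejections += bool(reject)
    p = rejections / replicates
    se_p = math.sqrt(p * (1.0 - p) / replicates)
    return EmpiricalPower(power=p, se=se_p, rejections=rejections, replicates=replicates)
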