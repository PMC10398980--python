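"""Domain types and bundled trial parameter sets.

The central objects of a trial-based cost-effectiveness power analysis are
per-arm summary moments (:class:`ArmStats`), pooled design parameters under
the balanced / common-variance simplification (:class:`SimplifiedCEAParams`),
and the hypothesis-test specification (:class:`TestSpec`).  The module also
ships the five Canadian Cancer Trials Group (CCTG) parameter sets used
throughout the documentation and tests.

All monetary quantities are Canadian dollars (CAD); effectiveness is measured
in life-years or QALYs depending on the trial.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Optional

__all__ = [
    "ArmStats",
    "SimplifiedCEAParams",
    "TestSpec",
    "SmallestImportantDifference",
    "CCTGTrial",
    "load_cctg_fixtures",
    "validate_params",
    "ParameterError",
]

Direction = Literal["greater", "less", "two_sided"]

_FIXTURE_FILE = "cctg_trials.json"


class ParameterError(ValueError):
    """Raised when a parameter violates its invariant.

    The message always names the offending field and echoes the value so
    configuration mistakes surface immediately.
    """


def _require(condition: bool, name: str, value) -> None:
    if not condition:
        raise ParameterError(f"invalid {name}: {value!r}")


@dataclass(frozen=True)
class ArmStats:
    """Summary moments of one randomized arm.

    Parameters
    ----------
    n : int
        Number of patients in the arm (>= 2).
    mean_effect, sd_effect : float
        Mean and standard deviation of effectiveness (life-years / QALYs).
    mean_cost, sd_cost : float
        Mean and standard deviation of cost (CAD).
    rho : float
        Within-arm Pearson correlation between effectiveness and cost.
    """

    n: int
    mean_effect: float
    sd_effect: float
    mean_cost: float
    sd_cost: float
    rho: float

    def __post_init__(self) -> None:
        _require(self.n >= 2, "n", self.n)
        _require(self.sd_effect > 0, "sd_effect", self.sd_effect)
        _require(self.sd_cost > 0, "sd_cost", self.sd_cost)
        _require(-1.0 <= self.rho <= 1.0, "rho", self.rho)


@dataclass(frozen=True)
class SimplifiedCEAParams:
    """Pooled design parameters of a balanced two-arm CEA.

    Assumes equal allocation and common per-arm standard deviations and
    correlation, the standard simplification for a-priori design work.

    Parameters
    ----------
    n_total : int
        Total sample size over both arms (>= 4, balanced allocation).
    sd_effect, sd_cost : float
        Common per-arm SD of effectiveness and of cost (CAD).
    rho : float
        Common within-arm effectiveness-cost correlation.
    delta_e, delta_c : float
        Incremental effectiveness (effect units) and incremental cost (CAD)
        of experimental versus control.
    pi : float, default 1.0
        Event ratio n_e / d_e of the efficacy design: planned sample size
        over planned number of events (>= 1).  Inflates the effectiveness
        variance contribution in the sample-size formula to account for
        censoring; irrelevant to the variance of an observed INB.
    """

    n_total: int
    sd_effect: float
    sd_cost: float
    rho: float
    delta_e: float
    delta_c: float
    pi: float = 1.0

    def __post_init__(self) -> None:
        _require(self.n_total >= 4, "n_total", self.n_total)
        _require(self.sd_effect > 0, "sd_effect", self.sd_effect)
        _require(self.sd_cost > 0, "sd_cost", self.sd_cost)
        _require(-1.0 <= self.rho <= 1.0, "rho", self.rho)
        _require(self.pi >= 1.0, "pi", self.pi)

    def with_(self, **changes) -> "SimplifiedCEAParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TestSpec:
    """Hypothesis-test specification for the INB at a willingness-to-pay.

    ``direction`` selects the alternative: ``"greater"`` tests
    H1: b(lambda) > 0 (treatment cost-effective), ``"less"`` the mirror
    image, and ``"two_sided"`` H1: b(lambda) != 0.
    """

    alpha: float = 0.05
    target_power: float = 0.80
    wtp: float = 100_000.0
    direction: Direction = "greater"

    def __post_init__(self) -> None:
        _require(0 < self.alpha < 0.5, "alpha", self.alpha)
        _require(0 < self.target_power < 1, "target_power", self.target_power)
        _require(self.wtp >= 0, "wtp", self.wtp)
        _require(
            self.direction in ("greater", "less", "two_sided"),
            "direction",
            self.direction,
        )


@dataclass(frozen=True)
class SmallestImportantDifference:
    """How the smallest important INB difference b(lambda)_delta is set.

    ``observed``     -- lambda * delta_e - delta_c from the supplied increments;
    ``frequentist``  -- the minimum detectable difference at the given alpha,
                        power and INB standard deviation (Lachin-style);
    ``explicit``     -- a user-supplied CAD value.
    """

    mode: Literal["observed", "frequentist", "explicit"] = "observed"
    value: Optional[float] = None

    def __post_init__(self) -> None:
        _require(
            self.mode in ("observed", "frequentist", "explicit"),
            "mode",
            self.mode,
        )
        if self.mode == "explicit":
            _require(
                self.value is not None and math.isfinite(self.value),
                "value",
                self.value,
            )


@dataclass(frozen=True)
class CCTGTrial:
    """One bundled CCTG parameter set.

    Carries the published total sample size, experimental-arm standard
    deviations and within-arm correlation.  Standard errors of the arm means
    are metadata only and never enter a computation.  Incremental
    effectiveness/cost are not published in the summary table and must be
    supplied by the user via :meth:`to_params`.
    """

    name: str
    n_total: int
    sd_effect: float
    sd_cost: float
    rho: float
    se_effect: float
    se_cost: float
    note: Optional[str] = None
    reference_variance_rho0_thousands: Optional[float] = field(default=None, repr=False)
    reference_variance_rho_obs_thousands: Optional[float] = field(default=None, repr=False)
    reference_relative_change_pct: Optional[float] = field(default=None, repr=False)

    def to_params(
        self,
        delta_e: float,
        delta_c: float,
        pi: float = 1.0,
        rho: Optional[float] = None,
    ) -> SimplifiedCEAParams:
        """Build pooled design parameters from this trial's moments.

        ``rho`` overrides the observed correlation (e.g. the conservative
        rho = 0 scenario)."""
        return SimplifiedCEAParams(
            n_total=self.n_total,
            sd_effect=self.sd_effect,
            sd_cost=self.sd_cost,
            rho=self.rho if rho is None else rho,
            delta_e=delta_e,
            delta_c=delta_c,
            pi=pi,
        )


def _fixture_text() -> str:
    try:
        return (
            resources.files("inbpower").joinpath("data", _FIXTURE_FILE).read_text()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise RuntimeError(
            f"bundled fixture file {_FIXTURE_FILE!r} is missing or unreadable"
        ) from exc


def load_cctg_fixtures() -> dict[str, CCTGTrial]:
    """Load the five bundled CCTG parameter sets.

    Returns a mapping from trial name (``"BR.10"``, ``"BR.21"``, ``"LY.12"``,
    ``"CO.17 (all patients)"``, ``"CO.17 (KRAS subgroup)"``) to
    :class:`CCTGTrial`.
    """
    try:
        raw = json.loads(_fixture_text())
        trials = {
            name: CCTGTrial(name=name, **entry)
            for name, entry in raw["trials"].items()
        }
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise RuntimeError(
            f"bundled fixture file {_FIXTURE_FILE!r} is corrupt: {exc}"
        ) from exc
    return trials


def load_worked_example() -> dict:
    """Published CO.17 variance-versus-correlation reference lines.

    Returns the raw reference block, including the entries known to be
    internally inconsistent with the sigma inputs (see the ``comment`` key);
    used by the reproduce report to flag them.
    """
    return json.loads(_fixture_text())["worked_example"]


_PARAM_FIELDS = {f.name: f for f in dataclasses.fields(SimplifiedCEAParams)}


def validate_params(raw: Mapping) -> SimplifiedCEAParams:
    """Build :class:`SimplifiedCEAParams` from an untyped mapping.

    Unknown keys are rejected; a missing ``pi`` defaults to 1.  All invariant
    violations are reported with the offending field name and value.
    """
    unknown = set(raw) - set(_PARAM_FIELDS)
    if unknown:
        raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
    missing = {
        name
        for name, f in _PARAM_FIELDS.items()
        if f.default is dataclasses.MISSING and name not in raw
    }
    if missing:
        raise ParameterError(f"missing parameter(s): {sorted(missing)}")
    kwargs = {}
    for name, value in raw.items():
        caster = int if name == "n_total" else float
        try:
            kwargs[name] = caster(value)
        except (TypeError, ValueError):
            raise ParameterError(f"invalid {name}: {value!r}") from None
    return SimplifiedCEAParams(**kwargs)
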