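"""Model inputs: natural history, test performance, compliance, costs,
utilities, economic settings, strategies and PrSA distribution assignments.

Parameters are read from / written to a human-editable YAML document (or a
flat CSV table).  A packaged default set ``fixture-hk2009`` carries every
value printed in the source cost-effectiveness literature for the Hong Kong
setting (compliance rates, discount rate, utility scenario sets, exchange
rate, strategy definitions); all remaining numeric inputs are
literature-plausible placeholders and are tagged ``placeholder`` in the
document's ``source_tags`` section, which the loader surfaces in logs so
they cannot be mistaken for calibrated values.
"""

from __future__ import annotations

import copy
import dataclasses
import io
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .states import (
    ALIVE_STATES,
    DEATH_STATES,
    DIAG_STATES,
    UNDIAG_STATES,
    HealthState,
    N_STATES,
)

logger = logging.getLogger(__name__)

STAGES = ("I", "II", "III", "IV")
SEXES = ("male", "female")
TEST_NAMES = ("g_fobt", "i_fobt", "colonoscopy")


class SchemaError(ValueError):
    """A required key is missing from a parameter document."""


class ParameterValidationError(ValueError):
    """One or more parameter values violate their bounds or invariants.

    Carries a list of (path, message) pairs in ``errors``.
    """

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = errors
        lines = "; ".join(f"{p}: {m}" for p, m in errors)
        super().__init__(f"invalid parameters: {lines}")


def _check_prob(errors: list, path: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        errors.append((path, f"non-finite value {value!r}"))
    elif not 0.0 <= value <= 1.0:
        errors.append((path, f"value {value} outside [0, 1]"))


def _check_nonneg(errors: list, path: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        errors.append((path, f"non-finite value {value!r}"))
    elif value < 0:
        errors.append((path, f"value {value} below 0"))


# ---------------------------------------------------------------------------
# Component parameter blocks


@dataclass
class NaturalHistoryParams:
    """Annual transition probabilities of the unscreened disease process.

    Normal epithelium and low-risk polyps carry no direct one-year CRC
    risk: cancer arises only from high-risk polyps.  ``crc_entry_distribution``
    splits incident cancer over undiagnosed stages I-III (default: all to
    stage I).  ``m_crc`` applies to undiagnosed and diagnosed disease alike;
    diagnosis halts stage progression but not mortality.
    """

    p_normal_to_low: float
    p_low_to_high: float
    p_high_to_crc: float
    p_stage_progress: list  # I->II, II->III, III->IV
    p_symptomatic: list  # stages I..IV
    m_crc: list  # stages I..IV
    initial_distribution: list  # NORMAL, LOW_RISK_POLYP, HIGH_RISK_POLYP at entry
    crc_entry_distribution: list = field(default_factory=lambda: [1.0, 0.0, 0.0])

    def validate(self, errors: list, prefix: str = "natural_history") -> None:
        for name in ("p_normal_to_low", "p_low_to_high", "p_high_to_crc"):
            _check_prob(errors, f"{prefix}.{name}", getattr(self, name))
        for name, n in (
            ("p_stage_progress", 3),
            ("p_symptomatic", 4),
            ("m_crc", 4),
            ("initial_distribution", 3),
            ("crc_entry_distribution", 3),
        ):
            vals = getattr(self, name)
            if len(vals) != n:
                errors.append((f"{prefix}.{name}", f"expected {n} entries, got {len(vals)}"))
                continue
            for i, v in enumerate(vals):
                _check_prob(errors, f"{prefix}.{name}.{i}", v)
        if abs(sum(self.initial_distribution) - 1.0) > 1e-9:
            errors.append(
                (f"{prefix}.initial_distribution", f"sums to {sum(self.initial_distribution)}, expected 1")
            )
        if abs(sum(self.crc_entry_distribution) - 1.0) > 1e-9:
            errors.append(
                (f"{prefix}.crc_entry_distribution", f"sums to {sum(self.crc_entry_distribution)}, expected 1")
            )


@dataclass
class MortalityBand:
    sex: str
    age_lo: int
    age_hi: int  # inclusive
    all_cause: float
    crc: float


class MortalityTable:
    """Quinquennial all-cause and CRC mortality rates by sex.

    Bands must jointly cover [entry_age, exit_age] for each sex.
    """

    def __init__(self, bands: Iterable[MortalityBand]):
        self.bands = list(bands)

    def lookup(self, sex: str, age: float) -> MortalityBand:
        for b in self.bands:
            if b.sex == sex and b.age_lo <= age <= b.age_hi:
                return b
        raise KeyError(f"no mortality band covers sex={sex!r}, age={age}")

    def validate(self, errors: list, prefix: str = "mortality") -> None:
        for i, b in enumerate(self.bands):
            _check_prob(errors, f"{prefix}.{i}.all_cause", b.all_cause)
            _check_prob(errors, f"{prefix}.{i}.crc", b.crc)
            if b.sex not in SEXES:
                errors.append((f"{prefix}.{i}.sex", f"unknown sex {b.sex!r}"))

    def covers(self, sex: str, lo: int, hi: int) -> bool:
        try:
            for age in range(lo, hi + 1):
                self.lookup(sex, age)
        except KeyError:
            return False
        return True

    def to_records(self) -> list[dict]:
        return [dataclasses.asdict(b) for b in self.bands]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "MortalityTable":
        return cls(MortalityBand(**r) for r in records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_records())[
            ["sex", "age_lo", "age_hi", "all_cause", "crc"]
        ].rename(columns={"age_lo": "age_band_start", "age_hi": "age_band_end",
                          "all_cause": "all_cause_rate", "crc": "crc_rate"})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MortalityTable":
        df = df.rename(columns={"age_band_start": "age_lo", "age_band_end": "age_hi",
                                "all_cause_rate": "all_cause", "crc_rate": "crc"})
        return cls.from_records(df[["sex", "age_lo", "age_hi", "all_cause", "crc"]].to_dict("records"))

    def __eq__(self, other):
        return isinstance(other, MortalityTable) and self.to_records() == other.to_records()


@dataclass
class TestCharacteristics:
    """Diagnostic performance and procedural harms of one screening test.

    Colonoscopy is modelled with perfect sensitivity and specificity; stool
    tests carry no procedural complication risk.
    """

    name: str
    sens_low_polyp: float
    sens_high_polyp: float
    sens_crc: list  # per stage I..IV
    specificity: float
    p_bleed: float = 0.0
    p_perforation: float = 0.0
    m_bleed: float = 0.0
    m_perforation: float = 0.0

    def validate(self, errors: list, prefix: str) -> None:
        _check_prob(errors, f"{prefix}.sens_low_polyp", self.sens_low_polyp)
        _check_prob(errors, f"{prefix}.sens_high_polyp", self.sens_high_polyp)
        if len(self.sens_crc) != 4:
            errors.append((f"{prefix}.sens_crc", f"expected 4 entries, got {len(self.sens_crc)}"))
        else:
            for i, v in enumerate(self.sens_crc):
                _check_prob(errors, f"{prefix}.sens_crc.{i}", v)
        for name in ("specificity", "p_bleed", "p_perforation", "m_bleed", "m_perforation"):
            _check_prob(errors, f"{prefix}.{name}", getattr(self, name))
        if self.name == "colonoscopy":
            if self.specificity != 1.0 or self.sens_low_polyp != 1.0 or self.sens_high_polyp != 1.0 \
                    or any(s != 1.0 for s in self.sens_crc):
                errors.append((prefix, "colonoscopy must have sensitivity and specificity of 1"))
        if self.name in ("g_fobt", "i_fobt") and (self.p_bleed != 0 or self.p_perforation != 0):
            errors.append((prefix, "stool tests carry no complication risk"))

    def sensitivity_for(self, state: HealthState) -> float:
        if state == HealthState.LOW_RISK_POLYP:
            return self.sens_low_polyp
        if state == HealthState.HIGH_RISK_POLYP:
            return self.sens_high_polyp
        if state in UNDIAG_STATES:
            return self.sens_crc[int(state) - int(HealthState.UNDIAG_CRC_I)]
        raise ValueError(f"no lesion sensitivity for state {state!r}")


@dataclass
class ComplianceParams:
    """Participation probabilities, independent across rounds (memory-less)."""

    c_screen: float = 0.60
    c_followup: float = 0.80
    c_symptomatic: float = 1.0

    def validate(self, errors: list, prefix: str = "compliance") -> None:
        for name in ("c_screen", "c_followup", "c_symptomatic"):
            _check_prob(errors, f"{prefix}.{name}", getattr(self, name))


UNIT_COST_KEYS = (
    "g_fobt",
    "i_fobt",
    "colonoscopy",
    "polypectomy",
    "complication_bleed",
    "complication_perforation",
    "specialist_visit",
)


@dataclass
class CostParams:
    """Direct medical costs, USD at 2009 prices.

    ``initial_cost`` is the first-year-of-diagnosis cost per stage;
    ``continuing_cost`` prices every subsequent year, with the terminal year
    priced identically to the continuing phase (single field).
    """

    unit_cost: dict
    initial_cost: list  # per stage I..IV
    continuing_cost: list  # per stage I..IV
    hkd_per_usd: float = 7.8

    def validate(self, errors: list, prefix: str = "costs") -> None:
        for key in UNIT_COST_KEYS:
            if key not in self.unit_cost:
                errors.append((f"{prefix}.unit_cost.{key}", "missing unit cost"))
            else:
                _check_nonneg(errors, f"{prefix}.unit_cost.{key}", self.unit_cost[key])
        for name in ("initial_cost", "continuing_cost"):
            vals = getattr(self, name)
            if len(vals) != 4:
                errors.append((f"{prefix}.{name}", f"expected 4 entries, got {len(vals)}"))
                continue
            for i, v in enumerate(vals):
                _check_nonneg(errors, f"{prefix}.{name}.{i}", v)
        _check_nonneg(errors, f"{prefix}.hkd_per_usd", self.hkd_per_usd)


@dataclass
class UtilityParams:
    """SF-6D-style utility weights per alive state (death = 0, full health = 1).

    Undiagnosed and diagnosed disease may carry distinct weights; the default
    set assigns them equal stage-specific values.
    """

    u_normal: float = 1.0
    u_low_polyp: float = 1.0
    u_high_polyp: float = 1.0
    u_undiag: list = field(default_factory=lambda: [1.0, 1.0, 1.0, 1.0])
    u_diag: list = field(default_factory=lambda: [1.0, 1.0, 1.0, 1.0])

    def validate(self, errors: list, prefix: str = "utilities") -> None:
        for name in ("u_normal", "u_low_polyp", "u_high_polyp"):
            _check_prob(errors, f"{prefix}.{name}", getattr(self, name))
        for name in ("u_undiag", "u_diag"):
            vals = getattr(self, name)
            if len(vals) != 4:
                errors.append((f"{prefix}.{name}", f"expected 4 entries, got {len(vals)}"))
                continue
            for i, v in enumerate(vals):
                _check_prob(errors, f"{prefix}.{name}.{i}", v)

    def state_vector(self) -> np.ndarray:
        """Length-14 utility vector; death states contribute 0."""
        u = np.zeros(N_STATES)
        u[HealthState.NORMAL] = self.u_normal
        u[HealthState.LOW_RISK_POLYP] = self.u_low_polyp
        u[HealthState.HIGH_RISK_POLYP] = self.u_high_polyp
        for k in range(4):
            u[HealthState.UNDIAG_CRC_I + k] = self.u_undiag[k]
            u[HealthState.DIAG_CRC_I + k] = self.u_diag[k]
        return u

    @classmethod
    def from_scenario(cls, cancer_free: float, stages: list) -> "UtilityParams":
        """Scenario set: one cancer-free weight, stage-specific CRC weights
        shared by undiagnosed and diagnosed disease."""
        return cls(
            u_normal=cancer_free,
            u_low_polyp=cancer_free,
            u_high_polyp=cancer_free,
            u_undiag=list(stages),
            u_diag=list(stages),
        )


#: Published alternative utility scenario sets used in multivariate analysis.
UTILITY_SETS = {
    "ramsey": UtilityParams.from_scenario(1.00, [0.90, 0.90, 0.80, 0.76]),
    "ness": UtilityParams.from_scenario(0.91, [0.74, 0.70, 0.50, 0.25]),
    "sharp": UtilityParams.from_scenario(0.94, [0.80, 0.80, 0.80, 0.80]),
    "all_ones": UtilityParams.from_scenario(1.0, [1.0, 1.0, 1.0, 1.0]),
}


@dataclass
class EconSettings:
    discount_rate: float = 0.035
    horizon_years: int = 25
    cycle_length: int = 1
    cohort_size: int = 100_000
    entry_age: int = 50
    exit_age: int = 75
    wtp_threshold: float = 50_000.0
    half_cycle_correction: bool = True
    sex_weights: list = field(default_factory=lambda: [0.5, 0.5])  # male, female

    def validate(self, errors: list, prefix: str = "econ") -> None:
        if self.discount_rate < 0:
            errors.append((f"{prefix}.discount_rate", f"{self.discount_rate} below 0"))
        if self.horizon_years != self.exit_age - self.entry_age:
            errors.append(
                (f"{prefix}.horizon_years",
                 f"{self.horizon_years} != exit_age - entry_age = {self.exit_age - self.entry_age}")
            )
        if self.cycle_length != 1:
            errors.append((f"{prefix}.cycle_length", "only 1-year cycles are supported"))
        if abs(sum(self.sex_weights) - 1.0) > 1e-9:
            errors.append((f"{prefix}.sex_weights", f"sum to {sum(self.sex_weights)}, expected 1"))
        _check_nonneg(errors, f"{prefix}.wtp_threshold", self.wtp_threshold)
        if self.cohort_size < 1:
            errors.append((f"{prefix}.cohort_size", "cohort_size must be >= 1"))


@dataclass
class ScreeningStrategy:
    """One comparator: a primary test with a repeat interval and age window."""

    name: str
    primary_test: Optional[str]  # None | 'g_fobt' | 'i_fobt' | 'colonoscopy'
    interval_years: Optional[int] = None
    start_age: int = 50
    stop_age: int = 75

    def validate(self, errors: list, prefix: str) -> None:
        if self.primary_test is not None and self.primary_test not in TEST_NAMES:
            errors.append((f"{prefix}.primary_test", f"unknown test {self.primary_test!r}"))
        if self.primary_test is not None and (self.interval_years is None or self.interval_years < 1):
            errors.append((f"{prefix}.interval_years", "screening strategy needs a positive interval"))

    def round_due(self, age: int) -> bool:
        if self.primary_test is None:
            return False
        if not (self.start_age <= age < self.stop_age):
            return False
        return (age - self.start_age) % self.interval_years == 0


def default_strategies() -> list[ScreeningStrategy]:
    """The six comparators: no screening, annual/biennial G-FOBT and I-FOBT,
    and colonoscopy every 10 years."""
    return [
        ScreeningStrategy("no_screening", None),
        ScreeningStrategy("annual_gfobt", "g_fobt", 1),
        ScreeningStrategy("biennial_gfobt", "g_fobt", 2),
        ScreeningStrategy("annual_ifobt", "i_fobt", 1),
        ScreeningStrategy("biennial_ifobt", "i_fobt", 2),
        ScreeningStrategy("colonoscopy_10y", "colonoscopy", 10),
    ]


# ---------------------------------------------------------------------------
# PrSA distribution assignments


@dataclass
class DistEntry:
    family: str  # 'beta' | 'lognormal' | 'fixed'
    arg1: float = 0.0  # beta: alpha; lognormal: mu (of log)
    arg2: float = 0.0  # beta: beta;  lognormal: sigma (of log)

    def draw(self, rng: np.random.Generator, base: float) -> float:
        if self.family == "fixed":
            return base
        if self.family == "beta":
            return float(rng.beta(self.arg1, self.arg2))
        if self.family == "lognormal":
            return float(rng.lognormal(self.arg1, self.arg2))
        raise ValueError(f"unknown distribution family {self.family!r}")


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shapes from a mean and standard error.

    Requires 0 < mean < 1 and se**2 < mean*(1-mean).
    """
    if not 0 < mean < 1:
        raise ValueError(f"beta mean {mean} outside (0, 1)")
    var = se * se
    if var <= 0 or var >= mean * (1 - mean):
        raise ValueError(f"beta variance {var} incompatible with mean {mean}")
    k = mean * (1 - mean) / var - 1
    return mean * k, (1 - mean) * k


def lognormal_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments log-normal (mu, sigma) from a mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ValueError("lognormal moments must be positive")
    sigma2 = math.log(1 + (se / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    return mu, math.sqrt(sigma2)


#: Parameter path prefixes that are never drawn in PrSA: the discount rate
#: and time horizon are analytic settings, and registry-based CRC mortality
#: carries negligible parameter uncertainty.
PRSA_DEFAULT_EXCLUDED = (
    "econ.discount_rate",
    "econ.horizon_years",
    "natural_history.m_crc",
    "mortality",
)


@dataclass
class PrsaDistributionSpec:
    """Per-parameter sampling families for probabilistic sensitivity analysis.

    Cost parameters are log-normal; probabilities, rates and utilities are
    beta.  Entries map dotted parameter paths to distribution shapes.
    """

    entries: dict = field(default_factory=dict)  # path -> DistEntry
    excluded: tuple = PRSA_DEFAULT_EXCLUDED

    def validate(self, errors: list, prefix: str = "prsa") -> None:
        for path, e in self.entries.items():
            if any(path.startswith(x) for x in self.excluded):
                errors.append((f"{prefix}.{path}", "excluded parameter carries a distribution"))
            if e.family not in ("beta", "lognormal", "fixed"):
                errors.append((f"{prefix}.{path}", f"unknown family {e.family!r}"))

    @classmethod
    def default_for(
        cls,
        params: "ModelParameters",
        prob_se_frac: float = 0.10,
        cost_se_frac: float = 0.20,
    ) -> "PrsaDistributionSpec":
        """Assign method-of-moments betas to every probability/utility input
        and log-normals to every cost input, with standard errors taken as a
        fraction of the base value."""
        entries: dict[str, DistEntry] = {}

        def add_beta(path: str) -> None:
            base = get_by_path(params, path)
            if base in (0.0, 1.0):
                entries[path] = DistEntry("fixed")
                return
            se = min(prob_se_frac * base, 0.9 * math.sqrt(base * (1 - base)))
            a, b = beta_from_moments(base, se)
            entries[path] = DistEntry("beta", a, b)

        def add_lognormal(path: str) -> None:
            base = get_by_path(params, path)
            if base <= 0:
                entries[path] = DistEntry("fixed")
                return
            mu, sigma = lognormal_from_moments(base, cost_se_frac * base)
            entries[path] = DistEntry("lognormal", mu, sigma)

        for name in ("p_normal_to_low", "p_low_to_high", "p_high_to_crc"):
            add_beta(f"natural_history.{name}")
        for i in range(3):
            add_beta(f"natural_history.p_stage_progress.{i}")
        for i in range(4):
            add_beta(f"natural_history.p_symptomatic.{i}")
        for test in ("g_fobt", "i_fobt"):
            add_beta(f"tests.{test}.sens_low_polyp")
            add_beta(f"tests.{test}.sens_high_polyp")
            add_beta(f"tests.{test}.specificity")
            for i in range(4):
                add_beta(f"tests.{test}.sens_crc.{i}")
        for name in ("p_bleed", "p_perforation", "m_bleed", "m_perforation"):
            add_beta(f"tests.colonoscopy.{name}")
        for name in ("c_screen", "c_followup", "c_symptomatic"):
            add_beta(f"compliance.{name}")
        add_beta("utilities.u_low_polyp")
        add_beta("utilities.u_high_polyp")
        for i in range(4):
            add_beta(f"utilities.u_undiag.{i}")
            add_beta(f"utilities.u_diag.{i}")
        for key in UNIT_COST_KEYS:
            add_lognormal(f"costs.unit_cost.{key}")
        for i in range(4):
            add_lognormal(f"costs.initial_cost.{i}")
            add_lognormal(f"costs.continuing_cost.{i}")
        return cls(entries=entries)


# ---------------------------------------------------------------------------
# Dotted-path access (used by one-way SA and PrSA)


def _resolve(obj: Any, token: str) -> Any:
    if isinstance(obj, dict):
        return obj[token]
    if isinstance(obj, (list, tuple)):
        return obj[int(token)]
    return getattr(obj, token)


def get_by_path(params: "ModelParameters", path: str) -> Any:
    obj: Any = params
    for token in path.split("."):
        obj = _resolve(obj, token)
    return obj


def set_by_path(params: "ModelParameters", path: str, value: Any) -> None:
    tokens = path.split(".")
    obj: Any = params
    for token in tokens[:-1]:
        obj = _resolve(obj, token)
    last = tokens[-1]
    if isinstance(obj, dict):
        obj[last] = value
    elif isinstance(obj, list):
        obj[int(last)] = value
    else:
        setattr(obj, last, value)


# ---------------------------------------------------------------------------
# The aggregate bundle


@dataclass
class ModelParameters:
    natural_history: NaturalHistoryParams
    mortality: MortalityTable
    tests: dict  # name -> TestCharacteristics
    compliance: ComplianceParams
    costs: CostParams
    utilities: UtilityParams
    econ: EconSettings
    strategies: list = field(default_factory=default_strategies)
    prsa: Optional[PrsaDistributionSpec] = None
    utility_sets: dict = field(default_factory=lambda: dict(UTILITY_SETS))
    source_tags: dict = field(default_factory=dict)

    def validate(self) -> None:
        errors: list[tuple[str, str]] = []
        self.natural_history.validate(errors)
        self.mortality.validate(errors)
        for name, t in self.tests.items():
            t.validate(errors, f"tests.{name}")
        self.compliance.validate(errors)
        self.costs.validate(errors)
        self.utilities.validate(errors)
        self.econ.validate(errors)
        for i, s in enumerate(self.strategies):
            s.validate(errors, f"strategies.{i}")
        if self.prsa is not None:
            self.prsa.validate(errors)
        for sex in SEXES:
            if not self.mortality.covers(sex, self.econ.entry_age, self.econ.exit_age - 1):
                errors.append(("mortality", f"bands do not cover ages "
                               f"[{self.econ.entry_age}, {self.econ.exit_age - 1}] for {sex}"))
        if errors:
            raise ParameterValidationError(errors)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "natural_history": dataclasses.asdict(self.natural_history),
            "mortality": self.mortality.to_records(),
            "tests": {k: dataclasses.asdict(v) for k, v in self.tests.items()},
            "compliance": dataclasses.asdict(self.compliance),
            "costs": dataclasses.asdict(self.costs),
            "utilities": dataclasses.asdict(self.utilities),
            "econ": dataclasses.asdict(self.econ),
            "strategies": [dataclasses.asdict(s) for s in self.strategies],
            "utility_sets": {k: dataclasses.asdict(v) for k, v in self.utility_sets.items()},
            "source_tags": dict(self.source_tags),
        }
        if self.prsa is not None:
            d["prsa"] = {
                "excluded": list(self.prsa.excluded),
                "entries": {p: dataclasses.asdict(e) for p, e in self.prsa.entries.items()},
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        required = ("natural_history", "mortality", "tests", "compliance",
                    "costs", "utilities", "econ")
        for key in required:
            if key not in d:
                raise SchemaError(f"missing required section {key!r}")
        try:
            nh = NaturalHistoryParams(**d["natural_history"])
        except TypeError as exc:
            raise SchemaError(f"natural_history: {exc}") from exc
        mort = MortalityTable.from_records(d["mortality"])
        tests = {}
        for name, td in d["tests"].items():
            td = dict(td)
            td.setdefault("name", name)
            tests[name] = TestCharacteristics(**td)
        compliance = ComplianceParams(**d["compliance"])
        costs = CostParams(**d["costs"])
        utilities = UtilityParams(**d["utilities"])
        econ = EconSettings(**d["econ"])
        strategies = [ScreeningStrategy(**s) for s in d.get("strategies", [])] or default_strategies()
        utility_sets = dict(UTILITY_SETS)
        for name, ud in d.get("utility_sets", {}).items():
            utility_sets[name] = UtilityParams(**ud)
        prsa = None
        if "prsa" in d and d["prsa"]:
            entries = {p: DistEntry(**e) for p, e in d["prsa"].get("entries", {}).items()}
            prsa = PrsaDistributionSpec(entries=entries,
                                        excluded=tuple(d["prsa"].get("excluded", PRSA_DEFAULT_EXCLUDED)))
        params = cls(
            natural_history=nh, mortality=mort, tests=tests, compliance=compliance,
            costs=costs, utilities=utilities, econ=econ, strategies=strategies,
            prsa=prsa, utility_sets=utility_sets, source_tags=d.get("source_tags", {}),
        )
        return params

    # -- CSV interchange ----------------------------------------------------

    def to_csv_frame(self) -> pd.DataFrame:
        """Flat tabular export: one row per scalar leaf."""
        rows = []

        def walk(obj: Any, path: str) -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    walk(v, f"{path}.{k}" if path else str(k))
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{path}.{i}")
            else:
                entry = self.prsa.entries.get(path) if self.prsa else None
                rows.append({
                    "parameter": path,
                    "stratum": "",
                    "value": obj,
                    "source_tag": self.source_tags.get(path, ""),
                    "distribution_family": entry.family if entry else "",
                    "dist_arg1": entry.arg1 if entry else "",
                    "dist_arg2": entry.arg2 if entry else "",
                })

        d = self.to_dict()
        for section in ("natural_history", "tests", "compliance", "costs", "utilities", "econ"):
            walk(d[section], section)
        for b in self.mortality.bands:
            for fld in ("all_cause", "crc"):
                rows.append({
                    "parameter": f"mortality.{fld}",
                    "stratum": f"{b.sex}:{b.age_lo}-{b.age_hi}",
                    "value": getattr(b, fld),
                    "source_tag": self.source_tags.get("mortality", ""),
                    "distribution_family": "", "dist_arg1": "", "dist_arg2": "",
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Loading / writing


def load_parameters(source) -> ModelParameters:
    """Load and validate a parameter bundle.

    ``source`` may be a mapping, a YAML path, or an open text stream.
    Raises :class:`SchemaError` for missing keys and
    :class:`ParameterValidationError` (naming the offending path) for
    out-of-range values.
    """
    if isinstance(source, ModelParameters):
        params = source
    elif isinstance(source, dict):
        params = ModelParameters.from_dict(source)
    else:
        if isinstance(source, (str, Path)):
            with open(source, "r") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
        if not isinstance(doc, dict):
            raise SchemaError("parameter document is not a mapping")
        params = ModelParameters.from_dict(doc)
    params.validate()
    placeholders = sorted({p for p, t in params.source_tags.items() if t == "placeholder"})
    if placeholders:
        logger.warning(
            "parameter set contains %d placeholder-tagged values (not calibrated): %s",
            len(placeholders), ", ".join(placeholders[:8]) + ("..." if len(placeholders) > 8 else ""),
        )
    return params


class _ParamDumper(yaml.SafeDumper):
    pass


_ParamDumper.add_multi_representer(
    np.floating, lambda d, x: d.represent_float(float(x)))
_ParamDumper.add_multi_representer(
    np.integer, lambda d, x: d.represent_int(int(x)))


def write_parameters(params: ModelParameters, target) -> None:
    """Write a parameter bundle as YAML to a path or stream."""
    doc = yaml.dump(params.to_dict(), Dumper=_ParamDumper, sort_keys=False)
    if isinstance(target, (str, Path)):
        Path(target).write_text(doc)
    else:
        target.write(doc)


def dumps_parameters(params: ModelParameters) -> str:
    buf = io.StringIO()
    write_parameters(params, buf)
    return buf.getvalue()


def default_parameters() -> ModelParameters:
    """The packaged ``fixture-hk2009`` default parameter set."""
    ref = resources.files("crc_cea").joinpath("data/fixture_hk2009.yaml")
    with ref.open("r") as fh:
        params = load_parameters(fh)
    if params.prsa is None:
        params.prsa = PrsaDistributionSpec.default_for(params)
    return params


# ---------------------------------------------------------------------------
# Synthetic parameter sets


def synthesize_parameters(seed: int, difficulty: str = "typical") -> ModelParameters:
    """Generate a random valid parameter set.

    The draw respects the orderings of the real disease process: adenoma
    incidence exceeds malignant conversion, CRC mortality rises with stage,
    utilities fall from normal health to stage IV, FOBT sensitivity rises
    with lesion severity, and I-FOBT is both more sensitive and more
    specific than G-FOBT.  ``difficulty`` widens the sampling ranges:
    'easy' keeps disease rare and tests accurate, 'hard' samples broader.
    """
    if difficulty not in ("easy", "typical", "hard"):
        raise ValueError(f"unknown difficulty {difficulty!r}")
    rng = np.random.default_rng(seed)
    widen = {"easy": 0.5, "typical": 1.0, "hard": 1.6}[difficulty]

    p_normal_to_low = float(rng.uniform(0.01, 0.01 + 0.04 * widen))
    p_high_to_crc = p_normal_to_low * float(rng.uniform(0.2, 0.9))  # < adenoma incidence
    nh = NaturalHistoryParams(
        p_normal_to_low=p_normal_to_low,
        p_low_to_high=float(rng.uniform(0.005, 0.005 + 0.045 * widen)),
        p_high_to_crc=p_high_to_crc,
        p_stage_progress=[float(rng.uniform(0.15, 0.15 + 0.35 * widen)) for _ in range(3)],
        p_symptomatic=sorted(float(rng.uniform(0.1, 0.9)) for _ in range(4)),
        m_crc=sorted(float(rng.uniform(0.005, 0.005 + 0.45 * widen)) for _ in range(4)),
        initial_distribution=[float(x) for x in rng.dirichlet([20.0, 3.0, 1.0])],
        crc_entry_distribution=[float(x) for x in rng.dirichlet([8.0, 1.5, 0.5])],
    )

    bands = []
    for sex in SEXES:
        base = float(rng.uniform(0.001, 0.004))
        growth = float(rng.uniform(1.3, 1.8))
        for i, lo in enumerate(range(50, 80, 5)):
            all_cause = min(base * growth**i, 0.5)
            crc = all_cause * float(rng.uniform(0.02, 0.15))
            bands.append(MortalityBand(sex, lo, lo + 4, all_cause, crc))
    mortality = MortalityTable(bands)

    # G-FOBT below I-FOBT in both sensitivity and specificity; within each
    # test, detection rises strictly with lesion severity (low polyp < high
    # polyp < CRC).
    s_low, s_high, s_crc = np.sort(rng.uniform(0.02, 0.85, size=3))
    g = TestCharacteristics(
        name="g_fobt",
        sens_low_polyp=float(s_low),
        sens_high_polyp=float(s_high),
        sens_crc=[float(s_crc)] * 4,
        specificity=float(rng.uniform(0.80, 0.93)),
    )
    shrink = float(rng.uniform(0.4, 0.9))  # 1 - miss-rate multiplier keeps order
    i_fobt = TestCharacteristics(
        name="i_fobt",
        sens_low_polyp=1 - (1 - g.sens_low_polyp) * shrink,
        sens_high_polyp=1 - (1 - g.sens_high_polyp) * shrink,
        sens_crc=[1 - (1 - g.sens_crc[0]) * shrink] * 4,
        specificity=float(rng.uniform(g.specificity + 0.01, 0.99)),
    )
    colo = TestCharacteristics(
        name="colonoscopy",
        sens_low_polyp=1.0, sens_high_polyp=1.0, sens_crc=[1.0] * 4, specificity=1.0,
        p_bleed=float(rng.uniform(0.0, 0.01)), p_perforation=float(rng.uniform(0.0, 0.005)),
        m_bleed=float(rng.uniform(0.0, 0.05)), m_perforation=float(rng.uniform(0.0, 0.1)),
    )

    compliance = ComplianceParams(
        c_screen=float(rng.uniform(0.3, 0.9)),
        c_followup=float(rng.uniform(0.5, 0.95)),
        c_symptomatic=1.0,
    )
    costs = CostParams(
        unit_cost={
            "g_fobt": float(rng.uniform(2, 10)),
            "i_fobt": float(rng.uniform(5, 20)),
            "colonoscopy": float(rng.uniform(300, 1500)),
            "polypectomy": float(rng.uniform(100, 500)),
            "complication_bleed": float(rng.uniform(500, 3000)),
            "complication_perforation": float(rng.uniform(2000, 10000)),
            "specialist_visit": float(rng.uniform(50, 250)),
        },
        initial_cost=sorted(float(rng.uniform(8000, 50000)) for _ in range(4)),
        continuing_cost=sorted(float(rng.uniform(500, 15000)) for _ in range(4)),
    )
    # Non-increasing utilities from normal health down to stage IV.
    levels = np.sort(rng.uniform(0.2, 1.0, size=7))[::-1]
    utilities = UtilityParams(
        u_normal=float(levels[0]), u_low_polyp=float(levels[1]), u_high_polyp=float(levels[2]),
        u_undiag=[float(x) for x in levels[3:7]],
        u_diag=[float(x) for x in levels[3:7]],
    )
    econ = EconSettings(sex_weights=[0.5, 0.5])
    params = ModelParameters(
        natural_history=nh, mortality=mortality,
        tests={"g_fobt": g, "i_fobt": i_fobt, "colonoscopy": colo},
        compliance=compliance, costs=costs, utilities=utilities, econ=econ,
        source_tags={"": "synthetic"},
    )
    params.prsa = PrsaDistributionSpec.default_for(params)
    params.validate()
    return params
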