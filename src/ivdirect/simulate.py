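"""Synthetic survey generator: structural causal models with known direction.

Every dataset is sampled in causal order from a fully specified structural
model mirroring the instrumented survey design:

* ``X1`` — observed categorical confounders (defaults: a 2-level, a 3-level
  and a 4-level variable echoing gender / education / age-group structure),
  each with a fixed centred level-effect pattern scaled by
  ``confounding_strength_x1`` wherever it enters Z, T or Y.
* ``X2 ~ N(0,1)`` — an optional latent confounder of T and Y only
  (``latent_x2_strength = 0`` recovers the classical IV setting).
* ``Z ~ Bernoulli(logistic(intercept + X1 effects))`` — the instrument.
* ``T`` — five-level ordinal intervention from an ordered-threshold
  (proportional-odds) model with logistic noise; the instrument enters with
  coefficient ``iv_strength``.  Cutpoints put most mass at T = 0, matching
  the heavy non-user skew of observed portal-use distributions.
* ``Y`` — five-level Likert outcome from an ordered-threshold model whose
  cutpoints skew towards confident responses.

Directions: ``forward`` draws T then Y with a ``effect_strength·(T−2)`` term;
``reverse`` draws Y first and feeds ``effect_strength·(Y−3)`` into T;
``null`` omits the edge; ``mixture`` assigns each record to an observed
subgroup (column ``grp``) that deterministically carries the forward or the
reverse mechanism.  MAR missingness (logistic in Z and Y) can be applied to
designated confounders.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .survey import StudyTable, VariableMap

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "generate_dataset",
    "preset",
    "PRESETS",
    "synthetic_variable_map",
]

DIRECTIONS = ("forward", "reverse", "null", "mixture")

#: default observed confounders: (name, marginal probabilities)
DEFAULT_X1 = (
    ("x_gender", (0.58, 0.42)),
    ("x_edu", (0.5, 0.3, 0.2)),
    ("x_age", (0.10, 0.15, 0.30, 0.45)),
)

#: centred per-level effect patterns, scaled by confounding_strength_x1
_X1_PATTERNS = {
    "x_gender": np.array([-0.5, 0.5]),
    "x_edu": np.array([-0.6, 0.0, 0.6]),
    "x_age": np.array([-0.6, -0.2, 0.2, 0.6]),
}

# ordered-threshold cutpoints (logistic latent scale)
# T baseline marginals ~ (.55, .14, .15, .08, .08): heavy non-user mass
_T_CUTS = np.array([0.2007, 0.8001, 1.6582, 2.4423])
# Y baseline marginals ~ (.05, .10, .20, .35, .30): confident-response skew
_Y_CUTS = np.array([-2.9444, -1.7346, -0.6190, 0.6190])

_MISS_Z_COEF = 0.5  # MAR missingness: logistic coefficient on Z
_MISS_Y_COEF = 0.3  # and on the centred outcome


@dataclass
class ScenarioSpec:
    """Full parameterization of one synthetic scenario."""

    n: int = 4000
    direction: str = "forward"
    x1_spec: tuple = DEFAULT_X1
    iv_strength: float = 1.2
    effect_strength: float = 0.8
    confounding_strength_x1: float = 0.5
    latent_x2_strength: float = 0.0
    mixture_fraction: float | None = None
    missing_rate: float = 0.0
    missing_on: tuple = ("x_edu",)
    z_intercept: float = 0.5
    cancer_prevalence: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"invalid field n={self.n}: must be >= 1")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"invalid field direction={self.direction!r}: one of {DIRECTIONS}"
            )
        for name, probs in self.x1_spec:
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or np.any(p > 1) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"invalid field x1_spec[{name}]: probabilities")
        if self.direction == "mixture":
            if self.mixture_fraction is None or not (0 < self.mixture_fraction < 1):
                raise ValueError(
                    "invalid field mixture_fraction: must be in (0,1) for mixture"
                )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("invalid field missing_rate: must be in [0, 1)")
        if not (0.0 < self.cancer_prevalence <= 1.0):
            raise ValueError("invalid field cancer_prevalence: must be in (0, 1]")

    def replace(self, **kw) -> "ScenarioSpec":
        return dataclasses.replace(self, **kw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["x1_spec"] = [[name, list(p)] for name, p in self.x1_spec]
        d["missing_on"] = list(self.missing_on)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["x1_spec"] = tuple((name, tuple(p)) for name, p in d["x1_spec"])
        d["missing_on"] = tuple(d["missing_on"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-record latents and generative coefficients for validation."""

    frame: pd.DataFrame  # true_propensity, x2, direction
    coefficients: dict = field(default_factory=dict)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _x1_effect(spec: ScenarioSpec, x1: dict[str, np.ndarray]) -> np.ndarray:
    """Summed centred level effects of all X1 variables, scaled by strength."""
    eff = np.zeros(spec.n)
    for name, probs in spec.x1_spec:
        pattern = _X1_PATTERNS.get(name)
        if pattern is None or len(pattern) != len(probs):
            # unseen variable: alternate +-0.5 pattern, centred
            k = len(probs)
            pattern = np.linspace(-0.5, 0.5, k)
        eff += spec.confounding_strength_x1 * pattern[x1[name]]
    return eff


def _ordinal(latent: np.ndarray, cuts: np.ndarray, offset: int = 0) -> np.ndarray:
    """Threshold a latent variable into ordered categories offset..offset+K."""
    return (latent[:, None] > cuts[None, :]).sum(axis=1) + offset


def generate_dataset(spec: ScenarioSpec) -> tuple[StudyTable, GroundTruth]:
    """Sample one dataset (and its ground truth) from the structural model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    x1 = {
        name: rng.choice(len(probs), size=n, p=np.asarray(probs, dtype=float))
        for name, probs in spec.x1_spec
    }
    x2 = rng.standard_normal(n)
    lam = spec.latent_x2_strength

    conf = _x1_effect(spec, x1)
    eta_z = spec.z_intercept + conf
    pi_true = _sigmoid(eta_z)
    z = (rng.random(n) < pi_true).astype(float)

    # per-record mechanism: +1 forward (T->Y), -1 reverse (Y->T), 0 none
    if spec.direction == "forward":
        grp = rng.random(n) < 0.5  # uninformative split for subgroup checks
        fwd = np.ones(n, dtype=bool)
        rev = np.zeros(n, dtype=bool)
    elif spec.direction == "reverse":
        grp = rng.random(n) < 0.5
        fwd = np.zeros(n, dtype=bool)
        rev = np.ones(n, dtype=bool)
    elif spec.direction == "null":
        grp = rng.random(n) < 0.5
        fwd = np.zeros(n, dtype=bool)
        rev = np.zeros(n, dtype=bool)
    else:  # mixture: observed group carries the mechanism
        fwd = rng.random(n) < spec.mixture_fraction
        rev = ~fwd
        grp = fwd

    noise_t = rng.logistic(size=n)
    noise_y = rng.logistic(size=n)

    t = np.zeros(n)
    y = np.zeros(n)

    # forward (and null) records: T first, then Y
    base_t = spec.iv_strength * z + conf + lam * x2 + noise_t
    base_y = conf + lam * x2 + noise_y
    m = ~rev
    t[m] = _ordinal(base_t[m], _T_CUTS)
    y_fwd_shift = np.where(fwd, spec.effect_strength * (t - 2.0), 0.0)
    y[m] = _ordinal(base_y[m] + y_fwd_shift[m], _Y_CUTS, offset=1)

    # reverse records: Y first, then T with the outcome feeding back
    y[rev] = _ordinal(base_y[rev], _Y_CUTS, offset=1)
    t[rev] = _ordinal(
        base_t[rev] + spec.effect_strength * (y[rev] - 3.0), _T_CUTS
    )

    cancer = (
        (rng.random(n) < spec.cancer_prevalence).astype(float)
        if spec.cancer_prevalence < 1.0
        else np.ones(n)
    )

    df = pd.DataFrame(
        {
            "Z": z,
            "T": t.astype(float),
            "Y": y.astype(float),
            "grp": grp.astype(float),
            "cancer": cancer,
        }
    )
    for name in x1:
        df[name] = x1[name].astype(float)

    # MAR missingness on designated confounders: logistic in Z and centred Y,
    # intercept calibrated so the realized rate matches missing_rate
    if spec.missing_rate > 0:
        score = _MISS_Z_COEF * z + _MISS_Y_COEF * (y - 3.0)
        a = _calibrate_intercept(score, spec.missing_rate)
        for colname in spec.missing_on:
            u = rng.random(n)
            df.loc[u < _sigmoid(a + score), colname] = np.nan

    direction_label = np.where(fwd, "forward", np.where(rev, "reverse", "none"))
    truth = GroundTruth(
        frame=pd.DataFrame(
            {"true_propensity": pi_true, "x2": x2, "direction": direction_label}
        ),
        coefficients={
            "z_intercept": spec.z_intercept,
            "iv_strength": spec.iv_strength,
            "effect_strength": spec.effect_strength,
            "confounding_strength_x1": spec.confounding_strength_x1,
            "latent_x2_strength": lam,
            "t_cutpoints": _T_CUTS.tolist(),
            "y_cutpoints": _Y_CUTS.tolist(),
        },
    )
    table = StudyTable(
        df=df,
        outcomes=["Y"],
        confounders=[name for name, _ in spec.x1_spec],
        subgroups=["grp"],
    )
    table.validate()
    return table, truth


def _calibrate_intercept(score: np.ndarray, rate: float) -> float:
    """Bisect the intercept so mean(sigmoid(a + score)) hits the target rate."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + score).mean() < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


PRESETS: dict[str, ScenarioSpec] = {
    "forward_strong": ScenarioSpec(n=4000, direction="forward"),
    "reverse_strong": ScenarioSpec(n=4000, direction="reverse"),
    "null": ScenarioSpec(n=2000, direction="null", effect_strength=0.0),
    "mixture_even": ScenarioSpec(n=6000, direction="mixture", mixture_fraction=0.5),
    "forward_confounded": ScenarioSpec(
        n=4000, direction="forward", latent_x2_strength=0.7
    ),
}


def preset(name: str, **overrides) -> ScenarioSpec:
    """A documented fixed-parameter scenario (seed etc. overridable)."""
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[name].replace(**overrides)


def synthetic_variable_map(table: StudyTable) -> VariableMap:
    """Identity variable map for re-loading a serialized synthetic table."""
    return VariableMap(
        intervention="T",
        iv="Z",
        outcomes={o: o for o in table.outcomes},
        confounders={c: c for c in table.confounders},
        subgroups={s: s for s in table.subgroups},
        cancer_flag="cancer",
        negative_missing=False,
    )
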