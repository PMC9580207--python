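"""Synthetic miRNA-seq cohorts with planted subtype and survival structure.

The generator emulates the statistical shape the downstream pipeline assumes:

* a samples × features log2-scale expression matrix with per-feature
  baselines drawn uniformly in [2, 12] (a typical miRNA-seq dynamic range),
* subtype-informative features receiving an additive mean shift
  (``effect_size``) in their subtype(s), Gaussian noise elsewhere,
* a subset of *multisubtype* features informative in 3 of the 5 subtypes —
  the kind the frequency/participation selection is designed to find.  Their
  shifts carry mixed signs across subtypes (up-regulated in some, down- in
  others, as real miRNAs are): a sign-uniform shift in 3 of 5 classes is
  gauge-equivalent, under the softmax's per-feature shift invariance, to
  coefficients in only the 2 complementary classes, and would therefore
  never register as ≥3-subtype participation downstream,
* right-censored survival times from an exponential proportional-hazards
  model over a planted prognostic subset, with independent exponential
  censoring whose rate is solved numerically to hit a target censoring
  fraction.

The default subtype sizes (86, 39, 24, 41, 41) and feature count (296) mirror
a TCGA breast-invasive-carcinoma miRNA-seq cohort after standard filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .cohort import SUBTYPES, CohortError, ExpressionCohort, SurvivalRecords

BASELINE_RANGE = (2.0, 12.0)  # log2 scale


class SimulationConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    ``informative_per_subtype`` counts subtype-exclusive informative features
    per subtype; ``n_multisubtype_features`` adds features informative in 3
    subtypes each.  Prognostic features are drawn from the multisubtype pool
    first so that the Cox filter's recovery is measurable downstream.
    """

    n_per_subtype: tuple[int, ...] = (86, 39, 24, 41, 41)
    n_features: int = 296
    informative_per_subtype: int = 10
    n_multisubtype_features: int = 10
    effect_size: float = 2.0
    # default noise keeps the 5-class task non-separable (ensemble test
    # accuracy ~0.9, as real subtype cohorts behave); tests that probe planted
    # means use a lower value explicitly
    noise_sd: float = 2.5
    n_prognostic: int = 5
    prognostic_beta: float = 1.0
    baseline_hazard_rate: float = 0.1
    censoring_rate_target: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_subtype) != len(SUBTYPES) or any(
            n <= 0 for n in self.n_per_subtype
        ):
            raise SimulationConfigError(
                "n_per_subtype: need 5 positive subtype sizes"
            )
        if self.n_features <= 0:
            raise SimulationConfigError("n_features: must be positive")
        if self.informative_per_subtype <= 0:
            raise SimulationConfigError("informative_per_subtype: must be positive")
        if self.n_multisubtype_features < 0:
            raise SimulationConfigError(
                "n_multisubtype_features: must be non-negative"
            )
        n_informative = (
            self.n_multisubtype_features
            + len(SUBTYPES) * self.informative_per_subtype
        )
        if n_informative > self.n_features:
            raise SimulationConfigError(
                "n_features: informative features "
                f"({n_informative}) exceed n_features ({self.n_features})"
            )
        if self.noise_sd <= 0:
            raise SimulationConfigError("noise_sd: must be positive")
        if self.n_prognostic < 0:
            raise SimulationConfigError("n_prognostic: must be non-negative")
        if self.n_prognostic > self.n_features:
            raise SimulationConfigError("n_prognostic: exceeds n_features")
        if self.baseline_hazard_rate <= 0:
            raise SimulationConfigError("baseline_hazard_rate: must be positive")
        if not 0.0 < self.censoring_rate_target < 1.0:
            raise SimulationConfigError(
                "censoring_rate_target: must lie strictly inside (0, 1)"
            )


@dataclass
class GroundTruth:
    """What was planted: informative sets per subtype, multisubtype set, Cox βs.

    ``signed_effects[feature][subtype]`` records the actual mean shift applied
    (±effect_size), so tests can verify separation in the planted direction.
    """

    informative_features: dict[int, set[str]]
    multisubtype_features: set[str]
    prognostic_features: dict[str, float]
    signed_effects: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        union = set().union(*self.informative_features.values()) if (
            self.informative_features
        ) else set()
        if not self.multisubtype_features <= union:
            raise CohortError("multisubtype features must be informative somewhere")
        for f in self.multisubtype_features:
            n_subtypes = sum(
                f in s for s in self.informative_features.values()
            )
            if n_subtypes < 3:
                raise CohortError(
                    f"multisubtype feature {f} informative in only "
                    f"{n_subtypes} subtypes"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_features": {
                str(j): sorted(s) for j, s in self.informative_features.items()
            },
            "multisubtype_features": sorted(self.multisubtype_features),
            "prognostic_features": dict(sorted(self.prognostic_features.items())),
            "signed_effects": {
                f: {str(j): e for j, e in sorted(d.items())}
                for f, d in sorted(self.signed_effects.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            informative_features={
                int(j): set(s) for j, s in payload["informative_features"].items()
            },
            multisubtype_features=set(payload["multisubtype_features"]),
            prognostic_features={
                k: float(v) for k, v in payload["prognostic_features"].items()
            },
            signed_effects={
                f: {int(j): float(e) for j, e in d.items()}
                for f, d in payload.get("signed_effects", {}).items()
            },
        )


def _solve_censoring_rate(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(C < T) = target.

    With T_i ~ Exp(rates_i) and C ~ Exp(c) independent,
    P(censored_i) = c / (c + rates_i); solve mean_i = target by bisection.
    """

    def frac(c: float) -> float:
        return float(np.mean(c / (c + rates))) - target

    lo = rates.min() * 1e-9
    hi = rates.max() * 1e9
    return float(brentq(frac, lo, hi, xtol=1e-12, rtol=1e-12))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionCohort, GroundTruth]:
    """Generate one cohort and its ground truth; bit-reproducible given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sub = np.asarray(config.n_per_subtype, dtype=int)
    n = int(n_sub.sum())
    p = config.n_features
    K = len(SUBTYPES)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    feature_ids = [f"miR-{k:04d}" for k in range(p)]
    labels = np.repeat(np.arange(1, K + 1), n_sub)

    # --- feature roles ----------------------------------------------------
    pool = rng.permutation(p)
    n_multi = config.n_multisubtype_features
    multi_idx = pool[:n_multi]
    singles = pool[n_multi : n_multi + K * config.informative_per_subtype]
    informative_idx: dict[int, list[int]] = {
        j: list(
            singles[
                (j - 1) * config.informative_per_subtype : j
                * config.informative_per_subtype
            ]
        )
        for j in range(1, K + 1)
    }
    # single-subtype features shift up by effect_size; multisubtype features
    # shift in 3 subtypes with mixed signs (never all equal — a sign-uniform
    # shift collapses, via softmax gauge freedom, onto the complement classes
    # and would not be identifiable as >=3-subtype participation)
    effects: dict[int, dict[int, float]] = {
        int(k): {j: config.effect_size}
        for j, idx in informative_idx.items()
        for k in idx
    }
    for k in multi_idx:
        subtypes_k = rng.choice(np.arange(1, K + 1), size=3, replace=False)
        signs = rng.choice([-1.0, 1.0], size=3)
        if np.all(signs == signs[0]):
            signs[rng.integers(3)] *= -1.0
        effects[int(k)] = {
            int(j): float(s) * config.effect_size
            for j, s in zip(subtypes_k, signs)
        }
        for j in subtypes_k:
            informative_idx[int(j)].append(int(k))

    # --- expression -------------------------------------------------------
    baseline = rng.uniform(*BASELINE_RANGE, size=p)
    values = baseline + rng.normal(0.0, config.noise_sd, size=(n, p))
    for k, per_subtype in effects.items():
        for j, effect in per_subtype.items():
            values[labels == j, k] += effect

    # --- survival ---------------------------------------------------------
    if config.n_prognostic > 0:
        ordered = list(multi_idx) + [k for k in pool[n_multi:]]
        prog_idx = np.array(ordered[: config.n_prognostic], dtype=int)
        betas = np.full(prog_idx.size, config.prognostic_beta)
        Xp = values[:, prog_idx]
        Z = (Xp - Xp.mean(axis=0)) / Xp.std(axis=0)
        linpred = Z @ betas
    else:
        prog_idx = np.array([], dtype=int)
        betas = np.array([])
        linpred = np.zeros(n)
    rates = config.baseline_hazard_rate * np.exp(linpred)
    t_event = rng.exponential(1.0 / rates)
    c_rate = _solve_censoring_rate(rates, config.censoring_rate_target)
    t_cens = rng.exponential(1.0 / c_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    cohort = ExpressionCohort(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        values=values,
        labels=labels,
        survival=SurvivalRecords(time=time, event=event),
        log_scale=True,
    )
    truth = GroundTruth(
        informative_features={
            j: {feature_ids[k] for k in idx} for j, idx in informative_idx.items()
        },
        multisubtype_features={feature_ids[k] for k in multi_idx},
        prognostic_features={
            feature_ids[k]: float(b) for k, b in zip(prog_idx, betas)
        },
        signed_effects={
            feature_ids[k]: dict(per_subtype) for k, per_subtype in effects.items()
        },
    )
    return cohort, truth


def realized_censoring(cohort: ExpressionCohort) -> float:
    """Fraction of samples with event = 0."""
    if cohort.survival is None or len(cohort.survival) == 0:
        raise CohortError("cohort has no survival records")
    return float(np.mean(cohort.survival.event == 0))
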