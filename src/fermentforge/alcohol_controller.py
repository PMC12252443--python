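"""Fuzzy soft sensor for alcohol concentration.

Wine tanks rarely carry an alcohol meter; this controller infers the
alcohol concentration (g/L) from the five measured correlates — sugar,
pH, CO₂, biomass and temperature.  Calibration is data-driven: each
attribute is partitioned into low/medium/high Gaussian classes from the
pooled training observations, and a rule base is induced by
Wang–Mendel-style grid learning (per sample, take the winning class per
attribute, weight the rule by the product of winning memberships, and
keep for each distinct antecedent combination the consequent with the
largest accumulated weight).  Inference is Mamdani: min firing
strength scaled by rule weight, max aggregation, centroid
defuzzification, followed by Gaussian smoothing of the inferred series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .fuzzy_core import (
    CLASSES,
    GaussianPartition,
    PartitionSettings,
    build_partition,
    compute_stats,
    gaussian_smooth,
)
from .simulator import ANTECEDENTS, CONSEQUENT, FermentationCurve

__all__ = ["FuzzyRule", "AlcoholController", "train_controller"]

logger = logging.getLogger(__name__)

ACTIVATION_FLOOR = 1e-6


@dataclass(frozen=True)
class FuzzyRule:
    """IF (attribute is class, ...) THEN alcohol is class, with a weight."""

    antecedent: tuple  # class index per antecedent attribute, ANTECEDENTS order
    consequent: int  # class index of the alcohol partition
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("rule weight must lie in [0, 1]")
        if len(self.antecedent) != len(ANTECEDENTS):
            raise ValueError("rule must cover all five antecedent attributes")


@dataclass
class AlcoholController:
    """Calibrated partitions + induced rule base + smoothing settings."""

    partitions: dict  # attribute -> GaussianPartition (5 antecedents + consequent)
    rules: list = field(default_factory=list)
    smoothing_sigma: float = 2.0
    defuzz_grid_size: int = 501

    def __post_init__(self) -> None:
        missing = [a for a in (*ANTECEDENTS, CONSEQUENT) if a not in self.partitions]
        if missing:
            raise ValueError(f"missing partitions for {missing}")

    # -- inference ----------------------------------------------------------

    def _firing_strengths(self, samples: np.ndarray) -> np.ndarray:
        """(n_samples, n_rules) Mamdani firing strengths (min ∘ weight)."""
        if not self.rules:
            raise ValueError("controller has an empty rule base")
        # memberships[a] has shape (3, n); clip inputs to each universe
        memberships = []
        for j, attr in enumerate(ANTECEDENTS):
            part = self.partitions[attr]
            x = np.clip(samples[:, j], *part.universe)
            memberships.append(part.memberships(x))
        ante = np.array([r.antecedent for r in self.rules])  # (R, 5)
        weights = np.array([r.weight for r in self.rules])
        # per rule, min over the 5 selected class memberships
        per_attr = np.stack(
            [memberships[j][ante[:, j], :] for j in range(len(ANTECEDENTS))]
        )  # (5, R, n)
        return (per_attr.min(axis=0) * weights[:, None]).T  # (n, R)

    def infer_alcohol(self, sample) -> float:
        """Infer alcohol (g/L) from one record of the 5 antecedent values."""
        return float(self._infer_batch(np.asarray(sample, dtype=float)[None, :])[0])

    def _infer_batch(self, samples: np.ndarray) -> np.ndarray:
        strengths = self._firing_strengths(samples)  # (n, R)
        cons_part = self.partitions[CONSEQUENT]
        grid = cons_part.grid(self.defuzz_grid_size)
        mf = cons_part.memberships(grid)  # (3, G)
        cons = np.array([r.consequent for r in self.rules])
        # per consequent class, strongest firing rule
        class_strength = np.zeros((samples.shape[0], len(CLASSES)))
        for c in range(len(CLASSES)):
            mask = cons == c
            if mask.any():
                class_strength[:, c] = strengths[:, mask].max(axis=1)
        agg = np.maximum.reduce(
            [np.minimum(class_strength[:, c : c + 1], mf[c][None, :]) for c in range(len(CLASSES))]
        )  # (n, G)
        area = agg.sum(axis=1)
        out = np.empty(samples.shape[0])
        covered = area > ACTIVATION_FLOOR
        out[covered] = (agg[covered] @ grid) / area[covered]
        if np.any(~covered):
            logger.warning(
                "%d sample(s) fired no rule above the activation floor; "
                "returning the consequent-universe midpoint",
                int(np.sum(~covered)),
            )
            out[~covered] = 0.5 * (grid[0] + grid[-1])
        return out

    def infer_series(self, curve: FermentationCurve) -> np.ndarray:
        """Pointwise inference over a curve, then Gaussian smoothing."""
        missing = [a for a in ANTECEDENTS if a not in curve.data.columns]
        if missing:
            raise ValueError(f"curve lacks antecedent attributes {missing}")
        samples = curve.data[list(ANTECEDENTS)].to_numpy(dtype=float)
        raw = self._infer_batch(samples)
        return gaussian_smooth(raw, self.smoothing_sigma)

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "smoothing_sigma": self.smoothing_sigma,
            "defuzz_grid_size": self.defuzz_grid_size,
            "partitions": {
                name: {
                    "centers": list(map(float, p.centers)),
                    "width": float(p.width),
                    "universe": list(map(float, p.universe)),
                    "offsets": list(map(float, p.offsets)),
                }
                for name, p in self.partitions.items()
            },
            "rules": [
                {
                    "antecedent": list(map(int, r.antecedent)),
                    "consequent": int(r.consequent),
                    "weight": float(r.weight),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AlcoholController":
        partitions = {
            name: GaussianPartition(
                attribute_name=name,
                centers=tuple(cfg["centers"]),
                width=cfg["width"],
                universe=tuple(cfg["universe"]),
                offsets=tuple(cfg.get("offsets", (0.0, 0.0, 0.0))),
            )
            for name, cfg in payload["partitions"].items()
        }
        rules = [
            FuzzyRule(tuple(r["antecedent"]), r["consequent"], r["weight"])
            for r in payload["rules"]
        ]
        return cls(
            partitions=partitions,
            rules=rules,
            smoothing_sigma=payload.get("smoothing_sigma", 2.0),
            defuzz_grid_size=payload.get("defuzz_grid_size", 501),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "AlcoholController":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def train_controller(
    curves,
    smoothing_sigma: float = 2.0,
    partition_settings: PartitionSettings = PartitionSettings(),
    resample_step_min: float | None = None,
) -> AlcoholController:
    """Calibrate partitions and induce the rule base from labelled curves.

    Hourly laboratory curves can be densified to the device's 5-minute
    cadence by passing ``resample_step_min=5`` (linear interpolation).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one training curve")
    for curve in curves:
        missing = [
            a for a in (*ANTECEDENTS, CONSEQUENT) if a not in curve.data.columns
        ]
        if missing:
            raise ValueError(f"training curve lacks attributes {missing}")
    if resample_step_min is not None:
        curves = [c.resample(resample_step_min) for c in curves]

    pooled = {
        attr: np.concatenate([c.data[attr].to_numpy(dtype=float) for c in curves])
        for attr in (*ANTECEDENTS, CONSEQUENT)
    }
    partitions = {
        attr: build_partition(compute_stats(v), attr, partition_settings)
        for attr, v in pooled.items()
    }

    # Wang–Mendel grid induction on all pooled samples
    n = len(pooled[CONSEQUENT])
    winning_class = {}
    winning_mu = {}
    for attr in (*ANTECEDENTS, CONSEQUENT):
        mf = partitions[attr].memberships(pooled[attr])  # (3, n)
        winning_class[attr] = mf.argmax(axis=0)
        winning_mu[attr] = mf.max(axis=0)

    weight = np.ones(n)
    for attr in (*ANTECEDENTS, CONSEQUENT):
        weight = weight * winning_mu[attr]

    accumulated: dict = {}
    ante_cols = np.stack([winning_class[a] for a in ANTECEDENTS], axis=1)
    cons_col = winning_class[CONSEQUENT]
    for i in range(n):
        key = tuple(ante_cols[i])
        cons = int(cons_col[i])
        bucket = accumulated.setdefault(key, {})
        bucket[cons] = bucket.get(cons, 0.0) + float(weight[i])

    rules = []
    for key, bucket in sorted(accumulated.items()):
        cons, acc = max(bucket.items(), key=lambda kv: (kv[1], -kv[0]))
        total = sum(bucket.values())
        rules.append(FuzzyRule(key, cons, acc / total if total > 0 else 0.0))

    controller = AlcoholController(
        partitions=partitions, rules=rules, smoothing_sigma=smoothing_sigma
    )
    logger.info("trained controller with %d rules from %d samples", len(rules), n)
    return controller
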