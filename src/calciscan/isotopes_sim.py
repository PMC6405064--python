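"""Synthetic individual-level isotope datasets with genotype structure.

Each stratum (treatment group, genetic type, n) draws shell weights from
a uniform range and generates d13C linearly in weight with a
genotype-specific intercept and slope, plus an optional additive
treatment effect and Gaussian noise; d18O is a common mean plus treatment
effect and noise.  The default parameters mimic the packaged isotope
table: treatment effects are null, and type IIa has the steepest
d13C-weight slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from calciscan.errors import ValidationError
from calciscan.fixtures import GENETIC_TYPES, GROUPS, IsotopeRecord


def _default_strata() -> tuple[tuple[str, str, int], ...]:
    # mirrors the packaged table's composition (group, type, n)
    return (
        ("A", "untyped", 14),
        ("B", "Ia", 7), ("B", "Ib", 6), ("B", "IIa", 6), ("B", "untyped", 1),
        ("C", "Ia", 8), ("C", "Ib", 2), ("C", "IIa", 5),
    )


@dataclass(frozen=True)
class IsotopeSimParams:
    """Generative parameters for a synthetic isotope dataset."""

    intercepts: dict[str, float] = field(default_factory=lambda: {
        "Ia": -0.75, "Ib": -0.70, "IIa": -0.60, "untyped": -0.75})
    slopes: dict[str, float] = field(default_factory=lambda: {
        "Ia": 0.085, "Ib": 0.08, "IIa": 0.128, "untyped": 0.085})
    d18o_mean: float = -1.85
    weight_range: tuple[float, float] = (1.0, 8.0)
    group_d13c_effect: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 0.0, "C": 0.0})
    group_d18o_effect: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 0.0, "C": 0.0})
    noise_sd_d13c: float = 0.25
    noise_sd_d18o: float = 0.35
    strata: tuple[tuple[str, str, int], ...] = field(default_factory=_default_strata)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_d13c < 0 or self.noise_sd_d18o < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.weight_range[0] <= 0 or self.weight_range[1] <= self.weight_range[0]:
            raise ValidationError("weight_range must be positive and increasing")
        for group, gtype, n in self.strata:
            if group not in GROUPS:
                raise ValidationError(f"unknown group {group!r}")
            if gtype not in GENETIC_TYPES:
                raise ValidationError(f"unknown genotype {gtype!r}")
            if n < 1:
                raise ValidationError("stratum sample size must be >= 1")
        for gtype in {s[1] for s in self.strata}:
            if gtype not in self.intercepts or gtype not in self.slopes:
                raise ValidationError(f"no intercept/slope for genotype {gtype!r}")


def make_isotope_dataset(params: IsotopeSimParams) -> list[IsotopeRecord]:
    """Draw one dataset; deterministic for fixed params (seed included)."""
    rng = np.random.default_rng(params.seed)
    records: list[IsotopeRecord] = []
    i = 0
    for group, gtype, n in params.strata:
        for _ in range(n):
            i += 1
            w = rng.uniform(*params.weight_range)
            d13c = (params.intercepts[gtype] + params.slopes[gtype] * w +
                    params.group_d13c_effect.get(group, 0.0) +
                    (rng.normal(0.0, params.noise_sd_d13c)
                     if params.noise_sd_d13c > 0 else 0.0))
            d18o = (params.d18o_mean +
                    params.group_d18o_effect.get(group, 0.0) +
                    (rng.normal(0.0, params.noise_sd_d18o)
                     if params.noise_sd_d18o > 0 else 0.0))
            records.append(IsotopeRecord(
                specimen_id=f"S{i}", group=group,
                genetic_type=gtype if group != "A" else "untyped",
                d13c=round(d13c, 6), d18o=round(d18o, 6), weight=round(w, 6)))
    return records
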