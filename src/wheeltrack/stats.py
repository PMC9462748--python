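"""Paired before/after cage permutation test.

The design: each cage contributes a summed "before" distance and a summed
"after" distance (e.g. three nights before and after a caloric-restriction
intervention); the test statistic is the mean across cages of the
after-minus-before differences. The null distribution is built by
independently swapping each cage's before/after labels — equivalently,
flipping the sign of each cage's difference — and recomputing the mean.

Three p-value estimators are exposed: the plain empirical tail fraction,
the add-one (Phipson-Smyth) correction guaranteeing p > 0, and a
density-AUC variant that integrates the tail of a Gaussian kernel density
fitted to the null sample. An exact enumeration over all 2^n sign
assignments serves as the oracle for small designs, and a Monte-Carlo
driver estimates type-I error and power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedDesign",
    "PermutationResult",
    "OperatingCharacteristics",
    "paired_mean_difference",
    "permutation_test",
    "exact_sign_flip_test",
    "simulate_operating_characteristics",
]

Sidedness = Literal["one_greater", "one_less", "two"]
Estimator = Literal["empirical", "empirical_add_one", "density_auc"]

#: absolute slack when counting null stats "at least as extreme" as the
#: observed one, so float round-off never drops an exact tie
_TIE_ATOL = 1e-9


@dataclass(frozen=True)
class PairedDesign:
    """Per-cage (before, after) summed distances plus an exclusion list."""

    cages: tuple[tuple[str, float, float], ...]
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cages = tuple((str(l), float(b), float(a)) for l, b, a in self.cages)
        object.__setattr__(self, "cages", cages)
        object.__setattr__(self, "excluded", tuple(str(x) for x in self.excluded))
        labels = [l for l, _, _ in cages]
        if len(set(labels)) != len(labels):
            raise ValueError("cage labels must be unique")
        for l, b, a in cages:
            if b < 0 or a < 0:
                raise ValueError(f"cage {l!r}: distances must be >= 0")
        unknown = set(self.excluded) - set(labels)
        if unknown:
            raise ValueError(f"excluded labels not in design: {sorted(unknown)}")

    def differences(self) -> np.ndarray:
        """after - before for every non-excluded cage, in cage order."""
        return np.array(
            [a - b for l, b, a in self.cages if l not in self.excluded]
        )

    @classmethod
    def from_csv(cls, text: str, excluded: Sequence[str] = ()) -> "PairedDesign":
        """Read 'cage,before_cm,after_cm' CSV text (header required)."""
        lines = [ln for ln in text.strip().split("\n") if ln]
        header = [h.strip().lower() for h in lines[0].split(",")]
        if header[:3] != ["cage", "before_cm", "after_cm"]:
            raise ValueError("expected header 'cage,before_cm,after_cm'")
        cages = []
        for line in lines[1:]:
            label, before, after = (f.strip() for f in line.split(",")[:3])
            cages.append((label, float(before), float(after)))
        return cls(cages=tuple(cages), excluded=tuple(excluded))


@dataclass
class PermutationResult:
    """Result of a Monte-Carlo sign-flip permutation test."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_permutations: int
    sidedness: Sidedness
    estimator: Estimator
    seed: int
    p_values: dict[str, float] = field(default_factory=dict)  # all estimators

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            if self.estimator == "empirical" and self.p_value == 0.0:
                pass  # empirical estimator may legitimately hit 0
            else:
                raise ValueError(f"p_value {self.p_value} outside (0, 1]")

    def summary(self) -> str:
        lines = [
            "Paired sign-flip permutation test",
            "=" * 44,
            f"{'observed mean difference':<30}{self.observed_stat:>14.3f}",
            f"{'permutations (B)':<30}{self.n_permutations:>14d}",
            f"{'sidedness':<30}{self.sidedness:>14}",
            f"{'seed':<30}{self.seed:>14d}",
            "-" * 44,
        ]
        for name, p in self.p_values.items():
            marker = " *" if name == self.estimator else ""
            lines.append(f"{'p (' + name + ')':<30}{p:>14.4f}{marker}")
        lines.append("-" * 44)
        lines.append("* selected estimator")
        return "\n".join(lines)


def _tail_count(null: np.ndarray, obs: float, sidedness: Sidedness) -> int:
    scale = max(1.0, abs(obs))
    atol = _TIE_ATOL * scale
    if sidedness == "one_greater":
        return int(np.sum(null >= obs - atol))
    if sidedness == "one_less":
        return int(np.sum(null <= obs + atol))
    return int(np.sum(np.abs(null) >= abs(obs) - atol))


def _density_auc(null: np.ndarray, obs: float, sidedness: Sidedness) -> float:
    if np.ptp(null) == 0:  # degenerate null: kde undefined; tail is all-or-nothing
        k = _tail_count(null, obs, sidedness)
        return 1.0 if k else 1.0 / (null.size + 1)
    kde = sps.gaussian_kde(null)
    if sidedness == "one_greater":
        p = kde.integrate_box_1d(obs, np.inf)
    elif sidedness == "one_less":
        p = kde.integrate_box_1d(-np.inf, obs)
    else:
        p = kde.integrate_box_1d(abs(obs), np.inf) + kde.integrate_box_1d(
            -np.inf, -abs(obs)
        )
    return float(min(max(p, 1.0 / (null.size + 1)), 1.0))


def paired_mean_difference(design: PairedDesign) -> float:
    """Mean over non-excluded cages of (after - before), in cm."""
    diffs = design.differences()
    if diffs.size == 0:
        raise ValueError("all cages excluded; no differences to average")
    return float(diffs.mean())


def permutation_test(
    design: PairedDesign,
    n_permutations: int = 1000,
    seed: int = 0,
    sidedness: Sidedness = "one_greater",
    estimator: Estimator = "empirical_add_one",
) -> PermutationResult:
    """Monte-Carlo sign-flip test of the paired mean difference.

    Each of the ``n_permutations`` draws independently swaps (or not) each
    cage's before/after labels — a Bernoulli(1/2) sign flip of its
    difference — and recomputes the mean; duplicate permutations are
    allowed. Ties with the observed statistic count as at least as
    extreme. The default add-one estimator returns (k + 1) / (B + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    diffs = design.differences()
    if diffs.size < 2:
        raise ValueError("need >= 2 non-excluded cages")
    obs = float(diffs.mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_permutations, diffs.size)) * 2 - 1
    null = (signs * diffs).mean(axis=1)
    k = _tail_count(null, obs, sidedness)
    B = n_permutations
    p_values = {
        "empirical": k / B,
        "empirical_add_one": (k + 1) / (B + 1),
        "density_auc": _density_auc(null, obs, sidedness),
    }
    return PermutationResult(
        observed_stat=obs,
        null_stats=null,
        p_value=p_values[estimator],
        n_permutations=B,
        sidedness=sidedness,
        estimator=estimator,
        seed=seed,
        p_values=p_values,
    )


def exact_sign_flip_test(
    design: PairedDesign, sidedness: Sidedness = "one_greater"
) -> float:
    """Exact p-value by enumerating all 2^n sign assignments (n <= 20)."""
    diffs = design.differences()
    n = diffs.size
    if n == 0:
        raise ValueError("all cages excluded")
    if n > 20:
        raise ValueError(
            f"n = {n} > 20: enumeration of 2^n assignments is impractical; "
            "use permutation_test (Monte-Carlo)"
        )
    obs = float(diffs.mean())
    total = 1 << n
    k = 0
    chunk = 1 << 16
    bits = np.arange(n)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        signs = ((idx[:, None] >> bits) & 1) * 2 - 1
        null = (signs * diffs).mean(axis=1)
        k += _tail_count(null, obs, sidedness)
    return k / total


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Empirical rejection rate at level alpha over simulated designs.

    Under ``effect = 0`` the rejection rate estimates the type-I error;
    under a positive effect it estimates power.
    """

    rejection_rate: float
    n_reps: int
    alpha: float
    effect: float

    @property
    def is_type_I(self) -> bool:
        return self.effect == 0.0


def simulate_operating_characteristics(
    n_cages: int,
    effect: float,
    noise_sd: float,
    n_reps: int = 1000,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    sidedness: Sidedness = "one_greater",
    estimator: Estimator = "empirical_add_one",
) -> OperatingCharacteristics:
    """Monte-Carlo calibration/power study for the sign-flip test.

    Each replicate draws per-cage differences ~ Normal(effect, noise_sd),
    runs the permutation test with ``B`` draws, and rejects at level
    ``alpha``. Fully vectorised across replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    diffs = rng.normal(effect, noise_sd, size=(n_reps, n_cages))
    obs = diffs.mean(axis=1)
    rejections = 0
    for r in range(n_reps):
        signs = rng.integers(0, 2, size=(B, n_cages)) * 2 - 1
        null = (signs * diffs[r]).mean(axis=1)
        k = _tail_count(null, obs[r], sidedness)
        if estimator == "empirical_add_one":
            p = (k + 1) / (B + 1)
        elif estimator == "empirical":
            p = k / B
        else:
            p = _density_auc(null, obs[r], sidedness)
        if p <= alpha:
            rejections += 1
    return OperatingCharacteristics(
        rejection_rate=rejections / n_reps,
        n_reps=n_reps,
        alpha=alpha,
        effect=effect,
    )


def power_discreteness_floor(n_cages: int) -> float:
    """Upper bound on exact-test power at alpha = 0.05: reachable only when
    the smallest attainable p, 2^-n (all-positive diffs), is <= alpha."""
    return 1.0 if math.pow(2.0, -n_cages) <= 0.05 else 0.0
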