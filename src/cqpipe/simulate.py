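"""Synthetic two-sex depth tracks and ROH segment sets with known ground truth.

The generator emulates the depth signal an XY system leaves in a
male + female resequencing pair after mapping and MAPQ filtering:

* copy factors — autosome male 1 / female 1, X male 0.5 / female 1,
  Y male 0.5 / female 0;
* a small fraction of collapsed-repeat loci whose expected depth is
  inflated by a common multiplier in both sexes;
* dropout loci with zero depth in one sex (mapping failure);
* sparse, low-mean female coverage on the Y (trace contamination or
  X-homologous mapping), which leaves the near-zero ratio signature
  intact;
* Poisson counts by default, or gamma-mixed Poisson with
  variance = mean * (1 + dispersion) for overdispersion.

Depth is simulated directly per base; no reads or alignments are modeled.
All randomness flows through one :class:`numpy.random.Generator` seeded
from the config, so identical seeds give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import DepthTrack, ScaffoldIndex
from .roh import Category, ROHSegment, LONG_MIN, SHORT_MAX

__all__ = [
    "SimulationError",
    "ScaffoldSpec",
    "SimConfig",
    "ROHMixture",
    "simulate_depth_pair",
    "scarab_scenario",
    "scenario_index",
    "simulate_roh_set",
    "DEFAULT_AUTOSOME_MBP",
    "X_MBP",
    "Y_MBP",
]


class SimulationError(ValueError):
    """Invalid simulation specification or infeasible request."""


@dataclass(frozen=True)
class ScaffoldSpec:
    """One scaffold to simulate, with its true class and artifact rates."""

    name: str
    length: int  # bp
    true_class: str  # AUTOSOME | X_LINKED | Y_LINKED
    repeat_fraction: float = 0.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SimulationError(f"{self.name}: length must be >= 1")
        if self.true_class not in _COPY_FACTORS:
            raise SimulationError(
                f"{self.name}: unknown class {self.true_class!r}"
            )
        for attr in ("repeat_fraction", "dropout_rate"):
            v = getattr(self, attr)
            if not 0 <= v < 1:
                raise SimulationError(f"{self.name}: {attr} must be in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Coverage model of the simulated male/female pair.

    Defaults mirror a HiFi male at ~65x and an Illumina female at ~60x
    single-copy coverage.  ``dispersion`` 0 gives Poisson counts;
    otherwise counts are gamma-mixed Poisson with variance
    mean * (1 + dispersion).  ``y_female_contamination`` is the per-locus
    probability that a Y locus receives spurious female coverage with
    mean ``0.05 * female_coverage``.
    """

    male_coverage: float = 65.0
    female_coverage: float = 60.0
    dispersion: float = 0.0
    repeat_multiplier: float = 5.0
    y_female_contamination: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.male_coverage <= 0 or self.female_coverage <= 0:
            raise SimulationError("coverages must be > 0")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.repeat_multiplier < 2:
            raise SimulationError("repeat_multiplier must be >= 2")
        if not 0 <= self.y_female_contamination < 1:
            raise SimulationError("y_female_contamination must be in [0, 1)")

    def with_overrides(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


# (male, female) expected-coverage multipliers per true class
_COPY_FACTORS: dict[str, tuple[float, float]] = {
    "AUTOSOME": (1.0, 1.0),
    "X_LINKED": (0.5, 1.0),
    "Y_LINKED": (0.5, 0.0),
}

_CONTAMINATION_MEAN_FACTOR = 0.05  # female mean on contaminated Y loci


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    counts = np.zeros(mean.shape, dtype=np.int64)
    positive = mean > 0
    if not np.any(positive):
        return counts
    m = mean[positive]
    if dispersion == 0:
        counts[positive] = rng.poisson(m)
    else:
        # gamma-Poisson: shape m/d, scale d => Var = m + d*m
        lam = rng.gamma(m / dispersion, dispersion)
        counts[positive] = rng.poisson(lam)
    return counts


def simulate_depth_pair(
    specs: Sequence[ScaffoldSpec], config: SimConfig
) -> tuple[dict[str, DepthTrack], dict[str, DepthTrack], dict[str, str]]:
    """Simulate per-base male and female depth tracks for ``specs``.

    Returns ``(male_tracks, female_tracks, truth)`` where ``truth`` maps
    scaffold name to its true class.  The random draw order per scaffold
    is fixed (repeat mask, dropout masks, contamination mask, male counts,
    female counts), so identical seeds are byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    male: dict[str, DepthTrack] = {}
    female: dict[str, DepthTrack] = {}
    truth: dict[str, str] = {}
    for spec in specs:
        n = spec.length
        positions = np.arange(1, n + 1, dtype=np.int64)
        mf, ff = _COPY_FACTORS[spec.true_class]
        mean_m = np.full(n, config.male_coverage * mf)
        mean_f = np.full(n, config.female_coverage * ff)

        if spec.repeat_fraction > 0:
            repeat = rng.random(n) < spec.repeat_fraction
            mean_m[repeat] *= config.repeat_multiplier
            mean_f[repeat] *= config.repeat_multiplier
        drop_m = (
            rng.random(n) < spec.dropout_rate if spec.dropout_rate > 0 else None
        )
        drop_f = (
            rng.random(n) < spec.dropout_rate if spec.dropout_rate > 0 else None
        )
        if spec.true_class == "Y_LINKED" and config.y_female_contamination > 0:
            contaminated = rng.random(n) < config.y_female_contamination
            mean_f[contaminated] = (
                _CONTAMINATION_MEAN_FACTOR * config.female_coverage
            )

        depth_m = _draw_counts(rng, mean_m, config.dispersion)
        depth_f = _draw_counts(rng, mean_f, config.dispersion)
        if drop_m is not None:
            depth_m[drop_m] = 0
        if drop_f is not None:
            depth_f[drop_f] = 0

        male[spec.name] = DepthTrack(spec.name, positions, depth_m)
        female[spec.name] = DepthTrack(spec.name, positions.copy(), depth_f)
        truth[spec.name] = spec.true_class
    return male, female, truth


# ---------------------------------------------------------------------------
# scarab-like scenario

# Representative lengths (Mbp) for the 9 autosomal scaffolds of a
# ~600 Mbp scarab assembly: largest 93.2 Mbp, N50 69.5 Mbp reached at the
# 4th scaffold, 10 scaffolds above 15 Mbp.  Only the largest and the Y
# lengths are pinned for the emulated genome; the rest interpolate those
# constraints.
DEFAULT_AUTOSOME_MBP = (93.2, 81.0, 74.4, 69.5, 58.6, 51.3, 44.8, 39.7, 33.2)
X_MBP = 28.0
Y_MBP = 1.1


def scarab_scenario(
    scale: float = 1.0,
    repeat_fraction: float = 0.01,
    dropout_rate: float = 0.001,
) -> list[ScaffoldSpec]:
    """Nine autosomes, one X and one 1.1 Mbp-proportioned Y, scaled by ``scale``.

    ``scale`` multiplies every length (use e.g. 0.01 for desk-scale runs;
    remember to scale ``CQConfig.min_scaffold_len`` identically).
    """
    if scale <= 0:
        raise SimulationError("scale must be > 0")
    specs: list[ScaffoldSpec] = []
    for i, mbp in enumerate(DEFAULT_AUTOSOME_MBP, start=1):
        specs.append(
            ScaffoldSpec(
                f"scaffold_{i:02d}",
                max(1, int(round(mbp * 1e6 * scale))),
                "AUTOSOME",
                repeat_fraction,
                dropout_rate,
            )
        )
    specs.append(
        ScaffoldSpec(
            "scaffold_10",
            max(1, int(round(X_MBP * 1e6 * scale))),
            "X_LINKED",
            repeat_fraction,
            dropout_rate,
        )
    )
    specs.append(
        ScaffoldSpec(
            "scaffold_11",
            max(1, int(round(Y_MBP * 1e6 * scale))),
            "Y_LINKED",
            repeat_fraction,
            dropout_rate,
        )
    )
    return specs


def scenario_index(specs: Sequence[ScaffoldSpec]) -> ScaffoldIndex:
    """Scaffold index matching a simulated scenario."""
    return ScaffoldIndex({s.name: s.length for s in specs})


# ---------------------------------------------------------------------------
# ROH simulation


@dataclass(frozen=True)
class ROHMixture:
    """Mixture of ROH length classes: per-class weight and length range.

    Lengths are drawn log-uniformly within each class's range, so short
    segments dominate within a class the way HMM calls on real data do.
    Default weights emulate a landscape dominated by short segments with
    occasional medium ones and no long ones.
    """

    weights: Mapping[Category, float] = field(
        default_factory=lambda: {
            Category.SHORT: 0.9,
            Category.MEDIUM: 0.1,
            Category.LONG: 0.0,
        }
    )
    length_ranges: Mapping[Category, tuple[int, int]] = field(
        default_factory=lambda: {
            Category.SHORT: (10_000, SHORT_MAX - 1),
            Category.MEDIUM: (SHORT_MAX, LONG_MIN),
            Category.LONG: (LONG_MIN + 1, 20_000_000),
        }
    )

    def __post_init__(self) -> None:
        total = sum(self.weights.get(c, 0.0) for c in Category)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SimulationError(f"mixture weights must sum to 1, got {total}")
        for cat in Category:
            w = self.weights.get(cat, 0.0)
            if w < 0:
                raise SimulationError("mixture weights must be >= 0")
            lo, hi = self.length_ranges[cat]
            if not 1 <= lo <= hi:
                raise SimulationError(f"invalid length range for {cat.name}")


def _default_genome() -> dict[str, int]:
    return {
        s.name: s.length
        for s in scarab_scenario(1.0)
        if s.true_class == "AUTOSOME"
    }


def simulate_roh_set(
    n_samples: int,
    mixture: ROHMixture | None = None,
    seed: int = 0,
    mean_segments: float = 40.0,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[ROHSegment]:
    """Simulate per-individual ROH segment sets with known class mixture.

    Per sample, the segment count is Poisson(``mean_segments``), classes
    are drawn from the mixture weights, lengths log-uniformly within the
    class range, and segments are placed without overlap on the autosomal
    scaffolds (random gaps partition each scaffold's free space).
    Deterministic under ``seed``.
    """
    mixture = mixture or ROHMixture()
    genome = dict(scaffold_lengths) if scaffold_lengths else _default_genome()
    rng = np.random.default_rng(seed)
    cats = [c for c in Category]
    weights = np.array([mixture.weights.get(c, 0.0) for c in cats])
    segments: list[ROHSegment] = []
    for si in range(n_samples):
        sample = f"ind_{si + 1:03d}"
        k = int(rng.poisson(mean_segments))
        if k == 0:
            continue
        drawn = rng.choice(len(cats), size=k, p=weights)
        lengths = np.empty(k, dtype=np.int64)
        for j, ci in enumerate(drawn):
            lo, hi = mixture.length_ranges[cats[ci]]
            lengths[j] = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
            lengths[j] = min(max(lengths[j], lo), hi)
        if lengths.sum() + k > sum(genome.values()):
            raise SimulationError(
                f"{sample}: total ROH length exceeds the genome; "
                "reduce mean_segments or the length ranges"
            )
        # greedy assignment: largest segments to the scaffold with most free space
        free = dict(genome)
        assigned: dict[str, list[int]] = {name: [] for name in genome}
        for length in sorted(lengths.tolist(), reverse=True):
            name = max(free, key=lambda s: (free[s], s))
            if free[name] < length + 1:
                raise SimulationError(
                    f"{sample}: cannot place a {length} bp segment without overlap"
                )
            assigned[name].append(length)
            free[name] -= length + 1
        for name in sorted(assigned):
            segs = assigned[name]
            if not segs:
                continue
            segs = [segs[i] for i in rng.permutation(len(segs))]
            slack = genome[name] - sum(segs)
            gaps = rng.dirichlet(np.ones(len(segs) + 1)) * slack
            cursor = 1
            for gap, length in zip(gaps, segs):
                start = cursor + int(gap)
                segments.append(ROHSegment(sample, name, start, start + length - 1))
                cursor = start + length
    return segments
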