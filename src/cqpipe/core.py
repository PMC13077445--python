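"""Chromosome-quotient (CQ) computation.

The CQ approach identifies sex-linked scaffolds from the relative
sequencing depth of a male and a female sample mapped to the same
assembly.  Each sex's per-base depth is normalized by that sex's modal
depth (the most frequent depth, a robust stand-in for single-copy
coverage), unreliable loci are disqualified (DQ), and the female:male
ratio of normalized depths is averaged in small fixed windows.  On an
XY system the expected window ratio is ~1 on autosomes (2:2 copies),
~2 on the X (2 female : 1 male) and ~0 on the Y (0 female : 1 male,
where male normalized depth itself sits near 0.5, i.e. hemizygous).

DQ rules applied per locus:

* male raw depth 0 -> ``DQ_MALE_ZERO`` (male reads are expected to map
  everywhere, so a male zero indicates a mapping failure);
* normalized depth > ``max_norm_depth`` in either sex ->
  ``DQ_HIGH_DEPTH`` (repeats or collapsed duplications);
* female raw depth 0 is *retained* with ratio exactly 0 — zero female
  coverage is the Y signature, not an artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

from .io import DepthTrack, ScaffoldIndex, SexDepthPair, join_sexes

__all__ = [
    "CQError",
    "ModalDepthError",
    "UndefinedMeanError",
    "LocusStatus",
    "CQConfig",
    "ModalDepth",
    "NormalizedLocus",
    "NormalizedLoci",
    "WindowRatio",
    "WindowTable",
    "ClassificationResult",
    "PipelineResult",
    "estimate_modal_depth",
    "normalize_and_flag",
    "compute_window_ratios",
    "modal_window_ratio",
    "classify_scaffold",
    "verify_hemizygosity",
    "classify_assembly",
    "run_pipeline",
]


class CQError(Exception):
    """Base class for chromosome-quotient computation failures."""


class ModalDepthError(CQError):
    """No loci qualified for modal-depth estimation."""


class UndefinedMeanError(CQError):
    """A mean over retained loci was requested but no locus is retained."""


class LocusStatus(IntEnum):
    OK = 0
    DQ_MALE_ZERO = 1
    DQ_HIGH_DEPTH = 2


@dataclass(frozen=True)
class CQConfig:
    """Tunable parameters of the CQ procedure.

    window_size
        Width (bp) of the non-overlapping windows over which locus ratios
        are averaged.
    min_scaffold_len
        Scaffolds shorter than this are reported UNASSIGNED_SHORT and are
        excluded from modal-depth estimation (short scaffolds carry noisy
        depth signals).
    max_norm_depth
        Normalized depth above which a locus is disqualified in either sex.
    autosome_band, x_band
        Closed intervals of the modal window ratio labelled AUTOSOME /
        X_LINKED.
    y_ratio_cutoff
        A window with mean ratio below this counts as "low"; a modal ratio
        below it is compatible with Y linkage.
    y_low_fraction
        Minimum fraction of low windows required for a Y_LINKED call.
    hemizygosity_band
        Interval of mean male normalized depth consistent with single-copy
        (hemizygous) sequence in the male.
    ratio_bin_width
        Bin width of the window-ratio histogram whose most populated bin
        defines the modal ratio.
    """

    window_size: int = 5
    min_scaffold_len: int = 1_000_000
    max_norm_depth: float = 3.0
    autosome_band: tuple[float, float] = (0.7, 1.3)
    x_band: tuple[float, float] = (1.7, 2.3)
    y_ratio_cutoff: float = 0.3
    y_low_fraction: float = 0.5
    hemizygosity_band: tuple[float, float] = (0.3, 0.7)
    ratio_bin_width: float = 0.1

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.min_scaffold_len < 1:
            raise ValueError("min_scaffold_len must be >= 1")
        if self.max_norm_depth <= 0:
            raise ValueError("max_norm_depth must be > 0")
        if self.ratio_bin_width <= 0:
            raise ValueError("ratio_bin_width must be > 0")
        for name in ("autosome_band", "x_band", "hemizygosity_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing interval")
        if self.autosome_band[1] > self.x_band[0]:
            raise ValueError("autosome_band and x_band must not overlap")
        if not 0 < self.y_ratio_cutoff < self.autosome_band[0]:
            raise ValueError(
                "y_ratio_cutoff must lie in (0, autosome_band lower bound)"
            )

    def with_overrides(self, **kwargs) -> "CQConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ModalDepth:
    """Modal per-base depth of one sex (argmax of the depth histogram, depths >= 1)."""

    sex: str
    value: int
    histogram: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 1:
            raise ValueError("modal depth must be >= 1")


class NormalizedLocus(NamedTuple):
    position: int
    male_norm: float
    female_norm: float
    ratio: float
    status: LocusStatus


@dataclass
class NormalizedLoci:
    """Columnar per-locus normalized depths, ratios and DQ status for one scaffold.

    ``ratio`` is NaN at disqualified loci; at retained loci with zero female
    depth it is exactly 0.
    """

    scaffold: str
    positions: np.ndarray
    male_raw: np.ndarray
    female_raw: np.ndarray
    male_norm: np.ndarray
    female_norm: np.ndarray
    ratio: np.ndarray
    status: np.ndarray  # LocusStatus codes, int8

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, i: int) -> NormalizedLocus:
        return NormalizedLocus(
            int(self.positions[i]),
            float(self.male_norm[i]),
            float(self.female_norm[i]),
            float(self.ratio[i]),
            LocusStatus(int(self.status[i])),
        )

    def __iter__(self) -> Iterator[NormalizedLocus]:
        return (self[i] for i in range(len(self)))

    @property
    def ok(self) -> np.ndarray:
        return self.status == LocusStatus.OK

    @property
    def n_ok(self) -> int:
        return int(np.count_nonzero(self.ok))


class WindowRatio(NamedTuple):
    scaffold: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    mean_ratio: float
    n_loci: int


@dataclass
class WindowTable:
    """Columnar per-window mean ratios for one scaffold (windows with >= 1 OK locus)."""

    scaffold: str
    start: np.ndarray
    end: np.ndarray
    mean_ratio: np.ndarray
    n_loci: np.ndarray

    def __len__(self) -> int:
        return len(self.start)

    def __getitem__(self, i: int) -> WindowRatio:
        return WindowRatio(
            self.scaffold,
            int(self.start[i]),
            int(self.end[i]),
            float(self.mean_ratio[i]),
            int(self.n_loci[i]),
        )

    def __iter__(self) -> Iterator[WindowRatio]:
        return (self[i] for i in range(len(self)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "scaffold": self.scaffold,
                "start": self.start,
                "end": self.end,
                "mean_ratio": self.mean_ratio,
                "n_loci": self.n_loci,
            }
        )


@dataclass(frozen=True)
class ClassificationResult:
    """Per-scaffold CQ call with its diagnostics."""

    scaffold: str
    length: int
    label: str  # AUTOSOME | X_LINKED | Y_LINKED | AMBIGUOUS | UNASSIGNED_SHORT
    modal_ratio: float  # NaN when no windows
    frac_low_ratio: float
    mean_male_norm: float  # NaN when no OK loci
    n_windows: int
    n_ok_loci: int = 0


@dataclass
class PipelineResult:
    male_mode: ModalDepth
    female_mode: ModalDepth
    classifications: list[ClassificationResult]
    windows: list[WindowTable]


# ---------------------------------------------------------------------------
# modal depth


def estimate_modal_depth(
    tracks: Mapping[str, DepthTrack],
    config: CQConfig,
    index: ScaffoldIndex | None = None,
    sex: str = "unspecified",
) -> ModalDepth:
    """Estimate single-copy coverage as the modal depth over qualifying loci.

    The histogram is built over depths >= 1 (zero-depth loci are the object
    of the DQ rules, not coverage evidence) on scaffolds of length >=
    ``config.min_scaffold_len``.  Scaffold length is taken from ``index``
    when given, else from the track's last position.  Ties in the histogram
    break toward the smaller depth.
    """
    pooled: list[np.ndarray] = []
    for name, track in tracks.items():
        length = index[name] if index is not None else (
            int(track.positions[-1]) if len(track) else 0
        )
        if length >= config.min_scaffold_len:
            pooled.append(track.depths)
    if pooled:
        depths = np.concatenate(pooled)
        counts = np.bincount(depths[depths > 0])
    else:
        counts = np.zeros(1, dtype=np.int64)
    if counts.sum() == 0:
        raise ModalDepthError(
            f"no loci with depth >= 1 on scaffolds >= {config.min_scaffold_len} bp "
            f"({sex}); lower min_scaffold_len or check the depth input"
        )
    value = int(np.argmax(counts))  # argmax returns the smallest tied depth
    histogram = {int(d): int(c) for d, c in enumerate(counts) if c > 0}
    return ModalDepth(sex=sex, value=value, histogram=histogram)


# ---------------------------------------------------------------------------
# normalization and DQ flagging


def normalize_and_flag(
    pair: SexDepthPair,
    male_mode: ModalDepth,
    female_mode: ModalDepth,
    config: CQConfig,
) -> NormalizedLoci:
    """Normalize both sexes by their modal depth and apply the DQ rules."""
    male_norm = pair.male_depth / male_mode.value
    female_norm = pair.female_depth / female_mode.value

    status = np.zeros(len(pair), dtype=np.int8)
    male_zero = pair.male_depth == 0
    status[male_zero] = LocusStatus.DQ_MALE_ZERO
    high = (~male_zero) & (
        (male_norm > config.max_norm_depth) | (female_norm > config.max_norm_depth)
    )
    status[high] = LocusStatus.DQ_HIGH_DEPTH

    ratio = np.full(len(pair), np.nan)
    ok = status == LocusStatus.OK
    # female zero at an OK locus gives ratio exactly 0 (retained: candidate
    # male-specific sequence)
    np.divide(female_norm, male_norm, out=ratio, where=ok)
    return NormalizedLoci(
        scaffold=pair.scaffold,
        positions=pair.positions,
        male_raw=pair.male_depth,
        female_raw=pair.female_depth,
        male_norm=male_norm,
        female_norm=female_norm,
        ratio=ratio,
        status=status,
    )


# ---------------------------------------------------------------------------
# windowing


def compute_window_ratios(
    loci: NormalizedLoci, scaffold_length: int, config: CQConfig
) -> WindowTable:
    """Average locus ratios in non-overlapping windows tiled from position 1.

    Windows are ``[1..w], [w+1..2w], ...`` (1-based inclusive); the mean is
    taken over OK loci only, windows without any OK locus are omitted, and
    the final partial window is kept if it has at least one OK locus.
    """
    w = config.window_size
    ok = loci.ok
    empty = WindowTable(
        loci.scaffold,
        np.empty(0, np.int64),
        np.empty(0, np.int64),
        np.empty(0, float),
        np.empty(0, np.int64),
    )
    if not np.any(ok):
        return empty
    widx = (loci.positions[ok] - 1) // w
    ratios = loci.ratio[ok]
    uniq, inverse = np.unique(widx, return_inverse=True)
    n_loci = np.bincount(inverse)
    sums = np.bincount(inverse, weights=ratios)
    start = uniq * w + 1
    end = np.minimum((uniq + 1) * w, scaffold_length)
    return WindowTable(
        scaffold=loci.scaffold,
        start=start.astype(np.int64),
        end=end.astype(np.int64),
        mean_ratio=sums / n_loci,
        n_loci=n_loci.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# classification


def _ratio_bin_edges(config: CQConfig) -> np.ndarray:
    n_bins = int(math.ceil((config.max_norm_depth + 1) / config.ratio_bin_width))
    return np.arange(n_bins + 1) * config.ratio_bin_width


def modal_window_ratio(mean_ratios: np.ndarray, config: CQConfig) -> float:
    """Midpoint of the most populated window-ratio histogram bin.

    Bins have width ``ratio_bin_width`` over [0, max_norm_depth + 1];
    ratios beyond the top edge fall into the last bin; ties break toward
    the lower bin.
    """
    edges = _ratio_bin_edges(config)
    idx = np.searchsorted(edges, mean_ratios, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    best = int(np.argmax(counts))  # first (lowest) bin on ties
    return float((best + 0.5) * config.ratio_bin_width)


def classify_scaffold(
    windows: WindowTable,
    loci: NormalizedLoci | None,
    scaffold_length: int,
    config: CQConfig,
) -> ClassificationResult:
    """Label one scaffold from its window-ratio distribution.

    Precedence: the Y test (majority of windows below ``y_ratio_cutoff``
    *and* modal ratio below it) runs before band membership, because trace
    female mapping can put a Y scaffold's modal bin slightly above zero.
    """
    n_windows = len(windows)
    if loci is not None and loci.n_ok:
        mean_male_norm = float(np.mean(loci.male_norm[loci.ok]))
        n_ok = loci.n_ok
    else:
        mean_male_norm, n_ok = math.nan, 0

    if n_windows:
        modal = modal_window_ratio(windows.mean_ratio, config)
        frac_low = float(np.mean(windows.mean_ratio < config.y_ratio_cutoff))
    else:
        modal, frac_low = math.nan, 0.0

    if scaffold_length < config.min_scaffold_len:
        label = "UNASSIGNED_SHORT"
    elif n_windows == 0:
        label = "AMBIGUOUS"
    elif frac_low >= config.y_low_fraction and modal < config.y_ratio_cutoff:
        label = "Y_LINKED"
    elif config.x_band[0] <= modal <= config.x_band[1]:
        label = "X_LINKED"
    elif config.autosome_band[0] <= modal <= config.autosome_band[1]:
        label = "AUTOSOME"
    else:
        label = "AMBIGUOUS"

    return ClassificationResult(
        scaffold=windows.scaffold,
        length=scaffold_length,
        label=label,
        modal_ratio=modal,
        frac_low_ratio=frac_low,
        mean_male_norm=mean_male_norm,
        n_windows=n_windows,
        n_ok_loci=n_ok,
    )


def verify_hemizygosity(
    loci: NormalizedLoci, config: CQConfig
) -> tuple[float, bool]:
    """Mean male normalized depth over retained loci, and whether it sits in
    the hemizygosity band (~0.5x expected for single-copy Y sequence)."""
    if not loci.n_ok:
        raise UndefinedMeanError(
            f"{loci.scaffold}: no retained loci, mean male depth undefined"
        )
    mean = float(np.mean(loci.male_norm[loci.ok]))
    lo, hi = config.hemizygosity_band
    return mean, lo <= mean <= hi


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    male: Mapping[str, DepthTrack],
    female: Mapping[str, DepthTrack],
    index: ScaffoldIndex,
    config: CQConfig | None = None,
) -> PipelineResult:
    """Full CQ procedure: modal depths -> join -> normalize -> window -> classify.

    Every scaffold of the index appears in the output; scaffolds without
    any depth data are reported with zero windows (UNASSIGNED_SHORT or
    AMBIGUOUS by length) rather than dropped.  Deterministic: identical
    inputs give identical outputs.
    """
    config = config or CQConfig()
    male_mode = estimate_modal_depth(male, config, index, sex="male")
    female_mode = estimate_modal_depth(female, config, index, sex="female")
    pairs = {p.scaffold: p for p in join_sexes(male, female, index)}

    classifications: list[ClassificationResult] = []
    windows: list[WindowTable] = []
    for name, length in index.items():
        pair = pairs.get(name)
        if pair is None:
            empty = WindowTable(
                name,
                np.empty(0, np.int64),
                np.empty(0, np.int64),
                np.empty(0, float),
                np.empty(0, np.int64),
            )
            classifications.append(classify_scaffold(empty, None, length, config))
            continue
        loci = normalize_and_flag(pair, male_mode, female_mode, config)
        table = compute_window_ratios(loci, length, config)
        windows.append(table)
        classifications.append(classify_scaffold(table, loci, length, config))
    return PipelineResult(male_mode, female_mode, classifications, windows)


def classify_assembly(
    male: Mapping[str, DepthTrack],
    female: Mapping[str, DepthTrack],
    index: ScaffoldIndex,
    config: CQConfig | None = None,
) -> list[ClassificationResult]:
    """Classify every scaffold; convenience wrapper around :func:`run_pipeline`."""
    return run_pipeline(male, female, index, config).classifications
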