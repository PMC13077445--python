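"""Runs-of-homozygosity (ROH) length classification and per-individual summaries.

ROH segments — contiguous homozygous stretches called upstream by an HMM
such as ``bcftools roh`` — are grouped into three length classes:

* SHORT   (< 1 Mbp): the signature of historical bottlenecks or long-term
  persistence at small effective population size;
* MEDIUM  (1-5 Mbp, closed interval): recent inbreeding within localized
  demes;
* LONG    (> 5 Mbp): very recent consanguineous mating.

Per individual, the module reports segment counts and cumulative coverage
per class, plus a normalized length histogram (the canonical rendering;
a kernel-density rendering is available for plotting).
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROHFormatError",
    "Category",
    "SHORT_MAX",
    "LONG_MIN",
    "ROHSegment",
    "IndividualROHProfile",
    "read_roh_segments",
    "write_roh_bed",
    "categorize",
    "profile_individuals",
    "profiles_frame",
    "length_density",
    "plot_cumulative_profile",
    "plot_length_density",
]


class ROHFormatError(ValueError):
    """An ROH record could not be parsed or has inconsistent coordinates."""


class Category(enum.IntEnum):
    """ROH length class; ordering SHORT < MEDIUM < LONG is meaningful."""

    SHORT = 0
    MEDIUM = 1
    LONG = 2


SHORT_MAX = 1_000_000  # lengths < SHORT_MAX are SHORT
LONG_MIN = 5_000_000  # lengths > LONG_MIN are LONG; [SHORT_MAX, LONG_MIN] is MEDIUM


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous interval of one individual, 1-based inclusive coordinates."""

    sample: str
    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ROHFormatError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ROHFormatError(
                f"end ({self.end}) < start ({self.start}) for {self.sample}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def category(self) -> Category:
        return categorize(self.length)


def categorize(length: int) -> Category:
    """Map a segment length (bp) to its class.

    Boundaries: < 1 Mbp SHORT; 1-5 Mbp inclusive MEDIUM; > 5 Mbp LONG —
    the closed middle interval is the only reading under which the three
    printed ranges tile all lengths.
    """
    if length < 1:
        raise ValueError("segment length must be >= 1")
    if length < SHORT_MAX:
        return Category.SHORT
    if length <= LONG_MIN:
        return Category.MEDIUM
    return Category.LONG


# ---------------------------------------------------------------------------
# parsing


def _parse_rg_lines(path: str | os.PathLike) -> list[ROHSegment]:
    # bcftools roh RG rows: RG <sample> <chrom> <start> <end> <len> <nmark> <qual>
    segments: list[ROHSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] != "RG":
                continue
            if len(fields) < 5:
                raise ROHFormatError(
                    f"{path}: RG row with < 5 fields at line {lineno}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ROHFormatError(
                    f"{path}: non-integer coordinate at line {lineno}"
                ) from None
            try:
                segments.append(ROHSegment(fields[1], fields[2], start, end))
            except ROHFormatError as exc:
                raise ROHFormatError(f"{path}: line {lineno}: {exc}") from None
    return segments


def _parse_bed(path: str | os.PathLike) -> list[ROHSegment]:
    # 4+-column BED, sample identifier in column 4; 0-based half-open in,
    # 1-based inclusive out.
    segments: list[ROHSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ROHFormatError(
                    f"{path}: BED row with < 4 fields at line {lineno}"
                )
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ROHFormatError(
                    f"{path}: non-integer coordinate at line {lineno}"
                ) from None
            try:
                segments.append(ROHSegment(fields[3], fields[0], start0 + 1, end0))
            except ROHFormatError as exc:
                raise ROHFormatError(f"{path}: line {lineno}: {exc}") from None
    return segments


def read_roh_segments(
    path: str | os.PathLike, dialect: str = "rg_lines"
) -> list[ROHSegment]:
    """Read ROH segments from ``bcftools roh`` RG output or 4+-column BED."""
    if dialect == "rg_lines":
        return _parse_rg_lines(path)
    if dialect == "bed":
        return _parse_bed(path)
    raise ValueError(f"unknown ROH dialect {dialect!r} (expected rg_lines or bed)")


def write_roh_bed(segments: Iterable[ROHSegment], path: str | os.PathLike) -> None:
    """Write segments as 4-column BED (0-based half-open), sample in column 4."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.scaffold}\t{seg.start - 1}\t{seg.end}\t{seg.sample}\n")


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class IndividualROHProfile:
    """Per-individual segment counts and cumulative coverage by length class."""

    sample: str
    counts: dict[Category, int]
    cumulative: dict[Category, int]  # bp

    @property
    def total_length(self) -> int:
        return sum(self.cumulative.values())

    @property
    def n_segments(self) -> int:
        return sum(self.counts.values())


def profile_individuals(
    segments: Iterable[ROHSegment],
) -> list[IndividualROHProfile]:
    """One profile per distinct sample, in lexicographic sample order.

    Overlapping segments within a sample are summed as-is; the upstream
    caller is responsible for emitting non-overlapping runs.
    """
    by_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    profiles = []
    for sample in sorted(by_sample):
        counts = {c: 0 for c in Category}
        cumulative = {c: 0 for c in Category}
        for seg in by_sample[sample]:
            cat = seg.category
            counts[cat] += 1
            cumulative[cat] += seg.length
        profiles.append(IndividualROHProfile(sample, counts, cumulative))
    return profiles


def profiles_frame(profiles: Sequence[IndividualROHProfile]) -> pd.DataFrame:
    """Tabular view of profiles (one row per sample, fixed column order)."""
    rows = [
        {
            "sample": p.sample,
            "n_short": p.counts[Category.SHORT],
            "n_medium": p.counts[Category.MEDIUM],
            "n_long": p.counts[Category.LONG],
            "bp_short": p.cumulative[Category.SHORT],
            "bp_medium": p.cumulative[Category.MEDIUM],
            "bp_long": p.cumulative[Category.LONG],
            "total_bp": p.total_length,
        }
        for p in profiles
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "n_short",
            "n_medium",
            "n_long",
            "bp_short",
            "bp_medium",
            "bp_long",
            "total_bp",
        ],
    )


def length_density(
    segments: Iterable[ROHSegment],
    n_bins: int = 30,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Per-sample normalized histogram of segment lengths.

    Bin edges are shared across samples (span of all observed lengths;
    geometric spacing when ``log_scale``).  Densities integrate to 1 per
    sample with at least one segment.  Columns: sample, bin_left,
    bin_right, density.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    segments = list(segments)
    columns = ["sample", "bin_left", "bin_right", "density"]
    if not segments:
        return pd.DataFrame(columns=columns)
    lengths = np.array([s.length for s in segments], dtype=float)
    samples = np.array([s.sample for s in segments])
    lo, hi = lengths.min(), lengths.max()
    if lo == hi:  # degenerate: a single observed length
        lo, hi = lo * 0.99, hi * 1.01
    if log_scale:
        edges = np.geomspace(lo, hi, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    rows = []
    for sample in sorted(set(samples)):
        dens, _ = np.histogram(lengths[samples == sample], bins=edges, density=True)
        for left, right, d in zip(edges[:-1], edges[1:], dens):
            rows.append((sample, left, right, d))
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# plotting (secondary artifacts; all testing runs on the tables above)


def plot_cumulative_profile(
    profiles: Sequence[IndividualROHProfile], path: str | os.PathLike
) -> None:
    """Stacked per-individual bars of cumulative ROH coverage by class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profiles_frame(profiles)
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(df)), 4))
    bottom = np.zeros(len(df))
    for col, label, color in (
        ("bp_short", "short (< 1 Mbp)", "#4c72b0"),
        ("bp_medium", "medium (1-5 Mbp)", "#dd8452"),
        ("bp_long", "long (> 5 Mbp)", "#c44e52"),
    ):
        vals = df[col].to_numpy(dtype=float) / 1e6
        ax.bar(df["sample"], vals, bottom=bottom, label=label, color=color)
        bottom += vals
    ax.set_ylabel("cumulative ROH (Mbp)")
    ax.set_xlabel("individual")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_length_density(
    segments: Iterable[ROHSegment],
    path: str | os.PathLike,
    kernel: bool = True,
) -> None:
    """Per-individual ROH length distributions (KDE lines, or step histograms)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    segments = list(segments)
    fig, ax = plt.subplots(figsize=(6, 4))
    lengths = np.array([s.length for s in segments], dtype=float)
    samples = np.array([s.sample for s in segments])
    for sample in sorted(set(samples)):
        vals = np.log10(lengths[samples == sample])
        if kernel and len(vals) > 1 and vals.std() > 0:
            from scipy import stats  # optional; fall back to histogram

            grid = np.linspace(vals.min() - 0.2, vals.max() + 0.2, 200)
            ax.plot(grid, stats.gaussian_kde(vals)(grid), lw=0.8, alpha=0.6)
        else:
            ax.hist(vals, bins=20, histtype="step", density=True, alpha=0.6)
    ax.set_xlabel("log10 ROH length (bp)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
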