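"""Reading and writing the tabular formats the pipeline consumes and emits.

Depth input is the 3-column per-base dialect produced by standard depth
tools (``samtools depth``-style): ``scaffold<TAB>position<TAB>depth`` with
1-based positions.  Scaffold lengths come from a FASTA index (``.fai``),
of which only the first two columns are used.  Result tables are plain
tab-separated text with a fixed column order and a deterministic row order
so that identical runs are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DepthFormatError",
    "ReferenceMismatchError",
    "DepthRecord",
    "DepthTrack",
    "ScaffoldIndex",
    "SexDepthPair",
    "read_depth_table",
    "write_depth_table",
    "read_fai",
    "join_sexes",
    "write_results",
    "write_bed",
]


class DepthFormatError(ValueError):
    """A depth/index table line could not be parsed or violates ordering."""


class ReferenceMismatchError(KeyError):
    """A scaffold in a depth table is absent from the scaffold index."""


@dataclass(frozen=True)
class DepthRecord:
    """One per-base observation: reads covering ``position`` on ``scaffold``."""

    scaffold: str
    position: int  # 1-based
    depth: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DepthFormatError(f"position must be >= 1, got {self.position}")
        if self.depth < 0:
            raise DepthFormatError(f"depth must be >= 0, got {self.depth}")


@dataclass
class DepthTrack:
    """Ordered per-locus depths for one sex on one scaffold."""

    scaffold: str
    positions: np.ndarray  # 1-based, strictly increasing
    depths: np.ndarray  # parallel, non-negative

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.positions.shape != self.depths.shape:
            raise DepthFormatError(
                f"{self.scaffold}: positions and depths differ in length"
            )
        if len(self.positions) and self.positions[0] < 1:
            raise DepthFormatError(f"{self.scaffold}: positions must be >= 1")
        if np.any(np.diff(self.positions) <= 0):
            raise DepthFormatError(
                f"{self.scaffold}: positions must be strictly increasing"
            )
        if np.any(self.depths < 0):
            raise DepthFormatError(f"{self.scaffold}: depths must be >= 0")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ScaffoldIndex:
    """Scaffold name -> length (bp), from the first two ``.fai`` columns."""

    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.entries.items():
            if length < 1:
                raise DepthFormatError(f"{name}: scaffold length must be >= 1")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> int:
        try:
            return self.entries[name]
        except KeyError:
            raise ReferenceMismatchError(
                f"scaffold {name!r} not present in the scaffold index"
            ) from None

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()


@dataclass
class SexDepthPair:
    """Per-locus male and female depths on one scaffold (position union)."""

    scaffold: str
    positions: np.ndarray
    male_depth: np.ndarray
    female_depth: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# readers


def _scan_depth_lines(path: str | os.PathLike) -> None:
    """Line-by-line validation used to attribute parse failures to a line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                raise DepthFormatError(f"{path}: blank line at line {lineno}")
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise DepthFormatError(
                    f"{path}: expected 3 tab-separated fields at line {lineno}, "
                    f"got {len(fields)}"
                )
            for col, value in (("position", fields[1]), ("depth", fields[2])):
                try:
                    int(value)
                except ValueError:
                    raise DepthFormatError(
                        f"{path}: non-integer {col} {value!r} at line {lineno}"
                    ) from None


def read_depth_table(path: str | os.PathLike) -> dict[str, DepthTrack]:
    """Read a 3-column per-base depth table into one :class:`DepthTrack` per scaffold.

    Positions must be ascending within each scaffold; lines may be grouped
    by scaffold in any scaffold order.  Malformed lines raise
    :class:`DepthFormatError` naming the offending line.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=("scaffold", "position", "depth"),
            dtype={"scaffold": str, "position": np.int64, "depth": np.int64},
            na_filter=False,
        )
    except pd.errors.EmptyDataError:
        return {}
    except (ValueError, TypeError, pd.errors.ParserError):
        _scan_depth_lines(path)  # raises with a line number
        raise  # pragma: no cover - scan always finds the culprit

    for col, low in (("position", 1), ("depth", 0)):
        bad = df.index[df[col] < low]
        if len(bad):
            raise DepthFormatError(
                f"{path}: {col} < {low} at line {int(bad[0]) + 1}"
            )

    tracks: dict[str, DepthTrack] = {}
    for scaffold, group in df.groupby("scaffold", sort=False):
        pos = group["position"].to_numpy()
        steps = np.diff(pos)
        if np.any(steps <= 0):
            first = int(group.index[int(np.argmax(steps <= 0)) + 1]) + 1
            raise DepthFormatError(
                f"{path}: non-increasing position within scaffold "
                f"{scaffold!r} at line {first}"
            )
        tracks[str(scaffold)] = DepthTrack(
            str(scaffold), pos, group["depth"].to_numpy()
        )
    return tracks


def write_depth_table(
    tracks: Mapping[str, DepthTrack] | Iterable[DepthTrack],
    path: str | os.PathLike,
) -> None:
    """Write tracks back to the 3-column dialect (inverse of the reader)."""
    if isinstance(tracks, Mapping):
        tracks = tracks.values()
    with open(path, "w") as fh:
        for track in tracks:
            frame = pd.DataFrame(
                {
                    "scaffold": track.scaffold,
                    "position": track.positions,
                    "depth": track.depths,
                }
            )
            frame.to_csv(fh, sep="\t", header=False, index=False)


def read_fai(path: str | os.PathLike) -> ScaffoldIndex:
    """Read scaffold lengths from a FASTA index; only columns 1-2 are used."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=("name", "length"), na_filter=False)
    except pd.errors.EmptyDataError:
        return ScaffoldIndex({})
    entries: dict[str, int] = {}
    for lineno, (name, length) in enumerate(
        zip(df["name"], df["length"]), start=1
    ):
        try:
            length = int(length)
        except (TypeError, ValueError):
            raise DepthFormatError(
                f"{path}: non-integer length at line {lineno}"
            ) from None
        name = str(name)
        if name in entries:
            raise DepthFormatError(f"{path}: duplicate scaffold {name!r}")
        entries[name] = length
    return ScaffoldIndex(entries)


# ---------------------------------------------------------------------------
# joining


def join_sexes(
    male: Mapping[str, DepthTrack],
    female: Mapping[str, DepthTrack],
    index: ScaffoldIndex,
) -> list[SexDepthPair]:
    """Join male and female tracks on the union of positions per scaffold.

    A position present in only one sex's table appears with depth 0 in the
    other sex (zero-depth loci carry meaning downstream, so they must be
    representable).  Scaffolds absent from both inputs are omitted; a
    scaffold missing from ``index`` raises :class:`ReferenceMismatchError`.
    Output order follows the index, so it is deterministic.
    """
    present = set(male) | set(female)
    for name in sorted(present):
        if name not in index:
            raise ReferenceMismatchError(
                f"scaffold {name!r} in depth input but not in the index"
            )
    pairs: list[SexDepthPair] = []
    for name, _length in index.items():
        if name not in present:
            continue
        mtrack = male.get(name)
        ftrack = female.get(name)
        mpos = mtrack.positions if mtrack is not None else np.empty(0, np.int64)
        fpos = ftrack.positions if ftrack is not None else np.empty(0, np.int64)
        if mpos.shape == fpos.shape and np.array_equal(mpos, fpos):
            pos = mpos
        else:
            pos = np.union1d(mpos, fpos)
        mdep = np.zeros(len(pos), dtype=np.int64)
        fdep = np.zeros(len(pos), dtype=np.int64)
        if mtrack is not None and len(mpos):
            mdep[np.searchsorted(pos, mpos)] = mtrack.depths
        if ftrack is not None and len(fpos):
            fdep[np.searchsorted(pos, fpos)] = ftrack.depths
        pairs.append(SexDepthPair(name, pos, mdep, fdep))
    return pairs


# ---------------------------------------------------------------------------
# writers

CLASSIFICATION_COLUMNS = (
    "scaffold",
    "length",
    "class",
    "modal_ratio",
    "frac_low_ratio",
    "mean_male_norm",
    "n_windows",
)
WINDOW_COLUMNS = ("scaffold", "start", "end", "mean_ratio", "n_loci")

_FLOAT_FMT = "%.6g"


def _classification_frame(classifications) -> pd.DataFrame:
    rows = [
        {
            "scaffold": c.scaffold,
            "length": c.length,
            "class": c.label,
            "modal_ratio": c.modal_ratio,
            "frac_low_ratio": c.frac_low_ratio,
            "mean_male_norm": c.mean_male_norm,
            "n_windows": c.n_windows,
        }
        for c in classifications
    ]
    df = pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["length", "scaffold"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df


def _window_frame(windows, scaffold_order: list[str]) -> pd.DataFrame:
    frames = {w.scaffold: w.to_frame() for w in windows}
    ordered = [frames[s] for s in scaffold_order if s in frames]
    if not ordered:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(ordered, ignore_index=True)[list(WINDOW_COLUMNS)]


def write_results(classifications, windows, out_prefix: str | os.PathLike) -> dict[str, str]:
    """Write the classification and window tables.

    Rows are ordered by descending scaffold length, ties broken by scaffold
    identifier; windows follow the same scaffold order, then start.  Returns
    the paths written (``classification`` and ``windows`` keys).
    """
    out_prefix = os.fspath(out_prefix)
    cls_df = _classification_frame(classifications)
    win_df = _window_frame(windows, list(cls_df["scaffold"]))
    paths = {
        "classification": out_prefix + ".classification.tsv",
        "windows": out_prefix + ".windows.tsv",
    }
    cls_df.to_csv(
        paths["classification"], sep="\t", index=False,
        float_format=_FLOAT_FMT, na_rep="NA",
    )
    win_df.to_csv(
        paths["windows"], sep="\t", index=False,
        float_format=_FLOAT_FMT, na_rep="NA",
    )
    return paths


def write_bed(classifications, path: str | os.PathLike) -> None:
    """Export classified scaffolds as 0-based half-open BED, class in the name column."""
    df = _classification_frame(classifications)
    bed = pd.DataFrame(
        {
            "chrom": df["scaffold"],
            "start": 0,
            "end": df["length"],
            "name": df["class"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
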