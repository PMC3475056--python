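"""Aligned-read I/O, fragment shifting, genome binning and bin-count tables.

ChIP-seq reads arrive as BED6 / tagAlign records (chrom, start, end, name,
score, strand; name and score are ignored).  Each read is shifted l/2 bases
towards its 3' end so that tags from both strands stack at the fragment
midpoint, then the genome is partitioned into non-overlapping bins of a
fixed width w and per-bin (and per-strand) ChIP/control counts are
aggregated into a :class:`BinTable` — the common currency of every
normalization-factor estimator in :mod:`ncisnorm.estimators`.

Coordinates are 0-based half-open throughout; bin k of a chromosome covers
``[k*w, (k+1)*w)`` with the last bin truncated at the chromosome end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "BinTable",
    "BedParseError",
    "UnknownChromosomeError",
    "load_reads",
    "save_reads",
    "shift_reads",
    "tags_to_reads",
    "bin_counts",
    "marginal_ratio_profile",
]

READ_COLUMNS = ["chrom", "start", "end", "strand"]
TAG_COLUMNS = ["chrom", "pos", "strand"]


class BedParseError(ValueError):
    """A BED/tagAlign line could not be parsed or violates an invariant."""


class UnknownChromosomeError(ValueError):
    """A record references a chromosome absent from the genome layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths of a reference genome.

    ``G`` (the summed length) feeds the uniform-background Poisson rates
    used by the SPP-style estimator.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths) or not self.names:
            raise ValueError("names and lengths must be equal-length and non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(int(l) <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @cached_property
    def lengths_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=np.int64)

    @cached_property
    def G(self) -> int:
        """Total genome length in bp."""
        return int(self.lengths_array.sum())

    @cached_property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    @cached_property
    def chrom_starts(self) -> np.ndarray:
        """Cumulative bp offset of each chromosome in a concatenated genome."""
        return np.concatenate([[0], np.cumsum(self.lengths_array)])

    def chrom_codes(self, chroms: pd.Series | np.ndarray) -> np.ndarray:
        codes = pd.Series(np.asarray(chroms)).map(self.index)
        if codes.isna().any():
            bad = sorted(set(np.asarray(chroms)[codes.isna().to_numpy()]))
            raise UnknownChromosomeError(
                f"chromosome(s) not in layout: {', '.join(map(str, bad))}"
            )
        return codes.to_numpy(dtype=np.int64)

    def n_bins(self, w: int) -> np.ndarray:
        """Number of width-w bins per chromosome (last bin truncated)."""
        return -(-self.lengths_array // int(w))

    def bin_offsets(self, w: int) -> np.ndarray:
        """Global bin-index offset of each chromosome at width w."""
        return np.concatenate([[0], np.cumsum(self.n_bins(w))])

    def total_bins(self, w: int) -> int:
        return int(self.n_bins(w).sum())

    def locate_bins(self, global_bins: np.ndarray, w: int):
        """Map global bin indices back to (chrom name, start, end)."""
        offsets = self.bin_offsets(w)
        codes = np.searchsorted(offsets, global_bins, side="right") - 1
        local = global_bins - offsets[codes]
        starts = local * int(w)
        ends = np.minimum(starts + int(w), self.lengths_array[codes])
        names = np.asarray(self.names, dtype=object)[codes]
        return names, starts, ends

    def global_to_chrom(self, gpos: np.ndarray):
        """Map concatenated-genome positions to (codes, within-chrom pos)."""
        codes = np.searchsorted(self.chrom_starts, gpos, side="right") - 1
        return codes, gpos - self.chrom_starts[codes]

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["name", "length"],
                         dtype={"name": str})
        return cls(tuple(df["name"]), tuple(int(x) for x in df["length"]))

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")


def load_reads(path: str | Path, format: str = "bed",
               layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Load aligned reads from a 6-column BED / tagAlign file.

    Returns a DataFrame with columns ``chrom, start, end, strand``.
    Malformed lines raise :class:`BedParseError` naming the line number;
    records on chromosomes absent from *layout* (when given) raise
    :class:`UnknownChromosomeError`.
    """
    if format not in ("bed", "tagalign"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str,
                          comment=None, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                             zip(READ_COLUMNS, [str, np.int64, np.int64, str])})
    if raw.shape[1] < 6:
        # locate the first row with missing fields for the error message
        short = raw.isna().any(axis=1)
        line = int(short.idxmax()) + 1 if short.any() else 1
        raise BedParseError(f"line {line}: expected 6 tab-separated fields")

    def _first_bad(mask: pd.Series) -> int:
        return int(np.flatnonzero(mask.to_numpy())[0]) + 1

    missing = raw.iloc[:, :6].isna().any(axis=1)
    if missing.any():
        raise BedParseError(f"line {_first_bad(missing)}: expected 6 fields")
    start = pd.to_numeric(raw[1], errors="coerce")
    end = pd.to_numeric(raw[2], errors="coerce")
    bad = start.isna() | end.isna()
    if bad.any():
        raise BedParseError(f"line {_first_bad(bad)}: non-numeric start/end")
    start = start.astype(np.int64)
    end = end.astype(np.int64)
    bad = (start < 0) | (start >= end)
    if bad.any():
        raise BedParseError(
            f"line {_first_bad(bad)}: requires 0 <= start < end")
    strand = raw[5].astype(str)
    bad = ~strand.isin(["+", "-"])
    if bad.any():
        raise BedParseError(f"line {_first_bad(bad)}: strand must be + or -")
    reads = pd.DataFrame({"chrom": raw[0].astype(str), "start": start,
                          "end": end, "strand": strand})
    if layout is not None:
        codes = layout.chrom_codes(reads["chrom"])
        too_long = reads["end"].to_numpy() > layout.lengths_array[codes]
        if too_long.any():
            raise BedParseError(
                f"line {int(np.flatnonzero(too_long)[0]) + 1}: "
                "read extends past chromosome end")
    return reads


def save_reads(reads: pd.DataFrame, path: str | Path) -> None:
    """Write reads as tagAlign (name '.', score 0)."""
    out = pd.DataFrame({
        0: reads["chrom"], 1: reads["start"], 2: reads["end"],
        3: ".", 4: 0, 5: reads["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def shift_reads(reads: pd.DataFrame, l: int,
                layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Shift each read l/2 bp towards its 3' end, yielding midpoint tags.

    Plus-strand tags land at ``start + l//2``; minus-strand tags at
    ``(end - 1) - l//2`` (the 3'-most base of a minus-strand read is
    ``end - 1``).  Tags shifted past a chromosome end are clamped to the
    terminal base so no reads are lost.
    """
    if l <= 0:
        raise ValueError("fragment length l must be positive")
    half = int(l) // 2
    start = reads["start"].to_numpy(dtype=np.int64)
    end = reads["end"].to_numpy(dtype=np.int64)
    plus = reads["strand"].to_numpy() == "+"
    pos = np.where(plus, start + half, end - 1 - half)
    pos = np.maximum(pos, 0)
    if layout is not None:
        codes = layout.chrom_codes(reads["chrom"])
        pos = np.minimum(pos, layout.lengths_array[codes] - 1)
    return pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "pos": pos,
                         "strand": reads["strand"].to_numpy()})


def tags_to_reads(tags: pd.DataFrame, l: int, layout: GenomeLayout,
                  read_len: int = 36) -> pd.DataFrame:
    """Inverse of :func:`shift_reads` for writing simulated tags to disk.

    Builds read intervals whose l/2 shift recovers the tag positions
    (up to clamping at chromosome boundaries).
    """
    half = int(l) // 2
    codes = layout.chrom_codes(tags["chrom"])
    lengths = layout.lengths_array[codes]
    pos = tags["pos"].to_numpy(dtype=np.int64)
    plus = tags["strand"].to_numpy() == "+"
    start = np.where(plus, pos - half, pos + half + 1 - read_len)
    start = np.clip(start, 0, np.maximum(lengths - read_len, 0))
    end = np.minimum(start + read_len, lengths)
    return pd.DataFrame({"chrom": tags["chrom"].to_numpy(), "start": start,
                         "end": end, "strand": tags["strand"].to_numpy()})


@dataclass
class BinTable:
    """Per-bin ChIP/control (and per-strand) tag counts at bin-width w.

    ``N1``/``N2`` are whole-sample totals and are unaffected by
    zero-filtering; ``m_w`` is the number of retained bins.
    """

    w: int
    global_bin: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    n1_plus: np.ndarray
    n1_minus: np.ndarray
    n2_plus: np.ndarray
    n2_minus: np.ndarray
    N1: int
    N2: int
    zero_filtered: bool
    layout: GenomeLayout | None = field(default=None, repr=False)

    @property
    def ni(self) -> np.ndarray:
        return self.n1 + self.n2

    @property
    def m_w(self) -> int:
        return int(len(self.n1))

    @property
    def depth_ratio(self) -> float:
        return self.N1 / self.N2

    @classmethod
    def from_counts(cls, n1, n2, w: int = 100, n1_plus=None, n2_plus=None,
                    N1: int | None = None, N2: int | None = None,
                    zero_filtered: bool = True,
                    layout: GenomeLayout | None = None) -> "BinTable":
        """Construct a table directly from count vectors (tests, examples).

        Strand counts default to an even split (plus strand gets the
        ceiling).  N1/N2 default to the column sums.
        """
        n1 = np.asarray(n1, dtype=np.int64)
        n2 = np.asarray(n2, dtype=np.int64)
        if n1.shape != n2.shape:
            raise ValueError("n1 and n2 must align")
        n1p = (n1 + 1) // 2 if n1_plus is None else np.asarray(n1_plus, dtype=np.int64)
        n2p = (n2 + 1) // 2 if n2_plus is None else np.asarray(n2_plus, dtype=np.int64)
        return cls(
            w=int(w), global_bin=np.arange(len(n1), dtype=np.int64),
            n1=n1, n2=n2, n1_plus=n1p, n1_minus=n1 - n1p,
            n2_plus=n2p, n2_minus=n2 - n2p,
            N1=int(n1.sum()) if N1 is None else int(N1),
            N2=int(n2.sum()) if N2 is None else int(N2),
            zero_filtered=zero_filtered, layout=layout)

    def to_frame(self) -> pd.DataFrame:
        if self.layout is None:
            raise ValueError("BinTable has no genome layout attached")
        names, starts, ends = self.layout.locate_bins(self.global_bin, self.w)
        return pd.DataFrame({
            "chrom": names, "bin_start": starts, "bin_end": ends,
            "n1": self.n1, "n2": self.n2,
            "n1_plus": self.n1_plus, "n1_minus": self.n1_minus,
            "n2_plus": self.n2_plus, "n2_minus": self.n2_minus,
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _strand_bincount(tags: pd.DataFrame, layout: GenomeLayout, w: int,
                     nbins: int) -> tuple[np.ndarray, np.ndarray]:
    codes = layout.chrom_codes(tags["chrom"])
    gidx = layout.bin_offsets(w)[codes] + tags["pos"].to_numpy(dtype=np.int64) // int(w)
    plus = tags["strand"].to_numpy() == "+"
    cp = np.bincount(gidx[plus], minlength=nbins)
    cm = np.bincount(gidx[~plus], minlength=nbins)
    return cp, cm


def bin_counts(chip: pd.DataFrame, control: pd.DataFrame,
               layout: GenomeLayout, w: int,
               drop_zero: bool = True) -> BinTable:
    """Aggregate shifted tags into a width-w :class:`BinTable`.

    With ``drop_zero`` (the default) bins with zero total count are
    discarded, matching the estimator-side filtering; whole-sample totals
    N1/N2 are recorded before filtering.
    """
    if w <= 0:
        raise ValueError("bin width must be positive")
    if len(chip) == 0 and len(control) == 0:
        raise ValueError("no reads in either sample")
    nbins = layout.total_bins(w)
    n1p, n1m = _strand_bincount(chip, layout, w, nbins)
    n2p, n2m = _strand_bincount(control, layout, w, nbins)
    n1 = n1p + n1m
    n2 = n2p + n2m
    gbin = np.arange(nbins, dtype=np.int64)
    if drop_zero:
        keep = (n1 + n2) > 0
        gbin, n1, n2 = gbin[keep], n1[keep], n2[keep]
        n1p, n1m, n2p, n2m = n1p[keep], n1m[keep], n2p[keep], n2m[keep]
    return BinTable(w=int(w), global_bin=gbin, n1=n1, n2=n2,
                    n1_plus=n1p, n1_minus=n1m, n2_plus=n2p, n2_minus=n2m,
                    N1=int(len(chip)), N2=int(len(control)),
                    zero_filtered=bool(drop_zero), layout=layout)


def marginal_ratio_profile(table: BinTable) -> pd.DataFrame:
    """Marginal ChIP/control ratio r_m(t) per distinct bin total t.

    r_m(t) = (sum of ChIP counts over bins with total t) / (sum of control
    counts over those bins).  Rows where the control sum is zero carry
    ``defined = False`` and NaN ratio.  One row per distinct observed
    total, ascending — the diagnostic behind the adaptive threshold search.
    """
    if not table.zero_filtered:
        raise ValueError("profile requires a zero-filtered table")
    ni = table.ni
    t_vals, inverse, counts = np.unique(ni, return_inverse=True,
                                        return_counts=True)
    chip_sum = np.bincount(inverse, weights=table.n1.astype(np.float64))
    ctrl_sum = np.bincount(inverse, weights=table.n2.astype(np.float64))
    defined = ctrl_sum > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r_m = np.where(defined, chip_sum / np.where(defined, ctrl_sum, 1.0),
                       np.nan)
    return pd.DataFrame({"t": t_vals, "r_m": r_m, "bins_at_t": counts,
                         "chip_sum": chip_sum.astype(np.int64),
                         "control_sum": ctrl_sum.astype(np.int64),
                         "defined": defined})
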