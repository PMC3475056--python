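"""ChIP/control normalization-factor estimators.

A ChIP sample with N1 reads mixes background and signal: Pi0*N1 reads are
background noise and (1-Pi0)*N1 are true enrichment.  The normalization
factor r = Pi0*N1/N2 is the ratio by which control bin counts must be
scaled to match the *background* component of ChIP bin counts; it is
bounded above by the sequencing depth ratio N1/N2.  Every estimator here
approximates the background bin set B and applies the background ratio

    r_hat = sum_{i in B} n1i / sum_{i in B} n2i.

NCIS chooses the bin-width w and total-count threshold t defining
B_w(t) = {i : n1i + n2i <= t} adaptively from the data.  The four
comparators (CisGenome, SPP, CCAT, PeakSeq) use the fixed tuning
parameters their publications prescribe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .read_io import BinTable, GenomeLayout, bin_counts

__all__ = [
    "DegenerateBackgroundError",
    "NcisConfig",
    "ComparatorConfig",
    "NormalizationResult",
    "FixedWidthEstimate",
    "background_ratio",
    "ncis_fixed_w",
    "ncis_estimate",
    "cisgenome_estimate",
    "spp_estimate",
    "ccat_estimate",
    "peakseq_estimate",
    "pi0_from_r",
    "estimate_all",
    "METHODS",
]

METHODS = ("ncis", "cisgenome", "spp", "ccat", "peakseq")

DEFAULT_GRID = (100, 200, 500, 1000, 2000, 5000, 10000)


class DegenerateBackgroundError(ValueError):
    """The candidate background bin set cannot support a ratio estimate."""


@dataclass(frozen=True)
class NcisConfig:
    """Bin-width grid and eligibility floor for the adaptive search.

    ``quartile_floor`` is the fraction of retained bins a threshold's
    background set must cover before it is considered (the search starts
    at the upper quartile of the non-zero totals, hence 0.75).
    """

    grid: tuple[int, ...] = DEFAULT_GRID
    quartile_floor: float = 0.75

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("bin-width grid must be strictly ascending")
        if not 0 < self.quartile_floor < 1:
            raise ValueError("quartile_floor must be in (0, 1)")


@dataclass(frozen=True)
class ComparatorConfig:
    """Fixed tuning parameters of the four comparator estimators."""

    cisgenome_w: int = 100
    cisgenome_t: int = 1
    spp_w: int = 1000
    spp_c: float = 1e-5
    ccat_w: int = 1000
    ccat_tol: float = 1e-6
    ccat_max_iter: int = 100
    peakseq_w: int = 10000
    peakseq_pf: float = 0.0

    def __post_init__(self) -> None:
        if min(self.cisgenome_w, self.spp_w, self.ccat_w, self.peakseq_w) <= 0:
            raise ValueError("bin widths must be positive")
        if not 0 < self.spp_c < 1:
            raise ValueError("SPP p-value threshold must be in (0, 1)")
        if self.ccat_tol <= 0:
            raise ValueError("CCAT tolerance must be positive")


@dataclass
class NormalizationResult:
    """An estimator's output: r_hat, Pi0_hat and how they were reached."""

    method: str
    r_hat: float
    pi0_hat: float
    w_star: int
    t_star: int | None
    n_background_bins: int
    depth_ratio: float
    trace: list[tuple[int, float]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "r_hat": self.r_hat,
            "pi0_hat": self.pi0_hat,
            "w_star": self.w_star,
            "t_star": self.t_star,
            "n_background_bins": self.n_background_bins,
            "depth_ratio": self.depth_ratio,
            "trace": [[int(w), float(r)] for w, r in self.trace],
            "flags": list(self.flags),
        }


class FixedWidthEstimate(NamedTuple):
    r_hat: float
    t_star: int
    n_background_bins: int
    fallback: bool


def background_ratio(table: BinTable, B: np.ndarray) -> float:
    """Eq.-style background ratio over the bin index set B."""
    B = np.asarray(B)
    if B.dtype == bool:
        if not B.any():
            raise DegenerateBackgroundError("background bin set is empty")
    elif B.size == 0:
        raise DegenerateBackgroundError("background bin set is empty")
    denom = int(table.n2[B].sum())
    if denom == 0:
        raise DegenerateBackgroundError("control count sum over B is zero")
    return float(table.n1[B].sum() / denom)


def pi0_from_r(r_hat: float, N1: int, N2: int) -> float:
    """Invert r = Pi0*N1/N2: Pi0_hat = r_hat * N2 / N1.

    Values above 1 (possible for conservative estimators on real data)
    are returned as-is with a warning.
    """
    if r_hat <= 0 or N1 <= 0 or N2 <= 0:
        raise ValueError("r_hat, N1 and N2 must be positive")
    pi0 = r_hat * N2 / N1
    if pi0 > 1:
        warnings.warn(f"estimated background proportion {pi0:.3f} exceeds 1",
                      stacklevel=2)
    return pi0


def _result(method: str, table: BinTable, r_hat: float, w_star: int,
            t_star: int | None, n_bins: int,
            trace: list[tuple[int, float]] | None = None,
            flags: list[str] | None = None) -> NormalizationResult:
    flags = list(flags or [])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pi0 = pi0_from_r(r_hat, table.N1, table.N2)
    if pi0 > 1:
        flags.append("pi0_above_1")
    return NormalizationResult(
        method=method, r_hat=float(r_hat), pi0_hat=float(pi0),
        w_star=int(w_star), t_star=t_star, n_background_bins=int(n_bins),
        depth_ratio=table.depth_ratio, trace=list(trace or []), flags=flags)


def ncis_fixed_w(table: BinTable,
                 quartile_floor: float = 0.75) -> FixedWidthEstimate:
    """Adaptive total-count threshold search at one fixed bin-width.

    Walk the ascending distinct observed totals t; the first t whose
    cumulative background set B_w(t) = {i : ni <= t} covers at least
    ``quartile_floor`` of the retained bins *and* whose ratio estimate is
    >= the estimate at the previous distinct total wins.  If no threshold
    qualifies, fall back to all bins (the estimate then approaches the
    depth ratio) and flag it.
    """
    if not table.zero_filtered:
        raise ValueError("NCIS operates on zero-filtered bin tables")
    m = table.m_w
    if m == 0:
        raise DegenerateBackgroundError("no non-empty bins")
    ni = table.ni
    order = np.argsort(ni, kind="stable")
    ni_s = ni[order]
    c1 = np.cumsum(table.n1[order], dtype=np.int64)
    c2 = np.cumsum(table.n2[order], dtype=np.int64)
    # index of the last bin at each distinct total
    t_vals, first_idx = np.unique(ni_s, return_index=True)
    last_idx = np.concatenate([first_idx[1:] - 1, [m - 1]])
    C1, C2 = c1[last_idx], c2[last_idx]
    sizes = last_idx + 1
    valid = C2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, C1 / np.where(valid, C2, 1), np.nan)
    if len(t_vals) >= 2:
        eligible = (sizes[1:] >= quartile_floor * m) & valid[1:] & valid[:-1]
        nondecr = eligible & (r[1:] >= r[:-1])
        hits = np.flatnonzero(nondecr)
        if hits.size:
            i = int(hits[0]) + 1
            return FixedWidthEstimate(float(r[i]), int(t_vals[i]),
                                      int(sizes[i]), False)
    if not valid[-1]:
        raise DegenerateBackgroundError(
            "control counts sum to zero over all bins")
    return FixedWidthEstimate(float(r[-1]), int(t_vals[-1]), m, True)


def ncis_estimate(chip, control, layout: GenomeLayout,
                  config: NcisConfig | None = None) -> NormalizationResult:
    """NCIS: adaptive (w, t) choice along an ascending bin-width grid.

    Fixed-width estimates r_hat_w are computed along the grid; the final
    estimate is the one at the first width w_i whose successor satisfies
    r_hat_{w_{i+1}} >= r_hat_{w_i}.  A strictly decreasing sequence over
    the whole grid falls back to the last width (flagged): in either limit
    the estimate approaches the depth-ratio upper bound.
    """
    if len(chip) == 0 or len(control) == 0:
        raise ValueError("both samples must contain reads")
    config = config or NcisConfig()
    trace: list[tuple[int, float]] = []
    chosen: tuple[int, FixedWidthEstimate] | None = None
    prev: tuple[int, FixedWidthEstimate] | None = None
    flags: list[str] = []
    table = None
    for w in config.grid:
        table = bin_counts(chip, control, layout, w, drop_zero=True)
        est = ncis_fixed_w(table, config.quartile_floor)
        trace.append((w, est.r_hat))
        if prev is not None and est.r_hat >= prev[1].r_hat:
            chosen = prev
            break
        prev = (w, est)
    if chosen is None:
        chosen = prev  # strictly decreasing through the grid
        flags.append("grid_exhausted")
    w_star, est = chosen
    if est.fallback:
        flags.append("fixed_w_fallback")
    # N1/N2/depth_ratio are width-independent, so any computed table serves
    return _result("ncis", table, est.r_hat, w_star, est.t_star,
                   est.n_background_bins, trace, flags)


def cisgenome_estimate(table: BinTable,
                       t: int = 1) -> NormalizationResult:
    """CisGenome-style estimator: background = bins with total count <= t.

    Defaults to t = 1 at w = 100 bp.  Deeply sequenced data may have no
    such bins at all, in which case this estimator is inapplicable and a
    degenerate-background error is raised.
    """
    B = table.ni <= t
    if not B.any():
        raise DegenerateBackgroundError(
            f"no bins with total count <= {t}; sample too deeply sequenced "
            "for the fixed low-count threshold")
    r = background_ratio(table, B)
    return _result("cisgenome", table, r, table.w, t, int(B.sum()))


def spp_estimate(table: BinTable, layout: GenomeLayout,
                 c: float = 1e-5) -> NormalizationResult:
    """SPP-style estimator: exclude bins extreme under a uniform model.

    p1i/p2i are exact upper-tail Poisson probabilities P(X >= n) at the
    uniform-background rate (depth * w / G); bins with min(p1i, p2i) <= c
    are excluded and the background ratio is taken over the rest.
    """
    rate1 = table.N1 * table.w / layout.G
    rate2 = table.N2 * table.w / layout.G
    p1 = stats.poisson.sf(table.n1 - 1, rate1)
    p2 = stats.poisson.sf(table.n2 - 1, rate2)
    B = np.minimum(p1, p2) > c
    if not B.any():
        raise DegenerateBackgroundError(
            "every bin is extreme under the uniform-background model")
    r = background_ratio(table, B)
    return _result("spp", table, r, table.w, None, int(B.sum()))


def ccat_estimate(table: BinTable, tol: float = 1e-6,
                  max_iter: int = 100) -> NormalizationResult:
    """CCAT-style strand-split iteration.

    Starting from the depth ratio, the background set is re-estimated
    from positive-strand counts, B = {i : n1i+ < r * n2i+}, and r is
    updated from negative-strand counts over B; iterate to convergence.
    An empty B (e.g. ChIP identical to control) leaves r at its current
    value, a trivial fixed point, and is flagged rather than fatal.
    """
    if table.N2 <= 0:
        raise ValueError("control sample is empty")
    r = table.depth_ratio
    flags: list[str] = []
    converged = False
    n_bins = table.m_w
    for j in range(max_iter):
        B = table.n1_plus < r * table.n2_plus
        n_bins = int(B.sum())
        if n_bins == 0:
            flags.append("empty_background_fixed_point")
            converged = True
            break
        denom = int(table.n2_minus[B].sum())
        if denom == 0:
            raise DegenerateBackgroundError(
                f"negative-strand control sum is zero at iteration {j}")
        r_new = float(table.n1_minus[B].sum() / denom)
        if abs(r_new - r) < tol:
            r = r_new
            converged = True
            break
        r = r_new
    if not converged:
        flags.append("not_converged")
    return _result("ccat", table, r, table.w, None, n_bins, flags=flags)


def peakseq_estimate(table: BinTable,
                     pf: float = 0.0) -> NormalizationResult:
    """PeakSeq-style estimator: OLS slope of ChIP on control bin counts.

    Only the zero-exclusion variant (Pf = 0) is supported; the regression
    includes an intercept and uses every bin (zero-total bins included),
    so pass an unfiltered table.
    """
    if pf != 0.0:
        raise NotImplementedError(
            "only Pf = 0 (no exclusion) is supported")
    n2 = table.n2.astype(np.float64)
    if len(n2) < 2 or np.all(n2 == n2[0]):
        raise DegenerateBackgroundError(
            "control bin counts are constant; regression slope undefined")
    slope = stats.linregress(n2, table.n1.astype(np.float64)).slope
    if slope <= 0:
        raise DegenerateBackgroundError(
            f"regression slope {slope:.4g} is not a valid ratio")
    return _result("peakseq", table, float(slope), table.w, None, table.m_w)


def estimate_all(chip, control, layout: GenomeLayout,
                 methods: Sequence[str] = METHODS,
                 ncis_config: NcisConfig | None = None,
                 comparator_config: ComparatorConfig | None = None,
                 ) -> dict[str, NormalizationResult]:
    """Run a set of estimators on shifted tag collections.

    Bin tables are built per method at that method's bin-width; PeakSeq
    receives an unfiltered table (its regression uses the full cloud).
    """
    cc = comparator_config or ComparatorConfig()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    out: dict[str, NormalizationResult] = {}
    for method in methods:
        if method == "ncis":
            out[method] = ncis_estimate(chip, control, layout, ncis_config)
        elif method == "cisgenome":
            table = bin_counts(chip, control, layout, cc.cisgenome_w)
            out[method] = cisgenome_estimate(table, cc.cisgenome_t)
        elif method == "spp":
            table = bin_counts(chip, control, layout, cc.spp_w)
            out[method] = spp_estimate(table, layout, cc.spp_c)
        elif method == "ccat":
            table = bin_counts(chip, control, layout, cc.ccat_w)
            out[method] = ccat_estimate(table, cc.ccat_tol, cc.ccat_max_iter)
        elif method == "peakseq":
            table = bin_counts(chip, control, layout, cc.peakseq_w,
                               drop_zero=False)
            out[method] = peakseq_estimate(table, cc.peakseq_pf)
    return out
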