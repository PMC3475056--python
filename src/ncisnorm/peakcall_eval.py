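"""Two-stage binomial peak calling, sample-swap FDR and evaluation.

Given a normalization factor r, the probability that a read in a
candidate region came from the ChIP sample rather than the (scaled)
control is r/(1+r); regions are scored by the upper-tail binomial
p-value of their ChIP count.  The caller is deliberately simple — a
liberal 100 bp first stage, a 20 bp refinement, a +/-110 bp scoring
window — because its purpose is to isolate the effect of the
normalization factor on FDR control and power, not to compete with
production peak callers.

Empirical FDR control uses sample swapping: the caller is re-run with
ChIP and control exchanged (and r replaced by 1/r), and at a common
p-value threshold s the FDR is estimated as R_I(s)/R_C(s), the ratio of
control-side to ChIP-side call counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .read_io import GenomeLayout

__all__ = [
    "CallerConfig",
    "SwapFdrResult",
    "EvalResult",
    "MseResult",
    "binomial_pvalue",
    "call_sites",
    "swap_fdr_call",
    "evaluate_calls",
    "estimator_mse",
]

SITE_COLUMNS = ["chrom", "pos", "win_start", "win_end", "n1", "n2", "pvalue"]


@dataclass(frozen=True)
class CallerConfig:
    stage1_bin: int = 100          # coarse scan bin width, bp
    stage1_alpha: float = 0.05     # liberal retention threshold
    fine_bin: int = 20             # refinement bin width, bp
    extend: int = 110              # half-width of the scoring window, bp
    nominal_fdr: float = 0.05
    match_dist: int = 100          # true/false-positive distance, bp
    merge_gap: int = 0             # max bp gap when merging stage-1 bins

    def __post_init__(self) -> None:
        if self.fine_bin > self.stage1_bin:
            raise ValueError("fine_bin must not exceed stage1_bin")
        if self.extend <= 0 or not 0 < self.nominal_fdr < 1:
            raise ValueError("extend > 0 and 0 < nominal_fdr < 1 required")


@dataclass
class SwapFdrResult:
    """Declared sites and the empirical FDR at the chosen threshold."""

    threshold: float | None
    R_C: int
    R_I: int
    empirical_fdr: float
    declared: pd.DataFrame
    chip_sites: pd.DataFrame
    control_sites: pd.DataFrame
    flags: list[str] = field(default_factory=list)


@dataclass
class EvalResult:
    """Classification of declared sites against known true sites.

    ``n_true_positive`` counts every declared site within ``match_dist``
    of some true site (so n_declared = TP + FP); ``power`` counts the
    distinct true sites recovered, so duplicate predictions of one site
    neither inflate power nor count as false positives.
    """

    n_declared: int
    n_true_positive: int
    n_false_positive: int
    realized_fdr: float
    power: int


class MseResult:
    __slots__ = ("bias", "variance", "mse")

    def __init__(self, bias: float, variance: float, mse: float):
        self.bias, self.variance, self.mse = bias, variance, mse

    def __iter__(self):
        return iter((self.bias, self.variance, self.mse))

    def __repr__(self):
        return (f"MseResult(bias={self.bias:.4g}, variance={self.variance:.4g}, "
                f"mse={self.mse:.4g})")


def binomial_pvalue(n1, n2, r_hat: float):
    """Upper-tail binomial p-value for ChIP enrichment.

    P(X >= n1) with X ~ Binomial(n1 + n2, r_hat/(1 + r_hat)); equals 1
    when the window is empty.  Vectorized over n1/n2.
    """
    if r_hat <= 0:
        raise ValueError("r_hat must be positive")
    n1 = np.asarray(n1, dtype=np.int64)
    n2 = np.asarray(n2, dtype=np.int64)
    n = n1 + n2
    pr = r_hat / (1.0 + r_hat)
    p = np.where(n > 0, stats.binom.sf(n1 - 1, np.maximum(n, 1), pr), 1.0)
    return float(p) if p.ndim == 0 else p


def _positions_by_chrom(tags: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, grp in tags.groupby("chrom", observed=True, sort=False):
        out[str(chrom)] = np.sort(grp["pos"].to_numpy(dtype=np.int64))
    return out


def _count_in(pos_sorted: np.ndarray, lo: int, hi: int) -> int:
    return int(np.searchsorted(pos_sorted, hi)
               - np.searchsorted(pos_sorted, lo))


def call_sites(chip: pd.DataFrame, control: pd.DataFrame,
               layout: GenomeLayout, r_hat: float,
               config: CallerConfig | None = None) -> pd.DataFrame:
    """Two-stage binomial site caller; returns sites sorted by p-value.

    Stage 1 bins the genome at ``stage1_bin`` bp, keeps bins whose
    binomial p-value is <= ``stage1_alpha`` and merges retained bins
    whose gap does not exceed ``merge_gap`` into candidate regions.
    Stage 2 locates, per region, the ``fine_bin``-bp bin with the
    highest ChIP count (leftmost on ties), takes its center as the
    predicted site, and scores ChIP vs control counts in the window
    [pos - extend, pos + extend) with the binomial p-value.
    """
    if r_hat <= 0:
        raise ValueError("r_hat must be positive")
    cfg = config or CallerConfig()
    empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        SITE_COLUMNS, [str, np.int64, np.int64, np.int64, np.int64,
                       np.int64, np.float64])})
    if len(chip) == 0:
        return empty
    w = cfg.stage1_bin
    nbins = layout.total_bins(w)
    offsets = layout.bin_offsets(w)

    def _bincount(tags: pd.DataFrame) -> np.ndarray:
        if len(tags) == 0:
            return np.zeros(nbins, dtype=np.int64)
        codes = layout.chrom_codes(tags["chrom"])
        gidx = offsets[codes] + tags["pos"].to_numpy(dtype=np.int64) // w
        return np.bincount(gidx, minlength=nbins)

    n1 = _bincount(chip)
    n2 = _bincount(control)
    pvals = binomial_pvalue(n1, n2, r_hat)
    retained = np.flatnonzero(pvals <= cfg.stage1_alpha)
    if retained.size == 0:
        return empty

    # merge retained bins into regions, never across chromosome boundaries
    bin_chrom = np.searchsorted(offsets, retained, side="right") - 1
    max_step = cfg.merge_gap // w + 1
    breaks = np.flatnonzero((np.diff(retained) > max_step)
                            | (np.diff(bin_chrom) != 0)) + 1
    groups = np.split(retained, breaks)

    chip_pos = _positions_by_chrom(chip)
    ctrl_pos = _positions_by_chrom(control)
    lengths = layout.lengths_array
    fb = cfg.fine_bin
    rows_chrom, rows_pos, rows_n1, rows_n2 = [], [], [], []
    for grp in groups:
        code = int(np.searchsorted(offsets, grp[0], side="right") - 1)
        chrom = layout.names[code]
        start = int((grp[0] - offsets[code]) * w)
        end = int(min((grp[-1] - offsets[code] + 1) * w, lengths[code]))
        cpos = chip_pos.get(chrom)
        if cpos is None:
            continue
        i0 = np.searchsorted(cpos, start)
        i1 = np.searchsorted(cpos, end)
        if i1 == i0:
            continue
        nb = -(-(end - start) // fb)
        hist = np.bincount((cpos[i0:i1] - start) // fb, minlength=nb)
        k = int(np.argmax(hist))  # leftmost maximum
        pos = start + k * fb + fb // 2
        lo, hi = pos - cfg.extend, pos + cfg.extend
        rows_chrom.append(chrom)
        rows_pos.append(pos)
        rows_n1.append(_count_in(cpos, lo, hi))
        ppos = ctrl_pos.get(chrom)
        rows_n2.append(_count_in(ppos, lo, hi) if ppos is not None else 0)
    if not rows_pos:
        return empty
    pos_arr = np.asarray(rows_pos, dtype=np.int64)
    n1_arr = np.asarray(rows_n1, dtype=np.int64)
    n2_arr = np.asarray(rows_n2, dtype=np.int64)
    sites = pd.DataFrame({
        "chrom": rows_chrom, "pos": pos_arr,
        "win_start": pos_arr - cfg.extend, "win_end": pos_arr + cfg.extend,
        "n1": n1_arr, "n2": n2_arr,
        "pvalue": binomial_pvalue(n1_arr, n2_arr, r_hat),
    })
    return sites.sort_values("pvalue", kind="stable").reset_index(drop=True)


def swap_fdr_call(chip: pd.DataFrame, control: pd.DataFrame,
                  layout: GenomeLayout, r_hat: float,
                  config: CallerConfig | None = None) -> SwapFdrResult:
    """Call sites with empirical FDR controlled by sample swapping.

    The caller runs ChIP-vs-control at r_hat and control-vs-ChIP at
    1/r_hat; the declared set uses the largest p-value threshold s among
    the ChIP-side p-values with R_I(s)/R_C(s) <= the nominal level.  If
    no threshold qualifies, nothing is declared (flagged).
    """
    cfg = config or CallerConfig()
    chip_sites = call_sites(chip, control, layout, r_hat, cfg)
    ctrl_sites = call_sites(control, chip, layout, 1.0 / r_hat, cfg)
    pc = chip_sites["pvalue"].to_numpy()
    pi = np.sort(ctrl_sites["pvalue"].to_numpy())
    flags: list[str] = []
    threshold = None
    if len(pc):
        cand = np.unique(pc)
        r_c = np.searchsorted(pc, cand, side="right")  # pc sorted ascending
        r_i = np.searchsorted(pi, cand, side="right")
        ok = r_i <= cfg.nominal_fdr * r_c
        if ok.any():
            threshold = float(cand[np.flatnonzero(ok)[-1]])
    if threshold is None:
        flags.append("no_threshold_qualifies")
        declared = chip_sites.iloc[0:0]
        R_C = R_I = 0
        fdr = 0.0
    else:
        R_C = int(np.searchsorted(pc, threshold, side="right"))
        R_I = int(np.searchsorted(pi, threshold, side="right"))
        declared = chip_sites.iloc[:R_C].reset_index(drop=True)
        fdr = R_I / R_C
    return SwapFdrResult(threshold=threshold, R_C=R_C, R_I=R_I,
                         empirical_fdr=fdr, declared=declared,
                         chip_sites=chip_sites, control_sites=ctrl_sites,
                         flags=flags)


def evaluate_calls(declared: pd.DataFrame, true_sites: pd.DataFrame,
                   match_dist: int = 100) -> EvalResult:
    """Classify declared sites against true site locations.

    A declared site is a true positive iff its distance to the closest
    true site is <= ``match_dist``; ``power`` is the number of distinct
    true sites recovered.
    """
    if match_dist <= 0:
        raise ValueError("match_dist must be positive")
    n_declared = len(declared)
    if n_declared == 0:
        return EvalResult(0, 0, 0, 0.0, 0)
    tp = 0
    hit_sites: set[tuple[str, int]] = set()
    true_by_chrom = {
        str(chrom): np.sort(grp["pos"].to_numpy(dtype=np.int64))
        for chrom, grp in true_sites.groupby("chrom", observed=True)}
    for chrom, grp in declared.groupby("chrom", observed=True):
        tpos = true_by_chrom.get(str(chrom))
        if tpos is None or len(tpos) == 0:
            continue
        dpos = grp["pos"].to_numpy(dtype=np.int64)
        j = np.clip(np.searchsorted(tpos, dpos), 0, len(tpos) - 1)
        jl = np.maximum(j - 1, 0)
        dist = np.minimum(np.abs(tpos[j] - dpos), np.abs(tpos[jl] - dpos))
        nearest = np.where(np.abs(tpos[j] - dpos) <= np.abs(tpos[jl] - dpos),
                           j, jl)
        within = dist <= match_dist
        tp += int(within.sum())
        hit_sites.update((str(chrom), int(s)) for s in nearest[within])
    fp = n_declared - tp
    return EvalResult(n_declared=n_declared, n_true_positive=tp,
                      n_false_positive=fp,
                      realized_fdr=fp / max(n_declared, 1),
                      power=len(hit_sites))


def estimator_mse(estimates, true_r: float) -> MseResult:
    """Bias, (population) variance and MSE of replicate estimates.

    MSE = bias^2 + variance holds exactly in the population form.
    """
    x = np.asarray(estimates, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least two replicate estimates")
    bias = float(x.mean() - true_r)
    variance = float(x.var())
    mse = float(np.mean((x - true_r) ** 2))
    return MseResult(bias, variance, mse)
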