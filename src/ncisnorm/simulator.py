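"""Paired ChIP/control simulation with known normalization ground truth.

The generator emulates the structure of deeply sequenced ChIP-seq pairs:

* a shared, non-uniform background — both samples draw reads from the
  same latent per-window intensity field (gamma-distributed, mean 1),
  so their background bin counts are linearly related in expectation;
* point-source signal (transcription-factor-like): site positions
  uniform over the genome, read positions Normal(mu_i, sigma^2 = 900),
  per-site read counts exponential with mean c*N2/p, spiked into the
  ChIP sample only;
* control-only artifacts: tight read piles at a handful of loci
  (PCR-over-amplification-like), totalling a small fraction of the
  control depth;
* diffuse enrichment (histone-modification-like): reads uniform over
  5-15 kb domains.

Every dataset records its exact background/signal read partition, so the
true background proportion Pi0 = (background ChIP reads)/N1 and the true
normalization factor r = Pi0*N1/N2 are known by construction.  All
operations are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .read_io import GenomeLayout, tags_to_reads, save_reads

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "yeast_like_genome",
    "synth_background",
    "split_subsample",
    "spike_point_sources",
    "add_control_artifacts",
    "spike_diffuse_regions",
    "make_power_truth",
    "simulate",
    "write_dataset",
]


def yeast_like_genome(total_bp: int = 12_000_000,
                      n_chrom: int = 4) -> GenomeLayout:
    """A yeast-sized multi-chromosome layout for simulations."""
    base = total_bp // n_chrom
    lengths = [base] * n_chrom
    lengths[-1] += total_bp - base * n_chrom
    return GenomeLayout(tuple(f"chr{i + 1}" for i in range(n_chrom)),
                        tuple(lengths))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated ChIP/control pair.

    Defaults follow the transcription-factor spike-in design: p = 1000
    point sources with positional variance sigma^2 = 900 bp^2, per-site
    counts exponential with mean c*N2/p (c = 1 the strong-signal case),
    20 control artifact loci carrying 0.5% of control depth, diffuse
    domains 5-15 kb.  ``background_depth`` is per sample before the 1/d
    subsampling thinning.
    """

    genome: GenomeLayout = field(default_factory=yeast_like_genome)
    background_depth: int = 200_000
    c: float = 1.0
    d: int = 1
    p: int = 1000
    sigma2: float = 900.0
    l: int = 200
    artifact_k: int = 20
    artifact_frac: float = 0.005
    artifact_jitter: int = 50
    region_len_range: tuple[int, int] = (5000, 15000)
    power_sites: int = 1000
    power_pool: int = 1572
    roughness: float = 0.25
    window: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_depth <= 0 or self.p <= 0 or self.d < 1:
            raise ValueError("depth, p must be positive; d >= 1")
        if not 0 < self.artifact_frac < 1:
            raise ValueError("artifact_frac must be in (0, 1)")
        if self.region_len_range[0] > self.region_len_range[1]:
            raise ValueError("region length range must be ordered")


@dataclass
class SimulatedDataset:
    """A ChIP/control tag pair with construction-known ground truth."""

    chip: pd.DataFrame
    control: pd.DataFrame
    true_r: float
    true_pi0: float
    true_sites: pd.DataFrame
    setting: str
    seed: int
    n_background_chip: int
    n_signal: int
    n_artifact: int
    config: SimConfig | None = field(default=None, repr=False)

    @property
    def N1(self) -> int:
        return len(self.chip)

    @property
    def N2(self) -> int:
        return len(self.control)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _tags(layout: GenomeLayout, codes: np.ndarray, pos: np.ndarray,
          strand: np.ndarray) -> pd.DataFrame:
    names = np.asarray(layout.names, dtype=object)[codes]
    return pd.DataFrame({"chrom": names, "pos": pos.astype(np.int64),
                         "strand": strand})


def _random_strands(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.where(rng.random(n) < 0.5, "+", "-")


def _uniform_genome_positions(layout: GenomeLayout, n: int,
                              rng: np.random.Generator):
    gpos = rng.integers(0, layout.G, size=n)
    return layout.global_to_chrom(gpos)


def synth_background(layout: GenomeLayout, depth1: int, depth2: int,
                     roughness: float = 0.25, window: int = 1000,
                     seed=0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw two read sets from one shared non-uniform background.

    A latent intensity, gamma with mean 1 and variance ``roughness``, is
    drawn once per ``window``-bp tile and shared by both samples; reads
    sample tiles proportionally to intensity*length, then land uniformly
    within the tile.  ``roughness`` -> 0 recovers a uniform background.
    The two samples are conditionally independent given the intensity,
    honoring the approximately-linear background relationship seen in
    real ChIP/control pairs.
    """
    if depth1 <= 0 or depth2 <= 0:
        raise ValueError("depths must be positive")
    rng = _rng(seed)
    n_win = layout.n_bins(window)
    total_win = int(n_win.sum())
    offsets = layout.bin_offsets(window)
    win_code = np.repeat(np.arange(len(layout.names)), n_win)
    win_local = np.concatenate([np.arange(k) for k in n_win])
    win_start = win_local * window
    win_len = np.minimum(win_start + window,
                         layout.lengths_array[win_code]) - win_start
    if roughness > 0:
        shape = 1.0 / roughness
        intensity = rng.gamma(shape, scale=1.0 / shape, size=total_win)
    else:
        intensity = np.ones(total_win)
    weights = intensity * win_len
    prob = weights / weights.sum()

    def one_sample(depth: int) -> pd.DataFrame:
        counts = rng.multinomial(depth, prob)
        reps = np.repeat(np.arange(total_win), counts)
        offs = np.floor(rng.random(depth) * win_len[reps]).astype(np.int64)
        pos = win_start[reps] + offs
        return _tags(layout, win_code[reps], pos, _random_strands(rng, depth))

    return one_sample(int(depth1)), one_sample(int(depth2))


def split_subsample(reads: pd.DataFrame, d: int, seed=0,
                    exact: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly split a read set in two halves, each thinned to 1/d.

    The halves are disjoint with sizes differing by at most one.  By
    default each read survives thinning independently with probability
    1/d (binomial thinning, matching sequencing-depth semantics); with
    ``exact`` the subsample size is exactly floor(size/d).
    """
    if len(reads) == 0:
        raise ValueError("cannot split an empty read set")
    if d < 1:
        raise ValueError("subsampling divisor d must be >= 1")
    rng = _rng(seed)
    n = len(reads)
    perm = rng.permutation(n)
    halves = [perm[: (n + 1) // 2], perm[(n + 1) // 2:]]
    out = []
    for idx in halves:
        if d > 1:
            if exact:
                idx = idx[: len(idx) // d]
            else:
                idx = idx[rng.random(len(idx)) < 1.0 / d]
        out.append(reads.iloc[np.sort(idx)].reset_index(drop=True))
    return out[0], out[1]


def _place_point_reads(layout: GenomeLayout, site_codes: np.ndarray,
                       site_pos: np.ndarray, counts: np.ndarray,
                       sigma2: float, rng: np.random.Generator) -> pd.DataFrame:
    """Normal(mu_i, sigma^2) read positions around point sources."""
    reps = np.repeat(np.arange(len(site_pos)), counts)
    n = len(reps)
    pos = np.rint(site_pos[reps]
                  + rng.normal(0.0, np.sqrt(sigma2), n)).astype(np.int64)
    codes = site_codes[reps]
    pos = np.clip(pos, 0, layout.lengths_array[codes] - 1)
    return _tags(layout, codes, pos, _random_strands(rng, n))


def spike_point_sources(background_chip: pd.DataFrame, layout: GenomeLayout,
                        p: int, c: float, N2: int, sigma2: float = 900.0,
                        seed=0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spike transcription-factor-like point-source signal into ChIP.

    p site centers are uniform over the genome; per-site read counts are
    exponential with mean c*N2/p (rounded), so on average c*N2 signal
    reads are added; read positions are Normal(mu_i, sigma^2).
    Returns the augmented ChIP tags and a true-site table.
    """
    if p < 1 or c <= 0:
        raise ValueError("p >= 1 and c > 0 required")
    rng = _rng(seed)
    codes, mu = _uniform_genome_positions(layout, p, rng)
    counts = np.rint(rng.exponential(c * N2 / p, size=p)).astype(np.int64)
    signal = _place_point_reads(layout, codes, mu, counts, sigma2, rng)
    chip = pd.concat([background_chip, signal], ignore_index=True)
    names = np.asarray(layout.names, dtype=object)[codes]
    sites = pd.DataFrame({"chrom": names, "pos": mu, "count": counts})
    return chip, sites


def add_control_artifacts(control: pd.DataFrame, layout: GenomeLayout,
                          k: int = 20, frac: float = 0.005,
                          jitter: int = 50, seed=0) -> pd.DataFrame:
    """Append tight artifact read piles to the control sample.

    floor(frac * N2) reads are split evenly over k uniform loci
    (remainder to the first locus), each read jittered uniformly within
    +/- ``jitter`` bp of its locus — mimicking PCR over-amplification
    piles seen in real control samples.
    """
    if not 0 < frac < 1 or k < 1:
        raise ValueError("require 0 < frac < 1 and k >= 1")
    rng = _rng(seed)
    n_art = int(frac * len(control))
    codes, locs = _uniform_genome_positions(layout, k, rng)
    per = np.full(k, n_art // k, dtype=np.int64)
    per[0] += n_art - per.sum()
    reps = np.repeat(np.arange(k), per)
    offs = rng.integers(-jitter, jitter + 1, size=n_art)
    pos = np.clip(locs[reps] + offs, 0,
                  layout.lengths_array[codes[reps]] - 1)
    piles = _tags(layout, codes[reps], pos, _random_strands(rng, n_art))
    return pd.concat([control, piles], ignore_index=True)


def spike_diffuse_regions(background_chip: pd.DataFrame, layout: GenomeLayout,
                          p: int, c: float, N2: int,
                          len_range: tuple[int, int] = (5000, 15000),
                          seed=0, max_tries: int = 100,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spike diffuse (histone-modification-like) enrichment domains.

    Region lengths are uniform in ``len_range``; starts uniform subject
    to the region fitting inside a chromosome (chromosomes chosen
    proportionally to length); per-region read counts are exponential
    with mean c*N2/p and reads land uniformly within the region.
    """
    if p < 1:
        raise ValueError("p >= 1 required")
    rng = _rng(seed)
    lo, hi = len_range
    lengths = layout.lengths_array
    reg_len = rng.integers(lo, hi + 1, size=p)
    reg_code = np.empty(p, dtype=np.int64)
    reg_start = np.empty(p, dtype=np.int64)
    probs = lengths / lengths.sum()
    for i in range(p):
        for attempt in range(max_tries):
            code = rng.choice(len(lengths), p=probs)
            if lengths[code] >= reg_len[i]:
                reg_code[i] = code
                reg_start[i] = rng.integers(0, lengths[code] - reg_len[i] + 1)
                break
        else:
            raise ValueError(
                f"could not place a {reg_len[i]} bp region after "
                f"{max_tries} tries")
    counts = np.rint(rng.exponential(c * N2 / p, size=p)).astype(np.int64)
    reps = np.repeat(np.arange(p), counts)
    n = len(reps)
    pos = reg_start[reps] + np.floor(
        rng.random(n) * reg_len[reps]).astype(np.int64)
    signal = _tags(layout, reg_code[reps], pos, _random_strands(rng, n))
    chip = pd.concat([background_chip, signal], ignore_index=True)
    names = np.asarray(layout.names, dtype=object)[reg_code]
    regions = pd.DataFrame({"chrom": names, "start": reg_start,
                            "end": reg_start + reg_len, "count": counts})
    return chip, regions


def make_power_truth(layout: GenomeLayout, n_sites: int = 1000,
                     site_pool_size: int = 1572,
                     mean_strength: float = 200.0,
                     seed=0) -> pd.DataFrame:
    """Sample binding sites with Poisson-mean signal strengths.

    A synthetic pool of (location, strength) pairs stands in for a
    peak-caller-derived site catalogue: strengths are exponential with
    the given mean.  ``n_sites`` sites are sampled without replacement
    and each receives a Poisson(strength) read count.
    """
    if n_sites > site_pool_size:
        raise ValueError("n_sites cannot exceed the pool size")
    rng = _rng(seed)
    codes, pos = _uniform_genome_positions(layout, site_pool_size, rng)
    strengths = rng.exponential(mean_strength, size=site_pool_size)
    pick = rng.choice(site_pool_size, size=n_sites, replace=False)
    pick.sort()
    counts = rng.poisson(strengths[pick])
    names = np.asarray(layout.names, dtype=object)[codes[pick]]
    return pd.DataFrame({"chrom": names, "pos": pos[pick],
                         "strength": strengths[pick],
                         "count": counts.astype(np.int64),
                         "_code": codes[pick]})


def _thinned_depth(depth: int, d: int, rng: np.random.Generator) -> int:
    return int(rng.binomial(depth, 1.0 / d)) if d > 1 else int(depth)


def simulate(config: SimConfig, setting: str | int = 1) -> SimulatedDataset:
    """Generate one dataset under simulation setting 1, 2, 3 or 'power'.

    1: shared background + point-source signal in ChIP.
    2: setting 1 plus control-only artifacts.
    3: shared background + diffuse 5-15 kb domains in ChIP.
    power: Poisson-strength sites from a fixed pool, plus artifacts —
    the arrangement used for FDR/power evaluation of the peak caller.
    """
    setting = str(setting)
    if setting not in ("1", "2", "3", "power"):
        raise ValueError(f"unknown setting {setting!r}")
    rng = np.random.default_rng(config.seed)
    layout = config.genome
    d1 = _thinned_depth(config.background_depth, config.d, rng)
    d2 = _thinned_depth(config.background_depth, config.d, rng)
    chip_bg, control = synth_background(layout, d1, d2, config.roughness,
                                        config.window, rng)
    N2_bg = len(control)
    if setting in ("1", "2"):
        chip, sites = spike_point_sources(chip_bg, layout, config.p,
                                          config.c, N2_bg, config.sigma2, rng)
    elif setting == "3":
        chip, sites = spike_diffuse_regions(chip_bg, layout, config.p,
                                            config.c, N2_bg,
                                            config.region_len_range, rng)
    else:  # power
        sites = make_power_truth(layout, config.power_sites,
                                 config.power_pool,
                                 config.c * N2_bg / config.power_sites, rng)
        signal = _place_point_reads(layout, sites.pop("_code").to_numpy(),
                                    sites["pos"].to_numpy(),
                                    sites["count"].to_numpy(),
                                    config.sigma2, rng)
        chip = pd.concat([chip_bg, signal], ignore_index=True)
    n_artifact = 0
    if setting in ("2", "power"):
        before = len(control)
        control = add_control_artifacts(control, layout, config.artifact_k,
                                        config.artifact_frac,
                                        config.artifact_jitter, rng)
        n_artifact = len(control) - before
    n_signal = len(chip) - len(chip_bg)
    true_pi0 = len(chip_bg) / len(chip)
    true_r = true_pi0 * len(chip) / len(control)  # = n_background / N2
    return SimulatedDataset(
        chip=chip, control=control, true_r=true_r, true_pi0=true_pi0,
        true_sites=sites, setting=setting, seed=int(config.seed),
        n_background_chip=len(chip_bg), n_signal=n_signal,
        n_artifact=n_artifact, config=config)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write a dataset as tagAlign pairs, truth BED and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = ds.config.genome if ds.config else None
    if layout is None:
        raise ValueError("dataset carries no config/genome to write with")
    l = ds.config.l
    save_reads(tags_to_reads(ds.chip, l, layout), outdir / "chip.tagAlign")
    save_reads(tags_to_reads(ds.control, l, layout),
               outdir / "control.tagAlign")
    truth = ds.true_sites.copy()
    if "pos" in truth.columns:
        bed = pd.DataFrame({0: truth["chrom"], 1: truth["pos"],
                            2: truth["pos"] + 1})
    else:
        bed = pd.DataFrame({0: truth["chrom"], 1: truth["start"],
                            2: truth["end"]})
    bed[3] = [f"site_{i}" for i in range(len(truth))]
    bed[4] = truth["count"]
    bed[5] = "."
    bed.to_csv(outdir / "truth.bed", sep="\t", header=False, index=False)
    layout.to_chrom_sizes(outdir / "genome.chrom.sizes")
    manifest = {
        "setting": ds.setting, "seed": ds.seed,
        "true_r": ds.true_r, "true_pi0": ds.true_pi0,
        "N1": ds.N1, "N2": ds.N2,
        "n_background_chip": ds.n_background_chip,
        "n_signal": ds.n_signal, "n_artifact": ds.n_artifact,
        "fragment_length": l,
        "config": {
            "background_depth": ds.config.background_depth,
            "c": ds.config.c, "d": ds.config.d, "p": ds.config.p,
            "sigma2": ds.config.sigma2,
            "artifact_k": ds.config.artifact_k,
            "artifact_frac": ds.config.artifact_frac,
            "region_len_range": list(ds.config.region_len_range),
            "roughness": ds.config.roughness, "window": ds.config.window,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
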