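"""Synthetic pancreatic-juice cfDNA cohort generator.

Emulates the statistical structure the downstream analysis assumes, at
desk scale: a grade-labeled cohort (LGD/HGD/INC) of paired tumor/normal
exome pileups over a seeded synthetic reference, with

* grade-dependent somatic burden (negative binomial, calibrated so the
  distribution median matches the configured per-grade medians 16 / 19.5
  / 64),
* per-sample tumor purity (Beta-distributed; clonal heterozygous diploid
  events then show tumor VAF ~ purity * cellular_fraction / 2),
* segmental copy-number truth profiles including recurrent regions with
  grade-dependent prevalence plus random passenger segments, observed as
  Poisson tumor/normal bin counts with lognormal bin-level noise,
* optional 8-oxoguanine contamination (low-VAF C>A in CCN context) in a
  configurable subset of samples,
* occasional high-noise samples (bin-level noise SD inflated ~5x), the
  pathology the residual-variance QC screens for,
* off-target bins carrying noisier coverage, for the off-target filter.

Everything is driven by one integer seed; identical configuration yields
byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import nbinom
from scipy.optimize import brentq

from .cna import make_bins
from .intervals import TargetInterval, read_bed, write_bed
from .pileup import PileupSite, SamplePileup, read_pileup_tsv, write_pileup_tsv
from .reference import SyntheticReference, load_reference
from .stats import SampleRecord
from .vcfio import _header, atomic_allele, vcf_alleles

# consequence-class mix of nonsynonymous somatic calls in PJD exomes
CLASS_PROBS = {"missense": 0.8532, "frameshift_del": 0.0518,
               "nonsense": 0.0432, "frameshift_ins": 0.0259,
               "splice": 0.0173, "inframe_del": 0.0086}


@dataclass(frozen=True)
class CnaProfileSpec:
    """A recurrent copy-number event with per-grade prevalence."""

    name: str
    chrom: str
    start: int
    end: int
    log2: float  # observed (tumor-fraction-diluted) log2 shift
    prevalence: tuple[float, float, float]  # LGD, HGD, INC


def _default_profiles() -> list[CnaProfileSpec]:
    return [
        CnaProfileSpec("amp_7q21_like", "2", 100_000, 160_000, 0.6,
                       (0.14, 0.06, 0.64)),
        CnaProfileSpec("amp_8q24_like", "3", 200_000, 260_000, 0.6,
                       (0.29, 0.06, 0.55)),
        CnaProfileSpec("del_17p13_like", "5", 50_000, 110_000, -0.6,
                       (0.10, 0.20, 0.45)),
    ]


def _default_chroms() -> dict[str, int]:
    return {str(i): 500_000 for i in range(1, 7)}


@dataclass(frozen=True)
class CohortConfig:
    # cohort composition (study-scale defaults: 8 LGD / 20 HGD / 11 INC)
    n_samples_per_grade: tuple[int, int, int] = (8, 20, 11)
    burden_median_by_grade: tuple[float, float, float] = (16.0, 19.5, 64.0)
    burden_dispersion: float = 8.0  # negative-binomial size parameter
    purity_mean: float = 0.35
    purity_sd: float = 0.15
    depth_tumor: float = 200.0
    depth_normal: float = 100.0
    # reference / targets
    chrom_sizes: dict = field(default_factory=_default_chroms)
    target_length: int = 160
    target_spacing: int = 2000
    # copy number
    cna_profiles: tuple = field(
        default_factory=lambda: tuple(_default_profiles()))
    passenger_rate: float = 2.0  # mean passenger segments per sample
    mean_reads_per_bin: float = 500.0
    bin_log2_sd: float = 0.12
    noisy_sample_fraction: float = 4 / 39
    noise_inflation: float = 5.0
    offtarget_bin_fraction: float = 0.10
    offtarget_noise_factor: float = 2.5
    # OxoG contamination
    oxog_rate_by_sample: tuple | None = None  # explicit per-sample counts
    n_oxog_samples: int = 3
    oxog_sites_per_sample: int = 150
    oxog_vaf_mean: float = 0.05
    # pileup noise model
    n_null_sites: int = 200
    clonal_fraction: float = 0.7
    error_rate: float = 1e-3
    baseq_mean: float = 32.0
    baseq_sd: float = 4.0
    baseq_range: tuple = (2.0, 41.0)
    mapq_mean: float = 50.0
    mapq_sd: float = 8.0
    mapq_range: tuple = (0.0, 60.0)
    tp53_coupling: float = 0.8  # P(TP53-like mutation | del profile, INC)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_tumor <= 0 or self.depth_normal <= 0:
            raise ValueError("depths must be positive")
        if any(m < 0 for m in self.burden_median_by_grade):
            raise ValueError("burden medians must be non-negative")
        for r in (self.noisy_sample_fraction, self.offtarget_bin_fraction,
                  self.clonal_fraction, self.error_rate, self.purity_mean):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")
        if not self.chrom_sizes:
            raise ValueError("empty reference")


@dataclass
class TruthEvent:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str  # atomic allele
    ccf: float  # cancer cell fraction; nan for artifacts
    consequence: str
    artifact: bool = False
    gene: str | None = None


@dataclass
class TruthSet:
    events: dict  # sample_id -> list[TruthEvent]
    segments: dict  # sample_id -> DataFrame(chrom, start, end, log2, name)
    purity: dict  # sample_id -> float
    grade: dict  # sample_id -> int
    noisy: dict  # sample_id -> bool
    oxog: dict  # sample_id -> bool


@dataclass
class Cohort:
    config: CohortConfig
    reference: SyntheticReference
    targets: list
    bins: pd.DataFrame  # on-target + off-target bins, sorted
    samples: list  # list[SampleRecord]
    truth: TruthSet
    pileups: dict  # sample_id -> SamplePileup
    bin_counts: dict  # sample_id -> (tumor, normal) arrays aligned to bins

    @property
    def contigs(self) -> dict[str, int]:
        return {c: self.reference.length(c) for c in self.reference.chroms()}


def nb_mean_for_median(target_median: float, dispersion: float) -> float:
    """Negative-binomial mean whose distribution median hits the target."""
    if target_median <= 0:
        return 0.0
    k = int(np.floor(target_median))

    def f(mu):
        return nbinom.cdf(k, dispersion, dispersion / (dispersion + mu)) - 0.5

    lo, hi = max(target_median / 4, 1e-6), target_median * 4
    if f(lo) < 0 or f(hi) > 0:  # pathological dispersion; fall back
        return float(target_median)
    return float(brentq(f, lo, hi, xtol=1e-6))


def make_targets(config: CohortConfig) -> list[TargetInterval]:
    """Regularly spaced exon-like capture targets over every chromosome."""
    targets = []
    for chrom, size in config.chrom_sizes.items():
        for start in range(config.target_spacing // 2,
                           size - config.target_length,
                           config.target_spacing):
            targets.append(TargetInterval(chrom, start,
                                          start + config.target_length))
    targets.sort()
    return targets


def _trunc_normal(rng, mean, sd, lo, hi, size):
    return np.clip(rng.normal(mean, sd, size), lo, hi)


class _SiteFactory:
    """Shared read-level machinery for building pileup sites."""

    def __init__(self, config: CohortConfig, reference: SyntheticReference):
        self.cfg = config
        self.ref = reference

    def _quals(self, rng, n):
        c = self.cfg
        return (_trunc_normal(rng, c.baseq_mean, c.baseq_sd, *c.baseq_range,
                              size=n),
                _trunc_normal(rng, c.mapq_mean, c.mapq_sd, *c.mapq_range,
                              size=n))

    def _alleles_with_error(self, rng, n, ref):
        """n reads of ``ref`` subject to the symmetric substitution error."""
        alleles = np.full(n, ref, dtype=object)
        err = rng.random(n) < self.cfg.error_rate
        if err.any():
            others = [b for b in "ACGT" if b != ref]
            alleles[err] = rng.choice(others, size=int(err.sum()))
        return alleles

    def site(self, rng, chrom, pos, alt=None, p_alt_tumor=0.0,
             p_alt_normal=0.0) -> PileupSite:
        cfg = self.cfg
        ref = self.ref.base(chrom, pos)
        context = self.ref.context(chrom, pos)
        arrays = []
        for depth_mean, p_alt in ((cfg.depth_tumor, p_alt_tumor),
                                  (cfg.depth_normal, p_alt_normal)):
            depth = rng.poisson(depth_mean)
            n_alt = rng.binomial(depth, p_alt) if alt and p_alt > 0 else 0
            alleles = self._alleles_with_error(rng, depth - n_alt, ref)
            if n_alt:
                alleles = np.concatenate(
                    [np.full(n_alt, alt, dtype=object), alleles])
            order = rng.permutation(len(alleles))
            bq, mq = self._quals(rng, len(alleles))
            arrays.append((alleles[order], bq, mq))
        (ta, tb, tm), (na, nb, nm) = arrays
        return PileupSite(chrom, pos, ref, context, ta, tb, tm, na, nb, nm)


def _target_position_sampler(targets, reference):
    """Uniform sampler over target bases, mapped to (chrom, 1-based pos)."""
    lengths = np.array([len(t) for t in targets])
    cum = np.concatenate([[0], np.cumsum(lengths)])

    def sample(rng, n):
        offs = rng.choice(cum[-1], size=n, replace=False)
        idx = np.searchsorted(cum, offs, side="right") - 1
        out = []
        for o, i in zip(offs, idx):
            t = targets[i]
            out.append((t.chrom, int(t.start + (o - cum[i]) + 1)))
        return out

    return sample


def _draw_event(rng, factory, chrom, pos, purity, ccf, consequence,
                reference) -> tuple[TruthEvent, PileupSite] | None:
    ref = reference.base(chrom, pos)
    if consequence in ("frameshift_del", "inframe_del"):
        length = 3 if consequence == "inframe_del" else int(rng.integers(1, 3))
        if pos + length >= reference.length(chrom):
            return None
        seq = "".join(reference.base(chrom, pos + k)
                      for k in range(1, length + 1))
        alt = "D:" + seq
    elif consequence == "frameshift_ins":
        length = int(rng.integers(1, 3))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        alt = "I:" + seq
    else:
        alt = rng.choice([b for b in "ACGT" if b != ref])
    p_alt = purity * ccf / 2.0  # clonal het event on a diploid background
    site = factory.site(rng, chrom, pos, alt=alt, p_alt_tumor=p_alt)
    return TruthEvent(chrom, pos, ref, str(alt), ccf, consequence), site


def find_ccn_sites(reference: SyntheticReference,
                   targets: Sequence[TargetInterval]) -> list[tuple[str, int]]:
    """Target positions whose pyrimidine-strand context is 5'-CC(N)-3'.

    Returns 1-based positions with ref C preceded by C, or ref G followed
    by G (the reverse-complement reading of the same motif).
    """
    out = []
    for t in targets:
        seq = reference.sequences[t.chrom]
        for i in range(t.start, t.end):
            b = seq[i]
            if b == "C" and i > 0 and seq[i - 1] == "C":
                out.append((t.chrom, i + 1))
            elif b == "G" and i + 1 < len(seq) and seq[i + 1] == "G":
                out.append((t.chrom, i + 1))
    return out


def inject_oxog(pileup: SamplePileup, reference: SyntheticReference,
                ccn_sites: Sequence[tuple[str, int]], n_sites: int,
                rng: np.random.Generator, config: CohortConfig,
                truth_events: list | None = None) -> SamplePileup:
    """Add low-VAF C>A (G>T) artifact sites in CCN context to a pileup.

    Positions already present in the pileup are skipped; injected events
    are appended to ``truth_events`` flagged as artifacts. ``n_sites`` of
    0 leaves the pileup unchanged.
    """
    if n_sites == 0:
        return pileup
    if not ccn_sites:
        raise ValueError("no CCN-context sites available")
    factory = _SiteFactory(config, reference)
    occupied = {(s.chrom, s.pos) for s in pileup.sites}
    candidates = [c for c in ccn_sites if c not in occupied]
    chosen = rng.choice(len(candidates), size=min(n_sites, len(candidates)),
                        replace=False)
    m = config.oxog_vaf_mean
    a, b = m * 50, (1 - m) * 50  # Beta with mean m, sd ~ 0.03
    for k in sorted(int(i) for i in chosen):
        chrom, pos = candidates[k]
        ref = reference.base(chrom, pos)
        alt = "A" if ref == "C" else "T"
        vaf = float(rng.beta(a, b))
        site = factory.site(rng, chrom, pos, alt=alt, p_alt_tumor=vaf)
        pileup.sites.append(site)
        if truth_events is not None:
            truth_events.append(TruthEvent(chrom, pos, ref, alt, float("nan"),
                                           "unknown", artifact=True))
    pileup.sort()
    return pileup


def _off_target_bins(config, targets, rng) -> pd.DataFrame:
    from .cna import BIN_COLUMNS

    n_off = int(round(config.offtarget_bin_fraction * len(targets)))
    rows = []
    pick = rng.choice(len(targets) - 1, size=min(n_off, len(targets) - 1),
                      replace=False) if n_off else []
    for i in sorted(int(x) for x in pick):
        t, u = targets[i], targets[i + 1]
        if t.chrom != u.chrom or u.start - t.end < 700:
            continue
        mid = (t.end + u.start) // 2
        rows.append((t.chrom, mid - 250, mid + 250, False, False))
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def _sample_segments(rng, config, grade) -> pd.DataFrame:
    rows = []
    for prof in config.cna_profiles:
        if rng.random() < prof.prevalence[grade - 1]:
            rows.append((prof.chrom, prof.start, prof.end, prof.log2,
                         prof.name))
    n_pass = rng.poisson(config.passenger_rate)
    chroms = list(config.chrom_sizes)
    for _ in range(n_pass):
        chrom = rng.choice(chroms)
        size = config.chrom_sizes[chrom]
        length = int(rng.integers(30_000, 120_000))
        start = int(rng.integers(0, max(1, size - length)))
        shift = float(rng.uniform(0.3, 0.9) * rng.choice([-1, 1]))
        rows.append((chrom, start, start + length, shift,
                     f"passenger_{chrom}_{start}"))
    return pd.DataFrame(rows,
                        columns=["chrom", "start", "end", "log2", "name"])


def _bin_shifts(bins: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    shift = np.zeros(len(bins))
    chrom = bins["chrom"].to_numpy()
    mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    for r in segments.itertuples():
        shift[(chrom == r.chrom) & (mid >= r.start) & (mid < r.end)] += r.log2
    return shift


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full grade-labeled cohort; deterministic in the seed."""
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root)
    reference = SyntheticReference.generate(config.chrom_sizes,
                                            seed=root.spawn(1)[0])
    targets = make_targets(config)
    if not targets:
        raise ValueError("target set is empty")
    on_bins = make_bins(targets)
    off_bins = _off_target_bins(config, targets, rng)
    bins = pd.concat([on_bins, off_bins], ignore_index=True) \
        .sort_values(["chrom", "start"], kind="mergesort") \
        .reset_index(drop=True)

    n_by_grade = config.n_samples_per_grade
    grades = [g + 1 for g, n in enumerate(n_by_grade) for _ in range(n)]
    n_total = len(grades)
    sample_ids = [f"S{idx:02d}" for idx in range(n_total)]

    # which samples carry the contamination / noise pathologies
    if config.oxog_rate_by_sample is not None:
        oxog_counts = list(config.oxog_rate_by_sample)
        if len(oxog_counts) != n_total:
            raise ValueError("oxog_rate_by_sample length mismatch")
    else:
        oxog_counts = [0] * n_total
        n_ox = min(config.n_oxog_samples, n_total)
        if n_ox:
            for i in rng.choice(n_total, size=n_ox, replace=False):
                oxog_counts[int(i)] = config.oxog_sites_per_sample
    n_noisy = int(round(config.noisy_sample_fraction * n_total))
    noisy = np.zeros(n_total, bool)
    if n_noisy:
        noisy[rng.choice(n_total, size=n_noisy, replace=False)] = True

    # purity: Beta with the configured mean/sd
    v = config.purity_sd ** 2
    mu = config.purity_mean
    common = mu * (1 - mu) / v - 1
    a, b = mu * common, (1 - mu) * common
    purities = rng.beta(a, b, size=n_total)

    mu_by_grade = [nb_mean_for_median(m, config.burden_dispersion)
                   for m in config.burden_median_by_grade]
    factory = _SiteFactory(config, reference)
    sample_pos = _target_position_sampler(targets, reference)
    ccn_sites = find_ccn_sites(reference, targets) \
        if any(oxog_counts) else []
    class_names = list(CLASS_PROBS)
    class_p = np.array(list(CLASS_PROBS.values()))
    class_p = class_p / class_p.sum()

    samples, truth_events, truth_segments = [], {}, {}
    purity_map, grade_map, noisy_map, oxog_map = {}, {}, {}, {}
    pileups, bin_counts = {}, {}
    child_seeds = root.spawn(n_total)

    for i, sid in enumerate(sample_ids):
        srng = np.random.default_rng(child_seeds[i])
        grade = grades[i]
        purity = float(purities[i])
        mu_b = mu_by_grade[grade - 1]
        n_mut = int(srng.negative_binomial(
            config.burden_dispersion,
            config.burden_dispersion / (config.burden_dispersion + mu_b))) \
            if mu_b > 0 else 0

        events: list[TruthEvent] = []
        sites: list[PileupSite] = []
        n_positions = n_mut + config.n_null_sites
        positions = sample_pos(srng, n_positions) if n_positions else []
        segs = _sample_segments(srng, config, grade)
        has_del = (segs["name"] == "del_17p13_like").any() \
            if len(segs) else False

        for k, (chrom, pos) in enumerate(positions[:n_mut]):
            ccf = 1.0 if srng.random() < config.clonal_fraction \
                else float(srng.uniform(0.3, 1.0))
            consequence = str(srng.choice(class_names, p=class_p))
            drawn = _draw_event(srng, factory, chrom, pos, purity, ccf,
                                consequence, reference)
            if drawn is None:
                continue
            ev, site = drawn
            events.append(ev)
            sites.append(site)
        # TP53-like point mutation coupled to the 17p-like deletion in INC
        if grade == 3 and has_del and srng.random() < config.tp53_coupling \
                and events:
            events[0].gene = "TP53"
        for chrom, pos in positions[n_mut:]:
            sites.append(factory.site(srng, chrom, pos))

        pu = SamplePileup(sid, sites)
        pu.sort()
        if oxog_counts[i]:
            inject_oxog(pu, reference, ccn_sites, oxog_counts[i], srng,
                        config, truth_events=events)

        # copy-number observations
        shift = _bin_shifts(bins, segs)
        sd = config.bin_log2_sd * \
            (config.noise_inflation if noisy[i] else 1.0)
        eps = srng.normal(0.0, sd, size=len(bins))
        off = ~bins["on_target"].to_numpy()
        eps[off] += srng.normal(0.0, sd * config.offtarget_noise_factor,
                                size=int(off.sum()))
        mu_t = config.mean_reads_per_bin * 2.0 ** (shift + eps)
        tumor = srng.poisson(mu_t).astype(np.int64)
        normal = srng.poisson(config.mean_reads_per_bin,
                              size=len(bins)).astype(np.int64)

        events.sort(key=lambda e: (e.chrom, e.pos))
        samples.append(SampleRecord(sid, grade,
                                    sex=str(srng.choice(["M", "F"])),
                                    duct_type=str(srng.choice(
                                        ["branch", "main", "mix"]))))
        truth_events[sid] = events
        truth_segments[sid] = segs
        purity_map[sid] = purity
        grade_map[sid] = grade
        noisy_map[sid] = bool(noisy[i])
        oxog_map[sid] = oxog_counts[i] > 0
        pileups[sid] = pu
        bin_counts[sid] = (tumor, normal)

    truth = TruthSet(truth_events, truth_segments, purity_map, grade_map,
                     noisy_map, oxog_map)
    return Cohort(config, reference, targets, bins, samples, truth,
                  pileups, bin_counts)


def simulate_null_sites(n_sites: int, depth_tumor: float = 100.0,
                        depth_normal: float = 100.0, af: float = 0.5,
                        seed: int | None = None,
                        config: CohortConfig | None = None) -> SamplePileup:
    """Null pileups: identical allele distribution in tumor and normal.

    Models germline-heterozygous-like sites (shared allele fraction
    ``af``) with no somatic signal — the relevant null for the Fisher
    site test's type-I error.
    """
    cfg = config or CohortConfig(depth_tumor=depth_tumor,
                                 depth_normal=depth_normal)
    cfg = dataclasses.replace(cfg, depth_tumor=depth_tumor,
                              depth_normal=depth_normal)
    rng = np.random.default_rng(seed)
    ref_seq = SyntheticReference({"null": "ACA" * (n_sites + 2)})
    factory = _SiteFactory(cfg, ref_seq)
    sites = []
    for k in range(n_sites):
        pos = 3 * k + 2  # every middle C of the ACA repeats
        sites.append(factory.site(rng, "null", pos, alt="T",
                                  p_alt_tumor=af, p_alt_normal=af))
    return SamplePileup("null", sites)


def truth_annotation(events: Sequence[TruthEvent]) -> dict:
    """Annotation map (chrom, pos, alt) -> (consequence, gene) for
    :func:`pjflow.calling.annotate_calls`."""
    return {(e.chrom, e.pos, e.alt): (e.consequence, e.gene)
            for e in events}


def simulate_clonal_sample(n_events: int, purity: float,
                           seed: int | None = None,
                           depth_tumor: float = 200.0,
                           depth_normal: float = 100.0,
                           ccf: float = 1.0) -> SamplePileup:
    """One sample of clonal heterozygous diploid events at known purity.

    The expected tumor VAF at every event is ``purity * ccf / 2``; used
    for calibration and tumor-fraction recovery experiments.
    """
    cfg = CohortConfig(depth_tumor=depth_tumor, depth_normal=depth_normal,
                       chrom_sizes={"1": 40_000}, seed=0)
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    reference = SyntheticReference.generate(cfg.chrom_sizes,
                                            seed=root.spawn(1)[0])
    factory = _SiteFactory(cfg, reference)
    positions = 2 + 5 * np.arange(n_events)
    sites = []
    for pos in positions:
        ref = reference.base("1", int(pos))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sites.append(factory.site(rng, "1", int(pos), alt=alt,
                                  p_alt_tumor=purity * ccf / 2.0))
    return SamplePileup(f"purity_{purity:.2f}", sites)


def simulate_marker_cohort(n_samples: int, n_markers: int,
                           seed: int | None = None,
                           spike: tuple | None = None,
                           background_rate: float = 3.0,
                           background_amp: tuple = (0.3, 0.9)
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Segment-structured marker matrix for recurrence analyses.

    Each sample carries Poisson(``background_rate``) random constant
    segments of amplitude +-U(background_amp). ``spike`` =
    (start, length, amplitude, prevalence) plants a shared event in a
    random subset of samples. Returns (values (S, M), spiked-sample mask).
    """
    rng = np.random.default_rng(seed)
    X = np.zeros((n_samples, n_markers))
    for s in range(n_samples):
        for _ in range(rng.poisson(background_rate)):
            length = int(rng.integers(3, max(4, n_markers // 5)))
            start = int(rng.integers(0, max(1, n_markers - length)))
            amp = float(rng.uniform(*background_amp) * rng.choice([-1, 1]))
            X[s, start:start + length] += amp
    carriers = np.zeros(n_samples, bool)
    if spike is not None:
        start, length, amplitude, prevalence = spike
        n_carriers = int(round(prevalence * n_samples))
        carriers[rng.choice(n_samples, size=n_carriers, replace=False)] = True
        X[carriers, start:start + length] += amplitude
    return X, carriers


# ---------------------------------------------------------------------------
# fixture serialization


def write_truth_vcf(path, events: Sequence[TruthEvent],
                    contigs: dict[str, int]) -> None:
    h = _header(contigs)
    h.info.add("CCF", 1, "Float", "True cancer cell fraction")
    h.info.add("CLASS", 1, "String", "Consequence class label")
    h.info.add("ARTIFACT", 0, "Flag", "Injected OxoG artifact")
    h.info.add("GENE", 1, "String", "Gene label")
    with pysam.VariantFile(str(path), "w", header=h) as vf:
        for ev in sorted(events, key=lambda e: (e.chrom, e.pos)):
            ref, alt = vcf_alleles(ev.ref, ev.alt)
            rec = vf.new_record(contig=ev.chrom, start=ev.pos - 1,
                                alleles=(ref, alt))
            if not np.isnan(ev.ccf):
                rec.info["CCF"] = ev.ccf
            rec.info["CLASS"] = ev.consequence
            if ev.artifact:
                rec.info["ARTIFACT"] = True
            if ev.gene:
                rec.info["GENE"] = ev.gene
            vf.write(rec)


def read_truth_vcf(path) -> list[TruthEvent]:
    events = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = atomic_allele(rec.ref, rec.alts[0])
            ccf = float(rec.info["CCF"]) if "CCF" in rec.info \
                else float("nan")
            events.append(TruthEvent(
                rec.contig, rec.pos, rec.ref[0], alt, ccf,
                rec.info.get("CLASS", "unknown"),
                artifact=bool(rec.info.get("ARTIFACT", False)),
                gene=rec.info.get("GENE")))
    return events


def write_fixture(directory, cohort: Cohort) -> None:
    """Serialize a cohort as plain-text fixtures (BED/TSV/VCF/FASTA/JSON)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_bed(d / "targets.bed", cohort.targets)
    cohort.reference.to_fasta(d / "reference.fa")
    cohort.bins.to_csv(d / "bins.tsv", sep="\t", index=False)
    (d / "pileups").mkdir(exist_ok=True)
    (d / "truth").mkdir(exist_ok=True)
    (d / "bin_counts").mkdir(exist_ok=True)
    for sid, pu in cohort.pileups.items():
        write_pileup_tsv(d / "pileups" / f"{sid}.tsv", pu)
        write_truth_vcf(d / "truth" / f"{sid}.vcf",
                        cohort.truth.events[sid], cohort.contigs)
        t, n = cohort.bin_counts[sid]
        pd.DataFrame({"tumor": t, "normal": n}).to_csv(
            d / "bin_counts" / f"{sid}.tsv", sep="\t", index=False)
        cohort.truth.segments[sid].to_csv(
            d / "truth" / f"{sid}.segments.tsv", sep="\t", index=False,
            float_format="%.6g")
    sheet = pd.DataFrame(
        [(s.sample_id, s.grade_label, s.sex, s.duct_type,
          f"{cohort.truth.purity[s.sample_id]:.6g}",
          cohort.truth.noisy[s.sample_id], cohort.truth.oxog[s.sample_id])
         for s in cohort.samples],
        columns=["sample_id", "grade", "sex", "duct_type", "purity",
                 "noisy", "oxog"])
    sheet.to_csv(d / "samples.tsv", sep="\t", index=False)
    manifest = {"seed": cohort.config.seed,
                "config": _jsonable(dataclasses.asdict(cohort.config)),
                "n_samples": len(cohort.samples)}
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_fixture(directory) -> Cohort:
    """Round-trip reader for :func:`write_fixture` output."""
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = manifest["config"]
    cfg_dict["cna_profiles"] = tuple(
        CnaProfileSpec(**{**p, "prevalence": tuple(p["prevalence"])})
        for p in cfg_dict["cna_profiles"])
    for key in ("n_samples_per_grade", "burden_median_by_grade",
                "baseq_range", "mapq_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    if cfg_dict.get("oxog_rate_by_sample") is not None:
        cfg_dict["oxog_rate_by_sample"] = tuple(
            cfg_dict["oxog_rate_by_sample"])
    config = CohortConfig(**cfg_dict)
    reference = load_reference(d / "reference.fa")
    targets = read_bed(d / "targets.bed")
    bins = pd.read_csv(d / "bins.tsv", sep="\t", dtype={"chrom": str})
    sheet = pd.read_csv(d / "samples.tsv", sep="\t",
                        dtype={"sample_id": str, "grade": str})
    samples, pileups, bin_counts = [], {}, {}
    events, segments = {}, {}
    purity, grade, noisy, oxog = {}, {}, {}, {}
    from .stats import GRADE_CODES

    for r in sheet.itertuples():
        sid = r.sample_id
        samples.append(SampleRecord(sid, GRADE_CODES[r.grade], sex=r.sex,
                                    duct_type=r.duct_type))
        pileups[sid] = read_pileup_tsv(d / "pileups" / f"{sid}.tsv", sid)
        events[sid] = read_truth_vcf(d / "truth" / f"{sid}.vcf")
        segments[sid] = pd.read_csv(d / "truth" / f"{sid}.segments.tsv",
                                    sep="\t", dtype={"chrom": str})
        bc = pd.read_csv(d / "bin_counts" / f"{sid}.tsv", sep="\t")
        bin_counts[sid] = (bc["tumor"].to_numpy(np.int64),
                           bc["normal"].to_numpy(np.int64))
        purity[sid] = float(r.purity)
        grade[sid] = GRADE_CODES[r.grade]
        noisy[sid] = bool(r.noisy)
        oxog[sid] = bool(r.oxog)
    truth = TruthSet(events, segments, purity, grade, noisy, oxog)
    return Cohort(config, reference, targets, bins, samples, truth,
                  pileups, bin_counts)
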