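"""Synthetic genomes, diploid populations, pooled VCFs, and 2b-RAD tag sets.

The generator emulates the data structure of a pooled male/female
resequencing + 2b-RAD study of a species with an unknown genetic
sex-determination system:

* a multi-scaffold reference genome, one scaffold of which is sex-linked;
* planted, non-overlapping SNP and InDel differences fixed between the
  gametologs (X vs Y, or Z vs W) on that scaffold, plus background
  "autosomal" polymorphism on the remaining scaffolds;
* a diverged gametolog haplotype: the non-recombining Y (or W) additionally
  differs from its X (Z) partner at a background substitution rate, which is
  what gives the sex-limited chromosome enough private restriction tags to be
  detectable by tag-set algebra (divergence is kept >= 500 bp away from the
  planted focal sites so their marker regions stay clean);
* pooled allele depths per site: depth Poisson around ``depth_mean`` per
  pool, alt reads Binomial at the realised pool allele frequency perturbed by
  a sequencing error rate — so at a sex-linked site the homogametic pool is
  homozygous and the heterogametic pool sits near 1:1;
* site-quality annotations drawn from hard-filter-passing ranges, except a
  configurable fraction of sites given exactly one failing metric (recorded
  in the truth table, so filter behaviour is fully attributable).

Everything is a pure function of (inputs, seed): one global seed drives
independent per-stage generators derived by fixed stage keys, so stages can
be re-run in isolation.

The pooled VCF contains exactly the planted sites. The gametolog background
divergence feeds only the tag-based stage; a real experiment would see those
sites in its VCF too, but keeping the VCF equal to the planted-truth set
makes screen recovery exactly scoreable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dna import BASES, random_sequence
from .io_formats import FastaRecord, SampleCall, VcfRecord
from .poolscreen import INDEL_FILTERS, SNP_FILTERS
from .radtags import DigestConfig, TagSet, digest

_STAGE_REFERENCE = 11
_STAGE_INDIVIDUALS = 22
_STAGE_POOLS = 33
_STAGE_TAGS = 44

#: margin from scaffold ends and minimum spacing of sex-linked sites, bp;
#: leaves room for a 300-400 bp amplicon on either side of every focal site.
SITE_MARGIN = 500

_PASSING_RANGES = {
    "QD": (5.0, 35.0),
    "MQ": (50.0, 60.0),
    "FS": (0.0, 10.0),
    "SOR": (0.5, 2.5),
    "MQRankSum": (-2.0, 2.0),
    "ReadPosRankSum": (-2.0, 2.0),
}
_FAILING_RANGES = {
    "SNP": {
        "QD": (0.1, 1.9),
        "MQ": (20.0, 39.5),
        "FS": (61.0, 150.0),
        "SOR": (3.1, 8.0),
        "MQRankSum": (-20.0, -12.6),
        "ReadPosRankSum": (-15.0, -8.1),
    },
    "InDel": {
        "QD": (0.1, 1.9),
        "FS": (201.0, 300.0),
        "SOR": (10.1, 15.0),
        "MQRankSum": (-20.0, -12.6),
        "ReadPosRankSum": (-15.0, -8.1),
    },
}


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of one simulated study; see module docstring for semantics."""

    seed: int = 0
    system: str = "XX_XY"  # XX_XY | ZZ_ZW
    n_males: int = 5
    n_females: int = 5
    n_scaffolds: int = 5
    scaffold_length: int = 1_000_000
    sex_scaffold_index: int = 0
    n_sex_linked_snps: int = 60
    n_sex_linked_indels: int = 12
    n_autosomal_sites: int = 300
    indel_size_range: tuple[int, int] = (3, 12)
    depth_mean: float = 60.0  # per pool; the study design aimed for ~30-60x
    seq_error_rate: float = 0.002
    frac_filter_fail_sites: float = 0.05
    tag_dropout_rate: float = 0.0
    gametolog_divergence: float = 0.02

    def __post_init__(self) -> None:
        if self.system not in ("XX_XY", "ZZ_ZW"):
            raise ValueError(f"unknown system {self.system!r}")
        counts = (
            self.n_males, self.n_females, self.n_scaffolds,
            self.n_sex_linked_snps, self.n_sex_linked_indels,
            self.n_autosomal_sites,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not (0 <= self.sex_scaffold_index < self.n_scaffolds):
            raise ValueError("sex_scaffold_index out of range")
        for rate in (self.seq_error_rate, self.frac_filter_fail_sites,
                     self.tag_dropout_rate, self.gametolog_divergence):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.indel_size_range
        if not (1 <= lo <= hi):
            raise ValueError("indel_size_range must satisfy 1 <= lo <= hi")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "indel_size_range" in kwargs:
            kwargs["indel_size_range"] = tuple(kwargs["indel_size_range"])
        return cls(**kwargs)

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]

    @property
    def sex_scaffold(self) -> str:
        return self.scaffold_names[self.sex_scaffold_index]

    @property
    def heterogametic_sex(self) -> str:
        """The sex carrying the sex-limited (Y- or W-like) chromosome."""
        return "male" if self.system == "XX_XY" else "female"


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted variant (VCF-style left-anchored alleles).

    ``pos`` is 1-based. For sex-linked sites the gametolog (Y/W) haplotype
    carries ``alt``; ``pool_freq`` is the autosomal population alt frequency
    (None for sex-linked sites). ``fail_metric`` names the one hard-filter
    metric this site was assigned to fail, if any.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str  # SNP | InDel
    is_sex_linked: bool
    pool_freq: float | None = None
    fail_metric: str | None = None

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def gametolog_allele(self) -> str | None:
        return self.alt if self.is_sex_linked else None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class DiploidIndividual:
    """One simulated diploid: two per-scaffold haplotype sequences plus the
    per-site genotype that produced them (0 = ref allele, 1 = alt)."""

    id: str
    phenotypic_sex: str  # male | female
    haplotype_a: dict[str, str]
    haplotype_b: dict[str, str]
    genotypes: dict[tuple[str, int], tuple[int, int]]
    carries_gametolog: bool

    def haplotypes(self, chrom: str) -> tuple[str, str]:
        return self.haplotype_a[chrom], self.haplotype_b[chrom]


@dataclass
class SimTruth:
    """Everything needed to score downstream recovery."""

    sites: list[PlantedSite]
    scaffold_lengths: dict[str, int]
    individuals: list[DiploidIndividual] = field(default_factory=list)
    gametolog_substitutions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def sex_linked_sites(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.is_sex_linked]

    @property
    def autosomal_sites(self) -> list[PlantedSite]:
        return [s for s in self.sites if not s.is_sex_linked]


def _spaced_positions(
    rng: np.random.Generator, low: int, high: int, n: int, sep: int, context: str
) -> np.ndarray:
    """``n`` sorted positions in [low, high) with pairwise separation > sep."""
    if n == 0:
        return np.empty(0, dtype=np.intp)
    span = (high - low) - (n - 1) * sep
    if span < n:
        raise ValueError(
            f"scaffold too short for {n} {context} sites with spacing {sep}: "
            f"usable span {high - low} bp, needs >= {n + (n - 1) * sep} bp "
            f"(scaffold length >= {n + (n - 1) * sep + 2 * SITE_MARGIN})"
        )
    draws = np.sort(rng.choice(span, size=n, replace=False))
    return low + draws + np.arange(n) * sep


def simulate_reference(config: SimConfig) -> tuple[list[FastaRecord], SimTruth]:
    """Random scaffolds plus the planted-site truth (positions and alleles).

    Sex-linked sites go on the sex scaffold with >= 500 bp spacing and end
    margins (room for a 300-400 bp amplicon wholly free of other planted
    variants); autosomal SNPs are spread round-robin over the remaining
    scaffolds with spacing > the maximum indel size.
    """
    rng = _stage_rng(config.seed, _STAGE_REFERENCE)
    records = [
        FastaRecord(id=name, description=name,
                    sequence=random_sequence(config.scaffold_length, rng))
        for name in config.scaffold_names
    ]
    seq_by_name = {r.id: r.sequence for r in records}
    indel_max = config.indel_size_range[1]
    sites: list[PlantedSite] = []

    # --- sex-linked sites on the sex scaffold
    n_sex = config.n_sex_linked_snps + config.n_sex_linked_indels
    positions = _spaced_positions(
        rng, SITE_MARGIN, config.scaffold_length - SITE_MARGIN - indel_max - 1,
        n_sex, SITE_MARGIN, "sex-linked",
    )
    vtypes = np.array(
        ["SNP"] * config.n_sex_linked_snps + ["InDel"] * config.n_sex_linked_indels
    )
    rng.shuffle(vtypes)
    chrom = config.sex_scaffold
    for pos0, vtype in zip(positions, vtypes):
        ref, alt = _draw_alleles(rng, seq_by_name[chrom], int(pos0), vtype, config)
        sites.append(PlantedSite(
            chrom=chrom, pos=int(pos0) + 1, ref=ref, alt=alt, vtype=vtype,
            is_sex_linked=True,
            fail_metric=_draw_fail_metric(rng, vtype, config),
        ))

    # --- autosomal SNPs on the other scaffolds
    autosomes = [n for n in config.scaffold_names if n != config.sex_scaffold]
    if config.n_autosomal_sites > 0 and not autosomes:
        raise ValueError("autosomal sites require at least two scaffolds")
    per = np.zeros(len(autosomes), dtype=int)
    if autosomes:
        per += config.n_autosomal_sites // len(autosomes)
        per[: config.n_autosomal_sites % len(autosomes)] += 1
    for name, count in zip(autosomes, per):
        positions = _spaced_positions(
            rng, SITE_MARGIN, config.scaffold_length - SITE_MARGIN,
            int(count), indel_max, "autosomal",
        )
        for pos0 in positions:
            ref, alt = _draw_alleles(rng, seq_by_name[name], int(pos0), "SNP", config)
            sites.append(PlantedSite(
                chrom=name, pos=int(pos0) + 1, ref=ref, alt=alt, vtype="SNP",
                is_sex_linked=False,
                pool_freq=round(float(rng.uniform(0.05, 0.95)), 6),
                fail_metric=_draw_fail_metric(rng, "SNP", config),
            ))

    order = {name: i for i, name in enumerate(config.scaffold_names)}
    sites.sort(key=lambda s: (order[s.chrom], s.pos))
    truth = SimTruth(
        sites=sites,
        scaffold_lengths={r.id: len(r.sequence) for r in records},
    )
    return records, truth


def _draw_alleles(rng, sequence: str, pos0: int, vtype: str,
                  config: SimConfig) -> tuple[str, str]:
    anchor = sequence[pos0]
    if vtype == "SNP":
        others = [b for b in "ACGT" if b != anchor]
        return anchor, others[int(rng.integers(3))]
    size = int(rng.integers(config.indel_size_range[0],
                            config.indel_size_range[1] + 1))
    if rng.random() < 0.5:  # insertion on the alt allele
        inserted = rng.choice(BASES, size=size).tobytes().decode("ascii")
        return anchor, anchor + inserted
    return sequence[pos0 : pos0 + 1 + size], anchor  # deletion


def _draw_fail_metric(rng, vtype: str, config: SimConfig) -> str | None:
    if rng.random() >= config.frac_filter_fail_sites:
        return None
    rules = SNP_FILTERS if vtype == "SNP" else INDEL_FILTERS
    return rules[int(rng.integers(len(rules)))][0]


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

def _apply_edits(sequence: str, subs: Sequence[tuple[int, str]],
                 indels: Sequence[tuple[int, str, str]]) -> str:
    """Apply non-overlapping substitutions then left-anchored indel edits."""
    if not subs and not indels:
        return sequence
    if subs:
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
        pos = np.fromiter((p for p, _ in subs), dtype=np.intp, count=len(subs))
        alt = np.fromiter((ord(b) for _, b in subs), dtype=np.uint8, count=len(subs))
        arr[pos] = alt
        sequence = arr.tobytes().decode("ascii")
    if not indels:
        return sequence
    pieces = []
    cursor = 0
    for pos0, ref, alt in sorted(indels):
        pieces.append(sequence[cursor:pos0])
        pieces.append(alt)
        cursor = pos0 + len(ref)
    pieces.append(sequence[cursor:])
    return "".join(pieces)


def simulate_individuals(
    reference: Sequence[FastaRecord], truth: SimTruth, config: SimConfig
) -> list[DiploidIndividual]:
    """Diploid individuals with full haplotype sequences and genotypes.

    Under XX_XY every male carries one gametolog ("Y-like") haplotype on the
    sex scaffold — the alternate allele at every planted sex-linked site plus
    the shared background divergence substitutions — and every female is
    homozygous reference there; ZZ_ZW mirrors this. Autosomal genotypes are
    two independent Bernoulli draws at each site's population frequency.
    The gametolog haplotype is identical by descent across all carriers.
    """
    if config.n_males + config.n_females == 0:
        raise ValueError("need at least one individual")
    rng = _stage_rng(config.seed, _STAGE_INDIVIDUALS)
    ref_seq = {r.id: r.sequence for r in reference}
    sex_chrom = config.sex_scaffold

    truth.gametolog_substitutions = _draw_gametolog_substitutions(
        rng, ref_seq[sex_chrom], truth, config
    )
    sex_sites = truth.sex_linked_sites
    gametolog_seq = _apply_edits(
        ref_seq[sex_chrom],
        truth.gametolog_substitutions,
        [(s.pos0, s.ref, s.alt) for s in sex_sites],
    )

    auto_sites = truth.autosomal_sites
    individuals = []
    labels = [("M", "male")] * config.n_males + [("F", "female")] * config.n_females
    counter = {"male": 0, "female": 0}
    for prefix, sex in labels:
        counter[sex] += 1
        ind_id = f"{prefix}{counter[sex]}"
        carries = sex == config.heterogametic_sex
        hap_a = {}
        hap_b = {}
        genotypes = {}
        # sex scaffold: hap_a is always the shared homogametic chromosome
        hap_a[sex_chrom] = ref_seq[sex_chrom]
        hap_b[sex_chrom] = gametolog_seq if carries else ref_seq[sex_chrom]
        for site in sex_sites:
            genotypes[site.key] = (0, 1) if carries else (0, 0)
        # autosomes: per-site Bernoulli(pool_freq) on each haplotype
        edits_a: dict[str, list] = {}
        edits_b: dict[str, list] = {}
        for site in auto_sites:
            ga = int(rng.random() < site.pool_freq)
            gb = int(rng.random() < site.pool_freq)
            genotypes[site.key] = (ga, gb)
            if ga:
                edits_a.setdefault(site.chrom, []).append((site.pos0, site.alt))
            if gb:
                edits_b.setdefault(site.chrom, []).append((site.pos0, site.alt))
        for chrom, seq in ref_seq.items():
            if chrom == sex_chrom:
                continue
            hap_a[chrom] = _apply_edits(seq, edits_a.get(chrom, ()), ())
            hap_b[chrom] = _apply_edits(seq, edits_b.get(chrom, ()), ())
        individuals.append(DiploidIndividual(
            id=ind_id, phenotypic_sex=sex, haplotype_a=hap_a, haplotype_b=hap_b,
            genotypes=genotypes, carries_gametolog=carries,
        ))
    truth.individuals = individuals
    return individuals


def _draw_gametolog_substitutions(
    rng, sequence: str, truth: SimTruth, config: SimConfig
) -> list[tuple[int, str]]:
    """Background Y/W divergence, excluded within SITE_MARGIN of focal sites."""
    d = config.gametolog_divergence
    if d == 0:
        return []
    length = len(sequence)
    positions = np.nonzero(rng.random(length) < d)[0]
    if truth.sex_linked_sites:
        starts = np.array([s.pos0 - SITE_MARGIN for s in truth.sex_linked_sites])
        ends = np.array(
            [s.pos0 + len(s.ref) + SITE_MARGIN for s in truth.sex_linked_sites]
        )
        # a position is excluded when it falls inside any [start, end) zone
        idx = np.searchsorted(starts, positions, side="right") - 1
        in_zone = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        positions = positions[~in_zone]
    subs = []
    for pos0 in positions:
        base = sequence[pos0]
        others = [b for b in "ACGT" if b != base]
        subs.append((int(pos0), others[int(rng.integers(3))]))
    return subs


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------

def simulate_pools(
    individuals: Sequence[DiploidIndividual], truth: SimTruth, config: SimConfig
) -> list[VcfRecord]:
    """Pooled VCF records (samples MALES and FEMALES) for every planted site.

    Per pool and site: DP ~ Poisson(depth_mean); alt depth ~ Binomial(DP, f')
    with f' the pool allele frequency perturbed by the sequencing error
    rate. At sex-linked sites the pool frequency is the realised one (exact:
    0.5 in the heterogametic pool, 0 in the homogametic pool); at autosomal
    sites both pools are sampled at the site's population frequency, so the
    two pools are identical in expectation and autosomal screen false
    positives can arise only from read-sampling noise. Quality metrics are
    drawn from hard-filter-passing ranges, except at sites the truth marked
    to fail, which get that one metric drawn past its threshold.
    """
    rng = _stage_rng(config.seed, _STAGE_POOLS)
    males = [i for i in individuals if i.phenotypic_sex == "male"]
    females = [i for i in individuals if i.phenotypic_sex == "female"]
    records = []
    for site in truth.sites:
        per_sample = {}
        for name, pool in (("MALES", males), ("FEMALES", females)):
            if site.is_sex_linked:
                alleles = [g for ind in pool for g in ind.genotypes[site.key]]
                freq = sum(alleles) / len(alleles) if alleles else 0.0
            else:
                freq = site.pool_freq
            e = config.seq_error_rate
            freq_obs = freq * (1 - e) + (1 - freq) * e
            dp = int(rng.poisson(config.depth_mean))
            ad_alt = int(rng.binomial(dp, freq_obs)) if dp else 0
            per_sample[name] = SampleCall(ad=(dp - ad_alt, ad_alt), dp=dp)
        info = {}
        for metric, (lo, hi) in _PASSING_RANGES.items():
            if metric == "MQ" and site.vtype == "InDel":
                continue  # the InDel expression does not use MQ
            info[metric] = float(rng.uniform(lo, hi))
        if site.fail_metric is not None:
            lo, hi = _FAILING_RANGES[site.vtype][site.fail_metric]
            info[site.fail_metric] = float(rng.uniform(lo, hi))
        records.append(VcfRecord(
            chrom=site.chrom, pos=site.pos, ref=site.ref, alts=(site.alt,),
            qual=float(np.round(rng.uniform(100.0, 2000.0), 2)),
            filter_field=".", info=info, per_sample=per_sample,
        ))
    return records


# ---------------------------------------------------------------------------
# tag sets
# ---------------------------------------------------------------------------

def simulate_tag_sets(
    individuals: Sequence[DiploidIndividual],
    digest_config: DigestConfig = DigestConfig(),
    config: SimConfig = SimConfig(),
) -> list[TagSet]:
    """Per-individual tag sets: the union of in-silico digests of both
    haplotypes, with each tag independently dropped at ``tag_dropout_rate``.

    Digestion results are cached per haplotype sequence object, so shared
    chromosomes (the reference X of every individual, the identical-by-
    descent Y of every male) are digested once.
    """
    rng = _stage_rng(config.seed, _STAGE_TAGS)
    cache: dict[int, set[str]] = {}

    def digest_cached(chrom: str, seq: str) -> set[str]:
        key = id(seq)
        if key not in cache:
            cache[key] = digest(
                [FastaRecord(id=chrom, description=chrom, sequence=seq)],
                digest_config,
            )
        return cache[key]

    tag_sets = []
    for ind in individuals:
        tags: set[str] = set()
        for chrom in ind.haplotype_a:
            tags |= digest_cached(chrom, ind.haplotype_a[chrom])
            tags |= digest_cached(chrom, ind.haplotype_b[chrom])
        if config.tag_dropout_rate > 0:
            rate = config.tag_dropout_rate
            tags = {t for t in sorted(tags) if rng.random() >= rate}
        tag_sets.append(TagSet(individual_id=ind.id,
                               sex_label=ind.phenotypic_sex, tags=tags))
    return tag_sets


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype", "is_sex_linked",
                  "pool_freq", "fail_metric"]


def emit_truth_table(truth: SimTruth, path: str | os.PathLike) -> None:
    """Tab-separated planted-site table; round-trips via read_truth_table."""
    rows = [
        {
            "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
            "vtype": s.vtype, "is_sex_linked": int(s.is_sex_linked),
            "pool_freq": "." if s.pool_freq is None else f"{s.pool_freq:.6f}",
            "fail_metric": s.fail_metric or ".",
        }
        for s in truth.sites
    ]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | os.PathLike) -> list[PlantedSite]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sites = []
    for row in df.itertuples(index=False):
        sites.append(PlantedSite(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            vtype=row.vtype, is_sex_linked=bool(int(row.is_sex_linked)),
            pool_freq=None if row.pool_freq == "." else float(row.pool_freq),
            fail_metric=None if row.fail_metric == "." else row.fail_metric,
        ))
    return sites


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryScore:
    """Screen performance against the planted truth.

    Recall is computed over sex-linked sites that were NOT deliberately
    assigned a failing quality metric (those are planted to test the hard
    filter, not the screen); the false-positive rate is the fraction of all
    planted autosomal sites that passed.
    """

    n_sex_linked_clean: int
    n_recovered: int
    n_autosomal: int
    n_false_positive: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_sex_linked_clean

    @property
    def false_positive_rate(self) -> float:
        return self.n_false_positive / self.n_autosomal if self.n_autosomal else 0.0


def score_recovery(result, truth: SimTruth) -> RecoveryScore:
    """Compare a :class:`~sexlink.poolscreen.ScreenResult` with the truth."""
    passed = {(s.chrom, s.pos) for s in result.passed}
    clean = [s for s in truth.sex_linked_sites if s.fail_metric is None]
    autosomal = truth.autosomal_sites
    return RecoveryScore(
        n_sex_linked_clean=len(clean),
        n_recovered=sum(s.key in passed for s in clean),
        n_autosomal=len(autosomal),
        n_false_positive=sum(s.key in passed for s in autosomal),
    )


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    """One fully realised simulated study."""

    config: SimConfig
    reference: list[FastaRecord]
    truth: SimTruth
    individuals: list[DiploidIndividual]
    vcf_records: list[VcfRecord]
    tag_sets: list[TagSet] | None = None


def run_simulation(
    config: SimConfig,
    digest_config: DigestConfig = DigestConfig(),
    with_tags: bool = True,
) -> Simulation:
    """Run every stage in order on one seed."""
    reference, truth = simulate_reference(config)
    individuals = simulate_individuals(reference, truth, config)
    vcf_records = simulate_pools(individuals, truth, config)
    tag_sets = (
        simulate_tag_sets(individuals, digest_config, config) if with_tags else None
    )
    return Simulation(config=config, reference=reference, truth=truth,
                      individuals=individuals, vcf_records=vcf_records,
                      tag_sets=tag_sets)
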