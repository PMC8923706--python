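"""Hard filtering and sex-bias screening of a two-pool (male/female) VCF.

The screen operationalises the pooled-resequencing logic for finding
sex-linked variants under a male-heterogametic (XX/XY) model: at a Y-linked
site the female pool, carrying only X chromosomes, is homozygous (pooled
alt-allele frequency near 0 or 1), while the male pool, an equal mix of X and
Y chromosomes, is heterozygous with allele frequency near 1:1. The ZZ/ZW
model mirrors the roles. Before that test, sites must survive the standard
GATK-style hard filters:

    SNP:    QD < 2.0 || MQ < 40.0 || FS > 60.0 || SOR > 3.0
            || MQRankSum < -12.5 || ReadPosRankSum < -8.0
    InDel:  QD < 2.0 || FS > 200.0 || SOR > 10.0
            || MQRankSum < -12.5 || ReadPosRankSum < -8.0

A site fails if ANY applicable inequality holds; a metric missing at a site
fails nothing (rank-sum annotations are routinely absent and their absence is
not evidence of a bad call). Depth must be strictly greater than
``min_depth`` in EACH pool separately.

Every input site ends up exactly once in either the passed list or the
per-site fail-reason map; reasons follow a fixed precedence (multiallelic,
hard filter, male depth, female depth, homozygosity, heterozygosity) so the
tallies are deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

MALE_SAMPLE = "MALES"
FEMALE_SAMPLE = "FEMALES"

#: (metric, op, threshold) in the order the expressions are written; "lt"
#: fails when value < threshold, "gt" when value > threshold.
SNP_FILTERS = (
    ("QD", "lt", 2.0),
    ("MQ", "lt", 40.0),
    ("FS", "gt", 60.0),
    ("SOR", "gt", 3.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
)
INDEL_FILTERS = (
    ("QD", "lt", 2.0),
    ("FS", "gt", 200.0),
    ("SOR", "gt", 10.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
)


class ZeroInformativeReads(ValueError):
    """No ref or alt supporting reads in a pool; allele frequency undefined.

    Distinct from a depth failure: DP may be ample while all reads are
    uninformative for the two alleles.
    """


@dataclass(frozen=True)
class InfoMetrics:
    """Site-quality annotations; ``None`` means absent at this site."""

    QD: float | None = None
    MQ: float | None = None
    FS: float | None = None
    SOR: float | None = None
    MQRankSum: float | None = None
    ReadPosRankSum: float | None = None

    def __post_init__(self) -> None:
        if self.FS is not None and self.FS < 0:
            raise ValueError("FS must be >= 0")
        if self.SOR is not None and self.SOR < 0:
            raise ValueError("SOR must be >= 0")

    def get(self, name: str) -> float | None:
        return getattr(self, name)


@dataclass(frozen=True)
class PoolCounts:
    """Allele depths of one pool at one site; DP reconstructed as the AD sum
    when the VCF omits it."""

    ad_ref: int
    ad_alt: int
    dp: int

    def __post_init__(self) -> None:
        if min(self.ad_ref, self.ad_alt, self.dp) < 0:
            raise ValueError("negative depth")

    @classmethod
    def from_call(cls, ad: tuple[int, ...], dp: int | None) -> "PoolCounts":
        ad_ref, ad_alt = ad[0], ad[1]
        return cls(ad_ref, ad_alt, dp if dp is not None else ad_ref + ad_alt)


@dataclass(frozen=True)
class PoolSite:
    """A biallelic site with both pools' depths and its quality metrics."""

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    vtype: str  # SNP | InDel
    male: PoolCounts
    female: PoolCounts
    metrics: InfoMetrics = InfoMetrics()


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the sex-bias screen.

    ``min_depth`` is strict (``dp > min_depth``) in each pool, reading
    "greater than 30x" literally. ``hom_tol`` bounds how far from 0 (or 1)
    the homogametic pool's allele frequency may sit; ``het_tol`` bounds
    ``|AF - 0.5|`` in the heterogametic pool. The het default is calibrated
    to pooled binomial noise at ~60x: the AF of a true 1:1 site has standard
    deviation ~0.065 there, so a +-0.15 band (~2.3 sd) accepts >97% of true
    sites while still excluding a 3:1 ratio (AF 0.25/0.75).
    """

    min_depth: int = 30
    hom_tol: float = 0.05
    het_tol: float = 0.15
    model: str = "XX_XY"

    def __post_init__(self) -> None:
        if not (0 <= self.hom_tol < 0.5 and 0 <= self.het_tol < 0.5):
            raise ValueError("tolerances must lie in [0, 0.5)")
        if self.model not in ("XX_XY", "ZZ_ZW"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class ScreenResult:
    """Partition of the input sites into passed sites and fail reasons."""

    passed: list[PoolSite] = field(default_factory=list)
    reasons: dict[tuple[str, int], str] = field(default_factory=dict)
    config: ScreenConfig = ScreenConfig()

    @property
    def reason_counts(self) -> Counter:
        return Counter(self.reasons.values())

    @property
    def n_input(self) -> int:
        return len(self.passed) + len(self.reasons)


def classify_variant(ref: str, alts: Sequence[str]) -> str:
    """SNP for a 1-bp substitution, InDel for a length change; multiallelic
    records are rejected (the screen is biallelic by construction)."""
    if len(alts) != 1:
        return "multiallelic"
    alt = alts[0]
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r})")
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    return "InDel"


def hard_filter(site: PoolSite) -> str | None:
    """None when the site passes; otherwise the first failing metric name.

    OR semantics over the applicable expression (SNP vs InDel); missing
    metrics never fail.
    """
    rules = SNP_FILTERS if site.vtype == "SNP" else INDEL_FILTERS
    for name, op, threshold in rules:
        value = site.metrics.get(name)
        if value is None:
            continue
        if (op == "lt" and value < threshold) or (op == "gt" and value > threshold):
            return name
    return None


def allele_frequency(counts: PoolCounts) -> float:
    """Pooled alt-allele frequency ad_alt / (ad_ref + ad_alt)."""
    informative = counts.ad_ref + counts.ad_alt
    if informative == 0:
        raise ZeroInformativeReads("no ref/alt reads at site")
    return counts.ad_alt / informative


def sex_bias_screen(site: PoolSite, config: ScreenConfig = ScreenConfig()) -> str | None:
    """None when the site shows the sex-linked pool pattern; else a reason.

    Under XX_XY the female pool must be homozygous (AF <= hom_tol or
    >= 1 - hom_tol — the reference may carry either gametolog allele) and the
    male pool heterozygous near 1:1; ZZ_ZW mirrors the roles. Depth is
    checked per pool first (male, then female, for deterministic tallies).
    A pool with zero informative reads fails its zygosity condition.
    """
    if site.male.dp <= config.min_depth:
        return "depth_male"
    if site.female.dp <= config.min_depth:
        return "depth_female"
    hom_counts, het_counts = (
        (site.female, site.male)
        if config.model == "XX_XY"
        else (site.male, site.female)
    )
    try:
        hom_af = allele_frequency(hom_counts)
    except ZeroInformativeReads:
        return "hom_fail"
    if not (hom_af <= config.hom_tol or hom_af >= 1 - config.hom_tol):
        return "hom_fail"
    try:
        het_af = allele_frequency(het_counts)
    except ZeroInformativeReads:
        return "het_fail"
    if abs(het_af - 0.5) > config.het_tol:
        return "het_fail"
    # Guard kept for future multiallelic support: the allele the homogametic
    # pool is fixed for must be one of the two site alleles. Trivially true
    # for biallelic sites.
    fixed_allele = site.alt if hom_af >= 0.5 else site.ref
    if fixed_allele not in (site.ref, site.alt):
        return "allele_inconsistency"
    return None


def site_from_record(record, male_sample: str = MALE_SAMPLE,
                     female_sample: str = FEMALE_SAMPLE) -> PoolSite:
    """Build a biallelic PoolSite from a VcfRecord (which must be usable)."""
    metrics = InfoMetrics(**{k: record.metric(k) for k in InfoMetrics.__annotations__})
    male = PoolCounts.from_call(
        record.per_sample[male_sample].ad, record.per_sample[male_sample].dp
    )
    female = PoolCounts.from_call(
        record.per_sample[female_sample].ad, record.per_sample[female_sample].dp
    )
    return PoolSite(
        chrom=record.chrom,
        pos=record.pos,
        ref=record.ref,
        alt=record.alts[0],
        vtype=classify_variant(record.ref, record.alts),
        male=male,
        female=female,
        metrics=metrics,
    )


def run_screen(
    records: Iterable,
    config: ScreenConfig = ScreenConfig(),
    male_sample: str = MALE_SAMPLE,
    female_sample: str = FEMALE_SAMPLE,
) -> ScreenResult:
    """classify -> hard filter -> sex-bias screen over VCF records, in order.

    Multiallelic or AD/DP-less records fail with reasons ``multiallelic`` /
    ``unusable`` rather than being dropped, so the partition property
    ``len(passed) + len(reasons) == n input`` always holds.
    """
    result = ScreenResult(config=config)
    for record in records:
        key = (record.chrom, record.pos)
        if record.multiallelic:
            result.reasons[key] = "multiallelic"
            continue
        if not record.usable_for([male_sample, female_sample]):
            result.reasons[key] = "unusable"
            continue
        site = site_from_record(record, male_sample, female_sample)
        failing_metric = hard_filter(site)
        if failing_metric is not None:
            result.reasons[key] = f"hard_filter:{failing_metric}"
            continue
        reason = sex_bias_screen(site, config)
        if reason is not None:
            result.reasons[key] = reason
            continue
        result.passed.append(site)
    return result


def scaffold_summary(result: ScreenResult) -> list[tuple[str, int, float]]:
    """Passed-site counts per scaffold, descending (ties by scaffold name).

    A sharp concentration of passed sites on one scaffold marks it as the
    sex-linked candidate region. Fractions sum to 1 when any site passed.
    """
    counts = Counter(site.chrom for site in result.passed)
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(chrom, n, n / total) for chrom, n in ordered]
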