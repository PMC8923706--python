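"""Allele-specific InDel PCR sex markers: design constraints, in-silico
amplification, and discrimination-rate scoring.

A sex-linked InDel where the homogametic sex is fixed and the heterogametic
sex is heterozygous supports a dominant presence/absence marker: one primer
of the pair is placed so that it overlaps the InDel itself and therefore
binds (with its 3' end intact) only on the sex-limited haplotype. PCR then
produces a product in the 300-400 bp window from heterogametic individuals
only. This module selects such candidates from the screen output, builds the
two local haplotype sequences, checks the primer-overlap constraint,
simulates the amplification, and scores predicted against phenotypic sex
with an exact binomial confidence interval.

Thermodynamic primer optimisation (melting temperature, GC, hairpins) is out
of scope — a practitioner hands the exported region to a primer-design tool;
here only placement and allele specificity are modelled. The in-silico
stringency model is: at most ``max_mismatch`` mismatches per primer, and the
3'-terminal ``three_prime_exact`` bases must match exactly (a 3' mismatch
aborts extension).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binomtest

from .dna import as_bytes, revcomp
from .poolscreen import PoolSite, ScreenResult, allele_frequency


@dataclass(frozen=True)
class PrimerPair:
    """A primer pair (both 5'→3') with its expected product-size window."""

    name: str
    fwd: str
    rev: str
    min_product: int = 300
    max_product: int = 400

    def __post_init__(self) -> None:
        if min(len(self.fwd), len(self.rev)) < 15:
            raise ValueError("primers must be >= 15 nt")
        if not (0 < self.min_product <= self.max_product):
            raise ValueError("need 0 < min_product <= max_product")


@dataclass(frozen=True)
class Amplicon:
    """One predicted product on the + strand of a template: ``start`` is the
    forward primer's 5' position, ``end`` the reverse primer's 5' position."""

    start: int
    end: int
    fwd_interval: tuple[int, int]
    rev_interval: tuple[int, int]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MarkerCandidate:
    """A sex-biased InDel with its local haplotype pair.

    ``region`` is the reference window around the site; ``hap_hom`` carries
    the allele the homogametic sex is fixed for, ``hap_gametolog`` the
    sex-limited allele. ``indel_interval`` is the divergent span (anchored
    REF allele span) in region coordinates; ``indel_interval_gametolog`` is
    the corresponding span on ``hap_gametolog``, which is where the
    overlapping primer must bind. All intervals 0-based half-open.
    """

    site: PoolSite
    chrom: str
    region_start: int  # 0-based offset of region on the scaffold
    region: str
    hap_hom: str
    hap_gametolog: str
    indel_interval: tuple[int, int]
    indel_interval_gametolog: tuple[int, int]
    gametolog_is_alt: bool


@dataclass(frozen=True)
class PredictionRecord:
    """Marker outcome for one individual."""

    individual_id: str
    phenotypic_sex: str
    band_present: bool
    predicted_sex: str
    amplified: bool = True  # False models a whole-PCR failure for that DNA

    @property
    def concordant(self) -> bool:
        return self.amplified and self.predicted_sex == self.phenotypic_sex


@dataclass(frozen=True)
class ValidationResult:
    """Discrimination-rate summary with an exact (Clopper-Pearson) 95% CI."""

    records: tuple[PredictionRecord, ...]
    n_correct: int
    n_total: int
    rate: float  # fraction in [0, 1]
    ci95: tuple[float, float]

    @property
    def rate_percent(self) -> float:
        """Rate as a percentage rounded to 2 decimals (e.g. 99.49)."""
        return round(100.0 * self.rate, 2)

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"sex discrimination rate {self.rate_percent:.2f}% "
            f"({self.n_correct}/{self.n_total}), "
            f"exact 95% CI [{100 * lo:.2f}%, {100 * hi:.2f}%]"
        )


def select_indel_candidates(result: ScreenResult) -> list[PoolSite]:
    """Passed InDel sites, largest length difference first (ties by locus)."""
    indels = [s for s in result.passed if s.vtype == "InDel"]
    indels.sort(key=lambda s: (-abs(len(s.ref) - len(s.alt)), s.chrom, s.pos))
    return indels


def build_candidate(site: PoolSite, reference, window: int = 500) -> MarkerCandidate:
    """Construct both marker haplotypes around an InDel site.

    The sex-limited allele is taken to be the one the homogametic pool is
    NOT fixed for (the reference assembly may carry either gametolog
    allele). The window must fit inside the scaffold.
    """
    seq = reference.sequence if hasattr(reference, "sequence") else reference
    pos0 = site.pos - 1
    start = pos0 - window
    end = pos0 + len(site.ref) + window
    if start < 0 or end > len(seq):
        raise ValueError(
            f"window {window} around {site.chrom}:{site.pos} truncated by "
            f"scaffold end (scaffold length {len(seq)})"
        )
    region = seq[start:end]
    local = pos0 - start
    ref_span = (local, local + len(site.ref))
    assert region[ref_span[0]:ref_span[1]] == site.ref, "reference/site mismatch"
    with_alt = region[: ref_span[0]] + site.alt + region[ref_span[1] :]
    alt_span = (local, local + len(site.alt))
    hom_af = allele_frequency(site.female)  # meaningful for either model:
    # the homogametic pool is the one near fixation; if the female pool is
    # heterozygous this site came from a ZZ_ZW screen and the male pool is
    # the fixed one.
    if abs(hom_af - 0.5) <= 0.25:
        hom_af = allele_frequency(site.male)
    gametolog_is_alt = hom_af < 0.5  # hom sex fixed for ref -> sex-limited allele is alt
    if gametolog_is_alt:
        hap_hom, hap_g = region, with_alt
        hom_span, g_span = ref_span, alt_span
    else:
        hap_hom, hap_g = with_alt, region
        hom_span, g_span = alt_span, ref_span
    return MarkerCandidate(
        site=site, chrom=site.chrom, region_start=start, region=region,
        hap_hom=hap_hom, hap_gametolog=hap_g,
        indel_interval=hom_span, indel_interval_gametolog=g_span,
        gametolog_is_alt=gametolog_is_alt,
    )


def _find_binding(template: str, primer: str) -> tuple[int, int] | None:
    """Leftmost exact binding interval of a forward-orientation primer."""
    hit = template.find(primer)
    return None if hit < 0 else (hit, hit + len(primer))


def primer_overlaps_indel(pair: PrimerPair, candidate: MarkerCandidate) -> tuple[bool, bool]:
    """Whether each primer's binding site on the gametolog haplotype overlaps
    the InDel interval (half-open intersection).

    The forward primer is searched on the + strand, the reverse primer on the
    - strand. A primer not found on the gametolog haplotype is reported as
    non-overlapping (it does not bind), not as an error.
    """
    lo, hi = candidate.indel_interval_gametolog

    def overlaps(interval: tuple[int, int] | None) -> bool:
        return interval is not None and interval[0] < hi and lo < interval[1]

    fwd_site = _find_binding(candidate.hap_gametolog, pair.fwd)
    rev_site = _find_binding(candidate.hap_gametolog, revcomp(pair.rev))
    return overlaps(fwd_site), overlaps(rev_site)


def _match_positions(template: str, primer: str, max_mismatch: int,
                     three_prime_exact: int) -> list[int]:
    """Start positions where ``primer`` (given in template orientation)
    anneals: <= ``max_mismatch`` mismatches overall, 0 in the 3'-terminal
    ``three_prime_exact`` bases (the primer's right end in this orientation).
    """
    k = len(primer)
    if len(template) < k:
        return []
    if max_mismatch == 0:
        hits, start = [], 0
        while (hit := template.find(primer, start)) >= 0:
            hits.append(hit)
            start = hit + 1
        return hits
    t = as_bytes(template)
    p = as_bytes(primer)
    n_windows = t.size - k + 1
    mismatches = np.zeros(n_windows, dtype=np.int32)
    tail = np.zeros(n_windows, dtype=np.int32)
    tail_start = k - min(three_prime_exact, k)
    for j in range(k):
        diff = t[j : j + n_windows] != p[j]
        mismatches += diff
        if j >= tail_start:
            tail += diff
    return np.nonzero((mismatches <= max_mismatch) & (tail == 0))[0].tolist()


def in_silico_pcr(
    template: str,
    pair: PrimerPair,
    max_mismatch: int = 0,
    three_prime_exact: int = 5,
) -> list[Amplicon]:
    """All products of ``pair`` on ``template`` within the product window.

    The forward primer must anneal on the + strand and the reverse primer on
    the - strand downstream of it; the product spans the forward primer's 5'
    end through the reverse primer's 5' end. Results are sorted by start.
    """
    fwd_hits = _match_positions(template, pair.fwd, max_mismatch, three_prime_exact)
    rev_starts = _match_rev(template, pair.rev, max_mismatch, three_prime_exact)
    amplicons = []
    for f in fwd_hits:
        for r in rev_starts:
            end = r + len(pair.rev)
            length = end - f
            if pair.min_product <= length <= pair.max_product:
                amplicons.append(Amplicon(
                    start=f, end=end,
                    fwd_interval=(f, f + len(pair.fwd)),
                    rev_interval=(r, end),
                ))
    amplicons.sort(key=lambda a: (a.start, a.end))
    return amplicons


def _match_rev(template: str, rev_primer: str, max_mismatch: int,
               three_prime_exact: int) -> list[int]:
    """Start positions (on +) of the reverse primer's binding site.

    In template orientation the annealed sequence is revcomp(rev_primer) and
    the primer's 3' terminus sits at the LEFT end of that window, so the
    exact-match tail is the window's first bases; flipping both strings
    reuses the right-tail matcher.
    """
    rc = revcomp(rev_primer)
    flipped = _match_positions(template[::-1], rc[::-1], max_mismatch,
                               three_prime_exact)
    k = len(rc)
    n = len(template)
    return sorted(n - k - s for s in flipped)


def design_overlap_primers(
    candidate: MarkerCandidate,
    name: str = "marker",
    primer_len: int = 24,
    product_len: int = 350,
    min_product: int = 300,
    max_product: int = 400,
    three_prime_exact: int = 5,
) -> PrimerPair:
    """Design a primer pair whose forward primer overlaps the InDel.

    The forward primer is read off the gametolog haplotype with its 3' end a
    few bases past the divergent interval, so its 3'-exact window spans the
    allele junction and it cannot prime on the homogametic haplotype; the
    reverse primer is placed to give a ~``product_len`` bp product. Several
    3'-end offsets are tried and the design is verified in silico (product on
    the gametolog haplotype, none on the homogametic one) before being
    returned; failure to verify raises ``ValueError``.
    """
    hap_g, hap_h = candidate.hap_gametolog, candidate.hap_hom
    lo, hi = candidate.indel_interval_gametolog
    for offset in (3, 4, 5, 6, 8, 10):
        end3 = hi + offset
        start = end3 - primer_len
        if start >= hi:  # primer would no longer overlap the indel interval
            break
        if start < 0 or start + product_len > len(hap_g):
            continue
        fwd = hap_g[start:end3]
        rev_window = hap_g[start + product_len - primer_len : start + product_len]
        pair = PrimerPair(name=name, fwd=fwd, rev=revcomp(rev_window),
                          min_product=min_product, max_product=max_product)
        fwd_overlap, _ = primer_overlaps_indel(pair, candidate)
        if not fwd_overlap:
            continue
        on_g = in_silico_pcr(hap_g, pair, 0, three_prime_exact)
        on_h = in_silico_pcr(hap_h, pair, 0, three_prime_exact)
        if len(on_g) >= 1 and not on_h:
            return pair
    raise ValueError(
        f"could not design a verified overlap primer pair for "
        f"{candidate.chrom}:{candidate.site.pos}"
    )


def predict_band(individual, pair: PrimerPair, chrom: str,
                 max_mismatch: int = 0, three_prime_exact: int = 5) -> bool:
    """Dominant-marker band call: True iff either haplotype of ``individual``
    on ``chrom`` yields at least one in-window product."""
    try:
        hap_a, hap_b = individual.haplotypes(chrom)
    except KeyError as exc:
        raise ValueError(f"individual {individual.id} has no sequence for "
                         f"{chrom}") from exc
    return any(
        in_silico_pcr(h, pair, max_mismatch, three_prime_exact)
        for h in (hap_a, hap_b)
    )


def assign_sex(band_present: bool, model: str) -> str:
    """Band semantics: under XX_XY the band marks the Y, so band -> male;
    under ZZ_ZW the band marks the W, so band -> female."""
    if model == "XX_XY":
        return "male" if band_present else "female"
    if model == "ZZ_ZW":
        return "female" if band_present else "male"
    raise ValueError(f"unknown model {model!r}")


def validate_marker(
    individuals: Iterable, pair: PrimerPair, chrom: str, model: str,
    max_mismatch: int = 0, three_prime_exact: int = 5,
) -> ValidationResult:
    """Score a marker across individuals with known phenotypic sex."""
    records = []
    for ind in individuals:
        band = predict_band(ind, pair, chrom, max_mismatch, three_prime_exact)
        records.append(PredictionRecord(
            individual_id=ind.id, phenotypic_sex=ind.phenotypic_sex,
            band_present=band, predicted_sex=assign_sex(band, model),
        ))
    return discrimination_rate(records)


def discrimination_rate(records: Sequence[PredictionRecord]) -> ValidationResult:
    """Concordance rate with exact binomial CI; individuals whose PCR failed
    outright count in the denominator as non-concordant."""
    records = tuple(records)
    if not records:
        raise ValueError("discrimination_rate needs at least one individual")
    n_correct = sum(r.concordant for r in records)
    return _result_from_counts(records, n_correct, len(records))


def discrimination_rate_from_counts(n_correct: int, n_total: int) -> ValidationResult:
    """Summary from bare counts (e.g. a published field-validation tally)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total")
    return _result_from_counts((), n_correct, n_total)


def _result_from_counts(records, n_correct: int, n_total: int) -> ValidationResult:
    ci = binomtest(n_correct, n_total).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return ValidationResult(
        records=tuple(records), n_correct=n_correct, n_total=n_total,
        rate=n_correct / n_total, ci95=(float(ci.low), float(ci.high)),
    )
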