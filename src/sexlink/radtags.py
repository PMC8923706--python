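"""In-silico type-IIB restriction digestion and tag-set sex-system inference.

A type IIB enzyme such as BsaXI recognises a degenerate internal motif
(default ``ACNNNNNCTCC``) and excises a uniform-length fragment around it;
sequencing those fragments (2b-RAD) yields one fixed-length, strand-specific
tag per recognition site per chromosome. Because the heterogametic sex
carries sequence the homogametic sex lacks, tags present in every male but no
female point to a Y chromosome (XX/XY system), and the mirror image points to
a W (ZZ/ZW). This module scans sequences for the motif, extracts tags,
performs the intersection/difference set algebra over per-individual tag
sets, and applies that decision rule.

Tags are exact-match strings: no error tolerance, no canonicalisation by
default (tags are strand-specific, as sequenced). ``N`` bases in a genome
never match any motif position, including the degenerate ones, so assembly
gaps produce no phantom tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dna import as_bytes, revcomp

_ACGT_CODES = frozenset(b"ACGT")


@dataclass(frozen=True)
class DigestConfig:
    """Geometry of the in-silico digestion.

    The emitted tag is ``flank`` bases, the motif match, then ``flank`` bases
    (``2*flank + len(motif) == tag_length``); the true double-sided cleavage
    chemistry of the enzyme is not modelled, only the resulting uniform tag
    length. ``canonicalize`` folds each tag onto the lexicographic minimum of
    itself and its reverse complement; it is off by default because 2b-RAD
    reads are strand-specific.
    """

    motif: str = "ACNNNNNCTCC"
    tag_length: int = 27
    flank: int = 8
    both_strands: bool = True
    canonicalize: bool = False

    def __post_init__(self) -> None:
        if set(self.motif) - set("ACGTN"):
            raise ValueError(f"motif may contain only ACGTN: {self.motif!r}")
        if 2 * self.flank + len(self.motif) != self.tag_length:
            raise ValueError(
                f"2*flank + motif length must equal tag_length "
                f"({2 * self.flank} + {len(self.motif)} != {self.tag_length})"
            )


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif match: ``start`` is the leftmost base of the match on the
    forward strand of the stored sequence, 0-based, for either strand."""

    chrom: str
    start: int
    strand: str  # "+" or "-"


@dataclass
class TagSet:
    """Deduplicated fixed-length tags for one individual, with its sex label."""

    individual_id: str
    sex_label: str  # male | female | unknown
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.sex_label not in ("male", "female", "unknown"):
            raise ValueError(f"bad sex label {self.sex_label!r}")
        lengths = {len(t) for t in self.tags}
        if len(lengths) > 1:
            raise ValueError(f"tags of mixed lengths {sorted(lengths)} in one set")

    def __len__(self) -> int:
        return len(self.tags)


@dataclass(frozen=True)
class SexSystemCall:
    """Outcome of the XX/XY-vs-ZZ/ZW decision rule with its supporting counts."""

    system: str  # XX_XY | ZZ_ZW | inconclusive
    male_exclusive_count: int
    female_exclusive_count: int
    min_exclusive: int
    max_minor_ratio: float


def _scan_pattern(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Start positions of all matches of a degenerate pattern (vectorised).

    Fixed pattern positions require equality; ``N`` positions match any of
    A/C/G/T (never an ``N`` in the sequence).
    """
    m = len(pattern)
    n = codes.size
    if n < m:
        return np.empty(0, dtype=np.intp)
    mask = np.ones(n - m + 1, dtype=bool)
    for offset, base in enumerate(pattern):
        window = codes[offset : n - m + 1 + offset]
        if base == "N":
            ok = (window == ord("A")) | (window == ord("C"))
            ok |= (window == ord("G")) | (window == ord("T"))
            mask &= ok
        else:
            mask &= window == ord(base)
    return np.nonzero(mask)[0]


def find_motif_sites(record, config: DigestConfig = DigestConfig()) -> list[MotifHit]:
    """All (possibly overlapping) motif matches in a FASTA record.

    Forward-strand matches are reported with strand ``+``. When
    ``both_strands`` is set, matches of the motif's reverse complement are
    reported with strand ``-`` and the leftmost coordinate of the match on
    the stored sequence. Hits are sorted by start, then strand.
    """
    codes = as_bytes(record.sequence)
    hits = [
        MotifHit(record.id, int(s), "+")
        for s in _scan_pattern(codes, config.motif)
    ]
    if config.both_strands:
        hits.extend(
            MotifHit(record.id, int(s), "-")
            for s in _scan_pattern(codes, revcomp(config.motif))
        )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def extract_tags(
    record,
    hits: Iterable[MotifHit],
    config: DigestConfig = DigestConfig(),
    skipped: list | None = None,
) -> set[str]:
    """Fixed-length tags centred on each motif hit, deduplicated.

    A ``-`` strand hit emits the reverse complement of its window, so the tag
    reads 5'→3' on the strand that carries the motif. Hits whose window would
    run off either sequence end are skipped (appended to ``skipped`` when a
    list is supplied), not fatal.
    """
    seq = record.sequence
    m = len(config.motif)
    flank = config.flank
    tags = set()
    for hit in hits:
        lo = hit.start - flank
        hi = hit.start + m + flank
        if lo < 0 or hi > len(seq):
            if skipped is not None:
                skipped.append(hit)
            continue
        tag = seq[lo:hi]
        if hit.strand == "-":
            tag = revcomp(tag)
        if config.canonicalize:
            tag = min(tag, revcomp(tag))
        tags.add(tag)
    return tags


def digest(records: Iterable, config: DigestConfig = DigestConfig()) -> set[str]:
    """Union of extracted tags over all records (a whole genome or haplotype)."""
    tags: set[str] = set()
    for record in records:
        tags |= extract_tags(record, find_motif_sites(record, config), config)
    return tags


def exclusive_tags(
    group_a: Sequence[TagSet], group_b: Sequence[TagSet]
) -> set[str]:
    """Tags present in *every* set of ``group_a`` and *no* set of ``group_b``.

    This is the intersection-minus-union screen applied to per-individual
    2b-RAD tag sets; the all-of intersection over zero sets is undefined, so
    an empty group raises ``ValueError``.
    """
    if not group_a or not group_b:
        raise ValueError("exclusive_tags requires two non-empty groups")
    common = set.intersection(*(ts.tags for ts in group_a))
    return common - set.union(*(ts.tags for ts in group_b))


def infer_sex_system(
    male_sets: Sequence[TagSet],
    female_sets: Sequence[TagSet],
    min_exclusive: int = 10,
    max_minor_ratio: float = 0.01,
) -> SexSystemCall:
    """Call XX/XY vs ZZ/ZW from exclusive-tag counts.

    Let M be the number of tags in all males and no female (candidate
    Y-derived tags) and F the mirror count (candidate W-derived). The call is
    XX_XY when M >= ``min_exclusive`` and F <= ``max_minor_ratio * M``;
    ZZ_ZW under the mirrored condition; otherwise inconclusive. The original
    comparison observed an all-or-nothing split (a large M against F = 0);
    the thresholds make the rule robust to tag dropout and error noise, and
    both counts are always reported.
    """
    m_count = len(exclusive_tags(male_sets, female_sets))
    f_count = len(exclusive_tags(female_sets, male_sets))
    if m_count >= min_exclusive and f_count <= max_minor_ratio * m_count:
        system = "XX_XY"
    elif f_count >= min_exclusive and m_count <= max_minor_ratio * f_count:
        system = "ZZ_ZW"
    else:
        system = "inconclusive"
    return SexSystemCall(
        system=system,
        male_exclusive_count=m_count,
        female_exclusive_count=f_count,
        min_exclusive=min_exclusive,
        max_minor_ratio=max_minor_ratio,
    )
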