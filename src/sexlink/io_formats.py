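"""Readers and writers for the formats the pipeline touches.

Three formats are handled: multi-record wrapped FASTA (via Biopython), a
constrained VCF v4.2 dialect (read via pysam/htslib; written by a small text
emitter), and plain-text tag files (one uppercase fixed-length tag per line,
deduplicated on read, filename convention ``<individual>_<sex>.tags``).

Coordinate convention: VCF positions are 1-based on disk, per the standard.
Everything downstream of this module works in 0-based half-open coordinates;
the conversion happens here and only here.

Site-quality INFO metrics (QD, MQ, FS, SOR, MQRankSum, ReadPosRankSum) that
are absent at a site are represented as an explicit ``None`` ("missing"),
never as 0 or NaN — the hard filter downstream must distinguish a missing
annotation from a failing one.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .dna import validate_dna
from .radtags import TagSet

#: INFO metrics parsed as float-or-missing for the hard filter.
INFO_METRICS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


class FormatError(ValueError):
    """A file does not conform to the dialect this pipeline reads."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastaRecord:
    """One FASTA record: ``id`` is the first whitespace-delimited header token."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("FASTA record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"FASTA record {self.id!r} has an empty sequence")
        validate_dna(self.sequence)  # rejects whitespace too (not in alphabet)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike) -> list[FastaRecord]:
    """Read all records of a (possibly wrapped, possibly lowercase) FASTA file.

    Line wrapping is transparent and sequences are uppercased. A file whose
    first non-blank line does not start with ``>`` raises :class:`FormatError`
    naming that line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header starting "
                        f"with '>', got {line.strip()[:30]!r}"
                    )
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            FastaRecord(
                id=rec.id,
                description=rec.description,
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def write_fasta(
    records: Iterable[FastaRecord], path: str | os.PathLike, line_width: int = 60
) -> None:
    """Write records as wrapped FASTA; round-trips through :func:`read_fasta`."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=_strip_id(r))
        for r in records
    ]
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=line_width)
        writer.write_file(seqrecords)


def _strip_id(record: FastaRecord) -> str:
    # Biopython renders the header as "id description"; avoid doubling the id
    # when the stored description already starts with it.
    desc = record.description
    if desc == record.id:
        return ""
    if desc.startswith(record.id + " "):
        return desc[len(record.id) + 1 :]
    return desc


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class SampleCall:
    """Per-sample allele depths (ref then alts) and total depth."""

    ad: tuple[int, ...] | None
    dp: int | None

    @property
    def usable(self) -> bool:
        return self.ad is not None and all(a is not None for a in self.ad)


@dataclass
class VcfRecord:
    """One VCF line restricted to the fields the screening stage consumes.

    ``pos`` is 1-based as on disk; use :attr:`pos0` for internal arithmetic.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    filter_field: str = "."
    id: str = "."
    info: dict = field(default_factory=dict)
    per_sample: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("VCF ref allele must be non-empty")
        if not self.alts:
            raise ValueError("VCF record needs at least one alt allele")

    @property
    def pos0(self) -> int:
        """0-based position of the first REF base."""
        return self.pos - 1

    @property
    def multiallelic(self) -> bool:
        return len(self.alts) > 1

    def usable_for(self, samples: Sequence[str]) -> bool:
        """True when AD and DP-or-reconstructable depths exist for ``samples``."""
        return all(
            s in self.per_sample and self.per_sample[s].usable for s in samples
        )

    def metric(self, name: str) -> float | None:
        """Float value of an INFO metric, or None when absent at this site."""
        value = self.info.get(name)
        return None if value is None else float(value)


def read_vcf(
    path: str | os.PathLike, required_samples: Sequence[str] = ()
) -> list[VcfRecord]:
    """Read a plain-text VCF into :class:`VcfRecord` objects, in file order.

    ``required_samples`` must all be present in the header; a missing sample
    raises :class:`FormatError` listing the samples that are available.
    Records lacking AD/DP for a required sample are kept but flagged (their
    :meth:`VcfRecord.usable_for` returns False) rather than silently dropped.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF: {exc}") from exc
    with vf:
        available = list(vf.header.samples)
        missing = [s for s in required_samples if s not in available]
        if missing:
            raise FormatError(
                f"{path}: sample(s) {missing} not in VCF; available: {available}"
            )
        records = []
        for rec in vf:
            info = {}
            for key in INFO_METRICS:
                if key in rec.info:
                    value = rec.info[key]
                    if isinstance(value, tuple):
                        value = value[0]
                    if value is not None:
                        info[key] = float(value)
            per_sample = {}
            for name in available:
                call = rec.samples[name]
                ad = call.get("AD")
                if ad is not None and any(a is None for a in ad):
                    ad = None
                dp = call.get("DP")
                per_sample[name] = SampleCall(
                    ad=tuple(int(a) for a in ad) if ad is not None else None,
                    dp=int(dp) if dp is not None else None,
                )
            filters = list(rec.filter.keys())
            records.append(
                VcfRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=rec.qual,
                    filter_field=";".join(filters) if filters else ".",
                    id=rec.id or ".",
                    info=info,
                    per_sample=per_sample,
                )
            )
    return records


_VCF_HEADER_LINES = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias Fisher phred">',
    '##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
]


def write_vcf(
    records: Sequence[VcfRecord],
    path: str | os.PathLike,
    samples: Sequence[str],
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write records as VCF v4.2 text; round-trips through :func:`read_vcf`.

    Float INFO values are printed with 6 significant digits (htslib stores
    them as 32-bit floats on read, so "lossless" means: equal at that
    precision).
    """
    lines = ["##fileformat=VCFv4.2"]
    if contigs is None:
        contigs = {}
        for rec in records:
            contigs.setdefault(rec.chrom, 0)
            end = rec.pos0 + len(rec.ref)
            contigs[rec.chrom] = max(contigs[rec.chrom], end)
    for name, length in contigs.items():
        entry = f"##contig=<ID={name}"
        if length:
            entry += f",length={length}"
        lines.append(entry + ">")
    lines.extend(_VCF_HEADER_LINES)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for rec in records:
        info_parts = [
            f"{k}={rec.info[k]:.6g}" for k in INFO_METRICS if rec.info.get(k) is not None
        ]
        cols = [
            rec.chrom,
            str(rec.pos),
            rec.id,
            rec.ref,
            ",".join(rec.alts),
            "." if rec.qual is None else f"{rec.qual:.6g}",
            rec.filter_field,
            ";".join(info_parts) if info_parts else ".",
            "AD:DP",
        ]
        for name in samples:
            call = rec.per_sample.get(name)
            if call is None or call.ad is None:
                ad_str = "."
            else:
                ad_str = ",".join(str(a) for a in call.ad)
            dp_str = "." if call is None or call.dp is None else str(call.dp)
            cols.append(f"{ad_str}:{dp_str}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tag files
# ---------------------------------------------------------------------------

def read_tag_file(
    path: str | os.PathLike,
    expected_length: int,
    individual_id: str | None = None,
    sex_label: str | None = None,
) -> TagSet:
    """Read a one-tag-per-line file into a deduplicated :class:`TagSet`.

    Identity and sex default to the ``<individual>_<sex>.tags`` filename
    convention (sex ``unknown`` when the name does not follow it). A tag whose
    length differs from ``expected_length``, or that contains a non-ACGT
    character, raises :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    if individual_id is None or sex_label is None:
        stem = path.name.removesuffix(".tags")
        parts = stem.rsplit("_", 1)
        if individual_id is None:
            individual_id = parts[0]
        if sex_label is None:
            sex_label = parts[1] if len(parts) == 2 and parts[1] in (
                "male",
                "female",
            ) else "unknown"
    tags = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line.strip()
            if not tag:
                continue
            if len(tag) != expected_length:
                raise FormatError(
                    f"{path}: line {lineno}: tag length {len(tag)} != "
                    f"expected {expected_length}"
                )
            if set(tag) - set("ACGT"):
                raise FormatError(
                    f"{path}: line {lineno}: non-ACGT character in tag {tag!r}"
                )
            tags.add(tag)
    return TagSet(individual_id=individual_id, sex_label=sex_label, tags=tags)


def write_tag_file(tagset: TagSet, path: str | os.PathLike) -> None:
    """Write tags one per line, sorted for deterministic output."""
    Path(path).write_text("".join(t + "\n" for t in sorted(tagset.tags)))
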