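"""Domain types and file IO for the randomized-library pipeline.

Every downstream stage consumes the types defined here; raw files are read
exactly once, at the boundary.  Sequence containers are deliberately plain
(frozen dataclasses holding strings) — reads are short single-end amplicons
and the pipeline is a streaming pass over them.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO, Union

import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "TemplateSpec",
    "ReadRecord",
    "ClassifierParams",
    "PipelineConfig",
    "ConfigError",
    "read_fastq",
    "write_fastq",
    "load_config",
    "write_config",
    "alpha_msh_template",
    "reverse_complement",
]

_ACGT = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return sequence.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """A configuration field is missing or violates an invariant."""


def _require_acgt(value: str, key: str, length: Optional[int] = None) -> None:
    if length is not None and len(value) != length:
        raise ConfigError(f"{key!r} must have length {length}, got {len(value)}")
    if not value:
        raise ConfigError(f"{key!r} must be a non-empty nucleotide string")
    if not set(value) <= _ACGT:
        raise ConfigError(f"{key!r} must contain only A/C/G/T, got {value!r}")


@dataclass(frozen=True)
class TemplateSpec:
    """Reference description of the amplicon around the randomized region.

    The extracted region of a read is ``left_flank + insert + right_flank``:
    the randomized insert together with the two constant trinucleotides that
    border it (the last codon of the secretion-signal CDS and the stop
    codon).  ``template_insert`` is the non-randomized CDS the library was
    derived from; template-biased reads still resemble it.

    Parameters
    ----------
    name : str
        Short library/template label.
    upstream_anchor, downstream_anchor : str
        Constant sequences immediately 5' / 3' of the region (exclusive of
        the flank trinucleotides); used to locate the region in each read.
    left_flank, right_flank : str
        The two flanking trinucleotides; retained reads must carry them
        exactly.
    template_insert : str
        Template CDS between the flanks; length must be a codon multiple.
    designed_random_length : int
        Designed length (nt) of the randomized insert.
    """

    name: str
    upstream_anchor: str
    downstream_anchor: str
    left_flank: str
    right_flank: str
    template_insert: str
    designed_random_length: int

    def __post_init__(self) -> None:
        _require_acgt(self.upstream_anchor, "upstream_anchor")
        _require_acgt(self.downstream_anchor, "downstream_anchor")
        _require_acgt(self.left_flank, "left_flank", length=3)
        _require_acgt(self.right_flank, "right_flank", length=3)
        _require_acgt(self.template_insert, "template_insert")
        if len(self.template_insert) % 3 != 0:
            raise ConfigError(
                "'template_insert' length must be divisible by 3, "
                f"got {len(self.template_insert)}"
            )
        if self.designed_random_length < 1:
            raise ConfigError("'designed_random_length' must be >= 1")

    @property
    def reference_region(self) -> str:
        """Template region the classifier aligns against (flanks included)."""
        return self.left_flank + self.template_insert + self.right_flank


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (FASTQ/FASTA carrier)."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds and scoring for template-bias classification.

    A region is called *insufficiently randomized* when its global alignment
    to the template region has fewer than ``max_mismatches`` mismatches and
    fewer than ``max_gaps`` gaps (strict bounds by default;
    ``inclusive_bounds`` switches both to <=).  ``count_gap_openings``
    switches the gap quantity from gap columns (default) to gap openings.
    """

    max_mismatches: int = 10
    max_gaps: int = 3
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -1.0
    inclusive_bounds: bool = False
    count_gap_openings: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ConfigError("'max_mismatches' must be >= 0")
        if self.max_gaps < 0:
            raise ConfigError("'max_gaps' must be >= 0")
        if not self.match_score > self.mismatch_score:
            raise ConfigError("'match_score' must exceed 'mismatch_score'")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the analysis pipeline reproducibly."""

    template: TemplateSpec
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    anchor_max_error_rate: float = 0.1
    search_both_orientations: bool = True
    internal_stop_policy: str = "keep_symbol"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.anchor_max_error_rate < 0.5:
            raise ConfigError(
                "'anchor_max_error_rate' must be in [0, 0.5), "
                f"got {self.anchor_max_error_rate}"
            )
        if self.internal_stop_policy not in ("keep_symbol", "truncate_at_stop"):
            raise ConfigError(
                "'internal_stop_policy' must be 'keep_symbol' or "
                f"'truncate_at_stop', got {self.internal_stop_policy!r}"
            )


def alpha_msh_template() -> TemplateSpec:
    """Template for the alpha-factor / alpha-MSH construct.

    The 39-nt insert is the alpha-MSH CDS (SYSMEHFRWGKPV); the designed
    randomized insert replacing it is 54 nt (18 codons).  Flanks are the
    last alpha-factor codon (TAC) and the stop codon (TAA); anchors are the
    constant primer-derived context on either side.
    """
    return TemplateSpec(
        name="alpha-MSH",
        upstream_anchor="AGAGAGGCTGAAGCA",
        downstream_anchor="GCAGCATCTGAATTCGATATC",
        left_flank="TAC",
        right_flank="TAA",
        template_insert="TCTTATTCTATGGAACATTTTAGATGGGGTAAACCAGTT",
        designed_random_length=54,
    )


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def _open_text(path: Union[str, os.PathLike]) -> TextIO:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fastq(path: Union[str, os.PathLike]) -> Iterator[ReadRecord]:
    """Yield reads from a FASTQ or FASTA file (gzip optional).

    Format is auto-detected from the first non-blank character ('@' FASTQ,
    '>' FASTA).  Sequences are uppercased and U is mapped to T.  Malformed
    records raise ``ValueError`` naming the record index.
    """
    handle = _open_text(path)
    with handle:
        first = handle.read(1)
        while first.isspace():
            first = handle.read(1)
        if not first:
            return
        handle.seek(0)
        if first == "@":
            iterator: Iterable = FastqGeneralIterator(handle)
            with_quality = True
        elif first == ">":
            iterator = SimpleFastaParser(handle)
            with_quality = False
        else:
            raise ValueError(
                f"{path}: cannot auto-detect format (first character {first!r})"
            )
        for index, fields in enumerate(iterator):
            if with_quality:
                title, seq, qual = fields
            else:
                title, seq = fields
                qual = None
            seq = seq.upper().replace("U", "T")
            if qual is not None and len(qual) != len(seq):
                raise ValueError(
                    f"{path}: record {index} ({title.split()[0]!r}): "
                    f"quality length {len(qual)} != sequence length {len(seq)}"
                )
            try:
                yield ReadRecord(title.split()[0], seq, qual)
            except ValueError as exc:
                raise ValueError(f"{path}: record {index}: {exc}") from exc


def write_fastq(path: Union[str, os.PathLike],
                records: Iterable[ReadRecord]) -> int:
    """Write records as FASTQ (or FASTA when no record has qualities).

    Gzip-compresses when the path ends in ``.gz``.  Returns the number of
    records written.
    """
    records = list(records)
    as_fastq = any(r.quality is not None for r in records) or not records
    opener = gzip.open if str(path).endswith(".gz") else open
    n = 0
    with opener(path, "wt") as out:
        for rec in records:
            if as_fastq:
                qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
                out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")
            else:
                out.write(f">{rec.read_id}\n{rec.sequence}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

_TEMPLATE_KEYS = ("name", "upstream_anchor", "downstream_anchor", "left_flank",
                  "right_flank", "template_insert", "designed_random_length")


def load_config(path: Union[str, os.PathLike]) -> PipelineConfig:
    """Load a YAML pipeline configuration.

    The ``template`` block is mandatory; classifier and pipeline options
    fall back to their documented defaults.  Missing mandatory keys and
    invariant violations raise :class:`ConfigError` naming the key.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "template" not in raw:
        raise ConfigError(f"{path}: missing mandatory 'template' section")
    tmpl = raw["template"]
    missing = [k for k in _TEMPLATE_KEYS if k not in tmpl]
    if missing:
        raise ConfigError(f"{path}: template section missing {missing}")
    template = TemplateSpec(**{k: tmpl[k] for k in _TEMPLATE_KEYS})
    classifier = ClassifierParams(**raw.get("classifier", {}))
    options = {k: v for k, v in raw.items() if k not in ("template", "classifier")}
    return PipelineConfig(template=template, classifier=classifier, **options)


def write_config(path: Union[str, os.PathLike], config: PipelineConfig) -> None:
    """Write a config so that ``load_config`` round-trips it unchanged."""
    data = {
        "template": dataclasses.asdict(config.template),
        "classifier": dataclasses.asdict(config.classifier),
        "anchor_max_error_rate": config.anchor_max_error_rate,
        "search_both_orientations": config.search_both_orientations,
        "internal_stop_policy": config.internal_stop_policy,
        "random_seed": config.random_seed,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)
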