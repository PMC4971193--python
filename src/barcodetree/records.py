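"""Barcode record I/O and record-quality filtering.

A barcode record is one specimen's COI sequence together with its
identification (species name or interim name, genus, family) and
collection locality (country, optional state/province). Records enter
as a FASTA file plus a tab-separated metadata table joined on record ID
and are screened with the standard barcode-library quality criteria:
a minimum count of unambiguous nucleotides, absence of curator flags
such as "error" or "contaminant", and absence of stop codons in every
forward reading frame under the invertebrate mitochondrial code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "BarcodeRecord",
    "FilterPolicy",
    "read_records",
    "write_records",
    "count_unambiguous_length",
    "has_internal_stop",
    "apply_filter",
]

#: IUPAC DNA alphabet accepted in barcode sequences (plus alignment gap).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")

#: Default genetic code for mitochondrial COI in invertebrates
#: (NCBI translation table 5).
INVERTEBRATE_MITO = "invertebrate_mitochondrial"

_CODE_IDS = {
    INVERTEBRATE_MITO: 5,
    "standard": 1,
    "vertebrate_mitochondrial": 2,
}

METADATA_COLUMNS = [
    "record_id",
    "species_name",
    "interim",
    "family",
    "genus",
    "country",
    "region",
    "flags",
]


@dataclass
class BarcodeRecord:
    """One specimen: sequence plus identification and locality metadata."""

    record_id: str
    sequence: str
    species_name: str = ""
    interim_name_flag: bool = False
    family: str = ""
    genus: str = ""
    country: str = ""
    region: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        validate_sequence(self.sequence)
        self.flags = frozenset(f.lower() for f in self.flags)


@dataclass(frozen=True)
class FilterPolicy:
    """Record-quality policy.

    ``min_length`` is a strict lower bound expressed as a minimum: a
    record is kept only if it has at least ``min_length`` unambiguous
    (A/C/G/T) bases. The default of 501 encodes the "more than 500 bp"
    convention. ``reject_flags`` are matched case-insensitively against
    the record's curator flags. When ``check_stop_codons`` is set, a
    record is rejected if every forward reading frame contains a stop
    codon under ``genetic_code``.
    """

    min_length: int = 501
    reject_flags: frozenset[str] = frozenset({"error", "contaminant", "stop_codon"})
    check_stop_codons: bool = True
    genetic_code: str = INVERTEBRATE_MITO

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        object.__setattr__(
            self, "reject_flags", frozenset(f.lower() for f in self.reject_flags)
        )


def validate_sequence(sequence: str) -> None:
    """Raise ``ValueError`` (with position) on a non-IUPAC character."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, ch in enumerate(sequence):
        if ch.upper() not in IUPAC_DNA:
            raise ValueError(
                f"invalid character {ch!r} at position {pos} in sequence"
            )


def count_unambiguous_length(sequence: str) -> int:
    """Number of unambiguous A/C/G/T bases (gaps and IUPAC codes excluded)."""
    validate_sequence(sequence)
    seq = sequence.upper()
    return sum(seq.count(b) for b in "ACGT")


def _stop_codons(genetic_code: str) -> frozenset[str]:
    try:
        table_id = _CODE_IDS[genetic_code]
    except KeyError:
        raise ValueError(f"unknown genetic code {genetic_code!r}") from None
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


def has_internal_stop(sequence: str, genetic_code: str = INVERTEBRATE_MITO) -> bool:
    """Whether every forward reading frame contains a stop codon.

    The gap-stripped sequence is translated in all three forward frames;
    the record passes (returns ``False``) as soon as one frame is free of
    stop codons, because the amplicon's reading frame is not recorded in
    barcode submissions. Codons containing ambiguity codes never count
    as stops. Reverse frames are not tested: barcodes are stored 5'->3'
    on the coding strand.
    """
    stops = _stop_codons(genetic_code)
    validate_sequence(sequence)
    seq = sequence.upper().replace("-", "")
    for frame in range(3):
        frame_has_stop = False
        for i in range(frame, len(seq) - 2, 3):
            if seq[i : i + 3] in stops:
                frame_has_stop = True
                break
        if not frame_has_stop:
            return False
    return True


def apply_filter(
    records: list[BarcodeRecord], policy: FilterPolicy | None = None
) -> tuple[list[BarcodeRecord], list[tuple[BarcodeRecord, str]]]:
    """Partition records into (kept, rejected-with-reason).

    A record is rejected for the first failing criterion in the fixed
    order: ``length`` (fewer than ``min_length`` unambiguous bases),
    ``flag`` (a curator flag in ``reject_flags``), ``stop_codon``
    (stop codons in all three forward frames).
    """
    if policy is None:
        policy = FilterPolicy()
    kept: list[BarcodeRecord] = []
    rejected: list[tuple[BarcodeRecord, str]] = []
    for rec in records:
        if count_unambiguous_length(rec.sequence) < policy.min_length:
            rejected.append((rec, "length"))
        elif rec.flags & policy.reject_flags:
            rejected.append((rec, "flag"))
        elif policy.check_stop_codons and has_internal_stop(
            rec.sequence, policy.genetic_code
        ):
            rejected.append((rec, "stop_codon"))
        else:
            kept.append(rec)
    return kept, rejected


def read_records(fasta_source, metadata_source) -> list[BarcodeRecord]:
    """Join a FASTA stream with a metadata TSV into barcode records.

    The FASTA header's first whitespace-delimited token is the record ID
    and must appear in the metadata table; extra metadata rows are
    tolerated. ``flags`` in the TSV are semicolon-separated.
    """
    meta = pd.read_csv(
        metadata_source, sep="\t", dtype=str, keep_default_na=False
    )
    missing_cols = [c for c in ("record_id",) if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata table lacks required column(s): {missing_cols}")
    if meta["record_id"].duplicated().any():
        dups = meta.loc[meta["record_id"].duplicated(), "record_id"].tolist()
        raise ValueError(f"duplicate record_id in metadata: {dups[:5]}")
    meta = meta.set_index("record_id")

    if isinstance(fasta_source, (str, bytes)) and "\n" in str(fasta_source):
        fasta_source = io.StringIO(fasta_source)
    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(fasta_source, "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA record ID {rid!r}")
        seen.add(rid)
        if rid not in meta.index:
            raise KeyError(f"FASTA record ID {rid!r} absent from metadata table")
        row = meta.loc[rid]
        flags = frozenset(
            f for f in str(row.get("flags", "")).split(";") if f.strip()
        )
        records.append(
            BarcodeRecord(
                record_id=rid,
                sequence=str(entry.seq),
                species_name=str(row.get("species_name", "")),
                interim_name_flag=_parse_bool(row.get("interim", "")),
                family=str(row.get("family", "")),
                genus=str(row.get("genus", "")),
                country=str(row.get("country", "")),
                region=str(row.get("region", "")),
                flags=flags,
            )
        )
    return records


def write_records(records: list[BarcodeRecord], fasta_sink, metadata_sink) -> None:
    """Write records as FASTA + metadata TSV, mirroring :func:`read_records`."""
    own_fasta = isinstance(fasta_sink, str)
    own_meta = isinstance(metadata_sink, str)
    fh = open(fasta_sink, "w") if own_fasta else fasta_sink
    try:
        for rec in records:
            fh.write(f">{rec.record_id}\n{rec.sequence}\n")
    finally:
        if own_fasta:
            fh.close()
    rows = [
        {
            "record_id": r.record_id,
            "species_name": r.species_name,
            "interim": "1" if r.interim_name_flag else "0",
            "family": r.family,
            "genus": r.genus,
            "country": r.country,
            "region": r.region,
            "flags": ";".join(sorted(r.flags)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        metadata_sink, sep="\t", index=False
    )
    _ = own_meta  # pandas handles both paths and buffers


def _parse_bool(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def relabel(record: BarcodeRecord, **changes) -> BarcodeRecord:
    """Return a copy of ``record`` with the given fields replaced."""
    return replace(record, **changes)
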