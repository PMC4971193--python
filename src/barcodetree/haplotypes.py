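"""Haplotype collapsing into OTUs and taxon-label encoding.

Identical sequences are merged into a single OTU (operational taxonomic
unit, here equal to one unique haplotype). Each OTU carries its member
record IDs, the multiset of species names attached to those members and
per-locality member counts. OTU labels compress this information into a
Newick-safe string: sanitized species name, then one block per locality
consisting of a three-letter country code (plus a two-letter state or
province code for the seven largest countries by area) and the count of
individuals sharing the haplotype at that locality.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .records import BarcodeRecord

__all__ = [
    "OTU",
    "LabelCodec",
    "collapse",
    "encode_label",
    "encode_labels",
    "decode_label",
    "write_otu_table",
    "write_otu_fasta",
]

#: Countries that receive an extra state/province code (largest 7 by area).
BIG7_COUNTRIES = (
    "Russia",
    "Canada",
    "China",
    "United States",
    "Brazil",
    "Australia",
    "India",
)

#: Small built-in country-code table covering the big-7 plus countries that
#: dominate barcode sampling; user-supplied tables extend or replace it.
DEFAULT_COUNTRY_CODES = {
    "Russia": "RUS",
    "Canada": "CAN",
    "China": "CHN",
    "United States": "USA",
    "Brazil": "BRA",
    "Australia": "AUS",
    "India": "IND",
    "Finland": "FIN",
    "Germany": "DEU",
    "Spain": "ESP",
    "Austria": "AUT",
    "New Zealand": "NZL",
    "Mongolia": "MNG",
    "Mexico": "MEX",
    "Costa Rica": "CRI",
    "Ecuador": "ECU",
}

_NEWICK_ILLEGAL = re.compile(r"[^A-Za-z0-9_.\-]")
_CONFLICT_MARKER = "-cf"


@dataclass
class OTU:
    """A unique haplotype with its member records and locality counts."""

    otu_id: str
    sequence: str
    members: list[str] = field(default_factory=list)
    species_names: Counter = field(default_factory=Counter)
    locality_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def majority_species(self) -> tuple[str, bool]:
        """(most common species name, whether names conflict).

        Ties are broken alphabetically so labels are deterministic.
        """
        if not self.species_names:
            return "", False
        top = max(self.species_names.items(), key=lambda kv: (kv[1], kv[0]))
        best_count = top[1]
        candidates = sorted(
            n for n, c in self.species_names.items() if c == best_count
        )
        return candidates[0], len(self.species_names) > 1


@dataclass(frozen=True)
class LabelCodec:
    """Country/region code tables used by the label grammar."""

    country_codes: dict[str, str] = None
    big7_region_codes: dict[tuple[str, str], str] = None
    big7_countries: frozenset[str] = frozenset(BIG7_COUNTRIES)

    def __post_init__(self):
        object.__setattr__(
            self,
            "country_codes",
            dict(self.country_codes or DEFAULT_COUNTRY_CODES),
        )
        object.__setattr__(
            self, "big7_region_codes", dict(self.big7_region_codes or {})
        )
        codes = list(self.country_codes.values())
        if len(set(codes)) != len(codes):
            raise ValueError("country codes must be unique")
        for country, code in self.country_codes.items():
            if len(code) != 3 or not code.isalpha():
                raise ValueError(
                    f"country code for {country!r} must be 3 letters, got {code!r}"
                )
        for (country, region), code in self.big7_region_codes.items():
            if len(code) != 2 or not code.isalpha():
                raise ValueError(
                    f"region code for {country}/{region} must be 2 letters"
                )

    @classmethod
    def from_tsv(cls, country_source, region_source=None) -> "LabelCodec":
        """Build a codec from TSV tables.

        ``country_source``: columns ``country``, ``code`` (3 letters).
        ``region_source`` (optional): columns ``country``, ``region``,
        ``code`` (2 letters); its countries form the big-7 set.
        """
        ctab = pd.read_csv(country_source, sep="\t", dtype=str)
        country_codes = dict(zip(ctab["country"], ctab["code"]))
        region_codes: dict[tuple[str, str], int] = {}
        big7 = frozenset(BIG7_COUNTRIES)
        if region_source is not None:
            rtab = pd.read_csv(region_source, sep="\t", dtype=str)
            region_codes = {
                (row.country, row.region): row.code
                for row in rtab.itertuples()
            }
            big7 = frozenset(rtab["country"])
        return cls(country_codes, region_codes, big7)

    def code_for(self, country: str) -> str:
        try:
            return self.country_codes[country]
        except KeyError:
            raise KeyError(f"unknown country {country!r} (no 3-letter code)") from None

    def region_code_for(self, country: str, region: str) -> str:
        key = (country, region)
        if key in self.big7_region_codes:
            return self.big7_region_codes[key]
        # Derive a deterministic 2-letter code when no table entry exists.
        letters = re.sub(r"[^A-Za-z]", "", region).upper()
        if len(letters) >= 2:
            return letters[:2]
        raise KeyError(f"no 2-letter code derivable for region {region!r}")


def collapse(records: list[BarcodeRecord]) -> list[OTU]:
    """Merge identical haplotypes (exact, case-insensitive) into OTUs.

    Sequences differing only in ambiguity codes are NOT merged, and
    sequences of different length are never merged. OTUs are ordered by
    the first-seen member record, and ``otu_id`` numbers follow that
    order.
    """
    by_seq: dict[str, OTU] = {}
    for rec in records:
        key = rec.sequence.upper()
        otu = by_seq.get(key)
        if otu is None:
            otu = OTU(otu_id="", sequence=key)
            by_seq[key] = otu
        otu.members.append(rec.record_id)
        if rec.species_name:
            otu.species_names[rec.species_name] += 1
        loc = (rec.country, rec.region)
        otu.locality_counts[loc] = otu.locality_counts.get(loc, 0) + 1
    otus = list(by_seq.values())  # dict preserves first-seen order
    width = max(4, len(str(len(otus))))
    for i, otu in enumerate(otus, start=1):
        otu.otu_id = f"OTU{i:0{width}d}"
    return otus


def sanitize_name(name: str) -> str:
    """Make a species name safe for Newick: spaces to ``_``, other
    illegal characters to ``-``."""
    return _NEWICK_ILLEGAL.sub("-", name.replace(" ", "_"))


def encode_label(otu: OTU, codec: LabelCodec | None = None) -> str:
    """Encode an OTU as ``Species_name_CCC[_RR]_n[...]``.

    Every distinct locality contributes one block of country code,
    region code when the country is among the big seven (and a region is
    recorded), and member count. Localities appear in deterministic
    (sorted) order. When members carry conflicting species names the
    majority name is used with a ``-cf`` marker appended.
    """
    if codec is None:
        codec = LabelCodec()
    name, conflict = otu.majority_species()
    label = sanitize_name(name) if name else otu.otu_id
    if conflict:
        label += _CONFLICT_MARKER
    for (country, region), count in sorted(otu.locality_counts.items()):
        block = [codec.code_for(country)]
        if country in codec.big7_countries and region:
            block.append(codec.region_code_for(country, region))
        block.append(str(count))
        label += "_" + "_".join(block)
    return label


def encode_labels(
    otus: list[OTU], codec: LabelCodec | None = None
) -> dict[str, str]:
    """Encode every OTU, disambiguating collisions.

    Distinct haplotypes of one species collected at identical localities
    encode to the same base label; since Newick leaf names must be
    unique, later duplicates get a ``.2``, ``.3`` ... suffix in
    first-seen order. Returns ``{otu_id: label}``.
    """
    seen: dict[str, int] = {}
    out: dict[str, str] = {}
    for otu in otus:
        base = encode_label(otu, codec)
        n = seen.get(base, 0) + 1
        seen[base] = n
        out[otu.otu_id] = base if n == 1 else f"{base}.{n}"
    return out


def decode_label(
    label: str, codec: LabelCodec | None = None
) -> tuple[str, list[tuple[tuple[str, str], int]]]:
    """Invert :func:`encode_label`.

    Returns ``(species_name, [((country, region), count), ...])``. The
    species name is everything before the first token recognized as a
    3-letter country code; underscores are restored to spaces. A
    trailing ``.<k>`` disambiguation suffix is ignored.
    """
    if codec is None:
        codec = LabelCodec()
    head, dot, tail = label.rpartition(".")
    if dot and tail.isdigit():
        label = head
    code_to_country = {v: k for k, v in codec.country_codes.items()}
    region_decode = {
        (country, code): region
        for (country, region), code in codec.big7_region_codes.items()
    }
    tokens = label.split("_")
    split_at = next(
        (i for i, t in enumerate(tokens) if t in code_to_country), None
    )
    if split_at is None or split_at == 0:
        raise ValueError(f"label {label!r}: no recognized country code token")
    species = " ".join(tokens[:split_at])
    localities: list[tuple[tuple[str, str], int]] = []
    i = split_at
    while i < len(tokens):
        code = tokens[i]
        if code not in code_to_country:
            raise ValueError(f"label {label!r}: expected country code, got {code!r}")
        country = code_to_country[code]
        i += 1
        region = ""
        if (
            country in codec.big7_countries
            and i < len(tokens)
            and not tokens[i].isdigit()
        ):
            region = region_decode.get((country, tokens[i]), tokens[i])
            i += 1
        if i >= len(tokens) or not tokens[i].isdigit():
            raise ValueError(f"label {label!r}: missing count after {code}")
        localities.append(((country, region), int(tokens[i])))
        i += 1
    return species, localities


def write_otu_table(otus: list[OTU], sink, codec: LabelCodec | None = None) -> None:
    """Write the OTU table as TSV (otu_id, label, n_members, member_ids)."""
    labels = encode_labels(otus, codec)
    rows = [
        {
            "otu_id": o.otu_id,
            "label": labels[o.otu_id],
            "n_members": o.n_members,
            "member_ids": ";".join(o.members),
        }
        for o in otus
    ]
    pd.DataFrame(
        rows, columns=["otu_id", "label", "n_members", "member_ids"]
    ).to_csv(sink, sep="\t", index=False)


def write_otu_fasta(otus: list[OTU], sink, codec: LabelCodec | None = None) -> None:
    """Write unique haplotypes as FASTA keyed by encoded label."""
    labels = encode_labels(otus, codec)
    own = isinstance(sink, str)
    fh = open(sink, "w") if own else sink
    try:
        for o in otus:
            fh.write(f">{labels[o.otu_id]}\n{o.sequence}\n")
    finally:
        if own:
            fh.close()
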