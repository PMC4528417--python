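"""Reading germline reference FASTA files in the IMGT reference-directory dialect.

IMGT reference directories ship gapped nucleotide sequences (periods mark the
numbering gaps) with pipe-delimited headers whose second field is the allele
name and whose fourth field is the functionality class (F, ORF or P, possibly
decorated with parentheses/brackets for mapped-but-unconfirmed entries).
Plain FASTA with the allele name as the only header token is accepted too,
with functionality defaulting to F.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO

from .nomenclature import AlleleName, NameParseError, parse_allele_name

_VALID_BASES = set("ACGTN")


class ReferenceParseError(ValueError):
    pass


@dataclass(frozen=True)
class GermlineAllele:
    """One germline segment: an ungapped nucleotide sequence plus its parsed name."""

    name: AlleleName
    region: str            # "V", "D" or "J"
    functionality: str     # "F", "ORF" or "P"
    sequence: str          # ungapped, uppercase, over ACGTN

    def __post_init__(self):
        if not self.sequence:
            raise ReferenceParseError(f"{self.name.full}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ReferenceParseError(
                f"{self.name.full}: invalid characters {sorted(bad)}"
            )


def _functionality(raw: str) -> str:
    # IMGT decorates provisional assignments: "(F)", "[ORF]" etc.
    return raw.strip().strip("()[]").upper()


def parse_imgt_fasta(
    text: str,
    region: str,
    include_pseudogenes: bool = False,
) -> list[GermlineAllele]:
    """Parse an IMGT-dialect germline FASTA into :class:`GermlineAllele` records.

    Periods (IMGT numbering gaps) are stripped from sequences.  By default only
    functional (F) and open-reading-frame (ORF) records are retained;
    pseudogenes (P) need ``include_pseudogenes=True``.  A malformed header
    raises :class:`ReferenceParseError` naming the record index.
    """
    if region not in ("V", "D", "J"):
        raise ValueError(f"region must be V, D or J, got {region!r}")
    alleles: list[GermlineAllele] = []
    for idx, rec in enumerate(SeqIO.parse(io.StringIO(text), "fasta")):
        fields = rec.description.split("|")
        try:
            if len(fields) >= 4:
                name = parse_allele_name(fields[1])
                functionality = _functionality(fields[3])
            else:
                name = parse_allele_name(fields[0].split()[0])
                functionality = "F"
        except NameParseError as exc:
            raise ReferenceParseError(f"record {idx}: {exc}") from exc
        if functionality not in ("F", "ORF", "P"):
            raise ReferenceParseError(
                f"record {idx} ({name.full}): unknown functionality "
                f"{functionality!r}"
            )
        if name.region != region:
            raise ReferenceParseError(
                f"record {idx}: {name.full} is not a {region} segment"
            )
        if functionality == "P" and not include_pseudogenes:
            continue
        seq = str(rec.seq).upper().replace(".", "").replace("-", "")
        alleles.append(
            GermlineAllele(
                name=name, region=region, functionality=functionality, sequence=seq
            )
        )
    return alleles


@dataclass
class DedupeResult:
    retained: list[GermlineAllele]
    synonyms: dict[str, str] = field(default_factory=dict)  # dropped -> kept

    def representative(self, allele_name: str) -> str:
        """Canonical retained name for any input allele name."""
        return self.synonyms.get(allele_name, allele_name)

    def equivalent(self, a: str, b: str) -> bool:
        return self.representative(a) == self.representative(b)


def dedupe_alleles(alleles: list[GermlineAllele]) -> DedupeResult:
    """Drop duplicate (gap-free identical) sequences, keeping the first seen.

    The synonym map records every dropped name against its retained
    representative, so downstream evaluation can treat genetically identical
    alleles as interchangeable.
    """
    seen: dict[str, str] = {}
    out = DedupeResult(retained=[])
    for al in alleles:
        kept = seen.get(al.sequence)
        if kept is None:
            seen[al.sequence] = al.name.full
            out.retained.append(al)
        else:
            out.synonyms[al.name.full] = kept
    return out
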