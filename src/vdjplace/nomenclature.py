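"""Germline allele nomenclature.

Immunoglobulin germline segments follow the IMGT naming hierarchy
``family > gene > allele``, e.g. ``IGHV3-23*01`` is allele ``*01`` of gene
``IGHV3-23`` in family ``IGHV3``.  Internal tree nodes may carry labels at
any level of this hierarchy (down to the bare region letter, e.g. ``IGHV``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# locus prefix (IGH/IGK/IGL/TRB/... or nothing), region letter, family token,
# optional "-gene" (possibly multi-part, e.g. 1-69-2), optional "*allele"
_NAME_RE = re.compile(
    r"^(?P<locus>[A-Z]*?)(?P<region>[VDJ])"
    r"(?P<family>[0-9]+[A-Za-z0-9/]*?)?"
    r"(?P<gene>(?:-[A-Za-z0-9]+)*)"
    r"(?:\*(?P<allele>[0-9]+))?$"
)

LEVELS = ("region", "family", "gene", "allele")


class NameParseError(ValueError):
    """Raised when an allele label does not follow the naming scheme."""


@dataclass(frozen=True)
class AlleleName:
    """Parsed germline segment label."""

    full: str
    region: str        # "V", "D" or "J"
    region_label: str  # e.g. "IGHV"
    family: str        # e.g. "IGHV3"
    gene: str          # e.g. "IGHV3-23"
    allele: str | None  # e.g. "01", or None for gene/family-level labels

    @property
    def level(self) -> str:
        """Most resolved level this label reaches."""
        if self.allele is not None:
            return "allele"
        if self.gene != self.family:
            return "gene"
        if self.family != self.region_label:
            return "family"
        return "region"

    def at_level(self, level: str) -> str:
        if level == "allele":
            if self.allele is None:
                raise ValueError(f"{self.full} carries no allele number")
            return self.full
        if level == "gene":
            return self.gene
        if level == "family":
            return self.family
        if level == "region":
            return self.region_label
        raise ValueError(f"unknown level {level!r}")


def parse_allele_name(name: str) -> AlleleName:
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise NameParseError(f"cannot parse germline label {name!r}")
    locus = m.group("locus") or ""
    region = m.group("region")
    region_label = locus + region
    family = region_label + (m.group("family") or "")
    gene = family + (m.group("gene") or "")
    if m.group("family") is None and m.group("gene"):
        raise NameParseError(f"gene without family in {name!r}")
    return AlleleName(
        full=name.strip(),
        region=region,
        region_label=region_label,
        family=family,
        gene=gene,
        allele=m.group("allele"),
    )


def shared_label(names: list[AlleleName]) -> str:
    """Most resolved label shared by all of ``names``.

    Used for internal-node labelling: the returned string is the full allele
    name if all inputs are the same allele, else the common gene, family or
    bare region label.
    """
    if not names:
        raise ValueError("no names supplied")
    first = names[0]
    if all(n.full == first.full for n in names):
        return first.full
    if all(n.gene == first.gene for n in names):
        return first.gene
    if all(n.family == first.family for n in names):
        return first.family
    if all(n.region_label == first.region_label for n in names):
        return first.region_label
    if all(n.region == first.region for n in names):
        return first.region
    raise ValueError("labels span multiple regions")
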