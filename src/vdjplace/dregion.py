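"""D allele assignment by local alignment of the junction.

The D segment is too short and too eroded for phylogenetic placement, so the
D allele is called by Smith-Waterman local alignment with affine gap
penalties of every dictionary entry — forward and inverted — against the
junction nucleotides.  All alleles tied at the maximum score are reported as
equally likely; scores below a configurable minimum yield "no D assigned".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner

DEFAULT_D_SCORING = {
    "match": 5.0, "mismatch": -4.0, "gap_open": -10.0, "gap_extend": -1.0,
}
DEFAULT_MIN_SCORE = 15.0  # three matched codons' worth of identity


@dataclass
class DCall:
    alleles: list = field(default_factory=list)  # (name, orientation, score)
    score: float = 0.0

    @property
    def assigned(self) -> bool:
        return bool(self.alleles)

    @property
    def names(self) -> list[str]:
        return [a[0] for a in self.alleles]

    def tsv_field(self) -> str:
        if not self.alleles:
            return ""
        return ";".join(
            name + ("|inv" if orient == "inverted" else "")
            for name, orient, _ in self.alleles
        )


def _aligner(scoring: dict) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = scoring["match"]
    al.mismatch_score = scoring["mismatch"]
    al.open_gap_score = scoring["gap_open"]
    al.extend_gap_score = scoring["gap_extend"]
    return al


def sw_align(a: str, b: str, scoring: dict | None = None) -> float:
    """Smith-Waterman affine-gap local alignment score (>= 0)."""
    if not a or not b:
        raise ValueError("empty sequence")
    al = _aligner(scoring or DEFAULT_D_SCORING)
    return max(0.0, float(al.align(a.upper(), b.upper()).score))


def assign_d(
    junction_nt: str,
    d_alleles: dict[str, dict],
    scoring: dict | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
) -> DCall:
    """Best-scoring D allele(s) for a junction; ties all reported."""
    if not junction_nt:
        return DCall()
    scoring = scoring or DEFAULT_D_SCORING
    al = _aligner(scoring)
    jn = junction_nt.upper()
    hits: list[tuple[str, str, float]] = []
    best = -1.0
    for name in sorted(d_alleles):
        entry = d_alleles[name]
        score = max(0.0, float(al.align(jn, entry["sequence"]).score))
        orient = "inverted" if entry["inverted"] else "forward"
        label = entry.get("partner", name)
        if score > best:
            best = score
            hits = [(label, orient, score)]
        elif score == best:
            hits.append((label, orient, score))
    if best < min_score:
        return DCall()
    # a forward/inverted pair of the same allele counts once (forward first)
    seen = set()
    uniq = []
    for label, orient, score in sorted(hits, key=lambda h: (h[0], h[1] != "forward")):
        if label not in seen:
            seen.add(label)
            uniq.append((label, orient, score))
    return DCall(alleles=uniq, score=best)
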