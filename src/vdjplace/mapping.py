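"""Homology mapping of query reads onto the reference coordinate system.

Each query is locally aligned (affine gaps, both strands) against a panel of
V+J templates: the reconstructed V and J most-recent-common-ancestor
concatenation plus every primary (*01) V x *01 J concatenation.  The best
mapping transfers reference column coordinates — and with them the
FR1-3/CDR1-3 boundaries, the FR3 3' cysteine and the J joining motif — onto
query positions.  The junction spans from the FW3 cysteine codon to the
first [FW]G.G motif in the J region, falling back to the alignment-mapped
position of the conserved tryptophan when the motif has been mutated away.
A rearrangement is called productive when an in-frame junction can be
extracted and the mapped translation is stop-free.

Reading frames are carried over from the templates' codon structure;
alignment scoring is nucleotide-level (match 5, mismatch -4, gap open 10,
gap extend 1), which the methods note discusses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .reference import ReferenceBundle, V_REGION_NAMES, reverse_complement

J_MOTIF_RE = re.compile(r"[FW]G.G")
MIN_QUERY_LEN = 30

DEFAULT_SCORING = {
    "match": 5.0, "mismatch": -4.0, "gap_open": -10.0, "gap_extend": -1.0,
}


class MappingError(ValueError):
    pass


@dataclass
class Template:
    """A V+J concatenation with per-position reference column ids.

    Global columns: V alignment columns ``[0, vC)``, J columns shifted to
    ``[vC, vC + jC)``.
    """

    name: str
    v_name: str
    j_name: str
    seq: str
    colmap: np.ndarray   # (len(seq),) global column per template position
    v_len: int           # template positions < v_len stem from the V segment


@dataclass
class PairwiseMap:
    template: Template
    score: float
    orientation: str             # "+" or "-"
    query: str                   # oriented query sequence
    qcols: np.ndarray            # (len(query),) global column or -1
    too_short: bool = False

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(q, int(c)) for q, c in enumerate(self.qcols) if c >= 0]


@dataclass
class JunctionSpec:
    nucleotides: str
    amino_acids: str
    cdr3_interior: str
    cdr3_length: int
    terminating_rule: str        # "J-motif" or "conserved-Trp-fallback"
    start: int                   # oriented-query coordinate of the Cys codon
    end: int                     # exclusive; first position of the motif/Trp


@dataclass
class RegionMap:
    regions: dict[str, tuple[int, int]]
    frame: int
    productive: bool
    stop_codon_found: bool
    junction: JunctionSpec | None = None
    breakpoint_window: tuple[int, int] = (0, 0)
    qcols: np.ndarray | None = field(default=None, repr=False)


def _ungapped_with_cols(row: str, offset: int) -> tuple[str, np.ndarray]:
    seq, cols = [], []
    for col, ch in enumerate(row):
        if ch not in "-.":
            seq.append(ch)
            cols.append(col + offset)
    return "".join(seq), np.array(cols, dtype=np.int64)


def build_templates(bundle: ReferenceBundle) -> list[Template]:
    """MRCA(V)+MRCA(J) plus all *01 V x *01 J concatenations."""
    vC = bundle.v_alignment.column_count
    out: list[Template] = []

    def add(name: str, v_name: str, j_name: str, vrow: str, jrow: str) -> None:
        vs, vcols = _ungapped_with_cols(vrow, 0)
        js, jcols = _ungapped_with_cols(jrow, vC)
        out.append(
            Template(
                name=name, v_name=v_name, j_name=j_name, seq=vs + js,
                colmap=np.concatenate([vcols, jcols]), v_len=len(vs),
            )
        )

    add("MRCA", "MRCA", "MRCA", bundle.v_ancestors.mrca, bundle.j_ancestors.mrca)
    for v in bundle.primary_v:
        for j in bundle.primary_j:
            add(f"{v}+{j}", v, j,
                bundle.v_alignment.rows[v], bundle.j_alignment.rows[j])
    return out


def _aligner(scoring: dict) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = scoring["match"]
    al.mismatch_score = scoring["mismatch"]
    al.open_gap_score = scoring["gap_open"]
    al.extend_gap_score = scoring["gap_extend"]
    return al


def codon_align_query(
    query: str,
    template: Template,
    scoring: dict | None = None,
    both_strands: bool = True,
) -> PairwiseMap:
    """Best local alignment of the query against one template (both strands)."""
    if not query:
        raise MappingError("empty query")
    scoring = scoring or DEFAULT_SCORING
    al = _aligner(scoring)
    best = None
    strands = [("+", query.upper())]
    if both_strands:
        strands.append(("-", reverse_complement(query.upper())))
    for orient, q in strands:
        res = al.align(template.seq, q)
        score = res.score
        if best is None or score > best[0] or (
            score == best[0] and orient == "+"
        ):
            best = (score, orient, q, res)
    score, orient, q, res = best
    qcols = np.full(len(q), -1, dtype=np.int64)
    aln = res[0]
    tblocks, qblocks = aln.aligned
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        qcols[qs:qe] = template.colmap[ts:te]
    return PairwiseMap(
        template=template, score=float(score), orientation=orient,
        query=q, qcols=qcols, too_short=len(query) < MIN_QUERY_LEN,
    )


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (random Eulerian walk)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])
    # walk greedily; back-track-free walk can strand edges, so retry a few times
    for _ in range(20):
        pool = {a: list(v) for a, v in edges.items()}
        out = [seq[0]]
        node = seq[0]
        ok = True
        for _ in range(len(seq) - 1):
            cand = pool.get(node)
            if not cand:
                ok = False
                break
            nxt = cand.pop(int(rng.integers(0, len(cand))))
            out.append(nxt)
            node = nxt
        if ok:
            return "".join(out)
        for a in edges:
            rng.shuffle(edges[a])
    return "".join(rng.permutation(list(seq)))


class MappingEngine:
    """Maps queries onto a bundle's reference coordinates.

    The unmappable floor is self-calibrated: scores of dinucleotide-shuffled
    copies of the first query form a null distribution, and anything scoring
    below mean + 3 SD of that null is rejected as unmappable.
    """

    def __init__(
        self,
        bundle: ReferenceBundle,
        scoring: dict | None = None,
        n_null: int = 30,
        null_seed: int = 20140240,
    ):
        self.bundle = bundle
        self.scoring = dict(scoring or DEFAULT_SCORING)
        self.templates = build_templates(bundle)
        self._by_name = {t.name: t for t in self.templates}
        self.n_null = n_null
        self._null_rng = np.random.default_rng(null_seed)
        self.floor: float | None = None

    def _calibrate_floor(self, query: str) -> float:
        scores = []
        mrca = self._by_name["MRCA"]
        for _ in range(self.n_null):
            shuf = dinucleotide_shuffle(query, self._null_rng)
            scores.append(
                codon_align_query(shuf, mrca, self.scoring).score
            )
        arr = np.array(scores)
        return float(arr.mean() + 3.0 * arr.std())

    def best_mapping(self, query: str) -> PairwiseMap | None:
        """Arg-max mapping over all templates; None when unmappable.

        The read's orientation is settled once against the MRCA template
        (both strands); the *01 x *01 panel is then scanned on that strand
        only, unless the two MRCA strand scores are too close to call.
        """
        if self.floor is None:
            self.floor = self._calibrate_floor(query)
        mrca = codon_align_query(query, self._by_name["MRCA"], self.scoring)
        rc_gap = abs(
            codon_align_query(
                query, self._by_name["MRCA"], self.scoring, both_strands=False
            ).score - mrca.score
        )
        settled = rc_gap > 0.1 * max(abs(mrca.score), 1.0) or mrca.orientation == "+"
        oriented = mrca.query if settled else None
        best: PairwiseMap | None = mrca
        for t in sorted(self.templates, key=lambda t: t.name):
            if t.name == "MRCA":
                continue
            if oriented is not None:
                m = codon_align_query(oriented, t, self.scoring,
                                      both_strands=False)
                m.orientation = mrca.orientation
            else:
                m = codon_align_query(query, t, self.scoring)
            if m.score > best.score or (
                m.score == best.score and m.template.name < best.template.name
            ):
                best = m
        if best is None or best.score < self.floor:
            return None
        return best

    def segment_regions(self, pmap: PairwiseMap) -> RegionMap:
        return segment_regions(pmap, self.bundle)


def _interval_for_cols(qcols: np.ndarray, lo: int, hi: int) -> tuple[int, int] | None:
    idx = np.nonzero((qcols >= lo) & (qcols < hi))[0]
    if idx.size == 0:
        return None
    return int(idx.min()), int(idx.max()) + 1


def _query_pos_of_col(qcols: np.ndarray, col: int) -> int | None:
    idx = np.nonzero(qcols == col)[0]
    return int(idx[0]) if idx.size else None


def _translate(seq: str) -> str:
    usable = seq[: len(seq) - len(seq) % 3]
    if not usable:
        return ""
    return str(Seq(usable).translate())


def segment_regions(pmap: PairwiseMap, bundle: ReferenceBundle) -> RegionMap:
    """Transfer reference region boundaries onto oriented query coordinates."""
    vC = bundle.v_alignment.column_count
    jC = bundle.j_alignment.column_count
    qcols = pmap.qcols
    regions: dict[str, tuple[int, int]] = {}
    for name in V_REGION_NAMES:
        a, b = bundle.v_alignment.boundaries[name]
        iv = _interval_for_cols(qcols, a, b)
        if iv is not None:
            regions[name] = iv
    j_iv = _interval_for_cols(qcols, vC, vC + jC)
    if j_iv is not None:
        regions["Jregion"] = j_iv

    # locate the FW3 3' cysteine codon on the query
    fr3 = bundle.v_alignment.boundaries["FR3"]
    qs = _query_pos_of_col(qcols, fr3[1] - 3)
    junction = None
    rule = None
    qe = None
    frame = 0
    if qs is not None:
        frame = qs % 3
        j_lo = j_iv[0] if j_iv else len(pmap.query)
        # scan the codon grid anchored at the cysteine for the joining motif
        aa = _translate(pmap.query[qs:])
        for m in J_MOTIF_RE.finditer(aa):
            pos = qs + 3 * m.start()
            if pos >= j_lo:
                qe, rule = pos, "J-motif"
                break
        if qe is None and bundle.j_alignment.trp_col is not None:
            qw = _query_pos_of_col(qcols, vC + bundle.j_alignment.trp_col)
            if qw is not None:
                qe, rule = qw, "conserved-Trp-fallback"
    stop_found = False
    productive = False
    if qs is not None and qe is not None and qe > qs:
        nt = pmap.query[qs:qe]
        aa = _translate(nt)
        in_frame = (qe - qs) % 3 == 0
        # stop scan across the whole mapped read in the anchored frame
        mapped = np.nonzero(qcols >= 0)[0]
        lo = int(mapped.min()) if mapped.size else qs
        start = qs - 3 * ((qs - lo) // 3)
        full_aa = _translate(pmap.query[start:])
        stop_found = "*" in full_aa
        productive = in_frame and not stop_found
        interior = _translate(nt[3:]) if in_frame else ""
        junction = JunctionSpec(
            nucleotides=nt,
            amino_acids=aa,
            cdr3_interior=interior,
            cdr3_length=len(interior),
            terminating_rule=rule,
            start=qs,
            end=qe,
        )
        regions["junction"] = (qs, qe)

    # breakpoint search window: 30 nt upstream of the cysteine codon to the
    # first J-aligned query position
    if qs is not None:
        lo = max(0, qs - 30)
    else:
        lo = 0
    hi = j_iv[0] if j_iv else len(pmap.query)
    if hi <= lo:
        hi = lo + 1
    return RegionMap(
        regions=regions,
        frame=frame,
        productive=productive,
        stop_codon_found=stop_found,
        junction=junction,
        breakpoint_window=(lo, hi),
        qcols=qcols,
    )


def extract_junction(
    regionmap: RegionMap, query: str, bundle: ReferenceBundle
) -> JunctionSpec | None:
    """Junction of an already segmented read (None when FR3 was not located)."""
    return regionmap.junction
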