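"""Reference bundle construction and serialization.

A :class:`ReferenceBundle` is the immutable input to classification: aligned,
deduplicated germline V and J sets, labelled trees with fitted GTR models and
ML branch lengths, joint-ML ancestral sequences for every internal node, and
the D allele dictionary (forward plus reverse-complement entries).  Bundles
serialize to a single canonical JSON container and round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from . import phylo
from .ancestors import ancestor_strings, reconstruct_ancestors
from .gtr import GTRModel, encode_sequence
from .io_imgt import DedupeResult, GermlineAllele, dedupe_alleles
from .nomenclature import parse_allele_name
from .trees import Tree, TreeError, label_internal_nodes, nj_tree, root_for_families

SCHEMA_VERSION = 1
V_REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3")
J_MOTIF_RE = re.compile(r"[FW]G.G")


class BundleError(ValueError):
    pass


@dataclass
class ReferenceAlignment:
    """Gapped reference alignment for one region (V or J)."""

    region: str
    rows: dict[str, str]
    boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)  # V only
    trp_col: int | None = None          # J only: conserved Trp codon start column
    motif_cols: tuple[int, int] | None = None  # J only: [FW]G.G column span
    frame: int = 0                      # column offset of the first full codon

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise BundleError(f"{self.region} alignment rows differ in length")
        if self.region == "V":
            if self.column_count % 3 != 0:
                raise BundleError("V alignment length must be a codon multiple")
            for nm, (a, b) in self.boundaries.items():
                if not (0 <= a < b <= self.column_count):
                    raise BundleError(f"bad boundary {nm}: {(a, b)}")
            ivs = [self.boundaries[n] for n in V_REGION_NAMES if n in self.boundaries]
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if b1 > a2:
                    raise BundleError("region boundaries overlap or out of order")

    @property
    def column_count(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, name: str) -> str:
        return self.rows[name].replace("-", "").replace(".", "")

    def encoded(self, name: str) -> np.ndarray:
        return encode_sequence(self.rows[name])

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "rows": self.rows,
            "boundaries": {k: list(v) for k, v in self.boundaries.items()},
            "trp_col": self.trp_col,
            "motif_cols": list(self.motif_cols) if self.motif_cols else None,
            "frame": self.frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceAlignment":
        return cls(
            region=d["region"],
            rows=dict(d["rows"]),
            boundaries={k: tuple(v) for k, v in d["boundaries"].items()},
            trp_col=d.get("trp_col"),
            motif_cols=tuple(d["motif_cols"]) if d.get("motif_cols") else None,
            frame=d.get("frame", 0),
        )


@dataclass
class AncestorSet:
    """Joint-ML sequences for internal nodes, in alignment coordinates."""

    sequences: dict[int, str]   # node id -> gapped sequence
    mrca: str                   # root sequence

    def to_dict(self) -> dict:
        return {"sequences": {str(k): v for k, v in self.sequences.items()},
                "mrca": self.mrca}

    @classmethod
    def from_dict(cls, d: dict) -> "AncestorSet":
        return cls(
            sequences={int(k): v for k, v in d["sequences"].items()},
            mrca=d["mrca"],
        )


@dataclass
class ReferenceBundle:
    v_alignment: ReferenceAlignment
    j_alignment: ReferenceAlignment
    v_tree: Tree
    j_tree: Tree
    v_model: GTRModel
    j_model: GTRModel
    v_ancestors: AncestorSet
    j_ancestors: AncestorSet
    d_alleles: dict[str, dict]   # name -> {"sequence", "inverted", "partner"}
    primary_v: list[str]
    primary_j: list[str]
    primary_d: list[str]
    synonyms: dict[str, str]
    provenance: str = ""
    config: dict = field(default_factory=dict)

    # -- convenience ---------------------------------------------------

    def d_forward(self) -> dict[str, str]:
        return {k: v["sequence"] for k, v in self.d_alleles.items()
                if not v["inverted"]}

    def representative(self, name: str) -> str:
        return self.synonyms.get(name, name)

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "provenance": self.provenance,
            "config": self.config,
            "v": {
                "alignment": self.v_alignment.to_dict(),
                "tree": self.v_tree.to_dict(),
                "model": self.v_model.to_dict(),
                "ancestors": self.v_ancestors.to_dict(),
            },
            "j": {
                "alignment": self.j_alignment.to_dict(),
                "tree": self.j_tree.to_dict(),
                "model": self.j_model.to_dict(),
                "ancestors": self.j_ancestors.to_dict(),
            },
            "d": self.d_alleles,
            "primary": {"V": self.primary_v, "J": self.primary_j,
                        "D": self.primary_d},
            "synonyms": self.synonyms,
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "ReferenceBundle":
        d = json.loads(text)
        if d.get("schema_version") != SCHEMA_VERSION:
            raise BundleError("unsupported bundle schema version")
        return cls(
            v_alignment=ReferenceAlignment.from_dict(d["v"]["alignment"]),
            j_alignment=ReferenceAlignment.from_dict(d["j"]["alignment"]),
            v_tree=Tree.from_dict(d["v"]["tree"]),
            j_tree=Tree.from_dict(d["j"]["tree"]),
            v_model=GTRModel.from_dict(d["v"]["model"]),
            j_model=GTRModel.from_dict(d["j"]["model"]),
            v_ancestors=AncestorSet.from_dict(d["v"]["ancestors"]),
            j_ancestors=AncestorSet.from_dict(d["j"]["ancestors"]),
            d_alleles=d["d"],
            primary_v=d["primary"]["V"],
            primary_j=d["primary"]["J"],
            primary_d=d["primary"]["D"],
            synonyms=d["synonyms"],
            provenance=d["provenance"],
            config=d["config"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ReferenceBundle":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()[:12]


# -- construction ------------------------------------------------------


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _encoded_matrix(tree: Tree, alignment: ReferenceAlignment) -> np.ndarray:
    states = np.full((tree.n_nodes, alignment.column_count), 4, dtype=np.int8)
    index = tree.leaf_index()
    for name in alignment.rows:
        if name not in index:
            raise BundleError(f"alignment row {name} missing from tree")
        states[index[name]] = alignment.encoded(name)
    return states


def _region_tree(
    alignment: ReferenceAlignment, newick: str | None
) -> tuple[Tree, GTRModel]:
    names = sorted(alignment.rows)
    if newick is not None:
        tree = Tree.from_newick(newick)
        leaf_names = {tree.labels[i] for i in tree.leaves}
        missing = set(names) ^ leaf_names
        if missing:
            raise BundleError(
                f"tree/alignment label mismatch for {alignment.region}: "
                f"{sorted(missing)}"
            )
    else:
        if len(names) < 3:
            raise BundleError(f"need >=3 {alignment.region} sequences for NJ")
        from .gtr import ml_pairwise_distance

        base = GTRModel.jukes_cantor()
        enc = {n: alignment.encoded(n) for n in names}
        D = np.zeros((len(names), len(names)))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                D[i, j] = D[j, i] = ml_pairwise_distance(
                    enc[names[i]], enc[names[j]], base
                )
        tree = nj_tree(names, D)
        tree = root_for_families(tree)
    states = _encoded_matrix(tree, alignment)
    uniq, weights = phylo.compress_columns(states)
    model, history = phylo.fit_gtr(tree, uniq, weights)
    if any(b < a - 1e-6 for a, b in zip(history, history[1:])):
        raise BundleError("reference model fit log-likelihood decreased")
    label_internal_nodes(tree)
    return tree, model


def _find_j_motif(alignment: ReferenceAlignment) -> tuple[int, tuple[int, int], int]:
    """Locate the conserved [FW]G.G motif columns and reading frame."""
    rows = [r for r in alignment.rows.values()]
    if any("-" in r or "." in r for r in rows):
        raise BundleError("gapped J alignments are not supported for motif scan")
    best = None
    for frame in range(3):
        positions = []
        for row in rows:
            aa = str(Seq(row[frame:len(row) - (len(row) - frame) % 3]).translate())
            m = J_MOTIF_RE.search(aa)
            if m:
                positions.append(frame + 3 * m.start())
        if positions:
            vals, counts = np.unique(positions, return_counts=True)
            cand = (int(counts.max()), frame, int(vals[counts.argmax()]))
            if best is None or cand[0] > best[0]:
                best = cand
    if best is None or best[0] < max(1, int(0.8 * len(rows))):
        raise BundleError("no conserved [FW]G.G motif found in J alignment")
    _, frame, start = best
    return start, (start, start + 12), frame


def build_bundle(
    v_alleles: list[GermlineAllele],
    j_alleles: list[GermlineAllele],
    d_alleles: list[GermlineAllele],
    v_rows: dict[str, str],
    j_rows: dict[str, str],
    v_boundaries: dict[str, tuple[int, int]],
    v_tree_newick: str | None = None,
    j_tree_newick: str | None = None,
    provenance: str = "",
    config: dict | None = None,
) -> ReferenceBundle:
    """Assemble a :class:`ReferenceBundle` from parsed references.

    ``v_rows``/``j_rows`` are gapped alignment rows (the IMGT reference
    directories are pre-aligned; the synthetic generator emits aligned rows).
    Trees may be supplied as newick; the fallback is neighbor joining on ML
    pairwise distances, rooted to keep families monophyletic, followed by a
    GTR + branch-length fit on the fixed topology.
    """
    config = dict(config or {})
    synonyms: dict[str, str] = {}
    keep: dict[str, list[GermlineAllele]] = {}
    for region, alleles in (("V", v_alleles), ("J", j_alleles), ("D", d_alleles)):
        if not alleles:
            raise BundleError(f"no {region} alleles supplied")
        res = dedupe_alleles(alleles)
        synonyms.update(res.synonyms)
        keep[region] = res.retained

    def _aligned_rows(region: str, rows: dict[str, str]) -> dict[str, str]:
        out = {}
        for al in keep[region]:
            if al.name.full not in rows:
                raise BundleError(f"no alignment row for {al.name.full}")
            out[al.name.full] = rows[al.name.full].upper().replace(".", "-")
        return out

    v_aln = ReferenceAlignment(
        region="V", rows=_aligned_rows("V", v_rows), boundaries=dict(v_boundaries)
    )
    j_aln = ReferenceAlignment(region="J", rows=_aligned_rows("J", j_rows))
    trp, motif, frame = _find_j_motif(j_aln)
    j_aln.trp_col, j_aln.motif_cols, j_aln.frame = trp, motif, frame

    v_tree, v_model = _region_tree(v_aln, v_tree_newick)
    j_tree, j_model = _region_tree(j_aln, j_tree_newick)

    def _ancestors(tree: Tree, aln: ReferenceAlignment, model: GTRModel) -> AncestorSet:
        states = _encoded_matrix(tree, aln)
        anc = reconstruct_ancestors(tree, states, model)
        strings = ancestor_strings(anc)
        return AncestorSet(sequences=strings, mrca=strings[tree.root])

    v_anc = _ancestors(v_tree, v_aln, v_model)
    j_anc = _ancestors(j_tree, j_aln, j_model)

    d_dict: dict[str, dict] = {}
    for al in keep["D"]:
        d_dict[al.name.full] = {
            "sequence": al.sequence, "inverted": False, "partner": al.name.full,
        }
        d_dict[al.name.full + "|inv"] = {
            "sequence": reverse_complement(al.sequence),
            "inverted": True,
            "partner": al.name.full,
        }

    def _primary(region: str) -> list[str]:
        return sorted(
            al.name.full for al in keep[region]
            if parse_allele_name(al.name.full).allele == "01"
        )

    return ReferenceBundle(
        v_alignment=v_aln,
        j_alignment=j_aln,
        v_tree=v_tree,
        j_tree=j_tree,
        v_model=v_model,
        j_model=j_model,
        v_ancestors=v_anc,
        j_ancestors=j_anc,
        d_alleles=d_dict,
        primary_v=_primary("V"),
        primary_j=_primary("J"),
        primary_d=_primary("D"),
        synonyms=synonyms,
        provenance=provenance,
        config=config,
    )
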