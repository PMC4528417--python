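"""Synthetic germline reference generator.

Produces small, fully specified germline V/D/J sets with the structural
features the classifier depends on: V families of related genes and alleles
with a known phylogeny-like hierarchy, codon-clean V sequences ending in the
conserved FR3 cysteine, J segments carrying the [FW]G.G joining motif and a
TVSS tail, and short D segments organised into families with near-identical
members (the realistic source of D-call ambiguity).  Everything is seeded and
deterministic, so reference bundles, simulated repertoires and ground truth
can be regenerated from a single integer.

The default shape (4 V families x 3 genes x 2 alleles, 10 D genes, 3 J genes
x 2 alleles) is chosen to mirror, at reduced scale, the hierarchical
structure of the human IGH locus while keeping exhaustive placement oracles
tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_imgt import GermlineAllele
from .nomenclature import parse_allele_name
from .reference import ReferenceBundle, build_bundle

_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# V region layout in codons: FR1 25, CDR1 8, FR2 17, CDR2 8, FR3 40
_V_CODONS = {"FR1": 25, "CDR1": 8, "FR2": 17, "CDR2": 8, "FR3": 40}


def v_region_boundaries() -> dict[str, tuple[int, int]]:
    out, pos = {}, 0
    for name, ncod in _V_CODONS.items():
        out[name] = (pos, pos + 3 * ncod)
        pos += 3 * ncod
    return out


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_CODONS[i] for i in rng.integers(0, len(_CODONS), n)]


def _mutate_codons(
    codons: list[str], n_mut: int, rng: np.random.Generator,
    frozen: set[int] = frozenset(),
) -> list[str]:
    """Introduce ~n_mut point mutations, never creating stops or touching
    frozen codon indices."""
    out = list(codons)
    done = 0
    attempts = 0
    while done < n_mut and attempts < 50 * n_mut + 100:
        attempts += 1
        ci = int(rng.integers(0, len(out)))
        if ci in frozen:
            continue
        pos = int(rng.integers(0, 3))
        old = out[ci]
        base = "ACGT"[int(rng.integers(0, 4))]
        cand = old[:pos] + base + old[pos + 1:]
        if cand == old or cand in ("TAA", "TAG", "TGA"):
            continue
        out[ci] = cand
        done += 1
    return out


@dataclass
class SyntheticReference:
    v_alleles: list[GermlineAllele]
    d_alleles: list[GermlineAllele]
    j_alleles: list[GermlineAllele]
    v_rows: dict[str, str]
    j_rows: dict[str, str]
    v_boundaries: dict[str, tuple[int, int]]

    def to_fasta(self, region: str) -> str:
        """IMGT-dialect FASTA (pipe headers, '.' alignment gaps for V)."""
        recs = {"V": self.v_alleles, "D": self.d_alleles, "J": self.j_alleles}[region]
        rows = {"V": self.v_rows, "J": self.j_rows}.get(region, {})
        out = []
        for i, al in enumerate(recs):
            seq = rows.get(al.name.full, al.sequence).replace("-", ".")
            out.append(
                f">Z{i:05d}|{al.name.full}|Synthetica exempli|{al.functionality}|"
                f"{al.region}-REGION|1..{len(seq)}|{len(seq)} nt|1| | | | |"
                f"{len(seq)}+0=={len(seq)}| | |\n{seq}"
            )
        return "\n".join(out) + "\n"


def synthetic_reference(
    seed: int = 0,
    n_families: int = 4,
    genes_per_family: int = 3,
    alleles_per_gene: int = 2,
    n_d_genes: int = 10,
    n_j_genes: int = 3,
    j_alleles_per_gene: int = 2,
    family_mut: int = 22,
    gene_mut: int = 9,
    allele_mut: int = 2,
) -> SyntheticReference:
    """Generate a seeded synthetic germline reference set."""
    rng = np.random.default_rng(seed)
    bounds = v_region_boundaries()
    ncod = sum(_V_CODONS.values())
    cys_idx = ncod - 1  # conserved FR3 3' cysteine is the last V codon

    ancestor = _random_codons(rng, ncod)
    ancestor[cys_idx] = "TGT"
    frozen = {cys_idx}

    v_alleles: list[GermlineAllele] = []
    v_rows: dict[str, str] = {}
    seen: set[str] = set()
    # one family carries a one-codon CDR1 deletion so the V alignment is gapped
    del_family = 2 if n_families >= 2 else -1
    del_codon = bounds["CDR1"][0] // 3 + 3
    for fam in range(1, n_families + 1):
        fam_codons = _mutate_codons(ancestor, family_mut, rng, frozen)
        for gene in range(1, genes_per_family + 1):
            gene_codons = _mutate_codons(fam_codons, gene_mut, rng, frozen)
            for allele in range(1, alleles_per_gene + 1):
                cod = (
                    list(gene_codons) if allele == 1
                    else _mutate_codons(gene_codons, allele_mut, rng, frozen)
                )
                if fam == del_family:
                    cod = list(cod)
                    cod[del_codon] = "---"
                row = "".join(cod)
                seq = row.replace("-", "")
                if seq in seen:  # keep the set duplicate-free
                    cod = _mutate_codons(cod, 1, rng, frozen | {del_codon})
                    row = "".join(cod)
                    seq = row.replace("-", "")
                seen.add(seq)
                name = f"IGHV{fam}-{gene}*{allele:02d}"
                v_alleles.append(
                    GermlineAllele(
                        name=parse_allele_name(name), region="V",
                        functionality="F", sequence=seq,
                    )
                )
                v_rows[name] = row

    # D segments: 3 families, genes within a family differ by only a few bases
    d_alleles: list[GermlineAllele] = []
    d_seen: set[str] = set()
    fam_seeds = {}
    for g in range(1, n_d_genes + 1):
        fam = (g - 1) % 3 + 1
        if fam not in fam_seeds:
            fam_seeds[fam] = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(14, 22)))
            )
        base = fam_seeds[fam]
        n_alleles = 2 if g % 3 == 0 else 1
        gene_seq = None
        for a in range(1, n_alleles + 1):
            src = base if a == 1 else gene_seq
            seq = list(src)
            for _ in range(int(rng.integers(2, 5)) if a == 1 else 1):
                p = int(rng.integers(0, len(seq)))
                seq[p] = "ACGT"[int(rng.integers(0, 4))]
            s = "".join(seq)
            while s in d_seen:
                p = int(rng.integers(0, len(s)))
                s = s[:p] + "ACGT"[int(rng.integers(0, 4))] + s[p + 1:]
            d_seen.add(s)
            if a == 1:
                gene_seq = s
            name = f"IGHD{fam}-{g}*{a:02d}"
            d_alleles.append(
                GermlineAllele(
                    name=parse_allele_name(name), region="D",
                    functionality="F", sequence=s,
                )
            )

    # J segments: 7 variable 5' codons + WGQG motif + TTVTVSS tail (frame 0)
    tail = ["ACC", "ACT", "GTC", "ACC", "GTC", "TCC", "TCA"]  # T T V T V S S
    motif = ["TGG", "GGC", "CAA", "GGG"]                       # W G Q G
    j_alleles: list[GermlineAllele] = []
    j_rows: dict[str, str] = {}
    j_seen: set[str] = set()
    for g in range(1, n_j_genes + 1):
        head = _random_codons(rng, 7)
        for a in range(1, j_alleles_per_gene + 1):
            cod = (list(head) if a == 1
                   else _mutate_codons(head, 1, rng))
            seq = "".join(cod + motif + tail)
            while seq in j_seen:
                cod = _mutate_codons(cod, 1, rng)
                seq = "".join(cod + motif + tail)
            j_seen.add(seq)
            name = f"IGHJ{g}*{a:02d}"
            j_alleles.append(
                GermlineAllele(
                    name=parse_allele_name(name), region="J",
                    functionality="F", sequence=seq,
                )
            )
            j_rows[name] = seq

    return SyntheticReference(
        v_alleles=v_alleles,
        d_alleles=d_alleles,
        j_alleles=j_alleles,
        v_rows=v_rows,
        j_rows=j_rows,
        v_boundaries=bounds,
    )


def synthetic_bundle(seed: int = 0, **kwargs) -> ReferenceBundle:
    """Build a full reference bundle from a seeded synthetic germline set."""
    ref = synthetic_reference(seed=seed, **kwargs)
    return build_bundle(
        v_alleles=ref.v_alleles,
        j_alleles=ref.j_alleles,
        d_alleles=ref.d_alleles,
        v_rows=ref.v_rows,
        j_rows=ref.j_rows,
        v_boundaries=ref.v_boundaries,
        provenance=f"synthetic-germline seed={seed}",
        config={"seed": seed, **{k: v for k, v in kwargs.items()}},
    )
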