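"""Ground-truth repertoire simulation.

Three generators share one truth record format:

* simple rearrangements — the Cartesian product of primary (*01) V, D and J
  alleles, concatenated with no deletions or N-regions;
* realistic rearrangements — alleles sampled with inverse alleles-per-gene
  weights (so genes, not alleles, are equiprobable), exonuclease deletion
  lengths for the V 3' end, both D ends and the J 5' end plus N1/N2 lengths
  drawn from configurable distributions, N bases from a base-composition
  vector, and three retention filters: no stop codons, a recognisable CDR3,
  and an in-frame J with the [FW]G.G and TVSS motifs;
* clonal families — unmutated rearrangements cloned and independently
  mutated.

Somatic hypermutation follows the S5F scheme: per-position mutability is the
5-mer-context weight (first/last two positions immutable), the mutated base
is drawn from the 5-mer's substitution profile, and weights are recomputed
after every mutation so contexts created by earlier mutations matter.

The shipped default parameter tables are synthetic stand-ins (geometric
deletion/N lengths, uniform composition and S5F); real inferred tables load
from TSV via :func:`load_length_table` / :func:`S5FModel.from_tsv`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .nomenclature import parse_allele_name
from .reference import ReferenceBundle

_STOPS = ("TAA", "TAG", "TGA")
_CODON_TABLE = {}


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    usable = nt[: len(nt) - len(nt) % 3]
    return str(Seq(usable).translate()) if usable else ""


def geometric_lengths(mean: float, max_len: int = 15) -> np.ndarray:
    """Truncated geometric length distribution with the given mean."""
    if mean <= 0:
        probs = np.zeros(max_len + 1)
        probs[0] = 1.0
        return probs
    p = 1.0 / (1.0 + mean)
    k = np.arange(max_len + 1)
    probs = p * (1 - p) ** k
    return probs / probs.sum()


def load_length_table(path) -> np.ndarray:
    """TSV with columns (length, probability) -> probability vector."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["length", "prob"],
                     comment="#")
    n = int(df["length"].max())
    out = np.zeros(n + 1)
    for _, row in df.iterrows():
        out[int(row["length"])] = float(row["prob"])
    if not np.isclose(out.sum(), 1.0, atol=1e-6):
        raise ValueError(f"{path}: probabilities sum to {out.sum():.6f}, not 1")
    return out / out.sum()


@dataclass
class RearrangementParams:
    """Deletion/N-length distributions and sampling weights."""

    del_v3: np.ndarray = field(default_factory=lambda: geometric_lengths(1.0))
    del_d5: np.ndarray = field(default_factory=lambda: geometric_lengths(2.0))
    del_d3: np.ndarray = field(default_factory=lambda: geometric_lengths(2.0))
    del_j5: np.ndarray = field(default_factory=lambda: geometric_lengths(2.0))
    n1_len: np.ndarray = field(default_factory=lambda: geometric_lengths(4.0, 25))
    n2_len: np.ndarray = field(default_factory=lambda: geometric_lengths(4.0, 25))
    n_base_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    cdr3_regex: str = r"C[A-Z]{2,32}W"
    max_attempts: int = 2000

    def __post_init__(self):
        for name in ("del_v3", "del_d5", "del_d3", "del_j5", "n1_len", "n2_len"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} is not a probability vector")
            setattr(self, name, v / v.sum())
        f = np.asarray(self.n_base_freqs, dtype=float)
        if f.shape != (4,) or not np.isclose(f.sum(), 1.0, atol=1e-9):
            raise ValueError("n_base_freqs must be 4 probabilities")
        self.n_base_freqs = f / f.sum()


@dataclass
class S5FModel:
    """5-mer context mutability and substitution profiles."""

    mutability: dict[str, float]
    substitution: dict[str, dict[str, float]]

    def __post_init__(self):
        for ctx, profile in self.substitution.items():
            total = sum(profile.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"substitution row for {ctx} sums to {total}")

    @classmethod
    def uniform(cls) -> "S5FModel":
        """Flat stand-in: every 5-mer equally mutable, uniform substitutions."""
        return cls(mutability={}, substitution={})

    def mutability_of(self, fivemer: str) -> float:
        if not self.mutability:
            return 1.0
        return self.mutability.get(fivemer, 0.0)

    def substitution_of(self, fivemer: str) -> dict[str, float]:
        if not self.substitution:
            centre = fivemer[2]
            others = [b for b in "ACGT" if b != centre]
            return {b: 1.0 / 3.0 for b in others}
        return self.substitution[fivemer]

    @classmethod
    def from_tsv(cls, mutability_path, substitution_path) -> "S5FModel":
        """Load 5-mer tables: (fivemer, mutability) and (fivemer, A, C, G, T)."""
        import pandas as pd

        mut = pd.read_csv(mutability_path, sep="\t", comment="#")
        mutability = dict(zip(mut.iloc[:, 0].str.upper(), mut.iloc[:, 1]))
        sub = pd.read_csv(substitution_path, sep="\t", comment="#")
        substitution = {}
        for _, row in sub.iterrows():
            ctx = str(row.iloc[0]).upper()
            profile = {b: float(row[b]) for b in "ACGT" if float(row[b]) > 0}
            substitution[ctx] = profile
        return cls(mutability=mutability, substitution=substitution)


@dataclass
class TruthRecord:
    read_id: str
    true_v: str
    true_d: str
    true_j: str
    del_v3: int = 0
    del_d5: int = 0
    del_d3: int = 0
    del_j5: int = 0
    n1: str = ""
    n2: str = ""
    n_mutations: int = 0
    clone_id: str | None = None

    def to_row(self) -> dict:
        return {
            "read_id": self.read_id, "v": self.true_v, "d": self.true_d,
            "j": self.true_j, "del_v3": self.del_v3, "del_d5": self.del_d5,
            "del_d3": self.del_d3, "del_j5": self.del_j5, "n1": self.n1,
            "n2": self.n2, "n_mutations": self.n_mutations,
            "clone_id": self.clone_id or "",
        }


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    truth: TruthRecord


def _segment_sets(bundle: ReferenceBundle):
    v = {n: bundle.v_alignment.ungapped(n) for n in bundle.v_alignment.rows}
    j = {n: bundle.j_alignment.ungapped(n) for n in bundle.j_alignment.rows}
    d = bundle.d_forward()
    return v, d, j


def simulate_simple(bundle: ReferenceBundle) -> list[SimulatedRead]:
    """All *01 V x *01 D x *01 J concatenations, no deletions or N-regions."""
    v, d, j = _segment_sets(bundle)
    out = []
    i = 0
    for vn in bundle.primary_v:
        for dn in bundle.primary_d:
            for jn in bundle.primary_j:
                seq = v[vn] + d[dn] + j[jn]
                truth = TruthRecord(
                    read_id=f"simple{i:06d}", true_v=vn, true_d=dn, true_j=jn
                )
                out.append(SimulatedRead(truth.read_id, seq, truth))
                i += 1
    return out


def _inverse_gene_weights(names: list[str]) -> np.ndarray:
    genes = [parse_allele_name(n).gene for n in names]
    counts: dict[str, int] = {}
    for g in genes:
        counts[g] = counts.get(g, 0) + 1
    w = np.array([1.0 / counts[g] for g in genes])
    return w / w.sum()


def passes_filters(sequence: str, cdr3_regex: str) -> bool:
    """The three retention filters on a candidate rearrangement."""
    aa = _translate(sequence)
    if "*" in aa:
        return False
    if not re.search(cdr3_regex, aa):
        return False
    m = re.search(r"[FW]G.G", aa)
    if not m or "TVSS" not in aa[m.start():]:
        return False
    return True


def simulate_rearrangement(
    bundle: ReferenceBundle,
    params: RearrangementParams,
    rng: np.random.Generator,
    read_id: str = "read",
) -> SimulatedRead | None:
    """One realistic rearrangement, or None if no draw passes the filters."""
    v, d, j = _segment_sets(bundle)
    v_names = sorted(v)
    d_names = sorted(d)
    j_names = sorted(j)
    wv = _inverse_gene_weights(v_names)
    wd = _inverse_gene_weights(d_names)
    wj = _inverse_gene_weights(j_names)
    for _ in range(params.max_attempts):
        vn = v_names[rng.choice(len(v_names), p=wv)]
        dn = d_names[rng.choice(len(d_names), p=wd)]
        jn = j_names[rng.choice(len(j_names), p=wj)]
        dv3 = int(rng.choice(len(params.del_v3), p=params.del_v3))
        dd5 = int(rng.choice(len(params.del_d5), p=params.del_d5))
        dd3 = int(rng.choice(len(params.del_d3), p=params.del_d3))
        dj5 = int(rng.choice(len(params.del_j5), p=params.del_j5))
        ln1 = int(rng.choice(len(params.n1_len), p=params.n1_len))
        ln2 = int(rng.choice(len(params.n2_len), p=params.n2_len))
        n1 = "".join("ACGT"[i] for i in
                     rng.choice(4, size=ln1, p=params.n_base_freqs))
        n2 = "".join("ACGT"[i] for i in
                     rng.choice(4, size=ln2, p=params.n_base_freqs))
        vtrim = v[vn][: len(v[vn]) - dv3] if dv3 else v[vn]
        dseq = d[dn]
        dtrim = dseq[dd5: len(dseq) - dd3] if dd3 else dseq[dd5:]
        jtrim = j[jn][dj5:]
        if len(vtrim) < 30 or len(jtrim) < 15:
            continue
        seq = vtrim + n1 + dtrim + n2 + jtrim
        if not passes_filters(seq, params.cdr3_regex):
            continue
        truth = TruthRecord(
            read_id=read_id, true_v=vn, true_d=dn, true_j=jn,
            del_v3=dv3, del_d5=dd5, del_d3=dd3, del_j5=dj5, n1=n1, n2=n2,
        )
        return SimulatedRead(read_id, seq, truth)
    return None


def s5f_mutate(
    sequence: str,
    n_mut: int,
    model: S5FModel,
    rng: np.random.Generator,
) -> str:
    """Introduce exactly n_mut context-weighted substitutions.

    Mutability of the first and last two positions is zero; weights are
    recomputed after every substitution so newly created contexts count.
    Already-mutated positions are excluded from later draws, so the Hamming
    distance to the input equals n_mut exactly.
    """
    seq = list(sequence.upper())
    L = len(seq)
    if n_mut >= L - 4:
        raise ValueError("more mutations requested than mutable positions")
    hit: set[int] = set()
    for _ in range(n_mut):
        weights = np.zeros(L)
        for i in range(2, L - 2):
            if i not in hit:
                weights[i] = model.mutability_of("".join(seq[i - 2:i + 3]))
        total = weights.sum()
        if total <= 0:
            raise ValueError("all-zero mutability; cannot place a mutation")
        pos = int(rng.choice(L, p=weights / total))
        hit.add(pos)
        ctx = "".join(seq[pos - 2:pos + 3])
        profile = model.substitution_of(ctx)
        bases = sorted(b for b in profile if b != seq[pos])
        probs = np.array([profile[b] for b in bases])
        if probs.sum() <= 0:
            continue
        seq[pos] = bases[int(rng.choice(len(bases), p=probs / probs.sum()))]
    return "".join(seq)


def simulate_repertoire(
    bundle: ReferenceBundle,
    params: RearrangementParams,
    n_reads: int,
    n_mut: int,
    seed: int,
    s5f: S5FModel | None = None,
    prefix: str = "sim",
) -> list[SimulatedRead]:
    """n_reads realistic rearrangements, each with n_mut S5F mutations."""
    rng = np.random.default_rng(seed)
    s5f = s5f or S5FModel.uniform()
    out = []
    for i in range(n_reads):
        sim = simulate_rearrangement(bundle, params, rng, f"{prefix}{i:06d}")
        if sim is None:
            raise RuntimeError("simulation filters rejected every attempt")
        if n_mut:
            mutated = s5f_mutate(sim.sequence, n_mut, s5f, rng)
            sim.truth.n_mutations = sum(
                a != b for a, b in zip(sim.sequence, mutated)
            )
            sim = SimulatedRead(sim.read_id, mutated, sim.truth)
        out.append(sim)
    return out


def simulate_clones(
    bundle: ReferenceBundle,
    params: RearrangementParams,
    n_clones: int,
    clone_size: int,
    n_mut: int,
    seed: int,
    s5f: S5FModel | None = None,
) -> list[SimulatedRead]:
    """Clonal families: one rearrangement each, members mutated independently."""
    rng = np.random.default_rng(seed)
    s5f = s5f or S5FModel.uniform()
    out = []
    for c in range(n_clones):
        seed_read = simulate_rearrangement(bundle, params, rng, f"clone{c:03d}")
        if seed_read is None:
            raise RuntimeError("simulation filters rejected every attempt")
        for m in range(clone_size):
            rid = f"clone{c:03d}_{m:03d}"
            seq = seed_read.sequence
            nm = 0
            if n_mut:
                seq = s5f_mutate(seed_read.sequence, n_mut, s5f, rng)
                nm = sum(a != b for a, b in zip(seed_read.sequence, seq))
            truth = TruthRecord(
                read_id=rid, true_v=seed_read.truth.true_v,
                true_d=seed_read.truth.true_d, true_j=seed_read.truth.true_j,
                del_v3=seed_read.truth.del_v3, del_d5=seed_read.truth.del_d5,
                del_d3=seed_read.truth.del_d3, del_j5=seed_read.truth.del_j5,
                n1=seed_read.truth.n1, n2=seed_read.truth.n2,
                n_mutations=nm, clone_id=f"clone{c:03d}",
            )
            out.append(SimulatedRead(rid, seq, truth))
    return out


def write_fasta(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def write_truth(reads: list[SimulatedRead], path) -> None:
    import pandas as pd

    pd.DataFrame([r.truth.to_row() for r in reads]).to_csv(
        path, sep="\t", index=False
    )
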