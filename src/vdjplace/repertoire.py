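"""Repertoire-level analysis: clonal clustering, evaluation, summaries.

Clonal clustering builds a graph whose nodes are reads and whose edges join
reads sharing at least one (V, J) rearrangement between their credible
sets; connected components approximate clonal partitions (the sharing
relation is symmetric, so ordinary — not strongly — connected components
apply).  Evaluation against simulation truth follows the column scheme of
comparative benchmarking tables: per region, the percentage of reads whose
correct allele received the highest model-averaged support (correct_top),
was only in the credible set (correct_in_credible), was missed outright
(wrong, with the wrong-gene subset), received an internal ancestral label
(ancestral), or got no assignment.  Synonymous (sequence-identical) alleles
count as correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .classify import RearrangementCall
from .nomenclature import parse_allele_name

REGIONS = ("V", "D", "J")


# -- clustering --------------------------------------------------------


@dataclass
class ClonalGraph:
    graph: nx.Graph
    components: list  # list[set[str]] sorted by size desc then min id

    @property
    def n_components(self) -> int:
        return len(self.components)


def cluster_by_shared_rearrangement(calls: list[RearrangementCall]) -> ClonalGraph:
    """Edges join reads whose credible sets share a (V, J) pair."""
    g = nx.Graph()
    pair_sets = {}
    for c in calls:
        g.add_node(c.read_id)
        pair_sets[c.read_id] = c.credible_pairs
    # invert: pair -> reads, then clique-connect per pair (linear via star)
    by_pair: dict[tuple, list[str]] = {}
    for rid, pairs in pair_sets.items():
        for p in pairs:
            by_pair.setdefault(p, []).append(rid)
    for reads in by_pair.values():
        reads.sort()
        for other in reads[1:]:
            g.add_edge(reads[0], other)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda s: (-len(s), min(s)))
    return ClonalGraph(graph=g, components=comps)


def aggregate_clone_support(calls: list[RearrangementCall]) -> pd.DataFrame:
    """Mean model-averaged support per (V, J) pair across reads.

    A read contributes its summed Akaike weight for the pair (0 when the
    pair is absent from its credible set).  The modal best assignment and
    its count are included per pair.
    """
    if not calls:
        raise ValueError("no calls to aggregate")
    support: dict[tuple, float] = {}
    best_counts: dict[tuple, int] = {}
    for c in calls:
        for v, j, w in c.credible_set:
            support[(v, j)] = support.get((v, j), 0.0) + w
        key = (c.best_v, c.best_j)
        best_counts[key] = best_counts.get(key, 0) + 1
    rows = [
        {
            "v": v, "j": j,
            "mean_support": s / len(calls),
            "best_count": best_counts.get((v, j), 0),
        }
        for (v, j), s in support.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["mean_support", "v", "j"], ascending=[False, True, True]
    )
    return df.reset_index(drop=True)


# -- evaluation --------------------------------------------------------


@dataclass
class EvaluationTable:
    table: pd.DataFrame          # index region, percentage columns
    denominators: dict[str, int]

    def row(self, region: str) -> pd.Series:
        return self.table.loc[region]

    def to_tsv(self, path) -> None:
        self.table.round(2).to_csv(path, sep="\t")


def _call_level(label: str) -> str:
    return parse_allele_name(label).level


def _is_ancestor_of(label: str, true_allele: str) -> bool:
    lab = parse_allele_name(label)
    tru = parse_allele_name(true_allele)
    if lab.level == "allele":
        return False
    return tru.at_level(lab.level) == label


def evaluate_assignments(
    calls: list[RearrangementCall],
    truth: dict[str, dict],
    synonyms: dict[str, str] | None = None,
    total_reads: int | None = None,
) -> EvaluationTable:
    """Score calls against simulation truth in the benchmark column scheme.

    ``truth`` maps read id -> {"v": allele, "d": allele, "j": allele}.
    Reads present in truth but absent from calls (unmappable) count as
    no_assignment.  D calls count correct when the true allele is in the
    tied top-score set; D has no credible set, so correct_in_credible stays
    0 there.
    """
    synonyms = synonyms or {}
    rep = lambda n: synonyms.get(n, n)
    missing = [c.read_id for c in calls if c.read_id not in truth]
    if missing:
        raise ValueError(f"calls without truth records: {missing[:5]}")
    n_total = total_reads if total_reads is not None else len(truth)
    counts = {
        r: {"correct_top": 0, "correct_in_credible": 0, "wrong": 0,
            "wrong_gene": 0, "ancestral": 0, "no_assignment": 0}
        for r in REGIONS
    }
    called_ids = set()
    for c in calls:
        called_ids.add(c.read_id)
        t = truth[c.read_id]
        # V and J: model-averaged best label vs truth
        for region, best, credible_labels in (
            ("V", c.best_v, {v for v, _, _ in c.credible_set}),
            ("J", c.best_j, {j for _, j, _ in c.credible_set}),
        ):
            true_allele = rep(t[region.lower()])
            bucket = counts[region]
            if rep(best) == true_allele:
                bucket["correct_top"] += 1
            elif _is_ancestor_of(best, true_allele):
                bucket["ancestral"] += 1
            elif any(rep(l) == true_allele for l in credible_labels):
                bucket["correct_in_credible"] += 1
            else:
                bucket["wrong"] += 1
                if _call_level(best) == "allele" and (
                    parse_allele_name(best).gene
                    != parse_allele_name(true_allele).gene
                ):
                    bucket["wrong_gene"] += 1
        # D: tied top-score set
        true_d = rep(t["d"])
        bucket = counts["D"]
        if not c.d_call.assigned:
            bucket["no_assignment"] += 1
        elif any(rep(n) == true_d for n in c.d_call.names):
            bucket["correct_top"] += 1
        else:
            bucket["wrong"] += 1
            if all(
                parse_allele_name(n).gene != parse_allele_name(true_d).gene
                for n in c.d_call.names
            ):
                bucket["wrong_gene"] += 1
    absent = n_total - len(called_ids)
    for r in REGIONS:
        counts[r]["no_assignment"] += absent
    rows = {}
    for r in REGIONS:
        b = counts[r]
        rows[r] = {k: 100.0 * v / max(n_total, 1) for k, v in b.items()}
        # headline "correct": top assignment right, or right-but-outweighed
        rows[r]["correct"] = (
            rows[r]["correct_top"] + rows[r]["correct_in_credible"]
        )
    table = pd.DataFrame(rows).T[
        ["correct", "correct_top", "correct_in_credible", "ancestral",
         "wrong", "wrong_gene", "no_assignment"]
    ]
    return EvaluationTable(table=table, denominators={r: n_total for r in REGIONS})


# -- summaries ---------------------------------------------------------


def summarize_repertoire(calls: list[RearrangementCall]) -> dict:
    """Hierarchical frequency tables, CDR3-length histogram, productivity."""
    if not calls:
        raise ValueError("no calls to summarize")
    n = len(calls)

    def freq_tables(labels: list[str]) -> dict:
        fam: dict[str, float] = {}
        gene: dict[str, float] = {}
        allele: dict[str, float] = {}
        for lab in labels:
            p = parse_allele_name(lab)
            fam[p.family] = fam.get(p.family, 0.0) + 1.0 / n
            if p.level in ("gene", "allele"):
                gene[p.gene] = gene.get(p.gene, 0.0) + 1.0 / n
            if p.level == "allele":
                allele[lab] = allele.get(lab, 0.0) + 1.0 / n
        return {"family": fam, "gene": gene, "allele": allele}

    cdr3_hist: dict[int, int] = {}
    for c in calls:
        if c.junction is not None and c.junction.cdr3_length:
            L = c.junction.cdr3_length
            cdr3_hist[L] = cdr3_hist.get(L, 0) + 1
    pair_freq: dict[str, float] = {}
    for c in calls:
        key = f"{c.best_v}|{c.best_j}"
        pair_freq[key] = pair_freq.get(key, 0.0) + 1.0 / n
    return {
        "n_reads": n,
        "productive_fraction": sum(c.productive for c in calls) / n,
        "v": freq_tables([c.best_v for c in calls]),
        "j": freq_tables([c.best_j for c in calls]),
        "rearrangements": pair_freq,
        "cdr3_length_histogram": {str(k): v for k, v in sorted(cdr3_hist.items())},
    }


def credible_set_sizes(calls: list[RearrangementCall], region: str = "V") -> np.ndarray:
    """Number of distinct region labels in each read's credible set."""
    out = []
    for c in calls:
        if region == "V":
            out.append(len({v for v, _, _ in c.credible_set}))
        else:
            out.append(len({j for _, j, _ in c.credible_set}))
    return np.array(out)
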