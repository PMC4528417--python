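"""Per-read classification: model-averaged rearrangement calls.

After the search, every evaluated model's Akaike weight is summed by the
(V label, J label) pair of its attachment branches.  The pair with the
highest total weight is reported as the inferred rearrangement; every other
pair reaching at least 0.01 total weight joins the credible set.  Marginal
per-region supports (summing over the other region) are reported alongside.
Labels are branch labels, so a read may legitimately be assigned to an
internal (gene- or family-level) node when the data cannot resolve an
allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chc import GAConfig, chc_search, exhaustive_search
from .dregion import DCall, DEFAULT_D_SCORING, DEFAULT_MIN_SCORE, assign_d
from .mapping import JunctionSpec, MappingEngine, RegionMap
from .placement import ModelPopulation, PlacementEngine
from .reference import ReferenceBundle

CREDIBLE_THRESHOLD = 0.01


@dataclass
class RearrangementCall:
    read_id: str
    best_v: str
    best_j: str
    v_support: float
    j_support: float
    rearrangement_support: float
    credible_set: list          # [(v_label, j_label, weight)], weight >= 0.01
    d_call: DCall
    junction: JunctionSpec | None
    productive: bool
    orientation: str
    mapping_score: float
    n_models: int = 0
    converged: bool = True
    v_marginals: dict = field(default_factory=dict)
    j_marginals: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)  # 0-based half-open intervals
    frame: int = 0

    @property
    def credible_pairs(self) -> set:
        return {(v, j) for v, j, _ in self.credible_set}

    def to_record(self) -> dict:
        return {
            "read_id": self.read_id,
            "best_v": self.best_v,
            "best_j": self.best_j,
            "v_support": round(self.v_support, 6),
            "j_support": round(self.j_support, 6),
            "rearrangement_support": round(self.rearrangement_support, 6),
            "d_call": self.d_call.tsv_field(),
            "cdr3_aa": self.junction.cdr3_interior if self.junction else "",
            "cdr3_length": self.junction.cdr3_length if self.junction else 0,
            "junction_nt": self.junction.nucleotides if self.junction else "",
            "productive": self.productive,
            "orientation": self.orientation,
            "frame": self.frame,
            # reported 1-based inclusive, in oriented-query coordinates
            "regions": ";".join(
                f"{name}:{a + 1}-{b}" for name, (a, b) in self.regions.items()
            ),
            "n_models": self.n_models,
            "credible_set": [
                {"v": v, "j": j, "weight": round(w, 6)}
                for v, j, w in self.credible_set
            ],
            "v_marginals": {k: round(v, 6) for k, v in
                            sorted(self.v_marginals.items()) if v >= 1e-6},
            "j_marginals": {k: round(v, 6) for k, v in
                            sorted(self.j_marginals.items()) if v >= 1e-6},
        }


@dataclass
class UnmappableRead:
    read_id: str
    reason: str


_ENDPOINT_TOL = 1e-6


def call_rearrangement(
    population: ModelPopulation,
    v_labels: dict[int, str],
    j_labels: dict[int, str],
    v_parent_labels: dict[int, str] | None = None,
    j_parent_labels: dict[int, str] | None = None,
) -> tuple[str, str, float, list, dict, dict]:
    """Sum model weights by (V label, J label); arg-max plus credible set.

    A model whose fitted parent-side length is zero places the query exactly
    at the branch's parent node, so — by the same reasoning that lets a
    zero-length branch propagate its label — it is labelled by that node
    rather than by the branch.  This stops one geometric placement from
    splitting its weight across the labels of the branches meeting there.
    """
    def label(branch, t_parent, labels, parent_labels):
        if parent_labels is not None and t_parent <= _ENDPOINT_TOL:
            return parent_labels.get(branch) or labels[branch]
        return labels[branch]

    pair_w: dict[tuple[str, str], float] = {}
    for m in population.models:
        key = (
            label(m.v_branch, m.fitted_lengths[1], v_labels, v_parent_labels),
            label(m.j_branch, m.fitted_lengths[4], j_labels, j_parent_labels),
        )
        pair_w[key] = pair_w.get(key, 0.0) + m.weight
    # deterministic arg-max: weight desc, then lexicographic label order
    ranked = sorted(pair_w.items(), key=lambda kv: (-kv[1], kv[0]))
    (best_v, best_j), support = ranked[0]
    credible = [
        (v, j, w) for (v, j), w in ranked if w >= CREDIBLE_THRESHOLD
    ]
    v_marg: dict[str, float] = {}
    j_marg: dict[str, float] = {}
    for (v, j), w in pair_w.items():
        v_marg[v] = v_marg.get(v, 0.0) + w
        j_marg[j] = j_marg.get(j, 0.0) + w
    return best_v, best_j, support, credible, v_marg, j_marg


class Classifier:
    """End-to-end read classification against a reference bundle."""

    def __init__(
        self,
        bundle: ReferenceBundle,
        seed: int = 0,
        ga_config: GAConfig | None = None,
        exhaustive: bool = False,
        d_scoring: dict | None = None,
        d_min_score: float = DEFAULT_MIN_SCORE,
    ):
        self.bundle = bundle
        self.seed = seed
        self.ga_config = ga_config or GAConfig()
        self.exhaustive = exhaustive
        self.d_scoring = dict(d_scoring or DEFAULT_D_SCORING)
        self.d_min_score = d_min_score
        self.mapper = MappingEngine(bundle)
        self.placer = PlacementEngine(bundle)

    def _read_seed(self, read_id: str) -> int:
        # stable per-read stream derived from the run seed
        h = 0
        for ch in read_id:
            h = (h * 131 + ord(ch)) % (2**31 - 1)
        return (self.seed * 1_000_003 + h) % (2**31 - 1)

    def classify(self, read_id: str, sequence: str):
        """Classify one read; returns RearrangementCall or UnmappableRead."""
        pmap = self.mapper.best_mapping(sequence)
        if pmap is None:
            return UnmappableRead(read_id, "score below shuffle-null floor")
        rmap = self.mapper.segment_regions(pmap)
        qdata = self.placer.prepare_query(pmap.query, pmap.qcols)
        if qdata.n_scored <= 8 + 1:
            return UnmappableRead(read_id, "too few scored columns")
        window = rmap.breakpoint_window
        if self.exhaustive:
            pop = exhaustive_search(qdata, window, self.ga_config)
        else:
            pop = chc_search(
                qdata, window, self._read_seed(read_id), self.ga_config
            )
        best_v, best_j, support, credible, v_marg, j_marg = call_rearrangement(
            pop, self.placer.v.branch_labels, self.placer.j.branch_labels,
            self.placer.v.parent_labels, self.placer.j.parent_labels,
        )
        junction = rmap.junction
        d_call = DCall()
        if junction is not None and junction.nucleotides:
            d_call = assign_d(
                junction.nucleotides, self.bundle.d_alleles,
                self.d_scoring, self.d_min_score,
            )
        return RearrangementCall(
            read_id=read_id,
            best_v=best_v,
            best_j=best_j,
            v_support=v_marg.get(best_v, 0.0),
            j_support=j_marg.get(best_j, 0.0),
            rearrangement_support=support,
            credible_set=credible,
            d_call=d_call,
            junction=junction,
            productive=rmap.productive,
            orientation=pmap.orientation,
            mapping_score=pmap.score,
            n_models=pop.n_evaluated,
            converged=pop.converged,
            v_marginals=v_marg,
            j_marginals=j_marg,
            regions=dict(rmap.regions),
            frame=rmap.frame,
        )

    def classify_many(self, reads) -> tuple[list, list]:
        """Classify (id, seq) pairs; returns (calls, unmappable)."""
        calls, failed = [], []
        for read_id, seq in reads:
            res = self.classify(read_id, seq)
            if isinstance(res, RearrangementCall):
                calls.append(res)
            else:
                failed.append(res)
        return calls, failed
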