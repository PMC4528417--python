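"""Search over rearrangement hypotheses.

Two drivers share one evaluation cache and output contract:

* :func:`exhaustive_search` scores every (V branch, J branch, breakpoint grid
  point) — the oracle, feasible only on small references.
* :func:`chc_search` is a CHC genetic algorithm: small population, elitist
  truncation selection, free (uniform) recombination by HUX crossover on a
  bitstring genome, incest prevention by a minimum Hamming distance that
  decays on stagnation, and cataclysmic restarts that re-seed the population
  by heavily mutating the elite.  The search terminates after a configured
  number of consecutive restarts without improvement of the best AIC_c.

The genome concatenates binary encodings of the V branch index, J branch
index and breakpoint grid index; out-of-range decodings wrap by modulo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .placement import AttachmentModel, ModelPopulation, QueryData, akaike_weights


@dataclass
class GAConfig:
    population: int = 32
    cataclysm_rate: float = 0.35
    max_restarts_without_gain: int = 3
    max_generations: int = 500
    exhaustive_grid: int = 3      # breakpoint step for the exhaustive oracle
    exhaustive_cap: int = 100_000


def _bits_needed(n: int) -> int:
    return max(1, int(np.ceil(np.log2(max(n, 2)))))


class _Genome:
    def __init__(self, n_v: int, n_j: int, n_bp: int):
        self.sizes = (n_v, n_j, n_bp)
        self.widths = (_bits_needed(n_v), _bits_needed(n_j), _bits_needed(n_bp))
        self.length = sum(self.widths)

    def decode(self, bits: np.ndarray) -> tuple[int, int, int]:
        out = []
        pos = 0
        for width, size in zip(self.widths, self.sizes):
            val = 0
            for b in bits[pos:pos + width]:
                val = (val << 1) | int(b)
            out.append(val % size)
            pos += width
        return tuple(out)

    def random(self, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(0, 2, self.length).astype(np.uint8)


def _breakpoint_grid(window: tuple[int, int], step: int) -> np.ndarray:
    lo, hi = window
    return np.arange(lo, max(hi, lo + 1), step, dtype=np.int64)


class _Evaluator:
    """Deduplicating evaluation cache over decoded models."""

    def __init__(self, qdata: QueryData, v_branches, j_branches, bp_grid):
        self.qdata = qdata
        self.v_branches = list(v_branches)
        self.j_branches = list(j_branches)
        self.bp_grid = bp_grid
        self.cache: dict[tuple[int, int, int], AttachmentModel] = {}

    def __call__(self, iv: int, ij: int, ib: int) -> AttachmentModel:
        key = (
            self.v_branches[iv], self.j_branches[ij], int(self.bp_grid[ib]),
        )
        if key not in self.cache:
            self.cache[key] = self.qdata.score(*key)
        return self.cache[key]


def exhaustive_search(
    qdata: QueryData,
    window: tuple[int, int],
    config: GAConfig | None = None,
) -> ModelPopulation:
    """Score every (V branch, J branch, breakpoint) on the grid."""
    config = config or GAConfig()
    vb = qdata.engine.v.branches
    jb = qdata.engine.j.branches
    grid = _breakpoint_grid(window, config.exhaustive_grid)
    total = len(vb) * len(jb) * len(grid)
    if total > config.exhaustive_cap:
        raise ValueError(
            f"{total} models exceed the exhaustive cap "
            f"({config.exhaustive_cap}); use the GA search"
        )
    ev = _Evaluator(qdata, vb, jb, grid)
    for iv in range(len(vb)):
        for ij in range(len(jb)):
            for ib in range(len(grid)):
                ev(iv, ij, ib)
    models = akaike_weights(list(ev.cache.values()))
    best = min(m.aicc for m in models)
    return ModelPopulation(
        models=models, best_aicc=best, converged=True,
        generations=0, seed=0, n_evaluated=len(models),
    )


def chc_search(
    qdata: QueryData,
    window: tuple[int, int],
    seed: int,
    config: GAConfig | None = None,
) -> ModelPopulation:
    """CHC genetic-algorithm search; reproducible for a given seed."""
    config = config or GAConfig()
    rng = np.random.default_rng(seed)
    vb = qdata.engine.v.branches
    jb = qdata.engine.j.branches
    grid = _breakpoint_grid(window, 1)
    genome = _Genome(len(vb), len(jb), len(grid))
    ev = _Evaluator(qdata, vb, jb, grid)

    def fitness(bits: np.ndarray) -> float:
        return ev(*genome.decode(bits)).aicc

    pop = [genome.random(rng) for _ in range(config.population)]
    fit = np.array([fitness(g) for g in pop])
    threshold = max(1, genome.length // 4)
    best_ever = float(fit.min())
    fruitless_restarts = 0
    generations = 0
    converged = False

    while generations < config.max_generations:
        generations += 1
        order = rng.permutation(config.population)
        children = []
        for i in range(0, config.population - 1, 2):
            p1, p2 = pop[order[i]], pop[order[i + 1]]
            diff = np.nonzero(p1 != p2)[0]
            if len(diff) // 2 <= threshold:
                continue  # incest prevention
            swap = rng.choice(diff, size=len(diff) // 2, replace=False)
            c1, c2 = p1.copy(), p2.copy()
            c1[swap], c2[swap] = p2[swap], p1[swap]
            children.extend([c1, c2])
        accepted = False
        if children:
            cfit = np.array([fitness(c) for c in children])
            merged = pop + children
            mfit = np.concatenate([fit, cfit])
            keep = np.argsort(mfit, kind="stable")[: config.population]
            worst_old = fit.max()
            accepted = any(k >= config.population and mfit[k] < worst_old
                           for k in keep)
            pop = [merged[k] for k in keep]
            fit = mfit[keep]
        if not accepted:
            threshold -= 1
        if threshold <= 0:
            # cataclysmic restart around the elite
            elite = pop[int(np.argmin(fit))]
            new_pop = [elite]
            for _ in range(config.population - 1):
                child = elite.copy()
                flips = rng.random(genome.length) < config.cataclysm_rate
                child[flips] ^= 1
                new_pop.append(child)
            pop = new_pop
            fit = np.array([fitness(g) for g in pop])
            threshold = max(1, genome.length // 4)
            if fit.min() < best_ever - 1e-9:
                best_ever = float(fit.min())
                fruitless_restarts = 0
            else:
                fruitless_restarts += 1
            if fruitless_restarts >= config.max_restarts_without_gain:
                converged = True
                break
        best_ever = min(best_ever, float(fit.min()))

    models = akaike_weights(list(ev.cache.values()))
    return ModelPopulation(
        models=models, best_aicc=min(m.aicc for m in models),
        converged=converged, generations=generations, seed=seed,
        n_evaluated=len(models),
    )
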