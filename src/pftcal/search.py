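"""Search of the mapping space.

With M fixations and m_i candidate targets each, the space of mappings has
prod(m_i) elements — far too many to enumerate in realistic sessions.  Two
heuristics are provided, plus an exhaustive oracle for small instances:

``exhaustive_search``  full enumeration (testing oracle; bounded space only).
``genetic_search``     population of mappings evolved by tournament
                       selection, uniform crossover and per-child mutation,
                       with an elitist copy of the incumbent each generation.
``incremental_search`` beam search that consumes fixations one at a time:
                       every beam mapping is extended by every new target
                       index, rescored on the extended prefix, sorted
                       descending and truncated to ``cutoff``.  Usable at any
                       intermediate point, which suits online calibration.

The incremental driver uses the O(M)-per-extension cached rescoring that the
direction and distance-correlation scores support; other scores fall back to
a full prefix recomputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import islice, product

import numpy as np

from .datamodel import Mapping, ScoredMapping, TrainingSet, mapping_space_size
from .mcf import MappingComparisonFunction, mcf_from_spec

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticParams",
    "IncrementalState",
    "exhaustive_search",
    "genetic_search",
    "incremental_step",
    "incremental_states",
    "incremental_search",
]


@dataclass(frozen=True)
class GeneticParams:
    """Genetic-search knobs.

    Defaults follow the published configuration: a population of 200 random
    mappings, at most 1000 generations with early stop after 200 generations
    without progress, tournament selection among 5, and mutation of 1.5% of
    each child's genes (at least one gene, so short mappings still mutate).
    """

    population_size: int = 200
    max_iterations: int = 1000
    patience: int = 200
    tournament_size: int = 5
    mutation_rate: float = 0.015
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


def _resolve_mcf(mcf) -> MappingComparisonFunction:
    return mcf if isinstance(mcf, MappingComparisonFunction) else mcf_from_spec(mcf)


# --------------------------------------------------------------------------
# Exhaustive oracle
# --------------------------------------------------------------------------

def exhaustive_search(
    ts: TrainingSet, mcf, max_space: int = 100_000, batch: int = 4096
) -> ScoredMapping:
    """Enumerate every mapping and return the best one.

    Ties are broken toward the lexicographically smaller index vector
    (enumeration order), making the result deterministic.  Refuses spaces
    larger than ``max_space``.
    """
    mcf = _resolve_mcf(mcf)
    size = mapping_space_size(ts)
    if size > max_space:
        raise ValueError(
            f"mapping space of {size} exceeds the exhaustive bound {max_space}"
        )
    ranges = [range(int(m)) for m in ts.m]
    best_score = -np.inf
    best = None
    it = product(*ranges)
    while True:
        chunk = np.array(list(islice(it, batch)), dtype=int)
        if chunk.size == 0:
            break
        scores = mcf.score_batch(ts, chunk)
        i = int(np.argmax(scores))  # first occurrence: lexicographic tie-break
        if scores[i] > best_score:
            best_score = float(scores[i])
            best = chunk[i].copy()
    return ScoredMapping(Mapping(best), best_score, mcf.id)


# --------------------------------------------------------------------------
# Genetic heuristic
# --------------------------------------------------------------------------

def genetic_search(
    ts: TrainingSet,
    mcf,
    params: GeneticParams | None = None,
    seed: int | None = None,
    return_history: bool = False,
):
    """Evolve a population of mappings toward the best score.

    Each generation keeps an elitist copy of the best mapping; the remaining
    population_size − 1 children are produced by two 5-way tournaments and a
    uniform crossover (each gene from either parent), then every non-elite
    child has ``max(1, round(mutation_rate · M))`` of its genes redrawn
    uniformly.  Stops after ``max_iterations`` generations or ``patience``
    generations without improvement of the best score.  Deterministic for a
    fixed seed.

    Returns the best-ever :class:`ScoredMapping` (and the per-generation
    best-score history when ``return_history``).
    """
    mcf = _resolve_mcf(mcf)
    params = params or GeneticParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    m = ts.m
    M = ts.M
    P = params.population_size

    pop = rng.integers(0, m[None, :], size=(P, M))
    scores = mcf.score_batch(ts, pop)
    best_i = int(np.argmax(scores))
    best = pop[best_i].copy()
    best_score = float(scores[best_i])
    history = [best_score]

    # at least one gene mutates when mutation is on at all, so short
    # mappings (where round(rate * M) == 0) can still move
    n_mut = max(1, round(params.mutation_rate * M)) if params.mutation_rate > 0 else 0
    iterations = 0
    no_progress = 0
    while iterations < params.max_iterations and no_progress < params.patience:
        # tournament selection of 2 parents per child
        cand = rng.integers(0, P, size=(2 * (P - 1), params.tournament_size))
        winners = cand[np.arange(cand.shape[0]),
                       np.argmax(scores[cand], axis=1)]
        p1 = pop[winners[: P - 1]]
        p2 = pop[winners[P - 1:]]
        cross = rng.random((P - 1, M)) < 0.5
        children = np.where(cross, p1, p2)
        # mutate every child: n_mut distinct positions redrawn uniformly
        pos = np.argsort(rng.random((P - 1, M)), axis=1)[:, :n_mut]
        rows = np.repeat(np.arange(P - 1), n_mut)
        cols = pos.ravel()
        children[rows, cols] = rng.integers(0, m[cols])
        pop = np.vstack([pop[int(np.argmax(scores))][None, :], children])
        scores = mcf.score_batch(ts, pop)
        gen_best = float(scores.max())
        if gen_best > best_score:
            best_score = gen_best
            best = pop[int(np.argmax(scores))].copy()
            no_progress = 0
        else:
            no_progress += 1
        iterations += 1
        history.append(best_score)
        logger.debug("generation %d: best %.6f", iterations, best_score)
    result = ScoredMapping(Mapping(best), best_score, mcf.id)
    return (result, history) if return_history else result


# --------------------------------------------------------------------------
# Incremental beam
# --------------------------------------------------------------------------

@dataclass
class IncrementalState:
    """Beam of prefix mappings sorted descending by score."""

    mappings: np.ndarray  # (B, k)
    scores: np.ndarray  # (B,)
    cutoff: int
    fixations_consumed: int
    cache: object = None

    def __post_init__(self) -> None:
        if self.mappings.shape[0] > self.cutoff:
            raise ValueError("beam exceeds cutoff")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("beam scores must be non-increasing")

    @property
    def head(self) -> ScoredMapping:
        return ScoredMapping(
            Mapping(self.mappings[0]), float(self.scores[0]), "beam"
        )


def _seed_state(
    ts: TrainingSet, mcf: MappingComparisonFunction, cutoff: int, seed_depth: int
) -> IncrementalState:
    """Enumerate all mappings of the first few fixations to start the beam.

    ``seed_depth`` is capped so the enumeration stays within
    ``cutoff · max(m_i)`` mappings.
    """
    m = ts.m
    depth = max(1, min(seed_depth, ts.M))
    limit = cutoff * int(m.max())
    while depth > 1 and int(np.prod(m[:depth])) > limit:
        depth -= 1
    grids = np.meshgrid(*[np.arange(int(mi)) for mi in m[:depth]], indexing="ij")
    mappings = np.stack([g.ravel() for g in grids], axis=1)
    scores = mcf.score_batch(ts.prefix(depth), mappings)
    order = np.argsort(-scores, kind="stable")[:cutoff]
    beam = mappings[order]
    state = IncrementalState(
        mappings=beam,
        scores=scores[order],
        cutoff=cutoff,
        fixations_consumed=depth,
    )
    state.cache = mcf.init_extension_state(ts, beam)
    return state


def incremental_step(
    state: IncrementalState, ts: TrainingSet, mcf
) -> IncrementalState:
    """Consume the next fixation: extend, rescore, sort, truncate.

    Every beam mapping is extended by every target index of fixation
    ``state.fixations_consumed``; extended mappings are scored on the
    extended prefix (using the cached fast path when the score supports it),
    sorted descending (stable, so older mappings win ties) and truncated to
    the cutoff.
    """
    mcf = _resolve_mcf(mcf)
    k = state.fixations_consumed
    if k >= ts.M:
        raise ValueError("all fixations already consumed")
    beam = state.mappings
    B = beam.shape[0]
    m_k = ts.target_sets[k].shape[0]

    cache = state.cache
    if mcf.supports_incremental and cache is None and not mcf.extends_additively:
        cache = mcf.init_extension_state(ts, beam)
    inc_scores, new_cache = mcf.extend_scores(ts, beam, cache, k)
    if mcf.extends_additively:
        new_scores = (state.scores[:, None] + inc_scores).reshape(-1)
    else:
        new_scores = inc_scores.reshape(-1)

    ext = np.concatenate(
        [np.repeat(beam, m_k, axis=0), np.tile(np.arange(m_k), B)[:, None]],
        axis=1,
    )
    order = np.argsort(-new_scores, kind="stable")[: state.cutoff]
    new_state = IncrementalState(
        mappings=ext[order],
        scores=new_scores[order],
        cutoff=state.cutoff,
        fixations_consumed=k + 1,
    )
    if mcf.supports_incremental:
        new_state.cache = mcf.select_state(new_cache, order)
    return new_state


def incremental_states(ts: TrainingSet, mcf, cutoff: int = 100,
                       seed_depth: int = 3):
    """Yield the beam state after each consumed fixation (online view)."""
    mcf = _resolve_mcf(mcf)
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    state = _seed_state(ts, mcf, cutoff, seed_depth)
    yield state
    while state.fixations_consumed < ts.M:
        state = incremental_step(state, ts, mcf)
        yield state


def incremental_search(
    ts: TrainingSet, mcf, cutoff: int = 100, seed_depth: int = 3
) -> ScoredMapping:
    """Run the beam over the whole training set and return the beam head."""
    mcf = _resolve_mcf(mcf)
    state = None
    for state in incremental_states(ts, mcf, cutoff=cutoff, seed_depth=seed_depth):
        pass
    head = state.head
    return ScoredMapping(head.mapping, head.score, mcf.id)
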