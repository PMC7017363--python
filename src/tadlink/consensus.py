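"""Consensus TAD calling across cell types.

A TAD called in a *basis* cell type A is scored for conservation against
three other cell types B, C, D:

    S_i = median( max_{T in B} J(T_i, T),
                  max_{T in C} J(T_i, T),
                  max_{T in D} J(T_i, T) )

where J is the Jaccard overlap of two intervals (intersection length over
union length).  S_i = 1 when the TAD appears at identical coordinates in
every cell type; S_i = 0 when it overlaps nothing in any other cell type.

Significance of an observed score is assessed by a permutation test that
replaces the TAD with uniform-random same-length intervals on the same
chromosome; p-values are Benjamini–Hochberg adjusted across the tested
TADs.  A conserved ("consensus") TAD must be at least ``min_length`` long,
score strictly above ``score_threshold`` and reach ``q < q_threshold``.
Each consensus TAD is reported in two boundary variants: the intersection
of the basis TAD with its best match in every other cell type, and their
union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet
from .stats import bh_fdr, mc_p_value

logger = logging.getLogger("tadlink.consensus")

__all__ = [
    "ConservationScore",
    "ConsensusTAD",
    "ConsensusConfig",
    "conservation_score",
    "permutation_null",
    "fdr_adjust",
    "call_consensus_tads",
    "build_intersection_tad",
    "build_union_tad",
    "score_all_tads",
]


@dataclass
class ConservationScore:
    """Conservation score of one basis TAD against three other cell types."""

    tad: GenomicInterval
    per_celltype_best: tuple[float, float, float]
    score: float
    best_matches: tuple[GenomicInterval | None, ...] = ()
    p_value: float | None = None
    q_value: float | None = None


@dataclass
class ConsensusTAD:
    """A conserved TAD with intersection and union boundary variants."""

    id: str
    source_tad: GenomicInterval
    intersection_iv: GenomicInterval
    union_iv: GenomicInterval
    score: float
    p_value: float
    q_value: float


@dataclass
class ConsensusConfig:
    min_length: int = 100_000
    score_threshold: float = 0.5  # strict: S must exceed this
    q_threshold: float = 0.05
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.score_threshold < 1) or not (0 < self.q_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


def _median3(values: Sequence[float]) -> float:
    return sorted(values)[1]


def _best_match(
    start: int, end: int, others_chrom: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> tuple[float, int]:
    """Max Jaccard of [start, end) against candidate arrays; ties to the
    leftmost-start, then shortest, candidate.  Returns (best, sorted-pos)."""
    starts, ends, _ = others_chrom
    if starts.size == 0:
        return 0.0, -1
    inter = np.minimum(ends, end) - np.maximum(starts, start)
    np.clip(inter, 0, None, out=inter)
    union = (end - start) + (ends - starts) - inter
    jac = inter / union
    best = float(jac.max())
    # candidates are sorted by (start, end): first argmax is the tie-break
    pos = int(np.argmax(jac == best))
    return best, pos


def conservation_score(
    tad: GenomicInterval, others: Sequence[IntervalSet]
) -> ConservationScore:
    """Score one basis TAD against exactly three other cell types.

    The per-cell-type value is the maximum Jaccard overlap against any TAD
    of that cell type on the same chromosome (0 if there is none); the
    score is the median of the three values.
    """
    if len(others) != 3:
        raise ValueError(f"expected exactly 3 other cell types, got {len(others)}")
    bests: list[float] = []
    matches: list[GenomicInterval | None] = []
    for ivset in others:
        arrays = ivset.chrom_arrays(tad.chrom)
        b, pos = _best_match(tad.start, tad.end, arrays)
        bests.append(b)
        if b > 0.0:
            matches.append(ivset.intervals[int(arrays[2][pos])])
        else:
            matches.append(None)
    return ConservationScore(
        tad=tad,
        per_celltype_best=tuple(bests),
        score=_median3(bests),
        best_matches=tuple(matches),
    )


def _null_scores(
    length: int,
    chrom: str,
    others: Sequence[IntervalSet],
    chrom_size: int,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conservation scores of ``n`` uniform-random same-length intervals."""
    starts = rng.integers(0, chrom_size - length + 1, size=n)
    ends = starts + length
    per_set = np.empty((3, n))
    for k, ivset in enumerate(others):
        c_starts, c_ends, _ = ivset.chrom_arrays(chrom)
        if c_starts.size == 0:
            per_set[k] = 0.0
            continue
        inter = np.minimum(c_ends[None, :], ends[:, None]) - np.maximum(
            c_starts[None, :], starts[:, None]
        )
        np.clip(inter, 0, None, out=inter)
        union = length + (c_ends - c_starts)[None, :] - inter
        per_set[k] = (inter / union).max(axis=1)
    return np.median(per_set, axis=0)


def permutation_null(
    tad: GenomicInterval,
    others: Sequence[IntervalSet],
    chrom_sizes: Mapping[str, int],
    n: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    observed_score: float | None = None,
) -> float:
    """Permutation p-value for one TAD's conservation score.

    The TAD is replaced by ``n`` uniform-random intervals of the same
    length on the same chromosome; p = (#{null >= observed} + 1) / (n + 1).
    """
    if tad.chrom not in chrom_sizes:
        raise KeyError(f"chromosome {tad.chrom!r} missing from chrom_sizes")
    if tad.length > chrom_sizes[tad.chrom]:
        raise ValueError(f"TAD longer than its chromosome: {tad}")
    if observed_score is None:
        observed_score = conservation_score(tad, others).score
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    null = _null_scores(tad.length, tad.chrom, others, chrom_sizes[tad.chrom], n, rng)
    return mc_p_value(int((null >= observed_score).sum()), n)


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted q-values (order-preserving)."""
    return list(bh_fdr(p_values))


def build_intersection_tad(
    tad: GenomicInterval, best_matches: Sequence[GenomicInterval]
) -> GenomicInterval | None:
    """Shared section of the basis TAD and its three best matches.

    Returns None when the common intersection is empty (the caller drops
    the TAD from the consensus with a warning).
    """
    ivs = [tad, *best_matches]
    start = max(iv.start for iv in ivs)
    end = min(iv.end for iv in ivs)
    if end <= start:
        return None
    return GenomicInterval(tad.chrom, start, end)


def build_union_tad(
    tad: GenomicInterval, best_matches: Sequence[GenomicInterval]
) -> GenomicInterval:
    """Full span of the basis TAD and its three best matches."""
    ivs = [tad, *best_matches]
    return GenomicInterval(tad.chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs))


def score_all_tads(
    basis: IntervalSet, others: Sequence[IntervalSet]
) -> list[ConservationScore]:
    """Conservation scores for every basis TAD, in input order."""
    return [conservation_score(tad, others) for tad in basis]


def call_consensus_tads(
    basis: IntervalSet,
    others: Sequence[IntervalSet],
    chrom_sizes: Mapping[str, int],
    cfg: ConsensusConfig | None = None,
) -> list[ConsensusTAD]:
    """Call conserved TADs from the basis cell type.

    Pipeline: score every basis TAD; keep those with length >=
    ``min_length`` and score strictly above ``score_threshold``; run the
    permutation test only on that tested set (one independent stream per
    TAD, seeded by (seed, basis index)); BH-adjust within the tested set;
    retain q < ``q_threshold``.  Retained TADs whose four-way intersection
    is empty — or that lack an overlapping match in some cell type — are
    dropped with a warning, since no shared section exists.
    """
    if len(basis) == 0:
        raise ValueError("basis cell type has no TADs")
    cfg = cfg or ConsensusConfig()
    scores = score_all_tads(basis, others)

    tested: list[tuple[int, ConservationScore]] = [
        (i, sc)
        for i, sc in enumerate(scores)
        if sc.tad.length >= cfg.min_length and sc.score > cfg.score_threshold
    ]
    if not tested:
        return []

    p_values = []
    for i, sc in tested:
        rng = np.random.default_rng([cfg.seed, i])
        p = permutation_null(
            sc.tad, others, chrom_sizes, cfg.n_permutations, rng, observed_score=sc.score
        )
        sc.p_value = p
        p_values.append(p)
    q_values = fdr_adjust(p_values)

    out: list[ConsensusTAD] = []
    n_dropped = 0
    for (i, sc), q in zip(tested, q_values):
        sc.q_value = q
        if q >= cfg.q_threshold:
            continue
        if any(m is None for m in sc.best_matches):
            n_dropped += 1
            logger.warning(
                "TAD %s (%s) passes thresholds but has no overlapping match in "
                "every cell type; dropped",
                basis.ids[i],
                sc.tad,
            )
            continue
        matches = [m for m in sc.best_matches if m is not None]
        inter = build_intersection_tad(sc.tad, matches)
        if inter is None:
            n_dropped += 1
            logger.warning(
                "TAD %s (%s) has an empty four-way intersection; dropped",
                basis.ids[i],
                sc.tad,
            )
            continue
        out.append(
            ConsensusTAD(
                id=basis.ids[i],
                source_tad=sc.tad,
                intersection_iv=inter,
                union_iv=build_union_tad(sc.tad, matches),
                score=sc.score,
                p_value=sc.p_value,
                q_value=q,
            )
        )
    if n_dropped:
        logger.warning("dropped %d significant TADs with no shared section", n_dropped)
    return out
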