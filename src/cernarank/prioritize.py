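"""Candidate lncRNA scoring, per-context ranking and rank fusion.

An lncRNA is represented by its *competing genes* -- the mRNAs it forms
significant ceRNA pairs with.  Inside one functional context (an
annotated ontology namespace or a biological network) the similarity of
two lncRNAs is the flat mean of all m x n competing-gene-pair
similarities.  A candidate is scored by its mean similarity to the seed
lncRNAs and ranked; per-context rank ratios are fused with the
order-statistic Q score

    Q(r_(1), ..., r_(N)) = P(U_(1) <= r_(1), ..., U_(N) <= r_(N))

for N independent uniforms, so a small Q means the candidate ranks
consistently well across data sources.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import MutableMapping, Protocol, Sequence

from scipy.stats import rankdata

__all__ = [
    "FunctionalContext",
    "LncRnaProfile",
    "RankedEntry",
    "RankedList",
    "FusionEntry",
    "FusionResult",
    "lncrna_pair_fs",
    "rank_candidates",
    "q_statistic",
    "fuse_ranks",
    "enrichment_score",
]


class FunctionalContext(Protocol):
    """One similarity backend exposing gene-pair functional similarity."""

    name: str

    def covers(self, gene_id: str) -> bool: ...

    def gene_fs(self, g1: str, g2: str) -> float: ...


@dataclass(frozen=True)
class LncRnaProfile:
    """An lncRNA and its set of competing mRNAs."""

    lncrna_id: str
    competing_genes: frozenset[str]


@dataclass(frozen=True)
class RankedEntry:
    lncrna_id: str
    score: float
    rank: float
    rank_ratio: float


@dataclass
class RankedList:
    """Per-context candidate ranking, sorted by score descending."""

    context_name: str
    entries: list[RankedEntry]

    def ratio_of(self) -> dict[str, float]:
        return {e.lncrna_id: e.rank_ratio for e in self.entries}

    def rank_of(self, lncrna_id: str) -> float | None:
        for e in self.entries:
            if e.lncrna_id == lncrna_id:
                return e.rank
        return None


@dataclass(frozen=True)
class FusionEntry:
    lncrna_id: str
    q: float
    n_sources: int
    final_rank: float


@dataclass
class FusionResult:
    """Fused ranking, ascending in Q (small Q = strong joint evidence)."""

    entries: list[FusionEntry]

    def rank_of(self, lncrna_id: str) -> float | None:
        for e in self.entries:
            if e.lncrna_id == lncrna_id:
                return e.final_rank
        return None


def lncrna_pair_fs(
    a: LncRnaProfile, b: LncRnaProfile, ctx: FunctionalContext
) -> float | None:
    """Mean gene-pair similarity over all m x n competing-gene pairs.

    Returns ``None`` (absent, not zero) when either profile is empty:
    an lncRNA without competing genes carries no evidence in any
    context, which is different from evidence of dissimilarity.
    """
    m, n = len(a.competing_genes), len(b.competing_genes)
    if m == 0 or n == 0:
        return None
    gene_fs = ctx.gene_fs
    total = math.fsum(
        gene_fs(ga, gb) for ga in a.competing_genes for gb in b.competing_genes
    )
    return total / (m * n)


def _usable(profile: LncRnaProfile, ctx: FunctionalContext) -> bool:
    return any(ctx.covers(g) for g in profile.competing_genes)


def rank_candidates(
    seeds: Sequence[LncRnaProfile],
    candidates: Sequence[LncRnaProfile],
    ctx: FunctionalContext,
    pair_fs_memo: MutableMapping[tuple[str, str], float | None] | None = None,
) -> RankedList:
    """Score candidates by mean similarity to the seeds and rank them.

    Seeds and candidates with no gene covered by the context are
    dropped (their similarity is undefined there, not zero).  Tied
    scores share their average rank; ``rank_ratio = rank / n_entries``.
    ``pair_fs_memo`` optionally caches lncRNA-pair similarities across
    calls that reuse the same profiles within the same context.
    """
    usable_seeds = [s for s in seeds if _usable(s, ctx)]
    if not usable_seeds:
        raise ValueError(f"no usable seed profile in context {ctx.name!r}")
    usable = [c for c in candidates if _usable(c, ctx)]
    if not usable:
        warnings.warn(
            f"no usable candidate in context {ctx.name!r}", stacklevel=2
        )
        return RankedList(ctx.name, [])

    scored: list[tuple[str, float]] = []
    for cand in usable:
        vals: list[float] = []
        for seed in usable_seeds:
            if pair_fs_memo is not None:
                key = (
                    (cand.lncrna_id, seed.lncrna_id)
                    if cand.lncrna_id <= seed.lncrna_id
                    else (seed.lncrna_id, cand.lncrna_id)
                )
                if key in pair_fs_memo:
                    fs = pair_fs_memo[key]
                else:
                    fs = lncrna_pair_fs(cand, seed, ctx)
                    pair_fs_memo[key] = fs
            else:
                fs = lncrna_pair_fs(cand, seed, ctx)
            if fs is not None:
                vals.append(fs)
        if vals:
            scored.append((cand.lncrna_id, math.fsum(vals) / len(vals)))

    if not scored:
        warnings.warn(
            f"all candidates lack a defined score in context {ctx.name!r}",
            stacklevel=2,
        )
        return RankedList(ctx.name, [])

    scored.sort(key=lambda t: (-t[1], t[0]))
    n = len(scored)
    ranks = rankdata([-s for _, s in scored], method="average")
    entries = [
        RankedEntry(lid, score, float(r), float(r) / n)
        for (lid, score), r in zip(scored, ranks)
    ]
    return RankedList(ctx.name, entries)


def q_statistic(rank_ratios: Sequence[float]) -> float:
    """Joint tail probability of uniform order statistics.

    With the ratios sorted ascending as r_(1) <= ... <= r_(N), computes
    Q = P(U_(1) <= r_(1), ..., U_(N) <= r_(N)) by the recursion

        W_0 = 1,
        W_k = sum_{i=1..k} (-1)^(i-1) C(k, i) W_{k-i} r_(N-k+1)^i,
        Q = W_N,

    where W_k = k! V_k rescales the classical alternating-sum recursion
    so that binomial coefficients stay exact integers.
    """
    r = sorted(float(x) for x in rank_ratios)
    if not r:
        raise ValueError("rank_ratios must be nonempty")
    if r[0] <= 0 or r[-1] > 1:
        raise ValueError(f"rank ratios must lie in (0, 1], got {rank_ratios}")
    N = len(r)
    W = [1.0]
    for k in range(1, N + 1):
        rk = r[N - k]  # r_(N-k+1), 1-based
        W.append(
            math.fsum(
                (-1) ** (i - 1) * math.comb(k, i) * W[k - i] * rk**i
                for i in range(1, k + 1)
            )
        )
    return min(1.0, max(0.0, W[N]))


def fuse_ranks(lists: Sequence[RankedList]) -> FusionResult:
    """Fuse per-context rankings with the Q score.

    Each lncRNA's Q is computed over the rank ratios of the lists that
    contain it (contexts where it is absent are dropped and N reduced
    -- missing annotation is not evidence of dissimilarity).  The fused
    order ascends in Q, ties broken by more sources used, then by id;
    tied Q values share their average final rank.
    """
    if not lists:
        raise ValueError("need at least one ranked list")
    ratios: dict[str, list[float]] = {}
    for rl in lists:
        for e in rl.entries:
            ratios.setdefault(e.lncrna_id, []).append(e.rank_ratio)
    if not ratios:
        return FusionResult([])
    scored = [
        (lid, q_statistic(rs), len(rs)) for lid, rs in sorted(ratios.items())
    ]
    scored.sort(key=lambda t: (t[1], -t[2], t[0]))
    ranks = rankdata([q for _, q, _ in scored], method="average")
    entries = [
        FusionEntry(lid, q, n_src, float(rk))
        for (lid, q, n_src), rk in zip(scored, ranks)
    ]
    return FusionResult(entries)


def enrichment_score(rank: float, n: int) -> float:
    """log2(n / 2 / rank): positive above the list midpoint, -1 at the
    bottom of the list."""
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if not (1 <= rank <= n):
        raise ValueError(f"rank must lie in [1, {n}], got {rank}")
    return math.log2(n / 2 / rank)
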