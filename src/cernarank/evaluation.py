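"""Leave-one-out cross-validation with decoy candidates and rank-based ROC.

For each disease with at least two seed lncRNAs, each seed is held out
in turn, mixed with randomly sampled decoy lncRNAs (99 by default, for
a candidate set of 100), and re-ranked against the remaining seeds --
per single functional context or through rank fusion.  The held-out
lncRNA's rank position is the test statistic: a perfect method ranks it
first in every run (AUC 1.0), an uninformative one ranks it uniformly
(AUC 0.5).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .prioritize import (
    FunctionalContext,
    LncRnaProfile,
    fuse_ranks,
    lncrna_pair_fs,
    rank_candidates,
)

__all__ = ["LoocvRun", "LoocvResult", "loocv", "roc_auc", "fs_group_comparison"]


@dataclass(frozen=True)
class LoocvRun:
    disease_id: str
    held_out_lncrna: str
    rank_position: float
    n_candidates: int


@dataclass
class LoocvResult:
    runs: list[LoocvRun]
    roc: np.ndarray  # (k, 2) array of (1 - specificity, sensitivity)
    auc: float
    per_disease_auc: dict[str, float]


def roc_auc(
    rank_positions: Sequence[float], n_candidates: int
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from held-out rank positions.

    Each run contributes one positive (the held-out lncRNA) among
    ``n_candidates`` ranked candidates.  At cutoff ``k`` the
    sensitivity is the fraction of runs whose positive ranks <= k; the
    false-positive rate is the fraction of the runs' pooled decoy
    positions <= k.  The resulting AUC equals the Mann-Whitney
    U-statistic estimate of P(positive outranks a random decoy).
    """
    ranks = np.asarray(list(rank_positions), dtype=float)
    if ranks.size == 0:
        raise ValueError("no rank positions supplied")
    if n_candidates < 2:
        raise ValueError("need at least two candidates per run")
    if np.any((ranks < 1) | (ranks > n_candidates)):
        raise ValueError(f"rank positions must lie in [1, {n_candidates}]")
    cutoffs = np.arange(n_candidates + 1)[:, None]
    hit = ranks[None, :] <= cutoffs  # (k+1, runs)
    sens = hit.mean(axis=1)
    # decoys fill the remaining positions of each run's list
    fpr = (cutoffs[:, 0] - hit.sum(axis=1) / ranks.size) / (n_candidates - 1)
    fpr = np.clip(fpr, 0.0, 1.0)
    points = np.column_stack([fpr, sens])
    auc = float(np.trapezoid(sens, fpr))
    return points, auc


def loocv(
    disease_seeds: Mapping[str, Sequence[LncRnaProfile]],
    decoy_pool: Sequence[LncRnaProfile],
    contexts: Sequence[FunctionalContext],
    n_decoys: int = 99,
    seed: int = 0,
) -> LoocvResult:
    """Run the hold-one-out benchmark over all diseases.

    Decoys are sampled uniformly without replacement from
    ``decoy_pool`` after excluding any lncRNA associated with the
    disease under test; the RNG is seeded so runs are reproducible
    bit for bit.  Diseases with fewer than two seeds are skipped with
    a warning.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    if not contexts:
        raise ValueError("need at least one functional context")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x10CF])
    pool_sorted = sorted(decoy_pool, key=lambda p: p.lncrna_id)

    memos: dict[str, dict] = {ctx.name: {} for ctx in contexts}
    runs: list[LoocvRun] = []
    for disease_id in sorted(disease_seeds):
        seeds = sorted(disease_seeds[disease_id], key=lambda p: p.lncrna_id)
        if len(seeds) < 2:
            warnings.warn(
                f"disease {disease_id!r} has fewer than two seeds; skipped",
                stacklevel=2,
            )
            continue
        seed_ids = {s.lncrna_id for s in seeds}
        pool = [p for p in pool_sorted if p.lncrna_id not in seed_ids]
        if len(pool) < n_decoys:
            raise ValueError(
                f"decoy pool for {disease_id!r} has {len(pool)} lncRNAs, "
                f"need {n_decoys}"
            )
        for held_out in seeds:
            rest = [s for s in seeds if s.lncrna_id != held_out.lncrna_id]
            idx = rng.choice(len(pool), size=n_decoys, replace=False)
            candidates = [held_out] + [pool[i] for i in sorted(idx)]
            lists = [
                rank_candidates(rest, candidates, ctx, pair_fs_memo=memos[ctx.name])
                for ctx in contexts
            ]
            if len(lists) == 1:
                ranked = lists[0]
                pos = ranked.rank_of(held_out.lncrna_id)
                n_cand = len(ranked.entries)
            else:
                fused = fuse_ranks(lists)
                pos = fused.rank_of(held_out.lncrna_id)
                n_cand = len(fused.entries)
            if pos is None:
                warnings.warn(
                    f"held-out {held_out.lncrna_id!r} absent from every "
                    f"context; run skipped",
                    stacklevel=2,
                )
                continue
            runs.append(LoocvRun(disease_id, held_out.lncrna_id, pos, n_cand))

    if not runs:
        raise ValueError("no validation runs could be performed")

    n_common = Counter(r.n_candidates for r in runs).most_common(1)[0][0]
    usable = [r for r in runs if r.n_candidates == n_common]
    if len(usable) != len(runs):
        warnings.warn(
            f"{len(runs) - len(usable)} runs with atypical candidate counts "
            "excluded from the pooled ROC",
            stacklevel=2,
        )
    roc, auc = roc_auc([r.rank_position for r in usable], n_common)
    per_disease: dict[str, float] = {}
    for disease_id in sorted({r.disease_id for r in usable}):
        d_runs = [r for r in usable if r.disease_id == disease_id]
        _, d_auc = roc_auc([r.rank_position for r in d_runs], n_common)
        per_disease[disease_id] = d_auc
    return LoocvResult(runs, roc, auc, per_disease)


def fs_group_comparison(
    validated_groups: Sequence[Sequence[LncRnaProfile]],
    pool: Sequence[LncRnaProfile],
    ctx: FunctionalContext,
    n_random: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Within-group pairwise similarity of validated disease lncRNA
    groups versus size-matched random groups.

    For every validated group of size n, ``n_random`` random groups of
    n lncRNAs are drawn from ``pool`` and all within-group pairwise
    similarities collected.  Returns the two value arrays and the
    one-sided Mann-Whitney U p-value for validated > random.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xF16])
    pool_sorted = sorted(pool, key=lambda p: p.lncrna_id)

    def within(group: Sequence[LncRnaProfile]) -> list[float]:
        vals = []
        members = sorted(group, key=lambda p: p.lncrna_id)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                fs = lncrna_pair_fs(a, b, ctx)
                if fs is not None:
                    vals.append(fs)
        return vals

    validated: list[float] = []
    random_vals: list[float] = []
    for group in validated_groups:
        if len(group) < 2:
            warnings.warn("group of size < 2 skipped", stacklevel=2)
            continue
        validated.extend(within(group))
        for _ in range(n_random):
            idx = rng.choice(len(pool_sorted), size=len(group), replace=False)
            random_vals.extend(within([pool_sorted[i] for i in idx]))
    if not validated or not random_vals:
        raise ValueError("need at least one usable group on each side")
    stat = mannwhitneyu(validated, random_vals, alternative="greater")
    return np.asarray(validated), np.asarray(random_vals), float(stat.pvalue)
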