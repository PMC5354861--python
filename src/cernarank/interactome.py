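"""Inference of lncRNA--mRNA competing-endogenous-RNA (ceRNA) pairs.

Two transcripts that share a significant number of miRNA partners are
assumed to compete for the same miRNA pool.  Given a bipartite
miRNA--target interaction table in which every target is typed as either
an lncRNA or an mRNA, each (lncRNA, mRNA) pair sharing at least one
miRNA is tested with an upper-tail hypergeometric test: out of ``N``
miRNAs in the universe, the lncRNA binds ``K`` and the mRNA binds ``M``;
the probability of observing ``x`` or more shared miRNAs by chance is

    P(X >= x),   X ~ Hypergeometric(N, K, M).

P-values are Benjamini--Hochberg adjusted across all tested pairs and
pairs below the significance threshold form the ceRNA map, i.e. each
lncRNA's set of *competing genes*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InteractionTable",
    "CeRnaPair",
    "CeRnaMap",
    "hypergeom_p",
    "bh_adjust",
    "infer_cerna",
    "read_interactions",
    "read_cerna_table",
]

LNCRNA = "lncRNA"
MRNA = "mRNA"
_CLASSES = (LNCRNA, MRNA)


@dataclass(frozen=True)
class InteractionTable:
    """Bipartite miRNA -> target interactions with typed targets.

    Parameters
    ----------
    records
        Set of ``(mirna_id, target_id, target_class)`` triples with
        ``target_class`` one of ``"lncRNA"`` / ``"mRNA"``.
    mirna_universe
        All miRNAs defining the universe size ``N`` of the
        hypergeometric test.  Defaults to the miRNAs appearing in
        ``records``; a superset may be supplied.
    """

    records: frozenset[tuple[str, str, str]]
    mirna_universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        seen = set(m for m, _, _ in self.records)
        universe = frozenset(self.mirna_universe) | seen
        object.__setattr__(self, "mirna_universe", universe)
        classes: dict[str, str] = {}
        for _, target, cls in self.records:
            if cls not in _CLASSES:
                raise ValueError(f"unknown target class {cls!r} for {target!r}")
            if classes.setdefault(target, cls) != cls:
                raise ValueError(f"target {target!r} assigned to both classes")

    def partners(self, target_class: str) -> dict[str, frozenset[str]]:
        """Map each target of ``target_class`` to its miRNA partner set."""
        out: dict[str, set[str]] = {}
        for mirna, target, cls in self.records:
            if cls == target_class:
                out.setdefault(target, set()).add(mirna)
        return {t: frozenset(s) for t, s in out.items()}

    @classmethod
    def from_pairs(
        cls,
        lncrna_pairs: Iterable[tuple[str, str]],
        mrna_pairs: Iterable[tuple[str, str]],
        mirna_universe: Iterable[str] = (),
    ) -> "InteractionTable":
        records = {(m, t, LNCRNA) for m, t in lncrna_pairs} | {
            (m, t, MRNA) for m, t in mrna_pairs
        }
        return cls(frozenset(records), frozenset(mirna_universe))


@dataclass(frozen=True)
class CeRnaPair:
    """One tested lncRNA--mRNA pair with its shared-miRNA evidence."""

    lncrna_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    x: int
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if self.x != len(self.shared_mirnas):
            raise ValueError("x must equal the number of shared miRNAs")


@dataclass
class CeRnaMap:
    """Significant ceRNA pairs retained at ``p_adj < alpha``."""

    pairs: list[CeRnaPair]
    alpha: float = 0.01

    def competing(self) -> dict[str, frozenset[str]]:
        """Deterministic lncRNA -> competing-mRNA mapping."""
        out: dict[str, set[str]] = {}
        for p in self.pairs:
            out.setdefault(p.lncrna_id, set()).add(p.mrna_id)
        return {k: frozenset(v) for k, v in sorted(out.items())}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p.lncrna_id, p.mrna_id, p.x, p.p_raw, p.p_adj) for p in self.pairs
        ]
        return pd.DataFrame(
            rows, columns=["lncrna_id", "mrna_id", "n_shared", "p_raw", "p_adj"]
        )


def hypergeom_p(N: int, K: int, M: int, x: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= x)``.

    ``N`` is the miRNA universe size, ``K`` and ``M`` the miRNA counts
    of the lncRNA and mRNA under test, ``x`` the observed shared count.
    """
    if not (0 <= K <= N):
        raise ValueError(f"K must satisfy 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= M <= N):
        raise ValueError(f"M must satisfy 0 <= M <= N, got M={M}, N={N}")
    if not (0 <= x <= min(K, M)):
        raise ValueError(
            f"x must satisfy 0 <= x <= min(K, M), got x={x}, K={K}, M={M}"
        )
    if x == 0:
        return 1.0  # upper tail at zero is the total probability
    # scipy parametrization: hypergeom(M=population, n=successes, N=draws)
    return float(stats.hypergeom.sf(x - 1, N, K, M))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini--Hochberg step-up adjusted p-values, input order kept."""
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)) or np.any(np.isnan(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in stats.false_discovery_control(ps, method="bh")]


def infer_cerna(table: InteractionTable, alpha: float = 0.01) -> CeRnaMap:
    """Test every lncRNA--mRNA pair sharing >= 1 miRNA, BH-adjust jointly,
    and retain pairs with ``p_adj < alpha``.

    Pairs with zero shared miRNAs are not hypotheses and are not part of
    the adjustment family.  The result is deterministic: pairs are
    sorted by (p_adj, lncrna_id, mrna_id).
    """
    if not table.records:
        raise ValueError("interaction table is empty")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")

    lnc = table.partners(LNCRNA)
    mrna = table.partners(MRNA)
    N = len(table.mirna_universe)

    # invert the mRNA map so only pairs with overlap are enumerated
    by_mirna: dict[str, list[str]] = {}
    for m_id, mirnas in mrna.items():
        for mi in mirnas:
            by_mirna.setdefault(mi, []).append(m_id)

    tested: list[tuple[str, str, frozenset[str]]] = []
    for l_id in sorted(lnc):
        l_mirnas = lnc[l_id]
        candidates: set[str] = set()
        for mi in l_mirnas:
            candidates.update(by_mirna.get(mi, ()))
        for m_id in sorted(candidates):
            shared = l_mirnas & mrna[m_id]
            tested.append((l_id, m_id, frozenset(shared)))

    if not tested:
        return CeRnaMap([], alpha=alpha)

    p_raw = [
        hypergeom_p(N, len(lnc[l]), len(mrna[m]), len(s)) for l, m, s in tested
    ]
    p_adj = bh_adjust(p_raw)

    pairs = [
        CeRnaPair(l, m, s, len(s), pr, pa)
        for (l, m, s), pr, pa in zip(tested, p_raw, p_adj)
        if pa < alpha
    ]
    pairs.sort(key=lambda p: (p.p_adj, p.lncrna_id, p.mrna_id))
    return CeRnaMap(pairs, alpha=alpha)


_HEADER_TOKENS = {
    "mirna", "mirna_id", "mir", "mir_id", "#mirna_id",
    "source", "target", "target_id", "gene", "gene_id", "lncrna_id",
}


def _read_pair_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column miRNA/target TSV, sniffing an optional header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    first = [str(v).strip().lower() for v in df.iloc[0, :2]]
    if any(tok in _HEADER_TOKENS for tok in first):
        df = df.iloc[1:]
    pairs = list(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))
    unique = list(dict.fromkeys(pairs))
    if len(unique) != len(pairs):
        warnings.warn(
            f"{path}: {len(pairs) - len(unique)} duplicate interaction rows "
            "dropped",
            stacklevel=2,
        )
    return unique


def read_interactions(
    lncrna_path: str | Path, mrna_path: str | Path
) -> InteractionTable:
    """Load miRNA->lncRNA and miRNA->mRNA two-column TSV tables."""
    return InteractionTable.from_pairs(
        _read_pair_tsv(lncrna_path), _read_pair_tsv(mrna_path)
    )


def write_cerna_table(cmap: CeRnaMap, path: str | Path, header_comment: str = "") -> None:
    """Write the retained pairs as TSV, deterministically sorted."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cmap.to_frame().to_csv(fh, sep="\t", index=False)


def read_cerna_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an lncRNA -> competing-mRNA map from the first two columns
    of a TSV (the ceRNA table written by this package, or any
    two-column lncrna_id/mrna_id list)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    out: dict[str, set[str]] = {}
    for l_id, m_id in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(l_id), set()).add(str(m_id))
    return {k: frozenset(v) for k, v in sorted(out.items())}
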