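"""Self-contained synthetic fixtures for every pipeline stage.

The generators emulate the statistical structure the prioritizer
exploits, without any external download:

* an interactome in which planted lncRNA--mRNA pairs share many miRNAs
  (hypergeometric p far below threshold) while background pairs share
  few;
* toy ontology namespaces whose deep terms mark gene modules, so genes
  of one module share a high-IC ancestor;
* stochastic-block-model networks whose within-module paths are short;
* disease benchmarks whose seed lncRNAs' competing genes concentrate,
  per ``signal_strength``, in one module, while decoy lncRNAs draw
  genes uniformly.

All generators are pure functions of :class:`SynthConfig`; a single
``rng_seed`` drives independent substreams per component.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .interactome import InteractionTable
from .network import BioNetwork, NetworkContext
from .ontology import AnnotationMap, GoContext, OntologyDag, compute_ic, propagate_annotations
from .prioritize import FunctionalContext, LncRnaProfile

__all__ = [
    "SynthConfig",
    "make_interactome",
    "make_ontology",
    "make_networks",
    "make_contexts",
    "make_disease_benchmark",
    "write_fixture",
    "NAMESPACES",
]

NAMESPACES = ("BP", "MF", "CC")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the scale of a curated disease--lncRNA benchmark:
    a few hundred lncRNAs, a decoy pool large enough for 99-decoy
    validation runs, nine functional contexts (three ontology
    namespaces plus six networks), and 300 hold-one-out runs.
    """

    n_mirnas: int = 150
    n_lncrnas: int = 420
    n_mrnas: int = 200
    overlap_planted: int = 8
    overlap_background: int = 1
    mirnas_per_lncrna: int = 8
    mirnas_per_mrna: int = 8
    n_planted_pairs: int = 100
    dag_depth: int = 4
    dag_branching: int = 3
    n_network_modules: int = 8
    module_size: int = 25
    n_networks: int = 6
    p_within: float = 0.35
    p_between: float = 0.02
    n_diseases: int = 30
    seeds_per_disease: int = 10
    genes_per_profile: int = 6
    signal_strength: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.overlap_planted > self.n_mirnas:
            raise ValueError("overlap_planted exceeds the miRNA universe")
        if self.overlap_planted > min(self.mirnas_per_lncrna, self.mirnas_per_mrna):
            raise ValueError("overlap_planted exceeds per-transcript miRNA counts")
        if self.mirnas_per_lncrna > self.n_mirnas or self.mirnas_per_mrna > self.n_mirnas:
            raise ValueError("per-transcript miRNA count exceeds the universe")
        if not (0.0 <= self.p_between < self.p_within <= 1.0):
            raise ValueError("need 0 <= p_between < p_within <= 1")
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be >= 2")
        if self.n_network_modules < 2:
            raise ValueError("n_network_modules must be >= 2")
        if self.seeds_per_disease < 2:
            raise ValueError("seeds_per_disease must be >= 2")
        if self.genes_per_profile > self.n_mrnas:
            raise ValueError("genes_per_profile exceeds the gene count")
        if self.n_diseases * self.seeds_per_disease > self.n_lncrnas:
            raise ValueError("not enough lncRNAs for the requested seed sets")


def _rng(cfg: SynthConfig, *tags: int | str) -> np.random.Generator:
    words = [int(cfg.rng_seed) & 0x7FFFFFFF]
    for tag in tags:
        words.append(
            zlib.crc32(tag.encode()) if isinstance(tag, str) else int(tag)
        )
    return np.random.default_rng(words)


def _mirna_ids(cfg: SynthConfig) -> list[str]:
    return [f"MIR{i + 1:04d}" for i in range(cfg.n_mirnas)]


def _lncrna_ids(cfg: SynthConfig) -> list[str]:
    return [f"LNC{i + 1:05d}" for i in range(cfg.n_lncrnas)]


def _gene_ids(cfg: SynthConfig) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(cfg.n_mrnas)]


def _module_of(cfg: SynthConfig, gene_index: int) -> int:
    return gene_index % cfg.n_network_modules


def make_interactome(
    cfg: SynthConfig,
) -> tuple[InteractionTable, frozenset[tuple[str, str]]]:
    """Interaction table with planted ceRNA pairs and its truth set.

    Planted pair i links lncRNA i with mRNA i; their shared-miRNA count
    interpolates between ``overlap_background`` and ``overlap_planted``
    with ``signal_strength`` (at 1 the mRNA reuses the lncRNA's full
    miRNA set, so x = K).  Background mRNAs draw miRNAs uniformly.
    """
    rng = _rng(cfg, "interactome")
    mirnas = np.array(_mirna_ids(cfg))
    lnc_ids = _lncrna_ids(cfg)
    gene_ids = _gene_ids(cfg)
    n_planted = min(cfg.n_planted_pairs, cfg.n_lncrnas, cfg.n_mrnas)

    lnc_sets = {
        lid: rng.choice(cfg.n_mirnas, size=cfg.mirnas_per_lncrna, replace=False)
        for lid in lnc_ids
    }
    x_planted = cfg.overlap_background + round(
        cfg.signal_strength * (cfg.overlap_planted - cfg.overlap_background)
    )

    gene_sets: dict[str, np.ndarray] = {}
    truth: set[tuple[str, str]] = set()
    for i, gid in enumerate(gene_ids):
        if i < n_planted:
            partner = lnc_sets[lnc_ids[i]]
            shared = rng.choice(partner, size=x_planted, replace=False)
            outside = np.setdiff1d(np.arange(cfg.n_mirnas), partner)
            extra = rng.choice(
                outside, size=cfg.mirnas_per_mrna - x_planted, replace=False
            )
            gene_sets[gid] = np.concatenate([shared, extra])
            truth.add((lnc_ids[i], gid))
        else:
            gene_sets[gid] = rng.choice(
                cfg.n_mirnas, size=cfg.mirnas_per_mrna, replace=False
            )

    lnc_pairs = [
        (str(mirnas[m]), lid) for lid in lnc_ids for m in sorted(lnc_sets[lid])
    ]
    gene_pairs = [
        (str(mirnas[m]), gid) for gid in gene_ids for m in sorted(gene_sets[gid])
    ]
    table = InteractionTable.from_pairs(lnc_pairs, gene_pairs, mirnas.tolist())
    return table, frozenset(truth)


def make_ontology(
    cfg: SynthConfig, namespace: str = "BP"
) -> tuple[OntologyDag, AnnotationMap]:
    """A rooted DAG with one deep high-IC term per gene module.

    Levels 0..dag_depth form a ``dag_branching``-ary tree; one extra
    part_of parent is added to ~20% of terms, producing diamonds.
    Each gene is annotated to its module's deep term plus one random
    shallow (level-1) term, so within-module pairs meet at a rare
    ancestor and cross-module pairs only at shallow ones.
    """
    rng = _rng(cfg, "ontology", namespace)
    b, depth = cfg.dag_branching, cfg.dag_depth
    prefix = f"TERM{namespace}"

    levels: list[list[str]] = []
    edges: set[tuple[str, str, str]] = set()
    counter = 0
    for level in range(depth + 1):
        n_terms = b**level
        ids = [f"{prefix}:{counter + j:04d}" for j in range(n_terms)]
        counter += n_terms
        if level > 0:
            for j, term in enumerate(ids):
                edges.add((term, levels[level - 1][j // b], "is_a"))
                if len(levels[level - 1]) > 1 and rng.random() < 0.2:
                    alt = levels[level - 1][rng.integers(len(levels[level - 1]))]
                    if alt != levels[level - 1][j // b]:
                        edges.add((term, alt, "part_of"))
        levels.append(ids)

    deepest = levels[depth]
    if len(deepest) < cfg.n_network_modules:
        raise ValueError("branching**depth must cover the module count")
    leaf_idx = rng.choice(len(deepest), size=cfg.n_network_modules, replace=False)
    module_term = {m: deepest[i] for m, i in enumerate(sorted(leaf_idx))}
    shallow = levels[1]

    direct = {}
    for i, gid in enumerate(_gene_ids(cfg)):
        terms = {
            module_term[_module_of(cfg, i)],
            shallow[rng.integers(len(shallow))],
        }
        direct[gid] = frozenset(terms)

    all_terms = frozenset(t for lev in levels for t in lev)
    dag = OntologyDag(all_terms, frozenset(edges), namespace=namespace)
    ann = propagate_annotations(dag, direct)
    return dag, ann


def make_networks(cfg: SynthConfig) -> list[BioNetwork]:
    """Stochastic-block-model graphs over the genes, one per network.

    Within-module edges appear with ``p_within``, cross-module edges
    with ``p_between``, so within-module shortest paths are
    stochastically shorter.  Every gene is a node even if isolated.
    """
    gene_ids = _gene_ids(cfg)
    n = cfg.n_mrnas
    modules = np.array([_module_of(cfg, i) for i in range(n)])
    iu, ju = np.triu_indices(n, k=1)
    same = modules[iu] == modules[ju]
    probs = np.where(same, cfg.p_within, cfg.p_between)

    nets = []
    for k in range(cfg.n_networks):
        rng = _rng(cfg, "network", k)
        mask = rng.random(len(iu)) < probs
        edges = [(gene_ids[i], gene_ids[j]) for i, j in zip(iu[mask], ju[mask])]
        nets.append(
            BioNetwork.from_edges(edges, name=f"NET{k + 1}", nodes=gene_ids)
        )
    return nets


def make_contexts(cfg: SynthConfig) -> list[FunctionalContext]:
    """Three annotated ontology namespaces plus the generated networks."""
    contexts: list[FunctionalContext] = []
    for ns in NAMESPACES:
        dag, ann = make_ontology(cfg, namespace=ns)
        contexts.append(GoContext(dag, ann, name=ns))
    contexts.extend(NetworkContext(net) for net in make_networks(cfg))
    return contexts


def make_disease_benchmark(
    cfg: SynthConfig,
) -> tuple[dict[str, list[LncRnaProfile]], list[LncRnaProfile], dict]:
    """Disease seed sets with planted functional coherence, plus decoys.

    Each disease is assigned one gene module; a fraction
    ``signal_strength`` of every seed's competing genes comes from that
    module and the rest is uniform.  Decoy lncRNAs draw all competing
    genes uniformly.  Returns (disease -> seed profiles, decoy pool,
    truth record).
    """
    rng = _rng(cfg, "benchmark")
    lnc_ids = _lncrna_ids(cfg)
    n_genes = cfg.n_mrnas
    gene_ids = _gene_ids(cfg)
    module_members = {
        m: np.array(
            [i for i in range(n_genes) if _module_of(cfg, i) == m]
        )
        for m in range(cfg.n_network_modules)
    }
    n_in = round(cfg.signal_strength * cfg.genes_per_profile)

    disease_seeds: dict[str, list[LncRnaProfile]] = {}
    disease_module: dict[str, int] = {}
    cursor = 0
    for d in range(cfg.n_diseases):
        disease_id = f"D{d + 1:03d}"
        module = d % cfg.n_network_modules
        disease_module[disease_id] = module
        seeds = []
        for _ in range(cfg.seeds_per_disease):
            lid = lnc_ids[cursor]
            cursor += 1
            chosen = list(
                rng.choice(module_members[module], size=n_in, replace=False)
            )
            remaining = np.setdiff1d(np.arange(n_genes), chosen)
            chosen += list(
                rng.choice(
                    remaining,
                    size=cfg.genes_per_profile - n_in,
                    replace=False,
                )
            )
            seeds.append(
                LncRnaProfile(lid, frozenset(gene_ids[g] for g in chosen))
            )
        disease_seeds[disease_id] = seeds

    decoys = []
    for lid in lnc_ids[cursor:]:
        chosen = rng.choice(n_genes, size=cfg.genes_per_profile, replace=False)
        decoys.append(LncRnaProfile(lid, frozenset(gene_ids[g] for g in chosen)))

    truth = {
        "disease_module": disease_module,
        "seeds": {
            d: sorted(p.lncrna_id for p in ps) for d, ps in disease_seeds.items()
        },
        "decoys": sorted(p.lncrna_id for p in decoys),
    }
    return disease_seeds, decoys, truth


# ---------------------------------------------------------------------------
# fixture directory in on-disk formats


def _write_obo(dag: OntologyDag, path: Path) -> None:
    parents_by_rel: dict[str, dict[str, list[str]]] = {}
    for child, parent, rel in sorted(dag.edges):
        parents_by_rel.setdefault(child, {}).setdefault(rel, []).append(parent)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: cernarank-synthetic\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write(f"namespace: {dag.namespace}\n")
            rels = parents_by_rel.get(term, {})
            for parent in rels.get("is_a", []):
                fh.write(f"is_a: {parent}\n")
            for parent in rels.get("part_of", []):
                fh.write(f"relationship: part_of {parent}\n")


def write_fixture(cfg: SynthConfig, outdir: str | Path, n_decoys: int = 99) -> Path:
    """Write a complete fixture directory in the formats the pipeline
    reads: interaction TSVs, OBO + annotation TSVs per namespace, edge
    lists with a manifest, disease seed lists, a profile table (the
    planted lncRNA -> competing-gene map in ceRNA-table form), a
    truth.json, and a ready-to-run config.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    table, planted = make_interactome(cfg)
    for cls, fname in (("lncRNA", "interactions_lncrna.tsv"), ("mRNA", "interactions_mrna.tsv")):
        rows = sorted(
            (m, t) for m, t, c in table.records if c == cls
        )
        with open(out / fname, "w") as fh:
            fh.write("mirna_id\ttarget_id\n")
            for m, t in rows:
                fh.write(f"{m}\t{t}\n")

    for ns in NAMESPACES:
        dag, ann = make_ontology(cfg, namespace=ns)
        _write_obo(dag, out / f"ontology_{ns}.obo")
        with open(out / f"annotations_{ns}.tsv", "w") as fh:
            fh.write("gene_id\tterm_id\n")
            for gene in sorted(ann.direct):
                for term in sorted(ann.direct[gene]):
                    fh.write(f"{gene}\t{term}\n")

    manifest = {}
    for net in make_networks(cfg):
        fname = f"network_{net.name}.tsv"
        manifest[net.name] = fname
        with open(out / fname, "w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
                fh.write(f"{a}\t{b}\n")
    with open(out / "networks.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    disease_seeds, decoys, truth = make_disease_benchmark(cfg)
    with open(out / "seeds.tsv", "w") as fh:
        fh.write("disease_id\tlncrna_id\n")
        for d in sorted(disease_seeds):
            for p in sorted(disease_seeds[d], key=lambda p: p.lncrna_id):
                fh.write(f"{d}\t{p.lncrna_id}\n")
    profiles = [p for ps in disease_seeds.values() for p in ps] + decoys
    with open(out / "profiles.tsv", "w") as fh:
        fh.write("lncrna_id\tmrna_id\n")
        for p in sorted(profiles, key=lambda p: p.lncrna_id):
            for g in sorted(p.competing_genes):
                fh.write(f"{p.lncrna_id}\t{g}\n")

    truth_all = dict(truth)
    truth_all["planted_cerna_pairs"] = sorted(list(p) for p in planted)
    truth_all["config"] = asdict(cfg)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_all, fh, indent=1, sort_keys=True)

    config = {
        "lncrna_interactions": "interactions_lncrna.tsv",
        "mrna_interactions": "interactions_mrna.tsv",
        "cerna_table": "profiles.tsv",
        "ontologies": {
            ns: {"obo": f"ontology_{ns}.obo", "annotations": f"annotations_{ns}.tsv"}
            for ns in NAMESPACES
        },
        "network_manifest": "networks.json",
        "seeds": "seeds.tsv",
        "contexts": list(NAMESPACES) + sorted(manifest),
        "alpha": 0.01,
        "n_decoys": n_decoys,
        "rng_seed": cfg.rng_seed,
    }
    with open(out / "config.json", "w") as fh:
        json.dump(config, fh, indent=1, sort_keys=True)
    return out
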