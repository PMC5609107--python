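"""Ortholog-family inference by Markov clustering of a protein similarity
graph, and core/shell/singleton partitioning.

Edges require >= 40% identity over >= 50% of both sequences (configurable);
the weight is ``identity * min(query_cov, subject_cov) / 100``.  An explicit
e-value gate is not reproducible without Karlin-Altschul statistics, so the
identity/coverage gate stands in for it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .align import AA_PARAMS, AlignParams, local_align

Node = tuple[str, str]  # (strain_id, gene_id)


@dataclass
class SimilarityGraph:
    nodes: list[Node]
    edges: dict[tuple[int, int], float]  # (i, j) with i < j -> weight > 0
    strains: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_graph(protein_sets: dict[str, dict[str, str]],
                params: AlignParams = AA_PARAMS,
                min_identity: float = 40.0,
                min_coverage: float = 50.0) -> SimilarityGraph:
    """All-vs-all protein similarity graph.

    Candidate pairs are restricted to proteins sharing at least one k-mer
    (k = ``params.kmer_size``); each candidate pair is aligned once (the local
    alignment score is symmetric) and gated on identity and the smaller of
    the two coverages.
    """
    if len(protein_sets) < 2:
        raise ValueError("at least two genomes are required")
    strains = sorted(protein_sets)
    nodes: list[Node] = []
    for strain in strains:
        if not protein_sets[strain]:
            import warnings

            warnings.warn(f"strain {strain!r} has no proteins")
        for gid in sorted(protein_sets[strain]):
            nodes.append((strain, gid))
    seqs = [protein_sets[s][g] for s, g in nodes]

    k = params.kmer_size
    kmer_to_node: dict[str, list[int]] = {}
    for ni, seq in enumerate(seqs):
        for i in range(len(seq) - k + 1):
            kmer_to_node.setdefault(seq[i : i + k], []).append(ni)
    candidates: set[tuple[int, int]] = set()
    for members in kmer_to_node.values():
        if len(members) > 1:
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    candidates.add((members[a], members[b]))

    edges: dict[tuple[int, int], float] = {}
    for i, j in sorted(candidates):
        hit = local_align(seqs[i], seqs[j], params, mode="aa")
        if hit is None:
            continue
        cov = min(hit.query_cov, hit.subject_cov)
        if hit.identity >= min_identity and cov >= min_coverage:
            weight = hit.identity * cov / 100.0
            if weight > 0:
                edges[(i, j)] = weight
    return SimilarityGraph(nodes=nodes, edges=edges, strains=strains)


@dataclass
class GeneFamilySet:
    families: dict[str, frozenset]  # family_id -> set of (strain, gene)
    strains: list[str]

    @property
    def n_families(self) -> int:
        return len(self.families)

    def presence(self) -> pd.DataFrame:
        """Boolean genomes x families presence/absence matrix."""
        fam_ids = list(self.families)
        data = np.zeros((len(self.strains), len(fam_ids)), dtype=bool)
        strain_index = {s: i for i, s in enumerate(self.strains)}
        for fj, fid in enumerate(fam_ids):
            for strain, _ in self.families[fid]:
                data[strain_index[strain], fj] = True
        return pd.DataFrame(data, index=self.strains, columns=fam_ids)

    def to_table(self) -> pd.DataFrame:
        rows = [(fid, strain, gene)
                for fid, members in self.families.items()
                for strain, gene in sorted(members)]
        return pd.DataFrame(rows, columns=["family_id", "strain_id", "gene_id"])


class MCLDiagnostics(RuntimeError):
    pass


def mcl(graph: SimilarityGraph, inflation: float = 1.5, max_iter: int = 200,
        tol: float = 1e-6, prune: float = 1e-6) -> GeneFamilySet:
    """Markov clustering of the similarity graph.

    Self-loops are added with the node's maximum incident edge weight (1 for
    isolated nodes), columns are normalized, and expansion (matrix square) is
    alternated with inflation (elementwise power + renormalization, entries
    below ``prune`` dropped) until the largest entry change falls below
    ``tol``.  Families are the connected components of the converged matrix;
    isolated nodes form their own families.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")

    loop = np.zeros(n)
    rows, cols, weights = [], [], []
    for (i, j), w in graph.edges.items():
        rows += [i, j]
        cols += [j, i]
        weights += [w, w]
        loop[i] = max(loop[i], w)
        loop[j] = max(loop[j], w)
    loop[loop == 0] = 1.0
    rows += list(range(n))
    cols += list(range(n))
    weights += loop.tolist()
    M = sp.csr_matrix((weights, (rows, cols)), shape=(n, n))
    M = _normalize_columns(M)

    for _ in range(max_iter):
        expanded = (M @ M).tocsr()
        expanded.data **= inflation
        expanded.data[expanded.data < prune] = 0.0
        expanded.eliminate_zeros()
        expanded = _normalize_columns(expanded)
        change = abs(expanded - M).max()
        M = expanded
        if change < tol:
            break
    else:
        raise MCLDiagnostics(
            f"MCL did not converge in {max_iter} iterations (last change {change:.3g})")

    n_comp, labels = connected_components(M + M.T, directed=False)
    members: dict[int, set[Node]] = {}
    for ni, lab in enumerate(labels):
        members.setdefault(int(lab), set()).add(graph.nodes[ni])
    ordered = sorted(members.values(), key=lambda m: min(m))
    families = {f"FAM{idx + 1:05d}": frozenset(m) for idx, m in enumerate(ordered)}
    return GeneFamilySet(families=families, strains=list(graph.strains))


def _normalize_columns(M: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(M.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return (M @ sp.diags(1.0 / sums)).tocsr()


@dataclass
class PangenomeSubsets:
    pangenome_size: int
    core: int
    shell: int
    singleton_families: int
    singleton_genes: int
    per_genome_unique: dict[str, int]
    core_ids: list[str] = field(default_factory=list)
    singleton_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pangenome": self.pangenome_size,
            "core": self.core,
            "shell": self.shell,
            "singleton_families": self.singleton_families,
            "singleton_genes": self.singleton_genes,
            "per_genome_unique": self.per_genome_unique,
        }


def subsets(families: GeneFamilySet, n_genomes: int | None = None) -> PangenomeSubsets:
    """Partition families into core (all genomes), singleton (one genome) and
    shell (the rest).  Singletons are also counted as genes, since a
    single-genome family may contain paralogs."""
    if not families.families:
        raise ValueError("no families")
    n = n_genomes if n_genomes is not None else len(families.strains)
    core_ids, singleton_ids = [], []
    singleton_genes = 0
    per_genome_unique = {s: 0 for s in families.strains}
    for fid, members in families.families.items():
        genomes = {strain for strain, _ in members}
        if len(genomes) == n:
            core_ids.append(fid)
        elif len(genomes) == 1:
            singleton_ids.append(fid)
            singleton_genes += len(members)
            per_genome_unique[next(iter(genomes))] += 1
    total = len(families.families)
    return PangenomeSubsets(
        pangenome_size=total,
        core=len(core_ids),
        shell=total - len(core_ids) - len(singleton_ids),
        singleton_families=len(singleton_ids),
        singleton_genes=singleton_genes,
        per_genome_unique=per_genome_unique,
        core_ids=core_ids,
        singleton_ids=singleton_ids,
    )
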