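"""Trunk/branch/private partition of multi-tumor mutation sets and the
derived clonal-relatedness evidence.

A patient contributes 2 or 3 tumor samples (esophageal T, regional node LN,
distant D). Mutations present in every tumor are trunk; in exactly one pair,
branch; in exactly one sample, private. Trees are drawn over nonsynonymous
mutated genes, with edge lengths equal to distinct gene counts. The B-allele
frequency (BAF) comparison and the cross-patient overlap matrix are the
supporting analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import VariantRecord

MutationKey = tuple[str, int, str, str]


def keys_of(records: Iterable[VariantRecord | MutationKey]) -> set[MutationKey]:
    out: set[MutationKey] = set()
    for r in records:
        out.add(r.key if isinstance(r, VariantRecord) else tuple(r))
    return out


@dataclass
class MutationPartition:
    """Disjoint cover of a patient's mutation keys by sharing pattern."""

    sample_ids: tuple[str, ...]
    trunk: set[MutationKey]
    branch: dict[frozenset, set[MutationKey]]  # pair of sample_ids -> keys
    private: dict[str, set[MutationKey]]

    @property
    def all_keys(self) -> set[MutationKey]:
        keys = set(self.trunk)
        for s in self.branch.values():
            keys |= s
        for s in self.private.values():
            keys |= s
        return keys

    @property
    def trunk_fraction(self) -> float:
        total = len(self.all_keys)
        return len(self.trunk) / total if total else float("nan")

    def check(self) -> None:
        """Assert the disjoint-cover invariant."""
        sets = [self.trunk, *self.branch.values(), *self.private.values()]
        total = sum(len(s) for s in sets)
        if total != len(self.all_keys):
            raise AssertionError("partition sets are not pairwise disjoint")


def partition_mutations(
    patient_callsets: Mapping[str, Iterable[VariantRecord | MutationKey]],
) -> MutationPartition:
    """Partition one patient's per-sample mutation keys.

    Input callsets must already be filtered and nonsynonymous-only. For a
    2-sample patient the pairwise intersection is the trunk (no branch sets);
    for 3 samples, keys in all three are trunk, in exactly two are branch,
    in one are private.
    """
    samples = tuple(patient_callsets.keys())
    if len(samples) < 2 or len(samples) > 3:
        raise ValueError(f"need 2 or 3 tumor samples, got {len(samples)}")
    key_sets = {s: keys_of(patient_callsets[s]) for s in samples}
    trunk = set.intersection(*key_sets.values())
    branch: dict[frozenset, set[MutationKey]] = {}
    if len(samples) == 3:
        for a, b in itertools.combinations(samples, 2):
            branch[frozenset((a, b))] = (key_sets[a] & key_sets[b]) - trunk
    private = {}
    for s in samples:
        others = set().union(*(key_sets[o] for o in samples if o != s))
        private[s] = key_sets[s] - others
    part = MutationPartition(sample_ids=samples, trunk=trunk, branch=branch, private=private)
    part.check()
    return part


def td_shared_count(partition: MutationPartition, t_sample: str, d_sample: str) -> int:
    """Trunk mutations plus T&D-shared branch mutations (0 branch for pairs)."""
    n = len(partition.trunk)
    pair = frozenset((t_sample, d_sample))
    if pair in partition.branch:
        n += len(partition.branch[pair])
    return n


# ---------------------------------------------------------------------------
# phylogenetic tree over mutated genes


@dataclass
class PhyloTree:
    """Rooted tree: germline root, trunk edge, optional shared clade, leaves.

    Edge lengths are distinct nonsynonymous mutated GENE counts, so the sum
    of lengths on the root-to-leaf path equals the number of mutated genes
    attributed to that sample.
    """

    newick: str
    trunk_genes: int
    edge_genes: dict[str, int]  # leaf -> terminal edge length
    clade: tuple[frozenset, int] | None  # (pair, branch edge length) if present

    def path_length(self, sample: str) -> int:
        n = self.trunk_genes + self.edge_genes[sample]
        if self.clade and sample in self.clade[0]:
            n += self.clade[1]
        return n


def build_tree(
    partition: MutationPartition, gene_of: Mapping[MutationKey, str]
) -> PhyloTree:
    """Build the per-patient tree from a partition and a key->gene map.

    When more than one pairwise branch set is nonempty the sets need not be
    tree-compatible; the pair with the largest distinct-gene count becomes
    the internal clade and the remaining branch genes are folded into the
    terminal edges of their member samples, preserving per-sample path sums.
    """

    def genes(keys: Iterable[MutationKey]) -> set[str]:
        return {gene_of[k] for k in keys}

    trunk_genes = len(genes(partition.trunk))
    branch_genes = {p: genes(ks) for p, ks in partition.branch.items() if ks}
    clade_pair = None
    if branch_genes:
        clade_pair = max(
            branch_genes, key=lambda p: (len(branch_genes[p]), tuple(sorted(p)))
        )
    edge_genes = {}
    for s in partition.sample_ids:
        g = genes(partition.private.get(s, set()))
        for p, bg in branch_genes.items():
            if p != clade_pair and s in p:
                g |= bg
        edge_genes[s] = len(g)

    def leaf(s: str) -> str:
        return f"{s}:{edge_genes[s]}"

    if clade_pair is not None:
        a, b = sorted(clade_pair)
        rest = [s for s in partition.sample_ids if s not in clade_pair]
        clade_len = len(branch_genes[clade_pair])
        inner = f"({leaf(a)},{leaf(b)}):{clade_len}"
        children = ",".join([inner] + [leaf(s) for s in rest])
    else:
        children = ",".join(leaf(s) for s in partition.sample_ids)
    newick = f"(({children}):{trunk_genes})germline;"
    return PhyloTree(
        newick=newick,
        trunk_genes=trunk_genes,
        edge_genes=edge_genes,
        clade=(clade_pair, len(branch_genes[clade_pair])) if clade_pair else None,
    )


def tree_as_dendropy(tree: PhyloTree):
    """Parse the Newick into a dendropy Tree (for plotting/export)."""
    import dendropy

    return dendropy.Tree.get(data=tree.newick, schema="newick")


# ---------------------------------------------------------------------------
# BAF distribution comparison


@dataclass
class BafComparison:
    """Paired tumor VAFs over the key union of two samples.

    ``shared_cluster_statistic`` is the fraction of union keys observed at
    VAF >= tau in BOTH samples — an explicit operationalization of the
    visual "shared mutation cluster" comparison; it is 1 for identical
    callsets and 0 for disjoint ones.
    """

    table: pd.DataFrame  # columns: key, vaf_a, vaf_b
    tau: float
    shared_cluster_statistic: float


def compare_baf(
    callset_a: Sequence[VariantRecord],
    callset_b: Sequence[VariantRecord],
    tau: float = 0.05,
) -> BafComparison:
    vaf_a = {r.key: (r.t_alt / r.t_depth if r.t_depth else 0.0) for r in callset_a}
    vaf_b = {r.key: (r.t_alt / r.t_depth if r.t_depth else 0.0) for r in callset_b}
    union = sorted(set(vaf_a) | set(vaf_b))
    rows = [(k, vaf_a.get(k, 0.0), vaf_b.get(k, 0.0)) for k in union]
    table = pd.DataFrame(rows, columns=["key", "vaf_a", "vaf_b"])
    if union:
        stat = float(np.mean((table["vaf_a"] >= tau) & (table["vaf_b"] >= tau)))
    else:
        stat = 0.0
    return BafComparison(table=table, tau=tau, shared_cluster_statistic=stat)


# ---------------------------------------------------------------------------
# cross-patient coincidence control


def cross_patient_overlap(
    cohort_callsets: Mapping[str, Mapping[str, Iterable[VariantRecord | MutationKey]]],
) -> pd.DataFrame:
    """Shared-key counts between all tumor pairs from DIFFERENT patients.

    Rows/columns are (patient, sample); same-patient cells are NaN (excluded
    by design — within-patient sharing is the signal, not the control).
    """
    patients = list(cohort_callsets.keys())
    if len(patients) < 2:
        raise ValueError("cross-patient control needs at least 2 patients")
    index = [
        (p, s) for p in patients for s in cohort_callsets[p].keys()
    ]
    key_sets = {(p, s): keys_of(cohort_callsets[p][s]) for p, s in index}
    mat = pd.DataFrame(
        np.full((len(index), len(index)), np.nan),
        index=pd.MultiIndex.from_tuples(index, names=["patient", "sample"]),
        columns=pd.MultiIndex.from_tuples(index, names=["patient", "sample"]),
    )
    for i, a in enumerate(index):
        for b in index[i:]:
            if a[0] == b[0]:
                continue
            n = len(key_sets[a] & key_sets[b])
            mat.loc[a, b] = n
            mat.loc[b, a] = n
    return mat
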