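"""Neighbor-joining trees, bootstrap supports, monophyly and divergence.

Trees are unrooted: topology questions ("does this species form a distinct
group?") are answered on bipartitions, the rooting-free notion of a clade.
NJ is the classic Saitou–Nei agglomeration, which reconstructs any additive
distance matrix exactly — topology and branch lengths — and is therefore
property-testable against randomly generated trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Alignment, DistanceMatrix, p_distance
from .formats import SpecimenRecord

_EPS = 1e-12


@dataclass
class UnrootedTree:
    """Unrooted tree: adjacency with branch lengths, leaf labels, supports.

    ``supports`` maps an internal edge (frozenset of its two node ids) to an
    integer bootstrap percentage. Zero-length internal edges produced by NJ
    on degenerate (e.g. all-equal) distances are collapsed to polytomies;
    negative NJ branch lengths are clamped to zero and flagged.
    """

    adj: dict[int, dict[int, float]] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)
    supports: dict[frozenset, int] = field(default_factory=dict)
    negative_clamped: bool = False

    # -- construction helpers -------------------------------------------------
    def _add_edge(self, u: int, v: int, length: float) -> None:
        self.adj.setdefault(u, {})[v] = length
        self.adj.setdefault(v, {})[u] = length

    # -- basic queries --------------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.labels.values())

    def n_leaves(self) -> int:
        return len(self.labels)

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u, nb in self.adj.items():
            for v, ln in nb.items():
                if u < v:
                    out.append((u, v, ln))
        return out

    def _side_leaves(self, u: int, v: int) -> frozenset:
        """Leaf labels reachable from v without crossing edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            x = stack.pop()
            if x in self.labels:
                out.append(self.labels[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def _normalize(self, side: frozenset) -> frozenset:
        ref = min(self.labels.values())
        return side if ref not in side else frozenset(self.labels.values()) - side

    def bipartitions(self, nontrivial_only: bool = True) -> dict[frozenset, frozenset]:
        """Map normalized split (leafset on the side away from the reference
        leaf) → edge key. Nontrivial means both sides have ≥2 leaves."""
        n = self.n_leaves()
        out: dict[frozenset, frozenset] = {}
        for u, v, _ in self.edges():
            side = self._side_leaves(u, v)
            if nontrivial_only and not (2 <= len(side) <= n - 2):
                continue
            out[self._normalize(side)] = frozenset((u, v))
        return out

    def split_set(self) -> frozenset:
        return frozenset(self.bipartitions().keys())

    def has_clade(self, leafset: Iterable[str]) -> bool:
        """True iff some edge separates exactly this leaf set from the rest."""
        ls = frozenset(leafset)
        all_leaves = frozenset(self.labels.values())
        if not ls or ls == all_leaves or len(ls) == 1:
            return True
        return self._normalize(ls) in self.bipartitions(nontrivial_only=False)

    # -- Newick ---------------------------------------------------------------
    def _smallest_leaf_below(self, u: int, parent: int, memo: dict) -> str:
        key = (u, parent)
        if key in memo:
            return memo[key]
        if u in self.labels:
            memo[key] = self.labels[u]
            return self.labels[u]
        best = min(
            self._smallest_leaf_below(v, u, memo) for v in self.adj[u] if v != parent
        )
        memo[key] = best
        return best

    def to_newick(self) -> str:
        if self.n_leaves() < 2:
            raise ValueError("newick output requires ≥2 leaves")
        for node, lab in self.labels.items():
            if not lab:
                raise ValueError(f"unnamed leaf node {node}")
        internal = [u for u in self.adj if u not in self.labels]
        if not internal:  # 2-leaf tree: single edge
            (u, v, ln) = self.edges()[0]
            return f"({self.labels[u]}:{ln:g},{self.labels[v]}:{ln:g});"
        ref = min(self.labels.values())
        ref_node = next(k for k, v in self.labels.items() if v == ref)
        root = next(iter(self.adj[ref_node]))
        memo: dict = {}

        def render(u: int, parent: int) -> str:
            ln = self.adj[u][parent]
            if u in self.labels:
                return f"{self.labels[u]}:{ln:g}"
            kids = sorted(
                (v for v in self.adj[u] if v != parent),
                key=lambda v: self._smallest_leaf_below(v, u, memo),
            )
            inner = ",".join(render(v, u) for v in kids)
            sup = self.supports.get(frozenset((u, parent)))
            lab = "" if sup is None else str(int(sup))
            return f"({inner}){lab}:{ln:g}"

        kids = sorted(self.adj[root], key=lambda v: self._smallest_leaf_below(v, root, memo))
        inner = ",".join(render(v, root) for v in kids)
        return f"({inner});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- parsing --------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "UnrootedTree":
        import dendropy

        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        dt.deroot()
        tree = cls()
        ids: dict = {}

        def nid(node) -> int:
            if node not in ids:
                ids[node] = len(ids)
            return ids[node]

        for node in dt.preorder_node_iter():
            u = nid(node)
            if node.taxon is not None:
                tree.labels[u] = node.taxon.label
            if node.parent_node is not None:
                p = nid(node.parent_node)
                ln = node.edge.length if node.edge.length is not None else 0.0
                tree._add_edge(p, u, float(ln))
                if node.taxon is None and node.label not in (None, ""):
                    try:
                        tree.supports[frozenset((p, u))] = int(float(node.label))
                    except ValueError:
                        pass
        return tree

    @classmethod
    def from_newick_file(cls, path: str | Path) -> "UnrootedTree":
        return cls.from_newick(Path(path).read_text())


@dataclass(frozen=True)
class MonophylyCall:
    species: str
    monophyletic: bool
    n_individuals: int


@dataclass(frozen=True)
class AgreementTable:
    """2×2 Sanger-vs-NGS monophyly concordance counts."""

    a: int  # Sanger mono / NGS mono
    b: int  # Sanger mono / NGS non
    c: int  # Sanger non / NGS mono
    d: int  # Sanger non / NGS non

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def overall_percent_agreement(self) -> float:
        return 100.0 * (self.a + self.d) / self.total

    @property
    def overall_percent_agreement_rounded(self) -> int:
        return round(self.overall_percent_agreement)


def nj_tree(dm: DistanceMatrix) -> UnrootedTree:
    """Saitou–Nei neighbor joining.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster representatives (a cluster is represented by its
    smallest member label), so the result is deterministic.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("nj_tree requires ≥3 labels")
    if len(set(dm.labels)) != n0:
        raise ValueError("duplicate labels in distance matrix")

    D = dm.d.astype(float).copy()
    tree = UnrootedTree()
    for i, lab in enumerate(dm.labels):
        tree.labels[i] = lab
    node_of = list(range(n0))  # active index -> tree node id
    reps = list(dm.labels)  # representative label per active cluster
    next_node = n0
    clamped = False
    pending: list[tuple[int, int, float]] = []  # edges before zero-collapse

    def pick_pair(Q: np.ndarray) -> tuple[int, int]:
        m = Q.shape[0]
        mask = ~np.eye(m, dtype=bool)
        qmin = Q[mask].min()
        best = None
        for i, j in np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-9)):
            if i >= j:
                continue
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or key < best[0]:
                best = (key, (int(i), int(j)))
        return best[1]

    while D.shape[0] > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        i, j = pick_pair(Q)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        u = next_node
        next_node += 1
        pending.append((u, node_of[i], li))
        pending.append((u, node_of[j], lj))
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        node_of = [node_of[k] for k in keep] + [u]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
        D = D2

    # close the unrooted tree with the final three-point formulas
    a, b, c = 0, 1, 2
    u = next_node
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, lk in ((a, la), (b, lb), (c, lc)):
        pending.append((u, node_of[k], lk))

    # clamp negatives; collapse exactly-zero internal edges to polytomies
    parent_map: dict[int, int] = {}
    for u_, v_, ln in pending:
        if ln < -_EPS:
            clamped = True
            ln = 0.0
        both_internal = u_ not in tree.labels and v_ not in tree.labels
        if both_internal and abs(ln) <= _EPS:
            parent_map[max(u_, v_)] = min(u_, v_)
        tree._add_edge(u_, v_, max(ln, 0.0))

    def find(x: int) -> int:
        while x in parent_map and parent_map[x] != x:
            x = parent_map[x]
        return x

    if parent_map:
        merged = UnrootedTree(labels=dict(tree.labels), negative_clamped=clamped)
        for u_, v_, ln in tree.edges():
            ru, rv = find(u_), find(v_)
            if ru != rv:
                merged._add_edge(ru, rv, ln)
        return merged
    tree.negative_clamped = clamped
    return tree


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 1000,
    gap_policy: str = "pairwise_deletion",
    seed: int = 0,
) -> UnrootedTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    yields p-distances and an NJ tree, and the support of every internal
    edge of the full-data tree is the percentage of replicate trees that
    contain the same bipartition. Replicates in which some pair has no
    comparable sites are skipped (with a warning) and excluded from the
    denominator.
    """
    from .align import p_distance_matrix  # local: avoids import at module load

    if len(alignment.rows) < 4:
        raise ValueError("bootstrap_support requires ≥4 rows")
    if n_reps < 1:
        raise ValueError("n_reps must be ≥1")
    base = nj_tree(p_distance_matrix(alignment, gap_policy))
    M = alignment.matrix()
    if gap_policy == "complete_deletion":
        M = M[:, (M != 0).all(axis=0)]
    n, L = M.shape
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {s: 0 for s in base.split_set()}
    used = 0
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        R = M[:, cols]
        d = np.zeros((n, n))
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                dij, comp = p_distance(R[i], R[j])
                if comp == 0:
                    ok = False
                    break
                d[i, j] = d[j, i] = dij
            if not ok:
                break
        if not ok:
            skipped += 1
            continue
        rep_tree = nj_tree(DistanceMatrix(alignment.ids, d))
        used += 1
        for s in rep_tree.split_set():
            if s in counts:
                counts[s] += 1
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicates skipped (no comparable sites)")
    if used == 0:
        raise ValueError("all bootstrap replicates degenerate")
    bip = base.bipartitions()
    for split, edge in bip.items():
        base.supports[edge] = int(round(100.0 * counts[split] / used))
    return base


def monophyly(
    tree: UnrootedTree,
    specimens: Sequence[SpecimenRecord],
    leaf_to_specimen: Mapping[str, str],
) -> tuple[list[MonophylyCall], dict[str, bool]]:
    """Classify each species as monophyletic or not on an unrooted tree.

    A species is monophyletic iff some bipartition separates exactly its
    leaves from all others (single-leaf species are monophyletic by
    convention). Every individual inherits its species' status.
    """
    by_id = {s.specimen_id: s for s in specimens}
    species_leaves: dict[str, set[str]] = {}
    species_individuals: dict[str, set[str]] = {}
    for leaf in tree.labels.values():
        if leaf not in leaf_to_specimen:
            raise ValueError(f"leaf {leaf!r} not mapped to a specimen")
        sid = leaf_to_specimen[leaf]
        if sid not in by_id:
            raise ValueError(f"specimen {sid!r} (leaf {leaf!r}) not in metadata")
        sp = by_id[sid].species
        species_leaves.setdefault(sp, set()).add(leaf)
        species_individuals.setdefault(sp, set()).add(sid)
    calls = [
        MonophylyCall(sp, tree.has_clade(leaves), len(species_individuals[sp]))
        for sp, leaves in sorted(species_leaves.items())
    ]
    status_by_species = {c.species: c.monophyletic for c in calls}
    individual_status = {
        sid: status_by_species[by_id[sid].species]
        for sids in species_individuals.values()
        for sid in sids
    }
    return calls, individual_status


def agreement_table(
    sanger_status: Mapping[str, bool],
    ngs_status: Mapping[str, bool],
) -> AgreementTable:
    """2×2 concordance of per-individual monophyly between two methods."""
    if set(sanger_status) != set(ngs_status):
        raise ValueError("sanger and NGS status maps cover different individuals")
    a = b = c = d = 0
    for k, s in sanger_status.items():
        g = ngs_status[k]
        if s and g:
            a += 1
        elif s and not g:
            b += 1
        elif not s and g:
            c += 1
        else:
            d += 1
    return AgreementTable(a, b, c, d)


_CATEGORIES = (
    "conspecific",
    "congeneric",
    "intergeneric",
    "within_tribe",
    "between_tribe",
    "between_subfamily",
)


def divergence_summary(
    dm: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    leaf_to_specimen: Mapping[str, str],
    exclude_genera: Sequence[str] = (),
) -> tuple[pd.DataFrame, bool | None]:
    """Mean/min/max pairwise p-distance (×100) per taxonomic category.

    Categories are mutually refining: congeneric excludes conspecific
    pairs, intergeneric excludes congeneric; the tribe/subfamily splits
    partition the intergeneric pairs when that metadata is present. Also
    reports whether a barcoding gap exists (min congeneric > max
    conspecific). Labels whose genus is in ``exclude_genera`` are dropped
    first (sensitivity reruns).
    """
    by_id = {s.specimen_id: s for s in specimens}
    keep_idx = []
    recs = []
    for idx, lab in enumerate(dm.labels):
        rec = by_id[leaf_to_specimen[lab]]
        if rec.genus in exclude_genera:
            continue
        keep_idx.append(idx)
        recs.append(rec)
    vals: dict[str, list[float]] = {c: [] for c in _CATEGORIES}
    for ai in range(len(keep_idx)):
        for bi in range(ai + 1, len(keep_idx)):
            ra, rb = recs[ai], recs[bi]
            d = 100.0 * dm.d[keep_idx[ai], keep_idx[bi]]
            if ra.species == rb.species:
                vals["conspecific"].append(d)
            elif ra.genus and ra.genus == rb.genus:
                vals["congeneric"].append(d)
            else:
                vals["intergeneric"].append(d)
                if ra.tribe and rb.tribe:
                    if ra.tribe == rb.tribe:
                        vals["within_tribe"].append(d)
                    elif ra.subfamily and ra.subfamily == rb.subfamily:
                        vals["between_tribe"].append(d)
                if ra.subfamily and rb.subfamily and ra.subfamily != rb.subfamily:
                    vals["between_subfamily"].append(d)
    rows = []
    for cat in _CATEGORIES:
        v = vals[cat]
        if v:
            rows.append((cat, len(v), float(np.mean(v)), float(np.min(v)), float(np.max(v))))
    table = pd.DataFrame(rows, columns=["category", "n_pairs", "mean", "min", "max"])
    gap: bool | None = None
    if vals["conspecific"] and vals["congeneric"]:
        gap = bool(min(vals["congeneric"]) > max(vals["conspecific"]))
    return table, gap
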