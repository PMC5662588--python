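"""Census pedigree cleaning and additive genetic relationship structures.

A pedigree is a directed acyclic parentage graph. The cleaning pipeline used
for census registers is: founderize adoptees, remove parentage loops, truncate
ancestry above the grandparents of phenotyped children, and prune branches
that carry no phenotypic information. After cleaning, every pair of phenotyped
individuals is classified as full siblings, half siblings, full cousins, half
cousins, or unrelated, and the additive genetic relationship matrix A is
assembled from the corresponding expected-relatedness coefficients
(0.5 / 0.25 / 0.125 / 0.0625 / 0). The matrix is block diagonal by extended
family, which the Gibbs sampler exploits.

A recursive kinship coefficient and a Henderson sparse A-inverse are provided
as independent routes to the same relatedness information; tests cross-check
the classification-based A against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

#: tokens that denote an unknown parent in pedigree files
UNKNOWN_TOKENS = {"0", "", "NA", "na", "nan"}


class RelationClass(Enum):
    """Pairwise relation classes recognized in a grandparent-truncated pedigree.

    Classes are mutually exclusive; when a pair qualifies for several (e.g.
    double half cousins) the highest-priority class — the one with the largest
    relatedness coefficient — is assigned.
    """

    FULL_SIBLING = "full_sibling"
    HALF_SIBLING = "half_sibling"
    FULL_COUSIN = "full_cousin"
    HALF_COUSIN = "half_cousin"
    OTHER = "other"


#: expected additive relatedness (twice the kinship coefficient) per class,
#: under the non-inbred convention
RELATEDNESS = {
    RelationClass.FULL_SIBLING: 0.5,
    RelationClass.HALF_SIBLING: 0.25,
    RelationClass.FULL_COUSIN: 0.125,
    RelationClass.HALF_COUSIN: 0.0625,
    RelationClass.OTHER: 0.0,
}


def relatedness_coefficient(rc: RelationClass) -> float:
    """Expected additive relatedness for a relation class."""
    return RELATEDNESS[rc]


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None
    mother: str | None
    adopted: bool = False
    phenotyped: bool = False

    def parents(self) -> tuple[str | None, str | None]:
        return (self.father, self.mother)

    def known_parents(self) -> tuple[str, ...]:
        return tuple(p for p in (self.father, self.mother) if p is not None)


class Pedigree:
    """An immutable-by-convention collection of :class:`Individual` records.

    Insertion order is preserved; all cleaning operations return new
    ``Pedigree`` objects and leave their input untouched.
    """

    def __init__(self, individuals: dict[str, Individual] | list[Individual]):
        if not isinstance(individuals, dict):
            individuals = {ind.id: ind for ind in individuals}
        self._inds: dict[str, Individual] = dict(individuals)
        self._children: dict[str, list[str]] | None = None

    def __len__(self) -> int:
        return len(self._inds)

    def __contains__(self, iid: str) -> bool:
        return iid in self._inds

    def __iter__(self):
        return iter(self._inds.values())

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self._inds[iid]
        except KeyError:
            raise KeyError(f"unknown individual id {iid!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._inds)

    def phenotyped_ids(self) -> list[str]:
        return sorted(i.id for i in self if i.phenotyped)

    def children_of(self, iid: str) -> list[str]:
        if self._children is None:
            ch: dict[str, list[str]] = {}
            for ind in self:
                for p in ind.known_parents():
                    ch.setdefault(p, []).append(ind.id)
            self._children = ch
        return self._children.get(iid, [])

    def parentage_graph(self) -> nx.DiGraph:
        """Directed graph with an edge parent -> child for every known link."""
        g = nx.DiGraph()
        g.add_nodes_from(self._inds)
        for ind in self:
            for p in ind.known_parents():
                if p in self._inds:
                    g.add_edge(p, ind.id)
        return g

    def founders(self) -> list[str]:
        return [i.id for i in self if not i.known_parents()]

    def with_individuals(self, inds: dict[str, Individual]) -> "Pedigree":
        return Pedigree(inds)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_HEADER_NAMES = {"id", "child_id", "iid"}


def _parse_token(tok: str) -> str | None:
    tok = tok.strip()
    return None if tok in UNKNOWN_TOKENS else tok


def read_pedigree(
    path: str | Path,
    phenotyped: set[str] | None = None,
    add_missing_founders: bool = True,
) -> Pedigree:
    """Read a delimited pedigree file (comma or tab autodetected).

    Columns: ``id, father_id, mother_id[, adopted(0/1)]``. The tokens ``0``,
    empty, and ``NA`` mean *unknown parent*. A header row is skipped when its
    first field looks like a column name. Parents that are referenced but have
    no row of their own are added as founder records (count logged).

    Parameters
    ----------
    phenotyped:
        Optional set of IDs to flag as phenotyped on load.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text:
        raise ParseError(f"{path}: empty pedigree file")
    sep = "\t" if "\t" in text[0] else ","
    inds: dict[str, Individual] = {}
    dupes: list[str] = []
    start = 1 if text[0].split(sep)[0].strip().lower() in _HEADER_NAMES else 0
    for lineno, line in enumerate(text[start:], start=start + 1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) not in (3, 4):
            raise ParseError(
                f"{path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
            )
        iid = fields[0]
        if iid in UNKNOWN_TOKENS:
            raise ParseError(f"{path}:{lineno}: invalid individual id {iid!r}")
        father, mother = _parse_token(fields[1]), _parse_token(fields[2])
        if iid in (father, mother):
            raise ValidationError(f"{path}:{lineno}: {iid!r} is its own parent")
        adopted = len(fields) == 4 and fields[3].strip() == "1"
        if iid in inds:
            dupes.append(iid)
            continue
        inds[iid] = Individual(
            id=iid,
            father=father,
            mother=mother,
            adopted=adopted,
            phenotyped=phenotyped is not None and iid in phenotyped,
        )
    if dupes:
        raise ValidationError(f"{path}: duplicate individual ids: {sorted(set(dupes))}")
    if add_missing_founders:
        missing = {
            p
            for ind in inds.values()
            for p in ind.known_parents()
            if p not in inds
        }
        for p in sorted(missing):
            inds[p] = Individual(id=p, father=None, mother=None)
        if missing:
            log.info("read_pedigree: added %d implicit founder records", len(missing))
    return Pedigree(inds)


def write_pedigree(ped: Pedigree, path: str | Path, sep: str = "\t") -> None:
    """Write a pedigree in the dialect :func:`read_pedigree` accepts."""
    with open(path, "w") as fh:
        for ind in ped:
            fh.write(
                sep.join(
                    [
                        ind.id,
                        ind.father or "0",
                        ind.mother or "0",
                        "1" if ind.adopted else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------


def founderize_adoptees(ped: Pedigree) -> tuple[Pedigree, int]:
    """Give every adopted individual unknown parents.

    Census parentage records legal, not biological, parents; severing the
    links of known adoptees prevents spurious genetic relatedness.

    Returns the cleaned pedigree and the number of modified records.
    """
    inds = {}
    n_mod = 0
    for ind in ped:
        if ind.adopted and (ind.father is not None or ind.mother is not None):
            ind = replace(ind, father=None, mother=None)
            n_mod += 1
        inds[ind.id] = ind
    log.info("founderize_adoptees: severed parents of %d adoptees", n_mod)
    return Pedigree(inds), n_mod


def remove_loops(ped: Pedigree) -> tuple[Pedigree, list[str]]:
    """Drop every individual that lies on a directed parentage cycle.

    Registry data can contain impossible records — a person listed as their
    own grandparent. All members of each cycle are removed (strongly connected
    components of size > 1 in the parent->child graph), and their surviving
    children get an unknown parent in place of the removed one.
    """
    g = ped.parentage_graph()
    on_cycle: set[str] = set()
    for comp in nx.strongly_connected_components(g):
        if len(comp) > 1:
            on_cycle |= comp
    inds = {}
    for ind in ped:
        if ind.id in on_cycle:
            continue
        f = ind.father if ind.father not in on_cycle else None
        m = ind.mother if ind.mother not in on_cycle else None
        if (f, m) != (ind.father, ind.mother):
            ind = replace(ind, father=f, mother=m)
        inds[ind.id] = ind
    removed = sorted(on_cycle)
    log.info("remove_loops: removed %d individuals on parentage cycles", len(removed))
    return Pedigree(inds), removed


def _generations_above_phenotyped(ped: Pedigree) -> dict[str, int]:
    """Minimum generation distance from each individual down to a phenotyped
    descendant (0 for phenotyped individuals; absent = no phenotyped descendant)."""
    from collections import deque

    dist = {i.id: 0 for i in ped if i.phenotyped}
    q = deque(dist)
    while q:
        cur = q.popleft()
        d = dist[cur] + 1
        for p in ped[cur].known_parents():
            if p in ped and dist.get(p, np.inf) > d:
                dist[p] = d
                q.append(p)
    return dist


def truncate_generations(ped: Pedigree, depth: int = 2) -> tuple[Pedigree, list[str]]:
    """Sever ancestry more than ``depth`` generations above phenotyped individuals.

    ``depth=2`` keeps parents and grandparents of phenotyped children and
    assumes great-grandparents unknown — the convention for register pedigrees
    whose deep ancestry is unreliable. Boundary is inclusive: an ancestor
    exactly ``depth`` generations above some phenotyped descendant is kept.
    """
    if depth < 1:
        raise ValidationError(f"truncation depth must be >= 1, got {depth}")
    dist = _generations_above_phenotyped(ped)
    drop = {
        i.id
        for i in ped
        if i.id in dist and dist[i.id] > depth
    }
    inds = {}
    for ind in ped:
        if ind.id in drop:
            continue
        f = ind.father if ind.father not in drop else None
        m = ind.mother if ind.mother not in drop else None
        if (f, m) != (ind.father, ind.mother):
            ind = replace(ind, father=f, mother=m)
        inds[ind.id] = ind
    removed = sorted(drop)
    log.info("truncate_generations(depth=%d): dropped %d ancestors", depth, len(removed))
    return Pedigree(inds), removed


def prune_noninformative(ped: Pedigree) -> tuple[Pedigree, list[str]]:
    """Remove non-phenotyped individuals with no phenotyped children or
    grandchildren, iterated to fixpoint.

    Such individuals contribute nothing to the relationship structure among
    phenotyped individuals. Removal severs their surviving children's parent
    pointers, which can make further ancestors non-informative, hence the
    fixpoint iteration. Phenotyped individuals are never removed.
    """
    inds = {i.id: i for i in ped}
    removed: list[str] = []
    while True:
        children: dict[str, list[str]] = {}
        for ind in inds.values():
            for p in ind.known_parents():
                if p in inds:
                    children.setdefault(p, []).append(ind.id)
        drop = set()
        for ind in inds.values():
            if ind.phenotyped:
                continue
            kids = children.get(ind.id, [])
            grandkids = [g for k in kids for g in children.get(k, [])]
            if not any(inds[k].phenotyped for k in kids) and not any(
                inds[g].phenotyped for g in grandkids
            ):
                drop.add(ind.id)
        if not drop:
            break
        new = {}
        for ind in inds.values():
            if ind.id in drop:
                continue
            f = ind.father if ind.father not in drop else None
            m = ind.mother if ind.mother not in drop else None
            if (f, m) != (ind.father, ind.mother):
                ind = replace(ind, father=f, mother=m)
            new[ind.id] = ind
        inds = new
        removed.extend(sorted(drop))
    log.info("prune_noninformative: removed %d non-informative individuals", len(removed))
    return Pedigree(inds), removed


def clean_pedigree(
    ped: Pedigree, depth: int = 2
) -> tuple[Pedigree, dict[str, int]]:
    """Full cleaning pipeline: founderize -> loops -> truncate -> prune.

    Returns the cleaned pedigree and a dict of per-stage removal counts.
    """
    ped, n_adopt = founderize_adoptees(ped)
    ped, looped = remove_loops(ped)
    ped, truncated = truncate_generations(ped, depth)
    ped, pruned = prune_noninformative(ped)
    counts = {
        "adoptees_founderized": n_adopt,
        "loop_members_removed": len(looped),
        "ancestors_truncated": len(truncated),
        "noninformative_pruned": len(pruned),
        "final_size": len(ped),
    }
    return ped, counts


# ---------------------------------------------------------------------------
# relation classification
# ---------------------------------------------------------------------------


def _sib_class(ped: Pedigree, i: str, j: str) -> RelationClass:
    """Sibling class of two distinct individuals (FULL/HALF/OTHER only)."""
    pi, pj = ped[i], ped[j]
    if (
        pi.father is not None
        and pi.mother is not None
        and pi.father == pj.father
        and pi.mother == pj.mother
    ):
        return RelationClass.FULL_SIBLING
    shared = (pi.father is not None and pi.father == pj.father) + (
        pi.mother is not None and pi.mother == pj.mother
    )
    if shared == 1:
        return RelationClass.HALF_SIBLING
    return RelationClass.OTHER


def classify_relation(ped: Pedigree, i: str, j: str) -> RelationClass:
    """Classify the relation between two phenotyped individuals.

    Evaluated in priority order full sibling > half sibling > full cousin >
    half cousin, so a pair qualifying for multiple classes takes the single
    class with the largest relatedness coefficient. Cousinship requires a
    parent of ``i`` and a parent of ``j`` to be (full or half) siblings.
    """
    if i == j:
        raise ValidationError("classify_relation requires two distinct individuals")
    sib = _sib_class(ped, i, j)
    if sib is not RelationClass.OTHER:
        return sib
    best = RelationClass.OTHER
    for pi in ped[i].known_parents():
        for pj in ped[j].known_parents():
            if pi == pj or pi not in ped or pj not in ped:
                continue
            psib = _sib_class(ped, pi, pj)
            if psib is RelationClass.FULL_SIBLING:
                return RelationClass.FULL_COUSIN
            if psib is RelationClass.HALF_SIBLING:
                best = RelationClass.HALF_COUSIN
    return best


# ---------------------------------------------------------------------------
# kinship (independent recursive oracle)
# ---------------------------------------------------------------------------


def _depths(ped: Pedigree) -> dict[str, int]:
    depth: dict[str, int] = {}

    def d(i: str, trail: tuple[str, ...] = ()) -> int:
        if i in depth:
            return depth[i]
        if i in trail:
            raise ValidationError(f"parentage cycle through {i!r}")
        ps = [p for p in ped[i].known_parents() if p in ped]
        depth[i] = 0 if not ps else 1 + max(d(p, trail + (i,)) for p in ps)
        return depth[i]

    for ind in ped:
        d(ind.id)
    return depth


def kinship(ped: Pedigree, i: str, j: str, _cache: dict | None = None) -> float:
    """Recursive kinship coefficient φ(i, j) on an acyclic pedigree.

    φ(i,i) = ½(1 + φ(father, mother)); for i ≠ j the recursion descends
    through the parents of the individual furthest from the founders.
    Unknown parents contribute 0. Exact in rational arithmetic for the
    coefficients arising here, returned as float.
    """
    cache = {} if _cache is None else _cache
    if "__depth__" not in cache:
        cache["__depth__"] = _depths(ped)
    depth = cache["__depth__"]

    def phi(a: str, b: str) -> float:
        if depth[a] < depth[b] or (depth[a] == depth[b] and a > b):
            a, b = b, a
        key = (a, b)
        if key in cache:
            return cache[key]
        pa = ped[a]
        if a == b:
            f, m = pa.father, pa.mother
            val = 0.5 * (
                1.0 + (phi(f, m) if f in ped._inds and m in ped._inds else 0.0)
            )
        else:
            # a is at least as deep as b and cannot be b's ancestor
            val = 0.0
            for p in pa.known_parents():
                if p in ped._inds:
                    val += 0.5 * phi(p, b)
        cache[key] = val
        return val

    return phi(i, j)


def kinship_matrix(ped: Pedigree, ids: list[str]) -> np.ndarray:
    """Dense matrix of 2·φ(i, j) over ``ids`` — the recursive additive
    relationship matrix, used as an oracle against the classification route."""
    cache: dict = {}
    n = len(ids)
    A = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            A[a, b] = A[b, a] = 2.0 * kinship(ped, ids[a], ids[b], cache)
    return A


# ---------------------------------------------------------------------------
# relationship structure
# ---------------------------------------------------------------------------


@dataclass
class RelationshipStructure:
    """Sparse expected additive relatedness over phenotyped individuals.

    ``A`` is symmetric with unit diagonal (non-inbred convention) and is block
    diagonal by extended family: ``families[k]`` holds the positional indices
    (into ``ids``) of the k-th connected component of the off-diagonal
    pattern. ``A_inverse``, when populated, covers the possibly larger ID set
    ``A_inverse_ids`` (the whole cleaned pedigree, Henderson assembly).
    """

    ids: list[str]
    A: sp.csr_matrix
    families: list[np.ndarray]
    A_inverse: sp.csr_matrix | None = None
    A_inverse_ids: list[str] | None = None
    family_labels: np.ndarray = field(default=None, repr=False)  # type: ignore

    @property
    def n(self) -> int:
        return len(self.ids)

    def family_blocks(self) -> list[np.ndarray]:
        """Dense A blocks, one per family, aligned with ``families``."""
        return [self.A[np.ix_(idx, idx)].toarray() for idx in self.families]


def build_relationship_structure(ped: Pedigree) -> RelationshipStructure:
    """Assemble A over phenotyped individuals from pairwise relation classes.

    Candidate related pairs are found by indexing phenotyped individuals by
    their parents and grandparents — any pair sharing such an ancestor is
    classified; all others are unrelated by construction of the four classes.
    ID order is sorted and therefore invariant to input row order.
    """
    ids = ped.phenotyped_ids()
    if not ids:
        raise ValidationError("pedigree contains no phenotyped individuals")
    pos = {iid: k for k, iid in enumerate(ids)}

    by_ancestor: dict[str, list[str]] = {}
    for iid in ids:
        seen: set[str] = set()
        for p in ped[iid].known_parents():
            if p in ped and p not in seen:
                by_ancestor.setdefault(p, []).append(iid)
                seen.add(p)
            if p in ped:
                for gp in ped[p].known_parents():
                    if gp in ped and gp not in seen:
                        by_ancestor.setdefault(gp, []).append(iid)
                        seen.add(gp)

    pairs: set[tuple[str, str]] = set()
    for members in by_ancestor.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                pairs.add((i, j) if i < j else (j, i))

    rows, cols, vals = [], [], []
    for i, j in pairs:
        r = relatedness_coefficient(classify_relation(ped, i, j))
        if r > 0:
            rows += [pos[i], pos[j]]
            cols += [pos[j], pos[i]]
            vals += [r, r]
    n = len(ids)
    offdiag = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    A = (offdiag + sp.eye(n, format="coo")).tocsr()

    n_fam, labels = connected_components(A, directed=False)
    families = [np.flatnonzero(labels == k) for k in range(n_fam)]
    log.info(
        "build_relationship_structure: %d phenotyped in %d families, %d related pairs",
        n, n_fam, len(vals) // 2,
    )
    return RelationshipStructure(
        ids=ids, A=A, families=families, family_labels=labels
    )


def build_A_inverse(ped: Pedigree) -> RelationshipStructure:
    """Sparse inverse of the full-pedigree A by Henderson's rules (non-inbred).

    Per individual i with d_i = 1 / (1 − 0.25 · #known parents): add d_i at
    (i,i), −d_i/2 between i and each known parent, and d_i/4 between the
    parents. Covers every individual in the cleaned pedigree; the phenotyped
    block of its inverse reproduces the recursive A.
    """
    order = _topological_ids(ped)
    pos = {iid: k for k, iid in enumerate(order)}
    rows, cols, vals = [], [], []

    def add(a: int, b: int, v: float) -> None:
        rows.append(a)
        cols.append(b)
        vals.append(v)

    for iid in order:
        parents = [p for p in ped[iid].known_parents() if p in ped]
        d = 1.0 / (1.0 - 0.25 * len(parents))
        i = pos[iid]
        add(i, i, d)
        for p in parents:
            add(i, pos[p], -d / 2.0)
            add(pos[p], i, -d / 2.0)
        for p in parents:
            for q in parents:
                add(pos[p], pos[q], d / 4.0)

    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(len(order),) * 2).tocsr()
    struct = build_relationship_structure(ped) if ped.phenotyped_ids() else None
    if struct is None:
        struct = RelationshipStructure(ids=[], A=sp.csr_matrix((0, 0)), families=[])
    struct.A_inverse = Ainv
    struct.A_inverse_ids = order
    return struct


def _topological_ids(ped: Pedigree) -> list[str]:
    """Pedigree IDs with parents before children (raises on cycles)."""
    g = ped.parentage_graph()
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible as e:
        raise ValidationError("pedigree is not acyclic; run remove_loops first") from e


def export_matrix(
    struct: RelationshipStructure, matrix_path: str | Path, ids_path: str | Path
) -> None:
    """Write A in Matrix Market symmetric coordinate format plus a sidecar file
    with the ID order, one per line."""
    scipy.io.mmwrite(str(matrix_path), struct.A, symmetry="symmetric")
    Path(ids_path).write_text("\n".join(struct.ids) + "\n")
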