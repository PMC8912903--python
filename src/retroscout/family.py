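"""Identity-based family clustering and distance-tree lineage assignment.

Elements are grouped into families by pairwise identity over their reverse
transcriptase, RNase H and integrase domain sequences: members of a family
share >95% identity (single-linkage, so "same family" is transitive). Family
representatives are then placed on a neighbor-joining distance tree together
with reference taxa from the two fission-yeast retroelement lineages
(Tf-like and Ty3-like) and labelled by their nearest reference in patristic
distance. Comparison is in nucleotide space by default (a config flag allows
amino-acid space); elements lacking all three domains are excluded from
clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from ._align import nw_align
from .references import TRIPLET_DOMAINS


@dataclass
class DomainTriplet:
    element_id: str
    sequences: dict[str, str]  # domain name -> nucleotide sequence
    sort_key: tuple = ()  # leftmost genomic coordinate for deterministic labels
    length: int = 0  # full element length (representative = longest member)

    def __post_init__(self):
        self.sequences = {
            d: s for d, s in self.sequences.items() if d in TRIPLET_DOMAINS and s
        }
        if not self.sequences:
            raise ValueError(
                f"{self.element_id}: at least one clustering domain required"
            )


@dataclass
class Family:
    family_id: str
    members: list[str]
    representative: str


@dataclass
class LineageTree:
    newick: str
    labels: dict[str, str]  # family id -> lineage label


def pairwise_identity(a: DomainTriplet, b: DomainTriplet) -> float | None:
    """Length-weighted mean identity over shared domains.

    Per domain: global alignment (match +1, mismatch -1, gap -2), identity =
    matches / aligned columns excluding terminal gaps. Returns None when the
    two triplets share no domain (an undefined comparison, not a number).
    """
    shared = sorted(set(a.sequences) & set(b.sequences))
    if not shared:
        return None
    num = den = 0
    for d in shared:
        # canonical argument order makes the result symmetric even when
        # co-optimal alignments would otherwise be tie-broken differently
        s1, s2 = sorted((a.sequences[d], b.sequences[d]))
        _, matches, cols = nw_align(s1, s2)
        num += matches
        den += cols
    return num / den if den else 0.0


def cluster_families(
    triplets: list[DomainTriplet], threshold: float = 0.95
) -> list[Family]:
    """Single-linkage transitive closure of identity > threshold.

    Elements incomparable with every cluster become singleton families.
    Family numbering is deterministic: Tj-style labels ordered by the
    leftmost genomic coordinate of each family's representative.
    """
    if not triplets:
        return []
    order = sorted(range(len(triplets)), key=lambda i: (triplets[i].sort_key,
                                                        triplets[i].element_id))
    parent = list(range(len(triplets)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            i, j = order[ii], order[jj]
            ident = pairwise_identity(triplets[i], triplets[j])
            if ident is not None and ident > threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in order:
        groups.setdefault(find(i), []).append(i)
    fams = []
    for members in groups.values():
        rep = sorted(
            members,
            key=lambda i: (-triplets[i].length, triplets[i].sort_key,
                           triplets[i].element_id),
        )[0]
        fams.append((triplets[rep].sort_key, triplets[rep].element_id, members, rep))
    fams.sort(key=lambda f: (f[0], f[1]))
    out = []
    for n, (_, _, members, rep) in enumerate(fams, 1):
        ids = sorted(triplets[i].element_id for i in members)
        out.append(Family(family_id=f"Tj{n}", members=ids,
                          representative=triplets[rep].element_id))
    return out


def assign_lineages(
    families: list[Family],
    triplets_by_id: dict[str, DomainTriplet],
    references: list[tuple[str, str, dict[str, str]]],
) -> LineageTree:
    """Neighbor-joining tree over family representatives plus references;
    each family is labelled with the lineage of its nearest reference by
    patristic distance. Distance = 1 - pairwise identity."""
    taxa: list[tuple[str, DomainTriplet | None]] = []
    for fam in families:
        taxa.append((fam.family_id, triplets_by_id[fam.representative]))
    ref_lineage = {}
    for name, lineage, seqs in references:
        taxa.append((name, DomainTriplet(element_id=name, sequences=dict(seqs))))
        ref_lineage[name] = lineage
    names = [t[0] for t in taxa]
    n = len(names)
    dm = np.zeros((n, n))
    comparable = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(taxa[i][1], taxa[j][1])
            if ident is None:
                comparable[i, j] = comparable[j, i] = False
                dm[i, j] = dm[j, i] = 1.0
            else:
                dm[i, j] = dm[j, i] = 1.0 - ident
    tree = nj(DistanceMatrix(dm, ids=names))
    labels: dict[str, str] = {}
    tip_dists = {t.name: t for t in tree.tips()}
    for fam in families:
        fam_idx = names.index(fam.family_id)
        if not any(comparable[fam_idx, names.index(r)] for r in ref_lineage):
            warnings.warn(f"{fam.family_id}: incomparable with all references")
            continue
        node = tip_dists[fam.family_id]
        best = min(
            ref_lineage, key=lambda r: node.distance(tip_dists[r])
        )
        labels[fam.family_id] = ref_lineage[best]
    return LineageTree(newick=str(tree).strip(), labels=labels)
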