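import numpy as np
import pytest
from Bio import Align

from retroscout._align import nw_align
from retroscout.family import (
    DomainTriplet,
    assign_lineages,
    cluster_families,
    pairwise_identity,
)
from retroscout.references import reference_triplets
from retroscout.synthio import mutate_nt


def trip(eid, rt=None, rh=None, integrase=None, key=(0, 0), length=0):
    seqs = {}
    if rt:
        seqs["reverse_transcriptase"] = rt
    if rh:
        seqs["rnase_h"] = rh
    if integrase:
        seqs["integrase"] = integrase
    return DomainTriplet(element_id=eid, sequences=seqs, sort_key=key,
                         length=length)


def rand_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPairwiseIdentity:
    def test_identical_triplets(self):
        a = trip("a", rt="ACGTACGTAA", rh="GGGCCC")
        b = trip("b", rt="ACGTACGTAA", rh="GGGCCC")
        assert pairwise_identity(a, b) == 1.0

    def test_single_mismatch_hand_value(self):
        a = trip("a", rt="ACGTACGT")
        b = trip("b", rt="ACGTTCGT")
        assert pairwise_identity(a, b) == pytest.approx(7 / 8)

    def test_no_shared_domain_is_undefined(self):
        a = trip("a", rt="ACGTACGT")
        b = trip("b", rh="ACGTACGT")
        assert pairwise_identity(a, b) is None

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = trip("a", rt=rand_nt(rng, 60), rh=rand_nt(rng, 40))
            b = trip("b", rt=rand_nt(rng, 55), rh=rand_nt(rng, 45))
            ab = pairwise_identity(a, b)
            ba = pairwise_identity(b, a)
            assert ab == ba
            assert 0.0 <= ab <= 1.0

    def test_identity_one_iff_shared_domains_identical(self):
        rng = np.random.default_rng(1)
        s = rand_nt(rng, 50)
        assert pairwise_identity(trip("a", rt=s), trip("b", rt=s)) == 1.0
        mutated = mutate_nt(s, 0.1, rng)
        assert mutated != s
        assert pairwise_identity(trip("a", rt=s), trip("b", rt=mutated)) < 1.0

    def test_matches_exhaustive_dp_oracle_on_random_50mers(self):
        """100 random pairs: score, matches and columns equal a plain
        O(nm) textbook DP with the same diagonal-first tie-break."""
        rng = np.random.default_rng(7)
        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=-1, open_gap_score=-2,
                                        extend_gap_score=-2)
        for _ in range(100):
            a, b = rand_nt(rng, 50), rand_nt(rng, 50)
            got = nw_align(a, b)
            assert got == _nw_oracle(a, b)
            assert got[0] == aligner.score(a, b)


def _nw_oracle(a, b, match=1, mis=-1, gap=-2):
    """Pure-python Needleman-Wunsch, written independently of the package
    kernel; tie-break: diagonal, then gap-in-b, then gap-in-a."""
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    P = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        H[i][0], P[i][0] = i * gap, 1
    for j in range(1, n + 1):
        H[0][j], P[0][j] = j * gap, 2
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mis)
            u = H[i - 1][j] + gap
            l = H[i][j - 1] + gap
            best, ptr = d, 0
            if u > best:
                best, ptr = u, 1
            if l > best:
                best, ptr = l, 2
            H[i][j], P[i][j] = best, ptr
    i, j, cols = m, n, []
    while i > 0 or j > 0:
        p = P[i][j]
        if i > 0 and j > 0 and p == 0:
            cols.append((0, a[i - 1] == b[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and (j == 0 or p == 1):
            cols.append((1, False))
            i -= 1
        else:
            cols.append((2, False))
            j -= 1
    cols.reverse()
    first, last = 0, len(cols)
    while first < last and cols[first][0] != 0:
        first += 1
    while last > first and cols[last - 1][0] != 0:
        last -= 1
    return H[m][n], sum(c[1] for c in cols[first:last]), last - first


class TestClusterFamilies:
    def build_triplets(self, rng, n_per=4, divergence=0.02):
        triplets = []
        for f in range(3):
            rt = rand_nt(rng, 500)
            rh = rand_nt(rng, 330)
            for k in range(n_per):
                triplets.append(
                    trip(f"f{f}m{k}", rt=mutate_nt(rt, divergence, rng),
                         rh=mutate_nt(rh, divergence, rng),
                         key=(f, k), length=1000 - k)
                )
        return triplets

    def test_recovers_planted_partition(self):
        rng = np.random.default_rng(0)
        triplets = self.build_triplets(rng)
        fams = cluster_families(triplets)
        got = sorted(tuple(sorted(f.members)) for f in fams)
        want = sorted(
            tuple(sorted(f"f{f}m{k}" for k in range(4))) for f in range(3)
        )
        assert got == want

    def test_strict_threshold_all_singletons(self):
        rng = np.random.default_rng(1)
        triplets = self.build_triplets(rng)
        fams = cluster_families(triplets, threshold=1.0)
        assert all(len(f.members) == 1 for f in fams)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        triplets = self.build_triplets(rng)
        fams_a = cluster_families(triplets)
        fams_b = cluster_families(list(reversed(triplets)))
        assert [(f.family_id, sorted(f.members)) for f in fams_a] == [
            (f.family_id, sorted(f.members)) for f in fams_b
        ]

    def test_representative_is_longest_member(self):
        rng = np.random.default_rng(3)
        triplets = self.build_triplets(rng)
        fams = cluster_families(triplets)
        by_id = {t.element_id: t for t in triplets}
        for f in fams:
            assert by_id[f.representative].length == max(
                by_id[m].length for m in f.members
            )

    def test_families_partition_the_input(self):
        rng = np.random.default_rng(4)
        triplets = self.build_triplets(rng)
        fams = cluster_families(triplets)
        members = sorted(m for f in fams for m in f.members)
        assert members == sorted(t.element_id for t in triplets)


class TestAssignLineages:
    def test_nj_recovers_additive_four_taxon_tree(self):
        """Distance matrix generated from a known tree
        ((A:2,B:3):1,(C:4,D:5)); NJ must reproduce all patristic distances
        exactly (additive matrix)."""
        from skbio import DistanceMatrix
        from skbio.tree import nj

        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ], dtype=float)
        tree = nj(DistanceMatrix(d, ids=ids))
        tips = {t.name: t for t in tree.tips()}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert tips[a].distance(tips[b]) == pytest.approx(
                        d[i, j], abs=1e-9
                    )

    def test_family_labelled_by_generating_lineage(self):
        rng = np.random.default_rng(5)
        refs = reference_triplets()
        fams_triplets = {}
        families = []
        from retroscout.family import Family

        for i, (name, lineage, seqs) in enumerate(refs[:2]):
            mutated = {d: mutate_nt(s, 0.05, rng) for d, s in seqs.items()}
            tid = f"el{i}"
            fams_triplets[tid] = DomainTriplet(element_id=tid,
                                               sequences=mutated,
                                               sort_key=(0, i), length=5000)
            families.append(Family(family_id=f"Tj{i + 1}", members=[tid],
                                   representative=tid))
            assert lineage in ("tf_like", "ty3_like")
        tree = assign_lineages(families, fams_triplets, refs)
        for i, (name, lineage, _) in enumerate(refs[:2]):
            assert tree.labels[f"Tj{i + 1}"] == lineage

    def test_tree_contains_every_taxon_once(self):
        rng = np.random.default_rng(6)
        refs = reference_triplets()
        from retroscout.family import Family

        tid = "el0"
        triplets = {
            tid: DomainTriplet(
                element_id=tid,
                sequences={d: mutate_nt(s, 0.05, rng)
                           for d, s in refs[0][2].items()},
                sort_key=(0, 0), length=5000,
            )
        }
        fams = [Family(family_id="Tj1", members=[tid], representative=tid)]
        tree = assign_lineages(fams, triplets, refs)
        import io

        from skbio import TreeNode

        parsed = TreeNode.read(io.StringIO(tree.newick))
        names = sorted(t.name for t in parsed.tips())
        assert names == sorted(["Tj1"] + [r[0] for r in refs])
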