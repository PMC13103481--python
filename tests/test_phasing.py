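"""Hi-C phasing: pruning, clustering, dedup, rescue, QC, accuracy."""

import numpy as np
import pytest

from hexorigin import phasing, simdata
from hexorigin.phasing import (
    ContactMap,
    Grouping,
    OverlapRecord,
    OverlapSet,
    assign_by_alignment,
    dedup_overlaps,
    detect_collapse,
    link_density,
    partition_groups,
    phasing_accuracy,
    prune_allelic,
    rescue_ungrouped,
)

from oracles import best_partition


def random_map(rng, n, lam=3.0, p_zero=0.5):
    ids = [f"u{i}" for i in range(n)]
    lengths = {u: int(rng.integers(10_000, 200_000)) for u in ids}
    counts = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() > p_zero:
                counts[(ids[i], ids[j])] = int(rng.poisson(lam)) + 1
    return ContactMap(lengths, counts), ids


def planted_map(rng, n_groups, per_group, lam_intra=20.0, lam_bg=1.0):
    ids, truth = [], {}
    for g in range(n_groups):
        for k in range(per_group):
            u = f"g{g}u{k}"
            ids.append(u)
            truth[u] = g
    lengths = {u: 50_000 for u in ids}
    counts = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            lam = lam_intra if truth[ids[i]] == truth[ids[j]] else lam_bg
            c = int(rng.poisson(lam))
            if c:
                counts[(ids[i], ids[j])] = c
    return ContactMap(lengths, counts), truth


class TestContactMap:
    def test_symmetry_and_defaults(self):
        m = ContactMap({"a": 100, "b": 100, "c": 100}, {("b", "a"): 5})
        assert m.get("a", "b") == m.get("b", "a") == 5
        assert m.get("a", "c") == 0

    def test_rejects_self_pairs_and_negatives(self):
        m = ContactMap({"a": 100, "b": 100})
        with pytest.raises(ValueError):
            m.set("a", "a", 1)
        with pytest.raises(ValueError):
            m.set("a", "b", -1)


class TestLinkDensity:
    def test_direct_formula(self):
        m = ContactMap({"u": 1000, "x": 500, "y": 500},
                       {("u", "x"): 5, ("u", "y"): 7})
        assert link_density(m, "u", {"x", "y"}) == pytest.approx(12 / 1000)

    def test_empty_group_is_zero(self):
        m = ContactMap({"u": 1000})
        assert link_density(m, "u", set()) == 0.0

    def test_matches_exhaustive_summation(self, rng):
        m, ids = random_map(rng, 12)
        group = set(ids[3:9])
        for u in ids:
            expected = sum(m.get(u, v) for v in group if v != u) / m.lengths[u]
            assert link_density(m, u, group) == pytest.approx(expected)


class TestPrune:
    def test_zeroes_allelic_pair(self):
        m = ContactMap({"u1": 100, "u2": 100, "u3": 100},
                       {("u1", "u2"): 10, ("u1", "u3"): 4})
        out = prune_allelic(m, {"g1": {"u1", "u2"}})
        assert out.get("u1", "u2") == 0
        assert out.get("u1", "u3") == 4

    def test_empty_table_is_identity(self, rng):
        m, _ = random_map(rng, 8)
        assert prune_allelic(m, {}) == m

    def test_idempotent_and_never_increases(self, rng):
        m, ids = random_map(rng, 10)
        alleles = {f"g{k}": set(rng.choice(ids, size=3, replace=False))
                   for k in range(4)}
        once = prune_allelic(m, alleles)
        twice = prune_allelic(once, alleles)
        assert once == twice
        for a, b, c in m.pairs():
            assert once.get(a, b) <= c

    def test_zeroed_set_equals_union_of_allelic_pairs(self, rng):
        m, ids = random_map(rng, 10, p_zero=0.0)
        alleles = {f"g{k}": set(rng.choice(ids, size=int(rng.integers(2, 5)),
                                           replace=False))
                   for k in range(5)}
        out = prune_allelic(m, alleles)
        expected = set()
        for us in alleles.values():
            for a in us:
                for b in us:
                    if a < b:
                        expected.add((a, b))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = sorted((ids[i], ids[j]))
                if (a, b) in expected:
                    assert out.get(a, b) == 0
                else:
                    assert out.get(a, b) == m.get(a, b)


class TestPartition:
    def test_two_perfect_triangles(self):
        lengths = {u: 1000 for u in "abcdef"}
        counts = {}
        for tri in ("abc", "def"):
            for x in tri:
                for y in tri:
                    if x < y:
                        counts[(x, y)] = 10
        g = partition_groups(ContactMap(lengths, counts), K=2)
        assert sorted(frozenset(s) for s in g.groups) == sorted(
            [frozenset("abc"), frozenset("def")]
        )

    def test_k_equals_n_gives_singletons(self, rng):
        m, ids = random_map(rng, 5)
        g = partition_groups(m, K=5)
        assert all(len(s) == 1 for s in g.groups)

    def test_too_few_unitigs_rejected(self, rng):
        m, _ = random_map(rng, 3)
        with pytest.raises(ValueError):
            partition_groups(m, K=4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_optimum_on_planted_blocks(self, seed):
        rng = np.random.default_rng(seed)
        m, truth = planted_map(rng, n_groups=2, per_group=4)
        g = partition_groups(m, K=2)
        best, best_obj = best_partition(m, sorted(m.lengths), 2)
        assert phasing.partition_objective(m, g.groups) == pytest.approx(best_obj)
        assert sorted(frozenset(s) for s in g.groups) == sorted(
            frozenset(s) for s in best
        )

    def test_matches_exhaustive_on_ten_unitigs(self):
        rng = np.random.default_rng(10)
        m, truth = planted_map(rng, n_groups=2, per_group=5)
        g = partition_groups(m, K=2)
        _, best_obj = best_partition(m, sorted(m.lengths), 2)
        assert phasing.partition_objective(m, g.groups) == pytest.approx(best_obj)


def overlap(a, b, length, la, lb, identity=0.95):
    return OverlapRecord(a, la, 0, length, "+", b, lb, 0, length,
                         int(identity * length), length, 60)


class TestDedup:
    def test_lower_density_member_removed(self):
        lengths = {"u1": 1000, "u2": 1000, "x": 1000}
        m = ContactMap(lengths, {("u1", "x"): 5, ("u2", "x"): 3})
        ovl = OverlapSet([overlap("u1", "u2", 800, 1000, 1000)])
        g = Grouping([{"u1", "u2", "x"}])
        out, log = dedup_overlaps(g, m, ovl, large_frac=0.5)
        assert out.groups[0] == {"u1", "x"}
        assert out.ungrouped == {"u2"}
        assert log[0].removed == "u2" and log[0].kept == "u1"

    def test_small_overlap_ignored(self):
        lengths = {"u1": 1000, "u2": 1000}
        m = ContactMap(lengths, {("u1", "u2"): 2})
        ovl = OverlapSet([overlap("u1", "u2", 300, 1000, 1000)])
        out, log = dedup_overlaps(Grouping([{"u1", "u2"}]), m, ovl, large_frac=0.5)
        assert out.groups[0] == {"u1", "u2"} and not log

    def test_low_identity_overlap_ignored(self):
        lengths = {"u1": 1000, "u2": 1000}
        m = ContactMap(lengths, {("u1", "u2"): 2})
        ovl = OverlapSet([overlap("u1", "u2", 800, 1000, 1000, identity=0.5)])
        out, log = dedup_overlaps(Grouping([{"u1", "u2"}]), m, ovl)
        assert not log

    def test_chain_equals_sequential_replay(self):
        # u1-u2-u3 overlap chain with distinct densities: replay the stated
        # procedure independently and compare
        lengths = {"u1": 1000, "u2": 1000, "u3": 1000, "x": 1000}
        m = ContactMap(lengths, {("u1", "x"): 8, ("u2", "x"): 5, ("u3", "x"): 2,
                                 ("u1", "u2"): 1})
        ovl = OverlapSet([
            overlap("u1", "u2", 900, 1000, 1000),
            overlap("u2", "u3", 700, 1000, 1000),
        ])
        group = {"u1", "u2", "u3", "x"}
        out, log = dedup_overlaps(Grouping([set(group)]), m, ovl)

        # independent replay: descending overlap length
        grp = set(group)
        removed = []
        for a, b in (("u1", "u2"), ("u2", "u3")):
            if a in grp and b in grp:
                da = link_density(m, a, grp - {a})
                db = link_density(m, b, grp - {b})
                drop = b if db < da else a
                grp.remove(drop)
                removed.append(drop)
        assert out.groups[0] == grp
        assert [e.removed for e in log] == removed


class TestRescue:
    def test_joins_strongest_nonconflicting_group(self):
        lengths = {"a1": 1000, "b1": 1000, "u5": 1000}
        m = ContactMap(lengths, {("a1", "u5"): 9, ("b1", "u5"): 4})
        ovl = OverlapSet([overlap("u5", "a1", 900, 1000, 1000)])
        g = Grouping([{"a1"}, {"b1"}], ungrouped={"u5"})
        out = rescue_ungrouped(g, m, ovl)
        assert out.groups[1] == {"b1", "u5"}
        assert not out.ungrouped

    def test_conflicts_everywhere_stays_ungrouped(self):
        lengths = {"a1": 1000, "b1": 1000, "u5": 1000}
        m = ContactMap(lengths, {("a1", "u5"): 9, ("b1", "u5"): 4})
        ovl = OverlapSet([overlap("u5", "a1", 900, 1000, 1000),
                          overlap("u5", "b1", 900, 1000, 1000)])
        g = Grouping([{"a1"}, {"b1"}], ungrouped={"u5"})
        out = rescue_ungrouped(g, m, ovl)
        assert out.ungrouped == {"u5"}

    def test_zero_signal_stays_ungrouped(self):
        m = ContactMap({"a1": 1000, "u5": 1000})
        out = rescue_ungrouped(Grouping([{"a1"}], ungrouped={"u5"}), m,
                               OverlapSet([]))
        assert out.ungrouped == {"u5"}

    def test_matches_stepwise_replay_on_random_maps(self, rng):
        for _ in range(5):
            m, ids = random_map(rng, 14, p_zero=0.3)
            grouped, pool = ids[:4], ids[4:]
            g = Grouping([set(grouped[:2]), set(grouped[2:])], set(pool))
            out = rescue_ungrouped(g, m, OverlapSet([]))

            # independent replay of the stated ordering rules
            groups = [set(grouped[:2]), set(grouped[2:])]
            ung = set(pool)
            order = sorted(
                pool,
                key=lambda u: (-max(link_density(m, u, grp) for grp in groups), u),
            )
            for u in order:
                cands = sorted(
                    ((link_density(m, u, grp), gi) for gi, grp in enumerate(groups)),
                    key=lambda t: (-t[0], t[1]),
                )
                if cands[0][0] > 0:
                    groups[cands[0][1]].add(u)
                    ung.remove(u)
            assert out.groups == groups and out.ungrouped == ung


class TestAssignAndCollapse:
    def test_argmax_with_tie_rule(self):
        hits = {
            "u9": [("chr1", 500.0), ("chr2", 900.0)],
            "u10": [("chr2", 700.0), ("chr1", 700.0)],
            "u11": [],
        }
        out = assign_by_alignment(hits)
        assert out == {"u9": "chr2", "u10": "chr1", "u11": None}

    def test_random_tables_match_bruteforce(self, rng):
        for _ in range(100):
            chroms = [f"chr{c}" for c in range(1, 6)]
            hits = {
                f"u{k}": [(c, float(rng.integers(0, 50)))
                          for c in rng.choice(chroms, size=int(rng.integers(0, 4)),
                                              replace=False)]
                for k in range(8)
            }
            out = assign_by_alignment(hits)
            for u, hl in hits.items():
                if not hl:
                    assert out[u] is None
                else:
                    best = max(s for _, s in hl)
                    expect = sorted(c for c, s in hl if s == best)[0]
                    assert out[u] == expect

    def test_threshold_rule(self):
        windows = [("chr1", 0, 100, 96.0), ("chr1", 100, 200, 48.0)]
        flagged, frac = detect_collapse(windows, median_depth=48.0, fold=1.75)
        assert [w[1] for w in flagged] == [0]
        assert frac == 0.5

    def test_uniform_depth_unflagged(self):
        windows = [("chr1", i * 10, (i + 1) * 10, 50.0) for i in range(10)]
        flagged, frac = detect_collapse(windows, 50.0)
        assert not flagged and frac == 0.0

    def test_simulated_duplicated_region_flagged(self, rng):
        # single-copy background at depth ~50, a collapsed segment at ~100
        depths = list(rng.normal(50, 3, size=90)) + list(rng.normal(100, 3, size=10))
        windows = [("chr1", i, i + 1, d) for i, d in enumerate(depths)]
        flagged, _ = detect_collapse(windows, float(np.median(depths)), fold=1.75)
        assert {w[1] for w in flagged} == set(range(90, 100))

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            detect_collapse([("c", 0, 1, 5.0)], 0.0)


class TestAccuracy:
    def test_perfect_and_permuted_groupings_score_one(self):
        lengths = {f"u{i}": 1000 for i in range(6)}
        truth = {f"u{i}": 1 + i // 3 for i in range(6)}
        g = Grouping([{"u0", "u1", "u2"}, {"u3", "u4", "u5"}])
        assert phasing_accuracy(g, truth, lengths) == 1.0
        g2 = Grouping([{"u3", "u4", "u5"}, {"u0", "u1", "u2"}])
        assert phasing_accuracy(g2, truth, lengths) == 1.0

    def test_random_two_group_assignment_near_half(self, rng):
        n = 200
        lengths = {f"u{i}": 1000 for i in range(n)}
        truth = {f"u{i}": 1 + (i % 2) for i in range(n)}
        accs = []
        for _ in range(20):
            perm = rng.permutation(n)
            g = Grouping([{f"u{i}" for i in perm[: n // 2]},
                          {f"u{i}" for i in perm[n // 2:]}])
            accs.append(phasing_accuracy(g, truth, lengths))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_length_weighting(self):
        lengths = {"big": 9000, "small": 1000}
        truth = {"big": 1, "small": 2}
        g = Grouping([{"big", "small"}])
        assert phasing_accuracy(g, truth, lengths) == 0.9


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_phasing_recovers_planted_haplotypes(self, seed):
        p = simdata.HistoryParams(n_genes=48, codons_per_gene=30, seed=seed)
        truth = simdata.SimTruth(params=p)
        cmap, overlaps, alleles, _ = simdata.fragment_and_contacts(
            truth, lambda_intra=20, lambda_allelic=4, lambda_bg=1,
            n_unitigs_per_hap=8, seed=seed,
        )
        pruned = prune_allelic(cmap, alleles)
        genic = sorted({u for us in alleles.values() for u in us})
        g = partition_groups(pruned, K=6, unitigs=genic)
        g.ungrouped = set(cmap.lengths) - set(genic)
        g, _ = dedup_overlaps(g, pruned, overlaps)
        g = rescue_ungrouped(g, pruned, overlaps)
        g.validate()
        truth_hap = {u: truth.unitigs[u][0] for u in cmap.lengths}
        acc = phasing_accuracy(g, truth_hap, cmap.lengths)
        assert acc >= 0.95

    def test_no_large_overlap_pair_remains_co_grouped(self, small_sim):
        cmap, overlaps, alleles = (small_sim["cmap"], small_sim["overlaps"],
                                   small_sim["alleles"])
        pruned = prune_allelic(cmap, alleles)
        genic = sorted({u for us in alleles.values() for u in us})
        g = partition_groups(pruned, K=6, unitigs=genic)
        g.ungrouped = set(cmap.lengths) - set(genic)
        g, _ = dedup_overlaps(g, pruned, overlaps)
        g = rescue_ungrouped(g, pruned, overlaps)
        for grp in g.groups:
            for a in grp:
                for b in grp:
                    if a < b:
                        assert not overlaps.is_large(a, b, cmap.lengths)
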