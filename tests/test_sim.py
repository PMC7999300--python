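import numpy as np
import pytest

from clonoscope.sim import (
    CloneNode,
    CloneTree,
    CnaEvent,
    SimConfig,
    _copy_fate_coin,
    _local_copies,
    sample_bulk,
    sample_organoid,
    simulate_lineage,
)
from clonoscope.variants import Variant


def single_lineage_config(**kwargs) -> SimConfig:
    base = dict(branching_times=[], driver_schedule={"apc": 0.0, "kras": 0.0, "tp53": None})
    base.update(kwargs)
    return SimConfig(**base)


def make_manual_tree(genome, n_variants=0, seed=0):
    """Root-only tree with hand-injected copy-neutral SNSs."""
    rng = np.random.default_rng(seed)
    tree = CloneTree()
    root = CloneNode(node_id="root", parent=None, birth_time_weeks=0.0)
    tree.add(root)
    chroms = list(genome.chromosomes)
    used = set()
    while len(root.sns) < n_variants:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, len(genome.chromosomes[chrom]) - 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = genome.base(chrom, pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        root.sns.append(Variant(chrom, pos, ref, alt))
    return tree


class TestSimulateLineage:
    def test_tp53_wildtype_has_zero_cnas(self, genome_small):
        for seed in range(5):
            config = SimConfig(
                driver_schedule={"apc": 0.0, "kras": 0.0, "tp53": None},
                duration_weeks=25.0,
                seed=seed,
            )
            tree = simulate_lineage(genome_small, config)
            assert all(not n.cnas for n in tree.nodes.values())

    def test_cnas_only_on_tp53_null_nodes(self, genome_small):
        config = SimConfig(duration_weeks=25.0,
                           driver_schedule={"apc": 0.0, "kras": 0.0, "tp53": 10.0},
                           cna_rate_per_week_tp53null=0.3, seed=4)
        tree = simulate_lineage(genome_small, config)
        for node in tree.nodes.values():
            if not node.tp53_mut:
                assert node.cnas == []

    def test_sns_rate_independent_of_driver_schedule(self, genome_small):
        # Monte-Carlo check of the built-in rate constancy
        def mean_count(tp53_week, seeds):
            counts = []
            for s in seeds:
                config = single_lineage_config(
                    duration_weeks=10.0, seed=s, sns_rate_per_week=1.5,
                    driver_schedule={"apc": 0.0, "kras": 0.0, "tp53": tp53_week},
                )
                tree = simulate_lineage(genome_small, config)
                counts.append(len(tree.full_sns(tree.leaves()[0])))
            return np.array(counts, dtype=float)

        a = mean_count(None, range(80))
        b = mean_count(2.0, range(100, 180))
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_zero_duration_limit(self, genome_small):
        config = single_lineage_config(duration_weeks=1e-9, seed=0)
        tree = simulate_lineage(genome_small, config)
        assert len(tree.full_sns(tree.leaves()[0])) == 0
        assert len(tree.full_cnas(tree.leaves()[0])) == 0

    def test_deterministic_for_fixed_seed(self, genome_small):
        config = SimConfig(seed=9, duration_weeks=15.0)
        a = simulate_lineage(genome_small, config)
        b = simulate_lineage(genome_small, config)
        assert a.to_json() == b.to_json()

    def test_infinite_sites(self, genome_small):
        config = SimConfig(seed=2, duration_weeks=25.0, sns_rate_per_week=3.0)
        tree = simulate_lineage(genome_small, config)
        keys = [v.key for n in tree.nodes.values() for v in n.sns]
        assert len(keys) == len(set(keys))

    def test_signature_context_placement(self, genome_small):
        config = single_lineage_config(
            duration_weeks=25.0, sns_rate_per_week=4.0, seed=5,
            signature_weights={"sig1": 1.0, "sig17": 0.0, "uniform": 0.0},
        )
        tree = simulate_lineage(genome_small, config)
        variants = tree.full_sns(tree.leaves()[0])
        assert len(variants) > 30
        for v in variants:
            ctx = genome_small.context(v.chrom, v.pos)
            assert ctx in ("ACG", "CCG", "GCG", "TCG")

    def test_parameter_recovery_slope(self, genome_small):
        from clonoscope.rates import fit_rate_regression

        points = []
        durations = [5.0, 10.0, 15.0, 20.0, 25.0]
        for i in range(50):
            config = single_lineage_config(
                duration_weeks=durations[i % 5], sns_rate_per_week=1.0, seed=1000 + i
            )
            tree = simulate_lineage(genome_small, config)
            points.append((durations[i % 5], float(len(tree.full_sns(tree.leaves()[0])))))
        result = fit_rate_regression(points)
        assert abs(result.slope - 1.0) / 1.0 < 0.15

    def test_genotype_monotonicity_enforced(self):
        tree = CloneTree()
        tree.add(CloneNode("a", None, 0.0, tp53_mut=True))
        with pytest.raises(ValueError, match="reverts"):
            tree.add(CloneNode("b", "a", 1.0, tp53_mut=False))

    def test_config_validation(self, genome_small):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(signature_weights={"sig1": 0.5, "sig17": 0.1, "uniform": 0.1}).validate()
        with pytest.raises(ValueError, match="duration"):
            SimConfig(duration_weeks=0.0).validate()


class TestSampleOrganoid:
    def test_mean_vaf_about_half(self, genome_small):
        tree = make_manual_tree(genome_small, n_variants=250, seed=1)
        vafs = []
        for seed in range(40):
            calls, _ = sample_organoid(tree, "root", genome_small, depth_mean=100,
                                       seed=seed)
            vafs.extend(c.vaf for c in calls)
        assert len(vafs) == 250 * 40
        assert abs(np.mean(vafs) - 0.50) < 0.015

    def test_unique_keys_and_single_sample_id(self, genome_small):
        tree = make_manual_tree(genome_small, n_variants=50, seed=2)
        calls, _ = sample_organoid(tree, "root", genome_small, seed=0, sample_id="org1")
        keys = [c.variant.key for c in calls]
        assert len(keys) == len(set(keys))
        assert {c.sample_id for c in calls} == {"org1"}

    def test_loss_before_sns_gives_vaf_one(self, genome_small):
        # deletion on the trunk, SNS acquired later inside it: 1 of 1 copies
        tree = CloneTree()
        root = CloneNode("root", None, 0.0)
        tree.add(root)
        root.cnas.append(CnaEvent("chr1", 1000, 50_000, "loss"))
        pos = 10_000
        ref = genome_small.base("chr1", pos)
        alt = "A" if ref != "A" else "C"
        child = CloneNode("child", "root", 5.0)
        tree.add(child)
        child.sns.append(Variant("chr1", pos, ref, alt))
        tot, mut = _local_copies(tree, "child", child.sns[0])
        assert (tot, mut) == (1, 1)
        calls, _ = sample_organoid(tree, "child", genome_small, depth_mean=200, seed=3)
        assert len(calls) == 1
        assert calls[0].vaf > 0.9

    def test_loss_after_sns_copy_fate(self, genome_small):
        # deletion acquired after the SNS: outcome follows the stable coin
        pos = 10_000
        ref = genome_small.base("chr1", pos)
        alt = "A" if ref != "A" else "C"
        variant = Variant("chr1", pos, ref, alt)
        cna = CnaEvent("chr1", 1000, 50_000, "loss")
        tree = CloneTree()
        root = CloneNode("root", None, 0.0)
        tree.add(root)
        root.sns.append(variant)
        child = CloneNode("child", "root", 5.0)
        tree.add(child)
        child.cnas.append(cna)
        tot, mut = _local_copies(tree, "child", variant)
        if _copy_fate_coin(variant, cna):
            assert (tot, mut) == (1, 0)  # mutated copy lost -> absent
            calls, _ = sample_organoid(tree, "child", genome_small, seed=0)
            assert calls == []
        else:
            assert (tot, mut) == (1, 1)  # mutated copy retained -> VAF 1

    def test_depth_bins_reflect_copy_loss(self, genome_small):
        tree = CloneTree()
        root = CloneNode("root", None, 0.0)
        tree.add(root)
        root.cnas.append(CnaEvent("chr1", 0, 150_000, "loss"))
        _, bins = sample_organoid(tree, "root", genome_small, depth_mean=500,
                                  seed=1, bin_width=10_000)
        df = bins.frame
        inside = df[(df.chrom == "chr1") & (df.end <= 150_000)]["count"].mean()
        outside = df[(df.chrom == "chr2")]["count"].mean()
        assert inside / outside == pytest.approx(0.5, abs=0.05)

    def test_depth_mean_validation(self, genome_small):
        tree = make_manual_tree(genome_small, 1)
        with pytest.raises(ValueError, match="depth_mean"):
            sample_organoid(tree, "root", genome_small, depth_mean=0.5)


class TestSampleBulk:
    def test_purity_dilution_closed_form(self, genome_small):
        # purity 0.6, clone fraction 0.5 -> expected VAF 0.15
        tree = CloneTree()
        root = CloneNode("root", None, 0.0)
        tree.add(root)
        a = CloneNode("a", "root", 1.0)
        b = CloneNode("b", "root", 1.0)
        tree.add(a)
        tree.add(b)
        pos = 20_000
        ref = genome_small.base("chr1", pos)
        a.sns.append(Variant("chr1", pos, ref, "A" if ref != "A" else "C"))
        vafs = []
        for seed in range(60):
            calls, _ = sample_bulk(
                tree, [("a", 0.5), ("b", 0.5)], genome_small, purity=0.6,
                depth_mean=2000, seed=seed,
            )
            vafs.extend(c.vaf for c in calls)
        assert abs(np.mean(vafs) - 0.15) < 0.01

    def test_pure_single_clone_matches_organoid_expectation(self, genome_small):
        tree = make_manual_tree(genome_small, n_variants=100, seed=3)
        org_calls, org_bins = sample_organoid(tree, "root", genome_small, seed=7)
        blk_calls, blk_bins = sample_bulk(
            tree, [("root", 1.0)], genome_small, purity=1.0, seed=7
        )
        assert len(org_calls) == len(blk_calls)
        assert abs(
            np.mean([c.vaf for c in org_calls]) - np.mean([c.vaf for c in blk_calls])
        ) < 0.03
        assert org_bins.frame[["chrom", "start", "end"]].equals(
            blk_bins.frame[["chrom", "start", "end"]]
        )

    def test_truncal_vaf_exceeds_subclonal(self, genome_small):
        tree = CloneTree()
        root = CloneNode("root", None, 0.0)
        tree.add(root)
        pos_trunk, pos_sub = 20_000, 40_000
        r1 = genome_small.base("chr1", pos_trunk)
        r2 = genome_small.base("chr1", pos_sub)
        root.sns.append(Variant("chr1", pos_trunk, r1, "A" if r1 != "A" else "C"))
        major = CloneNode("major", "root", 1.0)
        minor = CloneNode("minor", "root", 1.0)
        tree.add(major)
        tree.add(minor)
        minor.sns.append(Variant("chr1", pos_sub, r2, "A" if r2 != "A" else "C"))
        trunk_vafs, sub_vafs = [], []
        for seed in range(30):
            calls, _ = sample_bulk(
                tree, [("major", 0.9), ("minor", 0.1)], genome_small,
                purity=0.8, depth_mean=500, seed=seed,
            )
            for c in calls:
                (trunk_vafs if c.variant.pos == pos_trunk else sub_vafs).append(c.vaf)
        assert np.mean(trunk_vafs) > np.mean(sub_vafs)

    def test_input_validation(self, genome_small):
        tree = make_manual_tree(genome_small, 1)
        with pytest.raises(ValueError, match="mixture"):
            sample_bulk(tree, [], genome_small)
        with pytest.raises(ValueError, match="purity"):
            sample_bulk(tree, [("root", 1.0)], genome_small, purity=0.0)
        with pytest.raises(ValueError, match="sum to 1"):
            sample_bulk(tree, [("root", 0.5)], genome_small)


class TestCloneTree:
    def test_json_roundtrip(self, genome_small):
        tree = simulate_lineage(genome_small, SimConfig(seed=3, duration_weeks=10.0))
        back = CloneTree.from_json(tree.to_json())
        assert back.to_json() == tree.to_json()

    def test_mrca(self):
        tree = CloneTree()
        tree.add(CloneNode("r", None, 0.0))
        tree.add(CloneNode("a", "r", 1.0))
        tree.add(CloneNode("b", "r", 1.0))
        tree.add(CloneNode("a1", "a", 2.0))
        assert tree.mrca(["a1", "b"]) == "r"
        assert tree.mrca(["a1", "a"]) == "a"
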