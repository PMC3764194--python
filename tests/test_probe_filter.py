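"""Probe-retention rules: worked examples, an exhaustive brute-force
truth table, SNP filters, detection masking, the cell-type filter and
shared-set construction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from apemeth import probe_filter as pf
from apemeth import synthetic_data as sd


def hit(n, pos=(), ct=False):
    return pf.MappingHit("p1", "Pan", n, frozenset(pos), ct)


class TestMappingRule:
    def test_perfect_match_kept(self):
        d = pf.classify_probe_mapping(hit(0))
        assert d.keep and d.reason == pf.Reason.perfect and d.perfect_match

    def test_two_mismatches_in_first_45_tolerated(self):
        d = pf.classify_probe_mapping(hit(2, (10, 20)))
        assert d.keep and d.reason == pf.Reason.tolerated_mismatch
        assert not d.perfect_match

    def test_three_prime_mismatch_dropped(self):
        d = pf.classify_probe_mapping(hit(1, (48,)))
        assert not d.keep and d.reason == pf.Reason.drop_3prime

    def test_three_mismatches_dropped(self):
        d = pf.classify_probe_mapping(hit(3, (3, 12, 40)))
        assert not d.keep and d.reason == pf.Reason.drop_excess_mismatch

    def test_unmapped_dropped(self):
        d = pf.classify_probe_mapping(hit(-1))
        assert not d.keep and d.reason == pf.Reason.drop_unmapped

    def test_cpg_ct_dropped_even_with_few_mismatches(self):
        d = pf.classify_probe_mapping(hit(1, (10,), ct=True))
        assert not d.keep and d.reason == pf.Reason.drop_cpg_ct

    def test_invalid_positions_raise(self):
        with pytest.raises(ValueError):
            hit(1, (51,))
        with pytest.raises(ValueError):
            hit(2, (10,))  # count/position mismatch

    def test_exhaustive_truth_table(self):
        """All position subsets of a 5'/3' representative set x counts
        0..3 x CpG flag, against an independent rule evaluator."""
        rep = [10, 20, 44, 46, 50]  # three 5' and two 3' positions
        for k in range(0, 4):
            for pos in itertools.combinations(rep, k):
                for ct in (False, True):
                    d = pf.classify_probe_mapping(hit(k, pos, ct))
                    expect = (
                        k <= 2
                        and not any(p >= 46 for p in pos)
                        and not ct
                    )
                    assert d.keep == expect, (k, pos, ct)
        assert not pf.classify_probe_mapping(hit(-1)).keep


def snps(*pairs):
    return pd.DataFrame(pairs, columns=["position", "maf"])


class TestSnpRule:
    def test_human_snp_in_last5_dropped(self):
        d = pf.apply_snp_filters("p", snps((47, 0.06)), None)
        assert not d.keep and d.reason == pf.Reason.drop_human_snp

    def test_species_snp_below_threshold_kept(self):
        d = pf.apply_snp_filters("p", None, snps((47, 0.10)))
        assert d.keep

    def test_species_snp_count_rule_is_strict(self):
        three = snps((5, 0.2), (15, 0.2), (30, 0.2))
        two = snps((5, 0.2), (15, 0.2))
        assert not pf.apply_snp_filters("p", None, three).keep
        assert pf.apply_snp_filters("p", None, two).keep

    def test_species_snp_in_last5_dropped(self):
        d = pf.apply_snp_filters("p", None, snps((46, 0.15)))
        assert not d.keep and d.reason == pf.Reason.drop_species_snp_3prime

    def test_invalid_maf_raises(self):
        with pytest.raises(ValueError):
            pf.apply_snp_filters("p", snps((10, 0.7)), None)

    def test_exhaustive_maf_position_grid(self):
        """Brute-force evaluation over a MAF x position grid for single
        human and species SNPs."""
        for posn in (1, 30, 45, 46, 50):
            for maf in (0.0, 0.04, 0.05, 0.06, 0.14, 0.15, 0.3, 0.5):
                h = pf.apply_snp_filters("p", snps((posn, maf)), None)
                assert h.keep == (not (maf >= 0.05 and posn >= 46))
                s = pf.apply_snp_filters("p", None, snps((posn, maf)))
                assert s.keep == (not (maf >= 0.15 and posn >= 46))


class TestDetection:
    def test_mask_is_per_sample(self):
        p = pd.DataFrame(
            {"s1": [0.005, 0.02], "s2": [0.02, 0.005]}, index=["p1", "p2"]
        )
        mask = pf.detection_mask(p)
        assert not mask.loc["p1", "s1"] and mask.loc["p1", "s2"]
        assert mask.loc["p2", "s1"] and not mask.loc["p2", "s2"]
        assert len(pf.fully_masked(mask)) == 0

    def test_fully_masked_probe_flagged(self):
        p = pd.DataFrame({"s1": [0.5, 0.001], "s2": [0.9, 0.001]}, index=["bad", "ok"])
        assert list(pf.fully_masked(pf.detection_mask(p))) == ["bad"]


class TestCelltypeFilter:
    def _mats(self, delta, q_breaker=False, n=6, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"p{i}" for i in range(100)]
        base = np.full((100, n), 0.3)
        wb = pd.DataFrame(
            base + rng.normal(0, 0.02, (100, n)), index=idx,
            columns=[f"wb{i}" for i in range(n)],
        )
        cd4 = pd.DataFrame(
            base + rng.normal(0, 0.02, (100, n)), index=idx,
            columns=[f"cd4_{i}" for i in range(n)],
        )
        cd4.iloc[:30] += delta  # plant enough sites for the FDR family
        cd16 = wb.copy()
        cd16.columns = [f"cd16_{i}" for i in range(n)]
        return wb, cd4, cd16

    def test_planted_delta_removed(self):
        wb, cd4, cd16 = self._mats(0.3)
        removed = pf.celltype_filter(wb, cd4, cd16)
        assert set(removed) == {f"p{i}" for i in range(30)}

    def test_small_delta_kept_despite_significance(self):
        wb, cd4, cd16 = self._mats(0.05)
        assert len(pf.celltype_filter(wb, cd4, cd16)) == 0

    def test_requires_min_samples(self):
        wb, cd4, cd16 = self._mats(0.3, n=1)
        with pytest.raises(ValueError):
            pf.celltype_filter(wb, cd4, cd16)

    def test_zero_fraction_removes_nothing(self, manifest_small):
        manifest, _, _ = manifest_small
        wb, cd4, cd16, truth = sd.simulate_blood_reference(
            manifest, frac_dm=0.0, seed=3
        )
        assert len(truth) == 0
        assert len(pf.celltype_filter(wb, cd4, cd16)) == 0

    def test_planted_fraction_recovered(self, manifest_small):
        manifest, _, _ = manifest_small
        wb, cd4, cd16, truth = sd.simulate_blood_reference(manifest, seed=4)
        removed = pf.celltype_filter(wb, cd4, cd16)
        frac = len(removed) / len(manifest)
        assert abs(frac - 0.1) <= 0.02
        assert len(set(truth) - set(removed)) / max(len(truth), 1) <= 0.1


def decision_frame(rows):
    return pd.DataFrame(
        rows, columns=["probe_id", "species", "keep", "reason", "perfect_match"]
    )


class TestSharedSets:
    def test_hand_enumerated_counts(self):
        decisions = decision_frame(
            [
                ("a", "Pan", True, "perfect", True),
                ("b", "Pan", True, "tolerated_mismatch", False),
                ("c", "Pan", False, "drop_3prime", False),
                ("a", "Pongo", True, "perfect", True),
                ("b", "Pongo", False, "drop_unmapped", False),
                ("c", "Pongo", True, "perfect", True),
            ]
        )
        snp = pd.DataFrame(
            [("a", "Pan", True, "perfect"), ("b", "Pan", True, "perfect")],
            columns=["probe_id", "species", "keep", "reason"],
        )
        allsp = pf.shared_probe_sets(decisions, snp, "all_species")
        assert list(allsp) == ["a"]
        hc = pf.shared_probe_sets(decisions, snp, "human_chimp", chimp_species="Pan")
        assert list(hc) == ["a", "b"]
        perf = pf.shared_probe_sets(decisions, snp, "perfect_only")
        assert list(perf) == ["a"]

    def test_snp_and_celltype_removal(self):
        decisions = decision_frame([("a", "Pan", True, "perfect", True),
                                    ("b", "Pan", True, "perfect", True)])
        snp = pd.DataFrame(
            [("a", "Pan", False, "drop_human_snp")],
            columns=["probe_id", "species", "keep", "reason"],
        )
        out = pf.shared_probe_sets(decisions, snp, "all_species",
                                   celltype_removed=["b"])
        assert len(out) == 0

    def test_perfect_subset_of_all(self, manifest_small):
        manifest, _, _ = manifest_small
        mapping, hs, ss = sd.simulate_mapping_and_snps(manifest, seed=5)
        decisions = pf.classify_mapping_table(mapping)
        snp = pd.concat(
            [
                pf.snp_filter_table(manifest.index, hs, ss, sp)
                for sp in decisions["species"].unique()
            ],
            ignore_index=True,
        )
        allsp = pf.shared_probe_sets(decisions, snp, "all_species")
        perf = pf.shared_probe_sets(decisions, snp, "perfect_only")
        assert set(perf) <= set(allsp)

    def test_empty_when_one_species_maps_nothing(self):
        decisions = decision_frame(
            [("a", "Pan", True, "perfect", True), ("a", "Pongo", False, "drop_unmapped", False)]
        )
        snp = pd.DataFrame(columns=["probe_id", "species", "keep", "reason"])
        assert len(pf.shared_probe_sets(decisions, snp, "all_species")) == 0


def test_filters_are_order_independent(manifest_small):
    """Applying mapping and SNP filters in either order yields the same
    kept set (they are independent predicates intersected)."""
    manifest, _, _ = manifest_small
    mapping, hs, ss = sd.simulate_mapping_and_snps(manifest, seed=6)
    decisions = pf.classify_mapping_table(mapping)
    sp = "Pan"
    snp = pf.snp_filter_table(manifest.index, hs, ss, sp)
    map_keep = set(decisions.loc[(decisions.species == sp) & decisions.keep, "probe_id"])
    snp_keep = set(snp.loc[snp.keep, "probe_id"])
    a = map_keep & snp_keep
    b = snp_keep & map_keep
    assert a == b
    sub = pf.shared_probe_sets(
        decisions[decisions.species == sp], snp, "human_chimp", chimp_species=sp
    )
    assert set(sub) == a


def test_retention_monotone_in_divergence(manifest_small):
    manifest, _, _ = manifest_small
    kept = []
    for d in (0.0, 0.01, 0.03):
        mapping, _, _ = sd.simulate_mapping_and_snps(
            manifest, {"Pan": d}, seed=9
        )
        decisions = pf.classify_mapping_table(mapping)
        kept.append(int(decisions["keep"].sum()))
    assert kept[0] == len(manifest)  # zero divergence: all perfect
    assert kept[0] >= kept[1] >= kept[2]
    assert kept[2] < kept[1]
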