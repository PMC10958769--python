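import numpy as np
import pytest

from helpers import plant_site, random_dna
from oligocov.coverage_stats import (CoverageReport, build_target_group,
                                     co_coverage_partition, copy_number_correct,
                                     coverage_percent, evaluate_mix_coverage,
                                     evaluate_oligo_coverage, extract_uncovered,
                                     pairwise_co_coverage)
from oligocov.oligo_engine import reverse_complement
from oligocov.refdb_io import Oligo, RefSeq, ReferenceDB


@pytest.mark.parametrize("n_hit,n_total,expected", [
    (73, 86, 84.9),
    (0, 5, 0.0),
    (209, 387, 54.0),
    (61, 86, 70.9),
    (48, 95, 50.5),
    (50, 95, 52.6),
    (1, 16, 6.3),     # 6.25 rounds half-up to 6.3
    (86, 86, 100.0),
])
def test_coverage_percent_half_up_one_decimal(n_hit, n_total, expected):
    assert coverage_percent(n_hit, n_total) == expected


def test_coverage_percent_undefined_for_empty_denominator():
    assert coverage_percent(0, 0) is None


def test_coverage_percent_rejects_bad_counts():
    with pytest.raises(ValueError):
        coverage_percent(5, 3)


def _probe(name, seq):
    return Oligo(name=name, sequence=seq, role="fish_probe")


@pytest.fixture()
def planted_db(rng):
    """10 in-group + 8 out-group sequences; probe A binds 7 in/2 out,
    probe B binds 4 in (2 shared with A)."""
    probe_a = _probe("prA", "CCCTCTGCCAAACTCCAG")
    probe_b = _probe("prB", "GTTAGCTACGGCACTAAAAGG")
    site_a = reverse_complement(probe_a.sequence)
    site_b = reverse_complement(probe_b.sequence)
    records, truth_a, truth_b = [], set(), set()

    def add(sid, taxon, plant):
        from helpers import naive_scan
        if plant is None:
            while True:
                seq = random_dna(rng, 260)
                if not naive_scan(site_a, seq, 0, 0) and \
                   not naive_scan(site_b, seq, 0, 0):
                    break
        else:
            seq = plant_site(rng, plant, 260, 60, [site_a, site_b])
        records.append(RefSeq(sid, seq, ("Bacteria", taxon)))

    for i in range(10):
        sid = f"in{i}"
        if i < 5:
            add(sid, "TargetGenus", site_a)
            truth_a.add(sid)
        elif i < 7:
            # plant A at 60 via add(), then splice B in at 150
            add(sid, "TargetGenus", site_a)
            rec = records.pop()
            seq = rec.sequence[:150] + site_b + rec.sequence[150 + len(site_b):]
            records.append(RefSeq(rec.id, seq, rec.taxonomy))
            truth_a.add(sid)
            truth_b.add(sid)
        elif i < 9:
            add(sid, "TargetGenus", site_b)
            truth_b.add(sid)
        else:
            add(sid, "TargetGenus", None)
    for i in range(8):
        sid = f"out{i}"
        taxon = "OtherGenusX" if i % 2 else "OtherGenusY"
        add(sid, taxon, site_a if i < 2 else None)
    db = ReferenceDB(records)
    return db, probe_a, probe_b, truth_a, truth_b


class TestTargetGroups:
    def test_predicate_group_from_taxonomy(self, planted_db):
        db, *_ = planted_db
        group = build_target_group(db, "TargetGenus")
        assert len(group) == 10

    def test_explicit_ids_group(self, planted_db):
        db, *_ = planted_db
        group = build_target_group(db, ["in0", "in1", "in2"], name="refined")
        assert group.member_ids == {"in0", "in1", "in2"}

    def test_explicit_ids_must_exist(self, planted_db):
        db, *_ = planted_db
        with pytest.raises(KeyError):
            build_target_group(db, ["in0", "ghost"])

    def test_empty_predicate_yields_empty_group_and_undefined_coverage(
            self, planted_db):
        db, probe_a, *_ = planted_db
        group = build_target_group(db, "AbsentGenus")
        assert len(group) == 0
        rep = evaluate_oligo_coverage(probe_a, db, group)
        assert rep.coverage_pct is None and rep.n_target == 0


class TestOligoCoverage:
    def test_counts_match_planted_truth(self, planted_db):
        db, probe_a, _, truth_a, _ = planted_db
        group = build_target_group(db, "TargetGenus")
        rep = evaluate_oligo_coverage(probe_a, db, group)
        assert rep.n_target == 10
        assert rep.n_target_hit == len(truth_a) == 7
        assert rep.coverage_pct == 70.0
        assert sum(rep.nontarget_hits.values()) == 2
        assert rep.uncovered_ids == {f"in{i}" for i in range(10)} - truth_a

    def test_nontarget_hits_grouped_by_lowest_rank(self, planted_db):
        db, probe_a, *_ = planted_db
        group = build_target_group(db, "TargetGenus")
        rep = evaluate_oligo_coverage(probe_a, db, group)
        assert set(rep.nontarget_hits) <= {"OtherGenusX", "OtherGenusY"}

    def test_binding_nothing_means_zero_coverage(self, planted_db, rng):
        db, *_ = planted_db
        group = build_target_group(db, "TargetGenus")
        inert = _probe("inert", "TTTTTTTTTTTTTTTTTT")
        rep = evaluate_oligo_coverage(inert, db, group)
        assert rep.coverage_pct == 0.0
        assert rep.uncovered_ids == group.member_ids

    def test_record_order_invariance(self, planted_db):
        db, probe_a, *_ = planted_db
        group = build_target_group(db, "TargetGenus")
        shuffled = ReferenceDB(sorted(db, key=lambda r: r.id, reverse=True))
        a = evaluate_oligo_coverage(probe_a, db, group).coverage_pct
        b = evaluate_oligo_coverage(probe_a, shuffled, group).coverage_pct
        assert a == b


class TestMixCoverage:
    def test_union_semantics(self, planted_db):
        db, probe_a, probe_b, truth_a, truth_b = planted_db
        group = build_target_group(db, "TargetGenus")
        rep = evaluate_mix_coverage([probe_a, probe_b], db, group,
                                    mix_name="mixAB")
        assert rep.n_target_hit == len(truth_a | truth_b) == 9
        assert rep.coverage_pct == 90.0

    def test_mix_of_one_equals_single_oligo(self, planted_db):
        db, probe_a, *_ = planted_db
        group = build_target_group(db, "TargetGenus")
        single = evaluate_oligo_coverage(probe_a, db, group)
        mix = evaluate_mix_coverage([probe_a], db, group)
        assert mix.n_target_hit == single.n_target_hit
        assert mix.coverage_pct == single.coverage_pct

    def test_mix_coverage_at_least_best_member(self, planted_db):
        db, probe_a, probe_b, *_ = planted_db
        group = build_target_group(db, "TargetGenus")
        best = max(evaluate_oligo_coverage(p, db, group).coverage_pct
                   for p in (probe_a, probe_b))
        mix = evaluate_mix_coverage([probe_a, probe_b], db, group)
        assert mix.coverage_pct >= best


class TestVennPartition:
    def test_regions_match_planted_signatures(self, planted_db):
        db, probe_a, probe_b, truth_a, truth_b = planted_db
        group = build_target_group(db, "TargetGenus")
        part = co_coverage_partition([probe_a, probe_b], db, group)
        assert part.count("prA") == len(truth_a - truth_b)
        assert part.count("prB") == len(truth_b - truth_a)
        assert part.count("prA", "prB") == len(truth_a & truth_b)
        assert part.count() == 10 - len(truth_a | truth_b)

    def test_regions_sum_to_group_and_marginals_match(self, planted_db):
        db, probe_a, probe_b, truth_a, truth_b = planted_db
        group = build_target_group(db, "TargetGenus")
        part = co_coverage_partition([probe_a, probe_b], db, group)
        assert sum(part.region_counts.values()) == len(group)
        assert part.marginal("prA") == len(truth_a)
        assert part.marginal("prB") == len(truth_b)

    def test_single_oligo_two_regions(self, planted_db):
        db, probe_a, *_ = planted_db
        group = build_target_group(db, "TargetGenus")
        part = co_coverage_partition([probe_a], db, group)
        assert len(part.region_counts) == 2
        assert sum(part.region_counts.values()) == len(group)

    def test_more_than_six_oligos_refused(self, planted_db):
        db, probe_a, *_ = planted_db
        group = build_target_group(db, "TargetGenus")
        many = [_probe(f"p{i}", "ACGTACGTACGTACGTAC") for i in range(7)]
        with pytest.raises(ValueError, match="pairwise"):
            co_coverage_partition(many, db, group)
        # the pairwise fallback works for the same set
        mat = pairwise_co_coverage(many, db, group)
        assert all(v == 0 for v in mat.values())


class TestUncovered:
    def test_blind_spots_are_exactly_the_non_binders(self, planted_db):
        db, probe_a, probe_b, truth_a, truth_b = planted_db
        group = build_target_group(db, "TargetGenus")
        blind = extract_uncovered([probe_a, probe_b], db, group)
        assert {r.id for r in blind} == group.member_ids - (truth_a | truth_b)

    def test_empty_probe_set_returns_whole_group(self, planted_db):
        db, *_ = planted_db
        group = build_target_group(db, "TargetGenus")
        blind = extract_uncovered([], db, group)
        assert {r.id for r in blind} == group.member_ids

    def test_all_covered_group_exports_nothing(self, planted_db):
        db, probe_a, _, truth_a, _ = planted_db
        group = build_target_group(db, sorted(truth_a), name="covered")
        assert extract_uncovered([probe_a], db, group) == []


class TestCopyNumberCorrection:
    def test_two_taxa(self):
        out = copy_number_correct({"a": 0.5, "b": 0.5}, {"a": 2, "b": 4})
        assert out["a"] == pytest.approx(2 / 3)
        assert out["b"] == pytest.approx(1 / 3)

    def test_equal_copies_is_identity(self):
        abund = {"a": 0.2, "b": 0.3, "c": 0.5}
        out = copy_number_correct(abund, {t: 3 for t in abund})
        assert out == pytest.approx(abund)

    def test_three_guilds_with_reported_copy_numbers(self):
        third = 1 / 3
        out = copy_number_correct(
            {"Ca_Accumulibacter": third, "Tetrasphaera": third,
             "Dechloromonas": third},
            {"Ca_Accumulibacter": 2, "Tetrasphaera": 1, "Dechloromonas": 4})
        assert out["Ca_Accumulibacter"] == pytest.approx(2 / 7)
        assert out["Tetrasphaera"] == pytest.approx(4 / 7)
        assert out["Dechloromonas"] == pytest.approx(1 / 7)

    def test_missing_copy_number_is_hard_error(self):
        with pytest.raises(KeyError):
            copy_number_correct({"a": 1.0}, {})

    def test_abundances_must_be_normalized(self):
        with pytest.raises(ValueError):
            copy_number_correct({"a": 0.4, "b": 0.4}, {"a": 1, "b": 1})

    def test_output_on_simplex_and_scale_invariant(self):
        abund = {"a": 0.1, "b": 0.6, "c": 0.3}
        copies = {"a": 2.0, "b": 3.0, "c": 4.0}
        out1 = copy_number_correct(abund, copies)
        out2 = copy_number_correct(abund, {t: 10 * c for t, c in copies.items()})
        assert sum(out1.values()) == pytest.approx(1.0)
        assert out1 == pytest.approx(out2)


def test_report_invariant_enforced():
    with pytest.raises(ValueError):
        CoverageReport(oligo_or_mix_name="x", database_tag="d", group_name="g",
                       n_target=5, n_target_hit=3, coverage_pct=60.0,
                       uncovered_ids=frozenset({"a"}))
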