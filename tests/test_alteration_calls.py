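import numpy as np
import pandas as pd
import pytest

from timedrivers.alteration_calls import (
    AlterationClass,
    AlterationEvent,
    NoRetainedDriversError,
    Source,
    apply_driver_filters,
    build_alteration_matrix,
    build_cohort_matrix,
    call_cna_alterations,
    compose_alterations,
    mutation_events,
)
from timedrivers.core_model import (
    CohortDataset,
    Consequence,
    DriverEntry,
    ExpressionMatrix,
    GeneCopyState,
    MutationCall,
    Role,
    SampleMeta,
    Tier,
)

LOF, GOF = AlterationClass.LOF, AlterationClass.GOF


def hand_labelled_cohort() -> CohortDataset:
    """Ten samples, three drivers; every calling rule exercised by hand.

    Expected final role-consistent events (worked out manually):
      TSG (tumour suppressor): truncating s01, missense s02,
        splicing + double-hit s05, homozygous loss s06
        (hotspot s03 role-dropped; lone het loss s04 no event;
         s07 copy state ignored: only 10% of transcript covered)
      ONC (oncogene): hotspot s01, damaging gains s03/s09/s10
        (truncating s02 role-dropped; s04 cn 5 at ploidy 3 is not > 2x ploidy)
      UNC (unclassified): truncating s07, damaging gains s08/s09/s10
    """
    ids = [f"s{i:02d}" for i in range(1, 11)]
    ploidy = {"s04": 3.0}
    purity = {"s04": 0.8, "s05": 0.5, "s06": 0.8}
    samples = [SampleMeta(s, "HN", purity.get(s, 0.7), ploidy.get(s, 2.0))
               for s in ids]
    mutations = [
        MutationCall("s01", "TSG", Consequence.TRUNCATING, 30, 100),
        MutationCall("s02", "TSG", Consequence.MISSENSE_DAMAGING, 30, 100),
        MutationCall("s03", "TSG", Consequence.HOTSPOT, 30, 100),
        MutationCall("s05", "TSG", Consequence.SPLICING_DAMAGING, 30, 100),
        MutationCall("s01", "ONC", Consequence.HOTSPOT, 30, 100),
        MutationCall("s02", "ONC", Consequence.TRUNCATING, 30, 100),
        MutationCall("s07", "UNC", Consequence.TRUNCATING, 30, 100),
        MutationCall("s09", "TSG", Consequence.BENIGN_OTHER, 30, 100),
    ]
    copy_states = [
        GeneCopyState("s04", "TSG", 1, 1.0),    # het loss alone -> nothing
        GeneCopyState("s05", "TSG", 1, 1.0),    # het loss + splicing -> double hit
        GeneCopyState("s06", "TSG", 0, 1.0),    # homozygous loss (0.4/0.8 < 1)
        GeneCopyState("s07", "TSG", 0, 0.10),   # below 25% coverage: ignored
        GeneCopyState("s03", "ONC", 5, 1.0),    # gain candidate (5 > 4)
        GeneCopyState("s09", "ONC", 5, 0.30),
        GeneCopyState("s10", "ONC", 5, 1.0),
        GeneCopyState("s04", "ONC", 5, 1.0),    # ploidy 3: 5 < 6, no candidate
        GeneCopyState("s08", "UNC", 6, 1.0),
        GeneCopyState("s09", "UNC", 6, 1.0),
        GeneCopyState("s10", "UNC", 6, 1.0),
    ]
    expr = pd.DataFrame(5.0, index=["TSG", "ONC", "UNC"], columns=ids)
    expr.loc["TSG", "s04"] = 2.4   # 2.4/0.8 = 3.0 > 1 -> het loss
    expr.loc["TSG", "s05"] = 1.0   # 1.0/0.5 = 2.0 > 1 -> het loss
    expr.loc["TSG", "s06"] = 0.4   # 0.4/0.8 = 0.5 < 1 -> homozygous loss
    expr.loc["TSG", "s07"] = 0.1
    for s in ("s03", "s09", "s10"):
        expr.loc["ONC", s] = 50.0 + float(s[-1])
    for s in ("s08", "s09", "s10"):
        expr.loc["UNC", s] = 40.0 + float(s[-1])
    drivers = [
        DriverEntry("TSG", Role.TUMOUR_SUPPRESSOR, Tier.CANONICAL, frozenset({"HN"})),
        DriverEntry("ONC", Role.ONCOGENE, Tier.CANONICAL, frozenset({"HN"})),
        DriverEntry("UNC", Role.UNCLASSIFIED, Tier.CANDIDATE, frozenset({"HN"})),
    ]
    return CohortDataset(samples, mutations, copy_states,
                         ExpressionMatrix(expr), drivers)


EXPECTED_EVENTS = {
    ("s01", "TSG", LOF, Source.TRUNCATING),
    ("s02", "TSG", LOF, Source.MISSENSE_DAMAGING),
    ("s05", "TSG", LOF, Source.SPLICING_DAMAGING),
    ("s05", "TSG", LOF, Source.DOUBLE_HIT),
    ("s06", "TSG", LOF, Source.HOMOZYGOUS_LOSS),
    ("s01", "ONC", GOF, Source.HOTSPOT),
    ("s03", "ONC", GOF, Source.DAMAGING_GAIN),
    ("s09", "ONC", GOF, Source.DAMAGING_GAIN),
    ("s10", "ONC", GOF, Source.DAMAGING_GAIN),
    ("s07", "UNC", LOF, Source.TRUNCATING),
    ("s08", "UNC", GOF, Source.DAMAGING_GAIN),
    ("s09", "UNC", GOF, Source.DAMAGING_GAIN),
    ("s10", "UNC", GOF, Source.DAMAGING_GAIN),
}


def full_call(cohort):
    mut = mutation_events(cohort.mutations)
    cna = call_cna_alterations(cohort)
    composed = compose_alterations(mut, cna)
    _, kept = apply_driver_filters(composed, cohort.drivers, "HN",
                                   n_samples=len(cohort.samples))
    return kept


class TestHandLabelledFixture:
    def test_every_rule_reproduced_exactly(self):
        kept = full_call(hand_labelled_cohort())
        got = {(e.sample_id, e.gene_id, e.klass, e.source) for e in kept}
        assert got == EXPECTED_EVENTS

    def test_matrix_matches_hand_enumeration(self):
        cohort = hand_labelled_cohort()
        matrix = build_cohort_matrix(cohort)
        expected = pd.DataFrame(0, index=[s.sample_id for s in cohort.samples],
                                columns=["TSG", "ONC", "UNC"])
        for s in ("s01", "s02", "s05", "s06"):
            expected.loc[s, "TSG"] = 1
        for s in ("s01", "s03", "s09", "s10"):
            expected.loc[s, "ONC"] = 1
        for s in ("s07", "s08", "s09", "s10"):
            expected.loc[s, "UNC"] = 1
        assert (matrix.indicators.to_numpy() == expected.to_numpy()).all()
        assert list(matrix.indicators.columns) == ["TSG", "ONC", "UNC"]


class TestCnaCalls:
    def test_loss_thresholds(self):
        cohort = hand_labelled_cohort()
        cna = call_cna_alterations(cohort)
        sources = {(e.sample_id, e.gene_id): e.source for e in cna}
        assert sources[("s06", "TSG")] == Source.HOMOZYGOUS_LOSS
        assert sources[("s04", "TSG")] == Source.HETEROZYGOUS_LOSS
        assert ("s07", "TSG") not in sources          # coverage < 25%
        assert ("s04", "ONC") not in sources          # 5 < 2 x ploidy 3

    def test_gain_requires_expression_support(self):
        # same copy-number gains but expression at baseline: no gain survives
        cohort = hand_labelled_cohort()
        flat = cohort.expression.values.copy()
        flat.loc["ONC"] = 5.0
        flat.loc["UNC"] = 5.0
        cohort = CohortDataset(cohort.samples, cohort.mutations, cohort.copy_states,
                               ExpressionMatrix(flat), cohort.drivers)
        cna = call_cna_alterations(cohort)
        assert not [e for e in cna if e.source == Source.DAMAGING_GAIN]

    def test_gain_in_every_sample_is_untestable(self):
        ids = ["a", "b", "c"]
        samples = [SampleMeta(s, "T", 0.7, 2.0) for s in ids]
        states = [GeneCopyState(s, "G", 6, 1.0) for s in ids]
        expr = ExpressionMatrix(pd.DataFrame([[9.0, 9.0, 9.0]], index=["G"],
                                             columns=ids))
        cohort = CohortDataset(samples, [], states, expr, [])
        with pytest.warns(UserWarning, match="untestable"):
            assert call_cna_alterations(cohort) == []


class TestCompose:
    def test_het_loss_plus_truncating_is_double_hit(self):
        mut = [AlterationEvent("s", "G", LOF, Source.TRUNCATING)]
        cna = [AlterationEvent("s", "G", LOF, Source.HETEROZYGOUS_LOSS)]
        out = compose_alterations(mut, cna)
        assert {e.source for e in out} == {Source.TRUNCATING, Source.DOUBLE_HIT}
        assert all(e.klass == LOF for e in out)

    def test_lone_het_loss_is_not_an_event(self):
        cna = [AlterationEvent("s", "G", LOF, Source.HETEROZYGOUS_LOSS)]
        assert compose_alterations([], cna) == []

    def test_hotspot_passes_through_as_gof(self):
        out = compose_alterations([AlterationEvent("s", "G", GOF, Source.HOTSPOT)], [])
        assert out == [AlterationEvent("s", "G", GOF, Source.HOTSPOT)]


class TestDriverFilters:
    DRIVERS = [DriverEntry("TS", Role.TUMOUR_SUPPRESSOR, Tier.CANONICAL,
                           frozenset({"T"}))]

    def _events(self, n, klass=LOF, source=Source.TRUNCATING):
        return [AlterationEvent(f"s{i}", "TS", klass, source) for i in range(n)]

    def test_ts_with_only_gof_dropped(self):
        retained, kept = apply_driver_filters(
            self._events(8, GOF, Source.HOTSPOT), self.DRIVERS, "T", 400)
        assert retained == [] and kept == []

    def test_count_rule_7_of_400(self):
        retained, _ = apply_driver_filters(self._events(7), self.DRIVERS, "T", 400)
        assert retained == ["TS"]   # 7 >= 5 although 1.75% < 2%

    def test_or_semantics_4_of_100(self):
        retained, _ = apply_driver_filters(self._events(4), self.DRIVERS, "T", 100)
        assert retained == ["TS"]   # 4 < 5 but 4% >= 2%

    def test_rare_driver_dropped(self):
        retained, _ = apply_driver_filters(self._events(4), self.DRIVERS, "T", 400)
        assert retained == []       # 4 < 5 and 1% < 2%

    @pytest.mark.parametrize("loosen", ["min_count", "min_frac"])
    def test_loosening_never_shrinks_retention(self, loosen):
        rng = np.random.default_rng(0)
        drivers = [DriverEntry(f"G{i}", Role.UNCLASSIFIED, Tier.CANDIDATE,
                               frozenset({"T"})) for i in range(10)]
        events = [AlterationEvent(f"s{rng.integers(100)}", f"G{rng.integers(10)}",
                                  LOF, Source.TRUNCATING) for _ in range(120)]
        strict = dict(min_count=6, min_frac=0.05)
        loose = dict(strict, **{loosen: 2 if loosen == "min_count" else 0.01})
        r_strict, _ = apply_driver_filters(events, drivers, "T", 100, **strict)
        r_loose, _ = apply_driver_filters(events, drivers, "T", 100, **loose)
        assert set(r_strict) <= set(r_loose)


class TestMatrix:
    def test_single_damaged_sample_column(self):
        events = [AlterationEvent("s1", "A", LOF, Source.TRUNCATING)]
        m = build_alteration_matrix(events, ["s1", "s2", "s3"], ["A"])
        assert list(m.indicators["A"]) == [1, 0, 0]

    def test_multiple_events_stay_binary(self):
        events = [AlterationEvent("s1", "A", LOF, Source.TRUNCATING),
                  AlterationEvent("s1", "A", LOF, Source.HOMOZYGOUS_LOSS)]
        m = build_alteration_matrix(events, ["s1"], ["A"])
        assert m.indicators.at["s1", "A"] == 1
        assert len(m.provenance[("s1", "A")]) == 2

    def test_empty_driver_set_signals(self):
        with pytest.raises(NoRetainedDriversError):
            build_alteration_matrix([], ["s1"], [])


def test_role_classified_drivers_never_carry_both_classes(planted_cohort):
    """After role filtering, no sample-gene of a role-classified driver has
    both LoF and GoF events (unclassified drivers may)."""
    cohort, _ = planted_cohort
    matrix = build_cohort_matrix(cohort)
    role = {d.gene_id: d.role for d in cohort.drivers}
    for (sid, gid), events in matrix.provenance.items():
        if role[gid] in (Role.TUMOUR_SUPPRESSOR, Role.ONCOGENE):
            assert len({e.klass for e in events}) == 1
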