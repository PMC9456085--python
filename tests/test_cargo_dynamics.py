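"""Compartment calls, Venn set algebra and the cross-contrast dynamics
classification (concurred / favored loading / retention)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from evmir.cargo_dynamics import (CompartmentCalls, CompCall, DynamicsRecord,
                                  Klass, classify_dynamics, compartment_calls,
                                  records_to_frame, summarize_dynamics,
                                  venn_sets)
from evmir.diff_enrichment import (ContrastResult, ContrastSpec, DECall)


# --- lightweight builders ---------------------------------------------------

def contrast_tables(rows, spec):
    """rows: mirna -> (status, log2fc, q, is_de, basis, direction)."""
    idx = pd.Index(list(rows), name="mirna")
    res = ContrastResult(spec=spec, table=pd.DataFrame(
        {
            "status": [r[0] for r in rows.values()],
            "mean_cpm_a": 100.0, "mean_cpm_b": 100.0,
            "log2fc": [r[1] for r in rows.values()],
            "p_value": [np.nan if r[2] is None else r[2] / 2
                        for r in rows.values()],
            "q_value": [np.nan if r[2] is None else r[2]
                        for r in rows.values()],
        }, index=idx))
    call = DECall(spec=spec, table=pd.DataFrame(
        {
            "is_de": [r[3] for r in rows.values()],
            "basis": [r[4] for r in rows.values()],
            "direction": [r[5] for r in rows.values()],
        }, index=idx))
    return res, call


EVC_N = ContrastSpec("evc_n", ("cell", "normoxia"), ("ev", "normoxia"))
EVC_H = ContrastSpec("evc_h", ("cell", "hypoxia"), ("ev", "hypoxia"))
HN_EV = ContrastSpec("hn_ev", ("ev", "normoxia"), ("ev", "hypoxia"))
HN_CELL = ContrastSpec("hn_cell", ("cell", "normoxia"), ("cell", "hypoxia"))

NEUTRAL = ("tested", 0.0, 0.9, False, "none", "none")
UP = ("tested", 2.0, 0.01, True, "quantitative", "up_in_b")
DOWN = ("tested", -2.0, 0.01, True, "quantitative", "down_in_b")
EXCL_EV = ("exclusive_b", np.nan, None, True, "qualitative", "up_in_b")
EXCL_CELL = ("exclusive_a", np.nan, None, True, "qualitative", "down_in_b")
ABSENT = ("absent", np.nan, None, False, "none", "none")


def comp_from(h_rows, n_rows):
    return compartment_calls({
        "normoxia": contrast_tables(n_rows, EVC_N),
        "hypoxia": contrast_tables(h_rows, EVC_H),
    })


class TestCompartmentCalls:
    def test_exclusive_to_ev_is_enriched(self):
        comp = comp_from({"m1": EXCL_EV}, {"m1": NEUTRAL})
        assert comp.call("m1", "hypoxia") == CompCall.ENRICHED_IN_EV.value
        assert comp.table.at["m1", "basis_hypoxia"] == "exclusive"

    def test_quantitative_enrichment_and_retention(self):
        comp = comp_from(
            {"m1": ("tested", 1.4, 0.02, True, "quantitative", "up_in_b"),
             "m2": ("tested", -2.2, 0.02, True, "quantitative", "down_in_b")},
            {"m1": NEUTRAL, "m2": NEUTRAL})
        assert comp.call("m1", "hypoxia") == CompCall.ENRICHED_IN_EV.value
        assert comp.table.at["m1", "basis_hypoxia"] == "quantitative"
        assert comp.call("m2", "hypoxia") == CompCall.RETAINED_IN_CELL.value

    def test_absent_in_both_compartments(self):
        comp = comp_from({"m1": ABSENT}, {"m1": NEUTRAL})
        assert comp.call("m1", "hypoxia") == CompCall.ABSENT.value

    def test_wrong_orientation_rejected(self):
        res, call = contrast_tables({"m1": NEUTRAL}, HN_EV)
        with pytest.raises(ValueError, match="oriented"):
            compartment_calls({"hypoxia": (res, call)})


def classify(ev_rows, cell_rows, h_rows, n_rows):
    _, de_ev = contrast_tables(ev_rows, HN_EV)
    _, de_cell = contrast_tables(cell_rows, HN_CELL)
    comp = comp_from(h_rows, n_rows)
    return classify_dynamics(de_ev, de_cell, comp)


class TestClassifyDynamics:
    """The four narrated behavioral patterns of the study, plus the mirror
    cases and priority/flag semantics."""

    def test_concurred_enrichment(self):
        # up in H-EVs and up in H-cells: EV cargo mirrors cell expression
        recs = classify({"m": UP}, {"m": UP}, {"m": NEUTRAL}, {"m": NEUTRAL})
        assert recs[0].klass == Klass.CONCURRED.value
        assert recs[0].cell_call == "up_in_h"

    def test_favored_loading_with_no_cell_change(self):
        # up in H-EVs, cell unchanged, enriched in H-EVs vs H-cells
        recs = classify({"m": UP}, {"m": NEUTRAL}, {"m": UP}, {"m": NEUTRAL})
        assert recs[0].klass == Klass.FAVORED_LOADING.value

    def test_favored_loading_with_opposite_cell_direction(self):
        # the miR-100-3p / miR-34a-5p pattern: down in H-cells yet enriched
        # in H-EVs -> still favored loading
        recs = classify({"m": UP}, {"m": DOWN}, {"m": UP}, {"m": NEUTRAL})
        assert recs[0].klass == Klass.FAVORED_LOADING.value
        assert recs[0].cell_call == "down_in_h"

    def test_retention_causing_ev_reduction(self):
        # down in H-EVs, cell unchanged, retained in H-cells
        recs = classify({"m": DOWN}, {"m": NEUTRAL}, {"m": DOWN}, {"m": NEUTRAL})
        assert recs[0].klass == Klass.RETENTION.value

    def test_retention_in_opposite_condition_for_up_in_h(self):
        # up in H-EVs because the miRNA is retained in N-cells (depressing
        # its N-EV level), with no loading evidence in hypoxia
        recs = classify({"m": UP}, {"m": NEUTRAL}, {"m": NEUTRAL}, {"m": DOWN})
        assert recs[0].klass == Klass.RETENTION.value

    def test_unexplained_when_no_mechanism_matches(self):
        recs = classify({"m": UP}, {"m": NEUTRAL}, {"m": NEUTRAL}, {"m": NEUTRAL})
        assert recs[0].klass == Klass.UNEXPLAINED.value
        assert recs[0].flags == frozenset()

    def test_priority_concurred_over_retention_with_flags(self):
        # concurred and retention evidence together: klass is concurred but
        # the retention flag is kept
        recs = classify({"m": UP}, {"m": UP}, {"m": NEUTRAL}, {"m": DOWN})
        assert recs[0].klass == Klass.CONCURRED.value
        assert recs[0].flags == {Klass.CONCURRED.value, Klass.RETENTION.value}

    def test_exclusivity_based_ev_de_counts(self):
        # qualitative EV DE (exclusive to H-EVs) is classified the same way
        recs = classify({"m": EXCL_EV}, {"m": NEUTRAL}, {"m": EXCL_EV},
                        {"m": ABSENT})
        assert recs[0].klass == Klass.FAVORED_LOADING.value

    def test_non_de_mirnas_are_excluded(self):
        recs = classify({"m": NEUTRAL}, {"m": UP}, {"m": UP}, {"m": UP})
        assert recs == []

    def test_order_invariance(self):
        rows_ev = {"a": UP, "b": DOWN, "c": EXCL_EV}
        rows_cell = {"a": UP, "b": NEUTRAL, "c": NEUTRAL}
        h = {"a": NEUTRAL, "b": DOWN, "c": UP}
        n = {"a": NEUTRAL, "b": NEUTRAL, "c": NEUTRAL}
        fwd = classify(rows_ev, rows_cell, h, n)

        def rev(d):
            return dict(reversed(list(d.items())))

        bwd = classify(rev(rows_ev), rev(rows_cell), rev(h), rev(n))
        assert {r.mirna: r.klass for r in fwd} == {r.mirna: r.klass for r in bwd}

    def test_condition_relabeling_symmetry(self):
        """Swapping normoxia <-> hypoxia everywhere mirrors up_in_h <->
        down_in_h and leaves the class totals unchanged."""
        flip = {"up_in_b": "down_in_b", "down_in_b": "up_in_b", "none": "none",
                "exclusive_a": "exclusive_b", "exclusive_b": "exclusive_a",
                "tested": "tested", "absent": "absent"}

        def flip_row(r):
            status, fc, q, is_de, basis, d = r
            return (flip[status], -fc if fc == fc else fc, q, is_de, basis,
                    flip[d])

        rows_ev = {"a": UP, "b": DOWN, "c": EXCL_EV, "d": UP}
        rows_cell = {"a": UP, "b": NEUTRAL, "c": NEUTRAL, "d": NEUTRAL}
        h = {"a": NEUTRAL, "b": DOWN, "c": UP, "d": NEUTRAL}
        n = {"a": NEUTRAL, "b": NEUTRAL, "c": ABSENT, "d": DOWN}
        fwd = classify(rows_ev, rows_cell, h, n)
        # relabel: H<->N flips the H-vs-N contrasts and swaps the
        # per-condition compartment tables
        rows_ev2 = {k: flip_row(v) for k, v in rows_ev.items()}
        rows_cell2 = {k: flip_row(v) for k, v in rows_cell.items()}
        bwd = classify(rows_ev2, rows_cell2, n, h)
        fwd_k = {r.mirna: r.klass for r in fwd}
        bwd_k = {r.mirna: r.klass for r in bwd}
        assert fwd_k == bwd_k
        dirs_fwd = {r.mirna: r.ev_direction for r in fwd}
        dirs_bwd = {r.mirna: r.ev_direction for r in bwd}
        mirror = {"up_in_h": "down_in_h", "down_in_h": "up_in_h"}
        assert dirs_bwd == {m: mirror[d] for m, d in dirs_fwd.items()}


class TestSummarize:
    def test_study_scale_fraction(self):
        # 39 EV-DE miRNAs of which 9 concurred -> 30/39 selective
        recs = ([DynamicsRecord(f"c{i}", "up_in_h", "up_in_h", "", "",
                                Klass.CONCURRED.value) for i in range(9)]
                + [DynamicsRecord(f"f{i}", "up_in_h", "no_change", "", "",
                                  Klass.FAVORED_LOADING.value) for i in range(16)]
                + [DynamicsRecord(f"r{i}", "up_in_h", "no_change", "", "",
                                  Klass.RETENTION.value) for i in range(14)])
        s = summarize_dynamics(recs)
        assert s.n_de_ev == 39 and s.n_concurred == 9 and s.n_selective == 30
        assert s.fraction_selective == pytest.approx(30 / 39)

    def test_all_concurred(self):
        recs = [DynamicsRecord("m", "up_in_h", "up_in_h", "", "",
                               Klass.CONCURRED.value)]
        assert summarize_dynamics(recs).fraction_selective == 0.0

    def test_empty_summary_has_nan_fraction(self):
        s = summarize_dynamics([])
        assert s.n_de_ev == 0
        assert np.isnan(s.fraction_selective)
        assert s.to_dict()["fraction_selective"] is None

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from([k.value for k in Klass]), max_size=40))
    def test_counts_match_bruteforce_tally(self, labels):
        recs = [DynamicsRecord(f"m{i}", "up_in_h", "no_change", "", "", k)
                for i, k in enumerate(labels)]
        s = summarize_dynamics(recs)
        assert s.n_concurred == sum(1 for k in labels if k == "concurred")
        assert s.n_favored_loading == sum(1 for k in labels
                                          if k == "favored_loading")
        assert s.n_retention == sum(1 for k in labels if k == "retention")
        assert s.n_unexplained == sum(1 for k in labels if k == "unexplained")
        assert (s.n_concurred + s.n_favored_loading + s.n_retention
                + s.n_unexplained) == s.n_de_ev


class TestVennSets:
    @staticmethod
    def comp_with(enr_n, enr_h, ret_n, ret_h, universe):
        rows = {}
        for m in universe:
            rows[m] = {}
        table = pd.DataFrame(index=pd.Index(sorted(universe), name="mirna"))
        for cond, enr, ret in (("normoxia", enr_n, ret_n),
                               ("hypoxia", enr_h, ret_h)):
            table[f"call_{cond}"] = [
                CompCall.ENRICHED_IN_EV.value if m in enr
                else CompCall.RETAINED_IN_CELL.value if m in ret
                else CompCall.NEUTRAL.value
                for m in table.index]
            table[f"basis_{cond}"] = "none"
        return CompartmentCalls(table=table, conditions=["normoxia", "hypoxia"])

    def test_basic_set_algebra(self):
        comp = self.comp_with({"a", "b", "c"}, {"b", "c", "d"}, set(), set(),
                              {"a", "b", "c", "d"})
        v = venn_sets(comp)
        assert v["enriched_both"] == {"b", "c"}
        assert v["enriched_normoxia_only"] == {"a"}
        assert v["enriched_hypoxia_only"] == {"d"}

    def test_empty_calls_give_empty_sets(self):
        comp = self.comp_with(set(), set(), set(), set(), {"a"})
        assert all(len(s) == 0 for s in venn_sets(comp).values())

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.builds(
        lambda u, en, eh, rn, rh: (set(u), set(en) & set(u), set(eh) & set(u),
                                   set(rn) & set(u), set(rh) & set(u)),
        st.sets(st.sampled_from("abcdefgh"), min_size=1),
        st.sets(st.sampled_from("abcdefgh")),
        st.sets(st.sampled_from("abcdefgh")),
        st.sets(st.sampled_from("abcdefgh")),
        st.sets(st.sampled_from("abcdefgh")),
    ))
    def test_matches_membership_enumeration(self, sets):
        u, en, eh, rn, rh = sets
        # a miRNA cannot be both enriched and retained in one condition
        en, eh = en - rn, eh - rh
        comp = self.comp_with(en, eh, rn, rh, u)
        v = venn_sets(comp)
        for m in u:
            expect = {
                "enriched_both": m in en and m in eh,
                "enriched_normoxia_only": m in en and m not in eh,
                "enriched_hypoxia_only": m in eh and m not in en,
                "retained_both": m in rn and m in rh,
                "retained_normoxia_only": m in rn and m not in rh,
                "retained_hypoxia_only": m in rh and m not in rn,
            }
            for name, should in expect.items():
                assert (m in v[name]) == should
        # disjointness within each family
        assert not (v["enriched_both"] & v["enriched_normoxia_only"])
        assert not (v["enriched_both"] & v["enriched_hypoxia_only"])
        assert not (v["enriched_normoxia_only"] & v["enriched_hypoxia_only"])


def test_records_frame_columns():
    recs = [DynamicsRecord("m", "up_in_h", "no_change", "enriched_in_ev",
                           "neutral", Klass.FAVORED_LOADING.value,
                           frozenset({"favored_loading"}))]
    df = records_to_frame(recs)
    assert list(df.columns) == ["ev_direction", "cell_call", "loading_h",
                                "loading_n", "class", "flags"]
    assert df.at["m", "flags"] == "favored_loading"
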