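"""Cross-contrast classification of differential EV miRNA cargo.

Given the four contrasts of the study design — EVs vs cells within each
condition, and hypoxia vs normoxia within each compartment — this module
decides, for every miRNA differentially enriched between H-EVs and N-EVs,
whether the EV difference merely mirrors a cellular expression change
(*concurred enrichment*) or reveals selective sorting: *favored loading*
into EVs, or *retention* in the cells, in one condition.

Per condition, a miRNA is enriched in EVs when it is exclusive to EVs or has
log2FC > 1 versus cells (with the FDR gate for tested miRNAs), and retained
in the cells when exclusive to cells or log2FC < -1.  A miRNA up in H-EVs
(vs N-EVs) is then classified, in priority order:

1. concurred — also DE in the cell contrast, same direction;
2. favored_loading — not concurred, and enriched in EVs in hypoxia (covers
   both "no cell change" and opposite-direction cell calls);
3. retention — not 1-2, and retained in the cells in *normoxia* (retention
   in the opposite condition depresses the miRNA's EV level there);
4. unexplained otherwise.

The mirror rules apply to miRNAs down in H-EVs.  ``flags`` records every
mechanism that matched, so the single priority label loses no information.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diff_enrichment import Basis, ContrastResult, DECall, Direction, Status


class CompCall(str, enum.Enum):
    """Per-condition EV-vs-cell call for one miRNA."""

    ENRICHED_IN_EV = "enriched_in_ev"
    RETAINED_IN_CELL = "retained_in_cell"
    NEUTRAL = "neutral"
    ABSENT = "absent"


class Klass(str, enum.Enum):
    CONCURRED = "concurred"
    FAVORED_LOADING = "favored_loading"
    RETENTION = "retention"
    UNEXPLAINED = "unexplained"


@dataclass
class CompartmentCalls:
    """Per-miRNA enrichment/retention calls, one column pair per condition.

    ``table`` columns: call_<condition>, basis_<condition> for each condition
    present in the inputs.
    """

    table: pd.DataFrame
    conditions: list[str]

    def call(self, mirna: str, condition: str) -> str:
        return self.table.at[mirna, f"call_{condition}"]

    def enriched_set(self, condition: str) -> set[str]:
        col = self.table[f"call_{condition}"]
        return set(col.index[col == CompCall.ENRICHED_IN_EV.value])

    def retained_set(self, condition: str) -> set[str]:
        col = self.table[f"call_{condition}"]
        return set(col.index[col == CompCall.RETAINED_IN_CELL.value])


def compartment_calls(
    ev_vs_cell: dict[str, tuple[ContrastResult, DECall]],
    lfc_threshold: float = 1.0,
) -> CompartmentCalls:
    """Apply the per-condition enrichment/retention rule.

    ``ev_vs_cell`` maps condition name -> (ContrastResult, DECall) for the
    contrast oriented cells (reference, a) -> EVs (focus, b) of that
    condition.  Enriched in EVs: exclusive to EVs, or tested with
    log2FC > lfc_threshold and the quantitative DE gate passed.  Retained in
    cells: symmetric with log2FC < -lfc_threshold.  Identified in neither
    compartment -> absent.
    """
    conditions = list(ev_vs_cell)
    frames = {}
    index = None
    for cond, (result, call) in ev_vs_cell.items():
        if result.spec.group_a[0] != "cell" or result.spec.group_b[0] != "ev":
            raise ValueError(
                f"contrast {result.spec.name!r} must be oriented cell (a) -> ev (b)"
            )
        t = result.table
        if index is None:
            index = t.index
        calls = np.full(len(t), CompCall.NEUTRAL.value, dtype=object)
        basis = np.full(len(t), "none", dtype=object)

        status = t["status"].to_numpy()
        calls[status == Status.ABSENT.value] = CompCall.ABSENT.value
        # Exclusive to EVs (= group b) / to cells (= group a).
        excl_ev = status == Status.EXCLUSIVE_B.value
        excl_cell = status == Status.EXCLUSIVE_A.value
        calls[excl_ev] = CompCall.ENRICHED_IN_EV.value
        calls[excl_cell] = CompCall.RETAINED_IN_CELL.value
        basis[excl_ev | excl_cell] = "exclusive"

        tested = status == Status.TESTED.value
        de_quant = (call.table["basis"] == Basis.QUANTITATIVE.value).to_numpy()
        lfc = t["log2fc"].to_numpy()
        up = tested & de_quant & (lfc > lfc_threshold)
        down = tested & de_quant & (lfc < -lfc_threshold)
        calls[up] = CompCall.ENRICHED_IN_EV.value
        calls[down] = CompCall.RETAINED_IN_CELL.value
        basis[up | down] = "quantitative"

        frames[f"call_{cond}"] = calls
        frames[f"basis_{cond}"] = basis
    return CompartmentCalls(
        table=pd.DataFrame(frames, index=index), conditions=conditions
    )


@dataclass
class DynamicsRecord:
    mirna: str
    ev_direction: str  # up_in_h | down_in_h
    cell_call: str     # up_in_h | down_in_h | no_change | not_tested
    loading_h: str
    loading_n: str
    klass: str
    flags: frozenset[str] = field(default_factory=frozenset)


def _cell_call(de_cell: DECall, mirna: str) -> str:
    """Direction of the cell-compartment H-vs-N DE call, or no_change.

    "No change" means no DE call of either basis — including miRNAs absent
    from the cells entirely.
    """
    row = de_cell.table.loc[mirna]
    if not row["is_de"]:
        return "no_change"
    if row["direction"] == Direction.UP_IN_B.value:
        return "up_in_h"
    return "down_in_h"


def classify_dynamics(
    de_ev: DECall,
    de_cell: DECall,
    comp: CompartmentCalls,
    hypoxia: str = "hypoxia",
    normoxia: str = "normoxia",
) -> list[DynamicsRecord]:
    """Classify each EV-DE miRNA by the priority rules in the module docstring.

    ``de_ev`` / ``de_cell`` are the H-vs-N DECalls for EVs and cells, both
    oriented normoxia (a) -> hypoxia (b).
    """
    records: list[DynamicsRecord] = []
    for mirna in de_ev.table.index[de_ev.table["is_de"]]:
        direction = de_ev.table.at[mirna, "direction"]
        ev_dir = "up_in_h" if direction == Direction.UP_IN_B.value else "down_in_h"
        cell = _cell_call(de_cell, mirna)
        load_h = comp.call(mirna, hypoxia)
        load_n = comp.call(mirna, normoxia)

        # Condition with the EV excess, and its opposite.
        if ev_dir == "up_in_h":
            same_cell, excess_load, opposite_load = "up_in_h", load_h, load_n
        else:
            same_cell, excess_load, opposite_load = "down_in_h", load_n, load_h

        flags = set()
        if cell == same_cell:
            flags.add(Klass.CONCURRED.value)
        if (cell != same_cell
                and excess_load == CompCall.ENRICHED_IN_EV.value):
            flags.add(Klass.FAVORED_LOADING.value)
        if opposite_load == CompCall.RETAINED_IN_CELL.value:
            flags.add(Klass.RETENTION.value)

        for k in (Klass.CONCURRED, Klass.FAVORED_LOADING, Klass.RETENTION):
            if k.value in flags:
                klass = k.value
                break
        else:
            klass = Klass.UNEXPLAINED.value

        records.append(
            DynamicsRecord(
                mirna=mirna, ev_direction=ev_dir, cell_call=cell,
                loading_h=load_h, loading_n=load_n, klass=klass,
                flags=frozenset(flags),
            )
        )
    return records


@dataclass
class DynamicsSummary:
    n_de_ev: int
    n_concurred: int
    n_favored_loading: int
    n_retention: int
    n_unexplained: int

    @property
    def n_selective(self) -> int:
        return self.n_favored_loading + self.n_retention

    @property
    def fraction_selective(self) -> float:
        if self.n_de_ev == 0:
            return float("nan")
        return self.n_selective / self.n_de_ev

    def to_dict(self) -> dict:
        return {
            "n_de_ev": self.n_de_ev,
            "n_concurred": self.n_concurred,
            "n_favored_loading": self.n_favored_loading,
            "n_retention": self.n_retention,
            "n_unexplained": self.n_unexplained,
            "n_selective": self.n_selective,
            "fraction_selective": (None if self.n_de_ev == 0
                                   else self.fraction_selective),
        }


def summarize_dynamics(records: list[DynamicsRecord]) -> DynamicsSummary:
    counts = {k.value: 0 for k in Klass}
    for r in records:
        counts[r.klass] += 1
    return DynamicsSummary(
        n_de_ev=len(records),
        n_concurred=counts[Klass.CONCURRED.value],
        n_favored_loading=counts[Klass.FAVORED_LOADING.value],
        n_retention=counts[Klass.RETENTION.value],
        n_unexplained=counts[Klass.UNEXPLAINED.value],
    )


def records_to_frame(records: list[DynamicsRecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna": r.mirna, "ev_direction": r.ev_direction,
            "cell_call": r.cell_call, "loading_h": r.loading_h,
            "loading_n": r.loading_n, "class": r.klass,
            "flags": ";".join(sorted(r.flags)),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna", "ev_direction", "cell_call", "loading_h",
                 "loading_n", "class", "flags"],
    ).set_index("mirna")


def venn_sets(comp: CompartmentCalls,
              normoxia: str = "normoxia",
              hypoxia: str = "hypoxia") -> dict[str, set[str]]:
    """Six disjoint sets: enriched-in-EV and retained-in-cell miRNAs split
    into both-conditions / normoxia-only / hypoxia-only."""
    enr_n, enr_h = comp.enriched_set(normoxia), comp.enriched_set(hypoxia)
    ret_n, ret_h = comp.retained_set(normoxia), comp.retained_set(hypoxia)
    return {
        "enriched_both": enr_n & enr_h,
        "enriched_normoxia_only": enr_n - enr_h,
        "enriched_hypoxia_only": enr_h - enr_n,
        "retained_both": ret_n & ret_h,
        "retained_normoxia_only": ret_n - ret_h,
        "retained_hypoxia_only": ret_h - ret_n,
    }
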