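"""Synthetic miRNA count studies with planted sorting dynamics.

The generator emulates the study design the pipeline analyses: 3 donors,
each contributing a cell and an EV library under normoxia and hypoxia
(12 samples), with on the order of a hundred detected miRNAs, overdispersed
counts, condition-dependent EV-loading effects and structural absences
that produce condition-exclusive miRNAs.  Every simulated matrix comes with
its ground truth, so presence, differential enrichment and dynamics
classification are all testable without external data.

Model.  Each miRNA i has a baseline log2 abundance b_i ~ Normal(mean, sd),
each donor d a log2 random effect.  The expected relative abundance of
miRNA i in sample j is

    a_ij = 2^( b_i + d_donor(j) + cell_effect_i * [condition = hypoxia]
               + loading_effect_{i, condition(j)} * [compartment = EV] ),

zeroed in structural-zero groups and then normalized over i so that
sum_i a_ij = 1 (counts are compositional, as CPM is).  Counts are drawn
NB(mean = L_j * a_ij, variance = mean + phi * mean^2) with library size
L_j lognormal around ``lib_size_mean``.

Planted classes (effect e = ``effect_log2``):

- ``concurred_up`` / ``concurred_down``: cell_effect = +/- e, no loading
  differential — the EV change mirrors the cellular change.
- ``favored_loading_h`` / ``favored_loading_n``: loading_effect = +e in that
  condition only — EV excess beyond cellular expression.
- ``retention_h`` / ``retention_n``: loading_effect = -e in that condition —
  the miRNA is held back in the cells, depleting its EVs there.

With probability ``exclusive_fraction`` a planted effect is realized
qualitatively instead: the affected feature gets structural zeros in the
depressed group(s) (for concurred classes, both compartments of the down
condition; for retention, the depleted EV group; for favored loading the
feature is present only in the elevated EV group), which yields the
exclusivity-based calls the presence rule is designed to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cargo_dynamics import DynamicsRecord, Klass
from .io_model import CountMatrix, Group, SampleMeta

PLANTED_CLASSES = (
    "null", "concurred_up", "concurred_down",
    "favored_loading_h", "favored_loading_n",
    "retention_h", "retention_n",
)

#: Map from a planted class to the dynamics class the pipeline should call.
EXPECTED_CALL = {
    "concurred_up": Klass.CONCURRED.value,
    "concurred_down": Klass.CONCURRED.value,
    "favored_loading_h": Klass.FAVORED_LOADING.value,
    "favored_loading_n": Klass.FAVORED_LOADING.value,
    "retention_h": Klass.RETENTION.value,
    "retention_n": Klass.RETENTION.value,
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults reproduce the emulated study design."""

    n_mirnas: int = 150
    n_donors: int = 3
    lib_size_mean: float = 2e6
    lib_size_cv: float = 0.2
    dispersion: float = 0.1
    donor_sd: float = 0.25
    baseline_log2cpm: tuple[float, float] = (5.0, 2.0)
    class_counts: dict = field(default_factory=dict)
    effect_log2: float = 2.5
    exclusive_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_donors < 1:
            raise ValueError("n_mirnas and n_donors must be >= 1")
        if self.lib_size_mean <= 0 or self.lib_size_cv < 0:
            raise ValueError("invalid library-size parameters")
        if self.dispersion < 0 or self.donor_sd < 0:
            raise ValueError("dispersion and donor_sd must be >= 0")
        if not (0 <= self.exclusive_fraction <= 1):
            raise ValueError("exclusive_fraction must be in [0, 1]")
        unknown = set(self.class_counts) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        if sum(self.class_counts.values()) > self.n_mirnas:
            raise ValueError("class_counts exceed n_mirnas")


@dataclass
class SyntheticTruth:
    """Ground truth: ``table`` indexed by miRNA with planted_class,
    cell_effect_log2, loading_effect_normoxia/hypoxia, and a parallel map of
    structural-zero groups."""

    table: pd.DataFrame
    structural_zeros: dict[str, frozenset[Group]]

    def planted(self, klass: str) -> list[str]:
        col = self.table["planted_class"]
        return list(col.index[col == klass])


def _structural_zero_groups(klass: str) -> frozenset[Group]:
    """Groups zeroed when a planted effect is realized qualitatively."""
    if klass == "concurred_up":        # elevated in hypoxia -> absent in normoxia
        return frozenset({("cell", "normoxia"), ("ev", "normoxia")})
    if klass == "concurred_down":
        return frozenset({("cell", "hypoxia"), ("ev", "hypoxia")})
    if klass == "retention_h":         # depleted EV group of the condition
        return frozenset({("ev", "hypoxia")})
    if klass == "retention_n":
        return frozenset({("ev", "normoxia")})
    if klass == "favored_loading_h":   # present only in the loaded EV group
        return frozenset(
            {("cell", "normoxia"), ("cell", "hypoxia"), ("ev", "normoxia")}
        )
    if klass == "favored_loading_n":
        return frozenset(
            {("cell", "normoxia"), ("cell", "hypoxia"), ("ev", "hypoxia")}
        )
    raise ValueError(f"class {klass!r} has no qualitative realization")


def simulate(cfg: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic study (CountMatrix + SyntheticTruth), deterministically
    in ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    features = [f"syn-mir-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    donors = [f"D{d + 1}" for d in range(cfg.n_donors)]
    samples_def: list[tuple[str, str, str]] = []
    for comp in ("cell", "ev"):
        for cond in ("normoxia", "hypoxia"):
            for d in donors:
                samples_def.append((f"{d}_{comp}_{cond}", d, comp, cond))

    # Planted classes: listed features first, remainder null.
    classes = []
    for k in PLANTED_CLASSES:
        if k != "null":
            classes += [k] * cfg.class_counts.get(k, 0)
    classes += ["null"] * (cfg.n_mirnas - len(classes))

    b = rng.normal(cfg.baseline_log2cpm[0], cfg.baseline_log2cpm[1],
                   size=cfg.n_mirnas)
    donor_eff = {d: rng.normal(0.0, cfg.donor_sd) for d in donors}

    cell_eff = np.zeros(cfg.n_mirnas)
    load_eff = {"normoxia": np.zeros(cfg.n_mirnas),
                "hypoxia": np.zeros(cfg.n_mirnas)}
    zero_groups: dict[str, frozenset[Group]] = {}
    e = cfg.effect_log2
    for i, klass in enumerate(classes):
        if klass == "null":
            continue
        as_exclusive = rng.random() < cfg.exclusive_fraction
        if as_exclusive:
            zero_groups[features[i]] = _structural_zero_groups(klass)
            continue
        if klass == "concurred_up":
            cell_eff[i] = e
        elif klass == "concurred_down":
            cell_eff[i] = -e
        elif klass == "favored_loading_h":
            load_eff["hypoxia"][i] = e
        elif klass == "favored_loading_n":
            load_eff["normoxia"][i] = e
        elif klass == "retention_h":
            load_eff["hypoxia"][i] = -e
        elif klass == "retention_n":
            load_eff["normoxia"][i] = -e

    sigma = np.sqrt(np.log1p(cfg.lib_size_cv ** 2))
    mu = np.log(cfg.lib_size_mean) - sigma ** 2 / 2
    lib_sizes = np.maximum(
        1, np.round(rng.lognormal(mu, sigma, size=len(samples_def)))
    ).astype(np.int64)

    counts = np.zeros((cfg.n_mirnas, len(samples_def)), dtype=np.int64)
    for j, (sid, d, comp, cond) in enumerate(samples_def):
        log2a = b + donor_eff[d]
        if cond == "hypoxia":
            log2a = log2a + cell_eff
        if comp == "ev":
            log2a = log2a + load_eff[cond]
        a = np.exp2(log2a)
        for i, f in enumerate(features):
            if f in zero_groups and (comp, cond) in zero_groups[f]:
                a[i] = 0.0
        a = a / a.sum()
        mean = lib_sizes[j] * a
        if cfg.dispersion == 0.0:
            counts[:, j] = rng.poisson(mean)
        else:
            r = 1.0 / cfg.dispersion
            # NB(mean m, var m + phi m^2) as Gamma-Poisson mixture.
            with np.errstate(divide="ignore", invalid="ignore"):
                p = r / (r + mean)
            draw = np.where(
                mean > 0, rng.negative_binomial(r, np.where(mean > 0, p, 1.0)), 0
            )
            counts[:, j] = draw

    samples = [
        SampleMeta(sample_id=sid, donor=d, compartment=comp, condition=cond,
                   library_size=int(max(1, counts[:, j].sum())))
        for j, (sid, d, comp, cond) in enumerate(samples_def)
    ]
    matrix = CountMatrix(features=features, samples=samples, counts=counts)

    truth_table = pd.DataFrame(
        {
            "planted_class": classes,
            "cell_effect_log2": cell_eff,
            "loading_effect_normoxia": load_eff["normoxia"],
            "loading_effect_hypoxia": load_eff["hypoxia"],
            "structural_zero_groups": [
                ";".join(f"{c}_{k}" for c, k in sorted(zero_groups.get(f, ())))
                for f in features
            ],
        },
        index=pd.Index(features, name="mirna"),
    )
    return matrix, SyntheticTruth(table=truth_table, structural_zeros=zero_groups)


def truth_confusion(records: list[DynamicsRecord],
                    truth: SyntheticTruth) -> pd.DataFrame:
    """Confusion matrix planted_class x called_class over the EV-DE-called
    miRNAs in ``records``."""
    called = {r.mirna: r.klass for r in records}
    unknown = set(called) - set(truth.table.index)
    if unknown:
        raise ValueError(f"records name miRNAs absent from truth: {sorted(unknown)}")
    klasses = [k.value for k in Klass]
    mat = pd.DataFrame(0, index=pd.Index(PLANTED_CLASSES, name="planted"),
                       columns=pd.Index(klasses, name="called"), dtype=int)
    for mirna, klass in called.items():
        planted = truth.table.at[mirna, "planted_class"]
        mat.at[planted, klass] += 1
    return mat
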