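"""Two-group differential enrichment of miRNA counts.

A miRNA is differentially enriched (DE) between two groups either
qualitatively — identified by the presence rule in exactly one of the two
groups (exclusivity) — or quantitatively — identified in both and passing a
negative-binomial likelihood-ratio test with |log2FC| > 1 at FDR <= 10%
(Benjamini-Hochberg across the tested set of the contrast).

The quantitative engine is a fixed-dispersion NB model: counts_ij ~
NB(mean = L_j * mu_g, variance = mean + phi * mean^2) with one rate mu per
group under the alternative and a shared rate under the null; the LR
statistic is referred to chi-square(1).  At phi = 0 the model reduces to
Poisson and the rate MLE is the pooled-count / pooled-library ratio.
Dispersion is a method-of-moments estimate from library-size-scaled counts,
optionally shrunk toward the across-feature median.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io_model import CountMatrix, Group, PresenceTable, cpm


class Status(str, enum.Enum):
    """Presence-based partition of features within one contrast."""

    TESTED = "tested"
    EXCLUSIVE_A = "exclusive_a"
    EXCLUSIVE_B = "exclusive_b"
    ABSENT = "absent"


class Basis(str, enum.Enum):
    QUALITATIVE = "qualitative"
    QUANTITATIVE = "quantitative"
    NONE = "none"


class Direction(str, enum.Enum):
    UP_IN_B = "up_in_b"
    DOWN_IN_B = "down_in_b"
    NONE = "none"


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison; log2FC is reported as group_b over group_a."""

    name: str
    group_a: Group  # reference
    group_b: Group  # focus

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError(f"contrast {self.name!r}: groups must differ")


@dataclass(frozen=True)
class DEConfig:
    """Thresholds and model settings for the quantitative test.

    Defaults reproduce the study's DE gate: |log2FC| > 1 (strict) at
    FDR <= 10% (inclusive, so a q-value of exactly 0.10 counts as DE).
    ``pseudo_cpm`` is the pseudocount c in
    log2FC = log2((mu_b*1e6 + c) / (mu_a*1e6 + c)).
    """

    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.10
    fdr_inclusive: bool = True
    pseudo_cpm: float = 0.5
    dispersion_mode: str = "per_feature_shrunk"  # or "common"
    dispersion_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be positive")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.pseudo_cpm <= 0:
            raise ValueError("pseudo_cpm must be positive")
        if self.dispersion_mode not in ("common", "per_feature_shrunk"):
            raise ValueError(f"unknown dispersion_mode {self.dispersion_mode!r}")
        if self.dispersion_floor < 0:
            raise ValueError("dispersion_floor must be >= 0")


@dataclass
class ContrastResult:
    """Per-miRNA results of one contrast, as a DataFrame ``table`` with
    columns mirna (index), status, mean_cpm_a, mean_cpm_b, log2fc, p_value,
    q_value.  log2fc/p/q are NaN unless status is ``tested``."""

    spec: ContrastSpec
    table: pd.DataFrame


@dataclass
class DECall:
    """Per-miRNA DE decision: ``table`` with columns is_de, basis, direction."""

    spec: ContrastSpec
    table: pd.DataFrame

    @property
    def de_features(self) -> list[str]:
        return list(self.table.index[self.table["is_de"]])


# ---------------------------------------------------------------------------
# NB likelihood machinery


def _nb_loglik(counts: np.ndarray, means: np.ndarray, phi: float) -> float:
    """NB log-likelihood with variance = mean + phi*mean^2 (Poisson at phi=0).

    Zero means contribute 0 when the count is 0 and -inf otherwise.
    """
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    ll = 0.0
    pos = means > 0
    if np.any(~pos):
        if np.any(counts[~pos] > 0):
            return -np.inf
    c, m = counts[pos], means[pos]
    if len(c) == 0:
        return 0.0
    if phi == 0.0:
        ll = np.sum(c * np.log(m) - m - special.gammaln(c + 1))
    else:
        r = 1.0 / phi
        ll = np.sum(
            special.gammaln(c + r) - special.gammaln(r) - special.gammaln(c + 1)
            + r * np.log(r / (r + m)) + c * np.log(m / (r + m))
        )
    return float(ll)


def _fit_rate(counts: np.ndarray, libs: np.ndarray, phi: float) -> float:
    """MLE of the per-read rate mu with mean_j = L_j * mu and fixed phi."""
    counts = np.asarray(counts, dtype=float)
    libs = np.asarray(libs, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    pooled = total / libs.sum()
    if phi == 0.0:
        # Poisson MLE is exact: pooled counts over pooled library.
        return float(pooled)

    def negll(log_mu: float) -> float:
        return -_nb_loglik(counts, libs * np.exp(log_mu), phi)

    x0 = np.log(pooled)
    res = optimize.minimize_scalar(
        negll, bracket=(x0 - 1.0, x0, x0 + 1.0), method="brent",
        options={"xtol": 1e-12},
    )
    return float(np.exp(res.x))


def nb_lrt(counts_a: np.ndarray, counts_b: np.ndarray,
           lib_a: np.ndarray, lib_b: np.ndarray, phi: float,
           pseudo_cpm: float = 0.5) -> tuple[float, float]:
    """Likelihood-ratio test of equal per-read rates between two groups.

    Returns (log2fc, p_value) where log2fc compares group b over group a on
    the CPM scale with pseudocount ``pseudo_cpm``.  All-zero input returns
    (0.0, 1.0).
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    lib_a = np.asarray(lib_a, dtype=float)
    lib_b = np.asarray(lib_b, dtype=float)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if len(counts_a) == 0 or len(counts_b) == 0:
        raise ValueError("count vectors must be non-empty")
    if (lib_a <= 0).any() or (lib_b <= 0).any():
        raise ValueError("library sizes must be positive")

    if counts_a.sum() == 0 and counts_b.sum() == 0:
        return 0.0, 1.0

    mu_a = _fit_rate(counts_a, lib_a, phi)
    mu_b = _fit_rate(counts_b, lib_b, phi)
    all_counts = np.concatenate([counts_a, counts_b])
    all_libs = np.concatenate([lib_a, lib_b])
    mu_0 = _fit_rate(all_counts, all_libs, phi)

    ll_alt = (_nb_loglik(counts_a, lib_a * mu_a, phi)
              + _nb_loglik(counts_b, lib_b * mu_b, phi))
    ll_null = _nb_loglik(all_counts, all_libs * mu_0, phi)
    lr = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(stats.chi2.sf(lr, df=1))

    log2fc = float(np.log2((mu_b * 1e6 + pseudo_cpm) / (mu_a * 1e6 + pseudo_cpm)))
    return log2fc, p


def estimate_dispersion(m: CountMatrix, spec: ContrastSpec, cfg: DEConfig,
                        fixed_phi: float | None = None) -> np.ndarray:
    """Method-of-moments dispersion per feature from the two contrast groups.

    Counts are scaled to the mean library size, residuals are taken about
    each group's mean, and phi_i = max(floor, (s2_i - mbar_i) / mbar_i^2).
    ``common`` mode returns the median over expressed features for every
    feature; ``per_feature_shrunk`` the midpoint of the per-feature value and
    that median.  Single-replicate groups require ``fixed_phi``.
    """
    idx_a = m.group_indices(spec.group_a)
    idx_b = m.group_indices(spec.group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"contrast {spec.name!r}: empty group")
    if len(idx_a) < 2 or len(idx_b) < 2:
        if fixed_phi is None:
            raise ValueError(
                f"contrast {spec.name!r}: single-replicate group needs fixed_phi"
            )
        return np.full(len(m.features), max(fixed_phi, cfg.dispersion_floor))

    libs = m.library_sizes
    lbar = libs.mean()
    y_a = m.counts[:, idx_a] * (lbar / libs[idx_a])[None, :]
    y_b = m.counts[:, idx_b] * (lbar / libs[idx_b])[None, :]
    y = np.concatenate([y_a, y_b], axis=1)
    mbar = y.mean(axis=1)
    resid = np.concatenate(
        [y_a - y_a.mean(axis=1, keepdims=True),
         y_b - y_b.mean(axis=1, keepdims=True)], axis=1,
    )
    df = (len(idx_a) - 1) + (len(idx_b) - 1)
    s2 = (resid ** 2).sum(axis=1) / df

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mbar) / np.square(mbar)
    raw = np.where(mbar > 0, raw, 0.0)
    phi_i = np.maximum(cfg.dispersion_floor, raw)

    expressed = mbar > 0
    common = (float(np.median(phi_i[expressed])) if expressed.any()
              else cfg.dispersion_floor)
    common = max(common, cfg.dispersion_floor)
    if cfg.dispersion_mode == "common":
        return np.full(len(m.features), common)
    return (phi_i + common) / 2.0


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up), input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def run_contrast(m: CountMatrix, presence: PresenceTable, spec: ContrastSpec,
                 cfg: DEConfig | None = None,
                 fixed_phi: float | None = None) -> tuple[ContrastResult, DECall]:
    """Full DE analysis of one contrast: status partition, NB-LRT on the
    tested set, BH over exactly that set, and the combined DE call.

    miRNAs identified (presence rule) in both groups are ``tested``;
    identified in one group only are exclusive to it and called DE on the
    qualitative basis; identified in neither are ``absent`` and excluded.
    """
    cfg = cfg or DEConfig()
    idx_a = m.group_indices(spec.group_a)
    idx_b = m.group_indices(spec.group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"contrast {spec.name!r}: empty group")

    ident_a = presence.identified[spec.group_a].to_numpy()
    ident_b = presence.identified[spec.group_b].to_numpy()
    cpm_df = cpm(m)
    mean_a = cpm_df.iloc[:, idx_a].mean(axis=1).to_numpy()
    mean_b = cpm_df.iloc[:, idx_b].mean(axis=1).to_numpy()

    n = len(m.features)
    status = np.empty(n, dtype=object)
    status[ident_a & ident_b] = Status.TESTED.value
    status[ident_a & ~ident_b] = Status.EXCLUSIVE_A.value
    status[~ident_a & ident_b] = Status.EXCLUSIVE_B.value
    status[~ident_a & ~ident_b] = Status.ABSENT.value

    tested = np.flatnonzero(status == Status.TESTED.value)
    log2fc = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    qvals = np.full(n, np.nan)
    if len(tested) > 0:
        phi = estimate_dispersion(m, spec, cfg, fixed_phi=fixed_phi)
        libs = m.library_sizes
        for i in tested:
            fc, p = nb_lrt(
                m.counts[i, idx_a], m.counts[i, idx_b],
                libs[idx_a], libs[idx_b], float(phi[i]),
                pseudo_cpm=cfg.pseudo_cpm,
            )
            log2fc[i], pvals[i] = fc, p
        qvals[tested] = bh_adjust(pvals[tested])

    index = pd.Index(m.features, name="mirna")
    result = ContrastResult(
        spec=spec,
        table=pd.DataFrame(
            {
                "status": status, "mean_cpm_a": mean_a, "mean_cpm_b": mean_b,
                "log2fc": log2fc, "p_value": pvals, "q_value": qvals,
            },
            index=index,
        ),
    )

    is_de = np.zeros(n, dtype=bool)
    basis = np.full(n, Basis.NONE.value, dtype=object)
    direction = np.full(n, Direction.NONE.value, dtype=object)

    excl_b = status == Status.EXCLUSIVE_B.value
    excl_a = status == Status.EXCLUSIVE_A.value
    is_de[excl_a | excl_b] = True
    basis[excl_a | excl_b] = Basis.QUALITATIVE.value
    direction[excl_b] = Direction.UP_IN_B.value
    direction[excl_a] = Direction.DOWN_IN_B.value

    if len(tested) > 0:
        q_ok = (qvals[tested] <= cfg.fdr_threshold if cfg.fdr_inclusive
                else qvals[tested] < cfg.fdr_threshold)
        fc_ok = np.abs(log2fc[tested]) > cfg.lfc_threshold
        hits = tested[q_ok & fc_ok]
        is_de[hits] = True
        basis[hits] = Basis.QUANTITATIVE.value
        up = hits[log2fc[hits] > 0]
        down = hits[log2fc[hits] < 0]
        direction[up] = Direction.UP_IN_B.value
        direction[down] = Direction.DOWN_IN_B.value

    call = DECall(
        spec=spec,
        table=pd.DataFrame(
            {"is_de": is_de, "basis": basis, "direction": direction},
            index=index,
        ),
    )
    return result, call


def export_contrast(result: ContrastResult, call: DECall) -> pd.DataFrame:
    """Joined per-miRNA table for TSV export."""
    return result.table.join(call.table)
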