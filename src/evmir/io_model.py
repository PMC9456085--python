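"""Data model and I/O for miRNA count studies with paired cell/EV compartments.

The study design this package targets is a features x samples integer count
matrix of mature-miRNA read counts, where each sample is one donor's cells or
extracellular vesicles (EVs) cultured under normoxia or hypoxia.  Counts are
bound to a sample sheet assigning every sample a donor, a compartment and a
condition.  Normalized abundance is counts per million (CPM), and a miRNA is
"identified" in a (compartment, condition) group when enough donors of that
group detect it at a minimum supporting read count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

COMPARTMENTS = ("cell", "ev")
CONDITIONS = ("normoxia", "hypoxia")

#: A (compartment, condition) pair, e.g. ("ev", "hypoxia").
Group = tuple[str, str]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library.

    ``library_size`` is the total mapped miRNA read count L_j used for CPM;
    when not supplied it defaults to the column sum of the count matrix.
    """

    sample_id: str
    donor: str
    compartment: str
    condition: str
    library_size: int

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"sample {self.sample_id!r}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"sample {self.sample_id!r}: condition must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )
        if self.library_size < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: library_size must be >= 1, "
                f"got {self.library_size}"
            )

    @property
    def group(self) -> Group:
        return (self.compartment, self.condition)


@dataclass
class CountMatrix:
    """Non-negative integer miRNA x sample counts bound to sample metadata."""

    features: list[str]
    samples: list[SampleMeta]
    counts: np.ndarray  # int64, len(features) x len(samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at feature {self.features[bad[0]]!r}, "
                    f"sample {self.samples[bad[1]].sample_id!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at feature {self.features[bad[0]]!r}, "
                f"sample {self.samples[bad[1]].sample_id!r}"
            )
        seen: set[str] = set()
        for f in self.features:
            if f in seen:
                raise ValueError(f"duplicate feature identifier {f!r}")
            seen.add(f)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sample_id {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def library_sizes(self) -> np.ndarray:
        return np.array([s.library_size for s in self.samples], dtype=float)

    def group_indices(self, group: Group) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        return np.array(
            [j for j, s in enumerate(self.samples) if s.group == group],
            dtype=int,
        )

    def groups(self) -> list[Group]:
        """Distinct (compartment, condition) groups, in sample order."""
        out: list[Group] = []
        for s in self.samples:
            if s.group not in out:
                out.append(s.group)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.features, name="mirna"),
            columns=self.sample_ids,
        )


@dataclass(frozen=True)
class PresenceConfig:
    """Detection rule: a donor detects a miRNA when its raw count reaches
    ``min_count`` reads; a group identifies it when at least ``min_donors``
    donors detect it.  Defaults (1 read, 2 of 3 donors) match the minimum
    supporting count of the upstream miRNA quantification and the two-of-three
    donor rule of the study design."""

    min_count: int = 1
    min_donors: int | None = 2  # None -> ceil(2n/3) per group

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.min_donors is not None and self.min_donors < 1:
            raise ValueError("min_donors must be >= 1")

    def donors_required(self, n_donors: int) -> int:
        if self.min_donors is not None:
            return self.min_donors
        return math.ceil(2 * n_donors / 3)


@dataclass
class PresenceTable:
    """Per-miRNA identification calls for each (compartment, condition) group.

    ``identified`` and ``n_detected`` are DataFrames indexed by miRNA with one
    column per group (column labels are ``Group`` tuples); ``n_donors`` maps a
    group to its donor count.
    """

    identified: pd.DataFrame
    n_detected: pd.DataFrame
    n_donors: dict[Group, int]

    def is_identified(self, mirna: str, group: Group) -> bool:
        return bool(self.identified.at[mirna, group])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.identified.index)
        for g in self.identified.columns:
            tag = f"{g[0]}_{g[1]}"
            out[f"identified_{tag}"] = self.identified[g]
            out[f"n_detected_{tag}"] = self.n_detected[g]
        return out


def read_samplesheet(path: str | Path) -> list[dict]:
    """Read the TSV sample sheet (sample_id, donor, compartment, condition
    and optional library_size).  Compartment/condition are case-insensitive
    and stored lower-case; "EV" maps to "ev"."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "donor", "compartment", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        row = {
            "sample_id": r["sample_id"],
            "donor": r["donor"],
            "compartment": r["compartment"].strip().lower(),
            "condition": r["condition"].strip().lower(),
        }
        if "library_size" in df.columns and pd.notna(r.get("library_size")):
            row["library_size"] = int(r["library_size"])
        rows.append(row)
    return rows


def read_counts(counts_path: str | Path, samplesheet_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column ``mirna``, one column per sample) and
    its sample sheet into a bound :class:`CountMatrix`.

    The two files must name exactly the same samples; column order follows
    the sample sheet.  Library size defaults to the per-sample column sum
    unless the sheet supplies a ``library_size`` column.
    """
    sheet = read_samplesheet(samplesheet_path)
    df = pd.read_csv(counts_path, sep="\t", dtype=str)
    if df.columns[0] != "mirna":
        raise ValueError(
            f"counts file must have first column 'mirna', got {df.columns[0]!r}"
        )
    file_samples = list(df.columns[1:])
    sheet_samples = [r["sample_id"] for r in sheet]
    extra = set(file_samples) - set(sheet_samples)
    if extra:
        raise ValueError(
            f"counts file sample(s) absent from sample sheet: {sorted(extra)}"
        )
    absent = set(sheet_samples) - set(file_samples)
    if absent:
        raise ValueError(
            f"sample sheet sample(s) absent from counts file: {sorted(absent)}"
        )

    features = df["mirna"].tolist()
    mat = np.empty((len(features), len(sheet_samples)), dtype=np.int64)
    for j, sid in enumerate(sheet_samples):
        col = df[sid]
        for i, v in enumerate(col):
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric count {v!r} for {features[i]!r}, sample {sid!r}"
                ) from None
            if fv != int(fv):
                raise ValueError(
                    f"non-integer count {v!r} for {features[i]!r}, sample {sid!r}"
                )
            mat[i, j] = int(fv)
    if (mat < 0).any():
        i, j = np.argwhere(mat < 0)[0]
        raise ValueError(
            f"negative count for {features[i]!r}, sample {sheet_samples[j]!r}"
        )

    col_sums = mat.sum(axis=0)
    samples = []
    for j, row in enumerate(sheet):
        lib = row.get("library_size", int(col_sums[j]))
        if lib <= 0:
            raise ValueError(
                f"sample {row['sample_id']!r} has zero library size "
                "(all-zero column and no library_size supplied)"
            )
        samples.append(
            SampleMeta(
                sample_id=row["sample_id"], donor=row["donor"],
                compartment=row["compartment"], condition=row["condition"],
                library_size=int(lib),
            )
        )
    return CountMatrix(features=features, samples=samples, counts=mat)


def write_counts(m: CountMatrix, counts_path: str | Path,
                 samplesheet_path: str | Path) -> None:
    """Write the counts TSV and sample sheet in the package's standard format."""
    m.to_frame().to_csv(counts_path, sep="\t")
    rows = [
        {
            "sample_id": s.sample_id, "donor": s.donor,
            "compartment": s.compartment, "condition": s.condition,
            "library_size": s.library_size,
        }
        for s in m.samples
    ]
    pd.DataFrame(rows).to_csv(samplesheet_path, sep="\t", index=False)


def cpm(m: CountMatrix) -> pd.DataFrame:
    """Counts per million: counts(i,j) / L_j * 1e6.

    For samples whose library size equals the column sum the CPM column sums
    to exactly 1e6 (up to float rounding).
    """
    lib = m.library_sizes
    if (lib <= 0).any():
        j = int(np.argwhere(lib <= 0)[0])
        raise ValueError(f"sample {m.samples[j].sample_id!r} has zero library size")
    vals = m.counts / lib[None, :] * 1e6
    return pd.DataFrame(
        vals, index=pd.Index(m.features, name="mirna"), columns=m.sample_ids
    )


def presence_calls(m: CountMatrix, cfg: PresenceConfig | None = None) -> PresenceTable:
    """Apply the donor-level presence rule per (compartment, condition) group.

    A donor detects a miRNA when its raw count is >= ``min_count``; the group
    identifies the miRNA when at least ``min_donors`` donors detect it.  Two
    samples from the same donor in one group make donor-level detection
    ill-defined and are rejected.
    """
    cfg = cfg or PresenceConfig()
    groups = m.groups()
    n_det = {}
    n_donors = {}
    for g in groups:
        idx = m.group_indices(g)
        donors = [m.samples[j].donor for j in idx]
        if len(set(donors)) != len(donors):
            dup = next(d for d in donors if donors.count(d) > 1)
            raise ValueError(
                f"group {g} has multiple samples for donor {dup!r}; "
                "donor-level detection is ill-defined"
            )
        detected = (m.counts[:, idx] >= cfg.min_count).sum(axis=1)
        n_det[g] = detected
        n_donors[g] = len(donors)
    index = pd.Index(m.features, name="mirna")
    n_detected = pd.DataFrame(n_det, index=index)
    identified = pd.DataFrame(
        {g: n_det[g] >= cfg.donors_required(n_donors[g]) for g in groups},
        index=index,
    )
    return PresenceTable(identified=identified, n_detected=n_detected,
                         n_donors=n_donors)
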