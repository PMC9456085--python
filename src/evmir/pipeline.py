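"""End-to-end pipeline: presence -> four contrasts -> compartment calls ->
dynamics classification -> summaries -> optional target ORA.

The four contrasts of the study design are EVs vs cells within each
condition (oriented cells -> EVs) and hypoxia vs normoxia within each
compartment (oriented normoxia -> hypoxia).  The report is deterministic
given the inputs and configuration and is written as JSON (summaries) plus
one TSV per per-miRNA table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cargo_dynamics import (CompartmentCalls, DynamicsRecord, classify_dynamics,
                             compartment_calls, records_to_frame,
                             summarize_dynamics, venn_sets)
from .diff_enrichment import (ContrastResult, ContrastSpec, DECall, DEConfig,
                              export_contrast, run_contrast)
from .io_model import CountMatrix, PresenceConfig, PresenceTable, cpm, presence_calls
from .target_ora import (GeneSetCollection, hypergeom_ora, target_multiplicity,
                         top_enriched_by_cpm)

logger = logging.getLogger(__name__)

CONTRAST_SPECS = {
    "ev_vs_cell_normoxia": ContrastSpec(
        "ev_vs_cell_normoxia", ("cell", "normoxia"), ("ev", "normoxia")),
    "ev_vs_cell_hypoxia": ContrastSpec(
        "ev_vs_cell_hypoxia", ("cell", "hypoxia"), ("ev", "hypoxia")),
    "hyp_vs_norm_ev": ContrastSpec(
        "hyp_vs_norm_ev", ("ev", "normoxia"), ("ev", "hypoxia")),
    "hyp_vs_norm_cell": ContrastSpec(
        "hyp_vs_norm_cell", ("cell", "normoxia"), ("cell", "hypoxia")),
}


@dataclass
class ORAConfig:
    enabled: bool = False
    targets_gmt: str | None = None
    pathways_gmt: str | None = None
    top_k: int = 10
    condition: str = "hypoxia"
    exclude_prefixes: tuple[str, ...] = ()
    universe: str = "pathway_union"  # or "explicit" with universe_genes
    universe_genes: tuple[str, ...] = ()


@dataclass
class PipelineConfig:
    presence: PresenceConfig = field(default_factory=PresenceConfig)
    de: DEConfig = field(default_factory=DEConfig)
    ora: ORAConfig = field(default_factory=ORAConfig)
    fixed_phi: float | None = None
    seed: int = 0

    _KNOWN = {"presence", "de", "ora", "fixed_phi", "seed"}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "presence" in d:
            kwargs["presence"] = PresenceConfig(**d["presence"])
        if "de" in d:
            kwargs["de"] = DEConfig(**d["de"])
        if "ora" in d:
            ora = dict(d["ora"])
            for k in ("exclude_prefixes", "universe_genes"):
                if k in ora:
                    ora[k] = tuple(ora[k])
            kwargs["ora"] = ORAConfig(**ora)
        for k in ("fixed_phi", "seed"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "presence": {"min_count": self.presence.min_count,
                         "min_donors": self.presence.min_donors},
            "de": {
                "lfc_threshold": self.de.lfc_threshold,
                "fdr_threshold": self.de.fdr_threshold,
                "fdr_inclusive": self.de.fdr_inclusive,
                "pseudo_cpm": self.de.pseudo_cpm,
                "dispersion_mode": self.de.dispersion_mode,
                "dispersion_floor": self.de.dispersion_floor,
            },
            "ora": {
                "enabled": self.ora.enabled,
                "targets_gmt": self.ora.targets_gmt,
                "pathways_gmt": self.ora.pathways_gmt,
                "top_k": self.ora.top_k,
                "condition": self.ora.condition,
                "exclude_prefixes": list(self.ora.exclude_prefixes),
                "universe": self.ora.universe,
                "universe_genes": list(self.ora.universe_genes),
            },
            "fixed_phi": self.fixed_phi,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class StudyReport:
    config: PipelineConfig
    presence: PresenceTable
    contrasts: dict[str, tuple[ContrastResult, DECall]]
    comp: CompartmentCalls
    records: list[DynamicsRecord]
    venn: dict[str, set[str]]
    top_mirnas: list[str] | None = None
    multiplicity: dict[str, int] | None = None
    ora_table: pd.DataFrame | None = None

    def summary_dict(self) -> dict:
        summary = summarize_dynamics(self.records)
        cfg_json = json.dumps(self.config.to_dict(), sort_keys=True)
        out = {
            "provenance": {
                "package_version": __version__,
                "config": self.config.to_dict(),
                "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                "seed": self.config.seed,
            },
            "n_identified_per_group": {
                f"{g[0]}_{g[1]}": int(self.presence.identified[g].sum())
                for g in self.presence.identified.columns
            },
            "contrasts": {
                name: {
                    "n_tested": int((res.table["status"] == "tested").sum()),
                    "n_exclusive_a": int((res.table["status"] == "exclusive_a").sum()),
                    "n_exclusive_b": int((res.table["status"] == "exclusive_b").sum()),
                    "n_de": int(call.table["is_de"].sum()),
                }
                for name, (res, call) in self.contrasts.items()
            },
            "venn": {k: sorted(v) for k, v in self.venn.items()},
            "dynamics": summary.to_dict(),
        }
        if self.top_mirnas is not None:
            out["top_mirnas"] = self.top_mirnas
        self._check_consistency(out)
        return out

    def _check_consistency(self, out: dict) -> None:
        # Venn sets are disjoint-by-construction and cover the call sets.
        enr = (self.venn["enriched_both"] | self.venn["enriched_normoxia_only"]
               | self.venn["enriched_hypoxia_only"])
        assert len(enr) == (len(self.venn["enriched_both"])
                            + len(self.venn["enriched_normoxia_only"])
                            + len(self.venn["enriched_hypoxia_only"]))
        dyn = out["dynamics"]
        assert dyn["n_de_ev"] == (dyn["n_concurred"] + dyn["n_favored_loading"]
                                  + dyn["n_retention"] + dyn["n_unexplained"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2, sort_keys=True) + "\n")
        self.presence.to_frame().to_csv(outdir / "presence.tsv", sep="\t")
        for name, (res, call) in self.contrasts.items():
            export_contrast(res, call).to_csv(
                outdir / f"contrast_{name}.tsv", sep="\t")
        self.comp.table.to_csv(outdir / "compartment_calls.tsv", sep="\t")
        records_to_frame(self.records).to_csv(outdir / "dynamics.tsv", sep="\t")
        if self.ora_table is not None:
            self.ora_table.to_csv(outdir / "ora.tsv", sep="\t", index=False)
        if self.multiplicity is not None:
            pd.Series(self.multiplicity, name="n_mirnas").rename_axis(
                "gene").sort_index().to_csv(outdir / "target_multiplicity.tsv",
                                            sep="\t")


def run_pipeline(m: CountMatrix, cfg: PipelineConfig | None = None) -> StudyReport:
    """Execute the full inference chain on one count matrix."""
    cfg = cfg or PipelineConfig()
    logger.info(
        "presence rule: count >= %d in >= %s donors",
        cfg.presence.min_count, cfg.presence.min_donors,
    )
    presence = presence_calls(m, cfg.presence)

    contrasts = {}
    for name, spec in CONTRAST_SPECS.items():
        logger.info(
            "contrast %s: |log2FC| > %g, FDR %s %g",
            name, cfg.de.lfc_threshold,
            "<=" if cfg.de.fdr_inclusive else "<", cfg.de.fdr_threshold,
        )
        contrasts[name] = run_contrast(m, presence, spec, cfg.de,
                                       fixed_phi=cfg.fixed_phi)

    comp = compartment_calls(
        {
            "normoxia": contrasts["ev_vs_cell_normoxia"],
            "hypoxia": contrasts["ev_vs_cell_hypoxia"],
        },
        lfc_threshold=cfg.de.lfc_threshold,
    )
    records = classify_dynamics(
        de_ev=contrasts["hyp_vs_norm_ev"][1],
        de_cell=contrasts["hyp_vs_norm_cell"][1],
        comp=comp,
    )
    venn = venn_sets(comp)

    report = StudyReport(config=cfg, presence=presence, contrasts=contrasts,
                         comp=comp, records=records, venn=venn)

    if cfg.ora.enabled:
        if not cfg.ora.targets_gmt or not cfg.ora.pathways_gmt:
            raise ValueError("ORA enabled but targets_gmt/pathways_gmt not set")
        from .target_ora import read_gmt

        targets = read_gmt(cfg.ora.targets_gmt)
        pathways = read_gmt(cfg.ora.pathways_gmt)
        cpm_df = cpm(m)
        ev_ids = [s.sample_id for s in m.samples
                  if s.compartment == "ev" and s.condition == cfg.ora.condition]
        report.top_mirnas = top_enriched_by_cpm(
            comp, cpm_df, ev_ids, cfg.ora.condition, cfg.ora.top_k)
        report.multiplicity = target_multiplicity(report.top_mirnas, targets)
        query = set(report.multiplicity)
        universe = (set(cfg.ora.universe_genes)
                    if cfg.ora.universe == "explicit" else None)
        report.ora_table = hypergeom_ora(
            query, pathways, universe=universe,
            exclude_prefixes=cfg.ora.exclude_prefixes)
    return report
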