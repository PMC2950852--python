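"""Stage orchestration: compose -> compare -> annotate -> tree -> report.

Wires the library modules into the full analysis: per-gene and per-group
composition tables, the synonymous-mutated-site table, pairwise divergence
reports, presequence annotations and the NJ/MP trees with bootstrap
supports.  Every run echoes its full parameter set into the report so any
number in the output is regenerable from inputs + config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import codon_compare as cc
from . import phylo_saturation as ps
from . import targeting
from .seq_io import (
    CodingGene,
    MaskPolicy,
    ProteinAlignment,
    apply_mask,
    back_align,
    load_genes,
    mask_columns,
    read_fasta,
    write_fasta,
)

log = logging.getLogger("egtkit")


@dataclass
class PipelineConfig:
    fasta: str | None = None
    metadata: str | None = None
    protein_alignment: str | None = None  # aligned FASTA; optional
    stages: list[str] = field(
        default_factory=lambda: ["compose", "compare", "presequence", "tree"]
    )
    mask_drop_gap: bool = True
    mask_drop_x: bool = True
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    saturation_cutoff: float | None = None  # None -> model default (median)
    bootstrap_replicates: int = 100
    tree_methods: list[str] = field(default_factory=lambda: ["NJ-plain", "NJ-filtered"])
    sp_min_len: int = 12
    sp_max_len: int = 30
    sp_threshold: float = 1.6
    tp_st_cutoff: float = 0.20
    seed: int = 0


@dataclass
class AnalysisReport:
    config: dict
    version: str
    composition: pd.DataFrame | None = None
    group_composition: pd.DataFrame | None = None
    synonymous_sites: cc.SynonymousSiteTable | None = None
    divergence: list[dict] = field(default_factory=list)
    presequences: pd.DataFrame | None = None
    trees: dict[str, str] = field(default_factory=dict)  # method -> newick
    parsimony_informative: int | None = None
    warnings: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(
            json.dumps({"version": self.version, **self.config}, indent=2, default=str)
        )
        if self.composition is not None:
            self.composition.to_csv(outdir / "composition.tsv", sep="\t", index=False)
        if self.group_composition is not None:
            self.group_composition.to_csv(
                outdir / "group_composition.tsv", sep="\t", index=False
            )
        if self.synonymous_sites is not None:
            self.synonymous_sites.records.to_csv(
                outdir / "synonymous_sites.tsv", sep="\t", index=False
            )
            self.synonymous_sites.by_category.to_csv(
                outdir / "synonymous_site_composition.tsv", sep="\t", index=False
            )
        if self.divergence:
            pd.DataFrame(self.divergence).to_csv(
                outdir / "divergence.tsv", sep="\t", index=False
            )
        if self.presequences is not None:
            self.presequences.to_csv(outdir / "presequences.tsv", sep="\t", index=False)
        for method, newick in self.trees.items():
            (outdir / f"tree_{method}.nwk").write_text(newick)
        summary = {
            "parsimony_informative": self.parsimony_informative,
            "warnings": self.warnings,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def build_protein_alignment(genes: list[CodingGene], config: PipelineConfig) -> ProteinAlignment:
    """Use a supplied alignment, or require already-homologous equal-length
    proteins (the simulator's indel-free case)."""
    if config.protein_alignment:
        records = read_fasta(config.protein_alignment, "aa")
        return ProteinAlignment(ids=[r[0] for r in records], rows=[r[1] for r in records])
    proteins = {g.id: g.protein for g in genes}
    lengths = {len(p) for p in proteins.values()}
    if len(lengths) > 1:
        raise ValueError(
            "proteins differ in length and no protein alignment was supplied; "
            "provide --protein-alignment (multiple alignment construction is out of scope)"
        )
    return ProteinAlignment(ids=list(proteins), rows=list(proteins.values()))


def run_pipeline(config: PipelineConfig, genes: list[CodingGene] | None = None) -> AnalysisReport:
    if genes is None:
        if not config.fasta or not config.metadata:
            raise ValueError("either genes or fasta+metadata paths are required")
        genes = load_genes(config.fasta, config.metadata)
    if not genes:
        raise ValueError("empty input set")
    if not config.stages:
        raise ValueError("at least one stage must be enabled")
    report = AnalysisReport(config=asdict(config), version=__version__)

    pa = mask_columns(
        build_protein_alignment(genes, config),
        MaskPolicy(drop_gap=config.mask_drop_gap, drop_x=config.mask_drop_x),
    )
    log.info("compose: %d genes, %d/%d columns kept", len(genes),
             len(pa.kept_columns()), pa.n_columns)

    if "compose" in config.stages:
        report.composition = cc.composition_profile(genes)
        report.group_composition = cc.group_composition(report.composition)

    if "compare" in config.stages:
        ca = apply_mask(back_align(pa, genes))
        categories = {g.id: g.compartment for g in genes}
        report.synonymous_sites = cc.synonymous_site_composition(
            ca, categories, genes[0].code
        )
        by_id = {g.id: g for g in genes}
        for i, g1_id in enumerate(pa.ids):
            for g2_id in pa.ids[i + 1 :]:
                g1, g2 = by_id[g1_id], by_id[g2_id]
                pair_pa = ProteinAlignment(
                    ids=[g1_id, g2_id], rows=[pa.row(g1_id), pa.row(g2_id)]
                )
                try:
                    rep = cc.pairwise_nucleotide_divergence(g1, g2, pair_pa)
                except ValueError as exc:
                    report.warnings.append(str(exc))
                    continue
                report.divergence.append(rep.to_dict())

    if "presequence" in config.stages:
        rows = []
        sp_cfg = targeting.SignalPeptideConfig(
            min_len=config.sp_min_len,
            max_len=config.sp_max_len,
            hydrophobicity_threshold=config.sp_threshold,
        )
        for g in genes:
            try:
                ann = targeting.annotate_presequence(
                    g.protein, sp_config=sp_cfg, tp_st_cutoff=config.tp_st_cutoff
                )
            except ValueError as exc:
                report.warnings.append(f"{g.id}: {exc}")
                continue
            rows.append(
                {
                    "id": g.id,
                    "verdict": ann.verdict,
                    "cleavage_site": ann.cleavage_site,
                    "cleavage_motif": ann.cleavage_motif,
                    "sp_mean_hydrophobicity": ann.sp_mean_hydrophobicity,
                    "tp_st_fraction": ann.tp_st_fraction,
                    "tp_net_charge": ann.tp_net_charge,
                }
            )
        report.presequences = pd.DataFrame(rows)

    if "tree" in config.stages and len(genes) >= 4:
        report.parsimony_informative = ps.parsimony_informative_count(pa.masked_rows())
        model = (
            ps.lg_model(cutoff=config.saturation_cutoff)
            if config.saturation_cutoff is not None
            else ps.lg_model()
        )
        builders = {
            "NJ-plain": ps.nj_plain_builder,
            "NJ-filtered": ps.nj_filtered_builder(model),
            "MP": ps.mp_builder(),
        }
        for method in config.tree_methods:
            tree = ps.bootstrap_support(
                pa, builders[method], replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            report.trees[method] = tree.as_string(schema="newick").strip()
            log.info("tree[%s]: %s", method, report.trees[method])
    return report
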