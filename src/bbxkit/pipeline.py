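"""End-to-end orchestration: simulate/load inputs, run every analysis stage,
write TSV outputs and a machine-readable run report.

Stage order follows the data dependencies: io -> domains -> homologs ->
kaks/windows -> tree/trajectory -> cis -> expression -> qpcr.  All
randomness derives from one root seed; rerunning with the same config
reproduces the deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cis_elements import aggregate_profiles, load_motif_library, scan_promoter
from .core_io import exon_count_table, extract_promoter, write_fasta
from .domains import assign_architecture, classify_clade, compute_mw, compute_pi, scan_all
from .evolution import codon_align, kaks, sliding_window, classify_selection
from .expression import bin_matrix, group_genes, relative_expression, tissue_venn
from .homology import find_homologs
from .phylogeny import (
    architecture_characters,
    fitch_reconstruct,
    label_events,
    nj_tree,
    root_with_outgroup,
    to_newick,
)
from .simulate import SimulationConfig, make_family, make_fpkm, make_qpcr

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline thresholds in one place.

    Defaults are the study parameters: 1500 bp promoters, a 150 bp / 9 bp
    sliding window, Ka/Ks selection bins <0.3 / 0.3-1 / >1, WGD Ks bounds
    0.8-1.6, the FPKM heat-map bins, and 1000 bootstrap replicates.
    """

    seed: int = 0
    outdir: str = "bbxkit_run"
    promoter_length: int = 1500
    window_bp: int = 150
    step_bp: int = 9
    min_identity: float = 0.4
    min_coverage: float = 0.5
    wgd_ks_bounds: tuple[float, float] = (0.8, 1.6)
    recent_ks_max: float = 0.2
    expressed_threshold_fpkm: float = 1.0
    bootstrap_n: int = 1000
    stages: tuple[str, ...] = (
        "simulate", "structure", "domains", "homologs", "kaks",
        "tree", "trajectory", "cis", "express", "qpcr",
    )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "wgd_ks_bounds" in raw:
            raw["wgd_ks_bounds"] = tuple(raw["wgd_ks_bounds"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages on a simulated family; returns the report.

    Outputs land under ``config.outdir``; the report (also written as
    ``report.json``) records the package version, seed, parameters and
    per-stage record counts, and notes skipped stages.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "stages"
        },
        "stages": {},
    }
    enabled = set(config.stages)

    def skip(stage: str) -> bool:
        if stage not in enabled:
            report["stages"][stage] = {"skipped": True}
            log.info("stage %s skipped by config", stage)
            return True
        return False

    try:
        data = _stage_simulate(config, outdir, report)
        genomes = sorted(data.models)
        all_models = [m for g in genomes for m in data.models[g]]
        all_proteins = [p for g in genomes for p in data.proteins[g]]
        cds_by_gene = {
            r.id: r.seq for g in genomes for r in data.cds[g]
        }

        if not skip("structure"):
            counts, histogram = exon_count_table(all_models)
            pd.Series(counts, name="exon_count").rename_axis("gene_id").to_csv(
                outdir / "exons.tsv", sep="\t"
            )
            report["stages"]["structure"] = {
                "n_genes": len(counts),
                "exon_histogram": {str(k): v for k, v in histogram.items()},
            }

        architectures = {}
        if not skip("domains"):
            rows = []
            for prot in all_proteins:
                hits = scan_all(prot)
                arch = assign_architecture(prot.id, hits)
                classify_clade(arch)
                architectures[prot.id] = arch
                for h in hits:
                    rows.append(
                        {"protein_id": prot.id, "domain": h.domain,
                         "start": h.start, "end": h.end}
                    )
            pd.DataFrame(rows).to_csv(outdir / "domains.tsv", sep="\t", index=False)
            stats = pd.DataFrame(
                {
                    "protein_id": [p.id for p in all_proteins],
                    "clade": [architectures[p.id].clade for p in all_proteins],
                    "architecture": [
                        "-".join(architectures[p.id].code) for p in all_proteins
                    ],
                    "mw_da": [round(compute_mw(p), 2) for p in all_proteins],
                    "pi": [compute_pi(p) for p in all_proteins],
                }
            )
            stats.to_csv(outdir / "family.tsv", sep="\t", index=False)
            report["stages"]["domains"] = {
                "n_proteins": len(all_proteins),
                "n_family_members": sum(
                    1 for a in architectures.values() if a.clade != "unclassified"
                ),
            }

        pairs, aln_cache = [], {}
        if not skip("homologs"):
            a, b = genomes[0], genomes[1] if len(genomes) > 1 else genomes[0]
            pairs, aln_cache = find_homologs(
                data.proteins[a],
                data.proteins[b] if len(genomes) > 1 else [],
                genome_a=a, genome_b=b,
                min_identity=config.min_identity,
                min_coverage=config.min_coverage,
            )
            pd.DataFrame(
                [
                    {
                        "id_a": p.id_a, "id_b": p.id_b, "relation": p.relation,
                        "identity": round(aln_cache[p.key].identity, 4),
                        "score": aln_cache[p.key].score,
                    }
                    for p in pairs
                ]
            ).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
            report["stages"]["homologs"] = {
                "n_pairs": len(pairs),
                "n_orthologs": sum(1 for p in pairs if p.relation == "ortholog"),
                "n_paralogs": sum(1 for p in pairs if p.relation == "paralog"),
            }

        if not skip("kaks"):
            rows, window_rows = [], []
            for pair in pairs:
                aln = aln_cache[pair.key]
                caln = codon_align(cds_by_gene[aln.id_a], cds_by_gene[aln.id_b], aln)
                caln.pair = pair
                result = kaks(caln)
                sel_class, sel_bin = classify_selection(result.ratio)
                rows.append(
                    {
                        "id_a": pair.id_a, "id_b": pair.id_b,
                        "relation": pair.relation,
                        "ka": result.ka, "ks": result.ks, "ratio": result.ratio,
                        "selection_class": sel_class, "selection_bin": sel_bin,
                        "duplication_class": result.duplication_class,
                    }
                )
                profile = sliding_window(caln, config.window_bp, config.step_bp)
                for start, end, ka_w, ks_w, ratio_w in profile.windows:
                    window_rows.append(
                        {"id_a": pair.id_a, "id_b": pair.id_b,
                         "start_bp": start, "end_bp": end,
                         "ka": ka_w, "ks": ks_w, "ratio": ratio_w}
                    )
            kaks_df = pd.DataFrame(rows)
            kaks_df.to_csv(outdir / "kaks.tsv", sep="\t", index=False)
            pd.DataFrame(window_rows).to_csv(
                outdir / "kaks_windows.tsv", sep="\t", index=False
            )
            report["stages"]["kaks"] = {
                "n_pairs": len(rows),
                "selection_bins": (
                    kaks_df["selection_bin"].value_counts().to_dict() if rows else {}
                ),
            }

        tree = None
        if not skip("tree"):
            # pairwise-alignment Poisson distances at family scale; a
            # ready multiple alignment (and hence bootstrap resampling)
            # is outside this stage's inputs
            names = [p.id for p in all_proteins]
            n = len(names)
            mat = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    key = tuple(sorted((names[i], names[j])))
                    if key not in aln_cache:
                        from .homology import align_global

                        aln_cache[key] = align_global(all_proteins[i], all_proteins[j])
                    aln = aln_cache[key]
                    shared = [
                        (x, y)
                        for x, y in zip(aln.aligned_a, aln.aligned_b)
                        if x != "-" and y != "-"
                    ]
                    p_mis = sum(1 for x, y in shared if x != y) / len(shared)
                    mat[i, j] = mat[j, i] = -np.log(max(1.0 - p_mis, 1e-9))
            tree = nj_tree(names, mat)
            (outdir / "tree.nwk").write_text(to_newick(tree))
            report["stages"]["tree"] = {"n_taxa": n, "bootstrap": "not run (pairwise distances)"}

        if not skip("trajectory"):
            clade_v = [
                pid for pid, arch in architectures.items() if arch.clade == "V"
            ]
            if tree is None or not clade_v:
                report["stages"]["trajectory"] = {"skipped": True, "reason": "no clade V outgroup"}
            else:
                rooted = root_with_outgroup(tree, sorted(clade_v)[0])
                leaf_states = {
                    pid: architecture_characters(arch)
                    for pid, arch in architectures.items()
                }
                states, score = fitch_reconstruct(rooted, leaf_states)
                events = label_events(rooted, states)
                pd.DataFrame(
                    [
                        {"parent": e.parent, "child": e.child,
                         "character": e.character, "event": e.event}
                        for e in events
                    ]
                ).to_csv(outdir / "trajectory_events.tsv", sep="\t", index=False)
                report["stages"]["trajectory"] = {
                    "parsimony_score": score, "n_events": len(events),
                }

        if not skip("cis"):
            library = load_motif_library()
            genome_records = {g: data.genomes[g] for g in genomes}
            profiles = []
            for g in genomes:
                for model in data.models[g]:
                    promoter = extract_promoter(
                        model, genome_records[g], config.promoter_length
                    )
                    profiles.append(scan_promoter(promoter, library))
            grid, category_sums, ratios = aggregate_profiles(profiles, library)
            grid.rename_axis("gene_id").to_csv(outdir / "cis_grid.tsv", sep="\t")
            category_sums.rename_axis("category").to_csv(
                outdir / "cis_category_sums.tsv", sep="\t"
            )
            ratios.to_csv(outdir / "cis_ratios.tsv", sep="\t")
            report["stages"]["cis"] = {
                "n_promoters": len(profiles),
                "category_sums": category_sums.to_dict(),
            }

        if not skip("express"):
            sim_cfg = SimulationConfig(seed=config.seed)
            do_genes = [m.gene_id for m in data.models[genomes[0]]]
            matrix, fpkm_truth = make_fpkm(
                sim_cfg, sorted(do_genes), np.random.default_rng(config.seed + 1)
            )
            matrix.rename_axis("gene_id").to_csv(outdir / "fpkm.tsv", sep="\t")
            bin_matrix(matrix).rename_axis("gene_id").to_csv(
                outdir / "fpkm_bins.tsv", sep="\t"
            )
            groups = group_genes(matrix)
            pd.Series(groups, name="group").rename_axis("gene_id").to_csv(
                outdir / "groups.tsv", sep="\t"
            )
            venn = tissue_venn(
                matrix,
                tissues=list(matrix.columns[:4]),
                expressed_threshold=config.expressed_threshold_fpkm,
            )
            pd.DataFrame(
                [
                    {"tissues": "&".join(sorted(k)), "n_genes": v}
                    for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))
                ]
            ).to_csv(outdir / "venn.tsv", sep="\t", index=False)
            report["stages"]["express"] = {
                "n_genes": len(matrix),
                "group_sizes": pd.Series(list(groups.values()))
                .value_counts()
                .to_dict(),
            }

        if not skip("qpcr"):
            sim_cfg = SimulationConfig(seed=config.seed)
            do_genes = sorted(m.gene_id for m in data.models[genomes[0]])
            records, qpcr_truth = make_qpcr(
                sim_cfg, do_genes, np.random.default_rng(config.seed + 2)
            )
            rows = []
            for record in records:
                res = relative_expression(record)
                rows.append(
                    {
                        "gene_id": res.gene_id, "treatment": res.treatment,
                        "timepoint_h": res.timepoint,
                        "fold_change": res.fold_change,
                        "direction": res.direction,
                        "p_value": res.p_value,
                        "significance": res.significance,
                    }
                )
            pd.DataFrame(rows).to_csv(outdir / "foldchange.tsv", sep="\t", index=False)
            report["stages"]["qpcr"] = {"n_measurements": len(rows)}

    except Exception as exc:  # halt with a report naming the failing stage
        done = set(report["stages"])
        pending = [s for s in config.stages if s not in done]
        report["failed_stage"] = pending[0] if pending else "unknown"
        report["error"] = str(exc)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _stage_simulate(config: RunConfig, outdir: Path, report: dict):
    sim_cfg = SimulationConfig(seed=config.seed, promoter_length=config.promoter_length)
    data = make_family(sim_cfg)
    for genome, scaffolds in data.genomes.items():
        write_fasta(scaffolds, outdir / f"{genome}_genome.fasta")
        (outdir / f"{genome}.gff3").write_text(data.gff3[genome])
        write_fasta(data.proteins[genome], outdir / f"{genome}_proteins.faa")
        write_fasta(data.cds[genome], outdir / f"{genome}_cds.fna")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(data.truth, fh, indent=2, default=str)
    report["stages"]["simulate"] = {
        "n_genes": {g: len(m) for g, m in data.models.items()},
        "n_planted_pairs": len(data.truth["pairs"]),
    }
    return data
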