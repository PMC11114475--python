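"""Single-config orchestration: simulate -> cluster -> call -> summarize.

Stages run in dependency order on plain files in an output directory; a
stage is skipped when its outputs already exist and are newer than its
inputs, so interrupted runs resume.  A manifest (parameters, seed,
package version, input checksums) is written before the first stage, and
outputs are fully determined by the manifest plus the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .genome_features import (
    compare_feature,
    feature_table,
    gc_summary,
    group_means,
)
from .homology import assign_calls, cluster_proteins
from .io_formats import (
    GroupAssignment,
    read_fasta,
    read_gff3,
    read_gff3_calls,
    read_group_assignment,
    read_newick,
    read_orthogroups,
    write_gff3_calls,
    write_orthogroups,
)
from .kmer_core import KmerConfig, core_kmers, extract_kmers, repeat_overlap_fraction
from .lineage_sets import combination_counts, node_descendant_counts, presence_matrix
from .pseudogene_caller import CallerConfig, call_pseudogenes
from .psi_stats import StatConfig, compare_psi, compute_psi, summarize_directions
from .synthetic_data import CohortConfig, DecayParams, simulate_cohort, write_cohort

logger = logging.getLogger("symbiopsi.pipeline")


@dataclass
class PipelineConfig:
    output_dir: str
    cohort_dir: str
    seed: int = 0
    simulate: bool = True
    cohort: Dict = field(default_factory=dict)  # CohortConfig overrides
    orthogroups: Optional[str] = None  # ingest instead of clustering
    caller: Dict = field(default_factory=dict)  # CallerConfig overrides
    stats: Dict = field(default_factory=dict)  # StatConfig overrides
    kmer: Dict = field(default_factory=dict)  # KmerConfig overrides
    comparisons: List[str] = field(
        default_factory=lambda: ["Ev:S1", "Ev:S2", "Ev:S1+S2"]
    )

    def caller_config(self) -> CallerConfig:
        return CallerConfig(**self.caller)

    def stat_config(self) -> StatConfig:
        return StatConfig(**self.stats)

    def kmer_config(self) -> KmerConfig:
        return KmerConfig(**self.kmer)

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(self.cohort)
        if "decay" in kwargs:
            kwargs["decay"] = DecayParams(**kwargs["decay"])
        kwargs.setdefault("seed", self.seed)
        return CohortConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fresh(outputs: Sequence[Path], inputs: Sequence[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    newest_in = max((p.stat().st_mtime for p in inputs), default=0.0)
    return min(p.stat().st_mtime for p in outputs) >= newest_in


class Pipeline:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.output_dir)
        self.cohort_dir = Path(cfg.cohort_dir)
        self.manifest_path = self.out / "manifest.json"
        self.skipped: List[str] = []
        self.ran: List[str] = []

    # -- stage inputs ------------------------------------------------------
    def _taxa(self) -> List[str]:
        groups = read_group_assignment(self.cohort_dir / "groups.tsv")
        return list(groups.groups)

    def _cohort_files(self, taxon: str) -> Dict[str, Path]:
        d = self.cohort_dir
        return {
            "genome": d / f"{taxon}.genome.fasta",
            "gff": d / f"{taxon}.gff3",
            "proteins": d / f"{taxon}.proteins.fasta",
            "repeats": d / f"{taxon}.repeats.bed",
        }

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        marker = self.cohort_dir / "groups.tsv"
        if marker.exists():
            self._skip("simulate")
            return
        if not self.cfg.simulate:
            raise FileNotFoundError(
                f"cohort directory {self.cohort_dir} missing and simulate=false"
            )
        cohort = simulate_cohort(self.cfg.cohort_config())
        write_cohort(cohort, self.cohort_dir)
        self._done("simulate")

    def stage_cluster(self) -> None:
        out = self.out / "orthogroups.tsv"
        if self.cfg.orthogroups:
            table = read_orthogroups(self.cfg.orthogroups)
            write_orthogroups(table, out)
            self._done("cluster")
            return
        inputs = [self._cohort_files(t)["proteins"] for t in self._taxa()]
        if _fresh([out], inputs):
            self._skip("cluster")
            return
        proteomes = {
            t: read_fasta(self._cohort_files(t)["proteins"], moltype="aa")
            for t in self._taxa()
        }
        table = cluster_proteins(proteomes)
        write_orthogroups(table, out)
        self._done("cluster")

    def stage_pseudogenes(self) -> None:
        cfg = self.cfg.caller_config()
        for taxon in self._taxa():
            files = self._cohort_files(taxon)
            out_gff = self.out / f"{taxon}.pseudogenes.gff3"
            out_tsv = self.out / f"{taxon}.pseudogenes.tsv"
            inputs = [files["genome"], files["gff"], files["proteins"]]
            if _fresh([out_gff, out_tsv], inputs):
                self._skip(f"pseudogenes:{taxon}")
                continue
            genome = read_fasta(files["genome"])
            models = read_gff3(files["gff"], genome, taxon=taxon)
            proteome = read_fasta(files["proteins"], moltype="aa")
            calls = call_pseudogenes(proteome, genome, models, cfg, taxon=taxon)
            write_gff3_calls(calls, out_gff)
            rows = [
                {
                    "call_id": c.call_id,
                    "scaffold": c.location.scaffold,
                    "start": c.location.start,
                    "end": c.location.end,
                    "strand": c.strand,
                    "n_fragments": len(c.fragments),
                    "best_identity": round(c.best_identity, 6),
                    "representative_query": c.representative_query,
                }
                for c in calls
            ]
            pd.DataFrame(
                rows,
                columns=[
                    "call_id", "scaffold", "start", "end", "strand",
                    "n_fragments", "best_identity", "representative_query",
                ],
            ).to_csv(out_tsv, sep="\t", index=False)
            self._done(f"pseudogenes:{taxon}")

    def load_calls(self):
        calls = []
        for taxon in self._taxa():
            path = self.out / f"{taxon}.pseudogenes.gff3"
            for c in read_gff3_calls(path):
                c.taxon = taxon
                calls.append(c)
        return calls

    def stage_psi(self) -> None:
        table_path = self.out / "orthogroups.tsv"
        call_paths = [self.out / f"{t}.pseudogenes.gff3" for t in self._taxa()]
        outs = [
            self.out / "psi_records.tsv",
            self.out / "psi_comparisons.tsv",
            self.out / "psi_summary.tsv",
        ]
        if _fresh(outs, call_paths + [table_path]):
            self._skip("psi")
            return
        table = read_orthogroups(table_path)
        groups = read_group_assignment(self.cohort_dir / "groups.tsv")
        assignment = assign_calls(self.load_calls(), table)
        records = compute_psi(assignment, table, groups)
        pd.DataFrame(
            [
                {
                    "set_id": r.set_id,
                    "group": r.group,
                    "n_pseudo": r.n_pseudo,
                    "n_genes": r.n_genes,
                    "psi": "" if r.n_genes == 0 else round(r.psi, 6),
                }
                for r in records
            ]
        ).to_csv(outs[0], sep="\t", index=False)
        stat_cfg = self.cfg.stat_config()
        all_comparisons = []
        for spec_str in self.cfg.comparisons:
            b, a = spec_str.split(":")  # e.g. "Ev:S1" tests S1 (a) vs Ev (b)
            all_comparisons.extend(compare_psi(records, a, b, stat_cfg))
        pd.DataFrame(
            [
                {
                    "set_id": c.set_id,
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "direction": c.direction,
                    "p_value": c.p_value,
                    "n_pseudo_a": c.n_pseudo_a,
                    "n_genes_a": c.n_genes_a,
                    "n_pseudo_b": c.n_pseudo_b,
                    "n_genes_b": c.n_genes_b,
                }
                for c in all_comparisons
            ]
        ).to_csv(outs[1], sep="\t", index=False)
        summary = summarize_directions(all_comparisons)
        pd.DataFrame(
            [
                {
                    "group_a": a,
                    "group_b": b,
                    "a_gt_b": tally["a_gt_b"],
                    "b_gt_a": tally["b_gt_a"],
                    "none": tally["none"],
                }
                for (a, b), tally in summary.items()
            ]
        ).to_csv(outs[2], sep="\t", index=False)
        self._done("psi")

    def stage_features(self) -> None:
        taxa = self._taxa()
        inputs = [self._cohort_files(t)["gff"] for t in taxa]
        outs = [
            self.out / "features.tsv",
            self.out / "gc_summary.tsv",
            self.out / "feature_comparisons.tsv",
        ]
        if _fresh(outs, inputs):
            self._skip("features")
            return
        groups = read_group_assignment(self.cohort_dir / "groups.tsv")
        rows = []
        summaries = []
        for taxon in taxa:
            files = self._cohort_files(taxon)
            genome = read_fasta(files["genome"])
            models = read_gff3(files["gff"], genome, taxon=taxon)
            rows.extend(feature_table(models, genome))
            summaries.append(gc_summary(genome, models, taxon=taxon))
        pd.DataFrame(
            [
                {
                    "taxon": r.taxon,
                    "gene_id": r.gene_id,
                    "gene_length": r.gene_length,
                    "n_introns": r.n_introns,
                    "intron_lengths": ",".join(map(str, r.intron_lengths)),
                    "exon_fraction": round(r.exon_fraction, 6),
                    "intron_fraction": round(r.intron_fraction, 6),
                    "cds_gc": round(r.cds_gc, 6),
                    "intron_gc": "" if r.intron_gc != r.intron_gc else round(r.intron_gc, 6),
                }
                for r in rows
            ]
        ).to_csv(outs[0], sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "taxon": s.taxon,
                    "genome_gc": round(s.genome_gc, 6),
                    "cds_gc": round(s.cds_gc, 6),
                    "intron_gc": round(s.intron_gc, 6),
                }
                for s in summaries
            ]
        ).to_csv(outs[1], sep="\t", index=False)
        comp_rows = []
        for feature in ("gene_length", "n_introns", "intron_length", "cds_gc", "intron_gc"):
            for c in compare_feature(groups, rows, feature):
                comp_rows.append(
                    {
                        "feature": c.feature,
                        "group_a": c.group_a,
                        "group_b": c.group_b,
                        "p_value": c.p_value,
                        "n_a": c.n_a,
                        "n_b": c.n_b,
                        "method": c.method,
                    }
                )
        pd.DataFrame(comp_rows).to_csv(outs[2], sep="\t", index=False)
        self._done("features")

    def stage_kmers(self) -> None:
        taxa = self._taxa()
        inputs = [self._cohort_files(t)["genome"] for t in taxa]
        out = self.out / "kmer_report.tsv"
        if _fresh([out], inputs):
            self._skip("kmers")
            return
        cfg = self.cfg.kmer_config()
        sets = []
        genomes = {}
        for taxon in taxa:
            genome = read_fasta(self._cohort_files(taxon)["genome"])
            genomes[taxon] = genome
            sets.append(extract_kmers(genome, cfg, taxon=taxon))
        core = core_kmers(sets)
        rows = [
            {"taxon": s.taxon, "k": s.k, "distinct_kmers": len(s), "core_fraction": ""}
            for s in sets
        ]
        rows.append(
            {"taxon": "core", "k": core.k, "distinct_kmers": len(core), "core_fraction": ""}
        )
        for taxon in taxa:
            bed = self._cohort_files(taxon)["repeats"]
            if bed.exists():
                from .io_formats import read_bed

                frac = repeat_overlap_fraction(core, genomes[taxon], read_bed(bed), cfg)
                rows.append(
                    {
                        "taxon": f"core_in_repeats_{taxon}",
                        "k": core.k,
                        "distinct_kmers": len(core),
                        "core_fraction": round(frac, 6),
                    }
                )
        pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
        self._done("kmers")

    def stage_lineage_sets(self) -> None:
        table_path = self.out / "orthogroups.tsv"
        tree_path = self.cohort_dir / "tree.nwk"
        outs = [self.out / "upset_counts.tsv", self.out / "node_counts.tsv"]
        if _fresh(outs, [table_path, tree_path]):
            self._skip("lineage_sets")
            return
        table = read_orthogroups(table_path)
        groups = read_group_assignment(self.cohort_dir / "groups.tsv")
        gmat = presence_matrix(table, groups)
        combos = combination_counts(gmat)
        pd.DataFrame(
            sorted(
                (
                    {"combination": "+".join(sorted(combo)), "count": n}
                    for combo, n in combos.items()
                ),
                key=lambda r: (-r["count"], r["combination"]),
            )
        ).to_csv(outs[0], sep="\t", index=False)
        if tree_path.exists():
            tree = read_newick(tree_path)
            tmat = presence_matrix(table, None)
            node_counts, tip_exclusive = node_descendant_counts(tree, tmat)
            pd.DataFrame(
                [
                    {
                        "node": name,
                        "sets_in_descendants": n,
                        "sets_exclusive_to_tip": tip_exclusive.get(name, ""),
                    }
                    for name, n in node_counts.items()
                ]
            ).to_csv(outs[1], sep="\t", index=False)
        self._done("lineage_sets")

    # -- bookkeeping -------------------------------------------------------
    def _skip(self, name: str) -> None:
        logger.info("stage %s: up to date, skipped", name)
        self.skipped.append(name)

    def _done(self, name: str) -> None:
        logger.info("stage %s: done", name)
        self.ran.append(name)

    def write_manifest(self) -> None:
        inputs = {}
        if self.cohort_dir.exists():
            for p in sorted(self.cohort_dir.glob("*")):
                if p.is_file():
                    inputs[str(p)] = _sha256(p)
        manifest = {
            "package": "symbiopsi",
            "version": __version__,
            "seed": self.cfg.seed,
            "config": asdict(self.cfg),
            "inputs": inputs,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.out.mkdir(parents=True, exist_ok=True)
        with open(self.manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    def run(self) -> None:
        self.out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(self.out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        try:
            self.write_manifest()
            for stage in (
                self.stage_simulate,
                self.stage_cluster,
                self.stage_pseudogenes,
                self.stage_psi,
                self.stage_features,
                self.stage_kmers,
                self.stage_lineage_sets,
            ):
                name = stage.__name__.removeprefix("stage_")
                try:
                    stage()
                except Exception:
                    logger.exception("stage %s failed; partial outputs retained", name)
                    raise RuntimeError(f"pipeline stage {name!r} failed") from None
            # refresh manifest with cohort checksums now that inputs exist
            self.write_manifest()
        finally:
            logger.removeHandler(handler)
            handler.close()


def run_pipeline(cfg: PipelineConfig) -> Pipeline:
    pipe = Pipeline(cfg)
    pipe.run()
    return pipe
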