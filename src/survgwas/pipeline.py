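"""End-to-end orchestration: simulate -> QC/GWAS -> gene tests -> survival
characterization -> colocalization -> VAF -> PheWAS, with a manifest.

Every stage reads and writes only via io_formats, so a run directory is a
set of TSVs plus a JSON manifest recording versions, seeds, input checksums
and per-stage row counts. Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io_formats as io
from .gene_based import collapse, per_variant_cox, results_table, run_gene_tests
from .gwas import qc_filter, stratified_scan
from .phewas import filter_phenotypes, phewas_table, phewas_threshold, run_phewas
from .simulate import (
    GeneSpec,
    SimConfig,
    VariantSpec,
    PhenotypeSpec,
    simulate_cohort,
    simulate_coloc_region,
    simulate_gene_burden,
    simulate_phenotypes,
    simulate_read_counts,
)
from .survival import cohort_null_residuals, kaplan_meier, survcurve_table
from .vaf import summarize_read_counts, summary_table
from .variant_classes import VariantClass, build_gene_sets

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, toggles, thresholds and seeds for a pipeline run."""

    seed: int = 0
    n_subjects: int = 2_000
    stages: tuple = ("simulate", "gwas", "gene-test", "survfit", "coloc", "vaf", "phewas")
    stratum: str = "all"
    max_missing: float = 0.05
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    max_rare_maf: float = 0.01
    min_carriers: int = 10
    min_mac: int = 3
    alpha: float = 0.05
    cohort_path: str | None = None
    genotype_path: str | None = None
    genotype_format: str = "dosage_tsv"
    annotation_path: str | None = None
    readcount_path: str | None = None
    phenotype_path: str | None = None
    phenotype_meta_path: str | None = None
    coloc_a_path: str | None = None
    coloc_b_path: str | None = None
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def sim_config(self) -> SimConfig:
        base = dict(
            n_subjects=self.n_subjects,
            seed=self.seed,
            variants=[VariantSpec(maf=0.3, log_hr=0.3), VariantSpec(maf=0.2), VariantSpec(maf=0.4)],
            genes=[
                GeneSpec("GENE1", n_variants=8, carrier_freq=0.004, variant_class="LoF", log_hr=0.7),
                GeneSpec("GENE2", n_variants=6, carrier_freq=0.005, variant_class="AlphaMissense",
                         log_hr=0.0, n_nonqualifying=2),
            ],
            phenotypes=[
                PhenotypeSpec("pheno_assoc", "binary", "C91", prevalence=0.15, carrier_effect=1.0),
                PhenotypeSpec("pheno_null", "binary", "I20", prevalence=0.2),
                PhenotypeSpec("pheno_cont", "continuous", ""),
            ],
            **self.sim,
        )
        return SimConfig(**base)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> Path:
    """Execute the enabled stages into ``outdir``; returns the run directory.

    Any stage error aborts the run with the stage named
    (:class:`PipelineError`).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "sim"},
        "stages": {},
        "inputs": {},
        "outputs": {},
    }
    state: dict = {}

    def record(stage: str, **counts):
        manifest["stages"][stage] = counts

    def require_inputs(stage: str, **paths):
        for name, p in paths.items():
            if p is None:
                raise PipelineError(stage, ValueError(f"config field {name!r} is required when the "
                                                      f"simulate stage is disabled"))
            if not Path(p).exists():
                raise PipelineError(stage, FileNotFoundError(f"{name}: {p}"))
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}

    stages = tuple(config.stages)

    if "simulate" in stages:
        try:
            sim = config.sim_config()
            cohort, G, truth = simulate_cohort(sim)
            _, ann = simulate_gene_burden(sim)
            io.write_cohort(cohort, outdir / "cohort.tsv")
            io.write_dosage_tsv(G, outdir / "dosages.tsv")
            io.write_annotations(ann, outdir / "annotations.tsv")
            state.update(cohort=cohort, G=G, annotations=ann, sim=sim, truth=truth)
            record("simulate", n_subjects=len(cohort), n_variants=G.n_variants,
                   n_events=int(cohort["event"].sum()))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("simulate", exc) from exc
    elif set(stages) & {"gwas", "gene-test", "survfit", "vaf", "phewas"}:
        require_inputs("load", cohort_path=config.cohort_path, genotype_path=config.genotype_path)
        state["cohort"] = io.read_cohort(config.cohort_path)
        state["G"] = io.read_genotypes(config.genotype_path, config.genotype_format)
        if config.annotation_path:
            manifest["inputs"]["annotation_path"] = {
                "path": config.annotation_path, "sha256": _sha256(Path(config.annotation_path))
            }
            state["annotations"] = io.read_annotations(config.annotation_path)

    if "gwas" in stages:
        try:
            cohort, G = state["cohort"], state["G"]
            common = G.subset(variants=G.maf >= config.min_maf)
            Gq, report = qc_filter(common, config.max_missing, config.min_maf, config.hwe_alpha)
            scan = stratified_scan(cohort, Gq, config.stratum)
            io.write_summary_stats(scan, outdir / "gwas.tsv")
            state["scan"] = scan
            record("gwas", n_variants_in=report.n_input, n_variants_kept=report.n_kept,
                   n_tested=len(scan))
        except Exception as exc:
            raise PipelineError("gwas", exc) from exc

    if "gene-test" in stages:
        try:
            cohort, G = state["cohort"], state["G"]
            ann = state["annotations"]
            _, resid = cohort_null_residuals(cohort)
            all_sets = []
            for vc in (VariantClass.LOF, VariantClass.AM, VariantClass.REVEL):
                all_sets.extend(build_gene_sets(G, ann, vc, config.max_rare_maf, config.min_carriers))
            results = run_gene_tests(resid, G, all_sets)
            table = results_table(results)
            table.to_csv(outdir / "gene_tests.tsv", sep="\t", index=False, float_format="%.17g")
            pv_rows = []
            for gs in all_sets:
                tab, thr = per_variant_cox(cohort, gs.dosage(G), gs.variant_ids,
                                           min_mac=config.min_mac, alpha=config.alpha)
                tab.insert(0, "gene", gs.gene)
                tab.insert(1, "class", gs.variant_class.value)
                pv_rows.append(tab)
            if pv_rows:
                pd.concat(pv_rows).to_csv(outdir / "per_variant_cox.tsv", sep="\t",
                                          index=False, float_format="%.17g")
            state["gene_sets"] = all_sets
            state["gene_results"] = results
            record("gene-test", n_sets=len(all_sets))
        except Exception as exc:
            raise PipelineError("gene-test", exc) from exc

    if "survfit" in stages:
        try:
            cohort = state["cohort"]
            G = state["G"]
            curves = []
            for gs in state.get("gene_sets", []):
                carrier = collapse(gs.dosage(G))
                cs = kaplan_meier(cohort["age"], cohort["event"], carrier)
                for c in cs:
                    c.group = f"{gs.gene}:{'carrier' if c.group == 1 else 'noncarrier'}"
                curves.extend(cs)
            if not curves:
                curves = kaplan_meier(cohort["age"], cohort["event"])
            survcurve_table(curves).to_csv(outdir / "survcurves.tsv", sep="\t",
                                           index=False, float_format="%.17g")
            record("survfit", n_curves=len(curves))
        except Exception as exc:
            raise PipelineError("survfit", exc) from exc

    if "coloc" in stages:
        try:
            from .coloc import colocalize

            if config.coloc_a_path and config.coloc_b_path:
                require_inputs("coloc", coloc_a_path=config.coloc_a_path,
                               coloc_b_path=config.coloc_b_path)
                a = io.read_summary_stats(config.coloc_a_path)
                b = io.read_summary_stats(config.coloc_b_path)
            else:
                sim = state.get("sim") or config.sim_config()
                a, b, _ = simulate_coloc_region(sim)
            res = colocalize(a, b)
            pd.DataFrame([res.as_dict()]).to_csv(outdir / "coloc.tsv", sep="\t",
                                                 index=False, float_format="%.17g")
            pd.DataFrame({"variant_id": res.variant_ids, "labf_a": res.labf_a,
                          "labf_b": res.labf_b}).to_csv(outdir / "coloc_abf.tsv", sep="\t",
                                                        index=False, float_format="%.17g")
            record("coloc", n_variants=res.n_variants, pp4=res.pp4)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("coloc", exc) from exc

    if "vaf" in stages:
        try:
            if config.readcount_path:
                require_inputs("vaf", readcount_path=config.readcount_path)
                rc = io.read_read_counts(config.readcount_path)
            else:
                sim = state.get("sim") or config.sim_config()
                G = state["G"]
                ann = state["annotations"]
                rows = []
                for j, vid in enumerate(G.variant_ids):
                    if vid not in set(ann["variant_id"]):
                        continue
                    for si in np.flatnonzero(np.nan_to_num(G.dosage[:, j]) == 1):
                        rows.append({"subject_id": G.subject_ids[si], "variant_id": vid})
                carriers = pd.DataFrame(rows, columns=["subject_id", "variant_id"])
                rc = simulate_read_counts(carriers, somatic=False, config=sim)
            io.write_read_counts(rc, outdir / "read_counts.tsv")
            summaries = summarize_read_counts(rc, state["annotations"], seed=config.seed)
            summary_table(summaries).to_csv(outdir / "vaf.tsv", sep="\t",
                                            index=False, float_format="%.17g")
            record("vaf", n_records=len(rc), n_gene_summaries=len(summaries))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("vaf", exc) from exc

    if "phewas" in stages:
        try:
            cohort = state["cohort"]
            if config.phenotype_path and config.phenotype_meta_path:
                require_inputs("phewas", phenotype_path=config.phenotype_path,
                               phenotype_meta_path=config.phenotype_meta_path)
                values, meta = io.read_phenotypes(config.phenotype_path, config.phenotype_meta_path)
            else:
                sim = state.get("sim") or config.sim_config()
                gene_sets = state.get("gene_sets", [])
                if gene_sets:
                    carrier = collapse(gene_sets[0].dosage(state["G"]))
                else:
                    carrier = np.zeros(len(cohort), dtype=int)
                values, meta = simulate_phenotypes(sim, carrier)
                state["phewas_carrier"] = carrier
            values, meta = filter_phenotypes(values, meta, min_cases=min(100, max(5, len(cohort) // 50)))
            carrier = state.get("phewas_carrier")
            if carrier is None:
                gene_sets = state.get("gene_sets", [])
                carrier = collapse(gene_sets[0].dosage(state["G"])) if gene_sets else np.zeros(len(cohort), int)
            covs = cohort[["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]]
            results = run_phewas(carrier, values.reset_index(drop=True), meta, covariates=covs)
            phewas_table(results).to_csv(outdir / "phewas.tsv", sep="\t",
                                         index=False, float_format="%.17g")
            thr, disp = phewas_threshold(len(meta)) if len(meta) else (float("nan"), float("nan"))
            record("phewas", n_phenotypes=len(meta), threshold=thr, threshold_display=disp)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("phewas", exc) from exc

    for p in sorted(outdir.glob("*.tsv")):
        manifest["outputs"][p.name] = {"sha256": _sha256(p), "n_rows": sum(1 for _ in open(p)) - 1}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return outdir
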