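"""End-to-end pipeline runner: simulate -> expression -> patterns -> qtl -> integration.

``run_pipeline`` executes the stages in order from a single configuration
mapping, writes every stage's tabular output plus a JSON manifest (seed,
versions, per-stage row counts) into the output directory, and returns the
in-memory results.  The configuration either references existing input files
or contains a ``simulate`` block; given a seed the run is deterministic.
"""

from __future__ import annotations

import json
import os
import platform
from dataclasses import asdict
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, io as hio
from . import expression as expr
from . import integrate as integ
from . import patterns as pat
from . import qtlmap as qm
from . import simulate as sim


DEFAULT_QTL_PLAN = [
    # trait, chrom, position (cM), additive effect (P1 allele sign convention)
    ("DTH", "chr03", 5.0, -3.0),
    ("DTH", "chr06", 31.0, 9.0),
    ("PHT", "chr01", 95.0, 8.0),
    ("TGW", "chr05", 25.0, 1.4),
]

DEFAULT_RESIDUAL_SD = {"DTH": 8.0, "PHT": 12.0, "TGW": 2.2}


def default_config(seed: int = 0, out_dir: str = "hetqtl_run") -> dict:
    """The default scaled-down synthetic study configuration."""
    return {
        "seed": int(seed),
        "out_dir": out_dir,
        "simulate": {
            "n_genes": 240,
            "n_chromosomes": 12,
            "divergence": 0.02,
            "signature_snp_fraction": 0.25,
            "library_size": 250_000,
            "dispersion": 0.1,
            "noise_model": "negative_binomial",
            "n_lines": 266,
            "n_envs": 6,
            "qtls": [list(q) for q in DEFAULT_QTL_PLAN],
            "residual_sd": dict(DEFAULT_RESIDUAL_SD),
        },
        "patterns": {"tau": 2.0, "threshold": 4.0},
        "qtl": {
            "step": 1.0,
            "n_perm": 200,
            "alpha": 0.01,
            "max_cofactors": 5,
            "window": 10.0,
            "min_mean_lod": 5.0,
        },
    }


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _require(config: Mapping, key: str, stage: str):
    if key not in config:
        raise PipelineError(stage, KeyError(f"configuration lacks required key {key!r}"))
    return config[key]


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Any]:
    """Run the full analysis; see module docstring.

    Returns a dict with the per-stage results (reference, counts, pattern
    calls, merged QTLs, integration report, manifest ...).
    """
    seed = int(config.get("seed", 0))
    out_dir = config.get("out_dir")
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": seed,
        "versions": {
            "hetqtl": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    results: dict[str, Any] = {"manifest": manifest}
    rng = np.random.default_rng(seed)
    subseed = lambda: int(rng.integers(2**31 - 1))

    # ------------------------------------------------------------------ simulate
    if "simulate" in config:
        try:
            sc = dict(config["simulate"])
            reference = sim.generate_reference(
                n_genes=sc.get("n_genes", 240),
                n_chromosomes=sc.get("n_chromosomes", 12),
                divergence=sc.get("divergence", 0.02),
                signature_snp_fraction=sc.get("signature_snp_fraction", 0.25),
                seed=subseed(),
            )
            truth = sim.generate_inheritance_truth(
                reference.genes["gene_id"].to_list(), seed=subseed()
            )
            counts, meta, gene_of_sig = sim.simulate_tag_libraries(
                reference,
                truth,
                library_size=sc.get("library_size", 250_000),
                dispersion=sc.get("dispersion", 0.1),
                noise_model=sc.get("noise_model", "negative_binomial"),
                seed=subseed(),
            )
            # physical marker positions share the reference bp scale
            chrom_bp = [
                len(reference.chromosomes["P1"][f"chr{c + 1:02d}"])
                for c in range(sc.get("n_chromosomes", 12))
            ]
            marker_map = sim.generate_marker_map(
                markers_per_chromosome=[11] * (sc.get("n_chromosomes", 12) - 1) + [10],
                chrom_bp=chrom_bp,
                seed=subseed(),
            )
            genotypes = sim.simulate_ril_genotypes(
                marker_map, n_lines=sc.get("n_lines", 266), seed=subseed()
            )
            qtl_truth = [
                sim.QTLTruth(trait=t, chrom=c, pos_cm=p, additive_effect=a)
                for t, c, p, a in sc.get("qtls", DEFAULT_QTL_PLAN)
            ]
            phenotypes = sim.simulate_phenotypes(
                genotypes,
                marker_map,
                qtl_truth,
                n_envs=sc.get("n_envs", 6),
                residual_sd=sc.get("residual_sd", DEFAULT_RESIDUAL_SD),
                seed=subseed(),
            )
            tf, chromatin, functional = sim.generate_annotation_categories(
                reference.genes["gene_id"].to_list(), seed=subseed()
            )
            if out_dir:
                sim.write_study(
                    out_dir,
                    reference=reference,
                    counts=counts,
                    meta=meta,
                    marker_map=marker_map,
                    genotypes=genotypes,
                    phenotypes=phenotypes,
                )
                sim.emit_truth(truth, qtl_truth, out_dir)
            manifest["stages"]["simulate"] = {
                "n_genes": int(len(reference.genes)),
                "n_signatures": int(len(counts)),
                "n_libraries": int(len(meta)),
                "n_lines": int(len(genotypes)),
                "n_markers": int(len(marker_map)),
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", e) from e
        annotation = reference.genes
        match_sequences = (reference.transcripts["P1"], reference.transcripts["P2"])
    else:
        try:
            inputs = _require(config, "inputs", "load")
            counts = hio.read_count_table(_require(inputs, "counts", "load"))
            meta = hio.read_library_meta(_require(inputs, "meta", "load"))
            annotation = hio.read_gff3(_require(inputs, "gff", "load"))
            marker_map = hio.read_marker_map(_require(inputs, "map", "load"))
            genotypes = hio.read_genotypes(_require(inputs, "genotypes", "load"))
            phenotypes = hio.read_phenotypes(_require(inputs, "phenotypes", "load"))
            match_sequences = (
                hio.read_fasta(_require(inputs, "ref1", "load")),
                hio.read_fasta(_require(inputs, "ref2", "load")),
            )
            gene_of_sig = None
            tf = pd.read_csv(inputs["tf"], sep="\t") if "tf" in inputs else None
            chromatin = (
                [l.strip() for l in open(inputs["chromatin"]) if l.strip()]
                if "chromatin" in inputs
                else None
            )
            functional = (
                pd.read_csv(inputs["functional"], sep="\t") if "functional" in inputs else None
            )
            truth = None
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("load", e) from e

    # ------------------------------------------------------------------ expression
    try:
        tpm = expr.normalize_tpm(counts, meta)
        flags = expr.apply_filters(counts, tpm)
        status = expr.match_to_references(list(tpm.index), *match_sequences)
        if gene_of_sig is None:
            gene_of_sig = _signatures_to_genes(tpm.index, match_sequences, annotation)
        gene_tpm = sim.aggregate_to_genes(tpm, gene_of_sig)
        gene_means = expr.replicate_means(gene_tpm, meta)
        summary = expr.library_summary(
            counts, meta, gene_of_signature=gene_of_sig, match_status=status
        )
        manifest["stages"]["expression"] = {
            "n_signatures": int(len(tpm)),
            "n_reliable_and_significant": int((flags["reliable"] & flags["significant"]).sum()),
            "n_genes_quantified": int(len(gene_tpm)),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("expression", e) from e

    # ------------------------------------------------------------------ patterns
    try:
        pc = config.get("patterns", {})
        calls = pat.call_patterns(
            gene_means, tau=pc.get("tau", 2.0), threshold=pc.get("threshold", 4.0)
        )
        distributions = {
            t: pat.pattern_distribution(calls, t)
            for t in calls["tissue"].unique()
        }
        manifest["stages"]["patterns"] = {"n_calls": int(len(calls))}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("patterns", e) from e

    # ------------------------------------------------------------------ qtl
    try:
        qc = config.get("qtl", {})
        step = qc.get("step", 1.0)
        window = qc.get("window", 10.0)
        records: list[qm.QTLRecord] = []
        for trait in sorted(phenotypes["trait"].unique()):
            for env in sorted(phenotypes[phenotypes["trait"] == trait]["environment"].unique()):
                sub = phenotypes[
                    (phenotypes["trait"] == trait) & (phenotypes["environment"] == env)
                ].set_index("line")["value"]
                cof = qm.select_cofactors(
                    genotypes, sub, max_cofactors=qc.get("max_cofactors", 5)
                )
                profile = qm.scan(
                    genotypes, sub, marker_map, step=step, cofactors=cof,
                    window=window, trait=trait, environment=env,
                )
                thr = qm.permutation_threshold(
                    genotypes, sub, marker_map,
                    n_perm=qc.get("n_perm", 200), alpha=qc.get("alpha", 0.01),
                    seed=subseed(), step=step, cofactors=cof, window=window,
                )
                records.extend(
                    qm.call_qtls(profile, thr, marker_map, genotypes, sub, window=window)
                )
        merged = qm.aggregate_environments(records)
        selected = qm.select_by_mean_lod(merged, qc.get("min_mean_lod", 5.0))
        manifest["stages"]["qtl"] = {
            "n_records": int(len(records)),
            "n_merged": int(len(merged)),
            "n_selected": int(len(selected)),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("qtl", e) from e

    # ------------------------------------------------------------------ integration
    try:
        qtl_genes = {}
        for m in selected:
            interval = integ.marker_physical_interval(m, marker_map)
            qtl_genes[m.name] = integ.genes_in_interval(interval, annotation)
        report = integ.annotate_gene_sets(
            qtl_genes, annotation, calls, tf=tf, chromatin=chromatin, functional=functional
        )
        manifest["stages"]["integration"] = {
            "n_qtl_genes": int(len(report.table)),
            **report.tallies,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("integration", e) from e

    if out_dir:
        tpm.to_csv(os.path.join(out_dir, "tpm.tsv"), sep="\t", index_label="signature")
        flags.to_csv(os.path.join(out_dir, "filters.tsv"), sep="\t", index_label="signature")
        summary.to_csv(os.path.join(out_dir, "library_summary.tsv"), sep="\t")
        calls.to_csv(os.path.join(out_dir, "pattern_calls.tsv"), sep="\t", index=False)
        qm.merged_to_frame(merged).to_csv(
            os.path.join(out_dir, "merged_qtls.tsv"), sep="\t", index=False
        )
        report.table.to_csv(os.path.join(out_dir, "integration.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    results.update(
        {
            "counts": counts,
            "meta": meta,
            "tpm": tpm,
            "flags": flags,
            "match_status": status,
            "gene_means": gene_means,
            "library_summary": summary,
            "pattern_calls": calls,
            "pattern_distributions": distributions,
            "qtl_records": records,
            "merged_qtls": merged,
            "selected_qtls": selected,
            "integration": report,
            "marker_map": marker_map,
            "genotypes": genotypes,
            "phenotypes": phenotypes,
            "annotation": annotation,
        }
    )
    if "simulate" in config:
        results["truth"] = truth
        results["qtl_truth"] = qtl_truth
        results["reference"] = reference
    return results


def _signatures_to_genes(signatures, match_sequences, annotation) -> pd.Series:
    """Map signatures to genes by exact substring search in parental transcripts."""
    p1, p2 = match_sequences
    out = {}
    for sig in signatures:
        hit = None
        for book in (p1, p2):
            for gene_id, seq in book.items():
                if sig in seq:
                    hit = gene_id
                    break
            if hit:
                break
        out[sig] = hit
    return pd.Series(out, name="gene_id")
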