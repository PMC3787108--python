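"""End-to-end orchestration: filters -> O/E -> mixture -> classes -> GO enrichment.

Runs the full analysis on either user-supplied FASTA + annotation TSV or
a simulated dataset, writing per-stage artifacts (each stage re-reads
only the previous stage's files, so any stage can be resumed) and a
versioned summary JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from cpgoe import composition, enrichment, mixture, seqio, simulate

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of (``fasta`` + ``annotation``) or ``preset`` must be
    set; ``preset`` simulates a dataset under a shipped species mixture.
    """

    outdir: str = "cpgoe_out"
    fasta: str | None = None
    annotation: str | None = None
    preset: str | None = None
    n_genes: int = 20_000
    seq_length: int = 999
    min_length: int = 300
    taxa: tuple[str, ...] = ("insect",)
    dedup: bool = True
    dinucleotides: tuple[str, ...] = ("CG", "TG", "CA")
    restarts: int = 5
    tol: float = 1e-8
    alpha: float = 0.05
    max_oe: float | None = None
    seed: int = 0

    def __post_init__(self):
        has_input = self.fasta is not None and self.annotation is not None
        has_preset = self.preset is not None
        if has_input == has_preset:
            raise ValueError(
                "exactly one of (fasta + annotation) or a simulate preset must be set"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("taxa", "dinucleotides"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the summary dictionary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": cfg.seed, "stages": {}}

    # stage 0: obtain input data
    if cfg.preset is not None:
        sim_cfg = simulate.SimConfig.from_preset(
            cfg.preset,
            n_genes=cfg.n_genes,
            seq_length=cfg.seq_length,
            rng_seed=cfg.seed,
        )
        sim = simulate.generate_dataset(sim_cfg)
        paths = simulate.write_dataset(sim, out / "simulated")
        fasta_path, annot_path = paths["fasta"], paths["annotation"]
        summary["stages"]["simulate"] = {
            "n_genes": sim_cfg.n_genes,
            "seq_length": sim_cfg.seq_length,
            "mixture": list(sim_cfg.mixture),
            "preset": cfg.preset,
        }
    else:
        fasta_path, annot_path = Path(cfg.fasta), Path(cfg.annotation)

    records = seqio.read_fasta(fasta_path)
    annot = seqio.read_annotation(annot_path)
    records = seqio.join_annotation(records, annot)
    summary["stages"]["input"] = {"n_records": len(records)}

    # stage 1: filters
    fcfg = seqio.FilterConfig(
        min_length=cfg.min_length,
        allowed_taxon_labels=frozenset(cfg.taxa),
        dedup_per_group=cfg.dedup,
        rng_seed=cfg.seed,
    )
    kept, log = seqio.filter_report(records, fcfg)
    seqio.write_fasta(kept, out / "filtered.fasta")
    log.to_csv(out / "filter_log.tsv", sep="\t", index=False)
    assert int(log.shape[0]) == len(records), "dropped + kept must equal input count"
    summary["stages"]["filter"] = {
        "n_in": len(records),
        "n_kept": len(kept),
        "n_dropped": len(records) - len(kept),
    }

    # stage 2: dinucleotide O/E
    table = composition.oe_table(kept, cfg.dinucleotides)
    table.to_csv(out / "oe.tsv", sep="\t", index=False, na_rep="")
    cpg = table[table["dinucleotide"] == "CpG"].copy()
    n_undefined = int(cpg["oe"].isna().sum())
    if len(cpg) and n_undefined / len(cpg) > 0.5:
        logger.warning("more than half of CpG O/E values are undefined")
    cpg = cpg.dropna(subset=["oe"])
    if cfg.max_oe is not None:
        cpg = cpg[cpg["oe"] <= cfg.max_oe]
    summary["stages"]["composition"] = {
        "n_genes": int(len(cpg)),
        "n_undefined": n_undefined,
    }

    # stage 3: mixture fits, bimodality LRT, intersection threshold
    values = cpg["oe"].to_numpy()
    fit1 = mixture.fit_mixture(values, k=1)
    fit2 = mixture.fit_mixture(
        values, k=2, seed=cfg.seed, restarts=cfg.restarts, tol=cfg.tol
    )
    test = mixture.lrt_bimodality(fit1, fit2)
    thr = mixture.intersection_threshold(fit2)
    fit_report = {
        "k1": {"mean": fit1.means[0], "sd": fit1.sds[0], "loglik": fit1.loglik},
        "k2": {
            "weights": list(fit2.weights),
            "means": list(fit2.means),
            "sds": list(fit2.sds),
            "loglik": fit2.loglik,
            "converged": fit2.converged,
            "n_iter": fit2.n_iter,
        },
        "g2": test.g2,
        "df": test.df,
        "p": test.p,
        "x_star": thr.x_star,
        "threshold_method": thr.method,
        "n": fit2.n,
        "seed": cfg.seed,
    }
    (out / "fit.json").write_text(json.dumps(fit_report, indent=2))
    summary["stages"]["mixture"] = fit_report

    # stage 4: classification
    classified = enrichment.classify(cpg, thr.x_star)
    cls_df = cpg[["gene_id", "oe"]].copy()
    cls_df["cls"] = [g.cls for g in classified]
    cls_df.to_csv(out / "classes.tsv", sep="\t", index=False)
    n_low = sum(1 for g in classified if g.cls == "low")
    summary["stages"]["classify"] = {
        "n_low": n_low,
        "n_high": len(classified) - n_low,
        "x_star": thr.x_star,
    }

    # stage 5: GO enrichment
    go_map = {rec.gene_id: rec.go_terms for rec in kept}
    rows = enrichment.enrich(classified, go_map, alpha=cfg.alpha)
    enrichment.enrichment_table(rows).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )
    sig = [r for r in rows if r.significant]
    summary["stages"]["enrich"] = {
        "n_terms": len(rows),
        "n_significant": len(sig),
        "significant": [
            {"go_id": r.go_id, "category": r.category, "enriched_in": r.enriched_in, "q": r.q}
            for r in sorted(sig, key=lambda r: r.q)
        ],
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
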