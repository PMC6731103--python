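"""End-to-end orchestration of the driver-discovery workflow.

Stages run strictly in order, each consuming files written by the previous
one, so any stage can be re-run in isolation with identical results:

1. ``dose``        - 4PL fits, IC50/IC25 per line
2. ``de``          - TMM + exact NB test per line, DE filter
3. ``network``     - pre/post/consensus TOMs, modules, condition labels
4. ``drivers``     - modulators, mediators, query signature
5. ``connectivity``- weighted-KS scores, like/contrary emulators
6. ``synergy``     - combination index table, standalone cytotoxicity, summary

A run manifest (config echo, package version, seed, per-stage counts) is
written as sorted JSON; re-running with the same config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import classify_emulators, score_perturbations
from .dose_response import fit_panel
from .drivers import build_signature, call_mediators, call_modulators
from .expression import CountMatrix, cpm, de_filter, de_test, tmm_norm_factors
from .io import read_counts_tsv, read_gct, read_matrix_tsv, read_viability_csv
from .network import adjacency_tom, compare_conditions, consensus_tom, detect_modules, soft_power
from .synergy import evaluate_combinations, standalone_cytotoxicity, summarize_panel
from .synthetic import GeneratorConfig, generate_bundle, write_bundle

logger = logging.getLogger("txdrivers")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class Thresholds:
    fc: float = 2.0
    fdr: float = 0.05
    r: float = 0.5
    p: float = 0.05
    essentiality_min_lines: int = 6
    signature_k: int = 150
    signature_min_lines: int = 3
    tau: float = 0.9
    additive_band: float = 0.1
    dispersion: float | str = "auto"


@dataclass
class NetworkParams:
    beta: int | str = 6  # classic unsigned default; "auto" = scale-free criterion
    top_n_genes: int | None = 2000  # network restricted to most variable genes
    target_r2: float = 0.8
    cut_height: float = 0.6
    min_size: int = 30
    signed: bool = False
    scale_quantile: float = 0.95
    jaccard_threshold: float = 0.5


@dataclass
class SyntheticBlock:
    n_lines: int = 11
    n_genes: int = 5000
    nb_dispersion: float = 0.05
    expression_noise_sd: float = 0.3
    viability_noise_sd: float = 2.0
    replicates: int = 3
    deterministic: bool = False  # noiseless limit: counts are rounded means
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides


@dataclass
class PipelineConfig:
    """Validated configuration: exactly one of ``inputs`` / ``synthetic``."""

    inputs: dict | None = None  # paths: counts_pre, counts_post, viability_single,
    #                             viability_combo, essentiality, reference
    synthetic: SyntheticBlock | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    network: NetworkParams = field(default_factory=NetworkParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("config must provide exactly one of 'inputs' or 'synthetic'")
        if not (0 < self.thresholds.fdr <= 1 and 0 < self.thresholds.p <= 1):
            raise ValueError("fdr and p thresholds must lie in (0, 1]")
        if not 0 < self.thresholds.tau <= 1:
            raise ValueError("tau must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {"seed": int(raw.get("seed", 0))}
        if "inputs" in raw and raw["inputs"] is not None:
            kwargs["inputs"] = dict(raw["inputs"])
        if "synthetic" in raw and raw["synthetic"] is not None:
            kwargs["synthetic"] = SyntheticBlock(**raw["synthetic"])
        if "thresholds" in raw:
            kwargs["thresholds"] = Thresholds(**raw["thresholds"])
        if "network" in raw:
            kwargs["network"] = NetworkParams(**raw["network"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _required_inputs(paths: dict, keys: tuple[str, ...], stage: str) -> None:
    missing = [k for k in keys if k not in paths or not Path(paths[k]).exists()]
    if missing:
        raise FileNotFoundError(f"stage {stage!r}: missing input file(s) {missing}")


def _line_mean_logcpm(cm: CountMatrix, condition: str) -> pd.DataFrame:
    """Genes x lines log2 CPM (prior 1), replicate-averaged, one condition."""
    factors = tmm_norm_factors(cm)
    log = cpm(cm, factors=factors, log=True, prior_count=1.0)
    meta = cm.samples[cm.samples["condition"] == condition]
    cols = {}
    for line, grp in meta.groupby("line", sort=True):
        cols[line] = log[grp["sample_id"].tolist()].mean(axis=1)
    return pd.DataFrame(cols)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    t0 = time.time()

    def stage_done(name: str, counts: dict) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s done in %.1fs: %s", name, time.time() - t0, counts)

    # -- stage 0: resolve inputs (optionally generating the synthetic bundle)
    try:
        if config.synthetic is not None:
            blk = config.synthetic
            gen_cfg = GeneratorConfig(**blk.generator)
            bundle = generate_bundle(
                n_lines=blk.n_lines,
                n_genes=blk.n_genes,
                config=gen_cfg,
                seed=config.seed,
                nb_dispersion=blk.nb_dispersion,
                expression_noise_sd=blk.expression_noise_sd,
                viability_noise_sd=blk.viability_noise_sd,
                replicates=blk.replicates,
                deterministic=blk.deterministic,
            )
            paths = {k: str(v) for k, v in write_bundle(bundle, outdir / "inputs").items()}
            stage_done("simulate", {"n_lines": blk.n_lines, "n_genes": blk.n_genes})
        else:
            paths = dict(config.inputs or {})
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # -- stage 1: dose-response
    try:
        _required_inputs(paths, ("viability_single",), "dose")
        via_single = read_viability_csv(paths["viability_single"])
        fits = fit_panel(via_single)
        fits.to_csv(outdir / "dose_fits.csv", index=False)
        ic50 = fits.set_index("line")["ic50_uM"]
        stage_done("dose", {"n_lines_fit": int(fits["converged"].sum())})
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'dose' failed: {exc}") from exc

    # -- stage 2: differential expression
    try:
        _required_inputs(paths, ("counts_pre", "counts_post"), "de")
        pre = read_counts_tsv(paths["counts_pre"])
        post = read_counts_tsv(paths["counts_post"])
        cm = CountMatrix.from_frame(pd.concat([pre, post], axis=1))
        lines_both = sorted(
            set(cm.samples.loc[cm.samples["condition"] == "pre", "line"])
            & set(cm.samples.loc[cm.samples["condition"] == "post", "line"])
        )
        de_tables: dict[str, pd.DataFrame] = {}
        long_rows = []
        for line in lines_both:
            tbl = de_test(cm, line, dispersion=config.thresholds.dispersion)
            de_tables[line] = tbl
            tbl.to_csv(outdir / f"de_{line}.tsv", sep="\t", index=False)
            long_rows.append(tbl.assign(line=line))
        pd.concat(long_rows, ignore_index=True).to_csv(
            outdir / "de_all_lines.tsv", sep="\t", index=False
        )
        de_sets = {
            line: de_filter(tbl, config.thresholds.fc, config.thresholds.fdr)
            for line, tbl in de_tables.items()
        }
        stage_done(
            "de",
            {
                "n_lines_tested": len(lines_both),
                "n_de_calls": int(sum(len(s) for s in de_sets.values())),
            },
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'de' failed: {exc}") from exc

    # -- stage 3: co-expression networks
    try:
        expr_pre = _line_mean_logcpm(cm, "pre")
        expr_post = _line_mean_logcpm(cm, "post")
        np_ = config.network
        if np_.top_n_genes is not None and np_.top_n_genes < len(expr_pre):
            # with ~11 samples, spurious correlations among thousands of flat
            # genes swamp TOM connectivity; keep the most variable genes
            var = (expr_pre.var(axis=1) + expr_post.var(axis=1)) / 2
            keep = var.nlargest(np_.top_n_genes).index
            expr_pre, expr_post = expr_pre.loc[keep], expr_post.loc[keep]
        if np_.beta == "auto":
            beta, _reached = soft_power(
                expr_pre, target_r2=np_.target_r2, signed=np_.signed
            )
        else:
            beta = int(np_.beta)
        net_pre = adjacency_tom(expr_pre, beta, signed=np_.signed, condition="pre")
        net_post = adjacency_tom(expr_post, beta, signed=np_.signed, condition="post")
        net_cons = consensus_tom(net_pre, net_post, scale_quantile=np_.scale_quantile)
        mods = {
            name: detect_modules(net, cut_height=np_.cut_height, min_size=np_.min_size)
            for name, net in (("pre", net_pre), ("post", net_post), ("consensus", net_cons))
        }
        comparison = compare_conditions(
            mods["pre"], mods["post"], mods["consensus"], np_.jaccard_threshold
        )
        rows = [
            {"gene_id": g, "condition_label": lab, "module_id": ""}
            for g, lab in sorted(comparison.gene_labels.items())
        ]
        member = {}
        for name in ("pre", "post", "consensus"):
            for mid, genes in mods[name].modules:
                for g in genes:
                    member.setdefault(g, f"{name}:{mid}")
        for r in rows:
            r["module_id"] = member.get(r["gene_id"], "")
        pd.DataFrame(rows, columns=["gene_id", "condition_label", "module_id"]).to_csv(
            outdir / "gene_condition_labels.tsv", sep="\t", index=False
        )
        unaffected_genes = {
            g for g, lab in comparison.gene_labels.items() if lab == "unaffected"
        }
        stage_done(
            "network",
            {
                "beta": int(beta),
                "n_modules_pre": len(mods["pre"].modules),
                "n_modules_post": len(mods["post"].modules),
                "n_modules_consensus": len(mods["consensus"].modules),
                "n_unaffected_genes": len(unaffected_genes),
                "n_pre_only_modules": len(comparison.pre_only_modules),
                "n_post_only_modules": len(comparison.post_only_modules),
            },
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'network' failed: {exc}") from exc

    # -- stage 4: driver classification
    try:
        _required_inputs(paths, ("essentiality",), "drivers")
        ess = read_matrix_tsv(paths["essentiality"])
        modulators = call_modulators(
            expr_pre,
            ic50,
            unaffected_genes,
            r_threshold=config.thresholds.r,
            p_threshold=config.thresholds.p,
        )
        mediators = call_mediators(
            de_sets, ess, essentiality_min_lines=config.thresholds.essentiality_min_lines
        )
        signature = build_signature(
            de_tables,
            k=config.thresholds.signature_k,
            min_lines=config.thresholds.signature_min_lines,
            fc_threshold=config.thresholds.fc,
            fdr_threshold=config.thresholds.fdr,
        )
        pd.DataFrame(
            [{"gene_id": m.gene_id, "r": m.pearson_r, "p": m.p_value, "label": m.label}
             for m in modulators]
        ).to_csv(outdir / "modulators.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene_id": m.gene_id,
                    "n_essential": m.n_lines_essential,
                    "n_de": m.n_lines_de,
                    "directions": ";".join(f"{l}:{d}" for l, d in sorted(m.directions.items())),
                }
                for m in mediators
            ]
        ).to_csv(outdir / "mediators.tsv", sep="\t", index=False)
        signature.to_gmt(outdir / "signature.gmt")
        catalog = {
            "modulators": {
                "assisting": sorted(m.gene_id for m in modulators if m.label == "assisting"),
                "impeding": sorted(m.gene_id for m in modulators if m.label == "impeding"),
            },
            "mediators": sorted(m.gene_id for m in mediators),
            "signature": {"up": signature.up_genes, "down": signature.down_genes},
        }
        with open(outdir / "driver_catalog.json", "w") as fh:
            json.dump(catalog, fh, indent=1, sort_keys=True)
        stage_done(
            "drivers",
            {
                "n_assisting": len(catalog["modulators"]["assisting"]),
                "n_impeding": len(catalog["modulators"]["impeding"]),
                "n_mediators": len(mediators),
                "signature_up": len(signature.up_genes),
                "signature_down": len(signature.down_genes),
            },
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'drivers' failed: {exc}") from exc

    # -- stage 5: connectivity / emulators
    try:
        _required_inputs(paths, ("reference",), "connectivity")
        reference = read_gct(paths["reference"])
        scores = classify_emulators(
            score_perturbations(signature, reference), tau=config.thresholds.tau
        )
        scores.to_csv(outdir / "connectivity_scores.tsv", sep="\t", index=False)
        stage_done(
            "connectivity",
            {
                "n_like": int((scores["class"] == "like").sum()),
                "n_contrary": int((scores["class"] == "contrary").sum()),
                "n_scored": len(scores),
            },
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'connectivity' failed: {exc}") from exc

    # -- stage 6: synergy
    try:
        _required_inputs(paths, ("viability_combo",), "synergy")
        via_combo = read_viability_csv(paths["viability_combo"])
        combos = evaluate_combinations(
            via_combo, additive_band=config.thresholds.additive_band, seed=config.seed
        )
        combos.to_csv(outdir / "combinations.csv", index=False)
        cytotox = standalone_cytotoxicity(via_combo)
        cytotox.to_csv(outdir / "standalone_cytotoxicity.csv", index=False)
        summarize_panel(combos, cytotox).to_csv(outdir / "driver_summary.csv", index=False)
        stage_done(
            "synergy",
            {
                "n_combinations": len(combos),
                "n_synergy": int((combos["ci_class"] == "synergy").sum()),
                "n_additive": int((combos["ci_class"] == "additive").sum()),
                "n_antagonism": int((combos["ci_class"] == "antagonism").sum()),
                "n_cytotoxic_calls": int(cytotox["significant"].sum()) if len(cytotox) else 0,
            },
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'synergy' failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
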