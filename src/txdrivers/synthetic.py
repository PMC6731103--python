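"""Synthetic panel generator with planted, fully known ground truth.

Emulates the five inputs of the driver-discovery pipeline for a panel of
drug-treated cancer cell lines:

* paired pre/post-treatment RNA-seq count matrices with planted
  block-correlated modules (persistent, pre-only or post-only),
  sensitivity-correlated modulator genes and post-treatment fold changes for
  mediator genes;
* single-agent dose-viability tables following planted four-parameter
  logistic curves, plus combination tables with planted interaction classes;
* a DEMETER-style essentiality matrix with mediators essential in a planted
  number of lines;
* a perturbation-signature reference (GCT) with planted signature-concordant
  (*like*), anti-concordant (*contrary*) and null columns.

Counts follow a negative-binomial observation model with variance
``mu + phi * mu**2`` over a latent log2 mean; ``phi = 0`` degenerates to
Poisson.  Library sizes are drawn log-normal so TMM normalisation has real
work to do.  All randomness flows from one integer seed: convenience
wrappers split it with :class:`numpy.random.SeedSequence` into one child
stream per data type, in a fixed documented order (panel, expression,
viability, essentiality, reference).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import four_pl
from .io import (
    write_counts_tsv,
    write_gct,
    write_matrix_tsv,
    write_viability_csv,
)

__all__ = [
    "GeneratorConfig",
    "ComboSpec",
    "PanelTruth",
    "SyntheticBundle",
    "generate_panel",
    "latent_log2_expression",
    "generate_expression",
    "generate_viability",
    "generate_essentiality",
    "generate_reference",
    "generate_bundle",
    "write_bundle",
]

#: 12-point etoposide dose grid (uM) used by the emulated viability assay.
DEFAULT_CONCENTRATIONS = (0.02, 0.05, 0.1, 0.2, 0.37, 0.78, 1.56, 3.13, 6.25, 12.5, 25.0, 50.0)

_PERSISTENCE = ("persistent", "pre_only", "post_only")


@dataclass
class ComboSpec:
    """Planted combination: inhibitor effect and interaction class."""

    inhibitor: str
    effect: float  # fractional single-agent effect of the inhibitor
    interaction: str  # "synergy" | "additive" | "antagonism"
    ci_target: float | None = None  # defaults: 0.6 / 1.0 / 1.5

    def resolved_ci(self) -> float:
        if self.ci_target is not None:
            return self.ci_target
        return {"synergy": 0.6, "additive": 1.0, "antagonism": 1.5}[self.interaction]


DEFAULT_COMBOS = (
    ComboSpec("inhA", 0.30, "synergy"),
    ComboSpec("inhB", 0.30, "additive"),
    ComboSpec("inhC", 0.30, "antagonism"),
)


@dataclass
class GeneratorConfig:
    """Planted study conditions for the synthetic panel.

    Defaults mirror the emulated study: an 11-line panel whose IC50 values
    span 0.3-99 uM, predominantly induced post-treatment fold changes (81%),
    mediators essential in >= 6 lines, and enough consistently regulated
    genes to fill a 150 up / 150 down query signature.
    """

    # dose-response truth
    ic50_min: float = 0.3
    ic50_max: float = 99.0
    hill_range: tuple[float, float] = (0.8, 2.0)
    top: float = 100.0
    bottom: float = 0.0
    # co-expression blocks
    n_persistent_modules: int = 4
    n_pre_only_modules: int = 1
    n_post_only_modules: int = 1
    module_size: int = 50
    # modulators (a sensitivity-correlated co-expression cluster of their own;
    # impeding-heavy split mirroring the emulated study's 71/909 ratio)
    n_assisting: int = 10
    n_impeding: int = 30
    modulator_slope: float = 1.0
    # mediators and signature-only DE genes
    n_mediators: int = 30
    n_de_only: int = 1000
    mediator_lfc_range: tuple[float, float] = (1.5, 3.0)
    induction_fraction: float = 0.81
    de_min_lines: int = 3
    mediator_essential_lines_range: tuple[int, int] = (6, 9)
    background_essential_max_lines: int = 3
    # emulator reference
    n_like: int = 3
    n_contrary: int = 3
    n_null: int = 10
    # observation model
    base_log2_mean: float = 6.64  # about 100 counts
    base_log2_sd: float = 0.5
    lib_size_log_sd: float = 0.2

    def n_planted_genes(self) -> int:
        n_blocks = self.n_persistent_modules + self.n_pre_only_modules + self.n_post_only_modules
        return (
            n_blocks * self.module_size
            + self.n_assisting
            + self.n_impeding
            + self.n_mediators
            + self.n_de_only
        )


@dataclass
class PanelTruth:
    """Everything the generator planted, keyed by the same identifiers the
    pipeline sees."""

    line_names: list[str]
    gene_names: list[str]
    ic50_true: pd.Series
    hill_true: pd.Series
    top_true: pd.Series
    bottom_true: pd.Series
    essential_genes: dict[str, set[str]]
    modulator_genes: dict[str, int]  # gene -> +1 (assisting) / -1 (impeding)
    mediator_genes: dict[str, dict[str, float]]  # gene -> line -> log2 FC
    de_only_genes: dict[str, dict[str, float]]  # same structure, no essentiality
    module_assignment: dict[str, tuple[str, str]]  # gene -> (block id, persistence)
    emulator_perturbations: dict[str, str]  # perturbation -> like/contrary/null
    seed: int
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if (self.ic50_true <= 0).any():
            raise ValueError("planted IC50 values must be positive")
        overlap = set(self.modulator_genes) & set(self.mediator_genes)
        if overlap:
            raise ValueError(f"genes planted in two driver categories: {sorted(overlap)[:5]}")

    def de_directions(self) -> dict[str, int]:
        """Sign of the planted post-treatment change for every DE gene."""
        out = {}
        for g, per_line in {**self.mediator_genes, **self.de_only_genes}.items():
            vals = [v for v in per_line.values() if v != 0]
            out[g] = 1 if vals and vals[0] > 0 else -1
        return out

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["ic50_true"] = self.ic50_true.to_dict()
        d["hill_true"] = self.hill_true.to_dict()
        d["top_true"] = self.top_true.to_dict()
        d["bottom_true"] = self.bottom_true.to_dict()
        d["essential_genes"] = {g: sorted(s) for g, s in self.essential_genes.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    counts_pre: pd.DataFrame
    counts_post: pd.DataFrame
    viability_single: pd.DataFrame
    viability_combo: pd.DataFrame
    essentiality: pd.DataFrame
    reference_signatures: pd.DataFrame
    truth: PanelTruth

    def __post_init__(self) -> None:
        genes = list(self.truth.gene_names)
        for name, m in (
            ("counts_pre", self.counts_pre),
            ("counts_post", self.counts_post),
            ("essentiality", self.essentiality),
            ("reference_signatures", self.reference_signatures),
        ):
            if list(m.index) != genes:
                raise ValueError(f"{name} gene universe differs from the truth object")
        for name, v in (("viability_single", self.viability_single),
                        ("viability_combo", self.viability_combo)):
            if (v["viability_pct"] < 0).any():
                raise ValueError(f"{name} contains negative viability")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_panel(
    n_lines: int = 11,
    n_genes: int = 5000,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> PanelTruth:
    """Plant the panel-level truth: lines, dose-response parameters and the
    driver-category assignment of every gene.

    IC50 values are log-spaced from ``ic50_min`` to ``ic50_max`` inclusive,
    then shuffled over lines, so the planted extremes always appear.
    """
    if n_lines < 3:
        raise ValueError("n_lines must be >= 3")
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    config = config or GeneratorConfig()
    if config.n_planted_genes() > n_genes:
        raise ValueError(
            f"config plants {config.n_planted_genes()} genes but n_genes={n_genes}"
        )
    rng = _rng(seed)
    lines = [f"L{i + 1:02d}" for i in range(n_lines)]
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]

    ic50 = np.exp(np.linspace(np.log(config.ic50_min), np.log(config.ic50_max), n_lines))
    rng.shuffle(ic50)
    hill = rng.uniform(*config.hill_range, size=n_lines)

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = genes[cursor : cursor + k]
        cursor += k
        return out

    module_assignment: dict[str, tuple[str, str]] = {}
    block_id = 0
    for persistence, n_blocks in (
        ("persistent", config.n_persistent_modules),
        ("pre_only", config.n_pre_only_modules),
        ("post_only", config.n_post_only_modules),
    ):
        for _ in range(n_blocks):
            block_id += 1
            for g in take(config.module_size):
                module_assignment[g] = (f"B{block_id:02d}", persistence)

    modulator_genes = {g: +1 for g in take(config.n_assisting)}
    modulator_genes.update({g: -1 for g in take(config.n_impeding)})

    def plant_de(gene_list: list[str]) -> dict[str, dict[str, float]]:
        out = {}
        for g in gene_list:
            sign = 1 if rng.random() < config.induction_fraction else -1
            mag = rng.uniform(*config.mediator_lfc_range)
            n_aff = int(rng.integers(config.de_min_lines, n_lines + 1))
            affected = rng.choice(lines, size=n_aff, replace=False)
            out[g] = {l: (sign * mag if l in set(affected) else 0.0) for l in lines}
        return out

    mediator_genes = plant_de(take(config.n_mediators))
    de_only_genes = plant_de(take(config.n_de_only))

    lo, hi = config.mediator_essential_lines_range
    essential_genes: dict[str, set[str]] = {}
    for g in mediator_genes:
        k = int(rng.integers(lo, hi + 1))
        essential_genes[g] = set(rng.choice(lines, size=min(k, n_lines), replace=False))

    emulators = {}
    for cls, n in (("like", config.n_like), ("contrary", config.n_contrary), ("null", config.n_null)):
        for i in range(n):
            emulators[f"{cls}_{i + 1}"] = cls

    return PanelTruth(
        line_names=lines,
        gene_names=genes,
        ic50_true=pd.Series(ic50, index=lines),
        hill_true=pd.Series(hill, index=lines),
        top_true=pd.Series(config.top, index=lines, dtype=float),
        bottom_true=pd.Series(config.bottom, index=lines, dtype=float),
        essential_genes=essential_genes,
        modulator_genes=modulator_genes,
        mediator_genes=mediator_genes,
        de_only_genes=de_only_genes,
        module_assignment=module_assignment,
        emulator_perturbations=emulators,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        config=config,
    )


def latent_log2_expression(
    truth: PanelTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent log2 mean expression per sample for both conditions.

    Columns follow ``<line>__<condition>__r<k>``.  Block genes load on one
    shared Gaussian factor per block per line (shared across conditions for
    persistent blocks, condition-private factors replaced by independent
    per-gene draws in the non-co-regulated condition); modulators carry a
    linear term in standardised log10 planted IC50 in both conditions;
    mediator and signature-only genes add their planted per-line log2 fold
    change post-treatment only.
    """
    cfg = truth.config
    rng = _rng(seed)
    lines, genes = truth.line_names, truth.gene_names
    n_lines, n_genes = len(lines), len(genes)
    gidx = {g: i for i, g in enumerate(genes)}
    lidx = {l: j for j, l in enumerate(lines)}

    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n_genes)
    x_pre = np.tile(base[:, None], (1, n_lines)).astype(float)
    x_post = x_pre.copy()

    z = np.log10(truth.ic50_true.loc[lines].to_numpy())
    z = (z - z.mean()) / z.std()

    def block_factor() -> np.ndarray:
        # orthogonalised against the sensitivity gradient so module membership
        # and sensitivity correlation stay separate planted properties
        f = rng.normal(size=n_lines)
        f = f - (f @ z) / (z @ z) * z
        f = f - f.mean()
        return f / f.std()

    blocks: dict[str, list[str]] = {}
    persistence: dict[str, str] = {}
    for g, (b, per) in truth.module_assignment.items():
        blocks.setdefault(b, []).append(g)
        persistence[b] = per
    for b in sorted(blocks):
        members = np.array([gidx[g] for g in blocks[b]])
        f = block_factor()
        per = persistence[b]
        if per == "persistent":
            x_pre[np.ix_(members, range(n_lines))] += f
            x_post[np.ix_(members, range(n_lines))] += f
        elif per == "pre_only":
            x_pre[np.ix_(members, range(n_lines))] += f
            x_post[np.ix_(members, range(n_lines))] += rng.normal(
                size=(members.size, n_lines)
            )
        else:  # post_only
            x_post[np.ix_(members, range(n_lines))] += f
            x_pre[np.ix_(members, range(n_lines))] += rng.normal(
                size=(members.size, n_lines)
            )

    for g, sign in truth.modulator_genes.items():
        x_pre[gidx[g], :] += sign * cfg.modulator_slope * z
        x_post[gidx[g], :] += sign * cfg.modulator_slope * z

    for g, per_line in {**truth.mediator_genes, **truth.de_only_genes}.items():
        for l, lfc in per_line.items():
            x_post[gidx[g], lidx[l]] += lfc

    def expand(x: np.ndarray, condition: str) -> pd.DataFrame:
        cols, mats = [], []
        for l in lines:
            for r in range(1, replicates + 1):
                cols.append(f"{l}__{condition}__r{r}")
                col = x[:, lidx[l]].copy()
                if noise_sd > 0:
                    col = col + rng.normal(scale=noise_sd, size=n_genes)
                mats.append(col)
        return pd.DataFrame(np.column_stack(mats), index=genes, columns=cols)

    return expand(x_pre, "pre"), expand(x_post, "post")


def generate_expression(
    truth: PanelTruth,
    nb_dispersion: float = 0.05,
    noise_sd: float = 0.3,
    seed: int = 0,
    replicates: int = 1,
    deterministic: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw pre/post count matrices from the NB observation model.

    Variance is ``mu + nb_dispersion * mu**2``; dispersion 0 gives Poisson
    counts.  ``noise_sd`` is the per-sample latent log2 noise.
    ``deterministic=True`` bypasses the observation model entirely and
    returns rounded means - the noiseless limit used by planted-truth
    round-trip checks, where even Poisson jitter would create sizeable
    spurious correlations across a panel of only ~11 lines.
    """
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    rng = _rng(seed)
    lat_pre, lat_post = latent_log2_expression(truth, noise_sd, rng, replicates)

    n_samples = lat_pre.shape[1] + lat_post.shape[1]
    size_factors = np.exp(rng.normal(0.0, truth.config.lib_size_log_sd, size=n_samples))

    def draw(lat: pd.DataFrame, sf: np.ndarray) -> pd.DataFrame:
        mu = (2.0 ** lat.to_numpy()) * sf[None, :]
        if deterministic:
            counts = np.rint(mu)
        elif nb_dispersion == 0:
            counts = rng.poisson(mu)
        else:
            shape = 1.0 / nb_dispersion
            counts = rng.poisson(rng.gamma(shape, mu / shape))
        return pd.DataFrame(counts.astype(np.int64), index=lat.index, columns=lat.columns)

    k = lat_pre.shape[1]
    return draw(lat_pre, size_factors[:k]), draw(lat_post, size_factors[k:])


def generate_viability(
    truth: PanelTruth,
    concentrations=DEFAULT_CONCENTRATIONS,
    replicates: int = 3,
    noise_sd: float = 2.0,
    combo_spec: tuple[ComboSpec, ...] = DEFAULT_COMBOS,
    seed: int = 0,
    inhibitor_concentrations=(0.001, 0.1, 10.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-agent dose grid plus combination tables with planted classes.

    The single-agent table follows each line's planted 4PL; the combination
    table pairs the treatment at its true IC25 (effect 0.25 of the planted
    dynamic range) with each planted inhibitor so that the noiseless
    combination index equals the spec's target (0.6 / 1.0 / 1.5 by class).
    Gaussian noise (``noise_sd`` percentage points) is added everywhere and
    viability floors at 0.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list must not be empty")
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly positive and sorted ascending")
    rng = _rng(seed)

    def noisy(v: float) -> float:
        return float(max(0.0, v + (rng.normal(scale=noise_sd) if noise_sd > 0 else 0.0)))

    single_rows = []
    for l in truth.line_names:
        top, bottom = truth.top_true[l], truth.bottom_true[l]
        hill, ic50 = truth.hill_true[l], truth.ic50_true[l]
        for c in conc:
            v = float(four_pl(np.array([c]), top, bottom, hill, ic50)[0])
            for r in range(1, replicates + 1):
                single_rows.append((l, "etoposide", c, r, noisy(v)))

    combo_rows = []
    for l in truth.line_names:
        top, bottom = truth.top_true[l], truth.bottom_true[l]
        span = (top - bottom) / 100.0
        ic25 = truth.ic50_true[l] * (0.25 / 0.75) ** (1.0 / truth.hill_true[l])
        e_a = 0.25 * span + (100.0 - top) / 100.0
        for r in range(1, replicates + 1):
            combo_rows.append((l, "vehicle", 0.0, r, noisy(100.0)))
            combo_rows.append((l, "etoposide", ic25, r, noisy(100.0 * (1 - e_a))))
        for spec in combo_spec:
            if spec.interaction not in ("synergy", "additive", "antagonism"):
                raise ValueError(f"unknown interaction class {spec.interaction!r}")
            e_b = spec.effect
            e_ab = min(0.98, (e_a + e_b) / spec.resolved_ci())
            for c in inhibitor_concentrations:
                for r in range(1, replicates + 1):
                    combo_rows.append((l, spec.inhibitor, c, r, noisy(100.0 * (1 - e_b))))
            for r in range(1, replicates + 1):
                combo_rows.append(
                    (l, f"etoposide+{spec.inhibitor}", ic25, r, noisy(100.0 * (1 - e_ab)))
                )

    cols = ["line", "agent", "concentration_uM", "replicate", "viability_pct"]
    return pd.DataFrame(single_rows, columns=cols), pd.DataFrame(combo_rows, columns=cols)


def generate_essentiality(truth: PanelTruth, seed: int = 0) -> pd.DataFrame:
    """DEMETER-style scores: negative = essential.

    Planted mediators are essential (scores in [-1.5, -0.2]) in their planted
    line sets; every other gene is essential in at most
    ``background_essential_max_lines`` random lines, keeping it strictly
    below the mediator threshold.
    """
    cfg = truth.config
    rng = _rng(seed)
    lines, genes = truth.line_names, truth.gene_names
    scores = rng.uniform(0.05, 1.2, size=(len(genes), len(lines)))
    df = pd.DataFrame(scores, index=genes, columns=lines)
    lidx = {l: j for j, l in enumerate(lines)}

    mediators = set(truth.mediator_genes)
    for i, g in enumerate(genes):
        if g in mediators:
            cols = [lidx[l] for l in truth.essential_genes[g]]
        else:
            k = int(rng.integers(0, cfg.background_essential_max_lines + 1))
            cols = list(rng.choice(len(lines), size=k, replace=False))
        for j in cols:
            df.iat[i, j] = -rng.uniform(0.2, 1.5)

    # record every gene's realised essential-line set on the truth object
    for g in genes:
        neg = set(df.columns[(df.loc[g] < 0).to_numpy()])
        if neg:
            truth.essential_genes[g] = neg
    return df


def generate_reference(
    truth: PanelTruth, seed: int = 0, signal_range=(4.0, 8.0)
) -> pd.DataFrame:
    """Perturbation reference: planted like/contrary columns place the true
    up-regulated genes at the score extremes; null columns are standard
    normal noise."""
    rng = _rng(seed)
    genes = truth.gene_names
    directions = truth.de_directions()
    cols = {}
    for pert, cls in truth.emulator_perturbations.items():
        col = rng.normal(size=len(genes))
        if cls in ("like", "contrary"):
            flip = 1.0 if cls == "like" else -1.0
            for i, g in enumerate(genes):
                d = directions.get(g)
                if d:
                    col[i] = flip * d * rng.uniform(*signal_range)
        cols[pert] = col
    return pd.DataFrame(cols, index=genes)


def generate_bundle(
    n_lines: int = 11,
    n_genes: int = 5000,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    nb_dispersion: float = 0.05,
    expression_noise_sd: float = 0.3,
    viability_noise_sd: float = 2.0,
    replicates: int = 1,
    viability_replicates: int = 3,
    concentrations=DEFAULT_CONCENTRATIONS,
    combo_spec: tuple[ComboSpec, ...] = DEFAULT_COMBOS,
    deterministic: bool = False,
) -> SyntheticBundle:
    """Generate the complete five-input bundle from one master seed.

    The master seed is split with ``SeedSequence(seed).generate_state(5)``
    into one child seed per component in the fixed order
    (panel, expression, viability, essentiality, reference).
    """
    children = [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(5)]
    truth = generate_panel(n_lines, n_genes, config, seed=children[0])
    truth.seed = int(seed)
    counts_pre, counts_post = generate_expression(
        truth,
        nb_dispersion,
        expression_noise_sd,
        seed=children[1],
        replicates=replicates,
        deterministic=deterministic,
    )
    via_single, via_combo = generate_viability(
        truth,
        concentrations,
        viability_replicates,
        viability_noise_sd,
        combo_spec,
        seed=children[2],
    )
    essentiality = generate_essentiality(truth, seed=children[3])
    reference = generate_reference(truth, seed=children[4])
    return SyntheticBundle(
        counts_pre, counts_post, via_single, via_combo, essentiality, reference, truth
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write every bundle component to plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts_pre": outdir / "counts_pre.tsv",
        "counts_post": outdir / "counts_post.tsv",
        "viability_single": outdir / "viability_single.csv",
        "viability_combo": outdir / "viability_combo.csv",
        "essentiality": outdir / "essentiality.tsv",
        "reference": outdir / "reference.gct",
        "truth": outdir / "truth.json",
    }
    write_counts_tsv(bundle.counts_pre, paths["counts_pre"])
    write_counts_tsv(bundle.counts_post, paths["counts_post"])
    write_viability_csv(bundle.viability_single, paths["viability_single"])
    write_viability_csv(bundle.viability_combo, paths["viability_combo"])
    write_matrix_tsv(bundle.essentiality, paths["essentiality"])
    write_gct(bundle.reference_signatures, paths["reference"])
    bundle.truth.to_json(paths["truth"])
    return paths
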