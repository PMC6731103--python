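"""Driver classification: modulators, mediators, and the query signature.

Three driver categories are called from the upstream analyses:

* **Modulators** — genes in treatment-unaffected co-expression modules whose
  pre-treatment expression correlates with drug sensitivity across the cell
  line panel (Pearson r versus log10 IC50).  Positive correlation with IC50
  is labelled *assisting*, negative *impeding*, following the convention of
  the screening design this package implements.
* **Mediators** — genes differentially expressed after treatment in at least
  one line and essential (negative DEMETER-style essentiality score) in at
  least ``essentiality_min_lines`` lines.
* **Signature** — the ranked up/down gene lists (at most k per direction)
  used to query a perturbation-signature reference for emulators.

All thresholds are strict: r = 0.5 exactly, FDR = 0.05 exactly and an
essentiality score of exactly 0 never produce a call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import de_filter

__all__ = [
    "ModulatorCall",
    "MediatorCall",
    "Signature",
    "call_modulators",
    "call_mediators",
    "build_signature",
]


@dataclass
class ModulatorCall:
    gene_id: str
    pearson_r: float
    p_value: float
    label: str  # "assisting" | "impeding"


@dataclass
class MediatorCall:
    gene_id: str
    n_lines_essential: int
    n_lines_de: int
    directions: dict[str, str] = field(default_factory=dict)


@dataclass
class Signature:
    """Disjoint ordered up/down gene lists for connectivity queries."""

    up_genes: list[str]
    down_genes: list[str]

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene lists must be disjoint")

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    def to_gmt(self, path, name: str = "query") -> None:
        with open(path, "w") as fh:
            fh.write("\t".join([f"{name}_UP", "up-regulated"] + self.up_genes) + "\n")
            fh.write("\t".join([f"{name}_DOWN", "down-regulated"] + self.down_genes) + "\n")

    @classmethod
    def from_gmt(cls, path) -> "Signature":
        with open(path) as fh:
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        if len(rows) != 2:
            raise ValueError("signature GMT must contain exactly two sets (UP, DOWN)")
        return cls(up_genes=rows[0][2:], down_genes=rows[1][2:])


def call_modulators(
    expr_pre: pd.DataFrame,
    ic50: pd.Series,
    unaffected_genes,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
    genome_wide: bool = False,
) -> list[ModulatorCall]:
    """Correlate pre-treatment expression with log10 IC50 across lines.

    ``expr_pre`` is genes x lines (log scale); ``ic50`` indexed by line, in
    uM.  Calls require |r| strictly above ``r_threshold`` and p strictly
    below ``p_threshold`` (two-sided t-test on n-2 df).  By default the
    screen is restricted to ``unaffected_genes``; ``genome_wide=True`` lifts
    the restriction for sensitivity analysis.
    """
    lines = [l for l in expr_pre.columns if l in ic50.index]
    if len(lines) < 4:
        raise ValueError("need at least 4 lines with both expression and IC50")
    if (ic50.loc[lines] <= 0).any():
        raise ValueError("IC50 values must be positive")
    x = np.log10(ic50.loc[lines].to_numpy(dtype=float))
    genes = list(expr_pre.index) if genome_wide else [
        g for g in expr_pre.index if g in set(unaffected_genes)
    ]
    sub = expr_pre.loc[genes, lines].to_numpy(dtype=float)
    n = len(lines)

    sd = sub.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"skipping {int(flat.sum())} zero-variance gene(s); correlation undefined"
        )
    xc = x - x.mean()
    yc = sub - sub.mean(axis=1, keepdims=True)
    denom = np.sqrt((yc ** 2).sum(axis=1) * (xc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)

    calls = []
    for g, ri, pi, bad in zip(genes, r, p, flat):
        if bad:
            continue
        if abs(ri) > r_threshold and pi < p_threshold:
            calls.append(
                ModulatorCall(g, float(ri), float(pi), "assisting" if ri > 0 else "impeding")
            )
    return calls


def call_mediators(
    de_sets: dict[str, pd.DataFrame],
    essentiality: pd.DataFrame,
    essentiality_min_lines: int = 6,
) -> list[MediatorCall]:
    """Intersect per-line DE calls with broad essentiality.

    ``de_sets`` maps line -> DataFrame(gene_id, direction) as produced by
    :func:`txdrivers.expression.de_filter`; ``essentiality`` is genes x lines
    of DEMETER-style scores where strictly negative means essential.
    """
    n_essential = (essentiality < 0).sum(axis=1)
    de_by_gene: dict[str, dict[str, str]] = {}
    for line, tbl in de_sets.items():
        for g, d in zip(tbl["gene_id"], tbl["direction"]):
            de_by_gene.setdefault(g, {})[line] = d

    calls = []
    for g in sorted(de_by_gene):
        if g not in essentiality.index:
            continue
        ness = int(n_essential.get(g, 0))
        if ness >= essentiality_min_lines:
            calls.append(MediatorCall(g, ness, len(de_by_gene[g]), dict(de_by_gene[g])))
    return calls


def build_signature(
    de_results: dict[str, pd.DataFrame],
    k: int = 150,
    min_lines: int = 3,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> Signature:
    """Build the top-k up / top-k down query signature from per-line DE tables.

    Candidates are genes passing the DE filter in the same direction in at
    least ``min_lines`` lines; genes passing in opposite directions in
    different lines are excluded from both sides.  Ranking: number of
    supporting lines (desc), median FDR over supporting lines (asc),
    |median log2 fold change| (desc), gene id (asc).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    support: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for line, tbl in de_results.items():
        hits = de_filter(tbl, fc_threshold=fc_threshold, fdr_threshold=fdr_threshold)
        stats_by_gene = tbl.set_index("gene_id")
        for g, d in zip(hits["gene_id"], hits["direction"]):
            row = stats_by_gene.loc[g]
            support.setdefault(g, {}).setdefault(d, []).append(
                (float(row["fdr"]), float(row["log2_fc"]))
            )

    ranked: dict[str, list[tuple]] = {"up": [], "down": []}
    for g, by_dir in support.items():
        if len(by_dir) > 1:
            continue  # conflicting directions across lines
        (direction, recs), = by_dir.items()
        if len(recs) < min_lines:
            continue
        med_fdr = float(np.median([r[0] for r in recs]))
        med_lfc = float(np.median([r[1] for r in recs]))
        ranked[direction].append((-len(recs), med_fdr, -abs(med_lfc), g))

    out = {}
    for direction in ("up", "down"):
        ranked[direction].sort()
        if len(ranked[direction]) < k:
            warnings.warn(
                f"only {len(ranked[direction])} qualifying {direction} genes (< {k})"
            )
        out[direction] = [t[3] for t in ranked[direction][:k]]
    return Signature(up_genes=out["up"], down_genes=out["down"])
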