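"""Weighted Kolmogorov-Smirnov connectivity scoring against a signature
reference.

A query signature (up/down gene lists) is scored against each column of a
gene x perturbation reference matrix of differential-expression scores.  Per
column the genes are ranked by score (descending, ties broken by gene id)
and a weighted KS running sum gives an enrichment score (ES) per gene set:
increments of ``|score|^w / sum(|score|^w)`` at set members, decrements of
``1/(N - |set|)`` elsewhere; the ES is the signed extremum of the running
sum.  The weighted two-sided connectivity score is

    wtcs = (ES_up - ES_down) / 2   if sign(ES_up) != sign(ES_down), else 0.

Perturbations with wtcs >= tau are *like* (signature-concordant) emulators,
those with wtcs <= -tau *contrary*.  No permutation-null normalisation is
applied; tau acts on the raw wtcs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drivers import Signature

__all__ = [
    "ConnectivityScore",
    "weighted_ks_es",
    "score_perturbations",
    "classify_emulators",
]


@dataclass
class ConnectivityScore:
    perturbation_id: str
    es_up: float
    es_down: float
    wtcs: float
    rank: int = 0


def _combine(es_up: float, es_down: float) -> float:
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def weighted_ks_es(gene_set, reference_profile: pd.Series, weight_exponent: float = 1.0) -> float:
    """Signed weighted-KS enrichment score of ``gene_set`` in a profile.

    ``reference_profile`` maps gene -> differential-expression score.  With
    ``weight_exponent=0`` this is the classic unweighted KS statistic.
    """
    members = set(gene_set) & set(reference_profile.index)
    if not members:
        raise ValueError("gene set has empty intersection with the reference universe")
    order = sorted(
        reference_profile.index, key=lambda g: (-reference_profile[g], str(g))
    )
    scores = reference_profile.loc[order].to_numpy(dtype=float)
    hit = np.fromiter((g in members for g in order), dtype=bool, count=len(order))
    n = len(order)
    n_hit = int(hit.sum())
    if n_hit == n:
        return 1.0
    w = np.abs(scores) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores are zero: fall back to unweighted steps
        hit_w = hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit) / (n - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def score_perturbations(
    signature: Signature,
    reference: pd.DataFrame,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Score every reference column against the signature.

    Returns a DataFrame sorted by descending wtcs with columns
    ``perturbation_id, es_up, es_down, wtcs, rank``.
    """
    universe = set(reference.index)
    covered = len((set(signature.up_genes) | set(signature.down_genes)) & universe)
    total = len(signature)
    if total and covered / total < 0.5:
        warnings.warn(
            f"reference covers only {covered}/{total} signature genes (<50%)"
        )
    rows = []
    for pert in reference.columns:
        col = reference[pert]
        if col.nunique() <= 1:
            warnings.warn(f"perturbation {pert!r} has constant scores; skipped")
            continue
        es_up = weighted_ks_es(signature.up_genes, col, weight_exponent)
        es_down = weighted_ks_es(signature.down_genes, col, weight_exponent)
        rows.append(
            {
                "perturbation_id": str(pert),
                "es_up": es_up,
                "es_down": es_down,
                "wtcs": _combine(es_up, es_down),
            }
        )
    out = pd.DataFrame(rows, columns=["perturbation_id", "es_up", "es_down", "wtcs"])
    out = out.sort_values(["wtcs", "perturbation_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def classify_emulators(scores: pd.DataFrame, tau: float = 0.9) -> pd.DataFrame:
    """Split perturbations into like / contrary / unclassified at |wtcs| >= tau."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    out = scores.copy()
    out["class"] = np.where(
        out["wtcs"] >= tau, "like", np.where(out["wtcs"] <= -tau, "contrary", "unclassified")
    )
    return out
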