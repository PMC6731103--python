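"""Count-matrix handling, TMM normalisation and negative-binomial DE testing.

The differential-expression test is an exact conditional test under a
negative-binomial model with a common dispersion: counts are scaled to a
common effective library size, the per-gene group sums are conditioned on
their total, and the two-sided p-value is twice the smaller tail
probability, capped at 1.  With dispersion 0 the conditional distribution
degenerates to a binomial.  This is a deliberately simple re-implementation
of the exact-test idea; it does not reproduce quantile-adjusted
pseudo-counts or moderated dispersion estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "tmm_norm_factors",
    "cpm",
    "de_test",
    "de_filter",
    "bh_adjust",
    "estimate_common_dispersion",
]

#: Prior dispersion used when a contrast has no replicates (one sample per
#: condition).  Corresponds to a biological coefficient of variation of 0.4,
#: a conventional value for cell-line data.
NO_REPLICATE_DISPERSION = 0.16

SAMPLE_SEP = "__"


@dataclass
class CountMatrix:
    """Gene x sample raw counts with (line, condition, replicate) metadata.

    ``counts`` is a genes-by-samples DataFrame of non-negative integers whose
    column names follow the convention ``<line>__<condition>__<replicate>``
    with ``condition`` one of ``pre`` / ``post``.  ``samples`` carries the
    parsed metadata, one row per column of ``counts``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        missing = set(self.counts.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValueError(f"samples metadata missing for: {sorted(missing)}")

    @classmethod
    def from_frame(cls, counts: pd.DataFrame) -> "CountMatrix":
        meta = []
        for sid in counts.columns:
            parts = str(sid).split(SAMPLE_SEP)
            if len(parts) != 3:
                raise ValueError(
                    f"sample id {sid!r} does not follow <line>__<condition>__<replicate>"
                )
            line, condition, rep = parts
            if condition not in ("pre", "post"):
                raise ValueError(f"condition of sample {sid!r} must be 'pre' or 'post'")
            meta.append({"sample_id": sid, "line": line, "condition": condition, "replicate": rep})
        return cls(counts=counts, samples=pd.DataFrame(meta))

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls.from_frame(counts)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_line(self, line: str) -> "CountMatrix":
        keep = self.samples[self.samples["line"] == line]
        if keep.empty:
            raise ValueError(f"no samples for line {line!r}")
        return CountMatrix(self.counts[keep["sample_id"].tolist()], keep.reset_index(drop=True))


def _choose_reference(counts: pd.DataFrame) -> str:
    """Sample whose upper-quartile (of scaled counts) is closest to the mean."""
    scaled = counts / counts.sum(axis=0)
    uq = scaled.quantile(0.75, axis=0)
    return str((uq - uq.mean()).abs().idxmin())


def tmm_norm_factors(
    counts: CountMatrix | pd.DataFrame,
    reference: str | None = None,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors, geometric mean 1.

    For each sample versus the reference, genewise log-ratios (M) and average
    log-intensities (A) are computed on library-size-scaled counts over genes
    expressed in both; the most extreme 30% of M values and 5% of A values
    are trimmed and the factor is the precision-weighted mean of the
    remaining M values (weights: inverse asymptotic variance of M).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    if reference is None:
        reference = _choose_reference(mat)
    if reference not in mat.columns:
        raise ValueError(f"reference sample {reference!r} not found")

    ref = mat[reference].to_numpy(dtype=float)
    n_ref = float(lib[reference])
    factors = {}
    for sample in mat.columns:
        if sample == reference:
            factors[sample] = 1.0
            continue
        obs = mat[sample].to_numpy(dtype=float)
        n_obs = float(lib[sample])
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        n = m.size
        if n == 0:
            factors[sample] = 1.0
            continue
        # doubly trimmed set: ranks within the central (1-2*trim) mass on both axes
        lo_m, hi_m = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
        lo_a, hi_a = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any():
            factors[sample] = 1.0
            continue
        f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
        factors[sample] = float(2.0 ** f)
    out = pd.Series(factors).reindex(mat.columns)
    out /= np.exp(np.mean(np.log(out)))
    out.name = "norm_factor"
    return out


def cpm(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    log: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million of effective library size (lib size x TMM factor)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0).astype(float)
    if factors is not None:
        if (factors.reindex(mat.columns) <= 0).any():
            raise ValueError("normalisation factors must be positive")
        lib = lib * factors.reindex(mat.columns)
    out = mat / lib * 1e6
    if log:
        out = np.log2(out + prior_count)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_common_dispersion(scaled: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across genes.

    ``scaled`` is genes x samples (counts scaled to a common library size);
    ``groups`` labels columns 0/1.  Per gene, the pooled within-group variance
    v and mean m give phi_g = (v - m) / m^2; the common value is the median
    over genes with positive mean, floored at 0.
    """
    phis = []
    for g in (0, 1):
        sub = scaled[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        phis.append(((v[ok] - m[ok]) / m[ok] ** 2))
    if not phis:
        return NO_REPLICATE_DISPERSION
    allphi = np.concatenate(phis)
    if allphi.size == 0:
        return NO_REPLICATE_DISPERSION
    return float(max(0.0, np.median(allphi)))


def _exact_nb_pvalue(s1: int, s2: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided exact conditional p-value for group sums s1 vs s2.

    Group sums of n iid NB(mu, phi) counts follow NB(n*mu, phi/n).  Given the
    total T = s1 + s2 the conditional law of s1 is evaluated exactly over
    0..T; the p-value doubles the smaller of P(S1 <= s1) and P(S1 >= s1),
    capped at 1.  With dispersion 0 this is the binomial split of T with
    success probability n1/(n1+n2).
    """
    total = s1 + s2
    if total == 0:
        return 1.0
    if dispersion <= 0:
        frac = n1 / (n1 + n2)
        lo = stats.binom.cdf(s1, total, frac)
        hi = stats.binom.sf(s1 - 1, total, frac)
        return float(min(1.0, 2.0 * min(lo, hi)))
    mu = total / (n1 + n2)
    s = np.arange(total + 1)
    # scipy parameterisation: nbinom(r, p) with p = r / (r + mean)
    r1, r2 = n1 / dispersion, n2 / dispersion
    lp = (
        stats.nbinom.logpmf(s, r1, r1 / (r1 + n1 * mu))
        + stats.nbinom.logpmf(total - s, r2, r2 / (r2 + n2 * mu))
    )
    w = np.exp(lp - lp.max())
    w /= w.sum()
    lo = w[: s1 + 1].sum()
    hi = w[s1:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def de_test(
    counts: CountMatrix,
    line: str,
    dispersion: float | str = "auto",
    norm_factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Pre/post exact conditional NB test for one cell line.

    Returns a DataFrame with columns ``gene_id, log2_fc, p_value, fdr,
    mean_cpm`` (log2_fc is post over pre).  ``dispersion`` may be a fixed
    common value or ``"auto"``: method-of-moments when replicates exist,
    otherwise the no-replicate prior of 0.16.
    """
    sub = counts.subset_line(line)
    cond = sub.samples.set_index("sample_id")["condition"]
    pre_ids = [s for s in sub.counts.columns if cond[s] == "pre"]
    post_ids = [s for s in sub.counts.columns if cond[s] == "post"]
    if not pre_ids or not post_ids:
        raise ValueError(f"line {line!r} needs at least one pre and one post sample")

    if norm_factors is None:
        norm_factors = tmm_norm_factors(sub)
    eff_lib = sub.lib_sizes().astype(float) * norm_factors.reindex(sub.counts.columns)
    target = float(np.exp(np.mean(np.log(eff_lib))))
    scaled = np.rint(sub.counts.to_numpy(dtype=float) * (target / eff_lib.to_numpy())).astype(np.int64)
    cols = list(sub.counts.columns)
    groups = np.array([0 if cond[c] == "pre" else 1 for c in cols])

    if dispersion == "auto":
        if len(pre_ids) > 1 or len(post_ids) > 1:
            phi = estimate_common_dispersion(scaled, groups)
        else:
            phi = NO_REPLICATE_DISPERSION
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be non-negative")

    n1, n2 = len(pre_ids), len(post_ids)
    s_pre = scaled[:, groups == 0].sum(axis=1)
    s_post = scaled[:, groups == 1].sum(axis=1)
    pvals = np.array(
        [_exact_nb_pvalue(int(a), int(b), n1, n2, phi) for a, b in zip(s_pre, s_post)]
    )
    log2_fc = np.log2((s_post / n2 + prior_count) / (s_pre / n1 + prior_count))
    mean_cpm = cpm(sub, factors=norm_factors).mean(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "log2_fc": log2_fc,
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
            "mean_cpm": mean_cpm,
        }
    ).reset_index(drop=True)


def de_filter(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Apply the DE filter: |fold change| strictly above ``fc_threshold`` and
    FDR strictly below ``fdr_threshold``; returns gene_id + direction."""
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if results.empty:
        return pd.DataFrame(columns=["gene_id", "direction"])
    keep = (results["log2_fc"].abs() > np.log2(fc_threshold)) & (
        results["fdr"] < fdr_threshold
    )
    out = results.loc[keep, ["gene_id", "log2_fc"]].copy()
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out[["gene_id", "direction"]].reset_index(drop=True)
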