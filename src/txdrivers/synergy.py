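"""Per-response-additivity combination index and standalone cytotoxicity.

Effects are fractions of maximal kill relative to vehicle,
``E = 1 - viability/100`` clipped to [0, 1].  For a drug pair the
combination index is

    CI = (E_A + E_B) / E_AB

with CI < 1 synergy, CI = 1 additivity and CI > 1 antagonism.  Because
replicate noise makes the knife-edge CI = 1 unusable in practice, values
within ``additive_band`` of 1 are classified additive (boundary inclusive);
the raw CI and a bootstrap percentile interval are always reported alongside
the class.

Standalone cytotoxicity of a single agent is tested per line with a
two-factor fixed-effects ANOVA (concentration level including vehicle, and
replicate batch); treatment-factor p-values are pooled across agents and
BH-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .expression import bh_adjust

__all__ = [
    "CombinationRecord",
    "combination_index",
    "classify_combination",
    "effect_from_viability",
    "evaluate_combinations",
    "standalone_cytotoxicity",
    "summarize_panel",
]


@dataclass
class CombinationRecord:
    line: str
    agent_a: str
    agent_b: str
    e_a: float
    e_b: float
    e_ab: float
    ci: float
    ci_class: str
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def combination_index(e_a: float, e_b: float, e_ab: float) -> float:
    """CI = (E_A + E_B) / E_AB for fractional effects."""
    if e_a < 0 or e_b < 0:
        raise ValueError("single-agent effects must be non-negative")
    if e_ab <= 0:
        raise ValueError("combination effect non-positive; CI undefined")
    return (e_a + e_b) / e_ab


def classify_combination(ci: float, additive_band: float = 0.1) -> str:
    """synergy / additive / antagonism with an inclusive additive band."""
    if ci <= 0:
        raise ValueError("CI must be positive")
    # inclusive band; tiny tolerance keeps e.g. |1.1 - 1| <= 0.1 true in floats
    if abs(ci - 1.0) <= additive_band + 1e-12:
        return "additive"
    return "synergy" if ci < 1.0 - additive_band else "antagonism"


def effect_from_viability(viability_pct) -> float:
    """Fraction affected: 1 - mean(viability)/100, clipped to [0, 1]."""
    return float(np.clip(1.0 - np.mean(np.asarray(viability_pct, dtype=float)) / 100.0, 0.0, 1.0))


def _bootstrap_ci(
    va: np.ndarray, vb: np.ndarray, vab: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    vals = []
    for _ in range(n_boot):
        ea = effect_from_viability(rng.choice(va, size=va.size, replace=True))
        eb = effect_from_viability(rng.choice(vb, size=vb.size, replace=True))
        eab = effect_from_viability(rng.choice(vab, size=vab.size, replace=True))
        if eab > 0:
            vals.append((ea + eb) / eab)
    if not vals:
        return float("nan"), float("nan")
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def evaluate_combinations(
    viability: pd.DataFrame,
    additive_band: float = 0.1,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compute CI records for every ``A+B`` agent in a long viability table.

    Expects columns ``line, agent, concentration_uM, replicate,
    viability_pct``; combination rows use ``A+B`` agent syntax and are matched
    with the single-agent rows of the same line (effects from replicate
    means, pooled over that agent's concentrations present in the table).
    """
    rng = np.random.default_rng(seed)
    combos = sorted(a for a in viability["agent"].unique() if "+" in str(a))
    rows = []
    for line, grp in viability.groupby("line", sort=True):
        for combo in combos:
            sub_ab = grp[grp["agent"] == combo]
            if sub_ab.empty:
                continue
            agent_a, agent_b = str(combo).split("+", 1)
            va = grp.loc[grp["agent"] == agent_a, "viability_pct"].to_numpy(dtype=float)
            vb = grp.loc[grp["agent"] == agent_b, "viability_pct"].to_numpy(dtype=float)
            vab = sub_ab["viability_pct"].to_numpy(dtype=float)
            if va.size == 0 or vb.size == 0:
                raise ValueError(
                    f"combination {combo!r} on line {line!r} lacks single-agent rows"
                )
            e_a, e_b, e_ab = map(effect_from_viability, (va, vb, vab))
            if e_ab <= 0:
                rows.append(
                    CombinationRecord(str(line), agent_a, agent_b, e_a, e_b, e_ab,
                                      float("nan"), "undefined")
                )
                continue
            ci = combination_index(e_a, e_b, e_ab)
            lo, hi = _bootstrap_ci(va, vb, vab, n_boot, rng)
            rows.append(
                CombinationRecord(
                    str(line), agent_a, agent_b, e_a, e_b, e_ab, ci,
                    classify_combination(ci, additive_band), lo, hi,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def standalone_cytotoxicity(
    viability: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag agents with significant cytotoxicity versus vehicle per line.

    ``viability`` must contain vehicle rows (``agent == 'vehicle'``) and, per
    (line, agent), >= 2 replicates per concentration.  A two-factor ANOVA
    (C(concentration) + C(replicate)) is fitted per line x agent with vehicle
    included as concentration 0; the concentration-factor p-values are pooled
    and BH-adjusted.  The significance flag additionally requires the mean
    viability at the top concentration to fall below the vehicle mean.
    """
    vehicle = viability[viability["agent"] == "vehicle"]
    if vehicle.empty:
        raise ValueError("viability table lacks vehicle rows")
    agents = sorted(
        a for a in viability["agent"].unique() if a != "vehicle" and "+" not in str(a)
    )
    rows = []
    for line, grp in viability.groupby("line", sort=True):
        veh = grp[grp["agent"] == "vehicle"]
        for agent in agents:
            sub = grp[grp["agent"] == agent]
            if sub.empty:
                continue
            tbl = pd.concat(
                [
                    veh.assign(concentration_uM=0.0),
                    sub,
                ],
                ignore_index=True,
            )[["concentration_uM", "replicate", "viability_pct"]]
            if tbl.groupby(["concentration_uM"])["replicate"].nunique().min() < 2:
                raise ValueError(
                    f"line {line!r}, agent {agent!r}: need >= 2 replicates per concentration"
                )
            model = smf.ols(
                "viability_pct ~ C(concentration_uM) + C(replicate)", data=tbl
            ).fit()
            anova = sm.stats.anova_lm(model, typ=2)
            p = float(anova.loc["C(concentration_uM)", "PR(>F)"])
            top_conc = sub["concentration_uM"].max()
            kill = (
                sub.loc[sub["concentration_uM"] == top_conc, "viability_pct"].mean()
                < veh["viability_pct"].mean()
            )
            rows.append(
                {"line": str(line), "agent": agent, "p_value": p, "reduces_viability": bool(kill)}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(fdr=[], significant=[])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = (out["fdr"] < alpha) & out["reduces_viability"]
    return out


def summarize_panel(
    combos: pd.DataFrame, cytotox: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-agent tallies of lines with standalone cytotoxicity and with
    synergy or additivity, mirroring a driver-validation summary table."""
    syn = (
        combos[combos["ci_class"].isin(["synergy", "additive"])]
        .groupby("agent_b")["line"]
        .nunique()
        .rename("n_lines_synergy_or_additivity")
    )
    out = syn.reset_index().rename(columns={"agent_b": "agent"})
    if cytotox is not None and not cytotox.empty:
        cyt = (
            cytotox[cytotox["significant"]]
            .groupby("agent")["line"]
            .nunique()
            .rename("n_lines_standalone_cytotoxicity")
        )
        out = out.merge(cyt.reset_index(), on="agent", how="outer")
    return out.fillna(0).sort_values("agent").reset_index(drop=True)
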