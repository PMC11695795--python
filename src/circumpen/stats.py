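"""Treatment summaries and statistics for the penetration experiment.

Covers the analyses applied to the measured resistances: per-treatment
means over the 0-10 mm penetration window, percent reductions relative to
the stationary treatment, analysis of covariance with circumnutation
frequency as a continuous and shaft material as a categorical predictor,
LSD (least significant difference) multiple comparisons with a compact
letter display, and ordinary least-squares regressions such as frictional
force against circumnutation intensity.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from . import cavity
from .probe import ProbeSpec
from .synthetic import GeneratorConfig, gen_force_traces

__all__ = [
    "TreatmentSummary",
    "RegressionResult",
    "treatment_summary",
    "percent_reduction",
    "ols_regression",
    "ancova",
    "lsd_letters",
    "run_experiment",
]


@dataclass
class TreatmentSummary:
    """Per-treatment mean resistance over the penetration window."""

    table: pd.DataFrame  # columns: material, f, mean_Q, se_Q, n
    replicate_means: pd.DataFrame  # columns: material, f, replicate, Q

    def mean(self, material: str, f: float) -> float:
        row = self.table[(self.table.material == material) & (self.table.f == f)]
        if row.empty:
            raise KeyError((material, f))
        return float(row.mean_Q.iloc[0])


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def treatment_summary(
    traces: pd.DataFrame,
    probes: dict[str, ProbeSpec],
    depth_range_mm: tuple[float, float] = (0.0, 10.0),
) -> TreatmentSummary:
    """Mean and standard error of mechanical resistance per treatment.

    ``traces`` holds per-sample forces with columns ``material, f,
    replicate, depth_mm, Fz_N``.  Each replicate is first averaged over the
    depth window, then treatments are summarised across replicates (SE is
    NaN for a single replicate).
    """
    lo, hi = depth_range_mm
    for material, grp in traces.groupby("material"):
        if grp.depth_mm.max() < hi - 1e-9:
            raise ValueError(
                f"traces for {material} do not cover the {lo}-{hi} mm window"
            )
    win = traces[(traces.depth_mm >= lo) & (traces.depth_mm <= hi)]
    reps = (
        win.groupby(["material", "f", "replicate"], as_index=False)
        .Fz_N.mean()
        .rename(columns={"Fz_N": "Fz"})
    )
    reps["Q"] = [
        cavity.resistance_from_force(fz, probes[m])
        for fz, m in zip(reps.Fz, reps.material)
    ]
    reps = reps.drop(columns="Fz")
    g = reps.groupby(["material", "f"], as_index=False).agg(
        mean_Q=("Q", "mean"), sd_Q=("Q", "std"), n=("Q", "size")
    )
    g["se_Q"] = g.sd_Q / np.sqrt(g.n)
    return TreatmentSummary(
        table=g[["material", "f", "mean_Q", "se_Q", "n"]], replicate_means=reps
    )


def percent_reduction(Q_ref: float, Q_treat: float) -> float:
    """Percent reduction of ``Q_treat`` relative to ``Q_ref``."""
    if Q_ref <= 0:
        raise ValueError("reference resistance must be positive")
    return 100.0 * (Q_ref - Q_treat) / Q_ref


def ols_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Simple least-squares regression with a two-sided slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(y, y[0]):  # degenerate: flat response, no trend
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, x.size)
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=x.size,
    )


def ancova(replicate_means: pd.DataFrame) -> pd.DataFrame:
    """ANCOVA of resistance on frequency (continuous) x material (categorical).

    Fits ``Q ~ f + C(material) + f:C(material)`` by least squares and
    returns type-II F-tests per term (rows ``f``, ``C(material)``,
    ``f:C(material)``, ``Residual``; for the balanced design used here
    type-II and type-I sums of squares agree).
    """
    df = replicate_means
    counts = df.groupby("material").Q.size()
    if (counts < 2).any():
        raise ValueError("every material needs at least 2 replicates")
    model = smf.ols("Q ~ f + C(material) + f:C(material)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def lsd_letters(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> dict[str, str]:
    """LSD multiple comparisons with a compact letter display.

    Pairwise t-tests use the pooled residual variance of the one-way layout
    (all groups).  Groups that do not differ at ``alpha`` share a letter;
    letters are assigned in descending order of the group means, starting
    at 'a'.  The insert-and-absorb construction makes the display exact for
    any overlap pattern and invariant to the input order.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = sorted(groups, key=lambda k: -float(np.mean(groups[k])))
    vals = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    n_tot = sum(v.size for v in vals.values())
    df_resid = n_tot - len(groups)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    mse = (
        sum(((v - v.mean()) ** 2).sum() for v in vals.values()) / df_resid
    )
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df_resid)

    def different(a: str, b: str) -> bool:
        va, vb = vals[a], vals[b]
        if mse == 0:
            return va.mean() != vb.mean()
        lsd = tcrit * np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
        return abs(va.mean() - vb.mean()) > lsd

    # insert-absorb: start with one column; split it for each significant pair
    columns: list[set[str]] = [set(names)]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if not different(a, b):
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                ca, cb = col - {b}, col - {a}
                for c in (ca, cb):
                    if not any(c <= other for other in columns):
                        columns.append(c)
    columns = [c for c in columns if not any(c < o for o in columns if o is not c)]
    columns.sort(key=lambda c: min(names.index(m) for m in c))
    letters = {k: "" for k in names}
    for letter, col in zip(string.ascii_lowercase, columns):
        for k in col:
            letters[k] += letter
    return {k: "".join(sorted(v)) for k, v in letters.items()}


def run_experiment(config: GeneratorConfig, mu_prime: float = 0.1) -> dict:
    """End-to-end synthetic experiment.

    Simulates force traces, summarises resistance per treatment, computes
    percent reductions against the stationary treatment of each material,
    runs the ANCOVA and LSD letters on per-replicate means, decomposes each
    treatment into cavity-expansion and frictional forces (stationary
    cavity force inherited within the shaft-material group), rescales
    friction to ``mu_prime``, and regresses frictional force on
    circumnutation intensity.  Fully seeded and reproducible.
    """
    traces, truth = gen_force_traces(config)
    summary = treatment_summary(traces, config.probes, (0.0, config.depth_mm))
    fric = cavity.FrictionParams(mu=config.mu, mu_prime=mu_prime)

    reductions = {}
    decomposition_rows = []
    for material in sorted(config.probes):
        probe = config.probes[material]
        Q0 = summary.mean(material, 0.0)
        Fz0 = cavity.force_from_resistance(Q0, probe)
        for f in config.frequencies:
            Q = summary.mean(material, f)
            if f > 0:
                reductions[f"{material}:{f:g}"] = percent_reduction(Q0, Q)
            dc = 0.0 if f == 0 else config.delta_c[(material, f)]
            dec = cavity.decompose_treatment(
                Fz0,
                cavity.force_from_resistance(Q, probe),
                dc,
                f,
                probe,
                fric,
                config.fmax,
            )
            Fz_p, Ff_p = cavity.friction_rescale(dec.Fz, fric, probe, dec.Fc_s)
            decomposition_rows.append(
                {
                    "material": material,
                    "f": f,
                    "Q_MPa": Q,
                    "Fz_N": dec.Fz,
                    "sigma_rs_MPa": dec.sigma_rs,
                    "Fr_s_N": dec.Fr_s,
                    "Fc_s_N": dec.Fc_s,
                    "Ff_s_N": dec.Ff_s,
                    "Fro_N": dec.Fro,
                    "Ff_m_N": dec.Ff_m if f > 0 else dec.Ff_s,
                    "Iasym": dec.Iasym,
                    "CI": dec.CI,
                    "Fz_prime_N": Fz_p,
                    "Ff_prime_N": Ff_p,
                }
            )
    forces = pd.DataFrame(decomposition_rows)

    anova_table = ancova(summary.replicate_means)
    letter_groups = {
        f"{m}:{f:g}": grp.Q.to_numpy()
        for (m, f), grp in summary.replicate_means.groupby(["material", "f"])
    }
    letters = lsd_letters(letter_groups)
    ff_ci = ols_regression(forces.CI.to_numpy(), forces.Ff_m_N.to_numpy())

    return {
        "config_seed": config.seed,
        "mode": config.mode,
        "truth": truth,
        "summary": summary,
        "forces": forces,
        "reductions": reductions,
        "ancova": anova_table,
        "lsd_letters": letters,
        "ff_ci_regression": ff_ci,
    }
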