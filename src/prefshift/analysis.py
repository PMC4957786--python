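"""Population-level statistics over fitted parameters.

Everything here is a pure function of a :class:`pandas.DataFrame` with one
row per participant (the *population table*), so that any report can be
recomputed from its serialized form.  Conventions:

* the preference shift ``m3 - m1`` is signed so that positive = toward the
  Other's taste;
* partial correlations are computed by double residualization (OLS of both
  variables on the controls, then Pearson correlation of the residuals);
* "near-zero taste uncertainty" flags participants with fitted ``u`` below a
  configurable cutoff (default 0.01), the near-deterministic responders that
  appear as separate clumps in community samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .inference import FitResult, ModelComparison

__all__ = [
    "build_population_table",
    "AssociationResult",
    "association_stats",
    "shift_regression",
    "GroupDifference",
    "group_difference",
    "mediation_by_partial",
    "results_report",
    "format_report",
]

NEAR_ZERO_U = 0.01


def _fits_by_id(fits: Optional[Sequence[FitResult]]) -> dict:
    return {f.participant_id: f for f in fits} if fits else {}


def build_population_table(
    datasets: Sequence[ParticipantDataset],
    kt_fits: Optional[Sequence[FitResult]] = None,
    ku_fits: Optional[Sequence[FitResult]] = None,
    perturb_fits: Optional[Sequence[FitResult]] = None,
    ps_fits: Optional[Sequence[FitResult]] = None,
) -> pd.DataFrame:
    """Assemble the one-row-per-participant table from per-model fits.

    The signed shift ``shift_toward`` is ``(m3 - m1) * sign(k_o - m1)`` using
    the perturbation-model taste modes, positive when the change is in the
    Other's direction.  ``other_direction`` is ``patient`` when the Other
    discounts less steeply than the participant's phase-1 estimate.
    """
    kt = _fits_by_id(kt_fits)
    ku = _fits_by_id(ku_fits)
    pe = _fits_by_id(perturb_fits)
    ps = _fits_by_id(ps_fits)
    rows = []
    for d in datasets:
        pid = d.participant_id
        row: dict = {"participant_id": pid, "age": d.age, "gender": d.gender}
        if d.truth:
            for key in ("m_s", "u_s", "sigma_r", "tau_o", "xi", "k_b", "k_o"):
                if key in d.truth:
                    row[f"true_{key}"] = d.truth[key]
        if pid in kt:
            row["kt_k"] = kt[pid].params["k"]
            row["kt_T"] = kt[pid].params["T"]
            row["kt_lnT"] = math.log(kt[pid].params["T"])
        if pid in ku:
            row["m1"] = ku[pid].params["m"]
            row["u1"] = ku[pid].params["u"]
        if pid in pe:
            row["perturb_m1"] = pe[pid].params["m1"]
            row["m3"] = pe[pid].params["m3"]
            row["shift_raw"] = pe[pid].params["m3"] - pe[pid].params["m1"]
        if pid in ps:
            row["ps_m"] = ps[pid].params["m_s"]
            row["ps_u"] = ps[pid].params["u_s"]
            row["ps_sigma_r"] = ps[pid].params["sigma_r"]
            row["ps_tau_o"] = ps[pid].params["tau_o"]
            row["ps_xi"] = ps[pid].params["xi"]
        k_o = row.get("true_k_o")
        if k_o is not None and "shift_raw" in row:
            toward = np.sign(k_o - row["perturb_m1"]) or 1.0
            row["shift_toward"] = row["shift_raw"] * toward
            row["other_direction"] = "patient" if k_o < row["perturb_m1"] else "impulsive"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    x: str
    y: str
    controls: tuple[str, ...]
    r: float
    p: float
    n: int


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), Z])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def association_stats(
    table: pd.DataFrame, x: str, y: str, controls: Sequence[str] = ()
) -> AssociationResult:
    """Pearson correlation, or partial correlation by double residualization
    on ``controls``, with a two-sided t-test p-value."""
    cols = [x, y, *controls]
    df = table[cols].dropna()
    n = len(df)
    if n < 3 + len(controls):
        raise ValueError(f"need at least {3 + len(controls)} complete rows, got {n}")
    for c in cols:
        if float(np.var(df[c].to_numpy(float))) <= 1e-30:
            raise ValueError(f"zero variance in {c!r}")
    xv = df[x].to_numpy(float)
    yv = df[y].to_numpy(float)
    if controls:
        Z = df[list(controls)].to_numpy(float)
        xr = _residualize(xv, Z)
        yr = _residualize(yv, Z)
        if (
            float(np.var(xr)) <= 1e-12 * float(np.var(xv))
            or float(np.var(yr)) <= 1e-12 * float(np.var(yv))
        ):
            raise ValueError("zero residual variance after controlling")
        r = float(np.corrcoef(xr, yr)[0, 1])
        dof = n - 2 - len(controls)
        t = r * math.sqrt(dof / max(1.0 - r * r, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    else:
        r, p = stats.pearsonr(xv, yv)
        r, p = float(r), float(p)
    return AssociationResult(x=x, y=y, controls=tuple(controls), r=r, p=p, n=n)


def shift_regression(
    table: pd.DataFrame,
    shift_col: str = "shift_toward",
    u_col: str = "ps_u",
    sr_col: str = "ps_sigma_r",
):
    """OLS of the signed shift on taste uncertainty, reference dispersion and
    their interaction:  shift = b0 + b1*u + b2*sigma_r + b3*u*sigma_r.
    Returns the fitted statsmodels results object."""
    df = table[[shift_col, u_col, sr_col]].dropna()
    if len(df) < 5:
        raise ValueError("need at least 5 complete rows")
    X = pd.DataFrame(
        {
            "u": df[u_col],
            "sigma_r": df[sr_col],
            "u_x_sigma_r": df[u_col] * df[sr_col],
        }
    )
    X = sm.add_constant(X)
    return sm.OLS(df[shift_col], X).fit()


# ---------------------------------------------------------------------------
# Group tests and mediation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDifference:
    group_col: str
    value_col: str
    groups: tuple[str, str]
    means: tuple[float, float]
    effect_size: float            # Cohen's d, group0 - group1, pooled SD
    p: float                      # two-sided rank-sum


def group_difference(
    table: pd.DataFrame, group_col: str, value_col: str
) -> GroupDifference:
    df = table[[group_col, value_col]].dropna()
    labels = sorted(df[group_col].unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups in {group_col!r}, got {labels}")
    a = df.loc[df[group_col] == labels[0], value_col].to_numpy(float)
    b = df.loc[df[group_col] == labels[1], value_col].to_numpy(float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = math.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / max(a.size + b.size - 2, 1)
    )
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return GroupDifference(
        group_col=group_col,
        value_col=value_col,
        groups=(str(labels[0]), str(labels[1])),
        means=(float(a.mean()), float(b.mean())),
        effect_size=float(d),
        p=p,
    )


def mediation_by_partial(
    table: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    alpha: float = 0.05,
) -> dict:
    """Partial-correlation reading of mediation.

    Reports the raw correlation ``r(x, y)``, the partial ``r(x, y; m)`` and
    the partial ``r(m, y; x)``.  "Full mediation" is declared when the raw
    x–y association is significant but vanishes (non-significant) once the
    mediator is controlled, while the mediator retains its own association.
    """
    raw = association_stats(table, x, y)
    part_x = association_stats(table, x, y, controls=[m])
    part_m = association_stats(table, m, y, controls=[x])
    fully = (raw.p < alpha) and (part_x.p >= alpha) and (part_m.p < alpha)
    return {
        "x": x, "mediator": m, "y": y,
        "r_xy": raw.r, "p_xy": raw.p,
        "partial_r_xy_given_m": part_x.r, "partial_p_xy_given_m": part_x.p,
        "partial_r_my_given_x": part_m.r, "partial_p_my_given_x": part_m.p,
        "fully_mediated": bool(fully),
        "n": raw.n,
    }


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def _safe(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (ValueError, KeyError):
        return None


def results_report(
    table: pd.DataFrame,
    ku_vs_kt: Optional[ModelComparison] = None,
    perturb_vs_ku: Optional[ModelComparison] = None,
    near_zero_u: float = NEAR_ZERO_U,
) -> dict:
    """Machine-readable summary of the headline population statistics.

    Every number is recomputable from the (serialized) population table, plus
    the optional model-comparison summaries.
    """
    rep: dict = {"n": int(len(table))}
    if "m1" in table:
        m1 = table["m1"].dropna()
        rep["mean_m1"] = float(m1.mean())
        rep["sd_m1"] = float(m1.std(ddof=1))
    if "u1" in table:
        u1 = table["u1"].dropna()
        rep["mean_u1"] = float(u1.mean())
        rep["near_zero_u_fraction"] = float((u1 < near_zero_u).mean())
    if "kt_T" in table:
        rep["mean_T"] = float(table["kt_T"].dropna().mean())
        rep["sd_T"] = float(table["kt_T"].dropna().std(ddof=1))
    a = _safe(association_stats, table, "kt_k", "kt_lnT")
    if a:
        rep["r_kt_k_lnT"] = a.r
        rep["p_kt_k_lnT"] = a.p
    a = _safe(association_stats, table, "m1", "u1")
    if a:
        rep["r_m1_u1"] = a.r
        rep["p_m1_u1"] = a.p
    if "u1" in table and "kt_lnT" in table:
        a = _safe(association_stats, table, "u1", "kt_lnT")
        if a:
            rep["r_u1_lnT"] = a.r
            rep["p_u1_lnT"] = a.p
    if "ps_sigma_r" in table:
        rep["mean_sigma_r"] = float(table["ps_sigma_r"].dropna().mean())
    if "shift_toward" in table and "ps_u" in table and "ps_sigma_r" in table:
        a = _safe(association_stats, table, "shift_toward", "ps_u", ["ps_sigma_r"])
        if a:
            rep["partial_r_shift_u"] = a.r
            rep["partial_p_shift_u"] = a.p
        a = _safe(association_stats, table, "shift_toward", "ps_sigma_r", ["ps_u"])
        if a:
            rep["partial_r_shift_sigma_r"] = a.r
            rep["partial_p_shift_sigma_r"] = a.p
    if "age" in table and table["age"].notna().any():
        a = _safe(association_stats, table, "m1", "age")
        if a:
            rep["r_m1_age"] = a.r
            rep["p_m1_age"] = a.p
        if "shift_raw" in table:
            tbl = table.assign(abs_shift=table["shift_raw"].abs())
            a = _safe(association_stats, tbl, "abs_shift", "age")
            if a:
                rep["r_abs_shift_age"] = a.r
                rep["p_abs_shift_age"] = a.p
            if "ps_u" in table:
                med = _safe(mediation_by_partial, tbl, "age", "ps_u", "abs_shift")
                if med:
                    rep["age_mediation"] = med
    if ku_vs_kt is not None:
        rep["ku_vs_kt"] = {
            "frac_ku_better_loglik": ku_vs_kt.frac_a_better,
            "sem": ku_vs_kt.frac_a_better_sem,
            "wilcoxon_p": ku_vs_kt.wilcoxon_p,
            "total_delta_bic": ku_vs_kt.total_delta_bic,
            "n": ku_vs_kt.n,
        }
    if perturb_vs_ku is not None:
        rep["perturb_vs_ku"] = {
            "frac_perturb_dbic_gt2": perturb_vs_ku.frac_a_dbic_gt2,
            "frac_perturb_dbic_gt6": perturb_vs_ku.frac_a_dbic_gt6,
            "n": perturb_vs_ku.n,
        }
    return rep


def format_report(rep: dict) -> str:
    """Plain-text rendering of :func:`results_report` output."""
    lines = [f"Population report (n = {rep.get('n', '?')})"]
    def fmt(key, label, pat="{:.3g}"):
        if key in rep:
            lines.append(f"  {label}: " + pat.format(rep[key]))
    fmt("mean_m1", "mean m1 (ln K, phase 1)")
    fmt("sd_m1", "SD m1")
    fmt("mean_u1", "mean u1 (taste uncertainty)")
    fmt("near_zero_u_fraction", "fraction with near-zero u")
    fmt("mean_T", "mean softmax T")
    if "r_kt_k_lnT" in rep:
        lines.append(
            f"  r(kt k, ln T) = {rep['r_kt_k_lnT']:.3f} (p = {rep['p_kt_k_lnT']:.2g})"
        )
    if "r_m1_u1" in rep:
        lines.append(f"  r(m1, u1) = {rep['r_m1_u1']:.3f} (p = {rep['p_m1_u1']:.2g})")
    if "partial_r_shift_u" in rep:
        lines.append(
            f"  partial r(shift, u; sigma_r) = {rep['partial_r_shift_u']:.3f} "
            f"(p = {rep['partial_p_shift_u']:.2g})"
        )
    if "partial_r_shift_sigma_r" in rep:
        lines.append(
            f"  partial r(shift, sigma_r; u) = {rep['partial_r_shift_sigma_r']:.3f} "
            f"(p = {rep['partial_p_shift_sigma_r']:.2g})"
        )
    fmt("mean_sigma_r", "mean reference dispersion sigma_r")
    if "ku_vs_kt" in rep:
        c = rep["ku_vs_kt"]
        lines.append(
            f"  KU better log-likelihood in {100 * c['frac_ku_better_loglik']:.1f}% "
            f"of {c['n']} participants (SEM {100 * c['sem']:.1f}%, "
            f"Wilcoxon p = {c['wilcoxon_p']:.2g}, total dBIC = {c['total_delta_bic']:.1f})"
        )
    if "perturb_vs_ku" in rep:
        c = rep["perturb_vs_ku"]
        lines.append(
            f"  perturbation model dBIC > 2 in {100 * c['frac_perturb_dbic_gt2']:.1f}% "
            f"and > 6 in {100 * c['frac_perturb_dbic_gt6']:.1f}% of {c['n']}"
        )
    return "\n".join(lines)
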